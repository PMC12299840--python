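"""Per-linker and per-CBM1 descriptors.

Covers linker length and amino-acid composition, N-glycosylation sequon
(Asn-X-Ser/Thr) scanning with the X=Pro exception, a per-column conservation
profile for aligned CBM1 sequences, and the CBM1 hallmark check (QCGG core,
four disulfide-forming cysteines, three cellulose-binding aromatics).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ghx.seqio import STANDARD_AA

MAX_IC_BITS = math.log2(20.0)


@dataclass(frozen=True)
class SequonCall:
    """One Asn-X-Ser/Thr motif; glycosylatable unless X is proline."""

    position: int  # 0-based index of Asn within the linker
    x_residue: str
    glycosylatable: bool


@dataclass
class LinkerFeatures:
    """Length, residue counts/fractions and sequon calls for one linker."""

    id: str
    length: int
    counts: dict[str, int]
    fractions: dict[str, float]
    sequons: list[SequonCall]
    class_label: Optional[str] = None
    has_x: bool = False

    @property
    def n_sequons(self) -> int:
        return len(self.sequons)

    @property
    def n_glycosylatable(self) -> int:
        return sum(1 for s in self.sequons if s.glycosylatable)


def compose(
    linker_sequence: str, rec_id: str = "", class_label: Optional[str] = None
) -> LinkerFeatures:
    """Exact residue counts and fractions for a linker.

    'X' (unknown residue) is excluded from the length and the composition
    denominator and flagged via ``has_x``.  An empty sequence yields length 0
    and empty maps.
    """
    counts = Counter(c for c in linker_sequence if c != "X")
    bad = set(counts) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-amino-acid letters in linker: {sorted(bad)}")
    length = sum(counts.values())
    fractions = {aa: n / length for aa, n in counts.items()} if length else {}
    return LinkerFeatures(
        id=rec_id,
        length=length,
        counts=dict(counts),
        fractions=fractions,
        sequons=scan_sequons(linker_sequence),
        class_label=class_label,
        has_x="X" in linker_sequence,
    )


def scan_sequons(sequence: str) -> list[SequonCall]:
    """All Asn-X-Ser/Thr motifs in a sequence, overlapping ones included.

    A call is glycosylatable iff X (the residue after the Asn) is not
    proline; N-P-S/T is the canonical non-functional sequon.
    """
    calls = []
    for i in range(len(sequence) - 2):
        if sequence[i] == "N" and sequence[i + 2] in "ST":
            x = sequence[i + 1]
            calls.append(SequonCall(position=i, x_residue=x, glycosylatable=x != "P"))
    return calls


def dominant_residues(features: Sequence[LinkerFeatures], k: int = 6) -> list[str]:
    """The ``k`` most abundant residues pooled over all linkers.

    Ranked by total count, ties broken alphabetically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 20:
        raise ValueError("k cannot exceed the 20 standard residues")
    totals: Counter[str] = Counter()
    for f in features:
        totals.update(f.counts)
    ranked = sorted(totals, key=lambda aa: (-totals[aa], aa))
    return ranked[:k]


@dataclass
class ConservationProfile:
    """Per-column residue frequencies, gap fraction and information content.

    ``frequencies`` is an (n_columns x 20) DataFrame over the standard
    residues; each row sums to 1 over non-gap symbols (NaN row when the
    column is all gaps).  ``ic_bits`` is log2(20) minus the Shannon entropy
    of the column's non-gap distribution, in [0, log2 20].
    """

    frequencies: pd.DataFrame
    gap_fraction: np.ndarray
    ic_bits: np.ndarray
    n_sequences: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = self.frequencies.copy()
        out.insert(0, "column", np.arange(1, len(out) + 1))
        out["gap_fraction"] = self.gap_fraction
        out["ic_bits"] = self.ic_bits
        return out


def conservation_profile(rows: Sequence[str]) -> ConservationProfile:
    """Column-wise conservation of an alignment of CBM1 (or any) sequences.

    Gaps ('-') are excluded from the column distribution; the gap fraction is
    reported separately.  All rows must have equal length.
    """
    if not rows:
        raise ValueError("alignment has no rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment rows")
    n = len(rows)
    aa_index = {aa: j for j, aa in enumerate(STANDARD_AA)}
    counts = np.zeros((width, 20), dtype=np.float64)
    gaps = np.zeros(width, dtype=np.float64)
    for row in rows:
        for i, c in enumerate(row.upper()):
            if c == "-":
                gaps[i] += 1
            elif c in aa_index:
                counts[i, aa_index[c]] += 1
            # 'X' contributes to neither residues nor gaps
    nongap = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / nongap[:, None]
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        entropy = -plogp.sum(axis=1)
    ic = MAX_IC_BITS - entropy
    ic[nongap == 0] = np.nan
    return ConservationProfile(
        frequencies=pd.DataFrame(freqs, columns=list(STANDARD_AA)),
        gap_fraction=gaps / n,
        ic_bits=ic,
        n_sequences=n,
    )


@dataclass
class CBM1Hallmarks:
    """Hallmark counts of one CBM1 sequence with advisory flags."""

    n_cysteines: int
    aromatic_count: int
    has_qcgg: bool
    flags: list[str] = field(default_factory=list)


def check_cbm1_hallmarks(cbm1_sequence: str) -> CBM1Hallmarks:
    """Count the conserved CBM1 hallmarks.

    CBM1 carries a QCGG core, four disulfide-forming cysteines, and three
    aromatic residues (W/Y/F) on its flat cellulose-binding face.  Deviations
    are advisory flags, not errors.
    """
    n_cys = cbm1_sequence.count("C")
    n_aromatic = sum(cbm1_sequence.count(a) for a in "WYF")
    has_qcgg = "QCGG" in cbm1_sequence
    flags = []
    if n_cys != 4:
        flags.append(f"expected 4 cysteines, found {n_cys}")
    if n_aromatic < 3:
        flags.append(f"expected >= 3 aromatic residues, found {n_aromatic}")
    if not has_qcgg:
        flags.append("QCGG core missing")
    return CBM1Hallmarks(n_cys, n_aromatic, has_qcgg, flags)


# --- tabular export -------------------------------------------------------


def features_frame(features: Sequence[LinkerFeatures]) -> pd.DataFrame:
    """Flatten per-linker features into a table (one row per linker)."""
    rows = []
    for f in features:
        row = {
            "id": f.id,
            "class": f.class_label if f.class_label is not None else "NA",
            "length": f.length,
            "n_sequons": f.n_sequons,
            "n_glycosylatable": f.n_glycosylatable,
        }
        for aa in STANDARD_AA:
            row[f"count_{aa}"] = f.counts.get(aa, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def sequons_frame(features: Sequence[LinkerFeatures]) -> pd.DataFrame:
    """One row per sequon call; linker positions reported 1-based."""
    rows = [
        {
            "id": f.id,
            "position": s.position + 1,
            "x_residue": s.x_residue,
            "glycosylatable": s.glycosylatable,
        }
        for f in features
        for s in f.sequons
    ]
    return pd.DataFrame(rows, columns=["id", "position", "x_residue", "glycosylatable"])
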