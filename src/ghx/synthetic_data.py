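"""Ground-truth synthetic GH7-like datasets for offline validation.

The generator emulates the statistical structure the downstream analysis
assumes, with every planted quantity recorded:

* proteins with the catalytic-domain / linker / CBM1 architecture, where the
  catalytic region is a lightly diverged copy of a synthetic reference
  containing one FSNIK anchor and two CBH-specific loop windows;
* class-specific linkers — class A (Sordariomycetes-like): shorter and
  Pro/Ala/Asn-enriched; class B (Eurotiomycetes-like): longer and
  Ser/Thr-enriched;
* Asn-X-Ser/Thr sequons planted at a controlled rate with a controlled
  X=Pro fraction, and *only* the planted ones present (accidental sequons
  arising from composition sampling are removed), so sequon truth is exact;
* a C-terminal CBM1 of fixed width with the QCGG core, four cysteines and
  three aromatic positions at fixed sites;
* decoys: QCGG-less, loop-deleted (endoglucanase-like) and N-terminally
  truncated (low reference coverage) records;
* label-mixing Newick trees and saccharification tables with known
  conversions.

All randomness flows from one integer seed through ``numpy``'s PCG64
generator; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ghx.seqio import LabelTable, ProteinRecord, Span, STANDARD_AA
from ghx.segmentation import ReferenceModel
from ghx.linker_features import scan_sequons

# Linker residue frequencies per class.  Class A mirrors a Sordariomycetes-
# like profile (more Pro/Ala/Asn), class B a Eurotiomycetes-like profile
# (more Ser/Thr).  Gly is planted with equal expected per-linker count in
# both classes (length_mean * frequency matched) to provide a known-null
# feature.  Pooled over default sample sizes the expected abundance order is
# T > S > P > A > N > G.
CLASS_A_LINKER_FREQS: dict[str, float] = {
    "T": 0.20, "S": 0.14, "P": 0.22, "A": 0.16, "N": 0.08,
    "G": 0.085, "Q": 0.045, "V": 0.045, "D": 0.025,
}
CLASS_B_LINKER_FREQS: dict[str, float] = {
    "T": 0.30, "S": 0.26, "P": 0.10, "A": 0.10, "N": 0.04,
    "G": 0.0626, "Q": 0.05, "V": 0.05, "D": 0.0374,
}

# Residues used for CBM1 non-hallmark positions: no Cys and no aromatics so
# the hallmark counts are exact by construction.
_CBM1_BODY_ALPHABET = "GSTQNAPLVD"

# Non-proline X residues for planted sequons; excludes N/S/T so planting a
# sequon can never create an overlapping one.
_SEQUON_X_ALPHABET = "AGQV"


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset.

    Defaults mirror the shape of the real comparison: 98 class-A vs 96
    class-B sequences, class-A linkers shorter (mean 28 vs 38 residues,
    SD 4), about 1.2 sequons per linker with 283/297 of them carrying X=Pro,
    and a 430-residue catalytic region diverged from the reference at 5%
    of positions.
    """

    n_class_a: int = 98
    n_class_b: int = 96
    class_a_name: str = "Sordariomycetes"
    class_b_name: str = "Eurotiomycetes"
    linker_mean_a: float = 28.0
    linker_mean_b: float = 38.0
    linker_sd: float = 4.0
    linker_min: int = 12
    linker_freqs_a: dict[str, float] = field(default_factory=lambda: dict(CLASS_A_LINKER_FREQS))
    linker_freqs_b: dict[str, float] = field(default_factory=lambda: dict(CLASS_B_LINKER_FREQS))
    sequon_rate: float = 1.2
    x_pro_prob: float = 283.0 / 297.0
    catalytic_len: int = 430
    cbm1_len: int = 36
    reference_linker_len: int = 30
    mutation_rate: float = 0.05
    decoy_frac_no_qcgg: float = 0.0
    decoy_frac_loop_deleted: float = 0.0
    decoy_frac_truncated: float = 0.0
    truncation_len: int = 130
    seed: int = 1

    def __post_init__(self) -> None:
        for name, freqs in (("linker_freqs_a", self.linker_freqs_a),
                            ("linker_freqs_b", self.linker_freqs_b)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{name} has negative frequencies")
        if self.n_class_a < 0 or self.n_class_b < 0:
            raise ValueError("class sizes must be >= 0")
        if not (0.0 <= self.x_pro_prob <= 1.0):
            raise ValueError("x_pro_prob must be in [0, 1]")
        if self.catalytic_len < 60:
            raise ValueError("catalytic stub too short to host anchors and loop windows")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated record."""

    id: str
    class_label: str
    decoy_type: Optional[str]  # None | no_qcgg | loop_deleted | truncated
    catalytic_span: Span
    linker_span: Span
    cbm1_span: Optional[Span]
    sequon_positions: list[int]  # 0-based within the linker
    sequon_x: list[str]
    passes_filters: bool


@dataclass
class SyntheticDataset:
    records: list[ProteinRecord]
    labels: LabelTable
    truths: list[SyntheticTruth]
    reference: ProteinRecord
    model: ReferenceModel

    def truth_by_id(self) -> dict[str, SyntheticTruth]:
        return {t.id: t for t in self.truths}


def _draw_sequence(rng: np.random.Generator, length: int, freqs: Mapping[str, float]) -> str:
    letters = sorted(freqs)
    probs = np.array([freqs[c] for c in letters], dtype=np.float64)
    probs = probs / probs.sum()
    return "".join(rng.choice(list(letters), size=length, p=probs))


def _remove_accidental_sequons(seq: list[str], rng: np.random.Generator,
                               freqs: Mapping[str, float]) -> None:
    """Replace the Ser/Thr of every N-X-S/T occurrence in place.

    Replacements are drawn from the composition restricted to non-N/S/T
    letters, so the pass cannot create new sequons.  Gly is also excluded so
    that the known-null Gly count is untouched by this correction.
    """
    letters = sorted(c for c in freqs if c not in "NSTG")
    probs = np.array([freqs[c] for c in letters], dtype=np.float64)
    probs = probs / probs.sum()
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 2] in "ST":
            seq[i + 2] = str(rng.choice(letters, p=probs))


def _make_linker(
    rng: np.random.Generator,
    length: int,
    freqs: Mapping[str, float],
    sequon_rate: float,
    x_pro_prob: float,
    max_tries: int = 80,
) -> tuple[str, list[int], list[str]]:
    """Sample a linker with exactly the planted sequons, no accidental ones."""
    for _ in range(max_tries):
        seq = list(_draw_sequence(rng, length, freqs))
        _remove_accidental_sequons(seq, rng, freqs)
        n_target = int(rng.poisson(sequon_rate))
        slots = rng.permutation(max(length - 2, 0))
        planted: list[int] = []
        for p in slots:
            if len(planted) >= n_target:
                break
            # skip slots holding Gly: planting must not disturb the
            # known-null Gly count distribution
            if any(seq[int(p) + j] == "G" for j in range(3)):
                continue
            if all(abs(int(p) - q) >= 3 for q in planted):
                planted.append(int(p))
        planted.sort()
        xs: list[str] = []
        for p in planted:
            x = "P" if rng.random() < x_pro_prob else str(rng.choice(list(_SEQUON_X_ALPHABET)))
            seq[p] = "N"
            seq[p + 1] = x
            seq[p + 2] = "S" if rng.random() < 0.5 else "T"
            xs.append(x)
        linker = "".join(seq)
        calls = scan_sequons(linker)
        if [c.position for c in calls] == planted and [c.x_residue for c in calls] == xs:
            return linker, planted, xs
    raise RuntimeError("failed to plant sequons without side effects")


def _make_cbm1(rng: np.random.Generator, length: int) -> str:
    """A CBM1-like domain: 6-residue leader, QCGG core, 4 Cys, 3 aromatics.

    Hallmark sites are fixed relative to the domain so that equal-length
    CBM1s are directly comparable column-by-column without alignment.
    """
    if length < 30:
        raise ValueError("CBM1 length must be >= 30")
    seq = list(_draw_sequence(rng, length, {c: 1.0 / len(_CBM1_BODY_ALPHABET)
                                            for c in _CBM1_BODY_ALPHABET}))
    seq[6:10] = list("QCGG")  # core; contributes cysteine 1 of 4
    for pos in (18, 24, length - 2):  # remaining disulfide cysteines
        seq[pos] = "C"
    for pos in (4, 13, length - 6):  # cellulose-binding aromatic face
        seq[pos] = str(rng.choice(["W", "Y", "Y"]))
    return "".join(seq)


def _make_catalytic_stub(rng: np.random.Generator, length: int, motif: str = "FSNIK") -> str:
    """Random catalytic region with the anchor motif planted once.

    The motif's last residue sits ``8`` positions before the stub end, so in
    the reference the linker begins exactly at the stub/linker junction.
    """
    comp = {c: 1.0 / 20 for c in STANDARD_AA}
    for _ in range(100):
        seq = list(_draw_sequence(rng, length, comp))
        start = length - 12
        seq[start : start + 5] = list(motif)
        stub = "".join(seq)
        if stub.count(motif) == 1 and "QCGG" not in stub:
            return stub
    raise RuntimeError("could not build a clean catalytic stub")


def _mutate_stub(
    rng: np.random.Generator,
    stub: str,
    rate: float,
    protected: Span,
    motif: str = "FSNIK",
) -> str:
    """Substitute residues at the given per-site rate, keeping anchors clean."""
    for _ in range(50):
        seq = np.array(list(stub))
        mask = rng.random(len(seq)) < rate
        mask[protected.start : protected.end] = False
        for i in np.flatnonzero(mask):
            choices = [c for c in STANDARD_AA if c != seq[i]]
            seq[i] = choices[int(rng.integers(len(choices)))]
        out = "".join(seq)
        if out.count(motif) == 1 and "QCGG" not in out:
            return out
    raise RuntimeError("could not mutate stub without disturbing anchors")


def make_reference(config: GeneratorConfig) -> tuple[ProteinRecord, ReferenceModel]:
    """Build the synthetic Cel7A-like reference and its segmentation model.

    The reference is catalytic stub + 30-residue linker + CBM1, with two
    loop windows inside the stub standing in for the CBH-specific loops.
    """
    rng = np.random.default_rng(config.seed)
    stub = _make_catalytic_stub(rng, config.catalytic_len)
    neutral = {
        aa: (config.linker_freqs_a.get(aa, 0.0) + config.linker_freqs_b.get(aa, 0.0)) / 2.0
        for aa in set(config.linker_freqs_a) | set(config.linker_freqs_b)
    }
    linker, _, _ = _make_linker(rng, config.reference_linker_len, neutral, 0.0, config.x_pro_prob)
    cbm1 = _make_cbm1(rng, config.cbm1_len)
    seq = stub + linker + cbm1
    if seq.count("QCGG") != 1 or seq.count("FSNIK") != 1:
        raise RuntimeError("reference assembly produced ambiguous anchors")
    reference = ProteinRecord(id="synthetic_ref", sequence=seq,
                              description="synthetic Cel7A-like reference")
    loop_windows = [Span(120, 140), Span(200, 220)]
    model = ReferenceModel(reference=reference, loop_windows=loop_windows)
    return reference, model


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full labeled dataset with truth records.

    Class members are complete catalytic-linker-CBM1 proteins; decoys are
    appended after them (QCGG-destroyed, loop-deleted, then truncated), each
    carrying a class label and a truth row flagging it as failing filters.
    """
    reference, model = make_reference(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7**5]))
    stub_ref = reference.sequence[: config.catalytic_len]
    fsnik = model.fsnik_span

    records: list[ProteinRecord] = []
    truths: list[SyntheticTruth] = []
    labels: dict[str, str] = {}

    class_specs = [
        (config.class_a_name, "a", config.n_class_a, config.linker_mean_a, config.linker_freqs_a),
        (config.class_b_name, "b", config.n_class_b, config.linker_mean_b, config.linker_freqs_b),
    ]

    def build_member(rng: np.random.Generator, mean: float, freqs: Mapping[str, float]):
        """One clean record's parts: (stub, linker, cbm1, planted, xs)."""
        for _ in range(50):
            stub = _mutate_stub(rng, stub_ref, config.mutation_rate, fsnik)
            length = max(config.linker_min, int(round(rng.normal(mean, config.linker_sd))))
            linker, planted, xs = _make_linker(
                rng, length, freqs, config.sequon_rate, config.x_pro_prob
            )
            cbm1 = _make_cbm1(rng, config.cbm1_len)
            seq = stub + linker + cbm1
            if seq.count("QCGG") == 1 and seq.count("FSNIK") == 1:
                return stub, linker, cbm1, planted, xs
        raise RuntimeError("could not assemble an unambiguous record")

    for class_name, prefix, n, mean, freqs in class_specs:
        for i in range(n):
            rec_id = f"{prefix}{i:04d}"
            stub, linker, cbm1, planted, xs = build_member(rng, mean, freqs)
            seq = stub + linker + cbm1
            c, l = len(stub), len(linker)
            records.append(ProteinRecord(id=rec_id, sequence=seq, class_label=class_name))
            labels[rec_id] = class_name
            truths.append(SyntheticTruth(
                id=rec_id, class_label=class_name, decoy_type=None,
                catalytic_span=Span(0, c), linker_span=Span(c, c + l),
                cbm1_span=Span(c + l, len(seq)),
                sequon_positions=planted, sequon_x=xs, passes_filters=True,
            ))

    # -- decoys ------------------------------------------------------------
    n_total = config.n_class_a + config.n_class_b
    decoy_plan = [
        ("no_qcgg", int(round(config.decoy_frac_no_qcgg * n_total))),
        ("loop_deleted", int(round(config.decoy_frac_loop_deleted * n_total))),
        ("truncated", int(round(config.decoy_frac_truncated * n_total))),
    ]
    for decoy_type, count in decoy_plan:
        for i in range(count):
            class_name, _, _, mean, freqs = class_specs[i % 2]
            rec_id = f"decoy_{decoy_type}_{i:03d}"
            stub, linker, cbm1, planted, xs = build_member(rng, mean, freqs)
            if decoy_type == "no_qcgg":
                cbm1 = cbm1.replace("QCGG", "QAGG")
                seq = stub + linker + cbm1
                c, l = len(stub), len(linker)
                truth = SyntheticTruth(
                    id=rec_id, class_label=class_name, decoy_type=decoy_type,
                    catalytic_span=Span(0, c), linker_span=Span(c, c + l),
                    cbm1_span=None, sequon_positions=planted, sequon_x=xs,
                    passes_filters=False,
                )
            elif decoy_type == "loop_deleted":
                kept = []
                prev = 0
                for w in model.loop_windows:
                    kept.append(stub[prev : w.start])
                    prev = w.end
                kept.append(stub[prev:])
                stub2 = "".join(kept)
                seq = stub2 + linker + cbm1
                c, l = len(stub2), len(linker)
                truth = SyntheticTruth(
                    id=rec_id, class_label=class_name, decoy_type=decoy_type,
                    catalytic_span=Span(0, c), linker_span=Span(c, c + l),
                    cbm1_span=Span(c + l, len(seq)), sequon_positions=planted,
                    sequon_x=xs, passes_filters=False,
                )
            else:  # truncated
                stub2 = stub[config.truncation_len :]
                seq = stub2 + linker + cbm1
                c, l = len(stub2), len(linker)
                truth = SyntheticTruth(
                    id=rec_id, class_label=class_name, decoy_type=decoy_type,
                    catalytic_span=Span(0, c), linker_span=Span(c, c + l),
                    cbm1_span=Span(c + l, len(seq)), sequon_positions=planted,
                    sequon_x=xs, passes_filters=False,
                )
            records.append(ProteinRecord(id=rec_id, sequence=seq, class_label=class_name))
            labels[rec_id] = class_name
            truths.append(truth)

    return SyntheticDataset(
        records=records, labels=LabelTable(labels), truths=truths,
        reference=reference, model=model,
    )


def truth_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    """Truth records as a table (coordinates 1-based inclusive, NA = absent)."""
    rows = []
    for t in truths:
        cs, ce = t.catalytic_span.to_one_based()
        ls, le = t.linker_span.to_one_based()
        if t.cbm1_span is not None:
            bs, be = t.cbm1_span.to_one_based()
        else:
            bs = be = "NA"
        rows.append({
            "id": t.id, "class": t.class_label,
            "decoy_type": t.decoy_type or "none",
            "catalytic_start": cs, "catalytic_end": ce,
            "linker_start": ls, "linker_end": le,
            "cbm1_start": bs, "cbm1_end": be,
            "sequon_positions": ",".join(str(p + 1) for p in t.sequon_positions) or ".",
            "sequon_x": ",".join(t.sequon_x) or ".",
            "passes_filters": t.passes_filters,
        })
    return pd.DataFrame(rows)


# --- trees ----------------------------------------------------------------


def _random_binary_newick(rng: np.random.Generator, leaves: list[str],
                          with_supports: bool) -> str:
    """Random binary topology over the given leaves, unit branch lengths."""
    def build(sub: list[str]) -> str:
        if len(sub) == 1:
            return f"{sub[0]}:1.0"
        cut = int(rng.integers(1, len(sub)))
        left, right = build(sub[:cut]), build(sub[cut:])
        support = str(int(rng.integers(0, 101))) if with_supports else ""
        return f"({left},{right}){support}:1.0"
    return build(leaves)


def generate_tree(
    labels: Mapping[str, str] | LabelTable,
    mixing: float,
    seed: int,
    with_supports: bool = True,
) -> str:
    """A Newick tree whose class interleaving is controlled by ``mixing``.

    ``mixing = 0`` places each class in its own clade (monophyletic);
    ``mixing = 1`` shuffles all leaves onto a random topology; intermediate
    values swap ``round(mixing * min(n1, n2) / 2)`` leaf pairs across the two
    class clades (half-swapped clades are maximally interleaved, so the swap
    count saturates at that point).  Internal nodes optionally carry integer
    support labels drawn uniformly from 0-100.
    """
    if not (0.0 <= mixing <= 1.0):
        raise ValueError(f"mixing must be in [0, 1], got {mixing}")
    table = labels.labels if isinstance(labels, LabelTable) else dict(labels)
    classes = sorted(set(table.values()))
    if len(classes) != 2:
        raise ValueError("tree generation requires exactly 2 classes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1315423911 % (2**31)]))
    side_a = sorted(i for i, c in table.items() if c == classes[0])
    side_b = sorted(i for i, c in table.items() if c == classes[1])
    if min(len(side_a), len(side_b)) < 2:
        raise ValueError("each class needs >= 2 leaves")

    if mixing >= 1.0:
        leaves = side_a + side_b
        perm = rng.permutation(len(leaves))
        shuffled = [leaves[i] for i in perm]
        root_support = "100" if with_supports else ""
        return f"({_random_binary_newick(rng, shuffled, with_supports)}){root_support};"

    n_swap = int(round(mixing * min(len(side_a), len(side_b)) / 2))
    ia = rng.choice(len(side_a), size=n_swap, replace=False)
    ib = rng.choice(len(side_b), size=n_swap, replace=False)
    for x, y in zip(ia, ib):
        side_a[int(x)], side_b[int(y)] = side_b[int(y)], side_a[int(x)]
    sub_a = _random_binary_newick(rng, [side_a[i] for i in rng.permutation(len(side_a))],
                                  with_supports)
    sub_b = _random_binary_newick(rng, [side_b[i] for i in rng.permutation(len(side_b))],
                                  with_supports)
    root_support = "100" if with_supports else ""
    return f"({sub_a},{sub_b}){root_support};"


# --- wet-lab fixture tables ------------------------------------------------


def generate_saccharification_table(
    seed: int,
    samples: Sequence[str] = ("wildtype", "mutant1", "mutant2"),
    timepoints: Sequence[float] = (0.0, 6.0, 12.0, 24.0, 48.0, 72.0),
    glucan_load: float = 5.0,
) -> tuple[pd.DataFrame, dict[tuple[str, float], float]]:
    """Sugar time courses with known conversions (inverse-formula planting).

    Each sample follows a saturating conversion curve to a random plateau in
    [30, 60]%; sugar concentrations are back-computed so that the glucan
    conversion of every row equals its planted value exactly.  Returns the
    table and the truth map (sample, time_h) -> conversion percent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 271828]))
    rows = []
    truth: dict[tuple[str, float], float] = {}
    for sample in samples:
        plateau = float(rng.uniform(30.0, 60.0))
        half_time = float(rng.uniform(8.0, 20.0))
        glucose_share = float(rng.uniform(0.7, 0.9))
        for t in timepoints:
            conv = plateau * t / (t + half_time)
            total_corrected = conv / 100.0 * glucan_load  # 0.9*glc + 0.95*cb
            glucose = glucose_share * total_corrected / 0.9
            cellobiose = (1.0 - glucose_share) * total_corrected / 0.95
            rows.append({
                "sample": sample, "time_h": t,
                "glucose_gL": glucose, "cellobiose_gL": cellobiose,
                "glucan_gL": glucan_load,
            })
            truth[(sample, t)] = conv
    return pd.DataFrame(rows), truth
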