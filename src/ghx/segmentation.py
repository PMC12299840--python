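"""Candidate filtering and motif-anchored domain segmentation.

A GH7 cellobiohydrolase I has the architecture

    catalytic domain — linker — CBM1

The CBM1 is anchored on the conserved QCGG motif: it starts six residues
upstream of the rightmost QCGG and runs to the C-terminus.  The linker start
is transferred from a reference sequence: the candidate position aligned to
the last residue of the reference's FSNIK motif, plus eight.  The catalytic
domain is everything before the linker.  Candidates are filtered on QCGG
presence, on coverage of the reference by the candidate (> 80% by default),
and on occupancy of CBH-specific loop regions, which distinguishes
cellobiohydrolases from endoglucanases whose loops are deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from ghx.seqio import ProteinRecord, Span, LabelTable, read_fasta

CBM1_MOTIF = "QCGG"
DEFAULT_CBM1_UPSTREAM_OFFSET = 6
DEFAULT_LINKER_DOWNSTREAM_OFFSET = 8
DEFAULT_COVERAGE_THRESHOLD = 80.0
DEFAULT_LOOP_OCCUPANCY_THRESHOLD = 0.8


@dataclass
class ReferenceModel:
    """Reference sequence plus the anchors and parameters for segmentation.

    Parameters
    ----------
    reference
        A Cel7A-like reference protein containing the FSNIK motif exactly once.
    loop_windows
        Reference spans of the CBH-specific loop regions used to separate
        cellobiohydrolases from endoglucanases.  Sorted, non-overlapping.
    matrix, gap_open, gap_extend
        Global-alignment scoring: substitution matrix name and affine gap
        penalties (a gap of length L costs ``gap_open + (L-1) * gap_extend``).
    """

    reference: ProteinRecord
    fsnik_motif: str = "FSNIK"
    loop_windows: list[Span] = field(default_factory=list)
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    cbm1_upstream_offset: int = DEFAULT_CBM1_UPSTREAM_OFFSET
    linker_downstream_offset: int = DEFAULT_LINKER_DOWNSTREAM_OFFSET
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    loop_occupancy_threshold: float = DEFAULT_LOOP_OCCUPANCY_THRESHOLD
    fsnik_span: Span = field(init=False)

    def __post_init__(self) -> None:
        n = self.reference.sequence.count(self.fsnik_motif)
        if n != 1:
            raise ValueError(
                f"motif {self.fsnik_motif!r} occurs {n} times in reference "
                f"{self.reference.id}; exactly one occurrence required"
            )
        start = self.reference.sequence.index(self.fsnik_motif)
        self.fsnik_span = Span(start, start + len(self.fsnik_motif))
        ref_len = len(self.reference)
        prev_end = -1
        for w in sorted(self.loop_windows, key=lambda s: s.start):
            if w.start < prev_end:
                raise ValueError("loop windows overlap")
            if w.end > ref_len:
                raise ValueError(f"loop window {w} outside reference (len {ref_len})")
            prev_end = w.end
        self.loop_windows = sorted(self.loop_windows, key=lambda s: s.start)

    # -- config file round-trip -------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceModel":
        """Load a reference model config (YAML).

        The config names a reference FASTA (path relative to the config file),
        the anchor motif, offsets, loop windows (1-based inclusive), alignment
        parameters and thresholds.
        """
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        ref_path = Path(cfg["reference_fasta"])
        if not ref_path.is_absolute():
            ref_path = path.parent / ref_path
        records = read_fasta(ref_path)
        ref_id = cfg.get("reference_id", records[0].id)
        by_id = {r.id: r for r in records}
        if ref_id not in by_id:
            raise ValueError(f"reference id {ref_id} not in {ref_path}")
        windows = [
            Span.from_one_based(int(a), int(b)) for a, b in cfg.get("loop_windows", [])
        ]
        return cls(
            reference=by_id[ref_id],
            fsnik_motif=cfg.get("fsnik_motif", "FSNIK"),
            loop_windows=windows,
            matrix=cfg.get("matrix", "BLOSUM62"),
            gap_open=float(cfg.get("gap_open", 10.0)),
            gap_extend=float(cfg.get("gap_extend", 1.0)),
            cbm1_upstream_offset=int(cfg.get("cbm1_upstream_offset", DEFAULT_CBM1_UPSTREAM_OFFSET)),
            linker_downstream_offset=int(
                cfg.get("linker_downstream_offset", DEFAULT_LINKER_DOWNSTREAM_OFFSET)
            ),
            coverage_threshold=float(cfg.get("coverage_threshold", DEFAULT_COVERAGE_THRESHOLD)),
            loop_occupancy_threshold=float(
                cfg.get("loop_occupancy_threshold", DEFAULT_LOOP_OCCUPANCY_THRESHOLD)
            ),
        )

    def to_yaml(self, path: str | Path, reference_fasta: str) -> None:
        """Write the model config; ``reference_fasta`` is stored as given."""
        cfg = {
            "reference_fasta": reference_fasta,
            "reference_id": self.reference.id,
            "fsnik_motif": self.fsnik_motif,
            "loop_windows": [list(w.to_one_based()) for w in self.loop_windows],
            "matrix": self.matrix,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "cbm1_upstream_offset": self.cbm1_upstream_offset,
            "linker_downstream_offset": self.linker_downstream_offset,
            "coverage_threshold": self.coverage_threshold,
            "loop_occupancy_threshold": self.loop_occupancy_threshold,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two gapped rows of equal length."""

    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("gapped rows differ in length")
        # ref_to_query[i] = query index aligned to reference position i, or -1
        mapping = np.full(len(self.aligned_ref.replace("-", "")), -1, dtype=np.int64)
        qi = ri = 0
        for qc, rc in zip(self.aligned_query, self.aligned_ref):
            if rc != "-":
                if qc != "-":
                    mapping[ri] = qi
                ri += 1
            if qc != "-":
                qi += 1
        self.ref_to_query = mapping

    def map_ref_position(self, ref_index: int) -> int:
        """Query index aligned to ``ref_index``; -1 if it aligns to a gap."""
        return int(self.ref_to_query[ref_index])


@dataclass
class DomainAnnotation:
    """Segmentation result and filter flags for one candidate."""

    id: str
    has_qcgg: bool = False
    catalytic_span: Optional[Span] = None
    linker_span: Optional[Span] = None
    cbm1_span: Optional[Span] = None
    ref_coverage_pct: Optional[float] = None
    loop_occupancy: Optional[float] = None
    is_cbh: bool = False
    passed_filters: bool = False
    notes: list[str] = field(default_factory=list)


def _make_aligner(model: ReferenceModel) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(model.matrix)
    aligner.open_gap_score = -model.gap_open
    aligner.extend_gap_score = -model.gap_extend
    return aligner


def align_to_reference(query: ProteinRecord, model: ReferenceModel) -> PairwiseAlignment:
    """Globally align a candidate to the reference with affine gap penalties.

    Deterministic: among co-optimal alignments the first in the aligner's
    canonical traversal order is taken, so repeated runs give identical
    coordinates.
    """
    aligner = _make_aligner(model)
    aln = aligner.align(query.sequence, model.reference.sequence)[0]
    return PairwiseAlignment(
        query_id=query.id,
        ref_id=model.reference.id,
        aligned_query=str(aln[0]),
        aligned_ref=str(aln[1]),
        score=float(aln.score),
    )


def reference_coverage(aln: PairwiseAlignment) -> float:
    """Percent of reference positions aligned to a candidate residue.

    Mirrors the query-coverage filter applied after homology search: the
    reference is the search query, so coverage is measured on it.
    """
    n_ref = len(aln.ref_to_query)
    return 100.0 * float(np.count_nonzero(aln.ref_to_query >= 0)) / n_ref


def find_cbm1(
    record: ProteinRecord, upstream_offset: int = DEFAULT_CBM1_UPSTREAM_OFFSET
) -> Optional[Span]:
    """Locate the CBM1 span: from ``upstream_offset`` residues before the
    rightmost QCGG motif to the C-terminus.

    The rightmost occurrence anchors the domain because CBM1 is C-terminal.
    Returns ``None`` when QCGG is absent or too close to the N-terminus.
    """
    q = record.sequence.rfind(CBM1_MOTIF)
    if q < 0 or q < upstream_offset:
        return None
    return Span(q - upstream_offset, len(record.sequence))


def find_linker(
    record: ProteinRecord,
    cbm1: Span,
    aln: PairwiseAlignment,
    model: ReferenceModel,
) -> tuple[Optional[Span], list[str]]:
    """Locate the linker span by transferring the FSNIK anchor.

    Let ``k`` be the reference index of the motif's last residue and ``p``
    the candidate index aligned to it.  If ``k`` aligns to a gap, the nearest
    mapped reference position at or before ``k`` is used (noted).  The linker
    is ``[p + offset, cbm1.start)``; a zero/negative-length interval yields
    ``None`` with a note.
    """
    notes: list[str] = []
    k = model.fsnik_span.end - 1
    p = aln.map_ref_position(k)
    if p < 0:
        for j in range(k - 1, -1, -1):
            p = aln.map_ref_position(j)
            if p >= 0:
                notes.append(f"FSNIK anchor gapped; used reference position {j + 1}")
                break
        if p < 0:
            notes.append("no mapped reference position at or before FSNIK anchor")
            return None, notes
    start = p + model.linker_downstream_offset
    if start >= cbm1.start:
        notes.append("zero-length linker")
        return None, notes
    return Span(start, cbm1.start), notes


def classify_cbh(aln: PairwiseAlignment, model: ReferenceModel) -> tuple[float, bool]:
    """Fraction of CBH-specific loop positions occupied by candidate residues.

    Endoglucanases lack these loops, so a candidate whose alignment leaves
    them largely unoccupied is flagged ``is_cbh=False``.
    """
    if not model.loop_windows:
        raise ValueError("reference model lacks loop definitions")
    total = occupied = 0
    for w in model.loop_windows:
        seg = aln.ref_to_query[w.start : w.end]
        total += len(seg)
        occupied += int(np.count_nonzero(seg >= 0))
    occupancy = occupied / total
    return occupancy, occupancy >= model.loop_occupancy_threshold


def segment_dataset(
    records: list[ProteinRecord],
    model: ReferenceModel,
    labels: Optional[LabelTable] = None,
) -> list[DomainAnnotation]:
    """Filter and segment a candidate set.

    Filters apply in order: QCGG presence, reference coverage above the
    threshold, CBH loop occupancy.  A record failing a step is annotated
    ``passed_filters=False`` with the failing step noted; per-record failures
    never abort the batch.  For passing records the three spans partition the
    sequence: catalytic ``[0, linker.start)``, linker, CBM1 to the C-terminus.
    """
    annotations: list[DomainAnnotation] = []
    for rec in records:
        if labels is not None and rec.id in labels:
            rec.class_label = labels[rec.id]
        ann = DomainAnnotation(id=rec.id)
        cbm1 = find_cbm1(rec, model.cbm1_upstream_offset)
        ann.has_qcgg = CBM1_MOTIF in rec.sequence
        ann.cbm1_span = cbm1
        if cbm1 is None:
            ann.notes.append(
                "filter:no-QCGG" if not ann.has_qcgg else "filter:QCGG-too-close-to-N-terminus"
            )
            ann.passed_filters = False
            annotations.append(ann)
            continue

        aln = align_to_reference(rec, model)
        ann.ref_coverage_pct = reference_coverage(aln)
        if ann.ref_coverage_pct <= model.coverage_threshold:
            ann.notes.append("filter:low-coverage")
            ann.passed_filters = False
            annotations.append(ann)
            continue

        ann.loop_occupancy, ann.is_cbh = classify_cbh(aln, model)
        if not ann.is_cbh:
            ann.notes.append("filter:loops-absent")
            ann.passed_filters = False
            annotations.append(ann)
            continue

        linker, notes = find_linker(rec, cbm1, aln, model)
        ann.notes.extend(notes)
        ann.linker_span = linker
        if linker is not None:
            ann.catalytic_span = Span(0, linker.start)
        ann.passed_filters = True
        annotations.append(ann)
    return annotations
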