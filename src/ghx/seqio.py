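"""Sequence and table I/O plus the shared coordinate convention.

Internally every interval is a :class:`Span`: 0-based, half-open
``[start, end)``.  All human-facing tables use 1-based inclusive
coordinates (``start+1 .. end``); the conversion is a bijection and is
confined to this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters accepted on ingestion ('X' = unknown residue, tolerated but
#: excluded from composition denominators downstream).
ALLOWED_LETTERS = frozenset(STANDARD_AA + "X")


@dataclass(frozen=True)
class Span:
    """0-based half-open interval ``[start, end)`` on a sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def to_one_based(self) -> tuple[int, int]:
        """Return the 1-based inclusive (start, end) pair used in output tables."""
        return self.start + 1, self.end

    @classmethod
    def from_one_based(cls, start: int, end: int) -> "Span":
        """Build a span from 1-based inclusive coordinates."""
        return cls(start - 1, end)

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class ProteinRecord:
    """One candidate sequence with an id and optional taxonomic class label."""

    id: str
    sequence: str
    description: str = ""
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be non-empty without whitespace: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = sorted(set(self.sequence) - ALLOWED_LETTERS)
        if bad:
            raise ValueError(
                f"record {self.id}: non-amino-acid letters {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_x(self) -> bool:
        return "X" in self.sequence


@dataclass
class LabelTable:
    """Mapping from sequence id to taxonomic class label."""

    labels: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, rec_id: str) -> str:
        return self.labels[rec_id]

    def get(self, rec_id: str, default: Optional[str] = None) -> Optional[str]:
        return self.labels.get(rec_id, default)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        """Distinct class labels, sorted."""
        return sorted(set(self.labels.values()))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The id is the token before the first whitespace in the header; the
    remainder is stored as the description.  Letters are uppercased and a
    single terminal ``'*'`` stop symbol is stripped.

    Raises
    ------
    ValueError
        On duplicate ids, an empty file, or letters outside the 20 standard
        amino acids plus ``'X'``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping (deterministic output)."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        for rec in seq_records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_labels(path: str | Path) -> LabelTable:
    """Read a two-column (id, class) TSV into a :class:`LabelTable`.

    Lines starting with ``'#'`` are comments.  An empty file yields an empty
    table with a warning; a row with a column count other than two is an
    error naming the line.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rec_id, label = parts[0].strip(), parts[1].strip()
            if not rec_id:
                raise ValueError(f"{path}:{lineno}: empty id")
            labels[rec_id] = label
    if not labels:
        warnings.warn(f"label table {path} is empty", stacklevel=2)
    return LabelTable(labels)


def write_labels(table: LabelTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id\tclass\n")
        for rec_id in sorted(table.labels):
            fh.write(f"{rec_id}\t{table.labels[rec_id]}\n")


# --- annotation table I/O -------------------------------------------------

ANNOTATION_COLUMNS = [
    "id",
    "has_qcgg",
    "catalytic_start",
    "catalytic_end",
    "linker_start",
    "linker_end",
    "cbm1_start",
    "cbm1_end",
    "ref_coverage_pct",
    "loop_occupancy",
    "is_cbh",
    "passed_filters",
    "notes",
]


def _span_cols(span: Optional[Span]) -> tuple[str, str]:
    if span is None:
        return "NA", "NA"
    s, e = span.to_one_based()
    return str(s), str(e)


def write_annotations(annotations, path: str | Path) -> None:
    """Write domain annotations as a TSV with 1-based inclusive coordinates.

    Header comment lines start with ``'#'``; missing spans are ``NA``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# Domain annotations; coordinates are 1-based inclusive; NA = absent\n")
        fh.write("# " + "\t".join(ANNOTATION_COLUMNS) + "\n")
        for ann in annotations:
            cs, ce = _span_cols(ann.catalytic_span)
            ls, le = _span_cols(ann.linker_span)
            bs, be = _span_cols(ann.cbm1_span)
            row = [
                ann.id,
                str(ann.has_qcgg).lower(),
                cs,
                ce,
                ls,
                le,
                bs,
                be,
                f"{ann.ref_coverage_pct:.4f}" if ann.ref_coverage_pct is not None else "NA",
                f"{ann.loop_occupancy:.4f}" if ann.loop_occupancy is not None else "NA",
                str(ann.is_cbh).lower(),
                str(ann.passed_filters).lower(),
                ";".join(ann.notes) if ann.notes else ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_annotations(path: str | Path):
    """Parse back a TSV written by :func:`write_annotations` (round-trip check)."""
    from ghx.segmentation import DomainAnnotation  # local import: avoid cycle

    path = Path(path)
    out = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(ANNOTATION_COLUMNS):
                raise ValueError(f"malformed annotation row: {raw!r}")

            def span_of(a: str, b: str) -> Optional[Span]:
                if a == "NA" or b == "NA":
                    return None
                return Span.from_one_based(int(a), int(b))

            out.append(
                DomainAnnotation(
                    id=f[0],
                    has_qcgg=f[1] == "true",
                    catalytic_span=span_of(f[2], f[3]),
                    linker_span=span_of(f[4], f[5]),
                    cbm1_span=span_of(f[6], f[7]),
                    ref_coverage_pct=None if f[8] == "NA" else float(f[8]),
                    loop_occupancy=None if f[9] == "NA" else float(f[9]),
                    is_cbh=f[10] == "true",
                    passed_filters=f[11] == "true",
                    notes=[] if f[12] == "." else f[12].split(";"),
                )
            )
    return out
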