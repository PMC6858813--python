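"""Sequence and region-annotation I/O.

Defines the coordinate system used throughout the package: transcript
positions are 1-based and count from the first nucleotide of the 5'UTR
(or of the CDS when the transcript has no 5'UTR).  All sequences are
normalized to the RNA alphabet A/C/G/U (plus N for ambiguity) in
5'->3' orientation.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import BoundsError, FormatError, ValidationError

RNA_ALPHABET = frozenset("ACGUN")

#: miRNA identifiers like ``ID03332.3p-miR`` come from de-novo prediction
#: surveys rather than miRBase; ``miR-``/``let-`` prefixed names are the
#: registry convention.
_NOVEL_ID = re.compile(r"^I?D\d{5}\.")
_MIRBASE_ID = re.compile(r"^(hsa-)?(miR-|let-)", re.IGNORECASE)


class Origin(str, enum.Enum):
    MIRBASE = "mirbase"
    NOVEL = "novel"
    UNKNOWN = "unknown"


class RegionLabel(str, enum.Enum):
    """Transcript region containing a position: leader, coding, trailer."""

    UTR5 = "5'UTR"
    CDS = "CDS"
    UTR3 = "3'UTR"

    @classmethod
    def from_string(cls, text: str) -> "RegionLabel":
        key = text.strip().replace("′", "'").upper()
        mapping = {
            "5'UTR": cls.UTR5,
            "UTR5": cls.UTR5,
            "CDS": cls.CDS,
            "3'UTR": cls.UTR3,
            "UTR3": cls.UTR3,
        }
        if key not in mapping:
            raise FormatError(f"unknown region label: {text!r}")
        return mapping[key]


def classify_origin(mirna_id: str) -> Origin:
    if _NOVEL_ID.match(mirna_id):
        return Origin.NOVEL
    if _MIRBASE_ID.match(mirna_id):
        return Origin.MIRBASE
    return Origin.UNKNOWN


def normalize_sequence(seq: str, *, record_id: str = "?") -> str:
    """Uppercase, DNA->RNA (T->U), and validate against A/C/G/U/N."""
    out = seq.upper().replace("T", "U")
    for i, ch in enumerate(out, start=1):
        if ch not in RNA_ALPHABET:
            raise ValidationError(
                f"record {record_id!r}: invalid character {ch!r} at position {i}"
            )
    return out


@dataclass(frozen=True)
class MiRNA:
    """A microRNA: short regulatory RNA, stored 5'->3'."""

    id: str
    sequence: str
    origin: Origin = Origin.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence, record_id=self.id))
        if len(self.sequence) < 1:
            raise ValidationError(f"miRNA {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Transcript:
    """An mRNA with 5'UTR/CDS/3'UTR boundaries and optional expression metadata.

    ``rpkm`` (reads per kilobase per million mapped reads) is carried
    through to reports but never used in any computation.
    """

    id: str
    sequence: str
    gene: str = ""
    utr5_len: int = 0
    cds_len: int = 0
    utr3_len: int = 0
    rpkm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence, record_id=self.id))
        if not self.gene:
            object.__setattr__(self, "gene", self.id)
        for name in ("utr5_len", "cds_len", "utr3_len"):
            if getattr(self, name) < 0:
                raise ValidationError(f"transcript {self.id!r}: {name} must be >= 0")
        total = self.utr5_len + self.cds_len + self.utr3_len
        if total != len(self.sequence):
            raise ValidationError(
                f"transcript {self.id!r}: region lengths sum to {total}, "
                f"sequence is {len(self.sequence)} nt"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionInfo:
    utr5_len: int
    cds_len: int
    utr3_len: int
    rpkm: float | None = None


def position_region(t: Transcript, pos: int) -> RegionLabel:
    """Region containing 1-based transcript position ``pos``."""
    if not 1 <= pos <= t.length:
        raise BoundsError(f"position {pos} outside transcript {t.id!r} [1, {t.length}]")
    if pos <= t.utr5_len:
        return RegionLabel.UTR5
    if pos <= t.utr5_len + t.cds_len:
        return RegionLabel.CDS
    return RegionLabel.UTR3


def _iter_fasta(path: Path) -> Iterable[SeqRecord]:
    # Biopython tolerates some malformed input silently; pre-check that the
    # first non-blank line opens a record so errors name the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: line {lineno}: expected FASTA header '>'")
                break
    yield from SeqIO.parse(str(path), "fasta")


def read_fasta(path: str | Path, kind: str = "mirna") -> list[MiRNA] | list[SeqRecord]:
    """Read a multi-record FASTA, normalizing to the RNA alphabet.

    ``kind='mirna'`` returns :class:`MiRNA` objects; ``kind='transcript'``
    returns normalized raw records (id, sequence) awaiting region
    annotation via :func:`assemble_transcripts`.
    """
    path = Path(path)
    if kind not in ("mirna", "transcript"):
        raise ValueError(f"kind must be 'mirna' or 'transcript', got {kind!r}")
    seen: set[str] = set()
    records = []
    for rec in _iter_fasta(path):
        rid = rec.id  # header token up to first whitespace
        if rid in seen:
            raise ValidationError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = normalize_sequence(str(rec.seq), record_id=rid)
        if kind == "mirna":
            records.append(MiRNA(id=rid, sequence=seq, origin=classify_origin(rid)))
        else:
            records.append(SeqRecord(Seq(seq), id=rid, description=""))
    return records


def write_fasta(records: Iterable[MiRNA | Transcript | SeqRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(SeqRecord(Seq(str(rec.seq)), id=rec.id, description=""))
        else:
            out.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=""))
    SeqIO.write(out, str(Path(path)), "fasta")


def load_regions(path: str | Path) -> dict[str, RegionInfo]:
    """Load the region-annotation sidecar TSV.

    Columns: ``transcript_id  utr5_len  cds_len  utr3_len  rpkm`` (rpkm
    optional; empty cells recorded as absent).
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "utr5_len", "cds_len", "utr3_len"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, RegionInfo] = {}
    for _, row in df.iterrows():
        tid = row["transcript_id"]
        lens = {}
        for col in ("utr5_len", "cds_len", "utr3_len"):
            val = int(row[col])
            if val < 0:
                raise ValidationError(f"{path}: {tid}: {col} is negative")
            lens[col] = val
        rpkm = None
        if "rpkm" in df.columns and pd.notna(row.get("rpkm")):
            rpkm = float(row["rpkm"])
            if rpkm < 0:
                raise ValidationError(f"{path}: {tid}: rpkm is negative")
        out[tid] = RegionInfo(lens["utr5_len"], lens["cds_len"], lens["utr3_len"], rpkm)
    return out


def assemble_transcripts(
    records: Iterable[SeqRecord],
    regions: Mapping[str, RegionInfo],
    *,
    gene_of: Mapping[str, str] | None = None,
) -> list[Transcript]:
    """Join raw transcript records with their region annotations.

    Region-sum/sequence-length mismatches are detected here (Transcript
    construction enforces the invariant).
    """
    out = []
    for rec in records:
        if rec.id not in regions:
            raise ValidationError(f"no region annotation for transcript {rec.id!r}")
        info = regions[rec.id]
        gene = (gene_of or {}).get(rec.id, rec.id)
        out.append(
            Transcript(
                id=rec.id,
                sequence=str(rec.seq),
                gene=gene,
                utr5_len=info.utr5_len,
                cds_len=info.cds_len,
                utr3_len=info.utr3_len,
                rpkm=info.rpkm,
            )
        )
    return out


def write_regions(regions: Mapping[str, RegionInfo], path: str | Path) -> None:
    rows = []
    for tid, info in regions.items():
        rows.append(
            {
                "transcript_id": tid,
                "utr5_len": info.utr5_len,
                "cds_len": info.cds_len,
                "utr3_len": info.utr3_len,
                "rpkm": "" if info.rpkm is None else info.rpkm,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
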