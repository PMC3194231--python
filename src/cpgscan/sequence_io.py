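"""Sequence and table I/O: FASTA in/out, BED output, methylation tables.

Coordinates are 0-based half-open internally and in BED; the human-readable
TSV report uses 1-based inclusive coordinates. IUPAC ambiguity codes other
than N are collapsed to N (the HMM cannot emit them); soft-masked lowercase
bases are kept as their uppercase base unless ``hard_mask`` is requested.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from cpgscan.island_scan import CpgIsland

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

# uppercase IUPAC codes that collapse to N (everything valid that is not ACGT)
_AMBIGUOUS = set("RYSWKMBDHVN")

_NORMALIZE_UPPER = str.maketrans(
    {c: ("N" if c in _AMBIGUOUS else c) for c in _AMBIGUOUS | set(BASES)}
)


class SequenceError(ValueError):
    """Malformed or empty sequence input."""


class TableError(ValueError):
    """Malformed methylation table input."""


@dataclass(frozen=True)
class GenomicSequence:
    """A normalized DNA sequence: residues over {A,C,G,T,N}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ObservationSequence:
    """Integer-coded bases (A=0, C=1, G=2, T=3) with an N mask.

    Masked positions carry an arbitrary code (0) and are excluded from
    likelihood computation and island calls.
    """

    bases: np.ndarray  # int8, shape (L,)
    mask: np.ndarray  # bool, shape (L,); True where residue was N

    def __len__(self) -> int:
        return len(self.bases)


def normalize_residues(raw: str, hard_mask: bool = False) -> str:
    """Uppercase, collapse ambiguity codes to N; optionally N out lowercase."""
    if hard_mask:
        raw = "".join("N" if c.islower() else c for c in raw)
    upper = raw.upper()
    out = []
    for c in upper:
        if c in BASE_TO_CODE:
            out.append(c)
        elif c in _AMBIGUOUS:
            out.append("N")
        else:
            raise SequenceError(f"invalid residue {c!r}")
    return "".join(out)


def read_fasta(path: str | Path, hard_mask: bool = False) -> list[GenomicSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Raises :class:`SequenceError` for a missing/empty file or a record with
    an empty sequence, naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise SequenceError(f"record {rec.id!r} has an empty sequence")
        out.append(GenomicSequence(rec.id, normalize_residues(str(rec.seq), hard_mask)))
    return out


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def encode(seq: GenomicSequence) -> ObservationSequence:
    """Map residues to integer codes with an N mask."""
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    mask = arr == ord("N")
    codes = np.zeros(len(arr), dtype=np.int8)
    for base, code in BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    codes[mask] = 0
    return ObservationSequence(bases=codes, mask=mask)


def write_bed(islands: "Iterable[CpgIsland]", path: str | Path) -> None:
    """Write islands as BED3+ (extra columns: length, GC%, Obs/Exp, I-fraction)."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.island_id}\t"
                f"{isl.length}\t{isl.gc_content * 100:.2f}\t"
                f"{isl.obs_exp:.4f}\t{isl.island_fraction:.4f}\n"
            )


def write_island_tsv(islands: "Iterable[CpgIsland]", path: str | Path) -> None:
    """Human-readable report, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("island_id\tchrom\tstart\tend\tlength\tgc_percent\tobs_exp\ti_fraction\n")
        for isl in islands:
            fh.write(
                f"{isl.island_id}\t{isl.chrom}\t{isl.start + 1}\t{isl.end}\t"
                f"{isl.length}\t{isl.gc_content * 100:.2f}\t"
                f"{isl.obs_exp:.4f}\t{isl.island_fraction:.4f}\n"
            )


def read_island_tsv(path: str | Path) -> "list[CpgIsland]":
    from cpgscan.island_scan import CpgIsland

    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                CpgIsland(
                    chrom=row["chrom"],
                    start=int(row["start"]) - 1,
                    end=int(row["end"]),
                    gc_content=float(row["gc_percent"]) / 100.0,
                    obs_exp=float(row["obs_exp"]),
                    island_fraction=float(row["i_fraction"]),
                    island_id=row["island_id"],
                )
            )
    return out


def export_island_fasta(
    islands: "Iterable[CpgIsland]", seq: GenomicSequence, path: str | Path
) -> None:
    """Export island slices as FASTA records ``<id>:<start>-<end>`` for
    external motif tools (MEME/MAST-style workflows)."""
    records = []
    for isl in islands:
        if isl.start < 0 or isl.end > seq.length:
            raise SequenceError(
                f"island {isl.start}-{isl.end} outside sequence of length {seq.length}"
            )
        records.append(
            SeqRecord(
                Seq(seq.residues[isl.start : isl.end]),
                id=f"{seq.id}:{isl.start}-{isl.end}",
                description="",
            )
        )
    SeqIO.write(records, str(path), "fasta")


@dataclass
class MethylationRecord:
    """One island's methylation score and (possibly unset) status."""

    island_id: str
    score: float
    status: Optional[str] = None  # "methylated" | "unmethylated" | None
    true_status: Optional[str] = field(default=None, compare=False)


_STATUSES = {"methylated", "unmethylated"}


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_methylation_table(path: str | Path) -> list[MethylationRecord]:
    """Read a delimited table with header columns island_id, score[, status].

    The delimiter (comma or tab) is auto-detected from the header line.
    Duplicate ids and non-numeric scores raise :class:`TableError` with the
    offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise TableError(f"methylation table not found: {path}")
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise TableError(f"empty methylation table: {path}")
        delim = _sniff_delimiter(header)
        names = [c.strip() for c in header.rstrip("\n").split(delim)]
        required = {"island_id", "score"}
        if not required.issubset(names):
            raise TableError(f"header must contain island_id and score, got {names}")
        reader = csv.DictReader(fh, fieldnames=names, delimiter=delim)
        out: list[MethylationRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            island_id = (row.get("island_id") or "").strip()
            if not island_id:
                raise TableError(f"row {lineno}: missing island_id")
            if island_id in seen:
                raise TableError(f"row {lineno}: duplicate island_id {island_id!r}")
            seen.add(island_id)
            try:
                score = float(row["score"])
            except (TypeError, ValueError):
                raise TableError(
                    f"row {lineno}: non-numeric score {row.get('score')!r}"
                ) from None
            status = (row.get("status") or "").strip().lower() or None
            if status is not None and status not in _STATUSES:
                raise TableError(f"row {lineno}: unknown status {status!r}")
            out.append(MethylationRecord(island_id, score, status))
    return out


def write_methylation_table(records: Iterable[MethylationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("island_id\tscore\tstatus\n")
        for r in records:
            fh.write(f"{r.island_id}\t{r.score:.6g}\t{r.status or ''}\n")
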