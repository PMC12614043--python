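"""Sequence and interval primitives shared by every pipeline stage.

Assemblies are held in memory as upper-cased sequences plus an explicit
boolean repeat mask recovered from soft-masking (lowercase letters in the
input FASTA).  All coordinates are 0-based, half-open; conversion to 1-based
happens only when writing human-readable reports.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOME = "genome"
TRANSCRIPTOME = "transcriptome"

_VALID_BASES = frozenset(b"ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be interpreted."""


class CompositionError(ValueError):
    """Raised when a composition statistic is undefined for a sequence."""


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (case preserved, N -> N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    contig_id: str
    sequence: str            # upper-case over {A,C,G,T,N}
    mask: np.ndarray         # bool per position, True = repeat-masked

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.sequence):
            raise ValueError(
                f"contig {self.contig_id!r}: mask length {len(self.mask)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> tuple[str, np.ndarray]:
        """Return (sequence, mask) for [start, end)."""
        return self.sequence[start:end], self.mask[start:end]


@dataclass
class AssemblyRecord:
    """One taxon's assembly: contigs with per-position repeat masks."""

    taxon: str
    datatype: str
    contigs: list[Contig]

    def __post_init__(self) -> None:
        if self.datatype not in (GENOME, TRANSCRIPTOME):
            raise ValueError(f"datatype must be genome|transcriptome, got {self.datatype!r}")
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"assembly {self.taxon!r}: duplicate contig ids")
        self._by_id = {c.contig_id: c for c in self.contigs}

    def contig(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def __iter__(self):
        return iter(self.contigs)


def read_fasta(path: str | Path, taxon: str | None = None,
               datatype: str = GENOME) -> AssemblyRecord:
    """Read a (soft-masked) FASTA file into an :class:`AssemblyRecord`.

    Lowercase letters mark repeat-masked positions; the stored sequence is
    upper-cased and the case information moves into the boolean mask.
    """
    path = Path(path)
    contigs: list[Contig] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: empty sequence for record {header!r} (line {header_line})")
        contigs.append(_contig_from_raw(header, seq))
        header, chunks = None, []

    with open(path) as fh:
        saw_any = False
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            saw_any = True
            if line.startswith(">"):
                _flush(i)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {i}")
                header_line = i
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence before any header at line {i}")
                chunks.append(line)
        if not saw_any:
            raise FastaParseError(f"{path}: empty file")
        _flush(i + 1)
    return AssemblyRecord(taxon=taxon or path.stem, datatype=datatype, contigs=contigs)


def _contig_from_raw(contig_id: str, raw_seq: str) -> Contig:
    arr = np.frombuffer(raw_seq.encode("ascii"), dtype=np.uint8)
    mask = (arr >= ord("a")) & (arr <= ord("z"))
    upper = raw_seq.upper()
    bad = set(upper) - {"A", "C", "G", "T", "N"}
    if bad:
        raise FastaParseError(
            f"contig {contig_id!r}: invalid characters {sorted(bad)!r}")
    return Contig(contig_id=contig_id, sequence=upper, mask=mask)


def write_fasta(assembly: AssemblyRecord, path: str | Path, width: int = 70) -> None:
    """Write an assembly back to soft-masked FASTA (lowercase = masked)."""
    with open(path, "w") as fh:
        for contig in assembly:
            chars = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8).copy()
            chars[contig.mask] += 32  # to lowercase
            seq = chars.tobytes().decode("ascii")
            fh.write(f">{contig.contig_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def gc_fraction(sequence: str) -> float:
    """GC fraction of a sequence, N positions excluded from both counts."""
    if not sequence:
        raise CompositionError("gc_fraction: empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    denom = len(s) - s.count("N")
    if denom == 0:
        raise CompositionError("gc_fraction: all-N sequence has undefined composition")
    return gc / denom


def repeat_fraction(mask: Sequence[bool] | np.ndarray) -> float:
    """Fraction of positions flagged as repeat-masked."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("repeat_fraction: zero-length mask")
    return float(mask.mean())


def merge_intervals(intervals: Iterable[tuple[int, int]],
                    max_gap: int = 0) -> list[tuple[int, int]]:
    """Merge intervals on one contig whose gap is strictly below ``max_gap``.

    Two intervals merge iff ``next.start - prev.end < max_gap``; overlapping
    or touching intervals always merge.  Output is sorted and pairwise
    disjoint, covering exactly the union plus the bridged gaps.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(intervals)
    if not ivs:
        return []
    for s, e in ivs:
        if s < 0:
            raise ValueError(f"negative coordinate in interval ({s}, {e})")
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        prev = merged[-1]
        if s - prev[1] < max_gap or s <= prev[1]:
            prev[1] = max(prev[1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class LocusInterval:
    """A conserved region on a reference contig."""

    locus_id: str
    contig_id: str
    start: int
    end: int
    occupancy_count: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"locus {self.locus_id!r}: bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def validate_locus_set(loci: Sequence[LocusInterval]) -> None:
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("locus ids are not unique within the set")


def extract_locus(assembly: AssemblyRecord, locus: LocusInterval) -> tuple[str, np.ndarray]:
    """(sequence, mask) of a locus on its assembly."""
    contig = assembly.contig(locus.contig_id)
    if locus.end > len(contig):
        raise ValueError(f"locus {locus.locus_id!r} exceeds contig {locus.contig_id!r}")
    return contig.slice(locus.start, locus.end)


def write_loci_tsv(loci: Sequence[LocusInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        [(l.locus_id, l.contig_id, l.start, l.end, l.occupancy_count) for l in loci],
        columns=["locus_id", "contig", "start", "end", "occupancy_count"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_loci_tsv(path: str | Path) -> list[LocusInterval]:
    df = pd.read_csv(path, sep="\t")
    loci = [
        LocusInterval(str(r.locus_id), str(r.contig), int(r.start), int(r.end),
                      int(r.occupancy_count))
        for r in df.itertuples()
    ]
    validate_locus_set(loci)
    return loci
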