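"""Conserved-locus discovery: read simulation, mapping, occupancy calling.

The procedure mirrors the classical genome-based UCE harvesting recipe:
error-free reads are tiled from every non-reference assembly, mapped back to
a designated reference at a strict divergence ceiling (default < 5 %,
full-length coverage, unique placement), and reference positions supported
by at least an occupancy threshold of taxa become candidate conserved
intervals.  Candidates are then gap-merged (< 100 bp), repeat-filtered
(> 25 % masked content dropped) and length-filtered (< 160 bp dropped).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aligner import DEFAULT_SEED_SIZE, _build_kmer_index, kmer_codes, make_pairwise_aligner
from .seqcore import (AssemblyRecord, LocusInterval, merge_intervals,
                      repeat_fraction, revcomp)


@dataclass
class DiscoveryParams:
    """Thresholds of the discovery stage.

    occupancy_fraction defaults to the genome recipe (0.90); transcriptome
    panels conventionally use 0.75.  occupancy_min_taxa, when set, overrides
    the ceil(fraction x n_taxa) arithmetic with an explicit count.
    """

    read_length: int = 100
    read_stride: int = 50
    max_divergence: float = 0.05
    occupancy_fraction: float = 0.90
    occupancy_min_taxa: int | None = None
    merge_gap: int = 100
    min_locus_length: int = 160
    max_repeat_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.max_divergence < 1):
            raise ValueError("max_divergence must be in (0, 1)")
        if not (0 < self.occupancy_fraction <= 1):
            raise ValueError("occupancy_fraction must be in (0, 1]")
        if self.min_locus_length <= 0:
            raise ValueError("min_locus_length must be positive")
        if self.read_stride < 1:
            raise ValueError("read_stride must be >= 1")


@dataclass
class Read:
    read_id: str
    taxon: str
    contig: str
    offset: int
    sequence: str


def simulate_reads(assembly: AssemblyRecord, read_length: int = 100,
                   read_stride: int = 50) -> list[Read]:
    """Tile error-free reads across each contig.

    Reads start at 0, stride, 2*stride, ... and only full-length windows are
    emitted (no padded tail read).  Contigs shorter than the read length
    yield nothing.
    """
    if read_stride < 1:
        raise ValueError("read_stride must be >= 1")
    reads: list[Read] = []
    for contig in assembly:
        for off in range(0, len(contig) - read_length + 1, read_stride):
            reads.append(Read(
                read_id=f"{assembly.taxon}|{contig.contig_id}|{off}",
                taxon=assembly.taxon, contig=contig.contig_id, offset=off,
                sequence=contig.sequence[off:off + read_length]))
    return reads


class _ReferenceIndex:
    """k-mer index over the reference for fast read placement."""

    def __init__(self, reference: AssemblyRecord, k: int = DEFAULT_SEED_SIZE):
        self.k = k
        self.contigs = {c.contig_id: np.frombuffer(c.sequence.encode(),
                                                   dtype=np.uint8)
                        for c in reference}
        self.index = {c.contig_id: _build_kmer_index(c.sequence, k)
                      for c in reference}


def _candidate_diagonals(seq: str, ref: _ReferenceIndex) -> set[tuple[str, int]]:
    """Candidate (contig, diagonal) placements from non-overlapping seeds."""
    k = ref.k
    codes = kmer_codes(seq, k)
    cands: set[tuple[str, int]] = set()
    for off in range(0, len(codes), k):
        code = int(codes[off])
        if code < 0:
            continue
        for contig_id, index in ref.index.items():
            hits = index.get(code)
            if hits is not None:
                for pos in hits:
                    cands.add((contig_id, int(pos) - off))
    return cands


def map_taxon_to_reference(reads: Sequence[Read], reference: AssemblyRecord,
                           max_divergence: float = 0.05,
                           seed_size: int = DEFAULT_SEED_SIZE,
                           gapped_rescue_margin: float = 0.05
                           ) -> dict[str, list[tuple[int, int]]]:
    """Reference intervals covered by a taxon's reads.

    A position is covered iff some read aligns across it full-length at
    identity >= 1 - max_divergence.  Reads qualifying at more than one
    reference location are discarded as non-unique (orthology proxy).

    Placement is seeded by exact k-mers (non-overlapping tiling of the read,
    so any placement with < read_length/k mismatches is guaranteed a seed by
    pigeonhole) and verified gap-free; placements whose gap-free identity
    falls just short (within ``gapped_rescue_margin``) are re-scored with a
    full local alignment so that small indels do not silently lose coverage.
    """
    ref = _ReferenceIndex(reference, k=seed_size)
    aligner = make_pairwise_aligner()
    min_identity = 1.0 - max_divergence
    covered: dict[str, list[tuple[int, int]]] = {cid: [] for cid in ref.contigs}

    for read in reads:
        L = len(read.sequence)
        placements: list[tuple[str, int]] = []
        for strand_seq in (read.sequence, revcomp(read.sequence)):
            arr = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
            for contig_id, diag in _candidate_diagonals(strand_seq, ref):
                target = ref.contigs[contig_id]
                if diag < 0 or diag + L > target.size:
                    continue
                ident = float((target[diag:diag + L] == arr).mean())
                if ident >= min_identity:
                    placements.append((contig_id, diag))
                elif ident >= min_identity - gapped_rescue_margin:
                    if _gapped_full_cover(aligner, strand_seq,
                                          ref, contig_id, diag, min_identity):
                        placements.append((contig_id, diag))
        # distinct locations: collapse near-identical diagonals on one contig
        distinct: list[tuple[str, int]] = []
        for contig_id, diag in sorted(set(placements)):
            if not any(c == contig_id and abs(d - diag) < L
                       for c, d in distinct):
                distinct.append((contig_id, diag))
        if len(distinct) == 1:
            contig_id, diag = distinct[0]
            covered[contig_id].append((max(0, diag), diag + L))

    return {cid: merge_intervals(ivs, max_gap=1) if ivs else []
            for cid, ivs in covered.items()}


def _gapped_full_cover(aligner, read_seq: str, ref: _ReferenceIndex,
                       contig_id: str, diag: int, min_identity: float) -> bool:
    """Local-align the read against a padded window; accept only full-length
    query coverage at the identity threshold."""
    L = len(read_seq)
    target = ref.contigs[contig_id]
    lo = max(0, diag - 10)
    hi = min(target.size, diag + L + 10)
    window = target[lo:hi].tobytes().decode("ascii")
    alns = aligner.align(window, read_seq)
    try:
        best = alns[0]
    except IndexError:
        return False
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return False
    _, qblocks = best.aligned
    qspan = int(qblocks[-1][1]) - int(qblocks[0][0])
    return qspan == L and counts.identities / columns >= min_identity


def occupancy_threshold(params: DiscoveryParams, n_taxa_total: int) -> int:
    """Supporting-taxon count implied by the occupancy fraction (ceil), or
    the explicit override when set."""
    if params.occupancy_min_taxa is not None:
        t = params.occupancy_min_taxa
    else:
        t = math.ceil(params.occupancy_fraction * n_taxa_total)
    if t > n_taxa_total:
        raise ValueError(
            f"occupancy threshold {t} exceeds the panel size {n_taxa_total}")
    return max(1, t)


def call_conserved_loci(per_taxon_coverages: dict[str, dict[str, list[tuple[int, int]]]],
                        reference: AssemblyRecord,
                        params: DiscoveryParams,
                        n_taxa_total: int | None = None) -> list[LocusInterval]:
    """Call conserved loci on the reference from per-taxon coverage maps.

    ``per_taxon_coverages`` maps non-reference taxa to the output of
    :func:`map_taxon_to_reference`; the reference itself always counts as one
    supporting taxon at every position.  Candidate intervals where the
    supporting count reaches the occupancy threshold are gap-merged, then
    repeat- and length-filtered.  Locus ids are ``uce-<N>`` in (contig,
    start) order; each locus records the number of taxa whose coverage
    touches it.
    """
    taxa = sorted(per_taxon_coverages)
    if n_taxa_total is None:
        n_taxa_total = len(taxa) + 1
    if len(taxa) + 1 < 2:
        raise ValueError("discovery needs at least two taxa incl. reference")
    threshold = occupancy_threshold(params, n_taxa_total)

    loci: list[LocusInterval] = []
    for contig in reference:
        n = len(contig)
        per_taxon_here = {
            taxon: per_taxon_coverages[taxon].get(contig.contig_id, [])
            for taxon in taxa
        }
        diff = np.zeros(n + 1, dtype=np.int32)
        diff[0] += 1          # the reference supports itself everywhere
        diff[n] -= 1
        for taxon in taxa:
            for s, e in per_taxon_here[taxon]:
                diff[s] += 1
                diff[min(e, n)] -= 1
        depth = np.cumsum(diff[:-1])

        above = depth >= threshold
        candidates = _runs(above)
        merged = merge_intervals(candidates, max_gap=params.merge_gap) \
            if candidates else []
        for s, e in merged:
            if e - s < params.min_locus_length:
                continue
            if repeat_fraction(contig.mask[s:e]) > params.max_repeat_fraction:
                continue
            support = 1  # the reference
            for taxon in taxa:
                if any(ts < e and s < te for ts, te in per_taxon_here[taxon]):
                    support += 1
            loci.append(LocusInterval(locus_id="", contig_id=contig.contig_id,
                                      start=s, end=e, occupancy_count=support))

    loci.sort(key=lambda l: (l.contig_id, l.start))
    for i, locus in enumerate(loci):
        locus.locus_id = f"uce-{i + 1}"
    return loci


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open intervals."""
    if not flags.any():
        return []
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def discover(reference: AssemblyRecord,
             others: Iterable[AssemblyRecord],
             params: DiscoveryParams | None = None) -> list[LocusInterval]:
    """End-to-end discovery: simulate, map, call.  ``others`` excludes the
    reference; the panel size for occupancy is len(others) + 1."""
    params = params or DiscoveryParams()
    coverages: dict[str, dict[str, list[tuple[int, int]]]] = {}
    n = 1
    for assembly in others:
        reads = simulate_reads(assembly, params.read_length, params.read_stride)
        coverages[assembly.taxon] = map_taxon_to_reference(
            reads, reference, params.max_divergence)
        n += 1
    return call_conserved_loci(coverages, reference, params, n_taxa_total=n)
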