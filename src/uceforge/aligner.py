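"""Seed-and-extend local sequence matching with explicit identity/coverage
semantics.

The matcher fills the role that genome-scale pipelines delegate to LASTZ or
BLAST: find local alignments of a short query (a probe, a locus sequence)
against an assembly, score them under a fixed scheme, and report fractional
identity and query coverage so that downstream stages can apply thresholds.

Scoring scheme (pinned for reproducibility): match +1, mismatch -1,
gap open -5, gap extend -2.  A gap of length L costs 5 + 2(L - 1).  Identity
counts gap columns as non-matching columns; query coverage is the aligned
query span divided by the query length.  Gap penalties are deliberately
harsh relative to the match score (as in LASTZ's defaults): with cheap gaps,
optimal local alignments between *unrelated* DNA drift to long, gap-riddled
paths that clear a 50 % identity / 50 % coverage screen, which would make
the redundancy filters vacuous.

Candidate regions are found with exact k-mer seeds (default k = 12) on both
strands; each seeded window is then resolved with an optimal local
(Smith-Waterman) alignment.  On small targets the matcher skips seeding and
aligns against the whole contig, which makes it exactly equivalent to an
exhaustive dynamic-programming search there.  Seeding bounds sensitivity:
alignments with no exact shared k-mer cannot be found, which is the standard
trade-off of seeded aligners.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .seqcore import AssemblyRecord, Contig, merge_intervals, revcomp

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN_SCORE = -5
GAP_EXTEND_SCORE = -2

DEFAULT_SEED_SIZE = 12
# contigs at or below this length are searched exhaustively (no seeding)
EXACT_TARGET_LIMIT = 3000


class AlignerError(ValueError):
    pass


@dataclass
class AlignmentHit:
    query_id: str
    target_contig: str
    target_start: int
    target_end: int
    strand: str              # '+' or '-'
    identity: float
    query_coverage: float
    score: int

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise ValueError("hit with empty target interval")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def make_pairwise_aligner() -> Align.PairwiseAligner:
    """A Smith-Waterman aligner configured with the pinned scoring scheme."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = MATCH_SCORE
    a.mismatch_score = MISMATCH_SCORE
    a.open_gap_score = GAP_OPEN_SCORE
    a.extend_gap_score = GAP_EXTEND_SCORE
    return a


def _alignment_stats(aln) -> tuple[int, int, int, int, int, int]:
    """(matches, columns, tstart, tend, qstart, qend) of a local alignment.

    The aligner is always called as align(target, query).
    """
    counts = aln.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    tblocks, qblocks = aln.aligned
    tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    return matches, columns, tstart, tend, qstart, qend


# ---------------------------------------------------------------------------
# k-mer machinery (2-bit encoding; windows containing N are invalid)

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer of ``seq``; -1 where the window has an N."""
    codes_per_base = _encode(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes_per_base, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows @ powers
    codes[(windows < 0).any(axis=1)] = -1
    return codes


def _build_kmer_index(seq: str, k: int) -> dict[int, np.ndarray]:
    codes = kmer_codes(seq, k)
    valid = codes >= 0
    positions = np.nonzero(valid)[0]
    codes = codes[valid]
    order = np.argsort(codes, kind="stable")
    codes, positions = codes[order], positions[order]
    uniq, starts = np.unique(codes, return_index=True)
    bounds = np.append(starts, len(codes))
    return {int(c): positions[bounds[i]:bounds[i + 1]] for i, c in enumerate(uniq)}


class AssemblyMatcher:
    """Reusable probe/locus matcher over one assembly.

    Builds a k-mer index per contig once, then answers queries via
    seed -> window -> optimal-local-alignment.
    """

    def __init__(self, assembly: AssemblyRecord, seed_size: int = DEFAULT_SEED_SIZE):
        self.assembly = assembly
        self.seed_size = seed_size
        self._aligner = make_pairwise_aligner()
        self._index = {c.contig_id: _build_kmer_index(c.sequence, seed_size)
                       for c in assembly}

    # -- candidate windows ------------------------------------------------
    def _windows(self, qseq: str, contig: Contig) -> list[tuple[int, int]]:
        index = self._index[contig.contig_id]
        codes = kmer_codes(qseq, self.seed_size)
        diags: list[np.ndarray] = []
        for off in range(len(codes)):
            code = int(codes[off])
            if code < 0:
                continue
            hits = index.get(code)
            if hits is not None:
                diags.append(hits - off)
        if not diags:
            return []
        diag = np.sort(np.concatenate(diags))
        qlen = len(qseq)
        pad = max(24, qlen // 4)
        band = max(8, qlen // 8)
        # long queries demand two independent seeds per diagonal cluster:
        # a lone random 12-mer hit is noise there, and each discarded window
        # saves a full window alignment
        min_seeds = 2 if qlen >= 200 else 1
        windows: list[tuple[int, int]] = []
        run_start = prev = diag[0]
        n_seeds = 1
        for d in diag[1:]:
            if d - prev > band:
                if n_seeds >= min_seeds:
                    windows.append((int(run_start), int(prev)))
                run_start, n_seeds = d, 0
            prev = d
            n_seeds += 1
        if n_seeds >= min_seeds:
            windows.append((int(run_start), int(prev)))
        out = []
        for lo, hi in windows:
            out.append((max(0, lo - pad), min(len(contig), hi + qlen + pad)))
        return merge_intervals(out, max_gap=1) if out else []

    # -- alignment --------------------------------------------------------
    def _align_window(self, qseq: str, tseq: str, toffset: int, strand: str,
                      query_id: str, qlen: int, min_score: int,
                      min_identity: float, min_query_coverage: float,
                      max_hits: int) -> list[AlignmentHit]:
        """Qualifying local alignments of qseq within tseq.

        The matched span is hard-masked after each hit and the window is
        re-searched (so tandem copies inside one window are each reported);
        the search stops at the first alignment that fails the thresholds,
        since weaker alignments of the same window rarely recover them.
        """
        hits: list[AlignmentHit] = []
        target = tseq
        for _ in range(max_hits):
            alns = self._aligner.align(target, qseq)
            try:
                best = alns[0]
            except IndexError:
                break
            if best.score < min_score:
                break
            matches, columns, tstart, tend, qstart, qend = _alignment_stats(best)
            if columns == 0:
                break
            identity = matches / columns
            coverage = (qend - qstart) / qlen
            if identity < min_identity or coverage < min_query_coverage:
                break
            hits.append(AlignmentHit(
                query_id=query_id, target_contig="",
                target_start=toffset + tstart, target_end=toffset + tend,
                strand=strand, identity=identity, query_coverage=coverage,
                score=int(best.score)))
            # hard-mask the matched span; stop if no room for another hit
            target = target[:tstart] + "#" * (tend - tstart) + target[tend:]
            room = max(tstart, len(target) - tend)
            if room < min_query_coverage * qlen:
                break
        return hits

    def match(self, query: str, min_identity: float, min_query_coverage: float,
              query_id: str = "query", max_hits_per_window: int = 4) -> list[AlignmentHit]:
        """All qualifying local alignments of ``query`` in the assembly."""
        if len(query) < self.seed_size:
            raise AlignerError(
                f"query length {len(query)} is below the minimum seed size "
                f"{self.seed_size}")
        qlen = len(query)
        min_score = max(1, int(np.floor(qlen * min_query_coverage
                                        * (2 * min_identity - 1))))
        raw: list[AlignmentHit] = []
        for contig in self.assembly:
            for strand, qseq in (("+", query), ("-", revcomp(query))):
                if len(contig) <= EXACT_TARGET_LIMIT:
                    windows = [(0, len(contig))]
                else:
                    windows = self._windows(qseq, contig)
                for wstart, wend in windows:
                    for hit in self._align_window(
                            qseq, contig.sequence[wstart:wend], wstart, strand,
                            query_id, qlen, min_score, min_identity,
                            min_query_coverage, max_hits_per_window):
                        hit.target_contig = contig.contig_id
                        raw.append(hit)
        return _collapse_overlaps(raw)


def _collapse_overlaps(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep only the best-scoring hit among mutually overlapping target spans."""
    hits = sorted(hits, key=lambda h: (-h.score, h.target_contig, h.target_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        clash = any(k.target_contig == h.target_contig
                    and h.target_start < k.target_end
                    and k.target_start < h.target_end
                    for k in kept)
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: (-h.score, h.target_contig, h.target_start))


def local_match(query: str, target: AssemblyRecord | Contig | str,
                min_identity: float, min_query_coverage: float,
                query_id: str = "query",
                seed_size: int = DEFAULT_SEED_SIZE) -> list[AlignmentHit]:
    """Match one query against a target assembly (one-shot convenience).

    Hits are sorted by descending score, ties broken by (contig, start).
    Small contigs (<= ``EXACT_TARGET_LIMIT`` bp) are searched exhaustively,
    so on desk-scale targets the best hit score equals the optimal
    Smith-Waterman score under the pinned scheme.
    """
    if isinstance(target, str):
        target = Contig("target", target, np.zeros(len(target), dtype=bool))
    if isinstance(target, Contig):
        target = AssemblyRecord("target", "genome", [target])
    matcher = AssemblyMatcher(target, seed_size=seed_size)
    return matcher.match(query, min_identity, min_query_coverage, query_id)


# ---------------------------------------------------------------------------
# similarity-based probe deduplication

def _ungapped_pass(a: np.ndarray, b: np.ndarray, offsets: Iterable[int],
                   min_identity: float, min_coverage: float) -> bool:
    """Cheap gap-free screen: does some diagonal already satisfy both
    thresholds?  (A gap-free alignment is a valid local alignment, so a pass
    here is conclusive; a failure is not.)"""
    short = min(len(a), len(b))
    for d in offsets:
        if d >= 0:
            span = min(len(a) - d, len(b))
            if span <= 0:
                continue
            matches = int((a[d:d + span] == b[:span]).sum())
        else:
            span = min(len(b) + d, len(a))
            if span <= 0:
                continue
            matches = int((a[:span] == b[-d:-d + span]).sum())
        if span / short >= min_coverage and matches / span >= min_identity:
            return True
    return False


def similar_pair(seq_a: str, seq_b: str, min_identity: float,
                 min_coverage: float, _aligner=None) -> bool:
    """True iff the best local alignment of the pair, in either orientation,
    reaches both thresholds.  Coverage is measured against the shorter
    sequence so the relation is symmetric."""
    aligner = _aligner or make_pairwise_aligner()
    arr_a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    short = min(len(seq_a), len(seq_b))
    for qseq in (seq_b, revcomp(seq_b)):
        arr_q = np.frombuffer(qseq.encode(), dtype=np.uint8)
        # screen a handful of diagonals around the ends and centre
        offsets = {0, len(seq_a) - len(qseq),
                   (len(seq_a) - len(qseq)) // 2}
        if _ungapped_pass(arr_a, arr_q, offsets, min_identity, min_coverage):
            return True
        alns = aligner.align(seq_a, qseq)
        try:
            best = alns[0]
        except IndexError:
            continue
        if best.score <= 0:
            continue
        matches, columns, tstart, tend, qstart, qend = _alignment_stats(best)
        if columns == 0:
            continue
        span = max(tend - tstart, qend - qstart)
        if matches / columns >= min_identity and span / short >= min_coverage:
            return True
    return False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def dedupe_by_similarity(probes: Sequence, min_identity: float = 0.5,
                         min_coverage: float = 0.5,
                         priority: Sequence[str] = (),
                         rank_key=None,
                         seed_size: int = DEFAULT_SEED_SIZE) -> list:
    """Collapse similar probes to one representative per similarity component.

    Builds an undirected graph with an edge wherever either orientation of a
    pair aligns at >= both thresholds, then keeps exactly one probe per
    connected component: the one whose source taxon comes earliest in
    ``priority`` (unknown taxa rank last), ties broken by lexicographic
    probe id.  Pairs sharing both locus id and source taxon are never linked:
    tiled probes of one locus overlap by construction and are intentional,
    not redundant.

    Candidate pairs are pre-filtered by shared k-mers in either orientation;
    pairs with no exact shared k-mer are treated as dissimilar.
    """
    probes = list(probes)
    if not probes:
        return []
    prio = {t: i for i, t in enumerate(priority)}
    if rank_key is None:
        def rank_key(p):
            return (prio.get(p.source_taxon, len(prio)), p.probe_id)

    # per-probe k-mer position maps (forward and reverse complement)
    def _code_pos(seq: str) -> dict[int, int]:
        out: dict[int, int] = {}
        for pos, code in enumerate(kmer_codes(seq, seed_size)):
            if code >= 0:
                out.setdefault(int(code), pos)
        return out

    fwd = [_code_pos(p.sequence) for p in probes]
    rc = [_code_pos(revcomp(p.sequence)) for p in probes]

    kmap: dict[int, list[int]] = {}
    for i, codes in enumerate(fwd):
        for code in codes:
            kmap.setdefault(code, []).append(i)
    pairs: set[tuple[int, int]] = set()
    for i in range(len(probes)):
        neigh: set[int] = set()
        for codes in (fwd[i], rc[i]):
            for code in codes:
                neigh.update(kmap.get(code, ()))
        for j in neigh:
            if j != i:
                pairs.add((min(i, j), max(i, j)))

    aligner = make_pairwise_aligner()
    uf = _UnionFind(len(probes))
    seqs = [p.sequence for p in probes]
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    rc_seqs = [revcomp(s) for s in seqs]
    rc_arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in rc_seqs]

    for i, j in sorted(pairs):
        pi, pj = probes[i], probes[j]
        if pi.locus_id == pj.locus_id and pi.source_taxon == pj.source_taxon:
            continue  # intentional tiling overlap
        if uf.find(i) == uf.find(j):
            continue  # already linked through another probe
        linked = False
        # cheap conclusive screen at the diagonals suggested by shared k-mers
        for qmap, qarr, qseq in ((fwd[j], arrs[j], seqs[j]),
                                 (rc[j], rc_arrs[j], rc_seqs[j])):
            diags = {fwd[i][c] - qmap[c] for c in fwd[i].keys() & qmap.keys()}
            if diags and _ungapped_pass(arrs[i], qarr, sorted(diags)[:8],
                                        min_identity, min_coverage):
                linked = True
                break
        if not linked:
            linked = similar_pair(seqs[i], seqs[j], min_identity,
                                  min_coverage, _aligner=aligner)
        if linked:
            uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(probes)):
        components.setdefault(uf.find(i), []).append(i)
    keep_idx = sorted(min(members, key=lambda m: rank_key(probes[m]))
                      for members in components.values())
    return [probes[i] for i in keep_idx]


def hits_to_tsv(hits: Sequence[AlignmentHit], path) -> None:
    import pandas as pd
    pd.DataFrame(
        [(h.query_id, h.target_contig, h.target_start, h.target_end, h.strand,
          round(h.identity, 6), round(h.query_coverage, 6), h.score)
         for h in hits],
        columns=["query_id", "contig", "start", "end", "strand",
                 "identity", "coverage", "score"],
    ).to_csv(path, sep="\t", index=False)
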