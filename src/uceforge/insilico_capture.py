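"""In-silico capture: evaluate a probe set against assemblies.

Capture of one taxon proceeds in five steps: (1) match every probe to the
assembly at the capture thresholds; (2) collapse the hits of each locus into
maximal target intervals; (3) slice each interval plus the configured flank,
clipped at contig ends and reverse-complemented for minus-strand hits so all
output is probe-oriented; (4) re-match the slices to the probes at the
stricter re-match thresholds (identity 0.80, probe coverage 0.67); (5) drop
conflicted material — a slice matching probes of more than one locus, or a
locus matched by more than one slice, is removed (matches within a locus's
own overlapping probe cohort are intentional, not conflicts).

The per-taxon results aggregate into a boolean loci x taxa occupancy matrix,
a pairwise shared-locus matrix, and per-taxon capture efficiencies
(captured loci / loci targeted by the probe set).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import (AssemblyMatcher, kmer_codes, make_pairwise_aligner,
                      _alignment_stats)
from .bait_design import ProbeRecord, ProbeSet
from .seqcore import AssemblyRecord, merge_intervals, revcomp


@dataclass
class CaptureParams:
    match_identity: float = 0.50       # 0.75 for genome-based probes vs genomes
    match_coverage: float = 0.83
    flank: int = 100
    rematch_min_coverage: float = 0.67
    rematch_min_identity: float = 0.80
    min_taxa_per_locus: int = 3

    def __post_init__(self) -> None:
        for name in ("match_identity", "match_coverage",
                     "rematch_min_coverage", "rematch_min_identity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class CapturedLocus:
    locus_id: str
    taxon: str
    contig: str
    span_start: int          # matched (core) interval on the contig
    span_end: int
    slice_start: int         # extracted interval incl. flank
    slice_end: int
    strand: str
    sequence: str            # probe-oriented


@dataclass
class TaxonCapture:
    taxon: str
    captured: dict[str, CapturedLocus]
    raw_locus_ids: set[str]              # loci matched before conflict rules
    conflicts: list[tuple[str, str]]     # (reason code, detail)

    def __len__(self) -> int:
        return len(self.captured)


@dataclass
class _Slice:
    locus_id: str            # originating locus (from the matched probes)
    contig: str
    span: tuple[int, int]
    bounds: tuple[int, int]
    strand: str
    sequence: str
    matched_loci: set[str] = field(default_factory=set)


def capture_taxon(probe_set: ProbeSet, assembly: AssemblyRecord,
                  params: CaptureParams | None = None) -> TaxonCapture:
    """Capture one assembly with a probe set (see module docstring)."""
    if len(probe_set) == 0:
        raise ValueError("empty probe set")
    params = params or CaptureParams()
    matcher = AssemblyMatcher(assembly)

    # (1) probe -> assembly matches, grouped per locus and contig
    clusters: dict[tuple[str, str], list[tuple[int, int, int, str]]] = {}
    for p in probe_set:
        for h in matcher.match(p.sequence, params.match_identity,
                               params.match_coverage, query_id=p.probe_id):
            clusters.setdefault((p.locus_id, h.target_contig), []).append(
                (h.target_start, h.target_end, h.score, h.strand))

    # (2) collapse per-locus hits to maximal intervals; (3) slice with flank
    slices: list[_Slice] = []
    raw_locus_ids = {lid for lid, _ in clusters}
    for (locus_id, contig_id), hits in sorted(clusters.items()):
        contig = assembly.contig(contig_id)
        merged = merge_intervals([(s, e) for s, e, _, _ in hits], max_gap=1)
        for s, e in merged:
            best = max((h for h in hits if h[0] < e and s < h[1]),
                       key=lambda h: h[2])
            strand = best[3]
            lo = max(0, s - params.flank)
            hi = min(len(contig), e + params.flank)
            seq = contig.sequence[lo:hi]
            if strand == "-":
                seq = revcomp(seq)
            slices.append(_Slice(locus_id, contig_id, (s, e), (lo, hi),
                                 strand, seq))

    # (4) re-match slices to the probes
    _rematch(slices, probe_set, params)

    # (5) conflict resolution
    captured, conflicts = resolve_conflicts(slices, assembly.taxon)
    return TaxonCapture(taxon=assembly.taxon, captured=captured,
                        raw_locus_ids=raw_locus_ids, conflicts=conflicts)


def _rematch(slices: Sequence[_Slice], probe_set: ProbeSet,
             params: CaptureParams, k: int = 12) -> None:
    """Fill ``matched_loci`` of every slice: loci whose probes align to the
    slice at the re-match thresholds (shared-k-mer candidates, then optimal
    local alignment)."""
    kmap: dict[int, set[int]] = {}
    probes = list(probe_set)
    for i, p in enumerate(probes):
        for code in np.unique(kmer_codes(p.sequence, k)):
            if code >= 0:
                kmap.setdefault(int(code), set()).add(i)
    aligner = make_pairwise_aligner()
    for sl in slices:
        cand: set[int] = set()
        for seq in (sl.sequence, revcomp(sl.sequence)):
            for code in np.unique(kmer_codes(seq, k)):
                if code >= 0:
                    cand.update(kmap.get(int(code), ()))
        for i in sorted(cand):
            p = probes[i]
            if p.locus_id in sl.matched_loci:
                continue
            if _probe_matches_slice(aligner, sl.sequence, p.sequence,
                                    params.rematch_min_identity,
                                    params.rematch_min_coverage):
                sl.matched_loci.add(p.locus_id)


def _probe_matches_slice(aligner, slice_seq: str, probe_seq: str,
                         min_identity: float, min_coverage: float) -> bool:
    for qseq in (probe_seq, revcomp(probe_seq)):
        alns = aligner.align(slice_seq, qseq)
        try:
            best = alns[0]
        except IndexError:
            continue
        if best.score <= 0:
            continue
        matches, columns, _, _, qstart, qend = _alignment_stats(best)
        if columns == 0:
            continue
        if (matches / columns >= min_identity
                and (qend - qstart) / len(qseq) >= min_coverage):
            return True
    return False


def resolve_conflicts(slices: Sequence[_Slice], taxon: str
                      ) -> tuple[dict[str, CapturedLocus], list[tuple[str, str]]]:
    """Apply the two conflict rules to a re-matched slice table.

    A slice matching probes of more than one distinct locus is removed
    (reason ``multi-probe-sequence``); a locus matched by more than one
    surviving slice is removed for this taxon (``multi-sequence-probe``);
    slices matching no probe at all fail the re-match and are dropped.
    """
    conflicts: list[tuple[str, str]] = []
    survivors: list[_Slice] = []
    for sl in slices:
        if not sl.matched_loci:
            conflicts.append(("no-rematch",
                              f"{sl.locus_id}@{sl.contig}:{sl.span[0]}-{sl.span[1]}"))
        elif len(sl.matched_loci) > 1:
            conflicts.append(("multi-probe-sequence",
                              f"{sl.locus_id}@{sl.contig}:{sl.span[0]}-{sl.span[1]}"
                              f" matches {sorted(sl.matched_loci)}"))
        else:
            survivors.append(sl)

    by_locus: dict[str, list[_Slice]] = {}
    for sl in survivors:
        by_locus.setdefault(next(iter(sl.matched_loci)), []).append(sl)

    captured: dict[str, CapturedLocus] = {}
    for locus_id, locus_slices in sorted(by_locus.items()):
        if len(locus_slices) > 1:
            conflicts.append(("multi-sequence-probe",
                              f"{locus_id}: {len(locus_slices)} slices"))
            continue
        sl = locus_slices[0]
        captured[locus_id] = CapturedLocus(
            locus_id=locus_id, taxon=taxon, contig=sl.contig,
            span_start=sl.span[0], span_end=sl.span[1],
            slice_start=sl.bounds[0], slice_end=sl.bounds[1],
            strand=sl.strand, sequence=sl.sequence)
    return captured, conflicts


def capture_panel(probe_set: ProbeSet,
                  assemblies: Iterable[AssemblyRecord],
                  params: CaptureParams | None = None) -> dict[str, TaxonCapture]:
    return {a.taxon: capture_taxon(probe_set, a, params) for a in assemblies}


def efficiency(capture_results: Mapping[str, TaxonCapture],
               probe_set: ProbeSet,
               exclude: Sequence[str] = ()) -> tuple[dict[str, float], float]:
    """Per-taxon capture efficiency and its mean over non-excluded taxa."""
    n_targets = len(probe_set.target_locus_ids)
    if n_targets == 0:
        raise ValueError("probe set targets zero loci")
    per_taxon = {taxon: len(result.captured) / n_targets
                 for taxon, result in sorted(capture_results.items())}
    included = [v for t, v in per_taxon.items() if t not in set(exclude)]
    if not included:
        raise ValueError("no taxa left after exclusions")
    return per_taxon, float(np.mean(included))


def occupancy_and_shared(capture_results: Mapping[str, TaxonCapture],
                         min_taxa_per_locus: int = 3,
                         occupancy_fraction_filters: Sequence[float] = (0.50, 0.75)
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict[float, list[str]]]:
    """Occupancy matrix, shared-locus matrix, and fraction-filtered lists.

    Loci present in fewer than ``min_taxa_per_locus`` taxa are removed.  The
    shared matrix S[i, j] counts loci present in both taxa i and j (diagonal
    = per-taxon counts).  Each fraction f yields the loci present in
    strictly more than f of the taxa.
    """
    taxa = sorted(capture_results)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    loci = sorted({lid for r in capture_results.values() for lid in r.captured})
    occ = pd.DataFrame(
        [[int(lid in capture_results[t].captured) for t in taxa]
         for lid in loci],
        index=loci, columns=taxa, dtype=int)
    occ = occ[occ.sum(axis=1) >= min_taxa_per_locus]
    mat = occ.to_numpy()
    shared = pd.DataFrame(mat.T @ mat, index=taxa, columns=taxa)
    filtered = {
        f: [lid for lid in occ.index
            if occ.loc[lid].sum() > f * len(taxa)]
        for f in occupancy_fraction_filters
    }
    return occ, shared, filtered


# ---------------------------------------------------------------------------
# serialization

def write_capture_fasta(result: TaxonCapture, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lid in sorted(result.captured):
            c = result.captured[lid]
            fh.write(f">{c.locus_id}|{c.taxon}|"
                     f"{c.contig}:{c.slice_start}-{c.slice_end}:{c.strand}\n")
            fh.write(c.sequence + "\n")


def write_summary_tsv(capture_results: Mapping[str, TaxonCapture],
                      probe_set: ProbeSet, path: str | Path,
                      exclude: Sequence[str] = ()) -> None:
    per_taxon, mean = efficiency(capture_results, probe_set, exclude=exclude)
    rows = [(t, len(capture_results[t].captured),
             len(capture_results[t].raw_locus_ids),
             len(capture_results[t].conflicts),
             round(per_taxon[t], 6), int(t in set(exclude)))
            for t in sorted(capture_results)]
    pd.DataFrame(rows, columns=["taxon", "n_loci", "n_loci_prefilter",
                                "n_conflicts", "efficiency", "excluded_from_mean"]
                 ).to_csv(path, sep="\t", index=False)
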