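"""Probe (bait) design over conserved loci.

The design ladder has four rungs:

1. **temporary set** — probes tiled on the reference copy of every
   discovered locus (two probes per locus at one-third probe-length stride,
   both overlapping the locus midpoint), GC/repeat-filtered, then
   self-screened for redundancy at 50 % identity / 50 % coverage;
2. **final loci** — loci whose temporary probes are recovered in at least
   ``min_species_for_final`` assemblies at the master thresholds
   (identity 0.50, coverage 0.83);
3. **master set** — probes re-designed from *every* assembly's own copy of
   each final locus, pooled and self-screened again;
4. **subset / merged sets** — reduction to chosen source taxa, and the
   cross-screened union of independently designed sets (e.g., genome-based
   plus transcriptome-based).

Filters drop individual probes, never whole loci; loci whose probes all fail
are reported as undesignable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aligner import AssemblyMatcher, dedupe_by_similarity
from .seqcore import (AssemblyRecord, CompositionError, LocusInterval,
                      extract_locus, gc_fraction, repeat_fraction, revcomp)


@dataclass
class DesignParams:
    probe_length: int = 120
    probes_per_locus: int = 2
    tiling_density: int = 3
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_repeat_fraction: float = 0.25
    dedupe_identity: float = 0.5
    dedupe_coverage: float = 0.5
    master_identity: float = 0.5
    master_coverage: float = 0.83
    min_species_for_final: int = 15

    def __post_init__(self) -> None:
        if self.tiling_density < 1 or self.probes_per_locus < 1:
            raise ValueError("densities must be >= 1")


@dataclass
class ProbeRecord:
    probe_id: str
    locus_id: str
    source_taxon: str
    offset: int              # start of the probe within its locus
    sequence: str
    gc: float
    repeat_frac: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty probe sequence")


@dataclass
class ProbeSet:
    probes: list[ProbeRecord]
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("probe ids are not unique within the set")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def target_locus_ids(self) -> list[str]:
        return sorted({p.locus_id for p in self.probes})

    @property
    def source_taxa(self) -> list[str]:
        return sorted({p.source_taxon for p in self.probes})


def design_probes_for_locus(locus_sequence: str, locus_mask: np.ndarray,
                            locus_id: str, source_taxon: str,
                            params: DesignParams) -> list[ProbeRecord]:
    """Tile probes over one locus so each overlaps the locus midpoint.

    With the defaults (probe 120 bp, tiling density 3) the stride is 40 bp
    and the two probes start at mid-100 and mid-60, clamped into the locus::

        locus   |------------------- mid -------------------|
        probe 1          [==========|==]
        probe 2              [======|======]

    Probes failing the GC window or the repeat ceiling are dropped
    individually.  A locus shorter than the probe length yields no probes.
    """
    pl = params.probe_length
    L = len(locus_sequence)
    if L < pl:
        return []
    stride = pl // params.tiling_density
    mid = L // 2
    start0 = mid - pl + stride // 2
    starts = []
    for i in range(params.probes_per_locus):
        s = min(max(start0 + i * stride, 0), L - pl)
        if s not in starts:
            starts.append(s)
    probes: list[ProbeRecord] = []
    for s in starts:
        seq = locus_sequence[s:s + pl]
        if "N" in seq:
            continue
        try:
            gc = gc_fraction(seq)
        except CompositionError:
            continue
        rf = repeat_fraction(locus_mask[s:s + pl])
        if not (params.gc_min <= gc <= params.gc_max):
            continue
        if rf > params.max_repeat_fraction:
            continue
        probes.append(ProbeRecord(
            probe_id=f"{locus_id}_{source_taxon}_o{s}",
            locus_id=locus_id, source_taxon=source_taxon, offset=s,
            sequence=seq, gc=gc, repeat_frac=rf))
    return probes


def build_temporary_set(reference_loci: Sequence[LocusInterval],
                        reference_assembly: AssemblyRecord,
                        params: DesignParams | None = None,
                        priority: Sequence[str] = ()) -> ProbeSet:
    """Design the reference-only (temporary) probe set."""
    params = params or DesignParams()
    designed: list[ProbeRecord] = []
    undesignable: list[str] = []
    for locus in reference_loci:
        seq, mask = extract_locus(reference_assembly, locus)
        probes = design_probes_for_locus(seq, mask, locus.locus_id,
                                         reference_assembly.taxon, params)
        if probes:
            designed.extend(probes)
        else:
            undesignable.append(locus.locus_id)
    kept = dedupe_by_similarity(designed, params.dedupe_identity,
                                params.dedupe_coverage, priority=priority)
    return ProbeSet(kept, stats={
        "loci_in": len(reference_loci),
        "probes_designed": len(designed),
        "probes_after_dedupe": len(kept),
        "undesignable_loci": undesignable,
    })


def probe_presence_by_assembly(probe_set: ProbeSet,
                               assemblies: Iterable[AssemblyRecord],
                               min_identity: float, min_coverage: float
                               ) -> pd.DataFrame:
    """Boolean loci x taxa table: locus present iff >=1 of its probes has a
    qualifying hit in the assembly."""
    by_locus: dict[str, list[ProbeRecord]] = {}
    for p in probe_set:
        by_locus.setdefault(p.locus_id, []).append(p)
    taxa, rows = [], {lid: [] for lid in by_locus}
    for assembly in assemblies:
        taxa.append(assembly.taxon)
        matcher = AssemblyMatcher(assembly)
        for lid, probes in by_locus.items():
            present = any(
                matcher.match(p.sequence, min_identity, min_coverage,
                              query_id=p.probe_id)
                for p in probes)
            rows[lid].append(present)
    return pd.DataFrame(rows, index=taxa).T.sort_index()


def select_final_loci(temporary_set: ProbeSet,
                      reference_loci: Sequence[LocusInterval],
                      assemblies: Sequence[AssemblyRecord],
                      params: DesignParams | None = None,
                      presence: pd.DataFrame | None = None) -> list[LocusInterval]:
    """Retain loci whose probes are recovered in enough assemblies.

    ``presence`` may be supplied to reuse a precomputed loci x taxa table
    (e.g., when sweeping ``min_species_for_final``)."""
    params = params or DesignParams()
    if presence is None:
        presence = probe_presence_by_assembly(
            temporary_set, assemblies, params.master_identity,
            params.master_coverage)
    counts = presence.sum(axis=1)
    keep_ids = {lid for lid, c in counts.items()
                if c >= params.min_species_for_final}
    return [l for l in reference_loci if l.locus_id in keep_ids]


def build_master_set(final_loci: Sequence[LocusInterval],
                     reference_assembly: AssemblyRecord,
                     assemblies: Sequence[AssemblyRecord],
                     params: DesignParams | None = None,
                     priority: Sequence[str] = ()) -> ProbeSet:
    """Design probes for every final locus from every assembly's own copy.

    Each locus is located in each assembly by matching its reference
    sequence at the master thresholds; the best qualifying hit defines that
    assembly's copy (reverse-complemented for minus-strand hits so all
    copies are reference-oriented), probes are tiled on the copy, pooled
    across assemblies and self-screened.
    """
    params = params or DesignParams()
    designed: list[ProbeRecord] = []
    located: dict[str, int] = {}
    for assembly in assemblies:
        matcher = AssemblyMatcher(assembly)
        for locus in final_loci:
            ref_seq, _ = extract_locus(reference_assembly, locus)
            hits = matcher.match(ref_seq, params.master_identity,
                                 params.master_coverage,
                                 query_id=locus.locus_id)
            if not hits:
                continue
            best = hits[0]
            contig = assembly.contig(best.target_contig)
            seq, mask = contig.slice(best.target_start, best.target_end)
            if best.strand == "-":
                seq, mask = revcomp(seq), mask[::-1]
            probes = design_probes_for_locus(seq, np.asarray(mask),
                                             locus.locus_id, assembly.taxon,
                                             params)
            designed.extend(probes)
            located[locus.locus_id] = located.get(locus.locus_id, 0) + 1
    kept = dedupe_by_similarity(designed, params.dedupe_identity,
                                params.dedupe_coverage, priority=priority)
    return ProbeSet(kept, stats={
        "loci_in": len(final_loci),
        "probes_designed": len(designed),
        "probes_after_dedupe": len(kept),
        "loci_located": located,
    })


def subset_by_taxa(master_set: ProbeSet, taxa: Sequence[str]) -> ProbeSet:
    """Retain exactly the probes contributed by the given source taxa."""
    if not taxa:
        raise ValueError("taxa must be non-empty")
    valid = set(master_set.source_taxa)
    unknown = [t for t in taxa if t not in valid]
    if unknown:
        raise ValueError(
            f"unknown source taxa {unknown}; valid: {sorted(valid)}")
    chosen = set(taxa)
    kept = [p for p in master_set if p.source_taxon in chosen]
    return ProbeSet(kept, stats={
        "probes_in": len(master_set), "probes_after_subset": len(kept)})


def merge_probe_sets(set_a: ProbeSet, set_b: ProbeSet,
                     identity: float = 0.5, coverage: float = 0.5,
                     priority: Sequence[str] = (),
                     label_a: str = "A", label_b: str = "B") -> ProbeSet:
    """Union of two probe sets with cross-redundancy removed.

    Locus-id namespaces are kept distinct per origin (ids are prefixed
    whenever the two sets could collide).  On a similarity tie the probe
    from ``set_a`` wins, then taxon priority, then lexicographic id.
    """
    ids_a = {p.probe_id for p in set_a}
    loci_a = set(set_a.target_locus_ids)
    collide = bool(ids_a & {p.probe_id for p in set_b}) or \
        bool(loci_a & set(set_b.target_locus_ids))

    def _tag(p: ProbeRecord, label: str) -> ProbeRecord:
        if not collide:
            return p
        return ProbeRecord(probe_id=f"{label}.{p.probe_id}",
                           locus_id=f"{label}.{p.locus_id}",
                           source_taxon=p.source_taxon, offset=p.offset,
                           sequence=p.sequence, gc=p.gc,
                           repeat_frac=p.repeat_frac)

    pool = [_tag(p, label_a) for p in set_a] + [_tag(p, label_b) for p in set_b]
    origin = {p.probe_id: 0 for p in pool[:len(set_a)]}
    origin.update({p.probe_id: 1 for p in pool[len(set_a):]})
    prio = {t: i for i, t in enumerate(priority)}

    def rank_key(p: ProbeRecord):
        return (origin[p.probe_id], prio.get(p.source_taxon, len(prio)),
                p.probe_id)

    kept = dedupe_by_similarity(pool, identity, coverage, rank_key=rank_key)
    return ProbeSet(kept, stats={
        "probes_in_a": len(set_a), "probes_in_b": len(set_b),
        "probes_after_merge": len(kept)})


# ---------------------------------------------------------------------------
# serialization

def write_probe_set(probe_set: ProbeSet, fasta_path: str | Path,
                    manifest_path: str | Path | None = None) -> None:
    with open(fasta_path, "w") as fh:
        for p in sorted(probe_set, key=lambda p: p.probe_id):
            fh.write(f">{p.probe_id}|{p.locus_id}|{p.source_taxon}|{p.offset}\n")
            fh.write(p.sequence + "\n")
    if manifest_path is not None:
        pd.DataFrame(
            [(p.probe_id, p.locus_id, p.source_taxon, p.offset,
              len(p.sequence), round(p.gc, 6), round(p.repeat_frac, 6))
             for p in sorted(probe_set, key=lambda p: p.probe_id)],
            columns=["probe_id", "locus_id", "source_taxon", "offset",
                     "length", "gc", "repeat_frac"],
        ).to_csv(manifest_path, sep="\t", index=False)


def read_probe_set(fasta_path: str | Path,
                   manifest_path: str | Path | None = None) -> ProbeSet:
    repeat: dict[str, float] = {}
    if manifest_path is not None:
        mdf = pd.read_csv(manifest_path, sep="\t")
        repeat = dict(zip(mdf.probe_id, mdf.repeat_frac))
    probes: list[ProbeRecord] = []
    header, seq_chunks = None, []

    def _flush():
        nonlocal header, seq_chunks
        if header is None:
            return
        fields = header.split("|")
        if len(fields) != 4:
            raise ValueError(f"malformed probe header {header!r}")
        pid, lid, taxon, offset = fields
        seq = "".join(seq_chunks).upper()
        probes.append(ProbeRecord(
            probe_id=pid, locus_id=lid, source_taxon=taxon,
            offset=int(offset), sequence=seq, gc=gc_fraction(seq),
            repeat_frac=float(repeat.get(pid, 0.0))))
        header, seq_chunks = None, []

    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:]
            else:
                seq_chunks.append(line)
    _flush()
    return ProbeSet(probes)
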