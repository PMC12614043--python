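"""Synthetic multi-taxon assembly panels with planted conserved elements.

The generator emulates the input side of a UCE probe-design study: a panel of
taxa whose genomes share nearly-invariant core regions (the planted UCEs)
embedded in fast-evolving background, with soft-masked tandem-repeat tracts
and optional per-taxon locus dropout.  Evolution is substitution-only on a
star phylogeny: each taxon derives independently from one ancestral sequence,
cores at a low per-branch substitution probability and background at a high
one.  The first taxon doubles as the reference and sits at the ancestor
(zero branch length), so the pairwise core divergence of any other taxon to
the reference equals that taxon's own core branch probability.

Substitution-only evolution keeps the truth-table coordinates of every
planted locus exact in every taxon, which is what makes end-to-end recovery
tests sharp.  What this panel does *not* emulate: indels, assembly gaps and
errors, paralogy, rate heterogeneity within a partition, and realistic tree
shape — conclusions from these fixtures are about the pipeline's logic, not
about any particular real assembly panel.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .seqcore import GENOME, TRANSCRIPTOME, AssemblyRecord, Contig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# substitution targets: for each ASCII base code, the three other bases
_ALT = np.zeros((256, 3), dtype=np.uint8)
for _b in _BASES:
    _ALT[_b] = np.array([x for x in _BASES if x != _b], dtype=np.uint8)


@dataclass
class PanelParams:
    """Knobs of the synthetic study panel (defaults are the standard test
    conditions: 20 taxa, 200 planted cores of 300-600 bp at 1-3 % core
    divergence over 15 % background divergence)."""

    n_taxa: int = 20
    n_loci: int = 200
    core_length: tuple[int, int] = (300, 600)
    spacer_length: tuple[int, int] = (600, 900)
    core_divergence: tuple[float, float] = (0.01, 0.03)
    background_divergence: float = 0.15
    reference_divergence: float = 0.0
    repeat_prob: float = 0.3           # chance a spacer carries a masked tract
    repeat_length: tuple[int, int] = (60, 180)
    dropout: float = 0.0               # per (taxon, locus) loss probability
    n_fragments: int = 1               # contigs per taxon genome

    def validate(self, min_locus_length: int = 160) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.core_length[0] < min_locus_length:
            raise ValueError(
                f"core_length minimum {self.core_length[0]} is below the "
                f"minimum locus length {min_locus_length}")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TruthSet:
    """Ground truth for a generated panel."""

    taxa: list[str]
    core_divergence: dict[str, float]
    background_divergence: dict[str, float]
    # taxon -> locus_id -> (contig, start, end); absent = dropped out
    planted: dict[str, dict[str, tuple[str, int, int]]]
    expressed: dict[str, list[str]] = field(default_factory=dict)
    params: PanelParams | None = None
    seed: int | None = None

    @property
    def locus_ids(self) -> list[str]:
        ids: set[str] = set()
        for m in self.planted.values():
            ids.update(m)
        return sorted(ids)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for taxon in self.taxa:
            expressed = set(self.expressed.get(taxon, ()))
            for locus_id, (contig, start, end) in sorted(self.planted[taxon].items()):
                rows.append((taxon, locus_id, contig, start, end,
                             int(locus_id in expressed)))
        pd.DataFrame(rows, columns=["taxon", "locus_id", "contig", "start",
                                    "end", "expressed"]).to_csv(
            path, sep="\t", index=False)


def evolve_sequence(ancestral: str, substitution_probability: float,
                    rng: np.random.Generator | int) -> str:
    """Apply independent per-site substitutions (uniform over the three
    alternative bases).  Length-preserving and deterministic per seed; N and
    case are left untouched (evolution operates on the upper-case alphabet)."""
    if not (0 <= substitution_probability < 1):
        raise ValueError("substitution probability must be in [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer(ancestral.encode("ascii"), dtype=np.uint8).copy()
    if substitution_probability == 0:
        return ancestral
    sub = rng.random(arr.size) < substitution_probability
    sub &= np.isin(arr, _BASES)
    idx = np.nonzero(sub)[0]
    choice = rng.integers(0, 3, size=idx.size)
    arr[idx] = _ALT[arr[idx], choice]
    return arr.tobytes().decode("ascii")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _tandem_repeat(rng: np.random.Generator, length: int) -> str:
    motif = _random_sequence(rng, int(rng.integers(2, 7)))
    return (motif * (length // len(motif) + 1))[:length]


def generate_panel(params: PanelParams | None = None, seed: int = 0
                   ) -> tuple[dict[str, AssemblyRecord], TruthSet]:
    """Generate the taxon panel and its truth table.

    Returns ``(assemblies, truth)`` where ``assemblies`` maps taxon name to
    its genome.  Taxon names are ``taxon_01`` (the reference) onward; planted
    loci are ``locus_0001`` onward in genomic order.
    """
    params = params or PanelParams()
    params.validate()
    rng = np.random.default_rng(seed)

    # --- ancestral genome -------------------------------------------------
    segments: list[str] = []           # sequence chunks
    mask_chunks: list[np.ndarray] = []
    core_coords: dict[str, tuple[int, int]] = {}
    pos = 0

    def _spacer() -> None:
        nonlocal pos
        length = int(rng.integers(*params.spacer_length, endpoint=True))
        seq = _random_sequence(rng, length)
        mask = np.zeros(length, dtype=bool)
        if rng.random() < params.repeat_prob and length > params.repeat_length[1] + 20:
            rep_len = int(rng.integers(*params.repeat_length, endpoint=True))
            off = int(rng.integers(10, length - rep_len - 10))
            seq = seq[:off] + _tandem_repeat(rng, rep_len) + seq[off + rep_len:]
            mask[off:off + rep_len] = True
        segments.append(seq)
        mask_chunks.append(mask)
        pos += length

    _spacer()
    for i in range(params.n_loci):
        length = int(rng.integers(*params.core_length, endpoint=True))
        core_coords[f"locus_{i + 1:04d}"] = (pos, pos + length)
        segments.append(_random_sequence(rng, length))
        mask_chunks.append(np.zeros(length, dtype=bool))
        pos += length
        _spacer()

    ancestral = "".join(segments)
    anc_mask = np.concatenate(mask_chunks)
    total = len(ancestral)

    # --- per-taxon evolution ----------------------------------------------
    taxa = [f"taxon_{i + 1:02d}" for i in range(params.n_taxa)]
    core_div: dict[str, float] = {}
    bg_div: dict[str, float] = {}
    assemblies: dict[str, AssemblyRecord] = {}
    planted: dict[str, dict[str, tuple[str, int, int]]] = {}

    is_core = np.zeros(total, dtype=bool)
    for s, e in core_coords.values():
        is_core[s:e] = True

    for t_index, taxon in enumerate(taxa):
        if t_index == 0:
            d_core = d_bg = params.reference_divergence
        else:
            d_core = float(rng.uniform(*params.core_divergence))
            d_bg = params.background_divergence
        core_div[taxon] = d_core
        bg_div[taxon] = d_bg

        evolved_core = evolve_sequence(ancestral, d_core, rng)
        evolved_bg = evolve_sequence(ancestral, d_bg, rng)
        arr = np.where(is_core,
                       np.frombuffer(evolved_core.encode(), dtype=np.uint8),
                       np.frombuffer(evolved_bg.encode(), dtype=np.uint8))

        taxon_planted: dict[str, tuple[str, int, int]] = {}
        for locus_id, (s, e) in core_coords.items():
            dropped = t_index != 0 and params.dropout > 0 \
                and rng.random() < params.dropout
            if dropped:
                repl = _random_sequence(rng, e - s)
                arr[s:e] = np.frombuffer(repl.encode(), dtype=np.uint8)
            else:
                taxon_planted[locus_id] = ("", s, e)  # contig filled below

        seq = arr.tobytes().decode("ascii")
        contigs, coord_map = _fragment(taxon, seq, anc_mask,
                                       params.n_fragments)
        planted[taxon] = {
            lid: coord_map(s, e)
            for lid, (_, s, e) in taxon_planted.items()
            if coord_map(s, e) is not None
        }
        assemblies[taxon] = AssemblyRecord(taxon=taxon, datatype=GENOME,
                                           contigs=contigs)

    truth = TruthSet(taxa=taxa, core_divergence=core_div,
                     background_divergence=bg_div, planted=planted,
                     params=params, seed=seed)
    return assemblies, truth


def _fragment(taxon: str, seq: str, mask: np.ndarray, n_fragments: int):
    """Split a genome into equal contigs; returns contigs plus a coordinate
    mapper that drops loci straddling a fragment boundary."""
    if n_fragments <= 1:
        contigs = [Contig("chr1", seq, mask.copy())]

        def coord_map(s: int, e: int):
            return ("chr1", s, e)
        return contigs, coord_map

    bounds = np.linspace(0, len(seq), n_fragments + 1).astype(int)
    contigs = [Contig(f"ctg{i + 1}", seq[bounds[i]:bounds[i + 1]],
                      mask[bounds[i]:bounds[i + 1]].copy())
               for i in range(n_fragments)]

    def coord_map(s: int, e: int):
        i = int(np.searchsorted(bounds, s, side="right") - 1)
        if e <= bounds[i + 1]:
            return (f"ctg{i + 1}", s - bounds[i], e - bounds[i])
        return None  # straddles a boundary: absent from this assembly view
    return contigs, coord_map


def make_transcriptome_view(genome: AssemblyRecord,
                            planted: dict[str, tuple[str, int, int]],
                            expressed_fraction: float = 0.85,
                            seed: int = 0,
                            native_flank: int = 50
                            ) -> tuple[AssemblyRecord, dict[str, tuple[str, int, int]]]:
    """Derive a transcriptome-like assembly: one contig per expressed planted
    locus (core plus a short native genomic flank), an exact substring of the
    genome.  Returns the view and the within-view truth coordinates of the
    expressed cores."""
    if not (0 < expressed_fraction <= 1):
        raise ValueError("expressed_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    view_truth: dict[str, tuple[str, int, int]] = {}
    for locus_id in sorted(planted):
        if rng.random() >= expressed_fraction:
            continue
        contig_id, s, e = planted[locus_id]
        src = genome.contig(contig_id)
        lo = max(0, s - native_flank)
        hi = min(len(src), e + native_flank)
        seq, mask = src.slice(lo, hi)
        tx_id = f"tx_{locus_id}"
        contigs.append(Contig(tx_id, seq, mask.copy()))
        view_truth[locus_id] = (tx_id, s - lo, e - lo)
    if not contigs:  # guarantee a non-empty assembly
        locus_id = sorted(planted)[0]
        contig_id, s, e = planted[locus_id]
        src = genome.contig(contig_id)
        lo, hi = max(0, s - native_flank), min(len(src), e + native_flank)
        seq, mask = src.slice(lo, hi)
        contigs.append(Contig(f"tx_{locus_id}", seq, mask.copy()))
        view_truth[locus_id] = (f"tx_{locus_id}", s - lo, e - lo)
    view = AssemblyRecord(taxon=genome.taxon, datatype=TRANSCRIPTOME,
                          contigs=contigs)
    return view, view_truth


def write_provenance(params: PanelParams, seed: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"seed": seed, "params": asdict(params)}, fh,
                       sort_keys=True)
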