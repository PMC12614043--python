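# uceforge

Design and evaluation of ultraconserved-element (UCE) probe sets for
target-enrichment phylogenomics, for clades where no off-the-shelf bait kit
works well — the situation faced by anyone building a first probe set for an
understudied lineage from a mixed panel of genome and transcriptome
assemblies.

UCEs are regions that are nearly invariant across distantly related taxa;
short synthetic baits ("probes") hybridize to them and pull down the locus
plus its variable, phylogenetically informative flanks. `uceforge`
implements the whole in-silico side of that workflow:

- **discovery** — tile error-free reads across each assembly, map them to a
  reference at a divergence ceiling (identity >= 1 - d, full-length, unique
  placement), and call loci where at least a fraction *o* of the taxa agree:

  depth(x) >= ceil(o · n_taxa), then merge gaps < 100 bp, drop loci with
  > 25 % repeat-masked content or length < 160 bp;

- **design** — two 120-bp baits per locus at 3× tiling density (stride
  120/3 = 40 bp, both covering the locus midpoint), GC confined to
  [0.30, 0.70], repeat content <= 25 %, redundancy screened at 50 %
  identity / 50 % coverage; a temporary (reference-only) set validates loci
  across the panel (identity 0.50 / coverage 0.83, >= 15 species), and a
  master set re-designs probes from every assembly's own locus copies;
  subsets by source taxon and cross-screened merges of genome-based and
  transcriptome-based sets (the "mixed" set) complete the ladder;

- **in-silico capture** — match probes to an assembly, slice matched spans
  ± flank (100-400 bp), re-match slices to probes at identity 0.80 /
  coverage 0.67, discard ambiguous material (one sequence ↔ several loci,
  or several sequences ↔ one locus), and report per-taxon efficiency
  (captured loci / targeted loci), a loci × taxa occupancy matrix and a
  pairwise shared-locus matrix;

- **synthetic panels** — a generator that plants conserved cores
  (300-600 bp, 1-3 % divergence) in fast-evolving background (15 %) with
  soft-masked tandem repeats, optional locus dropout and transcriptome
  views, plus the exact truth table, so every stage is testable end to end.

All matching runs through one seed-and-extend local aligner with pinned
scoring (match +1, mismatch −1, gap open −5, gap extend −2) that is exactly
optimal on small targets; see `docs/methods.md` for the model and the
reasoning behind every threshold.

## Worked example

A five-taxon toy panel, end to end through the CLI:

```yaml
# config.yaml
seed: 7
priority: [taxon_01, taxon_02, taxon_03, taxon_04, taxon_05]
simulate: {n_taxa: 5, n_loci: 10}
design: {min_species_for_final: 4}
capture: {match_identity: 0.75, flank: 100}
```

```
$ uceforge simulate --config config.yaml --out sim
[uceforge] wrote 5 assemblies, 10 planted loci
$ uceforge discover --config config.yaml --assemblies sim/assemblies \
      --reference taxon_01 --out disc
[uceforge] called 10 conserved loci
$ uceforge design temp --config config.yaml --loci disc/loci.tsv \
      --reference sim/assemblies/taxon_01.fasta --out temp
[uceforge] temporary set: 20 probes, 10 loci
$ uceforge design master --config config.yaml --loci disc/loci.tsv \
      --reference taxon_01 --assemblies sim/assemblies \
      --temp-probes temp/temp_probes.fasta --out master
[uceforge] master set: 10 probes over 10 loci (10 final of 10 input)
$ uceforge capture --config config.yaml --probes master/master_probes.fasta \
      --assemblies sim/assemblies --out cap
[uceforge] captured panel of 5 assemblies; mean efficiency 1.000
$ uceforge report --run-dir cap
  taxon_01: 10 loci (occupancy-matrix sum 10), efficiency 1.000
  ...
mean efficiency (non-excluded): 1.0000
```

Reading the numbers: discovery recalls all 10 planted loci (each supported
by all 5 taxa at the 90 % occupancy threshold); the temporary set carries
the full 2 baits/locus; the master redesign pools 100 probes (10 loci × 5
taxa × 2) and the 50/50 redundancy screen collapses the near-identical
cross-taxon copies to one representative per locus; capturing the panel
with its own master set recovers every locus in every taxon, hence
efficiency 1.0. On real assemblies, divergence, missing data and repeat
content push efficiency well below 1 — the per-taxon summary and occupancy
matrix are where that structure shows up.

The library API mirrors the CLI (`uceforge.discover`,
`build_temporary_set`, `select_final_loci`, `build_master_set`,
`subset_by_taxa`, `merge_probe_sets`, `capture_panel`, `efficiency`,
`occupancy_and_shared`, `generate_panel`, ...).

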