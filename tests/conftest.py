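"""Shared fixtures: one small synthetic panel, discovered and designed once
per session, feeds most unit tests."""
from __future__ import annotations

import numpy as np
import pytest

import uceforge as uf

SMALL_SEED = 11


@pytest.fixture(scope="session")
def small_panel():
    """6 taxa x 12 planted loci; reference = taxon_01 at the ancestor."""
    params = uf.PanelParams(n_taxa=6, n_loci=12)
    assemblies, truth = uf.generate_panel(params, seed=SMALL_SEED)
    return assemblies, truth


@pytest.fixture(scope="session")
def small_loci(small_panel):
    assemblies, truth = small_panel
    reference = assemblies["taxon_01"]
    others = [assemblies[t] for t in truth.taxa[1:]]
    return uf.discover(reference, others, uf.DiscoveryParams())


@pytest.fixture(scope="session")
def small_design(small_panel, small_loci):
    """Temporary set, final loci and master set over the small panel."""
    assemblies, truth = small_panel
    reference = assemblies["taxon_01"]
    params = uf.DesignParams(min_species_for_final=5)
    temp = uf.build_temporary_set(small_loci, reference, params,
                                  priority=truth.taxa)
    from uceforge.bait_design import probe_presence_by_assembly
    presence = probe_presence_by_assembly(
        temp, list(assemblies.values()), params.master_identity,
        params.master_coverage)
    final = uf.select_final_loci(temp, small_loci, list(assemblies.values()),
                                 params, presence=presence)
    master = uf.build_master_set(final, reference, list(assemblies.values()),
                                 params, priority=truth.taxa)
    return {"params": params, "temp": temp, "presence": presence,
            "final": final, "master": master}


@pytest.fixture
def rng():
    return np.random.default_rng(SMALL_SEED)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
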