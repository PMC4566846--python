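import numpy as np
import pandas as pd
import pytest

from magicpop.breeding_sim import (
    FunnelDesign,
    genotype_mosaics,
    simulate_founder_panel,
    simulate_funnel_population,
    synthetic_map,
)
from magicpop.genome_model import GeneticMap
from magicpop.hmm_reconstruct import em_fit


@pytest.fixture(scope="session")
def tiny_map() -> GeneticMap:
    """Two chromosomes, 30 markers each, 1 Morgan per chromosome."""
    rows = []
    for c in (1, 2):
        for i in range(30):
            bp = 1 + i * 1_000_000
            rows.append((f"t{c}_{i}", c, bp, i * 100 / 29))
    return GeneticMap(
        pd.DataFrame(
            rows,
            columns=["marker_id", "chromosome", "position_bp", "position_cM"],
        )
    )


@pytest.fixture(scope="session")
def magic_map() -> GeneticMap:
    """Desk-scale synthetic array map: 10 chromosomes, 19.96 Morgans."""
    return synthetic_map(n_markers=1500, seed=11)


@pytest.fixture(scope="session")
def design() -> FunnelDesign:
    return FunnelDesign(lines_per_funnel=4)


@pytest.fixture(scope="session")
def population(design, magic_map):
    """140 simulated F6 lines with known mosaics."""
    return simulate_funnel_population(design, magic_map, rng=21)


@pytest.fixture(scope="session")
def founders(design, magic_map):
    return simulate_founder_panel(magic_map, design, seed=22)


@pytest.fixture(scope="session")
def genotypes(population, founders, magic_map):
    return genotype_mosaics(
        population, founders, magic_map,
        error_rate=0.01, missing_rate=0.15, rng=23,
    )


@pytest.fixture(scope="session")
def reconstruction(genotypes, founders, magic_map):
    return em_fit(genotypes, founders, magic_map, max_iter=6)


@pytest.fixture(scope="session")
def posteriors_8(reconstruction, founders):
    """Posterior array reduced to the eight main founders."""
    from magicpop.qtl_linkage import drop_ninth_founder

    res = reconstruction.results
    G = founders.n_founders
    P = np.zeros((len(res), res[0].posteriors.shape[0], G))
    for i, r in enumerate(res):
        P[i, :, : r.n_states] = r.posteriors
    if G == 9:
        P = drop_ninth_founder(P)[0]
    return P


@pytest.fixture(scope="session")
def truth_paths(population, magic_map):
    """Founder index of each homolog at every marker, per line."""
    bp = magic_map.table["position_bp"].to_numpy()
    ch = magic_map.table["chromosome"].to_numpy()
    idx = {c: np.flatnonzero(ch == c) for c in magic_map.chromosomes}
    out = []
    for mos in population:
        t0 = np.empty(len(bp), dtype=int)
        t1 = np.empty(len(bp), dtype=int)
        for c, ix in idx.items():
            h0, h1 = mos.homologs[c]
            t0[ix] = h0.founder_at(bp[ix])
            t1[ix] = h1.founder_at(bp[ix])
        out.append((t0, t1))
    return out
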