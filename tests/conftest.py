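import numpy as np
import pandas as pd
import pytest

import sortscreen as ss


@pytest.fixture
def toy_library() -> pd.DataFrame:
    """Four targeting sgRNAs (two genes) plus two NTCs, one sublibrary."""
    return pd.DataFrame(
        {
            "sgrna_id": ["g1_sg1", "g1_sg2", "g2_sg1", "g2_sg2", "ntc_1", "ntc_2"],
            "protospacer": ["ACGTA", "CCGTA", "GCGTA", "TCGTA", "AAGTA", "ACGTT"],
            "target_gene": ["GENE1", "GENE1", "GENE2", "GENE2", "NTC", "NTC"],
            "is_ntc": [False, False, False, False, True, True],
            "sublibrary": ["lib0"] * 6,
        }
    )


def small_sim_params(seed: int = 11, **overrides) -> ss.SimParams:
    """A fast, small screen: 120 genes, 60 NTCs, modest depth."""
    defaults = dict(
        n_genes=120,
        n_ntc=60,
        frac_modifiers=0.1,
        effect_dist="fixed",
        effect_mu_sd=2.0,
        cells_per_sgrna=80,
        reads_per_bin=200_000,
        seed=seed,
    )
    defaults.update(overrides)
    return ss.SimParams(**defaults)


@pytest.fixture(scope="session")
def small_screen():
    """One small simulated screen, scored: (library, counts, truth, result)."""
    params = small_sim_params()
    library, counts, truth = ss.simulate_screen(params)
    result = ss.score_screen(counts, library, seed=params.seed)
    return library, counts, truth, result


def mwu_enumeration_pvalue(gene: np.ndarray, ntc: np.ndarray) -> float:
    """Independent brute-force two-sided Mann-Whitney p-value.

    Enumerates every assignment of the pooled (tie-free) values to a
    gene-sized subset, computes the U statistic of each, and counts
    assignments at least as extreme as the observed one under the
    symmetric two-sided rule min(1, P(U <= u_min) + P(U >= nm - u_min)).
    """
    from itertools import combinations

    pooled = np.concatenate([gene, ntc])
    n, m = len(gene), len(ntc)
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"

    def u_stat(g_vals, n_vals):
        return sum(1.0 for a in g_vals for b in n_vals if a > b)

    u_obs = u_stat(gene, ntc)
    u_min = min(u_obs, n * m - u_obs)
    total = 0
    extreme = 0
    idx = range(n + m)
    for comb in combinations(idx, n):
        g_vals = pooled[list(comb)]
        rest = pooled[[i for i in idx if i not in comb]]
        u = u_stat(g_vals, rest)
        total += 1
        if u <= u_min or u >= n * m - u_min:
            extreme += 1
    return min(1.0, extreme / total)
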