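"""Calibration and power experiments on simulated screens.

These run the full pipeline (simulate → phenotypes → Mann–Whitney →
quasi-gene null → empirical-FDR hits) on a fixed screen geometry of 2,000
genes × 5 sgRNAs plus 400 NTCs, 300 cells per sgRNA at sort and 2×10⁶
reads per 30% bin — a desk-scale rendition of a genome-scale bin-sort
screen — and measure hit-calling behaviour against the simulation's
ground truth.
"""

from __future__ import annotations

from typing import Sequence

from .simulate import SimParams, evaluate_recovery, simulate_screen
from .stats import score_screen


def study_params(
    seed: int,
    frac_modifiers: float = 0.05,
    effect_mu_sd: float = 2.0,
    effect_dist: str = "fixed",
) -> SimParams:
    """The standard experiment geometry with configurable effect structure."""
    return SimParams(
        n_genes=2000,
        sgrnas_per_gene=5,
        n_ntc=400,
        frac_modifiers=frac_modifiers,
        effect_mu_sd=effect_mu_sd,
        effect_dist=effect_dist,
        efficacy_range=(0.7, 1.0),
        cell_noise_sd=1.0,
        cells_per_sgrna=300,
        reads_per_bin=2_000_000,
        bin_fraction=0.30,
        seed=seed,
    )


def run_screen_metrics(params: SimParams, alpha: float = 0.05) -> dict:
    """Simulate one screen, score it, and evaluate recovery vs truth."""
    library, counts, truth = simulate_screen(params)
    result = score_screen(counts, library, seed=params.seed, alpha=alpha)
    return evaluate_recovery(result, truth)


def null_hit_fractions(seeds: Sequence[int], alpha: float = 0.05) -> list[float]:
    """Fraction of genes called hits on screens with zero true modifiers."""
    return [
        run_screen_metrics(study_params(seed, frac_modifiers=0.0), alpha)["hit_fraction"]
        for seed in seeds
    ]


def recovery_at_effect_size(
    mu: float, seeds: Sequence[int], alpha: float = 0.05
) -> dict[str, list]:
    """Recall/FDP/sign accuracy at fixed |μ| = mu, 5% modifier genes."""
    out: dict[str, list] = {"recall": [], "false_discovery_proportion": [], "sign_accuracy": []}
    for seed in seeds:
        m = run_screen_metrics(study_params(seed, effect_mu_sd=mu), alpha)
        out["recall"].append(m["recall"])
        out["false_discovery_proportion"].append(m["false_discovery_proportion"] or 0.0)
        out["sign_accuracy"].append(m["sign_accuracy"])
    return out
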