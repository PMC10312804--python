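"""Generative model of a FACS bin-sort pooled CRISPR screen.

The model emulates the design of a reporter-based CRISPRi screen: a library
of 5 sgRNAs per gene plus non-targeting controls is delivered to a pool of
cells; each cell's log-reporter signal is shifted by its sgRNA's (gene
effect × sgRNA efficacy); the pool is gated into the lowest and highest
30% of the global reporter distribution, and each bin is sequenced as a
multinomial draw over the sgRNAs of the cells it contains.

The simulation is fully deterministic given the seed and returns ground
truth (per-gene effect sizes and modifier flags, per-sgRNA efficacies) so
that hit-calling performance can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import ScreenResult

_PROTO_LEN = 20
_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Parameters of the simulated screen.

    Effect sizes are in units of the cell-level log-reporter noise SD
    (``cell_noise_sd``, default 1). ``effect_dist`` chooses how modifier
    effects are drawn: ``"normal"`` draws μ_g ~ Normal(0, effect_mu_sd²);
    ``"fixed"`` sets |μ_g| = effect_mu_sd with a random sign, which is the
    natural design for power analyses at a controlled effect magnitude.
    ``bin_fraction`` is the proportion of cells gated into each tail bin
    (0.30 mirrors a lowest-30%/highest-30% FACS sort).
    """

    n_genes: int = 2000
    sgrnas_per_gene: int = 5
    n_ntc: int = 400
    frac_modifiers: float = 0.05
    effect_mu_sd: float = 2.0
    effect_dist: str = "normal"
    efficacy_range: tuple[float, float] = (0.7, 1.0)
    cell_noise_sd: float = 1.0
    cells_per_sgrna: int = 300
    reads_per_bin: int = 2_000_000
    bin_fraction: float = 0.30
    seed: int = 0
    #: optional separate seed for the cell/sequencing noise; with a fixed
    #: `seed` and different `noise_seed` values the same ground truth is
    #: re-screened, emulating replicate screens on one library
    noise_seed: int | None = None

    def validate(self) -> None:
        if not 0 < self.bin_fraction <= 0.5:
            raise ValidationError(f"bin_fraction must be in (0, 0.5], got {self.bin_fraction}")
        lo, hi = self.efficacy_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError(f"efficacy_range must satisfy 0<=lo<=hi<=1, got {self.efficacy_range}")
        if not 0 <= self.frac_modifiers <= 1:
            raise ValidationError(f"frac_modifiers must be in [0,1], got {self.frac_modifiers}")
        if self.effect_dist not in ("normal", "fixed"):
            raise ValidationError(f"effect_dist must be 'normal' or 'fixed', got {self.effect_dist!r}")
        for name in ("n_genes", "sgrnas_per_gene", "n_ntc", "cells_per_sgrna", "reads_per_bin"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated screen."""

    genes: pd.DataFrame  # gene, mu, is_modifier
    sgrnas: pd.DataFrame  # sgrna_id, target_gene, efficacy
    params: SimParams = field(repr=False, default=None)


def _protospacers(n: int) -> list[str]:
    """Deterministic unique ACGT strings: index in base 4, fixed width."""
    idx = np.arange(n)
    digits = np.empty((n, _PROTO_LEN), dtype=int)
    for j in range(_PROTO_LEN - 1, -1, -1):
        digits[:, j] = idx % 4
        idx //= 4
    return ["".join(row) for row in _BASES[digits]]


def simulate_screen(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate one screen; returns (library, bin counts, truth).

    Steps: draw gene effects μ_g (0 for non-modifiers and NTCs) and
    per-sgRNA efficacies e_i ~ Uniform(efficacy_range); give each of
    ``cells_per_sgrna`` cells per sgRNA a log-reporter value
    x ~ Normal(e_i·μ_g, cell_noise_sd²); gate the pooled cells into the
    global lowest and highest ``bin_fraction`` tails; sequence each bin as
    Multinomial(reads_per_bin, p ∝ cells per sgRNA in the bin).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i:05d}" for i in range(params.n_genes)]
    n_mod = int(round(params.frac_modifiers * params.n_genes))
    mod_idx = rng.choice(params.n_genes, size=n_mod, replace=False)
    mu = np.zeros(params.n_genes)
    if params.effect_dist == "normal":
        mu[mod_idx] = rng.normal(0.0, params.effect_mu_sd, size=n_mod)
    else:  # fixed magnitude, random sign
        mu[mod_idx] = params.effect_mu_sd * rng.choice([-1.0, 1.0], size=n_mod)

    n_targeting = params.n_genes * params.sgrnas_per_gene
    n_sg = n_targeting + params.n_ntc
    sg_ids = [
        f"{genes[g]}_sg{j + 1}"
        for g in range(params.n_genes)
        for j in range(params.sgrnas_per_gene)
    ] + [f"NTC_{i:05d}" for i in range(params.n_ntc)]
    target = np.repeat(genes, params.sgrnas_per_gene).tolist() + ["NTC"] * params.n_ntc
    is_ntc = np.zeros(n_sg, dtype=bool)
    is_ntc[n_targeting:] = True

    lo, hi = params.efficacy_range
    efficacy = np.zeros(n_sg)
    efficacy[:n_targeting] = rng.uniform(lo, hi, size=n_targeting)
    sg_mu = np.zeros(n_sg)
    sg_mu[:n_targeting] = np.repeat(mu, params.sgrnas_per_gene)
    shift = efficacy * sg_mu

    if params.noise_seed is not None:
        rng = np.random.default_rng(params.noise_seed)
    n_cells = n_sg * params.cells_per_sgrna
    cell_sg = np.repeat(np.arange(n_sg), params.cells_per_sgrna)
    x = rng.normal(np.repeat(shift, params.cells_per_sgrna), params.cell_noise_sd)

    k = int(round(params.bin_fraction * n_cells))
    if k < 1:
        raise ValidationError("bin_fraction × total cells < 1 cell; raise coverage")
    order = np.argsort(x, kind="stable")
    low_cells = np.bincount(cell_sg[order[:k]], minlength=n_sg)
    high_cells = np.bincount(cell_sg[order[-k:]], minlength=n_sg)
    counts = {}
    for bin_name, cells in (("count_low", low_cells), ("count_high", high_cells)):
        total = cells.sum()
        if total == 0:
            raise ValidationError(f"{bin_name} bin received zero cells; raise coverage")
        counts[bin_name] = rng.multinomial(params.reads_per_bin, cells / total)

    library = pd.DataFrame(
        {
            "sgrna_id": sg_ids,
            "protospacer": _protospacers(n_sg),
            "target_gene": target,
            "is_ntc": is_ntc,
            "sublibrary": "lib0",
        }
    )
    count_df = pd.DataFrame(
        {
            "sgrna_id": sg_ids,
            "count_low": counts["count_low"],
            "count_high": counts["count_high"],
            "screen_id": f"sim_seed{params.seed}"
            + (f"_rep{params.noise_seed}" if params.noise_seed is not None else ""),
        }
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {"gene": genes, "mu": mu, "is_modifier": np.isin(np.arange(params.n_genes), mod_idx)}
        ),
        sgrnas=pd.DataFrame(
            {"sgrna_id": sg_ids, "target_gene": target, "efficacy": efficacy}
        ),
        params=params,
    )
    return library, count_df, truth


def evaluate_recovery(result: ScreenResult, truth: SimTruth) -> dict:
    """Hit-calling performance against simulation ground truth.

    Returns precision, recall (power), the observed false-discovery
    proportion among called hits, and sign accuracy (fraction of true-
    positive hits whose direction matches sign(μ_g)). Undefined ratios
    (no hits, no modifiers) are reported as None.
    """
    genes = result.genes.merge(truth.genes, on="gene", how="left")
    hits = genes[genes["is_hit"].fillna(False)]
    modifiers = genes[genes["is_modifier"].fillna(False)]
    n_hits, n_mod = len(hits), len(modifiers)
    tp = hits[hits["is_modifier"].fillna(False)]
    n_tp = len(tp)
    sign_ok = (
        int(((tp["mu"] > 0) == (tp["direction"] == "+")).sum()) if n_tp else 0
    )
    return {
        "n_hits": n_hits,
        "n_modifiers": n_mod,
        "n_true_positives": n_tp,
        "precision": n_tp / n_hits if n_hits else None,
        "recall": n_tp / n_mod if n_mod else None,
        "false_discovery_proportion": (n_hits - n_tp) / n_hits if n_hits else None,
        "sign_accuracy": sign_ok / n_tp if n_tp else None,
        "hit_fraction": n_hits / len(genes) if len(genes) else None,
    }


def params_record(params: SimParams) -> dict:
    d = asdict(params)
    d["efficacy_range"] = list(d["efficacy_range"])
    return d
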