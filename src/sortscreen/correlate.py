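"""Expression-vs-vulnerability correlation across cell types.

Given, per cell type, a gene's expression (or expression-change effect
size) and the cell type's abundance-change effect size, this module
computes the Pearson correlation between the two, Benjamini–Hochberg
adjustment of the per-gene p-values, and a bootstrap 95% confidence band
around the ordinary least-squares regression line (case resampling, 1,000
resamples by default). Upstream per-cell-type effect-size estimation is
out of scope and consumed as an input table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, pearsonr

from .errors import DegenerateStatisticError, ValidationError

_MAX_RESAMPLE_RETRIES = 100


def _validate_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    for col in ("value_x", "value_y"):
        if col not in table.columns:
            raise ValidationError(f"table missing column {col!r}")
    if len(table) < 3:
        raise ValidationError(f"need >= 3 cell types, got {len(table)}")
    x = table["value_x"].to_numpy(float)
    y = table["value_y"].to_numpy(float)
    return x, y


def correlate(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson r and two-sided p-value of value_x vs value_y."""
    x, y = _validate_xy(table)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("constant vector: correlation undefined")
    r, p = pearsonr(x, y)
    # a perfect line yields p exactly 0; keep p in (0, 1] for BH downstream
    return float(r), float(max(p, 5e-324))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return false_discovery_control(p, method="bh")


@dataclass
class BootstrapFit:
    """OLS line with a per-x bootstrap confidence band."""

    slope: float
    intercept: float
    band: pd.DataFrame  # columns: x, y_fit, ci_low, ci_high
    n_boot: int
    seed: int


def bootstrap_fit(
    table: pd.DataFrame, n_boot: int = 1000, seed: int = 0, ci: float = 95.0
) -> BootstrapFit:
    """OLS fit of value_y on value_x with a case-resampling bootstrap band.

    Rows (cell types) are resampled with replacement ``n_boot`` times; the
    band at each observed x is the (2.5, 97.5) percentile of the refit
    lines' fitted values. A resample with constant x cannot be fit and is
    redrawn (capped retries). Deterministic given ``seed``.
    """
    x, y = _validate_xy(table)
    if np.ptp(x) == 0:
        raise DegenerateStatisticError("constant value_x: regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    n = len(x)
    fits = np.empty((n_boot, n))
    for b in range(n_boot):
        for attempt in range(_MAX_RESAMPLE_RETRIES):
            idx = rng.integers(0, n, size=n)
            if np.ptp(x[idx]) > 0:
                break
        else:
            raise DegenerateStatisticError(
                "could not draw a bootstrap resample with non-constant x"
            )
        s, c = np.polyfit(x[idx], y[idx], 1)
        fits[b] = s * x + c
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(fits, [half, 100.0 - half], axis=0)
    band = pd.DataFrame(
        {"x": x, "y_fit": slope * x + intercept, "ci_low": lo, "ci_high": hi}
    )
    return BootstrapFit(
        slope=float(slope), intercept=float(intercept), band=band, n_boot=n_boot, seed=seed
    )


def correlate_genes(
    long_table: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-gene correlation over a long-format (gene, cell_type, x, y) table.

    Returns one row per gene with Pearson r, raw p, and BH-adjusted p
    (the adjustment family is whatever set of genes the input contains).
    """
    if "gene" not in long_table.columns:
        raise ValidationError("long-format table requires a 'gene' column")
    rows = []
    for gene, grp in long_table.groupby("gene", sort=True):
        r, p = correlate(grp)
        rows.append((gene, len(grp), r, p))
    out = pd.DataFrame(rows, columns=["gene", "n_cell_types", "pearson_r", "p_value"])
    out["p_adj"] = adjust_fdr(out["p_value"].to_numpy())
    return out
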