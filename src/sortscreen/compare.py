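"""Pairwise and multi-screen comparison of scored screens.

Screens run with the same library under different conditions (different
antibodies, genotypes, lots) are compared by the Pearson correlation of
their normalized gene scores over common genes, by lists of genes unique
to one screen at a |normalized score| cutoff (±5 by convention), and by
Venn-region overlaps of their hit-gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import pearsonr

from .errors import DegenerateStatisticError, ValidationError
from .stats import ScreenResult


@dataclass
class ComparisonResult:
    """Pairwise screen comparison: concordance and screen-unique genes."""

    screen_a: str
    screen_b: str
    pearson_r: float
    pearson_p: float
    n_common: int
    unique_a: tuple[str, ...]
    unique_b: tuple[str, ...]
    cutoff: float
    n_only_a: int = 0  # genes scored in a but absent from b (excluded)
    n_only_b: int = 0


def compare_screens(
    a: ScreenResult,
    b: ScreenResult,
    cutoff: float = 5.0,
    hits_only: bool = False,
) -> ComparisonResult:
    """Compare two scored screens on their common genes.

    Pearson r is computed over the normalized scores of genes present in
    both screens (optionally restricted to genes that are a hit in either);
    ``unique_a`` lists common genes with \\|norm_score| ≥ ``cutoff`` in
    screen a but not in screen b (and symmetrically for b). Genes scored
    in only one screen are excluded from both statistics and counted.
    """
    ga = a.genes[["gene", "norm_score"] + (["is_hit"] if hits_only else [])]
    gb = b.genes[["gene", "norm_score"] + (["is_hit"] if hits_only else [])]
    merged = ga.merge(gb, on="gene", suffixes=("_a", "_b"))
    n_only_a = len(ga) - len(merged)
    n_only_b = len(gb) - len(merged)
    if hits_only:
        merged = merged[merged["is_hit_a"] | merged["is_hit_b"]]
    if len(merged) < 3:
        raise ValidationError(
            f"need >= 3 common genes to compare screens, got {len(merged)}"
        )
    xa = merged["norm_score_a"].to_numpy()
    xb = merged["norm_score_b"].to_numpy()
    if xa.std() == 0 or xb.std() == 0:
        raise DegenerateStatisticError("zero variance in a screen's score vector")
    r, p = pearsonr(xa, xb)
    hi_a = merged["norm_score_a"].abs() >= cutoff
    hi_b = merged["norm_score_b"].abs() >= cutoff
    unique_a = tuple(sorted(merged.loc[hi_a & ~hi_b, "gene"]))
    unique_b = tuple(sorted(merged.loc[hi_b & ~hi_a, "gene"]))
    return ComparisonResult(
        screen_a=a.screen_id,
        screen_b=b.screen_id,
        pearson_r=float(r),
        pearson_p=float(p),
        n_common=len(merged),
        unique_a=unique_a,
        unique_b=unique_b,
        cutoff=cutoff,
        n_only_a=n_only_a,
        n_only_b=n_only_b,
    )


def _hit_set(result: ScreenResult, direction: str, blacklist: set[str]) -> set[str]:
    genes = result.genes.loc[result.genes["is_hit"].astype(bool)]
    if direction == "+":
        genes = genes[genes["direction"] == "+"]
    elif direction == "-":
        genes = genes[genes["direction"] == "-"]
    elif direction != "both":
        raise ValidationError(f"direction must be '+', '-', or 'both', got {direction!r}")
    return set(genes["gene"]) - blacklist


def overlap_hits(
    screens: Sequence[ScreenResult],
    direction: str = "both",
    blacklist: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """Venn-region decomposition of hit genes across 2 or 3 screens.

    Each region is keyed by the '&'-joined ids of the screens whose hit
    sets contain exactly those genes (e.g. ``"T22&TOC1"`` holds hits shared
    by T22 and TOC1 but absent from any third screen). ``blacklist``
    (e.g. a user-supplied mitochondrial gene list) is removed from every
    hit set first; ``direction`` optionally restricts to hits whose
    phenotype is positive or negative.
    """
    if not 2 <= len(screens) <= 3:
        raise ValidationError(f"overlap_hits takes 2 or 3 screens, got {len(screens)}")
    ids = [s.screen_id for s in screens]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"screen ids must be distinct, got {ids}")
    bl = set(blacklist) if blacklist is not None else set()
    sets = {s.screen_id: _hit_set(s, direction, bl) for s in screens}
    regions: dict[str, list[str]] = {}
    for r in range(len(ids), 0, -1):
        for members in combinations(ids, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(set(), *(sets[m] for m in ids if m not in members))
            regions["&".join(members)] = sorted(inside - outside)
    return regions
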