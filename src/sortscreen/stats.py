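"""Gene-level statistics for bin-sorted pooled CRISPR screens.

The analysis mirrors the MAGeCK-iNC style of scoring used for FACS bin-sort
CRISPRi screens:

1. Each sgRNA gets a **phenotype score** ε, the log2 ratio of its frequency
   in the high-signal bin versus the low-signal bin, optionally centered on
   the median ε of the non-targeting controls (NTCs).
2. Each gene gets a two-sided **Mann–Whitney U p-value** comparing its
   sgRNA ε values against all NTC ε values, and a **gene score**
   ``phenotype × (−log10 p)`` where the gene phenotype aggregates member ε
   (by default the mean of the 3 sgRNAs largest in |ε|).
3. **Quasi-genes** — random disjoint groups of NTCs the size of a real
   gene's sgRNA set — are scored identically and provide the empirical
   null: gene scores are divided by the standard deviation of quasi-gene
   scores (per sublibrary) to give normalized scores, and hits are called
   at an empirical false-discovery rate computed from the fraction of
   quasi-genes exceeding each candidate |normalized score| threshold.

Frequencies use a pseudocount applied on the frequency scale
(``pseudocount / N`` per sgRNA, N the number of sgRNAs in the sublibrary),
which equals adding ``pseudocount`` reads per sgRNA at a reference depth of
N reads and makes every downstream statistic exactly invariant to
sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import DegenerateStatisticError, ValidationError

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # clamp for degenerate asymptotic p-values; keeps p in (0, 1]


@dataclass(frozen=True)
class QuasiGeneSet:
    """A seeded random partition of NTC sgRNAs into gene-sized groups."""

    groups: tuple[tuple[str, ...], ...]
    m: int
    seed: int
    leftover: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class ScreenResult:
    """Scored screen: per-gene and per-quasi-gene tables plus parameters.

    The ``params`` record holds everything needed to regenerate the result
    from the raw counts (pseudocount, quasi group size and seed, FDR level,
    aggregation rule, and the hit threshold record per sublibrary).
    """

    screen_id: str
    genes: pd.DataFrame
    quasi: pd.DataFrame
    params: dict = field(default_factory=dict)


def compute_phenotypes(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    pseudocount: float = 1.0,
    center_on_ntc: bool = True,
    min_count: int = 0,
) -> pd.DataFrame:
    """Per-sgRNA phenotype scores ε from two-bin counts.

    Within each sublibrary (separately sequenced pools are normalized
    separately): ``f_bin(i) = count_bin(i)/T_bin + pseudocount/N`` and
    ``ε_raw(i) = log2(f_high(i)/f_low(i))``; with ``center_on_ntc`` the
    per-sublibrary NTC median of ε_raw is subtracted so NTCs sit at 0.

    ``min_count`` (default 0 = off) drops sgRNAs whose count in either bin
    falls below the threshold, before frequencies are computed.
    """
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    df = library[["sgrna_id", "target_gene", "is_ntc", "sublibrary"]].merge(
        counts[["sgrna_id", "count_low", "count_high"]], on="sgrna_id", how="left"
    )
    if df["count_low"].isna().any():
        df = df.fillna({"count_low": 0, "count_high": 0})
    if min_count > 0:
        keep = (df["count_low"] >= min_count) & (df["count_high"] >= min_count)
        if (~keep).any():
            logger.info("min_count=%d filter removed %d sgRNAs", min_count, int((~keep).sum()))
        df = df[keep].reset_index(drop=True)
    out = []
    for sub, grp in df.groupby("sublibrary", sort=True):
        t_low = grp["count_low"].sum()
        t_high = grp["count_high"].sum()
        if t_low <= 0 or t_high <= 0:
            raise ValidationError(f"sublibrary {sub!r} has a zero-read bin")
        delta = pseudocount / len(grp)
        f_low = grp["count_low"].to_numpy(float) / t_low + delta
        f_high = grp["count_high"].to_numpy(float) / t_high + delta
        eps = np.log2(f_high / f_low)
        if center_on_ntc:
            ntc_mask = grp["is_ntc"].to_numpy()
            if not ntc_mask.any():
                raise ValidationError(
                    f"NTC-median centering requested but sublibrary {sub!r} has no NTCs"
                )
            eps = eps - np.median(eps[ntc_mask])
        sub_out = grp[["sgrna_id", "target_gene", "is_ntc", "sublibrary"]].copy()
        sub_out["epsilon"] = eps
        out.append(sub_out)
    return pd.concat(out, ignore_index=True)


def gene_pvalue(
    gene_eps: Sequence[float], ntc_eps: Sequence[float], mode: str = "auto"
) -> float:
    """Two-sided Mann–Whitney U p-value of gene sgRNA phenotypes vs NTCs.

    ``mode='auto'`` uses the exact null distribution when the gene has ≤ 8
    sgRNAs and the pooled values are tie-free, otherwise the tie-corrected
    normal approximation. The return value is clamped to (0, 1]; if every
    value in both samples is identical the p-value is 1.
    """
    gene = np.asarray(gene_eps, dtype=float)
    ntc = np.asarray(ntc_eps, dtype=float)
    if gene.size == 0:
        raise ValidationError("gene_pvalue requires a non-empty gene sample")
    if ntc.size < 2:
        raise ValidationError("gene_pvalue requires >= 2 NTC values")
    pooled = np.concatenate([gene, ntc])
    n_unique = np.unique(pooled).size
    if n_unique == 1:
        return 1.0
    has_ties = n_unique < pooled.size
    if mode == "auto":
        mode = "exact" if (gene.size <= 8 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValidationError("exact Mann-Whitney mode requires tie-free data")
        p = mannwhitneyu(gene, ntc, alternative="two-sided", method="exact").pvalue
    elif mode == "normal":
        p = mannwhitneyu(gene, ntc, alternative="two-sided", method="asymptotic").pvalue
    else:
        raise ValidationError(f"unknown p-value mode {mode!r}")
    return float(min(max(p, _P_FLOOR), 1.0))


def build_quasi_genes(ntc_ids: Sequence[str], m: int = 5, seed: int = 0) -> QuasiGeneSet:
    """Partition NTC sgRNAs into disjoint random groups of size ``m``.

    A single seeded uniform permutation of the NTC ids is chunked into
    ``floor(n/m)`` groups; the remainder ids are unused (and logged).
    Regeneration with the same ids, m and seed is identical.
    """
    ids = list(ntc_ids)
    if m < 2:
        raise ValidationError(f"quasi-gene size m must be >= 2, got {m}")
    if len(ids) < m:
        raise ValidationError(f"need at least m={m} NTCs, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_groups = len(ids) // m
    groups = tuple(tuple(perm[i * m : (i + 1) * m]) for i in range(n_groups))
    leftover = tuple(perm[n_groups * m :])
    if leftover:
        logger.info("%d NTC sgRNAs left over after quasi-gene grouping", len(leftover))
    return QuasiGeneSet(groups=groups, m=m, seed=seed, leftover=leftover)


def _aggregate(eps: np.ndarray, ids: np.ndarray, aggregation: str, k: int) -> float:
    if aggregation == "mean_all":
        return float(np.mean(eps))
    if aggregation == "top_k_by_abs":
        # deterministic tie-break on sgRNA id
        order = np.lexsort((ids, -np.abs(eps)))
        return float(np.mean(eps[order[: min(k, len(eps))]]))
    raise ValidationError(f"unknown aggregation {aggregation!r}")


def score_genes(
    phenotypes: pd.DataFrame,
    quasi: QuasiGeneSet | Mapping[str, QuasiGeneSet],
    aggregation: str = "top_k_by_abs",
    k: int = 3,
    pvalue_mode: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every gene and quasi-gene: phenotype, p-value, gene score.

    The gene phenotype is the aggregation of member ε (default: mean of the
    ``k``\\ =3 sgRNAs largest in \\|ε|; a gene with fewer members uses all of
    them); the p-value is the Mann–Whitney U test of member ε against all
    NTC ε in the same sublibrary; the score is ``phenotype × (−log10 p)``.
    Quasi-genes are scored by the identical procedure. Genes with fewer
    than 2 sgRNAs get p = 1 and a ``low_confidence`` flag.

    ``quasi`` is either one :class:`QuasiGeneSet` (single-sublibrary
    screens) or a mapping from sublibrary label to its QuasiGeneSet.
    """
    sublibs = sorted(phenotypes["sublibrary"].unique())
    if isinstance(quasi, QuasiGeneSet):
        if len(sublibs) != 1:
            raise ValidationError(
                "a single QuasiGeneSet was given for a multi-sublibrary screen; "
                "pass a mapping sublibrary -> QuasiGeneSet"
            )
        quasi_map: Mapping[str, QuasiGeneSet] = {sublibs[0]: quasi}
    else:
        quasi_map = quasi
    eps_by_id = dict(zip(phenotypes["sgrna_id"], phenotypes["epsilon"]))
    gene_rows, quasi_rows = [], []
    for sub in sublibs:
        grp = phenotypes[phenotypes["sublibrary"] == sub]
        ntc_eps = grp.loc[grp["is_ntc"], "epsilon"].to_numpy()
        for gene, g in grp[~grp["is_ntc"]].groupby("target_gene", sort=True):
            eps = g["epsilon"].to_numpy()
            ids = g["sgrna_id"].to_numpy()
            if len(eps) == 0:
                logger.info("gene %s has no surviving sgRNAs; excluded", gene)
                continue
            phen = _aggregate(eps, ids, aggregation, k)
            low_conf = len(eps) < 2
            p = 1.0 if low_conf else gene_pvalue(eps, ntc_eps, mode=pvalue_mode)
            gene_rows.append((gene, sub, len(eps), phen, p, phen * -np.log10(p), low_conf))
        qset = quasi_map.get(sub)
        if qset is None:
            raise ValidationError(f"no QuasiGeneSet supplied for sublibrary {sub!r}")
        for i, members in enumerate(qset.groups):
            eps = np.array([eps_by_id[sg] for sg in members if sg in eps_by_id])
            if len(eps) == 0:
                continue
            ids = np.array([sg for sg in members if sg in eps_by_id])
            phen = _aggregate(eps, ids, aggregation, k)
            low_conf = len(eps) < 2
            p = 1.0 if low_conf else gene_pvalue(eps, ntc_eps, mode=pvalue_mode)
            quasi_rows.append(
                (f"quasi_{sub}_{i:04d}", sub, len(eps), phen, p, phen * -np.log10(p), low_conf)
            )
    cols = ["gene", "sublibrary", "n_sgrnas", "phenotype", "p_value", "score", "low_confidence"]
    gene_df = pd.DataFrame(gene_rows, columns=cols)
    quasi_df = pd.DataFrame(quasi_rows, columns=cols)
    for df in (gene_df, quasi_df):
        df["direction"] = np.where(df["phenotype"] >= 0, "+", "-")
    return gene_df, quasi_df


def normalize_scores(
    gene_df: pd.DataFrame, quasi_df: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Divide gene and quasi-gene scores by the quasi-gene score SD.

    The SD (sample SD, ddof=1) is computed per sublibrary, so each
    sublibrary's empirical null has unit spread after normalization.
    Returns the two tables with a ``norm_score`` column plus the per-
    sublibrary sigma record.
    """
    sigmas: dict[str, float] = {}
    for sub in sorted(gene_df["sublibrary"].unique()):
        q = quasi_df.loc[quasi_df["sublibrary"] == sub, "score"]
        if len(q) < 2:
            raise ValidationError(f"sublibrary {sub!r} has fewer than 2 quasi-genes")
        sigma = float(q.std(ddof=1))
        if sigma == 0.0:
            raise DegenerateStatisticError(
                f"quasi-gene score SD is zero in sublibrary {sub!r}"
            )
        sigmas[sub] = sigma
    gene_df = gene_df.copy()
    quasi_df = quasi_df.copy()
    for df in (gene_df, quasi_df):
        df["norm_score"] = df["score"] / df["sublibrary"].map(sigmas)
    return gene_df, quasi_df, sigmas


def _call_hits_family(
    gene_ns: np.ndarray, quasi_ns: np.ndarray, alpha: float
) -> tuple[float | None, pd.DataFrame]:
    """Empirical-FDR threshold for one normalization family (sublibrary).

    For each candidate threshold t (the observed gene |norm_score| values),
    FDR̂(t) = [(#quasi ≥ t)/N_quasi] · N_genes / max(1, #genes ≥ t); the
    quasi exceedance fraction is rescaled to the gene-list size so that the
    ratio estimates the number of false positives among the genes called.
    Returns (t*, curve) where t* is the smallest candidate with FDR̂ ≤ α,
    or None if no candidate qualifies.
    """
    g = np.sort(np.abs(gene_ns))
    q = np.sort(np.abs(quasi_ns))
    cand = np.unique(g)
    n_gene_ge = len(g) - np.searchsorted(g, cand, side="left")
    n_quasi_ge = len(q) - np.searchsorted(q, cand, side="left")
    fdr = (n_quasi_ge / len(q)) * len(g) / np.maximum(1, n_gene_ge)
    curve = pd.DataFrame(
        {"threshold": cand, "n_genes_ge": n_gene_ge, "n_quasi_ge": n_quasi_ge, "fdr_hat": fdr}
    )
    ok = np.nonzero(fdr <= alpha)[0]
    t_star = float(cand[ok[0]]) if len(ok) else None
    return t_star, curve


def call_hits(
    gene_df: pd.DataFrame,
    quasi_df: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Flag hit genes at empirical FDR ``alpha`` on \\|norm_score|.

    Thresholds are calibrated per sublibrary against that sublibrary's
    quasi-genes. Returns the gene and quasi tables with an ``is_hit``
    column (quasi-genes exceeding the threshold are flagged too, for
    auditing) and a per-sublibrary threshold record including the full
    FDR̂ curve.
    """
    if not 0 <= alpha < 1:
        raise ValidationError(f"alpha must be in [0, 1), got {alpha}")
    if "norm_score" not in gene_df.columns:
        raise ValidationError("call_hits requires normalized scores; run normalize_scores")
    gene_df = gene_df.copy()
    quasi_df = quasi_df.copy()
    gene_df["is_hit"] = False
    quasi_df["is_hit"] = False
    record: dict = {"alpha": alpha, "sublibraries": {}}
    for sub in sorted(gene_df["sublibrary"].unique()):
        gmask = gene_df["sublibrary"] == sub
        qmask = quasi_df["sublibrary"] == sub
        t_star, curve = _call_hits_family(
            gene_df.loc[gmask, "norm_score"].to_numpy(),
            quasi_df.loc[qmask, "norm_score"].to_numpy(),
            alpha,
        )
        if t_star is None:
            logger.warning("sublibrary %r: no threshold achieves FDR <= %g; zero hits", sub, alpha)
        else:
            gene_df.loc[gmask, "is_hit"] = gene_df.loc[gmask, "norm_score"].abs() >= t_star
            quasi_df.loc[qmask, "is_hit"] = quasi_df.loc[qmask, "norm_score"].abs() >= t_star
        record["sublibraries"][sub] = {
            "threshold": t_star,
            "fdr_curve": curve.to_dict(orient="list"),
        }
    return gene_df, quasi_df, record


def combine_sublibraries(results: Sequence[ScreenResult]) -> ScreenResult:
    """Concatenate per-sublibrary screen results into one screen-level result.

    A gene must live in exactly one sublibrary; overlapping gene sets are a
    hard error. Hit flags and normalized scores are preserved unchanged.
    """
    if not results:
        raise ValidationError("no results to combine")
    seen: dict[str, str] = {}
    offenders = []
    for res in results:
        for gene, sub in zip(res.genes["gene"], res.genes["sublibrary"]):
            if gene in seen and seen[gene] != sub:
                offenders.append(gene)
            seen[gene] = sub
    if offenders:
        raise ValidationError(f"genes present in multiple sublibraries: {sorted(set(offenders))[:10]}")
    genes = pd.concat([r.genes for r in results], ignore_index=True)
    quasi = pd.concat([r.quasi for r in results], ignore_index=True)
    params = {"combined_from": [r.screen_id for r in results]}
    for r in results:
        for key, val in r.params.items():
            params.setdefault(key, val)
    return ScreenResult(screen_id=results[0].screen_id, genes=genes, quasi=quasi, params=params)


def score_screen(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    pseudocount: float = 1.0,
    center_on_ntc: bool = True,
    min_count: int = 0,
    m: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    aggregation: str = "top_k_by_abs",
    k: int = 3,
    pvalue_mode: str = "auto",
    screen_id: str | None = None,
) -> ScreenResult:
    """Full scoring pipeline: counts → phenotypes → scores → hits.

    Each sublibrary is processed independently (phenotypes, quasi-genes,
    normalization, hit calling) and the per-sublibrary tables are then
    combined. The quasi-gene seed for each sublibrary is derived
    deterministically from ``seed`` and the sublibrary's rank in sorted
    label order; all parameters are recorded in the result.
    """
    if screen_id is None:
        screen_id = str(counts["screen_id"].iloc[0]) if "screen_id" in counts.columns else "screen"
    phen = compute_phenotypes(counts, library, pseudocount, center_on_ntc, min_count)
    sublibs = sorted(phen["sublibrary"].unique())
    per_sub = []
    quasi_seeds: dict[str, int] = {}
    for i, sub in enumerate(sublibs):
        sub_phen = phen[phen["sublibrary"] == sub]
        ntc_ids = sorted(sub_phen.loc[sub_phen["is_ntc"], "sgrna_id"])
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        quasi_seeds[sub] = sub_seed
        qset = build_quasi_genes(ntc_ids, m=m, seed=sub_seed)
        gene_df, quasi_df = score_genes(sub_phen, qset, aggregation, k, pvalue_mode)
        gene_df, quasi_df, sigmas = normalize_scores(gene_df, quasi_df)
        gene_df, quasi_df, record = call_hits(gene_df, quasi_df, alpha)
        per_sub.append(
            ScreenResult(
                screen_id=screen_id,
                genes=gene_df,
                quasi=quasi_df,
                params={
                    "sigmas": sigmas,
                    "hit_thresholds": {
                        s: rec["threshold"] for s, rec in record["sublibraries"].items()
                    },
                },
            )
        )
    combined = combine_sublibraries(per_sub)
    combined.params = {
        "screen_id": screen_id,
        "pseudocount": pseudocount,
        "center_on_ntc": center_on_ntc,
        "min_count": min_count,
        "quasi_group_size": m,
        "seed": seed,
        "quasi_seeds": quasi_seeds,
        "alpha": alpha,
        "aggregation": aggregation,
        "k": k,
        "pvalue_mode": pvalue_mode,
        "sigmas": {s: sig for r in per_sub for s, sig in r.params["sigmas"].items()},
        "hit_thresholds": {
            s: t for r in per_sub for s, t in r.params["hit_thresholds"].items()
        },
    }
    return combined
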