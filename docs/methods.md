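# Methods

## Screen model and statistics

The package analyses two-bin sort screens: a pooled knockdown library, a
continuous per-cell reporter, and FACS gates on the lowest and highest
`bin_fraction` tails of the pooled reporter distribution (default 0.30
per tail). The analysis makes no distributional assumption about counts
beyond multinomial sequencing of each bin; inference is rank-based.

**Phenotype score.** For each sgRNA, each bin's count is converted to a
frequency and the score is the log2 ratio of high-bin to low-bin
frequency. The pseudocount is applied on the frequency scale — π/N per
sgRNA, with N the number of sgRNAs in the sublibrary and π = 1 by
default. This equals adding π reads per sgRNA at a reference depth of N
reads, keeps scores finite when an sgRNA drops out of one bin, and —
unlike a count-scale pseudocount — makes every downstream statistic
*exactly* invariant to each bin's sequencing depth (scaling one bin's
counts by any positive constant changes nothing beyond float rounding).
Scores are computed per sublibrary, because sublibraries are physically
separate pools sequenced separately.

**Centering.** By default the per-sublibrary NTC median of the raw
scores is subtracted, so non-targeting controls define phenotype zero.
Whether bin-frequency normalization alone or NTC centering is intended by
"normalized log2 ratio" is genuinely ambiguous in this screen tradition;
both are supported (`center_on_ntc`), centering is the default, and the
choice is recorded in every result's parameter sidecar.

**Gene p-values.** Each gene's sgRNA phenotypes are compared with the
full NTC phenotype population by a two-sided Mann–Whitney U test. With
≤ 8 sgRNAs and tie-free data the exact permutation null is used;
otherwise the tie-corrected normal approximation with continuity
correction. P-values are clamped to (0, 1]; a gene whose values tie
completely with the controls gets p = 1. Genes reduced to a single sgRNA
(by the optional per-bin minimum-count filter) are retained with p = 1
and a `low_confidence` flag rather than dropped, so the gene universe
stays stable across screens.

**Gene phenotype aggregation.** Default: mean of the 3 sgRNAs largest in
absolute phenotype (ties broken deterministically by sgRNA id), the
convention of the MAGeCK-iNC lineage of bin-sort screen tools, which
rewards libraries with several strong sgRNAs while tolerating weak ones;
`mean_all` is available. Gene score = phenotype × (−log10 p).

**Quasi-gene null and normalization.** The NTC sgRNAs are permuted once
(seeded) and chunked into disjoint groups of m = 5 — the library's
sgRNAs-per-gene — giving ⌊nNTC/m⌋ quasi-genes; the remainder is unused
and logged. Quasi-genes are scored by the identical code path as genes,
against the full NTC population (their own members included, as for any
negative-control gene). Gene and quasi-gene scores are divided by the
sample SD of quasi-gene scores within each sublibrary, so normalized
scores are in null-SD units and sublibraries are comparable after
combination. Sampling without replacement keeps quasi-gene scores
independent of one another.

**Hit calling.** Hits are defined by a threshold on |normalized score|,
calibrated against the quasi-genes: for each candidate threshold t (the
observed gene values), the estimated FDR is the quasi-gene exceedance
fraction rescaled to the gene-list size, divided by the number of genes
exceeding t. The smallest t with estimated FDR ≤ α (default 0.05) is the
hit threshold; the full FDR curve and threshold are stored in the result
sidecar so the alternative reading of "FDR 0.05" (Benjamini–Hochberg on
the Mann–Whitney p-values) can be audited against it. When no threshold
qualifies, the screen has zero hits and a warning is logged. With the
default geometry (80 quasi-genes per 2,000 genes) the granularity of the
quasi tail means the threshold typically lands just above the quasi
maximum; the null-calibration test pins the realized false-hit rate.

**Sublibrary combination.** Scoring, normalization and hit calling run
per sublibrary; the per-sublibrary tables are then concatenated. A gene
present in two sublibraries is an error, so combination commutes with
hit filtering.

## Screen comparison

Pearson correlation of normalized scores over genes present in both
screens (a `hits_only` flag restricts to genes that are a hit in either);
genes scored in only one screen are excluded and counted, since their
concordance cannot be assessed. Screen-unique genes use |normalized
score| ≥ 5 in one screen and < 5 in the other. Venn regions over 2–3
screens are computed by exact set algebra on hit sets, with an optional
user-supplied blacklist (e.g. mitochondrial genes) removed first — the
blacklist is deliberately an input, not a hard-coded list.

## Synthetic screens

The generator emulates the screened design: `n_genes` × `sgrnas_per_gene`
(default 5) targeting sgRNAs plus `n_ntc` controls. Modifier genes (a
`frac_modifiers` fraction) get effect sizes either ~ Normal(0,
`effect_mu_sd`²) or fixed-magnitude ±`effect_mu_sd` (for power analyses
at a controlled effect); per-sgRNA knockdown efficacy is Uniform over
`efficacy_range` (default 0.7–1.0). Each cell's log-reporter is Normal
with mean efficacy × effect and SD `cell_noise_sd` = 1, which defines
the effect-size unit; binning takes the pooled distribution's global
`bin_fraction` tails, mirroring FACS gating on the whole population, and
each bin is sequenced as one multinomial draw of `reads_per_bin` reads.
A `noise_seed` separate from `seed` re-screens the same ground truth
with fresh cells and reads, emulating replicate screens.

Defaults (2,000 genes, 400 NTCs, 300 cells/sgRNA, 2×10⁶ reads per bin)
are a desk-scale rendition of a genome-scale screen sublibrary chosen so
the full pipeline runs in seconds per screen; coverage at sort is not
published for the real screens, so 300× is a stated assumption, not an
inference. The model omits lentiviral MOI structure, differentiation
dropout, growth-based selection and replicate correlation; passing
recovery tests therefore demonstrate the statistics' behaviour under the
stated sampling model, not under every failure mode of real screens.

## Expression–vulnerability correlation

Input is a per-cell-type table of a gene's expression (or
expression-change effect size) against the cell type's abundance-change
effect size; upstream single-nucleus effect-size estimation is consumed,
not reimplemented. Pearson r and p per gene; Benjamini–Hochberg
adjustment within whatever gene family the input table defines; ordinary
least-squares line with a 95% confidence band from 1,000 case-resampled
refits (percentiles 2.5/97.5 of fitted values at each observed x). Case
resampling is used because rows (cell types) are the sampling unit; a
degenerate resample with constant x is redrawn with capped retries.
Perfect-fit p-values of exactly zero are floored to the smallest positive
double so they remain in BH's domain.

## Numerical and determinism notes

* All randomness flows through `numpy.random.default_rng` seeds;
  per-sublibrary quasi seeds derive from the screen seed and the
  sublibrary's sorted rank via `SeedSequence`. Identical inputs + seed
  give bit-identical written tables; result TSVs are written with
  `%.17g` and read back with round-trip float parsing.
* Mann–Whitney p-value floor 1e-300; quasi-gene score SD of zero, a
  constant score vector, or fewer than 2 quasi-genes raise typed
  degenerate-statistics errors rather than producing NaNs.
* FASTQ counting is exact-match by design: mismatch-tolerant alignment
  belongs to upstream read-processing tools, and exact matching is
  reproducible and sufficient for count-table generation from clean
  amplicons. Read-trimming coordinates (offset/length) are user
  configuration since amplicon layouts vary.
* The acceptance experiments use 20 null screens and 10 screens per
  effect size at the standard geometry — sizes at which the measured
  quantities (mean null hit fraction, mean recall/FDP) are stable to a
  few percent while the whole run stays within a few minutes.

## Known limitations

* The empirical FDR threshold is granular when quasi-genes are few;
  screens with < ~50 NTC groups will see coarse thresholds.
* Replicate count tables are averaged upstream at most; no
  negative-binomial or maximum-likelihood count modelling is offered.
* The observed false-discovery proportion at strong effects fluctuates
  seed-to-seed (the threshold sits in the extreme null tail, where
  counts are small); calibration holds on average, as the tests measure.
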