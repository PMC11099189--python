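# Methods

## Screen scoring model

The scoring pipeline treats each (cell line, half-library, replicate)
triple as an independent analysis unit with one PD0 (baseline) and one
PD14 (endpoint) sample.

1. **PD0 filter.** Guides with fewer than 50 reads in the unit's PD0
   sample are removed from that unit only ("less than" is strict: a
   guide at exactly 50 is kept). Poorly represented guides at baseline
   carry no usable fold-change information; removals are logged per
   category (targeting / nontargeting).
2. **Normalized abundance.** A pseudocount of 1 is added to every raw
   count, then counts are converted to within-sample proportions. The
   pseudocount placement (before normalization) keeps zero-count guides
   finite and makes two identical samples score exactly zero.
3. **CRISPR score.** `L_i = log2(p_PD14 / p_PD0)` per guide;
   `CS_i = L_i − median(L over surviving nontargeting guides)`. Any
   per-sample depth constant cancels in the subtraction, so CS is
   invariant to uniform depth rescaling up to a pseudocount effect of
   order `(k−1)/(k·c·ln 2)` that vanishes as counts grow.
4. **Replicates** are averaged at guide level over the replicates in
   which the guide survived filtering (n_reps recorded). Averaging
   before the gene collapse is symmetric with the half-library merge,
   which is also a guide-level operation.
5. **Half-library merge** concatenates the disjoint A/B guide sets, so
   the gene collapse sees up to the full 6-guide multiplicity.
6. **Gene score.** med.CS is the sample median of a gene's surviving
   guide CS values (even cardinality: mean of the two central order
   statistics). Genes with fewer than `min_guides = 3` survivors are
   reported with `status=insufficient_guides` and no score — a median of
   one or two guides is dominated by single-guide off-target behaviour.

Numerical note: with an even number of nontargeting guides, naively
subtracting the rounded midpoint leaves an O(1e−18) residue in the NT
median. `compute_cs` anchors the shift at the lower central NT value so
the two central values land at exactly ±h in floating point and the
self-normalization invariant (NT median CS ≡ 0) holds bit-exactly.

## Synthetic screens

The generator emulates a GeCKOv2-like protocol: `n_genes` genes × 6
guides (split 3+3 between half-libraries A and B, alternating within
each gene with a per-gene phase so odd multiplicities still balance),
plus 1000 nontargeting controls split evenly. Each half-library is an
independently transduced population; a sample carries reads only for its
own guides.

Per guide: initial abundance `a_i ~ LogNormal(0, σ)` with σ = 0.5
(roughly a 2.7-fold interquartile spread, a realistic plasmid-pool
dispersion); per-gene fitness effect `s_g ~ Uniform(−0.35, −0.15)` for
the essential fraction (5% by default), `s_g = 0` otherwise; per-guide
cutting efficacy `e_i ~ Beta(5, 1.5)` (mean ≈ 0.77, left tail for weak
guides). After `D = 14` doublings the expected relative abundance is

```
w_i ∝ a_i · 2^(D · (1 + s_g · e_i))
```

so neutral guides are exactly invariant in proportion and an essential
guide's expected log2 fold-change relative to neutral guides is the
closed form `D · s_g · e_i` (e.g. −2.8 for s = −0.2, e = 1). Reads are
negative binomial around `reads_per_sample × proportion` with variance
`μ + φμ²` (φ = 0.05 by default; φ = 0 is Poisson), drawn independently
per replicate and timepoint; `reads_per_sample` defaults to
coverage × library size (300×), matching the screening protocol's
coverage bookkeeping (300 × 123,411 guides ≈ 3.7 × 10⁷ cells at full
scale). MOI (0.3) is recorded metadata only — multiple integrations,
copy-number artifacts and off-target cutting are not modeled, so passing
recovery tests demonstrates correctness of the scoring arithmetic and
ranking behaviour under count noise, not robustness to those real-data
artifacts.

The default desk-scale configuration (n_genes = 2000, 2 replicates) runs
the full pipeline in ~2 s and gives half-library concordance r ≈ 0.86
and essential-vs-neutral AUROC ≈ 1.0; these sizes were chosen so the
planted effect range (|D·s·ē| ≈ 1.6–3.8) sits well clear of the noise
floor at 300× coverage while remaining desk-scale.

Reproducibility: all draws come from
`np.random.default_rng([seed, crc32(cell_line)])`, so screens of
different cell lines are independent but bit-reproducible.

## QC and benchmarking

Concordance is Pearson r on med.CS over the intersection of scored genes
(≥ 3 required). Reference separation takes the union of
essential-reference sets as positives and the union of
nonessential-reference sets (minus any overlap with the positives) as
negatives, and reports the AUROC of the med.CS ranking (most negative
first) via the rank-sum identity with midranks — deterministic, equal to
the normalized Mann–Whitney U, and invariant to monotone transforms.
Reference lists are supplied by the user as GMT; the package does not
bundle published essential/nonessential lists.

## Prioritization

Ranking sorts scored genes by med.CS ascending with lexicographic
tie-breaks (deterministic output). Selectivity defaults are
`tau_dep = −1.0` and `tau_neutral = −0.3` in CS units: a selective
dependency must be depleted past tau_dep in *every* own screen and
scored no lower than tau_neutral in *every* comparator screen; a gene
unscored in any comparator is flagged and never selected (absence of
evidence of neutrality is not evidence). The thresholds are configurable
because the underlying comparison is qualitative; −1.0 corresponds to a
2-fold endpoint depletion relative to controls and −0.3 bounds ordinary
null scatter at default noise. Fisher enrichment uses the hypergeometric
upper tail `P(X ≥ k)` on (universe, selection, set) with BH FDR across
sets; the enrichment universe defaults to the genes actually scored in
the screen (conditioning on testability), not the whole manifest.

## Pharmacology

`fraction_affected` averages replicate viabilities per dose, divides by
the dose-0 control, and clips fa to [1e−4, 1 − 1e−4] before any logit
transform (flagging clipped points); the clip bound is the package's
handling of fa ∈ {0, 1}, which the median-effect linearization cannot
accept.

The 4PL fit minimizes squared error of
`V(d) = bottom + (top − bottom)/(1 + (d/ic50)^h)` with multi-start
initialization (log-spaced IC50 grid × Hill slopes {0.5, 1, 2, 4}) and
box bounds; a response whose variance is below 1e−6 is rejected as
degenerate rather than fitted. The reported IC50 is the relative EC50
(inflection dose). The median-effect fit is ordinary least squares of
`log(fa/(1−fa))` on `log d`; slope m, `Dm = exp(−intercept/m)`, exact on
noise-free data for any Dm, m > 0.

The combination index is evaluated non-constant-ratio: each observed
dose pair uses its own combined fa, with
`Dx_j = Dm_j (fa/(1−fa))^{1/m_j}` and `CI = d1/Dx1 + d2/Dx2`; the
additive call band defaults to [0.9, 1.1]. This matches designs that
cross fixed concentrations of one inhibitor with a dilution series of
the other rather than constant-ratio dilutions. Isobologram coordinates
are `(d1/Dx1, d2/Dx2)` for pairs within a tolerance of the requested
effect level; additivity is the line x + y = 1.

## Known limitations

- The simulator's truth is guide-independent within gene apart from
  efficacy; it does not plant off-target or copy-number confounders, so
  benchmark AUROCs here are upper bounds on real-screen performance.
- Replicate averaging assumes replicates are exchangeable; batch effects
  between replicate populations are not modeled or corrected.
- MAGeCK-style model-based β-scores are out of scope; med.CS is the only
  gene statistic.
- The 4PL fit is unweighted least squares; strongly heteroscedastic
  viability data may warrant external weighting before fitting.
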