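# Methods

`dietniche` implements the quantitative core of a stomach-flushing dietary
study of three syntopic anurans (*Microhyla heymonsi*, *M. mukhlesuri*,
*Occidozyga lingnanica*; 26/42/48 stomachs, 501/878/280 prey items): prey
volume and composition tables, diversity and niche indices, and
permutation-based community comparison. This note records the model choices,
defaults, and numerical conventions.

## Composition metrics

Prey items are measured by maximum length *L* and width *W* (mm) and their
volume approximated as a prolate spheroid, V = 4π/3 · (L/2) · (W/2)²
(full-precision π; the 0.1 mm measurement grain dominates any rounding of π).
Per prey category *i* within one predator species:

- *F*(i): stomachs containing ≥ 1 item of *i*;
- %N, %V: shares of total item count and total item volume;
- IRI(i) = (%F + %N + %V)/3, the index of relative importance.

**%F basis.** Published composition tables of this kind have %F columns that
sum to 100 across categories, which is only possible when %F is normalised
over *occurrence records* (Σ_j F(j)), not over stomachs. We implement that
basis as `pct_f` so each column sums to 100 and IRI columns sum to 100 as
well, and additionally expose the conventional per-stomach occurrence
fraction (F / non-empty stomachs) as `occ_fraction`.

**Order level.** At order level N and V aggregate over the order's
categories. `F_count` is recomputed as the number of stomachs containing the
order (not additive over categories), but `pct_f` keeps the category-level
occurrence-record basis and therefore *is* additive — this is the convention
that reproduces the published order rows, whose %F equals the sum of their
family rows.

**Empty stomachs** are counted in `n_stomachs` but enter no numerator or
denominator; items lacking a measured dimension count toward N and F but
contribute zero volume (both are validation warnings).

**Per-species summaries.** Count statistics are over all stomachs
(mean = items/stomachs). Width/length statistics pool items. Volume
statistics are over per-stomach *total* volumes of non-empty stomachs —
that is what "stomach contents volume" means in field studies of this kind,
and it is the only reading consistent with the published per-species volume
means (tens of mm³ against per-item volumes of ~1–2 mm³).

## Niche indices

All indices take a species' *niche profile*: counts n_i or proportions
p_i = n_i/N over the categories registered in its diet, at the finest
identified level by default (family / larval bin / residual bin) — the level
at which the published breadth values are reproducible (n = 8 and 11 for the
two *Microhyla*).

- Simpson (finite-sample): D = Σ n_i(n_i−1) / [N(N−1)]; reported as 1−D.
  Computed from counts, not the p² approximation.
- Shannon H' = −Σ p_i ln p_i; evenness J' = H'/ln S with S the number of
  registered categories. The study's printed J' values (0.12/0.27/0.82) are
  not reproducible from its composition table with this S (we obtain
  ≈0.16/0.31/0.80); the S its authors used is unstated, so J is reported
  with an explicit S and agreement is not forced.
- Levins breadth B = 1/Σp_i², standardised B_sta = (B−1)/(n−1) with n the
  number of registered (nonzero) categories.
- Pianka overlap O_jk = Σ P_ij P_ik / √(Σ P_ij² · Σ P_ik²), profiles aligned
  on the union of categories with zeros for absences. The square-rooted
  denominator is the canonical form, bounded on [0,1] by Cauchy–Schwarz
  (renderings that drop the root are not bounded and are treated as typos).

Reconstructing profiles from the printed %N columns reproduces the published
B_sta (0.02, 0.06; the third species computes to 0.344 against a printed
0.33 — an input-rounding effect), 1−D (0.15, 0.39, 0.91, matching the
published summary table; the running text swaps the two *Microhyla* values,
and reconstruction supports the table), and overlaps 0.49/0.98/0.52 against
printed 49%/97%/47% — the residuals on the latter two pairs again reflect
that only rounded proportions, not per-stomach data, are published.

## Community comparison

Each non-empty stomach is a sample; cells are item counts ("abundance") or
summed volumes ("volume"). Dissimilarity is Bray–Curtis,
d_jk = Σ|x_ij − x_ik| / Σ(x_ij + x_ik).

**ANOSIM** (Clarke): with all pairwise dissimilarities ranked (mid-rank
ties), r = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
so r = 1 when every between-group pair is farther than every within-group
pair. Significance by random relabelling with the +1 correction,
p = (1 + #{r_perm ≥ r_obs})/(1 + n_permutations); 999 permutations by
default (the conventional vegan default), seed mandatory and recorded in the
result.

**NMDS** minimises Kruskal stress-1,
√(Σ(δ̂ − d_conf)²/Σ d_conf²), where δ̂ is the isotonic (pool-adjacent-
violators) regression of configuration distances on the input
dissimilarities, via SMACOF iterations (Guttman transform on the
disparities). The first start is the deterministic classical-scaling
(principal-coordinate) configuration; remaining restarts are seeded random.
Stress is enforced non-increasing within a run: an uphill step reverts to
the previous configuration and stops. Convergence is a relative stress
improvement below `tol` (default 1e-7) within `max_iter` (default 300);
non-convergence flags the result instead of raising. Degenerate axes in the
classical-scaling start receive ~1e-6 Gaussian jitter so SMACOF can move.

## Morphometric statistics

Pearson r (two-sided t-test, n−2 df) for the allometric trait pairs and
Kendall tau-b (tie-corrected, normal-approximation p) for SVL versus
per-individual stomach-content volume, both via scipy behind a common result
type. The multiple regression of body size on prey size that the source
analysis ran in standard software is out of scope; the tidy per-individual
table (`per_individual_table`) exports everything such a fit needs.

## Synthetic data generator

The generator emulates the study's published summary structure per species:

- **Categories**: i.i.d. multinomial with probabilities equal to the
  published %N/100 (8/11/28 categories).
- **Per-stomach counts**: negative binomial parameterised by the published
  mean/SD (k = m²/(s²−m); the published SDs exceed the means, ruling out
  Poisson), truncated by resampling to the published min–max (1–60, 3–125,
  1–19). Because the minima are ≥ 1, no generated stomach is empty.
- **Prey sizes**: length and width are log-normals moment-matched to the
  published pooled mean/SD, truncated to the published ranges, rounded to
  0.1 mm, with W ≤ L enforced by swapping. Sizes are shared across
  categories — only pooled size statistics are published — so synthetic %V
  differentiates categories far less than real data, where taxon identity
  and size are strongly confounded (termites are small, beetle larvae
  large). A `category_size_overrides` hook accepts per-category models.
- **Morphometrics**: a latent Gaussian copula targeting the published
  pairwise Pearson r (SVL–MW, SVL–BM, MW–BM), with range-truncated normal
  marginals from the published mean/SD/min–max. Head-length correlations are
  not published; defaults of 0.90 (SVL–HL) and 0.85 (HL–MW, HL–BM) were
  chosen once as typical strong allometric coupling. Truncation preserves
  the published range exactly and the mean nearly, but analytically
  attenuates the marginal SD and slightly the realised correlations; tests
  compare against the truncated distributions' own analytic moments.
- Sex is drawn at the observed ratio but diet is independent of it, as in
  the source analysis.

Everything is deterministic given the config seed; datasets written to CSV
carry a provenance header (tool version, seed, spec hash).

What passing tests on synthetic data do **not** show: real stomach contents
have within-stomach category clumping (a frog sitting on a termite trail),
size–taxon coupling, and predator-size–prey-size covariance; the generator
has none of these, so the community-comparison checks exercise calibration
and separation behaviour, not field realism. In particular the published
ANOSIM r/p values cannot be targeted numerically.

## Problem sizes and numerical conventions

Report tables round to 2 decimals (raw precision always kept in JSON
exports); computation is full double precision. Proportion vectors must sum
to 1 within 1e-9 (percentage constructors renormalise printed rounding
residue). Calibration runs use 200 replicates of two 20-stomach groups with
99 permutations; large-sample recovery checks use 150–4200 stomachs per
species (≥ 5000 items for proportion recovery); NMDS checks run on the
116-stomach study-shaped dataset with 1–4 restarts. These sizes were chosen
so sampling error sits well below the tolerances being asserted while the
suite stays quick.

## Known limitations

- %F normalisation follows the occurrence-record basis of the source tables;
  studies using the per-stomach basis should read `occ_fraction`.
- ANOSIM p-values are one-sided (large r); NMDS stress is the only
  goodness-of-fit diagnostic exposed.
- The generator draws item categories i.i.d. within stomachs
  (no overdispersion of composition between stomachs of one species), which
  makes within-species Bray–Curtis distances more homogeneous than in real
  assemblages.
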