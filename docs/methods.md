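# Methods

This note documents the models behind `lipisign`, the choices made where
the procedure is genuinely open, and what the synthetic-data generator does
and does not emulate.

## 1. The hybrid association score

For each (probe, lipid, sex stratum) the four base statistics are the
Pearson coefficient `r_P` with its two-sided p-value `p_P` (from
`t = r·sqrt(n−2)/sqrt(1−r²)` on `n−2` df) and the Spearman coefficient
`r_S` (Pearson on midranks) with `p_S` from the same t approximation.  The
score is

    HyPi = r_P·(−log10 p_P) + r_S·(−log10 p_S),

accepted only when the two coefficients agree in sign.

Conventions the formula leaves open, and how this package resolves them:

* **p-value floor.**  p-values are clipped to `P_MIN = 1e-300` before the
  log, so perfectly collinear data produce a large finite score rather than
  an infinity.  Correlations within 1e-13 of ±1 are snapped to ±1 so exact
  collinearity reliably hits the floor instead of leaking float round-off.
* **Zero coefficients.**  Both coefficients exactly zero → concordant with
  score 0; exactly one zero → non-concordant (no accepted score).
* **Spearman p.**  The t approximation is used at every n — standard at
  cohort sample sizes (n ≈ 10²–10³).  `exact_spearman_p` enumerates all
  n! rank permutations for n ≤ 8 and exists as an oracle for the
  approximation and for the test suite, not as the default.
* **Missing betas.**  Pairwise-complete per probe; records with fewer than
  `min_n` (default 30) complete pairs, or constant vectors, are flagged in
  the output rather than dropped.
* **Two-cohort selection.**  "Observed in both cohorts" is top-k by |HyPi|
  per (lipid, stratum) — k configurable, threshold selection available —
  requiring matching sign across cohorts.  Ties break lexicographically by
  probe id so selection is deterministic.
* **Sex strata** are scored separately ("F", "M"), with a pooled "all"
  stratum available.

## 2. Synthetic human cohorts

`simulate_cohort` plants `n_true_probes` probes whose beta values are
monotone functions of one lipid marker (assigned round-robin over HDL /
TCH / TGY, random sign).  The construction is

    beta = expit( s · ( w·u + sqrt(1−w²)·ε ) ),   ε ~ N(0,1)

with `u` the standardised lipid z-score for linear probes (latent scale
`s = 0.8`, keeping betas well inside (0,1) with SD ≈ 0.18 around 0.5).
The signal weight `w` is solved by bisection on a fixed 200 000-draw
calibration sample (its own constant seed) so the **population** Pearson
correlation equals `effect_r`; Monte-Carlo calibration error is ≈ 0.002.
Null probes use `w = 0`.

**Non-linear probes.**  The stated intent of the non-linear fraction is to
make Spearman exceed Pearson, exercising the hybrid score's motivation.  A
polynomial link with heavy tails (e.g. a cube) does the opposite: its
outliers inflate the Pearson moment (measured: Pearson 0.64 vs Spearman
0.50 at target 0.5).  The package therefore uses a *saturating* link — a
signed cube root of the z-score pushed through a steeper sigmoid
(`s = 4`) — which compresses the tails and yields Spearman 0.500 vs
Pearson ≈ 0.46 at target 0.5.  For these probes `w` is calibrated against
the Spearman correlation.  The steeper sigmoid also gives these probes a
broader, mildly bimodal beta distribution, which is typical of real
methylation probes.

**Shared truth across cohorts.**  Probe-level randomness (which probes are
true, signs, links) is seeded from the config seed alone; subject-level
randomness from (seed, CRC32(cohort label)).  Two cohorts simulated under
different labels therefore share their planted probes — the premise of the
two-cohort intersection — while having independent subjects.

Default lipid marginals (mg/dL): HDL 52 ± 13, TCH 192 ± 35, TGY 132 ± 75,
typical adult serum values; negatives are folded.  Sexes are Bernoulli with
`sex_ratio` (default 0.5) and carry no effect.

## 3. Synthetic pan-mammalian dataset

`simulate_species_tree` draws a rooted binary ultrametric tree by
sequential random coalescence (exponential waiting times at rate k(k−1)/2)
and rescales the root height to 1, so `brownian_sigma` is interpretable as
the SD of species drift root-to-tip.

`simulate_mammalian_dataset` builds each sample's beta as

    species baseline (Brownian motion on the tree, per probe)
    + γ·(log maximum lifespan − mean log lifespan)   [on a probe subset]
    + tissue offset
    + tissue age slope × age
    + sex effect (default 0)
    + N(0, noise_sd),  clipped to [0, 1].

Root baselines are Uniform(0.3, 0.7) per probe, which keeps the clipped
fraction below 1% at default noise; the realised clipped fraction is
reported in the ground truth.  `shared_species_effect` controls whether all
tissues inherit one Brownian realisation (the biological regime in which
blood mirrors internal organs) or draw independently (the null against
which that concordance is tested).  Ages are Uniform(0, species maximum
lifespan) — no real age distribution is assumed — and sexes alternate
within each species × tissue block so both sexes are always represented.
Tissue age slopes accept a per-probe mapping, which is how couplings
between human effect sizes and mammalian aging rates are planted.

What the generator does **not** emulate: array normalisation artefacts,
batch effects, cell-type composition, probe-level missingness patterns,
non-uniform age pyramids, and unbalanced tissue panels per species (every
species contributes every configured tissue).  Passing recovery tests
therefore demonstrates the correctness of the inference machinery under
the stated model, not robustness to those real-data complications.

## 4. Mammalian analyses

* **Sample filters.**  Species with ≥ 200 samples are kept (counts taken on
  the input); tissue counts are then recomputed on the survivors and
  tissues with ≥ 50 samples kept.  The sequential semantics is a choice —
  a joint rule is equally defensible — and the retention report makes it
  auditable.  Note the filter is a one-shot selection: re-applying it is a
  no-op only while every retained group still meets its threshold, which a
  sufficiently aggressive first pass can break.
* **Age correlations** are Pearson by default (Spearman by flag), within
  species (or tissue, or species × tissue) strata, so species-native age
  units never mix.  Strata under 10 samples or with constant inputs are
  flagged.
* **HyPi-vs-age concordance** regresses, per sex stratum, each probe's
  unweighted mean per-species age correlation on its strongest accepted
  human HyPi score.  Unweighted means (rather than pooled correlations)
  keep well-sampled species from dominating the y-axis.
* **Lifespan association** correlates per-species mean beta (one point per
  species, so sample counts do not weight the fit) against log maximum
  lifespan; ≥ 4 species required.
* **Tissue identity** is quantified as the mean silhouette width of samples
  in the probe-beta space grouped by tissue (or species) — a label-purity
  statistic that replaces a qualitative embedding plot with a number.

## 5. Aging trends

Per tissue, OLS of beta on age (n ≥ 10, analytic slope SE).  Slope equality
across tissues is tested with Cochran's Q = Σ wᵢ(bᵢ−b̄_w)², wᵢ = 1/SEᵢ²,
p from χ²(k−1).  The per-tissue-fits + Q formulation was chosen over a
single pooled age × tissue interaction model because it is self-contained
and each piece is testable against a closed form; the pooled dummy
interaction fit is statistically equivalent for balanced designs.  Pattern
labels: *flat* if every |slope| ≤ ε (default 1e-4 beta/age-unit);
*heterogeneous* if non-flat slopes disagree in sign or Q rejects at
α = 0.05; otherwise *consistent-decline* / *consistent-gain*.  Species are
pooled within tissue by default; a species-restricted mode exists for
strictly homogeneous age units.

## 6. Dendrograms and tanglegrams

Trees are built by Lance–Williams agglomeration on Euclidean distances
between species mean profiles.  Average linkage (UPGMA) is the default —
the standard choice for ultrametric mean-profile trees — with single,
complete and ward available.  Ward runs on squared distances internally
and records square-root heights, matching the centroid formulation when
distances are Euclidean.  Ties merge the pair whose clusters have the
lexicographically smallest minimum leaf labels, making runs
bit-reproducible and oracle-checkable merge by merge.

Cophenetic distance between two leaves is the height of their first common
merge; the cophenetic correlation between two trees on the same leaves is
the Pearson correlation (Spearman by flag) of the condensed vectors, and is
undefined (an error) when a tree's merges are all at one height.

**Entanglement** is defined here — tanglegram literature offers several
variants — as the normalised L1 rank displacement between the two leaf
orders, Σ|rank₁(i) − rank₂(i)| / M with M the displacement of the exact
reversal.  It is bounded in [0, 1], hand-checkable, and 0 iff the orders
are parallel.  **Untangling** is a greedy alternating sweep: every internal
node of tree 1, then tree 2, is flipped iff entanglement strictly
decreases; sweeps repeat to a fixed point or `max_iter` (default 20).
Rotations never touch merge heights, so the cophenetic correlation is
invariant under untangling.  Greedy sweeps can stall in local minima for
topologically discordant trees; that residual entanglement is the signal
the tanglegram is meant to show.

Newick export writes branch length = parent height − child height (an
ultrametric rooted tree) and single-quotes labels containing
metacharacters; the exported tree reparses to the identical cophenetic
matrix.  Topology agreement is additionally summarised as the symmetric
clade-set difference (Robinson–Foulds for rooted trees).

Missing probes in a species mean matrix are dropped probe-wise before
distances (the alternative — dropping the species — is available by
subsetting upstream).

## 7. Pipeline and problem sizes

`run_all` chains the six stages and writes a JSON report containing every
threshold, per-stage counts, input hashes and the seed; the config hash
excludes the output directory so a rerun elsewhere is byte-identical.  The
default synthetic configuration — two cohorts of 300 subjects × 400 probes
with 12 planted markers, and 8 species × 4 tissues × 18 samples — runs in
a few seconds on one CPU.  `scripts/acceptance.py` uses larger, fixed
problem sizes chosen to make each recovery statistically decisive at desk
scale: 500 × 1000 × 10 seeds for marker recovery, 10 000 probes for null
calibration, 10 seeds × 8 species for concordance, 400 CI events for
coverage.  Sub-seeds for these replicates are derived from the single
`--seed` argument.

## 8. Known limitations

* The Spearman t-approximation is slightly anti-conservative for n < 30;
  the exact permutation p is available but quadratic-factorial in n.
* Covariate adjustment (age, BMI, medication), multiple-testing correction
  and cell-composition deconvolution are deliberately out of scope of the
  association stage.
* The untangler is heuristic (greedy, rotations only); it guarantees
  monotone improvement, not the global minimum.
* Ward linkage on non-Euclidean distance matrices follows the
  Lance–Williams recursion formally but loses its variance interpretation.
* The pattern classifier's Q gate means same-sign slopes with decisively
  different magnitudes are labelled *heterogeneous*, not
  *consistent-decline*; tune `alpha_het` to taste.
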