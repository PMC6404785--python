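# Methods

## Model and procedure

`esknn` targets two-class problems where the feature vector mixes a few
informative coordinates with many irrelevant ones. A single kNN
classifier weights every coordinate equally in the Euclidean metric, so
irrelevant coordinates inject pure noise into the neighbourhood
structure. The ensemble counters this in two ways: each base learner
sees only a random feature subset (members built on mostly-informative
subsets behave well), and two explicit selection stages discard members
that do not help.

Stage 1 is individual: each of the m subset-kNN learners is scored by
accuracy on its own out-of-bag rows — the ≈ 36.8 % of construction rows
a size-n bootstrap misses — and only the top h = ⌊reselect_fraction·m⌋
survive. Stage 2 is collective: members are added in rank order to a
growing ensemble and kept only if the Brier score of the averaged
class-1 probability on a held-out validation set strictly decreases.
The Brier score, BS = mean (y − p̂)², is used instead of the error rate
because it is sensitive to probability sharpening that does not move
any prediction across the 0.5 cut-off; the error rate would accept
almost no candidate. BS⟨r−1⟩ always refers to the currently accepted
ensemble, rejected candidates are dropped permanently, and the scan
continues through all h, so one bad candidate cannot block a later good
one.

Assumptions: labels are binary; features are numeric and comparable on
an unscaled Euclidean metric (see below); the training data is i.i.d.
so that bootstrap out-of-bag rows and the validation split are unbiased
proxies for test performance.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| m | 1001 | base learners; forced odd so member votes cannot tie. Costs scale linearly in m; 101 is used for the repeated-replicate studies below and changes results little. |
| subset size l | max(2, ⌊d/3⌋) | features per learner; one third of the inputs, floored at 2 so low-dimensional problems still get subsets. |
| reselect_fraction | 0.4 | share of m kept after out-of-bag ranking (h = ⌊0.4·m⌋, min 1). |
| validation_fraction | 0.3 | share of the training data held out for stage 2. No canonical value exists; 0.3 keeps several dozen validation points at typical benchmark sizes while leaving the construction set large. |
| k grid | 1…10 | neighbour counts searched by stratified tenfold CV on the construction set; ties prefer the smallest k. k is selected once and shared by all members — a per-member CV would multiply cost by m for little benefit, since all members see bootstrap samples of the same data. |
| combine rule | mean_prob | averaged probability with strict 0.5 cut-off, matching the Brier-based selection; majority voting is provided as an alternative, with exact vote ties resolved by the probability rule. |

Probabilities exactly at the cut-off classify as 0 (strict inequality).
Distance ties at the k-th rank include the lowest training index, which
makes every result reproducible bit-for-bit under a fixed seed.

## Synthetic generators

Two generators produce the benchmark conditions.

**Correlated-Gaussian model.** Class 1 ~ N(2·1_d, w·Ψ) with
Ψ_ij = (1/2)^|i−j| (AR(1)-type decay, unit diagonal); class 2 has d
i.i.d. N(1, 1) features; d = 20 by default. w scales class-1 dispersion
(1 … 20). Appended noise features are N(0, 1) — the parameters of the
noise distribution are a design choice here, standard normal being the
natural non-informative default at the same scale as the informative
features. Sampling uses the Cholesky factor of w·Ψ. Per-class sample
sizes default to 500 + 500, chosen so one dataset has the same 1000-row
scale as the second model; both are configurable.

**Distance-band model.** x uniform on [0, 100]^4; with r = ‖x − c‖,
P(y = 1 | x) = 1 for r < 110, (150 − r)/140 for 110 ≤ r ≤ 140, 0
beyond; labels are Bernoulli draws. The central point c defaults to the
origin: from the hypercube's centre every point has r ≤ 100 < 110 and
all labels would be 1, whereas from the origin the r distribution (rms
≈ 115) straddles all three branches and classes come out near-balanced.
Appended noise features are uniform on [0, 100], the same range as the
informative coordinates.

What these generators do not emulate: real datasets have heterogeneous
feature scales and types, dependent rows, label noise unrelated to a
clean geometric rule, and informative/noise boundaries that are not
crisp. Passing the simulation benchmarks therefore demonstrates the
selection machinery and noise robustness under controlled conditions,
not performance on any particular real dataset; the `benchmark` command
exists to measure the latter on user-supplied CSVs.

An important consequence of the uniform-noise choice: with several
hundred U(0, 100) noise columns the noise contribution to squared
distances fluctuates more across pairs than the entire informative
4-coordinate signal, so *every* kNN-family method — including this
ensemble, whose members then rarely see an informative majority in
their subsets — approaches the prevalence-limited error. The
robustness claim that survives this regime is relative (the subset
ensemble degrades much more slowly than plain kNN), and that is the
property the tests assert.

## Numerical and design choices

- **Distances** are unscaled Euclidean; feature standardisation is
  deliberately not applied implicitly (it would silently change the
  metric), but `standardize()` is provided for callers who want
  z-scored features. (Whether to scale is genuinely open for mixed-unit
  data; the default keeps the metric transparent.)
- **k-nearest lookup** uses `argpartition` with a full stable-sort
  fallback for the rare rows where a distance tie straddles the k-th
  rank, preserving the lowest-index tie rule exactly.
- **Bagged kNN** evaluates all B members from one sorted neighbour
  order of the full training set, walking cumulative bootstrap
  multiplicities; this is algebraically identical to rebuilding each
  member (duplicate rows are adjacent in the sort) and is what makes
  B = 1001 affordable.
- **Subspace ensembles** cache member predictions per distinct feature
  subset; with d = 4 and l = 2 only six subsets exist, so a
  1001-member random-subspace ensemble costs six kNN evaluations.
- **Degenerate cases**: a bootstrap with no out-of-bag rows scores
  accuracy 0 with a warning (probability < 1e-8 for n ≥ 40) rather
  than being redrawn; Brier ties during the greedy scan reject the
  candidate (keeps ensembles minimal); a single-class validation split
  is allowed with a warning; rows with missing values are dropped at
  load time with a logged count.
- **Seeding**: every stochastic component (splits, CV folds, subsets,
  bootstraps) draws from one seeded generator chain
  (`numpy.random.SeedSequence` spawning), so identical configs
  reproduce identical ensembles and tables bit-for-bit.
- **MFS vs RkNN**: the multiple-feature-subsets method draws its
  subsets *with* replacement — a feature drawn twice genuinely doubles
  its weight in the member's metric — while random kNN draws without
  replacement and trains on all rows (no bootstrap). This is the
  distinction between the two constructions as cited in the ensemble
  literature; both reduce to plain kNN in the appropriate degenerate
  configuration.

## Problem sizes

Library defaults mirror a full study (m = 1001, 1000 resplits, 500
replicate datasets via `--full`). The test suite and the acceptance
script run reduced configurations chosen as the package's quick-run
defaults: m = 101, 25–100 replicate datasets per scenario, one
stratified 90/10 split per simulated dataset, B = 101 in the acceptance
script's comparisons. Replication counts are always recorded alongside
the reported means (the `n` column / field), and standard errors are
reported in the benchmarking tables so stochastic agreement can be
judged.

## Known limitations

- Two classes only; the Brier stage is written for the binary score.
- No feature-importance output; the ensemble discards uninformative
  subsets implicitly but does not rank features.
- The greedy scan is order-dependent by design (rank order from stage
  1); it does not revisit rejected members or consider joint swaps.
- Prediction requires the stored construction rows (kNN is
  instance-based), so serialised models embed their construction data.
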