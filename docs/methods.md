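# Methods

## Problem and model

Centroided imaging MS data assign to every pixel a list of (m/z, intensity)
peaks. A candidate annotation is a database formula combined with an adduct
at the dataset polarity; its theoretical evidence is the first T = 4
isotopic peaks of the ion's isotope pattern. The engine scores each
candidate with five features, ranks target candidates against decoy
candidates with a learned score, and reports each target with a continuous
FDR estimate.

### Ion images and observed isotope evidence

For a target m/z, the ion image sums all centroid intensities per pixel
inside the closed symmetric window |peak − mz| ≤ mz·tol/1e6 (default
tol = 3 ppm). When several centroids fall in the window, the per-pixel
matched m/z is their intensity-weighted mean; the per-isotope observed m/z
m̄ᵢ is the intensity-weighted mean of those per-pixel values across pixels
with nonzero matched intensity. Sum aggregation (rather than max) was
chosen because centroided intensities are additive; the alternative only
matters when the window captures more than one centroid.

### The five features

- **mz_error_abs** = 1 − |m̄₁ − m̂₁|, computed in native m/z units
  (Da-scale differences). A `mz_error_in_ppm` switch converts deviations
  to ppm before the 1 − |·| transform; tree models are insensitive to this
  monotone rescaling, so the literal Da form is the default.
- **mz_error_rel** = 1 − |Σᵢ₌₂ᵀ((dᵢ − d₁)·Îᵢ) / Σᵢ₌₂ᵀ Îᵢ| with
  dᵢ = m̄ᵢ − m̂ᵢ, restricted to observed isotopes. Missing-isotope policy:
  a missing first isotope forces both error scores to the worst value 0;
  missing higher isotopes are excluded from both sums; if no higher isotope
  is observed the relative error is 0 — absence of evidence must not look
  like perfect agreement.
- **ρ_spectral** = 1 − ½‖p/‖p‖₁ − q/‖q‖₁‖₁, p the theoretical relative
  intensities, q the observed per-isotope total intensities (missing
  isotopes contribute 0; all-zero q scores 0). Totals are sums over pixels;
  after L1 normalization the sum/mean choice is immaterial when masks
  agree.
- **ρ_spatial**: Î-weighted mean over isotopes i ≥ 2 of
  max(0, Pearson(image₁, imageᵢ)) over acquired pixels. Negative
  correlations are clipped to zero (an anticorrelated isotope image is not
  evidence); a constant or empty principal image scores 0.
- **ρ_chaos**: at each of 30 intensity thresholds, quantile-spaced over the
  principal image's nonzero intensities, the image is binarized (≥
  threshold) and the ratio of 4-connected components to retained pixels is
  taken; the score is 1 − mean ratio, clipped to [0, 1]. A solid blob of
  100 equal-intensity pixels scores 0.99; isolated single pixels score 0.
  For smoothly varying blobs the top quantile levels retain few pixels, so
  the score saturates around 0.9 rather than 1 — a property of the
  definition, not noise.

The exact ρ formulas are this package's normative definitions (the
predecessor rule-based engine's implementations are not reproduced
bit-for-bit); they are isolated behind `ionrank.scoring` so alternates can
be swapped. MSM = ρ_spatial·ρ_spectral·ρ_chaos.

### Isotope patterns

Patterns are computed by element-wise convolution of natural isotope
abundances (pyteomics `nist_mass` table) over nominal-mass-shift bins,
tracking per-bin probability and probability-weighted centroid mass,
truncated to the first T bins and normalized to the most intense kept
peak. This matches "first four isotopic peaks" semantics at FTICR/Orbitrap
resolution; fine structure within a nominal bin is aggregated. The electron
mass is included in m/z; charge is restricted to ±1. A test oracle
enumerates every isotopologue by brute force and agrees to < 1e-9 (L1) on
molecules up to 10 atoms.

### Decoys

Each target formula draws S_D = 20 decoy adducts without replacement from
a configurable universe of ~70 chemically implausible single-element
attachments (He, Li, Be, B, transition metals, rare earths…), shipped as a
text file and user-overridable. The draw is a named RNG stream keyed by
(purpose, formula) derived from the master seed, so a formula's decoy set
is stable under corpus growth, and the same set is shared across all of
that formula's target adducts. In negative mode decoy ions are built as
M+X with charge −1 — plain composition bookkeeping; decoys are implausible
by construction and no proton balancing is attempted.

### FDR estimation

Per (database, target adduct) group, targets and all shared decoys are
sorted by descending score; ties rank decoy-before-target so tied scores
never understate the FDR. With cumulative counts Tᵢ, Dᵢ at rank i:

    FDRᵢ = ((Dᵢ+1)/S_D) / ((Tᵢ+1) + (Dᵢ+1)/S_D)

Dᵢ is the raw decoy count; the 1/S_D weight enters only through the
formula. The pseudocounts (rule of succession) keep the FDR strictly
positive: a clean top target at S_D = 20 has FDR 1/20 ÷ (2 + 1/20) =
0.0244. The monotonicity adjustment is the standard q-value-style reverse
cumulative minimum. On synthetic rankings where false-target scores are
exchangeable with decoy scores, the empirical false-target fraction at
q ∈ {5, 10, 20}% stays below q (conservative), which the acceptance script
measures over 200 seeded replicates.

### Ranking model

Gradient-boosted trees with a pairwise logistic ranking loss (xgboost
`rank:pairwise`; the loss family of CatBoost's PairLogit), 1000 iterations
by default, learning rate 0.1, depth 4, single-threaded and deterministic
under seed. Pairs are formed within datasets only — the dataset is the
query group — with targets as winners. Raw ensemble outputs are min-max
scaled to [0, 1] with bounds recorded over the training corpus predictions
(a backend-independent proxy for leaf-value extremes; documented as an
approximation). Scaling is strictly monotone, so rankings and hence FDR
estimates are invariant to it. Cross-validation is 5-fold and
context-stratified: each context's datasets are permuted under the seed
and dealt round-robin to folds; contexts with fewer than k datasets stay
in training with a warning. AP is computed per held-out dataset; MAP is
the unweighted mean. Attribution uses TreeSHAP values computed natively by
the backend; per-ion shares are |SHAP_f| / Σ_g |SHAP_g| and aggregate per
dataset by the median.

### Reliability score

Targets and decoys with their adjusted FDRs are treated as positive and
negative instances over the sweep of observed unique FDR cutoffs (no fixed
grid, no 0/1 endpoints). At each cutoff, precision and recall come from
unweighted counts — a `decoy_weight = 1/S_D` switch provides the weighted
alternative consistent with the FDR formula — and F-beta uses β = 0.5 to
weight precision, since decoys outnumber targets S_D-fold. For a default
threshold t ∈ {5, 10, 20, 50}%, reliability = b[cutoff nearest t]/max(b) ·
(1 − optim_fdr); argmin/argmax ties resolve toward smaller cutoffs
(conservative), and the optimal default threshold is the smallest one
attaining the maximum score.

### QC

The profile-mode score is the mean, over the 50 pixels with the most
nonzero peaks, of the fraction of consecutive peak gaps with
m_{i+1} − m_i ≤ m_i·tol/1e6: profile data sample the peak shape densely,
so consecutive points fall inside the matching tolerance and the score
approaches 1, while genuine centroids are sparse and score near 0;
exclusion above 0.5. A literal variant that compares the absolute Da gap
against tol/1e6 and counts wide gaps is retained behind a flag for audit —
it inverts the intended direction and is not used by the rules. The other
exclusion rules: fewer than 10 annotations at FDR 20% in *every*
(adduct, database) combination (one adequate combination rescues the
dataset), and median per-pixel nonzero peak count above 50,000.

### Context classification and corpus selection

Contexts combine polarity, ionization source, mass analyzer, m/z class
(max ≤ 400 → small molecules; min > 500 → Lipids; otherwise both), sample
type, and species after grouping the rare tail (species whose cumulative
ascending frequency is ≤ 10% of the total, inclusive at the boundary, map
to OTHER; alphabetical tie-breaks). Selection within a context (eligible
from 45 datasets; 30 selected by default) first takes one dataset per
(project, group) combination — datasets without a project get a
(submitter, submission-day) pseudo-label — then fills remaining slots from
combinations ranked lexicographically by (Shannon entropy of the
combination's submission-day composition, descending; relative size,
descending; name), drawing members at random under the seed. The entropy
captures within-combination diversity; the exact size/entropy weighting
was an open design choice and this lexicographic rule is the package's
normative version. Test selections are drawn first and removed from the
pool before training selections (mutual exclusivity).

## Synthetic data

The generator plants formula+adduct ions with their T-peak theoretical
patterns at m/z values jittered by Gaussian ppm noise (default sd 0.5 ppm,
well inside the 3 ppm tolerance), intensities proportional to pattern ×
spatial template × lognormal pixel noise, plus uniform-random noise peaks
(default 30/pixel over m/z 100–1000) at exponential intensities scaled by
1/SNR (default SNR 10). Spatial templates are smooth thresholded Gaussian
random fields ("blob"; "region" gives a binary plateau, "uniform" fills
the grid), so planted ions are spatially coherent and informative while
decoy matches against noise are scattered — the mechanism the ρ features
exploit. Uniform noise m/z means decoy ions occasionally match noise,
which keeps FDR curves non-degenerate. `profile_mode_shoulders` expands
every peak into a cluster of satellites spaced 0.8 ppm apart with
geometrically decaying heights, emulating mistakenly submitted
profile-mode data. Defaults (32×32 grid, 10 molecules, T = 4) are the
study conditions used throughout the tests.

The generator does **not** emulate instrument peak shapes,
mass-resolution decay, intensity drift, or tissue morphology; passing
tests demonstrate the correctness of the computations and the internal
consistency of the statistics, not performance on real tissue data.

`generate_feature_corpus` emits feature vectors directly with a planted
informativeness profile (per-feature separation strength: 1 = disjoint
class distributions, intermediate = overlapping Gaussians, 0 = identical).
The ranker consumes only feature vectors, so this exercises
cross-validation and attribution recovery at a fraction of the cost of
full spectra simulation; full-dataset generation remains the primary path
and feeds the end-to-end tests. `simulate_exchangeable_ranking` produces
scored rankings in which false-target scores are exchangeable with decoy
scores — the regime in which target-decoy FDR estimation is calibrated —
for the calibration measurements.

## Numerical choices and problem sizes

- Oracle equivalence checks enumerate all target/decoy label patterns up
  to length 12 exhaustively (FDR, F-beta, AP) and add 600 random rankings
  of lengths 13–20 for the FDR formula; the identity being checked is
  length-independent and the sizes keep the default runs fast.
- Fisher p-values are checked against from-scratch hypergeometric tail
  sums exhaustively for table totals up to 12 and on random tables with
  margins up to 50.
- Calibration uses 200 replicates of 60 targets (half false) with
  S_D = 20; QC separation uses 100 seeded trials on 8×8 grids; ranker
  recovery uses 20 datasets × (20 targets + 100 decoys) with 100 boosting
  iterations (the 1000-iteration default is unnecessary on separable
  synthetic corpora).
- Enrichment defaults to the one-tailed ("greater") Fisher test;
  a two-sided alternative is exposed as a flag.
- All RNG streams derive from a single master seed (numpy Generator;
  derived seeds stay below 2³¹); xgboost runs single-threaded with a fixed
  seed, making the full pipeline byte-deterministic.

## Known limitations

- Singly charged ions only; no isotopic fine structure within a nominal
  mass bin; no multiply charged or cluster adducts.
- The decoy-adduct universe is a plausible stand-in, not a curated list;
  it is user-overridable.
- Min-max scaling bounds come from training-corpus predictions, so unseen
  data can clip at 0 or 1 (clipping preserves threshold semantics but not
  resolution beyond the training range).
- The corpus-selection entropy/size ranking is one defensible reading of
  an under-specified procedure; alternates can be plugged in at
  `ionrank.context.select_datasets`.
- Headline numbers from large public-corpus studies (median MAP of a
  trained model across ~1700 real datasets, fold gains, LC-MS/MS TPR)
  require those corpora and are out of desk-scale scope; the test suite
  validates the machinery with oracles and planted ground truth instead.
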