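# Methods

## Staining Density Index

Ordinal section scores are a pragmatic stand-in for counts that cannot be
made precise (fiber density especially). Two scales feed the same index:
cell counts binned 0 / 1–6 / 7–11 / ≥12 → 0–3, and fiber codes
0/+/++/+++ → 0–3. The published cell bins overlap at their edges ("1–6" vs
"6–12", "6–12" vs "12 or more"); we resolve the overlap in favor of the
explicit phrases — 6 cells score 1, 12 cells score 3 — leaving 7–11 for
score 2. Fiber scoring itself is an observer judgment (e.g. one axon in a
small region vs a few in a large one); the package deliberately ingests the
ordinal code rather than attempting to automate that judgment.

The index per animal × region × modality is
SDI = (3N₃ + 2N₂ + N₁)/(3NT), with NT counting *all* sections the region
spans. Zero-scored sections therefore dilute the index; adding one strictly
decreases a nonzero SDI. The tally form is checked exhaustively against the
sum-of-scores form Σscoreᵢ/(3NT) for every score vector up to NT = 6.

Pooling across animals is the arithmetic mean of per-animal SDIs (the
source analyses say only "pooled"; mean is the natural reading and the
median is available). A region missing from an animal's table is treated as
missing, not zero — zero must come from an explicit NT > 0 record. NT is
recorded per animal × region rather than fixed per region, since section
spans can differ between brains.

Tertile classification uses the empirical 33.3/66.7 percentiles (linear
interpolation) of the pooled SDI; a value exactly on a boundary goes to the
denser class, and a degenerate distribution (all values equal) collapses to
one class with a warning rather than an arbitrary split.

The sex screen is Welch's t-test per region, two-sided, uncorrected:
with three animals per sex it is exploratory, and regions with fewer than
`min_obs` (default 2) values in either sex are listed as excluded rather
than silently dropped. Both groups constant and equal makes t 0/0; it is
reported as NaN, not as "no difference".

## DCV size cutoff

The estimator is the crossing point of the two Gaussian-kernel density
estimates of vesicle area, located between the two sample modes — the area
where the locally dominant population switches. Numerically: both KDEs are
evaluated on a common grid over [0, 1.2·max area] (512 points), sign
changes of their difference between the modes are bracketed, and each root
is polished with Brent's method. Multiple crossings can occur at small n in
the tails; the crossing nearest the midpoint of the modes is selected and
all crossings are reported in a warning. Identical samples (or equal means)
raise instead of returning a meaningless root.

Bandwidth defaults to Silverman's rule of thumb per sample (neither a
kernel nor a bandwidth is prescribed by the measurement protocol the
defaults emulate); a numeric bandwidth in area units can be supplied and is
recorded in the output. The closed-form intersection of two normal
densities (quadratic in x after taking logs) serves as the analytic
counterpart and as the convergence target of a test at n = 10⁴ per group
(tolerance 5·10⁻⁴ µm²).

The "fraction of labeled vesicles at or below the cutoff" is a validation
property, not an optimization target: the intersection is the estimator,
and the fraction is flagged when it reaches 5%. At the default population
parameters the analytic sub-cutoff mass at the reported (3-decimal) cutoff
is Φ(−1.6) ≈ 5.5%, i.e. right at the flag boundary — single samples of
n = 61 scatter on both sides of it, which is expected behavior, not an
error. Classification at the boundary assigns an area exactly equal to the
cutoff to the negative class ("at or below").

The underlying area populations are summarized in the literature only as
mean ± SD; normality (truncated at zero) is this package's modeling
assumption, used by the generator and the analytic oracle, and is not a
claim about the real vesicle-size distribution. Areas are single ultrathin
(~60 nm) cross-sections; no stereological correction for section-plane
truncation is applied because none is described for the workflow emulated.

Equivalent diameter is d = 2√(A/π), reported to the nearest 10 nm only at
the report layer (0.016 µm² → 142.7 nm → "~140 nm").

Incidence is the fraction of profiles containing ≥ 1 supra-cutoff DCV
(the ≥ 1 rule is implied rather than stated by the emulated workflow and is
adopted here), with Wilson score intervals — chosen over Wald for sane
behavior at the small per-region profile counts (30–156).

## Concordance model

After harmonization (explicit label mapping; multi-subregion receptor
scores averaged; unmatched regions carried with `included=False` and a
reason, so the audit conserves rows on both sides), included regions are
fit with OLS: `pooled_sdi ~ receptor_score * C(category)` with treatment
coding. The orientation — which variable is the response — is genuinely
ambiguous in the workflow this emulates; the default regresses SDI on the
receptor score and the transpose is a flag. Trends are invariant to the
reference category, which is tested.

The interaction test is the nested-model F comparing the full interaction
fit against `response ~ covariate + category`. Degenerate, perfectly fitted
data (zero residual) would make the F ratio 0/0; the implementation reports
F = 0, p = 1 when the interaction gain in sum of squares is negligible
relative to the total, and floors the denominator otherwise so F stays
finite. The numerator df follows from the fitted design (k − 1 interaction
terms for k categories); no external df convention is imposed.

Per-category trends are linear contrasts (covariate coefficient + the
category's interaction coefficient), SE by the delta method from the
coefficient covariance, two-sided t on the residual df. A fit with a
single-region category is refused by name: its slope is unidentifiable.
Receptor scores are treated as continuous (a trend is a slope per score
unit); regions are unweighted, as no per-region weighting scheme is
described. The hindbrain category is carried through harmonization but
excluded from the default trend analysis (five parent categories), and can
be re-included via the `categories` argument.

## Puncta summaries

"Expressing" means ≥ 1 punctum by default (configurable; no threshold is
prescribed). Percent expressing is computed per section and summarized as
mean ± SD across sections, matching how replicate sections are usually
reported. Puncta density is reported under both conventions — among
expressing cells and among all cells — because the convention is ambiguous
in the summaries the defaults emulate; zeros can only lower the all-cells
mean, and the default headline value is among expressing cells. The
negative control passes at median 0 ("no specific labeling"
operationalized), the positive at mean > 15 puncta per cell.

## Synthetic data

The generators define the study conditions the tests run under:

* vesicle areas: two normals truncated at 0 by rejection, defaults
  0.016 ± 0.005 µm² (n = 61) and 0.004 ± 0.002 µm² (n = 60). Truncation
  sits 3.2σ and 2σ from zero, so the induced positive bias is ≈ 0 for the
  labeled and ≈ +0.0001 µm² for the unlabeled population — negligible at
  these sample sizes but real, hence documented;
* profile incidence: Bernoulli(p) per profile, defaults at the printed
  per-region rates (6% of 48 LH axons … 40% of 30 SON dendrites);
* section scores: Poisson(λ) cell counts per section pushed through the
  score bins, with an optional additive sex effect on λ (applied to males,
  floored at 0); default λs give one saturated, one intermediate and one
  sparse region;
* concordance tables: receptor score uniform on [1, 4] (continuous by
  default; the ordinal flag draws integers), SDI = α + βscore + N(0, σ)
  clipped to [0, 1]; default βs are the published per-category trends
  (0.13, −0.04, −0.010, −0.003, 0.03) with σ = 0.05 and 14 regions per
  category, sized like the real region lists;
* puncta: Bernoulli(p) expression × shifted-Poisson (1 + Poisson(μ−1))
  counts, so expressing cells always show ≥ 1 punctum; defaults at the
  printed 15.4–23.9% / 3.4–8.4 puncta per cell;
* EM image: 8-bit grayscale, dark disks dart-thrown (≤ 10⁴ attempts)
  without overlap on a noisy bright background, with ground truth returned;
  the companion measurement (midpoint threshold + 4-connected components)
  recovers areas within 15% for disks ≥ 6 px across. This fixture
  exercises the area-measurement path end to end; it does not model
  microscope optics, staining variability, or touching vesicles.

One seed per generator call is split per table with `SeedSequence.spawn`,
so each table is independently reproducible and fixed seeds give
bit-identical output. Clipping SDIs to [0, 1] slightly attenuates extreme
slopes near the interval ends; the default parameters keep generated values
comfortably inside, so recovery tests are unaffected.

What passing on synthetic data does *not* show: the generators assume
independence across sections, profiles and cells, no observer drift in the
ordinal scoring, and exactly-normal area populations. Real data violate all
three to some degree; the tests establish correctness of the estimators
under the stated model, not robustness to those violations.

## Problem sizes

Default test/replication sizes — 200 replicates for cutoff and trend
recovery, 500 for binomial recovery, 1000 tables for CI coverage, 10⁴
draws for KDE convergence — were chosen so each stochastic check has
standard error comfortably below its asserted tolerance while the whole
suite stays fast.
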