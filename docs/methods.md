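# Methods

## Normalization

Raw well signals (fluorescence/absorbance proportional to viable cell number)
are divided by the mean signal of the vehicle-control wells (both doses 0) to
give a surviving fraction per condition; replicate fractions are then averaged
arithmetically and clipped to [0, 1].  If a `plate` column is present each
plate is normalized against its own controls and plates are averaged
afterwards; otherwise a single pooled control mean is used (the choice between
per-plate and global normalization was genuinely open; per-plate is used
whenever the data identify plates, because control drift between plates is the
dominant nuisance the division removes).  Clipping to 1 discards
above-control proliferation: the downstream statistics describe kill, and a
survival ratio above 1 would make R uninterpretable.  Normalization is
scale-free — multiplying every signal on a plate by any positive constant
changes nothing downstream.

## The fractional-product statistic R

R is defined on surviving fractions: R = s_combo / (s_A · s_B), the observed
combined survival over the Bliss-independence expectation.  The alternative
formulation on affected fractions (Bliss excess) is deliberately not used:
the surviving-fraction ratio is what the name "fractional product" denotes,
and it makes R < 1 the synergy direction used by all the thresholds here.
Classification boundaries: R < 0.4 strong synergy (strict — the reference hit
table's largest entry is 0.398), 0.4 ≤ R < 0.7 synergy, 0.7 ≤ R ≤ 1
non-synergy, R > 1 antagonism; the four labels partition (0, ∞).

When the Bliss-expected survival s_A·s_B is 0 the ratio is undefined; such
results carry R = NaN and no label and are excluded from summaries.  More
broadly, dose pairs whose expected survival falls below an admissibility
floor (default 0.05) are excluded from compound-level summaries: near the
kill floor both numerator and denominator are assay noise, and R becomes a
ratio of noise terms with huge variance.

The same operation serves three data types: in-vitro survival, apoptosis
(converted to the non-apoptotic fraction first) and in-vivo tumor growth,
where each group's mean caliper volume (l·w·h/2, mm³) is divided by the
control-group mean at the same day to give a fractional volume.

## The screening cascade

The primary screen tests every compound at 1 and 10 µM alone and combined
with the anchor at 200 nM (a dose chosen to kill ~20% of cells alone), in
triplicate.  Per dose:

- **cytotoxic_alone** — ≥ 90% reduction alone and ≥ 80% in combination
  (synergy cannot be assessed over that much single-agent kill);
- **potential_hit** — otherwise, R < 0.7 and combination reduction
  strictly > 80% (the two gates are phrased with different strictness on
  purpose, mirroring how the two selection sentences differ);
- **non_hit** — everything else.

A compound qualifying at either dose advances with its better (lower) R.
Precedence across the two doses is potential_hit > cytotoxic_alone > non_hit:
advancing to synergy confirmation is the most informative outcome a compound
can achieve, and in the motivating screen both cytotoxic-alone and potential
hits proceeded to the secondary stage.  Compounds with missing arms are
flagged `unevaluable`, never dropped.

The secondary screen re-tests shortlisted compounds on a 5 anchor-dose ×
12 compound-dose checkerboard.  R is computed at every strictly positive dose
pair; the compound-level R is the **minimum over admissible pairs** with its
argmin dose pair recorded.  The source screen reports a single R per compound
without stating the reduction rule; the minimum reproduces a best-synergy
ranking and matches the screen's intent of finding the strongest interaction
anywhere on the surface.  It is biased low under noise, which is why the
admissibility floor matters; both the rule and the floor are configurable
through `SynergyThresholds`.

## Median-effect engine

The fit is ordinary least squares of log10(fa/fu) on log10(D) — plain,
unweighted, base-10 (m, r and CI are base-invariant; base 10 fixes the
intercept's reporting convention at −m·log10 Dm).  Points with fa ≤ 0 or
fa ≥ 1 carry no information on the log-odds scale and are dropped; surviving
points are clipped to [1e−6, 1−1e−6] before the transform.  At least two
usable points with distinct doses are required.  r is the Pearson correlation
of the regression.  No weighting is applied; weighted variants exist in
commercial implementations but the weights are undocumented, so the plain
estimator is used and stated.

Combination indices default to the mutually-exclusive two-term form
CI = d₁/Dx₁ + d₂/Dx₂; the non-exclusive form (adding d₁d₂/(Dx₁Dx₂), always
≥ the exclusive value) is available behind a flag.  Constant-ratio series are
fitted on total dose d₁+d₂ and split by the ratio at report time; default
report levels are fa = 0.50, 0.75, 0.90.  For non-constant-ratio
checkerboards, `pointwise_ci` evaluates the same formula per observed well.
Everything is invariant to rescaling doses by a positive constant except Dm
and the Dx, which scale with it.

## Synthetic screen generator

Single agents follow s(D) = 1/(1 + (D/Dm)^m) — the exact model the fitter
assumes, so noise-free round trips are sharp tests (recovery to 1e−9).
Combinations are generated under Bliss (s_a·s_b), Loewe (isobole equation
solved for fa by Brent root-finding, tolerance 1e−10) or a multiplicative
interaction factor ψ with s_combo = clip(ψ·s_a·s_b, 0, 1).  The ψ model is
the generator's invented minimal ground truth: it maps one-to-one onto the R
scale (R = ψ wherever clipping does not bind), which is what makes recovery
tests exact.  Each analytic null holds exactly at zero noise: Bliss → R = 1,
Loewe → CI = 1, ψ → R = ψ.

Noise is multiplicative lognormal on raw signals with mean 1 and a chosen
coefficient of variation — plate-reader-like, keeps signals positive, and
leaves the clipping semantics meaningful; it is not additive noise on
fractions.  Default study conditions mirror the screen being modelled:
triplicate wells, 5% signal CV, primary doses {1, 10 µM} × anchor
{0, 200 nM}, the secondary 12 × 5 dose grids, and an anchor dose–response
fixed at (Dm = 800 nM, m = 1) so that 200 nM kills exactly 20% alone.
Compound potencies are drawn log-uniform on [100 nM, 50 µM] and slopes
uniform on [0.8, 2.5] — a broad, realistic potency spread for a diverse
small-molecule library against a cell line.  Interaction classes use
ψ ∈ [0.1, 0.3] (strong), [0.45, 0.65] (medium), exactly 1 (null) and
[1.2, 1.5] (antagonist).

Determinism: generation is a pure function of (spec, seed).  Each compound
draws from its own seed substream (keyed by compound index), and classes are
apportioned to compounds by a greedy largest-deficit rule that depends only
on the compound's index — so enlarging a library never perturbs the data of
existing compounds, and a 200-compound library with mix
0.25/0.25/0.40/0.10 contains exactly 50/50/80/20 compounds per class.

The tumor-growth generator grows control volumes exponentially from 50 mm³
(the treatment-start size) and scales group means multiplicatively
(combination = effect_a · effect_b · ψ), back-computing equal caliper sides
from (2V)^(1/3) so the volume formula holds exactly.

What the generator does **not** emulate: plate-geometry artifacts (edge
effects, spatial gradients), serial-dilution errors correlated across a dose
series, compound fluorescence interfering with the readout, cell-line
heterogeneity, pharmacokinetics or animal dropout.  Passing recovery tests
therefore shows the analysis is correct *under its own statistical
assumptions*, not that those assumptions hold for any particular real screen.

## Problem sizes and numerical choices

The validation suite uses a 200-compound library (36,000 secondary wells) at
5% noise in triplicate for cascade recovery, 200 simulation seeds for noisy
median-effect recovery, and 6–8-point dose series elsewhere — sizes at which
every estimator's behaviour is already stable.  Root-finding brackets fa in
[1e−12, 1−1e−12]; degenerate inputs (identical doses, < 2 usable points,
missing control wells, missing treatment groups) raise errors naming the
offending unit rather than returning silent NaNs.

## Known limitations

- The compound-level minimum-R rule is biased low under noise (a minimum over
  many noisy ratios); the admissibility floor bounds but does not remove the
  bias.  A compound whose true ψ sits within ~0.05 of a class boundary can be
  assigned the neighbouring label.
- CI confidence bands (Monte-Carlo, as in commercial tools), dose-reduction
  indices and isobologram graphics are out of scope.
- The median-effect fit assumes log-odds linearity; strongly biphasic
  responses violate it, and r is the only diagnostic surfaced.
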