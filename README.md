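# synerscreen

Analysis toolkit for drug-combination viability screens: plate normalization,
the fractional-product (Bliss) synergy statistic *R* with a two-stage
hit-calling cascade, and a from-scratch Chou–Talalay median-effect /
combination-index engine, plus a synthetic-screen generator with known ground
truth for validating every stage.

It is written for the kind of experiment in which a large compound library is
tested alone and in combination with a fixed "anchor" drug (the motivating
screen combined 2697 NCI library compounds with the BET bromodomain inhibitor
JQ1 in BE(2)-C neuroblastoma cells), and shortlisted pairs are then
re-measured on full dose checkerboards and constant-ratio series.

## The statistics

**Fractional product (Webb / Bliss independence).** On surviving fractions
*s*, two independently acting drugs satisfy *s*<sub>AB</sub> =
*s*<sub>A</sub>·*s*<sub>B</sub>.  The synergy ratio is

> R = s_combo / (s_A · s_B)

with R < 1 synergy, R = 1 additivity, R > 1 antagonism.  Hit calling uses
R < 0.4 for strong synergy and 0.4 ≤ R < 0.7 for synergy.  The same statistic
applies to apoptosis assays (on the non-apoptotic fraction) and to xenograft
experiments (on mean fractional tumor volumes, with caliper volume
*l·w·h*/2).

**Chou–Talalay median effect.** Each dose–response series is fitted to
fa/fu = (D/Dm)^m — a straight line of log(fa/fu) on log D — giving the
median-effect dose Dm, the slope m, and the correlation r of the
median-effect plot.  For a constant-ratio combination the index at effect
level fa is

> CI(fa) = d₁/Dx₁(fa) + d₂/Dx₂(fa)

(CI < 1 synergy, = 1 Loewe additivity, > 1 antagonism), where Dx = Dm ·
(fa/(1−fa))^(1/m).  A sham combination (a drug mixed with itself) yields
CI ≡ 1 by construction, which the test suite verifies.

## Worked example

```python
import numpy as np
from synerscreen import (AgentModel, median_effect_fit, combination_index,
                         fa_ci_table, fractional_product_R)

doses = np.array([12.5, 25, 50, 100, 200, 400])        # nM
drug = AgentModel(Dm=100, m=2)                         # ground truth
fit = median_effect_fit(doses, drug.fa(doses))
print(fit.summary())

res = fractional_product_R(s_combo=0.15, s_a=0.6, s_b=0.8)
print(f"R = {res.R:.4f} ({res.label})")

mixture = AgentModel(Dm=55, m=2)                       # more potent than additive
combo = median_effect_fit(doses, mixture.fa(doses), ratio=(1, 1))
print(fa_ci_table(combination_index(fit, fit, combo)).to_string(index=False))
```

prints

```
Median-effect fit
========================================
Dm (nM)                      100
m (slope)                      2
r (correlation)                1
n points                       6

R = 0.3125 (strong_synergy)

  fa   CI        d1        d2        Dx1        Dx2       label
0.50 0.55 27.500000 27.500000 100.000000 100.000000 synergistic
0.75 0.55 47.631397 47.631397 173.205081 173.205081 synergistic
0.90 0.55 82.500000 82.500000 300.000000 300.000000 synergistic
```

The fit recovers the generating parameters exactly on noise-free data (r = 1);
the combination kills 85% of cells where independence predicts 52%, giving
R = 0.31 (strong synergy); and a 1:1 mixture reaching every effect level at
0.55× the additive dose has CI = 0.55 at fa = 0.50, 0.75 and 0.90.

A command-line interface mirrors the pipeline
(`synerscreen primary | secondary | ci | report | simulate`); the packaged
hit table — the 33 compounds with strong JQ1 synergy, annotated with
mode-of-action codes — is summarized by `synerscreen report` (9
anti-microtubule drugs, 9 quinone-containing compounds of which 6 are DNA
intercalators, vincristine the best approved drug at R = 0.145).

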