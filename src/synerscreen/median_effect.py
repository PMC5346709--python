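"""Chou-Talalay median-effect analysis and combination indices.

The median-effect equation relates dose D to the fraction of cells affected
(fa, with fu = 1 - fa the surviving fraction):

    fa / fu = (D / Dm)^m

Dm is the median-effect dose (the IC50 analogue) and m the sigmoidicity of the
dose-response curve.  Taking logs, log10(fa/fu) is linear in log10(D), so the
fit is an ordinary least-squares regression on the "median-effect plot"; its
Pearson correlation r is the standard fit-quality diagnostic.

For a combination tested at a constant dose ratio p:q, the mixture is fitted
as a single agent on total dose, and the combination index at effect level fa
is

    CI(fa) = d1/Dx1(fa) + d2/Dx2(fa)        (mutually exclusive form)

where (d1, d2) are the component doses of the mixture reaching fa and Dx1, Dx2
the single-agent doses reaching fa alone.  CI < 1 indicates synergy, CI = 1
additivity (Loewe), CI > 1 antagonism.  The non-exclusive form adds
(d1*d2)/(Dx1*Dx2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FA_EPS = 1e-6  # fa clipped to [eps, 1-eps] before the log-odds transform
DEFAULT_FA_LEVELS = (0.50, 0.75, 0.90)


class MedianEffectModel:
    """Median-effect (Hill-type) dose-response model for one agent or mixture.

    Parameters
    ----------
    dose : array-like
        Doses (nM).  Points with nonpositive dose are dropped before the fit.
    fa : array-like
        Fraction affected at each dose, in (0, 1).  Points with fa <= 0 or
        fa >= 1 carry no information on the log-odds scale and are dropped.
    ratio : tuple (p, q), optional
        Constant dose ratio drug A : drug B when the series is a fixed-ratio
        combination whose ``dose`` is the total dose d1 + d2.

    Examples
    --------
    >>> model = MedianEffectModel([50, 100, 200], [0.2, 0.5, 0.8])
    >>> res = model.fit()
    >>> round(res.Dm), round(res.m, 3)
    (100, 2.0)
    """

    def __init__(self, dose, fa, ratio: tuple[float, float] | None = None):
        self.dose = np.asarray(dose, dtype=float)
        self.fa = np.asarray(fa, dtype=float)
        if self.dose.shape != self.fa.shape:
            raise ValueError("dose and fa must have the same length")
        if ratio is not None:
            p, q = ratio
            if p < 0 or q < 0 or p + q <= 0:
                raise ValueError(f"invalid dose ratio {ratio}")
        self.ratio = ratio

    @classmethod
    def from_survival(cls, dose, survival, ratio=None) -> "MedianEffectModel":
        """Build from surviving fractions (fa = 1 - survival)."""
        return cls(dose, 1.0 - np.asarray(survival, dtype=float), ratio=ratio)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col="dose_nM", fa_col="fa", ratio=None):
        return cls(df[dose_col].to_numpy(), df[fa_col].to_numpy(), ratio=ratio)

    def fit(self) -> "MedianEffectResults":
        """OLS fit of the median-effect plot; returns a results object."""
        usable = (self.dose > 0) & (self.fa > 0) & (self.fa < 1)
        dose, fa = self.dose[usable], self.fa[usable]
        if dose.size < 2:
            raise ValueError(
                f"need >=2 points with dose > 0 and 0 < fa < 1, have {dose.size}"
            )
        if np.all(dose == dose[0]):
            raise ValueError("all doses identical: median-effect regression degenerate")
        fa = np.clip(fa, FA_EPS, 1.0 - FA_EPS)
        x = np.log10(dose)
        y = np.log10(fa / (1.0 - fa))
        reg = stats.linregress(x, y)
        m = reg.slope
        if m <= 0:
            warnings.warn("non-positive median-effect slope; dose-response inverted")
        Dm = 10.0 ** (-reg.intercept / m)
        return MedianEffectResults(self, Dm=Dm, m=m, r=reg.rvalue, n_points=int(dose.size))


@dataclass(frozen=True)
class MedianEffectResults:
    """Fitted median-effect parameters: Dm (nM), slope m, correlation r."""

    model: MedianEffectModel
    Dm: float
    m: float
    r: float
    n_points: int

    @property
    def ratio(self) -> tuple[float, float] | None:
        return self.model.ratio

    def fa_at_dose(self, dose):
        """Fraction affected predicted at a dose: fa = 1 / (1 + (Dm/D)^m)."""
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            out = 1.0 / (1.0 + (self.Dm / dose) ** self.m)
        return out if out.ndim else float(out)

    def dose_for_effect(self, fa):
        """Invert the fit: Dx = Dm * (fa / (1 - fa))^(1/m)."""
        fa = np.asarray(fa, dtype=float)
        if np.any((fa <= 0) | (fa >= 1)):
            raise ValueError("effect level fa must lie strictly in (0, 1)")
        out = self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)
        return out if out.ndim else float(out)

    def summary(self) -> str:
        lines = [
            "Median-effect fit",
            "=" * 40,
            f"{'Dm (nM)':<18}{self.Dm:>14.6g}",
            f"{'m (slope)':<18}{self.m:>14.6g}",
            f"{'r (correlation)':<18}{self.r:>14.6g}",
            f"{'n points':<18}{self.n_points:>14d}",
        ]
        if self.ratio is not None:
            p, q = self.ratio
            lines.append(f"{'dose ratio a:b':<18}{p:>7g}:{q:<6g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Median-effect plot: log10(fa/fu) against log10(D), data and fit line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        usable = (self.model.dose > 0) & (self.model.fa > 0) & (self.model.fa < 1)
        d = self.model.dose[usable]
        fa = np.clip(self.model.fa[usable], FA_EPS, 1 - FA_EPS)
        x = np.log10(d)
        ax.scatter(x, np.log10(fa / (1 - fa)), label="data")
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, self.m * (grid - np.log10(self.Dm)), label=f"fit (r={self.r:.3f})")
        ax.set_xlabel("log10 dose (nM)")
        ax.set_ylabel("log10(fa / fu)")
        ax.legend()
        return ax


def median_effect_fit(dose, fa, ratio=None) -> MedianEffectResults:
    """Convenience wrapper: fit the median-effect model in one call."""
    return MedianEffectModel(dose, fa, ratio=ratio).fit()


@dataclass(frozen=True)
class CombinationIndexResult:
    """CI at one effect level, with its dose components (all doses in nM)."""

    fa: float
    CI: float
    D_combo: float
    d1: float
    d2: float
    Dx1: float
    Dx2: float


def _ci_from_components(d1, d2, Dx1, Dx2, exclusive: bool) -> float:
    ci = d1 / Dx1 + d2 / Dx2
    if not exclusive:
        ci += (d1 * d2) / (Dx1 * Dx2)
    return ci


def combination_index(
    fit_a: MedianEffectResults,
    fit_b: MedianEffectResults,
    fit_combo: MedianEffectResults,
    fa_levels=DEFAULT_FA_LEVELS,
    exclusive: bool = True,
) -> list[CombinationIndexResult]:
    """Combination indices for a constant-ratio series at given effect levels.

    ``fit_combo`` must carry the mixture's dose ratio p:q (drug A : drug B, on
    total dose).  For each fa the total mixture dose reaching fa is split into
    its components and referred to the single-agent doses reaching the same fa.
    """
    if fit_combo.ratio is None:
        raise ValueError("combination fit must carry its dose ratio (p, q)")
    p, q = fit_combo.ratio
    results = []
    for fa in fa_levels:
        if not 0.0 < fa < 1.0:
            raise ValueError(f"fa must lie in (0, 1), got {fa}")
        D = fit_combo.dose_for_effect(fa)
        d1 = D * p / (p + q)
        d2 = D * q / (p + q)
        Dx1 = fit_a.dose_for_effect(fa)
        Dx2 = fit_b.dose_for_effect(fa)
        ci = _ci_from_components(d1, d2, Dx1, Dx2, exclusive)
        results.append(CombinationIndexResult(fa, ci, D, d1, d2, Dx1, Dx2))
    return results


def pointwise_ci(
    fit_a: MedianEffectResults,
    fit_b: MedianEffectResults,
    points,
    exclusive: bool = True,
) -> list[CombinationIndexResult]:
    """CI per observed combination point (d1, d2, fa) without a combination fit.

    Supports checkerboard designs where the dose ratio varies across wells.
    Points with fa outside (0, 1) are skipped with a warning.
    """
    results = []
    for d1, d2, fa in points:
        if not 0.0 < fa < 1.0:
            warnings.warn(f"skipping point (d1={d1}, d2={d2}): fa={fa} outside (0, 1)")
            continue
        Dx1 = fit_a.dose_for_effect(fa)
        Dx2 = fit_b.dose_for_effect(fa)
        ci = _ci_from_components(d1, d2, Dx1, Dx2, exclusive)
        results.append(CombinationIndexResult(fa, ci, d1 + d2, d1, d2, Dx1, Dx2))
    return results


def classify_ci(ci: float) -> str:
    """CI < 1 synergistic, CI = 1 additive, CI > 1 antagonistic."""
    if ci < 1.0:
        return "synergistic"
    if ci > 1.0:
        return "antagonistic"
    return "additive"


def fa_ci_table(results) -> pd.DataFrame:
    """Tabulate CI results as fa, CI, dose components and classification."""
    return pd.DataFrame(
        {
            "fa": [r.fa for r in results],
            "CI": [r.CI for r in results],
            "d1": [r.d1 for r in results],
            "d2": [r.d2 for r in results],
            "Dx1": [r.Dx1 for r in results],
            "Dx2": [r.Dx2 for r in results],
            "label": [classify_ci(r.CI) for r in results],
        }
    )
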