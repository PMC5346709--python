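"""Median-effect fitting, dose inversion and combination indices."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synerscreen import (
    AgentModel,
    MedianEffectModel,
    combination_index,
    fa_ci_table,
    median_effect_fit,
    pointwise_ci,
)

DOSES = np.array([12.5, 25.0, 50.0, 100.0, 200.0, 400.0])


def hill_fa(dose, Dm, m):
    return 1.0 / (1.0 + (Dm / np.asarray(dose, dtype=float)) ** m)


def bisect_isobole_fa(d1, d2, fit_a, fit_b, iters=200):
    """Independent brute-force root solve of d1/Dx1(fa) + d2/Dx2(fa) = 1."""
    lo, hi = 1e-12, 1 - 1e-12
    f = lambda fa: d1 / fit_a.dose_for_effect(fa) + d2 / fit_b.dose_for_effect(fa) - 1
    # f is strictly decreasing in fa: doses overshoot the isobole while fa is too small
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize("Dm, m", [(100.0, 2.0), (250.0, 1.5), (30.0, 0.9)])
def test_noise_free_fit_recovers_parameters_exactly(Dm, m):
    res = median_effect_fit(DOSES, hill_fa(DOSES, Dm, m))
    assert res.Dm == pytest.approx(Dm, rel=1e-9)
    assert res.m == pytest.approx(m, rel=1e-9)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.n_points == len(DOSES)


def test_fitted_effect_at_Dm_is_half():
    res = median_effect_fit([50.0, 200.0], [hill_fa(50, 100, 2), hill_fa(200, 100, 2)])
    assert res.fa_at_dose(res.Dm) == pytest.approx(0.5)


def test_dose_for_effect_examples():
    res = median_effect_fit(DOSES, hill_fa(DOSES, 100.0, 1.0))
    assert res.dose_for_effect(0.5) == pytest.approx(res.Dm)
    assert res.dose_for_effect(0.75) == pytest.approx(300.0, rel=1e-9)
    with pytest.raises(ValueError):
        res.dose_for_effect(1.0)


@given(Dm=st.floats(10, 1e4), m=st.floats(0.5, 4), rel_dose=st.floats(0.01, 100.0))
def test_dose_for_effect_inverts_fa_at_dose(Dm, m, rel_dose):
    # doses within 100x of Dm keep fa representable away from {0, 1}
    res = median_effect_fit(DOSES * Dm / 100, hill_fa(DOSES * Dm / 100, Dm, m))
    dose = rel_dose * Dm
    fa = res.fa_at_dose(dose)
    assert res.dose_for_effect(fa) == pytest.approx(dose, rel=1e-6)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match=">=2 points"):
        median_effect_fit([100.0], [0.5])
    with pytest.raises(ValueError, match="identical"):
        median_effect_fit([100.0, 100.0], [0.4, 0.6])
    # fa at 0 and 1 carry no log-odds information and are dropped
    with pytest.raises(ValueError, match=">=2 points"):
        median_effect_fit([10.0, 100.0, 1000.0], [0.0, 0.5, 1.0])


def test_noisy_fit_recovers_Dm_with_small_median_error():
    Dm, m, n_seeds = 250.0, 1.5, 200
    doses = 250.0 * 2.0 ** np.arange(-3.5, 4.5)  # 8 doses around Dm
    errs_dm, errs_m = [], []
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        ratio = (doses / Dm) ** m * rng.lognormal(0.0, 0.05, size=doses.size)
        fa = ratio / (1.0 + ratio)
        res = median_effect_fit(doses, fa)
        errs_dm.append(abs(res.Dm - Dm) / Dm)
        errs_m.append(abs(res.m - m) / m)
    assert np.median(errs_dm) < 0.10
    assert np.median(errs_m) < 0.15


@pytest.mark.parametrize("Dm, m", [(100.0, 2.0), (500.0, 1.2)])
def test_sham_self_combination_is_exactly_additive(Dm, m):
    fa = hill_fa(DOSES, Dm, m)
    single = median_effect_fit(DOSES, fa)
    sham = median_effect_fit(DOSES, fa, ratio=(1, 1))
    for res in combination_index(single, single, sham):
        assert res.CI == pytest.approx(1.0, abs=1e-9)
        assert res.d1 + res.d2 == pytest.approx(res.D_combo)


def test_loewe_additive_combination_has_CI_1():
    a, b = AgentModel(100.0, 1.0), AgentModel(200.0, 1.0)
    fit_a = median_effect_fit(DOSES, hill_fa(DOSES, a.Dm, a.m))
    fit_b = median_effect_fit(DOSES, hill_fa(DOSES, b.Dm, b.m))
    totals = np.array([20, 40, 80, 160, 320, 640], dtype=float)
    combo_fa = [bisect_isobole_fa(t / 2, t / 2, fit_a, fit_b) for t in totals]
    fit_combo = median_effect_fit(totals, combo_fa, ratio=(1, 1))
    for res in combination_index(fit_a, fit_b, fit_combo, (0.5, 0.75, 0.9)):
        assert res.CI == pytest.approx(1.0, abs=1e-6)


def test_halving_combination_doses_halves_CI():
    a, b = AgentModel(100.0, 1.0), AgentModel(200.0, 1.0)
    fit_a = median_effect_fit(DOSES, hill_fa(DOSES, a.Dm, a.m))
    fit_b = median_effect_fit(DOSES, hill_fa(DOSES, b.Dm, b.m))
    totals = np.array([20, 40, 80, 160, 320, 640], dtype=float)
    combo_fa = [bisect_isobole_fa(t / 2, t / 2, fit_a, fit_b) for t in totals]
    fit_half = median_effect_fit(totals / 2, combo_fa, ratio=(1, 1))
    for res in combination_index(fit_a, fit_b, fit_half, (0.5, 0.75, 0.9)):
        assert res.CI == pytest.approx(0.5, abs=1e-6)


def test_missing_combination_ratio_is_an_error():
    fit = median_effect_fit(DOSES, hill_fa(DOSES, 100, 2))
    with pytest.raises(ValueError, match="ratio"):
        combination_index(fit, fit, fit)


@given(scale=st.floats(min_value=1e-2, max_value=1e3))
def test_unit_invariance_of_m_r_and_CI(scale):
    fa_a, fa_b = hill_fa(DOSES, 100, 2), hill_fa(DOSES, 300, 1.4)
    combo_fa = hill_fa(DOSES, 150, 1.8)
    base = [median_effect_fit(DOSES, f, ratio=r)
            for f, r in ((fa_a, None), (fa_b, None), (combo_fa, (1, 2)))]
    scaled = [median_effect_fit(DOSES * scale, f, ratio=r)
              for f, r in ((fa_a, None), (fa_b, None), (combo_fa, (1, 2)))]
    for fb, fs in zip(base, scaled):
        assert fs.Dm == pytest.approx(fb.Dm * scale, rel=1e-9)
        assert fs.m == pytest.approx(fb.m, rel=1e-9)
        assert fs.r == pytest.approx(fb.r, abs=1e-12)
    for rb, rs in zip(combination_index(*base), combination_index(*scaled)):
        assert rs.CI == pytest.approx(rb.CI, rel=1e-9)


def test_exclusive_CI_never_exceeds_non_exclusive():
    fa_a, fa_b = hill_fa(DOSES, 100, 2), hill_fa(DOSES, 300, 1.4)
    combo_fa = hill_fa(DOSES, 150, 1.8)
    fits = [median_effect_fit(DOSES, f, ratio=r)
            for f, r in ((fa_a, None), (fa_b, None), (combo_fa, (1, 1)))]
    excl = combination_index(*fits, exclusive=True)
    nonexcl = combination_index(*fits, exclusive=False)
    for e, n in zip(excl, nonexcl):
        assert e.CI <= n.CI


def test_pointwise_ci_on_isobole_and_monotherapy():
    fit_a = median_effect_fit(DOSES, hill_fa(DOSES, 100, 1))
    fit_b = median_effect_fit(DOSES, hill_fa(DOSES, 200, 1))
    fa = bisect_isobole_fa(50.0, 40.0, fit_a, fit_b)
    (on_isobole,) = pointwise_ci(fit_a, fit_b, [(50.0, 40.0, fa)])
    assert on_isobole.CI == pytest.approx(1.0, abs=1e-9)
    (mono,) = pointwise_ci(fit_a, fit_b, [(50.0, 0.0, 0.25)])
    assert mono.CI == pytest.approx(50.0 / fit_a.dose_for_effect(0.25))


def test_pointwise_ci_matches_direct_formula_on_bliss_surface():
    # m = 1 agents: Dx(fa) = Dm * fa / (1 - fa) in closed form, so CI can be
    # recomputed independently of the fitted inversion
    Dm_a, Dm_b = 100.0, 200.0
    fit_a = median_effect_fit(DOSES, hill_fa(DOSES, Dm_a, 1))
    fit_b = median_effect_fit(DOSES, hill_fa(DOSES, Dm_b, 1))
    points = []
    expected = []
    for d1 in (25.0, 100.0):
        for d2 in (50.0, 400.0):
            s = (1 / (1 + d1 / Dm_a)) * (1 / (1 + d2 / Dm_b))  # Bliss survival
            fa = 1 - s
            points.append((d1, d2, fa))
            expected.append(d1 / (Dm_a * fa / (1 - fa)) + d2 / (Dm_b * fa / (1 - fa)))
    results = pointwise_ci(fit_a, fit_b, points)
    for res, want in zip(results, expected):
        assert res.CI == pytest.approx(want, rel=1e-9)


def test_pointwise_ci_skips_out_of_range_fa_with_warning():
    fit = median_effect_fit(DOSES, hill_fa(DOSES, 100, 1))
    with pytest.warns(UserWarning, match="outside"):
        results = pointwise_ci(fit, fit, [(10.0, 10.0, 0.0), (10.0, 10.0, 0.5)])
    assert len(results) == 1


@pytest.mark.parametrize("ci, label", [(0.76, "synergistic"), (1.0, "additive"), (1.3, "antagonistic")])
def test_fa_ci_table_classification(ci, label):
    from synerscreen.median_effect import CombinationIndexResult

    table = fa_ci_table([CombinationIndexResult(0.5, ci, 10, 5, 5, 10, 10)])
    assert table.label.item() == label


def test_summary_and_plot_render(tmp_path):
    res = median_effect_fit(DOSES, hill_fa(DOSES, 100, 2), ratio=(1, 2))
    text = res.summary()
    assert "Dm" in text and "1:2" in text.replace(" ", "")
    ax = res.plot()
    assert ax.get_xlabel().startswith("log10")
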