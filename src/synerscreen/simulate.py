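"""Synthetic combination-screen generator with known ground truth.

Single agents follow the median-effect (Hill-type) model

    s(D) = 1 / (1 + (D / Dm)^m),     s(0) = 1,

the exact model the fitting engine assumes, so noise-free round trips recover
parameters to machine precision.  Combinations are generated under one of
three interaction models:

bliss
    s_combo = s_a * s_b (the fractional-product null: pipeline R = 1).
loewe
    s_combo solves the isobole equation d1/Dx1(fa) + d2/Dx2(fa) = 1 by
    bracketed root-finding (CI = 1 for any constant-ratio series).
factor
    s_combo = clip(psi * s_a * s_b, 0, 1): a minimal one-parameter synergy
    ground truth that maps one-to-one onto the R scale (R = psi wherever no
    clipping occurs); psi < 1 synergy, psi = 1 Bliss, psi > 1 antagonism.

Noise is multiplicative lognormal on raw signals (plate-reader-like, mean 1,
coefficient of variation ``noise_cv``), applied per well.  Every generator is
a pure function of its spec and seed; compounds draw from independent seed
substreams so adding a compound never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .plate_io import RAW_COLUMNS

CONTROL_LEVEL = 1000.0  # arbitrary raw-signal units for vehicle wells

PRIMARY_COMPOUND_DOSES = (1000.0, 10000.0)  # 1 and 10 uM
PRIMARY_ANCHOR_DOSE = 200.0  # nM JQ1
SECONDARY_ANCHOR_DOSES = (0.0, 125.0, 250.0, 500.0, 1000.0)
SECONDARY_COMPOUND_DOSES = (
    0.0, 1.0, 2.0, 3.90625, 7.8125, 15.625, 31.25, 62.5, 125.0, 250.0, 500.0, 1000.0,
)

# 200 nM of the anchor kills 20% of cells alone: Dm = 800, m = 1 reproduces that
DEFAULT_ANCHOR_MODEL_PARAMS = (800.0, 1.0)

CLASS_PSI_RANGES = {
    "strong": (0.1, 0.3),
    "medium": (0.45, 0.65),
    "none": (1.0, 1.0),
    "antagonist": (1.2, 1.5),
}


@dataclass(frozen=True)
class AgentModel:
    """Median-effect dose-response of one agent: Dm in nM, slope m."""

    Dm: float
    m: float

    def __post_init__(self) -> None:
        if self.Dm <= 0 or self.m <= 0:
            raise ValueError("Dm and m must be positive")

    def survival(self, dose):
        """Surviving fraction s(D) = 1 / (1 + (D/Dm)^m); s(0) = 1."""
        dose = np.asarray(dose, dtype=float)
        out = 1.0 / (1.0 + (dose / self.Dm) ** self.m)
        return out if out.ndim else float(out)

    def fa(self, dose):
        return 1.0 - self.survival(dose)

    def dose_for_effect(self, fa: float) -> float:
        return self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def loewe_survival(model_a: AgentModel, model_b: AgentModel, d1: float, d2: float,
                   tol: float = 1e-10) -> float:
    """Combined survival under Loewe additivity at doses (d1, d2).

    Solves d1/Dx1(fa) + d2/Dx2(fa) = 1 for fa by bracketed root-finding; the
    left side is strictly decreasing in fa, so the root is unique.
    """
    if d1 == 0 and d2 == 0:
        return 1.0
    if d2 == 0:
        return model_a.survival(d1)
    if d1 == 0:
        return model_b.survival(d2)

    def isobole(fa: float) -> float:
        return d1 / model_a.dose_for_effect(fa) + d2 / model_b.dose_for_effect(fa) - 1.0

    lo, hi = 1e-12, 1.0 - 1e-12
    try:
        fa = brentq(isobole, lo, hi, xtol=tol, rtol=8.881784197001252e-16)
    except ValueError as err:
        raise RuntimeError(f"Loewe root-solve failed at dose pair ({d1}, {d2})") from err
    return 1.0 - fa


def combo_survival(model_a: AgentModel, model_b: AgentModel, d1: float, d2: float,
                   interaction_model: str = "bliss", psi: float = 1.0) -> float:
    """Noise-free expected combined survival under the chosen interaction model."""
    s_a, s_b = model_a.survival(d1), model_b.survival(d2)
    if d1 == 0 or d2 == 0:
        return s_a * s_b  # at most one factor differs from 1
    if interaction_model == "bliss":
        return s_a * s_b
    if interaction_model == "factor":
        return float(np.clip(psi * s_a * s_b, 0.0, 1.0))
    if interaction_model == "loewe":
        return loewe_survival(model_a, model_b, d1, d2)
    raise ValueError(f"unknown interaction model {interaction_model!r}")


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _wells(compound_id: str, conditions, n_replicates: int, noise_cv: float,
           rng: np.random.Generator) -> pd.DataFrame:
    """Expand (dose_a, dose_b, expected survival) conditions into noisy wells."""
    rows = []
    for dose_a, dose_b, s in conditions:
        factors = _noise_factors(rng, noise_cv, n_replicates)
        for rep in range(1, n_replicates + 1):
            rows.append((compound_id, dose_a, dose_b, rep, CONTROL_LEVEL * s * factors[rep - 1]))
    return pd.DataFrame(rows, columns=RAW_COLUMNS)


def simulate_single_agent(model: AgentModel, doses, noise_cv: float = 0.0,
                          n_replicates: int = 3, seed=0,
                          compound_id: str = "agent") -> pd.DataFrame:
    """Raw readings for one agent over a dose series (dose 0 = control wells)."""
    rng = np.random.default_rng(seed)
    conditions = [(float(d), 0.0, model.survival(d)) for d in doses]
    return _wells(compound_id, conditions, n_replicates, noise_cv, rng)


def simulate_combination(model_a: AgentModel, model_b: AgentModel,
                         dose_pairs, interaction_model: str = "bliss",
                         psi: float = 1.0, noise_cv: float = 0.0,
                         n_replicates: int = 3, seed=0,
                         compound_id: str = "combo") -> pd.DataFrame:
    """Raw readings at arbitrary dose pairs (singles and controls included
    whenever a dose is 0)."""
    rng = np.random.default_rng(seed)
    conditions = [
        (float(d1), float(d2),
         combo_survival(model_a, model_b, float(d1), float(d2), interaction_model, psi))
        for d1, d2 in dose_pairs
    ]
    return _wells(compound_id, conditions, n_replicates, noise_cv, rng)


def checkerboard_pairs(doses_a, doses_b):
    """Full factorial dose grid, (0, 0) first."""
    return [(a, b) for a in doses_a for b in doses_b]


@dataclass(frozen=True)
class SyntheticScreenSpec:
    """Ground-truth description of a simulated combination screen.

    ``class_mix`` gives the proportion of compounds per interaction class
    (strong / medium / none / antagonist); each compound draws its interaction
    factor psi uniformly from the class range in ``psi_ranges``.  Compound
    potencies Dm are log-uniform on ``dm_range`` (nM) and slopes m uniform on
    ``m_range``; the anchor drug is fixed at ``anchor_model``.
    """

    n_compounds: int = 100
    interaction_model: str = "factor"
    class_mix: dict = field(default_factory=lambda: {"strong": 0.25, "medium": 0.25,
                                                     "none": 0.4, "antagonist": 0.1})
    psi_ranges: dict = field(default_factory=lambda: dict(CLASS_PSI_RANGES))
    noise_cv: float = 0.05
    n_replicates: int = 3
    dm_range: tuple = (100.0, 50000.0)
    m_range: tuple = (0.8, 2.5)
    anchor_model: AgentModel = AgentModel(*DEFAULT_ANCHOR_MODEL_PARAMS)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScreenSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "anchor_model" in raw:
            raw["anchor_model"] = AgentModel(**raw["anchor_model"])
        for key in ("dm_range", "m_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "psi_ranges" in raw:
            raw["psi_ranges"] = {k: tuple(v) for k, v in raw["psi_ranges"].items()}
        return cls(**raw)


def _assign_classes(n: int, mix: dict) -> list[str]:
    """Greedy largest-deficit apportionment of compounds to classes.

    Compound i's class depends only on i and the mix (never on n), so growing
    the library never reassigns existing compounds; every prefix stays within
    one compound of exact proportionality.
    """
    order = list(mix)
    counts = {c: 0 for c in order}
    classes = []
    for i in range(n):
        deficits = {c: mix[c] * (i + 1) - counts[c] for c in order}
        chosen = max(order, key=lambda c: deficits[c])
        counts[chosen] += 1
        classes.append(chosen)
    return classes


def _compound_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_library(spec: SyntheticScreenSpec):
    """Generate primary tables, secondary tables and the ground-truth table.

    Returns
    -------
    primary : DataFrame of raw readings
        Per compound: vehicle controls, anchor alone, compound alone at 1 and
        10 uM, and both combinations, in ``n_replicates``.
    secondary : DataFrame of raw readings
        Per compound: the full anchor x compound checkerboard in triplicate.
    ground_truth : DataFrame
        compound_id, class, psi, Dm, m.
    """
    classes = _assign_classes(spec.n_compounds, spec.class_mix)
    primary_parts, secondary_parts, truth_rows = [], [], []
    lo, hi = np.log(spec.dm_range[0]), np.log(spec.dm_range[1])
    for i in range(spec.n_compounds):
        rng = _compound_rng(spec.seed, i)
        cls = classes[i]
        p_lo, p_hi = spec.psi_ranges[cls]
        psi = float(rng.uniform(p_lo, p_hi))
        model = AgentModel(float(np.exp(rng.uniform(lo, hi))),
                           float(rng.uniform(*spec.m_range)))
        cid = f"C{i:04d}"
        truth_rows.append((cid, cls, psi, model.Dm, model.m))

        primary_pairs = [(0.0, 0.0), (0.0, PRIMARY_ANCHOR_DOSE)]
        for d in PRIMARY_COMPOUND_DOSES:
            primary_pairs += [(d, 0.0), (d, PRIMARY_ANCHOR_DOSE)]
        primary_parts.append(simulate_combination(
            model, spec.anchor_model, primary_pairs, spec.interaction_model, psi,
            spec.noise_cv, spec.n_replicates, seed=rng, compound_id=cid))

        pairs = checkerboard_pairs(SECONDARY_COMPOUND_DOSES, SECONDARY_ANCHOR_DOSES)
        secondary_parts.append(simulate_combination(
            model, spec.anchor_model, pairs, spec.interaction_model, psi,
            spec.noise_cv, spec.n_replicates, seed=rng, compound_id=cid))

    primary = pd.concat(primary_parts, ignore_index=True)
    secondary = pd.concat(secondary_parts, ignore_index=True)
    ground_truth = pd.DataFrame(truth_rows,
                                columns=["compound_id", "class", "psi", "Dm", "m"])
    return primary, secondary, ground_truth


def simulate_tumor_growth(effect_a: float, effect_b: float, psi: float = 1.0,
                          days=(0, 4, 7, 10, 13, 16, 19, 22), noise_cv: float = 0.0,
                          n_per_group: int = 5, growth_rate: float = 0.15,
                          v0: float = 50.0, seed=0) -> pd.DataFrame:
    """Four-arm xenograft experiment with multiplicative treatment effects.

    Control tumors grow exponentially from ``v0`` mm^3 (the treatment-start
    size) at ``growth_rate`` per day; each drug scales the mean volume by its
    effect in (0, 1], and the combination by effect_a * effect_b * psi, so the
    fractional-product R on group means recovers psi exactly at zero noise.
    Caliper dimensions are back-computed as equal sides of (2V)^(1/3) so that
    volume = (length x width x height) / 2 holds exactly.
    """
    if not (0 < effect_a <= 1 and 0 < effect_b <= 1):
        raise ValueError("drug effects must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    effects = {"control": 1.0, "drug_a": effect_a, "drug_b": effect_b,
               "combination": effect_a * effect_b * psi}
    rows = []
    for day in sorted(days):
        base = v0 * np.exp(growth_rate * day)
        for group, eff in effects.items():
            vols = base * eff * _noise_factors(rng, noise_cv, n_per_group)
            for v in vols:
                side = (2.0 * v) ** (1.0 / 3.0)
                rows.append((group, int(day), side, side, side))
    return pd.DataFrame(rows, columns=["group", "day", "length_mm", "width_mm", "height_mm"])
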