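"""Two-stage hit-calling cascade of the combination screen.

Stage 1 (primary): every library compound is tested at two single doses (1 and
10 uM) alone and combined with a fixed anchor dose (200 nM JQ1).  Compounds
killing >= 90% of cells on their own (and >= 80% in combination) are set aside
as cytotoxic-alone; the rest qualify as potential hits when the combination
kills more than 80% of cells AND the fractional-product R is below 0.7.

Stage 2 (secondary): qualifying compounds are re-tested on a full anchor-dose
x compound-dose checkerboard.  R is computed at every strictly positive dose
pair whose Bliss-expected survival clears a floor (near the kill floor R is a
ratio of assay noise), and the compound-level R is the minimum admissible R —
the "best synergy" the pair achieves — classified with the standard cuts.

The packaged hit table lists the 33 compounds reported to show strong synergy
with JQ1 in the BE(2)-C neuroblastoma screen this package models (NSC id, R,
mode-of-action codes, name).  Mode codes: M anti-microtubule, Q quinone, IC
DNA intercalator, PI proteasome inhibitor, ION ionophore, HDACI histone
deacetylase inhibitor, ND not determined.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .synergy import SynergyThresholds, classify_R, fractional_product_R

HIT_TABLE_RESOURCE = "jq1_strong_synergy_hits.tsv"
HIT_TABLE_SHA256 = "0b5ea6cfb516e4d13b7f3fb04f386f3a6cd88d2071f4ff0cc9e1434443cf4898"
MODE_CODES = frozenset({"M", "Q", "IC", "PI", "ION", "HDACI", "ND"})

# well-known approved oncology drugs among the packaged hits (NSC ids);
# used to report the top approved hit, overridable by the caller
FDA_APPROVED_NSC = frozenset({67574, 628503, 49842, 608210, 3053, 681239, 754143})

PRIMARY_CATEGORIES = ("cytotoxic_alone", "potential_hit", "non_hit", "unevaluable")


def _survival_lookup(group: pd.DataFrame) -> dict:
    return {
        (row.dose_a_nM, row.dose_b_nM): row.survival
        for row in group.itertuples()
    }


def primary_screen(records: pd.DataFrame,
                   thresholds: SynergyThresholds = SynergyThresholds()) -> pd.DataFrame:
    """Triage every compound at the primary-screen doses.

    ``records`` is a normalized viability table; each compound needs the
    anchor-alone condition (dose_a = 0, dose_b > 0), at least one
    compound-alone condition (dose_a > 0, dose_b = 0) and the matching
    combination.  A compound qualifying at either compound dose advances with
    its better (lower) R; compounds with missing arms are flagged
    ``unevaluable``, never dropped.

    Returns one row per compound: category, qualifying dose, percent reduction
    alone and in combination, and the primary R.
    """
    combo_gate = 100.0 * thresholds.combined_kill_gate
    alone_gate = 100.0 * thresholds.cytotoxic_alone_gate
    rows = []
    for cid, group in records.groupby("compound_id", sort=True):
        surv = _survival_lookup(group)
        anchor = sorted(b for a, b in surv if a == 0 and b > 0)
        per_dose = []
        for dose in sorted(a for a, b in surv if a > 0 and b == 0):
            for b in anchor:
                if (dose, b) not in surv:
                    continue
                s_alone, s_anchor, s_combo = surv[(dose, 0.0)], surv[(0.0, b)], surv[(dose, b)]
                red_alone = 100.0 * (1.0 - s_alone)
                red_combo = 100.0 * (1.0 - s_combo)
                res = fractional_product_R(s_combo, s_alone, s_anchor, thresholds, dose, b)
                if red_alone >= alone_gate and red_combo >= combo_gate:
                    category = "cytotoxic_alone"
                elif res.defined and res.R < thresholds.synergy_cut and red_combo > combo_gate:
                    category = "potential_hit"
                else:
                    category = "non_hit"
                per_dose.append((category, dose, red_alone, red_combo, res.R))
        if not per_dose:
            rows.append((cid, "unevaluable", np.nan, np.nan, np.nan, np.nan))
            continue
        # advancing to the secondary screen is the most informative outcome
        for category in ("potential_hit", "cytotoxic_alone", "non_hit"):
            matches = [d for d in per_dose if d[0] == category]
            if matches:
                best = min(matches, key=lambda d: (d[4] if np.isfinite(d[4]) else np.inf))
                rows.append((cid, category, best[1], best[2], best[3], best[4]))
                break
    return pd.DataFrame(rows, columns=["compound_id", "category", "dose_a_nM",
                                       "reduction_alone", "reduction_combo", "R_primary"])


def secondary_screen(records: pd.DataFrame,
                     thresholds: SynergyThresholds = SynergyThresholds()):
    """Score each compound on its full dose checkerboard.

    R is computed at every strictly positive dose pair; pairs whose
    Bliss-expected survival falls below ``thresholds.expected_survival_floor``
    are kept in the matrix but marked inadmissible.  The compound-level R is
    the minimum over admissible pairs, recorded with its argmin dose pair.

    Returns
    -------
    r_matrix : DataFrame
        compound_id, dose_a_nM, dose_b_nM, s_combo, expected, R, admissible.
    summary : DataFrame
        compound_id, R, dose_a_nM, dose_b_nM, label, n_admissible (label is
        None and R NaN for unevaluable compounds).
    """
    matrix_rows, summary_rows = [], []
    for cid, group in records.groupby("compound_id", sort=True):
        surv = _survival_lookup(group)
        singles_a = {a: s for (a, b), s in surv.items() if a > 0 and b == 0}
        singles_b = {b: s for (a, b), s in surv.items() if a == 0 and b > 0}
        best = None
        n_admissible = 0
        for (a, b), s_combo in sorted(surv.items()):
            if a == 0 or b == 0 or a not in singles_a or b not in singles_b:
                continue
            expected = singles_a[a] * singles_b[b]
            R = s_combo / expected if expected > 0 else np.nan
            admissible = expected >= thresholds.expected_survival_floor
            matrix_rows.append((cid, a, b, s_combo, expected, R, admissible))
            if admissible:
                n_admissible += 1
                if best is None or R < best[0]:
                    best = (R, a, b)
        if best is None:
            summary_rows.append((cid, np.nan, np.nan, np.nan, None, 0))
        else:
            summary_rows.append((cid, best[0], best[1], best[2],
                                 classify_R(best[0], thresholds), n_admissible))
    r_matrix = pd.DataFrame(matrix_rows, columns=["compound_id", "dose_a_nM", "dose_b_nM",
                                                  "s_combo", "expected", "R", "admissible"])
    summary = pd.DataFrame(summary_rows, columns=["compound_id", "R", "dose_a_nM",
                                                  "dose_b_nM", "label", "n_admissible"])
    return r_matrix, summary


def load_hit_table() -> pd.DataFrame:
    """Load the packaged 33-compound strong-synergy hit table.

    The file is checksum-verified; modes are parsed into frozensets of codes
    from the fixed vocabulary.
    """
    ref = resources.files("synerscreen.data").joinpath(HIT_TABLE_RESOURCE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != HIT_TABLE_SHA256:
        raise RuntimeError(
            f"hit-table checksum mismatch: {digest} != {HIT_TABLE_SHA256}")
    df = pd.read_csv(ref.open("r", encoding="utf-8"), sep="\t")
    df["mode"] = df["mode"].map(lambda s: frozenset(s.split(";")))
    unknown = set().union(*df["mode"]) - MODE_CODES
    if unknown:
        raise RuntimeError(f"unknown mode codes in hit table: {sorted(unknown)}")
    return df


def summarize_hits(hits: pd.DataFrame,
                   thresholds: SynergyThresholds = SynergyThresholds(),
                   fda_approved=FDA_APPROVED_NSC) -> dict:
    """Classify and group a hit table.

    Returns a dict with the total count, counts per synergy label, counts per
    mode group (anti-microtubule M; quinone-containing Q; quinone DNA
    intercalators Q&IC), the list ranked ascending by R, and the top (lowest
    R) approved-drug entry if any id in ``fda_approved`` is present.
    """
    if hits.empty:
        raise ValueError("hit table is empty")
    df = hits.copy()
    df["label"] = df["R"].map(lambda r: classify_R(r, thresholds))
    ranked = df.sort_values(["R", "nsc_id"], kind="mergesort").reset_index(drop=True)
    approved = ranked[ranked["nsc_id"].isin(fda_approved)]
    return {
        "n_hits": int(len(df)),
        "label_counts": df["label"].value_counts().to_dict(),
        "mode_group_counts": {
            "anti_microtubule": int(df["mode"].map(lambda m: "M" in m).sum()),
            "quinone_containing": int(df["mode"].map(lambda m: "Q" in m).sum()),
            "quinone_intercalator": int(
                df["mode"].map(lambda m: {"Q", "IC"} <= m).sum()),
        },
        "ranked": ranked,
        "top_fda_approved": None if approved.empty else approved.iloc[0].to_dict(),
    }


def hits_report(summary: dict) -> str:
    """Deterministic plain-text report of a summarize_hits result."""
    lines = [
        "Hit summary",
        "=" * 48,
        f"compounds: {summary['n_hits']}",
        "labels:",
    ]
    for label in ("strong_synergy", "synergy", "non_synergy", "antagonism"):
        if label in summary["label_counts"]:
            lines.append(f"  {label:<16} {summary['label_counts'][label]}")
    groups = summary["mode_group_counts"]
    lines += [
        "mode groups:",
        f"  anti-microtubule (M)        {groups['anti_microtubule']}",
        f"  quinone-containing (Q)      {groups['quinone_containing']}",
        f"  quinone intercalator (Q&IC) {groups['quinone_intercalator']}",
        "top compounds by R:",
    ]
    for row in summary["ranked"].head(5).itertuples(index=False):
        lines.append(f"  NSC {row.nsc_id:<8} R={row.R:<7g} {row.name}")
    top = summary["top_fda_approved"]
    if top is not None:
        lines.append(f"top approved drug: NSC {top['nsc_id']} (R={top['R']:g}) {top['name']}")
    return "\n".join(lines) + "\n"
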