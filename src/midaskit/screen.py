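"""Scoring of multiwell variant screens.

The pipeline mirrors how arrayed reporter screens are read out:

1. each well's raw signal is corrected for transfection/expression with a
   co-expressed reference reporter (``expression_normalize``);
2. responses are expressed relative to the vehicle control as fold change
   or percent increase (``normalize_response``);
3. site × substitution activity matrices are summarized into per-site
   mutational tolerance (mean and sum of activity relative to wild type);
4. substrate-specificity preferences are computed from per-substrate
   activities relative to the parent, after censoring any variant below a
   fraction (default 25 %) of parent activity on any substrate;
5. dose-response curves are fit with the four-parameter logistic
   ("log(agonist/inhibitor) vs response, variable slope") model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ScoreMatrix",
    "SpecificityResult",
    "DoseResponseFit",
    "normalize_response",
    "expression_normalize",
    "screen_table",
    "activity_matrix",
    "tolerance_scores",
    "specificity_matrix",
    "four_parameter_logistic",
    "fit_dose_response",
]

SCREEN_COLUMNS = [
    "plate", "well", "variant", "site", "substitution",
    "condition", "concentration", "signal", "reference_signal", "role",
]


def normalize_response(signal, control_signal, mode: str = "fold"):
    """Response relative to the vehicle control.

    ``fold`` = s/s₀; ``percent-increase`` = (s/s₀ − 1) × 100. The two modes
    are mutually consistent: percent-increase = (fold − 1) × 100.
    """
    s = np.asarray(signal, dtype=float)
    s0 = np.asarray(control_signal, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("control signal must be positive")
    fold = s / s0
    if mode == "fold":
        out = fold
    elif mode == "percent-increase":
        out = (fold - 1.0) * 100.0
    else:
        raise ValueError("mode must be 'fold' or 'percent-increase'")
    return float(out) if out.ndim == 0 else out


def expression_normalize(signal, reference_signal):
    """Activity per unit of expression: signal / co-expressed reference.

    Removes per-well transfection-efficiency differences, since both
    reporters are translated from the same transfected product.
    """
    s = np.asarray(signal, dtype=float)
    ref = np.asarray(reference_signal, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference signal must be positive")
    out = s / ref
    return float(out) if out.ndim == 0 else out


def screen_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy screen table (one row per well measurement)."""
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    if (df["signal"] < 0).any():
        raise ValueError("signals must be nonnegative")
    for cond, grp in df.groupby("condition"):
        if "vehicle" not in set(grp["role"]) and "parent" not in set(grp["role"]):
            raise ValueError(f"condition {cond!r} has no control wells")
    return df


def activity_matrix(
    table: pd.DataFrame, condition: str | None = None, relative_to_parent: bool = True
) -> pd.DataFrame:
    """site × substitution matrix of expression-normalized activities.

    Technical replicates are averaged after per-well expression
    normalization. With ``relative_to_parent`` the matrix is scaled by the
    parent (wild-type construct) activity measured under the same condition.
    """
    df = table if condition is None else table[table["condition"] == condition]
    df = df.copy()
    df["activity"] = expression_normalize(df["signal"], df["reference_signal"])
    samples = df[df["role"] == "sample"]
    mat = samples.pivot_table(
        index="site", columns="substitution", values="activity", aggfunc="mean"
    )
    if relative_to_parent:
        parent = df[df["role"] == "parent"]["activity"]
        if parent.empty:
            raise ValueError("no parent control wells in table")
        mat = mat / parent.mean()
    return mat


@dataclass
class ScoreMatrix:
    """A site × substitution grid of scores plus a congruent censor mask."""

    values: pd.DataFrame
    censored: pd.DataFrame | None = None
    substrate: str | None = None

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if not self.values.index.equals(self.censored.index) or not (
            self.values.columns.equals(self.censored.columns)
        ):
            raise ValueError("censor mask not congruent with score grid")

    def masked(self) -> pd.DataFrame:
        return self.values.mask(self.censored)


def tolerance_scores(
    matrix: pd.DataFrame,
    wt_activity: float = 1.0,
    include_wt_cell: bool = True,
    wt_substitution: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-site mutational tolerance: mean and sum of activity / wild type.

    With all 20 substitutions present the mean is sum/20. The wild-type
    identity cell is included by default (it appears in saturation arrays as
    the identity payload); pass ``include_wt_cell=False`` with a site→wt-aa
    mapping to exclude it. Missing cells are allowed and counted in ``n``.
    """
    rel = matrix / wt_activity
    if not include_wt_cell:
        if wt_substitution is None:
            raise ValueError("excluding the wild-type cell requires site→aa mapping")
        rel = rel.copy()
        for site, aa in dict(wt_substitution).items():
            if site in rel.index and aa in rel.columns:
                rel.loc[site, aa] = np.nan
    out = pd.DataFrame(
        {
            "mean": rel.mean(axis=1, skipna=True),
            "sum": rel.sum(axis=1, skipna=True),
            "n": rel.notna().sum(axis=1),
        }
    )
    if (out["n"] < rel.shape[1]).any():
        warnings.warn("some sites are missing substitutions; see the 'n' column")
    return out


@dataclass
class SpecificityResult:
    """Substrate-preference scores with censoring.

    ``relative``   substrate → site×substitution activity / parent
    ``censored``   True where activity < threshold × parent on ANY substrate
    ``preference`` (X, Y) → ratio (or difference) of relative activities
    ``preferred``  site×substitution label of the substrate a variant
                   prefers over every other (NaN if none or censored)
    """

    relative: dict[str, pd.DataFrame]
    censored: pd.DataFrame
    preference: dict[tuple[str, str], pd.DataFrame]
    preferred: pd.DataFrame
    threshold: float
    stat: str


def specificity_matrix(
    activities: dict[str, pd.DataFrame],
    parent: dict[str, float],
    censor_threshold: float = 0.25,
    stat: str = "ratio",
    call_threshold: float | None = None,
) -> SpecificityResult:
    """Substrate-specificity scores from per-substrate activity matrices.

    A variant is censored when its activity is strictly below
    ``censor_threshold`` × parent on any substrate (low-signal wells have
    high coefficients of variation, so their ratios are unreliable). For
    uncensored variants, preference of X over Y is the ratio (default) or
    difference of parent-relative activities; a variant *prefers* X when its
    preference over every other substrate exceeds ``call_threshold``
    (default 1 for ratios, 0 for differences — raise it above the assay
    noise to suppress chance calls among equivalent variants).
    """
    if stat not in ("ratio", "difference"):
        raise ValueError("stat must be 'ratio' or 'difference'")
    subs = sorted(activities)
    if len(subs) < 2:
        raise ValueError("at least two substrates required")
    first = activities[subs[0]]
    for s in subs[1:]:
        if not activities[s].index.equals(first.index) or not (
            activities[s].columns.equals(first.columns)
        ):
            raise ValueError("activity matrices not congruent across substrates")
    for s in subs:
        if parent[s] <= 0:
            raise ValueError(f"parent activity for {s!r} must be positive")
    rel = {s: activities[s] / parent[s] for s in subs}
    censored = pd.DataFrame(False, index=first.index, columns=first.columns)
    for s in subs:
        censored |= rel[s] < censor_threshold
    pref: dict[tuple[str, str], pd.DataFrame] = {}
    for x in subs:
        for y in subs:
            if x == y:
                continue
            pref[(x, y)] = (rel[x] / rel[y]) if stat == "ratio" else (rel[x] - rel[y])
    cut = (
        call_threshold
        if call_threshold is not None
        else (1.0 if stat == "ratio" else 0.0)
    )
    preferred = pd.DataFrame(np.nan, index=first.index, columns=first.columns, dtype=object)
    for x in subs:
        wins = ~censored
        for y in subs:
            if y != x:
                wins &= pref[(x, y)] > cut
        preferred = preferred.mask(wins, x)
    return SpecificityResult(rel, censored, pref, preferred, censor_threshold, stat)


# ---------------------------------------------------------------------------
# Dose-response fitting
# ---------------------------------------------------------------------------


def four_parameter_logistic(dose, bottom, top, ec50, hill):
    """Variable-slope 4PL on log dose:
    y = bottom + (top − bottom) / (1 + 10^((log10 EC50 − log10 dose) · hill))."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** ((np.log10(ec50) - np.log10(dose)) * hill)
    )


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    r_squared: float
    converged: bool
    message: str = ""

    def predict(self, dose):
        return four_parameter_logistic(dose, self.bottom, self.top, self.ec50, self.hill)


def fit_dose_response(
    doses, responses, hill_bounds: tuple[float, float] = (-10.0, 10.0)
) -> DoseResponseFit:
    """Least-squares 4PL fit.

    Needs ≥ 4 positive dose levels spanning the transition. Initialization:
    bottom/top from the response extremes, EC50 at the dose nearest the
    half-range crossing, hill = 1; EC50 bounded three decades beyond the
    sampled dose range. Non-convergence is reported in the result, never
    silently swallowed.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses differ in shape")
    if np.any(d <= 0):
        raise ValueError("doses must be positive (vehicle wells are handled upstream)")
    if len(np.unique(d)) < 4:
        raise ValueError("at least 4 distinct dose levels required")
    lo, hi = float(np.min(y)), float(np.max(y))
    half = (lo + hi) / 2.0
    ec0 = float(d[np.argmin(np.abs(y - half))])
    span = hi - lo if hi > lo else 1.0
    p0 = [lo, hi, ec0, 1.0]
    bounds = (
        [lo - span, lo - span, d.min() / 1e3, hill_bounds[0]],
        [hi + span, hi + span, d.max() * 1e3, hill_bounds[1]],
    )
    try:
        popt, _ = curve_fit(
            four_parameter_logistic, d, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as err:
        return DoseResponseFit(*p0, r_squared=np.nan, converged=False, message=str(err))
    resid = y - four_parameter_logistic(d, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return DoseResponseFit(*map(float, popt), r_squared=r2, converged=True)
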