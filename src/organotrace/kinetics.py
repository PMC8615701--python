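"""Kinetic and dose-response curve fitting.

Two nonlinear families cover every readout in this package:

* a symmetric four-parameter logistic **in time**, used to extract the
  half-transition time t\\ :sub:`1/2` of nuclear androgen-receptor (AR)
  translocation and of taxane-induced tubulin stabilization::

      v(t) = baseline + (plateau - baseline) / (1 + exp(-(t - t50) / slope))

* a four-parameter logistic **in dose** (4PL), the standard viability
  dose-response model::

      r(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill)

Groups of per-experiment t1/2 values are compared with pairwise unpaired
two-tailed Welch t-tests; Bonferroni correction is applied when more than
one pairwise comparison is made.  Whole dose-response curves are compared
with the extra-sum-of-squares F-test (one shared 4PL versus two separate
4PLs), the procedure commercial curve-fitting software applies for the
same question.

A fitted time-course only yields a meaningful t1/2 when the transition
actually completes inside the observation window; otherwise the fitted
plateau is an extrapolation.  ``SigmoidFit.plateau_reached`` encodes this:
when it is ``False``, ``t_half`` is ``None`` ("not attained") rather than
a number.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger("organotrace")

__all__ = [
    "logistic_time",
    "four_param_logistic",
    "SigmoidFit",
    "FourPLFit",
    "GroupComparison",
    "CurveComparison",
    "fit_sigmoid_time",
    "compare_t_half",
    "normalize_to_vehicle",
    "fit_4pl",
    "compare_dose_curves",
]


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def logistic_time(t, baseline, plateau, t50, slope):
    """Symmetric logistic transition in time; half-transition at ``t50``."""
    t = np.asarray(t, dtype=float)
    return baseline + (plateau - baseline) * special.expit((t - t50) / slope)


def four_param_logistic(dose, top, bottom, ec50, hill):
    """4PL dose-response: ``top`` at dose 0, ``bottom`` at saturating dose.

    ``hill > 0`` gives a monotonically decreasing curve (viability under an
    inhibitor); the midpoint r(ec50) = (top + bottom) / 2 holds exactly.
    """
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ec50, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


def _logistic_log_ec50(dose, top, bottom, log_ec50, hill):
    return four_param_logistic(dose, top, bottom, math.exp(log_ec50), hill)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    """Least-squares fit of a logistic time-course."""

    baseline: float
    plateau: float
    t50_h: float
    slope_h: float
    converged: bool
    plateau_reached: bool
    rss: float
    n_points: int

    @property
    def t_half(self) -> float | None:
        """t1/2 of the transition, or ``None`` when not attained."""
        if self.converged and self.plateau_reached:
            return float(self.t50_h)
        return None

    @property
    def t_half_label(self) -> str:
        t = self.t_half
        return "not attained" if t is None else f"{t:.3f}"


@dataclass
class FourPLFit:
    """Least-squares fit of a 4PL dose-response curve."""

    top: float
    bottom: float
    ec50: float
    hill: float
    rss: float
    n_points: int
    converged: bool
    warning: bool = False
    ci95_ec50: tuple[float, float] | None = None


@dataclass
class GroupComparison:
    """One pairwise Welch t-test with Bonferroni-adjusted p-value."""

    group_a: str
    group_b: str
    statistic: float
    raw_p: float
    adjusted_p: float
    m_tests: int
    method: str = "unpaired two-tailed Welch t-test"


@dataclass
class CurveComparison:
    """Extra-sum-of-squares F-test between two 4PL datasets."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    rss_shared: float
    rss_separate: float
    fit_a: FourPLFit = field(repr=False, default=None)
    fit_b: FourPLFit = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# time-course fitting
# ---------------------------------------------------------------------------

def fit_sigmoid_time(
    times_h: Sequence[float],
    values: Sequence[float],
    plateau_fraction: float = 0.9,
    range_margin: float = 0.2,
) -> SigmoidFit:
    """Fit the logistic time model and report t1/2.

    Parameters
    ----------
    times_h, values:
        Observed time-course; at least 5 strictly increasing time points.
    plateau_fraction:
        The transition counts as complete when the last observed value has
        covered this fraction of the fitted rise.
    range_margin:
        The fitted plateau must additionally lie within the observed value
        range extended by this fraction of the observed amplitude,
        otherwise the plateau (and hence t1/2) is an extrapolation.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size != v.size:
        raise ValueError("times_h and values must be 1-D and equal length")
    if t.size < 5:
        raise ValueError("need at least 5 time points to fit a sigmoid")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times_h must be strictly increasing")

    n = t.size
    vmin, vmax = float(v.min()), float(v.max())
    amp = vmax - vmin
    if np.var(v) < 1e-10:
        return SigmoidFit(vmin, vmax, math.nan, math.nan, False, False,
                          float(np.sum((v - v.mean()) ** 2)), n)

    span = float(t[-1] - t[0])
    # half-crossing time as t50 init
    half = vmin + 0.5 * amp
    above = np.nonzero(v >= half)[0]
    t50_0 = float(t[above[0]]) if above.size else float(t[n // 2])
    p0 = [vmin, vmax, t50_0, max(span / 10.0, 1e-3)]
    lb = [vmin - amp, vmin - amp, t[0] - span, 1e-4]
    ub = [vmax + amp, vmax + 2 * amp, t[-1] + span, 10.0 * span]
    try:
        popt, _ = optimize.curve_fit(
            logistic_time, t, v, p0=p0, bounds=(lb, ub), maxfev=20000
        )
    except (RuntimeError, ValueError):
        return SigmoidFit(vmin, vmax, math.nan, math.nan, False, False,
                          math.nan, n)

    baseline, plateau, t50, slope = (float(x) for x in popt)
    rss = float(np.sum((v - logistic_time(t, *popt)) ** 2))
    rise = plateau - baseline
    reached = bool(
        abs(rise) > 0
        and (v[-1] - baseline) >= plateau_fraction * rise
        and (vmin - range_margin * amp) <= plateau <= (vmax + range_margin * amp)
    )
    if not reached:
        logger.info("sigmoid fit: plateau not reached within observation window")
    return SigmoidFit(baseline, plateau, t50, slope, True, reached, rss, n)


def compare_t_half(
    groups: Mapping[str, Sequence[float]],
    m_tests: int | None = None,
) -> list[GroupComparison]:
    """Pairwise Welch t-tests on per-experiment t1/2 values.

    Each group must contain at least two independent replicates (the
    replication unit is the experiment: technical-replicate t1/2 values are
    averaged per experiment before they enter here).  Bonferroni adjustment
    uses ``m_tests`` (default: the number of pairs actually compared).
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
    pairs = list(itertools.combinations(names, 2))
    m = int(m_tests) if m_tests is not None else len(pairs)
    out = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        res = stats.ttest_ind(xa, xb, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):  # zero within-group variance
            same = math.isclose(xa.mean(), xb.mean(), rel_tol=0, abs_tol=1e-12)
            stat, p = (0.0, 1.0) if same else (math.inf, 0.0)
        out.append(GroupComparison(a, b, stat, p, min(1.0, m * p), m))
    return out


# ---------------------------------------------------------------------------
# dose-response fitting
# ---------------------------------------------------------------------------

def normalize_to_vehicle(table: pd.DataFrame) -> pd.DataFrame:
    """Express viability as percent of the mean vehicle (dose 0) response.

    Expects columns ``dose`` and ``response``; returns a copy with a
    ``viability_pct`` column.
    """
    vehicle = table.loc[table["dose"] == 0, "response"]
    if vehicle.empty:
        raise ValueError("no vehicle (dose == 0) wells to normalize against")
    ref = float(vehicle.mean())
    if ref <= 0:
        raise ValueError("vehicle mean response must be positive")
    out = table.copy()
    out["viability_pct"] = out["response"] / ref * 100.0
    return out


def _fit_4pl_core(doses: np.ndarray, responses: np.ndarray,
                  weighting: str = "relative"):
    """4PL least squares; ``weighting='relative'`` scales residuals by the
    predicted response (floored at 1% of the maximum), the standard choice
    for luminescence-type readouts whose noise is proportional to signal.
    The returned rss is on the (possibly weighted) residual scale.
    """
    top0 = float(np.max(responses))
    bot0 = float(np.min(responses))
    pos = doses[doses > 0]
    log_ec50_0 = float(np.mean(np.log(pos)))
    p0 = [top0, bot0, log_ec50_0, 1.0]
    amp = max(top0 - bot0, 1e-9)
    lb = [bot0 - amp, bot0 - amp, np.log(pos.min()) - 10, 1e-3]
    ub = [top0 + amp, top0 + amp, np.log(pos.max()) + 10, 50.0]
    popt, pcov = optimize.curve_fit(
        _logistic_log_ec50, doses, responses, p0=p0, bounds=(lb, ub),
        maxfev=20000,
    )
    if weighting == "relative":
        pred = _logistic_log_ec50(doses, *popt)
        floor = 0.01 * float(np.max(np.abs(responses))) or 1e-12
        sigma = np.maximum(np.abs(pred), floor)
        popt, pcov = optimize.curve_fit(
            _logistic_log_ec50, doses, responses, p0=popt,
            bounds=(lb, ub), sigma=sigma, maxfev=20000,
        )
        resid = (responses - _logistic_log_ec50(doses, *popt)) / sigma
    elif weighting == "none":
        resid = responses - _logistic_log_ec50(doses, *popt)
    else:
        raise ValueError("weighting must be 'relative' or 'none'")
    return popt, pcov, float(np.sum(resid**2))


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    n_boot: int = 0,
    seed: int | None = None,
    weighting: str = "relative",
) -> FourPLFit:
    """Fit a 4PL dose-response curve by least squares.

    ``doses`` may include vehicle wells at dose 0 (they pin the top
    asymptote).  Responses are expected vehicle-normalized (percent).  The
    EC50 is fitted on a log scale for numerical stability.  When ``n_boot``
    > 0 a nonparametric case bootstrap (seeded) produces a 95% CI for the
    EC50.  A fit without detectable dose dependence (the Hill-slope 95% CI
    spans zero effect, or a negligible fitted amplitude) is returned with
    ``warning=True`` rather than raising.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.size != r.size:
        raise ValueError("doses and responses must have equal length")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    if np.unique(d[d > 0]).size < 4:
        raise ValueError("need >= 4 distinct non-zero doses")

    try:
        popt, pcov, rss = _fit_4pl_core(d, r, weighting)
    except (RuntimeError, ValueError):
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                         d.size, converged=False, warning=True)
    top, bottom, log_ec50, hill = (float(x) for x in popt)
    ec50 = math.exp(log_ec50)

    warning = False
    amp = abs(top - bottom)
    resid_raw = r - _logistic_log_ec50(d, *popt)
    resid_sd = math.sqrt(float(np.sum(resid_raw**2)) / max(d.size - 4, 1))
    if amp < 2.0 * resid_sd:
        warning = True  # no resolvable dose dependence
    else:
        se_hill = math.sqrt(max(pcov[3, 3], 0.0)) if np.all(np.isfinite(pcov)) else math.inf
        if 1.96 * se_hill >= hill:
            warning = True
    if warning:
        logger.warning("4PL fit shows no reliable dose dependence; "
                       "EC50 estimate is unreliable")

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = []
        idx = np.arange(d.size)
        for _ in range(n_boot):
            take = rng.choice(idx, size=idx.size, replace=True)
            if np.unique(d[take][d[take] > 0]).size < 4:
                continue
            try:
                p_b, _, _ = _fit_4pl_core(d[take], r[take], weighting)
                boot.append(math.exp(p_b[2]))
            except (RuntimeError, ValueError):
                continue
        if len(boot) >= max(20, n_boot // 5):
            ci = tuple(float(q) for q in np.percentile(boot, [2.5, 97.5]))

    return FourPLFit(top, bottom, ec50, hill, rss, d.size,
                     converged=True, warning=warning, ci95_ec50=ci)


def compare_dose_curves(
    doses_a: Sequence[float],
    responses_a: Sequence[float],
    doses_b: Sequence[float],
    responses_b: Sequence[float],
    weighting: str = "relative",
) -> CurveComparison:
    """Extra-sum-of-squares F-test: one shared 4PL versus two separate 4PLs.

    The null model fits a single 4PL to the pooled data (4 parameters); the
    alternative fits each dataset its own 4PL (8 parameters).  Under the
    null of identical curves, F = ((RSS0 - RSS1)/4) / (RSS1/(n - 8)) follows
    an F(4, n-8) distribution.
    """
    da = np.asarray(doses_a, dtype=float)
    ra = np.asarray(responses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    rb = np.asarray(responses_b, dtype=float)

    fit_a = fit_4pl(da, ra, weighting=weighting)
    fit_b = fit_4pl(db, rb, weighting=weighting)
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both individual 4PL fits must converge")

    pooled_d = np.concatenate([da, db])
    pooled_r = np.concatenate([ra, rb])
    try:
        _, _, rss_shared = _fit_4pl_core(pooled_d, pooled_r, weighting)
    except (RuntimeError, ValueError) as exc:
        raise ValueError("shared 4PL fit failed") from exc

    rss_sep = fit_a.rss + fit_b.rss
    n = pooled_d.size
    df_num, df_den = 4, n - 8
    if df_den <= 0:
        raise ValueError("too few points for the extra-sum-of-squares test")
    # guard against tiny negative differences from optimizer tolerance
    f_stat = max(rss_shared - rss_sep, 0.0) / df_num / (rss_sep / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return CurveComparison(float(f_stat), df_num, df_den, p,
                           float(rss_shared), float(rss_sep), fit_a, fit_b)
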