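"""Dwell-time survival kinetics and group statistics.

Dwell times (consecutive frames a molecule stays detected) are summarized
as frame-wise survival curves S(t) = P(dwell >= t) and fitted with the
one-phase decay model

    Y(t) = (Y0 - plateau) * exp(-K * t) + plateau,   T1/2 = ln(2) / K.

Rapidly diffusing molecules yield sub-frame half-lives (the continuous
decay fitted to discrete survival), stably bound molecules decay at the
photobleaching-limited rate, and the two regimes differ by more than an
order of magnitude.  Fits across experimental groups are compared with the
extra-sum-of-squares F-test (null: one parameter set explains all data),
with Bonferroni correction across comparisons; cohort scalars (velocity,
run length, event frequency) are compared with Student's t-test, one-way
ANOVA with post-hoc Tukey, or pairwise Fisher exact tests for counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class FitError(RuntimeError):
    """One-phase decay fit failed (non-convergence or K <= 0)."""


@dataclass
class SurvivalCurve:
    """Frame-wise survival of dwell durations: S(t) = #{d >= t} / N."""

    t: np.ndarray
    s: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.s = np.asarray(self.s, float)
        if (np.diff(self.s) > 1e-12).any():
            raise ValueError("survival must be non-increasing")
        if ((self.s < -1e-12) | (self.s > 1 + 1e-12)).any():
            raise ValueError("survival values must lie in [0, 1]")


@dataclass
class DecayFit:
    """One-phase decay parameters with the half-life and its 95% CI."""

    y0: float
    plateau: float
    k: float
    t_half: float
    ci95: tuple[float, float]
    ss_residual: float
    df: int
    converged: bool
    k_se: float = float("nan")

    def __post_init__(self) -> None:
        # T1/2 and K are redundant by definition; keep them consistent.
        assert abs(self.t_half * self.k - np.log(2.0)) < 1e-9 * max(1.0, abs(np.log(2.0)))


@dataclass
class FTestResult:
    """Extra-sum-of-squares F-test between shared and per-group fits."""

    f: float
    df_num: int
    df_den: int
    p: float
    p_adjusted: float
    hypothesis: str = "one curve fits all data"


# ---------------------------------------------------------------------------
# dwell times and survival
# ---------------------------------------------------------------------------


def dwell_times(tracks) -> np.ndarray:
    """Dwell durations (frames) from tracks: length of each contiguous
    visible span.  Gaps split a track into separate dwells.

    Accepts objects with ``frames`` (and optionally ``visible``) arrays, or
    a truth-table DataFrame with molecule_id/frame/visible columns.
    """
    durations: list[int] = []
    if isinstance(tracks, pd.DataFrame):
        items = [
            (grp["frame"].to_numpy(), grp.get("visible", pd.Series(np.ones(len(grp)))).to_numpy())
            for _, grp in tracks.groupby("molecule_id")
        ]
    else:
        items = [
            (np.asarray(tr.frames), np.asarray(getattr(tr, "visible", np.ones(len(tr.frames), bool))))
            for tr in tracks
        ]
    for frames, visible in items:
        vis_frames = frames[visible.astype(bool)]
        if len(vis_frames) == 0:
            continue
        splits = np.flatnonzero(np.diff(vis_frames) > 1)
        for span in np.split(vis_frames, splits + 1):
            durations.append(len(span))
    return np.asarray(durations, int)


def survival_curve(durations: np.ndarray) -> SurvivalCurve:
    """Survival S(t) = #{d >= t}/N for integer t = 1..max(d)."""
    d = np.asarray(durations, int)
    if len(d) == 0:
        raise ValueError("need at least one dwell")
    tmax = int(d.max())
    t = np.arange(1, tmax + 1)
    s = (d[None, :] >= t[:, None]).mean(axis=1)
    return SurvivalCurve(t=t.astype(float), s=s, n=len(d))


# ---------------------------------------------------------------------------
# one-phase decay fitting
# ---------------------------------------------------------------------------


def _decay(t, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * t) + plateau


def _init_k(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Log-linear regression of positive values for (Y0, K) starting points."""
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0 = max(-slope, 1e-6)
        y00 = float(np.exp(intercept))
    else:
        k0 = 1.0 / max(t.mean(), 1e-6)
        y00 = float(y.max()) if len(y) else 1.0
    return y00, k0


def fit_one_phase_decay(
    curve: SurvivalCurve | tuple[np.ndarray, np.ndarray],
    fix_plateau_zero: bool = True,
    weights: np.ndarray | None = None,
) -> DecayFit:
    """Fit Y(t) = (Y0 - plateau) exp(-K t) + plateau by nonlinear least
    squares (Levenberg–Marquardt).

    K is initialized from a log-linear regression of the positive values.
    The plateau is fixed at 0 by default (every molecule eventually
    disappears); pass ``fix_plateau_zero=False`` for the free-plateau
    variant.  The 95% CI of T1/2 is obtained by transforming the asymptotic
    CI of K (t-distribution quantile on the residual degrees of freedom) —
    monotonicity of ln2/K makes the transform exact.  Unweighted least
    squares is the default; ``weights`` (per-point sigma) are optional.
    """
    if isinstance(curve, SurvivalCurve):
        t, y = curve.t, curve.s
    else:
        t, y = np.asarray(curve[0], float), np.asarray(curve[1], float)
    n_params = 2 if fix_plateau_zero else 3
    if len(t) < n_params + 1:
        raise FitError(f"need at least {n_params + 1} points for a {n_params}-parameter fit")
    y00, k0 = _init_k(t, y)
    sigma = None if weights is None else np.asarray(weights, float)
    try:
        if fix_plateau_zero:
            popt, pcov = optimize.curve_fit(
                lambda tt, y0, k: _decay(tt, y0, 0.0, k),
                t,
                y,
                p0=[y00, k0],
                sigma=sigma,
                maxfev=10000,
            )
            y0_hat, k_hat = popt
            plateau_hat = 0.0
            k_var = pcov[1, 1]
        else:
            popt, pcov = optimize.curve_fit(
                _decay, t, y, p0=[y00, min(y.min(), 0.0), k0], sigma=sigma, maxfev=10000
            )
            y0_hat, plateau_hat, k_hat = popt
            k_var = pcov[2, 2]
    except RuntimeError as e:
        raise FitError(f"one-phase decay fit did not converge: {e}") from e
    if k_hat <= 0:
        raise FitError("fitted rate constant K <= 0")
    resid = y - _decay(t, y0_hat, plateau_hat, k_hat)
    ss = float(resid @ resid)
    df = len(t) - n_params
    k_se = float(np.sqrt(k_var)) if np.isfinite(k_var) else float("nan")
    tq = stats.t.ppf(0.975, df) if df > 0 else np.nan
    k_lo = k_hat - tq * k_se
    k_hi = k_hat + tq * k_se
    ln2 = np.log(2.0)
    ci = (ln2 / k_hi if k_hi > 0 else 0.0, ln2 / k_lo if k_lo > 0 else np.inf)
    return DecayFit(
        y0=float(y0_hat),
        plateau=float(plateau_hat),
        k=float(k_hat),
        t_half=float(ln2 / k_hat),
        ci95=(float(ci[0]), float(ci[1])),
        ss_residual=ss,
        df=df,
        converged=True,
        k_se=k_se,
    )


def fit_dwell_survival(
    durations: np.ndarray,
    fix_plateau_zero: bool = True,
    ci_method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int | None = None,
) -> DecayFit:
    """Fit the one-phase decay to the survival curve of dwell durations.

    For survival curves the points are cumulative fractions of the same
    molecules and hence strongly correlated, so the asymptotic
    (curve-covariance) CI of the plain fit is far too narrow; with access
    to the underlying durations, the default here is a percentile bootstrap
    over dwell resamples, which calibrates correctly.  ``ci_method``
    'asymptotic' keeps the plain curve-fit CI.
    """
    d = np.asarray(durations, int)
    fit = fit_one_phase_decay(survival_curve(d), fix_plateau_zero=fix_plateau_zero)
    if ci_method == "bootstrap":
        ci = bootstrap_t_half_ci(
            d, n_boot=n_boot, seed=seed, fix_plateau_zero=fix_plateau_zero
        )
        lo = min(ci[0], fit.t_half)
        hi = max(ci[1], fit.t_half)
        fit = DecayFit(
            y0=fit.y0,
            plateau=fit.plateau,
            k=fit.k,
            t_half=fit.t_half,
            ci95=(float(lo), float(hi)),
            ss_residual=fit.ss_residual,
            df=fit.df,
            converged=fit.converged,
            k_se=fit.k_se,
        )
    elif ci_method != "asymptotic":
        raise ValueError("ci_method must be 'bootstrap' or 'asymptotic'")
    return fit


def bootstrap_t_half_ci(
    durations: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    fix_plateau_zero: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for T1/2 (useful when the asymptotic CI
    is unreliable, e.g. slow decays observed over few events)."""
    rng = np.random.default_rng(seed)
    d = np.asarray(durations, int)
    vals = []
    for _ in range(n_boot):
        res = rng.choice(d, size=len(d), replace=True)
        try:
            vals.append(
                fit_one_phase_decay(survival_curve(res), fix_plateau_zero=fix_plateau_zero).t_half
            )
        except FitError:
            continue
    return tuple(np.percentile(vals, [2.5, 97.5]))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def compare_decays_f_test(
    curves_by_group: dict[str, SurvivalCurve | tuple],
    fix_plateau_zero: bool = True,
    m_comparisons: int = 1,
) -> FTestResult:
    """Extra-sum-of-squares F-test: does one decay explain all groups?

    Fits (a) a single shared parameter set to the pooled points and (b)
    separate parameter sets per group;
    F = [(SS_shared - SS_sep)/(df_shared - df_sep)] / (SS_sep/df_sep), with
    the p value from the F distribution and Bonferroni adjustment
    p_adjusted = min(1, m * p).
    """
    if len(curves_by_group) < 2:
        raise ValueError("need at least 2 groups")

    def as_xy(c):
        if isinstance(c, SurvivalCurve):
            return c.t, c.s
        return np.asarray(c[0], float), np.asarray(c[1], float)

    n_params = 2 if fix_plateau_zero else 3
    ss_sep = 0.0
    n_total = 0
    for c in curves_by_group.values():
        t, y = as_xy(c)
        fit = fit_one_phase_decay((t, y), fix_plateau_zero=fix_plateau_zero)
        ss_sep += fit.ss_residual
        n_total += len(t)
    t_all = np.concatenate([as_xy(c)[0] for c in curves_by_group.values()])
    y_all = np.concatenate([as_xy(c)[1] for c in curves_by_group.values()])
    fit_shared = fit_one_phase_decay((t_all, y_all), fix_plateau_zero=fix_plateau_zero)
    ss_shared = fit_shared.ss_residual
    df_shared = n_total - n_params
    df_sep = n_total - n_params * len(curves_by_group)
    if df_sep <= 0:
        raise ValueError("not enough points for per-group fits")
    df_num = df_shared - df_sep
    if ss_sep == 0.0:
        # perfect separate fits: no evidence against sharing unless the
        # shared fit has residual error
        f = 0.0 if ss_shared <= 1e-300 else np.inf
    else:
        f = max(0.0, (ss_shared - ss_sep) / df_num / (ss_sep / df_sep))
    p = float(stats.f.sf(f, df_num, df_sep))
    return FTestResult(
        f=float(f),
        df_num=df_num,
        df_den=df_sep,
        p=p,
        p_adjusted=min(1.0, m_comparisons * p),
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def group_compare(
    values,
    groups,
    method: str = "t",
    m: int = 1,
) -> pd.DataFrame:
    """Compare groups of scalar measurements or counts.

    method 't': two-sided Student's t-test (exactly 2 groups).
    method 'anova_tukey': one-way ANOVA, then post-hoc Tukey HSD pairwise.
    method 'fisher_pairwise': pairwise Fisher exact tests on 2-column count
    rows (values must then be a dict group -> (successes, failures)).
    Bonferroni adjustment by ``m`` (and additionally by the number of
    pairwise tests for the pairwise methods).
    """
    if method == "fisher_pairwise":
        if not isinstance(values, dict):
            raise ValueError("fisher_pairwise expects dict group -> (successes, failures)")
        pairs = list(itertools.combinations(values.keys(), 2))
        n_tests = m * len(pairs) if m > 1 else len(pairs)
        rows = []
        for a, b in pairs:
            odds, p = stats.fisher_exact([list(values[a]), list(values[b])])
            rows.append(
                {
                    "comparison": f"{a} vs {b}",
                    "statistic": odds,
                    "p": p,
                    "p_adjusted": min(1.0, n_tests * p),
                    "method": "fisher_exact",
                }
            )
        return pd.DataFrame(rows)

    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    samples = {g: values[groups == g] for g in names}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if method == "t":
        if len(names) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        a, b = names
        res = stats.ttest_ind(samples[a], samples[b])
        return pd.DataFrame(
            [
                {
                    "comparison": f"{a} vs {b}",
                    "statistic": float(res.statistic),
                    "p": float(res.pvalue),
                    "p_adjusted": min(1.0, m * float(res.pvalue)),
                    "method": "t",
                }
            ]
        )
    if method == "anova_tukey":
        fstat, p = stats.f_oneway(*[samples[g] for g in names])
        rows = [
            {
                "comparison": "ANOVA",
                "statistic": float(fstat),
                "p": float(p),
                "p_adjusted": min(1.0, m * float(p)),
                "method": "anova",
            }
        ]
        tk = stats.tukey_hsd(*[samples[g] for g in names])
        for i, j in itertools.combinations(range(len(names)), 2):
            rows.append(
                {
                    "comparison": f"{names[i]} vs {names[j]}",
                    "statistic": float(tk.statistic[i, j]),
                    "p": float(tk.pvalue[i, j]),
                    "p_adjusted": min(1.0, m * float(tk.pvalue[i, j])),
                    "method": "tukey_hsd",
                }
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown method {method!r}")
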