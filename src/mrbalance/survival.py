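"""Survival statistics: Kaplan-Meier, log-rank, Cox PH, cut-point search.

The Cox model maximizes the partial likelihood by Newton-Raphson with
analytic gradient and Hessian, supporting Efron (default) and Breslow tie
handling.  The maximally selected cut-point scans every candidate threshold
in a quantile-trimmed grid and reports the one maximizing the two-group
log-rank statistic (or, in ``cox_scan`` mode, the Wald chi-square of the
dichotomized indicator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

logger = logging.getLogger(__name__)

Z975 = norm.ppf(0.975)


class SurvivalError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Cox Newton-Raphson failed to converge (e.g. monotone likelihood)."""


def _validate_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise SurvivalError("times and events must be 1-D and equal length")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise SurvivalError("times must be finite and >= 0")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise SurvivalError("events must be 0/1")
    return t, e.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance.

    ``times`` is the grid of distinct event times; ``survival`` the KM
    estimate just after each, ``at_risk``/``n_events`` the risk-set size and
    death count at each, ``variance`` the Greenwood variance.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "greenwood_var": self.variance,
            }
        )


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are still at risk for that event
    (the standard convention: censoring happens just after ties).
    """
    t, e = _validate_surv(times, events)
    if t.size == 0:
        raise SurvivalError("empty input")
    if np.all(t == 0):
        raise SurvivalError("all survival times are zero")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    event_times, d = np.unique(t[e == 1], return_counts=True)
    if event_times.size == 0:  # no events: survival identically 1
        return KMCurve(
            times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([], dtype=int),
            n_events=np.array([], dtype=int),
            variance=np.array([]),
            n=n,
        )
    at_risk = n - np.searchsorted(t, event_times, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    gw_terms = np.where(at_risk > d, d / (at_risk * np.maximum(at_risk - d, 1)), 0.0)
    variance = surv**2 * np.cumsum(gw_terms)
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        variance=variance,
        n=n,
    )


# ---------------------------------------------------------------------------
# Log-rank test (K groups)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(times, events, groups) -> LogrankResult:
    """K-group log-rank test with the hypergeometric variance estimator."""
    t, e = _validate_surv(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise SurvivalError("groups must align with times")
    labels, gidx = np.unique(g, return_inverse=True)
    k = labels.size
    if k < 2:
        raise SurvivalError("need >= 2 non-empty groups")
    counts = np.bincount(gidx, minlength=k)
    if np.any(counts == 0):
        raise SurvivalError("empty group")

    order = np.argsort(t, kind="stable")
    t, e, gidx = t[order], e[order], gidx[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return LogrankResult(
            statistic=0.0, df=k - 1, p_value=1.0,
            observed=np.zeros(k), expected=np.zeros(k),
        )
    # suffix group counts: n_at_risk per group at each sorted position
    onehot = np.zeros((t.size + 1, k))
    onehot[np.arange(t.size), gidx] = 1.0
    suffix = np.cumsum(onehot[::-1], axis=0)[::-1]
    start = np.searchsorted(t, event_times, side="left")
    n_kj = suffix[start]  # (U, k) at-risk counts per group
    n_j = n_kj.sum(axis=1)
    # death counts per (event time, group)
    ev = np.nonzero(e == 1)[0]
    tpos = np.searchsorted(event_times, t[ev])
    d_kj = np.zeros((event_times.size, k))
    np.add.at(d_kj, (tpos, gidx[ev]), 1.0)
    d_j = d_kj.sum(axis=1)

    observed = d_kj.sum(axis=0)
    frac = n_kj / n_j[:, None]
    expected = (d_j[:, None] * frac).sum(axis=0)
    c = np.where(n_j > 1, d_j * (n_j - d_j) / np.maximum(n_j - 1, 1), 0.0)
    V = np.zeros((k, k))
    V[np.diag_indices(k)] = (c[:, None] * frac).sum(axis=0)
    V -= np.einsum("u,uk,ul->kl", c, frac, frac)
    diff = (observed - expected)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    if not np.any(Vsub):
        stat = 0.0
    else:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
        stat = max(stat, 0.0)
    p = float(chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return LogrankResult(
        statistic=stat, df=k - 1, p_value=p, observed=observed, expected=expected
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Newton-Raphson fit of the Cox partial likelihood."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    converged: bool
    n_dropped: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_low": self.ci_low,
                "hr_ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "covariates": {
                name: {
                    "coef": float(b),
                    "hr": float(h),
                    "hr_ci": [float(lo), float(hi)],
                    "p": float(p),
                }
                for name, b, h, lo, hi, p in zip(
                    self.names, self.beta, self.hr, self.ci_low, self.ci_high, self.p
                )
            },
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
            "n_dropped": self.n_dropped,
        }


def _cox_ll_grad_hess(beta, t, e, X, ties):
    """Partial log-likelihood, gradient and Hessian on time-sorted data."""
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums: risk set of time t_i is {j : t_j >= t_i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev = np.nonzero(e == 1)[0]
    first = np.searchsorted(t, t[ev], side="left")  # risk-set start per event

    ll = float(eta[ev].sum())
    grad = X[ev].sum(axis=0)
    hess = np.zeros((p, p))

    # tie groups among event times
    ut, inv, d_counts = np.unique(t[ev], return_inverse=True, return_counts=True)
    singleton = d_counts[inv] == 1
    # untied events: plain Breslow terms (Efron coincides when d = 1)
    idx_s = first[singleton]
    if idx_s.size:
        s0 = S0[idx_s]
        ll -= float(np.log(s0).sum())
        r1 = S1[idx_s] / s0[:, None]
        grad -= r1.sum(axis=0)
        hess -= (
            S2[idx_s] / s0[:, None, None] - r1[:, :, None] * r1[:, None, :]
        ).sum(axis=0)

    for k in np.nonzero(d_counts > 1)[0]:
        members = ev[inv == k]
        start = int(first[inv == k][0])
        d = members.size
        s0, s1, s2 = S0[start], S1[start], S2[start]
        if ties == "breslow":
            ll -= d * np.log(s0)
            r1 = s1 / s0
            grad -= d * r1
            hess -= d * (s2 / s0 - np.outer(r1, r1))
        else:  # efron
            tw = w[members].sum()
            tw1 = wx[members].sum(axis=0)
            tw2 = wxx[members].sum(axis=0)
            for l in range(d):
                f = l / d
                a0 = s0 - f * tw
                a1 = s1 - f * tw1
                a2 = s2 - f * tw2
                ll -= np.log(a0)
                r1 = a1 / a0
                grad -= r1
                hess -= a2 / a0 - np.outer(r1, r1)
    return ll, grad, hess


def cox_fit(
    times,
    events,
    covariates,
    ties: str = "efron",
    names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Rows with any missing covariate are dropped with a logged count.
    Convergence: absolute log-likelihood change below ``tol`` within
    ``max_iter`` Newton steps (with step-halving).  Monotone likelihood
    (perfect separation) raises :class:`ConvergenceError`.
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown ties method {ties!r}")
    t, e = _validate_surv(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != t.size:
        raise SurvivalError("covariate rows must match times")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    keep = np.all(np.isfinite(X), axis=1)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("cox_fit: dropped %d rows with missing covariates", n_dropped)
        t, e, X = t[keep], e[keep], X[keep]
    if t.size == 0 or e.sum() == 0:
        raise SurvivalError("no events after missing-data removal")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        j = int(np.argmin(col_sd))
        raise SurvivalError(f"constant covariate {names[j]!r}")

    # center for numerical stability (leaves beta unchanged)
    center = X.mean(axis=0)
    Xc = X - center
    order = np.argsort(t, kind="stable")
    t, e, Xc = t[order], e[order], Xc[order]

    p = Xc.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(beta, t, e, Xc, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new = _cox_ll_grad_hess(new_beta, t, e, Xc, ties)
        halvings = 0
        while new[0] < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = _cox_ll_grad_hess(new_beta, t, e, Xc, ties)
            halvings += 1
        delta = new[0] - ll
        beta, (ll, grad, hess) = new_beta, new
        # standardized effect this large means a monotone partial likelihood
        if np.any(np.abs(beta) * Xc.std(axis=0) > 10):
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation?): "
                f"standardized |beta| exceeded 10 at iteration {it}"
            )
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - Z975 * se),
        ci_high=np.exp(beta + Z975 * se),
        p=pvals,
        loglik=float(ll),
        n=int(t.size),
        n_events=int(e.sum()),
        ties=ties,
        n_iter=it,
        converged=converged,
        n_dropped=n_dropped,
    )


def cox_score_test(times, events, covariate) -> tuple[float, float]:
    """Score (Rao) test of a single covariate at beta = 0, Breslow ties.

    Returns (chi-square statistic, p).  On tie-free data this equals the
    two-group log-rank statistic when the covariate is a group indicator.
    """
    t, e = _validate_surv(times, events)
    x = np.asarray(covariate, dtype=float)[:, None]
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    _, grad, hess = _cox_ll_grad_hess(np.zeros(1), t, e, x - x.mean(), "breslow")
    stat = float(grad[0] ** 2 / -hess[0, 0])
    return stat, float(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Maximally selected cut-point
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    threshold: float
    statistic: float
    p_value: float
    n_below: int
    n_above: int
    mode: str
    grid: np.ndarray = field(repr=False)
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "threshold": float(self.threshold),
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_below": self.n_below,
            "n_above": self.n_above,
            "mode": self.mode,
            "grid_size": int(self.grid.size),
            "grid_range": [float(self.grid.min()), float(self.grid.max())],
        }
        if self.permutation_p is not None:
            d["permutation_p"] = float(self.permutation_p)
        return d


def _scan_statistic(values, t, e, grid, mode) -> np.ndarray:
    stats = np.full(grid.size, -np.inf)
    for i, thr in enumerate(grid):
        above = values >= thr
        if above.all() or not above.any():
            continue
        if mode == "logrank":
            stats[i] = logrank_test(t, e, above.astype(int)).statistic
        else:  # cox_scan: Wald chi-square of the dichotomized indicator
            try:
                fit = cox_fit(t, e, above.astype(float), ties="efron")
            except (ConvergenceError, SurvivalError):
                continue
            stats[i] = float((fit.beta[0] / fit.se[0]) ** 2)
    return stats


def optimal_cutpoint(
    maa,
    times,
    events,
    q_low: float = 0.10,
    q_high: float = 0.90,
    mode: str = "logrank",
    n_perm: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected threshold on a continuous score.

    Scans every distinct score value within the [q_low, q_high] quantile
    range and returns the one maximizing the selected two-group statistic.
    The headline p-value is the uncorrected chi-square(1) p at the optimum;
    ``n_perm > 0`` additionally computes a permutation-adjusted p for the
    maximal statistic.
    """
    if mode not in ("logrank", "cox_scan"):
        raise SurvivalError(f"unknown cut-point mode {mode!r}")
    vals = np.asarray(maa, dtype=float)
    t, e = _validate_surv(times, events)
    if vals.size != t.size:
        raise SurvivalError("maa must align with times")
    if vals.size < 50:
        raise SurvivalError("need >= 50 subjects for cut-point search")
    lo, hi = np.quantile(vals, [q_low, q_high])
    grid = np.unique(vals[(vals >= lo) & (vals <= hi)])
    if grid.size == 0:
        raise SurvivalError("empty candidate grid")

    stats = _scan_statistic(vals, t, e, grid, mode)
    best = int(np.argmax(stats))
    if not np.isfinite(stats[best]):
        raise SurvivalError("no admissible threshold in the grid")
    thr = float(grid[best])
    n_above = int(np.sum(vals >= thr))
    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(vals)
            pstats = _scan_statistic(perm, t, e, grid, mode)
            if np.max(pstats) >= stats[best]:
                exceed += 1
        perm_p = (exceed + 1) / (n_perm + 1)
    return CutpointResult(
        threshold=thr,
        statistic=float(stats[best]),
        p_value=float(chi2.sf(stats[best], 1)),
        n_below=int(vals.size - n_above),
        n_above=n_above,
        mode=mode,
        grid=grid,
        permutation_p=perm_p,
    )


# ---------------------------------------------------------------------------
# Stage-stratified analysis
# ---------------------------------------------------------------------------

FINE_STAGES = ("I", "II", "IIIA", "IIIB", "IV")


def _stage_dummies(stages: pd.Series) -> pd.DataFrame:
    """Multivariate design dummies: reference I; IIIA/IIIB pooled to III."""
    pooled = stages.replace({"IIIA": "III", "IIIB": "III"})
    out = pd.DataFrame(index=stages.index)
    for s in ("II", "III", "IV"):
        out[f"stage_{s}"] = (pooled == s).astype(float)
    out[pooled.isna()] = np.nan
    return out


def stage_stratified_analysis(
    maa,
    clinical: pd.DataFrame,
    endpoint: str = "os",
    ties: str = "efron",
    min_events: int = 10,
) -> dict:
    """Per-stage univariate Cox fits plus one adjusted multivariate fit.

    The univariate block uses fine-grained stages (IIIA and IIIB separate);
    the multivariate design uses MAA, sex, stage dummies (reference I,
    IIIA/IIIB pooled to III), age and pack-years.  Stage categories with
    fewer than ``min_events`` events are skipped with a warning.
    """
    df = clinical.reset_index(drop=True).copy()
    df["maa"] = np.asarray(maa, dtype=float)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in df.columns or ecol not in df.columns:
        raise SurvivalError(f"clinical table lacks {tcol}/{ecol}")
    df = df[df[tcol].notna() & df[ecol].notna() & (df[tcol] > 0)]

    out: dict = {"endpoint": endpoint, "univariate_by_stage": {}, "multivariate": None}
    if "stage" in df.columns:
        for stage in FINE_STAGES:
            sub = df[df["stage"] == stage]
            if sub.empty:
                continue
            n_ev = int(sub[ecol].sum())
            if n_ev < min_events:
                logger.warning(
                    "stage %s skipped: %d events < %d", stage, n_ev, min_events
                )
                out["univariate_by_stage"][stage] = {"skipped": True, "n_events": n_ev}
                continue
            fit = cox_fit(
                sub[tcol], sub[ecol], sub[["maa"]].to_numpy(), ties=ties, names=["maa"]
            )
            out["univariate_by_stage"][stage] = fit.to_dict()

    covs = {"maa": df["maa"].to_numpy(dtype=float)}
    if "sex" in df.columns:
        sex = df["sex"].map(lambda s: {"M": 1.0, "F": 0.0}.get(str(s).upper(), np.nan))
        covs["sex_male"] = sex.to_numpy(dtype=float)
    if "stage" in df.columns:
        for col, v in _stage_dummies(df["stage"]).items():
            covs[col] = v.to_numpy(dtype=float)
    if "age" in df.columns:
        covs["age"] = df["age"].to_numpy(dtype=float)
    if "pack_years" in df.columns:
        covs["pack_years"] = df["pack_years"].to_numpy(dtype=float)
    X = np.column_stack(list(covs.values()))
    try:
        mfit = cox_fit(df[tcol], df[ecol], X, ties=ties, names=list(covs))
        out["multivariate"] = mfit.to_dict()
    except (SurvivalError, ConvergenceError) as exc:
        logger.warning("multivariate fit failed: %s", exc)
        out["multivariate"] = {"error": str(exc)}
    return out
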