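"""Case-control-weighted survival statistics.

Implements, from first principles: the weighted Breslow Cox partial
likelihood (Newton-Raphson with step-halving, sandwich robust variance),
the Breslow baseline hazard and covariate-profile survival curves, Harrell's
C by pairwise enumeration, a Schoenfeld-residual proportional-hazards check,
the exact two-sided Fisher test by hypergeometric enumeration, the
eigenvalue-based effective number of tests, and incidence-derived control
weights for outcome-enriched sampling designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CohortRecord, age_band_midpoint

logger = logging.getLogger("germtrace")

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more likely than the observed
    table (relative tolerance 1e-7 on the comparison).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    n1 = a + b  # row 1 margin
    k1 = a + c  # column 1 margin
    n = a + b + c + d
    if n1 == 0 or c + d == 0 or k1 == 0 or b + d == 0:
        raise ValueError("every margin of the 2x2 table must be positive")
    lo = max(0, n1 - (n - k1))
    hi = min(n1, k1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, k1, n1)
    p_obs = stats.hypergeom.pmf(a, n, k1, n1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Incidence-based control weights
# ---------------------------------------------------------------------------

@dataclass
class WeightSpec:
    """Outcome-enriched sampling design: cases weight 1, controls 1/p.

    ``p`` is the proportion of controls actually sampled out of the number
    needed for events to make up ``incidence`` of the cohort at the horizon.
    """

    n_cases: int
    n_controls_sampled: int
    incidence: float

    def __post_init__(self) -> None:
        if not 0 < self.incidence < 1:
            raise ValueError("incidence must be in (0, 1)")
        if self.n_cases <= 0 or self.n_controls_sampled <= 0:
            raise ValueError("case and control counts must be positive")

    @property
    def controls_needed(self) -> float:
        return self.n_cases * (1.0 - self.incidence) / self.incidence

    @property
    def p(self) -> float:
        return self.n_controls_sampled / self.controls_needed


def control_weight(spec: WeightSpec) -> float:
    """Weight 1/p for each control; warns when the design is over-sampled."""
    w = 1.0 / spec.p
    if w < 1.0:
        logger.warning(
            "more controls sampled (%d) than needed (%.2f): control weight %.3f < 1",
            spec.n_controls_sampled,
            spec.controls_needed,
            w,
        )
    return w


# ---------------------------------------------------------------------------
# Weighted Breslow Cox partial likelihood
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Fitted weighted Cox model (Breslow ties)."""

    covariates: list[str]
    coef: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool
    baseline_times: np.ndarray  # ascending distinct event times
    baseline_cumhaz: np.ndarray  # H0 at the reference profile
    x_reference: np.ndarray
    # retained inputs for residual diagnostics
    _times: np.ndarray = field(repr=False, default=None)
    _events: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _weights: np.ndarray = field(repr=False, default=None)

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se_robust
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "hazard_ratio": np.exp(self.coef),
                "se_robust": self.se_robust,
                "hr_ci_lo": np.exp(self.coef - 1.96 * self.se_robust),
                "hr_ci_hi": np.exp(self.coef + 1.96 * self.se_robust),
                "z": z,
                "p": p,
            }
        )


def _breslow_loglik_grad_hess(
    beta: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    want_derivatives: bool = True,
):
    """Weighted Breslow log partial likelihood and its derivatives."""
    order = np.argsort(-times, kind="stable")
    t, d, Xs, w = times[order], events[order], X[order], weights[order]
    eta = Xs @ beta
    r = w * np.exp(eta)
    S0 = np.cumsum(r)
    if want_derivatives:
        S1 = np.cumsum(r[:, None] * Xs, axis=0)
        S2 = np.cumsum(r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    p = X.shape[1]
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        ev = d[i : j + 1].astype(bool)
        if ev.any():
            w_ev = w[i : j + 1][ev]
            x_ev = Xs[i : j + 1][ev]
            eta_ev = eta[i : j + 1][ev]
            D = w_ev.sum()
            loglik += float(w_ev @ eta_ev) - D * np.log(S0[j])
            if want_derivatives:
                xbar = S1[j] / S0[j]
                grad += w_ev @ x_ev - D * xbar
                hess -= D * (S2[j] / S0[j] - np.outer(xbar, xbar))
        i = j + 1
    if want_derivatives:
        return loglik, grad, hess
    return loglik


def fit_weighted_cox(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    weights: Optional[np.ndarray] = None,
    covariate_names: Optional[list[str]] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CoxFit:
    """Maximize the weighted Breslow partial likelihood by Newton-Raphson.

    Step-halving guards each Newton step; convergence is declared when the
    max-norm of the score drops below ``tol``. The robust covariance is the
    weighted sandwich built from per-subject score residuals.
    """
    if isinstance(X, pd.DataFrame):
        covariate_names = covariate_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{i}" for i in range(p)]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be > 0")
    if events.sum() == 0:
        raise ValueError("no events: cannot fit the partial likelihood")

    beta = np.zeros(p)
    loglik, grad, hess = _breslow_loglik_grad_hess(beta, times, events, X, weights)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            variances = X.var(axis=0)
            worst = covariate_names[int(np.argmin(variances))]
            raise ValueError(f"singular Hessian; check covariate '{worst}'") from None
        # step-halving: never accept a (beyond-roundoff) likelihood decrease
        slack = 1e-10 * (1.0 + abs(loglik))
        scale = 1.0
        for _halving in range(30):
            cand = beta + scale * step
            new = _breslow_loglik_grad_hess(cand, times, events, X, weights)
            if new[0] >= loglik - slack:
                break
            scale /= 2.0
        beta = cand
        loglik, grad, hess = new
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if not converged:
        logger.warning("Cox fit did not converge; returning partial output")

    info = -hess
    cov_model = np.linalg.inv(info)
    resid = _score_residuals(beta, times, events, X, weights)
    wU = weights[:, None] * resid
    B = wU.T @ wU
    cov_robust = cov_model @ B @ cov_model

    x_ref = (weights[:, None] * X).sum(axis=0) / weights.sum()
    bl_times, bl_cumhaz = _breslow_baseline(beta, times, events, X, weights, x_ref)

    return CoxFit(
        covariates=list(covariate_names),
        coef=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        log_partial_likelihood=float(loglik),
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        baseline_times=bl_times,
        baseline_cumhaz=bl_cumhaz,
        x_reference=x_ref,
        _times=times,
        _events=events,
        _X=X,
        _weights=weights,
    )


def _risk_set_stats(beta, times, events, X, weights):
    """Per distinct event time (ascending): weighted deaths, S0, xbar."""
    order = np.argsort(-times, kind="stable")
    t, d, Xs, w = times[order], events[order], X[order], weights[order]
    r = w * np.exp(Xs @ beta)
    S0 = np.cumsum(r)
    S1 = np.cumsum(r[:, None] * Xs, axis=0)
    out_t, out_d, out_s0, out_xbar = [], [], [], []
    i, n = 0, t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        ev = d[i : j + 1].astype(bool)
        if ev.any():
            out_t.append(t[i])
            out_d.append(w[i : j + 1][ev].sum())
            out_s0.append(S0[j])
            out_xbar.append(S1[j] / S0[j])
        i = j + 1
    return (
        np.array(out_t)[::-1],
        np.array(out_d)[::-1],
        np.array(out_s0)[::-1],
        np.array(out_xbar)[::-1],
    )


def _score_residuals(beta, times, events, X, weights) -> np.ndarray:
    """Per-subject score residuals of the weighted partial likelihood."""
    ev_t, ev_d, ev_s0, ev_xbar = _risk_set_stats(beta, times, events, X, weights)
    # cumulative d/S0 and xbar*d/S0 over event times <= t
    inc0 = ev_d / ev_s0
    C0 = np.cumsum(inc0)
    C1 = np.cumsum(ev_xbar * inc0[:, None], axis=0)
    idx = np.searchsorted(ev_t, times, side="right") - 1  # last event time <= t_i
    n, p = X.shape
    U = np.zeros((n, p))
    exp_eta = np.exp(X @ beta)
    has_prior = idx >= 0
    U[has_prior] -= exp_eta[has_prior, None] * (
        X[has_prior] * C0[idx[has_prior], None] - C1[idx[has_prior]]
    )
    ev_pos = {t: k for k, t in enumerate(ev_t)}
    for i in np.flatnonzero(events):
        k = ev_pos[times[i]]
        U[i] += X[i] - ev_xbar[k]
    return U


def _breslow_baseline(beta, times, events, X, weights, x_ref):
    """Cumulative baseline hazard at the reference profile (step function)."""
    ev_t, ev_d, ev_s0, _ = _risk_set_stats(beta, times, events, X - x_ref, weights)
    return ev_t, np.cumsum(ev_d / ev_s0)


def baseline_survival(
    fit: CoxFit, covariate_profile: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Survival step function S(t | profile) from the fitted baseline.

    ``S(t|x) = exp(-H0(t) * exp(beta . (x - x_ref)))`` with H0 the weighted
    Breslow cumulative baseline hazard at the reference profile (weighted
    covariate means).
    """
    if not fit.converged:
        raise ValueError("cannot compute baseline survival from a non-converged fit")
    if covariate_profile is None:
        covariate_profile = fit.x_reference
    rel = float(np.exp(fit.coef @ (np.asarray(covariate_profile, float) - fit.x_reference)))
    surv = np.exp(-fit.baseline_cumhaz * rel)
    return fit.baseline_times, surv


def survival_at(times_grid: np.ndarray, step_times: np.ndarray, step_surv: np.ndarray) -> np.ndarray:
    """Evaluate a right-continuous survival step function on a grid."""
    idx = np.searchsorted(step_times, times_grid, side="right") - 1
    out = np.ones_like(np.asarray(times_grid, dtype=float))
    mask = idx >= 0
    out[mask] = step_surv[idx[mask]]
    return out


def prs_percentile_curves(
    fit: CoxFit,
    prs_covariate: str,
    prs_values: np.ndarray,
    percentiles: Sequence[float] = (10, 25, 50, 75, 90),
) -> pd.DataFrame:
    """Survival curves sweeping the PRS covariate over cohort percentiles,
    holding all other covariates at the reference profile."""
    j = fit.covariates.index(prs_covariate)
    rows = []
    for pct in percentiles:
        profile = fit.x_reference.copy()
        profile[j] = np.percentile(np.asarray(prs_values, float), pct)
        t, s = baseline_survival(fit, profile)
        for ti, si in zip(t, s):
            rows.append({"percentile": pct, "time": ti, "survival": si})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concordance index
# ---------------------------------------------------------------------------

def harrell_c(
    linear_predictors: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Harrell's C by direct pairwise enumeration.

    A pair is comparable when the earlier time is an event (ties in time are
    comparable only as event-vs-censored); concordant when the earlier
    subject has the higher predictor; tied predictors count half. Pair
    weights multiply.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events).astype(bool)
    n = lp.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if d.sum() == 0:
        raise ValueError("no events: no comparable pairs")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    # comparable[i, j]: i is the earlier event, j survived longer
    earlier = d[:, None] & ((t[:, None] < t[None, :]) | ((t[:, None] == t[None, :]) & ~d[None, :]))
    pair_w = w[:, None] * w[None, :]
    conc = np.where(lp[:, None] > lp[None, :], 1.0, np.where(lp[:, None] == lp[None, :], 0.5, 0.0))
    denom = float((earlier * pair_w).sum())
    if denom == 0:
        raise ValueError("no comparable pairs")
    return float((earlier * pair_w * conc).sum() / denom)


# ---------------------------------------------------------------------------
# Proportional-hazards check
# ---------------------------------------------------------------------------

def ph_assumption_check(fit: CoxFit) -> pd.DataFrame:
    """Schoenfeld-residual test: correlation with event-time rank.

    For each covariate, the residual at each event (covariate value minus
    the weighted risk-set mean) is correlated with the rank of the event
    time; a two-sided p-value tests zero correlation.
    """
    times, events, X, w = fit._times, fit._events, fit._X, fit._weights
    if events.sum() < 2:
        raise ValueError("need at least 2 events for the PH check")
    ev_t, _, _, ev_xbar = _risk_set_stats(fit.coef, times, events, X, w)
    pos = {t: k for k, t in enumerate(ev_t)}
    ev_idx = np.flatnonzero(events)
    resid = np.array([X[i] - ev_xbar[pos[times[i]]] for i in ev_idx])
    ranks = stats.rankdata([times[i] for i in ev_idx])
    rows = []
    for j, name in enumerate(fit.covariates):
        if np.ptp(resid[:, j]) == 0:
            rho, pval = 0.0, 1.0
        else:
            rho, pval = stats.pearsonr(resid[:, j], ranks)
        rows.append({"covariate": name, "rho": float(rho), "p": float(pval)})
    return pd.DataFrame(rows)


def schoenfeld_residuals(fit: CoxFit) -> pd.DataFrame:
    """Raw Schoenfeld residuals per event, for diagnostics."""
    times, events, X, w = fit._times, fit._events, fit._X, fit._weights
    ev_t, _, _, ev_xbar = _risk_set_stats(fit.coef, times, events, X, w)
    pos = {t: k for k, t in enumerate(ev_t)}
    ev_idx = np.flatnonzero(events)
    data = {"time": [times[i] for i in ev_idx]}
    for j, name in enumerate(fit.covariates):
        data[name] = [X[i, j] - ev_xbar[pos[times[i]], j] for i in ev_idx]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Effective number of tests
# ---------------------------------------------------------------------------

@dataclass
class MeffResult:
    eigenvalues: np.ndarray
    m_eff: float

    def q_values(self, p_values: Sequence[float]) -> np.ndarray:
        return np.minimum(1.0, np.asarray(p_values, dtype=float) * self.m_eff)


def li_ji_meff(score_matrix: np.ndarray | pd.DataFrame) -> MeffResult:
    """Effective number of tests from correlation-matrix eigenvalues.

    Each eigenvalue contributes I(lambda >= 1) plus its fractional part;
    negative numerical eigenvalues are clipped at zero.
    """
    M = np.asarray(score_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 score columns")
    if M.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if np.any(np.ptp(M, axis=0) == 0):
        raise ValueError("constant score column: correlation undefined")
    corr = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(np.round(lam, 10), 0.0, None)
    m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return MeffResult(eigenvalues=lam[::-1], m_eff=m_eff)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def prs_group_comparison(prs: np.ndarray, event_flags: np.ndarray) -> dict[str, object]:
    """Compare score distributions between event and non-event groups.

    Reports group means, their ratio, and a two-sided rank-based p-value
    (skipped when a group has fewer than 2 members).
    """
    prs = np.asarray(prs, dtype=float)
    flags = np.asarray(event_flags).astype(bool)
    g1, g0 = prs[flags], prs[~flags]
    if g1.size == 0 or g0.size == 0:
        raise ValueError("both groups must be non-empty")
    out: dict[str, object] = {
        "mean_event": float(g1.mean()),
        "mean_no_event": float(g0.mean()),
        "fold_change": float(g1.mean() / g0.mean()) if g0.mean() != 0 else float("nan"),
        "p_value": None,
    }
    if g1.size >= 2 and g0.size >= 2:
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
        out["p_value"] = float(res.pvalue)
    return out


# ---------------------------------------------------------------------------
# Cohort-level orchestration
# ---------------------------------------------------------------------------

def build_design(
    cohort: Sequence[CohortRecord],
    prs_name: str,
    covariates: Sequence[str] = ("grade", "size_cm", "age", "european"),
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, list[str]]:
    """Design matrix for the Cox fit; patients missing lesion size are
    excluded, the age band enters as its decade midpoint."""
    kept = [r for r in cohort if ("size_cm" not in covariates or r.size_cm is not None)]
    n_dropped = len(cohort) - len(kept)
    if n_dropped:
        logger.info("excluding %d patients missing lesion size", n_dropped)
    cols: dict[str, list[float]] = {prs_name: []}
    for name in covariates:
        cols[name] = []
    times, events, ids = [], [], []
    for r in kept:
        if prs_name not in r.prs_values:
            raise ValueError(f"patient {r.patient_id} lacks PRS '{prs_name}'")
        cols[prs_name].append(r.prs_values[prs_name])
        for name in covariates:
            if name == "grade":
                if r.grade is None:
                    raise ValueError(
                        f"patient {r.patient_id} missing grade: impute from CN burden first"
                    )
                cols[name].append(float(r.grade))
            elif name == "size_cm":
                cols[name].append(float(r.size_cm))
            elif name == "age":
                cols[name].append(age_band_midpoint(r.age_group))
            elif name == "european":
                cols[name].append(1.0 if r.european_ancestry else 0.0)
            else:
                raise ValueError(f"unknown covariate {name}")
        times.append(r.time)
        events.append(r.event)
        ids.append(r.patient_id)
    design = pd.DataFrame(cols, index=ids)
    return np.asarray(times, float), np.asarray(events, bool), design, list(design.columns)


def cohort_weights(events: np.ndarray, incidence: float) -> np.ndarray:
    """Per-subject weights: cases 1, controls 1/p for the stated incidence."""
    events = np.asarray(events).astype(bool)
    spec = WeightSpec(
        n_cases=int(events.sum()),
        n_controls_sampled=int((~events).sum()),
        incidence=incidence,
    )
    w = np.ones(events.size)
    w[~events] = control_weight(spec)
    return w
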