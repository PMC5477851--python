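"""Survival machinery built from first principles.

Implements the product-limit (Kaplan-Meier) estimator, the two-group
log-rank test, maximally-selected log-rank cut-point dichotomization of a
continuous marker, and Cox proportional-hazards regression via
Newton-Raphson maximization of the partial likelihood (Efron or Breslow
tie handling).

The maximally-selected cut-point statistic is the stratification of a
continuous marker (here, gene expression) that maximizes the two-group
log-rank chi-square over all admissible thresholds.  Because the threshold
is chosen to maximize the statistic, the naive chi-square p-value is
anti-conservative; a permutation-adjusted p-value is offered alongside it
and both are always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CutpointResult",
    "CoxFit",
    "StratifiedSurvivalResult",
    "MonotoneLikelihoodError",
    "ConvergenceError",
    "KaplanMeier",
    "MaximallySelectedCutpoint",
    "CoxPH",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "cox_fit",
    "stratified_survival_analysis",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge."""


class MonotoneLikelihoodError(ConvergenceError):
    """Partial likelihood is monotone in a coefficient (perfect separation).

    Arises when, e.g., every event in one covariate group precedes every
    event in the other: the MLE of the log hazard ratio is infinite.
    """


def _check_time_event(time, event):
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    if time.size == 0:
        raise ValueError("empty survival data")
    if time.size != event.size:
        raise ValueError("time and event must have equal length")
    if not np.all(np.isfinite(time)):
        raise ValueError("survival times must be finite")
    if np.any(time < 0):
        raise ValueError("survival times must be nonnegative")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicator must be 0/1")
    return time, ev.astype(int)


def _unpack_y(y):
    """Accept (time, event) tuples, 2-column arrays, DataFrames or structured arrays."""
    if isinstance(y, tuple) and len(y) == 2:
        return _check_time_event(y[0], y[1])
    if isinstance(y, pd.DataFrame):
        tcol = "os_months" if "os_months" in y.columns else "time"
        return _check_time_event(y[tcol].to_numpy(), y["event"].to_numpy())
    arr = np.asarray(y)
    if arr.dtype.names:
        return _check_time_event(arr["time"], arr["event"])
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise ValueError("y must be (time, event) pairs")
    return _check_time_event(arr[:, 0], arr[:, 1])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate of the survival function.

    ``survival_prob[i]`` is S(t) just after ``event_times[i]``; censored
    observations tied with an event time remain in that time's risk set.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: int
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_prob[idx - 1])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival_prob,
            }
        )


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    time, event = _check_time_event(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    at_risk = n - first
    mask = d > 0
    et, dt, nt = uniq[mask], d[mask], at_risk[mask]
    surv = np.cumprod(1.0 - dt / nt) if et.size else np.empty(0)
    return KMCurve(
        event_times=et,
        survival_prob=surv,
        n_at_risk=nt,
        n_events=dt,
        n_censored=int(n - e.sum()),
        n=n,
    )


class KaplanMeier(BaseEstimator):
    """Estimator wrapper around :func:`km_estimate`.

    ``fit(X, y)`` ignores ``X`` (pass None); ``y`` carries (time, event).
    """

    def fit(self, X=None, y=None):
        time, event = _unpack_y(y)
        self.curve_ = km_estimate(time, event)
        self.event_times_ = self.curve_.event_times
        self.survival_prob_ = self.curve_.survival_prob
        return self

    def predict(self, t):
        return np.array([self.curve_.survival_at(v) for v in np.atleast_1d(t)])


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def _logrank_scan(time, event, G):
    """Two-group log-rank chi-square for many binary groupings at once.

    Parameters
    ----------
    time, event : sorted ascending by time.
    G : (n, K) boolean matrix; column k marks membership of "group 1".

    Returns (O1, E1, V, chi2), each length K, by accumulating observed and
    expected events and the hypergeometric variance at every distinct
    event time.
    """
    n = time.size
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    uniq, first = np.unique(time, return_index=True)
    d = np.add.reduceat(event.astype(float), first)
    n_risk = (n - first).astype(float)
    # group-1 members at risk at each distinct time = total - those exited before
    csum = np.vstack([np.zeros((1, G.shape[1])), np.cumsum(G, axis=0)])
    n1 = G.sum(axis=0)[None, :] - csum[first, :]
    d1 = np.add.reduceat(event[:, None] * G, first, axis=0)
    mask = d > 0
    dd = d[mask][:, None]
    nn = n_risk[mask][:, None]
    p1 = n1[mask] / nn
    E1 = dd * p1
    with np.errstate(divide="ignore", invalid="ignore"):
        V = dd * p1 * (1.0 - p1) * (nn - dd) / np.where(nn > 1, nn - 1.0, 1.0)
    O1 = d1[mask].sum(axis=0)
    E = E1.sum(axis=0)
    Vs = V.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(Vs > 0, (O1 - E) ** 2 / Vs, 0.0)
    return O1, E, Vs, chi2


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    observed: np.ndarray   # events per group (group0, group1)
    expected: np.ndarray
    variance: float


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test: chi2 = (O1 - E1)^2 / V, p from chi2_1."""
    time, event = _check_time_event(time, event)
    group = np.asarray(group).ravel()
    if group.size != time.size:
        raise ValueError("group labels must match data length")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(
            f"log-rank test requires exactly 2 non-empty groups, got {levels.size}"
        )
    g1 = group == levels[1]
    order = np.argsort(time, kind="stable")
    O1, E1, V, chi2 = _logrank_scan(time[order], event[order], g1[order])
    total_events = float(event.sum())
    o1, e1, v, c2 = float(O1[0]), float(E1[0]), float(V[0]), float(chi2[0])
    p = float(stats.chi2.sf(c2, df=1))
    return LogRankResult(
        chi2=c2,
        df=1,
        p_value=p,
        observed=np.array([total_events - o1, o1]),
        expected=np.array([total_events - e1, e1]),
        variance=v,
    )


# ---------------------------------------------------------------------------
# Maximally-selected log-rank cut-point
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    threshold: float
    chi2_max: float
    p_naive: float
    n_low: int
    n_high: int
    scan_table: pd.DataFrame
    p_adjusted: float | None = None

    @property
    def high_mask(self):  # convenience, set by optimal_cutpoint
        return self._high_mask

    _high_mask: np.ndarray = field(default=None, repr=False, compare=False)


class MaximallySelectedCutpoint(BaseEstimator):
    """Dichotomize a continuous marker at the threshold maximizing the
    log-rank chi-square.

    Candidate thresholds are midpoints between consecutive distinct marker
    values whose induced low/high split leaves at least
    ``floor(min_group_frac * n)`` samples on each side.  Ties in the
    maximal chi-square are broken toward the smallest threshold.

    The naive p-value (chi-square with 1 df at the selected threshold) is
    anti-conservative because of the maximization; when
    ``n_permutations > 0`` a permutation-adjusted p-value is computed by
    re-running the full scan on permuted marker assignments.

    Parameters
    ----------
    min_group_frac : float in (0, 0.5), minimum fraction per side (default 0.10).
    n_permutations : int, permutations for the adjusted p (0 disables).
    random_state : seed for the permutation stream.
    """

    def __init__(self, min_group_frac: float = 0.10, n_permutations: int = 0,
                 random_state=None):
        self.min_group_frac = min_group_frac
        self.n_permutations = n_permutations
        self.random_state = random_state

    @staticmethod
    def _scan(marker, time, event, min_group_frac):
        n = marker.size
        order = np.argsort(time, kind="stable")
        t, e, m = time[order], event[order], marker[order]
        sv = np.unique(marker)
        if sv.size < 2:
            raise ValueError("constant marker: no valid split exists")
        cand = (sv[:-1] + sv[1:]) / 2.0
        n_high = (marker[None, :] > cand[:, None]).sum(axis=1)
        min_n = int(np.floor(min_group_frac * n))
        ok = (n_high >= min_n) & ((n - n_high) >= min_n)
        cand = cand[ok]
        if cand.size == 0:
            raise ValueError(
                "no candidate threshold satisfies the minimum group-size "
                f"constraint (min_group_frac={min_group_frac})"
            )
        G = m[:, None] > cand[None, :]
        _, _, _, chi2 = _logrank_scan(t, e, G)
        return cand, chi2

    def fit(self, X, y):
        marker = np.asarray(X, dtype=float).ravel()
        time, event = _unpack_y(y)
        if marker.size != time.size:
            raise ValueError("marker length must equal number of outcomes")
        if not np.all(np.isfinite(marker)):
            raise ValueError("marker values must be finite")
        if not (0.0 < self.min_group_frac < 0.5):
            raise ValueError("min_group_frac must lie in (0, 0.5)")
        cand, chi2 = self._scan(marker, time, event, self.min_group_frac)
        best = int(np.argmax(chi2))          # argmax returns first maximum:
        self.threshold_ = float(cand[best])  # smallest threshold on ties
        self.chi2_ = float(chi2[best])
        self.p_naive_ = float(stats.chi2.sf(self.chi2_, df=1))
        self.scan_table_ = pd.DataFrame({"threshold": cand, "chi2": chi2})
        high = marker > self.threshold_
        self.n_high_ = int(high.sum())
        self.n_low_ = int(marker.size - self.n_high_)
        self.p_adjusted_ = None
        if self.n_permutations:
            # Permute the marker against the (time, event) pairs and redo
            # the full maximization each time; the candidate thresholds
            # and group sizes are permutation-invariant, so the scans are
            # batched into one group matrix per chunk of permutations.
            rng = np.random.default_rng(self.random_state)
            order = np.argsort(time, kind="stable")
            t_s, e_s = time[order], event[order]
            B = int(self.n_permutations)
            exceed = 0
            for _ in range(B):
                perm = rng.permutation(marker)[order]
                G = perm[:, None] > cand[None, :]
                _, _, _, c2 = _logrank_scan(t_s, e_s, G)
                if c2.max() >= self.chi2_:
                    exceed += 1
            self.p_adjusted_ = (exceed + 1.0) / (B + 1.0)
        return self

    def predict(self, X):
        """Return the high-expression indicator for marker values X."""
        return np.asarray(X, dtype=float).ravel() > self.threshold_

    def result_(self) -> CutpointResult:
        res = CutpointResult(
            threshold=self.threshold_,
            chi2_max=self.chi2_,
            p_naive=self.p_naive_,
            n_low=self.n_low_,
            n_high=self.n_high_,
            scan_table=self.scan_table_,
            p_adjusted=self.p_adjusted_,
        )
        return res


def optimal_cutpoint(marker, time, event, min_group_frac: float = 0.10,
                     n_permutations: int = 0, seed=None) -> CutpointResult:
    """Functional wrapper over :class:`MaximallySelectedCutpoint`."""
    est = MaximallySelectedCutpoint(
        min_group_frac=min_group_frac,
        n_permutations=n_permutations,
        random_state=seed,
    ).fit(np.asarray(marker, dtype=float), (time, event))
    res = est.result_()
    res._high_mask = est.predict(marker)
    return res


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    names: list
    loglik_path: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratios,
                "HR_ci_lower": self.ci_lower,
                "HR_ci_upper": self.ci_upper,
                "p": self.p_values,
            },
            index=self.names,
        )


def _cox_blocks(X, time, event):
    """Sort descending by time and locate tied-event blocks."""
    order = np.argsort(-time, kind="stable")
    return X[order], time[order], event[order]


def _cox_ll_grad_info(beta, X, time, event, ties):
    """Partial log-likelihood, score and observed information.

    Subjects are processed in descending time order so the risk set grows
    cumulatively; at each distinct event time the Efron (or Breslow)
    tie-corrected contributions are added.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S = 0.0
    Z = np.zeros(p)
    Q = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        t_i = time[i]
        while j < n and time[j] == t_i:
            j += 1
        block = slice(i, j)
        wb = w[block]
        Xb = X[block]
        S += wb.sum()
        Z += wb @ Xb
        Q += (Xb * wb[:, None]).T @ Xb
        ev = event[block] == 1
        d = int(ev.sum())
        if d > 0:
            Xd = Xb[ev]
            wd = wb[ev]
            ll += float(eta[block][ev].sum())
            grad += Xd.sum(axis=0)
            Sd = wd.sum()
            Zd = wd @ Xd
            Qd = (Xd * wd[:, None]).T @ Xd
            for ell in range(d):
                frac = ell / d if ties == "efron" else 0.0
                phi = S - frac * Sd
                zbar = (Z - frac * Zd) / phi
                ll -= np.log(phi)
                grad -= zbar
                info += (Q - frac * Qd) / phi - np.outer(zbar, zbar)
        i = j
    return ll, grad, info


class CoxPH(BaseEstimator):
    """Cox proportional-hazards regression maximizing the partial likelihood.

    Newton-Raphson with step-halving; Efron tie correction by default
    (``ties="breslow"`` selectable).  Standard errors come from the inverse
    observed information; confidence intervals and p-values are Wald-based
    at the 95 % level.  Monotone partial likelihood (perfect separation of
    event orderings by a covariate) is detected and raised as
    :class:`MonotoneLikelihoodError`.
    """

    _BETA_BOUND = 20.0

    def __init__(self, ties: str = "efron", max_iter: int = 100,
                 tol: float = 1e-9, alpha: float = 0.05):
        self.ties = ties
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha

    def fit(self, X, y):
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        names = None
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1:
            X = X.T
        time, event = _unpack_y(y)
        n, p = X.shape
        if n != time.size:
            raise ValueError("covariate rows must match number of outcomes")
        if n <= p:
            raise ValueError(f"need n > p (got n={n}, p={p})")
        ptps = X.max(axis=0) - X.min(axis=0)
        if np.any(ptps == 0):
            bad = int(np.argmin(ptps))
            nm = names[bad] if names else f"column {bad}"
            raise ValueError(f"covariate {nm} is constant")
        if event.sum() == 0:
            raise ValueError("no events: partial likelihood is undefined")
        if names is None:
            names = [f"x{k}" for k in range(p)]

        Xs, ts, es = _cox_blocks(X, time, event)
        beta = np.zeros(p)
        ll, grad, info = _cox_ll_grad_info(beta, Xs, ts, es, self.ties)
        path = [ll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    "singular information matrix (collinear covariates?)"
                ) from exc
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_ll_grad_info(
                new_beta, Xs, ts, es, self.ties
            )
            halvings = 0
            while new_ll < ll - 1e-12 and halvings < 30:
                step = step / 2.0
                new_beta = beta + step
                new_ll, new_grad, new_info = _cox_ll_grad_info(
                    new_beta, Xs, ts, es, self.ties
                )
                halvings += 1
            delta_ll = new_ll - ll
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            path.append(ll)
            if np.linalg.norm(beta, np.inf) > self._BETA_BOUND:
                raise MonotoneLikelihoodError(
                    "coefficient diverging: the partial likelihood is "
                    "monotone (perfect separation of event orderings)"
                )
            if abs(delta_ll) < self.tol and np.linalg.norm(grad, np.inf) < 1e-5:
                converged = True
                break
        if np.linalg.norm(beta, np.inf) > self._BETA_BOUND:
            raise MonotoneLikelihoodError(
                "coefficient diverging: the partial likelihood is monotone "
                "(perfect separation of event orderings)"
            )
        if not converged:
            warnings.warn("CoxPH did not converge; results may be unreliable")

        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        z = stats.norm.ppf(1.0 - self.alpha / 2.0)
        self.coef_ = beta
        self.se_ = se
        self.hazard_ratios_ = np.exp(beta)
        self.ci_lower_ = np.exp(beta - z * se)
        self.ci_upper_ = np.exp(beta + z * se)
        self.p_values_ = 2.0 * stats.norm.sf(np.abs(beta / se))
        self.log_likelihood_ = float(ll)
        self.n_iter_ = it
        self.converged_ = converged
        self.names_ = names
        self.loglik_path_ = np.asarray(path)
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_

    def result_(self) -> CoxFit:
        return CoxFit(
            coef=self.coef_,
            se=self.se_,
            hazard_ratios=self.hazard_ratios_,
            ci_lower=self.ci_lower_,
            ci_upper=self.ci_upper_,
            p_values=self.p_values_,
            log_likelihood=self.log_likelihood_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            names=self.names_,
            loglik_path=self.loglik_path_,
        )


def cox_fit(covariates, time, event, ties: str = "efron",
            names=None) -> CoxFit:
    """Fit a Cox PH model; thin wrapper over :class:`CoxPH`."""
    X = covariates
    if names is not None and not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float)).reshape(
            len(time), -1), columns=names)
    return CoxPH(ties=ties).fit(X, (time, event)).result_()


# ---------------------------------------------------------------------------
# Stratified end-to-end analysis
# ---------------------------------------------------------------------------

_STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class StratifiedSurvivalResult:
    cutpoint: CutpointResult
    km_high: KMCurve
    km_low: KMCurve
    cox_univariate: CoxFit
    cox_multivariate: CoxFit | None
    logrank: LogRankResult
    n: int
    filters: dict


def _encode_ordinal(series: pd.Series) -> np.ndarray:
    vals = series.astype(object)
    out = np.empty(len(vals), dtype=float)
    for i, v in enumerate(vals):
        if isinstance(v, str) and v in _STAGE_CODES:
            out[i] = _STAGE_CODES[v]
        else:
            out[i] = float(v)
    return out


def stratified_survival_analysis(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    gene: str = "KIFC1",
    filters: dict | None = None,
    adjust_for: tuple = ("grade", "stage"),
    min_group_frac: float = 0.10,
    n_permutations: int = 0,
    seed=None,
) -> StratifiedSurvivalResult:
    """Dichotomize ``gene`` by its optimal survival cut-point within a
    clinically filtered cohort, and fit univariate and covariate-adjusted
    Cox models on the resulting high/low indicator.

    ``expression`` is genes x samples; ``clinical`` has one row per sample
    with columns sample_id, histotype, site, grade, stage, os_months,
    event.  ``filters`` maps clinical columns to required values, e.g.
    ``{"site": "primary", "histotype": "serous adenocarcinoma"}``.
    Grade and stage enter the multivariate model as ordinal scores.
    """
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
        else clinical
    common = [s for s in expression.columns if s in clin.index]
    clin = clin.loc[common]
    filters = dict(filters or {})
    for col, val in filters.items():
        if col not in clin.columns:
            raise KeyError(f"unknown clinical column {col!r} in filters")
        clin = clin[clin[col] == val]
    clin = clin.dropna(subset=["os_months", "event"])
    if len(clin) < 20:
        raise ValueError(
            f"filtered cohort has {len(clin)} samples (< 20); filters={filters}"
        )
    samples = list(clin.index)
    marker = expression.loc[gene, samples].to_numpy(dtype=float)
    time = clin["os_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()

    cut = optimal_cutpoint(marker, time, event,
                           min_group_frac=min_group_frac,
                           n_permutations=n_permutations, seed=seed)
    high = marker > cut.threshold
    km_high = km_estimate(time[high], event[high])
    km_low = km_estimate(time[~high], event[~high])
    lr = logrank_test(time, event, high.astype(int))

    uni = cox_fit(high.astype(float)[:, None], time, event,
                  names=[f"{gene}_high"])
    multi = None
    if adjust_for:
        cols = [high.astype(float)]
        names = [f"{gene}_high"]
        for cov in adjust_for:
            if cov not in clin.columns:
                raise KeyError(f"adjustment covariate {cov!r} not in clinical table")
            cols.append(_encode_ordinal(clin[cov]))
            names.append(cov)
        Xm = pd.DataFrame(np.column_stack(cols), columns=names)
        multi = cox_fit(Xm, time, event)
    return StratifiedSurvivalResult(
        cutpoint=cut,
        km_high=km_high,
        km_low=km_low,
        cox_univariate=uni,
        cox_multivariate=multi,
        logrank=lr,
        n=len(samples),
        filters=filters,
    )
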