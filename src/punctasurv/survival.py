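"""Right-censored survival analysis: Kaplan-Meier and Cox proportional hazards.

Deaths in this assay are observed on a 24 h imaging grid, so event times are
heavily tied; the Cox partial likelihood is therefore maximized with the
Efron tie correction (Breslow is also available and coincides exactly with
Efron when no ties are present). Estimation is Newton-Raphson from beta = 0
with step halving; the covariance estimate is the inverse observed
information at the maximum.

The estimators are written against plain (duration, event, covariate)
arrays; :func:`build_records` turns annotated tracks plus neuron-level
aggregate calls into the record table they consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError
from .imaging import Track

__all__ = [
    "KMEstimate",
    "CoxFit",
    "build_records",
    "build_design",
    "kaplan_meier",
    "cox_fit",
    "wald_test",
    "lr_test",
]

RECORD_COLUMNS = ["neuron_id", "time", "event", "group", "aggregate"]


# ---------------------------------------------------------------------------
# record construction


def build_records(
    tracks: Sequence[Track],
    neuron_calls: Mapping[int, bool],
    group_labels: Mapping[int, str] | str,
    *,
    interval_hours: float = 24.0,
    n_timepoints: int = 10,
    known_groups: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn death-annotated tracks into right-censored survival records.

    Parameters
    ----------
    tracks
        Death-annotated tracks (see :func:`punctasurv.imaging.call_death`).
    neuron_calls
        Neuron-level aggregate status by ``neuron_id``. Neurons missing here
        (e.g. no usable CV) are excluded and logged, never silently dropped.
    group_labels
        Either one group name for all tracks or a mapping ``neuron_id ->
        group``.
    known_groups
        If given, any other group label raises a ValueError.

    Returns
    -------
    (records, exclusions)
        ``records`` has columns ``RECORD_COLUMNS``; death at interval k maps
        to time = k * interval_hours with event = True, censored neurons to
        time = n_timepoints * interval_hours with event = False.
        ``exclusions`` has columns (neuron_id, reason).
    """
    rows, excluded = [], []
    for tr in tracks:
        gid = tr.neuron_id
        group = group_labels if isinstance(group_labels, str) else group_labels[gid]
        if known_groups is not None and group not in known_groups:
            raise ValueError(f"unknown group label {group!r} for neuron {gid}")
        if tr.first_timepoint != 0:
            excluded.append({"neuron_id": gid, "reason": "missing timepoint-1 ROI"})
            continue
        if tr.death_interval is None and not tr.censored:
            excluded.append({"neuron_id": gid, "reason": "death not annotated"})
            continue
        if gid not in neuron_calls:
            excluded.append({"neuron_id": gid, "reason": "no usable CV"})
            continue
        if tr.censored:
            time, event = n_timepoints * interval_hours, False
        else:
            time, event = tr.death_interval * interval_hours, True
        rows.append(
            {
                "neuron_id": gid,
                "time": float(time),
                "event": bool(event),
                "group": group,
                "aggregate": bool(neuron_calls[gid]),
            }
        )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["neuron_id", "reason"])
    return records, exclusions


def build_design(
    records: pd.DataFrame,
    covariates: Sequence[str],
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Binary design matrix for the Cox model.

    ``'group'`` expands into one indicator per non-reference group (the
    reference is explicit; by default the first group in sorted order).
    ``'aggregate'`` enters as a single 0/1 column.
    """
    cols = {}
    for cov in covariates:
        if cov == "group":
            groups = sorted(records["group"].unique())
            ref = reference_group if reference_group is not None else groups[0]
            if ref not in groups:
                raise ValueError(f"reference group {ref!r} not present")
            for g in groups:
                if g != ref:
                    cols[f"group[{g}]"] = (records["group"] == g).astype(float)
        elif cov == "aggregate":
            cols["aggregate"] = records["aggregate"].astype(float)
        elif cov in records.columns:
            cols[cov] = records[cov].astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=records.index)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate.

    ``times`` starts at 0 (S = 1); subsequent entries are the distinct event
    times with the survival probability just after each, the number at risk
    and the number of events there. Cumulative risk of death is 1 - S(t).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    @property
    def cumulative_risk(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.survival[max(i, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "cumulative_risk": self.cumulative_risk,
                "n_at_risk": self.at_risk,
                "n_events": self.events,
            }
        )


def kaplan_meier(
    durations: Sequence[float], events: Sequence[bool]
) -> KMEstimate:
    """Kaplan-Meier estimate from durations and event flags.

    Deaths and censorings at the same time follow the standard convention:
    deaths are counted against the full at-risk set at that time.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("at least one record is required")
    if t.shape != e.shape:
        raise ValueError("durations and events must be aligned")
    event_times = np.unique(t[e])
    times = [0.0]
    surv = [1.0]
    at_risk = [t.size]
    n_events = [0]
    s = 1.0
    for tau in event_times:
        n = int((t >= tau).sum())
        d = int(((t == tau) & e).sum())
        s *= 1.0 - d / n
        times.append(float(tau))
        surv.append(s)
        at_risk.append(n)
        n_events.append(d)
    return KMEstimate(
        times=np.array(times),
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        events=np.array(n_events),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    Coefficients are on the log-hazard scale; ``hazard_ratios`` = exp(beta)
    with 95% normal-approximation confidence intervals on the log scale.
    ``lr_statistic``/``lr_p`` test the model against beta = 0.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    converged: bool

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)), index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def confidence_intervals(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.se)
        hi = np.exp(self.params + z * self.se)
        return pd.DataFrame({"hr_lower": lo, "hr_upper": hi})

    @property
    def wald_z(self) -> pd.Series:
        return self.params / self.se

    @property
    def wald_p(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.wald_z.values)), index=self.params.index
        )

    @property
    def lr_statistic(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def lr_p(self) -> float:
        df = len(self.params)
        return float(stats.chi2.sf(self.lr_statistic, df)) if df else 1.0

    def summary(self) -> pd.DataFrame:
        ci = self.confidence_intervals()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "hr": self.hazard_ratios,
                "hr_lower": ci["hr_lower"],
                "hr_upper": ci["hr_upper"],
                "z": self.wald_z,
                "p": self.wald_p,
            }
        )

    def to_dict(self) -> dict:
        ci = self.confidence_intervals()
        return {
            "coef": self.params.to_dict(),
            "se": self.se.to_dict(),
            "hazard_ratio": self.hazard_ratios.to_dict(),
            "hr_ci95_lower": ci["hr_lower"].to_dict(),
            "hr_ci95_upper": ci["hr_upper"].to_dict(),
            "wald_z": self.wald_z.to_dict(),
            "wald_p": self.wald_p.to_dict(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "lr_statistic": self.lr_statistic,
            "lr_p": self.lr_p,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def cox_loglik(
    beta: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    ties: str = "efron",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Cox log partial likelihood with gradient and observed information.

    At each distinct event time tau with tied event set D (|D| = d) and risk
    set R = {i : t_i >= tau}, the Efron correction replaces the risk-set sum
    by ``S0(R) - (l/d) * S0(D)`` for l = 0..d-1; Breslow uses l/d = 0.

    Returns (loglik, gradient, information); information is the negative
    Hessian.
    """
    if ties not in {"efron", "breslow"}:
        raise ValueError("ties must be 'efron' or 'breslow'")
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # stabilize exponentials; PL is shift-invariant
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for tau in np.unique(durations[events]):
        in_risk = durations >= tau
        in_tied = (durations == tau) & events
        d = int(in_tied.sum())
        wR, XR = w[in_risk], X[in_risk]
        wD, XD = w[in_tied], X[in_tied]
        s0R = wR.sum()
        s1R = wR @ XR
        s2R = XR.T @ (wR[:, None] * XR)
        if ties == "efron" and d > 1:
            fracs = np.arange(d) / d
        else:
            fracs = np.zeros(d)
        s0D = wD.sum()
        s1D = wD @ XD
        s2D = XD.T @ (wD[:, None] * XD)
        phi = s0R - fracs * s0D  # (d,)
        m = (s1R[None, :] - fracs[:, None] * s1D[None, :]) / phi[:, None]  # (d, p)
        s2 = s2R[None] - fracs[:, None, None] * s2D[None]  # (d, p, p)
        ll += eta[in_tied].sum() - np.log(phi).sum()
        grad += X[in_tied].sum(axis=0) - m.sum(axis=0)
        info += (s2 / phi[:, None, None]).sum(axis=0) - np.einsum("li,lj->ij", m, m)
    return float(ll), grad, info


def cox_fit(
    durations: Sequence[float],
    events: Sequence[bool],
    X: pd.DataFrame | np.ndarray,
    ties: str = "efron",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson from beta = 0.

    Convergence when the score's max absolute component drops below
    ``score_tol`` or the step's norm below ``step_tol``. A monotone
    likelihood (a covariate perfectly separating events) raises
    :class:`ConvergenceError`.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    if Xv.shape[0] != t.size or t.size != e.size:
        raise ValueError("durations, events and covariates must be aligned")
    if not e.any():
        raise ValueError("Cox fit requires at least one event")
    if np.linalg.matrix_rank(Xv - Xv.mean(axis=0)) < Xv.shape[1]:
        raise ValueError("covariates are collinear (or constant)")

    beta = np.zeros(Xv.shape[1])
    ll, grad, info = cox_loglik(beta, t, e, Xv, ties)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(
                "singular information matrix (monotone likelihood?)"
            ) from err
        # step-halve until the log partial likelihood does not decrease
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, grad_new, info_new = cox_loglik(cand, t, e, Xv, ties)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError("step halving failed to improve likelihood")
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        # |beta| = 15 means a hazard ratio above 3e6: far beyond any real
        # effect, and the signature of a monotone likelihood whose score
        # decays to the tolerance before beta stops growing
        if np.abs(beta).max() > 15:
            raise ConvergenceError(
                "coefficient diverging: a covariate appears to perfectly "
                "separate events (monotone likelihood)"
            )
        if np.abs(grad).max() < score_tol or np.abs(step * delta).max() < step_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} steps")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ConvergenceError("information matrix not invertible at optimum") from err
    return CoxFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        loglik_null=ll_null,
        n=int(t.size),
        n_events=int(e.sum()),
        ties=ties,
        n_iter=it,
        converged=converged,
    )


def wald_test(fit: CoxFit) -> pd.DataFrame:
    """Per-coefficient Wald z statistics with two-sided normal p-values."""
    return pd.DataFrame({"z": fit.wald_z, "p": fit.wald_p})


def lr_test(fit_full: CoxFit, fit_null: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested null fit against a full fit.

    Returns (statistic, df, p). The null's covariates must be a subset of
    the full model's; both fits must use the same data and tie handling
    (checked via n, n_events and ties).
    """
    if not set(fit_null.params.index) <= set(fit_full.params.index):
        raise ValueError("null model covariates are not nested in the full model")
    if (fit_null.n, fit_null.n_events, fit_null.ties) != (
        fit_full.n,
        fit_full.n_events,
        fit_full.ties,
    ):
        raise ValueError("fits do not appear to share data/tie handling")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    df = len(fit_full.params) - len(fit_null.params)
    if df == 0:
        p = 1.0 if abs(stat) < 1e-10 else float(stats.chi2.sf(max(stat, 0.0), 1))
        return float(max(stat, 0.0)), 0, p
    return float(stat), df, float(stats.chi2.sf(stat, df))
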