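"""Cox proportional-hazards fits, window risks, and relative risk reduction.

The Cox model relates the hazard of the outcome to the exposure indicator
(and optional covariates) through h(t | x) = h0(t) exp(x'beta); beta is
estimated by maximizing the partial likelihood, which is free of the
baseline hazard h0. Tied event times are handled by the Breslow (default)
or Efron approximation; the two coincide when all event times are distinct.
Standard errors come from the inverse observed information, and the 95%
confidence interval for the hazard ratio is exp(beta +/- 1.959964 SE).

Follow-up windows (e.g. 5/10/20 years from the index prescription) are
imposed by administrative truncation: events after the window are censored
at the window. Window "risk" is the plain proportion of an arm with the
outcome inside the window, and the relative risk reduction is
RRR = (risk_control - risk_exposed) / risk_control = 1 - risk ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

Z95 = 1.959964


class CoxError(ValueError):
    """Non-identifiable or non-converged partial-likelihood fit."""


@dataclass
class CoxFit:
    beta: np.ndarray                # coefficient vector, arm indicator first
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    covariate_names: list[str]
    n_iter: int

    @property
    def log_hr(self) -> float:
        return float(self.beta[0])

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta[0]))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = float(np.exp(self.beta[0] - Z95 * self.se[0]))
        hi = float(np.exp(self.beta[0] + Z95 * self.se[0]))
        return lo, hi

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 1.0 or hi < 1.0


@dataclass
class RiskSummary:
    window: float
    risk_exposed: float
    risk_control: float
    n_exposed: int
    n_control: int

    @property
    def rrr(self) -> float | None:
        if self.risk_control == 0.0:
            return None
        return (self.risk_control - self.risk_exposed) / self.risk_control


def truncate_follow_up(records: pd.DataFrame, window: float,
                       time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Censor at the window: events after it become censored at the window."""
    if window <= 0:
        raise ValueError("window must be positive")
    out = records.copy()
    late = out[time_col] > window
    out.loc[late, event_col] = 0
    out.loc[late, time_col] = window
    return out


def _partial_loglik_derivs(
    times: np.ndarray, events: np.ndarray, X: np.ndarray, beta: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient, Hessian at beta (Breslow/Efron)."""
    order = np.argsort(-times, kind="stable")   # descending: risk sets are prefixes
    t, d, x = times[order], events[order], X[order]
    eta = x @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    xw = x * w[:, None]
    S0 = np.cumsum(w)
    S1 = np.cumsum(xw, axis=0)
    S2 = np.cumsum(np.einsum("ij,ik->ijk", x, xw), axis=0)

    ll = 0.0
    p = X.shape[1]
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # rows i..j-1 share the event time; risk set = rows 0..j-1
        ev = np.arange(i, j)[d[i:j] == 1]
        m = len(ev)
        if m:
            s0, s1, s2 = S0[j - 1], S1[j - 1], S2[j - 1]
            ll += float(eta[ev].sum())
            if ties == "breslow" or m == 1:
                ll -= m * np.log(s0)
                mu = s1 / s0
                grad += x[ev].sum(axis=0) - m * mu
                hess -= m * (s2 / s0 - np.outer(mu, mu))
            else:  # efron
                e0 = w[ev].sum()
                e1 = xw[ev].sum(axis=0)
                e2 = np.einsum("ij,ik->jk", x[ev], xw[ev])
                grad += x[ev].sum(axis=0)
                for l in range(m):
                    f = l / m
                    a0 = s0 - f * e0
                    a1 = s1 - f * e1
                    a2 = s2 - f * e2
                    ll -= np.log(a0)
                    mu = a1 / a0
                    grad -= mu
                    hess -= a2 / a0 - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def cox_fit(
    records: pd.DataFrame,
    ties: str = "breslow",
    covariates: Sequence[str] = (),
    time_col: str = "time",
    event_col: str = "event",
    arm_col: str = "arm",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson maximization of the Cox partial likelihood.

    The arm indicator is the first coefficient; additional covariate
    columns may be adjusted for. Requires at least one event in each arm
    (otherwise the arm likelihood is monotone and beta diverges).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    times = records[time_col].to_numpy(float)
    events = records[event_col].to_numpy(int)
    arm = records[arm_col].to_numpy(float)
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    for a in (0, 1):
        if events[arm == a].sum() == 0:
            raise CoxError(f"no events in arm {a}: log hazard ratio not identifiable")
    names = [arm_col] + list(covariates)
    X = np.column_stack([arm] + [records[c].to_numpy(float) for c in covariates])
    # center covariates for numerical stability (leaves beta unchanged)
    X = X - X.mean(axis=0)

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _partial_loglik_derivs(times, events, X, beta, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError(f"singular information matrix: {exc}") from exc
        new_beta = beta - step
        new_ll, new_grad, new_hess = _partial_loglik_derivs(times, events, X, new_beta, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step = step / 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _partial_loglik_derivs(times, events, X, new_beta, ties)
            halvings += 1
        rel = abs(new_ll - ll) / (abs(ll) + 1e-300)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if rel < tol:
            break
    else:
        raise CoxError(f"Newton-Raphson did not converge in {max_iter} iterations")
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxError(f"singular information at optimum: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
        raise CoxError("non-finite estimates (monotone likelihood?)")
    return CoxFit(
        beta=beta, se=se, loglik=float(ll), n=len(times),
        n_events=int(events.sum()), ties=ties, covariate_names=names,
        n_iter=n_iter,
    )


def window_risks(records: pd.DataFrame, window: float,
                 time_col: str = "time", event_col: str = "event",
                 arm_col: str = "arm") -> RiskSummary:
    """Proportion of each arm with the outcome inside the window.

    Denominators are arm sizes at index (no person-time adjustment).
    """
    for a in (0, 1):
        if (records[arm_col] == a).sum() == 0:
            raise ValueError(f"arm {a} is empty")
    tr = truncate_follow_up(records, window, time_col, event_col)
    exp_mask = tr[arm_col] == 1
    risk_e = float(tr.loc[exp_mask, event_col].mean())
    risk_c = float(tr.loc[~exp_mask, event_col].mean())
    return RiskSummary(
        window=window, risk_exposed=risk_e, risk_control=risk_c,
        n_exposed=int(exp_mask.sum()), n_control=int((~exp_mask).sum()),
    )


def forest_table(
    fits: Mapping[tuple[str, str, float, str], tuple[CoxFit, RiskSummary]],
) -> pd.DataFrame:
    """One row per (drug, group, window, subgroup): Ns, risks, HR, CI, flag."""
    rows = []
    for (drug, group, window, subgroup), (fit, risk) in sorted(fits.items()):
        lo, hi = fit.ci95
        rows.append({
            "drug": drug, "group": group, "window_years": window, "subgroup": subgroup,
            "n_exposed": risk.n_exposed, "n_control": risk.n_control,
            "risk_exposed": risk.risk_exposed, "risk_control": risk.risk_control,
            "HR": fit.hr, "ci_low": lo, "ci_high": hi,
            "significant": fit.significant,
        })
    return pd.DataFrame(rows)


def rrr_trend(summaries: Sequence[RiskSummary]) -> tuple[pd.DataFrame, str]:
    """RRR series ordered by window, classified by last-minus-first sign:
    'waning' (RRR falls), 'strengthening' (rises), or 'flat'."""
    if len(summaries) < 2:
        raise ValueError("need at least two windows for a trend")
    ordered = sorted(summaries, key=lambda s: s.window)
    df = pd.DataFrame(
        {"window_years": [s.window for s in ordered], "rrr": [s.rrr for s in ordered]}
    )
    first, last = df["rrr"].iloc[0], df["rrr"].iloc[-1]
    if first is None or last is None or pd.isna(first) or pd.isna(last):
        label = "undefined"
    elif last < first:
        label = "waning"
    elif last > first:
        label = "strengthening"
    else:
        label = "flat"
    return df, label
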