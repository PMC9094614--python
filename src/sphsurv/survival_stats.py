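"""Right-censored survival statistics: Cox partial likelihood, linear CoxPH,
Harrell's concordance index, Kaplan-Meier estimation and median-risk
stratification.

Model
-----
The proportional-hazards model writes the hazard of subject with covariates x
as lambda(t | x) = lambda_0(t) * exp(h(x)), where h is the log-risk.  In the
classical Cox model h(x) = beta^T x is linear; the network elsewhere in this
package replaces it with a learned h_theta(x) (the DeepSurv construction)
while keeping the same training objective: the average negative log partial
likelihood over subjects with observed events.

Conventions (fixed and documented because implementations differ):

* Ties among event times are handled with the Breslow approximation; the risk
  set of subject i includes i itself (T_j >= T_i).
* Concordance follows Harrell: a pair (i, j) is comparable when the subject
  with the shorter time has an observed event (or, at equal times, exactly
  one of the two has an event); concordant pairs score 1, tied risk scores
  0.5.  Higher score means higher risk, i.e. shorter expected survival.
* Median stratification assigns scores equal to the median to the low-risk
  group, so with distinct scores and even n the groups have equal size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalCohort",
    "KMEstimate",
    "neg_log_partial_likelihood",
    "partial_likelihood_gradient",
    "fit_linear_coxph",
    "CoxFitResult",
    "concordance_index",
    "kaplan_meier",
    "stratify_by_median",
]


@dataclass
class SurvivalCohort:
    """Per-subject right-censored records.

    time: observation time (months, > 0); event: 1 if the terminal event was
    observed at ``time``, 0 if censored; covariates: optional (n, p) matrix;
    risk: optional per-subject log-risk scores; subject_id: optional labels.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None
    risk: np.ndarray | None = None
    subject_id: np.ndarray | None = None
    covariate_names: list[str] | None = None
    true_log_risk: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        if self.event.shape != self.time.shape:
            raise ValueError("event/time length mismatch")
        if np.any(self.time <= 0):
            raise ValueError("all observation times must be > 0")
        ev = np.unique(self.event)
        if not np.all(np.isin(ev, [0, 1])):
            raise ValueError("event must be binary 0/1")
        self.event = self.event.astype(int)
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != len(self.time):
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != len(self.time):
                raise ValueError("covariate rows must match number of subjects")
        if self.subject_id is None:
            self.subject_id = np.array([f"s{i:04d}" for i in range(len(self.time))])

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalCohort":
        idx = np.asarray(idx)
        return SurvivalCohort(
            time=self.time[idx],
            event=self.event[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            risk=None if self.risk is None else np.asarray(self.risk)[idx],
            subject_id=self.subject_id[idx],
            covariate_names=self.covariate_names,
            true_log_risk=None
            if self.true_log_risk is None
            else np.asarray(self.true_log_risk)[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.subject_id, "time": self.time, "event": self.event}
        )
        if self.true_log_risk is not None:
            df["true_log_risk"] = self.true_log_risk
        if self.covariates is not None:
            names = self.covariate_names or [
                f"covariate_{i}" for i in range(self.covariates.shape[1])
            ]
            for i, name in enumerate(names):
                col = name if name.startswith("covariate_") else f"covariate_{name}"
                df[col] = self.covariates[:, i]
        if self.risk is not None:
            df["risk"] = self.risk
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalCohort":
        df = pd.read_csv(path)
        cov_cols = [c for c in df.columns if c.startswith("covariate_")]
        return cls(
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
            covariates=df[cov_cols].to_numpy() if cov_cols else None,
            risk=df["risk"].to_numpy() if "risk" in df else None,
            subject_id=df["subject_id"].to_numpy() if "subject_id" in df else None,
            covariate_names=[c[len("covariate_"):] for c in cov_cols] or None,
            true_log_risk=df["true_log_risk"].to_numpy()
            if "true_log_risk" in df
            else None,
        )


def _check_scores(h, cohort: SurvivalCohort) -> np.ndarray:
    h = np.asarray(h, dtype=float).ravel()
    if h.shape != cohort.time.shape:
        raise ValueError("scores must align with cohort subjects")
    if not np.all(np.isfinite(h)):
        raise ValueError("scores must be finite")
    return h


def neg_log_partial_likelihood(h, cohort: SurvivalCohort) -> float:
    """Average negative log Cox partial likelihood of log-risk scores ``h``.

    L = -(1/N_E) sum_{i: E_i=1} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ]

    Breslow handling of ties; stabilized log-sum-exp, safe for |h| up to
    several hundred.
    """
    h = _check_scores(h, cohort)
    if cohort.n_events == 0:
        raise ValueError("partial likelihood undefined: cohort has no events")
    order = np.argsort(-cohort.time, kind="stable")  # descending time
    hs = h[order]
    ts = cohort.time[order]
    es = cohort.event[order]
    hmax = hs.max()
    cum = np.cumsum(np.exp(hs - hmax))
    # risk set of subject i (in descending order) = prefix up to the last
    # index sharing T_i (ties all included)
    last_tied = np.searchsorted(-ts, -ts, side="right") - 1
    log_risk_sum = np.log(cum[last_tied]) + hmax
    contrib = hs - log_risk_sum
    return float(-contrib[es == 1].sum() / es.sum())


def partial_likelihood_gradient(h, cohort: SurvivalCohort) -> np.ndarray:
    """Gradient of :func:`neg_log_partial_likelihood` with respect to ``h``."""
    h = _check_scores(h, cohort)
    n = len(h)
    ne = cohort.n_events
    if ne == 0:
        raise ValueError("partial likelihood undefined: cohort has no events")
    order = np.argsort(-cohort.time, kind="stable")
    hs, ts, es = h[order], cohort.time[order], cohort.event[order]
    hmax = hs.max()
    ex = np.exp(hs - hmax)
    cum = np.cumsum(ex)
    last_tied = np.searchsorted(-ts, -ts, side="right") - 1
    denom = cum[last_tied]
    # sum over events i of (exp(h_k)/denom_i) for k in risk set of i:
    # k is in risk set of i iff position(k) <= last_tied(i); accumulate
    # per-event weights 1/denom_i into a suffix^T-style cumulative sum.
    inv = np.zeros(n)
    np.add.at(inv, last_tied[es == 1], 1.0 / denom[es == 1])
    # k receives sum of 1/denom_i over events i with last_tied(i) >= pos(k)
    carry = np.cumsum(inv[::-1])[::-1]
    grad_sorted = -(es - ex * carry) / ne
    grad = np.empty(n)
    grad[order] = grad_sorted
    return grad


@dataclass
class CoxFitResult:
    beta: np.ndarray
    loss: float
    n_iter: int
    gradient_norm: float


def fit_linear_coxph(
    cohort: SurvivalCohort,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> CoxFitResult:
    """Newton fit of the linear Cox model h(x) = beta^T x on the Breslow
    partial likelihood.  Intended as the reference/oracle fitter; raises on
    non-convergence or monotone likelihood (perfect separation)."""
    if cohort.covariates is None:
        raise ValueError("cohort has no covariates")
    X = cohort.covariates
    if cohort.n_events == 0:
        raise ValueError("cannot fit CoxPH: no events")
    n, p = X.shape
    beta = np.zeros(p)
    order = np.argsort(-cohort.time, kind="stable")
    Xs, ts, es = X[order], cohort.time[order], cohort.event[order]
    last_tied = np.searchsorted(-ts, -ts, side="right") - 1
    ev = es == 1
    ne = es.sum()
    loss = np.inf
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        emax = eta.max()
        w = np.exp(eta - emax)
        S0 = np.cumsum(w)[last_tied]
        S1 = np.cumsum(w[:, None] * Xs, axis=0)[last_tied]
        S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)[
            last_tied
        ]
        mu = S1 / S0[:, None]
        loss = float(-(eta[ev] - (np.log(S0[ev]) + emax)).sum() / ne)
        grad = -(Xs[ev] - mu[ev]).sum(axis=0) / ne
        V = S2[ev] / S0[ev, None, None] - mu[ev, :, None] * mu[ev, None, :]
        Hmat = V.sum(axis=0) / ne + ridge * np.eye(p)
        if not np.all(np.isfinite(grad)) or not np.all(np.isfinite(Hmat)):
            raise RuntimeError(
                "CoxPH fit diverged (likely monotone likelihood / separation); "
                f"iteration {it}, beta={beta}"
            )
        gnorm = np.abs(grad).max()
        if gnorm < tol:
            return CoxFitResult(beta=beta, loss=loss, n_iter=it, gradient_norm=gnorm)
        try:
            step = np.linalg.solve(Hmat, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information matrix at iteration {it}") from exc
        if np.linalg.norm(step) > 50:
            raise RuntimeError(
                "CoxPH fit not converging (huge Newton step); data may be "
                "perfectly separated or degenerate"
            )
        beta = beta - step
    raise RuntimeError(
        f"CoxPH Newton did not converge in {max_iter} iterations "
        f"(last gradient inf-norm {gnorm:.3e})"
    )


def concordance_index(h, cohort: SurvivalCohort) -> float:
    """Harrell's C-index of risk scores against right-censored outcomes.

    Comparable pairs: (i earlier) if E_i = 1 and T_i < T_j, or T_i = T_j with
    E_i = 1 and E_j = 0.  Concordant means the earlier subject has the higher
    risk score; score ties count 1/2.
    """
    h = _check_scores(h, cohort)
    T, E = cohort.time, cohort.event
    n = len(h)
    num = 0.0
    den = 0
    for i in range(n):
        if E[i] != 1:
            continue
        earlier = (T[i] < T) | ((T[i] == T) & (E == 0))
        den += int(earlier.sum())
        num += (h[i] > h[earlier]).sum() + 0.5 * (h[i] == h[earlier]).sum()
    if den == 0:
        raise ValueError("no comparable pairs: cannot compute C-index")
    return float(num / den)


@dataclass
class KMEstimate:
    """Kaplan-Meier survivor-function estimate.

    ``times`` are the distinct event times (ascending); ``survival`` the
    estimate S(t) just after each event time; ``at_risk``/``n_events`` the
    risk-set size and event count at each time.  S(0) = 1 by convention.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            out = np.ones_like(t)
            return out if out.shape else 1.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.shape else float(out)

    @property
    def median_time(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "n_risk": self.at_risk,
                "n_event": self.n_events,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def kaplan_meier(cohort: SurvivalCohort) -> KMEstimate:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i) over
    distinct event times; censored subjects leave the risk set just after
    their recorded time."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    T, E = cohort.time, cohort.event
    event_times = np.unique(T[E == 1])
    surv = []
    s = 1.0
    at_risk = []
    d_counts = []
    for t in event_times:
        n_i = int((T >= t).sum())
        d_i = int(((T == t) & (E == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    return KMEstimate(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        n_events=np.array(d_counts),
    )


def stratify_by_median(h) -> np.ndarray:
    """Split scores at their median: label array of 'low'/'high'.

    Scores equal to the median go to 'low' (deterministic tie rule), so with
    distinct scores and even n the two groups have equal size.
    """
    h = np.asarray(h, dtype=float).ravel()
    if len(h) < 2:
        raise ValueError("need at least 2 subjects to stratify")
    med = np.median(h)
    return np.where(h > med, "high", "low")
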