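"""Cell-cycle gene prognostic risk score (CMPS) and survival stratification.

A penalized (lasso) Cox proportional-hazards model is fitted on the
expression of a caller-supplied gene list, with 10-fold cross-validation
selecting the penalty that maximizes the held-out log partial likelihood
(the "minimal lambda" rule).  Fitting is delegated to the coordinate-
descent Cox-net solver of scikit-survival; this module owns the score
contract:

    CMPS_i = sum_g coef_g * expr_{i,g}

evaluated on the same per-gene standardization used during fitting (means
and scales are recorded in fit metadata and re-applied at scoring time).
Patients are split at the median score (ties to "low", the conservative
direction for a high-risk call) and the two survival curves are compared by
the standard two-group Mantel–Haenszel log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # follow-up, days
    event: int  # 1 = death observed, 0 = censored

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"time must be > 0 (patient {self.patient_id})")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1 (patient {self.patient_id})")


@dataclass
class CMPSModel:
    """Nonzero lasso-Cox coefficients plus the fitting metadata needed to
    reproduce scores (per-gene standardization, penalty, folds)."""

    cancer_type: str
    coefficients: dict[str, float]
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.coefficients:
            raise ValueError("CMPS model must have at least one nonzero coefficient")
        if any(c == 0 for c in self.coefficients.values()):
            raise ValueError("zero coefficients must not be stored")

    def to_dict(self) -> dict:
        return {
            "cancer_type": self.cancer_type,
            "coefficients": self.coefficients,
            "fit_metadata": self.fit_metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CMPSModel":
        return cls(
            cancer_type=d["cancer_type"],
            coefficients=dict(d["coefficients"]),
            fit_metadata=dict(d.get("fit_metadata", {})),
        )


def _records_to_frame(survival: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in survival],
            "event": [r.event for r in survival],
        },
        index=[r.patient_id for r in survival],
    )


def _log_partial_likelihood(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of linear predictors ``scores``."""
    order = np.argsort(time, kind="mergesort")
    s, t, e = scores[order], time[order], event[order]
    # risk set at time t_i = all with t_j >= t_i: cumulative logsumexp from
    # the back, stabilized by the global max
    m = s.max()
    csum = np.cumsum(np.exp(s[::-1] - m))
    log_risk = (m + np.log(csum))[::-1]
    # tie groups share the risk-set at the group's first index
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        if e[i:j].any():
            ll += float(s[i:j][e[i:j] == 1].sum()) - float(e[i:j].sum()) * log_risk[i]
        i = j
    return ll


def fit_cmps_model(
    expr: pd.DataFrame,
    survival: list[SurvivalRecord],
    cancer_type: str = "",
    n_folds: int = 10,
    l1_ratio: float = 1.0,
    seed: int = 0,
    min_patients: int = 20,
    min_events: int = 5,
) -> CMPSModel:
    """Fit the lasso-Cox gene selection model with cross-validated penalty.

    ``expr``: genes as rows, patients as columns (the caller restricts rows
    to the candidate gene list).  Expression is z-scaled per gene inside the
    fit; the scaling is folded into the stored coefficients' metadata so
    :func:`cmps_score` reproduces the fitted linear predictor.

    The penalty grid comes from the solver's full-data path; each fold
    refits along that grid, and the alpha maximizing the mean held-out
    Breslow log partial likelihood is chosen (lambda-min rule).
    """
    surv_df = _records_to_frame(survival)
    missing = [p for p in surv_df.index if p not in expr.columns]
    if missing:
        raise ValueError(f"expression matrix missing patients: {missing[:5]}")
    X = expr.loc[:, surv_df.index].to_numpy(dtype=float).T  # patients x genes
    genes = list(expr.index)
    n, k = X.shape
    events = surv_df["event"].to_numpy()
    if events.sum() == 0:
        raise ValueError("all patients censored; Cox model unidentifiable")
    if n < min_patients or events.sum() < min_events:
        raise ValueError(
            f"need >= {min_patients} patients with >= {min_events} events; "
            f"got n={n}, events={int(events.sum())}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        flat = [genes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant-expression genes cannot be fitted: {flat[:5]}")
    Z = (X - mu) / sd
    y = Surv.from_arrays(event=events.astype(bool), time=surv_df["time"].to_numpy())

    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alpha_min_ratio=0.01, n_alphas=50)
    path.fit(Z, y)
    alphas = path.alphas_

    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_ll = np.zeros(len(alphas))
    time_arr = surv_df["time"].to_numpy()
    n_fitted = len(alphas)  # the solver may truncate the path on some folds
    for train, test in folds.split(Z):
        model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas, fit_baseline_model=False)
        model.fit(Z[train], y[train])
        coefs = model.coef_  # genes x fitted alphas (prefix of the grid)
        n_fitted = min(n_fitted, coefs.shape[1])
        for ai in range(coefs.shape[1]):
            scores = Z[test] @ coefs[:, ai]
            cv_ll[ai] += _log_partial_likelihood(
                scores, time_arr[test], events[test]
            )
    best = int(np.argmax(cv_ll[:n_fitted]))
    alpha_min = float(alphas[best])

    final = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, alphas=[alpha_min], fit_baseline_model=False
    )
    final.fit(Z, y)
    beta = final.coef_[:, 0]
    nonzero = np.flatnonzero(beta)
    if nonzero.size == 0:
        raise ValueError(
            "selected penalty drove all coefficients to zero; "
            "no prognostic model can be formed"
        )
    coefficients = {genes[i]: float(beta[i]) for i in nonzero}
    return CMPSModel(
        cancer_type=cancer_type,
        coefficients=coefficients,
        fit_metadata={
            "n_folds": n_folds,
            "l1_ratio": l1_ratio,
            "alpha_min": alpha_min,
            "penalty_rule": "cv-max-partial-likelihood (lambda-min)",
            "seed": seed,
            "n_patients": n,
            "n_events": int(events.sum()),
            "standardization": {
                genes[i]: {"mean": float(mu[i]), "sd": float(sd[i])} for i in nonzero
            },
        },
    )


def cmps_score(model: CMPSModel, expr: pd.DataFrame) -> pd.Series:
    """Patient-level risk score: sum over model genes of coefficient times
    expression, on the standardization recorded at fit time (identity when
    no standardization metadata is present)."""
    std = model.fit_metadata.get("standardization", {})
    scores = pd.Series(0.0, index=expr.columns)
    for gene, coef in model.coefficients.items():
        if gene not in expr.index:
            raise ValueError(f"expression matrix missing model gene {gene!r}")
        x = expr.loc[gene].astype(float)
        if gene in std:
            x = (x - std[gene]["mean"]) / std[gene]["sd"]
        scores += coef * x
    scores.name = "cmps"
    return scores


def stratify_by_median(scores: pd.Series) -> pd.Series:
    """Median split: score > median -> "high", score <= median -> "low".

    Ties at the median go to "low".  Constant scores cannot be stratified.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to stratify")
    if scores.nunique() == 1:
        raise ValueError("degenerate stratification: all scores identical")
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="risk_group"
    )


def logrank(
    groups: pd.Series, survival: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group Mantel–Haenszel log-rank test.

    ``groups``: patient -> {"high", "low"}.  Returns (chi-square statistic
    on 1 df, p-value).  Errors if either group is empty or no events exist.
    """
    surv = _records_to_frame(survival).loc[groups.index]
    if surv["event"].sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    labels = set(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {sorted(labels)}")
    a, b = sorted(labels)
    mask = groups == a
    res = _lifelines_logrank(
        surv.loc[mask.values, "time"],
        surv.loc[~mask.values, "time"],
        event_observed_A=surv.loc[mask.values, "event"],
        event_observed_B=surv.loc[~mask.values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)
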