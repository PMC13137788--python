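"""Phenotype calling for pooled base-editing screens with single-cell
readout.

Cells are QC-filtered (genes detected > 500, total UMIs > 300,
mitochondrial fraction < 10%, exactly one assigned sgRNA — all strict) and
each surviving cell is linked to one guide.  The effect of a guide on cell
fitness is estimated with a logistic GLM:

    logit(p) = b0 + b1 * I_gRNA + b2 * g(F_D0)

where p is the probability that an observation unit carries the guide,
I_gRNA indicates the target guide (vs non-targeting controls) and F_D0 is
the guide's normalized Day-0 library frequency.  Observation units are
(cell, candidate-guide) rows over the target plus all control guides; since
covariates are constant within a candidate, the fit is carried out on the
equivalent aggregated binomial data (identical likelihood).  b1 is the
target-vs-control log-odds shift after adjusting for initial abundance; the
likelihood-ratio test against the b1-free model gives the p-value, and
log2FC = b1 / ln 2 converts the effect to a log2 fold-change in odds.

The abundance covariate enters on the log scale by default
(g = log), because library frequency acts multiplicatively on a cell's
odds of carrying a guide: under a no-effect screen the carriage log-odds
are linear in log F_D0, so the log scale makes the null exactly
representable and the likelihood-ratio test calibrate.  Entering F_D0
untransformed (``method="linear"``) leaves curvature that the target
indicator absorbs, inflating the type-I error by about a percentage point
at realistic per-guide coverage; it is retained as an option for
comparison, as is an aggregated variant with a fixed log-odds offset
(``method="offset"``).

Complete separation (e.g. a guide absent from every endpoint cell) is
handled by a Firth-penalized refit, flagged, never silently reported as an
unpenalized estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gene_significance import bh_adjust

QC_MIN_GENES = 500
QC_MIN_UMIS = 300
QC_MAX_MITO = 10.0


def qc_filter(cells: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the strict QC rule: n_genes > 500 AND n_umis > 300 AND
    mito_pct < 10 AND exactly one assigned gRNA.

    Returns the passing subset and a report counting every rejection reason
    (a cell failing several criteria is counted under each).
    """
    n_grnas = cells["assigned_grnas"].map(len)
    fail_genes = ~(cells["n_genes"] > QC_MIN_GENES)
    fail_umis = ~(cells["n_umis"] > QC_MIN_UMIS)
    fail_mito = ~(cells["mito_pct"] < QC_MAX_MITO)
    fail_multi = n_grnas != 1
    passed = cells[~(fail_genes | fail_umis | fail_mito | fail_multi)].copy()
    report = {
        "input": int(len(cells)),
        "passed": int(len(passed)),
        "low_genes": int(fail_genes.sum()),
        "low_umis": int(fail_umis.sum()),
        "high_mito": int(fail_mito.sum()),
        "multi_grna": int(fail_multi.sum()),
    }
    return passed, report


def day0_frequencies(counts: pd.Series, pseudocount: float = 0.0) -> pd.Series:
    """Normalize Day-0 gRNA counts to frequencies summing to one."""
    c = counts.astype(float) + pseudocount
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero Day-0 counts cannot be normalized")
    return c / total


@dataclass
class ScreenDataset:
    """QC-passed cells with single-guide assignments plus library metadata."""

    cells: pd.DataFrame  # columns: barcode, grna
    grna_map: pd.DataFrame  # index grna; columns gene, is_control
    day0_counts: pd.Series
    day0_freq: pd.Series = field(init=False)
    qc_report: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.cells["grna"]) - set(self.grna_map.index)
        if unknown:
            raise ValueError(f"cells assigned to unmapped gRNAs: {sorted(unknown)[:5]}")
        if not self.grna_map["is_control"].any():
            raise ValueError(
                "no control gRNA in map; a non-targeting baseline is required"
            )
        self.day0_freq = day0_frequencies(self.day0_counts)
        if abs(self.day0_freq.sum() - 1.0) > 1e-9:
            raise ValueError("Day-0 frequencies do not sum to 1")

    @property
    def control_grnas(self) -> list[str]:
        return list(self.grna_map.index[self.grna_map["is_control"]])

    @property
    def target_grnas(self) -> list[str]:
        return list(self.grna_map.index[~self.grna_map["is_control"]])

    @classmethod
    def from_tables(
        cls,
        raw_cells: pd.DataFrame,
        grna_map: pd.DataFrame,
        day0_counts: pd.Series,
    ) -> "ScreenDataset":
        """QC-filter a raw cell table and assemble the dataset."""
        passed, report = qc_filter(raw_cells)
        cells = pd.DataFrame(
            {
                "barcode": passed["barcode"].to_numpy(),
                "grna": [g[0] for g in passed["assigned_grnas"]],
            }
        )
        return cls(
            cells=cells, grna_map=grna_map, day0_counts=day0_counts, qc_report=report
        )


@dataclass
class GRNAEffect:
    grna: str
    gene: str
    beta1: float | None
    log2fc: float | None
    lrt_stat: float | None
    p: float | None
    fdr: float | None = None
    flag: str = "ok"
    n_cells: int = 0


# ---------------------------------------------------------------------------
# Firth-penalized binomial logistic regression (separation fallback)

def _firth_binomial(
    X: np.ndarray, succ: np.ndarray, n: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Firth-penalized logistic fit on aggregated binomial data.

    Returns (beta, penalized log-likelihood).  The penalty is Jeffreys'
    invariant prior, 0.5 * log det(X'WX), which keeps estimates finite under
    complete separation.
    """
    k = X.shape[1]
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        # hat diagonal of W^{1/2} X (X'WX)^-1 X' W^{1/2}
        cov = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w
        score = X.T @ (succ - n * p + h * (0.5 - p))
        step = cov @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-300, 1 - 1e-16)
    ll = float(succ @ np.log(p) + (n - succ) @ np.log1p(-p))
    w = n * p * (1.0 - p)
    sign, logdet = np.linalg.slogdet((X.T * w) @ X)
    return beta, ll + 0.5 * logdet


def _glm_binomial(
    X: np.ndarray, succ: np.ndarray, n: np.ndarray, beta1_col: int | None = None
) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood binomial GLM fit; returns (beta, llf, clean)
    where clean is False when the fit shows signs of separation.

    Only the effect coefficient (``beta1_col``) is screened for runaway
    magnitude — the Day-0 frequency covariate legitimately takes large
    coefficients because F_D0 lives on a ~1/k scale.
    """
    endog = np.column_stack([succ, n - succ])
    res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    fitted = res.predict(X)
    clean = bool(
        res.converged
        and np.all(np.isfinite(res.params))
        and np.all(fitted > 1e-12)
        and np.all(fitted < 1 - 1e-12)
    )
    if clean and beta1_col is not None and abs(res.params[beta1_col]) > 15:
        clean = False
    return np.asarray(res.params), float(res.llf), clean


def _aggregate(dataset: ScreenDataset, grna: str) -> tuple[pd.DataFrame, int]:
    """Aggregated design for one target: one row per candidate guide
    (target + every control) with success = cells assigned to it out of all
    cells assigned within the candidate set."""
    candidates = [grna] + [c for c in dataset.control_grnas if c != grna]
    assigned = dataset.cells["grna"].value_counts()
    n_c = np.array([int(assigned.get(c, 0)) for c in candidates])
    n_cells = int(n_c.sum())
    design = pd.DataFrame(
        {
            "grna": candidates,
            "succ": n_c,
            "trials": n_cells,
            "I_grna": [1.0] + [0.0] * (len(candidates) - 1),
            "F_d0": [float(dataset.day0_freq.get(c, 0.0)) for c in candidates],
        }
    )
    return design, n_cells


def fit_grna_glm(
    dataset: ScreenDataset,
    grna: str,
    min_cells: int = 50,
    method: str = "covariate",
) -> GRNAEffect:
    """Fit the fitness GLM for one target guide against the control guides.

    ``method="covariate"`` is the primary model (log F_D0 entered as a
    covariate with a free slope); ``method="linear"`` enters F_D0
    untransformed; ``method="offset"`` is the aggregated binomial
    alternative with logit(F_D0) as a fixed offset, kept as a sign
    cross-check.  LRT compares the full model with the b1-free reduction
    on 1 df.
    """
    if grna not in dataset.grna_map.index:
        raise KeyError(f"unknown gRNA {grna!r}")
    if dataset.grna_map.loc[grna, "is_control"]:
        raise ValueError(f"{grna!r} is a control; only targets are tested")
    gene = str(dataset.grna_map.loc[grna, "gene"])
    design, n_cells = _aggregate(dataset, grna)
    if n_cells < min_cells:
        return GRNAEffect(
            grna=grna, gene=gene, beta1=None, log2fc=None, lrt_stat=None,
            p=None, flag="low_cells", n_cells=n_cells,
        )
    succ = design["succ"].to_numpy(dtype=float)
    trials = design["trials"].to_numpy(dtype=float)
    if method in ("covariate", "linear"):
        f = design["F_d0"].to_numpy()
        if (f <= 0).any() and method == "covariate":
            raise ValueError("zero Day-0 frequency for a candidate gRNA")
        abundance = np.log(f) if method == "covariate" else f
        X_full = np.column_stack(
            [np.ones(len(design)), design["I_grna"], abundance]
        )
        X_red = X_full[:, [0, 2]]
    elif method == "offset":
        # offset on the candidate's baseline log-odds of being drawn
        f = design["F_d0"].to_numpy()
        offset = np.log(np.clip(f, 1e-300, 1)) - np.log1p(-np.clip(f, 0, 1 - 1e-12))
        X_full = np.column_stack([np.ones(len(design)), design["I_grna"]])
        X_red = X_full[:, [0]]
        return _fit_with_offset(design, succ, trials, X_full, X_red, offset, grna, gene, n_cells)
    else:
        raise ValueError(f"unknown method {method!r}")

    beta_f, ll_f, clean_f = _glm_binomial(X_full, succ, trials, beta1_col=1)
    beta_r, ll_r, clean_r = _glm_binomial(X_red, succ, trials)
    flag = "ok"
    if succ[0] == 0 or not (clean_f and clean_r):
        flag = "separation"
        beta_f, ll_f = _firth_binomial(X_full, succ, trials)
        _, ll_r = _firth_binomial(X_red, succ, trials)
    lrt = max(2.0 * (ll_f - ll_r), 0.0)
    from scipy.stats import chi2

    p = float(chi2.sf(lrt, 1))
    b1 = float(beta_f[1])
    return GRNAEffect(
        grna=grna, gene=gene, beta1=b1, log2fc=b1 / math.log(2),
        lrt_stat=lrt, p=p, flag=flag, n_cells=n_cells,
    )


def _fit_with_offset(design, succ, trials, X_full, X_red, offset, grna, gene, n_cells):
    endog = np.column_stack([succ, trials - succ])
    full = sm.GLM(endog, X_full, family=sm.families.Binomial(), offset=offset).fit(
        maxiter=100, tol=1e-8
    )
    red = sm.GLM(endog, X_red, family=sm.families.Binomial(), offset=offset).fit(
        maxiter=100, tol=1e-8
    )
    from scipy.stats import chi2

    lrt = max(2.0 * (full.llf - red.llf), 0.0)
    b1 = float(full.params[1])
    flag = "ok" if full.converged and abs(b1) < 30 else "separation"
    return GRNAEffect(
        grna=grna, gene=gene, beta1=b1, log2fc=b1 / math.log(2),
        lrt_stat=float(lrt), p=float(chi2.sf(lrt, 1)), flag=flag, n_cells=n_cells,
    )


def screen_results(effects: list[GRNAEffect], alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust the tested guides and classify each as enriched, lethal or
    neutral.

    Guides flagged ``low_cells`` (no p-value) are excluded from the BH
    family but kept in the output with class ``untested``.  enriched:
    fdr < alpha and log2fc > 0; lethal: fdr < alpha and log2fc < 0.
    """
    tested = [e for e in effects if e.p is not None]
    if not tested:
        raise ValueError("no testable gRNA effects (empty BH family)")
    qs = bh_adjust(np.array([e.p for e in tested]))
    for e, q in zip(tested, qs):
        e.fdr = float(q)
    rows = []
    for e in effects:
        if e.p is None:
            cls = "untested"
        elif e.fdr < alpha and e.log2fc > 0:
            cls = "enriched"
        elif e.fdr < alpha and e.log2fc < 0:
            cls = "lethal"
        else:
            cls = "neutral"
        rows.append(
            (e.grna, e.gene, e.beta1, e.log2fc, e.lrt_stat, e.p, e.fdr, cls, e.flag, e.n_cells)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "grna", "gene", "beta1", "log2fc", "lrt_stat", "p", "fdr",
            "class", "flag", "n_cells",
        ],
    )


def run_screen(
    dataset: ScreenDataset,
    alpha: float = 0.05,
    min_cells: int = 50,
    method: str = "covariate",
) -> pd.DataFrame:
    """Fit every target guide and return the BH-adjusted results table,
    ordered by gRNA id for determinism."""
    effects = [
        fit_grna_glm(dataset, g, min_cells=min_cells, method=method)
        for g in sorted(dataset.target_grnas)
    ]
    return screen_results(effects, alpha=alpha)
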