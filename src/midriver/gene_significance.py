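"""Per-cohort gene mutation-enrichment significance.

A deliberately simple stand-in for a full covariate-aware driver-detection
model: a single cohort-wide background rate of nonsilent mutations per base
per sample is estimated, and each gene is tested for an excess of nonsilent
mutations over that background with an exact one-sided binomial tail.  The
surrounding framework is engine-agnostic — externally computed per-gene
p-values (e.g. from a covariate-based tool) can be supplied instead via
:func:`significance_from_pvalues` and flow through identically.

Genes absent from the length table carry no exposure term and are excluded
(logged).  Significantly mutated genes (SMGs) are called at FDR < 0.1,
Benjamini–Hochberg adjusted, with a strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneLengthTable, MutationCatalog

logger = logging.getLogger(__name__)

#: Above this Bernoulli-trial count the binomial tail may be replaced by its
#: Poisson limit (numerically indistinguishable at somatic rates).
POISSON_SWITCH_N = 10**6


@dataclass(frozen=True)
class BackgroundModel:
    """Uniform background: nonsilent mutations per base per sample."""

    per_base_rate: float
    n_samples: int
    tissue: str
    cohort: str

    def __post_init__(self):
        if not (0.0 < self.per_base_rate < 1.0):
            raise ValueError(f"per_base_rate must be in (0, 1), got {self.per_base_rate}")


@dataclass
class GeneSignificance:
    """Per-gene observed/expected nonsilent counts with p and BH q values."""

    table: pd.DataFrame  # index gene; columns observed, expected, p, q
    cohort: str
    tissue: str

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def p(self, gene: str) -> float:
        return float(self.table.loc[gene, "p"])

    def q(self, gene: str) -> float:
        return float(self.table.loc[gene, "q"])


def estimate_background(
    catalog: MutationCatalog,
    lengths: GeneLengthTable,
    exclude: set[str] | None = None,
    pseudocount: float = 0.0,
    robust: bool = True,
    robust_alpha: float = 0.01,
    max_iter: int = 5,
) -> BackgroundModel:
    """Estimate the cohort-wide nonsilent per-base per-sample mutation rate.

    rate = (total nonsilent mutations in scored genes + pseudocount)
           / (sum of scored gene lengths * n_samples)

    ``exclude`` removes genes (e.g. known drivers) from both numerator and
    denominator.  With ``robust`` (the default), genes whose counts are
    extreme outliers against the current rate (upper-tail binomial
    p < ``robust_alpha`` / n_genes, a Bonferroni-style cut) are excluded
    and the rate re-estimated until the exclusion set stabilizes — without
    this, a handful of hypermutated or mutation-tolerant genes can inflate
    the neutral rate substantially.  A zero-mutation catalog is an error
    unless a positive ``pseudocount`` is configured.
    """
    if not catalog.records:
        raise ValueError("cannot estimate background from an empty catalog")
    exclude = set(exclude or set())
    counts = catalog.nonsilent_counts()

    def _rate(excluded: set[str]) -> float:
        scored = [g for g in lengths.genes if g not in excluded]
        total_len = sum(lengths[g] for g in scored)
        if total_len <= 0:
            raise ValueError("total covered length is zero")
        total_muts = sum(counts.get(g, 0) for g in scored)
        if total_muts == 0 and pseudocount <= 0:
            raise ValueError(
                "no nonsilent mutations in scored genes; set a positive "
                "background_pseudocount to proceed"
            )
        return (total_muts + pseudocount) / (total_len * catalog.n_samples)

    rate = _rate(exclude)
    if robust:
        n_genes = max(len(lengths.genes), 1)
        cut = robust_alpha / n_genes
        dropped = set(exclude)
        for _ in range(max_iter):
            outliers = set(dropped)
            for g in lengths.genes:
                if g in exclude:
                    continue
                obs = counts.get(g, 0)
                if obs == 0:
                    continue
                n = lengths[g] * catalog.n_samples
                if float(stats.binom.sf(obs - 1, n, rate)) < cut:
                    outliers.add(g)
            if outliers == dropped:
                break
            dropped = outliers
            rate = _rate(dropped)
        if dropped - exclude:
            logger.info(
                "estimate_background: %d outlier genes excluded from the "
                "neutral rate", len(dropped - exclude),
            )
    return BackgroundModel(
        per_base_rate=rate,
        n_samples=catalog.n_samples,
        tissue=catalog.tissue,
        cohort=catalog.cohort,
    )


def gene_pvalue(
    observed: int,
    length: int,
    model: BackgroundModel,
    approx: str = "auto",
) -> float:
    """One-sided upper-tail p-value for a gene's nonsilent mutation count.

    The count is referred to Binomial(n = length * n_samples,
    pi = per_base_rate); p = P(X >= observed).  The exact binomial tail is
    used throughout; ``approx="poisson"`` (or ``"auto"`` with very large n)
    substitutes the Poisson tail with the same mean.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if length <= 0:
        raise ValueError("gene length must be positive")
    if observed == 0:
        return 1.0
    n = length * model.n_samples
    if approx == "poisson" or (approx == "auto" and n > POISSON_SWITCH_N):
        return float(stats.poisson.sf(observed - 1, n * model.per_base_rate))
    return float(stats.binom.sf(observed - 1, n, model.per_base_rate))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, aligned to input order.

    Standard step-up with cumulative minimum from the largest p downward;
    tied p-values receive identical q-values.
    """
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to BH adjustment")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def score_catalog(
    catalog: MutationCatalog,
    lengths: GeneLengthTable,
    model: BackgroundModel | None = None,
    approx: str = "auto",
) -> GeneSignificance:
    """Score every gene in the length table against the background model.

    Genes missing from the length table are skipped with a logged count
    (no exposure term is derivable for them).
    """
    if model is None:
        model = estimate_background(catalog, lengths)
    counts = catalog.nonsilent_counts()
    skipped = [g for g in counts if g not in lengths]
    if skipped:
        logger.info(
            "score_catalog: %d mutated genes absent from length table, skipped",
            len(skipped),
        )
    genes = lengths.genes
    observed = np.array([counts.get(g, 0) for g in genes])
    n_trials = np.array([lengths[g] * model.n_samples for g in genes], dtype=float)
    expected = n_trials * model.per_base_rate
    pvals = np.array(
        [gene_pvalue(int(o), lengths[g], model, approx) for o, g in zip(observed, genes)]
    )
    q = bh_adjust(pvals)
    table = pd.DataFrame(
        {"observed": observed, "expected": expected, "p": pvals, "q": q},
        index=pd.Index(genes, name="gene"),
    )
    return GeneSignificance(table=table, cohort=catalog.cohort, tissue=catalog.tissue)


def significance_from_pvalues(
    pvals: pd.Series | dict[str, float],
    cohort: str,
    tissue: str = "",
) -> GeneSignificance:
    """Wrap externally computed per-gene p-values (engine-agnostic path).

    BH adjustment is applied here so the downstream contract (p and q per
    gene) is identical to the internal engine's.
    """
    s = pd.Series(pvals, dtype=float)
    q = bh_adjust(s.to_numpy())
    table = pd.DataFrame(
        {"observed": np.nan, "expected": np.nan, "p": s.to_numpy(), "q": q},
        index=pd.Index(s.index, name="gene"),
    )
    return GeneSignificance(table=table, cohort=cohort, tissue=tissue)


def call_smgs(sig: GeneSignificance, fdr_threshold: float = 0.1) -> set[str]:
    """Significantly mutated genes: q strictly below the FDR threshold."""
    mask = sig.table["q"] < fdr_threshold
    return set(sig.table.index[mask])
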