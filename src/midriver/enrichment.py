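"""Permutation and hypergeometric enrichment tests for gene sets.

Two set statistics mirror the questions asked of mutation-intolerant genes:
how many members of a gene set participate in any known synthetic-lethal
(SL) pair, and how many SL pairs fall entirely inside the set.  Observed
values are compared against randomly drawn gene sets of the same size (and,
optionally, matched per expression-variance stratum), with the Phipson–Smyth
add-one correction so a permutation p-value can never be exactly zero:
p = (n_ge + 1) / (n_iter + 1).

Co-expression pair calling uses Pearson correlation with a two-sided
t-based p-value per pair, keeping pairs with |r| > 0.5 and p < 1e-8 by
default (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SLPairSet


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    n_iter: int
    n_ge: int
    p_value: float
    null_mean: float
    null_sd: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "n_iter": self.n_iter,
            "n_ge": self.n_ge,
            "p_value": self.p_value,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "seed": self.seed,
        }


def sl_stats(gene_set: set[str], sl: SLPairSet) -> tuple[int, int]:
    """(genes_in_sl, pairs_within) for a gene set against an SL pair list.

    genes_in_sl counts set members appearing in any SL pair; pairs_within
    counts SL pairs with both members inside the set.
    """
    sl_genes = sl.genes
    genes_in = len(gene_set & sl_genes)
    pairs_within = sum(1 for p in sl.pairs if p <= gene_set)
    return genes_in, pairs_within


class MatchedNullSampler:
    """Draws random gene sets matched in size (and optionally per-stratum
    composition) to an observed set.

    ``strata`` maps every universe gene to a bin label (e.g. log-variance
    decile).  Stratified draws preserve the observed set's per-stratum
    counts exactly.
    """

    def __init__(
        self,
        universe: list[str],
        set_size: int,
        strata: dict[str, object] | None = None,
        observed_set: set[str] | None = None,
    ):
        self.universe = list(universe)
        self.set_size = set_size
        if set_size > len(self.universe):
            raise ValueError("set_size exceeds universe size")
        self._strata = strata
        if strata is None:
            self._plan = None
        else:
            if observed_set is None:
                raise ValueError("stratified sampling needs the observed set")
            by_bin: dict[object, list[str]] = {}
            for g in self.universe:
                by_bin.setdefault(strata[g], []).append(g)
            need: dict[object, int] = {}
            for g in observed_set:
                need[strata[g]] = need.get(strata[g], 0) + 1
            for b, k in need.items():
                pool = by_bin.get(b, [])
                if len(pool) < k:
                    raise ValueError(
                        f"stratum {b!r} has {len(pool)} universe genes but the "
                        f"observed set needs {k}"
                    )
            self._plan = [(np.array(by_bin[b]), k) for b, k in sorted(need.items(), key=lambda x: str(x[0]))]

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self._plan is None:
            return rng.choice(self.universe, size=self.set_size, replace=False)
        parts = [rng.choice(pool, size=k, replace=False) for pool, k in self._plan]
        return np.concatenate(parts)


def variance_strata(expr: pd.DataFrame, n_bins: int = 10) -> dict[str, int]:
    """Assign each gene (row of ``expr``) to a log-variance quantile bin."""
    v = expr.var(axis=1)
    logv = np.log(v + 1e-300)
    bins = pd.qcut(logv, q=n_bins, labels=False, duplicates="drop")
    return {g: int(b) for g, b in bins.items()}


def permutation_test(
    observed_set: set[str],
    universe: list[str],
    stat: Callable[[set[str]], float],
    n_iter: int = 1_000_000,
    sampler: MatchedNullSampler | None = None,
    seed: int = 0,
) -> PermutationResult:
    """One-sided upper-tail permutation test of a gene-set statistic.

    The null distribution is streamed (only running moments and the
    exceedance count are kept).  p = (#{null >= observed} + 1) / (n_iter + 1).
    """
    universe_set = set(universe)
    if not observed_set <= universe_set:
        raise ValueError("observed set is not contained in the universe")
    if sampler is None:
        sampler = MatchedNullSampler(list(universe), len(observed_set))
    rng = np.random.default_rng(seed)
    observed = float(stat(observed_set))
    n_ge = 0
    s1 = 0.0
    s2 = 0.0
    for _ in range(n_iter):
        draw = sampler.draw(rng)
        val = float(stat(set(draw)))
        if val >= observed:
            n_ge += 1
        s1 += val
        s2 += val * val
    mean = s1 / n_iter
    var = max(s2 / n_iter - mean * mean, 0.0)
    return PermutationResult(
        observed_stat=observed,
        n_iter=n_iter,
        n_ge=n_ge,
        p_value=(n_ge + 1) / (n_iter + 1),
        null_mean=mean,
        null_sd=float(np.sqrt(var)),
        seed=seed,
    )


def sl_permutation_test(
    gene_set: set[str],
    universe: list[str],
    sl: SLPairSet,
    statistic: str = "pairs_within",
    n_iter: int = 1_000_000,
    sampler: MatchedNullSampler | None = None,
    seed: int = 0,
) -> PermutationResult:
    """Permutation enrichment of a gene set in SL genes or SL pairs.

    ``statistic``: ``"genes_in_sl"`` (members in any SL pair) or
    ``"pairs_within"`` (SL pairs fully inside the set).  This vectorized
    path makes the published 10^6-iteration setting tractable.
    """
    if statistic not in ("genes_in_sl", "pairs_within"):
        raise ValueError(f"unknown statistic {statistic!r}")
    universe = list(universe)
    universe_set = set(universe)
    if not gene_set <= universe_set:
        raise ValueError("observed set is not contained in the universe")
    idx = {g: i for i, g in enumerate(universe)}
    sl_gene_idx = np.array(
        sorted(idx[g] for g in sl.genes if g in universe_set), dtype=np.int64
    )
    pair_idx = np.array(
        [
            sorted(idx[g] for g in p)
            for p in sl.pairs
            if all(g in universe_set for g in p)
        ],
        dtype=np.int64,
    ).reshape(-1, 2)

    def stat_from_mask(member: np.ndarray) -> int:
        if statistic == "genes_in_sl":
            return int(member[sl_gene_idx].sum())
        return int((member[pair_idx[:, 0]] & member[pair_idx[:, 1]]).sum()) if len(pair_idx) else 0

    obs_mask = np.zeros(len(universe), dtype=bool)
    obs_mask[[idx[g] for g in gene_set]] = True
    observed = stat_from_mask(obs_mask)

    if sampler is None:
        sampler = MatchedNullSampler(universe, len(gene_set))
    rng = np.random.default_rng(seed)
    n_ge = 0
    s1 = 0.0
    s2 = 0.0
    member = np.zeros(len(universe), dtype=bool)
    for _ in range(n_iter):
        draw = sampler.draw(rng)
        member[:] = False
        member[[idx[g] for g in draw]] = True
        val = stat_from_mask(member)
        if val >= observed:
            n_ge += 1
        s1 += val
        s2 += val * val
    mean = s1 / n_iter
    var = max(s2 / n_iter - mean * mean, 0.0)
    return PermutationResult(
        observed_stat=float(observed),
        n_iter=n_iter,
        n_ge=n_ge,
        p_value=(n_ge + 1) / (n_iter + 1),
        null_mean=mean,
        null_sd=float(np.sqrt(var)),
        seed=seed,
    )


def hypergeometric_test(
    set_size: int,
    annotated_in_set: int,
    universe_size: int,
    annotated_total: int,
) -> float:
    """Upper-tail hypergeometric enrichment p-value: P(X >= annotated_in_set)
    where X counts annotated genes in a random set of ``set_size`` drawn
    from a universe with ``annotated_total`` annotated members."""
    if annotated_in_set > min(set_size, annotated_total):
        raise ValueError("overlap exceeds set size or annotation total")
    if max(set_size, annotated_total) > universe_size or min(
        set_size, annotated_in_set, annotated_total, universe_size
    ) < 0:
        raise ValueError("inconsistent counts")
    return float(
        stats.hypergeom.sf(annotated_in_set - 1, universe_size, annotated_total, set_size)
    )


def coexpression_pairs(
    expr: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 1e-8,
) -> set[frozenset]:
    """All gene pairs with |Pearson r| > ``r_min`` and two-sided t-test
    p < ``p_max`` (both strict) across samples.

    ``expr``: genes as rows, samples as columns; needs >= 3 samples.
    Constant-expression genes are excluded (their correlation is undefined).
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError("co-expression needs at least 3 samples")
    sd = expr.std(axis=1)
    usable = expr.loc[sd > 0]
    genes = list(usable.index)
    if len(genes) < 2:
        return set()
    r = np.corrcoef(usable.to_numpy())
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    ii, jj = np.triu_indices(len(genes), k=1)
    keep = (np.abs(r[ii, jj]) > r_min) & (p[ii, jj] < p_max)
    return {frozenset((genes[i], genes[j])) for i, j in zip(ii[keep], jj[keep])}
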