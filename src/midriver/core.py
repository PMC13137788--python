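"""The mutation-intolerance statistic.

For each gene in a matched tumor–healthy tissue pair, two one-sided
significance values are paired: P, the gene's mutation-enrichment p-value in
the healthy cohort (small when the gene tolerates mutations in normal
tissue), and 1 − P_cancer, its complement in the tumor cohort (small when
the gene is *not* significantly mutated in tumors).  The two are combined by
Fisher's method,

    combined_stat = -2 * sum_i ln p_i,

referred to a chi-square upper tail.  Fisher's theory gives 2k degrees of
freedom for k combined p-values (4 here); the published formulation prints
6, so ``fisher_df`` is exposed as an override for exact replication.

A gene is a mutation-intolerant gene (MIG) when its combined FDR is below
0.1 and its mean CRISPR dependence score over lineage-matched cell lines
exceeds 0.9.  The top-MIG triage additionally requires lack of tumor
enrichment (cancer FDR > 0.6), healthy-tissue tolerance (healthy FDR < 0.1),
and a log2 nonsilent mutation-burden ratio (healthy / tumor, per sample,
pseudocount 1 on counts) above 1 — all strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gene_significance import GeneSignificance, bh_adjust
from .io_formats import DependenceMatrix, MutationCatalog

DEFAULT_EPS = 1e-12


def pair_pvalues(
    p_healthy: float, p_cancer: float, eps: float = DEFAULT_EPS
) -> tuple[float, float]:
    """Form the (tolerance, intolerance) p-value pair for one gene.

    p1 = clamp(p_healthy, eps, 1) — small when the gene is mutated
    (tolerated) in healthy tissue; p2 = clamp(1 - p_cancer, eps, 1) — small
    when the gene is NOT significantly mutated in cancer.  The lower clamp
    guards against p_cancer = 1, which is routine for tumor-unmutated genes.
    """
    for name, v in (("p_healthy", p_healthy), ("p_cancer", p_cancer)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} outside [0, 1]: {v}")
    p1 = min(max(p_healthy, eps), 1.0)
    p2 = min(max(1.0 - p_cancer, eps), 1.0)
    return p1, p2


def fisher_combine(
    p_list: list[float] | np.ndarray, df: int | None = None
) -> tuple[float, float]:
    """Fisher's method: stat = -2 sum ln p_i, upper tail of chi-square.

    ``df`` defaults to 2k (k = number of p-values); pass an explicit value
    to reproduce alternative published degrees of freedom.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("all p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    if df is None:
        df = 2 * p.size
    return stat, float(stats.chi2.sf(stat, df))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg q-values (alias of the shared implementation)."""
    return bh_adjust(np.asarray(pvals, dtype=float))


def mutation_burden_ratio(
    healthy: MutationCatalog,
    tumor: MutationCatalog,
    gene: str,
    pseudocount: int = 1,
) -> float:
    """log2 of the healthy / tumor per-sample nonsilent burden for a gene.

    mbr = log2( ((c_H + pc) / n_H) / ((c_T + pc) / n_T) ) with the
    pseudocount added to counts, not rates, so the ratio stays defined for
    tumor-unmutated genes.
    """
    if healthy.n_samples <= 0 or tumor.n_samples <= 0:
        raise ValueError("both cohorts must have n_samples > 0")
    c_h = healthy.nonsilent_counts().get(gene, 0)
    c_t = tumor.nonsilent_counts().get(gene, 0)
    num = (c_h + pseudocount) / healthy.n_samples
    den = (c_t + pseudocount) / tumor.n_samples
    return math.log2(num / den)


@dataclass
class MIGTable:
    """Combined intolerance statistics for one tumor–healthy pair."""

    table: pd.DataFrame
    tissue_pair: tuple[str, str]  # (healthy tissue, cancer type)
    params: dict = field(default_factory=dict)

    @property
    def migs(self) -> set[str]:
        return set(self.table.index[self.table["is_mig"]])


def combine_pair(
    healthy_sig: GeneSignificance,
    cancer_sig: GeneSignificance,
    eps: float = DEFAULT_EPS,
    fisher_df: int | None = None,
) -> pd.DataFrame:
    """Fisher-combine healthy tolerance and cancer intolerance per gene.

    Only genes present in both cohorts' significance tables are scored.
    Returns a frame indexed by gene with p_healthy, p_cancer, healthy_fdr,
    cancer_fdr, combined_stat, combined_p, fdr.
    """
    genes = [g for g in healthy_sig.genes if g in set(cancer_sig.genes)]
    if not genes:
        raise ValueError("no genes shared between the two cohorts")
    rows = []
    for g in genes:
        p1, p2 = pair_pvalues(healthy_sig.p(g), cancer_sig.p(g), eps)
        stat, comb = fisher_combine([p1, p2], df=fisher_df)
        rows.append((g, healthy_sig.p(g), cancer_sig.p(g), stat, comb))
    df = pd.DataFrame(
        rows, columns=["gene", "p_healthy", "p_cancer", "combined_stat", "combined_p"]
    ).set_index("gene")
    df["fdr"] = bh_adjust(df["combined_p"].to_numpy())
    df["healthy_fdr"] = [healthy_sig.q(g) for g in df.index]
    df["cancer_fdr"] = [cancer_sig.q(g) for g in df.index]
    return df


def meta_combine(per_pair_p: pd.DataFrame, fisher_df: int | None = None) -> pd.Series:
    """Optional second Fisher pass across multiple tissue pairs.

    ``per_pair_p``: genes x pairs matrix of combined p-values; rows with any
    NaN are skipped.  Returns a meta-combined p-value per gene.
    """
    out = {}
    for g, row in per_pair_p.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size == 0:
            continue
        _, p = fisher_combine(np.clip(vals, DEFAULT_EPS, 1.0), df=fisher_df)
        out[g] = p
    return pd.Series(out, name="meta_combined_p")


def mean_dependence(
    dep: DependenceMatrix, lineage: str, genes: list[str], invert: bool = False
) -> pd.Series:
    """Mean dependence over lineage-matched cell lines, NaN-ignoring.

    ``invert`` flips effect-score conventions (lower = more essential) onto
    the probability-of-dependency orientation via 1 - score.
    """
    lines = dep.lines_for_lineage(lineage)
    sub = dep.scores.loc[:, lines]
    if invert:
        sub = 1.0 - sub
    means = sub.mean(axis=1, skipna=True)
    return means.reindex(genes)


def call_migs(
    combined: pd.DataFrame,
    dependence: DependenceMatrix,
    lineage: str,
    tissue_pair: tuple[str, str] = ("", ""),
    fdr_threshold: float = 0.1,
    dep_threshold: float = 0.9,
    invert_dependence: bool = False,
) -> MIGTable:
    """Call MIGs: combined FDR < ``fdr_threshold`` AND mean lineage-matched
    dependence > ``dep_threshold`` (both strict).

    Genes with no dependence data in any matched line get mean_dependence
    NaN, is_mig False, and the flag ``no_dependence_data``.
    """
    table = combined.copy()
    dep_mean = mean_dependence(
        dependence, lineage, list(table.index), invert=invert_dependence
    )
    table["mean_dependence"] = dep_mean
    has_dep = dep_mean.notna()
    table["flag"] = np.where(has_dep, "ok", "no_dependence_data")
    table["is_mig"] = (
        (table["fdr"] < fdr_threshold)
        & has_dep
        & (dep_mean > dep_threshold)
    )
    return MIGTable(
        table=table,
        tissue_pair=tissue_pair,
        params={
            "fdr_threshold": fdr_threshold,
            "dep_threshold": dep_threshold,
            "lineage": lineage,
            "invert_dependence": invert_dependence,
        },
    )


def attach_mbr(
    mig_table: MIGTable,
    healthy: MutationCatalog,
    tumor: MutationCatalog,
    pseudocount: int = 1,
) -> MIGTable:
    """Add the per-gene log2 mutation-burden ratio column in place."""
    mig_table.table["mbr_log2"] = [
        mutation_burden_ratio(healthy, tumor, g, pseudocount)
        for g in mig_table.table.index
    ]
    mig_table.params["mbr_pseudocount"] = pseudocount
    return mig_table


def rank_top_migs(
    mig_table: MIGTable,
    mbr_min: float = 1.0,
    cancer_fdr_min: float = 0.6,
    healthy_fdr_max: float = 0.1,
) -> list[str]:
    """Three-rule triage for top mutation-intolerant genes.

    Keep genes with (1) cancer FDR > ``cancer_fdr_min`` (no significant
    tumor enrichment), (2) healthy FDR < ``healthy_fdr_max`` (significant
    tolerance in healthy tissue), and (3) mbr_log2 > ``mbr_min`` — all
    strict.  Order: mbr_log2 descending, ties broken by combined_p
    ascending, then gene symbol, so the ranking is deterministic.
    """
    t = mig_table.table
    required = {"cancer_fdr", "healthy_fdr", "mbr_log2", "combined_p"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"MIG table missing columns: {sorted(missing)}")
    keep = t[
        (t["cancer_fdr"] > cancer_fdr_min)
        & (t["healthy_fdr"] < healthy_fdr_max)
        & (t["mbr_log2"] > mbr_min)
    ].copy()
    keep["_gene"] = keep.index
    keep = keep.sort_values(
        by=["mbr_log2", "combined_p", "_gene"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return list(keep.index)


def run_pair(
    healthy_sig: GeneSignificance,
    cancer_sig: GeneSignificance,
    dependence: DependenceMatrix,
    lineage: str,
    healthy: MutationCatalog | None = None,
    tumor: MutationCatalog | None = None,
    eps: float = DEFAULT_EPS,
    fisher_df: int | None = None,
    fdr_threshold: float = 0.1,
    dep_threshold: float = 0.9,
    mbr_pseudocount: int = 1,
    invert_dependence: bool = False,
) -> MIGTable:
    """End-to-end scoring of one tumor–healthy tissue pair.

    Combines per-cohort significance, calls MIGs against the dependence
    matrix, and (when the raw catalogs are supplied) attaches burden ratios
    and the ``is_top_mig`` triage flag.
    """
    combined = combine_pair(healthy_sig, cancer_sig, eps=eps, fisher_df=fisher_df)
    mig_table = call_migs(
        combined,
        dependence,
        lineage,
        tissue_pair=(healthy_sig.tissue, cancer_sig.tissue),
        fdr_threshold=fdr_threshold,
        dep_threshold=dep_threshold,
        invert_dependence=invert_dependence,
    )
    if healthy is not None and tumor is not None:
        attach_mbr(mig_table, healthy, tumor, pseudocount=mbr_pseudocount)
        top = rank_top_migs(mig_table)
        mig_table.table["is_top_mig"] = mig_table.table.index.isin(top)
    mig_table.params.update({"eps": eps, "fisher_df": fisher_df})
    return mig_table
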