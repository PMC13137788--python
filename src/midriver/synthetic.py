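"""Synthetic cohort, dependence, survival and screen generators with
planted ground truth.

Each generator is a pure function of its spec: the spec-level seed is fanned
out into independent named substreams (one per random component), so
regenerating with the same spec reproduces every output bit-for-bit while
components stay statistically independent.

The mutation model is deliberately minimal — per-gene Poisson counts with
gene-length-proportional background rates, mutations spread uniformly over
samples, a fixed silent fraction — because the downstream statistics consume
only gene-level nonsilent counts.  Defaults emulate a desk-scale version of
a pan-cancer contrast: hundreds of samples per cohort at a somatic rate of
a few mutations per megabase, planted mutation-intolerant genes carrying a
10x healthy-rate excess and zero tumor rate, and planted tumor drivers the
mirror image.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    DependenceMatrix,
    GeneLengthTable,
    MutationCatalog,
    build_catalog,
)
from .prognosis import SurvivalRecord

_MAX_EXPECTED_MUTATIONS = 10**7


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent child stream of the spec-level seed (stable
    across processes: the name enters through CRC32, not Python's
    randomized hash)."""
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    return np.random.default_rng(ss)


@dataclass
class CohortSpec:
    """Stated world for a matched healthy/tumor cohort pair."""

    n_genes: int = 100
    gene_length_range: tuple[int, int] = (500, 3000)
    n_samples_healthy: int = 500
    n_samples_tumor: int = 500
    background_rate: float = 2e-6  # nonsilent mutations / base / sample
    planted_migs: list[str] = field(default_factory=list)
    mig_healthy_multiplier: float = 10.0
    mig_tumor_multiplier: float = 0.0
    planted_smgs_tumor: list[str] = field(default_factory=list)
    smg_tumor_multiplier: float = 10.0
    silent_fraction: float = 0.3
    seed: int = 0

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def simulate_cohort_pair(
    spec: CohortSpec,
) -> tuple[MutationCatalog, MutationCatalog, dict, GeneLengthTable]:
    """Simulate a matched healthy/tumor catalog pair with planted effects.

    Per gene g and cohort c the nonsilent+silent mutation count is
    Poisson(rate_c * multiplier_{g,c} * length_g * n_samples_c), spread
    uniformly over samples; each mutation is silent with probability
    ``silent_fraction``.  Returns (healthy, tumor, truth, lengths) where
    truth records the planted gene lists.
    """
    genes = spec.gene_names()
    for g in spec.planted_migs + spec.planted_smgs_tumor:
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not in the simulated gene universe")
    rng_len = _stream(spec.seed, "lengths")
    lo, hi = spec.gene_length_range
    lengths = GeneLengthTable(
        {g: int(L) for g, L in zip(genes, rng_len.integers(lo, hi + 1, spec.n_genes))}
    )

    def multipliers(cohort: str) -> np.ndarray:
        m = np.ones(spec.n_genes)
        for i, g in enumerate(genes):
            if g in spec.planted_migs:
                m[i] = (
                    spec.mig_healthy_multiplier
                    if cohort == "healthy"
                    else spec.mig_tumor_multiplier
                )
            elif g in spec.planted_smgs_tumor and cohort == "tumor":
                m[i] = spec.smg_tumor_multiplier
        return m

    catalogs = {}
    for cohort, n_samples in (
        ("healthy", spec.n_samples_healthy),
        ("tumor", spec.n_samples_tumor),
    ):
        rng = _stream(spec.seed, f"mutations-{cohort}")
        L = np.array([lengths[g] for g in genes], dtype=float)
        lam = spec.background_rate * multipliers(cohort) * L * n_samples
        if lam.sum() > _MAX_EXPECTED_MUTATIONS:
            raise ValueError(
                f"expected mutation total {lam.sum():.3g} exceeds desk-scale guard"
            )
        counts = rng.poisson(lam)
        rows = []
        for g, k in zip(genes, counts):
            if k == 0:
                continue
            samples = rng.integers(0, n_samples, size=k)
            silent = rng.random(k) < spec.silent_fraction
            for s, is_sil in zip(samples, silent):
                rows.append(
                    (f"{cohort[0].upper()}S{s:05d}", g,
                     "synonymous" if is_sil else "nonsynonymous")
                )
        catalogs[cohort] = build_catalog(
            rows, cohort=cohort, tissue="synthetic", n_samples=n_samples
        )
    truth = {
        "planted_migs": list(spec.planted_migs),
        "planted_smgs_tumor": list(spec.planted_smgs_tumor),
        "null_genes": [
            g
            for g in genes
            if g not in spec.planted_migs and g not in spec.planted_smgs_tumor
        ],
    }
    return catalogs["healthy"], catalogs["tumor"], truth, lengths


def simulate_dependence(
    genes: list[str],
    n_lines: int = 10,
    planted_essential: list[str] | None = None,
    essential_mean: float = 0.95,
    null_mean: float = 0.3,
    concentration: float = 50.0,
    lineage: str = "synthetic",
    seed: int = 0,
) -> DependenceMatrix:
    """Beta-distributed dependence scores with planted essentials.

    Scores for planted genes are Beta with mean ``essential_mean`` and the
    given concentration (alpha + beta); null genes get mean ``null_mean``.
    At concentration 50 and n_lines >= 5 a planted gene's mean score clears
    the 0.9 call threshold with probability > 0.99.
    """
    if not (0 < essential_mean < 1 and 0 < null_mean < 1):
        raise ValueError("means must lie strictly inside (0, 1)")
    planted = set(planted_essential or [])
    rng = _stream(seed, "dependence")
    rows = []
    for g in genes:
        mean = essential_mean if g in planted else null_mean
        a, b = mean * concentration, (1 - mean) * concentration
        rows.append(rng.beta(a, b, size=n_lines))
    lines = [f"LINE{i:03d}" for i in range(n_lines)]
    scores = pd.DataFrame(rows, index=genes, columns=lines)
    return DependenceMatrix(scores=scores, lineages={c: lineage for c in lines})


def simulate_survival(
    n_patients: int,
    genes: list[str],
    coefficients: dict[str, float],
    censoring_fraction: float = 0.3,
    baseline_hazard: float = 1.0 / 365.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SurvivalRecord], pd.Series]:
    """Exponential survival with log-hazard linear in expression.

    Expression is standard normal per gene; event times are exponential
    with hazard baseline * exp(sum coef * expr); censoring is independent
    uniform on [0, T_c] with T_c calibrated so the realized censored
    fraction approximates the request.  Returns (expression genes x
    patients, survival records, true linear score).
    """
    if not (0 <= censoring_fraction < 1):
        raise ValueError("censoring_fraction must be in [0, 1)")
    for g in coefficients:
        if g not in genes:
            raise ValueError(f"coefficient for gene {g!r} not in gene list")
    rng = _stream(seed, "survival")
    patients = [f"P{i:04d}" for i in range(n_patients)]
    expr = pd.DataFrame(
        rng.standard_normal((len(genes), n_patients)), index=genes, columns=patients
    )
    score = pd.Series(0.0, index=patients, name="true_score")
    for g, c in coefficients.items():
        score += c * expr.loc[g]
    hazard = baseline_hazard * np.exp(score.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    if censoring_fraction > 0:
        # uniform censoring horizon calibrated by bisection on the expected
        # censored fraction E[P(C < T)] with C ~ U(0, tc)
        def censored_frac(tc: float) -> float:
            # P(C < T) for C ~ U(0, tc), T ~ Exp(lam): (1 - e^{-lam tc})/(lam tc)
            return float(np.mean((1 - np.exp(-hazard * tc)) / (hazard * tc)))

        lo, hi = 1e-6, 1e9
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censored_frac(mid) > censoring_fraction:
                lo = mid
            else:
                hi = mid
        t_cens = rng.uniform(0, np.sqrt(lo * hi), size=n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(n_patients, dtype=int)
    time = np.maximum(time, 1e-9)
    records = [
        SurvivalRecord(patient_id=p, time=float(t), event=int(e))
        for p, t, e in zip(patients, time, event)
    ]
    return expr, records, score


@dataclass
class ScreenSpec:
    """Stated world for a pooled base-editing screen with single-cell
    readout: a guide library with non-targeting controls, Day-0 frequencies
    drawn from a symmetric Dirichlet (concentration 50 emulates a tightly
    cloned library), and endpoint cells assigned multinomially with odds
    proportional to Day-0 frequency times a per-guide fitness multiplier.
    QC covariates are drawn so roughly 90% of cells survive the strict
    filter thresholds."""

    n_grnas: int = 40
    n_controls: int = 20
    day0_concentration: float = 50.0
    fitness: dict[str, float] = field(default_factory=dict)  # gRNA -> odds multiplier
    n_cells: int = 5000
    day0_reads: int = 100_000
    doublet_rate: float = 0.04
    seed: int = 0

    def grna_names(self) -> tuple[list[str], list[str]]:
        targets = [f"sg{i:03d}" for i in range(self.n_grnas)]
        controls = [f"ctrl{i:03d}" for i in range(self.n_controls)]
        return targets, controls


def simulate_screen(
    spec: ScreenSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Simulate (raw cell table, Day-0 counts, gRNA map, truth).

    Controls always have fitness 1; target fitness defaults to 1 unless
    planted via ``spec.fitness``.  Truth records each guide's fitness and
    its implied log2 odds change.
    """
    targets, controls = spec.grna_names()
    grnas = targets + controls
    for g, w in spec.fitness.items():
        if g not in grnas:
            raise ValueError(f"fitness planted on unknown gRNA {g!r}")
        if g in controls and w != 1.0:
            raise ValueError("controls must keep fitness 1")
        if w < 0:
            raise ValueError("fitness multipliers must be >= 0")
    rng = _stream(spec.seed, "screen")
    k = len(grnas)
    latent_p = rng.dirichlet(np.full(k, spec.day0_concentration))
    day0_counts = pd.Series(
        rng.multinomial(spec.day0_reads, latent_p), index=grnas, dtype=float
    )
    if (day0_counts == 0).any():
        day0_counts += 1.0  # keep every guide representable in the library
    day0_freq = (day0_counts / day0_counts.sum()).to_numpy()
    fitness = np.array([spec.fitness.get(g, 1.0) for g in grnas])
    # endpoint odds proportional to the normalized Day-0 frequency (the
    # quantity the model conditions on) times the per-guide fitness
    end_p = day0_freq * fitness
    end_p = end_p / end_p.sum()
    assignment = rng.choice(k, size=spec.n_cells, p=end_p)

    # QC covariates: ~90% of cells pass all four strict criteria
    n_genes = rng.normal(3500, 1200, spec.n_cells).clip(0).astype(int)
    n_umis = (n_genes * rng.uniform(2.5, 3.5, spec.n_cells)).astype(int)
    mito = rng.gamma(shape=2.0, scale=2.2, size=spec.n_cells)
    is_doublet = rng.random(spec.n_cells) < spec.doublet_rate
    second = rng.choice(k, size=spec.n_cells, p=end_p)

    primary = [grnas[i] for i in assignment]
    ids = list(primary)
    assigned = [[p] for p in primary]
    for i in np.flatnonzero(is_doublet):
        q = grnas[second[i]]
        ids[i] = f"{ids[i]};{q}"
        assigned[i] = [primary[i], q]
    cells = pd.DataFrame(
        {
            "barcode": [f"CELL{i:06d}" for i in range(spec.n_cells)],
            "grna_ids": ids,
            "n_genes": n_genes,
            "n_umis": n_umis,
            "mito_pct": np.clip(mito, 0, 100),
        }
    )
    cells["assigned_grnas"] = assigned
    grna_map = pd.DataFrame(
        {
            "gene": [f"GENE_{g}" for g in targets] + ["non-targeting"] * len(controls),
            "is_control": [False] * len(targets) + [True] * len(controls),
        },
        index=pd.Index(grnas, name="grna"),
    )
    truth = {
        "fitness": {g: spec.fitness.get(g, 1.0) for g in grnas},
        "log2_odds": {
            g: (np.log2(w) if w > 0 else -np.inf)
            for g, w in ((g, spec.fitness.get(g, 1.0)) for g in grnas)
        },
        "day0_freq": pd.Series(day0_freq, index=grnas),
    }
    return cells, day0_counts, grna_map, truth
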