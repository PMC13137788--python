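"""Readers, writers and validated in-memory containers for every table the
pipeline touches.

Somatic mutation tables come in two dialects: full TCGA-style MAF (columns
``Hugo_Symbol`` / ``Tumor_Sample_Barcode`` / ``Variant_Classification``) and
minimal TSV exports with lower-case names (``gene`` / ``sample_id`` /
``variant_class``).  Both are accepted through a synonym map.  Variant-class
vocabulary is normalized to the four-way split {silent, nonsilent, noncoding,
unknown}; the non-silent set is what feeds burden ratios and significance
testing downstream.

Mutation-free samples are invisible in a MAF, so cohort size defaults to the
number of distinct sample identifiers seen; an optional sample manifest
supplies the true denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

COHORTS = ("healthy", "tumor")

#: Functional category after normalization.
VARIANT_CATEGORIES = ("silent", "nonsilent", "noncoding", "unknown")

# Default dialect table.  Keys are lower-cased before lookup, so entries
# cover both ANNOVAR-style exonic labels and MAF Variant_Classification
# values with a single spelling.
DEFAULT_CLASS_MAP: dict[str, str] = {
    # ANNOVAR exonic function labels
    "nonsynonymous": "nonsilent",
    "nonsynonymous snv": "nonsilent",
    "synonymous": "silent",
    "synonymous snv": "silent",
    "stopgain": "nonsilent",
    "stoploss": "nonsilent",
    "frameshift": "nonsilent",
    "frameshift insertion": "nonsilent",
    "frameshift deletion": "nonsilent",
    "nonframeshift": "nonsilent",
    "nonframeshift insertion": "nonsilent",
    "nonframeshift deletion": "nonsilent",
    # MAF Variant_Classification values
    "missense_mutation": "nonsilent",
    "nonsense_mutation": "nonsilent",
    "nonstop_mutation": "nonsilent",
    "silent": "silent",
    "frame_shift_ins": "nonsilent",
    "frame_shift_del": "nonsilent",
    "in_frame_ins": "nonsilent",
    "in_frame_del": "nonsilent",
    "splice_site": "nonsilent",
    "translation_start_site": "nonsilent",
    # already-normalized categories (identity, for round-trips; "silent"
    # is covered by the MAF entry above)
    "nonsilent": "nonsilent",
    "noncoding": "noncoding",
    # noncoding
    "intron": "noncoding",
    "intronic": "noncoding",
    "3'utr": "noncoding",
    "5'utr": "noncoding",
    "3'flank": "noncoding",
    "5'flank": "noncoding",
    "utr3": "noncoding",
    "utr5": "noncoding",
    "igr": "noncoding",
    "intergenic": "noncoding",
    "rna": "noncoding",
    "upstream": "noncoding",
    "downstream": "noncoding",
    "ncrna_exonic": "noncoding",
    "ncrna_intronic": "noncoding",
}

# Column-name synonyms, checked in order.
_COLUMN_SYNONYMS = {
    "sample_id": ("Tumor_Sample_Barcode", "sample_id", "Sample_ID", "sample"),
    "gene": ("Hugo_Symbol", "gene", "Gene", "gene_symbol"),
    "variant_class": (
        "Variant_Classification",
        "variant_class",
        "variant_classification",
        "ExonicFunc",
    ),
}


class SchemaError(ValueError):
    """A required column is missing or a table violates its contract."""


class ParseError(ValueError):
    """A cell value cannot be interpreted."""


def normalize_variant_class(
    raw: str,
    class_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> str:
    """Map a raw variant-classification label to one of
    {silent, nonsilent, noncoding, unknown}.

    Matching is case-insensitive on the whitespace-trimmed label.  Unmapped
    labels yield ``"unknown"`` unless ``strict`` is set, in which case a
    :class:`ParseError` is raised naming the offending value.
    """
    table = DEFAULT_CLASS_MAP if class_map is None else class_map
    key = str(raw).strip().lower()
    out = table.get(key, "unknown")
    if out == "unknown" and strict:
        raise ParseError(f"unknown variant class: {raw!r}")
    return out


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    variant_class: str  # normalized category
    cohort: str
    tissue: str

    def __post_init__(self):
        if not self.sample_id or not self.gene:
            raise SchemaError("sample_id and gene must be non-empty")
        if self.variant_class not in VARIANT_CATEGORIES:
            raise ParseError(f"unnormalized variant class: {self.variant_class!r}")
        if self.cohort not in COHORTS:
            raise SchemaError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")


@dataclass
class MutationCatalog:
    """Per-sample, per-gene somatic mutation records for one cohort.

    ``n_samples`` is the cohort denominator: manifest size when a sample
    manifest was supplied, otherwise the number of distinct sample ids seen
    in the records.
    """

    records: list[MutationRecord]
    n_samples: int
    tissue: str
    cohort: str

    def __post_init__(self):
        seen = {r.sample_id for r in self.records}
        if self.n_samples < len(seen):
            raise SchemaError(
                f"n_samples={self.n_samples} below distinct sample count {len(seen)}"
            )
        for r in self.records:
            if r.cohort != self.cohort:
                raise SchemaError(
                    f"record cohort {r.cohort!r} does not match catalog {self.cohort!r}"
                )

    def nonsilent_counts(self) -> dict[str, int]:
        """Per-gene count of nonsilent mutations."""
        out: dict[str, int] = {}
        for r in self.records:
            if r.variant_class == "nonsilent":
                out[r.gene] = out.get(r.gene, 0) + 1
        return out

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in VARIANT_CATEGORIES}
        for r in self.records:
            out[r.variant_class] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "variant_class": [r.variant_class for r in self.records],
            }
        )


@dataclass
class GeneLengthTable:
    """Gene symbol -> coding length in bases (positive integers)."""

    lengths: dict[str, int]

    def __post_init__(self):
        for g, L in self.lengths.items():
            if L <= 0:
                raise SchemaError(f"non-positive length {L} for gene {g!r}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths

    def __getitem__(self, gene: str) -> int:
        return self.lengths[gene]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @property
    def genes(self) -> list[str]:
        return list(self.lengths)


@dataclass
class DependenceMatrix:
    """Gene x cell-line grid of CRISPR dependence scores.

    Scores follow the probability-of-dependency convention: values in [0, 1],
    higher meaning the line depends more strongly on the gene.  Missing
    values are NaN.  ``lineages`` labels each cell line with its lineage /
    cancer type so that lineage-matched means can be taken.
    """

    scores: pd.DataFrame  # genes as index, lines as columns
    lineages: dict[str, str] = field(default_factory=dict)  # line -> lineage

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.columns)

    def lines_for_lineage(self, lineage: str) -> list[str]:
        lines = [c for c in self.scores.columns if self.lineages.get(c) == lineage]
        if not lines:
            avail = sorted(set(self.lineages.values()))
            raise KeyError(
                f"no cell line with lineage {lineage!r}; available: {avail}"
            )
        return lines


@dataclass
class SLPairSet:
    """Unordered, deduplicated synthetic-lethal gene pairs."""

    pairs: set[frozenset]
    universe: set[str] | None = None

    def __post_init__(self):
        for p in self.pairs:
            if len(p) != 2:
                raise SchemaError(f"self-pair or malformed pair: {set(p)}")

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out |= p
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def _resolve_columns(df: pd.DataFrame) -> dict[str, str]:
    resolved = {}
    for canon, synonyms in _COLUMN_SYNONYMS.items():
        for s in synonyms:
            if s in df.columns:
                resolved[canon] = s
                break
        else:
            raise SchemaError(
                f"required column {canon!r} not found "
                f"(accepted names: {', '.join(synonyms)})"
            )
    return resolved


def read_maf(
    path: str | Path,
    cohort: str,
    tissue: str,
    sample_manifest: str | Path | None = None,
    class_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> MutationCatalog:
    """Read a MAF-like mutation table into a :class:`MutationCatalog`.

    Accepts both TCGA-MAF and minimal-TSV column names.  Variant classes are
    normalized on read; unknown labels are kept as ``unknown`` records (they
    never enter downstream counts) and their number is logged, unless
    ``strict`` escalates them to errors.
    """
    if cohort not in COHORTS:
        raise SchemaError(f"cohort must be one of {COHORTS}, got {cohort!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise SchemaError(f"empty mutation file: {path}")
    cols = _resolve_columns(df)
    records = []
    n_unknown = 0
    for _, row in df.iterrows():
        vc = normalize_variant_class(row[cols["variant_class"]], class_map, strict)
        if vc == "unknown":
            n_unknown += 1
        records.append(
            MutationRecord(
                sample_id=str(row[cols["sample_id"]]).strip(),
                gene=str(row[cols["gene"]]).strip(),
                variant_class=vc,
                cohort=cohort,
                tissue=tissue,
            )
        )
    if n_unknown:
        logger.info("read_maf: %d records with unknown variant class", n_unknown)
    if sample_manifest is not None:
        manifest = [
            line.strip()
            for line in Path(sample_manifest).read_text().splitlines()
            if line.strip()
        ]
        n_samples = len(set(manifest))
    else:
        n_samples = len({r.sample_id for r in records})
        logger.info(
            "read_maf: no manifest; using %d distinct sample ids as cohort size",
            n_samples,
        )
    return MutationCatalog(records=records, n_samples=n_samples, tissue=tissue, cohort=cohort)


def write_maf(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalog back out as a minimal TSV (gene, sample_id,
    variant_class with normalized labels)."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    """Read a 2-column TSV (gene, length_bp) into a length table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError("gene length table needs two columns (gene, length_bp)")
    gcol, lcol = df.columns[:2]
    lengths: dict[str, int] = {}
    for i, row in df.iterrows():
        gene = str(row[gcol]).strip()
        try:
            L = int(row[lcol])
        except (TypeError, ValueError):
            raise ParseError(f"non-integer length at row {i}: {row[lcol]!r}") from None
        if L <= 0:
            raise SchemaError(f"non-positive length {L} for gene {gene!r} (row {i})")
        if gene in lengths:
            raise SchemaError(f"duplicate gene in length table: {gene!r}")
        lengths[gene] = L
    return GeneLengthTable(lengths)


def write_gene_lengths(table: GeneLengthTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(table.lengths), "length_bp": list(table.lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_dependence(
    path: str | Path, lineages: Mapping[str, str] | None = None
) -> DependenceMatrix:
    """Read a dependence-score TSV: genes in the first column, one column
    per cell line.  Non-numeric cells raise a :class:`ParseError` with the
    row number; empty cells are missing values.

    Cell-line lineage labels may be embedded in the header as
    ``LINE|LINEAGE`` or supplied via ``lineages``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    line_lineage: dict[str, str] = dict(lineages or {})
    rename = {}
    for col in df.columns:
        if "|" in col:
            line, lineage = col.split("|", 1)
            rename[col] = line
            line_lineage.setdefault(line, lineage)
    df = df.rename(columns=rename)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.to_numpy().argmax())
            raise ParseError(
                f"non-numeric dependence score in column {col!r}, row {row}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = coerced
    return DependenceMatrix(scores=df.astype(float), lineages=line_lineage)


def write_dependence(dep: DependenceMatrix, path: str | Path) -> None:
    out = dep.scores.copy()
    out.columns = [
        f"{c}|{dep.lineages[c]}" if c in dep.lineages else c for c in out.columns
    ]
    out.to_csv(path, sep="\t")


def read_sl_pairs(path: str | Path) -> SLPairSet:
    """Read a 2-column TSV of synthetic-lethal gene pairs.

    Pairs are stored order-invariantly ((A,B) == (B,A)) and deduplicated;
    self-pairs are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise SchemaError("SL pair file needs two gene columns")
    a_col, b_col = df.columns[:2]
    pairs: set[frozenset] = set()
    n_self = 0
    for _, row in df.iterrows():
        a, b = str(row[a_col]).strip(), str(row[b_col]).strip()
        if a == b:
            n_self += 1
            continue
        pairs.add(frozenset((a, b)))
    if n_self:
        logger.warning("read_sl_pairs: dropped %d self-pairs", n_self)
    return SLPairSet(pairs=pairs)


def write_sl_pairs(sl: SLPairSet, path: str | Path) -> None:
    rows = sorted(tuple(sorted(p)) for p in sl.pairs)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_screen_cells(path: str | Path) -> pd.DataFrame:
    """Read a per-cell screen table: barcode, grna_ids (semicolon-joined),
    n_genes, n_umis, mito_pct.  Returns a frame with ``assigned_grnas`` as
    lists."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "grna_ids": str})
    required = {"barcode", "grna_ids", "n_genes", "n_umis", "mito_pct"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"screen cell table missing columns: {sorted(missing)}")
    df["assigned_grnas"] = [
        [] if pd.isna(v) or not str(v).strip() else str(v).split(";")
        for v in df["grna_ids"]
    ]
    if ((df["mito_pct"] < 0) | (df["mito_pct"] > 100)).any():
        raise SchemaError("mito_pct outside [0, 100]")
    return df


def read_day0_counts(path: str | Path) -> pd.Series:
    """Read Day-0 gRNA counts: 2-column TSV (grna, count)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise SchemaError("Day-0 count table needs two columns (grna, count)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    if (s < 0).any():
        raise SchemaError("negative Day-0 count")
    return s.astype(float)


def read_grna_map(path: str | Path) -> pd.DataFrame:
    """Read the gRNA map: TSV with columns grna, gene, is_control."""
    df = pd.read_csv(path, sep="\t", dtype={"grna": str, "gene": str})
    required = {"grna", "gene", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"gRNA map missing columns: {sorted(missing)}")
    df["is_control"] = df["is_control"].astype(bool)
    return df.set_index("grna")


def build_catalog(
    rows: Iterable[tuple[str, str, str]],
    cohort: str,
    tissue: str,
    n_samples: int | None = None,
    class_map: Mapping[str, str] | None = None,
) -> MutationCatalog:
    """Build a catalog from (sample_id, gene, raw_variant_class) triples.

    Convenience constructor used by the simulators and by tests.
    """
    records = [
        MutationRecord(
            sample_id=s,
            gene=g,
            variant_class=normalize_variant_class(vc, class_map),
            cohort=cohort,
            tissue=tissue,
        )
        for s, g, vc in rows
    ]
    if n_samples is None:
        n_samples = len({r.sample_id for r in records})
    return MutationCatalog(records=records, n_samples=n_samples, tissue=tissue, cohort=cohort)
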