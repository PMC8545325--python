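"""Reading, validating and filtering per-time-point differential-expression tables.

The pipeline consumes DE results (log2 fold change + adjusted p-value per
gene per time point) produced upstream by limma/DESeq2-style contrasts of
each time point against baseline.  Two analysis modes exist: *combined*
pools miRNA and mRNA gene lists per time point, *separate* keeps the two
gene types apart.  Significance filtering is per time point, independent of
every other time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_TYPES = ("miRNA", "mRNA")
COMBINED = "combined"
SEPARATE = "separate"


class DataIngestError(ValueError):
    """Malformed DE table, ID map or invalid filter parameters."""


@dataclass(frozen=True)
class TimeCourseDE:
    """Long-form DE result set with an ordered time-point axis.

    ``table`` has columns ``gene``, ``gene_type``, ``time_point``,
    ``log2fc``, ``padj``; every (gene, gene_type, time_point) triple is
    unique, every time point is a member of ``time_points``.
    """

    table: pd.DataFrame
    time_points: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"gene", "gene_type", "time_point", "log2fc", "padj"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataIngestError(f"DE table missing columns: {sorted(missing)}")
        if len(self.time_points) == 0:
            raise DataIngestError("time_points must be non-empty")
        bad_tp = set(self.table["time_point"]) - set(self.time_points)
        if bad_tp:
            raise DataIngestError(f"records reference undeclared time points: {sorted(bad_tp)}")
        dup = self.table.duplicated(subset=["gene", "gene_type", "time_point"])
        if dup.any():
            first = self.table.loc[dup, ["gene", "gene_type", "time_point"]].iloc[0]
            raise DataIngestError(
                f"duplicate record for gene={first['gene']!r} type={first['gene_type']} "
                f"time_point={first['time_point']}"
            )
        if not np.isfinite(self.table["log2fc"].to_numpy(dtype=float)).all():
            raise DataIngestError("non-finite log2fc values present")
        padj = self.table["padj"].to_numpy(dtype=float)
        if not ((padj >= 0) & (padj <= 1)).all():
            raise DataIngestError("padj values must lie in [0, 1]")

    @property
    def records(self) -> pd.DataFrame:
        return self.table

    def genes(self, gene_type: str | None = None) -> set[str]:
        t = self.table
        if gene_type is not None:
            t = t[t["gene_type"] == gene_type]
        return set(t["gene"])

    def trajectory(self, gene: str, gene_type: str, value: str = "log2fc") -> np.ndarray:
        """Value vector for one gene across ``time_points`` (NaN where absent)."""
        sub = self.table[(self.table["gene"] == gene) & (self.table["gene_type"] == gene_type)]
        lookup = dict(zip(sub["time_point"], sub[value]))
        return np.array([lookup.get(tp, np.nan) for tp in self.time_points], dtype=float)

    def wide(self, value: str = "log2fc", gene_type: str | None = None) -> pd.DataFrame:
        """Genes x time-points matrix of ``value``, columns in course order."""
        t = self.table
        if gene_type is not None:
            t = t[t["gene_type"] == gene_type]
        w = t.pivot_table(index="gene", columns="time_point", values=value, aggfunc="first")
        return w.reindex(columns=list(self.time_points))

    def concat(self, other: "TimeCourseDE") -> "TimeCourseDE":
        if tuple(other.time_points) != tuple(self.time_points):
            raise DataIngestError("cannot concatenate DE sets with differing time-point axes")
        return TimeCourseDE(
            pd.concat([self.table, other.table], ignore_index=True), self.time_points
        )


@dataclass(frozen=True)
class IDMap:
    """Identifier mapping: input label -> entrez / ensembl / adjusted label.

    ``table`` columns: ``input_label``, ``gene_type``, ``entrez``,
    ``ensembl``, ``adjusted_label``.  Absent mappings are pd.NA.  Adjusted
    labels are unique per gene type and preserve miRNA -3p/-5p suffixes, so
    both arms of a miRNA stay distinct in networks even when their mapped
    entrez/ensembl IDs coincide.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"input_label", "gene_type", "entrez", "ensembl", "adjusted_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataIngestError(f"ID map missing columns: {sorted(missing)}")
        for gt, sub in self.table.groupby("gene_type"):
            if sub["adjusted_label"].duplicated().any():
                raise DataIngestError(f"adjusted labels not unique within gene type {gt}")

    def to_namespace(self, labels: Iterable[str], namespace: str) -> dict[str, str]:
        """Map input labels to IDs in ``namespace`` ('entrez'|'ensembl'); unmapped labels omitted."""
        if namespace not in ("entrez", "ensembl"):
            raise DataIngestError(f"unknown namespace {namespace!r}")
        sub = self.table.dropna(subset=[namespace])
        lut = dict(zip(sub["input_label"], sub[namespace]))
        return {lab: lut[lab] for lab in labels if lab in lut}

    def adjusted(self, label: str) -> str:
        sub = self.table[self.table["input_label"] == label]
        if sub.empty:
            return label
        return str(sub["adjusted_label"].iloc[0])


@dataclass(frozen=True)
class SignificantSets:
    """Per-context significant gene sets after the padj <= alpha filter.

    In combined mode ``sets`` maps time_point -> pooled miRNA+mRNA label
    set; in separate mode it maps (time_point, gene_type) -> label set.
    ``all_genes`` records every gene present in the source DE data (the
    default enrichment universe).
    """

    sets: Mapping
    mode: str
    alpha: float
    time_points: tuple[str, ...]
    all_genes: Mapping[str, frozenset] = field(default_factory=dict)

    def contexts(self) -> list:
        return list(self.sets.keys())


def read_de_table(
    path,
    gene_type: str,
    time_points: Iterable[str],
) -> TimeCourseDE:
    """Read one tab-separated DE table (wide or long dialect).

    Wide dialect: first column is the gene label, then one
    ``log2fc_<tp>`` and one ``padj_<tp>`` column per declared time point.
    Long dialect: columns ``gene``, ``time_point``, ``log2fc``, ``padj``.
    """
    if gene_type not in GENE_TYPES:
        raise DataIngestError(f"gene_type must be one of {GENE_TYPES}, got {gene_type!r}")
    time_points = tuple(time_points)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns.size == 0:
        raise DataIngestError(f"{path}: empty table")

    if "time_point" in raw.columns:  # long dialect
        need = {"gene", "time_point", "log2fc", "padj"}
        missing = need - set(raw.columns)
        if missing:
            raise DataIngestError(f"{path}: long-format table missing columns {sorted(missing)}")
        long = raw[["gene", "time_point", "log2fc", "padj"]].copy()
        long = long[long["time_point"].isin(time_points)]
    else:  # wide dialect
        gene_col = raw.columns[0]
        if raw[gene_col].duplicated().any():
            dup = raw.loc[raw[gene_col].duplicated(), gene_col].iloc[0]
            raise DataIngestError(f"{path}: duplicate gene label {dup!r}")
        frames = []
        for tp in time_points:
            for kind in ("log2fc", "padj"):
                col = f"{kind}_{tp}"
                if col not in raw.columns:
                    raise DataIngestError(f"{path}: missing column {col!r}")
            frames.append(
                pd.DataFrame(
                    {
                        "gene": raw[gene_col],
                        "time_point": tp,
                        "log2fc": raw[f"log2fc_{tp}"],
                        "padj": raw[f"padj_{tp}"],
                    }
                )
            )
        long = pd.concat(frames, ignore_index=True)

    for col in ("log2fc", "padj"):
        converted = pd.to_numeric(long[col], errors="coerce")
        bad = converted.isna() & long[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DataIngestError(
                f"{path}: non-numeric {col} value {long[col].iloc[row]!r} (row {row + 1})"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise DataIngestError(f"{path}: missing {col} value (row {row + 1})")
        long[col] = converted

    long["gene_type"] = gene_type
    long = long[["gene", "gene_type", "time_point", "log2fc", "padj"]]
    return TimeCourseDE(long.reset_index(drop=True), time_points)


def write_de_table(de: TimeCourseDE, path, gene_type: str) -> None:
    """Write one gene type back to the wide tab-separated dialect."""
    cols = {"gene": sorted(de.genes(gene_type))}
    out = pd.DataFrame(cols)
    for value in ("log2fc", "padj"):
        w = de.wide(value=value, gene_type=gene_type)
        for tp in de.time_points:
            out[f"{value}_{tp}"] = w.reindex(out["gene"])[tp].to_numpy()
    # interleave columns per time point to match the reader's contract
    ordered = ["gene"]
    for tp in de.time_points:
        ordered += [f"log2fc_{tp}", f"padj_{tp}"]
    out[ordered].to_csv(path, sep="\t", index=False, float_format="%.10g")


def filter_significant(de: TimeCourseDE, mode: str = COMBINED, alpha: float = 0.05) -> SignificantSets:
    """Per-time-point significance filter (padj <= alpha, inclusive boundary).

    Combined mode pools the two gene types into one label set per time
    point; separate mode keys sets by (time point, gene type).
    """
    if not (0 < alpha <= 1):
        raise DataIngestError(f"alpha must be in (0, 1], got {alpha}")
    if mode not in (COMBINED, SEPARATE):
        raise DataIngestError(f"mode must be 'combined' or 'separate', got {mode!r}")
    hits = de.table[de.table["padj"] <= alpha]
    sets: dict = {}
    if mode == COMBINED:
        for tp in de.time_points:
            sets[tp] = frozenset(hits.loc[hits["time_point"] == tp, "gene"])
    else:
        for tp in de.time_points:
            for gt in GENE_TYPES:
                sel = (hits["time_point"] == tp) & (hits["gene_type"] == gt)
                sets[(tp, gt)] = frozenset(hits.loc[sel, "gene"])
    if all(len(s) == 0 for s in sets.values()):
        logger.warning("no gene passed padj <= %g at any time point", alpha)
    all_genes = {gt: frozenset(de.genes(gt)) for gt in GENE_TYPES}
    return SignificantSets(sets, mode, alpha, tuple(de.time_points), all_genes)


def map_ids(de: TimeCourseDE, map_table) -> IDMap:
    """Build the ID map covering every (gene, gene_type) in the DE data.

    ``map_table`` is a tab-separated file (input_label, entrez, ensembl).
    Labels without a mapping row keep their input label as adjusted label
    with absent entrez/ensembl.  Two mRNA labels mapping to one entrez are
    both retained with a logged warning (enrichment later de-duplicates by
    mapped ID).
    """
    try:
        m = pd.read_csv(map_table, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise as contract error
        raise DataIngestError(f"cannot read ID map {map_table}: {exc}") from exc
    need = {"input_label", "entrez", "ensembl"}
    missing = need - set(m.columns)
    if missing:
        raise DataIngestError(f"ID map missing columns {sorted(missing)}")
    lut = m.set_index("input_label")

    rows = []
    pairs = de.table[["gene", "gene_type"]].drop_duplicates()
    for gene, gene_type in pairs.itertuples(index=False):
        if gene in lut.index:
            entrez = lut.at[gene, "entrez"]
            ensembl = lut.at[gene, "ensembl"]
        else:
            entrez = ensembl = pd.NA
        rows.append(
            {
                "input_label": gene,
                "gene_type": gene_type,
                "entrez": entrez if pd.notna(entrez) else pd.NA,
                "ensembl": ensembl if pd.notna(ensembl) else pd.NA,
                # input labels are unique per gene type, so they double as
                # adjusted labels: -3p/-5p suffixes survive shared entrez IDs
                "adjusted_label": gene,
            }
        )
    table = pd.DataFrame(rows)
    for gt in GENE_TYPES:
        sub = table[(table["gene_type"] == gt) & table["entrez"].notna()]
        dups = sub[sub["entrez"].duplicated(keep=False)]
        if not dups.empty and gt == "mRNA":
            logger.warning(
                "mRNA labels share entrez IDs: %s", sorted(dups["input_label"])
            )
    return IDMap(table)
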