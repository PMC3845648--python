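"""Read-count normalization (rpkm) and lineage-level aggregation.

rpkm = count / ((length_bp / 1000) * (total_mapped_reads / 1e6)) —
reads per kilobase of transcript (or contig) length per million mapped
reads.  The depth denominator is the sample's total mappable reads as
given in the sample sheet; it is not recomputed from the count table,
since unmapped reads are invisible there.

Lineage expression is the *sum* of member-feature rpkm per sample, with
features left unassigned dropped from the totals; per-condition values
are then arithmetic means across biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleSheet",
    "ExpressionTable",
    "LineageExpression",
    "ValidationReport",
    "compute_rpkm",
    "rpkm_table",
    "aggregate_to_lineage",
    "validate_inputs",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "species_id",
    "photo_type",
    "design",
    "condition",
    "replicate",
    "total_mapped_reads",
]


@dataclass
class SampleSheet:
    """Per-sample metadata: species, C3/C4 type, sampling design
    (``diurnal`` light/dark or developmental ``gradient`` segments A-D),
    replicate index, and total mapped reads (the rpkm depth)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[
                self.frame["sample_id"].duplicated(), "sample_id"
            ].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if (self.frame["total_mapped_reads"] <= 0).any():
            raise ValueError("total_mapped_reads must be positive")
        self.frame = self.frame.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def depth(self, sample_id: str) -> int:
        return int(self.frame.loc[sample_id, "total_mapped_reads"])

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionTable:
    """Raw counts (features x samples) plus per-feature lengths in bp."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.lengths = self.lengths.astype(float)

    @classmethod
    def read_tsv(cls, counts_path, lengths_path) -> "ExpressionTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(
            lengths_path, sep="\t", index_col=0
        ).iloc[:, 0]
        return cls(counts=counts, lengths=lengths)

    def write_tsv(self, counts_path, lengths_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        self.lengths.rename("length_bp").to_csv(
            lengths_path, sep="\t", index_label="feature_id"
        )


def compute_rpkm(count: float, length_bp: float, total_mapped_reads: float) -> float:
    """rpkm of one feature in one sample."""
    if length_bp <= 0:
        raise ValueError(f"length_bp must be positive, got {length_bp}")
    if total_mapped_reads <= 0:
        raise ValueError(
            f"total_mapped_reads must be positive, got {total_mapped_reads}"
        )
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    return count / ((length_bp / 1000.0) * (total_mapped_reads / 1e6))


def rpkm_table(table: ExpressionTable, sheet: SampleSheet) -> pd.DataFrame:
    """Feature x sample rpkm matrix."""
    lengths = table.lengths.reindex(table.counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"features without lengths: {missing}")
    depths = np.array([sheet.depth(s) for s in table.counts.columns], float)
    scale = np.outer(lengths.to_numpy() / 1000.0, depths / 1e6)
    return table.counts.astype(float) / scale


@dataclass
class LineageExpression:
    """Lineage-level rpkm, per replicate and averaged per condition.

    ``per_replicate`` columns: family_id, lineage_id, species_id,
    condition, replicate, rpkm.  ``means`` columns: family_id,
    lineage_id, species_id, condition, mean_rpkm.
    """

    per_replicate: pd.DataFrame
    means: pd.DataFrame
    unassigned_rpkm: float = 0.0

    def mean_rpkm(
        self, family_id: str, lineage_id: str, species_id: str, condition: str
    ) -> float:
        m = self.means
        sel = m[
            (m["family_id"] == family_id)
            & (m["lineage_id"] == lineage_id)
            & (m["species_id"] == species_id)
            & (m["condition"] == condition)
        ]
        if sel.empty:
            raise KeyError(
                f"no expression for {family_id}/{lineage_id} "
                f"in {species_id} {condition}"
            )
        return float(sel["mean_rpkm"].iloc[0])

    def write_tsv(self, path) -> None:
        merged = self.per_replicate.merge(
            self.means,
            on=["family_id", "lineage_id", "species_id", "condition"],
            how="left",
        )
        merged.to_csv(path, sep="\t", index=False)


def aggregate_to_lineage(
    table: ExpressionTable,
    sheet: SampleSheet,
    assignment: dict[str, tuple[str, str]],
) -> LineageExpression:
    """Sum member-feature rpkm per lineage per sample, then average over
    replicates within each (species, condition).

    ``assignment`` maps feature_id -> (family_id, lineage_id); features
    mapped to the sentinel ``UNASSIGNED`` lineage (or absent from the
    mapping) are excluded, and their total rpkm is reported on the result
    for transparency.
    """
    from .delimit import UNASSIGNED

    missing = [f for f in assignment if f not in table.counts.index]
    if missing:
        raise ValueError(
            f"assigned features missing from count table: {sorted(missing)}"
        )

    rpkm = rpkm_table(table, sheet)
    assigned_rows = []
    unassigned_total = 0.0
    for feature, (family, lineage) in assignment.items():
        if lineage == UNASSIGNED:
            unassigned_total += float(rpkm.loc[feature].sum())
            continue
        assigned_rows.append((feature, family, lineage))

    records = []
    meta = sheet.frame
    for family, lineage in sorted({(f, l) for _, f, l in assigned_rows}):
        features = [ft for ft, f, l in assigned_rows if (f, l) == (family, lineage)]
        lineage_rpkm = rpkm.loc[features].sum(axis=0)
        for sample_id, value in lineage_rpkm.items():
            row = meta.loc[sample_id]
            records.append(
                {
                    "family_id": family,
                    "lineage_id": lineage,
                    "species_id": row["species_id"],
                    "condition": row["condition"],
                    "replicate": row["replicate"],
                    "rpkm": float(value),
                }
            )
    per_replicate = pd.DataFrame(
        records,
        columns=[
            "family_id",
            "lineage_id",
            "species_id",
            "condition",
            "replicate",
            "rpkm",
        ],
    )
    if per_replicate.empty:
        means = pd.DataFrame(
            columns=["family_id", "lineage_id", "species_id", "condition", "mean_rpkm"]
        )
    else:
        means = (
            per_replicate.groupby(
                ["family_id", "lineage_id", "species_id", "condition"],
                as_index=False,
            )["rpkm"]
            .mean()
            .rename(columns={"rpkm": "mean_rpkm"})
        )
    return LineageExpression(
        per_replicate=per_replicate,
        means=means,
        unassigned_rpkm=unassigned_total,
    )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(table: ExpressionTable, sheet: SampleSheet) -> ValidationReport:
    """Consistency checks run before the pipeline proceeds; hard errors
    (missing lengths, unknown samples, duplicate features, negative
    counts) block downstream stages."""
    report = ValidationReport()
    idx = table.counts.index
    if idx.duplicated().any():
        dups = idx[idx.duplicated()].tolist()
        report.errors.append(f"duplicated feature rows: {dups}")
    no_length = [f for f in idx if f not in table.lengths.index]
    if no_length:
        report.errors.append(f"features without lengths: {no_length}")
    unknown = [s for s in table.counts.columns if s not in set(sheet.sample_ids)]
    if unknown:
        report.errors.append(f"samples absent from sample sheet: {unknown}")
    if (table.counts.to_numpy() < 0).any():
        report.errors.append("negative counts present")
    unused = [s for s in sheet.sample_ids if s not in table.counts.columns]
    if unused:
        report.warnings.append(f"sheet samples without counts: {unused}")
    return report
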