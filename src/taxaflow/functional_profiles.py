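"""RPKM arithmetic and functional-profile transformations.

The operations here sit between the raw stratified tables and everything a
pathway-level figure shows: replicate aggregation into per-treatment columns,
subsetting a table to one KEGG pathway's EC inventory, counting detected
functions, per-gene contribution percentages, per-treatment pathway totals
(mean ± standard error over replicates) and optional noise filtering of very
low RPKM entries.

RPKM = reads / ((gene length / 1e3) * (library size / 1e6)); detection uses
strict > 0 since the RPKM of a genuinely present function cannot be exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    PathwayPanel,
    SampleMetadata,
    StratifiedTable,
    UnstratifiedTable,
)

__all__ = [
    "RpkmParams",
    "compute_rpkm",
    "to_unstratified",
    "sum_replicates",
    "subset_pathway",
    "detected_function_count",
    "contribution_percentages",
    "mean_total_rpkm",
    "noise_filter",
]


@dataclass(frozen=True)
class RpkmParams:
    gene_length_bp: int
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.gene_length_bp <= 0:
            raise ValueError("gene_length_bp must be positive")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")


def compute_rpkm(read_count: int | float, params: RpkmParams) -> float:
    """Reads Per Kilobase per Million mapped reads."""
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count / (
        (params.gene_length_bp / 1_000) * (params.total_mapped_reads / 1_000_000)
    )


def to_unstratified(table: StratifiedTable) -> UnstratifiedTable:
    """Sum each function over its contributing taxa."""
    return UnstratifiedTable(table.data.groupby(level="function_id", sort=False).sum())


def sum_replicates(
    table: StratifiedTable | UnstratifiedTable, metadata: SampleMetadata
):
    """Sum replicate columns into one column per treatment (the aggregate
    table with one sample column per soil type).  Grand total is preserved."""
    df = table.data
    missing = set(df.columns) - set(metadata.sample_ids)
    if missing:
        raise ValueError(f"columns not in metadata: {sorted(missing)}")
    out = pd.DataFrame(index=df.index)
    for t in metadata.treatments:
        cols = [s for s in metadata.samples_of(t) if s in df.columns]
        if cols:
            out[t] = df[cols].sum(axis=1)
    return type(table)(out)


def subset_pathway(table, panel: PathwayPanel):
    """Keep only rows whose EC number belongs to the panel."""
    df = table.data
    if isinstance(table, StratifiedTable):
        keep = df.index.get_level_values("function_id").isin(panel.ec_list)
    else:
        keep = df.index.isin(panel.ec_list)
    return type(table)(df[keep])


def detected_function_count(table, panel: PathwayPanel) -> tuple[int, int]:
    """(number of panel ECs with RPKM > 0 in any sample, panel size)."""
    sub = subset_pathway(table, panel)
    df = sub.data
    if isinstance(sub, StratifiedTable):
        by_ec = df.groupby(level="function_id", sort=False).sum()
    else:
        by_ec = df
    detected = int((by_ec.sum(axis=1) > 0).sum())
    return detected, len(panel.ec_list)


def contribution_percentages(table, panel: PathwayPanel) -> pd.Series:
    """Percent of total pathway RPKM contributed by each gene symbol.

    A gene's RPKM is the sum over its EC rows, all taxa and all samples.
    Panel fixtures keep EC -> symbol a partition (composite symbols such as
    ``narGZHYIV`` group subunits), so the percentages sum to 100.
    """
    sub = subset_pathway(table, panel)
    df = sub.data
    if isinstance(sub, StratifiedTable):
        ec_values = df.groupby(level="function_id", sort=False).sum().sum(axis=1)
    else:
        ec_values = df.sum(axis=1)
    total = float(ec_values.sum())
    if total <= 0:
        raise ValueError("table has zero total RPKM; percentages undefined")
    ec2gene = panel.ec_to_gene()
    by_gene = ec_values.groupby([ec2gene[ec] for ec in ec_values.index]).sum()
    return (by_gene / total * 100.0).sort_values(ascending=False)


def mean_total_rpkm(
    table: StratifiedTable | UnstratifiedTable,
    metadata: SampleMetadata,
    panel: PathwayPanel | None = None,
) -> pd.DataFrame:
    """Per-treatment mean ± standard error of the per-sample pathway-total
    RPKM (columns: mean, se, n; se is NaN for a single replicate)."""
    if panel is not None:
        table = subset_pathway(table, panel)
    totals = table.data.sum(axis=0)
    rows = []
    for t in metadata.treatments:
        cols = [s for s in metadata.samples_of(t) if s in totals.index]
        vals = totals[cols].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append((t, mean, se, n))
    return pd.DataFrame(rows, columns=["treatment", "mean", "se", "n"]).set_index(
        "treatment"
    )


def noise_filter(table, threshold: float):
    """Remove very low RPKM entries: cells below ``threshold`` are zeroed and
    rows left entirely at zero are dropped.  ``threshold=0`` is the identity
    (values are non-negative)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    df = table.data.copy()
    if threshold > 0:
        df[df < threshold] = 0.0
        df = df[(df > 0).any(axis=1)]
    return type(table)(df)
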