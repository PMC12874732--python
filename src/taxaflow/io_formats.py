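"""Readers and writers for every external format the pipeline touches.

All tables are tab-delimited UTF-8 with ``.`` decimals; sequence files are
plain FASTA / FASTQ (Sanger quality encoding) handled through Biopython.
Pathway panels ship as frozen TSV fixtures (gene, EC, process) rather than
live KEGG REST queries, for reproducibility without a network dependency.
"""

from __future__ import annotations

import importlib.resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    PathwayPanel,
    SampleMetadata,
    SoilProperties,
    StratifiedTable,
    TaxonLineage,
    UnstratifiedTable,
)

__all__ = [
    "read_stratified_table",
    "write_stratified_table",
    "read_unstratified_table",
    "write_unstratified_table",
    "read_metadata",
    "write_metadata",
    "read_soil_properties",
    "write_soil_properties",
    "read_assignments",
    "write_assignments",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "load_pathway_panel",
    "read_panel_file",
    "available_panels",
]

PANEL_FIXTURES = {
    "map00910": "panel_map00910.tsv",
    "map00440": "panel_map00440.tsv",
}


# ---------------------------------------------------------------------------
# tabular formats


def read_stratified_table(
    path: str | Path, metadata: SampleMetadata | None = None
) -> StratifiedTable:
    """Read a stratified (function + taxon) RPKM TSV.

    Layout: header row; first two columns ``function_id`` and ``lineage``
    (rank-prefixed, semicolon-delimited); remaining columns are samples.
    When ``metadata`` is given the sample columns must match its ids exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#")
    if df.shape[1] < 2 or list(df.columns[:2]) != ["function_id", "lineage"]:
        raise ValueError(
            "stratified table must start with 'function_id' and 'lineage' columns"
        )
    # canonicalise lineage strings (also validates them)
    df["lineage"] = [TaxonLineage.from_string(s).to_string() for s in df["lineage"]]
    df = df.set_index(["function_id", "lineage"])
    for col in df.columns:
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in sample column {col!r}")
    table = StratifiedTable(df.astype(float))
    if metadata is not None:
        table.validate_against(metadata)
    return table


def write_stratified_table(table: StratifiedTable, path: str | Path) -> None:
    table.data.reset_index().to_csv(path, sep="\t", index=False)


def read_unstratified_table(path: str | Path) -> UnstratifiedTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return UnstratifiedTable(df.astype(float))


def write_unstratified_table(table: UnstratifiedTable, path: str | Path) -> None:
    table.data.reset_index().to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str})
    required = {"sample_id", "treatment", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return SampleMetadata(
        tuple(df["sample_id"]),
        dict(zip(df["sample_id"], df["treatment"])),
        dict(zip(df["sample_id"], df["replicate"].astype(int))),
    )


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.to_frame().to_csv(path, sep="\t", index=False)


def read_soil_properties(path: str | Path) -> SoilProperties:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    return SoilProperties(df.astype(float))


def write_soil_properties(props: SoilProperties, path: str | Path) -> None:
    props.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read a classifier assignment table: read_id, sample_id, lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"read_id", "sample_id", "lineage"}
    if not required.issubset(df.columns):
        raise ValueError(f"assignment table must have columns {sorted(required)}")
    df["lineage"] = [TaxonLineage.from_string(s).to_string() for s in df["lineage"]]
    return df


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence formats


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        if len(quals) != len(rec.seq):  # pragma: no cover - Biopython pre-validates
            raise ValueError(f"record {i}: sequence/quality length mismatch")
        out.append((rec.id, str(rec.seq), quals))
    return out


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    def _records():
        for i, (rid, seq, qual) in enumerate(records):
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {i} ({rid!r}): sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


# ---------------------------------------------------------------------------
# pathway panels


def available_panels() -> tuple[str, ...]:
    return tuple(PANEL_FIXTURES)


def _panel_from_frame(pathway_id: str, df: pd.DataFrame) -> PathwayPanel:
    required = {"gene", "ec", "process"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file must have columns {sorted(required)}")
    gene_map: dict[str, tuple[str, ...]] = {}
    process_map: dict[str, str] = {}
    for gene, sub in df.groupby("gene", sort=False):
        gene_map[gene] = tuple(sub["ec"])
        processes = set(sub["process"])
        if len(processes) > 1:
            raise ValueError(f"gene {gene!r} maps to multiple processes: {processes}")
        process_map[gene] = sub["process"].iloc[0]
    ec_list = frozenset(df["ec"])
    return PathwayPanel(pathway_id, ec_list, gene_map, process_map)


def read_panel_file(path: str | Path, pathway_id: str | None = None) -> PathwayPanel:
    """Read a user-supplied panel TSV with columns gene, ec, process."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return _panel_from_frame(pathway_id or Path(path).stem, df)


def load_pathway_panel(pathway_id: str) -> PathwayPanel:
    """Load a packaged pathway panel (``map00910`` nitrogen metabolism or
    ``map00440`` phosphonate/phosphinate metabolism)."""
    if pathway_id not in PANEL_FIXTURES:
        raise ValueError(
            f"unknown pathway {pathway_id!r}; available panels: "
            f"{', '.join(available_panels())}"
        )
    text = (
        importlib.resources.files("taxaflow.data")
        .joinpath(PANEL_FIXTURES[pathway_id])
        .read_text(encoding="utf-8")
    )
    df = pd.read_csv(StringIO(text), sep="\t", dtype=str, comment="#")
    return _panel_from_frame(pathway_id, df)
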