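"""Core domain containers shared across the pipeline.

The central object is the :class:`StratifiedTable`: a function x taxon x sample
matrix of RPKM values (Reads Per Kilobase per Million mapped reads), the
standard export of stratified functional profilers.  Everything downstream —
pathway subsetting, replicate aggregation, ordination, flow construction —
consumes either this table or one of the light wrappers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "TaxonLineage",
    "SampleMetadata",
    "StratifiedTable",
    "UnstratifiedTable",
    "PathwayPanel",
    "SoilProperties",
]

#: Fixed rank order, domain through species.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Explicit placeholder for a rank the classifier left unassigned.
UNASSIGNED = "unassigned"

_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_RANK = dict(zip(_PREFIXES, RANKS))


@dataclass(frozen=True)
class TaxonLineage:
    """A seven-rank taxonomic lineage with explicit placeholders.

    Lineage strings use the rank-prefixed, semicolon-delimited dialect common
    to classifier exports (``d__Bacteria;p__...;...;s__...``).  All seven
    ranks are always present; a missing rank carries the ``unassigned``
    placeholder rather than being dropped.
    """

    names: tuple[str, ...]  # one name per rank in RANKS order

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"lineage needs {len(RANKS)} rank names, got {len(self.names)}"
            )

    @classmethod
    def from_string(cls, text: str) -> "TaxonLineage":
        """Parse a semicolon-delimited, rank-prefixed lineage string.

        Ranks may be given in any subset, but must appear in canonical order;
        absent ranks become :data:`UNASSIGNED`.
        """
        names = {r: UNASSIGNED for r in RANKS}
        last_idx = -1
        for token in text.split(";"):
            token = token.strip()
            if not token:
                continue
            prefix = token[:3]
            if prefix not in _PREFIX_TO_RANK:
                raise ValueError(f"unknown rank prefix in lineage token {token!r}")
            rank = _PREFIX_TO_RANK[prefix]
            idx = RANKS.index(rank)
            if idx <= last_idx:
                raise ValueError(f"rank order violated at token {token!r} in {text!r}")
            last_idx = idx
            name = token[3:].strip()
            names[rank] = name if name else UNASSIGNED
        return cls(tuple(names[r] for r in RANKS))

    @classmethod
    def from_ranks(cls, **kwargs: str) -> "TaxonLineage":
        """Build a lineage from keyword rank names (e.g. ``genus="Pseudomonas"``)."""
        unknown = set(kwargs) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown ranks: {sorted(unknown)}")
        return cls(tuple(kwargs.get(r, UNASSIGNED) for r in RANKS))

    def to_string(self) -> str:
        return ";".join(p + n for p, n in zip(_PREFIXES, self.names))

    def name(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    @property
    def domain(self) -> str:
        return self.names[0]

    @property
    def phylum(self) -> str:
        return self.names[1]

    @property
    def genus(self) -> str:
        return self.names[5]

    @property
    def species(self) -> str:
        return self.names[6]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass
class SampleMetadata:
    """Sample → (treatment, replicate) design table.

    The reference design is 7 treatment groups x 3 replicates (five organic
    amendments plus unamended Control and undisturbed Natural soils), but any
    design with unique sample ids and non-empty groups is accepted.
    """

    sample_ids: tuple[str, ...]
    treatment: dict[str, str]
    replicate: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        for s in self.sample_ids:
            if s not in self.treatment:
                raise ValueError(f"sample {s!r} has no treatment")
            if self.replicate.get(s, 0) < 1:
                raise ValueError(f"sample {s!r} needs a positive replicate number")

    @classmethod
    def from_design(
        cls, treatments: Sequence[str], n_replicates: int = 3
    ) -> "SampleMetadata":
        """Fully crossed design: ``<treatment>_r<replicate>`` sample ids."""
        ids, trt, rep = [], {}, {}
        for t in treatments:
            for r in range(1, n_replicates + 1):
                sid = f"{t}_r{r}"
                ids.append(sid)
                trt[sid] = t
                rep[sid] = r
        return cls(tuple(ids), trt, rep)

    @property
    def treatments(self) -> tuple[str, ...]:
        """Treatment labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.treatment[s], None)
        return tuple(seen)

    def samples_of(self, treatment: str) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.treatment[s] == treatment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "treatment": [self.treatment[s] for s in self.sample_ids],
                "replicate": [self.replicate[s] for s in self.sample_ids],
            }
        )


def _check_nonnegative(df: pd.DataFrame, what: str) -> None:
    if df.size and (df.to_numpy() < 0).any():
        r, c = np.argwhere(df.to_numpy() < 0)[0]
        raise ValueError(
            f"negative value in {what} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )


@dataclass
class StratifiedTable:
    """Function x taxon x sample RPKM matrix.

    ``data`` is indexed by a two-level MultiIndex ``(function_id, lineage)``
    where ``lineage`` is the canonical seven-rank string; columns are sample
    ids.  Values are non-negative RPKM.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.nlevels != 2:
            raise ValueError("StratifiedTable index must be (function_id, lineage)")
        self.data.index = self.data.index.set_names(["function_id", "lineage"])
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate (function_id, lineage) row: {dup!r}")
        _check_nonnegative(self.data, "stratified table")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def function_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data.index.get_level_values("function_id")))

    def lineages(self) -> list[TaxonLineage]:
        return [
            TaxonLineage.from_string(s)
            for s in self.data.index.get_level_values("lineage")
        ]

    def genus_labels(self) -> pd.Index:
        """Genus name of each row (``unassigned`` where the rank is missing)."""
        return pd.Index(
            [ln.genus for ln in self.lineages()], name="genus"
        )

    def validate_against(self, metadata: SampleMetadata) -> None:
        unknown = set(self.data.columns) - set(metadata.sample_ids)
        if unknown:
            raise ValueError(f"unknown sample columns: {sorted(unknown)}")
        missing = set(metadata.sample_ids) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing sample columns: {sorted(missing)}")

    def total_by_sample(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class UnstratifiedTable:
    """Function x sample (or function x treatment) RPKM matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = self.data.index.rename("function_id")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate function row: {dup!r}")
        _check_nonnegative(self.data, "unstratified table")


@dataclass
class PathwayPanel:
    """EC inventory of one KEGG pathway plus the gene-symbol/process grouping.

    ``gene_map`` maps a gene symbol (possibly a composite like ``narGZHYIV``)
    to one or more EC numbers; ``process_map`` assigns each symbol exactly one
    process label (the figure-level grouping, e.g. ``denitrification``).
    """

    pathway_id: str
    ec_list: frozenset[str]
    gene_map: dict[str, tuple[str, ...]]
    process_map: dict[str, str]

    def __post_init__(self) -> None:
        for gene, ecs in self.gene_map.items():
            for ec in ecs:
                if ec not in self.ec_list:
                    raise ValueError(
                        f"gene {gene!r} references EC {ec!r} outside the panel's EC list"
                    )
        for gene in self.gene_map:
            if gene not in self.process_map:
                raise ValueError(f"gene {gene!r} has no process label")
        for gene in self.process_map:
            if gene not in self.gene_map:
                raise ValueError(f"process entry {gene!r} has no gene_map entry")

    @property
    def processes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.process_map.values()))

    def ec_to_gene(self) -> dict[str, str]:
        """EC → gene symbol.  Panel fixtures keep this a partition so that
        per-symbol contributions sum to 100%."""
        out: dict[str, str] = {}
        for gene, ecs in self.gene_map.items():
            for ec in ecs:
                if ec in out and out[ec] != gene:
                    raise ValueError(
                        f"EC {ec} claimed by both {out[ec]!r} and {gene!r};"
                        " use a composite symbol"
                    )
                out[ec] = gene
        return out

    def process_of_ec(self, ec: str) -> str | None:
        gene = self.ec_to_gene().get(ec)
        return None if gene is None else self.process_map[gene]


@dataclass
class SoilProperties:
    """Per-sample numeric soil measurements (EC, pH, TOC, TN, AP, water
    retention, basal respiration, enzyme activities, bacterial fatty acids).

    Consumed only by the Pearson correlation screen.  Missing values are NaN
    and are excluded pairwise there.
    """

    data: pd.DataFrame  # index: sample_id; columns: property names

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample_id in soil properties")
        non_numeric = [
            c for c in self.data.columns if not pd.api.types.is_numeric_dtype(self.data[c])
        ]
        if non_numeric:
            raise ValueError(f"non-numeric property columns: {non_numeric}")
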