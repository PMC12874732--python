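"""Treatment → genus → process flow construction (Sankey-ready tables).

Selects the most abundant genera per treatment (abundance = summed pathway
RPKM, matching the "proportional to the total sum of RPKM values" weighting
of the flow diagrams), groups gene contributions into metabolic processes via
the pathway panel, and annotates each genus with its coverage-verification
flag so potentially spurious taxonomic labels remain visible downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .coverage_checker import GenusVerdict
from .types import PathwayPanel, StratifiedTable, UNASSIGNED

__all__ = ["FlowTable", "top_n_genera", "build_flows", "annotate_flags"]

UNCLASSIFIED_PROCESS = "unclassified"


@dataclass
class FlowTable:
    """Weighted (treatment, genus, process) edges plus per-genus flags."""

    edges: pd.DataFrame  # columns: treatment, genus, process, weight
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["treatment", "genus", "process", "weight"]
        if list(self.edges.columns[:4]) != required:
            raise ValueError(f"edges must have columns {required}")

    def frame(self) -> pd.DataFrame:
        out = self.edges.copy()
        out["flag"] = out["genus"].map(lambda g: self.flags.get(g, "unverified"))
        return out

    def treatment_total(self, treatment: str) -> float:
        sub = self.edges[self.edges["treatment"] == treatment]
        return float(sub["weight"].sum())


def top_n_genera(
    table: StratifiedTable, n: int = 5
) -> dict[str, list[str]]:
    """Top ``n`` genera per treatment by summed pathway RPKM.

    ``table`` must already be treatment-aggregated (one column per
    treatment) and pathway-subset.  Ties break lexicographically by genus
    name; rows without an assigned genus are excluded; if fewer than ``n``
    genera are present all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    genus = table.genus_labels()
    df = table.data.groupby(genus.to_numpy()).sum()
    df = df[df.index != UNASSIGNED]
    out: dict[str, list[str]] = {}
    for treatment in df.columns:
        ranked = df[treatment].sort_index().sort_values(
            ascending=False, kind="stable"
        )
        ranked = ranked[ranked > 0]
        out[treatment] = list(ranked.index[:n])
    return out


def build_flows(
    table: StratifiedTable,
    panel: PathwayPanel,
    selected: dict[str, list[str]],
    noise_threshold: float = 0.0,
) -> FlowTable:
    """Edge weights: summed RPKM per (treatment, genus, process) over the
    treatment's column, the genus' rows and every gene mapped to the
    process.  Only genera selected for that treatment contribute; edges
    below ``noise_threshold`` are dropped.  Panel ECs without a process
    label are routed to ``unclassified`` with a warning."""
    if noise_threshold < 0:
        raise ValueError("noise_threshold must be non-negative")
    ec2gene = panel.ec_to_gene()
    genus = table.genus_labels().to_numpy()
    ecs = table.data.index.get_level_values("function_id")
    rows = []
    warned: set[str] = set()
    for treatment, genera in selected.items():
        if treatment not in table.data.columns:
            raise ValueError(f"treatment {treatment!r} not a column of the table")
        col = table.data[treatment].to_numpy()
        acc: dict[tuple[str, str], float] = {}
        for value, ec, gn in zip(col, ecs, genus):
            if gn not in genera or ec not in panel.ec_list:
                continue
            gene = ec2gene.get(ec)
            if gene is None:
                process = UNCLASSIFIED_PROCESS
                if ec not in warned:
                    warnings.warn(f"EC {ec} has no process label; routed to "
                                  f"{UNCLASSIFIED_PROCESS!r}")
                    warned.add(ec)
            else:
                process = panel.process_map[gene]
            acc[(gn, process)] = acc.get((gn, process), 0.0) + float(value)
        for (gn, process), weight in sorted(acc.items()):
            if weight > 0 and weight >= noise_threshold:
                rows.append((treatment, gn, process, weight))
    edges = pd.DataFrame(rows, columns=["treatment", "genus", "process", "weight"])
    return FlowTable(edges=edges)


def annotate_flags(flows: FlowTable, verdicts: list[GenusVerdict]) -> FlowTable:
    """Attach coverage-verification flags: ``confirmed`` or
    ``potentially_spurious`` from the verdicts, ``unverified`` for genera the
    verifier never saw."""
    verdict_of = {v.genus: v.flag for v in verdicts}
    flags = {
        g: verdict_of.get(g, "unverified")
        for g in flows.edges["genus"].unique()
    }
    return FlowTable(edges=flows.edges.copy(), flags=flags)
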