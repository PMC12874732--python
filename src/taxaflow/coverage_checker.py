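"""Coverage-based verification of classifier taxonomic assignments.

A read classifier (e.g. Kraken2) can assign reads to species whose genomes
the reads do not actually cover.  This module verifies assignments by mapping
each species' assigned reads back to that species' reference genome and
computing, per species and treatment:

* the number of assigned reads,
* the number and fraction of *confirmed* reads (an exact k-mer seed extended
  to an ungapped alignment at >= 90% identity over >= 80% of the read), and
* the breadth of coverage (fraction of genome positions covered by at least
  one confirmed read).

Genera are then flagged ``potentially_spurious`` unless at least one of their
species, within at least one treatment, reaches 1% genome breadth or — the
rescue clause for rare community members — at least 100 assigned reads with
at least 50% of them confirmed.  Boundary values pass ("at least").

The mapper is a built-in exact-k-mer seed + ungapped extension on both
strands (the verification task needs no gapped or spliced alignment);
externally computed per-read mappings can be supplied instead for real data.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import SampleMetadata, TaxonLineage

__all__ = [
    "MappingParams",
    "Thresholds",
    "ReadMapping",
    "SpeciesCoverage",
    "GenusVerdict",
    "CoverageReport",
    "pool_reads_by_taxon",
    "map_reads",
    "breadth_of_coverage",
    "flag_genera",
    "verify",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MappingParams:
    """Per-read confirmation criterion of the built-in mapper."""

    seed_kmer_length: int = 31
    min_identity: float = 0.90
    min_aligned_fraction_of_read: float = 0.80

    def __post_init__(self) -> None:
        if self.seed_kmer_length < 11:
            raise ValueError("seed_kmer_length must be >= 11")
        for name in ("min_identity", "min_aligned_fraction_of_read"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class Thresholds:
    """Genus-level decision rule thresholds (inclusive)."""

    breadth_min: float = 0.01
    reads_min: int = 100
    confirmed_min: float = 0.50
    #: secondary breadth reported as an annotation only (trace presence)
    fallback_breadth: float = 0.001

    def __post_init__(self) -> None:
        for name in ("breadth_min", "confirmed_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.reads_min < 1:
            raise ValueError("reads_min must be a positive integer")


@dataclass(frozen=True)
class ReadMapping:
    confirmed: bool
    interval: tuple[int, int] | None  # 0-based half-open, forward genome coords


@dataclass
class SpeciesCoverage:
    lineage: str
    treatment: str
    n_assigned_reads: int
    n_confirmed_reads: int
    breadth: float
    genome_length: int
    status: str = "ok"  # ok | unverifiable
    note: str = ""

    @property
    def confirmed_fraction(self) -> float:
        if self.n_assigned_reads == 0:
            return 0.0
        return self.n_confirmed_reads / self.n_assigned_reads

    @property
    def covered_bases(self) -> int:
        return int(round(self.breadth * self.genome_length))

    @property
    def genus(self) -> str:
        return TaxonLineage.from_string(self.lineage).genus

    def passes(self, thresholds: Thresholds) -> bool:
        if self.status != "ok":
            return False
        return self.breadth >= thresholds.breadth_min or (
            self.n_assigned_reads >= thresholds.reads_min
            and self.confirmed_fraction >= thresholds.confirmed_min
        )


@dataclass
class GenusVerdict:
    genus: str
    flag: str  # confirmed | potentially_spurious
    rule_mode: str
    species_results: list[SpeciesCoverage] = field(default_factory=list)

    @property
    def confirmed(self) -> bool:
        return self.flag == "confirmed"


@dataclass
class CoverageReport:
    species: list[SpeciesCoverage]
    verdicts: list[GenusVerdict]

    def species_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lineage": [s.lineage for s in self.species],
                "genus": [s.genus for s in self.species],
                "treatment": [s.treatment for s in self.species],
                "n_assigned_reads": [s.n_assigned_reads for s in self.species],
                "n_confirmed_reads": [s.n_confirmed_reads for s in self.species],
                "confirmed_fraction": [s.confirmed_fraction for s in self.species],
                "breadth": [s.breadth for s in self.species],
                "covered_bases": [s.covered_bases for s in self.species],
                "genome_length": [s.genome_length for s in self.species],
                "status": [s.status for s in self.species],
                "note": [s.note for s in self.species],
            }
        )

    def verdict_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genus": [v.genus for v in self.verdicts],
                "flag": [v.flag for v in self.verdicts],
                "rule_mode": [v.rule_mode for v in self.verdicts],
            }
        )

    def flagged_genera(self) -> set[str]:
        return {v.genus for v in self.verdicts if not v.confirmed}


# ---------------------------------------------------------------------------
# read pooling


def pool_reads_by_taxon(
    assignments: pd.DataFrame, metadata: SampleMetadata
) -> dict[tuple[str, str], set[str]]:
    """Pool assigned read ids per (species lineage, treatment).

    Replicates of a treatment are unioned: the decision rule operates
    "within any one treatment", not per sample.
    """
    unknown = set(assignments["sample_id"]) - set(metadata.sample_ids)
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")
    pools: dict[tuple[str, str], set[str]] = {}
    treatments = assignments["sample_id"].map(metadata.treatment)
    for (lineage, treatment), sub in assignments.groupby(
        [assignments["lineage"], treatments], sort=False
    ):
        pools[(lineage, treatment)] = set(sub["read_id"])
    return pools


# ---------------------------------------------------------------------------
# mapping


class GenomeIndex:
    """Exact k-mer position index over one reference genome."""

    def __init__(self, genome: str, k: int):
        if len(genome) < k:
            raise ValueError("genome shorter than seed k-mer length")
        self.genome = genome
        self.k = k
        self.arr = np.frombuffer(genome.encode(), dtype="S1")
        index: dict[str, list[int]] = {}
        for i in range(len(genome) - k + 1):
            index.setdefault(genome[i : i + k], []).append(i)
        self.index = index

    def seed_positions(self, kmer: str) -> list[int]:
        return self.index.get(kmer, [])


def _map_one(
    read: str, idx: GenomeIndex, params: MappingParams
) -> ReadMapping:
    k = params.seed_kmer_length
    rl = len(read)
    if rl < k:
        return ReadMapping(False, None)
    L = len(idx.arr)
    min_overlap = params.min_aligned_fraction_of_read * rl
    for oriented in (read, _revcomp(read)):
        r_arr = np.frombuffer(oriented.encode(), dtype="S1")
        seen: set[int] = set()
        for o in range(rl - k + 1):
            for p in idx.seed_positions(oriented[o : o + k]):
                a = p - o  # alignment start of the read on the genome
                if a in seen:
                    continue
                seen.add(a)
                g0, g1 = max(0, a), min(L, a + rl)
                overlap = g1 - g0
                if overlap < min_overlap:
                    continue
                matches = int(
                    (idx.arr[g0:g1] == r_arr[g0 - a : g1 - a]).sum()
                )
                if matches / overlap >= params.min_identity:
                    return ReadMapping(True, (g0, g1))
        # strand loop continues; `seen` is per strand since offsets differ
    return ReadMapping(False, None)


def map_reads(
    reads: Sequence[str],
    genome: str,
    params: MappingParams = MappingParams(),
) -> list[ReadMapping]:
    """Map reads to one genome: exact k-mer seed (either strand) extended to
    an ungapped alignment; confirmed iff identity >= ``min_identity`` over
    >= ``min_aligned_fraction_of_read`` of the read length.  Intervals are
    reported in forward genome coordinates, 0-based half-open."""
    if not reads:
        return []
    idx = GenomeIndex(genome, params.seed_kmer_length)
    return [_map_one(r, idx, params) for r in reads]


# ---------------------------------------------------------------------------
# breadth


def breadth_of_coverage(
    intervals: Iterable[tuple[int, int]], genome_length: int
) -> float:
    """|union of intervals| / genome_length; order- and duplication-invariant."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    ivs = sorted(intervals)
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in ivs:
        if s < 0 or e > genome_length or s > e:
            raise ValueError(f"interval ({s}, {e}) out of bounds [0, {genome_length})")
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    if cur_start is not None:
        covered += cur_end - cur_start
    return covered / genome_length


# ---------------------------------------------------------------------------
# decision rule


def flag_genera(
    coverages: Sequence[SpeciesCoverage],
    thresholds: Thresholds = Thresholds(),
    rule_mode: str = "any_species",
) -> list[GenusVerdict]:
    """Aggregate species x treatment coverage rows into genus verdicts.

    ``any_species`` (default): a genus is confirmed iff *some* species passes
    the rule in *some* treatment.  ``all_species``: every assigned species
    must pass in some treatment.  Unverifiable rows (no reference genome)
    never count as passes.
    """
    if rule_mode not in ("any_species", "all_species"):
        raise ValueError(f"unknown rule_mode {rule_mode!r}")
    if not coverages:
        raise ValueError("no species coverage rows; genus verdict undefined")
    by_genus: dict[str, list[SpeciesCoverage]] = {}
    for cov in coverages:
        by_genus.setdefault(cov.genus, []).append(cov)
    verdicts = []
    for genus, rows in by_genus.items():
        ok_rows = [r for r in rows if r.status == "ok"]
        if not ok_rows:
            continue  # entirely unverifiable; reported via species rows
        if rule_mode == "any_species":
            confirmed = any(r.passes(thresholds) for r in ok_rows)
        else:
            species = {r.lineage for r in ok_rows}
            confirmed = all(
                any(r.passes(thresholds) for r in ok_rows if r.lineage == sp)
                for sp in species
            )
        verdicts.append(
            GenusVerdict(
                genus=genus,
                flag="confirmed" if confirmed else "potentially_spurious",
                rule_mode=rule_mode,
                species_results=rows,
            )
        )
    return verdicts


# ---------------------------------------------------------------------------
# end-to-end verification


def verify(
    assignments: pd.DataFrame,
    genomes: Mapping[str, str],
    reads: Mapping[str, Sequence[tuple]],
    metadata: SampleMetadata,
    params: MappingParams = MappingParams(),
    thresholds: Thresholds = Thresholds(),
    rule_mode: str = "any_species",
    precomputed: Mapping[tuple[str, str], Sequence[ReadMapping]] | None = None,
) -> CoverageReport:
    """Run the full verification: pool reads per (species, treatment), map
    them back to the species' reference genome, compute breadth and confirmed
    fractions, and flag genera.

    ``genomes`` maps species-level lineage strings to reference sequences;
    a species without a genome is reported with status ``unverifiable``.
    ``reads`` maps sample_id to ``(read_id, sequence, ...)`` tuples.
    ``precomputed`` optionally supplies externally computed per-read mappings
    keyed by (lineage, treatment), bypassing the built-in mapper.
    """
    pools = pool_reads_by_taxon(assignments, metadata)
    read_seq: dict[str, str] = {}
    for sample_reads in reads.values():
        for rec in sample_reads:
            read_seq[rec[0]] = rec[1]
    indexes: dict[str, GenomeIndex] = {}
    coverages: list[SpeciesCoverage] = []
    for (lineage, treatment), pool in pools.items():
        n_assigned = len(pool)
        genome = genomes.get(lineage)
        if genome is None:
            coverages.append(
                SpeciesCoverage(
                    lineage=lineage,
                    treatment=treatment,
                    n_assigned_reads=n_assigned,
                    n_confirmed_reads=0,
                    breadth=0.0,
                    genome_length=0,
                    status="unverifiable",
                    note="no reference genome",
                )
            )
            continue
        if precomputed is not None and (lineage, treatment) in precomputed:
            mappings = list(precomputed[(lineage, treatment)])
        else:
            if lineage not in indexes:
                indexes[lineage] = GenomeIndex(genome, params.seed_kmer_length)
            idx = indexes[lineage]
            mappings = [_map_one(read_seq[rid], idx, params) for rid in sorted(pool)]
        intervals = [m.interval for m in mappings if m.confirmed]
        breadth = breadth_of_coverage(intervals, len(genome))
        cov = SpeciesCoverage(
            lineage=lineage,
            treatment=treatment,
            n_assigned_reads=n_assigned,
            n_confirmed_reads=len(intervals),
            breadth=breadth,
            genome_length=len(genome),
        )
        if thresholds.fallback_breadth <= breadth < thresholds.breadth_min:
            cov.note = (
                f"exceeds {thresholds.fallback_breadth:.1%} fallback"
                f" ({cov.covered_bases} bases covered)"
            )
        coverages.append(cov)
    verdicts = flag_genera(coverages, thresholds, rule_mode) if coverages else []
    return CoverageReport(species=coverages, verdicts=verdicts)
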