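"""Synthetic community and planted-effect generators.

Every downstream stage of the pipeline (coverage verification, functional
profiling, multivariate statistics, flow construction) is exercised against
data generated here with known ground truth:

* random genomes organised in a genus/species hierarchy, plus *phantom*
  genomes that exist as references but contribute no reads — the scenario a
  coverage-based verifier must catch;
* shotgun reads with a substitution-only error model and a truth table of
  source intervals;
* classifier assignment tables with planted misassignment to phantom taxa;
* stratified RPKM tables for a 7-treatment x 3-replicate soil-restoration
  design with planted treatment effects, genus structure and log-normal
  replicate noise, calibrated to the gene-share and per-treatment-total
  magnitudes reported for the nitrogen (map00910) and phosphonate (map00440)
  pathways.

A single seed fans out to per-stage substreams via ``numpy.random.SeedSequence``
so that each stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    PathwayPanel,
    SampleMetadata,
    SoilProperties,
    StratifiedTable,
    TaxonLineage,
    UNASSIGNED,
)

__all__ = [
    "Genome",
    "CommunityTruth",
    "PlantedDesign",
    "TREATMENTS",
    "generate_genomes",
    "make_community",
    "simulate_reads",
    "simulate_classifier_output",
    "generate_stratified_rpkm",
    "expected_stratified",
    "generate_soil_properties",
    "default_nitrogen_design",
    "default_phosphonate_design",
    "genus_lineage",
]

#: The reference experimental design: five organic amendments, unamended
#: Control plots and undisturbed Natural reference soils, three replicates.
TREATMENTS: tuple[str, ...] = (
    "Natural",
    "Control",
    "COVG",
    "COHort",
    "SS",
    "COVG+SS",
    "COHort+SS",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# phylum of each genus used in the default designs (for realistic lineages)
_GENUS_PHYLUM = {
    "Streptomyces": "Actinomycetota",
    "Mycobacterium": "Actinomycetota",
    "Mycolicibacter": "Actinomycetota",
    "Nocardioides": "Actinomycetota",
    "Bifidobacterium": "Actinomycetota",
    "Pseudomonas": "Pseudomonadota",
    "Stutzerimonas": "Pseudomonadota",
    "Halomonas": "Pseudomonadota",
    "Luteimonas": "Pseudomonadota",
    "Nitrosospira": "Pseudomonadota",
    "Mesorhizobium": "Pseudomonadota",
    "Bradyrhizobium": "Pseudomonadota",
    "Rhizobium": "Pseudomonadota",
    "Bosea": "Pseudomonadota",
    "Cohaesibacter": "Pseudomonadota",
    "Pseudorhizobium": "Pseudomonadota",
    "Burkholderia": "Pseudomonadota",
    "Skermanella": "Pseudomonadota",
}


def genus_lineage(genus: str, species: str | None = None) -> TaxonLineage:
    """Lineage for a (possibly simulated) genus; unknown ranks stay unassigned."""
    return TaxonLineage.from_ranks(
        domain="Bacteria",
        phylum=_GENUS_PHYLUM.get(genus, UNASSIGNED),
        genus=genus,
        species=species if species is not None else UNASSIGNED,
    )


# ---------------------------------------------------------------------------
# genomes and reads


@dataclass(frozen=True)
class Genome:
    genome_id: str
    lineage: TaxonLineage
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CommunityTruth:
    """Ground truth of a synthetic community.

    ``abundance`` maps sample_id -> {genome_id -> relative abundance}; each
    sample's abundances sum to 1.  ``phantom_taxa`` are species-level lineage
    strings that exist only as misassignment targets: their genomes are
    generated (a verifier needs a reference to map against) but no reads
    truly originate from them.
    """

    genomes: list[Genome]
    abundance: dict[str, dict[str, float]]
    phantom_taxa: frozenset[str]

    def __post_init__(self) -> None:
        for sample, ab in self.abundance.items():
            vals = np.array(list(ab.values()))
            if (vals < 0).any():
                raise ValueError(f"negative abundance in sample {sample!r}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances in sample {sample!r} sum to {vals.sum()}, not 1"
                )
        true_species = {
            g.lineage.to_string()
            for g in self.genomes
            if g.lineage.to_string() not in self.phantom_taxa
        }
        if true_species & set(self.phantom_taxa):
            raise ValueError("phantom taxa overlap true community species")

    def genome_by_id(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def species_to_genome(self) -> dict[str, Genome]:
        return {g.lineage.to_string(): g for g in self.genomes}


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def generate_genomes(
    n_genera: int,
    species_per_genus: int,
    genome_length_bp: int,
    gc_fraction: float,
    seed: int | np.random.SeedSequence,
    genus_prefix: str = "SimGenus",
) -> list[Genome]:
    """Random i.i.d. genomes arranged in a genus/species hierarchy.

    Deterministic under a fixed seed; observed GC converges on
    ``gc_fraction`` (binomial sampling noise only).
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("counts must be >= 1")
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genomes = []
    for i in range(1, n_genera + 1):
        genus = f"{genus_prefix}{i:02d}"
        for j in range(1, species_per_genus + 1):
            species = f"{genus} sp{j}"
            lineage = TaxonLineage.from_ranks(
                domain="Bacteria", genus=genus, species=species
            )
            genomes.append(
                Genome(
                    genome_id=f"{genus}_sp{j}",
                    lineage=lineage,
                    sequence=_random_sequence(rng, genome_length_bp, gc_fraction),
                )
            )
    return genomes


def make_community(
    metadata: SampleMetadata,
    n_genera: int = 20,
    n_phantom_genera: int = 5,
    species_per_genus: int = 1,
    genome_length_bp: int = 10_000,
    gc_fraction: float = 0.5,
    abundance_concentration: float = 5.0,
    seed: int | np.random.SeedSequence = 0,
) -> CommunityTruth:
    """True community plus phantom reference genomes, with per-sample
    Dirichlet abundances over the true genomes (phantoms stay at 0)."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_true, s_phantom, s_abund = ss.spawn(3)
    true = generate_genomes(
        n_genera, species_per_genus, genome_length_bp, gc_fraction, s_true
    )
    phantoms = (
        generate_genomes(
            n_phantom_genera,
            1,
            genome_length_bp,
            gc_fraction,
            s_phantom,
            genus_prefix="PhantomGenus",
        )
        if n_phantom_genera
        else []
    )
    rng = np.random.default_rng(s_abund)
    abundance: dict[str, dict[str, float]] = {}
    for sample in metadata.sample_ids:
        weights = rng.dirichlet(np.full(len(true), abundance_concentration))
        ab = {g.genome_id: float(w) for g, w in zip(true, weights)}
        ab.update({g.genome_id: 0.0 for g in phantoms})
        abundance[sample] = ab
    return CommunityTruth(
        genomes=true + phantoms,
        abundance=abundance,
        phantom_taxa=frozenset(g.lineage.to_string() for g in phantoms),
    )


def simulate_reads(
    community: CommunityTruth,
    depth_per_sample: int | Mapping[str, int],
    read_length: int = 100,
    substitution_rate: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Uniform shotgun reads with i.i.d. substitution errors.

    Returns ``(reads, truth)`` where ``reads[sample]`` is a list of
    ``(read_id, sequence, qualities)`` and ``truth`` records the source
    genome, 0-based half-open source interval and introduced error count of
    every read.
    """
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    min_len = min((g.length for g in community.genomes), default=0)
    if read_length > min_len:
        raise ValueError("read_length exceeds the shortest genome")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    seqs = {g.genome_id: np.frombuffer(g.sequence.encode(), dtype="S1") for g in community.genomes}
    qual = "I" * read_length
    reads: dict[str, list[tuple[str, str, str]]] = {}
    truth_rows = []
    for sample, ab in community.abundance.items():
        n = (
            depth_per_sample[sample]
            if isinstance(depth_per_sample, Mapping)
            else depth_per_sample
        )
        gids = [gid for gid, w in ab.items() if w > 0]
        weights = np.array([ab[g] for g in gids])
        sample_reads: list[tuple[str, str, str]] = []
        if n:
            choices = rng.choice(len(gids), size=n, p=weights / weights.sum())
            for i, gi in enumerate(choices):
                gid = gids[gi]
                genome = seqs[gid]
                start = int(rng.integers(0, len(genome) - read_length + 1))
                frag = genome[start : start + read_length].copy()
                n_err = int(rng.binomial(read_length, substitution_rate))
                if n_err:
                    pos = rng.choice(read_length, size=n_err, replace=False)
                    for p in pos:
                        alt = [b for b in _BASES if b != frag[p]]
                        frag[p] = alt[int(rng.integers(0, 3))]
                read_id = f"{sample}_read{i:06d}"
                sample_reads.append((read_id, frag.tobytes().decode(), qual))
                truth_rows.append(
                    (read_id, sample, gid, start, start + read_length, n_err)
                )
        reads[sample] = sample_reads
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample_id", "genome_id", "start", "end", "n_errors"],
    )
    return reads, truth


def simulate_classifier_output(
    read_truth: pd.DataFrame,
    community: CommunityTruth,
    misassignment_rate: float,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Emulate a read classifier with planted misassignment.

    Each read is independently relabelled, with probability
    ``misassignment_rate``, to a phantom species chosen uniformly; otherwise
    it carries its true species.  Columns: read_id, sample_id, lineage,
    true_lineage, is_misassigned.
    """
    if not 0 <= misassignment_rate <= 1:
        raise ValueError("misassignment_rate must be in [0, 1]")
    phantoms = sorted(community.phantom_taxa)
    if misassignment_rate > 0 and not phantoms:
        raise ValueError("misassignment_rate > 0 requires phantom taxa")
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    lineage_of = {g.genome_id: g.lineage.to_string() for g in community.genomes}
    true_lineage = read_truth["genome_id"].map(lineage_of)
    n = len(read_truth)
    mis = (
        rng.random(n) < misassignment_rate
        if misassignment_rate > 0
        else np.zeros(n, dtype=bool)
    )
    assigned = true_lineage.to_numpy(dtype=object).copy()
    if mis.any():
        assigned[mis] = rng.choice(phantoms, size=int(mis.sum()))
    return pd.DataFrame(
        {
            "read_id": read_truth["read_id"].to_numpy(),
            "sample_id": read_truth["sample_id"].to_numpy(),
            "lineage": assigned,
            "true_lineage": true_lineage.to_numpy(),
            "is_misassigned": mis,
        }
    )


# ---------------------------------------------------------------------------
# planted stratified RPKM tables


@dataclass
class PlantedDesign:
    """Planted-effect recipe for a stratified RPKM table.

    ``baseline`` maps ``(gene_symbol, genus)`` to a non-negative baseline
    RPKM; ``multipliers`` maps ``(treatment, gene)`` or
    ``(treatment, gene, genus)`` to a positive effect multiplier (the most
    specific key wins; default 1).  Each replicate cell is

        baseline * multiplier * exp(N(0, sigma)),

    and a zero baseline stays exactly 0 ("function not detected").
    """

    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 3
    baseline: dict[tuple[str, str], float] = field(default_factory=dict)
    multipliers: dict[tuple, float] = field(default_factory=dict)
    sigma: float = 0.1
    #: optional record of the genus planted as dominant per treatment
    dominant_genus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for {key} must be positive")
        for key, b in self.baseline.items():
            if b < 0:
                raise ValueError(f"baseline for {key} must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def multiplier(self, treatment: str, gene: str, genus: str) -> float:
        specific = self.multipliers.get((treatment, gene, genus))
        if specific is not None:
            return specific
        return self.multipliers.get((treatment, gene), 1.0)

    @property
    def genera(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g for _, g in self.baseline))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g for g, _ in self.baseline))


def _design_rows(
    design: PlantedDesign, panel: PathwayPanel, genus_pool: Sequence[str] | None
) -> list[tuple[str, str, str, str]]:
    """(gene, genus, ec, lineage) rows, validating genes against the panel."""
    rows = []
    for (gene, genus), _ in design.baseline.items():
        if gene not in panel.gene_map:
            raise ValueError(f"gene {gene!r} absent from panel {panel.pathway_id}")
        if genus_pool is not None and genus not in genus_pool:
            continue
        ec = panel.gene_map[gene][0]
        rows.append((gene, genus, ec, genus_lineage(genus).to_string()))
    return rows


def expected_stratified(
    design: PlantedDesign,
    panel: PathwayPanel,
    genus_pool: Sequence[str] | None = None,
) -> tuple[StratifiedTable, SampleMetadata]:
    """The noiseless (sigma=0) table the design implies — the planted truth."""
    metadata = SampleMetadata.from_design(design.treatments, design.n_replicates)
    rows = _design_rows(design, panel, genus_pool)
    index = pd.MultiIndex.from_tuples(
        [(ec, lin) for _, _, ec, lin in rows], names=["function_id", "lineage"]
    )
    data = np.empty((len(rows), len(metadata.sample_ids)))
    for j, sample in enumerate(metadata.sample_ids):
        t = metadata.treatment[sample]
        for i, (gene, genus, _, _) in enumerate(rows):
            data[i, j] = design.baseline[(gene, genus)] * design.multiplier(
                t, gene, genus
            )
    df = pd.DataFrame(data, index=index, columns=list(metadata.sample_ids))
    df = df.groupby(level=[0, 1], sort=False).sum()  # merge genes sharing an EC
    return StratifiedTable(df), metadata


def generate_stratified_rpkm(
    design: PlantedDesign,
    panel: PathwayPanel,
    genus_pool: Sequence[str] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[StratifiedTable, SampleMetadata, dict]:
    """Planted stratified RPKM table with log-normal replicate noise.

    Returns ``(table, metadata, truth)`` where ``truth`` carries the design,
    the noiseless expected table and the per-(gene, genus, treatment)
    multipliers, for recovery tests.
    """
    expected, metadata = expected_stratified(design, panel, genus_pool)
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    values = expected.data.to_numpy().copy()
    if design.sigma > 0:
        noise = np.exp(rng.normal(0.0, design.sigma, size=values.shape))
        values = values * noise  # zero baselines stay exactly 0
    table = StratifiedTable(
        pd.DataFrame(values, index=expected.data.index, columns=expected.data.columns)
    )
    truth = {
        "design": design,
        "expected": expected,
        "multipliers": dict(design.multipliers),
    }
    return table, metadata, truth


# --- default designs calibrated to the reference study conditions ----------

# nitrogen pathway: gene shares (percent of total pathway RPKM) and
# per-treatment mean per-sample totals (RPKM)
_N_GENE_SHARES = {
    "glnA": 47.0,
    "gltBD": 12.0,
    "gudB": 5.0,
    "gdhA": 4.0,
    "pmoABC-amoABC": 4.0,
    "napAB": 2.0,
    "nosZ": 2.0,
}
_N_ZERO_GENES = ("vnfDKG", "hzsABC", "hdh", "hox", "nadR", "cpsIII", "atzF")
_N_TOTALS = {
    "Natural": 520.0,
    "Control": 541.0,
    "COVG": 723.0,
    "COHort": 647.0,
    "SS": 687.0,
    "COVG+SS": 549.0,
    "COHort+SS": 759.0,
}
_N_GENUS_WEIGHTS = {
    "Streptomyces": 0.20,
    "Pseudomonas": 0.14,
    "Mycobacterium": 0.10,
    "Halomonas": 0.09,
    "Mesorhizobium": 0.09,
    "Nocardioides": 0.08,
    "Nitrosospira": 0.07,
    "Bradyrhizobium": 0.07,
    "Stutzerimonas": 0.06,
    "Luteimonas": 0.05,
    "Skermanella": 0.03,
    "Mycolicibacter": 0.02,
}
_N_DOMINANT = {
    "Natural": "Bradyrhizobium",
    "Control": "Streptomyces",
    "COVG": "Mycobacterium",
    "COHort": "Nocardioides",
    "SS": "Pseudomonas",
    "COVG+SS": "Halomonas",
    "COHort+SS": "Mesorhizobium",
}

_P_GENE_SHARES = {
    "phnJ": 41.0,
    "phnW": 20.0,
    "phnGHIL": 12.0,
    "pmmS": 7.0,
    "PPT": 4.0,
}
_P_OTHER_GENES = (
    "phnM",
    "phnN",
    "phnX",
    "phnA",
    "palA",
    "phnY",
    "pepM",
    "ppd",
    "phpD",
    "mpnS",
    "aepCT",
    "psd",
)
_P_TOTALS = {
    "Natural": 31.0,
    "Control": 33.0,
    "COVG": 38.0,
    "COHort": 46.0,
    "SS": 38.0,
    "COVG+SS": 52.0,
    "COHort+SS": 69.0,
}
_P_GENUS_WEIGHTS = {
    "Pseudomonas": 0.22,
    "Rhizobium": 0.14,
    "Streptomyces": 0.13,
    "Mesorhizobium": 0.11,
    "Burkholderia": 0.09,
    "Bosea": 0.08,
    "Halomonas": 0.07,
    "Cohaesibacter": 0.06,
    "Pseudorhizobium": 0.05,
    "Bifidobacterium": 0.05,
}
_P_DOMINANT = {
    "Natural": "Streptomyces",
    "Control": "Bifidobacterium",
    "COVG": "Burkholderia",
    "COHort": "Bosea",
    "SS": "Pseudomonas",
    "COVG+SS": "Halomonas",
    "COHort+SS": "Rhizobium",
}


def _calibrated_design(
    panel_genes: Sequence[str],
    named_shares: Mapping[str, float],
    zero_genes: Sequence[str],
    genus_weights: Mapping[str, float],
    dominant: Mapping[str, str],
    totals: Mapping[str, float],
    sigma: float,
    dominant_boost: float,
    other_genes: Sequence[str] | None = None,
) -> PlantedDesign:
    """Outer-product baseline (gene mass x genus weight) with a genus-wide
    dominant boost per treatment.  Because the boost scales every gene of the
    dominant genus equally, gene shares are exactly the planted masses at
    sigma=0, while per-treatment totals hit the calibrated targets."""
    if other_genes is None:
        other_genes = [
            g for g in panel_genes if g not in named_shares and g not in zero_genes
        ]
    remaining = 100.0 - sum(named_shares.values())
    shares = dict(named_shares)
    shares.update({g: remaining / len(other_genes) for g in other_genes})
    baseline: dict[tuple[str, str], float] = {}
    for gene, share in shares.items():
        for genus, w in genus_weights.items():
            baseline[(gene, genus)] = share / 100.0 * w
    first_genus = next(iter(genus_weights))
    for gene in zero_genes:
        baseline[(gene, first_genus)] = 0.0
    multipliers: dict[tuple, float] = {}
    for t, total in totals.items():
        dom = dominant[t]
        scale = total / (1.0 + (dominant_boost - 1.0) * genus_weights[dom])
        for gene in shares:
            multipliers[(t, gene)] = scale
            multipliers[(t, gene, dom)] = scale * dominant_boost
    return PlantedDesign(
        treatments=tuple(totals),
        n_replicates=3,
        baseline=baseline,
        multipliers=multipliers,
        sigma=sigma,
        dominant_genus=dict(dominant),
    )


def default_nitrogen_design(panel: PathwayPanel, sigma: float = 0.1) -> PlantedDesign:
    """Nitrogen-pathway planted design: 32 of 39 panel ECs detected, glnA at
    47% of total RPKM, per-treatment totals 520-759, one dominant genus per
    treatment (boost 3x)."""
    return _calibrated_design(
        tuple(panel.gene_map),
        _N_GENE_SHARES,
        _N_ZERO_GENES,
        _N_GENUS_WEIGHTS,
        _N_DOMINANT,
        _N_TOTALS,
        sigma,
        dominant_boost=3.0,
    )


def default_phosphonate_design(panel: PathwayPanel, sigma: float = 0.1) -> PlantedDesign:
    """Phosphonate-pathway planted design: 17 of 31 panel ECs detected, phnJ
    at 41% of total RPKM, per-treatment totals 31-69."""
    zero = [
        g
        for g in panel.gene_map
        if g not in _P_GENE_SHARES and g not in _P_OTHER_GENES
    ]
    return _calibrated_design(
        tuple(panel.gene_map),
        _P_GENE_SHARES,
        zero,
        _P_GENUS_WEIGHTS,
        _P_DOMINANT,
        _P_TOTALS,
        sigma,
        dominant_boost=3.0,
        other_genes=_P_OTHER_GENES,
    )


# ---------------------------------------------------------------------------
# soil properties

PROPERTY_NAMES = (
    "EC",
    "pH",
    "TOC",
    "TN",
    "AP",
    "pF_1500",
    "pF_33",
    "basal_respiration",
    "urease",
    "phosphatase",
    "TB_FA",
)


def generate_soil_properties(
    metadata: SampleMetadata,
    seed: int | np.random.SeedSequence = 0,
    property_names: Sequence[str] = PROPERTY_NAMES,
    drivers: Mapping[str, Mapping[str, float]] | None = None,
    slopes: Mapping[str, float] | None = None,
    intercepts: Mapping[str, float] | None = None,
    sigma: float = 1.0,
) -> SoilProperties:
    """Per-sample soil measurements with optional planted linear relations.

    A property listed in ``drivers`` equals
    ``intercept + slope * driver[sample] + N(0, sigma)`` — with ``sigma=0``
    its Pearson correlation with the driver (e.g. a gene's per-sample RPKM)
    is exactly ±1.  Properties without a driver are independent standard
    normals scaled by ``sigma`` (null columns for type-I checks).
    """
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    drivers = drivers or {}
    slopes = slopes or {}
    intercepts = intercepts or {}
    data: dict[str, np.ndarray] = {}
    for prop in property_names:
        noise = rng.normal(0.0, sigma, size=len(metadata.sample_ids)) if sigma else 0.0
        if prop in drivers:
            base = np.array([drivers[prop][s] for s in metadata.sample_ids])
            data[prop] = (
                intercepts.get(prop, 0.0) + slopes.get(prop, 1.0) * base + noise
            )
        else:
            data[prop] = intercepts.get(prop, 0.0) + noise
    return SoilProperties(
        pd.DataFrame(data, index=pd.Index(metadata.sample_ids, name="sample_id"))
    )
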