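"""Synthetic-data generation: F2 crosses, pooled sequencing, gene fixtures
and greenhouse load-cell seasons.

The cross simulator emulates an F2 population from a biparental cross of
two fully homozygous parents.  Each F2 genotype is the sum of two gametes;
each gamete is produced under the Haldane model: a Poisson number of
crossovers (mean = chromosome genetic length in Morgans) placed uniformly
on the chromosome, no interference, chromosomes assorting independently.
One recessive causal locus determines the true phenotype class (mutant iff
homozygous for the mutant parental allele); an optional misclassification
rate flips the observed class.

Pooled sequencing is emulated at the allele-count level: per marker and
pool, depth ~ Poisson(mean_depth) and the alt count ~ Binomial(depth, p')
with p' = p(1-e) + (1-p)e, or Beta-Binomial when an overdispersion
parameter rho > 0 is set (rho is the beta-binomial intra-class
correlation; it emulates the extra variance of pooled RNA-seq, where
individuals contribute unequal amounts of RNA).

The load-cell simulator produces a gravimetric time series for one potted
plant: system weight = tare + soil water + plant fresh weight, with a diel
sinusoidal transpiration sink inside the daylight window, nocturnal
irrigation (refill-to-capacity or feedback drought mode), a daily fresh
weight increment, and Gaussian measurement noise.  All ground-truth
quantities (per-interval sink, irrigation volumes, daily transpiration)
are recorded so analyses can be checked by exact bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from palemapper.formats import GenomeMap, GeneModel, VariantRecord

MUTANT_LIKE = "mutant_like"
WT_LIKE = "wt_like"

# codons used as filler in gene fixtures; none is a stop, none contains ATG
_FILLER_CODONS = ("GCT", "GAA", "CTG", "AAA", "GTC", "TCA", "CCG", "GAC")

_STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Cross simulation
# ---------------------------------------------------------------------------


@dataclass
class CrossSimConfig:
    """Parameters of the F2 cross and pooled-sequencing simulator.

    Defaults describe a desk-scale version of the mapping experiment:
    7 chromosomes x 50 Mb at 2 markers/Mb, an F2 of 565 plants pooled
    100 + 100, 50x mean pooled depth and 1% base error.
    """

    chromosomes: tuple[tuple[str, int], ...] = tuple(
        (f"chr{i}H", 50_000_000) for i in range(1, 8)
    )
    marker_density: float = 2.5  # markers per Mb
    genetic_length_morgans: float = 1.5  # per chromosome
    n_f2: int = 565
    causal_chrom: str = "chr7H"
    causal_pos: int = 25_000_000
    misclassification_rate: float = 0.0
    pool_sizes: tuple[int, int] = (100, 100)  # (mutant-like, wt-like)
    mean_depth: float = 50.0
    base_error: float = 0.01
    overdispersion_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be positive")
        if self.genetic_length_morgans < 0:
            raise ValueError("genetic length must be non-negative")
        if self.n_f2 <= 0:
            raise ValueError("n_f2 must be positive")
        if not 0 <= self.misclassification_rate < 0.5:
            raise ValueError("misclassification_rate must be in [0, 0.5)")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        chrom_lengths = dict(self.chromosomes)
        if self.causal_chrom is not None:
            if self.causal_chrom not in chrom_lengths:
                raise ValueError(f"causal chromosome {self.causal_chrom!r} not in genome")
            if not 1 <= self.causal_pos <= chrom_lengths[self.causal_chrom]:
                raise ValueError("causal position outside its chromosome")

    @property
    def genome(self) -> GenomeMap:
        return GenomeMap(dict(self.chromosomes))


@dataclass
class PhenoModel:
    """Per-class normal trait distributions, keyed trait -> class -> (mean, sd).

    Defaults carry the maximum PSII quantum yield (Fv/Fm) used to class
    F2 plants: mutant-like 0.81 +/- 0.02, wild-type-like 0.74 +/- 0.02.
    """

    traits: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "fv_fm": {MUTANT_LIKE: (0.81, 0.02), WT_LIKE: (0.74, 0.02)},
        }
    )

    def __post_init__(self) -> None:
        for trait, by_class in self.traits.items():
            for cls, (_, sd) in by_class.items():
                if sd < 0:
                    raise ValueError(f"sd < 0 for {trait}/{cls}")


@dataclass
class F2Cohort:
    """A simulated F2 population.

    ``genotypes`` holds, per individual and marker, the dosage of the
    mutant parental allele (0, 1 or 2).  ``true_class`` is the Mendelian
    phenotype (mutant iff dosage 2 at the causal marker);
    ``phenotype_class`` is the observed class after misclassification.
    """

    marker_chrom: np.ndarray  # (n_markers,) str
    marker_pos: np.ndarray  # (n_markers,) int, 1-based
    genotypes: np.ndarray  # (n_f2, n_markers) int8
    true_class: np.ndarray  # (n_f2,) str
    phenotype_class: np.ndarray  # (n_f2,) str
    causal_index: int | None
    quantitative_traits: pd.DataFrame | None = None
    seed: int | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Per-individual table: classes plus any quantitative traits."""
        df = pd.DataFrame(
            {
                "individual": np.arange(self.n_individuals),
                "true_class": self.true_class,
                "phenotype_class": self.phenotype_class,
            }
        )
        if self.quantitative_traits is not None:
            df = pd.concat(
                [df, self.quantitative_traits.reset_index(drop=True)], axis=1
            )
        return df


def _marker_positions(config: CrossSimConfig) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Regular marker grid plus the causal position (inserted if absent)."""
    chroms: list[str] = []
    positions: list[int] = []
    spacing = int(round(1_000_000 / config.marker_density))
    for name, length in config.chromosomes:
        grid = list(range(spacing, length + 1, spacing))
        if name == config.causal_chrom and config.causal_pos not in grid:
            grid.append(config.causal_pos)
            grid.sort()
        chroms.extend([name] * len(grid))
        positions.extend(grid)
    chrom_arr = np.array(chroms)
    pos_arr = np.array(positions, dtype=np.int64)
    causal_index = None
    if config.causal_chrom is not None:
        hits = np.flatnonzero(
            (chrom_arr == config.causal_chrom) & (pos_arr == config.causal_pos)
        )
        causal_index = int(hits[0])
    return chrom_arr, pos_arr, causal_index


def _simulate_gametes(
    rng: np.random.Generator,
    n_gametes: int,
    marker_pos: np.ndarray,
    chrom_length: int,
    morgans: float,
) -> np.ndarray:
    """Alleles (0/1) carried by ``n_gametes`` gametes at each marker.

    Allele 1 is the mutant parent's haplotype.  A gamete starts on a
    random parental haplotype and switches at each crossover; the allele
    at a marker is the start haplotype XOR the parity of crossovers to
    its left.
    """
    starts = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
    n_co = rng.poisson(morgans, size=n_gametes)
    alleles = np.empty((n_gametes, marker_pos.size), dtype=np.int8)
    for g in range(n_gametes):
        if n_co[g] == 0:
            alleles[g] = starts[g]
            continue
        xovers = np.sort(rng.uniform(0, chrom_length, size=n_co[g]))
        parity = np.searchsorted(xovers, marker_pos) % 2
        alleles[g] = starts[g] ^ parity.astype(np.int8)
    return alleles


def simulate_f2_population(config: CrossSimConfig) -> F2Cohort:
    """Simulate an F2 cohort under the Haldane crossover model.

    Each individual's dosage at a marker is the sum of two independent
    gametes; chromosomes assort independently.  The true phenotype class
    is mutant iff the dosage at the causal marker is 2; the observed
    class flips with ``misclassification_rate``.
    """
    rng = np.random.default_rng(config.seed)
    marker_chrom, marker_pos, causal_index = _marker_positions(config)
    chrom_lengths = dict(config.chromosomes)

    genotypes = np.empty((config.n_f2, marker_pos.size), dtype=np.int8)
    for name, length in config.chromosomes:
        idx = np.flatnonzero(marker_chrom == name)
        pos = marker_pos[idx].astype(float)
        maternal = _simulate_gametes(
            rng, config.n_f2, pos, length, config.genetic_length_morgans
        )
        paternal = _simulate_gametes(
            rng, config.n_f2, pos, length, config.genetic_length_morgans
        )
        genotypes[:, idx] = maternal + paternal

    if causal_index is not None:
        is_mutant = genotypes[:, causal_index] == 2
    else:
        is_mutant = np.zeros(config.n_f2, dtype=bool)
    true_class = np.where(is_mutant, MUTANT_LIKE, WT_LIKE)
    flips = rng.random(config.n_f2) < config.misclassification_rate
    observed = np.where(
        flips,
        np.where(is_mutant, WT_LIKE, MUTANT_LIKE),
        true_class,
    )
    return F2Cohort(
        marker_chrom=marker_chrom,
        marker_pos=marker_pos,
        genotypes=genotypes,
        true_class=true_class,
        phenotype_class=observed,
        causal_index=causal_index,
        seed=config.seed,
    )


def _ref_alt_alleles(
    rng: np.random.Generator, n: int, causal_index: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a ref/alt nucleotide pair per marker; the causal site is G>A."""
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    shift = rng.integers(1, 4, size=n)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    if causal_index is not None:
        ref[causal_index], alt[causal_index] = "G", "A"
    return ref, alt


def pool_and_sequence(
    cohort: F2Cohort, config: CrossSimConfig
) -> list[VariantRecord]:
    """Emulate pooled sequencing of the two phenotype bulks.

    Pool members are sampled without replacement from each observed
    phenotype class.  The alt allele is the mutant parental allele; the
    true pool frequency at a marker is (sum of member dosages) / (2 *
    pool size).  Depth ~ Poisson(mean_depth); alt count ~
    Binomial(depth, p') with p' = p(1-e)+(1-p)e, or Beta-Binomial with
    intra-class correlation rho when overdispersion_rho > 0.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 0x706F6F6C))  # distinct stream
    )
    n_mut_pool, n_wt_pool = config.pool_sizes
    if n_mut_pool == 0 or n_wt_pool == 0:
        raise ValueError("pool sizes must be positive")
    if cohort.causal_index is None:
        # null design: no causal locus, both bulks are disjoint random subsets
        if n_mut_pool + n_wt_pool > cohort.n_individuals:
            raise ValueError("pool sizes exceed cohort size")
        both = rng.choice(
            cohort.n_individuals, size=n_mut_pool + n_wt_pool, replace=False
        )
        mut_pool, wt_pool = both[:n_mut_pool], both[n_mut_pool:]
    else:
        mut_idx = np.flatnonzero(cohort.phenotype_class == MUTANT_LIKE)
        wt_idx = np.flatnonzero(cohort.phenotype_class == WT_LIKE)
        if n_mut_pool > mut_idx.size or n_wt_pool > wt_idx.size:
            raise ValueError(
                f"pool sizes {config.pool_sizes} exceed class counts "
                f"({mut_idx.size} mutant-like, {wt_idx.size} wt-like)"
            )
        mut_pool = rng.choice(mut_idx, size=n_mut_pool, replace=False)
        wt_pool = rng.choice(wt_idx, size=n_wt_pool, replace=False)

    e = config.base_error
    rho = config.overdispersion_rho
    records: list[VariantRecord] = []
    ref_alleles, alt_alleles = _ref_alt_alleles(
        rng, cohort.n_markers, cohort.causal_index
    )
    p_mut = cohort.genotypes[mut_pool].sum(axis=0) / (2 * n_mut_pool)
    p_wt = cohort.genotypes[wt_pool].sum(axis=0) / (2 * n_wt_pool)

    def _sample_counts(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(config.mean_depth, size=p.size)
        p_obs = p * (1 - e) + (1 - p) * e
        if rho > 0:
            # beta-binomial: p per site drawn from Beta with mean p_obs
            conc = 1.0 / rho - 1.0
            a = np.clip(p_obs * conc, 1e-12, None)
            b = np.clip((1 - p_obs) * conc, 1e-12, None)
            p_draw = np.where(
                (p_obs > 0) & (p_obs < 1), rng.beta(a, b), p_obs
            )
        else:
            p_draw = p_obs
        alt = rng.binomial(depth, p_draw)
        return depth, alt

    depth_mut, alt_mut = _sample_counts(p_mut)
    depth_wt, alt_wt = _sample_counts(p_wt)

    for i in range(cohort.n_markers):
        records.append(
            VariantRecord(
                chrom=str(cohort.marker_chrom[i]),
                pos=int(cohort.marker_pos[i]),
                ref=str(ref_alleles[i]),
                alt=str(alt_alleles[i]),
                ad_mut=(int(depth_mut[i] - alt_mut[i]), int(alt_mut[i])),
                ad_wt=(int(depth_wt[i] - alt_wt[i]), int(alt_wt[i])),
            )
        )
    return records


def assign_phenotypes(
    cohort: F2Cohort, model: PhenoModel, seed: int = 0
) -> F2Cohort:
    """Draw quantitative traits from each individual's class distribution.

    Traits are drawn from the *observed* class (the class a phenotyper
    would act on).  Returns the cohort with ``quantitative_traits``
    filled in; deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for trait, by_class in model.traits.items():
        missing = set(np.unique(cohort.phenotype_class)) - set(by_class)
        if missing:
            raise ValueError(f"trait {trait!r} lacks parameters for {missing}")
        out = np.empty(cohort.n_individuals)
        for cls, (mean, sd) in by_class.items():
            mask = cohort.phenotype_class == cls
            out[mask] = mean + sd * rng.standard_normal(mask.sum())
        values[trait] = out
    cohort.quantitative_traits = pd.DataFrame(values)
    return cohort


# ---------------------------------------------------------------------------
# Gene fixtures
# ---------------------------------------------------------------------------


def make_gene_fixture(
    n_codons: int,
    substitutions: list[tuple[int, str]] | None = None,
    intron_layout: list[tuple[int, int]] | None = None,
    *,
    strand: str = "+",
    chrom: str = "chrSim",
    gene_start: int = 1001,
    gene_id: str = "geneSim",
    allow_internal_stop: bool = False,
) -> tuple[GeneModel, str, dict[str, str]]:
    """Construct a synthetic gene model plus matching sequences.

    The CDS is ATG + filler codons + TAA; ``substitutions`` replaces the
    codon at each 1-based ``codon_index`` with the given triplet.
    ``intron_layout`` lists ``(cds_offset, intron_length)`` pairs: an
    intron of that length is inserted immediately after the stated
    1-based CDS position, so genomic and CDS coordinates differ.

    Returns ``(model, cds_sequence, {chrom: genomic_sequence})``; the
    genomic sequence covers positions 1..end so it can be written as a
    FASTA reference directly.
    """
    if n_codons < 3:
        raise ValueError("need at least start, one internal and stop codon")
    codons = ["ATG"]
    for i in range(1, n_codons - 1):
        codons.append(_FILLER_CODONS[i % len(_FILLER_CODONS)])
    codons.append("TAA")
    for codon_index, triplet in substitutions or []:
        if not 1 <= codon_index <= n_codons:
            raise ValueError(f"codon index {codon_index} out of range")
        triplet = triplet.upper()
        if len(triplet) != 3 or set(triplet) - set("ACGT"):
            raise ValueError(f"invalid codon {triplet!r}")
        if (
            triplet in _STOP_CODONS
            and codon_index != n_codons
            and not allow_internal_stop
        ):
            raise ValueError(
                f"substitution at codon {codon_index} creates a premature stop"
            )
        codons[codon_index - 1] = triplet
    cds = "".join(codons)

    # split the CDS at intron insertion points (offsets on the CDS, 1-based)
    layout = sorted(intron_layout or [])
    offsets = [off for off, _ in layout]
    if any(not 1 <= off < len(cds) for off in offsets):
        raise ValueError("intron offsets must fall strictly inside the CDS")
    if len(set(offsets)) != len(offsets):
        raise ValueError("duplicate intron offsets")
    pieces: list[str] = []
    prev = 0
    for off, _ in layout:
        pieces.append(cds[prev:off])
        prev = off
    pieces.append(cds[prev:])

    # assemble genomic sequence on the coding strand
    coding_parts: list[str] = []
    exon_bounds: list[tuple[int, int]] = []  # offsets within the gene body, 0-based
    cursor = 0
    for i, piece in enumerate(pieces):
        exon_bounds.append((cursor, cursor + len(piece)))
        coding_parts.append(piece)
        cursor += len(piece)
        if i < len(layout):
            intron_len = layout[i][1]
            if intron_len < 4:
                raise ValueError("introns must be at least 4 bp (GT..AG)")
            intron = "GT" + "C" * (intron_len - 4) + "AG"
            coding_parts.append(intron)
            cursor += intron_len
    gene_body = "".join(coding_parts)

    if strand == "+":
        intervals = tuple(
            (gene_start + s, gene_start + e - 1) for s, e in exon_bounds
        )
        genomic_gene = gene_body
    elif strand == "-":
        # place the reverse complement; flip exon coordinates
        genomic_gene = gene_body.translate(_COMPLEMENT)[::-1]
        body_len = len(gene_body)
        intervals = tuple(
            sorted(
                (gene_start + body_len - e, gene_start + body_len - 1 - s)
                for s, e in exon_bounds
            )
        )
    else:
        raise ValueError("strand must be '+' or '-'")

    flank = "T" * (gene_start - 1)
    genomic_seq = flank + genomic_gene + "T" * 50
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=intervals,
        cds_intervals=intervals,
    )
    return model, cds, {chrom: genomic_seq}


# ---------------------------------------------------------------------------
# Load-cell season simulation
# ---------------------------------------------------------------------------


@dataclass
class LoadCellSimConfig:
    """Parameters of the gravimetric greenhouse season simulator.

    ``baseline_transpiration`` is the midday transpiration rate in
    g water per g plant fresh weight per minute; ``genotype_scaling``
    multiplies it (e.g. 0.55 for a low-transpiration genotype).
    ``irrigation_mode`` is ``"well_watered"`` (nightly refill to pot
    capacity) or ``"feedback"`` (nightly volume = ``feedback_fraction``
    of the plant's own previous-day transpiration — the standardized
    drought protocol).
    """

    n_days: int = 10
    sampling_interval: float = 3.0  # minutes
    day_window: tuple[float, float] = (6.0, 18.0)  # clock hours
    baseline_transpiration: float = 0.025  # g water / g plant / min at midday
    genotype_scaling: float = 1.0
    growth_rate: float = 1.5  # g fresh weight per day
    initial_fresh_weight: float = 5.0  # g
    tare: float = 1200.0  # pot + soil + sensors, g
    soil_water_capacity: float = 800.0  # g of plant-available water at pot capacity
    irrigation_mode: str = "well_watered"
    feedback_fraction: float = 0.8
    irrigation_hour: float = 2.0  # nocturnal
    biomass_per_water: float = 0.004  # g dry weight per ml transpired
    noise_sd: float = 0.0  # g
    start: datetime = datetime(2023, 1, 19)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.genotype_scaling <= 0:
            raise ValueError("genotype_scaling must be positive")
        if self.irrigation_mode not in {"well_watered", "feedback"}:
            raise ValueError("irrigation_mode must be well_watered or feedback")
        if not 0 < self.feedback_fraction <= 1:
            raise ValueError("feedback_fraction must be in (0, 1]")
        start, end = self.day_window
        if not 0 <= start < end <= 24:
            raise ValueError("day_window must satisfy 0 <= start < end <= 24")


@dataclass
class LoadCellGroundTruth:
    """Simulator internals recorded for bookkeeping checks."""

    sink: np.ndarray  # g water transpired in interval [t_i, t_{i+1})
    rate_per_fw: np.ndarray  # g water / g plant / min, at interval start
    fresh_weight: np.ndarray  # g, per sample
    irrigation: pd.DataFrame  # columns: timestamp, volume_ml
    daily_transpiration: pd.Series  # full-day ml, indexed by date
    daily_transpiration_daylight: pd.Series  # daylight-window ml
    growth_total: float  # g fresh weight added over the run
    dry_weight: float  # g, biomass_per_water * total transpiration
    drought_flagged: bool  # soil water hit zero at least once


@dataclass
class LoadCellSeries:
    """A gravimetric time series: system weight sampled every few minutes.

    ``data`` columns: ``timestamp`` (datetime), ``weight_g``, ``fw_g``
    (plant fresh weight, when known) and ``event`` (irrigation flag).
    ``ground_truth`` is present only for simulated series.
    """

    data: pd.DataFrame
    ground_truth: LoadCellGroundTruth | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        ts = self.data["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        if (self.data["weight_g"] < 0).any():
            raise ValueError("weights must be non-negative")

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out["event"] = out["event"].astype(int)  # 0/1 survives the round trip
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LoadCellSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if "event" not in df:
            df["event"] = 0
        df["event"] = df["event"].astype(int).astype(bool)
        return cls(data=df)


def _diel_shape(hour: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Half-sine transpiration profile inside the daylight window, 0 at night."""
    start, end = window
    frac = (hour - start) / (end - start)
    shape = np.sin(np.pi * np.clip(frac, 0.0, 1.0))
    return np.where((hour >= start) & (hour < end), shape, 0.0)


def simulate_loadcell_season(config: LoadCellSimConfig) -> LoadCellSeries:
    """Simulate a greenhouse load-cell season for one plant.

    System weight = tare + soil water + plant fresh weight (+ noise).
    Transpiration follows a half-sine diel curve inside the daylight
    window, scaled by genotype and current fresh weight; fresh weight
    grows by ``growth_rate`` once per day at midnight; irrigation happens
    nightly at ``irrigation_hour``.  If the soil water store would go
    negative, transpiration is clipped and the run flagged (terminal
    drought).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval
    n_per_day = int(round(24 * 60 / dt))
    n_samples = config.n_days * n_per_day + 1
    times = np.array(
        [config.start + timedelta(minutes=dt * i) for i in range(n_samples)]
    )
    hours = np.array([t.hour + t.minute / 60 + t.second / 3600 for t in times])
    day_index = np.array([(t.date() - config.start.date()).days for t in times])

    shape = _diel_shape(hours, config.day_window)
    peak = config.baseline_transpiration * config.genotype_scaling

    fresh_weight = config.initial_fresh_weight + config.growth_rate * day_index
    soil = np.empty(n_samples)
    sink = np.zeros(n_samples - 1)
    rate = peak * shape * fresh_weight  # g/min at each sample
    soil[0] = config.soil_water_capacity
    irrigation_rows: list[tuple[datetime, float]] = []
    daily_truth = np.zeros(config.n_days)
    drought_flagged = False

    # irrigation happens at the first sample at/after irrigation_hour each day
    irr_sample = {}
    for d in range(1, config.n_days):
        target = config.start + timedelta(days=d, hours=config.irrigation_hour)
        idx = int(np.searchsorted(times, target))
        if idx < n_samples:
            irr_sample[idx] = d

    for i in range(n_samples - 1):
        demand = rate[i] * dt
        actual = min(demand, soil[i])
        if actual < demand:
            drought_flagged = True
        sink[i] = actual
        d = day_index[i]
        if d < config.n_days:
            daily_truth[d] += actual
        nxt = soil[i] - actual
        j = i + 1
        if j in irr_sample:
            d_irr = irr_sample[j]
            if config.irrigation_mode == "well_watered":
                volume = config.soil_water_capacity - nxt
            else:
                volume = config.feedback_fraction * daily_truth[d_irr - 1]
            volume = max(volume, 0.0)
            nxt += volume
            irrigation_rows.append((times[j], volume))
        soil[j] = nxt

    weight = config.tare + soil + fresh_weight
    if config.noise_sd > 0:
        weight = weight + rng.normal(0.0, config.noise_sd, size=n_samples)

    event = np.zeros(n_samples, dtype=bool)
    for idx in irr_sample:
        event[idx] = True

    dates = pd.to_datetime(
        [config.start.date() + timedelta(days=d) for d in range(config.n_days)]
    )
    # daylight-window portion of the ground-truth sink
    daylight = np.zeros(config.n_days)
    w0, w1 = config.day_window
    for i in range(n_samples - 1):
        if w0 <= hours[i] < w1 and day_index[i] < config.n_days:
            daylight[day_index[i]] += sink[i]

    truth = LoadCellGroundTruth(
        sink=sink,
        rate_per_fw=peak * shape,
        fresh_weight=fresh_weight.astype(float),
        irrigation=pd.DataFrame(irrigation_rows, columns=["timestamp", "volume_ml"]),
        daily_transpiration=pd.Series(daily_truth, index=dates),
        daily_transpiration_daylight=pd.Series(daylight, index=dates),
        growth_total=float(fresh_weight[-1] - fresh_weight[0]),
        dry_weight=float(config.biomass_per_water * sink.sum()),
        drought_flagged=drought_flagged,
    )
    data = pd.DataFrame(
        {
            "timestamp": times,
            "weight_g": weight,
            "fw_g": fresh_weight.astype(float),
            "event": event,
        }
    )
    return LoadCellSeries(data=data, ground_truth=truth, seed=config.seed)
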