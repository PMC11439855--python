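"""Pooled allele-frequency mapping: AF computation, segregating-variant
filtering, fixed-width genomic binning and candidate-region detection.

In a bulked-segregant design for a recessive mutation, the mutant-like
pool is homozygous for the mutagenized parent's alleles at the causal
locus (alt AF -> 1), while the wild-type-like pool — a 1:2 mix of
homozygous-reference and heterozygous plants — sits at AF ~ 1/3 there.
Away from the locus both pools drift back to 0.5.  The detector
formalizes the visual read-out of an AF-vs-position plot: maximal runs of
consecutive well-populated bins whose mutant-pool mean AF exceeds a
threshold (default 0.5, strict) while the wild-type-pool mean stays below
it (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from palemapper.formats import (
    GenomeMap,
    VariantRecord,
    read_vcf_minimal,
    to_zero_based_start,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Depth and segregation filters applied to pooled allele frequencies.

    ``min_af_both`` / ``max_af_wt`` implement the segregating-variant
    rule: alt AF strictly above ``min_af_both`` in both pools and
    strictly below ``max_af_wt`` in the wild-type-like pool.
    """

    min_af_both: float = 0.1
    max_af_wt: float = 0.9
    min_depth: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.min_af_both < self.max_af_wt <= 1:
            raise ValueError("need 0 <= min_af_both < max_af_wt <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass(frozen=True)
class PoolAF:
    """Per-pool alt-allele frequencies for one retained variant."""

    variant: VariantRecord
    af_mut: float
    af_wt: float
    depth_mut: int
    depth_wt: int


@dataclass(frozen=True)
class ExcludedVariant:
    variant: VariantRecord
    reason: str


@dataclass(frozen=True)
class BinSummary:
    """Aggregate over one fixed-width genomic bin (0-based half-open)."""

    chrom: str
    bin_start: int
    bin_width: int
    n_variants: int
    mean_af_mut: float  # NaN when empty
    mean_af_wt: float
    frac_high_mut: float

    @property
    def bin_end(self) -> int:
        return self.bin_start + self.bin_width


@dataclass(frozen=True)
class CandidateRegion:
    """A detected causal-locus interval (1-based closed coordinates).

    Boundaries come from the outermost retained variants inside the
    qualifying bin run, not from bin edges.
    """

    chrom: str
    start: int
    end: int
    n_bins: int
    peak_af_mut: float
    mean_af_wt: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionConfig:
    """Thresholds of the candidate-region detector."""

    af_threshold: float = 0.5
    high_threshold: float = 0.9
    min_bins: int = 2
    min_variants_per_bin: int = 5

    def __post_init__(self) -> None:
        for name in ("af_threshold", "high_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_bins < 1 or self.min_variants_per_bin < 0:
            raise ValueError("min_bins >= 1 and min_variants_per_bin >= 0 required")


def compute_pool_af(
    record: VariantRecord, cfg: FilterConfig
) -> PoolAF | ExcludedVariant:
    """Alt-allele frequency per pool, or an exclusion for low depth.

    Exclusion is a value, not an error: records failing the per-pool
    depth floor are returned as :class:`ExcludedVariant` with a reason.
    """
    if record.depth_mut < cfg.min_depth:
        return ExcludedVariant(record, "low depth mut_pool")
    if record.depth_wt < cfg.min_depth:
        return ExcludedVariant(record, "low depth wt_pool")
    return PoolAF(
        variant=record,
        af_mut=record.ad_mut[1] / record.depth_mut,
        af_wt=record.ad_wt[1] / record.depth_wt,
        depth_mut=record.depth_mut,
        depth_wt=record.depth_wt,
    )


def compute_pool_afs(
    records: Iterable[VariantRecord], cfg: FilterConfig
) -> tuple[list[PoolAF], list[ExcludedVariant]]:
    """Vector form of :func:`compute_pool_af`, keeping exclusions aside."""
    kept: list[PoolAF] = []
    excluded: list[ExcludedVariant] = []
    for record in records:
        result = compute_pool_af(record, cfg)
        (kept if isinstance(result, PoolAF) else excluded).append(result)
    return kept, excluded


def filter_segregating(afs: Sequence[PoolAF], cfg: FilterConfig) -> list[PoolAF]:
    """Keep variants segregating between pools.

    Retained iff af_mut > min_af_both AND af_wt > min_af_both AND
    af_wt < max_af_wt (all strict).  Order-preserving and idempotent.
    """
    return [
        af
        for af in afs
        if af.af_mut > cfg.min_af_both
        and af.af_wt > cfg.min_af_both
        and af.af_wt < cfg.max_af_wt
    ]


def bin_variants(
    afs: Sequence[PoolAF],
    genome: GenomeMap,
    bin_width: int = 2_000_000,
    high_threshold: float = 0.9,
    statistic: str = "mean",
) -> list[BinSummary]:
    """Aggregate retained variants into fixed-width bins along the genome.

    A variant at 1-based position p falls in the bin starting at
    ``floor((p-1)/bin_width) * bin_width`` (0-based half-open).  Every
    bin of every chromosome is emitted, empty ones with NaN means.
    ``statistic`` selects the per-bin AF aggregate: ``"mean"`` (default,
    unweighted arithmetic mean of per-variant AFs) or ``"median"``.
    """
    if statistic not in {"mean", "median"}:
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median

    by_bin: dict[tuple[str, int], list[PoolAF]] = {}
    for af in afs:
        chrom, pos = af.variant.chrom, af.variant.pos
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} not in genome map")
        if not 1 <= pos <= genome[chrom]:
            raise ValueError(f"{chrom}:{pos} beyond chromosome length {genome[chrom]}")
        start = to_zero_based_start(pos) // bin_width * bin_width
        by_bin.setdefault((chrom, start), []).append(af)

    bins: list[BinSummary] = []
    for chrom in genome.chromosomes:
        n_bins = -(-genome[chrom] // bin_width)  # ceil
        for k in range(n_bins):
            start = k * bin_width
            members = by_bin.get((chrom, start), [])
            if members:
                af_mut = np.array([m.af_mut for m in members])
                af_wt = np.array([m.af_wt for m in members])
                bins.append(
                    BinSummary(
                        chrom=chrom,
                        bin_start=start,
                        bin_width=bin_width,
                        n_variants=len(members),
                        mean_af_mut=float(agg(af_mut)),
                        mean_af_wt=float(agg(af_wt)),
                        frac_high_mut=float(np.mean(af_mut >= high_threshold)),
                    )
                )
            else:
                bins.append(
                    BinSummary(chrom, start, bin_width, 0, np.nan, np.nan, np.nan)
                )
    return bins


def _bin_qualifies(b: BinSummary, cfg: RegionConfig) -> bool:
    return (
        b.n_variants >= cfg.min_variants_per_bin
        and b.mean_af_mut > cfg.af_threshold
        and b.mean_af_wt < cfg.af_threshold
    )


def detect_candidate_regions(
    bins: Sequence[BinSummary],
    cfg: RegionConfig,
    afs: Sequence[PoolAF] | None = None,
) -> list[CandidateRegion]:
    """Find maximal runs of qualifying bins and rank them.

    A bin qualifies iff it holds at least ``min_variants_per_bin``
    variants, its mutant-pool mean AF is strictly above ``af_threshold``
    and its wild-type-pool mean is strictly below it.  A region is a
    maximal run of >= ``min_bins`` consecutive qualifying bins on one
    chromosome whose peak per-bin mutant AF reaches ``high_threshold``
    — the mutant bulk must approach fixation somewhere in the run, the
    defining signature of the causal interval; without this floor,
    sampling noise around 0.5 would yield chance runs genome-wide.
    When ``afs`` is given, region boundaries are the outermost
    retained-variant positions inside the run; otherwise bin edges are
    used (1-based).  Regions are ranked by peak per-bin mutant AF, ties
    broken by run length, then chromosome order.
    """
    regions: list[tuple[CandidateRegion, int]] = []
    chrom_order = {b.chrom: i for i, b in enumerate(bins)}  # first-seen order

    i = 0
    n = len(bins)
    while i < n:
        if not _bin_qualifies(bins[i], cfg):
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and bins[j + 1].chrom == bins[i].chrom
            and bins[j + 1].bin_start == bins[j].bin_start + bins[j].bin_width
            and _bin_qualifies(bins[j + 1], cfg)
        ):
            j += 1
        run = bins[i : j + 1]
        peak = max(b.mean_af_mut for b in run)
        if len(run) >= cfg.min_bins and peak >= cfg.high_threshold:
            chrom = run[0].chrom
            lo_edge = run[0].bin_start + 1  # 1-based
            hi_edge = run[-1].bin_end
            start, end = lo_edge, hi_edge
            if afs is not None:
                inside = [
                    a.variant.pos
                    for a in afs
                    if a.variant.chrom == chrom and lo_edge <= a.variant.pos <= hi_edge
                ]
                if inside:
                    start, end = min(inside), max(inside)
            regions.append(
                (
                    CandidateRegion(
                        chrom=chrom,
                        start=start,
                        end=end,
                        n_bins=len(run),
                        peak_af_mut=max(b.mean_af_mut for b in run),
                        mean_af_wt=float(np.mean([b.mean_af_wt for b in run])),
                    ),
                    chrom_order[chrom],
                )
            )
        i = j + 1

    regions.sort(key=lambda rc: (-rc[0].peak_af_mut, -rc[0].n_bins, rc[1]))
    return [r for r, _ in regions]


@dataclass
class MappingReport:
    """End-to-end mapping result with per-stage bookkeeping."""

    n_input: int
    n_skipped_multiallelic: int
    n_skipped_indel: int
    n_low_depth: int
    n_after_af: int
    n_after_filter: int
    bins: list[BinSummary]
    regions: list[CandidateRegion]
    retained: list[PoolAF]
    filter_config: FilterConfig
    region_config: RegionConfig
    bin_width: int

    @property
    def top_region(self) -> CandidateRegion | None:
        return self.regions[0] if self.regions else None

    def to_dict(self) -> dict:
        return {
            "counts": {
                "input": self.n_input,
                "skipped_multiallelic": self.n_skipped_multiallelic,
                "skipped_indel": self.n_skipped_indel,
                "low_depth": self.n_low_depth,
                "after_af": self.n_after_af,
                "after_filter": self.n_after_filter,
            },
            "filter_config": asdict(self.filter_config),
            "region_config": asdict(self.region_config),
            "bin_width": self.bin_width,
            "regions": [asdict(r) for r in self.regions],
        }


def map_pipeline(
    source: str | Path | Sequence[VariantRecord],
    genome: GenomeMap,
    filter_cfg: FilterConfig | None = None,
    region_cfg: RegionConfig | None = None,
    bin_width: int = 2_000_000,
    sample_names: tuple[str, str] = ("mut_pool", "wt_pool"),
) -> MappingReport:
    """Run read -> AF -> filter -> bin -> detect end to end.

    ``source`` is either a VCF path or an in-memory list of records.
    """
    filter_cfg = filter_cfg or FilterConfig()
    region_cfg = region_cfg or RegionConfig()

    if isinstance(source, (str, Path)):
        records, skipped = read_vcf_minimal(source, sample_names)
    else:
        records, skipped = list(source), {"multiallelic": 0, "indel": 0}

    afs, excluded = compute_pool_afs(records, filter_cfg)
    retained = filter_segregating(afs, filter_cfg)
    bins = bin_variants(
        retained, genome, bin_width, high_threshold=region_cfg.high_threshold
    )
    regions = detect_candidate_regions(bins, region_cfg, afs=retained)
    return MappingReport(
        n_input=len(records) + skipped["multiallelic"] + skipped["indel"],
        n_skipped_multiallelic=skipped["multiallelic"],
        n_skipped_indel=skipped["indel"],
        n_low_depth=len(excluded),
        n_after_af=len(afs),
        n_after_filter=len(retained),
        bins=bins,
        regions=regions,
        retained=retained,
        filter_config=filter_cfg,
        region_config=region_cfg,
        bin_width=bin_width,
    )
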