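"""Classification of two-population SNP data into shared/private count tables.

A site segregating (0 < frequency < 1) in both populations is *shared*; a site
segregating in exactly one is *private* to that population.  Frequencies are
folded (minor-allele frequency, in [0, 0.5]) because no attempt is made to
orient alleles against an ancestral state, and the frequency of shared sites
is taken in the focal population — the one from which the private
polymorphisms are drawn — so that a frequency filter applies symmetrically to
both categories.  Sites are binned by folded MAF in bins of width 0.1, with a
pooled bin for all frequencies above 0.1 for use when data are sparse.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .counts import PolymorphismCounts

__all__ = [
    "SiteRecord",
    "ClassifiedSite",
    "BinnedCounts",
    "classify_shared_private",
    "fold_maf",
    "bin_by_frequency",
    "apply_min_count_filter",
    "bgc_filter",
    "split_by_recombination",
    "group_by_gene_set",
    "expected_random_overlap",
]

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")
# Strong/weak conserving pairs, unaffected by GC-biased gene conversion.
_BGC_NEUTRAL_PAIRS = (frozenset("AT"), frozenset("GC"))

CATEGORIES = ("shared", "private_pop1", "private_pop2", "monomorphic", "fixed_difference")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP with per-population alternate-allele frequencies."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    freq_by_pop: Mapping[str, float]
    func_class: str = "other"
    gene_id: str = ""
    recomb_rate: float | None = None
    gene_sets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"alleles must be single nucleotides, got {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for pop, f in self.freq_by_pop.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency for {pop} out of [0,1]: {f}")


@dataclass(frozen=True)
class ClassifiedSite:
    site: SiteRecord
    category: str
    focal_maf: float


@dataclass
class BinnedCounts:
    """Per-frequency-bin count tables plus the pooled >0.1 bin.

    Bins are half-open (lo, hi] over folded MAF, so a site at exactly 0.1
    falls in the lowest bin and is excluded from the pooled strictly-above-0.1
    set; MAF exactly 0.5 falls in the top bin.
    """

    bin_edges: np.ndarray
    per_bin: list[PolymorphismCounts]
    combined_above: PolymorphismCounts
    flagged: list[bool] = field(default_factory=list)
    combined_flagged: bool = False

    @property
    def total(self) -> PolymorphismCounts:
        pooled = PolymorphismCounts(0, 0, 0, 0)
        for t in self.per_bin:
            pooled = pooled + t
        return pooled


def fold_maf(freq: float) -> float:
    """Fold an allele frequency onto the minor-allele scale, min(f, 1-f)."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency out of [0,1]: {freq}")
    return min(freq, 1.0 - freq)


def _segregating(f: float) -> bool:
    return 0.0 < f < 1.0


def classify_shared_private(
    sites: Iterable[SiteRecord],
    pop1: str,
    pop2: str,
    focal: str,
) -> list[ClassifiedSite]:
    """Categorize each site as shared/private/monomorphic/fixed_difference.

    ``focal_maf`` is the folded frequency in the focal population, computed
    for shared sites and for sites private to the focal population.  Sites
    private to the non-focal population are excluded from the returned
    analysis set (they belong to the reciprocal analysis); sites with a
    missing frequency are rejected and logged.
    """
    if focal not in (pop1, pop2):
        raise ValueError(f"focal population {focal!r} must be one of {pop1!r}, {pop2!r}")
    out: list[ClassifiedSite] = []
    n_rejected = 0
    for site in sites:
        try:
            f1 = site.freq_by_pop[pop1]
            f2 = site.freq_by_pop[pop2]
        except KeyError as exc:
            n_rejected += 1
            logger.warning("site %s:%s rejected: missing frequency for %s", site.chrom, site.pos, exc)
            continue
        seg1, seg2 = _segregating(f1), _segregating(f2)
        if seg1 and seg2:
            category = "shared"
        elif seg1:
            category = "private_pop1"
        elif seg2:
            category = "private_pop2"
        elif f1 == f2:
            category = "monomorphic"
        else:
            category = "fixed_difference"
        focal_freq = f1 if focal == pop1 else f2
        out.append(ClassifiedSite(site, category, fold_maf(focal_freq)))
    if n_rejected:
        logger.info("rejected %d sites with missing frequencies", n_rejected)
    return out


def _focal_private_category(classified: Sequence[ClassifiedSite], focal_is_pop1: bool) -> str:
    return "private_pop1" if focal_is_pop1 else "private_pop2"


def bin_by_frequency(
    classified: Iterable[ClassifiedSite],
    bin_width: float = 0.1,
    focal_private: str = "private_pop1",
) -> BinnedCounts:
    """Bin shared and focal-private sites by folded MAF into count tables.

    Only shared sites and sites in the ``focal_private`` category enter the
    tables, and only nonsynonymous/synonymous functional classes are counted.
    The pooled table ``combined_above`` sums every bin whose lower edge is at
    least 0.1 (i.e. all sites with focal MAF strictly above 0.1).
    """
    n_bins_f = 0.5 / bin_width
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} must divide 0.5 evenly")
    n_bins = int(round(n_bins_f))
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    cells = np.zeros((n_bins, 4))  # columns: s_n, s_s, r_n, r_s
    for cs in classified:
        if cs.category not in ("shared", focal_private):
            continue
        fc = cs.site.func_class
        if fc not in ("nonsynonymous", "synonymous"):
            continue
        if cs.focal_maf <= 0.0:
            continue  # folded frequency 0: not polymorphic in the focal pop
        # half-open bins (lo, hi]: index by ceil(maf/width) - 1
        idx = min(int(np.ceil(cs.focal_maf / bin_width)) - 1, n_bins - 1)
        col = (0 if fc == "nonsynonymous" else 1) if cs.category == "shared" else (
            2 if fc == "nonsynonymous" else 3
        )
        cells[idx, col] += 1
    per_bin = [PolymorphismCounts(*row) for row in cells]
    above = cells[1:].sum(axis=0)
    return BinnedCounts(
        bin_edges=edges,
        per_bin=per_bin,
        combined_above=PolymorphismCounts(*above),
        flagged=[False] * n_bins,
    )


def apply_min_count_filter(binned: BinnedCounts, min_polymorphisms: int = 20) -> BinnedCounts:
    """Flag (not delete) bins where any of the four cells is below the threshold."""
    if min_polymorphisms < 0:
        raise ValueError("min_polymorphisms must be >= 0")

    def low(t: PolymorphismCounts) -> bool:
        return bool(min(t.s_n, t.s_s, t.r_n, t.r_s) < min_polymorphisms)

    return BinnedCounts(
        bin_edges=binned.bin_edges,
        per_bin=binned.per_bin,
        combined_above=binned.combined_above,
        flagged=[low(t) for t in binned.per_bin],
        combined_flagged=low(binned.combined_above),
    )


def bgc_filter(sites: Iterable[SiteRecord]) -> list[SiteRecord]:
    """Retain only A<>T and G<>C mutations, which GC-biased gene conversion cannot favour."""
    return [
        s for s in sites if frozenset((s.ref_allele, s.alt_allele)) in _BGC_NEUTRAL_PAIRS
    ]


def split_by_recombination(
    sites: Iterable[SiteRecord],
    gene_rates: Mapping[str, float] | None = None,
) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Partition sites into low/high recombination halves at the median gene rate.

    The split operates on genes, not sites: each gene gets one rate (from
    ``gene_rates`` or the mean of its sites' ``recomb_rate``), genes are
    divided at the median rate with ties going to the low partition, and sites
    follow their gene.  Genes with no rate are excluded and logged.
    """
    sites = list(sites)
    by_gene: dict[str, list[SiteRecord]] = defaultdict(list)
    for s in sites:
        by_gene[s.gene_id].append(s)

    rates: dict[str, float] = {}
    excluded = []
    for gene, gsites in by_gene.items():
        if gene_rates is not None and gene in gene_rates:
            rates[gene] = gene_rates[gene]
        else:
            site_rates = [s.recomb_rate for s in gsites if s.recomb_rate is not None]
            if site_rates:
                rates[gene] = float(np.mean(site_rates))
            else:
                excluded.append(gene)
    for gene in excluded:
        logger.warning("gene %s excluded from recombination split: no rate available", gene)
    if not rates:
        return [], []
    median = float(np.median(list(rates.values())))
    low, high = [], []
    for gene, rate in rates.items():
        (low if rate <= median else high).extend(by_gene[gene])
    return low, high


def group_by_gene_set(
    classified: Iterable[ClassifiedSite],
    set_map: Mapping[str, Iterable[str]] | None = None,
    min_polys_above_01: int = 100,
    bin_width: float = 0.1,
    focal_private: str = "private_pop1",
    complement_of: str | None = None,
) -> dict[str, BinnedCounts]:
    """Pool binned counts per gene set, flagging sets with sparse high-frequency data.

    ``set_map`` maps gene_id to its set labels (defaulting to the
    ``gene_sets`` carried on each site).  Sets whose total number of counted
    polymorphisms at focal MAF > 0.1 falls below ``min_polys_above_01`` are
    flagged.  If ``complement_of`` names a set, a pseudo-set
    ``"non_<name>"`` containing every site outside it is included.
    """
    classified = list(classified)
    membership: dict[str, list[ClassifiedSite]] = defaultdict(list)
    for cs in classified:
        if set_map is not None:
            labels = set_map.get(cs.site.gene_id, ())
        else:
            labels = cs.site.gene_sets
        for label in labels:
            membership[label].append(cs)
    if complement_of is not None:
        inside = {
            id(cs)
            for cs in membership.get(complement_of, [])
        }
        membership[f"non_{complement_of}"] = [cs for cs in classified if id(cs) not in inside]

    out: dict[str, BinnedCounts] = {}
    for label, members in membership.items():
        binned = bin_by_frequency(members, bin_width=bin_width, focal_private=focal_private)
        above = binned.combined_above
        binned.combined_flagged = above.total < min_polys_above_01
        out[label] = binned
    return out


def expected_random_overlap(
    candidate_count: int, background_fraction: float
) -> tuple[float, int]:
    """Expected chance overlap between a candidate list and a background set.

    Returns the raw expectation ``candidate_count * background_fraction`` and
    its nearest-integer rounding.
    """
    if candidate_count < 0:
        raise ValueError("candidate_count must be >= 0")
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError("background_fraction must lie in [0, 1]")
    raw = candidate_count * background_fraction
    return raw, round(raw)
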