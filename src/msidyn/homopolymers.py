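"""Coding-homopolymer statistics for MMR-deficient tumors.

Microsatellite instability erodes mononucleotide runs (homopolymers) in coding
sequence. This module represents homopolymer loci, calls frameshift
instability from read-length distributions (a site is mutant when at least 5%
of reads deviate from the reference length, with at least 50 reads present),
computes the Shannon diversity of repeat-length alleles, summarizes mutated
fractions by base class (A:T vs C:G), and classifies whether a
premature-termination variant is positioned to escape nonsense-mediated decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy

__all__ = [
    "HomopolymerSite",
    "LengthDistribution",
    "FrameshiftCall",
    "DiversitySummary",
    "PtcContext",
    "call_frameshift",
    "shannon_site",
    "filter_catalog",
    "mutated_fraction_by_base",
    "classify_nmd_escape",
]


@dataclass(frozen=True)
class HomopolymerSite:
    """A mononucleotide run; ``start`` is the 1-based position of the first
    repeat base and ``ref_length`` its reference repeat count."""

    chrom: str
    start: int
    unit: str
    ref_length: int
    gene: str | None = None

    def __post_init__(self):
        if self.ref_length < 1:
            raise ValueError("ref_length must be >= 1")
        if self.unit.upper() not in "ACGT" or len(self.unit) != 1:
            raise ValueError(f"unit must be a single base, got {self.unit!r}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.start}:{self.unit}{self.ref_length}"

    @property
    def base_class(self) -> str:
        """Strand-pooled base class: A and T units are 'A:T', C and G 'C:G'."""
        return "A:T" if self.unit.upper() in "AT" else "C:G"


@dataclass
class LengthDistribution:
    """Read counts per observed repeat length, tumor plus optional matched
    normal."""

    site: HomopolymerSite
    tumor_counts: dict[int, int]
    normal_counts: dict[int, int] | None = None

    def __post_init__(self):
        for counts in (self.tumor_counts, self.normal_counts):
            if counts and any(c < 0 for c in counts.values()):
                raise ValueError("read counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(sum(self.tumor_counts.values()))


@dataclass
class FrameshiftCall:
    site: HomopolymerSite
    status: str  # mutant | wild_type | no_call
    unstable_fraction: float
    total_reads: int
    min_unstable_frac: float
    min_reads: int
    germline_flag: bool = False


@dataclass
class DiversitySummary:
    site: HomopolymerSite
    shannon: float
    n_lengths: int
    proportions: dict[int, float]


@dataclass(frozen=True)
class PtcContext:
    """Position of a premature-termination variant within its transcript."""

    exon_index: int
    n_exons: int
    cds_offset_nt: int
    dist_to_last_junction_bp: int | None = None

    def __post_init__(self):
        if not (1 <= self.exon_index <= self.n_exons):
            raise ValueError("exon_index must be within [1, n_exons]")


def call_frameshift(
    dist: LengthDistribution,
    min_unstable_frac: float = 0.05,
    min_reads: int = 50,
) -> FrameshiftCall:
    """Call frameshift instability from a read-length distribution.

    A read is unstable when its length differs from the site's reference
    length (insertions and deletions pooled). The site is mutant when at least
    ``min_unstable_frac`` of reads are unstable and at least ``min_reads``
    reads are present (both boundaries inclusive); below ``min_reads`` the
    result is a no-call. When a matched normal is present and itself shows the
    unstable fraction at or above threshold, the call is flagged as possible
    germline/artifact.
    """
    total = dist.total_reads
    ref_len = dist.site.ref_length
    unstable = sum(c for l, c in dist.tumor_counts.items() if l != ref_len)
    frac = unstable / total if total else 0.0
    if total < min_reads:
        status = "no_call"
    elif frac >= min_unstable_frac:
        status = "mutant"
    else:
        status = "wild_type"
    germline = False
    if dist.normal_counts:
        n_total = sum(dist.normal_counts.values())
        n_unstable = sum(c for l, c in dist.normal_counts.items() if l != ref_len)
        if n_total and n_unstable / n_total >= min_unstable_frac:
            germline = True
    return FrameshiftCall(
        site=dist.site,
        status=status,
        unstable_fraction=frac,
        total_reads=total,
        min_unstable_frac=min_unstable_frac,
        min_reads=min_reads,
        germline_flag=germline,
    )


def shannon_site(dist: LengthDistribution) -> DiversitySummary:
    """Shannon diversity -sum(p_i ln p_i) over observed repeat lengths.

    ``p_i`` is the proportion of total reads at the i-th observed length and
    the sum runs over the R lengths with nonzero counts (0 ln 0 := 0).
    """
    items = [(l, c) for l, c in sorted(dist.tumor_counts.items()) if c > 0]
    total = sum(c for _, c in items)
    if total == 0:
        raise ValueError(f"no reads at {dist.site.site_id}; diversity undefined")
    counts = np.array([c for _, c in items], dtype=float)
    props = counts / total
    h = float(entropy(props))  # natural log
    return DiversitySummary(
        site=dist.site,
        shannon=h,
        n_lengths=len(items),
        proportions={l: p for (l, _), p in zip(items, props)},
    )


def filter_catalog(
    sites: list[HomopolymerSite], min_len: int = 6, max_len: int = 11
) -> list[HomopolymerSite]:
    """Retain exonic homopolymers with reference length in [min_len, max_len]
    inclusive (default 6-11, the range informative for instability analysis)."""
    return [s for s in sites if min_len <= s.ref_length <= max_len]


def mutated_fraction_by_base(calls: list[FrameshiftCall]) -> dict[str, float | None]:
    """Fraction of called sites that are mutant, per strand-pooled base class.

    No-calls are excluded from the denominator. A class with no called sites
    maps to None.
    """
    out: dict[str, float | None] = {}
    for cls in ("A:T", "C:G"):
        considered = [
            c for c in calls
            if c.site.base_class == cls and c.status in ("mutant", "wild_type")
        ]
        if not considered:
            out[cls] = None
        else:
            n_mut = sum(c.status == "mutant" for c in considered)
            out[cls] = n_mut / len(considered)
    return out


def classify_nmd_escape(ctx: PtcContext) -> tuple[bool, str]:
    """Positional nonsense-mediated-decay escape rules for a PTC variant.

    Escape when the variant lies (1) in the first exon within the first 200 nt
    of the coding sequence, (2) in the last exon, or (3) in the penultimate
    exon within 50 bp of the last exon-exon junction. Returns ``(escape,
    category)`` where category names the rule that fired.
    """
    if ctx.exon_index == ctx.n_exons:
        return True, "last_exon"
    if ctx.exon_index == 1 and ctx.cds_offset_nt <= 200:
        return True, "first_exon_proximal"
    if ctx.exon_index == ctx.n_exons - 1:
        if ctx.dist_to_last_junction_bp is not None and ctx.dist_to_last_junction_bp <= 50:
            return True, "penultimate_near_junction"
        return False, "penultimate_far"
    if ctx.exon_index == 1:
        return False, "first_exon_far"
    return False, "middle_exon"
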