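"""Biallelic site resolution, filtering and per-SNP FST for pooled reads.

Pool-seq estimates allele frequencies from read counts rather than from
genotypes, so every step here works on per-pool read counts.  A sync
record is reduced to a biallelic site by requiring each "real" allele to
reach a combined minimum read count across the two pools (alleles below
that are treated as sequencing errors), and sites are screened by
per-pool coverage and by combined minor allele frequency (MAF).

The MAF filter belongs to the outlier-scan branch of the pipeline only;
the demographic (SFS) branch deliberately keeps low-MAF sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

from .io_formats import SyncRecord

__all__ = [
    "FilterConfig",
    "BiallelicSite",
    "Rejection",
    "RejectReason",
    "resolve_biallelic",
    "apply_site_filters",
    "fst_site",
    "sites_from_sync",
]

#: sync count-field order; only the four nucleotides are candidate alleles
_BASES = ("A", "T", "C", "G")


class RejectReason(str, Enum):
    MONOMORPHIC = "monomorphic"
    MULTIALLELIC = "multiallelic"
    LOW_COVERAGE = "low_coverage"
    HIGH_COVERAGE = "high_coverage"
    LOW_COUNT = "low_count"
    LOW_MAF = "low_maf"


@dataclass(frozen=True)
class Rejection:
    """A structured rejection of a site, with the failing rule."""

    reason: RejectReason
    chrom: str
    pos: int


@dataclass(frozen=True)
class FilterConfig:
    """Site-filtering parameters for pooled data.

    Defaults match a stringent pooled exome design: a minor allele must
    be seen at least ``min_count`` times across the two pools combined,
    each pool must have coverage within ``[min_coverage, max_coverage]``
    at the site, and (in the scan branch only) the combined minor allele
    frequency must be at least ``maf_min``.  ``pool_haploid_size`` is the
    number of haploid chromosomes per pool (20 diploids -> 40).
    """

    min_count: int = 6
    min_coverage: int = 80
    max_coverage: int = 500
    maf_min: float = 0.05
    pool_haploid_size: int = 40

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= self.max_coverage):
            raise ValueError("need 0 < min_coverage <= max_coverage")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.pool_haploid_size < 2:
            raise ValueError("pool_haploid_size must be >= 2")


@dataclass(frozen=True)
class BiallelicSite:
    """A filtered biallelic site with per-pool minor-allele frequencies."""

    chrom: str
    pos: int
    major: str
    minor: str
    coverage: tuple[int, int]
    minor_counts: tuple[int, int]
    freqs: tuple[float, float]
    maf: float
    fst: float | None = None


def resolve_biallelic(
    record: SyncRecord,
    cfg: FilterConfig,
    pool_indices: tuple[int, int] = (0, 1),
) -> BiallelicSite | Rejection:
    """Reduce a sync record to a biallelic site for one pool pair.

    An allele is "real" when its combined read count across the two
    pools reaches ``cfg.min_count``; sites with fewer than two real
    alleles are non-informative (monomorphic), sites with more are
    multiallelic, and both are rejected.  Coverage and frequencies are
    computed over the two real alleles only, so sub-threshold error
    reads never influence the frequency estimates.
    """
    if len(record.pools) < 2:
        raise ValueError("sync record has fewer than 2 pools")
    p1 = record.pools[pool_indices[0]]
    p2 = record.pools[pool_indices[1]]
    combined = [p1[i] + p2[i] for i in range(4)]
    real = [i for i in range(4) if combined[i] >= cfg.min_count]
    if len(real) < 2:
        return Rejection(RejectReason.MONOMORPHIC, record.chrom, record.pos)
    if len(real) > 2:
        return Rejection(RejectReason.MULTIALLELIC, record.chrom, record.pos)
    a, b = real
    # major = larger combined count; ties broken by alphabetical base order
    # (indices are in sync order A,T,C,G, not alphabetical)
    if (combined[b], _BASES[a]) > (combined[a], _BASES[b]):
        major_i, minor_i = b, a
    else:
        major_i, minor_i = a, b
    cov = (p1[major_i] + p1[minor_i], p2[major_i] + p2[minor_i])
    minor_counts = (p1[minor_i], p2[minor_i])
    freqs = tuple(
        mc / c if c > 0 else 0.0 for mc, c in zip(minor_counts, cov)
    )
    total_cov = cov[0] + cov[1]
    maf = (minor_counts[0] + minor_counts[1]) / total_cov
    return BiallelicSite(
        chrom=record.chrom,
        pos=record.pos,
        major=_BASES[major_i],
        minor=_BASES[minor_i],
        coverage=cov,
        minor_counts=minor_counts,
        freqs=freqs,  # type: ignore[arg-type]
        maf=maf,
    )


def apply_site_filters(
    site: BiallelicSite,
    cfg: FilterConfig,
    maf_filter: bool = True,
) -> Rejection | None:
    """Check coverage, count and (optionally) MAF filters.

    Returns ``None`` when the site passes, otherwise a structured
    rejection.  ``maf_filter=False`` is the demographic-SFS branch,
    which keeps low-MAF sites.
    """
    for c in site.coverage:
        if c < cfg.min_coverage:
            return Rejection(RejectReason.LOW_COVERAGE, site.chrom, site.pos)
        if c > cfg.max_coverage:
            return Rejection(RejectReason.HIGH_COVERAGE, site.chrom, site.pos)
    if sum(site.minor_counts) < cfg.min_count:
        return Rejection(RejectReason.LOW_COUNT, site.chrom, site.pos)
    if maf_filter and site.maf < cfg.maf_min:
        return Rejection(RejectReason.LOW_MAF, site.chrom, site.pos)
    return None


def fst_site(site: BiallelicSite, corrected: bool = False,
             pool_haploid_size: int = 40) -> float:
    """Per-SNP FST from the two pool allele frequencies.

    Uses the heterozygosity form: with per-pool minor allele frequency
    ``f_p``, ``pi_p = 2 f_p (1 - f_p)``, ``pi_S = (pi_1 + pi_2)/2``,
    ``pi_T = 2 fbar (1 - fbar)`` with the unweighted mean ``fbar``, and
    ``FST = (pi_T - pi_S) / pi_T`` (0 when ``pi_T = 0``).

    With ``corrected=True`` each heterozygosity gets the finite-sample
    factor ``n/(n-1)`` with ``n = min(pool_haploid_size, coverage)`` per
    pool (and the pooled total for ``pi_T``); corrected values may be
    negative and are deliberately not clamped, since downstream outlier
    calling is quantile-based.
    """
    f1, f2 = site.freqs
    pi1 = 2.0 * f1 * (1.0 - f1)
    pi2 = 2.0 * f2 * (1.0 - f2)
    fbar = 0.5 * (f1 + f2)
    pi_t = 2.0 * fbar * (1.0 - fbar)
    if corrected:
        n1 = min(pool_haploid_size, site.coverage[0])
        n2 = min(pool_haploid_size, site.coverage[1])
        nt = min(2 * pool_haploid_size, site.coverage[0] + site.coverage[1])
        pi1 *= n1 / (n1 - 1)
        pi2 *= n2 / (n2 - 1)
        pi_t *= nt / (nt - 1)
    pi_s = 0.5 * (pi1 + pi2)
    if pi_t == 0.0:
        return 0.0
    return (pi_t - pi_s) / pi_t


def sites_from_sync(
    records: Iterable[SyncRecord],
    cfg: FilterConfig,
    maf_filter: bool = True,
    pool_indices: tuple[int, int] = (0, 1),
    corrected_fst: bool = False,
) -> tuple[list[BiallelicSite], dict[str, int]]:
    """Run resolution + filters + FST over a stream of sync records.

    Returns the passing sites (with ``fst`` filled in) and a tally of
    rejection reasons.
    """
    sites: list[BiallelicSite] = []
    tally: dict[str, int] = {r.value: 0 for r in RejectReason}
    for rec in records:
        resolved = resolve_biallelic(rec, cfg, pool_indices)
        if isinstance(resolved, Rejection):
            tally[resolved.reason.value] += 1
            continue
        rejection = apply_site_filters(resolved, cfg, maf_filter=maf_filter)
        if rejection is not None:
            tally[rejection.reason.value] += 1
            continue
        value = fst_site(
            resolved,
            corrected=corrected_fst,
            pool_haploid_size=cfg.pool_haploid_size,
        )
        sites.append(replace(resolved, fst=value))
    return sites, tally
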