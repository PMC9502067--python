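"""Divergence-island detection by a sliding-window resampling test.

The scan slides a window of 10 adjacent SNPs along each chromosome in
steps of 2 SNPs and counts, per window, the SNPs whose FST is strictly
above the genome-wide top-percentile threshold.  Significance comes from
an empirical null built by resampling 10 SNPs (with replacement) from
the genome-wide FST vector many times; the null is window-independent by
construction, so it is computed once and reused for every window.
Significant windows that share a SNP merge into maximal non-overlapping
islands.

Gene-set enrichment of island genes uses upper-tail hypergeometric tests
with Bonferroni correction against a user-supplied background list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneInterval
from .poolfreq import BiallelicSite

__all__ = [
    "Window",
    "NullDistribution",
    "Island",
    "EnrichmentResult",
    "fst_threshold",
    "enumerate_windows",
    "score_windows",
    "resample_null",
    "window_pvalue",
    "call_islands",
    "shared_islands",
    "genes_in_islands",
    "enrich_terms",
]


@dataclass
class Window:
    """A run of consecutive SNPs on one chromosome."""

    chrom: str
    index: int  #: ordinal of the window in the scan (0-based)
    start_ordinal: int  #: 0-based ordinal of the first member SNP (per chrom)
    sites: list[BiallelicSite] = field(repr=False, default_factory=list)
    outlier_count: int | None = None
    p_value: float | None = None

    @property
    def start_pos(self) -> int:
        return self.sites[0].pos

    @property
    def end_pos(self) -> int:
        return self.sites[-1].pos

    @property
    def end_ordinal(self) -> int:
        return self.start_ordinal + len(self.sites) - 1


@dataclass(frozen=True)
class NullDistribution:
    """Resampling null over per-window outlier counts.

    ``histogram[c]`` is the number of resampled windows with exactly
    ``c`` outlier SNPs; ``p_hat`` is the exact fraction of genome-wide
    values strictly above the threshold.
    """

    resamples: int
    histogram: np.ndarray
    threshold: float
    p_hat: float
    seed: int | None = None

    def tail_probability(self, count: int) -> float:
        """Empirical P(outlier count >= count); 1 for count <= 0."""
        if count <= 0:
            return 1.0
        if count >= len(self.histogram):
            return 0.0
        return float(self.histogram[count:].sum()) / self.resamples


@dataclass(frozen=True)
class Island:
    """A maximal run of merged significant windows (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    window_indices: tuple[int, ...]
    n_snps: int
    min_p: float


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    term_size: int
    candidate_size: int
    overlap: int
    p_value: float
    p_bonferroni: float


def fst_threshold(values: Sequence[float], quantile: float = 0.99) -> float:
    """Top-percentile threshold via the linear-interpolation sample quantile.

    Uses the ``h = (n - 1) q + 1`` convention; the outlier predicate
    downstream is *strictly greater than* this threshold.  Fewer than 100
    values make the upper quantile unstable and raise.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 100:
        raise ValueError(
            f"need at least 100 FST values for a stable quantile, got "
            f"{arr.size}"
        )
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(arr, quantile, method="linear"))


def enumerate_windows(
    sites: Sequence[BiallelicSite],
    size: int = 10,
    step: int = 2,
) -> list[Window]:
    """Sliding windows of ``size`` adjacent SNPs every ``step`` SNPs.

    Sites must be sorted by (chromosome block, position); windows never
    cross chromosomes, and a trailing run shorter than ``size`` SNPs
    yields no window.
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    # verify sortedness: chromosomes contiguous, positions non-decreasing
    seen_chroms: set[str] = set()
    by_chrom: dict[str, list[BiallelicSite]] = {}
    prev_chrom: str | None = None
    prev_pos = -1
    for s in sites:
        if s.chrom != prev_chrom:
            if s.chrom in seen_chroms:
                raise ValueError(
                    f"input not sorted: chromosome {s.chrom} appears in "
                    "multiple blocks"
                )
            seen_chroms.add(s.chrom)
            prev_chrom = s.chrom
            prev_pos = -1
        if s.pos < prev_pos:
            raise ValueError(
                f"input not sorted: {s.chrom}:{s.pos} after position "
                f"{prev_pos}"
            )
        prev_pos = s.pos
        by_chrom.setdefault(s.chrom, []).append(s)
    windows: list[Window] = []
    for chrom, chrom_sites in by_chrom.items():
        n = len(chrom_sites)
        for start in range(0, n - size + 1, step):
            windows.append(
                Window(
                    chrom=chrom,
                    index=len(windows),
                    start_ordinal=start,
                    sites=chrom_sites[start : start + size],
                )
            )
    return windows


def score_windows(
    windows: Iterable[Window],
    threshold: float,
    null: NullDistribution | None = None,
) -> None:
    """Fill in outlier counts (strict ``>``) and, when given, p-values."""
    for w in windows:
        w.outlier_count = sum(
            1 for s in w.sites if s.fst is not None and s.fst > threshold
        )
        if null is not None:
            w.p_value = window_pvalue(w, null)


def resample_null(
    values: Sequence[float],
    threshold: float,
    resamples: int = 100_000,
    seed: int | None = None,
    window_size: int = 10,
) -> NullDistribution:
    """Empirical null for the per-window outlier count.

    Each resample draws ``window_size`` values uniformly with replacement
    from the genome-wide FST vector and counts how many are strictly
    above the threshold.  With outlier fraction ``p_hat`` the histogram
    converges to Binomial(window_size, p_hat).
    """
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    arr = np.asarray(values, dtype=float)
    outlier = arr > threshold
    rng = np.random.default_rng(seed)
    counts = np.zeros(resamples, dtype=np.int64)
    # chunked to bound memory at large resample counts
    chunk = 200_000
    done = 0
    while done < resamples:
        b = min(chunk, resamples - done)
        draws = rng.integers(0, arr.size, size=(b, window_size))
        counts[done : done + b] = outlier[draws].sum(axis=1)
        done += b
    histogram = np.bincount(counts, minlength=window_size + 1)
    return NullDistribution(
        resamples=resamples,
        histogram=histogram,
        threshold=threshold,
        p_hat=float(outlier.mean()),
        seed=seed,
    )


def window_pvalue(window: Window, null: NullDistribution) -> float:
    """One-sided upper-tail p-value of a window's outlier count."""
    if window.outlier_count is None:
        raise ValueError("window has no outlier count; call score_windows")
    return null.tail_probability(window.outlier_count)


def call_islands(
    windows: Sequence[Window], alpha: float = 0.001
) -> list[Island]:
    """Merge significant windows (p < alpha) into non-overlapping islands.

    Windows sharing at least one member SNP merge; the island span runs
    from the first to the last member SNP position.
    """
    sig = [w for w in windows if w.p_value is not None and w.p_value < alpha]
    by_chrom: dict[str, list[Window]] = {}
    for w in sig:
        by_chrom.setdefault(w.chrom, []).append(w)
    islands: list[Island] = []
    for chrom in by_chrom:
        ws = sorted(by_chrom[chrom], key=lambda w: w.start_ordinal)
        group: list[Window] = []
        for w in ws:
            if group and w.start_ordinal <= group[-1].end_ordinal:
                group.append(w)
            else:
                if group:
                    islands.append(_merge(chrom, group))
                group = [w]
        if group:
            islands.append(_merge(chrom, group))
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


def _merge(chrom: str, group: list[Window]) -> Island:
    first = min(group, key=lambda w: w.start_ordinal)
    last = max(group, key=lambda w: w.end_ordinal)
    return Island(
        chrom=chrom,
        start=first.start_pos,
        end=last.end_pos,
        window_indices=tuple(w.index for w in group),
        n_snps=last.end_ordinal - first.start_ordinal + 1,
        min_p=min(w.p_value for w in group),  # type: ignore[type-var]
    )


def shared_islands(
    islands_a: Sequence[Island], islands_b: Sequence[Island]
) -> list[tuple[str, int, int]]:
    """Intersections (>= 1 bp) between two island sets on shared coordinates."""
    out: list[tuple[str, int, int]] = []
    for a in islands_a:
        for b in islands_b:
            if a.chrom != b.chrom:
                continue
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if lo <= hi:
                out.append((a.chrom, lo, hi))
    out.sort()
    return out


def genes_in_islands(
    islands: Sequence[Island], genes: Sequence[GeneInterval]
) -> list[str]:
    """Deduplicated, sorted identifiers of genes overlapping any island."""
    hits: set[str] = set()
    for g in genes:
        for isl in islands:
            if (
                g.chrom == isl.chrom
                and g.start <= isl.end
                and g.end >= isl.start
            ):
                hits.add(g.gene_id)
                break
    return sorted(hits)


def enrich_terms(
    candidates: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric gene-set enrichment with Bonferroni correction.

    For each term with at least one background gene, computes the exact
    upper tail ``P(X >= k)`` of drawing ``k`` term genes among the
    candidates (population = background, successes = term genes in the
    background, draws = candidates).  The Bonferroni factor is the number
    of terms actually tested.
    """
    bg = set(background)
    cand = set(candidates)
    missing = cand - bg
    if missing:
        raise ValueError(
            f"candidate genes absent from background: {sorted(missing)[:5]}"
        )
    tested: list[tuple[str, int, int]] = []
    for term, genes in term_map.items():
        term_genes = set(genes) & bg
        if not term_genes:
            continue
        k = len(term_genes & cand)
        tested.append((term, len(term_genes), k))
    n_terms = len(tested)
    results = []
    for term, K, k in tested:
        p = float(stats.hypergeom.sf(k - 1, len(bg), K, len(cand)))
        results.append(
            EnrichmentResult(
                term=term,
                term_size=K,
                candidate_size=len(cand),
                overlap=k,
                p_value=p,
                p_bonferroni=min(1.0, p * n_terms),
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.p_value, r.term))
    return results
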