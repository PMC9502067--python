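"""End-to-end composition of the scan pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import islands as isl
from .io_formats import SyncRecord
from .poolfreq import BiallelicSite, FilterConfig, sites_from_sync

__all__ = ["ScanResult", "fst_scan"]


@dataclass
class ScanResult:
    """Everything the island scan produces for one species pair."""

    sites: list[BiallelicSite]
    threshold: float
    null: isl.NullDistribution
    windows: list[isl.Window]
    islands: list[isl.Island]
    rejections: dict[str, int]


def fst_scan(
    records: Sequence[SyncRecord],
    cfg: FilterConfig | None = None,
    *,
    quantile: float = 0.99,
    window_size: int = 10,
    step: int = 2,
    resamples: int = 100_000,
    alpha: float = 0.001,
    seed: int | None = None,
    corrected_fst: bool = False,
) -> ScanResult:
    """Sync records -> filtered sites -> per-SNP FST -> windows -> islands.

    Applies the full scan-branch filter set (including the MAF filter),
    computes per-SNP FST, derives the genome-wide top-percentile
    threshold, builds the resampling null once, scores every sliding
    window against it and merges significant windows into islands.
    """
    cfg = cfg or FilterConfig()
    sites, rejections = sites_from_sync(
        records, cfg, maf_filter=True, corrected_fst=corrected_fst
    )
    fst_values = [s.fst for s in sites]
    threshold = isl.fst_threshold(fst_values, quantile)
    null = isl.resample_null(
        fst_values, threshold, resamples=resamples, seed=seed,
        window_size=window_size,
    )
    windows = isl.enumerate_windows(sites, size=window_size, step=step)
    isl.score_windows(windows, threshold, null)
    called = isl.call_islands(windows, alpha=alpha)
    return ScanResult(
        sites=sites,
        threshold=threshold,
        null=null,
        windows=windows,
        islands=called,
        rejections=rejections,
    )
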