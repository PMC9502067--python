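"""Synthetic pool-seq data with known truth.

Generates complete datasets for exercising the pipeline end to end:
background allele-frequency pairs come from a two-population structured
coalescent, localized blocks of SNPs ("islands") are overwritten with
strongly divergent frequency pairs, and pooled read counts are drawn
binomially at a coverage law matching the pipeline's coverage filters.
Every dataset carries a machine-readable truth table.

Islands are imposed at the allele-frequency level rather than by
simulating linked selection: the scan's detection surface needs
controllable truth, not a selection model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim
from .io_formats import SyncRecord, write_sync

__all__ = [
    "SynthConfig",
    "TruthTable",
    "default_background_model",
    "generate_truth_frequencies",
    "simulate_pool_counts",
    "generate_dataset",
]


def default_background_model() -> coalsim.DemographicModel:
    """Background divergence for synthetic datasets.

    A split with continuous symmetric migration, tuned so the mean
    per-SNP pooled FST lands near the few-percent genome-wide
    differentiation of a recently diverged species pair.
    """
    return coalsim.sym_mig(nu1=1.0, nu2=1.0, m=5.0, T=0.1)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic pooled-sequencing dataset.

    Defaults emulate a two-pool exome design: two pools of 20 diploids
    (40 haploid genomes each), 5,000 biallelic SNPs spread over two
    10-Mbp chromosomes, per-pool coverage Poisson(150) truncated to the
    pipeline's [80, 500] filter range, and 8 divergence islands of 20
    SNPs whose per-SNP frequency pairs come from Beta(8, 2) x Beta(2, 8)
    (strong, noisy differentiation against a weak background).
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
    )
    snp_density: float = 2.5e-4  #: SNPs per bp (5,000 over 20 Mbp)
    background_model: coalsim.DemographicModel = field(
        default_factory=default_background_model
    )
    n_islands: int = 8
    island_n_snps: int = 20
    island_beta1: tuple[float, float] = (8.0, 2.0)  #: pool-1 frequency law
    island_beta2: tuple[float, float] = (2.0, 8.0)  #: pool-2 frequency law
    pool_haploid_sizes: tuple[int, int] = (40, 40)
    coverage_mean: float = 150.0
    coverage_range: tuple[int, int] = (80, 500)
    error_rate: float = 0.0
    seed: int = 0

    #: minimum combined (sample) minor allele frequency of background SNPs.
    #: The emitted SNP set emulates a post-MAF-filter pool-seq callset, so
    #: background frequency pairs are drawn conditional on this; set to 0
    #: to emit the raw segregating-site law instead.
    background_maf_min: float = 0.05

    #: minimum SNP gap kept between islands so detected islands stay distinct
    island_min_gap_snps: int = 30

    def __post_init__(self) -> None:
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if self.island_n_snps < 1 or self.n_islands < 0:
            raise ValueError("invalid island configuration")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        lo, hi = self.coverage_range
        if not 0 < lo <= hi:
            raise ValueError("invalid coverage range")

    def snps_per_chrom(self) -> list[int]:
        return [
            int(round(length * self.snp_density))
            for _, length in self.chrom_lengths
        ]


@dataclass
class TruthTable:
    """Per-SNP generating truth plus island spans and parameters."""

    snps: pd.DataFrame  #: chrom, pos, p1, p2, in_island, island_id
    islands: pd.DataFrame  #: chrom, start, end, island_id (1-based inclusive)
    params: dict


def _place_islands(
    n_snps: int, n_islands: int, width: int, gap: int, rng: np.random.Generator
) -> list[int]:
    """Disjoint island start ordinals with at least ``gap`` SNPs between.

    Uses the standard spacing construction: sample sorted starts in a
    compressed coordinate system, then re-expand by the reserved width.
    """
    slack = n_snps - n_islands * (width + gap)
    if slack < 0:
        raise ValueError(
            f"cannot place {n_islands} islands of {width} SNPs (gap {gap}) "
            f"among {n_snps} SNPs"
        )
    base = np.sort(rng.choice(slack + 1, size=n_islands, replace=True))
    # nudge ties apart deterministically, then expand
    starts = [int(b) + i * (width + gap) + gap // 2 for i, b in enumerate(base)]
    return starts


def _conditioned_background_pairs(
    cfg: SynthConfig, total: int, seed: int
) -> np.ndarray:
    """Background frequency pairs with combined MAF above the cutoff.

    Rejection-samples coalescent SNPs until ``total`` pairs pass the
    combined minor-allele-frequency condition, so the emitted SNP set
    has the shape of a MAF-filtered pool-seq callset.
    """
    n1, n2 = cfg.pool_haploid_sizes
    kept: list[np.ndarray] = []
    have = 0
    batch_seed = seed
    while have < total:
        batch = coalsim.sample_snp_frequencies(
            cfg.background_model, n1, n2, 2 * (total - have) + 100,
            batch_seed % 2**31,
        )
        if cfg.background_maf_min > 0:
            combined = (n1 * batch[:, 0] + n2 * batch[:, 1]) / (n1 + n2)
            maf = np.minimum(combined, 1.0 - combined)
            batch = batch[maf >= cfg.background_maf_min]
        kept.append(batch)
        have += len(batch)
        batch_seed += 1
    return np.concatenate(kept)[:total]


def generate_truth_frequencies(cfg: SynthConfig) -> TruthTable:
    """Draw SNP positions and true per-pool allele-frequency pairs.

    Background pairs come from the structured coalescent under the
    configured demography (sample sizes = the pool haploid sizes);
    island-member SNPs get independent Beta-law frequency pairs.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(3)
    pos_rng = np.random.default_rng(children[0])
    isl_rng = np.random.default_rng(children[1])
    freq_seed_state = children[2].generate_state(1, dtype=np.uint32)[0]
    counts = cfg.snps_per_chrom()
    total = sum(counts)
    n1, n2 = cfg.pool_haploid_sizes
    freqs = _conditioned_background_pairs(
        cfg, total, int(freq_seed_state) % 2**31
    )
    chroms: list[str] = []
    positions: list[int] = []
    for (name, length), k in zip(cfg.chrom_lengths, counts):
        pos = np.sort(
            pos_rng.choice(np.arange(1, length + 1), size=k, replace=False)
        )
        chroms.extend([name] * k)
        positions.extend(int(p) for p in pos)
    in_island = np.zeros(total, dtype=bool)
    island_id = np.full(total, -1, dtype=int)
    island_rows = []
    # round-robin islands over chromosomes
    per_chrom = [0] * len(counts)
    for i in range(cfg.n_islands):
        per_chrom[i % len(counts)] += 1
    offset = 0
    isl_idx = 0
    for (name, _), k, n_isl in zip(cfg.chrom_lengths, counts, per_chrom):
        if n_isl:
            starts = _place_islands(
                k, n_isl, cfg.island_n_snps, cfg.island_min_gap_snps, isl_rng
            )
            for s in starts:
                sl = slice(offset + s, offset + s + cfg.island_n_snps)
                in_island[sl] = True
                island_id[sl] = isl_idx
                freqs[sl, 0] = isl_rng.beta(*cfg.island_beta1, cfg.island_n_snps)
                freqs[sl, 1] = isl_rng.beta(*cfg.island_beta2, cfg.island_n_snps)
                island_rows.append(
                    {
                        "chrom": name,
                        "start": positions[sl.start],
                        "end": positions[sl.stop - 1],
                        "island_id": isl_idx,
                    }
                )
                isl_idx += 1
        offset += k
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "p1": freqs[:, 0],
            "p2": freqs[:, 1],
            "in_island": in_island,
            "island_id": island_id,
        }
    )
    params = {"seed": cfg.seed, "n_snps": total, "n_islands": cfg.n_islands}
    return TruthTable(
        snps=snps, islands=pd.DataFrame(island_rows), params=params
    )


def _truncated_poisson(
    mean: float, lo: int, hi: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    out = rng.poisson(mean, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.poisson(mean, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_pool_counts(
    freq_pair: tuple[float, float],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Pooled read counts for one SNP: binomial reads at truncated coverage.

    By convention the major allele maps to base A and the minor allele
    to base T in the sync count order (A, T, C, G, N, del).  A non-zero
    error rate reassigns each read to a uniformly chosen other base.
    """
    pools = []
    for p in freq_pair:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency {p} outside [0, 1]")
        cov = int(
            _truncated_poisson(
                cfg.coverage_mean, *cfg.coverage_range, 1, rng
            )[0]
        )
        minor = int(rng.binomial(cov, p))
        counts = np.array([cov - minor, minor, 0, 0, 0, 0])
        if cfg.error_rate > 0:
            for src in range(4):
                if counts[src] == 0:
                    continue
                n_err = rng.binomial(counts[src], cfg.error_rate)
                counts[src] -= n_err
                targets = [b for b in range(4) if b != src]
                counts[targets] += rng.multinomial(
                    n_err, [1 / 3] * 3
                )
        pools.append(tuple(int(c) for c in counts))
    return pools[0], pools[1]


def generate_dataset(
    cfg: SynthConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write a full synthetic dataset: sync, truth BED/TSV, manifest JSON.

    Returns the paths of the written files.  The sync file round-trips
    through :func:`poolscape.io_formats.read_sync`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_truth_frequencies(cfg)
    read_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(4)[3]
    )
    records = []
    for row in truth.snps.itertuples(index=False):
        pool1, pool2 = simulate_pool_counts(
            (row.p1, row.p2), cfg, read_rng
        )
        records.append(
            SyncRecord(row.chrom, int(row.pos), "A", (pool1, pool2))
        )
    paths = {
        "sync": out / "pools.sync",
        "truth_bed": out / "truth_islands.bed",
        "truth_tsv": out / "truth_snps.tsv",
        "params": out / "params.json",
    }
    write_sync(records, paths["sync"])
    with open(paths["truth_bed"], "w") as fh:
        for row in truth.islands.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                f"island_{row.island_id}\n"
            )
    truth.snps.to_csv(paths["truth_tsv"], sep="\t", index=False)
    manifest = {
        "seed": cfg.seed,
        "n_snps": int(len(truth.snps)),
        "n_islands": int(cfg.n_islands),
        "island_n_snps": int(cfg.island_n_snps),
        "chrom_lengths": list(map(list, cfg.chrom_lengths)),
        "coverage_mean": cfg.coverage_mean,
        "coverage_range": list(cfg.coverage_range),
        "pool_haploid_sizes": list(cfg.pool_haploid_sizes),
        "background_model": cfg.background_model.name,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "seed": cfg.seed,
                    "chrom_lengths": list(map(list, cfg.chrom_lengths)),
                    "snp_density": cfg.snp_density,
                    "n_islands": cfg.n_islands,
                    "island_n_snps": cfg.island_n_snps,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    with open(paths["params"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
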