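"""Readers and writers for the external formats the pipeline touches.

Formats handled here:

* ``sync`` pooled allele counts (one line per site, one colon-delimited
  A:T:C:G:N:del count field per pool) — the de-facto pool-seq exchange
  format;
* gene annotation intervals as BED (0-based half-open) or GFF3 (1-based
  inclusive), normalized to 1-based inclusive coordinates internally;
* the SNP exchange table consumed by SFS-based demographic inference
  (one header line, then one row per SNP with per-population allele
  counts);
* plain TSV result tables for per-SNP FST values, windows, islands and
  enrichment results.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SyncRecord",
    "GeneInterval",
    "SnpTableRow",
    "SyncParseError",
    "read_sync",
    "write_sync",
    "apply_position_blacklist",
    "read_gene_intervals",
    "write_snp_table",
    "read_snp_table",
    "write_fst_table",
    "read_fst_table",
    "write_windows_table",
    "write_islands_bed",
    "write_enrichment_table",
]

#: base order of the count fields in a sync column
SYNC_BASES = ("A", "T", "C", "G", "N", "del")


class SyncParseError(ValueError):
    """A sync line that could not be parsed, with its line number."""


@dataclass(frozen=True)
class SyncRecord:
    """One site of a sync file: position plus per-pool base counts."""

    chrom: str
    pos: int
    ref: str
    pools: tuple[tuple[int, int, int, int, int, int], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        for counts in self.pools:
            if len(counts) != 6:
                raise ValueError("each pool needs exactly 6 counts")
            if any(c < 0 for c in counts):
                raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must not exceed end")


@dataclass(frozen=True)
class SnpTableRow:
    """One SNP of the SFS exchange table: two alleles, counts per pop."""

    chrom: str
    pos: int
    allele1: str
    allele2: str
    allele1_counts: tuple[int, ...]
    allele2_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.allele1_counts) != len(self.allele2_counts):
            raise ValueError("allele count vectors must have equal length")
        if any(c < 0 for c in self.allele1_counts + self.allele2_counts):
            raise ValueError("allele counts must be non-negative")


def read_sync(path: str | PathLike, expected_pool_count: int) -> list[SyncRecord]:
    """Parse a sync file; malformed lines raise rather than being skipped."""
    if expected_pool_count < 1:
        raise ValueError("expected_pool_count must be >= 1")
    records: list[SyncRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3 + expected_pool_count:
                raise SyncParseError(
                    f"line {lineno}: expected {expected_pool_count} pool "
                    f"columns after chrom/pos/ref, found {len(fields) - 3}"
                )
            chrom, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(
                    f"line {lineno}: position {pos_s!r} is not an integer"
                ) from None
            pools = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"line {lineno}: count field {col!r} does not have "
                        "6 colon-delimited entries"
                    )
                try:
                    counts = tuple(int(p) for p in parts)
                except ValueError:
                    raise SyncParseError(
                        f"line {lineno}: non-integer count in {col!r}"
                    ) from None
                pools.append(counts)
            try:
                records.append(SyncRecord(chrom, pos, ref, tuple(pools)))
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: {exc}") from None
    return records


def write_sync(records: Sequence[SyncRecord], path: str | PathLike) -> None:
    """Write sync records; round-trips byte-stably through :func:`read_sync`."""
    pool_counts = {len(r.pools) for r in records}
    if len(pool_counts) > 1:
        raise ValueError(
            f"records have heterogeneous pool counts: {sorted(pool_counts)}"
        )
    with open(path, "w") as fh:
        for r in records:
            cols = "\t".join(":".join(str(c) for c in p) for p in r.pools)
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{cols}\n")


def apply_position_blacklist(
    records: Iterable[SyncRecord],
    blacklist: set[tuple[str, int]],
) -> list[SyncRecord]:
    """Drop records at blacklisted (chrom, pos) sites.

    Sync inputs are assumed to have indel-adjacent regions masked
    upstream; this optional filter lets callers apply such a mask here.
    """
    return [r for r in records if (r.chrom, r.pos) not in blacklist]


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, _, val = item.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_gene_intervals(
    path: str | PathLike, format: str = "bed"
) -> list[GeneInterval]:
    """Read gene intervals from BED or GFF3, normalized to 1-based inclusive.

    BED coordinates are 0-based half-open and take the gene identifier
    from column 4; GFF3 is 1-based inclusive and takes it from the
    ``ID`` attribute (``gene_id`` as fallback, ``Name`` as the optional
    symbol).  Non-gene GFF3 features are ignored.
    """
    fmt = format.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unsupported interval format: {format!r}")
    out: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if fmt == "bed" and line.startswith(("track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "bed":
                if len(fields) < 4:
                    raise ValueError(
                        f"line {lineno}: BED gene interval needs a name in "
                        "column 4"
                    )
                chrom, start_s, end_s, name = fields[:4]
                out.append(
                    GeneInterval(chrom, int(start_s) + 1, int(end_s), name)
                )
            else:
                if len(fields) < 9:
                    raise ValueError(
                        f"line {lineno}: GFF3 line has fewer than 9 columns"
                    )
                chrom, _, ftype, start_s, end_s = fields[:5]
                if ftype.lower() != "gene":
                    continue
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if not gene_id:
                    raise ValueError(
                        f"line {lineno}: GFF3 gene record lacks an ID or "
                        "gene_id attribute"
                    )
                out.append(
                    GeneInterval(
                        chrom,
                        int(start_s),
                        int(end_s),
                        gene_id,
                        symbol=attrs.get("Name"),
                    )
                )
    return out


_SNP_TABLE_HEADER = (
    "InGroup",
    "OutGroup",
    "Allele1",
    "Allele2",
    "Gene",
    "Position",
)


def write_snp_table(
    rows: Sequence[SnpTableRow],
    population_labels: Sequence[str],
    path: str | PathLike,
    haploid_sizes: Sequence[int] | None = None,
) -> None:
    """Write the SNP exchange table used for joint-SFS construction.

    Sites are written unpolarized: the ingroup context is ``-X-`` with X
    the first allele, and the outgroup context is ``---`` so downstream
    consumers are forced to fold the spectrum.  Per population, the two
    allele counts must sum to the haploid sample size (inferred from the
    first row when not given).
    """
    npop = len(population_labels)
    if rows and haploid_sizes is None:
        haploid_sizes = [
            a + b
            for a, b in zip(rows[0].allele1_counts, rows[0].allele2_counts)
        ]
    with open(path, "w") as fh:
        header = (
            ["InGroup", "OutGroup", "Allele1"]
            + list(population_labels)
            + ["Allele2"]
            + list(population_labels)
            + ["Gene", "Position"]
        )
        fh.write("\t".join(header) + "\n")
        for row in rows:
            if len(row.allele1_counts) != npop:
                raise ValueError(
                    f"{row.chrom}:{row.pos}: expected counts for {npop} "
                    f"populations, got {len(row.allele1_counts)}"
                )
            for p, (a, b) in enumerate(
                zip(row.allele1_counts, row.allele2_counts)
            ):
                if a + b != haploid_sizes[p]:
                    raise ValueError(
                        f"{row.chrom}:{row.pos}: population "
                        f"{population_labels[p]} counts {a}+{b} do not sum "
                        f"to the haploid sample size {haploid_sizes[p]}"
                    )
            cells = (
                [f"-{row.allele1}-", "---", row.allele1]
                + [str(c) for c in row.allele1_counts]
                + [row.allele2]
                + [str(c) for c in row.allele2_counts]
                + [row.chrom, str(row.pos)]
            )
            fh.write("\t".join(cells) + "\n")


def read_snp_table(
    path: str | PathLike,
) -> tuple[list[SnpTableRow], list[str]]:
    """Read a SNP exchange table back; returns rows and population labels."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 8 or header[2] != "Allele1":
            raise ValueError("not a recognizable SNP exchange table header")
        npop = (len(header) - 6) // 2
        labels = header[3 : 3 + npop]
        rows: list[SnpTableRow] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 6 + 2 * npop:
                raise ValueError(
                    f"line {lineno}: expected {6 + 2 * npop} columns, got "
                    f"{len(f)}"
                )
            a1 = f[2]
            c1 = tuple(int(x) for x in f[3 : 3 + npop])
            a2 = f[3 + npop]
            c2 = tuple(int(x) for x in f[4 + npop : 4 + 2 * npop])
            rows.append(
                SnpTableRow(f[-2], int(f[-1]), a1, a2, c1, c2)
            )
    return rows, labels


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_fst_table(sites, path: str | PathLike) -> None:
    """Per-SNP FST results as TSV (chrom, pos, major, minor, f1, f2, maf, fst)."""
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "major": [s.major for s in sites],
            "minor": [s.minor for s in sites],
            "f1": [s.freqs[0] for s in sites],
            "f2": [s.freqs[1] for s in sites],
            "maf": [s.maf for s in sites],
            "fst": [s.fst for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fst_table(path: str | PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "fst"}
    if not required.issubset(df.columns):
        raise ValueError(f"FST table must have columns {sorted(required)}")
    return df


def write_windows_table(windows, path: str | PathLike) -> None:
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start_pos for w in windows],
            "end": [w.end_pos for w in windows],
            "n_snps": [len(w.sites) for w in windows],
            "outlier_count": [w.outlier_count for w in windows],
            "p_value": [w.p_value for w in windows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_islands_bed(islands, path: str | PathLike) -> None:
    """Islands as BED: 1-based inclusive spans become 0-based half-open."""
    with open(path, "w") as fh:
        for idx, isl in enumerate(islands, start=1):
            fh.write(
                f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\tisland_{idx}\t"
                f"{isl.min_p:.3g}\n"
            )


def write_enrichment_table(results, path: str | PathLike) -> None:
    df = pd.DataFrame(
        {
            "term": [r.term for r in results],
            "term_size": [r.term_size for r in results],
            "candidate_size": [r.candidate_size for r in results],
            "overlap": [r.overlap for r in results],
            "p_value": [r.p_value for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
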