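"""Structured-coalescent simulation for two demes.

Implements a Monte-Carlo backward-in-time coalescent with piecewise
constant deme sizes and asymmetric migration.  It is used in two roles:

* as the engine behind the expected joint site frequency spectrum (SFS)
  of a two-population demographic model (branch-length estimator), which
  the demographic fitting machinery maximizes a composite likelihood
  over; and
* as the source of background allele-frequency pairs for synthetic
  pool-seq data.

Units follow the convention common to diffusion-based SFS tools: time in
units of ``2 * N_ref`` generations, deme sizes ``nu`` relative to
``N_ref`` (pairwise coalescence rate ``1/nu``), and per-lineage backward
migration rates ``m12``/``m21`` on the same time scale (a lineage
currently in deme 1 jumps to deme 2 at rate ``m12``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _engine

__all__ = [
    "Epoch",
    "DemographicModel",
    "Sfs2D",
    "fold_sfs",
    "simulate_genealogy",
    "Genealogy",
    "Branch",
    "expected_sfs",
    "sample_snp_frequencies",
    "single_population",
    "no_mig",
    "sym_mig",
    "asym_mig",
    "anc_sym_mig",
    "anc_asym_mig",
    "sec_contact_sym_mig",
    "sec_contact_asym_mig",
    "MODEL_FAMILIES",
    "build_model",
]


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant interval of a two-deme demography.

    Epochs are listed from the present backward; only the final
    (ancestral, single-population) epoch may have infinite duration.
    """

    duration: float
    nu1: float
    nu2: float = 1.0
    m12: float = 0.0
    m21: float = 0.0
    single_pop: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if self.nu1 <= 0 or self.nu2 <= 0:
            raise ValueError("deme sizes must be positive")
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be non-negative")


@dataclass(frozen=True)
class DemographicModel:
    """A named two-deme demography as an ordered list of epochs.

    ``k`` is the number of free parameters of the model family, used for
    AIC.  The final epoch must be the ancestral single-population phase
    (size ``nu_anc = 1`` by convention) with infinite duration.
    """

    name: str
    epochs: tuple[Epoch, ...]
    k: int = 0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("model needs at least one epoch")
        last = self.epochs[-1]
        if not (last.single_pop and math.isinf(last.duration)):
            raise ValueError(
                "the final epoch must be an unbounded ancestral single-"
                "population phase"
            )
        for ep in self.epochs[:-1]:
            if math.isinf(ep.duration):
                raise ValueError("only the ancestral epoch may be unbounded")

    def epoch_array(self) -> np.ndarray:
        out = np.empty((len(self.epochs), 6))
        for i, ep in enumerate(self.epochs):
            out[i] = (
                ep.duration,
                ep.nu1,
                ep.nu2,
                ep.m12,
                ep.m21,
                1.0 if ep.single_pop else 0.0,
            )
        return out


_ANC = Epoch(duration=math.inf, nu1=1.0, nu2=1.0, single_pop=True)


def single_population(nu: float = 1.0) -> DemographicModel:
    """A single panmictic deme of constant relative size ``nu``."""
    anc = Epoch(duration=math.inf, nu1=nu, nu2=nu, single_pop=True)
    return DemographicModel("single_population", (anc,), k=1)


def no_mig(nu1: float, nu2: float, T: float) -> DemographicModel:
    """Clean split ``T`` ago with complete isolation since."""
    return DemographicModel("no_mig", (Epoch(T, nu1, nu2), _ANC), k=3)


def sym_mig(nu1: float, nu2: float, m: float, T: float) -> DemographicModel:
    """Split with continuous symmetric migration."""
    return DemographicModel("sym_mig", (Epoch(T, nu1, nu2, m, m), _ANC), k=4)


def asym_mig(
    nu1: float, nu2: float, m12: float, m21: float, T: float
) -> DemographicModel:
    """Split with continuous asymmetric migration."""
    return DemographicModel(
        "asym_mig", (Epoch(T, nu1, nu2, m12, m21), _ANC), k=5
    )


def anc_sym_mig(
    nu1: float, nu2: float, m: float, T1: float, T2: float
) -> DemographicModel:
    """Ancient symmetric migration (duration T1) followed by isolation (T2)."""
    return DemographicModel(
        "anc_sym_mig",
        (Epoch(T2, nu1, nu2), Epoch(T1, nu1, nu2, m, m), _ANC),
        k=5,
    )


def anc_asym_mig(
    nu1: float, nu2: float, m12: float, m21: float, T1: float, T2: float
) -> DemographicModel:
    """Ancient asymmetric migration (T1) followed by isolation (T2)."""
    return DemographicModel(
        "anc_asym_mig",
        (Epoch(T2, nu1, nu2), Epoch(T1, nu1, nu2, m12, m21), _ANC),
        k=6,
    )


def sec_contact_sym_mig(
    nu1: float, nu2: float, m: float, T1: float, T2: float
) -> DemographicModel:
    """Isolation (duration T1) followed by symmetric secondary contact (T2)."""
    return DemographicModel(
        "sec_contact_sym_mig",
        (Epoch(T2, nu1, nu2, m, m), Epoch(T1, nu1, nu2), _ANC),
        k=5,
    )


def sec_contact_asym_mig(
    nu1: float, nu2: float, m12: float, m21: float, T1: float, T2: float
) -> DemographicModel:
    """Isolation (T1) followed by asymmetric secondary contact (T2)."""
    return DemographicModel(
        "sec_contact_asym_mig",
        (Epoch(T2, nu1, nu2, m12, m21), Epoch(T1, nu1, nu2), _ANC),
        k=6,
    )


#: the seven standard two-population divergence model families:
#: name -> (ordered parameter names, builder)
MODEL_FAMILIES: dict[str, tuple[tuple[str, ...], Callable[..., DemographicModel]]] = {
    "no_mig": (("nu1", "nu2", "T"), no_mig),
    "sym_mig": (("nu1", "nu2", "m", "T"), sym_mig),
    "asym_mig": (("nu1", "nu2", "m12", "m21", "T"), asym_mig),
    "anc_sym_mig": (("nu1", "nu2", "m", "T1", "T2"), anc_sym_mig),
    "anc_asym_mig": (("nu1", "nu2", "m12", "m21", "T1", "T2"), anc_asym_mig),
    "sec_contact_sym_mig": (("nu1", "nu2", "m", "T1", "T2"), sec_contact_sym_mig),
    "sec_contact_asym_mig": (
        ("nu1", "nu2", "m12", "m21", "T1", "T2"),
        sec_contact_asym_mig,
    ),
}


def build_model(family: str, params: Sequence[float]) -> DemographicModel:
    """Instantiate a model family from an ordered parameter vector."""
    try:
        names, builder = MODEL_FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown model family: {family!r}") from None
    if len(params) != len(names):
        raise ValueError(
            f"{family} expects {len(names)} parameters {names}, "
            f"got {len(params)}"
        )
    return builder(*params)


# ---------------------------------------------------------------------------
# joint site frequency spectra
# ---------------------------------------------------------------------------


class Sfs2D:
    """Joint (two-population) site frequency spectrum.

    ``data[i, j]`` carries the mass of sites with ``i`` copies of the
    derived (unfolded) or minor (folded) allele among the ``n1`` deme-1
    samples and ``j`` copies among the ``n2`` deme-2 samples.  The two
    invariant corners are always masked; folding additionally masks the
    conjugate-duplicate half of the matrix.
    """

    def __init__(
        self,
        data: np.ndarray,
        folded: bool = False,
        mask: np.ndarray | None = None,
    ) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("an Sfs2D is a 2-D matrix")
        self.data = data
        self.folded = folded
        if mask is None:
            mask = self.default_mask(data.shape, folded)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != data.shape:
            raise ValueError("mask shape does not match data shape")

    @staticmethod
    def default_mask(shape: tuple[int, int], folded: bool) -> np.ndarray:
        n1, n2 = shape[0] - 1, shape[1] - 1
        mask = np.zeros(shape, dtype=bool)
        mask[0, 0] = True
        mask[n1, n2] = True
        if folded:
            i, j = np.meshgrid(
                np.arange(n1 + 1), np.arange(n2 + 1), indexing="ij"
            )
            mask |= (i + j) > (n1 + n2) / 2
        return mask

    @property
    def n1(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.data.shape[1] - 1

    def total(self) -> float:
        """Total mass over unmasked cells."""
        return float(self.data[~self.mask].sum())

    def normalized(self) -> "Sfs2D":
        """Return a copy scaled to unit mass over unmasked cells."""
        tot = self.total()
        if tot <= 0:
            raise ValueError("cannot normalize a spectrum with no mass")
        out = np.where(self.mask, 0.0, self.data / tot)
        return Sfs2D(out, folded=self.folded, mask=self.mask.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "folded" if self.folded else "unfolded"
        return f"<Sfs2D {self.n1}x{self.n2} {kind} mass={self.total():.4g}>"


def fold_sfs(sfs: Sfs2D) -> Sfs2D:
    """Fold an unfolded joint spectrum onto minor-allele counts.

    A cell (i, j) with total allele count ``i + j`` above half the total
    sample size folds onto its conjugate (n1 - i, n2 - j); cells exactly
    at half split the conjugate pair's mass evenly (a self-conjugate cell
    keeps its own mass once).  Total unmasked mass is conserved for any
    spectrum whose invariant corners are empty.
    """
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    d = sfs.data
    n1, n2 = sfs.n1, sfs.n2
    rev = d[::-1, ::-1]
    i, j = np.meshgrid(np.arange(n1 + 1), np.arange(n2 + 1), indexing="ij")
    tot = i + j
    half = (n1 + n2) / 2
    folded = np.where(tot <= half, d + rev, 0.0)
    folded[tot == half] *= 0.5
    return Sfs2D(folded, folded=True)


# ---------------------------------------------------------------------------
# simulation entry points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Branch:
    """A genealogy branch: subtended sample counts per deme and length."""

    n_deme1: int
    n_deme2: int
    length: float


@dataclass
class Genealogy:
    """Coalescence times and branch composition of one simulated tree."""

    coalescence_times: list[float] = field(default_factory=list)
    branches: list[Branch] = field(default_factory=list)

    @property
    def tmrca(self) -> float:
        return self.coalescence_times[-1]


def simulate_genealogy(
    model: DemographicModel, n1: int, n2: int, seed: int | np.random.Generator
) -> Genealogy:
    """Simulate one genealogy under the structured coalescent.

    This is a direct, readable implementation of the same dynamics the
    vectorized kernels use; it returns the full branch decomposition and
    is the reference the fast path is checked against.
    """
    if n1 + n2 < 2:
        raise ValueError("need at least 2 sampled lineages")
    if n1 < 0 or n2 < 0:
        raise ValueError("sample sizes must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ep = model.epoch_array()
    deme = [0] * n1 + [1] * n2
    comp = [(1, 0)] * n1 + [(0, 1)] * n2
    birth = [0.0] * (n1 + n2)
    if ep[0, _engine.SINGLE] > 0.5:
        deme = [0] * len(deme)
    t = 0.0
    e = 0
    epoch_end = ep[0, _engine.DUR]
    out = Genealogy()
    while len(deme) > 1:
        _, nu1, nu2, m12, m21, _ = ep[e]
        k0 = deme.count(0)
        k1 = len(deme) - k0
        rates = [
            k0 * (k0 - 1) / 2.0 / nu1,
            k1 * (k1 - 1) / 2.0 / nu2,
            k0 * m12,
            k1 * m21,
        ]
        total = sum(rates)
        boundary = total <= 0.0
        if not boundary:
            t_next = t + rng.exponential(1.0 / total)
            boundary = t_next >= epoch_end
        if boundary:
            if not np.isfinite(epoch_end):
                raise RuntimeError(
                    "structured coalescent stalled: model lacks an "
                    "ancestral merge"
                )
            t = epoch_end
            e += 1
            epoch_end += ep[e, _engine.DUR]
            if ep[e, _engine.SINGLE] > 0.5:
                deme = [0] * len(deme)
            continue
        t = t_next
        which = rng.choice(4, p=np.asarray(rates) / total)
        if which in (0, 1):
            d = int(which)
            members = [i for i, dm in enumerate(deme) if dm == d]
            a, b = rng.choice(len(members), size=2, replace=False)
            a, b = members[a], members[b]
            for lin in (a, b):
                out.branches.append(Branch(*comp[lin], t - birth[lin]))
            out.coalescence_times.append(t)
            comp[a] = (comp[a][0] + comp[b][0], comp[a][1] + comp[b][1])
            birth[a] = t
            del deme[b], comp[b], birth[b]
        else:
            src = int(which) - 2
            members = [i for i, dm in enumerate(deme) if dm == src]
            lin = members[int(rng.integers(len(members)))]
            deme[lin] = 1 - src
    return out


def _check_sample_sizes(n1: int, n2: int) -> None:
    if n1 < 0 or n2 < 0:
        raise ValueError("sample sizes must be non-negative")
    if n1 + n2 < 2:
        raise ValueError("need at least 2 sampled lineages")


def _as_seed(seed: int) -> int:
    seed = int(seed)
    if not 0 <= seed < 2**32:
        raise ValueError("seed must fit in an unsigned 32-bit integer")
    return seed


def expected_sfs(
    model: DemographicModel,
    n1: int,
    n2: int,
    num_genealogies: int,
    seed: int,
) -> Sfs2D:
    """Monte-Carlo expected (unfolded, unnormalized) joint SFS.

    Cell (i, j) accumulates, over ``num_genealogies`` independent
    genealogies, the total branch length subtending exactly i deme-1 and
    j deme-2 samples; under the infinite-sites model the expectation of
    the cell is proportional to the probability that a SNP has derived
    allele counts (i, j).
    """
    _check_sample_sizes(n1, n2)
    if num_genealogies < 1:
        raise ValueError("num_genealogies must be >= 1")
    S = _engine.sfs_kernel(
        model.epoch_array(), n1, n2, int(num_genealogies), _as_seed(seed)
    )
    return Sfs2D(S, folded=False)


def mean_tmrca(
    model: DemographicModel,
    n1: int,
    n2: int,
    num_genealogies: int,
    seed: int,
) -> tuple[float, float]:
    """Mean TMRCA and its Monte-Carlo standard error."""
    _check_sample_sizes(n1, n2)
    times = _engine.tmrca_kernel(
        model.epoch_array(), n1, n2, int(num_genealogies), _as_seed(seed)
    )
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(len(times)))


def sample_snp_frequencies(
    model: DemographicModel,
    n1: int,
    n2: int,
    num_snps: int,
    seed: int,
) -> np.ndarray:
    """Sample per-deme allele frequencies of unlinked segregating SNPs.

    Each SNP comes from its own genealogy with exactly one mutation
    placed uniformly by branch length (infinite sites), so every SNP
    segregates in the combined sample.  Returns an array of shape
    ``(num_snps, 2)`` of sample frequencies ``(i/n1, j/n2)``.
    """
    _check_sample_sizes(n1, n2)
    if num_snps < 1:
        raise ValueError("num_snps must be >= 1")
    if n1 == 0 or n2 == 0:
        raise ValueError("both demes need at least one sample")
    counts = _engine.snp_pairs_kernel(
        model.epoch_array(), n1, n2, int(num_snps), _as_seed(seed)
    )
    return np.column_stack((counts[:, 0] / n1, counts[:, 1] / n2))
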