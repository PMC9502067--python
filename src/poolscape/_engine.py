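"""Event-loop kernels for the two-deme structured coalescent.

The kernels operate on a compact epoch table (one row per epoch, most
recent first) and simulate genealogies backward in time with exponential
competing risks.  Waiting times that cross an epoch boundary are clipped
to the boundary and redrawn under the new rates, which is exact for
piecewise-constant rates.

Epoch row layout (float64): duration, nu1, nu2, m12, m21, single_pop.
Time is measured in units of 2*N_ref generations; within a deme of
relative size nu the pairwise coalescence rate is 1/nu, and a lineage in
deme 1 migrates (backward in time) to deme 2 at rate m12.

Branch lengths are accrued per lineage between coalescence events, so
migration events cost O(1): a migration changes only the deme label of a
lineage, never the set of samples it subtends.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: column indices of the epoch table
DUR, NU1, NU2, M12, M21, SINGLE = 0, 1, 2, 3, 4, 5


@njit(cache=True)
def _simulate_one(ep, n1, n2, deme, c1, c2, birth, S):  # pragma: no cover - jit
    """Simulate one genealogy; accrue subtended branch lengths into S.

    Returns the TMRCA.  S[i, j] accumulates the total length of branches
    subtending exactly i of the n1 deme-1 samples and j of the n2 deme-2
    samples.  The root branch is never accrued (it would land in the
    (n1, n2) corner, which carries no polymorphism).
    """
    n = n1 + n2
    for i in range(n1):
        deme[i] = 0
        c1[i] = 1
        c2[i] = 0
        birth[i] = 0.0
    for i in range(n1, n):
        deme[i] = 1
        c1[i] = 0
        c2[i] = 1
        birth[i] = 0.0
    nact = n
    t = 0.0
    e = 0
    epoch_end = ep[0, DUR]
    k0 = n1  # running count of deme-0 lineages
    if ep[0, SINGLE] > 0.5:
        for i in range(nact):
            deme[i] = 0
        k0 = nact
    while nact > 1:
        nu1 = ep[e, NU1]
        nu2 = ep[e, NU2]
        m12 = ep[e, M12]
        m21 = ep[e, M21]
        k1 = nact - k0
        rc0 = k0 * (k0 - 1) * 0.5 / nu1
        rc1 = k1 * (k1 - 1) * 0.5 / nu2
        rm01 = k0 * m12
        rm10 = k1 * m21
        total = rc0 + rc1 + rm01 + rm10
        hit_boundary = False
        if total <= 0.0:
            if not np.isfinite(epoch_end):
                raise RuntimeError(
                    "structured coalescent stalled: no feasible events in an "
                    "unbounded epoch (model lacks an ancestral merge)"
                )
            t = epoch_end
            hit_boundary = True
        else:
            u = np.random.random()
            dt = -np.log(u) / total
            if t + dt >= epoch_end:
                t = epoch_end
                hit_boundary = True
            else:
                t = t + dt
                v = np.random.random() * total
                if v < rc0 + rc1:
                    d = 0
                    kd = k0
                    if v >= rc0:
                        d = 1
                        kd = k1
                    ai = int(np.random.random() * kd)
                    if ai == kd:
                        ai = kd - 1
                    bi = int(np.random.random() * (kd - 1))
                    if bi == kd - 1:
                        bi = kd - 2
                    if bi >= ai:
                        bi += 1
                    a = -1
                    b = -1
                    seen = 0
                    for i in range(nact):
                        if deme[i] == d:
                            if seen == ai:
                                a = i
                            if seen == bi:
                                b = i
                            seen += 1
                    S[c1[a], c2[a]] += t - birth[a]
                    S[c1[b], c2[b]] += t - birth[b]
                    c1[a] += c1[b]
                    c2[a] += c2[b]
                    birth[a] = t
                    nact -= 1
                    if d == 0:
                        k0 -= 1
                    deme[b] = deme[nact]
                    c1[b] = c1[nact]
                    c2[b] = c2[nact]
                    birth[b] = birth[nact]
                else:
                    v -= rc0 + rc1
                    src = 0
                    kd = k0
                    if v >= rm01:
                        src = 1
                        kd = k1
                    ai = int(np.random.random() * kd)
                    if ai == kd:
                        ai = kd - 1
                    seen = 0
                    for i in range(nact):
                        if deme[i] == src:
                            if seen == ai:
                                deme[i] = 1 - src
                                break
                            seen += 1
                    if src == 0:
                        k0 -= 1
                    else:
                        k0 += 1
        if hit_boundary:
            e += 1
            epoch_end += ep[e, DUR]
            if ep[e, SINGLE] > 0.5:
                for i in range(nact):
                    deme[i] = 0
                k0 = nact
    return t


@njit(cache=True)
def sfs_kernel(ep, n1, n2, num_genealogies, seed):  # pragma: no cover - jit
    """Accumulate subtended branch lengths over many genealogies."""
    np.random.seed(seed)
    S = np.zeros((n1 + 1, n2 + 1))
    n = n1 + n2
    deme = np.empty(n, np.int8)
    c1 = np.empty(n, np.int64)
    c2 = np.empty(n, np.int64)
    birth = np.empty(n, np.float64)
    for _ in range(num_genealogies):
        _simulate_one(ep, n1, n2, deme, c1, c2, birth, S)
    return S


@njit(cache=True)
def tmrca_kernel(ep, n1, n2, num_genealogies, seed):  # pragma: no cover - jit
    """Return the TMRCA of each simulated genealogy."""
    np.random.seed(seed)
    out = np.empty(num_genealogies)
    n = n1 + n2
    S = np.zeros((n1 + 1, n2 + 1))
    deme = np.empty(n, np.int8)
    c1 = np.empty(n, np.int64)
    c2 = np.empty(n, np.int64)
    birth = np.empty(n, np.float64)
    for g in range(num_genealogies):
        out[g] = _simulate_one(ep, n1, n2, deme, c1, c2, birth, S)
    return out


@njit(cache=True)
def snp_pairs_kernel(ep, n1, n2, num_snps, seed):  # pragma: no cover - jit
    """Draw one segregating mutation per genealogy.

    Each SNP comes from an independent genealogy: a single mutation is
    placed uniformly by branch length, and the subtended sample counts
    (i, j) become the SNP's allele counts in the two demes.  Every SNP
    segregates in the combined sample because the root branch (the only
    branch subtending all samples) is never accrued.
    """
    np.random.seed(seed)
    out = np.empty((num_snps, 2), np.int64)
    n = n1 + n2
    deme = np.empty(n, np.int8)
    c1 = np.empty(n, np.int64)
    c2 = np.empty(n, np.int64)
    birth = np.empty(n, np.float64)
    S = np.zeros((n1 + 1, n2 + 1))
    for s in range(num_snps):
        S[:, :] = 0.0
        _simulate_one(ep, n1, n2, deme, c1, c2, birth, S)
        tot = 0.0
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                tot += S[i, j]
        u = np.random.random() * tot
        acc = 0.0
        ii = 0
        jj = 0
        done = False
        for i in range(n1 + 1):
            if done:
                break
            for j in range(n2 + 1):
                acc += S[i, j]
                if acc >= u:
                    ii = i
                    jj = j
                    done = True
                    break
        out[s, 0] = ii
        out[s, 1] = jj
    return out
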