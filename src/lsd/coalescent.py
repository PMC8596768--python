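"""Structured-coalescent simulation of single non-recombining loci.

Implements the continuous-time exponential-race (Hudson) algorithm under an
arbitrary :class:`~lsd.demography.DemographicModel`: within deme ``i`` at time
``t`` each pair of lineages coalesces at rate ``1 / (2 N_i(t))`` per
generation, and each lineage migrates ``i -> j`` at the backward rate
``m_ij(t) = M_ij / N_i(t)``. Exponential growth within an epoch is handled by
analytic integration of the cumulative hazard. Infinite-sites mutations are
then dropped on the genealogy at ``mu`` per bp per generation.

This engine generates both the ABC reference table and the neutral loci of
validation pseudogenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, expm1, log
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .demography import DemographicModel, ResolvedDemography

DEFAULT_TIME_CEILING = 1e9


class NonCoalescingError(RuntimeError):
    """Raised when the genealogy fails to find a common ancestor in time."""


@dataclass
class Genealogy:
    """A rooted tree (or, internally, forest segment) over sampled lineages.

    Leaves are nodes ``0 .. n_leaves-1``; ``parent[root] == -1``. ``time`` is
    in generations before present; parents are strictly older than children
    except for zero-length degenerate branches. ``leaf_demes[k]`` is the deme
    of leaf ``k`` at sampling time.
    """

    parent: np.ndarray
    time: np.ndarray
    leaf_demes: list
    n_leaves: int

    def total_branch_length(self) -> float:
        par = self.parent
        has_parent = par >= 0
        return float(np.sum(self.time[par[has_parent]] - self.time[has_parent]))

    def leaf_masks(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves) matrix: leaves below each node."""
        n_nodes = len(self.parent)
        masks = np.zeros((n_nodes, self.n_leaves), dtype=bool)
        masks[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        order = np.argsort(self.time, kind="stable")  # children before parents
        for node in order:
            p = self.parent[node]
            if p >= 0:
                masks[p] |= masks[node]
        return masks


@dataclass
class LocusData:
    """Binary haplotype matrix for one locus (0 = ancestral, 1 = derived)."""

    haplotypes: np.ndarray  #: (n_samples, S) uint8
    positions: np.ndarray  #: S relative positions in [0, 1), strictly increasing
    locus_length: int  #: bp
    pop_labels: list  #: per-sample deme id

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def rows(self, pop) -> np.ndarray:
        """Row indices belonging to deme ``pop``."""
        return np.flatnonzero(np.asarray([p == pop for p in self.pop_labels]))


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def simulate_genealogy(
    model: DemographicModel | ResolvedDemography,
    params: Mapping[str, float] | None,
    sample_config: Mapping[str, int],
    rng,
    *,
    start_time: float = 0.0,
    time_ceiling: float = DEFAULT_TIME_CEILING,
) -> Genealogy:
    """Simulate the genealogy of ``sample_config`` (deme -> haploid count).

    All samples are contemporaneous at ``start_time`` (0 = the present; a
    positive value is used internally to close forward simulations at the
    selection onset). Raises :class:`NonCoalescingError` if no common
    ancestor is reached before ``time_ceiling``.
    """
    rng = _as_rng(rng)
    resolved = model if isinstance(model, ResolvedDemography) else ResolvedDemography(model, params)

    n = int(sum(sample_config.values()))
    if n < 1:
        raise ValueError("need at least one sampled lineage")

    parent = [-1] * n
    time = [float(start_time)] * n
    leaf_demes: list = []
    lineages: dict = {}  # active deme -> list of node ids
    for deme, count in sample_config.items():
        for _ in range(int(count)):
            leaf_demes.append(deme)
    # place leaves, honouring joins already past start_time
    ep0 = resolved.epoch_at(start_time)
    node = 0
    for deme, count in sample_config.items():
        target = ep0.alias[deme]
        lineages.setdefault(target, [])
        for _ in range(int(count)):
            lineages[target].append(node)
            node += 1
    lineages = {d: v for d, v in lineages.items() if v}

    t = float(start_time)
    epochs = resolved.epochs
    ep_idx = next(i for i in reversed(range(len(epochs))) if epochs[i].start <= t)
    n_active = n

    rand = rng.random  # scalar draws are the hot path
    while n_active > 1:
        ep = epochs[ep_idx]
        # epoch-entry bookkeeping: joined demes hand their lineages over
        for deme in list(lineages):
            tgt = ep.alias.get(deme, deme)
            if tgt != deme:
                lineages.setdefault(tgt, []).extend(lineages.pop(deme))
        lineages = {d: v for d, v in lineages.items() if v}

        # per-deme base rates at current time t: everything in deme d scales
        # as 1/N_d(t), so the instantaneous rate is B_d * exp(g_d * u)
        base = []  # (deme, coal_rate, [(dest, mig_rate)], growth)
        total0 = 0.0
        mig_by_source: dict = {}
        for (i, j), m in ep.migration.items():
            if m > 0.0 and j in ep.active:
                mig_by_source.setdefault(i, []).append((j, m))
        for d, pool in lineages.items():
            k = len(pool)
            n_t = ep.size_at(d, t)
            coal = k * (k - 1) / 2.0 / (2.0 * n_t)
            migs = [(j, k * m / n_t) for j, m in mig_by_source.get(d, ())]
            base.append((d, coal, migs, ep.growth[d]))
            total0 += coal + sum(r for _, r in migs)

        horizon = min(ep.end, time_ceiling)
        growth_free = all(g == 0.0 for *_, g in base)
        if total0 <= 0.0:
            if horizon >= time_ceiling:
                raise NonCoalescingError(
                    f"no coalescence possible and time ceiling {time_ceiling:g} reached "
                    f"({n_active} lineages left)"
                )
            t = horizon
            ep_idx += 1
            continue

        target = -log(1.0 - rand())
        if growth_free:
            dt = target / total0
        else:
            # cumulative hazard H(u) = sum_d B_d * (exp(g_d u) - 1) / g_d
            def hazard(u: float) -> float:
                h = 0.0
                for _, coal, migs, g in base:
                    b = coal + sum(r for _, r in migs)
                    h += b * u if g == 0.0 else b * expm1(g * u) / g
                return h

            span = horizon - t
            if span > 0 and hazard(span) < target:
                dt = span + 1.0  # defer to next epoch
            else:
                dt = brentq(lambda u: hazard(u) - target, 0.0, max(span, 1e-12))

        if t + dt >= horizon:
            if horizon >= time_ceiling:
                raise NonCoalescingError(
                    f"time ceiling {time_ceiling:g} reached with {n_active} lineages"
                )
            t = horizon
            ep_idx += 1
            continue

        t += dt
        # choose the event proportional to instantaneous rates at time t
        if growth_free:
            u = rand() * total0
            scales = None
        else:
            scales = {d: exp(g * dt) for d, _, _, g in base}
            u = rand() * sum(
                (coal + sum(r for _, r in migs)) * scales[d] for d, coal, migs, _ in base
            )
        chosen = None
        for d, coal, migs, _ in base:
            s = 1.0 if scales is None else scales[d]
            u -= coal * s
            if u < 0.0:
                chosen = ("coal", d, None)
                break
            for dest, r in migs:
                u -= r * s
                if u < 0.0:
                    chosen = ("mig", d, dest)
                    break
            if chosen:
                break
        if chosen is None:  # numerical edge: fall back to the last event
            d, coal, migs, _ = base[-1]
            chosen = ("coal", d, None) if coal > 0 else ("mig", d, migs[-1][0])
        kind, d, dest = chosen
        pool = lineages[d]
        k = len(pool)
        if kind == "mig":
            i = int(rand() * k)
            pool[i], pool[-1] = pool[-1], pool[i]
            lineages.setdefault(dest, []).append(pool.pop())
        else:
            i = int(rand() * k)
            j = int(rand() * (k - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            new = len(parent)
            parent.append(-1)
            time.append(t)
            parent[a] = parent[b] = new
            for idx in sorted((i, j), reverse=True):
                pool[idx], pool[-1] = pool[-1], pool[idx]
                pool.pop()
            pool.append(new)
            n_active -= 1

    return Genealogy(
        parent=np.asarray(parent, dtype=np.int64),
        time=np.asarray(time, dtype=float),
        leaf_demes=leaf_demes,
        n_leaves=n,
    )


def _unique_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct uniform positions in [0, 1); collisions re-drawn."""
    pos = rng.random(n)
    while len(np.unique(pos)) < n:
        _, first = np.unique(pos, return_index=True)
        dup = np.ones(n, dtype=bool)
        dup[first] = False
        pos[dup] = rng.random(int(dup.sum()))
    return pos


def drop_mutations(
    genealogy: Genealogy, mu: float, locus_length: int, rng
) -> LocusData:
    """Drop infinite-sites mutations on a genealogy.

    The number of mutations is Poisson(``mu * L * total branch length``); each
    falls uniformly on branches and flips all leaves below its branch to the
    derived state 1.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if locus_length <= 0:
        raise ValueError("locus_length must be > 0")
    rng = _as_rng(rng)
    par = genealogy.parent
    has_parent = par >= 0
    blens = np.where(has_parent, genealogy.time[np.where(has_parent, par, 0)] - genealogy.time,
                     0.0)
    total = float(blens.sum())
    n_mut = int(rng.poisson(mu * locus_length * total)) if total > 0 else 0
    if n_mut == 0:
        return LocusData(
            np.zeros((genealogy.n_leaves, 0), dtype=np.uint8),
            np.empty(0),
            locus_length,
            list(genealogy.leaf_demes),
        )
    cum = np.cumsum(blens)
    branch = np.searchsorted(cum, rng.random(n_mut) * total, side="right")
    branch = np.minimum(branch, len(blens) - 1)
    positions = _unique_positions(n_mut, rng)
    order = np.argsort(positions)
    masks = genealogy.leaf_masks()
    haps = masks[branch[order]].T.astype(np.uint8)
    return LocusData(haps, positions[order], locus_length, list(genealogy.leaf_demes))


def simulate_locus(
    model: DemographicModel | ResolvedDemography,
    params: Mapping[str, float] | None,
    sample_config: Mapping[str, int],
    locus_length: int,
    rng,
    *,
    time_ceiling: float = DEFAULT_TIME_CEILING,
) -> LocusData:
    """One neutral locus: genealogy plus infinite-sites mutations."""
    rng = _as_rng(rng)
    resolved = model if isinstance(model, ResolvedDemography) else ResolvedDemography(model, params)
    tree = simulate_genealogy(
        resolved, None, sample_config, rng, time_ceiling=time_ceiling
    )
    return drop_mutations(tree, resolved.mutation_rate, locus_length, rng)
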