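"""Forward Wright-Fisher simulation of selected loci and validation pseudogenomes.

Selected loci carry a single biallelic site (ancestral ``a``, derived ``A``)
under genotype-table selection in two contrasting environments, fully linked
to the surrounding neutral window (no within-locus recombination). The
generator produces pseudo-observed pseudogenomes of neutral plus selected
loci used to evaluate the scan's power.

Simulation scheme
-----------------
The selection phase (from the onset ``T_S`` to the present) is simulated
forward in time as an individual-based Wright-Fisher pedigree of the ``2 N_i``
haploid genomes per deme: each offspring picks a source deme (forward
migration fraction ``m~_ij = M_ij / N_i``), then a parent within the source
deme with probability proportional to the parent allele's marginal fitness,
and inherits the selected-site allele exactly. The genealogy of the sampled
haplotypes is extracted from the pedigree; lineages that have not coalesced
by ``T_S`` are closed with the neutral structured coalescent under the same
model (the locus is neutral before the onset, so this is the exact
stationary-state replacement for a long neutral burn-in). Neutral
infinite-sites mutations are then dropped on the composite genealogy.

Forward simulation at the published population sizes is impractical, so
models are rescaled by a factor ``lambda``: ``N -> N/lambda``,
``t -> t/lambda``, ``s -> s*lambda``, ``mu -> mu*lambda``, leaving the
compound parameters ``4*N*mu``, ``M = N*m``, ``N*s`` and ``t/N`` invariant
(standard diffusion-regime rescaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .coalescent import Genealogy, LocusData, _as_rng, drop_mutations, simulate_genealogy, simulate_locus
from .demography import (
    Deme,
    DemographicEvent,
    DemographicModel,
    MigrationSpec,
    ResolvedDemography,
    _resolve,
)


class LossRegimeError(RuntimeError):
    """The derived allele was lost in every attempt: a loss regime."""


@dataclass(frozen=True)
class SelectionRegime:
    """Divergent selection on alternate alleles in two environments.

    ``s1``/``s2`` are the selection coefficients favouring the derived allele
    in environment 1 and the ancestral allele in environment 2. ``t_onset``
    is the onset of selection in generations before present; ``f1``/``f2``
    the initial derived-allele frequencies at the onset. ``origin`` is
    ``"standing"`` (f1 = f2 = 0.1 in the validation design) or ``"de_novo"``
    (one copy in deme 1, none in deme 2; ``f1``/``f2`` are then ignored and
    resolved against the deme sizes at simulation time).
    """

    s1: float
    s2: float
    t_onset: float
    f1: float = 0.1
    f2: float = 0.1
    origin: str = "standing"
    env_demes: tuple = ()  #: (env1 deme id, env2 deme id); default: model's first two

    def __post_init__(self) -> None:
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("selection coefficients must be >= 0")
        if not (0 <= self.f1 <= 1 and 0 <= self.f2 <= 1):
            raise ValueError("initial frequencies must lie in [0, 1]")
        if self.t_onset <= 0:
            raise ValueError("t_onset must be > 0")
        if self.origin not in ("standing", "de_novo"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass(frozen=True)
class FitnessTable:
    """Genotype fitnesses (w_AA, w_Aa, w_aa) in one environment."""

    w_AA: float
    w_Aa: float
    w_aa: float

    def __post_init__(self) -> None:
        if min(self.w_AA, self.w_Aa, self.w_aa) <= 0:
            raise ValueError("fitnesses must be > 0")

    def marginal(self, p: float) -> tuple[float, float]:
        """Marginal fitnesses (w_A, w_a) of the two alleles at frequency p."""
        return (p * self.w_AA + (1 - p) * self.w_Aa, p * self.w_Aa + (1 - p) * self.w_aa)


def fitness_tables(regime: SelectionRegime, dominance: str = "as_printed") -> tuple[FitnessTable, FitnessTable]:
    """Per-environment fitness tables for (env1, env2).

    ``"as_printed"`` uses (1+s1, 1, 1) and (1, 1, 1+s2) for (AA, Aa, aa) —
    the beneficial allele advantageous only when homozygous.
    ``"dominant"`` makes the locally beneficial allele dominant:
    (1+s1, 1+s1, 1) and (1, 1+s2, 1+s2).
    """
    if dominance == "as_printed":
        return (FitnessTable(1 + regime.s1, 1, 1), FitnessTable(1, 1, 1 + regime.s2))
    if dominance == "dominant":
        return (
            FitnessTable(1 + regime.s1, 1 + regime.s1, 1),
            FitnessTable(1, 1 + regime.s2, 1 + regime.s2),
        )
    raise ValueError(f"unknown dominance mode {dominance!r}")


@dataclass
class Trajectory:
    """Per-deme derived-allele frequency path from the onset to the present.

    ``freqs[t, i]`` is the frequency in deme ``i`` at ``t`` generations after
    the onset (row 0 = initial state, last row = present).
    """

    freqs: np.ndarray
    demes: list
    survived: bool


@dataclass
class Pseudogenome:
    """A simulated collection of independent loci with truth labels."""

    loci: list  #: list of (LocusData, label in {"neutral", "selected"}, regime | None)
    locus_length: int

    @property
    def n_neutral(self) -> int:
        return sum(1 for _, lab, _ in self.loci if lab == "neutral")

    @property
    def n_selected(self) -> int:
        return sum(1 for _, lab, _ in self.loci if lab == "selected")

    @property
    def total_length(self) -> int:
        return len(self.loci) * self.locus_length

    @property
    def labels(self) -> list:
        return [lab for _, lab, _ in self.loci]


# ---------------------------------------------------------------------------
# rescaling


def rescale(
    model: DemographicModel, regime: SelectionRegime | None, lam: float
) -> tuple[DemographicModel, SelectionRegime | None]:
    """Diffusion rescaling by ``lam >= 1``: N/lam, t/lam, s*lam, mu*lam.

    Scaled migration rates ``M = N*m`` are invariant. Raises if the rescaled
    model leaves the diffusion regime (``s*lam > 1`` or a forward migration
    fraction ``M/N' > 1``).
    """
    if lam < 1:
        raise ValueError("rescaling factor must be >= 1")

    def num(v, what):
        if isinstance(v, str):
            raise ValueError(f"cannot rescale symbolic {what} {v!r}")
        return float(v)

    demes = [
        Deme(d.id, num(d.initial_size, "size") / lam, num(d.growth_rate, "growth") * lam)
        for d in model.demes
    ]
    sizes = {d.id: d.initial_size for d in demes}
    for (i, _), m in model.migration.entries.items():
        if not isinstance(m, str) and float(m) / sizes[i] > 1.0:
            raise ValueError(f"rescaled migration fraction M/N' = {float(m)/sizes[i]:.3g} > 1")
    events = []
    for e in model.events:
        payload = dict(e.payload)
        if e.kind == "size_change":
            payload["size"] = num(payload["size"], "size") / lam
            if "growth_rate" in payload:
                payload["growth_rate"] = num(payload["growth_rate"], "growth") * lam
        elif e.kind == "growth_change":
            payload["rate"] = num(payload["rate"], "growth") * lam
        events.append(DemographicEvent(num(e.time, "time") / lam, e.kind, payload))
    model2 = DemographicModel(
        demes=demes,
        migration=model.migration,
        events=tuple(events),
        mutation_rate=num(model.mutation_rate, "mutation rate") * lam,
        free_parameters=tuple(model.free_parameters),
    )
    regime2 = regime
    if regime is not None:
        s1, s2 = regime.s1 * lam, regime.s2 * lam
        if max(s1, s2) > 1.0:
            raise ValueError(f"rescaled selection coefficient {max(s1, s2):.3g} > 1")
        regime2 = replace(regime, s1=s1, s2=s2, t_onset=regime.t_onset / lam)
    return model2, regime2


def default_lambda(model: DemographicModel, params: Mapping | None = None, cap: float = 1000.0) -> float:
    """Smallest integer rescaling putting every deme size at or below ``cap``."""
    sizes = [_resolve(d.initial_size, params or {}) for d in model.demes]
    return float(max(1, int(np.ceil(max(sizes) / cap))))


# ---------------------------------------------------------------------------
# shared helpers


def _env_map(model: DemographicModel, regime: SelectionRegime) -> dict:
    """deme id -> environment index (1, 2) or 0 for neutral demes."""
    ids = model.deme_ids
    if regime.env_demes:
        e1, e2 = regime.env_demes
    else:
        if len(ids) < 2:
            raise ValueError("need two demes (or explicit env_demes) for divergent selection")
        e1, e2 = ids[0], ids[1]
    return {d: (1 if d == e1 else 2 if d == e2 else 0) for d in ids}


def _initial_frequencies(regime: SelectionRegime, env: dict, sizes: dict) -> dict:
    """Initial derived-allele frequency per deme at the onset."""
    if regime.origin == "de_novo":
        e1 = next(d for d, e in env.items() if e == 1)
        return {d: (1.0 / (2.0 * sizes[d]) if d == e1 else 0.0) for d in env}
    freq = {1: regime.f1, 2: regime.f2}
    return {d: freq.get(env[d], 0.0) for d in env}


def _forward_fractions(resolved: ResolvedDemography, t: float) -> dict:
    """deme -> list of (source deme, fraction m~_ij = M_ij / N_i)."""
    ep = resolved.epoch_at(t)
    out: dict = {d: [] for d in ep.active}
    for (i, j), m in ep.migration.items():
        if i in ep.active and j in ep.active and m > 0:
            out[i].append((j, m / ep.size_at(i, t)))
    return out


def _check_survival(freqs: np.ndarray, rule: str) -> bool:
    if rule == "none":
        return True
    lost = np.all(freqs == 0.0)
    if rule == "not_lost":
        return not lost
    if rule == "segregating":
        return (not lost) and not np.all(freqs == 1.0)
    raise ValueError(f"unknown retention rule {rule!r}")


# ---------------------------------------------------------------------------
# allele-frequency trajectory (diffusion-scale recursion)


def simulate_trajectory(
    model: DemographicModel,
    params: Mapping[str, float] | None,
    regime: SelectionRegime,
    rng,
    *,
    dominance: str = "as_printed",
    condition: bool = True,
    retention: str = "not_lost",
    resample_cap: int = 10_000,
) -> Trajectory:
    """Per-generation Wright-Fisher frequency recursion from the onset.

    Each generation applies (1) selection ``p* = p w_A / w_bar`` with the
    deme's fitness table, (2) migration
    ``p_i <- (1 - sum_j m~_ij) p_i* + sum_j m~_ij p_j*``, and (3) binomial
    drift ``p_i <- Binomial(2 N_i, p_i) / (2 N_i)``. With ``condition=True``
    the path is rejection-resampled until the retention rule holds at the
    present (the survival-conditioning analogue); exceeding ``resample_cap``
    raises :class:`LossRegimeError`.
    """
    rng = _as_rng(rng)
    resolved = ResolvedDemography(model, params)
    env = _env_map(model, regime)
    tables = fitness_tables(regime, dominance)
    demes = model.deme_ids
    t_gen = int(round(regime.t_onset))

    for _attempt in range(resample_cap if condition else 1):
        sizes0 = {d: resolved.epoch_at(regime.t_onset).size_at(d, regime.t_onset) for d in demes}
        p = np.array(
            [_initial_frequencies(regime, env, sizes0)[d] for d in demes], dtype=float
        )
        path = np.empty((t_gen + 1, len(demes)))
        path[0] = p
        for g in range(1, t_gen + 1):
            t = regime.t_onset - g  # generations before present
            ep = resolved.epoch_at(max(t, 0.0))
            n2 = np.array([2.0 * ep.size_at(d, max(t, 0.0)) for d in demes])
            # selection
            p_star = p.copy()
            for k, d in enumerate(demes):
                if env[d] in (1, 2):
                    w_a_, w_b_ = tables[env[d] - 1].marginal(p[k])
                    wbar = p[k] * w_a_ + (1 - p[k]) * w_b_
                    p_star[k] = p[k] * w_a_ / wbar
            # migration
            frac = _forward_fractions(resolved, max(t, 0.0))
            p_mig = p_star.copy()
            for k, d in enumerate(demes):
                inflow = frac.get(d, [])
                stay = 1.0 - sum(f for _, f in inflow)
                p_mig[k] = stay * p_star[k] + sum(
                    f * p_star[demes.index(src)] for src, f in inflow
                )
            # drift
            p = rng.binomial(np.round(n2).astype(np.int64), np.clip(p_mig, 0, 1)) / np.round(n2)
            path[g] = p
            if condition and np.all(p == 0.0):
                path[g:] = 0.0  # lost for good; zero-fill and restart
                break
        if not condition or _check_survival(path[-1], retention):
            return Trajectory(path, list(demes), survived=bool(_check_survival(path[-1], retention)))
    raise LossRegimeError(
        f"derived allele lost in all {resample_cap} attempts (s1={regime.s1}, s2={regime.s2})"
    )


# ---------------------------------------------------------------------------
# individual-based selected-locus simulation


def _pedigree_frame(resolved: ResolvedDemography, regime: SelectionRegime):
    """Static layout of the forward simulation (deme blocks of 2N haploids)."""
    demes = list(resolved.model.deme_ids)
    t_gen = int(round(regime.t_onset))
    ep0 = resolved.epoch_at(regime.t_onset)
    if any(ep0.alias[d] != d for d in demes):
        raise ValueError("join events inside the selection window are not supported")
    sizes = {d: int(round(ep0.size_at(d, regime.t_onset))) for d in demes}
    n_hap = {d: 2 * sizes[d] for d in demes}
    offsets = np.cumsum([0] + [n_hap[d] for d in demes])
    return demes, t_gen, sizes, n_hap, offsets


def _count_path(
    resolved: ResolvedDemography,
    regime: SelectionRegime,
    env: dict,
    tables: tuple[FitnessTable, FitnessTable],
    rng: np.random.Generator,
    abort_on_loss: bool = True,
):
    """Simulate the selected-site allele-count path (cheap stage).

    Each generation draws, per destination deme, the migrant group sizes
    (multinomial over source demes) and the derived count within each group
    (binomial at the source's post-selection frequency). Those draws fully
    determine the count dynamics; parent-index assignment is exchangeable
    given them and is filled in later by :func:`_fill_pedigree`.

    Returns (draws, counts0, traj) or None if the allele was lost mid-run.
    ``draws[g-1]`` is a list per deme of (source, group size, derived count).
    """
    demes, t_gen, sizes, n_hap, offsets = _pedigree_frame(resolved, regime)
    f0 = _initial_frequencies(regime, env, {d: float(sizes[d]) for d in demes})
    counts0 = {}
    for d in demes:
        n_derived = int(round(f0[d] * n_hap[d]))
        if regime.origin == "de_novo" and env[d] == 1:
            n_derived = 1
        counts0[d] = n_derived
    counts = dict(counts0)

    draws: list = []
    traj = np.empty((t_gen + 1, len(demes)))
    traj[0] = [counts[d] / n_hap[d] for d in demes]

    # migration fractions are epoch-constant; with a single growth-free epoch
    # covering the window the per-generation multinomials can be pre-drawn
    ep_start = resolved.epoch_at(0.0)
    ep_end = resolved.epoch_at(max(regime.t_onset - 1, 0.0))
    static = ep_start is ep_end and not any(ep_start.growth[d] for d in demes)
    frac_static = _forward_fractions(resolved, 0.0) if static else None
    pre_sizes = {}
    if static:
        for d in demes:
            inflow = frac_static.get(d, [])
            if inflow:
                probs = [f for _, f in inflow] + [max(1.0 - sum(f for _, f in inflow), 0.0)]
                pre_sizes[d] = rng.multinomial(n_hap[d], probs, size=t_gen)
            else:
                pre_sizes[d] = np.full((t_gen, 1), n_hap[d])

    frac_cache: tuple | None = None
    for g in range(1, t_gen + 1):
        t_before = max(regime.t_onset - g, 0.0)
        if static:
            frac = frac_static
        else:
            ep = resolved.epoch_at(t_before)
            if frac_cache is not None and frac_cache[0] is ep and not any(
                ep.growth[d] for d in demes
            ):
                frac = frac_cache[1]
            else:
                frac = _forward_fractions(resolved, t_before)
                frac_cache = (ep, frac)
        p_sel = {}
        for d in demes:
            p = counts[d] / n_hap[d]
            if env[d] in (1, 2) and 0.0 < p < 1.0:
                w_der, w_anc = tables[env[d] - 1].marginal(p)
                p = p * w_der / (p * w_der + (1 - p) * w_anc)
            p_sel[d] = p
        gen_draws = []
        new_counts = {}
        for d in demes:
            inflow = frac.get(d, [])
            if static:
                group_sizes = pre_sizes[d][g - 1]
            elif inflow:
                probs = [f for _, f in inflow]
                group_sizes = rng.multinomial(n_hap[d], probs + [max(1.0 - sum(probs), 0.0)])
            else:
                group_sizes = [n_hap[d]]
            sources = [src for src, _ in inflow] + [d]
            groups = []
            derived_total = 0
            for src, cnt in zip(sources, group_sizes):
                n_derived = int(rng.binomial(cnt, p_sel[src])) if cnt else 0
                groups.append((src, int(cnt), n_derived))
                derived_total += n_derived
            gen_draws.append(groups)
            new_counts[d] = derived_total
        counts = new_counts
        draws.append(gen_draws)
        traj[g] = [counts[d] / n_hap[d] for d in demes]
        if abort_on_loss and sum(counts.values()) == 0:
            return None  # lost; cannot recover without recurrent mutation
    return draws, counts0, traj


def _fill_pedigree(
    resolved: ResolvedDemography,
    regime: SelectionRegime,
    draws: list,
    counts0: dict,
    rng: np.random.Generator,
):
    """Replay a stored count path, assigning concrete parent indices.

    Returns (parents, sel_final, sel_initial, offsets).
    """
    demes, t_gen, _, n_hap, offsets = _pedigree_frame(resolved, regime)
    total = int(offsets[-1])
    sel = np.zeros(total, dtype=bool)
    for k, d in enumerate(demes):
        if counts0[d]:
            idx = rng.choice(n_hap[d], size=counts0[d], replace=False)
            sel[offsets[k] + idx] = True
    sel0 = sel.copy()

    parents = np.empty((t_gen, total), dtype=np.int32)
    for g in range(1, t_gen + 1):
        row = parents[g - 1]
        new_sel = np.empty(total, dtype=bool)
        u = rng.random(total)  # one batch of uniforms serves every group
        idx_a = {}
        idx_n = {}
        for k, d in enumerate(demes):
            block = sel[offsets[k] : offsets[k + 1]]
            idx_a[d] = np.flatnonzero(block) + offsets[k]
            idx_n[d] = np.flatnonzero(~block) + offsets[k]
        for k, d in enumerate(demes):
            pos = offsets[k]
            for src, cnt, n_derived in draws[g - 1][k]:
                if cnt == 0:
                    continue
                pool_a, pool_n = idx_a[src], idx_n[src]
                n_der = n_derived if len(pool_a) else 0
                if n_der:
                    pick = (u[pos : pos + n_der] * len(pool_a)).astype(np.int64)
                    row[pos : pos + n_der] = pool_a[pick]
                    new_sel[pos : pos + n_der] = True
                n_anc = cnt - n_der
                if n_anc:
                    pool = pool_n if len(pool_n) else pool_a
                    pick = (u[pos + n_der : pos + cnt] * len(pool)).astype(np.int64)
                    row[pos + n_der : pos + cnt] = pool[pick]
                    new_sel[pos + n_der : pos + cnt] = bool(len(pool_n) == 0)
                pos += cnt
        sel = new_sel
    return parents, sel, sel0, offsets


def simulate_selected_locus(
    model: DemographicModel,
    params: Mapping[str, float] | None,
    regime: SelectionRegime,
    locus_length: int,
    mu: float,
    sample_config: Mapping[str, int],
    rng,
    *,
    dominance: str = "as_printed",
    retention: str = "not_lost",
    resample_cap: int = 10_000,
    return_trajectory: bool = False,
):
    """Simulate one selected locus under the (already rescaled) model.

    The selected site is embedded in the locus and fully linked; survival
    conditioning rejection-resamples whole pedigrees until the retention rule
    holds (``"not_lost"``: derived allele present somewhere at sampling,
    possibly fixed; ``"segregating"``: present and not fixed system-wide).
    """
    rng = _as_rng(rng)
    resolved = ResolvedDemography(model, params)
    env = _env_map(model, regime)
    tables = fitness_tables(regime, dominance)
    demes = list(model.deme_ids)
    t_gen = int(round(regime.t_onset))

    path = None
    attempts = 1 if retention == "none" else resample_cap
    for _attempt in range(attempts):
        out = _count_path(
            resolved, regime, env, tables, rng, abort_on_loss=retention != "none"
        )
        if out is None:
            continue
        draws, counts0, traj = out
        if _check_survival(traj[-1], retention):
            path = (draws, counts0, traj)
            break
    if path is None:
        raise LossRegimeError(
            f"derived allele lost in all {resample_cap} attempts "
            f"(s1={regime.s1}, s2={regime.s2}, origin={regime.origin})"
        )
    draws, counts0, traj = path
    parents, sel, sel0, offsets = _fill_pedigree(resolved, regime, draws, counts0, rng)

    # --- sample haplotypes and trace their pedigree ancestry ----------------
    deme_of = np.empty(offsets[-1], dtype=np.int64)
    for k in range(len(demes)):
        deme_of[offsets[k] : offsets[k + 1]] = k
    sample_ids: list[int] = []
    leaf_demes: list = []
    for k, d in enumerate(demes):
        n_take = int(sample_config.get(d, 0))
        block = offsets[k + 1] - offsets[k]
        if n_take > block:
            raise ValueError(f"cannot sample {n_take} haplotypes from {block} in deme {d}")
        if n_take:
            sample_ids.extend(offsets[k] + rng.choice(block, size=n_take, replace=False))
            leaf_demes.extend([d] * n_take)
    n = len(sample_ids)
    if n == 0:
        raise ValueError("empty sample")

    parent_node = [-1] * n
    node_time = [0.0] * n
    current: dict[int, int] = {}  # individual id -> genealogy node carrying it
    for node, ind in enumerate(sample_ids):
        if ind in current:  # same haplotype sampled twice: zero-length merge
            new = len(parent_node)
            parent_node.append(-1)
            node_time.append(0.0)
            parent_node[current[ind]] = new
            parent_node[node] = new
            current[ind] = new
        else:
            current[ind] = node
    for g in range(t_gen):
        # one generation back: generation index t_gen-1-g of the parents array
        row = parents[t_gen - 1 - g]
        t = float(g + 1)
        nxt: dict[int, list[int]] = {}
        for ind, node in current.items():
            nxt.setdefault(int(row[ind]), []).append(node)
        current = {}
        for anc, nodes in nxt.items():
            if len(nodes) == 1:
                current[anc] = nodes[0]
            else:
                new = len(parent_node)
                parent_node.append(-1)
                node_time.append(t)
                for nd in nodes:
                    parent_node[nd] = new
                current[anc] = new
        if len(current) == 1:
            break

    # --- close open lineages at the onset with the neutral coalescent -------
    root_inds = sorted(current)
    sel_site = np.zeros(n, dtype=np.uint8)
    for node, ind in enumerate(sample_ids):
        sel_site[node] = 1 if sel[ind] else 0
    if len(root_inds) > 1:
        top_config: dict = {}
        roots_by_deme: dict = {}
        for ind in root_inds:
            d = demes[deme_of[ind]]
            top_config[d] = top_config.get(d, 0) + 1
            roots_by_deme.setdefault(d, []).append(current[ind])
        top = simulate_genealogy(
            resolved, None, top_config, rng, start_time=float(t_gen)
        )
        # graft: leaves of `top` (per-deme insertion order) == our open roots
        base = len(parent_node)
        k_top = top.n_leaves
        top_leaf_nodes: list[int] = []
        for d in top_config:
            top_leaf_nodes.extend(roots_by_deme[d])
        for i in range(k_top, len(top.parent)):
            parent_node.append(-1)
            node_time.append(float(top.time[i]))
        mapping = {i: top_leaf_nodes[i] for i in range(k_top)}
        mapping.update({i: base + (i - k_top) for i in range(k_top, len(top.parent))})
        for i, p in enumerate(top.parent):
            if p >= 0:
                parent_node[mapping[i]] = mapping[int(p)]

    tree = Genealogy(
        parent=np.asarray(parent_node, dtype=np.int64),
        time=np.asarray(node_time, dtype=float),
        leaf_demes=leaf_demes,
        n_leaves=n,
    )
    locus = drop_mutations(tree, mu, locus_length, rng)

    # --- embed the selected site (skip if monomorphic in the sample) --------
    if 0 < int(sel_site.sum()) < n:
        pos = float(rng.random())
        while pos in locus.positions:
            pos = float(rng.random())
        at = int(np.searchsorted(locus.positions, pos))
        haps = np.insert(locus.haplotypes, at, sel_site, axis=1)
        positions = np.insert(locus.positions, at, pos)
        locus = LocusData(haps, positions, locus_length, locus.pop_labels)

    if return_trajectory:
        return locus, Trajectory(traj, demes, survived=True)
    return locus


def build_pseudogenome(
    model: DemographicModel,
    params: Mapping[str, float],
    regime: SelectionRegime | None,
    n_neutral: int,
    n_selected: int,
    locus_length: int,
    sample_config: Mapping[str, int],
    rng,
    *,
    lam: float | None = None,
    rescale_cap: float = 1000.0,
    dominance: str = "as_printed",
    retention: str = "not_lost",
    resample_cap: int = 10_000,
) -> Pseudogenome:
    """Neutral + selected loci sharing one sample configuration.

    Neutral loci come from the coalescent under the model as given; selected
    loci from the forward simulator under the ``lam``-rescaled model (default
    ``lam`` chosen so every rescaled deme size is at most ``rescale_cap``
    diploids). Loci are independent (free recombination between loci).
    """
    if n_neutral < 0 or n_selected < 0:
        raise ValueError("locus counts must be >= 0")
    rng = _as_rng(rng)
    loci: list = []
    resolved = ResolvedDemography(model, params)
    for _ in range(n_neutral):
        loci.append((simulate_locus(resolved, None, sample_config, locus_length, rng), "neutral", None))
    if n_selected:
        if regime is None:
            raise ValueError("a SelectionRegime is required when n_selected > 0")
        literal = _literal_model(model, params)
        if lam is None:
            lam = default_lambda(literal, cap=rescale_cap)
        model_s, regime_s = rescale(literal, regime, lam)
        for _ in range(n_selected):
            locus = simulate_selected_locus(
                model_s,
                None,
                regime_s,
                locus_length,
                ResolvedDemography(model_s, None).mutation_rate,
                sample_config,
                rng,
                dominance=dominance,
                retention=retention,
                resample_cap=resample_cap,
            )
            loci.append((locus, "selected", regime))
    return Pseudogenome(loci, locus_length)


def _literal_model(model: DemographicModel, params: Mapping[str, float]) -> DemographicModel:
    """Substitute parameter values so the model can be rescaled numerically."""
    def sub(v):
        return _resolve(v, params) if isinstance(v, str) else v

    return DemographicModel(
        demes=[Deme(d.id, sub(d.initial_size), sub(d.growth_rate)) for d in model.demes],
        migration=MigrationSpec({k: sub(v) for k, v in model.migration.entries.items()}),
        events=tuple(
            DemographicEvent(sub(e.time), e.kind, {k: sub(v) for k, v in e.payload.items()})
            for e in model.events
        ),
        mutation_rate=sub(model.mutation_rate),
        free_parameters=(),
    )
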