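"""Discrete-deme demographic models with time-varying sizes, migration and events.

A :class:`DemographicModel` describes the neutral backdrop of the scan: a set of
demes with diploid effective sizes ``N_i`` (optionally growing exponentially),
a matrix of scaled migration rates ``M_ij`` (migrants per generation), and a
list of timed events (size changes, growth changes, migration changes, and
backward-in-time joins). Model entries may be numeric literals or bare
parameter names resolved against a :class:`ParameterSet` drawn from
:class:`ParameterPrior` objects.

Conventions
-----------
* Migration is stated in the backward (ms-style) convention:
  ``M_ij = N_i * m_ij`` is the expected number of lineages currently in deme
  ``i`` per generation whose parent lived in deme ``j``; ``m_ij`` is the
  per-lineage, per-generation backward migration rate.
* Time is measured in generations before present.  An event at time ``t``
  applies to all times ``>= t`` (half-open ``[t, next_event)`` backward).
* Sizes are diploid; a sample of ``n`` individuals contributes ``2n``
  haploid genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, isfinite
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

Value = Union[float, int, str]  #: literal or free-parameter name

EVENT_KINDS = ("size_change", "growth_change", "migration_change", "join")


@dataclass(frozen=True)
class Deme:
    """A panmictic deme with diploid effective size ``initial_size``.

    ``growth_rate`` is the exponential growth rate per generation looking
    forward in time; backward in time the size shrinks as
    ``N(t) = N(0) * exp(-g * t)``. ``0`` means constant size.
    """

    id: str
    initial_size: Value
    growth_rate: Value = 0.0


@dataclass(frozen=True)
class MigrationSpec:
    """Backward migration matrix: ``entries[(i, j)] = M_ij`` migrants/generation.

    Missing pairs default to 0.  The diagonal is ignored.
    """

    entries: Mapping[tuple[str, str], Value] = field(default_factory=dict)

    def rate(self, i: str, j: str) -> Value:
        return self.entries.get((i, j), 0.0)


@dataclass(frozen=True)
class DemographicEvent:
    """A timed change to the model, applied backward at ``time`` generations.

    kinds and payloads:

    * ``size_change``: ``{"deme", "size"}`` — set ``N_deme`` (also resets
      growth to 0 unless ``"growth_rate"`` is given).
    * ``growth_change``: ``{"deme", "rate"}`` — set the growth rate.
    * ``migration_change``: ``{"source", "dest", "rate"}`` — set ``M_sd``.
    * ``join``: ``{"derived", "ancestral"}`` — lineages in ``derived`` move
      into ``ancestral`` (backward merge); ``derived`` is inactive older
      than ``time``.
    """

    time: Value
    kind: str
    payload: Mapping[str, Value] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class DemographicModel:
    demes: Sequence[Deme]
    migration: MigrationSpec = field(default_factory=MigrationSpec)
    events: Sequence[DemographicEvent] = ()
    mutation_rate: Value = 0.0  #: per bp per generation
    free_parameters: Sequence[str] = ()

    @property
    def deme_ids(self) -> list[str]:
        return [d.id for d in self.demes]


@dataclass(frozen=True)
class ParameterPrior:
    """Uniform prior on ``scale`` (``"linear"`` or ``"log10"``) over [lower, upper]."""

    name: str
    scale: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown prior scale {self.scale!r}")
        if not self.lower < self.upper:
            raise ValueError(
                f"prior {self.name}: lower ({self.lower}) must be < upper ({self.upper})"
            )

    def sample(self, rng: np.random.Generator, size: int | None = None):
        u = rng.uniform(self.lower, self.upper, size=size)
        return 10.0 ** u if self.scale == "log10" else u


ParameterSet = dict  #: mapping parameter name -> value on the natural scale


def sample_parameters(
    priors: Sequence[ParameterPrior], rng: np.random.Generator | int
) -> ParameterSet:
    """Draw one value per prior, uniform on its stated scale.

    log10-scale priors are returned on the natural scale (``10**u``).
    """
    if not priors:
        raise ValueError("priors must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return {p.name: float(p.sample(rng)) for p in priors}


def _resolve(value: Value, params: Mapping[str, float]) -> float:
    if isinstance(value, str):
        try:
            return float(params[value])
        except KeyError:
            raise KeyError(f"unresolved parameter {value!r}") from None
    return float(value)


def _references(values: Iterable[Value]) -> set[str]:
    return {v for v in values if isinstance(v, str)}


def model_references(model: DemographicModel) -> set[str]:
    """All parameter names referenced anywhere in the model."""
    refs: set[str] = set()
    for d in model.demes:
        refs |= _references([d.initial_size, d.growth_rate])
    refs |= _references(model.migration.entries.values())
    for e in model.events:
        refs |= _references([e.time, *e.payload.values()])
    refs |= _references([model.mutation_rate])
    refs.discard("")
    # payload fields naming demes are labels, not parameters
    deme_ids = set(model.deme_ids)
    return {r for r in refs if r not in deme_ids}


def validate_model(model: DemographicModel) -> list[str]:
    """Return a list of diagnostics; empty iff the model is usable.

    Checks that (a) every parameter reference appears in ``free_parameters``,
    (b) deme ids are unique and referenced demes exist, and (c) the backward
    process guarantees a common ancestor: a single deme, or join events
    merging everything, or a migration graph from which some deme is
    reachable by every lineage. A parameter-valued migration entry is treated
    as potentially positive.
    """
    diags: list[str] = []
    ids = model.deme_ids
    if len(set(ids)) != len(ids):
        diags.append("duplicate deme ids")
    if not ids:
        diags.append("model has no demes")
        return diags

    free = set(model.free_parameters)
    unresolved = model_references(model) - free
    if unresolved:
        diags.append(f"unresolved parameter references: {sorted(unresolved)}")

    for d in model.demes:
        if not isinstance(d.initial_size, str) and not float(d.initial_size) > 0:
            diags.append(f"deme {d.id}: initial_size must be > 0")

    id_set = set(ids)
    for e in model.events:
        for key in ("deme", "source", "dest", "derived", "ancestral"):
            if key in e.payload and e.payload[key] not in id_set:
                diags.append(f"event {e.kind}: unknown deme {e.payload[key]!r}")
        if not isinstance(e.time, str) and float(e.time) < 0:
            diags.append(f"event {e.kind}: negative time")

    # --- common-ancestor reachability -------------------------------------
    # apply joins: union demes into ancestral representatives
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            x = parent[x]
        return x

    for e in model.events:
        if e.kind == "join":
            a, b = e.payload.get("derived"), e.payload.get("ancestral")
            if a in id_set and b in id_set:
                parent[find(a)] = find(b)
    groups = {find(i) for i in ids}
    if len(groups) > 1:
        # backward-migration digraph over join-collapsed groups: edge i->j if
        # a lineage in i can ever move to j
        edges: dict[str, set[str]] = {g: set() for g in groups}
        maybe_positive = []
        for (i, j), v in model.migration.entries.items():
            if i == j or i not in id_set or j not in id_set:
                continue
            maybe_positive.append(((i, j), v))
        for e in model.events:
            if e.kind == "migration_change":
                i, j = e.payload.get("source"), e.payload.get("dest")
                if i in id_set and j in id_set and i != j:
                    maybe_positive.append(((i, j), e.payload.get("rate", 0.0)))
        for (i, j), v in maybe_positive:
            positive = isinstance(v, str) or float(v) > 0
            if positive:
                edges[find(i)].add(find(j))
        # some group must be reachable from every group
        def reachable(src: str) -> set[str]:
            seen, stack = {src}, [src]
            while stack:
                for nxt in edges[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            return seen

        reach = {g: reachable(g) for g in groups}
        if not any(all(g in reach[h] for h in groups) for g in groups):
            diags.append("no common ancestor reachable (zero migration and no joins)")
    return diags


@dataclass
class DemeState:
    """Per-deme instantaneous state at some time ``t``."""

    size: float  #: diploid N_i(t)
    growth_rate: float


@dataclass
class Epoch:
    """A half-open backward interval ``[start, end)`` of piecewise-smooth rates."""

    start: float
    end: float  #: inf for the last epoch
    sizes: dict  #: deme id -> N at epoch start
    growth: dict  #: deme id -> exponential rate (backward shrink)
    migration: dict  #: (i, j) -> M_ij migrants/generation
    active: list  #: deme ids not yet joined away
    alias: dict  #: deme id -> active deme carrying its lineages

    def size_at(self, deme: str, t: float) -> float:
        """Diploid size of ``deme`` at absolute time ``t`` within this epoch."""
        n = self.sizes[deme] * exp(-self.growth[deme] * (t - self.start))
        if not (n > 0 and isfinite(n)):
            raise ValueError(f"deme {deme}: non-positive resolved size at t={t}")
        return n

    def lineage_migration(self, i: str, j: str, t: float) -> float:
        """Backward per-lineage migration rate m_ij(t) = M_ij / N_i(t)."""
        m = self.migration.get((i, j), 0.0)
        return m / self.size_at(i, t) if m else 0.0


class ResolvedDemography:
    """A model with parameters substituted, exposed as a list of epochs."""

    def __init__(self, model: DemographicModel, params: Mapping[str, float] | None = None):
        params = dict(params or {})
        self.model = model
        self.params = params
        self.mutation_rate = _resolve(model.mutation_rate, params)

        events = sorted(model.events, key=lambda e: _resolve(e.time, params))
        times = sorted({0.0} | {_resolve(e.time, params) for e in events})

        sizes = {d.id: _resolve(d.initial_size, params) for d in model.demes}
        growth = {d.id: _resolve(d.growth_rate, params) for d in model.demes}
        migration = {
            k: _resolve(v, params) for k, v in model.migration.entries.items() if k[0] != k[1]
        }
        for (i, j), m in migration.items():
            if m < 0:
                raise ValueError(f"negative migration rate M[{i}][{j}] = {m}")
        for d, n in sizes.items():
            if not n > 0:
                raise ValueError(f"deme {d}: non-positive size {n}")
        active = list(model.deme_ids)
        alias = {d: d for d in model.deme_ids}

        self.epochs: list[Epoch] = []
        for k, t0 in enumerate(times):
            # advance sizes of growing demes to the epoch start
            if self.epochs:
                prev = self.epochs[-1]
                sizes = {d: prev.size_at(d, t0) if d in prev.active else sizes[d] for d in sizes}
            for e in events:
                if _resolve(e.time, params) != t0:
                    continue
                p = e.payload
                if e.kind == "size_change":
                    sizes[p["deme"]] = _resolve(p["size"], params)
                    growth[p["deme"]] = _resolve(p.get("growth_rate", 0.0), params)
                elif e.kind == "growth_change":
                    growth[p["deme"]] = _resolve(p["rate"], params)
                elif e.kind == "migration_change":
                    migration[(p["source"], p["dest"])] = _resolve(p["rate"], params)
                elif e.kind == "join":
                    derived, anc = p["derived"], p["ancestral"]
                    if derived in active:
                        active.remove(derived)
                    for d, a in alias.items():
                        if a == derived:
                            alias[d] = anc
                    migration = {
                        (i, j): m for (i, j), m in migration.items() if derived not in (i, j)
                    }
            t1 = times[k + 1] if k + 1 < len(times) else float("inf")
            self.epochs.append(
                Epoch(t0, t1, dict(sizes), dict(growth), dict(migration), list(active), dict(alias))
            )

    def epoch_at(self, t: float) -> Epoch:
        if t < 0:
            raise ValueError("t must be >= 0")
        for ep in reversed(self.epochs):
            if ep.start <= t:
                return ep
        return self.epochs[0]


def resolve_at_time(
    model: DemographicModel, params: Mapping[str, float], t: float
) -> tuple[dict, dict]:
    """Instantaneous rates at time ``t`` (generations before present).

    Returns ``(sizes, m)`` where ``sizes[i] = N_i(t)`` (diploid) and
    ``m[(i, j)]`` is the backward per-lineage migration rate
    ``m_ij(t) = M_ij / N_i(t)`` for active demes. Events with time <= t have
    been applied (half-open backward convention).
    """
    resolved = ResolvedDemography(model, params)
    ep = resolved.epoch_at(t)
    sizes = {d: ep.size_at(d, t) for d in ep.active}
    mig = {
        (i, j): ep.lineage_migration(i, j, t)
        for (i, j) in ep.migration
        if i in ep.active and j in ep.active
    }
    return sizes, mig


def two_deme_im_model(
    n1: Value = 10_000,
    n2: Value = 10_000,
    mutation_rate: Value = 5e-7,
    m12: Value = "M12",
    m21: Value = "M21",
    free_parameters: Sequence[str] = ("M12", "M21"),
) -> DemographicModel:
    """The simple two-deme isolation-with-migration model (reciprocal migration).

    Defaults fix N1 = N2 = 10,000 diploids and leave the two scaled migration
    rates M12, M21 (migrants per generation, backward convention) free.
    """
    return DemographicModel(
        demes=[Deme("deme1", n1), Deme("deme2", n2)],
        migration=MigrationSpec({("deme1", "deme2"): m12, ("deme2", "deme1"): m21}),
        mutation_rate=mutation_rate,
        free_parameters=tuple(free_parameters),
    )


def default_migration_priors(lower: float = -4.0, upper: float = 3.0) -> list[ParameterPrior]:
    """log10 M12, log10 M21 ~ U[-4, 3] — the scan's focal-parameter priors."""
    return [
        ParameterPrior("M12", "log10", lower, upper),
        ParameterPrior("M21", "log10", lower, upper),
    ]
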