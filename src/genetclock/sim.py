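"""Exact stochastic simulation of a modular clonal organism.

The organism is a population of modules, each reduced to the stem-cell pool
of one ramet.  Modules grow by a pure-birth process at per-cell rate ``b``
until they reach the homeostatic size ``N``; homeostatic modules turn cells
over by symmetric (Moran) divisions at per-cell rate ``lambda_sym`` and/or
asymmetric divisions at per-cell rate ``gamma_asym``, and found new modules
at rate ``r`` by branching (``N0`` founder cells copied out, parent
untouched) or splitting (``N0`` founder cells removed, parent regrows).
Every division endows newly divided cells with Poisson(``mu``) novel
mutations.  Somatic variants fix in a module when every stem cell carries
them; fixed-variant counts per module over time are the simulator's output.

The event loop is an exact Gillespie algorithm: one exponential waiting time
and one uniformly selected transition per event.  As a statistically exact
optimisation, asymmetric homeostatic divisions that would draw zero new
mutations (which leave the state bit-identical) can be merged out of the
loop by thinning that channel to rate ``gamma*N*Z_hom*(1 - exp(-mu))`` with
zero-truncated Poisson mutation counts; see ``SimulationParams.thin_asymmetric``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "SimulationParams",
    "StochasticQuiescence",
    "SeasonalQuiescence",
    "Module",
    "OrganismState",
    "Trajectory",
    "AbsorbedStateError",
    "initialize",
    "transition_rates",
    "step",
    "form_module",
    "count_fixed",
    "run",
    "sample_mean_fixed",
]


class AbsorbedStateError(RuntimeError):
    """Raised when all transition rates are zero and no event can occur."""


@dataclass(frozen=True)
class StochasticQuiescence:
    """Homeostatic modules enter a quiescent state at ``rate_in`` (per module
    per year) and quiescent modules wake at ``rate_out``.  Quiescent modules
    contribute to no transition rates."""

    rate_in: float
    rate_out: float


@dataclass(frozen=True)
class SeasonalQuiescence:
    """Deterministic annual duty cycle: the first ``active_fraction`` of each
    ``period`` (years) has normal rates, the remainder has all rates zero.
    Implemented as an exact time warp between "active time" and wall time."""

    active_fraction: float = 0.5
    period: float = 1.0


@dataclass
class SimulationParams:
    """All model rates and sizes, plus mode flags.

    Rates are per year; sizes are stem-cell or module counts.
    """

    b: float = 122.0  # cell division rate during growth (yr^-1 cell^-1)
    lambda_sym: float = 0.0  # symmetric (Moran) division rate (yr^-1 cell^-1)
    gamma_asym: float = 122.0  # asymmetric division rate (yr^-1 cell^-1)
    r: float = 5.0  # module formation rate (yr^-1 module^-1)
    N: int = 10  # homeostatic module size (stem cells)
    N0: int = 3  # founder cells per new module
    Z: int = 100  # maximum module count
    mu: float = 0.0069  # mean new mutations per cell division
    xi: float = 0.0  # time-dependent mutation rate (mut cell^-1 yr^-1)
    formation_mode: Literal["branching", "splitting"] = "branching"
    quiescence: Optional[StochasticQuiescence | SeasonalQuiescence] = None
    t_max: float = 17.0
    seed: Optional[int] = None
    # which newly divided cells draw Poisson(mu): independently per daughter,
    # or one shared count per division (ids always distinct)
    mutation_draws: Literal["per_daughter", "per_division"] = "per_daughter"
    # at the module cap Z, may the parent itself be the killed module?
    kill_excludes_parent: bool = False
    # merge silent (zero-mutation) asymmetric divisions out of the event loop
    thin_asymmetric: bool = True

    def validate(self) -> None:
        for name in ("b", "lambda_sym", "gamma_asym", "r", "mu", "xi"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not (1 <= self.N0 <= self.N):
            raise ValueError(f"require 1 <= N0 <= N, got N0={self.N0}, N={self.N}")
        if self.formation_mode == "splitting" and self.N0 > self.N - 1:
            raise ValueError(
                f"splitting requires N0 <= N-1 so the parent survives, "
                f"got N0={self.N0}, N={self.N}"
            )
        if self.formation_mode not in ("branching", "splitting"):
            raise ValueError(f"unknown formation_mode {self.formation_mode!r}")
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")
        if isinstance(self.quiescence, SeasonalQuiescence):
            q = self.quiescence
            if not (0 < q.active_fraction <= 1):
                raise ValueError("active_fraction must be in (0, 1]")
            if q.period <= 0:
                raise ValueError("period must be > 0")
        elif isinstance(self.quiescence, StochasticQuiescence):
            q = self.quiescence
            if q.rate_in < 0 or q.rate_out < 0:
                raise ValueError("quiescence rates must be >= 0")


@dataclass(eq=False)
class Module:
    """Stem-cell population of one ramet.

    ``cells`` holds one mutation-id set per stem cell; ``birth_times`` holds
    the matching cell birth times (used only for the xi mutation channel).
    """

    cells: list
    birth_times: list
    phase: Literal["growing", "homeostatic", "quiescent"]
    founding_time: float
    module_id: int
    parent_id: Optional[int] = None

    def size(self) -> int:
        return len(self.cells)


def count_fixed(module: Module) -> int:
    """Number of mutations carried by every stem cell of the module."""
    if not module.cells:
        raise ValueError("count_fixed of an empty module is undefined")
    return len(set.intersection(*module.cells)) if len(module.cells) > 1 else len(module.cells[0])


@dataclass
class OrganismState:
    """Full simulation state: module lists by phase plus cached tallies.

    ``n_growth`` (total cells in growing modules) and the homeostatic /
    quiescent module counts are maintained incrementally and always equal
    their recomputed-from-scratch values.
    """

    growing: list = field(default_factory=list)
    homeostatic: list = field(default_factory=list)
    quiescent: list = field(default_factory=list)
    t: float = 0.0
    n_growth: int = 0
    next_mutation_id: int = 0
    next_module_id: int = 0
    rng: np.random.Generator = None  # type: ignore[assignment]

    @property
    def modules(self) -> list:
        return self.growing + self.homeostatic + self.quiescent

    @property
    def z_homeostatic(self) -> int:
        return len(self.homeostatic)

    def n_modules(self) -> int:
        return len(self.growing) + len(self.homeostatic) + len(self.quiescent)

    def recompute_tallies(self) -> tuple:
        """(n_growth, z_homeostatic) recomputed from scratch, for invariants."""
        return sum(m.size() for m in self.growing), len(self.homeostatic)


def initialize(params: SimulationParams) -> OrganismState:
    """One module of a single mutation-free cell at t = 0."""
    params.validate()
    state = OrganismState(rng=np.random.default_rng(params.seed))
    mod = Module(
        cells=[set()],
        birth_times=[0.0],
        phase="homeostatic" if params.N == 1 else "growing",
        founding_time=0.0,
        module_id=0,
    )
    state.next_module_id = 1
    if mod.phase == "growing":
        state.growing.append(mod)
        state.n_growth = 1
    else:
        state.homeostatic.append(mod)
    return state


def transition_rates(state: OrganismState, params: SimulationParams) -> tuple:
    """(r_a, r_b, r_c, r_d): growth division, Moran, asymmetric, formation.

    Quiescent modules contribute to none of the four rates.  When the
    asymmetric channel is thinned, r_c is the rate of mutation-bearing
    asymmetric divisions only.
    """
    zh = state.z_homeostatic
    r_a = params.b * state.n_growth
    r_b = params.lambda_sym * params.N * zh
    r_c = params.gamma_asym * params.N * zh
    if params.thin_asymmetric and params.xi == 0.0:
        r_c *= -math.expm1(-params.mu)
    r_d = params.r * zh
    return r_a, r_b, r_c, r_d


def _poisson_positive(rng: np.random.Generator, mu: float) -> int:
    """Zero-truncated Poisson(mu) draw by inverse transform."""
    u = rng.random() * -math.expm1(-mu)
    k, cum, term = 1, 0.0, math.exp(-mu) * mu
    while True:
        cum += term
        if u < cum or k > 10_000:
            return k
        k += 1
        term *= mu / k


def _new_mutations(state: OrganismState, k: int, cell: set) -> None:
    nid = state.next_mutation_id
    for j in range(k):
        cell.add(nid + j)
    state.next_mutation_id = nid + k


def _mutation_counts(state: OrganismState, params: SimulationParams, n_daughters: int):
    rng = state.rng
    if params.mutation_draws == "per_division":
        m = int(rng.poisson(params.mu))
        return [m] * n_daughters
    return [int(rng.poisson(params.mu)) for _ in range(n_daughters)]


def _xi_accrue(state: OrganismState, params: SimulationParams, module: Module, idx: int) -> None:
    """Charge lifetime-dependent mutations to a dividing cell (xi channel)."""
    if params.xi == 0.0:
        return
    dt = state.t - module.birth_times[idx]
    if dt > 0:
        k = int(state.rng.poisson(params.xi * dt))
        if k:
            _new_mutations(state, k, module.cells[idx])


def _pick_growing_cell(state: OrganismState) -> tuple:
    """Uniform cell among all cells of growing modules."""
    u = int(state.rng.integers(state.n_growth))
    acc = 0
    for mod in state.growing:
        s = mod.size()
        if u < acc + s:
            return mod, u - acc
        acc += s
    raise AssertionError("n_growth out of sync")  # pragma: no cover


def _enter_homeostasis(state: OrganismState, mod: Module) -> None:
    state.growing.remove(mod)
    mod.phase = "homeostatic"
    state.homeostatic.append(mod)
    state.n_growth -= mod.size()


def _growth_division(state: OrganismState, params: SimulationParams) -> None:
    mod, i = _pick_growing_cell(state)
    _xi_accrue(state, params, mod, i)
    cell = mod.cells[i]
    daughter = set(cell)
    counts = _mutation_counts(state, params, 2)
    if counts[0]:
        _new_mutations(state, counts[0], cell)
    if counts[1]:
        _new_mutations(state, counts[1], daughter)
    mod.birth_times[i] = state.t
    mod.cells.append(daughter)
    mod.birth_times.append(state.t)
    state.n_growth += 1
    if mod.size() == params.N:
        _enter_homeostasis(state, mod)


def _moran_update(state: OrganismState, params: SimulationParams) -> None:
    rng = state.rng
    mod = state.homeostatic[int(rng.integers(len(state.homeostatic)))]
    n = mod.size()
    i = int(rng.integers(n))
    if n == 1:  # degenerate N=1 module: division replaces the lone cell
        j = i
    else:
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
    _xi_accrue(state, params, mod, i)
    counts = _mutation_counts(state, params, 2)
    if j != i:
        mod.cells[j] = set(mod.cells[i])
    if counts[0]:
        _new_mutations(state, counts[0], mod.cells[i])
    if counts[1] and j != i:
        _new_mutations(state, counts[1], mod.cells[j])
    mod.birth_times[i] = state.t
    mod.birth_times[j] = state.t


def _asymmetric_update(state: OrganismState, params: SimulationParams, thinned: bool) -> None:
    """One progeny stays, the other leaves the stem compartment immediately;
    only the retained progeny's mutation draw matters."""
    rng = state.rng
    mod = state.homeostatic[int(rng.integers(len(state.homeostatic)))]
    i = int(rng.integers(mod.size()))
    _xi_accrue(state, params, mod, i)
    if thinned:
        k = _poisson_positive(rng, params.mu)
    else:
        k = int(rng.poisson(params.mu))
    if k:
        _new_mutations(state, k, mod.cells[i])
    mod.birth_times[i] = state.t


def _kill_module(state: OrganismState, exclude: Module) -> None:
    """Uniformly chosen victim among all modules (optionally excluding one)."""
    rng = state.rng
    pool = state.modules
    if exclude is not None:
        pool = [m for m in pool if m is not exclude]
    victim = pool[int(rng.integers(len(pool)))]
    if victim.phase == "growing":
        state.growing.remove(victim)
        state.n_growth -= victim.size()
    elif victim.phase == "homeostatic":
        state.homeostatic.remove(victim)
    else:
        state.quiescent.remove(victim)


def form_module(state: OrganismState, parent: Module, params: SimulationParams) -> None:
    """Found a new module from ``N0`` cells of a homeostatic parent.

    Branching copies the founder cells (parent unchanged); splitting removes
    them (parent re-enters growth).  At the module cap Z a uniformly chosen
    module (never the new child; optionally never the parent) dies first.
    """
    if parent.phase != "homeostatic":
        raise ValueError("parent module must be homeostatic and non-quiescent")
    rng = state.rng
    if state.n_modules() >= params.Z:
        _kill_module(state, parent if params.kill_excludes_parent else None)
        if parent.phase not in ("homeostatic",) or parent not in state.homeostatic:
            # the parent itself was killed; its cells still found the child
            pass
    idx = rng.choice(parent.size(), size=params.N0, replace=False)
    child = Module(
        cells=[set(parent.cells[i]) for i in idx],
        birth_times=[parent.birth_times[i] for i in idx],
        phase="growing",
        founding_time=state.t,
        module_id=state.next_module_id,
        parent_id=parent.module_id,
    )
    state.next_module_id += 1
    if params.formation_mode == "splitting":
        keep = sorted(set(range(parent.size())) - set(int(i) for i in idx))
        parent.cells = [parent.cells[i] for i in keep]
        parent.birth_times = [parent.birth_times[i] for i in keep]
        if parent in state.homeostatic:
            state.homeostatic.remove(parent)
            parent.phase = "growing"
            state.growing.append(parent)
            state.n_growth += parent.size()
    if child.size() == params.N:
        child.phase = "homeostatic"
        state.homeostatic.append(child)
    else:
        state.growing.append(child)
        state.n_growth += child.size()


def _all_rates(state: OrganismState, params: SimulationParams) -> list:
    rates = list(transition_rates(state, params))
    if isinstance(params.quiescence, StochasticQuiescence):
        rates.append(params.quiescence.rate_in * state.z_homeostatic)
        rates.append(params.quiescence.rate_out * len(state.quiescent))
    return rates


def _apply_event(state: OrganismState, params: SimulationParams, rates: list) -> None:
    rng = state.rng
    u = rng.random() * sum(rates)
    acc = 0.0
    for event, rate in enumerate(rates):
        acc += rate
        if u < acc:
            break
    if event == 0:
        _growth_division(state, params)
    elif event == 1:
        _moran_update(state, params)
    elif event == 2:
        _asymmetric_update(
            state, params, thinned=params.thin_asymmetric and params.xi == 0.0
        )
    elif event == 3:
        parent = state.homeostatic[int(rng.integers(len(state.homeostatic)))]
        form_module(state, parent, params)
    elif event == 4:  # enter quiescence
        mod = state.homeostatic.pop(int(rng.integers(len(state.homeostatic))))
        mod.phase = "quiescent"
        state.quiescent.append(mod)
    else:  # exit quiescence
        mod = state.quiescent.pop(int(rng.integers(len(state.quiescent))))
        mod.phase = "homeostatic"
        state.homeostatic.append(mod)


def step(state: OrganismState, params: SimulationParams) -> OrganismState:
    """Apply exactly one Gillespie transition and advance time.

    Raises AbsorbedStateError when all rates vanish.
    """
    rates = _all_rates(state, params)
    total = sum(rates)
    if total <= 0.0:
        raise AbsorbedStateError("all transition rates are zero")
    state.t += state.rng.exponential(1.0 / total)
    _apply_event(state, params, rates)
    return state


# -- seasonal time warp -------------------------------------------------------

def _wall_to_active(t_wall: float, q: SeasonalQuiescence) -> float:
    """Active (rate-bearing) time elapsed by wall time ``t_wall``."""
    a, p = q.active_fraction, q.period
    full = math.floor(t_wall / p)
    return full * a * p + min(t_wall - full * p, a * p)


def _active_to_wall(t_act: float, q: SeasonalQuiescence) -> float:
    a, p = q.active_fraction, q.period
    full = math.floor(t_act / (a * p))
    rem = t_act - full * a * p
    # the boundary t_act == k*a*p maps to the start of the k-th active window
    return full * p + rem


@dataclass
class Trajectory:
    """Fixed somatic-variant counts per surviving module at discrete times."""

    record_times: np.ndarray
    module_ids: list  # list of int arrays, one per record time
    fixed_counts: list  # list of int arrays, one per record time
    params: Optional[SimulationParams] = None

    def to_frame(self):
        import pandas as pd

        rows = []
        for t, ids, counts in zip(self.record_times, self.module_ids, self.fixed_counts):
            for mid, c in zip(ids, counts):
                rows.append((t, int(mid), int(c)))
        return pd.DataFrame(rows, columns=["time", "module_id", "fixed_count"])


def _snapshot(state: OrganismState) -> tuple:
    mods = state.modules
    ids = np.array([m.module_id for m in mods], dtype=np.int64)
    counts = np.array([count_fixed(m) for m in mods], dtype=np.int64)
    order = np.argsort(ids)
    return ids[order], counts[order]


def run(
    params: SimulationParams,
    record_times: Sequence[float],
    state: Optional[OrganismState] = None,
) -> Trajectory:
    """Simulate to ``params.t_max`` recording fixed counts at given wall times."""
    params.validate()
    rec = np.asarray(list(record_times), dtype=float)
    if rec.size and (np.any(np.diff(rec) < 0) or rec[-1] > params.t_max + 1e-9):
        raise ValueError("record_times must be sorted and <= t_max")
    seasonal = params.quiescence if isinstance(params.quiescence, SeasonalQuiescence) else None
    if state is None:
        state = initialize(params)
    # engine time is "active" time under a seasonal duty cycle
    rec_engine = (
        np.array([_wall_to_active(t, seasonal) for t in rec]) if seasonal else rec
    )
    t_end = _wall_to_active(params.t_max, seasonal) if seasonal else params.t_max
    module_ids: list = []
    fixed_counts: list = []
    ri = 0
    while ri < rec_engine.size or state.t < t_end:
        rates = _all_rates(state, params)
        total = sum(rates)
        t_next = (
            state.t + state.rng.exponential(1.0 / total) if total > 0 else math.inf
        )
        # record times passed before the next event see the pre-event state
        while ri < rec_engine.size and rec_engine[ri] <= min(t_next, t_end):
            ids, counts = _snapshot(state)
            module_ids.append(ids)
            fixed_counts.append(counts)
            ri += 1
        if t_next >= t_end:
            state.t = t_end
            break
        state.t = t_next
        _apply_event(state, params, rates)
    return Trajectory(record_times=rec, module_ids=module_ids, fixed_counts=fixed_counts, params=params)


def sample_mean_fixed(
    trajectory: Trajectory, k: int, seed: Optional[int] = None
) -> np.ndarray:
    """Mean fixed count over ``k`` uniformly sampled distinct modules per time."""
    rng = np.random.default_rng(seed)
    out = np.empty(trajectory.record_times.size)
    for i, counts in enumerate(trajectory.fixed_counts):
        n = counts.size
        if k > n:
            raise ValueError(
                f"requested {k} modules but only {n} survive at "
                f"t={trajectory.record_times[i]:g}"
            )
        idx = rng.choice(n, size=k, replace=False)
        out[i] = counts[idx].mean()
    return out
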