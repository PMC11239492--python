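"""Closed-form conditional fixation times and calibration-design rate estimation.

A neutral somatic variant present in one stem cell fixes within a module
through repeated module-formation bottlenecks (asymmetric cell division) or
through homeostatic Moran turnover (symmetric division).  The closed forms
used here are diffusion approximations of those processes:

* module splitting:  ``4 N0 (1 - N0/N) / r``
* module branching:  ``4 N0 / ((1 - N0^2/N^2) r)``
* Moran turnover:    ``N / b``

``wf_fixation_oracle`` is an independent brute-force simulation of the
bottleneck renewal process (hypergeometric bottleneck, stochastic pure-birth
regrowth, bottlenecks at rate ``r`` along a module lineage), and
``moran_fixation_oracle`` is the analogous direct Moran-process simulation.
They exist to cross-check the closed forms, never to replace them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FixationQuery",
    "RateEstimate",
    "fixation_time_splitting",
    "fixation_time_branching",
    "fixation_time_moran",
    "equilibrium_rate",
    "wf_fixation_oracle",
    "moran_fixation_oracle",
    "CALIBRATION_DESIGN",
    "estimate_rate_two_timepoints",
    "simulate_calibration_slopes",
]


@dataclass(frozen=True)
class FixationQuery:
    """Parameters of a conditional-fixation-time query."""

    N: int
    N0: int = 1
    r: float = 0.0
    b: float = 0.0

    def time(self, mode: str) -> float:
        if mode == "splitting":
            return fixation_time_splitting(self.N, self.N0, self.r)
        if mode == "branching":
            return fixation_time_branching(self.N, self.N0, self.r)
        if mode == "moran":
            return fixation_time_moran(self.N, self.b)
        raise ValueError(f"unknown mode {mode!r}")


def fixation_time_splitting(N: int, N0: int, r: float) -> float:
    """Conditional fixation time (years) under module splitting."""
    if r <= 0:
        raise ValueError(f"module formation rate r must be > 0, got {r}")
    if not 1 <= N0 <= N:
        raise ValueError(f"require 1 <= N0 <= N, got N0={N0}, N={N}")
    return 4.0 * N0 * (1.0 - N0 / N) / r


def fixation_time_branching(N: int, N0: int, r: float) -> float:
    """Conditional fixation time (years) under module branching."""
    if r <= 0:
        raise ValueError(f"module formation rate r must be > 0, got {r}")
    if not 1 <= N0 <= N:
        raise ValueError(f"require 1 <= N0 <= N, got N0={N0}, N={N}")
    if N0 == N:
        raise ValueError("branching fixation time diverges at N0 = N")
    return 4.0 * N0 / ((1.0 - N0**2 / N**2) * r)


def fixation_time_moran(N: int, b: float) -> float:
    """Conditional fixation time (years) under symmetric (Moran) turnover."""
    if b <= 0:
        raise ValueError(f"cell division rate b must be > 0, got {b}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    return N / b


def equilibrium_rate(mu: float, b: float) -> float:
    """Equilibrium accumulation rate of fixed variants: mu * b per year."""
    if mu < 0 or b < 0:
        raise ValueError("mu and b must be >= 0")
    return mu * b


# -- brute-force oracles ------------------------------------------------------

def _polya_regrow(rng: np.random.Generator, m: np.ndarray, K: int, N: int) -> np.ndarray:
    """Vectorised stochastic pure-birth regrowth K -> N (uniform cell copies)."""
    m = m.astype(np.int64).copy()
    for size in range(K, N):
        m += rng.random(m.size) < m / size
    return m


def wf_fixation_oracle(
    N: int,
    N0: int,
    r: float,
    mode: str = "branching",
    replicates: int = 2000,
    seed: Optional[int] = None,
    start_copies: int = 1,
) -> Tuple[float, int]:
    """Mean conditional fixation time of the bottleneck renewal process.

    A single module lineage starts with the variant in ``start_copies`` of
    ``N`` cells (default one).
    Bottlenecks occur at rate ``r``; each samples founder cells without
    replacement (branching: ``N0`` copied, lineage follows the child;
    splitting: the lineage is equally likely to follow the ``N0``-cell child
    or the ``N - N0``-cell parent remainder) and regrows to ``N`` by a
    stochastic pure-birth process.  Returns ``(mean_time, n_fixed)`` over
    replicates that fixed; raises if none fixed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if mode not in ("branching", "splitting"):
        raise ValueError(f"unknown mode {mode!r}")
    if r <= 0:
        raise ValueError("r must be > 0")
    if not 1 <= N0 <= (N if mode == "branching" else N - 1):
        raise ValueError(f"invalid N0={N0} for N={N}, mode={mode}")
    if not 0 <= start_copies <= N:
        raise ValueError("start_copies must be in [0, N]")
    rng = np.random.default_rng(seed)
    i = np.full(replicates, start_copies, dtype=np.int64)
    t = np.zeros(replicates)
    active = (i > 0) & (i < N)
    while active.any():
        idx = np.flatnonzero(active)
        t[idx] += rng.exponential(1.0 / r, idx.size)
        if mode == "branching":
            K = np.full(idx.size, N0)
        else:
            K = np.where(rng.random(idx.size) < 0.5, N0, N - N0)
        cur = i[idx]
        new = np.empty(idx.size, dtype=np.int64)
        for Kv in np.unique(K):
            sel = K == Kv
            k = rng.hypergeometric(cur[sel], N - cur[sel], Kv)
            new[sel] = _polya_regrow(rng, k, int(Kv), N)
        i[idx] = new
        active[idx] = (new > 0) & (new < N)
    fixed = i == N
    if not fixed.any():
        raise RuntimeError(
            f"no fixing replicate out of {replicates}; increase replicates "
            f"(fixation probability is ~1/{N})"
        )
    return float(t[fixed].mean()), int(fixed.sum())


def moran_fixation_oracle(
    N: int,
    b: float,
    replicates: int = 2000,
    seed: Optional[int] = None,
) -> Tuple[float, int]:
    """Mean conditional fixation time of a direct neutral Moran simulation.

    One module of ``N`` cells, division events at total rate ``b * N``; each
    event picks a divider and a distinct cell to remove uniformly at random.
    The variant starts in one cell.  Returns ``(mean_time, n_fixed)``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if b <= 0 or N < 2:
        raise ValueError("need b > 0 and N >= 2")
    rng = np.random.default_rng(seed)
    i = np.ones(replicates, dtype=np.int64)
    t = np.zeros(replicates)
    active = np.ones(replicates, dtype=bool)
    event_rate = b * N
    while active.any():
        idx = np.flatnonzero(active)
        t[idx] += rng.exponential(1.0 / event_rate, idx.size)
        cur = i[idx]
        p_move = cur * (N - cur) / (N * (N - 1))  # P(divider mutant, removed wt)
        u = rng.random(idx.size)
        cur = cur + (u < p_move) - ((u >= p_move) & (u < 2 * p_move))
        i[idx] = cur
        active[idx] = (cur > 0) & (cur < N)
    fixed = i == N
    if not fixed.any():
        raise RuntimeError(f"no fixing replicate out of {replicates}")
    return float(t[fixed].mean()), int(fixed.sum())


# -- calibration-design rate estimation ---------------------------------------

#: the two-timepoint sampling layout of the eelgrass calibration experiments:
#: at 4 years three genets with two sampled modules each, at 17 years two
#: genets with five and six sampled modules.
CALIBRATION_DESIGN: Tuple[Tuple[float, Tuple[int, ...]], ...] = (
    (4.0, (2, 2, 2)),
    (17.0, (5, 6)),
)


@dataclass(frozen=True)
class RateEstimate:
    """OLS estimate of the fixed-variant accumulation rate (per year)."""

    slope: float
    intercept: float
    n_genets: int
    design: Tuple[Tuple[float, Tuple[int, ...]], ...]


def estimate_rate_two_timepoints(
    sim_outputs: Mapping[float, Sequence[np.ndarray]],
    design: Sequence[Tuple[float, Sequence[int]]] = CALIBRATION_DESIGN,
    seed: Optional[int] = None,
) -> RateEstimate:
    """Accumulation rate from module samples at the design's timepoints.

    ``sim_outputs`` maps each design age to one per-module fixed-count array
    per genet.  For every genet the design's number of modules is sampled
    uniformly without replacement and averaged; an ordinary least-squares
    line of genet mean fixed count on age gives the rate.
    """
    rng = np.random.default_rng(seed)
    ages, means = [], []
    for age, per_genet in design:
        arrays = sim_outputs[age]
        if len(arrays) != len(per_genet):
            raise ValueError(
                f"design wants {len(per_genet)} genets at age {age}, "
                f"got {len(arrays)}"
            )
        for counts, k in zip(arrays, per_genet):
            counts = np.asarray(counts)
            if k > counts.size:
                raise ValueError(
                    f"design wants {k} modules but genet has {counts.size} "
                    f"surviving at age {age}"
                )
            idx = rng.choice(counts.size, size=k, replace=False)
            ages.append(age)
            means.append(float(counts[idx].mean()))
    ages_a = np.asarray(ages)
    if np.unique(ages_a).size < 2:
        raise ValueError("need at least two distinct ages to fit a rate")
    slope, intercept = np.polyfit(ages_a, np.asarray(means), 1)
    design_t = tuple((float(a), tuple(int(x) for x in ks)) for a, ks in design)
    return RateEstimate(float(slope), float(intercept), len(means), design_t)


def simulate_calibration_slopes(
    params,
    design: Sequence[Tuple[float, Sequence[int]]] = CALIBRATION_DESIGN,
    n_replicates: int = 20,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Replicate slope estimates mimicking the calibration experiment.

    Each replicate simulates one independent genet per design entry to its
    age, samples the designed number of modules, and fits the OLS rate.
    """
    from . import sim as _sim

    ss = np.random.SeedSequence(seed)
    slopes = np.empty(n_replicates)
    for rep, child in enumerate(ss.spawn(n_replicates)):
        genet_seeds = child.spawn(sum(len(ks) for _, ks in design) + 1)
        gi = 0
        outputs: Dict[float, list] = {}
        for age, per_genet in design:
            outputs[float(age)] = []
            for _k in per_genet:
                p = dataclasses.replace(
                    params, t_max=float(age), seed=genet_seeds[gi]
                )
                gi += 1
                traj = _sim.run(p, [float(age)])
                outputs[float(age)].append(traj.fixed_counts[-1])
        est = estimate_rate_two_timepoints(
            outputs, design, seed=genet_seeds[gi].generate_state(1)[0] % (2**31)
        )
        slopes[rep] = est.slope
    return slopes
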