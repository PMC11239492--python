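"""Ground-truthed synthetic ramet genealogies, variants and read counts.

The clock's statistical assumptions are generated here directly: ramets of
a genet are leaves of a (by default ultrametric) genealogy rooted at the
founder zygote; fixed somatic variants drop on branches as a Poisson
process and sit at true allele frequency 0.5 in every descendant leaf;
mosaic variants are private to single ramets at low frequency.  Sequencing
is emulated by per-(ramet, site) depth draws (optionally over-dispersed)
and binomial read sampling with a symmetric error rate, producing exactly
the normal/tumor pair tables and Size_e values the clock consumes — so
every clock stage is testable against known truth without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clock import PAIR_COLUMNS, GenetSample

__all__ = [
    "RametGenealogy",
    "MosaicConfig",
    "SyntheticTruth",
    "ReadSimParams",
    "CALIBRATION_GENETS",
    "CalibrationFixture",
    "make_genealogy",
    "drop_variants",
    "simulate_pair_tables",
    "build_genet_sample",
    "calibration_fixture",
]


@dataclass
class RametGenealogy:
    """Rooted binary genealogy of sampled ramets, branch lengths in years.

    ``parent[i]`` is the parent node of node ``i`` (-1 for node 0) and
    ``length[i]`` the branch length above it.  Node 0's branch is the trunk
    from the founder zygote to the first split (zero-length once the genet
    has split immediately); variants on it are shared by every ramet.
    """

    parent: np.ndarray
    length: np.ndarray
    leaves: np.ndarray  # node indices of the sampled ramets
    leaf_names: List[str]

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def root_path(self, node: int) -> List[int]:
        """Nodes from the trunk down to ``node`` (inclusive)."""
        path = []
        while node >= 0:
            path.append(node)
            node = int(self.parent[node])
        return path[::-1]

    def leaves_below(self, node: int) -> frozenset:
        """Names of sampled ramets descending from (or equal to) ``node``."""
        children: Dict[int, List[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        out, stack = [], [node]
        leafset = set(int(x) for x in self.leaves)
        names = {int(l): n for l, n in zip(self.leaves, self.leaf_names)}
        while stack:
            n = stack.pop()
            if n in leafset:
                out.append(names[n])
            stack.extend(children.get(n, []))
        return frozenset(out)

    def depth(self, node: int) -> float:
        d = 0.0
        while node >= 0:
            d += float(self.length[node])
            node = int(self.parent[node])
        return d


def make_genealogy(
    n_ramets: int,
    age: float,
    branching_pattern: str = "yule",
    seed: Optional[int] = None,
) -> RametGenealogy:
    """Ultrametric genealogy with all sampled ramets at depth ``age``.

    ``star``: all splits at the founding — the sampled genealogy of a
    rapidly expanding clone, whose coalescences compress toward the root;
    every ramet then accumulates variants independently over the full age,
    matching the clock's S(R_x) ~ Poisson(rate x age) model.  ``yule``:
    split times uniform on (0, age), each split applied to a uniformly
    chosen extant lineage (slowly expanding clone; part of each ramet's
    history is shared and invisible to pairwise comparison).
    ``caterpillar``: evenly spaced splits always applied to the first
    lineage (a comb).
    """
    if n_ramets < 1:
        raise ValueError("n_ramets must be >= 1")
    if age <= 0:
        raise ValueError("age must be > 0")
    rng = np.random.default_rng(seed)
    parent = [-1]
    length = [0.0]
    start = [0.0]  # time at which each node's branch began
    # active lineages: (node_index)
    active = [0]
    if branching_pattern == "yule":
        split_times = np.sort(rng.uniform(0.0, age, size=n_ramets - 1))
    elif branching_pattern == "star":
        split_times = np.zeros(n_ramets - 1)
    elif branching_pattern == "caterpillar":
        split_times = np.arange(1, n_ramets) * (age / n_ramets)
    else:
        raise ValueError(f"unknown branching_pattern {branching_pattern!r}")
    for ts in split_times:
        which = (
            0 if branching_pattern == "caterpillar"
            else int(rng.integers(len(active)))
        )
        node = active[which]
        length[node] = ts - start[node]
        for _ in range(2):
            parent.append(node)
            length.append(0.0)
            start.append(float(ts))
        active[which] = len(parent) - 2
        active.append(len(parent) - 1)
    for node in active:
        length[node] = age - start[node]
    leaves = np.array(sorted(active), dtype=int)
    names = [f"R{i + 1:02d}" for i in range(leaves.size)]
    return RametGenealogy(
        parent=np.array(parent, dtype=int),
        length=np.array(length, dtype=float),
        leaves=leaves,
        leaf_names=names,
    )


@dataclass(frozen=True)
class MosaicConfig:
    """Per-ramet mosaic variants: Poisson count at low uniform frequency.

    The true mosaic-frequency distribution in eelgrass is uncharacterised;
    Uniform(0.05, 0.35) in a single ramet is a labelled assumption chosen so
    mosaics fail the VRF >= 0.5 filter at high depth but stress it at low
    depth.
    """

    mean_per_ramet: float = 3.0
    freq_low: float = 0.05
    freq_high: float = 0.35


@dataclass
class SyntheticTruth:
    """Known variant truth for one genet."""

    tree: RametGenealogy
    variants: pd.DataFrame  # columns: pos, kind, freq, carriers (frozenset)
    genome_size: int
    rate_fixed: float
    true_s: Dict[str, int]  # per-ramet fixed variants since the founder


def _unique_positions(rng: np.random.Generator, n: int, genome_size: int) -> np.ndarray:
    taken: set = set()
    while len(taken) < n:
        for p in rng.integers(1, genome_size + 1, size=n - len(taken)):
            taken.add(int(p))
    return np.array(sorted(taken), dtype=np.int64)


def drop_variants(
    tree: RametGenealogy,
    rate_fixed: float,
    mosaic_config: Optional[MosaicConfig] = MosaicConfig(),
    genome_size: int = 10_000_000,
    seed: Optional[int] = None,
) -> SyntheticTruth:
    """Poisson fixed variants per branch plus per-ramet mosaic variants.

    A fixed variant on a branch is carried, at true allele frequency 0.5, by
    exactly the ramets below that branch; the per-ramet truth S(R_x) is the
    branch-count sum along the root-to-leaf path.
    """
    if rate_fixed < 0:
        raise ValueError("rate_fixed must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_fixed * tree.length)
    rows: List[tuple] = []
    for node in range(tree.n_nodes):
        if counts[node] == 0:
            continue
        carriers = tree.leaves_below(node)
        if not carriers:
            continue
        for _ in range(int(counts[node])):
            rows.append(("fixed", 0.5, carriers, node))
    if mosaic_config is not None:
        for leaf, name in zip(tree.leaves, tree.leaf_names):
            k = int(rng.poisson(mosaic_config.mean_per_ramet))
            freqs = rng.uniform(mosaic_config.freq_low, mosaic_config.freq_high, k)
            for f in freqs:
                rows.append(("mosaic", float(f), frozenset([name]), int(leaf)))
    pos = _unique_positions(rng, len(rows), genome_size)
    order = rng.permutation(len(rows))
    variants = pd.DataFrame(
        {
            "pos": pos,
            "kind": [rows[i][0] for i in order],
            "freq": [rows[i][1] for i in order],
            "carriers": [rows[i][2] for i in order],
            "node": [rows[i][3] for i in order],
        }
    ).sort_values("pos", ignore_index=True)
    true_s = {}
    for leaf, name in zip(tree.leaves, tree.leaf_names):
        path = set(tree.root_path(int(leaf)))
        true_s[name] = int(sum(counts[n] for n in path))
    return SyntheticTruth(
        tree=tree,
        variants=variants,
        genome_size=genome_size,
        rate_fixed=rate_fixed,
        true_s=true_s,
    )


@dataclass(frozen=True)
class ReadSimParams:
    """Read-count emulation: depth model and symmetric sequencing error.

    ``depth_dispersion`` = 0 gives a fixed depth at every site; > 0 draws
    negative-binomial depths with variance ``d + dispersion * d^2``.
    """

    mean_depth: float = 200.0
    depth_dispersion: float = 0.1
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    def draw_depths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        d = self.mean_depth
        if self.depth_dispersion == 0.0:
            return np.full(n, int(round(d)), dtype=np.int64)
        shape = 1.0 / self.depth_dispersion
        p = shape / (shape + d)
        return rng.negative_binomial(shape, p, size=n).astype(np.int64)

    def callable_fraction(self, min_depth: int = 23) -> float:
        """P(depth >= min_depth) under the depth model."""
        from scipy import stats

        d = self.mean_depth
        if self.depth_dispersion == 0.0:
            return float(round(d) >= min_depth)
        shape = 1.0 / self.depth_dispersion
        p = shape / (shape + d)
        return float(stats.nbinom.sf(min_depth - 1, shape, p))


def simulate_pair_tables(
    truth: SyntheticTruth,
    readsim: ReadSimParams = ReadSimParams(),
    seed: Optional[int] = None,
) -> Tuple[Dict[Tuple[str, str], pd.DataFrame], Dict[str, int]]:
    """Observed read counts for every ordered clonemate pair, plus Size_e.

    Reads are drawn once per (ramet, site) — the same physical evidence is
    reused in every pair a ramet appears in.  A carrier site yields alt
    reads ~ Binomial(depth, f(1-e) + (1-f)e) with f the true allele
    frequency; a non-carrier site uses f = 0.  Size_e is a binomial draw of
    callable sites (coverage >= 23) over the whole genome.
    """
    rng = np.random.default_rng(seed)
    names = truth.tree.leaf_names
    nv = len(truth.variants)
    e = readsim.error_rate
    depth: Dict[str, np.ndarray] = {}
    alt: Dict[str, np.ndarray] = {}
    carriers = truth.variants["carriers"].to_numpy()
    freqs = truth.variants["freq"].to_numpy(dtype=float)
    for name in names:
        d = readsim.draw_depths(rng, nv)
        f = np.where(np.array([name in c for c in carriers], dtype=bool), freqs, 0.0)
        p_obs = f * (1 - e) + (1 - f) * e
        alt[name] = rng.binomial(d, p_obs)
        depth[name] = d
    size_e: Dict[str, int] = {}
    frac = readsim.callable_fraction(23)
    for name in names:
        size_e[name] = int(rng.binomial(truth.genome_size, frac))
    tables: Dict[Tuple[str, str], pd.DataFrame] = {}
    pos = truth.variants["pos"].to_numpy()
    for tumor in names:
        mask = np.array([tumor in c for c in carriers], dtype=bool)
        for normal in names:
            if normal == tumor:
                continue
            tables[(normal, tumor)] = pd.DataFrame(
                {
                    "site_chrom": "synthetic_contig_1",
                    "site_pos": pos[mask],
                    "normal_depth": depth[normal][mask],
                    "normal_alt": alt[normal][mask],
                    "tumor_depth": depth[tumor][mask],
                    "tumor_alt": alt[tumor][mask],
                }
            )[PAIR_COLUMNS]
    return tables, size_e


def build_genet_sample(
    truth: SyntheticTruth,
    readsim: ReadSimParams = ReadSimParams(),
    seed: Optional[int] = None,
    name: str = "genet",
) -> GenetSample:
    """Assemble the GenetSample the clock consumes from synthetic truth."""
    tables, size_e = simulate_pair_tables(truth, readsim, seed)
    return GenetSample(
        ramets=list(truth.tree.leaf_names),
        pair_tables=tables,
        size_e={k: float(v) for k, v in size_e.items()},
        genome_size=float(truth.genome_size),
        name=name,
    )


#: genets of the calibration experiments: three 4-year-old genets with two
#: ramets each and two 17-year-old genets with five and six ramets.
CALIBRATION_GENETS: Tuple[Tuple[float, int], ...] = (
    (4.0, 2),
    (4.0, 2),
    (4.0, 2),
    (17.0, 5),
    (17.0, 6),
)


@dataclass
class CalibrationFixture:
    """A full synthetic calibration table plus its generating truth."""

    points: List[Tuple[float, float]]  # (age, mean_vrf50) per genet
    genets: List[GenetSample]
    truths: List[SyntheticTruth]
    rate_fixed: float

    @property
    def truth_slope(self) -> float:
        """Expected mean-VRF50-per-year slope: 0.5 x fixed-variant rate."""
        return 0.5 * self.rate_fixed


def calibration_fixture(
    rate_fixed: float = 1.0,
    design: Sequence[Tuple[float, int]] = CALIBRATION_GENETS,
    readsim: ReadSimParams = ReadSimParams(),
    mosaic_config: Optional[MosaicConfig] = MosaicConfig(),
    genome_size: int = 10_000_000,
    branching_pattern: str = "star",
    seed: Optional[int] = None,
) -> CalibrationFixture:
    """Synthetic (age, mean VRF50) calibration table with known truth.

    The default star genealogy mirrors the clock's statistical model: each
    ramet's fixed-variant count is an independent Poisson(rate x age) draw
    relative to the founder, so the expected calibration slope is
    0.5 x rate_fixed in mean-VRF50 units.
    """
    from .clock import mean_vrf50 as _mean_vrf50

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 * len(design))
    points, genets, truths = [], [], []
    for gi, (age, n_ramets) in enumerate(design):
        tree = make_genealogy(
            n_ramets, age, branching_pattern=branching_pattern, seed=children[3 * gi]
        )
        truth = drop_variants(
            tree,
            rate_fixed,
            mosaic_config=mosaic_config,
            genome_size=genome_size,
            seed=children[3 * gi + 1],
        )
        genet = build_genet_sample(
            truth, readsim, seed=children[3 * gi + 2], name=f"genet{gi + 1}"
        )
        points.append((float(age), _mean_vrf50(genet)))
        genets.append(genet)
        truths.append(truth)
    return CalibrationFixture(
        points=points, genets=genets, truths=truths, rate_fixed=rate_fixed
    )
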