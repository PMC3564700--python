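"""Sequence-family simulation under K2P or F84 and the accuracy benchmark.

The simulator draws a root sequence from the model's stationary base
frequencies and evolves it down a phylogeny whose branch lengths are in
expected substitutions per site.  Substitutions use the transition
probability matrix ``P(t) = expm(Q t)`` of the analytically constructed,
unit-mean-rate generator Q; the K2P closed form is equivalent and both
models are time-reversible.  Optional indels (Poisson number of events per
branch, geometric lengths) are logged through homology keys so the true
multiple alignment implied by the simulation history can be written out —
the benchmark itself never uses it, since the point of the relative
complexity measure is to work on unaligned sequences.

The benchmark design: a fully balanced 16-taxon topology (depth-4
cherries, equal branch lengths), families of mean length 500, and a
"rose-like" low-divergence preset whose branch length is calibrated so
that sister leaves have ~95% expected substitution identity.  Each family
is pushed through RCM distances -> neighbor joining and scored by the
Robinson-Foulds symmetric distance to the generating topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .phylo import nj_tree, rf_distance
from .rcm import distance_matrix
from .sequences import NucSequence

__all__ = [
    "EvolveConfig",
    "FamilyResult",
    "BenchmarkResult",
    "balanced16_tree",
    "rate_matrix",
    "transition_matrix",
    "expected_p_distance",
    "calibrate_branch_length",
    "rose_like_config",
    "evolve_family",
    "benchmark_rcm",
    "score_trees",
]

BASE_ORDER = "ACGT"
_PURINES = (0, 2)  # A, G


# ---------------------------------------------------------------------------
# Substitution models


def _k2p_rate_matrix(kappa: float) -> np.ndarray:
    # kappa = alpha/beta (transition/transversion *rate* ratio); normalised
    # so the expected substitution rate is 1 per unit branch length
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    Q = np.full((4, 4), beta)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        Q[i, j] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _f84_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    # F84: transversion rate to j proportional to pi_j; transitions get an
    # extra kappa * pi_j / pi_group(j) within-group term
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    pi = np.asarray(freqs, dtype=float)
    pi_r = pi[_PURINES[0]] + pi[_PURINES[1]]
    pi_y = 1.0 - pi_r
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            group = pi_r if j in _PURINES else pi_y
            is_transition = (i in _PURINES) == (j in _PURINES)
            Q[i, j] = pi[j] * (1.0 + kappa / group) if is_transition else pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))  # expected rate under stationarity
    return Q / mu


def rate_matrix(model: str, kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """Unit-mean-rate generator for the named model (order A, C, G, T)."""
    model = model.upper()
    if model == "K2P":
        return _k2p_rate_matrix(kappa)
    if model == "F84":
        return _f84_rate_matrix(kappa, np.asarray(freqs, dtype=float))
    raise ValueError(f"unknown substitution model {model!r} (expected K2P or F84)")


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probabilities over a branch of length t (expm of Q t)."""
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    return expm(Q * t)


def expected_p_distance(Q: np.ndarray, freqs: Sequence[float], t: float) -> float:
    """Expected proportion of differing sites between the ends of a path of
    total length t, under stationarity: 1 - sum_i pi_i P_ii(t)."""
    pi = np.asarray(freqs, dtype=float)
    P = transition_matrix(Q, t)
    return float(1.0 - pi @ np.diag(P))


def calibrate_branch_length(
    Q: np.ndarray,
    freqs: Sequence[float],
    *,
    target_identity: float = 0.95,
    path_edges: int = 2,
) -> float:
    """Per-edge branch length such that two leaves separated by
    ``path_edges`` edges have the target expected substitution identity."""
    target_p = 1.0 - target_identity
    total = brentq(lambda t: expected_p_distance(Q, freqs, t) - target_p, 1e-9, 20.0)
    return float(total) / path_edges


# ---------------------------------------------------------------------------
# Benchmark topology


def balanced16_tree(branch_length: float) -> dendropy.Tree:
    """The fully balanced 16-taxon topology (depth-4 cherries) with equal
    branch lengths; taxa T01..T16."""
    names = [f"T{i:02d}" for i in range(1, 17)]
    b = f"{branch_length:.10g}"
    level = names
    while len(level) > 1:
        level = [
            f"({level[k]}:{b},{level[k + 1]}:{b})" for k in range(0, len(level), 2)
        ]
    nw = level[0] + ";"
    tree = dendropy.Tree.get(data=nw, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class EvolveConfig:
    """Parameters of one simulated sequence family.

    ``kappa`` is the transition-bias parameter of the chosen model (the
    transition/transversion rate ratio for K2P, F84's within-group rate
    boost).  ``base_freqs`` are A,C,G,T stationary frequencies; K2P forces
    1/4 each.  ``indel_rate`` is the expected number of indel events per
    site per branch (half insertions, half deletions) with geometric event
    lengths of mean ``indel_mean_length``.  ``tree`` defaults to the
    balanced 16-taxon topology with ``branch_length`` on every edge.
    Branch lengths are expected substitutions per site.
    """

    model: str = "K2P"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    root_length_mean: int = 500
    length_jitter: float = 0.0  # +/- fraction of uniform length jitter
    indel_rate: float = 0.0
    indel_mean_length: float = 2.0
    branch_length: float = 0.05
    tree: Optional[dendropy.Tree] = None

    def __post_init__(self) -> None:
        model = self.model.upper()
        object.__setattr__(self, "model", model)
        if model == "K2P":
            object.__setattr__(self, "base_freqs", (0.25, 0.25, 0.25, 0.25))
        pi = np.asarray(self.base_freqs, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must be 4 non-negative values summing to 1")
        if self.root_length_mean < 1:
            raise ValueError("root_length_mean must be >= 1")
        for name in ("indel_rate", "indel_mean_length", "length_jitter", "branch_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rate_matrix(self) -> np.ndarray:
        return rate_matrix(self.model, self.kappa, self.base_freqs)

    def resolved_tree(self) -> dendropy.Tree:
        return self.tree if self.tree is not None else balanced16_tree(self.branch_length)


def rose_like_config(model: str = "K2P", **overrides) -> EvolveConfig:
    """Low-divergence benchmark preset on the balanced 16-taxon topology.

    The per-edge branch length is calibrated so that sister leaves (a
    two-edge path) have ~95% expected substitution identity; small indels
    (one event per 100 sites per branch) make the leaf sequences vary in
    length around the 500-letter mean.  F84 uses mildly AT-rich base
    frequencies typical of the plant markers this method targets.
    """
    model = model.upper()
    freqs = (0.25,) * 4 if model == "K2P" else (0.3, 0.2, 0.2, 0.3)
    kappa = overrides.pop("kappa", 2.0)
    freqs = overrides.pop("base_freqs", freqs)
    Q = rate_matrix(model, kappa, freqs)
    b = calibrate_branch_length(Q, freqs, target_identity=0.95, path_edges=2)
    defaults = dict(
        model=model,
        kappa=kappa,
        base_freqs=tuple(freqs),
        root_length_mean=500,
        indel_rate=0.01,
        indel_mean_length=2.0,
        branch_length=b,
    )
    defaults.update(overrides)
    return EvolveConfig(**defaults)


# ---------------------------------------------------------------------------
# Simulation


@dataclass(frozen=True)
class FamilyResult:
    tree: dendropy.Tree  # generating (true) tree
    leaves: tuple[NucSequence, ...]  # ungapped leaf sequences
    alignment: dict  # leaf label -> gapped row of the true alignment


def _sample_children(P_cum: np.ndarray, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(len(states))
    # clip guards against u falling above a cumsum that rounds below 1.0
    return np.minimum((P_cum[states] < u[:, None]).sum(axis=1), 3)


def evolve_family(
    cfg: EvolveConfig,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> FamilyResult:
    """Simulate one sequence family along ``cfg``'s tree.

    Homology keys (Fraction positions with a uniqueness counter) track
    every site through substitutions and indels, so the returned alignment
    is the exact alignment implied by the simulation history.  With all
    branch lengths zero and no indels, every leaf equals the root sequence
    and the alignment is gap-free.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = cfg.resolved_tree()
    Q = cfg.rate_matrix()
    pi = np.asarray(cfg.base_freqs, dtype=float)

    L = cfg.root_length_mean
    if cfg.length_jitter > 0:
        lo = int(round(L * (1 - cfg.length_jitter)))
        hi = int(round(L * (1 + cfg.length_jitter)))
        L = int(rng.integers(lo, hi + 1))
    states0 = rng.choice(4, size=L, p=pi)
    keys0 = [(Fraction(k), k) for k in range(L)]
    uid = [L]  # mutable uniqueness counter for inserted columns

    p_cache: dict[float, np.ndarray] = {}

    def branch_P_cum(t: float) -> np.ndarray:
        key = round(float(t), 12)
        if key not in p_cache:
            p_cache[key] = transition_matrix(Q, float(t)).cumsum(axis=1)
        return p_cache[key]

    geo_p = min(1.0, 1.0 / max(cfg.indel_mean_length, 1.0))

    def apply_indels(states: np.ndarray, keys: list) -> tuple[np.ndarray, list]:
        lam = cfg.indel_rate * len(states) / 2.0
        for _ in range(int(rng.poisson(lam))):  # deletions
            if len(states) <= 1:
                break
            g = int(rng.geometric(geo_p))
            start = int(rng.integers(0, len(states)))
            end = min(start + g, len(states))
            states = np.delete(states, slice(start, end))
            del keys[start:end]
        for _ in range(int(rng.poisson(lam))):  # insertions
            g = int(rng.geometric(geo_p))
            pos = int(rng.integers(0, len(states) + 1))
            left = keys[pos - 1][0] if pos > 0 else Fraction(-1)
            right = keys[pos][0] if pos < len(keys) else (
                keys[-1][0] + 1 if keys else Fraction(0)
            )
            new_keys = []
            for k in range(g):
                frac = left + (right - left) * Fraction(k + 1, g + 1)
                new_keys.append((frac, uid[0]))
                uid[0] += 1
            new_states = rng.choice(4, size=g, p=pi)
            states = np.insert(states, pos, new_states)
            keys[pos:pos] = new_keys
        return states, keys

    leaf_data: dict[str, tuple[np.ndarray, list]] = {}
    node_data = {tree.seed_node: (states0, keys0)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        p_states, p_keys = node_data[node.parent_node]
        t = node.edge.length or 0.0
        states = _sample_children(branch_P_cum(t), p_states, rng) if t > 0 else p_states.copy()
        keys = list(p_keys)
        if cfg.indel_rate > 0:
            states, keys = apply_indels(states, keys)
        if node.is_leaf():
            if len(states) == 0:
                raise RuntimeError(
                    f"leaf {node.taxon.label} lost all sites; indel_rate too high"
                )
            leaf_data[node.taxon.label] = (states, keys)
        else:
            node_data[node] = (states, keys)

    leaves = tuple(
        NucSequence(label, "".join(BASE_ORDER[x] for x in states))
        for label, (states, _) in sorted(leaf_data.items())
    )
    columns = sorted({k for _, keys in leaf_data.values() for k in keys})
    col_index = {k: i for i, k in enumerate(columns)}
    alignment = {}
    for label, (states, keys) in sorted(leaf_data.items()):
        row = ["-"] * len(columns)
        for st, k in zip(states, keys):
            row[col_index[k]] = BASE_ORDER[st]
        alignment[label] = "".join(row)
    return FamilyResult(tree=tree, leaves=leaves, alignment=alignment)


# ---------------------------------------------------------------------------
# Benchmark


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-family RF scores of one method against the true topologies."""

    method: str
    model: str
    rf_raw: tuple[int, ...]
    rf_normalized: tuple[float, ...]

    @property
    def n_families(self) -> int:
        return len(self.rf_raw)

    @property
    def mean_raw(self) -> float:
        return float(np.mean(self.rf_raw)) if self.rf_raw else float("nan")

    @property
    def sd_raw(self) -> float:
        return float(np.std(self.rf_raw)) if self.rf_raw else float("nan")

    @property
    def mean_normalized(self) -> float:
        return float(np.mean(self.rf_normalized)) if self.rf_normalized else float("nan")

    @property
    def sd_normalized(self) -> float:
        return float(np.std(self.rf_normalized)) if self.rf_normalized else float("nan")

    def row(self) -> tuple:
        return (
            self.method,
            self.model,
            self.n_families,
            self.mean_raw,
            self.sd_raw,
            self.mean_normalized,
            self.sd_normalized,
        )


def score_trees(
    method: str,
    model: str,
    estimated: Sequence[dendropy.Tree],
    true_trees: Sequence[dendropy.Tree],
) -> BenchmarkResult:
    """Score externally produced trees exactly like the RCM pipeline, so
    results from other reconstruction programs can be tabulated alongside."""
    if len(estimated) != len(true_trees):
        raise ValueError(
            f"{len(estimated)} estimated trees vs {len(true_trees)} true trees"
        )
    raw = []
    norm = []
    for est, true in zip(estimated, true_trees):
        raw.append(int(rf_distance(est, true)))
        norm.append(float(rf_distance(est, true, normalized=True)))
    return BenchmarkResult(method, model, tuple(raw), tuple(norm))


def benchmark_rcm(
    cfg: EvolveConfig,
    n_families: int,
    *,
    seed: int = 0,
    keep_families: bool = False,
) -> BenchmarkResult | tuple[BenchmarkResult, list[FamilyResult]]:
    """Simulate ``n_families`` families and score RCM + neighbor joining on
    the *unaligned* leaf sequences against the true topology.

    Family f uses the RNG substream ``SeedSequence(seed, spawn_key=(f,))``,
    so results are reproducible and independent of n_families.
    """
    raw: list[int] = []
    norm: list[float] = []
    families: list[FamilyResult] = []
    for f in range(n_families):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(f,)))
        fam = evolve_family(cfg, rng=rng)
        dm = distance_matrix(fam.leaves)
        est = nj_tree(dm)
        raw.append(int(rf_distance(est, fam.tree)))
        norm.append(float(rf_distance(est, fam.tree, normalized=True)))
        if keep_families:
            families.append(fam)
    result = BenchmarkResult("RCM", cfg.model, tuple(raw), tuple(norm))
    return (result, families) if keep_families else result
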