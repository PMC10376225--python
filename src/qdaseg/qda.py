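"""Quantum-inspired dragonfly optimizer for intensity-cluster refinement.

The dragonfly algorithm (DA) moves a swarm with five operators —
separation, alignment, cohesion, food attraction, enemy distraction — plus
a Lévy flight for neighborless individuals.  The quantum computing
mechanism (QCM) replaces the two Newtonian behaviors (inertia and Lévy
flight): a step or position is quantized onto [-1, 1], encoded as a
unit-norm amplitude pair, advanced by a 2x2 rotation gate whose sign
points toward the current food (best) solution, and dequantized back.  A
Gaussian mutation with greedy acceptance adds local search diversity.

Each agent's position is the full K-vector of candidate tissue centroids;
the scalar gate equations apply coordinate-wise.  The swarm is seeded from
the k-means solution, so with elitism the final fitness never exceeds the
seed's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterModel, assign

__all__ = [
    "Bounds",
    "DAWeights",
    "QubitValue",
    "QDAConfig",
    "SwarmState",
    "quantize",
    "rotate",
    "dequantize",
    "mape",
    "fitness",
    "init_swarm",
    "neighbor_set",
    "swarm_operators",
    "da_step",
    "levy_step",
    "levy_qcm_update",
    "gaussian_mutation",
    "optimize",
]


@dataclass(frozen=True)
class Bounds:
    """Closed search interval for every centroid coordinate."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("bounds must be finite")
        if self.lo >= self.hi:
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def range(self) -> float:
        return self.hi - self.lo

    def clip(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.clip(x, self.lo, self.hi)


@dataclass(frozen=True)
class DAWeights:
    """Operator weights for one iteration.

    s, a, c: separation / alignment / cohesion weights; f, e: food and
    enemy factors; xi: inertia weight applied to the QCM-transformed
    previous step.
    """

    s: float
    a: float
    c: float
    f: float
    e: float
    xi: float

    def __post_init__(self) -> None:
        for name in ("s", "a", "c", "f", "e", "xi"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be >= 0")


def da_weights(t: int, T: int, rng: np.random.Generator) -> DAWeights:
    """Canonical adaptive DA schedule: random per-iteration scaling that
    decays with t, with the inertia weight annealed linearly 0.9 -> 0.4."""
    T = max(T, 1)
    frac = t / T
    my_c = max(0.1 - frac * 0.2, 0.0)
    r = rng.uniform(size=4)
    return DAWeights(
        s=2.0 * r[0] * my_c,
        a=2.0 * r[1] * my_c,
        c=2.0 * r[2] * my_c,
        f=2.0 * r[3],
        e=my_c,
        xi=0.9 - frac * 0.5,
    )


@dataclass(frozen=True)
class QubitValue:
    """A quantized value q in [-1, 1] with its amplitude pair.

    The scalar is mapped to the |1> amplitude by beta = sin(pi*(q+1)/4) so
    q in [-1, 1] corresponds smoothly to beta in [0, 1]; alpha completes
    the unit norm.  After a rotation the amplitudes are kept exactly (so
    gate composition holds) and q is recovered from the clipped beta.
    """

    q: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.q <= 1.0 + 1e-12:
            raise ValueError(f"q={self.q} outside [-1, 1]")
        norm = self.alpha**2 + self.beta**2
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"amplitude norm {norm} != 1")


def _qubit_from_q(q: float) -> QubitValue:
    q = float(np.clip(q, -1.0, 1.0))
    beta = math.sin(math.pi * (q + 1.0) / 4.0)
    alpha = math.sqrt(max(0.0, 1.0 - beta * beta))
    return QubitValue(q=q, alpha=alpha, beta=beta)


def _q_from_beta(beta: float) -> float:
    return 4.0 * math.asin(float(np.clip(beta, 0.0, 1.0))) / math.pi - 1.0


def quantize(dx: float, b: Bounds) -> QubitValue:
    """Map a (clamped) real value onto [-1, 1]: q = (2dx - (hi+lo))/(hi-lo)."""
    dx = float(b.clip(dx))
    q = (2.0 * dx - (b.hi + b.lo)) / b.range
    return _qubit_from_q(q)


def rotate(qb: QubitValue, theta: float) -> QubitValue:
    """Apply the rotation gate [[cos, -sin], [sin, cos]] to the amplitudes.

    Renormalization only absorbs round-off; the rotated pair is kept
    exactly so that rotate(rotate(x, t1), t2) == rotate(x, t1 + t2).
    """
    if theta == 0.0:
        return qb  # exact identity, no arcsin round-trip
    ct, st = math.cos(theta), math.sin(theta)
    alpha = ct * qb.alpha - st * qb.beta
    beta = st * qb.alpha + ct * qb.beta
    norm = math.hypot(alpha, beta)
    if abs(norm - 1.0) > 1e-15 and norm > 0:
        alpha, beta = alpha / norm, beta / norm
    return QubitValue(q=_q_from_beta(beta), alpha=alpha, beta=beta)


def dequantize(qb: QubitValue, b: Bounds) -> float:
    """Inverse of quantize: dx = (hi*(1+q) + lo*(1-q)) / 2."""
    return 0.5 * (b.hi * (1.0 + qb.q) + b.lo * (1.0 - qb.q))


def _qcm_scalar(value: float, target: float, theta: float, b: Bounds) -> float:
    """Quantize -> rotate toward the target's quantized value -> dequantize."""
    qb = quantize(value, b)
    qt = quantize(target, b)
    sign = math.copysign(1.0, qt.q - qb.q) if qt.q != qb.q else 0.0
    return dequantize(rotate(qb, sign * theta), b)


@dataclass
class QDAConfig:
    """Swarm size, iteration budget, gate angle and mutation settings.

    theta is the rotation-angle magnitude in radians (the sign is chosen
    per coordinate, pointing the rotated amplitude toward the food
    solution's quantized value).  levy_beta is the Lévy stability exponent
    for the Mantegna sampler.  Stagnation stops the loop early when the
    best fitness improves by less than stagnation_tol over
    stagnation_window iterations.
    """

    n_agents: int = 20
    n_iter: int = 100
    theta: float = 0.02 * math.pi
    mutation_prob: float = 0.1
    mutation_k: float = 1.0
    levy_beta: float = 1.5
    stagnation_window: int = 15
    stagnation_tol: float = 1e-6
    seed: int | None = 0
    init_spread: float = 0.1
    fitness_mode: str = "unsupervised"
    printed_cohesion_sign: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if not (0 < self.theta < math.pi / 2):
            raise ValueError("theta must lie in (0, pi/2)")
        if not (0 <= self.mutation_prob <= 1):
            raise ValueError("mutation_prob must lie in [0, 1]")
        if not (1 < self.levy_beta <= 2):
            raise ValueError("levy_beta must lie in (1, 2]")
        if self.fitness_mode not in ("unsupervised", "mape"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")


@dataclass
class SwarmState:
    """Positions, step vectors and bookkeeping of the dragonfly swarm."""

    positions: np.ndarray        # (N, d)
    steps: np.ndarray            # (N, d); doubles as the velocity V
    fitness: np.ndarray          # (N,)
    food_pos: np.ndarray         # best position ever seen
    food_fit: float
    enemy_pos: np.ndarray        # worst position of the current population
    enemy_fit: float
    bounds: Bounds
    t: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def radius(self, T: int) -> float:
        """Neighborhood radius, growing linearly from range/4 to range."""
        frac = min(self.t / max(T, 1), 1.0)
        return self.bounds.range * (0.25 + 0.75 * frac)


def mape(y: np.ndarray, f: np.ndarray) -> float:
    """Mean absolute percentage error between actual and predicted classes.

    Instances with y == 0 are excluded (percentage error is undefined
    there); the value is on the 0-100 scale.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    f = np.asarray(f, dtype=np.float64).ravel()
    keep = y != 0
    if not keep.any():
        raise ValueError("no instances with nonzero actual class")
    return float(np.mean(np.abs(y[keep] - f[keep]) / y[keep]) * 100.0)


def fitness(
    position: np.ndarray,
    pixels: np.ndarray,
    bounds: Bounds,
    truth_labels: np.ndarray | None = None,
) -> float:
    """Clustering quality of a candidate centroid vector (lower is better).

    Unsupervised (default): the mean absolute quantization error
    ``mean(|pixel - nearest centroid|) / (hi - lo)``, a rate in [0, 1].
    With ``truth_labels`` given: MAPE between the actual classes and the
    1-based ascending-centroid cluster index (labels of 0 are excluded).
    """
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if pixels.size == 0:
        raise ValueError("pixels must be nonempty")
    centroids = np.sort(np.asarray(position, dtype=np.float64).ravel())
    labels = assign(pixels, centroids)
    if truth_labels is None:
        return float(np.mean(np.abs(pixels - centroids[labels]))) / bounds.range
    return mape(truth_labels, labels + 1)


def init_swarm(
    cfg: QDAConfig,
    bounds: Bounds,
    seed_centroids: np.ndarray,
    pixels: np.ndarray,
    truth_labels: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SwarmState:
    """Seed the swarm around the k-means centroids.

    Agent 0 is exactly the seed vector; the rest are the seed plus seeded
    uniform perturbations of amplitude ``init_spread * range``, clamped to
    bounds.  Step vectors start at zero; food/enemy are set from the
    initial fitness values.
    """
    seed_centroids = np.asarray(seed_centroids, dtype=np.float64).ravel()
    if np.any(seed_centroids < bounds.lo) or np.any(seed_centroids > bounds.hi):
        raise ValueError("seed centroids violate bounds")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    d = seed_centroids.size
    pert = rng.uniform(-1.0, 1.0, size=(cfg.n_agents, d))
    pert *= cfg.init_spread * bounds.range
    pert[0] = 0.0
    positions = np.asarray(bounds.clip(seed_centroids[None, :] + pert))
    fits = np.array(
        [fitness(p, pixels, bounds, truth_labels) for p in positions]
    )
    best = int(np.argmin(fits))
    worst = int(np.argmax(fits))
    return SwarmState(
        positions=positions,
        steps=np.zeros_like(positions),
        fitness=fits,
        food_pos=positions[best].copy(),
        food_fit=float(fits[best]),
        enemy_pos=positions[worst].copy(),
        enemy_fit=float(fits[worst]),
        bounds=bounds,
        t=0,
        rng=rng,
    )


def neighbor_set(st: SwarmState, i: int, T: int = 1, radius: float | None = None) -> np.ndarray:
    """Indices j != i with Euclidean distance D_ij <= the current radius."""
    r = st.radius(T) if radius is None else radius
    d = np.linalg.norm(st.positions - st.positions[i], axis=1)
    d[i] = np.inf
    return np.flatnonzero(d <= r)


def swarm_operators(
    st: SwarmState, i: int, neighbors: np.ndarray | None = None,
    T: int = 1, printed_cohesion_sign: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The five DA operators (Si, Ai, Ci, Fi, Ei) for agent i.

    Si = -sum_j (Xi - Xj); Ai = mean of neighbor step vectors; Ci =
    mean(Xj) - Xi (attraction to the neighborhood center; the repulsive
    printed sign is available behind ``printed_cohesion_sign``); Fi =
    X_food - Xi; Ei = X_enemy + Xi.  With no neighbors Si = Ai = Ci = 0.
    """
    nb = neighbor_set(st, i, T) if neighbors is None else np.asarray(neighbors)
    xi = st.positions[i]
    if nb.size:
        xj = st.positions[nb]
        S = -np.sum(xi[None, :] - xj, axis=0)
        A = st.steps[nb].mean(axis=0)
        C = xj.mean(axis=0) - xi
        if printed_cohesion_sign:
            C = -C
    else:
        S = np.zeros_like(xi)
        A = np.zeros_like(xi)
        C = np.zeros_like(xi)
    F = st.food_pos - xi
    E = st.enemy_pos + xi
    return S, A, C, F, E


def _levy_sigma(beta: float) -> float:
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    return (num / den) ** (1.0 / beta)


def levy_step(rng: np.random.Generator, beta: float = 1.5, size: int = 1) -> np.ndarray:
    """Heavy-tailed Lévy draw by the Mantegna algorithm (0.01 scaling)."""
    sigma = _levy_sigma(beta)
    u = rng.normal(0.0, sigma, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return 0.01 * u / np.abs(v) ** (1.0 / beta)


def levy_qcm_update(
    x: float,
    b: Bounds,
    theta: float,
    t: int,
    cfg: QDAConfig,
    rng: np.random.Generator,
    target: float | None = None,
) -> float:
    """QCM replacement of the Lévy flight for a neighborless coordinate.

    The position itself is quantized, rotated by ``theta`` (sign toward
    ``target``, the food coordinate, when given), dequantized to x', and
    the new position is ``clamp(x' + Levy * x)``.
    """
    if target is None:
        xr = dequantize(rotate(quantize(x, b), theta), b)
    else:
        xr = _qcm_scalar(x, target, theta, b)
    levy = float(levy_step(rng, cfg.levy_beta, size=1)[0])
    return float(b.clip(xr + levy * x))


def da_step(
    st: SwarmState,
    w: DAWeights | None,
    pixels: np.ndarray,
    cfg: QDAConfig,
    truth_labels: np.ndarray | None = None,
    T: int | None = None,
) -> SwarmState:
    """One synchronous swarm update (mutates and returns ``st``).

    Agents with neighbors follow the five-operator step rule with the
    inertia term passed through the QCM (quantize -> rotate -> dequantize);
    neighborless agents take the QCM Lévy update.  Positions are clamped,
    fitness re-evaluated, the food updated with elitism (never worsens) and
    the enemy set to the current worst.
    """
    T = cfg.n_iter if T is None else T
    if w is None:
        w = da_weights(st.t, T, st.rng)
    b = st.bounds
    new_pos = st.positions.copy()
    new_steps = st.steps.copy()
    for i in range(st.n_agents):
        nb = neighbor_set(st, i, T)
        if nb.size:
            S, A, C, F, E = swarm_operators(
                st, i, neighbors=nb, printed_cohesion_sign=cfg.printed_cohesion_sign
            )
            inertia = np.array(
                [
                    _qcm_scalar(
                        float(st.steps[i, k]),
                        float(st.food_pos[k] - st.positions[i, k]),
                        cfg.theta,
                        b,
                    )
                    for k in range(st.dim)
                ]
            )
            step = w.s * S + w.a * A + w.c * C + w.f * F + w.e * E + w.xi * inertia
            new_steps[i] = step
            new_pos[i] = b.clip(st.positions[i] + step)
        else:
            for k in range(st.dim):
                new_pos[i, k] = levy_qcm_update(
                    float(st.positions[i, k]),
                    b,
                    cfg.theta,
                    st.t,
                    cfg,
                    st.rng,
                    target=float(st.food_pos[k]),
                )
            new_steps[i] = 0.0
    st.positions = new_pos
    st.steps = new_steps
    st.fitness = np.array(
        [fitness(p, pixels, b, truth_labels) for p in st.positions]
    )
    best = int(np.argmin(st.fitness))
    if st.fitness[best] < st.food_fit:
        st.food_fit = float(st.fitness[best])
        st.food_pos = st.positions[best].copy()
    worst = int(np.argmax(st.fitness))
    st.enemy_fit = float(st.fitness[worst])
    st.enemy_pos = st.positions[worst].copy()
    st.t += 1
    return st


def gaussian_mutation(
    x: np.ndarray, cfg: QDAConfig, rng: np.random.Generator
) -> np.ndarray:
    """With probability mutation_prob, return clamp(x * (1 + k * r)) for a
    single standard-normal draw r; otherwise return x unchanged."""
    x = np.asarray(x, dtype=np.float64)
    if rng.uniform() >= cfg.mutation_prob:
        return x.copy()
    r = rng.standard_normal()
    return np.asarray(np.clip(x * (1.0 + cfg.mutation_k * r), None, None))


def optimize(
    pixels: np.ndarray,
    kmeans_model: ClusterModel,
    cfg: QDAConfig | None = None,
    bounds: Bounds | None = None,
    truth_labels: np.ndarray | None = None,
) -> tuple[ClusterModel, list[float]]:
    """Refine k-means centroids with the quantum dragonfly swarm.

    Returns the best centroid vector re-labeled over ``pixels`` as a
    ClusterModel, plus the per-iteration best-fitness trace (monotone
    non-increasing by elitism; the trace starts at the seeded swarm's best).
    With ``cfg.n_iter == 0`` the k-means solution is returned unchanged.
    """
    cfg = cfg or QDAConfig()
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if bounds is None:
        bounds = Bounds(float(pixels.min()), float(pixels.max()) + 1e-9)
    labels_arg = truth_labels if cfg.fitness_mode == "mape" else None

    if cfg.n_iter == 0:
        fit0 = fitness(kmeans_model.centroids, pixels, bounds, labels_arg)
        return kmeans_model, [fit0]

    rng = np.random.default_rng(cfg.seed)
    st = init_swarm(cfg, bounds, kmeans_model.centroids, pixels, labels_arg, rng)
    history = [st.food_fit]
    for _ in range(cfg.n_iter):
        da_step(st, None, pixels, cfg, labels_arg)
        # greedy Gaussian mutation: a mutant replaces its parent only when
        # strictly better, preserving the monotone best-fitness trace
        for i in range(st.n_agents):
            cand = np.asarray(bounds.clip(gaussian_mutation(st.positions[i], cfg, rng)))
            if np.array_equal(cand, st.positions[i]):
                continue
            f_cand = fitness(cand, pixels, bounds, labels_arg)
            if f_cand < st.fitness[i]:
                st.positions[i] = cand
                st.fitness[i] = f_cand
                if f_cand < st.food_fit:
                    st.food_fit = float(f_cand)
                    st.food_pos = cand.copy()
        history.append(st.food_fit)
        if (
            len(history) > cfg.stagnation_window
            and history[-1 - cfg.stagnation_window] - history[-1]
            < cfg.stagnation_tol
        ):
            break

    centroids = np.sort(st.food_pos)
    labels = assign(pixels, centroids)
    objective = float(np.sum(np.abs(pixels - centroids[labels])))
    best = ClusterModel(
        centroids=centroids,
        labels=labels,
        objective=objective,
        K=centroids.size,
    )
    return best, history
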