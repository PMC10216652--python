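"""Hybrid water-wave / whale optimization (HybWWoA) and its feature-selection wrapper.

Water-wave optimization (WWO) moves each agent ("wave") by a uniform step
scaled by its wavelength delta and the search-range length per dimension;
fitter waves get shorter wavelengths (finer search) through a per-iteration
multiplicative update.  A stagnation counter ("wave height") triggers
refraction — a Gaussian jump toward the current best.  Whale optimization
(WOA) alternates prey encircling, a logarithmic-spiral exploitation move
around the best agent, and an exploration move toward a random agent, all
governed by a coefficient `a` that decays linearly from 2 to 0.

The hybrid interleaves the two: each iteration, each agent takes a WWO
propagation step with probability ``p_hybrid`` and a WOA move otherwise.
WWO steps are accepted greedily (an agent keeps its old position when the
step does not improve it); WOA moves are always accepted, following each
algorithm's own convention.  The best-ever solution is tracked separately,
so the reported trace is monotone non-increasing.

Feature selection wraps the continuous optimizer: positions in [-4, 4]^D
pass through a sigmoid transfer function and a 0.5 threshold to a boolean
mask, scored by a 1-nearest-neighbour surrogate under stratified 3-fold
cross-validation plus a small subset-size penalty.  All problems are
minimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "SearchBounds",
    "HybConfig",
    "Wave",
    "SelectionMask",
    "ObjectiveSpec",
    "propagate",
    "update_wavelength",
    "refract",
    "woa_coefficients",
    "woa_move",
    "optimize",
    "binarize",
    "feature_fitness",
    "select_features",
    "sphere",
    "rastrigin",
    "random_search",
]


@dataclass(frozen=True)
class SearchBounds:
    """Box constraints; ``length(d) = ub(d) - lb(d)``."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.asarray(self.lb, dtype=float)
        ub = np.asarray(self.ub, dtype=float)
        if lb.shape != ub.shape or np.any(ub <= lb):
            raise ValueError("require ub > lb elementwise")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def length(self) -> np.ndarray:
        return self.ub - self.lb

    @classmethod
    def cube(cls, dim: int, lo: float, hi: float) -> "SearchBounds":
        return cls(np.full(dim, lo), np.full(dim, hi))


@dataclass(frozen=True)
class HybConfig:
    """Hybrid optimizer configuration.

    ``alpha`` is the wavelength-reduction base, ``h_max`` the initial wave
    height (stagnation budget), ``b_spiral`` the spiral shape constant,
    ``p_threshold`` the spiral-vs-encircle branch point, and ``p_hybrid``
    the per-agent probability of a WWO propagation step instead of a WOA
    move.  ``refraction=False`` disables the height-triggered Gaussian
    jump (used to recover pure WOA behaviour).
    """

    pop_size: int = 20
    iterations: int = 100
    alpha: float = 1.0026
    epsilon: float = 1e-12
    h_max: int = 6
    b_spiral: float = 1.0
    p_threshold: float = 0.5
    p_hybrid: float = 0.5
    refraction: bool = True
    delta_init: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.p_hybrid <= 1.0:
            raise ValueError("p_hybrid must lie in [0, 1]")


@dataclass
class Wave:
    """One search agent: position, wavelength, stagnation height, fitness."""

    position: np.ndarray
    wavelength: float
    height: int
    fitness: float


@dataclass(frozen=True)
class SelectionMask:
    """Boolean mask over feature indices (never empty)."""

    selected: np.ndarray

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=bool)
        if sel.ndim != 1 or not sel.any():
            raise ValueError("mask must be 1-D and select at least one feature")
        object.__setattr__(self, "selected", sel)

    @property
    def count(self) -> int:
        return int(self.selected.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


@dataclass(frozen=True)
class ObjectiveSpec:
    """A minimization problem: callable, dimensionality and box bounds."""

    evaluate: object
    dim: int
    bounds: SearchBounds


def propagate(wave: Wave, bounds: SearchBounds, rng, evaluate=None) -> Wave:
    """WWO propagation: per-dimension uniform step scaled by wavelength.

    ``x'(d) = x(d) + U(-1, 1) * delta * L(d)``; a coordinate leaving its
    bounds is resampled uniformly inside them.  Fitness is re-evaluated
    when ``evaluate`` is given, else carried over.
    """
    step = rng.uniform(-1.0, 1.0, size=wave.position.shape)
    x = wave.position + step * wave.wavelength * bounds.length
    out = (x < bounds.lb) | (x > bounds.ub)
    if out.any():
        x[out] = bounds.lb[out] + rng.uniform(size=int(out.sum())) * bounds.length[out]
    f = float(evaluate(x)) if evaluate is not None else wave.fitness
    return Wave(position=x, wavelength=wave.wavelength, height=wave.height,
                fitness=f)


def update_wavelength(wave: Wave, fmax: float, fmin: float,
                      cfg: HybConfig) -> float:
    """Wavelength update: delta * alpha^(-(f - fmin + eps)/(fmax - fmin + eps)).

    Minimization orientation: the best wave (f = fmin) keeps its wavelength
    almost unchanged, the worst (f = fmax) shrinks it by a full factor
    1/alpha, so better waves search more finely over time only relative to
    worse ones.
    """
    if fmax < fmin:
        raise ValueError("fmax must be >= fmin")
    expo = -(wave.fitness - fmin + cfg.epsilon) / (fmax - fmin + cfg.epsilon)
    return float(wave.wavelength * cfg.alpha ** expo)


def refract(wave: Wave, best: Wave, cfg: HybConfig, rng, evaluate=None) -> Wave:
    """WWO refraction: Gaussian jump toward the best agent on stagnation.

    Each coordinate is redrawn from N((x* + x)/2, |x* - x|/2); the height
    resets to ``h_max`` and the wavelength is rescaled by the fitness ratio
    f(old)/f(new) (guarded against division by zero).
    """
    mean = 0.5 * (best.position + wave.position)
    sd = 0.5 * np.abs(best.position - wave.position)
    x = rng.normal(mean, sd)
    if evaluate is not None:
        f_new = float(evaluate(x))
        ratio = wave.fitness / f_new if f_new != 0.0 else 1.0
        delta = float(wave.wavelength * abs(ratio)) or wave.wavelength
    else:
        f_new, delta = wave.fitness, wave.wavelength
    return Wave(position=x, wavelength=delta, height=cfg.h_max, fitness=f_new)


def woa_coefficients(a: float, rng):
    """WOA coefficients: A = 2*a*r - a in [-a, a] and C = 2*r in [0, 2]."""
    r1 = rng.uniform()
    r2 = rng.uniform()
    return 2.0 * a * r1 - a, 2.0 * r2


def woa_move(agent_pos: np.ndarray, best_pos: np.ndarray, population,
             cfg: HybConfig, a: float, rng) -> np.ndarray:
    """One WOA position update (spiral / encircle / explore), clamped to bounds.

    With probability ``p_threshold`` the spiral update
    ``X' = |X* - X| * exp(b l) * cos(2 pi l) + X*`` is taken; otherwise the
    encircling move ``X' = X* - A |C X* - X|`` when |A| < 1, else the
    exploration move toward a uniformly chosen agent from ``population``.
    """
    p = rng.uniform()
    l = rng.uniform(-1.0, 1.0)
    A, C = woa_coefficients(a, rng)
    if p >= cfg.p_threshold:
        d = np.abs(best_pos - agent_pos)
        x = d * np.exp(cfg.b_spiral * l) * np.cos(2.0 * np.pi * l) + best_pos
    elif abs(A) < 1.0:
        d = np.abs(C * best_pos - agent_pos)
        x = best_pos - A * d
    else:
        other = population[rng.integers(len(population))]
        d = np.abs(C * other - agent_pos)
        x = other - A * d
    return x


def optimize(objective: ObjectiveSpec, cfg: HybConfig):
    """Run the hybrid optimizer; returns (best_position, best_fitness, trace).

    ``trace[i]`` is the best-ever fitness after iteration i (monotone
    non-increasing).  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    bounds = objective.bounds
    f = objective.evaluate
    pos = bounds.lb + rng.uniform(size=(cfg.pop_size, objective.dim)) * bounds.length
    waves = [Wave(position=pos[i].copy(), wavelength=cfg.delta_init,
                  height=cfg.h_max, fitness=float(f(pos[i])))
             for i in range(cfg.pop_size)]
    best = min(waves, key=lambda w: w.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    trace = []

    for it in range(cfg.iterations):
        a = 2.0 * (1.0 - it / max(cfg.iterations - 1, 1))
        fits = [w.fitness for w in waves]
        fmax, fmin = max(fits), min(fits)
        pop_positions = [w.position for w in waves]
        for i, w in enumerate(waves):
            w = replace_wavelength(w, update_wavelength(w, fmax, fmin, cfg))
            if rng.uniform() < cfg.p_hybrid:
                cand = propagate(w, bounds, rng, evaluate=f)
                if cand.fitness < w.fitness:  # greedy WWO acceptance
                    new = Wave(cand.position, w.wavelength, cfg.h_max,
                               cand.fitness)
                else:
                    new = Wave(w.position, w.wavelength, w.height - 1,
                               w.fitness)
            else:
                x = woa_move(w.position, best_pos, pop_positions, cfg, a, rng)
                x = np.clip(x, bounds.lb, bounds.ub)
                fx = float(f(x))
                h = cfg.h_max if fx < w.fitness else w.height - 1
                new = Wave(x, w.wavelength, h, fx)  # WOA always accepts
            if cfg.refraction and new.height <= 0:
                new = refract(new, Wave(best_pos, 1.0, cfg.h_max, best_fit),
                              cfg, rng, evaluate=f)
                new.position = np.clip(new.position, bounds.lb, bounds.ub)
            waves[i] = new
            if new.fitness < best_fit:
                best_fit = new.fitness
                best_pos = new.position.copy()
        trace.append(best_fit)
    return best_pos, best_fit, np.asarray(trace)


def replace_wavelength(wave: Wave, delta: float) -> Wave:
    return Wave(wave.position, delta, wave.height, wave.fitness)


def binarize(position: np.ndarray) -> SelectionMask:
    """Sigmoid transfer + 0.5 threshold; guards against the empty mask.

    Feature d is selected iff 1/(1 + exp(-x_d)) > 0.5, i.e. x_d > 0.  If
    nothing is selected, the dimension with the largest transfer value is
    forced on.
    """
    x = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")
    sel = x > 0.0
    if not sel.any():
        sel = sel.copy()
        sel[int(np.argmax(x))] = True
    return SelectionMask(selected=sel)


def feature_fitness(mask: SelectionMask, features: np.ndarray,
                    labels: np.ndarray, omega: float = 0.99,
                    seed: int = 0) -> float:
    """Wrapper fitness: omega * err + (1 - omega) * |mask| / D (minimized).

    ``err`` is the misclassification rate of a 1-nearest-neighbour
    surrogate under seeded stratified 3-fold cross-validation restricted to
    the selected columns.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have matching rows")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain at least two classes")
    Xs = X[:, mask.selected]
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    errors = 0
    for tr, te in skf.split(Xs, y):
        knn = KNeighborsClassifier(n_neighbors=1)
        knn.fit(Xs[tr], y[tr])
        errors += int(np.sum(knn.predict(Xs[te]) != y[te]))
    err = errors / X.shape[0]
    return float(omega * err + (1.0 - omega) * mask.count / X.shape[1])


def select_features(features: np.ndarray, labels: np.ndarray,
                    cfg: HybConfig, omega: float = 0.99):
    """Feature selection: hybrid optimizer over [-4, 4]^D with the wrapper fitness.

    Returns ``(mask, trace)``; reproducible from ``cfg.seed``.
    """
    X = np.asarray(features, dtype=float)
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least two candidate features")
    bounds = SearchBounds.cube(d, -4.0, 4.0)

    cache: dict = {}

    def evaluate(pos):
        key = binarize(pos).selected.tobytes()
        if key not in cache:
            cache[key] = feature_fitness(SelectionMask(np.frombuffer(key, dtype=bool)),
                                         X, labels, omega=omega, seed=cfg.seed)
        return cache[key]

    spec = ObjectiveSpec(evaluate=evaluate, dim=d, bounds=bounds)
    best_pos, _, trace = optimize(spec, cfg)
    return binarize(best_pos), trace


# --- benchmark objectives -------------------------------------------------

def sphere(x: np.ndarray) -> float:
    """f(x) = sum x_i^2; global minimum 0 at the origin."""
    return float(np.sum(np.square(x)))


def rastrigin(x: np.ndarray) -> float:
    """Multimodal benchmark: 10 d + sum(x^2 - 10 cos(2 pi x))."""
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def random_search(objective: ObjectiveSpec, n_evals: int, seed: int):
    """Uniform random search baseline at a fixed evaluation budget."""
    rng = np.random.default_rng(seed)
    b = objective.bounds
    best_x, best_f = None, np.inf
    for _ in range(n_evals):
        x = b.lb + rng.uniform(size=objective.dim) * b.length
        fx = float(objective.evaluate(x))
        if fx < best_f:
            best_f, best_x = fx, x
    return best_x, best_f
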