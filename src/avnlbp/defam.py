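"""Differential evolution of Fuzzy ARTMAP populations (DEFAM).

Trained FAM networks are encoded as fixed-length real vectors (a fixed
number ``catmax`` of category *slots*, each holding ``2d`` weight
components, one label gene and one validity gene; a slot is active iff its
validity gene is >= 0.5).  Differential evolution then searches this space
with a neighbourhood-to-best mutation

    V = x_r3 + F1 (x_best - x_r3) + F2 (x_r1 - x_r2),

where r1, r2, r3 are distinct members drawn from the top-ranked fraction of
the population, binomial crossover, and pairwise greedy selection.  The
objective couples classification accuracy ``pcc`` (percent correct) and
network size ``Na`` (active categories):

    F = |100 catmin - pcc Na| / ((catmax - Na) pcc^2),

minimized subject to ``catmin <= Na < catmax``; infeasible members carry a
large finite penalty.  The optimum F = 0 is reached at ``Na = catmin`` with
``pcc = 100`` — the smallest network with the highest accuracy, which is
exactly the remedy for category proliferation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from avnlbp.fam import FuzzyARTMAP

from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DEParams",
    "NetworkCodec",
    "FitnessRecord",
    "encode",
    "decode",
    "mutate_classic",
    "mutate_neigh_to_best",
    "crossover",
    "fitness",
    "fitness_raw",
    "select",
    "evolve",
    "train_diverse_population",
    "DEFAMClassifier",
]

logger = logging.getLogger(__name__)

#: Large finite penalty assigned to infeasible encodings (Na outside
#: [catmin, catmax) or zero accuracy); graded by |Na - catmin| so the
#: search still has a pull back towards feasibility.
PENALTY = 1.0e6


@dataclass
class DEParams:
    """Differential-evolution control parameters.

    F / F1 / F2 are the mutation scale factors (F1 pulls towards the best
    member, F2 scales the difference vector), CR the binomial crossover
    rate, ``neigh_frac`` the fraction of top-ranked members eligible as
    mutation donors (0.3–0.6), and ``catmin``/``catmax`` the category-count
    bounds of the fitness constraint (catmin should equal the number of
    classes; ``n_classes <= catmin <= catmax`` is required).
    """

    F: float = 1.0
    F1: float = 1.0
    F2: float = 1.0
    CR: float = 0.7
    generations: int = 30
    neigh_frac: float = 0.5
    catmin: int = 2
    catmax: int = 20
    seed: int | None = None
    crossover_dialect: str = "canonical"
    max_stagnation: int | None = None
    #: Accuracy floor (pcc units): members below it are infeasible.  None
    #: means "derive from the initial population" in :func:`evolve` (best
    #: initial pcc minus ``pcc_tolerance``); the floor is what makes the
    #: pruning accuracy-preserving — without it the objective has a
    #: degenerate basin at pcc*Na ~ 100*catmin with very low accuracy.
    min_pcc: float | None = None
    pcc_tolerance: float = 2.0

    def validate(self, n_classes: int | None = None) -> None:
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError(f"CR must lie in [0, 1], got {self.CR}")
        if not 0.3 <= self.neigh_frac <= 0.6:
            raise ValueError(
                f"neigh_frac must lie in [0.3, 0.6], got {self.neigh_frac}")
        if self.catmin > self.catmax:
            raise ValueError(
                f"need catmin <= catmax, got {self.catmin} > {self.catmax}")
        if n_classes is not None and n_classes > self.catmin:
            raise ValueError(
                f"need n_classes <= catmin, got {n_classes} > {self.catmin}")
        if self.crossover_dialect not in ("canonical", "printed"):
            raise ValueError(f"unknown crossover dialect {self.crossover_dialect!r}")


@dataclass
class FitnessRecord:
    """Accuracy, active-category count and guarded objective value of one
    encoded network."""

    pcc: float
    n_active: int
    value: float


@dataclass
class NetworkCodec:
    """Fixed-capacity slot codec between FAM networks and DE vectors.

    Every vector has dimension ``catmax * (2d + 2)``; keeping the dimension
    constant across members is what makes DE's difference arithmetic
    well-defined.  Weight genes are clipped to [0, 1] on decode and label
    genes are rounded to the nearest valid class index.
    """

    n_features: int
    classes: np.ndarray
    catmax: int

    @property
    def slot_size(self) -> int:
        return 2 * self.n_features + 2

    @property
    def dim(self) -> int:
        return self.catmax * self.slot_size

    def encode(self, network: FuzzyARTMAP) -> np.ndarray:
        if network.n_categories_ > self.catmax:
            raise ValueError(
                f"network has {network.n_categories_} categories, exceeding "
                f"the encoding capacity catmax={self.catmax}")
        vec = np.zeros(self.dim)
        slots = vec.reshape(self.catmax, self.slot_size)
        n = network.n_categories_
        slots[:n, :-2] = network.weights_
        slots[:n, -2] = network.category_classes_
        slots[:n, -1] = 1.0
        return vec

    def decode(self, vector: np.ndarray) -> FuzzyARTMAP:
        slots = np.asarray(vector, dtype=np.float64).reshape(
            self.catmax, self.slot_size)
        active = slots[:, -1] >= 0.5
        weights = np.clip(slots[active, :-2], 0.0, 1.0)
        labels = np.clip(np.rint(slots[active, -2]), 0,
                         len(self.classes) - 1).astype(np.intp)
        return FuzzyARTMAP.from_arrays(
            weights.reshape(-1, 2 * self.n_features), labels, self.classes)

    def n_active(self, vector: np.ndarray) -> int:
        slots = np.asarray(vector).reshape(self.catmax, self.slot_size)
        return int(np.count_nonzero(slots[:, -1] >= 0.5))


def encode(network: FuzzyARTMAP, catmax: int) -> tuple[np.ndarray, NetworkCodec]:
    """Encode a trained network; returns (vector, codec)."""
    codec = NetworkCodec(network.n_features_in_, network.classes_, catmax)
    return codec.encode(network), codec


def decode(vector: np.ndarray, codec: NetworkCodec) -> FuzzyARTMAP:
    """Decode a DE vector back into a fitted FAM network."""
    return codec.decode(vector)


# -- mutation --------------------------------------------------------------

_CLASSIC_STRATEGIES = ("rand/1", "best/1", "rand-to-best/1", "rand/2")


def mutate_classic(vectors: np.ndarray, fitness_values: np.ndarray, i: int,
                   strategy: str, F: float, rng) -> np.ndarray:
    """Classic DE mutation strategies.

    rand/1:         V = x_r1 + F (x_r2 - x_r3)
    best/1:         V = x_best + F (x_r1 - x_r2)
    rand-to-best/1: V = x_i + F (x_best - x_i) + F (x_r1 - x_r2)
    rand/2:         V = x_r1 + F (x_r2 - x_r3) + F (x_r4 - x_r5)

    The r-indices are distinct and different from ``i``; ``x_best`` is the
    member with the smallest fitness value.
    """
    if strategy not in _CLASSIC_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; use one of "
                         f"{_CLASSIC_STRATEGIES}")
    n = len(vectors)
    needed = {"rand/1": 3, "best/1": 2, "rand-to-best/1": 2, "rand/2": 5}[strategy]
    if n < needed + 1:
        raise ValueError(
            f"population of {n} too small for {strategy} (needs {needed} "
            "distinct members besides the target)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pool = np.delete(np.arange(n), i)
    r = rng.choice(pool, size=needed, replace=False)
    best = vectors[int(np.argmin(fitness_values))]
    x = vectors
    if strategy == "rand/1":
        return x[r[0]] + F * (x[r[1]] - x[r[2]])
    if strategy == "best/1":
        return best + F * (x[r[0]] - x[r[1]])
    if strategy == "rand-to-best/1":
        return x[i] + F * (best - x[i]) + F * (x[r[0]] - x[r[1]])
    return x[r[0]] + F * (x[r[1]] - x[r[2]]) + F * (x[r[3]] - x[r[4]])


def mutate_neigh_to_best(vectors: np.ndarray, fitness_values: np.ndarray,
                         params: DEParams, rng) -> np.ndarray:
    """Neighbourhood-to-best mutation: donors are drawn from the top-ranked
    fraction of the population, the attractor is the global best.

    ``V = x_r3 + F1 (x_best - x_r3) + F2 (x_r1 - x_r2)`` with r1, r2, r3
    distinct members of the top ``neigh_frac`` pool (pool size >= 3).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    order = np.argsort(fitness_values, kind="stable")
    pool_size = max(int(np.ceil(params.neigh_frac * len(vectors))), 3)
    if len(vectors) < 3:
        raise ValueError(
            f"population of {len(vectors)} too small: the donor pool needs "
            "at least 3 members")
    pool = order[:min(pool_size, len(vectors))]
    r1, r2, r3 = rng.choice(pool, size=3, replace=False)
    best = vectors[order[0]]
    return (vectors[r3] + params.F1 * (best - vectors[r3])
            + params.F2 * (vectors[r1] - vectors[r2]))


def crossover(target: np.ndarray, mutant: np.ndarray, CR: float, rng,
              dialect: str = "canonical") -> np.ndarray:
    """Binomial crossover between a target and a mutant vector.

    Canonical dialect: trial[j] = mutant[j] iff rand_j <= CR or j == jrand
    (jrand uniform, so at least one mutant gene always survives).  The
    'printed' dialect inverts the inequality (rand_j > CR).
    """
    if not 0.0 <= CR <= 1.0:
        raise ValueError(f"CR must lie in [0, 1], got {CR}")
    if target.shape != mutant.shape:
        raise ValueError("target and mutant dimension mismatch")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = target.size
    draws = rng.random(d)
    if dialect == "canonical":
        take = draws <= CR
    elif dialect == "printed":
        take = draws > CR
    else:
        raise ValueError(f"unknown crossover dialect {dialect!r}")
    take[rng.integers(d)] = True
    return np.where(take, mutant, target)


# -- fitness ---------------------------------------------------------------

def fitness_raw(pcc: float, n_active: int, catmin: int, catmax: int) -> float:
    """Unguarded objective exactly as formulated: may change sign and
    diverge as ``n_active`` approaches ``catmax``.  Exposed for inspection
    only; the search uses :func:`fitness`."""
    return (100.0 * catmin - pcc * n_active) / ((catmax - n_active) * pcc ** 2)


def fitness(vector: np.ndarray, codec: NetworkCodec, X_eval, y_eval,
            params: DEParams) -> FitnessRecord:
    """Guarded fitness of an encoded network on an evaluation set.

    value = |100 catmin - pcc Na| / ((catmax - Na) pcc^2)  when
    catmin <= Na < catmax, pcc > 0 and pcc >= params.min_pcc (if set);
    infeasible members receive a large finite penalty graded by the
    violation.  Minimized.

    The accuracy floor matters: without it the quotient has a degenerate
    basin at pcc*Na ~ 100*catmin where near-zero numerators reward
    low-accuracy networks; the floor encodes the actual goal — shrink the
    network *without* giving up accuracy.
    """
    n_active = codec.n_active(vector)
    if n_active == 0:
        return FitnessRecord(0.0, 0, PENALTY + abs(n_active - params.catmin))
    net = codec.decode(vector)
    pcc = net.pcc(X_eval, y_eval)
    feasible = (params.catmin <= n_active < params.catmax and pcc > 0.0
                and (params.min_pcc is None or pcc >= params.min_pcc))
    if not feasible:
        shortfall = max(params.min_pcc - pcc, 0.0) if params.min_pcc else 0.0
        return FitnessRecord(
            pcc, n_active, PENALTY + abs(n_active - params.catmin) + shortfall)
    value = (abs(100.0 * params.catmin - pcc * n_active)
             / ((params.catmax - n_active) * pcc ** 2))
    return FitnessRecord(pcc, n_active, value)


def select(target: np.ndarray, trial: np.ndarray, fit_target: FitnessRecord,
           fit_trial: FitnessRecord) -> tuple[np.ndarray, FitnessRecord]:
    """Pairwise greedy selection: the smaller guarded fitness survives; on a
    tie the target is kept."""
    if fit_trial.value < fit_target.value:
        return trial, fit_trial
    return target, fit_target


# -- evolution loop --------------------------------------------------------

@dataclass
class EvolutionResult:
    """Outcome of :func:`evolve`: the decoded best network and bookkeeping."""

    network: FuzzyARTMAP
    record: FitnessRecord
    trace: list[FitnessRecord] = field(default_factory=list)

    def trace_values(self) -> np.ndarray:
        return np.array([r.value for r in self.trace])


def evolve(networks: list[FuzzyARTMAP], X_eval, y_eval,
           params: DEParams) -> EvolutionResult:
    """Evolve a population of trained FAM networks.

    Each generation: rank by fitness, neighbourhood-to-best mutation,
    binomial crossover, pairwise selection.  Selection is elitist per
    member, so the per-generation best fitness trace is non-increasing.
    ``trace[0]`` is the best initial fitness; with ``generations=0`` the
    best initial network is returned unchanged.

    If ``params.max_stagnation`` generations pass without improvement the
    loop stops early with a logged warning and returns the best so far.
    """
    if len(networks) < 6:
        raise ValueError(
            f"need at least 6 initial networks for DE, got {len(networks)}")
    first = networks[0]
    params.validate(n_classes=len(first.classes_))
    codec = NetworkCodec(first.n_features_in_, first.classes_, params.catmax)
    rng = np.random.default_rng(params.seed)

    if params.min_pcc is None:
        # accuracy-preserving pruning: the evolved network may not fall
        # more than pcc_tolerance below the best initial member
        best_initial = max(net.pcc(X_eval, y_eval) for net in networks)
        params = replace(params, min_pcc=best_initial - params.pcc_tolerance)

    vectors = np.stack([codec.encode(net) for net in networks])
    records = [fitness(v, codec, X_eval, y_eval, params) for v in vectors]
    values = np.array([r.value for r in records])

    trace = [records[int(np.argmin(values))]]
    stagnant = 0
    for _ in range(int(params.generations)):
        for i in range(len(vectors)):
            mutant = mutate_neigh_to_best(vectors, values, params, rng)
            trial = crossover(vectors[i], mutant, params.CR, rng,
                              params.crossover_dialect)
            fit_trial = fitness(trial, codec, X_eval, y_eval, params)
            vectors[i], records[i] = select(vectors[i], trial, records[i], fit_trial)
            values[i] = records[i].value
        best_now = records[int(np.argmin(values))]
        if best_now.value < trace[-1].value:
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_now)
        if params.max_stagnation is not None and stagnant >= params.max_stagnation:
            logger.warning(
                "evolution stagnated for %d generations; returning best so far",
                stagnant)
            break

    best_idx = int(np.argmin(values))
    best_record = records[best_idx]
    if not (params.catmin <= best_record.n_active <= params.catmax):
        raise RuntimeError(
            f"evolution failed to produce a feasible network: best has "
            f"Na={best_record.n_active} outside [{params.catmin}, {params.catmax}]")
    return EvolutionResult(codec.decode(vectors[best_idx]), best_record, trace)


def train_diverse_population(X, y, n_networks: int, rng,
                             rho: float = 1.0, rho_jitter: float = 0.15,
                             **fam_params) -> list[FuzzyARTMAP]:
    """Train an initial DE population of FAM networks with diversity seeded
    the way category proliferation arises in practice: every member sees the
    training data in a different shuffled order and with a jittered
    vigilance ``rho - U(0, rho_jitter)``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nets = []
    for _ in range(n_networks):
        member_rho = max(0.0, rho - rng.uniform(0.0, rho_jitter))
        seed = int(rng.integers(2 ** 31))
        net = FuzzyARTMAP(rho=member_rho, shuffle=True, random_state=seed,
                          **fam_params)
        nets.append(net.fit(X, y))
    return nets


class DEFAMClassifier(ClassifierMixin, BaseEstimator):
    """FAM classifier pruned by differential evolution.

    Trains ``n_networks`` FAM networks under deliberately diverse
    conditions (shuffled presentation orders, jittered vigilance), then
    evolves the population towards the smallest network that preserves
    accuracy.  Fitness is evaluated on a held-out fraction of the training
    data (or on the training data itself when ``validation_fraction=0``).

    Parameters
    ----------
    n_networks : int, default=10
        DE population size (>= 6).
    catmin : int or None, default=None
        Lower category bound; None means "number of classes" (the stated
        optimum).
    catmax : int, default=30
        Slot capacity of the encoding and upper category bound.
    generations, F1, F2, CR, neigh_frac : DE controls, see :class:`DEParams`.
    rho, alpha, beta, epsilon, epochs : base FAM parameters.
    validation_fraction : float, default=0.25
        Fraction of the training data held out for fitness evaluation.
    random_state : int, optional

    Attributes
    ----------
    network_ : FuzzyARTMAP        — the evolved best network.
    result_ : EvolutionResult     — full fitness trace.
    initial_networks_ : list[FuzzyARTMAP]
    """

    def __init__(self, n_networks: int = 10, catmin: int | None = None,
                 catmax: int = 30, generations: int = 30, F1: float = 1.0,
                 F2: float = 1.0, CR: float = 0.7, neigh_frac: float = 0.5,
                 rho: float = 1.0, alpha: float = 0.001, beta: float = 0.8,
                 epsilon: float = 0.001, epochs: int = 5,
                 validation_fraction: float = 0.25, random_state=None):
        self.n_networks = n_networks
        self.catmin = catmin
        self.catmax = catmax
        self.generations = generations
        self.F1 = F1
        self.F2 = F2
        self.CR = CR
        self.neigh_frac = neigh_frac
        self.rho = rho
        self.alpha = alpha
        self.beta = beta
        self.epsilon = epsilon
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        if self.validation_fraction > 0.0:
            idx = rng.permutation(len(X))
            n_val = max(int(round(self.validation_fraction * len(X))), 1)
            val, tr = idx[:n_val], idx[n_val:]
            # keep every class represented on both sides
            if (len(np.unique(y[tr])) < len(np.unique(y))
                    or len(np.unique(y[val])) < len(np.unique(y))):
                tr = val = np.arange(len(X))
        else:
            tr = val = np.arange(len(X))
        self.initial_networks_ = train_diverse_population(
            X[tr], y[tr], self.n_networks, rng, rho=self.rho,
            alpha=self.alpha, beta=self.beta, epsilon=self.epsilon,
            epochs=self.epochs)
        n_classes = len(self.initial_networks_[0].classes_)
        params = DEParams(
            F1=self.F1, F2=self.F2, CR=self.CR, generations=self.generations,
            neigh_frac=self.neigh_frac,
            catmin=self.catmin if self.catmin is not None else n_classes,
            catmax=self.catmax, seed=int(rng.integers(2 ** 31)))
        max_cat = max(net.n_categories_ for net in self.initial_networks_)
        if max_cat > params.catmax:
            raise ValueError(
                f"initial networks reach {max_cat} categories, above "
                f"catmax={params.catmax}; raise catmax or lower rho")
        self.result_ = evolve(self.initial_networks_, X[val], y[val], params)
        self.network_ = self.result_.network
        self.classes_ = self.network_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.network_.predict(X)

    @property
    def n_categories_(self) -> int:
        check_is_fitted(self)
        return self.network_.n_categories_
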