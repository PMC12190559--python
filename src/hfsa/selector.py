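"""Accurate wrapper stage: hybrid binary GA / Tiki-Taka search over feature masks.

One search cycle runs a genetic-algorithm generation (roulette selection,
one-point crossover, single-bit-flip mutation, elitism of one) followed by a
Tiki-Taka generation: every player's ball moves relative to the cyclic
neighbour's ball, the player then moves toward its ball and the key (best)
player, and the continuous position is binarized through a sigmoid transfer
to yield the player's new mask.  The GA output population is the Tiki-Taka
input and vice versa.  Single-route ablations (``ga_only``, ``tta_only``) and
an exhaustive enumeration oracle are provided for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .chi2_filter import ChiScores, run_fast_stage
from .dataset import DatasetError, FeatureMask, SymptomDataset

METHODS = ("hfsa", "ga_only", "tta_only")
TRANSFER_RULES = ("as_printed", "conventional")


@dataclass
class HOAConfig:
    """Search parameters for the hybrid wrapper stage."""

    pop_size: int = 30
    p_sel: float = 0.8
    p_cross: float = 0.9
    p_mut: float = 0.01
    c1: float = 1.2       # ball reflection magnitude on an unsuccessful pass
    c2: float = 2.5       # pull toward the player's own ball
    c3: float = 1.0       # pull toward the key player
    epsilon: float = 0.2  # probability of losing the ball
    max_it: int = 200
    patience: int = 30
    transfer_rule: str = "as_printed"
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_sel", "p_cross", "p_mut"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.5 <= self.c1 <= 1.5:
            raise ValueError("c1 must lie in [0.5, 1.5]")
        if not 1.0 <= self.c2 <= 2.5:
            raise ValueError("c2 must lie in [1, 2.5]")
        if not 0.5 <= self.c3 <= 1.5:
            raise ValueError("c3 must lie in [0.5, 1.5]")
        if not 0.1 <= self.epsilon <= 0.3:
            raise ValueError("epsilon must lie in [0.1, 0.3]")
        if self.max_it < 1 or self.pop_size < 2:
            raise ValueError("max_it must be >= 1 and pop_size >= 2")
        if self.transfer_rule not in TRANSFER_RULES:
            raise ValueError(f"transfer_rule must be one of {TRANSFER_RULES}")


@dataclass
class Player:
    """A candidate mask plus the continuous state used by the Tiki-Taka moves."""

    mask: FeatureMask
    position: np.ndarray
    ball: np.ndarray
    fitness: float = 0.0

    @classmethod
    def from_mask(cls, mask: FeatureMask, fitness: float = 0.0) -> "Player":
        pos = mask.bits.astype(np.float64)
        return cls(mask=mask, position=pos, ball=pos.copy(), fitness=fitness)


@dataclass
class SelectionResult:
    best_mask: FeatureMask          # over the v filtered features
    best_fitness: float
    kept_original_indices: list[int]  # final m predictors, original column ids
    history: list[float] = field(default_factory=list)
    chi_scores: ChiScores | None = None
    method: str = "hfsa"

    @property
    def m(self) -> int:
        return self.best_mask.popcount


def init_population(c: int, v: int, seed=None, rng=None) -> list[Player]:
    """Bernoulli(0.5) masks, all-zero resampled; positions seeded from the bits."""
    if c < 2 or v < 1:
        raise ValueError("need c >= 2 players and v >= 1 features")
    if rng is None:
        rng = np.random.default_rng(seed)
    players = []
    for _ in range(c):
        bits = (rng.random(v) < 0.5).astype(np.int8)
        while bits.sum() == 0:
            bits = (rng.random(v) < 0.5).astype(np.int8)
        players.append(Player.from_mask(FeatureMask(bits)))
    return players


def roulette_select(
    pop: list[Player], rng, p_sel: float = 1.0
) -> tuple[Player, Player]:
    """Two parents by fitness-proportional draws, gated by p_sel.

    With probability 1 - p_sel the pair is drawn uniformly instead.  When all
    fitness values are zero the roulette degenerates to uniform as well.
    """
    n = len(pop)
    fitness = np.array([max(p.fitness, 0.0) for p in pop])
    total = fitness.sum()
    if rng.random() >= p_sel or total <= 0.0:
        i, j = rng.integers(n), rng.integers(n)
    else:
        probs = fitness / total
        i = rng.choice(n, p=probs)
        j = rng.choice(n, p=probs)
    return pop[int(i)], pop[int(j)]


def one_point_crossover(
    a: FeatureMask, b: FeatureMask, p_cross: float, rng
) -> tuple[FeatureMask, FeatureMask]:
    """Swap suffixes after a uniform cut point, gated by p_cross."""
    if len(a) != len(b):
        raise DatasetError("crossover parents must have equal length")
    v = len(a)
    if v < 2 or rng.random() >= p_cross:
        return FeatureMask(a.bits.copy()), FeatureMask(b.bits.copy())
    cut = int(rng.integers(1, v))  # cut in [1, v-1]
    child_a = np.concatenate([a.bits[:cut], b.bits[cut:]])
    child_b = np.concatenate([b.bits[:cut], a.bits[cut:]])
    return FeatureMask(child_a), FeatureMask(child_b)


def bit_flip_mutation(mask: FeatureMask, p_mut: float, rng) -> FeatureMask:
    """With probability p_mut flip one uniformly chosen bit; repair all-zero."""
    bits = mask.bits.copy()
    if rng.random() < p_mut:
        pos = int(rng.integers(bits.size))
        bits[pos] ^= 1
    if bits.sum() == 0:
        bits[int(rng.integers(bits.size))] = 1
    return FeatureMask(bits)


def _apply_elitism(offspring: list[Player], incumbent: Player) -> list[Player]:
    """Keep the incumbent best alive: replace the worst offspring if absent."""
    best_key = incumbent.mask.key()
    if any(p.mask.key() == best_key for p in offspring):
        return offspring
    worst = min(range(len(offspring)), key=lambda i: offspring[i].fitness)
    offspring[worst] = replace(
        incumbent,
        mask=FeatureMask(incumbent.mask.bits.copy()),
        position=incumbent.position.copy(),
        ball=incumbent.ball.copy(),
    )
    return offspring


def ga_generation(
    pop: list[Player], config: HOAConfig, fitness_fn, rng
) -> list[Player]:
    """One select -> crossover -> mutate sweep producing a same-size population."""
    c = len(pop)
    incumbent = max(pop, key=lambda p: p.fitness)
    offspring: list[Player] = []
    while len(offspring) < c:
        pa, pb = roulette_select(pop, rng, p_sel=config.p_sel)
        child_a, child_b = one_point_crossover(pa.mask, pb.mask, config.p_cross, rng)
        for child in (child_a, child_b):
            if len(offspring) >= c:
                break
            mutated = bit_flip_mutation(child, config.p_mut, rng)
            offspring.append(Player.from_mask(mutated, fitness=fitness_fn(mutated)))
    return _apply_elitism(offspring, incumbent)


def sigmoid(x):
    return expit(np.asarray(x, dtype=np.float64))


def update_ball(ball_i: np.ndarray, ball_next: np.ndarray, config: HOAConfig, rng):
    """Move a ball relative to the neighbour's ball.

    One pass-success draw per ball; one step-size draw per dimension.  On a
    successful pass the ball moves away from the neighbour by a random
    multiple of their separation; on an unsuccessful pass it is reflected
    toward (and past) the neighbour with magnitude c1 + r.
    """
    ball_i = np.asarray(ball_i, dtype=np.float64)
    ball_next = np.asarray(ball_next, dtype=np.float64)
    if ball_i.shape != ball_next.shape:
        raise DatasetError("ball vectors must have equal length")
    rand_p = rng.random()
    r = 1.0 - rng.random(ball_i.shape)  # uniform in (0, 1]
    diff = ball_i - ball_next
    if rand_p > config.epsilon:  # successful pass
        return r * diff + ball_i
    return ball_i - (config.c1 + r) * diff


def update_player(
    pl: np.ndarray, ball: np.ndarray, q: np.ndarray, config: HOAConfig, rng
):
    """Move a player toward its ball and the key player."""
    pl = np.asarray(pl, dtype=np.float64)
    ball = np.asarray(ball, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if not (pl.shape == ball.shape == q.shape):
        raise DatasetError("player, ball and key-player vectors must match")
    r = 1.0 - rng.random(pl.shape)  # uniform in (0, 1]
    return pl + r * config.c2 * (ball - pl) + r * config.c3 * (q - pl)


def binarize(values: np.ndarray, rule: str, rng) -> FeatureMask:
    """Sample a mask from continuous values through the sigmoid transfer.

    ``as_printed`` sets a bit when the uniform draw is >= sigmoid(value);
    ``conventional`` when the draw is < sigmoid(value).  An all-zero outcome
    is repaired by switching one uniformly chosen bit on.
    """
    if rule not in TRANSFER_RULES:
        raise ValueError(f"unknown transfer rule {rule!r}")
    values = np.asarray(values, dtype=np.float64)
    draws = rng.random(values.shape)
    sig = sigmoid(values)
    bits = (draws >= sig) if rule == "as_printed" else (draws < sig)
    bits = bits.astype(np.int8)
    if bits.sum() == 0:
        bits[int(rng.integers(bits.size))] = 1
    return FeatureMask(bits)


def tta_generation(
    pop: list[Player], config: HOAConfig, fitness_fn, rng
) -> list[Player]:
    """One Tiki-Taka sweep: pass balls around the ring, chase, binarize."""
    incumbent = max(pop, key=lambda p: p.fitness)
    q = incumbent.position.copy()
    c = len(pop)
    old_balls = [p.ball for p in pop]
    new_pop: list[Player] = []
    for i, player in enumerate(pop):
        neighbour_ball = old_balls[(i + 1) % c]  # ring wraps: last passes to first
        new_ball = update_ball(player.ball, neighbour_ball, config, rng)
        new_position = update_player(player.position, new_ball, q, config, rng)
        new_mask = binarize(new_position, config.transfer_rule, rng)
        new_pop.append(
            Player(
                mask=new_mask,
                position=new_position,
                ball=new_ball,
                fitness=fitness_fn(new_mask),
            )
        )
    return _apply_elitism(new_pop, incumbent)


def _better(fitness: float, mask: FeatureMask, best_fitness, best_mask) -> bool:
    """Strictly fitter, or equally fit with fewer features, or lexicographically
    smaller at equal size (gives deterministic, parsimony-leaning ties)."""
    if best_mask is None or fitness > best_fitness + 1e-12:
        return True
    if fitness < best_fitness - 1e-12:
        return False
    if mask.popcount != best_mask.popcount:
        return mask.popcount < best_mask.popcount
    return mask.bits.tobytes() < best_mask.bits.tobytes()


def run_search(
    v: int, config: HOAConfig, fitness_fn, method: str = "hfsa"
) -> tuple[FeatureMask, float, list[float]]:
    """Drive the cycle loop for any of the three methods over v-bit masks."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    config.validate()
    rng = np.random.default_rng(config.seed)
    pop = init_population(config.pop_size, v, rng=rng)
    for player in pop:
        player.fitness = fitness_fn(player.mask)

    best_mask: FeatureMask | None = None
    best_fitness = -np.inf
    history: list[float] = []
    stale = 0
    for _ in range(config.max_it):
        if method in ("hfsa", "ga_only"):
            pop = ga_generation(pop, config, fitness_fn, rng)
        if method in ("hfsa", "tta_only"):
            # GA output feeds the Tiki-Taka input; positions re-seeded from bits
            if method == "hfsa":
                pop = [Player.from_mask(p.mask, p.fitness) for p in pop]
            pop = tta_generation(pop, config, fitness_fn, rng)
        improved = False
        for player in pop:
            if _better(player.fitness, player.mask, best_fitness, best_mask):
                if player.fitness > best_fitness + 1e-12:
                    improved = True
                best_fitness = player.fitness
                best_mask = FeatureMask(player.mask.bits.copy())
        history.append(best_fitness)
        stale = 0 if improved else stale + 1
        if stale >= config.patience:
            break
    assert best_mask is not None
    return best_mask, float(best_fitness), history


def select_features(
    train: SymptomDataset,
    method: str = "hfsa",
    v=None,
    config: HOAConfig | None = None,
    fitness_factory=None,
) -> SelectionResult:
    """Fast chi-square stage to v features, then the wrapper search.

    ``fitness_factory(reduced_train) -> callable(mask) -> float`` defaults to
    a cached cross-validated naive-Bayes accuracy evaluator.
    """
    config = config or HOAConfig()
    reduced, chi_scores = run_fast_stage(train, v)
    if fitness_factory is None:
        from .naive_bayes import FitnessEvaluator

        fitness_factory = lambda ds: FitnessEvaluator(ds, seed=config.seed)
    fitness_fn = fitness_factory(reduced)
    best_mask, best_fitness, history = run_search(
        reduced.n_features, config, fitness_fn, method=method
    )
    survivors = np.sort(chi_scores.kept_indices)  # reduced columns, original order
    kept_original = [int(survivors[i]) for i in best_mask.indices()]
    return SelectionResult(
        best_mask=best_mask,
        best_fitness=best_fitness,
        kept_original_indices=kept_original,
        history=history,
        chi_scores=chi_scores,
        method=method,
    )


def exhaustive_oracle(
    n_features: int, fitness_fn
) -> tuple[FeatureMask, float]:
    """Enumerate every nonempty mask and return the argmax.

    Ties go to the smaller popcount, then the lexicographically smaller bit
    string.  Only feasible for n_features <= 12.
    """
    if n_features > 12:
        raise ValueError("exhaustive enumeration limited to 12 features")
    best_mask: FeatureMask | None = None
    best_fitness = -np.inf
    for code in range(1, 2**n_features):
        bits = np.array(
            [(code >> i) & 1 for i in range(n_features)], dtype=np.int8
        )
        mask = FeatureMask(bits)
        fitness = fitness_fn(mask)
        if _better(fitness, mask, best_fitness, best_mask):
            best_fitness = fitness
            best_mask = mask
    assert best_mask is not None
    return best_mask, float(best_fitness)
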