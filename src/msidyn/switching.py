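"""Stochastic birth-death tumor growth with mutation-rate switching.

The model tracks a growing tumor in discrete synchronous generations (one
step = one round of cell doubling). Each cell carries a mutation-rate regime
(basal hypermutator, mu_basal mutations/division, or ultra-hypermutator,
mu_high), a neoantigen burden, permanent immune-escape and lethal-mutation
flags, and an integer microsatellite allele (0 = in-frame, +-k = net
insertions/deletions at a single tracked MS locus).

Per step, every cell dies with probability 1 - (1 - d0) * fitness (survival
proportional to fitness, with d0 the baseline death probability of a fully
fit cell); survivors divide into two daughters. Each daughter may toggle its
regime with probability beta, then draws K ~ Poisson(mu of its regime) new
mutations. Each mutation is independently antigenic (P_antigen), immune
escape (P_escape), lethal (P_lethal) and MS-hitting (P_ms) — the classes are
non-exclusive. An MS hit moves the tracked allele one step up or down with
equal probability.

Fitness is 0 for lethal cells; 1 for escaped or antigen-free cells; 1 + s
otherwise (s in [-1, 0] is the immune selection coefficient, applied once
regardless of antigen count). A tumor starts from n0 identical founders and
runs until elimination (no cells) or detection (population >= n_detect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import entropy

__all__ = [
    "SimParams",
    "Population",
    "Trajectory",
    "TumorOutcome",
    "step_population",
    "simulate_tumor",
    "ms_shannon",
    "growth_time",
    "diversity_experiment",
    "growth_time_experiment",
    "elimination_experiment",
]


@dataclass(frozen=True)
class SimParams:
    mu_basal: float = 6.0
    mu_high: float = 120.0
    beta: float = 0.0
    p_antigen: float = 0.1
    p_escape: float = 1e-6
    p_lethal: float = 5e-4
    p_ms: float = 1e-3
    s: float = -0.8
    n0: int = 100
    n_detect: int = 100_000
    d0: float = 0.02
    founder_regime: str = "basal"  # or "high"
    max_steps: int = 10_000

    def validate(self) -> None:
        for name in ("beta", "p_antigen", "p_escape", "p_lethal", "p_ms", "d0"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (-1.0 <= self.s <= 0.0):
            raise ValueError("s must be in [-1, 0]")
        if self.mu_basal < 0 or self.mu_high < 0:
            raise ValueError("mutation rates must be non-negative")
        if not (0 < self.n0 <= self.n_detect):
            raise ValueError("need 0 < n0 <= n_detect")
        if self.founder_regime not in ("basal", "high"):
            raise ValueError("founder_regime must be 'basal' or 'high'")


@dataclass
class Population:
    """Structure-of-arrays cell state; one entry per live cell."""

    high: np.ndarray  # bool: ultra-hypermutator regime
    n_antigens: np.ndarray  # int32
    escaped: np.ndarray  # bool
    lethal: np.ndarray  # bool
    ms_state: np.ndarray  # int32

    @classmethod
    def founders(cls, params: SimParams) -> "Population":
        n = params.n0
        return cls(
            high=np.full(n, params.founder_regime == "high"),
            n_antigens=np.zeros(n, dtype=np.int32),
            escaped=np.zeros(n, dtype=bool),
            lethal=np.zeros(n, dtype=bool),
            ms_state=np.zeros(n, dtype=np.int32),
        )

    def __len__(self) -> int:
        return len(self.high)

    def fitness(self, s: float) -> np.ndarray:
        f = np.ones(len(self))
        antigenic = (self.n_antigens > 0) & ~self.escaped
        f[antigenic] = 1.0 + s
        f[self.lethal] = 0.0
        return f


@dataclass
class Trajectory:
    total: list[int] = field(default_factory=list)
    escaped: list[int] = field(default_factory=list)
    high_fraction: list[float] = field(default_factory=list)

    def record(self, pop: Population) -> None:
        n = len(pop)
        self.total.append(n)
        self.escaped.append(int(pop.escaped.sum()))
        self.high_fraction.append(float(pop.high.mean()) if n else 0.0)


@dataclass
class TumorOutcome:
    status: str  # eliminated | detected | censored
    t_final: int
    growth_time: int | None
    ms_shannon: float | None
    high_fraction_final: float | None
    n_final: int


def step_population(pop: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """One synchronous generation: death, division, switching, mutation."""
    n = len(pop)
    if n == 0:
        return pop
    fitness = pop.fitness(params.s)
    p_death = np.clip(1.0 - (1.0 - params.d0) * fitness, 0.0, 1.0)
    survive = rng.random(n) >= p_death
    if not survive.any():
        return Population(*[np.empty(0, dtype=a.dtype) for a in
                            (pop.high, pop.n_antigens, pop.escaped, pop.lethal, pop.ms_state)])

    # two daughters per survivor
    high = np.repeat(pop.high[survive], 2)
    n_ant = np.repeat(pop.n_antigens[survive], 2)
    escaped = np.repeat(pop.escaped[survive], 2)
    lethal = np.repeat(pop.lethal[survive], 2)
    ms = np.repeat(pop.ms_state[survive], 2)
    m = len(high)

    # regime toggle first: the daughter's replication fidelity is set by its
    # own (possibly switched) MMR state
    if params.beta > 0:
        toggle = rng.random(m) < params.beta
        high = np.where(toggle, ~high, high)

    mu = np.where(high, params.mu_high, params.mu_basal)
    k = rng.poisson(mu)

    n_ant = n_ant + rng.binomial(k, params.p_antigen).astype(np.int32)
    escaped = escaped | (rng.binomial(k, params.p_escape) > 0)
    lethal = lethal | (rng.binomial(k, params.p_lethal) > 0)
    hits = rng.binomial(k, params.p_ms)
    up = rng.binomial(hits, 0.5)
    ms = ms + (2 * up - hits).astype(np.int32)

    return Population(high=high, n_antigens=n_ant, escaped=escaped, lethal=lethal,
                      ms_state=ms)


def simulate_tumor(
    params: SimParams, seed: int | np.random.SeedSequence = 0
) -> tuple[TumorOutcome, Trajectory]:
    """Run one tumor from n0 founders to elimination or detection.

    Deterministic given the seed. Runs exceeding ``max_steps`` return a
    censored outcome.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    pop = Population.founders(params)
    traj = Trajectory()
    traj.record(pop)
    t = 0
    status = "censored"
    while t < params.max_steps:
        if len(pop) == 0:
            status = "eliminated"
            break
        if len(pop) >= params.n_detect:
            status = "detected"
            break
        pop = step_population(pop, params, rng)
        t += 1
        traj.record(pop)
    else:
        # loop ran out: classify the final state if it terminated exactly here
        if len(pop) == 0:
            status = "eliminated"
        elif len(pop) >= params.n_detect:
            status = "detected"

    gt = growth_time(traj) if status == "detected" else None
    outcome = TumorOutcome(
        status=status,
        t_final=t,
        growth_time=gt,
        ms_shannon=ms_shannon(pop) if len(pop) else None,
        high_fraction_final=float(pop.high.mean()) if len(pop) else None,
        n_final=len(pop),
    )
    return outcome, traj


def ms_shannon(pop: Population) -> float:
    """Shannon index (natural log) of the MS-allele distribution."""
    if len(pop) == 0:
        raise ValueError("Shannon diversity undefined for an empty population")
    _, counts = np.unique(pop.ms_state, return_counts=True)
    return float(entropy(counts))


def growth_time(traj: Trajectory, threshold: int = 20, use_total: bool = False) -> int:
    """Generations between immune-escape establishment and detection.

    Growth start is the last time point at which the (immune-escaped, or
    total with ``use_total``) cell count was below ``threshold``; growth time
    is t_final minus that. Defined only for detected trajectories.
    """
    series = np.array(traj.total if use_total else traj.escaped)
    t_final = len(series) - 1
    below = np.nonzero(series < threshold)[0]
    start = int(below[-1]) if len(below) else 0
    return t_final - start


# --------------------------------------------------------------------------
# Experiment drivers. Replicates draw independent streams from a spawning
# SeedSequence so sweeps are reproducible and order-independent.


def _spawn(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def diversity_experiment(
    base: SimParams,
    founder_regimes: tuple[str, ...] = ("basal", "high"),
    betas: tuple[float, ...] = (0.0,),
    n_detected: int = 50,
    seed: int = 0,
    max_attempts: int = 500_000,
) -> dict[tuple[str, float], list[float]]:
    """MS Shannon diversity of detected tumors per (founder regime, beta) arm."""
    arms = [(fr, b) for fr in founder_regimes for b in betas]
    streams = _spawn(seed, len(arms))
    out: dict[tuple[str, float], list[float]] = {}
    for (fr, b), ss in zip(arms, streams):
        params = replace(base, founder_regime=fr, beta=b)
        vals: list[float] = []
        attempts = 0
        while len(vals) < n_detected and attempts < max_attempts:
            outcome, _ = simulate_tumor(params, ss.spawn(1)[0])
            attempts += 1
            if outcome.status == "detected":
                vals.append(outcome.ms_shannon)
        out[(fr, b)] = vals
    return out


def growth_time_experiment(
    base: SimParams,
    betas: tuple[float, ...] = (0.0, 0.02),
    n_detected: int = 100,
    seed: int = 0,
    max_attempts: int = 500_000,
) -> dict[float, list[int]]:
    """Growth times of detected tumors per switching rate."""
    streams = _spawn(seed, len(betas))
    out: dict[float, list[int]] = {}
    for b, ss in zip(betas, streams):
        params = replace(base, beta=b)
        times: list[int] = []
        attempts = 0
        while len(times) < n_detected and attempts < max_attempts:
            outcome, _ = simulate_tumor(params, ss.spawn(1)[0])
            attempts += 1
            if outcome.status == "detected":
                times.append(outcome.growth_time)
        out[b] = times
    return out


def elimination_experiment(
    base: SimParams,
    s_grid: tuple[float, ...] = (0.0, -0.3, -0.6, -0.8),
    betas: tuple[float, ...] = (0.0, 0.02),
    n_surviving: int = 10,
    n_replicates: int = 50,
    seed: int = 0,
    max_attempts: int = 200_000,
) -> dict[tuple[float, float], list[float]]:
    """Eliminated lineages per ten surviving, per (s, beta), one value per
    replicate batch (each batch simulates lineages until ``n_surviving``
    reach detection and scales the eliminated count to per-ten-surviving)."""
    arms = [(s, b) for s in s_grid for b in betas]
    streams = _spawn(seed, len(arms))
    out: dict[tuple[float, float], list[float]] = {}
    for (s, b), ss in zip(arms, streams):
        params = replace(base, s=s, beta=b)
        batches: list[float] = []
        attempts = 0
        for _ in range(n_replicates):
            detected = 0
            eliminated = 0
            while detected < n_surviving and attempts < max_attempts:
                outcome, _ = simulate_tumor(params, ss.spawn(1)[0])
                attempts += 1
                if outcome.status == "detected":
                    detected += 1
                elif outcome.status == "eliminated":
                    eliminated += 1
            if detected == 0:
                break
            batches.append(eliminated * 10.0 / detected)
        out[(s, b)] = batches
    return out
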