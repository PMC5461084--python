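"""Simulated-annealing search for the SVDD hyperparameters (C, s).

Each candidate (C, s) is scored by fitting the SVDD on the target-only
training set and measuring the validation error

    Error = #wrong / (#correct + #wrong)

where #correct counts validation targets accepted by the sphere and #wrong
counts validation targets rejected plus validation outliers accepted;
correctly rejected outliers do not enter the criterion, so the error focuses
on the target class. Moves are Metropolis-accepted: an improvement is always
taken, a worsening move with probability exp(-dE / (kb*T)), and the
temperature follows the geometric schedule T <- rho*T. Search space is the
closed box [0.01, 1] x [0.01, 20] for (C, s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampling import SampleSet
from .svdd import SVDDModel, decision_distances, fit_svdd

__all__ = [
    "SAConfig",
    "SATrace",
    "evaluate_error",
    "propose_move",
    "accept",
    "cool",
    "optimize",
]


@dataclass
class SAConfig:
    """Annealing schedule and proposal parameters.

    ``T0=None`` triggers automatic calibration: the initial temperature is
    set from warm-up probes of the error surface so that a typical
    worsening move would initially be accepted with probability
    ``initial_acceptance``.
    """

    bounds_C: tuple[float, float] = (0.01, 1.0)
    bounds_s: tuple[float, float] = (0.01, 20.0)
    rho: float = 0.9
    T0: float | None = None
    kb: float = 1.0
    iters_per_temperature: int = 10
    min_temp_ratio: float = 1e-3
    stall_limit: int = 200
    max_evaluations: int | None = None
    proposal_scale: float = 0.1
    warmup_probes: int = 20
    initial_acceptance: float = 0.8
    reanneal_from_best: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError("cooling coefficient rho must be in (0, 1)")
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError("T0 must be > 0")
        if self.kb <= 0:
            raise ValueError("kb must be > 0")
        for lo, hi in (self.bounds_C, self.bounds_s):
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < lo < hi")


@dataclass
class SATrace:
    """Evaluation-by-evaluation history of one annealing run."""

    iterations: list = field(default_factory=list)  # dict records
    best: tuple[float, float, float] | None = None  # (C, s, E)
    evaluations: int = 0
    T0: float = float("nan")

    def record(self, C, s, E, T, accepted) -> None:
        self.evaluations += 1
        if self.best is None or E < self.best[2]:
            self.best = (C, s, E)
        self.iterations.append(
            {
                "iteration": len(self.iterations),
                "C": C,
                "s": s,
                "error": E,
                "temperature": T,
                "accepted": accepted,
                "best_error": self.best[2],
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def evaluate_error(model: SVDDModel, validation: SampleSet) -> float:
    """Validation error in [0, 1]; correct outlier rejections are excluded.

    Requires a non-empty validation set with at least one target sample
    (the denominator is then always positive).
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    is_target = validation.is_target
    if not is_target.any():
        raise ValueError("validation set contains no target samples")
    accepted = decision_distances(model, validation.spectra) <= model.R2
    n_correct = int(np.sum(is_target & accepted))
    n_wrong = int(np.sum(is_target & ~accepted)) + int(np.sum(~is_target & accepted))
    return n_wrong / (n_correct + n_wrong)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real number into [lo, hi] by reflection at the walls."""
    span = hi - lo
    y = (x - lo) % (2.0 * span)
    return lo + (y if y <= span else 2.0 * span - y)


def propose_move(
    current: tuple[float, float], T: float, config: SAConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Gaussian perturbation of (C, s), reflected into the search box.

    The step scale is ``proposal_scale * log-range * (T / T0)``, so
    proposals localize as the system cools. Both coordinates are perturbed
    on a log scale: each spans multiple decades (two for C, three for s),
    and the error surface varies on a relative, not absolute, scale.
    """
    ratio = T / config.T0 if config.T0 else 1.0
    out = []
    for value, (lo, hi) in zip(current, (config.bounds_C, config.bounds_s)):
        llo, lhi = math.log(lo), math.log(hi)
        step = rng.normal(0.0, config.proposal_scale * (lhi - llo) * ratio)
        out.append(math.exp(_reflect(math.log(value) + step, llo, lhi)))
    return tuple(out)


def accept(
    E_new: float, E_old: float, T: float, kb: float, rng: np.random.Generator
) -> bool:
    """Metropolis rule: always accept improvements, otherwise accept with
    the Boltzmann probability exp(-(E_new - E_old) / (kb*T))."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if E_new <= E_old:
        return True
    return rng.uniform() < math.exp(-(E_new - E_old) / (kb * T))


def cool(T: float, rho: float) -> float:
    """Geometric cooling: next temperature = rho * T."""
    if T <= 0 or not (0 < rho < 1):
        raise ValueError("require T > 0 and 0 < rho < 1")
    return T * rho


def optimize(
    training: SampleSet,
    validation: SampleSet,
    config: SAConfig | None = None,
    **fit_kwargs,
) -> tuple[float, float, SATrace]:
    """Anneal (C, s) to minimize the validation error.

    Runs ``iters_per_temperature`` Metropolis steps per temperature level,
    cooling geometrically until the temperature falls below
    ``min_temp_ratio * T0``, the incumbent stalls for ``stall_limit``
    evaluations, or ``max_evaluations`` is reached. Returns the incumbent
    best (C, s) and the full trace; identical seed and inputs reproduce the
    trace exactly. Candidates with C < 1/n (dual infeasible) are rejected
    and resampled.
    """
    config = config or SAConfig()
    rng = np.random.default_rng(config.seed)
    n = len(training)
    c_feasible = 1.0 / n

    def score(C: float, s: float) -> float:
        model = fit_svdd(training, C, s, **fit_kwargs)
        return evaluate_error(model, validation)

    def draw_state() -> tuple[float, float]:
        # log-uniform over the box, matching the log-scale proposal geometry
        while True:
            C = math.exp(rng.uniform(*map(math.log, config.bounds_C)))
            s = math.exp(rng.uniform(*map(math.log, config.bounds_s)))
            if C >= c_feasible:
                return C, s

    trace = SATrace()
    # warm-up probes: calibrate T0 from the error surface and remember the
    # best probe as the anneal's starting state
    probes = [draw_state() for _ in range(max(config.warmup_probes, 1))]
    probe_E = [score(*st) for st in probes]
    if config.T0 is None:
        deltas = [b - a for a, b in zip(probe_E[:-1], probe_E[1:]) if b > a]
        if deltas:
            T0 = float(np.mean(deltas)) / (
                config.kb * math.log(1.0 / config.initial_acceptance)
            )
        else:
            T0 = 1.0  # flat surface seen: any scale works
        config = SAConfig(**{**config.__dict__, "T0": T0})
    trace.T0 = config.T0

    cur = probes[int(np.argmin(probe_E))]
    cur_E = min(probe_E)
    T = config.T0
    trace.record(cur[0], cur[1], cur_E, T, True)
    stall = 0

    def done() -> bool:
        if config.max_evaluations is not None and trace.evaluations >= config.max_evaluations:
            return True
        return stall >= config.stall_limit

    while not done() and T >= config.min_temp_ratio * config.T0:
        for _ in range(config.iters_per_temperature):
            cand = propose_move(cur, T, config, rng)
            if cand[0] < c_feasible:  # infeasible dual: resample
                continue
            E = score(*cand)
            prev_best = trace.best[2]
            ok = accept(E, cur_E, T, config.kb, rng)
            trace.record(cand[0], cand[1], E, T, ok)
            if ok:
                cur, cur_E = cand, E
            stall = 0 if trace.best[2] < prev_best else stall + 1
            if done():
                break
        T = cool(T, config.rho)
        if config.reanneal_from_best:
            cur, cur_E = (trace.best[0], trace.best[1]), trace.best[2]

    best_C, best_s, _ = trace.best
    return best_C, best_s, trace
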