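"""Gaussian-process / Expected-Improvement search over CNN training hyperparameters.

The objective is the validation loss of a CNN trained with a candidate
(learning rate, momentum, L2 coefficient, part depth).  Observations are
treated as noisy; a zero-mean-shifted GP with a squared-exponential kernel
is fit exactly on the normalized search cube, and the next trial maximizes
the closed-form Expected Improvement for minimization over a quasi-random
candidate set (gradients are useless here: one dimension is an integer).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import norm, qmc

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperparamPoint:
    """One point the optimizer moves: SGD settings plus the network depth."""

    lr: float
    momentum: float
    l2: float
    part_depth: int = 1

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    scale: str = "linear"   # 'linear' | 'log'
    integer: bool = False

    def to_unit(self, value: float) -> float:
        if self.scale == "log":
            lo, hi = np.log(self.low), np.log(self.high)
            return (np.log(value) - lo) / (hi - lo)
        return (value - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        u = float(np.clip(u, 0.0, 1.0))
        if self.scale == "log":
            lo, hi = np.log(self.low), np.log(self.high)
            v = float(np.exp(lo + u * (hi - lo)))
        else:
            v = self.low + u * (self.high - self.low)
        if self.integer:
            v = float(np.clip(round(v), self.low, self.high))
        return v


@dataclass
class SearchSpace:
    """Bounded, possibly log-scaled box; maps to/from the unit hypercube."""

    dimensions: tuple[Dimension, ...]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    @property
    def n_dims(self) -> int:
        return len(self.dimensions)

    def to_unit(self, point: dict) -> np.ndarray:
        return np.array([d.to_unit(point[d.name]) for d in self.dimensions])

    def from_unit(self, u: np.ndarray) -> dict:
        return {d.name: d.from_unit(ui) for d, ui in zip(self.dimensions, u)}

    def snap(self, u: np.ndarray) -> np.ndarray:
        """Round integer dimensions to their feasible grid, in unit coordinates."""
        return self.to_unit(self.from_unit(u))

    def point(self, u: np.ndarray) -> HyperparamPoint:
        d = self.from_unit(u)
        return HyperparamPoint(
            lr=d.get("lr", 0.0), momentum=d.get("momentum", 0.0),
            l2=d.get("l2", 0.0), part_depth=int(d.get("part_depth", 1)),
        )


def default_space(depth_range: tuple[int, int] = (1, 7)) -> SearchSpace:
    """Bounds enveloping the published trial values."""
    return SearchSpace((
        Dimension("lr", 1e-3, 1e-2, scale="log"),
        Dimension("momentum", 0.6, 0.99),
        Dimension("l2", 1e-10, 1e-3, scale="log"),
        Dimension("part_depth", depth_range[0], depth_range[1], integer=True),
    ))


@dataclass
class Trial:
    point: dict
    y: float
    seed: int
    wall_time: float
    status: str = "ok"     # 'ok' | 'failed'


@dataclass
class TrialLedger:
    """Ordered record of (hyperparameters, observed validation loss) pairs."""

    trials: list[Trial] = field(default_factory=list)

    def add(self, trial: Trial) -> None:
        self.trials.append(trial)

    def ok_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.status == "ok"]

    @property
    def f_best(self) -> float:
        ok = self.ok_trials()
        if not ok:
            raise ValueError("ledger holds no successful trials")
        return min(t.y for t in ok)

    @property
    def best_trial(self) -> Trial:
        return min(self.ok_trials(), key=lambda t: t.y)

    def best_trajectory(self) -> list[float]:
        best, out = np.inf, []
        for t in self.trials:
            if t.status == "ok":
                best = min(best, t.y)
            out.append(best)
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([asdict(t) for t in self.trials], indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrialLedger":
        data = json.loads(Path(path).read_text())
        return cls([Trial(**t) for t in data])


class NotFittedError(RuntimeError):
    pass


@dataclass
class SurrogateState:
    """Fitted GP posterior over normalized inputs.

    The prior mean is the empirical mean of the observed objective; the
    kernel is squared-exponential with a shared length scale; the Cholesky
    factor of ``K + noise_var * I`` is cached for prediction.
    """

    X: np.ndarray              # (n, d) unit-cube inputs
    y: np.ndarray              # (n,)
    length_scale: float
    signal_var: float
    noise_var: float
    mean0: float
    chol: tuple                # cho_factor of K + noise_var I
    alpha: np.ndarray          # (K + noise_var I)^-1 (y - mean0)


def _sq_exp(X1: np.ndarray, X2: np.ndarray, length_scale: float,
            signal_var: float) -> np.ndarray:
    d2 = ((X1[:, None, :] - X2[None, :, :]) ** 2).sum(axis=-1)
    return signal_var * np.exp(-0.5 * d2 / length_scale ** 2)


_JITTERS = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)


def gp_fit(X: np.ndarray, y: np.ndarray, length_scale: float = 0.3,
           signal_var: float | None = None,
           noise_var: float | None = None,
           optimize_hypers: bool = False) -> SurrogateState:
    """Exact GP regression on unit-cube inputs.

    Defaults: fixed length scale 0.3 in normalized coordinates, signal
    variance = var(y) (floored at 1e-12), noise variance = 1e-4 * var(y).
    ``optimize_hypers`` switches on a small marginal-likelihood search over
    the length scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 1:
        raise ValueError("need at least one observation")
    var_y = float(np.var(y))
    if signal_var is None:
        signal_var = max(var_y, 1e-12)
    if noise_var is None:
        noise_var = 1e-4 * max(var_y, 1e-12)
    if optimize_hypers and len(y) >= 3:
        length_scale = _ml_length_scale(X, y, signal_var, noise_var, length_scale)
    mean0 = float(np.mean(y))
    K = _sq_exp(X, X, length_scale, signal_var)
    n = len(y)
    last_exc: Exception | None = None
    for jit in _JITTERS:
        try:
            chol = cho_factor(K + (noise_var + jit) * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError as exc:
            last_exc = exc
    else:
        cond = np.linalg.cond(K + noise_var * np.eye(n))
        raise np.linalg.LinAlgError(
            f"Cholesky failed even with jitter 1e-6 (condition ~{cond:.2e})"
        ) from last_exc
    alpha = cho_solve(chol, y - mean0)
    return SurrogateState(X=X, y=y, length_scale=length_scale,
                          signal_var=signal_var, noise_var=noise_var,
                          mean0=mean0, chol=chol, alpha=alpha)


def _ml_length_scale(X, y, signal_var, noise_var, fallback) -> float:
    best_ls, best_ll = fallback, -np.inf
    n = len(y)
    yc = y - y.mean()
    for ls in np.geomspace(0.05, 2.0, 25):
        K = _sq_exp(X, X, ls, signal_var) + noise_var * np.eye(n)
        try:
            c = cho_factor(K + 1e-10 * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            continue
        a = cho_solve(c, yc)
        ll = -0.5 * yc @ a - np.log(np.diag(c[0])).sum()
        if ll > best_ll:
            best_ll, best_ls = ll, ls
    return best_ls


def gp_fit_ledger(ledger: TrialLedger, space: SearchSpace, **kwargs) -> SurrogateState:
    ok = ledger.ok_trials()
    X = np.stack([space.to_unit(t.point) for t in ok])
    y = np.array([t.y for t in ok])
    return gp_fit(X, y, **kwargs)


def gp_predict(state: SurrogateState, Xstar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at ``Xstar``; variance clipped at 0."""
    if state is None:
        raise NotFittedError("surrogate not fitted")
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    Ks = _sq_exp(Xstar, state.X, state.length_scale, state.signal_var)  # (m, n)
    mean = state.mean0 + Ks @ state.alpha
    # V[f(x)] = k(x,x) - K*^T (K + sigma_n^2 I)^-1 K*
    L = state.chol[0]
    v = solve_triangular(L, Ks.T, lower=True)
    var = state.signal_var - (v ** 2).sum(axis=0)
    bad = var < -1e-10
    if bad.any():
        log.warning("clipping %d negative posterior variances", int(bad.sum()))
    return mean, np.maximum(var, 0.0)


def expected_improvement(mean: np.ndarray, sd: np.ndarray,
                         f_best: float) -> np.ndarray:
    """Closed-form EI for minimization: E[max(0, f_best - f)].

    With z = (f_best - mu) / sigma: EI = sigma * (z * Phi(z) + phi(z));
    at sigma = 0 this degenerates to max(0, f_best - mu).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.maximum(f_best - mean, 0.0)
    pos = sd > 0
    if np.any(pos):
        z = (f_best - mean[pos]) / sd[pos]
        out = np.array(out, dtype=float)
        out[pos] = sd[pos] * (z * norm.cdf(z) + norm.pdf(z))
    return np.maximum(out, 0.0)


def ei_at(state: SurrogateState, x_unit: np.ndarray, f_best: float) -> float:
    mean, var = gp_predict(state, x_unit)
    return float(expected_improvement(mean, np.sqrt(var), f_best)[0])


def propose_next(state: SurrogateState, space: SearchSpace, f_best: float,
                 n_candidates: int = 2048,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Return the unit-cube candidate maximizing EI over a Sobol' draw.

    Integer dimensions are snapped to their feasible grid before EI is
    evaluated; ties go to the first maximizer in draw order.
    """
    if state is None:
        raise NotFittedError("surrogate not fitted")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sobol_seed = int(rng.integers(0, 2 ** 31 - 1))
    sampler = qmc.Sobol(d=space.n_dims, scramble=True, rng=sobol_seed)
    cand = sampler.random(n_candidates)
    cand = np.stack([space.snap(u) for u in cand])
    mean, var = gp_predict(state, cand)
    ei = expected_improvement(mean, np.sqrt(var), f_best)
    return cand[int(np.argmax(ei))]


def optimize(objective: Callable[[HyperparamPoint], float],
             space: SearchSpace,
             n_init: int = 8,
             n_iter: int = 20,
             seed: int = 0,
             n_candidates: int = 2048,
             gp_kwargs: dict | None = None) -> tuple[HyperparamPoint, TrialLedger]:
    """Space-filling initialization followed by GP-EI iterations.

    The objective receives a :class:`HyperparamPoint` and returns the
    validation loss; a NaN return is recorded as a failed trial and
    excluded from the surrogate.  Fully reproducible from ``seed`` given a
    deterministic objective.
    """
    rng = np.random.default_rng(seed)
    gp_kwargs = gp_kwargs or {}
    ledger = TrialLedger()

    def run_trial(u: np.ndarray) -> None:
        point = space.point(u)
        t0 = time.perf_counter()
        y = float(objective(point))
        dt = time.perf_counter() - t0
        if np.isfinite(y):
            ledger.add(Trial(point.as_dict(), y, seed, dt, "ok"))
        else:
            log.warning("objective returned %r at %s; trial marked failed", y, point)
            ledger.add(Trial(point.as_dict(), float("nan"), seed, dt, "failed"))

    init_seed = int(rng.integers(0, 2 ** 31 - 1))
    with warnings.catch_warnings():
        # Sobol' balance only holds at powers of two; any n_init is allowed here
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        init = qmc.Sobol(d=space.n_dims, scramble=True, rng=init_seed).random(n_init)
    for u in init:
        run_trial(space.snap(u))

    for _ in range(n_iter):
        if not ledger.ok_trials():
            # all trials failed so far: keep exploring quasi-randomly
            run_trial(space.snap(rng.random(space.n_dims)))
            continue
        state = gp_fit_ledger(ledger, space, **gp_kwargs)
        u = propose_next(state, space, ledger.f_best, n_candidates, rng)
        run_trial(u)

    best = ledger.best_trial
    return HyperparamPoint(**best.point), ledger
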