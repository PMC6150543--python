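"""Finite-generation propagation of copy-number distributions.

The g-th power of the sub-stochastic block answers every finite-time
question about a chain: row i of ``T**g`` holds the unnormalized occupation
probabilities after g generations for a lineage founded at i copies, its row
sum is the surviving fraction ``s_g(i)``, and the normalized row is the
copy-number distribution among viable cells.

Propagation renormalizes the state vector every generation and accumulates
the per-step survival in log space, which stays accurate out to millions of
generations where the raw surviving fraction underflows any float. When only
the final generation is wanted and g is large, matrix powers are formed by
repeated squaring with the same log-space scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chain_models import ChainMatrices

__all__ = [
    "Trajectory",
    "propagate",
    "surviving_fraction",
    "mean_copy_trajectory",
    "matrix_power_scaled",
    "time_to_inactivation",
]

#: above this generation count, single-time queries use repeated squaring
SQUARING_THRESHOLD = 10_000


@dataclass
class Trajectory:
    """Per-generation state of a propagated chain.

    ``conditional[g]`` is the distribution among viable cells at generation
    g; ``log_surviving[g]`` is ``log s_g`` for the initial distribution, so
    ``masses[g] = conditional[g] * exp(log_surviving[g])`` recovers the
    unnormalized row of the matrix power (it underflows exactly where the
    raw computation would).
    """

    states: list
    generations: np.ndarray
    conditional: np.ndarray  # (g+1, n)
    log_surviving: np.ndarray  # (g+1,)
    truncated: bool = False

    @property
    def surviving(self) -> np.ndarray:
        """Surviving fractions s_g in linear space (may underflow to 0)."""
        return np.exp(self.log_surviving)

    @property
    def masses(self) -> np.ndarray:
        """Unnormalized state masses, i.e. rows of initial @ T**g."""
        return self.conditional * np.exp(self.log_surviving)[:, None]

    def mean_copies(self) -> np.ndarray:
        """Mean copy number among viable cells at each generation."""
        labels = np.array(
            [s if isinstance(s, (int, np.integer)) else 0 for s in self.states],
            dtype=float,
        )
        numeric = labels > 0
        w = self.conditional[:, numeric]
        denom = w.sum(axis=1)
        out = np.full(len(self.generations), np.nan)
        ok = denom > 0
        out[ok] = (w[ok] @ labels[numeric]) / denom[ok]
        return out


def _as_initial(chain: ChainMatrices, initial) -> np.ndarray:
    n = chain.n_states
    if isinstance(initial, (int, np.integer)) or (
        isinstance(initial, str) and initial in chain.states
    ):
        idx = chain.states.index(initial)
        v = np.zeros(n)
        v[idx] = 1.0
        return v
    v = np.asarray(initial, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"initial distribution must have length {n}, got {v.shape}")
    if np.any(v < 0) or not math.isclose(v.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("initial distribution must be nonnegative and sum to 1")
    return v


def propagate(chain: ChainMatrices, initial, g: int) -> Trajectory:
    """Evolve a distribution over states for g generations.

    ``initial`` is either a state label (point mass on a founder) or a
    probability vector over ``chain.states``. Each step multiplies by the
    sub-stochastic block, renormalizes, and adds the step's log survival to
    a running total.
    """
    if g < 0:
        raise ValueError(f"generation count must be >= 0, got {g}")
    w = _as_initial(chain, initial)
    n = chain.n_states
    cond = np.zeros((g + 1, n))
    logs = np.zeros(g + 1)
    cond[0] = w
    truncated = False
    for t in range(1, g + 1):
        w = w @ chain.T
        step = w.sum()
        if step <= 0.0:
            cond[t:] = 0.0
            logs[t:] = -np.inf
            truncated = True
            break
        logs[t] = logs[t - 1] + math.log(step)
        w = w / step
        cond[t] = w
    gens = np.arange(g + 1)
    return Trajectory(list(chain.states), gens, cond, logs, truncated)


def matrix_power_scaled(T: np.ndarray, g: int) -> tuple[np.ndarray, float]:
    """Compute ``T**g`` as ``(B, log_scale)`` with ``T**g = B * exp(log_scale)``.

    Repeated squaring with per-step max-rescaling, so entries stay
    representable for g up to 10**6 and beyond.
    """
    n = T.shape[0]
    result = np.eye(n)
    log_result = 0.0
    base = T.copy()
    log_base = 0.0
    k = g
    while k > 0:
        if k & 1:
            result = result @ base
            log_result += log_base
            m = result.max()
            if m > 0:
                result /= m
                log_result += math.log(m)
        k >>= 1
        if k:
            base = base @ base
            log_base *= 2.0
            m = base.max()
            if m > 0:
                base /= m
                log_base += math.log(m)
    return result, log_result


def final_conditional(
    chain: ChainMatrices, initial, g: int
) -> tuple[np.ndarray, float]:
    """Distribution among viable cells and log s_g at generation g only.

    Uses repeated squaring above :data:`SQUARING_THRESHOLD`, stepwise
    propagation otherwise. Returns ``(conditional, log_surviving)``.
    """
    if g > SQUARING_THRESHOLD:
        w = _as_initial(chain, initial)
        B, log_scale = matrix_power_scaled(chain.T, g)
        mass = w @ B
        s = mass.sum()
        if s <= 0:
            return np.zeros(chain.n_states), -math.inf
        return mass / s, math.log(s) + log_scale
    traj = propagate(chain, initial, g)
    return traj.conditional[-1], float(traj.log_surviving[-1])


def surviving_fraction(
    chain: ChainMatrices, founder: int, g: int
) -> tuple[float, np.ndarray]:
    """Surviving fraction s_g(founder) and the per-generation log series.

    ``s_g(i)`` is the probability that a random lineage founded at ``i``
    copies is still viable after g generations — the i-th row sum of the
    g-th matrix power. Returned as ``(s_g linear, log s series of length
    g+1)``; the linear value underflows to 0 exactly where the direct
    computation would.
    """
    traj = propagate(chain, founder, g)
    return float(np.exp(traj.log_surviving[-1])), traj.log_surviving


def mean_copy_trajectory(chain: ChainMatrices, initial, g: int) -> np.ndarray:
    """Per-generation mean copy number among viable cells."""
    return propagate(chain, initial, g).mean_copies()


def time_to_inactivation(
    chain: ChainMatrices,
    g_max: int,
    conditional: bool = True,
) -> int | None:
    """Generations until most cells carry no active copy of gene X.

    For the ax chain started from a diploid founder with two active copies
    (state sigma), returns the smallest g at which the mass on the ordinary
    copy-number states 1..N exceeds 1/2, or ``None`` if that never happens
    by ``g_max``. By default the proportion is taken among viable cells (the
    conditional distribution); ``conditional=False`` uses the raw
    unnormalized masses instead.
    """
    if chain.kind != "ax":
        raise ValueError(f"time_to_inactivation needs an ax chain, got {chain.kind!r}")
    traj = propagate(chain, "sigma", g_max)
    numeric = chain.numeric_slice()
    weights = traj.conditional if conditional else traj.masses
    inactive_mass = weights[:, numeric].sum(axis=1)
    hits = np.nonzero(inactive_mass > 0.5)[0]
    return int(hits[0]) if len(hits) else None
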