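"""Direct stochastic simulation of the branching cell-division model.

Follows random lineages — founder cell, then one uniformly chosen daughter
per division — which is exactly the process each Markov chain describes, so
empirical lineage statistics are an implementation-independent oracle for
every transition matrix and trajectory computed elsewhere in the package.

Two division rules are available: ``linearized`` (at most one missegregation
per chromosome per division, matching the transition matrices, which drop
terms quadratic in p) and ``binomial`` (every copy missegregates
independently; the full division rule before linearization), used to
quantify how small the neglected O(p^2) terms are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .chain_models import ChainMatrices, ChainParams, N_CHROMOSOMES

__all__ = ["LineageSample", "simulate_lineages", "empirical_vs_chain"]

DEAD = 0
SIGMA = -2
TAU = -1


@dataclass
class LineageSample:
    """Terminal states of simulated lineages after g generations.

    ``outcomes`` holds one terminal state per lineage: a copy number 1..N,
    0 for dead, and -2/-1 for the ax chain's sigma/tau states. Bit-for-bit
    reproducible from (seed, parameters, g, n_lineages, rule).
    """

    params: ChainParams
    kind: str
    g: int
    n_lineages: int
    seed: int
    rule: str
    outcomes: np.ndarray

    @property
    def n_surviving(self) -> int:
        return int(np.count_nonzero(self.outcomes != DEAD))

    @property
    def surviving_fraction(self) -> float:
        return self.n_surviving / self.n_lineages

    def viable_counts(self, states: list) -> np.ndarray:
        """Tallies over the given state labels (sigma/tau included if listed)."""
        codes = {"sigma": SIGMA, "tau": TAU}
        out = np.array(
            [
                int(np.count_nonzero(self.outcomes == codes.get(s, s)))
                for s in states
            ]
        )
        return out

    def conditional(self, states: list) -> np.ndarray:
        counts = self.viable_counts(states)
        total = counts.sum()
        return counts / total if total > 0 else counts.astype(float)


def _divide_linearized(
    state: np.ndarray, alive: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """One division under the at-most-one-missegregation rule.

    From i copies the random daughter has i-1 / i+1 copies with probability
    i*p/2 each — the rows of the basic transition matrix.
    """
    u = rng.random(state.shape)
    thresh = state * p / 2.0
    new = state.copy()
    new[alive & (u < thresh)] -= 1
    new[alive & (u >= thresh) & (u < 2 * thresh)] += 1
    return new

def _divide_binomial(
    state: np.ndarray, alive: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """One division with every copy missegregating independently.

    Each of the i copies contributes 0, 1 or 2 copies to a random daughter
    with probabilities p/2, 1-p, p/2; the daughter's count is the sum.
    """
    new = state.copy()
    i = state[alive]
    doubled = rng.binomial(i, p / 2.0)
    rest = i - doubled
    lost = rng.binomial(rest, (p / 2.0) / (1.0 - p / 2.0))
    new[alive] = (rest - lost) + 2 * doubled
    return new


def simulate_lineages(
    params: ChainParams,
    founder,
    g: int,
    n_lineages: int,
    seed: int,
    rule: str = "linearized",
    kind: str = "basic",
) -> LineageSample:
    """Simulate random lineages of the cell-division model.

    Per generation and lineage: spontaneous death with probability
    ``1 - C*mu**i`` (scored kinds), then either a whole-genome duplication
    event (rate ``p_gd``: half the mass doubles the count, half dies — the
    uncreated daughter) or an ordinary division under the chosen rule; any
    copy number outside [1, N] kills the lineage. ``kind`` selects the model:
    basic, scored, gd (duplication, scored), or ax (founder must then be the
    string "sigma" or "tau").

    The ax kind follows the early-tumor matrix semantics: while an active
    copy of gene X remains, any missegregation among the cell's 46
    chromosome copies is lethal, and each active copy of X mutates with rate
    ``m_r`` per generation.
    """
    if rule not in ("linearized", "binomial"):
        raise ValueError(f"unknown division rule {rule!r}")
    if kind not in ("basic", "scored", "gd", "ax"):
        raise ValueError(f"unknown chain kind {kind!r}")
    rng = np.random.default_rng(seed)
    N, p = params.N, params.p
    divide = _divide_linearized if rule == "linearized" else _divide_binomial

    if kind == "ax":
        start = {"sigma": SIGMA, "tau": TAU}.get(founder, founder)
        state = np.full(n_lineages, start, dtype=np.int64)
    else:
        if not 1 <= int(founder) <= N:
            raise ValueError(f"founder copy number {founder} outside [1, {N}]")
        state = np.full(n_lineages, int(founder), dtype=np.int64)

    pgd = params.p_gd_vector()
    use_gd = kind == "gd"
    use_scores = kind in ("scored", "gd", "ax")
    if use_scores:
        qmax = max(params.C * params.mu**i for i in (1, N))
        if qmax > 1.0 + 1e-12:
            raise ValueError(
                f"survival factor C*mu^i reaches {qmax:.6g} > 1: a single "
                "chromosome's chain is only simulable when its q is a "
                "probability (choose a constant split with C*mu^N <= 1)"
            )
    no_misseg_46 = (1.0 - p) ** (2 * N_CHROMOSOMES)

    if kind == "ax" and no_misseg_46 - 2.0 * params.m_r < 0:
        raise ValueError("(1-p)^46 - 2*m_r < 0: sigma's stay probability negative")

    for _ in range(g):
        alive = state != DEAD
        if not alive.any():
            break
        early = (state == SIGMA) | (state == TAU)
        numeric = alive & ~early

        if use_scores:
            # spontaneous death; sigma/tau cells carry two copies
            copies = np.where(early, 2, np.clip(state, 1, N))
            q = params.C * params.mu ** copies.astype(float)
            dies = alive & (rng.random(n_lineages) >= q)
            state[dies] = DEAD
            early &= state != DEAD
            numeric &= state != DEAD

        if early.any():
            # single-draw thresholds matching the printed transition rows:
            # sigma: tau w.p. 2*m_r, sigma w.p. (1-p)^46 - 2*m_r, else dead;
            # tau: 2 w.p. m_r, 1 w.p. p/2, tau w.p. (1-p)^46 - m_r, else dead
            u = rng.random(n_lineages)
            is_sigma = early & (state == SIGMA)
            is_tau = early & (state == TAU)
            new = state.copy()
            new[is_sigma] = DEAD
            new[is_sigma & (u < no_misseg_46)] = SIGMA
            new[is_sigma & (u < 2.0 * params.m_r)] = TAU
            new[is_tau] = DEAD
            new[
                is_tau
                & (u >= params.m_r + p / 2.0)
                & (u < no_misseg_46 + p / 2.0)
            ] = TAU
            new[is_tau & (u >= params.m_r) & (u < params.m_r + p / 2.0)] = 1
            new[is_tau & (u < params.m_r)] = 2
            state = new

        if numeric.any():
            if use_gd:
                u = rng.random(n_lineages)
                rates = pgd[np.clip(state, 1, N) - 1]
                dup = numeric & (u < rates / 2.0)
                gd_dead = numeric & (u >= rates / 2.0) & (u < rates)
                normal = numeric & (u >= rates)
                state[dup] *= 2
                state[gd_dead] = DEAD
                state = np.where(normal, divide(state, normal, p, rng), state)
            else:
                state = np.where(numeric, divide(state, numeric, p, rng), state)
            out_of_range = (state != SIGMA) & (state != TAU) & (
                (state < 1) | (state > N)
            )
            state[out_of_range] = DEAD

    return LineageSample(params, kind, g, n_lineages, seed, rule, state)


@dataclass
class GoodnessReport:
    """Agreement between simulated lineages and a chain's prediction."""

    chi2: float
    dof: int
    p_value: float
    z_scores: np.ndarray
    expected: np.ndarray
    observed: np.ndarray
    surviving_expected: float
    surviving_observed: float
    surviving_z: float
    defined: bool = True


def empirical_vs_chain(
    sample: LineageSample,
    expected_conditional: np.ndarray,
    expected_surviving: float,
    states: list,
    min_expected: float = 5.0,
) -> GoodnessReport:
    """Chi-square comparison of lineage tallies with a chain's distribution.

    ``expected_conditional`` and ``expected_surviving`` come from the matrix
    computation at the same parameters and generation. States whose expected
    count falls below ``min_expected`` are pooled into their neighbor before
    the chi-square (standard validity guard); per-state z-scores are reported
    unpooled. With zero surviving lineages the conditional comparison is
    undefined and flagged.
    """
    observed = sample.viable_counts(states).astype(float)
    n_surv = observed.sum()
    q = float(expected_surviving)
    n_tot = sample.n_lineages
    se = math.sqrt(max(q * (1.0 - q), 1e-300) * n_tot)
    surv_z = (n_surv - q * n_tot) / se if se > 0 else math.inf
    if n_surv == 0:
        return GoodnessReport(
            math.nan, 0, math.nan, np.full(len(states), np.nan),
            np.asarray(expected_conditional, dtype=float), observed,
            q, 0.0, surv_z, defined=False,
        )
    expected = np.asarray(expected_conditional, dtype=float) * n_surv
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(expected > 0, (observed - expected) / np.sqrt(expected), 0.0)
    # pool adjacent low-expectation bins
    obs_pool, exp_pool = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_pool.append(acc_o)
            exp_pool.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and obs_pool:
        obs_pool[-1] += acc_o
        exp_pool[-1] += acc_e
    obs_pool = np.array(obs_pool)
    exp_pool = np.array(exp_pool) * (obs_pool.sum() / sum(exp_pool))
    if len(obs_pool) >= 2:
        chi2, p_value = scipy.stats.chisquare(obs_pool, exp_pool)
        dof = len(obs_pool) - 1
    else:
        chi2, p_value, dof = 0.0, 1.0, 0
    return GoodnessReport(
        float(chi2), dof, float(p_value), z, expected, observed,
        q, n_surv / n_tot, surv_z,
    )
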