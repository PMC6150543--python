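"""The 23-chromosome product chain: karyotypes, population size, diversity.

Missegregation events on different chromosomes are independent, so the full
karyotype chain is the product of 23 single-chromosome chains and every
population-level quantity factorizes over chromosomes. The N^23 joint state
space is never enumerated: joint probabilities are products of marginal
entries, the expected viable population is ``2^g * prod_k s_g^(k)(f_k)``,
and the karyotype diversity index is the sum of the per-chromosome Shannon
entropies of copy-number fractions among viable cells,

    K = - sum_k sum_j a_kj * ln(a_kj),    0 <= K <= 23 ln N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .chain_models import (
    ChainMatrices,
    ChainParams,
    ScoreTable,
    build_duplication,
    build_scored,
)
from .dynamics import final_conditional, matrix_power_scaled, propagate

__all__ = [
    "KaryotypeModel",
    "DiversitySurface",
    "karyotype_probability",
    "expected_population",
    "diversity_index",
    "diversity_surface",
    "optimal_p",
]


@dataclass
class KaryotypeModel:
    """Per-chromosome chains sharing N and p, plus a founder karyotype."""

    chains: list[ChainMatrices]
    founder: np.ndarray

    def __post_init__(self) -> None:
        self.founder = np.asarray(self.founder, dtype=int)
        Ns = {c.params.N for c in self.chains}
        ps = {c.params.p for c in self.chains}
        if len(Ns) != 1 or len(ps) != 1:
            raise ValueError("all chains in a karyotype model must share N and p")
        if self.founder.shape != (len(self.chains),):
            raise ValueError(
                f"founder must have one entry per chain "
                f"({len(self.chains)}), got shape {self.founder.shape}"
            )
        N = Ns.pop()
        if np.any(self.founder < 1) or np.any(self.founder > N):
            raise ValueError(f"founder copy numbers must lie in [1, {N}]")

    @property
    def N(self) -> int:
        return self.chains[0].params.N

    @property
    def p(self) -> float:
        return self.chains[0].params.p

    @classmethod
    def from_scores(
        cls,
        scores: ScoreTable,
        N: int = 8,
        p: float = 0.0025,
        founder: int | Sequence[int] = 4,
        p_gd: float = 0.0,
    ) -> "KaryotypeModel":
        """Build the standard 23-chain model from a score table.

        Each chromosome gets its own mu_k; the global survival constant c is
        split evenly (C_k = exp(c/23)), which is immaterial to conditional
        distributions and to the surviving-fraction product.
        """
        C = scores.c_split
        chains = []
        for mu in scores.mu:
            params = ChainParams(N=N, p=p, mu=mu, C=C, p_gd=p_gd)
            if np.any(np.atleast_1d(p_gd) > 0):
                chains.append(build_duplication(params, scored=True))
            else:
                chains.append(build_scored(params))
        f = np.full(len(scores), founder) if np.isscalar(founder) else founder
        return cls(chains, np.asarray(f, dtype=int))


def karyotype_probability(
    model: KaryotypeModel,
    karyotype: Sequence[int],
    g: int,
    conditional: bool = False,
) -> float:
    """Probability of one karyotype after g generations, from the founder.

    The unnormalized value is the product over chromosomes of the
    ``(f_k -> n_k)`` entry of the k-th chain's g-th matrix power — the
    fraction of the 2^g potential cells that are viable with exactly this
    karyotype. With ``conditional=True`` it is divided by the surviving
    fraction, giving the probability among viable cells.
    """
    n = np.asarray(karyotype, dtype=int)
    if n.shape != model.founder.shape:
        raise ValueError("karyotype and founder must have the same length")
    if np.any(n < 1) or np.any(n > model.N):
        raise ValueError(f"karyotype entries must lie in [1, {model.N}]")
    log_prob = 0.0
    for chain, f_k, n_k in zip(model.chains, model.founder, n):
        cond, log_s = final_conditional(chain, int(f_k), g)
        entry = cond[chain.states.index(int(n_k))]
        if entry <= 0.0:
            return 0.0
        log_prob += math.log(entry)
        if not conditional:
            log_prob += log_s
    return math.exp(log_prob)


def expected_population(model: KaryotypeModel, g: int) -> tuple[float, float]:
    """Expected viable-cell count after g generations, as (log, linear).

    ``2^g * prod_k s_g^(k)(f_k)``: doubling per generation discounted by the
    per-chromosome surviving fractions of the founder. The linear value is
    ``inf`` when it exceeds float range. Independent of how the global
    survival constant c is split among chromosomes.
    """
    if g < 0:
        raise ValueError(f"generation count must be >= 0, got {g}")
    log_pop = g * math.log(2.0)
    for chain, f_k in zip(model.chains, model.founder):
        _, log_s = final_conditional(chain, int(f_k), g)
        log_pop += log_s
    try:
        linear = math.exp(log_pop)
    except OverflowError:
        linear = math.inf
    return log_pop, linear


def diversity_index(marginals: np.ndarray) -> float:
    """Karyotype diversity K: summed Shannon entropy of the marginals.

    ``marginals`` is a (chromosomes x states) array of copy-number fractions
    among viable cells, each row summing to 1; 0*ln(0) counts as 0.
    """
    a = np.atleast_2d(np.asarray(marginals, dtype=float))
    if np.any(a < 0):
        raise ValueError("copy-number fractions must be nonnegative")
    if not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each chromosome's marginal must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a > 0, a * np.log(a), 0.0)
    return float(-terms.sum())


@dataclass
class DiversitySurface:
    """K and surviving fraction over a (generations x missegregation) grid."""

    g_grid: np.ndarray
    p_grid: np.ndarray
    K: np.ndarray  # (len(g_grid), len(p_grid))
    log_surviving: np.ndarray  # same shape

    @property
    def surviving(self) -> np.ndarray:
        return np.exp(self.log_surviving)

    def optimal_g_per_p(self) -> np.ndarray:
        """g(p): the grid generation maximizing K at each p (first argmax)."""
        return self.g_grid[np.argmax(self.K, axis=0)]


def _model_marginals_at(
    model: KaryotypeModel, g_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Marginals a_kj and log surviving fractions at the grid generations.

    One pass per chromosome: matrix powers are advanced incrementally along
    the sorted grid by repeated squaring of the generation gaps, so a grid
    spanning 10..10^6 generations costs O(log g) matrix products per point.
    """
    n_chrom = len(model.chains)
    N = model.N
    gs = np.asarray(sorted(set(int(g) for g in g_grid)))
    marg = np.zeros((len(gs), n_chrom, N))
    logs = np.zeros((len(gs), n_chrom))
    for k, (chain, f_k) in enumerate(zip(model.chains, model.founder)):
        row = np.zeros(chain.n_states)
        row[chain.states.index(int(f_k))] = 1.0
        log_acc = 0.0
        prev_g = 0
        for gi, g in enumerate(gs):
            if g > prev_g:
                B, log_scale = matrix_power_scaled(chain.T, g - prev_g)
                row = row @ B
                s = row.sum()
                if s <= 0:
                    row = np.zeros_like(row)
                    log_acc = -math.inf
                else:
                    log_acc += math.log(s) + log_scale
                    row = row / s
                prev_g = g
            sl = chain.numeric_slice()
            mass = row[sl].sum()
            marg[gi, k] = row[sl] / mass if mass > 0 else 0.0
            logs[gi, k] = log_acc
    # map back onto the requested (possibly unsorted / repeated) grid
    index = {int(g): i for i, g in enumerate(gs)}
    order = [index[int(g)] for g in g_grid]
    return marg[order], logs[order]


def diversity_surface(
    model_factory: Callable[[float], KaryotypeModel] | KaryotypeModel,
    g_grid: Sequence[int],
    p_grid: Sequence[float],
) -> DiversitySurface:
    """Karyotype diversity K(g, p) and surviving fraction over a grid.

    ``model_factory`` maps a missegregation rate to a model (or is a single
    model used as a template, rebuilt at each p with the same scores, cap
    and founder). For fixed p, K(g, p) converges as g grows to the diversity
    of the limiting distribution; the transient can overshoot that limit.
    """
    g_grid = np.asarray(g_grid, dtype=int)
    p_grid = np.asarray(p_grid, dtype=float)
    if g_grid.size == 0 or p_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if isinstance(model_factory, KaryotypeModel):
        template = model_factory
        mus = [c.params.mu for c in template.chains]
        Cs = [c.params.C for c in template.chains]
        N, founder = template.N, template.founder

        def model_factory(p: float) -> KaryotypeModel:
            chains = [
                build_scored(ChainParams(N=N, p=p, mu=mu, C=C))
                for mu, C in zip(mus, Cs)
            ]
            return KaryotypeModel(chains, founder)

    K = np.zeros((len(g_grid), len(p_grid)))
    logS = np.zeros_like(K)
    for j, p in enumerate(p_grid):
        model = model_factory(float(p))
        marg, logs = _model_marginals_at(model, g_grid)
        for i in range(len(g_grid)):
            K[i, j] = diversity_index(marg[i])
            logS[i, j] = logs[i].sum()
    return DiversitySurface(g_grid, p_grid, K, logS)


def _objective_on_grid(
    model_factory: Callable[[float], KaryotypeModel],
    g: int,
    objective: str,
    p_values: np.ndarray,
) -> np.ndarray:
    """Log-scale objective values (monotone transform of the raw objective)."""
    out = np.empty(len(p_values))
    for j, p in enumerate(p_values):
        model = model_factory(float(p))
        marg, logs = _model_marginals_at(model, np.array([g]))
        log_s = logs[0].sum()
        if objective == "surviving":
            out[j] = log_s
        else:
            K = diversity_index(marg[0])
            logK = math.log(K) if K > 0 else -math.inf
            out[j] = logK if objective == "K" else log_s + logK
    return out


def optimal_p(
    model_factory: Callable[[float], KaryotypeModel] | KaryotypeModel,
    g: int,
    objective: str = "surviving*K",
    p_grid: Sequence[float] | None = None,
    refine_iters: int = 40,
) -> tuple[float, float]:
    """Missegregation rate maximizing an objective after g generations.

    Objectives: ``surviving`` (fraction of viable cells), ``K`` (karyotype
    diversity), or their product ``surviving*K`` — the trade-off between
    generating heterogeneity and avoiding nullisomy. Grid search on log p
    followed by golden-section refinement between the argmax's neighbors;
    ties break toward smaller p. Returns ``(p*, objective value at p*)``.
    """
    if objective not in ("surviving", "K", "surviving*K"):
        raise ValueError(f"unknown objective {objective!r}")
    if isinstance(model_factory, KaryotypeModel):
        template = model_factory
        mus = [c.params.mu for c in template.chains]
        Cs = [c.params.C for c in template.chains]
        N, founder = template.N, template.founder

        def model_factory(p: float) -> KaryotypeModel:
            chains = [
                build_scored(ChainParams(N=N, p=p, mu=mu, C=C))
                for mu, C in zip(mus, Cs)
            ]
            return KaryotypeModel(chains, founder)

        if p_grid is None:
            p_grid = np.logspace(-7, math.log10(1.0 / N), 25)
    p_grid = np.asarray(p_grid, dtype=float)
    vals = _objective_on_grid(model_factory, g, objective, p_grid)
    best = int(np.argmax(vals))  # first argmax = smallest p on ties
    lo = p_grid[max(best - 1, 0)]
    hi = p_grid[min(best + 1, len(p_grid) - 1)]
    if lo == hi:
        value = vals[best]
        return float(p_grid[best]), float(math.exp(value))
    # golden-section on log p
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = math.log(lo), math.log(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _objective_on_grid(model_factory, g, objective, np.array([math.exp(c)]))[0]
    fd = _objective_on_grid(model_factory, g, objective, np.array([math.exp(d)]))[0]
    for _ in range(refine_iters):
        if b - a < 1e-4:
            break
        if fc >= fd:  # keep the left interval on ties -> smaller p
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _objective_on_grid(
                model_factory, g, objective, np.array([math.exp(c)])
            )[0]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _objective_on_grid(
                model_factory, g, objective, np.array([math.exp(d)])
            )[0]
    x = (a + b) / 2.0
    fx = _objective_on_grid(model_factory, g, objective, np.array([math.exp(x)]))[0]
    candidates = [(vals[best], float(p_grid[best])), (fx, math.exp(x))]
    fbest, pbest = max(candidates, key=lambda t: (t[0], -t[1]))
    return float(pbest), float(math.exp(fbest))
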