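"""Transition matrices for per-chromosome copy-number Markov chains.

Each chain tracks the number of copies of a single chromosome in a random
cell lineage of a clonally expanding population. Copy numbers outside
[1, N] are lethal (nullisomy, or exceeding the tolerated maximum), so the
chain is absorbing: we store the transition matrix restricted to the
non-absorbing states 1..N together with an explicit per-state ``death_mass``
(the weight of the transition into the absorbing dead state), so that every
row of the sub-stochastic block plus its death mass sums to exactly 1.

Chain kinds
-----------
basic
    Missegregation only: from ``i`` copies, move to ``i±1`` with probability
    ``i*p/2`` each (one missegregation per division; terms quadratic in ``p``
    are dropped), stay with probability ``1 - i*p``.
drift
    The p-independent generator ``J`` with ``M = I + p*J``.
scored
    Chromosome-score survival: each generation the cell first survives with
    probability ``q(i) = C * mu**i`` and then divides as in the basic chain,
    giving ``A = D M`` with ``D = diag(q(i))``.
gd
    Whole-genome duplication added: an extra ``i -> 2i`` transition with
    probability ``p_gd/2`` (to the dead state when ``2i > N``).
ax
    Early-tumor aneuploidy intolerance: two extra states ``sigma`` (two
    active copies of the tolerance gene X) and ``tau`` (one active, one
    mutated copy) precede the ordinary copy-number states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_C_GLOBAL",
    "DEFAULT_D",
    "ChainParams",
    "ScoreTable",
    "ChainMatrices",
    "build_basic",
    "build_drift",
    "survival_factor",
    "karyotype_survival",
    "build_scored",
    "build_duplication",
    "build_inactivation",
]

#: Global survival constants: Q_surv = exp(c + d*S) for a cell with total
#: score S. c is calibrated so that Q_surv <= 1 for every valid karyotype.
DEFAULT_C_GLOBAL = -0.036132164
DEFAULT_D = 0.00039047

N_CHROMOSOMES = 23


class InvalidParameterError(ValueError):
    """A parameter combination makes the linearized chain ill-defined."""


@dataclass(frozen=True)
class ChainParams:
    """Scalar parameters of one chromosome's copy-number chain.

    Parameters
    ----------
    N : int
        Maximum tolerated copy number; states are 1..N.
    p : float
        Missegregation rate per chromosome copy per division.
    mu : float
        Per-copy survival multiplier ``mu = exp(d * s_k)``; 1 means the
        chromosome carries no net oncogenic/tumor-suppressive weight.
    C : float
        Per-chromosome survival constant ``exp(c_k)``. The split of the
        global ``c`` among chromosomes is immaterial to conditional
        distributions; the default is the even split ``exp(c/23)``.
    p_gd : float or sequence of float
        Whole-genome duplication rate; a scalar or one value per state.
    m_r : float
        Gene-X inactivating mutation rate (ax chain only).
    """

    N: int = 8
    p: float = 0.0
    mu: float = 1.0
    C: float = math.exp(DEFAULT_C_GLOBAL / N_CHROMOSOMES)
    p_gd: float | Sequence[float] = 0.0
    m_r: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise InvalidParameterError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError(f"p must lie in [0, 1], got {self.p}")
        if self.mu <= 0:
            raise InvalidParameterError(f"mu must be positive, got {self.mu}")
        if self.C <= 0:
            raise InvalidParameterError(f"C must be positive, got {self.C}")
        pgd = np.atleast_1d(np.asarray(self.p_gd, dtype=float))
        if np.any(pgd < 0) or np.any(pgd > 1):
            raise InvalidParameterError("p_gd must lie in [0, 1] entrywise")
        if not 0.0 <= self.m_r <= 1.0:
            raise InvalidParameterError(f"m_r must lie in [0, 1], got {self.m_r}")
        qmax = max(self.C * self.mu**i for i in (1, self.N))
        if qmax > 1.0 + 1e-12:
            # static message so the warnings filter deduplicates it
            warnings.warn(
                "C*mu^i exceeds 1 for some copy number; per-chromosome survival "
                "factors are not individually interpretable as probabilities, "
                "but the product chain is unaffected by the constant split.",
                stacklevel=2,
            )

    def p_gd_vector(self) -> np.ndarray:
        """Per-state genome-duplication rates as a length-N array."""
        pgd = np.asarray(self.p_gd, dtype=float)
        if pgd.ndim == 0:
            return np.full(self.N, float(pgd))
        if pgd.shape != (self.N,):
            raise InvalidParameterError(
                f"p_gd vector must have length N={self.N}, got shape {pgd.shape}"
            )
        return pgd.copy()


@dataclass(frozen=True)
class ScoreTable:
    """Chromosome scores and the survival constants that convert them.

    Each of the 23 chromosomes carries a signed score ``s_k`` (positive =
    oncogenic, negative = tumor-suppressive). A cell with karyotype
    ``(n_1..n_23)`` survives a generation with probability
    ``Q_surv = exp(c + d * sum_k s_k n_k)``; per chromosome this factors as
    ``q_k(i) = C_k * mu_k**i`` with ``mu_k = exp(d * s_k)``.
    """

    chromosomes: tuple[int, ...]
    scores: tuple[float, ...]
    mu: tuple[float, ...]
    c: float = DEFAULT_C_GLOBAL
    d: float = DEFAULT_D

    def __post_init__(self) -> None:
        if sorted(self.chromosomes) != list(range(1, len(self.chromosomes) + 1)):
            raise ValueError(
                "score table must contain exactly one row per chromosome label "
                f"1..{len(self.chromosomes)}; got {self.chromosomes}"
            )
        if not (len(self.chromosomes) == len(self.scores) == len(self.mu)):
            raise ValueError("chromosomes, scores and mu must have equal length")
        if self.d <= 0:
            raise ValueError(f"d must be positive, got {self.d}")
        for k, s, m in zip(self.chromosomes, self.scores, self.mu):
            expected = math.exp(self.d * s)
            if abs(m - expected) > 1e-9 * expected:
                raise ValueError(
                    f"chromosome {k}: mu={m} inconsistent with exp(d*s)={expected!r}"
                )

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def c_split(self) -> float:
        """Even split of the global constant: C_k = exp(c / n_chromosomes)."""
        return math.exp(self.c / len(self))

    def mu_for(self, chromosome: int) -> float:
        return self.mu[self.chromosomes.index(chromosome)]

    def score_for(self, chromosome: int) -> float:
        return self.scores[self.chromosomes.index(chromosome)]

    @classmethod
    def from_scores(
        cls,
        scores: Sequence[float],
        c: float = DEFAULT_C_GLOBAL,
        d: float = DEFAULT_D,
    ) -> "ScoreTable":
        """Build a table from raw scores, deriving mu_k = exp(d*s_k)."""
        labels = tuple(range(1, len(scores) + 1))
        mu = tuple(math.exp(d * s) for s in scores)
        return cls(labels, tuple(float(s) for s in scores), mu, c=c, d=d)


@dataclass
class ChainMatrices:
    """A sub-stochastic transition matrix plus explicit death bookkeeping.

    ``T[a, b]`` is the one-generation transition weight from ``states[a]``
    to ``states[b]`` among non-absorbing states; ``death_mass[a]`` is the
    weight of the transition into the absorbing dead state, so each row of
    ``T`` plus its death mass sums to 1 (for the drift kind, to 0).
    """

    kind: str
    states: list
    T: np.ndarray
    death_mass: np.ndarray
    params: ChainParams | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def copy_numbers(self) -> np.ndarray:
        """Integer copy-number labels (excludes sigma/tau for the ax kind)."""
        return np.array([s for s in self.states if isinstance(s, (int, np.integer))])

    def numeric_slice(self) -> slice:
        """Index range of the ordinary copy-number states within ``states``."""
        first = next(
            i for i, s in enumerate(self.states) if isinstance(s, (int, np.integer))
        )
        return slice(first, self.n_states)

    def full_matrix(self) -> np.ndarray:
        """The (n+1) x (n+1) stochastic matrix with the dead state first."""
        n = self.n_states
        full = np.zeros((n + 1, n + 1))
        full[0, 0] = 1.0
        full[1:, 0] = self.death_mass
        full[1:, 1:] = self.T
        return full


def _check_basic_params(params: ChainParams) -> None:
    if params.p > 1.0 / params.N:
        bad = math.ceil(1.0 / params.p) if params.p > 0 else params.N
        bad = min(bad, params.N)
        raise InvalidParameterError(
            f"p={params.p} exceeds 1/N={1.0 / params.N:.6g}: the stay probability "
            f"1 - i*p of state i={bad} would be negative under the linearized "
            "division rule"
        )


def build_basic(params: ChainParams) -> ChainMatrices:
    """Missegregation-only chain M over copy-number states 1..N.

    From ``i`` copies a random daughter has ``i-1`` or ``i+1`` copies with
    probability ``i*p/2`` each and ``i`` copies otherwise (at most one
    missegregation per chromosome per division). Leaving [1, N] is lethal:
    state 1 loses ``p/2`` to death, state N loses ``N*p/2``.
    """
    _check_basic_params(params)
    N, p = params.N, params.p
    i = np.arange(1, N + 1, dtype=float)
    T = np.diag(1.0 - i * p)
    if N > 1:
        T += np.diag(i[:-1] * p / 2.0, k=1)
        T += np.diag(i[1:] * p / 2.0, k=-1)
    death = np.zeros(N)
    death[0] += p / 2.0
    death[-1] += N * p / 2.0
    return ChainMatrices("basic", list(range(1, N + 1)), T, death, params)


def build_drift(N: int) -> ChainMatrices:
    """The p-independent drift matrix J with M = I + p*J.

    ``J`` has ``-i`` on the diagonal and ``i/2`` on both off-diagonals; its
    largest eigenvalue and left Perron eigenvector determine the limiting
    conditional distribution of the basic chain for every p > 0.
    """
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    i = np.arange(1, N + 1, dtype=float)
    T = np.diag(-i)
    if N > 1:
        T += np.diag(i[:-1] / 2.0, k=1)
        T += np.diag(i[1:] / 2.0, k=-1)
    # rows of J sum to 0 once the boundary leak is included
    death = np.zeros(N)
    death[0] = 0.5
    death[-1] = N / 2.0
    return ChainMatrices("drift", list(range(1, N + 1)), T, death, ChainParams(N=N))


def survival_factor(params: ChainParams, i: int) -> float:
    """Per-chromosome survival factor q(i) = C * mu**i for a cell with i copies."""
    if not 1 <= i <= params.N:
        raise ValueError(f"copy number {i} outside [1, {params.N}]")
    q = params.C * params.mu**i
    if q > 1.0 + 1e-12:
        warnings.warn(
            f"survival factor q({i}) = {q:.6g} > 1; only the product across "
            "chromosomes is a probability",
            stacklevel=2,
        )
    return q


def karyotype_survival(scores: ScoreTable, karyotype: Sequence[int]) -> float:
    """Survival probability Q_surv = exp(c + d * sum_k s_k * n_k) of a cell."""
    n = np.asarray(karyotype, dtype=float)
    if n.shape != (len(scores),):
        raise ValueError(
            f"karyotype must have {len(scores)} entries, got shape {n.shape}"
        )
    S = float(np.dot(scores.scores, n))
    return math.exp(scores.c + scores.d * S)


def build_scored(params: ChainParams) -> ChainMatrices:
    """Score-weighted chain A = D M with D = diag(q(i)), q(i) = C*mu^i.

    Each generation the cell first survives with probability q(i) and then
    divides as in the basic chain; the death mass of state i is therefore
    ``1 - q(i) * (row-i sum of M)``, covering both spontaneous death and
    lethal missegregation.
    """
    basic = build_basic(params)
    i = np.arange(1, params.N + 1)
    q = params.C * params.mu ** i.astype(float)
    T = q[:, None] * basic.T
    death = 1.0 - q * (basic.T.sum(axis=1))
    return ChainMatrices("scored", list(range(1, params.N + 1)), T, death, params)


def build_duplication(params: ChainParams, scored: bool = False) -> ChainMatrices:
    """Chain with whole-genome duplication: M_gd = M + G (or A_gd = D(M+G)).

    With probability ``p_gd`` a cell duplicates its genome instead of
    dividing; per chromosome this is a transition ``i -> 2i`` with weight
    ``p_gd/2`` plus a ``p_gd/2`` transition to death (the daughter that was
    never created), and the diagonal loses ``p_gd``. When ``2i > N`` the
    duplication itself is lethal and both halves go to the dead state.
    ``p_gd`` may vary with the copy number (one value per state).
    """
    _check_basic_params(params)
    N, p = params.N, params.p
    pgd = params.p_gd_vector()
    i = np.arange(1, N + 1)
    diag = 1.0 - i * p - pgd
    if np.any(diag < 0):
        bad = int(i[np.argmax(diag < 0)])
        raise InvalidParameterError(
            f"p + p_gd too large: stay probability of state {bad} is negative "
            f"({diag[bad - 1]:.6g})"
        )
    basic = build_basic(params)
    T = basic.T.copy()
    death = basic.death_mass.copy()
    T[i - 1, i - 1] -= pgd
    for idx, copies in enumerate(i):
        target = 2 * copies
        if target <= N:
            T[idx, target - 1] += pgd[idx] / 2.0
            death[idx] += pgd[idx] / 2.0
        else:
            death[idx] += pgd[idx]
    kind = "gd"
    if scored:
        q = params.C * params.mu ** i.astype(float)
        rowsum = T.sum(axis=1)
        T = q[:, None] * T
        death = 1.0 - q * rowsum
        kind = "gd_scored"
    return ChainMatrices(kind, list(range(1, N + 1)), T, death, params)


def build_inactivation(params: ChainParams) -> ChainMatrices:
    """Early-tumor chain AX with tolerance-gene states sigma and tau.

    Before gene X is inactivated, any missegregation among the cell's 46
    chromosome copies is lethal; a copy of gene X mutates with rate ``m_r``
    per generation. State ``sigma`` has two active copies of X, ``tau`` one
    active and one mutated copy; once no active copy remains the cell
    behaves as the scored chain on states 1..N.
    """
    p, m_r = params.p, params.m_r
    no_misseg = (1.0 - p) ** (2 * N_CHROMOSOMES)
    if no_misseg - 2.0 * m_r < 0:
        raise InvalidParameterError(
            f"(1-p)^46 - 2*m_r = {no_misseg - 2 * m_r:.6g} < 0: the sigma state's "
            "stay probability would be negative"
        )
    scored = build_scored(params)
    N = params.N
    q2 = params.C * params.mu**2
    n = N + 2
    T = np.zeros((n, n))
    T[2:, 2:] = scored.T
    # sigma row: survive q(2); die unless none of the 46 copies missegregates;
    # either active copy of X may mutate (prob ~ 2*m_r), sending it to tau.
    T[0, 0] = (no_misseg - 2.0 * m_r) * q2
    T[0, 1] = 2.0 * m_r * q2
    # tau row: the remaining active copy mutates (-> state 2) with prob m_r,
    # or missegregates so that a random daughter keeps no active copy
    # (-> state 1) with prob p/2.
    T[1, 1] = (no_misseg - m_r) * q2
    T[1, 2] = (p / 2.0) * q2
    if N >= 2:
        T[1, 3] = m_r * q2
    death = 1.0 - T.sum(axis=1)
    states: list = ["sigma", "tau", *range(1, N + 1)]
    return ChainMatrices("ax", states, T, death, params)


def load_score_table(path: str | Path | None = None) -> ScoreTable:
    """Read a score table from a 3-column TSV (chromosome, score, mu).

    With ``path=None`` the packaged table of experimentally derived human
    chromosome scores is returned.
    """
    import pandas as pd

    if path is None:
        from importlib.resources import files

        path = files("karyomc.data").joinpath("chromosome_scores.tsv")
        with path.open("r") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    expected_cols = ["chromosome", "score", "mu"]
    if list(df.columns) != expected_cols:
        raise ValueError(
            f"score table must have columns {expected_cols}, got {list(df.columns)}"
        )
    for col in ("score", "mu"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"non-numeric value in column {col!r} (line {row})")
    labels = df["chromosome"].astype(int).tolist()
    dupes = {k for k in labels if labels.count(k) > 1}
    if dupes:
        raise ValueError(f"duplicate chromosome labels: {sorted(dupes)}")
    missing = set(range(1, max(len(labels), N_CHROMOSOMES) + 1)) - set(labels)
    if missing:
        raise ValueError(f"missing chromosome rows: {sorted(missing)}")
    return ScoreTable(
        tuple(labels),
        tuple(df["score"].astype(float)),
        tuple(df["mu"].astype(float)),
    )
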