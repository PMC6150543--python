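"""Quasi-stationary analysis of the copy-number chains.

The chains built in :mod:`karyomc.chain_models` are absorbing, so their
stationary distribution is trivially concentrated on the dead state. The
biologically meaningful object is the limiting distribution *conditional on
viability*: the left Perron eigenvector of the sub-stochastic block,
normalized to sum 1 (the quasi-stationary distribution).

Because the blocks are tridiagonal, their characteristic polynomials obey a
three-term recurrence and the Perron eigenvector has a closed form in terms
of the lower-order polynomials evaluated at the Perron root. This module
implements that closed form (the production path) alongside a dense
eigensolver (:func:`quasi_stationary_numeric`) used as an independent
cross-check.

For the basic chain, ``M = I + p*J`` with a p-independent drift matrix
``J``: the conditional limit does not depend on the missegregation rate at
all, only on the copy-number cap ``N``. With chromosome scores the limit
depends on both ``p`` and ``mu`` (but never on the constant ``C``, which
rescales the whole matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import scipy.linalg

from .chain_models import ChainMatrices

__all__ = [
    "CharPoly",
    "QuasiStationaryResult",
    "char_poly_basic",
    "char_poly_scored",
    "largest_root",
    "limiting_basic",
    "limiting_scored",
    "quasi_stationary_numeric",
    "growth_rate",
    "mixing_estimate",
]


class NumericalFailureError(RuntimeError):
    """A spectral computation failed to converge or returned garbage."""


@dataclass(frozen=True)
class CharPoly:
    """Characteristic polynomials P_0..P_N of a nested tridiagonal family.

    ``polys[n]`` holds the coefficients of P_n in ascending degree order;
    exact rationals for the basic (drift) family, floats otherwise. P_n is
    monic of degree exactly n.
    """

    polys: tuple[tuple, ...]
    kind: str

    @property
    def N(self) -> int:
        return len(self.polys) - 1

    @property
    def coefficients(self) -> tuple:
        """Ascending coefficients of the top polynomial P_N."""
        return self.polys[-1]

    def evaluate(self, x: float, n: int | None = None) -> float:
        """Horner evaluation of P_n (default P_N) at a float point."""
        coeffs = self.polys[self.N if n is None else n]
        acc = 0.0
        for c in reversed(coeffs):
            acc = acc * x + float(c)
        return acc

    def derivative_at(self, x: float, n: int | None = None) -> float:
        coeffs = self.polys[self.N if n is None else n]
        acc = 0.0
        for k in range(len(coeffs) - 1, 0, -1):
            acc = acc * x + k * float(coeffs[k])
        return acc


def _poly_mul_linear(poly: list, a, b) -> list:
    """Multiply ascending-coefficient poly by (b + a*x)."""
    out = [poly[0] * b]
    for k in range(1, len(poly)):
        out.append(poly[k] * b + poly[k - 1] * a)
    out.append(poly[-1] * a)
    return out


def _poly_sub_scaled(poly: list, other: list, factor) -> list:
    out = list(poly)
    for k, c in enumerate(other):
        out[k] = out[k] - factor * c
    return out


def char_poly_basic(N: int) -> CharPoly:
    """Characteristic polynomials of the drift matrix J, in exact rationals.

    Three-term recurrence (from expanding the tridiagonal determinant along
    its last row): ``P_n(x) = (x + n) P_{n-1}(x) - n(n-1)/4 * P_{n-2}(x)``
    with ``P_0 = 1`` and ``P_1 = x + 1``. For N = 8 the top polynomial is
    x^8 + 36x^7 + 504x^6 + 3528x^5 + 13230x^4 + 26460x^3 + 26460x^2
    + 11340x + 2835/2.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    polys: list[list[Fraction]] = [[Fraction(1)], [Fraction(1), Fraction(1)]]
    for n in range(2, N + 1):
        p = _poly_mul_linear(polys[n - 1], Fraction(1), Fraction(n))
        p = _poly_sub_scaled(p, polys[n - 2] + [Fraction(0), Fraction(0)],
                             Fraction(n * (n - 1), 4))
        polys.append(p)
    return CharPoly(tuple(tuple(p) for p in polys), "basic")


def char_poly_scored(N: int, p: float, mu: float) -> CharPoly:
    """Characteristic polynomials of the scored matrix A (with C = 1).

    Recurrence: ``P_n(x) = (x - mu^n (1 - n p)) P_{n-1}(x)
    - mu^(2n-1) p^2 n(n-1)/4 * P_{n-2}(x)`` with ``P_0 = 1`` and
    ``P_1 = x - mu (1 - p)``. Exact rational arithmetic is used when both
    ``p`` and ``mu`` are given as :class:`fractions.Fraction`.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    exact = isinstance(p, Fraction) and isinstance(mu, Fraction)
    one = Fraction(1) if exact else 1.0
    polys = [[one], [-mu * (1 - p) * one, one]]
    for n in range(2, N + 1):
        lin = _poly_mul_linear(polys[n - 1], one, -(mu**n) * (1 - n * p))
        factor = mu ** (2 * n - 1) * p * p * n * (n - 1) / 4
        if exact:
            factor = Fraction(factor)
        poly = _poly_sub_scaled(lin, polys[n - 2] + [0 * one, 0 * one], factor)
        polys.append(poly)
    return CharPoly(tuple(tuple(q) for q in polys), "scored")


def largest_root(poly: CharPoly, x0: float | None = None) -> float:
    """Largest real root of P_N by Newton iteration from above.

    All the matrices behind these polynomials are similar to symmetric
    tridiagonal matrices, so the spectrum is real and simple; Newton started
    at any point above the largest root converges monotonically to it.
    """
    if x0 is None:
        # Cauchy bound on root moduli for a monic polynomial
        coeffs = [float(c) for c in poly.coefficients]
        x0 = 1.0 + max(abs(c) for c in coeffs[:-1])
    x = float(x0)
    for _ in range(200):
        f = poly.evaluate(x)
        fp = poly.derivative_at(x)
        if fp == 0.0:
            raise NumericalFailureError("zero derivative in Newton iteration")
        step = f / fp
        x_new = x - step
        if abs(step) < 1e-15 * max(1.0, abs(x)):
            x = x_new
            break
        x = x_new
    else:
        raise NumericalFailureError("Newton iteration did not converge")
    scale = max(abs(float(c)) * abs(x) ** k for k, c in enumerate(poly.coefficients))
    if abs(poly.evaluate(x)) > 1e-10 * max(scale, 1.0):
        raise NumericalFailureError(
            f"largest-root residual too large: P({x}) = {poly.evaluate(x):.3g}"
        )
    return x


def _basic_scaled_eval(N: int, x: float) -> tuple[list[float], list[float]]:
    """Evaluate the scaled polynomials Phat_n = P_n / n! of J at x.

    The scaled recurrence ``Phat_n = ((x+n)/n) Phat_{n-1} - Phat_{n-2}/4``
    keeps every intermediate value of moderate size, so the Perron pair of
    J is computable for N in the hundreds without overflow.
    """
    ph = [1.0, x + 1.0]
    dph = [0.0, 1.0]
    for n in range(2, N + 1):
        ph.append((x + n) / n * ph[n - 1] - 0.25 * ph[n - 2])
        dph.append(ph[n - 1] / n + (x + n) / n * dph[n - 1] - 0.25 * dph[n - 2])
    return ph, dph


def _alpha_basic(N: int) -> float:
    """Largest eigenvalue of J via Newton on the scaled recurrence.

    Gershgorin puts every eigenvalue of J in [-2N, 0]; P_N(0) > 0, so Newton
    from 0 descends monotonically onto the largest root.
    """
    x = 0.0
    for _ in range(200):
        ph, dph = _basic_scaled_eval(N, x)
        step = ph[N] / dph[N]
        x -= step
        if abs(step) < 1e-14 * max(1.0, abs(x)):
            return x
    raise NumericalFailureError("Newton failed for the drift Perron root")


def _scored_eval(N: int, p: float, mu: float, x: float) -> tuple[list[float], list[float]]:
    """Evaluate the scaled scored polynomials Phat_n = P_n / s_n at x.

    With the scale ``s_n = n! (p/2)^n mu^(n(n+1)/2)`` the recurrence becomes
    ``Phat_n = (x - mu^n (1-np)) / (n (p/2) mu^n) * Phat_{n-1} - Phat_{n-2}``
    and every intermediate stays O(1): the raw P_n shrink like p^n and lose
    all precision to cancellation at small missegregation rates.
    """
    c1 = (x - mu * (1.0 - p)) / ((p / 2.0) * mu)
    P = [1.0, c1]
    dP = [0.0, 1.0 / ((p / 2.0) * mu)]
    for n in range(2, N + 1):
        scale = n * (p / 2.0) * mu**n
        c = (x - mu**n * (1.0 - n * p)) / scale
        P.append(c * P[n - 1] - P[n - 2])
        dP.append(P[n - 1] / scale + c * dP[n - 1] - dP[n - 2])
    return P, dP


def _alpha_scored(N: int, p: float, mu: float) -> float:
    """Largest eigenvalue of A (C = 1) via Newton on the recurrence.

    Row i of A sums to mu^i, so Gershgorin bounds the spectrum above by
    max_i mu^i; Newton from just above that bound descends monotonically.
    """
    x = max(mu, mu**N) * (1.0 + 1e-9) + 1e-12
    for _ in range(200):
        P, dP = _scored_eval(N, p, mu, x)
        step = P[N] / dP[N]
        x -= step
        if abs(step) < 1e-15 * max(1.0, abs(x)):
            return x
    raise NumericalFailureError("Newton failed for the scored Perron root")


@dataclass(frozen=True)
class QuasiStationaryResult:
    """Limiting conditional (quasi-stationary) distribution of a chain.

    Attributes
    ----------
    rho : float
        Largest eigenvalue of the sub-stochastic block (the per-generation
        survival factor in the quasi-stationary regime). For the closed-form
        basic result this is the drift eigenvalue ``alpha`` itself.
    alpha : float
        Perron root in the parameter-free convention: the largest eigenvalue
        of J (basic) or of A with C = 1 (scored).
    rho2 : float or None
        Second-largest eigenvalue modulus of the block.
    v : numpy.ndarray
        Limiting distribution over the non-absorbing states (sums to 1).
    states : list
        State labels aligned with ``v``.
    mean_copies : float
        Mean copy number under ``v`` (numeric states only, renormalized).
    mode : int
        Modal copy number; ties broken toward the smaller copy number.
    mixing_estimate : float or None
        ``1 / (1 - rho2/rho)``, a proxy for the number of generations needed
        to approach ``v``.
    reducible : bool
        True when the Perron eigenvector has (numerically) zero entries, as
        happens for the ax chain whose sigma/tau states are transient.
    """

    rho: float
    alpha: float
    rho2: float | None
    v: np.ndarray
    states: list
    mean_copies: float
    mode: int
    mixing_estimate: float | None
    reducible: bool = False


def _summarize(v: np.ndarray, states: Sequence) -> tuple[float, int]:
    labels = np.array(
        [s if isinstance(s, (int, np.integer)) else -1 for s in states]
    )
    numeric = labels > 0
    mass = v[numeric].sum()
    if mass <= 0:
        return math.nan, -1
    w = v[numeric] / mass
    copies = labels[numeric].astype(float)
    mean = float(np.dot(copies, w))
    mode = int(copies[int(np.argmax(w))])  # argmax takes the first = smallest
    return mean, mode


def _result_from_formula(
    alpha: float,
    u: np.ndarray,
    N: int,
    rho: float,
    rho2: float | None,
) -> QuasiStationaryResult:
    if np.any(u <= 0):
        raise NumericalFailureError(
            "closed-form Perron eigenvector has non-positive entries"
        )
    v = u / u.sum()
    states = list(range(1, N + 1))
    mean, mode = _summarize(v, states)
    mix = mixing_estimate(rho, rho2) if rho2 is not None else None
    return QuasiStationaryResult(rho, alpha, rho2, v, states, mean, mode, mix)


def limiting_basic(N: int) -> QuasiStationaryResult:
    """Limiting conditional distribution of the basic chain (closed form).

    ``v_i`` is proportional to ``2^(i-1)/i! * P_{i-1}(alpha)`` with ``alpha``
    the largest root of P_N. Independent of the missegregation rate p and of
    the founder's copy number; the modal copy number is always 1 but the
    mean grows with the cap N (about 2.97 at N = 8).
    """
    alpha = _alpha_basic(N)
    ph, _ = _basic_scaled_eval(N, alpha)
    # u_i = 2^(i-1)/i! * P_{i-1}(alpha) = 2^(i-1)/i * Phat_{i-1}(alpha)
    u = np.array([2.0 ** (i - 1) / i * ph[i - 1] for i in range(1, N + 1)])
    rho2 = _second_eigenvalue_drift(N) if N >= 2 else None
    return _result_from_formula(alpha, u, N, alpha, rho2)


def limiting_scored(N: int, p: float, mu: float) -> QuasiStationaryResult:
    """Limiting conditional distribution of the scored chain (closed form).

    ``v_i`` is proportional to
    ``2^(i-1) P_{i-1}(alpha) / (i! p^(i-1) mu^((i^2+i-2)/2))`` with ``alpha``
    the largest root of the scored P_N (eigenvector normalization forces the
    powers of p and mu into the denominator, and the limit reduces to the
    basic one when mu = 1). The result does not depend on the constant C.
    """
    if not 0 < p <= 1.0 / N:
        raise ValueError(f"p must lie in (0, 1/N]; got p={p}, N={N}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    alpha = _alpha_scored(N, p, mu)
    u = _scored_eigenvector(N, p, mu, alpha)
    rho2 = _second_eigenvalue_scored(N, p, mu) if N >= 2 else None
    return _result_from_formula(alpha, u, N, alpha, rho2)


def _scored_eigenvector(N: int, p: float, mu: float, alpha: float) -> np.ndarray:
    """Left Perron eigenvector of A (C = 1), unnormalized.

    The forward three-term recurrence in the copy number is exactly the
    closed form ``u_i = 2^(i-1) P_{i-1}(alpha) / (i! p^(i-1)
    mu^((i^2+i-2)/2))``, but the eigenvector is the *minimal* solution of
    the recurrence wherever its entries decay (steeply so for small p with
    mu < 1), and a one-directional sweep loses it to rounding. So the sweep
    is run from both ends and spliced at the entry where both directions are
    reliable (the peak of the product), the standard treatment for
    tridiagonal eigenvectors from an approximate eigenvalue.
    """
    i = np.arange(1, N + 1, dtype=float)
    diag = (1.0 - i * p) * mu**i  # a_{i,i}
    up = i * p * mu**i / 2.0  # a_{i,i+1}
    down = (i + 1.0) * p * mu ** (i + 1.0) / 2.0  # a_{i+1,i}
    if N == 1:
        return np.array([1.0])
    f = np.zeros(N)
    f[0] = 1.0
    f[1] = (alpha - diag[0]) * f[0] / down[0]
    for k in range(2, N):
        f[k] = ((alpha - diag[k - 1]) * f[k - 1] - up[k - 2] * f[k - 2]) / down[k - 1]
    b = np.zeros(N)
    b[N - 1] = 1.0
    b[N - 2] = (alpha - diag[N - 1]) * b[N - 1] / up[N - 2]
    for k in range(N - 3, -1, -1):
        b[k] = ((alpha - diag[k + 1]) * b[k + 1] - down[k + 1] * b[k + 2]) / up[k]
    with np.errstate(over="ignore", invalid="ignore"):
        m = int(np.nanargmax(np.where(np.isfinite(f * b), np.abs(f * b), -np.inf)))
    v = np.empty(N)
    v[: m + 1] = f[: m + 1] / f[m]
    v[m:] = b[m:] / b[m]
    return v


def _second_eigenvalue_drift(N: int) -> float:
    """Second-largest eigenvalue of J via its symmetric tridiagonalization."""
    i = np.arange(1, N + 1, dtype=float)
    diag = -i
    off = np.sqrt(i[:-1] * i[1:]) / 2.0
    w = scipy.linalg.eigh_tridiagonal(diag, off, eigvals_only=True)
    return float(w[-2])


def _second_eigenvalue_scored(N: int, p: float, mu: float) -> float:
    i = np.arange(1, N + 1, dtype=float)
    diag = (1.0 - i * p) * mu**i
    upper = i[:-1] * p * mu ** i[:-1] / 2.0
    lower = i[1:] * p * mu ** i[1:] / 2.0
    off = np.sqrt(upper * lower)
    w = scipy.linalg.eigh_tridiagonal(diag, off, eigvals_only=True)
    return float(w[-2])


def quasi_stationary_numeric(chain: ChainMatrices) -> QuasiStationaryResult:
    """Quasi-stationary distribution by dense left eigendecomposition.

    Works for every chain kind; used as the independent numerical oracle for
    the closed-form routes and as the only route for the duplication and ax
    chains. For the ax chain the sigma/tau states are transient whenever
    m_r > 0, so the block is reducible and the Perron vector carries no mass
    there; this is reported via ``reducible`` rather than as an error.
    """
    T = np.asarray(chain.T, dtype=float)
    w, vl = scipy.linalg.eig(T.T)
    order = np.argsort(w.real)
    top = order[-1]
    rho = float(w[top].real)
    if abs(w[top].imag) > 1e-9 * max(1.0, abs(rho)):
        raise NumericalFailureError("Perron eigenvalue came out complex")
    v = vl[:, top].real
    if v.sum() < 0:
        v = -v
    tol = 1e-12 * max(1.0, np.abs(v).max())
    if np.any(v < -1e-8 * np.abs(v).max()):
        # mixed signs beyond roundoff: not a Perron vector
        raise NumericalFailureError("Perron eigenvector has mixed signs")
    v = np.clip(v, 0.0, None)
    v = v / v.sum()
    reducible = bool(np.any(v <= tol))
    mods = np.sort(np.abs(w))
    rho2 = float(mods[-2]) if len(mods) >= 2 else None
    mean, mode = _summarize(v, chain.states)
    mix = mixing_estimate(rho, rho2) if rho2 is not None else None
    alpha = rho
    if chain.params is not None and chain.kind in ("scored", "gd_scored"):
        alpha = rho / chain.params.C  # back to the C = 1 convention
    return QuasiStationaryResult(
        rho, alpha, rho2, v, list(chain.states), mean, mode, mix, reducible
    )


def mixing_estimate(rho: float, rho2: float) -> float:
    """Generations-to-mix proxy 1 / (1 - rho2/rho) from the spectral gap."""
    return 1.0 / (1.0 - rho2 / rho)


def growth_rate(
    alpha: float | Sequence[float],
    p: float | None = None,
    kind: str = "basic",
    n_chromosomes: int = 23,
) -> tuple[float, float]:
    """Limiting per-generation growth factor of the viable population.

    basic kind
        ``alpha`` is the drift Perron root; the viable count multiplies by
        ``2 (1 + p*alpha)^23`` per generation once karyotypes follow the
        limiting distribution.
    full kind
        ``alpha`` is the sequence of 23 per-chromosome Perron eigenvalues of
        the scored chains (including their C_k factors, whose product is
        e^c); the rate is ``2 * prod(alpha_k)``.

    Returns ``(rate, threshold)`` where the threshold ``1/rate`` is the
    survival-culling fraction below which the expected viable count decays
    to zero.
    """
    if kind == "basic":
        if p is None:
            raise ValueError("the basic growth rate needs the missegregation rate p")
        rate = 2.0 * (1.0 + p * float(alpha)) ** n_chromosomes
    elif kind == "full":
        alphas = np.asarray(alpha, dtype=float)
        rate = 2.0 * float(np.prod(alphas))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return rate, 1.0 / rate
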