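"""Raw, central, and discrete orthogonal Hahn moments of 2-D grids.

Three moment families characterise a numeric matrix ``f(i, j)``:

* raw moments ``M_xy = sum_i sum_j i^x j^y f(i, j)`` about the origin
  (zero-based indices, one convention shared by all families);
* central moments ``mu_xy`` about the centroid ``(M10/M00, M01/M00)``,
  which are translation invariant;
* Hahn moments, projections onto the orthonormalised discrete Hahn
  polynomial basis ``h~_n^{mu,nu}(r, N)`` on the support ``r = 0..N-1``.

The Hahn family with ``mu = nu = 0`` reduces to the discrete Chebyshev
polynomials (uniform weight).  The basis table is validated at construction
against the orthonormality identity ``sum_r h~_m(r) h~_n(r) = delta_mn``,
which is the ground truth the weighting and square-norm factors exist to
achieve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

MomentFamily = Literal["raw", "central", "hahn"]
OrderScheme = Literal["triangle", "grid"]


class MomentError(ValueError):
    """Invalid input to a moment computation."""


class BasisError(ArithmeticError):
    """Hahn basis construction failed (overflow or orthonormality violation)."""


def moment_orders(order_max: int, scheme: OrderScheme = "triangle") -> list[tuple[int, int]]:
    """Enumerate moment orders (x, y), lexicographic (x ascending, then y).

    ``triangle``: all x + y <= order_max (10 pairs for order 3).
    ``grid``: all x, y in {0..order_max} (16 pairs for order 3).
    """
    if order_max < 0:
        raise MomentError("order_max must be >= 0")
    if scheme == "triangle":
        return [(x, y) for x in range(order_max + 1) for y in range(order_max + 1 - x)]
    if scheme == "grid":
        return [(x, y) for x in range(order_max + 1) for y in range(order_max + 1)]
    raise ValueError(f"unknown order scheme {scheme!r}")


@dataclass(frozen=True)
class MomentSet:
    """Ordered moments of one family: entries are (x-order, y-order, value)."""

    family: MomentFamily
    order_max: int
    entries: tuple[tuple[int, int, float], ...]

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.entries])

    def get(self, x: int, y: int) -> float:
        for ex, ey, v in self.entries:
            if (ex, ey) == (x, y):
                return v
        raise KeyError((x, y))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["x", "y", "value"]).assign(
            family=self.family
        )[["family", "x", "y", "value"]]


def _as_grid(M) -> np.ndarray:
    values = getattr(M, "values", M)
    grid = np.asarray(values, dtype=float)
    if grid.ndim != 2 or grid.size == 0:
        raise MomentError("moment input must be a non-empty 2-D grid")
    return grid


def raw_moments(M, order_max: int, scheme: OrderScheme = "triangle") -> MomentSet:
    """Raw (origin-referenced) moments M_xy = sum i^x j^y f(i,j), zero-based."""
    grid = _as_grid(M)
    rows, cols = grid.shape
    i = np.arange(rows, dtype=float)
    j = np.arange(cols, dtype=float)
    orders = moment_orders(order_max, scheme)
    entries = tuple(
        (x, y, float((i**x) @ grid @ (j**y))) for x, y in orders
    )
    return MomentSet(family="raw", order_max=order_max, entries=entries)


def centroid(M) -> tuple[float, float]:
    """Centroid (p_bar, q_bar) = (M10/M00, M01/M00); undefined when M00 == 0."""
    grid = _as_grid(M)
    m00 = grid.sum()
    if m00 <= 0:
        raise MomentError("centroid undefined: total mass M00 is not positive")
    rows, cols = grid.shape
    p_bar = float(np.arange(rows) @ grid.sum(axis=1)) / m00
    q_bar = float(grid.sum(axis=0) @ np.arange(cols)) / m00
    return p_bar, q_bar


def central_moments(M, order_max: int, scheme: OrderScheme = "triangle") -> MomentSet:
    """Centroid-referenced moments mu_xy; translation invariant by construction."""
    grid = _as_grid(M)
    p_bar, q_bar = centroid(grid)
    rows, cols = grid.shape
    dp = np.arange(rows, dtype=float) - p_bar
    dq = np.arange(cols, dtype=float) - q_bar
    orders = moment_orders(order_max, scheme)
    entries = tuple(
        (x, y, float((dp**x) @ grid @ (dq**y))) for x, y in orders
    )
    return MomentSet(family="central", order_max=order_max, entries=entries)


# --- Hahn basis -------------------------------------------------------------


def pochhammer(a: float, k: int) -> float:
    """Rising factorial (a)_k = a (a+1) ... (a+k-1); (a)_0 = 1.

    Uses the Gamma-function form exp(lgamma(a+k) - lgamma(a)) for a > 0 and a
    direct product otherwise (negative arguments are legal and arise in the
    terminating hypergeometric sums, e.g. (-n)_k).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 1.0
    if a > 0:
        return math.exp(math.lgamma(a + k) - math.lgamma(a))
    out = 1.0
    for i in range(k):
        out *= a + i
    return out


def hahn_weight(r: int, N: int, mu: float = 0.0, nu: float = 0.0) -> float:
    """Orthogonality weight rho(r) of the Hahn family on {0..N-1}.

    rho(r) = Gamma(nu+r+1) Gamma(mu+N-r) / (Gamma(r+1) Gamma(N-r)); uniform
    (rho = 1) in the discrete Chebyshev case mu = nu = 0.
    """
    return math.exp(
        math.lgamma(nu + r + 1)
        + math.lgamma(mu + N - r)
        - math.lgamma(r + 1)
        - math.lgamma(N - r)
    )


def _hahn_sum(n: int, r: float, N: int, mu: float, nu: float) -> float:
    # terminating 3F2(-n, n+mu+nu+1, -r; nu+1, 1-N; 1), term-ratio recurrence
    s = 1.0
    t = 1.0
    for k in range(n):
        t *= ((-n + k) * (n + mu + nu + 1 + k) * (-r + k)) / (
            (nu + 1 + k) * (1 - N + k) * (k + 1)
        )
        s += t
    return s


def hahn_polynomial(n: int, r: int, N: int, mu: float = 0.0, nu: float = 0.0) -> float:
    """Value of the discrete Hahn polynomial h_n^{mu,nu}(r, N).

    Defined as (-1)^n (N+nu-1)_n (N-1)_n 3F2(-n, n+mu+nu+1, -r; nu+1, 1-N; 1);
    a polynomial of degree n in r, orthogonal on r = 0..N-1 under
    :func:`hahn_weight`.  The sign convention makes the mu = nu = 0 case agree
    with the discrete Chebyshev polynomials with positive leading coefficient.
    """
    if not 0 <= n < N:
        raise MomentError(f"order n={n} must satisfy 0 <= n < N={N}")
    if not 0 <= r < N:
        raise MomentError(f"support point r={r} must satisfy 0 <= r < N={N}")
    pre = pochhammer(N + nu - 1, n) * pochhammer(N - 1, n)
    return (-1.0) ** n * pre * _hahn_sum(n, float(r), N, mu, nu)


@dataclass(frozen=True)
class HahnBasis:
    """Orthonormalised Hahn basis table h~_n(r) for n = 0..order_max, r = 0..N-1."""

    N: int
    order_max: int
    mu: float
    nu: float
    table: np.ndarray = field(repr=False)  # (order_max+1, N)
    d2: np.ndarray = field(repr=False)  # per-order square norms of h_n
    rho: np.ndarray = field(repr=False)  # weights rho(r)


def build_hahn_basis(
    N: int, order_max: int, mu: float = 0.0, nu: float = 0.0, tol: float = 1e-8
) -> HahnBasis:
    """Build the normalized table h~_n(r) = h_n(r) sqrt(rho(r) / d_n^2).

    The square norm d_n^2 = sum_r h_n(r)^2 rho(r) is computed directly, and
    the finished table must satisfy the orthonormality identity (Gram matrix
    equal to the identity within ``tol``) or construction fails.
    """
    if N < 1:
        raise MomentError("N must be >= 1")
    if order_max >= N:
        raise MomentError(f"order_max={order_max} must be < N={N}")
    rho = np.array([hahn_weight(int(x), N, mu, nu) for x in range(N)])
    raw = np.empty((order_max + 1, N))
    for n in range(order_max + 1):
        sign = (-1.0) ** n
        raw[n] = sign * np.array([_hahn_sum(n, float(x), N, mu, nu) for x in range(N)])
    if not np.all(np.isfinite(raw)):
        raise BasisError(
            "non-finite Hahn polynomial values; evaluate in log space (larger N "
            "requires the scaled accumulation path)"
        )
    weighted = raw * np.sqrt(rho)
    norms = np.sqrt((weighted**2).sum(axis=1))
    table = weighted / norms[:, None]
    gram = table @ table.T
    dev = float(np.max(np.abs(gram - np.eye(order_max + 1))))
    if dev > tol:
        raise BasisError(f"Hahn basis orthonormality violated: max deviation {dev:.3e}")
    # d2 on the scale of hahn_polynomial (prefactor included) so that
    # h~ = h * sqrt(rho / d2) holds for the public polynomial values.
    pre = np.array(
        [pochhammer(N + nu - 1, n) * pochhammer(N - 1, n) for n in range(order_max + 1)]
    )
    d2 = (pre * norms) ** 2
    return HahnBasis(N=N, order_max=order_max, mu=mu, nu=nu, table=table, d2=d2, rho=rho)


def hahn_transform(M, basis: HahnBasis) -> np.ndarray:
    """Full grid of Hahn moments H_ij = sum_q sum_p beta_pq h~_i(q) h~_j(p).

    Index i runs over the column coordinate q and j over the row coordinate p.
    Returns an (order_max+1) x (order_max+1) array.
    """
    grid = _as_grid(M)
    if grid.shape != (basis.N, basis.N):
        raise MomentError(
            f"matrix shape {grid.shape} does not match basis support N={basis.N}"
        )
    A = basis.table
    return (A @ grid @ A.T).T


def hahn_moments(
    M, basis: HahnBasis, order_max: int | None = None, scheme: OrderScheme = "triangle"
) -> MomentSet:
    """Hahn moments of a square grid as a :class:`MomentSet`.

    Orders beyond the basis support (possible only for tiny grids with
    N <= order_max) are reported as 0 so the entry layout stays fixed.
    """
    if order_max is None:
        order_max = basis.order_max
    H = hahn_transform(M, basis)
    entries = tuple(
        (x, y, float(H[x, y]) if max(x, y) <= basis.order_max else 0.0)
        for x, y in moment_orders(order_max, scheme)
    )
    return MomentSet(family="hahn", order_max=order_max, entries=entries)


def reconstruct_from_hahn(H: np.ndarray, basis: HahnBasis) -> np.ndarray:
    """Inverse of :func:`hahn_transform` for a full-order (N x N) moment grid.

    beta_pq = sum_i sum_j H_ij h~_i(q) h~_j(p); exact (orthonormal transform)
    when H was produced at full order order_max = N - 1.
    """
    H = np.asarray(H, dtype=float)
    if H.shape != (basis.order_max + 1, basis.order_max + 1):
        raise MomentError(
            f"moment grid shape {H.shape} does not match basis orders "
            f"0..{basis.order_max}"
        )
    A = basis.table
    return (A.T @ H @ A).T


def write_moments_tsv(path: str | Path, sets: Sequence[MomentSet]) -> None:
    """Serialize moment sets to TSV with columns family, x, y, value."""
    frame = pd.concat([s.to_frame() for s in sets], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)
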