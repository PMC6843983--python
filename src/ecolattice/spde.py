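"""Matern Gaussian Markov random fields on a regular lattice via the SPDE link.

A stationary Matern field with smoothness nu = 1 in two dimensions can be
represented as the solution of the SPDE

    (kappa^2 - Delta) u(s) = W(s) / tau,

discretised with linear finite elements. On a regular lattice (the analysis
grid itself, squares split into right triangles) this yields a sparse
precision matrix

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G),

with C the mass-lumped (diagonal) mass matrix and G the stiffness matrix.
The marginal variance of the stationary solution is sigma^2 =
1 / (4 pi kappa^2 tau^2), and kappa = sqrt(8 nu) / rho where rho is the
distance at which the correlation has fallen to roughly 0.1.

The lattice is padded with ghost rings so that boundary-induced variance
inflation does not reach the real cells; the field is reported at real
cells only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import kv

from .errors import AssemblyError, ConfigError, NumericalConditioningError

__all__ = [
    "MaternSpec",
    "PCPriorSpec",
    "LatticeMesh",
    "PrecisionOperator",
    "kappa_from_range",
    "tau_from_sd",
    "matern1_correlation",
    "build_precision",
    "sample_field",
    "pc_prior_logdensity",
]


@dataclass(frozen=True)
class MaternSpec:
    """Range and marginal standard deviation of a smoothness-1 Matern field.

    Parameters
    ----------
    range_m
        Correlation range rho (> 0), in the units of the coordinates
        (metres for projected lattices). Correlation at distance rho is
        about 0.14 under the kappa = sqrt(8)/rho convention.
    sd
        Marginal standard deviation sigma (>= 0). A value of exactly 0 is
        allowed by generators to switch the field off; the precision
        construction requires sd > 0.
    """

    range_m: float
    sd: float

    def __post_init__(self) -> None:
        if self.range_m <= 0:
            raise ConfigError(f"Matern range must be > 0, got {self.range_m}")
        if self.sd < 0:
            raise ConfigError(f"Matern sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class PCPriorSpec:
    """Penalised-complexity prior for (range, sd) of a Matern field.

    Encodes the two tail statements P(rho < rho0) = alpha_rho and
    P(sigma > sigma0) = alpha_sigma. The implied densities are
    pi(rho) = lam_r rho^-2 exp(-lam_r / rho) with lam_r = -ln(alpha_rho) rho0,
    and sigma ~ Exponential(lam_s) with lam_s = -ln(alpha_sigma) / sigma0.
    """

    rho0: float
    alpha_rho: float
    sigma0: float
    alpha_sigma: float

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.sigma0 <= 0:
            raise ConfigError("PC prior reference values must be > 0")
        if not (0 < self.alpha_rho < 1 and 0 < self.alpha_sigma < 1):
            raise ConfigError("PC prior tail probabilities must lie in (0, 1)")

    @property
    def lambda_rho(self) -> float:
        return -np.log(self.alpha_rho) * self.rho0

    @property
    def lambda_sigma(self) -> float:
        return -np.log(self.alpha_sigma) / self.sigma0


def kappa_from_range(range_m: float, nu: float = 1.0) -> float:
    """Inverse correlation length kappa = sqrt(8 nu) / rho."""
    if range_m <= 0:
        raise ConfigError(f"range must be > 0, got {range_m}")
    return float(np.sqrt(8.0 * nu) / range_m)


def tau_from_sd(sd: float, kappa: float) -> float:
    """Precision scale tau with marginal variance sigma^2 = 1/(4 pi kappa^2 tau^2)."""
    if sd <= 0:
        raise ConfigError(f"sd must be > 0, got {sd}")
    return float(1.0 / (sd * kappa * np.sqrt(4.0 * np.pi)))


def matern1_correlation(d, range_m: float):
    """Smoothness-1 Matern correlation r(d) = (kappa d) K1(kappa d), r(0) = 1."""
    kappa = kappa_from_range(range_m)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ConfigError("distances must be >= 0")
    x = kappa * d
    with np.errstate(invalid="ignore", over="ignore"):
        r = np.where(x > 0, x * kv(1, np.where(x > 0, x, 1.0)), 1.0)
    r = np.where(np.isfinite(r), r, 0.0)  # kv underflows to 0 for huge x
    return r if r.ndim else float(r)


class LatticeMesh:
    """Regular-lattice SPDE mesh: real cells plus ghost padding rings.

    Nodes sit at cell centroids of an (ny + 2 g) x (nx + 2 g) grid with the
    stated spacing; each square is split into two right triangles with a
    fixed diagonal. ``real_index`` maps row-major real cells (row, col with
    row 0 at the bottom) to mesh node indices.
    """

    def __init__(self, nx: int, ny: int, spacing: float, n_ghost: int = 2):
        if nx < 2 or ny < 2:
            raise ConfigError("lattice must be at least 2 x 2")
        if spacing <= 0:
            raise ConfigError("spacing must be > 0")
        if n_ghost < 0:
            raise ConfigError("n_ghost must be >= 0")
        self.nx, self.ny, self.spacing, self.n_ghost = nx, ny, float(spacing), n_ghost
        g = n_ghost
        self.nx_tot, self.ny_tot = nx + 2 * g, ny + 2 * g
        cols, rows = np.meshgrid(np.arange(self.nx_tot), np.arange(self.ny_tot))
        # real cell (0, 0) centroid at (spacing/2, spacing/2)
        self.coords = np.column_stack(
            [
                (cols.ravel() - g + 0.5) * self.spacing,
                (rows.ravel() - g + 0.5) * self.spacing,
            ]
        )
        self.n_nodes = self.nx_tot * self.ny_tot
        rr, cc = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        self.real_index = ((rr + g) * self.nx_tot + (cc + g)).ravel()

    @property
    def n_real(self) -> int:
        return self.nx * self.ny

    def triangles(self) -> np.ndarray:
        """(n_tri, 3) node indices; each grid square split along one diagonal."""
        nxt, nyt = self.nx_tot, self.ny_tot
        c, r = np.meshgrid(np.arange(nxt - 1), np.arange(nyt - 1))
        n00 = (r * nxt + c).ravel()
        n01, n10 = n00 + 1, n00 + nxt
        n11 = n10 + 1
        return np.vstack(
            [np.column_stack([n00, n01, n11]), np.column_stack([n00, n11, n10])]
        )


def _fem_matrices(mesh: LatticeMesh) -> tuple[np.ndarray, sp.csr_matrix]:
    """Mass-lumped mass vector C (diagonal) and stiffness matrix G."""
    tri = mesh.triangles()
    p = mesh.coords[tri]  # (n_tri, 3, 2)
    # edge vectors opposite each vertex: b_i = y_j - y_k, c_i = x_k - x_j
    j, k = [1, 2, 0], [2, 0, 1]
    b = p[:, j, 1] - p[:, k, 1]
    c = p[:, k, 0] - p[:, j, 0]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    area = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    ke = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (
        4.0 * area[:, None, None]
    )
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    G = sp.csr_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    G.sum_duplicates()
    G.eliminate_zeros()
    C = np.zeros(mesh.n_nodes)
    np.add.at(C, tri.ravel(), np.repeat(area / 3.0, 3))
    return C, G


class PrecisionOperator:
    """Sparse SPD precision of the lattice GMRF with a cached dense factor.

    The sparse matrix keeps the Markov (near-neighbour) structure inspectable
    and exportable; factorisation for sampling/log-determinants is dense,
    which is cheap at the lattice sizes this package targets (a few thousand
    nodes).
    """

    def __init__(self, Q: sp.csr_matrix, mesh: LatticeMesh, spec: MaternSpec):
        self.Q = Q
        self.mesh = mesh
        self.spec = spec
        self._chol: np.ndarray | None = None

    def _factor(self) -> np.ndarray:
        if self._chol is None:
            try:
                self._chol = np.linalg.cholesky(self.Q.toarray())
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise AssemblyError("precision matrix is not positive definite") from exc
        return self._chol

    @property
    def logdet(self) -> float:
        L = self._factor()
        return float(2.0 * np.sum(np.log(np.diag(L))))

    def solve(self, b: np.ndarray) -> np.ndarray:
        from scipy.linalg import cho_solve

        return cho_solve((self._factor(), True), b)

    def marginal_variance(self, nodes: np.ndarray | None = None) -> np.ndarray:
        """Diagonal of Q^-1 at the given nodes (default: all real cells)."""
        if nodes is None:
            nodes = self.mesh.real_index
        L = self._factor()
        out = np.empty(len(nodes))
        from scipy.linalg import cho_solve

        for i, node in enumerate(np.asarray(nodes)):
            e = np.zeros(self.Q.shape[0])
            e[node] = 1.0
            out[i] = cho_solve((L, True), e)[node]
        return out


def build_precision(
    mesh: LatticeMesh | tuple[int, int, float], spec: MaternSpec
) -> PrecisionOperator:
    """Assemble the SPDE precision Q = tau^2 (k^4 C + 2 k^2 G + G C^-1 G)."""
    if not isinstance(mesh, LatticeMesh):
        mesh = LatticeMesh(*mesh)
    if mesh.n_real < 4:
        raise ConfigError("lattice must have at least 4 cells")
    if spec.sd <= 0:
        raise ConfigError("field sd must be > 0 to build a precision")
    kappa = kappa_from_range(spec.range_m)
    tau = tau_from_sd(spec.sd, kappa)
    C, G = _fem_matrices(mesh)
    Cinv = sp.diags(1.0 / C)
    K = kappa**2 * sp.diags(C) + G
    Q = (tau**2) * (K @ Cinv @ K)
    Q = sp.csr_matrix((Q + Q.T) * 0.5)
    op = PrecisionOperator(Q, mesh, spec)
    op._factor()  # fail fast if not SPD
    return op


def sample_field(
    precision: PrecisionOperator,
    rng: np.random.Generator | int,
    n_samples: int = 1,
) -> np.ndarray:
    """Draw zero-mean GMRF samples; shape (n_samples, n_nodes).

    Uses the dense Cholesky factor L of Q and back-substitution
    x = L^-T z with z standard normal, the standard GMRF sampler.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = precision._factor()
    z = rng.standard_normal((precision.Q.shape[0], n_samples))
    from scipy.linalg import solve_triangular

    try:
        x = solve_triangular(L.T, z, lower=False)
    except Exception as exc:  # pragma: no cover
        raise NumericalConditioningError("back-solve failed") from exc
    return x.T


def pc_prior_logdensity(rho: float, sigma: float, pc: PCPriorSpec) -> float:
    """Joint log density of the PC prior at (rho, sigma); fields independent."""
    if rho <= 0 or sigma <= 0:
        raise ConfigError("rho and sigma must be > 0")
    lam_r, lam_s = pc.lambda_rho, pc.lambda_sigma
    log_rho = np.log(lam_r) - 2.0 * np.log(rho) - lam_r / rho
    log_sig = np.log(lam_s) - lam_s * sigma
    return float(log_rho + log_sig)
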