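"""Bayesian spatial Poisson regression of lattice species counts.

The model for cell i is

    O_i ~ Poisson(mu_i),      log mu_i = x_i' beta + u_i + v_i,

with u a smoothness-1 Matern GMRF (SPDE construction, PC prior on range and
marginal sd), v iid Gaussian heterogeneity (PC/exponential prior on its sd),
and independent zero-mean Gaussian priors on the coefficients beta.

Inference is a nested Laplace approximation in the spirit of INLA: for
fixed hyperparameters theta = (range, field sd, iid sd) the latent vector
(beta, u, v) is Gaussian-approximated at its conditional mode (Newton
iterations on the log posterior, which is concave); the Laplace-approximated
marginal posterior of theta is then either maximised (``method="laplace"``,
the fast path) or explored by random-walk Metropolis (``method="mcmc"``),
with latent draws taken from the conditional Gaussian in both cases. A soft
sum-to-zero constraint on the structured field separates it from the
intercept.

Relative risks exp(beta) and the per-cell excess surface exp(u + v) are
summarised draw-wise, so reported posterior means are means of exp, not exp
of means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import gammaln

from . import design as design_mod
from .errors import ConfigError, ConvergenceError, ValidationError
from .spde import (
    LatticeMesh,
    MaternSpec,
    PCPriorSpec,
    build_precision,
    pc_prior_logdensity,
)

__all__ = [
    "ModelSpec",
    "ModelData",
    "FittedModel",
    "model_data_from_cells",
    "poisson_loglik",
    "log_joint",
    "fit",
    "relative_risks",
    "excess_surface",
]

_ETA_BOUND = 30.0  # |log mu| cap inside the optimiser
_QUANTS = (0.025, 0.05, 0.5, 0.95, 0.975)


@dataclass
class ModelSpec:
    """Priors and inference settings for the lattice count model."""

    field: MaternSpec = dc_field(
        default_factory=lambda: MaternSpec(range_m=30_000.0, sd=0.5)
    )
    pc_field: PCPriorSpec | None = None  # default set from lattice extent at fit time
    iid_sd: float = 0.2  # initial value
    pc_iid: tuple[float, float] = (1.0, 0.01)  # P(iid sd > 1) = 0.01
    coef_prior_sd: float = 5.0
    include_field: bool = True
    include_iid: bool = True
    optimize_hyper: bool = True
    method: str = "laplace"  # "laplace" | "mcmc"
    n_draws: int = 1000
    chains: int = 4
    mcmc_iter: int = 300  # kept draws per chain
    mcmc_warmup: int = 150
    seed: int = 0
    sum_to_zero_sd: float | None = 1e-3
    max_opt_iter: int = 150
    rhat_limit: float = 1.05

    def __post_init__(self) -> None:
        if self.method not in ("laplace", "mcmc"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.n_draws < 1 or self.chains < 1:
            raise ConfigError("need >= 1 draw and >= 1 chain")
        if self.coef_prior_sd <= 0:
            raise ConfigError("coefficient prior sd must be > 0")


@dataclass
class ModelData:
    """Counts, design and lattice geometry for one fit."""

    counts: np.ndarray
    X: np.ndarray
    coef_names: list[str]
    mesh: LatticeMesh | None = None
    offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.counts.ndim != 1 or self.X.shape[0] != len(self.counts):
            raise ValidationError("counts and design rows disagree")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValidationError("counts must be non-negative integers")
        if self.X.shape[1] != len(self.coef_names):
            raise ValidationError("coef_names and design columns disagree")
        if self.mesh is not None and self.mesh.n_real != len(self.counts):
            raise ValidationError("mesh real-cell count and data length disagree")


def model_data_from_cells(
    cells: pd.DataFrame,
    schemes=None,
    continuous: tuple[str, ...] = (),
    n_ghost: int = 2,
) -> tuple[ModelData, list]:
    """Build ModelData from a cell table (row-major lattice order enforced)."""
    if "row" in cells.columns and "col" in cells.columns:
        cells = cells.sort_values(["row", "col"]).reset_index(drop=True)
        nx = int(cells["col"].max()) + 1
        ny = int(cells["row"].max()) + 1
    else:
        xs = np.unique(cells["x"])
        ys = np.unique(cells["y"])
        nx, ny = len(xs), len(ys)
        cells = cells.sort_values(["y", "x"]).reset_index(drop=True)
    if nx * ny != len(cells):
        raise ValidationError("cell table is not a complete regular lattice")
    xs = np.sort(np.unique(cells["x"]))
    spacing = float(np.min(np.diff(xs))) if len(xs) > 1 else 1.0
    if schemes is None:
        schemes = design_mod.default_schemes(cells)
    X, labels = design_mod.build_design(cells, schemes, continuous=continuous)
    mesh = LatticeMesh(nx, ny, spacing, n_ghost=n_ghost)
    data = ModelData(
        counts=cells["species_count"].to_numpy(),
        X=X,
        coef_names=labels,
        mesh=mesh,
    )
    return data, schemes


def poisson_loglik(counts, eta) -> float:
    """Sum of Poisson log pmfs with log-mean eta (normalising constant included)."""
    y = np.asarray(counts, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


# ---------------------------------------------------------------------------
# latent layout and Laplace machinery
# ---------------------------------------------------------------------------


class _Layout:
    """Index bookkeeping for the stacked latent vector [beta, u_mesh, v]."""

    def __init__(self, data: ModelData, spec: ModelSpec):
        self.p = data.X.shape[1]
        self.n = len(data.counts)
        self.has_u = spec.include_field and data.mesh is not None
        self.has_v = spec.include_iid
        self.m = data.mesh.n_nodes if self.has_u else 0
        self.d = self.p + self.m + (self.n if self.has_v else 0)
        if self.has_u:
            self.iu = self.p + data.mesh.real_index  # latent index per cell
        if self.has_v:
            self.iv = self.p + self.m + np.arange(self.n)


def _eta_of(z, data: ModelData, lay: _Layout) -> np.ndarray:
    eta = data.X @ z[: lay.p]
    if lay.has_u:
        eta = eta + z[lay.iu]
    if lay.has_v:
        eta = eta + z[lay.iv]
    if data.offset is not None:
        eta = eta + data.offset
    return eta


def _default_pc_field(data: ModelData) -> PCPriorSpec:
    # P(range < diameter/5) = 0.5, P(sd > 1) = 0.01
    mesh = data.mesh
    diam = np.hypot(mesh.nx * mesh.spacing, mesh.ny * mesh.spacing)
    return PCPriorSpec(rho0=diam / 5.0, alpha_rho=0.5, sigma0=1.0, alpha_sigma=0.01)


def _prior_precision(theta: dict, data: ModelData, spec: ModelSpec, lay: _Layout):
    """Dense latent prior precision P0 and its log determinant."""
    P0 = np.zeros((lay.d, lay.d))
    idx = np.arange(lay.p)
    P0[idx, idx] = 1.0 / spec.coef_prior_sd**2
    logdet = -2.0 * lay.p * np.log(spec.coef_prior_sd)
    if lay.has_u:
        op = build_precision(
            data.mesh, MaternSpec(range_m=theta["range"], sd=theta["field_sd"])
        )
        Qu = op.Q.toarray()
        if spec.sum_to_zero_sd is not None:
            a = np.zeros(data.mesh.n_nodes)
            a[data.mesh.real_index] = 1.0 / lay.n
            Qu = Qu + np.outer(a, a) / spec.sum_to_zero_sd**2
        sl = slice(lay.p, lay.p + lay.m)
        P0[sl, sl] = Qu
        Lu = np.linalg.cholesky(Qu)
        logdet += 2.0 * float(np.sum(np.log(np.diag(Lu))))
    if lay.has_v:
        iv = lay.iv
        P0[iv, iv] = 1.0 / theta["iid_sd"] ** 2
        logdet += -2.0 * lay.n * np.log(theta["iid_sd"])
    return P0, logdet


def _newton_mode(theta, data, spec, lay, z0=None, tol=1e-8, maxit=60):
    """Conditional mode of the latent field and Cholesky of the curvature."""
    P0, logdetP0 = _prior_precision(theta, data, spec, lay)
    z = np.zeros(lay.d) if z0 is None else z0.copy()
    if z0 is None and "intercept" in data.coef_names:
        z[data.coef_names.index("intercept")] = np.log(np.mean(data.counts) + 0.5)
    y = data.counts

    def objective(zv):
        eta = np.clip(_eta_of(zv, data, lay), -_ETA_BOUND, _ETA_BOUND)
        return float(y @ eta - np.exp(eta).sum() - 0.5 * zv @ (P0 @ zv)), eta

    f, eta = objective(z)
    H = None
    for _ in range(maxit):
        mu = np.exp(eta)
        r = y - mu
        grad = -P0 @ z
        grad[: lay.p] += data.X.T @ r
        if lay.has_u:
            np.add.at(grad, lay.iu, r)
        if lay.has_v:
            grad[lay.iv] += r
        H = P0.copy()
        XW = data.X.T * mu  # (p, n)
        H[: lay.p, : lay.p] += XW @ data.X
        if lay.has_u:
            H[lay.iu, lay.iu] += mu
            H[: lay.p, lay.iu] += XW
            H[lay.iu, : lay.p] += XW.T
        if lay.has_v:
            H[lay.iv, lay.iv] += mu
            H[: lay.p, lay.iv] += XW
            H[lay.iv, : lay.p] += XW.T
        if lay.has_u and lay.has_v:
            H[lay.iu, lay.iv] += mu
            H[lay.iv, lay.iu] += mu
        try:
            chol = cho_factor(H, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("latent curvature not positive definite") from exc
        delta = cho_solve(chol, grad)
        step = 1.0
        for _ in range(30):
            z_new = z + step * delta
            f_new, eta_new = objective(z_new)
            if f_new >= f - 1e-12:
                break
            step *= 0.5
        moved = step * np.max(np.abs(delta))
        z, f, eta = z_new, f_new, eta_new
        if moved < tol * (1.0 + np.max(np.abs(z))):
            break
    Lh = np.linalg.cholesky(H)
    logdetH = 2.0 * float(np.sum(np.log(np.diag(Lh))))
    return z, Lh, f, logdetP0, logdetH, float(np.max(np.abs(grad)))


def _hyper_names(spec: ModelSpec, lay: _Layout) -> list[str]:
    names = []
    if lay.has_u:
        names += ["range", "field_sd"]
    if lay.has_v:
        names += ["iid_sd"]
    return names


def _log_hyperprior(theta: dict, spec: ModelSpec, pc_field: PCPriorSpec, lay: _Layout):
    lp = 0.0
    if lay.has_u:
        lp += pc_prior_logdensity(theta["range"], theta["field_sd"], pc_field)
        lp += np.log(theta["range"]) + np.log(theta["field_sd"])  # log-scale Jacobian
    if lay.has_v:
        s0, a = spec.pc_iid
        lam = -np.log(a) / s0
        lp += np.log(lam) - lam * theta["iid_sd"] + np.log(theta["iid_sd"])
    return float(lp)


def log_joint(params: dict, data: ModelData, spec: ModelSpec) -> float:
    """Unnormalised log posterior density at explicit parameter values.

    ``params`` holds ``beta`` (p,), optionally ``u`` (mesh nodes) and ``v``
    (cells), and the hyperparameters ``range``, ``field_sd``, ``iid_sd``
    as needed. All model terms are evaluated with their normalising
    constants so the value can be checked term by term.
    """
    lay = _Layout(data, spec)
    beta = np.asarray(params["beta"], dtype=float)
    eta = data.X @ beta
    lp = 0.0
    if lay.has_u:
        u = np.asarray(params["u"], dtype=float)
        eta = eta + u[data.mesh.real_index]
        op = build_precision(
            data.mesh, MaternSpec(range_m=params["range"], sd=params["field_sd"])
        )
        m = len(u)
        lp += 0.5 * op.logdet - 0.5 * m * np.log(2 * np.pi) - 0.5 * u @ (op.Q @ u)
        if spec.sum_to_zero_sd is not None:
            s = spec.sum_to_zero_sd
            mean_u = float(np.mean(u[data.mesh.real_index]))
            lp += -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * (mean_u / s) ** 2
        pc = spec.pc_field if spec.pc_field is not None else _default_pc_field(data)
        lp += pc_prior_logdensity(params["range"], params["field_sd"], pc)
    if lay.has_v:
        v = np.asarray(params["v"], dtype=float)
        eta = eta + v
        sv = float(params["iid_sd"])
        lp += np.sum(-0.5 * np.log(2 * np.pi) - np.log(sv) - 0.5 * (v / sv) ** 2)
        s0, a = spec.pc_iid
        lam = -np.log(a) / s0
        lp += np.log(lam) - lam * sv
    if data.offset is not None:
        eta = eta + data.offset
    lp += poisson_loglik(data.counts, eta)
    lp += np.sum(
        -0.5 * np.log(2 * np.pi)
        - np.log(spec.coef_prior_sd)
        - 0.5 * (beta / spec.coef_prior_sd) ** 2
    )
    if not np.isfinite(lp):
        raise ConvergenceError("log joint is not finite at the supplied parameters")
    return float(lp)


@dataclass
class FittedModel:
    """Posterior draws and summaries for one fit."""

    coef_names: list[str]
    beta_draws: np.ndarray  # (n_draws, p)
    u_draws: np.ndarray | None  # (n_draws, n_cells), real cells only
    v_draws: np.ndarray | None
    hyper: dict[str, np.ndarray]  # draws (possibly length-1) per hyperparameter
    diagnostics: dict
    spec: ModelSpec
    beta_mode: np.ndarray | None = None  # posterior mode (laplace) / mean (mcmc)

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.coef_names):
            rows.append(_summ_row(name, self.beta_draws[:, j]))
        for name, draws in self.hyper.items():
            rows.append(_summ_row(name, np.asarray(draws)))
        return pd.DataFrame(rows).set_index("parameter")


def _summ_row(name: str, draws: np.ndarray) -> dict:
    qs = np.quantile(draws, _QUANTS) if len(draws) > 1 else [float(draws[0])] * 5
    return {
        "parameter": name,
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0,
        "q2.5": float(qs[0]),
        "q5": float(qs[1]),
        "q50": float(qs[2]),
        "q95": float(qs[3]),
        "q97.5": float(qs[4]),
    }


def _marginal_logpost(logtheta, names, data, spec, pc_field, lay, warm):
    theta = dict(warm.get("fixed", {}))
    theta.update({k: float(np.exp(t)) for k, t in zip(names, logtheta)})
    try:
        z, Lh, f, logdetP0, logdetH, _ = _newton_mode(
            theta, data, spec, lay, z0=warm.get("z")
        )
    except (ConvergenceError, np.linalg.LinAlgError):
        return -1e10, None
    warm["z"] = z
    lp = f + 0.5 * logdetP0 - 0.5 * logdetH + _log_hyperprior(theta, spec, pc_field, lay)
    return float(lp), (z, Lh, theta)


def _draw_latent(z_hat, Lh, rng, n_draws):
    eps = rng.standard_normal((Lh.shape[0], n_draws))
    return (z_hat[:, None] + solve_triangular(Lh.T, eps, lower=False)).T


def fit(data: ModelData, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the spatial Poisson model; returns draws and diagnostics.

    ``method="laplace"`` (default): hyperparameters are set to the mode of
    their Laplace-approximated marginal posterior (numerical optimisation on
    the log scale) and latent draws come from the conditional Gaussian at
    that mode; hyperparameter spread is reported from a finite-difference
    curvature at the mode. ``method="mcmc"``: random-walk Metropolis over
    the hyperparameters with conditional Gaussian latent draws, split-chain
    R-hat checked against ``spec.rhat_limit``.
    """
    spec = spec or ModelSpec()
    lay = _Layout(data, spec)
    if lay.has_u and data.mesh is None:
        raise ConfigError("spatial field requested but no mesh supplied")
    pc_field = spec.pc_field
    if pc_field is None and lay.has_u:
        pc_field = _default_pc_field(data)
    rng = np.random.default_rng(spec.seed)
    names = _hyper_names(spec, lay)
    theta0 = {}
    if lay.has_u:
        theta0["range"] = spec.field.range_m
        theta0["field_sd"] = max(spec.field.sd, 1e-8)
    if lay.has_v:
        theta0["iid_sd"] = max(spec.iid_sd, 1e-8)
    warm: dict = {"fixed": theta0}
    diagnostics: dict = {"method": spec.method}

    active = names if (spec.optimize_hyper and names) else []
    x0 = np.log([theta0[k] for k in active]) if active else np.array([])

    if spec.method == "laplace" or not active:
        if active:
            res = minimize(
                lambda lt: -_marginal_logpost(lt, active, data, spec, pc_field, lay, warm)[0],
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-2, "fatol": 1e-3, "maxiter": spec.max_opt_iter},
            )
            xopt = res.x
            diagnostics["opt_converged"] = bool(res.success or res.nit >= 10)
            diagnostics["opt_iterations"] = int(res.nit)
        else:
            xopt = x0
        lp, payload = _marginal_logpost(xopt, active, data, spec, pc_field, lay, warm)
        if payload is None:
            raise ConvergenceError("Laplace mode finding failed at the optimum")
        z_hat, Lh, theta = payload
        _, _, _, _, _, gnorm = _newton_mode(theta, data, spec, lay, z0=z_hat)
        diagnostics["newton_grad_norm"] = gnorm
        draws = _draw_latent(z_hat, Lh, rng, spec.n_draws)
        hyper = {}
        if active:
            # finite-difference curvature of the theta-posterior (log scale)
            k = len(active)
            h = 0.08
            Hn = np.zeros((k, k))
            f0 = lp
            for i in range(k):
                for j in range(i, k):
                    ei, ej = np.eye(k)[i] * h, np.eye(k)[j] * h
                    fpp = _marginal_logpost(xopt + ei + ej, active, data, spec, pc_field, lay, warm)[0]
                    fpm = _marginal_logpost(xopt + ei - ej, active, data, spec, pc_field, lay, warm)[0]
                    fmp = _marginal_logpost(xopt - ei + ej, active, data, spec, pc_field, lay, warm)[0]
                    fmm = _marginal_logpost(xopt - ei - ej, active, data, spec, pc_field, lay, warm)[0]
                    Hn[i, j] = Hn[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
            try:
                cov = np.linalg.inv(-Hn)
                if np.any(np.diag(cov) <= 0):
                    raise np.linalg.LinAlgError
                Lc = np.linalg.cholesky(cov)
                lt_draws = xopt[None, :] + (Lc @ rng.standard_normal((k, spec.n_draws))).T
                for i, nm in enumerate(active):
                    hyper[nm] = np.exp(lt_draws[:, i])
            except np.linalg.LinAlgError:
                for i, nm in enumerate(active):
                    hyper[nm] = np.full(spec.n_draws, np.exp(xopt[i]))
                diagnostics["hyper_curvature"] = "not PD; point mass reported"
        for nm in names:
            hyper.setdefault(nm, np.full(spec.n_draws, theta[nm]))
    else:
        # independence Metropolis over log-hyperparameters: multivariate-t
        # proposal centred at the Laplace mode with curvature-based scale
        # (heavy tails so ridge regions of the marginal posterior are reached)
        k = len(active)
        res = minimize(
            lambda lt: -_marginal_logpost(lt, active, data, spec, pc_field, lay, warm)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 2e-2, "fatol": 1e-2, "maxiter": spec.max_opt_iter},
        )
        xmode = res.x
        h = 0.1
        Hn = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                ei, ej = np.eye(k)[i] * h, np.eye(k)[j] * h
                fpp = _marginal_logpost(xmode + ei + ej, active, data, spec, pc_field, lay, warm)[0]
                fpm = _marginal_logpost(xmode + ei - ej, active, data, spec, pc_field, lay, warm)[0]
                fmp = _marginal_logpost(xmode - ei + ej, active, data, spec, pc_field, lay, warm)[0]
                fmm = _marginal_logpost(xmode - ei - ej, active, data, spec, pc_field, lay, warm)[0]
                Hn[i, j] = Hn[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        try:
            pcov = np.linalg.inv(-Hn)
            prop = np.linalg.cholesky(pcov) * 1.5
        except np.linalg.LinAlgError:
            prop = np.eye(k) * 0.3
        prop_df = 4.0
        logdet_prop = float(np.sum(np.log(np.diag(prop))))

        def logq(x):
            r = solve_triangular(prop, x - xmode, lower=True)
            return -0.5 * (prop_df + k) * np.log1p((r @ r) / prop_df) - logdet_prop

        def draw_prop():
            g = rng.chisquare(prop_df) / prop_df
            return xmode + (prop @ rng.standard_normal(k)) / np.sqrt(g)

        chains_lt = np.empty((spec.chains, spec.mcmc_iter, k))
        chains_lp = np.empty((spec.chains, spec.mcmc_iter))
        accept = 0
        total = 0
        payload_store = []
        for c in range(spec.chains):
            cw = {"fixed": theta0}
            x = draw_prop()
            lp, payload = _marginal_logpost(x, active, data, spec, pc_field, lay, cw)
            kept_payloads = []
            for it in range(spec.mcmc_warmup + spec.mcmc_iter):
                xp = draw_prop()
                lpp, pl = _marginal_logpost(xp, active, data, spec, pc_field, lay, cw)
                total += 1
                if np.log(rng.uniform()) < (lpp - lp) - (logq(xp) - logq(x)):
                    x, lp, payload = xp, lpp, pl
                    accept += 1
                if it >= spec.mcmc_warmup:
                    chains_lt[c, it - spec.mcmc_warmup] = x
                    chains_lp[c, it - spec.mcmc_warmup] = lp
                    kept_payloads.append(payload)
            payload_store.append(kept_payloads)
        diagnostics["accept_rate"] = accept / max(total, 1)
        rhats = _split_rhat(chains_lt)
        diagnostics["rhat"] = {nm: float(rhats[i]) for i, nm in enumerate(active)}
        bad = [nm for i, nm in enumerate(active) if rhats[i] > spec.rhat_limit]
        if bad:
            raise ConvergenceError(
                f"split-chain R-hat exceeds {spec.rhat_limit} for: {bad} "
                f"(values {[diagnostics['rhat'][b] for b in bad]})"
            )
        # one latent draw per retained theta, thinned to n_draws
        flat = [pl for ch in payload_store for pl in ch if pl is not None]
        sel = np.linspace(0, len(flat) - 1, min(spec.n_draws, len(flat))).astype(int)
        draw_list, hyper_list = [], []
        for idx in sel:
            z_hat, Lh, theta = flat[idx]
            draw_list.append(_draw_latent(z_hat, Lh, rng, 1)[0])
            hyper_list.append([theta[nm] for nm in names])
        draws = np.array(draw_list)
        hv = np.array(hyper_list)
        hyper = {nm: hv[:, i] for i, nm in enumerate(names)}

    beta_draws = draws[:, : lay.p]
    u_draws = draws[:, lay.iu] if lay.has_u else None
    v_draws = draws[:, lay.iv] if lay.has_v else None
    if spec.method == "laplace" or not active:
        beta_mode = z_hat[: lay.p].copy()
    else:
        beta_mode = beta_draws.mean(axis=0)
    return FittedModel(
        coef_names=list(data.coef_names),
        beta_draws=beta_draws,
        u_draws=u_draws,
        v_draws=v_draws,
        hyper=hyper,
        diagnostics=diagnostics,
        spec=spec,
        beta_mode=beta_mode,
    )


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction per parameter; chains (c, n, k)."""
    c, n, k = chains.shape
    half = n // 2
    sub = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, nn = sub.shape[0], sub.shape[1]
    means = sub.mean(axis=1)  # (m, k)
    vars_ = sub.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = nn * means.var(axis=0, ddof=1)
    var_plus = (nn - 1) / nn * W + B / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(np.isfinite(rhat), rhat, 1.0)


_QLABEL = re.compile(r"^(?P<var>.+)_q(?P<cat>\d+)$")
_LULABEL = re.compile(r"^landuse8\[(?P<cat>.+)\]$")


def relative_risks(fitted: FittedModel, percent: bool = True) -> pd.DataFrame:
    """Relative risks exp(beta) per covariate category, with reference rows.

    rr summaries are computed draw-wise (mean of exp, not exp of mean).
    ``excess_pct`` is (posterior-mean rr - 1) * 100.
    """
    rows = []
    seen_vars: set[str] = set()
    for j, name in enumerate(fitted.coef_names):
        mq = _QLABEL.match(name)
        ml = _LULABEL.match(name)
        if mq:
            var, cat = mq.group("var"), f"q{mq.group('cat')}"
        elif ml:
            var, cat = "landuse8", ml.group("cat")
        else:
            continue
        if var not in seen_vars:
            seen_vars.add(var)
            ref_cat = "q1" if mq else design_mod.LANDUSE8[0]
            rows.append(
                {
                    "variable": var,
                    "category": ref_cat,
                    "reference": True,
                    "rr_mean": 1.0,
                    "rr_q2.5": 1.0,
                    "rr_q5": 1.0,
                    "rr_q50": 1.0,
                    "rr_q95": 1.0,
                    "rr_q97.5": 1.0,
                    "excess_pct": 0.0,
                }
            )
        rr = np.exp(fitted.beta_draws[:, j])
        qs = np.quantile(rr, _QUANTS)
        rows.append(
            {
                "variable": var,
                "category": cat,
                "reference": False,
                "rr_mean": float(np.mean(rr)),
                "rr_q2.5": float(qs[0]),
                "rr_q5": float(qs[1]),
                "rr_q50": float(qs[2]),
                "rr_q95": float(qs[3]),
                "rr_q97.5": float(qs[4]),
                "excess_pct": float((np.mean(rr) - 1.0) * 100.0),
            }
        )
    if not rows:
        raise ValidationError("no categorical coefficients found in the fit")
    return pd.DataFrame(rows)


def excess_surface(fitted: FittedModel) -> pd.DataFrame:
    """Per-cell posterior of exp(u + v): multiplicative departure from expected.

    Values above 1 mean more species than the covariates predict. Computed
    draw-wise from the stored latent draws.
    """
    if fitted.u_draws is None and fitted.v_draws is None:
        raise ValidationError("fit has no random effects; no excess surface")
    tot = 0.0
    if fitted.u_draws is not None:
        tot = tot + fitted.u_draws
    if fitted.v_draws is not None:
        tot = tot + fitted.v_draws
    surf = np.exp(tot)
    qs = np.quantile(surf, _QUANTS, axis=0)
    return pd.DataFrame(
        {
            "mean": surf.mean(axis=0),
            "q2.5": qs[0],
            "q5": qs[1],
            "q50": qs[2],
            "q95": qs[3],
            "q97.5": qs[4],
        }
    )
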