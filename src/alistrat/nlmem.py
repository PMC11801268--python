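"""Nonlinear mixed-effects estimation of the PT% kinetic model.

Population model: patient k's parameters are ``params_k = theta * exp(eta_k)``
with fixed effects ``theta = (g, D, P0)`` and random effects
``eta_k ~ N(0, Omega)`` (diagonal, log scale); observations carry additive
Gaussian residuals of constant SD ``sigma``:

    y_kj = P(t_kj; theta * exp(eta_k)) + eps_kj,   eps_kj ~ N(0, sigma^2).

Estimation is by SAEM (stochastic-approximation EM): the E-step samples each
patient's log-parameters from their conditional posterior with a few
random-walk Metropolis transitions (componentwise proposals adapted toward a
30% acceptance rate); sufficient statistics are stochastically approximated
with step size 1 during exploration and 1/j during smoothing; the M-step
updates ``log theta``, the diagonal of ``Omega`` and ``sigma^2`` in closed
form.  Individual parameters are then the empirical-Bayes MAP of ``eta_k``
given the population estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from alistrat.pt_model import PTParams, fit_individual_ls
from alistrat.synthetic_cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationModel",
    "IndividualEstimate",
    "SaemConfig",
    "fit_population_saem",
    "estimate_individual_eb",
    "two_stage_estimate",
]

_OMEGA_FLOOR = 1e-8
_SIGMA_FLOOR = 1e-6


@dataclass
class PopulationModel:
    theta: PTParams
    omega: np.ndarray  # 3 log-scale variances (g, D, P0)
    sigma: float
    trace: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (3,) or np.any(self.omega < 0):
            raise ValueError("omega must be 3 non-negative variances")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def mu(self) -> np.ndarray:
        """Fixed effects on the log scale."""
        return np.log(self.theta.as_array())


@dataclass
class IndividualEstimate:
    id: str
    params: PTParams
    eta: np.ndarray
    converged: bool = True


@dataclass
class SaemConfig:
    n_explore: int = 300
    n_smooth: int = 200
    n_mcmc: int = 5          # Metropolis transitions per patient per iteration
    target_accept: float = 0.30
    explore_omega_floor: float = 0.01  # variance floor while exploring (anti-collapse)
    seed: int = 0


def _extract_series(cohort) -> tuple[list[str], list[np.ndarray], list[np.ndarray]]:
    """Pull (id, times, finite PT% values) triples out of a Cohort or list."""
    ids, times, ys = [], [], []
    if isinstance(cohort, Cohort):
        items = [(p.id, p.times, p.pt_obs) for p in cohort.patients]
    else:
        items = [(f"P{i:04d}", t, y) for i, (t, y) in enumerate(cohort)]
    for pid, t, y in items:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(y)
        ids.append(pid)
        times.append(t[keep])
        ys.append(y[keep])
    return ids, times, ys


def _pad(times: list[np.ndarray], ys: list[np.ndarray]):
    n = len(times)
    T = max(len(t) for t in times)
    tmat = np.zeros((n, T))
    ymat = np.zeros((n, T))
    mask = np.zeros((n, T), dtype=bool)
    for k, (t, y) in enumerate(zip(times, ys)):
        tmat[k, : len(t)] = t
        ymat[k, : len(y)] = y
        mask[k, : len(t)] = True
    return tmat, ymat, mask


def _rss(phi: np.ndarray, tmat, ymat, mask) -> np.ndarray:
    """Per-patient residual sum of squares at log-parameters ``phi`` (n,3)."""
    with np.errstate(over="ignore", invalid="ignore"):
        g = np.exp(phi[:, 0])[:, None]
        D = np.exp(phi[:, 1])[:, None]
        P0 = np.exp(phi[:, 2])[:, None]
        eq = g / D
        pred = eq + (P0 - eq) * np.exp(-D * tmat)
        resid = np.where(mask, ymat - pred, 0.0)
        rss = np.einsum("ij,ij->i", resid, resid)
    return np.where(np.isfinite(rss), rss, np.inf)


def two_stage_estimate(cohort, n_starts: int = 4, seed: int = 0) -> PopulationModel:
    """Naive two-stage population estimate (initializer / cross-check oracle).

    Stage 1: independent per-patient least-squares fits; stage 2: ``theta``
    is the exponentiated mean of the log-parameters, ``omega`` their
    log-scale variance, ``sigma`` the pooled residual SD.  Ignores shrinkage,
    hence biased upward in omega when data are noisy — exactly why SAEM is
    the estimator of record.
    """
    ids, times, ys = _extract_series(cohort)
    logs, rss_total, n_obs = [], 0.0, 0
    for pid, t, y in zip(ids, times, ys):
        if len(y) < 3:
            continue
        params, flag = fit_individual_ls(t, y, n_starts=n_starts, seed=seed)
        if flag != "ok":
            continue
        logs.append(np.log(params.as_array()))
        pred_rss = _rss(np.log(params.as_array())[None, :], t[None, :], y[None, :],
                        np.ones((1, len(t)), dtype=bool))[0]
        rss_total += pred_rss
        n_obs += len(y)
    if len(logs) < 3:
        raise ValueError("fewer than 3 usable (non-degenerate) individual fits")
    logs = np.array(logs)
    mu = logs.mean(axis=0)
    omega = logs.var(axis=0)
    sigma = max(np.sqrt(rss_total / max(n_obs - 3 * len(logs), 1)), _SIGMA_FLOOR)
    g, D, P0 = np.exp(mu)
    return PopulationModel(theta=PTParams(g=g, D=D, P0=P0), omega=omega, sigma=float(sigma))


def fit_population_saem(
    cohort,
    config: SaemConfig | None = None,
    init: PopulationModel | None = None,
) -> PopulationModel:
    """Fit the population model by SAEM.

    Patients with fewer than two PT% observations are excluded with a
    warning.  Returns the final :class:`PopulationModel` with a convergence
    trace (per-iteration theta, omega, sigma) in ``.trace``.
    """
    config = config or SaemConfig()
    ids, times, ys = _extract_series(cohort)
    keep = [k for k in range(len(ids)) if len(ys[k]) >= 2]
    dropped = len(ids) - len(keep)
    if dropped:
        logger.warning("excluding %d patient(s) with < 2 PT%% observations", dropped)
    times = [times[k] for k in keep]
    ys = [ys[k] for k in keep]
    n = len(times)
    if n == 0:
        raise ValueError("no patients with >= 2 observations")
    tmat, ymat, mask = _pad(times, ys)
    n_obs_total = int(mask.sum())

    # Initialization: per-patient least-squares fits anchor both the chain
    # states and the population starting values.  Unconstrained LS on
    # near-equilibrium patients can put (g, D) anywhere along the g/D ridge,
    # so the starting Omega is clipped to a plausible range.
    phi_init = np.full((n, 3), np.nan)
    if init is None:
        for k in range(n):
            if len(ys[k]) >= 3:
                try:
                    params, flag = fit_individual_ls(times[k], ys[k], n_starts=3, seed=config.seed)
                except ValueError:
                    continue
                if flag == "ok":
                    phi_init[k] = np.log(params.as_array())
        good = np.all(np.isfinite(phi_init), axis=1)
        if good.sum() >= 3:
            mu = np.median(phi_init[good], axis=0)
            omega = np.clip(np.var(phi_init[good], axis=0), 0.04, 1.0)
            rss0 = _rss(phi_init[good], tmat[good], ymat[good], mask[good])
            sigma2 = float(np.clip(rss0.sum() / max(mask[good].sum(), 1), 0.25, 100.0))
        else:
            mu = np.log([30.0, 0.5, max(float(np.median(ymat[:, 0])), 1.0)])
            omega = np.array([0.1, 0.1, 0.1])
            sigma2 = 25.0
    else:
        mu = init.mu.copy()
        omega = np.clip(init.omega.copy(), 0.02, 1.0)
        sigma2 = float(np.clip(init.sigma, 0.5, 10.0)) ** 2

    rng = np.random.default_rng(config.seed)
    phi = np.tile(mu, (n, 1)) + rng.normal(0.0, np.sqrt(omega), size=(n, 3))
    use_ls = np.all(np.isfinite(phi_init), axis=1)
    # Start chains at data-supported values where available, clipped to a
    # band around the population start to avoid ridge-degenerate outliers.
    phi[use_ls] = np.clip(phi_init[use_ls], mu - 3.0, mu + 3.0)
    rss = _rss(phi, tmat, ymat, mask)
    prop_sd = np.full(4, 0.3)

    s_phi = np.zeros((n, 3))
    s_phi2 = np.zeros((n, 3))
    s_rss = np.zeros(n)
    first = True

    n_iter = config.n_explore + config.n_smooth
    trace = {"theta": np.zeros((n_iter, 3)), "omega": np.zeros((n_iter, 3)),
             "sigma": np.zeros(n_iter), "obj": np.zeros(n_iter)}

    for it in range(n_iter):
        # --- E-step: componentwise random-walk Metropolis on phi_k ---
        acc = np.zeros(4)
        om_safe = np.maximum(omega, _OMEGA_FLOOR)
        for _ in range(config.n_mcmc):
            # Componentwise proposals plus a joint g-D move along the
            # equilibrium-preserving ridge (g/D constant), which the
            # componentwise kernel traverses slowly.
            for c in range(4):
                prop = phi.copy()
                if c < 3:
                    prop[:, c] = phi[:, c] + rng.normal(0.0, prop_sd[c], size=n)
                else:
                    delta = rng.normal(0.0, prop_sd[3], size=n)
                    prop[:, 0] += delta
                    prop[:, 1] += delta
                rss_prop = _rss(prop, tmat, ymat, mask)
                dprior = np.sum(
                    ((prop - mu) ** 2 - (phi - mu) ** 2) / (2.0 * om_safe), axis=1
                )
                logr = -(rss_prop - rss) / (2.0 * sigma2) - dprior
                accept = np.log(rng.random(n)) < logr
                phi[accept] = prop[accept]
                rss[accept] = rss_prop[accept]
                acc[c] += accept.mean()
        acc /= config.n_mcmc
        prop_sd *= np.where(acc > config.target_accept + 0.05, 1.15,
                            np.where(acc < config.target_accept - 0.05, 1 / 1.15, 1.0))
        prop_sd = np.clip(prop_sd, 1e-3, 2.0)

        # --- SA update of sufficient statistics ---
        gamma = 1.0 if it < config.n_explore else 1.0 / (it - config.n_explore + 1)
        if first:
            s_phi, s_phi2, s_rss = phi.copy(), phi**2, rss.copy()
            first = False
        else:
            s_phi += gamma * (phi - s_phi)
            s_phi2 += gamma * (phi**2 - s_phi2)
            s_rss += gamma * (rss - s_rss)

        # --- M-step: closed-form normal updates ---
        mu = s_phi.mean(axis=0)
        omega = np.maximum(s_phi2.mean(axis=0) - mu**2, _OMEGA_FLOOR)
        sigma2 = max(s_rss.sum() / n_obs_total, _SIGMA_FLOOR**2)
        if it < config.n_explore:
            # Variance floor during exploration: a component that collapses
            # to zero freezes its chain in whatever mode it started from.
            omega = np.maximum(omega, config.explore_omega_floor)

        trace["theta"][it] = np.exp(mu)
        trace["omega"][it] = omega
        trace["sigma"][it] = np.sqrt(sigma2)
        # Complete-data objective (up to constants), for convergence audit.
        trace["obj"][it] = -(
            s_rss.sum() / (2 * sigma2)
            + n_obs_total / 2 * np.log(sigma2)
            + n / 2 * np.sum(np.log(np.maximum(omega, _OMEGA_FLOOR)))
            + np.sum((s_phi2.mean(axis=0) - 2 * mu * s_phi.mean(axis=0) + mu**2) * n
                     / (2 * np.maximum(omega, _OMEGA_FLOOR)))
        )
        if not np.all(np.isfinite(mu)) or not np.isfinite(sigma2):
            raise RuntimeError(f"non-finite SAEM state at iteration {it}")

    g, D, P0 = np.exp(mu)
    return PopulationModel(
        theta=PTParams(g=float(g), D=float(D), P0=float(P0)),
        omega=omega,
        sigma=float(np.sqrt(sigma2)),
        trace=trace,
    )


def estimate_individual_eb(
    pop: PopulationModel, times, pt_obs, id: str = "", ls_seed: int = 0
) -> IndividualEstimate:
    """Empirical-Bayes MAP estimate of one patient's random effects.

    Maximizes the Gaussian residual likelihood (SD ``pop.sigma``) times the
    ``N(0, Omega)`` prior over ``eta``; multi-start from the prior mode and
    from the individual least-squares fit mapped to the log scale.  Omega
    components equal to zero pin the corresponding eta at 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(pt_obs, dtype=float)
    keep = np.isfinite(y)
    t, y = t[keep], y[keep]
    if t.size == 0:
        raise ValueError("at least one observation is required")
    mu = pop.mu
    free = pop.omega > 0
    sigma2 = pop.sigma**2
    mask = np.ones((1, t.size), dtype=bool)

    def negpost(eta_free: np.ndarray) -> float:
        eta = np.zeros(3)
        eta[free] = eta_free
        phi = (mu + eta)[None, :]
        rss = _rss(phi, t[None, :], y[None, :], mask)[0]
        prior = np.sum(eta[free] ** 2 / (2.0 * pop.omega[free]))
        return rss / (2.0 * sigma2) + prior

    starts = [np.zeros(int(free.sum()))]
    if t.size >= 3:
        try:
            ls_params, flag = fit_individual_ls(t, y, n_starts=3, seed=ls_seed)
            if flag == "ok":
                eta_ls = np.log(ls_params.as_array()) - mu
                starts.append(eta_ls[free])
        except ValueError:
            pass

    best = None
    for x0 in starts:
        if x0.size == 0:
            best_val, best_x = negpost(x0), x0
            best = (best_val, best_x)
            break
        res = minimize(negpost, x0, method="L-BFGS-B", bounds=[(-12.0, 12.0)] * x0.size)
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    eta = np.zeros(3)
    eta[free] = best[1]
    g, D, P0 = np.exp(mu + eta)
    return IndividualEstimate(
        id=id, params=PTParams(g=float(g), D=float(D), P0=float(P0)), eta=eta
    )


def estimate_all_eb(pop: PopulationModel, cohort) -> list[IndividualEstimate]:
    """Empirical-Bayes estimates for every patient in a cohort."""
    ids, times, ys = _extract_series(cohort)
    return [
        estimate_individual_eb(pop, t, y, id=pid)
        for pid, t, y in zip(ids, times, ys)
        if np.isfinite(y).sum() >= 1
    ]
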