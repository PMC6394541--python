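"""Three-stage hierarchical Bayesian estimation of the mother-infant kinetics.

Stage 1 (data): saliva enrichments are normal around the structural-model
prediction with a combined residual model, sd = sqrt(sigma_add^2 +
(sigma_prop * f)^2) (set ``error_model="additive"`` for sigma_prop = 0).

Stage 2 (heterogeneity): individual log-parameters
ln(theta_i) = (ln CL_mb, ln CL_bo, ln k_mm, ln V_m) are multivariate normal
around covariate-adjusted population means with covariance
Omega = V rho V, V = diag(lambda). The full covariate model places a power
of maternal weight (reference 70 kg) on V_m and of infant weight (reference
5 kg) on CL_bo, both on the log scale.

Stage 3 (priors): vague priors throughout — N(0, 1000) on population
log-means, half-normal(1000) on the scales lambda and on the residual sigma
components, and an LKJ(1) prior (uniform over correlation matrices) on rho.

Sampling uses an adaptive Metropolis-within-Gibbs scheme written for this
model: a per-pair multivariate random-walk Metropolis step on ln(theta_i)
whose proposal covariance adapts during warmup, an exact conjugate Gibbs
draw of the population coefficient vector, and adaptive random-walk steps on
the scales, the correlations (with positive-definiteness enforced by
construction) and the residual sigmas. The physiological constraint
CL_mb < k_mm * V_m (the milk route cannot exceed the mother's total output)
is imposed as prior support truncation. Chains are independent and the whole
run is reproducible from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

import arviz as az
from sklearn.base import BaseEstimator

from .io import PairDataset, preprocess_pair
from .kinetics import EQUAL_RATE_RTOL, InfantPool
from .simulate import PARAM_NAMES

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "ModelDefinition",
    "build_model",
    "HierarchicalDtmModel",
    "PosteriorDraws",
    "fit",
    "rhat",
    "effective_sample_size",
]

_LOG2PI = np.log(2.0 * np.pi)

BETA_NAMES_BASE = ["lnCL_mb", "lnCL_bo", "lnk_mm", "lnV_m"]
BETA_NAMES_FULL = BETA_NAMES_BASE + ["slope_Vm_MWT", "slope_CLbo_BWT"]


@dataclass
class PriorSpec:
    """Vague stage-3 priors; means/sds are overridable for degenerate checks."""

    logmu_sd: float = 1000.0
    logmu_mean: np.ndarray | float = 0.0
    scale_sd: float = 1000.0  # half-normal sd on each lambda
    sigma_sd: float = 1000.0  # half-normal sd on sigma components
    lkj_shape: float = 1.0

    def __post_init__(self) -> None:
        if min(self.logmu_sd, self.scale_sd, self.sigma_sd) <= 0:
            raise ValueError("prior sds must be positive")
        if self.lkj_shape < 1:
            raise ValueError("LKJ shape must be >= 1")


@dataclass
class McmcSettings:
    """Sampler protocol. Defaults follow the field protocol: three chains of
    10,000 retained samples after a 1,000-sample burn-in."""

    n_chains: int = 3
    n_draws: int = 10_000
    n_warmup: int = 1_000
    thin: int = 5
    seed: int = 0
    target_accept: float = 0.234

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_draws", "n_warmup", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcSettings":
        """Small profile for tests and worked examples."""
        return cls(n_chains=3, n_draws=1_000, n_warmup=1_500, thin=5, seed=seed)


@dataclass(frozen=True)
class ModelDefinition:
    """Bookkeeping for one model variant: which parameters exist."""

    covariate_model: str  # "none" | "full"
    error_model: str  # "additive" | "combined"
    beta_names: tuple
    n_scales: int = 4
    has_correlation: bool = True

    @property
    def n_beta(self) -> int:
        return len(self.beta_names)

    @property
    def sigma_names(self) -> tuple:
        return ("sigma_add",) if self.error_model == "additive" else ("sigma_add", "sigma_prop")


def build_model(covariate_config: str = "full", error_model: str = "combined") -> ModelDefinition:
    """Model variant definition: base (no covariates) or full (MWT on V_m,
    BWT on CL_bo), with additive or combined residual error."""
    if covariate_config not in ("none", "base", "full"):
        raise ValueError(f"unknown covariate config {covariate_config!r}")
    if error_model not in ("additive", "combined"):
        raise ValueError(f"unknown error model {error_model!r}")
    names = BETA_NAMES_FULL if covariate_config == "full" else BETA_NAMES_BASE
    cfg = "full" if covariate_config == "full" else "none"
    return ModelDefinition(covariate_model=cfg, error_model=error_model, beta_names=tuple(names))


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _PreparedData:
    pair_ids: list
    dose: np.ndarray  # (n,)
    t_m: np.ndarray  # (n, Tm) padded
    y_m: np.ndarray
    mask_m: np.ndarray
    t_b: np.ndarray  # (n, Tb)
    y_b: np.ndarray
    mask_b: np.ndarray
    vb_t: np.ndarray  # V_b at infant obs times
    vb_mid: np.ndarray  # (n,)
    growth_rate: np.ndarray  # (n,) L/day
    c_v: np.ndarray  # ln(MWT/70)
    c_b: np.ndarray  # ln(BWT_start/5)
    pools: list

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_obs(self) -> int:
        return int(self.mask_m.sum() + self.mask_b.sum())


def _prepare(pairs: Sequence[PairDataset], water_fraction: float) -> _PreparedData:
    kept = [p for p in pairs if not p.field_excluded]
    if not kept:
        raise ValueError("no pairs left after removing field-excluded ones")
    processed = [preprocess_pair(p) for p in kept]
    for p in processed:
        p.validate()
    times_m, ys_m, times_b, ys_b = [], [], [], []
    pools = []
    for p in processed:
        rm = sorted(p.postdose_records("mother"), key=lambda r: r.time)
        rb = sorted(p.postdose_records("infant"), key=lambda r: r.time)
        times_m.append([r.time for r in rm])
        ys_m.append([r.enrichment for r in rm])
        times_b.append([r.time for r in rb])
        ys_b.append([r.enrichment for r in rb])
        duration = max(14.0, max(r.time for r in rm + rb))
        pools.append(
            InfantPool(
                weight_start=p.infant_weight_start,
                weight_end=p.infant_weight_end,
                water_fraction=water_fraction,
                duration=duration,
            )
        )

    def pad(rows, fill):
        width = max(len(r) for r in rows)
        arr = np.full((len(rows), width), fill, dtype=float)
        mask = np.zeros((len(rows), width), dtype=bool)
        for i, r in enumerate(rows):
            arr[i, : len(r)] = r
            mask[i, : len(r)] = True
        return arr, mask

    t_m, mask_m = pad(times_m, 0.0)
    y_m, _ = pad(ys_m, 0.0)
    t_b, mask_b = pad(times_b, 0.0)
    y_b, _ = pad(ys_b, 0.0)
    vb_t = np.ones_like(t_b)
    for i, pool in enumerate(pools):
        vb_t[i, mask_b[i]] = pool.volume(t_b[i, mask_b[i]])
    return _PreparedData(
        pair_ids=[p.pair_id for p in processed],
        dose=np.array([p.dose for p in processed]),
        t_m=t_m,
        y_m=y_m,
        mask_m=mask_m,
        t_b=t_b,
        y_b=y_b,
        mask_b=mask_b,
        vb_t=vb_t,
        vb_mid=np.array([pool.midpoint_volume for pool in pools]),
        growth_rate=np.array([pool.growth_rate for pool in pools]),
        c_v=np.log(np.array([p.mother_weight for p in processed]) / 70.0),
        c_b=np.log(np.array([p.infant_weight_start for p in processed]) / 5.0),
        pools=pools,
    )


def _design_matrix(data: _PreparedData, model: ModelDefinition) -> np.ndarray:
    """X with shape (n, 4, q): row p of X_i maps beta to the stage-2 mean of
    parameter p for pair i."""
    n, q = data.n_pairs, model.n_beta
    X = np.zeros((n, 4, q))
    for p in range(4):
        X[:, p, p] = 1.0
    if model.covariate_model == "full":
        X[:, 3, 4] = data.c_v  # maternal weight on V_m
        X[:, 1, 5] = data.c_b  # infant weight on CL_bo
    return X


# ---------------------------------------------------------------------------
# likelihood and prior machinery (vectorized over pairs)


def _predict_curves(eta: np.ndarray, data: _PreparedData):
    """Structural-model enrichment predictions for every pair and time."""
    cl_mb, cl_bo, k_mm, v_m = (np.exp(eta[:, j]) for j in range(4))
    f_m = 1e6 * data.dose[:, None] / v_m[:, None] * np.exp(-k_mm[:, None] * data.t_m)
    k_mb = cl_mb / v_m
    k_bo = cl_bo / data.vb_mid
    diff = (k_mm - k_bo)[:, None]
    degen = np.abs(diff) < EQUAL_RATE_RTOL * np.abs(k_mm[:, None])
    e_bo = np.exp(-k_bo[:, None] * data.t_b)
    e_mm = np.exp(-k_mm[:, None] * data.t_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        amt = data.dose[:, None] * k_mb[:, None] / diff * (e_bo - e_mm)
    limit = data.dose[:, None] * k_mb[:, None] * data.t_b * e_mm
    amt = np.where(degen, limit, amt)
    f_b = 1e6 * amt / data.vb_t
    return f_m, f_b


def _loglik_pairs(f_m, f_b, data: _PreparedData, sigma: np.ndarray) -> np.ndarray:
    """Per-pair Stage-1 log likelihood under the combined error model."""
    sig_a, sig_p = sigma
    out = np.zeros(data.n_pairs)
    for f, y, mask in ((f_m, data.y_m, data.mask_m), (f_b, data.y_b, data.mask_b)):
        var = sig_a**2 + (sig_p * f) ** 2
        ll = -0.5 * (_LOG2PI + np.log(var) + (y - f) ** 2 / var)
        out += np.sum(np.where(mask, ll, 0.0), axis=1)
    return out


def _pointwise_loglik(f_m, f_b, data: _PreparedData, sigma) -> np.ndarray:
    """Flattened per-observation log densities (mother obs then infant obs,
    pair by pair) — the pointwise quantities WAIC and PSIS-LOO consume."""
    sig_a, sig_p = sigma
    chunks = []
    for i in range(data.n_pairs):
        for f, y, mask in (
            (f_m[i], data.y_m[i], data.mask_m[i]),
            (f_b[i], data.y_b[i], data.mask_b[i]),
        ):
            var = sig_a**2 + (sig_p * f[mask]) ** 2
            chunks.append(-0.5 * (_LOG2PI + np.log(var) + (y[mask] - f[mask]) ** 2 / var))
    return np.concatenate(chunks)


def _omega_from(lam: np.ndarray, rho: np.ndarray) -> np.ndarray:
    return rho * np.outer(lam, lam)


def _mvn_logpdf_pairs(eta, mean, chol_omega) -> np.ndarray:
    dev = (eta - mean).T  # (4, n)
    sol = solve_triangular(chol_omega, dev, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol_omega)))
    return -0.5 * (4 * _LOG2PI + logdet + np.sum(sol**2, axis=0))


def _constraint_ok(eta: np.ndarray) -> np.ndarray:
    # CL_mb < k_mm * V_m  <=>  lnCL_mb < lnk_mm + lnV_m
    return eta[:, 0] < eta[:, 2] + eta[:, 3]


def _halfnormal_logpdf(x, sd):
    return np.sum(-0.5 * (x / sd) ** 2)  # constants cancel in MH ratios


# ---------------------------------------------------------------------------
# initial values


def _initial_estimates(data: _PreparedData, model: ModelDefinition):
    """Cheap per-pair starting values: log-linear regression on the mother
    curve, then a bounded least-squares fit of the infant curve."""
    from scipy.optimize import curve_fit

    n = data.n_pairs
    eta = np.zeros((n, 4))
    for i in range(n):
        t = data.t_m[i, data.mask_m[i]]
        y = np.clip(data.y_m[i, data.mask_m[i]], 1e-3, None)
        slope, intercept = np.polyfit(t, np.log(y), 1)
        k_mm = float(np.clip(-slope, 0.02, 0.5))
        v_m = float(np.clip(1e6 * data.dose[i] / np.exp(intercept), 10.0, 70.0))

        tb = data.t_b[i, data.mask_b[i]]
        yb = data.y_b[i, data.mask_b[i]]
        vb = data.vb_t[i, data.mask_b[i]]

        def curve(t_, k_bo, k_mb, _k=k_mm, _v=vb, _t=tb, _d=data.dose[i]):
            d = _k - k_bo
            d = np.where(np.abs(d) < 1e-9, 1e-9, d)
            return 1e6 * _d * k_mb / d * (np.exp(-k_bo * t_) - np.exp(-_k * t_)) / _v

        try:
            popt, _ = curve_fit(
                curve,
                tb,
                yb,
                p0=(0.25, 0.03),
                bounds=((0.02, 1e-4), (1.5, 0.5)),
                maxfev=2000,
            )
            k_bo, k_mb = popt
        except Exception:
            k_bo, k_mb = 0.25, 0.8 / v_m
        cl_bo = float(np.clip(k_bo * data.vb_mid[i], 0.05, 5.0))
        cl_mb = float(np.clip(k_mb * v_m, 0.05, 0.9 * k_mm * v_m))
        eta[i] = np.log([cl_mb, cl_bo, k_mm, v_m])

    X = _design_matrix(data, model)
    # least-squares regression of eta on the design for starting beta
    Xf = X.reshape(n * 4, model.n_beta)
    beta, *_ = np.linalg.lstsq(Xf, eta.reshape(n * 4), rcond=None)
    resid = eta - np.einsum("ipq,q->ip", X, beta)
    lam = np.clip(resid.std(axis=0), 0.05, 1.0)
    return eta, beta, lam


# ---------------------------------------------------------------------------
# the sampler


def _run_chain(
    data: _PreparedData,
    model: ModelDefinition,
    priors: PriorSpec,
    settings: McmcSettings,
    rng: np.random.Generator,
    init,
    sigma_fixed=None,
):
    n, q = data.n_pairs, model.n_beta
    X = _design_matrix(data, model)
    eta0, beta0, lam0 = init
    eta = eta0 + rng.normal(0.0, 0.05, size=eta0.shape)
    bad = ~_constraint_ok(eta)
    eta[bad] = eta0[bad]
    beta = beta0 + rng.normal(0.0, 0.02, size=q)
    lam = lam0 * np.exp(rng.normal(0.0, 0.05, size=4))
    rho = np.eye(4)
    estimate_sigma = sigma_fixed is None
    if estimate_sigma:
        sigma = np.array([5.0, 0.02] if model.error_model == "combined" else [5.0, 0.0])
    else:
        sigma = np.array(
            [sigma_fixed[0], sigma_fixed[1] if model.error_model == "combined" else 0.0]
        )
        sigma = np.clip(sigma, 1e-6, None)

    logmu_mean = np.broadcast_to(np.asarray(priors.logmu_mean, dtype=float), (q,)).copy()
    prior_prec = 1.0 / priors.logmu_sd**2

    omega = _omega_from(lam, rho)
    chol_om = cholesky(omega, lower=True)
    mean = np.einsum("ipq,q->ip", X, beta)
    f_m, f_b = _predict_curves(eta, data)
    ll = _loglik_pairs(f_m, f_b, data, sigma)
    lp_eta = _mvn_logpdf_pairs(eta, mean, chol_om)

    # adaptation state
    log_step_eta = np.full(n, np.log(0.3))
    L_prop = np.tile(np.eye(4) * 0.05, (n, 1, 1))
    welford_count = 0
    welford_mean = np.zeros((n, 4))
    welford_m2 = np.zeros((n, 4, 4))
    log_step_lam = np.log(0.1)
    tri = [(j, k) for j in range(4) for k in range(j + 1, 4)]
    log_step_rho = np.full(len(tri), np.log(0.2))
    log_step_sig = np.log(0.1)

    total = settings.n_warmup + settings.n_draws * settings.thin
    keep_eta = np.empty((settings.n_draws, n, 4))
    keep_beta = np.empty((settings.n_draws, q))
    keep_lam = np.empty((settings.n_draws, 4))
    keep_rho = np.empty((settings.n_draws, 4, 4))
    keep_sigma = np.empty((settings.n_draws, 2))
    acc_eta_count = np.zeros(n)
    acc_sig_count = 0
    post_iters = 0

    def mvn_sum(lam_, rho_):
        om = _omega_from(lam_, rho_)
        try:
            ch = cholesky(om, lower=True)
        except np.linalg.LinAlgError:
            return None, None, -np.inf
        lp = _mvn_logpdf_pairs(eta, mean, ch)
        return om, ch, lp

    for it in range(total):
        warm = it < settings.n_warmup
        gamma = (it + 1) ** -0.6 if warm else 0.0

        # -- individual parameters ----------------------------------------
        z = rng.standard_normal((n, 4))
        prop = eta + np.exp(log_step_eta)[:, None] * np.einsum("nij,nj->ni", L_prop, z)
        ok = _constraint_ok(prop)
        fm_p, fb_p = _predict_curves(prop, data)
        ll_p = _loglik_pairs(fm_p, fb_p, data, sigma)
        lp_p = _mvn_logpdf_pairs(prop, mean, chol_om)
        logr = np.where(ok, (ll_p + lp_p) - (ll + lp_eta), -np.inf)
        accept = np.log(rng.random(n)) < logr
        eta[accept] = prop[accept]
        ll[accept] = ll_p[accept]
        lp_eta[accept] = lp_p[accept]
        f_m[accept] = fm_p[accept]
        f_b[accept] = fb_p[accept]
        if warm:
            p_acc = np.exp(np.minimum(0.0, logr))
            log_step_eta += gamma * (p_acc - settings.target_accept)
            welford_count += 1
            delta = eta - welford_mean
            welford_mean += delta / welford_count
            welford_m2 += delta[:, :, None] * (eta - welford_mean)[:, None, :]
            if welford_count > 200 and it % 100 == 0:
                cov = welford_m2 / (welford_count - 1) + 1e-8 * np.eye(4)
                for i in range(n):
                    try:
                        L_prop[i] = cholesky(cov[i], lower=True)
                    except np.linalg.LinAlgError:
                        pass
        else:
            acc_eta_count += accept

        # -- population coefficients (conjugate Gibbs) --------------------
        om_inv = cho_solve((chol_om, True), np.eye(4))
        A = np.einsum("ipa,pq,iqb->ab", X, om_inv, X) + prior_prec * np.eye(q)
        b = np.einsum("ipa,pq,iq->a", X, om_inv, eta) + prior_prec * logmu_mean
        chA = cholesky(A, lower=True)
        beta_mean = cho_solve((chA, True), b)
        beta = beta_mean + solve_triangular(chA.T, rng.standard_normal(q), lower=False)
        mean = np.einsum("ipq,q->ip", X, beta)
        lp_eta = _mvn_logpdf_pairs(eta, mean, chol_om)

        # -- scales lambda -------------------------------------------------
        lam_p = lam * np.exp(np.exp(log_step_lam) * rng.standard_normal(4))
        _, ch_p, lp_vec = mvn_sum(lam_p, rho)
        if np.isfinite(np.sum(lp_vec)):
            cur = np.sum(lp_eta) + _halfnormal_logpdf(lam, priors.scale_sd) + np.sum(np.log(lam))
            new = np.sum(lp_vec) + _halfnormal_logpdf(lam_p, priors.scale_sd) + np.sum(
                np.log(lam_p)
            )
            logr_l = new - cur
            if np.log(rng.random()) < logr_l:
                lam = lam_p
                chol_om = ch_p
                omega = _omega_from(lam, rho)
                lp_eta = lp_vec
            if warm:
                log_step_lam += gamma * (np.exp(min(0.0, logr_l)) - settings.target_accept)
        elif warm:
            log_step_lam += gamma * (0.0 - settings.target_accept)

        # -- correlations rho ---------------------------------------------
        for e, (j, k) in enumerate(tri):
            r_p = rho.copy()
            r_p[j, k] = r_p[k, j] = rho[j, k] + np.exp(log_step_rho[e]) * rng.standard_normal()
            if abs(r_p[j, k]) >= 1.0:
                logr_r = -np.inf
            else:
                _, ch_p, lp_vec = mvn_sum(lam, r_p)
                if not np.isfinite(np.sum(lp_vec)):
                    logr_r = -np.inf
                else:
                    prior_term = 0.0
                    if priors.lkj_shape != 1.0:
                        s_new = np.linalg.slogdet(r_p)[1]
                        s_old = np.linalg.slogdet(rho)[1]
                        prior_term = (priors.lkj_shape - 1.0) * (s_new - s_old)
                    logr_r = np.sum(lp_vec) - np.sum(lp_eta) + prior_term
            if np.isfinite(logr_r) and np.log(rng.random()) < logr_r:
                rho = r_p
                chol_om = ch_p
                omega = _omega_from(lam, rho)
                lp_eta = lp_vec
            if warm:
                log_step_rho[e] += gamma * (
                    np.exp(min(0.0, logr_r)) - settings.target_accept
                )

        # -- residual sigma -----------------------------------------------
        if estimate_sigma:
            n_sig = 2 if model.error_model == "combined" else 1
            sig_p = sigma.copy()
            sig_p[:n_sig] = sigma[:n_sig] * np.exp(
                np.exp(log_step_sig) * rng.standard_normal(n_sig)
            )
            ll_p2 = _loglik_pairs(f_m, f_b, data, sig_p)
            cur = (
                np.sum(ll)
                + _halfnormal_logpdf(sigma[:n_sig], priors.sigma_sd)
                + np.sum(np.log(sigma[:n_sig]))
            )
            new = (
                np.sum(ll_p2)
                + _halfnormal_logpdf(sig_p[:n_sig], priors.sigma_sd)
                + np.sum(np.log(sig_p[:n_sig]))
            )
            logr_s = new - cur
            if np.log(rng.random()) < logr_s:
                sigma = sig_p
                ll = ll_p2
                acc_sig_count += 0 if warm else 1
            if warm:
                log_step_sig += gamma * (np.exp(min(0.0, logr_s)) - settings.target_accept)

        if not warm:
            post_iters += 1
            offset = it - settings.n_warmup
            if offset % settings.thin == 0:
                s = offset // settings.thin
                keep_eta[s] = eta
                keep_beta[s] = beta
                keep_lam[s] = lam
                keep_rho[s] = rho
                keep_sigma[s] = sigma

    accept_rates = {
        "eta": acc_eta_count / max(post_iters, 1),
        "sigma": acc_sig_count / max(post_iters, 1) if estimate_sigma else np.nan,
    }
    return keep_eta, keep_beta, keep_lam, keep_rho, keep_sigma, accept_rates


# ---------------------------------------------------------------------------
# posterior container and diagnostics


@dataclass
class PosteriorDraws:
    """MCMC output: per-chain, per-draw population and individual parameters."""

    eta: np.ndarray  # (chains, draws, n_pairs, 4)
    beta: np.ndarray  # (chains, draws, q)
    lam: np.ndarray  # (chains, draws, 4)
    rho: np.ndarray  # (chains, draws, 4, 4)
    sigma: np.ndarray  # (chains, draws, 2) — (sigma_add, sigma_prop)
    pair_ids: list
    beta_names: tuple
    model: ModelDefinition
    settings: McmcSettings
    accept_rates: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.eta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.eta.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains (first axis = chain*draw)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def individual_theta(self, pair_id: str) -> np.ndarray:
        """Pooled natural-scale draws (S, 4) ordered (CL_mb, CL_bo, k_mm, V_m)."""
        i = self.pair_ids.index(pair_id)
        return np.exp(self.pooled("eta")[:, i, :])

    def beta_summary(self):
        import pandas as pd

        pooled = self.pooled("beta")
        return pd.DataFrame(
            {
                "mean": pooled.mean(axis=0),
                "sd": pooled.std(axis=0, ddof=1),
                "q2.5": np.quantile(pooled, 0.025, axis=0),
                "q97.5": np.quantile(pooled, 0.975, axis=0),
            },
            index=list(self.beta_names),
        )

    def to_inferencedata(self, log_likelihood: np.ndarray | None = None) -> az.InferenceData:
        posterior = {
            "beta": (("chain", "draw", "beta_dim"), self.beta),
            "lam": (("chain", "draw", "param"), self.lam),
            "sigma": (("chain", "draw", "sigma_dim"), self.sigma),
            "eta": (("chain", "draw", "pair", "param"), self.eta),
        }
        coords = {
            "beta_dim": list(self.beta_names),
            "param": list(PARAM_NAMES),
            "sigma_dim": ["sigma_add", "sigma_prop"],
            "pair": list(self.pair_ids),
        }
        import xarray as xr

        post = xr.Dataset(
            {k: xr.DataArray(v[1], dims=v[0]) for k, v in posterior.items()}, coords=coords
        )
        groups = {"posterior": post}
        if log_likelihood is not None:
            groups["log_likelihood"] = xr.Dataset(
                {"y": xr.DataArray(log_likelihood, dims=("chain", "draw", "obs"))}
            )
        return az.InferenceData(**groups)

    def to_frame(self):
        """Long-format columnar view: one row per (chain, draw)."""
        import pandas as pd

        c, d = self.n_chains, self.n_draws
        cols = {
            "chain": np.repeat(np.arange(c), d),
            "draw": np.tile(np.arange(d), c),
        }
        for j, name in enumerate(self.beta_names):
            cols[f"beta.{name}"] = self.beta[:, :, j].ravel()
        for j, name in enumerate(PARAM_NAMES):
            cols[f"lam.{name}"] = self.lam[:, :, j].ravel()
        cols["sigma_add"] = self.sigma[:, :, 0].ravel()
        cols["sigma_prop"] = self.sigma[:, :, 1].ravel()
        for j in range(4):
            for k in range(j + 1, 4):
                cols[f"rho.{PARAM_NAMES[j]}.{PARAM_NAMES[k]}"] = self.rho[:, :, j, k].ravel()
        for i, pid in enumerate(self.pair_ids):
            for j, name in enumerate(PARAM_NAMES):
                cols[f"eta.{pid}.{name}"] = self.eta[:, :, i, j].ravel()
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        """Persist draws as a columnar CSV plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "pair_ids": list(self.pair_ids),
            "beta_names": list(self.beta_names),
            "covariate_model": self.model.covariate_model,
            "error_model": self.model.error_model,
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "settings": {
                "n_warmup": self.settings.n_warmup,
                "thin": self.settings.thin,
                "seed": self.settings.seed,
            },
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        import json
        from pathlib import Path

        import pandas as pd

        path = Path(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        df = pd.read_csv(path)
        c, d = meta["n_chains"], meta["n_draws"]
        pair_ids = meta["pair_ids"]
        beta_names = tuple(meta["beta_names"])

        def grab(cols, shape):
            return df[cols].to_numpy().reshape((c, d, len(cols))).reshape(shape)

        beta = grab([f"beta.{n}" for n in beta_names], (c, d, len(beta_names)))
        lam = grab([f"lam.{n}" for n in PARAM_NAMES], (c, d, 4))
        sigma = grab(["sigma_add", "sigma_prop"], (c, d, 2))
        rho = np.tile(np.eye(4), (c, d, 1, 1))
        for j in range(4):
            for k in range(j + 1, 4):
                vals = df[f"rho.{PARAM_NAMES[j]}.{PARAM_NAMES[k]}"].to_numpy().reshape(c, d)
                rho[:, :, j, k] = vals
                rho[:, :, k, j] = vals
        eta = np.empty((c, d, len(pair_ids), 4))
        for i, pid in enumerate(pair_ids):
            for j, name in enumerate(PARAM_NAMES):
                eta[:, :, i, j] = df[f"eta.{pid}.{name}"].to_numpy().reshape(c, d)
        model = build_model(meta["covariate_model"], meta["error_model"])
        settings = McmcSettings(
            n_chains=c,
            n_draws=d,
            n_warmup=meta["settings"]["n_warmup"],
            thin=meta["settings"]["thin"],
            seed=meta["settings"]["seed"],
        )
        return cls(
            eta=eta,
            beta=beta,
            lam=lam,
            rho=rho,
            sigma=sigma,
            pair_ids=pair_ids,
            beta_names=beta_names,
            model=model,
            settings=settings,
        )

    def diagnostics(self) -> dict:
        """Split-Rhat and effective sample size for every population parameter."""
        out = {}
        for j, name in enumerate(self.beta_names):
            out[name] = {
                "rhat": rhat(self.beta[:, :, j]),
                "n_eff": effective_sample_size(self.beta[:, :, j]),
            }
        for j, name in enumerate(PARAM_NAMES):
            out[f"lam_{name}"] = {
                "rhat": rhat(self.lam[:, :, j]),
                "n_eff": effective_sample_size(self.lam[:, :, j]),
            }
        sig_names = self.model.sigma_names
        for j, name in enumerate(sig_names):
            out[name] = {
                "rhat": rhat(self.sigma[:, :, j]),
                "n_eff": effective_sample_size(self.sigma[:, :, j]),
            }
        return out


def rhat(samples) -> float:
    """Rank-normalized split potential-scale-reduction factor.

    ``samples`` has shape (chains, draws); at least two chains are required.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2:
        raise ValueError("samples must have shape (chains, draws)")
    if arr.shape[0] < 2:
        raise ValueError("Rhat needs at least 2 chains")
    if np.ptp(arr) == 0:
        warnings.warn("constant chains: Rhat is degenerate", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(az.rhat(arr))


def effective_sample_size(samples) -> float:
    """Autocorrelation-based effective number of draws (bulk ESS)."""
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    if np.ptp(arr) == 0:
        warnings.warn("constant chain: effective sample size is 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float(az.ess(arr))


# ---------------------------------------------------------------------------
# estimator


class HierarchicalDtmModel(BaseEstimator):
    """Hierarchical Bayesian model of D2O disposition in mother-infant pairs.

    Parameters
    ----------
    covariate_model : "none" or "full"
        "full" adds the maternal-weight power on V_m (reference 70 kg) and
        the infant-weight power on CL_bo (reference 5 kg).
    error_model : "additive" or "combined"
        Residual model; "combined" is sd = sqrt(sa^2 + (sp*f)^2).
    n_chains, n_draws, n_warmup, thin : int
        Sampler protocol; ``n_draws`` counts retained draws per chain.
    sigma_fixed : tuple or None
        Fix (sigma_add, sigma_prop) instead of sampling them.
    random_state : int
        Seed for the whole run.

    Fitted attributes end in an underscore: ``posterior_`` (the draws),
    ``diagnostics_`` (Rhat / ESS per population parameter), ``pair_ids_``.
    """

    def __init__(
        self,
        covariate_model: str = "full",
        error_model: str = "combined",
        n_chains: int = 3,
        n_draws: int = 10_000,
        n_warmup: int = 1_000,
        thin: int = 5,
        random_state: int = 0,
        water_fraction: float = 0.60,
        priors: PriorSpec | None = None,
        sigma_fixed: tuple | None = None,
        rhat_warn: float = 1.05,
    ) -> None:
        self.covariate_model = covariate_model
        self.error_model = error_model
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.thin = thin
        self.random_state = random_state
        self.water_fraction = water_fraction
        self.priors = priors
        self.sigma_fixed = sigma_fixed
        self.rhat_warn = rhat_warn

    def fit(self, pairs: Sequence[PairDataset], y=None) -> "HierarchicalDtmModel":
        model = build_model(self.covariate_model, self.error_model)
        priors = self.priors if self.priors is not None else PriorSpec()
        settings = McmcSettings(
            n_chains=self.n_chains,
            n_draws=self.n_draws,
            n_warmup=self.n_warmup,
            thin=self.thin,
            seed=self.random_state,
        )
        data = _prepare(pairs, self.water_fraction)
        init = _initial_estimates(data, model)
        streams = np.random.SeedSequence(self.random_state).spawn(settings.n_chains)
        chains = [
            _run_chain(
                data,
                model,
                priors,
                settings,
                np.random.default_rng(stream),
                init,
                sigma_fixed=self.sigma_fixed,
            )
            for stream in streams
        ]
        self.model_ = model
        self.data_ = data
        self.pair_ids_ = list(data.pair_ids)
        self.posterior_ = PosteriorDraws(
            eta=np.stack([c[0] for c in chains]),
            beta=np.stack([c[1] for c in chains]),
            lam=np.stack([c[2] for c in chains]),
            rho=np.stack([c[3] for c in chains]),
            sigma=np.stack([c[4] for c in chains]),
            pair_ids=self.pair_ids_,
            beta_names=model.beta_names,
            model=model,
            settings=settings,
            accept_rates=[c[5] for c in chains],
        )
        self.diagnostics_ = self.posterior_.diagnostics()
        worst = max(v["rhat"] for v in self.diagnostics_.values())
        self.max_rhat_ = worst
        low_acc = min(float(np.min(c[5]["eta"])) for c in chains)
        self.min_accept_rate_ = low_acc
        if worst > self.rhat_warn:
            warnings.warn(
                f"max Rhat {worst:.3f} exceeds {self.rhat_warn}: chains may not have converged",
                RuntimeWarning,
                stacklevel=2,
            )
        if low_acc < 0.05:
            warnings.warn(
                f"minimum per-pair acceptance rate {low_acc:.3f} is very low",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def attach(self, pairs: Sequence[PairDataset], posterior: PosteriorDraws) -> "HierarchicalDtmModel":
        """Restore a fitted state from persisted draws plus the original data."""
        data = _prepare(pairs, self.water_fraction)
        if list(data.pair_ids) != list(posterior.pair_ids):
            raise ValueError("pair ids of the data do not match the saved draws")
        self.model_ = posterior.model
        self.data_ = data
        self.pair_ids_ = list(data.pair_ids)
        self.posterior_ = posterior
        self.diagnostics_ = posterior.diagnostics()
        self.max_rhat_ = max(v["rhat"] for v in self.diagnostics_.values())
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def pointwise_log_likelihood(self) -> np.ndarray:
        """log p(y_ij | theta_i, sigma) per (chain, draw, observation)."""
        self._check_fitted()
        post = self.posterior_
        n_obs = self.data_.n_obs
        out = np.empty((post.n_chains, post.n_draws, n_obs))
        for c in range(post.n_chains):
            for s in range(post.n_draws):
                f_m, f_b = _predict_curves(post.eta[c, s], self.data_)
                out[c, s] = _pointwise_loglik(f_m, f_b, self.data_, post.sigma[c, s])
        return out

    def predict_curves(self, pair_id: str, t, role: str, include_noise: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Posterior(-predictive) enrichment draws for one pair on a time grid.

        Returns an (S, len(t)) array of pooled-chain draws.
        """
        self._check_fitted()
        i = self.pair_ids_.index(pair_id)
        t = np.asarray(t, dtype=float)
        theta = self.posterior_.pooled("eta")[:, i, :]
        sigma = self.posterior_.pooled("sigma")
        cl_mb, cl_bo, k_mm, v_m = (np.exp(theta[:, j]) for j in range(4))
        pool = self.data_.pools[i]
        dose = self.data_.dose[i]
        if role == "mother":
            f = 1e6 * dose / v_m[:, None] * np.exp(-k_mm[:, None] * t[None, :])
        elif role == "infant":
            k_mb = cl_mb / v_m
            k_bo = cl_bo / self.data_.vb_mid[i]
            diff = (k_mm - k_bo)[:, None]
            amt = dose * k_mb[:, None] / diff * (
                np.exp(-k_bo[:, None] * t[None, :]) - np.exp(-k_mm[:, None] * t[None, :])
            )
            f = 1e6 * amt / pool.volume(t)[None, :]
        else:
            raise ValueError(f"role must be 'mother' or 'infant', got {role!r}")
        if include_noise:
            rng = rng or np.random.default_rng(self.random_state)
            sd = np.sqrt(sigma[:, 0:1] ** 2 + (sigma[:, 1:2] * f) ** 2)
            f = f + rng.standard_normal(f.shape) * sd
        return f

    def sample_prior_population(self, n_draws: int = 1000, seed: int = 0) -> np.ndarray:
        """Stage-3 prior draws of the population coefficient vector (no data)."""
        model = build_model(self.covariate_model, self.error_model)
        priors = self.priors if self.priors is not None else PriorSpec()
        rng = np.random.default_rng(seed)
        mean = np.broadcast_to(
            np.asarray(priors.logmu_mean, dtype=float), (model.n_beta,)
        )
        return mean + priors.logmu_sd * rng.standard_normal((n_draws, model.n_beta))


def fit(
    pairs: Sequence[PairDataset],
    model: ModelDefinition | None = None,
    settings: McmcSettings | None = None,
    **kwargs,
) -> HierarchicalDtmModel:
    """Thin functional wrapper: build the estimator, fit, return it."""
    model = model or build_model()
    settings = settings or McmcSettings()
    est = HierarchicalDtmModel(
        covariate_model=model.covariate_model,
        error_model=model.error_model,
        n_chains=settings.n_chains,
        n_draws=settings.n_draws,
        n_warmup=settings.n_warmup,
        thin=settings.thin,
        random_state=settings.seed,
        **kwargs,
    )
    return est.fit(pairs)
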