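"""Metropolis-within-Gibbs sampler over the full ancestry model.

Each iteration alternates two steps.  Step 1 runs the forward-backward
engine for every haplotype copy and samples ancestral states G from the
posterior field gamma.  Step 2 sweeps Metropolis updates over every
parameter block, in a fixed order chosen for reproducibility:

    A (global ancestry), A_X, crossover augmentation + lambda,
    p (allele frequencies), beta (PCR coefficients), P, B,
    tau, omega / omega_X, alpha.

All proposals are independence proposals drawn from the conjugate-style
posterior or prior forms; acceptance ratios are the corresponding
prior/likelihood density ratios.  Genetic distances entering the
Poisson crossover rates are accumulated in Morgans (d / 100), the same
scale as the lambda*w/100 rates of the recombination model, so that
lambda keeps units of generations throughout.

Multiple chains can be run in lockstep; during burn-in each chain
blends its parameters with the across-chain mean using the weight
iter/n_burn (local) vs 1 - iter/n_burn (remote), which pulls early
exploration together while letting chains sample independently after
burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .ancestral_model import AncestralPrior
from .hmm_engine import (
    AncestryField,
    EmissionModel,
    forward_backward,
    recomb_prob,
    sample_paths,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParameters",
    "CrossoverSample",
    "McmcConfig",
    "McmcResult",
    "update_global_ancestry",
    "update_x_ancestry",
    "sample_crossovers",
    "update_lambda",
    "update_allele_freqs",
    "update_beta",
    "update_hyper_P",
    "update_hyper_B",
    "update_tau",
    "update_omega",
    "update_omega_x",
    "update_alpha",
    "combine_chains",
    "run_mcmc",
]

_EPS = 1e-12


@dataclass
class ModelParameters:
    """Full MCMC state.  Arrays are documented with their shapes."""

    A: np.ndarray                 # (n_ind, 2, K) global ancestry per haplotype copy
    lam: np.ndarray               # (n_ind, 2) generations since admixture
    tau: np.ndarray               # (K,) surrogate-concentration per population
    p: np.ndarray                 # (M, K) allele frequencies
    beta: list                    # per window: (K-1, m_j) PCR coefficients
    P: np.ndarray                 # (M, K) hyper allele frequencies
    B: list                       # per window: (K-1, m_j) coefficient hyper means
    omega: np.ndarray             # (K,) Dirichlet concentration for A
    omega_x: float                # scalar concentration for A_X
    m_gamma: float                # mean of lambda's Gamma prior (alpha1/alpha2)
    v_gamma: float                # variance of lambda's Gamma prior (alpha1/alpha2^2)
    AX: np.ndarray | None = None  # (n_ind, K) X-chromosome ancestry

    @property
    def alpha(self) -> tuple[float, float]:
        """(shape, rate) of lambda's Gamma prior from the (m, v) parameterization."""
        return self.m_gamma**2 / self.v_gamma, self.m_gamma / self.v_gamma

    def validate(self) -> None:
        if not np.allclose(self.A.sum(axis=-1), 1.0, atol=1e-8):
            raise FloatingPointError("A rows off the simplex")
        for name in ("lam", "tau", "omega"):
            if np.any(~np.isfinite(getattr(self, name))) or np.any(getattr(self, name) <= 0):
                raise FloatingPointError(f"non-positive or non-finite {name}")
        if np.any(self.p <= 0) or np.any(self.p >= 1):
            raise FloatingPointError("p outside (0,1)")


@dataclass
class CrossoverSample:
    """Auxiliary crossover-count sample (one HMM pass worth)."""

    nx: np.ndarray        # (H, J) sampled counts (>=1 where proposed, 0 elsewhere)
    px0: np.ndarray       # (H, J) P(zero crossovers | G)
    retained: np.ndarray  # (H, J) counts kept after thinning by 1 - px0
    counts: np.ndarray    # (H,) total retained per haplotype copy
    total_d: float        # sum of inter-window distances, Morgans


@dataclass
class McmcConfig:
    n_burn: int = 100
    n_keep: int = 200
    n_chains: int = 1
    thin: int = 1
    beta_refit_every: int = 1
    lam_init: float = 6.0
    tau_init: float = 300.0
    omega_init: float = 10.0
    omega_x_init: float = 10.0
    m_gamma_init: float = 6.0
    v_gamma_init: float = 4.0
    record_full: bool = False


# ---------------------------------------------------------------- updates


def _dirichlet_rows(conc, rng):
    """Vectorized Dirichlet draws, one per leading row of ``conc``."""
    g = rng.gamma(np.maximum(conc, 1e-6))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def update_global_ancestry(A, gamma_sums, omega, rng):
    """Propose A ~ Dirichlet(omega + sum_j gamma) per haplotype copy.

    Accepted with the prior-density ratio prod_k (A'/A)^(omega-1).
    Returns (A_new, accept_fraction).
    """
    prop = _dirichlet_rows(omega + gamma_sums, rng)
    prop = np.clip(prop, _EPS, None)
    prop /= prop.sum(axis=-1, keepdims=True)
    logr = np.sum((omega - 1.0) * (np.log(prop) - np.log(A)), axis=-1)
    acc = np.log(rng.random(logr.shape)) < np.minimum(0.0, logr)
    out = np.where(acc[..., None], prop, A)
    return out, float(acc.mean())


def update_x_ancestry(AX, A_ind, gamma_sums_x, omega_x, rng):
    """Propose A_X ~ Dirichlet(omega_X * A + X-window gamma sums) per individual."""
    if AX is None:
        logger.info("no X data: skipping A_X update")
        return None, 0.0
    conc0 = omega_x * A_ind
    prop = _dirichlet_rows(conc0 + gamma_sums_x, rng)
    prop = np.clip(prop, _EPS, None)
    prop /= prop.sum(axis=-1, keepdims=True)
    logr = np.sum((conc0 - 1.0) * (np.log(prop) - np.log(AX)), axis=-1)
    acc = np.log(rng.random(logr.shape)) < np.minimum(0.0, logr)
    return np.where(acc[..., None], prop, AX), float(acc.mean())


def sample_crossovers(lam_h, d_morgans, G, A_h, rng) -> CrossoverSample:
    """Sample admixture-era crossover counts between consecutive windows.

    For each (haplotype, window) with a defined inter-window distance,
    draw the Poisson count conditional on >= 1 crossover by uniform
    CDF inversion on (P(x=0), 1), then thin: a proposed count is kept
    with probability 1 - px0, where px0 = P(x = 0 | G) is 0 when the
    sampled states differ across the step and
    exp(-mu) / (exp(-mu) + A_g (1 - exp(-mu))) when they agree
    (mu = lambda * d Morgans, A_g the global weight of the shared state).
    """
    H, J = G.shape
    valid = ~np.isnan(d_morgans)
    dv = d_morgans[valid]
    mu = lam_h[:, None] * dv[None, :]
    p0 = np.exp(-mu)
    q = p0 + rng.random(mu.shape) * (1.0 - p0)
    # invert the Poisson CDF: smallest nx with CDF(nx) >= q (nx >= 1 since q > p0)
    nx = np.ones(mu.shape, dtype=np.int64)
    cdf = p0.copy()
    term = p0.copy()
    k = 0
    while True:
        k += 1
        term = term * mu / k
        cdf = cdf + term
        todo = q > cdf
        if not todo.any():
            break
        nx[todo] += 1
        if k > 10000:  # pragma: no cover - defensive
            break
    jj = np.nonzero(valid)[0]
    same = G[:, jj] == G[:, jj - 1]
    Ag = np.take_along_axis(A_h, G[:, jj], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        px0_same = p0 / (p0 + Ag * (1.0 - p0))
    px0v = np.where(same, px0_same, 0.0)
    keep = rng.random(mu.shape) < (1.0 - px0v)
    retained_v = nx * keep

    nx_full = np.zeros((H, J), dtype=np.int64)
    px0_full = np.ones((H, J))
    ret_full = np.zeros((H, J), dtype=np.int64)
    nx_full[:, jj] = nx
    px0_full[:, jj] = px0v
    ret_full[:, jj] = retained_v
    return CrossoverSample(
        nx=nx_full,
        px0=px0_full,
        retained=ret_full,
        counts=ret_full.sum(axis=1),
        total_d=float(np.nansum(dv)),
    )


def update_lambda(lam_h, counts, total_d, alpha, rng):
    """Propose lambda ~ Gamma(alpha1 + #crossovers, alpha2 + sum d) per copy.

    The rate increment sum_j d is in Morgans, matching the lambda*d
    Poisson rates.  Accepted with the Gamma prior-density ratio.
    """
    a1, a2 = alpha
    prop = rng.gamma(a1 + counts, 1.0 / (a2 + total_d))
    prop = np.maximum(prop, 1e-8)
    logr = (a1 - 1.0) * (np.log(prop) - np.log(lam_h)) - a2 * (prop - lam_h)
    acc = np.log(rng.random(logr.shape)) < np.minimum(0.0, logr)
    return np.where(acc, prop, lam_h), float(acc.mean())


def update_allele_freqs(p, P, tau, n_var, n_ref, rng):
    """Propose p ~ Beta(tau P + #variant, tau (1-P) + #reference) per (marker, pop).

    Counts are taken over haplotypes currently assigned ancestry k at
    the marker's window.  Accepted with the Beta prior-density ratio.
    """
    a = tau[None, :] * P + n_var
    b = tau[None, :] * (1.0 - P) + n_ref
    prop = np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)
    logr = (tau[None, :] * P - 1.0) * (np.log(prop) - np.log(p)) + (
        tau[None, :] * (1.0 - P) - 1.0
    ) * (np.log1p(-prop) - np.log1p(-p))
    acc = np.log(rng.random(logr.shape)) < np.minimum(0.0, logr)
    return np.where(acc, prop, p), float(acc.mean())


def update_beta(beta_j, B_j, Sigma_j, tau_c, beta_hat, n, rng):
    """One window's PCR-coefficient update.

    Proposal N((n beta_hat + tau B) / (n + tau), diag(Sigma)/(n+tau)^2)
    per contrast; accepted with the N(B, diag(Sigma)/tau^2) prior ratio.
    beta_hat is the refit on currently G-labelled haplotypes (n used).
    Returns (beta_new, accepted_count).
    """
    nc, m = beta_j.shape
    out = beta_j.copy()
    n_acc = 0
    for c in range(nc):
        tau = tau_c[c]
        mean = (n * beta_hat[c] + tau * B_j[c]) / (n + tau)
        sd = np.sqrt(Sigma_j[c]) / (n + tau)
        prop = mean + sd * rng.standard_normal(m)
        q_new = np.sum((prop - B_j[c]) ** 2 / Sigma_j[c])
        q_old = np.sum((beta_j[c] - B_j[c]) ** 2 / Sigma_j[c])
        logr = -0.5 * tau**2 * (q_new - q_old)
        if np.log(rng.random()) < min(0.0, logr):
            out[c] = prop
            n_acc += 1
    return out, n_acc


def update_hyper_P(P, Omega, tau, p, rng):
    """Propose P ~ Beta(Omega) per (marker, pop); accept with the
    Beta(tau P', tau (1-P')) vs Beta(tau P, tau (1-P)) likelihood ratio at p."""
    prop = np.clip(rng.beta(Omega[..., 0], Omega[..., 1]), 1e-9, 1 - 1e-9)
    t = tau[None, :]

    def loglik(Pv):
        return (
            -gammaln(t * Pv)
            - gammaln(t * (1 - Pv))
            + (t * Pv - 1.0) * np.log(p)
            + (t * (1 - Pv) - 1.0) * np.log1p(-p)
        )

    logr = loglik(prop) - loglik(P)
    acc = np.log(rng.random(logr.shape)) < np.minimum(0.0, logr)
    return np.where(acc, prop, P), float(acc.mean())


def update_hyper_B(B_j, H_j, Sigma_j, tau_c, beta_j, rng):
    """Propose B ~ N(H, diag(Sigma)); accept with the beta-likelihood ratio
    exp(-tau^2/2 [(beta-B')' S^-1 (beta-B') - (beta-B)' S^-1 (beta-B)])."""
    nc, m = B_j.shape
    out = B_j.copy()
    n_acc = 0
    for c in range(nc):
        prop = H_j[c] + np.sqrt(Sigma_j[c]) * rng.standard_normal(m)
        q_new = np.sum((beta_j[c] - prop) ** 2 / Sigma_j[c])
        q_old = np.sum((beta_j[c] - B_j[c]) ** 2 / Sigma_j[c])
        logr = -0.5 * tau_c[c] ** 2 * (q_new - q_old)
        if np.log(rng.random()) < min(0.0, logr):
            out[c] = prop
            n_acc += 1
    return out, n_acc


def _tau_loglik_p(tau_k, P_k, p_k):
    return np.sum(
        gammaln(tau_k)
        - gammaln(tau_k * P_k)
        - gammaln(tau_k * (1 - P_k))
        + (tau_k * P_k - 1.0) * np.log(p_k)
        + (tau_k * (1 - P_k) - 1.0) * np.log1p(-p_k)
    )


def update_tau(tau, p, P, beta, B, Sigma, rng):
    """Propose tau from its log10-normal prior N(2, 0.5) per population.

    Accepted with the product of two likelihood ratios: the Beta
    likelihood of p given (tau, P) over markers, and the
    N(B, diag(Sigma)/tau^2) likelihood of beta over windows (for the
    populations that own a PCR contrast; population 1 is the reference
    and is constrained through p only).
    """
    K = tau.shape[0]
    out = tau.copy()
    accs = np.zeros(K, dtype=bool)
    # per-contrast quadratic forms, shared by every tau evaluation
    for k in range(K):
        prop = 10.0 ** rng.normal(2.0, 0.5)
        logr = _tau_loglik_p(prop, P[:, k], p[:, k]) - _tau_loglik_p(out[k], P[:, k], p[:, k])
        if k >= 1:
            c = k - 1
            for bj, Bj, Sj in zip(beta, B, Sigma):
                if bj.shape[0] == 0:
                    continue
                Q = np.sum((bj[c] - Bj[c]) ** 2 / Sj[c])
                ell = bj[c].shape[0]
                logr += ell * (np.log(prop) - np.log(out[k]))
                logr += -0.5 * (prop**2 - out[k] ** 2) * Q
        if np.log(rng.random()) < min(0.0, logr):
            out[k] = prop
            accs[k] = True
    return out, float(accs.mean())


def _dirichlet_logpdf_terms(omega, A):
    """Sum over rows of the Dirichlet(omega) log density at rows of A."""
    n = A.shape[0]
    return (
        n * gammaln(np.sum(omega))
        - n * np.sum(gammaln(omega))
        + np.sum((omega - 1.0) * np.log(A))
    )


def update_omega(omega, A_rows, rng):
    """Propose each omega_k from its log10-normal prior N(1, 0.5) jointly;
    accept with the Dirichlet density ratio over all haplotype copies."""
    prop = 10.0 ** rng.normal(1.0, 0.5, size=omega.shape)
    logr = _dirichlet_logpdf_terms(prop, A_rows) - _dirichlet_logpdf_terms(omega, A_rows)
    if np.log(rng.random()) < min(0.0, logr):
        return prop, True
    return omega, False


def update_omega_x(omega_x, A_ind, AX, rng):
    """Propose omega_X from log10-normal N(1, 0.5); accept with the
    Dirichlet(omega_X * A_i) density ratio over individuals."""
    if AX is None:
        return omega_x, False
    prop = 10.0 ** rng.normal(1.0, 0.5)

    def ll(w):
        conc = w * A_ind
        return np.sum(
            gammaln(conc.sum(axis=1))
            - np.sum(gammaln(conc), axis=1)
            + np.sum((conc - 1.0) * np.log(AX), axis=1)
        )

    logr = ll(prop) - ll(omega_x)
    if np.log(rng.random()) < min(0.0, logr):
        return prop, True
    return omega_x, False


def _gamma_loglik(lam_flat, a1, a2):
    return np.sum(a1 * np.log(a2) - gammaln(a1) + (a1 - 1.0) * np.log(lam_flat) - a2 * lam_flat)


def update_alpha(m_gamma, v_gamma, lam_flat, rng):
    """Update the (mean, variance) parameterization of lambda's Gamma prior.

    m and v are proposed independently from their log10-normal N(1, 0.5)
    priors; each proposal is accepted with the Gamma(alpha(m, v))
    likelihood ratio over all haplotype copies, where alpha1 = m^2/v and
    alpha2 = m/v.
    """
    acc = 0
    for which in ("m", "v"):
        prop = 10.0 ** rng.normal(1.0, 0.5)
        if which == "m":
            new_m, new_v = prop, v_gamma
        else:
            new_m, new_v = m_gamma, prop
        a1n, a2n = new_m**2 / new_v, new_m / new_v
        a1o, a2o = m_gamma**2 / v_gamma, m_gamma / v_gamma
        logr = _gamma_loglik(lam_flat, a1n, a2n) - _gamma_loglik(lam_flat, a1o, a2o)
        if np.log(rng.random()) < min(0.0, logr):
            m_gamma, v_gamma = new_m, new_v
            acc += 1
    return m_gamma, v_gamma, acc


def combine_chains(local: ModelParameters, remote: ModelParameters, it: int, n_burn: int) -> ModelParameters:
    """Blend a chain's parameters with the across-chain mean during burn-in.

    Every continuous parameter becomes (it/n_burn) * local +
    (1 - it/n_burn) * remote; simplex-valued blocks are renormalized
    after blending (a convex combination of simplex points is already on
    the simplex up to rounding).
    """
    if not 0 <= it <= n_burn:
        raise ValueError("iteration outside burn-in")
    w = it / n_burn

    def mix(a, b):
        return w * a + (1.0 - w) * b

    A = mix(local.A, remote.A)
    A = A / A.sum(axis=-1, keepdims=True)
    AX = None
    if local.AX is not None:
        if remote.AX is None:
            raise ValueError("chain structure mismatch: A_X")
        AX = mix(local.AX, remote.AX)
        AX = AX / AX.sum(axis=-1, keepdims=True)
    if len(local.beta) != len(remote.beta):
        raise ValueError("chain structure mismatch: beta")
    return ModelParameters(
        A=A,
        AX=AX,
        lam=mix(local.lam, remote.lam),
        tau=mix(local.tau, remote.tau),
        p=np.clip(mix(local.p, remote.p), 1e-9, 1 - 1e-9),
        beta=[mix(a, b) for a, b in zip(local.beta, remote.beta)],
        P=np.clip(mix(local.P, remote.P), 1e-9, 1 - 1e-9),
        B=[mix(a, b) for a, b in zip(local.B, remote.B)],
        omega=mix(local.omega, remote.omega),
        omega_x=mix(local.omega_x, remote.omega_x),
        m_gamma=mix(local.m_gamma, remote.m_gamma),
        v_gamma=mix(local.v_gamma, remote.v_gamma),
    )


def _mean_params(states: list[ModelParameters]) -> ModelParameters:
    n = len(states)

    def avg(xs):
        return sum(xs) / n

    return ModelParameters(
        A=avg([s.A for s in states]),
        AX=None if states[0].AX is None else avg([s.AX for s in states]),
        lam=avg([s.lam for s in states]),
        tau=avg([s.tau for s in states]),
        p=avg([s.p for s in states]),
        beta=[avg([s.beta[j] for s in states]) for j in range(len(states[0].beta))],
        P=avg([s.P for s in states]),
        B=[avg([s.B[j] for s in states]) for j in range(len(states[0].B))],
        omega=avg([s.omega for s in states]),
        omega_x=avg([s.omega_x for s in states]),
        m_gamma=avg([s.m_gamma for s in states]),
        v_gamma=avg([s.v_gamma for s in states]),
    )


# ---------------------------------------------------------------- orchestration


def _refit_beta_window(em: EmissionModel, j: int, G_j, K: int, warm, min_n: int):
    """Refit the window-j PCR on haplotypes as labelled by the current G.

    Returns (beta_hat (K-1, m), n_used) or (None, 0) when too few
    haplotypes are assigned (the beta update is then skipped).
    """
    from .ancestral_model import _logistic_irls

    proj = em.proj[j]
    m = proj.shape[1] + 1
    Z = np.column_stack([np.ones(proj.shape[0]), proj])
    beta_hat = np.zeros((K - 1, m))
    n_used = 0
    for c in range(1, K):
        sel = (G_j == 0) | (G_j == c)
        n = int(sel.sum())
        n_ref = int(np.sum(G_j == 0))
        n_alt = n - n_ref if K == 2 else int(np.sum(G_j == c))
        if n < min_n or min(n_ref, n_alt) < 2:
            return None, 0
        y = (G_j[sel] == c).astype(float)
        try:
            bh, _ = _logistic_irls(
                Z[sel], y, ridge=1e-4 * n, beta0=warm[c - 1] if warm is not None else None,
                maxiter=4,
            )
        except np.linalg.LinAlgError:
            return None, 0
        if not np.all(np.isfinite(bh)):
            return None, 0
        beta_hat[c - 1] = bh
        n_used = n
    return beta_hat, n_used


@dataclass
class McmcResult:
    field: AncestryField                  # posterior-mean gamma and last sampled G
    A_mean: np.ndarray                    # (n_ind, 2, K)
    AX_mean: np.ndarray | None
    lam_mean: np.ndarray                  # (n_ind, 2)
    traces: list[pd.DataFrame]
    params: ModelParameters               # final state of chain 0
    acceptance: dict = dc_field(default_factory=dict)


class _Chain:
    def __init__(self, em: EmissionModel, prior: AncestralPrior, cfg: McmcConfig, rng, x_mask):
        self.em = em
        self.prior = prior
        self.cfg = cfg
        self.rng = rng
        self.x_mask = x_mask
        self.aut = ~x_mask
        H = em.H_hap
        self.n_ind = H // 2
        K = prior.K
        win = prior.windows
        self.d_m = win.d_cm / 100.0     # Morgans; NaN at chromosome firsts
        self.d_cm = win.d_cm
        self.first = win.chrom_first()
        self.marker_window = win.marker_window

        # --- frequentist initialization: window-wise ML classification under
        # the prior PCR with a uniform prior; both copies of an individual
        # start with equal global ancestry.
        beta0 = [wp.H.copy() for wp in prior.window_priors]
        q = em.pcr_posterior(beta0)
        hard = np.argmax(q, axis=2)
        counts = np.stack([(hard == k).mean(axis=1) for k in range(K)], axis=1)  # (H, K)
        A_ind = 0.5 * (counts[0::2] + counts[1::2])
        A = np.repeat(A_ind[:, None, :], 2, axis=1)
        A = np.clip(A, 0.01, None)
        A /= A.sum(axis=-1, keepdims=True)
        self.state = ModelParameters(
            A=A,
            AX=(A_ind / A_ind.sum(1, keepdims=True)).copy() if x_mask.any() else None,
            lam=np.full((self.n_ind, 2), cfg.lam_init),
            tau=np.full(K, cfg.tau_init),
            p=prior.P.copy(),
            beta=beta0,
            P=prior.P.copy(),
            B=[wp.H.copy() for wp in prior.window_priors],
            omega=np.full(K, cfg.omega_init),
            omega_x=cfg.omega_x_init,
            m_gamma=cfg.m_gamma_init,
            v_gamma=cfg.v_gamma_init,
        )
        self.Sigma = [wp.Sigma_diag for wp in prior.window_priors]
        self.Hprior = [wp.H for wp in prior.window_priors]
        self.min_n = [
            (wp.H.shape[1] + 5) if wp.use_pcr else np.inf for wp in prior.window_priors
        ]
        self.trace_rows = []
        self.gamma = None
        self.G = None
        self.acc = {k: [] for k in ("A", "AX", "lam", "p", "beta", "P", "B", "tau", "omega", "alpha")}

    def _lam_h(self):
        return self.state.lam.reshape(-1)

    def _A_h(self):
        return self.state.A.reshape(-1, self.prior.K)

    def sample_field(self):
        s = self.state
        E = self.em.emissions(s.p, s.beta, self._lam_h())
        pr = recomb_prob(np.where(self.first, 0.0, self.d_cm), self._lam_h()[:, None])
        pr[:, self.first] = 1.0
        A_h = self._A_h()
        if self.x_mask.any():
            gamma = np.empty_like(E)
            G = np.empty(E.shape[:2], dtype=np.int64)
            aut_idx = np.nonzero(self.aut)[0]
            x_idx = np.nonzero(self.x_mask)[0]
            gamma[:, aut_idx], gf = forward_backward(
                E[:, aut_idx], pr[:, aut_idx], A_h, return_forward=True
            )
            G[:, aut_idx] = sample_paths(gf, pr[:, aut_idx], A_h, self.rng)
            AX_h = np.repeat(s.AX, 2, axis=0)
            gamma[:, x_idx], gfx = forward_backward(
                E[:, x_idx], pr[:, x_idx], AX_h, return_forward=True
            )
            G[:, x_idx] = sample_paths(gfx, pr[:, x_idx], AX_h, self.rng)
        else:
            gamma, gf = forward_backward(E, pr, A_h, return_forward=True)
            G = sample_paths(gf, pr, A_h, self.rng)
        self.gamma = gamma
        self.G = G

    def step2(self, refit_beta: bool):
        s = self.state
        rng = self.rng
        K = self.prior.K
        H = self.em.H_hap
        # A: gamma sums over autosomal windows per copy
        gsum = self.gamma[:, self.aut, :].sum(axis=1).reshape(self.n_ind, 2, K)
        s.A, a = update_global_ancestry(s.A, gsum, s.omega, rng)
        self.acc["A"].append(a)
        if s.AX is not None:
            gx = self.gamma[:, self.x_mask, :].sum(axis=1)
            gx_ind = gx[0::2] + gx[1::2]
            A_ind = s.A.mean(axis=1)
            s.AX, ax = update_x_ancestry(s.AX, A_ind, gx_ind, s.omega_x, rng)
            self.acc["AX"].append(ax)
        # crossovers + lambda
        xo = sample_crossovers(self._lam_h(), self.d_m, self.G, self._A_h(), rng)
        lam_flat, a = update_lambda(
            self._lam_h(), xo.counts, xo.total_d, s.alpha, rng
        )
        s.lam = lam_flat.reshape(self.n_ind, 2)
        self.acc["lam"].append(a)
        # p
        Gm = self.G[:, self.marker_window]  # (H, M)
        n_var = np.zeros_like(s.p)
        n_ref = np.zeros_like(s.p)
        for k in range(K):
            mask = Gm == k
            n_var[:, k] = (self.em.obs1 * mask).sum(axis=0)
            n_ref[:, k] = (self.em.obs0 * mask).sum(axis=0)
        s.p, a = update_allele_freqs(s.p, s.P, s.tau, n_var, n_ref, rng)
        self.acc["p"].append(a)
        # beta
        if refit_beta:
            accs = 0
            tries = 0
            tau_c = s.tau[1:]
            for j in np.nonzero(self.em.use_pcr)[0]:
                bh, n = _refit_beta_window(
                    self.em, j, self.G[:, j], K, s.beta[j], int(self.min_n[j])
                )
                if bh is None:
                    continue
                s.beta[j], na = update_beta(
                    s.beta[j], s.B[j], self.Sigma[j], tau_c, bh, n, rng
                )
                accs += na
                tries += K - 1
            self.acc["beta"].append(accs / max(tries, 1))
        # P
        s.P, a = update_hyper_P(s.P, self.prior.Omega, s.tau, s.p, rng)
        self.acc["P"].append(a)
        # B
        accs = 0
        tries = 0
        for j in np.nonzero(self.em.use_pcr)[0]:
            s.B[j], na = update_hyper_B(
                s.B[j], self.Hprior[j], self.Sigma[j], s.tau[1:], s.beta[j], rng
            )
            accs += na
            tries += K - 1
        self.acc["B"].append(accs / max(tries, 1))
        # tau
        pcr_idx = np.nonzero(self.em.use_pcr)[0]
        s.tau, a = update_tau(
            s.tau,
            s.p,
            s.P,
            [s.beta[j] for j in pcr_idx],
            [s.B[j] for j in pcr_idx],
            [self.Sigma[j] for j in pcr_idx],
            rng,
        )
        self.acc["tau"].append(a)
        # omega, omega_X
        s.omega, _ = update_omega(s.omega, self._A_h(), rng)
        if s.AX is not None:
            s.omega_x, _ = update_omega_x(s.omega_x, s.A.mean(axis=1), s.AX, rng)
        # alpha
        s.m_gamma, s.v_gamma, na = update_alpha(s.m_gamma, s.v_gamma, self._lam_h(), rng)
        self.acc["alpha"].append(na / 2)
        s.validate()

    def trace_row(self, it):
        s = self.state
        row = {"iteration": it, "lam_mean": float(s.lam.mean()), "omega_x": s.omega_x,
               "m_gamma": s.m_gamma, "v_gamma": s.v_gamma}
        for k in range(self.prior.K):
            row[f"A_mean_{k}"] = float(s.A[..., k].mean())
            row[f"tau_{k}"] = float(s.tau[k])
            row[f"omega_{k}"] = float(s.omega[k])
        self.trace_rows.append(row)


def run_mcmc(haplotypes, prior: AncestralPrior, config: McmcConfig | None = None, rng=None) -> McmcResult:
    """Run the full two-step sampler.

    ``haplotypes``: (H, M) int matrix, alleles in {0, 1}, missing < 0;
    rows 2i, 2i+1 are the two copies of individual i.  Windows on a
    chromosome labelled 'X' use the X-ancestry prior.  Reproducible for
    a fixed rng and a single chain.
    """
    cfg = config or McmcConfig()
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(haplotypes)
    if X.shape[0] % 2:
        raise ValueError("haplotype count must be even (two copies per individual)")
    em = EmissionModel(X, prior)
    chroms = prior.windows.table["chromosome"].to_numpy()
    x_mask = chroms == "X"
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_chains)
    chains = [
        _Chain(em, prior, cfg, np.random.default_rng(int(s)), x_mask) for s in seeds
    ]

    n_total = cfg.n_burn + cfg.n_keep
    keep_gamma = None
    keep_A = None
    keep_AX = None
    keep_lam = None
    n_kept = 0
    for it in range(n_total):
        for ch in chains:
            ch.sample_field()
            refit = (it % cfg.beta_refit_every) == 0
            ch.step2(refit)
            ch.trace_row(it)
        if cfg.n_chains > 1 and it < cfg.n_burn:
            remote = _mean_params([ch.state for ch in chains])
            for ch in chains:
                ch.state = combine_chains(ch.state, remote, it + 1, cfg.n_burn)
        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            ch0 = chains[0]
            if keep_gamma is None:
                keep_gamma = np.zeros_like(ch0.gamma)
                keep_A = np.zeros_like(ch0.state.A)
                keep_lam = np.zeros_like(ch0.state.lam)
                keep_AX = None if ch0.state.AX is None else np.zeros_like(ch0.state.AX)
            keep_gamma += ch0.gamma
            keep_A += ch0.state.A
            keep_lam += ch0.state.lam
            if keep_AX is not None:
                keep_AX += ch0.state.AX
            n_kept += 1
        if not np.all(np.isfinite(chains[0].state.lam)):  # pragma: no cover
            raise FloatingPointError(f"non-finite lambda at iteration {it}")

    ch0 = chains[0]
    if n_kept == 0:
        if ch0.gamma is None:
            ch0.sample_field()
        gamma_mean, A_mean, lam_mean = ch0.gamma, ch0.state.A, ch0.state.lam
        AX_mean = ch0.state.AX
    else:
        gamma_mean = keep_gamma / n_kept
        A_mean = keep_A / n_kept
        lam_mean = keep_lam / n_kept
        AX_mean = None if keep_AX is None else keep_AX / n_kept
    traces = [pd.DataFrame(ch.trace_rows) for ch in chains]
    acceptance = {
        k: float(np.mean(v)) for k, v in ch0.acc.items() if len(v)
    }
    return McmcResult(
        field=AncestryField(gamma=gamma_mean, G=ch0.G),
        A_mean=A_mean,
        AX_mean=AX_mean,
        lam_mean=lam_mean,
        traces=traces,
        params=ch0.state,
        acceptance=acceptance,
    )
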