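"""Forward-backward ancestral-state inference along windowed chromosomes.

The hidden state of window j on one haplotype copy is its ancestral
population g in {1..K}.  The chain prior combines the haplotype's
global ancestry A with the previous window's state through the
probability of an admixture-era recombination over the inter-window
distance d (in cM), which depends on the number of generations since
admixture, lambda:

    P(r) = 1 - ((1 + exp(-2 d / 100)) / 2) ** lambda
    P(g = k) = A_k * P(r) + gamma_{j-1,k} * (1 - P(r))

For the first window of a chromosome P(r) = 1, i.e. the prior is the
global ancestry.  Emissions combine the window's member-marker allele
frequencies with the PC-regression ancestry likelihood of the support
haplotype, blended by the probability that at least one crossover has
hit the support span w since admixture, P(X > 0 | w) = 1 - exp(-lambda
w / 100): once a crossover disrupts the support haplotype the PCR is no
longer informative and only the allele frequencies remain.  Forward and
reverse chains are run with per-window renormalization; their product,
renormalized, is the posterior field gamma, from which states G are
sampled per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AncestryField",
    "recomb_prob",
    "crossover_prob",
    "transition_prior",
    "emission_prob",
    "forward_backward",
    "sample_states",
]


@dataclass
class AncestryField:
    """Posterior ancestral-state probabilities and sampled states.

    gamma: (n_hap, n_windows, K), each (hap, window) row on the simplex.
    G: (n_hap, n_windows) int states in 0..K-1 (or -1 if unsampled).
    Haplotype copies of individual i occupy rows 2i and 2i+1.
    """

    gamma: np.ndarray
    G: np.ndarray

    @property
    def n_pops(self) -> int:
        return self.gamma.shape[2]

    def diploid_dosage(self) -> np.ndarray:
        """Expected diploid ancestry dosage per individual: (n_ind, n_windows, K)."""
        g = self.gamma
        return g[0::2] + g[1::2]


def recomb_prob(d, lam):
    """P(recombination) over d cM after lam generations.

    1 - ((1 + exp(-2d/100)) / 2) ** lam; reduces to (1 - exp(-2d/100))/2
    at lam = 1 (single-generation map function).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative genetic distance")
    return 1.0 - ((1.0 + np.exp(-2.0 * d / 100.0)) / 2.0) ** lam


def crossover_prob(w, lam):
    """P(any crossover in a window of w cM since admixture): 1 - exp(-lam w / 100)."""
    w = np.asarray(w, dtype=float)
    return 1.0 - np.exp(-lam * w / 100.0)


def transition_prior(gamma_prev, A, pr):
    """Chain prior for the next window: A * pr + gamma_prev * (1 - pr)."""
    gamma_prev = np.asarray(gamma_prev, float)
    A = np.asarray(A, float)
    return A * pr + gamma_prev * (1.0 - pr)


def emission_prob(hap_window, k, p, lam=None, w=None, H=None, projected=None,
                  temper: float = 1.0):
    """Emission weight of one window's observation under ancestry k.

    Single-marker or degenerate windows: the Bernoulli likelihood of the
    observed allele(s) under the population-k frequencies ``p`` (a
    missing allele, coded negative, contributes 1).  PCR windows blend
    the member-marker frequency evidence with the PCR class posterior:

        f_k = pbar_k * P(X>0|w) + q_k * (1 - P(X>0|w))

    where pbar is the K-normalized member-marker frequency likelihood
    (``p`` then has shape (n_members, K)), q the softmax PCR posterior
    of the support haplotype, and P(X>0|w) the crossover probability
    over the support span w.  Scalar entry point used by the tests; the
    MCMC uses the vectorized :class:`EmissionModel`.
    """
    x = np.atleast_1d(np.asarray(hap_window))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if H is None:
        pk = p if p.ndim == 1 else p[:, k]
        obs = x >= 0
        like = np.prod(np.where(x[obs] == 1, pk[obs], 1.0 - pk[obs]))
        return float(like)
    if p.ndim != 2:
        raise ValueError("PCR emission needs per-population member frequencies")
    from .ancestral_model import pcr_class_probs

    obs = x >= 0
    loglike = np.zeros(p.shape[1])
    for kk in range(p.shape[1]):
        pk = p[obs, kk]
        loglike[kk] = np.sum(np.where(x[obs] == 1, np.log(pk), np.log1p(-pk)))
    pbar = np.exp(loglike - loglike.max())
    pbar /= pbar.sum()
    q = pcr_class_probs(H, np.atleast_2d(projected))[0]
    q = q**temper
    q /= q.sum()
    px = crossover_prob(w, lam)
    f = pbar * px + q * (1.0 - px)
    if f[k] < -1e-12 or f[k] > 1 + 1e-12:
        raise ValueError("emission probability outside [0,1]; corrupted beta/p")
    return float(f[k])


def forward_backward(emissions, pr, A, return_forward: bool = False):
    """Posterior ancestry probabilities for one chromosome.

    emissions: (..., J, K) nonnegative emission weights per window;
    pr: (..., J) recombination probabilities, pr[..., 0] = 1 (first
    window of the chromosome); A: (..., K) global ancestry.  Leading
    axes broadcast over haplotypes.

    The chain's one-step kernel is T_j(k* -> k) = pr_j A_k +
    (1 - pr_j) 1[k = k*] (a recombination resets the state to the
    global-ancestry draw).  The forward pass carries the running
    posterior with per-window renormalization (scaled forward
    algorithm); the reverse pass carries the emission-free backward
    weights of the same kernel from the opposite chromosome end; their
    normalized product is the smoothed field gamma, which matches
    exhaustive path enumeration.  The kernel is reversible with respect
    to A, so the reverse chain has the identical functional form.
    """
    E = np.asarray(emissions, dtype=float)
    pr = np.asarray(pr, dtype=float)
    A = np.asarray(A, dtype=float)
    J, K = E.shape[-2], E.shape[-1]
    lead = E.shape[:-2]
    A = np.broadcast_to(A, lead + (K,))
    pr = np.broadcast_to(pr, lead + (J,))

    # forward: gamma^f_j = || E_j * (A pr_j + gamma^f_{j-1} (1 - pr_j)) ||
    gf = np.empty(lead + (J, K))
    prev = None
    for j in range(J):
        p_r = pr[..., j, None]
        prior = A if j == 0 else A * p_r + prev * (1.0 - p_r)
        num = E[..., j, :] * prior
        tot = num.sum(axis=-1, keepdims=True)
        if np.any(tot <= 0):
            bad = int(np.argwhere(tot.reshape(-1, 1) <= 0)[0][0])
            raise FloatingPointError(
                f"all-zero posterior at window {j} (flat index {bad})"
            )
        prev = num / tot
        gf[..., j, :] = prev

    # backward: b_j(k*) = sum_k T_{j+1}(k* -> k) E_{j+1}(k) b_{j+1}(k)
    b = np.empty(lead + (J, K))
    b[..., J - 1, :] = 1.0 / K
    for j in range(J - 2, -1, -1):
        p_r = pr[..., j + 1, None]
        eb = E[..., j + 1, :] * b[..., j + 1, :]
        mix = np.sum(A * eb, axis=-1, keepdims=True)
        num = p_r * mix + (1.0 - p_r) * eb
        tot = num.sum(axis=-1, keepdims=True)
        if np.any(tot <= 0):
            raise FloatingPointError(f"all-zero posterior at window {j}")
        b[..., j, :] = num / tot

    prod = gf * b
    gamma = prod / prod.sum(axis=-1, keepdims=True)
    if return_forward:
        return gamma, gf
    return gamma


def sample_paths(forward, pr, A, rng) -> np.ndarray:
    """Joint posterior sample of the ancestral path (backward sampling).

    ``forward``: (..., J, K) per-window forward posteriors from
    :func:`forward_backward`; the path is drawn backwards through the
    chain kernel T_j(k* -> k) = pr_j A_k + (1 - pr_j) 1[k = k*].
    Adjacent sampled states then carry the chain's switch statistics,
    which is what the crossover-count augmentation of the MCMC
    conditions on; a chromosome boundary (pr = 1) decouples the sample
    automatically.
    """
    gf = np.asarray(forward, float)
    lead, J, K = gf.shape[:-2], gf.shape[-2], gf.shape[-1]
    pr = np.broadcast_to(np.asarray(pr, float), lead + (J,))
    A = np.broadcast_to(np.asarray(A, float), lead + (K,))
    G = np.empty(lead + (J,), dtype=np.int64)

    def draw(w):
        w = w / w.sum(axis=-1, keepdims=True)
        cdf = np.cumsum(w, axis=-1)
        u = rng.random(w.shape[:-1] + (1,))
        return (u > cdf[..., :-1]).sum(axis=-1).astype(np.int64)

    G[..., J - 1] = draw(gf[..., J - 1, :])
    for j in range(J - 2, -1, -1):
        p_r = pr[..., j + 1, None]
        nxt = G[..., j + 1]
        A_next = np.take_along_axis(A, nxt[..., None], axis=-1)
        w = gf[..., j, :] * (p_r * A_next)
        stay = np.take_along_axis(gf[..., j, :], nxt[..., None], axis=-1) * (1.0 - p_r)
        np.put_along_axis(w, nxt[..., None],
                          np.take_along_axis(w, nxt[..., None], axis=-1) + stay, axis=-1)
        G[..., j] = draw(w)
    return G


def sample_states(gamma, rng) -> np.ndarray:
    """Independent categorical draw per (haplotype, window) from gamma."""
    g = np.asarray(gamma, dtype=float)
    cdf = np.cumsum(g, axis=-1)
    u = rng.random(g.shape[:-1] + (1,))
    return (u > cdf[..., :-1]).sum(axis=-1).astype(np.int64) if g.shape[-1] > 1 else np.zeros(
        g.shape[:-1], dtype=np.int64
    )


class EmissionModel:
    """Vectorized emission computation for a full dataset.

    Precomputes, once, the PC projection of every admixed haplotype in
    every window and the window/support bookkeeping; per MCMC iteration
    only the parts touched by updated parameters (p, beta, lambda) are
    recomputed.
    """

    def __init__(self, haplotypes, prior):
        from .ancestral_model import AncestralPrior  # noqa: F401  (type only)

        self.X = np.asarray(haplotypes)
        self.prior = prior
        win = prior.windows
        self.J = win.n_windows
        self.K = prior.K
        self.H_hap = self.X.shape[0]
        tab = win.table
        self.starts = tab["start"].to_numpy(int)
        self.stops = tab["stop"].to_numpy(int)
        self.use_pcr = np.array([wp.use_pcr for wp in prior.window_priors])
        self.support_w = np.array(
            [wp.support_span_cm for wp in prior.window_priors], dtype=float
        )
        # Adjacent windows share almost all of their PCR support, so the
        # chain would otherwise count each support marker's evidence
        # ~(support/window) times; the posterior odds are tempered by
        # window/support so the evidence is counted once along the chain.
        self.temper = np.where(
            self.support_w > 0,
            np.minimum(win.window_cm / np.maximum(self.support_w, 1e-9), 1.0),
            1.0,
        )
        self.proj = []
        from .ancestral_model import project_pcs

        for wp in prior.window_priors:
            sup = self.X[:, wp.support_start : wp.support_stop].astype(float)
            # missing support alleles imputed at the fit-time mean (centered zero)
            ref = wp.loadings[0]
            miss = sup < 0
            if miss.any():
                sup = np.where(miss, np.broadcast_to(ref.mean, sup.shape), sup)
            self.proj.append(project_pcs(sup, ref))
        self.obs1 = (self.X == 1).astype(float)
        self.obs0 = (self.X == 0).astype(float)

    def member_loglik(self, p) -> np.ndarray:
        """(H, J, K) member-marker Bernoulli log-likelihood sums."""
        lp1 = np.log(p)       # (M, K)
        lp0 = np.log1p(-p)
        S = self.obs1[:, :, None] * lp1[None] + self.obs0[:, :, None] * lp0[None]
        return np.add.reduceat(S, self.starts, axis=1)

    def pcr_posterior(self, beta) -> np.ndarray:
        """(H, J, K) PCR class posteriors from current coefficients."""
        from .ancestral_model import pcr_class_probs

        q = np.full((self.H_hap, self.J, self.K), 1.0 / self.K)
        for j in np.nonzero(self.use_pcr)[0]:
            q[:, j, :] = pcr_class_probs(beta[j], self.proj[j])
        return q

    def emissions(self, p, beta, lam_h) -> np.ndarray:
        """(H, J, K) emission weights for per-haplotype lambdas ``lam_h``."""
        mem = self.member_loglik(p)
        mx = mem.max(axis=2, keepdims=True)
        like = np.exp(mem - mx)           # scaled member likelihood; scale cancels
        E = np.empty_like(like)
        pcr = self.use_pcr
        # non-PCR windows: raw member likelihood
        E[:, ~pcr, :] = like[:, ~pcr, :]
        if pcr.any():
            q = self.pcr_posterior(beta)[:, pcr, :]
            qt = q ** self.temper[pcr][None, :, None]
            qt /= qt.sum(axis=2, keepdims=True)
            pbar = like[:, pcr, :] / like[:, pcr, :].sum(axis=2, keepdims=True)
            px = crossover_prob(self.support_w[pcr][None, :], lam_h[:, None])
            E[:, pcr, :] = pbar * px[:, :, None] + qt * (1 - px[:, :, None])
        return E
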