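"""Synthetic ancestral panels, admixed chromosomes and phenotypes.

The panel generator stands in for real reference panels (e.g. HapMap
YRI/CEU): per-marker ancestral frequencies are drawn once and each
population's frequencies follow a Balding-Nichols Beta spread around
them with a configurable divergence (an F_ST parameter).  Within-
population LD is produced by a haplotype-copying process: a pool of
founder haplotypes carrying autocorrelated alleles (a Gaussian AR(1)
copula along the cM map) is sampled, and every panel haplotype is a
Li-Stephens-style mosaic of founders whose switch rate is 1/ld_decay_cm
per cM, so allele correlation decays with genetic distance.

Admixed chromosomes are then built in two steps: admixture-era
recombination breakpoints are placed as a Poisson process of rate
lambda per Morgan (lambda drawn per chromosome from a Gamma with mean 6
and sd 2), and each inter-breakpoint segment is copied from a uniformly
chosen haplotype of a source panel selected with probability equal to
the chromosome's global ancestry (Beta with mean 0.82, sd 0.1).  Truth
labels and breakpoints are recorded, emulating a typical African-
American admixture history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome_windows import GeneticMap, WindowSet

__all__ = [
    "SyntheticPanelSpec",
    "AdmixedChromosome",
    "uniform_map",
    "simulate_panels",
    "simulate_admixed",
    "perturb_priors",
    "simulate_phenotypes",
    "truth_window_labels",
    "window_accuracy",
]


def _beta_ab(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of a Beta with the given mean and sd."""
    v = sd**2
    t = mean * (1 - mean) / v - 1.0
    if t <= 0:
        raise ValueError("sd too large for a Beta with this mean")
    return mean * t, (1 - mean) * t


def _gamma_ab(mean: float, sd: float) -> tuple[float, float]:
    """(shape, rate) of a Gamma with the given mean and sd."""
    return (mean / sd) ** 2, mean / sd**2


@dataclass
class SyntheticPanelSpec:
    """Conditions for the synthetic ancestral panels."""

    K: int = 2
    n_hap: int = 100                 # haplotypes per population
    n_markers: int = 2000
    divergence: float = 0.15         # Balding-Nichols F_ST parameter
    ld_decay_cm: float = 0.2         # within-population allele-correlation length
    length_cm: float = 100.0
    chromosome: str = "1"
    n_founders: int = 100
    seed: int = 0
    marker_cm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0 < self.divergence < 1:
            raise ValueError("divergence must be in (0,1)")
        if min(self.K, self.n_hap, self.n_markers) <= 0:
            raise ValueError("counts must be positive")

    def positions_cm(self) -> np.ndarray:
        if self.marker_cm is not None:
            return np.asarray(self.marker_cm, float)
        return np.linspace(0.0, self.length_cm, self.n_markers)

    def genetic_map(self) -> GeneticMap:
        cm = self.positions_cm()
        bp = np.round(1 + cm * 1e6).astype(np.int64)  # 1 cM ~ 1 Mb
        return GeneticMap(
            pd.DataFrame(
                {
                    "id": [f"rs{i}" for i in range(cm.size)],
                    "chromosome": self.chromosome,
                    "position_bp": bp,
                    "position_cm": cm,
                }
            )
        )


def _copula_haplotypes(n, thresholds, rho, rng):
    """n haplotypes of autocorrelated Bernoulli alleles.

    thresholds: (M,) Gaussian thresholds Phi^-1(p_m); rho: (M,) AR(1)
    lag correlations (rho[0] unused).
    """
    M = thresholds.size
    z = np.empty((n, M))
    z[:, 0] = rng.standard_normal(n)
    noise = rng.standard_normal((n, M))
    for m in range(1, M):
        z[:, m] = rho[m] * z[:, m - 1] + np.sqrt(1 - rho[m] ** 2) * noise[:, m]
    return (z < thresholds[None, :]).astype(np.int8)


def simulate_panels(spec: SyntheticPanelSpec):
    """Generate K ancestral haplotype panels.

    Returns (panels, ancestral_freqs, pop_freqs): a list of K (n_hap,
    n_markers) int8 matrices, the shared ancestral frequencies and the
    per-population Balding-Nichols frequencies actually used.
    Deterministic for a fixed spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    cm = spec.positions_cm()
    M = cm.size
    anc = rng.uniform(0.05, 0.95, size=M)
    F = spec.divergence
    a = anc * (1 - F) / F
    b = (1 - anc) * (1 - F) / F
    pop_freqs = np.clip(rng.beta(a, b, size=(spec.K, M)), 0.01, 0.99)

    dcm = np.diff(cm, prepend=cm[0])
    rho = np.exp(-np.maximum(dcm, 0.0) / max(spec.ld_decay_cm, 1e-9))
    rho[0] = 0.0
    switch = 1.0 - np.exp(-np.maximum(dcm, 0.0) / max(spec.ld_decay_cm, 1e-9))
    panels = []
    for k in range(spec.K):
        thr = norm.ppf(pop_freqs[k])
        founders = _copula_haplotypes(spec.n_founders, thr, rho, rng)
        # Li-Stephens mosaic of the founder pool
        fidx = np.empty((spec.n_hap, M), dtype=np.int64)
        fidx[:, 0] = rng.integers(0, spec.n_founders, size=spec.n_hap)
        jumps = rng.random((spec.n_hap, M)) < switch[None, :]
        new = rng.integers(0, spec.n_founders, size=(spec.n_hap, M))
        for m in range(1, M):
            fidx[:, m] = np.where(jumps[:, m], new[:, m], fidx[:, m - 1])
        panels.append(founders[fidx, np.arange(M)[None, :]])
    return panels, anc, pop_freqs


@dataclass
class AdmixedChromosome:
    """One simulated haploid chromosome with full ancestry truth."""

    alleles: np.ndarray          # (M,) int8
    truth_ancestry: np.ndarray   # (M,) population label per marker
    breakpoints: np.ndarray      # cM positions of admixture-era crossovers
    G_true: np.ndarray           # (K,) assigned global ancestry
    lam_true: float              # generations since admixture
    source_hap: np.ndarray       # (M,) panel haplotype index each allele came from


def simulate_admixed(
    panels,
    marker_cm,
    n_chrom: int = 400,
    lam_mean: float = 6.0,
    lam_sd: float = 2.0,
    g_mean: float = 0.82,
    g_sd: float = 0.1,
    seed: int = 0,
):
    """Simulate admixed chromosomes from the panels.

    Per chromosome: draw lambda ~ Gamma(mean lam_mean, sd lam_sd) and a
    global ancestry vector G ~ Beta(mean g_mean, sd g_sd) (population 1
    weight; the complement is split evenly for K > 2); place
    breakpoints as a Poisson process of rate lambda per Morgan; fill
    each segment from a uniformly chosen haplotype of a panel drawn
    with probability G.  Returns a list of AdmixedChromosome.
    """
    rng = np.random.default_rng(seed)
    cm = np.asarray(marker_cm, float)
    L_morgan = (cm[-1] - cm[0]) / 100.0
    K = len(panels)
    ga, gb = _beta_ab(g_mean, g_sd)
    la, lb = _gamma_ab(lam_mean, lam_sd)
    out = []
    for _ in range(n_chrom):
        lam = rng.gamma(la, 1.0 / lb)
        g1 = rng.beta(ga, gb)
        G = np.empty(K)
        G[0] = g1
        G[1:] = (1.0 - g1) / max(K - 1, 1)
        n_bp = rng.poisson(lam * L_morgan)
        bps = np.sort(rng.uniform(cm[0], cm[-1], size=n_bp))
        edges = np.concatenate([[cm[0] - 1e-9], bps, [cm[-1] + 1e-9]])
        seg_pop = rng.choice(K, size=len(edges) - 1, p=G)
        seg_hap = np.array([rng.integers(0, panels[k].shape[0]) for k in seg_pop])
        seg_of_marker = np.searchsorted(edges, cm, side="right") - 1
        truth = seg_pop[seg_of_marker].astype(np.int8)
        hap_idx = seg_hap[seg_of_marker]
        alleles = np.empty(cm.size, dtype=np.int8)
        for s, (k, h) in enumerate(zip(seg_pop, seg_hap)):
            sel = seg_of_marker == s
            alleles[sel] = panels[k][h, sel]
        out.append(
            AdmixedChromosome(
                alleles=alleles,
                truth_ancestry=truth,
                breakpoints=bps,
                G_true=G,
                lam_true=float(lam),
                source_hap=hap_idx,
            )
        )
    return out


def perturb_priors(H, Sigma_diag, scale: float, seed: int = 0):
    """Degrade PCR coefficient priors to mimic imperfect surrogate panels.

    Adds N(0, scale * SE) noise elementwise, SE = sqrt(Sigma_diag).
    ``H``/``Sigma_diag`` may be single arrays or per-window lists.
    """
    rng = np.random.default_rng(seed)
    if isinstance(H, (list, tuple)):
        return [
            h + scale * np.sqrt(s) * rng.standard_normal(h.shape)
            for h, s in zip(H, Sigma_diag)
        ]
    H = np.asarray(H, float)
    S = np.asarray(Sigma_diag, float)
    if H.shape != S.shape:
        raise ValueError("H and Sigma_diag shapes differ")
    return H + scale * np.sqrt(S) * rng.standard_normal(H.shape)


def truth_window_labels(chroms: list[AdmixedChromosome], windows: WindowSet) -> np.ndarray:
    """Majority truth ancestry per (chromosome, window): (n_chrom, n_windows)."""
    mw = windows.marker_window
    J = windows.n_windows
    out = np.empty((len(chroms), J), dtype=np.int8)
    K = int(max(c.truth_ancestry.max() for c in chroms)) + 1
    for i, c in enumerate(chroms):
        votes = np.zeros((J, K))
        np.add.at(votes, (mw, c.truth_ancestry), 1.0)
        out[i] = votes.argmax(axis=1)
    return out


def window_accuracy(gamma, truth_labels) -> float:
    """Fraction of (haplotype, window) calls matching the truth labels."""
    calls = np.argmax(gamma, axis=2)
    return float((calls == truth_labels).mean())


def simulate_phenotypes(
    dosage,
    risk_window: int,
    effect_size: float,
    model: str = "case_control",
    seed: int = 0,
    baseline: float = 0.0,
):
    """Phenotypes driven by local-ancestry dosage at one risk window.

    ``dosage``: (n_ind, n_windows) diploid dosage of the risk ancestry
    (0..2).  Liability at the risk window rises by ``effect_size`` per
    dose on the link scale.  model = 'quantitative' draws
    y = baseline + effect * dose + N(0,1); 'case_control' draws
    Bernoulli(logit^-1(baseline + effect * dose)); 'case_only' keeps
    only the cases of the case_control draw.  effect_size = 0 is the
    null.  Returns a DataFrame (individual, phenotype).
    """
    rng = np.random.default_rng(seed)
    dosage = np.asarray(dosage, float)
    if not 0 <= risk_window < dosage.shape[1]:
        raise ValueError("risk window outside the simulated region")
    dose = dosage[:, risk_window]
    eta = baseline + effect_size * dose
    if model == "quantitative":
        y = eta + rng.standard_normal(dose.size)
    elif model in ("case_control", "case_only"):
        y = (rng.random(dose.size) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    else:
        raise ValueError(f"unknown phenotype model: {model}")
    tab = pd.DataFrame({"individual": np.arange(dose.size), "phenotype": y})
    if model == "case_only":
        tab = tab[tab["phenotype"] == 1].reset_index(drop=True)
    return tab
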