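"""Marker, individual and MCMC-parameter quality control.

Marker checks: an exact Hardy-Weinberg test, missingness screening
(default 5%), strand-ambiguous (A-T / G-C) flip detection and
irregular-frequency screening against the surrogate panels.  Individual
checks: missingness, X-heterozygosity sex check and allele-sharing
relatedness screening.  Parameter checks: burn-in/follow-on drift tests
on MCMC traces and the tau rule -- a posterior tau below 100 (warning)
or 50 (strong warning) indicates poorly chosen surrogate panels or
allele flips.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "hwe_exact",
    "hwe_exact_all",
    "marker_qc",
    "individual_qc",
    "trace_diagnostics",
]

AMBIGUOUS_PAIRS = ({"A", "T"}, {"G", "C"})


def hwe_exact_all(n: int, n_a: int):
    """Exact HWE p-values for every heterozygote count at fixed allele counts.

    For n diploids carrying n_a copies of allele A (0 <= n_a <= 2n),
    heterozygote counts share the parity of n_a; under the exact
    conditional HWE distribution

        P(het = h) = n! 2^h / (n_AA! h! n_aa!)  /  [ C(2n, n_a) scale ]

    Returns (het_values, pvalues) where pvalues[i] is the sum of the
    probabilities of all configurations no more probable than het h_i.
    """
    if n <= 0:
        raise ValueError("zero individuals")
    n_b = 2 * n - n_a
    h_min = n_a % 2
    h_max = min(n_a, n_b)
    hs = np.arange(h_min, h_max + 1, 2)
    if hs.size == 0:  # monomorphic
        return np.array([0]), np.array([1.0])
    naa = (n_a - hs) // 2
    nbb = (n_b - hs) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(naa + 1)
        - gammaln(hs + 1)
        - gammaln(nbb + 1)
        + hs * np.log(2.0)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    pvals = np.array([prob[prob <= prob[i] * (1 + 1e-12)].sum() for i in range(hs.size)])
    return hs, np.minimum(pvals, 1.0)


def hwe_exact(genotype_counts) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    ``genotype_counts`` = (hom_ref, het, hom_alt).  The p-value is the
    total probability of all heterozygote counts (same parity, fixed
    allele counts) no more probable than the observed one.  A
    monomorphic marker returns 1.
    """
    hom_ref, het, hom_alt = (int(c) for c in genotype_counts)
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("negative genotype counts")
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("zero individuals")
    n_a = 2 * hom_ref + het
    hs, pvals = hwe_exact_all(n, n_a)
    idx = np.searchsorted(hs, het)
    if idx >= hs.size or hs[idx] != het:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(pvals[idx])


def hwe_enumeration_oracle(n: int, n_a: int):
    """Independent exact-integer enumeration of the HWE distribution.

    Uses exact binomial coefficients (no log-gamma); test oracle only.
    """
    n_b = 2 * n - n_a
    hs = list(range(n_a % 2, min(n_a, n_b) + 1, 2))
    if not hs:
        return np.array([0]), np.array([1.0])
    weights = [
        comb(n, (n_a - h) // 2) * comb(n - (n_a - h) // 2, h) * 2**h for h in hs
    ]
    total = sum(weights)
    probs = np.array([w / total for w in weights])
    pvals = np.array([probs[probs <= probs[i] * (1 + 1e-12)].sum() for i in range(len(hs))])
    return np.array(hs), np.minimum(pvals, 1.0)


def _report(rows) -> pd.DataFrame:
    cols = ["scope", "id", "check", "observed", "threshold", "action"]
    return pd.DataFrame(rows, columns=cols)


def marker_qc(
    haplotypes,
    panel_freqs,
    marker_ids=None,
    alleles=None,
    miss_threshold: float = 0.05,
    freq_margin: float = 0.1,
    hwe_alpha: float | None = None,
    genotype_counts=None,
) -> pd.DataFrame:
    """Per-marker QC report.

    ``haplotypes``: (H, M) admixed alleles with missing < 0;
    ``panel_freqs``: (M, K) surrogate frequencies; ``alleles``: optional
    (M, 2) ref/alt letters for strand-flip checks.  Flags markers over
    the missingness threshold; drops strand-ambiguous (A-T / G-C)
    markers whose admixed frequency is not consistent with any
    surrogate (a near-0.5 frequency is never resolvable); flags markers
    whose admixed frequency falls outside the convex hull of the
    surrogate frequencies by more than ``freq_margin``.  When diploid
    ``genotype_counts`` (M, 3) are given and ``hwe_alpha`` is set, an
    exact HWE test is run per marker.
    """
    X = np.asarray(haplotypes)
    pf = np.asarray(panel_freqs, float)
    M = X.shape[1]
    ids = np.arange(M) if marker_ids is None else np.asarray(marker_ids)
    rows = []
    obs = X >= 0
    miss = 1.0 - obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(obs.sum(0) > 0, (X == 1).sum(0) / np.maximum(obs.sum(0), 1), np.nan)
    lo = pf.min(axis=1) - freq_margin
    hi = pf.max(axis=1) + freq_margin
    for m in range(M):
        if miss[m] > miss_threshold + 1e-12:
            rows.append(("marker", ids[m], "missingness", miss[m], miss_threshold, "flag"))
        ambiguous = alleles is not None and {str(alleles[m][0]).upper(), str(alleles[m][1]).upper()} in AMBIGUOUS_PAIRS
        if ambiguous:
            unresolvable = abs(freq[m] - 0.5) < 0.1 if np.isfinite(freq[m]) else True
            inconsistent = np.isfinite(freq[m]) and not (lo[m] <= freq[m] <= hi[m])
            if unresolvable or inconsistent:
                rows.append(("marker", ids[m], "strand_flip", freq[m], 0.5, "drop"))
            else:
                rows.append(("marker", ids[m], "strand_ambiguous", freq[m], 0.5, "flag"))
        if np.isfinite(freq[m]) and not (lo[m] <= freq[m] <= hi[m]):
            rows.append(("marker", ids[m], "irregular_frequency", freq[m], freq_margin, "flag"))
        if genotype_counts is not None and hwe_alpha is not None:
            p = hwe_exact(genotype_counts[m])
            if p < hwe_alpha:
                rows.append(("marker", ids[m], "hwe", p, hwe_alpha, "flag"))
    return _report(rows)


def individual_qc(
    haplotypes,
    sample_ids=None,
    miss_threshold: float = 0.05,
    relatedness_threshold: float = 0.9,
    reported_sex=None,
    x_marker_mask=None,
    male_het_threshold: float = 0.02,
) -> pd.DataFrame:
    """Per-individual QC report.

    ``haplotypes``: (2N, M); rows 2i, 2i+1 belong to individual i.
    Flags individuals over the missingness threshold; when X markers
    and reported sexes ('M'/'F') are given, calls male if X
    heterozygosity < ``male_het_threshold`` and flags mismatches; flags
    pairs whose genotype identity fraction exceeds the relatedness
    threshold (duplicates / first-degree relatives).
    """
    X = np.asarray(haplotypes)
    N = X.shape[0] // 2
    ids = np.arange(N) if sample_ids is None else np.asarray(sample_ids)
    rows = []
    obs = X >= 0
    ind_miss = 1.0 - 0.5 * (obs[0::2].mean(axis=1) + obs[1::2].mean(axis=1))
    for i in range(N):
        if ind_miss[i] > miss_threshold + 1e-12:
            rows.append(("individual", ids[i], "missingness", ind_miss[i], miss_threshold, "flag"))
    if reported_sex is not None and x_marker_mask is not None and np.any(x_marker_mask):
        Xx = X[:, np.asarray(x_marker_mask, bool)]
        both = (Xx[0::2] >= 0) & (Xx[1::2] >= 0)
        het = np.where(
            both.sum(1) > 0,
            ((Xx[0::2] != Xx[1::2]) & both).sum(1) / np.maximum(both.sum(1), 1),
            np.nan,
        )
        for i in range(N):
            called = "M" if het[i] < male_het_threshold else "F"
            if np.isfinite(het[i]) and str(reported_sex[i]).upper()[:1] != called:
                rows.append(("individual", ids[i], "sex_check", het[i], male_het_threshold, "flag"))
    # relatedness: proportion of identical diploid genotypes
    gt = np.where((X[0::2] >= 0) & (X[1::2] >= 0), X[0::2] + X[1::2], -9)
    for i in range(N):
        for j in range(i + 1, N):
            both = (gt[i] >= 0) & (gt[j] >= 0)
            if both.sum() == 0:
                continue
            share = float((gt[i][both] == gt[j][both]).mean())
            if share > relatedness_threshold:
                rows.append(
                    ("individual", f"{ids[i]}|{ids[j]}", "relatedness", share,
                     relatedness_threshold, "flag")
                )
    return _report(rows)


def trace_diagnostics(
    traces,
    n_burn: int,
    drift_alpha: float = 0.01,
    tau_warn: float = 100.0,
    tau_strong: float = 50.0,
    out_dir=None,
) -> pd.DataFrame:
    """Convergence diagnostics on MCMC traces.

    For every parameter column: a linear-trend test over the follow-on
    phase (a significant slope means the burn-in was too short), the
    across-chain spread of follow-on means, and the tau
    surrogate-quality rule (posterior mean below ``tau_warn`` warns,
    below ``tau_strong`` warns strongly).  Trace plots are written to
    ``out_dir`` when given.
    """
    import statsmodels.api as sm

    if isinstance(traces, pd.DataFrame):
        traces = [traces]
    if not traces:
        raise ValueError("no traces given")
    cols = [c for c in traces[0].columns if c != "iteration"]
    rows = []
    for col in cols:
        follow_means = []
        drift = False
        slope_p = np.nan
        for tr in traces:
            follow = tr[tr["iteration"] >= n_burn]
            y = follow[col].to_numpy(float)
            follow_means.append(np.nanmean(y) if len(y) else np.nan)
            if len(y) >= 10 and np.nanstd(y) > 0:
                t = np.arange(len(y), dtype=float)
                res = sm.OLS(y, np.column_stack([np.ones_like(t), t])).fit()
                slope_p = float(res.pvalues[1])
                if slope_p < drift_alpha:
                    drift = True
        mean = float(np.nanmean(follow_means))
        status = "ok"
        if drift:
            status = "drift"
        if col.startswith("tau"):
            if mean < tau_strong:
                status = "tau_strong_warning"
            elif mean < tau_warn:
                status = "tau_warning"
        rows.append(
            dict(parameter=col, follow_on_mean=mean,
                 across_chain_sd=float(np.nanstd(follow_means)),
                 drift_p=slope_p, status=status)
        )
    report = pd.DataFrame(rows)
    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for col in cols:
            fig, ax = plt.subplots(figsize=(6, 3))
            for c, tr in enumerate(traces):
                ax.plot(tr["iteration"], tr[col], lw=0.8, label=f"chain {c}")
            ax.axvline(n_burn, color="k", ls="--", lw=0.8)
            ax.set_xlabel("iteration")
            ax.set_ylabel(col)
            if len(traces) > 1:
                ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(out / f"trace_{col}.png", dpi=100)
            plt.close(fig)
    return report
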