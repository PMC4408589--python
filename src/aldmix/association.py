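"""Admixture-mapping (MALD) association statistics.

Three generalized linear models over local-ancestry dosage:

* case-only: global ancestry regressed on local ancestry (identity
  link) among cases -- an excess of risk-population ancestry at a locus
  relative to the genome-wide proportion signals a disease locus;
* case-control / quantitative: link(Y) ~ local + global + covariates,
  Wald test on the local-ancestry coefficient;
* fine mapping: link(Y) ~ genotype + local + global + covariates,
  Wald test on the genotype coefficient, for localizing the signal to
  specific variants once a region is implicated.

Local ancestry enters as the expected diploid dosage (sum of the two
haplotype posteriors), which propagates inference uncertainty into the
association model; a sampled-state mode is available by passing hard
dosages.  Bonferroni-adjusted p-values and Benjamini-Hochberg q-values
are appended to every scan.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .hmm_engine import AncestryField

__all__ = ["case_only_scan", "mald_scan", "fine_map"]

_COND_LIMIT = 1e8


def _local_dosage(local, pop: int) -> np.ndarray:
    """(n_ind, n_windows) diploid dosage of ancestry ``pop``."""
    if isinstance(local, AncestryField):
        return local.diploid_dosage()[:, :, pop]
    return np.asarray(local, float)


def _design(*cols):
    X = np.column_stack([np.ones(len(cols[0]))] + [np.asarray(c, float) for c in cols])
    return X


def _fit_one(y, X, link: str):
    """Fit one GLM; return (est, se, z, p, flag) for the first non-intercept column."""
    flag = ""
    if np.linalg.cond(X) > _COND_LIMIT:
        return np.nan, np.nan, np.nan, np.nan, "collinear"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if link == "identity":
                res = sm.OLS(y, X).fit()
            elif link == "logit":
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if not res.mle_retvals.get("converged", True):
                    return np.nan, np.nan, np.nan, np.nan, "nonconverged"
            else:
                raise ValueError(f"unknown link: {link}")
        except Exception:
            return np.nan, np.nan, np.nan, np.nan, "nonconverged"
    est = res.params[1]
    se = res.bse[1]
    if not np.isfinite(se) or se <= 0:
        return est, np.nan, np.nan, np.nan, "nonconverged"
    z = est / se
    p = res.pvalues[1]
    return est, se, z, max(min(p, 1.0), np.finfo(float).tiny), flag


def _finish(rows, model_tag: str) -> pd.DataFrame:
    tab = pd.DataFrame(rows)
    tab["model"] = model_tag
    ok = tab["p"].notna()
    tab["p_bonferroni"] = np.nan
    tab["q_bh"] = np.nan
    if ok.any():
        m = int(ok.sum())
        tab.loc[ok, "p_bonferroni"] = np.minimum(tab.loc[ok, "p"] * m, 1.0)
        tab.loc[ok, "q_bh"] = multipletests(tab.loc[ok, "p"], method="fdr_bh")[1]
    return tab


def case_only_scan(local, global_A, covariates=None, pop: int = 1, conventional: bool = False):
    """Case-only scan: per window, global ~ b0 + b1 * local (+ covariates).

    ``global_A``: per-individual global proportion of ancestry ``pop``
    (0..1); ``local``: AncestryField or (n_ind, n_windows) diploid
    dosage.  The regression direction follows the case-only model as
    stated (global on local); ``conventional=True`` runs the usual
    local-on-global direction instead, clearly tagged in the output.
    Windows with constant dosage are flagged non-testable.
    """
    D = _local_dosage(local, pop)
    g = np.asarray(global_A, float)
    cov = [] if covariates is None else [np.asarray(covariates, float)]
    rows = []
    for j in range(D.shape[1]):
        d = D[:, j]
        if np.ptp(d) < 1e-12:
            rows.append(dict(window=j, estimate=np.nan, se=np.nan, z=np.nan, p=np.nan,
                             n=len(d), flag="nontestable"))
            continue
        if conventional:
            y, x1 = d, g
        else:
            y, x1 = g, d
        est, se, z, p, flag = _fit_one(y, _design(x1, *cov), "identity")
        rows.append(dict(window=j, estimate=est, se=se, z=z, p=p, n=len(d), flag=flag))
    return _finish(rows, "case_only_conventional" if conventional else "case_only")


def mald_scan(phenotype, link, local, global_A, covariates=None, pop: int = 1):
    """Admixture-mapping scan: link(Y) ~ local + global (+ covariates) per window."""
    y = np.asarray(phenotype, float)
    if link == "logit" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logit link requires a binary phenotype")
    D = _local_dosage(local, pop)
    g = np.asarray(global_A, float)
    cov = [] if covariates is None else [np.asarray(covariates, float)]
    rows = []
    for j in range(D.shape[1]):
        d = D[:, j]
        if np.ptp(d) < 1e-12:
            rows.append(dict(window=j, estimate=np.nan, se=np.nan, z=np.nan, p=np.nan,
                             n=len(y), flag="nontestable"))
            continue
        est, se, z, p, flag = _fit_one(y, _design(d, g, *cov), link)
        rows.append(dict(window=j, estimate=est, se=se, z=z, p=p, n=len(y), flag=flag))
    return _finish(rows, f"mald_{link}")


def fine_map(phenotype, genotypes, local, global_A, covariates=None, link="identity",
             windows_of_markers=None, pop: int = 1):
    """Per-marker fine mapping: link(Y) ~ genotype + local + global (+ cov).

    ``genotypes``: (n_ind, n_markers) diploid allele dosages;
    ``windows_of_markers`` maps each marker to its window so the
    matching local dosage is conditioned on (defaults to window 0).
    Markers collinear with local ancestry are flagged with a
    condition-number note.
    """
    y = np.asarray(phenotype, float)
    Gt = np.atleast_2d(np.asarray(genotypes, float))
    if Gt.shape[0] != y.size:
        Gt = Gt.T
    D = _local_dosage(local, pop)
    g = np.asarray(global_A, float)
    cov = [] if covariates is None else [np.asarray(covariates, float)]
    mw = (
        np.zeros(Gt.shape[1], dtype=int)
        if windows_of_markers is None
        else np.asarray(windows_of_markers, dtype=int)
    )
    rows = []
    for m in range(Gt.shape[1]):
        x = Gt[:, m]
        d = D[:, mw[m]]
        est, se, z, p, flag = _fit_one(y, _design(x, d, g, *cov), link)
        rows.append(dict(marker=m, window=int(mw[m]), estimate=est, se=se, z=z, p=p,
                         n=len(y), flag=flag))
    return _finish(rows, f"fine_map_{link}")
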