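"""Window PCA of ancestral haplotype panels and logistic PC regression.

Within-population LD left over from the ancestral populations confounds
naive marker-by-marker ancestry inference on dense data.  Here that LD
is modeled indirectly: for every window, a PCA of the surrounding
markers (default support span 2 cM) is run on each surrogate ancestral
panel, and a logistic (K = 2) or multinomial (K > 2) principal
component regression (PCR) of population membership on the projected
components supplies the ancestry likelihood of a haplotype.  Components
are retained up to 80% of cumulative variance.  The fitted coefficients
``H`` and their variance ``Sigma`` -- together with pseudocounted panel
allele counts ``Omega`` and frequencies ``P`` -- are the prior
hyperparameters of the MCMC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_windows import WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "PCLoadings",
    "WindowPrior",
    "AncestralPrior",
    "fit_window_pca",
    "project_pcs",
    "fit_pcr",
    "compute_priors",
]


@dataclass
class PCLoadings:
    """Column-centered PCA of one population's haplotypes over a support window."""

    mean: np.ndarray            # (p,) fit-time column means
    eigvecs: np.ndarray         # (p, r) retained orthonormal components
    eigvals: np.ndarray         # full spectrum, descending
    support_markers: np.ndarray  # global indices of the support columns
    variance_fraction_retained: float
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.eigvecs.shape[1]


def fit_window_pca(panel, support_markers=None, var_threshold: float = 0.8) -> PCLoadings:
    """PCA of a binary haplotype panel restricted to a support window.

    The panel is column-centered by its own means; the smallest number
    of leading components whose cumulative eigenvalue fraction reaches
    ``var_threshold`` is retained.  Monomorphic markers contribute zero
    loadings.  A panel with no polymorphic marker is flagged degenerate
    (the window then falls back to allele-frequency emissions).
    """
    X = np.asarray(panel, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("panel must be a 2-D matrix with at least 2 haplotypes")
    if support_markers is None:
        support_markers = np.arange(X.shape[1])
    support_markers = np.asarray(support_markers)
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float(np.sum(Xc * Xc))
    if total <= 1e-12:
        return PCLoadings(
            mean=mean,
            eigvecs=np.zeros((X.shape[1], 0)),
            eigvals=np.zeros(0),
            support_markers=support_markers,
            variance_fraction_retained=0.0,
            degenerate=True,
        )
    # SVD of the centered matrix: eigenvalues of the covariance up to 1/(n-1)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    frac = np.cumsum(eigvals) / eigvals.sum()
    r = int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    r = min(r, len(eigvals))
    return PCLoadings(
        mean=mean,
        eigvecs=vt[:r].T.copy(),
        eigvals=eigvals,
        support_markers=support_markers,
        variance_fraction_retained=float(frac[r - 1]),
        degenerate=False,
    )


def project_pcs(haplotypes, loadings: PCLoadings) -> np.ndarray:
    """Project haplotypes onto fitted loadings (with fit-time centering)."""
    X = np.atleast_2d(np.asarray(haplotypes, dtype=float))
    if X.shape[1] != loadings.mean.shape[0]:
        raise ValueError(
            f"haplotype has {X.shape[1]} markers, loadings expect {loadings.mean.shape[0]}"
        )
    return (X - loadings.mean) @ loadings.eigvecs


def _logistic_irls(Z, y, ridge: float = 0.0, beta0=None, maxiter: int = 50, tol: float = 1e-8):
    """Newton/IRLS for (optionally ridge-penalized) logistic regression.

    Returns (beta, cov_diag) where cov_diag is the diagonal of the
    inverse (penalized) Fisher information.
    """
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    m = Z.shape[1]
    beta = np.zeros(m) if beta0 is None else np.array(beta0, float)
    eye = np.eye(m)
    for _ in range(maxiter):
        eta = np.clip(Z @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = Z.T @ (y - mu) - ridge * beta
        info = (Z.T * w) @ Z + ridge * eye
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(Z @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-10)
    info = (Z.T * w) @ Z + ridge * eye
    cov = np.linalg.inv(info)
    return beta, np.diag(cov).copy()


def fit_pcr(panels, loadings: PCLoadings, ridge_on_separation: bool = True):
    """Logistic / multinomial PCR of population membership on projected PCs.

    ``panels`` is a list of K binary haplotype matrices over the same
    support markers; all are projected with the *reference* population's
    loadings and population membership is regressed on the components
    (population 1 is the reference class).  Returns ``(H, Sigma_diag)``
    with one row per contrast (K-1 rows), each of length m = r + 1
    including the intercept.

    Complete separation -- routine when panels are strongly diverged --
    is handled by re-fitting with an L2 penalty of 1e-4 * n and logged.
    """
    K = len(panels)
    if K < 2:
        raise ValueError("need at least two panels")
    projs = [project_pcs(p, loadings) for p in panels]
    Z = np.vstack(projs)
    n = Z.shape[0]
    Z = np.column_stack([np.ones(n), Z])
    labels = np.concatenate([np.full(p.shape[0], k) for k, p in enumerate(projs)])
    m = Z.shape[1]

    if K == 2:
        y = (labels == 1).astype(float)
        beta, cov_diag = _logistic_irls(Z, y)
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta[1:] * Z[:, 1:].std(0))) > 30:
            if not ridge_on_separation:
                raise FloatingPointError("separation in PCR fit")
            logger.info("PCR separation: refitting with L2 penalty")
            beta, cov_diag = _logistic_irls(Z, y, ridge=1e-4 * n)
        return beta[None, :], cov_diag[None, :]

    # multinomial logit, population 1 (= class 0) as reference
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(labels, Z).fit(disp=0, maxiter=200)
            params = res.params  # (m, K-1)
            cov = np.diag(res.cov_params()).reshape(K - 1, m)
            if not np.all(np.isfinite(params.to_numpy() if hasattr(params, "to_numpy") else params)):
                raise np.linalg.LinAlgError
            H = np.asarray(params).T  # (K-1, m)
            return H, cov
        except Exception:
            if not ridge_on_separation:
                raise
            logger.info("multinomial PCR separation: one-vs-reference ridge fits")
            H = np.zeros((K - 1, m))
            S = np.zeros((K - 1, m))
            for k in range(1, K):
                sel = (labels == 0) | (labels == k)
                H[k - 1], S[k - 1] = _logistic_irls(
                    Z[sel], (labels[sel] == k).astype(float), ridge=1e-4 * sel.sum()
                )
            return H, S


def pcr_class_probs(H, projected) -> np.ndarray:
    """Class membership probabilities from PCR coefficients.

    ``projected`` is (n, r) on the reference population's components;
    returns (n, K) softmax probabilities (K = n_contrasts + 1).
    """
    H = np.atleast_2d(H)
    Z = np.column_stack([np.ones(projected.shape[0]), projected])
    eta = Z @ H.T  # (n, K-1)
    logits = np.column_stack([np.zeros(eta.shape[0]), eta])
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class WindowPrior:
    """Per-window prior: loadings per population, PCR coefficients and support."""

    loadings: list[PCLoadings]          # one per population; [0] is the reference
    H: np.ndarray                       # (K-1, m) PCR coefficient prior means
    Sigma_diag: np.ndarray              # (K-1, m) prior coefficient variances
    support_start: int
    support_stop: int
    use_pcr: bool                       # False for single-marker / degenerate windows
    support_span_cm: float              # actual cM span of the support columns


@dataclass
class AncestralPrior:
    """All prior hyperparameters derived from the surrogate ancestral panels."""

    windows: WindowSet
    window_priors: list[WindowPrior]
    Omega: np.ndarray                   # (M, K, 2): (variant + .5, reference + .5)
    P: np.ndarray                       # (M, K) prior variant-allele frequencies
    K: int
    panel_sizes: list[int]
    support_cm: float
    var_threshold: float
    version: str = "aldmix-prior-1"

    def save(self, path) -> None:
        """Serialize to a single .npz archive (versioned)."""
        win = self.windows
        flat: dict[str, np.ndarray] = {
            "version": np.array(self.version),
            "Omega": self.Omega,
            "P": self.P,
            "K": np.array(self.K),
            "panel_sizes": np.array(self.panel_sizes),
            "support_cm": np.array(self.support_cm),
            "var_threshold": np.array(self.var_threshold),
            "n_windows": np.array(len(self.window_priors)),
            "win_window_cm": np.array(win.window_cm),
            "win_marker_cm": win.marker_cm,
            "win_marker_chrom": win.marker_chrom.astype(str),
            "win_chrom": win.table["chromosome"].to_numpy(str),
            "win_float": win.table[
                ["start_cm", "end_cm", "midpoint_cm", "width_cm", "d_cm"]
            ].to_numpy(float),
            "win_int": win.table[["n_markers", "start", "stop"]].to_numpy(int),
        }
        for j, wp in enumerate(self.window_priors):
            flat[f"w{j}_H"] = wp.H
            flat[f"w{j}_S"] = wp.Sigma_diag
            flat[f"w{j}_meta"] = np.array(
                [wp.support_start, wp.support_stop, int(wp.use_pcr), wp.support_span_cm]
            )
            for k, ld in enumerate(wp.loadings):
                flat[f"w{j}_p{k}_mean"] = ld.mean
                flat[f"w{j}_p{k}_vecs"] = ld.eigvecs
        np.savez_compressed(path, **flat)

    @classmethod
    def load(cls, path) -> "AncestralPrior":
        """Reload a prior bundle written by :meth:`save`."""
        import pandas as pd

        z = np.load(path, allow_pickle=False)
        version = str(z["version"])
        if not version.startswith("aldmix-prior"):
            raise ValueError(f"not an aldmix prior bundle: {version!r}")
        K = int(z["K"])
        nw = int(z["n_windows"])
        flo = z["win_float"]
        fin = z["win_int"]
        table = pd.DataFrame(
            {
                "chromosome": z["win_chrom"],
                "start_cm": flo[:, 0],
                "end_cm": flo[:, 1],
                "midpoint_cm": flo[:, 2],
                "width_cm": flo[:, 3],
                "n_markers": fin[:, 0],
                "start": fin[:, 1],
                "stop": fin[:, 2],
                "d_cm": flo[:, 4],
            }
        )
        windows = WindowSet(
            table=table,
            window_cm=float(z["win_window_cm"]),
            marker_cm=z["win_marker_cm"],
            marker_chrom=z["win_marker_chrom"],
        )
        wps = []
        for j in range(nw):
            meta = z[f"w{j}_meta"]
            loads = []
            for k in range(K):
                mean = z[f"w{j}_p{k}_mean"]
                vecs = z[f"w{j}_p{k}_vecs"]
                loads.append(
                    PCLoadings(
                        mean=mean,
                        eigvecs=vecs,
                        eigvals=np.zeros(0),
                        support_markers=np.arange(int(meta[0]), int(meta[1])),
                        variance_fraction_retained=float("nan"),
                        degenerate=vecs.shape[1] == 0,
                    )
                )
            wps.append(
                WindowPrior(
                    loadings=loads,
                    H=z[f"w{j}_H"],
                    Sigma_diag=z[f"w{j}_S"],
                    support_start=int(meta[0]),
                    support_stop=int(meta[1]),
                    use_pcr=bool(meta[2]),
                    support_span_cm=float(meta[3]),
                )
            )
        return cls(
            windows=windows,
            window_priors=wps,
            Omega=z["Omega"],
            P=z["P"],
            K=K,
            panel_sizes=list(z["panel_sizes"]),
            support_cm=float(z["support_cm"]),
            var_threshold=float(z["var_threshold"]),
            version=version,
        )


def allele_count_priors(panels, pseudocount: float = 0.5):
    """Pseudocounted per-marker, per-population allele counts and frequencies.

    Omega[m, k] = (variant count + c, reference count + c); P = variant
    fraction of Omega, strictly inside (0, 1).  Missing alleles (coded
    negative) are excluded from the counts.
    """
    K = len(panels)
    M = panels[0].shape[1]
    Omega = np.zeros((M, K, 2))
    for k, pan in enumerate(panels):
        X = np.asarray(pan)
        obs = X >= 0
        Omega[:, k, 0] = np.sum((X == 1) & obs, axis=0) + pseudocount
        Omega[:, k, 1] = np.sum((X == 0) & obs, axis=0) + pseudocount
    P = Omega[:, :, 0] / Omega.sum(axis=2)
    return Omega, P


def compute_priors(
    panels,
    windows: WindowSet,
    support_cm: float = 2.0,
    var_threshold: float = 0.8,
) -> AncestralPrior:
    """Fit all per-window PCAs and PCRs plus allele-count priors.

    The support of window j is every marker of the same chromosome
    within ``support_cm`` total span centered on the window midpoint.
    """
    if not panels:
        raise ValueError("no panels given")
    K = len(panels)
    M = panels[0].shape[1]
    if windows.marker_cm.shape[0] != M:
        raise ValueError("panel marker count does not match window set")
    Omega, P = allele_count_priors(panels)

    cm = windows.marker_cm
    chroms = windows.marker_chrom
    half = support_cm / 2.0
    window_priors: list[WindowPrior] = []
    # contiguous per-chromosome ranges for searchsorted
    chrom_bounds: dict[str, tuple[int, int]] = {}
    for c in dict.fromkeys(chroms):
        where = np.nonzero(chroms == c)[0]
        chrom_bounds[c] = (int(where[0]), int(where[-1] + 1))

    for j in range(windows.n_windows):
        row = windows.table.iloc[j]
        c = row["chromosome"]
        lo, hi = chrom_bounds[c]
        mid = row["midpoint_cm"]
        ss = lo + int(np.searchsorted(cm[lo:hi], mid - half, side="left"))
        se = lo + int(np.searchsorted(cm[lo:hi], mid + half, side="right"))
        support = np.arange(ss, se)
        span = float(cm[se - 1] - cm[ss]) if se - ss > 1 else 0.0
        loads = [
            fit_window_pca(np.asarray(pan)[:, ss:se], support, var_threshold)
            for pan in panels
        ]
        ref = loads[0]
        single = int(row["n_markers"]) < 2
        if ref.degenerate or single or ref.n_components == 0:
            m = ref.n_components + 1
            window_priors.append(
                WindowPrior(
                    loadings=loads,
                    H=np.zeros((K - 1, m)),
                    Sigma_diag=np.ones((K - 1, m)),
                    support_start=ss,
                    support_stop=se,
                    use_pcr=False,
                    support_span_cm=span,
                )
            )
            continue
        H, S = fit_pcr([np.asarray(p)[:, ss:se] for p in panels], ref)
        window_priors.append(
            WindowPrior(
                loadings=loads,
                H=H,
                Sigma_diag=S,
                support_start=ss,
                support_stop=se,
                use_pcr=True,
                support_span_cm=span,
            )
        )
    return AncestralPrior(
        windows=windows,
        window_priors=window_priors,
        Omega=Omega,
        P=P,
        K=K,
        panel_sizes=[p.shape[0] for p in panels],
        support_cm=support_cm,
        var_threshold=var_threshold,
    )
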