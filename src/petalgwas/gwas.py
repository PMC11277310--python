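"""Mixed-linear-model association scan with kinship control.

The model is y = X beta + u + e with a polygenic random effect
u ~ N(0, sigma2_g K) and iid residuals e ~ N(0, sigma2_e I). Variance
components are estimated once on the null model by REML over the variance
ratio delta = sigma2_e / sigma2_g, using the spectral decomposition of the
projected kinship (the EMMA device), and are then held fixed for every marker
test (the P3D strategy) so the scan is a single generalized-least-squares
pass per marker.

`MixedModelGWAS` / `GWASResults` are the object interface; the underlying
operations (`vanraden_kinship`, `fit_null_mlm`, `mlm_scan`,
`bonferroni_threshold`, `find_peaks`, `candidate_windows`) are importable
functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MISSING, GeneModel, GenotypeMatrix

logger = logging.getLogger(__name__)

_DELTA_GRID = np.logspace(-5, 5, 61)
_DELTA_MAX = 1e8  # delta above this is numerically "no genetic variance"


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def imputed_dosages(G: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-marker mean imputation of missing calls."""
    X = G.calls.astype(float)
    obs = X >= 0
    with np.errstate(invalid="ignore"):
        col_mean = np.where(obs, X, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    return np.where(obs, X, col_mean)


def vanraden_kinship(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix K = WW' / (2 sum p_j (1-p_j)).

    W is the dosage matrix centred by twice the allele frequency; missing
    calls are mean-imputed per marker. Monomorphic markers contribute nothing
    and are tolerated (they add zero columns).
    """
    if isinstance(G, GenotypeMatrix):
        X = imputed_dosages(G)
    else:
        X = np.asarray(G, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("kinship needs at least 2 samples")
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    denom = 2.0 * np.sum(p * (1 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; kinship undefined")
    return (W @ W.T) / denom


# ---------------------------------------------------------------------------
# Null model REML (EMMA)
# ---------------------------------------------------------------------------


@dataclass
class MlmNullFit:
    """REML variance components of the null mixed model plus the spectral
    handles needed to run the scan."""

    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    eigvals: np.ndarray  # eigenvalues of K
    eigvecs: np.ndarray  # eigenvectors of K (columns)
    X: np.ndarray  # fixed-effect design, intercept first

    @property
    def delta(self) -> float:
        return self.sigma2_e / self.sigma2_g if self.sigma2_g > 0 else math.inf

    # `lambda` in the sigma2_e/sigma2_g sense
    lambda_ = delta

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _reml_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    q = xi.size
    denom = xi + delta
    ss = float(np.sum(eta2 / denom))
    return 0.5 * (q * math.log(q / (2 * math.pi)) - q - q * math.log(ss)
                  - float(np.sum(np.log(denom))))


def fit_null_mlm(
    y: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
) -> MlmNullFit:
    """REML fit of y = X beta + u + e with u ~ N(0, sigma2_g K).

    X always contains an intercept; `covariates` appends columns. The
    profiled REML log-likelihood in delta = sigma2_e/sigma2_g is maximized on
    a log-spaced bracketing grid refined by bounded scalar optimization.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite (drop incomplete samples first)")
    n = y.size
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError(f"K shape {K.shape} does not match n={n}")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    p = X.shape[1]
    q = n - p

    # restricted spectrum: eigen of S (K + I) S, S the residual-forming matrix
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    w_all, U_all = np.linalg.eigh(S @ (K + np.eye(n)) @ S)
    idx = np.argsort(w_all)[::-1][:q]
    xi = np.clip(w_all[idx] - 1.0, 0.0, None)
    eta = U_all[:, idx].T @ y
    eta2 = eta**2

    lls = np.array([_reml_loglik(d, xi, eta2) for d in _DELTA_GRID])
    best = int(np.argmax(lls))
    lo = _DELTA_GRID[max(best - 1, 0)]
    hi = _DELTA_GRID[min(best + 1, _DELTA_GRID.size - 1)]
    res = optimize.minimize_scalar(
        lambda d: -_reml_loglik(d, xi, eta2),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res.message}")
    delta = float(res.x)
    ll = _reml_loglik(delta, xi, eta2)

    sigma2_g = float(np.sum(eta2 / (xi + delta)) / q)
    sigma2_e = delta * sigma2_g
    if best == _DELTA_GRID.size - 1 and delta >= _DELTA_GRID[-1] * 0.99:
        # boundary: effectively zero genetic variance
        sigma2_e = float(np.sum(eta2) / q)
        sigma2_g = 0.0

    evals, evecs = np.linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    return MlmNullFit(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        reml_loglik=ll,
        eigvals=evals,
        eigvecs=evecs,
        X=X,
    )


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def mlm_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    null_fit: MlmNullFit,
) -> pd.DataFrame:
    """Per-marker generalized least squares with variance components fixed at
    the null fit; Wald t-test on the marker effect.

    Missing genotypes are mean-imputed per marker. A monomorphic marker gets
    beta = 0, p = 1 with a warning count. Returns the association table
    (chrom, pos, id, beta, se, p, neglog10p).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if G.n_samples != n:
        raise ValueError("genotype matrix and phenotype length differ")
    X = null_fit.X
    p_fix = X.shape[1]
    delta = null_fit.delta

    U = null_fit.eigvecs
    if math.isfinite(delta) and delta < _DELTA_MAX:
        w = 1.0 / np.sqrt(null_fit.eigvals + delta)
    else:
        w = np.ones(n)
    yt = w * (U.T @ y)
    Xt = w[:, None] * (U.T @ X)
    Gt = w[:, None] * (U.T @ imputed_dosages(G))

    # residualize against fixed effects
    XtX_inv = np.linalg.inv(Xt.T @ Xt)
    proj = Xt @ (XtX_inv @ Xt.T)
    ry = yt - proj @ yt
    Rg = Gt - proj @ Gt

    gg = np.einsum("ij,ij->j", Rg, Rg)
    gy = Rg.T @ ry
    dof = n - p_fix - 1
    yy = float(ry @ ry)

    poly = gg > 1e-12 * max(1.0, float(np.max(gg, initial=0.0)))
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("mlm_scan: %d monomorphic marker(s), p set to 1", n_mono)

    beta = np.zeros(G.n_variants)
    se = np.full(G.n_variants, np.nan)
    pvals = np.ones(G.n_variants)
    beta[poly] = gy[poly] / gg[poly]
    rss = np.maximum(yy - beta[poly] ** 2 * gg[poly], 0.0)
    sigma2 = rss / dof
    se_poly = np.sqrt(sigma2 / gg[poly])
    se[poly] = se_poly
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se_poly > 0, beta[poly] / se_poly, np.inf)
    pvals[poly] = np.clip(2.0 * stats.t.sf(np.abs(tstat), dof), 1e-300, 1.0)

    out = G.variants[["chrom", "pos", "id"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = pvals
    out["neglog10p"] = -np.log10(pvals)
    return out


# ---------------------------------------------------------------------------
# Threshold, peaks, candidate windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignificanceThreshold:
    """Bonferroni cutoff alpha / n_independent."""

    alpha: float
    n_independent: int
    p_threshold: float
    neglog10_threshold: float


def bonferroni_threshold(
    n_independent: int, alpha: float = 0.01, mode: str = "alpha_over_n"
) -> SignificanceThreshold:
    """Significance threshold from the number of independent markers.

    ``mode="alpha_over_n"`` gives p = alpha/n (default); ``mode="one_over_n"``
    gives p = 1/n, the alternative reading of a -log10(1/n) cutoff.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly in (0, 1)")
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    if mode == "alpha_over_n":
        p_thr = alpha / n_independent
    elif mode == "one_over_n":
        p_thr = 1.0 / n_independent
    else:
        raise ValueError("mode must be 'alpha_over_n' or 'one_over_n'")
    return SignificanceThreshold(
        alpha=alpha,
        n_independent=n_independent,
        p_threshold=p_thr,
        neglog10_threshold=-math.log10(p_thr),
    )


def estimate_n_independent(
    G: GenotypeMatrix, r2_max: float = 0.2, window: int = 50
) -> int:
    """Greedy LD-pruning estimate of the number of independent markers.

    Within a sliding window of ``window`` markers, a marker correlated at
    r^2 > ``r2_max`` with an already-kept marker is pruned.
    """
    X = imputed_dosages(G)
    sd = X.std(axis=0)
    kept: list[int] = []
    for j in range(G.n_variants):
        if sd[j] == 0:
            continue
        ok = True
        for k in reversed(kept):
            if j - k > window:
                break
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return max(len(kept), 1)


def find_peaks(
    assoc: pd.DataFrame,
    threshold: SignificanceThreshold,
    clump_distance: int = 500_000,
) -> pd.DataFrame:
    """Greedy distance-based clumping of significant markers into peaks.

    The lowest-p significant marker seeds a peak and absorbs all significant
    markers within ``clump_distance`` bp on its chromosome; repeat until no
    significant marker is unassigned. Returns peak rows (subset of assoc)
    with an ``n_clumped`` column.
    """
    sig = assoc[assoc["p"] < threshold.p_threshold].copy()
    peaks = []
    while not sig.empty:
        top = sig.loc[sig["p"].idxmin()]
        near = (sig["chrom"] == top["chrom"]) & (
            (sig["pos"] - top["pos"]).abs() <= clump_distance
        )
        rec = top.to_dict()
        rec["n_clumped"] = int(near.sum())
        peaks.append(rec)
        sig = sig[~near]
    cols = list(assoc.columns) + ["n_clumped"]
    return pd.DataFrame(peaks, columns=cols)


@dataclass(frozen=True)
class CandidateWindow:
    """+/- 250 kb region around a peak marker with the genes it overlaps."""

    peak_id: str
    chrom: str
    peak_pos: int
    start: int
    end: int
    gene_ids: tuple[str, ...]


def candidate_windows(
    peaks: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    flank: int = 250_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[CandidateWindow]:
    """Genes whose span overlaps [pos - flank, pos + flank] per peak.

    Overlap is 1-based inclusive; the window is clipped to [1, chromosome
    length] when lengths are provided.
    """
    out = []
    for row in peaks.itertuples(index=False):
        start = max(1, int(row.pos) - flank)
        end = int(row.pos) + flank
        if chrom_lengths and row.chrom in chrom_lengths:
            end = min(end, chrom_lengths[row.chrom])
        genes = tuple(
            g.gene_id
            for g in gene_models
            if g.chrom == row.chrom
            and g.gene_span[0] <= end
            and g.gene_span[1] >= start
        )
        out.append(
            CandidateWindow(
                peak_id=str(row.id),
                chrom=str(row.chrom),
                peak_pos=int(row.pos),
                start=start,
                end=end,
                gene_ids=genes,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class MixedModelGWAS:
    """Mixed-linear-model genome scan for one quantitative trait.

    Parameters
    ----------
    y : array-like
        Trait values, one per sample of ``G`` (order must match).
    G : GenotypeMatrix
        Marker panel; missing calls are mean-imputed for testing.
    K : ndarray, optional
        Kinship; computed with :func:`vanraden_kinship` when omitted.
    covariates : ndarray, optional
        Extra fixed-effect columns (an intercept is always included).
    n_pcs : int
        Number of leading kinship eigenvectors appended as structure
        covariates (0 by default).
    """

    def __init__(
        self,
        y: np.ndarray,
        G: GenotypeMatrix,
        K: np.ndarray | None = None,
        covariates: np.ndarray | None = None,
        n_pcs: int = 0,
    ) -> None:
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.size != G.n_samples:
            raise ValueError("phenotype length does not match sample count")
        self.G = G
        self.K = vanraden_kinship(G) if K is None else np.asarray(K, dtype=float)
        cov = None
        if n_pcs > 0:
            evals, evecs = np.linalg.eigh(self.K)
            pcs = evecs[:, np.argsort(evals)[::-1][:n_pcs]]
            cov = pcs
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != self.y.size:
                C = C.T
            cov = C if cov is None else np.hstack([cov, C])
        self.covariates = cov

    @classmethod
    def from_dataframe(
        cls,
        pheno: pd.DataFrame,
        trait: str,
        G: GenotypeMatrix,
        **kwargs,
    ) -> "MixedModelGWAS":
        """Build from a sample-indexed phenotype table, aligning and dropping
        samples with a missing trait value."""
        y = pheno[trait].reindex(G.samples)
        keep = np.flatnonzero(y.notna().to_numpy())
        if keep.size < G.n_samples:
            G = G.take_samples(keep)
        return cls(y.to_numpy(dtype=float)[keep], G, **kwargs)

    def fit(self) -> "GWASResults":
        null = fit_null_mlm(self.y, self.K, self.covariates)
        assoc = mlm_scan(self.G, self.y, null)
        return GWASResults(model=self, null_fit=null, assoc=assoc)


@dataclass
class GWASResults:
    """Fitted scan: variance components, association table, and helpers."""

    model: MixedModelGWAS
    null_fit: MlmNullFit
    assoc: pd.DataFrame
    _threshold: SignificanceThreshold | None = field(default=None, repr=False)

    @property
    def h2(self) -> float:
        return self.null_fit.h2

    def threshold(
        self, n_independent: int | None = None, alpha: float = 0.01, **kwargs
    ) -> SignificanceThreshold:
        if n_independent is None:
            n_independent = estimate_n_independent(self.model.G)
        self._threshold = bonferroni_threshold(n_independent, alpha, **kwargs)
        return self._threshold

    def find_peaks(
        self,
        threshold: SignificanceThreshold | None = None,
        clump_distance: int = 500_000,
    ) -> pd.DataFrame:
        thr = threshold or self._threshold or self.threshold()
        return find_peaks(self.assoc, thr, clump_distance)

    def candidate_windows(
        self, gene_models: Sequence[GeneModel], flank: int = 250_000, **kwargs
    ) -> list[CandidateWindow]:
        return candidate_windows(self.find_peaks(), gene_models, flank, **kwargs)

    def manhattan_data(self) -> pd.DataFrame:
        return self.assoc[["chrom", "pos", "neglog10p"]].copy()

    def qq_data(self) -> pd.DataFrame:
        obs = np.sort(self.assoc["p"].to_numpy())
        m = obs.size
        exp = (np.arange(1, m + 1) - 0.5) / m
        return pd.DataFrame(
            {"expected_neglog10p": -np.log10(exp), "observed_neglog10p": -np.log10(obs)}
        )

    def summary(self) -> str:
        nf = self.null_fit
        top = self.assoc.loc[self.assoc["p"].idxmin()] if len(self.assoc) else None
        lines = [
            "Mixed linear model GWAS (REML variance components, P3D scan)",
            "=" * 62,
            f"samples: {self.model.G.n_samples}    markers: {self.model.G.n_variants}",
            f"sigma2_g: {nf.sigma2_g:.6g}    sigma2_e: {nf.sigma2_e:.6g}",
            f"pseudo-heritability h2: {nf.h2:.4f}    REML logL: {nf.reml_loglik:.4f}",
        ]
        if top is not None:
            lines.append(
                f"top marker: {top['id']} ({top['chrom']}:{int(top['pos'])}) "
                f"beta={top['beta']:.4g} p={top['p']:.3g}"
            )
        if self._threshold is not None:
            thr = self._threshold
            n_sig = int((self.assoc["p"] < thr.p_threshold).sum())
            lines.append(
                f"threshold: alpha={thr.alpha} / n={thr.n_independent} -> "
                f"-log10 p = {thr.neglog10_threshold:.4g}; significant markers: {n_sig}"
            )
        return "\n".join(lines)

    def plot_manhattan(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.manhattan_data()
        fig, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            ax.scatter(sub["pos"] + offset, sub["neglog10p"], s=4)
            offset += sub["pos"].max()
        if self._threshold is not None:
            ax.axhline(self._threshold.neglog10_threshold, color="red", lw=0.8)
        ax.set_xlabel("genomic position")
        ax.set_ylabel(r"$-\log_{10} p$")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
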