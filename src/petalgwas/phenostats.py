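"""Phenotype-level statistics: trait correlations, canonical correlation of
organ phenotype blocks, mean-split size concordance, and FPKM normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats


def star_label(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson_matrix(
    pheno: pd.DataFrame, trait_subset: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with two-sided t-based p-values.

    Returns (r, p, stars) DataFrames. A zero-variance trait is flagged by
    raising rather than silently propagating NaN.
    """
    cols = list(trait_subset) if trait_subset is not None else list(pheno.columns)
    X = pheno[cols]
    zero_var = [c for c in cols if X[c].dropna().nunique() <= 1]
    if zero_var:
        raise ValueError(f"zero-variance traits (correlation undefined): {zero_var}")

    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    np.fill_diagonal(p, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            pair = X[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for {cols[i]} vs {cols[j]}"
                )
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    stars = p_df.map(star_label)
    for c in cols:
        stars.loc[c, c] = ""
    return r_df, p_df, stars


@dataclass(frozen=True)
class CcaResult:
    """Canonical correlations (non-increasing) and the weight vectors."""

    correlations: np.ndarray
    x_weights: np.ndarray  # p x k
    y_weights: np.ndarray  # q x k

    def __post_init__(self) -> None:
        rho = self.correlations
        if np.any(rho < -1e-9) or np.any(rho > 1 + 1e-9):
            raise ValueError("canonical correlations must lie in [0, 1]")
        if np.any(np.diff(rho) > 1e-9):
            raise ValueError("canonical correlations must be non-increasing")


def canonical_correlation(X: pd.DataFrame | np.ndarray, Y: pd.DataFrame | np.ndarray) -> CcaResult:
    """Canonical correlation analysis via SVD of the whitened cross-covariance.

    Columns are centred internally; requires n > p + q and full-rank blocks
    (a rank-deficient block raises an error naming the collinear columns).
    """
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.ndim != 2 or Ya.ndim != 2 or Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must be 2-D with equal row counts")
    n, p = Xa.shape
    q = Ya.shape[1]
    if n <= p + q:
        raise ValueError(f"need n > p + q, got n={n}, p={p}, q={q}")
    Xc = Xa - Xa.mean(axis=0)
    Yc = Ya - Ya.mean(axis=0)

    for block, names, label in ((Xc, x_names, "X"), (Yc, y_names, "Y")):
        rank = np.linalg.matrix_rank(block)
        if rank < block.shape[1]:
            cols = names if names is not None else list(range(block.shape[1]))
            raise ValueError(
                f"rank-deficient {label} block (rank {rank} < {block.shape[1]}); "
                f"check columns {cols} for collinearity"
            )

    # QR-based whitening is numerically stable for ill-conditioned blocks
    Qx, Rx = np.linalg.qr(Xc)
    Qy, Ry = np.linalg.qr(Yc)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    k = min(p, q)
    rho = np.clip(s[:k], 0.0, 1.0)
    a = linalg.solve_triangular(Rx, U[:, :k])
    b = linalg.solve_triangular(Ry, Vt.T[:, :k])
    return CcaResult(correlations=rho, x_weights=a, y_weights=b)


def mean_split_concordance(
    petal_trait: pd.Series, seed_trait: pd.Series, tie_rule: str = "small"
) -> pd.DataFrame:
    """Cross-tabulate large/small calls from each trait's own mean split.

    "Large" means strictly above the trait mean; a value exactly equal to the
    mean counts as "small" under the default tie rule (``tie_rule="large"``
    flips that). Returns a 2x2 table indexed large/small x large/small over
    samples where both traits are observed.
    """
    if tie_rule not in ("small", "large"):
        raise ValueError("tie_rule must be 'small' or 'large'")
    pair = pd.concat([petal_trait, seed_trait], axis=1, join="inner").dropna()
    if pair.iloc[:, 0].nunique() <= 1 or pair.iloc[:, 1].nunique() <= 1:
        raise ValueError("zero-variance trait in concordance split")
    x, y = pair.iloc[:, 0], pair.iloc[:, 1]
    if tie_rule == "small":
        lx, ly = x > x.mean(), y > y.mean()
    else:
        lx, ly = x >= x.mean(), y >= y.mean()
    table = pd.DataFrame(
        {
            "seed_large": [int((lx & ly).sum()), int((~lx & ly).sum())],
            "seed_small": [int((lx & ~ly).sum()), int((~lx & ~ly).sum())],
        },
        index=["petal_large", "petal_small"],
    )
    assert int(table.to_numpy().sum()) == len(pair)
    return table


def fpkm(
    exon_mapped_fragments: float | np.ndarray,
    total_mapped_fragments: float,
    exon_length_bp: float | np.ndarray,
) -> float | np.ndarray:
    """Fragments per kilobase of exon model per million mapped fragments.

    FPKM = ExonMappedFragments * 1e9 / (TotalMappedFragments * ExonLength).
    """
    counts = np.asarray(exon_mapped_fragments, dtype=float)
    lengths = np.asarray(exon_length_bp, dtype=float)
    if np.any(counts < 0):
        raise ValueError("fragment counts must be >= 0")
    if np.any(lengths <= 0):
        raise ValueError("exon length must be > 0")
    if total_mapped_fragments <= 0:
        raise ValueError("total mapped fragments must be > 0")
    out = counts * 1e9 / (total_mapped_fragments * lengths)
    return float(out) if out.ndim == 0 else out


def fpkm_table(counts: pd.DataFrame, lib_sizes: pd.Series, exon_lengths: pd.Series) -> pd.DataFrame:
    """FPKM for a genes x libraries count table."""
    lengths = exon_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise KeyError("exon lengths missing for some genes")
    out = {}
    for lib in counts.columns:
        out[lib] = fpkm(counts[lib].to_numpy(), float(lib_sizes[lib]), lengths.to_numpy())
    return pd.DataFrame(out, index=counts.index)
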