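"""Sliding-window population-genetic statistics and pairwise LD.

Nucleotide diversity uses the unbiased per-site estimator
pi_site = (2N/(2N-1)) * 2 p (1-p) with 2N the observed allele count; windowed
pi divides the per-site sum by the window width in bp. FST is the
Weir & Cockerham (1984) variance-components estimator aggregated over a
window as a ratio of sums. Tajima's D uses the 1989 constants with the
sample size taken as the window-median observed allele count. Two-locus LD
on unphased diploids resolves the double-heterozygote ambiguity with an EM
haplotype-frequency estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 20_000
DEFAULT_FST_STEP_BP = 2_000
MIN_CALLED_ALLELES = 4


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end before start")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def make_windows(
    chrom: str, span: tuple[int, int], width: int = DEFAULT_WINDOW_BP, step: int | None = None
) -> list[GenomicWindow]:
    """Tile [span] with windows of ``width`` bp advancing by ``step`` bp
    (step defaults to width, i.e. non-overlapping)."""
    step = step or width
    lo, hi = span
    return [
        GenomicWindow(chrom, s, s + width - 1)
        for s in range(lo, hi + 1, step)
    ]


def _site_freq_and_count(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and observed allele count (2N) per site."""
    obs = calls != MISSING
    an = 2.0 * obs.sum(axis=0)
    ac = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    return p, an


def _pi_per_site(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site heterozygosity; sites with < MIN_CALLED_ALLELES
    observed alleles get NaN."""
    p, an = _site_freq_and_count(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(
            an >= MIN_CALLED_ALLELES,
            (an / np.maximum(an - 1, 1)) * 2.0 * p * (1.0 - p),
            np.nan,
        )
    return pi, an


def _window_mask(variants: pd.DataFrame, w: GenomicWindow) -> np.ndarray:
    return (
        (variants["chrom"] == w.chrom)
        & (variants["pos"] >= w.start)
        & (variants["pos"] <= w.end)
    ).to_numpy()


def window_pi(G: GenotypeMatrix, windows: list[GenomicWindow]) -> pd.DataFrame:
    """Windowed nucleotide diversity: sum of per-site pi over window width."""
    pi_site, _ = _pi_per_site(G.calls)
    rows = []
    for w in windows:
        idx = _window_mask(G.variants, w)
        vals = pi_site[idx]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "statistic": "pi",
                "value": float(vals.sum()) / w.width,
                "n_sites": int(vals.size),
                "pops": "all",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def weir_cockerham_components(
    calls: np.ndarray, pop_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site W&C (1984) variance components (a, a+b+c) for diploid data.

    ``calls`` is samples x sites; sites where any population has fewer than
    2 genotyped samples are NaN in both outputs.
    """
    pops = np.unique(pop_labels)
    r = pops.size
    if r < 2:
        raise ValueError("need at least 2 populations")
    m = calls.shape[1]

    n_i = np.zeros((r, m))
    p_i = np.zeros((r, m))
    h_i = np.zeros((r, m))
    for k, pop in enumerate(pops):
        sub = calls[pop_labels == pop]
        obs = sub != MISSING
        n_i[k] = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[k] = np.where(obs, sub, 0).sum(axis=0) / np.maximum(2 * n_i[k], 1)
            h_i[k] = np.where(obs & (sub == 1), 1, 0).sum(axis=0) / np.maximum(n_i[k], 1)

    valid = (n_i >= 2).all(axis=0)
    n_sum = n_i.sum(axis=0)
    nbar = n_sum / r
    nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / n_sum
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / n_sum

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
    total = a + b + c
    a = np.where(valid, a, np.nan)
    total = np.where(valid, total, np.nan)
    return a, total


def window_fst(
    G: GenotypeMatrix,
    pop_labels: np.ndarray,
    windows: list[GenomicWindow],
    aggregation: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Windowed Weir & Cockerham FST.

    Default aggregation is the weighted ratio-of-sums
    (sum a) / (sum a+b+c); ``aggregation="mean"`` averages per-site ratios
    instead. Windows where a population is entirely absent are skipped with a
    log entry.
    """
    pop_labels = np.asarray(pop_labels)
    if pop_labels.size != G.n_samples:
        raise ValueError("pop_labels length must match sample count")
    a, total = weir_cockerham_components(G.calls, pop_labels)
    pops = ",".join(str(p) for p in np.unique(pop_labels))
    rows = []
    for w in windows:
        idx = _window_mask(G.variants, w)
        aw, tw = a[idx], total[idx]
        ok = ~np.isnan(aw) & ~np.isnan(tw)
        if idx.sum() > 0 and not ok.any():
            logger.info("window_fst: no usable sites in %s:%d-%d", w.chrom, w.start, w.end)
            continue
        if aggregation == "ratio_of_sums":
            denom = float(tw[ok].sum())
            value = float(aw[ok].sum()) / denom if denom != 0 else float("nan")
        elif aggregation == "mean":
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios = aw[ok] / tw[ok]
            ratios = ratios[np.isfinite(ratios)]
            value = float(ratios.mean()) if ratios.size else float("nan")
        else:
            raise ValueError("aggregation must be 'ratio_of_sums' or 'mean'")
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "statistic": "fst",
                "value": value,
                "n_sites": int(ok.sum()),
                "pops": pops,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n sampled sequences."""
    if n < 2:
        raise ValueError("Tajima's D needs n >= 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(pi_total: float, S: int, n: int) -> float:
    """D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S-1))."""
    if S < 1:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / k["a1"]) / math.sqrt(var)


def window_tajima_d(G: GenotypeMatrix, windows: list[GenomicWindow]) -> pd.DataFrame:
    """Windowed Tajima's D.

    pi_total is the window sum of unbiased per-site heterozygosity (not
    divided by width); S the count of segregating sites among usable sites;
    the sequence count n is the window-median observed allele count. Windows
    with S = 0 get NaN, flagged via n_sites.
    """
    pi_site, an = _pi_per_site(G.calls)
    p, _ = _site_freq_and_count(G.calls)
    rows = []
    for w in windows:
        idx = _window_mask(G.variants, w)
        usable = idx & ~np.isnan(pi_site)
        seg = usable & (p > 0) & (p < 1)
        S = int(seg.sum())
        if S > 0:
            n_seq = int(np.median(an[seg]))
            value = tajima_d(float(pi_site[seg].sum()), S, n_seq)
        else:
            value = float("nan")
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "statistic": "tajima_d",
                "value": value,
                "n_sites": S,
                "pops": "all",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-sample heterozygosity
# ---------------------------------------------------------------------------

def sample_heterozygosity(G: GenotypeMatrix) -> pd.DataFrame:
    """Observed het calls, HWE-expected het, and F = 1 - obs/exp per sample.

    Expected counts sum per-site 2p(1-p) from pooled observed frequencies
    over the sites genotyped in that sample.
    """
    p, an = _site_freq_and_count(G.calls)
    site_ok = an >= MIN_CALLED_ALLELES
    exp_site = np.where(site_ok, 2.0 * p * (1.0 - p), 0.0)
    rows = []
    for i, s in enumerate(G.samples):
        called = (G.calls[i] != MISSING) & site_ok
        obs = int(((G.calls[i] == 1) & site_ok).sum())
        exp = float(exp_site[called].sum())
        f = 1.0 - obs / exp if exp > 0 else float("nan")
        rows.append(
            {"sample": s, "n_sites": int(called.sum()), "obs_het": obs, "exp_het": exp, "F": f}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-locus LD (EM for unphased diploids)
# ---------------------------------------------------------------------------

def _em_haplotype_freqs(
    g1: np.ndarray, g2: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """EM estimate of the four two-locus haplotype frequencies
    (ref-ref, ref-alt, alt-ref, alt-alt) from unphased genotype codes."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    n = a.size
    if n < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((a == i) & (b == j))

    # haplotype contributions known except for the double heterozygote
    f = np.full(4, 0.25)  # order: 00, 01, 10, 11 (allele at locus1, locus2)
    known = np.zeros(4)
    # each genotype pair contributes 2 haplotypes
    contrib = {
        (0, 0): {0: 2}, (0, 1): {0: 1, 1: 1}, (0, 2): {1: 2},
        (1, 0): {0: 1, 2: 1}, (1, 2): {1: 1, 3: 1},
        (2, 0): {2: 2}, (2, 1): {2: 1, 3: 1}, (2, 2): {3: 2},
    }
    for (i, j), haps in contrib.items():
        for h, w in haps.items():
            known[h] += counts[i, j] * w
    n_dh = counts[1, 1]
    total = 2.0 * n
    for _ in range(max_iter):
        # split double-hets between cis (00+11) and trans (01+10)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w_cis = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = known.copy()
        new[0] += n_dh * w_cis
        new[3] += n_dh * w_cis
        new[1] += n_dh * (1 - w_cis)
        new[2] += n_dh * (1 - w_cis)
        new /= total
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def pairwise_ld(G: GenotypeMatrix, region: tuple[str, int, int] | None = None) -> pd.DataFrame:
    """r^2 and D' for every variant pair in a region (1-based inclusive).

    Haplotype frequencies come from the EM estimator; monomorphic variants
    are skipped. Returns a long-form pair table.
    """
    if region is not None:
        chrom, lo, hi = region
        idx = np.flatnonzero(
            (G.variants["chrom"] == chrom)
            & (G.variants["pos"] >= lo)
            & (G.variants["pos"] <= hi)
        )
        sub = G.take_variants(idx)
    else:
        sub = G
    if sub.n_variants < 2:
        raise ValueError("need at least 2 variants in the region")

    p = sub.allele_frequencies()
    poly = np.flatnonzero((p > 0) & (p < 1))
    rows = []
    ids = sub.variants["id"].tolist()
    for ii, j1 in enumerate(poly):
        for j2 in poly[ii + 1:]:
            f = _em_haplotype_freqs(sub.calls[:, j1], sub.calls[:, j2])
            pA = f[2] + f[3]  # alt freq at locus 1
            pB = f[1] + f[3]  # alt freq at locus 2
            D = f[3] - pA * pB
            denom = pA * (1 - pA) * pB * (1 - pB)
            if denom <= 0:
                continue
            r2 = D * D / denom
            if D >= 0:
                dmax = min(pA * (1 - pB), (1 - pA) * pB)
            else:
                dmax = min(pA * pB, (1 - pA) * (1 - pB))
            dprime = abs(D) / dmax if dmax > 0 else float("nan")
            rows.append(
                {
                    "id1": ids[j1],
                    "id2": ids[j2],
                    "r2": min(r2, 1.0),
                    "d_prime": min(dprime, 1.0) if not math.isnan(dprime) else dprime,
                    "f_rr": f[0],
                    "f_ra": f[1],
                    "f_ar": f[2],
                    "f_aa": f[3],
                }
            )
    return pd.DataFrame(rows)


def ld_matrix(G: GenotypeMatrix, region: tuple[str, int, int] | None = None) -> pd.DataFrame:
    """Square r^2 matrix built from :func:`pairwise_ld`."""
    pairs = pairwise_ld(G, region)
    ids = sorted(set(pairs["id1"]) | set(pairs["id2"]))
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for row in pairs.itertuples(index=False):
        mat.loc[row.id1, row.id2] = row.r2
        mat.loc[row.id2, row.id1] = row.r2
    return mat
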