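"""Candidate-gene haplotype screening.

Samples are grouped by the ordered string of genotype codes across a gene's
SNPs (gene span or CDS intervals only); groups carried by strictly more than
5% of the panel are "dominant", and every dominant pair is tested for a
phenotype difference (Welch t-test by default, Wilcoxon rank-sum as an
option). A gene is flagged significant when any dominant pair differs at
p < 0.05.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GeneModel, GenotypeMatrix
from .phenostats import star_label

logger = logging.getLogger(__name__)


def extract_region_snps(
    G: GenotypeMatrix, gene_model: GeneModel, segment: str = "gene"
) -> GenotypeMatrix:
    """Variants inside the gene span (``segment="gene"``) or inside any CDS
    interval (``segment="CDS"``), 1-based inclusive, order preserved."""
    if segment not in ("gene", "CDS"):
        raise ValueError("segment must be 'gene' or 'CDS'")
    chrom_ok = G.variants["chrom"] == gene_model.chrom
    pos = G.variants["pos"]
    if segment == "gene":
        lo, hi = gene_model.gene_span
        inside = (pos >= lo) & (pos <= hi)
    else:
        inside = pd.Series(False, index=pos.index)
        for a, b in gene_model.cds_intervals:
            inside |= (pos >= a) & (pos <= b)
    return G.take_variants(np.flatnonzero((chrom_ok & inside).to_numpy()))


@dataclass
class HaplotypeGroup:
    """Samples sharing one ordered genotype-code string over region SNPs."""

    key: str
    members: tuple[str, ...]
    frequency: float

    @property
    def n(self) -> int:
        return len(self.members)


def call_haplotypes(
    region_G: GenotypeMatrix, missing_policy: str = "exclude"
) -> list[HaplotypeGroup]:
    """Group samples by their exact genotype-code string over the region.

    ``missing_policy="exclude"`` (default) drops samples with any missing
    call in the region from grouping (counted in the log);
    ``missing_policy="code"`` keeps them, with '.' in the key. Frequencies
    are relative to the full sample count. Groups are returned largest first.
    """
    if region_G.n_variants == 0:
        raise ValueError("empty region: no variants to build haplotypes from")
    if missing_policy not in ("exclude", "code"):
        raise ValueError("missing_policy must be 'exclude' or 'code'")
    total = region_G.n_samples
    keys: dict[str, list[str]] = {}
    n_excluded = 0
    for i, s in enumerate(region_G.samples):
        codes = region_G.calls[i]
        if missing_policy == "exclude" and np.any(codes == MISSING):
            n_excluded += 1
            continue
        key = "".join("." if c == MISSING else str(int(c)) for c in codes)
        keys.setdefault(key, []).append(s)
    if n_excluded:
        logger.info("call_haplotypes: excluded %d sample(s) with missing calls", n_excluded)
    groups = [
        HaplotypeGroup(key=k, members=tuple(v), frequency=len(v) / total)
        for k, v in keys.items()
    ]
    return sorted(groups, key=lambda g: (-g.n, g.key))


def dominant_haplotypes(
    groups: list[HaplotypeGroup], total_n: int, min_frac: float = 0.05
) -> list[HaplotypeGroup]:
    """Groups whose share of ``total_n`` strictly exceeds ``min_frac``.

    The rule is strict ("exceeded 5%"): a group at exactly the threshold is
    dropped.
    """
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    kept = [g for g in groups if g.n / total_n > min_frac]
    if not kept:
        logger.warning("dominant_haplotypes: no group exceeds %.1f%%", 100 * min_frac)
    return kept


@dataclass(frozen=True)
class HapTestResult:
    hap1: str
    hap2: str
    statistic: float
    p: float
    stars: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    median1: float
    median2: float


def haplotype_phenotype_test(
    groups: list[HaplotypeGroup],
    pheno_trait: pd.Series,
    test: str = "welch",
    min_group_n: int = 3,
) -> tuple[list[HapTestResult], bool | None]:
    """Test every pair of dominant groups for a trait difference.

    Returns the pair results and the verdict: True when any pair has
    p < 0.05, False when all pairs are non-significant, None when fewer than
    two groups have >= ``min_group_n`` phenotyped members ("not testable").
    """
    if test not in ("welch", "wilcoxon"):
        raise ValueError("test must be 'welch' or 'wilcoxon'")
    eligible = []
    for g in groups:
        vals = pheno_trait.reindex(list(g.members)).dropna().to_numpy(dtype=float)
        if vals.size >= min_group_n:
            eligible.append((g, vals))
    if len(eligible) < 2:
        return [], None

    results = []
    for (g1, v1), (g2, v2) in itertools.combinations(eligible, 2):
        if test == "welch":
            res = stats.ttest_ind(v1, v2, equal_var=False)
        else:
            res = stats.mannwhitneyu(v1, v2, alternative="two-sided")
        p = float(res.pvalue)
        results.append(
            HapTestResult(
                hap1=g1.key,
                hap2=g2.key,
                statistic=float(res.statistic),
                p=p,
                stars=star_label(p),
                n1=v1.size,
                n2=v2.size,
                mean1=float(v1.mean()),
                mean2=float(v2.mean()),
                median1=float(np.median(v1)),
                median2=float(np.median(v2)),
            )
        )
    verdict = any(r.p < 0.05 for r in results)
    return results, verdict


def _holm_adjust(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def screen_candidate_genes(
    G: GenotypeMatrix,
    gene_models: list[GeneModel],
    pheno: pd.DataFrame,
    trait: str,
    gene_list: list[str] | None = None,
    min_frac: float = 0.05,
    test: str = "welch",
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene haplotype significance report over gene and CDS segments.

    Returns (verdict table, long-form pair-test table). Verdicts are
    "Yes"/"No"/"not testable"/"no SNPs" per segment; ``holm=True`` adjusts
    pair p-values within a gene segment before the 0.05 verdict call.
    """
    by_id = {g.gene_id: g for g in gene_models}
    targets = gene_list if gene_list is not None else list(by_id)
    unknown = [g for g in targets if g not in by_id]
    if unknown:
        raise KeyError(f"genes absent from annotation: {unknown}")
    trait_values = pheno[trait]

    verdict_rows = []
    pair_rows = []
    for gid in targets:
        gm = by_id[gid]
        verdicts = {}
        for segment in ("gene", "CDS"):
            region = extract_region_snps(G, gm, segment)
            if region.n_variants == 0:
                verdicts[segment] = "no SNPs"
                continue
            groups = call_haplotypes(region)
            dom = dominant_haplotypes(groups, region.n_samples, min_frac)
            tests, verdict = haplotype_phenotype_test(dom, trait_values, test=test)
            if holm and tests:
                adj = _holm_adjust([t.p for t in tests])
                verdict = any(a < 0.05 for a in adj)
            else:
                adj = [None] * len(tests)
            for t, ap in zip(tests, adj):
                pair_rows.append(
                    {
                        "gene_id": gid,
                        "segment": segment,
                        "hap1": t.hap1,
                        "hap2": t.hap2,
                        "n1": t.n1,
                        "n2": t.n2,
                        "mean1": t.mean1,
                        "mean2": t.mean2,
                        "statistic": t.statistic,
                        "p": t.p,
                        "p_holm": ap,
                        "stars": t.stars,
                    }
                )
            if verdict is None:
                verdicts[segment] = "not testable"
            else:
                verdicts[segment] = "Yes" if verdict else "No"
        verdict_rows.append(
            {
                "gene_id": gid,
                "trait": trait,
                "gene_segment_significant": verdicts["gene"],
                "cds_segment_significant": verdicts["CDS"],
            }
        )
    return pd.DataFrame(verdict_rows), pd.DataFrame(pair_rows)
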