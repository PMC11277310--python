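"""SNP-SNP interaction tables and the thresholded interaction network.

For every marker pair a 3x3 genotype contingency table (codes 0/1/2 on each
axis) is built over pairwise-complete samples. Two pair measures are
reported: the marginal-comparison statistic

    T = ((R-1)/R) * sum_i (n_i - m_i)^2 / (n_i + m_i - 2 A_ii),  R = 3,

with n_i/m_i the row/column totals and A_ii the diagonal counts (terms with
a zero denominator are skipped and counted), and the squared Pearson
correlation of the genotype codes (genotype r^2). Edges enter the network
when the chosen measure passes the threshold (default r^2 >= 0.95), and
connected components are the interaction groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

R_CATEGORIES = 3


@dataclass(frozen=True)
class InteractionTable:
    """3x3 genotype contingency table with its margins."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (R_CATEGORIES, R_CATEGORIES) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 table")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def pair_table(g1: np.ndarray, g2: np.ndarray) -> InteractionTable:
    """Cross-tabulate two coded genotype vectors over complete pairs."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    counts = np.zeros((R_CATEGORIES, R_CATEGORIES), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return InteractionTable(counts=counts)


def marginal_T(table: InteractionTable) -> tuple[float, int]:
    """The marginal-comparison statistic T, exactly as defined above.

    Returns (T, number of skipped terms); a term is skipped when its
    denominator n_i + m_i - 2 A_ii is zero (which forces n_i = m_i there,
    i.e. a zero numerator too). T is NaN when every term is skipped.
    """
    A = table.counts.astype(float)
    n = table.row_totals.astype(float)
    m = table.col_totals.astype(float)
    total = 0.0
    skipped = 0
    for i in range(R_CATEGORIES):
        denom = n[i] + m[i] - 2 * A[i, i]
        if denom <= 0:
            skipped += 1
            continue
        total += (n[i] - m[i]) ** 2 / denom
    if skipped == R_CATEGORIES:
        return float("nan"), skipped
    return (R_CATEGORIES - 1) / R_CATEGORIES * total, skipped


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1/2 codes over complete pairs."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok], g2[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance genotype vector; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class InteractionNetwork:
    """Thresholded pair network with its connected components."""

    edges: pd.DataFrame  # id1, id2, r2, T, T_skipped_terms, passes_threshold
    components: list[tuple[str, ...]]  # all nodes, singletons included
    threshold: float
    edge_measure: str

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_table(self) -> pd.DataFrame:
        rows = [
            {"component": k, "variant": v, "size": len(comp)}
            for k, comp in enumerate(self.components)
            for v in comp
        ]
        return pd.DataFrame(rows)


def build_network(
    G: GenotypeMatrix,
    edge_measure: str = "r2",
    threshold: float = 0.95,
) -> InteractionNetwork:
    """All-pairs interaction network over the matrix's variants.

    ``edge_measure`` is "r2" (genotype correlation, default) or "T" (the
    marginal statistic); a pair with an undefined measure is skipped. Both
    measures are reported for every evaluated pair. Isolated variants are
    singleton components.
    """
    if G.n_variants < 2:
        raise ValueError("need at least 2 variants")
    if edge_measure not in ("r2", "T"):
        raise ValueError("edge_measure must be 'r2' or 'T'")
    ids = G.variants["id"].tolist()
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    rows = []
    for j1, j2 in itertools.combinations(range(G.n_variants), 2):
        g1, g2 = G.calls[:, j1], G.calls[:, j2]
        try:
            r2 = genotype_r2(g1, g2)
        except ValueError:
            continue
        t_stat, skipped = marginal_T(pair_table(g1, g2))
        measure = r2 if edge_measure == "r2" else t_stat
        passes = bool(np.isfinite(measure) and measure >= threshold)
        rows.append(
            {
                "id1": ids[j1],
                "id2": ids[j2],
                "r2": r2,
                "T": t_stat,
                "T_skipped_terms": skipped,
                "passes_threshold": passes,
            }
        )
        if passes:
            graph.add_edge(ids[j1], ids[j2])
    comps = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c))
    return InteractionNetwork(
        edges=pd.DataFrame(
            rows,
            columns=["id1", "id2", "r2", "T", "T_skipped_terms", "passes_threshold"],
        ),
        components=comps,
        threshold=threshold,
        edge_measure=edge_measure,
    )
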