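"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators: structured diploid genotypes (Balding–Nichols model over
three subpopulations emulating cultivar / landrace / wild panels), heritable
correlated petal/seed phenotypes, petal scenes with analytic shape truth, and
negative-binomial expression counts. All are pure functions of their
configuration plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, PetalMeasure

# ---------------------------------------------------------------------------
# Genotypes: Balding–Nichols structured panel
# ---------------------------------------------------------------------------


@dataclass
class PopSimConfig:
    """Three-subpopulation panel configuration.

    Defaults mirror a 123:90:96 cultivar/landrace/wild resource panel.
    ``divergence`` holds the Balding–Nichols F per subpopulation (the amount
    of drift from the shared ancestral allele frequency).
    """

    n_per_subpop: tuple[int, int, int] = (123, 90, 96)
    n_variants: int = 2000
    divergence: tuple[float, float, float] = (0.05, 0.10, 0.15)
    family_size: int = 5
    family_divergence: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    chrom: str = "Chr07"
    start_pos: int = 41_000_000
    pos_step: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_subpop) or self.n_variants <= 0:
            raise ValueError("sample and variant counts must be positive")
        if not all(0 < f < 1 for f in self.divergence):
            raise ValueError("divergence must lie in (0, 1)")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if not 0 <= self.family_divergence < 1:
            raise ValueError("family_divergence must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


SUBPOP_NAMES = ("cultivar", "landrace", "wild")


def simulate_genotypes(config: PopSimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a structured diploid panel.

    Ancestral allele frequencies are drawn uniformly in ``maf_range``; each
    subpopulation's frequency is a Beta(p(1-F)/F, (1-p)(1-F)/F) perturbation
    (the Balding–Nichols model). Within a subpopulation, samples come in
    families of ``family_size`` whose frequencies take a second, nested
    Balding–Nichols perturbation at ``family_divergence`` — resource panels
    of a selfing crop carry substantial within-group relatedness, which is
    what makes a kinship matrix informative. Genotypes are Hardy–Weinberg
    binomial draws given the family frequency. Returns the matrix and
    per-sample subpopulation labels.
    """
    rng = np.random.default_rng(config.seed)
    n_sub = len(config.n_per_subpop)
    m = config.n_variants
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    labels = np.repeat(np.arange(n_sub), config.n_per_subpop)
    Ff = config.family_divergence
    blocks = []
    for k, (n_k, F) in enumerate(zip(config.n_per_subpop, config.divergence)):
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_k = rng.beta(a, b)
        rows = []
        done = 0
        while done < n_k:
            fam_n = min(config.family_size, n_k - done)
            if Ff > 0 and config.family_size > 1:
                p_eff = np.clip(p_k, 1e-6, 1 - 1e-6)
                p_fam = rng.beta(p_eff * (1 - Ff) / Ff, (1 - p_eff) * (1 - Ff) / Ff)
            else:
                p_fam = p_k
            rows.append(rng.binomial(2, p_fam, size=(fam_n, m)).astype(np.int8))
            done += fam_n
        blocks.append(np.concatenate(rows, axis=0))
    calls = np.concatenate(blocks, axis=0)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)

    pos = config.start_pos + config.pos_step * np.arange(m)
    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "id": [f"{config.chrom}_{p}" for p in pos],
            "ref": "A",
            "alt": "T",
        }
    )
    samples = [
        f"{SUBPOP_NAMES[k][:3].upper()}{i:04d}" for i, k in enumerate(labels)
    ]
    G = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    return G, labels


# ---------------------------------------------------------------------------
# Phenotypes: causal + polygenic + shared organ-size factor
# ---------------------------------------------------------------------------


@dataclass
class PhenoSimConfig:
    """Heritable, cross-organ-correlated trait simulation.

    The phenotype model is y = sum_j beta_j g_j + u + c*f + e with a polygenic
    term u whose covariance is proportional to the kinship matrix (variance
    ``h2_poly`` of the non-causal part), a latent organ-size factor f shared
    by every trait with loading ``cross_trait_loading``, and iid noise. A
    loading of c on unit-variance components gives a between-trait Pearson
    correlation of roughly c^2 / (h2 + c^2 + noise_sd^2) when traits share
    only the factor.
    """

    causal_variants: dict[str, float] = field(default_factory=dict)
    h2_poly: float = 0.3
    cross_trait_loading: float = 0.8
    noise_sd: float = 0.65
    petal_traits: tuple[str, ...] = ("vexil_area", "standard_area")
    seed_traits: tuple[str, ...] = ("seed_area", "seed_perimeter")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2_poly <= 1:
            raise ValueError("h2_poly must be in [0, 1]")
        if self.cross_trait_loading < 0:
            raise ValueError("cross_trait_loading must be >= 0")


def loading_for_target_r(r: float, h2_poly: float, noise_sd: float) -> float:
    """Factor loading giving expected between-trait Pearson correlation ``r``.

    Solves c^2 / (h2 + c^2 + sd^2) = r for traits that share only the latent
    organ-size factor.
    """
    if not 0 < r < 1:
        raise ValueError("target r must be in (0, 1)")
    return math.sqrt(r * (h2_poly + noise_sd**2) / (1 - r))


def simulate_phenotypes(
    G: GenotypeMatrix, config: PhenoSimConfig, kinship: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate petal and seed traits on top of a genotype panel.

    Returns a sample-indexed trait table and a truth record holding the
    causal effects, heritability and factor loading used.
    """
    from .gwas import vanraden_kinship  # deferred: avoids import cycle

    rng = np.random.default_rng(config.seed)
    n = G.n_samples
    ids = list(G.variants["id"])
    missing_ids = [v for v in config.causal_variants if v not in ids]
    if missing_ids:
        raise KeyError(f"causal variants absent from genotype matrix: {missing_ids}")

    # causal component, standardized genotypes
    causal = np.zeros(n)
    for vid, beta in config.causal_variants.items():
        j = ids.index(vid)
        g = G.calls[:, j].astype(float)
        obs = g >= 0
        mu = g[obs].mean() if obs.any() else 0.0
        g = np.where(obs, g, mu)
        sd = g.std()
        if sd > 0:
            g = (g - mu) / sd
        causal += beta * g

    K = vanraden_kinship(G) if kinship is None else np.asarray(kinship, float)
    # square root of K for a correctly specified polygenic term
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    L = U * np.sqrt(w)

    traits = list(config.petal_traits) + list(config.seed_traits)
    c = config.cross_trait_loading
    factor = rng.standard_normal(n)
    table = {}
    for t in traits:
        u = L @ rng.standard_normal(n)
        u_sd = u.std()
        if u_sd > 0:
            u = u / u_sd
        y = (
            causal
            + math.sqrt(config.h2_poly) * u
            + c * factor
            + config.noise_sd * rng.standard_normal(n)
        )
        table[t] = y
    pheno = pd.DataFrame(table, index=pd.Index(G.samples, name="sample"))
    truth = {
        "causal_variants": dict(config.causal_variants),
        "h2_poly": config.h2_poly,
        "cross_trait_loading": config.cross_trait_loading,
        "noise_sd": config.noise_sd,
        "petal_traits": list(config.petal_traits),
        "seed_traits": list(config.seed_traits),
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# Petal scenes with analytic truth
# ---------------------------------------------------------------------------


@dataclass
class PetalSceneSpec:
    """One rendered petal scene: an ellipse plus a 1-cm white reference disk."""

    shape: tuple[int, int] = (600, 800)  # rows, cols
    semi_major_px: float = 150.0
    semi_minor_px: float = 100.0
    rotation_deg: float = 0.0
    center: tuple[float, float] | None = None  # (row, col); default: frame centre
    petal_intensity: float = 0.55
    background_intensity: float = 0.12
    disk_diameter_px: float = 120.0
    disk_center: tuple[float, float] | None = None  # default: upper-left corner area
    disk_intensity: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.semi_minor_px > self.semi_major_px:
            raise ValueError("semi_minor_px must not exceed semi_major_px")
        if min(self.petal_intensity - self.background_intensity,
               self.disk_intensity - self.petal_intensity) < 0.15:
            raise ValueError("insufficient intensity contrast for edge detection")


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def _coverage(
    mask_fn,
    shape: tuple[int, int],
    bbox: tuple[int, int, int, int],
    supersample: int = 4,
) -> np.ndarray:
    """Anti-aliased coverage fractions by supersampled point sampling.

    Only the bounding box (r0, r1, c0, c1) is evaluated; outside is zero.
    """
    s = supersample
    r0, r1, c0, c1 = bbox
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    rows = r0 + (np.arange((r1 - r0) * s) + 0.5) / s - 0.5
    cols = c0 + (np.arange((c1 - c0) * s) + 0.5) / s - 0.5
    fine = mask_fn(rows[:, None], cols[None, :]).astype(float)
    out = np.zeros(shape)
    out[r0:r1, c0:c1] = fine.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    return out


def render_petal_image(spec: PetalSceneSpec) -> tuple[np.ndarray, PetalMeasure]:
    """Render a scene and return it with the analytic ground-truth measure.

    The ground truth is expressed in centimetres using the scene's own disk
    (pixels_per_cm = disk_diameter_px / 1 cm): area = pi*a*b, eccentricity =
    sqrt(1-(b/a)^2), perimeter from Ramanujan's approximation and circularity
    from those two.
    """
    a, b = spec.semi_major_px, spec.semi_minor_px
    h_img, w_img = spec.shape
    cy, cx = spec.center if spec.center is not None else (h_img * 0.58, w_img * 0.55)
    r_disk = spec.disk_diameter_px / 2.0
    dy, dx = (
        spec.disk_center
        if spec.disk_center is not None
        else (r_disk + 12.0, r_disk + 12.0)
    )

    theta = math.radians(spec.rotation_deg)
    ct, st = math.cos(theta), math.sin(theta)

    # geometric guards: in-frame and non-overlapping
    if not (a < cy < h_img - a and a < cx < w_img - a):
        raise ValueError("petal ellipse does not fit in the frame")
    if not (r_disk <= dy <= h_img - r_disk and r_disk <= dx <= w_img - r_disk):
        raise ValueError("reference disk does not fit in the frame")
    if math.hypot(cy - dy, cx - dx) < a + r_disk + 4:
        raise ValueError("petal and reference disk overlap")

    def in_ellipse(rr, cc):
        y, x = rr - cy, cc - cx
        u = x * ct + y * st
        v = -x * st + y * ct
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def in_disk(rr, cc):
        return (rr - dy) ** 2 + (cc - dx) ** 2 <= r_disk**2

    pad = 3
    bbox_petal = (
        int(cy - a) - pad, int(cy + a) + pad, int(cx - a) - pad, int(cx + a) + pad
    )
    bbox_disk = (
        int(dy - r_disk) - pad, int(dy + r_disk) + pad,
        int(dx - r_disk) - pad, int(dx + r_disk) + pad,
    )
    cov_petal = _coverage(in_ellipse, spec.shape, bbox_petal)
    cov_disk = _coverage(in_disk, spec.shape, bbox_disk)
    img = (
        spec.background_intensity
        + (spec.petal_intensity - spec.background_intensity) * cov_petal
        + (spec.disk_intensity - spec.background_intensity) * cov_disk
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    scale = spec.disk_diameter_px  # px per cm, disk is 1 cm across
    area = math.pi * a * b / scale**2
    perim = _ellipse_perimeter(a, b) / scale
    ecc = math.sqrt(max(0.0, 1.0 - (b / a) ** 2))
    truth = PetalMeasure(
        major_length_cm=2 * a / scale,
        minor_length_cm=2 * b / scale,
        area_cm2=area,
        perimeter_cm=perim,
        eccentricity=ecc,
        ratio=b / a,
        circularity=4 * math.pi * area / perim**2,
    )
    return img, truth


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def simulate_counts(
    n_genes: int = 200,
    conditions: tuple[str, str] = ("E1", "E2"),
    timepoints: tuple[str, str] = ("DAF20", "DAF30"),
    n_reps: int = 3,
    nb_dispersion: float = 0.1,
    fold_changes: dict[int, float] | None = None,
    base_mean: float = 500.0,
    exon_length_range: tuple[int, int] = (300, 5000),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial counts for two conditions x two timepoints x replicates.

    ``fold_changes`` maps gene index -> multiplicative change applied to the
    first condition relative to the second. Returns (counts, library sizes,
    exon lengths); counts are genes x libraries.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    fold_changes = fold_changes or {}
    base = rng.lognormal(mean=math.log(base_mean), sigma=0.8, size=n_genes)
    lengths = pd.Series(
        rng.integers(exon_length_range[0], exon_length_range[1] + 1, size=n_genes),
        index=[f"gene{i:04d}" for i in range(n_genes)],
        name="exon_length_bp",
    )

    libs = [f"{c}_{t}_rep{r+1}" for c in conditions for t in timepoints for r in range(n_reps)]
    r_nb = 1.0 / nb_dispersion
    data = np.zeros((n_genes, len(libs)), dtype=np.int64)
    for k, lib in enumerate(libs):
        mu = base.copy()
        if lib.startswith(conditions[0]):
            for gi, fc in fold_changes.items():
                mu[gi] *= fc
        p = r_nb / (r_nb + mu)
        data[:, k] = rng.negative_binomial(r_nb, p)
    counts = pd.DataFrame(data, index=lengths.index, columns=libs)
    lib_sizes = counts.sum(axis=0).rename("total_fragments")
    return counts, lib_sizes, lengths
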