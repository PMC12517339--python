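"""Model-faithful simulator: AR(1) latent-Gaussian genotype panels, Z-scores
drawn from the summary-statistic likelihood, annotation tracks with known
enrichment, and the perfect-LD mismatch scenario.

A single global seed fans out to per-region substreams through
``numpy.random.default_rng([seed, stream, region])`` so that changing the
region count never shifts the draws of earlier regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from bts.core_model import AnnotationMatrix, CausalConfig, RegionData, Variant
from bts.region_prep import GenotypeDosagePanel, compute_ld

__all__ = [
    "TrueEffects",
    "SimulatedDataset",
    "simulate_ld_panel",
    "simulate_zscores",
    "simulate_annotated_dataset",
    "make_mismatch_region",
]

TRUE_TRACK = "track_true"


@dataclass
class TrueEffects:
    """Ground truth for one simulated dataset."""

    causal: dict[str, tuple[int, ...]]
    lam: dict[str, np.ndarray]
    E: np.ndarray
    seed: int


@dataclass
class SimulatedDataset:
    """In-memory simulated dataset in the formats the model consumes."""

    regions: list[RegionData]
    annotations: list[AnnotationMatrix]
    tracks: dict[str, list[tuple[str, int, int]]]
    truth: TrueEffects
    panels: list[GenotypeDosagePanel] = field(default_factory=list)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ld_panel(
    n_variants: int,
    n_samples: int,
    rho: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed=0,
) -> tuple[GenotypeDosagePanel, np.ndarray]:
    """Diploid dosage panel from a latent AR(1) Gaussian.

    Haplotype alleles are thresholded at MAF-matched quantiles of the latent
    normal with correlation rho^|i-j|, then summed in pairs to dosages.
    Returns the panel and its empirical signed correlation matrix. A panel
    with a monomorphic column is redrawn up to 10 times.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = _rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    thresholds = norm.ppf(1.0 - mafs)
    for _ in range(10):
        latent = rng.standard_normal((2 * n_samples, n_variants))
        for j in range(1, n_variants):
            latent[:, j] = rho * latent[:, j - 1] + math.sqrt(1 - rho * rho) * latent[:, j]
        haps = (latent > thresholds).astype(float)
        dosages = haps[0::2] + haps[1::2]
        if np.all(dosages.std(axis=0) > 0.0):
            keys = [("chrSIM", 1 + 100 * j, "A", "G") for j in range(n_variants)]
            panel = GenotypeDosagePanel(dosages=dosages, keys=keys)
            return panel, compute_ld(panel)
    raise RuntimeError(
        "monomorphic column persisted over 10 panel draws; "
        "increase n_samples or the lower MAF bound"
    )


def _psd_factor(sigma: np.ndarray, max_shift: float = 1e-8) -> np.ndarray:
    """Square-root factor of sigma, clipping tiny negative eigenvalues."""
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < -max_shift:
        raise ValueError(
            f"sigma is not PSD (min eigenvalue {vals.min():.3g}); "
            "not repairable within the allowed shift"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_zscores(
    sigma: np.ndarray,
    config,
    lam=None,
    W: float = 1.0,
    seed=0,
) -> np.ndarray:
    """One Z-score draw from N(sigma @ (lam o c), sigma).

    ``lam`` may be a full-length vector, one value per causal index, a
    scalar shared by all causal indices, or None to draw each causal effect
    from N(0, W) (realizing the marginal likelihood's covariance
    sigma + W * sigma I_C sigma).
    """
    rng = _rng(seed)
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0]
    idx = list(config.indices if isinstance(config, CausalConfig) else config)
    if idx and (min(idx) < 0 or max(idx) >= n):
        raise IndexError(f"causal index out of range for n={n}")
    lam_full = np.zeros(n)
    if idx:
        if lam is None:
            lam_full[idx] = rng.normal(0.0, math.sqrt(W), size=len(idx))
        else:
            lam_arr = np.asarray(lam, dtype=float)
            if lam_arr.ndim == 0:
                lam_full[idx] = float(lam_arr)
            elif lam_arr.size == n:
                lam_full[idx] = lam_arr[idx]
            elif lam_arr.size == len(idx):
                lam_full[idx] = lam_arr
            else:
                raise ValueError(
                    f"lam has {lam_arr.size} entries; expected scalar, "
                    f"{len(idx)}, or {n}"
                )
    mean = sigma @ lam_full
    factor = _psd_factor(sigma)
    return mean + factor @ rng.standard_normal(n)


def simulate_annotated_dataset(
    n_regions: int,
    region_size: int = 20,
    true_E: tuple[float, float] = (-3.0, 2.0),
    rho: float = 0.5,
    W: float = 1.0,
    d: int = 2,
    n_decoys: int = 20,
    coverage: float = 0.2,
    n_samples: int = 400,
    variant_spacing: int = 1000,
    lam_magnitude: float | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Regions with one truly enriched annotation track and decoy tracks.

    Per region: a ~``coverage`` fraction of variants is covered by the true
    track; causal status is Bernoulli(logistic(E0 + E1 * A_i)), resampled
    until at most ``d`` variants are causal; true effects are N(0, W) at
    causal indices (or fixed magnitude ``lam_magnitude`` with random sign,
    for well-powered recovery experiments); Z-scores follow the
    summary-statistic likelihood under the region's empirical LD. Decoy
    tracks have the same coverage but no effect on causality.
    """
    E0, E1 = float(true_E[0]), float(true_E[1])
    n = region_size
    n_cov = max(1, round(coverage * n))
    p_in, p_out = expit(E0 + E1), expit(E0)
    expected = n_cov * p_in + (n - n_cov) * p_out
    if expected > 5 * d:
        raise ValueError(
            f"expected causal count {expected:.1f} exceeds 5*d={5 * d}; "
            "lower E0 (more negative baseline) or raise d"
        )

    track_names = [TRUE_TRACK] + [f"decoy_{j:02d}" for j in range(n_decoys)]
    tracks: dict[str, list[tuple[str, int, int]]] = {name: [] for name in track_names}
    regions: list[RegionData] = []
    annotations: list[AnnotationMatrix] = []
    panels: list[GenotypeDosagePanel] = []
    causal_truth: dict[str, tuple[int, ...]] = {}
    lam_truth: dict[str, np.ndarray] = {}

    for r in range(n_regions):
        rng = np.random.default_rng([seed, 1, r])
        panel, sigma = simulate_ld_panel(n, n_samples, rho, seed=rng)
        chrom = "chr1"
        base = 1 + r * 10_000_000
        positions = [base + i * variant_spacing for i in range(n)]
        region_id = f"sim{r:04d}"
        variants = [
            Variant(f"{region_id}_v{i}", chrom, positions[i], "A", "G")
            for i in range(n)
        ]

        overlap = np.zeros((n, 1 + n_decoys), dtype=np.int8)
        covered = rng.choice(n, size=n_cov, replace=False)
        overlap[covered, 0] = 1
        for j in range(n_decoys):
            overlap[rng.choice(n, size=n_cov, replace=False), j + 1] = 1
        for col, name in enumerate(track_names):
            for i in np.where(overlap[:, col])[0]:
                tracks[name].append((chrom, positions[i] - 1, positions[i]))

        prior = expit(E0 + E1 * overlap[:, 0])
        for _ in range(1000):
            causal = np.where(rng.random(n) < prior)[0]
            if causal.size <= d:
                break
        else:
            raise RuntimeError("could not draw <= d causal variants in 1000 tries")
        lam = np.zeros(n)
        if lam_magnitude is None:
            lam[causal] = rng.normal(0.0, math.sqrt(W), size=causal.size)
        else:
            lam[causal] = lam_magnitude * rng.choice([-1.0, 1.0], size=causal.size)
        z = simulate_zscores(sigma, tuple(causal), lam=lam, W=W, seed=rng)

        regions.append(RegionData(region_id, variants, z, sigma))
        annotations.append(AnnotationMatrix.from_overlaps(overlap, track_names))
        panels.append(
            GenotypeDosagePanel(
                dosages=panel.dosages,
                keys=[(chrom, positions[i], "A", "G") for i in range(n)],
            )
        )
        causal_truth[region_id] = tuple(int(i) for i in causal)
        lam_truth[region_id] = lam

    truth = TrueEffects(
        causal=causal_truth, lam=lam_truth, E=np.array([E0, E1]), seed=seed
    )
    return SimulatedDataset(
        regions=regions,
        annotations=annotations,
        tracks=tracks,
        truth=truth,
        panels=panels,
    )


def make_mismatch_region(
    a: float,
    b: float,
    seed: int = 0,
    n: int = 8,
    pair: tuple[int, int] = (5, 6),
    background_rho: float = 0.2,
    n_samples: int = 500,
) -> RegionData:
    """Small region embedding a perfectly correlated pair with Z = (a, b).

    Emulates meta-analysis LD mismatch: the pair shares a haplotype
    (r = 1) but carries very different evidence. All other variants are
    weakly correlated with null Z-scores.
    """
    i, j = pair
    if not (0 <= i < j < n):
        raise ValueError(f"pair {pair} invalid for n={n}")
    rng = np.random.default_rng([seed, 2, 0])
    panel, _ = simulate_ld_panel(n, n_samples, background_rho, seed=rng)
    dos = panel.dosages.copy()
    dos[:, j] = dos[:, i]  # duplicate haplotype member: exact r = 1
    sigma = compute_ld(GenotypeDosagePanel(dosages=dos, keys=panel.keys))
    z = simulate_zscores(sigma, (), W=1.0, seed=rng)
    z[i] = float(a)
    z[j] = float(b)
    variants = [
        Variant(f"mm_v{k}", "chr2", 1 + 1000 * k, "A", "G") for k in range(n)
    ]
    return RegionData(f"mismatch_{seed}", variants, z, sigma)
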