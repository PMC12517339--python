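"""Core Bayesian model: causal-configuration enumeration, Bayes factors,
logistic priors, and factored posterior computation.

For a region with Z-scores ``z`` and signed LD correlation matrix ``sigma``,
the Bayes factor of a causal configuration ``C`` against the all-null
configuration depends only on the sub-vector ``z1 = z[C]`` and sub-matrix
``sigma11 = sigma[C, C]``::

    log BF_C = -1/2 * logdet(I + W*sigma11) + (W/2) * z1' (I + W*sigma11)^-1 z1

The matrix ``I + W*sigma11`` is strictly positive definite for any
correlation matrix, so perfect-LD duplicates need no regularization.
Per-variant causal priors are logistic in the annotation design matrix, and
the marginal posterior of each variant is a normalized dot product between
the cached Bayes factors and the configuration priors.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logsumexp

__all__ = [
    "RegionData",
    "ModelConfig",
    "CausalConfig",
    "BayesFactorStore",
    "AnnotationMatrix",
    "EnrichmentCoefficients",
    "PosteriorSet",
    "enumerate_configurations",
    "count_configurations",
    "log_bayes_factor",
    "pairwise_mismatch_bf",
    "build_bf_store",
    "variant_prior",
    "config_log_prior",
    "config_log_priors",
    "variant_posteriors",
    "credible_set",
]

DEFAULT_ENUMERATION_CAP = 5_000_000

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Variant:
    """A single variant record (1-based position)."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class RegionData:
    """One analysis locus: variants, Z-scores, and signed LD matrix.

    ``z`` holds the effect of the alternative allele; ``ld`` is the signed
    Pearson correlation matrix in the same variant order.
    """

    region_id: str
    variants: list[Variant]
    z: np.ndarray
    ld: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.ld = np.asarray(self.ld, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.z)

    def validate(self) -> None:
        n = self.n
        if n < 1:
            raise ValueError(f"region {self.region_id}: needs >= 1 variant")
        if len(self.variants) != n:
            raise ValueError(
                f"region {self.region_id}: {len(self.variants)} variant records "
                f"but {n} z-scores"
            )
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"region {self.region_id}: non-finite z-scores")
        if self.ld.shape != (n, n):
            raise ValueError(
                f"region {self.region_id}: ld shape {self.ld.shape} != ({n}, {n})"
            )
        if not np.allclose(self.ld, self.ld.T, atol=1e-8):
            raise ValueError(f"region {self.region_id}: ld not symmetric")
        if not np.allclose(np.diag(self.ld), 1.0, atol=1e-6):
            raise ValueError(f"region {self.region_id}: ld diagonal not 1")
        if np.any(np.abs(self.ld) > 1.0 + 1e-8):
            raise ValueError(f"region {self.region_id}: |ld| entries exceed 1")


@dataclass
class ModelConfig:
    """Model hyper-parameters and reporting thresholds.

    ``W`` is the prior variance of true effect sizes (default 1, chosen to
    balance LD-mismatch sensitivity against null domination), ``d`` the
    maximum number of causal variants per configuration (default 2), and
    ``t`` the pruning threshold in orders of magnitude below the largest
    configuration likelihood (default 12).
    """

    W: float = 1.0
    d: int = 2
    t: float = 12.0
    credible_level: float = 0.9
    top_posterior_threshold: float = 0.5
    delta_flag_threshold: float = 0.2
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP

    def __post_init__(self) -> None:
        if self.W < 0:
            raise ValueError(f"W must be >= 0, got {self.W}")
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.d > 5:
            warnings.warn(
                f"d={self.d} exceeds the supported maximum of 5; "
                "runtime and memory grow steeply",
                stacklevel=2,
            )
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        if not 0.0 < self.credible_level <= 1.0:
            raise ValueError(
                f"credible_level must be in (0, 1], got {self.credible_level}"
            )


@dataclass(frozen=True, order=True)
class CausalConfig:
    """A putatively causal variant set: strictly increasing 0-based indices.

    The empty tuple is the null configuration.
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(self.indices)
        if list(idx) != sorted(set(idx)):
            raise ValueError(f"indices must be strictly increasing, got {idx}")
        if idx and idx[0] < 0:
            raise ValueError(f"negative index in {idx}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    @property
    def is_null(self) -> bool:
        return not self.indices


NULL_CONFIG = CausalConfig(())


class BayesFactorStore:
    """Immutable cache of log Bayes factors over enumerated configurations.

    Built once per region and shared across every annotation model and EM
    iteration. Pruning (when enabled) drops configurations whose Bayes
    factor is more than ``t`` orders of magnitude below the maximum; the
    null configuration is always retained so the posterior denominator
    stays proper.
    """

    def __init__(
        self,
        region_id: str,
        n: int,
        configs: Sequence[tuple[int, ...]],
        log_bf: np.ndarray,
        *,
        W: float,
        d: int,
        t: float,
        config_count_total: int,
        pruned: bool,
    ) -> None:
        self.region_id = region_id
        self.n = int(n)
        self.configs: tuple[tuple[int, ...], ...] = tuple(tuple(c) for c in configs)
        self.log_bf = np.asarray(log_bf, dtype=float)
        self.log_bf.setflags(write=False)
        self.W = float(W)
        self.d = int(d)
        self.t = float(t)
        self.config_count_total = int(config_count_total)
        self.pruned = bool(pruned)
        if self.configs[0] != ():
            raise ValueError("null configuration must come first")
        if self.log_bf[0] != 0.0:
            raise ValueError("null configuration must have log BF exactly 0")
        self.max_log_bf = float(self.log_bf.max())
        # flattened (variant index, config index) incidence for fast marginals
        sizes = np.fromiter((len(c) for c in self.configs), dtype=np.int64)
        self._flat_var = np.fromiter(
            (i for c in self.configs for i in c), dtype=np.int64, count=int(sizes.sum())
        )
        self._flat_cfg = np.repeat(np.arange(len(self.configs)), sizes)
        self._index = {c: i for i, c in enumerate(self.configs)}

    @property
    def config_count_retained(self) -> int:
        return len(self.configs)

    def log_bf_of(self, config: CausalConfig | tuple[int, ...]) -> float:
        key = tuple(config.indices if isinstance(config, CausalConfig) else config)
        return float(self.log_bf[self._index[key]])

    def __contains__(self, config) -> bool:
        key = tuple(config.indices if isinstance(config, CausalConfig) else config)
        return key in self._index

    def __len__(self) -> int:
        return len(self.configs)


@dataclass
class AnnotationMatrix:
    """Binary variant-by-annotation design matrix with an intercept column.

    Column 0 is identically one; columns 1..N_A are named annotation
    tracks (1 if the variant overlaps any interval of the track).
    """

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("annotation matrix must be 2-D")
        if self.matrix.shape[1] != 1 + len(self.names):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.names)} track names (+1 intercept expected)"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("annotation matrix entries must be 0/1")
        if not np.all(self.matrix[:, 0] == 1):
            raise ValueError("column 0 must be the all-ones intercept")
        self.names = tuple(self.names)

    @classmethod
    def from_overlaps(cls, overlaps: np.ndarray, names: Sequence[str]) -> "AnnotationMatrix":
        """Prepend the intercept column to a raw n x N_A overlap matrix."""
        overlaps = np.asarray(overlaps)
        if overlaps.ndim == 1:
            overlaps = overlaps[:, None]
        ones = np.ones((overlaps.shape[0], 1), dtype=overlaps.dtype)
        return cls(np.hstack([ones, overlaps]), tuple(names))

    @classmethod
    def intercept_only(cls, n: int) -> "AnnotationMatrix":
        return cls(np.ones((n, 1), dtype=np.int8), ())

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tracks(self) -> int:
        return len(self.names)

    def column_index(self, name: str) -> int:
        """0-based column index (intercept is column 0)."""
        return 1 + self.names.index(name)


@dataclass
class EnrichmentCoefficients:
    """Logistic enrichment coefficients aligned to AnnotationMatrix columns.

    Element 0 is the baseline (intercept) log-odds of causality.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("enrichment coefficients must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _coef_array(E) -> np.ndarray:
    if isinstance(E, EnrichmentCoefficients):
        return E.values
    return np.asarray(E, dtype=float).ravel()


@dataclass
class PosteriorSet:
    """Per-variant marginal causal posteriors for one region and context."""

    region_id: str
    context: str
    marginal: np.ndarray
    credible_set: list[int]
    credible_mass: float
    top_posterior: float
    log_relative_likelihood: float
    config_posterior: dict[tuple[int, ...], float] | None = None

    @property
    def n(self) -> int:
        return len(self.marginal)


# ---------------------------------------------------------------------------
# operations


def count_configurations(n: int, d: int) -> int:
    """Number of causal configurations of size <= d among n variants."""
    return sum(math.comb(n, l) for l in range(0, min(d, n) + 1))


def enumerate_configurations(
    n: int, d: int, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[CausalConfig]:
    """All causal configurations of size 0..d, null first, then by size and
    lexicographic order within each size (deterministic)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    total = count_configurations(n, d)
    if total > cap:
        raise ValueError(
            f"enumeration of {total} configurations (n={n}, d={d}) exceeds the "
            f"cap of {cap}; reduce d, split the region, or raise the cap "
            "explicitly if you have the memory"
        )
    out: list[CausalConfig] = []
    for size in range(0, min(d, n) + 1):
        for combo in itertools.combinations(range(n), size):
            out.append(CausalConfig(combo))
    return out


def log_bayes_factor(
    config: CausalConfig | Sequence[int], region: RegionData, W: float
) -> float:
    """log Bayes factor of a causal configuration against the null.

    Depends only on the configuration's Z sub-vector and LD sub-matrix;
    the null configuration returns exactly 0.
    """
    idx = list(config.indices if isinstance(config, CausalConfig) else config)
    if not idx:
        return 0.0
    if min(idx) < 0 or max(idx) >= region.n:
        raise IndexError(f"configuration {idx} out of range for n={region.n}")
    z1 = region.z[idx]
    s11 = region.ld[np.ix_(idx, idx)]
    return _log_bf_from_parts(z1, s11, W)


def _log_bf_from_parts(z1: np.ndarray, s11: np.ndarray, W: float) -> float:
    m = np.eye(len(z1)) + W * s11
    c, low = cho_factor(m, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = float(z1 @ cho_solve((c, low), z1))
    return -0.5 * logdet + 0.5 * W * quad


def pairwise_mismatch_bf(a: float, b: float, W: float) -> float:
    """Closed-form log Bayes factor of the both-causal configuration for two
    variants in perfect LD with Z-scores ``a`` and ``b``.

    The ``W*(a-b)**2`` term in the exponent is the spurious contribution of
    LD mismatch: for a true shared haplotype a == b and it vanishes.
    """
    if W < 0:
        raise ValueError(f"W must be >= 0, got {W}")
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("non-finite Z-scores")
    return -0.5 * math.log1p(2.0 * W) + (
        W / (2.0 * (1.0 + 2.0 * W))
    ) * ((a * a + b * b) + W * (a - b) ** 2)


def _all_log_bfs(region: RegionData, configs: list[CausalConfig], W: float) -> np.ndarray:
    """Log BFs for an enumerated configuration list (null first).

    Sizes 1 and 2 are closed-form and vectorized; larger sizes fall back to
    a Cholesky solve per configuration.
    """
    n = region.n
    z = region.z
    ld = region.ld
    out = np.empty(len(configs))
    sizes = np.fromiter((len(c) for c in configs), dtype=np.int64)

    # size 0
    (null_pos,) = np.where(sizes == 0)
    out[null_pos] = 0.0

    # size 1: M = 1 + W, scalar
    ones = np.where(sizes == 1)[0]
    if ones.size:
        i1 = np.fromiter((configs[k].indices[0] for k in ones), dtype=np.int64)
        out[ones] = -0.5 * math.log1p(W) + 0.5 * W * z[i1] ** 2 / (1.0 + W)

    # size 2: 2x2 closed form with unit-diagonal sigma11
    twos = np.where(sizes == 2)[0]
    if twos.size:
        ii = np.fromiter((configs[k].indices[0] for k in twos), dtype=np.int64)
        jj = np.fromiter((configs[k].indices[1] for k in twos), dtype=np.int64)
        r = ld[ii, jj]
        det = (1.0 + W) ** 2 - (W * r) ** 2
        quad = ((1.0 + W) * (z[ii] ** 2 + z[jj] ** 2) - 2.0 * W * r * z[ii] * z[jj]) / det
        out[twos] = -0.5 * np.log(det) + 0.5 * W * quad

    for k in np.where(sizes >= 3)[0]:
        idx = list(configs[k].indices)
        out[k] = _log_bf_from_parts(z[idx], ld[np.ix_(idx, idx)], W)
    return out


def build_bf_store(region: RegionData, params: ModelConfig) -> BayesFactorStore:
    """Enumerate all configurations up to size d and cache their log Bayes
    factors, pruning those more than ``t`` orders of magnitude below the
    maximum (the null configuration is always retained)."""
    configs = enumerate_configurations(region.n, params.d, cap=params.enumeration_cap)
    log_bf = _all_log_bfs(region, configs, params.W)
    total = len(configs)
    pruned = False
    if np.isfinite(params.t):
        cutoff = log_bf.max() - params.t * LN10
        keep = log_bf >= cutoff
        keep[0] = True  # null always retained
        if not keep.all():
            pruned = True
            configs = [c for c, k in zip(configs, keep) if k]
            log_bf = log_bf[keep]
    return BayesFactorStore(
        region_id=region.region_id,
        n=region.n,
        configs=[c.indices for c in configs],
        log_bf=log_bf,
        W=params.W,
        d=params.d,
        t=params.t,
        config_count_total=total,
        pruned=pruned,
    )


def variant_prior(annotation_row, E) -> float:
    """Logistic prior probability of causality for one variant."""
    row = np.asarray(annotation_row, dtype=float).ravel()
    coef = _coef_array(E)
    if row.shape != coef.shape:
        raise ValueError(f"row length {row.size} != coefficient length {coef.size}")
    return float(expit(row @ coef))


def region_priors(annotations: AnnotationMatrix, E) -> np.ndarray:
    """Per-variant logistic priors for a whole region."""
    coef = _coef_array(E)
    if annotations.matrix.shape[1] != coef.size:
        raise ValueError(
            f"annotation matrix has {annotations.matrix.shape[1]} columns, "
            f"E has {coef.size}"
        )
    return expit(annotations.matrix @ coef)


def _check_priors(priors: np.ndarray) -> np.ndarray:
    p = np.asarray(priors, dtype=float).ravel()
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("per-variant priors must lie strictly inside (0, 1)")
    return p


def config_log_prior(config: CausalConfig | Sequence[int], per_variant_priors) -> float:
    """Log prior of one configuration, computed incrementally from the cached
    null-configuration log prior with one O(1) update per causal index."""
    p = _check_priors(per_variant_priors)
    idx = list(config.indices if isinstance(config, CausalConfig) else config)
    log_p = np.log(p)
    log_1mp = np.log1p(-p)
    null_lp = float(log_1mp.sum())
    if not idx:
        return null_lp
    return null_lp + float((log_p[idx] - log_1mp[idx]).sum())


def _store_config_log_priors(store: BayesFactorStore, priors: np.ndarray) -> np.ndarray:
    log_p = np.log(priors)
    log_1mp = np.log1p(-priors)
    null_lp = log_1mp.sum()
    odds = log_p - log_1mp
    delta = np.bincount(
        store._flat_cfg, weights=odds[store._flat_var], minlength=len(store.configs)
    )
    return null_lp + delta


def config_log_priors(configs: Iterable, per_variant_priors) -> np.ndarray:
    """Vectorized log priors for a configuration collection."""
    p = _check_priors(per_variant_priors)
    return np.array([config_log_prior(c, p) for c in configs])


def variant_posteriors(
    store: BayesFactorStore,
    per_variant_priors,
    *,
    context: str = "null",
    credible_level: float = 0.9,
    keep_config_posteriors: bool = False,
) -> PosteriorSet:
    """Marginal causal posterior of each variant from cached Bayes factors.

    posterior(i) = sum_{C : i in C} BF_C * P(C) / sum_C BF_C * P(C), with the
    normalizer computed by log-sum-exp. Also records the region's log
    relative likelihood (the per-region factor of the total data
    likelihood). The store is never mutated.
    """
    p = _check_priors(per_variant_priors)
    if p.size != store.n:
        raise ValueError(f"got {p.size} priors for a region of {store.n} variants")
    log_prior = _store_config_log_priors(store, p)
    lw = store.log_bf + log_prior
    total = float(logsumexp(lw))
    w = np.exp(lw - total)
    marginal = np.bincount(
        store._flat_var, weights=w[store._flat_cfg], minlength=store.n
    )
    marginal = np.clip(marginal, 0.0, 1.0)
    cs, mass = credible_set(marginal, credible_level)
    cfg_post = None
    if keep_config_posteriors:
        cfg_post = {c: float(wi) for c, wi in zip(store.configs, w)}
    return PosteriorSet(
        region_id=store.region_id,
        context=context,
        marginal=marginal,
        credible_set=cs,
        credible_mass=mass,
        top_posterior=float(marginal.max()),
        log_relative_likelihood=total,
        config_posterior=cfg_post,
    )


def credible_set(posteriors, level: float = 0.9) -> tuple[list[int], float]:
    """Smallest set of variants holding >= ``level`` of the region's
    normalized marginal posterior mass.

    Variants are taken in order of decreasing marginal posterior (ties by
    genomic order); marginals are normalized by their within-region sum
    before cumulation. Returns (indices, achieved normalized mass).
    """
    if isinstance(posteriors, PosteriorSet):
        marg = posteriors.marginal
    else:
        marg = np.asarray(posteriors, dtype=float).ravel()
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must be in (0, 1], got {level}")
    total = marg.sum()
    if total <= 0.0:
        warnings.warn("all-zero posterior vector; credible set is empty", stacklevel=2)
        return [], 0.0
    order = np.argsort(-marg, kind="stable")
    cum = np.cumsum(marg[order]) / total
    k = int(np.searchsorted(cum, level - 1e-12) + 1)
    k = min(k, len(marg))
    return [int(i) for i in order[:k]], float(cum[k - 1])
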