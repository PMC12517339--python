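"""EM estimation of annotation enrichment coefficients across regions,
per-annotation scanning with likelihood-ratio tests, and comparison of
annotated posteriors against the annotation-free (null) model.

The E-step computes per-variant marginal causal posteriors from the cached
Bayes-factor stores under the current coefficients; the M-step is a weighted
Newton logistic regression of expected causal status on the selected
annotation columns. Because the configuration log-prior is additive in the
per-variant indicators, the M-step needs only the marginal posteriors and
the EM objective is exactly non-decreasing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import chi2

from bts.core_model import (
    AnnotationMatrix,
    BayesFactorStore,
    PosteriorSet,
    _store_config_log_priors,
    variant_posteriors,
)

__all__ = [
    "EMTrace",
    "AnnotationScanResult",
    "total_log_likelihood",
    "em_fit",
    "lrt_annotation",
    "scan_annotations",
    "delta_vs_null",
    "select_final_columns",
]

COEF_CAP = 20.0


@dataclass
class EMTrace:
    """Per-iteration log-likelihood record of one EM fit."""

    loglik: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    final_loglik: float = float("nan")


@dataclass
class AnnotationScanResult:
    """One row of the per-annotation scan."""

    track: str
    E: np.ndarray | None
    prior_odds: float
    loglik_null: float
    loglik_alt: float
    lrt_stat: float
    pvalue: float
    n_regions_overlapped: int
    n_prioritized_overlapped: int
    status: str  # "ok" | "skipped_no_overlap" | "failed: <reason>"


def _check_alignment(stores, matrices) -> None:
    if len(stores) != len(matrices):
        raise ValueError(f"{len(stores)} stores but {len(matrices)} annotation matrices")
    for s, m in zip(stores, matrices):
        if s.n != m.n_variants:
            raise ValueError(
                f"region {s.region_id}: store has {s.n} variants, "
                f"annotation matrix has {m.n_variants}"
            )


def _region_priors_sel(matrix: np.ndarray, columns, E: np.ndarray) -> np.ndarray:
    return expit(matrix[:, columns] @ E)


def total_log_likelihood(
    stores: list[BayesFactorStore],
    matrices: list[AnnotationMatrix],
    E,
    columns=None,
) -> float:
    """Total log relative likelihood: sum over regions of
    log sum_C BF_C * P(C | E, A).

    Constant per-region factors P(Z | C0) are omitted; they cancel in every
    likelihood-ratio test and EM update.
    """
    _check_alignment(stores, matrices)
    E = np.asarray(E, dtype=float).ravel()
    total = 0.0
    for store, ann in zip(stores, matrices):
        cols = columns if columns is not None else range(ann.matrix.shape[1])
        p = _region_priors_sel(ann.matrix, list(cols), E)
        lw = store.log_bf + _store_config_log_priors(store, p)
        total += float(logsumexp(lw))
    return total


def _m_step(
    X: np.ndarray,
    q: np.ndarray,
    E: np.ndarray,
    *,
    max_inner: int = 25,
    grad_tol: float = 1e-8,
) -> np.ndarray:
    """Weighted logistic regression of expected causal status q on X.

    Newton iterations with step halving so the expected complete-data
    log-likelihood never decreases; coefficients capped at +/- COEF_CAP
    against separation.
    """

    def objective(e):
        eta = X @ e
        # sum q*log(sigma) + (1-q)*log(1-sigma), numerically via logaddexp
        return float(-(np.logaddexp(0.0, -eta) @ q) - (np.logaddexp(0.0, eta) @ (1.0 - q)))

    E = E.copy()
    obj = objective(E)
    for _ in range(max_inner):
        p = expit(X @ E)
        g = X.T @ (q - p)
        if np.max(np.abs(g)) < grad_tol:
            break
        wdiag = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * wdiag[:, None]).T @ X
        H.flat[:: H.shape[0] + 1] += 1e-10
        step = np.linalg.solve(H, g)
        new_E = E + step
        new_obj = objective(np.clip(new_E, -COEF_CAP, COEF_CAP))
        halvings = 0
        while new_obj < obj - 1e-12 and halvings < 20:
            step *= 0.5
            new_E = E + step
            new_obj = objective(np.clip(new_E, -COEF_CAP, COEF_CAP))
            halvings += 1
        E = new_E
        if np.any(np.abs(E) > COEF_CAP):
            warnings.warn(
                "enrichment coefficient hit the separation cap of "
                f"+/-{COEF_CAP}; annotation may perfectly predict causal status",
                stacklevel=3,
            )
            E = np.clip(E, -COEF_CAP, COEF_CAP)
        obj = objective(E)
    return E


def em_fit(
    stores: list[BayesFactorStore],
    matrices: list[AnnotationMatrix],
    columns: list[int],
    init_E=None,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, EMTrace]:
    """Fit enrichment coefficients for the selected annotation columns by EM.

    ``columns`` indexes into the annotation matrices and must include the
    intercept column 0. Returns the coefficient vector aligned to
    ``columns`` and the iteration trace.
    """
    _check_alignment(stores, matrices)
    if not stores:
        raise ValueError("need at least one region")
    if 0 not in columns:
        raise ValueError("selected columns must include the intercept column 0")
    columns = list(columns)

    if init_E is None:
        median_n = float(np.median([s.n for s in stores]))
        E = np.zeros(len(columns))
        E[columns.index(0)] = _logit(1.0 / max(median_n, 2.0))
    else:
        E = np.asarray(init_E, dtype=float).ravel().copy()
        if E.size != len(columns):
            raise ValueError(f"init E has {E.size} entries for {len(columns)} columns")

    X = np.vstack([m.matrix[:, columns].astype(float) for m in matrices])
    trace = EMTrace()
    prev_ll = None
    for it in range(max_iter):
        ll = 0.0
        q_parts = []
        for store, ann in zip(stores, matrices):
            p = _region_priors_sel(ann.matrix, columns, E)
            post = variant_posteriors(store, p)
            ll += post.log_relative_likelihood
            q_parts.append(post.marginal)
        trace.loglik.append(ll)
        trace.iterations = it + 1
        if prev_ll is not None:
            if ll < prev_ll - 1e-6:
                raise RuntimeError(
                    f"EM log-likelihood decreased from {prev_ll:.9g} to {ll:.9g} "
                    f"at iteration {it}; this indicates a numerical problem"
                )
            if abs(ll - prev_ll) < tol:
                trace.converged = True
                break
        prev_ll = ll
        E = _m_step(X, np.concatenate(q_parts), E)

    trace.final_loglik = total_log_likelihood(stores, matrices, E, columns)
    return E, trace


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def lrt_annotation(loglik_with: float, loglik_without: float, df: int = 1) -> float:
    """Likelihood-ratio p-value for adding annotation coefficients.

    Upper tail of chi-square(df) at 2*(loglik_with - loglik_without),
    clamped at 0.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    delta = loglik_with - loglik_without
    if delta < -1e-6:
        raise ValueError(
            f"annotated log-likelihood is lower than the null by {-delta:.3g}; "
            "the EM fit likely failed to converge"
        )
    stat = max(0.0, 2.0 * delta)
    return float(chi2.sf(stat, df))


def scan_annotations(
    stores: list[BayesFactorStore],
    matrices: list[AnnotationMatrix],
    *,
    top_posterior_threshold: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[list[AnnotationScanResult], np.ndarray, float]:
    """Fit one single-annotation model per track against the shared
    intercept-only null model.

    Returns (results sorted by p-value, null-model intercept E0, null
    log-likelihood). Tracks overlapping no region are skipped; a failed fit
    marks the track as failed without aborting the scan.
    """
    _check_alignment(stores, matrices)
    names = matrices[0].names
    for m in matrices:
        if m.names != names:
            raise ValueError("annotation matrices disagree on track names/order")

    E_null, _ = em_fit(stores, matrices, [0], max_iter=max_iter, tol=tol)
    ll_null = total_log_likelihood(stores, matrices, E_null, [0])

    results: list[AnnotationScanResult] = []
    for j, name in enumerate(names, start=1):
        overlaps = [int(m.matrix[:, j].sum()) for m in matrices]
        n_regions_overlapped = sum(1 for o in overlaps if o > 0)
        if n_regions_overlapped == 0:
            results.append(
                AnnotationScanResult(
                    track=name,
                    E=None,
                    prior_odds=float("nan"),
                    loglik_null=ll_null,
                    loglik_alt=float("nan"),
                    lrt_stat=float("nan"),
                    pvalue=float("nan"),
                    n_regions_overlapped=0,
                    n_prioritized_overlapped=0,
                    status="skipped_no_overlap",
                )
            )
            continue
        try:
            init = np.array([E_null[0], 0.0])
            E_fit, _ = em_fit(
                stores, matrices, [0, j], init_E=init, max_iter=max_iter, tol=tol
            )
            ll_alt = total_log_likelihood(stores, matrices, E_fit, [0, j])
            pval = lrt_annotation(ll_alt, ll_null, df=1)
            n_prio = 0
            for store, ann, o in zip(stores, matrices, overlaps):
                if o == 0:
                    continue
                p = _region_priors_sel(ann.matrix, [0, j], E_fit)
                post = variant_posteriors(store, p)
                if post.top_posterior > top_posterior_threshold:
                    n_prio += 1
            results.append(
                AnnotationScanResult(
                    track=name,
                    E=E_fit,
                    prior_odds=float(np.exp(E_fit[1])),
                    loglik_null=ll_null,
                    loglik_alt=ll_alt,
                    lrt_stat=max(0.0, 2.0 * (ll_alt - ll_null)),
                    pvalue=pval,
                    n_regions_overlapped=n_regions_overlapped,
                    n_prioritized_overlapped=n_prio,
                    status="ok",
                )
            )
        except Exception as exc:  # noqa: BLE001 - a bad track must not kill the scan
            results.append(
                AnnotationScanResult(
                    track=name,
                    E=None,
                    prior_odds=float("nan"),
                    loglik_null=ll_null,
                    loglik_alt=float("nan"),
                    lrt_stat=float("nan"),
                    pvalue=float("nan"),
                    n_regions_overlapped=n_regions_overlapped,
                    n_prioritized_overlapped=0,
                    status=f"failed: {exc}",
                )
            )

    ok = sorted(
        (r for r in results if r.status == "ok"), key=lambda r: (r.pvalue, r.track)
    )
    rest = [r for r in results if r.status != "ok"]
    return ok + rest, E_null, ll_null


def delta_vs_null(
    posteriors_annotated: PosteriorSet,
    posteriors_null: PosteriorSet,
    threshold: float = 0.2,
) -> tuple[np.ndarray, bool]:
    """Per-variant posterior increase of an annotated model over the null
    model, and whether any variant gains at least ``threshold``."""
    if posteriors_annotated.region_id != posteriors_null.region_id:
        raise ValueError(
            f"region mismatch: {posteriors_annotated.region_id} vs "
            f"{posteriors_null.region_id}"
        )
    if posteriors_annotated.n != posteriors_null.n:
        raise ValueError("posterior sets have different variant counts")
    deltas = posteriors_annotated.marginal - posteriors_null.marginal
    return deltas, bool(np.any(deltas >= threshold))


def select_final_columns(
    results: list[AnnotationScanResult],
    matrices: list[AnnotationMatrix],
    *,
    k: int = 5,
    p_cut: float = 0.01,
) -> list[int]:
    """Columns (intercept + up to k significant tracks) for a joint refit."""
    names = matrices[0].names
    cols = [0]
    for r in results:
        if r.status == "ok" and r.pvalue < p_cut:
            cols.append(1 + names.index(r.track))
        if len(cols) >= 1 + k:
            break
    return cols
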