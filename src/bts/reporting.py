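"""End-to-end orchestration and tabular report generation.

``run_pipeline`` drives the full workflow: normalize summary statistics,
select tag variants by LD pruning, expand and regionize, build Bayes-factor
stores once, fit the annotation-free null model, scan every annotation
track, and emit the four report tables plus a JSON run summary. ``scan_bundles``
runs the model stages on prebuilt region bundles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from bts import bundle as bundle_io
from bts.core_model import (
    AnnotationMatrix,
    ModelConfig,
    PosteriorSet,
    RegionData,
    Variant,
    build_bf_store,
    variant_posteriors,
)
from bts.enrichment_em import AnnotationScanResult, delta_vs_null, scan_annotations
from bts.region_prep import (
    GenotypeDosagePanel,
    build_annotation_matrix,
    compute_ld,
    define_region,
    exclude_regions,
    ld_expand,
    ld_prune,
    merge_regions,
    normalize_sumstats,
    read_bed,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "scan_bundles", "write_reports"]

NULL_CONTEXT = "null"


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    sumstats: str | None = None
    panel: str | None = None
    bundle_dir: str | None = None
    tracks: str | None = None
    out_dir: str = "bts_out"
    model: ModelConfig = field(default_factory=ModelConfig)
    p_gwas: float = 5e-8
    r2: float = 0.7
    window: int = 1_000_000
    max_flank: int = 1000
    ann_p: float = 0.01
    exclusions: list[tuple[str, int, int]] = field(default_factory=list)
    min_prioritized_regions: int = 0  # optional report filter (display choice)
    seed: int = 0


def _load_panel(path: str) -> GenotypeDosagePanel:
    df = pd.read_csv(path, sep="\t")
    keys = []
    for col in df.columns:
        parts = str(col).split(":")
        if len(parts) != 4:
            raise ValueError(
                f"panel column {col!r} is not a chrom:pos:ref:alt variant key"
            )
        keys.append((parts[0], int(parts[1]), parts[2], parts[3]))
    return GenotypeDosagePanel(dosages=df.to_numpy(dtype=float), keys=keys)


def _load_tracks(manifest_path: str) -> dict[str, list[tuple[str, int, int]]]:
    manifest = bundle_io.read_track_manifest(manifest_path)
    tracks: dict[str, list[tuple[str, int, int]]] = {}
    for row in manifest.itertuples():
        bed = Path(row.path)
        if not bed.exists():
            raise FileNotFoundError(
                f"track {row.track_id!r}: BED file not found: {bed}"
            )
        tracks[str(row.label)] = read_bed(bed)
    return tracks


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run summary dict."""
    t0 = time.time()
    if config.bundle_dir is not None:
        return scan_bundles(config)
    if config.sumstats is None or config.panel is None:
        raise ValueError("run_pipeline needs sumstats + panel (or bundle_dir)")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _config_echo(config), "stages": {}}

    raw = pd.read_csv(config.sumstats, sep="\t", dtype={"chrom": str})
    sumstats, dropped = normalize_sumstats(raw)
    summary["stages"]["normalize"] = {
        "rows_in": len(raw),
        "rows_kept": len(sumstats),
        "rows_dropped": len(dropped),
    }

    panel = _load_panel(config.panel)
    key_to_col = {k: j for j, k in enumerate(panel.keys)}
    sumstats["key"] = list(
        zip(sumstats["chrom"], sumstats["pos"], sumstats["ref"], sumstats["alt"])
    )
    matched = sumstats[sumstats["key"].isin(key_to_col)].copy()
    matched = matched.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    summary["stages"]["panel_match"] = {
        "panel_variants": panel.n_variants,
        "matched_variants": len(matched),
    }
    if len(matched) == 0:
        logger.warning("no sumstats variant matches the genotype panel")

    intervals = []
    n_tags_total = 0
    for chrom, sub in matched.groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        cols = [key_to_col[k] for k in sub["key"]]
        dos = panel.dosages[:, cols]
        sd = dos.std(axis=0)
        keep = sd > 0.0
        if not keep.all():
            logger.info(
                "chr %s: dropping %d zero-variance panel variants", chrom, (~keep).sum()
            )
            sub = sub[keep].reset_index(drop=True)
            dos = dos[:, keep]
        if len(sub) == 0:
            continue
        sub_keys = [
            (str(c), int(p), str(rf), str(al))
            for c, p, rf, al in zip(sub["chrom"], sub["pos"], sub["ref"], sub["alt"])
        ]
        ld = compute_ld(GenotypeDosagePanel(dosages=dos, keys=sub_keys))
        pvals = sub["pvalue"].astype(float).to_numpy()
        tags = ld_prune(pvals, ld, config.p_gwas, config.r2)
        n_tags_total += len(tags)
        if not tags:
            continue
        candidates = ld_expand(tags, ld, config.r2)
        positions = sub["pos"].to_numpy()
        for tag in tags:
            tag_id = _variant_id(sub, tag)
            intervals.append(
                define_region(
                    tag,
                    candidates,
                    positions,
                    str(chrom),
                    ld,
                    tag_id,
                    config.r2,
                    config.window,
                    config.max_flank,
                )
            )
    merged = merge_regions(intervals)
    kept, excluded = exclude_regions(merged, config.exclusions)
    summary["stages"]["regions"] = {
        "tags": n_tags_total,
        "blocks": len(intervals),
        "merged_regions": len(merged),
        "excluded": len(excluded),
        "final": len(kept),
    }

    regions: list[RegionData] = []
    region_meta: list[dict] = []
    for iv in kept:
        sub = matched[
            (matched["chrom"] == iv.chrom)
            & (matched["pos"] >= iv.start)
            & (matched["pos"] <= iv.end)
        ].sort_values("pos", kind="stable")
        cols = [key_to_col[k] for k in sub["key"]]
        dos = panel.dosages[:, cols]
        keep_cols = dos.std(axis=0) > 0.0
        sub = sub[keep_cols]
        dos = dos[:, keep_cols.nonzero()[0]] if not keep_cols.all() else dos
        if len(sub) == 0:
            continue
        region_id = f"{iv.chrom}_{iv.start}_{iv.end}"
        variants = [
            Variant(_variant_id_row(r), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in sub.itertuples()
        ]
        sub_keys = [(v.chrom, v.pos, v.ref, v.alt) for v in variants]
        ld = compute_ld(GenotypeDosagePanel(dosages=dos, keys=sub_keys))
        regions.append(
            RegionData(region_id, variants, sub["z"].astype(float).to_numpy(), ld)
        )
        region_meta.append(
            {
                "region_id": region_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "n_variants": len(variants),
                "n_tags": len(iv.tags),
                "merged": iv.merged,
                "excluded_reason": "",
            }
        )
    for iv, reason in excluded:
        region_meta.append(
            {
                "region_id": f"{iv.chrom}_{iv.start}_{iv.end}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "n_variants": 0,
                "n_tags": len(iv.tags),
                "merged": iv.merged,
                "excluded_reason": reason,
            }
        )
    _write_regions_tsv(out_dir, region_meta)

    if not regions:
        logger.warning("no genome-wide significant regions; writing empty reports")
        write_reports(out_dir, [], [], {}, [], [], config)
        summary["stages"]["model"] = {"regions": 0}
        summary["runtime_sec"] = round(time.time() - t0, 3)
        _write_summary(out_dir, summary)
        return summary

    tracks = _load_tracks(config.tracks) if config.tracks else {}
    matrices = [build_annotation_matrix(reg.variants, tracks) for reg in regions]

    _model_stages(regions, matrices, config, out_dir, summary)
    summary["runtime_sec"] = round(time.time() - t0, 3)
    _write_summary(out_dir, summary)
    return summary


def scan_bundles(config: RunConfig) -> dict:
    """Run the model stages on prebuilt region bundles."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _config_echo(config), "stages": {}}
    ids = bundle_io.list_bundle_ids(config.bundle_dir)
    if not ids:
        raise FileNotFoundError(f"no region bundles (*.z.tsv) in {config.bundle_dir}")
    regions = []
    matrices = []
    for rid in ids:
        region, ann = bundle_io.read_region_bundle(config.bundle_dir, rid)
        if ann is None:
            ann = AnnotationMatrix.intercept_only(region.n)
        regions.append(region)
        matrices.append(ann)
    _write_regions_tsv(
        out_dir,
        [
            {
                "region_id": reg.region_id,
                "chrom": reg.variants[0].chrom,
                "start": reg.variants[0].pos,
                "end": reg.variants[-1].pos,
                "n_variants": reg.n,
                "n_tags": 0,
                "merged": False,
                "excluded_reason": "",
            }
            for reg in regions
        ],
    )
    _model_stages(regions, matrices, config, out_dir, summary)
    summary["runtime_sec"] = round(time.time() - t0, 3)
    _write_summary(out_dir, summary)
    return summary


def _model_stages(
    regions: list[RegionData],
    matrices: list[AnnotationMatrix],
    config: RunConfig,
    out_dir: Path,
    summary: dict,
) -> None:
    t_bf = time.time()
    stores = [build_bf_store(reg, config.model) for reg in regions]
    summary["stages"]["bf_stores"] = {
        "regions": len(stores),
        "configs_retained": int(sum(len(s) for s in stores)),
        "configs_total": int(sum(s.config_count_total for s in stores)),
        "seconds": round(time.time() - t_bf, 3),
    }

    t_scan = time.time()
    results, E_null, ll_null = scan_annotations(
        stores,
        matrices,
        top_posterior_threshold=config.model.top_posterior_threshold,
    )
    summary["stages"]["scan"] = {
        "tracks": len(results),
        "ok": sum(r.status == "ok" for r in results),
        "skipped": sum(r.status == "skipped_no_overlap" for r in results),
        "failed": sum(r.status.startswith("failed") for r in results),
        "seconds": round(time.time() - t_scan, 3),
    }

    null_posts = [
        variant_posteriors(
            s,
            region_priors_intercept(m, E_null[0]),
            context=NULL_CONTEXT,
            credible_level=config.model.credible_level,
        )
        for s, m in zip(stores, matrices)
    ]

    context_posts: dict[str, list[PosteriorSet]] = {}
    for r in results:
        if r.status != "ok" or not (r.pvalue < config.ann_p):
            continue
        j = 1 + matrices[0].names.index(r.track)
        posts = []
        for s, m in zip(stores, matrices):
            p = region_priors_sel(m, [0, j], r.E)
            posts.append(
                variant_posteriors(
                    s, p, context=r.track, credible_level=config.model.credible_level
                )
            )
        context_posts[r.track] = posts

    write_reports(out_dir, results, null_posts, context_posts, regions, matrices, config)
    summary["stages"]["reports"] = {
        "significant_tracks": len(context_posts),
    }


def region_priors_intercept(matrix: AnnotationMatrix, e0: float) -> np.ndarray:
    return region_priors_sel(matrix, [0], np.array([e0]))


def region_priors_sel(matrix: AnnotationMatrix, columns, E) -> np.ndarray:
    from scipy.special import expit

    return expit(matrix.matrix[:, list(columns)] @ np.asarray(E, dtype=float))


def _g6(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.6g}"


def write_reports(
    out_dir: str | Path,
    scan_results: list[AnnotationScanResult],
    null_posts: list[PosteriorSet],
    context_posts: dict[str, list[PosteriorSet]],
    regions: list[RegionData],
    matrices: list[AnnotationMatrix],
    config: RunConfig,
) -> None:
    """Emit annotations.tsv, region_by_context.tsv, variants.tsv, and
    credible_sets.tsv with stable ordering and 6-significant-digit floats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    merged_by_region = _read_merged_flags(out_dir)
    region_ids = {reg.region_id for reg in regions}

    if config.min_prioritized_regions > 0:
        shown = [
            r
            for r in scan_results
            if r.status != "ok"
            or r.n_prioritized_overlapped >= config.min_prioritized_regions
        ]
    else:
        shown = scan_results
    with open(out_dir / "annotations.tsv", "w") as fh:
        fh.write(
            "track\tE0\tE1\tprior_odds\tloglik_null\tloglik_alt\tlrt_stat\t"
            "pvalue\tn_regions_overlapped\tn_prioritized_overlapped\tstatus\n"
        )
        for r in shown:
            e0 = _g6(float(r.E[0])) if r.E is not None else "NA"
            e1 = _g6(float(r.E[1])) if r.E is not None and len(r.E) > 1 else "NA"
            fh.write(
                f"{r.track}\t{e0}\t{e1}\t{_g6(r.prior_odds)}\t{_g6(r.loglik_null)}\t"
                f"{_g6(r.loglik_alt)}\t{_g6(r.lrt_stat)}\t{_g6(r.pvalue)}\t"
                f"{r.n_regions_overlapped}\t{r.n_prioritized_overlapped}\t{r.status}\n"
            )

    contexts: list[tuple[str, list[PosteriorSet]]] = [(NULL_CONTEXT, null_posts)]
    contexts += sorted(context_posts.items())
    null_by_region = {p.region_id: p for p in null_posts}

    with open(out_dir / "region_by_context.tsv", "w") as fh:
        fh.write("region\tcontext\ttop_posterior\tdelta_flag\tmerged_flag\n")
        for context, posts in contexts:
            for post in posts:
                if post.top_posterior <= config.model.top_posterior_threshold:
                    continue
                if context == NULL_CONTEXT:
                    flag = False
                else:
                    _, flag = delta_vs_null(
                        post,
                        null_by_region[post.region_id],
                        config.model.delta_flag_threshold,
                    )
                assert post.region_id in region_ids, "unknown region in report"
                fh.write(
                    f"{post.region_id}\t{context}\t{_g6(post.top_posterior)}\t"
                    f"{flag}\t{merged_by_region.get(post.region_id, False)}\n"
                )

    mat_by_region = {
        reg.region_id: m for reg, m in zip(regions, matrices)
    }
    reg_by_id = {reg.region_id: reg for reg in regions}
    with open(out_dir / "variants.tsv", "w") as fh:
        fh.write(
            "region\tcontext\tvariant_id\tchrom\tpos\tposterior\tnull_posterior\t"
            "delta\tin_credible_set\toverlaps_context\n"
        )
        for context, posts in contexts:
            for post in posts:
                reg = reg_by_id[post.region_id]
                nullp = null_by_region[post.region_id]
                deltas = post.marginal - nullp.marginal
                cs = set(post.credible_set)
                mat = mat_by_region[post.region_id]
                if context == NULL_CONTEXT:
                    overlap_col = np.zeros(reg.n, dtype=int)
                else:
                    overlap_col = mat.matrix[:, mat.column_index(context)]
                for i, v in enumerate(reg.variants):
                    fh.write(
                        f"{post.region_id}\t{context}\t{v.variant_id}\t{v.chrom}\t"
                        f"{v.pos}\t{_g6(post.marginal[i])}\t{_g6(nullp.marginal[i])}\t"
                        f"{_g6(deltas[i])}\t{i in cs}\t{int(overlap_col[i])}\n"
                    )

    with open(out_dir / "credible_sets.tsv", "w") as fh:
        fh.write("region\tcontext\tlevel\tset_size\tmembers\tcumulative_mass\n")
        for context, posts in contexts:
            for post in posts:
                reg = reg_by_id[post.region_id]
                members = ",".join(reg.variants[i].variant_id for i in post.credible_set)
                fh.write(
                    f"{post.region_id}\t{context}\t{_g6(config.model.credible_level)}\t"
                    f"{len(post.credible_set)}\t{members}\t{_g6(post.credible_mass)}\n"
                )


def _write_regions_tsv(out_dir: Path, region_meta: list[dict]) -> None:
    cols = [
        "region_id",
        "chrom",
        "start",
        "end",
        "n_variants",
        "n_tags",
        "merged",
        "excluded_reason",
    ]
    df = pd.DataFrame(region_meta, columns=cols)
    df.to_csv(out_dir / "regions.tsv", sep="\t", index=False)


def _read_merged_flags(out_dir: Path) -> dict[str, bool]:
    path = out_dir / "regions.tsv"
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t")
    return {str(r.region_id): bool(r.merged) for r in df.itertuples()}


def _write_summary(out_dir: Path, summary: dict) -> None:
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["model"] = asdict(config.model)
    return echo


def _variant_id(sub: pd.DataFrame, i: int) -> str:
    row = sub.iloc[i]
    if "variant_id" in sub.columns and isinstance(row.get("variant_id"), str):
        return row["variant_id"]
    return f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"


def _variant_id_row(r) -> str:
    vid = getattr(r, "variant_id", None)
    if isinstance(vid, str) and vid:
        return vid
    return f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
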