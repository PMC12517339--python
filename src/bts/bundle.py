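"""On-disk interchange formats: per-region bundles (z / LD / annotation
TSVs), Bayes-factor store serialization, track manifests, and dataset
emission for the simulator.

A region bundle is a prefix with three files::

    <region>.z.tsv            variant_id chrom pos ref alt z
    <region>.ld.tsv           square tab-separated matrix, row order = z file
    <region>.annotations.tsv  binary matrix, header of track names

The intercept column is added in memory and never stored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from bts.core_model import AnnotationMatrix, BayesFactorStore, RegionData, Variant

__all__ = [
    "write_region_bundle",
    "read_region_bundle",
    "list_bundle_ids",
    "write_bf_store",
    "read_bf_store",
    "read_track_manifest",
    "write_dataset",
]

_FLOAT_FMT = "%.17g"  # full double precision for exact round-trips


def write_region_bundle(
    out_dir: str | Path,
    region: RegionData,
    annotations: AnnotationMatrix | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / region.region_id

    zdf = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in region.variants],
            "chrom": [v.chrom for v in region.variants],
            "pos": [v.pos for v in region.variants],
            "ref": [v.ref for v in region.variants],
            "alt": [v.alt for v in region.variants],
            "z": [_FLOAT_FMT % z for z in region.z],
        }
    )
    zdf.to_csv(f"{prefix}.z.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.ld.tsv", region.ld, fmt=_FLOAT_FMT, delimiter="\t")
    if annotations is not None and annotations.n_tracks > 0:
        ann = pd.DataFrame(annotations.matrix[:, 1:], columns=list(annotations.names))
        ann.to_csv(f"{prefix}.annotations.tsv", sep="\t", index=False)
    return prefix


def read_region_bundle(
    directory: str | Path, region_id: str
) -> tuple[RegionData, AnnotationMatrix | None]:
    prefix = Path(directory) / region_id
    zdf = pd.read_csv(
        f"{prefix}.z.tsv", sep="\t", dtype={"chrom": str}, float_precision="round_trip"
    )
    variants = [
        Variant(str(r.variant_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in zdf.itertuples()
    ]
    z = zdf["z"].astype(float).to_numpy()
    ld = np.loadtxt(f"{prefix}.ld.tsv", delimiter="\t", ndmin=2)
    region = RegionData(region_id, variants, z, ld)
    ann_path = Path(f"{prefix}.annotations.tsv")
    annotations = None
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t")
        annotations = AnnotationMatrix.from_overlaps(
            ann.to_numpy(dtype=np.int8), list(ann.columns)
        )
    return region, annotations


def list_bundle_ids(directory: str | Path) -> list[str]:
    """Region ids of all bundles in a directory, sorted."""
    return sorted(p.name[: -len(".z.tsv")] for p in Path(directory).glob("*.z.tsv"))


def write_bf_store(store: BayesFactorStore, prefix: str | Path) -> None:
    prefix = str(prefix)
    with open(f"{prefix}.bf.tsv", "w") as fh:
        fh.write("config_indices\tlog_bf\n")
        for cfg, lbf in zip(store.configs, store.log_bf):
            fh.write(",".join(map(str, cfg)) + "\t" + _FLOAT_FMT % lbf + "\n")
    meta = {
        "region_id": store.region_id,
        "n": store.n,
        "d": store.d,
        "t": store.t if np.isfinite(store.t) else None,
        "W": store.W,
        "max_log_bf": store.max_log_bf,
        "pruned": store.pruned,
        "config_count_total": store.config_count_total,
    }
    with open(f"{prefix}.bf.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_bf_store(prefix: str | Path) -> BayesFactorStore:
    prefix = str(prefix)
    with open(f"{prefix}.bf.json") as fh:
        meta = json.load(fh)
    configs: list[tuple[int, ...]] = []
    log_bf: list[float] = []
    with open(f"{prefix}.bf.tsv") as fh:
        header = fh.readline()
        if not header.startswith("config_indices"):
            raise ValueError(f"{prefix}.bf.tsv: unexpected header")
        for line in fh:
            idx_s, lbf_s = line.rstrip("\n").split("\t")
            configs.append(
                tuple(int(x) for x in idx_s.split(",")) if idx_s else ()
            )
            log_bf.append(float(lbf_s))
    return BayesFactorStore(
        region_id=meta["region_id"],
        n=meta["n"],
        configs=configs,
        log_bf=np.array(log_bf),
        W=meta["W"],
        d=meta["d"],
        t=float("inf") if meta["t"] is None else meta["t"],
        config_count_total=meta["config_count_total"],
        pruned=meta["pruned"],
    )


def read_track_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV mapping track_id -> BED path -> label. Paths are
    resolved relative to the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"track_id", "path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"track manifest must have columns {sorted(required)}")
    df["path"] = [
        str((path.parent / p)) if not Path(p).is_absolute() else p for p in df["path"]
    ]
    return df


def write_dataset(dataset, out_dir: str | Path) -> Path:
    """Write a SimulatedDataset as pipeline-ready inputs plus model-ready
    bundles: region bundles, per-track BED files + manifest, truth JSON,
    and sumstats/panel TSVs consumable by the end-to-end pipeline."""
    out_dir = Path(out_dir)
    bundles = out_dir / "bundles"
    beds = out_dir / "tracks"
    bundles.mkdir(parents=True, exist_ok=True)
    beds.mkdir(parents=True, exist_ok=True)

    for region, ann in zip(dataset.regions, dataset.annotations):
        write_region_bundle(bundles, region, ann)

    manifest_rows = []
    for name, intervals in dataset.tracks.items():
        bed_path = beds / f"{name}.bed"
        with open(bed_path, "w") as fh:
            for chrom, start, end in sorted(intervals):
                fh.write(f"{chrom}\t{start}\t{end}\n")
        manifest_rows.append({"track_id": name, "path": f"tracks/{name}.bed", "label": name})
    pd.DataFrame(manifest_rows).to_csv(out_dir / "tracks.manifest.tsv", sep="\t", index=False)

    truth = {
        "E": [float(x) for x in dataset.truth.E],
        "seed": dataset.truth.seed,
        "causal": {k: list(v) for k, v in dataset.truth.causal.items()},
        "lam": {k: [float(x) for x in v] for k, v in dataset.truth.lam.items()},
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    # pipeline-style inputs
    rows = []
    for region in dataset.regions:
        pvals = 2.0 * norm.sf(np.abs(region.z))
        for v, z, p in zip(region.variants, region.z, pvals):
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "effect_allele": v.alt,
                    "z": _FLOAT_FMT % z,
                    "pvalue": _FLOAT_FMT % max(p, 5e-324),
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "sumstats.tsv", sep="\t", index=False)

    if dataset.panels:
        cols = {}
        n_samples = min(p.n_samples for p in dataset.panels)
        for panel in dataset.panels:
            for j, (chrom, pos, ref, alt) in enumerate(panel.keys):
                cols[f"{chrom}:{pos}:{ref}:{alt}"] = panel.dosages[:n_samples, j]
        pd.DataFrame(cols).to_csv(
            out_dir / "panel.tsv", sep="\t", index=False, float_format="%.0f"
        )
    return out_dir
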