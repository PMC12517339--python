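"""Summary-statistics preprocessing: allele normalization, LD computation
from a genotype dosage panel, greedy LD pruning of genome-wide-significant
variants, LD expansion, block construction/merging, exclusion regions, and
annotation-overlap matrix construction.

Genomic coordinates are 1-based inclusive internally; BED input is 0-based
half-open. LD is the signed Pearson correlation r; r-squared thresholds
apply to its square.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from bts.core_model import AnnotationMatrix, Variant

__all__ = [
    "GenotypeDosagePanel",
    "RegionInterval",
    "normalize_sumstats",
    "compute_ld",
    "ld_prune",
    "ld_expand",
    "define_region",
    "merge_regions",
    "exclude_regions",
    "read_bed",
    "build_annotation_matrix",
    "DEFAULT_EXCLUSIONS",
]

logger = logging.getLogger(__name__)

P_GWAS_DEFAULT = 5e-8
R2_DEFAULT = 0.7
WINDOW_DEFAULT = 1_000_000
MAX_FLANK_DEFAULT = 1000

# HLA region, GRCh37 chr6:25-34 Mbp; configurable, shipped as data not code.
DEFAULT_EXCLUSIONS = [("chr6", 25_000_000, 34_000_000), ("6", 25_000_000, 34_000_000)]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeDosagePanel:
    """Samples-by-variants matrix of alt-allele dosages in [0, 2]."""

    dosages: np.ndarray
    keys: list[tuple[str, int, str, str]]  # (chrom, pos, ref, alt)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.keys):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.keys)} keys"
            )
        if np.any(self.dosages < -1e-9) or np.any(self.dosages > 2.0 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class RegionInterval:
    """A candidate analysis region (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    tags: list[str] = field(default_factory=list)
    merged: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "effect_allele", "pvalue")


def normalize_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize summary statistics so z reflects the alt-allele effect.

    Accepts either beta+se or z columns. Rows whose effect allele matches
    neither ref nor alt, or with se <= 0, are dropped with a logged reason.
    Strand-ambiguous (A/T, C/G) variants are kept but flagged. Duplicate
    (chrom, pos, ref, alt) keys are an input error.

    Returns (normalized frame with a ``z`` column, dropped rows with a
    ``drop_reason`` column).
    """
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sumstats missing required columns: {missing}")
    has_beta = "beta" in df.columns and "se" in df.columns
    has_z = "z" in df.columns
    if not (has_beta or has_z):
        raise ValueError("sumstats must provide either (beta, se) or z")

    for col in ("ref", "alt", "effect_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)

    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["chrom", "pos", "ref", "alt"]].drop_duplicates()
        raise ValueError(
            f"duplicate variant keys in sumstats (first: "
            f"{keys.iloc[0].tolist()}); deduplicate the input"
        )

    reasons = pd.Series("", index=df.index)
    bad_allele = (df["effect_allele"] != df["ref"]) & (df["effect_allele"] != df["alt"])
    reasons[bad_allele] = "allele mismatch"
    if has_beta and not has_z:
        bad_se = pd.to_numeric(df["se"], errors="coerce") <= 0
        bad_se |= df["se"].isna()
        reasons[bad_se & (reasons == "")] = "nonpositive se"

    dropped = df[reasons != ""].copy()
    dropped["drop_reason"] = reasons[reasons != ""]
    for _, row in dropped.iterrows():
        logger.info(
            "dropping %s:%s %s>%s: %s",
            row["chrom"], row["pos"], row["ref"], row["alt"], row["drop_reason"],
        )
    df = df[reasons == ""].copy()

    if has_z:
        z = pd.to_numeric(df["z"], errors="coerce")
    else:
        z = pd.to_numeric(df["beta"], errors="coerce") / pd.to_numeric(
            df["se"], errors="coerce"
        )
    flip = df["effect_allele"] == df["ref"]
    z = z.where(~flip, -z)
    df["z"] = z
    df["strand_ambiguous"] = [
        (r, a) in _AMBIGUOUS_PAIRS for r, a in zip(df["ref"], df["alt"])
    ]
    n_amb = int(df["strand_ambiguous"].sum())
    if n_amb:
        logger.info("%d strand-ambiguous (A/T, C/G) variants kept and flagged", n_amb)
    return df.reset_index(drop=True), dropped.reset_index(drop=True)


def compute_ld(panel: GenotypeDosagePanel) -> np.ndarray:
    """Signed Pearson correlation matrix of the panel's dosage columns."""
    if panel.n_samples < 2:
        raise ValueError("need >= 2 samples to compute LD")
    sd = panel.dosages.std(axis=0)
    zero = np.where(sd == 0.0)[0]
    if zero.size:
        key = panel.keys[zero[0]]
        raise ValueError(
            f"zero-variance (monomorphic) variant in panel: "
            f"{key[0]}:{key[1]} {key[2]}>{key[3]}"
        )
    r = np.corrcoef(panel.dosages, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def ld_prune(
    pvalues: Sequence[float],
    ld: np.ndarray,
    p_threshold: float = P_GWAS_DEFAULT,
    r2_threshold: float = R2_DEFAULT,
) -> list[int]:
    """Greedy selection of pairwise-independent tag variants.

    Significant variants (p < p_threshold) are visited in order of ascending
    p-value (ties by genomic order); each selected tag removes all remaining
    variants with r^2 > r2_threshold to it. The returned tags satisfy
    pairwise r^2 <= r2_threshold.
    """
    p = np.asarray(pvalues, dtype=float)
    sig = np.where(p < p_threshold)[0]
    if sig.size == 0:
        return []
    order = sig[np.lexsort((sig, p[sig]))]
    remaining = list(order)
    tags: list[int] = []
    while remaining:
        tag = remaining.pop(0)
        tags.append(tag)
        r2_to_tag = ld[tag, remaining] ** 2
        remaining = [v for v, r2 in zip(remaining, r2_to_tag) if r2 <= r2_threshold]
    # invariant: tags are pairwise independent
    if len(tags) > 1:
        sub = ld[np.ix_(tags, tags)] ** 2
        np.fill_diagonal(sub, 0.0)
        assert np.all(sub <= r2_threshold + 1e-12), "pruning left correlated tags"
    return tags


def ld_expand(
    tags: Sequence[int],
    ld: np.ndarray,
    r2_threshold: float = R2_DEFAULT,
) -> list[int]:
    """Candidate set: every variant with r^2 > threshold to some tag, plus
    the tags themselves. Sorted, unique."""
    out: set[int] = set(int(t) for t in tags)
    for t in tags:
        linked = np.where(ld[t] ** 2 > r2_threshold)[0]
        out.update(int(v) for v in linked)
    return sorted(out)


def define_region(
    tag: int,
    candidates: Sequence[int],
    positions: Sequence[int],
    chrom: str,
    ld: np.ndarray,
    tag_id: str,
    r2_threshold: float = R2_DEFAULT,
    window: int = WINDOW_DEFAULT,
    max_flank_variants: int = MAX_FLANK_DEFAULT,
) -> RegionInterval:
    """LD block of one tag variant.

    Bounds sit at the leftmost/rightmost candidate linked to the tag
    (r^2 > threshold), restricted to within ``window`` bp of the tag and to
    at most ``max_flank_variants`` variants between the boundary variant and
    the tag. ``positions`` covers all variants on the chromosome in
    ascending order; indices refer to that order.
    """
    if tag not in set(candidates):
        raise ValueError("tag must be among the candidates")
    pos = np.asarray(positions)
    tag_pos = int(pos[tag])
    left = tag
    right = tag
    for v in candidates:
        if ld[tag, v] ** 2 <= r2_threshold and v != tag:
            continue
        if abs(int(pos[v]) - tag_pos) > window:
            continue
        between = abs(v - tag) - 1  # variants strictly between v and the tag
        if between > max_flank_variants:
            continue
        left = min(left, v)
        right = max(right, v)
    return RegionInterval(
        chrom=chrom, start=int(pos[left]), end=int(pos[right]), tags=[tag_id]
    )


def merge_regions(intervals: list[RegionInterval]) -> list[RegionInterval]:
    """Merge strictly overlapping intervals per chromosome.

    Touching-but-not-overlapping intervals (end + 1 == next start, 1-based
    inclusive) are not merged. The merged flag is set when >= 2 inputs
    contributed.
    """
    out: list[RegionInterval] = []
    by_chrom: dict[str, list[RegionInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur = RegionInterval(
            chrom, ivs[0].start, ivs[0].end, list(ivs[0].tags), ivs[0].merged
        )
        count = 1
        for iv in ivs[1:]:
            if iv.start <= cur.end:  # strict overlap under 1-based inclusive
                cur.end = max(cur.end, iv.end)
                cur.tags.extend(iv.tags)
                count += 1
            else:
                cur.merged = cur.merged or count > 1
                out.append(cur)
                cur = RegionInterval(chrom, iv.start, iv.end, list(iv.tags), iv.merged)
                count = 1
        cur.merged = cur.merged or count > 1
        out.append(cur)
    return out


def exclude_regions(
    intervals: list[RegionInterval],
    exclusions: Sequence[tuple[str, int, int]],
) -> tuple[list[RegionInterval], list[tuple[RegionInterval, str]]]:
    """Drop regions overlapping any exclusion interval.

    Returns (kept, [(dropped region, reason), ...]).
    """
    kept: list[RegionInterval] = []
    dropped: list[tuple[RegionInterval, str]] = []
    for iv in intervals:
        hit = None
        for chrom, start, end in exclusions:
            if iv.overlaps(str(chrom), int(start), int(end)):
                hit = (chrom, start, end)
                break
        if hit is None:
            kept.append(iv)
        else:
            reason = f"overlaps exclusion {hit[0]}:{hit[1]}-{hit[2]}"
            logger.info("excluding region %s:%d-%d: %s", iv.chrom, iv.start, iv.end, reason)
            dropped.append((iv, reason))
    return kept, dropped


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Parse a BED3(+) file into (chrom, start, end) with 0-based half-open
    coordinates. Malformed lines raise with their line number."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            intervals.append((parts[0], start, end))
    return intervals


def build_annotation_matrix(
    variants: Sequence[Variant],
    tracks: dict[str, list[tuple[str, int, int]]],
) -> AnnotationMatrix:
    """Binary overlap matrix: entry 1 iff the variant's 0-based position
    falls in [start, end) of any interval of the track. The intercept column
    is prepended."""
    n = len(variants)
    names = list(tracks)
    overlaps = np.zeros((n, len(names)), dtype=np.int8)
    for j, name in enumerate(names):
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, start, end in _merge_half_open(tracks[name]):
            starts, ends = by_chrom.setdefault(chrom, ([], []))
            starts.append(start)
            ends.append(end)
        for i, v in enumerate(variants):
            if v.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[v.chrom]
            p0 = v.pos - 1  # 1-based variant -> 0-based coordinate
            k = bisect_right(starts, p0) - 1
            if k >= 0 and p0 < ends[k]:
                overlaps[i, j] = 1
    return AnnotationMatrix.from_overlaps(overlaps, names)


def _merge_half_open(
    intervals: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent half-open intervals so bisect lookup works."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        out.append((chrom, cs, ce))
    return out
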