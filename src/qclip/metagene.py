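"""Anchor-centered coverage profiles with bootstrap confidence ribbons.

Builds per-base read-depth coverage from stranded BED intervals, extracts
fixed-width windows around anchor positions (stop codons, PAS, QBMs or
peaks) in transcript orientation, normalizes to depth per 10^7 reads, and
summarizes anchors with a column-wise mean plus a percentile bootstrap
confidence interval over anchor resamples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome_model import GenomeBuild

logger = logging.getLogger(__name__)


class MetageneError(ValueError):
    pass


def build_coverage(
    bed: pd.DataFrame, build: GenomeBuild, stranded: bool = True
) -> dict[tuple[str, str], np.ndarray]:
    """Per-base read depth from BED intervals, keyed by (chrom, strand).

    With ``stranded=False`` both strand keys view the combined depth.
    """
    cov: dict[tuple[str, str], np.ndarray] = {}
    strands = ("+", "-") if stranded else ("*",)
    for chrom, length in build.chrom_lengths.items():
        for s in strands:
            cov[(chrom, s)] = np.zeros(length + 1, dtype=np.float64)
    for (chrom, strand), sub in bed.groupby(["chrom", "strand"], sort=False):
        key = (chrom, strand if stranded else "*")
        if key not in cov:
            logger.warning("coverage: unknown chromosome %s skipped", chrom)
            continue
        arr = cov[key]
        starts = np.clip(sub["start"].to_numpy(), 0, arr.size - 1)
        ends = np.clip(sub["end"].to_numpy(), 0, arr.size - 1)
        np.add.at(arr, starts, 1.0)
        np.add.at(arr, ends, -1.0)
    out = {key: np.cumsum(arr)[:-1] for key, arr in cov.items()}
    if not stranded:
        return {
            (chrom, s): depth
            for (chrom, _), depth in out.items()
            for s in ("+", "-")
        }
    return out


def normalize_coverage(
    cov: dict, library_size: int, per: float = 1e7
) -> dict:
    """Scale depth to reads-per-``per`` (default 10^7) for cross-library
    comparability; applied before any bootstrapping."""
    if library_size <= 0:
        raise MetageneError("library size must be positive")
    f = per / library_size
    return {k: v * f for k, v in cov.items()}


def extract_anchor_matrix(
    anchors: pd.DataFrame,
    cov: dict[tuple[str, str], np.ndarray],
    half_width: int = 500,
) -> np.ndarray:
    """Anchor x offset depth matrix, offsets -half_width .. half_width-1 in
    transcript orientation (positive offsets 3' of the anchor).

    ``anchors``: rows with chrom, pos, strand.  Anchors within half_width
    of a chromosome end are dropped with a warning.  '-' strand rows are
    reversed so that offset +k reads genomic position anchor - k.
    """
    if len(anchors) == 0:
        raise MetageneError("empty anchor set")
    rows, dropped = [], 0
    for a in anchors.itertuples(index=False):
        key = (a.chrom, a.strand)
        if key not in cov:
            dropped += 1
            continue
        depth = cov[key]
        pos = int(a.pos)
        if pos - half_width < 0 or pos + half_width > depth.size:
            dropped += 1
            continue
        if a.strand == "+":
            rows.append(depth[pos - half_width : pos + half_width])
        else:
            # offset +k -> genomic pos - k: slice (pos+hw, pos-hw] reversed
            rows.append(depth[pos - half_width + 1 : pos + half_width + 1][::-1])
    if dropped:
        logger.warning("extract_anchor_matrix: %d anchors dropped "
                       "(edge or unknown chromosome)", dropped)
    if not rows:
        raise MetageneError("no usable anchors after edge filtering")
    return np.vstack(rows)


def bootstrap_profile(
    matrix: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Column-wise mean with a percentile bootstrap CI over anchor rows.

    Returns offset, mean, ci_lo, ci_hi (offsets centered on the anchor).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise MetageneError("bootstrap CI undefined for a single anchor")
    rng = np.random.default_rng(seed)
    mean = matrix.mean(axis=0)
    boots = np.empty((n_boot, matrix.shape[1]))
    chunk = max(1, int(2e7 // (n * matrix.shape[1])))  # bound peak memory
    for lo in range(0, n_boot, chunk):
        hi = min(lo + chunk, n_boot)
        idx = rng.integers(0, n, size=(hi - lo, n))
        boots[lo:hi] = matrix[idx].mean(axis=1)
    a = (1.0 - level) / 2.0
    ci_lo = np.quantile(boots, a, axis=0)
    ci_hi = np.quantile(boots, 1.0 - a, axis=0)
    half = matrix.shape[1] // 2
    return pd.DataFrame({
        "offset": np.arange(-half, matrix.shape[1] - half),
        "mean": mean, "ci_lo": ci_lo, "ci_hi": ci_hi,
    })


def metagene_profiles(
    beds: dict[str, pd.DataFrame],
    roles: dict[str, str],
    anchors: pd.DataFrame,
    build: GenomeBuild,
    half_width: int = 500,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized bootstrap profiles per sample role (clip/igg/input),
    averaging coverage across samples sharing a role.  Returns a long frame
    with group, offset, mean, ci_lo, ci_hi, n_anchors."""
    frames = []
    by_role: dict[str, list[str]] = {}
    for name, role in roles.items():
        by_role.setdefault(role, []).append(name)
    for role, names in by_role.items():
        total = None
        for name in names:
            bed = beds[name]
            cov = build_coverage(bed, build)
            cov = normalize_coverage(cov, max(len(bed), 1))
            if total is None:
                total = cov
            else:
                total = {k: total[k] + cov[k] for k in total}
        total = {k: v / len(names) for k, v in total.items()}
        mat = extract_anchor_matrix(anchors, total, half_width)
        prof = bootstrap_profile(mat, n_boot=n_boot, level=level, seed=seed)
        prof.insert(0, "group", role)
        prof["n_anchors"] = mat.shape[0]
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)
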