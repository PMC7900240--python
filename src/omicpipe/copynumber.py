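"""Array copy-number segmentation and gene-level summaries.

Probe-level log2 intensity ratios are partitioned into constant-mean
segments by circular binary segmentation (CBS): the maximal t-like
statistic over all circular arcs of a chromosome's probe vector is
tested against a permutation null, and significant arcs split the
segment recursively. Segment means sit on the log2(copy-number/2) scale,
so diploid regions are at 0, a single-copy gain at 1, a single-copy loss
at -1.

Two probe-masking modes mirror the regular vs masked segment outputs:
the regular mode only drops pseudo-autosomal (PAR) probes in males (X/Y
homology would otherwise double-count them); the masked mode further
drops chromosome-Y probes and probes inside known germline copy-number
variant regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "segment_mean_from_cn",
    "cbs_segment",
    "mask_probes",
    "gene_level_cnv",
]


@dataclass(frozen=True)
class Segment:
    """A constant-copy-number region: 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    num_probes: int
    segment_mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.num_probes < 1:
            raise ValueError("segment must contain at least one probe")


def segment_mean_from_cn(copy_number: float) -> float:
    """log2(copy_number / 2): 0 at diploid, positive for gains."""
    if copy_number <= 0:
        raise ValueError("copy number must be positive")
    return math.log2(copy_number / 2.0)


def _max_arc_tstat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t|-like statistic over circular arcs of ``x``.

    An arc is the index range (i, j]; its mean is compared with the mean
    of its complement, scaled by sqrt(1/k + 1/(n-k)). Returns
    (statistic, i, j). Arcs narrower than ``min_width`` on either side
    are excluded. Constant input returns statistic 0.
    """
    n = x.size
    s = np.concatenate(([0.0], np.cumsum(x)))
    total = s[-1]
    var = float(np.var(x))
    if var <= 1e-24 or n < 2 * min_width:
        return 0.0, 0, n
    i = np.arange(n + 1)
    # k[a, b] = b - a, arc (a, b]
    diff = s[None, :] - s[:, None]          # arc sums
    k = i[None, :] - i[:, None]             # arc lengths
    valid = (k >= min_width) & ((n - k) >= min_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = diff / k
        mean2 = (total - diff) / (n - k)
        t = np.abs(mean1 - mean2) / np.sqrt(var * (1.0 / k + 1.0 / (n - k)))
    t = np.where(valid, t, -np.inf)
    flat = int(np.argmax(t))
    a, b = divmod(flat, n + 1)
    return float(t[a, b]), int(a), int(b)


def _permutation_pvalue(
    x: np.ndarray,
    observed: float,
    min_width: int,
    n_permutations: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value of the max arc statistic, with early stop.

    Stops as soon as the exceedance count guarantees p >= alpha, which
    cannot change the accept/reject decision.
    """
    limit = math.floor(alpha * (n_permutations + 1))
    exceed = 0
    for b in range(n_permutations):
        perm = rng.permutation(x)
        stat, _, _ = _max_arc_tstat(perm, min_width)
        if stat >= observed:
            exceed += 1
            if exceed > limit:
                break
    return (1 + exceed) / (1 + n_permutations)


def _segment_indices(
    x: np.ndarray,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive CBS on a value vector; returns sorted interior changepoints."""
    n = x.size
    if n < 2 * min_width:
        return []
    stat, i, j = _max_arc_tstat(x, min_width)
    if stat <= 0:
        return []
    p = _permutation_pvalue(x, stat, min_width, n_permutations, alpha, rng)
    if p >= alpha:
        return []
    cps = sorted({c for c in (i, j) if 0 < c < n})
    if not cps:
        return []
    out: list[int] = []
    bounds = [0] + cps + [n]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out.extend(lo + c for c in _segment_indices(x[lo:hi], alpha, n_permutations, min_width, rng))
    return sorted(set(out) | set(cps))


def cbs_segment(
    series: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> list[Segment]:
    """Circular binary segmentation of a probe series.

    Parameters
    ----------
    series
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``value``
        (log2 ratio), sorted by (chrom, pos) within each chromosome.
    alpha
        Permutation significance level for accepting a split.
    n_permutations
        Permutations per split test.
    min_width
        Minimum probes per segment.
    seed
        Seed for the permutation stream.

    Returns segments tiling each chromosome's probe extent, with
    ``segment_mean`` equal to the arithmetic mean of member probes.
    """
    required = {"chrom", "pos", "value"}
    if not required.issubset(series.columns):
        raise ValueError(f"probe series needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom in series["chrom"].drop_duplicates():
        sub = series[series["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"probes on {chrom} are not sorted by position")
        x = sub["value"].to_numpy(dtype=float)
        cps = _segment_indices(x, alpha, n_permutations, min_width, rng)
        bounds = [0] + cps + [x.size]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]),
                    num_probes=hi - lo,
                    segment_mean=float(np.mean(x[lo:hi])),
                )
            )
    return segments


def segments_to_frame(segments: Sequence[Segment], sample: str = "sample") -> pd.DataFrame:
    """SEG-style table (sample, chrom, start, end, num_probes, segment_mean)."""
    return pd.DataFrame(
        [
            {
                "sample": sample,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "num_probes": s.num_probes,
                "segment_mean": s.segment_mean,
            }
            for s in segments
        ]
    )


def _in_intervals(chrom: str, pos: int, intervals: Iterable[tuple[str, int, int]]) -> bool:
    return any(c == chrom and s <= pos <= e for c, s, e in intervals)


def mask_probes(
    series: pd.DataFrame,
    germline_cnv_probes: set[str] | None = None,
    sex: str = "unknown",
    par_regions: Sequence[tuple[str, int, int]] = (),
    mode: str = "regular",
) -> pd.DataFrame:
    """Apply the probe exclusions for regular or masked segmentation.

    Regular mode removes probes inside pseudo-autosomal regions when
    ``sex == "male"``. Masked mode additionally removes all chromosome-Y
    probes and probes on the germline copy-number-variant exclusion list.
    """
    if mode not in ("regular", "masked"):
        raise ValueError("mode must be 'regular' or 'masked'")
    keep = pd.Series(True, index=series.index)
    if sex == "male" and len(par_regions):
        in_par = series.apply(
            lambda r: _in_intervals(str(r["chrom"]), int(r["pos"]), par_regions), axis=1
        )
        keep &= ~in_par
    if mode == "masked":
        keep &= ~series["chrom"].astype(str).isin(("chrY", "Y"))
        if germline_cnv_probes:
            keep &= ~series["probe_id"].isin(germline_cnv_probes)
    removed = int((~keep).sum())
    if removed:
        logger.info("probe masking (%s mode) removed %d probe(s)", mode, removed)
    return series[keep].reset_index(drop=True)


def gene_level_cnv(
    segments: Sequence[Segment], model: GeneModel
) -> Mapping[str, float]:
    """Average segment mean per gene, weighted by overlapped bases.

    The gene's genomic span (full start-end extent, not the exon union)
    is intersected with each segment; the value is the overlap-weighted
    mean of the intersecting segments' means. Genes with no overlapping
    segment are reported as NaN and logged.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)

    out: dict[str, float] = {}
    for gid, rec in model.records.items():
        gstart, gend = rec.span
        wsum = 0.0
        weight = 0.0
        for seg in by_chrom.get(rec.chrom, ()):
            ov = min(gend, seg.end) - max(gstart, seg.start) + 1
            if ov > 0:
                wsum += seg.segment_mean * ov
                weight += ov
        if weight > 0:
            out[gid] = wsum / weight
        else:
            logger.info("gene %s overlaps no segment; value missing", gid)
            out[gid] = float("nan")
    return out
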