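"""Methylation beta values and CpG probe re-annotation.

Beadchip arrays report per-CpG methylated (M) and unmethylated (U)
intensities; the beta value M/(M+U) lies in [0, 1] and is missing where
both intensities are zero. Probes re-mapped to a new reference build are
masked when the mapping is unreliable: Type II probes need mapping
quality >= 10; Type I probes additionally require their methylated and
unmethylated bead probes to land on the same locus. Masked probes carry
chrom '*' and pos -1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMapping",
    "beta_values",
    "filter_probe_mappings",
    "annotate_probes",
]

MIN_MAPQ = 10


@dataclass(frozen=True)
class ProbeMapping:
    """Re-mapping result for one array probe on the target reference."""

    probe_id: str
    design: str  # "TypeI" or "TypeII"
    chrom: str
    pos: int
    mapq: int
    paired_mapq: int | None = None
    paired_locus_same: bool | None = None

    @property
    def masked(self) -> bool:
        return self.chrom == "*" and self.pos == -1


def beta_values(M: pd.DataFrame, U: pd.DataFrame) -> pd.DataFrame:
    """Beta = M / (M + U); entries with zero total intensity become NaN.

    Raises ``ValueError`` on negative intensities or mismatched shapes.
    """
    if not M.index.equals(U.index) or not M.columns.equals(U.columns):
        raise ValueError("M and U matrices must share probes and samples")
    if (M.to_numpy() < 0).any() or (U.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    total = M + U
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = M / total
    beta = beta.where(total > 0)
    beta.attrs["unit"] = "beta"
    return beta


def _mask(mapping: ProbeMapping) -> ProbeMapping:
    return replace(mapping, chrom="*", pos=-1)


def filter_probe_mappings(mappings: Iterable[ProbeMapping]) -> list[ProbeMapping]:
    """Mask unreliably mapped probes (idempotent).

    Type II probes are masked iff mapq < 10. Type I probes are masked if
    either bead probe has mapq < 10 or the two bead probes map to
    different loci.
    """
    out = []
    for m in mappings:
        if m.masked:
            out.append(m)
            continue
        if m.design == "TypeII":
            bad = m.mapq < MIN_MAPQ
        elif m.design == "TypeI":
            paired_mapq = m.mapq if m.paired_mapq is None else m.paired_mapq
            bad = (
                m.mapq < MIN_MAPQ
                or paired_mapq < MIN_MAPQ
                or m.paired_locus_same is False
            )
        else:
            raise ValueError(f"unknown probe design {m.design!r}")
        out.append(_mask(m) if bad else m)
    return out


def _signed_distance(pos: int, start: int, end: int, strand: str = "+") -> int:
    """0 inside the feature; negative upstream of the feature start.

    Upstream is defined on the feature's strand: on '+' a probe before
    ``start`` is upstream (negative); on '-' a probe after ``end`` is.
    """
    if start <= pos <= end:
        return 0
    if strand == "-":
        return end - pos if pos > end else start - pos
    return pos - start if pos < start else pos - end


def annotate_probes(
    mappings: Sequence[ProbeMapping],
    transcripts: pd.DataFrame,
    cpg_islands: pd.DataFrame,
) -> pd.DataFrame:
    """Associate each mapped probe with transcripts and CpG islands.

    ``transcripts`` needs columns (transcript_id, chrom, start, end,
    strand); ``cpg_islands`` needs (island_id, chrom, start, end), both
    1-based inclusive. Masked probes are omitted from the output.

    Per probe the table reports: semicolon-joined ids of all overlapping
    transcripts with matching signed distances (0 when overlapping), the
    overlapping island if any, and the nearest island with its signed
    distance (ties broken toward the lower-coordinate island; islands
    are unstranded, so the '+' convention applies).
    """
    rows = []
    for m in mappings:
        if m.masked:
            continue
        tsub = transcripts[transcripts["chrom"] == m.chrom]
        hits = tsub[(tsub["start"] <= m.pos) & (m.pos <= tsub["end"])]
        t_ids = ";".join(hits["transcript_id"].astype(str))
        t_dists = ";".join(
            str(_signed_distance(m.pos, int(r.start), int(r.end), str(r.strand)))
            for r in hits.itertuples()
        )
        isub = cpg_islands[cpg_islands["chrom"] == m.chrom]
        overlapping = ""
        nearest = ""
        nearest_dist: int | None = None
        if len(isub):
            dists = [
                (abs(_signed_distance(m.pos, int(r.start), int(r.end))), int(r.start), r)
                for r in isub.itertuples()
            ]
            dists.sort(key=lambda t: (t[0], t[1]))
            best = dists[0][2]
            nearest = str(best.island_id)
            nearest_dist = _signed_distance(m.pos, int(best.start), int(best.end))
            if nearest_dist == 0:
                overlapping = nearest
        rows.append(
            {
                "probe_id": m.probe_id,
                "chrom": m.chrom,
                "pos": m.pos,
                "transcripts": t_ids,
                "transcript_distances": t_dists,
                "overlapping_island": overlapping,
                "nearest_island": nearest,
                "nearest_island_distance": nearest_dist,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "chrom",
            "pos",
            "transcripts",
            "transcript_distances",
            "overlapping_island",
            "nearest_island",
            "nearest_island_distance",
        ],
    )
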