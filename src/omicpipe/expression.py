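"""RNA-seq and miRNA-seq count normalization and dataset comparison.

Count matrices are pandas DataFrames with features as the index and
sample ids as columns. Normalized outputs keep the same shape and carry
their unit ("FPKM", "FPKM-UQ", "RPM") in ``DataFrame.attrs["unit"]``.

FPKM divides each gene's count by the total count over *protein-coding*
genes (not all genes) and by the gene's exonic length in bases:

    FPKM(g)    = RC_g * 1e9 / (RC_pc  * L_g)
    FPKM-UQ(g) = RC_g * 1e9 / (RC_g75 * L_g)

where RC_g75 is the sample's 75th-percentile count among protein-coding
genes. Both are invariant under uniform scaling of a sample's counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import GeneModel, exonic_length

__all__ = [
    "fpkm",
    "fpkm_uq",
    "rpm_mirna",
    "quartile_groups",
    "paired_spearman",
]


def _gene_lengths(counts: pd.DataFrame, model: GeneModel) -> pd.Series:
    missing = [g for g in counts.index if g not in model]
    if missing:
        raise KeyError(f"{len(missing)} feature(s) absent from gene model, e.g. {missing[:3]}")
    lengths = pd.Series(
        {g: exonic_length(model[g]) for g in counts.index}, name="length", dtype=float
    )
    zero_len = lengths.index[lengths <= 0]
    if len(zero_len):
        raise ValueError(f"gene(s) with non-positive exonic length: {list(zero_len[:3])}")
    return lengths


def _protein_coding_rows(counts: pd.DataFrame, model: GeneModel) -> pd.Index:
    return pd.Index([g for g in counts.index if model[g].biotype == "protein_coding"])


def fpkm(counts: pd.DataFrame, model: GeneModel) -> pd.DataFrame:
    """Fragments per kilobase per million, with a protein-coding denominator.

    Raises ``ValueError`` naming the sample if any sample has zero reads
    mapped to protein-coding genes.
    """
    lengths = _gene_lengths(counts, model)
    pc = _protein_coding_rows(counts, model)
    rc_pc = counts.loc[pc].sum(axis=0).astype(float)
    bad = rc_pc.index[rc_pc <= 0]
    if len(bad):
        raise ValueError(f"zero protein-coding read count in sample(s): {list(bad)}")
    out = counts.astype(float).div(lengths, axis=0).mul(1e9).div(rc_pc, axis=1)
    out.attrs["unit"] = "FPKM"
    return out


def upper_quartile(counts: pd.DataFrame, model: GeneModel, include_zeros: bool = False) -> pd.Series:
    """Per-sample 75th-percentile count over protein-coding genes.

    By default zero-count genes are excluded from the percentile base set;
    set ``include_zeros=True`` to rank over all protein-coding genes.
    Percentiles use linear interpolation.
    """
    pc = _protein_coding_rows(counts, model)
    uq = {}
    for sample in counts.columns:
        vals = counts.loc[pc, sample].to_numpy(dtype=float)
        if not include_zeros:
            vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError(f"empty upper-quartile base set for sample {sample!r}")
        uq[sample] = float(np.percentile(vals, 75))
    out = pd.Series(uq, name="RCg75")
    bad = out.index[out <= 0]
    if len(bad):
        raise ValueError(f"zero 75th-percentile count in sample(s): {list(bad)}")
    return out


def fpkm_uq(
    counts: pd.DataFrame, model: GeneModel, include_zeros: bool = False
) -> pd.DataFrame:
    """Upper-quartile-normalized FPKM (library size replaced by RC_g75)."""
    lengths = _gene_lengths(counts, model)
    uq = upper_quartile(counts, model, include_zeros=include_zeros)
    out = counts.astype(float).div(lengths, axis=0).mul(1e9).div(uq, axis=1)
    out.attrs["unit"] = "FPKM-UQ"
    return out


def rpm_mirna(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization for miRNA species counts.

    Column sums of the output equal 1e6 when all features are kept.
    """
    libsize = counts.sum(axis=0).astype(float)
    bad = libsize.index[libsize <= 0]
    if len(bad):
        raise ValueError(f"zero library size in sample(s): {list(bad)}")
    out = counts.astype(float).mul(1e6).div(libsize, axis=1)
    out.attrs["unit"] = "RPM"
    return out


def quartile_groups(matrix: pd.DataFrame) -> pd.Series:
    """Assign each feature to Q1..Q4 by quartile of its mean across samples.

    Cut points are the 25/50/75 percentiles of the per-feature means;
    features whose mean falls exactly on a cut go to the lower group, so
    the assignment is deterministic under ties.
    """
    if len(matrix.index) < 4:
        raise ValueError("quartile grouping needs at least 4 features")
    means = matrix.mean(axis=1)
    cuts = np.percentile(means.to_numpy(dtype=float), [25, 50, 75])
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])
    # side="left": a mean exactly on a cut counts into the lower group
    idx = np.searchsorted(cuts, means.to_numpy(dtype=float), side="left")
    return pd.Series(labels[idx], index=matrix.index, name="quartile_group")


def paired_spearman(
    a: pd.DataFrame,
    b: pd.DataFrame,
    axis: str = "sample",
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Spearman correlation between two datasets over shared features/samples.

    The matrices are first restricted to their shared features and shared
    samples. With ``axis="sample"`` one correlation is computed per shared
    sample (across features); with ``axis="feature"``, per shared feature
    (across samples). Ties get average ranks (scipy default).

    Returns a DataFrame with columns ``id``, ``rho``, ``n`` (and ``group``
    when ``groups`` is given). Pairs with fewer than 2 observations or
    zero variance yield ``rho = NaN`` and stay in the table rather than
    being dropped. Use :func:`group_summary` for per-group mean/sd.
    """
    if axis not in ("sample", "feature"):
        raise ValueError("axis must be 'sample' or 'feature'")
    feats = a.index.intersection(b.index)
    samps = a.columns.intersection(b.columns)
    if len(feats) == 0 or len(samps) == 0:
        raise ValueError("no shared features or no shared samples")
    a = a.loc[feats, samps]
    b = b.loc[feats, samps]

    rows = []
    ids = samps if axis == "sample" else feats
    for key in ids:
        x = a[key] if axis == "sample" else a.loc[key]
        y = b[key] if axis == "sample" else b.loc[key]
        x = x.to_numpy(dtype=float)
        y = y.to_numpy(dtype=float)
        if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
            rho = np.nan
        else:
            rho = float(stats.spearmanr(x, y).statistic)
        rows.append({"id": key, "rho": rho, "n": int(x.size)})
    out = pd.DataFrame(rows)
    if groups is not None:
        out["group"] = out["id"].map(groups)
    return out


def group_summary(correlations: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and sd of the correlations from :func:`paired_spearman`."""
    if "group" not in correlations.columns:
        raise ValueError("correlations table has no 'group' column")
    return (
        correlations.groupby("group")["rho"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
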