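"""Multi-omic integration: per-type filtering, PCA, weighting, and t-SNE.

Four data types (mRNA counts, miRNA counts, methylation betas, gene-level
copy number) measured on a shared sample cohort are each reduced by PCA;
the pooled components are re-ranked by variance explained, the top k
kept, score columns scaled by per-type weights (default 3:3:1:1 for
mRNA : methylation : miRNA : CNV), and the result embedded in 2-D with
t-SNE. Because t-SNE's objective is non-convex, the embedding is run
many times from random initializations and the run with the lowest final
KL divergence is kept.

All matrices are features x samples DataFrames; PCA scores and
embeddings are samples x components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "DEFAULT_WEIGHTS",
    "Embedding",
    "filter_low_expressed",
    "filter_impute_methylation",
    "per_type_pca",
    "combine_select_weight",
    "tsne_best_of",
    "integrate_cohort",
]

DEFAULT_WEIGHTS = {"mRNA": 3.0, "methylation": 3.0, "miRNA": 1.0, "cnv": 1.0}


@dataclass
class Embedding:
    """A 2-D embedding with the KL cost and seed of its winning run."""

    coordinates: pd.DataFrame  # samples x 2
    cost: float
    seed: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.coordinates.to_numpy()).all():
            raise ValueError("embedding coordinates must be finite")


def filter_low_expressed(matrix: pd.DataFrame, max_count: int = 1, frac: float = 0.99) -> pd.DataFrame:
    """Drop features that are (near-)silent in almost every sample.

    A feature is removed when the fraction of samples with count
    <= ``max_count`` is ``frac`` (99%) or more; idempotent.
    """
    low = (matrix <= max_count).mean(axis=1)
    return matrix[low < frac]


def filter_impute_methylation(
    matrix: pd.DataFrame,
    max_missing_frac: float = 0.05,
    downsample_frac: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Missingness filter, mean imputation, and probe down-sampling.

    Probes missing in strictly more than ``max_missing_frac`` of samples
    are removed; remaining missing entries are replaced by the probe's
    mean beta; then a seeded random fraction ``downsample_frac`` of the
    surviving probes is retained (1.0 disables down-sampling, keeping
    probe order).
    """
    missing = matrix.isna().mean(axis=1)
    kept = matrix[missing <= max_missing_frac]
    imputed = kept.apply(lambda row: row.fillna(row.mean()), axis=1)
    if downsample_frac >= 1.0:
        return imputed
    rng = np.random.default_rng(seed)
    n_keep = int(round(downsample_frac * len(imputed)))
    chosen = rng.choice(len(imputed), size=n_keep, replace=False)
    return imputed.iloc[np.sort(chosen)]


def per_type_pca(matrix: pd.DataFrame, k: int = 200) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of one data type.

    Samples are observations (matrix is transposed internally), features
    are centered, values are not scaled. Returns (scores, explained
    variance ratio); components are ordered by decreasing variance
    explained and fewer than k are returned for rank-deficient input.
    """
    X = matrix.T.to_numpy(dtype=float)
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_comp = min(k, n_samples - 1, n_features)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    # drop numerically-zero components (degenerate rank)
    nonzero = pca.explained_variance_ > 1e-12
    scores = scores[:, nonzero]
    ratio = pca.explained_variance_ratio_[nonzero]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.columns, columns=cols), ratio


def combine_select_weight(
    pcs_by_type: dict[str, tuple[pd.DataFrame, np.ndarray]],
    k: int = 200,
    weights: dict[str, float] | None = None,
    ranking: str = "fraction",
) -> pd.DataFrame:
    """Pool per-type PCs, keep the top k by variance explained, weight them.

    ``pcs_by_type`` maps data type -> (scores, explained-variance ratio)
    as returned by :func:`per_type_pca`. Components compete on their
    per-type *fraction* of variance explained by default (cross-type
    absolute variances are not comparable); set ``ranking="absolute"``
    to rank on the score columns' own variances instead. The kept
    components' score columns are multiplied by their type's weight
    (applied after selection). Columns are named ``<type>:<PCi>``.
    """
    weights = DEFAULT_WEIGHTS if weights is None else weights
    sample_index = None
    pool = []
    for dtype, (scores, ratio) in pcs_by_type.items():
        if sample_index is None:
            sample_index = scores.index
        elif not scores.index.equals(sample_index):
            raise ValueError(f"sample ids of {dtype!r} differ from the other types")
        for j, col in enumerate(scores.columns):
            if ranking == "fraction":
                rank_val = float(ratio[j])
            elif ranking == "absolute":
                rank_val = float(np.var(scores[col].to_numpy()))
            else:
                raise ValueError("ranking must be 'fraction' or 'absolute'")
            pool.append((rank_val, dtype, col))
    pool.sort(key=lambda t: -t[0])
    kept = pool[:k]
    data = {
        f"{dtype}:{col}": pcs_by_type[dtype][0][col] * weights.get(dtype, 1.0)
        for _, dtype, col in kept
    }
    return pd.DataFrame(data, index=sample_index)


def tsne_best_of(
    X: pd.DataFrame,
    runs: int = 1000,
    perplexity: float = 30.0,
    seed_base: int = 0,
) -> Embedding:
    """Best-of-N t-SNE: keep the run with the lowest final KL divergence.

    Runs are seeded ``seed_base .. seed_base + runs - 1`` with random
    initialization so they genuinely differ. Perplexity is capped below
    the sample count.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("input to t-SNE contains non-finite values")
    n = values.shape[0]
    perplexity = min(perplexity, (n - 1) / 3.0)
    best: Embedding | None = None
    for seed in range(seed_base, seed_base + runs):
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="random",
            random_state=seed,
        )
        coords = tsne.fit_transform(values)
        cost = float(tsne.kl_divergence_)
        if best is None or cost < best.cost:
            best = Embedding(
                coordinates=pd.DataFrame(coords, index=X.index, columns=["tsne1", "tsne2"]),
                cost=cost,
                seed=seed,
            )
    return best


def integrate_cohort(
    matrices: dict[str, pd.DataFrame],
    k: int = 200,
    weights: dict[str, float] | None = None,
    runs: int = 50,
    perplexity: float = 30.0,
    seed: int = 0,
) -> Embedding:
    """End-to-end integration of a four-type cohort into a 2-D embedding.

    ``matrices`` maps data type ("mRNA", "miRNA", "methylation", "cnv")
    to a features x samples DataFrame. Count types pass the
    low-expression filter; methylation passes the missingness filter,
    mean imputation and probe down-sampling; then per-type PCA, pooled
    component selection with 3:3:1:1 weighting, and best-of-N t-SNE.
    """
    processed: dict[str, pd.DataFrame] = {}
    for dtype, mat in matrices.items():
        if dtype in ("mRNA", "miRNA"):
            processed[dtype] = filter_low_expressed(mat)
        elif dtype == "methylation":
            processed[dtype] = filter_impute_methylation(mat, seed=seed)
        else:
            processed[dtype] = mat.dropna(how="any")
    pcs = {dtype: per_type_pca(mat, k=k) for dtype, mat in processed.items()}
    combined = combine_select_weight(pcs, k=k, weights=weights)
    return tsne_best_of(combined, runs=runs, perplexity=perplexity, seed_base=seed)
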