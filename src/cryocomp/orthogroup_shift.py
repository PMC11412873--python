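"""Orthogroup expansion/contraction scoring across lifestyle groups.

Gene counts per orthogroup are first converted to standard normal deviates
using the 50% trimmed mean and standard deviation of each orthogroup (25% of
values removed from each tail — the midmean; the trim fraction is
configurable, including the 50%-per-tail reading that reduces to the
median).  The shift of a focal group (e.g. psychrophiles) against the
background is then scored per orthogroup with a Welch-type t statistic

    t = (c_p - c_n) / sqrt(s_p^2 / n_p + s_n^2 / n_n)

where c, s and n are the mean, standard deviation and size of the focal (p)
and background (n) normalized score sets.  A literal variant without the /n
terms, t = (c_p - c_n)/sqrt(s_p^2 + s_n^2), is available as
``t_formula="paper_literal"``; it differs from the standard Welch statistic
only by a monotone group-size rescaling when group sizes are fixed, so
rankings agree.

Downstream utilities rank the most expanded/contracted orthogroups, count
per-species shifted orthogroups at a |score| threshold, and cluster species
on correlation distance (1 - Pearson r) with Ward linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .errors import DegenerateInputError
from .io_formats import GeneCountMatrix


@dataclass(frozen=True)
class NormalizationConfig:
    """Trim fraction per tail (0.25 = midmean) and zero-SD handling."""

    trim_fraction_per_tail: float = 0.25
    zero_sd_policy: str = "zeros"  # zeros | drop

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction_per_tail < 0.5:
            raise ValueError("trim fraction per tail must be in [0, 0.5)")
        if self.zero_sd_policy not in ("zeros", "drop"):
            raise ValueError("zero_sd_policy must be 'zeros' or 'drop'")


@dataclass(frozen=True)
class ShiftConfig:
    """Per-species shift threshold, top-list size and t-statistic variant."""

    species_threshold: float = 0.75
    top_n: int = 50
    t_formula: str = "welch"  # welch | paper_literal

    def __post_init__(self) -> None:
        if self.species_threshold <= 0:
            raise ValueError("species_threshold must be positive")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.t_formula not in ("welch", "paper_literal"):
            raise ValueError("t_formula must be 'welch' or 'paper_literal'")


@dataclass
class NormalizedMatrix:
    """Orthogroup x species standard-normal-deviate scores."""

    scores: pd.DataFrame
    dropped_orthogroups: list[str] = field(default_factory=list)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.scores.columns)


def trimmed_stats(
    values: Sequence[float], trim_fraction_per_tail: float = 0.25
) -> tuple[float, float]:
    """Mean and sample SD after removing floor(f*n) values from each tail.

    Values are sorted, ``k = floor(trim_fraction_per_tail * n)`` removed from
    each end, and the mean and sample standard deviation (denominator
    ``n_kept - 1``) of the remainder returned.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    k = int(np.floor(trim_fraction_per_tail * n))
    kept = v[k : n - k]
    if kept.size < 2:
        raise DegenerateInputError(
            f"trimming {k} per tail leaves {kept.size} < 2 values"
        )
    return float(np.mean(kept)), float(np.std(kept, ddof=1))


def normalize_counts(
    matrix: GeneCountMatrix, config: NormalizationConfig = NormalizationConfig()
) -> NormalizedMatrix:
    """Convert each orthogroup's counts to standard normal deviates.

    score(g, i) = (count(g, i) - trimmed_mean_g) / trimmed_sd_g.  Orthogroups
    whose trimmed SD is zero either get all-zero scores (policy ``zeros``,
    keeping the matrix shape stable) or are dropped (policy ``drop``).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    n_sp = counts.shape[1]
    k = int(np.floor(config.trim_fraction_per_tail * n_sp))
    if n_sp - 2 * k < 2:
        raise DegenerateInputError("trimming leaves fewer than 2 values per orthogroup")

    srt = np.sort(counts, axis=1)
    kept = srt[:, k : n_sp - k]
    means = kept.mean(axis=1)
    sds = kept.std(axis=1, ddof=1)

    zero_sd = sds == 0
    safe_sds = np.where(zero_sd, 1.0, sds)
    scores = (counts - means[:, None]) / safe_sds[:, None]
    scores[zero_sd, :] = 0.0

    df = pd.DataFrame(scores, index=matrix.counts.index, columns=matrix.counts.columns)
    dropped: list[str] = []
    if config.zero_sd_policy == "drop" and zero_sd.any():
        dropped = list(df.index[zero_sd])
        df = df.loc[~zero_sd]
    return NormalizedMatrix(scores=df, dropped_orthogroups=dropped)


def welch_t_scores(
    normalized: NormalizedMatrix,
    groups: Mapping[str, str],
    focal_group: str,
    config: ShiftConfig = ShiftConfig(),
) -> pd.DataFrame:
    """Per-orthogroup shift statistic of the focal group vs the background.

    Returns a DataFrame indexed by orthogroup with columns c_p, c_n, s_p,
    s_n, n_p, n_n and t.  Group summaries use the plain mean and sample SD of
    the normalized scores (no trimming at this step).  When both group SDs
    are zero, t is 0 for equal means and +/-inf otherwise (ranked extreme).
    """
    focal = [s for s in normalized.species_ids if groups.get(s) == focal_group]
    background = [s for s in normalized.species_ids if groups.get(s) != focal_group]
    if not focal:
        raise ValueError(f"unknown focal group {focal_group!r}")
    if len(focal) < 2 or len(background) < 2:
        raise ValueError("need at least 2 species in focal group and background")

    p = normalized.scores[focal].to_numpy()
    n = normalized.scores[background].to_numpy()
    n_p, n_n = p.shape[1], n.shape[1]
    c_p, c_n = p.mean(axis=1), n.mean(axis=1)
    s_p, s_n = p.std(axis=1, ddof=1), n.std(axis=1, ddof=1)

    if config.t_formula == "welch":
        denom = np.sqrt(s_p**2 / n_p + s_n**2 / n_n)
    else:
        denom = np.sqrt(s_p**2 + s_n**2)
    diff = c_p - c_n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)

    return pd.DataFrame(
        {
            "c_p": c_p,
            "c_n": c_n,
            "s_p": s_p,
            "s_n": s_n,
            "n_p": n_p,
            "n_n": n_n,
            "t": t,
        },
        index=normalized.scores.index,
    )


def rank_shifts(
    scores: pd.DataFrame, config: ShiftConfig = ShiftConfig()
) -> tuple[list[str], list[str]]:
    """Top-n most expanded (largest t) and most contracted (smallest t) ids.

    Ties are broken by orthogroup id (lexicographic); the two lists are
    disjoint (contracted candidates exclude already-selected expanded ids).
    """
    if len(scores) < 2 * config.top_n:
        raise ValueError(
            f"need at least {2 * config.top_n} orthogroups, have {len(scores)}"
        )
    frame = scores[["t"]].copy()
    frame["og"] = frame.index
    desc = frame.sort_values(["t", "og"], ascending=[False, True])
    expanded = list(desc.index[: config.top_n])
    asc = frame.drop(index=expanded).sort_values(["t", "og"], ascending=[True, True])
    contracted = list(asc.index[: config.top_n])
    return expanded, contracted


def per_species_shift_counts(
    normalized: NormalizedMatrix, config: ShiftConfig = ShiftConfig()
) -> pd.DataFrame:
    """Per species: number of orthogroups with score strictly beyond the threshold.

    Columns ``n_expanded`` (score > threshold) and ``n_contracted``
    (score < -threshold); scores exactly at the threshold count in neither.
    """
    s = normalized.scores
    thr = config.species_threshold
    return pd.DataFrame(
        {
            "n_expanded": (s > thr).sum(axis=0),
            "n_contracted": (s < -thr).sum(axis=0),
        }
    )


def species_correlation(
    normalized: NormalizedMatrix,
    orthogroup_subset: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between species score vectors.

    Returns ``(corr, flagged)``: a symmetric species x species matrix with
    unit diagonal, and the list of zero-variance species whose off-diagonal
    correlations are set to 0.
    """
    scores = normalized.scores
    if orthogroup_subset is not None:
        unknown = set(orthogroup_subset) - set(scores.index)
        if unknown:
            raise ValueError(f"unknown orthogroup ids: {sorted(unknown)[:3]}")
        scores = scores.loc[list(orthogroup_subset)]
    if len(scores) < 2:
        raise ValueError("need at least 2 orthogroups for correlation")

    x = scores.to_numpy()
    flagged = [sp for j, sp in enumerate(scores.columns) if np.std(x[:, j]) == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return (
        pd.DataFrame(corr, index=scores.columns, columns=scores.columns),
        flagged,
    )


def ward_cluster(
    corr: pd.DataFrame, n_clusters: int
) -> tuple[np.ndarray, dict[str, int]]:
    """Ward-linkage agglomerative clustering on distance d = 1 - r.

    Returns the scipy linkage matrix and a species -> cluster-id mapping
    (cluster ids 1..n_clusters).
    """
    mat = corr.to_numpy()
    if not np.allclose(mat, mat.T):
        raise ValueError("correlation matrix must be symmetric")
    if not 2 <= n_clusters <= len(corr):
        raise ValueError("n_clusters must be between 2 and the number of species")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return z, dict(zip(corr.index, (int(c) for c in labels)))


def pca_scores(
    corr: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the (column-centered) correlation matrix.

    Species are samples, their correlation profiles features.  Returns
    component scores per species and the explained-variance fractions
    (non-increasing, summing to <= 1).  Component signs are fixed by making
    each component's largest-magnitude loading positive.
    """
    n_species = len(corr)
    if n_components is None:
        n_components = min(n_species, 2)
    if n_components > n_species:
        raise ValueError("n_components must not exceed the number of species")

    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(corr.to_numpy())
    # a constant matrix has no variance after centering; report 0 explained
    pca.explained_variance_ratio_ = np.nan_to_num(
        pca.explained_variance_ratio_, nan=0.0
    )
    for j in range(n_components):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return (
        pd.DataFrame(scores, index=corr.index, columns=cols),
        pca.explained_variance_ratio_,
    )
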