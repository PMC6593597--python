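"""The twiner penalty: angular distances between per-disease correlation
profiles and the per-gene penalty factors derived from them.

For diseases A and B with gene-gene Pearson correlation matrices
``Sigma_A`` and ``Sigma_B``, the dissimilarity of gene j across the two
diseases is the angle between its correlation columns,

    d_j(A, B) = arccos( <s_j^A, s_j^B> / (||s_j^A|| * ||s_j^B||) ),

and the penalty factor is the distance normalized by the largest one,

    w_j = d_j / max_k d_k,   w_j in [0, 1].

Genes whose correlation pattern with the rest of the transcriptome is
nearly the same in both diseases ("twin" genes) get small weights and are
therefore shrunk less by the weighted elastic net.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

__all__ = [
    "CorrelationProfile",
    "TwinerWeights",
    "correlation_profile",
    "angular_distance",
    "twiner_weight_vector",
    "prefilter_by_angle",
    "write_weights",
    "write_correlation",
]

SampleFilter = Literal["all", "tumor_only", "normal_only"]

# allowed floating-point overshoot of |cos| beyond 1 before it is an error
_COS_OVERSHOOT_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationProfile:
    """A p x p Pearson correlation matrix for one disease cohort."""

    matrix: np.ndarray
    gene_ids: list[str]
    cohort: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        p = len(self.gene_ids)
        if m.shape != (p, p):
            raise ValueError("matrix must be p x p aligned to gene_ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        if m.min() < -1 - 1e-10 or m.max() > 1 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class TwinerWeights:
    """Per-gene angular distances (degrees) and normalized penalty factors."""

    gene_ids: list[str]
    distance_deg: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_deg, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        p = len(self.gene_ids)
        if d.shape != (p,) or w.shape != (p,):
            raise ValueError("distance/weight must align with gene_ids")
        if np.any(d < 0) or np.any(d > 180):
            raise ValueError("angular distances must lie in [0, 180] degrees")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "distance_deg", d)
        object.__setattr__(self, "weight", w)

    def subset(self, mask: np.ndarray) -> "TwinerWeights":
        mask = np.asarray(mask, dtype=bool)
        return TwinerWeights(
            [g for g, m in zip(self.gene_ids, mask) if m],
            self.distance_deg[mask],
            self.weight[mask],
        )


def correlation_profile(
    ds: ExpressionDataset, sample_filter: SampleFilter = "tumor_only"
) -> CorrelationProfile:
    """Pearson correlation matrix of all gene pairs in one cohort.

    ``sample_filter`` selects which samples define the disease's
    co-expression structure; the default uses tumor samples only, since
    the penalty targets the disease's correlation network.
    """
    if sample_filter == "all":
        sub = ds
    elif sample_filter in ("tumor_only", "normal_only"):
        if ds.labels is None:
            raise ValueError(f"sample_filter={sample_filter!r} requires labels")
        want = 1 if sample_filter == "tumor_only" else 0
        sub = ds.select_samples(ds.labels == want)
    else:
        raise ValueError(f"unknown sample_filter {sample_filter!r}")
    if sub.n_samples < 3:
        raise ValueError(
            f"need >= 3 samples to estimate correlations, got {sub.n_samples}"
        )
    sd = sub.values.std(axis=0)
    if np.any(sd == 0):
        bad = [g for g, s in zip(sub.gene_ids, sd) if s == 0]
        raise ValueError(f"zero-variance genes after filtering: {bad[:5]}")
    m = np.corrcoef(sub.values, rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return CorrelationProfile(m, list(sub.gene_ids), cohort=ds.cohort)


def angular_distance(
    profile_a: CorrelationProfile,
    profile_b: CorrelationProfile,
    include_self: bool = False,
) -> np.ndarray:
    """Per-gene angle (degrees) between correlation columns of A and B.

    With ``include_self=False`` (default) the diagonal entry — a gene's
    self-correlation, identically 1 in both diseases — is removed from
    each column before the angle is taken, so that it does not deflate
    all distances uniformly. ``include_self=True`` keeps the full column.
    """
    if profile_a.gene_ids != profile_b.gene_ids:
        raise ValueError("profiles must cover identical genes in identical order")
    A, B = profile_a.matrix, profile_b.matrix
    p = A.shape[0]
    if not include_self:
        # drop entry j from column j of both matrices
        off = ~np.eye(p, dtype=bool)
        A = A.T[off].reshape(p, p - 1).T  # column j -> length p-1
        B = B.T[off].reshape(p, p - 1).T
    norm_a = np.linalg.norm(A, axis=0)
    norm_b = np.linalg.norm(B, axis=0)
    zero = (norm_a == 0) | (norm_b == 0)
    if zero.any():
        bad = [g for g, z in zip(profile_a.gene_ids, zero) if z]
        raise ValueError(f"zero-norm correlation column for genes {bad[:5]}")
    cos = np.einsum("ij,ij->j", A, B) / (norm_a * norm_b)
    if np.any(np.abs(cos) > 1 + _COS_OVERSHOOT_TOL):
        raise ValueError("cosine overshoot beyond floating-point tolerance")
    # arccos of the clamped cosine, computed through Kahan's
    # 2*atan2(||a-b||, ||a+b||) form on the normalized columns: identical
    # to arccos in exact arithmetic but stable near 0 and 180 degrees,
    # where arccos loses half the significant digits.
    Ahat, Bhat = A / norm_a, B / norm_b
    chord = np.linalg.norm(Ahat - Bhat, axis=0)
    anti = np.linalg.norm(Ahat + Bhat, axis=0)
    return np.degrees(2.0 * np.arctan2(chord, anti))


def twiner_weight_vector(
    distances: np.ndarray, gene_ids: list[str] | None = None
) -> TwinerWeights:
    """Normalize angular distances by their maximum into penalty factors.

    ``w_j = d_j / max_k d_k``; a gene with distance 0 is unpenalized.
    If every distance is 0 the normalization is 0/0: all weights are set
    to 0 (every feature unpenalized), with a warning, as the only limit
    consistent with smaller distances earning smaller penalties.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("angular distances must be non-negative")
    if not np.all(np.isfinite(d)):
        raise ValueError("angular distances must be finite")
    d_max = d.max() if d.size else 0.0
    if d_max == 0:
        warnings.warn(
            "all angular distances are zero; every weight set to 0 "
            "(fully unpenalized limit)",
            stacklevel=2,
        )
        w = np.zeros_like(d)
    else:
        w = d / d_max
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(d.size)]
    return TwinerWeights(list(gene_ids), d, w)


def prefilter_by_angle(
    ds_merged: ExpressionDataset,
    weights: TwinerWeights,
    threshold_deg: float = 75.0,
) -> tuple[ExpressionDataset, TwinerWeights, list[str]]:
    """Keep only genes with angular distance strictly below the threshold.

    Mirrors the protocol of discarding genes whose correlation patterns
    diverge between the diseases (default threshold 75 degrees) before
    model fitting. Weights are NOT renormalized after filtering: the
    max-normalization is defined on the full pre-filter gene set.

    Returns (restricted dataset, restricted weights, dropped gene ids).
    """
    if not (0 < threshold_deg <= 180):
        raise ValueError("threshold_deg must lie in (0, 180]")
    if ds_merged.gene_ids != weights.gene_ids:
        raise ValueError("dataset and weights must cover identical genes")
    keep = weights.distance_deg < threshold_deg
    if not keep.any():
        raise ValueError("angular pre-filter removed every gene")
    dropped = [g for g, k in zip(weights.gene_ids, keep) if not k]
    sub_ds = ExpressionDataset(
        ds_merged.values[:, keep],
        list(ds_merged.sample_ids),
        [g for g, k in zip(ds_merged.gene_ids, keep) if k],
        ds_merged.labels,
        ds_merged.cohort,
    )
    return sub_ds, weights.subset(keep), dropped


def write_correlation(profile: CorrelationProfile, path: str | Path) -> None:
    """Write a correlation matrix as square TSV with header row/column."""
    pd.DataFrame(
        profile.matrix, index=profile.gene_ids, columns=profile.gene_ids
    ).to_csv(Path(path), sep="\t", float_format="%.12g")


def write_weights(weights: TwinerWeights, path: str | Path) -> None:
    """Write (gene_id, distance_deg, weight) as TSV."""
    pd.DataFrame(
        {
            "gene_id": weights.gene_ids,
            "distance_deg": weights.distance_deg,
            "weight": weights.weight,
        }
    ).to_csv(Path(path), sep="\t", index=False, float_format="%.12g")
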