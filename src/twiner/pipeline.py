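"""Resampling protocol comparing plain elastic net (EN) against twiner.

The protocol: repeat ``n_runs`` times — draw a random (stratified)
75/25 train/test split, choose lambda by 10-fold cross-validation on the
training set, refit, and record test metrics and the selected genes —
once with unit penalty factors (EN) and once with the twiner weights,
sharing each run's split so the comparison is paired. Genes selected in
more than a stated fraction of runs (default 75%) form each method's
consensus signature.

Metrics follow the protocol's conventions: the "MSE of classification"
is the Brier score on predicted probabilities, discrimination is the
area under the precision-recall curve (robust to the tumor >> normal
class imbalance), and misclassifications are counted at a 0.5 cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score
from sklearn.model_selection import train_test_split

from .datasets import ExpressionDataset
from .solver import PenaltySpec, cv_lambda, fit_weighted_enet, predict_prob
from .weights import (
    TwinerWeights,
    angular_distance,
    correlation_profile,
    prefilter_by_angle,
    twiner_weight_vector,
)

__all__ = [
    "RunRecord",
    "StabilityResult",
    "split_train_test",
    "mse_classification",
    "auc_precision_recall",
    "misclassification_count",
    "run_stability",
    "export_selected_gene_network",
    "compute_twiner_weights",
    "write_stability",
]

logger = logging.getLogger(__name__)

Method = Literal["en", "twiner"]


@dataclass(frozen=True)
class RunRecord:
    """Metrics and selections from one train/test split for one method."""

    run_id: int
    method: Method
    seed: int
    train_mse: float
    test_mse: float
    train_auc_pr: float
    test_auc_pr: float
    train_miscl: int
    test_miscl: int
    selected_genes: frozenset[str]
    lambda_opt: float


@dataclass(frozen=True)
class StabilityResult:
    """Aggregate of all runs: frequencies, consensus sets, medians, Venn."""

    records: list[RunRecord]
    selection_frequency: pd.DataFrame  # index gene_id, one column per method
    consensus: dict[str, list[str]]
    medians: pd.DataFrame  # index method, columns metric medians
    venn: dict[str, list[str]]  # en_only / shared / twiner_only
    freq_threshold: float

    def records_frame(self) -> pd.DataFrame:
        rows = [
            {
                "run_id": r.run_id,
                "method": r.method,
                "seed": r.seed,
                "train_mse": r.train_mse,
                "test_mse": r.test_mse,
                "train_auc_pr": r.train_auc_pr,
                "test_auc_pr": r.test_auc_pr,
                "train_miscl": r.train_miscl,
                "test_miscl": r.test_miscl,
                "n_selected": len(r.selected_genes),
                "lambda_opt": r.lambda_opt,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def split_train_test(
    ds: ExpressionDataset,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Random disjoint, exhaustive train/test partition of the samples."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    ds.require_two_classes()
    idx = np.arange(ds.n_samples)
    strat = ds.labels if stratified else None
    tr, te = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=strat
    )
    train, test = ds.select_samples(np.sort(tr)), ds.select_samples(np.sort(te))
    if len(np.unique(train.labels)) < 2:
        raise ValueError("a class is absent from the training split")
    return train, test


def mse_classification(
    probs: np.ndarray, labels: np.ndarray, hard: bool = False, cutoff: float = 0.5
) -> float:
    """Brier score: mean squared difference between probability and label.

    With ``hard=True`` the probabilities are thresholded at ``cutoff``
    first, giving the misclassification rate instead.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels differ in length")
    if hard:
        probs = (probs >= cutoff).astype(float)
    return float(np.mean((probs - labels) ** 2))


def auc_precision_recall(probs: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("PR-AUC requires both classes present")
    return float(average_precision_score(labels, probs))


def misclassification_count(
    probs: np.ndarray, labels: np.ndarray, cutoff: float = 0.5
) -> int:
    """Number of samples whose thresholded prediction differs from the label.

    A probability exactly at the cutoff counts as a positive call.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels differ in length")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    return int(np.sum((probs >= cutoff).astype(int) != labels))


def _evaluate(fit, train, test) -> dict:
    out = {}
    for tag, part in (("train", train), ("test", test)):
        probs = predict_prob(fit, part)
        out[f"{tag}_mse"] = mse_classification(probs, part.labels)
        out[f"{tag}_auc_pr"] = auc_precision_recall(probs, part.labels)
        out[f"{tag}_miscl"] = misclassification_count(probs, part.labels)
    return out


def run_stability(
    ds_merged: ExpressionDataset,
    weights: TwinerWeights,
    n_runs: int = 100,
    alpha: float = 0.9,
    cv_folds: int = 10,
    train_fraction: float = 0.75,
    freq_threshold: float = 0.75,
    base_seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    metric: Literal["mse", "deviance"] = "mse",
    stratified: bool = True,
    tol: float = 1e-7,
) -> StabilityResult:
    """Paired EN-vs-twiner resampling over random train/test splits.

    Run r uses seed ``base_seed + r`` for its split and its CV folds, so
    any single run is re-derivable; both methods see the same split. The
    EN arm is exactly the twiner code path with unit penalty factors.
    """
    if ds_merged.gene_ids != weights.gene_ids:
        raise ValueError("dataset and weights must cover identical genes")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    method_w = {"en": "unit", "twiner": weights.weight}
    records: list[RunRecord] = []
    counts = {m: np.zeros(ds_merged.n_genes) for m in method_w}
    for r in range(n_runs):
        seed = base_seed + r
        try:
            train, test = split_train_test(
                ds_merged, train_fraction, seed=seed, stratified=stratified
            )
            for method, w in method_w.items():
                pen = PenaltySpec(alpha=alpha, weights=w)
                lam_opt, _ = cv_lambda(
                    train,
                    pen,
                    k=cv_folds,
                    metric=metric,
                    seed=seed,
                    n_lambda=n_lambda,
                    lambda_min_ratio=lambda_min_ratio,
                    tol=tol,
                )
                fit = fit_weighted_enet(train, pen.with_lambda(lam_opt), tol=tol)
                metrics = _evaluate(fit, train, test)
                selected = frozenset(fit.selected_genes)
                counts[method] += np.array(
                    [g in selected for g in ds_merged.gene_ids], dtype=float
                )
                records.append(
                    RunRecord(
                        run_id=r,
                        method=method,  # type: ignore[arg-type]
                        seed=seed,
                        selected_genes=selected,
                        lambda_opt=lam_opt,
                        **metrics,
                    )
                )
        except Exception as exc:
            raise RuntimeError(f"stability run {r} (seed {seed}) failed: {exc}") from exc
        logger.info("run %d/%d done", r + 1, n_runs)

    freq = pd.DataFrame(
        {m: counts[m] / n_runs for m in method_w}, index=ds_merged.gene_ids
    )
    consensus = {
        m: [g for g in ds_merged.gene_ids if freq.loc[g, m] > freq_threshold]
        for m in method_w
    }
    med_rows = {}
    df = pd.DataFrame([r.__dict__ for r in records])
    metric_cols = [
        "train_mse", "test_mse", "train_auc_pr", "test_auc_pr",
        "train_miscl", "test_miscl", "lambda_opt",
    ]
    for m in method_w:
        sub = df[df["method"] == m]
        med_rows[m] = {c: float(sub[c].median()) for c in metric_cols}
        med_rows[m]["median_n_selected"] = float(
            sub["selected_genes"].apply(len).median()
        )
    en_set = set(consensus.get("en", []))
    tw_set = set(consensus.get("twiner", []))
    venn = {
        "en_only": sorted(en_set - tw_set),
        "shared": sorted(en_set & tw_set),
        "twiner_only": sorted(tw_set - en_set),
    }
    return StabilityResult(
        records=records,
        selection_frequency=freq,
        consensus=consensus,
        medians=pd.DataFrame(med_rows).T,
        venn=venn,
        freq_threshold=freq_threshold,
    )


def export_selected_gene_network(
    ds: ExpressionDataset,
    genes: Sequence[str],
    sample_filter: Literal["all", "tumor_only", "normal_only"] = "tumor_only",
    min_abs: float = 0.0,
) -> pd.DataFrame:
    """All-pairs Pearson correlations among selected genes as an edge list.

    Rows (gene_i, gene_j, r, sign, abs_r) for i < j in the given gene
    order; ``min_abs`` drops edges below an absolute-correlation floor
    for display.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a network")
    missing = [g for g in genes if g not in set(ds.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from dataset: {missing[:5]}")
    idx = {g: i for i, g in enumerate(ds.gene_ids)}
    sub = ExpressionDataset(
        ds.values[:, [idx[g] for g in genes]],
        list(ds.sample_ids),
        genes,
        ds.labels,
        ds.cohort,
    )
    prof = correlation_profile(sub, sample_filter=sample_filter)
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = prof.matrix[i, j]
            if abs(r) < min_abs:
                continue
            rows.append(
                {
                    "gene_i": genes[i],
                    "gene_j": genes[j],
                    "r": r,
                    "sign": "positive" if r >= 0 else "negative",
                    "abs_r": abs(r),
                }
            )
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "r", "sign", "abs_r"])


def _align_genes(ds: ExpressionDataset, gene_ids: list[str]) -> ExpressionDataset:
    idx = {g: i for i, g in enumerate(ds.gene_ids)}
    missing = [g for g in gene_ids if g not in idx]
    if missing:
        raise ValueError(f"genes absent from cohort: {missing[:5]}")
    cols = [idx[g] for g in gene_ids]
    return ExpressionDataset(
        ds.values[:, cols], list(ds.sample_ids), list(gene_ids), ds.labels, ds.cohort
    )


def compute_twiner_weights(
    a: ExpressionDataset,
    b: ExpressionDataset,
    gene_ids: list[str] | None = None,
    sample_filter: Literal["all", "tumor_only", "normal_only"] = "tumor_only",
    include_self: bool = False,
) -> TwinerWeights:
    """Angular distances and penalty factors between two cohorts.

    Computes each cohort's gene-gene Pearson correlation matrix (over
    ``sample_filter`` samples) on a shared, ordered gene set, then the
    per-gene angle between the two correlation columns, normalized by
    the maximum into penalty factors.
    """
    if gene_ids is None:
        bset = set(b.gene_ids)
        gene_ids = [g for g in a.gene_ids if g in bset]
        if not gene_ids:
            raise ValueError("cohorts share no genes")
    prof_a = correlation_profile(_align_genes(a, gene_ids), sample_filter)
    prof_b = correlation_profile(_align_genes(b, gene_ids), sample_filter)
    d = angular_distance(prof_a, prof_b, include_self=include_self)
    return twiner_weight_vector(d, gene_ids)


def write_stability(result: StabilityResult, outdir: str | Path) -> None:
    """Write runs.tsv, frequency.tsv, consensus lists and venn.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.records_frame().to_csv(outdir / "runs.tsv", sep="\t", index=False)
    freq = result.selection_frequency.rename_axis("gene_id").reset_index()
    freq.to_csv(outdir / "frequency.tsv", sep="\t", index=False)
    for method, genes in result.consensus.items():
        (outdir / f"consensus_{method}.txt").write_text(
            "\n".join(genes) + ("\n" if genes else "")
        )
    venn_rows = [
        {"part": part, "n_genes": len(genes), "genes": ",".join(genes)}
        for part, genes in result.venn.items()
    ]
    pd.DataFrame(venn_rows).to_csv(outdir / "venn.tsv", sep="\t", index=False)
    result.medians.rename_axis("method").reset_index().to_csv(
        outdir / "medians.tsv", sep="\t", index=False
    )
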