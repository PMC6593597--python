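"""Synthetic two-cohort expression data with a planted twin gene block.

The generator emulates the premise the twiner penalty targets: two
disease cohorts whose transcriptomes share a block of genes with
near-identical correlation structure (the "twin" block), alongside
blocks whose correlation structure is disease-specific, plus independent
noise genes. Binary tumor/normal outcomes are driven by a known subset
of twin genes through a logistic model, so recovery of the planted
signal can be scored exactly.

Expression is drawn at the post-preprocessing scale (Gaussian z-scores),
since log-FPKM z-scores are approximately Gaussian; a lognormal
pre-image mode exponentiates the draws to exercise the preprocessing
path on FPKM-like values.

Correlated blocks use a one-factor model: gene j in a block with target
correlation rho loads as ``x_j = s_j*sqrt(rho)*f + sqrt(1-rho)*e_j``
with signs ``s_j = +/-1``, giving corr(x_i, x_j) = s_i*s_j*rho and unit
variance. Cohort B re-signs half the loadings of each disease-specific
block (and permutes their order) relative to cohort A, which makes the
correlation columns of those genes nearly orthogonal between cohorts —
large angular distances by construction — while the twin block keeps
identical loadings in both cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .datasets import ExpressionDataset, SurvivalTable

__all__ = ["TwinScenario", "generate", "generate_survival"]


@dataclass(frozen=True)
class TwinScenario:
    """Parameters of one planted two-cohort scenario."""

    n_a: int = 150
    n_b: int = 150
    p: int = 300
    twin_block: tuple[int, ...] = tuple(range(0, 30))
    specific_blocks: tuple[tuple[int, ...], ...] = (
        tuple(range(30, 60)),
        tuple(range(60, 90)),
    )
    rho_twin: float = 0.7
    rho_specific: float = 0.7
    signal_genes: tuple[int, ...] = tuple(range(0, 5))
    effect_size: float = 1.0
    tumor_fraction_a: float = 0.85
    tumor_fraction_b: float = 0.85
    seed: int = 0
    mode: Literal["zscore", "lognormal"] = "zscore"

    def __post_init__(self) -> None:
        blocks = [set(self.twin_block), *(set(b) for b in self.specific_blocks)]
        union: set[int] = set()
        for b in blocks:
            if union & b:
                raise ValueError("gene blocks must be disjoint")
            union |= b
        if union and (min(union) < 0 or max(union) >= self.p):
            raise ValueError("block indices out of range")
        for rho in (self.rho_twin, self.rho_specific):
            if not -1.0 < rho < 1.0:
                raise ValueError("block correlations must lie in (-1, 1)")
        if not set(self.signal_genes) <= set(self.twin_block):
            raise ValueError("signal genes must lie inside the twin block")
        for f in (self.tumor_fraction_a, self.tumor_fraction_b):
            if not 0.0 < f < 1.0:
                raise ValueError("tumor fractions must lie in (0, 1)")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{j + 1:04d}" for j in range(self.p)]

    @property
    def signal_gene_ids(self) -> list[str]:
        return [f"G{j + 1:04d}" for j in self.signal_genes]


def _draw_cohort(
    rng: np.random.Generator,
    n: int,
    p: int,
    loadings: dict[int, float],
    block_of: dict[int, int],
    n_blocks: int,
    rho: dict[int, float],
) -> np.ndarray:
    """One-factor block draw: per-block common factor plus idiosyncratic noise."""
    X = rng.standard_normal((n, p))
    factors = rng.standard_normal((n, n_blocks))
    for j, u in loadings.items():
        b = block_of[j]
        X[:, j] = u * factors[:, b] + np.sqrt(1.0 - rho[j]) * X[:, j]
    return X


def generate(
    scenario: TwinScenario,
) -> tuple[ExpressionDataset, ExpressionDataset, dict]:
    """Draw cohorts A and B plus the planted ground truth.

    Returns (A, B, ground_truth) where ground_truth records the twin
    block, each disease-specific block, noise genes and the
    outcome-driving signal genes, all as gene identifiers.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    gene_ids = sc.gene_ids

    # block design: loadings per cohort; twin identical, specific re-signed
    blocks = [list(sc.twin_block)] + [list(b) for b in sc.specific_blocks]
    rhos = [sc.rho_twin] + [sc.rho_specific] * len(sc.specific_blocks)
    load_a: dict[int, float] = {}
    load_b: dict[int, float] = {}
    block_of: dict[int, int] = {}
    rho_of: dict[int, float] = {}
    for b_idx, (members, rho) in enumerate(zip(blocks, rhos)):
        root = np.sqrt(rho)
        for j in members:
            block_of[j] = b_idx
            rho_of[j] = rho
            load_a[j] = root
        if b_idx == 0:
            for j in members:
                load_b[j] = root  # twin: same structure in both cohorts
        else:
            flipped = rng.permutation(members)[: len(members) // 2]
            flip = set(int(x) for x in flipped)
            for j in members:
                load_b[j] = -root if j in flip else root

    def _cohort(n: int, tumor_fraction: float, loadings: dict[int, float], tag: str):
        X = _draw_cohort(rng, n, sc.p, loadings, block_of, len(blocks), rho_of)
        b0 = np.log(tumor_fraction / (1.0 - tumor_fraction))
        eta = b0 + sc.effect_size * X[:, list(sc.signal_genes)].sum(axis=1)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        values = np.exp(X) if sc.mode == "lognormal" else X
        return ExpressionDataset(
            values,
            [f"{tag}_s{i + 1:04d}" for i in range(n)],
            list(gene_ids),
            labels=y,
            cohort=tag,
        )

    ds_a = _cohort(sc.n_a, sc.tumor_fraction_a, load_a, "A")
    ds_b = _cohort(sc.n_b, sc.tumor_fraction_b, load_b, "B")

    in_block = set(block_of)
    ground_truth = {
        "twin_genes": [gene_ids[j] for j in sc.twin_block],
        "specific_genes": [
            [gene_ids[j] for j in blk] for blk in sc.specific_blocks
        ],
        "noise_genes": [gene_ids[j] for j in range(sc.p) if j not in in_block],
        "signal_genes": sc.signal_gene_ids,
        "flipped_in_b": sorted(
            gene_ids[j] for j in load_b if load_b[j] != load_a[j]
        ),
    }
    return ds_a, ds_b, ground_truth


def generate_survival(
    expr: ExpressionDataset,
    signature: Sequence[str],
    hazard_coefs: np.ndarray,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential survival times driven by a gene signature.

    Event times are Exp(baseline_rate * exp(sum_j coef_j * x_j)) per
    sample, censoring times independent Exp(censor_rate); the observed
    time is the minimum and the event indicator marks which came first.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    sig = list(signature)
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in sig if g not in idx]
    if missing:
        raise ValueError(f"signature genes absent from dataset: {missing[:5]}")
    coefs = np.asarray(hazard_coefs, dtype=float)
    if coefs.shape != (len(sig),):
        raise ValueError("hazard_coefs must align with the signature")
    rng = np.random.default_rng(seed)
    lp = expr.values[:, [idx[g] for g in sig]] @ coefs
    rate = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / censor_rate, size=expr.n_samples)
    return SurvivalTable(
        sample_ids=list(expr.sample_ids),
        time=np.minimum(t_event, t_cens),
        event=(t_event <= t_cens).astype(int),
    )
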