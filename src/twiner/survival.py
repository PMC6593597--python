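"""Survival-based validation of a gene signature.

A consensus signature is validated downstream on tumor samples: a Cox
proportional-hazards model is fitted on the signature genes jointly, the
fitted relative risk exp(X beta) splits samples at its median into high-
and low-risk groups, and a two-group log-rank test (chi-squared with 1
degree of freedom) asks whether the Kaplan-Meier survival curves differ.

The Cox fit uses the Breslow tie approximation and an optional small
ridge term (default 1e-4) to stabilize signatures of many genes against
few events; set ``ridge_eps=0`` to force the unpenalized fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .datasets import ExpressionDataset, SurvivalTable

__all__ = ["RiskStratification", "stratify_and_test", "km_curve", "write_risk"]


@dataclass(frozen=True)
class RiskStratification:
    """Median-risk dichotomization with KM curves and the log-rank test."""

    sample_ids: list[str]
    relative_risk: np.ndarray
    group: np.ndarray  # "high" / "low" per sample
    km_curves: pd.DataFrame  # columns: group, time, survival, n_at_risk
    logrank_stat: float
    logrank_p: float
    cox_coefficients: pd.Series


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier step function with at-risk counts (starts at S(0)=1)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "n_at_risk": at_risk.to_numpy(dtype=int),
        }
    )


def stratify_and_test(
    expr: ExpressionDataset,
    surv: SurvivalTable,
    signature: Sequence[str],
    ridge_eps: float = 1e-4,
) -> RiskStratification:
    """Cox fit on a signature, median-risk split, KM curves, log-rank test.

    ``expr`` should hold tumor samples only; ``surv`` sample ids must be
    a subset of the expression samples (alignment is by identifier). The
    exact-median sample, and any sample tied with the median risk, goes
    to the low-risk group.
    """
    signature = list(signature)
    if not signature:
        raise ValueError("signature is empty")
    gene_idx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in signature if g not in gene_idx]
    if missing:
        raise ValueError(f"signature genes absent from expression data: {missing[:5]}")
    sample_idx = {s: i for i, s in enumerate(expr.sample_ids)}
    unknown = [s for s in surv.sample_ids if s not in sample_idx]
    if unknown:
        raise ValueError(f"survival samples absent from expression data: {unknown[:5]}")
    if int(surv.event.sum()) < 2:
        raise ValueError("need at least 2 observed events for the log-rank test")

    rows = [sample_idx[s] for s in surv.sample_ids]
    X = expr.values[np.ix_(rows, [gene_idx[g] for g in signature])]
    frame = pd.DataFrame(X, columns=signature)

    cox = CoxPHSurvivalAnalysis(alpha=ridge_eps, ties="breslow")
    cox.fit(frame, Surv.from_arrays(surv.event.astype(bool), surv.time))
    beta = pd.Series(cox.coef_, index=signature, name="coefficient")

    lp = X @ beta.to_numpy()
    rr = np.exp(lp)
    high = rr > np.median(rr)  # ties (and the exact median) go low
    if not high.any():
        raise ValueError(
            "fitted relative risks are constant; median split cannot stratify"
        )
    group = np.where(high, "high", "low")

    curves = []
    for g in ("high", "low"):
        mask = group == g
        c = km_curve(surv.time[mask], surv.event[mask])
        c.insert(0, "group", g)
        curves.append(c)
    km = pd.concat(curves, ignore_index=True)

    lr = logrank_test(
        surv.time[high], surv.time[~high], surv.event[high], surv.event[~high]
    )
    return RiskStratification(
        sample_ids=list(surv.sample_ids),
        relative_risk=rr,
        group=group,
        km_curves=km,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        cox_coefficients=beta,
    )


def write_risk(result: RiskStratification, outdir: str | Path) -> None:
    """Write risk.tsv, km.tsv and logrank.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": result.sample_ids,
            "relative_risk": result.relative_risk,
            "group": result.group,
        }
    ).to_csv(outdir / "risk.tsv", sep="\t", index=False)
    result.km_curves.to_csv(outdir / "km.tsv", sep="\t", index=False)
    (outdir / "logrank.txt").write_text(
        f"statistic\t{result.logrank_stat:.10g}\ndf\t1\np\t{result.logrank_p:.10g}\n"
    )
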