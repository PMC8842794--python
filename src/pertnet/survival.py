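"""Univariate Cox screening and Kaplan–Meier median-split comparison.

The Cox solver maximizes the single-covariate partial likelihood by
Newton–Raphson with the Efron correction for tied event times, converging
when the step falls below 1e-8 (at most 50 iterations). The covariate is
the gene's expression, standardized to unit variance by default so betas
are per-SD log hazard ratios. Screening calls a gene survival-related at a
strict Wald p < 0.05.

Kaplan–Meier display dichotomizes the cohort at the median expression
(strictly above the median = high group) and compares the groups with the
log-rank test; both are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import DataError
from .io import SurvivalCohort

logger = logging.getLogger(__name__)

MAX_ITER = 50
TOL = 1e-8


@dataclass
class CoxResult:
    gene: str
    beta: float
    se: float
    z: float
    p: float
    direction: str  # "high expression, worse survival" when HR > 1
    converged: bool

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, survival) step function
    logrank_statistic: float
    logrank_p: float
    group_sizes: dict[str, int]
    median_cut: float


def _efron_derivatives(
    beta: float,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
) -> tuple[float, float, float]:
    """Partial log-likelihood, score and information at beta (Efron ties).

    Inputs must be sorted by ascending time.
    """
    eta = beta * x
    w = np.exp(eta)
    xw = x * w
    xxw = x * x * w
    # suffix sums: risk set at time t = samples with time >= t
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(xw[::-1])[::-1]
    s2 = np.cumsum(xxw[::-1])[::-1]

    ll = 0.0
    score = 0.0
    info = 0.0
    n = len(x)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        d = len(d_idx)
        if d:
            s0r, s1r, s2r = s0[i], s1[i], s2[i]
            s0d = float(np.sum(w[d_idx]))
            s1d = float(np.sum(xw[d_idx]))
            s2d = float(np.sum(xxw[d_idx]))
            ll += float(np.sum(eta[d_idx]))
            for l in range(d):
                f = l / d
                phi0 = s0r - f * s0d
                phi1 = s1r - f * s1d
                phi2 = s2r - f * s2d
                ll -= np.log(phi0)
                score -= phi1 / phi0
                info += phi2 / phi0 - (phi1 / phi0) ** 2
            score += float(np.sum(x[d_idx]))
        i = j
    return ll, score, info


def cox_fit(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float, bool]:
    """Newton–Raphson MLE of the univariate Cox beta; returns (beta, se, converged)."""
    order = np.argsort(time, kind="mergesort")
    t = np.asarray(time, dtype=float)[order]
    e = np.asarray(event, dtype=int)[order]
    xs = np.asarray(x, dtype=float)[order]
    if e.sum() == 0:
        raise DataError("no events in cohort")
    if np.std(xs) == 0:
        raise DataError("no variation in covariate")
    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(MAX_ITER):
        _, score, info = _efron_derivatives(beta, xs, t, e)
        if info <= 0:
            break
        step = score / info
        # dampen huge steps to keep the iteration stable
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < TOL:
            converged = True
            break
    if not converged or abs(beta) > 15:
        converged = False
        logger.warning(
            "cox_fit: no finite maximum reached (monotone likelihood?); "
            "beta reported at last iterate %.3f", beta,
        )
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return float(beta), float(se), converged


def cox_univariate(
    cohort: SurvivalCohort, gene: str, standardize: bool = True
) -> CoxResult:
    """Univariate Cox proportional-hazards fit of survival on one gene."""
    x = cohort.covariate(gene)
    if np.std(x) == 0:
        raise DataError(f"no variation in covariate for gene {gene!r}")
    if standardize:
        x = (x - x.mean()) / x.std()
    beta, se, converged = cox_fit(
        cohort.time.to_numpy(), cohort.event.to_numpy(), x
    )
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = (
        "high expression, worse survival" if beta > 0
        else "high expression, better survival"
    )
    return CoxResult(gene=gene, beta=beta, se=se, z=z, p=p,
                     direction=direction, converged=converged)


def cox_screen(
    cohort: SurvivalCohort, genes: Iterable[str], standardize: bool = True
) -> list[CoxResult]:
    """Univariate Cox fit per gene; genes that cannot be fit are skipped with a log entry."""
    out: list[CoxResult] = []
    for g in genes:
        try:
            out.append(cox_univariate(cohort, g, standardize=standardize))
        except DataError as exc:
            logger.info("cox_screen: skipping %s (%s)", g, exc)
    return out


def classify_survival_related(
    results: Iterable[CoxResult], p_max: float = 0.05
) -> set[str]:
    """Genes with Wald p strictly below p_max."""
    return {r.gene for r in results if r.p < p_max}


def km_median_split(cohort: SurvivalCohort, gene: str) -> KMResult:
    """Kaplan–Meier curves for the high (> median) vs low (<= median) groups
    with a two-group log-rank test."""
    x = cohort.covariate(gene)
    med = float(np.median(x))
    high = x > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise DataError(
            f"no split: median dichotomization of {gene!r} leaves a group with <2 samples"
        )
    t = cohort.time.to_numpy()
    e = cohort.event.to_numpy()
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for label, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask], label=label)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf[label].to_numpy(dtype=float)}
        )
        sizes[label] = int(mask.sum())
    lr = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    return KMResult(
        curves=curves,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        group_sizes=sizes,
        median_cut=med,
    )


def cox_results_frame(results: Iterable[CoxResult]) -> pd.DataFrame:
    rows = [
        (r.gene, r.beta, r.se, r.z, r.p, r.hazard_ratio, r.direction, r.converged)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "beta", "se", "z", "p", "hr", "direction", "converged"],
    ).set_index("gene")
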