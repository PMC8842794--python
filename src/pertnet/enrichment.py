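"""Gene-set over-representation (hypergeometric) and preranked GSEA.

Over-representation uses the upper-tail hypergeometric probability
P(X >= k) of drawing k or more set members among the n query genes from a
universe of N genes containing K set members. The universe defaults to the
genes actually measured, not all annotated genes. Sets are reported only
when the overlap reaches ``min_overlap`` (filtering happens before testing)
and can be called significant either on BH FDR (GO-style) or on the raw p
(KEGG-style).

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum: walking
down the ranking, a hit adds \\|r\\|^weight normalized by the set's total
\\|r\\|^weight and a miss subtracts 1/(N - K); the enrichment score ES is the
signed maximum deviation of the running sum. The null is built from random
same-size gene sets; NES divides ES by the mean \\|null ES\\| of matching
sign, and the p-value is the add-one empirical tail proportion among nulls
of that sign, BH-adjusted across sets.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr, deg_genes
from .errors import ParameterError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_overrep(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ParameterError(
            f"invalid hypergeometric bounds: N={N}, K={K}, n={n}, k={k}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    degs: pd.DataFrame | Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    min_overlap: int = 5,
    mode: str = "fdr",
    fdr_max: float = 0.05,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of DEGs in each gene set.

    ``degs`` may be a DEG table (rows with ``is_deg`` are used) or a plain
    gene collection. Rows are reported for sets whose overlap with the query
    is at least ``min_overlap``; ``significant`` is FDR < fdr_max in ``fdr``
    mode or raw p < p_max in ``raw`` mode (both strict, matching the
    reported thresholds "FDR < 0.05" and "p < 0.05").
    """
    if mode not in ("fdr", "raw"):
        raise ParameterError(f"unknown significance mode {mode!r}")
    query = deg_genes(degs) if isinstance(degs, pd.DataFrame) else set(degs)
    uni = set(universe)
    if not uni:
        raise ParameterError("empty universe")
    stray = query - uni
    if stray:
        raise ParameterError(f"query genes outside the universe: {sorted(stray)[:10]}")
    N, n = len(uni), len(query)
    rows = []
    for name in sets:
        members = sets.members(name) & uni
        overlap = members & query
        k = len(overlap)
        if k < min_overlap:
            continue
        p = hypergeom_overrep(N, len(members), n, k)
        rows.append((name, N, len(members), n, k, p, ",".join(sorted(overlap))))
    df = pd.DataFrame(
        rows, columns=["set", "N", "K", "n", "k", "p", "overlap"]
    ).set_index("set")
    if len(df):
        df.insert(5, "fdr", bh_fdr(df["p"].to_numpy()))
        df["significant"] = (
            df["fdr"] < fdr_max if mode == "fdr" else df["p"] < p_max
        )
        df = df.sort_values(["p", "set"], kind="mergesort")
    else:
        df.insert(5, "fdr", pd.Series(dtype=float))
        df["significant"] = pd.Series(dtype=bool)
    return df


def _running_es(order_scores: np.ndarray, hit: np.ndarray, weight: float) -> tuple[float, int]:
    """Signed max deviation of the weighted KS running sum; returns (ES, argmax)."""
    absw = np.abs(order_scores) ** weight
    denom = absw[hit].sum()
    n = len(order_scores)
    k = int(hit.sum())
    step = np.where(hit, absw / denom if denom > 0 else 1.0 / k, -1.0 / (n - k))
    run = np.cumsum(step)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def gsea_preranked(
    ranked: Mapping[str, float] | pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Preranked GSEA over a gene → log2 fold-change ranking.

    Sets with fewer than ``min_size`` ranked members, or covering the whole
    ranking (miss increment undefined), are skipped with a log entry. The
    permutation null draws random same-size gene sets from the ranking.
    """
    s = pd.Series(ranked, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ParameterError("ranking scores must be finite")
    # sort by score descending, gene name as deterministic tie-break
    s = s.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    genes = np.array(s.index)
    scores = s.to_numpy()
    n = len(genes)
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name in sets:
        idx = np.array(sorted(pos_of[g] for g in sets.members(name) if g in pos_of))
        k = len(idx)
        if k < min_size:
            logger.info("gsea_preranked: skipping %s (<%d ranked members)", name, min_size)
            continue
        if k == n:
            logger.info("gsea_preranked: skipping %s (covers whole ranking)", name)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es, peak = _running_es(scores, hit, weight)
        if es >= 0:
            lead = [g for g in genes[: peak + 1] if pos_of[g] in set(idx)]
        else:
            lead = [g for g in genes[peak:] if pos_of[g] in set(idx)]

        null = np.empty(n_perm)
        absw = np.abs(scores) ** weight
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        for j in range(n_perm):
            h = np.zeros(n, dtype=bool)
            h[perm_idx[j]] = True
            denom = absw[h].sum()
            step = np.where(h, absw / denom if denom > 0 else 1.0 / k, -1.0 / (n - k))
            run = np.cumsum(step)
            null[j] = run[np.argmax(np.abs(run))]

        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same):
            nes = es / np.mean(np.abs(same))
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
        else:
            nes, p = np.nan, 1.0
        rows.append((name, k, es, nes, p, ",".join(lead)))

    df = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "p", "leading_edge"]
    ).set_index("set")
    if len(df):
        df.insert(4, "fdr", bh_fdr(df["p"].to_numpy()))
        df = df.sort_values(["p", "set"], kind="mergesort")
    else:
        df.insert(4, "fdr", pd.Series(dtype=float))
    return df


def significant_gsea(df: pd.DataFrame, fdr_max: float = 0.05, nes_min: float = 1.0) -> pd.DataFrame:
    """Filter GSEA rows: BH-adjusted p below cutoff and |NES| >= nes_min."""
    return df[(df["fdr"] < fdr_max) & (df["nes"].abs() >= nes_min)]
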