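"""Per-gene differential expression for intensity and count designs.

The intensity route is a classical pooled-variance (Student) two-sample
t-test on log2 intensities; fold-change is linear, ``2**(mean_b - mean_a)``,
with direction relative to the treated group. Probe-level tables are
collapsed to one row per gene by keeping the most significant probe. The
DEG filter is inclusive: p <= p_max AND (FC >= fc_min OR FC <= 1/fc_min).

The count route normalizes to log2 counts-per-million with a 0.5
pseudocount, applies a Welch t-test, and calls DEGs at a Benjamini–Hochberg
FDR cutoff. This stands in for count-GLM machinery deliberately: the
logCPM + Welch + BH combination is documented, dependency-free, and
adequate for cohort-scale group sizes.

Degenerate genes (zero variance in both groups with unequal means) are kept
in the table flagged ``degenerate`` with NaN statistics; they are never
called DEGs and their count is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError
from .io import COUNTS, INTENSITY, ExpressionMatrix

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["statistic", "p", "fdr", "fc", "log2_fc", "direction", "degenerate", "is_deg"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _assemble(index, stat, p, log2_fc, degenerate) -> pd.DataFrame:
    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        fdr[ok] = bh_fdr(p[ok])
    df = pd.DataFrame(
        {
            "statistic": stat,
            "p": p,
            "fdr": fdr,
            "fc": 2.0 ** log2_fc,
            "log2_fc": log2_fc,
            "direction": np.where(log2_fc > 0, "up", "down"),
            "degenerate": degenerate,
            "is_deg": False,
        },
        index=index,
    )
    return df


def ttest_fold_change(
    expr: ExpressionMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Unfiltered pooled-variance t-test table, direction relative to group_b.

    ``group_a`` is the reference (control), ``group_b`` the treated group;
    log2 fold-change is ``mean_b - mean_a`` of the log2 intensities.
    """
    if expr.flavor != INTENSITY:
        raise ParameterError("ttest_fold_change requires an intensity matrix")
    sa = expr.samples_in_group(group_a)
    sb = expr.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ParameterError("each group needs >= 2 samples")
    a = expr.values[sa].to_numpy(dtype=float)
    b = expr.values[sb].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df_ = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df_
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mb - ma

    stat = np.full(len(diff), np.nan)
    p = np.full(len(diff), np.nan)
    degenerate = np.zeros(len(diff), dtype=bool)
    pos = se > 0
    stat[pos] = diff[pos] / se[pos]
    p[pos] = 2.0 * stats.t.sf(np.abs(stat[pos]), df_)
    zero = ~pos
    eq = zero & (diff == 0)
    stat[eq] = 0.0
    p[eq] = 1.0
    degenerate = zero & (diff != 0)
    if degenerate.any():
        logger.info("ttest_fold_change: %d zero-variance genes with unequal "
                    "means excluded from testing", int(degenerate.sum()))
    return _assemble(expr.values.index, stat, p, diff, degenerate)


def collapse_probes(table: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse a probe-level table to one row per gene.

    Per gene the probe with the smallest raw p survives; ties are broken by
    larger \\|log2 fold-change\\|, then lexicographically smallest probe id.
    Probes without a gene mapping are dropped with a logged count.
    """
    if table.empty:
        return table.copy()
    mapped = table.index.isin(probe_to_gene)
    dropped = int((~mapped).sum())
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    t = table.loc[mapped].copy()
    if t.empty:
        return t
    t["probe"] = t.index
    t["gene"] = [probe_to_gene[p] for p in t.index]
    t["_p"] = t["p"].fillna(np.inf)
    t["_absfc"] = -t["log2_fc"].abs()
    t = t.sort_values(["gene", "_p", "_absfc", "probe"], kind="mergesort")
    t = t.drop_duplicates("gene", keep="first")
    t = t.set_index("gene").drop(columns=["_p", "_absfc"])
    t.index.name = "gene"
    return t


def call_degs(table: pd.DataFrame, p_max: float = 0.05, fc_min: float = 1.5) -> pd.DataFrame:
    """Flag DEGs: p <= p_max and linear FC >= fc_min or <= 1/fc_min (inclusive)."""
    if fc_min < 1:
        raise ParameterError("fc_min must be >= 1")
    out = table.copy()
    p_ok = out["p"].to_numpy() <= p_max
    fc = out["fc"].to_numpy()
    fc_ok = (fc >= fc_min) | (fc <= 1.0 / fc_min)
    out["is_deg"] = p_ok & fc_ok & ~out["degenerate"].to_numpy()
    return out


def _effective_library_sizes(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors rescaled to the raw library-size scale.

    Falls back to raw totals when no gene is expressed in every sample.
    """
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        return lib
    logref = np.log(counts[expressed]).mean(axis=1)
    sf = np.exp(np.median(np.log(counts[expressed]) - logref[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf * lib.mean()


def count_degs(
    expr: ExpressionMatrix,
    fdr_max: float = 0.05,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Cohort count differential expression at an FDR cutoff.

    Library-size normalization to log2 CPM (+0.5 pseudocount), per-gene
    Welch t-test between the two groups, BH adjustment; ``is_deg`` is
    FDR <= fdr_max (inclusive). Effective library sizes are median-of-ratios
    size factors rather than raw totals: when a sizeable fraction of genes
    truly changes, total counts shift systematically in one group and plain
    CPM paints every other gene as anti-changed (the composition effect);
    the median ratio against a geometric-mean reference is robust to it.
    Groups default to the matrix's two labels in sorted order
    (a = reference, b = contrast), so a tumor/normal cohort reports
    tumor-vs-normal direction.
    """
    if expr.flavor != COUNTS:
        raise ParameterError("count_degs requires a counts matrix")
    labels = sorted(set(expr.group_of.values()))
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ParameterError("matrix must have exactly two groups")
        group_a, group_b = labels
    sa = expr.samples_in_group(group_a)
    sb = expr.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ParameterError("each group needs >= 2 samples")
    counts = expr.values.to_numpy(dtype=float)
    if counts.size == 0:
        return _assemble(expr.values.index, np.array([]), np.array([]),
                         np.array([]), np.array([], dtype=bool))
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [expr.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise DataError(f"samples with zero total count: {bad}")
    lib = _effective_library_sizes(counts, lib)
    logcpm = np.log2(counts / lib[None, :] * 1e6 + 0.5)
    x = pd.DataFrame(logcpm, index=expr.values.index, columns=expr.sample_ids)
    a = x[sa].to_numpy()
    b = x[sb].to_numpy()
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    na, nb = a.shape[1], b.shape[1]
    diff = mb - ma
    sem2 = va / na + vb / nb

    stat = np.full(len(diff), np.nan)
    p = np.full(len(diff), np.nan)
    pos = sem2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dof = sem2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    stat[pos] = diff[pos] / np.sqrt(sem2[pos])
    p[pos] = 2.0 * stats.t.sf(np.abs(stat[pos]), dof[pos])
    zero = ~pos
    eq = zero & (diff == 0)
    stat[eq] = 0.0
    p[eq] = 1.0
    degenerate = zero & (diff != 0)
    out = _assemble(expr.values.index, stat, p, diff, degenerate)
    out["is_deg"] = (out["fdr"] <= fdr_max).fillna(False) & ~out["degenerate"]
    return out


def deg_genes(table: pd.DataFrame) -> set[str]:
    """Convenience: the set of genes flagged as DEGs."""
    return set(table.index[table["is_deg"]])


def write_deg_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in ["probe", *DEG_COLUMNS] if c in table.columns]
    table[cols].to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    for col in ("degenerate", "is_deg"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
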