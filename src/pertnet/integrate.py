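"""Cross-cohort concordance, survival×perturbation contingency and
upstream-regulator nomination.

Concordance intersects two direction-annotated DEG tables. Two modes exist
because a drug that reverses a disease signature can be bookkept either
way: ``same`` counts genes moving in the same direction in both tables
(common-up / common-down bookkeeping), ``reversal`` counts genes whose drug
direction opposes their tumor-vs-normal direction. The default is ``same``.

The contingency step crosses survival-related against drug-altered
membership among a DEG background and scores enrichment with a one-sided
Fisher exact test.

Regulator nomination is a pure rule filter over four evidence fields: Wald
p < 0.05, hazard ratio > 1, up-regulated in the tumor cohort, and
down-regulated by the drug. No scoring or weighting is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .errors import DataError, ParameterError
from .io import TFTargetMap
from .survival import CoxResult

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    mode: str
    common: set[str]
    common_down: set[str]
    common_up: set[str]
    concordant: set[str]
    discordant: set[str]

    @property
    def concordant_total(self) -> int:
        return len(self.concordant)


@dataclass
class ContingencyResult:
    table: np.ndarray  # rows: survival yes/no, cols: drug-altered yes/no
    odds_ratio: float
    p: float
    warning: str | None = None


@dataclass
class Candidate:
    regulator: str
    cox_p: float
    hazard_ratio: float
    tumor_direction: str
    drug_direction: str


def _directions(table: pd.DataFrame, genes: set[str]) -> dict[str, str]:
    sub = table.loc[table.index.isin(genes)]
    if sub["direction"].isna().any():
        bad = list(sub.index[sub["direction"].isna()])[:5]
        raise DataError(f"genes with missing direction: {bad}")
    return dict(sub["direction"])


def intersect_concordant(
    a: pd.DataFrame, b: pd.DataFrame, mode: str = "same"
) -> ConcordanceResult:
    """Intersect two DEG tables and classify shared genes by direction.

    ``a`` is the drug-perturbation table, ``b`` the cohort table; only rows
    flagged ``is_deg`` enter. common_down / common_up always record genes
    down (resp. up) in BOTH tables; ``concordant`` depends on the mode.
    """
    if mode not in ("same", "reversal"):
        raise ParameterError(f"unknown concordance mode {mode!r}")
    degs_a = set(a.index[a["is_deg"]])
    degs_b = set(b.index[b["is_deg"]])
    common = degs_a & degs_b
    dir_a = _directions(a, common)
    dir_b = _directions(b, common)
    common_down = {g for g in common if dir_a[g] == "down" and dir_b[g] == "down"}
    common_up = {g for g in common if dir_a[g] == "up" and dir_b[g] == "up"}
    if mode == "same":
        concordant = common_down | common_up
    else:
        concordant = {g for g in common if dir_a[g] != dir_b[g]}
    return ConcordanceResult(
        mode=mode,
        common=common,
        common_down=common_down,
        common_up=common_up,
        concordant=concordant,
        discordant=common - concordant,
    )


def survival_contingency(
    all_degs: Iterable[str],
    survival_related: Iterable[str],
    drug_altered: Iterable[str],
) -> ContingencyResult:
    """2×2 survival-related × drug-altered membership among the DEG background,
    with a one-sided Fisher exact test for over-representation of
    drug-altered genes among the survival-related ones."""
    background = set(all_degs)
    if not background:
        raise ParameterError("empty DEG background")
    surv = set(survival_related)
    drug = set(drug_altered)
    stray = (surv | drug) - background
    if stray:
        raise ParameterError(
            f"sets must be subsets of the DEG background; stray: {sorted(stray)[:10]}"
        )
    a = len(surv & drug)
    b = len(surv - drug)
    c = len(drug - surv)
    d = len(background - surv - drug)
    table = np.array([[a, b], [c, d]])
    warning = None
    if not surv or not drug or surv == background or drug == background:
        warning = "degenerate margin: no enrichment is testable"
        logger.warning("survival_contingency: %s", warning)
    odds, p = fisher_exact(table, alternative="greater")
    return ContingencyResult(table=table, odds_ratio=float(odds), p=float(p),
                             warning=warning)


def rank_regulators(
    tf_map: TFTargetMap, pathway_degs: Iterable[str]
) -> list[tuple[str, int]]:
    """Regulators ranked by how many pathway DEGs they target.

    Sorted by descending target count, ties broken lexicographically.
    """
    degs = set(pathway_degs)
    counts = [(reg, len(tf_map.targets[reg] & degs)) for reg in tf_map.targets]
    return sorted(counts, key=lambda rc: (-rc[1], rc[0]))


def nominate_candidates(
    regulators: Iterable[str],
    cox: Iterable[CoxResult],
    tumor_degs: pd.DataFrame,
    drug_degs: pd.DataFrame,
    p_max: float = 0.05,
) -> list[Candidate]:
    """Keep regulators that satisfy all four evidence rules.

    (i) Cox Wald p < p_max; (ii) hazard ratio above 1 (high expression,
    worse survival); (iii) up-regulated DEG in the tumor cohort table;
    (iv) down-regulated DEG in the drug table. A regulator absent from any
    evidence table is excluded and logged as not evaluable.
    """
    cox_by_gene = {r.gene: r for r in cox}
    out: list[Candidate] = []
    for reg in regulators:
        if reg not in cox_by_gene:
            logger.info("nominate_candidates: %s not evaluable (no Cox fit)", reg)
            continue
        if reg not in tumor_degs.index or reg not in drug_degs.index:
            logger.info("nominate_candidates: %s not evaluable (missing DEG row)", reg)
            continue
        r = cox_by_gene[reg]
        tum = tumor_degs.loc[reg]
        drg = drug_degs.loc[reg]
        if (
            r.p < p_max
            and r.beta > 0
            and bool(tum["is_deg"]) and tum["direction"] == "up"
            and bool(drg["is_deg"]) and drg["direction"] == "down"
        ):
            out.append(
                Candidate(
                    regulator=reg,
                    cox_p=r.p,
                    hazard_ratio=r.hazard_ratio,
                    tumor_direction=str(tum["direction"]),
                    drug_direction=str(drg["direction"]),
                )
            )
    return out
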