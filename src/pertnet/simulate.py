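"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and an integer seed: a
dedicated ``numpy.random.Generator`` is created per call, never global
state, so stage reordering cannot change results.

The generators emulate the statistical structure the downstream stages
assume, not any particular platform:

* :func:`simulate_perturbation` — a small treated/control log2-intensity
  experiment with planted fold-changes (default 3 vs 3 replicates; the
  down/up sign split defaults to 76%/24%, the ratio typical of a
  growth-suppressing drug perturbation).
* :func:`simulate_cohort` — a tumor/normal negative-binomial count cohort.
* :func:`simulate_survival` — exponential event times whose hazard is
  log-linear in standardized expression of designated risk genes
  (proportional hazards holds exactly), with administrative censoring.
* :func:`simulate_network` — a Barabási–Albert scale-free graph with an
  optional planted dense module.
* :func:`simulate_gene_sets` — pathway-like gene sets with controllable
  overlap with the planted differentially expressed genes.

Ground truth travels alongside every simulated object in a
:class:`SimulationTruth` so recovery tests can score the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import COUNTS, INTENSITY, ExpressionMatrix, GeneSetCollection, SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated object.

    ``genes`` is a DataFrame indexed by gene with columns ``is_de``,
    ``true_lfc`` and ``true_beta`` (zero where not applicable).
    """

    genes: pd.DataFrame
    planted_module: list[str] = field(default_factory=list)
    enriched_sets: dict[str, float] = field(default_factory=dict)

    @property
    def de_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_de"]])


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"GENE{i:0{width}d}" for i in range(n)]


def _truth_frame(genes: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"is_de": False, "true_lfc": 0.0, "true_beta": 0.0},
        index=pd.Index(genes, name="gene"),
    )


def _planted_lfcs(
    rng: np.random.Generator, n_de: int, lfc_location: float, down_fraction: float
) -> np.ndarray:
    """Signed log2 fold-changes: magnitude lognormal around the location,
    sign split down/up at the requested fraction."""
    mags = lfc_location * rng.lognormal(mean=0.0, sigma=0.2, size=n_de)
    n_down = int(round(down_fraction * n_de))
    signs = np.array([-1.0] * n_down + [1.0] * (n_de - n_down))
    rng.shuffle(signs)
    return mags * signs


def simulate_perturbation(
    n_genes: int = 1000,
    n_per_group: int = 3,
    de_fraction: float = 0.05,
    lfc_location: float = 2.0,
    sigma: float = 0.5,
    seed: int = 0,
    down_fraction: float = 0.76,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Two-group treated/control log2-intensity matrix with planted effects.

    Each gene gets a baseline ~ U(6, 12); treated samples of DE genes are
    shifted by the planted log2 fold-change; i.i.d. Gaussian noise with
    standard deviation ``sigma`` is added everywhere.
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2 (the t-test needs replicates)")
    if not 0.0 <= de_fraction <= 1.0:
        raise ParameterError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    truth = _truth_frame(genes)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfcs = np.zeros(n_genes)
    if n_de:
        lfcs[de_idx] = _planted_lfcs(rng, n_de, lfc_location, down_fraction)
    truth.iloc[de_idx, truth.columns.get_loc("is_de")] = True
    truth["true_lfc"] = lfcs

    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    ctrl = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_per_group))
    trt = (
        baseline[:, None]
        + lfcs[:, None]
        + rng.normal(0.0, sigma, size=(n_genes, n_per_group))
    )
    samples = [f"trt{i + 1}" for i in range(n_per_group)] + [
        f"ctrl{i + 1}" for i in range(n_per_group)
    ]
    values = pd.DataFrame(
        np.hstack([trt, ctrl]), index=pd.Index(genes, name="gene"), columns=samples
    )
    groups = {s: ("treated" if s.startswith("trt") else "control") for s in samples}
    em = ExpressionMatrix(values=values, group_of=groups, flavor=INTENSITY)
    return em, SimulationTruth(genes=truth)


def simulate_cohort(
    n_tumor: int = 100,
    n_normal: int = 50,
    n_genes: int = 2000,
    de_fraction: float = 0.05,
    dispersion: float = 0.1,
    seed: int = 0,
    lfc_location: float = 1.0,
    down_fraction: float = 0.36,
    lfc_of: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Tumor/normal negative-binomial count cohort with planted fold-changes.

    Counts are NB with gene-specific lognormal base means, a common
    dispersion, lognormal per-sample library-size factors, and a tumor-group
    multiplier ``2**lfc`` on DE genes. ``lfc_of`` overrides the random truth
    with explicit per-gene tumor-vs-normal log2 fold-changes (used to wire a
    coherent multi-stage study).
    """
    if n_tumor < 2 or n_normal < 2:
        raise ParameterError("both group sizes must be >= 2")
    if dispersion <= 0:
        raise ParameterError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    truth = _truth_frame(genes)

    lfcs = np.zeros(n_genes)
    if lfc_of is not None:
        for g, v in lfc_of.items():
            if g not in truth.index:
                raise ParameterError(f"lfc_of names unknown gene {g!r}")
            lfcs[truth.index.get_loc(g)] = v
    else:
        n_de = int(round(de_fraction * n_genes))
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        if n_de:
            lfcs[de_idx] = _planted_lfcs(rng, n_de, lfc_location, down_fraction)
    truth["true_lfc"] = lfcs
    truth["is_de"] = lfcs != 0.0

    base = rng.lognormal(mean=5.0, sigma=1.0, size=n_genes)
    n_samples = n_tumor + n_normal
    size_factors = rng.lognormal(mean=0.0, sigma=0.15, size=n_samples)
    mult = np.ones((n_genes, n_samples))
    mult[:, :n_tumor] = 2.0 ** lfcs[:, None]
    lam = base[:, None] * mult * size_factors[None, :]
    shape = 1.0 / dispersion
    counts = rng.poisson(rng.gamma(shape, lam / shape))
    samples = [f"tumor{i + 1}" for i in range(n_tumor)] + [
        f"normal{i + 1}" for i in range(n_normal)
    ]
    values = pd.DataFrame(
        counts, index=pd.Index(genes, name="gene"), columns=samples, dtype=np.int64
    )
    groups = {s: ("tumor" if s.startswith("tumor") else "normal") for s in samples}
    em = ExpressionMatrix(values=values, group_of=groups, flavor=COUNTS)
    return em, SimulationTruth(genes=truth)


def simulate_survival(
    expr: ExpressionMatrix,
    risk_genes: dict[str, float],
    base_hazard: float = 0.1,
    censor_time: float = 20.0,
    seed: int = 0,
) -> SurvivalCohort:
    """Exponential survival times with hazard log-linear in expression.

    Per sample i the rate is ``base_hazard * exp(sum_g beta_g * z_g(i))``
    where z is the gene's expression standardized across samples. Times
    beyond ``censor_time`` are administratively censored (event = 0).
    """
    if base_hazard <= 0:
        raise ParameterError("base_hazard must be > 0")
    missing = [g for g in risk_genes if g not in expr.values.index]
    if missing:
        raise ParameterError(f"risk genes absent from expression: {missing}")
    rng = np.random.default_rng(seed)
    lin = np.zeros(len(expr.sample_ids))
    for g, beta in risk_genes.items():
        x = expr.values.loc[g].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ParameterError(f"risk gene {g!r} has constant expression")
        lin += beta * (x - x.mean()) / sd
    rate = base_hazard * np.exp(lin)
    t = rng.exponential(1.0 / rate)
    event = (t <= censor_time).astype(int)
    # survival times must stay positive even under immediate censoring
    t = np.minimum(t, max(censor_time, 1e-12))
    idx = pd.Index(expr.sample_ids, name="sample")
    return SurvivalCohort(
        time=pd.Series(t, index=idx),
        event=pd.Series(event, index=idx),
        expression=expr.values,
    )


def simulate_network(
    n_nodes: int = 2000,
    edges_per_node: int = 3,
    planted_module_size: int = 0,
    planted_density: float = 0.0,
    seed: int = 0,
    node_names: list[str] | None = None,
    planted_nodes: list[str] | None = None,
) -> tuple[nx.Graph, SimulationTruth]:
    """Scale-free (preferential attachment) graph with an optional planted
    dense module.

    The planted module nodes are additionally wired among themselves with
    uniformly chosen missing pairs until their internal edge density reaches
    ``planted_density``. ``planted_nodes`` pins the module onto named nodes;
    otherwise module nodes are drawn uniformly.
    """
    if node_names is not None and len(node_names) != n_nodes:
        raise ParameterError("node_names length must equal n_nodes")
    if planted_module_size > n_nodes:
        raise ParameterError("planted module larger than the network")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(
        n_nodes, edges_per_node, seed=int(rng.integers(2**31))
    )
    names = node_names if node_names is not None else _gene_names(n_nodes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))

    module: list[str] = []
    if planted_nodes is not None:
        missing = [n for n in planted_nodes if n not in g]
        if missing:
            raise ParameterError(f"planted nodes absent from network: {missing}")
        module = list(planted_nodes)
    elif planted_module_size > 0:
        module = [names[i] for i in rng.choice(n_nodes, planted_module_size, replace=False)]

    if module and planted_density > 0:
        background = nx.density(g)
        if planted_density < background:
            logger.warning(
                "planted_density %.4f below background density %.4f — module "
                "will not stand out", planted_density, background,
            )
        k = len(module)
        target = math.ceil(planted_density * k * (k - 1) / 2)
        pairs = [
            (module[i], module[j])
            for i in range(k)
            for j in range(i + 1, k)
            if not g.has_edge(module[i], module[j])
        ]
        have = k * (k - 1) // 2 - len(pairs)
        need = max(0, target - have)
        if need:
            chosen = rng.choice(len(pairs), size=min(need, len(pairs)), replace=False)
            g.add_edges_from(pairs[i] for i in chosen)

    truth = SimulationTruth(genes=_truth_frame(names), planted_module=module)
    return g, truth


def simulate_gene_sets(
    genes: list[str],
    de_genes: list[str],
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    enriched_sets: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[GeneSetCollection, SimulationTruth]:
    """Pathway-like gene sets with controllable DE overlap.

    Enriched sets (name → fraction) draw that fraction of their members from
    ``de_genes`` and the rest uniformly from the remaining genes; background
    sets are uniform draws from all genes. Total set count is ``n_sets``
    including the enriched ones.
    """
    lo, hi = set_size_range
    if lo < 5:
        raise ParameterError("set sizes below 5 cannot satisfy the min-overlap rule")
    if hi > len(genes):
        raise ParameterError("requested set size exceeds the gene universe")
    enriched_sets = enriched_sets or {}
    if len(enriched_sets) > n_sets:
        raise ParameterError("more enriched sets than n_sets")
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes)
    de_set = set(de_genes)
    non_de = np.array([g for g in genes if g not in de_set])
    de_arr = np.array(sorted(de_set & set(genes)))

    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for name, fraction in enriched_sets.items():
        if not 0.0 <= fraction <= 1.0:
            raise ParameterError(f"fraction for {name!r} must be in [0, 1]")
        size = int(rng.integers(lo, hi + 1))
        k_de = min(int(round(fraction * size)), len(de_arr))
        members = list(rng.choice(de_arr, size=k_de, replace=False)) if k_de else []
        rest = size - len(members)
        pool = non_de if len(non_de) >= rest else gene_arr
        extra = [g for g in rng.choice(pool, size=rest, replace=False) if g not in members]
        sets[name] = sorted(set(members) | set(extra))
        desc[name] = f"planted enriched set (DE fraction {fraction:g})"
    n_bg = n_sets - len(enriched_sets)
    for i in range(n_bg):
        name = f"PATH{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        sets[name] = sorted(rng.choice(gene_arr, size=size, replace=False))
        desc[name] = "background set"

    truth = SimulationTruth(
        genes=_truth_frame(list(genes)), enriched_sets=dict(enriched_sets)
    )
    return GeneSetCollection(sets=sets, descriptions=desc), truth


# ---------------------------------------------------------------------------
# coherent multi-stage study
# ---------------------------------------------------------------------------

@dataclass
class StudyInputs:
    """Every input of one coherent simulated study, plus ground truth.

    The scenario wires the stages together the way the analysis expects
    real data to be wired: the cohort's DE genes are the drug's DE genes
    with the opposite sign (the drug reverses the disease signature), the
    dense network module is planted on DE genes, enriched gene sets draw
    from the DE truth, and one designated regulator is tumor-up, drug-down
    and hazard-increasing so the nomination rules have a true positive.
    """

    perturbation: ExpressionMatrix
    perturbation_truth: SimulationTruth
    cohort: ExpressionMatrix
    cohort_truth: SimulationTruth
    survival: SurvivalCohort
    network: nx.Graph
    network_truth: SimulationTruth
    gene_sets: GeneSetCollection
    sets_truth: SimulationTruth
    tf_targets: "TFTargetMap"
    true_regulator: str
    module_set_names: list[str]


def simulate_study(
    seed: int,
    n_genes: int = 2000,
    n_per_group: int = 3,
    de_fraction: float = 0.05,
    lfc_location: float = 2.0,
    sigma: float = 0.5,
    n_tumor: int = 100,
    n_normal: int = 50,
    dispersion: float = 0.1,
    edges_per_node: int = 3,
    planted_module_size: int | None = None,
    planted_density: float = 0.04,
    n_sets: int = 20,
    regulator_beta: float = 1.0,
    base_hazard: float = 0.1,
    censor_time: float = 20.0,
    reversal_fraction: float = 0.3,
) -> StudyInputs:
    """Generate one coherent study across all five input kinds."""
    from .io import TFTargetMap  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(2**31, size=8)]

    pert, pert_truth = simulate_perturbation(
        n_genes=n_genes, n_per_group=n_per_group, de_fraction=de_fraction,
        lfc_location=lfc_location, sigma=sigma, seed=sub[0],
    )
    genes = list(pert.gene_ids)
    de = pert_truth.de_genes

    # cohort truth: most DE genes keep the drug's sign in the tumor-vs-normal
    # contrast (common up/down bookkeeping), a fraction is reversed — the
    # disease signature the drug pushes back. The regulator is drawn from
    # the reversed, drug-down genes (tumor-up, drug-down).
    n_rev = int(round(reversal_fraction * len(de)))
    reversed_genes = {
        str(g) for g in rng.choice(np.array(sorted(de)), size=n_rev, replace=False)
    } if n_rev else set()
    lfc_of = {
        g: (-1.0 if g in reversed_genes else 1.0)
        * float(pert_truth.genes.loc[g, "true_lfc"])
        for g in de
    }
    cohort, cohort_truth = simulate_cohort(
        n_tumor=n_tumor, n_normal=n_normal, n_genes=n_genes,
        dispersion=dispersion, seed=sub[1], lfc_of=lfc_of,
    )

    # gene sets: two planted pathway-like sets drawing half their members
    # from the drug-DOWN DE genes — pathways are co-regulated, so the
    # planted signal is direction-coherent and visible to the ranked GSEA
    de_down = [g for g in de if pert_truth.genes.loc[g, "true_lfc"] < 0]
    module_set_names = ["CELL_CYCLE", "DNA_REPLICATION"]
    gsc, sets_truth = simulate_gene_sets(
        genes, de_down, n_sets=n_sets, set_size_range=(15, 60),
        enriched_sets={name: 0.5 for name in module_set_names}, seed=sub[2],
    )

    # network: excess wiring planted across the DE genes so DEG groups
    # interact densely; a low density over the whole DE set (rather than a
    # small dense island) keeps the degree-preserving null's induced DEG
    # subgraph sub-critical, which is what makes the LCC statistic informative
    k = len(de) if planted_module_size is None else min(planted_module_size, len(de))
    planted = sorted(str(g) for g in rng.choice(np.array(de), size=k, replace=False)) if k else None
    net, net_truth = simulate_network(
        n_nodes=n_genes, edges_per_node=edges_per_node,
        planted_module_size=k, planted_density=planted_density,
        seed=sub[3], node_names=genes, planted_nodes=planted,
    )

    # regulator story: the true regulator is drug-down / tumor-up and
    # hazard-increasing; decoys are other DE genes
    reg_pool = sorted(set(de_down) & reversed_genes) or sorted(de_down)
    true_reg = reg_pool[int(rng.integers(len(reg_pool)))]
    decoys = [g for g in sorted(de) if g != true_reg]
    decoy_regs = [decoys[i] for i in
                  rng.choice(len(decoys), size=min(5, len(decoys)), replace=False)]
    pathway_genes = sorted(set(gsc.sets["DNA_REPLICATION"]) | set(gsc.sets["CELL_CYCLE"]))
    targets: dict[str, set[str]] = {}
    class_of: dict[str, str] = {}
    n_path = len(pathway_genes)
    for i, reg in enumerate([true_reg, *decoy_regs]):
        size = int(rng.integers(max(2, n_path // 4), max(3, n_path // 2)))
        targets[reg] = {
            str(pathway_genes[i]) for i in rng.choice(n_path, size=size, replace=False)
        }
        class_of[reg] = "TF" if i % 2 == 0 else "cofactor"
    tf_map = TFTargetMap(targets=targets, class_of=class_of)

    # survival only over tumor samples: mixing normals in would let the
    # tumor/normal contrast confound every DE gene into a survival signal
    tumor_samples = cohort.samples_in_group("tumor")
    tumor_em = ExpressionMatrix(
        values=cohort.values[tumor_samples],
        group_of={s: "tumor" for s in tumor_samples},
        flavor=COUNTS,
    )
    surv = simulate_survival(
        tumor_em, {true_reg: regulator_beta}, base_hazard=base_hazard,
        censor_time=censor_time, seed=sub[4],
    )
    # record the hazard truth
    cohort_truth.genes.loc[true_reg, "true_beta"] = regulator_beta

    return StudyInputs(
        perturbation=pert, perturbation_truth=pert_truth,
        cohort=cohort, cohort_truth=cohort_truth,
        survival=surv, network=net, network_truth=net_truth,
        gene_sets=gsc, sets_truth=sets_truth,
        tf_targets=tf_map, true_regulator=true_reg,
        module_set_names=module_set_names,
    )
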