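"""End-to-end orchestration: configuration, stage ordering, manifest.

Stage order follows the analysis chain: drug-perturbation DEG screen →
over-representation + preranked GSEA → PPI module significance → cohort
count DEG screen → cross-cohort concordance → survival screening and
contingency → regulator ranking and nomination.

Runs are deterministic: one integer seed drives every stochastic stage
through dedicated sub-seeds, all output TSVs are written with fixed float
formatting, and a manifest records the configuration, seed, package
version and every behavioural flag in effect, so identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffexpr, enrichment, integrate, io, nettest
from . import survival as surv_mod
from .errors import ParameterError, PertnetError
from .simulate import StudyInputs

logger = logging.getLogger(__name__)

STAGES = ["deg", "enrich", "gsea", "nettest", "cohort_deg", "concordance",
          "survival", "regulators"]


@dataclass
class PipelineConfig:
    """File paths, thresholds and the master seed for one pipeline run."""

    # inputs
    matrix: str = "expression.tsv"
    groups: str = "groups.tsv"
    probe_map: str | None = None
    gene_sets: str = "gene_sets.gmt"
    network: str = "network.tsv"
    cohort_matrix: str = "cohort_counts.tsv"
    cohort_groups: str = "cohort_groups.tsv"
    clinical: str = "clinical.tsv"
    tf_targets: str = "tf_targets.tsv"
    # stage thresholds
    p_max: float = 0.05
    fc_min: float = 1.5
    fdr_max: float = 0.05
    min_overlap: int = 5
    enrich_mode: str = "fdr"
    n_perm: int = 1000
    gsea_weight: float = 1.0
    n_random: int = 1000
    scheme: str = "degree_preserving"
    concordance_mode: str = "same"
    survival_p_max: float = 0.05
    # module definition: gene sets whose DEGs form the focal module group
    module_sets: list[str] = field(default_factory=list)
    # bookkeeping
    seed: int = 0
    out_dir: str = "pertnet_out"

    def validate(self) -> None:
        if not 0 < self.p_max <= 1 or not 0 < self.fdr_max <= 1:
            raise ParameterError("p_max and fdr_max must be in (0, 1]")
        if self.fc_min < 1:
            raise ParameterError("fc_min must be >= 1")
        if self.min_overlap < 0 or self.n_perm < 1 or self.n_random < 1:
            raise ParameterError("min_overlap, n_perm, n_random out of range")
        if self.scheme not in nettest.SCHEMES:
            raise ParameterError(f"unknown scheme {self.scheme!r}")
        if self.enrich_mode not in ("fdr", "raw"):
            raise ParameterError(f"unknown enrich mode {self.enrich_mode!r}")
        if self.concordance_mode not in ("same", "reversal"):
            raise ParameterError(f"unknown concordance mode {self.concordance_mode!r}")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword overrides take precedence over the file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def write_study_inputs(study: StudyInputs, out_dir: str | Path) -> PipelineConfig:
    """Write every simulated input file plus a truth TSV and a ready config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_expression_matrix(study.perturbation, out / "expression.tsv", out / "groups.tsv")
    io.write_expression_matrix(study.cohort, out / "cohort_counts.tsv", out / "cohort_groups.tsv")
    io.write_clinical(study.survival, out / "clinical.tsv")
    io.write_edge_list(study.network, out / "network.tsv")
    io.write_gmt(study.gene_sets, out / "gene_sets.gmt")
    io.write_tf_targets(study.tf_targets, out / "tf_targets.tsv")
    truth = study.perturbation_truth.genes.copy()
    truth["cohort_lfc"] = study.cohort_truth.genes["true_lfc"]
    truth["true_beta"] = study.cohort_truth.genes["true_beta"]
    truth["in_planted_module"] = truth.index.isin(study.network_truth.planted_module)
    truth.to_csv(out / "truth_genes.tsv", sep="\t", float_format="%.10g")
    cfg = PipelineConfig(
        matrix=str(out / "expression.tsv"),
        groups=str(out / "groups.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        network=str(out / "network.tsv"),
        cohort_matrix=str(out / "cohort_counts.tsv"),
        cohort_groups=str(out / "cohort_groups.tsv"),
        clinical=str(out / "clinical.tsv"),
        tf_targets=str(out / "tf_targets.tsv"),
        module_sets=list(study.module_set_names),
        out_dir=str(out / "results"),
    )
    save_config(cfg, out / "config.yaml")
    return cfg


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest. Raises PertnetError naming the
    failing stage; partial outputs are retained next to a FAILED marker."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sub = {name: int(s) for name, s in
           zip(STAGES, rng.integers(2**31, size=len(STAGES)))}
    manifest: dict = {
        "package": "pertnet",
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": sub,
        "design_flags": {
            "fold_change_scale": "linear (2^dlog2), symmetric cutoff",
            "probe_collapse_tie": "larger |log2FC|, then lexicographic probe id",
            "fdr_procedure": "Benjamini-Hochberg",
            "cohort_de": "logCPM(+0.5) + Welch t + BH",
            "network_scheme": cfg.scheme,
            "empirical_p": "add-one, non-strict upper tail",
            "cox_ties": "Efron",
            "cox_covariate": "standardized continuous expression",
            "survival_threshold": "strict p < survival_p_max",
            "concordance_mode": cfg.concordance_mode,
        },
        "stages": {},
        "outputs": [],
    }
    stage = "setup"
    try:
        pert = io.read_expression_matrix(
            cfg.matrix, cfg.groups, flavor=io.INTENSITY, probe_map=cfg.probe_map
        )
        gsc = io.read_gmt(cfg.gene_sets)
        net = io.read_edge_list(cfg.network)
        cohort_em = io.read_expression_matrix(
            cfg.cohort_matrix, cfg.cohort_groups, flavor=io.COUNTS
        )
        clinical = io.read_clinical(cfg.clinical)
        tf_map = io.read_tf_targets(cfg.tf_targets)

        # --- drug perturbation DEG screen -------------------------------
        stage = "deg"
        groups = sorted(set(pert.group_of.values()))
        ref, trt = ("control", "treated") if set(groups) == {"control", "treated"} else groups[:2]
        table = diffexpr.ttest_fold_change(pert, ref, trt)
        if pert.probe_to_gene:
            table = diffexpr.collapse_probes(table, pert.probe_to_gene)
        drug_table = diffexpr.call_degs(table, p_max=cfg.p_max, fc_min=cfg.fc_min)
        diffexpr.write_deg_table(drug_table, out / "drug_degs.tsv")
        drug_degs = diffexpr.deg_genes(drug_table)
        manifest["stages"]["deg"] = {
            "n_genes": len(drug_table), "n_degs": len(drug_degs),
            "n_up": int((drug_table["is_deg"] & (drug_table["direction"] == "up")).sum()),
            "n_down": int((drug_table["is_deg"] & (drug_table["direction"] == "down")).sum()),
        }

        # --- over-representation ----------------------------------------
        stage = "enrich"
        universe = list(drug_table.index)
        enr = enrichment.enrich(
            drug_table, gsc, universe, min_overlap=cfg.min_overlap,
            mode=cfg.enrich_mode, fdr_max=cfg.fdr_max, p_max=cfg.p_max,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["enrich"] = {
            "n_tested": len(enr), "n_significant": int(enr["significant"].sum()),
        }

        # --- preranked GSEA ----------------------------------------------
        stage = "gsea"
        ranking = drug_table["log2_fc"]
        gsea = enrichment.gsea_preranked(
            ranking, gsc, n_perm=cfg.n_perm, weight=cfg.gsea_weight,
            seed=sub["gsea"],
        )
        gsea.to_csv(out / "gsea.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["gsea"] = {
            "n_tested": len(gsea),
            "n_significant": len(enrichment.significant_gsea(gsea, cfg.fdr_max)),
        }

        # --- network module test -----------------------------------------
        stage = "nettest"
        module_sets = cfg.module_sets or ([enr.index[0]] if len(enr) else [])
        module_members: set[str] = set()
        for name in module_sets:
            if name in gsc.sets:
                module_members |= gsc.members(name)
        cc_degs = drug_degs & module_members
        other_degs = drug_degs - cc_degs
        result = nettest.run_network_test(
            net, cc_degs, other_degs, n_random=cfg.n_random,
            scheme=cfg.scheme, seed=sub["nettest"],
        )
        pd.DataFrame({
            "null_ppi": result.null_ppi_counts, "null_lcc": result.null_lccs,
        }).to_csv(out / "network_null.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "observed_ppi": result.observed_ppi_count,
            "observed_lcc": result.observed_lcc,
            "empirical_p_ppi": result.empirical_p_ppi,
            "empirical_p_lcc": result.empirical_p_lcc,
            "n_random": result.n_random, "scheme": result.scheme,
        }]).to_csv(out / "network_test.tsv", sep="\t", index=False,
                   float_format="%.10g")
        manifest["stages"]["nettest"] = {
            "cc_degs": len(cc_degs), "other_degs": len(other_degs),
            "empirical_p_ppi": result.empirical_p_ppi,
            "empirical_p_lcc": result.empirical_p_lcc,
        }

        # --- cohort count DEG screen -------------------------------------
        stage = "cohort_deg"
        cohort_table = diffexpr.count_degs(cohort_em, fdr_max=cfg.fdr_max)
        diffexpr.write_deg_table(cohort_table, out / "cohort_degs.tsv")
        cohort_degs = diffexpr.deg_genes(cohort_table)
        manifest["stages"]["cohort_deg"] = {
            "n_genes": len(cohort_table), "n_degs": len(cohort_degs),
        }

        # --- cross-cohort concordance ------------------------------------
        stage = "concordance"
        conc = integrate.intersect_concordant(
            drug_table, cohort_table, mode=cfg.concordance_mode
        )
        rows = [(g, g in conc.common_down, g in conc.common_up,
                 g in conc.concordant) for g in sorted(conc.common)]
        pd.DataFrame(
            rows, columns=["gene", "common_down", "common_up", "concordant"]
        ).to_csv(out / "concordance.tsv", sep="\t", index=False)
        manifest["stages"]["concordance"] = {
            "common": len(conc.common), "common_down": len(conc.common_down),
            "common_up": len(conc.common_up),
            "concordant": conc.concordant_total,
            "discordant": len(conc.discordant), "mode": conc.mode,
        }

        # --- survival screening ------------------------------------------
        stage = "survival"
        cohort = io.build_cohort(clinical, cohort_em)
        screen_genes = sorted(cohort_degs & module_members) or sorted(cohort_degs)
        cox_results = surv_mod.cox_screen(cohort, screen_genes)
        cox_df = surv_mod.cox_results_frame(cox_results)
        cox_df.to_csv(out / "cox_screen.tsv", sep="\t", float_format="%.10g")
        survival_related = surv_mod.classify_survival_related(
            cox_results, p_max=cfg.survival_p_max
        )
        cont = integrate.survival_contingency(
            set(screen_genes), survival_related, set(screen_genes) & drug_degs
        )
        pd.DataFrame(
            cont.table, index=["survival", "non_survival"],
            columns=["drug_altered", "not_drug_altered"],
        ).to_csv(out / "contingency.tsv", sep="\t")
        manifest["stages"]["survival"] = {
            "n_screened": len(screen_genes),
            "n_survival_related": len(survival_related),
            "fisher_p": cont.p, "odds_ratio": cont.odds_ratio,
        }

        # --- regulator nomination ----------------------------------------
        stage = "regulators"
        pathway_degs = drug_degs & module_members
        ranked = integrate.rank_regulators(tf_map, pathway_degs)
        pd.DataFrame(ranked, columns=["regulator", "n_pathway_targets"]).to_csv(
            out / "regulators.tsv", sep="\t", index=False
        )
        reg_cox = surv_mod.cox_screen(
            cohort, [r for r, _ in ranked if r in cohort.expression.index]
        )
        candidates = integrate.nominate_candidates(
            [r for r, _ in ranked], reg_cox, cohort_table, drug_table,
            p_max=cfg.survival_p_max,
        )
        pd.DataFrame(
            [(c.regulator, c.cox_p, c.hazard_ratio, c.tumor_direction,
              c.drug_direction) for c in candidates],
            columns=["regulator", "cox_p", "hazard_ratio", "tumor_direction",
                     "drug_direction"],
        ).to_csv(out / "candidates.tsv", sep="\t", index=False,
                 float_format="%.10g")
        manifest["stages"]["regulators"] = {
            "n_ranked": len(ranked), "n_candidates": len(candidates),
            "candidates": [c.regulator for c in candidates],
        }

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PertnetError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_report(manifest, out / "report.txt")
    manifest["outputs"] = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_report(manifest: dict, path: Path) -> None:
    s = manifest["stages"]
    lines = [
        f"pertnet {manifest['version']} run report (seed {manifest['seed']})",
        "",
        f"drug DEG screen: {s['deg']['n_degs']} DEGs of {s['deg']['n_genes']} genes "
        f"({s['deg']['n_up']} up, {s['deg']['n_down']} down)",
        f"over-representation: {s['enrich']['n_significant']} significant of "
        f"{s['enrich']['n_tested']} tested sets",
        f"GSEA: {s['gsea']['n_significant']} significant of {s['gsea']['n_tested']} sets",
        f"network test: PPI p = {s['nettest']['empirical_p_ppi']:.4g}, "
        f"LCC p = {s['nettest']['empirical_p_lcc']:.4g} "
        f"({s['nettest']['cc_degs']} module DEGs vs {s['nettest']['other_degs']} others)",
        f"cohort DEG screen: {s['cohort_deg']['n_degs']} DEGs of "
        f"{s['cohort_deg']['n_genes']} genes",
        f"concordance ({s['concordance']['mode']}): {s['concordance']['common']} common, "
        f"{s['concordance']['common_down']} common down, "
        f"{s['concordance']['common_up']} common up, "
        f"{s['concordance']['concordant']} concordant",
        f"survival: {s['survival']['n_survival_related']} survival-related of "
        f"{s['survival']['n_screened']} screened (Fisher p = "
        f"{s['survival']['fisher_p']:.4g})",
        f"regulators: {s['regulators']['n_candidates']} candidates of "
        f"{s['regulators']['n_ranked']} ranked: "
        + (", ".join(s["regulators"]["candidates"]) or "none"),
        "",
    ]
    path.write_text("\n".join(lines))
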