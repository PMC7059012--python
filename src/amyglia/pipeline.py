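"""End-to-end orchestration: synthesize/load inputs, run every stage, report.

Stage order follows the analysis's dependency structure: bulk DE feeds the
ranked enrichment and co-expression stages; module membership, risk sets and
DE significance meet in the multi-set intersection prioritization; the bulk
z-matrix feeds the cell-type shift statistic and the microgliosis index; the
single-cell stage supplies state fractions and state means for the
deconvolution verdicts.  With a fixed config (all stage seeds derive from
one master seed) the whole run is deterministic.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulk_de, coexpression, deconvolution, enrichment, io
from . import multiset, shifts, single_cell, synthetic
from .containers import GROUPS, STRAINS, BulkExperiment, ParameterError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "amyglia_out",
    "synthetic": {
        "bulk": {},
        "single_cell": {},
        "gwas": {"n_background": 1800, "enrichment_strength": 0.6, "n_risk": 300},
    },
    "bulk_de": {
        "min_mean": 5.0,
        "min_samples_fraction": 10.0 / 96.0,
        "pseudocount": 0.5,
        "contrast_style": "vs_rest",
        "alpha": 0.05,
    },
    "enrichment": {
        "cutoffs": [5e-8, 5e-6, 1e-4, 1e-3, 1e-2, 5e-2],
        "n_resamples": 1000,
        "weight_exponent": 1.0,
    },
    "coexpression": {
        "candidate_powers": [1, 2, 3, 4, 5, 6, 7, 8, 10, 12],
        "r2_target": 0.9,
        "min_module_size": 30,
        "merge_corr": 0.75,
        "cut_height": 0.95,
    },
    "shifts": {"n_random": 10000, "sidedness": "two-sided"},
    "single_cell": {
        "min_reads": 750,
        "max_mito": 0.05,
        "doublet_cap": 30000,
        "min_cells_per_gene": 100,
        "lfc_threshold": 0.2,
    },
    "deconvolution": {"r2_threshold": 0.67, "prioritization_cutoff": 1e-3},
}

STAGES = (
    "synthesize",
    "bulk_de",
    "enrichment",
    "coexpression",
    "intersection",
    "shifts",
    "single_cell",
    "deconvolution",
)


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a YAML config against the defaults and validate it."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg.get("seed"), int):
        raise ParameterError("config: seed must be an integer")
    for key in ("bulk_de", "enrichment", "coexpression", "shifts",
                "single_cell", "deconvolution"):
        if key not in cfg or not isinstance(cfg[key], dict):
            raise ParameterError(f"config: missing stage block {key!r}")
    if cfg["bulk_de"]["contrast_style"] not in ("vs_rest", "classical"):
        raise ParameterError("config: contrast_style must be vs_rest or classical")
    cuts = cfg["enrichment"]["cutoffs"]
    if sorted(cuts) != list(cuts):
        raise ParameterError("config: enrichment cutoffs must be ascending")
    if cfg["shifts"]["n_random"] < 1000:
        raise ParameterError("config: shifts.n_random must be >= 1000")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def null_config(cfg: dict | None = None) -> dict:
    """A preset with every planted effect off (type-I-error scenario)."""
    cfg = copy.deepcopy(cfg or DEFAULT_CONFIG)
    cfg["synthetic"]["bulk"].update(
        interaction_lfc=0.0,
        program_activity_sd=0.0,
        microgliosis={},
        neuronal_factor={},
    )
    cfg["synthetic"]["gwas"]["enrichment_strength"] = 0.0
    flat = {g: 0.08 for g in GROUPS}
    cfg["synthetic"]["single_cell"]["arm_fractions"] = flat
    return cfg


@dataclass
class RunReport:
    config: dict
    summaries: dict
    artifacts: dict
    state: dict | None = None  # in-memory stage objects (keep_state=True)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": config_hash(self.config),
                "summaries": self.summaries,
                "artifacts": self.artifacts,
            },
            indent=2,
            sort_keys=True,
            default=io._jsonable,
        )


def run_pipeline(
    cfg: dict,
    outdir=None,
    stop_after: str | None = None,
    write_artifacts: bool = True,
    keep_state: bool = False,
) -> RunReport:
    """Execute the stages in dependency order; see module docstring."""
    validate_config(cfg)
    seed = cfg["seed"]
    out = Path(outdir or cfg.get("outdir", "amyglia_out"))
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    summaries: dict = {}
    artifacts: dict = {}
    state: dict = {}

    def save(name, fn):
        if write_artifacts:
            path = out / name
            fn(path)
            artifacts[name] = str(path)

    # --- synthesize -------------------------------------------------------
    bulk_cfg = synthetic.BulkConfig(seed=seed, **cfg["synthetic"]["bulk"])
    experiment, truth = synthetic.generate_bulk_counts(bulk_cfg)
    marker_sets = synthetic.generate_marker_sets(bulk_cfg)
    gwas_cfg = cfg["synthetic"]["gwas"]
    gwas_table = synthetic.generate_gwas_table(
        truth,
        n_background=gwas_cfg["n_background"],
        enrichment_strength=gwas_cfg["enrichment_strength"],
        n_risk=gwas_cfg.get("n_risk", 300),
        universe=experiment.genes,
    )
    sc_cfg = synthetic.SingleCellConfig(seed=seed, **cfg["synthetic"]["single_cell"])
    adata, sc_truth = synthetic.generate_single_cell_counts(sc_cfg)
    save("bulk_counts.tsv", lambda p: io.write_counts_tsv(experiment.counts, p))
    save("samples.tsv", lambda p: io.write_samples_tsv(experiment.samples, p))
    save("marker_sets.gmt", lambda p: io.write_gmt(marker_sets, p))
    if keep_state:
        state.update(
            experiment=experiment, truth=truth, marker_sets=marker_sets,
            gwas_table=gwas_table, adata=adata, sc_truth=sc_truth,
        )
    summaries["synthesize"] = {
        "n_genes": int(experiment.counts.shape[0]),
        "n_samples": int(experiment.counts.shape[1]),
        "n_cells": int(adata.n_obs),
        "n_program": len(truth.module_assignment),
    }
    if stop_after == "synthesize":
        return RunReport(cfg, summaries, artifacts, state if keep_state else None)

    # --- bulk DE per strain ----------------------------------------------
    de_cfg = cfg["bulk_de"]
    alpha = de_cfg["alpha"]
    de_results: dict[str, dict] = {}
    normalized: dict[str, object] = {}
    for strain in STRAINS:
        sub = experiment.subset_strain(strain)
        min_samples = int(round(de_cfg["min_samples_fraction"] * sub.counts.shape[1]))
        filtered = bulk_de.filter_low_counts(
            sub, min_mean=de_cfg["min_mean"], min_samples=min_samples
        )
        norm = bulk_de.normalize_log_cpm(filtered, de_cfg["pseudocount"])
        norm = bulk_de.residualize_covariates(
            norm, filtered.samples[["batch", "concentration"]], filtered.samples
        )
        normalized[strain] = norm
        de_results[strain] = bulk_de.fit_two_by_two_model(
            norm, filtered.samples, de_cfg["contrast_style"]
        )
        for contrast, res in de_results[strain].items():
            save(
                f"de_{strain}_{contrast}.tsv",
                lambda p, r=res: r.table.to_csv(p, sep="\t", float_format="%.10g"),
            )
            save(
                f"ranking_{strain}_{contrast}.rnk",
                lambda p, r=res: io.write_rnk(bulk_de.signed_ranking(r), p),
            )
        save(
            f"pca_{strain}.tsv",
            lambda p, m=norm: bulk_de.pca_coordinates(m).to_csv(
                p, sep="\t", float_format="%.10g"
            ),
        )
    cross_strain = {}
    for contrast in bulk_de.CONTRASTS:
        try:
            cross_strain[contrast] = bulk_de.rank_correlation(
                de_results["APP"][contrast], de_results["TAU"][contrast],
                alpha=alpha,
            )
        except ParameterError:
            cross_strain[contrast] = None
    if keep_state:
        state.update(de_results=de_results, normalized=normalized)
    summaries["cross_strain_rank_correlation"] = cross_strain
    summaries["bulk_de"] = {
        strain: {
            contrast: {
                "n_sig": int((r.table["p_adj"] < alpha).sum()),
                "n_up": int(
                    ((r.table["p_adj"] < alpha) & (r.table["lfc"] > 0)).sum()
                ),
                "n_down": int(
                    ((r.table["p_adj"] < alpha) & (r.table["lfc"] < 0)).sum()
                ),
                "n_total": int(len(r.table)),
            }
            for contrast, r in de_results[strain].items()
        }
        for strain in STRAINS
    }
    if stop_after == "bulk_de":
        return RunReport(cfg, summaries, artifacts, state if keep_state else None)

    # --- ranked enrichment ------------------------------------------------
    en_cfg = cfg["enrichment"]
    enrich_tables = {}
    gwas_sets_by_strain = {}
    for strain in STRAINS:
        universe = de_results[strain]["age_x_genotype"].table.index
        gwas_sets = enrichment.build_gwas_sets(
            gwas_table, en_cfg["cutoffs"], universe
        )
        gwas_sets = {k: v for k, v in gwas_sets.items() if len(v) >= 3}
        gwas_sets_by_strain[strain] = gwas_sets
        ranked = bulk_de.signed_ranking(de_results[strain]["age_x_genotype"])
        enrich_tables[strain] = enrichment.preranked_test(
            ranked,
            gwas_sets,
            n_resamples=en_cfg["n_resamples"],
            seed=seed + 101,
            weight_exponent=en_cfg["weight_exponent"],
        )
        save(
            f"enrichment_{strain}.tsv",
            lambda p, t=enrich_tables[strain]: t.to_csv(
                p, sep="\t", float_format="%.10g"
            ),
        )
    if keep_state:
        state.update(enrich_tables=enrich_tables, gwas_sets=gwas_sets_by_strain)
    summaries["enrichment"] = {
        strain: {
            "any_significant": bool((t["p_adj"] < alpha).any()),
            "min_p_adj": float(t["p_adj"].min()),
        }
        for strain, t in enrich_tables.items()
    }
    if stop_after == "enrichment":
        return RunReport(cfg, summaries, artifacts, state if keep_state else None)

    # --- co-expression ----------------------------------------------------
    cx_cfg = cfg["coexpression"]
    partitions = {}
    module_enrichment = {}
    for strain in STRAINS:
        norm = normalized[strain]
        beta, fit_table = coexpression.pick_soft_power(
            norm, cx_cfg["candidate_powers"], cx_cfg["r2_target"]
        )
        tom = coexpression.adjacency_and_tom(norm, beta)
        part = coexpression.detect_modules(
            tom,
            coexpression.NetworkConfig(
                beta=beta,
                r2_target=cx_cfg["r2_target"],
                min_module_size=cx_cfg["min_module_size"],
                merge_corr=cx_cfg["merge_corr"],
                cut_height=cx_cfg["cut_height"],
            ),
            matrix=norm,
        )
        part.tom = None  # free memory; TOM not needed downstream
        partitions[strain] = part
        modules = {m: part.module_genes(m) for m in part.modules}
        fam = {**marker_sets, **gwas_sets_by_strain[strain]}
        module_enrichment[strain] = enrichment.fisher_enrichment_table(
            modules, fam, universe=part.labels.index
        )
        save(
            f"modules_{strain}.tsv",
            lambda p, s=part.labels: s.rename("module").rename_axis("gene").to_csv(
                p, sep="\t"
            ),
        )
        save(
            f"module_enrichment_{strain}.tsv",
            lambda p, t=module_enrichment[strain]: t.to_csv(
                p, sep="\t", index=False, float_format="%.10g"
            ),
        )
        summaries.setdefault("coexpression", {})[strain] = {
            "beta": int(beta),
            "n_modules": len(part.modules),
        }
    if stop_after == "coexpression":
        return RunReport(cfg, summaries, artifacts, state if keep_state else None)

    # --- multi-set intersection / prioritization --------------------------
    dc_cfg = cfg["deconvolution"]
    cutoff = dc_cfg["prioritization_cutoff"]
    target_modules = {}
    prioritized = {}
    for strain in STRAINS:
        cut_name = f"P_mar<{cutoff:g}"
        gw = gwas_sets_by_strain[strain].get(cut_name, [])
        me = module_enrichment[strain]
        if len(me):
            risk_rows = me[
                (me["set"] == cut_name) & (me["p_adj"] < alpha) & (me["lor"] > 0)
            ]
        else:
            risk_rows = me
        target = (
            risk_rows.sort_values("p_adj")["module"].iloc[0]
            if len(risk_rows)
            else None
        )
        target_modules[strain] = target
        if target is None:
            prioritized[strain] = {"genes": [], "test": None}
            continue
        result = prioritize_genes(
            de_results[strain]["age_x_genotype"],
            partitions[strain],
            gw,
            target,
            alpha=alpha,
        )
        prioritized[strain] = result
        save(
            f"prioritized_{strain}.json",
            lambda p, r=result: io.write_json(
                {"genes": r["genes"], "test": r["test"].summary()}, p
            ),
        )
    if keep_state:
        state.update(partitions=partitions, module_enrichment=module_enrichment,
                     prioritized=prioritized, target_modules=target_modules)
    summaries["intersection"] = {
        strain: {
            "target_module": target_modules[strain],
            "n_prioritized": len(prioritized[strain]["genes"]),
            "p_upper": (
                float(prioritized[strain]["test"].p_upper)
                if prioritized[strain]["test"]
                else None
            ),
        }
        for strain in STRAINS
    }
    if stop_after == "intersection":
        return RunReport(cfg, summaries, artifacts, state if keep_state else None)

    # --- cell-type shifts -------------------------------------------------
    sh_cfg = cfg["shifts"]
    shift_tables = {}
    z_matrices = {}
    for strain in STRAINS:
        norm = normalized[strain]
        sub = experiment.subset_strain(strain)
        group = sub.group.loc[norm.samples]
        baseline = f"{strain}_WT_4M"
        z = shifts.znorm_to_baseline(norm, group.index[group == baseline])
        z_matrices[strain] = (z, group)
        shift_tables[strain] = shifts.shift_test(
            z,
            marker_sets,
            group,
            baseline_group=baseline,
            n_random=sh_cfg["n_random"],
            seed=seed + 202,
            sidedness=sh_cfg["sidedness"],
        )
        save(
            f"shifts_{strain}.tsv",
            lambda p, t=shift_tables[strain]: t.to_csv(
                p, sep="\t", index=False, float_format="%.10g"
            ),
        )
    if keep_state:
        state.update(shift_tables=shift_tables)
    summaries["shifts"] = {
        strain: {
            "microglia_sig_positive": sorted(
                t.loc[
                    (t["set_name"] == "microglia")
                    & (t["p_bonf"] < alpha)
                    & (t["z_tg"] > 0),
                    "group",
                ]
            )
        }
        for strain, t in shift_tables.items()
    }
    if stop_after == "shifts":
        return RunReport(cfg, summaries, artifacts, state if keep_state else None)

    # --- single-cell states ----------------------------------------------
    sc_stage = cfg["single_cell"]
    kept, qc_report = single_cell.qc_filter(
        adata,
        min_reads=sc_stage["min_reads"],
        max_mito=sc_stage["max_mito"],
        doublet_cap=sc_stage["doublet_cap"],
        min_cells_per_gene=sc_stage["min_cells_per_gene"],
    )
    norm_cells = single_cell.normalize_cells(kept)
    scores = pd.DataFrame(
        {
            state: single_cell.module_score(
                norm_cells, sig, seed=seed + 303
            )
            for state, sig in sc_truth.state_signatures.items()
        }
    )
    assignment = single_cell.assign_states(
        scores, norm_cells.obs["group"], homeostatic="HM"
    )
    norm_cells.obs["state"] = assignment.states
    state_de_results = {}
    for strain in STRAINS:
        grp = norm_cells.obs["group"].astype(str)
        arm_cells = norm_cells.obs_names[
            grp.str.startswith(strain) & (assignment.states == "ARM")
        ]
        hm_cells = norm_cells.obs_names[
            grp.str.startswith(strain) & (assignment.states == "HM")
        ]
        if len(arm_cells) >= 3 and len(hm_cells) >= 3:
            state_de_results[strain] = single_cell.state_de(
                norm_cells,
                arm_cells,
                hm_cells,
                lfc_threshold=sc_stage["lfc_threshold"],
                alpha=alpha,
            )
    concordance = None
    if len(state_de_results) == 2:
        try:
            concordance = single_cell.state_de_concordance(
                *state_de_results.values()
            )
        except ParameterError:
            concordance = None
    save(
        "state_fractions.tsv",
        lambda p: assignment.fractions.to_csv(p, sep="\t", float_format="%.10g"),
    )
    save(
        "qc_cells.tsv",
        lambda p: qc_report.cells.to_csv(p, sep="\t", float_format="%.10g"),
    )
    save(
        "cell_states.tsv",
        lambda p: assignment.states.rename("state")
        .rename_axis("barcode")
        .to_csv(p, sep="\t"),
    )
    for strain, de_tab in state_de_results.items():
        save(
            f"state_de_{strain}.tsv",
            lambda p, t=de_tab: t.to_csv(p, sep="\t", float_format="%.10g"),
        )
    if keep_state:
        state.update(assignment=assignment, qc_report=qc_report,
                     state_de=state_de_results, concordance=concordance)
    summaries["single_cell"] = {
        "n_cells_pass": qc_report.n_passed,
        "fractions": {
            g: {s: float(v) for s, v in row.items()}
            for g, row in assignment.fractions.iterrows()
        },
        "state_de_concordance": concordance,
    }
    if stop_after == "single_cell":
        return RunReport(cfg, summaries, artifacts, state if keep_state else None)

    # --- deconvolution ----------------------------------------------------
    # one z-matrix across all 8 groups (both strains), anchored at the
    # amyloid-strain young wild-type baseline, for the microgliosis index
    # and the observed group means
    amyloid = bulk_cfg.amyloid_strain
    min_samples_all = int(
        round(de_cfg["min_samples_fraction"] * experiment.counts.shape[1])
    )
    filt_all = bulk_de.filter_low_counts(
        experiment, de_cfg["min_mean"], min_samples_all
    )
    norm_all = bulk_de.normalize_log_cpm(filt_all, de_cfg["pseudocount"])
    group_all = filt_all.group
    norm_all = bulk_de.residualize_covariates(
        norm_all,
        filt_all.samples[["batch", "concentration"]],
        pd.get_dummies(group_all).astype(float),
    )
    baseline_all = f"{amyloid}_WT_4M"
    z_all = shifts.znorm_to_baseline(
        norm_all, group_all.index[group_all == baseline_all]
    )
    mg_index = deconvolution.microgliosis_index(
        z_all, marker_sets["microglia"], group_all
    )
    genes_panel = prioritized[amyloid]["genes"]
    if not genes_panel:
        genes_panel = sorted(truth.module_assignment)[: 18]
    groups_in = [g for g in mg_index.m_g.index]
    frac = assignment.fractions.reindex(groups_in).fillna(0.0)
    frac = frac[["ARM", "HM"]] if "ARM" in frac.columns else frac
    pred_rows, obs_rows, share_rows = {}, {}, {}
    sc_genes = set(norm_cells.var_names)
    for gene in genes_panel:
        if gene not in sc_genes:
            continue
        mu_hm, mu_arm = {}, {}
        for g in groups_in:
            mus = deconvolution.state_mean_expression(
                norm_cells, assignment, gene, g
            )
            mu_hm[g] = mus["mu_HM"]
            mu_arm[g] = mus["mu_ARMplus"]
        mu_hm = pd.Series(mu_hm)
        mu_arm = pd.Series(mu_arm)
        pred = deconvolution.predicted_bulk(mg_index.m_g, frac, mu_hm, mu_arm)
        obs = z_all.loc[gene].groupby(group_all).mean().reindex(groups_in)
        pred_rows[gene] = pred
        obs_rows[gene] = obs
        share_rows[gene] = deconvolution.driver_decomposition(
            mg_index.m_g, frac, mu_hm.fillna(0.0), mu_arm.fillna(0.0)
        )
    if pred_rows:
        predicted = pd.DataFrame(pred_rows).T
        observed = pd.DataFrame(obs_rows).T
        shares = pd.DataFrame(share_rows).T
        fit = deconvolution.fit_contribution(
            predicted,
            observed,
            r2_threshold=dc_cfg["r2_threshold"],
            alpha=alpha,
            driver_shares=shares,
        )
        save(
            "deconvolution.tsv",
            lambda p: fit.table.to_csv(p, sep="\t", float_format="%.10g"),
        )
        summaries["deconvolution"] = {
            "n_genes": int(len(fit.table)),
            "n_explained": int(fit.table["explained"].sum()),
            "microgliosis_index": {
                g: float(v) for g, v in mg_index.m_g.items()
            },
        }
    else:
        summaries["deconvolution"] = {"n_genes": 0, "n_explained": 0}

    if keep_state and pred_rows:
        state.update(deconv_fit=fit, mg_index=mg_index)
    report = RunReport(cfg, summaries, artifacts, state if keep_state else None)
    if write_artifacts:
        (out / "report.json").write_text(report.to_json())
    return report


def prioritize_genes(
    de_result,
    partition,
    gwas_set,
    target_module: str,
    alpha: float = 0.05,
) -> dict:
    """Module ∩ risk-set ∩ DE-significant gene list plus its exact
    intersection test against the analysis universe."""
    universe = de_result.table.index
    module_genes = set(partition.module_genes(target_module)) & set(universe)
    risk = set(gwas_set) & set(universe)
    sig = set(universe[(de_result.table["p_adj"] < alpha).to_numpy()])
    genes = sorted(module_genes & risk & sig)
    test = multiset.intersection_test(
        len(universe),
        [len(module_genes), len(risk), len(sig)],
        len(genes),
    )
    return {"genes": genes, "test": test}
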