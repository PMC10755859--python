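"""End-to-end pipeline orchestration.

``run_pipeline`` chains simulate → type-strains → track → fct → ecology →
trial on one output directory, writing each stage's tables plus a
manifest (resolved config, config hash, output hashes).  Stages log at
INFO; a stage failure aborts with the stage name while preserving
partial outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecology_stats, fct, longitudinal_tracking as track, strain_typing, trial_stats
from .io import (
    RunConfig,
    write_catalog_json,
    write_fasta_refs,
    write_manifest,
    write_newick,
    write_pileup_tsv,
)
from .synthetic_cohort import (
    CohortConfig,
    default_dmm_params,
    simulate_biomarkers_and_growth,
    simulate_catalog,
    simulate_cohort,
    simulate_genus_tables,
    simulate_pileups,
    simulate_strain_genomes,
)

log = logging.getLogger("strainflow")


def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate the synthetic cohort and write all interchange files."""
    sim_kwargs = dict(config.simulate)
    catalog_kwargs = {
        k: sim_kwargs.pop(k) for k in ("n_genes", "length_range") if k in sim_kwargs
    }
    genome_kwargs = {
        k: sim_kwargs.pop(k)
        for k in (
            "n_autoch_subclades",
            "snv_rate_between",
            "snv_rate_within_probiotic",
            "outgroup_rate",
        )
        if k in sim_kwargs
    }
    pileup_kwargs = {
        k: sim_kwargs.pop(k)
        for k in ("depth_per_unit_abundance", "error_rate", "library_factor_sd")
        if k in sim_kwargs
    }
    if "arm_sizes" in sim_kwargs and sim_kwargs["arm_sizes"] is not None:
        sim_kwargs["arm_sizes"] = tuple(sim_kwargs["arm_sizes"])
    cohort_cfg = CohortConfig(seed=config.seed, **sim_kwargs)
    catalog = simulate_catalog(seed=config.seed, **catalog_kwargs)
    strains = simulate_strain_genomes(catalog, seed=config.seed + 1, **genome_kwargs)
    truth = simulate_cohort(cohort_cfg, strains)
    pileups = simulate_pileups(truth, seed=config.seed + 2, **pileup_kwargs)
    dmm = default_dmm_params(cohort_cfg.n_fct, concentration=cohort_cfg.fct_concentration)
    genus = simulate_genus_tables(
        truth.samples["fct_label"],
        dmm,
        library_size=config.library_size,
        seed=config.seed + 3,
        sample_ids=list(truth.samples["sample_id"]),
    )
    biomarkers, growth = simulate_biomarkers_and_growth(truth, seed=config.seed + 4)

    write_catalog_json(catalog, outdir / "catalog.json")
    write_fasta_refs(strains.sequences, catalog, outdir / "references.fasta")
    write_pileup_tsv(pileups, outdir / "pileups.tsv")
    genus.to_csv(outdir / "genus_counts.tsv", sep="\t")
    truth.samples.drop(columns=["strain", "second_strain", "mixture", "true_category", "fct_label"]).to_csv(
        outdir / "metadata.csv", index=False
    )
    biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    json.dump(biomarkers.attrs.get("limits", {}), open(outdir / "biomarker_limits.json", "w"))
    growth.to_csv(outdir / "growth.csv", index=False)
    truth.to_json(outdir / "truth.json")
    return {
        "truth": truth,
        "catalog": catalog,
        "strains": strains,
        "pileups": pileups,
        "genus": genus,
        "biomarkers": biomarkers,
        "growth": growth,
        "dmm_truth": dmm,
    }


def typing_stage(config: RunConfig, state: dict, outdir: Path) -> dict:
    params = strain_typing.TypingParams(
        af_threshold=config.af_threshold,
        min_depth=config.min_depth,
        min_reads=config.min_reads,
        min_genes=config.min_genes,
        gene_low_af_max=config.gene_low_af_max,
        low_abund_threshold=config.low_abund_threshold,
        het_max=config.het_max,
        probiotic_radius=config.probiotic_radius,
        min_shared=config.min_shared,
    )
    truth = state["truth"]
    abund = truth.samples.set_index("sample_id")["abundance"]
    refs = {
        sid: seq
        for sid, seq in state["strains"].sequences.items()
    }
    classes, profiles = strain_typing.type_samples(
        state["pileups"], abund, refs, params
    )
    classes.to_csv(outdir / "classifications.tsv", sep="\t", index=False)
    tips = strain_typing.placeable_profiles(profiles, classes, refs, params)
    rng = np.random.default_rng(config.seed)
    if len(tips) > config.tree_max_tips:
        n_refs = len(refs)
        sample_tips = tips[: len(tips) - n_refs]
        keep = rng.choice(len(sample_tips), config.tree_max_tips - n_refs, replace=False)
        tips = [sample_tips[i] for i in sorted(keep)] + tips[len(tips) - n_refs:]
    dist, labels = strain_typing.distance_matrix(tips, params.min_shared)
    ok = ~np.isnan(dist).any(axis=1)
    tree = strain_typing.build_strain_tree(
        dist[np.ix_(ok, ok)], [l for l, k in zip(labels, ok) if k]
    )
    write_newick(tree, outdir / "strain_tree.nwk")
    return {"classifications": classes, "profiles": profiles, "tree": tree, "params": params}


def tracking_stage(config: RunConfig, state: dict, outdir: Path) -> dict:
    truth = state["truth"]
    meta = truth.samples[["sample_id", "infant_id", "visit", "arm", "feeding"]]
    traj = track.build_trajectories(state["classifications"], meta)
    traj.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    summary = track.summarize(traj)
    json.dump(summary, open(outdir / "tracking_summary.json", "w"), indent=2, default=float)
    return {"trajectories": traj, "tracking_summary": summary}


def fct_stage(config: RunConfig, state: dict, outdir: Path) -> dict:
    genus = state["genus"]
    models = fct.fit_dmm_range(
        genus, k_max=config.kmax, n_restarts=config.restarts, seed=config.seed
    )
    chosen = fct.select_k(models)
    best = models[chosen["primary"] - 1]
    truth = state["truth"]
    visits = list(truth.config.visits)
    vidx = truth.samples.set_index("sample_id")["visit"].map(
        {v: i for i, v in enumerate(visits)}
    )
    assignments = fct.order_chronologically(best, list(genus.index), vidx)
    assignments.to_csv(outdir / "fct_assignments.tsv", sep="\t", index=False)
    meta = truth.samples[["sample_id", "infant_id", "visit"]]
    transitions = fct.transition_summary(assignments, meta)
    transitions.to_csv(outdir / "fct_transitions.tsv", sep="\t", index=False)
    # community-type trajectories by colonizing-strain group
    traj = state["trajectories"].set_index("infant_id")
    typed = traj[visits].isin(["LMG11588"]).any(axis=1)
    other = traj[visits].isin(["OtherInfantis"]).any(axis=1)
    groups = pd.Series(
        np.where(typed, "LMG11588", np.where(other, "OtherInfantis", "none")),
        index=traj.index,
    )
    comparison = fct.compare_trajectories(
        assignments, meta, groups, visits=tuple(visits), seed=config.seed
    )
    comparison.to_csv(outdir / "fct_group_comparison.tsv", sep="\t", index=False)
    diag = {
        "selected": chosen,
        "models": [
            {
                "K": m.K,
                "log_likelihood": m.log_likelihood,
                "laplace": m.laplace,
                "aic": m.aic,
                "bic": m.bic,
                "converged": m.converged,
            }
            for m in models
        ],
        "pi": best.pi.tolist(),
        "alpha": best.alpha.tolist(),
    }
    json.dump(diag, open(outdir / "dmm_models.json", "w"), indent=2, default=float)
    return {"dmm_models": models, "dmm_selected": chosen, "assignments": assignments,
            "fct_group_comparison": comparison}


def ecology_stage(config: RunConfig, state: dict, outdir: Path) -> dict:
    genus = state["genus"]
    rel = genus.div(genus.sum(axis=1), axis=0)
    alpha = ecology_stats.alpha_diversity(rel)
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    bc = ecology_stats.bray_curtis(rel)
    truth = state["truth"]
    meta = truth.samples.set_index("sample_id")[["arm", "visit"]]
    res = ecology_stats.permanova(
        bc, meta, ["arm", "visit"], n_perm=config.n_perm, seed=config.seed
    )
    res.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
    ord_res = ecology_stats.pcoa(bc)
    coords = ord_res.samples.iloc[:, :2]
    bio = state["biomarkers"].set_index("sample_id")
    common = coords.index.intersection(bio.index)
    prc = ecology_stats.procrustes_correlation(
        coords.loc[common].to_numpy(),
        ecology_stats.biomarker_pca_coords(bio.loc[common]),
        n_perm=min(config.n_perm, 999),
        seed=config.seed,
    )
    assoc = ecology_stats.kendall_associations(
        rel.loc[common], bio.loc[common], always_include=["Bifidobacterium"]
    )
    assoc.to_csv(outdir / "kendall_associations.tsv", sep="\t", index=False)
    json.dump(
        {"permanova": res.to_dict(orient="records"), "procrustes": prc},
        open(outdir / "ecology_summary.json", "w"),
        indent=2,
        default=float,
    )
    return {"permanova": res, "procrustes": prc, "kendall": assoc}


def trial_stage(config: RunConfig, state: dict, outdir: Path) -> dict:
    growth = state["growth"]
    anc = trial_stats.ancova_adjusted_means(growth)
    results = []
    for comp in anc["comparisons"]:
        if "CG" not in comp["comparison"]:
            continue
        ni = trial_stats.noninferiority_decision(
            comp["tukey_ci"],
            margin=config.margin,
            estimate=comp["estimate"],
            se=comp["se"],
            df=comp["df"],
            comparison=comp["comparison"],
        )
        results.append(
            {
                "comparison": comp["comparison"],
                "estimate": comp["estimate"],
                "ci_low": comp["tukey_ci"][0],
                "ci_high": comp["tukey_ci"][1],
                "margin": config.margin,
                "noninferior": ni.decision,
                "p_noninferiority": ni.p,
            }
        )
    table2 = pd.DataFrame(results)
    table2.to_csv(outdir / "noninferiority.tsv", sep="\t", index=False)
    return {"ancova": anc, "noninferiority": table2}


STAGES = [
    ("simulate", simulate_stage),
    ("type-strains", typing_stage),
    ("track", tracking_stage),
    ("fct", fct_stage),
    ("ecology", ecology_stage),
    ("trial", trial_stage),
]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; abort on failure naming the stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for name, fn in STAGES:
        log.info("stage %s starting", name)
        try:
            if name == "simulate":
                state.update(fn(config, outdir))
            else:
                state.update(fn(config, state, outdir))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        outputs = {p.name: p for p in outdir.iterdir() if p.is_file() and not p.name.startswith("manifest")}
        write_manifest(config, name, outputs, outdir)
        log.info("stage %s done", name)
    return state
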