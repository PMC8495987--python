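"""End-to-end orchestration: simulate -> ancestry -> GRM -> GP -> PRS ->
WGRS -> carriers -> liability, with every artifact written to a run
directory and a machine-readable summary.

A run is configured by a nested dict (typically loaded from YAML/JSON)
with a mandatory ``seed``, exactly one of a ``simulate`` block (passed to
:class:`polyliab.simdata.SimConfig`) or an ``inputs`` block (paths to a
genotype source and subject table), and optional per-stage parameter
blocks ``ancestry``, ``gblup``, ``prs``, ``wgrs``, ``liability``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import carriers as carr
from . import gblup, grm, liability, prs, scores, simdata
from .io import GenotypeMatrix, read_dosage_tsv, read_plink

logger = logging.getLogger(__name__)

STAGES = ["data", "ancestry", "grm", "gblup", "prs", "wgrs", "carriers", "liability"]


class ConfigError(ValueError):
    pass


def _require(config: dict) -> None:
    if "seed" not in config:
        raise ConfigError("config field 'seed' is mandatory")
    has_sim = "simulate" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise ConfigError("config must contain exactly one of 'simulate' or 'inputs'")


def _load_inputs(block: dict) -> tuple[GenotypeMatrix, pd.DataFrame]:
    if "genotypes_tsv" in block:
        geno = read_dosage_tsv(block["genotypes_tsv"])
    elif "plink_prefix" in block:
        geno = read_plink(block["plink_prefix"])
    else:
        raise ConfigError("inputs block needs 'genotypes_tsv' or 'plink_prefix'")
    if "subjects_tsv" not in block:
        raise ConfigError("inputs block needs 'subjects_tsv'")
    subjects = pd.read_csv(block["subjects_tsv"], sep="\t", dtype={"subject_id": str})
    return geno, subjects


def run(config: dict, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the summary dict.

    Artifacts written: genotypes (if simulated), ancestry eigenvectors and
    clusters, matched pairs, GP/PRS/WGRS score TSVs, carrier calls and
    severity table, a logistic evaluation table, the liability report, and
    ``summary.json`` / ``report.md``.
    """
    _require(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"seed": seed, "stages": {}}
    stage = "data"
    try:
        # ------------------------------------------------ data
        truth = None
        if "simulate" in config:
            sim_cfg = simdata.SimConfig(**{**config["simulate"], "seed": seed})
            geno, subjects, truth = simdata.simulate_cohort(sim_cfg)
            simdata.write_cohort(geno, subjects, truth, outdir, fmt=config.get("format", "tsv"))
            summary["stages"]["data"] = {
                "simulated": True,
                "n_cases": int((subjects["cohort"] == "case").sum()),
                "n_matched_controls": int((subjects["cohort"] == "matched_control").sum()),
                "n_pool_controls": int((subjects["cohort"] == "pool_control").sum()),
                "m_snps": geno.m_variants,
                "pdv_shift": sim_cfg.pdv_shift,
            }
        else:
            geno, subjects = _load_inputs(config["inputs"])
            summary["stages"]["data"] = {
                "simulated": False,
                "n_subjects": geno.n_subjects,
                "m_snps": geno.m_variants,
            }

        # ------------------------------------------------ ancestry
        stage = "ancestry"
        a_cfg = config.get("ancestry", {})
        prune_cfg = a_cfg.get("prune", {})
        pruned = anc.ld_prune(
            geno,
            window=prune_cfg.get("window", 50),
            step=prune_cfg.get("step", 5),
            r2_max=prune_cfg.get("r2_max", 0.64),
        )
        space = anc.compute_eigenvectors(geno, pruned, d=a_cfg.get("d", 3))
        space = anc.cluster_subjects(space, k=a_cfg.get("k"), seed=seed)
        analysis = subjects[subjects["cohort"] != "pool_control"] if "cohort" in subjects else subjects
        sub_space = _restrict_space(space, analysis["subject_id"].to_numpy())
        pairs = anc.match_pairs(sub_space, analysis)
        pd.DataFrame(
            space.eigenvectors,
            columns=[f"EV{i + 1}" for i in range(space.d)],
        ).assign(subject_id=space.subject_ids, cluster=space.clusters).to_csv(
            outdir / "ancestry.tsv", sep="\t", index=False
        )
        pairs.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        summary["stages"]["ancestry"] = {
            "m_pruned": len(pruned),
            "n_clusters": space.n_clusters,
            "n_pairs": pairs.n_pairs,
            "mean_pair_distance": pairs.mean_distance if pairs.n_pairs else None,
            "n_unmatched_cases": len(pairs.unmatched_cases),
            "n_unmatched_controls": len(pairs.unmatched_controls),
        }

        # ------------------------------------------------ grm
        stage = "grm"
        if "cohort" in subjects.columns:
            pool_ids = subjects.loc[subjects["cohort"] == "pool_control", "subject_id"]
        else:
            paired = set(pairs.subject_ids())
            pool_ids = [s for s in subjects["subject_id"] if s not in paired]
        cluster_of = dict(zip(space.subject_ids, space.clusters))
        pool_geno = geno.subset_subjects(pool_ids)
        pool_clusters = np.array([cluster_of[s] for s in pool_geno.subject_ids])
        freqs = grm.estimate_frequencies(pool_geno, pool_clusters)
        mask = grm.polymorphic_mask(freqs, pool_geno)
        paired_ids = pairs.subject_ids()
        paired_geno = geno.subset_subjects(paired_ids)
        paired_clusters = np.array([cluster_of[s] for s in paired_ids])
        mode = config.get("grm", {}).get("mode", "CLS")
        kinship = grm.compute_grm(paired_geno, mode, freqs, paired_clusters, variant_mask=mask)
        kinship.save(str(outdir / "grm"))
        summary["stages"]["grm"] = {
            "mode": mode,
            "m_variants": kinship.m_variants,
            "prior_strength": freqs.prior_strength,
            "fst_hat": freqs.fst_hat,
        }

        # ------------------------------------------------ gblup
        stage = "gblup"
        g_cfg = config.get("gblup", {})
        h2 = g_cfg.get("h2", 0.70)
        op = gblup.build_leave_pair_out(kinship, pairs, h2=h2)
        status_map = subjects.set_index("subject_id")["status"]
        y = status_map.loc[op.subject_ids].to_numpy(dtype=float)
        gp = op.predict(y)
        gp.to_frame().to_csv(outdir / "gp.tsv", sep="\t", index=False)
        gp_eval = scores.evaluate_score(gp, y)
        lam = gblup.permutation_gc_lambda(
            op, y, n_permutations=g_cfg.get("gc_permutations", 200), seed=seed
        )
        chi2_obs = gblup.case_control_chi2(gp.values, y)
        summary["stages"]["gblup"] = {
            "h2": h2,
            "evaluation": gp_eval.to_dict(),
            "gc_lambda": lam,
            "chi2_observed": chi2_obs,
            "chi2_gc_corrected": gblup.gc_correct(chi2_obs, lam),
        }

        # ------------------------------------------------ prs
        stage = "prs"
        p_cfg = config.get("prs", {})
        prs_config = prs.PRSConfig(
            p_threshold=p_cfg.get("p_threshold", 0.01),
            clump_r2=p_cfg.get("clump_r2", 0.1),
            clump_window_kb=p_cfg.get("clump_window_kb", 250),
        )
        prs_scores = []
        stat_sources: dict[str, pd.DataFrame] = {}
        if "summary_stats" in p_cfg:
            for name, path in p_cfg["summary_stats"].items():
                stat_sources[name] = prs.read_summary_stats(path, p_cfg.get("column_map"))
        elif truth is not None:
            n_gwas = p_cfg.get("gwas_n_cases", 500)
            sim_cfg_local = sim_cfg
            stat_sources["ASD-PRS"] = simdata.simulate_gwas_stats(
                sim_cfg_local, n_gwas, seed=seed + 101
            )
            stat_sources["SCZ-PRS"] = simdata.simulate_gwas_stats(
                sim_cfg_local, n_gwas, seed=seed + 211
            )
        prs_summary = {}
        for name, stats in stat_sources.items():
            aligned = prs.align_alleles(stats, geno, drop_ambiguous=True)
            index_set = prs.clump(aligned, pool_geno, prs_config)
            if not index_set:
                logger.warning("PRS %s: empty index set; skipped", name)
                continue
            sv = prs.score(paired_geno, aligned, index_set, name=name)
            sv.to_frame().to_csv(outdir / f"{name.lower().replace('-', '_')}.tsv", sep="\t", index=False)
            prs_scores.append(sv)
            prs_summary[name] = {
                "m_index_variants": len(index_set),
                "evaluation": scores.evaluate_score(sv, status_map.loc[sv.subject_ids].to_numpy(float)).to_dict(),
            }
        summary["stages"]["prs"] = prs_summary

        # ------------------------------------------------ wgrs
        stage = "wgrs"
        # reorder PRS components onto the GP's fold-by-fold subject order
        components = [gp] + [
            scores.ScoreVector.from_raw(
                s.name, gp.subject_ids, s.to_series().loc[gp.subject_ids].to_numpy(), s.provenance
            )
            for s in prs_scores
        ]
        wgrs, weights = scores.combine_wgrs(
            components, y, scheme=config.get("wgrs", {}).get("scheme", "pseudoR2")
        )
        wgrs.to_frame().to_csv(outdir / "wgrs.tsv", sep="\t", index=False)
        summary["stages"]["wgrs"] = {
            "components": weights.components,
            "weights": weights.weights.tolist(),
            "scheme": weights.scheme,
            "evaluation": scores.evaluate_score(wgrs, y).to_dict(),
        }

        # ------------------------------------------------ carriers
        stage = "carriers"
        c_cfg = config.get("carriers", {})
        if "records_tsv" in c_cfg:
            records = pd.read_csv(c_cfg["records_tsv"], sep="\t", dtype={"subject_id": str})
            risk_genes = [g.strip() for g in open(c_cfg["risk_genes"]) if g.strip()]
        else:
            records, risk_genes = simdata.generate_pdv_records(subjects, seed=seed)
        calls = carr.classify_carriers(records, subjects["subject_id"], risk_genes)
        calls.to_csv(outdir / "carrier_calls.tsv", sep="\t", index=False)
        sev = carr.severity_table(calls)
        summary["stages"]["carriers"] = sev.to_dict()

        # ------------------------------------------------ liability
        stage = "liability"
        l_cfg = config.get("liability", {})
        model = liability.LiabilityModel(
            l_cfg.get("prevalence", 0.015),
            l_cfg.get("risk_ratio", 15.0),
            l_cfg.get("risk_scale", "odds_ratio"),
        )
        contrasts = scores.burden_contrasts(wgrs, subjects, calls, seed=seed)
        gobs = contrasts["groups"]
        observed = None
        if {"cases", "controls", "carrier_cases"} <= gobs.keys():
            observed = {
                "affected": gobs["cases"]["mean"],
                "unaffected": gobs["controls"]["mean"],
                "affected_carriers": gobs["carrier_cases"]["mean"],
            }
        report = liability.additivity_diagnostics(model, observed)
        report["burden_contrasts"] = contrasts
        summary["stages"]["liability"] = report
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=_jsonable, sort_keys=True))
    (outdir / "report.md").write_text(_render_report(summary))
    logger.info("run complete: %s", outdir)
    return summary


def _restrict_space(space: anc.AncestrySpace, ids) -> anc.AncestrySpace:
    order = {s: i for i, s in enumerate(space.subject_ids)}
    idx = np.array([order[s] for s in ids])
    return anc.AncestrySpace(
        space.eigenvectors[idx],
        space.eigenvalues,
        space.subject_ids[idx],
        None if space.clusters is None else space.clusters[idx],
    )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _render_report(summary: dict) -> str:
    """Markdown run report shaped like the analysis' headline tables."""
    lines = ["# polyliab run report", "", f"Seed: {summary['seed']}", ""]
    st = summary["stages"]
    if "data" in st:
        lines += ["## Data", "", "```json", json.dumps(st["data"], indent=2, default=_jsonable), "```", ""]
    if "ancestry" in st:
        a = st["ancestry"]
        lines += [
            "## Ancestry and matching",
            "",
            f"- pruned variants: {a['m_pruned']}",
            f"- clusters: {a['n_clusters']}",
            f"- matched pairs: {a['n_pairs']} (mean distance {a['mean_pair_distance']:.4g})"
            if a["n_pairs"]
            else "- matched pairs: 0",
            "",
        ]
    eval_rows = []
    if "gblup" in st:
        eval_rows.append(("GP", st["gblup"]["evaluation"]))
    for name, block in st.get("prs", {}).items():
        eval_rows.append((name, block["evaluation"]))
    if "wgrs" in st:
        eval_rows.append(("WGRS", st["wgrs"]["evaluation"]))
    if eval_rows:
        lines += [
            "## Case-control evaluation (logistic regression, per SD of score)",
            "",
            "| Score | OR | 95% CI | P | pseudo-R2 (%) |",
            "|---|---|---|---|---|",
        ]
        for name, ev in eval_rows:
            ci = ev["CI95"]
            lines.append(
                f"| {name} | {ev['OR']:.2f} | {ci[0]:.2f}-{ci[1]:.2f} | {ev['P']:.3g} | {100 * ev['pseudo_R2']:.2f} |"
            )
        lines.append("")
    if "gblup" in st:
        g = st["gblup"]
        lines += [
            f"Genomic control: lambda = {g['gc_lambda']:.3f}; "
            f"case-control chi-square {g['chi2_observed']:.2f} -> {g['chi2_gc_corrected']:.2f} after GC.",
            "",
        ]
    if "carriers" in st:
        lines += ["## Carrier calls (most severe class)", ""]
        lines += [f"- {k}: {v}" for k, v in st["carriers"].items()]
        lines.append("")
    if "liability" in st:
        li = st["liability"]
        lines += [
            "## Liability-threshold calculus",
            "",
            f"- prevalence K = {li['prevalence']}, threshold t = {li['threshold']:.4f}",
            f"- mean liability: affected {li['mean_affected']:.3f}, unaffected {li['mean_unaffected']:.3f}",
            f"- carrier shift delta = {li['carrier_shift']:.3f} ({li['risk_scale']} scale)",
            f"- half-distance {li['half_distance']:.3f}; arithmetic midpoint {li['midpoint']:.3f}",
            f"- delta position on [unaffected, affected]: {li['carrier_shift_position']:.3f}",
        ]
        if li.get("observed"):
            o = li["observed"]
            lines += [
                "",
                "Observed WGRS group means: "
                f"affected {o['affected']:.3f}, unaffected {o['unaffected']:.3f}, "
                f"affected carriers {o['affected_carriers']:.3f} "
                f"(carrier position {o['carrier_position']:.3f} on [unaffected, affected]).",
            ]
        lines.append("")
    return "\n".join(lines)
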