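"""End-to-end orchestration: simulate → call-cna → timeline → deconvolve →
barcodes → cells, with every intermediate written to the output directory and
a machine-readable run report. Deterministic: rerunning with the same config
and seed reproduces every output byte for byte."""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, barcodes, cells, cna, io, sim, subclones, timing
from .genome import GenomeModel, demo_genome

__all__ = ["run_pipeline"]

log = logging.getLogger("preneo")


def _genome_from_config(config: dict) -> GenomeModel:
    g = config["genome"]
    if g.get("file"):
        return io.read_genome_model(g["file"], bin_size=g.get("bin_size"))
    return demo_genome(bin_size=g.get("bin_size") or 1_000_000)


def _sim_config(config: dict, genome: GenomeModel) -> sim.SimulationConfig:
    s = config["simulate"]
    return sim.SimulationConfig(genome=genome, seed=config["seed"], **s)


def run_pipeline(config: dict) -> dict:
    """Run every stage in dependency order; returns the run report dict."""
    logging.basicConfig(
        level=getattr(logging, str(config.get("log_level", "INFO")).upper(), logging.INFO),
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report: dict = {"version": __version__, "seed": seed, "stages": {}}

    genome = _genome_from_config(config)
    io.write_genome_model(genome, out / "genome.tsv")
    # normalized echo of the effective config (out_dir elided so that two runs
    # into different directories produce byte-identical output trees)
    io.write_config({**config, "out_dir": "."}, out / "config.yaml")

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        scfg = _sim_config(config, genome)
        history = sim.simulate_evolution(scfg)
    except Exception as err:
        raise RuntimeError(f"stage {stage} failed: {err}") from err
    if history.extinct:
        log.warning("simulate: extinction recorded: %s", history.extinct)
    history.clones_table().to_csv(out / "truth_clones.tsv", sep="\t", index=False)
    sizes_rows = []
    for phase, df in history.sizes.items():
        long = df.stack()
        long = long[long > 0]
        for (cid, day), n in long.items():
            sizes_rows.append({"phase": phase, "clone_id": cid, "day": day, "size": int(n)})
    pd.DataFrame(sizes_rows).to_csv(out / "truth_sizes.tsv", sep="\t", index=False)
    io.write_census(history.census_table(), out / "census.tsv")
    report["stages"][stage] = {
        "n_clones": len(history.clones),
        "extinct": {str(k): v for k, v in history.extinct.items()},
    }
    log.info("simulate: %d clones", len(history.clones))

    # --- call-cna per replicate and time point -----------------------------
    stage = "call-cna"
    swgs_days = [d for d in config["swgs"]["days"] if d <= scfg.n_days]
    cna_cfg = config["cna"]
    profiles_by_rep: dict[int, list[cna.CopyNumberProfile]] = {}
    try:
        for rep in range(scfg.n_replicates):
            profiles = []
            for day in swgs_days:
                replicate = rep if day >= scfg.effective_split_day else None
                if replicate is not None and replicate in history.extinct \
                        and day >= history.extinct[replicate]:
                    continue
                cov = sim.sample_swgs(
                    history, day,
                    mean_coverage=config["swgs"]["mean_coverage"],
                    read_length=config["swgs"]["read_length"],
                    replicate=replicate, seed=seed,
                    sample_id=f"R{rep + 1}_d{day}",
                )
                io.write_binned_coverage(cov, genome, out / f"bins_R{rep + 1}_d{day}.tsv")
                profiles.append(
                    cna.call_profile(
                        cov, genome,
                        penalty=cna_cfg["penalty"],
                        loss_threshold=cna_cfg["loss_threshold"],
                        gain_threshold=cna_cfg["gain_threshold"],
                        arm_call_fraction=cna_cfg["arm_call_fraction"],
                    )
                )
            profiles_by_rep[rep] = profiles
        all_profiles = [p for ps in profiles_by_rep.values() for p in ps]
        io.write_seg(all_profiles, out / "segments.seg")
        io.write_events(all_profiles, out / "events.tsv")
        io.write_metrics(all_profiles, out / "metrics.tsv")
    except Exception as err:
        raise RuntimeError(f"stage {stage} failed: {err}") from err
    report["stages"][stage] = {"n_profiles": len(all_profiles)}
    log.info("call-cna: %d profiles", len(all_profiles))

    # --- timeline ----------------------------------------------------------
    stage = "timeline"
    try:
        all_timelines = []
        for rep, profiles in profiles_by_rep.items():
            if len(profiles) >= 2:
                all_timelines.extend(
                    timing.build_timelines(
                        profiles, culture_id=f"R{rep + 1}",
                        tolerance=config["timing"]["tolerance"],
                    )
                )
        tl_rows = [
            {
                "culture": tl.culture_id,
                "event_id": tl.event_id,
                "persistent": tl.persistent,
                "extinct": tl.extinct,
                "time_of_appearance": tl.time_of_appearance
                if tl.time_of_appearance is not None else io.MISSING,
            }
            for tl in all_timelines
        ]
        pd.DataFrame(tl_rows).to_csv(out / "timelines.tsv", sep="\t", index=False)
        timing.summarize_order(all_timelines).to_csv(
            out / "event_order.tsv", sep="\t", index=False, float_format="%.6g"
        )
    except Exception as err:
        raise RuntimeError(f"stage {stage} failed: {err}") from err
    report["stages"][stage] = {"n_timelines": len(all_timelines)}

    # --- deconvolve --------------------------------------------------------
    stage = "deconvolve"
    try:
        n_clone_rows = 0
        for rep, profiles in profiles_by_rep.items():
            if len(profiles) < 2:
                continue
            traj = subclones.arm_event_trajectories(profiles)
            if traj.empty:
                continue
            groups = subclones.cluster_trajectories(
                traj, distance_threshold=config["deconvolve"]["distance_threshold"]
            )
            tree = subclones.build_clone_tree(
                groups, traj, nesting_tolerance=config["deconvolve"]["nesting_tolerance"]
            )
            subclones.detect_interference(tree)
            fish = tree.to_fishplot_table()
            fish.insert(0, "replicate", f"R{rep + 1}")
            fish.to_csv(out / f"clones_R{rep + 1}.tsv", sep="\t", index=False,
                        float_format="%.6g")
            pd.DataFrame(tree.episodes).to_csv(
                out / f"episodes_R{rep + 1}.tsv", sep="\t", index=False
            )
            n_clone_rows += len(fish)
    except Exception as err:
        raise RuntimeError(f"stage {stage} failed: {err}") from err
    report["stages"][stage] = {"n_fishplot_rows": n_clone_rows}

    # --- barcodes ----------------------------------------------------------
    stage = "barcodes"
    bcfg = config["barcodes"]
    try:
        bc_days = [d for d in bcfg["days"]
                   if d >= scfg.effective_split_day and d <= scfg.n_days]
        reps: list[barcodes.BarcodeCounts] = []
        for rep in range(scfg.n_replicates):
            days = [d for d in bc_days
                    if rep not in history.extinct or d < history.extinct[rep]]
            counts = sim.sample_barcode_counts(
                history, rep, days,
                total_reads=bcfg["total_reads"],
                overdispersion=bcfg["overdispersion"],
                seed=seed,
            )
            io.write_barcode_counts(counts, out / f"barcode_counts_R{rep + 1}.tsv")
            reps.append(
                barcodes.counts_to_frequencies(
                    counts, replicate_id=f"R{rep + 1}",
                    min_reads=bcfg["min_reads"], min_frequency=bcfg["min_frequency"],
                )
            )
        fitness_rows = []
        muller_frames = []
        for rep, bc in enumerate(reps):
            census = history.census_table()
            census = census[census["phase"] == rep][["day", "n_cells"]]
            if len(census) >= 2 and len(bc.days) >= 4:
                curves = barcodes.clone_growth(bc, census, span=bcfg["span"])
                for curve in curves.values():
                    for i, day in enumerate(curve.days):
                        fitness_rows.append(
                            {
                                "replicate": bc.replicate_id,
                                "barcode": curve.barcode_id,
                                "day": int(day),
                                "abundance": curve.abundance[i],
                                "growth_derivative": curve.derivative[i],
                                "fold_change": curve.fold_change[i],
                            }
                        )
            mt = barcodes.muller_table(bc)
            mt.insert(0, "replicate", bc.replicate_id)
            muller_frames.append(mt)
        pd.DataFrame(fitness_rows).to_csv(
            out / "fitness.tsv", sep="\t", index=False, float_format="%.6g", na_rep=io.MISSING
        )
        pd.concat(muller_frames).to_csv(
            out / "muller.tsv", sep="\t", index=False, float_format="%.6g"
        )
        conc = barcodes.replicate_concordance(reps, min_frequency=bcfg["min_frequency"])
        conc_rows = [
            {"pair": f"{a}|{b}", "spearman": rho}
            for (a, b), rho in conc["pairwise_correlations"].items()
        ]
        pd.DataFrame(conc_rows).to_csv(
            out / "concordance.tsv", sep="\t", index=False, float_format="%.6g"
        )
        report["stages"][stage] = {
            "same_winner": bool(conc["same_winner"]),
            "winners": conc["winners"],
            "mean_correlation": conc["mean_correlation"],
        }
        log.info("barcodes: same winner across replicates = %s", conc["same_winner"])
    except Exception as err:
        raise RuntimeError(f"stage {stage} failed: {err}") from err

    # --- cells -------------------------------------------------------------
    stage = "cells"
    ccfg = config["cells"]
    scrna_cfg = config["scrna"]
    try:
        day = min(scrna_cfg["day"], scfg.n_days)
        rep0 = next(
            (r for r in range(scfg.n_replicates)
             if r not in history.extinct or day < history.extinct[r]),
            None,
        )
        if rep0 is None:
            raise RuntimeError("all replicates extinct before the scRNA day")
        n_cells = min(scrna_cfg["n_cells"], history.population_size(day, rep0))
        adata = sim.sample_scrna(
            history, day, n_cells,
            genes_per_arm=scrna_cfg["genes_per_arm"], seed=seed, replicate=rep0,
        )
        io.write_cell_matrix(adata, out, prefix="cells")
        filtered, qc_report = cells.qc_filter(adata, min_counts=100, min_genes=20)
        reference = sim.sample_diploid_reference(
            genome, n_cells=scrna_cfg["n_reference_cells"],
            genes_per_arm=scrna_cfg["genes_per_arm"], seed=seed,
        )
        io.write_cell_matrix(reference, out, prefix="reference")
        cc = cells.infer_cell_cna(
            filtered, reference, genome,
            window_genes=ccfg["window_genes"],
            arm_threshold=ccfg["arm_threshold"],
            min_cells=ccfg["min_cells"],
        )
        cc.arm_calls.to_csv(out / "cell_arm_calls.tsv", sep="\t", na_rep=io.MISSING)
        cc.consensus.to_csv(out / "barcode_arm_calls.tsv", sep="\t", na_rep=io.MISSING)
        bulk = next(
            (p for p in profiles_by_rep.get(rep0, []) if p.day == day), None
        )
        linkage_report = {}
        if bulk is not None:
            link = cells.link_barcode_cna(cc, bulk)
            link["table"].to_csv(out / "cna_linkage.tsv", sep="\t", index=False)
            linkage_report = {"jaccard": link["jaccard"]}

        atlas, _programs = sim.sample_typed_reference(
            genome, n_cells=max(200, 8 * ccfg["k"]),
            genes_per_arm=scrna_cfg["genes_per_arm"], seed=seed,
        )
        model = cells.fit_reference(
            atlas, atlas.obs["cell_type"], n_dims=ccfg["n_dims"],
            n_top_genes=ccfg["n_top_genes"],
        )
        coords, shared = cells.project_cells(model, filtered)
        pd.DataFrame(
            coords, index=filtered.obs_names,
            columns=[f"LSI{i + 1}" for i in range(coords.shape[1])],
        ).to_csv(out / "projection.tsv", sep="\t", float_format="%.6g")
        type_freq = cells.knn_type_frequencies(
            coords, model, k=ccfg["k"], samples=filtered.obs["sample_id"]
        )
        type_freq.to_csv(out / "type_frequencies.tsv", sep="\t", float_format="%.6g")

        # DE + enrichment: cells of the winning barcode vs the rest
        bc_counts = filtered.obs["barcode_id"].value_counts()
        deg_report = {}
        if len(bc_counts) >= 2 and (bc_counts >= 3).sum() >= 2:
            top_bc = int(bc_counts.index[0])
            group_a = filtered[filtered.obs["barcode_id"] == top_bc]
            group_b = filtered[filtered.obs["barcode_id"] != top_bc]
            if group_a.n_obs >= 3 and group_b.n_obs >= 3:
                degs = cells.deg_wilcoxon(group_a, group_b)
                degs.to_csv(out / "degs.tsv", sep="\t", float_format="%.6g")
                scores = pd.Series(
                    degs["direction"] * -np.log10(np.maximum(degs["p"], 1e-300)),
                    index=degs.index,
                )
                arm_sets = {
                    f"arm_{arm}": list(adata.var_names[adata.var["arm"] == arm])
                    for arm in adata.var["arm"].unique()
                    if arm != "MT"
                }
                gsea = cells.gsea_ks(scores, arm_sets)
                gsea.to_csv(out / "gsea.tsv", sep="\t", float_format="%.6g")
                deg_report = {"n_significant": int(degs["significant"].sum())}
        report["stages"][stage] = {
            "n_cells": int(filtered.n_obs),
            "qc": qc_report,
            "shared_gene_fraction": shared,
            **linkage_report,
            **deg_report,
        }
    except Exception as err:
        raise RuntimeError(f"stage {stage} failed: {err}") from err

    io.write_run_report(report, out / "run_report.json")
    log.info("pipeline complete: %s", out)
    return report
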