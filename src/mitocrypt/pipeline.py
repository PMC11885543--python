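"""End-to-end pipeline: QC -> call -> classify -> annotate -> cSFS -> stats -> fit.

``run_pipeline`` binds the library stages together, writes every artifact as
TSV under the configured output directory, and returns a machine-readable
run report accounting for every record (retained or named-filter-dropped),
the thresholds actually used, and the seed.  Reruns with an identical config
are byte-identical.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalescent_fit, io, sfs_stats, variant_calling

logger = logging.getLogger("mitocrypt")

__all__ = ["run_pipeline", "annotation_opportunity"]


def annotation_opportunity(annotation: pd.DataFrame) -> tuple[int, int]:
    """(non-synonymous, synonymous) substitution counts of the annotation universe."""
    n_nonsyn = int(annotation["class"].isin(["low", "high", "non-synonymous"]).sum())
    n_syn = int((annotation["class"] == "synonymous").sum())
    return n_nonsyn, n_syn


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Execute the full analysis described by ``config`` and write artifacts."""
    logging.basicConfig(level=config.verbosity.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {}, "stages": {}}
    report["config"] = {
        k: v
        for k, v in vars(config).items()
        if not k.startswith("_")
    }
    report["config"]["theta_bounds"] = list(config.theta_bounds)
    logger.info("thresholds: %s", report["config"])

    stage = "read"
    try:
        counts = io.read_base_counts(config.counts, config.metadata)
        meta = io.read_metadata(config.metadata)
        annotation = io.read_annotation(config.annotation)
        reference = io.read_reference(config.reference)
    except Exception as exc:  # noqa: BLE001 - abort with the stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report["stages"]["read"] = {
        "count_rows": int(len(counts)),
        "cells": int(counts["cell"].nunique()),
        "donors": int(counts["donor"].nunique()),
    }

    stage = "qc"
    try:
        mask = variant_calling.qc_filter(
            counts,
            min_depth=config.min_depth,
            min_positions=config.min_positions,
            sigma_mult=config.sigma_mult,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report["stages"]["qc"] = {
        "cells_retained": mask.n_retained,
        "cells_dropped": int((~mask.retained_cells).sum()),
        "qualified_positions": int(mask.qualified.sum()),
    }

    stage = "call"
    try:
        called = variant_calling.call_variants(counts, mask, reference)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report["stages"]["call"] = {"variants_called": int(len(called))}

    stage = "classify"
    try:
        site_idx = pd.MultiIndex.from_frame(called[["donor", "site"]])
        site_ok = (
            mask.site_cell_counts.reindex(site_idx).fillna(0).to_numpy()
            >= config.min_cells_per_site
        )
        vt = variant_calling.classify_variants(
            called,
            mask,
            cryptic_floor=config.cryptic_floor,
            report_floor=config.report_floor,
            common_donor_count=config.common_donor_count,
            min_cells_per_site=config.min_cells_per_site,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    n_site_dropped = int((~site_ok).sum())
    report["stages"]["classify"] = {
        "dropped_site_qc": n_site_dropped,
        "dropped_report_floor": int(len(called)) - n_site_dropped - int(len(vt)),
        "retained": int(len(vt)),
        "by_class": vt["classification"].value_counts().to_dict()
        if len(vt)
        else {},
    }

    stage = "annotate"
    try:
        species = meta.drop_duplicates("donor").set_index("donor")["species"]
        vt = variant_calling.annotate_variants(vt, annotation, species=species)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    io.write_variant_table(vt, out / "variants.tsv", format="tsv")
    io.write_variant_table(vt, out / "variants.vcf", format="vcf")

    stage = "csfs"
    donors = sorted(meta["donor"].unique())
    spectra = {}
    try:
        for donor in donors:
            if donor not in set(vt["donor"]):
                continue
            csfs = sfs_stats.build_csfs(
                vt,
                donor,
                bins=config.bins,
                homoplasmy_cut=config.homoplasmy_cut,
                floor=config.report_floor,
            )
            spectra[donor] = csfs
            io.write_csfs(
                csfs,
                out / f"csfs_{donor}.tsv",
                out / f"csfs_{donor}_raw.tsv",
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report["stages"]["csfs"] = {
        d: int(s.counts.sum()) for d, s in spectra.items()
    }

    stage = "statistics"
    try:
        ages = meta.drop_duplicates("donor").set_index("donor")["age_years"]
        pairs = [
            (a, b)
            for a, b in itertools.combinations(donors, 2)
            if a in spectra and b in spectra
            and not spectra[a].empty and not spectra[b].empty
        ]
        comp_rows = []
        for a, b in pairs:
            older, younger = (a, b) if ages[a] >= ages[b] else (b, a)
            res = sfs_stats.compare_sfs(
                spectra[older].heteroplasmies,
                spectra[younger].heteroplasmies,
                family_size=max(len(pairs), 1),
            )
            comp_rows.append(
                {
                    "group1": older,
                    "group2": younger,
                    "age_gap": float(ages[older] - ages[younger]),
                    "r": res["r"],
                    "U": res["U"],
                    "p": res["p"],
                    "p_bonferroni": res["p_bonferroni"],
                }
            )
        comparisons = pd.DataFrame(comp_rows)
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)

        selection = {}
        if len(vt):
            opp = annotation_opportunity(annotation)
            for scope in ("cryptic", "non-cryptic"):
                res = sfs_stats.dnds_test(
                    vt, scope=scope, floor=config.report_floor, opportunity=opp
                )
                selection[scope] = {
                    "ratio": res["ratio"],
                    "p": res["p"],
                    "odds_ratio": res["odds_ratio"],
                }
        bulk = (
            sfs_stats.pseudobulk_spectrum(counts, vt, bulk_cut=config.bulk_cut)
            if len(vt)
            else None
        )
        if bulk is not None:
            bulk["per_variant"].to_csv(out / "pseudobulk.tsv", sep="\t", index=False)
        qpos = mask.qualified_per_cell[mask.retained_cells]
        homo = (
            sfs_stats.homoplasmy_rate(vt, qpos, cut=config.homoplasmy_cut)
            if len(vt)
            else None
        )
        loads = []
        for cell, grp in vt.groupby("cell"):
            rec = sfs_stats.mutation_load(grp, t=config.report_floor)
            loads.append(
                {
                    "cell": cell,
                    "load": rec.load,
                    "threshold": rec.threshold,
                    "n_contributing": rec.n_contributing,
                }
            )
        pd.DataFrame(loads).to_csv(out / "loads.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report["stages"]["statistics"] = {
        "n_comparisons": len(pairs),
        "selection": selection,
        "pseudobulk_fraction_below_cut": None
        if bulk is None
        else bulk["fraction_below_cut"],
        "homoplasmy_rate_cohort": None if homo is None else homo["cohort_mean"],
    }

    if config.run_fit:
        stage = "fit"
        try:
            fit_rows = []
            for donor, csfs in spectra.items():
                if csfs.empty:
                    continue
                n_cells = int(
                    meta.loc[
                        meta["donor"] == donor, "cell"
                    ].isin(mask.retained_cells[mask.retained_cells].index).sum()
                )
                fit = coalescent_fit.fit_donor(
                    csfs.heteroplasmies,
                    n_cells,
                    priors={
                        "W_max": config.w_max,
                        "theta_bounds": config.theta_bounds,
                    },
                    seed=config.seed,
                    floor=config.report_floor,
                    bins=config.bins,
                    homoplasmy_cut=config.homoplasmy_cut,
                    reference_N=config.reference_N,
                )
                nu = coalescent_fit.rate_from_theta(fit.map_theta, config.N)
                fit_rows.append(
                    {
                        "donor": donor,
                        "age_years": float(ages[donor]),
                        "map_W": fit.map_W,
                        "map_theta": fit.map_theta,
                        "nu": nu,
                        "ci_W_low": fit.ci_W[0],
                        "ci_W_high": fit.ci_W[1],
                        "ci_theta_low": fit.ci_theta[0],
                        "ci_theta_high": fit.ci_theta[1],
                    }
                )
            fits = pd.DataFrame(fit_rows)
            fits.to_csv(out / "fits.tsv", sep="\t", index=False)
            report["stages"]["fit"] = {
                "donors_fit": len(fit_rows),
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
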