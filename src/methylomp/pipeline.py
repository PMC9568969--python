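"""End-to-end orchestration: simulate/load -> filter -> OMP -> cluster ->
stability -> genes -> deconvolution, with a machine-readable run manifest.

A single master seed in the config fans out to per-stage seeds (stage-name
hashed), so each stage is reproducible in isolation and two runs with the
same config produce byte-identical output directories. All numeric
thresholds of every stage live in one config mapping whose defaults are the
procedure's published values (1.5 fence multiplier via the Tukey rule;
3/5/0.8 promoter gene rules; any-missing probe trimming).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import clustering, deconvolution, filtering, genes, omp, stability, synthetic
from .data_io import (
    BetaMatrix,
    DataValidationError,
    ProbeAnnotation,
    SampleSheet,
    read_beta_matrix,
    read_probe_annotation,
    read_probe_subset,
    read_sample_sheet,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
)
from .synthetic import CohortSpec, derive_seed

logger = logging.getLogger("methylomp")

STAGES = ("simulate", "filter", "omp", "cluster", "stability", "genes", "deconv")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "skip": [],
    "simulate": {},  # CohortSpec overrides; set to None to load inputs instead
    "inputs": {},  # cord, saliva, sample_sheet, annotation (paths)
    "filter": {
        "max_missing_frac": 0.0,
        "exclude_for_clustering": ["xy_snp"],
        "exclude_for_stability": ["blood_saliva_discordant"],
        "restrict": {},  # subset name -> path
    },
    "omp": {
        "quantile_method": "linear",
        "leave_one_out": False,
        "external_reference": None,  # path to a beta matrix, or null
        "n_external_simulated": 7,
    },
    "cluster": {"B": 100, "k_outliers": 3, "metric": "correlation", "linkage": "average"},
    "stability": {"ci_method": "fisher", "subsets": {}},  # name -> path
    "genes": {
        "min_cpgs_hyper": 3,
        "min_cpgs_hypo": 5,
        "min_frac": 0.8,
        "denominator": "outlier",
        "promoter_groups": list(synthetic.PROMOTER_GROUPS),
    },
    "deconv": {"reference": None},  # path, or null for the synthetic panel
}


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: dict[str, Any], outdir: Path):
        self.config = config
        self.outdir = outdir
        self.manifest: dict[str, Any] = {
            "config": config,
            "stages": {},
            "files": {},
        }
        self.cord: BetaMatrix | None = None
        self.saliva: BetaMatrix | None = None
        self.sheet: SampleSheet | None = None
        self.ann: ProbeAnnotation | None = None
        self.truth: synthetic.CohortTruth | None = None
        self.cord_filtered: BetaMatrix | None = None
        self.saliva_filtered: BetaMatrix | None = None
        self.omp_result: omp.OmpResult | None = None
        self.external_result: omp.OmpResult | None = None
        self.dendrogram: clustering.Dendrogram | None = None

    def record_file(self, path: Path) -> None:
        self.manifest["files"][str(path.relative_to(self.outdir))] = _sha256(path)

    def write_manifest(self) -> None:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")


def run_full(config: Mapping[str, Any], outdir: str | Path) -> Path:
    """Execute the pipeline per the config; returns the run directory.

    Any stage listed in ``config['skip']`` is skipped (noted in the
    manifest). A stage failure halts the run after writing a partial
    manifest naming the failed stage.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(cfg, outdir)
    skip = set(cfg["skip"])
    try:
        for stage in STAGES:
            if stage in skip:
                run.manifest["stages"][stage] = {"status": "skipped"}
                continue
            info = _STAGE_FUNCS[stage](run)
            run.manifest["stages"][stage] = {"status": "ok", **(info or {})}
    except Exception as exc:
        run.manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        run.write_manifest()
        raise
    run.write_manifest()
    return outdir


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(run: PipelineRun) -> dict[str, Any]:
    cfg = run.config
    if cfg.get("simulate") is None:
        paths = cfg["inputs"]
        run.cord = read_beta_matrix(paths["cord"])
        run.saliva = read_beta_matrix(paths["saliva"])
        run.sheet = read_sample_sheet(paths["sample_sheet"])
        run.ann = read_probe_annotation(paths["annotation"])
        return {"mode": "loaded", "n_probes": run.cord.n_probes}
    spec_kwargs = dict(cfg["simulate"])
    spec_kwargs.setdefault("seed", derive_seed(cfg["seed"], "simulate"))
    spec = CohortSpec(**spec_kwargs)
    run.cord, run.saliva, run.sheet, run.ann, run.truth = synthetic.simulate_cohort(spec)
    run.spec = spec
    for name, writer, obj in (
        ("cord_betas.tsv", write_beta_matrix, run.cord),
        ("saliva_betas.tsv", write_beta_matrix, run.saliva),
    ):
        path = run.outdir / name
        writer(obj, path)
        run.record_file(path)
    path = run.outdir / "sample_sheet.tsv"
    write_sample_sheet(run.sheet, path)
    run.record_file(path)
    path = run.outdir / "probe_annotation.tsv"
    write_probe_annotation(run.ann, path)
    run.record_file(path)
    return {
        "mode": "simulated",
        "n_probes": run.cord.n_probes,
        "n_individuals": spec.n_individuals,
        "planted_omp": sorted(run.truth.planted_omp),
        "seed": spec.seed,
    }


def _stage_filter(run: PipelineRun) -> dict[str, Any]:
    fcfg = run.config["filter"]
    cord, rep_c = filtering.drop_failed_probes(run.cord, fcfg["max_missing_frac"])
    saliva, rep_s = filtering.drop_failed_probes(run.saliva, fcfg["max_missing_frac"])
    for name, path in fcfg.get("restrict", {}).items():
        subset = read_probe_subset(path)
        cord = filtering.restrict_to_subset(cord, subset, name)
        saliva = filtering.restrict_to_subset(saliva, subset, name)
    run.cord_filtered = cord
    run.saliva_filtered = saliva
    report = {"cord": rep_c.to_dict(), "saliva": rep_s.to_dict()}
    path = run.outdir / "filter_report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    run.record_file(path)
    return {"n_probes_cord": cord.n_probes, "n_probes_saliva": saliva.n_probes}


def _named_subsets(run: PipelineRun, names: Iterable[str]) -> dict[str, set[str]]:
    out = {}
    for name in names:
        out[name] = run.ann.subset(name) if run.ann is not None else set()
    return out


def _stage_omp(run: PipelineRun) -> dict[str, Any]:
    ocfg = run.config["omp"]
    method = ocfg["quantile_method"]
    cord = run.cord_filtered
    sample_to_ind = run.sheet.sample_to_individual()
    fences = omp.compute_fences(cord, method)
    profiles = omp.call_outliers(cord.select_probes(fences.probe_ids), fences, sample_to_ind)
    result = omp.call_omp(profiles, method, leave_one_out=ocfg["leave_one_out"])
    run.omp_result = result

    path = run.outdir / "fences.tsv"
    fences.to_frame().to_csv(path, sep="\t", index_label="probe_id")
    run.record_file(path)
    counts = pd.DataFrame(
        {
            "individual_id": [p.individual_id for p in profiles],
            "n_outliers": [p.n_outliers for p in profiles],
            "n_missing": [p.n_missing for p in profiles],
            "omp_call": [p.individual_id in result.omp_calls for p in profiles],
        }
    )
    path = run.outdir / "outlier_counts.tsv"
    counts.to_csv(path, sep="\t", index=False)
    run.record_file(path)
    for prof in profiles:
        if prof.individual_id in result.omp_calls:
            df = pd.DataFrame(
                sorted(prof.outlier_probes.items()), columns=["probe_id", "direction"]
            )
            path = run.outdir / f"outlier_probes_{prof.individual_id}.tsv"
            df.to_csv(path, sep="\t", index=False)
            run.record_file(path)

    info: dict[str, Any] = {
        "count_upper_limit": result.count_upper_limit,
        "omp_calls": sorted(result.omp_calls),
    }
    ref = None
    if ocfg.get("external_reference"):
        ref = read_beta_matrix(ocfg["external_reference"])
    elif run.truth is not None and ocfg.get("n_external_simulated"):
        ref = synthetic.simulate_external_reference(
            run.spec, run.truth, int(ocfg["n_external_simulated"])
        )
    if ref is not None:
        ext = omp.call_omp_external(cord, ref, method, individual_ids=sample_to_ind)
        run.external_result = ext
        info["external"] = {
            "count_upper_limit": ext.count_upper_limit,
            "omp_calls": sorted(ext.omp_calls),
            "n_shared_probes": ext.n_shared_probes,
        }
    if run.truth is not None:
        planted = run.truth.planted_omp
        info["planted_omp_recovered"] = sorted(result.omp_calls & planted)
        info["n_planted_recovered"] = len(result.omp_calls & planted)
        info["n_planted"] = len(planted)
    return info


def _stage_cluster(run: PipelineRun) -> dict[str, Any]:
    ccfg = run.config["cluster"]
    excl = _named_subsets(run, run.config["filter"]["exclude_for_clustering"])
    m = run.cord_filtered
    for name, subset in excl.items():
        m, _rep = filtering.exclude_subset(m, subset, name)
    dend = clustering.bootstrap_support(
        m,
        B=int(ccfg["B"]),
        seed=derive_seed(run.config["seed"], "cluster"),
        metric=ccfg["metric"],
        linkage=ccfg["linkage"],
    )
    run.dendrogram = dend
    path = run.outdir / "dendrogram.nwk"
    with open(path, "w") as fh:
        fh.write(dend.to_newick() + "\n")
    run.record_file(path)

    joins = dend.singleton_join_heights()
    outliers = clustering.outlier_branches(dend, int(ccfg["k_outliers"]))
    fam_samples = {
        fam: [
            s for s in run.sheet.samples_for_tissue("cord_blood")["sample_id"]
            if run.sheet.sample_to_individual()[s] in inds
        ]
        for fam, inds in run.sheet.families().items()
    }
    clades = clustering.family_clade_report(dend, fam_samples)
    df = pd.DataFrame(
        {
            "sample_id": list(joins),
            "singleton_join_height": [joins[s] for s in joins],
            "outlier_branch": [s in outliers for s in joins],
        }
    ).sort_values("sample_id")
    path = run.outdir / "cluster_outliers.tsv"
    df.to_csv(path, sep="\t", index=False)
    run.record_file(path)
    path = run.outdir / "family_clades.tsv"
    pd.DataFrame(
        sorted(clades.items()), columns=["family_id", "forms_clade"]
    ).to_csv(path, sep="\t", index=False)
    run.record_file(path)
    return {
        "outlier_branches": sorted(outliers),
        "families_forming_clades": sum(clades.values()),
        "families_checked": len(clades),
    }


def _stage_stability(run: PipelineRun) -> dict[str, Any]:
    scfg = run.config["stability"]
    excl = _named_subsets(run, run.config["filter"]["exclude_for_stability"])
    cord, saliva = run.cord_filtered, run.saliva_filtered
    for name, subset in excl.items():
        cord, _ = filtering.exclude_subset(cord, subset, name)
        saliva, _ = filtering.exclude_subset(saliva, subset, name)
    pairs = stability.pair_samples(run.sheet)
    subsets = {name: read_probe_subset(p) for name, p in scfg.get("subsets", {}).items()}
    table = stability.stability_table(cord, saliva, pairs, subsets, scfg["ci_method"])
    path = run.outdir / "stability.tsv"
    table.to_csv(path, sep="\t")
    run.record_file(path)

    partition_rows = []
    if run.omp_result is not None:
        by_id = {p.individual_id: p for p in run.omp_result.profiles}
        shared = set(cord.probe_ids.intersection(saliva.probe_ids))
        for ind in sorted(run.omp_result.omp_calls):
            pair = next((p for p in pairs if p.individual_id == ind), None)
            if pair is None:
                continue
            outlier_set = set(by_id[ind].outlier_probes) & shared
            if not outlier_set or outlier_set >= shared:
                continue
            for res in stability.stability_partition(
                cord, saliva, pair, outlier_set, scfg["ci_method"]
            ):
                partition_rows.append(dataclasses.asdict(res))
    if partition_rows:
        path = run.outdir / "stability_partition.tsv"
        pd.DataFrame(partition_rows).to_csv(path, sep="\t", index=False)
        run.record_file(path)
    return {
        "n_pairs": len(pairs),
        "r2_all_min": float(table["r2_all"].min()),
        "r2_all_max": float(table["r2_all"].max()),
    }


def _stage_genes(run: PipelineRun) -> dict[str, Any]:
    gcfg = run.config["genes"]
    if run.omp_result is None or not run.omp_result.omp_calls:
        return {"note": "no OMP calls; gene stage produced no lists"}
    inter = genes.intersect_outliers(run.omp_result.profiles, run.omp_result.omp_calls)
    pmap = genes.restrict_to_promoters(
        inter.directions(), run.ann, gcfg["promoter_groups"]
    )
    calls = genes.call_genes(
        pmap,
        min_cpgs_hyper=int(gcfg["min_cpgs_hyper"]),
        min_cpgs_hypo=int(gcfg["min_cpgs_hypo"]),
        min_frac=float(gcfg["min_frac"]),
        denominator=gcfg["denominator"],
    )
    paths = genes.export_gene_lists(calls, run.outdir)
    for p in paths.values():
        run.record_file(p)
    return {
        "n_common_outliers": len(inter.common_probes),
        "n_consistent_hyper": len(inter.consistent_hyper),
        "n_consistent_hypo": len(inter.consistent_hypo),
        "n_mixed": len(inter.mixed),
        "n_gene_calls_hyper": sum(1 for c in calls if c.direction == "hyper"),
        "n_gene_calls_hypo": sum(1 for c in calls if c.direction == "hypo"),
    }


def _stage_deconv(run: PipelineRun) -> dict[str, Any]:
    dcfg = run.config["deconv"]
    if dcfg.get("reference"):
        ref = deconvolution.read_celltype_reference(dcfg["reference"])
    else:
        ref = deconvolution.CellTypeReference(
            synthetic.make_celltype_reference(
                seed=derive_seed(getattr(run, "spec", None).seed
                                 if run.truth is not None else run.config["seed"],
                                 "celltype_ref")
            )
        )
    frames = []
    for m in (run.cord, run.saliva):
        frames.append(deconvolution.estimate_proportions(m, ref))
    props = pd.concat(frames)
    path = run.outdir / "cell_proportions.tsv"
    props.to_csv(path, sep="\t")
    run.record_file(path)
    return {
        "mean_leukocyte_fraction": float(props["leukocyte"].mean()),
        "n_samples": int(props.shape[0]),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "omp": _stage_omp,
    "cluster": _stage_cluster,
    "stability": _stage_stability,
    "genes": _stage_genes,
    "deconv": _stage_deconv,
}


# ---------------------------------------------------------------------------
# Sensitivity re-run
# ---------------------------------------------------------------------------


def sensitivity_rerun(
    config: Mapping[str, Any],
    drop_individuals: set[str],
    outdir: str | Path,
) -> Path:
    """Recompute OMP and clustering after dropping individuals.

    Mirrors the design check of excluding a subgroup (e.g. the unassisted
    conceptions) and asking whether the same individuals are called OMP.
    Writes the reduced-cohort outputs plus ``sensitivity_report.json``
    comparing the calls to the full run.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    full_dir = outdir / "full"
    reduced_dir = outdir / "reduced"

    run_full(cfg, full_dir)
    with open(full_dir / "manifest.json") as fh:
        full_manifest = json.load(fh)
    full_calls = set(full_manifest["stages"]["omp"]["omp_calls"])

    # rebuild the cohort identically, then drop
    run = PipelineRun(cfg, reduced_dir)
    reduced_dir.mkdir(parents=True, exist_ok=True)
    _stage_simulate(run)
    keep = [i for i in run.sheet.individuals if i not in drop_individuals]
    if len(keep) < 4:
        raise DataValidationError("sensitivity re-run would leave fewer than 4 individuals")
    missing = set(drop_individuals) - set(run.sheet.individuals)
    if missing:
        raise DataValidationError(f"cannot drop unknown individuals: {sorted(missing)}")
    run.sheet = run.sheet.restrict_individuals(keep)
    keep_samples = [s for s in run.cord.sample_ids if s in set(run.sheet.sample_ids)]
    run.cord = run.cord.select_samples(keep_samples)
    keep_samples = [s for s in run.saliva.sample_ids if s in set(run.sheet.sample_ids)]
    run.saliva = run.saliva.select_samples(keep_samples)
    if run.truth is not None:
        run.truth.planted_omp &= set(keep)

    for stage in ("filter", "omp", "cluster"):
        info = _STAGE_FUNCS[stage](run)
        run.manifest["stages"][stage] = {"status": "ok", **(info or {})}
    run.write_manifest()

    reduced_calls = set(run.manifest["stages"]["omp"]["omp_calls"])
    expected = full_calls - set(drop_individuals)
    report = {
        "dropped": sorted(drop_individuals),
        "full_omp_calls": sorted(full_calls),
        "reduced_omp_calls": sorted(reduced_calls),
        "calls_identical_on_retained": reduced_calls == expected,
    }
    with open(outdir / "sensitivity_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
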