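"""End-to-end orchestration: chronology -> staging -> profiles -> deconvolution.

The preset synthetic pipeline generates every input it needs (with ground
truth written alongside), runs each analysis stage, and writes deterministic
TSV/JSON results plus a manifest with seeds and file checksums. Reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import chronology as chron
from . import deconvolution as deconv
from . import io as dio
from . import profiles as prof
from . import synthetic as synth
from ._splines import SplineConfig
from .config import PipelineConfig
from .staging import StagePlan, compare_rate_models, fit_stage_model

logger = logging.getLogger("devocoevol.pipeline")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


def _stage_chronology(cfg: PipelineConfig, outdir: Path) -> None:
    ccfg = synth.ChronologySimConfig(sigma=cfg.synthetic.chronology_sigma,
                                     n=cfg.synthetic.chronology_n)
    pairs, _ = synth.simulate_weight_age(ccfg.curve, ccfg.sigma, ccfg.n, cfg.seed)
    model = chron.fit_weight_age(pairs, species="synthetic")
    grid = np.linspace(*model.training_range, 50)
    pred = pd.DataFrame({"weight_mg": grid, "age_dpc": model.predict(grid)})
    dio.write_table(pred.set_index("weight_mg"), outdir / "chronology_curve.tsv")
    summary = {"species": model.species, "box_cox_lambda": model.transform_lambda,
               "rmse_days": model.rmse, "training_range_mg": list(model.training_range)}
    milestones = {}
    for sp, m in cfg.milestones.items():
        milestones[sp] = {"age_at_0": m.age_at_0, "age_at_10": m.age_at_10}
    with open(outdir / "chronology_summary.json", "w") as fh:
        json.dump({"model": summary, "milestones": milestones}, fh, indent=2, sort_keys=True)


def _staging_plan(cfg: PipelineConfig) -> StagePlan:
    s = cfg.staging
    K = len(s.stage_labels)
    rc = tuple(s.rate_classes) if s.rate_classes is not None else tuple(range(K - 1))
    return StagePlan(tuple(s.stage_labels), tuple([s.substates] * (K - 1) + [1]),
                     rc, start_time=s.start_time, name="configured")


def _stage_staging(cfg: PipelineConfig, outdir: Path) -> None:
    plan = _staging_plan(cfg)
    durations = np.asarray(synth.MOLAR_DURATIONS[:plan.n_stages - 1], float)
    durations = durations / durations.sum() * 0.82 * (cfg.staging.window[1] - cfg.staging.window[0])
    rates = np.asarray(plan.substates_per_stage[:-1], float)[
        list(range(plan.n_stages - 1))] / durations
    # one rate per stage in the generating model; fit the configured classes
    gen_plan = StagePlan(plan.stage_labels, plan.substates_per_stage,
                         tuple(range(plan.n_stages - 1)), plan.start_time, name="full")
    cohort = synth.simulate_staging_cohort(gen_plan, rates, cfg.staging.n_embryos,
                                           cfg.staging.window, cfg.seed)
    dio.write_table(cohort.as_frame(), outdir / "staging_observations.tsv",
                    index_label="embryo")
    fit = fit_stage_model(plan, (cohort.t, cohort.stage), seed=cfg.seed)
    out = pd.DataFrame({
        "stage": plan.stage_labels[:-1],
        "rate": fit.rates[list(plan.rate_class)],
        "duration": fit.durations,
        "relative_duration": fit.relative_durations,
        "true_relative_duration": cohort.true_relative_durations,
    }).set_index("stage")
    dio.write_table(out, outdir / "staging_durations.tsv")
    # nested rate-class comparison: common rate vs per-stage rates
    plans = [StagePlan(plan.stage_labels, plan.substates_per_stage,
                       tuple([0] * (plan.n_stages - 1)), plan.start_time, name="1-rate"),
             gen_plan]
    comp = compare_rate_models((cohort.t, cohort.stage), plans, seed=cfg.seed)
    dio.write_table(pd.DataFrame(comp.lrt_table).set_index("reduced"),
                    outdir / "staging_lrt.tsv")


def _stage_profiles(cfg: PipelineConfig, outdir: Path) -> dict:
    n = cfg.synthetic.n_genes_per_class
    pcfg = replace(synth.ProfilesSimConfig(),
                   n_per_class={c: n for c in ("simple", "species", "tooth", "complex")},
                   times=tuple(np.linspace(0.0, 10.0, cfg.synthetic.n_timepoints)),
                   effect_size=cfg.synthetic.effect_size,
                   dispersion=cfg.synthetic.dispersion,
                   spline=SplineConfig(degree=cfg.spline.degree,
                                       interior_knots=cfg.spline.interior_knots))
    sim = synth.simulate_profiles(pcfg, cfg.seed)
    dio.write_counts(sim.dataset.counts, outdir / "profiles_counts.tsv")
    dio.write_table(sim.dataset.samples, outdir / "profiles_samples.tsv",
                    index_label="sample")
    dio.write_table(sim.truth, outdir / "profiles_truth.tsv")

    sel = prof.select_profile_model(sim.dataset, pcfg.spline, keep_fits=True)
    cols = [c for c in sel.table.columns if c != "reason"]
    dio.write_table(sel.table[cols], outdir / "profiles_selection.tsv")
    index = prof.coevolution_index(sel)
    counts = sel.class_counts.to_dict()
    with open(outdir / "profiles_coevolution.json", "w") as fh:
        json.dump({"coevolution_index": index,
                   "class_counts": {k: int(v) for k, v in counts.items()}},
                  fh, indent=2, sort_keys=True)

    organs = sim.dataset.organ_levels
    divergence = {}
    for organ in organs:
        table, proportion = prof.divergence_per_organ(sim.dataset, organ, pcfg.spline)
        dio.write_table(table, outdir / f"divergence_{organ}.tsv")
        divergence[organ] = proportion
    with open(outdir / "divergence_summary.json", "w") as fh:
        json.dump(divergence, fh, indent=2, sort_keys=True)

    # windowed distances between the two species, per organ, complex fits
    rows = []
    species = sim.dataset.species_levels
    for gene, fits in (sel.fits or {}).items():
        if sel.table.at[gene, "model_class"] != "complex":
            continue
        for organ in organs:
            d = prof.windowed_distance(fits["complex"], (species[0], organ),
                                       (species[1], organ))
            rows.append({"gene": gene, "organ": organ,
                         **{f"w{i+1}": v for i, v in enumerate(d)}})
    if rows:
        dist = pd.DataFrame(rows).set_index("gene")
        dio.write_table(dist, outdir / "window_distances.tsv")
        mean = dist.groupby("organ").mean(numeric_only=True)
        dio.write_table(mean, outdir / "window_distances_mean.tsv")
    return {"coevolution_index": index, "divergence": divergence}


def _stage_deconvolution(cfg: PipelineConfig, outdir: Path) -> None:
    scfg = cfg.synthetic
    signature = synth.simulate_signature(scfg.n_markers, seed=cfg.seed)
    results = []
    for i, p in enumerate([tuple(scfg.mixture_proportions), (0.5, 0.5), (0.9, 0.1)]):
        bulk, truth = synth.simulate_mixture(signature, p, scfg.mixture_noise_cv,
                                             cfg.seed + i)
        bulk.name = f"mix{i+1}"
        res = deconv.bootstrap_deconvolve(bulk, signature, n_bootstrap=1000,
                                          seed=cfg.seed + i)
        row = res.proportions.iloc[0].to_dict()
        for t in signature.tissues:
            row[f"{t}_low"] = res.ci_low.at[bulk.name, t]
            row[f"{t}_high"] = res.ci_high.at[bulk.name, t]
            row[f"{t}_true"] = truth[signature.tissues.index(t)]
        results.append(pd.Series(row, name=bulk.name))
    dio.write_table(pd.DataFrame(results), outdir / "deconvolution.tsv",
                    index_label="sample")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages on the synthetic preset; returns the output directory.

    Any stage failure aborts with a stage-tagged error; partial outputs are
    marked by the absence of manifest.json (written last, after all stages).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.inputs.checksums:
        dio.verify_checksums(cfg.inputs.checksums)
    for name, fn in [("chronology", _stage_chronology), ("staging", _stage_staging),
                     ("profiles", _stage_profiles), ("deconvolution", _stage_deconvolution)]:
        logger.info("[%s] running", name)
        try:
            fn(cfg, outdir)
        except Exception as exc:  # noqa: BLE001 - stage-tagged abort
            raise StageFailure(name, exc) from exc
    inputs = dict(cfg.inputs.checksums)
    dio.write_manifest(outdir, seed=cfg.seed, config=cfg.model_dump(mode="json"),
                       inputs=inputs)
    return outdir
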