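"""Seeded benchmark experiments exercising every pipeline stage end to end.

Each function generates data with the synthetic module at the preset study
conditions, runs the corresponding analysis, and returns summary numbers
(recovery errors, error rates, indices). They are used by the test suite
and by the reproduction script; all randomness is controlled by the `seed`
argument.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import erlang, kstest

from . import chronology as chron
from .deconvolution import bootstrap_deconvolve, deconvolve
from .profiles import coevolution_index, compare_divergence_proportions, select_profile_model
from .staging import StagePlan, compare_rate_models, fit_stage_model, stage_occupancy
from .synthetic import (ChronologySimConfig, ProfilesSimConfig, rodent_preset,
                        simulate_mixture, simulate_profiles, simulate_signature,
                        simulate_staging_cohort, simulate_weight_age)


def staging_erlang_agreement() -> float:
    """Max |occupancy - closed-form Erlang survival| over a time grid."""
    plan = StagePlan(("a", "b"), (3, 1), (0,))
    ts = np.arange(0.1, 2.01, 0.1)
    occ = stage_occupancy(plan, np.array([4.0]), ts)
    return float(np.abs(occ[:, 0] - erlang.sf(ts, 3, scale=0.25)).max())


def staging_duration_recovery(seed: int, n: int = 400) -> dict:
    """9-stage cusp-patterning cohort: recover relative stage durations."""
    cfg = rodent_preset(seed).staging
    cohort = simulate_staging_cohort(cfg.plan, cfg.rates, n, cfg.window, seed)
    fit = fit_stage_model(cfg.plan, (cohort.t, cohort.stage), seed=seed)
    err = np.abs(fit.relative_durations - cohort.true_relative_durations)
    return {"max_abs_error": float(err.max()), "n": n,
            "estimated": fit.relative_durations,
            "truth": cohort.true_relative_durations}


_PLAN_1RATE = StagePlan(("s1", "s2", "s3", "s4"), (5, 5, 5, 1), (0, 0, 0), name="1rate")
_PLAN_2RATE = StagePlan(("s1", "s2", "s3", "s4"), (5, 5, 5, 1), (0, 1, 0), name="2rate")


def staging_lrt_type1(seed: int, n_reps: int = 200, n: int = 300) -> dict:
    """Fraction of equal-rate cohorts where the 2-rate model is selected."""
    hits = 0
    for rep in range(n_reps):
        cohort = simulate_staging_cohort(_PLAN_1RATE, [2.0], n, (0, 10),
                                         seed=(seed * 100_003 + rep) % 2**31)
        comp = compare_rate_models((cohort.t, cohort.stage), [_PLAN_1RATE, _PLAN_2RATE],
                                   n_restarts=3, seed=rep)
        hits += comp.selected == "2rate"
    return {"rate": hits / n_reps, "n": n_reps}


def staging_lrt_power(seed: int, n_reps: int = 200, n: int = 300) -> dict:
    """Power to detect a 5x slower middle stage with the 2-rate model."""
    hits = 0
    for rep in range(n_reps):
        cohort = simulate_staging_cohort(_PLAN_2RATE, [5.0, 1.0], n, (0, 10),
                                         seed=(seed * 100_019 + rep) % 2**31)
        comp = compare_rate_models((cohort.t, cohort.stage), [_PLAN_1RATE, _PLAN_2RATE],
                                   n_restarts=3, seed=rep)
        hits += comp.selected == "2rate"
    return {"rate": hits / n_reps, "n": n_reps}


def profile_classification_benchmark(seed: int, n_per_class: int = 500) -> dict:
    """Confusion summary of the four-class selection on the preset design."""
    cfg = ProfilesSimConfig(n_per_class={c: n_per_class for c in
                                         ("simple", "species", "tooth", "complex")})
    sim = simulate_profiles(cfg, seed)
    sel = select_profile_model(sim.dataset)
    tab = sel.table.join(sim.truth)
    out = {"n_genes": int(len(tab))}
    for cls in ("species", "tooth", "complex"):
        sub = tab[tab.true_class == cls]
        out[f"accuracy_{cls}"] = float((sub.model_class == cls).mean())
    simple = tab[tab.true_class == "simple"]
    out["simple_false_informative"] = float((simple.model_class != "simple").mean())
    return out


def profile_null_calibration(seed: int, n_genes: int = 500) -> dict:
    """All-null cohort: KS uniformity of the raw LRT p-values, BH FDR."""
    cfg = ProfilesSimConfig(n_per_class={"simple": n_genes, "species": 0,
                                         "tooth": 0, "complex": 0})
    sim = simulate_profiles(cfg, seed)
    sel = select_profile_model(sim.dataset)
    tab = sel.table.query("tested")
    out = {"n_genes": int(len(tab)),
           "false_informative": float(tab.informative.mean())}
    for fam in ("t1", "t2", "t3", "t4"):
        out[f"ks_p_{fam}"] = float(kstest(tab[f"p_{fam}"].to_numpy(float), "uniform").pvalue)
    return out


def coevolution_recovery(seed: int) -> dict:
    """Cohort with 60% species-class genes among informative, strong effects.

    Effects are set high (log-amplitude 2) so classification error is
    negligible and the check exercises the index computation itself.
    """
    cfg = ProfilesSimConfig(n_per_class={"simple": 100, "species": 300,
                                         "tooth": 100, "complex": 100},
                            effect_size=2.0)
    sim = simulate_profiles(cfg, seed)
    sel = select_profile_model(sim.dataset)
    index = coevolution_index(sel)
    n_inf = 500
    half = 1.96 * np.sqrt(0.6 * 0.4 / n_inf)
    return {"index": float(index), "target": 0.6,
            "low": 0.6 - half, "high": 0.6 + half, "n": n_inf}


def deconvolution_noiseless_grid(seed: int, n_markers: int = 100) -> dict:
    """Exact mixture recovery over a proportion grid."""
    sig = simulate_signature(n_markers, seed=seed)
    errs = []
    for p1 in np.linspace(0, 1, 11):
        bulk, _ = simulate_mixture(sig, (p1, 1 - p1), 0.0, seed)
        errs.append(abs(deconvolve(bulk, sig)[0] - p1))
    return {"max_error": float(max(errs)), "n": 11}


def deconvolution_noisy_mae(seed: int, n_reps: int = 200, n_markers: int = 100) -> dict:
    """Mean |p1_hat - 0.7| under 20% CV multiplicative noise."""
    sig = simulate_signature(n_markers, seed=seed)
    errs = []
    for rep in range(n_reps):
        bulk, _ = simulate_mixture(sig, (0.7, 0.3), 0.2, (seed * 100_043 + rep) % 2**31)
        errs.append(abs(deconvolve(bulk, sig)[0] - 0.7))
    return {"mae": float(np.mean(errs)), "n": n_reps}


def deconvolution_bootstrap_coverage(seed: int, n_outer: int = 100,
                                     n_bootstrap: int = 1000) -> dict:
    """Fraction of outer replicates whose 95% marker-bootstrap CI covers truth."""
    sig = simulate_signature(100, seed=seed)
    covered = 0
    for rep in range(n_outer):
        bulk, truth = simulate_mixture(sig, (0.7, 0.3), 0.2, (seed * 100_057 + rep) % 2**31)
        bulk.name = "mix"
        res = bootstrap_deconvolve(bulk, sig, n_bootstrap=n_bootstrap, seed=rep)
        t0 = sig.tissues[0]
        covered += (res.ci_low.at["mix", t0] <= truth[0] <= res.ci_high.at["mix", t0])
    return {"coverage": covered / n_outer, "n": n_outer}


def chronology_recovery(seed: int, n: int = 500) -> dict:
    """Monotone weight -> age fit on the noisy power-law simulation."""
    cfg = ChronologySimConfig(n=n)
    pairs, true_age = simulate_weight_age(cfg.curve, cfg.sigma, cfg.n, seed)
    model = chron.fit_weight_age(pairs, "synthetic")
    pred = model.predict(np.array([p.weight for p in pairs]))
    err = np.abs(pred - true_age)
    return {"median_abs_error_days": float(np.median(err)),
            "rmse_days": float(np.sqrt(np.mean(err ** 2))), "n": n}


def milestone_mapping() -> dict:
    """Relative-time anchors for the mouse and hamster milestone pairs."""
    mouse = chron.Milestones("mouse", 14.6, 18.0)
    hamster = chron.Milestones("hamster", 12.3, 14.6)
    return {
        "mouse_age_14.6": chron.to_relative_time(14.6, mouse),
        "mouse_age_18.0": chron.to_relative_time(18.0, mouse),
        "hamster_age_12.3": chron.to_relative_time(12.3, hamster),
        "hamster_age_14.6": chron.to_relative_time(14.6, hamster),
    }


def divergence_proportion_consistency(n: int = 14532) -> float:
    """Two-sided two-proportion test on 21.4% vs 17.5% divergent genes."""
    return compare_divergence_proportions(0.214, n, 0.175, n)
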