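"""Seeded synthetic data with the statistical structure of each pipeline stage.

Every generator is a pure function of (config, seed) and returns the ground
truth alongside the data, so recovery is scorable without external inputs.
A single pipeline seed fans out into independent named streams (one per
generator), so e.g. adding genes to the profile simulation does not shift
the staging draws.

The default rodent preset mirrors the study design this package addresses:
8 timepoints x 2 organs x 2 species with one replicate each (32 samples),
a 9-stage cusp-patterning sequence sampled uniformly over the relative
timeline, two-compartment bulk mixtures, and a power-law weight -> age
calibration curve. A bat-like preset provides the sparse 3-timepoint limb
design.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._splines import SplineConfig, build_basis
from .chronology import WeightAgePair
from .deconvolution import SignatureMatrix
from .profiles import ExpressionDataset
from .staging import StagePlan, stage_occupancy


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent, platform-stable RNG stream derived from (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


# ---------------------------------------------------------------------------
# configs and presets


@dataclass(frozen=True)
class StagingSimConfig:
    plan: StagePlan
    rates: tuple[float, ...]
    n_embryos: int = 400
    window: tuple[float, float] = (0.0, 10.0)


@dataclass(frozen=True)
class ProfilesSimConfig:
    """Design and effect sizes of the expression time-course simulation.

    Curves are spline-coefficient vectors on the analysis basis; class
    structure is imposed by sharing or perturbing coefficient vectors
    (perturbations ~ N(0, effect_size^2) per coefficient, natural-log
    scale). Counts are NB with the given dispersion after scaling by
    log-uniform library sizes.
    """

    n_per_class: dict = field(default_factory=lambda: {
        "simple": 500, "species": 500, "tooth": 500, "complex": 500})
    times: tuple[float, ...] = tuple(np.linspace(0.0, 10.0, 8))
    species: tuple[str, str] = ("hamster", "mouse")
    organs: tuple[str, str] = ("lower", "upper")
    n_replicates: int = 1
    effect_size: float = 1.0
    curve_sd: float = 0.7
    base_log_mean: float = float(np.log(200.0))
    base_log_sd: float = 1.0
    offset_sd: float = 0.5
    dispersion: float = 0.05
    libsize_range: tuple[float, float] = (0.5, 2.0)
    spline: SplineConfig = SplineConfig()


@dataclass(frozen=True)
class MixtureSimConfig:
    n_markers: int = 100
    proportions: tuple[float, ...] = (0.7, 0.3)
    noise_cv: float = 0.2


@dataclass(frozen=True)
class ChronologySimConfig:
    """age = a + b * weight^power + N(0, sigma^2); weights log-uniform."""

    a: float = 11.4
    b: float = 0.39
    power: float = 0.4
    sigma: float = 0.1
    n: int = 500
    weight_range: tuple[float, float] = (150.0, 1300.0)

    def curve(self, w):
        return self.a + self.b * np.asarray(w, float) ** self.power


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    staging: StagingSimConfig = None
    profiles: ProfilesSimConfig = field(default_factory=ProfilesSimConfig)
    mixtures: MixtureSimConfig = field(default_factory=MixtureSimConfig)
    chronology: ChronologySimConfig = field(default_factory=ChronologySimConfig)


def molar_stage_plan(n_stages: int = 9, substates: int = 5, *,
                     rate_classes: tuple[int, ...] | None = None,
                     start_time: float = 0.0, name: str = "molar") -> StagePlan:
    """Cusp-patterning stage sequence: PEK, 1-SEK, ..., crest."""
    labels = ["PEK"] + [f"{i}-SEK" for i in range(1, n_stages - 1)] + ["crest"]
    m = tuple([substates] * (n_stages - 1) + [1])
    rc = tuple(range(n_stages - 1)) if rate_classes is None else tuple(rate_classes)
    return StagePlan(tuple(labels), m, rc, start_time=start_time, name=name)


#: stage durations (relative-time units) of the default 9-stage preset
MOLAR_DURATIONS = (1.6, 0.7, 0.5, 0.9, 1.2, 0.8, 1.1, 1.4)


def rodent_preset(seed: int = 0) -> SimulationConfig:
    plan = molar_stage_plan()
    rates = tuple(plan.substates_per_stage[k] / d for k, d in enumerate(MOLAR_DURATIONS))
    return SimulationConfig(seed=seed,
                            staging=StagingSimConfig(plan=plan, rates=rates))


def bat_preset(seed: int = 0) -> SimulationConfig:
    """Sparse limb design: 3 timepoints, 2 organs (fore/hind), replicates."""
    cfg = rodent_preset(seed)
    profiles = replace(cfg.profiles,
                       times=(0.0, 5.0, 10.0),
                       species=("bat", "mouse"),
                       organs=("forelimb", "hindlimb"),
                       n_replicates=3)
    return replace(cfg, profiles=profiles)


# ---------------------------------------------------------------------------
# generators


@dataclass
class StagingCohort:
    t: np.ndarray
    stage: np.ndarray
    true_relative_durations: np.ndarray
    plan: StagePlan
    rates: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "relative_time": self.t,
            "stage_label": [self.plan.stage_labels[s] for s in self.stage],
        })


def simulate_staging_cohort(plan: StagePlan, rates, n: int,
                            window: tuple[float, float], seed: int) -> StagingCohort:
    """Uniform sampling times in `window`, exact categorical stage draws."""
    lo, hi = window
    if not hi > lo:
        raise ValueError("empty sampling window")
    if lo < plan.start_time:
        raise ValueError("window starts before the process origin")
    rng = stream(seed, "staging")
    rates = np.asarray(rates, dtype=float)
    t = np.sort(rng.uniform(lo, hi, size=n))
    occ = stage_occupancy(plan, rates, t)
    u = rng.random(n)
    stage = (u[:, None] > np.cumsum(occ, axis=1)).sum(axis=1)
    m = np.asarray(plan.substates_per_stage[:-1], float)
    dur = m / rates[list(plan.rate_class)]
    return StagingCohort(t=t, stage=stage, true_relative_durations=dur / dur.sum(),
                         plan=plan, rates=rates)


@dataclass
class ProfilesSim:
    dataset: ExpressionDataset
    truth: pd.DataFrame                       # per gene: true_class
    means: pd.DataFrame                       # pre-noise NB means (incl. library size)
    curves: dict                              # gene -> {(species, organ): coef vector}
    offsets: dict                             # gene -> {species: baseline offset}
    library_sizes: pd.Series


def simulate_profiles(config: ProfilesSimConfig, seed: int) -> ProfilesSim:
    """NB count time courses for 2 species x 2 organs under the four classes.

    Per gene a base coefficient vector is drawn; the true class dictates
    which groups share it and which get an independent N(0, effect_size^2)
    coefficient perturbation. Species baseline offsets are always drawn, so
    `simple` genes still differ in level (not in dynamics) across species.
    """
    rng = stream(seed, "profiles")
    if config.dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    times = np.asarray(config.times, float)
    spA, spB = config.species
    orgs = config.organs

    sample_rows = []
    for s in config.species:
        for o in orgs:
            for ti in times:
                for r in range(config.n_replicates):
                    sample_rows.append({
                        "sample": f"{s}_{o}_t{ti:g}_r{r+1}",
                        "species": s, "organ": o, "relative_time": ti})
    samples = pd.DataFrame(sample_rows).set_index("sample")
    # knots from the full sample time vector, matching the analysis basis
    basis = build_basis(config.spline, np.asarray(samples["relative_time"], float))
    nb = basis.n_basis
    B = basis.evaluate(np.asarray(samples["relative_time"], float))
    libs = np.exp(rng.uniform(np.log(config.libsize_range[0]),
                              np.log(config.libsize_range[1]), size=len(samples)))
    library_sizes = pd.Series(libs, index=samples.index, name="library_size")

    groups = [(s, o) for s in config.species for o in orgs]
    counts_rows, mean_rows, truth_rows = [], [], []
    curves, offsets = {}, {}
    gi = 0
    for cls in ("simple", "species", "tooth", "complex"):
        for _ in range(int(config.n_per_class.get(cls, 0))):
            gene = f"g{gi:05d}_{cls}"
            gi += 1
            base = rng.normal(0.0, config.curve_sd, nb) \
                + rng.normal(config.base_log_mean, config.base_log_sd)
            off = {spA: 0.0, spB: float(rng.normal(0.0, config.offset_sd))}

            def perturb():
                return base + rng.normal(0.0, config.effect_size, nb)

            if cls == "simple":
                gcurves = {g: base for g in groups}
            elif cls == "species":
                alt = perturb()
                gcurves = {g: (base if g[0] == spA else alt) for g in groups}
            elif cls == "tooth":
                alt = perturb()
                gcurves = {g: (base if g[1] == orgs[0] else alt) for g in groups}
            else:
                gcurves = {groups[0]: base}
                for g in groups[1:]:
                    gcurves[g] = perturb()

            eta = np.empty(len(samples))
            for gidx, g in enumerate(groups):
                mask = (samples["species"] == g[0]) & (samples["organ"] == g[1])
                eta[mask.to_numpy()] = B[mask.to_numpy()] @ gcurves[g] + off[g[0]]
            mu = np.exp(eta) * libs
            if config.dispersion < 1e-12:
                y = rng.poisson(mu)
            else:
                r = 1.0 / config.dispersion
                y = rng.negative_binomial(r, r / (r + mu))
            counts_rows.append(y)
            mean_rows.append(mu)
            truth_rows.append({"gene": gene, "true_class": cls})
            curves[gene] = gcurves
            offsets[gene] = off

    genes = [r["gene"] for r in truth_rows]
    counts = pd.DataFrame(np.asarray(counts_rows, dtype=np.int64),
                          index=genes, columns=samples.index)
    means = pd.DataFrame(np.asarray(mean_rows), index=genes, columns=samples.index)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    dataset = ExpressionDataset(counts=counts, samples=samples)
    return ProfilesSim(dataset=dataset, truth=truth, means=means, curves=curves,
                       offsets=offsets, library_sizes=library_sizes)


def simulate_signature(n_markers: int = 100,
                       tissues: tuple[str, str] = ("epithelium", "mesenchyme"),
                       seed: int = 0,
                       lfc_range: tuple[float, float] = (3.0, 8.0)) -> SignatureMatrix:
    """Synthetic two-tissue signature: half the markers defined per tissue."""
    rng = stream(seed, "signature")
    half = n_markers // 2
    n_markers = 2 * half
    high = np.exp(rng.normal(np.log(100.0), 1.0, n_markers))
    lfc = rng.uniform(*lfc_range, n_markers)
    low = high / 2.0 ** lfc
    t0 = np.r_[high[:half], low[half:]]
    t1 = np.r_[low[:half], high[half:]]
    genes = [f"m{i:04d}" for i in range(n_markers)]
    values = pd.DataFrame({tissues[0]: t0, tissues[1]: t1}, index=genes)
    tissue_of = pd.Series([tissues[0]] * half + [tissues[1]] * half, index=genes)
    return SignatureMatrix(values=values, marker_tissue=tissue_of)


def simulate_mixture(signature: SignatureMatrix, proportions, noise_cv: float,
                     seed: int) -> tuple[pd.Series, np.ndarray]:
    """Bulk vector b = S p with multiplicative gamma noise of the given CV."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must lie on the simplex")
    S = signature.values.to_numpy(dtype=float)
    b = S @ p
    if noise_cv > 0:
        rng = stream(seed, "mixture")
        shape = 1.0 / noise_cv ** 2
        b = b * rng.gamma(shape, 1.0 / shape, size=b.shape)
    return pd.Series(b, index=signature.values.index, name="bulk"), p


def simulate_weight_age(curve, sigma: float, n: int, seed: int,
                        weight_range: tuple[float, float] = (150.0, 1300.0),
                        ) -> tuple[list[WeightAgePair], np.ndarray]:
    """Log-uniform weights; ages = curve(weight) + Gaussian noise.

    Returns the pairs and the true (noise-free) ages. The curve must be
    monotone non-decreasing over the weight range.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    lo, hi = weight_range
    grid = np.geomspace(lo, hi, 512)
    vals = np.asarray(curve(grid), float)
    if np.any(np.diff(vals) < -1e-12):
        raise ValueError("weight -> age curve must be monotone non-decreasing")
    rng = stream(seed, "chronology")
    w = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    true_age = np.asarray(curve(w), float)
    age = true_age + rng.normal(0.0, sigma, size=n)
    age = np.maximum(age, 1e-6)
    pairs = [WeightAgePair(weight=float(wi), age=float(ai)) for wi, ai in zip(w, age)]
    return pairs, true_age
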