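"""Nested negative-binomial spline models of temporal expression profiles.

Orthologue-paired count time courses from 2 species x 2 serial organs
(e.g. hamster/mouse upper and lower molars, or bat/mouse fore- and
hindlimbs) are modelled per gene on the shared relative timeline with
B-spline mean curves, a log link, log size-factor offsets and a fixed
per-gene NB dispersion.

Four nested mean models are compared:

  simple   one curve for all four series (plus species baseline offset)
  species  one curve per species                 ("hamster/mouse")
  tooth    one curve per organ + species offset  ("upper/lower")
  complex  one curve per species x organ

Four likelihood-ratio tests drive a bottom-up decision tree: t1 (species
vs simple), t2 (tooth vs simple), t3 (complex vs tooth), t4 (complex vs
species); p-values are BH-adjusted per test family across genes. A gene is
*informative* when its selected model is not `simple`. The coevolution
index is the fraction of `species` models among informative genes: profiles
that changed between species in the same way in both organs.

Per-organ divergence contrasts a `divergent` model (one curve per species,
species offsets) with a `nondivergent` one (single curve + species offset).
Windowed profile distances summarize where along the timeline two fitted
curves differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from ._nbglm import (FitError, common_dispersion, dispersion_curvature,
                     estimate_dispersion, fit_nb_glm, moderate_dispersions)
from ._splines import SplineBasis, SplineConfig, build_basis

logger = logging.getLogger(__name__)

MODEL_CLASSES = ("simple", "species", "tooth", "complex")
SINGLE_ORGAN_CLASSES = ("nondivergent", "divergent")


class DesignError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class ExpressionDataset:
    """Orthologue-paired counts with sample metadata on the relative timeline.

    counts : genes x samples table of non-negative integers, rows aligned
        1:1 across species (each row is one orthologue pair).
    samples : indexed by sample name, with columns `species`, `organ`,
        `relative_time`, and optionally `size_factor` (geometric mean 1).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and samples index must match and be ordered alike")
        for col in ("species", "organ", "relative_time"):
            if col not in self.samples.columns:
                raise ValueError(f"samples metadata missing column '{col}'")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        for (sp, org), sub in self.samples.groupby(["species", "organ"], observed=True):
            if sub["relative_time"].nunique() < 3:
                raise ValueError(f"need >= 3 distinct relative times for {sp}/{org}")
        if "size_factor" in self.samples.columns:
            sf = np.asarray(self.samples["size_factor"], float)
            if np.any(sf <= 0):
                raise ValueError("size factors must be positive")
            if abs(np.exp(np.mean(np.log(sf))) - 1.0) > 1e-8:
                raise ValueError("size factors must have geometric mean 1")

    @property
    def species_levels(self) -> list[str]:
        return sorted(self.samples["species"].unique())

    @property
    def organ_levels(self) -> list[str]:
        return sorted(self.samples["organ"].unique())

    def with_size_factors(self) -> "ExpressionDataset":
        if "size_factor" in self.samples.columns:
            return self
        samples = self.samples.copy()
        samples["size_factor"] = size_factors(self.counts).values
        return ExpressionDataset(self.counts, samples)

    def restrict_organ(self, organ: str) -> "ExpressionDataset":
        keep = self.samples["organ"] == organ
        if not keep.any():
            raise ValueError(f"no samples for organ '{organ}'")
        return ExpressionDataset(self.counts.loc[:, keep.values], self.samples.loc[keep])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per gene, the reference is its geometric mean across samples (genes
    with a zero anywhere are excluded from the reference set); each
    sample's factor is the median ratio of its counts to the reference.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.shape[1] < 2:
        raise NormalizationError("need >= 2 samples")
    pos = np.all(mat > 0, axis=1)
    if not pos.any():
        raise NormalizationError("no gene has positive counts in every sample")
    sub = mat[pos]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    sf = np.median(sub / geo[:, None], axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# designs


@dataclass
class ModelDesign:
    """A design matrix shared by all genes for one model class."""

    model_class: str
    X: np.ndarray = field(repr=False)
    roles: pd.DataFrame = field(repr=False)   # per column: role, species, organ, basis_index
    basis: SplineBasis = field(repr=False)
    species_levels: list[str] = field(default_factory=list)
    organ_levels: list[str] = field(default_factory=list)

    @property
    def df(self) -> int:
        return self.X.shape[1]


def build_design(samples: pd.DataFrame, model_class: str, basis: SplineBasis) -> ModelDesign:
    """Design matrix for one model class.

    Curve blocks are the spline basis restricted to the samples of a group;
    species baselines are single additive indicator columns (one per
    non-reference species). The column spaces nest: simple within every
    other class, species and tooth within complex.
    """
    species_levels = sorted(samples["species"].unique())
    organ_levels = sorted(samples["organ"].unique())
    t = np.asarray(samples["relative_time"], float)
    B = basis.evaluate(t)
    nb = basis.n_basis
    sp = samples["species"].to_numpy()
    org = samples["organ"].to_numpy()

    def curve_block(mask, species=None, organ=None):
        block = B * mask[:, None].astype(float)
        roles = pd.DataFrame({
            "role": "curve", "species": species, "organ": organ,
            "basis_index": np.arange(nb),
        })
        return block, roles

    def offset_cols():
        cols, roles = [], []
        for s in species_levels[1:]:
            cols.append((sp == s).astype(float)[:, None])
            roles.append({"role": "offset", "species": s, "organ": None, "basis_index": -1})
        return cols, roles

    blocks, roles = [], []
    if model_class in ("simple", "nondivergent"):
        b, r = curve_block(np.ones(len(samples), bool))
        blocks, roles = [b], [r]
        oc, orl = offset_cols()
        blocks += oc
        roles += [pd.DataFrame(orl)] if orl else []
    elif model_class in ("species", "divergent"):
        if len(species_levels) < 2:
            raise DesignError(f"'{model_class}' needs >= 2 species")
        for s in species_levels:
            b, r = curve_block(sp == s, species=s)
            blocks.append(b)
            roles.append(r)
    elif model_class == "tooth":
        if len(organ_levels) < 2:
            raise DesignError("'tooth' needs >= 2 organs")
        for o in organ_levels:
            b, r = curve_block(org == o, organ=o)
            blocks.append(b)
            roles.append(r)
        oc, orl = offset_cols()
        blocks += oc
        roles += [pd.DataFrame(orl)] if orl else []
    elif model_class == "complex":
        if len(species_levels) < 2 or len(organ_levels) < 2:
            raise DesignError("'complex' needs 2 species x 2 organs")
        for s in species_levels:
            for o in organ_levels:
                mask = (sp == s) & (org == o)
                if not mask.any():
                    raise DesignError(f"no samples for group {s}/{o}")
                b, r = curve_block(mask, species=s, organ=o)
                blocks.append(b)
                roles.append(r)
    else:
        raise DesignError(f"unknown model class '{model_class}'")

    X = np.hstack(blocks)
    role_df = pd.concat(roles, ignore_index=True)
    return ModelDesign(model_class=model_class, X=X, roles=role_df, basis=basis,
                       species_levels=species_levels, organ_levels=organ_levels)


# ---------------------------------------------------------------------------
# per-gene fits


@dataclass
class GeneFit:
    gene: str
    design: ModelDesign
    coefficients: np.ndarray
    dispersion: float
    log_likelihood: float
    df: int

    @property
    def model_class(self) -> str:
        return self.design.model_class


def fit_gene(gene: str, y: np.ndarray, design: ModelDesign, size_factors: np.ndarray,
             alpha_g: float) -> GeneFit:
    res = fit_nb_glm(y, design.X, size_factors, alpha_g, check_rank=False)
    return GeneFit(gene=gene, design=design, coefficients=res.coef, dispersion=alpha_g,
                   log_likelihood=res.loglik, df=res.df)


def _nested(reduced: ModelDesign, full: ModelDesign, tol: float = 1e-8) -> bool:
    q, _ = np.linalg.qr(full.X)
    resid = reduced.X - q @ (q.T @ reduced.X)
    scale = max(np.abs(reduced.X).max(), 1.0)
    return bool(np.abs(resid).max() <= tol * scale)


def lrt(fit_full: GeneFit, fit_reduced: GeneFit) -> float:
    """Chi-square LRT p-value of the full against the nested reduced fit."""
    if fit_full.df <= fit_reduced.df:
        raise ValueError("full model must have more free parameters than reduced")
    if abs(fit_full.dispersion - fit_reduced.dispersion) > 1e-12:
        raise ValueError("LRT requires the same fixed dispersion in both fits")
    if not _nested(fit_reduced.design, fit_full.design):
        raise ValueError("reduced design is not nested in the full design")
    stat = max(0.0, 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood))
    df = fit_full.df - fit_reduced.df
    return float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionResult:
    """Per-gene test results and assigned profile-model classes.

    table columns: p_t1..p_t4 (raw), padj_t1..padj_t4 (BH per family),
    model_class, informative, dispersion, loglik_<class>, tested, reason.
    """

    table: pd.DataFrame
    alpha: float
    fits: dict[str, dict[str, GeneFit]] | None = None

    @property
    def class_counts(self) -> pd.Series:
        return self.table.loc[self.table["tested"], "model_class"].value_counts()


def _gene_dispersions(counts: pd.DataFrame, X: np.ndarray, sf: np.ndarray, *,
                      min_total_count: int, moderate: bool) -> dict[str, float]:
    """Per-gene CR dispersions under the fullest design, optionally moderated."""
    genes, alphas, infos, ys = [], [], [], []
    for gene in counts.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        if y.sum() < min_total_count:
            continue
        try:
            a = estimate_dispersion(y, X, sf)
            info = dispersion_curvature(y, X, sf, a) if moderate else 1.0
        except FitError:
            continue
        genes.append(gene)
        alphas.append(a)
        infos.append(info)
        ys.append(y)
    if not genes:
        return {}
    if moderate and len(genes) >= 10:
        center = common_dispersion(ys, X, sf)
        alphas = moderate_dispersions(np.asarray(alphas), np.asarray(infos), center)
    return dict(zip(genes, np.asarray(alphas, float)))


def _decide(sig: dict[str, bool], ll_species: float, ll_tooth: float) -> str:
    if not sig["t1"] and not sig["t2"]:
        return "simple"
    if sig["t1"] and not sig["t2"]:
        return "complex" if sig["t4"] else "species"
    if sig["t2"] and not sig["t1"]:
        return "complex" if sig["t3"] else "tooth"
    if sig["t3"] or sig["t4"]:
        return "complex"
    return "species" if ll_species >= ll_tooth else "tooth"


def select_profile_model(
    dataset: ExpressionDataset,
    spline: SplineConfig = SplineConfig(),
    alpha: float = 0.05,
    *,
    min_total_count: int = 10,
    keep_fits: bool = False,
    moderate: bool = True,
) -> SelectionResult:
    """Fit the four nested models per gene and classify by the decision tree.

    Dispersion is estimated once per gene under the complex design (Cox-Reid
    adjusted profile likelihood), moderated across genes by empirical-Bayes
    shrinkage of the log-dispersions (`moderate=True`; the per-gene estimate
    on few residual df is noisy enough to visibly inflate the LRTs), and
    held fixed across the nested fits. The four LRT p-value families (t1:
    species vs simple, t2: tooth vs simple, t3: complex vs tooth, t4:
    complex vs species) are BH-adjusted across genes separately;
    significance is strict (adjusted p < alpha). Genes with total count
    below `min_total_count` or failing fits are marked untested.
    """
    dataset = dataset.with_size_factors()
    samples = dataset.samples
    if len(samples["species"].unique()) < 2 or len(samples["organ"].unique()) < 2:
        raise DesignError("profile selection needs 2 species and 2 organs")
    basis = build_basis(spline, np.asarray(samples["relative_time"], float))
    designs = {c: build_design(samples, c, basis) for c in MODEL_CLASSES}
    sf = np.asarray(samples["size_factor"], float)
    counts = dataset.counts

    dispersions = _gene_dispersions(counts, designs["complex"].X, sf,
                                    min_total_count=min_total_count, moderate=moderate)

    rows = []
    fits_store: dict[str, dict[str, GeneFit]] = {}
    for gene in counts.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        row = {"gene": gene, "tested": False, "reason": "",
               "model_class": None, "informative": False, "dispersion": np.nan}
        if y.sum() < min_total_count:
            row["reason"] = f"total count {int(y.sum())} < {min_total_count}"
            rows.append(row)
            continue
        alpha_g = dispersions.get(gene, np.nan)
        if not np.isfinite(alpha_g):
            row["reason"] = "fit error: dispersion not estimable"
            rows.append(row)
            continue
        try:
            fits = {c: fit_gene(gene, y, designs[c], sf, alpha_g) for c in MODEL_CLASSES}
        except FitError as exc:
            row["reason"] = f"fit error: {exc}"
            rows.append(row)
            continue
        row.update(
            tested=True, dispersion=alpha_g,
            p_t1=lrt(fits["species"], fits["simple"]),
            p_t2=lrt(fits["tooth"], fits["simple"]),
            p_t3=lrt(fits["complex"], fits["tooth"]),
            p_t4=lrt(fits["complex"], fits["species"]),
            **{f"loglik_{c}": fits[c].log_likelihood for c in MODEL_CLASSES},
        )
        if keep_fits:
            fits_store[gene] = fits
        rows.append(row)

    table = pd.DataFrame(rows).set_index("gene")
    tested = table["tested"].to_numpy(bool)
    n_untested = int((~tested).sum())
    if n_untested:
        logger.info("select_profile_model: %d genes untested", n_untested)
    for t in ("t1", "t2", "t3", "t4"):
        table[f"padj_{t}"] = np.nan
        if tested.any():
            table.loc[tested, f"padj_{t}"] = multipletests(
                table.loc[tested, f"p_{t}"].to_numpy(float), method="fdr_bh")[1]

    for gene in table.index[tested]:
        sig = {t: bool(table.at[gene, f"padj_{t}"] < alpha) for t in ("t1", "t2", "t3", "t4")}
        cls = _decide(sig, table.at[gene, "loglik_species"], table.at[gene, "loglik_tooth"])
        table.at[gene, "model_class"] = cls
        table.at[gene, "informative"] = cls != "simple"
    return SelectionResult(table=table, alpha=alpha, fits=fits_store if keep_fits else None)


def coevolution_index(selection: SelectionResult, genes: list[str] | None = None) -> float:
    """Fraction of `species` models among informative genes.

    count(species) / (count(species) + count(tooth) + count(complex)); a
    gene subset (e.g. a pathway list) restricts the computation.
    """
    table = selection.table
    if genes is not None:
        table = table.loc[table.index.intersection(genes)]
    cls = table.loc[table["tested"], "model_class"]
    informative = cls.isin(("species", "tooth", "complex"))
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError("coevolution index undefined: no informative genes")
    return float((cls == "species").sum() / n_inf)


def divergence_per_organ(
    dataset: ExpressionDataset,
    organ: str | None = None,
    spline: SplineConfig = SplineConfig(),
    alpha: float = 0.05,
    *,
    min_total_count: int = 10,
    moderate: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Per-gene divergent-vs-nondivergent LRT within one organ.

    Both models carry species baseline offsets so only the temporal dynamic
    is tested. Dispersions are estimated under the divergent design and
    moderated across genes as in `select_profile_model`. Returns the
    per-gene table (raw and BH-adjusted p, divergent flag) and the
    proportion of divergent genes among tested genes.
    """
    if organ is not None:
        dataset = dataset.restrict_organ(organ)
    dataset = dataset.with_size_factors()
    samples = dataset.samples
    if len(samples["organ"].unique()) != 1:
        raise DesignError("divergence test expects samples from a single organ")
    if len(samples["species"].unique()) < 2:
        raise DesignError("divergence test needs both species")
    basis = build_basis(spline, np.asarray(samples["relative_time"], float))
    d_div = build_design(samples, "divergent", basis)
    d_non = build_design(samples, "nondivergent", basis)
    sf = np.asarray(samples["size_factor"], float)

    dispersions = _gene_dispersions(dataset.counts, d_div.X, sf,
                                    min_total_count=min_total_count, moderate=moderate)
    rows = []
    for gene in dataset.counts.index:
        y = dataset.counts.loc[gene].to_numpy(dtype=float)
        row = {"gene": gene, "tested": False, "p": np.nan}
        alpha_g = dispersions.get(gene, np.nan)
        if np.isfinite(alpha_g):
            try:
                f_div = fit_gene(gene, y, d_div, sf, alpha_g)
                f_non = fit_gene(gene, y, d_non, sf, alpha_g)
                row.update(tested=True, p=lrt(f_div, f_non))
            except FitError:
                pass
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    tested = table["tested"].to_numpy(bool)
    table["padj"] = np.nan
    if tested.any():
        table.loc[tested, "padj"] = multipletests(
            table.loc[tested, "p"].to_numpy(float), method="fdr_bh")[1]
    table["divergent"] = table["padj"] < alpha
    n_tested = int(tested.sum())
    if n_tested == 0:
        raise ValueError("no testable genes")
    proportion = float(table.loc[tested, "divergent"].sum() / n_tested)
    return table, proportion


def compare_divergence_proportions(p1: float, n1: int, p2: float, n2: int) -> float:
    """Two-sided two-proportion z-test on divergence proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    counts = np.array([round(p1 * n1), round(p2 * n2)])
    _, p = proportions_ztest(counts, np.array([n1, n2]), alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# curve prediction and distances


def predict_curve(fit: GeneFit, times: np.ndarray, group: tuple[str, str],
                  include_baseline: bool = True) -> np.ndarray:
    """Log-scale (offset-free) linear predictor of a fit at given times.

    `group` is a (species, organ) pair; columns whose species/organ role
    matches (or is shared) contribute. Species baseline offsets are included
    unless `include_baseline=False`.
    """
    species, organ = group
    design = fit.design
    if species not in design.species_levels:
        raise ValueError(f"species '{species}' absent from fit")
    if design.organ_levels and organ not in design.organ_levels:
        raise ValueError(f"organ '{organ}' absent from fit")
    B = design.basis.evaluate(np.asarray(times, float))
    out = np.zeros(len(B))
    for j, role in design.roles.iterrows():
        r_sp, r_org = role["species"], role["organ"]
        if role["role"] == "curve":
            if not (pd.isna(r_sp) or r_sp == species):
                continue
            if not (pd.isna(r_org) or r_org == organ):
                continue
            out += fit.coefficients[j] * B[:, role["basis_index"]]
        elif role["role"] == "offset" and include_baseline:
            if r_sp == species:
                out += fit.coefficients[j]
    return out


def windowed_distance(
    fit: GeneFit,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    n_points: int = 100,
    n_windows: int = 10,
    include_baseline: bool = True,
) -> np.ndarray:
    """Per-window RMS distance between two predicted curves.

    Curves are evaluated at `n_points` equally spaced times over the
    timeline, split into `n_windows` consecutive blocks; each window
    reports the Euclidean norm of the pointwise differences divided by
    sqrt(points per window), so a constant offset c gives c in every window.
    """
    if fit.model_class != "complex":
        raise ValueError("windowed distances require a complex-class fit")
    if n_points % n_windows != 0:
        raise ValueError("n_points must be a multiple of n_windows")
    lo, hi = fit.design.basis.config.domain
    times = np.linspace(lo, hi, n_points)
    a = predict_curve(fit, times, group_a, include_baseline)
    b = predict_curve(fit, times, group_b, include_baseline)
    per = n_points // n_windows
    diff = (a - b).reshape(n_windows, per)
    return np.linalg.norm(diff, axis=1) / np.sqrt(per)


def variance_decomposition(
    normalized: pd.DataFrame,
    factors: pd.DataFrame,
    *,
    log: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Between-group variance share per factor on principal components.

    PCA on centered (log-scale) normalized counts; for each factor the
    between-group sum of squares of the component scores, weighted by the
    component variances, gives the factor's share of total variance.
    Returns (overall share per factor, per-component R^2 table).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(normalized, dtype=float).T  # samples x genes
    if log:
        X = np.log1p(X)
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix: no variance to decompose")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    var_c = scores.var(axis=0)

    shares = {}
    percomp = {}
    for factor in factors.columns:
        labels = factors[factor].to_numpy()
        if len(np.unique(labels)) < 2:
            raise ValueError(f"factor '{factor}' needs >= 2 groups")
        r2 = np.empty(n_comp)
        for c in range(n_comp):
            s = scores[:, c]
            tot = np.sum((s - s.mean()) ** 2)
            between = sum(
                (labels == g).sum() * (s[labels == g].mean() - s.mean()) ** 2
                for g in np.unique(labels))
            r2[c] = between / tot if tot > 0 else 0.0
        percomp[factor] = r2
        shares[factor] = float(np.sum(var_c * r2) / np.sum(var_c))
    percomp_df = pd.DataFrame(percomp, index=[f"PC{i+1}" for i in range(n_comp)])
    return pd.Series(shares, name="between_group_share"), percomp_df
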