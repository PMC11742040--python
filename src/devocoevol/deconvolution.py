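"""Marker-based tissue deconvolution of bulk transcriptomes.

Marker genes are selected by pairwise NB differential analysis between
compartment-specific transcriptomes (e.g. dental epithelium vs mesenchyme:
BH-adjusted p < 0.05 and |log2 fold change| above a threshold, strict
inequalities). Mean normalized marker expression per pure tissue forms the
signature matrix S; a bulk sample b is decomposed by solving

    min || b - S p ||_2   subject to   p >= 0,  sum(p) = 1,

a simplex-constrained least-squares problem solved exactly by support
enumeration (the optimum restricted to its active support is the
equality-constrained solution, so for the small k used here enumerating
supports is exact). Estimation uncertainty comes from bootstrapping the
marker list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ._nbglm import FitError, estimate_dispersion, fit_nb_glm


class DeconvolutionError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerConfig:
    """Marker-selection thresholds.

    lfc_threshold : minimum |log2 fold change| (strict), e.g. 3 for
        epithelium/mesenchyme markers, 1 for buccal/lingual.
    alpha : BH-adjusted significance level (strict).
    min_mean : minimum mean normalized expression for eligibility.
    """

    lfc_threshold: float = 3.0
    alpha: float = 0.05
    min_mean: float = 0.0

    def __post_init__(self):
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SignatureMatrix:
    """Mean normalized expression of marker genes per pure tissue."""

    values: pd.DataFrame          # markers x tissues
    marker_tissue: pd.Series      # defining tissue per marker

    def __post_init__(self):
        if (np.asarray(self.values) < 0).any():
            raise ValueError("signature entries must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated marker genes in signature")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame     # samples x tissues, point estimates
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_bootstrap: int


def select_markers(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    config: MarkerConfig = MarkerConfig(),
    size_factors: pd.Series | None = None,
) -> tuple[list[str], list[str]]:
    """NB Wald test of the tissue effect; returns (markers_a, markers_b).

    A gene is a marker when its BH-adjusted Wald p-value is < alpha and its
    |log2FC| strictly exceeds the threshold; the sign of the fold change
    assigns the defining tissue.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise DeconvolutionError("need >= 2 samples per tissue")
    genes = counts_a.index.intersection(counts_b.index)
    counts = pd.concat([counts_a.loc[genes], counts_b.loc[genes]], axis=1)
    if size_factors is None:
        from .profiles import size_factors as _sf
        size_factors = _sf(counts)
    sf = np.asarray(size_factors, float)
    n_a = counts_a.shape[1]
    X = np.column_stack([np.ones(counts.shape[1]),
                         np.r_[np.ones(n_a), np.zeros(counts.shape[1] - n_a)]])
    norm_mean = (np.asarray(counts, float) / sf).mean(axis=1)

    lfc = np.full(len(genes), np.nan)
    pvals = np.full(len(genes), np.nan)
    for i, gene in enumerate(genes):
        y = counts.loc[gene].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        try:
            alpha_g = estimate_dispersion(y, X, sf)
            fit = fit_nb_glm(y, X, sf, alpha_g, check_rank=False)
        except FitError:
            continue
        # Wald z from the observed-information covariance of the IRLS fit
        mu = fit.mu
        w = mu / (1.0 + alpha_g * mu)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se = np.sqrt(cov[1, 1])
        lfc[i] = fit.coef[1] / np.log(2.0)
        pvals[i] = 2.0 * norm.sf(abs(fit.coef[1]) / se)

    tested = np.isfinite(pvals)
    padj = np.full(len(genes), np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    ok = tested & (padj < config.alpha) & (np.abs(lfc) > config.lfc_threshold) \
        & (norm_mean >= config.min_mean)
    markers_a = [g for g, keep, l in zip(genes, ok, lfc) if keep and l > 0]
    markers_b = [g for g, keep, l in zip(genes, ok, lfc) if keep and l < 0]
    return markers_a, markers_b


def build_signature(
    tissue_counts: dict[str, pd.DataFrame],
    markers: dict[str, list[str]],
    size_factors: dict[str, pd.Series] | None = None,
) -> SignatureMatrix:
    """Mean normalized expression per marker per tissue.

    tissue_counts maps tissue name -> genes x samples counts; markers maps
    tissue name -> its marker list.
    """
    all_markers = [g for t in markers for g in markers[t]]
    if not all_markers:
        raise DeconvolutionError("empty marker set")
    if len(set(all_markers)) != len(all_markers):
        raise DeconvolutionError("duplicated genes across marker lists")
    cols = {}
    for tissue, counts in tissue_counts.items():
        missing = [g for g in all_markers if g not in counts.index]
        if missing:
            raise DeconvolutionError(f"markers absent from '{tissue}' counts: {missing[:5]}")
        mat = counts.loc[all_markers].to_numpy(dtype=float)
        if size_factors is not None:
            mat = mat / np.asarray(size_factors[tissue], float)
        cols[tissue] = mat.mean(axis=1)
    values = pd.DataFrame(cols, index=all_markers)
    tissue_of = pd.Series({g: t for t in markers for g in markers[t]}, name="tissue")
    return SignatureMatrix(values=values, marker_tissue=tissue_of.loc[values.index])


def _simplex_lstsq(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact min ||b - S p|| s.t. p >= 0, sum p = 1 by support enumeration."""
    k = S.shape[1]
    best_p, best_obj = None, np.inf
    for mask in range(1, 2 ** k):
        idx = [i for i in range(k) if mask >> i & 1]
        Ss = S[:, idx]
        # KKT system of the equality-constrained problem on this support
        G = Ss.T @ Ss
        kkt = np.zeros((len(idx) + 1, len(idx) + 1))
        kkt[:-1, :-1] = 2.0 * G
        kkt[:-1, -1] = 1.0
        kkt[-1, :-1] = 1.0
        rhs = np.concatenate([2.0 * Ss.T @ b, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            continue
        p_sub = sol[:-1]
        if np.any(p_sub < -1e-9):
            continue
        p = np.zeros(k)
        p[idx] = np.maximum(p_sub, 0.0)
        obj = float(np.sum((b - S @ p) ** 2))
        if obj < best_obj - 1e-15:
            best_obj, best_p = obj, p
    if best_p is None:
        raise DeconvolutionError("simplex least squares failed (degenerate signature)")
    return best_p / best_p.sum()


def nnls_normalized(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fallback: unconstrained-sum NNLS renormalized onto the simplex.

    Differs in general from the simplex-constrained optimum, which is the
    authoritative solution (`deconvolve`).
    """
    p, _ = nnls(S, b)
    tot = p.sum()
    if tot <= 0:
        raise DeconvolutionError("NNLS returned the zero vector")
    return p / tot


def deconvolve(bulk: pd.Series | np.ndarray, signature: SignatureMatrix) -> np.ndarray:
    """Tissue proportions of one bulk sample on the normalized linear scale."""
    S = signature.values.to_numpy(dtype=float)
    if isinstance(bulk, pd.Series):
        b = bulk.loc[signature.values.index].to_numpy(dtype=float)
    else:
        b = np.asarray(bulk, dtype=float)
        if b.shape != (S.shape[0],):
            raise DeconvolutionError("bulk vector must be restricted to signature genes")
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e10:
        raise DeconvolutionError(f"signature columns nearly collinear (cond={cond:.3g})")
    return _simplex_lstsq(S, b)


def bootstrap_deconvolve(
    bulk: pd.Series,
    signature: SignatureMatrix,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DeconvolutionResult:
    """Point estimate plus percentile intervals from marker-list bootstrap.

    The marker list is resampled with replacement `n_bootstrap` times; the
    signature and deconvolution are recomputed per replicate, and per-tissue
    2.5-97.5% percentile intervals are reported. Fully reproducible for a
    fixed seed.
    """
    if n_bootstrap < 2:
        raise DeconvolutionError("need at least 2 bootstrap replicates")
    markers = signature.values.index
    if len(markers) < 20:
        warnings.warn(f"only {len(markers)} markers: bootstrap intervals may be unstable",
                      RuntimeWarning)
    point = deconvolve(bulk, signature)
    S = signature.values.to_numpy(dtype=float)
    b = bulk.loc[markers].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_bootstrap, S.shape[1]))
    for i in range(n_bootstrap):
        take = rng.integers(0, len(markers), size=len(markers))
        reps[i] = _simplex_lstsq(S[take], b[take])
    low = np.percentile(reps, 2.5, axis=0)
    high = np.percentile(reps, 97.5, axis=0)
    low = np.minimum(low, point)
    high = np.maximum(high, point)
    tissues = signature.tissues
    name = bulk.name if bulk.name is not None else "sample"
    return DeconvolutionResult(
        proportions=pd.DataFrame([point], index=[name], columns=tissues),
        ci_low=pd.DataFrame([low], index=[name], columns=tissues),
        ci_high=pd.DataFrame([high], index=[name], columns=tissues),
        n_bootstrap=n_bootstrap,
    )
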