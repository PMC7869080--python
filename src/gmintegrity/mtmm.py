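"""Builders for the gray-matter integrity MTMM models.

Each function returns a :class:`~gmintegrity.modelspec.ModelSpec` for one of
the study's models: per-region CFAs, the full multitrait-multimethod
measurement model (4 trait factors, 3 mutually correlated method factors
orthogonal to the traits, residual covariances between VBM indicators of
neighbouring regions), its extension with age, the episodic-memory
correlational and regression variants, covariate-adjusted models, and the
multigroup measurement-invariance ladder.

Identification: trait factors are scaled by fixing the loading of their VBM
indicator to one (for the merged prefrontal factor, the medio-orbitofrontal
VBM indicator); method factors by the respective precuneus indicator.  The
episodic-memory factor uses the verbal-learning score as reference (any of
the four tasks is statistically equivalent).
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .dataset import Dataset
from .fit import FitResult, LRTResult, fit_multigroup, likelihood_ratio_test
from .modelspec import ModelSpec
from .simulate import (MEMORY_INDICATORS, METHOD_FACTORS, MODALITIES,
                       MR_INDICATORS, ROI_FACTORS, ROI_OF, ROIS)

#: indicators of each trait factor
ROI_INDICATORS = {
    "PFC": [f"{m}_{r}" for m in MODALITIES for r in ("mofc", "dlpfc")],
    "HC": [f"{m}_hc" for m in MODALITIES],
    "PHG": [f"{m}_phg" for m in MODALITIES],
    "PRE": [f"{m}_pre" for m in MODALITIES],
}
#: reference indicator per trait factor (its VBM measure)
ROI_REFERENCE = {"PFC": "vbm_mofc", "HC": "vbm_hc", "PHG": "vbm_phg",
                 "PRE": "vbm_pre"}
#: reference indicator per method factor (its precuneus measure)
METHOD_REFERENCE = {"VBM": "vbm_pre", "MT": "mt_pre", "MD": "md_pre"}

EM_REFERENCE = "vlmt"


def _loading_start(indicator: str) -> float:
    # mean-diffusivity indicators load negatively on integrity factors
    return -1.0 if indicator.startswith("md_") else 1.0


def roi_cfa_spec(roi: str) -> ModelSpec:
    """Single-factor CFA for one region's three (or six) indicators."""
    if roi not in ROI_INDICATORS:
        raise ValueError(f"unknown ROI factor {roi!r}; use one of {list(ROI_INDICATORS)}")
    inds = ROI_INDICATORS[roi]
    spec = ModelSpec(observed=list(inds), latents=[roi])
    ref = ROI_REFERENCE[roi]
    for ind in inds:
        if ind == ref:
            spec.add_loading(roi, ind, fixed=1.0)
        else:
            spec.add_loading(roi, ind, start=_loading_start(ind))
    spec.add_cov(roi, roi, start=1.0)
    for ind in inds:
        spec.add_cov(ind, ind)
    spec.validate()
    return spec


def mtmm_measurement_spec(fix_md_mofc_residual: bool = False) -> ModelSpec:
    """The 15-indicator MTMM measurement model.

    Four correlated trait factors, three correlated method factors
    orthogonal to the traits, free residual covariances between the VBM
    indicators of neighbouring regions (medio-orbitofrontal with
    dorsolateral prefrontal; hippocampus with parahippocampal gyrus).  With
    ``fix_md_mofc_residual`` the residual variance of the MD
    medio-orbitofrontal indicator is constrained to zero, the remedy applied
    after it was estimated at a small negative value.
    """
    spec = ModelSpec(observed=list(MR_INDICATORS),
                     latents=list(ROI_FACTORS) + list(METHOD_FACTORS))
    for ind in MR_INDICATORS:
        modality, roi = ind.split("_", 1)
        trait = ROI_OF[roi]
        if ind == ROI_REFERENCE[trait]:
            spec.add_loading(trait, ind, fixed=1.0)
        else:
            spec.add_loading(trait, ind, start=_loading_start(ind))
        method = modality.upper()
        if ind == METHOD_REFERENCE[method]:
            spec.add_loading(method, ind, fixed=1.0)
        else:
            spec.add_loading(method, ind, start=1.0)
    for f in list(ROI_FACTORS) + list(METHOD_FACTORS):
        spec.add_cov(f, f, start=1.0)
    for i, a in enumerate(ROI_FACTORS):
        for b in ROI_FACTORS[i + 1:]:
            spec.add_cov(a, b)
    for i, a in enumerate(METHOD_FACTORS):
        for b in METHOD_FACTORS[i + 1:]:
            spec.add_cov(a, b)
    # trait-method covariances are omitted, i.e. fixed to zero (orthogonality)
    for ind in MR_INDICATORS:
        if ind == "md_mofc" and fix_md_mofc_residual:
            spec.add_cov(ind, ind, fixed=0.0)
        else:
            spec.add_cov(ind, ind)
    spec.add_cov("vbm_mofc", "vbm_dlpfc")
    spec.add_cov("vbm_hc", "vbm_phg")
    spec.validate()
    return spec


def add_age(spec: ModelSpec) -> ModelSpec:
    """Let observed age covary with all seven latent factors."""
    out = copy.deepcopy(spec)
    if "age" in out.observed:
        raise ValueError("age already in the model")
    out.observed.append("age")
    out.add_cov("age", "age")
    for f in out.latents:
        out.add_cov("age", f)
    out.validate()
    return out


def correlational_spec(zero_em_method_covs: bool = False,
                       fix_md_mofc_residual: bool = True) -> ModelSpec:
    """Measurement model plus an episodic-memory factor correlated with the
    trait factors (and, unless fixed to zero, with the method factors).

    The MD medio-orbitofrontal residual is fixed to zero by default (the
    study's remedy for its near-zero estimate); pass
    ``fix_md_mofc_residual=False`` when the data-generating process has a
    regular residual there.
    """
    spec = mtmm_measurement_spec(fix_md_mofc_residual=fix_md_mofc_residual)
    spec.observed += list(MEMORY_INDICATORS)
    spec.latents.append("EM")
    for task in MEMORY_INDICATORS:
        if task == EM_REFERENCE:
            spec.add_loading("EM", task, fixed=1.0)
        else:
            spec.add_loading("EM", task, start=1.0)
        spec.add_cov(task, task)
    spec.add_cov("EM", "EM", start=1.0)
    for f in ROI_FACTORS:
        spec.add_cov("EM", f)
    if not zero_em_method_covs:
        for f in METHOD_FACTORS:
            spec.add_cov("EM", f)
    spec.validate()
    return spec


def regression_spec(fix_md_mofc_residual: bool = True) -> ModelSpec:
    """Episodic memory regressed on the four trait factors.

    Statistically equivalent to ``correlational_spec(zero_em_method_covs=
    True)`` — the structural layer between memory and the traits is
    saturated either way — but reports unique (partial) effects.
    """
    spec = correlational_spec(zero_em_method_covs=True,
                              fix_md_mofc_residual=fix_md_mofc_residual)
    spec.covs = [c for c in spec.covs if c.key != ("EM", "EM")
                 and not (("EM" in (c.a, c.b)) and (c.a in ROI_FACTORS or c.b in ROI_FACTORS))]
    for f in ROI_FACTORS:
        spec.add_regression("EM", f, start=0.0)
    spec.add_cov("EM", "EM", start=1.0)  # residual variance
    spec.validate()
    return spec


def r_squared(fr: FitResult, outcome: str = "EM") -> float:
    """Share of the latent outcome's variance explained by its predictors.

    ``R^2 = 1 - residual variance / model-implied total variance``.
    """
    ram = fr.ram
    mapping = fr.grouped.maps[0] if fr.grouped is not None else np.arange(len(fr.params))
    A, S, M = ram.materialize(fr.theta[mapping])
    m = A.shape[0]
    E = np.linalg.inv(np.eye(m) - A)
    V = E @ S @ E.T
    i = ram.var_names.index(outcome)
    total = V[i, i]
    if total <= 0:
        raise ValueError(f"non-positive implied variance for {outcome!r}")
    return float(1.0 - S[i, i] / total)


def covariate_adjusted_spec(covariates=("age",),
                            fix_md_mofc_residual: bool = True) -> ModelSpec:
    """Correlational model with all latent factors regressed on covariates.

    The covariates form a saturated exogenous block; the estimated latent
    covariances (episodic memory with the trait factors in particular) are
    the covariate-adjusted associations.
    """
    allowed = ("age", "education", "sex")
    covariates = list(covariates)
    for c in covariates:
        if c not in allowed:
            raise ValueError(f"unknown covariate {c!r}; choose from {allowed}")
    spec = correlational_spec(zero_em_method_covs=True,
                              fix_md_mofc_residual=fix_md_mofc_residual)
    spec.observed += covariates
    for i, a in enumerate(covariates):
        spec.add_cov(a, a)
        for b in covariates[i + 1:]:
            spec.add_cov(a, b)
        for f in spec.latents:
            spec.add_regression(f, a, start=0.0)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# measurement invariance across groups
# ---------------------------------------------------------------------------

INVARIANCE_LEVELS = ("configural", "metric", "scalar")


def median_split(values: pd.Series) -> pd.Series:
    """Binary split at the sample median; ties go to the lower group."""
    med = values.median()
    return (values > med).astype(int)


def _group_spec(spec: ModelSpec, g: int, shared_loadings: bool,
                shared_intercepts: bool, reference_group: bool) -> ModelSpec:
    out = copy.deepcopy(spec)
    suffix = f".g{g}"
    loading_labels = {p.label for p in out.paths
                      if p.label is not None and p.src in out.latents
                      and p.dst in out.observed}
    for p in out.paths:
        if p.label is None:
            continue
        if shared_loadings and p.label in loading_labels:
            continue
        p.label = p.label + suffix
    for c in out.covs:
        if c.label is not None:
            c.label = c.label + suffix
    means = {}
    for v in out.observed:
        term = out.mean_term(v)
        if isinstance(term, str):
            means[v] = term if shared_intercepts else term + suffix
        else:
            means[v] = term
    if shared_intercepts and not reference_group:
        # free latent means in non-reference groups
        for lat in out.latents:
            means[lat] = f"alpha_{lat}{suffix}"
    out.means = means
    return out


def invariance_ladder(spec: ModelSpec, ds: Dataset, group_col: str,
                      levels=INVARIANCE_LEVELS, min_group_n: int = 30,
                      compute_se: bool = False):
    """Fit the configural / metric / scalar sequence across groups.

    Returns ``(fits, tests)``: a dict of :class:`FitResult` per level and a
    dict of sequential :class:`LRTResult` (each level against the previous,
    less constrained one).
    """
    if group_col not in ds.frame.columns:
        raise ValueError(f"no group column {group_col!r}")
    labels = ds.frame[group_col]
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    frames = []
    for gval in groups:
        sub = ds.frame.loc[labels == gval, spec.observed]
        if sub.notna().any(axis=1).sum() < min_group_n:
            raise ValueError(f"group {gval!r} has fewer than {min_group_n} usable rows")
        frames.append(sub)

    fits: dict[str, FitResult] = {}
    tests: dict[str, LRTResult] = {}
    previous = None
    for level in levels:
        if level not in INVARIANCE_LEVELS:
            raise ValueError(f"unknown invariance level {level!r}")
        shared_loadings = level in ("metric", "scalar")
        shared_intercepts = level == "scalar"
        specs = [_group_spec(spec, g, shared_loadings, shared_intercepts,
                             reference_group=(g == 0))
                 for g in range(len(groups))]
        fr = fit_multigroup(specs, frames, compute_se=compute_se)
        fits[level] = fr
        if previous is not None:
            tests[level] = likelihood_ratio_test(fits[previous], fr)
        previous = level
    return fits, tests
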