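"""Synthetic-data generator for the multimodal gray-matter integrity design.

The generating model is a linear-normal MTMM factor model: four regional
"integrity" trait factors (prefrontal cortex PFC, hippocampus HC,
parahippocampal gyrus PHG, precuneus PRE), three imaging-method factors
(VBM, MT, MD) orthogonal to the trait factors, and a latent episodic-memory
factor (EM).  Each of 15 regional imaging indicators loads on one trait and
one method factor; four memory task scores load on EM.  Age, education and
sex act on the latent factors; the *total* factor correlation matrix is held
at its configured value by absorbing the covariate-induced covariance into
the latent residual covariance.

Observed variables are generated directly on the analysis scale
(mean 5, SD 2); :func:`emit_raw_scale` maps them onto the original
measurement scales for exercising the preparation operators.

Missingness follows the study design: an MR block observed for ``n_mr`` of
``n_total`` participants (selection probability depends on sex, which keeps
the mechanism missing-at-random while reproducing the observed sex
selectivity), modality sub-blocks masked independently within the MR
subsample, and a small per-column loss on the memory scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset

ROI_FACTORS = ("PFC", "HC", "PHG", "PRE")
METHOD_FACTORS = ("VBM", "MT", "MD")
FACTORS = ROI_FACTORS + METHOD_FACTORS + ("EM",)

ROIS = ("hc", "phg", "pre", "mofc", "dlpfc")
MODALITIES = ("vbm", "mt", "md")
MR_INDICATORS = tuple(f"{m}_{r}" for m in MODALITIES for r in ROIS)
MEMORY_INDICATORS = ("vlmt", "fp", "se", "ol")
COVARIATES = ("age", "education", "sex")

#: trait factor measured by each regional indicator (both frontal ROIs -> PFC)
ROI_OF = {r: ("PFC" if r in ("mofc", "dlpfc") else r.upper()) for r in ROIS}

# Original measurement scales (mean, SD) for emit_raw_scale; memory scores and
# covariates from the full-sample descriptives, MR variables from the MR sample.
RAW_SCALES = {
    "age": (70.60, 3.84),
    "education": (14.16, 2.89),
    "vlmt": (8.50, 2.68),
    "fp": (0.27, 0.21),
    "se": (0.28, 0.14),
    "ol": (13.26, 4.00),
    "vbm_hc": (0.5218, 0.0458),
    "vbm_phg": (0.4316, 0.0317),
    "vbm_pre": (0.3969, 0.0304),
    "vbm_mofc": (0.4156, 0.0307),
    "vbm_dlpfc": (0.4147, 0.0297),
    "mt_hc": (332.58, 31.15),
    "mt_phg": (363.62, 14.92),
    "mt_pre": (335.81, 18.81),
    "mt_mofc": (354.50, 16.79),
    "mt_dlpfc": (300.51, 21.40),
    "md_hc": (0.0014, 0.000135),
    "md_phg": (0.0013, 0.000111),
    "md_pre": (0.0012, 0.000112),
    "md_mofc": (0.0012, 0.000102),
    "md_dlpfc": (0.0012, 0.000081),
}


@dataclass
class SimulationConfig:
    """Generating parameters for the synthetic study.

    Loadings are given on the standardized scale (unit-variance factors,
    indicator SD ``indicator_sd``); residual variances are on the observed
    scale.  Covariate effects on the latent factors are standardized for age
    and education (which are generated as standard normal deviates) and
    per-unit for sex (0 = male, 1 = female).
    """

    n_total: int = 1522
    n_mr: int = 333
    roi_loadings: dict = field(default_factory=dict)       # indicator -> (factor, std loading)
    method_loadings: dict = field(default_factory=dict)    # indicator -> (factor, std loading)
    em_loadings: dict = field(default_factory=dict)        # task -> std loading
    roi_factor_cov: np.ndarray = None                      # 4x4 total correlations
    method_factor_cov: np.ndarray = None                   # 3x3 total correlations
    em_roi_cov: dict = field(default_factory=dict)         # roi factor -> total corr with EM
    em_method_cov: dict = field(default_factory=dict)      # method factor -> total corr with EM
    covariate_effects: dict = field(default_factory=dict)  # covariate -> {factor: effect}
    residual_variances: dict = field(default_factory=dict)  # indicator -> observed-scale var
    residual_covariances: dict = field(default_factory=dict)  # (ind, ind) -> observed-scale cov
    missingness: dict = field(default_factory=dict)        # block/column -> observe probability
    sex_p: float = 0.5072          # P(female) in the total sample
    sex_p_mr: float = 0.3844       # P(female) within the MR subsample
    indicator_mean: float = 5.0
    indicator_sd: float = 2.0
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def indicator_names(self) -> list[str]:
        return list(MR_INDICATORS) + list(MEMORY_INDICATORS)

    @property
    def observed_names(self) -> list[str]:
        return list(COVARIATES) + self.indicator_names

    def validate(self) -> None:
        if not (1 <= self.n_mr <= self.n_total):
            raise ValueError("need 1 <= n_mr <= n_total")
        for key, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"observe probability for {key!r} outside [0,1]: {p}")
        if not 0.0 < self.sex_p < 1.0 or not 0.0 < self.sex_p_mr < 1.0:
            raise ValueError("sex probabilities must be in (0,1)")
        phi = self.factor_corr()
        _assert_pd(phi, "total factor covariance")
        _assert_pd(self.latent_residual_cov(), "latent residual covariance")

    # -- generating matrices -------------------------------------------
    def factor_corr(self) -> np.ndarray:
        """Total 8x8 latent correlation matrix over FACTORS."""
        k = len(FACTORS)
        phi = np.eye(k)
        phi[:4, :4] = self.roi_factor_cov
        phi[4:7, 4:7] = self.method_factor_cov
        for i, f in enumerate(ROI_FACTORS):
            phi[7, i] = phi[i, 7] = self.em_roi_cov.get(f, 0.0)
        for i, f in enumerate(METHOD_FACTORS):
            phi[7, 4 + i] = phi[4 + i, 7] = self.em_method_cov.get(f, 0.0)
        return phi

    def covariate_beta(self) -> np.ndarray:
        """Effects matrix B (factors x covariates), centered-covariate scale."""
        b = np.zeros((len(FACTORS), len(COVARIATES)))
        for j, cov in enumerate(COVARIATES):
            for i, f in enumerate(FACTORS):
                b[i, j] = self.covariate_effects.get(cov, {}).get(f, 0.0)
        return b

    def covariate_cov(self) -> np.ndarray:
        """Covariance of the centered internal covariates (z_age, z_edu, sex)."""
        return np.diag([1.0, 1.0, self.sex_p * (1.0 - self.sex_p)])

    def latent_residual_cov(self) -> np.ndarray:
        """Psi: latent covariance net of covariate effects.

        Chosen so that B Sigma_c B' + Psi equals the configured total factor
        correlation matrix exactly.
        """
        b = self.covariate_beta()
        return self.factor_corr() - b @ self.covariate_cov() @ b.T

    def loading_matrix(self) -> np.ndarray:
        """Observed-scale Lambda (19 indicators x 8 factors)."""
        lam = np.zeros((len(self.indicator_names), len(FACTORS)))
        fidx = {f: i for i, f in enumerate(FACTORS)}
        iidx = {v: i for i, v in enumerate(self.indicator_names)}
        for ind, (f, val) in self.roi_loadings.items():
            lam[iidx[ind], fidx[f]] = val * self.indicator_sd
        for ind, (f, val) in self.method_loadings.items():
            lam[iidx[ind], fidx[f]] = val * self.indicator_sd
        for ind, val in self.em_loadings.items():
            lam[iidx[ind], fidx["EM"]] = val * self.indicator_sd
        return lam

    def residual_cov(self) -> np.ndarray:
        """Observed-scale Theta (19 x 19)."""
        names = self.indicator_names
        iidx = {v: i for i, v in enumerate(names)}
        theta = np.diag([self.residual_variances[v] for v in names])
        for (a, bname), val in self.residual_covariances.items():
            theta[iidx[a], iidx[bname]] = theta[iidx[bname], iidx[a]] = val
        return theta


def _assert_pd(mat: np.ndarray, what: str) -> None:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{what} is not symmetric")
    eigmin = np.linalg.eigvalsh(mat).min()
    if eigmin <= 0:
        raise ValueError(f"{what} is not positive definite (min eigenvalue {eigmin:.3g})")


def default_base2_config() -> SimulationConfig:
    """Default configuration emulating the study's published structure.

    Sample sizes, the trait/method factor correlations, covariate effects and
    the missingness design follow the published descriptives; standardized
    loadings are regular values inside the published ranges (trait loadings
    0.27-0.86 in absolute value, method loadings above 0.18, memory loadings
    0.46-0.56).  MD indicators load negatively on the trait factors (higher
    latent integrity means lower diffusivity).
    """
    roi_loadings = {
        "vbm_hc": ("HC", 0.75), "vbm_phg": ("PHG", 0.70), "vbm_pre": ("PRE", 0.55),
        "vbm_mofc": ("PFC", 0.65), "vbm_dlpfc": ("PFC", 0.60),
        "mt_hc": ("HC", 0.60), "mt_phg": ("PHG", 0.55), "mt_pre": ("PRE", 0.45),
        "mt_mofc": ("PFC", 0.50), "mt_dlpfc": ("PFC", 0.45),
        "md_hc": ("HC", -0.65), "md_phg": ("PHG", -0.60), "md_pre": ("PRE", -0.55),
        "md_mofc": ("PFC", -0.30), "md_dlpfc": ("PFC", -0.45),
    }
    method_loadings = {
        "vbm_hc": ("VBM", 0.35), "vbm_phg": ("VBM", 0.35), "vbm_pre": ("VBM", 0.45),
        "vbm_mofc": ("VBM", 0.50), "vbm_dlpfc": ("VBM", 0.50),
        "mt_hc": ("MT", 0.50), "mt_phg": ("MT", 0.45), "mt_pre": ("MT", 0.55),
        "mt_mofc": ("MT", 0.55), "mt_dlpfc": ("MT", 0.55),
        "md_hc": ("MD", 0.45), "md_phg": ("MD", 0.50), "md_pre": ("MD", 0.55),
        "md_mofc": ("MD", 0.55), "md_dlpfc": ("MD", 0.50),
    }
    em_loadings = {"vlmt": 0.56, "fp": 0.46, "se": 0.50, "ol": 0.52}

    # Published trait-factor correlations (order PFC, HC, PHG, PRE)
    roi_corr = np.array([
        [1.00, 0.59, 0.68, 0.18],
        [0.59, 1.00, 0.84, 0.13],
        [0.68, 0.84, 1.00, 0.37],
        [0.18, 0.13, 0.37, 1.00],
    ])
    # Published method-factor correlations (order VBM, MT, MD)
    method_corr = np.array([
        [1.00, 0.25, -0.53],
        [0.25, 1.00, -0.77],
        [-0.53, -0.77, 1.00],
    ])
    em_roi = {"PFC": 0.24, "HC": 0.33, "PHG": 0.27, "PRE": 0.16}

    covariate_effects = {
        # standardized (per SD of the covariate, factors have unit variance)
        "age": {"PFC": -0.28, "HC": -0.28, "PHG": -0.17, "PRE": -0.06,
                "VBM": -0.16, "MT": -0.29, "MD": 0.40, "EM": -0.22},
        "education": {"PFC": 0.06, "HC": 0.02, "PHG": -0.02, "PRE": -0.12,
                      "EM": 0.29},
        # per-unit female advantage in latent SD units
        "sex": {"PFC": 0.32, "HC": 0.69, "PHG": 0.43, "PRE": 0.31, "EM": 0.32},
    }

    cfg = SimulationConfig(
        roi_loadings=roi_loadings,
        method_loadings=method_loadings,
        em_loadings=em_loadings,
        roi_factor_cov=roi_corr,
        method_factor_cov=method_corr,
        em_roi_cov=em_roi,
        em_method_cov={"VBM": 0.0, "MT": 0.0, "MD": 0.0},
        covariate_effects=covariate_effects,
        missingness={
            "vbm": 330.0 / 333.0, "mt": 197.0 / 333.0, "md": 274.0 / 333.0,
            "vlmt": 1500.0 / 1522.0, "fp": 1500.0 / 1522.0,
            "se": 1500.0 / 1522.0, "ol": 1500.0 / 1522.0,
        },
    )
    # residual variances close the indicator variance to indicator_sd^2
    sd2 = cfg.indicator_sd ** 2
    res = {}
    for ind in cfg.indicator_names:
        comm = 0.0
        if ind in roi_loadings:
            comm += roi_loadings[ind][1] ** 2
        if ind in method_loadings:
            comm += method_loadings[ind][1] ** 2
        if ind in em_loadings:
            comm += em_loadings[ind] ** 2
        res[ind] = sd2 * (1.0 - comm)
    cfg.residual_variances = res
    # residual covariances between VBM indicators of neighbouring ROIs,
    # expressed as residual correlation 0.30 / 0.25 of the residual SDs
    cfg.residual_covariances = {
        ("vbm_mofc", "vbm_dlpfc"): 0.30 * np.sqrt(res["vbm_mofc"] * res["vbm_dlpfc"]),
        ("vbm_hc", "vbm_phg"): 0.25 * np.sqrt(res["vbm_hc"] * res["vbm_phg"]),
    }
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# closed-form population moments
# ---------------------------------------------------------------------------

def population_moments(config: SimulationConfig) -> tuple[pd.Series, pd.DataFrame]:
    """Exact implied mean and covariance of all observed variables.

    Composition on the observed scale: with centered covariates ``c`` of
    covariance ``Sigma_c``, latent factors ``eta = B c + zeta``
    (``Var(zeta) = Psi``), and indicators ``x = nu + Lambda eta + eps``:

    ``Cov(x)   = Lambda (B Sigma_c B' + Psi) Lambda' + Theta``
    ``Cov(x,c) = Lambda B Sigma_c``

    Observed age and education are ``5 + 2 z``; sex is the raw 0/1 variable.
    """
    config.validate()
    lam = config.loading_matrix()
    phi = config.factor_corr()          # = B Sigma_c B' + Psi by construction
    theta = config.residual_cov()
    b = config.covariate_beta()
    sigma_c = config.covariate_cov()

    cov_ii = lam @ phi @ lam.T + theta
    cov_ic = lam @ b @ sigma_c          # indicators x centered covariates

    # observed covariate scale: age/education 5 + 2 z, sex raw 0/1
    scale = np.array([2.0, 2.0, 1.0])
    cov_cc = sigma_c * np.outer(scale, scale)
    cov_ic = cov_ic * scale[None, :]

    names = config.observed_names
    k = len(names)
    cov = np.zeros((k, k))
    nc = len(COVARIATES)
    cov[:nc, :nc] = cov_cc
    cov[nc:, nc:] = cov_ii
    cov[nc:, :nc] = cov_ic
    cov[:nc, nc:] = cov_ic.T

    mean = np.full(k, config.indicator_mean)
    mean[0] = mean[1] = 5.0
    mean[2] = config.sex_p
    return pd.Series(mean, index=names), pd.DataFrame(cov, index=names, columns=names)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def generate_complete(config: SimulationConfig, n: int | None = None,
                      seed: int | None = None) -> Dataset:
    """Draw a complete dataset from the generating model.

    Deterministic given ``seed`` (defaults to ``config.seed``).  Column
    order: participant id, covariates, memory scores, MR indicators.
    """
    config.validate()
    if n is None:
        n = config.n_total
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    z_age = rng.standard_normal(n)
    z_edu = rng.standard_normal(n)
    sex = (rng.random(n) < config.sex_p).astype(float)
    c_centered = np.column_stack([z_age, z_edu, sex - config.sex_p])

    psi = config.latent_residual_cov()
    zeta = rng.standard_normal((n, len(FACTORS))) @ np.linalg.cholesky(psi).T
    eta = c_centered @ config.covariate_beta().T + zeta

    theta = config.residual_cov()
    eps = rng.standard_normal((n, theta.shape[0])) @ np.linalg.cholesky(theta).T
    x = config.indicator_mean + eta @ config.loading_matrix().T + eps

    frame = pd.DataFrame({"pid": np.arange(1, n + 1)})
    frame["age"] = 5.0 + 2.0 * z_age
    frame["education"] = 5.0 + 2.0 * z_edu
    frame["sex"] = sex
    for j, name in enumerate(config.indicator_names):
        frame[name] = x[:, j]
    # spec column order: covariates, memory, MR
    order = ["pid", "age", "education", "sex"] + list(MEMORY_INDICATORS) + list(MR_INDICATORS)
    frame = frame[order]
    roles = {"pid": "id", "age": "covariate", "education": "covariate", "sex": "covariate"}
    return Dataset(frame, roles)


def apply_missingness(ds: Dataset, config: SimulationConfig,
                      seed: int | None = None) -> Dataset:
    """Mask the dataset according to the study's missingness design.

    Exactly ``n_total - n_mr`` rows lose the whole MR block; MR rows are
    chosen without replacement with sex-dependent weights so that the female
    fraction in the MR subsample matches ``sex_p_mr`` in expectation (a
    missing-at-random mechanism: it depends only on observed sex).  Within MR
    rows each modality block is masked independently with its configured
    probability; memory scores are masked per column.  Deterministic given
    ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = ds.copy()
    n = out.n
    n_mr = min(config.n_mr, n) if n != config.n_total else config.n_mr

    # sex-weighted MR selection: w proportional to P(selected | sex)
    pi = n_mr / n
    sex = out.frame["sex"].to_numpy()
    p_f, q_f = config.sex_p, config.sex_p_mr
    w = np.where(sex > 0.5, pi * q_f / p_f, pi * (1 - q_f) / (1 - p_f))
    idx_mr = rng.choice(n, size=n_mr, replace=False, p=w / w.sum())
    in_mr = np.zeros(n, dtype=bool)
    in_mr[idx_mr] = True

    cols = {m: [f"{m}_{r}" for r in ROIS] for m in MODALITIES}
    for m in MODALITIES:
        p_obs = config.missingness.get(m, 1.0)
        keep = in_mr & (rng.random(n) < p_obs)
        out.frame.loc[~keep, cols[m]] = np.nan
    for task in MEMORY_INDICATORS:
        p_obs = config.missingness.get(task, 1.0)
        drop = rng.random(n) >= p_obs
        out.frame.loc[drop, task] = np.nan
    return out


def emit_raw_scale(ds: Dataset, config: SimulationConfig,
                   include_icv: bool = False, seed: int = 0,
                   icv_r2: float = 0.09) -> Dataset:
    """Map a generated dataset onto the original measurement scales.

    Each column is transformed affinely to the published mean/SD.  With
    ``include_icv`` an intracranial-volume column (ml) is added and a head
    -size component explaining ``icv_r2`` of each raw VBM variance is mixed
    in, so that the ICV-adjustment operator has something real to remove;
    the total raw SD is preserved.
    """
    out = ds.copy()
    for col, (m, s) in RAW_SCALES.items():
        if col not in out.frame.columns:
            continue
        z = (out.frame[col] - config.indicator_mean) / config.indicator_sd
        if col in ("age", "education"):
            z = (out.frame[col] - 5.0) / 2.0
        out.frame[col] = m + s * z
    if include_icv:
        rng = np.random.default_rng(seed)
        icv = rng.normal(1450.0, 150.0, out.n)
        out.frame["icv"] = icv
        out.roles["icv"] = "covariate"
        shrink = np.sqrt(1.0 - icv_r2)
        for col in [f"vbm_{r}" for r in ROIS]:
            m, s = RAW_SCALES[col]
            b = np.sqrt(icv_r2) * s / 150.0
            out.frame[col] = m + shrink * (out.frame[col] - m) + b * (icv - 1450.0)
    return out
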