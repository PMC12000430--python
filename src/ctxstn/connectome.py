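"""Linking coupling spatial patterns to structural and functional connectivity.

Structural connectivity between a cortical and a subthalamic contact is
the number of atlas streamlines passing within 5 mm of the ECoG contact
and 3 mm of the STN-LFP contact (Euclidean distance in MNI mm, vertex
proximity, boundary inclusive).  Functional connectivity is a
seed-correlation map of a 4D volume (5 mm spherical seed at the ECoG
contact), summarised as the mean correlation within target parcels
(e.g. indirect-pathway nuclei).  Either measure is then related to the
band-averaged coupling pattern values by a random-intercept linear
mixed-effects model::

    connectivity ~ pattern + medication + (1 | subject)

fitted by REML, reporting per-term coefficients and p-values, the
conditional R^2 (fixed + random variance over total), the BIC (from a
maximum-likelihood refit, comparable across fixed-effect sets) and the
Pearson r between fitted and observed responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: contact proximity radii (mm)
R_ECOG = 5.0
R_STN = 3.0


@dataclass
class FiberAtlas:
    """Streamline polylines, points in MNI mm."""

    streamlines: list

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline must be an (n >= 2, 3) polyline")
            if not np.isfinite(s).all():
                raise ValueError("streamline coordinates must be finite")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class ContactPair:
    ecog_xyz: tuple[float, float, float]
    stn_xyz: tuple[float, float, float]
    r_ecog: float = R_ECOG
    r_stn: float = R_STN
    fiber_count: int | None = None

    def __post_init__(self) -> None:
        if self.r_ecog <= 0 or self.r_stn <= 0:
            raise ValueError("radii must be positive")


@dataclass
class MixedModelResult:
    fixed_effects: dict  # term -> {"beta", "se", "p"}
    random_intercept_variance: float
    residual_variance: float
    conditional_r2: float
    bic: float
    fit_quality_r: float
    converged: bool = True
    boundary_warning: bool = False
    n_obs: int = 0
    meta: dict = field(default_factory=dict)


def count_connecting_fibers(atlas: FiberAtlas, pair: ContactPair) -> int:
    """Streamlines passing within both contact radii (vertex proximity).

    A streamline counts iff the minimum distance from any of its
    vertices to the ECoG contact is <= r_ecog AND to the STN contact is
    <= r_stn; boundaries are inclusive.
    """
    e = np.asarray(pair.ecog_xyz, dtype=float)
    s = np.asarray(pair.stn_xyz, dtype=float)
    n = 0
    for line in atlas.streamlines:
        de = np.linalg.norm(line - e, axis=1).min()
        if de > pair.r_ecog:
            continue
        ds = np.linalg.norm(line - s, axis=1).min()
        if ds <= pair.r_stn:
            n += 1
    return n


def seed_correlation_map(volume_4d, seed_xyz, r: float = 5.0) -> np.ndarray:
    """Whole-volume Pearson correlation with a spherical seed time course.

    ``volume_4d`` is a nibabel spatial image (x, y, z, t) whose affine
    maps voxel indices to MNI mm.  The seed time course is the mean over
    voxels within ``r`` mm of ``seed_xyz``; the map holds the
    correlation of that time course with every voxel, with
    zero-variance voxels masked as NaN.
    """
    import nibabel as nib

    data = np.asarray(volume_4d.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] < 10:
        raise ValueError("need a 4D volume with >= 10 time points")
    shape = data.shape[:3]
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = nib.affines.apply_affine(volume_4d.affine, vox)
    dist = np.linalg.norm(mm - np.asarray(seed_xyz, dtype=float), axis=1)
    in_seed = dist <= r
    if not in_seed.any():
        raise ValueError(f"no voxels within {r} mm of seed {tuple(seed_xyz)}")
    flat = data.reshape(-1, data.shape[-1])
    seed_ts = flat[in_seed].mean(axis=0)
    seed_ts = seed_ts - seed_ts.mean()
    seed_sd = seed_ts.std()
    if seed_sd == 0:
        raise ValueError("seed time course has zero variance")
    centered = flat - flat.mean(axis=1, keepdims=True)
    sds = centered.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_map = (centered @ seed_ts) / (flat.shape[-1] * sds * seed_sd)
    r_map[sds == 0] = np.nan
    return r_map.reshape(shape)


def parcel_mean(corr_map: np.ndarray, parcel_mask: np.ndarray) -> float:
    """Mean of defined (non-NaN) map voxels inside the parcel."""
    corr_map = np.asarray(corr_map, dtype=float)
    parcel_mask = np.asarray(parcel_mask, dtype=bool)
    if corr_map.shape != parcel_mask.shape:
        raise ValueError("parcel mask not aligned to map grid")
    vals = corr_map[parcel_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty parcel (no defined voxels)")
    return float(vals.mean())


def _perfect_fit_fallback(df, response: str, fixed_effects, group: str,
                          formula: str) -> MixedModelResult:
    """Degenerate (zero-variance) designs: plain least squares on fixed effects.

    MixedLM's profiled likelihood is singular when the response is an
    exact linear function of the predictors; the coefficients are then
    recovered by ordinary least squares and both variance components
    are zero (conditional R^2 = 1).
    """
    import patsy

    y, x = patsy.dmatrices(formula, df, return_type="dataframe")
    beta, *_ = np.linalg.lstsq(x.to_numpy(), y.to_numpy().ravel(), rcond=None)
    fitted = x.to_numpy() @ beta
    resid = y.to_numpy().ravel() - fitted
    if np.var(resid) > 1e-10 * max(np.var(y.to_numpy()), 1e-30):
        raise ValueError("mixed-model fit failed on a non-degenerate design")
    fe = {term: {"beta": float(b), "se": 0.0, "p": 0.0}
          for term, b in zip(x.columns, beta)}
    n = len(df)
    k = len(beta) + 2
    llf = -0.5 * n * (np.log(2 * np.pi * max(np.var(resid), 1e-300)) + 1)
    return MixedModelResult(
        fixed_effects=fe, random_intercept_variance=0.0,
        residual_variance=float(np.var(resid)), conditional_r2=1.0,
        bic=float(-2 * llf + k * np.log(n)), fit_quality_r=1.0,
        converged=True, boundary_warning=True, n_obs=n,
        meta={"formula": formula, "fallback": "perfect_fit_ols"},
    )


def lme_fit(
    table,
    response: str = "response",
    fixed_effects: tuple[str, ...] = ("pattern", "medication"),
    group: str = "subject",
) -> MixedModelResult:
    """Random-intercept linear mixed model via REML.

    Fits ``response ~ fixed_effects + (1 | group)`` with statsmodels
    MixedLM.  Alternative fixed-effect sets (e.g. single connectivity
    predictors or combinations of parcel means) support the
    model-comparison analyses; the BIC comes from a maximum-likelihood
    refit so it is comparable across fixed-effect sets.
    """
    import pandas as pd
    import statsmodels.api as sm
    from scipy.stats import pearsonr

    df = pd.DataFrame(table)
    for col in (response, group, *fixed_effects):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df[group].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    formula = f"{response} ~ " + " + ".join(fixed_effects) if fixed_effects else f"{response} ~ 1"
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(formula, groups=group, data=df)
            fit = model.fit(reml=True)
            fit_ml = sm.MixedLM.from_formula(formula, groups=group, data=df).fit(reml=False)
    except np.linalg.LinAlgError:
        return _perfect_fit_fallback(df, response, fixed_effects, group, formula)
    k = len(fit_ml.fe_params) + 2  # fixed effects + random-intercept var + residual var
    n = len(df)
    bic = -2.0 * fit_ml.llf + k * np.log(n)
    fe = {}
    for term in fit.fe_params.index:
        fe[term] = {
            "beta": float(fit.fe_params[term]),
            "se": float(fit.bse[term]),
            "p": float(fit.pvalues[term]),
        }
    var_re = float(np.asarray(fit.cov_re).ravel()[0])
    var_resid = float(fit.scale)
    exog = model.exog
    fitted_fixed = exog @ fit.fe_params.values
    re = fit.random_effects
    offsets = np.array([float(np.asarray(re[g]).ravel()[0]) for g in df[group]])
    fitted = fitted_fixed + offsets
    var_fixed = float(np.var(fitted_fixed))
    denom = var_fixed + var_re + var_resid
    cond_r2 = (var_fixed + var_re) / denom if denom > 0 else 1.0
    y = df[response].to_numpy(dtype=float)
    if np.std(fitted) > 0 and np.std(y) > 0:
        r_fit = float(pearsonr(fitted, y)[0])
    else:
        r_fit = np.nan
    boundary = var_re <= 1e-10 * max(var_resid, 1e-30)
    return MixedModelResult(
        fixed_effects=fe,
        random_intercept_variance=var_re,
        residual_variance=var_resid,
        conditional_r2=float(np.clip(cond_r2, 0.0, 1.0)),
        bic=float(bic),
        fit_quality_r=r_fit,
        converged=bool(getattr(fit, "converged", True)),
        boundary_warning=bool(boundary),
        n_obs=n,
        meta={"formula": formula},
    )
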