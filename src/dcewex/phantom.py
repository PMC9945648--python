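"""Digital tumor phantom for end-to-end validation of the pipeline.

No deposited animal data exist for this protocol, so a 3D phantom
emulates the statistical structure of the three experiments: an
ellipsoidal glioma with a well-perfused rim and a hypoperfused core
(heterogeneity in all five kinetic parameters), a parametric
first-pass AIF with recirculation washout, the segmented 8°-25°-8°
acquisition at 5 s/frame, Rician magnitude noise, test–retest pairs
with physiological drift confined to the flow/permeability/exchange
parameters, a treated-vs-control longitudinal cohort with aggressive
tumor growth in both arms, and an FDG-PET SUV volume linearly coupled
to k_io and blurred to 1.4 mm PET resolution.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinetics import AIFCurve, TissueParams
from .relaxation import AcquisitionSchedule, RelaxationContext, spgr_signal
from .fitting import predict_signal

__all__ = [
    "PhantomSpec",
    "make_aif",
    "aif_auc_analytic",
    "make_phantom",
    "simulate_dce",
    "simulate_test_retest",
    "simulate_cohorts",
    "simulate_suv",
    "simulate_suv_cohort",
]

#: region means for the five parameters: a well-perfused rim and a
#: hypoperfused core, magnitudes in the range tabulated for GL261 gliomas
#: (F_p a few tenths min^-1, PS a few hundredths min^-1, k_io of order 1 s^-1)
RIM_MEANS = {"ve": 0.15, "vp": 0.04, "Fp": 0.60, "PS": 0.060, "kio": 2.25}
CORE_MEANS = {"ve": 0.20, "vp": 0.015, "Fp": 0.12, "PS": 0.015, "kio": 0.75}


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth geometry, parameter distributions and noise/effect settings."""

    shape: tuple = (64, 64, 64)
    voxel_mm: float = 0.156
    tumor_center: tuple = (32.0, 32.0, 32.0)
    tumor_semiaxes_vox: tuple = (7.0, 6.0, 6.0)
    rim_inner_fraction: float = 0.7  # normalized radius where the rim shell starts
    rim_means: dict = field(default_factory=lambda: dict(RIM_MEANS))
    core_means: dict = field(default_factory=lambda: dict(CORE_MEANS))
    param_cv: float = 0.10
    # pre-contrast relaxation/equilibrium values
    t1_background_s: float = 1.6
    t1_tumor_s: float = 2.0
    t1_blood_s: float = 2.2
    m0: float = 1000.0
    n_vessel_voxels: int = 30
    # parametric AIF: gamma-variate bolus + recirculation washout
    aif_peak_mM: float = 4.0
    aif_peak_delay_s: float = 9.0
    aif_shape: float = 3.0
    aif_washout_mM: float = 0.8
    aif_recirc_rise_s: float = 15.0
    aif_washout_tau_s: tuple = (40.0, 350.0)
    aif_washout_weights: tuple = (0.5, 0.5)
    # noise
    snr: float = 100.0  # pre-contrast tumor signal over Rician sigma
    seed: int = 0
    # test-retest drift: multiplicative factors on the truth between scans
    # (volume fractions held fixed; flow, permeability and exchange drift,
    # mirroring the physiological pattern seen in vivo)
    drift: dict = field(default_factory=lambda: {"Fp": 1.4, "PS": 1.2, "kio": 1.2})
    # treatment effect: per-time-point multipliers for the treated group
    # (Pre-Tx, Tx-1, Tx-2); anti-angiogenic + cytotoxic combination halves
    # then roughly thirds k_io and shrinks the vascular fraction
    effect: dict = field(default_factory=lambda: {
        "kio": (1.0, 0.5, 0.35), "vp": (1.0, 0.85, 0.7)})
    growth: tuple = (1.0, 1.8, 3.0)  # tumor volume factors per time point
    between_animal_cv: float = 0.25
    measurement_cv: float = 0.20  # ROI-median estimation noise in the cohort model
    # SUV coupling: SUV = a + b * kio + N(0, sigma)
    suv_a: float = 0.4
    suv_b: float = 0.35
    suv_sigma: float = 0.15
    pet_fwhm_mm: float = 1.4
    pet_grid_mm: float = 1.4

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("SNR must be positive")


def _aif_curve_fn(spec: PhantomSpec, injection_s: float):
    """Continuous AIF as a function of time (s), zero before injection."""
    a = spec.aif_shape
    tp = spec.aif_peak_delay_s

    def fn(t):
        tt = np.asarray(t, dtype=float) - injection_s
        out = np.zeros_like(tt)
        pos = tt > 0
        x = tt[pos]
        bolus = spec.aif_peak_mM * (x / tp) ** a * np.exp(a * (1.0 - x / tp))
        w1, w2 = spec.aif_washout_weights
        t1, t2 = spec.aif_washout_tau_s
        wash = (spec.aif_washout_mM * (1.0 - np.exp(-x / spec.aif_recirc_rise_s))
                * (w1 * np.exp(-x / t1) + w2 * np.exp(-x / t2)))
        out[pos] = bolus + wash
        return out

    return fn


def make_aif(spec: PhantomSpec, schedule: AcquisitionSchedule) -> AIFCurve:
    """Sample the parametric plasma AIF on the frame grid.

    The bolus is a gamma-variate peaking ``aif_peak_delay_s`` after
    injection at ``aif_peak_mM``; a recirculation/washout term rises
    over ``aif_recirc_rise_s`` and decays biexponentially.
    """
    t = schedule.frame_times
    Ca = _aif_curve_fn(spec, schedule.injection_s)(t)
    Ca[t < schedule.injection_s] = 0.0
    return AIFCurve(t=t, Ca=Ca, injection_time=schedule.injection_s)


def aif_auc_analytic(spec: PhantomSpec) -> float:
    """Closed-form integral of the parametric AIF over (injection, inf), mM*s."""
    a = spec.aif_shape
    tp = spec.aif_peak_delay_s
    bolus = spec.aif_peak_mM * math.exp(a) * tp * math.gamma(a + 1.0) / a ** (a + 1.0)
    w1, w2 = spec.aif_washout_weights
    t1, t2 = spec.aif_washout_tau_s
    tr = spec.aif_recirc_rise_s
    wash = spec.aif_washout_mM * (
        w1 * (t1 - 1.0 / (1.0 / tr + 1.0 / t1))
        + w2 * (t2 - 1.0 / (1.0 / tr + 1.0 / t2))
    )
    return bolus + wash


def _ellipsoid_radius(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape, dtype=float)
    r2 = np.zeros(spec.shape)
    for ax in range(3):
        r2 += ((idx[ax] - spec.tumor_center[ax]) / spec.tumor_semiaxes_vox[ax]) ** 2
    return np.sqrt(r2)


def make_phantom(spec: PhantomSpec, seed: int | None = None) -> dict:
    """Ground-truth parameter maps, T1/M0 maps and masks.

    Returns a dict with 3D arrays ``ve, vp, Fp, PS, kio, T1, M0`` and
    boolean masks ``tumor, rim, core, vessel``.  Per-voxel parameters
    are drawn around the region means with coefficient of variation
    ``param_cv`` and truncated so that every voxel satisfies
    v_e + v_p < 0.95 and stays inside the fitting bounds.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    r = _ellipsoid_radius(spec)
    tumor = r <= 1.0
    core = r <= spec.rim_inner_fraction
    rim = tumor & ~core

    maps = {}
    for name in ("ve", "vp", "Fp", "PS", "kio"):
        m = np.zeros(spec.shape)
        for region, means in ((rim, spec.rim_means), (core, spec.core_means)):
            n = int(region.sum())
            vals = means[name] * (1.0 + spec.param_cv * rng.standard_normal(n))
            vals = np.clip(vals, 0.25 * means[name], 4.0 * means[name])
            m[region] = vals
        maps[name] = m
    # constructive truncation: v_e + v_p < 0.95 everywhere
    tot = maps["ve"] + maps["vp"]
    over = tot > 0.9
    for name in ("ve", "vp"):
        maps[name] = np.where(over, maps[name] * 0.9 / np.where(over, tot, 1.0), maps[name])

    # a short vessel segment away from the tumor supplies the AIF voxels
    vessel = np.zeros(spec.shape, dtype=bool)
    cx = int(spec.shape[0] * 0.15)
    cy = int(spec.shape[1] * 0.5)
    z0 = int(spec.shape[2] * 0.3)
    vessel[cx, cy, z0 : z0 + spec.n_vessel_voxels] = True

    T1 = np.full(spec.shape, spec.t1_background_s)
    T1[tumor] = spec.t1_tumor_s
    T1[vessel] = spec.t1_blood_s
    M0 = spec.m0 * (1.0 + 0.02 * rng.standard_normal(spec.shape))

    maps.update(T1=T1, M0=M0, tumor=tumor, rim=rim, core=core, vessel=vessel)
    return maps


def _rician(rng: np.random.Generator, S: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return S
    n1 = rng.standard_normal(S.shape)
    n2 = rng.standard_normal(S.shape)
    return np.sqrt((S + sigma * n1) ** 2 + (sigma * n2) ** 2)


def simulate_dce(
    phantom: dict,
    schedule: AcquisitionSchedule,
    ctx: RelaxationContext,
    spec: PhantomSpec,
    seed: int | None = None,
    aif: AIFCurve | None = None,
):
    """Forward-simulate the 4D dynamic volume plus VFA volumes.

    Tumor voxels run the full kinetics + three-pool signal model with
    their own ground-truth parameters; vessel voxels are pure blood
    (single-pool SPGR at R1 = 1/T1_blood + r1 C_a(t)); everything else
    does not enhance.  Rician noise is applied to the magnitude signal
    with sigma = (mean pre-contrast tumor signal)/SNR; SNR = inf
    reproduces the noiseless forward model bit for bit.

    Returns ``(dce 4D array (x,y,z,frame), vfa dict, aif, sigma)``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if aif is None:
        aif = make_aif(spec, schedule)
    angles, _ = schedule.frame_flip_angles()
    n_frames = schedule.n_frames
    shape = phantom["T1"].shape

    # non-enhancing signal per frame depends only on frame angle and voxel T1
    dce = np.empty(shape + (n_frames,), dtype=float)
    R1bg = 1.0 / phantom["T1"]
    for a in np.unique(angles):
        m = angles == a
        dce[..., m] = (spgr_signal(R1bg, a, schedule.tr_s, phantom["M0"]))[..., None]

    # vessel voxels: single-pool blood with the AIF
    vx = np.flatnonzero(phantom["vessel"].ravel())
    if vx.size:
        R1b = 1.0 / spec.t1_blood_s + ctx.r1 * aif.Ca  # (n_frames,)
        Sb = np.empty(n_frames)
        for a in np.unique(angles):
            m = angles == a
            Sb[m] = spgr_signal(R1b[m], a, schedule.tr_s, 1.0)
        flat = dce.reshape(-1, n_frames)
        M0flat = phantom["M0"].ravel()
        for i in vx:
            flat[i] = Sb * M0flat[i]

    # tumor voxels: full forward model
    tix = np.flatnonzero(phantom["tumor"].ravel())
    flat = dce.reshape(-1, n_frames)
    M0flat = phantom["M0"].ravel()
    T1flat = phantom["T1"].ravel()
    pmaps = {k: phantom[k].ravel() for k in ("ve", "vp", "Fp", "PS", "kio")}
    for i in tix:
        p = TissueParams(ve=pmaps["ve"][i], vp=pmaps["vp"][i], Fp=pmaps["Fp"][i],
                         PS=pmaps["PS"][i], kio=pmaps["kio"][i])
        vctx = ctx.with_(R10=1.0 / T1flat[i], M0=M0flat[i])
        flat[i] = predict_signal(p, aif, schedule, vctx, frame_angles=angles).S

    pre = schedule.pre_injection_frames()
    sigma = 0.0 if np.isinf(spec.snr) else float(
        dce[phantom["tumor"]][:, pre].mean() / spec.snr)
    dce = _rician(rng, dce, sigma)

    # VFA acquisition for T1 mapping (same noise level)
    vfa_angles = (8.0, 2.0, 12.0)
    vfa = np.empty(shape + (len(vfa_angles),))
    for j, a in enumerate(vfa_angles):
        vfa[..., j] = spgr_signal(R1bg, a, schedule.tr_s, phantom["M0"])
    vfa = _rician(rng, vfa, sigma)
    return dce, {"angles": vfa_angles, "volumes": vfa}, aif, sigma


def simulate_test_retest(
    spec: PhantomSpec,
    schedule: AcquisitionSchedule,
    ctx: RelaxationContext,
    seed: int | None = None,
    shift_voxels: tuple = (0.0, 0.0, 0.0),
    image_level: bool = True,
):
    """Paired scan/rescan datasets with physiological drift.

    The second scan's ground truth multiplies F_p, PS and k_io by the
    drift factors (volume fractions held fixed).  If ``shift_voxels``
    is nonzero the second scan's volumes are resampled under that known
    translation so registration can be exercised against ground truth.

    Returns a dict with ``scan1``/``scan2`` entries (phantom truths and,
    when ``image_level``, simulated DCE + VFA data) and the drift spec.
    """
    from .registration import RigidTransform, apply_rigid

    base_seed = spec.seed if seed is None else seed
    truth1 = make_phantom(spec, seed=base_seed)
    truth2 = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in truth1.items()}
    for name, factor in spec.drift.items():
        t = truth2[name].copy()
        t[truth2["tumor"]] *= factor
        truth2[name] = t

    out = {"drift": dict(spec.drift), "shift_voxels": tuple(shift_voxels),
           "scan1": {"truth": truth1}, "scan2": {"truth": truth2}}
    if image_level:
        dce1, vfa1, aif1, s1 = simulate_dce(truth1, schedule, ctx, spec, seed=base_seed + 1)
        dce2, vfa2, aif2, s2 = simulate_dce(truth2, schedule, ctx, spec, seed=base_seed + 2)
        if any(abs(s) > 0 for s in shift_voxels):
            tr = RigidTransform((0.0, 0.0, 0.0), tuple(shift_voxels))
            vol2 = {k: apply_rigid(truth2[k].astype(float), tr) for k in ("T1", "M0")}
            out["scan2"]["shifted_T1"] = vol2["T1"]
            out["scan2"]["shifted_M0"] = vol2["M0"]
        out["scan1"].update(dce=dce1, vfa=vfa1, aif=aif1, sigma=s1)
        out["scan2"].update(dce=dce2, vfa=vfa2, aif=aif2, sigma=s2)
    return out


TIMEPOINTS = ("Pre-Tx", "Tx-1", "Tx-2")


def simulate_cohorts(
    spec: PhantomSpec,
    seed: int | None = None,
    n_per_group: int = 5,
):
    """Control + treated longitudinal cohorts at the ROI-median level.

    Each animal draws a baseline parameter vector around the pooled
    tumor means (between-animal CV ``between_animal_cv``); the treated
    group's truth is multiplied by the per-time-point effect factors,
    the control group's only by 1.  Tumor volume grows by the same
    ``growth`` factors in both arms.  Measured medians add
    multiplicative lognormal estimation noise with CV
    ``measurement_cv`` — the dominant uncertainty at the whole-tumor
    median level once voxelwise fits are aggregated.

    Returns ``(measured, truth)`` long-form DataFrames with columns
    animal, group, timepoint, the five parameters and volume_uL.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = ("ve", "vp", "Fp", "PS", "kio")
    pooled = {k: 0.5 * (spec.rim_means[k] + spec.core_means[k]) for k in names}
    base_vol = (4.0 / 3.0) * math.pi * math.prod(spec.tumor_semiaxes_vox) \
        * spec.voxel_mm ** 3  # uL (mm^3)

    sig = math.sqrt(math.log(1.0 + spec.measurement_cv ** 2))
    rows_m, rows_t = [], []
    animal = 0
    for group in ("control", "treated"):
        for _ in range(n_per_group):
            animal += 1
            baseline = {k: pooled[k] * (1.0 + spec.between_animal_cv * rng.standard_normal())
                        for k in names}
            baseline = {k: max(v, 0.05 * pooled[k]) for k, v in baseline.items()}
            for j, tp in enumerate(TIMEPOINTS):
                truth = dict(baseline)
                if group == "treated":
                    for k, factors in spec.effect.items():
                        truth[k] = baseline[k] * factors[j]
                vol = base_vol * spec.growth[j]
                meas = {k: v * math.exp(sig * rng.standard_normal() - 0.5 * sig * sig)
                        for k, v in truth.items()}
                rows_t.append({"animal": f"m{animal:02d}", "group": group,
                               "timepoint": tp, **truth, "volume_uL": vol})
                rows_m.append({"animal": f"m{animal:02d}", "group": group,
                               "timepoint": tp, **meas, "volume_uL": vol})
    return pd.DataFrame(rows_m), pd.DataFrame(rows_t)


def simulate_suv(
    kio_map: np.ndarray,
    tumor_mask: np.ndarray,
    spec: PhantomSpec,
    seed: int | None = None,
):
    """SUV volume coupled to the k_io truth map, degraded to PET resolution.

    SUV_highres = a + b*k_io + N(0, sigma) inside the tumor (background
    a/2), then Gaussian blur at the PET point-spread FWHM and block
    averaging onto the coarser PET grid.  Returns ``(suv_pet,
    suv_highres)``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    hr = np.full(kio_map.shape, spec.suv_a / 2.0)
    hr[tumor_mask] = (spec.suv_a + spec.suv_b * kio_map[tumor_mask]
                      + spec.suv_sigma * rng.standard_normal(int(tumor_mask.sum())))
    sigma_vox = spec.pet_fwhm_mm / spec.voxel_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    blurred = ndimage.gaussian_filter(hr, sigma=sigma_vox, mode="nearest")
    f = max(1, int(round(spec.pet_grid_mm / spec.voxel_mm)))
    # crop (roughly centered) to a multiple of the block factor, then
    # block-average; the tumor sits deep inside, so only uniform
    # background border is discarded
    starts = [(s % f) // 2 for s in blurred.shape]
    ns = tuple(s // f for s in blurred.shape)
    cropped = blurred[
        starts[0] : starts[0] + ns[0] * f,
        starts[1] : starts[1] + ns[1] * f,
        starts[2] : starts[2] + ns[2] * f,
    ]
    pet = cropped.reshape(ns[0], f, ns[1], f, ns[2], f).mean(axis=(1, 3, 5))
    return pet, hr


def simulate_suv_cohort(spec: PhantomSpec, n_tumors: int = 7, seed: int | None = None):
    """Per-tumor k_io medians and mean SUV under the linear coupling.

    Emulates the DCE-then-PET experiment at the summary level: each
    tumor draws a k_io median around the pooled mean (between-animal
    CV) and its mean SUV is a + b*k_io + N(0, sigma).  Returns a
    DataFrame with columns ``kio`` and ``suv``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pooled = 0.5 * (spec.rim_means["kio"] + spec.core_means["kio"])
    kio = pooled * (1.0 + spec.between_animal_cv * rng.standard_normal(n_tumors))
    kio = np.clip(kio, 0.05 * pooled, None)
    suv_vals = spec.suv_a + spec.suv_b * kio + spec.suv_sigma * rng.standard_normal(n_tumors)
    return pd.DataFrame({"kio": kio, "suv": suv_vals})
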