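"""Synthetic osteochondral-plug phantoms with known ground truth.

This module generates every input the analysis stages consume, so the whole
pipeline can be exercised and validated without real μCT data:

* μCT attenuation volumes of a cylindrical cartilage layer on bone in air or
  fluid, with depthwise nanoparticle uptake following exponential saturation
  kinetics ``P(t) = Pmax [1 - exp(-t/tau)]``, optional surface tilt, optional
  surface lesions (scalpel cuts and v-cuts to a fraction of cartilage depth)
  and additive Gaussian attenuation noise;
* indentation records (stress-relaxation and sinusoidal loading) consistent
  with the inverse Hayes map used by :mod:`cectkit.biomechanics`, so every
  mechanical truth parameter round-trips exactly in the noiseless limit;
* digital-densitometry section and calibration-filter images;
* cohorts of samples whose proteoglycan content, stiffness and uptake
  parameters are coupled through a latent variable, for correlation testing.

The attenuation model is linear in partition: ``HU = hu_cartilage +
(bath_hu / 100) * P(%)``, the exact inverse of the pipeline's
division-by-bath partition definition.  Surface tilt is applied analytically
(the slab interface is a tilted plane evaluated at voxel centres, not a
resampled image), so the truth geometry is exact.  Noise is i.i.d. Gaussian
per voxel, drawn fresh per time point from seeds recorded in the truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import biomechanics as bm
from .diffusion_pipeline import DEPTH_GRID_PCT
from .volume_io import AttenuationVolume

__all__ = [
    "PhantomSpec",
    "UptakeTruth",
    "LesionSpec",
    "ViscoTruth",
    "CohortSpec",
    "StressRelaxationProtocol",
    "SinusoidProtocol",
    "generate_plug_volume",
    "generate_diffusion_series",
    "generate_stress_relaxation",
    "generate_sinusoid",
    "generate_cohort",
    "cohort_member_truths",
    "generate_od_section",
    "DEFAULT_TIMES_H",
    "DEFAULT_CALIBRATION_ODS",
]

#: Imaging schedule of the diffusion experiment (hours of immersion).
DEFAULT_TIMES_H = (0.0, 1.0, 3.0, 6.0, 10.0, 24.0, 48.0, 72.0)

#: Nominal optical densities of the densitometry calibration filter set.
DEFAULT_CALIBRATION_ODS = (0.0, 0.15, 0.3, 0.6, 1.3, 1.6, 2.0, 2.3, 2.6, 3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, attenuation palette and noise level of a plug phantom.

    Default HU palette (air −1000, fluid 0, cartilage 100, bone 2000) is a
    plausible μCT palette for a 150 kVp scan; all values are configurable.
    """

    plug_diameter_mm: float = 4.0
    cartilage_thickness_mm: float = 2.0
    bone_thickness_mm: float = 1.0
    voxel_size_um: float = 40.0
    surface_tilt_deg: tuple[float, float] = (0.0, 0.0)
    hu_air: float = -1000.0
    hu_fluid: float = 0.0
    hu_cartilage: float = 100.0
    hu_bone: float = 2000.0
    noise_sd_hu: float = 0.0
    seed: int = 0
    margin_plane_vox: int = 3
    margin_axial_vox: int = 6

    def __post_init__(self) -> None:
        if self.plug_diameter_mm <= 0:
            raise ValueError("plug_diameter_mm must be positive")
        if self.cartilage_thickness_mm <= 0:
            raise ValueError("cartilage_thickness_mm must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if not self.hu_bone > self.hu_cartilage > self.hu_air:
            raise ValueError("attenuation ordering hu_bone > hu_cartilage > hu_air violated")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


@dataclass
class UptakeTruth:
    """Ground-truth uptake kinetics of the contrast agent.

    ``bath_hu_gain`` is attenuation per unit partition (HU per %); the bath
    attenuation itself is ``100 * bath_hu_gain`` so that a 100 % partition
    matches the bath exactly.  ``depth_weight`` modulates Pmax over
    normalized depth (default: constant 1, i.e. depth-uniform uptake).
    """

    p_max_pct: float = 56.49
    tau_h: float = 62.85
    depth_weight: Callable[[np.ndarray], np.ndarray] | None = None
    bath_hu_gain: float = 12.0

    def __post_init__(self) -> None:
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        w = self.weight(np.linspace(0.0, 1.0, 101))
        if np.any(w < 0):
            raise ValueError("depth_weight must be non-negative on [0, 1]")

    @property
    def bath_hu(self) -> float:
        return 100.0 * self.bath_hu_gain

    def weight(self, depth_norm: np.ndarray) -> np.ndarray:
        if self.depth_weight is None:
            return np.ones_like(np.asarray(depth_norm, dtype=float))
        return np.asarray(self.depth_weight(depth_norm), dtype=float)

    def partition(self, depth_norm: np.ndarray, t_h: float) -> np.ndarray:
        """Partition (%) at normalized depth(s) after t_h hours of immersion."""
        sat = 1.0 - math.exp(-t_h / self.tau_h)
        return self.p_max_pct * self.weight(depth_norm) * sat


@dataclass(frozen=True)
class LesionSpec:
    """A surface lesion: a straight scalpel cut or a v-shaped groove.

    ``position_mm`` offsets the cut line from the plug centre (in-plane,
    perpendicular to the line); ``orientation_deg`` rotates the line in the
    x-y plane.  ``depth_fraction`` is the lesion depth as a fraction of
    cartilage thickness (2/3 by default, as cut by scalpel to two-thirds
    depth).  A sharp cut keeps its width down to full lesion depth; a v-cut
    narrows linearly from ``width_at_surface_mm`` to zero.
    """

    kind: str = "sharp_cut"
    width_at_surface_mm: float = 0.1
    depth_fraction: float = 2.0 / 3.0
    position_mm: float = 0.0
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("sharp_cut", "v_cut"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not 0.0 < self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must be in (0, 1]")
        if self.width_at_surface_mm <= 0:
            raise ValueError("width_at_surface_mm must be positive")


def generate_plug_volume(
    spec: PhantomSpec,
    uptake: UptakeTruth,
    t_h: float,
    lesions: Sequence[LesionSpec] = (),
    medium: str = "air",
    lesion_fill_hu: float | None = None,
) -> tuple[AttenuationVolume, dict]:
    """Voxelize one plug at immersion time ``t_h``; returns (volume, truth).

    The truth record carries the exact noiseless depthwise partition profile
    on the standard 100-point grid, the bulk partition, the label volume
    (0 background, 1 cartilage, 2 bone; lesion voxels are background) and the
    geometry/seed bookkeeping needed to reproduce the volume.
    """
    if t_h < 0:
        raise ValueError("immersion time must be non-negative")
    if medium not in ("air", "fluid"):
        raise ValueError("medium must be 'air' or 'fluid'")
    vox = spec.voxel_size_mm
    radius = spec.plug_diameter_mm / 2.0 / vox
    thick = spec.cartilage_thickness_mm / vox
    bone = spec.bone_thickness_mm / vox
    if thick < 3:
        raise ValueError("cartilage thinner than 3 voxels; depth profile undefined")
    for les in lesions:
        if les.width_at_surface_mm >= spec.plug_diameter_mm:
            raise ValueError("lesion wider than the plug")

    tan_x = math.tan(math.radians(spec.surface_tilt_deg[0]))
    tan_y = math.tan(math.radians(spec.surface_tilt_deg[1]))
    tilt_span = radius * (abs(tan_x) + abs(tan_y))
    nx = ny = int(math.ceil(2 * radius)) + 2 * spec.margin_plane_vox
    # the articular surface sits half a voxel above the first cartilage voxel
    # centre (the generic registration of a plane in a voxel grid)
    z0 = spec.margin_axial_vox + tilt_span + 0.5
    nz = int(math.ceil(z0 + thick + bone + spec.margin_axial_vox + tilt_span))

    zz = np.arange(nz, dtype=float)[:, None, None]
    yy = np.arange(ny, dtype=float)[None, :, None]
    xx = np.arange(nx, dtype=float)[None, None, :]
    yc, xc = (ny - 1) / 2.0, (nx - 1) / 2.0
    in_plug = (xx - xc) ** 2 + (yy - yc) ** 2 <= radius**2
    z_surface = z0 + tan_x * (xx - xc) + tan_y * (yy - yc)
    depth = zz - z_surface  # voxels below the (tilted) articular surface
    cart = in_plug & (depth >= 0) & (depth < thick)
    bone_mask = in_plug & (depth >= thick) & (depth < thick + bone)

    background = spec.hu_air if medium == "air" else spec.hu_fluid
    values = np.full((nz, ny, nx), background, dtype=float)
    depth_norm = np.clip(depth / thick, 0.0, 1.0)
    hu_cart = spec.hu_cartilage + uptake.bath_hu_gain * uptake.partition(depth_norm, t_h)
    values[cart] = np.broadcast_to(hu_cart, values.shape)[cart]
    values[bone_mask] = spec.hu_bone

    lesion_mask = np.zeros_like(cart)
    fill = spec.hu_fluid if lesion_fill_hu is None else lesion_fill_hu
    for les in lesions:
        phi = math.radians(les.orientation_deg)
        # signed in-plane distance from the cut line (line direction phi)
        s = -math.sin(phi) * (xx - xc) + math.cos(phi) * (yy - yc) - les.position_mm / vox
        les_depth = les.depth_fraction * thick
        half = les.width_at_surface_mm / 2.0 / vox
        if les.kind == "v_cut":
            halfwidth = half * (1.0 - np.clip(depth, 0.0, les_depth) / les_depth)
        else:
            halfwidth = half
        this = in_plug & (depth >= 0) & (depth < les_depth) & (np.abs(s) <= halfwidth)
        lesion_mask |= this
    values[lesion_mask] = fill
    cart_labels = cart & ~lesion_mask
    bone_labels = bone_mask & ~lesion_mask

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        values = values + rng.normal(0.0, spec.noise_sd_hu, size=values.shape)

    labels = np.zeros(values.shape, dtype=np.uint8)
    labels[cart_labels] = 1
    labels[bone_labels] = 2
    profile = uptake.partition(DEPTH_GRID_PCT / 100.0, t_h)
    truth = {
        "time_h": float(t_h),
        "partition_profile_pct": profile,
        "bulk_partition_pct": float(profile.mean()),
        "labels": labels,
        "lesion_mask": lesion_mask,
        "surface_z0_vox": z0,
        "tilt_deg": spec.surface_tilt_deg,
        "bath_hu": uptake.bath_hu,
        "seed": spec.seed,
        "noise_sd_hu": spec.noise_sd_hu,
    }
    meta = {
        "time_h": float(t_h),
        "bath_hu": uptake.bath_hu,
        "seed": int(spec.seed),
        "medium": medium,
    }
    return AttenuationVolume(values, spec.voxel_size_um, meta), truth


def generate_diffusion_series(
    spec: PhantomSpec,
    uptake: UptakeTruth,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
    lesions: Sequence[LesionSpec] = (),
    medium: str = "air",
) -> tuple[list[AttenuationVolume], list[dict]]:
    """One volume per immersion time point, identical geometry, fresh noise.

    The per-time-point noise seeds are spawned deterministically from
    ``spec.seed`` and recorded in each truth record.
    """
    times = np.asarray(times_h, dtype=float)
    if times.size == 0 or times[0] != 0.0:
        raise ValueError("times must start at 0 h (the native-attenuation baseline)")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    children = np.random.SeedSequence(spec.seed).spawn(times.size)
    volumes, truths = [], []
    for t, child in zip(times, children):
        seed_t = int(child.generate_state(1)[0] % (2**31))
        vol, truth = generate_plug_volume(
            replace(spec, seed=seed_t), uptake, float(t), lesions=lesions, medium=medium
        )
        volumes.append(vol)
        truths.append(truth)
    return volumes, truths


# ---------------------------------------------------------------------------
# indentation records


@dataclass
class ViscoTruth:
    """Ground-truth viscoelastic parameters of a synthetic sample.

    ``alpha_s``/``beta`` parameterize the stretched-exponential hold decay;
    the 600 s holds are ten relaxation times long at the defaults, so the
    final-window equilibrium read-out is unbiased.  ``eta_over_k_s`` is the
    loss ratio of the sinusoidal response (phase shift =
    ``arctan(2 pi f eta/k)``); the default gives a ~17° phase at 1 Hz,
    typical of articular cartilage.
    """

    e_eq_mpa: float = 0.5
    e_inst0_mpa: float = 5.0
    e_inst_slope_mpa: float = 10.0
    alpha_s: float = 60.0
    beta: float = 0.8
    eta_over_k_s: float = 0.05

    def __post_init__(self) -> None:
        if self.e_eq_mpa <= 0:
            raise ValueError("e_eq_mpa must be positive")
        if self.alpha_s <= 0:
            raise ValueError("alpha_s must be positive")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class StressRelaxationProtocol:
    n_steps: int = 4
    step_strain: float = 0.04  # of the thickness remaining at each step
    ramp_rate_per_s: float = 1.0  # 100 %/s
    hold_s: float = 600.0
    baseline_s: float = 2.0
    fs_ramp_hz: float = 2000.0
    fs_hold_hz: float = 5.0


@dataclass(frozen=True)
class SinusoidProtocol:
    n_cycles: int = 4
    freq_hz: float = 1.0
    fs_hz: float = 500.0
    peak_to_peak_strain: float = 0.04

    def __post_init__(self) -> None:
        if self.n_cycles < 2:
            raise ValueError("at least 2 cycles are required")
        if self.fs_hz < 100.0:
            raise ValueError("sample rate must be at least 100 Hz")


def _inverse_hayes_force_mn(
    stress_kpa: float, geometry: bm.IndentationGeometry, nu: float
) -> float:
    """Force producing a given Hayes-corrected stress (inverse of the analysis map)."""
    unit = bm.hayes_stress_kpa(1.0, geometry, nu)
    return stress_kpa / unit


def generate_stress_relaxation(
    truth: ViscoTruth,
    geometry: bm.IndentationGeometry,
    protocol: StressRelaxationProtocol = StressRelaxationProtocol(),
    noise_sd_mn: float = 0.0,
    seed: int = 0,
) -> tuple[bm.IndentationRecord, dict]:
    """Synthesize a stress-relaxation force record from viscoelastic truth.

    Within each hold the force follows
    ``F_eq(eps) + dF(eps) * exp[-(t/alpha)^beta]``; equilibrium forces are
    consistent with ``e_eq`` and ramp-end peaks with ``Einst(eps)`` through
    the exact inverse of the Hayes maps applied by the analysis, so the
    analysis round-trips every parameter in the noiseless limit.
    """
    p = protocol
    strains = truth_strains = p.step_strain * np.arange(1, p.n_steps + 1)
    e_inst = truth.e_inst0_mpa + truth.e_inst_slope_mpa * strains
    f_eq = np.array(
        [
            _inverse_hayes_force_mn(truth.e_eq_mpa * 1000.0 * eps, geometry, geometry.poisson_eq)
            for eps in strains
        ]
    )
    f_peak = np.empty(p.n_steps)
    prev = 0.0
    for i in range(p.n_steps):
        d_stress = e_inst[i] * 1000.0 * p.step_strain
        f_peak[i] = prev + _inverse_hayes_force_mn(d_stress, geometry, geometry.poisson_dyn)
        prev = f_eq[i]

    f_pre = geometry.prestress_kpa * math.pi * geometry.indenter_radius_mm**2
    ramp_dur = p.step_strain / p.ramp_rate_per_s
    h0_um = geometry.cartilage_thickness_mm * 1000.0

    times, disp, force, steps = [], [], [], []
    t_base = np.arange(0.0, p.baseline_s, 1.0 / p.fs_hold_hz)
    times.append(t_base)
    disp.append(np.zeros_like(t_base))
    force.append(np.full_like(t_base, f_pre))
    t_cursor = p.baseline_s
    u_prev = 0.0
    f_prev_end = 0.0  # force (above prestress) at the end of the previous segment
    for i in range(p.n_steps):
        step_disp = p.step_strain * (h0_um - u_prev)
        n_ramp = int(round(ramp_dur * p.fs_ramp_hz))
        t_ramp = t_cursor + np.arange(1, n_ramp + 1) / p.fs_ramp_hz
        frac = np.arange(1, n_ramp + 1) / n_ramp
        i_ramp0 = sum(len(a) for a in times[:-1]) + len(times[-1])
        times.append(t_ramp)
        disp.append(u_prev + frac * step_disp)
        force.append(f_pre + f_prev_end + frac * (f_peak[i] - f_prev_end))
        t_cursor = t_ramp[-1]
        u_prev = u_prev + step_disp

        n_hold = int(round(p.hold_s * p.fs_hold_hz))
        t_hold = t_cursor + np.arange(1, n_hold + 1) / p.fs_hold_hz
        th = t_hold - t_cursor
        decay = np.exp(-((th / truth.alpha_s) ** truth.beta))
        i_hold0 = i_ramp0 + n_ramp
        times.append(t_hold)
        disp.append(np.full_like(t_hold, u_prev))
        force.append(f_pre + f_eq[i] + (f_peak[i] - f_eq[i]) * decay)
        t_cursor = t_hold[-1]
        f_prev_end = f_eq[i] + (f_peak[i] - f_eq[i]) * decay[-1]
        steps.append((i_ramp0, i_hold0, i_hold0 + n_hold))

    time_s = np.concatenate(times)
    force_mn = np.concatenate(force)
    if noise_sd_mn > 0:
        force_mn = force_mn + np.random.default_rng(seed).normal(0, noise_sd_mn, force_mn.shape)
    record = bm.IndentationRecord(
        time_s=time_s,
        displacement_um=np.concatenate(disp),
        force_mn=force_mn,
        protocol="stress_relaxation",
        steps=steps,
    )
    summary = {
        "e_eq_mpa": truth.e_eq_mpa,
        "e_inst_mpa": e_inst,
        "e_inst_intercept_mpa": truth.e_inst0_mpa,
        "e_inst_slope_mpa": truth.e_inst_slope_mpa,
        "alpha_s": truth.alpha_s,
        "beta": truth.beta,
        "strains": truth_strains,
        "f_eq_mn": f_eq,
        "f_peak_mn": f_peak,
    }
    return record, summary


def generate_sinusoid(
    truth: ViscoTruth,
    geometry: bm.IndentationGeometry,
    protocol: SinusoidProtocol = SinusoidProtocol(),
    noise_sd_mn: float = 0.0,
    seed: int = 0,
) -> tuple[bm.IndentationRecord, dict]:
    """Synthesize a sinusoidal loading record (Kelvin–Voigt-like response).

    Displacement is a sinusoid of 4 % peak-to-peak strain; the force leads it
    by ``delta = arctan(2 pi f eta/k)`` with in-phase modulus ``e_inst0`` and
    dynamic modulus ``e_inst0 sqrt(1 + (2 pi f eta/k)^2)``.
    """
    p = protocol
    omega = 2.0 * math.pi * p.freq_hz
    delta_rad = math.atan(omega * truth.eta_over_k_s)
    e_dyn = truth.e_inst0_mpa * math.sqrt(1.0 + (omega * truth.eta_over_k_s) ** 2)
    h_um = geometry.cartilage_thickness_mm * 1000.0
    w_amp = p.peak_to_peak_strain / 2.0 * h_um
    strain_amp = w_amp / h_um
    f_amp = _inverse_hayes_force_mn(e_dyn * 1000.0 * strain_amp, geometry, geometry.poisson_dyn)
    f_pre = geometry.prestress_kpa * math.pi * geometry.indenter_radius_mm**2

    t = np.arange(0.0, p.n_cycles / p.freq_hz, 1.0 / p.fs_hz)
    disp = w_amp + w_amp * np.sin(omega * t)
    force = f_pre + f_amp * np.sin(omega * t + delta_rad)
    if noise_sd_mn > 0:
        force = force + np.random.default_rng(seed).normal(0, noise_sd_mn, force.shape)
    record = bm.IndentationRecord(
        time_s=t,
        displacement_um=disp,
        force_mn=force,
        protocol="sinusoid",
        meta={"freq_hz": p.freq_hz},
    )
    return record, {
        "dynamic_modulus_mpa": e_dyn,
        "phase_shift_deg": math.degrees(delta_rad),
    }


# ---------------------------------------------------------------------------
# cohorts


def _default_couplings() -> dict:
    # intercept + slope * latent_pg; slopes tuned to emulate the magnitude of
    # the reported structure-function correlations (|rho| ~ 0.4-0.65 at n=27)
    return {
        "pg_od_superficial": (0.0, 1.0),
        "pg_od_bulk": (0.1, 0.75),
        "e_eq_mpa": (0.2, 0.25),
        "p_max_pct": (18.0, 32.0),
        "tau_h": (-9.0, 60.0),
        "phase_shift_deg": (19.2, -6.0),
    }


def _default_noise_sd() -> dict:
    return {
        "pg_od_superficial": 0.15,
        "pg_od_bulk": 0.12,
        "e_eq_mpa": 0.12,
        "p_max_pct": 7.0,
        "tau_h": 14.0,
        "phase_shift_deg": 1.3,
    }


@dataclass
class CohortSpec:
    """A cohort whose per-sample parameters share a latent proteoglycan level.

    ``couplings[var] = (intercept, slope)`` maps the latent PG optical
    density to each induced variable; ``noise_sd[var]`` adds independent
    Gaussian scatter.  Default signs: higher PG raises Pmax, tau and Eeq and
    lowers the phase shift.
    """

    n_samples: int = 27
    pg_mean: float = 1.2
    pg_sd: float = 0.25
    couplings: dict = field(default_factory=_default_couplings)
    noise_sd: dict = field(default_factory=_default_noise_sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("a cohort needs at least 3 samples")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Truth table: one row per sample, latent PG plus induced parameters."""
    rng = np.random.default_rng(spec.seed)
    latent = rng.normal(spec.pg_mean, spec.pg_sd, spec.n_samples)
    data = {"sample_id": [f"S{i:02d}" for i in range(spec.n_samples)], "latent_pg": latent}
    for var, (icpt, slope) in spec.couplings.items():
        sd = spec.noise_sd.get(var, 0.0)
        noise = rng.normal(0.0, sd, spec.n_samples) if sd > 0 else 0.0
        data[var] = icpt + slope * latent + noise
    df = pd.DataFrame(data)
    if "e_eq_mpa" in df:
        df["e_eq_mpa"] = df["e_eq_mpa"].clip(lower=0.05)
    if "tau_h" in df:
        df["tau_h"] = df["tau_h"].clip(lower=1.0)
    if "phase_shift_deg" in df:
        df["phase_shift_deg"] = df["phase_shift_deg"].clip(lower=0.5, upper=85.0)
    return df


def cohort_member_truths(row: pd.Series, freq_hz: float = 1.0) -> tuple[UptakeTruth, ViscoTruth]:
    """Materialize the per-sample generator truths from one cohort row."""
    uptake = UptakeTruth(p_max_pct=float(row["p_max_pct"]), tau_h=float(row["tau_h"]))
    eta_over_k = math.tan(math.radians(float(row["phase_shift_deg"]))) / (2 * math.pi * freq_hz)
    visco = ViscoTruth(e_eq_mpa=float(row["e_eq_mpa"]), eta_over_k_s=eta_over_k)
    return uptake, visco


# ---------------------------------------------------------------------------
# densitometry sections


def generate_od_section(
    od_truth: Callable[[np.ndarray], np.ndarray],
    calibration_ods: Sequence[float] = DEFAULT_CALIBRATION_ODS,
    image_shape: tuple[int, int] = (120, 60),
    gray_intercept: float = 250.0,
    gray_slope: float = -70.0,
    noise_sd: float = 0.0,
    n_sections: int = 3,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray], dict]:
    """Section images (surface at the top row) plus calibration-filter images.

    ``od_truth`` maps normalized depth in [0, 1] to optical density.  Gray
    values follow the linear camera model ``gray = intercept + slope * OD``
    (slope negative: denser stain transmits less light).  Returns
    (sections, filter_images, truth).
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = image_shape
    depths = (np.arange(n_rows) + 0.5) / n_rows
    od_col = np.asarray(od_truth(depths), dtype=float)
    ods = np.asarray(calibration_ods, dtype=float)
    if od_col.min() < ods.min() - 1e-12 or od_col.max() > ods.max() + 1e-12:
        warnings.warn(
            "truth OD outside the calibration range; profile values will be extrapolated",
            stacklevel=2,
        )
    sections = []
    for _ in range(n_sections):
        img = gray_intercept + gray_slope * od_col[:, None] * np.ones((1, n_cols))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        sections.append(img)
    filters = []
    for od in ods:
        img = np.full((32, 32), gray_intercept + gray_slope * od)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        filters.append(img)
    truth = {
        "od_profile": od_col,
        "depths_norm": depths,
        "gray_intercept": gray_intercept,
        "gray_slope": gray_slope,
        "calibration_ods": ods,
    }
    return sections, filters, truth
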