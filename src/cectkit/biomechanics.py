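"""Functional parameters from indentation testing of osteochondral plugs.

The testing protocol has two parts, both in indentation geometry with a
plane-ended cylindrical indenter (d = 0.55 mm) after a 40 kPa prestress:

* stress-relaxation — four steps, each 4 % of the remaining cartilage
  thickness, applied at a 100 %/s ramp and held for 600 s.  Steps 2–4 yield
  the equilibrium modulus ``Eeq`` (ν = 0.2), the strain-dependent
  instantaneous modulus ``Einst`` (ν = 0.5), and the stretched-exponential
  relaxation parameters ``alpha`` (time constant) and ``beta`` (stretching
  exponent);
* sinusoidal loading — four cycles at 1 Hz with 4 % peak-to-peak strain,
  yielding the dynamic modulus and the force–displacement phase shift
  (ν = 0.5).

All moduli are Hayes-corrected for the finite bonded layer; see
:mod:`cectkit.hayes`.  Units: time s, displacement μm, force mN, stress kPa
(mN/mm²), moduli MPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .hayes import hayes_kappa

__all__ = [
    "IndentationGeometry",
    "IndentationRecord",
    "MechanicalSummary",
    "hayes_kappa",
    "hayes_stress_kpa",
    "equilibrium_modulus",
    "instantaneous_modulus",
    "relaxation_fit",
    "relaxation_summary",
    "dynamic_analysis",
    "summarize",
]


@dataclass(frozen=True)
class IndentationGeometry:
    """Indenter/sample geometry and the Poisson's ratios used per protocol."""

    cartilage_thickness_mm: float
    indenter_diameter_mm: float = 0.55
    poisson_eq: float = 0.2
    poisson_dyn: float = 0.5
    prestress_kpa: float = 40.0

    def __post_init__(self) -> None:
        if self.cartilage_thickness_mm <= 0:
            raise ValueError("cartilage_thickness_mm must be positive")
        if self.indenter_diameter_mm <= 0:
            raise ValueError("indenter_diameter_mm must be positive")

    @property
    def indenter_radius_mm(self) -> float:
        return self.indenter_diameter_mm / 2.0


@dataclass
class IndentationRecord:
    """A force–displacement–time record from one protocol run.

    ``steps`` holds, per loading step, the sample indices
    ``(ramp_start, hold_start, end)`` into the arrays; for sinusoidal
    records it is empty and ``meta`` carries the frequency.
    """

    time_s: np.ndarray
    displacement_um: np.ndarray
    force_mn: np.ndarray
    protocol: str
    steps: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        self.force_mn = np.asarray(self.force_mn, dtype=float)
        n = self.time_s.size
        if self.displacement_um.size != n or self.force_mn.size != n:
            raise ValueError("time, displacement and force arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class MechanicalSummary:
    e_eq_mpa: float
    e_inst_mpa: np.ndarray
    e_inst_intercept_mpa: float
    e_inst_slope_mpa: float
    alpha_s: float
    beta: float
    dynamic_modulus_mpa: float
    phase_shift_deg: float
    flags: dict = field(default_factory=dict)


def hayes_stress_kpa(
    force_mn: np.ndarray | float, geometry: IndentationGeometry, nu: float
) -> np.ndarray | float:
    """Hayes-corrected indentation stress (kPa) for a given load (mN).

    Defined so that modulus = stress / strain with strain = w / h reproduces
    the Hayes relation E = P (1 - nu^2) / (2 a kappa w).
    """
    a = geometry.indenter_radius_mm
    h = geometry.cartilage_thickness_mm
    kappa = hayes_kappa(a / h, nu)
    return force_mn * (1.0 - nu**2) / (2.0 * a * kappa * h)


def _baseline_force(record: IndentationRecord) -> float:
    """Prestress force offset: mean force before the first ramp."""
    if record.steps:
        i0 = record.steps[0][0]
        if i0 > 0:
            return float(np.mean(record.force_mn[:i0]))
    return float(record.force_mn[0])


def _step_equilibrium_forces(
    record: IndentationRecord, window_s: float = 5.0
) -> np.ndarray:
    """Per-step equilibrium force: mean of the final ``window_s`` of each hold."""
    out = []
    for _, hold_start, end in record.steps:
        t = record.time_s[hold_start:end]
        f = record.force_mn[hold_start:end]
        sel = t >= t[-1] - window_s
        out.append(float(np.mean(f[sel])))
    return np.asarray(out)


def _cumulative_strains(n_steps: int, step_strain: float = 0.04) -> np.ndarray:
    """Applied strain after each step; each step is ``step_strain`` of the
    thickness remaining at its start, so defined strains add."""
    return step_strain * np.arange(1, n_steps + 1)


def equilibrium_modulus(
    record: IndentationRecord,
    geometry: IndentationGeometry,
    window_s: float = 5.0,
    relaxed_drift_tol: float = 0.02,
) -> tuple[float, dict]:
    """Equilibrium modulus Eeq (MPa) from steps 2-4 of a stress-relaxation run.

    Per-step equilibrium force = mean of the final ``window_s`` seconds of the
    600 s hold; Hayes-corrected equilibrium stress (ν = 0.2) is regressed on
    applied strain over steps 2-4.
    """
    if record.protocol != "stress_relaxation":
        raise ValueError("equilibrium_modulus requires a stress-relaxation record")
    if len(record.steps) < 4:
        raise ValueError("stress-relaxation record must contain at least 4 steps")
    flags: dict = {}
    base = _baseline_force(record)
    f_eq = _step_equilibrium_forces(record, window_s) - base
    # unrelaxed-hold check: force drift over the final 60 s relative to the
    # equilibrium force must stay below relaxed_drift_tol
    for k, (_, hold_start, end) in enumerate(record.steps):
        t = record.time_s[hold_start:end]
        f = record.force_mn[hold_start:end]
        sel = t >= t[-1] - 60.0
        slope = linregress(t[sel], f[sel]).slope
        drift = abs(slope) * 60.0
        if f_eq[k] != 0 and drift / abs(f_eq[k]) > relaxed_drift_tol:
            flags[f"unrelaxed_step_{k + 1}"] = float(drift / abs(f_eq[k]))
    stress = hayes_stress_kpa(f_eq, geometry, geometry.poisson_eq)
    strain = _cumulative_strains(len(record.steps))
    res = linregress(strain[1:4], stress[1:4])
    e_eq = res.slope / 1000.0  # kPa -> MPa
    if e_eq <= 0:
        flags["non_physical_eeq"] = float(e_eq)
    return float(e_eq), {
        "flags": flags,
        "equilibrium_stress_kpa": stress,
        "strain": strain,
        "intercept_kpa": res.intercept,
    }


def instantaneous_modulus(
    record: IndentationRecord, geometry: IndentationGeometry, step_strain: float = 0.04
) -> tuple[np.ndarray, float, float, dict]:
    """Per-step instantaneous modulus Einst (MPa) and its strain dependence.

    Einst at step i = incremental Hayes stress (ν = 0.5) between the ramp-end
    peak and the preceding equilibrium, divided by the step strain; the
    strain dependence is the least-squares line of Einst against applied
    strain over steps 2-4.  Returns (per-step Einst, intercept, slope, info).
    """
    if record.protocol != "stress_relaxation":
        raise ValueError("instantaneous_modulus requires a stress-relaxation record")
    base = _baseline_force(record)
    f_eq_prev = 0.0
    e_inst = []
    for ramp_start, hold_start, end in record.steps:
        if hold_start - ramp_start < 2:
            raise ValueError("ramp shorter than 2 samples; cannot locate the peak force")
        f_peak = float(np.max(record.force_mn[ramp_start : hold_start + 1])) - base
        d_stress = hayes_stress_kpa(f_peak - f_eq_prev, geometry, geometry.poisson_dyn)
        e_inst.append(d_stress / step_strain / 1000.0)  # MPa
        t = record.time_s[hold_start:end]
        f = record.force_mn[hold_start:end]
        f_eq_prev = float(np.mean(f[t >= t[-1] - 5.0])) - base
    e_inst = np.asarray(e_inst)
    strain = _cumulative_strains(len(record.steps), step_strain)
    res = linregress(strain[1:4], e_inst[1:4])
    return e_inst, float(res.intercept), float(res.slope), {"strain": strain}


def relaxation_fit(
    time_s: np.ndarray, force_mn: np.ndarray
) -> tuple[float, float, dict]:
    """Fit a stretched exponential to one hold-phase force trace.

    Model: ``F(t) = F_eq + (F_peak - F_eq) exp[-(t/alpha)^beta]`` with
    ``F_eq`` free, ``alpha > 0`` and ``beta`` in (0, 1]; ``t`` is measured
    from the start of the hold.  Returns (alpha, beta, info).
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(force_mn, dtype=float)
    if t.size < 100:
        raise ValueError("hold trace must contain at least 100 samples")
    t = t - t[0]

    def model(tt, f_eq, df, alpha, beta):
        return f_eq + df * np.exp(-((tt / alpha) ** beta))

    f_eq0 = f[-1]
    df0 = f[0] - f[-1]
    # initial alpha: time at which the decay has lost 1-1/e of its range
    target = f_eq0 + df0 / np.e
    below = np.nonzero((f - target) * np.sign(df0) <= 0)[0]
    alpha0 = t[below[0]] if below.size and below[0] > 0 else t[-1] / 3.0
    alpha0 = max(alpha0, t[1])
    p0 = [f_eq0, df0, alpha0, 0.8]
    bounds = ([-np.inf, -np.inf, 1e-9, 1e-6], [np.inf, np.inf, np.inf, 1.0])
    popt, _ = curve_fit(model, t, f, p0=p0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    f_eq, df, alpha, beta = popt
    info = {"f_eq_mn": float(f_eq), "delta_f_mn": float(df)}
    if beta >= 1.0 - 1e-9 or beta <= 1e-6 + 1e-9:
        info["beta_at_bound"] = float(beta)
    return float(alpha), float(beta), info


def relaxation_summary(record: IndentationRecord) -> tuple[float, float, dict]:
    """Stretched-exponential (alpha, beta), averaged over steps 2-4."""
    alphas, betas, infos = [], [], []
    for ramp_start, hold_start, end in record.steps[1:4]:
        # the decay clock starts at the ramp-end peak, so include that sample
        i0 = max(hold_start - 1, ramp_start)
        a, b, info = relaxation_fit(record.time_s[i0:end], record.force_mn[i0:end])
        alphas.append(a)
        betas.append(b)
        infos.append(info)
    return float(np.mean(alphas)), float(np.mean(betas)), {"per_step": infos}


def _sine_regression(t: np.ndarray, x: np.ndarray, freq_hz: float) -> tuple[float, float]:
    """Amplitude and phase (deg) of x(t) ~ c0 + A sin(2 pi f t + phi)."""
    w = 2.0 * np.pi * freq_hz
    design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    amp = float(np.hypot(coef[1], coef[2]))
    phase = float(np.degrees(np.arctan2(coef[2], coef[1])))
    return amp, phase


def dynamic_analysis(
    record: IndentationRecord,
    geometry: IndentationGeometry,
    freq_hz: float = 1.0,
    n_cycles_used: int = 3,
) -> tuple[float, float]:
    """Dynamic modulus (MPa) and phase shift (deg) from a sinusoidal record.

    Force and displacement amplitudes/phases are estimated by least-squares
    sinusoid regression at the known drive frequency (leakage-free on short
    records, unlike FFT peak-picking), over the last ``n_cycles_used``
    cycles.  Phase shift = force phase - displacement phase, wrapped to
    [0°, 90°); dynamic modulus = Hayes-corrected (ν = 0.5) stress amplitude
    over strain amplitude.
    """
    if record.protocol != "sinusoid":
        raise ValueError("dynamic_analysis requires a sinusoidal record")
    t = record.time_s
    span = t[-1] - t[0]
    if span * freq_hz < 2.0:
        raise ValueError("record must contain at least 2 full cycles")
    if t.size / (span * freq_hz) < 50.0:
        raise ValueError("sample rate below 50 samples per cycle")
    sel = t >= t[-1] - n_cycles_used / freq_hz
    amp_w, ph_w = _sine_regression(t[sel], record.displacement_um[sel], freq_hz)
    amp_f, ph_f = _sine_regression(t[sel], record.force_mn[sel], freq_hz)
    if amp_w <= 0 or amp_f <= 0:
        raise ValueError("non-positive sinusoid amplitude")
    delta = (ph_f - ph_w + 180.0) % 360.0 - 180.0
    if -0.5 < delta < 0.0:  # numerical jitter around the elastic limit
        delta = abs(delta)
    strain_amp = amp_w / (geometry.cartilage_thickness_mm * 1000.0)
    stress_amp = hayes_stress_kpa(amp_f, geometry, geometry.poisson_dyn)
    e_dyn = stress_amp / strain_amp / 1000.0  # MPa
    if not 0.0 <= delta < 90.0:
        warnings.warn(f"phase shift {delta:.2f} deg outside [0, 90)", stacklevel=2)
    return float(e_dyn), float(delta)


def summarize(
    relax_record: IndentationRecord,
    sinus_record: IndentationRecord,
    geometry: IndentationGeometry,
) -> MechanicalSummary:
    """Full mechanical characterisation of one sample from its two records."""
    e_eq, eq_info = equilibrium_modulus(relax_record, geometry)
    e_inst, icpt, slope, _ = instantaneous_modulus(relax_record, geometry)
    alpha, beta, _ = relaxation_summary(relax_record)
    e_dyn, phase = dynamic_analysis(
        sinus_record, geometry, freq_hz=sinus_record.meta.get("freq_hz", 1.0)
    )
    return MechanicalSummary(
        e_eq_mpa=e_eq,
        e_inst_mpa=e_inst,
        e_inst_intercept_mpa=icpt,
        e_inst_slope_mpa=slope,
        alpha_s=alpha,
        beta=beta,
        dynamic_modulus_mpa=e_dyn,
        phase_shift_deg=phase,
        flags=eq_info["flags"],
    )
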