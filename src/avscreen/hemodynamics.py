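"""Dimensionless hemodynamic quantitation of multi-site Doppler velocimetry.

An arteriovenous (AV) access is probed with pulsed Doppler ultrasound at three
sites along the direction of flow — the arterial anastomosis (A), the loop (L)
and the venous anastomosis (V).  From each site's peak-systolic velocity
``V_p``, peak-diastolic velocity ``V_m``, heart rate and hydraulic diameter,
this module computes

* the Reynolds number ``Re = rho * V * D_H / mu`` (inertial/viscous forces),
* the Womersley number ``alpha = (D_H / 2) * sqrt(2*pi*f / nu)`` (pulsatile
  frequency vs. viscous effects),
* the Strouhal number ``St = f * D_H / V`` (oscillatory vs. convective
  inertia),
* the critical peak Reynolds number ``Re_peak = 169 * alpha**0.83 *
  St**-0.27``, the power-law transition threshold to turbulence for pulsatile
  flow in compliant ducts,
* the supracritical Reynolds number ``Re_supra = |Re - Re_peak|``, the
  distance of the working point from that transition,
* the resistive index ``Res = (V_p - V_m) / V_p``, and
* the pressure drop ``dP = 4 * V_p**2`` (V_p in m/s, dP in mmHg; the
  simplified Bernoulli relation used in echocardiography).

The per-site supracritical Reynolds numbers are normalised by the loop-site
value ("per unit" ratios), so that ``Ratio(L) == 1`` by construction and gross
changes at the anastomoses are read directly off the ratios.  The screening
feature vector is the ordered 6-tuple

    phi = [Ratio_A, Ratio_L, Ratio_V, Res_A, Res_L, Res_V]

Velocities cross the I/O boundary in cm/s and hydraulic diameters in mm
(matching clinical report conventions); conversions to SI happen internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np

from .exceptions import DegenerateLoopError, DomainError, IncompleteSubjectError

__all__ = [
    "Site",
    "DOSClass",
    "CRITICAL_HC",
    "AcousticConfig",
    "FluidProperties",
    "SiteMeasurement",
    "CrossSection",
    "HemodynamicProfile",
    "FeaturePattern",
    "Subject",
    "doppler_velocity",
    "resistive_index",
    "pressure_drop",
    "reynolds",
    "womersley",
    "strouhal",
    "critical_peak_reynolds",
    "supracritical_reynolds",
    "hydraulic_diameter",
    "degree_of_stenosis",
    "classify_dos",
    "supra_ratios",
    "site_profile",
    "build_feature_vector",
    "featurize_subjects",
]

#: loop-site denominator below this magnitude is treated as degenerate
LOOP_DENOMINATOR_TOL = 1e-9


class Site(str, Enum):
    """Measurement site along the AV access, in the direction of flow."""

    A = "A"  #: arterial anastomosis
    L = "L"  #: loop segment
    V = "V"  #: venous anastomosis


class DOSClass(str, Enum):
    """Degree-of-stenosis class: I (DOS < 0.30), II (0.30–0.50), III (> 0.50)."""

    I = "I"
    II = "II"
    III = "III"


#: critical decision values of the hue fraction H_C for the three classes
CRITICAL_HC: Mapping[DOSClass, float] = {
    DOSClass.I: 2.0 / 3.0,
    DOSClass.II: 1.0 / 3.0,
    DOSClass.III: 1.0,
}


def classify_dos(dos: float) -> DOSClass:
    """Map a degree-of-stenosis value in [0, 1] to its screening class."""
    if not 0.0 <= dos <= 1.0:
        raise DomainError(f"DOS must lie in [0, 1], got {dos}")
    if dos < 0.30:
        return DOSClass.I
    if dos <= 0.50:
        return DOSClass.II
    return DOSClass.III


@dataclass(frozen=True)
class AcousticConfig:
    """Acoustic constants of the Doppler measurement.

    Parameters
    ----------
    sound_speed_c : float
        Speed of sound in tissue, m/s.  Nominal 1540 m/s.
    center_frequency_f0 : float
        Transmitted center frequency, Hz (clinically 7.5–10 MHz for an AV
        access).
    doppler_angle_theta : float
        Angle between the acoustic beam and the flow axis, degrees; must be
        strictly below 90 so that cos(theta) > 0.
    """

    sound_speed_c: float = 1540.0
    center_frequency_f0: float = 7.5e6
    doppler_angle_theta: float = 60.0

    def __post_init__(self) -> None:
        if self.sound_speed_c <= 0:
            raise DomainError("sound_speed_c must be positive")
        if self.center_frequency_f0 <= 0:
            raise DomainError("center_frequency_f0 must be positive")
        if not 0.0 <= self.doppler_angle_theta < 90.0:
            raise DomainError(
                "doppler_angle_theta must lie in [0, 90) degrees so that "
                f"cos(theta) > 0, got {self.doppler_angle_theta}"
            )


@dataclass(frozen=True)
class FluidProperties:
    """Bulk rheological properties of blood.

    Defaults are whole blood at ~40% hematocrit: density 1055 kg/m^3,
    dynamic viscosity 0.01063 N·s/m^2.
    """

    density: float = 1055.0
    dynamic_viscosity_mu: float = 0.01063
    hematocrit: float = 0.40  # informational only

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError("density must be positive")
        if self.dynamic_viscosity_mu <= 0:
            raise DomainError("dynamic_viscosity_mu must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho, m^2/s."""
        return self.dynamic_viscosity_mu / self.density


@dataclass(frozen=True)
class SiteMeasurement:
    """One site's Doppler-derived velocity landmarks.

    Velocities are stored in cm/s and the hydraulic diameter in mm (the units
    of clinical reports); use :attr:`V_p_si`, :attr:`D_H_si` for SI values.

    Parameters
    ----------
    subject_id : str
    site : Site
    V_p : float
        Peak-systolic velocity (PSV), cm/s.
    V_m : float
        Peak-diastolic velocity (PDV), cm/s; 0 < V_m <= V_p.
    heart_rate : float
        Cardiac frequency, Hz.
    D_H : float
        Hydraulic diameter at the site, mm.
    V_ed : float, optional
        End-diastolic velocity, cm/s.  Carried through I/O but not used by
        the feature vector.
    """

    subject_id: str
    site: Site
    V_p: float
    V_m: float
    heart_rate: float
    D_H: float
    V_ed: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", Site(self.site))
        if self.V_p <= 0:
            raise DomainError(f"V_p must be positive, got {self.V_p}")
        if not 0 < self.V_m <= self.V_p:
            raise DomainError(
                f"V_m must satisfy 0 < V_m <= V_p, got V_m={self.V_m}, V_p={self.V_p}"
            )
        if self.heart_rate <= 0:
            raise DomainError(f"heart_rate must be positive, got {self.heart_rate}")
        if self.D_H <= 0:
            raise DomainError(f"D_H must be positive, got {self.D_H}")
        if self.V_ed is not None and self.V_ed < 0:
            raise DomainError(f"V_ed must be non-negative, got {self.V_ed}")

    @property
    def V_p_si(self) -> float:
        """Peak-systolic velocity in m/s."""
        return self.V_p / 100.0

    @property
    def V_m_si(self) -> float:
        """Peak-diastolic velocity in m/s."""
        return self.V_m / 100.0

    @property
    def D_H_si(self) -> float:
        """Hydraulic diameter in m."""
        return self.D_H / 1000.0


@dataclass(frozen=True)
class CrossSection:
    """A (possibly noncircular) duct cross-section for hydraulic-diameter
    computation: area plus the list of wetted-perimeter segment lengths."""

    area_A: float
    perimeter_segments: tuple

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "perimeter_segments", tuple(float(s) for s in self.perimeter_segments)
        )
        if self.area_A <= 0:
            raise DomainError("area_A must be positive")
        if not self.perimeter_segments or any(s <= 0 for s in self.perimeter_segments):
            raise DomainError("every perimeter segment length must be positive")

    @property
    def wetted_perimeter(self) -> float:
        return float(sum(self.perimeter_segments))


@dataclass(frozen=True)
class HemodynamicProfile:
    """Dimensionless numbers and derived indices for one measurement site."""

    site: Site
    Re: float
    alpha: float
    St: float
    Re_peak: float
    Re_supra: float
    Res: float
    delta_P: float

    def __post_init__(self) -> None:
        if self.Re < 0 or self.alpha <= 0 or self.St <= 0 or self.Re_peak <= 0:
            raise DomainError("invalid dimensionless numbers in profile")
        if self.Re_supra < 0 or not 0 <= self.Res < 1 or self.delta_P < 0:
            raise DomainError("invalid derived indices in profile")


@dataclass(frozen=True)
class FeaturePattern:
    """The 6-element screening pattern phi with optional DOS labels."""

    phi: np.ndarray
    dos_class: Optional[DOSClass] = None
    dos_value: Optional[float] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.phi, dtype=float)
        if arr.shape != (6,):
            raise DomainError(f"phi must be a 6-vector, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DomainError("phi entries must be finite and non-negative")
        arr.flags.writeable = False
        object.__setattr__(self, "phi", arr)
        if self.dos_class is not None:
            object.__setattr__(self, "dos_class", DOSClass(self.dos_class))


@dataclass(frozen=True)
class Subject:
    """A complete three-site examination of one subject."""

    subject_id: str
    sites: Mapping[Site, SiteMeasurement]
    dos_value: Optional[float] = None
    dos_class: Optional[DOSClass] = None

    def __post_init__(self) -> None:
        sites = {Site(k): v for k, v in dict(self.sites).items()}
        missing = [s.value for s in Site if s not in sites]
        if missing:
            raise IncompleteSubjectError(
                f"subject {self.subject_id!r} missing site(s): {', '.join(missing)}"
            )
        object.__setattr__(self, "sites", sites)
        if self.dos_class is not None:
            object.__setattr__(self, "dos_class", DOSClass(self.dos_class))


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def doppler_velocity(f_d: float, cfg: AcousticConfig) -> float:
    """Flow velocity (m/s) from the Doppler frequency shift.

    V = f_d * c / (2 * f0 * cos(theta)); strictly increasing in f_d.
    """
    if f_d < 0:
        raise DomainError(f"Doppler shift must be non-negative, got {f_d}")
    cos_theta = math.cos(math.radians(cfg.doppler_angle_theta))
    return f_d * cfg.sound_speed_c / (2.0 * cfg.center_frequency_f0 * cos_theta)


def resistive_index(V_p: float, V_m: float) -> float:
    """Resistive index Res = (V_p - V_m) / V_p, unit-free, in [0, 1).

    V_m > V_p signals swapped inputs and is rejected.
    """
    if V_p <= 0:
        raise DomainError(f"V_p must be positive, got {V_p}")
    if V_m < 0 or V_m > V_p:
        raise DomainError(f"V_m must satisfy 0 <= V_m <= V_p, got V_m={V_m}, V_p={V_p}")
    return (V_p - V_m) / V_p


def pressure_drop(V_p: float) -> float:
    """Pressure drop dP = 4 * V_p^2 (simplified Bernoulli), V_p in m/s, dP in mmHg."""
    if V_p < 0:
        raise DomainError(f"V_p must be non-negative, got {V_p}")
    return 4.0 * V_p * V_p


def reynolds(V: float, D_H: float, fluid: FluidProperties) -> float:
    """Reynolds number Re = rho * V * D_H / mu (SI inputs)."""
    if V <= 0 or D_H <= 0:
        raise DomainError("V and D_H must be positive")
    return fluid.density * V * D_H / fluid.dynamic_viscosity_mu


def womersley(D_H: float, heart_rate: float, fluid: FluidProperties) -> float:
    """Womersley number alpha = (D_H / 2) * sqrt(omega / nu), omega = 2*pi*f."""
    if D_H <= 0 or heart_rate <= 0:
        raise DomainError("D_H and heart_rate must be positive")
    nu = fluid.kinematic_viscosity
    return (D_H / 2.0) * math.sqrt(2.0 * math.pi * heart_rate / nu)


def strouhal(heart_rate: float, D_H: float, V: float) -> float:
    """Strouhal number St = f * D_H / V (SI inputs)."""
    if heart_rate <= 0 or D_H <= 0 or V <= 0:
        raise DomainError("heart_rate, D_H and V must be positive")
    return heart_rate * D_H / V


def critical_peak_reynolds(alpha: float, St: float) -> float:
    """Critical peak Reynolds number, the pulsatile transition threshold.

    Re_peak = 169 * alpha**0.83 * St**-0.27, increasing in alpha and
    decreasing in St.
    """
    if alpha <= 0 or St <= 0:
        raise DomainError("alpha and St must be positive")
    return 169.0 * alpha**0.83 * St**-0.27


def supracritical_reynolds(Re: float, Re_peak: float) -> float:
    """Supracritical Reynolds number Re_supra = |Re - Re_peak|."""
    if Re < 0:
        raise DomainError(f"Re must be non-negative, got {Re}")
    if Re_peak <= 0:
        raise DomainError(f"Re_peak must be positive, got {Re_peak}")
    return abs(Re - Re_peak)


def hydraulic_diameter(cs: CrossSection) -> float:
    """Hydraulic diameter D_H = 4*A / P of a (noncircular) duct.

    For a circular duct this reduces to the geometric diameter.
    """
    P = cs.wetted_perimeter
    if P <= 0:
        raise DomainError("wetted perimeter must be positive")
    return 4.0 * cs.area_A / P


def degree_of_stenosis(d_H: float, D_H: float) -> float:
    """Degree of stenosis DOS = 1 - (d_H / D_H)^2 in [0, 1].

    ``d_H`` is the hydraulic diameter of the lesion, ``D_H`` of the adjacent
    normal vessel; DOS = 1.00 is total occlusion.
    """
    if D_H <= 0:
        raise DomainError(f"D_H must be positive, got {D_H}")
    if d_H < 0 or d_H > D_H:
        raise DomainError(f"d_H must satisfy 0 <= d_H <= D_H, got d_H={d_H}, D_H={D_H}")
    return 1.0 - (d_H / D_H) ** 2


def supra_ratios(
    Re_supra_A: float, Re_supra_L: float, Re_supra_V: float
) -> tuple[float, float, float]:
    """Per-unit supracritical-Reynolds ratios, normalised by the loop site.

    Returns (Ratio_A, Ratio_L, Ratio_V) with Ratio_L == 1 exactly.
    """
    for name, v in (("A", Re_supra_A), ("L", Re_supra_L), ("V", Re_supra_V)):
        if v < 0:
            raise DomainError(f"Re_supra({name}) must be non-negative, got {v}")
    if Re_supra_L < LOOP_DENOMINATOR_TOL:
        raise DegenerateLoopError(
            "loop-site Re_supra is zero to tolerance; the per-unit basis is "
            "undefined (loop site at the exact transition point)"
        )
    return (Re_supra_A / Re_supra_L, 1.0, Re_supra_V / Re_supra_L)


# ---------------------------------------------------------------------------
# per-site profile and feature assembly
# ---------------------------------------------------------------------------

def site_profile(m: SiteMeasurement, fluid: FluidProperties) -> HemodynamicProfile:
    """All dimensionless numbers for one site, using V = V_p (peak-systolic).

    The critical peak Reynolds criterion is a *peak*-flow transition
    threshold, so the peak-systolic velocity is the working velocity for Re
    and St.
    """
    V = m.V_p_si
    D = m.D_H_si
    Re = reynolds(V, D, fluid)
    alpha = womersley(D, m.heart_rate, fluid)
    St = strouhal(m.heart_rate, D, V)
    Re_peak = critical_peak_reynolds(alpha, St)
    return HemodynamicProfile(
        site=m.site,
        Re=Re,
        alpha=alpha,
        St=St,
        Re_peak=Re_peak,
        Re_supra=supracritical_reynolds(Re, Re_peak),
        Res=resistive_index(m.V_p, m.V_m),
        delta_P=pressure_drop(V),
    )


def _as_site_mapping(measurements) -> Mapping[Site, SiteMeasurement]:
    if isinstance(measurements, Subject):
        return measurements.sites
    if isinstance(measurements, Mapping):
        sites = {Site(k): v for k, v in measurements.items()}
    else:
        sites = {}
        for m in measurements:
            if m.site in sites:
                raise DomainError(f"duplicate measurement for site {m.site.value}")
            sites[m.site] = m
    missing = [s.value for s in Site if s not in sites]
    if missing:
        raise IncompleteSubjectError(f"missing site(s): {', '.join(missing)}")
    subject_ids = {m.subject_id for m in sites.values()}
    if len(subject_ids) > 1:
        raise DomainError(f"measurements mix subjects: {sorted(subject_ids)}")
    return sites


def build_feature_vector(
    measurements,
    fluid: FluidProperties = FluidProperties(),
    dos_value: Optional[float] = None,
    dos_class: Optional[DOSClass] = None,
) -> FeaturePattern:
    """Assemble phi = [Ratio_A, Ratio_L, Ratio_V, Res_A, Res_L, Res_V].

    ``measurements`` may be a :class:`Subject`, a mapping site -> measurement,
    or an iterable of the three :class:`SiteMeasurement` of one subject.
    """
    if isinstance(measurements, Subject):
        dos_value = measurements.dos_value if dos_value is None else dos_value
        dos_class = measurements.dos_class if dos_class is None else dos_class
    sites = _as_site_mapping(measurements)
    profiles = {s: site_profile(m, fluid) for s, m in sites.items()}
    ratios = supra_ratios(
        profiles[Site.A].Re_supra,
        profiles[Site.L].Re_supra,
        profiles[Site.V].Re_supra,
    )
    phi = np.array(
        [
            ratios[0],
            ratios[1],
            ratios[2],
            profiles[Site.A].Res,
            profiles[Site.L].Res,
            profiles[Site.V].Res,
        ]
    )
    if dos_class is None and dos_value is not None:
        dos_class = classify_dos(dos_value)
    return FeaturePattern(
        phi=phi,
        dos_class=dos_class,
        dos_value=dos_value,
        subject_id=sites[Site.A].subject_id,
    )


def featurize_subjects(
    subjects: Iterable[Subject], fluid: FluidProperties = FluidProperties()
) -> list[FeaturePattern]:
    """Feature vectors for a cohort of complete subjects."""
    return [build_feature_vector(s, fluid) for s in subjects]
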