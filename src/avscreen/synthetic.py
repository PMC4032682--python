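"""Synthetic cohorts with class-conditional, per-site Doppler velocity statistics.

The generator emulates the published group statistics of a 30-patient AV-access
cohort: per degree-of-stenosis class (I/II/III, sizes 12/11/7) and per site
(A/L/V), peak-systolic and peak-diastolic velocities are drawn from correlated
truncated normals whose means and SDs are the reported values (cm/s):

    Class I   (DOS < 0.30, n=12):  A 103.20±18.35 / 37.00±10.80,
                                   L  64.60±28.05 / 28.83±16.61,
                                   V  82.56±25.30 / 35.43±17.37
    Class II  (0.30–0.50, n=11):   A 106.70±28.80 / 35.49±19.96,
                                   L  54.91±21.54 / 16.61± 8.69,
                                   V  77.79±18.54 / 29.87±15.81
    Class III (DOS > 0.50, n=7):   A  72.21±40.58 / 17.84± 8.70,
                                   L  25.61± 9.62 /  7.86± 3.84,
                                   V  66.03±42.12 / 14.92±14.19

Only marginal moments are published; V_p and V_m are drawn with correlation
0.7 (configurable) because independent draws produce implausible V_p/V_m
ratios, and the pair is resampled until 0 < V_m < V_p.  Heart rate is uniform
on 1.00–1.25 Hz.  Each subject gets one baseline hydraulic diameter
(N(5, 0.5) mm truncated above 2 mm); the stenosis is localised at the loop
segment, whose measured diameter is d_H = D_H * sqrt(1 - DOS) with DOS drawn
uniformly inside the subject's class band.

A small pulsatile-waveform toolkit rounds out the module: a two-pulse
(raised-Gaussian systolic + diastolic) velocity waveform with Gaussian noise,
and a landmark extractor (autocorrelation period, per-cycle extrema medians)
that inverts it.  These support end-to-end exercises from a raw velocity trace
to the PSV/PDV/EDV/heart-rate landmarks; they are not an ultrasound physics
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ConfigError, DomainError, ExtractionError
from .hemodynamics import (
    DOSClass,
    FluidProperties,
    Site,
    SiteMeasurement,
    Subject,
    classify_dos,
)

__all__ = [
    "VelocityStats",
    "TABLE_STATS",
    "DEFAULT_CLASS_SIZES",
    "CohortConfig",
    "WaveformConfig",
    "sample_cohort",
    "synthesize_waveform",
    "extract_velocity_landmarks",
]

_MAX_RESAMPLE = 10_000


@dataclass(frozen=True)
class VelocityStats:
    """Marginal mean/SD of V_p and V_m (cm/s) for one class x site cell."""

    vp_mean: float
    vp_sd: float
    vm_mean: float
    vm_sd: float

    def __post_init__(self) -> None:
        if self.vp_sd < 0 or self.vm_sd < 0:
            raise ConfigError("velocity SDs must be non-negative")
        if self.vp_mean <= 0 or self.vm_mean <= 0:
            raise ConfigError("velocity means must be positive")


#: published per-class, per-site velocity statistics (cm/s)
TABLE_STATS: Mapping[DOSClass, Mapping[Site, VelocityStats]] = {
    DOSClass.I: {
        Site.A: VelocityStats(103.20, 18.35, 37.00, 10.80),
        Site.L: VelocityStats(64.60, 28.05, 28.83, 16.61),
        Site.V: VelocityStats(82.56, 25.30, 35.43, 17.37),
    },
    DOSClass.II: {
        Site.A: VelocityStats(106.70, 28.80, 35.49, 19.96),
        Site.L: VelocityStats(54.91, 21.54, 16.61, 8.69),
        Site.V: VelocityStats(77.79, 18.54, 29.87, 15.81),
    },
    DOSClass.III: {
        Site.A: VelocityStats(72.21, 40.58, 17.84, 8.70),
        Site.L: VelocityStats(25.61, 9.62, 7.86, 3.84),
        Site.V: VelocityStats(66.03, 42.12, 14.92, 14.19),
    },
}

DEFAULT_CLASS_SIZES: Mapping[DOSClass, int] = {
    DOSClass.I: 12,
    DOSClass.II: 11,
    DOSClass.III: 7,
}

_DEFAULT_DOS_RANGES: Mapping[DOSClass, tuple] = {
    DOSClass.I: (0.05, 0.30),
    DOSClass.II: (0.30, 0.50),
    DOSClass.III: (0.50, 0.95),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generating conditions for a labelled synthetic cohort.

    Defaults reproduce the published study conditions: class sizes 12/11/7,
    the velocity table above, heart rate U(1.00, 1.25) Hz, baseline hydraulic
    diameter N(5, 0.5) mm truncated above 2 mm, DOS uniform inside each class
    band, V_p–V_m correlation 0.7, stenosis localised at the loop site.
    """

    class_sizes: Mapping[DOSClass, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    velocity_stats: Mapping[DOSClass, Mapping[Site, VelocityStats]] = field(
        default_factory=lambda: {c: dict(TABLE_STATS[c]) for c in TABLE_STATS}
    )
    heart_rate_range: tuple = (1.00, 1.25)
    baseline_DH_mean: float = 5.0
    baseline_DH_sd: float = 0.5
    baseline_DH_min: float = 2.0
    dos_ranges: Mapping[DOSClass, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_DOS_RANGES)
    )
    vp_vm_correlation: float = 0.7
    v_ed_fraction: float = 0.6
    stenosis_site: Site = Site.L
    fluid: FluidProperties = field(default_factory=FluidProperties)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        sizes = {DOSClass(c): int(n) for c, n in dict(self.class_sizes).items()}
        if any(n < 1 for n in sizes.values()) or set(sizes) != set(DOSClass):
            raise ConfigError("class_sizes needs a count >= 1 for each of I, II, III")
        object.__setattr__(self, "class_sizes", sizes)
        lo, hi = self.heart_rate_range
        if not 0 < lo <= hi:
            raise ConfigError(f"invalid heart_rate_range {self.heart_rate_range}")
        if self.baseline_DH_mean <= 0 or self.baseline_DH_sd < 0:
            raise ConfigError("invalid baseline hydraulic-diameter parameters")
        if self.baseline_DH_min <= 0:
            raise ConfigError("baseline_DH_min must be positive")
        if self.baseline_DH_mean - 5 * self.baseline_DH_sd > 0 and (
            self.baseline_DH_mean + 5 * self.baseline_DH_sd < self.baseline_DH_min
        ):
            raise ConfigError("baseline diameter truncation is infeasible")
        if not -1.0 < self.vp_vm_correlation < 1.0:
            raise ConfigError("vp_vm_correlation must lie in (-1, 1)")
        if not 0 <= self.v_ed_fraction <= 1:
            raise ConfigError("v_ed_fraction must lie in [0, 1]")
        bands = {
            DOSClass.I: (0.0, 0.30),
            DOSClass.II: (0.30, 0.50),
            DOSClass.III: (0.50, 1.0),
        }
        ranges = {DOSClass(c): tuple(r) for c, r in dict(self.dos_ranges).items()}
        for c, (dlo, dhi) in ranges.items():
            blo, bhi = bands[c]
            if not (blo <= dlo <= dhi <= bhi):
                raise ConfigError(
                    f"dos range {dlo}–{dhi} leaves the Class {c.value} band {blo}–{bhi}"
                )
        object.__setattr__(self, "dos_ranges", ranges)


@dataclass(frozen=True)
class WaveformConfig:
    """Sampling and shape parameters of the synthetic velocity waveform."""

    sampling_rate: float = 250.0
    n_cycles: int = 10
    noise_sd: float = 0.0
    systolic_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.sampling_rate < 50:
            raise ConfigError("sampling_rate must be >= 50 Hz")
        if self.n_cycles < 2:
            raise ConfigError("n_cycles must be >= 2")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0.1 <= self.systolic_fraction <= 0.5:
            raise ConfigError("systolic_fraction must lie in [0.1, 0.5]")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _draw_velocity_pair(
    stats: VelocityStats, corr: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Correlated (V_p, V_m) resampled until 0 < V_m < V_p."""
    for _ in range(_MAX_RESAMPLE):
        z1 = rng.standard_normal()
        z2 = rng.standard_normal()
        vp = stats.vp_mean + stats.vp_sd * z1
        vm = stats.vm_mean + stats.vm_sd * (corr * z1 + np.sqrt(1 - corr**2) * z2)
        if 0 < vm < vp or (vp == stats.vp_mean and vm == stats.vm_mean and 0 < vm <= vp):
            return float(vp), float(vm)
    raise ConfigError(
        "velocity truncation infeasible: could not draw 0 < V_m < V_p from "
        f"{stats} in {_MAX_RESAMPLE} attempts"
    )


def _draw_baseline_diameter(cfg: CohortConfig, rng: np.random.Generator) -> float:
    if cfg.baseline_DH_sd == 0:
        if cfg.baseline_DH_mean <= cfg.baseline_DH_min:
            raise ConfigError("degenerate baseline diameter below the truncation floor")
        return cfg.baseline_DH_mean
    for _ in range(_MAX_RESAMPLE):
        d = rng.normal(cfg.baseline_DH_mean, cfg.baseline_DH_sd)
        if d > cfg.baseline_DH_min:
            return float(d)
    raise ConfigError("baseline diameter truncation infeasible")


def sample_cohort(
    cfg: CohortConfig = CohortConfig(), rng: Optional[np.random.Generator] = None
) -> list[Subject]:
    """Draw a labelled cohort of complete three-site subjects.

    Deterministic for a fixed seed/config; subject ids are S001, S002, ...
    in class order I, II, III.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    subjects: list[Subject] = []
    n = 0
    for dos_class in (DOSClass.I, DOSClass.II, DOSClass.III):
        dlo, dhi = cfg.dos_ranges[dos_class]
        for _ in range(cfg.class_sizes[dos_class]):
            n += 1
            subject_id = f"S{n:03d}"
            dos = float(rng.uniform(dlo, dhi))
            base_dh = _draw_baseline_diameter(cfg, rng)
            heart_rate = float(rng.uniform(*cfg.heart_rate_range))
            sites = {}
            for site in (Site.A, Site.L, Site.V):
                vp, vm = _draw_velocity_pair(
                    cfg.velocity_stats[dos_class][site], cfg.vp_vm_correlation, rng
                )
                dh = base_dh
                if site is cfg.stenosis_site:
                    dh = base_dh * float(np.sqrt(1.0 - dos))
                sites[site] = SiteMeasurement(
                    subject_id=subject_id,
                    site=site,
                    V_p=vp,
                    V_m=vm,
                    heart_rate=heart_rate,
                    D_H=dh,
                    V_ed=cfg.v_ed_fraction * vm,
                )
            subjects.append(
                Subject(
                    subject_id=subject_id,
                    sites=sites,
                    dos_value=dos,
                    dos_class=classify_dos(dos),
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# pulsatile waveform synthesis and landmark extraction
# ---------------------------------------------------------------------------

def synthesize_waveform(
    V_p: float,
    V_m: float,
    V_ed: float,
    heart_rate: float,
    wcfg: WaveformConfig = WaveformConfig(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pulse periodic velocity waveform (cm/s) with Gaussian noise.

    Each cycle carries a raised-Gaussian systolic pulse peaking at V_p and a
    broader diastolic pulse peaking at V_m on an end-diastolic floor V_ed.
    Returns (times s, velocities cm/s).
    """
    if not V_p > V_m > V_ed >= 0:
        raise DomainError(
            f"landmarks must satisfy V_p > V_m > V_ed >= 0, got {(V_p, V_m, V_ed)}"
        )
    if heart_rate <= 0:
        raise DomainError("heart_rate must be positive")
    T = 1.0 / heart_rate
    n = int(round(wcfg.sampling_rate * wcfg.n_cycles * T))
    t = np.arange(n) / wcfg.sampling_rate
    tc = t % T
    sf = wcfg.systolic_fraction
    t_s, sig_s = 0.5 * sf * T, sf * T / 6.0
    t_d, sig_d = (sf + 0.30) * T, 0.10 * T
    v = (
        V_ed
        + (V_p - V_ed) * np.exp(-0.5 * ((tc - t_s) / sig_s) ** 2)
        + (V_m - V_ed) * np.exp(-0.5 * ((tc - t_d) / sig_d) ** 2)
    )
    if wcfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        v = v + rng.normal(0.0, wcfg.noise_sd, n)
    return t, v


def _dominant_period(x: np.ndarray, sampling_rate: float) -> int:
    """Cycle length in samples from the first strong autocorrelation peak."""
    n = x.size
    x = x - x.mean()
    power = float(np.dot(x, x))
    if power <= 0 or np.isclose(x.std(), 0.0):
        raise ExtractionError("series is constant; no periodicity to extract")
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    min_lag = max(2, int(sampling_rate / 4.0))  # heart rate <= 4 Hz
    max_lag = min(n // 2, int(3.0 * sampling_rate))  # heart rate >= 1/3 Hz
    if max_lag <= min_lag:
        raise ExtractionError("series too short: need at least two cycles")
    peaks, _ = find_peaks(ac[min_lag : max_lag + 1])
    if peaks.size == 0:
        raise ExtractionError("no periodicity found in the autocorrelation")
    heights = ac[peaks + min_lag]
    if heights.max() < 0.2 * ac[0]:
        raise ExtractionError("autocorrelation peak too weak; no stable period")
    candidates = peaks[heights >= 0.8 * heights.max()]
    return int(candidates.min()) + min_lag


def extract_velocity_landmarks(
    series: np.ndarray, sampling_rate: float
) -> tuple[float, float, float, float]:
    """Recover (V_p, V_m, V_ed, heart_rate) from a pulsatile velocity series.

    The cycle length comes from the dominant autocorrelation period; the
    series is cut into consecutive cycles and V_p / V_ed are the medians of
    the per-cycle maxima / minima.  V_m is the median of the largest
    *secondary* local maximum per cycle (local maxima within a tenth of a
    cycle of the systolic peak are treated as part of it).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ExtractionError("series must be a 1-D array spanning >= 2 cycles")
    lag = _dominant_period(x, sampling_rate)
    heart_rate = sampling_rate / lag
    vps, vms, veds = [], [], []
    for start in range(0, x.size - lag + 1, lag):
        cyc = x[start : start + lag]
        imax = int(np.argmax(cyc))
        vps.append(float(cyc[imax]))
        veds.append(float(cyc.min()))
        peaks, _ = find_peaks(cyc)
        secondary = [p for p in peaks if abs(p - imax) > 0.1 * lag]
        if secondary:
            vms.append(float(max(cyc[p] for p in secondary)))
    if not vps:
        raise ExtractionError("could not segment any full cycle")
    if not vms:
        raise ExtractionError("no secondary (diastolic) peak found in any cycle")
    return (
        float(np.median(vps)),
        float(np.median(vms)),
        float(np.median(veds)),
        float(heart_rate),
    )
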