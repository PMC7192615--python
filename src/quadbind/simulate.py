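"""Synthetic experiments with known ground truth.

Forward-simulates the three measurement modalities analysed by this
package — fast-exchange HSQC CSP titrations, one-site ITC isotherms, and
CD spectral series / thermal melts — under the same models the fitters
invert, plus seeded instrument-class noise. With the noise set to zero
every generator round-trips exactly through its fitter, which is the
backbone of the test suite; with realistic noise they drive the parameter
recovery studies.

Default designs mirror the hnRNPA1/TERRA study conditions: a 138 uM
15N-labelled RGG-box titrated with RNA to protein:RNA ratios 0.2-3, 20 x
2 ul injections of 200 uM protein into 5 uM RNA in a 200 ul cell, 5 uM
RNA scanned 325-225 nm at protein steps 0-25 uM, and 262 nm melts sampled
every 0.5 C from 10 to 100 C.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .binding import fraction_protein_bound
from .cd import CDSpectrum, MeltingCurve, two_state_ellipticity
from .csp import PeakAssignment, TitrationPoint, TitrationSeries
from .itc import InjectionSchedule, one_site_heats

__all__ = [
    "CspSimConfig",
    "ItcSimConfig",
    "CdTitrationSimConfig",
    "CdMeltSimConfig",
    "gen_csp_experiment",
    "gen_itc_experiment",
    "gen_cd_titration",
    "gen_cd_melt",
    "gen_cd_series",
]

# Pseudo-assignment labels of the kind seen in a glycine/arginine-rich
# disordered region (partial assignment).
_DEFAULT_LABELS = (
    "G#1", "G#2", "G#3", "G#4", "R#1", "R#2", "F#1",
    "Y244", "S197", "R232", "G221", "R206", "S231", "F257",
)


@dataclasses.dataclass
class CspSimConfig:
    """Ground truth and design for a synthetic CSP titration.

    ``ddmax`` may be an explicit per-residue array (ppm); if None,
    ``n_residues`` amplitudes are drawn uniformly from ``ddmax_range``.
    ``sigma_h``/``sigma_n`` are per-dimension Gaussian peak-position noise
    in ppm, applied at every step including the reference.
    """

    seed: int
    kd: float = 11.0                       # uM
    ddmax: np.ndarray | None = None        # ppm per residue
    n_residues: int = 14
    ddmax_range: tuple[float, float] = (0.05, 0.30)
    protein_total: float = 138.0           # uM
    molar_ratios: tuple[float, ...] = (0.0, 0.2, 0.5, 1.0, 2.0, 3.0)
    sigma_h: float = 0.005                 # ppm
    sigma_n: float = 0.025                 # ppm
    n_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_h < 0 or self.sigma_n < 0:
            raise ValueError("noise levels must be non-negative")


def gen_csp_experiment(config: CspSimConfig) -> TitrationSeries:
    """Simulate a fast-exchange HSQC titration as a :class:`TitrationSeries`.

    Each residue gets a reference peak position and a fixed unit direction
    in the scaled (dH, dN/n_scale) plane drawn once from the seed, so its
    peak moves colinearly across steps (the fast-exchange signature). The
    combined CSP magnitude along that direction is ddmax * f_bound from the
    ligand-depletion isotherm; Gaussian noise is then added per spectral
    dimension.
    """
    rng = np.random.default_rng(config.seed)
    n_res = config.n_residues
    ddmax = config.ddmax
    if ddmax is None:
        ddmax = rng.uniform(*config.ddmax_range, size=n_res)
    else:
        ddmax = np.asarray(ddmax, dtype=float)
        n_res = len(ddmax)
    labels = list(_DEFAULT_LABELS[:n_res]) + [
        f"Peak {i + 1}" for i in range(len(_DEFAULT_LABELS), n_res)
    ]
    # reference positions: amide region of a disordered Gly/Arg-rich protein
    ref_h = rng.uniform(7.6, 8.8, size=n_res)
    ref_n = rng.uniform(105.0, 126.0, size=n_res)
    # fixed unit direction per residue in the scaled CSP plane
    phi = rng.uniform(0, 2 * np.pi, size=n_res)
    dir_h, dir_n = np.cos(phi), np.sin(phi) * config.n_scale

    points = []
    for ratio in config.molar_ratios:
        l_tot = ratio * config.protein_total
        if l_tot > 0:
            f = fraction_protein_bound(
                p_total=config.protein_total, l_total=l_tot, kd=config.kd
            )
        else:
            f = 0.0
        d_obs = ddmax * f
        h = ref_h + d_obs * dir_h + rng.normal(0, config.sigma_h, n_res)
        n15 = ref_n + d_obs * dir_n + rng.normal(0, config.sigma_n, n_res)
        peaks = tuple(
            PeakAssignment(labels[j], float(h[j]), float(n15[j]))
            for j in range(n_res)
        )
        points.append(
            TitrationPoint(
                protein_total=config.protein_total,
                ligand_total=l_tot,
                peaks=peaks,
            )
        )
    return TitrationSeries(tuple(points))


@dataclasses.dataclass
class ItcSimConfig:
    """Ground truth and geometry for a synthetic one-site ITC run.

    Noise is Gaussian per injection with sigma = max(noise_frac * |heat|,
    noise_floor ucal); an optional constant dilution heat (ucal per
    injection volume-normalized, i.e. kcal/mol injectant) can be layered on
    top to exercise the dilution-correction paths.
    """

    seed: int
    n: float = 0.82
    kd: float = 0.92                 # uM
    dH: float = -41.88               # kcal/mol
    baseline: float = 0.0            # kcal/mol injectant
    cell_volume: float = 200.0       # ul
    cell_conc: float = 5.0           # uM
    syringe_conc: float = 200.0      # uM
    n_injections: int = 20
    injection_volume: float = 2.0    # ul
    temperature: float = 298.15      # K
    spacing: float = 180.0           # s
    noise_frac: float = 0.02
    noise_floor: float = 0.02        # ucal
    dilution_heat: float = 0.0       # kcal/mol injectant, constant

    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule(
            cell_volume=self.cell_volume,
            cell_conc=self.cell_conc,
            syringe_conc=self.syringe_conc,
            injections=(self.injection_volume,) * self.n_injections,
            temperature=self.temperature,
            spacing=self.spacing,
        )


def gen_itc_experiment(
    config: ItcSimConfig,
) -> tuple[InjectionSchedule, np.ndarray]:
    """Simulate per-injection heats (ucal) for a one-site titration."""
    rng = np.random.default_rng(config.seed)
    schedule = config.schedule()
    ndh = one_site_heats(
        schedule, config.n, config.kd, config.dH,
        config.baseline + config.dilution_heat,
    )
    dv = np.asarray(schedule.injections)
    heats = ndh * schedule.syringe_conc * dv * 1e-3  # ucal
    if config.noise_frac > 0 or config.noise_floor > 0:
        sigma = np.maximum(config.noise_frac * np.abs(heats), config.noise_floor)
        heats = heats + rng.normal(0, 1, len(heats)) * sigma
    return schedule, heats


@dataclasses.dataclass
class CdTitrationSimConfig:
    """Synthetic protein-into-G4 CD titration series.

    The spectrum is a parallel-G4 reference shape — a positive Gaussian
    band near 262 nm and a negative trough near 240 nm — whose amplitude
    scales with foldedness. Foldedness decays exponentially with titrant
    concentration toward a residual plateau:
    F(c) = f_inf + (1 - f_inf) exp(-c / decay_conc). Noise is Gaussian per
    wavelength point, sigma = noise_frac * 262 nm band amplitude.
    """

    seed: int
    concentrations: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0)
    decay_conc: float = 25.0     # uM
    f_inf: float = 0.1
    band_amplitude: float = 12.0  # mdeg at 262 nm, fully folded
    trough_amplitude: float = -4.0  # mdeg at 240 nm
    rna_conc: float = 5e-6       # M strand
    path: float = 1.0            # cm
    n_residues: int = 24
    wl_min: float = 225.0
    wl_max: float = 325.0
    wl_step: float = 1.0
    noise_frac: float = 0.01

    def foldedness(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.f_inf + (1 - self.f_inf) * np.exp(-c / self.decay_conc)


def gen_cd_titration(config: CdTitrationSimConfig) -> list[CDSpectrum]:
    """Simulate CD wavelength scans at each protein titration step."""
    rng = np.random.default_rng(config.seed)
    wl = np.arange(config.wl_min, config.wl_max + config.wl_step / 2,
                   config.wl_step)
    band = np.exp(-0.5 * ((wl - 262.0) / 8.0) ** 2)
    trough = np.exp(-0.5 * ((wl - 240.0) / 6.0) ** 2)
    spectra = []
    for c in config.concentrations:
        f = float(config.foldedness(c))
        theta = f * (config.band_amplitude * band
                     + config.trough_amplitude * trough)
        if config.noise_frac > 0:
            theta = theta + rng.normal(
                0, config.noise_frac * config.band_amplitude, len(wl)
            )
        spectra.append(
            CDSpectrum(
                wavelengths=wl, ellipticity=theta, conc=config.rna_conc,
                path=config.path, n_residues=config.n_residues,
                titrant_conc=c,
            )
        )
    return spectra


@dataclasses.dataclass
class CdMeltSimConfig:
    """Synthetic two-state 262 nm melting trace.

    Defaults produce a stable intramolecular G-quadruplex melt (midpoint
    80.5 C, van't Hoff enthalpy 45 kcal/mol) with gently sloped baselines;
    noise sigma = noise_frac * (folded - unfolded) amplitude at the
    midpoint.
    """

    seed: int
    tm: float = 80.5              # C
    dh_vanthoff: float = 45.0     # kcal/mol
    theta_folded: float = 12.0    # mdeg
    slope_folded: float = -0.02   # mdeg / C
    theta_unfolded: float = 2.0
    slope_unfolded: float = -0.005
    t_min: float = 10.0
    t_max: float = 100.0
    t_step: float = 0.5
    noise_frac: float = 0.02

    @property
    def amplitude(self) -> float:
        return abs(
            (self.theta_folded + self.slope_folded * self.tm)
            - (self.theta_unfolded + self.slope_unfolded * self.tm)
        )


def gen_cd_melt(config: CdMeltSimConfig) -> MeltingCurve:
    """Simulate a fixed-wavelength thermal melt as a :class:`MeltingCurve`."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.t_min, config.t_max + config.t_step / 2, config.t_step)
    theta = two_state_ellipticity(
        t, config.tm, config.dh_vanthoff,
        config.theta_folded, config.slope_folded,
        config.theta_unfolded, config.slope_unfolded,
    )
    if config.noise_frac > 0:
        theta = theta + rng.normal(
            0, config.noise_frac * config.amplitude, len(t)
        )
    return MeltingCurve(temperature=t, ellipticity=theta)


def gen_cd_series(config):
    """Dispatch on config type: titration series or melting curve."""
    if isinstance(config, CdTitrationSimConfig):
        return gen_cd_titration(config)
    if isinstance(config, CdMeltSimConfig):
        return gen_cd_melt(config)
    raise TypeError(f"unsupported CD simulation config: {type(config).__name__}")
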