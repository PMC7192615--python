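"""Circular dichroism analysis of G-quadruplex folding.

Spectrum normalization to molar ellipticity per residue, tracking of the
parallel-G4 262 nm band during a protein titration (relative foldedness),
percent-decrease comparison between protein constructs, and two-state
van't Hoff thermal melting fits with sloped folded/unfolded baselines.
"""

from __future__ import annotations

import dataclasses

import lmfit
import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .binding import R_KCAL

__all__ = [
    "CDSpectrum",
    "MeltingCurve",
    "FoldednessCurve",
    "MeltFitResult",
    "TwoStateMeltModel",
    "molar_ellipticity_per_residue",
    "foldedness_curve",
    "percent_decrease_foldedness",
    "fit_melting",
    "two_state_ellipticity",
]

G4_BAND_NM = 262.0  # parallel G-quadruplex CD maximum


@dataclasses.dataclass(frozen=True)
class CDSpectrum:
    """One CD wavelength scan with its sample metadata.

    ``ellipticity`` is the raw machine signal in mdeg; ``conc`` the strand
    concentration in M, ``path`` the cuvette path length in cm,
    ``n_residues`` the nucleotides per strand, ``titrant_conc`` the added
    protein concentration in uM for titration series.
    """

    wavelengths: np.ndarray   # nm
    ellipticity: np.ndarray   # mdeg
    conc: float               # M strand
    path: float = 1.0         # cm
    n_residues: int = 24
    titrant_conc: float = 0.0  # uM

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        e = np.asarray(self.ellipticity, dtype=float)
        if w.shape != e.shape:
            raise ValueError("wavelength and ellipticity arrays differ in length")
        if self.conc <= 0 or self.path <= 0 or self.n_residues <= 0:
            raise ValueError("conc, path and n_residues must be positive")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "ellipticity", e)

    def at(self, wavelength: float, tol: float = 1.0) -> float:
        """Ellipticity at the sampled wavelength nearest the target (no interpolation)."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol:
            raise ValueError(
                f"no sampled wavelength within {tol} nm of {wavelength} nm"
            )
        return float(self.ellipticity[i])


@dataclasses.dataclass(frozen=True)
class MeltingCurve:
    """Ellipticity at a fixed wavelength versus temperature (C)."""

    temperature: np.ndarray   # C, strictly increasing
    ellipticity: np.ndarray   # mdeg
    wavelength: float = G4_BAND_NM

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        e = np.asarray(self.ellipticity, dtype=float)
        if t.shape != e.shape:
            raise ValueError("temperature and ellipticity arrays differ in length")
        if t.size < 20:
            raise ValueError("melting curve needs at least 20 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "ellipticity", e)


@dataclasses.dataclass(frozen=True)
class FoldednessCurve:
    """Relative foldedness (262 nm signal ratioed to the protein-free scan)."""

    titrant_conc: np.ndarray  # uM
    foldedness: np.ndarray    # dimensionless, 1 at zero titrant

    def interpolate(self, at_conc: float) -> float:
        c = np.asarray(self.titrant_conc)
        if at_conc < c.min() or at_conc > c.max():
            raise ValueError(f"{at_conc} uM outside measured range")
        return float(np.interp(at_conc, c, self.foldedness))


@dataclasses.dataclass
class MeltFitResult:
    """Two-state melting fit: midpoint, van't Hoff enthalpy, baselines."""

    tm: float                  # C
    tm_stderr: float | None
    dh_vanthoff: float         # kcal/mol
    dh_stderr: float | None
    theta_folded: float        # mdeg intercepts/slopes of the two baselines
    slope_folded: float
    theta_unfolded: float
    slope_unfolded: float
    residuals: np.ndarray
    redchi: float
    flags: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def molar_ellipticity_per_residue(spec: CDSpectrum) -> np.ndarray:
    """Molar ellipticity per residue, deg cm^2 dmol^-1.

    [theta] = theta_mdeg / (10 * path_cm * conc_M * n_residues).
    """
    return spec.ellipticity / (10.0 * spec.path * spec.conc * spec.n_residues)


def foldedness_curve(
    spectra: list[CDSpectrum],
    wavelength: float = G4_BAND_NM,
    tol: float = 1.0,
    unfolded_reference: CDSpectrum | None = None,
) -> FoldednessCurve:
    """Relative foldedness versus titrant concentration from a spectral series.

    F(c) = theta(c) / theta(0) at the G4 band (nearest sampled wavelength
    within ``tol`` nm). Values are not clipped: instrument noise can push F
    slightly above 1. If ``unfolded_reference`` is given, its band signal
    is used as the fully-unfolded offset and the ratio becomes
    (theta(c) - theta_u) / (theta(0) - theta_u) (min-max variant).
    """
    spectra = sorted(spectra, key=lambda s: s.titrant_conc)
    if not spectra or spectra[0].titrant_conc != 0:
        raise ValueError("a zero-titrant reference spectrum is required")
    theta_u = 0.0
    if unfolded_reference is not None:
        theta_u = unfolded_reference.at(wavelength, tol)
    ref = spectra[0].at(wavelength, tol) - theta_u
    if ref == 0:
        raise ValueError("reference band ellipticity is zero")
    concs = np.array([s.titrant_conc for s in spectra])
    fold = np.array(
        [(s.at(wavelength, tol) - theta_u) / ref for s in spectra]
    )
    return FoldednessCurve(titrant_conc=concs, foldedness=fold)


def percent_decrease_foldedness(
    curve_a: FoldednessCurve, curve_b: FoldednessCurve, at_conc: float
) -> float:
    """Percent decrease in foldedness of b relative to reference a.

    100 * (F_a - F_b) / F_a at ``at_conc`` (uM), linearly interpolating each
    curve. Used to compare the unfolding efficiency of two protein
    constructs at a common concentration (e.g. UP1+RGG versus UP1 at
    25 uM).
    """
    fa = curve_a.interpolate(at_conc)
    fb = curve_b.interpolate(at_conc)
    if fa == 0:
        raise ValueError("reference foldedness is zero; percent change undefined")
    return 100.0 * (fa - fb) / fa


def two_state_ellipticity(
    temperature_c,
    tm: float,
    dh_vanthoff: float,
    theta_folded: float,
    slope_folded: float,
    theta_unfolded: float,
    slope_unfolded: float,
):
    """Two-state melting model with sloped baselines.

    The folded fraction follows a van't Hoff equilibrium
    K_unf(T) = exp[(dH/R)(1/Tm - 1/T)] (T in K), f = 1/(1 + K_unf),
    so f(Tm) = 1/2; the observed signal is the f-weighted sum of linear
    folded and unfolded baselines evaluated at T in C.
    """
    t_c = np.asarray(temperature_c, dtype=float)
    t_k = t_c + 273.15
    tm_k = tm + 273.15
    k_unf = np.exp((dh_vanthoff / R_KCAL) * (1.0 / tm_k - 1.0 / t_k))
    f = 1.0 / (1.0 + k_unf)
    return (
        (theta_folded + slope_folded * t_c) * f
        + (theta_unfolded + slope_unfolded * t_c) * (1.0 - f)
    )


def _smoothed_derivative(t: np.ndarray, e: np.ndarray) -> np.ndarray:
    # window ~ 1/6 of the trace: heavy enough that point noise does not
    # dominate the derivative, still much narrower than a two-state
    # transition (tens of degrees at ~45 kcal/mol)
    window = int(np.clip(len(e) // 6, 5, 41))
    if window % 2 == 0:
        window += 1
    if len(e) > window:
        e = savgol_filter(e, window, 3)
    return np.gradient(e, t)


class TwoStateMeltModel(BaseEstimator):
    """Two-state van't Hoff melting fit of a fixed-wavelength CD trace.

    Fits (Tm, dH_vH) together with linear folded/unfolded baselines.
    Initialization places Tm at the extremum of the smoothed derivative and
    seeds the baselines from the first/last ``edge_fraction`` of points. A
    trace whose derivative peaks at an endpoint (no transition inside the
    scanned range) is flagged rather than fitted silently.

    Parameters
    ----------
    sloped_baselines : bool, default True
        If False both baseline slopes are fixed at zero (short traces).
    dh_init : float, default 45.0
        Initial van't Hoff enthalpy, kcal/mol.

    Attributes
    ----------
    tm_ : float
        Fitted midpoint, C (folded fraction = 1/2).
    dh_vanthoff_ : float
        Fitted van't Hoff enthalpy, kcal/mol.
    result_ : MeltFitResult
    """

    def __init__(
        self,
        sloped_baselines: bool = True,
        dh_init: float = 45.0,
        edge_fraction: float = 0.15,
    ):
        self.sloped_baselines = sloped_baselines
        self.dh_init = dh_init
        self.edge_fraction = edge_fraction

    def fit(self, X, y=None):
        """Fit a :class:`MeltingCurve`, or arrays (temperature_C, ellipticity)."""
        if isinstance(X, MeltingCurve):
            t, e = X.temperature, X.ellipticity
        else:
            t = np.asarray(X, dtype=float).ravel()
            e = np.asarray(y, dtype=float)

        flags: list[str] = []
        deriv = np.abs(_smoothed_derivative(t, e))
        i_max = int(np.argmax(deriv))
        edge = max(2, int(0.05 * len(t)))
        # a genuine transition shows a derivative peak well above the
        # baseline slopes and away from the scan edges
        med = float(np.median(deriv))
        prominent = deriv[i_max] > 5.0 * max(med, 1e-12)
        if i_max < edge or i_max >= len(t) - edge or not prominent:
            flags.append("no_transition")
        tm0 = float(t[i_max]) if "no_transition" not in flags else float(np.median(t))

        n_edge = max(3, int(self.edge_fraction * len(t)))
        cf = np.polyfit(t[:n_edge], e[:n_edge], 1)
        cu = np.polyfit(t[-n_edge:], e[-n_edge:], 1)

        params = lmfit.Parameters()
        params.add("tm", value=tm0, min=t.min() - 20, max=t.max() + 20)
        params.add("dh", value=self.dh_init, min=1.0, max=500.0)
        if self.sloped_baselines:
            params.add("theta_f", value=float(cf[1]))
            params.add("slope_f", value=float(cf[0]))
            params.add("theta_u", value=float(cu[1]))
            params.add("slope_u", value=float(cu[0]))
        else:
            params.add("theta_f", value=float(e[:n_edge].mean()))
            params.add("slope_f", value=0.0, vary=False)
            params.add("theta_u", value=float(e[-n_edge:].mean()))
            params.add("slope_u", value=0.0, vary=False)

        def residual(p):
            return (
                two_state_ellipticity(
                    t, p["tm"].value, p["dh"].value,
                    p["theta_f"].value, p["slope_f"].value,
                    p["theta_u"].value, p["slope_u"].value,
                )
                - e
            )

        out = lmfit.minimize(residual, params, method="least_squares")
        if not out.success:
            flags.append("not_converged")
        tm = float(out.params["tm"].value)
        if not (t.min() <= tm <= t.max()) and "no_transition" not in flags:
            flags.append("tm_outside_range")

        def se(name):
            s = out.params[name].stderr
            return float(s) if s is not None else None

        self.result_ = MeltFitResult(
            tm=tm, tm_stderr=se("tm"),
            dh_vanthoff=float(out.params["dh"].value), dh_stderr=se("dh"),
            theta_folded=float(out.params["theta_f"].value),
            slope_folded=float(out.params["slope_f"].value),
            theta_unfolded=float(out.params["theta_u"].value),
            slope_unfolded=float(out.params["slope_u"].value),
            residuals=np.asarray(out.residual), redchi=float(out.redchi),
            flags=flags,
        )
        self.tm_ = tm
        self.dh_vanthoff_ = self.result_.dh_vanthoff
        return self

    def predict(self, X):
        """Model ellipticity at temperatures X (C) for the fitted parameters."""
        r = self.result_
        return two_state_ellipticity(
            np.asarray(X, dtype=float),
            r.tm, r.dh_vanthoff, r.theta_folded, r.slope_folded,
            r.theta_unfolded, r.slope_unfolded,
        )


def fit_melting(curve: MeltingCurve, **kwargs) -> MeltFitResult:
    """Two-state melting fit; see :class:`TwoStateMeltModel`."""
    model = TwoStateMeltModel(**kwargs)
    model.fit(curve)
    return model.result_
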