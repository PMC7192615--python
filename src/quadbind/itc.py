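"""One-site isothermal titration calorimetry analysis.

Concentration bookkeeping for an overflow (perfusion) cell, the standard
single-site Wiseman isotherm for per-injection heats, heat-of-dilution
correction, and a least-squares fitter for (n, Kd, dH, baseline). Heats
are handled in ucal, normalized heats in kcal per mol of injectant,
concentrations in uM, volumes in ul.
"""

from __future__ import annotations

import dataclasses
import logging

import lmfit
import numpy as np
from sklearn.base import BaseEstimator

from .binding import Thermodynamics, delta_g_from_kd, fraction_protein_bound, tds_from_dh_dg

__all__ = [
    "InjectionSchedule",
    "ItcIsotherm",
    "ItcFitResult",
    "OneSiteItcModel",
    "build_isotherm",
    "one_site_heats",
    "fit_one_site",
    "correct_heat_of_dilution",
    "integrate_thermogram",
    "derive_thermodynamics",
]

logger = logging.getLogger(__name__)

# ucal per (uM * ul * kcal/mol): 1e-6 mol/L * 1e-6 L * kcal/mol = 1e-12 kcal
_UCAL_PER_UM_UL_KCAL = 1e-3


@dataclasses.dataclass(frozen=True)
class InjectionSchedule:
    """Geometry of an overflow-cell ITC experiment.

    The macromolecule (here: RNA) sits in the cell at ``cell_conc`` uM; the
    titrant (protein) is injected from the syringe at ``syringe_conc`` uM in
    the listed ``injections`` volumes (ul). ``spacing`` (s) is metadata only.
    """

    cell_volume: float          # ul
    cell_conc: float            # uM macromolecule in cell
    syringe_conc: float         # uM titrant in syringe
    injections: tuple[float, ...]  # ul per injection
    temperature: float = 298.15    # K
    spacing: float = 180.0         # s, metadata

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if any(v <= 0 for v in self.injections):
            raise ValueError("injection volumes must be positive")

    @property
    def cumulative_volumes(self) -> np.ndarray:
        return np.cumsum(self.injections)


def _cell_concentrations(schedule: InjectionSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Titrant and macromolecule concentration in the cell after each injection.

    Overflow-cell bookkeeping with the conventional dV/2V0 perfusion
    approximation: injected volume displaces an equal volume of (averaged)
    cell contents, giving, at cumulative injected volume dV,

        [M] = M0 (1 - dV/2V0) / (1 + dV/2V0)
        [X] = X_syr (dV/V0) / (1 + dV/2V0)

    This matches the treatment in vendor fitting software; it differs from
    exact stepwise exponential dilution by <1% for typical schedules
    (40 ul total into a 200 ul cell).
    """
    v0 = schedule.cell_volume
    dv = schedule.cumulative_volumes
    if dv[-1] > v0:
        logger.warning(
            "cumulative injected volume %.1f ul exceeds cell volume %.1f ul",
            dv[-1], v0,
        )
    mt = schedule.cell_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
    xt = schedule.syringe_conc * (dv / v0) / (1 + dv / (2 * v0))
    return xt, mt


@dataclasses.dataclass(frozen=True)
class ItcIsotherm:
    """Per-injection state of an ITC run: concentrations, ratios and heats."""

    schedule: InjectionSchedule
    titrant_cell: np.ndarray      # uM, after each injection
    macromol_cell: np.ndarray     # uM
    molar_ratio: np.ndarray       # titrant / macromolecule
    heats: np.ndarray             # observed ucal per injection
    normalized_heats: np.ndarray  # kcal per mol of injectant

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.molar_ratio) > 0):
            raise ValueError("molar ratio must be strictly increasing")
        if not np.all(np.isfinite(self.normalized_heats)):
            raise ValueError("normalized heats must be finite")


@dataclasses.dataclass
class ItcFitResult:
    """One-site fit: stoichiometry, Kd, enthalpy, baseline, diagnostics.

    ``c`` is the Wiseman parameter n * [cell] / Kd; fits with c < 1 carry a
    ``"low_c"`` flag — the isotherm is then too shallow to constrain n and
    Kd independently with confidence.
    """

    n: float
    kd: float                 # uM
    dH: float                 # kcal/mol
    baseline: float           # kcal per mol injectant
    n_stderr: float | None
    kd_stderr: float | None
    dH_stderr: float | None
    baseline_stderr: float | None
    c: float
    residuals: np.ndarray
    redchi: float
    flags: list[str] = dataclasses.field(default_factory=list)
    thermodynamics: Thermodynamics | None = None

    @property
    def ok(self) -> bool:
        return "not_converged" not in self.flags


def build_isotherm(
    schedule: InjectionSchedule, heats: np.ndarray
) -> ItcIsotherm:
    """Assemble an :class:`ItcIsotherm` from a schedule and observed heats (ucal)."""
    heats = np.asarray(heats, dtype=float)
    if len(heats) != len(schedule.injections):
        raise ValueError("one heat per injection required")
    xt, mt = _cell_concentrations(schedule)
    dv = np.asarray(schedule.injections)
    moles_factor = schedule.syringe_conc * dv  # uM*ul per injection
    ndh = heats / (moles_factor * _UCAL_PER_UM_UL_KCAL)  # kcal/mol injectant
    return ItcIsotherm(
        schedule=schedule,
        titrant_cell=xt,
        macromol_cell=mt,
        molar_ratio=xt / mt,
        heats=heats,
        normalized_heats=ndh,
    )


def one_site_heats(
    schedule: InjectionSchedule,
    n: float,
    kd: float,
    dH: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """Predicted normalized heats (kcal/mol injectant) for a one-site model.

    The cumulative heat content of the cell after injection i is

        Q_i = n [M]_i V0 dH f_i

    with f_i the fraction of sites occupied from the exact 1:1 quadratic
    (site concentration n[M]_i, titrant [X]_i). The differential heat adds
    back the heat carried out by the displaced volume,

        dQ_i = Q_i - Q_{i-1} + (dV_i / V0)(Q_i + Q_{i-1}) / 2,

    and is normalized by the moles of titrant in injection i. ``baseline``
    is a constant offset per mole of injectant (residual dilution heat).
    """
    if n <= 0 or kd <= 0:
        raise ValueError("n and kd must be positive")
    xt, mt = _cell_concentrations(schedule)
    sites = n * mt
    f = fraction_protein_bound(p_total=sites, l_total=xt, kd=kd)
    q = sites * f * schedule.cell_volume * dH  # uM*ul*kcal/mol
    dv = np.asarray(schedule.injections)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (dv / schedule.cell_volume) * (q + q_prev) / 2.0
    moles_factor = schedule.syringe_conc * dv  # uM*ul
    return dq / moles_factor + baseline


def correct_heat_of_dilution(
    isotherm: ItcIsotherm,
    mode: str = "tail_average",
    control: ItcIsotherm | None = None,
    k: int = 3,
) -> ItcIsotherm:
    """Subtract the heat of dilution from an isotherm.

    mode="control_titration" subtracts a matched titrant-into-buffer control
    injection-by-injection (normalized heats); mode="tail_average" subtracts
    the mean of the last ``k`` (default 3) post-saturation normalized heats.
    """
    ndh = isotherm.normalized_heats
    if mode == "control_titration":
        if control is None:
            raise ValueError("control isotherm required")
        if len(control.normalized_heats) != len(ndh):
            raise ValueError("control and sample isotherm lengths differ")
        corrected = ndh - control.normalized_heats
    elif mode == "tail_average":
        if k < 1 or k > len(ndh):
            raise ValueError("invalid tail length")
        corrected = ndh - ndh[-k:].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dv = np.asarray(isotherm.schedule.injections)
    moles_factor = isotherm.schedule.syringe_conc * dv
    heats = corrected * moles_factor * _UCAL_PER_UM_UL_KCAL
    return dataclasses.replace(
        isotherm, heats=heats, normalized_heats=corrected
    )


class OneSiteItcModel(BaseEstimator):
    """Least-squares one-site fit of an ITC isotherm.

    All four parameters (n, Kd, dH, baseline) float, as is conventional.
    Initialization: n0 at the molar ratio of steepest heat change, dH0 from
    the first usable heat, Kd0 at the cell concentration.

    Parameters
    ----------
    discard_first : bool, default False
        Drop the first injection from the residuals (syringe-tip diffusion
        artifact); the point is retained in the isotherm itself.
    fit_baseline : bool, default True
        If False the baseline is fixed at 0 (e.g. after dilution
        correction).

    Attributes
    ----------
    n_, kd_, dh_, baseline_ : float
        Fitted parameters (kd_ in uM, dh_ in kcal/mol).
    c_ : float
        Wiseman c = n * cell_conc / Kd of the fitted parameters.
    result_ : ItcFitResult
    """

    def __init__(
        self,
        discard_first: bool = False,
        fit_baseline: bool = True,
        kd_bounds: tuple[float, float] = (1e-4, 1e4),
        n_bounds: tuple[float, float] = (0.05, 10.0),
    ):
        self.discard_first = discard_first
        self.fit_baseline = fit_baseline
        self.kd_bounds = kd_bounds
        self.n_bounds = n_bounds

    def fit(self, X: ItcIsotherm, y=None):
        """Fit the one-site model to an :class:`ItcIsotherm`."""
        iso = X
        ndh = iso.normalized_heats
        schedule = iso.schedule
        usable = np.ones(len(ndh), dtype=bool)
        if self.discard_first:
            usable[0] = False
        if usable.sum() < 6:
            raise ValueError("need at least 6 usable injections")

        ratio = iso.molar_ratio
        slopes = np.abs(np.diff(ndh[usable]))
        steepest = int(np.argmax(slopes))
        n0 = float(np.clip(ratio[usable][steepest], *self.n_bounds))
        dh0 = float(ndh[usable][0] - ndh[usable][-1])
        if dh0 == 0:
            dh0 = -1.0
        kd0 = float(np.clip(schedule.cell_conc, *self.kd_bounds))

        params = lmfit.Parameters()
        params.add("n", value=n0, min=self.n_bounds[0], max=self.n_bounds[1])
        params.add("kd", value=kd0, min=self.kd_bounds[0], max=self.kd_bounds[1])
        params.add("dH", value=dh0)
        params.add("baseline", value=float(ndh[-3:].mean()),
                   vary=self.fit_baseline)

        def residual(pars):
            model = one_site_heats(
                schedule, pars["n"].value, pars["kd"].value,
                pars["dH"].value, pars["baseline"].value,
            )
            return (model - ndh)[usable]

        out = lmfit.minimize(residual, params, method="least_squares")

        flags: list[str] = []
        if not out.success:
            flags.append("not_converged")
        n = float(out.params["n"].value)
        kd = float(out.params["kd"].value)
        c = n * schedule.cell_conc / kd
        if c < 1:
            flags.append("low_c")

        def se(name):
            s = out.params[name].stderr
            return float(s) if s is not None else None

        self.result_ = ItcFitResult(
            n=n, kd=kd, dH=float(out.params["dH"].value),
            baseline=float(out.params["baseline"].value),
            n_stderr=se("n"), kd_stderr=se("kd"), dH_stderr=se("dH"),
            baseline_stderr=se("baseline"),
            c=c, residuals=np.asarray(out.residual),
            redchi=float(out.redchi), flags=flags,
        )
        self.n_, self.kd_ = n, kd
        self.dh_ = self.result_.dH
        self.baseline_ = self.result_.baseline
        self.c_ = c
        return self

    def predict(self, X: InjectionSchedule | ItcIsotherm) -> np.ndarray:
        """Predicted normalized heats for a schedule at the fitted parameters."""
        schedule = X.schedule if isinstance(X, ItcIsotherm) else X
        return one_site_heats(schedule, self.n_, self.kd_, self.dh_, self.baseline_)


def fit_one_site(
    isotherm: ItcIsotherm, discard_first: bool = False, **kwargs
) -> ItcFitResult:
    """One-site fit of an isotherm; see :class:`OneSiteItcModel`."""
    model = OneSiteItcModel(discard_first=discard_first, **kwargs)
    model.fit(isotherm)
    return model.result_


def integrate_thermogram(
    time_s: np.ndarray,
    power: np.ndarray,
    injection_times: np.ndarray,
    pre_window: float = 10.0,
) -> np.ndarray:
    """Per-injection heats (ucal) from a raw power trace (ucal/s).

    Secondary input path for instruments exporting thermograms instead of
    integrated heats. Each injection window runs from its injection time
    to the next (or the end of the trace); a linear baseline is drawn
    between the mean power over the ``pre_window`` seconds preceding the
    window start and preceding its end, and the baseline-subtracted power
    is integrated by the trapezoidal rule. Assumes injection peaks relax
    back to baseline within the injection spacing.
    """
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(power, dtype=float)
    inj = np.sort(np.asarray(injection_times, dtype=float))
    if inj[0] <= t[0] or inj[-1] >= t[-1]:
        raise ValueError("injection times must lie inside the trace")
    edges = np.concatenate([inj, [t[-1]]])

    def level_before(t_end: float) -> float:
        mask = (t >= t_end - pre_window) & (t < t_end)
        if not mask.any():
            raise ValueError(f"no samples in the {pre_window} s before t={t_end}")
        return float(p[mask].mean())

    heats = np.empty(len(inj))
    for i in range(len(inj)):
        t0, t1 = edges[i], edges[i + 1]
        # half-open window: the sample at t1 already carries the next
        # injection's onset
        mask = (t >= t0) & ((t < t1) if i < len(inj) - 1 else (t <= t1))
        b0, b1 = level_before(t0), level_before(t1)
        # each mean represents the baseline at its averaging-window
        # midpoint; anchoring there keeps a drifting baseline unbiased
        a0, a1 = t0 - pre_window / 2, t1 - pre_window / 2
        baseline = b0 + (b1 - b0) * (t[mask] - a0) / (a1 - a0)
        heats[i] = np.trapezoid(p[mask] - baseline, t[mask])
    return heats


def derive_thermodynamics(
    fit: ItcFitResult, temperature: float = 298.15
) -> Thermodynamics:
    """Complete a one-site fit with dG = RT ln Kd and TdS = dH - dG."""
    dG = delta_g_from_kd(fit.kd, temperature)
    thermo = Thermodynamics(
        kd=fit.kd, dG=dG, dH=fit.dH, TdS=tds_from_dh_dg(fit.dH, dG),
        temperature=temperature, n=fit.n,
    )
    fit.thermodynamics = thermo
    return thermo
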