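"""Closed-form 1:1 binding mathematics and thermodynamic relations.

These are the shared primitives of the package: the ligand-depletion
(quadratic) binding isotherm used to model fast-exchange NMR chemical shift
perturbation titrations, and the standard-state thermodynamic identities
(dG = RT ln Kd, TdS = dH - dG) used to complete one-site ITC results.

All concentrations entering the binding math share one unit (micromolar is
the package canonical); unit conversion is the caller's responsibility.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "R_KCAL",
    "STANDARD_STATE_UM",
    "BindingState",
    "Thermodynamics",
    "fraction_protein_bound",
    "csp_predicted",
    "delta_g_from_kd",
    "tds_from_dh_dg",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: 1 M standard state expressed in the package's canonical uM unit.
STANDARD_STATE_UM = 1.0e6

# sqrt arguments of the quadratic isotherm can dip below zero by round-off
# when p ~ l and kd -> 0; anything more negative than this is a logic error.
_SQRT_CLAMP_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class BindingState:
    """A 1:1 equilibrium: total protein, total ligand, dissociation constant.

    All three fields share one concentration unit (uM canonical).
    """

    p_total: float
    l_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.p_total < 0 or self.l_total < 0:
            raise ValueError("total concentrations must be non-negative")
        if self.kd < 0:
            raise ValueError("kd must be non-negative")


@dataclasses.dataclass(frozen=True)
class Thermodynamics:
    """One-site binding thermodynamics at a stated temperature.

    kd is in uM; dG, dH and TdS in kcal/mol; temperature in K; n is the
    binding stoichiometry (sites per macromolecule). The fields satisfy
    dG = dH - TdS and dG = RT ln(kd / 1 M) up to experimental rounding.
    """

    kd: float
    dG: float
    dH: float
    TdS: float
    temperature: float = 298.15
    n: float = 1.0

    def identity_residuals(self) -> tuple[float, float]:
        """Return (dG - (dH - TdS), dG - RT ln Kd) in kcal/mol."""
        return (
            self.dG - (self.dH - self.TdS),
            self.dG - delta_g_from_kd(self.kd, self.temperature),
        )


def fraction_protein_bound(
    state: BindingState | None = None,
    *,
    p_total: float | np.ndarray | None = None,
    l_total: float | np.ndarray | None = None,
    kd: float | np.ndarray | None = None,
):
    """Fraction of total protein bound under 1:1 ligand depletion.

    Solves the exact mass balance for a single-site equilibrium
    P + L <=> PL with dissociation constant ``kd``:

        f = (p + l + kd - sqrt((p + l + kd)^2 - 4 p l)) / (2 p)

    This is the bracketed term of the depletion isotherm divided by the
    total protein concentration; no excess-ligand approximation is made,
    which matters when protein and ligand concentrations are comparable
    (e.g. 138 uM protein titrated with sub-stoichiometric RNA).

    Accepts either a :class:`BindingState` or keyword arrays; broadcasting
    follows numpy rules. Returns values in [0, 1].
    """
    if state is not None:
        p_total, l_total, kd = state.p_total, state.l_total, state.kd
    p = np.asarray(p_total, dtype=float)
    l = np.asarray(l_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p_total must be positive")
    if np.any(k <= 0):
        raise ValueError("kd must be positive")
    if np.any(l < 0):
        raise ValueError("l_total must be non-negative")
    s = p + l + k
    disc = s * s - 4.0 * p * l
    # round-off can push the discriminant slightly negative at kd -> 0, p ~ l
    disc = np.where(disc < 0, 0.0, disc)
    # conjugate form of (s - sqrt(disc)) / 2p: avoids cancellation when the
    # bound fraction is small (e.g. the p -> 0 Langmuir limit)
    f = 2.0 * l / (s + np.sqrt(disc))
    out = np.clip(f, 0.0, 1.0)
    if np.ndim(out) == 0:
        return float(out)
    return out


def csp_predicted(
    state: BindingState | None = None,
    ddmax: float | np.ndarray = 0.0,
    **kwargs,
):
    """Predicted combined chemical shift perturbation under fast exchange.

    In the fast-exchange regime the observed peak position is the
    population-weighted average of free and bound positions, so the
    observed CSP is the maximal (fully saturated) CSP ``ddmax`` scaled by
    the fraction of protein bound:

        dd_obs = ddmax * f_bound(p_total, l_total, kd)

    ``ddmax`` is in ppm (combined 1H/15N statistic or any single
    dimension); concentrations as in :func:`fraction_protein_bound`.
    """
    dd = np.asarray(ddmax, dtype=float)
    if np.any(dd < 0):
        raise ValueError("ddmax must be non-negative")
    res = dd * fraction_protein_bound(state, **kwargs)
    if np.ndim(res) == 0:
        return float(res)
    return res


def delta_g_from_kd(kd, temperature: float = 298.15):
    """Standard binding free energy dG = RT ln(Kd / 1 M), in kcal/mol.

    ``kd`` is in uM (1 M standard state); ``temperature`` in K. Negative for
    sub-molar dissociation constants, zero at exactly 1 M.
    """
    k = np.asarray(kd, dtype=float)
    if np.any(k <= 0):
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    out = R_KCAL * temperature * np.log(k / STANDARD_STATE_UM)
    if np.ndim(out) == 0:
        return float(out)
    return out


def tds_from_dh_dg(dH, dG):
    """Entropic term TdS = dH - dG (kcal/mol), exact subtraction."""
    out = np.asarray(dH, dtype=float) - np.asarray(dG, dtype=float)
    if np.ndim(out) == 0:
        return float(out)
    return out


def kd_from_delta_g(dG: float, temperature: float = 298.15) -> float:
    """Inverse of :func:`delta_g_from_kd`; returns Kd in uM."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return float(STANDARD_STATE_UM * math.exp(dG / (R_KCAL * temperature)))
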