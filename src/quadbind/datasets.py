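"""Reference values for hnRNPA1 / TERRA G-quadruplex binding.

Published one-site ITC thermodynamic parameters for the hnRNPA1 UP1 domain,
the UP1+RGG construct and the isolated RGG-box binding single-stranded RNA
and TERRA RNA G-quadruplexes, together with the NMR-derived dissociation
constants and CD melting temperatures used throughout the documentation and
the recovery tests. These serve as realistic ground-truth parameter sets
for the synthetic-data generators and as fixtures for the thermodynamic
identity checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "itc_thermodynamics_table",
    "RGG_TERRA24_GLOBAL_KD_UM",
    "RGG_TERRA24_GLOBAL_KD_SE_UM",
    "RGG_TEL22_KD_UM",
    "TERRA24_TM_C",
    "TEL22_TM_C",
    "CSP_INDIVIDUAL_KD_RANGE_UM",
    "CD_TITRATION_STEPS_UM",
    "NMR_PROTEIN_TOTAL_UM",
    "NMR_MOLAR_RATIOS",
]

# Columns: experiment label, Kd (uM) +/- SE, dG, dH, TdS (kcal/mol) +/- SE,
# stoichiometry n +/- SE.  Measured at 25 C.  The TdS entry of the
# UP1:TERRA-24 row is inconsistent with dH - dG as printed in the original
# report (a typographical error); `tds_consistent` flags rows whose printed
# TdS satisfies TdS = dH - dG within 0.02 kcal/mol.
_ITC_ROWS = [
    # label,                      kd,   kd_se, dG,    dG_se, dH,     dH_se, TdS,    TdS_se, n,    n_se, tds_ok
    ("UP1:ssRNA-18",              2.37, 0.49, -7.67, 1.58, -19.70, 1.23, -12.03, 2.81, 1.04, 0.05, True),
    ("UP1+RGG:ssRNA-18",          2.28, 0.26, -7.69, 0.86, -20.40, 0.71, -12.71, 1.57, 0.97, 0.03, True),
    ("UP1:TERRA-6",               2.02, 0.17, -7.76, 0.64, -31.31, 1.40, -23.55, 2.04, 1.22, 0.04, True),
    ("UP1+RGG:TERRA-6",           2.38, 0.23, -7.66, 0.75, -38.84, 2.74, -31.18, 3.48, 1.14, 0.07, True),
    ("UP1:TERRA-12",              2.04, 0.47, -7.75, 1.77, -36.38, 5.61, -28.63, 7.38, 0.93, 0.12, True),
    ("UP1+RGG:TERRA-12",          1.07, 0.14, -8.13, 1.08, -43.01, 2.48, -34.88, 3.56, 0.88, 0.04, True),
    ("UP1:TERRA-24",              1.71, 0.17, -7.86, 0.76, -29.66, 0.95, -37.52, 1.70, 0.80, 0.02, False),
    ("UP1+RGG:TERRA-24",          0.92, 0.17, -8.23, 1.53, -41.88, 2.81, -33.65, 4.34, 0.82, 0.04, True),
    ("UP1+RGG:TERRA-24 (20% PEG 200)", 3.00, 0.55, -7.53, 1.40, -40.89, 4.15, -33.36, 5.55, 1.14, 0.09, True),
    ("RGG:TERRA-24",              9.00, 4.30, -6.88, 3.31, -0.67, 0.27, 6.21, 3.58, 1.06, 0.34, True),
]

_ITC_COLUMNS = [
    "experiment", "kd_uM", "kd_se_uM", "dG_kcal", "dG_se_kcal",
    "dH_kcal", "dH_se_kcal", "TdS_kcal", "TdS_se_kcal",
    "n", "n_se", "tds_consistent",
]


def itc_thermodynamics_table() -> pd.DataFrame:
    """Reference ITC thermodynamics for hnRNPA1 constructs at 25 C.

    Returns a DataFrame with one row per protein-nucleic-acid pair:
    dissociation constant, free energy, enthalpy, entropic term (all with
    standard errors) and stoichiometry for UP1, UP1+RGG and the isolated
    RGG-box binding ssRNA-18 and the tetrameric (TERRA-6), dimeric
    (TERRA-12) and intramolecular (TERRA-24) TERRA G-quadruplexes.
    """
    return pd.DataFrame(_ITC_ROWS, columns=_ITC_COLUMNS)


#: Global shared-Kd of the isolated RGG-box binding the intramolecular
#: TERRA-24 RNA G-quadruplex from NMR CSP titration (uM).
RGG_TERRA24_GLOBAL_KD_UM = 11.0
RGG_TERRA24_GLOBAL_KD_SE_UM = 1.5

#: Reported range of per-residue apparent Kds in the same titration (uM).
CSP_INDIVIDUAL_KD_RANGE_UM = (3.0, 18.0)

#: RGG-box binding the Tel22 telomeric DNA G-quadruplex (uM); ~31-fold
#: weaker than TERRA-24 RNA G-quadruplex binding.
RGG_TEL22_KD_UM = 349.0

#: CD melting midpoints of the intramolecular G-quadruplexes (C).
TERRA24_TM_C = 80.5
TEL22_TM_C = 68.0

#: CD protein-titration schedule (uM added protein) for 5 uM RNA.
CD_TITRATION_STEPS_UM = (0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0)

#: NMR CSP titration design: 15N-labelled RGG-box concentration (uM) and
#: protein:RNA molar ratios at successive steps.
NMR_PROTEIN_TOTAL_UM = 138.0
NMR_MOLAR_RATIOS = (0.0, 0.2, 0.5, 1.0, 2.0, 3.0)
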