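"""Calibration constants of the fucoxanthin assay and the fits that produce them.

The assay rests on four groups of constants:

* specific extinction coefficients (L/g/cm) of fucoxanthin and Chl a at
  the two analytical wavelengths, fitted from dilution series of purified
  standards (Beer-Lambert standard curves, through the origin);
* the two background regressions n1, n2 — residual non-target absorbance
  at 445 and 663 nm as a linear function of A750 (intercept included:
  there is a cell-free offset);
* the closed-form whole-cell formula obtained by substituting n1 and n2
  into the extract formula and collecting terms in A445, A663, A750;
* per-wavelength plate-reader-to-cuvette scale factors for 96-well
  microplate measurements (200 uL, ~0.5 cm path).

The package ships the published P. tricornutum constants as defaults
(provenance ``"published"``).  Re-deriving the A663 coefficient from
the extinction coefficients gives 5.20 rather than the published 5.18;
both are available, the published value is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ExtinctionCoefficient",
    "BackgroundModel",
    "AssayFormula",
    "PlateCalibration",
    "PUBLISHED_EPS_FUC_445",
    "PUBLISHED_EPS_CHLA_445",
    "PUBLISHED_EPS_CHLA_663",
    "PUBLISHED_BG_445",
    "PUBLISHED_BG_663",
    "PUBLISHED_FORMULA",
    "DEFAULT_PLATE_CALIBRATION",
    "fit_extinction",
    "convert_specific_extinction",
    "fit_background",
    "derive_extract_formula",
    "expand_whole_cell_formula",
    "plate_to_cuvette",
    "cuvette_to_plate",
    "fit_plate_calibration",
]


class SingularFitError(ValueError):
    """Raised when a regression design is degenerate (no unique fit)."""


@dataclass(frozen=True)
class ExtinctionCoefficient:
    """Pigment-, wavelength- and solvent-specific absorptivity (L/g/cm)."""

    pigment: str
    wavelength: float  # nm
    solvent: str
    value: float
    source: str = "literature"  # {"literature", "fitted"}
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"extinction coefficient must be > 0, got {self.value}")


@dataclass(frozen=True)
class BackgroundModel:
    """Linear model of non-target absorbance vs A750 at one wavelength."""

    wavelength: float  # nm
    slope: float  # AU per AU(A750)
    intercept: float  # AU
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    def evaluate(self, a750: float) -> float:
        return self.slope * a750 + self.intercept

    __call__ = evaluate


@dataclass(frozen=True)
class AssayFormula:
    """Closed-form linear fucoxanthin rule over (A445, A663, A750).

    Evaluates ``coef_a445*A445 - coef_a663*A663 + coef_a750*A750 + constant``
    in mg/L; ``coef_a663`` is stored as the positive magnitude of the
    subtracted Chl a term.
    """

    coef_a445: float
    coef_a663: float
    coef_a750: float = 0.0
    constant: float = 0.0
    provenance: str = "derived"  # {"published", "derived"}

    def evaluate(self, a445: float, a663: float, a750: float = 0.0) -> float:
        return (
            self.coef_a445 * a445
            - self.coef_a663 * a663
            + self.coef_a750 * a750
            + self.constant
        )

    __call__ = evaluate


@dataclass(frozen=True)
class PlateCalibration:
    """Per-wavelength plate-reader/cuvette scale factors (plate / cuvette)."""

    scales: dict[float, float] = field(
        default_factory=lambda: {445.0: 0.504, 663.0: 0.497, 750.0: 0.444}
    )
    nominal_path: float = 0.5  # cm

    def __post_init__(self) -> None:
        for wl, s in self.scales.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"scale at {wl} nm must be in (0, 1], got {s}")

    def scale(self, wavelength: float) -> float:
        try:
            return self.scales[float(wavelength)]
        except KeyError:
            raise KeyError(
                f"no calibration at {wavelength} nm; calibrated wavelengths: "
                + ", ".join(str(w) for w in sorted(self.scales))
            ) from None


# --- published constants -----------------------------------------------------

PUBLISHED_EPS_FUC_445 = ExtinctionCoefficient("fucoxanthin", 445.0, "ethanol", 156.54)
PUBLISHED_EPS_CHLA_445 = ExtinctionCoefficient("chl_a", 445.0, "80pct_acetone", 66.8)
PUBLISHED_EPS_CHLA_663 = ExtinctionCoefficient("chl_a", 663.0, "80pct_acetone", 82.04)
PUBLISHED_BG_445 = BackgroundModel(445.0, 0.14, 1.0, r_squared=0.9968)
PUBLISHED_BG_663 = BackgroundModel(663.0, 0.233, 0.217, r_squared=0.9962)
#: The published whole-cell formula; canonical default for P. tricornutum.
PUBLISHED_FORMULA = AssayFormula(6.39, 5.18, 0.312, -5.27, provenance="published")
DEFAULT_PLATE_CALIBRATION = PlateCalibration()


# --- fitting -----------------------------------------------------------------


def fit_extinction(
    dilution_table,
    pigment: str = "unknown",
    wavelength: float = float("nan"),
    solvent: str = "ethanol",
    through_origin: bool = True,
) -> ExtinctionCoefficient:
    """Fit a Beer-Lambert standard curve and return the coefficient in L/g/cm.

    ``dilution_table`` is an iterable of (concentration mg/L, absorbance AU)
    pairs or a DataFrame whose first two columns are those.  The OLS slope
    (AU per mg/L) is multiplied by 1000 to express the coefficient per g/L.
    """
    arr = np.asarray(dilution_table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("expected (concentration, absorbance) pairs")
    c, a = arr[:, 0], arr[:, 1]
    if np.unique(c).size < 2:
        raise SingularFitError("need >= 2 distinct concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if through_origin:
        slope = float(c @ a / (c @ c))
        resid = a - slope * c
        tss = float(a @ a)  # uncentred total SS, the through-origin convention
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    else:
        fit = stats.linregress(c, a)
        slope = float(fit.slope)
        r2 = float(fit.rvalue**2)
    return ExtinctionCoefficient(
        pigment, wavelength, solvent, slope * 1000.0, source="fitted",
        r_squared=min(max(r2, 0.0), 1.0),
    )


def convert_specific_extinction(e_one_percent: float) -> float:
    """Convert a 1% (w/v, g/100 mL) extinction coefficient to L/g/cm.

    1% w/v is 10 g/L, so the specific coefficient is the 1% value / 10.
    """
    if e_one_percent <= 0:
        raise ValueError(f"1% extinction must be > 0, got {e_one_percent}")
    return e_one_percent / 10.0


def fit_background(pairs, wavelength: float) -> BackgroundModel:
    """OLS fit of residual absorbance vs A750 at one wavelength.

    ``pairs`` iterates (A750, residual absorbance).  Intercept included:
    the residual has a cell-free offset.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (A750, residual) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise SingularFitError("A750 values must not all be equal")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.std(y) > 0 else 1.0
    return BackgroundModel(wavelength, float(fit.slope), float(fit.intercept), r2)


# --- formula algebra ---------------------------------------------------------


def derive_extract_formula(
    eps_fuc_445: ExtinctionCoefficient | float,
    eps_chla_445: ExtinctionCoefficient | float,
    eps_chla_663: ExtinctionCoefficient | float,
) -> AssayFormula:
    """Derive the extract-based unmixing coefficients from extinction coefficients.

    Solving the two-wavelength Beer-Lambert system for the fucoxanthin
    concentration (mg/L) gives ``C = (1000/e_f445)*A445 -
    (1000*e_a445/(e_a663*e_f445))*A663``.  With the published coefficients
    this evaluates to 6.39 and 5.20; the published formula prints 5.18.
    """
    f445 = eps_fuc_445.value if isinstance(eps_fuc_445, ExtinctionCoefficient) else float(eps_fuc_445)
    a445 = eps_chla_445.value if isinstance(eps_chla_445, ExtinctionCoefficient) else float(eps_chla_445)
    a663 = eps_chla_663.value if isinstance(eps_chla_663, ExtinctionCoefficient) else float(eps_chla_663)
    for v in (f445, a445, a663):
        if v <= 0:
            raise ValueError("extinction coefficients must be > 0")
    return AssayFormula(
        coef_a445=1000.0 / f445,
        coef_a663=1000.0 * a445 / (a663 * f445),
        provenance="derived",
    )


def expand_whole_cell_formula(
    coef_a445: float,
    coef_a663: float,
    bg445: BackgroundModel,
    bg663: BackgroundModel,
    provenance: str = "derived",
) -> AssayFormula:
    """Substitute the background regressions into the extract formula.

    ``C = c445*(A445 - n1(A750)) - c663*(A663 - n2(A750))`` collected in
    the three absorbances gives an A750 coefficient of
    ``c663*slope663 - c445*slope445`` and a constant of
    ``c663*intercept663 - c445*intercept445``.  Arithmetic is kept at full
    precision; rounding to the published 0.312 / -5.27 is presentational.
    """
    if not np.isclose(bg445.wavelength, 445.0):
        raise ValueError(f"bg445 is calibrated at {bg445.wavelength} nm, expected 445")
    if not np.isclose(bg663.wavelength, 663.0):
        raise ValueError(f"bg663 is calibrated at {bg663.wavelength} nm, expected 663")
    return AssayFormula(
        coef_a445=coef_a445,
        coef_a663=coef_a663,
        coef_a750=coef_a663 * bg663.slope - coef_a445 * bg445.slope,
        constant=coef_a663 * bg663.intercept - coef_a445 * bg445.intercept,
        provenance=provenance,
    )


# --- microplate --------------------------------------------------------------


def plate_to_cuvette(
    reading: float,
    wavelength: float,
    calib: PlateCalibration = DEFAULT_PLATE_CALIBRATION,
) -> float:
    """Convert a 96-well plate reading to its 1 cm cuvette equivalent."""
    return reading / calib.scale(wavelength)


def cuvette_to_plate(
    reading: float,
    wavelength: float,
    calib: PlateCalibration = DEFAULT_PLATE_CALIBRATION,
) -> float:
    """Inverse of :func:`plate_to_cuvette`."""
    return reading * calib.scale(wavelength)


def fit_plate_calibration(
    pairs_by_wavelength: dict[float, "np.ndarray | list"],
    nominal_path: float = 0.5,
) -> PlateCalibration:
    """Fit through-origin plate-vs-cuvette scale factors per wavelength.

    ``pairs_by_wavelength`` maps wavelength to (cuvette AU, plate AU) pairs.
    """
    scales: dict[float, float] = {}
    for wl, pairs in pairs_by_wavelength.items():
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"need >= 2 pairs at {wl} nm")
        cuv, plate = arr[:, 0], arr[:, 1]
        denom = float(cuv @ cuv)
        if denom == 0.0:
            raise SingularFitError(f"all-zero cuvette readings at {wl} nm")
        scales[float(wl)] = float(cuv @ plate / denom)
    return PlateCalibration(scales=scales, nominal_path=nominal_path)
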