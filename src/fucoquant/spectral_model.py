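"""Synthetic diatom absorbance spectra.

Generates the data the whole-cell fucoxanthin assay consumes: visible
absorbance spectra (400-800 nm) of mixed pigments built from Gaussian
bands, an OD750-indexed scattering/background baseline, dilution series
of purified standards, and paired culture-medium/ethanol readings.

Pigment bands are anchored so that the absorbance of a 1 g/L solution
over a 1 cm path at each anchor wavelength equals the pigment's specific
extinction coefficient (L/g/cm).  Chlorophyll a is anchored at both
663 nm (82.04, the Arnon coefficient) and 445 nm (66.8); fucoxanthin at
445 nm (156.54).  Non-target pigments (Chl c, diatoxanthin, beta-carotene)
carry placeholder bands: in intact cells their contribution, together
with cell debris, is modelled by the OD750-indexed background term, which
is how the assay itself treats them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DEFAULT_GRID",
    "PigmentBand",
    "Spectrum",
    "SyntheticCulture",
    "CultureReadings",
    "BAND_LIBRARY",
    "pigment_extinction",
    "pigment_spectrum",
    "scattering_baseline",
    "simulate_culture_readings",
    "dilution_series",
    "simulate_dataset",
]

#: 400-800 nm at 1 nm steps: the full visible scan range of the method.
DEFAULT_GRID: np.ndarray = np.arange(400.0, 801.0, 1.0)

#: Default additive Gaussian noise on a single absorbance reading (AU).
DEFAULT_NOISE_SD: float = 0.005


@dataclass(frozen=True)
class PigmentBand:
    """One Gaussian absorbance band of a pigment.

    ``relative_height`` is in specific-absorbance units (L/g/cm): the
    contribution of this band, at its centre, to the absorbance of a
    1 g/L solution over a 1 cm path.
    """

    pigment: str
    center: float  # nm
    width: float  # Gaussian sigma, nm
    relative_height: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.relative_height <= 0:
            raise ValueError(
                f"band height must be > 0, got {self.relative_height}"
            )

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Specific absorbance of this band on ``grid`` (per g/L per cm)."""
        g = np.asarray(grid, dtype=float)
        return self.relative_height * np.exp(
            -0.5 * ((g - self.center) / self.width) ** 2
        )


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    absorbances: np.ndarray
    medium: str = "ethanol"  # {"ethanol", "aqueous"}
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.ndim != 1 or ab.shape != wl.shape:
            raise ValueError("wavelengths and absorbances must be 1-D, same length")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbances must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    def at(self, wavelength: float) -> float:
        """Absorbance at ``wavelength``; linear interpolation off-grid."""
        return float(np.interp(wavelength, self.wavelengths, self.absorbances))


# --- band library -----------------------------------------------------------
#
# Shapes: (center nm, sigma nm, raw height).  Anchors: (wavelength nm,
# specific extinction L/g/cm) the scaled pigment must reproduce exactly.
# Only the fucoxanthin and Chl a anchors are constrained by the assay;
# the remaining shapes are free parameters of the generator.

_SHAPES: dict[str, list[tuple[float, float, float]]] = {
    "fucoxanthin": [(445.0, 45.0, 1.0)],
    "chl_a": [(430.0, 22.0, 1.0), (663.0, 11.0, 1.0)],
    "chl_c": [(444.0, 20.0, 1.0), (630.0, 12.0, 0.15)],
    "diatoxanthin": [(452.0, 25.0, 1.0)],
    "beta_carotene": [(452.0, 30.0, 1.0)],
}

_ANCHORS: dict[str, list[tuple[float, float]]] = {
    "fucoxanthin": [(445.0, 156.54)],
    "chl_a": [(445.0, 66.8), (663.0, 82.04)],
    "chl_c": [(444.0, 40.0)],
    "diatoxanthin": [(452.0, 120.0)],
    "beta_carotene": [(452.0, 250.0)],
}


def _scale_bands(pigment: str) -> list[PigmentBand]:
    """Scale raw band shapes so the anchors are met exactly.

    One anchor: uniform scaling of all heights.  As many anchors as bands:
    heights solved from the square linear system anchor-by-anchor, so the
    configured extinction coefficients hold to machine precision.
    """
    shapes = _SHAPES[pigment]
    anchors = _ANCHORS[pigment]
    centers = np.array([s[0] for s in shapes])
    sigmas = np.array([s[1] for s in shapes])
    raw = np.array([s[2] for s in shapes])
    wl = np.array([a[0] for a in anchors])
    eps = np.array([a[1] for a in anchors])
    # design[i, j] = response of band j at anchor wavelength i
    design = raw * np.exp(-0.5 * ((wl[:, None] - centers[None, :]) / sigmas) ** 2)
    if len(anchors) == len(shapes):
        heights = raw * np.linalg.solve(design, eps)
    else:
        heights = raw * float(eps[0] / design[0].sum())
    return [
        PigmentBand(pigment, c, s, h)
        for c, s, h in zip(centers, sigmas, heights)
    ]


BAND_LIBRARY: dict[str, list[PigmentBand]] = {
    name: _scale_bands(name) for name in _SHAPES
}


def _require_pigment(pigment: str) -> list[PigmentBand]:
    try:
        return BAND_LIBRARY[pigment]
    except KeyError:
        raise KeyError(
            f"unknown pigment {pigment!r}; available: "
            + ", ".join(sorted(BAND_LIBRARY))
        ) from None


def pigment_extinction(pigment: str, wavelength: float) -> float:
    """Specific extinction coefficient (L/g/cm) of ``pigment`` at ``wavelength``."""
    bands = _require_pigment(pigment)
    return float(sum(b.profile(np.array([wavelength]))[0] for b in bands))


def pigment_spectrum(
    pigment: str,
    concentration: float,
    grid: np.ndarray = DEFAULT_GRID,
    path_length: float = 1.0,
) -> Spectrum:
    """Beer-Lambert spectrum of a pure pigment solution in ethanol.

    Parameters
    ----------
    pigment
        Name in the band library.
    concentration
        mg/L; absorbance is exactly linear in it.
    grid
        Wavelength grid (nm).
    path_length
        Optical path in cm.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    bands = _require_pigment(pigment)
    g = np.asarray(grid, dtype=float)
    specific = np.sum([b.profile(g) for b in bands], axis=0)
    ab = (concentration / 1000.0) * specific * path_length
    return Spectrum(g, ab, medium="ethanol", path_length=path_length)


# --- scattering / background baseline ---------------------------------------

# Paper-derived anchor regressions: residual (non-fucoxanthin, non-Chl a)
# absorbance vs A750.  Imported lazily to avoid a module cycle with
# calibration, which re-exports these as BackgroundModel defaults.
_N1 = (0.14, 1.0)  # slope, intercept at 445 nm
_N2 = (0.233, 0.217)  # at 663 nm


def scattering_baseline(
    od750: float,
    grid: np.ndarray = DEFAULT_GRID,
    n1: tuple[float, float] = _N1,
    n2: tuple[float, float] = _N2,
) -> Spectrum:
    """Background spectrum of a whole-cell suspension at cell density ``od750``.

    Anchored exactly at the three wavelengths the assay reads: value
    ``n1[0]*od750 + n1[1]`` at 445 nm, ``n2[0]*od750 + n2[1]`` at 663 nm,
    and ``od750`` itself at 750 nm.  Between anchors the shape is a
    shape-preserving PCHIP interpolant; it is monotone wherever the
    anchors are (they are not for od750 above ~0.28, where scattering at
    750 nm exceeds the residual absorbance at 663 nm) and is otherwise
    an arbitrary smooth choice, unconstrained by the assay.
    """
    if od750 < 0:
        raise ValueError(f"od750 must be >= 0, got {od750}")
    g = np.asarray(grid, dtype=float)
    v445 = n1[0] * od750 + n1[1]
    v663 = n2[0] * od750 + n2[1]
    v750 = od750
    # end anchors extend the adjacent trends so PCHIP stays well-behaved
    v400 = v445 + (v445 - v663) * (45.0 / 218.0)
    v800 = 0.9 * v750
    interp = PchipInterpolator(
        [400.0, 445.0, 663.0, 750.0, 800.0],
        [v400, v445, v663, v750, v800],
        extrapolate=True,
    )
    return Spectrum(g, interp(g), medium="aqueous", path_length=1.0)


# --- whole cultures ----------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCulture:
    """Ground-truth description of one simulated diatom culture.

    ``concentrations`` maps pigment name to mg/L.  Non-target pigments
    default to absent because their whole-cell contribution is carried by
    the OD750-indexed background term (as the assay assumes); giving them
    explicit non-zero values injects absorbance the assay cannot remove.
    """

    concentrations: dict[str, float] = field(
        default_factory=lambda: {"fucoxanthin": 10.0, "chl_a": 5.0}
    )
    cell_density_od750: float = 0.4
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        for name, conc in self.concentrations.items():
            _require_pigment(name)
            if conc < 0:
                raise ValueError(f"negative concentration for {name}: {conc}")
        if self.cell_density_od750 < 0:
            raise ValueError("cell_density_od750 must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CultureReadings:
    """The three readings the whole-cell assay takes on one culture."""

    a445_ethanol: float
    a663_ethanol: float
    a750_medium: float


def _mixture_absorbance(concentrations: dict[str, float], wavelength: float) -> float:
    return sum(
        (conc / 1000.0) * pigment_extinction(name, wavelength)
        for name, conc in concentrations.items()
    )


def simulate_culture_readings(
    culture: SyntheticCulture,
    n1: tuple[float, float] = _N1,
    n2: tuple[float, float] = _N2,
) -> CultureReadings:
    """Simulate the paired readings for one culture.

    A445/A663 are measured on cells resuspended in ethanol: pigment
    mixture plus the OD750-indexed background, plus i.i.d. Gaussian
    noise.  A750 is measured on the culture in its medium.  Fixed seed
    gives identical triples.
    """
    rng = np.random.default_rng(culture.seed)
    od = culture.cell_density_od750
    noise = rng.normal(0.0, culture.noise_sd, size=3) if culture.noise_sd > 0 else np.zeros(3)
    a445 = _mixture_absorbance(culture.concentrations, 445.0) + n1[0] * od + n1[1] + noise[0]
    a663 = _mixture_absorbance(culture.concentrations, 663.0) + n2[0] * od + n2[1] + noise[1]
    a750 = od + noise[2]
    return CultureReadings(float(a445), float(a663), float(a750))


def dilution_series(
    pigment: str,
    concentrations: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Absorbance of a purified-standard dilution series at 445 and 663 nm.

    Returns a DataFrame with columns ``concentration_mg_per_L``, ``a445``,
    ``a663``; absorbances are linear in concentration up to noise.
    """
    if len(concentrations) == 0:
        raise ValueError("concentrations list must not be empty")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    e445 = pigment_extinction(pigment, 445.0)
    e663 = pigment_extinction(pigment, 663.0)
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, noise_sd, size=(conc.size, 2))
        if noise_sd > 0
        else np.zeros((conc.size, 2))
    )
    return pd.DataFrame(
        {
            "concentration_mg_per_L": conc,
            "a445": conc / 1000.0 * e445 + noise[:, 0],
            "a663": conc / 1000.0 * e663 + noise[:, 1],
        }
    )


def simulate_dataset(
    n_samples: int,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a batch of cultures as a long-format readings table.

    Fucoxanthin is drawn uniformly from 1-20 mg/L, Chl a from 2-10 mg/L
    and OD750 from 0.1-0.8 (the assay's stated working range).  Returns
    ``(readings, truth)``: readings with columns sample_id, wavelength_nm,
    absorbance, medium, path_length_cm, dilution_factor; truth with
    sample_id, pigment, concentration_mg_per_L.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for i in range(n_samples):
        sample = f"S{i + 1:03d}"
        fuc = rng.uniform(1.0, 20.0)
        chl = rng.uniform(2.0, 10.0)
        od = rng.uniform(0.1, 0.8)
        culture = SyntheticCulture(
            concentrations={"fucoxanthin": fuc, "chl_a": chl},
            cell_density_od750=od,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        r = simulate_culture_readings(culture)
        rows += [
            (sample, 445.0, r.a445_ethanol, "ethanol", 1.0, 1.0),
            (sample, 663.0, r.a663_ethanol, "ethanol", 1.0, 1.0),
            (sample, 750.0, r.a750_medium, "culture_medium", 1.0, 1.0),
        ]
        truth_rows += [
            (sample, "fucoxanthin", fuc),
            (sample, "chl_a", chl),
        ]
    readings = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "wavelength_nm",
            "absorbance",
            "medium",
            "path_length_cm",
            "dilution_factor",
        ],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "pigment", "concentration_mg_per_L"]
    )
    return readings, truth
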