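"""Pigment quantification: Arnon Chl a, extract and whole-cell fucoxanthin.

The whole-cell path is the method's product: readings are first
multiplied by their dilution factors (cultures are diluted with medium
for A750 and with ethanol for A445/A663 to land in the instrument's
valid windows), then the closed-form linear formula is applied.
Readings outside the recommended measurement windows (A750 in [0.1, 0.8],
A445/A663 in [0.2, 1]) are flagged, not rejected; negative estimates are
reported with a flag, never clamped, so that validation statistics stay
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import PUBLISHED_FORMULA, AssayFormula

__all__ = [
    "ARNON_EPS_663",
    "A750_WINDOW",
    "PIGMENT_WINDOW",
    "ConcentrationResult",
    "chl_a_arnon",
    "fucoxanthin_extract",
    "fucoxanthin_whole_cell",
    "batch_quantify",
]

#: Arnon specific extinction coefficient of Chl a at 663 nm (L/g/cm).
ARNON_EPS_663 = 82.04

#: Recommended measured-value windows (AU), from the assay protocol.
A750_WINDOW = (0.1, 0.8)
PIGMENT_WINDOW = (0.2, 1.0)


@dataclass(frozen=True)
class ConcentrationResult:
    """A pigment concentration in mg per litre of original culture."""

    sample_id: str
    pigment: str
    concentration: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration):
            raise ValueError("concentration must be finite")


def chl_a_arnon(a663: float) -> float:
    """Chl a concentration (mg/L) from A663 via the Arnon coefficient."""
    if a663 < 0:
        raise ValueError(f"absorbance must be >= 0, got {a663}")
    return 1000.0 * a663 / ARNON_EPS_663


def fucoxanthin_extract(
    a445: float,
    a663: float,
    formula: AssayFormula = PUBLISHED_FORMULA,
    sample_id: str = "sample",
) -> ConcentrationResult:
    """Fucoxanthin (mg/L) in a clarified ethanol extract, two-wavelength unmixing.

    Uses only the A445/A663 terms of ``formula`` (no background correction:
    cell debris was removed by centrifugation before reading).
    """
    if a445 < 0 or a663 < 0:
        raise ValueError("absorbances must be >= 0")
    conc = formula.coef_a445 * a445 - formula.coef_a663 * a663
    flags = frozenset({"negative_estimate"}) if conc < 0 else frozenset()
    return ConcentrationResult(sample_id, "fucoxanthin", float(conc), flags)


def _window_flags(measured: float, window: tuple[float, float]) -> set[str]:
    if measured < window[0]:
        return {"below_range"}
    if measured > window[1]:
        return {"above_range"}
    return set()


def fucoxanthin_whole_cell(
    a445_ethanol: float,
    a663_ethanol: float,
    a750_medium: float,
    assay: AssayFormula = PUBLISHED_FORMULA,
    dilution_445: float = 1.0,
    dilution_663: float = 1.0,
    dilution_750: float = 1.0,
    extract_ratio: float = 1.0,
    sample_id: str = "sample",
) -> ConcentrationResult:
    """Whole-cell fucoxanthin (mg/L of original culture), background-corrected.

    Parameters
    ----------
    a445_ethanol, a663_ethanol
        Absorbance of the cell suspension in ethanol, as measured (i.e.
        after any dilution with ethanol).
    a750_medium
        Absorbance of the culture in its medium, as measured.
    assay
        The closed-form formula; defaults to the published P. tricornutum
        constants.
    dilution_445, dilution_663, dilution_750
        Per-channel dilution factors (total volume / sample volume, >= 1);
        measured values are multiplied by them to reconstruct undiluted
        absorbances before the formula is applied.
    extract_ratio
        Extract-to-culture volume ratio.  The default 1.0 matches the
        protocol (cells from a volume of culture resuspended in an equal
        volume of ethanol), in which case no volume correction applies.
    """
    readings = {
        "A445": (a445_ethanol, dilution_445),
        "A663": (a663_ethanol, dilution_663),
        "A750": (a750_medium, dilution_750),
    }
    for name, (value, dil) in readings.items():
        if value is None or not np.isfinite(value):
            raise ValueError(f"missing or non-finite reading for channel {name}")
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
        if dil < 1.0:
            raise ValueError(f"dilution factor for {name} must be >= 1, got {dil}")

    flags: set[str] = set()
    flags |= _window_flags(a445_ethanol, PIGMENT_WINDOW)
    flags |= _window_flags(a663_ethanol, PIGMENT_WINDOW)
    flags |= _window_flags(a750_medium, A750_WINDOW)

    conc = assay.evaluate(
        a445_ethanol * dilution_445,
        a663_ethanol * dilution_663,
        a750_medium * dilution_750,
    ) * extract_ratio
    if conc < 0:
        flags.add("negative_estimate")
    return ConcentrationResult(sample_id, "fucoxanthin", float(conc), frozenset(flags))


_CHANNELS = {445.0: "A445", 663.0: "A663", 750.0: "A750"}


def batch_quantify(
    readings: pd.DataFrame,
    assay: AssayFormula = PUBLISHED_FORMULA,
    extract_ratio: float = 1.0,
) -> pd.DataFrame:
    """Quantify every sample in a long-format readings table.

    ``readings`` needs columns sample_id, wavelength_nm, absorbance and
    dilution_factor (missing dilution_factor defaults to 1).  Each sample
    must contribute one reading per channel (445, 663, 750 nm); samples
    with an incomplete or duplicated triple get an error record and the
    batch continues.  Output columns: sample_id, pigment,
    concentration_mg_per_L, flags (semicolon-joined), error; ordered by
    sample_id.
    """
    required = {"sample_id", "wavelength_nm", "absorbance"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings table missing columns: {sorted(missing)}")
    df = readings.copy()
    if "dilution_factor" not in df.columns:
        df["dilution_factor"] = 1.0

    out = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        channels: dict[str, tuple[float, float]] = {}
        error = ""
        for _, row in grp.iterrows():
            wl = float(row["wavelength_nm"])
            name = _CHANNELS.get(wl)
            if name is None:
                continue  # other wavelengths may ride along in the table
            if name in channels:
                error = f"duplicate reading for channel {name}"
                break
            channels[name] = (float(row["absorbance"]), float(row["dilution_factor"]))
        if not error:
            absent = sorted(set(_CHANNELS.values()) - set(channels))
            if absent:
                error = "missing channel(s): " + ", ".join(absent)
        if error:
            out.append((str(sample_id), "fucoxanthin", np.nan, "", error))
            continue
        try:
            res = fucoxanthin_whole_cell(
                channels["A445"][0],
                channels["A663"][0],
                channels["A750"][0],
                assay=assay,
                dilution_445=channels["A445"][1],
                dilution_663=channels["A663"][1],
                dilution_750=channels["A750"][1],
                extract_ratio=extract_ratio,
                sample_id=str(sample_id),
            )
        except ValueError as exc:
            out.append((str(sample_id), "fucoxanthin", np.nan, "", str(exc)))
            continue
        out.append(
            (res.sample_id, res.pigment, res.concentration,
             ";".join(sorted(res.flags)), "")
        )
    return pd.DataFrame(
        out,
        columns=["sample_id", "pigment", "concentration_mg_per_L", "flags", "error"],
    )
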