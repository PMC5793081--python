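"""CSV readers/writers and the calibration config file.

All interchange is plain comma-separated UTF-8 with a header row and "."
decimals.  Numeric fields are serialised at full precision (repr round
trip) so a write-then-read cycle is bit-exact.  Calibration constants
are stored as JSON with one documented entry per constant (value, units,
provenance).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import pandas as pd

from .calibration import (
    DEFAULT_PLATE_CALIBRATION,
    AssayFormula,
    PlateCalibration,
    plate_to_cuvette,
)

__all__ = [
    "READINGS_COLUMNS",
    "read_readings_csv",
    "write_readings_csv",
    "read_plate_csv",
    "read_plate_layout_csv",
    "save_calibration",
    "load_calibration",
]

log = logging.getLogger("fucoquant")

READINGS_COLUMNS = [
    "sample_id",
    "wavelength_nm",
    "absorbance",
    "medium",
    "path_length_cm",
    "dilution_factor",
]

_MEDIA = {"ethanol", "culture_medium"}
_WELL_RE = re.compile(r"^([A-H])(1[0-2]|[1-9])$")


def _check_numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        # +2: header is line 1, first data row line 2
        row = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: non-numeric {column} {df[column][bad.idxmax()]!r} at row {row}"
        )
    if values.isna().any():
        row = int(values.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing {column} at row {row}")
    return values.astype(float)


def read_readings_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format absorbance readings table.

    Required columns: sample_id, wavelength_nm, absorbance, medium,
    path_length_cm, dilution_factor.  Errors name the offending row
    (header = row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(READINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        log.warning("%s: readings file has a header but no rows", path)
        return pd.DataFrame(columns=READINGS_COLUMNS)
    df = df.reset_index(drop=True)
    out = pd.DataFrame({"sample_id": df["sample_id"].astype(str)})
    for col in ("wavelength_nm", "absorbance", "path_length_cm", "dilution_factor"):
        out[col] = _check_numeric(df, col, path)
    medium = df["medium"].astype(str)
    bad = ~medium.isin(_MEDIA)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: unknown medium {medium[bad.idxmax()]!r} at row {row}; "
            f"expected one of {sorted(_MEDIA)}"
        )
    out["medium"] = medium
    if (out["dilution_factor"] < 1).any():
        row = int((out["dilution_factor"] < 1).idxmax()) + 2
        raise ValueError(f"{path}: dilution_factor < 1 at row {row}")
    if (out["path_length_cm"] <= 0).any():
        row = int((out["path_length_cm"] <= 0).idxmax()) + 2
        raise ValueError(f"{path}: non-positive path_length_cm at row {row}")
    return out[READINGS_COLUMNS]


def write_readings_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a readings table; floats at full repr precision."""
    df.to_csv(path, index=False, float_format=None)


def normalize_well(well: str) -> str:
    """Validate and normalise an 8x12 plate coordinate (a1 -> A1)."""
    w = str(well).strip().upper()
    if not _WELL_RE.match(w):
        raise ValueError(f"invalid well coordinate {well!r} (expected A1..H12)")
    return w


def read_plate_layout_csv(path: str | Path) -> pd.DataFrame:
    """Read a well -> sample map: columns well, sample_id[, medium, dilution_factor]."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    need = {"well", "sample_id"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: layout needs columns {sorted(need)}")
    df = df.reset_index(drop=True)
    df["well"] = [normalize_well(w) for w in df["well"]]
    dup = df["well"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate well assignment(s): "
            + ", ".join(sorted(df['well'][dup].unique()))
        )
    if "medium" not in df.columns:
        df["medium"] = "ethanol"
    if "dilution_factor" in df.columns:
        df["dilution_factor"] = pd.to_numeric(df["dilution_factor"])
    else:
        df["dilution_factor"] = 1.0
    return df


def read_plate_csv(
    path: str | Path,
    layout: pd.DataFrame,
    calib: PlateCalibration = DEFAULT_PLATE_CALIBRATION,
    pre_corrected: bool = False,
) -> pd.DataFrame:
    """Read a generic plate export and return cuvette-equivalent readings.

    The export has columns well, wavelength_nm, absorbance.  Every well
    with data must be mapped in ``layout``; mapped wells without data are
    only warned about.  Unless ``pre_corrected`` (instrument software
    already path-corrected), each value is divided by the per-wavelength
    plate/cuvette scale.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    need = {"well", "wavelength_nm", "absorbance"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: plate export needs columns {sorted(need)}")
    if df.empty:
        return pd.DataFrame(columns=READINGS_COLUMNS)
    df = df.reset_index(drop=True)
    df["well"] = [normalize_well(w) for w in df["well"]]
    df["wavelength_nm"] = _check_numeric(df, "wavelength_nm", path)
    df["absorbance"] = _check_numeric(df, "absorbance", path)

    mapped = dict(zip(layout["well"], layout.index))
    unmapped = sorted(set(df["well"]) - set(mapped))
    if unmapped:
        raise ValueError(f"{path}: data in unmapped well(s): {', '.join(unmapped)}")
    silent = sorted(set(mapped) - set(df["well"]))
    if silent:
        log.warning("%s: mapped well(s) without data: %s", path, ", ".join(silent))

    rows = []
    for _, r in df.iterrows():
        lay = layout.loc[mapped[r["well"]]]
        value = float(r["absorbance"])
        if not pre_corrected:
            value = plate_to_cuvette(value, float(r["wavelength_nm"]), calib)
        rows.append(
            (
                str(lay["sample_id"]),
                float(r["wavelength_nm"]),
                value,
                str(lay["medium"]),
                1.0,  # cuvette-equivalent after correction
                float(lay["dilution_factor"]),
            )
        )
    return pd.DataFrame(rows, columns=READINGS_COLUMNS)


# --- calibration config ------------------------------------------------------


def save_calibration(
    formula: AssayFormula,
    path: str | Path,
    plate: PlateCalibration | None = None,
    extra: dict | None = None,
) -> None:
    """Write assay constants to a JSON config, one documented key each."""
    doc = {
        "assay_formula": {
            "coef_a445": {"value": formula.coef_a445, "units": "mg/L per AU"},
            "coef_a663": {
                "value": formula.coef_a663,
                "units": "mg/L per AU",
                "note": "positive magnitude of the subtracted Chl a term",
            },
            "coef_a750": {"value": formula.coef_a750, "units": "mg/L per AU"},
            "constant": {"value": formula.constant, "units": "mg/L"},
            "provenance": formula.provenance,
        },
    }
    if plate is not None:
        doc["plate_calibration"] = {
            "scales": {str(int(w)): s for w, s in sorted(plate.scales.items())},
            "units": "plate AU / cuvette AU",
            "nominal_path_cm": plate.nominal_path,
        }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_calibration(path: str | Path) -> tuple[AssayFormula, PlateCalibration | None]:
    """Load assay constants written by :func:`save_calibration`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    f = doc["assay_formula"]
    formula = AssayFormula(
        coef_a445=float(f["coef_a445"]["value"]),
        coef_a663=float(f["coef_a663"]["value"]),
        coef_a750=float(f["coef_a750"]["value"]),
        constant=float(f["constant"]["value"]),
        provenance=str(f.get("provenance", "derived")),
    )
    plate = None
    if "plate_calibration" in doc:
        p = doc["plate_calibration"]
        plate = PlateCalibration(
            scales={float(w): float(s) for w, s in p["scales"].items()},
            nominal_path=float(p.get("nominal_path_cm", 0.5)),
        )
    return formula, plate
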