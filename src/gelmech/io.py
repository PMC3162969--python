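"""CSV/JSON readers and writers for the package's record types.

All numeric CSV output uses full double precision (Python's shortest
round-trip float repr), so write -> read is exactly identity.

Formats
-------
records  : time_s, m1x, m1y, m2x, m2y, m3x, m3y, m4x, m4y, load_x_g, load_y_g
curves   : axis, strain, stress_kPa
tangent  : axis, strain, Et_kPa
sweep    : mode, abscissa, G_storage_Pa, G_loss_Pa (+ JSON metadata sidecar)
params   : JSON object with keys C10_kPa, k1_kPa, k2, gamma_deg, kappa
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .biaxial import BiaxialRecord, MarkerQuad
from .curves import StressStrainCurve, TangentModulusCurve
from .errors import FormatError
from .goh import MaterialParams
from .rheometry import OscillatorySweep

RECORD_COLUMNS = ["time_s", "m1x", "m1y", "m2x", "m2y", "m3x", "m3y", "m4x", "m4y",
                  "load_x_g", "load_y_g"]
CURVE_COLUMNS = ["axis", "strain", "stress_kPa"]
TANGENT_COLUMNS = ["axis", "strain", "Et_kPa"]
SWEEP_COLUMNS = ["mode", "abscissa", "G_storage_Pa", "G_loss_Pa"]


def _read_csv(path, expected: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # parse failure is a format error
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected header {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    return df


def write_records_csv(path, records: Sequence[BiaxialRecord]) -> None:
    rows = []
    for r in records:
        rows.append([r.time_s, *r.markers.points.ravel(), r.load_x_g, r.load_y_g])
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> list[BiaxialRecord]:
    df = _read_csv(path, RECORD_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        vals = np.asarray(row, dtype=float)
        records.append(
            BiaxialRecord(
                time_s=float(vals[0]),
                markers=MarkerQuad(vals[1:9].reshape(4, 2)),
                load_x_g=float(vals[9]),
                load_y_g=float(vals[10]),
            )
        )
    return records


def write_curves_csv(path, curves: Sequence[StressStrainCurve]) -> None:
    frames = [
        pd.DataFrame({"axis": c.axis, "strain": c.strain, "stress_kPa": c.stress_kPa})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path) -> list[StressStrainCurve]:
    df = _read_csv(path, CURVE_COLUMNS)
    curves = []
    for axis in df["axis"].unique():
        sub = df[df["axis"] == axis]
        curves.append(
            StressStrainCurve(str(axis), sub["strain"].to_numpy(),
                              sub["stress_kPa"].to_numpy())
        )
    return curves


def read_curve_pair(path) -> tuple[StressStrainCurve, StressStrainCurve]:
    curves = {c.axis: c for c in read_curves_csv(path)}
    if set(curves) != {"x", "y"}:
        raise FormatError(f"{path}: expected exactly axes 'x' and 'y', got {sorted(curves)}")
    return curves["x"], curves["y"]


def write_tangent_csv(path, curves: Sequence[TangentModulusCurve]) -> None:
    frames = [
        pd.DataFrame({"axis": c.axis, "strain": c.strain, "Et_kPa": c.Et_kPa})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tangent_csv(path) -> list[TangentModulusCurve]:
    df = _read_csv(path, TANGENT_COLUMNS)
    return [
        TangentModulusCurve(sub["strain"].to_numpy(), sub["Et_kPa"].to_numpy(),
                            axis=str(axis))
        for axis, sub in df.groupby("axis", sort=False)
    ]


def write_sweep_csv(path, sweep: OscillatorySweep, *, sidecar: bool = True) -> None:
    pd.DataFrame(
        {"mode": sweep.mode, "abscissa": sweep.abscissa,
         "G_storage_Pa": sweep.G_storage_Pa, "G_loss_Pa": sweep.G_loss_Pa}
    ).to_csv(path, index=False)
    if sidecar:
        Path(str(path) + ".meta.json").write_text(
            json.dumps(dict(sweep.metadata), indent=2, sort_keys=True) + "\n"
        )


def read_sweep_csv(path) -> OscillatorySweep:
    df = _read_csv(path, SWEEP_COLUMNS)
    modes = df["mode"].unique()
    if len(modes) != 1:
        raise FormatError(f"{path}: sweep must have a single mode, got {list(modes)}")
    meta_path = Path(str(path) + ".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return OscillatorySweep(
        str(modes[0]), df["abscissa"].to_numpy(), df["G_storage_Pa"].to_numpy(),
        df["G_loss_Pa"].to_numpy(), metadata=metadata,
    )


def params_to_dict(params: MaterialParams) -> dict:
    return {"C10_kPa": params.C10, "k1_kPa": params.k1, "k2": params.k2,
            "gamma_deg": params.gamma_deg, "kappa": params.kappa}


def write_params_json(path, params: MaterialParams) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=2, sort_keys=True) + "\n")


def read_params_json(path) -> MaterialParams:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse JSON {path}: {exc}") from exc
    required = {"C10_kPa", "k1_kPa", "k2", "gamma_deg", "kappa"}
    missing = required - set(obj)
    if missing:
        raise FormatError(f"{path}: missing parameter keys {sorted(missing)}")
    return MaterialParams(C10=obj["C10_kPa"], k1=obj["k1_kPa"], k2=obj["k2"],
                          gamma_deg=obj["gamma_deg"], kappa=obj["kappa"])
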