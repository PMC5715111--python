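"""File readers and writers.

On-disk units follow lab convention (nm, nN, degrees, mPa·s); everything in
memory is SI.  Readers validate and reject malformed input rather than
coercing it; every accepted file re-serialises losslessly to within double
precision.

Schemas
-------
sweeps CSV        ``gap_height_nm,frequency_hz,phase_rad[,amplitude_au]`` (long format)
calibration JSON  ``{"spring_constant_N_per_m", "bead_radius_um",
                  "fluid_viscosity_mPa_s"[, "f_far_hz", "drive_amplitude_nm"]}``
force-curve CSV   ``separation_nm,force_nN``
geometry CSV      ``pair_id,l_nm,l1_nm..l4_nm,theta1_deg..theta4_deg``
profile CSV       ``position_nm,intensity_au``
results JSON      tagged dataclass dump with provenance metadata
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    CantileverCalibration,
    ForceCurve,
    FrequencySweep,
    HertzFitResult,
    IntensityProfile,
    JunctionGeometry,
    SweepSeries,
    TensionFitResult,
    ViscosityResult,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

NM = 1e-9
UM = 1e-6
NN = 1e-9
MPA_S = 1e-3

_SWEEP_COLUMNS = ["gap_height_nm", "frequency_hz", "phase_rad"]
_GEOMETRY_COLUMNS = [
    "pair_id",
    "l_nm",
    "l1_nm",
    "l2_nm",
    "l3_nm",
    "l4_nm",
    "theta1_deg",
    "theta2_deg",
    "theta3_deg",
    "theta4_deg",
]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a parseable CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_calibration(path: str | Path) -> CantileverCalibration:
    """Load a probe calibration record from JSON."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    try:
        k_c = float(payload["spring_constant_N_per_m"])
        radius = float(payload["bead_radius_um"]) * UM
        mu = float(payload["fluid_viscosity_mPa_s"]) * MPA_S
    except KeyError as exc:
        raise FormatError(f"{path}: missing calibration key {exc}") from exc
    f_far = payload.get("f_far_hz")
    amp = payload.get("drive_amplitude_nm")
    return CantileverCalibration(
        spring_constant=k_c,
        bead_radius=radius,
        fluid_viscosity=mu,
        f_far=float(f_far) if f_far is not None else None,
        drive_amplitude=float(amp) * NM if amp is not None else None,
    )


def write_calibration(calib: CantileverCalibration, path: str | Path) -> None:
    payload = {
        "spring_constant_N_per_m": calib.spring_constant,
        "bead_radius_um": calib.bead_radius / UM,
        "fluid_viscosity_mPa_s": calib.fluid_viscosity / MPA_S,
    }
    if calib.f_far is not None:
        payload["f_far_hz"] = calib.f_far
    if calib.drive_amplitude is not None:
        payload["drive_amplitude_nm"] = calib.drive_amplitude / NM
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_sweep_series(
    path: str | Path,
    calib_path: str | Path,
    phase_increasing: bool = False,
) -> SweepSeries:
    """Read a long-format sweep CSV plus its calibration JSON.

    Gaps are sorted farthest-first and the largest gap becomes the
    reference.  Each sweep must bracket the pi/2 phase; ``phase_increasing``
    negates phases about pi/2 on load for instruments whose phase grows
    through resonance.
    """
    calibration = read_calibration(calib_path)
    df = _read_csv(path, _SWEEP_COLUMNS)
    has_amp = "amplitude_au" in df.columns

    sweeps: list[FrequencySweep] = []
    for gap_nm, group in df.groupby("gap_height_nm", sort=False):
        freqs = group["frequency_hz"].to_numpy(dtype=float)
        phases = group["phase_rad"].to_numpy(dtype=float)
        if phase_increasing:
            phases = np.pi - phases
        sweep = FrequencySweep(
            gap_height=float(gap_nm) * NM,
            frequencies=freqs,
            phases=phases,
            amplitudes=group["amplitude_au"].to_numpy(dtype=float) if has_amp else None,
        )
        if not sweep.crosses_half_pi():
            raise ValidationError(
                f"{path}: phase record at gap {gap_nm:g} nm never crosses pi/2; "
                "the pi/2 resonance cannot be extracted from it"
            )
        sweeps.append(sweep)
        logger.info("loaded sweep at %g nm (%d samples)", gap_nm, len(freqs))

    if not sweeps:
        raise FormatError(f"{path}: file contains no sweep rows")
    reference_gap = max(s.gap_height for s in sweeps)
    series = SweepSeries(calibration=calibration, sweeps=sweeps, reference_gap=reference_gap)
    logger.info(
        "sweep series: %d gaps, reference %.0f nm", len(sweeps), reference_gap / NM
    )
    return series


def write_sweep_series(series: SweepSeries, path: str | Path) -> None:
    rows = []
    for sweep in series.sweeps:
        frame = {
            "gap_height_nm": sweep.gap_height / NM,
            "frequency_hz": sweep.frequencies,
            "phase_rad": sweep.phases,
        }
        if sweep.amplitudes is not None:
            frame["amplitude_au"] = sweep.amplitudes
        rows.append(pd.DataFrame(frame))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_force_curve(path: str | Path) -> ForceCurve:
    df = _read_csv(path, ["separation_nm", "force_nN"])
    return ForceCurve(
        separations=df["separation_nm"].to_numpy(dtype=float) * NM,
        forces=df["force_nN"].to_numpy(dtype=float) * NN,
    )


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"separation_nm": curve.separations / NM, "force_nN": curve.forces / NN}
    ).to_csv(path, index=False)


def read_geometry_table(path: str | Path) -> list[JunctionGeometry]:
    df = _read_csv(path, _GEOMETRY_COLUMNS)
    geometries = []
    for _, row in df.iterrows():
        geometries.append(
            JunctionGeometry(
                shared_edge_length=float(row["l_nm"]) * NM,
                flanking_lengths=tuple(float(row[f"l{i}_nm"]) * NM for i in range(1, 5)),
                flanking_angles=tuple(
                    float(np.radians(row[f"theta{i}_deg"])) for i in range(1, 5)
                ),
                pair_id=str(row["pair_id"]),
            )
        )
    return geometries


def write_geometry_table(geometries: list[JunctionGeometry], path: str | Path) -> None:
    rows = []
    for g in geometries:
        row = {"pair_id": g.pair_id, "l_nm": g.shared_edge_length / NM}
        for i, (l, th) in enumerate(zip(g.flanking_lengths, g.flanking_angles), start=1):
            row[f"l{i}_nm"] = l / NM
            row[f"theta{i}_deg"] = np.degrees(th)
        rows.append(row)
    pd.DataFrame(rows, columns=_GEOMETRY_COLUMNS).to_csv(path, index=False)


def read_profile(path: str | Path) -> IntensityProfile:
    df = _read_csv(path, ["position_nm", "intensity_au"])
    return IntensityProfile(
        positions=df["position_nm"].to_numpy(dtype=float) * NM,
        intensities=df["intensity_au"].to_numpy(dtype=float),
    )


def write_profile(profile: IntensityProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"position_nm": profile.positions / NM, "intensity_au": profile.intensities}
    ).to_csv(path, index=False)


_RESULT_TYPES = {
    "TensionFitResult": TensionFitResult,
    "ViscosityResult": ViscosityResult,
    "HertzFitResult": HertzFitResult,
}


def write_results(result, path: str | Path) -> None:
    """Serialise a result dataclass to tagged JSON with provenance metadata."""
    type_name = type(result).__name__
    if type_name not in _RESULT_TYPES:
        raise ValidationError(f"cannot serialise result type {type_name}")
    data = {}
    for f in dataclasses.fields(result):
        value = getattr(result, f.name)
        data[f.name] = value.tolist() if isinstance(value, np.ndarray) else value
    payload = {
        "type": type_name,
        "data": data,
        "meta": {"package": "epimech", "version": __version__},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_results(path: str | Path):
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    try:
        cls = _RESULT_TYPES[payload["type"]]
        return cls(**payload["data"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a recognised results file ({exc})") from exc
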