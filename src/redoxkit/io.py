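"""File I/O for all data types.

Curve-like records are stored as tab-separated two-column text with a
``#key: value`` metadata header — readable by any plotting tool and by
:func:`read_table`.  Ion frames use standard (multi-frame) XYZ in Å;
scalar voxel grids are written in OpenDX format via GridDataFormats;
curve ensembles can be bundled into one HDF5 file.
"""

from __future__ import annotations

import os
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
from gridData import Grid

from .datatypes import (
    CurrentTrace,
    DensityGrid,
    ForceCurve,
    IonTrajectory,
    PotentialField,
    ProbeRetractionCurve,
    Sensogram,
)

__all__ = [
    "write_table",
    "read_table",
    "write_iz_curve",
    "read_iz_curve",
    "write_trace",
    "read_trace",
    "write_force_curve",
    "read_force_curve",
    "write_sensogram",
    "read_sensogram",
    "write_xyz",
    "read_xyz",
    "write_grid_dx",
    "save_iz_ensemble_h5",
    "load_iz_ensemble_h5",
]


# ---------------------------------------------------------------------------
# generic TSV dialect
# ---------------------------------------------------------------------------

def write_table(path, columns: dict[str, np.ndarray], metadata: dict | None = None):
    """Write named columns as TSV with a ``#key: value`` header."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            if np.isscalar(value) or isinstance(value, (bool, str)):
                fh.write(f"#{key}: {value}\n")
        fh.write("#" + "\t".join(columns) + "\n")
        arr = np.column_stack(list(columns.values()))
        np.savetxt(fh, arr, delimiter="\t", fmt="%.10g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read the TSV dialect back: (dataframe, metadata dict).

    Metadata values are parsed as int/float/bool where possible.
    """
    meta: dict = {}
    names: list[str] | None = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = _parse_scalar(val.strip())
            else:
                names = body.split("\t")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    return df, meta


def _parse_scalar(s: str):
    for caster in (int, float):
        try:
            return caster(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    return s


# ---------------------------------------------------------------------------
# typed writers/readers
# ---------------------------------------------------------------------------

def _scalar_meta(d: dict) -> dict:
    return {k: v for k, v in d.items() if np.isscalar(v) or isinstance(v, (bool, str))}


def write_iz_curve(path, curve: ProbeRetractionCurve):
    meta = {
        "sample_potential_V": curve.sample_potential,
        "probe_potential_V": curve.probe_potential,
        **_scalar_meta(curve.metadata),
    }
    write_table(path, {"z_nm": curve.z, "current_nA": curve.current}, meta)


def read_iz_curve(path) -> ProbeRetractionCurve:
    df, meta = read_table(path)
    return ProbeRetractionCurve(
        z=df.iloc[:, 0].to_numpy(),
        current=df.iloc[:, 1].to_numpy(),
        sample_potential=meta.pop("sample_potential_V", np.nan),
        probe_potential=meta.pop("probe_potential_V", np.nan),
        metadata=meta,
    )


def write_trace(path, trace: CurrentTrace):
    meta = {
        "bias_voltage_V": trace.bias_voltage,
        "current_setpoint_nA": trace.current_setpoint,
        "sampling_rate_Hz": trace.sampling_rate,
        **_scalar_meta(trace.metadata),
    }
    write_table(path, {"time_s": trace.time, "current_nA": trace.current}, meta)


def read_trace(path) -> CurrentTrace:
    df, meta = read_table(path)
    return CurrentTrace(
        time=df.iloc[:, 0].to_numpy(),
        current=df.iloc[:, 1].to_numpy(),
        bias_voltage=meta.pop("bias_voltage_V"),
        current_setpoint=meta.pop("current_setpoint_nA", np.nan),
        sampling_rate=meta.pop("sampling_rate_Hz", None),
        metadata=meta,
    )


def write_force_curve(path, curve: ForceCurve):
    meta = {
        "velocity_um_s": curve.pulling_velocity,
        "stiffness_pN_nm": curve.cantilever_stiffness,
        **_scalar_meta(curve.metadata),
    }
    write_table(
        path, {"separation_nm": curve.separation, "force_pN": curve.force}, meta
    )


def read_force_curve(path) -> ForceCurve:
    df, meta = read_table(path)
    return ForceCurve(
        separation=df.iloc[:, 0].to_numpy(),
        force=df.iloc[:, 1].to_numpy(),
        pulling_velocity=meta.pop("velocity_um_s"),
        cantilever_stiffness=meta.pop("stiffness_pN_nm"),
        metadata=meta,
    )


def write_sensogram(path, sensogram: Sensogram):
    meta = {
        "concentration_M": sensogram.concentration,
        "association_end_s": sensogram.association_end,
        "reference_subtracted": sensogram.reference_subtracted,
        **_scalar_meta(sensogram.metadata),
    }
    write_table(
        path, {"time_s": sensogram.time, "response_RU": sensogram.response}, meta
    )


def read_sensogram(path) -> Sensogram:
    df, meta = read_table(path)
    return Sensogram(
        time=df.iloc[:, 0].to_numpy(),
        response=df.iloc[:, 1].to_numpy(),
        concentration=meta.pop("concentration_M"),
        association_end=meta.pop("association_end_s"),
        reference_subtracted=meta.pop("reference_subtracted", True),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# XYZ ion frames and OpenDX grids
# ---------------------------------------------------------------------------

def write_xyz(path, traj: IonTrajectory, element: str = "Na"):
    """Write ion frames as multi-frame XYZ (coordinates in Å).

    The comment line of each frame records the box dimensions and the
    ion charge so the trajectory can be reconstructed.
    """
    bx, by, bz = traj.box_dimensions
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(
                f"frame {i} box_A {bx:.6g} {by:.6g} {bz:.6g} "
                f"charge_e {traj.ion_charge:.6g}\n"
            )
            for x, y, z in frame:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(
    path,
    box_dimensions: tuple[float, float, float] | None = None,
    ion_charge: float | None = None,
) -> IonTrajectory:
    """Read multi-frame XYZ back into an :class:`IonTrajectory`.

    Box and charge default to the values stored in the comment lines by
    :func:`write_xyz`; pass them explicitly for third-party files.
    """
    frames: list[np.ndarray] = []
    box = box_dimensions
    charge = ion_charge
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        natoms = int(lines[i].strip())
        comment = lines[i + 1]
        tokens = comment.split()
        if box is None and "box_A" in tokens:
            j = tokens.index("box_A")
            box = tuple(float(t) for t in tokens[j + 1: j + 4])
        if charge is None and "charge_e" in tokens:
            charge = float(tokens[tokens.index("charge_e") + 1])
        coords = np.array(
            [
                [float(v) for v in lines[i + 2 + k].split()[1:4]]
                for k in range(natoms)
            ]
        ).reshape(natoms, 3)
        frames.append(coords)
        i += 2 + natoms
    if box is None:
        maxima = [f.max(axis=0) for f in frames if f.size]
        box = tuple(np.max(maxima, axis=0)) if maxima else (1.0, 1.0, 1.0)
    return IonTrajectory(
        frames=frames, box_dimensions=box, ion_charge=charge if charge is not None else 1.0
    )


def write_grid_dx(path, grid: DensityGrid | PotentialField):
    """Write a density or potential grid as an OpenDX scalar field (Å)."""
    values = np.nan_to_num(grid.values)
    g = Grid(
        values,
        origin=np.asarray(grid.origin) + grid.voxel_edge / 2.0,
        delta=[grid.voxel_edge] * 3,
    )
    g.export(str(path), file_format="dx")


# ---------------------------------------------------------------------------
# HDF5 ensemble bundles
# ---------------------------------------------------------------------------

def save_iz_ensemble_h5(path, curves: Iterable[ProbeRetractionCurve]):
    with h5py.File(path, "w") as fh:
        for i, c in enumerate(curves):
            grp = fh.create_group(f"curve_{i:05d}")
            grp.create_dataset("z_nm", data=c.z)
            grp.create_dataset("current_nA", data=c.current)
            grp.attrs["sample_potential_V"] = c.sample_potential
            grp.attrs["probe_potential_V"] = c.probe_potential
            for k, v in _scalar_meta(c.metadata).items():
                grp.attrs[k] = v


def load_iz_ensemble_h5(path) -> list[ProbeRetractionCurve]:
    curves = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            grp = fh[name]
            attrs = dict(grp.attrs)
            curves.append(
                ProbeRetractionCurve(
                    z=grp["z_nm"][...],
                    current=grp["current_nA"][...],
                    sample_potential=float(attrs.pop("sample_potential_V", np.nan)),
                    probe_potential=float(attrs.pop("probe_potential_V", np.nan)),
                    metadata={k: v for k, v in attrs.items()},
                )
            )
    return curves


def ensure_dir(path):
    os.makedirs(path, exist_ok=True)
    return path
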