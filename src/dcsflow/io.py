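"""File formats: correlation-curve CSV, BFi-series CSV, photon-record HDF5,
JSON reports.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, one header row, with
metadata in ``#``-prefixed ``key: value`` lines before the header.  All
numeric payloads round-trip at full double precision (values are written
with ``repr``-level precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .core_models import CorrelationCurve
from .mc_transport import PhotonRecords
from .physio_analysis import BfiTimeSeries

__all__ = [
    "write_curves_csv",
    "read_curves_csv",
    "write_bfi_csv",
    "read_bfi_csv",
    "save_records_h5",
    "load_records_h5",
    "write_report_json",
    "read_report_json",
]

PathLike = Union[str, Path]


def _write_meta_lines(fh, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"# {key}: {value}\n")


def _read_meta_lines(path: Path) -> dict:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_curves_csv(path: PathLike, curves: Sequence[CorrelationCurve]) -> None:
    """Write one or more correlation curves.

    A single curve yields columns ``tau_s,value``; a stream additionally
    carries ``timestamp_s`` for grouping.  Kind and beta go into ``#``
    metadata lines.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to write")
    kind = curves[0].kind
    if any(c.kind != kind for c in curves):
        raise ValueError("cannot mix curve kinds in one file")
    path = Path(path)
    frames = []
    for i, c in enumerate(curves):
        df = pd.DataFrame({"tau_s": c.tau, "value": c.values})
        if len(curves) > 1:
            ts = c.timestamp if c.timestamp is not None else float(i)
            df.insert(0, "timestamp_s", ts)
        frames.append(df)
    meta = {"kind": kind}
    if curves[0].beta is not None:
        meta["beta"] = repr(curves[0].beta)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta_lines(fh, meta)
        pd.concat(frames, ignore_index=True).to_csv(
            fh, index=False, float_format="%.17g")


def read_curves_csv(path: PathLike) -> List[CorrelationCurve]:
    """Read curves written by :func:`write_curves_csv` (returns a list,
    possibly of length 1)."""
    path = Path(path)
    meta = _read_meta_lines(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("tau_s", "value"):
        if col not in df.columns:
            raise ValueError(f"curve file {path} is missing required column {col!r}")
    if df[["tau_s", "value"]].isna().any().any():
        raise ValueError(f"curve file {path} contains missing values")
    kind = meta.get("kind", "homodyne_g2")
    beta = float(meta["beta"]) if "beta" in meta else None
    curves = []
    if "timestamp_s" in df.columns:
        for ts, group in df.groupby("timestamp_s", sort=True):
            curves.append(CorrelationCurve(
                tau=group["tau_s"].to_numpy(), values=group["value"].to_numpy(),
                kind=kind, beta=beta, timestamp=float(ts)))
    else:
        curves.append(CorrelationCurve(tau=df["tau_s"].to_numpy(),
                                       values=df["value"].to_numpy(),
                                       kind=kind, beta=beta))
    return curves


def write_bfi_csv(path: PathLike, series: BfiTimeSeries) -> None:
    """Write a BFi series as ``t_s,bfi_cm2_s`` with rate and annotations in
    metadata lines."""
    path = Path(path)
    meta = {"rate_hz": repr(series.rate)}
    for i, (label, onset, duration) in enumerate(series.annotations):
        meta[f"annotation_{i}"] = f"{label},{onset},{duration}"
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta_lines(fh, meta)
        pd.DataFrame({"t_s": series.t, "bfi_cm2_s": series.bfi}).to_csv(
            fh, index=False, float_format="%.17g")


def read_bfi_csv(path: PathLike) -> BfiTimeSeries:
    path = Path(path)
    meta = _read_meta_lines(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("t_s", "bfi_cm2_s"):
        if col not in df.columns:
            raise ValueError(f"BFi file {path} is missing required column {col!r}")
    if df["bfi_cm2_s"].isna().any():
        raise ValueError(f"BFi file {path} contains missing bfi values")
    t = df["t_s"].to_numpy()
    if "rate_hz" in meta:
        rate = float(meta["rate_hz"])
    else:
        rate = 1.0 / float(np.median(np.diff(t)))
    annotations = []
    for key in sorted(k for k in meta if k.startswith("annotation_")):
        label, onset, duration = meta[key].split(",")
        annotations.append((label, float(onset), float(duration)))
    return BfiTimeSeries(t=t, bfi=df["bfi_cm2_s"].to_numpy(), rate=rate,
                         annotations=annotations)


def save_records_h5(path: PathLike, records: PhotonRecords,
                    extra_attrs: Optional[dict] = None) -> None:
    """Persist photon records: datasets ``weight``, ``pathlength_cm``
    (N x n_layers), ``momentum_transfer``; run metadata as attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weight", data=records.weight)
        f.create_dataset("pathlength_cm", data=records.pathlength)
        f.create_dataset("momentum_transfer", data=records.momentum_transfer)
        f.attrs["n_launched"] = records.n_launched
        f.attrs["seed"] = records.seed
        f.attrs["annulus_cm"] = list(records.annulus)
        for key, value in (extra_attrs or {}).items():
            f.attrs[key] = value


def load_records_h5(path: PathLike) -> PhotonRecords:
    with h5py.File(path, "r") as f:
        for name in ("weight", "pathlength_cm", "momentum_transfer"):
            if name not in f:
                raise ValueError(f"records file {path} is missing dataset {name!r}")
        return PhotonRecords(
            weight=f["weight"][...],
            pathlength=f["pathlength_cm"][...],
            momentum_transfer=f["momentum_transfer"][...],
            n_launched=int(f.attrs["n_launched"]),
            seed=int(f.attrs["seed"]),
            annulus=tuple(f.attrs["annulus_cm"]),
        )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return super().default(obj)


def write_report_json(path: PathLike, report: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_report_json(path: PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
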