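"""Plain-text readers and writers for curves, events, records and bursts.

Formats are deliberately simple and diffable:

* one TSV per force-extension curve with columns
  ``time_s  head_height_nm  extension_nm  force_pN``, plus a JSON sidecar
  carrying events and labels;
* a batch manifest CSV listing curve files with speed/seed metadata;
* per-curve analysis records as CSV;
* photon streams and burst tables as CSV;
* off-rate curves and parameter tables as CSV.

Every writer's output round-trips through its reader at full precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from types import SimpleNamespace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import CurveRecord, Increment
from .fret import Burst, PhotonStream
from .simulate import SimCurve, SimEvent

__all__ = [
    "write_curve_tsv",
    "read_curve_tsv",
    "write_records_csv",
    "read_records_csv",
    "write_photon_stream_csv",
    "read_photon_stream_csv",
    "write_bursts_csv",
    "read_bursts_csv",
    "write_offrate_csv",
    "read_offrate_csv",
]

CURVE_COLUMNS = ("time_s", "head_height_nm", "extension_nm", "force_pN")


def write_curve_tsv(curve: SimCurve, path, sidecar: bool = True) -> None:
    """Write one curve as TSV plus a JSON sidecar of events and labels."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": curve.time,
        "head_height_nm": curve.head_height,
        "extension_nm": curve.extension,
        "force_pN": curve.force,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "binding_mode": curve.binding_mode,
            "true_pathway": curve.true_pathway,
            "speed_nm_per_s": curve.speed,
            "ruptured": curve.ruptured,
            "no_rupture_reason": curve.no_rupture_reason,
            "events": [asdict(ev) for ev in curve.events],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_curve_tsv(path, sidecar: bool = True):
    """Read a curve TSV (and its sidecar when present) back into an object
    with the same attributes as :class:`catchkit.simulate.SimCurve`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing curve columns {missing}")
    curve = SimpleNamespace(
        time=df["time_s"].to_numpy(),
        head_height=df["head_height_nm"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        events=[], binding_mode=None, true_pathway=None,
        speed=None, ruptured=None, no_rupture_reason=None,
    )
    side = path.with_suffix(".json")
    if sidecar and side.exists():
        meta = json.loads(side.read_text())
        curve.binding_mode = meta.get("binding_mode")
        curve.true_pathway = meta.get("true_pathway")
        curve.speed = meta.get("speed_nm_per_s")
        curve.ruptured = meta.get("ruptured")
        curve.no_rupture_reason = meta.get("no_rupture_reason")
        curve.events = [SimEvent(**ev) for ev in meta.get("events", [])]
    return curve


def records_to_frame(records: Sequence[CurveRecord],
                     extra: Optional[dict] = None) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "source_id": rec.source_id,
            "pathway": rec.pathway,
            "rupture_force_pN": rec.rupture_force,
            "loading_rate_pN_s": rec.loading_rate,
            "fingerprint_ok": rec.fingerprint_ok,
            "xmod_step_present": rec.xmod_step_present,
            "xmod_unfold_force_pN": rec.xmod_unfold_force,
            "xmod_unfold_rate_pN_s": rec.xmod_unfold_rate,
            "increments_nm": ";".join(f"{i.size:.3f}@{i.position:.3f}"
                                      for i in rec.increments),
            "flags": "|".join(rec.flags),
        })
    df = pd.DataFrame(rows)
    if extra:
        for key, vals in extra.items():
            df[key] = vals
    return df


def write_records_csv(records: Sequence[CurveRecord], path,
                      extra: Optional[dict] = None) -> None:
    records_to_frame(records, extra).to_csv(path, index=False,
                                            float_format="%.17g")


def read_records_csv(path) -> list[CurveRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        incs = []
        if isinstance(row.get("increments_nm"), str) and row["increments_nm"]:
            for tok in row["increments_nm"].split(";"):
                size, pos = tok.split("@")
                incs.append(Increment(position=float(pos), size=float(size)))
        out.append(CurveRecord(
            source_id=str(row["source_id"]),
            increments=incs,
            pathway=row["pathway"],
            rupture_force=_opt(row.get("rupture_force_pN")),
            loading_rate=_opt(row.get("loading_rate_pN_s")),
            fingerprint_ok=bool(row["fingerprint_ok"]),
            xmod_step_present=bool(row["xmod_step_present"]),
            xmod_unfold_force=_opt(row.get("xmod_unfold_force_pN")),
            xmod_unfold_rate=_opt(row.get("xmod_unfold_rate_pN_s")),
            flags=str(row.get("flags") or "").split("|") if row.get("flags") else [],
        ))
    return out


def _opt(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def write_photon_stream_csv(stream: PhotonStream, path) -> None:
    channels = np.array(["DD", "DA", "AA"])[stream.channels]
    pd.DataFrame({"timestamp_s": stream.timestamps,
                  "channel": channels}).to_csv(path, index=False,
                                               float_format="%.17g")


def read_photon_stream_csv(path) -> PhotonStream:
    df = pd.read_csv(path, float_precision="round_trip")
    lut = {"DD": 0, "DA": 1, "AA": 2}
    return PhotonStream(
        timestamps=df["timestamp_s"].to_numpy(dtype=float),
        channels=df["channel"].map(lut).to_numpy(dtype=int),
    )


def write_bursts_csv(bursts: Sequence[Burst], path) -> None:
    pd.DataFrame([{
        "I_DD": b.I_DD, "I_DA": b.I_DA, "I_AA": b.I_AA,
        "start_time_s": b.start_time, "duration_s": b.duration,
    } for b in bursts]).to_csv(path, index=False, float_format="%.17g")


def read_bursts_csv(path) -> list[Burst]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [Burst(I_DD=r.I_DD, I_DA=r.I_DA, I_AA=r.I_AA,
                  start_time=r.start_time_s, duration=r.duration_s)
            for r in df.itertuples()]


def write_offrate_csv(curve, path) -> None:
    data = {"force_pN": curve.force, "k_off_per_s": curve.k_off}
    if curve.k_off_std is not None:
        data["k_off_std_per_s"] = curve.k_off_std
    if curve.counts is not None:
        data["n"] = curve.counts
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_offrate_csv(path):
    from .kinetics import OffRateCurve

    df = pd.read_csv(path, float_precision="round_trip")
    return OffRateCurve(
        force=df["force_pN"].to_numpy(),
        k_off=df["k_off_per_s"].to_numpy(),
        k_off_std=df["k_off_std_per_s"].to_numpy()
        if "k_off_std_per_s" in df.columns else None,
        counts=df["n"].to_numpy() if "n" in df.columns else None,
    )
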