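"""File formats: curve archives (HDF5/CSV), ground truth (JSON-lines),
events tables (CSV), height images (TIFF / plain matrix text), manifests.

All archives carry an explicit units declaration; values are stored in the
package-wide units (nm, pN, s, um/s for pulling speed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .afm import HeightMap
from .curves import ForceCurve, RuptureEvent
from .errors import InvalidInputError
from .simulate import GroundTruth, SimulatedDataset

UNITS = {"distance": "nm", "force": "pN", "pulling_speed": "um/s",
         "contact_time": "s", "loading_rate": "pN/s", "height": "nm",
         "volume": "nm^3"}

EVENT_COLUMNS = ["curve_id", "rank", "unbinding_force", "effective_spring_constant",
                 "loading_rate", "unbinding_length", "noise_sigma"]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# curve archives

def write_curve_archive(dataset: SimulatedDataset, h5_path,
                        truth_path=None, manifest_path=None) -> None:
    """Write curves to HDF5 (one group per curve), ground truth to
    JSON-lines and the manifest (with checksums) to JSON."""
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as f:
        f.attrs["schema_version"] = 1
        f.attrs["units"] = json.dumps(UNITS)
        for curve in dataset.curves:
            g = f.create_group(curve.curve_id)
            g.create_dataset("distance", data=curve.distance)
            g.create_dataset("force", data=curve.force)
            g.attrs["pulling_speed"] = curve.pulling_speed
            g.attrs["contact_time"] = curve.contact_time
            g.attrs["curve_id"] = curve.curve_id
            g.attrs["noise_sigma"] = curve.metadata.get("noise_sigma", float("nan"))
    files = {h5_path.name: sha256_of(h5_path)}
    if truth_path is not None:
        truth_path = Path(truth_path)
        write_truth_jsonl(dataset.truths, truth_path)
        files[truth_path.name] = sha256_of(truth_path)
    if manifest_path is not None:
        manifest = dict(dataset.manifest)
        manifest["files"] = files
        manifest["units"] = UNITS
        Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_curve_archive(h5_path) -> list[ForceCurve]:
    curves = []
    with h5py.File(h5_path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            curves.append(ForceCurve(
                distance=g["distance"][()],
                force=g["force"][()],
                pulling_speed=float(g.attrs["pulling_speed"]),
                contact_time=float(g.attrs["contact_time"]),
                curve_id=str(g.attrs["curve_id"]),
                metadata={"noise_sigma": float(g.attrs.get("noise_sigma", float("nan")))},
            ))
    return curves


def write_truth_jsonl(truths, path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(json.dumps({
                "curve_id": t.curve_id, "bound": t.bound, "n_bonds": t.n_bonds,
                "pattern": t.pattern, "rupture_forces": list(t.rupture_forces),
                "rupture_positions": list(t.rupture_positions),
                "spring_constants": list(t.spring_constants),
                "loading_rate": t.loading_rate, "noise_sigma": t.noise_sigma,
                "pulling_speed": t.pulling_speed, "contact_time": t.contact_time,
            }) + "\n")


def read_truth_jsonl(path) -> list[GroundTruth]:
    out = []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        out.append(GroundTruth(
            curve_id=d["curve_id"], bound=d["bound"], n_bonds=d["n_bonds"],
            pattern=d["pattern"], rupture_forces=tuple(d["rupture_forces"]),
            rupture_positions=tuple(d["rupture_positions"]),
            spring_constants=tuple(d["spring_constants"]),
            loading_rate=d["loading_rate"], noise_sigma=d["noise_sigma"],
            pulling_speed=d["pulling_speed"], contact_time=d["contact_time"]))
    return out


def curve_to_csv(curve: ForceCurve, path) -> None:
    """Two-column CSV (distance_nm, force_pN) with metadata header lines."""
    with open(path, "w") as fh:
        fh.write(f"# curve_id={curve.curve_id}\n")
        fh.write(f"# pulling_speed_um_s={float(curve.pulling_speed)!r}\n")
        fh.write(f"# contact_time_s={float(curve.contact_time)!r}\n")
        fh.write("distance_nm,force_pN\n")
        for d, f in zip(curve.distance, curve.force):
            fh.write(f"{float(d)!r},{float(f)!r}\n")


def curve_from_csv(path) -> ForceCurve:
    meta = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            try:
                key, value = line[1:].strip().split("=", 1)
            except ValueError as exc:
                raise InvalidInputError(
                    f"malformed metadata line {header_lines} in {path}: {line!r}") from exc
            meta[key] = value
    tab = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    if list(tab.columns) != ["distance_nm", "force_pN"]:
        raise InvalidInputError(
            f"unexpected columns {list(tab.columns)} in {path}; "
            "expected [distance_nm, force_pN]")
    return ForceCurve(
        distance=tab["distance_nm"].to_numpy(),
        force=tab["force_pN"].to_numpy(),
        pulling_speed=float(meta.get("pulling_speed_um_s", "nan")),
        contact_time=float(meta.get("contact_time_s", "nan")),
        curve_id=meta.get("curve_id", Path(path).stem),
    )


# ---------------------------------------------------------------------------
# events tables

def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame([{
        "curve_id": e.curve_id, "rank": e.rank,
        "unbinding_force": e.unbinding_force,
        "effective_spring_constant": e.effective_spring_constant,
        "loading_rate": e.loading_rate,
        "unbinding_length": e.unbinding_length,
        "noise_sigma": e.noise_sigma,
    } for e in events], columns=EVENT_COLUMNS)


def frame_to_events(frame: pd.DataFrame) -> list[RuptureEvent]:
    return [RuptureEvent(
        unbinding_force=row.unbinding_force,
        effective_spring_constant=row.effective_spring_constant,
        loading_rate=row.loading_rate,
        unbinding_length=row.unbinding_length,
        noise_sigma=row.noise_sigma,
        rank=int(row.rank), curve_id=str(row.curve_id),
    ) for row in frame.itertuples()]


# ---------------------------------------------------------------------------
# height images

def write_tiff(img: HeightMap, path) -> None:
    tifffile.imwrite(path, img.heights.astype(np.float32),
                     metadata={"pixel_size_nm": img.pixel_size})


def read_tiff(path) -> HeightMap:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = float(meta.get("pixel_size_nm", 1.0))
    return HeightMap(heights=data, pixel_size=px)


def write_matrix_text(img: HeightMap, path) -> None:
    np.savetxt(path, img.heights.astype(np.float32), fmt="%.9e",
               header=f"pixel_size_nm={img.pixel_size}")


def read_matrix_text(path) -> HeightMap:
    px = 1.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "pixel_size_nm=" in first:
        px = float(first.split("pixel_size_nm=")[1])
    try:
        data = np.loadtxt(path)
    except ValueError as exc:
        raise InvalidInputError(f"malformed matrix text file {path}: {exc}") from exc
    return HeightMap(heights=data, pixel_size=px)
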