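"""File output: label grids, time series, snapshots, run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import time
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np

from .geometry import (DEFAULT_PALETTE, TissueLabelGrid, render_labels)
from .metrics import TimeSeriesResult

__all__ = [
    "write_label_grid_csv", "read_label_grid_csv", "write_label_png",
    "write_timeseries_csv", "write_snapshots_h5", "read_snapshots_h5",
    "write_snapshots_csv", "write_manifest", "write_outputs",
]


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_label_grid_csv(grid: TissueLabelGrid, path: str | Path) -> None:
    path = Path(path)

    def writer(tmp: Path) -> None:
        with open(tmp, "w") as fh:
            fh.write(f"# pixel_size_mm={grid.pixel_size!r}\n")
            np.savetxt(fh, grid.labels, fmt="%d", delimiter=",")

    _atomic_write(path, writer)


def read_label_grid_csv(path: str | Path) -> TissueLabelGrid:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# pixel_size_mm="):
            raise ValueError(f"{path}: missing pixel-size header")
        pixel_size = float(header.split("=", 1)[1])
        labels = np.loadtxt(fh, dtype=np.int16, delimiter=",")
    return TissueLabelGrid(labels, pixel_size)


def write_label_png(grid: TissueLabelGrid, path: str | Path,
                    palette: Mapping[int, Tuple[int, int, int]] | None = None
                    ) -> None:
    import imageio.v3 as iio
    path = Path(path)
    img = render_labels(grid, palette or DEFAULT_PALETTE)
    _atomic_write(path, lambda tmp: iio.imwrite(tmp, img,
                                                extension=".png"))


def write_timeseries_csv(result: TimeSeriesResult,
                         path: str | Path) -> None:
    path = Path(path)
    frame = result.to_frame()
    _atomic_write(path, lambda tmp: frame.to_csv(tmp, index=False))


def write_snapshots_h5(result: TimeSeriesResult, path: str | Path) -> None:
    import h5py
    path = Path(path)

    def writer(tmp: Path) -> None:
        with h5py.File(tmp, "w") as fh:
            for t, c, bR, bE in result.snapshots:
                grp = fh.create_group(f"t_{t:.6f}")
                grp.attrs["t_s"] = t
                grp.create_dataset("c_t", data=c)
                grp.create_dataset("b_R", data=bR)
                grp.create_dataset("b_E", data=bE)

    _atomic_write(path, writer)


def read_snapshots_h5(path: str | Path):
    import h5py
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh, key=lambda n: fh[n].attrs["t_s"]):
            grp = fh[name]
            out.append((float(grp.attrs["t_s"]), grp["c_t"][...],
                        grp["b_R"][...], grp["b_E"][...]))
    return out


def write_snapshots_csv(result: TimeSeriesResult, outdir: str | Path,
                        prefix: str = "snapshot") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t, c, bR, bE in result.snapshots:
        for name, arr in (("ct", c), ("bR", bR), ("bE", bE)):
            np.savetxt(outdir / f"{prefix}_{name}_t{t:.1f}s.csv", arr,
                       delimiter=",")


def config_hash(config) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if not f.name.startswith("_")}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(path: str | Path, config, seed: int,
                   wall_time_s: float,
                   extra: Dict[str, object] | None = None) -> None:
    import dcbsim
    payload = {
        "config_hash": config_hash(config),
        "config": _jsonable(config),
        "seed": seed,
        "wall_time_s": wall_time_s,
        "package_version": dcbsim.__version__,
        "written_at_unix": time.time(),
    }
    if extra:
        payload.update(extra)
    _atomic_write(Path(path),
                  lambda tmp: tmp.write_text(json.dumps(payload, indent=2,
                                                        sort_keys=True)))


def preflight_writable(outdir: str | Path) -> None:
    """Fail before any simulation starts if the output path is unusable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("ok")
    finally:
        if probe.exists():
            probe.unlink()


def write_outputs(result: TimeSeriesResult, grid: TissueLabelGrid,
                  config, outdir: str | Path, seed: int = 0,
                  wall_time_s: float = 0.0, prefix: str = "run",
                  snapshot_format: str = "h5") -> Dict[str, Path]:
    """Write the standard output set: time-series CSV, label-map PNG and
    CSV, optional snapshots, and a JSON run manifest."""
    outdir = Path(outdir)
    preflight_writable(outdir)
    paths = {}
    paths["timeseries"] = outdir / f"{prefix}_timeseries.csv"
    write_timeseries_csv(result, paths["timeseries"])
    paths["labels_csv"] = outdir / f"{prefix}_labels.csv"
    write_label_grid_csv(grid, paths["labels_csv"])
    paths["labels_png"] = outdir / f"{prefix}_labels.png"
    write_label_png(grid, paths["labels_png"])
    if result.snapshots:
        if snapshot_format == "h5":
            paths["snapshots"] = outdir / f"{prefix}_snapshots.h5"
            write_snapshots_h5(result, paths["snapshots"])
        else:
            write_snapshots_csv(result, outdir, prefix=f"{prefix}_snap")
    paths["manifest"] = outdir / f"{prefix}_manifest.json"
    write_manifest(paths["manifest"], config, seed, wall_time_s,
                   extra={"failure": result.failure,
                          "grid_hash": grid.content_hash()})
    return paths
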