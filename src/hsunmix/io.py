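"""Readers and writers for the formats the toolkit touches.

Supported inputs (``read_input``):

* HDF5 array container — datasets ``/cube`` (ny, nx, m) and
  ``/channel_axis`` (m), free-form string attributes as metadata;
* per-channel grayscale TIFF stack (one page per channel);
* delimited-text matrix (CSV, header row, first column = channel
  coordinate) with a JSON grid-shape sidecar ``<file>.grid.json``.

Outputs (``write_results``): endmember spectra as CSV (channel axis plus
one column per endmember), abundance maps as a float32 multi-page TIFF
(full precision) and per-component 8-bit PNG previews (min-max normalized,
previews only), and a JSON run report (config, seed, objective trace, k,
file manifest).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .datamodel import AbundanceMapStack, HyperspectralCube, abundances_to_maps
from .factorize import FactorModel
from .synth import GroundTruth

__all__ = [
    "read_input",
    "read_image",
    "write_cube",
    "write_matrix_csv",
    "write_results",
    "save_ground_truth",
    "load_ground_truth",
    "config_digest",
]


class UnknownFormatError(ValueError):
    pass


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise UnknownFormatError(f"cannot infer input format from {path.name!r}")


def read_input(path: "str | Path", format: str | None = None) -> HyperspectralCube:
    """Load a hyperspectral cube from any of the supported formats."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return _read_h5(path)
    if fmt == "tiff":
        return _read_tiff_stack(path)
    if fmt == "csv":
        return _read_csv(path)
    raise UnknownFormatError(f"unknown format {fmt!r}")


def _read_h5(path: Path) -> HyperspectralCube:
    with h5py.File(path, "r") as f:
        if "cube" not in f:
            raise UnknownFormatError(f"{path.name}: no /cube dataset")
        values = f["cube"][()]
        channel_axis = f["channel_axis"][()] if "channel_axis" in f else None
        meta = {k: _from_attr(v) for k, v in f["cube"].attrs.items()}
    return HyperspectralCube(values=values, channel_axis=channel_axis, meta=meta)


def _read_tiff_stack(path: Path) -> HyperspectralCube:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.ndim != 3:
        raise UnknownFormatError(f"{path.name}: expected a stack of 2-D grayscale pages")
    # pages are (m, ny, nx): one channel image per page
    values = np.moveaxis(pages.astype(float), 0, -1)
    return HyperspectralCube(values=values, meta={"source": str(path)})


def _read_csv(path: Path) -> HyperspectralCube:
    sidecar = path.with_name(path.name + ".grid.json")
    if not sidecar.exists():
        raise UnknownFormatError(f"missing grid-shape sidecar {sidecar.name}")
    with open(sidecar) as f:
        info = json.load(f)
    ny, nx = info["grid_shape"]
    raw = np.genfromtxt(path, delimiter=",", skip_header=1)
    if raw.ndim == 1:
        raw = raw[None, :]
    if np.isnan(raw).any():
        raise ValueError(f"{path.name}: non-numeric payload")
    channel_axis = raw[:, 0]
    X = raw[:, 1:]
    if X.shape[1] != ny * nx:
        raise ValueError(
            f"{path.name}: {X.shape[1]} pixel columns do not match grid {ny} x {nx}"
        )
    values = X.T.reshape(ny, nx, X.shape[0])
    return HyperspectralCube(values=values, channel_axis=channel_axis, meta={"source": str(path)})


def read_image(path: "str | Path") -> np.ndarray:
    """Load a single 2-D grayscale image (TIFF/PNG/CSV) for the sliding FFT."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    elif path.suffix.lower() in (".csv", ".txt"):
        img = np.genfromtxt(path, delimiter=",")
    else:
        img = np.asarray(iio.imread(path), dtype=float)
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = img[..., :3].mean(axis=-1)
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"{path.name}: expected a single 2-D grayscale image")
    return img


def write_cube(path: "str | Path", cube: HyperspectralCube) -> Path:
    """Write a cube to the HDF5 array container (full precision round trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("cube", data=cube.values)
        ca = np.asarray(cube.channel_axis)
        if not np.issubdtype(ca.dtype, np.number):
            ca = ca.astype("S")
        f.create_dataset("channel_axis", data=ca)
        for k, v in cube.meta.items():
            d.attrs[k] = _to_attr(v)
    return path


def write_matrix_csv(path: "str | Path", X: np.ndarray, channel_axis: np.ndarray,
                     grid_shape: tuple[int, int]) -> Path:
    """Write an (m, n) matrix as delimited text plus its grid sidecar."""
    path = Path(path)
    header = "channel," + ",".join(f"px{j}" for j in range(X.shape[1]))
    body = np.column_stack([np.asarray(channel_axis, dtype=float), X])
    np.savetxt(path, body, delimiter=",", header=header, comments="")
    with open(path.with_name(path.name + ".grid.json"), "w") as f:
        json.dump({"grid_shape": list(map(int, grid_shape))}, f)
    return path


def save_ground_truth(path: "str | Path", cube: HyperspectralCube, gt: GroundTruth) -> Path:
    """Container holding a synthetic cube alongside its generating factors."""
    path = write_cube(path, cube)
    with h5py.File(path, "a") as f:
        g = f.create_group("ground_truth")
        g.create_dataset("endmembers", data=gt.endmembers_true)
        g.create_dataset("abundances", data=gt.abundances_true)
        g.attrs["grid_shape"] = list(gt.grid_shape)
        g.attrs["noise_model"] = gt.noise_model
        g.attrs["noise_param"] = gt.noise_param
        g.attrs["seed"] = gt.seed
        g.attrs["sum_to_one"] = gt.sum_to_one
        g.attrs["params"] = json.dumps(gt.params)
    return path


def load_ground_truth(path: "str | Path") -> GroundTruth:
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            raise UnknownFormatError("container holds no ground truth")
        g = f["ground_truth"]
        return GroundTruth(
            endmembers_true=g["endmembers"][()],
            abundances_true=g["abundances"][()],
            grid_shape=tuple(int(x) for x in g.attrs["grid_shape"]),
            noise_model=str(g.attrs["noise_model"]),
            noise_param=float(g.attrs["noise_param"]),
            seed=int(g.attrs["seed"]),
            sum_to_one=bool(g.attrs["sum_to_one"]),
            params=json.loads(g.attrs["params"]),
        )


def _to_attr(v):
    if isinstance(v, (str, int, float, bool, np.integer, np.floating)):
        return v
    return json.dumps(v)


def _from_attr(v):
    if isinstance(v, bytes):
        v = v.decode()
    if isinstance(v, str):
        try:
            return json.loads(v)
        except (json.JSONDecodeError, ValueError):
            return v
    if isinstance(v, np.generic):
        return v.item()
    return v


def config_digest(config_dict: dict) -> str:
    """Stable hash of a run configuration (canonical JSON, sha256)."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_results(
    model: FactorModel,
    outdir: "str | Path",
    extra_report: dict | None = None,
) -> dict:
    """Write a fitted model's artifacts to ``outdir`` and return the manifest.

    Files: ``endmembers.csv``, ``abundances.tif`` (float32, one page per
    component, full precision up to the declared bit depth),
    ``abundance_NN.png`` previews, and ``report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    chan = (
        np.asarray(model.channel_axis, dtype=float)
        if model.channel_axis is not None and np.issubdtype(np.asarray(model.channel_axis).dtype, np.number)
        else np.arange(model.U.shape[0], dtype=float)
    )
    k = model.k
    header = "channel," + ",".join(f"endmember_{i + 1}" for i in range(k))
    csv_path = outdir / "endmembers.csv"
    np.savetxt(csv_path, np.column_stack([chan, model.U]), delimiter=",", header=header, comments="")
    manifest["endmembers_csv"] = csv_path.name

    if model.grid_shape is not None:
        stack: AbundanceMapStack = abundances_to_maps(model.V, model.grid_shape)
        tif_path = outdir / "abundances.tif"
        tifffile.imwrite(tif_path, stack.maps.astype(np.float32), photometric="minisblack")
        manifest["abundance_tiff"] = tif_path.name
        for i in range(k):
            m = stack.maps[i]
            rng_span = m.max() - m.min()
            preview = np.zeros_like(m) if rng_span == 0 else (m - m.min()) / rng_span
            png_path = outdir / f"abundance_{i + 1:02d}.png"
            iio.imwrite(png_path, (preview * 255).astype(np.uint8))
            manifest[f"abundance_png_{i + 1}"] = png_path.name

    cfg = model.config.to_dict() if model.config is not None else {"method": model.method}
    meta_clean = {
        k: (v.tolist() if isinstance(v, np.ndarray) and v.size <= 32 else v)
        for k, v in model.meta.items()
        if not (isinstance(v, np.ndarray) and v.size > 32)
    }
    report = {
        "config": cfg,
        "config_digest": config_digest(cfg),
        "method": model.method,
        "k": k,
        "seed": cfg.get("seed"),
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
        "objective_trace": [float(x) for x in model.objective_trace],
        "warnings": meta_clean,
        "files": manifest,
    }
    if model.explained_variance_ratio is not None:
        report["explained_variance_ratio"] = [float(x) for x in model.explained_variance_ratio]
    if model.singular_values is not None:
        report["singular_values"] = [float(x) for x in model.singular_values]
    if extra_report:
        report.update(extra_report)
    report_path = outdir / "report.json"
    with open(report_path, "w") as f:
        json.dump(report, f, indent=2)
    manifest["report"] = report_path.name
    return report
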