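"""Dataset container read/write and stimulus preprocessing.

Datasets are stored as a single HDF5 file with a fixed schema:

* ``images``          — ``(n, p, p)`` float, training stimuli
* ``train_responses`` — ``(n, m)`` float, non-negative single-trial responses
* ``val_images``      — ``(v, p, p)`` float (optional)
* ``val_responses``   — ``(v, m, r)`` float (optional, paired with val_images)
* root attribute ``metadata`` — JSON string (region name, units, seed, ...)

Datasets are written without HDF5 object timestamps so a pipeline rerun from
the same config and seed produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .fitting import Dataset
from .model_core import validate_images

__all__ = [
    "read_dataset", "write_dataset", "crop_downsample",
    "write_hsm_archive", "read_hsm_archive",
    "write_rln_archive", "read_rln_archive",
]

_REQUIRED = ("images", "train_responses")
_OPTIONAL = ("val_images", "val_responses")


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a :class:`~poprf.fitting.Dataset` to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        def put(name: str, arr: np.ndarray) -> None:
            f.create_dataset(name, data=np.asarray(arr, dtype=np.float64),
                             track_times=False)
        put("images", dataset.images)
        put("train_responses", dataset.train_responses)
        if dataset.val_images is not None:
            put("val_images", dataset.val_images)
            put("val_responses", dataset.val_responses)
        f.attrs["metadata"] = json.dumps(dataset.metadata, sort_keys=True)
        f.attrs["schema"] = "poprf-dataset-v1"


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset container, validating the schema field by field.

    A container without the validation pair loads with validation marked
    absent; downstream operations that need repeated trials then fail with
    their own errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        missing = [name for name in _REQUIRED if name not in f]
        if missing:
            raise ValueError(f"dataset container is missing arrays: {missing}")
        arrays = {name: f[name][()] for name in _REQUIRED}
        have_val = [name for name in _OPTIONAL if name in f]
        if len(have_val) == 1:
            raise ValueError(
                f"dataset container has {have_val[0]} without its partner; "
                "val_images and val_responses must appear together")
        for name in have_val:
            arrays[name] = f[name][()]
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    try:
        return Dataset(images=arrays["images"],
                       train_responses=arrays["train_responses"],
                       val_images=arrays.get("val_images"),
                       val_responses=arrays.get("val_responses"),
                       metadata=metadata)
    except ValueError as exc:
        raise ValueError(f"invalid dataset container {path}: {exc}") from exc


def crop_downsample(images: np.ndarray, roi: tuple[int, int, int, int],
                    target: int = 31) -> np.ndarray:
    """Crop a region of interest and block-mean down-sample to ``target**2``.

    ``roi`` is ``(row0, col0, height, width)`` in full-resolution pixels.  A
    non-square ROI is first squared by symmetric expansion of the shorter
    side; the square region is then pooled to ``target x target`` by
    area-weighted averaging (exact block means when the side is a multiple of
    ``target``).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3:
        raise ValueError("expected (n, H, W) image stack")
    n, H, W = images.shape
    row0, col0, h, w = (int(v) for v in roi)
    if h < 1 or w < 1:
        raise ValueError("ROI must have positive size")
    # square by symmetric expansion of the shorter side
    if h != w:
        side = max(h, w)
        grow_r = (side - h) // 2
        grow_c = (side - w) // 2
        row0 -= grow_r
        col0 -= grow_c
        h = w = side
    if row0 < 0 or col0 < 0 or row0 + h > H or col0 + w > W:
        raise ValueError(
            f"ROI (rows {row0}:{row0 + h}, cols {col0}:{col0 + w}) falls outside "
            f"the {H}x{W} image")
    if h < target:
        raise ValueError(f"ROI side ({h}) must be at least the target ({target})")
    crop = images[:, row0:row0 + h, col0:col0 + w]
    P = _pooling_matrix(h, target)
    return np.einsum("ia,nab,jb->nij", P, crop, P)


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------

def write_hsm_archive(results, config, path: str | Path) -> None:
    """Write fitted HSM(s) as packed vectors plus config and diagnostics.

    ``results`` is one :class:`~poprf.fitting.FitResult` (population fit) or
    a list of them (per-neuron fits).  The config and seed are embedded so
    the archive is self-describing and the run reproducible.
    """
    from dataclasses import asdict
    from .fitting import FitResult
    from .model_core import pack_params

    per_neuron = not isinstance(results, FitResult)
    items = list(results) if per_neuron else [results]
    with h5py.File(Path(path), "w") as f:
        f.attrs["schema"] = "poprf-hsm-v1"
        f.attrs["per_neuron"] = per_neuron
        cfg = asdict(config)
        f.attrs["config"] = json.dumps(cfg, sort_keys=True)
        for i, res in enumerate(items):
            g = f.create_group(f"fit{i}")
            g.create_dataset("params", data=pack_params(res.params),
                             track_times=False)
            g.attrs["diagnostics"] = json.dumps({
                "final_loglik": res.final_loglik,
                "train_performance": res.train_performance,
                "seed": res.seed,
                "n_iterations": res.n_iterations,
                "converged": res.converged,
                "restarts": res.restarts,
            }, sort_keys=True)


def read_hsm_archive(path: str | Path):
    """Read an HSM archive; returns ``(results, config)``.

    ``results`` is a FitResult for population archives or a list of them for
    per-neuron archives.
    """
    from .fitting import FitResult
    from .model_core import ModelConfig, unpack_params

    with h5py.File(Path(path), "r") as f:
        if f.attrs.get("schema") != "poprf-hsm-v1":
            raise ValueError(f"{path} is not an HSM archive")
        cfg_dict = json.loads(f.attrs["config"])
        for key in ("init_sigma_c", "init_sigma_s", "init_weight",
                    "init_threshold", "init_alpha_beta"):
            if key in cfg_dict and cfg_dict[key] is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        per_neuron = bool(f.attrs["per_neuron"])
        results = []
        i = 0
        while f"fit{i}" in f:
            g = f[f"fit{i}"]
            diag = json.loads(g.attrs["diagnostics"])
            cfg_i = config
            if per_neuron:
                from dataclasses import replace
                cfg_i = replace(config, s3=1, s2=config.hidden_size)
            params = unpack_params(g["params"][()], cfg_i)
            results.append(FitResult(
                params=params, final_loglik=diag["final_loglik"],
                train_performance=diag["train_performance"], seed=diag["seed"],
                n_iterations=diag["n_iterations"], converged=diag["converged"],
                restarts=diag.get("restarts", [])))
            i += 1
    if per_neuron:
        return results, config
    return results[0], config


def write_rln_archive(models, path: str | Path,
                      metadata: dict | None = None) -> None:
    """Write a list of per-neuron rLN models (kernels + nonlinearities)."""
    with h5py.File(Path(path), "w") as f:
        f.attrs["schema"] = "poprf-rln-v1"
        f.attrs["metadata"] = json.dumps(metadata or {}, sort_keys=True)
        for i, mdl in enumerate(models):
            g = f.create_group(f"neuron{i}")
            g.create_dataset("kernel", data=mdl.kernel, track_times=False)
            g.create_dataset("bin_centers", data=mdl.nonlinearity.bin_centers,
                             track_times=False)
            g.create_dataset("bin_values", data=mdl.nonlinearity.bin_values,
                             track_times=False)
            g.attrs["alpha_reg"] = float(mdl.alpha_reg)
            g.attrs["p"] = int(mdl.p)


def read_rln_archive(path: str | Path):
    """Read an rLN archive back into a list of RLNModel."""
    from .rln import PointNonlinearity, RLNModel

    models = []
    with h5py.File(Path(path), "r") as f:
        if f.attrs.get("schema") != "poprf-rln-v1":
            raise ValueError(f"{path} is not an rLN archive")
        i = 0
        while f"neuron{i}" in f:
            g = f[f"neuron{i}"]
            nl = PointNonlinearity(bin_centers=g["bin_centers"][()],
                                   bin_values=g["bin_values"][()])
            models.append(RLNModel(kernel=g["kernel"][()],
                                   alpha_reg=float(g.attrs["alpha_reg"]),
                                   nonlinearity=nl, p=int(g.attrs["p"])))
            i += 1
    return models


def _pooling_matrix(side: int, target: int) -> np.ndarray:
    """Area-weighted 1-D pooling matrix ``(target, side)``; rows sum to 1."""
    P = np.zeros((target, side))
    cell = side / target
    for i in range(target):
        lo, hi = i * cell, (i + 1) * cell
        for j in range(int(np.floor(lo)), min(side, int(np.ceil(hi)))):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                P[i, j] = overlap / cell
    return P
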