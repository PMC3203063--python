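"""Round-trip-safe readers/writers for the pipeline's artifacts.

Two archive families:

* data archives — stimulus matrix + spike counts (+ optional ground-truth
  features), stored as NPZ with JSON metadata, or as a plain-text CSV
  fallback (one row per bin, response in the last column) that round-trips
  float64 exactly via 17-significant-digit repr;
* model archives — ``(a, h, upper triangle of J)`` with provenance,
  normalisation record and optional fold traces;
* feature CSVs — one row per feature (eigenvalue, significance flag, D
  components), final row reserved for the linear residual with its
  magnitude in the eigenvalue column.

Every writer embeds a format version and the effective configuration; the
readers check the version and name any missing key.
"""

from __future__ import annotations

import io
import json
import os
import zipfile
from typing import Optional

import numpy as np

from .containers import FeatureSet, QuadraticModel, SpikeResponse, StimulusEnsemble

__all__ = [
    "FORMAT_VERSION",
    "write_data_archive",
    "read_data_archive",
    "write_model_archive",
    "read_model_archive",
    "write_features_csv",
    "read_features_csv",
]

FORMAT_VERSION = "1"
_FLOAT_FMT = "%.17g"  # guarantees exact float64 round trip


class ArchiveError(ValueError):
    pass


def _require(container, key, path):
    if key not in container:
        raise ArchiveError(f"archive {path!r} is missing required key {key!r}")
    return container[key]


def _check_version(version, path):
    if str(version) != FORMAT_VERSION:
        raise ArchiveError(
            f"archive {path!r} has format version {version!r}, "
            f"this build reads version {FORMAT_VERSION!r}"
        )


def _geometry_to_json(geometry) -> str:
    return json.dumps(list(geometry))


def _geometry_from_json(text) -> tuple:
    kind, p1, p2 = json.loads(str(text))
    return (kind, p1, p2) if kind == "image" else (kind, int(p1), float(p2))


def write_data_archive(
    path: str,
    ensemble: StimulusEnsemble,
    response: SpikeResponse,
    truth_features: Optional[np.ndarray] = None,
    config: Optional[dict] = None,
) -> None:
    """Write a stimulus/response pair (NPZ, or CSV when the path ends in
    ``.csv``)."""
    if path.endswith(".csv"):
        _write_data_csv(path, ensemble, response)
        return
    payload = {
        "version": np.array(FORMAT_VERSION),
        "stimulus": ensemble.data.astype(np.float64),
        "counts": response.counts.astype(np.int64),
        "geometry": np.array(_geometry_to_json(ensemble.geometry)),
        "seed": np.array(-1 if ensemble.rng_seed is None else ensemble.rng_seed),
        "config": np.array(json.dumps(config or {})),
    }
    if ensemble.norm_mean is not None:
        payload["norm_mean"] = ensemble.norm_mean
        payload["norm_scale"] = np.array(ensemble.norm_scale)
    if truth_features is not None:
        payload["truth_features"] = np.asarray(truth_features, float)
    np.savez(path, **payload)


def read_data_archive(path: str):
    """Read a data archive; returns ``(ensemble, response, truth_or_None)``."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".csv"):
        ens, resp = _read_data_csv(path)
        return ens, resp, None
    with _open_npz(path) as z:
        _check_version(_require(z, "version", path), path)
        stimulus = _require(z, "stimulus", path)
        counts = _require(z, "counts", path)
        geometry = _geometry_from_json(_require(z, "geometry", path))
        seed = int(z["seed"]) if "seed" in z else -1
        norm_mean = z["norm_mean"] if "norm_mean" in z else None
        norm_scale = float(z["norm_scale"]) if "norm_scale" in z else None
        truth = z["truth_features"] if "truth_features" in z else None
        ens = StimulusEnsemble(
            data=stimulus, geometry=geometry,
            rng_seed=None if seed < 0 else seed,
            norm_mean=norm_mean, norm_scale=norm_scale,
        )
        return ens, SpikeResponse(counts=counts), truth


def _open_npz(path):
    """np.load with every corrupt-file failure mode mapped to ArchiveError."""
    try:
        z = np.load(path, allow_pickle=False)
        if not hasattr(z, "files"):
            raise ArchiveError(f"{path!r} is not an NPZ archive")
        return z
    except ArchiveError:
        raise
    except (zipfile.BadZipFile, OSError, ValueError) as exc:
        raise ArchiveError(f"corrupt or unreadable archive {path!r}: {exc}") from exc


def _write_data_csv(path, ensemble, response):
    n, d = ensemble.data.shape
    if n * d > 10**7:
        raise ArchiveError("CSV fallback is limited to N*D <= 1e7; use NPZ")
    header = (
        f"version={FORMAT_VERSION} geometry={_geometry_to_json(ensemble.geometry)} "
        "columns=stimulus-row-major,counts-last"
    )
    table = np.column_stack([ensemble.data, response.counts.astype(float)])
    np.savetxt(path, table, fmt=_FLOAT_FMT, delimiter=",", header=header)


def _read_data_csv(path):
    with open(path) as fh:
        first = fh.readline()
    if "version=" not in first:
        raise ArchiveError(f"CSV archive {path!r} is missing its header")
    version = first.split("version=")[1].split()[0]
    _check_version(version, path)
    geometry = _geometry_from_json(first.split("geometry=")[1].split(" columns")[0])
    table = np.atleast_2d(np.loadtxt(path, delimiter=","))
    ens = StimulusEnsemble(data=table[:, :-1], geometry=geometry)
    resp = SpikeResponse(counts=table[:, -1].astype(np.int64))
    return ens, resp


def write_model_archive(path: str, model: QuadraticModel,
                        fit_result=None, config: Optional[dict] = None) -> None:
    payload = {
        "version": np.array(FORMAT_VERSION),
        "a": np.array(model.a),
        "h": model.h,
        "j_upper": model.j_upper,
        "provenance": np.array(model.provenance),
        "config": np.array(json.dumps(config or {})),
    }
    if model.norm_mean is not None:
        payload["norm_mean"] = model.norm_mean
        payload["norm_scale"] = np.array(model.norm_scale)
    if fit_result is not None:
        for k, trace in enumerate(fit_result.train_traces):
            payload[f"train_trace_{k}"] = np.asarray(trace)
        for k, trace in enumerate(fit_result.test_traces):
            payload[f"test_trace_{k}"] = np.asarray(trace)
        payload["stop_iterations"] = np.asarray(fit_result.stop_iterations)
    np.savez(path, **payload)


def read_model_archive(path: str) -> QuadraticModel:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with _open_npz(path) as z:
        _check_version(_require(z, "version", path), path)
        return QuadraticModel(
            a=float(_require(z, "a", path)),
            h=_require(z, "h", path),
            j_upper=_require(z, "j_upper", path),
            provenance=str(_require(z, "provenance", path)),
            norm_mean=z["norm_mean"] if "norm_mean" in z else None,
            norm_scale=float(z["norm_scale"]) if "norm_scale" in z else None,
        )


def write_features_csv(path: str, features: FeatureSet,
                       config: Optional[dict] = None) -> None:
    """One row per feature: eigenvalue, significant flag, D components;
    final row is the linear residual, its magnitude in the eigenvalue
    column and flag fixed to 0."""
    buf = io.StringIO()
    buf.write(f"# version={FORMAT_VERSION} source={features.source} "
              f"columns=eigenvalue,significant,components...\n")
    buf.write(f"# config={json.dumps(config or {})}\n")
    buf.write("# last row: linear residual (magnitude in eigenvalue column)\n")
    for lam, flag, row in zip(features.eigenvalues, features.significant,
                              features.features):
        comps = ",".join(_FLOAT_FMT % v for v in row)
        buf.write(f"{_FLOAT_FMT % lam},{int(flag)},{comps}\n")
    comps = ",".join(_FLOAT_FMT % v for v in features.linear_residual)
    buf.write(f"{_FLOAT_FMT % features.residual_magnitude},0,{comps}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_features_csv(path: str) -> FeatureSet:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or "version=" not in lines[0]:
        raise ArchiveError(f"feature CSV {path!r} is missing its header")
    _check_version(lines[0].split("version=")[1].split()[0], path)
    source = lines[0].split("source=")[1].split()[0]
    rows = [np.fromstring(line, sep=",") for line in lines
            if not line.startswith("#") and line.strip()]
    table = np.vstack(rows)
    return FeatureSet(
        features=table[:-1, 2:],
        eigenvalues=table[:-1, 0],
        significant=table[:-1, 1] > 0.5,
        linear_residual=table[-1, 2:],
        residual_magnitude=float(table[-1, 0]),
        source=source,
    )
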