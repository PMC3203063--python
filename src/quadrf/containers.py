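"""Core data containers shared across the estimation pipeline.

Conventions used throughout the package:

* A stimulus ensemble is an ``N x D`` float64 matrix: one row per time bin
  (or trial), one column per stimulus dimension.  Image patches are
  flattened row-major; time-embedded flicker places the most recent bin at
  the last index.
* Spike responses are integer counts per bin; every estimator works on the
  binarised response ``r = min(counts, 1)``.
* A second-order model is the triplet ``(a, h, J)`` entering the logistic
  spike probability ``P(spike|s) = 1 / (1 + exp(a + h.s + s'Js))``: a more
  negative polynomial means a higher spike probability.  ``J`` is symmetric
  and stored as its upper triangle (``D(D+1)/2`` free entries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "StimulusEnsemble",
    "SpikeResponse",
    "QuadraticModel",
    "FeatureSet",
    "FitResult",
    "NullSpectrum",
    "pack_params",
    "unpack_params",
    "upper_triangle_indices",
]


def upper_triangle_indices(dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle (diagonal included),
    row-major, matching the packed storage order of ``J``."""
    return np.triu_indices(dims)


def pack_params(a: float, h: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Flatten ``(a, h, J)`` into a single parameter vector of length
    ``1 + D + D(D+1)/2``; ``J`` must be symmetric."""
    h = np.asarray(h, dtype=float)
    j = np.asarray(j, dtype=float)
    if j.shape != (h.size, h.size):
        raise ValueError("J must be D x D with D = len(h)")
    if not np.allclose(j, j.T, atol=1e-10):
        raise ValueError("J must be symmetric")
    iu, ju = upper_triangle_indices(h.size)
    return np.concatenate(([float(a)], h, j[iu, ju]))


def unpack_params(theta: np.ndarray, dims: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Inverse of :func:`pack_params`: rebuild ``(a, h, J)`` with ``J``
    symmetrised from its stored upper triangle."""
    theta = np.asarray(theta, dtype=float)
    n_quad = dims * (dims + 1) // 2
    if theta.size != 1 + dims + n_quad:
        raise ValueError(
            f"parameter vector has length {theta.size}, expected {1 + dims + n_quad}"
        )
    a = float(theta[0])
    h = theta[1 : 1 + dims].copy()
    j = np.zeros((dims, dims))
    iu, ju = upper_triangle_indices(dims)
    j[iu, ju] = theta[1 + dims :]
    j = j + np.triu(j, 1).T
    return a, h, j


@dataclass
class StimulusEnsemble:
    """An ``N x D`` stimulus matrix with geometry metadata.

    Parameters
    ----------
    data
        The stimulus matrix, one sample per row.
    geometry
        Either ``("image", height, width)`` with ``height * width == D``
        (row-major flattening) or ``("temporal", embed_depth, bin_duration)``
        with ``embed_depth == D``; ``bin_duration`` is in seconds and may be
        ``nan`` when unknown.
    rng_seed
        Seed used to generate the ensemble, or ``None`` for data loaded
        from file.
    norm_mean, norm_scale
        Standardisation record: per-dimension means subtracted and the
        single global scale divided out.  ``None`` until
        :meth:`standardized` is called; sufficient to invert exactly.
    """

    data: np.ndarray
    geometry: tuple
    rng_seed: Optional[int] = None
    norm_mean: Optional[np.ndarray] = None
    norm_scale: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("stimulus data must be 2-D (N samples x D dims)")
        n, d = self.data.shape
        if n < 1 or d < 1:
            raise ValueError("need N >= 1 samples and D >= 1 dimensions")
        kind = self.geometry[0]
        if kind == "image":
            _, height, width = self.geometry
            if height * width != d:
                raise ValueError(
                    f"image geometry {height}x{width} does not match D={d}"
                )
        elif kind == "temporal":
            _, depth, _ = self.geometry
            if depth != d:
                raise ValueError(f"embed depth {depth} does not match D={d}")
        else:
            raise ValueError(f"unknown geometry kind {kind!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_dims(self) -> int:
        return self.data.shape[1]

    def standardized(self) -> "StimulusEnsemble":
        """Per-dimension zero mean, global scale to unit average variance.

        A single global scale (not per-dimension) is used so that feature
        *directions* are identical in standardised and raw units.
        """
        mean = self.data.mean(axis=0)
        centered = self.data - mean
        scale = float(np.sqrt(np.mean(centered**2)))
        if scale == 0.0:
            raise ValueError("cannot standardize a constant ensemble")
        return StimulusEnsemble(
            data=centered / scale,
            geometry=self.geometry,
            rng_seed=self.rng_seed,
            norm_mean=mean,
            norm_scale=scale,
        )

    def unstandardized_data(self) -> np.ndarray:
        """Invert the stored standardisation record exactly."""
        if self.norm_mean is None or self.norm_scale is None:
            return self.data.copy()
        return self.data * self.norm_scale + self.norm_mean


@dataclass
class SpikeResponse:
    """Per-bin spike counts and their binarised form.

    ``binary[n] = min(counts[n], 1)``: all multi-spike events are set to one
    before any model fitting, matching the binarisation every estimator in
    this package assumes.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = counts

    @property
    def binary(self) -> np.ndarray:
        return np.minimum(self.counts, 1).astype(np.float64)

    @property
    def n_spikes(self) -> int:
        return int(np.minimum(self.counts, 1).sum())


@dataclass
class QuadraticModel:
    """Parameters ``(a, h, J)`` of a second-order spike-probability model.

    ``J`` is stored as its upper triangle (``j_upper``) so the symmetry
    invariant holds by construction.  ``provenance`` records which method
    produced the model.
    """

    a: float
    h: np.ndarray
    j_upper: np.ndarray
    provenance: str = "minimal_model"
    norm_mean: Optional[np.ndarray] = None
    norm_scale: Optional[float] = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.j_upper = np.asarray(self.j_upper, dtype=np.float64)
        d = self.h.size
        if self.j_upper.size != d * (d + 1) // 2:
            raise ValueError("j_upper length must be D(D+1)/2")
        if self.provenance not in {"minimal_model", "nmid", "mid", "ground_truth"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @classmethod
    def from_full(cls, a, h, j, provenance="minimal_model", **kw) -> "QuadraticModel":
        j = np.asarray(j, dtype=float)
        if not np.allclose(j, j.T, atol=1e-8):
            raise ValueError("J must be symmetric")
        j = 0.5 * (j + j.T)
        iu, ju = upper_triangle_indices(len(h))
        return cls(a=float(a), h=np.asarray(h, float), j_upper=j[iu, ju],
                   provenance=provenance, **kw)

    @property
    def n_dims(self) -> int:
        return self.h.size

    @property
    def j(self) -> np.ndarray:
        """The full symmetric ``D x D`` quadratic kernel."""
        d = self.n_dims
        j = np.zeros((d, d))
        iu, ju = upper_triangle_indices(d)
        j[iu, ju] = self.j_upper
        return j + np.triu(j, 1).T

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate(([self.a], self.h, self.j_upper))


@dataclass
class FeatureSet:
    """Ranked features (unit-norm rows), eigenvalues, significance flags,
    and the linear residual orthogonal to every listed feature."""

    features: np.ndarray
    eigenvalues: np.ndarray
    significant: np.ndarray
    linear_residual: np.ndarray
    residual_magnitude: float
    source: str

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, float))
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        self.significant = np.asarray(self.significant, bool)
        self.linear_residual = np.asarray(self.linear_residual, float)
        if self.source not in {"stc", "minimal_model", "nmid", "mid", "ground_truth"}:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def significant_features(self) -> np.ndarray:
        return self.features[self.significant]


@dataclass
class FitResult:
    """Cross-validated fit output: per-fold parameter vectors, the averaged
    model, and the train/test objective traces used for early stopping."""

    fold_params: list
    model: QuadraticModel
    train_traces: list
    test_traces: list
    stop_iterations: list
    seed: Optional[int] = None


@dataclass
class NullSpectrum:
    """Pooled eigenvalues of Gaussian random symmetric matrices matched in
    element variance to an empirical kernel, with percentile thresholds."""

    eigenvalues: np.ndarray
    lower: float
    upper: float
    element_variance: float
    seed: Optional[int] = None
    percentiles: tuple = (2.5, 97.5)
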