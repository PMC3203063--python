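"""Stimulus-ensemble generators with controlled statistics.

Second-order receptive-field estimators behave very differently on white
Gaussian noise, correlated Gaussian noise, and naturalistic inputs (heavy
tails, approximately 1/f spatial power spectra).  This module generates all
three regimes, plus time-embedded scalar flicker, and can crop patches from
an external grayscale image database when one is available.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import os
from typing import Callable, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import StimulusEnsemble

__all__ = [
    "generate_gaussian",
    "generate_naturalistic_patches",
    "time_embed",
    "load_image_patches",
    "radial_spectral_slope",
]


def generate_gaussian(
    n_samples: int,
    dims: int,
    covariance_spec: Union[str, np.ndarray] = "white",
    seed: int = 0,
) -> StimulusEnsemble:
    """Draw ``n_samples`` rows from a zero-mean Gaussian.

    Parameters
    ----------
    covariance_spec
        ``"white"`` for the identity covariance, or a symmetric
        positive-definite ``dims x dims`` matrix.

    Raises
    ------
    ValueError
        If the covariance is not symmetric positive-definite; the message
        names the offending (smallest) eigenvalue.
    """
    if n_samples < 1 or dims < 1:
        raise ValueError("need n_samples >= 1 and dims >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, dims))
    if isinstance(covariance_spec, str):
        if covariance_spec != "white":
            raise ValueError(f"unknown covariance spec {covariance_spec!r}")
        data = z
    else:
        cov = np.asarray(covariance_spec, dtype=float)
        if cov.shape != (dims, dims):
            raise ValueError(f"covariance must be {dims}x{dims}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals[0] <= 0:
            raise ValueError(
                f"covariance is not positive definite: smallest eigenvalue "
                f"{eigvals[0]:.3e} <= 0"
            )
        chol = np.linalg.cholesky(cov)
        data = z @ chol.T
    # use a square-ish image geometry only when dims is a perfect square;
    # otherwise treat as a temporal embedding of depth dims
    side = int(round(np.sqrt(dims)))
    if side * side == dims:
        geometry = ("image", side, side)
    else:
        geometry = ("temporal", dims, float("nan"))
    return StimulusEnsemble(data=data, geometry=geometry, rng_seed=seed)


def _tail_transform_fn(tail_transform) -> Callable[[np.ndarray], np.ndarray]:
    if callable(tail_transform):
        return tail_transform
    if tail_transform == "identity":
        return lambda g: g
    if tail_transform == "lognormal":
        # exp of a unit-variance Gaussian field, mild contrast so the
        # power-law spectral shape survives the pointwise nonlinearity
        return lambda g: np.exp(0.45 * g)
    raise ValueError(f"unknown tail transform {tail_transform!r}")


def generate_naturalistic_patches(
    n_samples: int,
    height: int,
    width: int,
    spectral_exponent: float = 2.0,
    tail_transform: Union[str, Callable] = "lognormal",
    seed: int = 0,
) -> StimulusEnsemble:
    """Synthetic naturalistic image patches.

    Each patch is an independent Gaussian random field shaped in the
    frequency domain so its power spectrum falls as ``1/f**spectral_exponent``,
    then passed through a pointwise monotone tail transform (``"lognormal"``
    = exponentiation, producing positive excess kurtosis as in photographic
    intensity histograms; ``"identity"`` keeps the field Gaussian), then
    mean-subtracted per pixel over the ensemble.

    With ``spectral_exponent=0`` and the identity transform this reduces to
    white Gaussian noise.
    """
    if height < 1 or width < 1 or height * width < 1:
        raise ValueError("patch must contain at least one pixel")
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_samples, height, width))
    if spectral_exponent > 0:
        fy = np.fft.fftfreq(height) * height
        fx = np.fft.fftfreq(width) * width
        f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
        amp = np.zeros_like(f)
        nonzero = f > 0
        amp[nonzero] = f[nonzero] ** (-spectral_exponent / 2.0)
        spectra = np.fft.fft2(g, axes=(1, 2)) * amp[None, :, :]
        g = np.fft.ifft2(spectra, axes=(1, 2)).real
        g /= g.std()
    fields = _tail_transform_fn(tail_transform)(g)
    data = fields.reshape(n_samples, height * width)
    data = data - data.mean(axis=0)
    return StimulusEnsemble(
        data=data, geometry=("image", height, width), rng_seed=seed
    )


def radial_spectral_slope(ensemble: StimulusEnsemble) -> float:
    """Log-log slope of the ensemble-average radial power spectrum.

    Used to verify that generated (or loaded) patches follow the requested
    ``1/f**exponent`` power law; returns the regression slope of
    ``log P(f)`` on ``log f`` over all nonzero integer-radius bins.
    """
    kind, height, width = ensemble.geometry
    if kind != "image":
        raise ValueError("spectral slope is defined for image ensembles")
    patches = ensemble.data.reshape(-1, height, width)
    power = np.abs(np.fft.fft2(patches, axes=(1, 2))) ** 2
    power = power.mean(axis=0)
    fy = np.fft.fftfreq(height) * height
    fx = np.fft.fftfreq(width) * width
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    radius = np.round(f).astype(int)
    max_r = min(height, width) // 2
    logf, logp = [], []
    for r in range(1, max_r + 1):
        mask = radius == r
        if mask.any():
            # mean log-frequency of the bin, not log(r): integer-radius bins
            # mix frequencies and would otherwise bias the slope shallow
            logf.append(np.mean(np.log(f[mask])))
            logp.append(np.log(power[mask].mean()))
    slope = np.polyfit(logf, logp, 1)[0]
    return float(slope)


def time_embed(
    intensity_series: Sequence[float],
    embed_depth: int,
    bin_duration: float = float("nan"),
) -> StimulusEnsemble:
    """Time-embed a scalar flicker sequence into an ``(T-depth+1) x depth``
    design matrix.

    Row ``t`` holds the ``embed_depth`` most recent intensities up to and
    including bin ``t``, ordered oldest -> most recent (the current bin sits
    at the last index); each row aligns with the response bin of its most
    recent sample.  Display conventions that plot kernels "as a function of
    time before a spike" simply reverse this axis.
    """
    series = np.asarray(intensity_series, dtype=float).ravel()
    if embed_depth < 1:
        raise ValueError("embed_depth must be >= 1")
    if series.size < embed_depth:
        raise ValueError(
            f"series length {series.size} < embed depth {embed_depth}"
        )
    data = sliding_window_view(series, embed_depth).copy()
    return StimulusEnsemble(
        data=data, geometry=("temporal", embed_depth, bin_duration)
    )


_IMAGE_EXTS = {".png", ".pgm", ".pbm", ".ppm", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


def load_image_patches(
    image_source: str,
    n_samples: int,
    height: int,
    width: int,
    seed: int = 0,
    log_intensity: bool = False,
) -> StimulusEnsemble:
    """Crop ``n_samples`` patches at uniformly random positions from the
    grayscale images in a directory.

    Images are read with :mod:`imageio` (any common raster format); color
    images are averaged to grayscale.  ``log_intensity`` applies
    ``log(1 + I)`` before cropping, the usual compression for photographic
    luminance databases.
    """
    import imageio.v3 as iio

    if not os.path.isdir(image_source):
        raise ValueError(f"image source {image_source!r} is not a directory")
    paths = sorted(
        os.path.join(image_source, name)
        for name in os.listdir(image_source)
        if os.path.splitext(name)[1].lower() in _IMAGE_EXTS
    )
    if not paths:
        raise ValueError(f"no raster images found in {image_source!r}")
    images = []
    for path in paths:
        try:
            img = np.asarray(iio.imread(path), dtype=float)
        except Exception as exc:
            raise ValueError(f"unreadable image file {path!r}: {exc}") from exc
        if img.ndim == 3:
            img = img.mean(axis=2)
        if img.shape[0] < height or img.shape[1] < width:
            raise ValueError(
                f"patch {height}x{width} larger than image {path!r} "
                f"({img.shape[0]}x{img.shape[1]})"
            )
        if log_intensity:
            img = np.log1p(np.maximum(img, 0.0))
        images.append(img)
    rng = np.random.default_rng(seed)
    data = np.empty((n_samples, height * width))
    img_idx = rng.integers(0, len(images), size=n_samples)
    for k in range(n_samples):
        img = images[img_idx[k]]
        top = rng.integers(0, img.shape[0] - height + 1)
        left = rng.integers(0, img.shape[1] - width + 1)
        data[k] = img[top : top + height, left : left + width].ravel()
    return StimulusEnsemble(
        data=data, geometry=("image", height, width), rng_seed=seed
    )
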