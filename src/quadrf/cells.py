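"""Simulated model neurons with known ground-truth features.

Three linear-nonlinear-Poisson cells are provided, all phase-invariant
(quadratic) in their feature projections:

* ``energy``: a V1 complex-cell energy model — spike probability
  proportional to the summed squared projections onto two quadrature Gabor
  features.
* ``divisive``: an energy numerator divisively normalised by a constant
  plus the summed squared projections onto four suppressive features (two
  center features at the orthogonal orientation, two surround features at
  the parallel orientation), six ground-truth dimensions in total.
* ``quadratic_logistic``: an explicit second-order logistic cell
  ``P(spike|s) = 1/(1+exp(a + h.s + s'Js))``, i.e. a neuron inside the
  minimal-model class.

Spike counts are Poisson per bin with intensity ``-ln(1-p)`` so that the
binarised response has spike probability exactly ``p``; calibration of the
mean spike probability therefore survives binarisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import QuadraticModel, SpikeResponse, StimulusEnsemble

__all__ = [
    "GaborSpec",
    "ModelCell",
    "make_gabor",
    "energy_model_cell",
    "divisive_model_cell",
    "quadratic_logistic_cell",
    "spike_probability",
    "energy_rate",
    "divisive_rate",
    "calibrate_scale",
    "sample_spikes",
]


@dataclass
class GaborSpec:
    """Parameters of one Gabor filter on a ``height x width`` pixel grid.

    ``mask`` restricts the spatial extent: ``None`` (full field),
    ``("disk", radius)`` (receptive-field center only) or
    ``("annulus", r_inner, r_outer)`` (surround only).  Distances are in
    pixels from ``center``.
    """

    center: tuple = (0.0, 0.0)  # (x, y) in pixels
    orientation: float = 0.0  # radians
    frequency: float = 0.25  # cycles / pixel along the carrier
    phase: float = 0.0  # radians
    sigma: tuple = (1.5, 1.5)  # envelope widths (along, across) in pixels
    mask: Optional[tuple] = None


def make_gabor(spec: GaborSpec, height: int, width: int) -> np.ndarray:
    """Render ``spec`` as a unit-norm feature vector of length
    ``height * width`` (row-major flattening).

    A pair of specs differing only by a pi/2 phase shift forms a quadrature
    pair, orthogonal up to pixel discretisation.
    """
    y, x = np.mgrid[0:height, 0:width].astype(float)
    cx, cy = spec.center
    dx, dy = x - cx, y - cy
    along = dx * np.cos(spec.orientation) + dy * np.sin(spec.orientation)
    across = -dx * np.sin(spec.orientation) + dy * np.cos(spec.orientation)
    sa, sc = spec.sigma
    envelope = np.exp(-(along**2 / (2 * sa**2) + across**2 / (2 * sc**2)))
    carrier = np.cos(2 * np.pi * spec.frequency * along + spec.phase)
    g = envelope * carrier
    if spec.mask is not None:
        r = np.sqrt(dx**2 + dy**2)
        if spec.mask[0] == "disk":
            g = np.where(r <= spec.mask[1], g, 0.0)
        elif spec.mask[0] == "annulus":
            g = np.where((r > spec.mask[1]) & (r <= spec.mask[2]), g, 0.0)
        else:
            raise ValueError(f"unknown mask kind {spec.mask[0]!r}")
    norm = np.linalg.norm(g)
    if norm < 1e-12:
        raise ValueError("degenerate Gabor spec: filter has zero energy")
    return (g / norm).ravel()


@dataclass
class ModelCell:
    """Ground-truth features plus a static nonlinearity.

    All feature rows are unit norm (any rescaling is absorbed into
    ``scale``); ``scale`` is the single free parameter adjusted by
    :func:`calibrate_scale` (for ``quadratic_logistic`` the calibrated
    parameter is the bias ``a`` of ``truth_model`` instead).
    """

    excitatory_features: np.ndarray
    inhibitory_features: np.ndarray
    nonlinearity: str
    scale: float = 1.0
    truth_model: Optional[QuadraticModel] = None

    def __post_init__(self) -> None:
        self.excitatory_features = np.atleast_2d(
            np.asarray(self.excitatory_features, float)
        )
        self.inhibitory_features = (
            np.atleast_2d(np.asarray(self.inhibitory_features, float))
            if np.size(self.inhibitory_features)
            else np.zeros((0, self.excitatory_features.shape[1]))
        )
        if self.nonlinearity not in {"energy", "divisive", "quadratic_logistic"}:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        for f in (self.excitatory_features, self.inhibitory_features):
            if f.shape[0]:
                norms = np.linalg.norm(f, axis=1)
                f /= norms[:, None]

    @property
    def features(self) -> np.ndarray:
        """All ground-truth features stacked (excitatory first)."""
        return np.vstack([self.excitatory_features, self.inhibitory_features])


def _rows(stimulus) -> np.ndarray:
    s = np.asarray(stimulus, float)
    return s[None, :] if s.ndim == 1 else s


def energy_rate(cell: ModelCell, stimulus) -> np.ndarray:
    """``min(1, scale * sum_k (e_k . s)^2)``: phase-invariant energy drive."""
    s = _rows(stimulus)
    drive = ((s @ cell.excitatory_features.T) ** 2).sum(axis=1)
    p = np.minimum(1.0, cell.scale * drive)
    return p if np.asarray(stimulus).ndim > 1 else float(p[0])


def divisive_rate(cell: ModelCell, stimulus) -> np.ndarray:
    """``min(1, scale * E / (1 + I))`` with ``E``/``I`` the summed squared
    excitatory/inhibitory projections — divisive normalisation."""
    s = _rows(stimulus)
    e = ((s @ cell.excitatory_features.T) ** 2).sum(axis=1)
    i = ((s @ cell.inhibitory_features.T) ** 2).sum(axis=1)
    p = np.minimum(1.0, cell.scale * e / (1.0 + i))
    return p if np.asarray(stimulus).ndim > 1 else float(p[0])


def _logistic_rate(model: QuadraticModel, s: np.ndarray) -> np.ndarray:
    from .minimal_model import predict_prob_matrix

    return predict_prob_matrix(model, s)


def spike_probability(cell: ModelCell, ensemble) -> np.ndarray:
    """Per-bin spike probability of ``cell`` over an ensemble (or matrix)."""
    s = ensemble.data if isinstance(ensemble, StimulusEnsemble) else _rows(ensemble)
    if cell.nonlinearity == "energy":
        return energy_rate(cell, s)
    if cell.nonlinearity == "divisive":
        return divisive_rate(cell, s)
    if cell.truth_model is None:
        raise ValueError("quadratic_logistic cell needs an explicit truth_model")
    return _logistic_rate(cell.truth_model, s)


def calibrate_scale(
    cell: ModelCell,
    ensemble: StimulusEnsemble,
    target_mean_prob: float = 0.15,
    rel_tol: float = 1e-4,
) -> ModelCell:
    """Deterministically calibrate the cell so its mean spike probability
    over ``ensemble`` hits ``target_mean_prob`` (bisection; result within
    ``rel_tol`` relative, far inside the 1% contract).

    For energy/divisive cells the multiplicative ``scale`` is bisected; for
    quadratic-logistic cells the bias ``a`` (the only monotone free
    parameter of that nonlinearity) is bisected instead.
    """
    if not 0.0 < target_mean_prob < 1.0:
        raise ValueError("target_mean_prob must be in (0, 1)")

    if cell.nonlinearity == "quadratic_logistic":
        model = cell.truth_model
        if model is None:
            raise ValueError("quadratic_logistic cell needs an explicit truth_model")

        def mean_at(a: float) -> float:
            m = QuadraticModel(a=a, h=model.h, j_upper=model.j_upper,
                               provenance="ground_truth")
            return float(np.mean(_logistic_rate(m, ensemble.data)))

        lo, hi = -50.0, 50.0
        while hi - lo > 1e-12:
            mid = 0.5 * (lo + hi)
            if mean_at(mid) > target_mean_prob:
                lo = mid  # mean decreases with a: raise a
            else:
                hi = mid
            if abs(mean_at(mid) / target_mean_prob - 1.0) < rel_tol:
                break
        a = 0.5 * (lo + hi)
        new_model = QuadraticModel(a=a, h=model.h, j_upper=model.j_upper,
                                   provenance="ground_truth")
        return ModelCell(cell.excitatory_features, cell.inhibitory_features,
                         cell.nonlinearity, scale=cell.scale,
                         truth_model=new_model)

    s = ensemble.data
    e = ((s @ cell.excitatory_features.T) ** 2).sum(axis=1)
    if cell.nonlinearity == "divisive":
        i = ((s @ cell.inhibitory_features.T) ** 2).sum(axis=1)
        raw = e / (1.0 + i)  # unclipped drive at scale = 1
    else:
        raw = e
    if not np.any(raw > 0):
        raise ValueError("unreachable target: the stimulus never drives the cell")

    def mean_at(scale: float) -> float:
        return float(np.mean(np.minimum(1.0, scale * raw)))

    lo, hi = 0.0, 1.0
    while mean_at(hi) < target_mean_prob:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(
                "unreachable target: mean probability saturates below target"
            )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target_mean_prob:
            lo = mid
        else:
            hi = mid
        if abs(mean_at(mid) / target_mean_prob - 1.0) < rel_tol:
            lo = hi = mid
            break
    scale = 0.5 * (lo + hi)
    return ModelCell(cell.excitatory_features, cell.inhibitory_features,
                     cell.nonlinearity, scale=scale, truth_model=cell.truth_model)


def sample_spikes(cell: ModelCell, ensemble: StimulusEnsemble, seed: int = 0) -> SpikeResponse:
    """Draw per-bin Poisson spike counts from the cell's rate.

    The Poisson intensity is ``-ln(1 - p)`` so that ``P(count >= 1)``
    equals the per-bin spike probability ``p`` exactly; multi-spike bins
    occur with the Poisson law's natural frequency and the binarised
    response mean matches the calibrated probability.
    """
    p = np.clip(spike_probability(cell, ensemble), 0.0, 1.0 - 1e-12)
    lam = -np.log1p(-p)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return SpikeResponse(counts=counts)


# ---------------------------------------------------------------------------
# The two reference model cells
# ---------------------------------------------------------------------------

def _quadrature_pair(height, width, orientation, frequency, sigma, mask, center=None):
    if center is None:
        center = ((width - 1) / 2.0, (height - 1) / 2.0)
    specs = [
        GaborSpec(center=center, orientation=orientation, frequency=frequency,
                  phase=ph, sigma=sigma, mask=mask)
        for ph in (0.0, np.pi / 2)
    ]
    return np.vstack([make_gabor(s, height, width) for s in specs])


def energy_model_cell(
    height: int = 8,
    width: int = 8,
    orientation: float = np.pi / 4,
    frequency: float = 0.3,
    sigma: tuple = (2.0, 2.0),
) -> ModelCell:
    """Complex-cell energy model: two quadrature (90-degrees-out-of-phase)
    Gabor features, squared and summed."""
    exc = _quadrature_pair(height, width, orientation, frequency, sigma, None)
    return ModelCell(excitatory_features=exc, inhibitory_features=np.zeros((0, height * width)),
                     nonlinearity="energy")


def divisive_model_cell(
    height: int = 8,
    width: int = 8,
    orientation: float = np.pi / 4,
    frequency: float = 0.3,
    center_radius: float = 2.4,
    surround_outer: float = 5.5,
) -> ModelCell:
    """Divisively normalised complex cell with six ground-truth features:
    an excitatory quadrature pair in the receptive-field center, an
    inhibitory pair at the orthogonal orientation in the center, and an
    inhibitory pair at the parallel orientation in the surround annulus."""
    d = height * width
    sigma_c = (center_radius, center_radius)
    sigma_s = (surround_outer, surround_outer)
    exc = _quadrature_pair(height, width, orientation, frequency, sigma_c,
                           ("disk", center_radius))
    inh_center = _quadrature_pair(height, width, orientation + np.pi / 2,
                                  frequency, sigma_c, ("disk", center_radius))
    inh_surround = _quadrature_pair(height, width, orientation, frequency,
                                    sigma_s, ("annulus", center_radius, surround_outer))
    inh = np.vstack([inh_center, inh_surround])
    return ModelCell(excitatory_features=exc, inhibitory_features=inh,
                     nonlinearity="divisive")


def quadratic_logistic_cell(a: float, h: np.ndarray, j: np.ndarray) -> ModelCell:
    """A cell drawn from the minimal-model class itself: spike probability
    is the logistic of ``-(a + h.s + s'Js)``.  Ground-truth features are the
    eigenvectors of ``J`` (stored stacked for convenience)."""
    model = QuadraticModel.from_full(a, h, j, provenance="ground_truth")
    eigvals, eigvecs = np.linalg.eigh(model.j)
    order = np.argsort(-np.abs(eigvals))
    feats = eigvecs[:, order].T
    return ModelCell(excitatory_features=feats, inhibitory_features=np.zeros((0, len(h))),
                     nonlinearity="quadratic_logistic", truth_model=model)
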