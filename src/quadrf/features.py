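"""From fitted quadratic kernels to ranked, significance-flagged features.

The eigenvectors of the symmetric kernel ``J`` are the principal axes of
the model's constant-probability (quadric) surfaces; the eigenvalue
magnitude along an axis measures the curvature — hence the selectivity —
of the surface in that direction.  Significance of each eigenvalue is
assessed against the pooled eigenvalue distribution of Gaussian random
symmetric matrices matched in element variance to ``J``.  The linear
kernel ``h`` may carry one additional feature: subtracting its projections
onto the significant eigenvectors leaves an orthogonal residual whose
magnitude is reported on the same scale as the eigenvalues.

Subspace recovery is scored with the subspace projection: the product of
the cosines of the principal angles between two feature subspaces, a
scalar in [0, 1] that is invariant to any invertible recombination or
rescaling of either basis.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .containers import FeatureSet, NullSpectrum, QuadraticModel

__all__ = [
    "diagonalize_quadratic",
    "eigenvalue_significance",
    "linear_residual",
    "subspace_projection",
]


def _sorted_eigh(j: np.ndarray):
    eigvals, eigvecs = np.linalg.eigh(j)
    order = np.argsort(-np.abs(eigvals), kind="stable")
    return eigvals[order], eigvecs[:, order].T  # rows = features


def diagonalize_quadratic(model: QuadraticModel) -> FeatureSet:
    """Full eigen-decomposition of ``J``, features (unit-norm, mutually
    orthogonal rows) sorted by eigenvalue magnitude descending; equal
    magnitudes keep ascending eigenvalue-index order."""
    eigvals, feats = _sorted_eigh(model.j)
    # all D eigenvectors span the space, so h has no orthogonal remainder
    residual = model.h - feats.T @ (feats @ model.h)
    return FeatureSet(
        features=feats,
        eigenvalues=eigvals,
        significant=np.zeros(eigvals.size, dtype=bool),
        linear_residual=residual,
        residual_magnitude=float(np.linalg.norm(residual)),
        source="minimal_model" if model.provenance == "minimal_model" else model.provenance,
    )


def eigenvalue_significance(
    model: QuadraticModel,
    n_null: int = 500,
    percentiles: tuple = (2.5, 97.5),
    seed: int = 0,
) -> tuple[FeatureSet, NullSpectrum]:
    """Flag eigenvalues of ``J`` outside the pooled null percentiles.

    ``n_null`` Gaussian random symmetric matrices are drawn whose
    independent elements have the same variance as the empirical set of
    elements of ``J``; their pooled eigenvalues give one global pair of
    percentile thresholds (linear interpolation).  Eigenvalues of ``J``
    below the lower or above the upper threshold are significant.

    The linear residual is recomputed against the significant features
    only, so ``h``'s unexplained component can be compared with the
    eigenvalue spectrum.
    """
    d = model.n_dims
    j = model.j
    element_var = float(j.ravel().var())
    fs = diagonalize_quadratic(model)
    if element_var <= 0.0:
        warnings.warn(
            "J has zero element variance; significance test is degenerate "
            "and no feature is flagged",
            RuntimeWarning,
        )
        null = NullSpectrum(eigenvalues=np.zeros(0), lower=0.0, upper=0.0,
                            element_variance=0.0, seed=seed, percentiles=percentiles)
        return fs, null

    rng = np.random.default_rng(seed)
    sd = np.sqrt(element_var)
    draws = rng.normal(0.0, sd, size=(n_null, d, d))
    upper = np.triu(draws)
    sym = upper + np.triu(draws, 1).transpose(0, 2, 1)
    pooled = np.linalg.eigvalsh(sym).ravel()
    lo = float(np.percentile(pooled, percentiles[0]))
    hi = float(np.percentile(pooled, percentiles[1]))
    flags = (fs.eigenvalues < lo) | (fs.eigenvalues > hi)

    sig = fs.features[flags]
    residual, magnitude = linear_residual(model, sig)
    result = FeatureSet(
        features=fs.features,
        eigenvalues=fs.eigenvalues,
        significant=flags,
        linear_residual=residual,
        residual_magnitude=magnitude,
        source=fs.source,
    )
    null = NullSpectrum(eigenvalues=pooled, lower=lo, upper=hi,
                        element_variance=element_var, seed=seed,
                        percentiles=percentiles)
    return result, null


def linear_residual(
    model: QuadraticModel, significant_features: np.ndarray
) -> tuple[np.ndarray, float]:
    """Component of the linear kernel ``h`` orthogonal to the significant
    features (which must be mutually orthonormal rows), and its norm."""
    v = np.atleast_2d(np.asarray(significant_features, float))
    if v.size == 0:
        residual = model.h.copy()
    else:
        gram = v @ v.T
        if not np.allclose(gram, np.eye(v.shape[0]), atol=1e-6):
            raise ValueError("significant features must be mutually orthonormal")
        residual = model.h - v.T @ (v @ model.h)
    return residual, float(np.linalg.norm(residual))


def subspace_projection(basis_a: np.ndarray, basis_b: np.ndarray) -> float:
    """Overlap of the subspaces spanned by the rows of two bases.

    Computed as the product of the cosines of the principal angles between
    the two spans (the singular values of ``Qa Qb'`` after orthonormalising
    each basis) — the normalised intersection of the volumes spanned by the
    two vector sets.  Equals 1 iff the spans coincide, 0 iff some direction
    of the smaller span is orthogonal to the other; invariant to any
    invertible recombination or rescaling of either basis, and symmetric
    when both bases have the same rank.
    """
    a = np.atleast_2d(np.asarray(basis_a, float))
    b = np.atleast_2d(np.asarray(basis_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("bases must live in the same ambient dimension")
    qa = _orthonormal_rows(a)
    qb = _orthonormal_rows(b)
    svals = np.linalg.svd(qa @ qb.T, compute_uv=False)
    return float(np.prod(np.clip(svals, 0.0, 1.0)))


def _orthonormal_rows(basis: np.ndarray) -> np.ndarray:
    u, s, vt = np.linalg.svd(basis, full_matrices=False)
    rank_tol = max(basis.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if s.size == 0 or np.any(s <= max(rank_tol, 1e-12)):
        raise ValueError("basis is rank deficient")
    return vt
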