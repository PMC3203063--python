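"""Information-per-spike estimation and maximally informative dimensions.

The information a projection ``x = v.s`` (or a pair of projections)
carries per spike is the Kullback-Leibler divergence between the
spike-conditional and prior distributions of ``x``,

    I_spike = sum_x P(x|spike) log2 [ P(x|spike) / P(x) ],

estimated here with quantile-binned histograms, which makes the estimate
exactly invariant to any strictly monotone transform of the projection.

Linear MID searches for the one or two directions maximising this
quantity.  Nonlinear MID (nMID) first expands the stimulus with all
pairwise products, ``y(s) = (s, upper-triangle of s s')`` with off-diagonal
terms doubled, so that a single direction ``v`` in the expanded space
encodes a full quadratic form: ``v.y(s) = h.s + s'Js``.  The search is
therefore one-dimensional regardless of how many features ``J`` contains,
avoiding the curse of dimensionality of multi-dimensional linear MID.

The objective is not convex, so the optimiser combines stochastic gradient
ascent (re-randomised minibatches) with simulated annealing, and uses the
same four-fold early-stopping protocol as the minimal-model fit.  Because
the hard-binned objective is piecewise constant in ``v``, gradients are
taken on a smoothed soft-bin surrogate (Gaussian bin memberships with
bandwidth set by the bin spacing); all accept/reject decisions and the
reported information use the hard quantile-bin estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .containers import (
    QuadraticModel,
    SpikeResponse,
    StimulusEnsemble,
    unpack_params,
    upper_triangle_indices,
)

__all__ = [
    "ExpandedStimulus",
    "quad_expand",
    "info_per_spike",
    "info_permutation_null",
    "optimize_mid",
    "fit_nmid",
    "MIDResult",
    "model_projection",
]

DEFAULT_BINS_1D = 16
DEFAULT_BINS_2D = 12


# ---------------------------------------------------------------------------
# Quadratic expansion
# ---------------------------------------------------------------------------

@dataclass
class ExpandedStimulus:
    """Stimulus matrix lifted to ``N x (D + D(D+1)/2)``.

    The first ``n_linear`` columns are the raw stimulus; the remaining
    columns are the upper-triangle products ``s_i s_j`` in row-major order
    with off-diagonal entries premultiplied by 2, so that for a direction
    ``v`` holding ``(h, upper-triangle of J)``, ``v . y(s) = h.s + s'Js``
    exactly.  ``index_map`` maps each expanded column to ``(i,)`` or
    ``(i, j)`` original indices.
    """

    data: np.ndarray
    index_map: list
    n_linear: int


def quad_expand(ensemble: Union[StimulusEnsemble, np.ndarray]) -> ExpandedStimulus:
    """Materialise the second-order stimulus expansion."""
    s = ensemble.data if isinstance(ensemble, StimulusEnsemble) else np.atleast_2d(np.asarray(ensemble, float))
    n, d = s.shape
    iu, ju = upper_triangle_indices(d)
    quad = s[:, iu] * s[:, ju]
    quad[:, iu != ju] *= 2.0
    index_map = [(i,) for i in range(d)] + list(zip(iu.tolist(), ju.tolist()))
    return ExpandedStimulus(data=np.hstack([s, quad]), index_map=index_map, n_linear=d)


def model_projection(model: QuadraticModel, s: np.ndarray) -> np.ndarray:
    """``h.s + s'Js`` for every row of ``s`` — the quadratic projection a
    second-order model induces, computed without materialising the
    expansion."""
    return s @ model.h + np.einsum("ni,ni->n", s @ model.j, s)


# ---------------------------------------------------------------------------
# Information per spike (hard quantile bins)
# ---------------------------------------------------------------------------

def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` quantile bins of the prior
    distribution (half-open edges, last bin closed)."""
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, x, side="right")


def info_per_spike(
    projections: np.ndarray,
    response_binary: np.ndarray,
    n_bins: Optional[int] = None,
) -> float:
    """Histogram estimate of the per-spike information (bits) carried by
    one or two projections.

    Bins are quantiles of the prior projection distribution, so the
    estimate is invariant to strictly monotone transforms of each
    projection.  Spike bins with zero count contribute zero.
    """
    x = np.asarray(projections, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] not in (1, 2):
        raise ValueError("projections must be N x k with k in {1, 2}")
    r = np.asarray(response_binary, float)
    n_spk = r.sum()
    if n_spk < 1:
        raise ValueError("information per spike needs at least one spike")
    if n_bins is None:
        n_bins = DEFAULT_BINS_1D if x.shape[1] == 1 else DEFAULT_BINS_2D
    flat = _quantile_bin(x[:, 0], n_bins)
    n_cells = n_bins
    if x.shape[1] == 2:
        flat = flat * n_bins + _quantile_bin(x[:, 1], n_bins)
        n_cells = n_bins * n_bins
    p_all = np.bincount(flat, minlength=n_cells).astype(float)
    p_all /= p_all.sum()
    p_spk = np.bincount(flat, weights=r, minlength=n_cells) / n_spk
    occupied = p_spk > 0
    return float(np.sum(p_spk[occupied] * np.log2(p_spk[occupied] / p_all[occupied])))


def info_permutation_null(
    projections: np.ndarray,
    response_binary: np.ndarray,
    n_perm: int = 100,
    n_bins: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Information estimates under ``n_perm`` random permutations of the
    response — the estimator's positive bias floor when the response is
    independent of the projection."""
    rng = np.random.default_rng(seed)
    r = np.asarray(response_binary, float)
    return np.array([
        info_per_spike(projections, rng.permutation(r), n_bins=n_bins)
        for _ in range(n_perm)
    ])


# ---------------------------------------------------------------------------
# Smoothed surrogate objective (for gradients only)
# ---------------------------------------------------------------------------

def soft_info_and_sample_grad(
    x: np.ndarray,
    r: np.ndarray,
    n_bins: int,
    centers: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Smoothed 1-d information and its gradient with respect to each
    projection value.

    Gaussian soft-bin memberships around quantile-spaced centers (treated
    as constants) replace the hard histogram; the returned per-sample
    derivatives ``dI/dx_n`` turn into a direction gradient via
    ``sum_n (dI/dx_n) y_n``.  This surrogate is differentiable, so its
    analytic gradient can be checked against finite differences.
    """
    r = np.asarray(r, float)
    n = x.size
    n_spk = r.sum()
    if centers is None:
        centers = np.quantile(x, (np.arange(n_bins) + 0.5) / n_bins)
    sigma = max(np.median(np.diff(np.sort(centers))), 1e-12) * 0.9
    z = (x[:, None] - centers[None, :]) / sigma
    u = np.exp(-0.5 * z**2)
    rho = u / np.maximum(u.sum(axis=1, keepdims=True), 1e-300)
    p = rho.mean(axis=0)
    q = (r @ rho) / n_spk
    eps = 1e-12
    log_ratio = np.log2((q + eps) / (p + eps))
    info = float(np.sum(q * log_ratio))
    d_q = log_ratio + 1.0 / np.log(2.0)
    d_p = -(q + eps) / ((p + eps) * np.log(2.0))
    mu = rho @ centers
    t = rho * (centers[None, :] - mu[:, None]) / sigma**2
    grad_x = t @ d_q * (r / n_spk) + (t @ d_p) / n
    return info, grad_x


def _soft_info_grad_2d(x1, x2, r, n_bins):
    """Smoothed 2-d information and per-sample gradients for both
    projections (product soft bins)."""
    r = np.asarray(r, float)
    n = x1.size
    n_spk = r.sum()

    def _memberships(x):
        centers = np.quantile(x, (np.arange(n_bins) + 0.5) / n_bins)
        sigma = max(np.median(np.diff(np.sort(centers))), 1e-12) * 0.9
        z = (x[:, None] - centers[None, :]) / sigma
        u = np.exp(-0.5 * z**2)
        rho = u / np.maximum(u.sum(axis=1, keepdims=True), 1e-300)
        mu = rho @ centers
        t = rho * (centers[None, :] - mu[:, None]) / sigma**2
        return rho, t

    rho1, t1 = _memberships(x1)
    rho2, t2 = _memberships(x2)
    p = (rho1.T @ rho2) / n
    q = ((r[:, None] * rho1).T @ rho2) / n_spk
    eps = 1e-12
    log_ratio = np.log2((q + eps) / (p + eps))
    info = float(np.sum(q * log_ratio))
    d_q = log_ratio + 1.0 / np.log(2.0)
    d_p = -(q + eps) / ((p + eps) * np.log(2.0))
    # dI/dx1_n = sum_bc t1_nb rho2_nc [ r_n d_q_bc / n_spk + d_p_bc / n ]
    g1 = np.einsum("nb,nc,bc->n", t1, rho2, d_q) * (r / n_spk) \
        + np.einsum("nb,nc,bc->n", t1, rho2, d_p) / n
    g2 = np.einsum("nb,nc,bc->n", rho1, t2, d_q) * (r / n_spk) \
        + np.einsum("nb,nc,bc->n", rho1, t2, d_p) / n
    return info, g1, g2


# ---------------------------------------------------------------------------
# Optimisation engine
# ---------------------------------------------------------------------------

class _MatrixOps:
    """Projections and weighted sums against an explicit stimulus matrix."""

    def __init__(self, x: np.ndarray):
        self.x = x
        self.n, self.dim = x.shape

    def project(self, v: np.ndarray, idx=None) -> np.ndarray:
        x = self.x if idx is None else self.x[idx]
        return x @ np.atleast_2d(v).T

    def weighted_sum(self, w: np.ndarray, idx=None) -> np.ndarray:
        x = self.x if idx is None else self.x[idx]
        return x.T @ w


class _QuadOps:
    """Implicit second-order expansion: projections and weighted sums of
    ``y(s)`` computed from the raw ``N x D`` matrix, never materialising
    the ``N x (D + D(D+1)/2)`` expansion."""

    def __init__(self, s: np.ndarray):
        self.s = s
        self.n, self.d = s.shape
        self.iu, self.ju = upper_triangle_indices(self.d)
        self.dim = self.d + self.iu.size

    def _unpack(self, v: np.ndarray):
        v = np.ravel(v)
        h = v[: self.d]
        j = np.zeros((self.d, self.d))
        j[self.iu, self.ju] = v[self.d :]
        j = j + np.triu(j, 1).T
        return h, j

    def project(self, v: np.ndarray, idx=None) -> np.ndarray:
        s = self.s if idx is None else self.s[idx]
        h, j = self._unpack(v)
        return (s @ h + np.einsum("ni,ni->n", s @ j, s))[:, None]

    def weighted_sum(self, w: np.ndarray, idx=None) -> np.ndarray:
        s = self.s if idx is None else self.s[idx]
        g_lin = s.T @ w
        g_mat = s.T @ (w[:, None] * s)
        g_quad = g_mat[self.iu, self.ju] * np.where(self.iu == self.ju, 1.0, 2.0)
        return np.concatenate([g_lin, g_quad])


@dataclass
class MIDResult:
    """Directions maximising the per-spike information, with per-fold
    vectors and the train/test information traces behind early stopping."""

    directions: np.ndarray
    fold_directions: list
    train_traces: list
    test_traces: list
    stop_iterations: list
    seed: Optional[int] = None


def _hard_info(ops, v, r, idx, n_bins):
    proj = ops.project(v, idx)
    return info_per_spike(proj if proj.shape[1] > 1 else proj[:, 0], r[idx], n_bins)


def _optimize_fold_mid(ops, r, train_idx, test_idx, v0, n_bins, annealing,
                       minibatch_frac, rng):
    t0, decay, n_iter = annealing
    k = v0.shape[0]
    v = v0 / np.linalg.norm(v0, axis=1, keepdims=True)
    step = 0.1
    train_trace = [_hard_info(ops, v, r, train_idx, n_bins)]
    test_trace = [_hard_info(ops, v, r, test_idx, n_bins)]
    best = {"v": v.copy(), "test": test_trace[0], "iter": 0}
    current_train = train_trace[0]
    n_train = train_idx.size

    for it in range(1, n_iter + 1):
        batch = train_idx[rng.random(n_train) < minibatch_frac]
        if batch.size < 50 or r[batch].sum() < 2:
            batch = train_idx
        proj = ops.project(v, batch)
        if k == 1:
            _, gx = soft_info_and_sample_grad(proj[:, 0], r[batch], n_bins)
            grads = [ops.weighted_sum(gx, batch)]
        else:
            _, g1, g2 = _soft_info_grad_2d(proj[:, 0], proj[:, 1], r[batch], n_bins)
            grads = [ops.weighted_sum(g1, batch), ops.weighted_sum(g2, batch)]
        proposal = v.copy()
        for row, g in enumerate(grads):
            gnorm = np.linalg.norm(g)
            if gnorm > 0:
                proposal[row] = v[row] + step * g / gnorm
        proposal /= np.linalg.norm(proposal, axis=1, keepdims=True)
        new_train = _hard_info(ops, proposal, r, train_idx, n_bins)
        temp = t0 * decay**it
        accept = new_train >= current_train or (
            temp > 0 and rng.random() < np.exp((new_train - current_train) / temp)
        )
        if accept:
            v = proposal
            current_train = new_train
            step *= 1.1
        else:
            step *= 0.6
        train_trace.append(current_train)
        test_info = _hard_info(ops, v, r, test_idx, n_bins)
        test_trace.append(test_info)
        if test_info > best["test"]:
            best.update(v=v.copy(), test=test_info, iter=it)
    return best["v"], train_trace, test_trace, best["iter"]


def _align(v, ref):
    """Rotate/reflect the rows of ``v`` onto ``ref`` (orthogonal Procrustes)
    so fold directions can be averaged despite sign/rotation ambiguity."""
    m = ref @ v.T
    u, _, wt = np.linalg.svd(m)
    return (u @ wt) @ v


def optimize_mid(
    stimulus: Union[StimulusEnsemble, ExpandedStimulus, np.ndarray],
    response: SpikeResponse,
    n_dims: int = 1,
    init: Optional[np.ndarray] = None,
    n_bins: Optional[int] = None,
    annealing: tuple = (0.05, 0.95, 150),
    folds: int = 4,
    seed: int = 0,
    minibatch_frac: float = 0.7,
) -> MIDResult:
    """Maximise the per-spike information over ``n_dims`` directions.

    ``stimulus`` is a raw ensemble/matrix for linear MID (``n_dims`` 1 or
    2, jointly optimised over the 2-d histogram) or an
    :class:`ExpandedStimulus` for nonlinear MID (``n_dims`` must be 1).
    Each fold trains on three quarters with the held-out quarter's
    information tracked every iteration; the parameters at the held-out
    maximum are kept and fold directions are Procrustes-aligned and
    averaged.  Deterministic under ``seed``.
    """
    if isinstance(stimulus, ExpandedStimulus):
        if n_dims != 1:
            raise ValueError("nonlinear MID is one-dimensional in the expanded space")
        ops = _MatrixOps(stimulus.data)
    else:
        if n_dims not in (1, 2):
            raise ValueError(
                "linear MID supports at most 2 dimensions: the histogram "
                "estimator cannot be sampled in higher dimension"
            )
        x = stimulus.data if isinstance(stimulus, StimulusEnsemble) else np.asarray(stimulus, float)
        ops = _MatrixOps(x)
    return _run_mid(ops, response, n_dims, init, n_bins, annealing, folds,
                    seed, minibatch_frac)


def _informed_start(ops, r, n_dims, n_bins, rng, n_candidates=20):
    """Multi-start initialisation: score candidate unit directions by the
    hard information on all data and seed the search from the best (for
    two dimensions, the best-scoring pair of the top candidates).

    The candidate pool mixes random directions with moment-based ones —
    the spike-triggered average and the top eigenvectors of the
    spike-triggered covariance difference, both computed from the data at
    hand.  The information landscape is flat around most random directions
    in high dimension and has strong local maxima, so informed starts
    matter more than the annealing that follows; starting an information
    maximisation from second-moment estimates is the field's standard
    remedy."""
    all_idx = np.arange(ops.n)
    cands = rng.standard_normal((n_candidates, ops.dim))
    if isinstance(ops, _MatrixOps):
        x = ops.x
        n_spk = r.sum()
        sta = x.T @ r / n_spk
        mean = x.mean(axis=0)
        xc = x - mean
        c_prior = (xc.T @ xc) / x.shape[0]
        xs = x - sta
        c_spike = (xs.T @ (r[:, None] * xs)) / n_spk
        eigvals, eigvecs = np.linalg.eigh(c_spike - c_prior)
        order = np.argsort(-np.abs(eigvals))[: min(8, ops.dim)]
        cands = np.vstack([cands, eigvecs[:, order].T, sta[None, :]])
    cands /= np.linalg.norm(cands, axis=1, keepdims=True)
    scores = [_hard_info(ops, v[None, :], r, all_idx, n_bins) for v in cands]
    order = np.argsort(scores)[::-1]
    if n_dims == 1:
        return cands[order[:1]]
    top = cands[order[:5]]
    best_pair, best_score = (0, 1), -np.inf
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            score = _hard_info(ops, top[[i, j]], r, all_idx, n_bins)
            if score > best_score:
                best_pair, best_score = (i, j), score
    return top[list(best_pair)]


def _run_mid(ops, response, n_dims, init, n_bins, annealing, folds, seed,
             minibatch_frac) -> MIDResult:
    r = response.binary if isinstance(response, SpikeResponse) else np.asarray(response, float)
    n = ops.n
    if n_bins is None:
        n_bins = DEFAULT_BINS_1D if n_dims == 1 else DEFAULT_BINS_2D
    rng = np.random.default_rng(seed)
    if init is None:
        v0 = _informed_start(ops, r, n_dims, n_bins, rng)
    else:
        v0 = np.atleast_2d(np.asarray(init, float)).copy()
    v0 /= np.linalg.norm(v0, axis=1, keepdims=True)

    edges = np.linspace(0, n, folds + 1).astype(int)
    fold_dirs, train_traces, test_traces, stops = [], [], [], []
    for k in range(folds):
        test_mask = np.zeros(n, dtype=bool)
        test_mask[edges[k]: edges[k + 1]] = True
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        if r[train_idx].sum() < 1 or r[test_idx].sum() < 1:
            raise ValueError(f"fold {k} has a split without spikes")
        v, tr, te, stop = _optimize_fold_mid(
            ops, r, train_idx, test_idx, v0, n_bins, annealing,
            minibatch_frac, np.random.default_rng(rng.integers(2**31)),
        )
        fold_dirs.append(v)
        train_traces.append(tr)
        test_traces.append(te)
        stops.append(stop)

    avg = fold_dirs[0].copy()
    for v in fold_dirs[1:]:
        avg += _align(v, fold_dirs[0])
    avg /= len(fold_dirs)
    avg /= np.linalg.norm(avg, axis=1, keepdims=True)
    return MIDResult(directions=avg, fold_directions=fold_dirs,
                     train_traces=train_traces, test_traces=test_traces,
                     stop_iterations=stops, seed=seed)


def fit_nmid(
    ensemble: StimulusEnsemble,
    response: SpikeResponse,
    mne_init: QuadraticModel,
    seed: int = 0,
    n_bins: Optional[int] = None,
    annealing: tuple = (0.02, 0.9, 40),
    folds: int = 4,
    minibatch_frac: float = 0.7,
) -> QuadraticModel:
    """Nonlinear MID: information maximisation over one direction of the
    quadratically expanded stimulus, started from a minimal-model estimate.

    The expansion is handled implicitly (projections and gradients are
    computed from the raw stimulus), so no ``N x (D + D(D+1)/2)`` matrix is
    built.  The averaged optimal direction is disassembled back into
    ``(h, J)``; the bias ``a`` plays no role in the histogram nonlinearity
    and is carried over from the initialisation.
    """
    s = ensemble.data
    if mne_init.norm_mean is not None and ensemble.norm_mean is None:
        s = (s - mne_init.norm_mean) / mne_init.norm_scale
    ops = _QuadOps(s)
    d = s.shape[1]
    iu, ju = upper_triangle_indices(d)
    v_init = np.concatenate([mne_init.h, mne_init.j[iu, ju]])
    if np.linalg.norm(v_init) < 1e-12:
        raise ValueError("mne_init has zero (h, J); no search direction")
    result = _run_mid(ops, response, 1, v_init[None, :], n_bins, annealing,
                      folds, seed, minibatch_frac)
    v = result.directions[0]
    theta = np.concatenate(([0.0], v))
    _, h, j = unpack_params(theta, d)
    model = QuadraticModel.from_full(
        mne_init.a, h, j, provenance="nmid",
        norm_mean=mne_init.norm_mean, norm_scale=mne_init.norm_scale,
    )
    model.fit_traces = {
        "train": result.train_traces,
        "test": result.test_traces,
        "stop_iterations": result.stop_iterations,
    }
    return model
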