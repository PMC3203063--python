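"""Second-order minimal (maximum-noise-entropy) model fitting.

The minimal model of a binary spike train constrained to match the observed
mean spike probability, spike-triggered average and spike-triggered
covariance is the logistic model

    P(spike | s) = 1 / (1 + exp(a + h.s + s'Js)),

the least-biased (maximum noise entropy, minimum mutual information) model
consistent with those first- and second-order stimulus/response moments.
Matching the moments is equivalent to maximizing the Bernoulli
log-likelihood of the data, which is concave in ``(a, h, J)``, so a
quasi-Newton ascent finds the global optimum from any start.

Overfitting is controlled by four-fold early stopping: the data is split
into four contiguous quarters; each fit trains on three quarters while the
held-out quarter's likelihood is tracked every iteration, the parameters at
its maximum are kept, and the four parameter vectors are averaged before
any eigen-analysis.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .containers import (
    FitResult,
    QuadraticModel,
    SpikeResponse,
    StimulusEnsemble,
    pack_params,
    unpack_params,
    upper_triangle_indices,
)

__all__ = [
    "predict_prob",
    "predict_prob_matrix",
    "log_likelihood_and_gradient",
    "fit_minimal_model",
    "check_constraints",
    "to_raw_units",
]


def _quad_form(s: np.ndarray, j: np.ndarray) -> np.ndarray:
    return np.einsum("ni,ni->n", s @ j, s)


def _model_matrix(model: QuadraticModel, ensemble) -> np.ndarray:
    """Stimulus matrix in the units the model was fitted in.

    If the model carries a standardisation record and the ensemble is raw
    (no record of its own), the model's record is applied.
    """
    if isinstance(ensemble, StimulusEnsemble):
        s = ensemble.data
        if model.norm_mean is not None and ensemble.norm_mean is None:
            s = (s - model.norm_mean) / model.norm_scale
        return s
    return np.atleast_2d(np.asarray(ensemble, float))


def predict_prob_matrix(model: QuadraticModel, s: np.ndarray) -> np.ndarray:
    z = model.a + s @ model.h + _quad_form(s, model.j)
    return expit(-z)  # overflow-safe: in (0,1) for any finite argument


def predict_prob(model: QuadraticModel, ensemble) -> np.ndarray:
    """Per-bin spike probability ``1/(1+exp(a + h.s + s'Js))``; a more
    negative polynomial yields a higher probability."""
    return predict_prob_matrix(model, _model_matrix(model, ensemble))


def log_likelihood_and_gradient(
    model: QuadraticModel, ensemble, response_binary: np.ndarray
) -> tuple[float, np.ndarray]:
    """Total Bernoulli log-likelihood and its gradient over the
    ``1 + D + D(D+1)/2`` packed parameters.

    Each gradient component is the (model minus empirical) moment mismatch
    under the Eq.-style sign convention of the exponent: ``sum_n (p_n - r_n)``
    for ``a``, ``sum_n (p_n - r_n) s_ni`` for ``h_i`` and
    ``sum_n (p_n - r_n) s_ni s_nj`` for ``J_ij`` (off-diagonal components
    doubled, since each off-diagonal element appears twice in ``s'Js``).
    The gradient vanishes exactly when the model moments match the data.
    """
    s = _model_matrix(model, ensemble)
    r = np.asarray(response_binary, float)
    ll, grad = _ll_grad_packed(model.theta, s, r)
    return ll, grad


def _ll_grad_packed(theta: np.ndarray, s: np.ndarray, r: np.ndarray):
    d = s.shape[1]
    a, h, j = unpack_params(theta, d)
    z = a + s @ h + _quad_form(s, j)
    p = expit(-z)
    # log P uses log-sigmoid forms, stable for large |z|
    ll = float(np.sum(np.where(r > 0.5, -np.logaddexp(0.0, z), -np.logaddexp(0.0, -z))))
    w = p - r
    g_a = float(w.sum())
    g_h = s.T @ w
    g_mat = s.T @ (w[:, None] * s)
    iu, ju = upper_triangle_indices(d)
    g_j = g_mat[iu, ju] * np.where(iu == ju, 1.0, 2.0)
    return ll, np.concatenate(([g_a], g_h, g_j))


def _optimize_fold(
    s_train: np.ndarray,
    r_train: np.ndarray,
    s_test: Optional[np.ndarray],
    r_test: Optional[np.ndarray],
    x0: np.ndarray,
    max_iter: int,
    tol: float,
):
    """L-BFGS ascent of the (concave) likelihood with per-iteration
    held-out tracking; returns the parameters at the held-out maximum."""
    n_train = s_train.shape[0]

    def objective(theta):
        ll, grad = _ll_grad_packed(theta, s_train, r_train)
        return -ll / n_train, -grad / n_train

    train_trace = []
    test_trace = []
    best = {"theta": x0.copy(), "test_ll": -np.inf, "iter": 0}

    def track(theta, iteration):
        ll_train, _ = _ll_grad_packed(theta, s_train, r_train)
        train_trace.append(ll_train / n_train)
        if s_test is not None:
            ll_test, _ = _ll_grad_packed(theta, s_test, r_test)
            test_trace.append(ll_test / s_test.shape[0])
            if ll_test > best["test_ll"]:
                best.update(theta=np.array(theta), test_ll=ll_test, iter=iteration)

    track(x0, 0)
    counter = {"k": 0}

    def callback(xk):
        counter["k"] += 1
        track(xk, counter["k"])

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14, "maxcor": 20},
    )
    if s_test is None:  # no early stopping: return the converged optimum
        return res.x, train_trace, test_trace, counter["k"]
    return best["theta"], train_trace, test_trace, best["iter"]


def _contiguous_folds(n: int, folds: int):
    edges = np.linspace(0, n, folds + 1).astype(int)
    return [(edges[k], edges[k + 1]) for k in range(folds)]


def fit_minimal_model(
    ensemble: StimulusEnsemble,
    response: SpikeResponse,
    folds: int = 4,
    max_iter: int = 100,
    tol: float = 1e-8,
    seed: Optional[int] = None,
    standardize: bool = True,
    init: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the second-order minimal model with ``folds``-fold early stopping.

    Folds are contiguous blocks (temporal structure preserved).  With
    ``folds=1`` the model is trained on all data to full convergence with no
    early stopping — the mode in which the moment-matching (maximum-entropy)
    constraints hold exactly.

    ``init`` overrides the default start (``h = J = 0`` and ``a`` set from
    the mean rate); ``seed`` instead draws a small random start, used to
    verify that concavity makes the optimum initialisation-independent.
    """
    r = response.binary
    n = ensemble.n_samples
    if n < 2 * folds:
        raise ValueError("too few samples for the requested fold count")
    if standardize:
        ensemble = ensemble.standardized()
    s = ensemble.data
    d = s.shape[1]

    n_params = 1 + d + d * (d + 1) // 2
    if init is not None:
        x0 = np.asarray(init, float).copy()
        if x0.size != n_params:
            raise ValueError("init has the wrong number of parameters")
    else:
        rate = max(r.mean(), 1.0 / n)
        x0 = np.zeros(n_params)
        x0[0] = np.log(1.0 / rate - 1.0)
        if seed is not None:
            x0 += np.random.default_rng(seed).normal(0.0, 0.1, size=n_params)

    fold_params, train_traces, test_traces, stops = [], [], [], []
    if folds == 1:
        theta, tr, te, stop = _optimize_fold(s, r, None, None, x0, max_iter, tol)
        fold_params, train_traces, test_traces, stops = [theta], [tr], [te], [stop]
    else:
        for k, (lo, hi) in enumerate(_contiguous_folds(n, folds)):
            test_mask = np.zeros(n, dtype=bool)
            test_mask[lo:hi] = True
            r_train = r[~test_mask]
            if r_train.sum() < 1:
                raise ValueError(f"training split for fold {k} contains no spikes")
            theta, tr, te, stop = _optimize_fold(
                s[~test_mask], r_train, s[test_mask], r[test_mask], x0, max_iter, tol
            )
            fold_params.append(theta)
            train_traces.append(tr)
            test_traces.append(te)
            stops.append(stop)

    theta_avg = np.mean(fold_params, axis=0)
    a, h, j = unpack_params(theta_avg, d)
    model = QuadraticModel.from_full(
        a, h, j, provenance="minimal_model",
        norm_mean=ensemble.norm_mean, norm_scale=ensemble.norm_scale,
    )
    return FitResult(
        fold_params=fold_params,
        model=model,
        train_traces=train_traces,
        test_traces=test_traces,
        stop_iterations=stops,
        seed=seed,
    )


def check_constraints(
    model: QuadraticModel, ensemble, response: SpikeResponse
) -> dict:
    """Moment-mismatch report: empirical minus model-predicted mean rate,
    STA moment and STC moment, all as per-sample averages in the units the
    model was fitted in.  At the fully converged optimum all three vanish
    (the defining maximum-entropy constraints)."""
    s = _model_matrix(model, ensemble)
    r = response.binary if isinstance(response, SpikeResponse) else np.asarray(response, float)
    p = predict_prob_matrix(model, s)
    n = s.shape[0]
    rate_mismatch = float((r - p).mean())
    sta_mismatch = (s.T @ (r - p)) / n
    stc_mismatch = (s.T @ ((r - p)[:, None] * s)) / n
    return {
        "mean_rate": rate_mismatch,
        "sta": sta_mismatch,
        "stc": stc_mismatch,
        "max_abs": max(
            abs(rate_mismatch),
            float(np.abs(sta_mismatch).max()),
            float(np.abs(stc_mismatch).max()),
        ),
    }


def to_raw_units(model: QuadraticModel) -> QuadraticModel:
    """Re-express a model fitted on standardised stimuli in raw stimulus
    units, using the stored normalisation record (exact)."""
    if model.norm_mean is None or model.norm_scale is None:
        return model
    m, c = model.norm_mean, model.norm_scale
    j = model.j
    j_raw = j / c**2
    h_raw = model.h / c - 2.0 * (j @ m) / c**2
    a_raw = model.a - model.h @ m / c + m @ j @ m / c**2
    return QuadraticModel.from_full(a_raw, h_raw, j_raw, provenance=model.provenance)
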