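"""Graph-regularized nonnegative matrix factorization of the association
matrix.

The binary association matrix ``Y`` (miRNAs x diseases) is approximated by
``W @ H.T`` with nonnegative factors ``W`` (miRNAs x k) and ``H``
(diseases x k).  The objective couples a Frobenius reconstruction term with
a ridge penalty and two graph penalties that pull the latent vectors of
similar miRNAs (resp. diseases) together:

    J(W, H) = || I o (Y - W H^T) ||_F^2
            + lambda_l (||W||_F^2 + ||H||_F^2)
            + lambda_m  sum_{i<p} ||w_i - w_p||^2 S_m[i, p]
            + lambda_d  sum_{j<q} ||h_j - h_q||^2 S_d[j, q]

where ``o`` is the Hadamard product and ``I`` an observation mask (all ones
here: unknown pairs are treated as weak negatives).  Each unordered pairwise
graph sum equals ``tr(W^T L W)`` with ``L = D - S`` the graph Laplacian, so
the KKT stationarity conditions yield the multiplicative updates

    W <- W o (Y H   + lambda_m S_m W) / (W H^T H + lambda_l W + lambda_m D_m W)
    H <- H o (Y^T W + lambda_d S_d H) / (H W^T W + lambda_l H + lambda_d D_d H)

Updates alternate (H uses the freshly updated W); from a positive start they
preserve nonnegativity and never increase the objective.  Predicted
association scores are ``Y* = W H^T``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "GraphLaplacian",
    "FactorModel",
    "laplacian",
    "objective",
    "init_factors",
    "update_step",
    "fit",
    "predict",
]


@dataclass(frozen=True)
class Hyperparams:
    """Solver hyperparameters.

    k          latent dimension of the factor matrices.
    lambda_l   ridge (Tikhonov) coefficient on ||W||_F^2 + ||H||_F^2.
    lambda_m   weight of the miRNA similarity graph penalty.
    lambda_d   weight of the disease similarity graph penalty.
    max_iter   iteration cap for the multiplicative updates.
    tol        relative objective-change convergence threshold.
    seed       seed for the (strictly positive) random initialization.
    eps        guard added to update denominators against 0/0.
    """

    k: int = 50
    lambda_l: float = 1.0
    lambda_m: float = 0.2
    lambda_d: float = 0.2
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        for name in ("lambda_l", "lambda_m", "lambda_d", "eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")

    def replace(self, **kwargs) -> "Hyperparams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class GraphLaplacian:
    """L = D - S for a symmetric nonnegative similarity matrix S."""

    L: np.ndarray
    D_diag: np.ndarray


@dataclass
class FactorModel:
    """Fitted nonnegative factors with the solver trace."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    converged: bool
    iterations_run: int
    hyper: Hyperparams


def _values(S) -> np.ndarray:
    return S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, float)


def laplacian(S) -> GraphLaplacian:
    """Graph Laplacian ``diag(rowsums(S)) - S`` of a similarity matrix."""
    S = _values(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if S.size and S.min() < 0:
        raise ValueError("similarity matrix must be nonnegative")
    d = S.sum(axis=1)
    L = np.diag(d) - S
    return GraphLaplacian(L=L, D_diag=d)


def objective(Y, I, W, H, S_m, S_d, hyper: Hyperparams) -> float:
    """Value of the regularized factorization objective.

    The unordered pairwise graph sums are evaluated through the trace
    identity ``sum_{i<p} ||w_i - w_p||^2 S[i, p] = tr(W^T L W)``.
    """
    Y, W, H = (np.asarray(a, float) for a in (Y, W, H))
    if W.min(initial=0) < 0 or H.min(initial=0) < 0:
        raise ValueError("factor matrices must be nonnegative")
    R = Y - W @ H.T
    if I is not None:
        R = np.asarray(I, float) * R
    val = float((R * R).sum())
    val += hyper.lambda_l * float((W * W).sum() + (H * H).sum())
    if hyper.lambda_m:
        Lm = laplacian(S_m).L
        val += hyper.lambda_m * float(((Lm @ W) * W).sum())
    if hyper.lambda_d:
        Ld = laplacian(S_d).L
        val += hyper.lambda_d * float(((Ld @ H) * H).sum())
    return val


def init_factors(
    n_m: int, n_d: int, y_mean: float, hyper: Hyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Strictly positive seeded initialization.

    Entries are Uniform(0.01, 1.01) scaled by sqrt(mean(Y)/k) so that the
    initial product W H^T has roughly the magnitude of the data; strict
    positivity avoids multiplicative-update lock-in at zero.
    """
    rng = np.random.default_rng(hyper.seed)
    scale = np.sqrt(max(y_mean, 1e-12) / hyper.k)
    W = (0.01 + rng.random((n_m, hyper.k))) * scale
    H = (0.01 + rng.random((n_d, hyper.k))) * scale
    return W, H


def update_step(Y, W, H, S_m, S_d, D_m, D_d, hyper: Hyperparams):
    """One alternating multiplicative update: W first, then H with the new W.

    ``D_m`` / ``D_d`` are the similarity degree vectors (or diagonal
    matrices) of ``S_m`` / ``S_d``.  Raises FloatingPointError if the
    iterate leaves the finite range.
    """
    Y = np.asarray(Y, float)
    S_m, S_d = _values(S_m), _values(S_d)
    D_m, D_d = (np.diag(D) if np.ndim(D) == 2 else np.asarray(D, float)
                for D in (D_m, D_d))
    lm, ld = hyper.lambda_m, hyper.lambda_d

    num_w = Y @ H + lm * (S_m @ W)
    den_w = W @ (H.T @ H) + hyper.lambda_l * W + lm * (D_m[:, None] * W) + hyper.eps
    W_new = W * num_w / den_w

    num_h = Y.T @ W_new + ld * (S_d @ H)
    den_h = (
        H @ (W_new.T @ W_new) + hyper.lambda_l * H + ld * (D_d[:, None] * H)
        + hyper.eps
    )
    H_new = H * num_h / den_h

    if not (np.isfinite(W_new).all() and np.isfinite(H_new).all()):
        raise FloatingPointError("non-finite entries in multiplicative update")
    return W_new, H_new


def fit(Y, S_m, S_d, hyper: Hyperparams | None = None) -> FactorModel:
    """Run the multiplicative updates until the relative objective change
    drops below ``hyper.tol`` or ``hyper.max_iter`` is reached.

    Deterministic for a given seed.  The recorded objective trace starts at
    the initial point, so ``len(trace) == iterations_run + 1``.
    """
    hyper = hyper or Hyperparams()
    Y = np.asarray(Y, float)
    S_m, S_d = _values(S_m), _values(S_d)
    n_m, n_d = Y.shape
    if S_m.shape != (n_m, n_m) or S_d.shape != (n_d, n_d):
        raise ValueError("similarity matrix shapes do not match Y")
    gl_m, gl_d = laplacian(S_m), laplacian(S_d)

    W, H = init_factors(n_m, n_d, float(Y.mean()), hyper)

    def _obj(W, H):
        R = Y - W @ H.T
        val = float((R * R).sum())
        val += hyper.lambda_l * float((W * W).sum() + (H * H).sum())
        val += hyper.lambda_m * float(((gl_m.L @ W) * W).sum())
        val += hyper.lambda_d * float(((gl_d.L @ H) * H).sum())
        return val

    trace = [_obj(W, H)]
    converged = False
    iterations = 0
    for it in range(1, hyper.max_iter + 1):
        try:
            W, H = update_step(Y, W, H, S_m, S_d, gl_m.D_diag, gl_d.D_diag, hyper)
        except FloatingPointError as exc:
            raise FloatingPointError(f"iteration {it}: {exc}") from exc
        trace.append(_obj(W, H))
        iterations = it
        prev, cur = trace[-2], trace[-1]
        if abs(prev - cur) <= hyper.tol * max(abs(prev), 1e-30):
            converged = True
            break
    return FactorModel(
        W=W, H=H, objective_trace=trace, converged=converged,
        iterations_run=iterations, hyper=hyper,
    )


def predict(model: FactorModel) -> np.ndarray:
    """Predicted association score matrix ``Y* = W H^T`` (nonnegative)."""
    return model.W @ model.H.T
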