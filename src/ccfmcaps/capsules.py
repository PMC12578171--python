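"""Capsule primitives: squash, prediction vectors, dynamic routing, losses.

A capsule is a group of neurons whose output vector encodes the pose of an
entity; the vector's length encodes the probability that the entity is
present.  Lower-level capsule outputs ``u_i`` are mapped to predictions
``u_hat_{j|i} = W_ij u_i`` for each higher-level capsule ``j``; *routing by
agreement* then iteratively concentrates each input capsule's coupling
coefficients ``c_ij`` (a softmax over ``j`` of logits ``b_ij``, initialized
to zero) on the output capsules whose aggregated, squashed output agrees
with its prediction:

    c = softmax(b);  s_j = sum_i c_ij u_hat_{j|i};  v_j = squash(s_j);
    b_ij += u_hat_{j|i} . v_j

The squash nonlinearity rescales a vector to length ||s||^2 / (1 + ||s||^2)
without changing its direction, so every capsule length is a probability in
[0, 1).

Training minimizes a per-class margin loss — present classes are pushed
above ``m_plus``, absent classes below ``m_minus`` with down-weight
``lambda_down`` — plus a reconstruction term weighted by ``recon_coeff``
(0.392 per flattened-pixel mean squared error by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarginLossConfig",
    "squash",
    "squash_backward",
    "predict",
    "coupling",
    "route",
    "margin_loss",
    "margin_loss_grad",
    "total_loss",
]

_EPS = 1e-7  # norm guard: squash(0) = 0 exactly, no division error


@dataclass
class MarginLossConfig:
    """Margins and weights of the composite capsule loss.

    The margin down-weight ``lambda_down`` (0.5) and the reconstruction
    coefficient ``recon_coeff`` (0.392) are distinct parameters even though
    both are conventionally written as a lambda.
    """

    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    recon_coeff: float = 0.392

    def __post_init__(self) -> None:
        if not 0 < self.m_minus < self.m_plus <= 1:
            raise ValueError("need 0 < m_minus < m_plus <= 1")
        if self.lambda_down <= 0:
            raise ValueError("lambda_down must be > 0")
        if self.recon_coeff < 0:
            raise ValueError("recon_coeff must be >= 0")


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vector squashing: same direction, length ||s||^2 / (1 + ||s||^2) < 1."""
    s = np.asarray(s, dtype=np.float64)
    sq = (s * s).sum(axis=axis, keepdims=True)
    norm = np.sqrt(sq + _EPS**2)
    return s * (norm / (1.0 + sq))


def squash_backward(s: np.ndarray, grad_v: np.ndarray, axis: int = -1
                    ) -> np.ndarray:
    """Gradient of ``squash`` with respect to its input.

    With n = ||s||, squash(s) = s * g(n) for g(n) = n / (1 + n^2), so
    ds = g(n) dv + (g'(n)/n) (s . dv) s with g'(n) = (1 - n^2)/(1 + n^2)^2.
    """
    s = np.asarray(s, dtype=np.float64)
    sq = (s * s).sum(axis=axis, keepdims=True)
    n = np.sqrt(sq + _EPS**2)
    g = n / (1.0 + sq)
    gp_over_n = (1.0 - sq) / ((1.0 + sq) ** 2 * n)
    dot = (s * grad_v).sum(axis=axis, keepdims=True)
    return g * grad_v + gp_over_n * dot * s


def predict(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Prediction vectors u_hat_{j|i} = W_ij u_i.

    u : (..., n_in, in_dim) input capsule vectors.
    W : (n_in, n_out, out_dim, in_dim) per-pair transform matrices.
    Returns (..., n_in, n_out, out_dim).
    """
    u = np.asarray(u, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if u.shape[-1] != W.shape[-1] or u.shape[-2] != W.shape[0]:
        raise ValueError(
            f"capsule/transform shape mismatch: u {u.shape} vs W {W.shape}")
    return np.einsum("...ip,ijdp->...ijd", u, W)


def coupling(b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Coupling coefficients: softmax of the routing logits over ``axis``.

    Normalization runs over the output capsules of each input capsule, so
    every input capsule distributes a unit of coupling across the layer
    above.
    """
    b = np.asarray(b, dtype=np.float64)
    z = b - b.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def route(u_hat: np.ndarray, iterations: int = 3, return_couplings: bool = False):
    """Dynamic routing by agreement.

    u_hat : (..., n_in, n_out, out_dim) prediction vectors.
    Returns the output capsule vectors v of shape (..., n_out, out_dim)
    (and the final coupling coefficients if requested).
    """
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    u_hat = np.asarray(u_hat, dtype=np.float64)
    b = np.zeros(u_hat.shape[:-1])
    for _ in range(iterations):
        c = coupling(b, axis=-1)
        s = np.einsum("...ij,...ijd->...jd", c, u_hat)
        v = squash(s, axis=-1)
        b = b + np.einsum("...ijd,...jd->...ij", u_hat, v)
    if return_couplings:
        return v, c
    return v


def margin_loss(v_norms: np.ndarray, one_hot: np.ndarray,
                cfg: MarginLossConfig | None = None) -> float:
    """Per-class hinge-squared margin loss, summed over classes, batch mean.

    L_k = T_k max(0, m+ - ||v_k||)^2
        + lambda (1 - T_k) max(0, ||v_k|| - m-)^2
    """
    cfg = cfg or MarginLossConfig()
    v_norms = np.atleast_2d(np.asarray(v_norms, dtype=np.float64))
    one_hot = np.atleast_2d(np.asarray(one_hot, dtype=np.float64))
    present = np.maximum(0.0, cfg.m_plus - v_norms) ** 2
    absent = np.maximum(0.0, v_norms - cfg.m_minus) ** 2
    per_class = one_hot * present + cfg.lambda_down * (1.0 - one_hot) * absent
    return float(per_class.sum(axis=-1).mean())


def margin_loss_grad(v_norms: np.ndarray, one_hot: np.ndarray,
                     cfg: MarginLossConfig | None = None) -> np.ndarray:
    """d(margin_loss)/d(v_norms), same shape as ``v_norms``."""
    cfg = cfg or MarginLossConfig()
    v_norms = np.atleast_2d(np.asarray(v_norms, dtype=np.float64))
    one_hot = np.atleast_2d(np.asarray(one_hot, dtype=np.float64))
    batch = v_norms.shape[0]
    g_present = -2.0 * np.maximum(0.0, cfg.m_plus - v_norms)
    g_absent = 2.0 * np.maximum(0.0, v_norms - cfg.m_minus)
    return (one_hot * g_present
            + cfg.lambda_down * (1.0 - one_hot) * g_absent) / batch


def total_loss(margin: float, reconstruction_error: float,
               cfg: MarginLossConfig | None = None) -> float:
    """Composite loss: margin + recon_coeff * mean-squared reconstruction error."""
    cfg = cfg or MarginLossConfig()
    if margin < 0 or reconstruction_error < 0:
        raise ValueError("loss terms must be non-negative")
    return float(margin + cfg.recon_coeff * reconstruction_error)
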