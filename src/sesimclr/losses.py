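"""Contrastive and classifier objectives.

The combined objective is

    L = L0 + rho * L1

where L0 is the NT-Xent contrastive loss over a batch of 2N projections (N
positive pairs; for each anchor the denominator runs over the other 2N-1
embeddings; similarities are cosine, scaled by a temperature tau), and L1 is
the *subspace penalty* on each positive pair.  L1 is, by default, the maximal
absolute coordinate of z_i - z_j (a Chebyshev/l-infinity distance): driving
the largest coordinate difference to zero pushes the two views' projections
to put their mass on the same coordinates, i.e. into a common subspace.  A
conventional sum-of-absolute-values l1 mode is available as
``subspace_norm="sum"``.

Batch conventions: projections arrive as a (2N, d) array with views
interleaved — rows 2k and 2k+1 are the positive pair of instance k.  L0 is
averaged over all 2N anchors; L1 is averaged over the N pairs, so rho has a
batch-size-independent meaning.

Each loss comes with an analytic gradient (``*_grad``) used by the trainer;
the gradients are checked against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "LossConfig",
    "EmbeddingPair",
    "cosine_sim",
    "ntxent_loss",
    "ntxent_loss_grad",
    "subspace_penalty",
    "subspace_penalty_grad",
    "combined_loss",
    "combined_loss_grad",
    "classifier_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Temperature tau, trade-off weight rho (default 0.01) and batch size N."""

    temperature: float = 0.5
    rho: float = 0.01
    batch_size: int = 128
    subspace_norm: str = "max"  # "max" (default, l-infinity) or "sum" (l1)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.subspace_norm not in ("max", "sum"):
            raise ValueError("subspace_norm must be 'max' or 'sum'")


@dataclass
class EmbeddingPair:
    """The two projected views (z_i, z_j) of one instance."""

    z_i: np.ndarray
    z_j: np.ndarray

    def __post_init__(self):
        self.z_i = np.asarray(self.z_i, dtype=float)
        self.z_j = np.asarray(self.z_j, dtype=float)
        if self.z_i.shape != self.z_j.shape:
            raise ValueError("z_i and z_j must have equal widths")
        if not (np.all(np.isfinite(self.z_i)) and np.all(np.isfinite(self.z_j))):
            raise ValueError("embeddings must be finite")


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (||u|| ||v||); raises on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def _pair_partner(n_rows: int) -> np.ndarray:
    """Partner index of each interleaved row: 0<->1, 2<->3, ..."""
    idx = np.arange(n_rows)
    return idx ^ 1


def _sim_matrix(z: np.ndarray, tau: float) -> np.ndarray:
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero embedding vector in batch")
    zhat = z / norms[:, None]
    return (zhat @ zhat.T) / tau, zhat, norms


def ntxent_loss(z: np.ndarray, temperature: float = 0.5) -> float:
    """Mean NT-Xent loss over all 2N anchors of an interleaved (2N, d) batch."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] == 0:
        raise ValueError("empty batch")
    if z.shape[0] % 2 != 0:
        raise ValueError("batch must hold 2N interleaved projections")
    n_rows = z.shape[0]
    s, _, _ = _sim_matrix(z, temperature)
    partner = _pair_partner(n_rows)
    s_masked = s.copy()
    np.fill_diagonal(s_masked, -np.inf)
    rows = np.arange(n_rows)
    return float(np.mean(-s[rows, partner] + logsumexp(s_masked, axis=1)))


def ntxent_loss_grad(z: np.ndarray, temperature: float = 0.5) -> tuple[float, np.ndarray]:
    """NT-Xent loss and its gradient w.r.t. the raw (unnormalized) projections."""
    z = np.asarray(z, dtype=float)
    n_rows = z.shape[0]
    if n_rows == 0 or n_rows % 2 != 0:
        raise ValueError("batch must hold 2N interleaved projections")
    s, zhat, norms = _sim_matrix(z, temperature)
    partner = _pair_partner(n_rows)

    # dL/dS: softmax over k != i, minus the positive indicator; averaged anchors
    s_masked = s.copy()
    np.fill_diagonal(s_masked, -np.inf)
    p = softmax(s_masked, axis=1)
    ds = p / n_rows
    rows = np.arange(n_rows)
    ds[rows, partner] -= 1.0 / n_rows

    lse = logsumexp(s_masked, axis=1)
    loss = float(np.mean(-s[rows, partner] + lse))

    # S = zhat zhat^T / tau  =>  dL/dzhat = (dS + dS^T) @ zhat / tau
    dzhat = (ds + ds.T) @ zhat / temperature
    # through row normalization: dz = (dzhat - zhat * <zhat, dzhat>) / ||z||
    inner = np.sum(zhat * dzhat, axis=1, keepdims=True)
    dz = (dzhat - zhat * inner) / norms[:, None]
    return loss, dz


def subspace_penalty(z_i: np.ndarray, z_j: np.ndarray, mode: str = "max") -> float:
    """Penalty on one positive pair: max_k |z_i - z_j|_k (default) or sum_k."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if z_i.shape != z_j.shape:
        raise ValueError("embedding widths differ")
    diff = np.abs(z_i - z_j)
    if mode == "max":
        return float(diff.max())
    if mode == "sum":
        return float(diff.sum())
    raise ValueError("mode must be 'max' or 'sum'")


def subspace_penalty_grad(z_i: np.ndarray, z_j: np.ndarray,
                          mode: str = "max") -> tuple[float, np.ndarray, np.ndarray]:
    """Penalty plus (sub)gradients w.r.t. z_i and z_j.

    In max mode the subgradient routes through the first coordinate attaining
    the maximum (a fixed tie-break so training is deterministic).
    """
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    d = z_i - z_j
    if mode == "max":
        k = int(np.argmax(np.abs(d)))
        g = np.zeros_like(d)
        g[k] = np.sign(d[k])
        return float(abs(d[k])), g, -g
    g = np.sign(d)
    return float(np.abs(d).sum()), g, -g


def combined_loss(z: np.ndarray, config: LossConfig) -> float:
    """L = NT-Xent + rho * mean pairwise subspace penalty, on an interleaved batch."""
    z = np.asarray(z, dtype=float)
    l0 = ntxent_loss(z, config.temperature)
    if config.rho == 0.0:
        return l0
    pens = [
        subspace_penalty(z[2 * k], z[2 * k + 1], config.subspace_norm)
        for k in range(z.shape[0] // 2)
    ]
    return l0 + config.rho * float(np.mean(pens))


def combined_loss_grad(z: np.ndarray, config: LossConfig) -> tuple[float, np.ndarray]:
    """Combined loss and gradient w.r.t. the raw projections."""
    z = np.asarray(z, dtype=float)
    loss, dz = ntxent_loss_grad(z, config.temperature)
    if config.rho == 0.0:
        return loss, dz
    n_pairs = z.shape[0] // 2
    pen_total = 0.0
    for k in range(n_pairs):
        pen, gi, gj = subspace_penalty_grad(z[2 * k], z[2 * k + 1], config.subspace_norm)
        pen_total += pen
        dz[2 * k] += config.rho * gi / n_pairs
        dz[2 * k + 1] += config.rho * gj / n_pairs
    return loss + config.rho * pen_total / n_pairs, dz


def classifier_loss(predictions, labels) -> float:
    """Mean squared error between slice probabilities and 0/1 labels."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if predictions.size == 0:
        raise ValueError("empty batch")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError("labels must be binary")
    return float(np.mean((predictions - labels) ** 2))
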