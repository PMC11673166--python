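"""Table-Similarity (TS) loss.

Compares a real and a synthetic table as *tables*, not as images: a table
carries the same statistical content under any permutation of its rows, so
the loss is built from row and column sums rather than cell-wise errors.

For an ``n_rows x n_cols`` pair (real X, synthetic Y):

* vertical term — column sums R_m, S_m; ``mu = mean_m |R_m - S_m|``
* horizontal term — row sums r_n, s_i; per real row the nearest synthetic
  row sum ``delta_n = min_i |r_n - s_i|``; ``nu = mean(delta)``;
  ``P = N / n_rows`` where N counts delta entries whose (rounded) value is
  repeated; ``D = nu * P``
* per-sample loss ``L = D + mu``; batch loss ``sqrt(mean_l L_l)``.

The loss is zero iff used on identical tables (up to row permutation of
equal row sums), invariant to row permutations of either argument, and
non-negative.  An analytic subgradient with respect to the synthetic table
is provided for training; the repeated-minimum fraction P is
piecewise-constant and is treated as a constant per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import ValidationError

__all__ = [
    "TSLossBreakdown",
    "row_sums",
    "column_sums",
    "ts_components",
    "ts_batch_loss",
    "ts_batch_loss_and_grad",
]


@dataclass
class TSLossBreakdown:
    """All intermediate TS-loss quantities for one real/synthetic pair."""

    row_sums_real: np.ndarray      # r, length n_rows
    row_sums_synth: np.ndarray     # s, length n_rows
    col_sums_real: np.ndarray      # R, length n_cols
    col_sums_synth: np.ndarray     # S, length n_cols
    col_diff_mean: float           # mu
    row_minima: np.ndarray         # delta, length n_rows
    repeated_count: int            # N
    repeated_fraction: float       # P = N / n_rows
    minima_mean: float             # nu
    horizontal_loss: float         # D = nu * P
    sample_loss: float             # L = D + mu


def _as_matrix(x) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValidationError("TS loss operands must be non-empty 2-D matrices")
    return m


def row_sums(table) -> np.ndarray:
    """Sum of each row (length n_rows)."""
    return _as_matrix(table).sum(axis=1)


def column_sums(table) -> np.ndarray:
    """Sum of each column (length n_cols)."""
    return _as_matrix(table).sum(axis=0)


def ts_components(real, synth, equality_decimals: int = 6,
                  signed_column_diff: bool = False) -> TSLossBreakdown:
    """Full TS-loss breakdown for one pair of equally shaped matrices.

    ``signed_column_diff`` switches the vertical term to the literal signed
    column differences (which can drive the loss negative); the default
    uses paired absolute differences, keeping every component >= 0.
    """
    X, Y = _as_matrix(real), _as_matrix(synth)
    if X.shape != Y.shape:
        raise ValidationError(f"shape mismatch: {X.shape} vs {Y.shape}")
    n_rows = X.shape[0]

    r, s = row_sums(X), row_sums(Y)
    R, S = column_sums(X), column_sums(Y)

    col_diff = (R - S) if signed_column_diff else np.abs(R - S)
    mu = float(col_diff.mean())

    delta = np.abs(r[:, None] - s[None, :]).min(axis=1)
    rounded = np.round(delta, equality_decimals)
    _, inverse, counts = np.unique(rounded, return_inverse=True, return_counts=True)
    N = int(np.sum(counts[inverse] >= 2))
    P = N / n_rows
    nu = float(delta.mean())
    D = nu * P
    return TSLossBreakdown(
        row_sums_real=r, row_sums_synth=s, col_sums_real=R, col_sums_synth=S,
        col_diff_mean=mu, row_minima=delta, repeated_count=N,
        repeated_fraction=P, minima_mean=nu, horizontal_loss=D,
        sample_loss=D + mu,
    )


def ts_batch_loss(pairs, apply_sqrt: bool = True,
                  equality_decimals: int = 6) -> float:
    """Batch TS loss: sqrt (by default) of the mean per-sample loss."""
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("ts_batch_loss: empty batch")
    losses = [ts_components(x, y, equality_decimals).sample_loss for x, y in pairs]
    mean = float(np.mean(losses))
    return float(np.sqrt(mean)) if apply_sqrt else mean


def _sample_grad(X: np.ndarray, Y: np.ndarray,
                 bd: TSLossBreakdown) -> np.ndarray:
    """dL/dY for one pair, holding P constant.

    mu term: dmu/dY_ij = -sign(R_j - S_j) / n_cols (same for every row i).
    D term: each delta_n picks an argmin synthetic row i*(n);
    d delta_n / ds_{i*} = -sign(r_n - s_{i*}), and ds_i/dY_ij = 1.
    At exact ties sign(0) = 0, so the gradient vanishes on identical
    tables.
    """
    n_rows, n_cols = X.shape
    grad = np.zeros_like(Y)
    # vertical term
    grad += -np.sign(bd.col_sums_real - bd.col_sums_synth) / n_cols
    # horizontal term
    r, s = bd.row_sums_real, bd.row_sums_synth
    diff = r[:, None] - s[None, :]
    argmin = np.abs(diff).argmin(axis=1)
    ds = np.zeros(n_rows)
    coef = bd.repeated_fraction / n_rows
    np.add.at(ds, argmin, -coef * np.sign(diff[np.arange(n_rows), argmin]))
    grad += ds[:, None]
    return grad


def ts_batch_loss_and_grad(reals, synths, apply_sqrt: bool = True,
                           equality_decimals: int = 6):
    """Batch loss and its subgradient w.r.t. each synthetic matrix.

    Returns ``(loss, grads)`` where ``grads`` is an array shaped like
    ``synths`` (batch, n_rows, n_cols).  The gradient is exactly zero when
    every synthetic table equals its real counterpart.
    """
    reals = np.asarray(reals, dtype=float)
    synths = np.asarray(synths, dtype=float)
    if reals.shape != synths.shape or reals.ndim != 3 or reals.shape[0] == 0:
        raise ValidationError("ts_batch_loss_and_grad: need matching 3-D batches")
    k = reals.shape[0]
    losses = np.empty(k)
    grads = np.empty_like(synths)
    for l in range(k):
        bd = ts_components(reals[l], synths[l], equality_decimals)
        losses[l] = bd.sample_loss
        grads[l] = _sample_grad(reals[l], synths[l], bd)
    mean = float(losses.mean())
    if not apply_sqrt:
        return mean, grads / k
    loss = float(np.sqrt(mean))
    if loss == 0.0:
        return 0.0, np.zeros_like(grads)
    return loss, grads / (2.0 * k * loss)
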