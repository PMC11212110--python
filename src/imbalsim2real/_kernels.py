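"""Numba-compiled forward/backward kernels for the flat-parameter MLP.

The layer loop over the small weight matrices is overhead-bound in pure
numpy; compiling it keeps full-protocol training runs at desk scale.  The
math is identical to a straightforward numpy implementation: float64
throughout, same BLAS matmuls, same reduction order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# activation codes
RELU = 0
LEAKY = 1


@njit(cache=True)
def forward(theta, X, dims, act_kind, slope, acts):
    """Forward pass writing every layer's activations into ``acts``.

    ``acts`` is a preallocated (n, sum(dims[1:])) buffer; returns nothing.
    Layer l's activation occupies columns [col_off_l, col_off_l + dims[l+1]).
    """
    n = X.shape[0]
    n_layers = dims.shape[0] - 1
    p_off = 0
    c_off = 0
    A = X
    for l in range(n_layers):
        d_in = dims[l]
        d_out = dims[l + 1]
        W = theta[p_off : p_off + d_in * d_out].reshape(d_in, d_out)
        p_off += d_in * d_out
        b = theta[p_off : p_off + d_out]
        p_off += d_out
        Z = np.dot(A, W)
        out = acts[:, c_off : c_off + d_out]
        if l < n_layers - 1:
            if act_kind == RELU:
                for i in range(n):
                    for j in range(d_out):
                        v = Z[i, j] + b[j]
                        out[i, j] = v if v > 0.0 else 0.0
            else:
                for i in range(n):
                    for j in range(d_out):
                        v = Z[i, j] + b[j]
                        out[i, j] = v if v > 0.0 else slope * v
        else:
            for i in range(n):
                for j in range(d_out):
                    out[i, j] = Z[i, j] + b[j]
        A = np.ascontiguousarray(out)
        acts[:, c_off : c_off + d_out] = A
        c_off += d_out


@njit(cache=True)
def backward(theta, X, acts, grad_out, dims, act_kind, slope, grad_buf, want_params):
    """Backprop; accumulates parameter grads into ``grad_buf`` when
    ``want_params`` and returns the gradient with respect to ``X``."""
    n_layers = dims.shape[0] - 1
    # parameter and activation-column offsets per layer
    p_offs = np.empty(n_layers, dtype=np.int64)
    c_offs = np.empty(n_layers, dtype=np.int64)
    p = 0
    c = 0
    for l in range(n_layers):
        p_offs[l] = p
        p += dims[l] * dims[l + 1] + dims[l + 1]
        c_offs[l] = c
        c += dims[l + 1]
    g = np.ascontiguousarray(grad_out)
    for l in range(n_layers - 1, -1, -1):
        d_in = dims[l]
        d_out = dims[l + 1]
        if l == 0:
            A_prev = X
        else:
            A_prev = np.ascontiguousarray(
                acts[:, c_offs[l - 1] : c_offs[l - 1] + d_in]
            )
        if want_params:
            gw = grad_buf[p_offs[l] : p_offs[l] + d_in * d_out].reshape(d_in, d_out)
            gw += np.dot(A_prev.T, g)
            gb = grad_buf[p_offs[l] + d_in * d_out : p_offs[l] + d_in * d_out + d_out]
            for j in range(d_out):
                s = 0.0
                for i in range(g.shape[0]):
                    s += g[i, j]
                gb[j] += s
        W = theta[p_offs[l] : p_offs[l] + d_in * d_out].reshape(d_in, d_out)
        g = np.dot(g, W.T)
        if l > 0:
            # post-activation > 0 iff pre-activation > 0 for both kinds
            if act_kind == RELU:
                for i in range(g.shape[0]):
                    for j in range(d_in):
                        if A_prev[i, j] <= 0.0:
                            g[i, j] = 0.0
            else:
                for i in range(g.shape[0]):
                    for j in range(d_in):
                        if A_prev[i, j] <= 0.0:
                            g[i, j] *= slope
    return g
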