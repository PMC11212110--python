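"""The three loss families of the transfer scheme, as pure functions.

Adversarial terms use the least-squares GAN form with target codes 1 (real)
and 0 (fake); the discriminator emits an unbounded linear score.  The
targeted regression loss is a plain MSE over the paired samples, and the
cycle-consistency loss is the L2 reconstruction error summed over both
mapping directions.
"""

from __future__ import annotations

import numpy as np


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return v


def adversarial_d_loss(scores_real, scores_fake) -> float:
    """LSGAN discriminator loss: mean (s_real - 1)^2 + mean (s_fake)^2."""
    sr = _as_vector(scores_real, "scores_real")
    sf = _as_vector(scores_fake, "scores_fake")
    return float(np.mean((sr - 1.0) ** 2) + np.mean(sf**2))


def adversarial_g_loss(scores_fake) -> float:
    """LSGAN generator loss: mean (s_fake - 1)^2 (zero iff all scores are 1)."""
    sf = _as_vector(scores_fake, "scores_fake")
    return float(np.mean((sf - 1.0) ** 2))


def targeted_regression_loss(predicted, truth) -> float:
    """MSE between generated and ground-truth responses on paired data."""
    p = _as_vector(predicted, "predicted")
    t = _as_vector(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(
            f"length mismatch: predicted has {p.size}, truth has {t.size}"
        )
    return float(np.mean((p - t) ** 2))


def cycle_loss(
    reconstructed_sim, original_sim, reconstructed_real, original_real
) -> float:
    """L2 cycle-consistency: mean squared reconstruction error, both directions."""
    rs = _as_vector(reconstructed_sim, "reconstructed_sim")
    os_ = _as_vector(original_sim, "original_sim")
    rr = _as_vector(reconstructed_real, "reconstructed_real")
    or_ = _as_vector(original_real, "original_real")
    if rs.shape != os_.shape:
        raise ValueError("sim reconstruction length mismatch")
    if rr.shape != or_.shape:
        raise ValueError("real reconstruction length mismatch")
    return float(np.mean((rs - os_) ** 2) + np.mean((rr - or_) ** 2))
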