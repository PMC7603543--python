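"""Rate-based Hebbian weight update.

The rule is dw_i = eta * x_i * y: the weight of edge i grows in proportion
to the product of the presynaptic activity x_i and the postsynaptic response
y, accumulated over one epoch.  Activities are the per-epoch spike counts of
the neurons at either end of the edge.  The rule is purely potentiating
(no decay or depression term), so weights are floored at zero only as a
formal safeguard.  Plasticity is disabled by default and is never active
during the synchrony weight-sweep experiments, which use fixed weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hebbian_update"]


def hebbian_update(weights, pre_rate, post_rate, eta: float) -> np.ndarray:
    """Apply w_i <- max(0, w_i + eta * x_i * y_i) elementwise.

    ``weights``, ``pre_rate`` and ``post_rate`` are broadcast against each
    other; rates must be non-negative and eta >= 0.
    """
    if eta < 0:
        raise ValueError(f"learning rate eta must be non-negative, got {eta}")
    weights = np.asarray(weights, dtype=float)
    pre = np.asarray(pre_rate, dtype=float)
    post = np.asarray(post_rate, dtype=float)
    if (pre < 0).any() or (post < 0).any():
        raise ValueError("firing rates must be non-negative")
    return np.maximum(0.0, weights + eta * pre * post)
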