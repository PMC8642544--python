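"""Construction of the random encoder and the fast balanced feedback weights.

The spiking network codes the teacher state through a random overcomplete
encoder ``F`` (one column per neuron): the decoded estimate is the linear
readout ``x_tilde = F r`` of the filtered spike trains ``r``.  The fast
recurrent weights are derived analytically from the encoder,

    Omega_f = F^T F + mu I,

rescaled so that the mean self-connection spans the threshold-to-reset gap.
Sending ``-Omega_f o`` through the fast synapses makes a spike instantly
inhibit every neuron with a similar encoding vector (and reset its own
drive), which keeps excitation and inhibition balanced: the population
tracks the encoded signal with sparse spikes and compensates on-line for
noise or silenced neurons.
"""

from __future__ import annotations

import numpy as np

from .dynamics import LIFParameters

__all__ = ["sample_encoder", "init_fast_weights"]


def sample_encoder(N_hat: int, N: int, rng: np.random.Generator) -> np.ndarray:
    """Random encoding matrix of shape ``(N_hat, N)``.

    Entries are i.i.d. standard normal divided by ``N_hat``, so column norms
    concentrate around ``sqrt(N_hat) / N_hat``.  An overcomplete code
    (``N >= N_hat``) is recommended.
    """
    return rng.standard_normal((N_hat, N)) / N_hat


def init_fast_weights(F: np.ndarray, params: LIFParameters,
                      mu: float | None = None) -> np.ndarray:
    """Fast balanced feedback weights derived from the encoder.

    ``Omega_f = F^T F + mu I`` rescaled by one scalar so that the mean
    diagonal element equals ``V_thresh - V_reset``: a spike's self-reset
    through ``-Omega_f o`` then spans the threshold-to-reset gap.  The small
    identity regulariser ``mu`` (default ``2e-4`` times the gap) stabilises
    near-duplicate encoding columns.  The result is symmetric and positive
    semidefinite up to the regulariser.
    """
    F = np.asarray(F, dtype=float)
    if not np.any(F):
        raise ValueError("encoder is identically zero")
    if np.any(~F.any(axis=0)):
        raise ValueError("encoder has an all-zero column")
    gap = params.threshold_gap
    if mu is None:
        mu = 2e-4 * gap
    G = F.T @ F + mu * np.eye(F.shape[1])
    scale = gap / float(np.mean(np.diag(G)))
    return scale * G
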