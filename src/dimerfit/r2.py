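"""Coefficient of determination for nonlinear fits."""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = ["r_squared"]


def r_squared(observed, predicted) -> float:
    """R² = 1 − SS_res/SS_tot on the given scale.

    Raises :class:`DataError` if the observed values have zero variance,
    where R² is undefined.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) == 0:
        raise DataError("observed and predicted must be 1-D of equal nonzero length")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("R^2 undefined: observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot
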