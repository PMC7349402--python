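"""Regression performance metrics."""

from __future__ import annotations

import numpy as np


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - yhat)))


def r2(y, yhat) -> float:
    """Coefficient of determination, 1 - RSS/TSS (may be negative)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant target: R^2 undefined")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss
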