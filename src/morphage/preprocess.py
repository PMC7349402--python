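"""Head-size normalization and robust outlier screening."""

from __future__ import annotations

import warnings

import numpy as np

from .data import MorphometryDataset


def icv_normalize(dataset: MorphometryDataset) -> MorphometryDataset:
    """Divide every feature value by the subject's intracranial volume.

    Normalizes morphometric measures to head size; metadata (including the
    ICV column itself) is unchanged.
    """
    icv = dataset.subjects["icv"].to_numpy(float)
    if (icv <= 0).any():
        bad = dataset.subjects.index[icv <= 0].tolist()
        raise ValueError(f"non-positive ICV for subjects: {bad[:5]}")
    return dataset.with_values(dataset.matrix() / icv[:, None])


def mad_outlier_mask(values, k: float = 3.0) -> np.ndarray:
    """Flag entries farther than ``k`` raw MADs from the median.

    Uses the raw (unscaled) median absolute deviation. If the MAD is zero
    the criterion is uninformative: nothing is flagged and a warning is
    emitted.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.size < 3:
        raise ValueError("need at least 3 values for the MAD criterion")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged", RuntimeWarning,
                      stacklevel=2)
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - med) > k * mad
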