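"""Column-wise z-score standardization (sample sd, denominator n-1).

Both the inputs and the output are standardized before MLP training; the
scaler pair is carried in the fitted results so predictions are always
returned on the original measurement scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StandardScaler", "fit_scaler"]


@dataclass(frozen=True)
class StandardScaler:
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardScaler":
        return cls(mean=np.asarray(d["mean"], float), sd=np.asarray(d["sd"], float))


def fit_scaler(columns: np.ndarray) -> StandardScaler:
    """Fit per-column mean/sd. 1-D input is treated as a single column.

    Raises on columns with fewer than 2 distinct values (sd = 0), which
    would make standardization ill-defined.
    """
    x = np.asarray(columns, dtype=float)
    x2 = x[:, None] if x.ndim == 1 else x
    if x2.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = x2.mean(axis=0)
    sd = x2.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0).tolist()
        raise ValueError(f"constant column(s) {bad}: standard deviation is zero")
    if x.ndim == 1:
        return StandardScaler(mean=mean[0] * np.ones(1), sd=sd[0] * np.ones(1))
    return StandardScaler(mean=mean, sd=sd)
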