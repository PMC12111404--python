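"""Process space and experiment designs for ultrasound-assisted dephenolization.

The process space has three factors: ethanol concentration (%, v/v),
solid-to-liquid ratio expressed as mL of solvent per g of defatted cake
(a "1:40 w/v" ratio is encoded as 40.0), and sonication time (min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

__all__ = ["ProcessBounds", "ExtractionCondition", "generate_design"]

#: axis order used for every (n, 3) condition array in the package
AXES = ("etoh", "sl", "time")


@dataclass(frozen=True)
class ProcessBounds:
    """Box constraints on the three extraction factors.

    Defaults are the screening ranges used for rapeseed-cake
    dephenolization: EtOH 70-90 %, S/L 10-60 mL/g, time 5-25 min.
    """

    etoh_range: tuple[float, float] = (70.0, 90.0)
    sl_range: tuple[float, float] = (10.0, 60.0)
    time_range: tuple[float, float] = (5.0, 25.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(AXES, self.ranges()):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} range must satisfy lo < hi, got ({lo}, {hi})")

    def ranges(self) -> tuple[tuple[float, float], ...]:
        return (self.etoh_range, self.sl_range, self.time_range)

    @property
    def lower(self) -> np.ndarray:
        return np.array([r[0] for r in self.ranges()], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([r[1] for r in self.ranges()], dtype=float)

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )


@dataclass(frozen=True)
class ExtractionCondition:
    """One point in the process space."""

    etoh: float
    sl: float
    time: float

    def as_array(self) -> np.ndarray:
        return np.array([self.etoh, self.sl, self.time], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ExtractionCondition":
        e, s, t = (float(v) for v in np.asarray(x, dtype=float))
        return cls(e, s, t)


def conditions_to_array(conditions) -> np.ndarray:
    """Stack ExtractionConditions into an (n, 3) float array."""
    return np.array([c.as_array() for c in conditions], dtype=float)


def generate_design(
    bounds: ProcessBounds,
    n: int,
    scheme: str = "latin_hypercube",
    seed: int | None = None,
) -> list[ExtractionCondition]:
    """Generate an n-point design over the process box.

    ``latin_hypercube`` stratifies every axis into n equal-width bins with
    exactly one point per bin (scrambled LHS, reproducible per seed).
    ``grid`` returns the first n points, in row-major order, of the
    ceil(n^(1/3))-level full-factorial lattice spanning the box inclusive
    of its faces; n = m**3 therefore yields the complete lattice.
    """
    if n < 4:
        raise ValueError(f"a design needs at least 4 points, got n={n}")
    if scheme == "latin_hypercube":
        sampler = qmc.LatinHypercube(d=3, seed=seed)
        unit = sampler.random(n)
        pts = qmc.scale(unit, bounds.lower, bounds.upper)
    elif scheme == "grid":
        # smallest lattice with m**3 >= n (fp-safe ceil of the cube root)
        m = max(2, round(n ** (1.0 / 3.0)))
        while m**3 < n:
            m += 1
        while (m - 1) ** 3 >= n:
            m -= 1
        levels = [np.linspace(lo, hi, m) for lo, hi in bounds.ranges()]
        grid = np.stack(np.meshgrid(*levels, indexing="ij"), axis=-1)
        pts = grid.reshape(-1, 3)[:n]
    else:
        raise ValueError(f"unknown design scheme: {scheme!r}")
    return [ExtractionCondition.from_array(p) for p in pts]
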