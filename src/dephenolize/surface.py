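"""Synthetic ground-truth response surface for dephenolization experiments.

The measured quantity is total phenolic content (TPC) of the ethanolic
extract, in mg gallic-acid equivalents per 100 g of dry defatted cake.
Real 33-run screening data for this process are not publicly deposited, so
the package ships a phenomenological surface with a known optimum and known
main-effect ordering against which every downstream stage (MLP surrogate,
Yoon importance, swarm optimization) can be verified:

    y(etoh, sl, t) = y0 * exp(-(etoh - e*)^2 / (2 se^2))   (unimodal in EtOH)
                        * sl / (sl + k_r)                  (saturating in S/L)
                        * exp(-(t - t*)^2 / (2 st^2))      (unimodal in time)

The default spec is calibrated so the noiseless maximum over the default
process box is 1887.76 mg GAE/100 g at 84% EtOH, 60 mL/g, 15 min, with the
solid-to-liquid ratio the dominant factor, EtOH second, time a minor effect.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import minimize

from .design import ExtractionCondition, ProcessBounds, conditions_to_array
from .experiments import ExperimentTable

__all__ = [
    "SurfaceSpec",
    "make_default_spec",
    "evaluate_surface",
    "simulate_experiments",
    "true_optimum",
    "true_main_effects",
    "MainEffects",
]

#: calibration anchor: reported maximal phenolic yield, mg GAE/100 g
DEFAULT_MAX_TPC = 1887.76


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of the ground-truth TPC surface.

    y0       overall scale, mg GAE/100 g (value of the saturation-free peak)
    e_star   EtOH concentration at the ridge, %
    sigma_e  width of the EtOH response, percentage points
    k_r      S/L half-saturation constant, mL/g
    t_star   sonication time at the ridge, min
    sigma_t  width of the time response, min
    noise_sd replicate noise, mg GAE/100 g (additive Gaussian, truncated at 0)
    """

    y0: float
    e_star: float
    sigma_e: float
    k_r: float
    t_star: float
    sigma_t: float
    noise_sd: float

    def __post_init__(self) -> None:
        if not self.y0 > 0:
            raise ValueError("y0 must be positive")
        if not (self.sigma_e > 0 and self.sigma_t > 0):
            raise ValueError("sigma_e and sigma_t must be positive")
        if not self.k_r > 0:
            raise ValueError("k_r must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceSpec":
        return cls(**{k: float(v) for k, v in d.items()})


def make_default_spec(max_tpc: float = DEFAULT_MAX_TPC) -> SurfaceSpec:
    """Default surface: optimum at (84% EtOH, 60 mL/g, 15 min).

    y0 is solved so the noiseless maximum over the default box equals
    ``max_tpc``: at the optimum both Gaussian factors are 1 and the
    saturation factor is 60/(60+25), hence y0 = max_tpc * 85/60.
    """
    bounds = ProcessBounds()
    sl_hi = bounds.sl_range[1]
    k_r = 25.0
    y0 = max_tpc * (sl_hi + k_r) / sl_hi
    return SurfaceSpec(
        y0=y0, e_star=84.0, sigma_e=15.0, k_r=k_r,
        t_star=15.0, sigma_t=20.0, noise_sd=40.0,
    )


def evaluate_surface(spec: SurfaceSpec, conditions) -> np.ndarray | float:
    """Noiseless TPC at one ExtractionCondition or an (n, 3) array.

    Returns a scalar for a single condition, an (n,) array otherwise.
    """
    single = isinstance(conditions, ExtractionCondition)
    if single:
        x = conditions.as_array()[None, :]
    else:
        x = np.asarray(conditions, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
            single = True
    etoh, sl, t = x[:, 0], x[:, 1], x[:, 2]
    if np.any(sl <= 0):
        raise ValueError("solid-to-liquid ratio must be positive (mL/g)")
    y = (
        spec.y0
        * np.exp(-((etoh - spec.e_star) ** 2) / (2.0 * spec.sigma_e**2))
        * sl / (sl + spec.k_r)
        * np.exp(-((t - spec.t_star) ** 2) / (2.0 * spec.sigma_t**2))
    )
    return float(y[0]) if single else y


def simulate_experiments(
    spec: SurfaceSpec, design, seed: int | None = None
) -> ExperimentTable:
    """Simulate measured TPC at the design points: surface + N(0, noise_sd), clipped at 0."""
    x = conditions_to_array(design) if isinstance(design, list) else np.asarray(design, float)
    y = np.asarray(evaluate_surface(spec, x), dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    y = np.maximum(y, 0.0)
    provenance = f"simulated from SurfaceSpec {spec.to_dict()} with seed={seed}"
    return ExperimentTable.from_arrays(x, y, seed=seed, provenance=provenance)


def true_optimum(
    spec: SurfaceSpec,
    bounds: ProcessBounds | None = None,
    n_grid: int = 201,
) -> tuple[ExtractionCondition, float]:
    """Argmax of the noiseless surface over the box: dense grid + local polish."""
    bounds = bounds or ProcessBounds()
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds.ranges()]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = evaluate_surface(spec, grid)
    x0 = grid[int(np.argmax(vals))]
    res = minimize(
        lambda x: -evaluate_surface(spec, x),
        x0,
        method="L-BFGS-B",
        bounds=list(bounds.ranges()),
    )
    x_best = np.clip(res.x, bounds.lower, bounds.upper)
    return ExtractionCondition.from_array(x_best), float(evaluate_surface(spec, x_best))


@dataclass(frozen=True)
class MainEffects:
    """First-order (Sobol) variance shares of the three factors, in percent."""

    shares: dict[str, float]
    order: tuple[str, ...]
    degenerate: bool  # True when the surface variance is ~0 and shares are meaningless


def true_main_effects(
    spec: SurfaceSpec,
    bounds: ProcessBounds | None = None,
    n_mc: int = 20000,
    seed: int | None = None,
) -> MainEffects:
    """Monte-Carlo first-order variance shares Var(E[y|x_i]) / Var(y), in %.

    Uses the pick-freeze estimator with two independent uniform sample
    matrices over the box (Sobol/Saltelli): S_i is estimated from
    cov(f(B), f(A with column i from B)). Deterministic per seed.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    bounds = bounds or ProcessBounds()
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lower, bounds.upper
    a = rng.uniform(lo, hi, size=(n_mc, 3))
    b = rng.uniform(lo, hi, size=(n_mc, 3))
    fa = evaluate_surface(spec, a)
    fb = evaluate_surface(spec, b)
    var = np.var(np.concatenate([fa, fb]), ddof=1)
    mean_all = float(np.mean(np.concatenate([fa, fb])))
    names = ("etoh", "sl", "time")
    if var <= 1e-12 * max(1.0, mean_all**2):
        return MainEffects(
            shares={n: 0.0 for n in names}, order=names, degenerate=True
        )
    shares = {}
    for i, name in enumerate(names):
        ab = a.copy()
        ab[:, i] = b[:, i]
        fab = evaluate_surface(spec, ab)
        # Sobol' pick-freeze: Var(E[y|x_i]) ~ mean(fB * (fAB - fA))
        shares[name] = float(np.mean(fb * (fab - fa)) / var * 100.0)
    order = tuple(sorted(names, key=lambda n: -shares[n]))
    return MainEffects(shares=shares, order=order, degenerate=False)
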