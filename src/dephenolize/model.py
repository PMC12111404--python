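"""MLP response-surface surrogate for phenolic extraction yield.

The modeling interface follows the Model/Results convention: build an
:class:`MLPSurrogate` from an experiment table, call :meth:`~MLPSurrogate.fit`
(one Levenberg-Marquardt run from a seeded random initialization) or
:meth:`~MLPSurrogate.fit_best` (best of several initializations), and work
with the returned :class:`MLPSurrogateResults` — predictions on the original
measurement scale, R²/MAE, Yoon relative importance, swarm optimization of
the predicted yield, and a text summary.

Hidden-layer size is chosen by :meth:`MLPSurrogate.select_topology`: for each
candidate size the mean over repeated training runs of the best-of-inits R²
is computed, and the smallest size that clears R² >= 0.9 and sits on a
plateau (successor improves by < 0.005) is selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .experiments import ExperimentTable
from .lm import levenberg_marquardt
from .mlp import MLPParams, mlp_forward, mlp_jacobian
from .scaling import StandardScaler, fit_scaler

__all__ = [
    "MLPSurrogate",
    "MLPSurrogateResults",
    "TopologyScan",
    "train_lm",
    "evaluate_fit",
    "select_topology",
    "kfold_r2",
]

R2_FLOOR = 0.9          # minimum acceptable mean R^2 for a topology
PLATEAU_DELTA = 0.005   # successor improvement below this counts as a plateau


def _fit_seed(master: int, repeat: int, init: int) -> np.random.Generator:
    """Deterministic per-(repeat, init) RNG derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence((master, repeat, init)))


class MLPSurrogate:
    """Tanh-MLP regression of phenolic yield on (EtOH %, S/L, time).

    Inputs and output are z-scored internally (scalers fitted on the
    training table); all reported metrics and predictions are on the
    original measurement scale.
    """

    def __init__(self, table: ExperimentTable):
        if len(table) < 4:
            raise ValueError("at least 4 experiments are required to fit")
        self.table = table
        self.x_scaler: StandardScaler = fit_scaler(table.x)
        self.y_scaler: StandardScaler = fit_scaler(table.y)
        self._xs = self.x_scaler.apply(table.x)
        self._ys = self.y_scaler.apply(table.y)

    @classmethod
    def from_csv(cls, path) -> "MLPSurrogate":
        from .experiments import read_experiments

        return cls(read_experiments(path))

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_hidden: int = 10,
        seed: int = 0,
        repeat: int = 0,
        init: int = 0,
        max_iter: int = 200,
    ) -> "MLPSurrogateResults":
        """One LM training run from a uniform(-0.5, 0.5) seeded initialization."""
        if n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        rng = _fit_seed(seed, repeat, init)
        p0 = MLPParams.init_random(n_hidden, rng)
        ys = self._ys

        def resid(theta):
            return ys - mlp_forward(MLPParams.unpack(theta, n_hidden), self._xs)

        def jac(theta):
            return -mlp_jacobian(MLPParams.unpack(theta, n_hidden), self._xs)

        lm = levenberg_marquardt(resid, jac, p0.pack(), max_iter=max_iter)
        params = MLPParams.unpack(lm.theta, n_hidden)
        return MLPSurrogateResults(
            model=self,
            params=params,
            seed=seed,
            n_iter=lm.n_iter,
            converged=lm.converged,
            sse_path=lm.sse_path,
        )

    def fit_best(
        self,
        n_hidden: int = 10,
        n_inits: int = 10,
        seed: int = 0,
        repeat: int = 0,
        max_iter: int = 200,
    ) -> "MLPSurrogateResults":
        """Best (training R²) of ``n_inits`` seeded initializations."""
        best = None
        for init in range(n_inits):
            res = self.fit(n_hidden, seed=seed, repeat=repeat, init=init,
                           max_iter=max_iter)
            if best is None or res.r2 > best.r2:
                best = res
        return best

    def select_topology(
        self,
        hidden_sizes=tuple(range(1, 16)),
        n_repeats: int = 10,
        n_inits: int = 10,
        seed: int = 0,
        max_iter: int = 200,
    ) -> "TopologyScan":
        """Repeated-run mean-R² scan over candidate hidden-layer sizes.

        Each repeat keeps its best-of-inits training R²; ``mean_r2`` averages
        the repeat bests. Selection: smallest size with mean_r2 >= 0.9 whose
        successor improves by < 0.005 (the last scanned size qualifies on the
        floor alone). If no size reaches the floor the argmax is returned,
        flagged ``plateau=False``.
        """
        sizes = tuple(int(s) for s in hidden_sizes)
        if not sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("hidden_sizes must be strictly increasing")
        if n_repeats < 1 or n_inits < 1:
            raise ValueError("n_repeats and n_inits must be >= 1")
        entries = []
        for nh in sizes:
            bests = [
                self.fit_best(nh, n_inits=n_inits, seed=seed + nh, repeat=rep,
                              max_iter=max_iter).r2
                for rep in range(n_repeats)
            ]
            entries.append(
                (nh, float(np.mean(bests)), float(np.std(bests, ddof=1)) if n_repeats > 1 else 0.0)
            )
        means = [m for _, m, _ in entries]
        selected, plateau = None, False
        if len(sizes) == 1:
            selected, plateau = sizes[0], True
        else:
            for idx, (nh, m, _) in enumerate(entries):
                if m < R2_FLOOR:
                    continue
                last = idx == len(entries) - 1
                if last or means[idx + 1] - m < PLATEAU_DELTA:
                    selected, plateau = nh, True
                    break
        if selected is None:
            selected, plateau = sizes[int(np.argmax(means))], False
        return TopologyScan(entries=entries, selected=selected, plateau=plateau)

    # -- metrics -----------------------------------------------------------

    def score(self, params: MLPParams, table: ExperimentTable | None = None):
        """(R², MAE) of a parameter set on a table, original scale."""
        table = table or self.table
        pred = self.predict(params, table.x)
        y = table.y
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError("table output is constant: R^2 undefined")
        ss_res = float(np.sum((y - pred) ** 2))
        return 1.0 - ss_res / ss_tot, float(np.mean(np.abs(y - pred)))

    def predict(self, params: MLPParams, conditions) -> np.ndarray:
        """Destandardized prediction at raw-scale conditions, (n, 3) or (3,)."""
        x = np.asarray(conditions, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        ys = mlp_forward(params, self.x_scaler.apply(x))
        y = self.y_scaler.invert(np.atleast_1d(ys))
        return float(y[0]) if single else y


@dataclass
class MLPSurrogateResults:
    """Fitted surrogate: trained weights, fit quality, and derived analyses."""

    model: MLPSurrogate
    params: MLPParams
    seed: int
    n_iter: int
    converged: bool
    sse_path: np.ndarray = field(repr=False)
    r2: float = field(init=False)
    mae: float = field(init=False)

    def __post_init__(self) -> None:
        self.r2, self.mae = self.model.score(self.params)

    # -- prediction and evaluation ----------------------------------------

    def predict(self, conditions) -> np.ndarray | float:
        return self.model.predict(self.params, conditions)

    def evaluate(self, table: ExperimentTable):
        """(R², MAE) on an arbitrary table, original scale."""
        return self.model.score(self.params, table)

    # -- derived analyses --------------------------------------------------

    def relative_importance(self):
        from .importance import yoon_ri

        return yoon_ri(self.params)

    def optimize(self, bounds=None, config=None, n_restarts: int = 5):
        from .design import ProcessBounds
        from .pso import optimize_surrogate

        return optimize_surrogate(
            self, bounds or ProcessBounds(), config=config, n_restarts=n_restarts
        )

    # -- reporting / persistence ------------------------------------------

    def summary(self) -> str:
        lines = [
            "MLP surrogate for phenolic yield (tanh hidden layer, linear output)",
            "=" * 68,
            f"Observations:        {len(self.model.table)}",
            f"Hidden neurons:      {self.params.n_hidden}",
            f"Free parameters:     {self.params.n_params}",
            f"Training R^2:        {self.r2:.4f}",
            f"Training MAE:        {self.mae:.4f} mg GAE/100 g",
            f"LM iterations:       {self.n_iter} (converged: {self.converged})",
            f"Init seed:           {self.seed}",
        ]
        try:
            ri = self.relative_importance()
            lines.append("Yoon relative importance (signed %):")
            for name, val in ri.as_dict().items():
                lines.append(f"    {name:<6} {val:+8.2f}")
        except ValueError:
            lines.append("Yoon relative importance: undefined (zero denominator)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "x_scaler": self.model.x_scaler.to_dict(),
            "y_scaler": self.model.y_scaler.to_dict(),
            "metadata": {
                "seed": self.seed,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "r2": self.r2,
                "mae": self.mae,
            },
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path


@dataclass(frozen=True)
class TopologyScan:
    """Result of the hidden-size scan: (size, mean_r2, sd_r2) per candidate."""

    entries: list[tuple[int, float, float]]
    selected: int
    plateau: bool

    def mean_r2(self, n_hidden: int) -> float:
        for nh, m, _ in self.entries:
            if nh == n_hidden:
                return m
        raise KeyError(n_hidden)

    @property
    def selected_mean_r2(self) -> float:
        return self.mean_r2(self.selected)


# -- functional façade ----------------------------------------------------


def train_lm(
    table: ExperimentTable, n_hidden: int, seed: int = 0, max_iter: int = 200
) -> MLPSurrogateResults:
    """Single seeded LM training run (see :meth:`MLPSurrogate.fit`)."""
    return MLPSurrogate(table).fit(n_hidden, seed=seed, max_iter=max_iter)


def evaluate_fit(result: MLPSurrogateResults, table: ExperimentTable):
    """(R², MAE) of a fitted surrogate on a table, original scale."""
    return result.evaluate(table)


def select_topology(
    table: ExperimentTable,
    hidden_sizes=tuple(range(1, 16)),
    n_repeats: int = 10,
    n_inits: int = 10,
    seed: int = 0,
) -> TopologyScan:
    """Hidden-size scan on a table (see :meth:`MLPSurrogate.select_topology`)."""
    return MLPSurrogate(table).select_topology(
        hidden_sizes, n_repeats=n_repeats, n_inits=n_inits, seed=seed
    )


def kfold_r2(
    table: ExperimentTable, n_hidden: int, k: int = 5, seed: int = 0
) -> float:
    """Optional k-fold cross-validated R² (not used for topology selection)."""
    n = len(table)
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n folds")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)
    y, pred = table.y, np.empty(n)
    for fi, fold in enumerate(folds):
        train_idx = np.setdiff1d(idx, fold)
        sub = ExperimentTable.from_arrays(table.x[train_idx], y[train_idx])
        res = MLPSurrogate(sub).fit_best(n_hidden, n_inits=3, seed=seed, repeat=fi)
        pred[fold] = res.predict(table.x[fold])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
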