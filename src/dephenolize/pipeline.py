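"""End-to-end workflow: simulate (or load) -> fit -> importance -> optimize -> report.

A single master seed fans out to stage seeds by a fixed counter scheme
(simulate: master, surrogate fits: master + 1, swarm: master + 2), so every
stage can also be re-run standalone with the same seed and reproduce the
pipeline's numbers. Reports store unrounded values; the human-readable
summary rounds for display (EtOH 0.1%, S/L 1 mL/g, time 0.1 min).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .design import ProcessBounds, generate_design
from .experiments import ExperimentTable, read_experiments, write_experiments
from .model import MLPSurrogate, MLPSurrogateResults, TopologyScan
from .pso import PSOConfig, PSOResult
from .surface import SurfaceSpec, make_default_spec, simulate_experiments

__all__ = ["PipelineConfig", "OptimizationReport", "run_pipeline"]

SIMULATE_OFFSET, FIT_OFFSET, PSO_OFFSET = 0, 1, 2


@dataclass
class PipelineConfig:
    """Configuration of one optimization run.

    Exactly one of ``surface`` (synthetic generator spec) and ``input_csv``
    (measured experiment table) supplies the data. ``hidden_sizes`` with a
    single entry skips the topology scan and fits that size directly.
    """

    bounds: ProcessBounds = field(default_factory=ProcessBounds)
    surface: SurfaceSpec | None = None
    input_csv: str | None = None
    design_scheme: str = "latin_hypercube"
    design_n: int = 33
    hidden_sizes: tuple[int, ...] = (10,)
    n_repeats: int = 10
    n_inits: int = 10
    pso: PSOConfig = field(default_factory=PSOConfig)
    n_restarts: int = 5
    master_seed: int = 7
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.surface is None) == (self.input_csv is None):
            raise ValueError(
                "exactly one of surface spec and input_csv must supply the data"
            )
        self.hidden_sizes = tuple(int(s) for s in self.hidden_sizes)

    @classmethod
    def default_synthetic(cls, master_seed: int = 7, **kwargs) -> "PipelineConfig":
        return cls(surface=make_default_spec(), master_seed=master_seed, **kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "bounds" in d:
            b = d["bounds"]
            d["bounds"] = ProcessBounds(
                etoh_range=tuple(b["etoh_range"]),
                sl_range=tuple(b["sl_range"]),
                time_range=tuple(b["time_range"]),
            )
        if d.get("surface") is not None:
            d["surface"] = SurfaceSpec.from_dict(d["surface"])
        if "pso" in d:
            d["pso"] = PSOConfig(**d["pso"])
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "bounds": {
                "etoh_range": list(self.bounds.etoh_range),
                "sl_range": list(self.bounds.sl_range),
                "time_range": list(self.bounds.time_range),
            },
            "surface": self.surface.to_dict() if self.surface else None,
            "input_csv": self.input_csv,
            "design_scheme": self.design_scheme,
            "design_n": self.design_n,
            "hidden_sizes": list(self.hidden_sizes),
            "n_repeats": self.n_repeats,
            "n_inits": self.n_inits,
            "pso": {
                "swarm_size": self.pso.swarm_size,
                "max_iter": self.pso.max_iter,
                "c1": self.pso.c1,
                "c2": self.pso.c2,
                "inertia": self.pso.inertia,
                "seed": self.pso.seed,
            },
            "n_restarts": self.n_restarts,
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
        }


@dataclass
class OptimizationReport:
    """Everything the pipeline computed, recomputable from (config, master_seed)."""

    config: dict
    data_source: str
    n_experiments: int
    topology_scan: list[tuple[int, float, float]] | None
    selected_hidden: int
    r2: float
    mae: float
    fit_seed: int
    relative_importance: dict[str, float]
    rank_order: tuple[str, ...]
    optimal_condition: dict[str, float]
    predicted_tpc: float
    restart_spread: float
    per_restart_best: list[float]
    version: str = __version__

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["rank_order"] = list(self.rank_order)
        return d

    def summary_text(self) -> str:
        c = self.optimal_condition
        lines = [
            "Dephenolization optimization report",
            "===================================",
            f"data source:       {self.data_source}",
            f"experiments:       {self.n_experiments}",
            f"hidden neurons:    {self.selected_hidden}",
            f"training R^2:      {self.r2:.4f}",
            f"training MAE:      {self.mae:.2f} mg GAE/100 g",
            "relative importance (Yoon, signed %):",
        ]
        for name in self.rank_order:
            lines.append(f"    {name:<6} {self.relative_importance[name]:+8.2f}")
        lines += [
            "optimal extraction conditions (predicted):",
            f"    ethanol        {c['etoh_pct']:.1f} %",
            f"    solid-liquid   {c['sl_ml_per_g']:.0f} mL/g",
            f"    time           {c['time_min']:.1f} min",
            f"    predicted TPC  {self.predicted_tpc:.2f} mg GAE/100 g",
            f"restart spread:    {self.restart_spread:.3f} % "
            f"({'OK' if self.restart_spread <= 5 else 'UNSTABLE'})",
        ]
        return "\n".join(lines)


def run_pipeline(
    config: PipelineConfig, verbose: bool = False
) -> tuple[OptimizationReport, MLPSurrogateResults, PSOResult]:
    """Execute the full workflow; persist artifacts when output_dir is set."""
    log = print if verbose else (lambda *a, **k: None)

    # stage 1: data
    if config.surface is not None:
        design = generate_design(
            config.bounds,
            config.design_n,
            scheme=config.design_scheme,
            seed=config.master_seed + SIMULATE_OFFSET,
        )
        table = simulate_experiments(
            config.surface, design, seed=config.master_seed + SIMULATE_OFFSET
        )
        source = f"synthetic ({config.design_scheme}, n={config.design_n})"
    else:
        table = read_experiments(config.input_csv)
        source = f"csv:{config.input_csv}"
    log(f"[simulate] data source: {source}, n={len(table)}")

    # stage 2: surrogate
    model = MLPSurrogate(table)
    fit_seed = config.master_seed + FIT_OFFSET
    scan: TopologyScan | None = None
    if len(config.hidden_sizes) > 1:
        scan = model.select_topology(
            config.hidden_sizes,
            n_repeats=config.n_repeats,
            n_inits=config.n_inits,
            seed=fit_seed,
        )
        selected = scan.selected
        log(f"[fit] topology scan selected {selected} hidden neurons "
            f"(mean R^2 {scan.selected_mean_r2:.4f})")
    else:
        selected = config.hidden_sizes[0]
    fit = model.fit_best(selected, n_inits=config.n_inits, seed=fit_seed)
    log(f"[fit] R^2={fit.r2:.4f} MAE={fit.mae:.3f}")

    # stage 3: importance
    ri = fit.relative_importance()
    log(f"[importance] {ri.as_dict()} rank={ri.rank_order}")

    # stage 4: swarm optimization
    pso_cfg = PSOConfig(
        swarm_size=config.pso.swarm_size,
        max_iter=config.pso.max_iter,
        c1=config.pso.c1,
        c2=config.pso.c2,
        inertia=config.pso.inertia,
        seed=config.master_seed + PSO_OFFSET,
        initial_span=config.pso.initial_span,
    )
    pso = fit.optimize(config.bounds, config=pso_cfg, n_restarts=config.n_restarts)
    log(f"[optimize] per-restart bests {pso.per_restart_best} "
        f"spread={pso.restart_spread:.3f}%")

    best = pso.best_condition
    report = OptimizationReport(
        config=config.to_dict(),
        data_source=source,
        n_experiments=len(table),
        topology_scan=scan.entries if scan else None,
        selected_hidden=selected,
        r2=fit.r2,
        mae=fit.mae,
        fit_seed=fit_seed,
        relative_importance=ri.as_dict(),
        rank_order=ri.rank_order,
        optimal_condition={
            "etoh_pct": best.etoh,
            "sl_ml_per_g": best.sl,
            "time_min": best.time,
        },
        predicted_tpc=pso.best_f,
        restart_spread=pso.restart_spread,
        per_restart_best=pso.per_restart_best,
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_experiments(table, out / "experiments.csv")
        fit.save(out / "model.json")
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True)
        )
        (out / "summary.md").write_text(report.summary_text() + "\n")
        log(f"[report] artifacts written to {out}")
    return report, fit, pso
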