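"""Experiment tables: design points with measured (or simulated) phenolic yield.

The on-disk format is a plain CSV with the fixed header
``etoh_pct,sl_ml_per_g,time_min,tpc_mg_gae_per_100g`` ('.' decimal, UTF-8).
Provenance (generator spec, seed) travels in a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExtractionCondition, conditions_to_array

__all__ = ["ExperimentTable", "read_experiments", "write_experiments", "COLUMNS"]

COLUMNS = ("etoh_pct", "sl_ml_per_g", "time_min", "tpc_mg_gae_per_100g")


@dataclass
class ExperimentTable:
    """Dephenolization runs: extraction conditions plus total phenolic yield.

    ``df`` holds one row per run with the canonical columns; ``seed`` and
    ``provenance`` record where simulated tables came from (None / free text
    for measured data).
    """

    df: pd.DataFrame
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if list(self.df.columns) != list(COLUMNS):
            unexpected = [c for c in self.df.columns if c not in COLUMNS]
            missing = [c for c in COLUMNS if c not in self.df.columns]
            raise ValueError(
                f"experiment table columns must be exactly {list(COLUMNS)}; "
                f"missing {missing}, unexpected {unexpected}"
            )
        if len(self.df) == 0:
            raise ValueError("experiment table is empty")
        for col in COLUMNS:
            if not np.issubdtype(self.df[col].dtype, np.number):
                raise ValueError(f"column {col!r} is not numeric")
        if self.df[list(COLUMNS)].isna().any().any():
            raise ValueError("experiment table contains missing values")
        bad = np.flatnonzero(self.df["tpc_mg_gae_per_100g"].to_numpy() < 0)
        if bad.size:
            raise ValueError(f"negative tpc_mg_gae_per_100g in row(s) {bad.tolist()}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        """(n, 3) condition array in (etoh, sl, time) order."""
        return self.df[list(COLUMNS[:3])].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """(n,) phenolic yields, mg GAE/100 g dry cake."""
        return self.df[COLUMNS[3]].to_numpy(dtype=float)

    def conditions(self) -> list[ExtractionCondition]:
        return [ExtractionCondition.from_array(row) for row in self.x]

    @classmethod
    def from_arrays(
        cls,
        conditions,
        yields,
        seed: int | None = None,
        provenance: str = "",
    ) -> "ExperimentTable":
        if isinstance(conditions, (list, tuple)) and conditions and isinstance(
            conditions[0], ExtractionCondition
        ):
            x = conditions_to_array(conditions)
        else:
            x = np.asarray(conditions, dtype=float)
        y = np.asarray(yields, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] != y.shape[0]:
            raise ValueError("conditions must be (n, 3) matching n yields")
        df = pd.DataFrame(np.column_stack([x, y]), columns=list(COLUMNS))
        return cls(df=df, seed=seed, provenance=provenance)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_experiments(table: ExperimentTable, path) -> Path:
    """Write the table CSV plus a ``<name>.csv.meta.json`` provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, float_format="%.17g")
    meta = {"seed": table.seed, "provenance": table.provenance}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_experiments(path) -> ExperimentTable:
    """Read a table written by :func:`write_experiments` (sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path)
    try:
        for col in COLUMNS:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    seed, provenance = None, ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seed = meta.get("seed")
        provenance = meta.get("provenance", "")
    return ExperimentTable(df=df, seed=seed, provenance=provenance)
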