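"""Core data containers shared by every analysis stage.

The pipeline consumes three kinds of gridded inputs:

* :class:`GridLandscape` — static per-cell geography (planar coordinates,
  geographic proxies, elevation, distance to coast, land mask).
* :class:`ClimateCube` — per-cell climate fields for every scenario x period
  combination (mean annual temperature, annual precipitation, isothermality,
  precipitation of the driest month).
* :class:`PresenceCube` — a binary species x cell x scenario x period
  occupancy array, the shape of thresholded species-distribution-model
  output.  Species richness is its per-cell column sum.

All containers round-trip losslessly through plain CSV/JSON so that real SDM
exports are drop-in replacements for the bundled simulator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: canonical period labels, oldest first
DEFAULT_PERIODS = ("Current", "1140", "4170", "7100")
#: canonical SSP scenario labels
DEFAULT_SCENARIOS = ("126", "370", "585")

CLIMATE_VARS = ("mat_c", "map_mm", "iso", "pdm_mm")

LANDSCAPE_COLUMNS = [
    "cell_id", "ix", "iy", "x_km", "y_km", "lon_deg", "lat_deg",
    "elevation_m", "coast_km", "is_land", "cell_area_km2",
]


@dataclass
class GridLandscape:
    """Complete rectangular lattice of grid cells with static geography."""

    cells: pd.DataFrame
    nx: int
    ny: int
    resolution_km: float

    def __post_init__(self) -> None:
        missing = set(LANDSCAPE_COLUMNS) - set(self.cells.columns)
        if missing:
            raise ValueError(f"landscape table missing columns: {sorted(missing)}")
        if len(self.cells) != self.nx * self.ny:
            raise ValueError("landscape is not a complete lattice")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")
        self.cells = self.cells.sort_values("cell_id").reset_index(drop=True)

    @property
    def land(self) -> pd.DataFrame:
        return self.cells[self.cells["is_land"]]

    @property
    def land_mask(self) -> np.ndarray:
        return self.cells["is_land"].to_numpy(dtype=bool)

    @property
    def cell_area_km2(self) -> float:
        return float(self.resolution_km) ** 2

    def grid_field(self, column: str) -> np.ndarray:
        """Reshape a per-cell column to the (ny, nx) raster layout."""
        out = np.full((self.ny, self.nx), np.nan)
        out[self.cells["iy"].to_numpy(), self.cells["ix"].to_numpy()] = (
            self.cells[column].to_numpy(dtype=float)
        )
        return out

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, resolution_km: float | None = None) -> "GridLandscape":
        cells = pd.read_csv(path)
        nx = int(cells["ix"].max()) + 1
        ny = int(cells["iy"].max()) + 1
        if resolution_km is None:
            xs = np.sort(cells["x_km"].unique())
            resolution_km = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
        cells["is_land"] = cells["is_land"].astype(bool)
        return cls(cells=cells, nx=nx, ny=ny, resolution_km=resolution_km)


@dataclass
class ClimateCube:
    """Per-cell climate fields for each (scenario, period).

    ``frames`` maps (scenario, period) to a DataFrame indexed like the
    landscape (sorted by cell_id) with columns ``mat_c, map_mm, iso, pdm_mm``.
    """

    frames: dict
    scenarios: tuple
    periods: tuple
    cell_ids: np.ndarray

    def field(self, var: str, scenario: str, period: str) -> np.ndarray:
        if var not in CLIMATE_VARS:
            raise KeyError(f"unknown climate variable {var!r}")
        key = (str(scenario), str(period))
        if key not in self.frames:
            raise KeyError(f"unknown scenario/period {key}")
        return self.frames[key][var].to_numpy(dtype=float)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (scen, per), df in self.frames.items():
            for var in CLIMATE_VARS:
                rows.append(pd.DataFrame({
                    "cell_id": self.cell_ids,
                    "scenario": scen,
                    "period": per,
                    "variable": var,
                    "value": df[var].to_numpy(),
                }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, long_df: pd.DataFrame,
                  scenarios: Sequence[str] | None = None,
                  periods: Sequence[str] | None = None) -> "ClimateCube":
        long_df = long_df.copy()
        long_df["scenario"] = long_df["scenario"].astype(str)
        long_df["period"] = long_df["period"].astype(str)
        if scenarios is None:
            scenarios = tuple(sorted(long_df["scenario"].unique()))
        if periods is None:
            seen = list(dict.fromkeys(long_df["period"]))
            periods = tuple(p for p in DEFAULT_PERIODS if p in seen) or tuple(seen)
        cell_ids = np.sort(long_df["cell_id"].unique())
        frames = {}
        for (scen, per), grp in long_df.groupby(["scenario", "period"]):
            wide = grp.pivot_table(index="cell_id", columns="variable",
                                   values="value").reindex(cell_ids)
            frames[(scen, per)] = wide[list(CLIMATE_VARS)].reset_index(drop=True)
        return cls(frames=frames, scenarios=tuple(scenarios),
                   periods=tuple(periods), cell_ids=cell_ids)

    @classmethod
    def from_csv(cls, path, **kw) -> "ClimateCube":
        return cls.from_long(pd.read_csv(path, dtype={"scenario": str, "period": str}), **kw)


@dataclass
class PresenceCube:
    """Binary occupancy, species x cell x scenario x period."""

    occupancy: np.ndarray  # (S, N, n_scenarios, n_periods) in {0, 1}
    species: tuple
    cell_ids: np.ndarray
    scenarios: tuple = DEFAULT_SCENARIOS
    periods: tuple = DEFAULT_PERIODS

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 4:
            raise ValueError("occupancy must be 4-D (species, cell, scenario, period)")
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy must be binary")
        self.occupancy = occ.astype(np.uint8)
        self.species = tuple(self.species)
        self.cell_ids = np.asarray(self.cell_ids)
        self.scenarios = tuple(str(s) for s in self.scenarios)
        self.periods = tuple(str(p) for p in self.periods)

    @property
    def n_species(self) -> int:
        return self.occupancy.shape[0]

    def _scen_idx(self, scenario: str) -> int:
        return self.scenarios.index(str(scenario))

    def _per_idx(self, period: str) -> int:
        return self.periods.index(str(period))

    def matrix(self, scenario: str, period: str) -> np.ndarray:
        """Cells x species binary matrix for one scenario/period slice."""
        return self.occupancy[:, :, self._scen_idx(scenario), self._per_idx(period)].T

    def richness(self, scenario: str, period: str) -> np.ndarray:
        """Per-cell species richness (column sum of the binary slice)."""
        return self.matrix(scenario, period).sum(axis=1).astype(int)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.occupancy).tobytes())
        h.update(repr((self.species, self.scenarios, self.periods)).encode())
        return h.hexdigest()

    def to_long(self) -> pd.DataFrame:
        S, N, A, T = self.occupancy.shape
        sp, cell, scen, per = np.meshgrid(
            np.arange(S), np.arange(N), np.arange(A), np.arange(T), indexing="ij")
        return pd.DataFrame({
            "species": np.asarray(self.species)[sp.ravel()],
            "cell_id": self.cell_ids[cell.ravel()],
            "scenario": np.asarray(self.scenarios)[scen.ravel()],
            "period": np.asarray(self.periods)[per.ravel()],
            "occupancy": self.occupancy.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame,
                  scenarios: Sequence[str] | None = None,
                  periods: Sequence[str] | None = None) -> "PresenceCube":
        df = df.copy()
        df["scenario"] = df["scenario"].astype(str)
        df["period"] = df["period"].astype(str)
        species = tuple(sorted(df["species"].unique()))
        cell_ids = np.sort(df["cell_id"].unique())
        if scenarios is None:
            scenarios = tuple(sorted(df["scenario"].unique()))
        if periods is None:
            seen = list(dict.fromkeys(df["period"]))
            periods = tuple(p for p in DEFAULT_PERIODS if p in seen) or tuple(seen)
        sp_idx = {s: i for i, s in enumerate(species)}
        cell_idx = {c: i for i, c in enumerate(cell_ids)}
        occ = np.zeros((len(species), len(cell_ids), len(scenarios), len(periods)),
                       dtype=np.uint8)
        occ[
            df["species"].map(sp_idx).to_numpy(),
            df["cell_id"].map(cell_idx).to_numpy(),
            df["scenario"].map({s: i for i, s in enumerate(scenarios)}).to_numpy(),
            df["period"].map({p: i for i, p in enumerate(periods)}).to_numpy(),
        ] = df["occupancy"].to_numpy(dtype=np.uint8)
        return cls(occupancy=occ, species=species, cell_ids=cell_ids,
                   scenarios=tuple(scenarios), periods=tuple(periods))

    @classmethod
    def from_csv(cls, path, **kw) -> "PresenceCube":
        return cls.from_long(pd.read_csv(path, dtype={"scenario": str, "period": str}), **kw)


@dataclass
class ShiftTruth:
    """Ground-truth generator parameters serialized alongside a synthetic cube.

    Enables parameter-recovery checks: the signs of constructed range shifts
    are derivable from these values without rerunning the simulator.
    """

    thermal_optimum_c: np.ndarray
    thermal_breadth_c: np.ndarray
    moisture_requirement_mm: np.ndarray
    suitability_threshold: np.ndarray
    scenario_delta_c: dict = field(default_factory=dict)
    lapse_rate_c_per_km: float = -6.0
    seed: int = 0

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        for k in ("thermal_optimum_c", "thermal_breadth_c",
                  "moisture_requirement_mm", "suitability_threshold"):
            payload[k] = np.asarray(payload[k]).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ShiftTruth":
        with open(path) as fh:
            payload = json.load(fh)
        for k in ("thermal_optimum_c", "thermal_breadth_c",
                  "moisture_requirement_mm", "suitability_threshold"):
            payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)
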