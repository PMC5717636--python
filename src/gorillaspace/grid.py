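"""Analysis grid and per-cell herbaceous energy density.

The spatial backbone of the pipeline is a regular lattice of square,
half-open grid cells (default 500 m) in projected planar coordinates.
Vegetation transect plots (1 m^2, placed along 200 m transects) provide
per-species structural measurements (stem length or leaf count) that are
converted to dry biomass via per-species calibration regressions and then
to metabolic energy (kcal m^-2) summed over species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "SpeciesCalibration",
    "EnergyField",
    "cell_of",
    "fit_species_calibration",
    "estimate_cell_energy_density",
]


class OutOfBoundsError(ValueError):
    """A point falls outside the grid extent."""


@dataclass(frozen=True)
class Grid:
    """Regular lattice of half-open square cells in planar metric coordinates.

    Cell (i, j) covers [origin_x + i*s, origin_x + (i+1)*s) x
    [origin_y + j*s, origin_y + (j+1)*s).  Every planar point inside the
    extent maps to exactly one cell.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 500.0
    n_cols: int = 20
    n_rows: int = 20

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered area."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        return (np.asarray(x) >= xmin) & (np.asarray(x) < xmax) & \
            (np.asarray(y) >= ymin) & (np.asarray(y) < ymax)

    def in_bounds(self, i, j) -> np.ndarray:
        return (np.asarray(i) >= 0) & (np.asarray(i) < self.n_cols) & \
            (np.asarray(j) >= 0) & (np.asarray(j) < self.n_rows)

    def cell_center(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        s = self.cell_size
        return (self.origin_x + (np.asarray(i) + 0.5) * s,
                self.origin_y + (np.asarray(j) + 0.5) * s)

    def neighbours(self, i: int, j: int) -> list[tuple[int, int]]:
        """The up-to-8 surrounding cells that lie inside the grid."""
        out = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < self.n_cols and 0 <= nj < self.n_rows:
                    out.append((ni, nj))
        return out


def cell_of(x, y, grid: Grid):
    """Map planar point(s) to grid cell indices by half-open floor division.

    Raises :class:`OutOfBoundsError` if any point is outside the grid extent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = grid.contains(x, y)
    if not np.all(inside):
        bad = np.argwhere(~np.atleast_1d(inside))
        raise OutOfBoundsError(
            f"{bad.size} point(s) outside grid extent {grid.extent}"
        )
    i = np.floor((x - grid.origin_x) / grid.cell_size).astype(int)
    j = np.floor((y - grid.origin_y) / grid.cell_size).astype(int)
    if i.ndim == 0:
        return int(i), int(j)
    return i, j


@dataclass(frozen=True)
class SpeciesCalibration:
    """Linear calibration from a structural measure to dry weight, plus energy.

    ``dry_weight_g = intercept + slope * measure_value``; negative predictions
    are clamped to zero downstream.  ``energy`` is kcal per gram dry weight.
    """

    species: str
    measure_kind: str  # "stem_length_m" | "leaf_count"
    slope: float
    intercept: float
    energy: float

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValueError("energy (kcal/g) must be >= 0")

    def predict_biomass(self, measure_value) -> np.ndarray:
        """Predicted dry biomass (g), clamped at zero."""
        pred = self.intercept + self.slope * np.asarray(measure_value, float)
        return np.maximum(pred, 0.0)


def fit_species_calibration(
    specimens,
    species: str = "",
    measure_kind: str = "stem_length_m",
    energy: float = 0.0,
) -> SpeciesCalibration:
    """Ordinary least squares of specimen dry weight on the structural measure.

    Parameters
    ----------
    specimens : sequence of (measure_value, dry_weight_g)
        At least two specimens with non-constant measure values.
    """
    arr = np.asarray(list(specimens), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (measure, dry_weight) specimens")
    x, w = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError(
            "constant measure values: calibration fit is singular"
        )
    slope, intercept = np.polyfit(x, w, 1)
    return SpeciesCalibration(species, measure_kind, float(slope),
                              float(intercept), float(energy))


@dataclass
class EnergyField:
    """Per-cell herbaceous energy density (kcal m^-2) on a grid.

    ``energy`` has shape (n_cols, n_rows); cells without vegetation data are
    masked (``mask`` True) and carry NaN.
    """

    grid: Grid
    energy: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.shape != (self.grid.n_cols, self.grid.n_rows):
            raise ValueError("energy array shape must be (n_cols, n_rows)")
        if self.mask is None:
            self.mask = np.isnan(self.energy)
        self.mask = np.asarray(self.mask, dtype=bool)
        present = self.energy[~self.mask]
        if present.size and np.nanmin(present) < 0:
            raise ValueError("energy densities must be >= 0")

    def value(self, i: int, j: int) -> float:
        """Energy density of a cell; NaN if masked."""
        if self.mask[i, j]:
            return float("nan")
        return float(self.energy[i, j])

    def has_data(self, i, j) -> np.ndarray:
        return ~self.mask[np.asarray(i), np.asarray(j)]

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(~self.mask)
        return pd.DataFrame({
            "i": ii, "j": jj, "kcal_per_m2": self.energy[ii, jj],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: Grid) -> "EnergyField":
        df = pd.read_csv(path)
        energy = np.full((grid.n_cols, grid.n_rows), np.nan)
        energy[df["i"].to_numpy(int), df["j"].to_numpy(int)] = \
            df["kcal_per_m2"].to_numpy(float)
        return cls(grid, energy)


def estimate_cell_energy_density(
    plots: pd.DataFrame,
    calibrations: dict[str, SpeciesCalibration],
    grid: Grid,
) -> EnergyField:
    """Convert transect plot records to a per-cell energy density field.

    For each cell and species: mean predicted dry biomass over that cell's
    plots (g m^-2, plots are 1 m^2) times the species energy (kcal g^-1),
    summed over species.  Cells with no plots are masked missing, not zero.

    Parameters
    ----------
    plots : DataFrame with columns cell_i, cell_j, plot_id, species,
        measure_kind, measure_value.  Every plot row for a species records
        that species' measure in that plot (absent species in a plot should
        appear with measure_value 0 if the plot was searched).
    calibrations : mapping species name -> :class:`SpeciesCalibration`.
    """
    required = {"cell_i", "cell_j", "plot_id", "species", "measure_value"}
    missing_cols = required - set(plots.columns)
    if missing_cols:
        raise ValueError(f"plots missing columns: {sorted(missing_cols)}")
    unknown = set(plots["species"]) - set(calibrations)
    if unknown:
        raise KeyError(
            f"no calibration for species: {sorted(unknown)}"
        )
    if (plots["measure_value"] < 0).any():
        raise ValueError("measure_value must be >= 0")

    energy = np.full((grid.n_cols, grid.n_rows), np.nan)
    for (ci, cj), cell_rows in plots.groupby(["cell_i", "cell_j"]):
        total = 0.0
        for sp, sp_rows in cell_rows.groupby("species"):
            cal = calibrations[sp]
            biomass = cal.predict_biomass(sp_rows["measure_value"].to_numpy())
            total += biomass.mean() * cal.energy
        energy[int(ci), int(cj)] = total
    return EnergyField(grid, energy)
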