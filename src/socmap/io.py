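"""Point-sample tables, regular grids, and the ESRI ASCII grid format.

Coordinates are planar kilometres. Grids are stored north-up: row 0 of the
value array is the *northernmost* row, while ``GridSpec`` anchors the
lower-left cell centre (the ``xllcenter`` dialect of the ESRI ASCII format).
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: covariate columns recognised in sample tables, with units (documentation only)
KNOWN_COVARIATES = {
    "no3n": "mg/kg", "nh4n": "mg/kg", "tn": "g/kg", "tp": "g/kg",
    "cec": "cmol/kg", "fe": "mg/kg", "ca": "cmol/kg", "mg": "cmol/kg",
    "ph": "-", "ele": "m", "slope": "deg", "asp": "deg",
    "mat": "degC", "map": "mm",
}

REQUIRED_COLUMNS = ("x", "y", "soc")


class SchemaError(ValueError):
    """A sample table or grid file violates the expected schema."""


class FormatError(ValueError):
    """A grid file cannot be parsed as ESRI ASCII."""


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Regular grid geometry; (x0, y0) is the lower-left cell centre (km)."""

    x0: float
    y0: float
    dx: float
    dy: float
    nx: int
    ny: int

    def __post_init__(self):
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes dx, dy must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid counts nx, ny must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, north-up row order."""
        xs = self.x0 + self.dx * np.arange(self.nx)
        ys = self.y0 + self.dy * np.arange(self.ny)[::-1]  # row 0 = north
        return np.meshgrid(xs, ys)

    def cell_centers_flat(self) -> np.ndarray:
        X, Y = self.cell_centers()
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclasses.dataclass
class FieldGrid:
    """A single-band raster on a :class:`GridSpec` with a nodata sentinel."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match "
                f"grid spec shape {self.spec.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


class SampleTable:
    """Validated point observations: coordinates, SOC response, covariates.

    A thin wrapper around a :class:`pandas.DataFrame` with columns
    ``x, y, soc`` (required), ``region`` (optional label) and any subset of
    :data:`KNOWN_COVARIATES`. Row order is preserved.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in REQUIRED_COLUMNS:
            if col not in frame.columns:
                raise SchemaError(f"required column '{col}' is missing")
        if "region" not in frame.columns:
            frame["region"] = "all"
        for col in frame.columns:
            if col == "region":
                continue
            vals = pd.to_numeric(frame[col], errors="coerce")
            bad = vals.isna() & frame[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"non-numeric value in column '{col}' at row {row}"
                )
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise SchemaError(f"missing value in column '{col}' at row {row}")
            frame[col] = vals.astype(float)
        if not np.isfinite(frame[["x", "y"]].to_numpy()).all():
            raise SchemaError("coordinates must be finite")
        if (frame["soc"] <= 0).any():
            row = int(np.flatnonzero((frame["soc"] <= 0).to_numpy())[0])
            raise SchemaError(f"soc must be positive (row {row})")
        dup = frame.duplicated(subset=["region", "x", "y"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise SchemaError(f"duplicated (x, y) within a region at row {row}")
        self.frame = frame.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy()

    @property
    def soc(self) -> np.ndarray:
        return self.frame["soc"].to_numpy()

    @property
    def covariates(self) -> list[str]:
        reserved = set(REQUIRED_COLUMNS) | {"region"}
        return [c for c in self.frame.columns if c not in reserved]

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise SchemaError(f"column '{name}' not present")
        return self.frame[name].to_numpy()

    def subset_region(self, region: str) -> "SampleTable":
        sub = self.frame[self.frame["region"] == region]
        if sub.empty:
            raise SchemaError(f"no rows with region '{region}'")
        return SampleTable(sub)


def read_samples(path, column_map: dict[str, str] | None = None) -> SampleTable:
    """Read a CSV sample table (comma-separated, '.' decimal, header row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    return SampleTable(frame)


def write_samples(table: SampleTable, path) -> None:
    table.frame.to_csv(path, index=False)


# -- ESRI ASCII grids ------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcenter", "yllcenter", "cellsize",
                "nodata_value")


def read_grid(path) -> FieldGrid:
    """Read an ESRI ASCII grid (.asc, xllcenter dialect, square cells)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].split() and lines[i].split()[0].lower() in _HEADER_KEYS:
        key, val = lines[i].split(maxsplit=1)
        header[key.lower()] = float(val)
        i += 1
    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(f"header keyword '{key}' missing in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = "\n".join(lines[i:])
    try:
        values = np.loadtxt(_io.StringIO(body), dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse data block of {path}: {exc}") from exc
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"data block is {values.shape}, header says ({nrows}, {ncols})"
        )
    spec = GridSpec(x0=header["xllcenter"], y0=header["yllcenter"],
                    dx=header["cellsize"], dy=header["cellsize"],
                    nx=ncols, ny=nrows)
    return FieldGrid(spec, values, nodata=header["nodata_value"])


def write_grid(path, field: FieldGrid, fmt: str = "%.10g") -> None:
    """Write a :class:`FieldGrid` as ESRI ASCII; requires square cells."""
    spec = field.spec
    if not np.isclose(spec.dx, spec.dy):
        raise FormatError("ESRI ASCII requires square cells (dx == dy)")
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.nx}\n")
        fh.write(f"nrows {spec.ny}\n")
        fh.write(f"xllcenter {spec.x0:.10g}\n")
        fh.write(f"yllcenter {spec.y0:.10g}\n")
        fh.write(f"cellsize {spec.dx:.10g}\n")
        fh.write(f"NODATA_value {field.nodata:.10g}\n")
        np.savetxt(fh, field.values, fmt=fmt)


# -- run configuration and seeding ----------------------------------------

def load_config(path) -> dict:
    """Load a YAML run/scenario configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"configuration in {path} is not a mapping")
    return cfg


def child_seed(master_seed: int, stream: int) -> int:
    """Derive a reproducible child seed for a named stochastic stream.

    Uses ``np.random.SeedSequence([master_seed, stream])``; the derivation
    is deterministic, so a run config needs to record only the master seed.
    Returned values are < 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
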