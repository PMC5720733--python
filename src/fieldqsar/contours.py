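"""Coefficient contour maps from a fitted model.

The regression coefficient of each retained column is mapped back to
unscaled units as the product ``b_j * sd_j`` (the customary "stdev*coeff"
convention) and laid out on the model's lattice.  Thresholding the lattice
at a fixed level (default +-4.0e-3) gives the favorable (positive) and
unfavorable (negative) point sets per field.  Contours are exported as
thresholded point clouds (JSON) plus the full scalar lattice (OpenDX), not
as triangulated isosurfaces — visualization programs do that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .fields import DescriptorMatrix, FieldGrid
from .plsqsar import QSARModel

__all__ = [
    "ContourSet",
    "coefficient_grid",
    "extract_contours",
    "write_dx",
    "write_contour_json",
]

DEFAULT_LEVEL = 4.0e-3


@dataclass
class ContourSet:
    """Thresholded lattice points of one field and sign."""

    field: str
    sign: int  # +1 or -1
    level: float
    points: np.ndarray  # (k, 3) A
    values: np.ndarray  # (k,) contribution values

    def __len__(self) -> int:
        return len(self.points)


def coefficient_grid(
    model: QSARModel, dm: DescriptorMatrix, field: str
) -> np.ndarray:
    """Per-lattice-point contribution b_j * sd_j of one field.

    Returns a flat array over *all* lattice points (z-fastest order);
    eliminated and excluded points contribute zero.
    """
    if field not in model.field_set:
        raise ParameterError(f"field {field!r} not in model {model.field_set}")
    vals = np.zeros(dm.grid.n_points)
    cols = np.flatnonzero(dm.column_fields == field)
    # model coefficients are over the subset matrix's columns, in dm order;
    # b_j is in scaled space, so divide by the scaling divisor to get the
    # raw-unit coefficient before applying the stdev*coeff convention
    model_cols = np.flatnonzero(np.isin(dm.column_fields, list(model.field_set)))
    col_to_model = {c: k for k, c in enumerate(model_cols)}
    for c in cols:
        j = col_to_model[c]
        vals[dm.column_points[c]] = (
            model.coef[j] / dm.column_scale[c] * dm.train_sd[c]
        )
    return vals


def extract_contours(
    coef_lattice: np.ndarray, grid: FieldGrid, level: float = DEFAULT_LEVEL,
    field: str = "",
) -> tuple[ContourSet, ContourSet]:
    """Threshold a coefficient lattice into positive and negative point sets."""
    if level <= 0:
        raise ParameterError("contour level must be positive")
    vals = np.asarray(coef_lattice, float)
    if vals.shape != (grid.n_points,):
        raise ParameterError("lattice length does not match grid")
    pts = grid.lattice_points()
    pos = vals >= level
    neg = vals <= -level
    return (
        ContourSet(field, +1, level, pts[pos], vals[pos]),
        ContourSet(field, -1, level, pts[neg], vals[neg]),
    )


def write_dx(path: str | Path, grid: FieldGrid, values: np.ndarray) -> None:
    """Write a scalar lattice as an OpenDX regular-grid file.

    Data are laid out z-fastest, matching the lattice ordering used
    throughout (and the OpenDX convention).
    """
    values = np.asarray(values, float)
    if values.shape != (grid.n_points,):
        raise ParameterError("values length does not match grid")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    d = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {grid.n_points} data follows",
    ]
    for start in range(0, len(values), 3):
        lines.append(" ".join(f"{v:.6e}" for v in values[start : start + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def write_contour_json(path: str | Path, contour_sets: list[ContourSet]) -> None:
    """Serialize contour point sets as JSON {field, sign, level, points}."""
    payload = [
        {
            "field": cs.field,
            "sign": cs.sign,
            "level": cs.level,
            "points": [
                {"x": float(p[0]), "y": float(p[1]), "z": float(p[2]), "value": float(v)}
                for p, v in zip(cs.points, cs.values)
            ],
        }
        for cs in contour_sets
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
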