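"""Population-level T2 calibration by exhaustive grid search.

The two T2 values of the two-component model are not fitted per voxel:
they are calibrated once, on the pooled training voxels, by evaluating
a global cost — the sum over voxels of the per-voxel fit RMSE — at every
candidate (t2_slow, t2_fast) pair on a grid and taking the argmin.  At
each grid cell only the two linear parameters (si0, sf_slow) are fitted
per voxel, so the whole surface is cheap to evaluate.

Only cells with t2_slow < t2_fast are populated (component
identifiability); the rest are NaN.  Ties are broken toward the smallest
t2_slow, then the smallest t2_fast, so the result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fitting import fit_two_component_table
from .signal_models import AcquisitionScheme, ComponentBasis

__all__ = [
    "GridSpec",
    "CostSurface",
    "grid_cost",
    "calibrate_t2",
    "normalize_cost_surface",
]


@dataclass(frozen=True)
class GridSpec:
    """Candidate T2 values (ms).  The default brackets prostate tissue T2s."""

    t2_slow_values: tuple[float, ...] = tuple(float(v) for v in range(20, 105, 5))
    t2_fast_values: tuple[float, ...] = tuple(float(v) for v in range(100, 410, 10))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "t2_slow_values", tuple(sorted(float(v) for v in self.t2_slow_values))
        )
        object.__setattr__(
            self, "t2_fast_values", tuple(sorted(float(v) for v in self.t2_fast_values))
        )
        if min(self.t2_slow_values) <= 0 or min(self.t2_fast_values) <= 0:
            raise ValueError("T2 candidates must be positive")


@dataclass
class CostSurface:
    """Pooled-cost grid with its argmin.

    ``total_rmse[i, j]`` is the pooled cost at
    ``(t2_slow_axis[i], t2_fast_axis[j])``; cells with
    t2_slow >= t2_fast are NaN.
    """

    t2_slow_axis: np.ndarray
    t2_fast_axis: np.ndarray
    total_rmse: np.ndarray
    optimum: tuple[float, float]
    n_voxels: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (t2_slow, t2_fast, total_rmse), populated cells only."""
        ii, jj = np.meshgrid(
            np.arange(len(self.t2_slow_axis)), np.arange(len(self.t2_fast_axis)), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "t2_slow": self.t2_slow_axis[ii.ravel()],
                "t2_fast": self.t2_fast_axis[jj.ravel()],
                "total_rmse": self.total_rmse.ravel(),
            }
        )
        return df[np.isfinite(df["total_rmse"])].reset_index(drop=True)


def grid_cost(
    pooled_voxels: np.ndarray,
    scheme: AcquisitionScheme,
    adc_pair: tuple[float, float],
    t2_pair: tuple[float, float],
) -> float:
    """Pooled cost at one candidate T2 pair: sum of per-voxel fit RMSEs."""
    S = np.atleast_2d(np.asarray(pooled_voxels, dtype=float))
    if S.shape[0] == 0:
        raise ValueError("empty voxel pool")
    basis = ComponentBasis(adc_pair[0], adc_pair[1], t2_pair[0], t2_pair[1])
    _, _, rmse, valid = fit_two_component_table(S, scheme, basis)
    if not valid.all():
        raise ValueError("pooled voxels must all be finite, non-zero signals")
    return float(rmse.sum())


def calibrate_t2(
    training_voxels: np.ndarray,
    scheme: AcquisitionScheme,
    adc_pair: tuple[float, float] = (0.3, 2.6),
    grid: GridSpec | None = None,
) -> CostSurface:
    """Evaluate the pooled cost over the full grid and locate its minimum."""
    grid = grid or GridSpec()
    S = np.atleast_2d(np.asarray(training_voxels, dtype=float))
    if S.shape[0] == 0:
        raise ValueError("empty voxel pool")
    slow_axis = np.array(grid.t2_slow_values)
    fast_axis = np.array(grid.t2_fast_values)
    surface = np.full((len(slow_axis), len(fast_axis)), np.nan)
    for i, t2s in enumerate(slow_axis):
        for j, t2f in enumerate(fast_axis):
            if t2s >= t2f:
                continue
            surface[i, j] = grid_cost(S, scheme, adc_pair, (t2s, t2f))
    if not np.isfinite(surface).any():
        raise ValueError("grid contains no cell with t2_slow < t2_fast")
    # argmin over populated cells; C-order argmin on the (slow, fast)-indexed
    # grid breaks ties toward the smallest t2_slow, then smallest t2_fast
    flat = np.where(np.isfinite(surface), surface, np.inf)
    i_opt, j_opt = np.unravel_index(np.argmin(flat), surface.shape)
    return CostSurface(
        t2_slow_axis=slow_axis,
        t2_fast_axis=fast_axis,
        total_rmse=surface,
        optimum=(float(slow_axis[i_opt]), float(fast_axis[j_opt])),
        n_voxels=int(S.shape[0]),
    )


def normalize_cost_surface(surface: CostSurface) -> CostSurface:
    """Scale the surface so the highest populated cost equals 1 (argmin unchanged)."""
    peak = np.nanmax(surface.total_rmse)
    if not np.isfinite(peak) or peak <= 0:
        return replace(surface, total_rmse=surface.total_rmse.copy())
    return replace(surface, total_rmse=surface.total_rmse / peak)
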