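"""Fixed-width 2D binning of a marker plane and per-bin / per-quadrant statistics.

The (x, y) plane — in asinh units — is cut into square bins of width 0.2 by
default, anchored at the origin: an event at (x, y) falls into the integer bin
``(floor(x / w), floor(y / w))``.  For every bin the statistics of a third
marker z are computed:

* ``n_cells`` — events in the bin,
* ``msi`` — mean signal intensity of z over all cells in the bin,
* ``n_zpos`` / ``freq_zpos`` — count and fraction of z-positive cells
  (``z >= z_threshold``),
* ``msi_pos`` — mean z over the z-positive cells only (MSI+).

All events enter the analysis; the five-cell display rule (``displayed`` /
``displayed_pos`` flags) applies only when rendering or extracting features.
Quadrant statistics split the plane at one threshold per axis (ties count as
high/positive) and report each quadrant's share of all cells ("black"
percentages) and the z-positive share within the quadrant ("red" percentages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, StateError
from .fcs import EventTable

__all__ = [
    "BinConfig",
    "BinAssignment",
    "BinGrid",
    "DEFAULT_QUADRANT_LAYOUT",
    "assign_bins",
    "compute_bin_grid",
    "quadrant_stats",
    "coexpression_stats",
]

#: Quadrant → (x side, y side). The layout is a convention, not a law of the
#: method; override via ``BinConfig.quadrant_layout``.
DEFAULT_QUADRANT_LAYOUT: dict[str, tuple[str, str]] = {
    "Q1": ("low", "low"),
    "Q2": ("low", "high"),
    "Q3": ("high", "high"),
    "Q4": ("high", "low"),
}


@dataclass(frozen=True)
class BinConfig:
    """Binning parameters for one (x, y, z) marker triple.

    ``z_threshold`` is needed only by the z-positive statistics (MSI+, red
    percentages); density and plain MSI work without it.  Quadrant thresholds
    are in asinh units and are user-set — the method does not choose them.
    """

    x_marker: str
    y_marker: str
    z_marker: str | None = None
    bin_width: float = 0.2
    min_cells_per_bin: int = 5
    x_threshold: float | None = None
    y_threshold: float | None = None
    z_threshold: float | None = None
    quadrant_layout: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_QUADRANT_LAYOUT)
    )

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ConfigError(f"bin_width must be > 0, got {self.bin_width}")
        if self.min_cells_per_bin < 1:
            raise ConfigError(
                f"min_cells_per_bin must be >= 1, got {self.min_cells_per_bin}"
            )
        sides = sorted(self.quadrant_layout.values())
        if sides != sorted({("low", "low"), ("low", "high"), ("high", "low"), ("high", "high")}):
            raise ConfigError("quadrant_layout must map 4 names to the 4 (x,y) sides")

    @property
    def quadrant_names(self) -> list[str]:
        return sorted(self.quadrant_layout)


@dataclass(frozen=True)
class BinAssignment:
    """Integer bin indices for the finite-coordinate events of a table."""

    ix: np.ndarray  # int indices, finite events only
    iy: np.ndarray
    valid: np.ndarray  # boolean mask over the original events
    n_excluded: int


def assign_bins(
    x_values: np.ndarray, y_values: np.ndarray, bin_width: float
) -> BinAssignment:
    """Map events to integer bin index pairs ``(floor(x/w), floor(y/w))``.

    Events with a non-finite coordinate are excluded and counted, never
    silently dropped.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not bin_width > 0:
        raise ConfigError(f"bin_width must be > 0, got {bin_width}")
    valid = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~valid).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} event(s) with non-finite coordinates excluded from binning",
            stacklevel=2,
        )
    ix = np.floor(x[valid] / bin_width).astype(np.int64)
    iy = np.floor(y[valid] / bin_width).astype(np.int64)
    return BinAssignment(ix=ix, iy=iy, valid=valid, n_excluded=n_excluded)


@dataclass
class BinGrid:
    """Per-bin statistics of one (x, y, z) triple.

    ``bins`` is a DataFrame indexed by the integer pair (i, j) with columns
    ``n_cells, msi, n_zpos, msi_pos, freq_zpos, displayed, displayed_pos``.
    The grid stores *all* non-empty bins; the display flags implement the
    five-cell rule downstream.
    """

    bins: pd.DataFrame
    config: BinConfig
    n_total_events: int
    n_excluded: int = 0

    @property
    def displayed(self) -> pd.DataFrame:
        return self.bins[self.bins["displayed"]]

    @property
    def displayed_pos(self) -> pd.DataFrame:
        return self.bins[self.bins["displayed_pos"]]

    def to_csv(self, path) -> None:
        """One row per bin: i, j, bin lower edges, counts and statistics."""
        out = self.bins.reset_index()
        out.insert(2, "x_lo", out["i"] * self.config.bin_width)
        out.insert(3, "y_lo", out["j"] * self.config.bin_width)
        out.to_csv(path, index=False)


def _resolve_triple(table: EventTable, config: BinConfig, need_z: bool):
    if not table.transformed:
        raise StateError("bin statistics require an arcsinh-transformed table")
    x = table.get(config.x_marker)
    y = table.get(config.y_marker)
    z = None
    if config.z_marker is not None:
        if config.z_marker in (config.x_marker, config.y_marker):
            warnings.warn(
                f"z marker {config.z_marker!r} equals a plane axis marker "
                "(degenerate but allowed)",
                stacklevel=3,
            )
        z = table.get(config.z_marker)
    elif need_z:
        raise ConfigError("this statistic requires a z marker in the BinConfig")
    return x, y, z


def compute_bin_grid(table: EventTable, config: BinConfig) -> BinGrid:
    """Compute the full per-bin statistics table for one marker triple."""
    x, y, z = _resolve_triple(table, config, need_z=False)
    assignment = assign_bins(x, y, config.bin_width)

    idx = pd.MultiIndex.from_arrays(
        [assignment.ix, assignment.iy], names=["i", "j"]
    )
    cols: dict[str, np.ndarray] = {}
    if z is not None:
        cols["z"] = z[assignment.valid]
    per_event = pd.DataFrame(cols, index=idx)

    grouped = per_event.groupby(level=["i", "j"], sort=True)
    bins = pd.DataFrame({"n_cells": grouped.size()})
    if z is not None:
        bins["msi"] = grouped["z"].mean()
        if config.z_threshold is not None:
            pos = per_event[per_event["z"] >= config.z_threshold]
            gpos = pos.groupby(level=["i", "j"], sort=True)
            bins["n_zpos"] = gpos.size().reindex(bins.index, fill_value=0)
            bins["msi_pos"] = gpos["z"].mean().reindex(bins.index)
            bins["freq_zpos"] = bins["n_zpos"] / bins["n_cells"]
        else:
            bins["n_zpos"] = np.nan
            bins["msi_pos"] = np.nan
            bins["freq_zpos"] = np.nan
    else:
        for c in ("msi", "n_zpos", "msi_pos", "freq_zpos"):
            bins[c] = np.nan
    bins["displayed"] = bins["n_cells"] >= config.min_cells_per_bin
    bins["displayed_pos"] = (
        (bins["n_zpos"] >= config.min_cells_per_bin)
        if config.z_threshold is not None and z is not None
        else False
    )
    return BinGrid(
        bins=bins,
        config=config,
        n_total_events=int(assignment.valid.sum()),
        n_excluded=assignment.n_excluded,
    )


def _quadrant_masks(
    x: np.ndarray, y: np.ndarray, config: BinConfig
) -> dict[str, np.ndarray]:
    if config.x_threshold is None or config.y_threshold is None:
        raise ConfigError("quadrant statistics require x_threshold and y_threshold")
    x_high = x >= config.x_threshold  # ties count as high
    y_high = y >= config.y_threshold
    side = {"low": lambda m: ~m, "high": lambda m: m}
    return {
        q: side[sx](x_high) & side[sy](y_high)
        for q, (sx, sy) in config.quadrant_layout.items()
    }


def quadrant_stats(table: EventTable, config: BinConfig) -> pd.DataFrame:
    """Per-quadrant cell counts and percentages.

    Returns a DataFrame indexed by quadrant name with columns ``n_cells``,
    ``pct_of_total`` (the black number: share of all events),``n_zpos`` and
    ``pct_zpos_of_quadrant`` (the red number: z-positive share within the
    quadrant).  Empty quadrants report the red percentage as missing, not 0.
    """
    need_z = config.z_threshold is not None
    x, y, z = _resolve_triple(table, config, need_z=False)
    finite = np.isfinite(x) & np.isfinite(y)
    if z is not None:
        finite &= np.isfinite(z)
    x, y = x[finite], y[finite]
    z = z[finite] if z is not None else None
    n_total = int(finite.sum())

    rows = []
    masks = _quadrant_masks(x, y, config)
    for q in sorted(config.quadrant_layout):
        mask = masks[q]
        n_q = int(mask.sum())
        row = {
            "n_cells": n_q,
            "pct_of_total": 100.0 * n_q / n_total if n_total else np.nan,
        }
        if need_z and z is not None:
            n_pos = int((z[mask] >= config.z_threshold).sum())
            row["n_zpos"] = n_pos
            row["pct_zpos_of_quadrant"] = 100.0 * n_pos / n_q if n_q else np.nan
        else:
            row["n_zpos"] = np.nan
            row["pct_zpos_of_quadrant"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(sorted(config.quadrant_layout), name="quadrant"))


COEXPR_CATEGORIES = ("z1+z2+", "z1+z2-", "z1-z2+", "z1-z2-")


def coexpression_stats(
    table: EventTable,
    config: BinConfig,
    z2_marker: str,
    z2_threshold: float,
) -> pd.DataFrame:
    """Joint z1/z2 positivity fractions per quadrant.

    For each quadrant the four joint categories (z1+z2+, z1+z2-, z1-z2+,
    z1-z2-) are reported as fractions of that quadrant's cells; they sum to 1
    for non-empty quadrants.  Feeds the co-expression pie charts.
    """
    if config.z_threshold is None:
        raise ConfigError("coexpression statistics require z_threshold for z1")
    if z2_marker == config.z_marker:
        warnings.warn("z2 marker equals z1 (degenerate but allowed)", stacklevel=2)
    x, y, z1 = _resolve_triple(table, config, need_z=True)
    z2 = table.get(z2_marker)
    finite = np.isfinite(x) & np.isfinite(y) & np.isfinite(z1) & np.isfinite(z2)
    x, y, z1, z2 = x[finite], y[finite], z1[finite], z2[finite]

    p1 = z1 >= config.z_threshold
    p2 = z2 >= z2_threshold
    joint = {
        "z1+z2+": p1 & p2,
        "z1+z2-": p1 & ~p2,
        "z1-z2+": ~p1 & p2,
        "z1-z2-": ~p1 & ~p2,
    }
    rows = []
    masks = _quadrant_masks(x, y, config)
    for q in sorted(config.quadrant_layout):
        mask = masks[q]
        n_q = int(mask.sum())
        if n_q:
            rows.append({c: joint[c][mask].sum() / n_q for c in COEXPR_CATEGORIES})
        else:
            rows.append({c: np.nan for c in COEXPR_CATEGORIES})
    out = pd.DataFrame(rows, index=pd.Index(sorted(config.quadrant_layout), name="quadrant"))
    out.attrs["z1_marker"] = config.z_marker
    out.attrs["z2_marker"] = z2_marker
    return out
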