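"""Per-sample scalar features engineered from bin grids and quadrant statistics.

Two families:

* threshold-independent bin-intensity features — the maximum (and range) of
  per-bin MSI over the *displayed* bins, i.e. the endpoints of the dynamic
  color legend;
* threshold-dependent quadrant features — the black quadrant percentages and
  the red z-positive percentages, which require user-set axis/z thresholds.

Feature names are deterministic functions of their configuration:
``CD90_CD44_CD86__max_bin_msi``, ``CD90_CD44__pct_Q2``,
``CD90_CD44_CD27__pct_zpos_Q2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .binning import BinConfig, BinGrid, compute_bin_grid, quadrant_stats
from .errors import ConfigError
from .fcs import EventTable

__all__ = [
    "PanelEntry",
    "max_bin_msi",
    "bin_msi_range",
    "quadrant_features",
    "build_feature_matrix",
    "feature_name",
]

ALL_STATISTICS = ("max_bin_msi", "bin_msi_range", "quadrant_pct", "zpos_pct")


@dataclass(frozen=True)
class PanelEntry:
    """One (x, y, z) triple plus the statistics to extract from it."""

    config: BinConfig
    statistics: tuple[str, ...] = ALL_STATISTICS

    def __post_init__(self) -> None:
        unknown = set(self.statistics) - set(ALL_STATISTICS)
        if unknown:
            raise ConfigError(f"unknown feature statistics: {sorted(unknown)}")


def feature_name(config: BinConfig, statistic: str, quadrant: str | None = None) -> str:
    """Deterministic feature-column name for a configuration."""
    if statistic == "quadrant_pct":
        return f"{config.x_marker}_{config.y_marker}__pct_{quadrant}"
    if statistic == "zpos_pct":
        return f"{config.x_marker}_{config.y_marker}_{config.z_marker}__pct_zpos_{quadrant}"
    return f"{config.x_marker}_{config.y_marker}_{config.z_marker}__{statistic}"


def max_bin_msi(grid: BinGrid) -> float:
    """Maximum per-bin MSI over displayed bins (the legend's upper bound).

    Missing (NaN) when no bin reaches the display threshold.  Independent of
    any z threshold.
    """
    shown = grid.displayed["msi"].dropna()
    return float(shown.max()) if len(shown) else float("nan")


def bin_msi_range(grid: BinGrid) -> tuple[float, float]:
    """(min, max) per-bin MSI over displayed bins — the dynamic color-scale
    endpoints.  (nan, nan) when nothing is displayed."""
    shown = grid.displayed["msi"].dropna()
    if not len(shown):
        return (float("nan"), float("nan"))
    return (float(shown.min()), float(shown.max()))


def quadrant_features(qs: pd.DataFrame, config: BinConfig) -> dict[str, float]:
    """Flatten quadrant statistics into named scalar features.

    Emits the black percentage ``pct_Qk`` for every quadrant and, when
    z-positive statistics are present, the red percentage ``pct_zpos_Qk``.
    """
    out: dict[str, float] = {}
    for q in qs.index:
        out[feature_name(config, "quadrant_pct", q)] = float(qs.loc[q, "pct_of_total"])
        if config.z_threshold is not None:
            # empty quadrants stay NaN (missing), never 0
            out[feature_name(config, "zpos_pct", q)] = float(
                qs.loc[q, "pct_zpos_of_quadrant"]
            )
    return out


def _sample_features(table: EventTable, panel: list[PanelEntry]) -> dict[str, float]:
    row: dict[str, float] = {}
    for entry in panel:
        cfg = entry.config
        try:
            if "max_bin_msi" in entry.statistics or "bin_msi_range" in entry.statistics:
                grid = compute_bin_grid(table, cfg)
                if "max_bin_msi" in entry.statistics:
                    row[feature_name(cfg, "max_bin_msi")] = max_bin_msi(grid)
                if "bin_msi_range" in entry.statistics:
                    lo, hi = bin_msi_range(grid)
                    row[feature_name(cfg, "min_bin_msi")] = lo
                    row[feature_name(cfg, "bin_msi_span")] = hi - lo
            wants_quadrants = {"quadrant_pct", "zpos_pct"} & set(entry.statistics)
            if wants_quadrants:
                qs = quadrant_stats(table, cfg)
                feats = quadrant_features(qs, cfg)
                for name, value in feats.items():
                    stat = "zpos_pct" if "__pct_zpos_" in name else "quadrant_pct"
                    if stat in entry.statistics:
                        row[name] = value
        except ConfigError as exc:
            warnings.warn(
                f"skipping panel entry ({cfg.x_marker}, {cfg.y_marker}, "
                f"{cfg.z_marker}): {exc}",
                stacklevel=3,
            )
    return row


def build_feature_matrix(
    samples: list[tuple[str, str, EventTable]],
    panel: list[PanelEntry],
) -> pd.DataFrame:
    """One row per sample, one column per engineered feature.

    ``samples`` is a list of ``(sample_id, group, EventTable)``; tables must
    be transformed (and typically gated).  A sample missing a panel marker
    gets missing values for the affected features, with a warning.  Column
    order is deterministic (panel order); the panel configuration should be
    serialized alongside the CSV for provenance.
    """
    if not panel:
        raise ConfigError("panel is empty")
    rows = {}
    groups = {}
    for sample_id, group, table in samples:
        rows[sample_id] = _sample_features(table, panel)
        groups[sample_id] = group
    # reindex keeps samples whose feature dict came out empty (all missing)
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(list(rows))
    # stable, panel-derived column order
    order = [c for c in _expected_columns(panel) if c in matrix.columns]
    extra = [c for c in matrix.columns if c not in order]
    matrix = matrix.reindex(columns=order + extra)
    matrix.insert(0, "group", pd.Series(groups))
    matrix.index.name = "sample_id"
    return matrix


def _expected_columns(panel: list[PanelEntry]) -> list[str]:
    cols: list[str] = []
    for entry in panel:
        cfg = entry.config
        if "max_bin_msi" in entry.statistics:
            cols.append(feature_name(cfg, "max_bin_msi"))
        if "bin_msi_range" in entry.statistics:
            cols.append(feature_name(cfg, "min_bin_msi"))
            cols.append(feature_name(cfg, "bin_msi_span"))
        for q in cfg.quadrant_names:
            if "quadrant_pct" in entry.statistics:
                cols.append(feature_name(cfg, "quadrant_pct", q))
            if "zpos_pct" in entry.statistics:
                cols.append(feature_name(cfg, "zpos_pct", q))
    seen: set[str] = set()
    return [c for c in cols if not (c in seen or seen.add(c))]


def panel_to_dict(panel: list[PanelEntry]) -> list[dict]:
    """Serializable provenance record of a feature panel."""
    return [
        {"config": asdict(e.config), "statistics": list(e.statistics)} for e in panel
    ]
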