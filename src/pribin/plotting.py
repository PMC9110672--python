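"""Bin-plot rendering: color-coded heat maps of per-bin statistics.

A bin plot paints each displayed bin of the (x, y) plane with a color encoding
its statistic — cell count (density), MSI or MSI+ — through a blue → yellow →
red palette (low → mid → high, 50 quantization levels).  The color scale is
either *dynamic* (a sample's own displayed-bin min/max — the feature-bearing
legend endpoints) or *common* (min/max pooled over a panel of samples, for
direct cross-sample comparison).  MSI+ plots draw bins that pass the 5-cell
display rule but hold fewer than 5 z-positive cells in gray.  Quadrant
threshold lines and black/red percentage annotations reproduce the standard
figure layout.  Vector (SVG) output is deterministic for identical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap, Normalize
from matplotlib.patches import Rectangle

from .binning import BinGrid, COEXPR_CATEGORIES
from .errors import ConfigError

__all__ = [
    "ColorScale",
    "common_range",
    "render_bin_plot",
    "render_panel",
    "render_coexpression_pies",
]

PALETTE_ANCHORS = ("#0000ff", "#ffff00", "#ff0000")  # blue -> yellow -> red
GRAY = "#b0b0b0"

matplotlib.rcParams["svg.hashsalt"] = "pribin"  # reproducible SVG ids


@dataclass(frozen=True)
class ColorScale:
    """Value → color mapping for bin statistics.

    ``mode`` records whether the endpoints came from one grid ("dynamic") or
    were pooled over a panel ("common").  Values are clamped to
    ``[v_min, v_max]``; a degenerate scale (v_min == v_max) maps everything
    to the palette midpoint.
    """

    v_min: float
    v_max: float
    mode: str = "dynamic"
    n_levels: int = 50

    def __post_init__(self) -> None:
        if self.v_min > self.v_max:
            raise ConfigError(f"v_min {self.v_min} > v_max {self.v_max}")
        if self.n_levels < 2:
            raise ConfigError("n_levels must be >= 2")

    def colormap(self) -> LinearSegmentedColormap:
        return LinearSegmentedColormap.from_list(
            "pri", list(PALETTE_ANCHORS), N=self.n_levels
        )

    def fraction(self, value: float) -> float:
        """Position of a value on the scale in [0, 1] (midpoint if degenerate)."""
        if self.v_min == self.v_max:
            return 0.5
        v = min(max(value, self.v_min), self.v_max)
        return (v - self.v_min) / (self.v_max - self.v_min)

    def color(self, value: float):
        return self.colormap()(self.fraction(value))


def _grid_values(grid: BinGrid, statistic: str):
    if statistic == "count":
        shown = grid.displayed
        return shown, shown["n_cells"].astype(float)
    if statistic == "msi":
        shown = grid.displayed
        return shown, shown["msi"]
    if statistic == "msi_pos":
        # drawn set is still the 5-cell displayed set; low-n_zpos bins go gray
        shown = grid.displayed
        return shown, shown["msi_pos"]
    raise ConfigError(f"unknown statistic {statistic!r}")


def _dynamic_endpoints(grid: BinGrid, statistic: str) -> tuple[float, float]:
    if statistic == "msi_pos":
        vals = grid.displayed_pos["msi_pos"].dropna()
    else:
        _, vals = _grid_values(grid, statistic)
        vals = vals.dropna()
    if not len(vals):
        raise ConfigError(f"no displayed bins carry statistic {statistic!r}")
    return float(vals.min()), float(vals.max())


def common_range(grids: list[BinGrid], statistic: str = "msi") -> ColorScale:
    """Color scale spanning the pooled displayed-bin min/max of several grids."""
    if not grids:
        raise ConfigError("need at least one grid")
    endpoints = [_dynamic_endpoints(g, statistic) for g in grids]
    return ColorScale(
        v_min=min(lo for lo, _ in endpoints),
        v_max=max(hi for _, hi in endpoints),
        mode="common" if len(grids) > 1 else "dynamic",
    )


def _annotate_quadrants(ax, grid: BinGrid, annotations) -> None:
    cfg = grid.config
    xt, yt = cfg.x_threshold, cfg.y_threshold
    ax.axvline(xt, color="black", linewidth=0.8)
    ax.axhline(yt, color="black", linewidth=0.8)
    x_lo, x_hi = ax.get_xlim()
    y_lo, y_hi = ax.get_ylim()
    pos = {
        ("low", "low"): (x_lo, y_lo, "left", "bottom"),
        ("low", "high"): (x_lo, y_hi, "left", "top"),
        ("high", "high"): (x_hi, y_hi, "right", "top"),
        ("high", "low"): (x_hi, y_lo, "right", "bottom"),
    }

    def fmt(v: float) -> str:
        # round half away from zero to 1 decimal
        return f"{np.floor(abs(v) * 10 + 0.5) / 10 * np.sign(v):.1f}"

    for q, sides in cfg.quadrant_layout.items():
        x, y, ha, va = pos[sides]
        black = annotations.loc[q, "pct_of_total"]
        lines = [f"{q}: {fmt(black)}"]
        red = annotations.loc[q, "pct_zpos_of_quadrant"]
        text = ax.text(
            x, y, lines[0], ha=ha, va=va, fontsize=7, color="black",
            transform=ax.transData,
        )
        if np.isfinite(red):
            offset = 1 if va == "bottom" else -1
            ax.annotate(
                fmt(red), xy=(x, y), xytext=(0, 10 * offset),
                textcoords="offset points", ha=ha, va=va, fontsize=7, color="red",
            )
        _ = text


def render_bin_plot(
    grid: BinGrid,
    out,
    statistic: str = "msi",
    scale: ColorScale | None = None,
    annotations=None,
    title: str | None = None,
) -> str:
    """Render one bin plot to PNG or SVG (chosen by the file suffix).

    ``scale=None`` uses the grid's own dynamic range.  For ``msi_pos``,
    displayed bins with fewer than ``min_cells_per_bin`` z-positive cells are
    drawn gray.  Pass the grid's quadrant statistics as ``annotations`` to
    print the black/red percentages.
    """
    cfg = grid.config
    try:
        if scale is None:
            scale = ColorScale(*_dynamic_endpoints(grid, statistic))
        shown, values = _grid_values(grid, statistic)
    except ConfigError:
        shown, values = grid.displayed.iloc[:0], None
        scale = scale or ColorScale(0.0, 1.0)
        warnings.warn("no displayed bins; rendering empty axes", stacklevel=2)

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    w = cfg.bin_width
    cmap = scale.colormap()
    for (i, j), row in shown.iterrows():
        if statistic == "msi_pos" and not row["displayed_pos"]:
            color = GRAY
        else:
            v = values.loc[(i, j)]
            if not np.isfinite(v):
                continue
            color = scale.color(float(v))
        ax.add_patch(Rectangle((i * w, j * w), w, w, facecolor=color, edgecolor="none"))

    if len(shown):
        ax.set_xlim(shown.index.get_level_values("i").min() * w - w,
                    (shown.index.get_level_values("i").max() + 2) * w)
        ax.set_ylim(shown.index.get_level_values("j").min() * w - w,
                    (shown.index.get_level_values("j").max() + 2) * w)
    ax.set_xlabel(f"{cfg.x_marker} (asinh)")
    ax.set_ylabel(f"{cfg.y_marker} (asinh)")
    label = {"count": "cells per bin", "msi": f"{cfg.z_marker} MSI",
             "msi_pos": f"{cfg.z_marker} MSI+"}[statistic]
    if title:
        ax.set_title(title, fontsize=9)

    sm = plt.cm.ScalarMappable(
        norm=Normalize(scale.v_min, scale.v_max if scale.v_max > scale.v_min
                       else scale.v_min + 1e-12),
        cmap=cmap,
    )
    cbar = fig.colorbar(sm, ax=ax, ticks=[scale.v_min, scale.v_max])
    cbar.set_label(f"{label} [{scale.mode}]", fontsize=8)
    cbar.ax.set_yticklabels([f"{scale.v_min:.2f}", f"{scale.v_max:.2f}"])

    if annotations is not None and cfg.x_threshold is not None and cfg.y_threshold is not None:
        _annotate_quadrants(ax, grid, annotations)

    fig.tight_layout()
    _save(fig, out)
    plt.close(fig)
    return str(out)


def render_panel(
    grids: dict[tuple[str, str], BinGrid],
    out_dir,
    statistic: str = "msi",
    filename_template: str = "{sample}_{x}_{y}_{z}_{stat}.png",
) -> list[str]:
    """Side-by-side pseudo-multiparametric panel.

    ``grids`` maps ``(sample_id, z_marker)`` to its grid; all grids must share
    the x/y plane and bin width.  Within each z marker all plots share one
    common color scale, so equal statistic values render as equal colors
    across samples.  Returns the written file paths (one per grid, plus a
    ``panel_<stat>.png`` contact sheet).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    planes = {
        (g.config.x_marker, g.config.y_marker, g.config.bin_width)
        for g in grids.values()
    }
    if len(planes) != 1:
        raise ConfigError(f"panel grids use mismatched x/y planes: {planes}")

    z_markers = sorted({z for _, z in grids})
    samples = sorted({s for s, _ in grids})
    scales = {
        z: common_range([g for (s, zz), g in grids.items() if zz == z], statistic)
        for z in z_markers
    }
    paths = []
    for (sample, z), grid in sorted(grids.items()):
        cfg = grid.config
        name = filename_template.format(
            sample=sample, x=cfg.x_marker, y=cfg.y_marker, z=z, stat=statistic
        )
        paths.append(
            render_bin_plot(
                grid, out_dir / name, statistic=statistic, scale=scales[z],
                title=f"{sample} | z = {z}",
            )
        )

    # contact sheet: samples as rows, z markers as columns
    fig, axes = plt.subplots(
        len(samples), len(z_markers),
        figsize=(2.2 * len(z_markers), 2.0 * len(samples)),
        squeeze=False,
    )
    for r, sample in enumerate(samples):
        for c, z in enumerate(z_markers):
            ax = axes[r][c]
            grid = grids[(sample, z)]
            scale = scales[z]
            w = grid.config.bin_width
            shown, values = _grid_values(grid, statistic)
            for (i, j), row in shown.iterrows():
                if statistic == "msi_pos" and not row["displayed_pos"]:
                    color = GRAY
                else:
                    v = values.loc[(i, j)]
                    if not np.isfinite(v):
                        continue
                    color = scale.color(float(v))
                ax.add_patch(Rectangle((i * w, j * w), w, w, facecolor=color,
                                       edgecolor="none"))
            ax.autoscale_view()
            ax.set_xticks([])
            ax.set_yticks([])
            if r == 0:
                ax.set_title(z, fontsize=8)
            if c == 0:
                ax.set_ylabel(sample, fontsize=7)
    sheet = out_dir / f"panel_{statistic}.png"
    fig.tight_layout()
    _save(fig, sheet)
    plt.close(fig)
    paths.append(str(sheet))
    return paths


_COEXPR_COLORS = {
    "z1+z2+": "#d62728",
    "z1+z2-": "#ff9896",
    "z1-z2+": "#1f77b4",
    "z1-z2-": "#c7c7c7",
}


def render_coexpression_pies(stats, out, title: str | None = None) -> str:
    """One pie per quadrant with the four joint z1/z2 positivity sectors.

    Sector angles are proportional to the fractions; empty quadrants are
    replaced by a placeholder label.
    """
    quadrants = list(stats.index)
    fig, axes = plt.subplots(1, len(quadrants), figsize=(2.4 * len(quadrants), 2.8))
    if len(quadrants) == 1:
        axes = [axes]
    for ax, q in zip(axes, quadrants):
        fracs = stats.loc[q, list(COEXPR_CATEGORIES)].to_numpy(dtype=float)
        if not np.isfinite(fracs).all() or fracs.sum() == 0:
            ax.text(0.5, 0.5, f"{q}\n(empty)", ha="center", va="center", fontsize=8)
            ax.set_axis_off()
            continue
        ax.pie(
            fracs,
            colors=[_COEXPR_COLORS[c] for c in COEXPR_CATEGORIES],
            startangle=90,
            counterclock=False,
        )
        ax.set_title(q, fontsize=9)
    handles = [
        plt.Line2D([], [], marker="s", linestyle="", color=_COEXPR_COLORS[c], label=c)
        for c in COEXPR_CATEGORIES
    ]
    fig.legend(handles=handles, loc="lower center", ncol=4, fontsize=7, frameon=False)
    if title:
        fig.suptitle(title, fontsize=9)
    _save(fig, out)
    plt.close(fig)
    return str(out)


def _save(fig, out) -> None:
    out = Path(out)
    if out.suffix.lower() == ".svg":
        # Date-free metadata keeps repeated renders byte-identical
        fig.savefig(out, format="svg", metadata={"Date": None})
    else:
        fig.savefig(out, dpi=150)
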