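"""End-to-end workflow: read → transform → gate → QC → bin → features → compare.

A run is driven by a :class:`RunConfig` (usually loaded from YAML) and writes
every artifact — gate report, QC tables, bin plots, feature matrix, group
comparison, resolved configuration and a log with content checksums — under
one output directory.  All numeric outputs are deterministic for fixed inputs
and configuration; re-running reproduces the CSVs byte-identically.

QC flags are advisory: flagged samples are excluded from the group comparison
only when ``qc.exclude_flagged`` is set, and then loudly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import plotting, qc, stats
from .binning import BinConfig, compute_bin_grid, quadrant_stats
from .errors import ConfigError, PribinError
from .fcs import GateSpec, TransformSpec, apply_gates, apply_transform, load_gate_spec, read_fcs
from .features import PanelEntry
from .synthetic import TRUTH_CHANNEL

__all__ = ["RunConfig", "run_pipeline", "default_panel", "load_run_config"]

log = logging.getLogger("pribin")


def default_panel(
    x_threshold: float = 2.6,
    y_threshold: float = 1.6,
    z_thresholds: dict[str, float] | None = None,
) -> list[PanelEntry]:
    """CD90 x CD44 plane with the standard z-marker set.

    Emits, per z marker, the max bin-MSI and MSI range (threshold-free) plus
    quadrant and z-positive percentages.  Thresholds default to the values
    appropriate for the package's synthetic cohort; real data needs
    experiment-specific ones.
    """
    zt = {"CD86": 1.5, "CD27": 1.5, "Ki67": 1.2, "Tbet": 1.5, "Foxp3": 1.5,
          "KLRG1": 1.0, "PDL1": 1.0}
    if z_thresholds:
        zt.update(z_thresholds)
    return [
        PanelEntry(
            BinConfig(
                x_marker="CD90", y_marker="CD44", z_marker=z,
                x_threshold=x_threshold, y_threshold=y_threshold,
                z_threshold=zt[z],
            )
        )
        for z in sorted(zt)
    ]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    manifest: str
    transform: TransformSpec = field(default_factory=TransformSpec)
    gates: GateSpec | None = None
    panel: list[PanelEntry] = field(default_factory=default_panel)
    qc_markers: list[str] | None = None  # None = all mapped markers
    qc_min_cell_count: int = 1000
    qc_outlier_factor: float = 3.0
    exclude_flagged: bool = False
    render_plots: bool = True
    plot_statistic: str = "msi"
    plot_format: str = "png"
    seed: int = 0

    def to_dict(self) -> dict:
        doc: dict = {
            "manifest": self.manifest,
            "transform": {
                "cofactor": self.transform.cofactor,
                "convention": self.transform.convention,
                "channels": list(self.transform.channels) if self.transform.channels else None,
            },
            "gates": None
            if self.gates is None
            else [
                {
                    "name": s.name,
                    "x_marker": s.x_marker,
                    "y_marker": s.y_marker,
                    "x_interval": [float(v) if math.isfinite(v) else None for v in s.x_interval],
                    "y_interval": [float(v) if math.isfinite(v) else None for v in s.y_interval],
                }
                for s in self.gates.steps
            ],
            "panel": feat.panel_to_dict(self.panel),
            "qc": {
                "markers": self.qc_markers,
                "min_cell_count": self.qc_min_cell_count,
                "outlier_factor": self.qc_outlier_factor,
                "exclude_flagged": self.exclude_flagged,
            },
            "plots": {
                "enabled": self.render_plots,
                "statistic": self.plot_statistic,
                "format": self.plot_format,
            },
            "seed": self.seed,
        }
        return doc


def _panel_from_config(entries: list[dict]) -> list[PanelEntry]:
    panel = []
    for e in entries:
        cfg = dict(e)
        statistics = tuple(cfg.pop("statistics", feat.ALL_STATISTICS))
        layout = cfg.pop("quadrant_layout", None)
        if layout is not None:
            cfg["quadrant_layout"] = {q: tuple(v) for q, v in layout.items()}
        panel.append(PanelEntry(BinConfig(**cfg), statistics))
    return panel


def load_run_config(path) -> RunConfig:
    """Load a pipeline configuration from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        tr = doc.get("transform", {}) or {}
        channels = tr.get("channels")
        transform = TransformSpec(
            cofactor=float(tr.get("cofactor", 0.1)),
            channels=tuple(channels) if channels else None,
            convention=tr.get("convention", "multiply"),
        )
        gates = None
        if doc.get("gates"):
            gates = load_gate_spec(doc["gates"]) if isinstance(doc["gates"], str) else None
        panel = (
            _panel_from_config(doc["panel"]) if doc.get("panel") else default_panel()
        )
        qc_doc = doc.get("qc", {}) or {}
        plots = doc.get("plots", {}) or {}
        return RunConfig(
            manifest=doc["manifest"],
            transform=transform,
            gates=gates,
            panel=panel,
            qc_markers=qc_doc.get("markers"),
            qc_min_cell_count=int(qc_doc.get("min_cell_count", 1000)),
            qc_outlier_factor=float(qc_doc.get("outlier_factor", 3.0)),
            exclude_flagged=bool(qc_doc.get("exclude_flagged", False)),
            render_plots=bool(plots.get("enabled", True)),
            plot_statistic=plots.get("statistic", "msi"),
            plot_format=plots.get("format", "png"),
            seed=int(doc.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"run config is missing key {exc}") from exc


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full workflow; return the output directory.

    Stages run in order and any failure aborts with the stage name and the
    offending sample; partial outputs are kept next to a ``FAILED`` marker.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    artifacts: dict[str, str] = {}
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

        stage = "read"
        manifest = pd.read_csv(config.manifest)
        samples = []
        for _, row in manifest.iterrows():
            log.info("reading %s", row["path"])
            table = read_fcs(row["path"])
            samples.append((str(row["sample_id"]), str(row["group"]), table))

        stage = "transform"
        transformed = []
        for sid, group, table in samples:
            spec = config.transform
            if spec.channels is None and TRUTH_CHANNEL in table.channels:
                spec = TransformSpec(
                    cofactor=spec.cofactor,
                    channels=tuple(c for c in table.channels if c != TRUTH_CHANNEL),
                    convention=spec.convention,
                )
            transformed.append((sid, group, apply_transform(table, spec)))
        samples = transformed

        stage = "gate"
        if config.gates is not None:
            gated = []
            reports = []
            for sid, group, table in samples:
                table, report = apply_gates(table, config.gates)
                report.insert(0, "sample_id", sid)
                reports.append(report)
                gated.append((sid, group, table))
            samples = gated
            pd.concat(reports).to_csv(out / "gate_report.csv", index=False)
            artifacts["gate_report.csv"] = _checksum(out / "gate_report.csv")

        stage = "qc"
        markers = config.qc_markers or [
            m for m in samples[0][2].marker_labels if m != TRUTH_CHANNEL
        ]
        report = qc.qc_report(
            samples, markers,
            min_cell_count=config.qc_min_cell_count,
            outlier_factor=config.qc_outlier_factor,
        )
        report.cell_counts.to_csv(out / "qc_cell_counts.csv")
        report.mds_coordinates.to_csv(out / "qc_mds.csv")
        report.flags.to_csv(out / "qc_flags.csv", index=False)
        for name in ("qc_cell_counts.csv", "qc_mds.csv", "qc_flags.csv"):
            artifacts[name] = _checksum(out / name)
        if config.render_plots:
            _render_qc(report, out)

        if report.flagged_samples:
            if config.exclude_flagged:
                log.warning(
                    "excluding flagged samples from comparison: %s",
                    report.flagged_samples,
                )
                samples = [s for s in samples if s[0] not in report.flagged_samples]
            else:
                log.warning(
                    "QC flagged samples %s; they remain in the analysis "
                    "(set qc.exclude_flagged to drop them)",
                    report.flagged_samples,
                )

        stage = "bin_plots"
        if config.render_plots:
            plot_dir = out / "plots"
            plot_dir.mkdir(exist_ok=True)
            for sid, _, table in samples:
                for entry in config.panel:
                    cfg = entry.config
                    try:
                        grid = compute_bin_grid(table, cfg)
                        ann = (
                            quadrant_stats(table, cfg)
                            if cfg.x_threshold is not None and cfg.y_threshold is not None
                            else None
                        )
                        name = f"{sid}_{cfg.x_marker}_{cfg.y_marker}_{cfg.z_marker}_{config.plot_statistic}.{config.plot_format}"
                        plotting.render_bin_plot(
                            grid, plot_dir / name,
                            statistic=config.plot_statistic,
                            annotations=ann, title=sid,
                        )
                    except (ConfigError, KeyError) as exc:
                        log.warning("plot skipped for %s / %s: %s", sid, cfg.z_marker, exc)

        stage = "features"
        matrix = feat.build_feature_matrix(samples, config.panel)
        matrix.to_csv(out / "features.csv")
        with open(out / "panel.yaml", "w") as fh:
            yaml.safe_dump(feat.panel_to_dict(config.panel), fh, sort_keys=False)
        artifacts["features.csv"] = _checksum(out / "features.csv")

        stage = "compare"
        comparison = stats.compare_groups(matrix)
        comparison.to_csv(out / "comparison.csv")
        artifacts["comparison.csv"] = _checksum(out / "comparison.csv")

        with open(out / "run_manifest.json", "w") as fh:
            json.dump({"artifacts": artifacts}, fh, indent=2, sort_keys=True)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise PribinError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _render_qc(report: qc.QCReport, out: Path) -> None:
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(report.mds_coordinates.iloc[:, 0], report.mds_coordinates.iloc[:, 1], s=25)
    for sid, row in report.mds_coordinates.iterrows():
        ax.annotate(sid, (row.iloc[0], row.iloc[1]), fontsize=6,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(report.mds_coordinates.columns[0])
    ax.set_ylabel(report.mds_coordinates.columns[1] if report.mds_coordinates.shape[1] > 1 else "")
    ax.set_title("MDS of median marker profiles", fontsize=9)
    fig.tight_layout()
    fig.savefig(out / "qc_mds.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    hierarchy.dendrogram(report.linkage, labels=list(report.profiles.index), ax=ax,
                         leaf_font_size=7)
    ax.set_title("Ward clustering of median marker profiles", fontsize=9)
    fig.tight_layout()
    fig.savefig(out / "qc_dendrogram.png", dpi=150)
    plt.close(fig)
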