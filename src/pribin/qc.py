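"""Sample-level quality control and marker ranking.

Samples are summarized by their per-marker median transformed intensity and
compared by Euclidean distance: classical (Torgerson) metric multidimensional
scaling for a 2-D overview, Ward's hierarchical clustering for a dendrogram.
Markers are ranked by the non-redundancy score (NRS): per sample, a PCA of
the cell x marker matrix is taken and each marker scores the sum over the
top components of eigenvalue x |loading|; markers carrying unique variance
score high.  NRS operates on transformed intensities and is deliberately not
scale-invariant.

Quality flags (low cell count, MDS outlier position) are advisory: the tool
never silently drops a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .errors import ConfigError, StateError
from .fcs import EventTable

__all__ = [
    "median_profiles",
    "classical_mds",
    "ward_clustering",
    "nrs",
    "qc_report",
    "QCReport",
]


def median_profiles(
    samples: list[tuple[str, EventTable]], markers: list[str]
) -> pd.DataFrame:
    """Per-sample median transformed intensity for each marker.

    Exact medians (midpoint of the two central order statistics for even n).
    """
    rows = {}
    for sample_id, table in samples:
        if not table.transformed:
            raise StateError(f"sample {sample_id!r} is not transformed")
        try:
            rows[sample_id] = {m: float(np.median(table.get(m))) for m in markers}
        except ConfigError as exc:
            raise ConfigError(f"sample {sample_id!r}: {exc}") from exc
    out = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
    out.index.name = "sample_id"
    return out


def classical_mds(
    profiles: pd.DataFrame, k: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) metric MDS of the median-profile matrix.

    Double-centers the squared Euclidean distance matrix, eigendecomposes it
    and returns the top-k coordinates (scaled by sqrt of the eigenvalues)
    plus the full eigenvalue spectrum, descending.  The embedding reproduces
    the input distances exactly when the profiles lie in a <=k dimensional
    affine subspace.
    """
    n = len(profiles)
    if n < 2:
        raise ConfigError("MDS needs at least 2 samples")
    if k >= n:
        raise ConfigError(f"k={k} must be < n_samples={n}")
    d2 = squareform(pdist(profiles.to_numpy(dtype=float))) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    frame = pd.DataFrame(
        coords, index=profiles.index, columns=[f"mds_{i + 1}" for i in range(k)]
    )
    return frame, eigval


def ward_clustering(profiles: pd.DataFrame) -> np.ndarray:
    """Ward's hierarchical clustering of samples on Euclidean distances.

    Returns the scipy linkage matrix (merge list with heights, heights
    non-decreasing); render with ``scipy.cluster.hierarchy.dendrogram``.
    """
    if len(profiles) < 2:
        raise ConfigError("clustering needs at least 2 samples")
    return hierarchy.linkage(profiles.to_numpy(dtype=float), method="ward")


def nrs(
    samples: list[tuple[str, EventTable]],
    markers: list[str],
    n_components: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Non-redundancy score per marker.

    Per sample, PCA of the (centered) cell x marker matrix; the NRS of marker
    m is ``sum_k eigenvalue_k * |loading_{m,k}|`` over the top
    ``n_components`` components.  Returns the per-sample score matrix and the
    cross-sample mean ranked descending.
    """
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    if len(markers) < n_components:
        raise ConfigError(
            f"need >= {n_components} markers for {n_components} components"
        )
    rows = {}
    for sample_id, table in samples:
        data = np.column_stack([table.get(m) for m in markers])
        if data.shape[0] < n_components + 1:
            raise ConfigError(
                f"sample {sample_id!r} has too few cells for {n_components} components"
            )
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(data)
        # explained_variance_ are covariance eigenvalues; components_ rows are
        # the unit-norm loading vectors
        scores = np.abs(pca.components_).T @ pca.explained_variance_
        rows[sample_id] = dict(zip(markers, scores))
    per_sample = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
    per_sample.index.name = "sample_id"
    summary = per_sample.mean(axis=0).sort_values(ascending=False)
    summary.name = "nrs"
    return per_sample, summary


@dataclass
class QCReport:
    """Advisory quality-control summary of a cohort."""

    cell_counts: pd.Series
    mds_coordinates: pd.DataFrame
    mds_eigenvalues: np.ndarray
    linkage: np.ndarray
    flags: pd.DataFrame  # sample_id, reason, detail
    profiles: pd.DataFrame = field(repr=False, default=None)

    @property
    def flagged_samples(self) -> list[str]:
        return sorted(self.flags["sample_id"].unique())


def qc_report(
    samples: list[tuple[str, str, EventTable]],
    markers: list[str],
    min_cell_count: int = 1000,
    outlier_factor: float = 3.0,
) -> QCReport:
    """Cohort QC: cell counts, MDS map, dendrogram and advisory flags.

    A sample is flagged when its cell count falls below ``min_cell_count`` or
    when its MDS position lies further from its group centroid than
    ``outlier_factor`` times the median within-group centroid distance
    (groups with < 3 samples are not tested for outliers).  Exclusion is
    left to the caller.
    """
    ids = [s for s, _, _ in samples]
    groups = pd.Series({s: g for s, g, _ in samples})
    counts = pd.Series({s: t.n_events for s, _, t in samples}, name="n_cells")
    profiles = median_profiles([(s, t) for s, _, t in samples], markers)
    coords, eigval = classical_mds(profiles, k=min(2, len(profiles) - 1))
    linkage = ward_clustering(profiles)

    flag_rows = []
    for s in ids:
        if counts[s] < min_cell_count:
            flag_rows.append(
                {"sample_id": s, "reason": "low_cell_count",
                 "detail": f"{counts[s]} < {min_cell_count}"}
            )
    for g in groups.unique():
        members = [s for s in ids if groups[s] == g]
        if len(members) < 3:
            continue
        pts = coords.loc[members].to_numpy()
        centroid = pts.mean(axis=0)
        dists = np.linalg.norm(pts - centroid, axis=1)
        med = np.median(dists)
        if med == 0:
            continue
        for s, d in zip(members, dists):
            if d > outlier_factor * med:
                flag_rows.append(
                    {"sample_id": s, "reason": "mds_outlier",
                     "detail": f"distance {d:.3g} > {outlier_factor} x median {med:.3g}"}
                )
    flags = pd.DataFrame(flag_rows, columns=["sample_id", "reason", "detail"])
    return QCReport(
        cell_counts=counts,
        mds_coordinates=coords,
        mds_eigenvalues=eigval,
        linkage=linkage,
        flags=flags,
        profiles=profiles,
    )
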