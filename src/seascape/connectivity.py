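"""Connectivity matrices and dispersal summaries from settlement records.

The connectivity matrix entry (i, j) is the probability that a particle
released at source i settles at destination j, with the number *released*
(not the number settled) as denominator, so each row sum plus the unsettled
fraction equals 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ptm import ParticleEnsemble, Status, TrajectoryBundle
from .sites import SiteTable


@dataclass
class ConnectivityMatrix:
    """Source x destination settlement probabilities."""

    site_ids: list[str]
    probabilities: np.ndarray  # (n_sites, n_sites)
    released: np.ndarray       # count per source
    settled_counts: np.ndarray  # (n_sites, n_sites) integer counts
    label: str = ""

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        n = len(self.site_ids)
        if self.probabilities.shape != (n, n):
            raise ValueError("probability matrix must be square over the site set")
        if np.any(self.probabilities < -1e-12) or np.any(self.probabilities > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(self.probabilities.sum(axis=1) > 1 + 1e-9):
            raise ValueError("row sums must be <= 1")

    @property
    def self_recruitment(self) -> np.ndarray:
        """Diagonal as fractions."""
        return np.diag(self.probabilities)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=self.site_ids, columns=self.site_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="site_id")

    @classmethod
    def read_csv(cls, path, label: str = "") -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        p = df.to_numpy(dtype=float)
        counts = np.zeros_like(p)
        return cls(list(df.index), p, released=np.zeros(len(df)), settled_counts=counts, label=label)

    def to_edge_list(self, threshold: float = 0.0) -> pd.DataFrame:
        """Off-diagonal entries > threshold as (source, destination, weight)."""
        rows = []
        for i, src in enumerate(self.site_ids):
            for j, dst in enumerate(self.site_ids):
                if i != j and self.probabilities[i, j] > threshold:
                    rows.append((src, dst, self.probabilities[i, j]))
        return pd.DataFrame(rows, columns=["source", "destination", "weight"])


def connectivity_matrix(
    final_particles: ParticleEnsemble,
    sites: SiteTable,
    label: str = "",
    allow_empty_sources: bool = False,
) -> ConnectivityMatrix:
    """Tally settlement outcomes into a source x destination probability matrix."""
    ids = sites.site_ids
    index = {sid: k for k, sid in enumerate(ids)}
    n = len(ids)
    counts = np.zeros((n, n), dtype=np.int64)
    released = np.zeros(n, dtype=np.int64)

    for origin in final_particles.origin_site_id:
        if origin not in index:
            raise ValueError(f"particle origin {origin!r} not in site table")
        released[index[origin]] += 1
    settled = final_particles.status == Status.SETTLED
    for origin, dest in zip(
        final_particles.origin_site_id[settled], final_particles.settled_site_id[settled]
    ):
        counts[index[origin], index[dest]] += 1

    if (released == 0).any() and not allow_empty_sources:
        empty = [sid for sid, k in index.items() if released[k] == 0]
        raise ValueError(f"no particles released from sites: {empty}")
    with np.errstate(invalid="ignore"):
        probs = np.where(released[:, None] > 0, counts / np.maximum(released[:, None], 1), np.nan)
    return ConnectivityMatrix(ids, probs, released=released, settled_counts=counts, label=label)


def _check_same_sites(matrices: list[ConnectivityMatrix]) -> list[str]:
    if not matrices:
        raise ValueError("need at least one connectivity matrix")
    ids = matrices[0].site_ids
    for m in matrices[1:]:
        if m.site_ids != ids:
            raise ValueError("connectivity matrices cover different site sets")
    return ids


def self_recruitment(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Per-site mean and sample SD of the diagonal across matrices, in percent."""
    ids = _check_same_sites(matrices)
    diags = np.vstack([100.0 * m.self_recruitment for m in matrices])
    mean = diags.mean(axis=0)
    sd = diags.std(axis=0, ddof=1) if len(matrices) > 1 else np.zeros(len(ids))
    return pd.DataFrame({"site_id": ids, "mean_pct": mean, "sd_pct": sd})


def seasonal_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of monthly matrices (the seasonally averaged network)."""
    ids = _check_same_sites(matrices)
    probs = np.mean([m.probabilities for m in matrices], axis=0)
    released = np.sum([m.released for m in matrices], axis=0)
    counts = np.sum([m.settled_counts for m in matrices], axis=0)
    return ConnectivityMatrix(ids, probs, released=released, settled_counts=counts, label="seasonal-mean")


def matrix_correlation(a, b) -> float:
    """Squared Pearson correlation between two matrices (or maps), flattened.

    Raises if either input has zero variance (correlation undefined).
    """
    x = np.asarray(getattr(a, "probabilities", a), dtype=float).ravel()
    y = np.asarray(getattr(b, "probabilities", b), dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("inputs must have the same shape")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("matrix correlation undefined: zero variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class DispersalMap:
    """Fraction of a source's position samples falling in each grid cell."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    density: dict  # source site id -> (n_lat_cells, n_lon_cells) array
    out_of_grid: dict  # source site id -> fraction of samples outside the grid

    def centroid(self, source: str) -> tuple[float, float]:
        d = self.density[source]
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        total = d.sum()
        if total == 0:
            return (np.nan, np.nan)
        return (
            float((d.sum(axis=0) * lon_c).sum() / total),
            float((d.sum(axis=1) * lat_c).sum() / total),
        )


def density_map(
    trajectories: TrajectoryBundle,
    lon_edges: np.ndarray,
    lat_edges: np.ndarray,
    mode: str = "window_samples",
    age_range_days: tuple[float, float] | None = None,
) -> DispersalMap:
    """Histogram particle positions per source over a cell grid.

    ``mode='window_samples'`` uses every valid sample (optionally restricted
    to ``age_range_days``); ``mode='final'`` uses each particle's last valid
    sample.  Densities are normalised by the total number of contributing
    samples per source, with mass falling outside the grid reported
    separately, so in-grid mass + out-of-grid mass = 1 per source.
    """
    if mode not in ("window_samples", "final"):
        raise ValueError(f"unknown mode {mode!r}")
    lon_edges = np.asarray(lon_edges, dtype=float)
    lat_edges = np.asarray(lat_edges, dtype=float)
    density: dict = {}
    out_of_grid: dict = {}
    sources = pd.unique(trajectories.origin_site_id)

    sample_mask = trajectories.valid.copy()
    if age_range_days is not None:
        a0, a1 = (d * 86_400.0 for d in age_range_days)
        keep = (trajectories.age_axis_s >= a0 - 1e-9) & (trajectories.age_axis_s <= a1 + 1e-9)
        sample_mask &= keep[None, :]
    if mode == "final":
        final_mask = np.zeros_like(sample_mask)
        for i in range(sample_mask.shape[0]):
            nz = np.nonzero(sample_mask[i])[0]
            if nz.size:
                final_mask[i, nz[-1]] = True
        sample_mask = final_mask

    for src in sources:
        rows = trajectories.origin_site_id == src
        m = sample_mask[rows]
        lons = trajectories.lons[rows][m]
        lats = trajectories.lats[rows][m]
        total = lons.size
        hist, _, _ = np.histogram2d(lats, lons, bins=[lat_edges, lon_edges])
        if total == 0:
            density[src] = hist
            out_of_grid[src] = 0.0
        else:
            density[src] = hist / total
            out_of_grid[src] = 1.0 - hist.sum() / total
    return DispersalMap(lon_edges=lon_edges, lat_edges=lat_edges, density=density, out_of_grid=out_of_grid)
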