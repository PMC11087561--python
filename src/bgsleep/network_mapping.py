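"""Optimal decoding map: from channel locations to channel selection.

Each recording site is modelled as a 5-mm-radius spherical volume of
tissue recorded in MNI space. Its functional connectivity profile to a
parcellated whole-brain connectome (166 parcels by default) is
correlated — per parcel, rank-based, optionally controlling covariates
— with the channel's decoding accuracy, producing the optimal decoding
map. Channels of an unseen subject are then ranked by the Spearman
similarity of their own connectivity profile to that map.

The normative connectome sits behind a small interface; the shipped
implementation is a synthetic connectome with spatially smooth
parcel mixing, adequate for testing the mapping machinery. A real
normative connectome can be plugged in by implementing the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "SeedVolume",
    "Connectome",
    "SyntheticConnectome",
    "seed_volume",
    "channel_connectivity",
    "build_optimal_map",
    "spatial_similarity",
    "loo_validate_map",
    "select_channel_by_map",
    "export_map_nifti",
]


@dataclass
class SeedVolume:
    """Voxel centres within ``radius`` mm of a seed coordinate.

    Voxels live on the global lattice of integer multiples of ``grid``
    mm, so translated seeds on lattice vectors produce congruent sets.
    """

    center: np.ndarray
    radius: float
    grid: float
    voxels: np.ndarray

    def __post_init__(self) -> None:
        d = np.linalg.norm(self.voxels - self.center, axis=1)
        if np.any(d > self.radius + 1e-9):
            raise ValueError("voxel outside the seed radius")


def seed_volume(
    center: np.ndarray | list[float], radius: float = 5.0, grid: float = 1.0
) -> SeedVolume:
    """Sphere of lattice voxel centres around a contact coordinate."""
    if radius <= 0 or grid <= 0:
        raise ValueError("radius and grid spacing must be > 0")
    center = np.asarray(center, dtype=float)
    lo = np.floor((center - radius) / grid).astype(int)
    hi = np.ceil((center + radius) / grid).astype(int)
    axes = [np.arange(lo[i], hi[i] + 1) * grid for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.linalg.norm(pts - center, axis=1) <= radius
    return SeedVolume(center=center, radius=radius, grid=grid, voxels=pts[keep])


class Connectome:
    """Interface: seed-to-parcel connectivity provider.

    Implementations expose ``n_parcels``, a ``parcel_series`` array of
    shape (n_parcels, T), and ``voxel_series(points)`` returning one
    series per queried voxel centre.
    """

    n_parcels: int
    parcel_series: np.ndarray

    def voxel_series(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SyntheticConnectome(Connectome):
    """Spatially smooth stand-in for a normative fMRI connectome.

    Synthetic: parcel centres are scattered in a +/-50 mm box; each
    voxel's series is a distance-weighted (Gaussian, ``sigma_mm``)
    mixture of parcel series plus voxel-private noise. Private noise is
    derived deterministically from the voxel coordinate, so identical
    seeds yield identical profiles.
    """

    def __init__(
        self,
        n_parcels: int = 166,
        n_timepoints: int = 1000,
        sigma_mm: float = 12.0,
        private_noise: float = 0.3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.n_parcels = n_parcels
        self.n_timepoints = n_timepoints
        self.sigma_mm = sigma_mm
        self.private_noise = private_noise
        self.seed = seed
        self.parcel_centers = rng.uniform(-50.0, 50.0, size=(n_parcels, 3))
        self.parcel_series = rng.standard_normal((n_parcels, n_timepoints))

    def voxel_series(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((points[:, None, :] - self.parcel_centers[None, :, :]) ** 2).sum(-1)
        w = np.exp(-0.5 * d2 / self.sigma_mm**2)
        w /= w.sum(axis=1, keepdims=True) + 1e-300
        series = w @ self.parcel_series
        for i, p in enumerate(points):
            key = np.int64(self.seed) * 1000003 + np.int64(
                abs(hash((round(p[0], 3), round(p[1], 3), round(p[2], 3))))
            ) % (2**31)
            vr = np.random.default_rng(int(key) % (2**63))
            series[i] += self.private_noise * vr.standard_normal(self.n_timepoints)
        return series


def channel_connectivity(seed: SeedVolume, connectome: Connectome) -> np.ndarray:
    """Seed-to-parcel connectivity profile of one recording site.

    The mean time series over the seed's voxels is Pearson-correlated
    with every parcel's series, giving a profile of length
    ``connectome.n_parcels``.
    """
    vox = connectome.voxel_series(seed.voxels)
    mean_series = vox.mean(axis=0)
    ps = connectome.parcel_series
    ms = mean_series - mean_series.mean()
    pc = ps - ps.mean(axis=1, keepdims=True)
    denom = np.sqrt((ms @ ms) * (pc * pc).sum(axis=1))
    if np.any(denom == 0):
        raise ValueError("zero-variance series in connectivity computation")
    return (pc @ ms) / denom


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.apply_along_axis(spstats.rankdata, axis, a)


def _partial_rank_corr(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """Spearman partial correlation of each column of x with y.

    Rank-transform everything, residualise x and y on the (ranked)
    covariates plus an intercept, then Pearson-correlate residuals.
    Without covariates this reduces to the plain Spearman correlation.
    """
    xr = _rank(x, axis=0)
    yr = spstats.rankdata(y)
    if covariates is not None and covariates.size:
        cr = _rank(np.atleast_2d(covariates.T).T, axis=0)
        design = np.column_stack([np.ones(len(yr)), cr])
        beta_x, *_ = np.linalg.lstsq(design, xr, rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, yr, rcond=None)
        xr = xr - design @ beta_x
        yr = yr - design @ beta_y
    else:
        xr = xr - xr.mean(axis=0)
        yr = yr - yr.mean()
    sx = np.sqrt((xr * xr).sum(axis=0))
    sy = np.sqrt(yr @ yr)
    if sy == 0:
        raise ValueError("accuracies are constant: correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xr.T @ yr) / (sx * sy)
    return np.where(np.isfinite(r), r, 0.0)


def build_optimal_map(
    profiles: np.ndarray,
    accuracies: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> np.ndarray:
    """Per-parcel association between connectivity and decoding accuracy.

    Rank-based (Spearman) partial correlation per parcel, controlling
    the supplied covariates (e.g. sleep fragmentation count). Only
    adjacent-referenced channels should be supplied: sandwich-referenced
    channels have a different recording-field geometry.
    """
    profiles = np.asarray(profiles, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] != accuracies.shape[0]:
        raise ValueError("profiles must be (n_channels, n_parcels) matching accuracies")
    if profiles.shape[0] < 5:
        raise ValueError("need at least 5 channels to build a map")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    return _partial_rank_corr(profiles, accuracies, cov)


def spatial_similarity(profile: np.ndarray, optimal_map: np.ndarray) -> float:
    """Spearman correlation between a channel profile and the map."""
    profile = np.asarray(profile, dtype=float)
    optimal_map = np.asarray(optimal_map, dtype=float)
    if profile.shape != optimal_map.shape:
        raise ValueError("profile and map lengths differ")
    if np.ptp(profile) == 0 or np.ptp(optimal_map) == 0:
        raise ValueError("constant vector: similarity undefined")
    rho, _ = spstats.spearmanr(profile, optimal_map)
    return float(rho)


def loo_validate_map(
    profiles: np.ndarray,
    accuracies: np.ndarray,
    subjects: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Leave-one-subject-out validation of the optimal map.

    For each subject, a map is built from all other subjects' channels;
    the held-out channels' similarities to that map are paired with
    their observed accuracies. Returns the per-channel table plus the
    pooled Spearman rho and p-value of similarity vs accuracy.
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 6:
        raise ValueError("need at least 6 subjects for leave-one-out validation")
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    rows = []
    for s in uniq:
        hold = subjects == s
        train_cov = None if cov is None else cov[~hold]
        m = build_optimal_map(profiles[~hold], accuracies[~hold], train_cov)
        for i in np.flatnonzero(hold):
            rows.append(
                {
                    "subject": s,
                    "channel_index": int(i),
                    "similarity": spatial_similarity(profiles[i], m),
                    "accuracy": float(accuracies[i]),
                }
            )
    table = pd.DataFrame(rows)
    rho, p = spstats.spearmanr(table["similarity"], table["accuracy"])
    return table, float(rho), float(p)


def select_channel_by_map(
    profiles: np.ndarray,
    optimal_map: np.ndarray,
    channel_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Rank one subject's channels by similarity to the optimal map.

    The top row is the recommended recording channel. Ties preserve
    input (deepest-first) channel order via a stable sort.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if channel_labels is None:
        channel_labels = [f"ch{i + 1}" for i in range(profiles.shape[0])]
    sims = [spatial_similarity(p, optimal_map) for p in profiles]
    table = pd.DataFrame({"channel": channel_labels, "similarity": sims})
    return table.sort_values(
        "similarity", ascending=False, kind="stable"
    ).reset_index(drop=True)


def export_map_nifti(
    optimal_map: np.ndarray,
    parcel_centers: np.ndarray,
    path: str,
    grid: float = 2.0,
    radius: float = 6.0,
) -> None:
    """Optional volumetric export: paint parcel values into a NIfTI volume.

    Each voxel takes the value of the nearest parcel centre within
    ``radius`` mm (NaN elsewhere), on an isotropic ``grid``-mm lattice
    covering the parcel centres.
    """
    import nibabel as nib

    centers = np.asarray(parcel_centers, dtype=float)
    lo = centers.min(axis=0) - radius
    hi = centers.max(axis=0) + radius
    shape = np.ceil((hi - lo) / grid).astype(int) + 1
    vol = np.full(shape, np.nan, dtype=np.float32)
    idx = np.indices(shape).reshape(3, -1).T
    pts = lo + idx * grid
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    ok = d[np.arange(len(pts)), nearest] <= radius
    vol[tuple(idx[ok].T)] = optimal_map[nearest[ok]]
    affine = np.eye(4) * grid
    affine[:3, 3] = lo
    affine[3, 3] = 1.0
    nib.save(nib.Nifti1Image(vol, affine), path)
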