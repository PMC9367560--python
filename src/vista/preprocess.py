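"""CT preprocessing: resampling, HU normalization, patch extraction, series assembly.

The pipeline mirrors standard nodule-analysis practice: resample each scan to
isotropic 1 mm spacing (trilinear for images, nearest-neighbour for masks),
clip HU to (-1000, 400) and min-max normalize to (0, 1), then cut a fixed
cubic patch centred on the VOI centroid.  A follow-up series is the ordered
collection of such patches with elapsed days and the per-scan VOI volume.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

HU_MIN = -1000.0
HU_MAX = 400.0
MIN_INTERVAL_DAYS = 30.0
DEFAULT_PATCH_SIZE = 32


@dataclass
class CTVolume:
    """A 3D HU grid with voxel spacing in mm per axis."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")


@dataclass
class VOIMask:
    """Binary nodule mask congruent with its CT volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D grid")


@dataclass
class FollowUpSeries:
    """The unit of prediction: patches, volumes and elapsed days for one nodule."""

    series_id: str
    times: np.ndarray                    # days since first scan, times[0]=0
    patches: np.ndarray                  # (T, S, S, S), values in [0, 1]
    volumes: np.ndarray                  # mm^3 per time point
    label: str | None = None             # {"IA", "non-IA"} or None at inference

    def __len__(self):
        return len(self.times)


def load_nifti(path: str | Path, is_mask: bool = False):
    """Read a NIfTI volume; spacing from the header zooms."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if is_mask:
        return VOIMask(data > 0.5, spacing)
    return CTVolume(data, spacing)


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Read a DICOM series directory, slices sorted by image position."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    image = reader.Execute()
    voxels = sitk.GetArrayFromImage(image).astype(np.float32)  # (z, y, x)
    sx, sy, sz = image.GetSpacing()
    return CTVolume(voxels, (float(sz), float(sy), float(sx)))


def resample_isotropic(vol: CTVolume | VOIMask, target_mm: float = 1.0):
    """Resample to isotropic spacing: trilinear for images, nearest for masks."""
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    is_mask = isinstance(vol, VOIMask)
    factors = [s / target_mm for s in vol.spacing]
    spacing = (target_mm,) * 3
    if np.allclose(factors, 1.0):
        return type(vol)(vol.voxels.copy(), spacing)
    data = vol.voxels.astype(np.float32)
    out = ndimage.zoom(data, factors, order=0 if is_mask else 1,
                       mode="nearest", grid_mode=True)
    if is_mask:
        return VOIMask(out > 0.5, spacing)
    return CTVolume(out, spacing)


def clip_normalize(vol: CTVolume) -> CTVolume:
    """Clip HU to (-1000, 400) and min-max normalize to (0, 1)."""
    out = (np.clip(vol.voxels, HU_MIN, HU_MAX) - HU_MIN) / (HU_MAX - HU_MIN)
    return CTVolume(out.astype(np.float32), vol.spacing)


def mask_volume_mm3(mask: VOIMask,
                    spacing: tuple[float, float, float] | None = None) -> float:
    """VOI volume: foreground voxel count times voxel volume."""
    spacing = spacing or mask.spacing
    count = int(mask.voxels.sum())
    if count == 0:
        raise ValueError("empty VOI")
    return count * float(np.prod(spacing))


def extract_patch(vol: CTVolume, mask: VOIMask,
                  size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Cut a cubic patch centred on the mask centroid; borders pad with 0."""
    if vol.voxels.shape != mask.voxels.shape:
        raise ValueError("volume and mask shapes differ")
    # round half-up so integer translations shift the crop consistently
    centroid = np.floor(np.asarray(ndimage.center_of_mass(mask.voxels))
                        + 0.5).astype(int)
    patch = np.zeros((size,) * 3, dtype=np.float32)
    lo = centroid - size // 2
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(lo + size, vol.voxels.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    patch[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        vol.voxels[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return patch


def _parse_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))


def build_series(scans: list[tuple[object, CTVolume, VOIMask]],
                 label: str | None = None, series_id: str = "",
                 target_mm: float = 1.0,
                 patch_size: int = DEFAULT_PATCH_SIZE) -> FollowUpSeries:
    """Assemble a follow-up series from dated (volume, mask) scans.

    Scans are sorted by acquisition date; a series needs at least two scans,
    and exactly two scans must be at least 30 days apart.  Each scan runs
    through resample -> clip/normalize -> patch extraction, with the VOI
    volume measured on the resampled mask.
    """
    if len(scans) < 2:
        raise ValueError("insufficient time points")
    dated = sorted(((_parse_date(d), v, m) for d, v, m in scans), key=lambda s: s[0])
    dates = [d for d, _, _ in dated]
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate scan dates")
    times = np.array([(d - dates[0]).days for d in dates], dtype=float)
    if len(scans) == 2 and times[1] < MIN_INTERVAL_DAYS:
        raise ValueError("interval below 30 days")
    patches, volumes = [], []
    for _, vol, mask in dated:
        vol_iso = resample_isotropic(vol, target_mm)
        mask_iso = resample_isotropic(mask, target_mm)
        norm = clip_normalize(vol_iso)
        patches.append(extract_patch(norm, mask_iso, patch_size))
        volumes.append(mask_volume_mm3(mask_iso))
    return FollowUpSeries(series_id=series_id, times=times,
                          patches=np.stack(patches),
                          volumes=np.array(volumes), label=label)


def series_from_synthetic(syn, patch_size: int = DEFAULT_PATCH_SIZE,
                          target_mm: float = 1.0) -> FollowUpSeries:
    """Preprocess an in-memory synthetic series (no disk round trip)."""
    patches, volumes = [], []
    for img, msk in zip(syn.images, syn.masks):
        vol_iso = resample_isotropic(CTVolume(img, syn.spacing), target_mm)
        mask_iso = resample_isotropic(VOIMask(msk, syn.spacing), target_mm)
        norm = clip_normalize(vol_iso)
        patches.append(extract_patch(norm, mask_iso, patch_size))
        volumes.append(mask_volume_mm3(mask_iso))
    return FollowUpSeries(series_id=syn.series_id, times=syn.times.copy(),
                          patches=np.stack(patches),
                          volumes=np.array(volumes), label=syn.label)


def series_from_manifest(manifest: pd.DataFrame | str | Path,
                         root: str | Path | None = None,
                         patch_size: int = DEFAULT_PATCH_SIZE,
                         target_mm: float = 1.0,
                         ) -> dict[str, list[FollowUpSeries]]:
    """Load and preprocess every series in a dataset manifest, keyed by split."""
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        root = root if root is not None else path.parent
        manifest = pd.read_csv(path)
    root = Path(root) if root is not None else Path(".")
    out: dict[str, list[FollowUpSeries]] = {}
    for sid, grp in manifest.groupby("series_id", sort=True):
        grp = grp.sort_values("timepoint")
        patches, volumes = [], []
        for _, row in grp.iterrows():
            vol = load_nifti(root / row["image"])
            mask = load_nifti(root / row["mask"], is_mask=True)
            vol_iso = resample_isotropic(vol, target_mm)
            mask_iso = resample_isotropic(mask, target_mm)
            norm = clip_normalize(vol_iso)
            patches.append(extract_patch(norm, mask_iso, patch_size))
            volumes.append(mask_volume_mm3(mask_iso))
        series = FollowUpSeries(series_id=str(sid),
                                times=grp["days"].to_numpy(dtype=float),
                                patches=np.stack(patches),
                                volumes=np.array(volumes),
                                label=str(grp["label"].iloc[0]))
        out.setdefault(str(grp["split"].iloc[0]), []).append(series)
    return out
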