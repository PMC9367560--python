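"""Synthetic follow-up CT series with known growth dynamics and invasiveness.

Real longitudinal nodule cohorts are rarely shareable, so this module renders
spherical nodule phantoms (ground-glass shell, concentric solid core) on a
uniform lung-parenchyma background and grows them over an irregular visit
schedule.  The schedule statistics emulate a clinical follow-up cohort:
series of 2-11 scans, inter-scan gaps of at least 30 days, first-to-last
spans with median ~366 days and a hard ceiling of 2813 days.

Invasiveness ground truth follows the clinical association between fast
volumetric growth / rapid solid transformation and invasive adenocarcinoma
(IA): a series is labelled IA when its intrinsic volume doubling time is
below 400 days or its solid core grows faster than 0.2 fraction/year (for
legacy parameter sets without a modelled speed, a final solid fraction
above one half), plus a small configurable label-noise rate so the
classification task stays non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

# Attenuation constants (HU).  Chosen to sit well inside the preprocessing
# clip window (-1000, 400): uniform parenchyma background, a ground-glass
# shell and a water-attenuation solid core.
BACKGROUND_HU = -850.0
SHELL_HU = -600.0
CORE_HU = 0.0
HU_FLOOR = -1024.0
HU_CEIL = 400.0

# Visit-schedule distribution.  Follow-up intensity varies strongly across
# patients, so each series draws its own gap scale (lognormal, median 45 d,
# sigma 1.3) and individual gaps scatter around it (sigma 0.9), clipped to
# [30, 900] d.  Under 2-11 visits per series this reproduces the target
# first-to-last span statistics (median ~330 d, IQR ~(172, 810), max 2813 d)
# while keeping visit count a poor proxy for elapsed time — growth-rate
# assessment genuinely needs the time stamps.
SCALE_LOG_MEDIAN = np.log(45.0)
SCALE_LOG_SIGMA = 1.3
GAP_LOG_SIGMA = 0.9
GAP_MIN_DAYS = 30.0
GAP_MAX_DAYS = 900.0
SPAN_MAX_DAYS = 2813.0
MIN_POINTS = 2
MAX_POINTS = 11

# Invasiveness label rule.
VDT_FAST_DAYS = 400.0
SOLID_IA_FRACTION = 0.5
DEFAULT_LABEL_NOISE = 0.05

DEFAULT_GRID = (48, 48, 48)
DEFAULT_SPACING = (1.0, 1.0, 1.0)

MANIFEST_COLUMNS = ["series_id", "timepoint", "days", "image", "mask",
                    "volume_mm3", "label", "split"]


@dataclass(frozen=True)
class GrowthParams:
    """Latent growth process of one nodule.

    dt_double is the intrinsic volume doubling time in days (+inf for a
    static nodule); solid0/solid_end are the solid-core volume fractions at
    the first and last scan, linearly interpolated in between.
    """

    model_kind: str = "exponential"      # {"exponential", "gompertz"}
    v0: float = 150.0                    # initial volume, mm^3
    dt_double: float = 365.0             # days
    solid0: float = 0.0
    solid_end: float = 0.0
    noise_sd: float = 30.0               # HU
    background_hu: float = BACKGROUND_HU
    carrying_volume: float = 30000.0     # mm^3, Gompertz plateau
    #: solid-core transformation speed (fraction/year).  When set, the solid
    #: fraction follows clip(solid0 + rate * t/365, 0, 0.95) and the
    #: solid_end field is ignored; when None, the solid fraction
    #: interpolates solid0 -> solid_end linearly over the series.
    solid_rate_per_year: float | None = None

    def __post_init__(self):
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.dt_double <= 0:
            raise ValueError("dt_double must be positive")
        if not 0.0 <= self.solid0 <= self.solid_end <= 1.0:
            raise ValueError("need 0 <= solid0 <= solid_end <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.model_kind not in ("exponential", "gompertz"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


@dataclass
class SyntheticSeries:
    """One simulated follow-up series: schedule, volumes, images, label."""

    series_id: str
    times: np.ndarray                    # days since first scan, times[0]=0
    volumes: np.ndarray                  # mm^3 per time point (as rendered)
    images: list[np.ndarray]             # HU grids
    masks: list[np.ndarray]              # binary grids
    label: str                           # {"IA", "non-IA"}
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    params: GrowthParams | None = None


def sample_growth_params(class_label: str, rng: np.random.Generator) -> GrowthParams:
    """Draw growth parameters conditioned on the intended invasiveness class.

    IA nodules get doubling times log-uniform on [60, 380] days (all
    fast-growing by the 400-day convention) and solid-core end fractions on
    [0.3, 0.9]; non-IA nodules are static with probability 0.3, otherwise
    slow growers (500-2500 days), with solid fractions capped at 0.45.
    """
    if class_label == "IA":
        dt_double = float(np.exp(rng.uniform(np.log(60.0), np.log(380.0))))
        solid_end = float(rng.uniform(0.3, 0.9))
    elif class_label == "non-IA":
        if rng.random() < 0.3:
            dt_double = np.inf
        else:
            dt_double = float(np.exp(rng.uniform(np.log(500.0), np.log(2500.0))))
        solid_end = float(rng.uniform(0.0, 0.45))
    else:
        raise ValueError(f"unknown class label {class_label!r}")
    solid0 = solid_end * float(rng.uniform(0.0, 0.5))
    v0 = float(np.exp(rng.uniform(np.log(50.0), np.log(500.0))))
    return GrowthParams(model_kind="exponential", v0=v0, dt_double=dt_double,
                        solid0=solid0, solid_end=solid_end)


def sample_prior_params(rng: np.random.Generator) -> GrowthParams:
    """Draw growth parameters from the broad cohort prior (class-agnostic).

    Volume doubling time: static with probability 0.3, fast (log-uniform on
    [120, 380] days) with probability 0.15, otherwise a slow grower
    (log-uniform on [450, 2200] days).  Baseline solid fraction uniform on
    [0, 0.6] — stable dense nodules (granuloma-like confusers) are allowed.
    Solid transformation speed: zero with probability 0.25, invasive-fast
    (log-uniform [0.25, 1.0]/year) with probability 0.35, otherwise indolent
    (log-uniform [0.03, 0.18]/year).  Growth and solidification are
    independent.  Invasiveness is carried by per-day dynamics: a fast
    grower looks like a slow one if followed for a tenth of the time, and
    final solidity conflates baseline density with transformation speed —
    so static snapshots and interval-blind sequence reading both leave
    genuine ambiguity that the time stamps resolve.
    """
    u = rng.random()
    if u < 0.3:
        dt_double = np.inf
    elif u < 0.45:
        dt_double = float(np.exp(rng.uniform(np.log(120.0), np.log(380.0))))
    else:
        dt_double = float(np.exp(rng.uniform(np.log(450.0), np.log(2200.0))))
    solid0 = float(rng.uniform(0.0, 0.6))
    w = rng.random()
    if w < 0.25:
        solid_rate = 0.0
    elif w < 0.6:
        solid_rate = float(np.exp(rng.uniform(np.log(0.25), np.log(1.0))))
    else:
        solid_rate = float(np.exp(rng.uniform(np.log(0.03), np.log(0.18))))
    v0 = float(np.exp(rng.uniform(np.log(150.0), np.log(1500.0))))
    return GrowthParams(model_kind="exponential", v0=v0, dt_double=dt_double,
                        solid0=solid0, solid_end=solid0,
                        solid_rate_per_year=solid_rate)


#: Solid transformation faster than this flags invasiveness (fraction/year).
SOLID_RATE_IA_PER_YEAR = 0.2


def label_rule(params: GrowthParams) -> str:
    """IA iff growing fast (doubling < 400 d) or solidifying fast.

    "Solidifying fast" means a solid-core transformation speed above 0.2
    fraction/year when the latent speed is modelled, else a final solid
    fraction above one half.
    """
    fast = params.dt_double < VDT_FAST_DAYS
    if params.solid_rate_per_year is not None:
        solid = params.solid_rate_per_year > SOLID_RATE_IA_PER_YEAR
    else:
        solid = params.solid_end > SOLID_IA_FRACTION
    return "IA" if (fast or solid) else "non-IA"


def volume_at(params: GrowthParams, t_days: float | np.ndarray) -> np.ndarray:
    """Nodule volume at elapsed time t (days) under the growth law."""
    t = np.asarray(t_days, dtype=float)
    if np.isinf(params.dt_double):
        return np.full_like(t, params.v0)
    if params.model_kind == "exponential":
        return params.v0 * 2.0 ** (t / params.dt_double)
    # Gompertz: saturating growth toward carrying_volume, calibrated so the
    # initial specific growth rate matches the exponential law's ln2/dt.
    k = params.carrying_volume
    a0 = np.log(k / params.v0)
    alpha = np.log(2.0) / (params.dt_double * a0)
    return k * np.exp(-a0 * np.exp(-alpha * t))


def sphere_radius(volume_mm3: float) -> float:
    return (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def render_nodule(volume_mm3: float, solid_fraction: float,
                  grid_shape: tuple[int, int, int] = DEFAULT_GRID,
                  noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None,
                  spacing: tuple[float, float, float] = DEFAULT_SPACING,
                  background_hu: float = BACKGROUND_HU,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize a spherical nodule phantom into an HU grid and binary mask.

    The mask is the sphere of the requested volume centred in the grid; the
    image is `background_hu` outside, a ground-glass shell inside, with a
    concentric solid core occupying `solid_fraction` of the nodule volume.
    Gaussian noise (HU) is added and values clipped to [-1024, 400].
    """
    if not 0.0 <= solid_fraction <= 1.0:
        raise ValueError("solid_fraction must lie in [0, 1]")
    r = sphere_radius(volume_mm3)
    extent = [n * s for n, s in zip(grid_shape, spacing)]
    if 2.0 * r >= min(extent):
        raise ValueError("nodule exceeds patch")
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(grid_shape, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = zz ** 2 + yy ** 2 + xx ** 2
    mask = d2 <= r * r
    r_core = r * solid_fraction ** (1.0 / 3.0)
    image = np.full(grid_shape, background_hu, dtype=np.float32)
    image[mask] = SHELL_HU
    image[d2 <= r_core * r_core] = CORE_HU
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        image = image + rng.normal(0.0, noise_sd, grid_shape).astype(np.float32)
    np.clip(image, HU_FLOOR, HU_CEIL, out=image)
    return image, mask.astype(np.uint8)


def sample_schedule(rng: np.random.Generator) -> np.ndarray:
    """Draw an irregular visit schedule (days since first scan, times[0]=0)."""
    n = int(rng.integers(MIN_POINTS, MAX_POINTS + 1))
    scale = rng.lognormal(SCALE_LOG_MEDIAN, SCALE_LOG_SIGMA)
    for _ in range(200):
        gaps = np.clip(rng.lognormal(np.log(scale), GAP_LOG_SIGMA, n - 1),
                       GAP_MIN_DAYS, GAP_MAX_DAYS)
        gaps = np.maximum(np.round(gaps), GAP_MIN_DAYS)
        if gaps.sum() <= SPAN_MAX_DAYS:
            break
    else:  # extremely rare: rescale into range, keeping the 30-day floor
        gaps = np.maximum(np.round(gaps * (SPAN_MAX_DAYS / gaps.sum())),
                          GAP_MIN_DAYS)
        while gaps.sum() > SPAN_MAX_DAYS:   # rounding/floor can overshoot
            i = int(np.argmax(gaps))
            gaps[i] = max(GAP_MIN_DAYS, gaps[i] - (gaps.sum() - SPAN_MAX_DAYS))
    return np.concatenate([[0.0], np.cumsum(gaps)])


def _max_renderable_volume(grid_shape, spacing) -> float:
    extent = min(n * s for n, s in zip(grid_shape, spacing))
    r_max = 0.5 * extent - 1.0       # one-voxel safety margin
    return 4.0 / 3.0 * np.pi * r_max ** 3


#: Per-scan volumetric delineation error (relative SD).  Hand-drawn VOIs
#: carry measurement noise, which is what makes growth rates estimated over
#: short intervals unreliable in practice.
DEFAULT_VOLUME_JITTER = 0.10


@dataclass
class _Kinetics:
    """Latent trajectory of one series before rendering."""

    times: np.ndarray
    volumes: np.ndarray          # true volumes, mm^3
    observed: np.ndarray         # delineated volumes (with jitter), mm^3
    solid: np.ndarray            # solid-core fraction per scan (with jitter)
    label: str


def solid_trajectory(params: GrowthParams, times: np.ndarray) -> np.ndarray:
    """Solid-core fraction at each scan time."""
    t = np.asarray(times, dtype=float)
    if params.solid_rate_per_year is not None:
        return np.clip(params.solid0 + params.solid_rate_per_year * t / 365.0,
                       0.0, 0.95)
    span = t[-1] if t[-1] > 0 else 1.0
    return params.solid0 + (params.solid_end - params.solid0) * t / span


def _sample_kinetics(params: GrowthParams, rng: np.random.Generator,
                     v_cap: float, volume_jitter: float,
                     label_noise: float) -> _Kinetics:
    """Draw a schedule and volume trajectory; truncate follow-up at the cap.

    A nodule that outgrows the largest renderable sphere stops being
    followed (clinically: rapidly growing lesions are resected, not
    observed for years), so the series is truncated to the scans where the
    true volume still fits, always keeping the first two.
    """
    times = sample_schedule(rng)
    volumes = volume_at(params, times)
    keep = max(int(np.sum(volumes <= v_cap)), MIN_POINTS)
    times, volumes = times[:keep], volumes[:keep]
    volumes = np.minimum(volumes, v_cap)     # at most the first kept scan can clip
    if volume_jitter > 0.0:
        jitter = np.clip(rng.normal(0.0, volume_jitter, len(volumes)), -0.3, 0.3)
        observed = np.minimum(volumes * (1.0 + jitter), v_cap)
    else:
        observed = volumes.copy()
    label = label_rule(params)
    if label_noise > 0.0 and rng.random() < label_noise:
        label = "IA" if label == "non-IA" else "non-IA"
    solid = solid_trajectory(params, times)
    if volume_jitter > 0.0:   # delineation error also blurs the core extent
        solid = np.clip(solid + rng.normal(0.0, 0.07, len(solid)), 0.0, 0.95)
    return _Kinetics(times=times, volumes=volumes, observed=observed,
                     solid=solid, label=label)


def _render_series(params: GrowthParams, kin: _Kinetics, rng, series_id,
                   grid_shape, spacing) -> SyntheticSeries:
    images, masks = [], []
    for v, s in zip(kin.observed, kin.solid):
        img, msk = render_nodule(v, float(s), grid_shape, params.noise_sd,
                                 rng, spacing, params.background_hu)
        images.append(img)
        masks.append(msk)
    return SyntheticSeries(series_id=series_id, times=kin.times,
                           volumes=kin.observed, images=images, masks=masks,
                           label=kin.label, spacing=spacing, params=params)


def sample_series(params: GrowthParams, rng: np.random.Generator,
                  series_id: str = "S0000",
                  grid_shape: tuple[int, int, int] = DEFAULT_GRID,
                  spacing: tuple[float, float, float] = DEFAULT_SPACING,
                  label_noise: float = 0.0,
                  volume_jitter: float = 0.0) -> SyntheticSeries:
    """Simulate one follow-up series under `params`.

    Volumes follow the growth law (follow-up truncated once the nodule
    outgrows the grid); the label comes from `label_rule` with an optional
    Bernoulli flip at rate `label_noise`.  `volume_jitter` adds per-scan
    relative delineation error to the rendered volume (never to the label).
    """
    v_cap = _max_renderable_volume(grid_shape, spacing)
    kin = _sample_kinetics(params, rng, v_cap, volume_jitter, label_noise)
    return _render_series(params, kin, rng, series_id, grid_shape, spacing)


def simulate_cohort(n_series: int, ia_fraction: float = 160.0 / 351.0,
                    seed: int | np.random.Generator = 0,
                    label_noise: float = DEFAULT_LABEL_NOISE,
                    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
                    spacing: tuple[float, float, float] = DEFAULT_SPACING,
                    ) -> list[SyntheticSeries]:
    """Simulate a cohort with a fixed IA prevalence (default 160/351).

    Parameters are drawn from the broad cohort prior and labelled by
    `label_rule`; draws are accepted per class until the requested
    prevalence is met exactly (before label noise), so within-class
    diversity is preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ia = int(round(n_series * ia_fraction))
    wanted = {"IA": n_ia, "non-IA": n_series - n_ia}
    classes = np.array(["IA"] * n_ia + ["non-IA"] * (n_series - n_ia))
    rng.shuffle(classes)
    v_cap = _max_renderable_volume(grid_shape, spacing)
    drawn: dict[str, list] = {"IA": [], "non-IA": []}
    while any(len(drawn[c]) < wanted[c] for c in wanted):
        params = sample_prior_params(rng)
        kin = _sample_kinetics(params, rng, v_cap, DEFAULT_VOLUME_JITTER,
                               label_noise)
        if len(drawn[kin.label]) < wanted[kin.label]:
            drawn[kin.label].append((params, kin))
    cohort = []
    for i, cls in enumerate(classes):
        params, kin = drawn[str(cls)].pop()
        cohort.append(_render_series(params, kin, rng, f"S{i:04d}",
                                     grid_shape, spacing))
    return cohort


def assign_splits(labels: list[str] | np.ndarray,
                  split: tuple[float, float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Nodule-level stratified train/validation/test assignment.

    Split sizes use largest-remainder rounding of the requested fractions
    (exact when n*fraction is integral); within each size the assignment is
    stratified by label so both classes appear in every split.
    """
    labels = np.asarray(labels)
    n = len(labels)
    fr = np.asarray(split, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("split fractions must sum to 1")
    target = np.floor(fr * n).astype(int)
    rem = fr * n - target
    for _ in range(n - target.sum()):
        i = int(np.argmax(rem))
        target[i] += 1
        rem[i] = -1.0
    names = np.array(["train", "val", "test"])
    out = np.empty(n, dtype=object)
    order = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        order.append(idx)
    # interleave classes so contiguous blocks are stratified
    interleaved = np.concatenate(order)
    prop = np.concatenate([np.linspace(0, 1, len(ix), endpoint=False) for ix in order])
    interleaved = interleaved[np.argsort(prop, kind="stable")]
    bounds = np.cumsum(target)
    out[interleaved[:bounds[0]]] = "train"
    out[interleaved[bounds[0]:bounds[1]]] = "val"
    out[interleaved[bounds[1]:]] = "test"
    assert all((out == s).sum() == t for s, t in zip(names, target))
    return out.astype(str)


def generate_dataset(out_dir: str | Path, n_series: int = 351,
                     ia_fraction: float = 160.0 / 351.0,
                     split: tuple[float, float, float] = (245 / 351, 37 / 351, 69 / 351),
                     seed: int = 0,
                     label_noise: float = DEFAULT_LABEL_NOISE,
                     grid_shape: tuple[int, int, int] = DEFAULT_GRID,
                     spacing: tuple[float, float, float] = DEFAULT_SPACING,
                     ) -> pd.DataFrame:
    """Write a cohort to disk (NIfTI images + masks, CSV manifest).

    One image/mask pair per time point; the manifest has one row per scan
    with columns series_id,timepoint,days,image,mask,volume_mm3,label,split.
    Splits are assigned at nodule level (all scans of a series share one).
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(n_series, ia_fraction, rng, label_noise,
                             grid_shape, spacing)
    splits = assign_splits([s.label for s in cohort], split, rng)
    affine = np.diag(list(spacing) + [1.0])
    rows = []
    for series, split_name in zip(cohort, splits):
        for k, (img, msk) in enumerate(zip(series.images, series.masks)):
            img_path = out_dir / "images" / f"{series.series_id}_t{k:02d}.nii.gz"
            msk_path = out_dir / "masks" / f"{series.series_id}_t{k:02d}.nii.gz"
            nib.save(nib.Nifti1Image(img, affine), img_path)
            nib.save(nib.Nifti1Image(msk, affine), msk_path)
            rows.append({
                "series_id": series.series_id,
                "timepoint": k,
                "days": float(series.times[k]),
                "image": str(img_path.relative_to(out_dir)),
                "mask": str(msk_path.relative_to(out_dir)),
                "volume_mm3": float(series.volumes[k]),
                "label": series.label,
                "split": split_name,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
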