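"""Synthetic two-class cohort of speckle-textured vessel-wall ROIs.

Each ROI frame emulates a B-mode view of an arterial wall band lying under a
darker lumen band: a rough wall-lumen interface (fractional Brownian
profile), a smooth multiplicative gain field (echo heterogeneity), and
multiplicative speckle built from a Rayleigh envelope smoothed by an
anisotropic Gaussian point-spread kernel.  The frame is rescaled so the
wall-band mean hits the class echo level (plus a per-subject random offset),
then clipped to [0, 255] and rounded.

The abnormal class is darker, more variable, rougher and coarser-grained
than the normal class; the shipped default parameters were calibrated once
so that the two classes reproduce the qualitative feature contrasts a
diseased arterial wall shows against a healthy one (hypoechoic, higher
contrast, more heterogeneous, coarser, more distinctive texture).
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .fbm import fbm_profile
from .image import GrayImage, load_gray_image, save_gray_image
from .texture import FEATURE_NAMES, FeatureConfig, extract_features

NORMAL, ABNORMAL = "normal", "abnormal"
TRAIN, TEST = "train", "test"

#: Fraction of ROI height nominally occupied by the lumen band (above wall).
LUMEN_FRACTION = 0.10
#: Lumen echo level relative to the wall band.
LUMEN_LEVEL = 0.70


@dataclass(frozen=True)
class ClassParams:
    """Image-formation parameters of one class.

    mean_echo
        Target mean gray level of the wall band, 0-255.
    speckle_scale
        Amplitude of the multiplicative speckle: the smoothed Rayleigh
        envelope is normalized to unit mean and its fluctuation is weighted
        by this factor, so 0 removes speckle entirely.
    psf_sigma_ax, psf_sigma_lat
        Axial (row) and lateral (column) sigmas, in pixels, of the Gaussian
        point-spread kernel applied to the raw envelope; they set the
        speckle grain size.
    rough_amp
        Standard deviation, in pixels, of the wall-interface perturbation.
    rough_hurst
        Hurst exponent of the interface profile, in (0, 1); lower = more
        jagged.
    heterogeneity
        Amplitude of the smooth multiplicative gain field (0 = uniform
        insonation).
    """

    mean_echo: float
    speckle_scale: float
    psf_sigma_ax: float
    psf_sigma_lat: float
    rough_amp: float
    rough_hurst: float
    heterogeneity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_echo <= 255.0:
            raise ValueError("mean_echo must lie in [0, 255]")
        if not 0.0 < self.rough_hurst < 1.0:
            raise ValueError("rough_hurst must lie in (0, 1)")
        if self.psf_sigma_ax <= 0 or self.psf_sigma_lat <= 0:
            raise ValueError("PSF sigmas must be positive")
        if self.speckle_scale < 0 or self.rough_amp < 0 or self.heterogeneity < 0:
            raise ValueError("amplitudes must be non-negative")


# Calibrated defaults: the normal wall is bright, finely speckled and smooth;
# the abnormal wall is darker, coarser-grained, rougher and more heterogeneous.
DEFAULT_NORMAL = ClassParams(
    mean_echo=202.0, speckle_scale=0.25, psf_sigma_ax=0.70, psf_sigma_lat=1.00,
    rough_amp=0.5, rough_hurst=0.70, heterogeneity=0.04,
)
DEFAULT_ABNORMAL = ClassParams(
    mean_echo=143.0, speckle_scale=0.72, psf_sigma_ax=0.95, psf_sigma_lat=1.30,
    rough_amp=5.0, rough_hurst=0.30, heterogeneity=0.16,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout and class parameters.

    Defaults reproduce the study design this generator emulates: 15 normal
    and 28 abnormal subjects, 3 ROIs per subject (plus 4 extra abnormal ROIs
    assigned round-robin for 45 + 88 = 133 ROIs), 100 frames per ROI, and a
    train/test split by ROI index (ROI #1 of every subject trains: 43 train,
    90 test).
    """

    n_normal_subjects: int = 15
    n_abnormal_subjects: int = 28
    rois_per_subject: int = 3
    frames_per_roi: int = 100
    roi_height: int = 64
    roi_width: int = 128
    subject_sd: float = 11.0
    texture_jitter: float = 0.25
    seed: int = 0
    split_by: str = "roi"  # "roi" (default) or "subject"
    abnormal_total_rois: int | None = 88
    normal: ClassParams = DEFAULT_NORMAL
    abnormal: ClassParams = DEFAULT_ABNORMAL

    def __post_init__(self) -> None:
        for name in ("n_normal_subjects", "n_abnormal_subjects",
                     "rois_per_subject", "frames_per_roi"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.split_by not in ("roi", "subject"):
            raise ValueError("split_by must be 'roi' or 'subject'")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("normal", "abnormal"):
            if key in d and isinstance(d[key], dict):
                d[key] = ClassParams(**d[key])
        return cls(**d)


@dataclass
class RoiSample:
    """One labeled ROI: a subject, class, train/test role and its frames."""

    subject: str
    label: str
    role: str
    frames: list  # list[GrayImage]


@dataclass
class Cohort:
    samples: list  # list[RoiSample]
    config: CohortConfig | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def counts(self) -> dict[str, int]:
        out = {NORMAL: 0, ABNORMAL: 0, TRAIN: 0, TEST: 0}
        for s in self.samples:
            out[s.label] += 1
            out[s.role] += 1
        return out


# ---------------------------------------------------------------------------
# Frame synthesis
# ---------------------------------------------------------------------------

def _roi_anatomy(
    params: ClassParams, shape: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-ROI structure: interface row per column, and the gain field."""
    h, w = shape
    if params.rough_amp > 0:
        profile = fbm_profile(w, params.rough_hurst, rng) * params.rough_amp
    else:
        rng.normal(size=0)  # keep stream layout independent of rough_amp
        profile = np.zeros(w)
    base_row = LUMEN_FRACTION * h
    interface = np.clip(np.round(base_row + profile), 1, h - 2).astype(int)
    if params.heterogeneity > 0:
        g = gaussian_filter(rng.normal(size=shape), sigma=(h / 3.0, w / 3.0),
                            mode="reflect")
        sd = g.std()
        g = g / sd if sd > 0 else g
        gain = np.clip(1.0 + params.heterogeneity * g, 0.1, None)
    else:
        gain = np.ones(shape)
    return interface, gain


def simulate_roi_frame(
    params: ClassParams,
    subject_offset: float,
    rng: np.random.Generator,
    shape: tuple[int, int] = (64, 128),
    interface: np.ndarray | None = None,
    gain: np.ndarray | None = None,
) -> GrayImage:
    """Synthesize one B-mode-like ROI frame.

    ``interface`` (wall-edge row per column) and ``gain`` may be passed in so
    that repeated frames of one ROI share their anatomy while the speckle is
    redrawn per frame; if omitted they are drawn from ``rng`` first.
    """
    h, w = shape
    if interface is None or gain is None:
        interface, gain = _roi_anatomy(params, shape, rng)
    rows = np.arange(h)[:, None]
    template = np.where(rows >= interface[None, :], 1.0, LUMEN_LEVEL)
    envelope = rng.rayleigh(scale=1.0, size=shape)
    if params.speckle_scale > 0:
        smoothed = gaussian_filter(
            envelope, sigma=(params.psf_sigma_ax, params.psf_sigma_lat),
            mode="reflect",
        )
        speckle = 1.0 + params.speckle_scale * (smoothed / smoothed.mean() - 1.0)
        speckle = np.clip(speckle, 0.0, None)
    else:
        speckle = np.ones(shape)
    img = template * gain * speckle
    wall = rows >= interface[None, :]
    target = params.mean_echo + subject_offset
    wall_mean = img[wall].mean()
    if wall_mean > 0:
        img = img * (max(target, 0.0) / wall_mean)
    return GrayImage(np.clip(np.round(img), 0, 255).astype(np.int64), levels=256)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_params(
    params: ClassParams, rng: np.random.Generator, jitter: float
) -> ClassParams:
    """Per-subject biological variability: log-normal factors on the texture
    amplitudes and scales, and a clipped perturbation of the interface Hurst
    exponent.  ``jitter`` is the relative SD (0 disables)."""
    f = np.exp(rng.normal(0.0, jitter, size=5)) if jitter > 0 else np.ones(5)
    dh = rng.normal(0.0, jitter * 0.5) if jitter > 0 else 0.0
    return ClassParams(
        mean_echo=params.mean_echo,
        speckle_scale=params.speckle_scale * f[0],
        psf_sigma_ax=params.psf_sigma_ax * f[1],
        psf_sigma_lat=params.psf_sigma_lat * f[2],
        rough_amp=params.rough_amp * f[3],
        rough_hurst=float(np.clip(params.rough_hurst + dh, 0.05, 0.95)),
        heterogeneity=params.heterogeneity * f[4],
    )

def _roi_counts(config: CohortConfig, n_subjects: int, label: str) -> list[int]:
    counts = [config.rois_per_subject] * n_subjects
    if label == ABNORMAL and config.abnormal_total_rois is not None:
        extra = config.abnormal_total_rois - sum(counts)
        if extra < 0:
            raise ValueError("abnormal_total_rois below rois_per_subject total")
        for k in range(extra):  # round-robin assignment of the extras
            counts[k % n_subjects] += 1
    return counts


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full labeled cohort; a fixed seed fixes every pixel.

    Each subject receives an independent Gaussian offset (SD
    ``subject_sd``) on its wall echo level; each ROI has its own interface
    profile and gain field shared by all of its frames.
    """
    root = np.random.SeedSequence(config.seed)
    shape = (config.roi_height, config.roi_width)
    samples: list[RoiSample] = []
    groups = [(NORMAL, config.n_normal_subjects, config.normal),
              (ABNORMAL, config.n_abnormal_subjects, config.abnormal)]
    subject_seeds = root.spawn(sum(n for _, n, _ in groups))
    si = 0
    for label, n_subjects, params in groups:
        roi_counts = _roi_counts(config, n_subjects, label)
        for j in range(n_subjects):
            ss = subject_seeds[si]
            si += 1
            subject = f"{label[0]}{j + 1:02d}"
            sub_rng = np.random.default_rng(ss)
            offset = float(sub_rng.normal(0.0, config.subject_sd))
            sparams = _subject_params(params, sub_rng, config.texture_jitter)
            if config.split_by == "subject":
                sub_role = TRAIN if j < max(1, round(n_subjects / 3)) else TEST
            for r in range(roi_counts[j]):
                roi_rng = np.random.default_rng(ss.spawn(1)[0])
                interface, gain = _roi_anatomy(sparams, shape, roi_rng)
                frames = [
                    simulate_roi_frame(sparams, offset, roi_rng, shape,
                                       interface=interface, gain=gain)
                    for _ in range(config.frames_per_roi)
                ]
                if config.split_by == "roi":
                    role = TRAIN if r == 0 else TEST
                else:
                    role = sub_role
                samples.append(RoiSample(subject, label, role, frames))
    return Cohort(samples, config)


# ---------------------------------------------------------------------------
# Feature tables and calibration summary
# ---------------------------------------------------------------------------

def features_table(
    cohort: Cohort, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Per-ROI feature table: subject, class, role, 19 features, degenerate."""
    rows = []
    for s in cohort.samples:
        vec, degen = extract_features(s.frames, config)
        rows.append([s.subject, s.label, s.role, *vec, degen])
    return pd.DataFrame(
        rows, columns=["subject", "class", "role", *FEATURE_NAMES, "degenerate"]
    )


def cohort_class_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean and SD of every feature, computed over ROI rows."""
    out = {}
    for label, grp in features.groupby("class"):
        out[(label, "mean")] = grp[list(FEATURE_NAMES)].mean()
        out[(label, "sd")] = grp[list(FEATURE_NAMES)].std(ddof=1)
    return pd.DataFrame(out)


#: Expected sign of (normal mean - abnormal mean) for the 11 features the
#: screened contrast should separate; +1 means normal is higher.
EXPECTED_SIGNS: dict[str, int] = {
    "AGL": +1, "SD": -1, "CON": -1, "ENE": +1, "ENT": -1, "ASM": +1,
    "COA": -1, "BUS": +1, "COM": -1, "STR": -1, "COV": -1,
}

AGL_WINDOW_NORMAL = (185.0, 210.0)
AGL_WINDOW_ABNORMAL = (120.0, 155.0)


def check_calibration(summary: pd.DataFrame) -> dict[str, bool]:
    """Directional calibration contract of the shipped default parameters.

    Checks that the class-mean AGL of each class falls in its target window
    and that the sign of (normal - abnormal) matches :data:`EXPECTED_SIGNS`
    for all 11 separating features.
    """
    nm = summary[(NORMAL, "mean")]
    am = summary[(ABNORMAL, "mean")]
    checks = {
        "agl_normal_in_window":
            AGL_WINDOW_NORMAL[0] <= nm["AGL"] <= AGL_WINDOW_NORMAL[1],
        "agl_abnormal_in_window":
            AGL_WINDOW_ABNORMAL[0] <= am["AGL"] <= AGL_WINDOW_ABNORMAL[1],
    }
    for feat, sign in EXPECTED_SIGNS.items():
        checks[f"sign_{feat}"] = np.sign(nm[feat] - am[feat]) == sign
    return checks


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir) -> None:
    """Write ``<class>/<subject>/<roi>/<frame>.png`` plus ``manifest.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    roi_index: dict[str, int] = {}
    for s in cohort.samples:
        k = roi_index.get(s.subject, 0)
        roi_index[s.subject] = k + 1
        roi_dir = out / s.label / s.subject / f"roi{k:02d}"
        roi_dir.mkdir(parents=True, exist_ok=True)
        for fi, frame in enumerate(s.frames):
            save_gray_image(frame, roi_dir / f"frame{fi:03d}.png")
        rows.append([s.subject, s.label, s.role,
                     str(roi_dir.relative_to(out)), len(s.frames)])
    with open(out / "manifest.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["subject", "class", "role", "path", "n_frames"])
        wr.writerows(rows)
    if cohort.config is not None:
        cohort.config.to_yaml(out / "config.yaml")


def load_cohort(in_dir) -> Cohort:
    root = Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        roi_dir = root / row["path"]
        frames = [load_gray_image(p) for p in sorted(roi_dir.glob("frame*.png"))]
        samples.append(RoiSample(str(row["subject"]), row["class"], row["role"],
                                 frames))
    cfg_path = root / "config.yaml"
    config = CohortConfig.from_yaml(cfg_path) if cfg_path.exists() else None
    return Cohort(samples, config)
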