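"""Six texture-feature families for gray-level ROI analysis.

The 19 features, in their fixed column order, are

====== ======================================================================
family features
====== ======================================================================
FOS    AGL (average gray level), SD (gray-level standard deviation)
FDTA   Df (fractal dimension from the Hurst exponent of the intensity surface)
SGLDM  CON, COR, ENE, HOM, ENT  (gray-level co-occurrence statistics, d = 1,
       averaged over the four principal angles)
GLDS   CON1, ASM, ENT1, MEAN    (absolute gray-level difference statistics at
       displacements (0,3), (3,3), (3,0), (3,-3), averaged)
NGTDM  COA, CON2, BUS, COM, STR (neighborhood gray-tone difference measures:
       coarseness, contrast, busyness, complexity, strength; d = 2)
SFM    CON3, COV                (statistical feature matrix: normalized
       root-contrast and normalized covariance over unit lags, averaged)
====== ======================================================================

All entropies use the base-10 logarithm.  Displacement vectors are written
``(dx, dy)`` with x = column and y = row, matching the image convention in
:mod:`vastex.image`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .image import GrayImage, quantize

FEATURE_NAMES: tuple[str, ...] = (
    "AGL", "SD", "Df",
    "CON", "COR", "ENE", "HOM", "ENT",
    "CON1", "ASM", "ENT1", "MEAN",
    "COA", "CON2", "BUS", "COM", "STR",
    "CON3", "COV",
)

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "FOS": ("AGL", "SD"),
    "FDTA": ("Df",),
    "SGLDM": ("CON", "COR", "ENE", "HOM", "ENT"),
    "GLDS": ("CON1", "ASM", "ENT1", "MEAN"),
    "NGTDM": ("COA", "CON2", "BUS", "COM", "STR"),
    "SFM": ("CON3", "COV"),
}

#: Guard added to reciprocal denominators in the NGTDM measures.
NGTDM_EPS = 1e-8

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLDS_DISPLACEMENTS: tuple[tuple[int, int], ...] = ((0, 3), (3, 3), (3, 0), (3, -3))
SFM_LAGS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))


@dataclass(frozen=True)
class FeatureConfig:
    """Per-family gray-level quantization and geometry settings.

    Co-occurrence-type statistics at the full 8-bit depth are sparse on small
    ROIs, so SGLDM/GLDS/NGTDM default to 64 levels; FOS, FDTA and SFM operate
    on the image as given.  ``None`` disables re-quantization for a family.
    """

    levels_sgldm: int | None = 64
    levels_glds: int | None = 64
    levels_ngtdm: int | None = 64
    sgldm_d: int = 1
    ngtdm_d: int = 2


def _maybe_quantize(image: GrayImage, levels: int | None) -> GrayImage:
    if levels is None or levels >= image.levels:
        return image
    return quantize(image, levels)


# ---------------------------------------------------------------------------
# FOS
# ---------------------------------------------------------------------------

def fos_features(image: GrayImage) -> tuple[float, float]:
    """First-order statistics of the gray-level histogram.

    Returns ``(AGL, SD)``: the histogram mean Σ i·p_i and the population
    standard deviation around it.
    """
    arr = image.astype_float()
    agl = float(arr.mean())
    sd = float(arr.std())
    return agl, sd


# ---------------------------------------------------------------------------
# FDTA: Hurst exponent and fractal dimension
# ---------------------------------------------------------------------------

def _block_average(arr: np.ndarray, w: int) -> np.ndarray:
    if w == 1:
        return arr
    h, wd = arr.shape
    h2, w2 = (h // w) * w, (wd // w) * w
    a = arr[:h2, :w2].reshape(h2 // w, w, w2 // w, w)
    return a.mean(axis=(1, 3))


def _mean_abs_diff(arr: np.ndarray, r: int) -> float:
    """Mean |I(p) - I(q)| over all horizontal and vertical pairs at distance r."""
    dh = np.abs(arr[:, :-r] - arr[:, r:])
    dv = np.abs(arr[:-r, :] - arr[r:, :])
    return float((dh.sum() + dv.sum()) / (dh.size + dv.size))


def estimate_hurst(arr: np.ndarray, max_distance: int = 8) -> float:
    """Hurst exponent: least-squares slope of log E|ΔI| vs log r, r = 1..8.

    For a fractional-Brownian intensity surface E|I(p) - I(q)| grows as
    ``r^H`` with r the pixel distance; axis-aligned pairs give exact integer
    distances.  Distances with zero mean difference are excluded; if fewer
    than two usable distances remain the surface is treated as perfectly
    smooth (H = 1).
    """
    rmax = min(max_distance, min(arr.shape) - 1)
    if rmax < 2:
        raise ValueError("image too small: need at least 2 distinct pair distances")
    rs, mbds = [], []
    for r in range(1, rmax + 1):
        m = _mean_abs_diff(arr, r)
        if m > 0:
            rs.append(r)
            mbds.append(m)
    if len(rs) < 2:
        return 1.0  # constant/degenerate surface: smooth limit
    slope = np.polyfit(np.log(rs), np.log(mbds), 1)[0]
    return float(slope)


def hurst_and_fractal(
    image: GrayImage, resolutions: tuple[int, ...] = (1, 2, 3)
) -> tuple[dict[int, float], float]:
    """Multiresolution Hurst exponents and the fractal dimension.

    The image is block-averaged by each factor ``w`` and the Hurst exponent
    estimated at that resolution.  The fractal dimension is taken from the
    full-resolution exponent, ``Df = 3 - H(1)``, clipped to the admissible
    surface range [2, 3]; the coarser-resolution exponents are diagnostics.
    """
    arr = image.astype_float()
    hs: dict[int, float] = {}
    for w in resolutions:
        sub = _block_average(arr, w)
        hs[w] = estimate_hurst(sub)
    df = float(np.clip(3.0 - hs[min(resolutions)], 2.0, 3.0))
    return hs, df


# ---------------------------------------------------------------------------
# SGLDM: spatial gray-level dependence (co-occurrence) matrix
# ---------------------------------------------------------------------------

def cooccurrence_matrix(image: GrayImage, d: int = 1, theta: int = 0) -> np.ndarray:
    """Symmetric gray-level co-occurrence matrix P(i, j; d, θ), sum = 1.

    Ordered pairs are counted in both the +θ and −θ directions, so the
    matrix is symmetric.  θ must be one of 0, 45, 90, 135 degrees; θ = 0 is
    the horizontal direction and angles increase counterclockwise.
    """
    if theta not in _ANGLE_OFFSETS:
        raise ValueError(f"theta must be one of {sorted(_ANGLE_OFFSETS)}, got {theta}")
    dr, dc = (o * d for o in _ANGLE_OFFSETS[theta])
    arr = image.pixels
    h, w = arr.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"no valid pixel pairs for d={d}, theta={theta}")
    a = arr[r0:r1, c0:c1].ravel()
    b = arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    L = image.levels
    counts = np.bincount(a * L + b, minlength=L * L)
    counts += np.bincount(b * L + a, minlength=L * L)
    mat = counts.reshape(L, L).astype(np.float64)
    return mat / mat.sum()


def _sgldm_from_matrix(P: np.ndarray) -> tuple[float, float, float, float, float]:
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    diff = i[:, None] - i[None, :]
    con = float(np.sum(diff * diff * P))
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x, mu_y = float(i @ px), float(i @ py)
    sig_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sig_y = float(np.sqrt(((i - mu_y) ** 2) @ py))
    if sig_x * sig_y == 0.0:
        warnings.warn("constant image: SGLDM correlation undefined, returning 0")
        cor = 0.0
    else:
        cor = float((np.sum(np.outer(i, i) * P) - mu_x * mu_y) / (sig_x * sig_y))
    ene = float(np.sum(P * P))
    hom = float(np.sum(P / (1.0 + np.abs(diff))))
    nz = P[P > 0]
    ent = float(-np.sum(nz * np.log10(nz)))
    return con, cor, ene, hom, ent


def sgldm_features(
    image: GrayImage,
    d: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> tuple[float, float, float, float, float]:
    """Co-occurrence contrast, correlation, energy, homogeneity and entropy.

    Each measure is computed per angle from the symmetric co-occurrence
    matrix and collapsed to a single value by the unweighted mean over the
    requested angles.
    """
    vals = np.array([_sgldm_from_matrix(cooccurrence_matrix(image, d, t)) for t in angles])
    return tuple(float(v) for v in vals.mean(axis=0))


# ---------------------------------------------------------------------------
# GLDS: gray-level difference statistics
# ---------------------------------------------------------------------------

def _shifted_pair(arr: np.ndarray, dx: int, dy: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views A(x, y), B(x+dx, y+dy); x = column, y = row."""
    h, w = arr.shape
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"displacement ({dx}, {dy}) leaves no pixel pairs")
    a = arr[r0:r1, c0:c1]
    b = arr[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    return a, b


def glds_features(
    image: GrayImage,
    displacements: tuple[tuple[int, int], ...] = GLDS_DISPLACEMENTS,
) -> tuple[float, float, float, float]:
    """Absolute gray-level difference statistics, averaged over displacements.

    For each displacement the probability vector f(i) of |I(x,y) −
    I(x+dx,y+dy)| is formed and summarized as contrast Σ i²f(i), angular
    second moment Σ f(i)², entropy −Σ f(i)·log10 f(i), and the L-normalized
    mean (1/L)·Σ i·f(i).
    """
    L = image.levels
    i = np.arange(L, dtype=np.float64)
    out = np.zeros((len(displacements), 4))
    for k, (dx, dy) in enumerate(displacements):
        a, b = _shifted_pair(image.pixels, dx, dy)
        diffs = np.abs(a - b).ravel()
        f = np.bincount(diffs, minlength=L).astype(np.float64)
        f /= f.sum()
        nz = f[f > 0]
        out[k] = (
            float((i * i) @ f),
            float(f @ f),
            float(-np.sum(nz * np.log10(nz))),
            float((i @ f) / L),
        )
    return tuple(float(v) for v in out.mean(axis=0))


# ---------------------------------------------------------------------------
# NGTDM: neighborhood gray-tone difference matrix
# ---------------------------------------------------------------------------

def ngtdm(
    image: GrayImage, d: int = 2
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Neighborhood gray-tone difference matrix s(i) plus occupancy data.

    For every interior pixel (margin ``d``) the average of the surrounding
    ``(2d+1)² − 1`` pixels (center excluded) is subtracted from the pixel
    value; s(i) sums these absolute deviations per gray level i.  Returns
    ``(s, p, n_levels, n_interior)`` where p(i) is the occurrence fraction of
    level i among the ``(H−2d)·(W−2d)`` interior pixels and ``n_levels`` is
    the number of distinct levels present there.
    """
    h, w = image.shape
    if h < 2 * d + 1 or w < 2 * d + 1:
        raise ValueError(f"image {h}x{w} too small for NGTDM with d={d}")
    arr = image.astype_float()
    k = 2 * d + 1
    total = uniform_filter(arr, size=k, mode="constant") * (k * k)
    nbr_mean = (total - arr) / (k * k - 1)
    interior = slice(d, h - d), slice(d, w - d)
    levels = image.pixels[interior].ravel()
    dev = np.abs(arr[interior] - nbr_mean[interior]).ravel()
    L = image.levels
    s = np.bincount(levels, weights=dev, minlength=L)
    counts = np.bincount(levels, minlength=L).astype(np.float64)
    n_interior = levels.size
    p = counts / n_interior
    n_levels = int(np.count_nonzero(counts))
    return s, p, n_levels, n_interior


def ngtdm_features(
    s: np.ndarray, p: np.ndarray, n_levels: int, n_interior: int
) -> tuple[float, float, float, float, float, bool]:
    """Coarseness, contrast, busyness, complexity and strength from an NGTDM.

    Pairwise sums run over gray levels actually present (p > 0).  With a
    single present level contrast, busyness, complexity and strength are
    undefined and returned as 0 with the degenerate flag set; coarseness then
    saturates at 1/ε.
    """
    psum = float(p @ s)
    coa = 1.0 / (NGTDM_EPS + psum)
    if n_levels <= 1:
        return coa, 0.0, 0.0, 0.0, 0.0, True
    idx = np.flatnonzero(p)
    pi, si = p[idx], s[idx]
    iv = idx.astype(np.float64)
    diff = iv[:, None] - iv[None, :]
    diff2 = diff * diff
    con2 = float(
        (np.sum(np.outer(pi, pi) * diff2) / (n_levels * (n_levels - 1)))
        * (s.sum() / n_interior)
    )
    ipi = iv * pi
    denom_bus = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
    bus = psum / denom_bus if denom_bus > 0 else 0.0
    ps = pi * si
    com = float(
        np.sum(np.abs(diff) / (n_interior * (pi[:, None] + pi[None, :]))
               * (ps[:, None] + ps[None, :]))
    )
    strength = float(np.sum((pi[:, None] + pi[None, :]) * diff2) / (NGTDM_EPS + s.sum()))
    return coa, con2, float(bus), com, strength, False


# ---------------------------------------------------------------------------
# SFM: statistical feature matrix
# ---------------------------------------------------------------------------

def sfm_features(
    image: GrayImage,
    lags: tuple[tuple[int, int], ...] = SFM_LAGS,
) -> tuple[float, float, bool]:
    """Normalized contrast and covariance over a set of small lags.

    Per lag δ, contrast(δ) = E[(I(p) − I(p+δ))²] and the normalized
    covariance is the Pearson correlation of the two aligned pixel sets.
    CON3 averages sqrt(contrast(δ)) / SD(image) over lags (dimensionless);
    COV averages the correlations.  A zero-variance image sets the
    degenerate flag and returns zeros.
    """
    arr = image.astype_float()
    sd = arr.std()
    if sd == 0:
        return 0.0, 0.0, True
    cons, covs = [], []
    for dx, dy in lags:
        a, b = _shifted_pair(arr, dx, dy)
        diff = a - b
        cons.append(np.sqrt(np.mean(diff * diff)) / sd)
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            covs.append(0.0)
        else:
            covs.append(float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)))
    return float(np.mean(cons)), float(np.mean(covs)), False


# ---------------------------------------------------------------------------
# Full 19-feature vector
# ---------------------------------------------------------------------------

def frame_features(
    image: GrayImage, config: FeatureConfig | None = None
) -> tuple[np.ndarray, bool]:
    """All 19 features of a single frame, in :data:`FEATURE_NAMES` order."""
    cfg = config or FeatureConfig()
    agl, sd = fos_features(image)
    _, df = hurst_and_fractal(image, resolutions=(1,))
    degenerate = sd == 0.0
    with warnings.catch_warnings():
        if degenerate:
            warnings.simplefilter("ignore")
        con, cor, ene, hom, ent = sgldm_features(
            _maybe_quantize(image, cfg.levels_sgldm), d=cfg.sgldm_d
        )
    con1, asm, ent1, mean = glds_features(_maybe_quantize(image, cfg.levels_glds))
    s, p, n_levels, n_int = ngtdm(_maybe_quantize(image, cfg.levels_ngtdm), d=cfg.ngtdm_d)
    coa, con2, bus, com, strength, ngtdm_degen = ngtdm_features(s, p, n_levels, n_int)
    con3, cov, sfm_degen = sfm_features(image)
    vec = np.array([
        agl, sd, df,
        con, cor, ene, hom, ent,
        con1, asm, ent1, mean,
        coa, con2, bus, com, strength,
        con3, cov,
    ])
    return vec, bool(degenerate or ngtdm_degen or sfm_degen)


def extract_features(
    frames, config: FeatureConfig | None = None
) -> tuple[np.ndarray, bool]:
    """ROI-level feature vector: per-frame features averaged across frames.

    ``frames`` is a non-empty iterable of :class:`GrayImage`; the degenerate
    flag is the OR over frames.
    """
    vecs, flags = [], []
    for fr in frames:
        v, flag = frame_features(fr, config)
        vecs.append(v)
        flags.append(flag)
    if not vecs:
        raise ValueError("extract_features requires at least one frame")
    return np.mean(vecs, axis=0), bool(any(flags))
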