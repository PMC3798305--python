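"""Independent brute-force reference implementations of every texture feature.

These are deliberately written as explicit Python double loops over pixels
and gray levels, sharing no code with the package, so that agreement with
the vectorized implementations is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-8
ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def fos_oracle(img: np.ndarray) -> tuple[float, float]:
    vals = [float(v) for row in img for v in row]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    return mean, math.sqrt(var)


def glcm_oracle(img: np.ndarray, levels: int, d: int, theta: int) -> np.ndarray:
    dr, dc = ANGLE_STEPS[theta]
    dr, dc = dr * d, dc * d
    h, w = img.shape
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            for sr, sc in ((dr, dc), (-dr, -dc)):
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < h and 0 <= c2 < w:
                    mat[img[r, c], img[r2, c2]] += 1
    return mat / mat.sum()


def sgldm_oracle(img: np.ndarray, levels: int, d: int = 1,
                 angles=(0, 45, 90, 135)) -> tuple[float, ...]:
    per_angle = []
    for theta in angles:
        P = glcm_oracle(img, levels, d, theta)
        con = ene = hom = ent = 0.0
        px = [sum(P[i][j] for j in range(levels)) for i in range(levels)]
        py = [sum(P[i][j] for i in range(levels)) for j in range(levels)]
        mux = sum(i * px[i] for i in range(levels))
        muy = sum(j * py[j] for j in range(levels))
        sx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(levels)))
        sy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(levels)))
        cross = 0.0
        for i in range(levels):
            for j in range(levels):
                p = P[i][j]
                con += (i - j) ** 2 * p
                ene += p * p
                hom += p / (1 + abs(i - j))
                if p > 0:
                    ent -= p * math.log10(p)
                cross += i * j * p
        cor = 0.0 if sx * sy == 0 else (cross - mux * muy) / (sx * sy)
        per_angle.append((con, cor, ene, hom, ent))
    return tuple(sum(v[k] for v in per_angle) / len(per_angle) for k in range(5))


def glds_oracle(img: np.ndarray, levels: int,
                displacements=((0, 3), (3, 3), (3, 0), (3, -3))) -> tuple[float, ...]:
    h, w = img.shape
    per = []
    for dx, dy in displacements:
        counts = [0] * levels
        total = 0
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dy, c + dx
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[abs(int(img[r, c]) - int(img[r2, c2]))] += 1
                    total += 1
        f = [cnt / total for cnt in counts]
        con = sum(i * i * f[i] for i in range(levels))
        asm = sum(fi * fi for fi in f)
        ent = -sum(fi * math.log10(fi) for fi in f if fi > 0)
        mean = sum(i * f[i] for i in range(levels)) / levels
        per.append((con, asm, ent, mean))
    return tuple(sum(v[k] for v in per) / len(per) for k in range(4))


def ngtdm_oracle(img: np.ndarray, levels: int, d: int = 2):
    h, w = img.shape
    s = [0.0] * levels
    occ = [0] * levels
    n_int = 0
    for r in range(d, h - d):
        for c in range(d, w - d):
            tot = 0.0
            cnt = 0
            for rr in range(r - d, r + d + 1):
                for cc in range(c - d, c + d + 1):
                    if (rr, cc) != (r, c):
                        tot += img[rr, cc]
                        cnt += 1
            i = int(img[r, c])
            s[i] += abs(i - tot / cnt)
            occ[i] += 1
            n_int += 1
    p = [o / n_int for o in occ]
    ng = sum(1 for o in occ if o)
    return s, p, ng, n_int


def ngtdm_features_oracle(s, p, ng, n_int) -> tuple[float, ...]:
    levels = len(s)
    psum = sum(p[i] * s[i] for i in range(levels))
    coa = 1.0 / (EPS + psum)
    if ng <= 1:
        return coa, 0.0, 0.0, 0.0, 0.0
    present = [i for i in range(levels) if p[i] > 0]
    con2 = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ng * (ng - 1))) * (sum(s) / n_int)
    denom = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
    bus = psum / denom if denom > 0 else 0.0
    com = sum(abs(i - j) / (n_int * (p[i] + p[j])) * (p[i] * s[i] + p[j] * s[j])
              for i in present for j in present)
    strength = sum((p[i] + p[j]) * (i - j) ** 2 for i in present
                   for j in present) / (EPS + sum(s))
    return coa, con2, bus, com, strength


def sfm_oracle(img: np.ndarray,
               lags=((1, 0), (0, 1), (1, 1), (1, -1))) -> tuple[float, float]:
    h, w = img.shape
    flat = [float(v) for row in img for v in row]
    mean = sum(flat) / len(flat)
    sd = math.sqrt(sum((v - mean) ** 2 for v in flat) / len(flat))
    if sd == 0:
        return 0.0, 0.0
    cons, covs = [], []
    for dx, dy in lags:
        pa, pb = [], []
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dy, c + dx
                if 0 <= r2 < h and 0 <= c2 < w:
                    pa.append(float(img[r, c]))
                    pb.append(float(img[r2, c2]))
        n = len(pa)
        contrast = sum((a - b) ** 2 for a, b in zip(pa, pb)) / n
        ma, mb = sum(pa) / n, sum(pb) / n
        sa = math.sqrt(sum((a - ma) ** 2 for a in pa) / n)
        sb = math.sqrt(sum((b - mb) ** 2 for b in pb) / n)
        if sa == 0 or sb == 0:
            covs.append(0.0)
        else:
            covs.append(sum((a - ma) * (b - mb) for a, b in zip(pa, pb)) / n
                        / (sa * sb))
        cons.append(math.sqrt(contrast) / sd)
    return sum(cons) / len(cons), sum(covs) / len(covs)


def hurst_oracle(arr: np.ndarray, max_distance: int = 8) -> float:
    h, w = arr.shape
    rmax = min(max_distance, min(h, w) - 1)
    rs, mbds = [], []
    for r in range(1, rmax + 1):
        tot = 0.0
        cnt = 0
        for i in range(h):
            for j in range(w):
                if j + r < w:
                    tot += abs(arr[i, j] - arr[i, j + r])
                    cnt += 1
                if i + r < h:
                    tot += abs(arr[i, j] - arr[i + r, j])
                    cnt += 1
        m = tot / cnt
        if m > 0:
            rs.append(r)
            mbds.append(m)
    if len(rs) < 2:
        return 1.0
    lx = [math.log(r) for r in rs]
    ly = [math.log(m) for m in mbds]
    n = len(lx)
    mx, my = sum(lx) / n, sum(ly) / n
    return (sum((x - mx) * (y - my) for x, y in zip(lx, ly))
            / sum((x - mx) ** 2 for x in lx))


def block_average_oracle(arr: np.ndarray, w: int) -> np.ndarray:
    h, wd = arr.shape
    out = np.zeros((h // w, wd // w))
    for i in range(h // w):
        for j in range(wd // w):
            out[i, j] = arr[i * w:(i + 1) * w, j * w:(j + 1) * w].mean()
    return out


def fractal_oracle(img: np.ndarray) -> float:
    hh = hurst_oracle(img.astype(float))
    return min(3.0, max(2.0, 3.0 - hh))


def full_vector_oracle(img: np.ndarray, levels: int) -> list[float]:
    """All 19 features at the image's own gray-level count (no requantization)."""
    agl, sd = fos_oracle(img)
    df = fractal_oracle(img)
    sgldm = sgldm_oracle(img, levels)
    glds = glds_oracle(img, levels)
    s, p, ng, n_int = ngtdm_oracle(img, levels)
    ngt = ngtdm_features_oracle(s, p, ng, n_int)
    sfm = sfm_oracle(img)
    return [agl, sd, df, *sgldm, *glds, *ngt, *sfm]
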