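"""Voxel-wise texture bank over the primary treated tumour sub-volume.

Six operator families are computed per 2D section of the analysed
sub-volume (section thickness is ~5x the in-plane resolution, so 2D
neighbourhoods are the appropriate support):

====================  =====  =========================================
family                maps   content
====================  =====  =========================================
histogram             21     7 local first-order statistics x windows {3,5,7}
gradient              10     finite differences, Sobel, Laplacian, Kirsch
haralick              65     13 grey-level co-occurrence statistics x
                             windows {3,5,7,9,11}
gabor                 35     5 wavelengths x 6 orientations, plus the
                             per-wavelength orientation maximum
laws                  34     all 3x3 (L3/E3/S3) and 5x5 (L5/E5/S5/W5/R5)
                             separable energy kernels
collage               26     13 co-occurrence statistics of the dominant
                             local gradient-orientation image x windows
                             {3,5}
====================  =====  =========================================

for 191 maps total; summarizing each map with 4 first-order statistics
(mean, variance, skewness, excess kurtosis) over the ROI yields the 764
texture features per case.

Voxels outside the wall ROI are filled with their nearest in-ROI value
before any filtering so that responses at the ROI border are not
contaminated by lumen or perirectal intensities; co-occurrence pairs are
additionally restricted to pixel pairs that both lie inside the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.stats import kurtosis as _kurtosis, skew as _skew

from .io import Mask, StudyCase, Volume, select_primary_subvolume

HARALICK_STATS = (
    "sum_avg", "contrast", "correlation", "entropy", "energy",
    "homogeneity", "sum_var", "sum_entropy", "diff_var", "diff_entropy",
    "info_corr1", "info_corr2", "idm",
)
HISTOGRAM_STATS = ("mean", "median", "std", "range", "min", "max", "iqr")
GRADIENT_OPS = ("dx", "dy", "magnitude", "orientation", "sobel_x", "sobel_y",
                "sobel_xy", "sobel_yx", "laplacian", "kirsch_max")
LAWS_3 = {"L3": [1, 2, 1], "E3": [-1, 0, 1], "S3": [-1, 2, -1]}
LAWS_5 = {"L5": [1, 4, 6, 4, 1], "E5": [-1, -2, 0, 2, 1],
          "S5": [-1, 0, 2, 0, -1], "W5": [-1, 2, 0, -2, 1],
          "R5": [1, -4, 6, -4, 1]}


@dataclass(frozen=True)
class TextureBankConfig:
    """Configuration of the texture bank; defaults yield exactly 191 maps."""

    families: tuple[str, ...] = ("histogram", "gradient", "haralick",
                                 "gabor", "laws", "collage")
    histogram_windows: tuple[int, ...] = (3, 5, 7)
    haralick_windows: tuple[int, ...] = (3, 5, 7, 9, 11)
    gray_levels: int = 64
    #: default wavelengths and their kernel window sizes; the 0.128 entry
    #: breaks the ascending order of the set but is retained verbatim from
    #: the reference descriptor bank (configurable)
    gabor_lambdas: tuple[float, ...] = (0.765, 0.128, 1.786, 2.296, 2.806)
    gabor_windows: tuple[int, ...] = (3, 5, 7, 9, 11)
    gabor_thetas: tuple[float, ...] = tuple(np.pi * k / 8 for k in (1, 2, 3, 4, 5, 6))
    gabor_orientation_max: bool = True
    collage_windows: tuple[int, ...] = (3, 5)
    collage_bins: int = 8
    summary_stats: tuple[str, ...] = ("mean", "variance", "skewness", "kurtosis")

    def map_names(self) -> list[str]:
        names: list[str] = []
        if "histogram" in self.families:
            names += [f"histogram.{s}.ws{w}" for s in HISTOGRAM_STATS
                      for w in self.histogram_windows]
        if "gradient" in self.families:
            names += [f"gradient.{op}" for op in GRADIENT_OPS]
        if "haralick" in self.families:
            names += [f"haralick.{s}.ws{w}" for s in HARALICK_STATS
                      for w in self.haralick_windows]
        if "gabor" in self.families:
            for i, lam in enumerate(self.gabor_lambdas):
                names += [f"gabor.l{lam}.t{k + 1}"
                          for k in range(len(self.gabor_thetas))]
                if self.gabor_orientation_max:
                    names.append(f"gabor.l{lam}.max")
        if "laws" in self.families:
            names += [f"laws.{a}{b}" for a in LAWS_3 for b in LAWS_3]
            names += [f"laws.{a}{b}" for a in LAWS_5 for b in LAWS_5]
        if "collage" in self.families:
            names += [f"collage.{s}.ws{w}" for s in HARALICK_STATS
                      for w in self.collage_windows]
        return names

    def feature_names(self) -> list[str]:
        return [f"{m}.{s}" for m in self.map_names() for s in self.summary_stats]


DEFAULT_CONFIG = TextureBankConfig()


# ---------------------------------------------------------------------------
# Sliding-window co-occurrence statistics (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _glcm_stats_section(q, roi, ws, G, out):  # pragma: no cover - jitted
    """13 co-occurrence statistics in a ws x ws window around every ROI
    pixel of one section.  ``q`` holds integer levels 1..G; co-occurrences
    pool the 4 in-plane unit offsets, symmetrized, and only count pairs
    with both pixels inside the ROI and the window."""
    nx, ny = q.shape
    h = ws // 2
    glcm = np.zeros((G, G), dtype=np.float64)
    touched = np.empty((2 * ws * ws * 4, 2), dtype=np.int64)
    px = np.zeros(G)
    py = np.zeros(G)
    psum = np.zeros(2 * G - 1)
    pdiff = np.zeros(G)
    offs = np.array([[1, 0], [0, 1], [1, 1], [1, -1]], dtype=np.int64)
    log2 = np.log(2.0)
    for i in range(nx):
        for j in range(ny):
            if not roi[i, j]:
                continue
            i0, i1 = max(i - h, 0), min(i + h, nx - 1)
            j0, j1 = max(j - h, 0), min(j + h, ny - 1)
            ntouch = 0
            total = 0.0
            for a in range(i0, i1 + 1):
                for b in range(j0, j1 + 1):
                    if not roi[a, b]:
                        continue
                    g1 = q[a, b] - 1
                    for o in range(4):
                        c, d = a + offs[o, 0], b + offs[o, 1]
                        if c < i0 or c > i1 or d < j0 or d > j1:
                            continue
                        if not roi[c, d]:
                            continue
                        g2 = q[c, d] - 1
                        if glcm[g1, g2] == 0.0:
                            touched[ntouch, 0] = g1
                            touched[ntouch, 1] = g2
                            ntouch += 1
                        glcm[g1, g2] += 1.0
                        if glcm[g2, g1] == 0.0:
                            touched[ntouch, 0] = g2
                            touched[ntouch, 1] = g1
                            ntouch += 1
                        glcm[g2, g1] += 1.0
                        total += 2.0
            if total == 0.0:
                # isolated pixel: degenerate single-cell distribution
                g1 = q[i, j] - 1
                glcm[g1, g1] = 2.0
                touched[0, 0] = g1
                touched[0, 1] = g1
                ntouch = 1
                total = 2.0
            # marginals
            for g in range(G):
                px[g] = 0.0
                py[g] = 0.0
                pdiff[g] = 0.0
            for s in range(2 * G - 1):
                psum[s] = 0.0
            mu_x = 0.0
            mu_y = 0.0
            sx2 = 0.0
            sy2 = 0.0
            sum_avg = 0.0
            contrast = 0.0
            corr_acc = 0.0
            energy = 0.0
            entropy = 0.0
            homog = 0.0
            idm = 0.0
            for t in range(ntouch):
                gi, gj = touched[t, 0], touched[t, 1]
                p = glcm[gi, gj] / total
                li, lj = gi + 1.0, gj + 1.0
                mu_x += li * p
                mu_y += lj * p
                sx2 += li * li * p
                sy2 += lj * lj * p
                sum_avg += (li + lj) * p
                contrast += (li - lj) * (li - lj) * p
                corr_acc += li * lj * p
                energy += p * p
                entropy -= p * np.log(p) / log2
                ad = abs(gi - gj)
                homog += p / (1.0 + ad)
                idm += p / (1.0 + ad * ad)
                px[gi] += p
                py[gj] += p
                psum[gi + gj] += p
                pdiff[ad] += p
            var_x = sx2 - mu_x * mu_x
            var_y = sy2 - mu_y * mu_y
            if var_x > 1e-12 and var_y > 1e-12:
                correlation = (corr_acc - mu_x * mu_y) / np.sqrt(var_x * var_y)
            else:
                correlation = 0.0
            sum_var = 0.0
            sum_ent = 0.0
            for s in range(2 * G - 1):
                ps = psum[s]
                if ps > 0.0:
                    sv = (s + 2.0) - sum_avg
                    sum_var += sv * sv * ps
                    sum_ent -= ps * np.log(ps) / log2
            mean_d = 0.0
            for d0 in range(G):
                mean_d += d0 * pdiff[d0]
            diff_var = 0.0
            diff_ent = 0.0
            for d0 in range(G):
                pd = pdiff[d0]
                if pd > 0.0:
                    diff_var += (d0 - mean_d) * (d0 - mean_d) * pd
                    diff_ent -= pd * np.log(pd) / log2
            hx = 0.0
            hy = 0.0
            for g in range(G):
                if px[g] > 0.0:
                    hx -= px[g] * np.log(px[g]) / log2
                if py[g] > 0.0:
                    hy -= py[g] * np.log(py[g]) / log2
            hxy1 = 0.0
            for t in range(ntouch):
                gi, gj = touched[t, 0], touched[t, 1]
                p = glcm[gi, gj] / total
                m = px[gi] * py[gj]
                if m > 0.0:
                    hxy1 -= p * np.log(m) / log2
            hxy2 = 0.0
            for gi in range(G):
                if px[gi] == 0.0:
                    continue
                for gj in range(G):
                    m = px[gi] * py[gj]
                    if m > 0.0:
                        hxy2 -= m * np.log(m) / log2
            hmax = max(hx, hy)
            info1 = (entropy - hxy1) / hmax if hmax > 0.0 else 0.0
            arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
            info2 = np.sqrt(arg) if arg > 0.0 else 0.0
            out[0, i, j] = sum_avg
            out[1, i, j] = contrast
            out[2, i, j] = correlation
            out[3, i, j] = entropy
            out[4, i, j] = energy
            out[5, i, j] = homog
            out[6, i, j] = sum_var
            out[7, i, j] = sum_ent
            out[8, i, j] = diff_var
            out[9, i, j] = diff_ent
            out[10, i, j] = info1
            out[11, i, j] = info2
            out[12, i, j] = idm
            # reset touched cells
            for t in range(ntouch):
                glcm[touched[t, 0], touched[t, 1]] = 0.0


def cooccurrence_stats(q: np.ndarray, roi: np.ndarray, ws: int,
                       G: int) -> np.ndarray:
    """13 sliding-window co-occurrence statistics of a 2D level image.

    Returns an array of shape ``(13, nx, ny)``; entries outside ``roi``
    are zero.  Levels in ``q`` are 1-based (1..G).
    """
    q = np.ascontiguousarray(q, dtype=np.int64)
    if q.min() < 1 or q.max() > G:
        raise ValueError("level image must hold values in 1..G")
    out = np.zeros((13,) + q.shape, dtype=np.float64)
    _glcm_stats_section(q, np.ascontiguousarray(roi, dtype=bool), ws, G, out)
    return out


def quantize(values: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of intensities to 1..levels over the ROI
    min-max range (a constant ROI maps to level 1 everywhere)."""
    vmin = values[roi].min()
    vmax = values[roi].max()
    if vmax <= vmin:
        return np.ones(values.shape, dtype=np.int64)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(np.int64) + 1
    return np.clip(q, 1, levels)


# ---------------------------------------------------------------------------
# Per-family map computation (2D sections)
# ---------------------------------------------------------------------------

def _nearest_fill(img2d: np.ndarray, roi2d: np.ndarray) -> np.ndarray:
    """Replace out-of-ROI pixels by their nearest in-ROI value."""
    if roi2d.all():
        return img2d
    if not roi2d.any():
        return img2d
    ind = ndimage.distance_transform_edt(~roi2d, return_indices=True)[1]
    return img2d[ind[0], ind[1]]


def _histogram_maps(sec: np.ndarray, windows) -> dict[str, np.ndarray]:
    out = {}
    nx, ny = sec.shape
    for ws in windows:
        if ws > min(nx, ny):
            raise ValueError(f"window {ws} larger than section extent {sec.shape}")
        h = ws // 2
        pad = np.pad(sec, h, mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(pad, (ws, ws))
        flat = win.reshape(nx, ny, ws * ws)
        out[f"histogram.mean.ws{ws}"] = flat.mean(axis=2)
        out[f"histogram.median.ws{ws}"] = np.median(flat, axis=2)
        out[f"histogram.std.ws{ws}"] = flat.std(axis=2)
        mx, mn = flat.max(axis=2), flat.min(axis=2)
        out[f"histogram.range.ws{ws}"] = mx - mn
        out[f"histogram.min.ws{ws}"] = mn
        out[f"histogram.max.ws{ws}"] = mx
        q75, q25 = np.percentile(flat, [75, 25], axis=2)
        out[f"histogram.iqr.ws{ws}"] = q75 - q25
    return out


_KIRSCH = []
_base = np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]], dtype=float)
_k = _base.copy()
for _ in range(8):
    _KIRSCH.append(_k.copy())
    # rotate the compass mask by 45 degrees
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    vals = [_k[p] for p in ring]
    vals = vals[-1:] + vals[:-1]
    for p, v in zip(ring, vals):
        _k[p] = v


def _gradient_maps(sec: np.ndarray) -> dict[str, np.ndarray]:
    dx, dy = np.gradient(sec)
    sx = ndimage.sobel(sec, axis=0, mode="reflect")
    sy = ndimage.sobel(sec, axis=1, mode="reflect")
    k_diag = np.array([[-2, -1, 0], [-1, 0, 1], [0, 1, 2]], dtype=float)
    k_anti = np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=float)
    kirsch = np.max(np.stack([
        ndimage.convolve(sec, k, mode="reflect") for k in _KIRSCH]), axis=0)
    return {
        "gradient.dx": dx,
        "gradient.dy": dy,
        "gradient.magnitude": np.hypot(dx, dy),
        "gradient.orientation": np.arctan2(dy, dx),
        "gradient.sobel_x": sx,
        "gradient.sobel_y": sy,
        "gradient.sobel_xy": ndimage.convolve(sec, k_diag, mode="reflect"),
        "gradient.sobel_yx": ndimage.convolve(sec, k_anti, mode="reflect"),
        "gradient.laplacian": ndimage.laplace(sec, mode="reflect"),
        "gradient.kirsch_max": kirsch,
    }


def gabor_kernel(lam: float, theta: float, ws: int) -> np.ndarray:
    """Complex 2D Gabor kernel with wavelength ``lam`` (pixels), orientation
    ``theta`` and a Gaussian envelope sized to the window; the real part is
    re-centred to zero mean so responses ignore constant offsets."""
    h = ws // 2
    y, x = np.mgrid[-h:h + 1, -h:h + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    sigma = max(ws / 5.0, 0.8)
    env = np.exp(-(xr**2 + yr**2) / (2 * sigma**2))
    k = env * np.exp(2j * np.pi * xr / lam)
    k = k - k.real.mean() - 1j * k.imag.mean()
    return k


def _gabor_maps(sec: np.ndarray, cfg: TextureBankConfig) -> dict[str, np.ndarray]:
    out = {}
    nx, ny = sec.shape
    for lam, ws in zip(cfg.gabor_lambdas, cfg.gabor_windows):
        if ws > min(nx, ny):
            raise ValueError(f"gabor kernel ws={ws} exceeds section size {sec.shape}")
        mags = []
        for t, theta in enumerate(cfg.gabor_thetas):
            k = gabor_kernel(lam, theta, ws)
            re = ndimage.convolve(sec, k.real, mode="reflect")
            im = ndimage.convolve(sec, k.imag, mode="reflect")
            mag = np.hypot(re, im)
            out[f"gabor.l{lam}.t{t + 1}"] = mag
            mags.append(mag)
        if cfg.gabor_orientation_max:
            out[f"gabor.l{lam}.max"] = np.max(np.stack(mags), axis=0)
    return out


def _laws_maps(sec: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for bank in (LAWS_3, LAWS_5):
        for na, ka in bank.items():
            along_x = ndimage.convolve1d(sec, np.array(ka, float), axis=0,
                                         mode="reflect")
            for nb, kb in bank.items():
                out[f"laws.{na}{nb}"] = ndimage.convolve1d(
                    along_x, np.array(kb, float), axis=1, mode="reflect")
    return out


def dominant_orientation(sec: np.ndarray, ws: int) -> np.ndarray:
    """Per-pixel dominant gradient orientation in [0, pi): the principal
    direction of the local (uncentred) gradient second-moment matrix."""
    gx, gy = np.gradient(sec)
    jxx = ndimage.uniform_filter(gx * gx, ws, mode="reflect")
    jyy = ndimage.uniform_filter(gy * gy, ws, mode="reflect")
    jxy = ndimage.uniform_filter(gx * gy, ws, mode="reflect")
    theta = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    theta = np.mod(theta, np.pi)
    theta[(jxx + jyy) < 1e-12] = 0.0  # zero-gradient neighbourhood -> bin 0
    return theta


def _collage_maps(sec: np.ndarray, roi2d: np.ndarray,
                  cfg: TextureBankConfig) -> dict[str, np.ndarray]:
    out = {}
    B = cfg.collage_bins
    for ws in cfg.collage_windows:
        theta = dominant_orientation(sec, ws)
        levels = np.clip((theta / np.pi * B).astype(np.int64), 0, B - 1) + 1
        stats = cooccurrence_stats(levels, roi2d, ws, B)
        for k, name in enumerate(HARALICK_STATS):
            out[f"collage.{name}.ws{ws}"] = stats[k]
    return out


# ---------------------------------------------------------------------------
# Bank driver and summarization
# ---------------------------------------------------------------------------

def compute_texture_maps(subvol: np.ndarray, roi: np.ndarray,
                         config: TextureBankConfig = DEFAULT_CONFIG,
                         ) -> dict[str, np.ndarray]:
    """Compute all configured texture maps on a (nx, ny, nsec) sub-volume.

    Returns a mapping from map name to a 3D array aligned with ``subvol``;
    values are meaningful on ``roi`` voxels.
    """
    if subvol.shape != roi.shape:
        raise ValueError("sub-volume and ROI shapes differ")
    if not roi.any():
        raise ValueError("empty ROI")
    nsec = subvol.shape[2]
    maps: dict[str, np.ndarray] = {
        name: np.zeros(subvol.shape) for name in config.map_names()}
    q3d = (quantize(subvol, roi, config.gray_levels)
           if "haralick" in config.families else None)
    for s in range(nsec):
        roi2d = roi[:, :, s]
        if not roi2d.any():
            continue
        sec = _nearest_fill(subvol[:, :, s], roi2d)
        per_sec: dict[str, np.ndarray] = {}
        if "histogram" in config.families:
            per_sec.update(_histogram_maps(sec, config.histogram_windows))
        if "gradient" in config.families:
            per_sec.update(_gradient_maps(sec))
        if "haralick" in config.families:
            for ws in config.haralick_windows:
                stats = cooccurrence_stats(q3d[:, :, s], roi2d, ws,
                                           config.gray_levels)
                for k, name in enumerate(HARALICK_STATS):
                    per_sec[f"haralick.{name}.ws{ws}"] = stats[k]
        if "gabor" in config.families:
            per_sec.update(_gabor_maps(sec, config))
        if "laws" in config.families:
            per_sec.update(_laws_maps(sec))
        if "collage" in config.families:
            per_sec.update(_collage_maps(sec, roi2d, config))
        for name, arr in per_sec.items():
            maps[name][:, :, s] = arr
    return maps


def summarize_maps(maps: dict[str, np.ndarray], roi: np.ndarray,
                   stats: tuple[str, ...] = ("mean", "variance",
                                             "skewness", "kurtosis"),
                   ) -> dict[str, float]:
    """First-order statistics of each texture map over the ROI voxels.

    A constant map has variance 0 and, by convention, skewness and excess
    kurtosis 0.  The optional ``median`` statistic may be added to the set.
    """
    if roi.sum() < 2:
        raise ValueError("ROI must contain at least 2 voxels to summarize")
    out: dict[str, float] = {}
    for name, arr in maps.items():
        vals = arr[roi]
        var = float(vals.var(ddof=1))
        degenerate = var < 1e-20
        for stat in stats:
            if stat == "mean":
                v = float(vals.mean())
            elif stat == "variance":
                v = var
            elif stat == "skewness":
                v = 0.0 if degenerate else float(_skew(vals))
            elif stat == "kurtosis":
                v = 0.0 if degenerate else float(_kurtosis(vals, fisher=True))
            elif stat == "median":
                v = float(np.median(vals))
            else:
                raise ValueError(f"unknown summary statistic {stat!r}")
            out[f"{name}.{stat}"] = v
    return out


def extract_texture_features(case: StudyCase,
                             config: TextureBankConfig = DEFAULT_CONFIG,
                             ) -> dict[str, float]:
    """764 texture features of one case, computed on the 3-section primary
    tumour sub-volume (cropped to the ROI bounding box for speed)."""
    sections = select_primary_subvolume(case.primary)
    sub = case.volume.voxels[:, :, list(sections)]
    roi = case.primary.voxels[:, :, list(sections)]
    # crop in-plane to the ROI bounding box plus a margin for the largest
    # filter support
    margin = 6
    ix = np.where(roi.any(axis=(1, 2)))[0]
    iy = np.where(roi.any(axis=(0, 2)))[0]
    x0, x1 = max(ix[0] - margin, 0), min(ix[-1] + margin + 1, roi.shape[0])
    y0, y1 = max(iy[0] - margin, 0), min(iy[-1] + margin + 1, roi.shape[1])
    sub = np.ascontiguousarray(sub[x0:x1, y0:y1])
    roi = np.ascontiguousarray(roi[x0:x1, y0:y1])
    maps = compute_texture_maps(sub, roi, config)
    return summarize_maps(maps, roi, config.summary_stats)
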