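"""3D radiomic feature extraction from an intensity volume and lesion mask.

The extractor emits a fixed roster of 423 named features per scan:

* 146 first-order features — intensity-distribution statistics over the
  masked voxels: 15 base statistics, the percentile grid p01..p99, and 8
  histogram statistics at each of four fixed binnings (8/16/32/64 bins).
* 33 volume/shape features — voxel and mesh volume, triangulated surface
  area, surface↔volume ratios, sphericity/compactness family, principal-axis
  and bounding-box geometry, convexity, and the RANO biperpendicular
  diameter product.
* 200 texture features — gray-level co-occurrence (merged over the 13 unique
  3D offsets at 16 and 32 levels, plus per-offset at 16 levels), run-length
  and size-zone matrices (16 and 32 levels), and the neighborhood
  gray-tone-difference family.
* 44 curvature features — 11 summary statistics of each of the two principal
  curvatures, mean curvature H and Gaussian curvature K, evaluated on the
  triangulated lesion boundary.

All geometry honors anisotropic voxel spacing; features are reported in
physical units (mm, mm², mm³, mm⁻¹).  Longitudinal "delta" features are the
element-wise absolute difference between two scans' feature vectors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes

from .response import bidimensional_product, _slice_diameters

FIRST_ORDER_HIST_BINS = (8, 16, 32, 64)
TEXTURE_BINS = (16, 32)
PER_OFFSET_BINS = 16
CURVATURE_SIGMA_VOX = 2.0  # Gaussian smoothing of the indicator, in voxels
DELTA_SUFFIX = ".delta"

# 13 unique 3D offsets (half of the 26-neighborhood).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)  # first nonzero component positive
)
assert len(OFFSETS_3D) == 13


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D intensity grid, a same-shaped binary lesion mask, and the
    physical voxel spacing in mm per axis."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        img = np.asarray(self.intensities, dtype=float)
        msk = np.asarray(self.mask, dtype=bool)
        if img.ndim != 3 or msk.shape != img.shape:
            raise ValueError("intensities and mask must be 3D arrays of equal shape")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive values")
        object.__setattr__(self, "intensities", img)
        object.__setattr__(self, "mask", msk)
        object.__setattr__(self, "spacing", sp)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def cropped(self, pad: int = 2) -> "LabeledVolume":
        """Crop to the mask bounding box with a background margin."""
        if not self.mask.any():
            raise ValueError("empty lesion mask")
        idx = np.nonzero(self.mask)
        sl = tuple(
            slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, n))
            for i, n in zip(idx, self.mask.shape)
        )
        return LabeledVolume(self.intensities[sl], self.mask[sl], self.spacing)


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------

_BASE_FO = (
    "mean", "median", "minimum", "maximum", "range", "variance", "std_dev",
    "skewness", "kurtosis", "rms", "energy", "total_energy",
    "mean_absolute_deviation", "median_absolute_deviation",
    "interquartile_range",
)
_HIST_FO = (
    "entropy", "uniformity", "max_probability", "mode", "hist_mean",
    "hist_variance", "hist_skewness", "hist_kurtosis",
)
_SHAPE = (
    "voxel_count", "volume", "volume_mesh", "surface_area",
    "surface_area_voxel", "surface_to_volume_ratio", "volume_to_surface_ratio",
    "sphericity", "sphericity_voxel", "compactness1", "compactness2",
    "spherical_disproportion", "equivalent_sphere_diameter",
    "normalized_surface_to_volume", "max_3d_diameter", "major_axis_length",
    "minor_axis_length", "least_axis_length", "elongation", "flatness",
    "bbox_dim_0", "bbox_dim_1", "bbox_dim_2", "bbox_volume", "extent",
    "convex_hull_volume", "solidity", "convex_surface_area", "convexity",
    "radius_of_gyration", "max_axial_diameter", "perpendicular_diameter",
    "bidimensional_product",
)
_GLCM_FULL = (
    "autocorrelation", "contrast", "correlation", "cluster_shade",
    "cluster_prominence", "dissimilarity", "energy", "entropy", "homogeneity",
    "inverse_difference", "idmn", "idn", "inverse_variance",
    "max_probability", "sum_average", "sum_entropy", "sum_variance",
    "difference_entropy", "difference_variance", "joint_variance",
)
_GLCM_OFFSET = (
    "contrast", "correlation", "dissimilarity", "energy", "entropy",
    "homogeneity", "max_probability",
)
_GLRLM = (
    "sre", "lre", "gln", "glnn", "rln", "rlnn", "rp", "glv", "rv",
    "run_entropy", "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)
_GLSZM = (
    "sae", "lae", "gln", "glnn", "szn", "sznn", "zp", "glv", "zv",
    "zone_entropy", "lglze", "hglze", "salgle", "sahgle", "lalgle", "lahgle",
)
_NGTDM = ("coarseness", "contrast", "busyness", "complexity", "strength")
_CURV_STATS = (
    "mean", "std", "minimum", "maximum", "median", "q1", "q3", "skewness",
    "kurtosis", "range", "energy",
)
_CURV_FIELDS = ("kappa1", "kappa2", "mean_curv", "gauss_curv")


def _first_order_names() -> list[str]:
    names = [f"fo.{n}" for n in _BASE_FO]
    names += [f"fo.p{p:02d}" for p in range(1, 100)]
    for b in FIRST_ORDER_HIST_BINS:
        names += [f"fo.hist{b}_{n}" for n in _HIST_FO]
    return names


def _shape_names() -> list[str]:
    return [f"shape.{n}" for n in _SHAPE]


def _texture_names() -> list[str]:
    names: list[str] = []
    for b in TEXTURE_BINS:
        names += [f"tex.glcm{b}_{n}" for n in _GLCM_FULL]
    for k in range(len(OFFSETS_3D)):
        names += [f"tex.glcm{PER_OFFSET_BINS}_o{k:02d}_{n}" for n in _GLCM_OFFSET]
    for b in TEXTURE_BINS:
        names += [f"tex.glrlm{b}_{n}" for n in _GLRLM]
    for b in TEXTURE_BINS:
        names += [f"tex.glszm{b}_{n}" for n in _GLSZM]
    names += [f"tex.ngtdm{PER_OFFSET_BINS}_{n}" for n in _NGTDM]
    return names


def _curvature_names() -> list[str]:
    return [f"curv.{f}_{s}" for f in _CURV_FIELDS for s in _CURV_STATS]


@dataclass(frozen=True)
class FeatureRoster:
    """The frozen, ordered feature roster (category blocks 146/33/200/44)."""

    first_order: tuple[str, ...] = tuple(_first_order_names())
    shape: tuple[str, ...] = tuple(_shape_names())
    texture: tuple[str, ...] = tuple(_texture_names())
    curvature: tuple[str, ...] = tuple(_curvature_names())

    def __post_init__(self) -> None:
        counts = (len(self.first_order), len(self.shape), len(self.texture),
                  len(self.curvature))
        if counts != (146, 33, 200, 44):
            raise ValueError(f"roster block sizes {counts} != (146, 33, 200, 44)")
        if len(set(self.names)) != 423:
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return self.first_order + self.shape + self.texture + self.curvature

    @property
    def version(self) -> str:
        return hashlib.sha1("|".join(self.names).encode()).hexdigest()[:12]


DEFAULT_ROSTER = FeatureRoster()


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def _safe_skew_kurt(x: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        return 0.0, 0.0
    return float(stats.skew(x)), float(stats.kurtosis(x, fisher=True))


def _hist_features(x: np.ndarray, bins: int) -> dict[str, float]:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        p = np.zeros(bins)
        p[0] = 1.0
        centers = np.full(bins, lo)
    else:
        counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
        p = counts / counts.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p ** 2).sum())
    mode = float(centers[int(np.argmax(p))])
    m = float((p * centers).sum())
    v = float((p * (centers - m) ** 2).sum())
    if v > 0:
        sk = float((p * (centers - m) ** 3).sum() / v ** 1.5)
        ku = float((p * (centers - m) ** 4).sum() / v ** 2 - 3.0)
    else:
        sk = ku = 0.0
    return {
        "entropy": entropy, "uniformity": uniformity,
        "max_probability": float(p.max()), "mode": mode,
        "hist_mean": m, "hist_variance": v,
        "hist_skewness": sk, "hist_kurtosis": ku,
    }


def extract_first_order(lv: LabeledVolume) -> dict[str, float]:
    """146 intensity-distribution statistics over the masked voxels."""
    if not lv.mask.any():
        raise ValueError("empty lesion mask")
    x = lv.intensities[lv.mask].astype(float)
    med = float(np.median(x))
    sk, ku = _safe_skew_kurt(x)
    q1, q3 = np.percentile(x, [25, 75])
    out: dict[str, float] = {
        "fo.mean": float(x.mean()),
        "fo.median": med,
        "fo.minimum": float(x.min()),
        "fo.maximum": float(x.max()),
        "fo.range": float(np.ptp(x)),
        "fo.variance": float(x.var()),
        "fo.std_dev": float(x.std()),
        "fo.skewness": sk,
        "fo.kurtosis": ku,
        "fo.rms": float(np.sqrt((x ** 2).mean())),
        "fo.energy": float((x ** 2).sum()),
        "fo.total_energy": float((x ** 2).sum() * lv.voxel_volume),
        "fo.mean_absolute_deviation": float(np.abs(x - x.mean()).mean()),
        "fo.median_absolute_deviation": float(np.median(np.abs(x - med))),
        "fo.interquartile_range": float(q3 - q1),
    }
    pcts = np.percentile(x, np.arange(1, 100))
    for p, v in zip(range(1, 100), pcts):
        out[f"fo.p{p:02d}"] = float(v)
    for b in FIRST_ORDER_HIST_BINS:
        for k, v in _hist_features(x, b).items():
            out[f"fo.hist{b}_{k}"] = v
    return out


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

MESH_SIGMA_VOX = 1.0  # indicator smoothing before meshing, in voxels


def surface_mesh(lv: LabeledVolume) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated 0.5-level isosurface of the mask indicator in physical
    coordinates; the mask is zero-padded so the surface is always closed.

    The indicator is smoothed by a fixed 1-voxel Gaussian before meshing:
    the raw binary isosurface carries a staircase area bias that does not
    vanish with resolution, whereas the smoothed surface converges to the
    true boundary as the voxel size shrinks.  Lesions too thin to survive
    the smoothing fall back to the raw binary isosurface.
    """
    pad = 1 + int(np.ceil(3 * MESH_SIGMA_VOX))
    m = np.pad(lv.mask.astype(float), pad)
    f = ndimage.gaussian_filter(m, MESH_SIGMA_VOX)
    if f.max() <= 0.6:  # tiny/thin lesion: smoothing would erase it
        f = m
    verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=lv.spacing)
    verts -= pad * np.asarray(lv.spacing)  # undo the pad shift
    return verts, faces


def _mesh_area_volume(verts: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    cross = np.cross(b - a, c - a)
    area = 0.5 * float(np.linalg.norm(cross, axis=1).sum())
    vol = abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum())) / 6.0
    return area, vol


def _voxel_surface_area(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Exposed voxel-face area (test-oracle style boundary measure)."""
    sp = np.asarray(spacing, float)
    face = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
    total = 0.0
    for ax in range(3):
        pad = np.pad(mask, [(1, 1) if k == ax else (0, 0) for k in range(3)])
        diff = np.diff(pad.astype(np.int8), axis=ax)
        total += float(np.abs(diff).sum()) * face[ax]
    return total


def extract_shape(lv: LabeledVolume) -> dict[str, float]:
    """33 morphology features of the lesion mask (physical units)."""
    if not lv.mask.any():
        raise ValueError("empty lesion mask")
    c = lv.cropped()
    n = int(c.mask.sum())
    vol = n * c.voxel_volume
    verts, faces = surface_mesh(c)
    surf, vol_mesh = _mesh_area_volume(verts, faces)
    surf_vox = _voxel_surface_area(c.mask, c.spacing)

    sphericity = float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / surf)
    sphericity_vox = float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / surf_vox)

    coords = np.argwhere(c.mask) * np.asarray(c.spacing)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    rg = float(np.sqrt((centered ** 2).sum(axis=1).mean()))
    if n > 1:
        cov = np.cov(centered.T)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    ext = coords.max(axis=0) - coords.min(axis=0) + np.asarray(c.spacing)
    bbox_volume = float(np.prod(ext))

    # max 3D diameter from the hull of the surface vertices
    try:
        hull_pts = verts[ConvexHull(verts).vertices]
    except QhullError:
        hull_pts = verts
    d = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_diam = float(np.sqrt((d ** 2).sum(axis=-1)).max())

    try:
        hull = ConvexHull(coords)
        hull_vol = float(hull.volume)
        hull_area = float(hull.area)
    except QhullError:  # degenerate (flat) lesion
        hull_vol = vol
        hull_area = surf

    counts = c.mask.sum(axis=(0, 1))
    z = int(np.argmax(counts))
    ii, jj = np.nonzero(c.mask[:, :, z])
    sp2 = np.asarray(c.spacing[:2])
    d1, d2 = _slice_diameters(np.column_stack([ii * sp2[0], jj * sp2[1]]), sp2)

    out = {
        "voxel_count": float(n),
        "volume": vol,
        "volume_mesh": vol_mesh,
        "surface_area": surf,
        "surface_area_voxel": surf_vox,
        "surface_to_volume_ratio": surf / vol,
        "volume_to_surface_ratio": vol / surf,
        "sphericity": sphericity,
        "sphericity_voxel": sphericity_vox,
        "compactness1": vol / (np.sqrt(np.pi) * surf ** 1.5),
        "compactness2": 36.0 * np.pi * vol ** 2 / surf ** 3,
        "spherical_disproportion": 1.0 / sphericity,
        "equivalent_sphere_diameter": 2.0 * (3.0 * vol / (4 * np.pi)) ** (1 / 3),
        "normalized_surface_to_volume": surf * vol ** (-2 / 3),
        "max_3d_diameter": max_diam,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elongation,
        "flatness": flatness,
        "bbox_dim_0": float(ext[0]),
        "bbox_dim_1": float(ext[1]),
        "bbox_dim_2": float(ext[2]),
        "bbox_volume": bbox_volume,
        "extent": vol / bbox_volume,
        "convex_hull_volume": max(hull_vol, vol * 1e-12),
        "solidity": vol / hull_vol if hull_vol > 0 else 1.0,
        "convex_surface_area": hull_area,
        "convexity": hull_area / surf,
        "radius_of_gyration": rg,
        "max_axial_diameter": d1,
        "perpendicular_diameter": d2,
        "bidimensional_product": d1 * d2,
    }
    return {f"shape.{k}": float(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def _quantize(lv: LabeledVolume, bins: int) -> np.ndarray:
    """Fixed-bin-count discretization over the masked intensity range.
    Returns int levels in [0, bins); background is -1."""
    q = np.full(lv.mask.shape, -1, dtype=np.int32)
    x = lv.intensities[lv.mask]
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        q[lv.mask] = 0
    else:
        lev = np.floor((lv.intensities[lv.mask] - lo) / (hi - lo) * bins).astype(np.int32)
        q[lv.mask] = np.clip(lev, 0, bins - 1)
    return q


def _shift_slices(off: tuple[int, int, int]) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    src, dst = [], []
    for o in off:
        if o > 0:
            src.append(slice(0, -o)); dst.append(slice(o, None))
        elif o < 0:
            src.append(slice(-o, None)); dst.append(slice(0, o))
        else:
            src.append(slice(None)); dst.append(slice(None))
    return tuple(src), tuple(dst)


def _glcm(q: np.ndarray, bins: int, off: tuple[int, int, int]) -> np.ndarray:
    src, dst = _shift_slices(off)
    a = q[src]
    b = q[dst]
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        m = np.zeros((bins, bins))
        m[0, 0] = 1.0
        return m
    pairs = a[ok] * bins + b[ok]
    m = np.bincount(pairs, minlength=bins * bins).reshape(bins, bins).astype(float)
    m = m + m.T  # symmetric
    return m / m.sum()


def _glcm_features(P: np.ndarray, which: Sequence[str]) -> dict[str, float]:
    bins = P.shape[0]
    i = np.arange(bins, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())
    sig = np.sqrt(sig2)
    diffs = np.abs(ii - jj)
    nz = P[P > 0]

    k = np.arange(2 * bins - 1, dtype=float)
    psum = np.zeros(2 * bins - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), P.ravel())
    kd = np.arange(bins, dtype=float)
    pdiff = np.zeros(bins)
    np.add.at(pdiff, diffs.astype(int).ravel(), P.ravel())
    nzs = psum[psum > 0]
    nzd = pdiff[pdiff > 0]

    vals: dict[str, float] = {}
    vals["contrast"] = float((diffs ** 2 * P).sum())
    vals["dissimilarity"] = float((diffs * P).sum())
    vals["homogeneity"] = float((P / (1.0 + (ii - jj) ** 2)).sum())
    vals["inverse_difference"] = float((P / (1.0 + diffs)).sum())
    vals["energy"] = float((P ** 2).sum())
    vals["entropy"] = float(-(nz * np.log2(nz)).sum())
    vals["max_probability"] = float(P.max())
    if sig2 > 0:
        vals["correlation"] = float((((ii - mu) * (jj - mu) * P).sum()) / sig2)
    else:
        vals["correlation"] = 1.0
    if which is _GLCM_OFFSET:
        return vals
    vals["autocorrelation"] = float((ii * jj * P).sum())
    vals["cluster_shade"] = float(((ii + jj - 2 * mu) ** 3 * P).sum())
    vals["cluster_prominence"] = float(((ii + jj - 2 * mu) ** 4 * P).sum())
    vals["idmn"] = float((P / (1.0 + (ii - jj) ** 2 / bins ** 2)).sum())
    vals["idn"] = float((P / (1.0 + diffs / bins)).sum())
    inv_var = P[diffs > 0] / (ii - jj)[diffs > 0] ** 2
    vals["inverse_variance"] = float(inv_var.sum())
    vals["sum_average"] = float((k * psum).sum())
    vals["sum_entropy"] = float(-(nzs * np.log2(nzs)).sum())
    sa = vals["sum_average"]
    vals["sum_variance"] = float(((k - sa) ** 2 * psum).sum())
    vals["difference_entropy"] = float(-(nzd * np.log2(nzd)).sum())
    da = float((kd * pdiff).sum())
    vals["difference_variance"] = float(((kd - da) ** 2 * pdiff).sum())
    vals["joint_variance"] = float(((ii - mu) ** 2 * P).sum())
    return vals


def _run_length_matrix(q: np.ndarray, bins: int) -> np.ndarray:
    """Gray-level run-length matrix summed over the 13 unique directions."""
    shape = q.shape
    max_len = int(max(shape)) + 1
    P = np.zeros((bins, max_len + 1))
    inside = q >= 0
    for off in OFFSETS_3D:
        src, dst = _shift_slices(off)
        same = np.zeros(shape, dtype=bool)
        same[dst] = inside[dst] & inside[src] & (q[dst] == q[src])
        # run starts: inside voxels not continuing a run from the -off side
        start = inside & ~same
        pos = np.argwhere(start)
        if len(pos) == 0:
            continue
        levels = q[start]
        lengths = np.ones(len(pos), dtype=np.int64)
        cur = pos.copy()
        alive = np.arange(len(pos))
        d = np.asarray(off)
        while len(alive) > 0:
            nxt = cur[alive] + d
            ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
            idx = alive[ok]
            n_ok = nxt[ok]
            cont = inside[tuple(n_ok.T)] & (q[tuple(n_ok.T)] == levels[idx])
            idx = idx[cont]
            if len(idx) == 0:
                break
            lengths[idx] += 1
            cur[idx] += d
            alive = idx
        np.add.at(P, (levels, lengths), 1.0)
    return P[:, 1:]  # drop length-0 column


def _rlm_style_features(P: np.ndarray) -> dict[str, float]:
    """The 16 standard run-length/size-zone statistics of a (level, size)
    count matrix."""
    Nr = P.sum()
    if Nr == 0:
        P = P.copy()
        P[0, 0] = 1.0
        Nr = 1.0
    g = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / Nr
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_g = float((g[:, 0] * pg).sum())
    mu_l = float((l[0] * pl).sum())
    nz = p[p > 0]
    return {
        "sre": float((p / l ** 2).sum()),
        "lre": float((p * l ** 2).sum()),
        "gln": float((P.sum(axis=1) ** 2).sum() / Nr),
        "glnn": float((pg ** 2).sum()),
        "rln": float((P.sum(axis=0) ** 2).sum() / Nr),
        "rlnn": float((pl ** 2).sum()),
        "rp": float(Nr / (P * l).sum()) if (P * l).sum() > 0 else 0.0,
        "glv": float(((g[:, 0] - mu_g) ** 2 * pg).sum()),
        "rv": float(((l[0] - mu_l) ** 2 * pl).sum()),
        "run_entropy": float(-(nz * np.log2(nz)).sum()),
        "lglre": float((p / g ** 2).sum()),
        "hglre": float((p * g ** 2).sum()),
        "srlgle": float((p / (g ** 2 * l ** 2)).sum()),
        "srhgle": float((p * g ** 2 / l ** 2).sum()),
        "lrlgle": float((p * l ** 2 / g ** 2).sum()),
        "lrhgle": float((p * g ** 2 * l ** 2).sum()),
    }


_SZM_RENAME = {
    "sre": "sae", "lre": "lae", "rln": "szn", "rlnn": "sznn", "rp": "zp",
    "rv": "zv", "run_entropy": "zone_entropy", "lglre": "lglze",
    "hglre": "hglze", "srlgle": "salgle", "srhgle": "sahgle",
    "lrlgle": "lalgle", "lrhgle": "lahgle",
}


def _size_zone_matrix(q: np.ndarray, bins: int) -> np.ndarray:
    """Gray-level size-zone matrix (26-connected zones per level)."""
    n_vox = int((q >= 0).sum())
    P = np.zeros((bins, n_vox + 1))
    structure = np.ones((3, 3, 3), dtype=bool)
    for g in range(bins):
        lab, nlab = ndimage.label(q == g, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(P[g], sizes, 1.0)
    return P[:, 1:]


def _ngtdm_features(q: np.ndarray, bins: int) -> dict[str, float]:
    inside = q >= 0
    vals = np.where(inside, q, 0).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nsum = ndimage.correlate(vals * inside, kernel, mode="constant")
    ncnt = ndimage.correlate(inside.astype(float), kernel, mode="constant")
    has_nb = inside & (ncnt > 0)
    A = np.zeros_like(vals)
    A[has_nb] = nsum[has_nb] / ncnt[has_nb]
    N = int(has_nb.sum())
    if N == 0:
        return {k: 0.0 for k in _NGTDM}
    lev = q[has_nb]
    dev = np.abs(lev - A[has_nb])
    s = np.zeros(bins)
    np.add.at(s, lev, dev)
    n_i = np.bincount(lev, minlength=bins).astype(float)
    p_i = n_i / N
    present = p_i > 0
    Ng = int(present.sum())
    i = np.arange(bins, dtype=float)

    coarseness = 1.0 / max(float((p_i * s).sum()), 1e-12)
    coarseness = min(coarseness, 1e6)
    if Ng > 1:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi_ > 0) & (pj_ > 0)
        contrast = float((pi_ * pj_ * (ii - jj) ** 2)[both].sum()) / (Ng * (Ng - 1))
        contrast *= float(s.sum()) / N
        denom = float(np.abs(i[present, None] * p_i[present, None]
                             - i[None, present] * p_i[None, present]).sum())
        busyness = float((p_i * s).sum()) / denom if denom > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = np.abs(ii - jj)[both] * (
                (pi_[both] * s[ii[both].astype(int)] + pj_[both] * s[jj[both].astype(int)])
                / (pi_[both] + pj_[both])
            )
        complexity = float(comp.sum()) / N
        strength = float(((pi_ + pj_)[both] * (ii - jj)[both] ** 2).sum())
        strength /= max(float(s.sum()), 1e-12)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness, "contrast": contrast, "busyness": busyness,
        "complexity": complexity, "strength": strength,
    }


def extract_texture(lv: LabeledVolume) -> dict[str, float]:
    """200 gray-level texture features (GLCM, GLRLM, GLSZM, NGTDM)."""
    if not lv.mask.any():
        raise ValueError("empty lesion mask")
    c = lv.cropped(pad=1)
    out: dict[str, float] = {}
    quantized = {b: _quantize(c, b) for b in set(TEXTURE_BINS) | {PER_OFFSET_BINS}}

    for b in TEXTURE_BINS:
        merged = sum(_glcm(quantized[b], b, off) for off in OFFSETS_3D)
        merged = merged / merged.sum()
        for k, v in _glcm_features(merged, _GLCM_FULL).items():
            out[f"tex.glcm{b}_{k}"] = v
    qo = quantized[PER_OFFSET_BINS]
    for k, off in enumerate(OFFSETS_3D):
        P = _glcm(qo, PER_OFFSET_BINS, off)
        feats = _glcm_features(P, _GLCM_OFFSET)
        for name in _GLCM_OFFSET:
            out[f"tex.glcm{PER_OFFSET_BINS}_o{k:02d}_{name}"] = feats[name]
    for b in TEXTURE_BINS:
        P = _run_length_matrix(quantized[b], b)
        for k, v in _rlm_style_features(P).items():
            out[f"tex.glrlm{b}_{k}"] = v
    for b in TEXTURE_BINS:
        P = _size_zone_matrix(quantized[b], b)
        feats = _rlm_style_features(P)
        for k, v in feats.items():
            out[f"tex.glszm{b}_{_SZM_RENAME.get(k, k)}"] = v
    for k, v in _ngtdm_features(quantized[PER_OFFSET_BINS], PER_OFFSET_BINS).items():
        out[f"tex.ngtdm{PER_OFFSET_BINS}_{k}"] = v
    return out


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def vertex_curvatures(lv: LabeledVolume) -> dict[str, np.ndarray]:
    """Principal (κ1 ≥ κ2), mean and Gaussian curvature per vertex of the
    lesion boundary, with the triangulation.

    The boundary is the 0.5 level set of the Gaussian-smoothed mask
    indicator; curvatures come from the gradient and Hessian of that
    implicit field (H from the divergence of the outward normal, K from the
    adjugate-Hessian form), sampled at the mesh vertices.  Sign convention:
    a sphere has H = 1/r > 0.
    """
    if not lv.mask.any():
        raise ValueError("empty lesion mask")
    c = lv.cropped(pad=max(4, int(np.ceil(CURVATURE_SIGMA_VOX * 3))))
    sp = np.asarray(c.spacing)
    f = ndimage.gaussian_filter(np.pad(c.mask.astype(float), 2), CURVATURE_SIGMA_VOX)
    verts_vox_based, faces, _, _ = marching_cubes(f, level=0.5)
    if len(verts_vox_based) < 4:
        raise ValueError("degenerate boundary mesh (<4 vertices)")

    g = np.gradient(f, *sp)
    hess = [[None] * 3 for _ in range(3)]
    for a in range(3):
        ga = np.gradient(g[a], *sp)
        for b in range(3):
            hess[a][b] = ga[b]

    coords = verts_vox_based.T  # in voxel units of the padded grid
    gv = np.stack([
        ndimage.map_coordinates(g[a], coords, order=1) for a in range(3)
    ])  # (3, V)
    Hv = np.empty((3, 3, gv.shape[1]))
    for a in range(3):
        for b in range(3):
            Hv[a, b] = ndimage.map_coordinates(hess[a][b], coords, order=1)

    gnorm = np.sqrt((gv ** 2).sum(axis=0))
    gnorm = np.maximum(gnorm, 1e-12)
    gHg = np.einsum("iv,ijv,jv->v", gv, Hv, gv)
    trH = Hv[0, 0] + Hv[1, 1] + Hv[2, 2]
    H = (gHg - gnorm ** 2 * trH) / (2.0 * gnorm ** 3)

    # adjugate of the Hessian
    adj = np.empty_like(Hv)
    for a in range(3):
        for b in range(3):
            r = [x for x in range(3) if x != b]
            cidx = [x for x in range(3) if x != a]
            minor = (Hv[r[0], cidx[0]] * Hv[r[1], cidx[1]]
                     - Hv[r[0], cidx[1]] * Hv[r[1], cidx[0]])
            adj[a, b] = (-1) ** (a + b) * minor
    gAg = np.einsum("iv,ijv,jv->v", gv, adj, gv)
    K = gAg / gnorm ** 4

    disc = np.sqrt(np.maximum(H ** 2 - K, 0.0))
    k1 = H + disc
    k2 = H - disc
    verts_phys = (verts_vox_based - 2.0) * sp  # undo pad, apply spacing
    return {
        "kappa1": k1, "kappa2": k2, "mean_curv": H, "gauss_curv": K,
        "verts": verts_phys, "faces": faces,
    }


def _curv_stats(x: np.ndarray) -> dict[str, float]:
    sk, ku = _safe_skew_kurt(x)
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "mean": float(x.mean()), "std": float(x.std()),
        "minimum": float(x.min()), "maximum": float(x.max()),
        "median": float(np.median(x)), "q1": float(q1), "q3": float(q3),
        "skewness": sk, "kurtosis": ku, "range": float(np.ptp(x)),
        "energy": float((x ** 2).mean()),
    }


def extract_curvature(lv: LabeledVolume) -> dict[str, float]:
    """44 curvature features: 11 statistics × {κ1, κ2, H, K}."""
    cv = vertex_curvatures(lv)
    out: dict[str, float] = {}
    for fname in _CURV_FIELDS:
        for k, v in _curv_stats(cv[fname]).items():
            out[f"curv.{fname}_{k}"] = v
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_all(lv: LabeledVolume, roster: FeatureRoster = DEFAULT_ROSTER) -> pd.Series:
    """The full 423-feature vector, in roster order, as a named Series."""
    feats: dict[str, float] = {}
    feats.update(extract_first_order(lv))
    feats.update(extract_shape(lv))
    feats.update(extract_texture(lv))
    feats.update(extract_curvature(lv))
    vec = pd.Series([feats[n] for n in roster.names], index=list(roster.names),
                    dtype=float)
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise AssertionError(f"non-finite features: {bad}")
    return vec


def delta_features(f1: pd.Series, f2: pd.Series, suffix: str = DELTA_SUFFIX) -> pd.Series:
    """Absolute per-feature difference |f2 − f1| (sign discarded), with
    feature names suffixed."""
    if list(f1.index) != list(f2.index):
        raise ValueError("feature rosters differ between time points")
    out = (f2 - f1).abs()
    out.index = [f"{n}{suffix}" for n in f1.index]
    return out


def combine_timepoints(f1: pd.Series, f2: pd.Series) -> pd.Series:
    """Baseline block followed by the delta block (846 values)."""
    return pd.concat([f1, delta_features(f1, f2)])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationState:
    mean: pd.Series
    std: pd.Series
    zero_variance: pd.Series  # boolean per column


@dataclass
class FeatureTable:
    """Rows = animals, columns = named features; tracks normalization."""

    data: pd.DataFrame
    normalization: NormalizationState | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def is_normalized(self) -> bool:
        return self.normalization is not None


def fit_normalization(table: FeatureTable) -> NormalizationState:
    df = table.data
    if len(df) < 2:
        raise ValueError("need at least 2 rows to normalize")
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=1)
    zero = std == 0
    return NormalizationState(mean=mean, std=std, zero_variance=zero)


def apply_normalization(table: FeatureTable, state: NormalizationState) -> FeatureTable:
    df = table.data
    std = state.std.replace(0.0, 1.0)
    z = (df - state.mean) / std
    z.loc[:, state.zero_variance] = 0.0
    return FeatureTable(data=z, normalization=state)


def zscore_normalize(table: FeatureTable) -> FeatureTable:
    """Per-column z-scoring (sample sd); constant columns map to 0 and are
    flagged in the stored normalization state."""
    return apply_normalization(table, fit_normalization(table))


def denormalize(table: FeatureTable) -> FeatureTable:
    if table.normalization is None:
        raise ValueError("table is not normalized")
    st = table.normalization
    std = st.std.replace(0.0, 1.0)
    raw = table.data * std + st.mean
    for col in st.zero_variance.index[st.zero_variance]:
        raw[col] = st.mean[col]
    return FeatureTable(data=raw, normalization=None)
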