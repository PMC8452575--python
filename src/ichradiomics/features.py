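"""Radiomics feature extraction from the haematoma region.

Implements IBSI-style first-order, shape, and texture (GLCM, GLRLM, GLSZM,
NGTDM) features over the 13 derived images, plus perihaematomal-oedema and
intraventricular-haemorrhage volumes, for a frozen 754-entry catalogue:

    24 shape + 13 images x 56 intensity/texture + 2 region volumes = 754

Grey levels are discretised per image with a fixed bin number (Ng = 32)
computed over the region-of-interest intensity range. Texture matrices use
the 13 unique 3-D direction offsets at Chebyshev distance 1 (GLCM/GLRLM,
normalised per direction and feature-averaged) and 26-connectivity
(GLSZM zones, NGTDM neighbourhoods).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .filters import DEFAULT_LOG_SIGMAS_MM, DEFAULT_WAVELET, build_image_set, canonical_image_names
from .imaging import (
    LABEL_ICH,
    LABEL_IVH,
    LABEL_PHE,
    ImagingError,
    RegionMask,
    VolumeGrid,
    region_volume_ml,
    resample_isotropic,
)

DEFAULT_NG = 32

#: the 13 unique 3-D offsets at Chebyshev distance 1 (half of the 26-neighbourhood)
DIRECTIONS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS) == 13

FIRST_ORDER_NAMES = (
    "mean", "variance", "standard deviation", "skewness", "kurtosis",
    "median", "minimum", "maximum", "range",
    "10th percentile", "25th percentile", "75th percentile", "90th percentile",
    "interquartile range", "mean absolute deviation",
    "robust mean absolute deviation", "energy", "root mean square",
    "entropy", "uniformity",
)
GLCM_NAMES = (
    "GLCM contrast", "GLCM dissimilarity", "GLCM entropy", "GLCM correlation",
    "GLCM energy", "GLCM homogeneity", "GLCM cluster shade",
    "GLCM cluster prominence", "GLCM autocorrelation",
)
GLRLM_NAMES = (
    "GLRLM short run emphasis", "GLRLM long run emphasis",
    "GLRLM grey level non-uniformity", "GLRLM run length non-uniformity",
    "GLRLM run percentage", "GLRLM low grey level run emphasis",
    "GLRLM high grey level run emphasis",
    "GLRLM long run low grey level emphasis",
    "GLRLM long run high grey level emphasis", "GLRLM run length variance",
)
GLSZM_NAMES = (
    "GLSZM small zone emphasis", "GLSZM large zone emphasis",
    "GLSZM grey level non-uniformity", "GLSZM zone size non-uniformity",
    "GLSZM zone percentage", "GLSZM low grey level zone emphasis",
    "GLSZM high grey level zone emphasis",
    "GLSZM small zone low grey level emphasis",
    "GLSZM small zone high grey level emphasis",
    "GLSZM large zone low grey level emphasis",
    "GLSZM large zone high grey level emphasis", "GLSZM grey level variance",
)
NGTDM_NAMES = (
    "NGTDM coarseness", "NGTDM contrast", "NGTDM busyness",
    "NGTDM complexity", "NGTDM strength",
)
PER_IMAGE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES

SHAPE_NAMES = (
    "voxel count", "voxel volume ml", "mesh volume ml", "surface area mm2",
    "surface to volume ratio", "sphericity", "compactness 1", "compactness 2",
    "spherical disproportion", "equivalent spherical diameter mm",
    "maximum 3d diameter mm", "max 2d diameter axis0 mm",
    "max 2d diameter axis1 mm", "max 2d diameter axis2 mm",
    "major axis length mm", "minor axis length mm", "least axis length mm",
    "elongation", "flatness", "extent", "solidity",
    "bounding box volume ml", "area density aabb", "area density convex hull",
)

VOLUME_FEATURE_NAMES = (
    "perihaematomal oedema volume ml",
    "intraventricular haemorrhage volume ml",
)

EXPECTED_CATALOGUE_SIZE = 754


class CatalogueError(ValueError):
    """Raised when the configured feature catalogue does not total 754."""


class EmptyROIError(ValueError):
    """Raised when a requested region of interest contains no voxels."""


class SubjectExcluded(RuntimeError):
    """Raised when a subject cannot be extracted (e.g. empty ICH mask)."""


def feature_id(image: str, family: str, name: str) -> str:
    if family in ("shape", "volume"):
        return name
    return f"{image} {name}"


def build_catalogue(sigmas=DEFAULT_LOG_SIGMAS_MM, expected: int | None = EXPECTED_CATALOGUE_SIZE):
    """Ordered list of (image, family, name) triples defining the catalogue."""
    entries = [("mask", "shape", n) for n in SHAPE_NAMES]
    for image in canonical_image_names(sigmas):
        for n in FIRST_ORDER_NAMES:
            entries.append((image, "first-order", n))
        for n in GLCM_NAMES:
            entries.append((image, "glcm", n))
        for n in GLRLM_NAMES:
            entries.append((image, "glrlm", n))
        for n in GLSZM_NAMES:
            entries.append((image, "glszm", n))
        for n in NGTDM_NAMES:
            entries.append((image, "ngtdm", n))
    for n in VOLUME_FEATURE_NAMES:
        entries.append(("mask", "volume", n))
    ids = [feature_id(*e) for e in entries]
    if len(set(ids)) != len(ids):
        raise CatalogueError("duplicate feature identifiers in catalogue")
    if expected is not None and len(entries) != expected:
        raise CatalogueError(
            f"catalogue has {len(entries)} entries, expected {expected}; "
            "check filter-bank configuration"
        )
    return entries


def catalogue_ids(sigmas=DEFAULT_LOG_SIGMAS_MM) -> list[str]:
    return [feature_id(*e) for e in build_catalogue(sigmas)]


# ---------------------------------------------------------------------------
# discretisation


@dataclass
class DiscretisedROI:
    """ROI grey levels after fixed-bin-number discretisation.

    ``levels`` is a 3-D integer array cropped to the ROI bounding box with 0
    outside the ROI and values 1..Ng inside; ``mask`` is the matching boolean
    ROI indicator.
    """

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    ng_effective: int
    bin_edges: np.ndarray

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _crop_to_bbox(arr: np.ndarray, mask: np.ndarray, pad: int = 0):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return arr[sl], mask[sl]


def discretise_roi(data: np.ndarray, mask: np.ndarray, ng: int = DEFAULT_NG) -> DiscretisedROI:
    """Fixed-bin-number discretisation of ``data`` within boolean ``mask``."""
    if ng < 1:
        raise ValueError(f"Ng must be >= 1, got {ng}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("empty ROI")
    data_c, mask_c = _crop_to_bbox(np.asarray(data, dtype=np.float64), mask)
    vals = data_c[mask_c]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(data_c.shape, dtype=np.int32)
    if vmax <= vmin:
        levels[mask_c] = 1
        edges = np.array([vmin, vmax])
        return DiscretisedROI(levels, mask_c, ng, 1, edges)
    w = (vmax - vmin) / ng
    lv = np.floor((data_c[mask_c] - vmin) / w).astype(np.int32) + 1
    np.clip(lv, 1, ng, out=lv)
    levels[mask_c] = lv
    edges = vmin + w * np.arange(ng + 1)
    ng_eff = int(np.unique(lv).size)
    return DiscretisedROI(levels, mask_c, ng, ng_eff, edges)


def discretise(vol: VolumeGrid, mask: RegionMask, label: int = LABEL_ICH,
               ng: int = DEFAULT_NG) -> DiscretisedROI:
    """Discretise a labelled region of a volume (fixed bin number)."""
    if ng < 2:
        raise ValueError(f"Ng must be >= 2, got {ng}")
    mask.check_geometry(vol)
    return discretise_roi(vol.data, mask.labels == label, ng)


# ---------------------------------------------------------------------------
# first-order


def first_order_features(values: np.ndarray, ng: int = DEFAULT_NG) -> dict[str, float]:
    """First-order statistics of ROI intensities.

    Variance/skewness/kurtosis use population moments; kurtosis is the
    Pearson (non-excess) convention. Percentiles use linear interpolation.
    Entropy and uniformity are computed on fixed-bin-number levels.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise EmptyROIError("first-order features need at least one voxel")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d**2))
    std = float(np.sqrt(m2))
    if m2 > 0:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2
    else:
        skew, kurt = 0.0, 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(inner - inner.mean()))) if inner.size else 0.0
    # histogram probabilities for entropy / uniformity
    vmin, vmax = float(x.min()), float(x.max())
    if vmax > vmin:
        lv = np.clip(np.floor((x - vmin) / ((vmax - vmin) / ng)), 0, ng - 1)
        counts = np.bincount(lv.astype(np.int64), minlength=ng)
    else:
        counts = np.array([x.size])
    p = counts[counts > 0] / x.size
    return {
        "mean": mean,
        "variance": m2,
        "standard deviation": std,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(p50),
        "minimum": vmin,
        "maximum": vmax,
        "range": vmax - vmin,
        "10th percentile": float(p10),
        "25th percentile": float(p25),
        "75th percentile": float(p75),
        "90th percentile": float(p90),
        "interquartile range": float(p75 - p25),
        "mean absolute deviation": float(np.mean(np.abs(d))),
        "robust mean absolute deviation": rmad,
        "energy": float(np.sum(x**2)),
        "root mean square": float(np.sqrt(np.mean(x**2))),
        "entropy": float(-np.sum(p * np.log2(p))),
        "uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# shape


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 24:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except QhullError:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(abs(np.einsum("ij,ij->", np.cross(tri[:, 0], tri[:, 1]), tri[:, 2])) / 6.0)


def shape_features(mask: RegionMask, label: int = LABEL_ICH) -> dict[str, float]:
    """Morphological features of one labelled region (physical mm units).

    Surface quantities come from a marching-cubes mesh over the 0.5
    iso-surface; axis lengths from the eigen-decomposition of the physical
    voxel-coordinate covariance. Degenerate regions (fewer than 4 voxels or a
    rank-deficient covariance) report axis ratios as 0 with a warning.
    """
    binmask = mask.labels == label
    n_vox = int(binmask.sum())
    if n_vox == 0:
        raise EmptyROIError(f"no voxels with label {label}")
    spacing = np.asarray(mask.spacing, dtype=np.float64)
    voxel_mm3 = float(spacing.prod())
    vol_voxel_ml = n_vox * voxel_mm3 / 1000.0
    coords = np.argwhere(binmask).astype(np.float64) * spacing

    cropped, cm = _crop_to_bbox(binmask.astype(np.float64), binmask, pad=1)
    padded = np.pad(cropped, 2)
    # light smoothing of the indicator before meshing suppresses the
    # staircase bias of marching cubes on digitised boundaries; tiny regions
    # whose smoothed field never reaches 0.5 fall back to the raw indicator
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    area, mesh_vol = 0.0, 0.0
    for fld in (smoothed, padded):
        try:
            verts, faces, _, _ = measure.marching_cubes(fld, level=0.5, spacing=tuple(spacing))
            area = float(measure.mesh_surface_area(verts, faces))
            mesh_vol = _mesh_volume(verts, faces)
            break
        except (ValueError, RuntimeError):
            continue
    v_for_surface = mesh_vol if mesh_vol > 0 else n_vox * voxel_mm3
    if area > 0:
        sphericity = (36.0 * np.pi * v_for_surface**2) ** (1.0 / 3.0) / area
        compact1 = v_for_surface / (np.sqrt(np.pi) * area**1.5)
        compact2 = 36.0 * np.pi * v_for_surface**2 / area**3
        r_eq = (3.0 * v_for_surface / (4.0 * np.pi)) ** (1.0 / 3.0)
        sph_disprop = area / (4.0 * np.pi * r_eq**2)
        s2v = area / v_for_surface
    else:
        sphericity = compact1 = compact2 = sph_disprop = s2v = 0.0

    degenerate = n_vox < 4
    major = minor = least = elong = flat = 0.0
    if not degenerate:
        cov = np.cov(coords, rowvar=False, ddof=0)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ev = np.clip(ev, 0.0, None)
        if ev[0] <= 1e-12:
            degenerate = True
        else:
            major, minor, least = (4.0 * np.sqrt(ev)).tolist()
            elong = float(np.sqrt(ev[1] / ev[0]))
            flat = float(np.sqrt(ev[2] / ev[0]))
    if degenerate:
        warnings.warn("degenerate region: axis features reported as 0", stacklevel=2)

    max3d = _max_pairwise(coords)
    max2d = []
    for axis in range(3):
        inplane = [i for i in range(3) if i != axis]
        best = 0.0
        idx = np.argwhere(binmask)
        for plane in np.unique(idx[:, axis]):
            pts = idx[idx[:, axis] == plane][:, inplane] * spacing[inplane]
            best = max(best, _max_pairwise(pts))
        max2d.append(best)

    idx = np.argwhere(binmask)
    bbox_counts = idx.max(axis=0) - idx.min(axis=0) + 1
    bbox_mm = bbox_counts * spacing
    bbox_vol_mm3 = float(np.prod(bbox_mm))
    extent = n_vox * voxel_mm3 / bbox_vol_mm3
    aabb_area = 2.0 * (bbox_mm[0] * bbox_mm[1] + bbox_mm[0] * bbox_mm[2] + bbox_mm[1] * bbox_mm[2])

    solidity = 0.0
    hull_area_density = 0.0
    if n_vox >= 4 and not degenerate:
        try:
            hull = ConvexHull(coords, qhull_options="QJ")
            if hull.volume > 0:
                solidity = n_vox * voxel_mm3 / hull.volume
            if hull.area > 0:
                hull_area_density = area / hull.area
        except QhullError:
            pass

    eq_diam = 2.0 * (3.0 * n_vox * voxel_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "voxel count": float(n_vox),
        "voxel volume ml": vol_voxel_ml,
        "mesh volume ml": mesh_vol / 1000.0,
        "surface area mm2": area,
        "surface to volume ratio": s2v,
        "sphericity": sphericity,
        "compactness 1": compact1,
        "compactness 2": compact2,
        "spherical disproportion": sph_disprop,
        "equivalent spherical diameter mm": eq_diam,
        "maximum 3d diameter mm": max3d,
        "max 2d diameter axis0 mm": max2d[0],
        "max 2d diameter axis1 mm": max2d[1],
        "max 2d diameter axis2 mm": max2d[2],
        "major axis length mm": major,
        "minor axis length mm": minor,
        "least axis length mm": least,
        "elongation": elong,
        "flatness": flat,
        "extent": extent,
        "solidity": solidity,
        "bounding box volume ml": bbox_vol_mm3 / 1000.0,
        "area density aabb": area / aabb_area if aabb_area > 0 else 0.0,
        "area density convex hull": hull_area_density,
    }


# ---------------------------------------------------------------------------
# texture matrices


def glcm_matrices(d: DiscretisedROI) -> list[np.ndarray]:
    """Per-direction symmetric, normalised co-occurrence matrices."""
    ng = d.ng
    lv = d.levels
    mats = []
    for off in DIRECTIONS:
        sl_a = tuple(slice(max(o, 0), n + min(o, 0)) for o, n in zip(off, lv.shape))
        sl_b = tuple(slice(max(-o, 0), n + min(-o, 0)) for o, n in zip(off, lv.shape))
        a, b = lv[sl_a], lv[sl_b]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        m = np.zeros((ng, ng))
        np.add.at(m, (a[valid] - 1, b[valid] - 1), 1.0)
        m = m + m.T
        mats.append(m / m.sum())
    return mats


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i, j = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1), indexing="ij")
    pi = p.sum(axis=1)
    mu_i = float((np.arange(1, ng + 1) * pi).sum())
    sig_i = float(np.sqrt(((np.arange(1, ng + 1) - mu_i) ** 2 * pi).sum()))
    diff = np.abs(i - j)
    nz = p > 0
    corr = 1.0
    if sig_i > 1e-12:
        corr = float(((i - mu_i) * (j - mu_i) * p).sum() / sig_i**2)
    return {
        "GLCM contrast": float((diff**2 * p).sum()),
        "GLCM dissimilarity": float((diff * p).sum()),
        "GLCM entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "GLCM correlation": corr,
        "GLCM energy": float((p**2).sum()),
        "GLCM homogeneity": float((p / (1.0 + diff)).sum()),
        "GLCM cluster shade": float(((i + j - 2 * mu_i) ** 3 * p).sum()),
        "GLCM cluster prominence": float(((i + j - 2 * mu_i) ** 4 * p).sum()),
        "GLCM autocorrelation": float((i * j * p).sum()),
    }


def glcm_features(d: DiscretisedROI) -> dict[str, float]:
    """Direction-averaged GLCM features (normalise per direction, average values)."""
    mats = glcm_matrices(d)
    if not mats:
        raise ValueError("no valid voxel pairs for GLCM")
    per_dir = [_glcm_features_one(m) for m in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glrlm_matrix(d: DiscretisedROI, direction) -> np.ndarray:
    """Run-length matrix (Ng x max-run) for one direction."""
    lv = d.levels
    shape = lv.shape
    off = np.asarray(direction)

    def shifted_same(k: int) -> np.ndarray:
        # True at voxel v iff v + k*off is in bounds, both in-ROI, equal level
        o = off * k
        out = np.zeros(shape, dtype=bool)
        sl_v = tuple(slice(max(-x, 0), n + min(-x, 0)) for x, n in zip(o, shape))
        sl_n = tuple(slice(max(x, 0), n + min(x, 0)) for x, n in zip(o, shape))
        a, b = lv[sl_v], lv[sl_n]
        out[sl_v] = (a > 0) & (a == b)
        return out

    in_roi = lv > 0
    prev_same = shifted_same(-1)
    starts = in_roi & ~prev_same
    start_idx = np.argwhere(starts)
    if len(start_idx) == 0:
        return np.zeros((d.ng, 1))
    lengths = np.ones(len(start_idx), dtype=np.int64)
    pos = start_idx.copy()
    alive = np.ones(len(start_idx), dtype=bool)
    nxt_same = shifted_same(1)
    while alive.any():
        p = pos[alive]
        cont = nxt_same[p[:, 0], p[:, 1], p[:, 2]]
        idx_alive = np.flatnonzero(alive)
        lengths[idx_alive[cont]] += 1
        pos[idx_alive[cont]] += off
        alive[idx_alive[~cont]] = False
    levels = lv[start_idx[:, 0], start_idx[:, 1], start_idx[:, 2]]
    rmax = int(lengths.max())
    mat = np.zeros((d.ng, rmax))
    np.add.at(mat, (levels - 1, lengths - 1), 1.0)
    return mat


def _glrlm_features_one(r: np.ndarray, n_vox: int) -> dict[str, float]:
    nr = r.sum()
    g = np.arange(1, r.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    rg = r.sum(axis=1)
    rl = r.sum(axis=0)
    p = r / nr
    mu_l = float((l * rl / nr).sum())
    return {
        "GLRLM short run emphasis": float((rl / l**2).sum() / nr),
        "GLRLM long run emphasis": float((rl * l**2).sum() / nr),
        "GLRLM grey level non-uniformity": float((rg**2).sum() / nr),
        "GLRLM run length non-uniformity": float((rl**2).sum() / nr),
        "GLRLM run percentage": float(nr / n_vox),
        "GLRLM low grey level run emphasis": float((rg / g**2).sum() / nr),
        "GLRLM high grey level run emphasis": float((rg * g**2).sum() / nr),
        "GLRLM long run low grey level emphasis": float(
            (r * (l[None, :] ** 2 / g[:, None] ** 2)).sum() / nr
        ),
        "GLRLM long run high grey level emphasis": float(
            (r * (l[None, :] ** 2 * g[:, None] ** 2)).sum() / nr
        ),
        "GLRLM run length variance": float((p.sum(axis=0) * (l - mu_l) ** 2).sum()),
    }


def glrlm_features(d: DiscretisedROI) -> dict[str, float]:
    """GLRLM features computed per direction then averaged over the 13 directions."""
    n_vox = int(d.mask.sum())
    if n_vox == 0:
        raise EmptyROIError("empty ROI")
    per_dir = [_glrlm_features_one(glrlm_matrix(d, off), n_vox) for off in DIRECTIONS]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(d: DiscretisedROI) -> np.ndarray:
    """Size-zone matrix over 26-connected constant-level zones."""
    lv = d.levels
    zones: list[tuple[int, int]] = []
    for g in np.unique(lv[lv > 0]):
        lab, n = ndimage.label(lv == g, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    mat = np.zeros((d.ng, smax))
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


def glszm_features(d: DiscretisedROI) -> dict[str, float]:
    n_vox = int(d.mask.sum())
    if n_vox == 0:
        raise EmptyROIError("empty ROI")
    z = glszm_matrix(d)
    nz = z.sum()
    g = np.arange(1, z.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, z.shape[1] + 1, dtype=np.float64)
    zg = z.sum(axis=1)
    zs = z.sum(axis=0)
    pg = zg / nz
    mu_g = float((g * pg).sum())
    return {
        "GLSZM small zone emphasis": float((zs / s**2).sum() / nz),
        "GLSZM large zone emphasis": float((zs * s**2).sum() / nz),
        "GLSZM grey level non-uniformity": float((zg**2).sum() / nz),
        "GLSZM zone size non-uniformity": float((zs**2).sum() / nz),
        "GLSZM zone percentage": float(nz / n_vox),
        "GLSZM low grey level zone emphasis": float((zg / g**2).sum() / nz),
        "GLSZM high grey level zone emphasis": float((zg * g**2).sum() / nz),
        "GLSZM small zone low grey level emphasis": float(
            (z / (s[None, :] ** 2 * g[:, None] ** 2)).sum() / nz
        ),
        "GLSZM small zone high grey level emphasis": float(
            (z * (g[:, None] ** 2 / s[None, :] ** 2)).sum() / nz
        ),
        "GLSZM large zone low grey level emphasis": float(
            (z * (s[None, :] ** 2 / g[:, None] ** 2)).sum() / nz
        ),
        "GLSZM large zone high grey level emphasis": float(
            (z * (s[None, :] ** 2 * g[:, None] ** 2)).sum() / nz
        ),
        "GLSZM grey level variance": float((pg * (g - mu_g) ** 2).sum()),
    }


def ngtdm_table(d: DiscretisedROI):
    """Per-level (n_i, p_i, s_i) with 26-neighbourhood mean differences."""
    lv = d.levels.astype(np.float64)
    roi = d.mask.astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(lv * roi, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(roi, kernel, mode="constant", cval=0.0)
    valid = d.mask & (nb_cnt > 0)
    diffs = np.zeros(lv.shape)
    diffs[valid] = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    ng = d.ng
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    levels = d.levels[valid]
    np.add.at(n_i, levels - 1, 1.0)
    np.add.at(s_i, levels - 1, diffs[valid])
    n_tot = n_i.sum()
    p_i = n_i / n_tot if n_tot > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(d: DiscretisedROI) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(d)
    n_tot = n_i.sum()
    if n_tot == 0:
        raise EmptyROIError("empty ROI (no voxels with valid neighbourhoods)")
    occ = p_i > 0
    g = np.arange(1, d.ng + 1, dtype=np.float64)
    n_g = int(occ.sum())
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 1e-12 else 1e6
    contrast = 0.0
    if n_g > 1:
        gi, gj = np.meshgrid(g[occ], g[occ], indexing="ij")
        pij = np.outer(p_i[occ], p_i[occ])
        contrast = float(
            (pij * (gi - gj) ** 2).sum() / (n_g * (n_g - 1)) * (s_i.sum() / n_tot)
        )
    busy_den = 0.0
    complexity = 0.0
    strength_num = 0.0
    if n_g > 1:
        ip = g[occ] * p_i[occ]
        busy_den = float(np.abs(ip[:, None] - ip[None, :]).sum())
        gi, gj = np.meshgrid(g[occ], g[occ], indexing="ij")
        psum = p_i[occ][:, None] + p_i[occ][None, :]
        num = np.abs(gi - gj) * (
            p_i[occ][:, None] * s_i[occ][:, None] + p_i[occ][None, :] * s_i[occ][None, :]
        )
        complexity = float((num / psum).sum() / n_tot)
        strength_num = float((psum * (gi - gj) ** 2).sum())
    busyness = ps / busy_den if busy_den > 1e-12 else 0.0
    s_sum = float(s_i.sum())
    strength = strength_num / s_sum if s_sum > 1e-12 else 0.0
    return {
        "NGTDM coarseness": coarseness,
        "NGTDM contrast": contrast,
        "NGTDM busyness": busyness,
        "NGTDM complexity": complexity,
        "NGTDM strength": strength,
    }


# ---------------------------------------------------------------------------
# per-subject extraction


def texture_features(d: DiscretisedROI) -> dict[str, float]:
    out: dict[str, float] = {}
    out.update(glcm_features(d))
    out.update(glrlm_features(d))
    out.update(glszm_features(d))
    out.update(ngtdm_features(d))
    return out


def extract_subject(
    vol: VolumeGrid,
    mask: RegionMask,
    subject_id: str = "subject",
    clinical: dict | None = None,
    ng: int = DEFAULT_NG,
    sigmas=DEFAULT_LOG_SIGMAS_MM,
    wavelet_name: str = DEFAULT_WAVELET,
    target_mm: float = 1.0,
    presampled: bool = False,
):
    """Extract the full 754-entry feature vector for one subject.

    Returns ``(values, meta)`` where ``values`` is a dict keyed by catalogue
    feature ids (in catalogue order) and ``meta`` carries subject id, batch
    and covariates from ``clinical`` (keys ``age``, ``gender``, ``treatment``,
    ``slice_thickness_mm`` when present).
    """
    catalogue = build_catalogue(sigmas)
    if not presampled:
        vol = resample_isotropic(vol, target_mm, "intensity")
        mask = resample_isotropic(mask, target_mm, "mask-label")
    mask.check_geometry(vol)
    ich = mask.labels == LABEL_ICH
    if not ich.any():
        raise SubjectExcluded(f"{subject_id}: empty ICH region after resampling")

    values: dict[str, float] = {}
    shp = shape_features(mask, LABEL_ICH)
    for n in SHAPE_NAMES:
        values[n] = shp[n]

    images = build_image_set(vol, sigmas, wavelet_name)
    for name, img in images.items():
        roi_vals = img.data[ich]
        fo = first_order_features(roi_vals, ng)
        d = discretise_roi(img.data, ich, ng)
        tex = texture_features(d)
        for fam_name in PER_IMAGE_NAMES:
            src = fo if fam_name in fo else tex
            values[feature_id(name, "x", fam_name)] = src[fam_name]

    values["perihaematomal oedema volume ml"] = region_volume_ml(mask, LABEL_PHE)
    values["intraventricular haemorrhage volume ml"] = region_volume_ml(mask, LABEL_IVH)

    ids = [feature_id(*e) for e in catalogue]
    missing = [i for i in ids if i not in values]
    if missing or len(values) != len(ids):
        raise CatalogueError(f"extracted {len(values)} values; missing {missing[:3]}...")
    ordered = {i: float(values[i]) for i in ids}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise SubjectExcluded(f"{subject_id}: non-finite features {bad[:5]}")
    meta = {"subject_id": subject_id}
    if clinical:
        meta.update(clinical)
    return ordered, meta
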