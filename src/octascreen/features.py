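"""The six quantitative OCTA features (13 scalars per eye).

Vascular features, all computed on the superficial plexus (SCP) except
vessel density which is computed on both layers:

* **BVT** (blood vessel tortuosity) — mean over skeleton branches of the
  geodesic/Euclidean length ratio; 1 for perfectly straight vessels.
* **BVC** (blood vascular caliber, µm) — vascular area divided by total
  vascular (centerline) length; an average vessel width.
* **VPI** (vessel perimeter index) — vessel-boundary pixel fraction of the
  image.
* **BVD** (blood vessel density) — fraction of pixels classified as vessel
  by the local fractal dimension (FD >= 0.7), measured in three circular
  regions around the fovea (C1: 0–1 mm radius, C2: 1–2 mm, C3: 2–3 mm)
  with the segmented FAZ excluded.

Foveal features, computed on both layers:

* **FAZ-A** (µm²) — foveal avascular zone area, pixel count times pixel
  area.
* **FAZ-CI** — contour irregularity: FAZ perimeter relative to the
  perimeter of the circle of equal area (1 for a perfect circle).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import segmentation as seg
from .preprocess import AngiogramImage, preprocess
from .segmentation import FazResult, SkeletonBranch, VesselMapSet

logger = logging.getLogger(__name__)

#: CSV column order for one eye's features
FEATURE_COLUMNS = [
    "BVT_S", "BVC_S", "VPI_S",
    "BVD_SC1", "BVD_SC2", "BVD_SC3",
    "BVD_DC1", "BVD_DC2", "BVD_DC3",
    "FAZ_A_S", "FAZ_A_D", "FAZ_CI_S", "FAZ_CI_D",
]


class UndefinedFeatureError(ValueError):
    """A feature has no defined value for this input (e.g. empty mask)."""


@dataclass
class FeatureVector:
    """The 13 scalar features for one eye (S = SCP, D = DCP)."""

    subject_id: str = ""
    eye: str = ""
    bvt_s: float = np.nan
    bvc_s: float = np.nan
    vpi_s: float = np.nan
    bvd_sc1: float = np.nan
    bvd_sc2: float = np.nan
    bvd_sc3: float = np.nan
    bvd_dc1: float = np.nan
    bvd_dc2: float = np.nan
    bvd_dc3: float = np.nan
    faz_a_s: float = np.nan
    faz_a_d: float = np.nan
    faz_ci_s: float = np.nan
    faz_ci_d: float = np.nan
    incomplete: bool = False

    def as_dict(self) -> dict:
        vals = [
            self.bvt_s, self.bvc_s, self.vpi_s,
            self.bvd_sc1, self.bvd_sc2, self.bvd_sc3,
            self.bvd_dc1, self.bvd_dc2, self.bvd_dc3,
            self.faz_a_s, self.faz_a_d, self.faz_ci_s, self.faz_ci_d,
        ]
        out = {"subject_id": self.subject_id, "eye": self.eye}
        out.update(dict(zip(FEATURE_COLUMNS, vals)))
        return out


@dataclass
class RegionSpec:
    """Concentric annuli C1–C3 around the fovea, with the FAZ excluded.

    ``radii_mm`` are the ring boundaries (default 0–1, 1–2, 2–3 mm radius,
    i.e. circles of diameter 2, 4 and 6 mm).  By default the regions are
    disjoint annuli; ``nested=True`` switches to nested disks.
    """

    center: tuple[float, float]  # (row, col) in pixels
    radii_mm: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    exclusion_mask: np.ndarray | None = None
    nested: bool = False

    def region_masks(self, shape: tuple[int, int], mm_per_pixel: float):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        dist_mm = np.hypot(rr - self.center[0], cc - self.center[1]) * mm_per_pixel
        masks = []
        for inner, outer in zip(self.radii_mm[:-1], self.radii_mm[1:]):
            lo = 0.0 if self.nested else inner
            m = (dist_mm >= lo) & (dist_mm < outer)
            if self.exclusion_mask is not None:
                m &= ~self.exclusion_mask.astype(bool)
            masks.append(m)
        return masks


# ---------------------------------------------------------------------------
# individual features


def compute_bvt(branches: list[SkeletonBranch]) -> float:
    """Mean geodesic/Euclidean length ratio over vessel branches.

    Closed loops (coincident endpoints, Euclidean length 0) have no
    defined ratio and are excluded with a log entry.
    """
    if not branches:
        raise UndefinedFeatureError("BVT undefined: no vessel branches")
    ratios = [b.tortuosity for b in branches if b.euclidean_length > 0]
    n_loops = len(branches) - len(ratios)
    if n_loops:
        logger.info("BVT: excluded %d closed-loop branches", n_loops)
    if not ratios:
        raise UndefinedFeatureError("BVT undefined: all branches are loops")
    return float(np.mean(ratios))


def compute_bvc(
    vessel_mask: np.ndarray, skeleton_mask: np.ndarray, mm_per_pixel: float
) -> float:
    """Average vessel caliber in µm: vascular area / centerline length.

    The area comes from the vessel map (pixel count times pixel area) and
    the length from the skeleton map (8-connected path length times pixel
    pitch).
    """
    skel = skeleton_mask.astype(bool)
    if not skel.any():
        raise UndefinedFeatureError("BVC undefined: empty skeleton")
    pitch_um = mm_per_pixel * 1000.0
    area_um2 = float(vessel_mask.astype(bool).sum()) * pitch_um**2
    length_um = _skeleton_length_px(skel) * pitch_um
    return area_um2 / length_um


def _skeleton_length_px(skel: np.ndarray) -> float:
    """8-connected total path length of a skeleton, in pixels.

    Each pair of 8-adjacent skeleton pixels contributes one step (1 for
    orthogonal, sqrt(2) for diagonal), plus one per connected component so
    an n-pixel straight line measures n (pixel-count convention); isolated
    pixels then measure 1 and area/length stays bounded.
    """
    from scipy import ndimage

    s = skel.astype(bool)
    ortho = (s[:, :-1] & s[:, 1:]).sum() + (s[:-1, :] & s[1:, :]).sum()
    diag = (s[:-1, :-1] & s[1:, 1:]).sum() + (s[:-1, 1:] & s[1:, :-1]).sum()
    _, n_comp = ndimage.label(s, structure=np.ones((3, 3), int))
    return float(ortho) + seg.SQRT2 * float(diag) + float(n_comp)


def compute_vpi(perimeter_mask: np.ndarray) -> float:
    """Vessel perimeter area over total image area."""
    m = perimeter_mask.astype(bool)
    return float(m.sum()) / m.size


def compute_bvd(
    fd_map: np.ndarray,
    region: RegionSpec,
    mm_per_pixel: float,
    fd_threshold: float = 0.7,
) -> dict[str, float]:
    """Vessel density per circular region from the FD map.

    A pixel counts as vascular when its local fractal dimension is at
    least ``fd_threshold`` (default 0.7).  For each region the density is
    vascular pixels / all pixels, both counted outside the FAZ exclusion
    mask.
    """
    if not (0.0 < fd_threshold < 1.0):
        raise ValueError("fd_threshold must lie in (0, 1)")
    vascular = fd_map >= fd_threshold
    out = {}
    for name, m in zip(
        ("c1", "c2", "c3"), region.region_masks(fd_map.shape, mm_per_pixel)
    ):
        total = int(m.sum())
        if total == 0:
            raise UndefinedFeatureError(
                f"BVD undefined for region {name}: region empty after FAZ exclusion"
            )
        out[name] = float((vascular & m).sum()) / total
    return out


def compute_faz_area(faz: FazResult, mm_per_pixel: float) -> float:
    """FAZ area in µm²: pixel count times single-pixel area."""
    n = int(faz.mask.astype(bool).sum())
    if n == 0:
        raise UndefinedFeatureError("FAZ-A undefined: empty FAZ mask")
    return n * (mm_per_pixel * 1000.0) ** 2


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:-1, 0], poly[:-1, 1]
    xn, yn = poly[1:, 0], poly[1:, 1]
    return 0.5 * abs(float(np.dot(x, yn) - np.dot(xn, y)))


def _polygon_perimeter(poly: np.ndarray) -> float:
    d = np.diff(poly, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _polygon_is_simple(poly: np.ndarray) -> bool:
    """Segment-pair self-intersection check on the closed polygon."""
    p = poly[:-1]
    n = len(p)
    if n < 4:
        return True
    a = p
    b = np.roll(p, -1, axis=0)
    d = b - a
    for i in range(n - 2):
        j0 = i + 2
        j1 = n - 1 if i == 0 else n  # skip the shared-vertex wraparound pair
        aj, dj = a[j0:j1], d[j0:j1]
        denom = d[i, 0] * dj[:, 1] - d[i, 1] * dj[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            diff = aj - a[i]
            t = (diff[:, 0] * dj[:, 1] - diff[:, 1] * dj[:, 0]) / denom
            u = (diff[:, 0] * d[i, 1] - diff[:, 1] * d[i, 0]) / denom
            hit = (denom != 0) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
        if hit.any():
            return False
    return True


def compute_faz_ci(faz: FazResult) -> float:
    """Contour irregularity: perimeter over that of the equal-area circle.

    Both perimeter and area come from the same sub-pixel contour polygon
    (shoelace area), so a circle gives exactly 1 and any other shape more
    (isoperimetric inequality).
    """
    poly = np.asarray(faz.contour, dtype=float)
    if len(poly) < 4 or not np.allclose(poly[0], poly[-1]):
        raise UndefinedFeatureError("FAZ-CI undefined: contour not closed")
    area = _polygon_area(poly)
    if area <= 0:
        raise UndefinedFeatureError("FAZ-CI undefined: zero contour area")
    if not _polygon_is_simple(poly):
        warnings.warn("FAZ contour self-intersects; FAZ-CI computed as-is",
                      stacklevel=2)
    return _polygon_perimeter(poly) / (2.0 * np.sqrt(np.pi * area))


# ---------------------------------------------------------------------------
# full chain


@dataclass
class ExtractionConfig:
    """Tunable parameters of the extraction chain with their defaults."""

    frangi_scales_px: tuple = (1, 2, 4, 8)
    threshold_window_px: int = 31
    threshold_offset: float = -0.02
    min_object_px: int = 20
    fd_window_px: int = 16
    fd_threshold: float = 0.7
    min_branch_px: int = 5
    background_scale_mm: float = 1.5
    region_radii_mm: tuple = (0.0, 1.0, 2.0, 3.0)
    nested_regions: bool = False
    faz_max_iter: int = 300
    keep_maps: bool = False


def _layer_maps(img: AngiogramImage, cfg: ExtractionConfig):
    pre = preprocess(img, cfg.background_scale_mm)
    maps = seg.build_vessel_maps(
        pre,
        scales_px=cfg.frangi_scales_px,
        window_px=cfg.threshold_window_px,
        min_object_px=cfg.min_object_px,
        offset=cfg.threshold_offset,
        fd_window_px=cfg.fd_window_px,
    )
    faz = seg.segment_faz(pre, maps.vessel_mask, max_iter=cfg.faz_max_iter)
    return pre, maps, faz


def _bvd_for_layer(
    img: AngiogramImage, maps: VesselMapSet, faz: FazResult, cfg: ExtractionConfig
):
    center = faz.centroid if faz.mask.any() else (
        img.height_px / 2.0, img.width_px / 2.0
    )
    region = RegionSpec(
        center=center,
        radii_mm=cfg.region_radii_mm,
        exclusion_mask=faz.mask,
        nested=cfg.nested_regions,
    )
    return compute_bvd(maps.fd_map, region, img.mm_per_pixel, cfg.fd_threshold)


def extract_all_features(
    scp: AngiogramImage,
    dcp: AngiogramImage | None = None,
    config: ExtractionConfig | None = None,
    subject_id: str = "",
    eye: str = "",
) -> FeatureVector:
    """Run the full chain on an SCP/DCP pair and return the 13 features.

    Tortuosity, caliber and perimeter index are SCP-only; vessel density
    (three regions), FAZ area and FAZ contour irregularity come from both
    layers.  A missing DCP yields a partial vector flagged ``incomplete``.
    """
    cfg = config or ExtractionConfig()
    fv = FeatureVector(subject_id=subject_id, eye=eye)

    _, maps_s, faz_s = _layer_maps(scp, cfg)
    branches = seg.extract_branches(maps_s.skeleton_mask, cfg.min_branch_px)
    fv.bvt_s = compute_bvt(branches)
    fv.bvc_s = compute_bvc(maps_s.vessel_mask, maps_s.skeleton_mask, scp.mm_per_pixel)
    fv.vpi_s = compute_vpi(maps_s.perimeter_mask)
    bvd_s = _bvd_for_layer(scp, maps_s, faz_s, cfg)
    fv.bvd_sc1, fv.bvd_sc2, fv.bvd_sc3 = bvd_s["c1"], bvd_s["c2"], bvd_s["c3"]
    fv.faz_a_s = compute_faz_area(faz_s, scp.mm_per_pixel)
    fv.faz_ci_s = compute_faz_ci(faz_s)

    if dcp is None:
        fv.incomplete = True
        return fv

    _, maps_d, faz_d = _layer_maps(dcp, cfg)
    bvd_d = _bvd_for_layer(dcp, maps_d, faz_d, cfg)
    fv.bvd_dc1, fv.bvd_dc2, fv.bvd_dc3 = bvd_d["c1"], bvd_d["c2"], bvd_d["c3"]
    fv.faz_a_d = compute_faz_area(faz_d, dcp.mm_per_pixel)
    fv.faz_ci_d = compute_faz_ci(faz_d)
    return fv
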