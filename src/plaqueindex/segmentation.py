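"""Semi-automatic aorta/plaque segmentation and plaque-index volumetry.

The procedure mirrors the three-phase clinical workflow:

1. a region of interest around the aorta is selected (``ct_io.crop_to_roi``);
2. the aorta is contoured sparsely (one closed polygon every N slices) and
   the contours are interpolated into a tubular mask via shape-based
   interpolation — linear blending of signed distance transforms;
3. lumen and calcified plaque are segmented by a region-growing flood fill
   constrained to the tube, with two disjoint Hounsfield bands (the lower
   band for contrast-enhanced lumen, the upper for calcium), which makes
   lumen/plaque overlap structurally impossible.

The plaque index is then ``API = 100 * V_plaque / (V_lumen + V_plaque)``
with volumes from voxel counts times the voxel volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import draw, measure

from .ct_io import CTVolume, MaskVolume

__all__ = [
    "SegmentationError",
    "ContourSet",
    "TubularMask",
    "SegmentationParams",
    "SegmentationResult",
    "APIResult",
    "interpolate_contours",
    "auto_keyframe_contours",
    "region_grow",
    "segment_aorta_plaque",
    "compute_api",
    "read_contours",
    "write_contours",
]


class SegmentationError(ValueError):
    pass


@dataclass
class ContourSet:
    """Sparse per-slice closed polygons outlining the aorta.

    ``contours`` is a list of ``(slice_index, vertices)`` where vertices is
    an (n, 2) float array in (y, x) voxel coordinates. Slice indices must be
    strictly increasing; polygons must be simple with >= 3 vertices.
    """

    contours: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.contours) < 2:
            raise SegmentationError("need at least 2 keyframe contours")
        ks = [k for k, _ in self.contours]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise SegmentationError(f"keyframe slice indices must be strictly increasing: {ks}")
        norm = []
        for k, verts in self.contours:
            verts = np.asarray(verts, float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise SegmentationError(f"contour at slice {k} needs >= 3 (y,x) vertices")
            poly = Polygon(verts)
            if not poly.is_valid or poly.area == 0:
                raise SegmentationError(f"contour at slice {k} is self-intersecting or degenerate")
            norm.append((int(k), verts))
        self.contours = norm

    @property
    def keyframes(self) -> list[int]:
        return [k for k, _ in self.contours]


@dataclass
class TubularMask:
    """Binary tube covering the interpolated aortic cross-sections."""

    mask: MaskVolume
    contours: ContourSet


@dataclass(frozen=True)
class SegmentationParams:
    """Dual-Hounsfield-band region-growing parameters.

    The lumen band ``[t_lumen_lo, t_lumen_hi)`` and the plaque band
    ``[t_plaque_lo, inf)`` must be disjoint (``t_lumen_hi <= t_plaque_lo``),
    which is what guarantees disjoint lumen/plaque masks. The defaults are
    full-width-half-maximum cuts for contrast CT — midpoints between soft
    tissue (~30 HU) and enhanced lumen (~250 HU), and between lumen and
    calcium (~700 HU) — which makes thresholded volumes first-order
    insensitive to partial-volume blur. The tube is dilated by
    ``dilation_margin`` voxels as the plaque growth constraint so mural
    calcium protruding slightly past the drawn contour is captured.
    """

    t_lumen_lo: float = 140.0
    t_lumen_hi: float = 475.0
    t_plaque_lo: float = 475.0
    connectivity: int = 6
    dilation_margin: int = 2

    def __post_init__(self) -> None:
        if not self.t_lumen_lo < self.t_lumen_hi <= self.t_plaque_lo:
            raise SegmentationError(
                "need t_lumen_lo < t_lumen_hi <= t_plaque_lo (disjoint bands), got "
                f"{self.t_lumen_lo}, {self.t_lumen_hi}, {self.t_plaque_lo}"
            )
        if self.connectivity not in (6, 26):
            raise SegmentationError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.dilation_margin < 0:
            raise SegmentationError("dilation margin must be >= 0")


@dataclass
class SegmentationResult:
    lumen: MaskVolume
    plaque: MaskVolume
    params: SegmentationParams

    def __post_init__(self) -> None:
        if self.lumen.shape != self.plaque.shape:
            raise SegmentationError("lumen and plaque masks must share a shape")
        if np.any(self.lumen.voxels & self.plaque.voxels):
            raise SegmentationError("lumen and plaque masks overlap")


@dataclass(frozen=True)
class APIResult:
    """Volumes (mm^3) and the plaque index in percent."""

    lumen_mm3: float
    plaque_mm3: float

    @property
    def total_mm3(self) -> float:
        return self.lumen_mm3 + self.plaque_mm3

    @property
    def api_percent(self) -> float:
        return 100.0 * self.plaque_mm3 / self.total_mm3

    def to_dict(self) -> dict:
        return {
            "lumen_mm3": self.lumen_mm3,
            "plaque_mm3": self.plaque_mm3,
            "total_mm3": self.total_mm3,
            "api_percent": self.api_percent,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# contour interpolation


def _rasterize(verts: np.ndarray, shape2d: tuple[int, int]) -> np.ndarray:
    rr, cc = draw.polygon(verts[:, 0], verts[:, 1], shape=shape2d)
    m = np.zeros(shape2d, dtype=bool)
    m[rr, cc] = True
    return m


def _sdf(mask2d: np.ndarray) -> np.ndarray:
    """Signed distance, positive inside."""
    inside = ndimage.distance_transform_edt(mask2d)
    outside = ndimage.distance_transform_edt(~mask2d)
    return inside - outside


def _largest_component(mask2d: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask2d)
    if n <= 1:
        return mask2d
    sizes = ndimage.sum_labels(mask2d, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def interpolate_contours(
    contours: ContourSet, vol_shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> TubularMask:
    """Shape-based interpolation of sparse contours into a tubular mask.

    Keyframe slices take the rasterised polygon interior; intermediate
    slices take the zero superlevel set of the linear blend of the two
    flanking signed distance transforms, after aligning both keyframe
    shapes on the linearly interpolated centroid (so a translating
    cross-section interpolates as a moving shape rather than fading out).
    Slices outside the keyframe range stay empty; each nonzero slice is
    reduced to its largest connected region so the tube is a single channel
    per slice.
    """
    nz, ny, nx = vol_shape
    ks = contours.keyframes
    if ks[-1] >= nz:
        raise SegmentationError(f"keyframe slice {ks[-1]} outside volume with nz={nz}")
    key_masks = {k: _rasterize(v, (ny, nx)) for k, v in contours.contours}
    for k, m in key_masks.items():
        if not m.any():
            raise SegmentationError(f"contour at slice {k} rasterises to an empty region")
    key_sdf = {k: _sdf(m) for k, m in key_masks.items()}

    key_centroid = {
        k: np.array(ndimage.center_of_mass(m)) for k, m in key_masks.items()
    }

    out = np.zeros(vol_shape, dtype=bool)
    for k, m in key_masks.items():
        out[k] = _largest_component(m)
    for (ka, kb) in zip(ks, ks[1:]):
        fa, fb = key_sdf[ka], key_sdf[kb]
        ca, cb = key_centroid[ka], key_centroid[kb]
        for k in range(ka + 1, kb):
            w = (k - ka) / (kb - ka)
            c = (1.0 - w) * ca + w * cb
            # sample each keyframe SDF in its own frame, centred on the
            # interpolated centroid (order-1 shift, outside filled as "far")
            fa_c = ndimage.shift(fa, c - ca, order=1, mode="constant", cval=fa.min())
            fb_c = ndimage.shift(fb, c - cb, order=1, mode="constant", cval=fb.min())
            out[k] = _largest_component(((1.0 - w) * fa_c + w * fb_c) > 0)
    return TubularMask(
        mask=MaskVolume(voxels=out.astype(np.uint8), spacing=spacing),
        contours=contours,
    )


def auto_keyframe_contours(vol: CTVolume, stride: int = 10, hu_floor: float = 140.0) -> ContourSet:
    """Automatic sparse contouring for unattended runs and pre-seeding review.

    On every ``stride``-th slice (the last slice is always included, so a
    stride larger than the stack still yields first + last keyframes), the
    slice is thresholded at ``hu_floor``, the largest connected bright
    region is kept and its closed boundary polygon extracted.
    """
    if stride < 1:
        raise SegmentationError("stride must be >= 1")
    nz = vol.shape[0]
    if nz < 2:
        raise SegmentationError("need at least 2 slices to contour")
    ks = sorted(set(range(0, nz, stride)) | {nz - 1})
    contours = []
    for k in ks:
        bw = vol.voxels[k] >= hu_floor
        if not bw.any():
            raise SegmentationError(f"no region above {hu_floor} HU on slice {k}")
        region = _largest_component(bw)
        padded = np.pad(region.astype(float), 1)
        paths = measure.find_contours(padded, 0.5)
        if not paths:
            raise SegmentationError(f"could not trace a boundary on slice {k}")
        verts = max(paths, key=len) - 1.0  # undo padding offset
        # drop the duplicated closing vertex; decimate very dense boundaries
        verts = verts[:-1]
        if len(verts) > 256:
            verts = verts[:: len(verts) // 256 + 1]
        if len(verts) < 3:
            raise SegmentationError(f"degenerate boundary on slice {k}")
        contours.append((k, verts))
    return ContourSet(contours)


# ---------------------------------------------------------------------------
# region growing


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def _grow_from_seed_mask(
    vol: CTVolume,
    seed_mask: np.ndarray,
    hu_lo: float,
    hu_hi: float,
    constraint: np.ndarray,
    connectivity: int,
) -> np.ndarray:
    band = (vol.voxels >= hu_lo) & (vol.voxels < hu_hi) & constraint
    if not seed_mask.any():
        return np.zeros(vol.shape, dtype=bool)
    lab, n = ndimage.label(band, structure=_structure(connectivity))
    hit = np.unique(lab[seed_mask & band])
    hit = hit[hit > 0]
    return np.isin(lab, hit)


def region_grow(
    vol: CTVolume,
    seeds: list[tuple[int, int, int]],
    hu_lo: float,
    hu_hi: float,
    constraint: MaskVolume,
    connectivity: int = 6,
) -> MaskVolume:
    """Flood fill from seeds through the half-open HU band ``[hu_lo, hu_hi)``.

    Growth uses face (6) or full (26) adjacency and never leaves
    ``constraint``. Every seed must lie inside the constraint and the band.
    """
    if connectivity not in (6, 26):
        raise SegmentationError(f"connectivity must be 6 or 26, got {connectivity}")
    if constraint.shape != vol.shape:
        raise SegmentationError("constraint shape must match volume shape")
    cons = constraint.voxels.astype(bool)
    seed_mask = np.zeros(vol.shape, dtype=bool)
    bad = []
    for s in seeds:
        k, j, i = s
        if not (0 <= k < vol.shape[0] and 0 <= j < vol.shape[1] and 0 <= i < vol.shape[2]):
            bad.append((tuple(s), "out of bounds"))
            continue
        hu = vol.voxels[k, j, i]
        if not cons[k, j, i]:
            bad.append((tuple(s), "outside constraint"))
        elif not (hu_lo <= hu < hu_hi):
            bad.append((tuple(s), f"HU {hu:.1f} outside [{hu_lo}, {hu_hi})"))
        else:
            seed_mask[k, j, i] = True
    if bad:
        raise SegmentationError(f"invalid seeds: {bad}")
    if not seeds:
        raise SegmentationError("at least one seed is required")
    grown = _grow_from_seed_mask(vol, seed_mask, hu_lo, hu_hi, cons, connectivity)
    return MaskVolume(voxels=grown.astype(np.uint8), spacing=vol.spacing, origin=vol.origin)


def segment_aorta_plaque(
    vol: CTVolume, tube: TubularMask, params: SegmentationParams = SegmentationParams()
) -> SegmentationResult:
    """Dual-band region growing of lumen and plaque inside the tube.

    The lumen grows in ``[t_lumen_lo, t_lumen_hi)`` seeded from every
    in-band voxel of the tube; the plaque grows in ``[t_plaque_lo, inf)``
    seeded likewise but constrained to the tube dilated by
    ``params.dilation_margin`` voxels. Band disjointness makes the two masks
    disjoint for every input.
    """
    if tube.mask.shape != vol.shape:
        raise SegmentationError("tube mask shape must match volume shape")
    tube_vox = tube.mask.voxels.astype(bool)
    v = vol.voxels

    lumen_seeds = tube_vox & (v >= params.t_lumen_lo) & (v < params.t_lumen_hi)
    if not lumen_seeds.any():
        raise SegmentationError(
            "no lumen seeds inside the tube — check HU thresholds and contours"
        )
    lumen = _grow_from_seed_mask(
        vol, lumen_seeds, params.t_lumen_lo, params.t_lumen_hi, tube_vox, params.connectivity
    )

    if params.dilation_margin > 0:
        dilated = ndimage.binary_dilation(
            tube_vox, structure=_structure(params.connectivity),
            iterations=params.dilation_margin,
        )
    else:
        dilated = tube_vox
    plaque_seeds = tube_vox & (v >= params.t_plaque_lo)
    plaque = _grow_from_seed_mask(
        vol, plaque_seeds, params.t_plaque_lo, np.inf, dilated, params.connectivity
    )

    mk = lambda m: MaskVolume(voxels=m.astype(np.uint8), spacing=vol.spacing, origin=vol.origin)
    return SegmentationResult(lumen=mk(lumen), plaque=mk(plaque), params=params)


def compute_api(seg: SegmentationResult, spacing: tuple[float, float, float] | None = None) -> APIResult:
    """Plaque index from voxel counts: API = 100 * Vp / (Vl + Vp) percent."""
    if spacing is None:
        spacing = seg.lumen.spacing
    sx, sy, sz = spacing
    vox = sx * sy * sz
    vl = float(seg.lumen.voxels.sum()) * vox
    vp = float(seg.plaque.voxels.sum()) * vox
    if vl + vp == 0:
        raise SegmentationError("empty segmentation: no aorta found")
    return APIResult(lumen_mm3=vl, plaque_mm3=vp)


# ---------------------------------------------------------------------------
# contour text format: one "k y x" line per vertex, blank line between contours


def write_contours(contours: ContourSet, path) -> None:
    with open(path, "w") as fh:
        for k, verts in contours.contours:
            for y, x in verts:
                fh.write(f"{k} {y:.4f} {x:.4f}\n")
            fh.write("\n")


def read_contours(path) -> ContourSet:
    groups: list[list[tuple[int, float, float]]] = [[]]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                if groups[-1]:
                    groups.append([])
                continue
            parts = line.split()
            if len(parts) != 3:
                raise SegmentationError(f"{path}: line {lineno}: expected 'k y x', got {line!r}")
            try:
                groups[-1].append((int(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise SegmentationError(f"{path}: line {lineno}: {exc}") from exc
    contours = []
    for g in groups:
        if not g:
            continue
        ks = {k for k, _, _ in g}
        if len(ks) != 1:
            raise SegmentationError(f"{path}: contour mixes slice indices {sorted(ks)}")
        contours.append((g[0][0], np.array([(y, x) for _, y, x in g])))
    return ContourSet(contours)
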