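"""Synthetic contrast-CT phantoms of the abdominal aorta with mural plaques.

The phantom is a tube of contrast-enhanced lumen running along the z axis of
the grid, its centreline a low-order polynomial ``(x(z), y(z))`` in mm, with
calcified plaques modelled as annular-arc solids attached to the inside of
the lumen wall (growing inward). Tissue Hounsfield values are drawn per
voxel, Gaussian pixel noise is added, and partial-volume blur is emulated by
a Gaussian filter. Ground-truth volumes always refer to the *continuous*
pre-blur solids, so segmentation accuracy tests face realistic boundary
blur.

The atherosclerotic plaque index of a phantom is

    API = 100 * V_plaque / (V_lumen + V_plaque)   [percent],

where lumen + plaque together make up the full vessel interior.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .ct_io import CTVolume

__all__ = [
    "PhantomError",
    "PlaqueSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "analytic_truth",
    "default_phantom_suite",
    "respace",
]

TWO_PI = 2.0 * np.pi


class PhantomError(ValueError):
    """Raised for geometrically or physically invalid phantom specs."""


@dataclass(frozen=True)
class PlaqueSpec:
    """A mural calcified plaque: an annular arc growing inward from the wall.

    ``z_mm`` is the axial extent, ``theta_rad`` the angular extent on the
    wall (anticlockwise from +x, wrap-around allowed via spans <= 2*pi),
    ``thickness_mm`` the radial depth measured inward from the lumen wall.
    """

    z_mm: tuple[float, float]
    theta_rad: tuple[float, float]
    thickness_mm: float
    hu_mean: float = 700.0
    hu_sd: float = 15.0

    def __post_init__(self) -> None:
        z0, z1 = self.z_mm
        t0, t1 = self.theta_rad
        if not z1 > z0:
            raise PhantomError(f"plaque axial extent must satisfy z1 > z0, got {self.z_mm}")
        if not 0.0 < (t1 - t0) <= TWO_PI:
            raise PhantomError(f"plaque angular span must lie in (0, 2*pi], got {self.theta_rad}")
        if self.thickness_mm <= 0:
            raise PhantomError("plaque thickness must be positive")

    @property
    def theta_span(self) -> float:
        return self.theta_rad[1] - self.theta_rad[0]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic aorta phantom.

    ``centerline_x`` / ``centerline_y`` are polynomial coefficients
    (ascending powers of z in mm, results in mm); ``radius_mm`` are
    coefficients of the lumen radius r(z) (constant or linear taper).
    ``smoothing_sigma_mm = None`` selects resolution-dependent partial-volume
    blur, 0.6 x max(spacing) (a point-spread FWHM of ~1.4 voxel pitches,
    typical of clinical CT reconstruction).
    """

    shape: tuple[int, int, int]  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (sx, sy, sz) mm
    centerline_x: tuple[float, ...] = (24.0,)
    centerline_y: tuple[float, ...] = (24.0,)
    radius_mm: tuple[float, ...] = (10.0,)
    lumen_hu: tuple[float, float] = (250.0, 10.0)  # mean, sd
    background_hu: tuple[float, float] = (30.0, 10.0)
    plaques: tuple[PlaqueSpec, ...] = ()
    smoothing_sigma_mm: float | None = None
    noise_sd_hu: float = 20.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        if min(nz, ny, nx) < 2:
            raise PhantomError(f"grid shape must be at least 2 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"spacing must be positive, got {self.spacing}")
        if self.smoothing_sigma_mm is not None and self.smoothing_sigma_mm < 0:
            raise PhantomError("smoothing sigma must be >= 0")
        if self.noise_sd_hu < 0:
            raise PhantomError("noise sd must be >= 0")
        for p in self.plaques:
            if not p.hu_mean > self.lumen_hu[0] > self.background_hu[0]:
                raise PhantomError(
                    "HU ordering violated: need plaque mean > lumen mean > background mean"
                )
        self._validate_geometry()

    # -- geometry helpers ---------------------------------------------------
    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size (Lz, Ly, Lx) of the grid in mm."""
        nz, ny, nx = self.shape
        sx, sy, sz = self.spacing
        return (nz * sz, ny * sy, nx * sx)

    def centerline(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cx = np.polynomial.polynomial.polyval(z, self.centerline_x)
        cy = np.polynomial.polynomial.polyval(z, self.centerline_y)
        return np.asarray(cx, float), np.asarray(cy, float)

    def radius(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(np.polynomial.polynomial.polyval(z, self.radius_mm), float)

    @property
    def sigma_mm(self) -> float:
        if self.smoothing_sigma_mm is not None:
            return self.smoothing_sigma_mm
        return 0.6 * max(self.spacing)

    def _validate_geometry(self) -> None:
        lz, ly, lx = self.extent_mm
        z = np.linspace(0.0, lz, 257)
        r = self.radius(z)
        if np.any(r <= 0):
            raise PhantomError("lumen radius must stay positive over the grid")
        cx, cy = self.centerline(z)
        if np.any(cx - r < 0) or np.any(cx + r > lx) or np.any(cy - r < 0) or np.any(cy + r > ly):
            raise PhantomError("lumen extends beyond the grid in-plane bounds")
        for p in self.plaques:
            z0, z1 = p.z_mm
            if z0 < 0 or z1 > lz:
                raise PhantomError(f"plaque axial extent {p.z_mm} outside grid [0, {lz}]")
            zp = np.linspace(z0, z1, 65)
            if np.any(p.thickness_mm >= self.radius(zp)):
                raise PhantomError("plaque thickness must be smaller than the lumen radius")

    # -- serialisation ------------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["plaques"] = [dataclasses.asdict(p) for p in self.plaques]
        return yaml.safe_dump(_listify(d), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        plaques = tuple(
            PlaqueSpec(
                z_mm=tuple(p["z_mm"]),
                theta_rad=tuple(p["theta_rad"]),
                thickness_mm=p["thickness_mm"],
                hu_mean=p.get("hu_mean", 700.0),
                hu_sd=p.get("hu_sd", 15.0),
            )
            for p in d.pop("plaques", [])
        )
        for key in ("shape", "spacing", "centerline_x", "centerline_y", "radius_mm",
                    "lumen_hu", "background_hu"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(plaques=plaques, **d)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth volumes of the continuous (pre-blur) phantom solids."""

    lumen_volume_mm3: float
    plaque_volume_mm3: float

    def __post_init__(self) -> None:
        if self.lumen_volume_mm3 < 0 or self.plaque_volume_mm3 < 0:
            raise PhantomError("truth volumes must be non-negative")

    @property
    def total_volume_mm3(self) -> float:
        return self.lumen_volume_mm3 + self.plaque_volume_mm3

    @property
    def api_percent(self) -> float:
        tot = self.total_volume_mm3
        return 0.0 if tot == 0 else 100.0 * self.plaque_volume_mm3 / tot


def _in_arc(theta: np.ndarray, t0: float, span: float) -> np.ndarray:
    return np.mod(theta - t0, TWO_PI) <= span


def analytic_truth(spec: PhantomSpec, supersample: int = 8) -> PhantomTruth:
    """Ground-truth volumes by occupancy counting on a supersampled grid.

    Counts sub-voxel centres inside the continuous lumen/plaque solids and
    multiplies by the sub-voxel volume; converges to the exact volumes as
    ``supersample`` grows (the estimate is independent of noise, blur, and
    voxel discretisation).
    """
    if supersample < 4:
        raise PhantomError("supersample must be >= 4")
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    s = int(supersample)
    zs = (np.arange(nz * s) + 0.5) * (sz / s)
    cx, cy = spec.centerline(zs)
    r = spec.radius(zs)

    # restrict in-plane sampling to the lumen's bounding box
    x_all = (np.arange(nx * s) + 0.5) * (sx / s)
    y_all = (np.arange(ny * s) + 0.5) * (sy / s)
    pad = float(r.max()) + max(sx, sy)
    xs = x_all[(x_all >= cx.min() - pad) & (x_all <= cx.max() + pad)]
    ys = y_all[(y_all >= cy.min() - pad) & (y_all <= cy.max() + pad)]

    sub_vol = (sx / s) * (sy / s) * (sz / s)
    lumen_count = 0
    plaque_count = 0
    for k in range(len(zs)):
        dx = xs[None, :] - cx[k]
        dy = ys[:, None] - cy[k]
        d2 = dx * dx + dy * dy
        inside = d2 <= r[k] * r[k]
        plaque_here = np.zeros_like(inside)
        for p in spec.plaques:
            z0, z1 = p.z_mm
            if not (z0 <= zs[k] <= z1):
                continue
            rin = r[k] - p.thickness_mm
            theta = np.arctan2(dy, dx)
            plaque_here |= (
                inside & (d2 >= rin * rin) & _in_arc(theta, p.theta_rad[0], p.theta_span)
            )
        plaque_count += int(plaque_here.sum())
        lumen_count += int((inside & ~plaque_here).sum())
    return PhantomTruth(
        lumen_volume_mm3=lumen_count * sub_vol,
        plaque_volume_mm3=plaque_count * sub_vol,
    )


def generate_phantom(spec: PhantomSpec, supersample_truth: int = 8) -> tuple[CTVolume, PhantomTruth]:
    """Render the phantom to a :class:`CTVolume` and return it with its truth.

    Deterministic given ``spec.seed``. Voxel HU = tissue mean + Gaussian
    noise (tissue sd and global pixel noise combined), then Gaussian-blurred
    with ``spec.sigma_mm`` to emulate partial volume.
    """
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    rng = np.random.default_rng(spec.seed)

    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy
    xc = (np.arange(nx) + 0.5) * sx
    cx, cy = spec.centerline(zc)
    r = spec.radius(zc)

    dx = xc[None, None, :] - cx[:, None, None]
    dy = yc[None, :, None] - cy[:, None, None]
    d2 = dx * dx + dy * dy
    inside = d2 <= (r ** 2)[:, None, None]

    mean = np.full(spec.shape, spec.background_hu[0])
    sd = np.full(spec.shape, spec.background_hu[1])
    mean[inside] = spec.lumen_hu[0]
    sd[inside] = spec.lumen_hu[1]

    if spec.plaques:
        theta = np.arctan2(dy, dx)
        for p in spec.plaques:
            z0, z1 = p.z_mm
            zsel = (zc >= z0) & (zc <= z1)
            rin = (r - p.thickness_mm)[:, None, None]
            m = (
                inside
                & zsel[:, None, None]
                & (d2 >= rin * rin)
                & _in_arc(theta, p.theta_rad[0], p.theta_span)
            )
            mean[m] = p.hu_mean
            sd[m] = p.hu_sd

    total_sd = np.sqrt(sd ** 2 + spec.noise_sd_hu ** 2)
    hu = mean + rng.standard_normal(spec.shape) * total_sd
    sigma = spec.sigma_mm
    if sigma > 0:
        hu = gaussian_filter(hu, sigma=(sigma / sz, sigma / sy, sigma / sx))

    vol = CTVolume(voxels=hu.astype(np.float32), spacing=spec.spacing)
    return vol, analytic_truth(spec, supersample=supersample_truth)


def respace(spec: PhantomSpec, spacing: tuple[float, float, float]) -> PhantomSpec:
    """Re-sample the same physical phantom at a different voxel spacing.

    The physical extents, centreline, radius and plaques are unchanged (so
    the ground truth is identical); only the grid changes. Extents must be
    integer multiples of the new spacing.
    """
    lz, ly, lx = spec.extent_mm
    sx, sy, sz = spacing
    shape = (round(lz / sz), round(ly / sy), round(lx / sx))
    for got, want, s in zip((shape[0] * sz, shape[1] * sy, shape[2] * sx), (lz, ly, lx), spacing):
        if abs(got - want) > 1e-9:
            raise PhantomError(f"extent {want} mm is not a multiple of spacing {s} mm")
    return dataclasses.replace(spec, shape=shape, spacing=spacing)


def default_phantom_suite() -> list[tuple[PhantomSpec, PhantomTruth]]:
    """Named phantoms spanning the clinically salient API range ~{0,2,5,10,20}%.

    All use a 48x48x80 mm grid at 1 mm isotropic spacing, a gently curved
    centreline and a 10 mm lumen radius; plaque arcs/thicknesses were solved
    against the annular-sector closed form so the target API values are
    exact for the continuous solids. Truth is reported by the supersampling
    oracle (supersample 8).
    """
    base = dict(
        shape=(80, 48, 48),
        spacing=(1.0, 1.0, 1.0),
        centerline_x=(24.0, 0.1, -0.00125),  # 2 mm bow at mid-stack
        centerline_y=(24.0, 0.05, -0.000625),
        radius_mm=(10.0,),
    )
    specs = [
        PhantomSpec(name="api00", seed=11, **base),
        PhantomSpec(
            name="api02", seed=12,
            plaques=(PlaqueSpec(z_mm=(20.0, 50.0), theta_rad=(0.3, 0.3 + np.pi / 2),
                                thickness_mm=1.131),),
            **base,
        ),
        PhantomSpec(
            name="api05", seed=13,
            plaques=(PlaqueSpec(z_mm=(18.0, 58.0), theta_rad=(2.0, 2.0 + np.pi / 2),
                                thickness_mm=2.254),),
            **base,
        ),
        PhantomSpec(
            name="api10", seed=14,
            plaques=(PlaqueSpec(z_mm=(20.0, 60.0), theta_rad=(1.0, 1.0 + np.pi),
                                thickness_mm=2.254),),
            **base,
        ),
        PhantomSpec(
            name="api20", seed=15,
            plaques=(
                PlaqueSpec(z_mm=(20.0, 60.0), theta_rad=(0.5, 0.5 + np.pi), thickness_mm=4.0),
                PlaqueSpec(z_mm=(25.0, 57.0), theta_rad=(4.0, 4.0 + np.pi / 2),
                           thickness_mm=2.254),
            ),
            **base,
        ),
    ]
    return [(s, analytic_truth(s, supersample=8)) for s in specs]
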