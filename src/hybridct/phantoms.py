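"""Digital phantoms: material-concentration maps on a voxel grid.

Three generators cover the study objects: an iodine-vials phantom for
linearity/CNR work, a resolution bar-pattern phantom, and a seeded
"brain in a PBS-filled vial" phantom for artifact-correction and
reconstruction studies. All phantoms are (nx, ny, nz) arrays with isotropic
voxels; axial planes are ``[:, :, k]`` and the in-plane origin is the grid
center. PBS is modeled as water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spectra import MATERIALS

#: natural densities (g/mL) used when a solid material fills a structure
SOLID_DENSITY = {"water": 1.0, "acrylic": 1.19, "aluminum": 2.699, "calcium": 1.55}


@dataclass
class DigitalPhantom:
    """Voxelized per-material concentration maps plus an integer label map.

    Water-like materials are in g/mL, iodine in mg/mL. ``label_map`` uses
    0 for background; ``meta`` carries generator bookkeeping (e.g. the drawn
    per-region iodine concentrations).
    """

    materials: dict
    voxel_size: float  # mm, isotropic
    label_map: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m: a.shape for m, a in self.materials.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"material maps disagree in shape: {shapes}")
        for name, arr in self.materials.items():
            if name not in MATERIALS:
                raise ValueError(f"unknown material {name!r}")
            if np.any(arr < 0):
                raise ValueError(f"negative concentrations in {name!r} map")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.label_map is not None:
            if self.label_map.shape != self.shape:
                raise ValueError("label_map shape mismatch")
            if not np.issubdtype(self.label_map.dtype, np.integer):
                raise ValueError("label_map must be integer")
            if self.label_map.min() < 0:
                raise ValueError("label IDs must be non-negative")

    @property
    def shape(self) -> tuple:
        return next(iter(self.materials.values())).shape

    def get(self, material: str) -> np.ndarray:
        """Concentration map for ``material`` (zeros if absent)."""
        if material in self.materials:
            return self.materials[material]
        return np.zeros(self.shape)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane physical coordinates (mm) of voxel centers, origin at center."""
        nx, ny = self.shape[:2]
        x = (np.arange(nx) - (nx - 1) / 2) * self.voxel_size
        y = (np.arange(ny) - (ny - 1) / 2) * self.voxel_size
        return np.meshgrid(x, y, indexing="ij")


def _disk(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
          radius: float) -> np.ndarray:
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _extrude(mask2d: np.ndarray, nz: int) -> np.ndarray:
    return np.repeat(mask2d[:, :, None], nz, axis=2)


def make_vials_phantom(concentrations, grid_size: int = 128,
                       voxel_size: float = 0.1, nz: int = 1,
                       vial_radius_mm: float | None = None,
                       ring_radius_mm: float | None = None) -> DigitalPhantom:
    """Water vial plus one iodine-in-water vial per requested concentration.

    Vials are parallel cylinders: the water vial plus ``len(concentrations)``
    iodine vials, arranged on a ring (single vial sits at the center). Labels
    are 1 for the water vial, then 2.. in concentration order.
    """
    concs = [float(c) for c in concentrations]
    if any(c < 0 for c in concs):
        raise ValueError("iodine concentrations must be >= 0")
    fov = grid_size * voxel_size
    r_vial = vial_radius_mm if vial_radius_mm is not None else 0.09 * fov
    n_vials = 1 + len(concs)
    if n_vials == 1:
        centers = [(0.0, 0.0)]
    else:
        r_ring = ring_radius_mm if ring_radius_mm is not None else 0.30 * fov
        ang = 2 * np.pi * np.arange(n_vials) / n_vials
        centers = [(r_ring * np.cos(a), r_ring * np.sin(a)) for a in ang]
        # overlap / out-of-grid geometry checks
        min_sep = 2 * r_ring * np.sin(np.pi / n_vials)
        if min_sep <= 2 * r_vial:
            raise ValueError(
                f"{n_vials} vials of radius {r_vial:.2f} mm overlap on a "
                f"ring of radius {r_ring:.2f} mm")
        if r_ring + r_vial >= fov / 2:
            raise ValueError("vial ring does not fit inside the grid")

    shape2d = (grid_size, grid_size)
    x = (np.arange(grid_size) - (grid_size - 1) / 2) * voxel_size
    xx, yy = np.meshgrid(x, x, indexing="ij")
    water = np.zeros(shape2d)
    iodine = np.zeros(shape2d)
    labels = np.zeros(shape2d, dtype=np.int32)
    for i, (cx, cy) in enumerate(centers):
        mask = _disk(xx, yy, cx, cy, r_vial)
        water[mask] = 1.0
        labels[mask] = i + 1
        if i > 0:
            iodine[mask] = concs[i - 1]
    return DigitalPhantom(
        materials={"water": _extrude(water, nz).astype(float),
                   "iodine": _extrude(iodine, nz).astype(float)},
        voxel_size=voxel_size,
        label_map=_extrude(labels, nz).astype(np.int32),
        meta={"concentrations_mg_ml": concs, "vial_radius_mm": r_vial,
              "centers_mm": centers})


def make_bar_pattern_phantom(frequencies, bar_material: str = "aluminum",
                             grid_size: int = 256, voxel_size: float = 0.022,
                             nz: int = 1) -> DigitalPhantom:
    """Resolution phantom: bar groups of alternating material/substrate.

    Each requested spatial frequency (lp/mm) gets a horizontal band of bars
    alternating along x inside an acrylic substrate block. A frequency whose
    half-period falls below one voxel is not representable and raises.
    """
    freqs = [float(f) for f in frequencies]
    if not freqs:
        raise ValueError("at least one bar frequency required")
    for f in freqs:
        if 1.0 / (2 * f) < voxel_size:
            raise ValueError(
                f"bar frequency {f} lp/mm exceeds the grid Nyquist limit "
                f"({1 / (2 * voxel_size):.2f} lp/mm)")
    if bar_material not in SOLID_DENSITY and bar_material != "iodine":
        raise ValueError(f"no density known for bar material {bar_material!r}")

    shape2d = (grid_size, grid_size)
    x = (np.arange(grid_size) - (grid_size - 1) / 2) * voxel_size
    xx, yy = np.meshgrid(x, x, indexing="ij")
    fov = grid_size * voxel_size
    block_half = 0.40 * fov
    block = (np.abs(xx) <= block_half) & (np.abs(yy) <= block_half)

    substrate = np.where(block, SOLID_DENSITY["acrylic"], 0.0)
    bars = np.zeros(shape2d)
    labels = np.zeros(shape2d, dtype=np.int32)
    band_h = 2 * block_half / len(freqs)
    bar_value = SOLID_DENSITY.get(bar_material, 10.0)
    for gi, f in enumerate(freqs):
        y_lo = -block_half + gi * band_h
        band = block & (yy >= y_lo + 0.15 * band_h) & (yy < y_lo + 0.85 * band_h)
        # bars occupy alternating half-periods of width 1/(2f) along x
        phase = np.floor((xx + fov) * 2 * f).astype(int) % 2 == 0
        sel = band & phase & (np.abs(xx) <= 0.8 * block_half)
        bars[sel] = bar_value
        substrate[sel] = 0.0
        labels[band & (np.abs(xx) <= 0.8 * block_half)] = gi + 1

    materials = {"acrylic": _extrude(substrate, nz).astype(float)}
    key = bar_material if bar_material != "acrylic" else "aluminum"
    materials[key] = _extrude(bars, nz).astype(float)
    return DigitalPhantom(
        materials=materials, voxel_size=voxel_size,
        label_map=_extrude(labels, nz).astype(np.int32),
        meta={"frequencies_lp_mm": freqs, "bar_material": bar_material,
              "band_height_mm": band_h, "block_half_mm": block_half})


def make_brain_vial_phantom(seed: int, grid_size: int = 128,
                            voxel_size: float = 0.1, nz: int = 1,
                            n_regions: int = 5,
                            mirror_symmetric: bool = False,
                            vial_radius_mm: float | None = None,
                            mean_iodine: float = 6.0, sd_iodine: float = 1.5,
                            texture_sd: float = 0.02,
                            include_brain: bool = True) -> DigitalPhantom:
    """Seeded stained-brain-in-PBS-vial phantom.

    An outer water cylinder (the PBS-filled vial) contains a smooth ellipsoidal
    "brain" split into ``n_regions`` concentric elliptical shells, each with a
    distinct iodine concentration drawn from N(mean_iodine, sd_iodine) mg/mL
    (clipped at 0.5). Brain water density carries a smooth random texture
    emulating tissue heterogeneity. ``include_brain=False`` yields the matching
    PBS-only vial used for gain-ratio calibration scans.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    fov = grid_size * voxel_size
    r_vial = vial_radius_mm if vial_radius_mm is not None else 0.42 * fov

    x = (np.arange(grid_size) - (grid_size - 1) / 2) * voxel_size
    xx, yy = np.meshgrid(x, x, indexing="ij")
    vial = _disk(xx, yy, 0.0, 0.0, r_vial)
    water2d = np.where(vial, 1.0, 0.0)
    iodine2d = np.zeros_like(water2d)
    labels2d = np.zeros(water2d.shape, dtype=np.int32)

    drawn = []
    if include_brain:
        a, b = 0.62 * r_vial, 0.72 * r_vial  # brain semi-axes, mm
        rho = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
        drawn = np.clip(rng.normal(mean_iodine, sd_iodine, n_regions),
                        0.5, None).tolist()
        edges = np.sqrt(np.linspace(0, 1, n_regions + 1))  # equal-area shells
        for k in range(n_regions):
            shell = (rho > edges[k]) & (rho <= edges[k + 1])
            iodine2d[shell] = drawn[k]
            labels2d[shell] = k + 1
        texture = ndimage.gaussian_filter(rng.standard_normal(water2d.shape), 2.0)
        texture /= max(texture.std(), 1e-12)
        water2d = np.where(rho <= 1.0,
                           1.0 + texture_sd * texture, water2d)
    if mirror_symmetric:
        half = grid_size // 2
        for arr in (water2d, iodine2d, labels2d):
            arr[grid_size - half:, :] = arr[half - 1::-1, :]
    water2d = np.clip(water2d, 0.0, None)

    return DigitalPhantom(
        materials={"water": _extrude(water2d, nz).astype(float),
                   "iodine": _extrude(iodine2d, nz).astype(float)},
        voxel_size=voxel_size,
        label_map=_extrude(labels2d, nz).astype(np.int32),
        meta={"seed": seed, "region_iodine_mg_ml": drawn,
              "vial_radius_mm": r_vial, "n_regions": n_regions,
              "include_brain": include_brain})
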