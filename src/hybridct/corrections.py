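"""Projection-domain corrections for PCD tile artifacts and EID beam hardening.

Tile (band/ring) correction is multiplicative, calibrated from a scan of the
PBS-filled vial alone: (1) reconstruct the PBS scan and replace it with an
idealized uniform cylinder, (2) forward-project the ideal vial, (3) divide
ideal by real counts to form a gain-ratio projection (median-filtered, with
out-of-PBS columns replaced by their nearest in-PBS neighbor), (4) multiply
sample projections by the ratio. Because all samples share the vial and
trajectory, one ratio corrects every scan.

Beam hardening in EID data is corrected by a per-detector-row second-degree
polynomial mapping log-normalized intensity to acrylic-equivalent thickness,
calibrated from slab scans of known acrylic/aluminum thickness and rescaled
by the attenuation of 1 mm of acrylic at the spectrum's effective energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import DetectorModel, ScanGeometry
from .phantoms import SOLID_DENSITY
from .projector import MM_TO_CM, Projector
from .recon import wfbp_reconstruct
from .simulate import ProjectionSet, log_normalize, unlog
from .spectra import EnergyGrid, MaterialTable, effective_energy


@dataclass
class GainRatioProjection:
    """Multiplicative per-pixel correction ratios (ideal / real PBS counts)."""

    ratios: dict                  # channel -> (views, rows, cols), > 0
    median_size: tuple
    column_mask: np.ndarray       # True where the column crosses the PBS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, r in self.ratios.items():
            if not np.all(np.isfinite(r)) or np.any(r <= 0):
                raise ValueError(f"ratio for {label} must be positive/finite")


@dataclass
class BeamHardeningModel:
    """Per-row degree-2 polynomial p -> acrylic-equivalent thickness (mm).

    ``coeffs[row] = (a, b, c)`` with thickness = a p^2 + b p + c, and
    ``mu_ref_per_mm`` the reference attenuation of 1 mm acrylic (at the
    detected spectrum's effective energy) used to rescale thickness back to
    an attenuation line integral.
    """

    coeffs: np.ndarray            # (n_rows, 3)
    mu_ref_per_mm: float
    effective_kev: float
    meta: dict = field(default_factory=dict)

    def thickness(self, p: np.ndarray) -> np.ndarray:
        """Evaluate the per-row polynomial on (views, rows, cols) data."""
        a = self.coeffs[:, 0][None, :, None]
        b = self.coeffs[:, 1][None, :, None]
        c = self.coeffs[:, 2][None, :, None]
        return a * p**2 + b * p + c


# --------------------------------------------------------------------------
# PBS gain-ratio correction
# --------------------------------------------------------------------------

def fit_uniform_cylinder(vol: np.ndarray, voxel_mm: float) -> tuple:
    """Fit (center_x, center_y, radius_mm, interior_value) to a cylinder.

    Works on the z-averaged slice: threshold at half the bright level, take
    the center of mass and equivalent-area radius, then the median interior
    value inside 80% of the fitted radius.
    """
    sl = vol.mean(axis=2)
    level = np.percentile(sl, 99)
    mask = sl > 0.5 * level
    if level <= 0 or mask.sum() < 16:
        raise ValueError("cylinder fit failed: no circular structure found")
    ix, iy = np.nonzero(mask)
    cx, cy = float(ix.mean()), float(iy.mean())
    radius_mm = np.sqrt(mask.sum() / np.pi) * voxel_mm
    xx, yy = np.meshgrid(np.arange(sl.shape[0]), np.arange(sl.shape[1]),
                         indexing="ij")
    interior = (xx - cx) ** 2 + (yy - cy) ** 2 <= (0.8 * radius_mm / voxel_mm) ** 2
    mu = float(np.median(sl[interior]))
    return cx, cy, radius_mm, mu


def build_ideal_pbs_projection(pbs_scan: ProjectionSet,
                               projector: Projector | None = None,
                               n_pix: int | None = None,
                               voxel_mm: float | None = None) -> ProjectionSet:
    """Reconstruct the PBS-only scan, idealize it as a uniform cylinder per
    channel, and forward-project the ideal vial on the same geometry."""
    scan = pbs_scan if pbs_scan.domain == "log_normalized" else log_normalize(pbs_scan)
    g = scan.geometry
    if projector is None:
        n_pix = n_pix or g.n_cols
        voxel_mm = voxel_mm or g.pixel_pitch
        projector = Projector(g, n_pix, voxel_mm,
                              nz=g.n_rows if g.mode == "circular" else None)
    recon = wfbp_reconstruct(scan, projector=projector)

    h = projector.voxel_mm
    n = projector.n_pix
    x = (np.arange(n) - (n - 1) / 2)
    ideal_channels = {}
    fits = {}
    for label in scan.labels:
        cx, cy, r_mm, mu = fit_uniform_cylinder(recon.channel(label), h)
        xx, yy = np.meshgrid(x + (n - 1) / 2, x + (n - 1) / 2, indexing="ij")
        disk = ((xx - cx) ** 2 + (yy - cy) ** 2) <= (r_mm / h) ** 2
        vol = np.where(disk, mu, 0.0)[:, :, None].repeat(projector.nz, axis=2)
        ideal_channels[label] = projector.project(vol)
        fits[label] = {"center_px": (cx, cy), "radius_mm": r_mm,
                       "mu_cm": mu}
    return ProjectionSet(channels=ideal_channels, flat=dict(scan.flat),
                         domain="log_normalized", geometry=g,
                         meta={**scan.meta, "ideal_cylinder_fits": fits})


def detect_pbs_columns(pbs_scan: ProjectionSet) -> np.ndarray:
    """Columns whose rays cross the PBS vial: mean log attenuation above the
    midpoint between air (~0) and the vial-center level."""
    scan = pbs_scan if pbs_scan.domain == "log_normalized" else log_normalize(pbs_scan)
    prof = np.mean([p.mean(axis=(0, 1)) for p in scan.channels.values()],
                   axis=0)
    level = np.percentile(prof, 95)
    return prof > 0.5 * level


def compute_gain_ratio(ideal: ProjectionSet, real_pbs: ProjectionSet,
                       median_size: tuple = (4, 4),
                       pbs_column_range: np.ndarray | None = None
                       ) -> GainRatioProjection:
    """ideal / real PBS counts, median filtered, out-of-PBS columns replaced.

    The ratio is formed in the intensity (count) domain — tile gains act
    multiplicatively on counts — converting log-normalized inputs as needed.
    The median filter runs within each tile's column band (reflect padding):
    tile boundaries are known hardware positions and the spectral steps
    there are exactly what the ratio must preserve, so noise smoothing must
    not blur across them.
    """
    ideal_c = ideal if ideal.domain == "counts" else unlog(ideal)
    real_c = real_pbs if real_pbs.domain == "counts" else unlog(real_pbs)
    if set(ideal_c.labels) != set(real_c.labels):
        raise ValueError("ideal and real scans have different channels")
    if pbs_column_range is None:
        mask = detect_pbs_columns(real_pbs)
    else:
        mask = np.asarray(pbs_column_range)
        if mask.dtype != bool:  # accept an index (lo, hi) pair
            lo, hi = mask
            mask = np.zeros(real_c.geometry.n_cols, dtype=bool)
            mask[int(lo):int(hi) + 1] = True
    if not mask.any():
        raise ValueError("no in-PBS columns found")
    in_cols = np.nonzero(mask)[0]
    nearest = in_cols[np.argmin(
        np.abs(np.arange(mask.size)[:, None] - in_cols[None, :]), axis=1)]

    ratios = {}
    for label in ideal_c.labels:
        real = real_c.channels[label]
        if np.any(real[..., mask] <= 0):
            frac = float(np.mean(real[..., mask] <= 0))
            raise ValueError(f"channel {label}: {100 * frac:.3f}% zero counts "
                             "inside the PBS region")
        ratio = ideal_c.channels[label] / np.maximum(real, 1e-12)
        for sl in real_c.geometry.tile_slices():
            ratio[..., sl] = ndimage.median_filter(
                ratio[..., sl], size=(1, *median_size), mode="reflect")
        ratio = ratio[:, :, nearest]  # column replacement outside the PBS
        ratios[label] = ratio
    return GainRatioProjection(ratios=ratios, median_size=tuple(median_size),
                               column_mask=mask,
                               meta={"source": "pbs_gain_ratio"})


def apply_gain_correction(proj: ProjectionSet,
                          ratio: GainRatioProjection) -> ProjectionSet:
    """Multiply sample projections by the gain ratio (count domain); the
    input domain is preserved on output."""
    was_log = proj.domain == "log_normalized"
    counts = unlog(proj) if was_log else proj
    out = {}
    for label, data in counts.channels.items():
        if label not in ratio.ratios:
            raise ValueError(f"gain ratio has no channel {label}")
        if ratio.ratios[label].shape != data.shape:
            raise ValueError(f"gain ratio shape mismatch for {label}")
        out[label] = data * ratio.ratios[label]
    corrected = ProjectionSet(channels=out, flat=dict(counts.flat),
                              domain="counts", geometry=counts.geometry,
                              meta={**counts.meta, "gain_corrected": True})
    return log_normalize(corrected) if was_log else corrected


def band_artifact_score(proj: ProjectionSet, channel: str,
                        column_mask: np.ndarray | None = None,
                        fit_width: int = 6) -> float:
    """Mean absolute inter-tile step of the view/row-averaged column profile.

    At each interior tile boundary the step is the gap between quadratic
    extrapolations of the profile from the ``fit_width`` columns on either
    side, so the smooth trend of the object (the curved chord-length profile
    of the vial) does not register as an artifact. Boundaries whose flanks
    leave ``column_mask`` (default: all columns) are skipped.
    """
    scan = proj if proj.domain == "log_normalized" else log_normalize(proj)
    profile = scan.channels[channel].mean(axis=(0, 1))
    g = scan.geometry
    if column_mask is None:
        column_mask = np.ones(g.n_cols, dtype=bool)
    steps = []
    for b in range(1, g.n_tiles):
        col = b * g.tile_width
        lo, hi = col - fit_width, col + fit_width
        if lo < 0 or hi > g.n_cols or not column_mask[lo:hi].all():
            continue
        xl = np.arange(lo, col)
        xr = np.arange(col, hi)
        left = np.polyval(np.polyfit(xl, profile[lo:col], 2), col - 0.5)
        right = np.polyval(np.polyfit(xr, profile[col:hi], 2), col - 0.5)
        steps.append(abs(left - right))
    if not steps:
        raise ValueError("no tile boundary lies inside the PBS column range")
    return float(np.mean(steps))


# --------------------------------------------------------------------------
# beam-hardening correction
# --------------------------------------------------------------------------

def acrylic_equivalent_mm(aluminum_mm: float, materials: MaterialTable,
                          kev: float) -> float:
    """Aluminum thickness expressed as acrylic of equal attenuation at
    the given energy."""
    mu_al = materials.mass_attenuation("aluminum", kev) * SOLID_DENSITY["aluminum"]
    mu_ac = materials.mass_attenuation("acrylic", kev) * SOLID_DENSITY["acrylic"]
    return aluminum_mm * float(mu_al / mu_ac)


def calibrate_beam_hardening(plate_scans, grid: EnergyGrid,
                             materials: MaterialTable,
                             detector: DetectorModel,
                             channel: str = "EID") -> BeamHardeningModel:
    """Fit thickness = a p^2 + b p + c per detector row from plate scans.

    ``plate_scans`` is a list of (ProjectionSet, acrylic_mm, aluminum_mm)
    with known slab thicknesses; aluminum enters the fit as its
    acrylic-equivalent at the effective energy. At least 3 distinct
    acrylic-equivalent thicknesses are required for the quadratic fit.
    """
    weights = detector.channel_weights(grid.energies)[
        detector.channel_labels.index(channel)]
    kev = effective_energy(grid, weights)
    mu_ref_per_mm = float(
        materials.mass_attenuation("acrylic", kev) * SOLID_DENSITY["acrylic"]
        * MM_TO_CM)

    thicknesses, row_values = [], []
    for scan, acrylic_mm, aluminum_mm in plate_scans:
        log = scan if scan.domain == "log_normalized" else log_normalize(scan)
        d_eq = acrylic_mm + acrylic_equivalent_mm(aluminum_mm, materials, kev)
        thicknesses.append(d_eq)
        row_values.append(log.channels[channel].mean(axis=(0, 2)))  # per row
    thicknesses = np.asarray(thicknesses)
    if np.unique(np.round(thicknesses, 9)).size < 3:
        raise ValueError("beam-hardening fit needs >= 3 distinct "
                         "acrylic-equivalent thicknesses")
    P = np.stack(row_values)          # (n_scans, n_rows)
    n_rows = P.shape[1]
    coeffs = np.empty((n_rows, 3))
    for r in range(n_rows):
        design = np.stack([P[:, r] ** 2, P[:, r], np.ones_like(P[:, r])],
                          axis=1)
        coeffs[r], *_ = np.linalg.lstsq(design, thicknesses, rcond=None)
    return BeamHardeningModel(coeffs=coeffs, mu_ref_per_mm=mu_ref_per_mm,
                              effective_kev=kev,
                              meta={"thicknesses_mm": thicknesses.tolist(),
                                    "channel": channel})


def apply_beam_hardening(eid_proj: ProjectionSet, model: BeamHardeningModel,
                         channel: str = "EID") -> ProjectionSet:
    """Map log-normalized EID data to acrylic thickness and rescale to an
    attenuation line integral (dimensionless)."""
    if eid_proj.domain != "log_normalized":
        raise ValueError("apply_beam_hardening expects log-normalized data")
    out = dict(eid_proj.channels)
    p = eid_proj.channels[channel]
    if model.coeffs.shape[0] != p.shape[1]:
        raise ValueError("model row count does not match detector rows")
    out[channel] = model.thickness(p) * model.mu_ref_per_mm
    return ProjectionSet(channels={k: v.copy() for k, v in out.items()},
                         flat=dict(eid_proj.flat), domain="log_normalized",
                         geometry=eid_proj.geometry,
                         meta={**eid_proj.meta, "beam_hardening_corrected": True})


def ring_artifact_score(image: np.ndarray, voxel_mm: float,
                        geometry: ScanGeometry,
                        annulus_mm: tuple[float, float],
                        fit_width: int = 5) -> float:
    """Mean absolute ring step of the azimuthally averaged radial profile.

    Tile boundaries backproject to rings at radii equal to the boundary
    detector coordinates; the step at each such radius inside the annulus is
    measured as the gap between linear extrapolations of the radial profile
    from either side (the image-domain analogue of
    :func:`band_artifact_score`).
    """
    nx, ny = image.shape
    xx, yy = np.meshgrid((np.arange(nx) - (nx - 1) / 2) * voxel_mm,
                         (np.arange(ny) - (ny - 1) / 2) * voxel_mm,
                         indexing="ij")
    r = np.hypot(xx, yy)
    nbins = int(r.max() / voxel_mm)
    bins = np.clip((r / voxel_mm).astype(int), 0, nbins)
    prof = np.bincount(bins.ravel(), weights=image.ravel(),
                       minlength=nbins + 1)
    cnt = np.bincount(bins.ravel(), minlength=nbins + 1)
    prof = prof / np.maximum(cnt, 1)

    half_det = (geometry.n_cols - 1) / 2
    steps = []
    for b in range(1, geometry.n_tiles):
        t_mm = abs((b * geometry.tile_width - 0.5 - half_det)
                   * geometry.pixel_pitch)
        if not annulus_mm[0] <= t_mm <= annulus_mm[1]:
            continue
        k = int(round(t_mm / voxel_mm))
        lo, hi = k - fit_width, k + fit_width
        if lo < 1 or hi >= nbins:
            continue
        xl, xr = np.arange(lo, k), np.arange(k + 1, hi + 1)
        left = np.polyval(np.polyfit(xl, prof[lo:k], 1), k)
        right = np.polyval(np.polyfit(xr, prof[k + 1:hi + 1], 1), k)
        steps.append(abs(left - right))
    if not steps:
        raise ValueError("no tile-boundary radius falls inside the annulus")
    return float(np.mean(steps))


def cupping_drop(profile_values: np.ndarray, band_frac: float = 0.15) -> float:
    """Edge-to-center drop of a line profile across a uniform object.

    Mean of the two edge bands minus the mean of the central band; positive
    values indicate the dark-center cupping typical of beam hardening.
    """
    v = np.asarray(profile_values, dtype=float)
    n = v.size
    k = max(1, int(band_frac * n))
    edges = 0.5 * (v[:k].mean() + v[-k:].mean())
    center = v[(n - k) // 2:(n + k) // 2].mean()
    return float(edges - center)
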