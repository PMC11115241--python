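"""Polychromatic forward simulation of PCD and EID imaging chains.

``forward_project`` drives rays through a :class:`DigitalPhantom`, attenuates
the source spectrum material-by-material (Beer-Lambert per energy bin), and
bins the transmitted photons with the detector's spectral weighting:
w(E) = 1 above each threshold for the counting detector, w(E) = E for the
energy integrator. Tile spectral mismatch enters as per-tile threshold
offsets and gains; flat fields are "measured" with the same distortions so
that flat-field normalization cancels pure gains but not the object-dependent
spectral residual — the origin of PCD band artifacts.

Noise: PCD counts are Poisson; the nested threshold bins are sampled jointly
(high bin first, plus an independent Poisson increment) so the physical
ordering counts(15 keV) >= counts(34 keV) holds pixel-by-pixel even in noise.
EID signals use the Gaussian compound-Poisson approximation with variance
N0 * sum s(E) E^2 T(E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import DetectorModel, ScanGeometry
from .phantoms import SOLID_DENSITY, DigitalPhantom
from .projector import Projector
from .spectra import EnergyGrid, MaterialTable


@dataclass
class ProjectionSet:
    """Per-channel projection stacks tied to one scan geometry.

    ``channels`` maps a label (PCD15, PCD34, EID, ...) to an array of shape
    (n_views, n_rows, n_cols); ``flat`` holds the per-channel flat-field
    reference (n_rows, n_cols). ``domain`` is "counts" or "log_normalized".
    """

    channels: dict
    flat: dict
    domain: str
    geometry: ScanGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain not in ("counts", "log_normalized"):
            raise ValueError(f"unknown domain {self.domain!r}")
        shape = (self.geometry.n_views, self.geometry.n_rows,
                 self.geometry.n_cols)
        for label, arr in self.channels.items():
            if arr.shape != shape:
                raise ValueError(f"channel {label}: shape {arr.shape} != {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {label}: non-finite values")
            if self.domain == "counts" and arr.min() < 0:
                raise ValueError(f"channel {label}: negative counts")

    @property
    def labels(self) -> tuple:
        return tuple(self.channels)

    def copy(self) -> "ProjectionSet":
        return ProjectionSet(
            channels={k: v.copy() for k, v in self.channels.items()},
            flat={k: np.array(v) for k, v in self.flat.items()},
            domain=self.domain, geometry=self.geometry, meta=dict(self.meta))

    def merge(self, other: "ProjectionSet") -> "ProjectionSet":
        """Concatenate channels of two sets sharing geometry and domain."""
        if other.geometry != self.geometry:
            raise ValueError("cannot merge projection sets on different geometries")
        if other.domain != self.domain:
            raise ValueError("cannot merge counts with log-normalized data")
        dup = set(self.channels) & set(other.channels)
        if dup:
            raise ValueError(f"duplicate channel labels {sorted(dup)}")
        return ProjectionSet(
            channels={**self.channels, **other.channels},
            flat={**self.flat, **other.flat},
            domain=self.domain, geometry=self.geometry,
            meta={**self.meta, **other.meta})


def _spectral_weights(detector: DetectorModel, grid: EnergyGrid,
                      n_tiles: int) -> tuple[np.ndarray, np.ndarray]:
    """W[ch, tile, E] = fluence * channel weight at tile's shifted threshold.

    Second return: W2 with E^2 weighting (EID noise second moment).
    """
    _, offsets = detector.gains_offsets(n_tiles)
    n_ch = len(detector.channel_labels)
    W = np.zeros((n_ch, n_tiles, grid.n_energies))
    for t in range(n_tiles):
        w = detector.channel_weights(grid.energies, threshold_offset=offsets[t])
        W[:, t, :] = w * grid.source_weights[None, :]
    W2 = W * grid.energies[None, None, :] if detector.kind == "EID" else W
    return W, W2


def forward_project(phantom: DigitalPhantom, geometry: ScanGeometry,
                    grid: EnergyGrid, materials: MaterialTable,
                    detector: DetectorModel,
                    noise_seed: int | None = None,
                    projector: Projector | None = None) -> ProjectionSet:
    """Simulate expected (optionally Poisson-noisy) detector counts.

    Returns a counts-domain :class:`ProjectionSet` with one channel per
    detector threshold (PCD) or a single EID channel, including the matching
    flat-field reference.
    """
    nx, ny, nz = phantom.shape
    if nx != ny:
        raise ValueError("phantom axial planes must be square")
    if projector is None:
        projector = Projector(geometry, nx, phantom.voxel_size, nz=nz)

    # line integrals per material, (views, rows, cols), in cm * unit
    integrals = {}
    for name, conc in phantom.materials.items():
        if np.any(conc):
            integrals[name] = projector.project(conc)
    for L in integrals.values():
        if not np.all(np.isfinite(L)):
            raise ValueError("non-finite line integrals")

    mu = {name: materials.mu_per_unit(name, grid.energies)
          for name in integrals}
    gains, _ = detector.gains_offsets(geometry.n_tiles)
    W, W2 = _spectral_weights(detector, grid, geometry.n_tiles)
    labels = detector.channel_labels
    n_ch = len(labels)
    shape = (geometry.n_views, geometry.n_rows, geometry.n_cols)
    tiles = geometry.tile_slices()

    expected = np.zeros((n_ch,) + shape)
    second = np.zeros_like(expected) if detector.kind == "EID" else None
    for e in range(grid.n_energies):
        acc = np.zeros(shape)
        for name, L in integrals.items():
            acc += mu[name][e] * L
        T_e = np.exp(-acc)
        for ch in range(n_ch):
            for t, sl in enumerate(tiles):
                expected[ch, ..., sl] += W[ch, t, e] * T_e[..., sl]
                if second is not None:
                    second[ch, ..., sl] += W2[ch, t, e] * T_e[..., sl]

    N0 = detector.flat_field_photons
    tile_gain = np.empty(geometry.n_cols)
    for t, sl in enumerate(tiles):
        tile_gain[sl] = gains[t]
    expected *= N0 * tile_gain
    if second is not None:
        second *= N0 * tile_gain**2

    # flat field (air scan) under the same distortions
    flat = np.zeros((n_ch, geometry.n_rows, geometry.n_cols))
    for ch in range(n_ch):
        for t, sl in enumerate(tiles):
            flat[ch, :, sl] = N0 * gains[t] * W[ch, t, :].sum()

    if detector.psf_sigma_cols > 0:
        for ch in range(n_ch):
            expected[ch] = ndimage.gaussian_filter1d(
                expected[ch], detector.psf_sigma_cols, axis=2, mode="nearest")
            if second is not None:
                second[ch] = ndimage.gaussian_filter1d(
                    second[ch], detector.psf_sigma_cols, axis=2, mode="nearest")

    if noise_seed is None:
        data = expected
    else:
        rng = np.random.default_rng(noise_seed)
        if detector.kind == "PCD":
            # sample nested bins jointly: highest threshold first, then add
            # independent increments so bin ordering is preserved under noise
            data = np.empty_like(expected)
            order = np.argsort([-t for t in detector.thresholds])
            prev = np.zeros(shape)
            prev_exp = np.zeros(shape)
            for ch in order:
                inc = rng.poisson(np.clip(expected[ch] - prev_exp, 0, None))
                data[ch] = prev + inc
                prev, prev_exp = data[ch], expected[ch]
            data = data.astype(float)
        else:
            sd = np.sqrt(np.clip(second, 0, None))
            data = np.clip(expected + rng.normal(size=shape) * sd, 0, None)

    return ProjectionSet(
        channels={lab: data[ch] for ch, lab in enumerate(labels)},
        flat={lab: flat[ch] for ch, lab in enumerate(labels)},
        domain="counts", geometry=geometry,
        meta={"detector_kind": detector.kind, "noise_seed": noise_seed,
              "thresholds": detector.thresholds})


def log_normalize(proj: ProjectionSet, clip_floor: float = 1.0) -> ProjectionSet:
    """-ln(counts / flat_field) per channel; domain becomes log_normalized.

    Counts below ``clip_floor`` are raised to it first; with a non-positive
    floor, any non-positive count is an error reporting the affected pixel
    fraction.
    """
    if proj.domain != "counts":
        raise ValueError("log_normalize expects counts-domain projections")
    out = {}
    for label, counts in proj.channels.items():
        if label not in proj.flat:
            raise ValueError(f"channel {label} lacks a flat-field reference")
        if clip_floor > 0:
            counts = np.maximum(counts, clip_floor)
        elif np.any(counts <= 0):
            frac = float(np.mean(counts <= 0))
            raise ValueError(
                f"channel {label}: {100 * frac:.3f}% of pixels have zero counts")
        out[label] = -np.log(counts / proj.flat[label][None, :, :])
    return ProjectionSet(channels=out, flat=dict(proj.flat),
                         domain="log_normalized", geometry=proj.geometry,
                         meta=dict(proj.meta))


def unlog(proj: ProjectionSet) -> ProjectionSet:
    """Inverse of :func:`log_normalize`: back to the counts domain."""
    if proj.domain != "log_normalized":
        raise ValueError("unlog expects log-normalized projections")
    out = {label: proj.flat[label][None, :, :] * np.exp(-p)
           for label, p in proj.channels.items()}
    return ProjectionSet(channels=out, flat=dict(proj.flat), domain="counts",
                         geometry=proj.geometry, meta=dict(proj.meta))


def simulate_plate_scan(acrylic_mm: float, aluminum_mm: float,
                        grid: EnergyGrid, materials: MaterialTable,
                        detector: DetectorModel, n_rows: int = 4,
                        n_cols: int = 256, n_tiles: int = 8,
                        noise_seed: int | None = None) -> ProjectionSet:
    """Flat calibration 'scan' of acrylic/aluminum slabs of known thickness.

    Every ray crosses the slabs at normal incidence, so the material line
    integrals are spatially uniform; used to calibrate the beam-hardening
    polynomial exactly as plate scans are in practice.
    """
    geometry = ScanGeometry(mode="circular", n_views=1, n_rows=n_rows,
                            n_cols=n_cols, n_tiles=n_tiles)
    shape = (1, n_rows, n_cols)
    L = {"acrylic": SOLID_DENSITY["acrylic"] * acrylic_mm * 0.1,
         "aluminum": SOLID_DENSITY["aluminum"] * aluminum_mm * 0.1}
    mu = {m: materials.mu_per_unit(m, grid.energies) for m in L}
    gains, _ = detector.gains_offsets(n_tiles)
    W, W2 = _spectral_weights(detector, grid, n_tiles)
    labels = detector.channel_labels
    tiles = geometry.tile_slices()

    T = np.exp(-sum(mu[m] * L[m] for m in L))  # per energy
    N0 = detector.flat_field_photons
    expected = np.zeros((len(labels),) + shape)
    flat = np.zeros((len(labels), n_rows, n_cols))
    var = np.zeros_like(expected)
    for ch in range(len(labels)):
        for t, sl in enumerate(tiles):
            expected[ch, ..., sl] = N0 * gains[t] * (W[ch, t] * T).sum()
            flat[ch, :, sl] = N0 * gains[t] * W[ch, t].sum()
            var[ch, ..., sl] = N0 * gains[t] ** 2 * (W2[ch, t] * T).sum()
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        if detector.kind == "PCD":
            expected = rng.poisson(expected).astype(float)
        else:
            expected = np.clip(expected + rng.normal(size=expected.shape)
                               * np.sqrt(var), 0, None)
    return ProjectionSet(
        channels={lab: expected[ch] for ch, lab in enumerate(labels)},
        flat={lab: flat[ch] for ch, lab in enumerate(labels)},
        domain="counts", geometry=geometry,
        meta={"acrylic_mm": acrylic_mm, "aluminum_mm": aluminum_mm,
              "detector_kind": detector.kind})
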