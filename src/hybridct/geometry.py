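"""Scan geometry and detector models.

The desk-scale system model is a stacked parallel-beam geometry: detector
columns span the transaxial (fan) direction, detector rows span the rotation
axis, and each row images one axial plane. ``circular`` mode maps rows to
fixed axial slices; ``helical`` mode translates the subject vertically across
the views so rows sweep through the volume. Detector tiles partition the
columns into equal contiguous bands, mirroring multi-tile photon-counting
ASICs whose tiles have slightly different spectral responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ScanGeometry:
    mode: str = "circular"
    n_views: int = 360
    angular_span: float = 180.0        # degrees
    vertical_translation: float = 0.0  # mm, total subject translation (helical)
    n_rows: int = 1
    n_cols: int = 256
    pixel_pitch: float = 0.05          # mm, detector pixel size (rows and cols)
    n_tiles: int = 8
    source_axis_mm: float = 230.0      # informational at desk scale
    source_detector_mm: float = 460.0

    def __post_init__(self) -> None:
        if self.mode not in ("circular", "helical"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.mode == "helical" and not self.vertical_translation > 0:
            raise ValueError("helical mode requires vertical_translation > 0")
        if self.n_cols % self.n_tiles:
            raise ValueError("detector columns must divide evenly into tiles")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        """View angles in degrees (end-exclusive over the angular span)."""
        return np.arange(self.n_views) * self.angular_span / self.n_views

    @property
    def tile_width(self) -> int:
        return self.n_cols // self.n_tiles

    def tile_slices(self) -> list[slice]:
        w = self.tile_width
        return [slice(i * w, (i + 1) * w) for i in range(self.n_tiles)]

    def tile_of_column(self) -> np.ndarray:
        """Tile index for every detector column."""
        return np.repeat(np.arange(self.n_tiles), self.tile_width)

    def view_z_offsets(self) -> np.ndarray:
        """Vertical subject offset (mm) at each view, centered on the scan."""
        if self.mode == "circular" or self.n_views == 1:
            return np.zeros(self.n_views)
        t = np.arange(self.n_views) / (self.n_views - 1)
        return (t - 0.5) * self.vertical_translation


@dataclass(frozen=True)
class DetectorModel:
    """Counting (PCD) or energy-integrating (EID) detector response.

    PCD channels count photons above each threshold (w(E) = 1 for E >= T);
    the EID weights photons by deposited energy (w(E) = E). Tile spectral
    mismatch is modeled as per-tile threshold offsets (keV) plus small
    multiplicative gains: pure gains cancel under flat-field normalization,
    while threshold offsets leave the object-dependent residual that produces
    band/ring artifacts.
    """

    kind: str = "PCD"
    thresholds: tuple = (15.0, 34.0)
    tile_threshold_offsets: tuple | None = None  # keV, one per tile (PCD)
    tile_gains: tuple | None = None              # dimensionless, one per tile
    flat_field_photons: float = 1e5              # mean photons/pixel in air
    psf_sigma_cols: float = 0.0                  # detector blur (columns), px

    def __post_init__(self) -> None:
        if self.kind not in ("PCD", "EID"):
            raise ValueError(f"unknown detector kind {self.kind!r}")
        thr = tuple(float(t) for t in self.thresholds)
        if self.kind == "PCD":
            if len(thr) < 1 or np.any(np.diff(thr) <= 0):
                raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", thr)
        if self.tile_gains is not None and np.any(np.asarray(self.tile_gains) <= 0):
            raise ValueError("tile gains must be positive")
        if not self.flat_field_photons > 0:
            raise ValueError("flat_field_photons must be positive")

    @property
    def channel_labels(self) -> tuple:
        if self.kind == "EID":
            return ("EID",)
        return tuple(f"PCD{int(round(t))}" for t in self.thresholds)

    def channel_weights(self, energies: np.ndarray,
                        threshold_offset: float = 0.0) -> np.ndarray:
        """Per-channel spectral weights w(E), shape (n_channels, n_energies)."""
        e = np.asarray(energies, dtype=float)
        if self.kind == "EID":
            return e[None, :].copy()
        rows = [(e >= t + threshold_offset).astype(float) for t in self.thresholds]
        return np.stack(rows)

    def gains_offsets(self, n_tiles: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-tile gain and threshold-offset arrays, defaulted to identity."""
        gains = (np.ones(n_tiles) if self.tile_gains is None
                 else np.asarray(self.tile_gains, dtype=float))
        offs = (np.zeros(n_tiles) if self.tile_threshold_offsets is None
                else np.asarray(self.tile_threshold_offsets, dtype=float))
        if gains.size != n_tiles or offs.size != n_tiles:
            raise ValueError("per-tile arrays must match geometry n_tiles")
        return gains, offs


def default_tile_distortions(n_tiles: int = 8, seed: int = 7,
                             offset_scale_kev: float = 0.6,
                             gain_scale: float = 0.03) -> tuple[tuple, tuple]:
    """Reproducible per-tile spectral distortions for simulation studies.

    Offsets ~ U(-scale, scale) keV and gains ~ 1 + U(-gain_scale, gain_scale)
    model tile-to-tile spectral response mismatch of a multi-tile PCD.
    """
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-offset_scale_kev, offset_scale_kev, n_tiles)
    gains = 1.0 + rng.uniform(-gain_scale, gain_scale, n_tiles)
    return tuple(offsets), tuple(gains)
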