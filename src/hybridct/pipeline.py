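"""End-to-end desk-scale study workflows.

These functions wire the simulator, corrections and reconstructions together
the way the physical studies are run: a PBS-only vial scan calibrates the
multiplicative tile-gain correction for all brain scans sharing the
trajectory; acrylic/aluminum plate scans calibrate the EID beam-hardening
polynomial; corrected PCD + EID projections feed the hybrid iterative
reconstruction. Study defaults are the simulation analogue of the physical
protocol at desk scale: a 256-column, 8-tile detector, 360 views over 180
degrees, 128^2 axial slices at 0.1 mm. Tile spectral distortions are drawn
once per study seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corrections import (apply_beam_hardening, apply_gain_correction,
                          build_ideal_pbs_projection, calibrate_beam_hardening,
                          compute_gain_ratio)
from .geometry import DetectorModel, ScanGeometry, default_tile_distortions
from .phantoms import (DigitalPhantom, make_bar_pattern_phantom,
                       make_brain_vial_phantom, make_vials_phantom)
from .projector import Projector
from .recon import ReconConfig, ReconVolumeSet, iterative_reconstruct, wfbp_reconstruct
from .simulate import (ProjectionSet, forward_project, log_normalize,
                       simulate_plate_scan)
from .spectra import EnergyGrid, MaterialTable, kramers_spectrum


@dataclass(frozen=True)
class StudySettings:
    """Desk-scale analogue of the physical acquisition protocol."""

    n_pix: int = 128
    voxel_mm: float = 0.1
    n_views: int = 360
    angular_span: float = 180.0
    n_cols: int = 256
    n_rows: int = 8
    pixel_pitch: float = 0.05
    n_tiles: int = 8
    thresholds: tuple = (15.0, 34.0)
    kvp: float = 60.0
    pcd_photons: float = 2.5e5
    eid_photons: float = 1.2e5
    eid_blur_px: float = 1.6
    pcd_blur_px: float = 0.5
    tile_offset_kev: float = 0.6
    tile_gain_scale: float = 0.03

    def geometry(self) -> ScanGeometry:
        return ScanGeometry(mode="circular", n_views=self.n_views,
                            angular_span=self.angular_span,
                            n_rows=self.n_rows, n_cols=self.n_cols,
                            pixel_pitch=self.pixel_pitch,
                            n_tiles=self.n_tiles)

    def detectors(self, seed: int) -> tuple[DetectorModel, DetectorModel]:
        """(PCD, EID) models; PCD tile distortions derive from the seed."""
        offsets, gains = default_tile_distortions(
            self.n_tiles, seed=seed, offset_scale_kev=self.tile_offset_kev,
            gain_scale=self.tile_gain_scale)
        pcd = DetectorModel(kind="PCD", thresholds=self.thresholds,
                            tile_threshold_offsets=offsets, tile_gains=gains,
                            flat_field_photons=self.pcd_photons,
                            psf_sigma_cols=self.pcd_blur_px)
        eid = DetectorModel(kind="EID", flat_field_photons=self.eid_photons,
                            psf_sigma_cols=self.eid_blur_px)
        return pcd, eid

    def spectrum(self) -> EnergyGrid:
        return kramers_spectrum(kvp=self.kvp)


def scan_phantom(phantom: DigitalPhantom, settings: StudySettings, seed: int,
                 projector: Projector | None = None,
                 pcd: DetectorModel | None = None,
                 eid: DetectorModel | None = None) -> ProjectionSet:
    """Sequential PCD + EID scan of one phantom, merged into one set."""
    geometry = settings.geometry()
    grid = settings.spectrum()
    table = MaterialTable()
    if pcd is None or eid is None:
        d_pcd, d_eid = settings.detectors(seed=1000 + seed % 1000)
        pcd = pcd or d_pcd
        eid = eid or d_eid
    if projector is None:
        projector = Projector(geometry, settings.n_pix, settings.voxel_mm,
                              nz=phantom.shape[2])
    pcd_scan = forward_project(phantom, geometry, grid, table, pcd,
                               noise_seed=seed, projector=projector)
    eid_scan = forward_project(phantom, geometry, grid, table, eid,
                               noise_seed=seed + 1, projector=projector)
    return pcd_scan.merge(eid_scan)


def beam_hardening_model(settings: StudySettings, seed: int | None = None,
                         acrylic_mm=(0.0, 2.0, 5.0, 10.0, 20.0),
                         aluminum_mm=(0.0, 0.5)):
    """Calibrate the per-row EID beam-hardening polynomial from plate scans."""
    grid = settings.spectrum()
    table = MaterialTable()
    _, eid = settings.detectors(seed=0)
    scans = []
    for i, d_ac in enumerate(acrylic_mm):
        for j, d_al in enumerate(aluminum_mm):
            noise = None if seed is None else seed + 10 * i + j
            scans.append((simulate_plate_scan(
                d_ac, d_al, grid, table, eid, n_rows=settings.n_rows,
                n_cols=settings.n_cols, n_tiles=settings.n_tiles,
                noise_seed=noise), d_ac, d_al))
    return calibrate_beam_hardening(scans, grid, table, eid)


def brain_study(seed: int, settings: StudySettings | None = None,
                recon_config: ReconConfig | None = None,
                mean_iodine: float = 6.0) -> dict:
    """Full brain-in-PBS-vial study: simulate, correct, reconstruct.

    Returns the phantom, raw and corrected projections, the gain ratio, the
    hybrid iterative reconstruction and the uncorrected/corrected wFBP
    reconstructions used for before/after comparisons.
    """
    settings = settings or StudySettings()
    geometry = settings.geometry()
    pcd, eid = settings.detectors(seed=1000 + seed % 1000)
    projector = Projector(geometry, settings.n_pix, settings.voxel_mm,
                          nz=settings.n_rows)

    brain = make_brain_vial_phantom(seed, grid_size=settings.n_pix,
                                    voxel_size=settings.voxel_mm,
                                    nz=settings.n_rows,
                                    mean_iodine=mean_iodine)
    pbs = make_brain_vial_phantom(seed, grid_size=settings.n_pix,
                                  voxel_size=settings.voxel_mm,
                                  nz=settings.n_rows, include_brain=False)
    grid = settings.spectrum()
    table = MaterialTable()

    pcd_brain = forward_project(brain, geometry, grid, table, pcd,
                                noise_seed=seed + 11, projector=projector)
    eid_brain = forward_project(brain, geometry, grid, table, eid,
                                noise_seed=seed + 12, projector=projector)
    pcd_pbs = forward_project(pbs, geometry, grid, table, pcd,
                              noise_seed=seed + 13, projector=projector)

    # tile-gain correction calibrated on the PBS-only scan
    pbs_log = log_normalize(pcd_pbs)
    ideal = build_ideal_pbs_projection(pbs_log, projector=projector)
    ratio = compute_gain_ratio(ideal, pcd_pbs)
    pcd_corr = apply_gain_correction(pcd_brain, ratio)

    # beam-hardening correction for the EID channel
    bh = beam_hardening_model(settings, seed=seed + 50)
    eid_log = log_normalize(eid_brain)
    eid_corr = apply_beam_hardening(eid_log, bh)

    hybrid_proj = log_normalize(pcd_corr).merge(eid_corr)
    uncorrected_proj = log_normalize(pcd_brain).merge(eid_log)

    config = recon_config or ReconConfig()
    hybrid = iterative_reconstruct(hybrid_proj, config, projector=projector)
    wfbp_corrected = wfbp_reconstruct(hybrid_proj, projector=projector)
    wfbp_uncorrected = wfbp_reconstruct(uncorrected_proj, projector=projector)

    return {"settings": settings, "phantom": brain, "pbs_phantom": pbs,
            "projector": projector, "geometry": geometry,
            "pcd_scan": pcd_brain, "eid_scan": eid_brain,
            "pbs_scan": pcd_pbs, "gain_ratio": ratio,
            "pcd_corrected": pcd_corr, "eid_corrected": eid_corr,
            "beam_hardening": bh, "hybrid_proj": hybrid_proj,
            "uncorrected_proj": uncorrected_proj,
            "hybrid_recon": hybrid, "wfbp_corrected": wfbp_corrected,
            "wfbp_uncorrected": wfbp_uncorrected}


def vials_study(seed: int, settings: StudySettings | None = None,
                concentrations=(9.25, 4.625, 2.3125, 1.1563),
                recon_config: ReconConfig | None = None) -> dict:
    """Water + iodine vials phantom: simulate, BH-correct EID, hybrid recon.

    No tile-gain correction is applied (the vials are not immersed in PBS),
    matching the physical protocol for this phantom.
    """
    settings = settings or StudySettings()
    geometry = settings.geometry()
    projector = Projector(geometry, settings.n_pix, settings.voxel_mm,
                          nz=settings.n_rows)
    phantom = make_vials_phantom(concentrations, grid_size=settings.n_pix,
                                 voxel_size=settings.voxel_mm,
                                 nz=settings.n_rows)
    scan = scan_phantom(phantom, settings, seed, projector=projector)
    bh = beam_hardening_model(settings, seed=seed + 50)
    log = log_normalize(scan)
    corrected = apply_beam_hardening(log, bh)
    config = recon_config or ReconConfig()
    recon = iterative_reconstruct(corrected, config, projector=projector)
    return {"settings": settings, "phantom": phantom, "projector": projector,
            "scan": scan, "proj": corrected, "recon": recon,
            "concentrations": list(concentrations)}


def resolution_study(seed: int, settings: StudySettings | None = None,
                     frequencies=(1.0, 1.6, 2.4, 3.2),
                     recon_config: ReconConfig | None = None) -> dict:
    """Bar-pattern phantom reconstructed three ways: PCD-only, EID-only,
    hybrid — the comparison behind the f10 resolution ordering."""
    settings = settings or StudySettings()
    geometry = settings.geometry()
    projector = Projector(geometry, settings.n_pix, settings.voxel_mm,
                          nz=settings.n_rows)
    phantom = make_bar_pattern_phantom(frequencies,
                                       grid_size=settings.n_pix,
                                       voxel_size=settings.voxel_mm,
                                       nz=settings.n_rows)
    scan = scan_phantom(phantom, settings, seed, projector=projector)
    bh = beam_hardening_model(settings, seed=seed + 50)
    log = log_normalize(scan)
    corrected = apply_beam_hardening(log, bh)
    config = recon_config or ReconConfig()

    def reconstruct(labels):
        sub = ProjectionSet(
            channels={l: corrected.channels[l] for l in labels},
            flat={l: corrected.flat[l] for l in labels},
            domain="log_normalized", geometry=geometry,
            meta=dict(corrected.meta))
        return iterative_reconstruct(sub, config, projector=projector)

    pcd_labels = [l for l in corrected.labels if l.startswith("PCD")]
    return {"settings": settings, "phantom": phantom,
            "proj": corrected,
            "pcd_only": reconstruct(pcd_labels),
            "eid_only": reconstruct(["EID"]),
            "hybrid": reconstruct(list(corrected.labels))}


def central_profile(recon: ReconVolumeSet, channel: str,
                    radius_frac: float = 0.85,
                    vial_radius_mm: float | None = None) -> np.ndarray:
    """Values along the central horizontal line through the vial center,
    restricted to the vial interior (the profile the uniformity metric uses)."""
    vol = recon.channel(channel)
    nx, ny, nz = vol.shape
    sl = vol[:, :, nz // 2]
    if vial_radius_mm is None:
        vial_radius_mm = 0.42 * nx * recon.voxel_size
    half = int(radius_frac * vial_radius_mm / recon.voxel_size)
    cx, cy = nx // 2, ny // 2
    return sl[cx - half:cx + half + 1, cy]
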