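"""Image-domain water/iodine material decomposition.

Each voxel's multi-energy attenuation vector X is modeled as
X(e) = C_H2O * M_H2O(e) + C_I * M_I(e): the sensitivity matrix M is
calibrated from a reconstruction of a phantom holding a water vial and vials
of known iodine concentration, and the per-voxel linear system is solved by
(pseudo-)inversion — least squares when there are more channels than
materials. Negative concentrations are prevented by projecting onto the
non-negative material cone: a voxel whose unconstrained solution leaves the
cone is re-fit on whichever single-material edge has the smaller residual
(exact active-set non-negative least squares for two materials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import ReconVolumeSet


@dataclass
class SensitivityMatrix:
    """Channels x materials sensitivities: water in cm^-1 per g/mL, iodine in
    cm^-1 per mg/mL."""

    M: np.ndarray                  # (n_channels, 2)
    channel_labels: tuple
    materials: tuple = ("water", "iodine")

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[1] != len(self.materials):
            raise ValueError("M must be (n_channels, n_materials)")
        if self.M.shape[0] != len(self.channel_labels):
            raise ValueError("channel labels must match M rows")
        if np.any(self.M < 0):
            raise ValueError("sensitivities must be non-negative")
        if np.linalg.matrix_rank(self.M) < self.M.shape[1]:
            raise ValueError(
                "sensitivity matrix is rank deficient (condition number "
                f"{np.linalg.cond(self.M):.3g}): channels see identical contrast")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.M))


@dataclass
class MaterialMaps:
    """Decomposed concentration volumes: water g/mL, iodine mg/mL."""

    water: np.ndarray
    iodine: np.ndarray
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.water.shape != self.iodine.shape:
            raise ValueError("material maps must share a grid")
        for name, arr in (("water", self.water), ("iodine", self.iodine)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {name} map")


def calibrate_sensitivities(recon: ReconVolumeSet, label_map: np.ndarray,
                            water_label: int, iodine_labels,
                            known_concs) -> SensitivityMatrix:
    """Estimate M from labeled vial ROIs of a calibration reconstruction.

    M_H2O(e) is the water-vial mean per channel (per 1 g/mL); M_I(e) is the
    through-origin least-squares slope of (vial mean - water mean) against
    the known iodine concentrations.
    """
    iodine_labels = list(iodine_labels)
    concs = np.asarray(list(known_concs), dtype=float)
    if len(iodine_labels) != concs.size or concs.size < 1:
        raise ValueError("need one known concentration per iodine vial")
    if label_map.shape != recon.volumes.shape[:3]:
        raise ValueError("label map does not match the reconstruction grid")
    if recon.n_channels < 2:
        raise ValueError("decomposition calibration needs >= 2 channels")

    wmask = label_map == water_label
    if not wmask.any():
        raise ValueError(f"water label {water_label} is empty")
    n_ch = recon.n_channels
    m_water = np.array([recon.volumes[..., c][wmask].mean()
                        for c in range(n_ch)])
    excess = np.empty((concs.size, n_ch))
    for i, lab in enumerate(iodine_labels):
        mask = label_map == lab
        if not mask.any():
            raise ValueError(f"iodine label {lab} is empty")
        excess[i] = [recon.volumes[..., c][mask].mean() - m_water[c]
                     for c in range(n_ch)]
    denom = float(np.sum(concs**2))
    m_iodine = (concs[:, None] * excess).sum(axis=0) / denom
    return SensitivityMatrix(M=np.stack([m_water, m_iodine], axis=1),
                             channel_labels=tuple(recon.labels))


def decompose(recon: ReconVolumeSet, sens: SensitivityMatrix) -> MaterialMaps:
    """Per-voxel (pseudo-)inversion of X = M C with non-negativity.

    Scale-equivariant before the non-negativity projection activates; output
    maps are >= 0 everywhere.
    """
    if tuple(recon.labels) != tuple(sens.channel_labels):
        raise ValueError(
            f"channel mismatch: recon {recon.labels} vs M {sens.channel_labels}")
    M = sens.M
    shape = recon.volumes.shape[:3]
    X = recon.volumes.reshape(-1, M.shape[0])          # (nvox, n_ch)
    C = X @ np.linalg.pinv(M).T                        # unconstrained LSQ

    bad = (C < 0).any(axis=1)
    if bad.any():
        Xb = X[bad]
        mw, mi = M[:, 0], M[:, 1]
        cw = np.clip(Xb @ mw / (mw @ mw), 0, None)     # water-only edge
        ci = np.clip(Xb @ mi / (mi @ mi), 0, None)     # iodine-only edge
        res_w = ((Xb - cw[:, None] * mw) ** 2).sum(axis=1)
        res_i = ((Xb - ci[:, None] * mi) ** 2).sum(axis=1)
        Cb = np.zeros_like(C[bad])
        use_w = res_w <= res_i
        Cb[use_w, 0] = cw[use_w]
        Cb[~use_w, 1] = ci[~use_w]
        C[bad] = Cb
    return MaterialMaps(water=C[:, 0].reshape(shape),
                        iodine=C[:, 1].reshape(shape),
                        voxel_size=recon.voxel_size,
                        meta={"condition_number": sens.condition_number,
                             "n_projected": int(bad.sum())})


DEFAULT_COLORS = {"iodine": (1.0, 0.1, 0.1), "water": (0.15, 0.3, 1.0)}


def render_composite(maps: MaterialMaps, color_assignment: dict | None = None,
                     windows: dict | None = None) -> np.ndarray:
    """Linear color mixing of the material maps into an RGB volume.

    Each material is display-windowed to [0, 1] then multiplied by its RGB
    color; the composite is the sum of the single-material renders (clipped
    to [0, 1] at the end). Window settings are recorded in the result's
    companion metadata via the returned array's ``windows`` convention in
    :mod:`hybridct.io`.
    """
    colors = {**DEFAULT_COLORS, **(color_assignment or {})}
    data = {"iodine": maps.iodine, "water": maps.water}
    if windows is None:
        windows = {m: (0.0, max(float(v.max()), 1e-12))
                   for m, v in data.items()}
    rgb = np.zeros(maps.water.shape + (3,))
    for m, vol in data.items():
        lo, hi = windows[m]
        level = np.clip((vol - lo) / (hi - lo), 0.0, 1.0)
        rgb += level[..., None] * np.asarray(colors[m])
    return np.clip(rgb, 0.0, 1.0)
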