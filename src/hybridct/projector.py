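"""Ray-driven parallel-beam projector / backprojector pair.

The system matrix R is built once per (geometry, grid) with Joseph's method:
each ray steps along its dominant axis in one-voxel increments and linearly
interpolates across the perpendicular axis, so every step contributes two
matrix entries weighted by the intersection length. Storing R as a sparse CSR
matrix makes the backprojector the exact transpose, which gives the adjoint
identity <Rx, y> = <x, R'y> to floating precision — a property the iterative
solver relies on.

Path lengths are in cm so that line integrals of attenuation maps in cm^-1
are dimensionless, matching log-normalized projection data.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .geometry import ScanGeometry

MM_TO_CM = 0.1


def _view_entries(theta: float, n_pix: float, pixel_mm: float, n_det: int,
                  pitch_mm: float):
    """COO entries (det_index, voxel_index, weight) for one parallel view."""
    c, s = np.cos(theta), np.sin(theta)
    t = (np.arange(n_det) - (n_det - 1) / 2) * pitch_mm  # detector coords, mm
    half = (n_pix - 1) / 2
    axes = np.arange(n_pix)
    # ray direction is (-s, c); step along the dominant axis of the direction
    if abs(c) >= abs(s):
        # step in y: ray meets plane y = y_j at x = (t - y_j * s) / c ... derive:
        # point = t*(c, s) + u*(-s, c); y = t*s + u*c = y_j -> u = (y_j - t*s)/c
        # x = t*c - u*s
        y_j = (axes - half) * pixel_mm
        u = (y_j[None, :] - t[:, None] * s) / c
        x = t[:, None] * c - u * s
        frac = x / pixel_mm + half
        step_len = pixel_mm * MM_TO_CM / abs(c)
        i0 = np.floor(frac).astype(np.int64)
        w1 = frac - i0
        fixed = np.broadcast_to(axes[None, :], i0.shape)  # y index
        vox_a = i0 * n_pix + fixed
        vox_b = (i0 + 1) * n_pix + fixed
    else:
        x_i = (axes - half) * pixel_mm
        u = (x_i[None, :] - t[:, None] * c) / (-s)
        y = t[:, None] * s + u * c
        frac = y / pixel_mm + half
        step_len = pixel_mm * MM_TO_CM / abs(s)
        i0 = np.floor(frac).astype(np.int64)
        w1 = frac - i0
        fixed = np.broadcast_to(axes[None, :], i0.shape)  # x index
        vox_a = fixed * n_pix + i0
        vox_b = fixed * n_pix + i0 + 1
    det_idx = np.broadcast_to(np.arange(n_det)[:, None], i0.shape)
    valid = (i0 >= 0) & (i0 + 1 <= n_pix - 1)
    rows = np.concatenate([det_idx[valid], det_idx[valid]])
    cols = np.concatenate([vox_a[valid], vox_b[valid]])
    wts = np.concatenate([(1 - w1)[valid], w1[valid]]) * step_len
    return rows, cols, wts


def parallel_system_matrix(n_pix: int, pixel_mm: float, n_det: int,
                           pitch_mm: float, angles_deg) -> sparse.csr_matrix:
    """Sparse Joseph system matrix, shape (n_views * n_det, n_pix**2)."""
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    rows, cols, wts = [], [], []
    for v, theta in enumerate(angles):
        r, c, w = _view_entries(theta, n_pix, pixel_mm, n_det, pitch_mm)
        rows.append(r + v * n_det)
        cols.append(c)
        wts.append(w)
    mat = sparse.coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(angles) * n_det, n_pix * n_pix))
    return mat.tocsr()


class Projector:
    """Forward/backprojector for a volume on a given scan geometry.

    Circular mode requires ``nz == geometry.n_rows`` (each detector row images
    one axial plane). Helical mode linearly interpolates between axial planes
    as the subject translates; it is intended for small grids.
    """

    def __init__(self, geometry: ScanGeometry, n_pix: int, voxel_mm: float,
                 nz: int | None = None):
        self.geometry = geometry
        self.n_pix = int(n_pix)
        self.voxel_mm = float(voxel_mm)
        self.nz = int(nz) if nz is not None else geometry.n_rows
        if geometry.mode == "circular" and self.nz != geometry.n_rows:
            raise ValueError("circular mode maps detector rows to slices: "
                             f"nz={self.nz} != n_rows={geometry.n_rows}")
        self.matrix = parallel_system_matrix(
            self.n_pix, self.voxel_mm, geometry.n_cols, geometry.pixel_pitch,
            geometry.angles_deg)

    # --- slice-level primitives (exact adjoints of each other) -------------

    def project_slices(self, vols: np.ndarray) -> np.ndarray:
        """(n_pix, n_pix, k) -> (n_views, k, n_cols) line integrals."""
        k = vols.shape[2]
        flat = vols.reshape(self.n_pix * self.n_pix, k)
        sino = self.matrix @ flat  # (views*cols, k)
        return sino.reshape(self.geometry.n_views, self.geometry.n_cols,
                            k).transpose(0, 2, 1)

    def backproject_slices(self, proj: np.ndarray) -> np.ndarray:
        """(n_views, k, n_cols) -> (n_pix, n_pix, k); transpose of project."""
        k = proj.shape[1]
        sino = proj.transpose(0, 2, 1).reshape(-1, k)
        flat = self.matrix.T @ sino
        return flat.reshape(self.n_pix, self.n_pix, k)

    # --- geometry-aware volume operators -----------------------------------

    def _row_slice_weights(self):
        """Helical row -> (slice index, interp weight) per view.

        Returns arrays (n_views, n_rows): floor slice k0, weight w toward k0+1,
        and a validity mask for rows that land inside the volume.
        """
        g = self.geometry
        row_z = (np.arange(g.n_rows) - (g.n_rows - 1) / 2) * g.pixel_pitch
        z_off = g.view_z_offsets()
        z = row_z[None, :] + z_off[:, None]  # sampled plane per (view, row), mm
        frac = z / self.voxel_mm + (self.nz - 1) / 2
        k0 = np.floor(frac).astype(int)
        w = frac - k0
        valid = (k0 >= 0) & (k0 + 1 <= self.nz - 1)
        return k0, w, valid

    def project(self, volume: np.ndarray) -> np.ndarray:
        """(n_pix, n_pix, nz) -> (n_views, n_rows, n_cols) line integrals (cm)."""
        g = self.geometry
        if volume.shape != (self.n_pix, self.n_pix, self.nz):
            raise ValueError("volume shape mismatch")
        if g.mode == "circular":
            return self.project_slices(volume)
        sino_all = self.project_slices(volume)  # (views, nz, cols)
        k0, w, valid = self._row_slice_weights()
        out = np.zeros((g.n_views, g.n_rows, g.n_cols))
        for v in range(g.n_views):
            kv = np.clip(k0[v], 0, self.nz - 2)
            lo = sino_all[v, kv, :]
            hi = sino_all[v, np.minimum(kv + 1, self.nz - 1), :]
            out[v] = (1 - w[v])[:, None] * lo + w[v][:, None] * hi
            out[v, ~valid[v], :] = 0.0
        return out

    def backproject(self, proj: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`project`."""
        g = self.geometry
        if g.mode == "circular":
            return self.backproject_slices(proj)
        k0, w, valid = self._row_slice_weights()
        spread = np.zeros((g.n_views, self.nz, g.n_cols))
        for v in range(g.n_views):
            pv = np.where(valid[v][:, None], proj[v], 0.0)
            kv = np.clip(k0[v], 0, self.nz - 2)
            np.add.at(spread[v], kv, (1 - w[v])[:, None] * pv)
            np.add.at(spread[v], np.minimum(kv + 1, self.nz - 1),
                      w[v][:, None] * pv)
        return self.backproject_slices(spread)
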