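"""Translation-invariant Born forward model for a homogeneous slab.

In a laterally homogeneous medium the excitation field of the line beam
and the detection field of a camera pixel depend only on displacements
from the source line / pixel, so the Born sum

    F[s, d, yb] = sum_{r'} G(r_d - r') * O(r') * Phi(r' - r_s)

is a cross-correlation of the fluorophore volume with a per-offset kernel

    K_d[u, v, z] = Phi_line[u, z] * G[d - u, v, z] * voxel_volume,

evaluated here with FFTs over (x, y).  Source positions and detector y
bins sit on the voxel lattice; detector offsets are integer multiples of
the voxel size.  This block-convolutional structure is what makes the
full 300-position scan tractable: one MC pair serves every stage
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2

from .mc import SlabKernels
from .medium import VoxelGrid

#: relative floor below which sensitivity entries are zeroed (MC shot noise
#: in deep voxels otherwise pollutes the inversion)
KERNEL_FLOOR_REL = 1.0e-6


@dataclass
class SlabForwardModel:
    """FFT-based W operator: fluorophore volume -> line-scan measurements.

    Measurements are indexed (s, d, yb): stage position on the voxel x
    lattice, detector offset ``offsets_vox[d]`` voxels from the source
    line (toward +x), detector y bin on the voxel y lattice.
    """

    kernels: SlabKernels
    grid: VoxelGrid
    offsets_vox: np.ndarray  # integer offsets, ascending, >= 1
    floor_rel: float = KERNEL_FLOOR_REL
    _fft: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.offsets_vox = np.asarray(self.offsets_vox, dtype=int)
        if self.offsets_vox.ndim != 1 or len(self.offsets_vox) == 0:
            raise ValueError("offsets_vox must be a nonempty 1-D integer array")
        if np.any(self.offsets_vox < 1) or np.any(np.diff(self.offsets_vox) <= 0):
            raise ValueError("offsets_vox must be ascending and >= 1")
        if self.kernels.voxel_size != self.grid.voxel_size:
            raise ValueError("kernel and grid voxel sizes differ")
        if self.kernels.nz < self.grid.nz:
            raise ValueError("MC kernels are shallower than the grid")
        if self.kernels.nfy < self.grid.ny:
            raise ValueError("green kernel y support smaller than grid ny")
        # offsets beyond the green x support are permitted: kernel() zero-fills
        self._floor_value = None

    # -- kernel assembly ---------------------------------------------------

    @property
    def n_offsets(self) -> int:
        return len(self.offsets_vox)

    @property
    def measurement_shape(self) -> tuple[int, int, int]:
        return (self.grid.nx, self.n_offsets, self.grid.ny)

    @property
    def n_rows(self) -> int:
        return int(np.prod(self.measurement_shape))

    @property
    def n_cols(self) -> int:
        return int(np.prod(self.grid.shape))

    def kernel(self, d_vox: int) -> np.ndarray:
        """K_d[u, v, z] for one detector offset (voxels), floored."""
        kk = self.kernels
        nz = self.grid.nz
        U = kk.nu_half
        V = self.grid.ny - 1
        phi = kk.phi_line[:, :nz]  # (2U+1, nz)
        gfull = kk.green[:, :, :nz]
        nfx, nfy = kk.nfx, kk.nfy
        u_idx = np.arange(-U, U + 1)
        gx = d_vox - u_idx  # green x displacement per u
        ok = np.abs(gx) <= nfx - 1
        v_idx = np.arange(-V, V + 1)
        okv = np.abs(v_idx) <= nfy - 1
        gsel = gfull[np.clip(gx, -(nfx - 1), nfx - 1) + nfx - 1][:, np.clip(v_idx, -(nfy - 1), nfy - 1) + nfy - 1, :]
        out = phi[:, None, :] * gsel * ok[:, None, None] * okv[None, :, None]
        out *= self.grid.voxel_volume
        floor = self._kernel_floor()
        out[out < floor] = 0.0
        return out

    def _kernel_floor(self) -> float:
        if self._floor_value is None:
            kk = self.kernels
            nz = self.grid.nz
            dmin = int(self.offsets_vox[0])
            U = kk.nu_half
            u_idx = np.arange(-U, U + 1)
            gx = np.abs(dmin - u_idx)
            ok = gx <= kk.nfx - 1
            gmax = kk.green[np.clip(gx, 0, kk.nfx - 1) + kk.nfx - 1, :, :nz]
            peak = float(
                (kk.phi_line[:, :nz][:, None, :] * gmax * ok[:, None, None]).max()
            ) * self.grid.voxel_volume
            self._floor_value = self.floor_rel * peak
        return self._floor_value

    # -- FFT plan ----------------------------------------------------------

    def _plan(self):
        if "A" in self._fft:
            return self._fft
        nx, ny, nz = self.grid.shape
        U = self.kernels.nu_half
        V = ny - 1
        Px = next_fast_len(nx + U)
        Py = next_fast_len(ny + V)
        nd = self.n_offsets
        # A[p, d, z] = Khat_d[z] at flattened frequency p
        A = np.empty((Px * (Py // 2 + 1), nd, nz), dtype=np.complex128)
        for j, d in enumerate(self.offsets_vox):
            kd = self.kernel(int(d))
            kpad = np.zeros((Px, Py, nz))
            u = np.arange(-U, U + 1) % Px
            v = np.arange(-V, V + 1) % Py
            kpad[np.ix_(u, v)] = kd
            khat = rfft2(kpad, axes=(0, 1))  # (Px, Py//2+1, nz)
            A[:, j, :] = khat.reshape(-1, nz)
        self._fft.update(A=A, Aconj=A.conj(), Px=Px, Py=Py)
        return self._fft

    # -- forward / adjoint -------------------------------------------------

    def forward(self, volume: np.ndarray) -> np.ndarray:
        """W @ O: (nx, ny, nz) volume -> (nx, nd, ny) measurements."""
        nx, ny, nz = self.grid.shape
        if volume.shape != (nx, ny, nz):
            raise ValueError("volume shape mismatch")
        p = self._plan()
        Px, Py = p["Px"], p["Py"]
        ohat = rfft2(volume, s=(Px, Py), axes=(0, 1)).reshape(-1, nz)
        fhat = np.matmul(p["Aconj"], ohat[:, :, None])[:, :, 0]  # (P, nd)
        f = irfft2(
            fhat.reshape(Px, Py // 2 + 1, -1), s=(Px, Py), axes=(0, 1)
        )[:nx, :ny, :]
        return np.ascontiguousarray(np.transpose(f, (0, 2, 1)))

    def adjoint(self, meas: np.ndarray) -> np.ndarray:
        """W^T @ F: (nx, nd, ny) measurements -> (nx, ny, nz) volume."""
        nx, ny, nz = self.grid.shape
        if meas.shape != self.measurement_shape:
            raise ValueError("measurement shape mismatch")
        p = self._plan()
        Px, Py = p["Px"], p["Py"]
        f = np.transpose(meas, (0, 2, 1))  # (nx, ny, nd)
        fhat = rfft2(f, s=(Px, Py), axes=(0, 1)).reshape(-1, self.n_offsets)
        # O_adj[p, z] = sum_d A[p, d, z] * Fhat[p, d]
        ohat = np.matmul(fhat[:, None, :], p["A"])[:, 0, :]  # (P, nz)
        vol = irfft2(
            ohat.reshape(Px, Py // 2 + 1, nz), s=(Px, Py), axes=(0, 1)
        )[:nx, :ny, :]
        return np.ascontiguousarray(vol)

    def forward_offsets(self, volume: np.ndarray, offsets_vox) -> np.ndarray:
        """Born forward for an arbitrary offset list without caching FFTs.

        Used to render full-resolution measurement stacks; returns
        (nx, len(offsets), ny).
        """
        nx, ny, nz = self.grid.shape
        offs = np.asarray(offsets_vox, dtype=int)
        U = self.kernels.nu_half
        V = ny - 1
        Px = next_fast_len(nx + U)
        Py = next_fast_len(ny + V)
        ohat = rfft2(volume, s=(Px, Py), axes=(0, 1)).reshape(-1, nz)
        out = np.empty((nx, len(offs), ny))
        u = np.arange(-U, U + 1) % Px
        v = np.arange(-V, V + 1) % Py
        for j, d in enumerate(offs):
            kd = self.kernel(int(d))
            kpad = np.zeros((Px, Py, nz))
            kpad[np.ix_(u, v)] = kd
            khat = rfft2(kpad, axes=(0, 1)).reshape(-1, nz)
            fhat = np.einsum("pz,pz->p", khat.conj(), ohat)
            f = irfft2(fhat.reshape(Px, Py // 2 + 1), s=(Px, Py))[:nx, :ny]
            out[:, j, :] = f
        return out

    # -- diagnostics -------------------------------------------------------

    def column_norm_by_layer(self) -> np.ndarray:
        """||W[:, voxel]||_2 per depth layer for interior voxels."""
        nz = self.grid.nz
        acc = np.zeros(nz)
        for d in self.offsets_vox:
            kd = self.kernel(int(d))
            acc += (kd**2).sum(axis=(0, 1))
        return np.sqrt(acc)

    def mean_sensitivity_depth(self) -> np.ndarray:
        """Sensitivity-weighted mean depth (mm) per detector offset."""
        zc = self.grid.z_centers
        out = np.empty(self.n_offsets)
        for j, d in enumerate(self.offsets_vox):
            kd = self.kernel(int(d))
            w = kd.sum(axis=(0, 1))
            out[j] = float((w * zc).sum() / w.sum()) if w.sum() > 0 else np.nan
        return out
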