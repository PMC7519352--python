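"""Assembly of the weighted sensitivity matrix W and depth compensation.

W maps voxel fluorophore yield to (stage position, detector offset[, y
bin]) measurements:  W[(s, d), v] = G_d(v) * Phi_s(v) * voxel_volume.
Two backends are provided:

* ``sparse`` — explicit scipy.sparse rows from per-position fluence fields
  and per-offset Green fields (arbitrary media, small grids);
* ``conv`` — the block-convolutional operator of a homogeneous slab
  (:class:`~flotsim.forward.SlabForwardModel`), where rows for different
  stage positions are x-translates of each other and one MC pair serves
  the whole scan.

Depth compensation scales the columns of W by a per-layer diagonal
D_gamma, layer l (surface = 1) receiving weight M(A_l)^gamma with M(A_l)
the maximum singular value of the submatrix of layers 1..l; gamma = 0
leaves W unchanged.  Because M(A_l) is nondecreasing in l, deep layers are
up-weighted, countering the depth decay of sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, svds

from .forward import SlabForwardModel
from .mc import FluenceField, GreenField
from .medium import VoxelGrid

#: entries below this fraction of max(W) are dropped in sparse assembly
SPARSE_FLOOR_REL = 1.0e-6


@dataclass
class SensitivityMatrix:
    """The weighted sensitivity matrix W with provenance and index maps.

    Rows are measurements; columns are voxels in C order of (x, y, z).
    ``depth_weights`` holds the per-layer compensation diagonal currently
    applied to the columns (None means uncompensated).
    """

    grid: VoxelGrid
    backend: str  # "sparse" | "conv"
    matrix: sp.spmatrix | None = None
    model: SlabForwardModel | None = None
    row_index: dict | None = None  # sparse backend: (s, d) -> row
    depth_weights: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend == "sparse":
            if self.matrix is None:
                raise ValueError("sparse backend requires a matrix")
        elif self.backend == "conv":
            if self.model is None:
                raise ValueError("conv backend requires a forward model")
        else:
            raise ValueError(f"unknown backend {self.backend!r}")

    # -- shape -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        if self.backend == "sparse":
            return self.matrix.shape
        return (self.model.n_rows, self.model.n_cols)

    @property
    def measurement_shape(self):
        if self.backend == "conv":
            return self.model.measurement_shape
        return (self.shape[0],)

    def _weights_flat(self) -> np.ndarray | None:
        if self.depth_weights is None:
            return None
        w = np.ones(self.grid.shape) * self.depth_weights[None, None, :]
        return w.ravel()

    # -- matvec ------------------------------------------------------------

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64).ravel()
        w = self._weights_flat()
        if w is not None:
            x = x * w
        if self.backend == "sparse":
            return self.matrix @ x
        return self.model.forward(x.reshape(self.grid.shape)).ravel()

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64).ravel()
        if self.backend == "sparse":
            out = self.matrix.T @ y
        else:
            out = self.model.adjoint(y.reshape(self.model.measurement_shape)).ravel()
        w = self._weights_flat()
        return out * w if w is not None else out

    def as_linear_operator(self) -> LinearOperator:
        return LinearOperator(
            self.shape, matvec=self.matvec, rmatvec=self.rmatvec, dtype=np.float64
        )

    def sigma_max(self, n_iter: int = 30, seed: int = 0) -> float:
        """Largest singular value by power iteration on W^T W."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.shape[1])
        x /= np.linalg.norm(x)
        s = 0.0
        for _ in range(n_iter):
            y = self.matvec(x)
            x = self.rmatvec(y)
            nrm = np.linalg.norm(x)
            if nrm == 0:
                return 0.0
            s = np.sqrt(nrm)
            x /= nrm
        return float(s)

    # -- diagnostics -------------------------------------------------------

    def column_norm_by_layer(self) -> np.ndarray:
        """RMS-free column 2-norms aggregated per depth layer (interior)."""
        if self.backend == "conv":
            base = self.model.column_norm_by_layer()
        else:
            cn2 = np.asarray(self.matrix.multiply(self.matrix).sum(axis=0)).ravel()
            cn2 = cn2.reshape(self.grid.shape)
            base = np.sqrt(cn2.max(axis=(0, 1)))
        if self.depth_weights is not None:
            base = base * self.depth_weights
        return base

    def mean_sensitivity_depth(self) -> np.ndarray:
        """Sensitivity-weighted mean depth per detector offset (conv mode)."""
        if self.backend != "conv":
            raise NotImplementedError("mean depth profile requires conv backend")
        return self.model.mean_sensitivity_depth()


def build_weight_matrix(
    phis: list[FluenceField],
    greens: dict[int, GreenField],
    grid: VoxelGrid,
    offsets: list[int] | None = None,
    floor_rel: float = SPARSE_FLOOR_REL,
) -> SensitivityMatrix:
    """Explicit sparse W from per-position fluences and per-offset Greens.

    ``phis[s]`` is the excitation field with the source at stage position
    s; ``greens[d]`` the Green field of the detector bin with offset id d.
    Rows are ordered (s major, d minor) following ``offsets`` (default:
    sorted keys of ``greens``).
    """
    if offsets is None:
        offsets = sorted(greens)
    missing = [d for d in offsets if d not in greens]
    if missing:
        raise ValueError(f"missing Green field for offset bin(s) {missing}")
    for f in phis:
        if f.grid != grid:
            raise ValueError("fluence field grid mismatch")
    for d in offsets:
        if greens[d].grid != grid:
            raise ValueError("green field grid mismatch")
    vv = grid.voxel_volume
    rows = []
    row_index = {}
    r = 0
    for s, f in enumerate(phis):
        for d in offsets:
            rows.append((greens[d].green * f.phi).ravel() * vv)
            row_index[(s, d)] = r
            r += 1
    W = np.vstack(rows)
    if floor_rel > 0 and W.size:
        W[W < floor_rel * W.max()] = 0.0
    mat = sp.csr_matrix(W)
    return SensitivityMatrix(
        grid,
        "sparse",
        matrix=mat,
        row_index=row_index,
        provenance={
            "n_positions": len(phis),
            "offsets": list(offsets),
            "floor_rel": floor_rel,
        },
    )


def build_weight_matrix_conv(
    model: SlabForwardModel, provenance: dict | None = None
) -> SensitivityMatrix:
    """Block-convolutional W for a homogeneous slab."""
    return SensitivityMatrix(
        model.grid, "conv", model=model, provenance=provenance or {}
    )


def _layer_sigma_max(W: SensitivityMatrix, n_layers: int) -> np.ndarray:
    """M(A_l) = sigma_max of the submatrix of layers 1..l, per l."""
    nz = W.grid.nz
    out = np.empty(nz)
    for l in range(1, nz + 1):
        mask = np.zeros(W.grid.shape)
        mask[:, :, :l] = 1.0
        mflat = mask.ravel()

        def mv(x, mflat=mflat):
            return W.matvec(np.asarray(x).ravel() * mflat)

        def rmv(y, mflat=mflat):
            return W.rmatvec(y) * mflat

        op = LinearOperator(W.shape, matvec=mv, rmatvec=rmv)
        if min(W.shape) <= 2:
            # svds needs k < min(shape); fall back to power iteration
            rng = np.random.default_rng(0)
            x = rng.standard_normal(W.shape[1])
            s = 0.0
            for _ in range(50):
                y = mv(x)
                x = rmv(y)
                nrm = np.linalg.norm(x)
                if nrm == 0:
                    break
                s = np.sqrt(nrm)
                x /= nrm
            out[l - 1] = s
        else:
            out[l - 1] = svds(op, k=1, return_singular_vectors=False)[0]
    return out


def depth_compensate(W: SensitivityMatrix, gamma: float) -> SensitivityMatrix:
    """Apply the per-layer depth-compensation column weighting.

    gamma = 0 returns W unchanged.  Layers whose columns are entirely zero
    make the layer weight undefined and are rejected.
    """
    if not (0 <= gamma <= 3):
        raise ValueError(f"gamma must be in [0, 3], got {gamma}")
    if gamma == 0:
        return W
    layer_norms = W.column_norm_by_layer()
    dead = np.nonzero(layer_norms == 0)[0]
    if dead.size:
        raise ValueError(
            f"depth compensation undefined: all-zero columns at layer(s) {dead.tolist()}"
        )
    M = _layer_sigma_max(W, W.grid.nz)
    weights = M**gamma
    prior = W.depth_weights if W.depth_weights is not None else 1.0
    return SensitivityMatrix(
        W.grid,
        W.backend,
        matrix=W.matrix,
        model=W.model,
        row_index=W.row_index,
        depth_weights=prior * weights,
        provenance={**W.provenance, "gamma": gamma, "layer_sigma_max": M.tolist()},
    )
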