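"""Tikhonov inversion of the Born system with L-curve parameter selection.

Solves min ||W x - dF||^2 + lam^2 ||x||^2 with a damped iterative
least-squares solver (LSMR) on the sensitivity operator; the
regularization strength is chosen at the maximum-curvature corner of the
L-curve (log residual norm vs log solution norm over a log-spaced sweep).
Negative voxels are clipped to zero after the solve (the minimal
nonnegativity step on top of plain Tikhonov), which is flagged in the
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, aslinearoperator, lsmr

from .acquisition import MeasurementStack
from .medium import VoxelGrid
from .sensitivity import SensitivityMatrix


@dataclass(frozen=True)
class LCurvePoint:
    lam: float
    residual_norm: float
    solution_norm: float


@dataclass
class ReconstructionVolume:
    """Estimated fluorophore distribution and solver diagnostics."""

    grid: VoxelGrid
    values: np.ndarray  # nonnegative, grid-shaped
    lam: float
    residual_norm: float
    solution_norm: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("reconstruction shape does not match grid")


def _as_operator(W):
    if isinstance(W, SensitivityMatrix):
        return W.as_linear_operator()
    if isinstance(W, LinearOperator):
        return W
    return aslinearoperator(np.asarray(W) if not hasattr(W, "tocsr") else W)


def tikhonov_solve(
    W,
    dF: np.ndarray,
    lam: float,
    atol: float = 1.0e-8,
    maxiter: int | None = None,
    x0: np.ndarray | None = None,
):
    """Damped least squares: argmin ||W x - dF||^2 + lam^2 ||x||^2.

    Accepts a SensitivityMatrix, LinearOperator, dense or sparse matrix.
    Returns (x, info) where info carries the residual/solution norms, the
    LSMR stop reason and iteration count, and ``minimum_norm_warning``
    when lam = 0 (a rank-deficient system then yields the minimum-norm
    least-squares solution).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    op = _as_operator(W)
    dF = np.asarray(dF, dtype=np.float64).ravel()
    if dF.shape[0] != op.shape[0]:
        raise ValueError(
            f"dF has length {dF.shape[0]}, W has {op.shape[0]} rows"
        )
    if maxiter is None:
        # scipy's default (min(m, n)) truncates damped systems well before
        # convergence; damped LSMR may need several times that
        maxiter = max(200, 4 * min(op.shape))
    res = lsmr(
        op,
        dF,
        damp=lam,
        atol=atol,
        btol=atol,
        conlim=0,
        maxiter=maxiter,
        x0=x0,
    )
    x = res[0]
    resid = float(np.linalg.norm(op.matvec(x) - dF))
    info = {
        "istop": int(res[1]),
        "itn": int(res[2]),
        "residual_norm": resid,
        "solution_norm": float(np.linalg.norm(x)),
        "minimum_norm_warning": lam == 0,
    }
    return x, info


def default_lambda_grid(W, n: int = 20, span=(1.0e-4, 1.0e2), seed: int = 0):
    """Log-spaced regularization grid scaled by an estimate of ||W||_2."""
    if isinstance(W, SensitivityMatrix):
        scale = W.sigma_max(seed=seed)
    else:
        op = _as_operator(W)
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(op.shape[1])
        x /= np.linalg.norm(x)
        s = 1.0
        for _ in range(30):
            y = op.matvec(x)
            x = op.rmatvec(y)
            nrm = np.linalg.norm(x)
            if nrm == 0:
                break
            s = np.sqrt(nrm)
            x /= nrm
        scale = s
    return scale * np.logspace(np.log10(span[0]), np.log10(span[1]), n)


def _corner_index(points: list[LCurvePoint]) -> tuple[int, np.ndarray]:
    """Index of the maximum-curvature corner of the log-log L-curve.

    Near-duplicate sweep points (the flat plateau where lam is far below
    the smallest relevant singular value) are collapsed before
    differencing — duplicated points otherwise produce spurious curvature
    at the plateau.  Curvature is then estimated by central finite
    differences along the pruned sweep; ties break toward larger lam
    (the smoother solution).
    """
    xi = np.log10([max(p.residual_norm, 1.0e-300) for p in points])
    eta = np.log10([max(p.solution_norm, 1.0e-300) for p in points])
    keep = [0]
    for i in range(1, len(points)):
        if (
            abs(xi[i] - xi[keep[-1]]) > 1.0e-3
            or abs(eta[i] - eta[keep[-1]]) > 1.0e-3
        ):
            keep.append(i)
    kappa_full = np.full(len(points), -np.inf)
    if len(keep) < 3:
        return len(points) - 1, kappa_full
    xk, yk = xi[keep], eta[keep]
    dx = np.gradient(xk)
    dy = np.gradient(yk)
    ddx = np.gradient(dx)
    ddy = np.gradient(dy)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (dx * ddy - dy * ddx) / denom, -np.inf)
    # endpoints carry one-sided estimates only
    kappa[0] = kappa[-1] = -np.inf
    kappa_full[np.asarray(keep)] = kappa
    best = int(np.nanargmax(kappa_full))
    cand = np.nonzero(
        np.isclose(kappa_full, kappa_full[best], rtol=1.0e-12, atol=0.0)
    )[0]
    return int(cand.max()), kappa_full


def l_curve_select(
    W,
    dF: np.ndarray,
    lambdas: np.ndarray | None = None,
    atol: float = 1.0e-6,
    maxiter: int | None = None,
    return_solutions: bool = False,
):
    """Sweep the regularization grid and pick the L-curve corner.

    Returns (lam_star, points[, solutions]).  The grid must hold at least
    5 points spanning at least 3 decades (a single point is returned
    as-is with the curvature flagged undefined).
    """
    if lambdas is None:
        lambdas = default_lambda_grid(W)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))
    if np.any(lambdas <= 0):
        raise ValueError("lambda grid must be positive")
    if len(lambdas) == 1:
        lam = float(lambdas[0])
        x, info = tikhonov_solve(W, dF, lam, atol=atol, maxiter=maxiter)
        pt = LCurvePoint(lam, info["residual_norm"], info["solution_norm"])
        out = (lam, [pt]) if not return_solutions else (lam, [pt], [x])
        return out
    if len(lambdas) < 5 or lambdas[-1] / lambdas[0] < 1.0e3:
        raise ValueError("lambda grid needs >= 5 points spanning >= 3 decades")
    points = []
    solutions = []
    x_warm = None
    for lam in lambdas[::-1]:  # largest first: cheap solves, warm starts
        x, info = tikhonov_solve(W, dF, float(lam), atol=atol, maxiter=maxiter, x0=x_warm)
        x_warm = x
        points.append(LCurvePoint(float(lam), info["residual_norm"], info["solution_norm"]))
        if return_solutions:
            solutions.append(x)
    points = points[::-1]
    solutions = solutions[::-1]
    rn = np.array([p.residual_norm for p in points])
    sn = np.array([p.solution_norm for p in points])
    if np.allclose(rn, rn[0]) and np.allclose(sn, sn[0]):
        raise ValueError("degenerate L-curve: all sweep points identical")
    idx, _ = _corner_index(points)
    lam_star = points[idx].lam
    if return_solutions:
        return lam_star, points, solutions
    return lam_star, points


@dataclass(frozen=True)
class ReconstructOptions:
    lam: float | None = None  # fixed lambda (skips the L-curve)
    lambdas: np.ndarray | None = None
    n_lambdas: int = 20
    lambda_span: tuple = (1.0e-4, 1.0e2)
    gamma: float = 0.0
    background: float | None = None  # dark level; None -> estimate
    atol: float = 1.0e-8
    sweep_atol: float = 1.0e-6
    maxiter: int | None = 200
    clip_negative: bool = True


def rebin_stack(stack: MeasurementStack, W: SensitivityMatrix) -> np.ndarray:
    """Average camera pixels onto W's measurement lattice.

    Maps stage positions to voxel x bins, offset pixels to W's offset
    bins, and along-line pixels to voxel y bins; the leakage (source)
    column is excluded.  Returns (nx, nd, ny) in camera counts.
    """
    if W.backend != "conv":
        raise ValueError("stack rebinning requires the conv backend")
    grid = W.grid
    model = W.model
    h = grid.voxel_size
    acq = stack.acq
    frames = stack.frames.astype(np.float64)

    sx = acq.stage_positions
    s_bin = np.floor(sx / h).astype(int)
    ok_s = (s_bin >= 0) & (s_bin < grid.nx)

    off = acq.offset_positions - acq.offset_positions[stack.source_col]
    d_vals = model.offsets_vox * h
    half = 0.5 * h * (model.offsets_vox[1] - model.offsets_vox[0]) if len(d_vals) > 1 else 0.5 * h
    d_bin = np.searchsorted(d_vals + half, off)
    ok_d = (d_bin < len(d_vals)) & (np.abs(off - d_vals[np.clip(d_bin, 0, len(d_vals) - 1)]) <= half)
    ok_d &= np.arange(len(off)) != stack.source_col

    yv = acq.along_positions
    y_bin = np.floor(yv / h).astype(int)
    ok_y = (y_bin >= 0) & (y_bin < grid.ny)

    acc = np.zeros(model.measurement_shape)
    cnt = np.zeros(model.measurement_shape)
    si = s_bin[ok_s]
    di = d_bin[ok_d]
    yi = y_bin[ok_y]
    sub = frames[np.ix_(ok_s, ok_d, ok_y)]
    for a, sb in enumerate(si):
        np.add.at(acc[sb], np.ix_(di, yi), sub[a])
        np.add.at(cnt[sb], np.ix_(di, yi), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return out


def reconstruct_volume(
    stack: MeasurementStack,
    W: SensitivityMatrix,
    options: ReconstructOptions | None = None,
) -> ReconstructionVolume:
    """Full inversion of a measurement stack.

    Rebins the frames onto W's measurement lattice (leakage column
    masked), subtracts the background level, selects lambda on the
    L-curve (unless fixed), solves the damped least-squares system, clips
    negatives, and reshapes to the grid.
    """
    opts = options or ReconstructOptions()
    if W.backend != "conv":
        raise ValueError("reconstruct_volume requires a conv-backend W")
    grid = W.grid
    meas = rebin_stack(stack, W)

    if opts.background is not None:
        n0 = opts.background
    else:
        # median of the deepest-offset 10% of bins: fluorescence there is
        # negligible, leaving dark level + noise
        tail = meas[:, -max(1, meas.shape[1] // 10):, :]
        n0 = float(np.median(tail))
    dF = (meas - n0).ravel()

    Wg = W
    if opts.gamma > 0:
        from .sensitivity import depth_compensate

        Wg = depth_compensate(W, opts.gamma)

    diagnostics = {"background": n0, "gamma": opts.gamma}
    if opts.lam is not None:
        lam = float(opts.lam)
        x, info = tikhonov_solve(Wg, dF, lam, atol=opts.atol, maxiter=opts.maxiter)
        points = []
    else:
        lambdas = opts.lambdas
        if lambdas is None:
            lambdas = default_lambda_grid(
                Wg, n=opts.n_lambdas, span=opts.lambda_span
            )
        lam, points = l_curve_select(
            Wg, dF, lambdas, atol=opts.sweep_atol, maxiter=opts.maxiter
        )
        x, info = tikhonov_solve(Wg, dF, lam, atol=opts.atol, maxiter=opts.maxiter)
    if Wg.depth_weights is not None:
        # the compensated system solves for D^-1 x; map back to yield units
        w = (np.ones(grid.shape) * Wg.depth_weights[None, None, :]).ravel()
        x = x * w
    n_neg = int((x < 0).sum())
    if opts.clip_negative:
        x = np.maximum(x, 0.0)
    diagnostics.update(
        lcurve=[(p.lam, p.residual_norm, p.solution_norm) for p in points],
        solver=info,
        clipped_negative_voxels=n_neg,
    )
    return ReconstructionVolume(
        grid,
        x.reshape(grid.shape),
        lam,
        info["residual_norm"],
        info["solution_norm"],
        diagnostics,
    )
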