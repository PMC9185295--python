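"""Temporally consistent dense optical flow against a clip's first frame.

Every frame ``t`` in {2..L} is registered to the reference frame (frame 1),
yielding displacement fields ``u`` (horizontal) and ``v`` (vertical) of shape
``N x M x (L-1)``.  The solver minimizes a discretized energy with three
terms:

* a robust (Charbonnier) brightness-constancy penalty, weight ``alpha``;
* a trajectory-subspace penalty, weight ``beta``: the per-pixel displacement
  trajectory ``(u(t), v(t))`` is pulled toward its projection onto the span
  of ``R`` basis trajectories (discrete cosine curves by default), which
  enforces temporal consistency of the flow across the clip;
* total-variation spatial regularization of the flow fields.

Minimization is block-coordinate: alternating (a) per-frame linearized
brightness + TV updates (coarse-to-fine with warping, IRLS-weighted Jacobi
sweeps) and (b) closed-form least-squares projection of trajectories onto the
basis span.  A backtracking step guard at the finest pyramid level makes the
tracked energy non-increasing over outer iterations.  The solver is fully
deterministic: flow is initialized to zero at the coarsest level and no
randomness is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.color import hsv2rgb
from skimage.transform import resize

from .clip_io import Clip
from .exceptions import ConfigError, InputError, SolverError

_EPS_BRIGHT = 1e-3   # Charbonnier epsilon for the data term (intensity units)
_EPS_TV = 0.05       # Charbonnier epsilon for the TV term (pixel units)


@dataclass
class FlowSolverConfig:
    """Parameters of the trajectory-regularized flow solver.

    ``alpha`` weights the brightness-constancy penalty and ``beta`` the
    trajectory-subspace penalty; the TV term has unit weight.  ``n_basis``
    (R) is the number of basis trajectories; ``None`` means ``min(6, L-1)``.
    ``basis_trajectories`` optionally supplies a custom ``(L-1, R)`` basis
    (orthonormalized internally); the default is the first R discrete cosine
    trajectories.  The ``pairwise`` backend solves each frame independently
    (equivalent to ``beta = 0``).
    """

    alpha: float = 10.0
    beta: float = 1.0
    n_basis: int | None = None
    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    iterations_per_level: int = 50
    inner_sweeps: int = 3
    backend: Literal["trajectory", "pairwise"] = "trajectory"
    basis_trajectories: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta < 0:
            raise ConfigError("alpha must be > 0 and beta >= 0")
        if self.pyramid_levels < 1:
            raise ConfigError("pyramid_levels must be >= 1")
        if not 0 < self.pyramid_scale < 1:
            raise ConfigError("pyramid_scale must be in (0, 1)")
        if self.backend not in ("trajectory", "pairwise"):
            raise ConfigError(f"unknown flow backend {self.backend!r}")


@dataclass
class FlowSequence:
    """Flow of frames 2..L against the reference frame (frame 1).

    ``U`` and ``V`` have shape (N, M, L-1); slice ``t`` maps reference-frame
    pixels to frame ``t+2`` (1-based).  ``energy_history`` records the
    solver's objective at each outer iteration of the finest pyramid level.
    """

    U: np.ndarray
    V: np.ndarray
    reference_index: int = 0
    energy_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.U.shape != self.V.shape:
            raise InputError("U and V must share shape")
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.V))):
            raise InputError("flow fields must be finite")

    @property
    def n_fields(self) -> int:
        return self.U.shape[2]


def dct_trajectory_basis(n_frames: int, n_basis: int) -> np.ndarray:
    """Orthonormal DCT-II basis trajectories, shape (n_frames, n_basis).

    The first trajectory is constant, the rest are cosines of increasing
    frequency — a smooth, orthogonal default for trajectory subspaces.
    """
    if not 1 <= n_basis <= n_frames:
        raise ConfigError(f"need 1 <= n_basis <= {n_frames}, got {n_basis}")
    t = np.arange(n_frames)
    Q = np.cos(np.pi * (2 * t[:, None] + 1) * np.arange(n_basis)[None, :] / (2 * n_frames))
    Q[:, 0] *= np.sqrt(1.0 / n_frames)
    if n_basis > 1:
        Q[:, 1:] *= np.sqrt(2.0 / n_frames)
    return Q


def _warp(img: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Backward-warp ``img`` by (U, V): out(y, x) = img(y + V, x + U).

    Bilinear sampling with out-of-bounds coordinates clamped to the border.
    """
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return map_coordinates(img, [yy + V, xx + U], order=1, mode="nearest")


def _project_trajectories(
    U: np.ndarray, V: np.ndarray, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project each pixel's (u(t), v(t)) trajectory onto span(Q) columns.

    U, V have shape (F, N, M); Q is (F, R) with orthonormal columns.  The
    projection is applied to the u and v components separately, equivalent to
    a 2R-dimensional basis of R² trajectories.
    """
    F = U.shape[0]
    flat_u = U.reshape(F, -1)
    flat_v = V.reshape(F, -1)
    Uhat = (Q @ (Q.T @ flat_u)).reshape(U.shape)
    Vhat = (Q @ (Q.T @ flat_v)).reshape(V.shape)
    return Uhat, Vhat


def _tv_charbonnier(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Per-frame, per-pixel coupled TV magnitude sqrt(|∇u|²+|∇v|²+eps²)."""
    uy = np.diff(U, axis=1, append=U[:, -1:, :])
    ux = np.diff(U, axis=2, append=U[:, :, -1:])
    vy = np.diff(V, axis=1, append=V[:, -1:, :])
    vx = np.diff(V, axis=2, append=V[:, :, -1:])
    return np.sqrt(ux**2 + uy**2 + vx**2 + vy**2 + _EPS_TV**2)


def flow_energy(
    ref: np.ndarray,
    targets: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    alpha: float,
    beta: float,
    basis: np.ndarray | None,
) -> float:
    """Discretized solver objective for flow fields stacked as (F, N, M).

    The trajectory term is evaluated at the optimal (closed-form) subspace
    coefficients for the given flow, so this is a function of (U, V) alone.
    """
    e = 0.0
    for t in range(targets.shape[0]):
        w = _warp(targets[t], U[t], V[t])
        e += alpha * np.sum(np.sqrt((w - ref) ** 2 + _EPS_BRIGHT**2))
    if beta > 0 and basis is not None:
        Uhat, Vhat = _project_trajectories(U, V, basis)
        e += beta * float(np.sum((U - Uhat) ** 2 + (V - Vhat) ** 2))
    e += float(np.sum(_tv_charbonnier(U, V)))
    return float(e)


def _neighbor_sums(X: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted 4-neighborhood sums for the lagged-diffusivity TV update.

    Returns (G, S) with G = sum of edge weights and S = sum of g_e * X_q over
    existing neighbors q; edge weight g_e = (g_p + g_q) / 2.
    """
    G = np.zeros_like(X)
    S = np.zeros_like(X)
    # axis 1 = rows, axis 2 = cols; borders simply have fewer neighbors
    ge = 0.5 * (g[:, 1:, :] + g[:, :-1, :])
    G[:, 1:, :] += ge
    G[:, :-1, :] += ge
    S[:, 1:, :] += ge * X[:, :-1, :]
    S[:, :-1, :] += ge * X[:, 1:, :]
    ge = 0.5 * (g[:, :, 1:] + g[:, :, :-1])
    G[:, :, 1:] += ge
    G[:, :, :-1] += ge
    S[:, :, 1:] += ge * X[:, :, :-1]
    S[:, :, :-1] += ge * X[:, :, 1:]
    return G, S


def _iterate(
    ref: np.ndarray,
    targets: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    alpha: float,
    beta: float,
    basis: np.ndarray | None,
    sweeps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One outer iteration: warp, linearize, IRLS weights, Jacobi sweeps."""
    F, h, w = targets.shape
    max_disp = float(max(h, w))
    Ix = np.empty_like(U)
    Iy = np.empty_like(U)
    c = np.empty_like(U)
    wb = np.empty_like(U)
    for t in range(F):
        wt = _warp(targets[t], U[t], V[t])
        gy, gx = np.gradient(wt)
        Ix[t], Iy[t] = gx, gy
        r0 = wt - ref
        c[t] = r0 - gx * U[t] - gy * V[t]
        wb[t] = alpha / (2.0 * np.sqrt(r0**2 + _EPS_BRIGHT**2))

    if beta > 0 and basis is not None:
        Uhat, Vhat = _project_trajectories(U, V, basis)
    else:
        Uhat = Vhat = None

    g = 1.0 / (2.0 * _tv_charbonnier(U, V))
    Un, Vn = U.copy(), V.copy()
    for _ in range(sweeps):
        Gu, Su = _neighbor_sums(Un, g)
        _, Sv = _neighbor_sums(Vn, g)
        a11 = wb * Ix**2 + beta + Gu
        a12 = wb * Ix * Iy
        a22 = wb * Iy**2 + beta + Gu
        b1 = -wb * Ix * c + Su
        b2 = -wb * Iy * c + Sv
        if Uhat is not None:
            b1 = b1 + beta * Uhat
            b2 = b2 + beta * Vhat
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        Un = np.clip((a22 * b1 - a12 * b2) / det, -max_disp, max_disp)
        Vn = np.clip((a11 * b2 - a12 * b1) / det, -max_disp, max_disp)
    return Un, Vn


def _downscale(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(
        gaussian_filter(img, sigma=1.0), shape,
        order=1, mode="edge", anti_aliasing=False, preserve_range=True,
    )


def estimate_flow_sequence(clip: Clip, config: FlowSolverConfig | None = None) -> FlowSequence:
    """Estimate the dense flow of every frame against the clip's first frame.

    Coarse-to-fine over an image pyramid with zero initialization at the
    coarsest level.  With the ``trajectory`` backend, flow updates alternate
    with projection of per-pixel trajectories onto the basis span; the
    ``pairwise`` backend sets the trajectory weight to zero, solving each
    frame independently.

    Raises
    ------
    SolverError
        If non-finite values appear, naming the pyramid level and iteration.
    """
    cfg = config if config is not None else FlowSolverConfig()
    frames = clip.frames
    h, w, L = frames.shape
    if L < 2:
        raise InputError("clip must have at least 2 frames")
    F = L - 1
    ref = frames[:, :, 0]
    targets = np.moveaxis(frames[:, :, 1:], 2, 0)  # (F, N, M)

    beta = 0.0 if cfg.backend == "pairwise" else cfg.beta
    basis = None
    if beta > 0:
        if cfg.basis_trajectories is not None:
            B = np.asarray(cfg.basis_trajectories, dtype=np.float64)
            if B.shape[0] != F:
                raise ConfigError(
                    f"basis_trajectories must have {F} rows, got {B.shape[0]}"
                )
            basis, _ = np.linalg.qr(B)
        else:
            R = cfg.n_basis if cfg.n_basis is not None else min(6, F)
            if not 1 <= R <= F:
                raise ConfigError(f"need 1 <= n_basis <= {F}, got {R}")
            basis = dct_trajectory_basis(F, R)

    # pyramid shapes, finest first; stop shrinking below 8 px
    shapes = [(h, w)]
    for _ in range(cfg.pyramid_levels - 1):
        ph = int(round(shapes[-1][0] * cfg.pyramid_scale))
        pw = int(round(shapes[-1][1] * cfg.pyramid_scale))
        if min(ph, pw) < 8:
            break
        shapes.append((ph, pw))
    pyr_ref = [ref] + [_downscale(ref, s) for s in shapes[1:]]
    pyr_tgt = [
        [targets[t]] + [_downscale(targets[t], s) for s in shapes[1:]]
        for t in range(F)
    ]

    # Phase 1: per-frame coarse-to-fine solve (brightness + TV only), each
    # frame's coarsest level warm-started from the previous frame's flow, so
    # only the incremental per-frame motion must be recovered from scratch.
    U = np.empty((F, h, w), dtype=np.float64)
    V = np.empty_like(U)
    prev_u = prev_v = None
    for t in range(F):
        if prev_u is None:
            u = np.zeros((1, *shapes[-1]))
            v = np.zeros_like(u)
        else:
            su = shapes[-1][1] / w
            sv = shapes[-1][0] / h
            u = resize(prev_u, shapes[-1], order=1, mode="edge", preserve_range=True)[None] * su
            v = resize(prev_v, shapes[-1], order=1, mode="edge", preserve_range=True)[None] * sv
        for level in range(len(shapes) - 1, -1, -1):
            shape = shapes[level]
            if u.shape[1:] != shape:
                su = shape[1] / u.shape[2]
                sv = shape[0] / u.shape[1]
                u = resize(u[0], shape, order=1, mode="edge", preserve_range=True)[None] * su
                v = resize(v[0], shape, order=1, mode="edge", preserve_range=True)[None] * sv
            tgt_l = pyr_tgt[t][level][None]
            for it in range(cfg.iterations_per_level):
                u, v = _iterate(
                    pyr_ref[level], tgt_l, u, v, cfg.alpha, 0.0, None, cfg.inner_sweeps
                )
                if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
                    raise SolverError(
                        f"non-finite flow for frame {t + 2} at pyramid level "
                        f"{level}, iteration {it}"
                    )
        U[t], V[t] = u[0], v[0]
        prev_u, prev_v = u[0], v[0]

    # Phase 2: joint refinement at the finest level, alternating linearized
    # brightness/TV updates with trajectory-subspace projection.  A
    # backtracking guard keeps the tracked energy non-increasing.
    energy_history: list[float] = []
    e_prev = flow_energy(ref, targets, U, V, cfg.alpha, beta, basis)
    energy_history.append(e_prev)
    for it in range(cfg.iterations_per_level):
        Un, Vn = _iterate(ref, targets, U, V, cfg.alpha, beta, basis, cfg.inner_sweeps)
        if not (np.all(np.isfinite(Un)) and np.all(np.isfinite(Vn))):
            raise SolverError(f"non-finite flow in joint refinement, iteration {it}")
        e_new = flow_energy(ref, targets, Un, Vn, cfg.alpha, beta, basis)
        if e_new <= e_prev * (1 + 1e-12) + 1e-12:
            U, V, e_prev = Un, Vn, e_new
        else:
            for step in (0.5, 0.25, 0.125):
                Ud = U + step * (Un - U)
                Vd = V + step * (Vn - V)
                e_d = flow_energy(ref, targets, Ud, Vd, cfg.alpha, beta, basis)
                if e_d <= e_prev:
                    U, V, e_prev = Ud, Vd, e_d
                    break
            else:
                energy_history.append(e_prev)
                break  # no descent direction left: converged
        energy_history.append(e_prev)

    if beta > 0 and basis is not None:
        # final consolidation onto the trajectory subspace
        U, V = _project_trajectories(U, V, basis)

    return FlowSequence(
        U=np.moveaxis(U, 0, 2), V=np.moveaxis(V, 0, 2),
        reference_index=0, energy_history=energy_history,
    )


def mean_endpoint_error(
    U: np.ndarray, V: np.ndarray, U_gt: np.ndarray, V_gt: np.ndarray
) -> float:
    """Average Euclidean distance between estimated and true displacement."""
    return float(np.mean(np.hypot(U - U_gt, V - V_gt)))


def flow_color_code(
    u: np.ndarray, v: np.ndarray, max_flow: float | None = None
) -> np.ndarray:
    """Color-code one flow field: hue = direction, saturation = magnitude.

    Zero flow maps to white; magnitude is normalized by the field's maximum
    unless ``max_flow`` is supplied.  Returns an (N, M, 3) float RGB image.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise InputError(f"u and v shapes differ: {u.shape} vs {v.shape}")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise InputError("flow field must be finite")
    mag = np.hypot(u, v)
    scale = max_flow if max_flow is not None else float(mag.max())
    sat = mag / scale if scale > 0 else np.zeros_like(mag)
    hue = (np.arctan2(v, u) + np.pi) / (2 * np.pi)
    hsv = np.stack([hue, np.clip(sat, 0, 1), np.ones_like(hue)], axis=-1)
    return hsv2rgb(hsv)
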