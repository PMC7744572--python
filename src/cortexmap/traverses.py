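"""Cortical traverses along a Laplacian depth field.

A harmonic scalar field is solved on the cortical ribbon with Dirichlet
boundary values 0 on the outer contour (layer I/II interface) and 1 on the
inner contour (grey/white-matter interface).  Traverses are streamlines of
the field gradient, seeded at equidistant arc-length positions on the outer
contour and integrated to the inner contour; they never cross (gradient
flow of a harmonic potential) and sample the cortex at every relative
depth.  GLI profiles are read along them by bilinear interpolation at
equidistant relative-depth (arc-length) positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from .gli import GLIImage

__all__ = [
    "ScalarField",
    "Traverse",
    "GLIProfile",
    "solve_laplace",
    "trace_traverses",
    "sample_profile",
    "profiles_to_csv",
]

_SHIFTS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class ScalarField:
    """Discrete harmonic field on the cortical domain.

    ``values`` holds the solution on domain and boundary pixels and a
    nearest-neighbour extrapolation elsewhere (so gradients can be sampled
    right up to the boundary); ``domain`` marks the true cortical pixels.
    """

    values: np.ndarray
    domain: np.ndarray
    outer_contour: np.ndarray
    inner_contour: np.ndarray
    max_residual: float


@dataclass
class Traverse:
    """One streamline from the outer to the inner contour."""

    points: np.ndarray  # (M, 2) float (row, col), sub-pixel
    seed_index: int  # order along the outer contour
    seed_arclength_px: float  # arc-length of the seed on the outer contour

    @property
    def arclength_px(self) -> float:
        return float(np.hypot(*np.diff(self.points, axis=0).T).sum())


@dataclass
class GLIProfile:
    """GLI amplitudes at equidistant relative cortical depths."""

    values: np.ndarray  # (n_points,)
    traverse_index: int = -1


def _rasterize_polyline(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of grid pixels touched by a polyline (dense sampling)."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(contour, dtype=float)
    seg = np.diff(pts, axis=0)
    for (r0, c0), (dr, dc) in zip(pts[:-1], seg):
        n = max(2, int(np.ceil(2 * max(abs(dr), abs(dc)))) + 1)
        t = np.linspace(0.0, 1.0, n)
        rr = np.clip(np.rint(r0 + t * dr).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.rint(c0 + t * dc).astype(int), 0, shape[1] - 1)
        mask[rr, cc] = True
    return mask


def solve_laplace(
    domain: np.ndarray,
    outer_contour: np.ndarray,
    inner_contour: np.ndarray,
    tol: float = 1e-4,
) -> ScalarField:
    """Solve the discrete Laplace equation on ``domain``.

    Dirichlet values: 0 on pixels under the outer contour, 1 under the inner
    contour; boundaries without a prescribed value are no-flux (Neumann).
    Solved as a sparse SPD system by conjugate gradients; afterwards the
    5-point residual |sum(neighbours) - deg*u| / deg is verified to stay
    below ``tol`` on every interior pixel.
    """
    domain = np.asarray(domain, dtype=bool)
    shape = domain.shape
    fix0 = _rasterize_polyline(outer_contour, shape)
    fix1 = _rasterize_polyline(inner_contour, shape)
    if (fix0 & fix1).any():
        raise ValueError("outer and inner contours intersect on the grid")
    valid = domain | fix0 | fix1
    _, n_comp = ndimage.label(domain)
    if n_comp > 1:
        raise ValueError("domain is disconnected")

    fixed = fix0 | fix1
    unknown = domain & ~fixed
    n = int(unknown.sum())
    if n == 0:
        raise ValueError("no interior pixels between the contours")
    idx = np.full(shape, -1, dtype=np.int64)
    idx[unknown] = np.arange(n)
    fixed_val = np.zeros(shape)
    fixed_val[fix1] = 1.0

    rows_list, cols_list = [], []
    diag = np.zeros(n)
    b = np.zeros(n)
    ur, uc = np.nonzero(unknown)
    me = idx[ur, uc]
    for dr, dc in _SHIFTS:
        nr, nc = ur + dr, uc + dc
        inb = (nr >= 0) & (nr < shape[0]) & (nc >= 0) & (nc < shape[1])
        nr_i, nc_i, me_i = nr[inb], nc[inb], me[inb]
        vmask = valid[nr_i, nc_i]
        nr_v, nc_v, me_v = nr_i[vmask], nc_i[vmask], me_i[vmask]
        diag[me_v] += 1.0
        is_unknown = unknown[nr_v, nc_v]
        rows_list.append(me_v[is_unknown])
        cols_list.append(idx[nr_v[is_unknown], nc_v[is_unknown]])
        fx = ~is_unknown
        np.add.at(b, me_v[fx], fixed_val[nr_v[fx], nc_v[fx]])

    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    A = sparse.coo_matrix(
        (np.concatenate([diag, -np.ones(rows.size)]),
         (np.concatenate([np.arange(n), rows]),
          np.concatenate([np.arange(n), cols]))),
        shape=(n, n),
    ).tocsr()
    # ||r||_2 <= tol  =>  per-pixel |r_p|/deg <= tol
    x, info = cg(A, b, rtol=0.0, atol=0.5 * tol, maxiter=50_000)
    if info != 0:
        raise RuntimeError(f"Laplace CG did not converge (info={info})")

    u = np.full(shape, np.nan)
    u[fix1] = 1.0
    u[fix0] = 0.0
    u[unknown] = x

    res = np.abs(A @ x - b) / np.maximum(diag, 1.0)
    max_res = float(res.max())
    if max_res >= tol:
        raise RuntimeError(f"residual {max_res:.2e} exceeds tol {tol:.2e}")

    # nearest-neighbour extrapolation outside the valid set, so streamline
    # integration can interpolate gradients near the boundary
    missing = ~valid
    if missing.any():
        _, (ir, ic) = ndimage.distance_transform_edt(missing, return_indices=True)
        u_filled = u.copy()
        u_filled[missing] = u[ir[missing], ic[missing]]
    else:
        u_filled = u
    return ScalarField(
        values=u_filled,
        domain=domain,
        outer_contour=np.asarray(outer_contour, dtype=float),
        inner_contour=np.asarray(inner_contour, dtype=float),
        max_residual=max_res,
    )


def _bilinear(grid: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(grid, pts.T, order=1, mode="nearest")


def trace_traverses(
    field: ScalarField,
    n_traverses: int,
    step_px: float = 0.25,
    margin_frac: float = 0.02,
) -> list[Traverse]:
    """Integrate ``n_traverses`` streamlines of the field gradient.

    Seeds sit at equidistant arc-length positions on the outer contour
    (keeping a small margin off the contour ends); integration is fixed-step
    RK4 on the normalised gradient until the field value reaches ~1, then
    the exact nearest point of the inner contour is appended.
    """
    u = field.values
    gy, gx = np.gradient(u)

    outer = field.outer_contour
    seg = np.hypot(*np.diff(outer, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    s_targets = np.linspace(margin_frac * total, (1 - margin_frac) * total, n_traverses)
    seeds = np.column_stack([
        np.interp(s_targets, arc, outer[:, 0]),
        np.interp(s_targets, arc, outer[:, 1]),
    ])

    max_steps = int(4 * (u.shape[0] + u.shape[1]) / step_px)
    pos = seeds.copy()
    active = np.ones(n_traverses, dtype=bool)
    paths: list[list[np.ndarray]] = [[seeds[i].copy()] for i in range(n_traverses)]

    def grad_dir(p: np.ndarray) -> np.ndarray:
        g = np.column_stack([_bilinear(gy, p), _bilinear(gx, p)])
        norm = np.hypot(g[:, 0], g[:, 1])
        small = norm < 1e-12
        norm[small] = 1.0
        d = g / norm[:, None]
        d[small] = 0.0
        return d

    for _ in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        k1 = grad_dir(p)
        k2 = grad_dir(p + 0.5 * step_px * k1)
        k3 = grad_dir(p + 0.5 * step_px * k2)
        k4 = grad_dir(p + step_px * k3)
        p_new = p + (step_px / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        vals = _bilinear(u, p_new)
        pos[active] = p_new
        act_idx = np.nonzero(active)[0]
        for i, j in enumerate(act_idx):
            paths[j].append(p_new[i].copy())
        done = vals >= 0.995
        active[act_idx[done]] = False

    if active.any():
        bad = int(np.nonzero(active)[0][0])
        raise RuntimeError(
            f"traverse seed {bad} (arc-length {s_targets[bad]:.1f} px) did not "
            f"reach the inner contour within {max_steps} steps"
        )

    inner = field.inner_contour
    traverses = []
    for i in range(n_traverses):
        pts = np.asarray(paths[i])
        d2 = ((inner - pts[-1]) ** 2).sum(axis=1)
        nearest = inner[int(np.argmin(d2))]
        if np.hypot(*(nearest - pts[-1])) > 1e-9:
            pts = np.vstack([pts, nearest])
        traverses.append(
            Traverse(points=pts, seed_index=i, seed_arclength_px=float(s_targets[i]))
        )
    return traverses


def sample_profile(gli: GLIImage, traverse: Traverse, n_points: int = 100) -> GLIProfile:
    """Bilinearly sample a GLI grid at equidistant arc-length positions."""
    pts = traverse.points
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise ValueError("degenerate traverse (zero length)")
    s = np.linspace(0.0, arc[-1], n_points)
    rows = np.interp(s, arc, pts[:, 0])
    cols = np.interp(s, arc, pts[:, 1])
    # source-image pixel coords -> field-grid coords (field centres)
    f = gli.field_px
    gi = (rows - (f / 2.0 - 0.5)) / f
    gj = (cols - (f / 2.0 - 0.5)) / f
    nh, nw = gli.values.shape
    if (gi < -1).any() or (gi > nh).any() or (gj < -1).any() or (gj > nw).any():
        raise ValueError("traverse leaves the GLI grid")
    vals = ndimage.map_coordinates(
        gli.values, np.vstack([gi, gj]), order=1, mode="nearest"
    )
    return GLIProfile(values=vals, traverse_index=traverse.seed_index)


def profiles_to_csv(profiles: list[GLIProfile], path) -> None:
    import pandas as pd

    n = len(profiles[0].values)
    df = pd.DataFrame(
        [p.values for p in profiles],
        columns=[f"p{i:03d}" for i in range(n)],
    )
    df.insert(0, "traverse", [p.traverse_index for p in profiles])
    df.to_csv(path, index=False)
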