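"""Voxel-based cortical thickness (VBCT) on tissue segmentations.

Thickness is computed in native space from the repaired GM/WM/CSF
probability maps with the Laplace-equation layer method: the maps are
resampled to a finer sampling grid, the GM compartment is delimited by a
WM shell (potential 0) and a CSF shell (potential 1), the Laplace equation
is relaxed inside GM, and from every GM voxel a streamline is integrated
both ways along the normalised potential gradient; the summed arc length of
the two half-streamlines is the thickness at that voxel.  Working on
segmentations rather than surface meshes avoids fitting deformable surfaces
to damaged or buried cortex.

Parameter semantics (this package's definitions of the classic four knobs):
``sampling_resolution_mm`` is the grid spacing of the computation;
``csf_smoothness_mm``/``csf_thinness`` reconstruct thin sulcal CSF — the
CSF probability is smoothed and wherever the smoothed value reaches the
thinness threshold the voxel is forced to CSF before the tissue argmax;
``n_dilations`` lets the GM compartment grow into unlabeled support voxels
(never into WM or CSF, so thickness is not inflated);
``max_thickness_mm`` caps the streamline length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tpm import TPMSet
from .volumes import Volume, gaussian_smooth, resample

__all__ = [
    "VbctParams",
    "extract_boundaries",
    "solve_laplace",
    "streamline_thickness",
    "vbct",
]


@dataclass
class VbctParams:
    """Tunables of the thickness computation (defaults used throughout)."""

    sampling_resolution_mm: float = 0.5
    csf_smoothness_mm: float = 3.0
    csf_thinness: float = 0.65
    n_dilations: int = 1
    max_thickness_mm: float = 10.0

    def validate(self, voxel_size_mm: float) -> None:
        if self.sampling_resolution_mm <= 0 or self.sampling_resolution_mm > voxel_size_mm + 1e-9:
            raise ValueError("sampling resolution must be positive and <= voxel size")
        if not 0.0 < self.csf_thinness < 1.0:
            raise ValueError("csf_thinness must lie in (0, 1)")
        if self.n_dilations < 0 or self.max_thickness_mm <= 0:
            raise ValueError("invalid VBCT parameters")


@dataclass
class BoundarySet:
    """GM compartment and its Dirichlet shells on the sampling grid.

    ``theta``/``gval`` carry the sub-voxel boundary model: for each of the
    six axis directions, the fractional distance (in voxels, (0, 1]) from a
    GM voxel centre to the tissue interface when the neighbour in that
    direction is a boundary voxel, and the potential value (0 at the WM
    interface, 1 at the CSF interface) to impose there.  Derived from the
    linear crossing of the class-probability difference, this removes the
    half-voxel staircase bias of naive voxel-centre Dirichlet conditions.
    """

    gm_region: np.ndarray  # bool
    wm_boundary: np.ndarray  # bool
    csf_boundary: np.ndarray  # bool
    affine: np.ndarray
    sampling_mm: float
    theta: np.ndarray | None = None  # (6,) + grid, fractional edge distances
    gval: np.ndarray | None = None  # (6,) + grid, interface potential values
    is_dirichlet_dir: np.ndarray | None = None  # (6,) + grid, bool


_STRUCT6 = ndimage.generate_binary_structure(3, 1)

#: the six axis directions in the order used for edge-wise boundary data
_DIRECTIONS = [(ax, sgn) for ax in range(3) for sgn in (1, -1)]


def _shift(arr: np.ndarray, ax: int, sgn: int) -> np.ndarray:
    """Neighbour values: out[x] = arr[x + sgn * e_ax], zero-padded."""
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if sgn == 1:
        dst[ax], src[ax] = slice(0, -1), slice(1, None)
    else:
        dst[ax], src[ax] = slice(1, None), slice(0, -1)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _sampling_grid(ref: Volume, sampling_mm: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    voxel = float(ref.voxel_size_mm[0])
    r = sampling_mm / voxel
    shape = tuple(int(round(n * voxel / sampling_mm)) for n in ref.shape)
    aff = ref.affine.copy()
    aff[:3, :3] = ref.affine[:3, :3] * r
    aff[:3, 3] = ref.affine[:3, :3] @ (np.full(3, (r - 1.0) / 2.0)) + ref.affine[:3, 3]
    return aff, shape


def extract_boundaries(tpms: TPMSet, params: VbctParams | None = None) -> BoundarySet:
    """Delimit the GM compartment and its WM / CSF Dirichlet shells.

    Expects repaired segmentations (lesion mass already reassigned).  The
    class maps are resampled to the sampling resolution, thin sulcal CSF is
    reconstructed from the smoothed CSF probability, the per-voxel argmax
    labels the tissue, and the boundary shells are the WM / CSF voxels
    6-adjacent to the GM region.
    """
    params = params or VbctParams()
    ref = tpms.reference
    params.validate(float(ref.voxel_size_mm[0]))
    aff, shape = _sampling_grid(ref, params.sampling_resolution_mm)
    up = {
        c: resample(tpms[c], aff, shape, order=1)
        for c in ("gm", "wm", "csf")
    }
    csf_eff = np.asarray(up["csf"].data, dtype=float)
    if params.csf_smoothness_mm > 0:
        csf_sm = gaussian_smooth(up["csf"], params.csf_smoothness_mm).data
        csf_eff = np.maximum(csf_eff, (csf_sm >= params.csf_thinness).astype(float))
    stack = np.stack([np.asarray(up["gm"].data), np.asarray(up["wm"].data), csf_eff])
    support = stack.sum(axis=0) > 0.5
    labels = np.where(support, np.argmax(stack, axis=0) + 1, 0)  # 1 gm, 2 wm, 3 csf
    gm = labels == 1
    if not gm.any():
        raise ValueError("GM region is empty")
    for _ in range(params.n_dilations):
        grow = ndimage.binary_dilation(gm, _STRUCT6) & support & (labels == 0)
        gm = gm | grow
    dil = ndimage.binary_dilation(gm, _STRUCT6) & ~gm
    wm_b = dil & (labels == 2)
    csf_b = dil & (labels == 3)
    if not wm_b.any() or not csf_b.any():
        raise ValueError("GM region does not touch both WM and CSF")
    # sub-voxel interface model: level sets whose zero crossing is the
    # argmax boundary; the linear crossing along each edge locates the
    # interface at sub-voxel precision when the maps carry partial volume
    f_wm = np.asarray(up["gm"].data) - np.asarray(up["wm"].data)
    f_csf = np.asarray(up["gm"].data) - csf_eff
    shape = gm.shape
    theta = np.ones((6,) + shape)
    gval = np.zeros((6,) + shape)
    is_dir = np.zeros((6,) + shape, dtype=bool)
    for d, (ax, sgn) in enumerate(_DIRECTIONS):
        nb_wm = _shift(wm_b, ax, sgn)
        nb_csf = _shift(csf_b, ax, sgn)
        offset = np.zeros(3, dtype=int)
        offset[ax] = sgn
        for nb, f, g in ((nb_wm, f_wm, 0.0), (nb_csf, f_csf, 1.0)):
            sel = gm & nb
            if not sel.any():
                continue
            pts = np.argwhere(sel)
            nbr = pts + offset
            fx = f[tuple(pts.T)]
            fn = f[tuple(nbr.T)]
            denom = fx - fn
            th = np.where(np.abs(denom) > 1e-12, fx / np.where(denom == 0, 1, denom), 1.0)
            theta[d][sel] = np.clip(th, 0.1, 1.0)
            gval[d][sel] = g
            is_dir[d][sel] = True
    return BoundarySet(gm, wm_b, csf_b, aff, params.sampling_resolution_mm,
                       theta=theta, gval=gval, is_dirichlet_dir=is_dir)


def exact_shell_boundaries(
    n: int, a_vox: float, b_vox: float, sampling_mm: float = 1.0
) -> BoundarySet:
    """Voxelised concentric-shell domain with exact sub-voxel crossings.

    Validation scaffolding: builds the GM compartment a < r < b on an n^3
    grid with the edge-wise interface distances computed analytically from
    the sphere equations, so the Laplace solution can be compared with the
    closed-form spherical potential independently of any map resampling.
    """
    centre = (np.array([n] * 3) - 1) / 2.0
    g = np.indices((n, n, n)).astype(float)
    r = np.sqrt(((g - centre.reshape(3, 1, 1, 1)) ** 2).sum(0))
    gm = (r > a_vox) & (r < b_vox)
    dil = ndimage.binary_dilation(gm, _STRUCT6) & ~gm
    wm_b = dil & (r <= a_vox)
    csf_b = dil & (r >= b_vox)
    shape = gm.shape
    theta = np.ones((6,) + shape)
    gval = np.zeros((6,) + shape)
    is_dir = np.zeros((6,) + shape, dtype=bool)
    for d, (ax, sgn) in enumerate(_DIRECTIONS):
        for nb, R, gv in ((_shift(wm_b, ax, sgn), a_vox, 0.0),
                          (_shift(csf_b, ax, sgn), b_vox, 1.0)):
            sel = gm & nb
            if not sel.any():
                continue
            pts = np.argwhere(sel).astype(float) - centre
            c_ax = pts[:, ax]
            r2 = (pts**2).sum(axis=1)
            disc = np.sqrt(np.maximum(c_ax**2 - (r2 - R * R), 0.0))
            t_hi = -sgn * c_ax + disc
            t_lo = -sgn * c_ax - disc
            t = np.where((t_hi > 0) & (t_hi <= 1.0001), t_hi, t_lo)
            theta[d][sel] = np.clip(t, 0.1, 1.0)
            gval[d][sel] = gv
            is_dir[d][sel] = True
    aff = np.eye(4) * sampling_mm
    aff[3, 3] = 1.0
    return BoundarySet(gm, wm_b, csf_b, aff, sampling_mm,
                       theta=theta, gval=gval, is_dirichlet_dir=is_dir)


def solve_laplace(
    gm_region: np.ndarray,
    wm_boundary: np.ndarray,
    csf_boundary: np.ndarray,
    tol: float = 1e-5,
    max_sweeps: int = 10_000,
    omega: float = 1.7,
    subvoxel: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Relax the Laplace equation on the GM compartment.

    Dirichlet conditions: potential 0 at the WM interface, 1 at the CSF
    interface.  Red-black successive over-relaxation on the non-uniform
    stencil; interior neighbours outside the domain are reflecting
    (no-flux).  Converged when the maximum update over a sweep drops below
    ``tol``.

    ``subvoxel`` is the optional (theta, gval, is_dirichlet_dir) triple of a
    :class:`BoundarySet`: where given, the boundary value is imposed at the
    fractional edge distance theta instead of the neighbouring voxel centre
    (ghost-value stencil), which removes the half-voxel staircase bias of
    the voxelised boundary.  Without it, theta = 1 reproduces the classic
    voxel-centre condition.
    """
    if not (wm_boundary.any() and csf_boundary.any()):
        raise ValueError("both boundary shells must be non-empty")
    domain = gm_region & ~wm_boundary & ~csf_boundary
    valid = domain | wm_boundary | csf_boundary
    shape = gm_region.shape
    idx = np.argwhere(valid)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, shape)
    sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    sl6 = (slice(None),) + sl

    D = domain[sl]
    dirich = (wm_boundary | csf_boundary)[sl]
    csf_b = csf_boundary[sl]
    if subvoxel is not None:
        theta, gval, is_dir = (a[sl6].copy() for a in subvoxel)
    else:
        theta = np.ones((6,) + D.shape)
        gval = np.zeros((6,) + D.shape)
        is_dir = np.zeros((6,) + D.shape, dtype=bool)
        for d, (ax, sgn) in enumerate(_DIRECTIONS):
            is_dir[d] = _shift(dirich, ax, sgn)
            gval[d] = _shift(csf_b.astype(float), ax, sgn)
    nb_domain = np.stack([_shift(D, ax, sgn) for ax, sgn in _DIRECTIONS])
    nb_domain &= ~is_dir
    missing = ~(nb_domain | is_dir)
    # non-uniform stencil coefficients per direction and axis pair
    coef = np.empty_like(theta)
    diag = np.zeros(D.shape)
    for ax in range(3):
        tp, tm = theta[2 * ax], theta[2 * ax + 1]
        coef[2 * ax] = 1.0 / (tp * (tp + tm))
        coef[2 * ax + 1] = 1.0 / (tm * (tp + tm))
        diag += 1.0 / (tp * tm)
    mirror = np.sum(coef * missing, axis=0)
    denom = np.maximum(diag - mirror, 1e-12)
    const = np.sum(coef * is_dir * gval, axis=0)  # Dirichlet contribution

    P = np.zeros(D.shape)
    P[D] = 0.5
    P[csf_b] = 1.0
    red = np.indices(D.shape).sum(axis=0) % 2 == 0

    if _HAVE_NUMBA:
        # flat representation: red voxels first, per-voxel neighbour indices
        # (6-neighbour stencils never couple voxels of the same colour)
        flat_idx = np.flatnonzero(D.ravel())
        is_red = red.ravel()[flat_idx]
        order = np.concatenate([flat_idx[is_red], flat_idx[~is_red]])
        n_red = int(is_red.sum())
        strides = np.array(
            [int(s // P.itemsize) for s in P.strides], dtype=np.int64
        )
        nb = np.empty((len(order), 6), dtype=np.int64)
        cf = np.empty((len(order), 6))
        for d, (ax, sgn) in enumerate(_DIRECTIONS):
            use = nb_domain[d].ravel()[order]
            nb[:, d] = np.where(use, order + sgn * strides[ax], order)
            cf[:, d] = coef[d].ravel()[order] * use
        Pf = P.ravel()
        sweeps = _sor_compiled(
            Pf, order, n_red, nb, cf,
            const.ravel()[order], denom.ravel()[order],
            omega, tol, max_sweeps,
        )
        if sweeps < 0:
            raise RuntimeError("Laplace relaxation did not converge")
        P = Pf.reshape(P.shape)
    else:
        def relaxed(P):
            num = const.copy()
            for d, (ax, sgn) in enumerate(_DIRECTIONS):
                num += coef[d] * np.where(nb_domain[d], _shift(P, ax, sgn), 0.0)
            return num / denom

        for _ in range(max_sweeps):
            max_delta = 0.0
            for colour in (red, ~red):
                new = relaxed(P)
                upd = colour & D
                delta = omega * (new - P)
                if upd.any():
                    max_delta = max(max_delta, float(np.max(np.abs(delta[upd]))))
                    P[upd] += delta[upd]
            if max_delta < tol:
                break
        else:
            raise RuntimeError("Laplace relaxation did not converge")
    psi = np.zeros(shape)
    psi[sl][D] = P[D]
    psi[wm_boundary] = 0.0
    psi[csf_boundary] = 1.0
    return psi


try:  # compiled streamline tracer; the numpy path below is the fallback
    import numba

    @numba.njit(fastmath=True, cache=False)
    def _trace_compiled(gx, gy, gz, in_gm, starts, sign, step, max_len):  # pragma: no cover - exercised via _trace
        nx, ny, nz = in_gm.shape
        M = starts.shape[0]
        out = np.empty(M)
        n_steps = int(np.ceil(max_len / step))
        for m in range(M):
            x = starts[m, 0]
            y = starts[m, 1]
            z = starts[m, 2]
            length = max_len
            for i in range(n_steps):
                # one RK4 step along the normalised gradient direction
                px, py, pz = x, y, z
                k1x, k1y, k1z = _dir3(gx, gy, gz, px, py, pz, sign)
                h2 = 0.5 * step
                k2x, k2y, k2z = _dir3(gx, gy, gz, px + h2 * k1x, py + h2 * k1y,
                                      pz + h2 * k1z, sign)
                k3x, k3y, k3z = _dir3(gx, gy, gz, px + h2 * k2x, py + h2 * k2y,
                                      pz + h2 * k2z, sign)
                k4x, k4y, k4z = _dir3(gx, gy, gz, px + step * k3x,
                                      py + step * k3y, pz + step * k3z, sign)
                x = px + step / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
                y = py + step / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
                z = pz + step / 6.0 * (k1z + 2 * k2z + 2 * k3z + k4z)
                ix = int(round(x))
                iy = int(round(y))
                iz = int(round(z))
                if (
                    ix < 0 or iy < 0 or iz < 0
                    or ix >= nx or iy >= ny or iz >= nz
                    or in_gm[ix, iy, iz] == 0
                ):
                    length = (i + 0.5) * step
                    break
            out[m] = length
        return out

    @numba.njit(fastmath=True, inline="always", cache=False)
    def _dir3(gx, gy, gz, x, y, z, sign):  # pragma: no cover
        nx, ny, nz = gx.shape
        # clamp (edge-value continuation, matching mode="nearest")
        if x < 0.0:
            x = 0.0
        elif x > nx - 1.000001:
            x = nx - 1.000001
        if y < 0.0:
            y = 0.0
        elif y > ny - 1.000001:
            y = ny - 1.000001
        if z < 0.0:
            z = 0.0
        elif z > nz - 1.000001:
            z = nz - 1.000001
        i0 = int(x)
        j0 = int(y)
        k0 = int(z)
        fx = x - i0
        fy = y - j0
        fz = z - k0
        vx = 0.0
        vy = 0.0
        vz = 0.0
        for di in range(2):
            wi = fx if di else 1.0 - fx
            for dj in range(2):
                wj = fy if dj else 1.0 - fy
                for dk in range(2):
                    wk = fz if dk else 1.0 - fz
                    w = wi * wj * wk
                    vx += w * gx[i0 + di, j0 + dj, k0 + dk]
                    vy += w * gy[i0 + di, j0 + dj, k0 + dk]
                    vz += w * gz[i0 + di, j0 + dj, k0 + dk]
        norm = np.sqrt(vx * vx + vy * vy + vz * vz)
        if norm < 1e-12:
            norm = 1e-12
        return sign * vx / norm, sign * vy / norm, sign * vz / norm

    @numba.njit(cache=False)
    def _sor_compiled(P, order, n_red, nb, coef, const, denom, omega, tol,
                      max_sweeps):  # pragma: no cover - exercised via solve_laplace
        M = order.shape[0]
        for sweep in range(max_sweeps):
            max_delta = 0.0
            for half in range(2):
                lo = 0 if half == 0 else n_red
                hi = n_red if half == 0 else M
                for t in range(lo, hi):
                    v = order[t]
                    num = const[t]
                    for d in range(6):
                        num += coef[t, d] * P[nb[t, d]]
                    delta = omega * (num / denom[t] - P[v])
                    ad = abs(delta)
                    if ad > max_delta:
                        max_delta = ad
                    P[v] += delta
            if max_delta < tol:
                return sweep + 1
        return -1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _interp_vec(field: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (3,)+grid field at (M, 3) positions."""
    return np.stack(
        [
            ndimage.map_coordinates(field[c], pos.T, order=1, mode="nearest")
            for c in range(3)
        ],
        axis=1,
    )


def _trace(
    start: np.ndarray,
    direction_field: np.ndarray,
    sign: float,
    in_gm: np.ndarray,
    step_vox: float,
    max_len_vox: float,
) -> np.ndarray:
    """Arc length (voxels) from each start point to the compartment edge.

    RK4 along the (re-normalised) gradient direction; a point terminates
    when its nearest voxel leaves the GM region, with the crossing placed
    half a step back.  Points that exhaust the cap carry the cap length.
    """
    if _HAVE_NUMBA:
        return _trace_compiled(
            np.ascontiguousarray(direction_field[0]),
            np.ascontiguousarray(direction_field[1]),
            np.ascontiguousarray(direction_field[2]),
            np.ascontiguousarray(in_gm.astype(np.uint8)),
            np.ascontiguousarray(start.astype(np.float64)),
            float(sign), float(step_vox), float(max_len_vox),
        )
    M = len(start)
    pos = start.astype(float).copy()
    lengths = np.full(M, max_len_vox)
    active = np.ones(M, dtype=bool)
    n_steps = int(np.ceil(max_len_vox / step_vox))
    shape = np.array(in_gm.shape)

    def f(p):
        v = _interp_vec(direction_field, p)
        n = np.linalg.norm(v, axis=1, keepdims=True)
        return sign * v / np.maximum(n, 1e-12)

    for i in range(1, n_steps + 1):
        p = pos[active]
        k1 = f(p)
        k2 = f(p + 0.5 * step_vox * k1)
        k3 = f(p + 0.5 * step_vox * k2)
        k4 = f(p + step_vox * k3)
        p_new = p + (step_vox / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        pos[active] = p_new
        nearest = np.rint(p_new).astype(int)
        inside = np.all((nearest >= 0) & (nearest < shape), axis=1)
        still_gm = np.zeros(len(p_new), dtype=bool)
        still_gm[inside] = in_gm[tuple(nearest[inside].T)]
        done = ~still_gm
        if done.any():
            act_idx = np.flatnonzero(active)
            lengths[act_idx[done]] = (i - 0.5) * step_vox
            active[act_idx[done]] = False
        if not active.any():
            break
    return lengths


def streamline_thickness(
    psi: np.ndarray,
    boundaries: BoundarySet,
    native_ref: Volume,
    params: VbctParams | None = None,
) -> Volume:
    """Thickness per GM voxel from bidirectional streamline arc lengths.

    Integrates from each GM voxel centre along +grad(psi) to the CSF side
    and along -grad(psi) to the WM side (RK4, step = sampling/5); thickness
    is the sum of the two arc lengths, capped at ``max_thickness_mm``, and
    is resampled back to the native grid restricted to native GM support.
    Voxels with a vanishing potential gradient inherit the value of their
    nearest valid neighbour.
    """
    params = params or VbctParams()
    gm = boundaries.gm_region
    h_mm = boundaries.sampling_mm
    # continue the potential outside the compartment by nearest-neighbour
    # fill (0 beyond WM, 1 beyond CSF); without this the jump back to zero
    # past the CSF shell flips the interpolated gradient just inside the
    # boundary and streamlines stall instead of exiting
    valid = gm | boundaries.wm_boundary | boundaries.csf_boundary
    psi_ext = psi.copy()
    if (~valid).any():
        _, idx = ndimage.distance_transform_edt(~valid, return_indices=True)
        psi_ext[~valid] = psi[idx[0][~valid], idx[1][~valid], idx[2][~valid]]
    grad = np.stack(np.gradient(psi_ext))
    # outside the solved compartment the potential is constant; limit the
    # direction field to meaningful gradients
    norm = np.linalg.norm(grad, axis=0)
    valid_grad = norm > 1e-8
    starts = np.argwhere(gm)
    start_valid = valid_grad[tuple(starts.T)]
    step_vox = 0.2  # sampling/5 expressed in sampling-grid voxels
    max_len_vox = params.max_thickness_mm / h_mm
    up = _trace(starts[start_valid], grad, +1.0, gm, step_vox, max_len_vox)
    down = _trace(starts[start_valid], grad, -1.0, gm, step_vox, max_len_vox)
    thick_vox = np.clip(up + down, 0.0, max_len_vox)
    tmap = np.zeros(psi.shape)
    tmap[tuple(starts[start_valid].T)] = thick_vox * h_mm
    if (~start_valid).any():
        # nearest valid neighbour fill for degenerate-gradient voxels
        filled = tmap > 0
        _, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~filled, return_indices=True
        )
        bad = starts[~start_valid]
        tmap[tuple(bad.T)] = tmap[ix[tuple(bad.T)], iy[tuple(bad.T)], iz[tuple(bad.T)]]
    # back to native grid: weighted resample restricted to GM support
    samp_vol = Volume(data=tmap, affine=boundaries.affine, space=native_ref.space)
    ind_vol = Volume(data=gm.astype(float), affine=boundaries.affine,
                     space=native_ref.space)
    num = resample(samp_vol, native_ref.affine, native_ref.shape, order=1)
    den = resample(ind_vol, native_ref.affine, native_ref.shape, order=1)
    out = np.zeros(native_ref.shape)
    ok = den.data > 0.25
    out[ok] = num.data[ok] / den.data[ok]
    out = np.clip(out, 0.0, params.max_thickness_mm)
    return native_ref.with_data(out)


def vbct(tpms: TPMSet, params: VbctParams | None = None) -> Volume:
    """Full voxel-based cortical thickness on repaired segmentations.

    Deterministic composition of boundary extraction, Laplace relaxation
    and streamline integration; returns thickness in mm on the native grid,
    zero outside grey matter.
    """
    params = params or VbctParams()
    boundaries = extract_boundaries(tpms, params)
    sub = None
    if boundaries.theta is not None:
        sub = (boundaries.theta, boundaries.gval, boundaries.is_dirichlet_dir)
    psi = solve_laplace(boundaries.gm_region, boundaries.wm_boundary,
                        boundaries.csf_boundary, subvoxel=sub)
    thick = streamline_thickness(psi, boundaries, tpms.reference, params)
    # restrict to native GM support
    gm_native = np.asarray(tpms["gm"].data) >= np.maximum(
        np.asarray(tpms["wm"].data), np.asarray(tpms["csf"].data)
    )
    gm_native &= np.asarray(tpms["gm"].data) > 0.01
    return thick.with_data(np.where(gm_native, thick.data, 0.0))
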