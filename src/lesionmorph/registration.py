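"""Diffeomorphic registration, template construction and Jacobian modulation.

Warps are parameterised by stationary velocity fields and exponentiated by
scaling-and-squaring, which guarantees invertibility (the inverse warp is
generated by the negated velocity).  Pairwise registration minimises the
multi-class sum of squared differences between warped tissue probability
maps under Gaussian regularisation of the velocity updates, over a
multiresolution pyramid.  Group templates are built by iterating
register-all / average / recentre.

Displacement fields are stored in voxel units of the fixed grid; the world
(mm) mapping follows from the grid affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tpm import TPMSet
from .volumes import Volume, fwhm_to_sigma

__all__ = [
    "VelocityField",
    "DeformationField",
    "RegistrationParams",
    "exp_velocity",
    "register_pair",
    "build_template",
    "warp_volume",
    "warp_mask",
    "jacobian_det",
    "modulate",
    "warped_weighted_smooth",
    "random_velocity",
]


@dataclass
class VelocityField:
    """Stationary velocity generator of a diffeomorphism (voxel units)."""

    disp: np.ndarray  # (3,) + grid
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("velocity must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("velocity field contains non-finite values")

    @property
    def shape(self):
        return self.disp.shape[1:]

    def __neg__(self) -> "VelocityField":
        return VelocityField(-self.disp, self.affine)


@dataclass
class DeformationField:
    """Map from target-grid voxel coordinates to source voxel coordinates.

    ``disp`` holds the displacement u(x) so that phi(x) = x + u(x), in voxel
    units of the target grid.
    """

    disp: np.ndarray  # (3,) + grid
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("deformation must have shape (3, nx, ny, nz)")

    @property
    def shape(self):
        return self.disp.shape[1:]

    def coordinates(self) -> np.ndarray:
        """phi(x) = x + u(x) as an array of source voxel coordinates."""
        return self.disp + _identity_grid(self.shape)


def _identity_grid(shape) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    )


def _interp_disp(disp: np.ndarray, coords: np.ndarray, order: int = 3) -> np.ndarray:
    """Interpolate a displacement field at fractional voxel coordinates."""
    return np.stack(
        [
            ndimage.map_coordinates(disp[c], coords, order=order, mode="nearest")
            for c in range(3)
        ]
    )


def _compose_disp(a: np.ndarray, b: np.ndarray, order: int = 3) -> np.ndarray:
    """Displacement of phi_a o phi_b: u(x) = u_b(x) + u_a(x + u_b(x))."""
    coords = b + _identity_grid(b.shape[1:])
    return b + _interp_disp(a, coords, order=order)


def exp_velocity(
    v: VelocityField, max_step_vox: float = 0.25, order: int = 3
) -> DeformationField:
    """Exponentiate a stationary velocity field by scaling and squaring.

    The number of squarings K is chosen so the per-step displacement stays
    below ``max_step_vox`` voxels, keeping the small-deformation composition
    accurate; compositions interpolate with a spline of the given order.
    ``exp_velocity(-v)`` generates the inverse warp.
    """
    if not np.all(np.isfinite(v.disp)):
        raise ValueError("non-finite velocity field")
    max_disp = float(np.max(np.linalg.norm(v.disp, axis=0))) if v.disp.size else 0.0
    if max_disp == 0.0:
        return DeformationField(np.zeros_like(v.disp), v.affine)
    K = max(0, int(np.ceil(np.log2(max_disp / max_step_vox))))
    u = v.disp / (2.0**K)
    for _ in range(K):
        u = _compose_disp(u, u, order=order)
    return DeformationField(u, v.affine)


def _exp_fast(v: np.ndarray) -> np.ndarray:
    """Cheap exponential for the inner optimisation loop."""
    return exp_velocity(VelocityField(v), max_step_vox=0.5, order=1).disp


def warp_volume(vol: Volume, phi: DeformationField, order: int = 1) -> Volume:
    """Pull-back interpolation: out(x) = vol(phi(x)); out-of-field voxels 0."""
    coords = phi.coordinates()
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), coords, order=order, mode="constant", cval=0.0
    )
    return Volume(data=out, affine=vol.affine, space=vol.space)


def warp_mask(mask: Volume, phi: DeformationField) -> Volume:
    """Warp a binary mask with nearest-neighbour sampling and re-binarise."""
    out = warp_volume(mask, phi, order=0)
    return out.with_data((out.data >= 0.5).astype(np.uint8))


def warp_tpms(tpms: TPMSet, phi: DeformationField, order: int = 1) -> TPMSet:
    warped = {c: warp_volume(v, phi, order=order) for c, v in tpms.items()}
    # linear interpolation can overshoot fractionally; clip for validity
    warped = {c: v.with_data(np.clip(v.data, 0.0, 1.0)) for c, v in warped.items()}
    return TPMSet(warped, validate=False)


def jacobian_det(phi: DeformationField) -> Volume:
    """Determinant of the deformation gradient in voxel units.

    Central differences in the interior, one-sided at the boundary
    (np.gradient convention).  Strictly positive for a diffeomorphism.
    """
    grads = np.empty((3, 3) + phi.shape)
    for c in range(3):
        gx, gy, gz = np.gradient(phi.disp[c])
        grads[c, 0], grads[c, 1], grads[c, 2] = gx, gy, gz
    for c in range(3):
        grads[c, c] += 1.0
    det = (
        grads[0, 0] * (grads[1, 1] * grads[2, 2] - grads[1, 2] * grads[2, 1])
        - grads[0, 1] * (grads[1, 0] * grads[2, 2] - grads[1, 2] * grads[2, 0])
        + grads[0, 2] * (grads[1, 0] * grads[2, 1] - grads[1, 1] * grads[2, 0])
    )
    return Volume(data=det, affine=phi.affine)


def modulate(warped_gm: Volume, jac: Volume) -> Volume:
    """Jacobian modulation: voxelwise product preserving tissue volume."""
    warped_gm.require_same_grid(jac, "map and Jacobian")
    return warped_gm.with_data(np.asarray(warped_gm.data) * np.asarray(jac.data))


def warped_weighted_smooth(
    thickness_warped: Volume, weight: Volume, fwhm_mm: float = 6.0, eps: float = 1e-3
) -> Volume:
    """Weight-aware smoothing: smooth(w*t)/smooth(w) where smooth(w) > eps.

    The weight is typically warped GM probability times the Jacobian, so the
    average stays within cortex instead of bleeding across tissue boundaries.
    """
    thickness_warped.require_same_grid(weight, "thickness and weight")
    w = np.asarray(weight.data, dtype=float)
    if w.min() < -1e-9:
        raise ValueError("weights must be non-negative")
    if w.max() <= 0:
        raise ValueError("all-zero weight image")
    from .volumes import gaussian_smooth

    num = gaussian_smooth(thickness_warped.with_data(w * thickness_warped.data), fwhm_mm)
    den = gaussian_smooth(weight.with_data(w), fwhm_mm)
    out = np.zeros_like(w)
    ok = den.data > eps
    out[ok] = num.data[ok] / den.data[ok]
    return thickness_warped.with_data(out)


def random_velocity(
    shape, amplitude_vox: float, fwhm_vox: float, rng: np.random.Generator
) -> VelocityField:
    """Smooth random velocity field with given maximum displacement (voxels).

    White noise per component, Gaussian-smoothed, then globally rescaled so
    the maximum displacement norm equals ``amplitude_vox``.  Tapered to zero
    at the field-of-view edge.
    """
    v = rng.standard_normal((3,) + tuple(shape))
    sigma = fwhm_to_sigma(fwhm_vox)
    for c in range(3):
        v[c] = ndimage.gaussian_filter(v[c], sigma=sigma, mode="constant")
    # taper so displacements vanish at the boundary
    taper = np.ones(shape)
    for ax, n in enumerate(shape):
        ramp = np.minimum(np.arange(n), np.arange(n)[::-1]) / max(n // 8, 1)
        ramp = np.clip(ramp, 0.0, 1.0)
        taper *= ramp.reshape([-1 if a == ax else 1 for a in range(3)])
    v *= taper
    norms = np.linalg.norm(v, axis=0)
    peak = norms.max()
    if peak > 0 and amplitude_vox > 0:
        v *= amplitude_vox / peak
    else:
        v[:] = 0.0
    return VelocityField(v)


# ---------------------------------------------------------------------------
# pairwise registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationParams:
    """Tunables for SSD diffeomorphic registration.

    scales/iters define the multiresolution pyramid (downsampling factors
    and iteration counts); ``reg_fwhm_vox`` is the Gaussian regularisation
    applied to velocity updates, in voxels at each scale.
    """

    scales: tuple[int, ...] = (4, 2, 1)
    iters: tuple[int, ...] = (40, 30, 15)
    reg_fwhm_vox: float = 4.0
    tol: float = 1e-5
    initial_step_vox: float = 0.4


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(data, dtype=float)
    sm = ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def _upsample_velocity(v: np.ndarray, target_shape, factor: float) -> np.ndarray:
    out = np.empty((3,) + tuple(target_shape))
    for c in range(3):
        zoomed = ndimage.zoom(v[c], np.array(target_shape) / np.array(v[c].shape), order=1)
        out[c] = zoomed * factor
    return out


def _ssd(moving_stack: np.ndarray, fixed_stack: np.ndarray, u: np.ndarray) -> tuple[float, np.ndarray]:
    # edge-clamped sampling: out-of-field voxels keep the edge tissue value,
    # so the objective is not dominated by artificial zeros at the grid rim
    coords = u + _identity_grid(u.shape[1:])
    warped = np.stack(
        [
            ndimage.map_coordinates(m, coords, order=1, mode="nearest")
            for m in moving_stack
        ]
    )
    resid = warped - fixed_stack
    return float(np.sum(resid**2)), warped


def _register_single_scale(
    moving_stack: np.ndarray,
    fixed_stack: np.ndarray,
    v: np.ndarray,
    n_iter: int,
    reg_sigma: float,
    tol: float,
    initial_step: float,
) -> np.ndarray:
    u = _exp_fast(v)
    ssd, warped = _ssd(moving_stack, fixed_stack, u)
    step = None
    for _ in range(n_iter):
        resid = warped - fixed_stack
        force = np.zeros_like(v)
        for m in range(moving_stack.shape[0]):
            g = np.stack(np.gradient(warped[m]))
            force += resid[m] * g
        for c in range(3):
            force[c] = ndimage.gaussian_filter(force[c], sigma=reg_sigma)
        fmax = np.max(np.abs(force))
        if fmax == 0:
            break
        if step is None:
            step = initial_step / fmax
        improved = False
        for _ in range(5):
            v_trial = v - step * force
            u_trial = _exp_fast(v_trial)
            ssd_trial, warped_trial = _ssd(moving_stack, fixed_stack, u_trial)
            if ssd_trial < ssd:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        rel = (ssd - ssd_trial) / max(ssd, 1e-30)
        v, ssd, warped = v_trial, ssd_trial, warped_trial
        step *= 1.2
        if rel < tol:
            break
    return v


def register_pair(
    moving: TPMSet, fixed: TPMSet, params: RegistrationParams | None = None
) -> VelocityField:
    """Estimate a stationary velocity field warping ``moving`` onto ``fixed``.

    Minimises the summed squared difference over all shared tissue classes
    with Gaussian-smoothed velocity updates and backtracking on the
    objective, coarse to fine.  The objective is non-increasing across
    accepted iterations by construction.
    """
    params = params or RegistrationParams()
    if list(moving.classes) != list(fixed.classes):
        raise ValueError("moving and fixed TPM sets must share the same classes")
    moving.reference.require_same_grid(fixed.reference, "moving and fixed TPMs")
    mov_full = moving.stack()
    fix_full = fixed.stack()
    if float(np.sum(mov_full.sum(0) * fix_full.sum(0))) == 0.0:
        raise ValueError("no overlap between moving and fixed brain support")
    shape = moving.shape
    v = None
    prev_scale = None
    for scale, n_iter in zip(params.scales, params.iters):
        if min(shape) // scale < 4:
            continue
        mov_s = np.stack([_downsample(m, scale) for m in mov_full])
        fix_s = np.stack([_downsample(f, scale) for f in fix_full])
        if v is None:
            v = np.zeros((3,) + mov_s.shape[1:])
        else:
            v = _upsample_velocity(v, mov_s.shape[1:], prev_scale / scale)
        reg_sigma = fwhm_to_sigma(params.reg_fwhm_vox) / scale
        v = _register_single_scale(
            mov_s, fix_s, v, n_iter, max(reg_sigma, 0.5), params.tol,
            params.initial_step_vox,
        )
        prev_scale = scale
    if v is None:
        v = np.zeros((3,) + tuple(shape))
        prev_scale = 1
    if v.shape[1:] != tuple(shape):
        v = _upsample_velocity(v, shape, prev_scale)
    return VelocityField(v, moving.reference.affine)


def build_template(
    subject_tpms: list[TPMSet],
    n_outer: int = 3,
    params: RegistrationParams | None = None,
) -> tuple[TPMSet, list[VelocityField]]:
    """Iterative group-average template construction.

    Alternates registering every subject to the current template, recentring
    the velocity fields to zero mean (so the template stays in the middle of
    the cohort), and averaging the warped maps.  ``n_outer = 0`` returns the
    plain voxelwise average with zero velocities.
    """
    if len(subject_tpms) < 2:
        raise ValueError("template construction needs at least 2 subjects")
    ref = subject_tpms[0]
    classes = ref.classes
    for s in subject_tpms[1:]:
        if list(s.classes) != list(classes):
            raise ValueError("all subjects must share the same class set")
    stacks = [s.stack() for s in subject_tpms]
    template_stack = np.mean(stacks, axis=0)
    template = ref.with_stack(np.clip(template_stack, 0, 1), validate=False)
    shape = ref.shape
    velocities = [VelocityField(np.zeros((3,) + tuple(shape))) for _ in subject_tpms]
    for _ in range(n_outer):
        velocities = [register_pair(s, template, params) for s in subject_tpms]
        mean_v = np.mean([v.disp for v in velocities], axis=0)
        velocities = [VelocityField(v.disp - mean_v, v.affine) for v in velocities]
        warped = []
        for s, v in zip(subject_tpms, velocities):
            phi = exp_velocity(v)
            warped.append(np.stack([
                np.clip(warp_volume(s[c], phi).data, 0, 1) for c in classes
            ]))
        template_stack = np.mean(warped, axis=0)
        template = ref.with_stack(np.clip(template_stack, 0, 1), validate=False)
    for v in velocities:
        v.affine = ref.reference.affine
    return template, velocities
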