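"""Synthetic brain phantoms with known ground truth.

Real small-vessel-disease cohorts pair a T1-weighted and a FLAIR volume per
subject; no such data ships with this package, so every downstream stage is
exercised on phantoms that emulate the features the pipeline must handle:

* concentric CSF / GM-shell / WM-core anatomy (or a flat slab) with a known
  cortical thickness,
* white matter hyperintensities (WMH) that are FLAIR-bright but GM-like on
  T1 — so a naive T1-only segmentation misclassifies them as grey matter,
* lacunar infarcts whose gliotic cores look like CSF on T1,
* per-subject smooth random diffeomorphic deformations,
* a cohort in which WMH load covaries with GM-shell thinning at a known
  rate, the association the morphometry analysis is designed to detect.

Microbleeds, MR physics and skull/dura are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import registration as reg
from .volumes import Volume

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "IntensityModel",
    "CohortSpec",
    "make_labelmap",
    "implant_lesions",
    "implant_lesion_load",
    "render_intensities",
    "make_cohort",
    "Subject",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
]

LABEL_CSF = 0  # background / CSF
LABEL_GM = 1
LABEL_WM = 2


@dataclass
class PhantomSpec:
    """Geometry of a single phantom brain.

    ``sphere_shell`` places a WM sphere of radius ``wm_radius_mm`` wrapped in
    a GM shell of thickness ``gm_thickness_mm`` inside a CSF background;
    ``flat_slab`` stacks WM / GM / CSF along the z axis.  The anatomy must
    fit in the grid with at least a 3-voxel CSF margin.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.0
    wm_radius_mm: float = 16.0
    gm_thickness_mm: float = 3.0
    geometry: str = "sphere_shell"

    def validate(self) -> None:
        if self.gm_thickness_mm <= 0:
            raise ValueError("gm_thickness_mm must be > 0")
        if self.wm_radius_mm <= 0:
            raise ValueError("wm_radius_mm must be > 0")
        if self.geometry not in ("sphere_shell", "flat_slab"):
            raise ValueError(f"unknown geometry '{self.geometry}'")
        outer = self.wm_radius_mm + self.gm_thickness_mm
        margin = 3.0 * self.voxel_size_mm
        if self.geometry == "sphere_shell":
            half_extent = min(self.grid_shape) / 2.0 * self.voxel_size_mm
            if outer + margin > half_extent:
                raise ValueError(
                    "sphere-shell anatomy does not fit inside the grid with a "
                    "3-voxel CSF margin"
                )
        else:
            extent = self.grid_shape[2] * self.voxel_size_mm
            if outer + margin > extent:
                raise ValueError(
                    "flat-slab anatomy does not fit inside the grid with a "
                    "3-voxel CSF margin"
                )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class LesionSpec:
    """Lesion load of a single phantom subject.

    WMH and lacunar infarcts (LI) are carved into white matter as spheres;
    the inner ``li_gliosis_fraction`` of each LI radius is rendered with a
    CSF-like gliotic intensity.  WMH and LI masks are kept disjoint.
    """

    n_wmh: int = 4
    wmh_radius_mm_range: tuple[float, float] = (2.0, 5.0)
    n_li: int = 1
    li_radius_mm_range: tuple[float, float] = (2.0, 4.0)
    li_gliosis_fraction: float = 0.7


@dataclass
class IntensityModel:
    """Bivariate (T1, FLAIR) Gaussian intensity model per tissue class.

    The defaults are free parameters of the phantom (no quantitative lesion
    intensity statistics are available for the emulated scanner); they are
    chosen so that: WMH has a T1 mean between GM and WM but nearest GM and
    the largest FLAIR mean of all classes (so a T1-only segmentation
    misclassifies WMH as GM, while two-channel segmentation isolates it);
    gliosis is CSF-like on both channels (so a naive segmentation sends LI
    cores to CSF); FLAIR suppresses free CSF.
    """

    means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "csf": (30.0, 20.0),
            "gm": (80.0, 100.0),
            "wm": (110.0, 90.0),
            "wmh": (84.0, 140.0),
            "gliosis": (35.0, 28.0),
        }
    )
    covariances: dict[str, np.ndarray] | None = None
    noise_scale: float = 1.0
    bias_field_amplitude: float = 0.0

    def covariance(self, cls: str) -> np.ndarray:
        if self.covariances is not None and cls in self.covariances:
            cov = np.asarray(self.covariances[cls], dtype=float)
        else:
            cov = np.eye(2) * 25.0  # default sd 5 per channel
        cov = cov * self.noise_scale**2
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError(f"covariance for '{cls}' must be symmetric 2x2")
        eigvals = np.linalg.eigvalsh(cov)
        if self.noise_scale > 0 and eigvals.min() <= 0:
            raise ValueError(f"covariance for '{cls}' is not positive definite")
        return cov

    def validate(self) -> None:
        t1 = {c: m[0] for c, m in self.means.items()}
        flair = {c: m[1] for c, m in self.means.items()}
        lo, hi = sorted((t1["gm"], t1["wm"]))
        if not lo < t1["wmh"] < hi:
            raise ValueError("WMH T1 mean must lie between the GM and WM means")
        if flair["wmh"] != max(flair.values()):
            raise ValueError("WMH must have the largest FLAIR mean")
        for cls in self.means:
            self.covariance(cls)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``thinning_coefficient_mm_per_10k`` is the mm of GM-shell thickness lost
    per 10,000 mm^3 of WMH — the effect size the voxelwise analyses and the
    GPR prediction are asked to recover.  ``wmhv_range_mm3`` is the uniform
    range the per-subject target lesion load is drawn from; it is scaled to
    what the phantom's WM core can host.
    """

    n_subjects: int = 20
    age_mean_years: float = 70.0
    age_sd_years: float = 9.5
    male_fraction: float = 0.64
    wmhv_range_mm3: tuple[float, float] = (500.0, 12000.0)
    thinning_coefficient_mm_per_10k: float = 0.5
    warp_amplitude_mm: float = 1.0
    warp_fwhm_mm: float = 12.0
    master_seed: int = 0

    def validate(self, base_thickness_mm: float) -> None:
        if self.n_subjects < 3:
            raise ValueError("a cohort needs at least 3 subjects")
        min_thick = base_thickness_mm - self.thinning_coefficient_mm_per_10k * (
            self.wmhv_range_mm3[1] / 10_000.0
        )
        if min_thick < 0.5:
            raise ValueError(
                "thinning would drive GM thickness below 0.5 mm; reduce the "
                "thinning coefficient or the WMHV range"
            )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def make_labelmap(spec: PhantomSpec) -> Volume:
    """Integer label volume {0: CSF/background, 1: GM, 2: WM}."""
    spec.validate()
    shape = tuple(spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int16)
    if spec.geometry == "sphere_shell":
        centre = (np.array(shape) - 1) / 2.0
        grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, centre))) * spec.voxel_size_mm
        labels[r < spec.wm_radius_mm] = LABEL_WM
        labels[(r >= spec.wm_radius_mm) & (r < spec.wm_radius_mm + spec.gm_thickness_mm)] = LABEL_GM
    else:  # flat_slab: WM at the bottom of z, GM layer above, CSF on top
        z_mm = (np.arange(shape[2]) + 0.5) * spec.voxel_size_mm
        wm_top = spec.wm_radius_mm
        gm_top = wm_top + spec.gm_thickness_mm
        col = np.zeros(shape[2], dtype=np.int16)
        col[z_mm < wm_top] = LABEL_WM
        col[(z_mm >= wm_top) & (z_mm < gm_top)] = LABEL_GM
        labels[:, :, :] = col[np.newaxis, np.newaxis, :]
    return Volume(data=labels, affine=spec.affine)


def truth_tpms(labels: Volume, wmh_truth: Volume | None = None) -> "TPMSet":
    """One-hot GM/WM/CSF probability maps from a label volume.

    With ``wmh_truth`` given, a fourth WMH class is carved out of WM.
    """
    from .tpm import TPMSet

    lab = np.asarray(labels.data)
    maps = {
        "gm": labels.with_data((lab == LABEL_GM).astype(float)),
        "wm": labels.with_data((lab == LABEL_WM).astype(float)),
        "csf": labels.with_data((lab == LABEL_CSF).astype(float)),
    }
    if wmh_truth is not None:
        w = np.asarray(wmh_truth.data, dtype=bool)
        wm = np.asarray(maps["wm"].data).copy()
        wm[w] = 0.0
        maps["wm"] = labels.with_data(wm)
        maps["wmh"] = labels.with_data(w.astype(float))
    return TPMSet(maps, validate=False)


def partial_volume_tpms(spec: PhantomSpec) -> "TPMSet":
    """Analytic partial-volume GM/WM/CSF probability maps for a phantom.

    Each voxel's class probability is the (linearised) fraction of the voxel
    inside the compartment — the idealised output of a probabilistic
    segmentation, with sub-voxel interface information that one-hot label
    maps cannot carry.
    """
    from .tpm import TPMSet

    spec.validate()
    shape = tuple(spec.grid_shape)
    h = spec.voxel_size_mm

    def inside_fraction(signed_dist_mm: np.ndarray) -> np.ndarray:
        # signed distance to the compartment boundary, positive inside
        return np.clip(signed_dist_mm / h + 0.5, 0.0, 1.0)

    if spec.geometry == "sphere_shell":
        centre = (np.array(shape) - 1) / 2.0
        grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, centre))) * h
        p_in_a = inside_fraction(spec.wm_radius_mm - r)
        p_in_b = inside_fraction(spec.wm_radius_mm + spec.gm_thickness_mm - r)
    else:
        z = (np.arange(shape[2]) + 0.5) * h
        zz = np.broadcast_to(z, shape)
        p_in_a = inside_fraction(spec.wm_radius_mm - zz)
        p_in_b = inside_fraction(spec.wm_radius_mm + spec.gm_thickness_mm - zz)
    ref = Volume(data=np.zeros(shape), affine=spec.affine)
    return TPMSet(
        {
            "gm": ref.with_data(p_in_b - p_in_a),
            "wm": ref.with_data(p_in_a),
            "csf": ref.with_data(1.0 - p_in_b),
        },
        validate=False,
    )


def _sphere_mask(shape, centre_vox, radius_mm, voxel_size) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, centre_vox))) * voxel_size
    return r <= radius_mm


def _place_sphere(
    wm_free: np.ndarray,
    radius_mm: float,
    voxel_size: float,
    rng: np.random.Generator,
    wm_depth: np.ndarray | None = None,
) -> np.ndarray:
    """Pick a centre in free WM, preferring centres whose sphere fits inside.

    ``wm_depth`` is the distance-to-WM-edge map of the *unlesioned* WM; it
    is computed once per subject and reused, so consecutive spheres may abut
    (the masks stay consistent because the sphere is intersected with the
    currently free WM).
    """
    if wm_depth is None:
        wm_depth = ndimage.distance_transform_edt(wm_free, sampling=voxel_size)
    deep = np.argwhere(wm_free & (wm_depth >= radius_mm))
    candidates = deep if len(deep) else np.argwhere(wm_free)
    if len(candidates) == 0:
        raise ValueError("no white matter left for lesion placement")
    centre = candidates[rng.integers(len(candidates))]
    return _sphere_mask(wm_free.shape, centre, radius_mm, voxel_size) & wm_free


def implant_lesions(
    labels: Volume, lesions: LesionSpec, seed: int
) -> tuple[Volume, Volume, Volume]:
    """Carve WMH and LI spheres into white matter.

    Returns the lesioned label volume together with disjoint binary truth
    masks for WMH and LI.  Reproducible for a fixed seed.
    """
    lab = np.asarray(labels.data).copy()
    if not np.any(lab == LABEL_WM):
        raise ValueError("label volume contains no white matter")
    voxel = float(labels.voxel_size_mm[0])
    rng = np.random.default_rng(seed)
    wmh = np.zeros(lab.shape, dtype=bool)
    li = np.zeros(lab.shape, dtype=bool)
    depth = ndimage.distance_transform_edt(lab == LABEL_WM, sampling=voxel)
    for _ in range(lesions.n_wmh):
        free = (lab == LABEL_WM) & ~wmh & ~li
        radius = rng.uniform(*lesions.wmh_radius_mm_range)
        wmh |= _place_sphere(free, radius, voxel, rng, depth)
    for _ in range(lesions.n_li):
        free = (lab == LABEL_WM) & ~wmh & ~li
        radius = rng.uniform(*lesions.li_radius_mm_range)
        li |= _place_sphere(free, radius, voxel, rng, depth)
    return (
        labels.with_data(lab),
        labels.with_data(wmh.astype(np.uint8)),
        labels.with_data(li.astype(np.uint8)),
    )


def implant_lesion_load(
    labels: Volume,
    target_wmhv_mm3: float,
    lesions: LesionSpec,
    seed: int,
) -> tuple[Volume, Volume, Volume]:
    """Implant WMH spheres until the target lesion volume is reached.

    Spheres of radius drawn from the WMH range are added until the truth
    mask volume meets ``target_wmhv_mm3`` (the last sphere may overshoot);
    the recorded WMHV is always the realised mask volume.  LI lesions are
    implanted afterwards from the count in ``lesions``.
    """
    lab = np.asarray(labels.data).copy()
    voxel = float(labels.voxel_size_mm[0])
    voxvol = labels.voxel_volume_mm3
    rng = np.random.default_rng(seed)
    wmh = np.zeros(lab.shape, dtype=bool)
    li = np.zeros(lab.shape, dtype=bool)
    wm_total = float(np.sum(lab == LABEL_WM)) * voxvol
    if target_wmhv_mm3 > 0.85 * wm_total:
        raise ValueError("requested WMH volume exceeds available white matter")
    depth = ndimage.distance_transform_edt(lab == LABEL_WM, sampling=voxel)
    guard = 0
    while wmh.sum() * voxvol < target_wmhv_mm3:
        free = (lab == LABEL_WM) & ~wmh & ~li
        radius = rng.uniform(*lesions.wmh_radius_mm_range)
        wmh |= _place_sphere(free, radius, voxel, rng, depth)
        guard += 1
        if guard > 10_000:
            raise ValueError("lesion placement failed to reach the target volume")
    for _ in range(lesions.n_li):
        free = (lab == LABEL_WM) & ~wmh & ~li
        radius = rng.uniform(*lesions.li_radius_mm_range)
        li |= _place_sphere(free, radius, voxel, rng, depth)
    return (
        labels.with_data(lab),
        labels.with_data(wmh.astype(np.uint8)),
        labels.with_data(li.astype(np.uint8)),
    )


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


def _gliosis_core(li_mask: np.ndarray, fraction: float, voxel: float) -> np.ndarray:
    """Inner part of each LI rendered with gliotic (CSF-like) intensity."""
    if fraction <= 0 or not li_mask.any():
        return np.zeros_like(li_mask, dtype=bool)
    if fraction >= 1:
        return li_mask.astype(bool)
    dist_in = ndimage.distance_transform_edt(li_mask, sampling=voxel)
    labels_cc, n_cc = ndimage.label(li_mask)
    core = np.zeros_like(li_mask, dtype=bool)
    for i in range(1, n_cc + 1):
        comp = labels_cc == i
        rmax = dist_in[comp].max()
        core |= comp & (dist_in >= (1.0 - fraction) * rmax)
    return core


def class_map(
    labels: Volume, wmh_truth: Volume, li_truth: Volume, gliosis_fraction: float = 0.7
) -> np.ndarray:
    """Per-voxel intensity class name index array.

    Order: 0 csf, 1 gm, 2 wm, 3 wmh, 4 gliosis.  LI voxels outside the
    gliotic core keep WM intensity (the rim of a lacune).
    """
    lab = np.asarray(labels.data)
    cls = np.zeros(lab.shape, dtype=np.int8)
    cls[lab == LABEL_GM] = 1
    cls[lab == LABEL_WM] = 2
    wmh = np.asarray(wmh_truth.data, dtype=bool)
    li = np.asarray(li_truth.data, dtype=bool)
    cls[wmh] = 3
    core = _gliosis_core(li, gliosis_fraction, float(labels.voxel_size_mm[0]))
    cls[li] = 2  # lacune rim: WM-like
    cls[core] = 4
    return cls


CLASS_NAMES = ("csf", "gm", "wm", "wmh", "gliosis")

#: CSF rim thickness around the brain that counts as intracranial (voxels)
HEAD_CSF_RIM_VOX = 3


def head_mask(labels: Volume, rim_vox: int = HEAD_CSF_RIM_VOX) -> Volume:
    """Intracranial support: brain tissue plus a CSF rim around it.

    The label volume's class 0 is unbounded background; only the rim
    adjacent to GM/WM is rendered as CSF, the rest as air.  The head mask
    deforms with the subject's warp, so total intracranial volume varies
    across a cohort.
    """
    brain = np.asarray(labels.data) != LABEL_CSF
    head = ndimage.binary_dilation(brain, iterations=rim_vox)
    return labels.with_data(head.astype(np.uint8))


def render_intensities(
    labels: Volume,
    wmh_truth: Volume,
    li_truth: Volume,
    model: IntensityModel,
    seed: int = 0,
    gliosis_fraction: float = 0.7,
    head: Volume | None = None,
) -> tuple[Volume, Volume]:
    """Draw per-voxel (T1, FLAIR) intensities from the class Gaussians.

    Label-0 voxels inside the head mask are CSF; outside they are air
    (near-zero intensity).  With ``bias_field_amplitude > 0`` a
    multiplicative smooth bias field (1 + amplitude * smoothed noise,
    normalised to peak amplitude) is applied to both channels.
    """
    labels.require_same_grid(wmh_truth, "labels and WMH mask")
    labels.require_same_grid(li_truth, "labels and LI mask")
    model.validate()
    cls = class_map(labels, wmh_truth, li_truth, gliosis_fraction)
    rng = np.random.default_rng(seed)
    shape = cls.shape
    t1 = np.zeros(shape)
    flair = np.zeros(shape)
    for idx, name in enumerate(CLASS_NAMES):
        sel = cls == idx
        n = int(sel.sum())
        if n == 0:
            continue
        mean = np.asarray(model.means[name], dtype=float)
        cov = model.covariance(name)
        if model.noise_scale == 0:
            samples = np.tile(mean, (n, 1))
        else:
            L = np.linalg.cholesky(cov)
            samples = mean + rng.standard_normal((n, 2)) @ L.T
        t1[sel] = samples[:, 0]
        flair[sel] = samples[:, 1]
    if head is not None:
        out = ~np.asarray(head.data, dtype=bool)
        t1[out] = np.abs(rng.normal(0.0, 2.0, int(out.sum())))
        flair[out] = np.abs(rng.normal(0.0, 2.0, int(out.sum())))
    if model.bias_field_amplitude > 0:
        noise = rng.standard_normal(shape)
        noise = ndimage.gaussian_filter(noise, sigma=min(shape) / 4.0)
        noise /= np.max(np.abs(noise))
        bias = 1.0 + model.bias_field_amplitude * noise
        t1 *= bias
        flair *= bias
    return labels.with_data(t1), labels.with_data(flair)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class Subject:
    """All per-subject phantom outputs, including ground truth."""

    subject_id: str
    t1: Volume
    flair: Volume
    labels: Volume
    wmh_truth: Volume
    li_truth: Volume
    head: Volume
    true_thickness_mm: float
    warp: reg.DeformationField


def make_cohort(
    cohort: CohortSpec,
    phantom: PhantomSpec,
    lesions: LesionSpec,
    model: IntensityModel,
) -> tuple[pd.DataFrame, list[Subject]]:
    """Generate a cohort in which WMH load drives GM-shell thinning.

    Each subject's target WMHV is drawn uniformly from the cohort range, the
    GM-shell thickness is ``base - coefficient * WMHV / 10,000`` mm, a smooth
    random diffeomorphic warp individualises the anatomy, lesions are then
    implanted into the warped WM, and intensities rendered.  The returned
    table records the realised (voxel-exact) WMHV and LIV.
    """
    phantom.validate()
    cohort.validate(phantom.gm_thickness_mm)
    ss = np.random.SeedSequence(cohort.master_seed)
    children = ss.spawn(cohort.n_subjects)
    rows = []
    subjects = []
    voxel = phantom.voxel_size_mm
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sid = f"sub-{i:03d}"
        age = float(rng.normal(cohort.age_mean_years, cohort.age_sd_years))
        sex = int(rng.random() < cohort.male_fraction)  # 1 = male
        target_wmhv = float(rng.uniform(*cohort.wmhv_range_mm3))
        thickness = phantom.gm_thickness_mm - (
            cohort.thinning_coefficient_mm_per_10k * target_wmhv / 10_000.0
        )
        if thickness < 0.5:
            raise ValueError("thinning drove GM thickness below 0.5 mm")
        spec_i = PhantomSpec(
            grid_shape=phantom.grid_shape,
            voxel_size_mm=phantom.voxel_size_mm,
            wm_radius_mm=phantom.wm_radius_mm,
            gm_thickness_mm=thickness,
            geometry=phantom.geometry,
        )
        base_labels = make_labelmap(spec_i)
        if cohort.warp_amplitude_mm > 0:
            v = reg.random_velocity(
                base_labels.shape,
                amplitude_vox=cohort.warp_amplitude_mm / voxel,
                fwhm_vox=cohort.warp_fwhm_mm / voxel,
                rng=rng,
            )
        else:
            v = reg.VelocityField(np.zeros((3,) + tuple(base_labels.shape)))
        phi = reg.exp_velocity(v)
        phi.affine = base_labels.affine
        warped_labels = reg.warp_volume(base_labels, phi, order=0)
        warped_labels = warped_labels.with_data(
            np.rint(warped_labels.data).astype(np.int16)
        )
        lesion_seed = int(rng.integers(0, 2**31 - 1))
        lab, wmh, li = implant_lesion_load(warped_labels, target_wmhv, lesions, lesion_seed)
        # the skull does not shrink with atrophy: the intracranial envelope
        # follows the *base* outer radius (warped), and CSF fills the space
        # freed by GM thinning
        base_head = make_labelmap(phantom)  # base-thickness anatomy
        head = head_mask(base_head)
        head = reg.warp_volume(head, phi, order=0)
        head = head.with_data(
            (np.asarray(head.data) >= 0.5) | (np.asarray(lab.data) != LABEL_CSF)
        )
        head = head.with_data(np.asarray(head.data).astype(np.uint8))
        render_seed = int(rng.integers(0, 2**31 - 1))
        t1, flair = render_intensities(
            lab, wmh, li, model, seed=render_seed,
            gliosis_fraction=lesions.li_gliosis_fraction, head=head,
        )
        wmhv = float(np.sum(wmh.data)) * lab.voxel_volume_mm3
        liv = float(np.sum(li.data)) * lab.voxel_volume_mm3
        rows.append(
            dict(subject_id=sid, age=age, sex=sex, wmhv_mm3=wmhv, liv_mm3=liv,
                 true_thickness_mm=thickness)
        )
        subjects.append(
            Subject(sid, t1, flair, lab, wmh, li, head, thickness, phi)
        )
    return pd.DataFrame(rows), subjects
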