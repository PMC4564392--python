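"""Tissue repair of lesion-corrupted segmentations.

WMH regions look like grey matter to a T1-driven segmentation and gliotic
lacune cores look like CSF, which corrupts the tissue maps exactly where the
anatomy is damaged and, downstream, the deformation fields and thickness
estimates.  Repair reassigns the probability mass: inside the WMH mask all
GM mass moves to WM; inside each lacunar-infarct (LI) mask the whole
GM+WM+CSF mass is assigned to the tissue class that is most likely at that
location across the cohort (a per-voxel majority vote in group space).  All
operations conserve total tissue probability mass and never touch voxels
outside the lesion masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tpm import TPMSet
from .volumes import Volume

__all__ = [
    "VolumeReport",
    "ReliabilityReport",
    "repair_wmh",
    "consensus_li_classes",
    "repair_li",
    "apply_brain_mask",
    "compute_volumes",
    "reliability_metrics",
    "CONSENSUS_LABELS",
]

#: precedence order for the consensus vote tie-break (lesions live in WM)
CONSENSUS_LABELS = {"wm": 1, "gm": 2, "csf": 3}


@dataclass
class VolumeReport:
    """Total intracranial and lesion volumes in mm^3."""

    tiv_mm3: float
    wmhv_mm3: float
    liv_mm3: float
    class_volumes_mm3: dict[str, float]

    def __post_init__(self):
        vals = [self.tiv_mm3, self.wmhv_mm3, self.liv_mm3, *self.class_volumes_mm3.values()]
        if any(v < 0 for v in vals):
            raise ValueError("volumes must be non-negative")


@dataclass
class ReliabilityReport:
    """Measurement reliability across raters / repeated measurements."""

    sem_mm3: float
    mean_variability_pct: float
    variability_sd_pct: float
    icc: float
    n_pairs: int
    n_excluded: int = 0

    def __post_init__(self):
        if not -1.0 <= self.icc <= 1.0 + 1e-12:
            raise ValueError("ICC must lie in [-1, 1]")
        if self.mean_variability_pct < 0:
            raise ValueError("variability must be non-negative")


def repair_wmh(gm: Volume, wm: Volume, wmh_mask: Volume) -> tuple[Volume, Volume]:
    """Move GM probability mass into WM inside the WMH mask.

    WMH is white matter pathology that the intensity model mistakes for GM;
    within the mask the full GM mass is transferred (wm' = wm + gm, gm' = 0)
    and the voxelwise gm + wm sum is preserved exactly.
    """
    gm.require_same_grid(wm, "GM and WM maps")
    gm.require_same_grid(wmh_mask, "GM map and WMH mask")
    m = np.asarray(wmh_mask.data, dtype=bool)
    g = np.asarray(gm.data, dtype=float).copy()
    w = np.asarray(wm.data, dtype=float).copy()
    w[m] += g[m]
    g[m] = 0.0
    return gm.with_data(g), wm.with_data(w)


def consensus_li_classes(
    li_masks_group: list[Volume], tpms_group: list[TPMSet]
) -> Volume:
    """Cohort-consensus tissue class at every lacune location (group space).

    At each voxel covered by at least one subject's LI mask, the label is
    the tissue class that wins the per-subject argmax most often across the
    whole cohort's (lesion-free) tissue posteriors.  Ties break by the
    precedence WM > GM > CSF.  Elsewhere the label is 0.
    """
    if not li_masks_group:
        raise ValueError("empty subject list")
    if len(li_masks_group) != len(tpms_group):
        raise ValueError("one TPM set per LI mask required")
    ref = li_masks_group[0]
    classes = [c for c in ("wm", "gm", "csf") if c in tpms_group[0].classes]
    union = np.zeros(ref.shape, dtype=bool)
    votes = np.zeros((len(classes),) + ref.shape, dtype=np.int32)
    for mask, tpms in zip(li_masks_group, tpms_group):
        ref.require_same_grid(mask, "LI masks")
        ref.require_same_grid(tpms.reference, "TPMs and LI masks")
        union |= np.asarray(mask.data, dtype=bool)
        stack = np.stack([np.asarray(tpms[c].data, dtype=float) for c in classes])
        # argmax with the precedence order as tie-break: first max index wins,
        # and `classes` is already ordered WM > GM > CSF
        winner = np.argmax(stack, axis=0)
        for i in range(len(classes)):
            votes[i][winner == i] += 1
    consensus = np.zeros(ref.shape, dtype=np.int16)
    winner = np.argmax(votes, axis=0)  # first (highest-precedence) max wins ties
    for i, c in enumerate(classes):
        consensus[union & (winner == i)] = CONSENSUS_LABELS[c]
    return ref.with_data(consensus)


def repair_li(
    gm: Volume,
    wm: Volume,
    csf: Volume,
    li_mask: Volume,
    consensus_native: Volume,
) -> TPMSet:
    """Assign the full tissue mass to the consensus class inside each lacune.

    Where the warped consensus carries no label (0) inside the mask, the
    subject's own argmax class is used instead and the voxel is counted in
    the returned set's ``fallback_voxels`` attribute.
    """
    for other, what in ((wm, "WM"), (csf, "CSF"), (li_mask, "LI mask"),
                        (consensus_native, "consensus")):
        gm.require_same_grid(other, f"GM map and {what}")
    m = np.asarray(li_mask.data, dtype=bool)
    cons = np.asarray(consensus_native.data).astype(int)
    g = np.asarray(gm.data, dtype=float).copy()
    w = np.asarray(wm.data, dtype=float).copy()
    c = np.asarray(csf.data, dtype=float).copy()
    total = g + w + c
    # fallback: subject argmax where the consensus is silent, in WM>GM>CSF order
    stack = np.stack([w, g, c])
    own = np.argmax(stack, axis=0)  # 0 wm, 1 gm, 2 csf
    own_label = np.choose(own, [CONSENSUS_LABELS["wm"], CONSENSUS_LABELS["gm"],
                                CONSENSUS_LABELS["csf"]])
    silent = m & (cons == 0)
    effective = np.where(silent, own_label, cons)
    for arr, label in ((w, CONSENSUS_LABELS["wm"]), (g, CONSENSUS_LABELS["gm"]),
                       (c, CONSENSUS_LABELS["csf"])):
        sel = m & (effective == label)
        arr[m] = np.where(sel[m], total[m], 0.0)
    out = TPMSet(
        {"gm": gm.with_data(g), "wm": wm.with_data(w), "csf": csf.with_data(c)},
        validate=False,
    )
    out.fallback_voxels = int(silent.sum())  # type: ignore[attr-defined]
    return out


def apply_brain_mask(tpms: TPMSet, brain: Volume) -> TPMSet:
    """Outside the brain mask, zero GM and WM and add their mass to CSF."""
    tpms.reference.require_same_grid(brain, "TPMs and brain mask")
    outside = ~np.asarray(brain.data, dtype=bool)
    g = np.asarray(tpms["gm"].data, dtype=float).copy()
    w = np.asarray(tpms["wm"].data, dtype=float).copy()
    c = np.asarray(tpms["csf"].data, dtype=float).copy()
    c[outside] += g[outside] + w[outside]
    g[outside] = 0.0
    w[outside] = 0.0
    maps = dict(tpms.items())
    maps["gm"] = tpms["gm"].with_data(g)
    maps["wm"] = tpms["wm"].with_data(w)
    maps["csf"] = tpms["csf"].with_data(c)
    return TPMSet(maps, validate=False)


def compute_volumes(
    tpms: TPMSet,
    wmh_mask: Volume,
    li_mask: Volume,
    tiv_threshold: float = 0.2,
) -> VolumeReport:
    """Lesion and tissue volumes in mm^3.

    WMHV and LIV are voxel counts of the binary masks times the voxel
    volume.  TIV counts voxels whose summed GM+WM+CSF probability is at or
    above the threshold (inclusive, >= 0.2 by default); per-class volumes
    are probability integrals.
    """
    tpms.reference.require_same_grid(wmh_mask, "TPMs and WMH mask")
    tpms.reference.require_same_grid(li_mask, "TPMs and LI mask")
    voxvol = tpms.reference.voxel_volume_mm3
    wmhv = float(np.sum(np.asarray(wmh_mask.data, dtype=bool))) * voxvol
    liv = float(np.sum(np.asarray(li_mask.data, dtype=bool))) * voxvol
    names = [c for c in ("gm", "wm", "csf") if c in tpms.classes]
    total = np.sum([np.asarray(tpms[c].data, dtype=float) for c in names], axis=0)
    tiv = float(np.sum(total >= tiv_threshold)) * voxvol
    class_volumes = {
        c: float(np.sum(np.asarray(tpms[c].data, dtype=float))) * voxvol
        for c in tpms.classes
    }
    return VolumeReport(tiv_mm3=tiv, wmhv_mm3=wmhv, liv_mm3=liv,
                        class_volumes_mm3=class_volumes)


def _icc_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Two-way single-measure agreement ICC, ICC(A,1) of McGraw & Wong.

    Computed from the two-way ANOVA mean squares of an n-subject x 2-rater
    table.  Degenerate cases: identical columns with between-subject spread
    give 1; no variance anywhere gives 1 by convention.
    """
    Y = np.stack([a, b], axis=1)
    n, k = Y.shape
    mean_all = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * np.sum((row_means - mean_all) ** 2)
    ssc = n * np.sum((col_means - mean_all) ** 2)
    sst = np.sum((Y - mean_all) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float((msr - mse) / denom)


def reliability_metrics(
    volumes_a, volumes_b, repeats_a=None
) -> ReliabilityReport:
    """Rater-agreement metrics on paired volume measurements.

    mean variability: mean over pairs of |a - b| / mean(a, b) * 100.
    SEM: sd of the paired differences / sqrt(2) (repeated-measure form);
    if ``repeats_a`` (repeated measurements by the same rater) is given it
    is used for the SEM instead of the a/b pairs.
    ICC: two-way agreement intraclass correlation, ICC(A,1).
    Pairs whose mean volume is zero are excluded (and counted).
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    means = (a + b) / 2.0
    ok = means > 0
    n_excluded = int((~ok).sum())
    a_ok, b_ok, means_ok = a[ok], b[ok], means[ok]
    if len(a_ok) < 2:
        raise ValueError("fewer than 2 usable pairs after excluding zero volumes")
    variability = np.abs(a_ok - b_ok) / means_ok * 100.0
    if repeats_a is not None:
        r = np.asarray(repeats_a, dtype=float)
        d = np.diff(r)
    else:
        d = a_ok - b_ok
    sem = float(np.std(d, ddof=1) / np.sqrt(2.0)) if len(d) > 1 else float(abs(d[0]) / np.sqrt(2.0))
    return ReliabilityReport(
        sem_mm3=sem,
        mean_variability_pct=float(variability.mean()),
        variability_sd_pct=float(variability.std(ddof=1)),
        icc=_icc_agreement(a_ok, b_ok),
        n_pairs=int(len(a_ok)),
        n_excluded=n_excluded,
    )
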