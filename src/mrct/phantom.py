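"""Synthetic co-registered T1-MR / CT sagittal head-slice phantoms.

Clinical paired MR/CT head data cannot be redistributed, so this module
generates parametric 2-D sagittal head phantoms with known tissue labels:
an elliptical head with scalp, a bony skull shell, a cortical gray-matter
band, white matter, a CSF ventricle and an air-filled frontal sinus.  Each
patient is a stack of sagittal slices whose in-plane geometry shrinks
smoothly with lateral offset from the midline, as cross-sections of an
ellipsoidal head do; the offset schedule is symmetric, so mirrored offsets
yield identical geometry (the left-right symmetry that motivates training
on sagittal planes).

CT intensities place each tissue safely inside its Hounsfield window (air
about -1000 HU, soft tissues within [-100, 100], bone about 1000 HU).  MR
intensities give the soft tissues distinct values while keeping air and
bone both near zero — the deliberate ambiguity of real T1 images that
forces a translation network to use spatial context rather than intensity
alone to separate air from bone.

The generator is deterministic given (spec, seed).  It produces crisp
tissue boundaries and independent additive Gaussian noise; it does not
model bias fields, motion, partial-volume blur (unless a smoothing width is
set) or real neuroanatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

# integer tissue labels
AIR, CSF, WHITE, GRAY, SCALP, BONE = range(6)
LABEL_NAMES = ("air", "csf", "white", "gray", "scalp", "bone")

_DEFAULT_CT_MEANS = {
    "air": -1000.0, "csf": 10.0, "white": 25.0, "gray": 40.0,
    "scalp": 60.0, "bone": 1000.0,
}
_DEFAULT_MR_MEANS = {
    "air": 0.0, "csf": 20.0, "white": 80.0, "gray": 60.0,
    "scalp": 70.0, "bone": 5.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic head cohort.

    Geometry fields in *_frac units are fractions of the image size and are
    randomized per patient within the given (low, high) ranges; thickness
    fields are pixels.  ``lateral_span`` is the fraction of the left-right
    semi-axis covered by the slice offset schedule.
    """

    size: int = 64
    slices_per_patient: int = 20
    lateral_span: float = 0.7
    head_si_frac: tuple[float, float] = (0.30, 0.34)   # superior-inferior semi-axis
    head_ap_frac: tuple[float, float] = (0.36, 0.40)   # anterior-posterior semi-axis
    head_lr_frac: tuple[float, float] = (0.32, 0.38)   # left-right semi-axis
    center_jitter_px: float = 1.5
    scalp_thickness_px: float = 2.0
    skull_thickness_px: tuple[float, float] = (2.4, 3.0)
    gray_thickness_px: float = 3.0
    ventricle_frac: tuple[float, float] = (0.055, 0.075)
    sinus_frac: float = 0.04
    ct_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CT_MEANS))
    mr_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MR_MEANS))
    ct_noise_sd: float = 15.0
    mr_noise_sd: float = 5.0
    boundary_smooth_px: float = 0.0

    def __post_init__(self) -> None:
        if self.ct_means["air"] >= -100:
            raise ValueError("air CT mean must lie below -100 HU (air window)")
        for t in ("csf", "white", "gray", "scalp"):
            if not -100 <= self.ct_means[t] <= 100:
                raise ValueError(f"{t} CT mean must lie within the soft-tissue window")
        if self.ct_means["bone"] <= 100:
            raise ValueError("bone CT mean must lie above 100 HU (bone window)")
        if abs(self.mr_means["air"]) > 15 or abs(self.mr_means["bone"]) > 15:
            raise ValueError("MR air and bone intensities must both be near zero")

    def noiseless(self) -> "PhantomSpec":
        """Copy of the spec with both noise standard deviations set to 0."""
        return replace(self, ct_noise_sd=0.0, mr_noise_sd=0.0)

    def ct_lookup(self) -> np.ndarray:
        return np.array([self.ct_means[n] for n in LABEL_NAMES], dtype=np.float32)

    def mr_lookup(self) -> np.ndarray:
        return np.array([self.mr_means[n] for n in LABEL_NAMES], dtype=np.float32)


@dataclass
class PhantomPatient:
    """One synthetic patient: aligned MR, CT, label and head-mask stacks.

    Arrays are (n_slices, H, W); MR/CT pairs are pixelwise aligned by
    construction.  ``offsets`` holds the lateral offset (pixels from the
    midline) of each sagittal slice.
    """

    patient_id: str
    seed: int
    mr: np.ndarray
    ct: np.ndarray
    labels: np.ndarray
    mask: np.ndarray
    offsets: np.ndarray

    @property
    def n_slices(self) -> int:
        return self.mr.shape[0]


def _ellipse(rr: np.ndarray, cc: np.ndarray, r0: float, c0: float,
             a_r: float, a_c: float) -> np.ndarray:
    if a_r <= 0 or a_c <= 0:
        return np.zeros_like(rr, dtype=bool)
    return ((rr - r0) / a_r) ** 2 + ((cc - c0) / a_c) ** 2 <= 1.0


def _slice_labels(spec: PhantomSpec, geom: dict, scale: float) -> np.ndarray:
    """Label map for one sagittal slice at in-plane scale ``scale``."""
    n = spec.size
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    r0, c0 = geom["center"]
    si, ap = geom["si"] * scale, geom["ap"] * scale
    if si + r0 + 1 > n or ap + c0 + 1 > n or r0 - si < 1 or c0 - ap < 1:
        raise ValueError(
            f"head geometry (semi-axes {si:.1f}x{ap:.1f} px at ({r0:.1f},{c0:.1f})) "
            f"does not fit a {n}x{n} image"
        )
    labels = np.full((n, n), AIR, dtype=np.int8)
    head = _ellipse(rr, cc, r0, c0, si, ap)
    skull_out = _ellipse(rr, cc, r0, c0, si - spec.scalp_thickness_px, ap - spec.scalp_thickness_px)
    brain = _ellipse(rr, cc, r0, c0, si - spec.scalp_thickness_px - geom["skull_t"],
                     ap - spec.scalp_thickness_px - geom["skull_t"])
    white = _ellipse(rr, cc, r0, c0,
                     si - spec.scalp_thickness_px - geom["skull_t"] - spec.gray_thickness_px,
                     ap - spec.scalp_thickness_px - geom["skull_t"] - spec.gray_thickness_px)
    labels[head] = SCALP
    labels[skull_out] = BONE
    labels[brain] = GRAY
    labels[white] = WHITE
    # CSF ventricle near the brain center, slightly posterior
    vent = _ellipse(rr, cc, r0, c0 - 0.12 * ap, geom["vent"] * scale, 1.4 * geom["vent"] * scale)
    labels[vent & white] = CSF
    # frontal sinus: air pocket in the anterior-inferior head
    brain_si = si - spec.scalp_thickness_px - geom["skull_t"]
    brain_ap = ap - spec.scalp_thickness_px - geom["skull_t"]
    sinus = _ellipse(rr, cc, r0 + 0.45 * brain_si, c0 + 0.55 * brain_ap,
                     spec.sinus_frac * n * scale, spec.sinus_frac * n * scale)
    labels[sinus & brain] = AIR
    return labels


def _render(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
    ct = spec.ct_lookup()[labels]
    mr = spec.mr_lookup()[labels]
    if spec.boundary_smooth_px > 0:
        ct = ndimage.gaussian_filter(ct, spec.boundary_smooth_px)
        mr = ndimage.gaussian_filter(mr, spec.boundary_smooth_px)
    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, ct.shape).astype(np.float32)
    if spec.mr_noise_sd > 0:
        mr = mr + rng.normal(0.0, spec.mr_noise_sd, mr.shape).astype(np.float32)
    return mr.astype(np.float32), ct.astype(np.float32)


def generate_patient(spec: PhantomSpec, seed: int, patient_id: str = "P000") -> PhantomPatient:
    """Generate one synthetic patient, deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    n = spec.size
    geom = {
        "si": rng.uniform(*spec.head_si_frac) * n,
        "ap": rng.uniform(*spec.head_ap_frac) * n,
        "lr": rng.uniform(*spec.head_lr_frac) * n,
        "skull_t": rng.uniform(*spec.skull_thickness_px),
        "vent": rng.uniform(*spec.ventricle_frac) * n,
        "center": (
            n / 2 + rng.uniform(-spec.center_jitter_px, spec.center_jitter_px),
            n / 2 + rng.uniform(-spec.center_jitter_px, spec.center_jitter_px),
        ),
    }
    offsets = np.linspace(-spec.lateral_span, spec.lateral_span,
                          spec.slices_per_patient) * geom["lr"]
    mrs, cts, labs = [], [], []
    for u in offsets:
        scale = float(np.sqrt(max(1.0 - (u / geom["lr"]) ** 2, 0.0)))
        labels = _slice_labels(spec, geom, scale)
        mr, ct = _render(spec, labels, rng)
        mrs.append(mr)
        cts.append(ct)
        labs.append(labels)
    labs = np.stack(labs)
    masks = np.stack([_head_mask_from_labels(l) for l in labs])
    return PhantomPatient(
        patient_id=patient_id,
        seed=int(seed),
        mr=np.stack(mrs),
        ct=np.stack(cts),
        labels=labs,
        mask=masks,
        offsets=offsets,
    )


def _head_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    """Analytic head mask: every non-air pixel plus enclosed air (sinus)."""
    head = labels != AIR
    return ndimage.binary_fill_holes(head)


def generate_cohort(spec: PhantomSpec, n_patients: int, master_seed: int
                    ) -> list[PhantomPatient]:
    """Generate ``n_patients`` phantoms with per-patient seeds derived
    deterministically from ``master_seed``."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_patients) % (2**31)
    return [
        generate_patient(spec, int(s), patient_id=f"P{i:03d}")
        for i, s in enumerate(seeds)
    ]


def oracle_translation(mr: np.ndarray, labels: np.ndarray,
                       spec: PhantomSpec = PhantomSpec()) -> np.ndarray:
    """Noiseless ground-truth mapping from tissue label to mean HU.

    This is the target an ideal translation network recovers on phantoms;
    the MR argument is checked for alignment only.
    """
    mr = np.asarray(mr)
    labels = np.asarray(labels)
    if mr.shape != labels.shape:
        raise ValueError(f"MR and label shapes differ: {mr.shape} vs {labels.shape}")
    if labels.min() < 0 or labels.max() >= len(LABEL_NAMES):
        bad = sorted(set(np.unique(labels)) - set(range(len(LABEL_NAMES))))
        raise ValueError(f"unknown tissue label(s): {bad}")
    return spec.ct_lookup()[labels].astype(np.float64)


def mr_air_bone_overlap(patient: PhantomPatient, bins: int = 60) -> float:
    """Histogram overlap of the MR intensity distributions in air vs bone.

    Values near 1 mean MR intensity alone cannot separate the two classes;
    phantoms are constructed so this exceeds 0.5.
    """
    air_vals = patient.mr[patient.labels == AIR]
    bone_vals = patient.mr[patient.labels == BONE]
    lo = min(air_vals.min(), bone_vals.min())
    hi = max(air_vals.max(), bone_vals.max())
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(air_vals, bins=edges, density=False)
    q, _ = np.histogram(bone_vals, bins=edges, density=False)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.minimum(p, q).sum())
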