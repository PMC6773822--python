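"""NIfTI and manifest plumbing.

Images travel as NIfTI (.nii / .nii.gz).  Volumes are stored (LR, SI, AP):
sagittal slices are taken along the first axis, 0-based.  Channel stacks
are written as 3-volume NIfTI files with channel order (air, tissue, bone)
recorded in the header description field.  Phantom cohorts are written as
per-patient NIfTI files plus a JSON manifest carrying patient ids, seeds,
the generating spec and a hash of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .hu_windows import ChannelStack
from .phantom import PhantomPatient, PhantomSpec

log = logging.getLogger("mrct")

_IDENTITY = np.eye(4)


def write_nifti(path: str | Path, data: np.ndarray, descrip: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _IDENTITY)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float32)


def read_pair(mr_path: str | Path, ct_path: str | Path,
              affine_tol: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Load an aligned (MR, CT) pair, checking grid shapes.

    Shape mismatch is an error; an affine mismatch beyond tolerance only
    logs a warning and the voxel grids are used as-is (registration is
    assumed to have happened upstream).
    """
    mr_img, ct_img = nib.load(str(mr_path)), nib.load(str(ct_path))
    if mr_img.shape != ct_img.shape:
        raise ValueError(
            f"MR/CT grid shapes differ: {mr_img.shape} ({mr_path}) vs "
            f"{ct_img.shape} ({ct_path})"
        )
    if not np.allclose(mr_img.affine, ct_img.affine, atol=affine_tol):
        log.warning("MR/CT affines differ beyond %g; proceeding on voxel grids", affine_tol)
    return (np.asarray(mr_img.get_fdata(), dtype=np.float32),
            np.asarray(ct_img.get_fdata(), dtype=np.float32))


def sagittal_slices(volume: np.ndarray) -> np.ndarray:
    """Sagittal slices of a 3-D volume: indexed along the first (LR) axis."""
    if volume.ndim == 2:
        return volume[None]
    if volume.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D volume, got ndim={volume.ndim}")
    return volume


def write_channel_stack(path: str | Path, stack: ChannelStack) -> None:
    write_nifti(path, stack.stacked().transpose(1, 2, 0),
                descrip="channels: air,tissue,bone")


def read_channel_stack(path: str | Path, normalized: bool = False) -> ChannelStack:
    data = read_nifti(path)
    return ChannelStack.from_array(data.transpose(2, 0, 1), normalized=normalized)


# -- cohorts ---------------------------------------------------------------


def spec_hash(spec: PhantomSpec) -> str:
    payload = json.dumps(dataclasses.asdict(spec), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_cohort(patients: list[PhantomPatient], spec: PhantomSpec,
                 out_dir: str | Path) -> Path:
    """Write per-patient NIfTI files and a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in patients:
        files = {}
        for kind, data in (("mr", p.mr), ("ct", p.ct),
                           ("labels", p.labels.astype(np.float32)),
                           ("mask", p.mask.astype(np.float32))):
            fname = f"{p.patient_id}_{kind}.nii.gz"
            write_nifti(out_dir / fname, data)
            files[kind] = fname
        entries.append({"patient_id": p.patient_id, "seed": p.seed,
                        "offsets": [float(o) for o in p.offsets], "files": files})
    manifest = {
        "spec": dataclasses.asdict(spec),
        "spec_hash": spec_hash(spec),
        "patients": entries,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_cohort(manifest_path: str | Path) -> tuple[list[PhantomPatient], PhantomSpec]:
    """Reload a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    spec_dict = manifest["spec"]
    for key, val in spec_dict.items():
        if isinstance(val, list):
            spec_dict[key] = tuple(val)
    spec = PhantomSpec(**spec_dict)
    root = manifest_path.parent
    patients = []
    for e in manifest["patients"]:
        patients.append(PhantomPatient(
            patient_id=e["patient_id"],
            seed=e["seed"],
            mr=read_nifti(root / e["files"]["mr"]),
            ct=read_nifti(root / e["files"]["ct"]),
            labels=read_nifti(root / e["files"]["labels"]).astype(np.int8),
            mask=read_nifti(root / e["files"]["mask"]) > 0.5,
            offsets=np.array(e["offsets"]),
        ))
    return patients, spec


def write_preview_png(path: str | Path, patient: PhantomPatient,
                      slice_index: int | None = None) -> None:
    """Side-by-side MR / CT preview of one slice for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i = patient.n_slices // 2 if slice_index is None else slice_index
    fig, axes = plt.subplots(1, 2, figsize=(6, 3))
    axes[0].imshow(patient.mr[i], cmap="gray")
    axes[0].set_title("MR")
    axes[1].imshow(patient.ct[i], cmap="gray", vmin=-1000, vmax=1500)
    axes[1].set_title("CT (HU)")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=90)
    plt.close(fig)
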