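"""File I/O: NIfTI-1 volumes, plain-text 4×4 transforms, JSON shim records,
cohort directories and template bundles."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .grids import VoxelGrid, Volume
from .harmonics import CoilCalibration, HarmonicBasis, ShimSetting
from .processing import FieldMap, PhaseVolume
from .spatial import AffineTransform, TemplateResult

__all__ = [
    "read_volume", "write_volume", "read_transform", "write_transform",
    "read_shim", "write_shim", "write_basis", "write_cohort", "read_cohort",
    "write_template", "read_template",
]


def read_volume(path) -> Volume:
    """Load a NIfTI-1 volume; the NIfTI affine defines index→world (mm)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"{path}: malformed affine header field")
    return Volume(np.asarray(data, float), VoxelGrid(data.shape, affine))


def write_volume(vol: Volume, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype), vol.grid.index_to_world)
    img.to_filename(str(path))


def read_transform(path, source="subject", target="standard",
                   dof: int = 12) -> AffineTransform:
    """Plain-text 4×4 affine (row-major, whitespace-separated), world mm."""
    try:
        m = np.loadtxt(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: unreadable transform text ({exc})") from exc
    if m.shape != (4, 4):
        raise FormatError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    return AffineTransform(m, source=source, target=target, dof=dof)


def write_transform(tx: AffineTransform, path) -> None:
    header = f"{tx.source} -> {tx.target} (dof={tx.dof}), world mm"
    np.savetxt(str(path), tx.matrix, fmt="%.12g", header=header)


def read_shim(path) -> ShimSetting:
    with open(path) as fh:
        d = json.load(fh)
    if not isinstance(d, dict) or "terms" not in d:
        raise FormatError(f"{path}: shim JSON must contain a 'terms' mapping")
    return ShimSetting.from_dict(d["terms"], d.get("max_order"))


def write_shim(shim: ShimSetting, path) -> None:
    with open(path, "w") as fh:
        json.dump({"max_order": shim.max_order, "terms": shim.to_dict()},
                  fh, indent=2)


def write_basis(basis: HarmonicBasis, path, sidecar: bool = True) -> None:
    """Export basis volumes as one 4D NIfTI (term order in a sidecar JSON)."""
    path = Path(path)
    data = np.moveaxis(basis.basis_volumes, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, basis.grid.index_to_world)
    img.header["descrip"] = b"solid harmonic basis; term order in sidecar"
    img.to_filename(str(path))
    if sidecar:
        side = path.with_name(path.name.split(".")[0] + "_terms.json")
        with open(side, "w") as fh:
            json.dump({"max_order": basis.max_order,
                       "terms": list(basis.term_names)}, fh, indent=2)


# --- cohort directories -----------------------------------------------------

def write_cohort(subjects, config, out_dir) -> Path:
    """Write per-subject NIfTI volumes, transforms, shims and a manifest."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for s in subjects:
        sid = s.id
        ids.append(sid)
        write_volume(Volume(s.field_true.values, s.grid), out / f"{sid}_field.nii.gz")
        write_volume(s.structural, out / f"{sid}_structural.nii.gz")
        write_volume(Volume(s.brain_mask.astype(np.uint8), s.grid),
                     out / f"{sid}_brainmask.nii.gz", dtype=np.uint8)
        write_transform(s.transform, out / f"{sid}_to_standard.txt")
        write_shim(s.baseline_shim, out / f"{sid}_baseline_shim.json")
        if s.phase1 is not None:
            write_volume(Volume(s.phase1.values, s.grid), out / f"{sid}_phase1.nii.gz")
            write_volume(Volume(s.phase2.values, s.grid), out / f"{sid}_phase2.nii.gz")
    manifest = {"config": asdict(config), "subjects": ids}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def read_cohort(cohort_dir):
    """Load a cohort directory written by :func:`write_cohort`.

    Returns ``(subjects, config_dict)``.
    """
    from .synthetic import Subject

    cohort_dir = Path(cohort_dir)
    try:
        with open(cohort_dir / "manifest.json") as fh:
            manifest = json.load(fh)
    except FileNotFoundError as exc:
        raise FormatError(f"{cohort_dir}: missing manifest.json") from exc
    subjects = []
    for sid in manifest["subjects"]:
        fld = read_volume(cohort_dir / f"{sid}_field.nii.gz")
        mask = read_volume(cohort_dir / f"{sid}_brainmask.nii.gz").values > 0.5
        structural = read_volume(cohort_dir / f"{sid}_structural.nii.gz")
        tx = read_transform(cohort_dir / f"{sid}_to_standard.txt",
                            source=f"subject/{sid}", target="standard")
        shim = read_shim(cohort_dir / f"{sid}_baseline_shim.json")
        field_true = FieldMap(fld.values, fld.grid, mask, provenance="synthetic",
                              shim_state="baseline-removed")
        phase1 = phase2 = None
        p1 = cohort_dir / f"{sid}_phase1.nii.gz"
        if p1.exists():
            v1 = read_volume(p1)
            v2 = read_volume(cohort_dir / f"{sid}_phase2.nii.gz")
            phase1 = PhaseVolume(v1.values, v1.grid, wrapped=True)
            phase2 = PhaseVolume(v2.values, v2.grid, wrapped=True)
        subjects.append(Subject(id=sid, field_true=field_true,
                                structural=structural, brain_mask=mask,
                                transform=tx, baseline_shim=shim,
                                phase1=phase1, phase2=phase2))
    return subjects, manifest["config"]


# --- template bundles -------------------------------------------------------

def write_template(template: TemplateResult, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(Volume(template.mean.values, template.mean.grid),
                 out / "mean.nii.gz")
    write_volume(Volume(template.mean.brain_mask.astype(np.uint8),
                        template.mean.grid), out / "mask.nii.gz", dtype=np.uint8)
    write_volume(template.std, out / "std.nii.gz")
    write_volume(Volume(template.count.astype(np.int16), template.mean.grid),
                 out / "count.nii.gz", dtype=np.int16)
    if template.anatomy is not None:
        write_volume(template.anatomy, out / "anatomy.nii.gz")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"n_subjects": template.n_subjects}, fh, indent=2)
    return out


def read_template(template_dir) -> TemplateResult:
    d = Path(template_dir)
    mean = read_volume(d / "mean.nii.gz")
    mask = read_volume(d / "mask.nii.gz").values > 0.5
    std = read_volume(d / "std.nii.gz")
    count = read_volume(d / "count.nii.gz").values.astype(int)
    anatomy = None
    if (d / "anatomy.nii.gz").exists():
        anatomy = read_volume(d / "anatomy.nii.gz")
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    mean_fm = FieldMap(mean.values, mean.grid, mask, provenance="synthetic",
                       shim_state="baseline-removed")
    return TemplateResult(mean=mean_fm, std=std, count=count,
                          n_subjects=int(manifest["n_subjects"]),
                          anatomy=anatomy)
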