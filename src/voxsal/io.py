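"""File formats: NIfTI volumes/atlases, TSV labels, CSV tables, checkpoints.

Atlases are written as one 4D NIfTI (area axis last) plus a TSV label table
with columns index/name/hemisphere/lobe/networks (semicolon-separated).
Cohorts are one NIfTI per subject plus a subjects CSV.  Model checkpoints
are a single ``.npz`` holding the architecture spec as a JSON header next
to the weight arrays and batch-norm running statistics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .model import ArchitectureSpec, ResidualClassifier3D, build_model
from .types import AreaLabel, ProbabilisticAtlas, SaliencyMap, SubjectRecord, VolumeGrid


# -- volumes ---------------------------------------------------------------

def save_volume(vol: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(data=np.asarray(img.dataobj, dtype=np.float32), affine=img.affine)


# -- atlas -----------------------------------------------------------------

def save_atlas(atlas: ProbabilisticAtlas, nii_path, labels_path) -> None:
    stack = np.moveaxis(atlas.probs, 0, -1).astype(np.float32)  # area axis last
    nib.save(nib.Nifti1Image(stack, atlas.affine), str(nii_path))
    rows = [
        {
            "index": lab.index,
            "name": lab.name,
            "hemisphere": lab.hemisphere,
            "lobe": lab.lobe,
            "networks": ";".join(sorted(lab.networks)),
        }
        for lab in atlas.labels
    ]
    pd.DataFrame(rows).to_csv(labels_path, sep="\t", index=False)


def load_atlas(nii_path, labels_path) -> ProbabilisticAtlas:
    img = nib.load(str(nii_path))
    probs = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    table = pd.read_csv(labels_path, sep="\t")
    labels = [
        AreaLabel(
            index=int(r["index"]),
            name=str(r["name"]),
            hemisphere=str(r["hemisphere"]),
            lobe=str(r["lobe"]),
            networks=frozenset(str(r["networks"]).split(";")) if r["networks"] else frozenset(),
        )
        for _, r in table.sort_values("index").iterrows()
    ]
    return ProbabilisticAtlas(probs=probs, labels=labels, affine=img.affine)


# -- cohort ----------------------------------------------------------------

def save_cohort(subjects: Sequence[SubjectRecord], volumes: Sequence[VolumeGrid], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s, v in zip(subjects, volumes):
        save_volume(v, out / f"{s.id}.nii.gz")
        rows.append(
            {
                "id": s.id,
                "true_class": s.true_class,
                "updrs_p3": s.updrs_p3,
                "moca": s.moca,
                "ledd": s.ledd,
                "years_onset": s.years_onset,
                "handedness": s.handedness,
                "medicated": s.medicated,
                "latent_severity": s.latent_severity,
                "fold": -1 if s.fold is None else s.fold,
                "predicted_class": s.predicted_class or "",
            }
        )
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)


def load_cohort(in_dir) -> tuple[list[SubjectRecord], list[VolumeGrid]]:
    src = Path(in_dir)
    table = pd.read_csv(src / "subjects.csv")
    subjects, volumes = [], []
    for _, r in table.iterrows():
        rec = SubjectRecord(
            id=str(r["id"]),
            true_class=str(r["true_class"]),
            updrs_p3=float(r["updrs_p3"]),
            moca=float(r["moca"]),
            ledd=float(r["ledd"]),
            years_onset=float(r["years_onset"]),
            handedness=str(r["handedness"]),
            medicated=bool(r["medicated"]),
            latent_severity=float(r["latent_severity"]),
            fold=None if int(r["fold"]) < 0 else int(r["fold"]),
            predicted_class=str(r["predicted_class"]) if isinstance(r["predicted_class"], str) and r["predicted_class"] else None,
        )
        subjects.append(rec)
        volumes.append(load_volume(src / f"{rec.id}.nii.gz"))
    return subjects, volumes


# -- saliency --------------------------------------------------------------

def save_saliency(smap: SaliencyMap, out_dir, affine=None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{smap.subject_id}_{smap.fold}_{smap.class_channel}.nii.gz"
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(smap.values.astype(np.float32), aff), str(path))
    return path


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: ResidualClassifier3D, path) -> None:
    arrays = model.state_arrays()
    arrays["spec_json"] = np.frombuffer(
        json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8
    )
    np.savez_compressed(str(path), **arrays)


def load_checkpoint(path) -> ResidualClassifier3D:
    with np.load(str(path)) as data:
        spec = ArchitectureSpec.from_dict(
            json.loads(bytes(data["spec_json"].tobytes()).decode())
        )
        model = build_model(spec, seed=0)
        model.load_state_arrays({k: data[k] for k in data.files if k != "spec_json"})
    return model
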