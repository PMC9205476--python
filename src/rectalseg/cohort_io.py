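"""Write/read cohorts as NIfTI volumes plus a CSV manifest."""

from __future__ import annotations

import os
from typing import Sequence, Union

import pandas as pd

from .core import Case, StageCategory, StageLabel, ValidationError
from .io_volumes import read_labels, read_volume, write_labels, write_volume

__all__ = ["write_cohort", "load_cohort", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.csv"


def write_cohort(cases: Sequence[Case], out_dir: Union[str, os.PathLike]) -> str:
    """Write one image (and, if labeled, one 4-channel label file) per case.

    Returns the manifest path.  Manifest columns: case_id, stage,
    has_labels, center_x_mm, center_y_mm, center_z_mm, mucinous.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for case in cases:
        img_path = os.path.join(out_dir, f"{case.case_id}_image.nii.gz")
        write_volume(case.volume, img_path)
        if case.labels is not None:
            write_labels(case.labels, case.volume, os.path.join(out_dir, f"{case.case_id}_labels.nii.gz"))
        rows.append(
            {
                "case_id": case.case_id,
                "stage": case.stage.category.value,
                "has_labels": case.labels is not None,
                "center_x_mm": case.center_mm[0],
                "center_y_mm": case.center_mm[1],
                "center_z_mm": case.center_mm[2],
                "mucinous": case.mucinous,
            }
        )
    manifest = os.path.join(out_dir, MANIFEST_NAME)
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _stage_from_str(s: str) -> StageLabel:
    for cat in StageCategory:
        if cat.value == s:
            return StageLabel(cat)
    raise ValidationError(f"unknown stage string: {s!r}")


def load_cohort(manifest_path: Union[str, os.PathLike]) -> list[Case]:
    """Load the cases listed in a manifest (paths relative to its folder)."""
    manifest_path = os.fspath(manifest_path)
    base = os.path.dirname(manifest_path)
    df = pd.read_csv(manifest_path)
    cases = []
    for row in df.itertuples(index=False):
        volume = read_volume(os.path.join(base, f"{row.case_id}_image.nii.gz"))
        labels = None
        if bool(row.has_labels):
            labels, _ = read_labels(os.path.join(base, f"{row.case_id}_labels.nii.gz"))
        cases.append(
            Case(
                volume=volume,
                center_mm=(row.center_x_mm, row.center_y_mm, row.center_z_mm),
                stage=_stage_from_str(row.stage),
                labels=labels,
                case_id=str(row.case_id),
                mucinous=bool(getattr(row, "mucinous", False)),
            )
        )
    return cases
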