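"""Reading and writing the dataset on disk.

Layout follows BIDS conventions loosely: one NIfTI-1 run and one
``*_events.tsv`` per subject (columns onset, duration, trial_type,
intensity; seconds, time origin at the first volume), plus a
``participants.tsv`` and a JSON manifest.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import BOLDRun
from .paradigm import Event, ParadigmDesign


def events_frame(design: ParadigmDesign) -> pd.DataFrame:
    """Event table of a design as a BIDS-events-like DataFrame."""
    rows = [
        {
            "onset": e.onset,
            "duration": e.duration,
            "trial_type": e.condition,
            "intensity": e.intensity if e.intensity is not None else "n/a",
        }
        for e in design.events
    ]
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "intensity"])


def design_from_events(df: pd.DataFrame, tr: float, n_volumes: int) -> ParadigmDesign:
    events = []
    for row in df.itertuples(index=False):
        intensity = row.intensity
        if intensity in ("n/a", "", None) or (
            isinstance(intensity, float) and np.isnan(intensity)
        ):
            intensity = None
        else:
            intensity = int(intensity)
        events.append(Event(float(row.onset), float(row.duration), row.trial_type, intensity))
    return ParadigmDesign(tr=tr, n_volumes=n_volumes, events=tuple(events))


def save_run(run: BOLDRun, path: str) -> None:
    img = nib.Nifti1Image(run.data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, path)


def load_run(path: str, mask: Optional[np.ndarray] = None) -> BOLDRun:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such run: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    tr = float(img.header.get_zooms()[3])
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BOLDRun(data=data, mask=mask, tr=tr)


def write_dataset(
    runs: Sequence[BOLDRun],
    designs: Sequence[ParadigmDesign],
    subjects: pd.DataFrame,
    directory: str,
    compress: bool = False,
    run_ids: Optional[Sequence[str]] = None,
) -> Dict:
    """Write runs, event tables and the participants table under ``directory``.

    One NIfTI file and one events.tsv per run.  Runs are matched by position
    to the rows of ``subjects`` unless ``run_ids`` names the subject of each
    run (the participants table may then list additional subjects without
    runs, e.g. QC exclusions).  Round-tripping a run through
    :func:`load_run` reproduces the array bit-exactly.
    """
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"no such directory: {directory}")
    if run_ids is None:
        if len(runs) != len(subjects):
            raise ValueError("runs and subjects must have equal length")
        run_ids = list(subjects["subject_id"])
    if len(runs) != len(designs) or len(runs) != len(run_ids):
        raise ValueError("runs, designs and run_ids must have equal length")
    known = set(subjects["subject_id"])
    missing = [s for s in run_ids if s not in known]
    if missing:
        raise ValueError(f"run subjects absent from participants table: {missing}")
    ext = ".nii.gz" if compress else ".nii"
    manifest: Dict = {"participants": "participants.tsv", "runs": []}
    for run, design, sid in zip(runs, designs, run_ids):
        bold_name = f"{sid}_task-odor_bold{ext}"
        events_name = f"{sid}_task-odor_events.tsv"
        try:
            save_run(run, os.path.join(directory, bold_name))
            events_frame(design).to_csv(
                os.path.join(directory, events_name), sep="\t", index=False
            )
        except OSError as err:
            raise OSError(f"failed writing {sid} under {directory}: {err}") from err
        manifest["runs"].append(
            {"subject_id": sid, "bold": bold_name, "events": events_name,
             "tr": design.tr, "n_volumes": design.n_volumes}
        )
    subjects.to_csv(os.path.join(directory, "participants.tsv"), sep="\t", index=False)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_dataset(directory: str):
    """Read back a dataset written by :func:`write_dataset`."""
    manifest_path = os.path.join(directory, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no manifest under {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    subjects = pd.read_csv(os.path.join(directory, manifest["participants"]), sep="\t")
    runs: List[BOLDRun] = []
    designs: List[ParadigmDesign] = []
    for entry in manifest["runs"]:
        runs.append(load_run(os.path.join(directory, entry["bold"])))
        ev = pd.read_csv(
            os.path.join(directory, entry["events"]), sep="\t",
            keep_default_na=False, na_values=[],
        )
        designs.append(design_from_events(ev, entry["tr"], entry["n_volumes"]))
    return runs, designs, subjects
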