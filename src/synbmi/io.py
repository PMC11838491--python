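"""Session container I/O.

Sessions are stored as HDF5 files holding the named arrays, per-trial
columns, scalar attributes (bin width, day id, schema version) and a JSON
metadata block (seeds, processing provenance).  Round trips are lossless:
write-then-read returns bit-identical arrays.
"""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np

from .session import BinnedSession, TrialTable

SCHEMA_VERSION = 1

_REQUIRED_ARRAYS = ("neural", "emg", "kinematics")
_TRIAL_COLUMNS = ("start_bin", "end_bin", "target",
                  "artifact_start", "artifact_end")


class ContainerError(RuntimeError):
    pass


def save_session(session: BinnedSession, path) -> None:
    path = pathlib.Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["bin_width"] = session.bin_width
        f.attrs["day_id"] = session.day_id
        f.attrs["metadata"] = json.dumps(session.metadata, default=str,
                                         sort_keys=True)
        for name in _REQUIRED_ARRAYS:
            f.create_dataset(name, data=getattr(session, name))
        if session.artifact_mask is not None:
            f.create_dataset("artifact_mask", data=session.artifact_mask)
        g = f.create_group("trials")
        for col in _TRIAL_COLUMNS:
            g.create_dataset(col, data=getattr(session.trials, col))
        ctx = np.array([c.encode() for c in session.trials.context])
        g.create_dataset("context", data=ctx)


def load_session(path) -> BinnedSession:
    path = pathlib.Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ContainerError(
                f"container schema version {version} is not supported "
                f"(expected {SCHEMA_VERSION}); regenerate the session with "
                f"this version of the package")
        for name in _REQUIRED_ARRAYS:
            if name not in f:
                raise ContainerError(f"container is missing the required "
                                     f"array {name!r}")
        if "trials" not in f:
            raise ContainerError("container is missing the 'trials' group")
        g = f["trials"]
        for col in _TRIAL_COLUMNS:
            if col not in g:
                raise ContainerError(f"trial table is missing column {col!r}")
        trials = TrialTable(
            start_bin=g["start_bin"][()], end_bin=g["end_bin"][()],
            target=g["target"][()],
            context=np.array([c.decode() for c in g["context"][()]],
                             dtype=object),
            artifact_start=g["artifact_start"][()],
            artifact_end=g["artifact_end"][()],
        )
        mask = f["artifact_mask"][()].astype(bool) if "artifact_mask" in f \
            else None
        return BinnedSession(
            neural=f["neural"][()], emg=f["emg"][()],
            kinematics=f["kinematics"][()], trials=trials,
            bin_width=float(f.attrs["bin_width"]),
            day_id=str(f.attrs["day_id"]), artifact_mask=mask,
            metadata=json.loads(f.attrs["metadata"]),
        )
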