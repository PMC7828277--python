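"""HDF5 persistence for leadfields and signature datasets."""

from __future__ import annotations

import h5py
import numpy as np

from .dataset_builder import SignatureDataset
from .volume_conductor import Leadfield

__all__ = ["save_leadfield", "load_leadfield", "save_dataset", "load_dataset"]


def save_leadfield(path, leadfield: Leadfield) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gains", data=leadfield.gains)
        f.create_dataset("source_positions", data=leadfield.source_positions_mm)
        f.attrs["rotation_deg"] = leadfield.rotation_deg
        f.attrs["encapsulation_fill"] = leadfield.encapsulation_fill


def load_leadfield(path) -> Leadfield:
    with h5py.File(path, "r") as f:
        return Leadfield(
            gains=f["gains"][:],
            source_positions_mm=f["source_positions"][:],
            rotation_deg=float(f.attrs["rotation_deg"]),
            encapsulation_fill=float(f.attrs["encapsulation_fill"]),
        )


def save_dataset(path, ds: SignatureDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signatures", data=ds.matrices, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=ds.labels)
        if ds.folds is not None:
            f.create_dataset("folds", data=ds.folds)
        for attr in ("snr_db", "timepoint_id", "normalization_constant", "seed"):
            val = getattr(ds, attr)
            if val is not None:
                f.attrs[attr] = val


def load_dataset(path) -> SignatureDataset:
    with h5py.File(path, "r") as f:
        return SignatureDataset(
            matrices=f["signatures"][:],
            labels=f["labels"][:],
            folds=f["folds"][:] if "folds" in f else None,
            snr_db=float(f.attrs["snr_db"]) if "snr_db" in f.attrs else None,
            timepoint_id=str(f.attrs["timepoint_id"]) if "timepoint_id" in f.attrs else None,
            normalization_constant=(
                float(f.attrs["normalization_constant"])
                if "normalization_constant" in f.attrs
                else None
            ),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
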