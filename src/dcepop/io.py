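"""Event-record CSV readers/writers, config loading and run manifests.

The on-disk dataset format is a NONMEM-style event-record table with columns
ID, OCC, TIME, TISSUE, DV, AMT, EVID, ANEST, VTI: one dose row per dataset
(EVID=1, AMT carries the dose in umol, DV empty) followed by observation
rows (EVID=0, DV carries the concentration in mM).  All outputs of a run
reference a :class:`RunManifest` recording the seed, config hashes and
package version.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DataError, SchemaError
from .estimation import SamplerConfig
from .population import StudyDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "load_sampler_config",
    "RunManifest",
]

_EVENT_COLUMNS = ["ID", "OCC", "TIME", "TISSUE", "DV", "AMT", "EVID", "ANEST", "VTI"]


def to_event_records(study: StudyDataset) -> pd.DataFrame:
    """Flatten a :class:`StudyDataset` into the event-record table."""
    rows = []
    for _, s in study.subjects.iterrows():
        rows.append({"ID": s["ID"], "OCC": s["OCC"], "TIME": 0.0, "TISSUE": ".",
                     "DV": "", "AMT": s["DOSE"], "EVID": 1,
                     "ANEST": int(s["ANEST"]), "VTI": int(s["VTI"])})
        obs = study.observations_for(s["ID"])
        for _, o in obs.iterrows():
            rows.append({"ID": o["ID"], "OCC": o["OCC"], "TIME": o["TIME"],
                         "TISSUE": o["TISSUE"], "DV": repr(float(o["DV"])),
                         "AMT": "", "EVID": 0,
                         "ANEST": int(s["ANEST"]), "VTI": int(s["VTI"])})
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def from_event_records(table: pd.DataFrame) -> StudyDataset:
    """Validate an event-record table and build a :class:`StudyDataset`."""
    missing = [c for c in _EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event-record table missing columns: {missing}")
    evid = pd.to_numeric(table["EVID"], errors="coerce")
    if evid.isna().any() or not set(np.unique(evid)) <= {0, 1}:
        raise SchemaError("EVID must be 0 (observation) or 1 (dose)")
    doses = table[evid == 1]
    obs = table[evid == 0]
    if doses.empty:
        raise SchemaError("no dose rows (EVID=1) found")
    amt = pd.to_numeric(doses["AMT"], errors="coerce")
    if amt.isna().any() or (amt <= 0).any():
        raise SchemaError("dose rows must carry a positive AMT")
    dup = doses["ID"].duplicated()
    if dup.any():
        raise SchemaError(f"multiple dose rows for dataset(s) {sorted(set(doses['ID'][dup]))}")
    subjects = pd.DataFrame({
        "ID": doses["ID"].to_numpy(),
        "OCC": doses["OCC"].to_numpy(),
        "DOSE": amt.to_numpy(dtype=float),
        "ANEST": pd.to_numeric(doses["ANEST"]).astype(int).to_numpy(),
        "VTI": pd.to_numeric(doses["VTI"]).astype(int).to_numpy(),
    })
    observations = pd.DataFrame({
        "ID": obs["ID"].to_numpy(),
        "OCC": obs["OCC"].to_numpy(),
        "TIME": pd.to_numeric(obs["TIME"]).to_numpy(dtype=float),
        "TISSUE": obs["TISSUE"].to_numpy(),
        "DV": pd.to_numeric(obs["DV"]).to_numpy(dtype=float),
    })
    return StudyDataset(observations=observations.reset_index(drop=True),
                        subjects=subjects.reset_index(drop=True))


def write_dataset(study: StudyDataset, path) -> None:
    to_event_records(study).to_csv(path, index=False)


def read_dataset(path) -> StudyDataset:
    try:
        table = pd.read_csv(path, dtype={"TISSUE": str, "OCC": str})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"cannot parse event-record CSV {path}: {exc}") from exc
    return from_event_records(table)


def write_truth(study: StudyDataset, path) -> None:
    if study.truth is None:
        raise DataError("study carries no truth ledger")
    study.truth.to_csv(path, index=False)


def load_sampler_config(path) -> SamplerConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "preset" in raw:
        preset = raw.pop("preset")
        cfg = SamplerConfig.preset(preset)
        for key, value in raw.items():
            setattr(cfg, key, value)
        return cfg
    return SamplerConfig(**raw)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()[:16]


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every set of outputs."""

    seed: int
    model_id: str
    config_hash: str = ""
    dataset_hash: str = ""
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @classmethod
    def create(cls, seed: int, model_id: str, config=None, dataset_path=None) -> "RunManifest":
        return cls(
            seed=seed, model_id=model_id,
            config_hash=_hash_obj(vars(config)) if config is not None else "",
            dataset_hash=_hash_file(dataset_path) if dataset_path else "",
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2)
            fh.write("\n")
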