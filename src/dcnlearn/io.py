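"""HDF5 trace storage and YAML/JSON configuration loading.

Trace layout: one dataset per trial at ``/animal_<id>/<nerve>/trial_<k>``
with shape [7, T] float32 (uV) and attributes ``sample_rate_hz`` and
``t0_index``; the generator config is echoed as JSON in the root attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .features import RawTrace
from .synthetic import GeneratorConfig, TrialSet

__all__ = ["write_trialset", "read_traces", "load_config"]


def load_config(path) -> GeneratorConfig:
    """Generator config from a YAML (or JSON — YAML superset) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GeneratorConfig.from_dict(data)


def write_trialset(trial_set: TrialSet, path) -> None:
    """Materialize a trial set into the HDF5 layout (trials synthesized
    on the fly, so memory stays bounded)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["config"] = json.dumps(trial_set.config.to_dict())
        h5.attrs["n_trials"] = len(trial_set)
        for trace, animal, nerve, trial, seed in trial_set.iter_traces():
            grp = h5.require_group(f"animal_{animal}/{nerve}")
            ds = grp.create_dataset(
                f"trial_{trial}",
                data=trace.samples.astype(np.float32),
                compression="gzip",
            )
            ds.attrs["sample_rate_hz"] = trace.sample_rate
            ds.attrs["t0_index"] = trace.t0_index
            ds.attrs["seed"] = seed


class _StoredTrialSet:
    """Read-side counterpart of :class:`TrialSet` backed by an HDF5 file."""

    def __init__(self, path):
        self.path = path
        with h5py.File(path, "r") as h5:
            self.config = GeneratorConfig.from_dict(
                json.loads(h5.attrs["config"])
            )
            rows = []
            for akey in h5:
                animal = akey.removeprefix("animal_")
                for nerve in h5[akey]:
                    for tkey in h5[akey][nerve]:
                        rows.append(
                            {
                                "animal": animal,
                                "nerve": nerve,
                                "trial": int(tkey.removeprefix("trial_")),
                                "seed": int(h5[akey][nerve][tkey].attrs["seed"]),
                            }
                        )
        self.labels = pd.DataFrame(rows).sort_values(
            ["animal", "nerve", "trial"], ignore_index=True
        )

    def __len__(self) -> int:
        return len(self.labels)

    def iter_traces(self):
        with h5py.File(self.path, "r") as h5:
            for row in self.labels.itertuples(index=False):
                ds = h5[f"animal_{row.animal}/{row.nerve}/trial_{row.trial}"]
                trace = RawTrace(
                    samples=ds[()].astype(float),
                    sample_rate=float(ds.attrs["sample_rate_hz"]),
                    t0_index=int(ds.attrs["t0_index"]),
                )
                yield trace, row.animal, row.nerve, row.trial, row.seed


def read_traces(path) -> _StoredTrialSet:
    """Open a stored trace file; supports the same iteration protocol as a
    freshly generated trial set."""
    return _StoredTrialSet(path)
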