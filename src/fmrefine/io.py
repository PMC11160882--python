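"""Table readers/writers, run configuration and manifests.

All tables are UTF-8 comma-separated files with a header row:

* ensemble:     state_id, obs_id, phi_deg     (long format)
* populations:  state_id, population
* observables:  obs_id, coupling_type, exp_value_hz

Populations off unit sum by more than 1e-6 are an error; smaller deviations
are renormalised with a warning.  Every CLI run writes a manifest JSON
(inputs, config hash, seed, package version) so results are regenerable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .toy import ToyEnsemble

__all__ = ["write_toy_tables", "read_tables", "tables_to_arrays",
           "write_manifest", "RunConfig"]


def write_toy_tables(outdir, ens: ToyEnsemble, observables, coupling_type="3J_HNHa",
                     seed=None, extra_meta=None):
    """Write ensemble/populations/observables CSVs plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [(s, o, ens.phi[i, j])
            for i, s in enumerate(ens.state_ids)
            for j, o in enumerate(ens.observable_ids)]
    pd.DataFrame(rows, columns=["state_id", "obs_id", "phi_deg"]).to_csv(
        outdir / "ensemble.csv", index=False)
    pd.DataFrame({"state_id": ens.state_ids,
                  "population": ens.populations}).to_csv(
        outdir / "populations.csv", index=False)
    pd.DataFrame({"obs_id": ens.observable_ids,
                  "coupling_type": coupling_type,
                  "exp_value_hz": np.asarray(observables, float)}).to_csv(
        outdir / "observables.csv", index=False)
    sidecar = {"seed": seed, **(extra_meta or {})}
    (outdir / "metadata.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def tables_to_arrays(obs_df: pd.DataFrame, ens_df: pd.DataFrame,
                     pop_df: pd.DataFrame | None = None):
    """Cross-key tidy tables into (data vector, ToyEnsemble)."""
    for col in ("obs_id", "exp_value_hz"):
        if col not in obs_df.columns:
            raise ValueError(f"observables table lacks column {col!r}")
    for col in ("state_id", "obs_id", "phi_deg"):
        if col not in ens_df.columns:
            raise ValueError(f"ensemble table lacks column {col!r}")
    if obs_df["obs_id"].duplicated().any():
        dup = obs_df.loc[obs_df["obs_id"].duplicated(), "obs_id"].tolist()
        raise ValueError(f"duplicate observable ids: {dup}")
    obs_ids = list(obs_df["obs_id"])
    missing = sorted(set(obs_ids) - set(ens_df["obs_id"]))
    if missing:
        raise ValueError(f"observables missing from ensemble table: {missing}")
    wide = ens_df.pivot(index="state_id", columns="obs_id", values="phi_deg")
    if wide.isna().any().any():
        raise ValueError("ensemble table has missing state/observable pairs")
    wide = wide[obs_ids]
    state_ids = list(wide.index)
    if pop_df is not None:
        pops = (pop_df.set_index("state_id")["population"]
                .reindex(state_ids))
        if pops.isna().any():
            raise ValueError("populations missing for some states")
        pops = pops.to_numpy(dtype=float)
        total = pops.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"populations sum to {total}, expected 1")
        if total != 1.0:
            warnings.warn("populations renormalised to unit sum")
            pops = pops / total
    else:
        pops = np.full(len(state_ids), 1.0 / len(state_ids))
    ens = ToyEnsemble(phi=wide.to_numpy(dtype=float), populations=pops,
                      state_ids=state_ids, observable_ids=obs_ids)
    data = obs_df["exp_value_hz"].to_numpy(dtype=float)
    return data, ens


def read_tables(obs_path, ens_path, pop_path=None):
    """Read CSV tables from disk; see :func:`tables_to_arrays`."""
    obs_df = pd.read_csv(obs_path)
    ens_df = pd.read_csv(ens_path)
    pop_df = pd.read_csv(pop_path) if pop_path else None
    return tables_to_arrays(obs_df, ens_df, pop_df)


@dataclass
class RunConfig:
    """Run configuration (YAML-serialisable)."""

    mode: str = "sample"            # toy-gen | sample | score | optimize | svd | nn-train
    observables: str = ""
    ensemble: str = ""
    populations: str = ""
    outdir: str = "results"
    seed: int = 0
    likelihood: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, mode: str, seed: int, inputs: dict, config: dict):
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "mode": mode, "seed": seed, "inputs": inputs, "config": config,
        "config_hash": _config_hash({"mode": mode, "seed": seed, **config}),
        "package_version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
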