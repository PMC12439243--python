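"""Config-driven batch simulation runs.

A run config (YAML or dict) names a basis source, a parameter sampling
scheme, optional artifact blocks (B0 map, nuisance profiles, coil
transients, post-processing), a stage, and a record count.  Records are
generated in batches; each record's random stream is derived from the master
seed and the record index only, so the batch size never changes outputs and
a rerun with the same config reproduces byte-identical containers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .b0 import make_b0_map
from .basis import BasisSet, load_basis, make_toy_basis
from .distributions import sample_params
from .model import simulate
from .nuisance import default_baseline_config, default_water_config
from .postprocess import ProcessParams, export_record, process_record
from .transients import sample_coil_params

__all__ = ["RunConfig", "load_run_config", "run"]

_STAGES = ("fid", "transients", "processed")
_FORMATS = ("container", "nifti_mrs")
_TOP_KEYS = {
    "seed",
    "n_records",
    "batch_size",
    "stage",
    "output_dir",
    "formats",
    "basis",
    "scheme",
    "nuisance",
    "b0",
    "coil",
    "process",
}


@dataclass
class RunConfig:
    basis: dict
    scheme: dict = field(default_factory=dict)
    stage: str = "processed"
    n_records: int = 1
    batch_size: int = 32
    output_dir: str = "simulated"
    formats: list[str] = field(default_factory=lambda: ["container"])
    seed: int = 0
    nuisance: Optional[dict] = None
    b0: Optional[dict] = None
    coil: Optional[dict] = None
    process: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}, got {self.stage!r}")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for fmt in self.formats:
            if fmt not in _FORMATS:
                raise ValueError(f"unknown export format {fmt!r}; expected {_FORMATS}")
        if not isinstance(self.basis, dict) or not ({"toy", "path"} & self.basis.keys()):
            raise ValueError("basis block must provide either 'toy' or 'path'")
        if self.stage == "transients" and not self.coil:
            raise ValueError("stage 'transients' requires a coil block")

    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "scheme": self.scheme,
            "stage": self.stage,
            "n_records": self.n_records,
            "batch_size": self.batch_size,
            "output_dir": self.output_dir,
            "formats": self.formats,
            "seed": self.seed,
            "nuisance": self.nuisance,
            "b0": self.b0,
            "coil": self.coil,
            "process": self.process,
        }

    def content_hash(self) -> str:
        """Hash of everything that affects record content (not output paths)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; errors before any work."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _build_basis(block: dict) -> BasisSet:
    if "path" in block:
        return load_basis(block["path"])
    toy = block["toy"]
    spec = [(c["name"], c["group"], [tuple(pk) for pk in c["peaks"]]) for c in toy["components"]]
    return make_toy_basis(
        spec,
        toy["spectral_width"],
        toy["n_points"],
        toy["f0"],
        toy["ppm_ref"],
    )


def record_rng(master_seed: int, index: int) -> np.random.Generator:
    """Per-record stream from (master seed, record index) only."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


def run(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Generate the configured records and return the written-file manifest."""
    out_dir = Path(output_dir if output_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    basis = _build_basis(config.basis)
    axes = basis.axes()
    b0_map = None
    if config.b0:
        blk = dict(config.b0)
        b0_map = make_b0_map(
            tuple(blk.get("shape", (10, 10, 10))),
            blk.get("dx", 0.0),
            blk.get("dy", 0.0),
            blk.get("dz", 0.0),
            blk.get("mu", 0.0),
        )
    nuis = config.nuisance or {}
    baseline_cfg = (
        default_baseline_config(**nuis["baseline"]) if "baseline" in nuis else None
    )
    water_cfg = (
        default_water_config(ppm_ref=basis.ppm_ref, **nuis["residual_water"])
        if "residual_water" in nuis
        else None
    )
    pp = None
    if config.process:
        blk = dict(config.process)
        if blk.get("ppm_window") is not None:
            blk["ppm_window"] = tuple(blk["ppm_window"])
        pp = ProcessParams(**blk)

    files: list[str] = []
    for batch_start in range(0, config.n_records, config.batch_size):
        batch_end = min(batch_start + config.batch_size, config.n_records)
        for idx in range(batch_start, batch_end):
            rng = record_rng(config.seed, idx)
            params = sample_params(config.scheme, 1, basis.names, rng)[0]
            params.b0 = b0_map
            params.baseline = baseline_cfg
            params.residual_water = water_cfg
            if config.stage == "transients":
                coil_blk = dict(config.coil)
                n_tr = int(coil_blk.pop("n_transients"))
                params.coil = sample_coil_params(n_tr, rng, **coil_blk)
            record = simulate(basis, params, axes, rng, stage=config.stage)
            if pp is not None and config.stage == "processed":
                record = process_record(record, pp)
            stem = out_dir / f"record_{idx:05d}"
            if "container" in config.formats:
                files.append(str(export_record(record, stem.with_suffix(".h5"), "container")))
            if "nifti_mrs" in config.formats:
                files.append(str(export_record(record, stem.with_suffix(".nii"), "nifti_mrs")))

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_records": config.n_records,
        "stage": config.stage,
        "files": sorted(files),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
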