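"""Config-driven orchestration of the screen/enrich/interact/simulate stages.

A single YAML config names the stages to run and their parameter blocks
(mirroring each subcommand's CLI options). Execution is deterministic: every
stage derives its seed from the global seed by stage-name hashing, so
reordering stages does not reshuffle randomness, and rerunning an identical
config reproduces byte-identical outputs. A JSON manifest records parameters,
seeds, package version, and a checksum for every input and output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import pandas as pd
import yaml

from . import __version__
from .domain_screen import percent_half_up

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "screen", "enrich", "interact")


@dataclass
class RunConfig:
    stages: list[str]
    params: dict[str, dict[str, Any]]
    seed: int = 0
    out_dir: Path = Path("tecapture_out")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        stages = list(raw.get("stages", []))
        unknown = [s for s in stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return cls(
            stages=stages,
            params={s: dict(raw.get(s, {})) for s in stages},
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "tecapture_out")),
            log_level=str(raw.get("log_level", "INFO")),
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed XOR CRC32 of the stage name (stable)."""
    return (global_seed ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_paths(block: Mapping[str, Any]) -> list[str]:
    keys = ("domains", "sets", "taxonomy", "genes", "tes", "pfam", "lengths",
            "models", "confidence", "benchmark", "domain_map", "radii")
    return [str(block[k]) for k in keys if k in block and block[k]]


def run_pipeline(
    config: RunConfig,
    stage_runners: Mapping[str, Callable[[dict[str, Any], Path, int], list[Path]]],
) -> dict:
    """Execute the configured stages in order and write manifest.json.

    ``stage_runners`` maps stage name -> callable(params, out_dir, seed) that
    returns the list of files it wrote. Inputs that are not produced inside
    the run's output directory must exist before any stage runs. Any stage
    error aborts with the manifest covering the completed stages.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_res = out_dir.resolve()
    missing = []
    for stage in config.stages:
        for p in _input_paths(config.params.get(stage, {})):
            path = Path(p)
            if not path.exists() and out_res not in path.resolve().parents:
                missing.append(p)
    if missing:
        raise FileNotFoundError(f"missing input paths: {missing}")

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    manifest_path = out_dir / "manifest.json"
    try:
        for stage in config.stages:
            params = config.params.get(stage, {})
            seed = stage_seed(config.seed, stage)
            logger.info("running stage %s (seed %d)", stage, seed)
            outputs = stage_runners[stage](params, out_dir, seed)
            manifest["stages"].append(
                {
                    "name": stage,
                    "seed": seed,
                    "params": {k: str(v) for k, v in params.items()},
                    "inputs": {
                        p: _sha256(Path(p))
                        for p in _input_paths(params)
                        if Path(p).exists()
                    },
                    "outputs": {str(p): _sha256(Path(p)) for p in outputs},
                }
            )
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def summarize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise fraction report from a count table (class, count, total).

    Adds ``percent`` (half-up, 1 decimal) and a ``flag`` column; rows with a
    zero denominator are flagged rather than dropped.
    """
    for col in ("class", "count", "total"):
        if col not in table.columns:
            raise ValueError(f"count table missing column {col!r}")
    percents, flags = [], []
    for count, total in zip(table["count"], table["total"]):
        if total == 0:
            percents.append(float("nan"))
            flags.append("zero_denominator")
        else:
            percents.append(percent_half_up(int(count), int(total)))
            flags.append("")
    out = table.copy()
    out["percent"] = percents
    out["flag"] = flags
    return out
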