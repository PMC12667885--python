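"""Configuration parsing and result serialization for the command-line
entry points.

Configs are flat YAML (or JSON, a YAML subset) mappings; unknown keys
are rejected so typos fail loudly. Results are written as TSV for
tabular records and JSON for summaries, with floats at 17 significant
digits so a round-trip through text is exact. Every run directory also
receives a ``run_info.json`` echo (config, seed, package versions) from
which the run can be reconstructed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

logger = logging.getLogger("stabsel")

__all__ = ["RunConfig", "parse_config", "write_results", "write_run_info", "read_table"]

_KNOWN_KEYS = {
    "predict": {"ne", "u", "vm", "vs", "ve", "optimum", "mu", "l"},
    "simulate": {
        "n", "u", "vm", "vs", "ve", "optimum", "burn_in", "record_every",
        "n_samples", "seed", "replicates", "engine",
    },
    "sweep": {
        "ne_values", "u_values", "vm_values", "vs", "ve", "replicates",
        "n_samples", "base_seed", "seed", "preset", "plot",
    },
}


@dataclasses.dataclass
class RunConfig:
    """Fully validated configuration for one CLI run."""

    subcommand: str
    options: dict
    output_dir: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"


def parse_config(
    subcommand: str,
    config_path: Optional[str] = None,
    overrides: Optional[Mapping[str, Any]] = None,
    seed: Optional[int] = None,
    output_dir: Optional[str] = None,
    log_level: str = "INFO",
) -> RunConfig:
    """Merge a config file with command-line overrides.

    Flag values (``overrides``) win over file values; every key that
    falls back to a package default is logged. Unknown or invalid keys
    raise ``ValueError`` naming the offending field.
    """
    if subcommand not in _KNOWN_KEYS:
        raise ValueError(f"unknown subcommand {subcommand!r}")
    known = _KNOWN_KEYS[subcommand]

    options: dict = {}
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise ValueError(f"config file not found: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        for key in loaded:
            if key.lower() not in known:
                raise ValueError(
                    f"unknown config key {key!r} for {subcommand!r}; "
                    f"allowed: {sorted(known)}"
                )
        options.update({k.lower(): v for k, v in loaded.items()})
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key.lower() not in known:
            raise ValueError(f"unknown option {key!r} for {subcommand!r}")
        if key.lower() in options:
            logger.info("flag --%s=%r overrides config file value", key, value)
        options[key.lower()] = value
    for key in sorted(known - set(options)):
        logger.info("%s: %r not set, using package default", subcommand, key)
    if seed is not None:
        options["seed"] = seed
    return RunConfig(
        subcommand=subcommand,
        options=options,
        output_dir=Path(output_dir) if output_dir else None,
        seed=int(options.get("seed", options.get("base_seed", 0)) or 0),
        log_level=log_level,
    )


def _jsonable(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, Path):
        return str(value)
    if hasattr(value, "tolist"):
        return value.tolist()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, float):
        return float(value)
    if hasattr(value, "item"):
        return value.item()
    return value


def write_results(records: Sequence[Mapping[str, Any]], fmt: str, path) -> Path:
    """Write records as TSV (tabular) or JSON (summary).

    Floats are written with 17 significant digits, so reading the file
    back recovers the exact values.
    """
    if len(records) == 0:
        raise ValueError("no records to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [_jsonable(dict(r)) for r in records]
    if fmt == "tsv":
        import pandas as pd

        df = pd.DataFrame(records)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "json":
        payload = records[0] if len(records) == 1 else records
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'tsv' or 'json'")
    return path


def read_table(path) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


def write_run_info(cfg: RunConfig, out_dir: Path) -> Path:
    """Echo config, seed, and versions so a run is reconstructable."""
    import numpy
    import scipy

    from . import __version__

    info = {
        "subcommand": cfg.subcommand,
        "options": _jsonable(cfg.options),
        "seed": cfg.seed,
        "versions": {
            "stabsel": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": sys.version.split()[0],
        },
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_info.json"
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2)
        fh.write("\n")
    return path
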