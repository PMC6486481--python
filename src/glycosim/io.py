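"""Profile and configuration I/O, validation, and run manifests.

Profiles travel as TSV with header ``composition<TAB>abundance_pct<TAB>
sem_pct`` (sem column empty when absent), deterministic key order.  Model,
rules and prior configurations are YAML.  Every CLI run writes a manifest
(JSON) recording config hashes, seeds, package version and output files, so
reruns with identical inputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .fitting import PriorSpec, split_param_name
from .rules import ConfigurationError, EnzymeRule, ScaleFactorTable
from .simulator import GlycanProfile, GolgiModel

__all__ = [
    "read_profile",
    "write_profile",
    "read_model",
    "write_model",
    "read_priors",
    "validate_config",
    "write_manifest",
]

_KEY_RE = re.compile(
    r"^(?:Fuc\d+)?(?:NeuAc\d+)?(?:Hex\d+)?(?:HexNAc\d+)?(?:Glc\d+)?$"
)


def _check_key(key: str, row: int, path) -> None:
    if not key or not _KEY_RE.match(key):
        raise ValueError(
            f"{path}: row {row}, column 'composition': bad composition key {key!r}"
        )


def read_profile(path, declared_prefilter: bool = False, tol: float = 1e-6) -> GlycanProfile:
    """Read a profile TSV; validation errors name the row and column."""
    df = pd.read_csv(
        path, sep="\t", dtype={"composition": str}, float_precision="round_trip"
    )
    expected = ["composition", "abundance_pct", "sem_pct"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    entries: dict[str, float] = {}
    sem: dict[str, float] = {}
    has_sem = df["sem_pct"].notna().any()
    for i, row in df.iterrows():
        key = row["composition"]
        _check_key(key, i, path)
        if key in entries:
            raise ValueError(f"{path}: row {i}: duplicate composition key {key!r}")
        ab = float(row["abundance_pct"])
        if ab < 0:
            raise ValueError(
                f"{path}: row {i}, column 'abundance_pct': negative abundance"
            )
        entries[key] = ab
        if pd.notna(row["sem_pct"]):
            s = float(row["sem_pct"])
            if s < 0:
                raise ValueError(f"{path}: row {i}, column 'sem_pct': negative SEM")
            sem[key] = s
    if declared_prefilter and abs(sum(entries.values()) - 100.0) > tol:
        raise ValueError(
            f"{path}: pre-filter abundances sum to {sum(entries.values())}, not 100"
        )
    return GlycanProfile(entries, sem if has_sem else None)


def write_profile(profile: GlycanProfile, path) -> None:
    # floats written with repr() so read -> write -> read is bit-identical
    lines = ["composition\tabundance_pct\tsem_pct"]
    for k in sorted(profile.entries):
        sem = (
            repr(float(profile.sem[k]))
            if profile.sem is not None and k in profile.sem
            else ""
        )
        lines.append(f"{k}\t{float(profile.entries[k])!r}\t{sem}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> GolgiModel:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    from .synthetic import _model_from_config

    return _model_from_config(cfg["model"] if "model" in cfg else cfg)


def write_model(model: GolgiModel, path) -> None:
    rates: dict[str, dict[int, float]] = {}
    for (enzyme, cisterna), rate in sorted(model.rates.items()):
        rates.setdefault(enzyme, {})[cisterna] = rate
    cfg = {
        "model": {
            "n_cisternae": model.n_cisternae,
            "residence_times": list(model.residence_times),
            "input_distribution": dict(model.input_distribution),
            "rates": rates,
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_priors(path) -> PriorSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    from .synthetic import _priors_from_config

    return _priors_from_config(cfg.get("priors", cfg))


def validate_config(
    model: GolgiModel,
    rules: list[EnzymeRule],
    table: ScaleFactorTable,
    priors: Optional[PriorSpec] = None,
) -> None:
    """Cross-check a model / rule set / prior specification.

    Errors: a prior naming a nonexistent cisterna or an enzyme with no rule.
    Warning (not error): rates for an enzyme that has no rule (inert).
    """
    rule_enzymes = {r.enzyme for r in rules}
    rate_enzymes = {e for e, _ in model.rates}
    inert = rate_enzymes - rule_enzymes
    if inert:
        warnings.warn(
            f"rates given for enzymes with no rule (inert): {sorted(inert)}",
            UserWarning,
            stacklevel=2,
        )
    for sf in table.entries:
        if sf.enzyme not in rule_enzymes:
            raise ConfigurationError(
                f"scale factor {sf.id!r} references unknown enzyme {sf.enzyme!r}"
            )
    if priors is not None:
        for name in priors:
            enzyme, cisterna = split_param_name(name)
            if enzyme not in rule_enzymes:
                raise ConfigurationError(
                    f"prior {name!r} references enzyme with no rule"
                )
            if not (1 <= cisterna <= model.n_cisternae):
                raise ConfigurationError(
                    f"prior {name!r} references cisterna {cisterna} of a "
                    f"{model.n_cisternae}-cisterna model"
                )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_path,
    command: str,
    seed: Optional[int],
    config_files: dict[str, str],
    outputs: list[str],
) -> None:
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "config_hashes": {
            name: _sha256(p) for name, p in config_files.items() if Path(p).exists()
        },
        "outputs": outputs,
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
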