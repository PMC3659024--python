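"""Delimited-text readers/writers and run configuration.

Everything is plain delimited text: pedigree and phenotype data in this
field are small and text-based by convention, and text files keep runs
diffable and auditable.  Writers prepend ``# key=value`` provenance
comment lines (seed, spec hash) which the readers skip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .simulate import DesignSpec, VarianceComponents


def provenance_lines(seed: int | None = None, **extra: Any) -> list[str]:
    lines = []
    if seed is not None:
        lines.append(f"seed={seed}")
    lines.extend(f"{k}={v}" for k, v in extra.items())
    return lines


def spec_hash(spec: DesignSpec) -> str:
    payload = json.dumps(dataclasses.asdict(spec), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def write_phenotypes(df: pd.DataFrame, path: str | Path, sep: str = "\t",
                     header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         dtype={"id": str})
    if "id" not in df.columns or "y" not in df.columns:
        raise ValueError(f"phenotype file {path} needs 'id' and 'y' columns")
    return df


def read_header_metadata(path: str | Path) -> dict[str, str]:
    """Parse the ``# key=value`` provenance comments of any output file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """One reproducible run: inputs, model, design and bookkeeping.

    Unused sections may stay at their defaults; ``seed`` is always recorded
    in every output the run produces.  Round-trips exactly through YAML.
    """

    pedigree: str | None = None
    cultural_pedigree: str | None = None
    phenotypes: str | None = None
    contacts: str | None = None
    trait: str = "y"
    fixed_effects: list[str] = dataclasses.field(default_factory=list)
    group_effects: list[str] = dataclasses.field(default_factory=list)
    random_effects: list[str] = dataclasses.field(
        default_factory=lambda: ["A"])
    cultural_form: str = "relatedness"  # identity | contacts | relatedness
    inertia: dict[str, float] = dataclasses.field(default_factory=dict)
    maternal: str = "rearing"
    design: dict[str, Any] = dataclasses.field(default_factory=dict)
    variance_components: dict[str, float] = dataclasses.field(
        default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def design_spec(self) -> DesignSpec:
        return DesignSpec(**{**self.design, "seed": self.seed})

    def vc(self) -> VarianceComponents:
        return VarianceComponents(**self.variance_components)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
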