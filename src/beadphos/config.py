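"""Run configuration: every stage threshold in one YAML-loadable object.

Defaults are the analysis constants used throughout the package: the QC gate
multiplier (1.5 SD over the negative control), the dephosphorylation score's
final-point count (3), the regulated-site gate (p < 0.05 and log2 fold
change > 0.58, i.e. 1.5-fold), the interactor gate (2-fold, p < 0.05), the
sequence-window flank (7), the fixed near/far boundary (residue 1000), and
the thermodynamic temperature for ΔΔG (298.15 K).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    # bead QC
    qc_multiplier: float = 1.5
    # dephos scoring
    n_final: int = 3
    dephos_statistic: str = "mean"
    # binding
    binding_statistic: str = "median"
    saturation_threshold: float | None = None   # absolute intensity rule
    saturation_quantile: float = 75.0           # relative rule (default)
    kd_aggregate: str = "mean"
    temperature_k: float = 298.15
    # phosphosite calling
    alpha: float = 0.05
    log2fc_min: float = 0.58
    # Ki67-style alternative profile uses a 2-fold gate
    log2fc_strict: float = 1.0
    interactor_fold_min: float = 2.0
    # motif analysis
    flank: int = 7
    motif_boundary: int = 1000
    # inputs (optional; simulators used when absent)
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
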