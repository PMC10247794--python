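"""Schema-validated run configuration.

The configuration is a nested YAML/JSON document; unknown keys are
rejected so typos in threshold names fail loudly.  Defaults are the
study's operating constants: beta < 0.1 / median < 0.02 resistant-site
thresholds, the 0.2 categorical methylation cut, the 450,000-test
Bonferroni factor, the 100-read coverage floor, the 1.62 epiLiver
threshold and the 400 ng/mL AFP threshold.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cohortsim import AfpSimConfig, PlasmaSimConfig, TissueSimConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DiscoveryConfig(_Strict):
    max_beta: float = 0.1
    max_median: float = 0.02
    meth_thresh: float = 0.2
    case_frac: float = 0.5
    ctrl_max: float = 0.2
    min_abs_delta: float = 0.2
    alpha: float = 0.05
    n_tests: int = 450_000
    top_k: int = 20
    target_size: int = 4
    spec_min_delta: float = 0.5
    spec_q_max: float = 1e-20
    spec_shortlist_size: int = 7


class TissueSimSection(_Strict):
    n_probes: int = 2000
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: dict(TissueSimConfig().group_sizes)
    )

    def to_sim_config(self) -> TissueSimConfig:
        return TissueSimConfig(n_probes=self.n_probes, group_sizes=dict(self.group_sizes))


class PlasmaSimSection(_Strict):
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: dict(PlasmaSimConfig().group_sizes)
    )
    coverage_mean: float = 4000.0
    background_error: float = 0.005
    low_coverage_fraction: float = 0.0125

    def to_sim_config(self) -> PlasmaSimConfig:
        return PlasmaSimConfig(
            group_sizes=dict(self.group_sizes),
            coverage_mean=self.coverage_mean,
            background_error=self.background_error,
            low_coverage_fraction=self.low_coverage_fraction,
        )


class PlasmaConfig(_Strict):
    pseudocount: float = 1.0
    min_reads: int = 100
    depth_rule: str = "min"


class ClassifyConfig(_Strict):
    threshold: float = 1.62
    afp_threshold: float = 400.0
    use_afp: bool = False


class RunConfig(_Strict):
    seed: int = 1
    out_dir: str = "epiliver_run"
    discovery: DiscoveryConfig = Field(default_factory=DiscoveryConfig)
    tissue_sim: TissueSimSection = Field(default_factory=TissueSimSection)
    plasma_sim: PlasmaSimSection = Field(default_factory=PlasmaSimSection)
    plasma: PlasmaConfig = Field(default_factory=PlasmaConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
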