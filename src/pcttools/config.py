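"""Run configuration: one YAML file drives every stage.

Unknown keys are rejected; a fully-defaulted config validates. Parameter
defaults are the procedure's canonical values (QC thresholds, doublet
formula, 3,200 variable genes, 32 LSI dimensions, clustering resolutions,
25 neighbours, DEG thresholds, CNV window, top-100 signature size).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

STAGE_ORDER = ["simulate", "qc", "reference", "project", "axis", "cnv", "mp", "pct"]
STAGE_DEPS = {
    "qc": "simulate",
    "reference": "qc",
    "project": "reference",
    "axis": "project",
    "cnv": "qc",
    "mp": "project",
    "pct": "mp",
}


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    n_tissues: int = 3
    samples_per_stage: dict[str, int] = Field(
        default_factory=lambda: {"healthy": 10, "precancer": 8, "cancer": 8}
    )
    cells_per_sample: int = 250
    n_genes: int = 2000
    n_mito_genes: int = 40
    n_transition_genes: int = 60
    transition_effect: float = 1.5
    n_programs: int = 3
    program_size: int = 40
    doublet_rate: float = 0.08
    depth_mean: float = 2000.0


class QCConfig(_Section):
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.25
    pN: float = 0.25
    pK: float = 0.09
    doublet_rate_coefficient: float = 0.08
    n_pcs: int = 20
    nexp_rule: Literal["quadratic", "linear"] = "quadratic"


class ReferenceConfig(_Section):
    n_variable_genes: int = 3200
    n_components: int = 32
    resolutions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.8)
    snn_k: int = 30


class ProjectConfig(_Section):
    k: int = 25


class AxisConfig(_Section):
    stem_label: str = "STM"
    fdr_cutoff: float = 0.05
    lfc_cutoff: float = 0.5
    min_samples: int = 2


class CNVConfig(_Section):
    window: int = 100
    clip: float = 3.0
    reference_stage: str = "healthy"
    norm_scale: float = 1e5  # ln(1 + CPM/10)


class MPConfig(_Section):
    rank_min: int = 4
    rank_max: int = 9
    n_top_genes: int = 50
    nmf_max_genes: int = 1500
    top_fraction: float = 0.05
    k_min: int = 2
    k_max: int = 7


class PCTConfig(_Section):
    top_n: int = 100
    fdr_cutoff: float = 0.05
    pseudo_bulk_lfc: float = 0.25
    subcluster_lfc: float = 0.25
    pct1_cutoff: float = 0.25
    ratio_cutoff: float = 1.5
    use_mp_rho: bool = False


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "pct_run"
    in_dir: str | None = None  # existing bundle when simulate is disabled
    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))
    format_version: str = "1"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    reference: ReferenceConfig = Field(default_factory=ReferenceConfig)
    project: ProjectConfig = Field(default_factory=ProjectConfig)
    axis: AxisConfig = Field(default_factory=AxisConfig)
    cnv: CNVConfig = Field(default_factory=CNVConfig)
    mp: MPConfig = Field(default_factory=MPConfig)
    pct: PCTConfig = Field(default_factory=PCTConfig)

    @model_validator(mode="after")
    def _check_stages(self) -> "RunConfig":
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        enabled = set(self.stages)
        for stage, dep in STAGE_DEPS.items():
            if stage in enabled and dep not in enabled:
                if dep == "simulate" and self.in_dir is not None:
                    continue
                raise ValueError(f"stage {stage!r} requires {dep!r} to be enabled")
        return self

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
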