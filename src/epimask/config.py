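"""Run configuration: a single YAML file with CLI flag overrides.

Seeds are mandatory for stochastic stages — there is no silent clock
seeding anywhere in the toolkit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run.

    delta_beta thresholds differ per analysis arm: 0.20 for ancestry-arm
    DMPs, 0.30 for tumour-arm DMPs, and 0.10 / 0.20 for the corresponding
    DMR arms.
    """

    outdir: str = "epimask_out"
    seed: int = 0
    # inputs (optional: the simulate stage can generate them)
    manifest: str | None = None
    dialect: str = "epicv1"
    vcf: str | None = None
    beta: str | None = None
    covariates: str | None = None
    coords: str | None = None
    # thresholds
    maf_threshold: float = 0.01
    fdr: float = 0.05
    delta_beta_dmp: float = 0.20
    delta_beta_dmr: float = 0.10
    dmr_lambda: float = 1000.0
    dmr_scale_c: float = 2.0
    dmr_min_cpgs: int = 5
    permutation_n: int = 10000
    group: str = "group"
    adjust: list[str] = field(default_factory=list)
    # simulation
    sim_n_probes: int = 500
    sim_n_dmps: int = 10
    sim_n_dmrs: int = 5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr must be in [0, 1]")
        if self.maf_threshold < 0:
            raise ValueError("maf_threshold must be non-negative")
        if self.dmr_lambda <= 0 or self.dmr_scale_c <= 0:
            raise ValueError("dmr_lambda and dmr_scale_c must be positive")
        if self.permutation_n < 1:
            raise ValueError("permutation_n must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
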