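"""Run configuration: every tunable of the pipeline with its default.

A serialized config plus fixed input files (or the simulation seed)
fully determines a run. Nested dataclasses mirror the pipeline stages;
``RunConfig.from_yaml`` / ``to_yaml`` round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml


def _build(cls, payload: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    return cls(**payload)


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_samples: int = 400
    n_markers_per_type: int = 10
    signature_fold: float = 4.0
    subtype_composition_shift: float = 3.0
    concentration: float = 5.0
    n_background: int = 1000
    n_de_genes: int = 100
    de_lfc: float = 1.0
    noise_sd: float = 0.1
    true_beta: float = float(np.log(2.5))
    baseline_rate: float = 1.0 / 1500.0
    censor_rate: float = 0.3
    mut_mean_high: float = 160.0
    mut_mean_low: float = 110.0
    population_seed: int = 0


@dataclass
class InputConfig:
    """Paths used when the simulate stage is disabled."""

    expression: str | None = None
    clinical: str | None = None
    maf: str | None = None
    signature: str | None = None
    expression_orientation: str = "genes-by-samples"


@dataclass
class DeconvolutionConfig:
    method: str = "nu-svr"  # or "nnls"


@dataclass
class ClusterConfig:
    k_min: int = 2
    k_max: int = 5
    n_reps: int = 100
    subsample: float = 0.8
    inner_restarts: int = 10
    kmeans_restarts: int = 25
    pac_tol: float = 0.01
    n_cell_clusters: int = 4


@dataclass
class DiffexprConfig:
    p_adj_max: float = 0.05
    lfc_min: float = float(np.log2(1.5))


@dataclass
class ScoringConfig:
    n_trees: int = 1000
    retain_rule: str = "decoy"  # or "top-n"
    top_n: int | None = None
    cox_p_max: float = 1.0
    minprop: float = 0.1
    maxstat_permutations: int = 0


@dataclass
class CharacterizationConfig:
    exome_mb: float = 38.0
    nonsyn_only: bool = True
    network_r_min: float = 0.2


@dataclass
class RunConfig:
    seed: int = 7
    outdir: str = "tmescore_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    inputs: InputConfig = field(default_factory=InputConfig)
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    diffexpr: DiffexprConfig = field(default_factory=DiffexprConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    characterization: CharacterizationConfig = field(
        default_factory=CharacterizationConfig
    )

    _SECTIONS = {
        "simulate": SimulateConfig,
        "inputs": InputConfig,
        "deconvolution": DeconvolutionConfig,
        "clustering": ClusterConfig,
        "diffexpr": DiffexprConfig,
        "scoring": ScoringConfig,
        "characterization": CharacterizationConfig,
    }

    def validate(self) -> None:
        if not self.simulate.enabled:
            for name in ("expression", "clinical"):
                if getattr(self.inputs, name) is None:
                    raise ValueError(
                        f"simulate stage disabled but inputs.{name} not given"
                    )
        if self.clustering.k_min < 2 or self.clustering.k_max < self.clustering.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in payload:
                kwargs[name] = _build(section_cls, payload.pop(name) or {})
        return _build(cls, {**payload, **kwargs})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
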