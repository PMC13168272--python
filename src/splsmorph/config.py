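"""Analysis configuration: a validated, YAML-loadable bag of settings."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml


@dataclass
class AnalysisConfig:
    """Everything one run needs: paths, tuning grids, permutations, seed.

    ``keepx_stop=None`` resolves to the feature count at run time.  The
    ``simulation`` mapping (if present) is forwarded to
    :class:`splsmorph.simulate.SimulationSpec`.
    """

    features: str | None = None
    phenotypes: str | None = None
    measure: str = "thickness"
    keepx_start: int = 5
    keepx_stop: int | None = None
    keepx_step: int = 5
    components: list[int] | None = None
    n_permutations: int = 1000
    seed: int = 0
    mad_threshold: float = 3.0
    var_tol: float = 1e-8
    retune_components: bool = False
    output_dir: str = "results"
    roi_parcels: list[str] = field(default_factory=list)
    simulation: dict | None = None

    def __post_init__(self) -> None:
        if self.keepx_start < 1:
            raise ValueError("keepx_start must be >= 1")
        if self.keepx_step < 1:
            raise ValueError("keepx_step must be >= 1")
        if self.keepx_stop is not None and self.keepx_stop < self.keepx_start:
            raise ValueError("keepx_stop must be >= keepx_start")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.components is not None:
            self.components = [int(k) for k in self.components]
            if any(k < 1 for k in self.components):
                raise ValueError("component candidates must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        valid = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - valid)
        if unknown:
            raise ValueError(
                f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def keepx_grid(self, n_features: int) -> list[int]:
        stop = self.keepx_stop if self.keepx_stop is not None else n_features
        stop = min(stop, n_features)
        return list(range(self.keepx_start, stop + 1, self.keepx_step))

    def to_dict(self) -> dict:
        return asdict(self)
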