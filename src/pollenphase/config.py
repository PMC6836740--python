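"""Run configuration: one object bundling every stage's parameters.

The cell order is authoritative: barcode bit c always refers to
``cell_order[c]``, and every per-cell output header repeats the order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .phase import PhaseParams
from .sim import SimConfig


@dataclass(frozen=True)
class AnchorParams:
    k: int = 21
    max_hits: int = 10
    min_coverage: float = 0.80


@dataclass(frozen=True)
class BarcodeParams:
    min_cells: int = 2


@dataclass(frozen=True)
class McoParams:
    min_run: int = 2
    n_bins: int = 10


@dataclass(frozen=True)
class MosaicParams:
    min_sites: int = 1


@dataclass
class RunConfig:
    mode: str = "simulate"
    seed: int = 0
    cell_order: list[str] | None = None
    outdir: str = "."
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    anchor: AnchorParams = field(default_factory=AnchorParams)
    barcode: BarcodeParams = field(default_factory=BarcodeParams)
    phase: PhaseParams = field(default_factory=PhaseParams)
    mco: McoParams = field(default_factory=McoParams)
    mosaic: MosaicParams = field(default_factory=MosaicParams)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ConfigError("mode must be 'simulate' or 'real'")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        if self.cell_order is None:
            self.cell_order = [f"cell{i:02d}" for i in range(self.sim.n_cells)]
        if len(set(self.cell_order)) != len(self.cell_order):
            raise ConfigError("cell_order contains duplicates")
        if len(self.cell_order) != self.sim.n_cells:
            raise ConfigError("cell_order length must equal sim.n_cells")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples are not YAML-native; store them as lists
        d["sim"]["coverage_range"] = list(d["sim"]["coverage_range"])
        d["sim"]["fragment_length_range"] = list(d["sim"]["fragment_length_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        for key in ("coverage_range", "fragment_length_range"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        try:
            return cls(
                sim=SimConfig(**sim_d),
                anchor=AnchorParams(**d.pop("anchor", {})),
                barcode=BarcodeParams(**d.pop("barcode", {})),
                phase=PhaseParams(**d.pop("phase", {})),
                mco=McoParams(**d.pop("mco", {})),
                mosaic=MosaicParams(**d.pop("mosaic", {})),
                **d,
            )
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
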