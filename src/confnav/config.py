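"""Run configuration: one serializable block per pipeline stage.

Every field has a default; unknown keys in a config file are rejected so
typos fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .descriptors import SoapParams

__all__ = [
    "SoapConfig",
    "RematchConfig",
    "SketchmapConfig",
    "ClusterConfig",
    "DiagnosticsConfig",
    "RunConfig",
]


def _from_dict(cls, data: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown keys in {cls.__name__.replace('Config', '').lower()} "
            f"config: {sorted(unknown)}"
        )
    return cls(**data)


@dataclass
class SoapConfig:
    cutoff: float = 4.0
    atom_sigma: float = 0.3
    n_max: int = 8
    l_max: int = 6
    zeta: float = 2.0
    species_mask: list[str] = field(default_factory=list)

    def to_params(self) -> SoapParams:
        return SoapParams(
            cutoff=self.cutoff,
            atom_sigma=self.atom_sigma,
            n_max=self.n_max,
            l_max=self.l_max,
            zeta=self.zeta,
            species_mask=frozenset(self.species_mask),
        )


@dataclass
class RematchConfig:
    gamma: float = 0.1
    normalize: bool = True
    tol: float = 1e-6
    max_iter: int = 5000


@dataclass
class SketchmapConfig:
    sigma: float | str = "auto"
    n_bins: int = 100
    A_hd: float = 1.0
    B_hd: float = 4.0
    a_ld: float = 1.0
    b_ld: float = 4.0
    n_starts: int = 5
    max_iter: int = 1000
    n_landmarks: int = 500


@dataclass
class ClusterConfig:
    cut_height: float = 0.1


@dataclass
class DiagnosticsConfig:
    cut_height: float = 0.1
    sigma_D_max: float = float("inf")
    sigma_E_min: float = float("inf")
    outlier_max_size: int = 2
    outlier_min_height: float = 0.0
    spread_mode: str = "sd"
    property: str = "energy"


@dataclass
class RunConfig:
    """All pipeline parameters, serializable to one human-readable file."""

    seed: int = 0
    soap: SoapConfig = field(default_factory=SoapConfig)
    rematch: RematchConfig = field(default_factory=RematchConfig)
    sketchmap: SketchmapConfig = field(default_factory=SketchmapConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)

    _SECTIONS = {
        "soap": SoapConfig,
        "rematch": RematchConfig,
        "sketchmap": SketchmapConfig,
        "cluster": ClusterConfig,
        "diagnostics": DiagnosticsConfig,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {"seed": int(data.get("seed", 0))}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _from_dict(section_cls, data[name] or {})
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
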