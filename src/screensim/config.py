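"""Screen configuration: nested parameter blocks and YAML (de)serialization."""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from .facs import FacsParams
from .genome import GeneClass, GenomeConfig
from .growth import GrowthParams
from .infection import InfectionParams
from .library import LibraryConfig
from .sequencing import SeqParams

__all__ = ["ScreenConfig", "load_config", "dump_config"]

FACS = "facs"
GROWTH = "growth"


@dataclass
class ScreenConfig:
    """Full configuration of one simulated screen."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    library: LibraryConfig = field(default_factory=LibraryConfig)
    infection: InfectionParams = field(default_factory=InfectionParams)
    selection_type: str = FACS
    facs: FacsParams = field(default_factory=FacsParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    sequencing: SeqParams = field(default_factory=SeqParams)
    pseudocount: float = 0.5
    top_n: int = 50

    def validate(self) -> None:
        self.genome.validate()
        self.library.validate()
        self.infection.validate()
        self.sequencing.validate()
        if self.selection_type == FACS:
            self.facs.validate()
        elif self.selection_type == GROWTH:
            self.growth.validate()
        else:
            raise ValueError(f"selection_type must be {FACS!r} or {GROWTH!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    def copy(self) -> "ScreenConfig":
        return copy.deepcopy(self)

    # -- dict / YAML round trip -------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        genome = asdict(self.genome)
        genome["fractions"] = {
            (k.value if isinstance(k, GeneClass) else str(k)): v
            for k, v in self.genome.fractions.items()
        }
        genome["positive_clamp"] = list(self.genome.positive_clamp)
        genome["negative_clamp"] = list(self.genome.negative_clamp)
        genome["sigmoid_p_bounds"] = list(self.genome.sigmoid_p_bounds)
        selection: dict[str, Any] = {"type": self.selection_type}
        if self.selection_type == FACS:
            selection.update(asdict(self.facs))
        else:
            selection.update(asdict(self.growth))
        return {
            "genome": genome,
            "library": asdict(self.library),
            "infection": asdict(self.infection),
            "selection": selection,
            "sequencing": asdict(self.sequencing),
            "analysis": {"pseudocount": self.pseudocount},
            "evaluation": {"top_n": self.top_n},
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ScreenConfig":
        cfg = cls()
        if "genome" in data:
            g = dict(data["genome"])
            if "fractions" in g:
                g["fractions"] = {GeneClass(k): float(v) for k, v in g["fractions"].items()}
            for key in ("positive_clamp", "negative_clamp", "sigmoid_p_bounds"):
                if key in g:
                    g[key] = tuple(g[key])
            cfg.genome = GenomeConfig(**g)
        if "library" in data:
            cfg.library = LibraryConfig(**data["library"])
        if "infection" in data:
            cfg.infection = InfectionParams(**data["infection"])
        if "selection" in data:
            sel = dict(data["selection"])
            cfg.selection_type = sel.pop("type", FACS)
            if cfg.selection_type == FACS:
                cfg.facs = FacsParams(**sel)
            elif cfg.selection_type == GROWTH:
                cfg.growth = GrowthParams(**sel)
            else:
                raise ValueError(f"unknown selection type {cfg.selection_type!r}")
        if "sequencing" in data:
            cfg.sequencing = SeqParams(**data["sequencing"])
        if "analysis" in data:
            cfg.pseudocount = float(data["analysis"].get("pseudocount", cfg.pseudocount))
        if "evaluation" in data:
            cfg.top_n = int(data["evaluation"].get("top_n", cfg.top_n))
        cfg.validate()
        return cfg


def load_config(path) -> ScreenConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ScreenConfig.from_dict(data)


def dump_config(config: ScreenConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
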