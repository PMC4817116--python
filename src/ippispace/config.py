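"""Pipeline configuration: a YAML-backed dataclass with validation.

Two significance levels are carried through the pipeline: the ligand-space
alpha (0.05) for descriptor comparisons and the much stricter pocket-space
alpha (1e-4) for cluster characterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import DISCRIMINATIVE_DESCRIPTORS, DatasetSpec, default_specs

#: The 20-descriptor chemical-space configuration: the 7 discriminative
#: descriptors plus 13 conventional 2D descriptors.
PCA_DESCRIPTORS = DISCRIMINATIVE_DESCRIPTORS + (
    "Fsp2",
    "TPSA",
    "HBA",
    "HBD",
    "n_chiral_centers",
    "rotatable_bond_fraction",
    "n_rings",
    "n_benz_like_rings",
    "Csp3_ratio",
    "O_fraction",
    "N_fraction",
    "double_bond_fraction",
    "n_halogens",
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the module docstring for the alphas."""

    output_dir: Path
    seed: int
    specs: list[DatasetSpec] = field(default_factory=lambda: list(default_specs().values()))
    input_table: Path | None = None  # pre-computed descriptor table instead of synthesis
    descriptors: list[str] = field(
        default_factory=lambda: list(DISCRIMINATIVE_DESCRIPTORS)
    )
    alpha_ligand: float = 0.05
    alpha_pocket: float = 1e-4
    n_clusters: int | None = None  # None: no tree cut
    ward_variant: str = "D2"
    standardize_pockets: bool = True

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        for name, a in (("alpha_ligand", self.alpha_ligand), ("alpha_pocket", self.alpha_pocket)):
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.input_table is None and not self.specs:
            raise ValueError("either synthetic specs or an input table is required")
        if self.seed is None and self.specs:
            raise ValueError("a seed is required when synthesis is enabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        specs = raw.pop("specs", None)
        if specs is not None:
            from .synth import DatasetSpec as DS

            raw["specs"] = [
                DS(
                    name=s["name"],
                    n=s["n"],
                    means=s["means"],
                    sds=s["sds"],
                    bounds={k: tuple(v) for k, v in s.get("bounds", {}).items()},
                    target=s.get("target"),
                    seed=s["seed"],
                )
                for s in specs
            ]
        if "input_table" in raw and raw["input_table"] is not None:
            raw["input_table"] = Path(raw["input_table"])
        return cls(**raw)

    def to_dict(self) -> dict:
        from .synth import spec_to_dict

        return {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "specs": [spec_to_dict(s) for s in self.specs],
            "input_table": str(self.input_table) if self.input_table else None,
            "descriptors": list(self.descriptors),
            "alpha_ligand": self.alpha_ligand,
            "alpha_pocket": self.alpha_pocket,
            "n_clusters": self.n_clusters,
            "ward_variant": self.ward_variant,
            "standardize_pockets": self.standardize_pockets,
        }
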