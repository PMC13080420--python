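"""Experiment manifest, pipeline configuration, and table IO.

The manifest is a JSON file mapping each plant (accession x condition x
replicate) to its image files: six side-view PNGs with their angles, a
three-band reflectance TIFF and an (F0, Fm) fluorescence TIFF. Trait tables
travel as long-format CSV with columns ``accession, species_group,
condition, replicate, trait, value``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

TABLE_COLUMNS = ["accession", "species_group", "condition", "replicate", "trait", "value"]


@dataclass
class PipelineConfig:
    """Validated knobs for the simulate / extract / stats stages."""

    n_accessions: int = 180
    n_conditions: int = 2
    n_reps: int = 3
    seed: int = 0
    # segmentation
    blue_margin: float = 0.2
    excess_green_threshold: float = 0.1
    min_component_px: int = 10
    # phantom rendering
    noise_sigma: float = 0.0
    # statistics
    heritability_basis: str = "plot"
    draw_threshold: float = 0.30
    strong_threshold: float = 0.60
    include_residual_contribution: bool = True

    def __post_init__(self):
        if min(self.n_accessions, self.n_conditions, self.n_reps) < 1:
            raise ValueError("design counts must be >= 1")
        if not 0.0 < self.blue_margin < 1.0:
            raise ValueError("blue_margin must lie in (0, 1)")
        if not -1.0 < self.excess_green_threshold < 2.0:
            raise ValueError("excess_green_threshold out of range")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.heritability_basis not in ("plot", "entry-mean"):
            raise ValueError("heritability_basis must be 'plot' or 'entry-mean'")
        if not 0.0 <= self.draw_threshold <= self.strong_threshold <= 1.0:
            raise ValueError("need 0 <= draw_threshold <= strong_threshold <= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class PlantEntry:
    """One experimental unit and the files recorded for it."""

    plant_id: str
    accession: str
    species_group: str
    condition: str
    replicate: int
    side_view_paths: dict[int, str] = field(default_factory=dict)  # angle -> path
    reflectance_path: str | None = None
    fluorescence_path: str | None = None


@dataclass
class ExperimentManifest:
    """All plants of one experiment plus provenance."""

    plants: list[PlantEntry]
    seed: int = 0
    note: str = ""
    manual_csv: str | None = None

    def __post_init__(self):
        keys = [(p.accession, p.condition, p.replicate) for p in self.plants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (accession, condition, replicate) entries in manifest")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "note": self.note,
            "manual_csv": self.manual_csv,
            "plants": [asdict(p) for p in self.plants],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path, check_files: bool = True) -> "ExperimentManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        plants = []
        for entry in payload["plants"]:
            entry["side_view_paths"] = {int(k): v for k, v in entry["side_view_paths"].items()}
            plants.append(PlantEntry(**entry))
        m = cls(
            plants=plants,
            seed=payload.get("seed", 0),
            note=payload.get("note", ""),
            manual_csv=payload.get("manual_csv"),
        )
        if check_files:
            root = path.parent
            missing = []
            for p in m.plants:
                for f in list(p.side_view_paths.values()) + [p.reflectance_path, p.fluorescence_path]:
                    if f is not None and not (root / f).exists():
                        missing.append(f)
            if m.manual_csv is not None and not (root / m.manual_csv).exists():
                missing.append(m.manual_csv)
            if missing:
                raise FileNotFoundError(f"manifest references missing files: {missing[:5]}")
        return m


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format trait table as CSV."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table lacks columns {missing}")
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format trait table; validates columns and key uniqueness."""
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table lacks columns {missing}")
    dup = table.duplicated(subset=["accession", "condition", "replicate", "trait"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (accession, condition, replicate, trait) keys")
    conds = table["condition"].nunique()
    if conds > 2:
        raise ValueError(f"expected at most two condition labels, found {conds}")
    return table
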