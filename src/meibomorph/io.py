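"""File I/O and run configuration.

Images and masks travel as 8-bit grayscale PNG (mask: 0 = background,
255 = foreground); cohort manifests and per-gland results as CSV; ground
truth and run metadata as JSON sidecars.  Every output carries the hash
of the configuration that produced it, so identical config + inputs give
identical, attributable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "RunConfig",
    "write_png",
    "read_png",
    "write_mask",
    "read_mask",
    "PER_GLAND_COLUMNS",
]

PER_GLAND_COLUMNS = [
    "subject_id", "eye", "group", "gland_index",
    "pa", "pb", "L_central", "w_avg", "sigma_w", "n", "variant", "D",
]


@dataclass
class RunConfig:
    """Serializable configuration for a pipeline run."""

    seed: int = 0
    variant: str = "normalized_plus_one"
    step_px: int = 1
    sigma_denominator: str = "n_plus_1"
    min_area: int = 64
    temporal_side_od: str = "left"
    temporal_side_os: str = "right"
    alpha: float = 0.05
    fdr_correct: bool = False
    n_subjects: int = 36
    noise_sd_image: float = 4.0
    segmentation: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def temporal_side(self, laterality: str) -> str:
        return self.temporal_side_od if laterality.upper() == "OD" else self.temporal_side_os


def write_png(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def read_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_png(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    return read_png(path) > 127


def eye_to_rows(record) -> list[dict]:
    """Flatten an EyeRecord into per-gland CSV rows."""
    rows = []
    for rec in record.records:
        geom = rec.geometry_ref
        rows.append(
            {
                "subject_id": record.subject_id,
                "eye": record.laterality,
                "group": record.group,
                "gland_index": rec.gland_index,
                "pa": geom.pa if geom else np.nan,
                "pb": geom.pb if geom else np.nan,
                "L_central": geom.L_central if geom else np.nan,
                "w_avg": geom.w_avg if geom else np.nan,
                "sigma_w": geom.sigma_w if geom else np.nan,
                "n": geom.n if geom else np.nan,
                "variant": rec.variant,
                "D": rec.D,
            }
        )
    return rows


def write_per_gland_csv(path: str | Path, records: list, config: RunConfig) -> pd.DataFrame:
    rows = []
    for record in records:
        rows.extend(eye_to_rows(record))
    df = pd.DataFrame(rows, columns=PER_GLAND_COLUMNS)
    df.to_csv(path, index=False)
    meta = Path(path).with_suffix(".meta.json")
    meta.write_text(json.dumps({"config": config.to_dict(), "config_hash": config.config_hash()}, indent=1))
    return df
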