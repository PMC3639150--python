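"""Run configuration: YAML file + command-line overrides (flags win).

Schema (all keys optional; defaults reproduce the reference system)::

    grid: {start_nm: 200.0, stop_nm: 500.0, spacing_nm: 0.5}
    order: 1
    delta_lambda_nm: 20.0
    min_slope: 1.0e-6
    seed: 0
    noise:
      multiplicative_sd: 0.003
      additive_sd: 0.0005
      baseline_drift: 0.0
    wavelengths:            # optional manual working-wavelength overrides
      clindamycin: 251.0
      tretinoin: 364.0
    species:                # optional replacement for the built-in fixtures
      <name>: {description: ..., bands: [{center_nm, width_nm, absorptivity}]}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .crossings import DEFAULT_MIN_SLOPE
from .errors import GridError, RangeError, ValidationError
from .simulate import (
    DEFAULT_GRID_SPACING,
    DEFAULT_GRID_START,
    DEFAULT_GRID_STOP,
    DEFAULT_SPECIES,
    NoiseModel,
    SpeciesModel,
    noise_from_config,
    species_from_config,
)
from .spectra import uniform_grid


@dataclasses.dataclass
class RunConfig:
    grid_start_nm: float = DEFAULT_GRID_START
    grid_stop_nm: float = DEFAULT_GRID_STOP
    grid_spacing_nm: float = DEFAULT_GRID_SPACING
    order: int = 1
    delta_lambda_nm: float = 20.0
    min_slope: float = DEFAULT_MIN_SLOPE
    seed: int = 0
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    wavelengths: dict[str, float] = dataclasses.field(default_factory=dict)
    species: dict[str, SpeciesModel] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SPECIES)
    )

    def __post_init__(self) -> None:
        if self.grid_spacing_nm <= 0:
            raise GridError("grid spacing must be positive")
        ratio = self.delta_lambda_nm / self.grid_spacing_nm
        if self.delta_lambda_nm <= 0 or abs(ratio - round(ratio)) > 1e-9:
            raise GridError(
                f"delta_lambda {self.delta_lambda_nm:g} nm must be a positive "
                f"integer multiple of the grid spacing {self.grid_spacing_nm:g} nm"
            )
        for analyte, wl in self.wavelengths.items():
            if not self.grid_start_nm <= wl <= self.grid_stop_nm:
                raise RangeError(
                    f"manual wavelength {wl:g} nm for {analyte!r} outside the "
                    f"grid range {self.grid_start_nm:g}-{self.grid_stop_nm:g} nm"
                )

    def grid(self) -> np.ndarray:
        return uniform_grid(self.grid_start_nm, self.grid_stop_nm, self.grid_spacing_nm)

    def digest(self) -> str:
        """Stable hash of the effective configuration, for run logging."""
        payload = {
            "grid": [self.grid_start_nm, self.grid_stop_nm, self.grid_spacing_nm],
            "order": self.order,
            "delta_lambda_nm": self.delta_lambda_nm,
            "min_slope": self.min_slope,
            "seed": self.seed,
            "noise": dataclasses.asdict(self.noise),
            "wavelengths": dict(sorted(self.wavelengths.items())),
            "species": {
                name: [dataclasses.asdict(b) for b in sp.bands]
                for name, sp in sorted(self.species.items())
            },
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config (optional) and apply keyword overrides (flags win).

    Override keys match :class:`RunConfig` field names; ``None`` values are
    ignored so CLI flags can be passed through unconditionally.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must be a mapping")
    grid = raw.get("grid", {})
    kwargs: dict = {
        "grid_start_nm": float(grid.get("start_nm", DEFAULT_GRID_START)),
        "grid_stop_nm": float(grid.get("stop_nm", DEFAULT_GRID_STOP)),
        "grid_spacing_nm": float(grid.get("spacing_nm", DEFAULT_GRID_SPACING)),
        "order": int(raw.get("order", 1)),
        "delta_lambda_nm": float(raw.get("delta_lambda_nm", 20.0)),
        "min_slope": float(raw.get("min_slope", DEFAULT_MIN_SLOPE)),
        "seed": int(raw.get("seed", 0)),
        "wavelengths": {
            str(k): float(v) for k, v in (raw.get("wavelengths") or {}).items()
        },
    }
    if "species" in raw and raw["species"]:
        kwargs["species"] = species_from_config(raw["species"])
    effective = {k: v for k, v in overrides.items() if v is not None}
    seed = int(effective.get("seed", kwargs["seed"]))
    kwargs["noise"] = noise_from_config(raw.get("noise") or {}, seed=seed)
    kwargs.update(effective)
    kwargs["seed"] = seed
    return RunConfig(**kwargs)
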