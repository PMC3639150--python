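"""Synthetic two-analyte spectral system.

Generates a clindamycin-like / tretinoin-like pair of chromophores with
strongly overlapping zero-order spectra, Beer-Lambert additive mixing and
instrument-style photometric noise, together with the calibration and
validation sample designs of the reference method, so that the full
zero-crossing workflow can be exercised and tested without instrument data.

Each species is a sum of Gaussian absorption bands:

    A(lambda) = c * sum_b  eps_b * exp(-(lambda - mu_b)^2 / (2 sigma_b^2))

with c the concentration (ug/ml) and eps_b the band absorptivity
(AU per ug/ml at the band maximum).  The default fixtures are explicit
constructions, not spectra of the real compounds; they reproduce the
*geometry* the method relies on: marked zero-order overlap in the
short-wavelength region, a short-wavelength-band analyte measurable at a
zero crossing of the long-wavelength analyte near its own steep flank, and
vice versa.  See docs/methods.md for the reasoning behind each band.

Noise model: multiplicative (photometric, relative), then additive (AU),
plus an optional linear baseline drift; every sample's noise stream is
derived deterministically from (seed, sample_id), so regeneration is
bit-identical and independent of generation order.
"""

from __future__ import annotations

import dataclasses
import zlib
from collections.abc import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .spectra import MixtureDesign, Spectrum, SpectrumSet, design_from_rows, uniform_grid

#: default scan range and sampling interval (nm); 0.5 nm makes every
#: reference delta-lambda (16, 20, 10.5, 14 nm) an exact step multiple
DEFAULT_GRID_START = 200.0
DEFAULT_GRID_STOP = 500.0
DEFAULT_GRID_SPACING = 0.5


def default_grid() -> np.ndarray:
    return uniform_grid(DEFAULT_GRID_START, DEFAULT_GRID_STOP, DEFAULT_GRID_SPACING)


@dataclasses.dataclass(frozen=True)
class Band:
    """One Gaussian absorption band."""

    center_nm: float
    width_nm: float  # Gaussian SD
    absorptivity: float  # AU per (ug/ml) at band max

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValidationError("band width must be positive")
        if self.absorptivity < 0:
            raise ValidationError("band absorptivity must be >= 0")


@dataclasses.dataclass(frozen=True)
class SpeciesModel:
    """A pure chromophore as a sum of Gaussian bands."""

    name: str
    bands: tuple[Band, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValidationError("a species needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))

    def absorptivity_curve(self, grid: np.ndarray) -> np.ndarray:
        """Absorbance per unit concentration on the grid."""
        grid = np.asarray(grid, dtype=float)
        out = np.zeros_like(grid)
        for b in self.bands:
            out += b.absorptivity * np.exp(
                -((grid - b.center_nm) ** 2) / (2.0 * b.width_nm**2)
            )
        return out


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Photometric noise: relative (multiplicative), absolute (additive),
    linear baseline drift, and the master seed."""

    additive_sd: float = 0.0005  # AU
    multiplicative_sd: float = 0.003  # relative fraction
    baseline_drift: float = 0.0  # AU per 100 nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValidationError("noise SDs must be >= 0")

    @property
    def is_silent(self) -> bool:
        return (
            self.additive_sd == 0
            and self.multiplicative_sd == 0
            and self.baseline_drift == 0
        )


NO_NOISE = NoiseModel(additive_sd=0.0, multiplicative_sd=0.0, baseline_drift=0.0)

# ---------------------------------------------------------------------------
# Default species fixtures.
#
# clindamycin-like: dominant far-UV band (210 nm) with a weak shoulder
# (245 nm) and a trace long-wavelength feature (390 nm) whose derivative
# zero crossing on the tretinoin-like band flank provides the interferent
# null at which the tretinoin-like analyte is read (the reference system
# likewise reports a long-wavelength first-derivative crossing for the
# short-wavelength analyte).
#
# tretinoin-like: strong visible-edge band (360 nm; 12.5 ug/ml -> 0.6 AU at
# the maximum) plus a secondary short-UV band (225 nm) sitting on the
# clindamycin-like main band's steep flank, whose zero crossing provides the
# interferent null at which the clindamycin-like analyte is read.

CLINDAMYCIN_LIKE = SpeciesModel(
    name="clindamycin",
    bands=(
        Band(center_nm=210.0, width_nm=10.0, absorptivity=8e-4),
        Band(center_nm=245.0, width_nm=15.0, absorptivity=2e-4),
        Band(center_nm=390.0, width_nm=9.0, absorptivity=1e-5),
    ),
    description="short-wavelength-band analyte, calibration 60-1200 ug/ml",
)

TRETINOIN_LIKE = SpeciesModel(
    name="tretinoin",
    bands=(
        Band(center_nm=225.0, width_nm=12.0, absorptivity=0.012),
        Band(center_nm=360.0, width_nm=30.0, absorptivity=0.048),
    ),
    description="long-wavelength-band analyte, calibration 1.25-25 ug/ml",
)

DEFAULT_SPECIES: dict[str, SpeciesModel] = {
    "clindamycin": CLINDAMYCIN_LIKE,
    "tretinoin": TRETINOIN_LIKE,
}

#: fixed interferent levels of the reference calibration designs (ug/ml)
TRETINOIN_FIXED = 12.5
CLINDAMYCIN_FIXED = 600.0
CLINDAMYCIN_LEVELS = (60.0, 120.0, 240.0, 360.0, 480.0, 720.0, 960.0, 1200.0)
TRETINOIN_LEVELS = (1.25, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0)
ACCURACY_CLINDAMYCIN_LEVELS = (60.0, 480.0, 1200.0)
ACCURACY_TRETINOIN_LEVELS = (1.25, 5.0, 15.0)
#: dosage-form label ratio 1.2 g : 25 mg per 100 g, 0.5 g sample in 50 ml
ASSAY_CLINDAMYCIN = 120.0
ASSAY_TRETINOIN = 2.5


# ---------------------------------------------------------------------------
# Spectrum generation


def species_spectrum(
    model: SpeciesModel, concentration: float, grid=None
) -> Spectrum:
    """Noiseless pure-component spectrum at the given concentration."""
    if concentration < 0:
        raise ValidationError(f"negative concentration: {concentration}")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    ab = concentration * model.absorptivity_curve(g)
    return Spectrum(g, ab, sample_id=f"{model.name}_{concentration:g}")


def _sample_rng(noise: NoiseModel, sample_id: str) -> np.random.Generator:
    # (seed, crc32(sample_id)) -> independent, order-free, reproducible stream
    tag = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(noise.seed), tag]))


def mixture_spectrum(
    species: Sequence[tuple[SpeciesModel, float]],
    noise: NoiseModel = NO_NOISE,
    grid=None,
    sample_id: str = "mixture",
) -> Spectrum:
    """Beer-Lambert additive mixture with baseline drift and noise.

    Noise is applied multiplicatively first (relative photometric error),
    then additively, seeded reproducibly per (noise.seed, sample_id).
    """
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    ab = np.zeros_like(g)
    for model, conc in species:
        ab = ab + species_spectrum(model, conc, g).absorbance
    if noise.baseline_drift != 0:
        ab = ab + noise.baseline_drift * (g - g[0]) / 100.0
    if noise.multiplicative_sd > 0 or noise.additive_sd > 0:
        rng = _sample_rng(noise, sample_id)
        if noise.multiplicative_sd > 0:
            ab = ab * (1.0 + noise.multiplicative_sd * rng.standard_normal(g.size))
        if noise.additive_sd > 0:
            ab = ab + noise.additive_sd * rng.standard_normal(g.size)
    return Spectrum(g, ab, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Sample designs

DESIGN_KINDS = (
    "clindamycin_calibration",
    "tretinoin_calibration",
    "accuracy_panel",
    "assay_sample",
)


def generate_design(kind: str, n_replicates: int = 3) -> MixtureDesign:
    """The reference study's sample designs.

    - ``clindamycin_calibration``: 8 levels 60-1200 ug/ml, tretinoin fixed
      at 12.5 ug/ml.
    - ``tretinoin_calibration``: 8 levels 1.25-25 ug/ml, clindamycin fixed
      at 600 ug/ml.
    - ``accuracy_panel``: 3 levels per analyte (60/480/1200 and 1.25/5/15)
      at the fixed partner concentrations, ``n_replicates`` each.
    - ``assay_sample``: the dosage-form label ratio (1.2 g clindamycin :
      25 mg tretinoin per 100 g; 0.5 g dissolved to 50 ml) -> 120 and
      2.5 ug/ml.
    """
    if kind == "clindamycin_calibration":
        rows = [
            (f"clin_cal_{c:g}", {"clindamycin": c, "tretinoin": TRETINOIN_FIXED})
            for c in CLINDAMYCIN_LEVELS
        ]
    elif kind == "tretinoin_calibration":
        rows = [
            (f"tret_cal_{c:g}", {"clindamycin": CLINDAMYCIN_FIXED, "tretinoin": c})
            for c in TRETINOIN_LEVELS
        ]
    elif kind == "accuracy_panel":
        rows = []
        for c in ACCURACY_CLINDAMYCIN_LEVELS:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (
                        f"acc_clin_{c:g}_r{rep}",
                        {"clindamycin": c, "tretinoin": TRETINOIN_FIXED},
                    )
                )
        for c in ACCURACY_TRETINOIN_LEVELS:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (
                        f"acc_tret_{c:g}_r{rep}",
                        {"clindamycin": CLINDAMYCIN_FIXED, "tretinoin": c},
                    )
                )
    elif kind == "assay_sample":
        rows = [
            (
                "assay_gel_extract",
                {"clindamycin": ASSAY_CLINDAMYCIN, "tretinoin": ASSAY_TRETINOIN},
            )
        ]
    else:
        raise ValidationError(
            f"unknown design kind {kind!r}; expected one of {DESIGN_KINDS}"
        )
    return design_from_rows(rows)


def replicate_design(design: MixtureDesign, n_series: int) -> MixtureDesign:
    """Expand a design into ``n_series`` replicate series (pooled rows).

    Mirrors running several independent calibration series: each original
    row appears once per series under a ``_s<k>`` suffixed sample_id.
    """
    if n_series < 1:
        raise ValidationError("n_series must be >= 1")
    if n_series == 1:
        return design
    rows = []
    for k in range(1, n_series + 1):
        for sid in design.sample_ids:
            rows.append(
                (
                    f"{sid}_s{k}",
                    {a: design.concentration(sid, a) for a in design.analytes},
                )
            )
    return design_from_rows(rows)


def generate_spectrum_set(
    design: MixtureDesign,
    species: Mapping[str, SpeciesModel] | None = None,
    noise: NoiseModel = NO_NOISE,
    grid=None,
) -> SpectrumSet:
    """Generate one mixture spectrum per design row."""
    models = DEFAULT_SPECIES if species is None else dict(species)
    for analyte in design.analytes:
        if analyte not in models:
            raise ValidationError(f"no species model for analyte {analyte!r}")
    spectra = [
        mixture_spectrum(
            [(models[a], design.concentration(sid, a)) for a in design.analytes],
            noise=noise,
            grid=grid,
            sample_id=sid,
        )
        for sid in design.sample_ids
    ]
    return SpectrumSet(spectra, metadata={"noise": dataclasses.asdict(noise)})


# ---------------------------------------------------------------------------
# Config-file support (key/value YAML schema, see docs/methods.md)


def species_from_config(cfg: Mapping) -> dict[str, SpeciesModel]:
    """Build species models from a config mapping.

    Schema::

        species:
          <name>:
            description: <text>          # optional
            bands:
              - {center_nm: ..., width_nm: ..., absorptivity: ...}
    """
    out: dict[str, SpeciesModel] = {}
    for name, spec in cfg.items():
        bands = tuple(
            Band(
                center_nm=float(b["center_nm"]),
                width_nm=float(b["width_nm"]),
                absorptivity=float(b["absorptivity"]),
            )
            for b in spec["bands"]
        )
        out[str(name)] = SpeciesModel(
            name=str(name), bands=bands, description=str(spec.get("description", ""))
        )
    return out


def noise_from_config(cfg: Mapping, seed: int | None = None) -> NoiseModel:
    return NoiseModel(
        additive_sd=float(cfg.get("additive_sd", 0.0005)),
        multiplicative_sd=float(cfg.get("multiplicative_sd", 0.003)),
        baseline_drift=float(cfg.get("baseline_drift", 0.0)),
        seed=int(cfg.get("seed", 0) if seed is None else seed),
    )
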