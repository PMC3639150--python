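"""Containers and CSV I/O for UV-Vis absorbance spectra and mixture designs.

A :class:`Spectrum` is a zero-order absorbance curve A(lambda) sampled on a
strictly increasing, uniformly spaced wavelength grid (nm).  Uniform spacing
is a hard invariant because every derivative later computed from the spectrum
takes its difference interval as an integer number of grid steps.

CSV conventions: comma separator, '.' decimal, UTF-8; a header row is
auto-detected (first row non-numeric).  Single-spectrum files carry columns
``wavelength_nm, absorbance``; multi-spectrum ("long") files add a leading
``sample_id`` column; mixture-design files carry ``sample_id`` plus one
concentration column (ug/ml) per analyte.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GridError, ParseError, RangeError

#: relative tolerance for declaring a wavelength grid uniformly spaced
UNIFORM_RTOL = 1e-9


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise GridError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_uniform(wavelengths: np.ndarray) -> float:
    """Return the grid spacing, raising GridError if the grid is invalid."""
    if wavelengths.size < 2:
        raise GridError("a spectrum needs at least two grid points")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise GridError("wavelength grid must be strictly increasing")
    spacing = float(wavelengths[-1] - wavelengths[0]) / (wavelengths.size - 1)
    if np.max(np.abs(steps - spacing)) > UNIFORM_RTOL * max(abs(spacing), 1.0):
        raise GridError(
            "wavelength grid is not uniformly spaced within tolerance "
            f"(mean step {spacing:g} nm, max deviation {np.max(np.abs(steps - spacing)):g})"
        )
    return spacing


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """A zero-order absorbance spectrum on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing, uniformly spaced grid in nm.
    absorbance
        Absorbance (AU) at each grid point; must be finite.
    sample_id
        Free-text label carried through all operations.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths_nm, "wavelengths_nm")
        ab = _as_float_array(self.absorbance, "absorbance")
        if wl.size != ab.size:
            raise GridError(
                f"wavelengths ({wl.size}) and absorbance ({ab.size}) differ in length"
            )
        _check_uniform(wl)
        if not np.all(np.isfinite(ab)):
            raise ParseError("absorbance contains non-finite values")
        wl.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)

    @property
    def spacing_nm(self) -> float:
        wl = self.wavelengths_nm
        return float(wl[-1] - wl[0]) / (wl.size - 1)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def with_absorbance(self, absorbance, sample_id: str | None = None) -> "Spectrum":
        return Spectrum(
            self.wavelengths_nm.copy(),
            absorbance,
            self.sample_id if sample_id is None else sample_id,
        )

    def same_grid(self, other: "Spectrum") -> bool:
        a, b = self.wavelengths_nm, other.wavelengths_nm
        if a.size != b.size:
            return False
        tol = UNIFORM_RTOL * max(abs(self.spacing_nm), 1.0)
        return bool(np.max(np.abs(a - b)) <= tol)


@dataclasses.dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavelength grid."""

    spectra: list[Spectrum]
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        if self.spectra:
            first = self.spectra[0]
            for s in self.spectra[1:]:
                if not first.same_grid(s):
                    raise GridError(
                        f"spectrum {s.sample_id!r} is not on the shared grid"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, key: int | str) -> Spectrum:
        if isinstance(key, str):
            for s in self.spectra:
                if s.sample_id == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]


@dataclasses.dataclass
class MixtureDesign:
    """Samples x known analyte concentrations (ug/ml).

    Wraps a DataFrame indexed by unique ``sample_id`` with one float column
    per analyte; all concentrations must be >= 0.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise ParseError(f"duplicate sample_id(s) in design: {dupes}")
        df = df.astype(float)
        if (df.to_numpy() < 0).any():
            raise ParseError("negative concentration in mixture design")
        self.table = df

    @property
    def analytes(self) -> list[str]:
        return [str(c) for c in self.table.columns]

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    def concentration(self, sample_id: str, analyte: str) -> float:
        return float(self.table.at[sample_id, analyte])

    def concentrations(self, analyte: str) -> np.ndarray:
        return self.table[analyte].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv_autoheader(path, expected_cols: Sequence[str]) -> pd.DataFrame:
    """Read a CSV, detecting an optional header row by its first cell."""
    path = Path(path)
    try:
        probe = pd.read_csv(path, header=None, nrows=1, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc
    first_cell = str(probe.iat[0, 0]).strip()
    try:
        float(first_cell)
        has_header = False
    except ValueError:
        has_header = True
    df = pd.read_csv(path, header=0 if has_header else None, dtype=str)
    if df.shape[1] < len(expected_cols):
        raise ParseError(
            f"{path}: expected at least {len(expected_cols)} columns "
            f"({', '.join(expected_cols)}), found {df.shape[1]}"
        )
    if not has_header:
        df.columns = list(expected_cols) + [
            str(c) for c in df.columns[len(expected_cols):]
        ]
    return df


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row}"
        )
    if converted.isna().any():
        row = int(np.argmax(converted.isna().to_numpy()))
        raise ParseError(f"{path}: missing value in column {col!r} at data row {row}")
    # re-parse with Python's correctly-rounded float() so that full-precision
    # round-trips are exact to the last ulp (pandas' fast parser is not)
    return np.array([float(v) for v in df[col]], dtype=float)


def read_spectrum_csv(path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (wavelength_nm, absorbance) CSV as a Spectrum.

    Rows are sorted by wavelength; duplicate wavelengths are rejected.
    """
    df = _read_csv_autoheader(path, ["wavelength_nm", "absorbance"])
    cols = list(df.columns[:2])
    wl = _numeric_column(df, cols[0], path)
    ab = _numeric_column(df, cols[1], path)
    order = np.argsort(wl, kind="stable")
    wl, ab = wl[order], ab[order]
    if np.any(np.diff(wl) == 0):
        dup = wl[np.argmax(np.diff(wl) == 0)]
        raise ParseError(f"{path}: duplicated wavelength {dup:g} nm")
    sid = sample_id if sample_id is not None else Path(path).stem
    return Spectrum(wl, ab, sample_id=sid)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a Spectrum as a two-column CSV at full float precision."""
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths_nm, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False, float_format="%.17g")


def read_spectrum_set_csv(path) -> SpectrumSet:
    """Read a long CSV (sample_id, wavelength_nm, absorbance) as a SpectrumSet.

    Sample order follows first appearance in the file.
    """
    df = _read_csv_autoheader(path, ["sample_id", "wavelength_nm", "absorbance"])
    cols = list(df.columns[:3])
    sid = df[cols[0]].astype(str)
    wl = _numeric_column(df, cols[1], path)
    ab = _numeric_column(df, cols[2], path)
    spectra = []
    for sample in sid.drop_duplicates():
        mask = (sid == sample).to_numpy()
        w, a = wl[mask], ab[mask]
        order = np.argsort(w, kind="stable")
        w, a = w[order], a[order]
        if np.any(np.diff(w) == 0):
            raise ParseError(f"{path}: duplicated wavelength for sample {sample!r}")
        spectra.append(Spectrum(w, a, sample_id=str(sample)))
    return SpectrumSet(spectra)


def write_spectrum_set_csv(spectra: SpectrumSet | Iterable[Spectrum], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "wavelength_nm": s.wavelengths_nm,
                "absorbance": s.absorbance,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_design_csv(path) -> MixtureDesign:
    """Read a mixture-design CSV: sample_id, then one column per analyte."""
    df = _read_csv_autoheader(path, ["sample_id"])
    if df.shape[1] < 2:
        raise ParseError(f"{path}: design needs at least one analyte column")
    cols = list(df.columns)
    out = {"sample_id": df[cols[0]].astype(str)}
    for c in cols[1:]:
        out[str(c)] = _numeric_column(df, c, path)
    return MixtureDesign(pd.DataFrame(out))


def write_design_csv(design: MixtureDesign, path) -> None:
    design.table.to_csv(path, index=True, float_format="%.17g")


def design_from_rows(
    rows: Iterable[tuple[str, Mapping[str, float]]]
) -> MixtureDesign:
    """Build a MixtureDesign from (sample_id, {analyte: conc}) pairs."""
    records = []
    for sample_id, conc in rows:
        rec = {"sample_id": str(sample_id)}
        rec.update({str(k): float(v) for k, v in conc.items()})
        records.append(rec)
    return MixtureDesign(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# Spectrum arithmetic


def blank_subtract(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Pointwise absorbance difference sample - blank (matrix correction).

    Emulates measuring against a blank of the excipient matrix; grids must
    match exactly.
    """
    if not sample.same_grid(blank):
        raise GridError(
            f"blank grid does not match sample {sample.sample_id!r} grid"
        )
    return sample.with_absorbance(sample.absorbance - blank.absorbance)


def resample_to_grid(spectrum: Spectrum, new_grid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new uniform grid.

    The new grid must lie within the original wavelength range; extrapolation
    is refused.
    """
    new_wl = _as_float_array(new_grid, "new_grid")
    _check_uniform(new_wl)
    lo, hi = spectrum.wavelengths_nm[0], spectrum.wavelengths_nm[-1]
    if new_wl[0] < lo - 1e-12 or new_wl[-1] > hi + 1e-12:
        raise RangeError(
            f"requested grid [{new_wl[0]:g}, {new_wl[-1]:g}] nm extends beyond "
            f"spectrum range [{lo:g}, {hi:g}] nm"
        )
    ab = np.interp(new_wl, spectrum.wavelengths_nm, spectrum.absorbance)
    return Spectrum(new_wl, ab, sample_id=spectrum.sample_id)


def uniform_grid(start_nm: float, stop_nm: float, spacing_nm: float) -> np.ndarray:
    """Inclusive uniform wavelength grid from start to stop."""
    if spacing_nm <= 0:
        raise GridError("grid spacing must be positive")
    n = int(round((stop_nm - start_nm) / spacing_nm))
    if n < 1 or abs(start_nm + n * spacing_nm - stop_nm) > 1e-9:
        raise GridError(
            f"({start_nm}, {stop_nm}) is not an integer number of {spacing_nm} nm steps"
        )
    return start_nm + spacing_nm * np.arange(n + 1)
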