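"""Domain containers for single-cell Raman spectra.

A spectrum is intensity (arbitrary counts) sampled on a wavenumber grid in
cm⁻¹ covering the biological fingerprint region (600–1725 cm⁻¹).  Spectra
carry metadata identifying the cell, the donor specimen, the ICRS grade of
the cartilage the cell came from, and whether the trace is a cell
measurement or a matched PBS background.

Plain-text exchange formats are used throughout: one CSV file per spectrum
(``wavenumber_cm1,intensity``) plus a TSV manifest for a set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GRADES = ("I", "II", "III")

MANIFEST_COLUMNS = ["cell_id", "specimen_id", "grade", "kind", "filename"]


class SpectrumFormatError(ValueError):
    """Malformed spectrum file or inconsistent grid/intensity data."""


class GridCoverageError(ValueError):
    """A spectrum does not cover the requested wavenumber range."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniformly spaced, strictly increasing wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise SpectrumFormatError("grid needs at least two points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise SpectrumFormatError("wavenumbers must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9 * abs(d[0])):
            raise SpectrumFormatError("grid spacing must be uniform")

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0, atol=1e-9
        )

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points in the closed interval [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


def default_grid(lo: float = 600.0, hi: float = 1725.0, step: float = 1.0) -> WavenumberGrid:
    """The package's working grid: 600–1725 cm⁻¹ at 1 cm⁻¹ (1126 points)."""
    n = int(round((hi - lo) / step)) + 1
    return WavenumberGrid(lo + step * np.arange(n))


@dataclass(frozen=True)
class SpectrumMeta:
    cell_id: str = ""
    specimen_id: str = ""
    grade: str = "NA"  # one of I, II, III, NA
    kind: str = "cell"  # cell | background

    def __post_init__(self) -> None:
        if self.grade not in GRADES + ("NA",):
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.kind not in ("cell", "background"):
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass(frozen=True)
class Spectrum:
    """One intensity trace on a wavenumber grid, with provenance metadata."""

    grid: WavenumberGrid
    intensity: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", y)
        if y.shape != (len(self.grid),):
            raise SpectrumFormatError(
                f"intensity length {y.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(y)):
            raise SpectrumFormatError("intensities must be finite")

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, intensity, self.meta)


@dataclass
class SpectrumSet:
    """A stack of spectra sharing one grid, with a row-aligned manifest.

    The manifest row order is the acquisition order; segmented
    cross-validation depends on it, so operations preserve it.
    """

    grid: WavenumberGrid
    matrix: np.ndarray  # (n_spectra, n_points)
    manifest: pd.DataFrame  # columns cell_id, specimen_id, grade, kind

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.grid):
            raise SpectrumFormatError("matrix shape incompatible with grid")
        if len(self.manifest) != self.matrix.shape[0]:
            raise SpectrumFormatError("manifest row count != matrix row count")
        self.manifest = self.manifest.reset_index(drop=True)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        row = self.manifest.iloc[i]
        return Spectrum(
            self.grid,
            self.matrix[i],
            SpectrumMeta(
                cell_id=str(row["cell_id"]),
                specimen_id=str(row["specimen_id"]),
                grade=str(row["grade"]),
                kind=str(row["kind"]),
            ),
        )

    def spectra(self) -> Iterable[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    @property
    def grades(self) -> pd.Series:
        return self.manifest["grade"]

    def grade_counts(self) -> dict[str, int]:
        return self.grades.value_counts().to_dict()

    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        mask = np.asarray(mask)
        return SpectrumSet(
            self.grid, self.matrix[mask], self.manifest.loc[mask].reset_index(drop=True)
        )

    def with_matrix(self, matrix: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(self.grid, matrix, self.manifest.copy())


# ---------------------------------------------------------------------------
# readers / writers


def read_spectrum(path: str | Path, meta: SpectrumMeta | None = None) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text spectrum.

    Accepts an optional ``wavenumber_cm1,intensity`` header row and either
    comma or whitespace delimiters.  Wavenumbers must be sorted ascending.
    """
    path = Path(path)
    wn, inten = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if lineno == 1 and not _is_number(parts[0]):
                continue  # header
            if len(parts) != 2 or not all(_is_number(p) for p in parts):
                raise SpectrumFormatError(f"{path}:{lineno}: expected two numeric columns")
            wn.append(float(parts[0]))
            inten.append(float(parts[1]))
    if len(wn) < 2:
        raise SpectrumFormatError(f"{path}: fewer than two data rows")
    wn_arr = np.array(wn)
    if np.any(np.diff(wn_arr) <= 0):
        raise SpectrumFormatError(f"{path}: wavenumbers not strictly increasing")
    return Spectrum(WavenumberGrid(wn_arr), np.array(inten), meta or SpectrumMeta())


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_spectrum(s: Spectrum, path: str | Path, precision: int = 10) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("wavenumber_cm1,intensity\n")
        for x, y in zip(s.grid.values, s.intensity):
            fh.write(f"{x:.4f},{y:.{precision}e}\n")


def assemble_set(spectra: Sequence[Spectrum], target_grid: WavenumberGrid) -> SpectrumSet:
    """Stack spectra onto a common grid by linear interpolation.

    Input order is preserved (it encodes acquisition order).  A spectrum
    whose grid does not cover the whole target range raises
    :class:`GridCoverageError` — extrapolation is never attempted.
    """
    rows = []
    meta_rows = []
    for i, s in enumerate(spectra):
        if s.grid.lo > target_grid.lo + 1e-9 or s.grid.hi < target_grid.hi - 1e-9:
            raise GridCoverageError(
                f"spectrum {i} ({s.meta.cell_id!r}) covers [{s.grid.lo}, {s.grid.hi}], "
                f"target is [{target_grid.lo}, {target_grid.hi}]"
            )
        if s.grid == target_grid:
            rows.append(s.intensity)
        else:
            rows.append(np.interp(target_grid.values, s.grid.values, s.intensity))
        meta_rows.append(
            {
                "cell_id": s.meta.cell_id,
                "specimen_id": s.meta.specimen_id,
                "grade": s.meta.grade,
                "kind": s.meta.kind,
            }
        )
    matrix = np.vstack(rows) if rows else np.empty((0, len(target_grid)))
    manifest = pd.DataFrame(meta_rows, columns=MANIFEST_COLUMNS[:4])
    return SpectrumSet(target_grid, matrix, manifest)


def write_set(sset: SpectrumSet, out_dir: str | Path, precision: int = 10) -> Path:
    """Write one CSV per spectrum plus a TSV manifest; returns manifest path.

    Filenames are deterministic (row index + cell id) so round-trips are
    order-stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(len(sset)):
        s = sset[i]
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", s.meta.cell_id) or "spectrum"
        fname = f"{i:04d}_{safe}.csv"
        write_spectrum(s, out_dir / fname, precision=precision)
        records.append(
            {
                "cell_id": s.meta.cell_id,
                "specimen_id": s.meta.specimen_id,
                "grade": s.meta.grade,
                "kind": s.meta.kind,
                "filename": fname,
            }
        )
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_set(manifest_path: str | Path, target_grid: WavenumberGrid | None = None) -> SpectrumSet:
    """Read a manifest TSV and its referenced spectrum files back into a set."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    spectra = []
    for _, row in manifest.iterrows():
        meta = SpectrumMeta(
            cell_id=row["cell_id"],
            specimen_id=row["specimen_id"],
            grade=row["grade"] or "NA",
            kind=row["kind"] or "cell",
        )
        spectra.append(read_spectrum(base / row["filename"], meta))
    if target_grid is None:
        if not spectra:
            raise SpectrumFormatError("empty manifest and no target grid given")
        target_grid = spectra[0].grid
    return assemble_set(spectra, target_grid)
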