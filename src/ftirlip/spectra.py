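"""Containers and I/O for FTIR absorbance spectra with sample metadata.

A :class:`SpectrumSet` couples an absorbance matrix to a shared wavenumber
grid and per-sample metadata.  The grid is stored **descending** (4000 -> 500
cm^-1), matching spectrometer output, and all downstream selection is done by
wavenumber value, never by raw index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    EmptySelectionError,
    MetadataError,
    SpectraFormatError,
)

#: Marker stored in ``tech_rep`` after technical replicates are averaged.
AVERAGED = None

_META_COLUMNS = ("sample_id", "species", "temperature", "day", "bio_rep", "tech_rep")

#: Default pattern mapping a sample id such as ``Mc_20C_d03_b1_t2`` to metadata.
DEFAULT_ID_PATTERN = (
    r"(?P<species>.+)_(?P<temperature>-?\d+(?:\.\d+)?)C"
    r"_d(?P<day>\d+)_b(?P<bio_rep>\d+)(?:_t(?P<tech_rep>\d+))?$"
)


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one measured spectrum within the cultivation design."""

    sample_id: str
    species: str
    temperature: float
    day: int
    bio_rep: int
    tech_rep: Optional[int] = AVERAGED  # None == averaged over technical reps

    def __post_init__(self):
        if self.day < 1:
            raise MetadataError(f"{self.sample_id}: day must be >= 1, got {self.day}")
        if self.bio_rep < 1:
            raise MetadataError(f"{self.sample_id}: bio_rep must be >= 1")

    @property
    def key(self):
        return (self.species, self.temperature, self.day, self.bio_rep, self.tech_rep)

    @property
    def bio_key(self):
        """Key identifying the biological replicate (tech reps collapse)."""
        return (self.species, self.temperature, self.day, self.bio_rep)

    @property
    def condition_key(self):
        return (self.species, self.temperature, self.day)


@dataclass(frozen=True)
class WavenumberRegion:
    """Closed wavenumber interval [low, high] in cm^-1."""

    high: float
    low: float

    def __post_init__(self):
        if not self.high > self.low:
            raise ValueError(f"region requires high > low, got ({self.high}, {self.low})")

    def contains(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.low) & (wavenumbers <= self.high)


#: Combined range carrying the bands diagnostic for fungal biomass.
DEFAULT_REGIONS = (WavenumberRegion(3100.0, 2800.0), WavenumberRegion(1800.0, 500.0))


@dataclass
class SpectrumSet:
    """Absorbance matrix on a shared, strictly descending wavenumber grid."""

    wavenumbers: np.ndarray  # (n_wavenumbers,), cm^-1, strictly descending
    absorbance: np.ndarray  # (n_samples, n_wavenumbers)
    meta: list = field(default_factory=list)  # list[SampleMeta]

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise SpectraFormatError("wavenumbers must be a 1-D vector")
        diffs = np.diff(self.wavenumbers)
        if diffs.size and np.all(diffs > 0):  # ascending input: flip to descending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()
            diffs = np.diff(self.wavenumbers)
        if diffs.size and not np.all(diffs < 0):
            raise SpectraFormatError("wavenumber grid must be strictly monotone")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise SpectraFormatError(
                f"absorbance has {self.absorbance.shape[1]} columns for "
                f"{self.wavenumbers.size} wavenumbers"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("absorbance contains non-finite values")
        if len(self.meta) != self.absorbance.shape[0]:
            raise MetadataError(
                f"{len(self.meta)} metadata records for {self.absorbance.shape[0]} spectra"
            )
        keys = [m.key for m in self.meta]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise MetadataError(f"duplicate sample keys: {sorted(dupes)}")

    # -- conveniences -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "species": m.species,
                    "temperature": m.temperature,
                    "day": m.day,
                    "bio_rep": m.bio_rep,
                    "tech_rep": m.tech_rep,
                }
                for m in self.meta
            ],
            columns=list(_META_COLUMNS),
        )

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        indices = np.asarray(indices, dtype=int)
        return SpectrumSet(
            self.wavenumbers.copy(),
            self.absorbance[indices].copy(),
            [self.meta[i] for i in indices],
        )

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.wavenumbers.copy(), self.absorbance.copy(), list(self.meta)
        )


@dataclass(frozen=True)
class ReaderDialect:
    """How to interpret a spectra table.

    ``layout`` is ``"wide"`` (one row per sample, numeric wavenumber columns)
    or ``"long"`` (columns sample_id, wavenumber, absorbance).  When no
    metadata columns are present, ``id_pattern`` (a regex with named groups
    species/temperature/day/bio_rep/tech_rep) is applied to sample ids.
    """

    layout: str = "wide"
    id_pattern: str = DEFAULT_ID_PATTERN
    delimiter: str = ","


def _meta_from_id(sample_id: str, pattern: str) -> SampleMeta:
    m = re.match(pattern, sample_id)
    if m is None:
        raise MetadataError(
            f"sample id {sample_id!r} does not match the metadata pattern {pattern!r}"
        )
    g = m.groupdict()
    tech = g.get("tech_rep")
    return SampleMeta(
        sample_id=sample_id,
        species=g["species"],
        temperature=float(g["temperature"]),
        day=int(g["day"]),
        bio_rep=int(g["bio_rep"]),
        tech_rep=int(tech) if tech is not None else AVERAGED,
    )


def _meta_from_row(row: pd.Series) -> SampleMeta:
    tech = row.get("tech_rep")
    if tech is None or (isinstance(tech, float) and np.isnan(tech)) or tech == "":
        tech = AVERAGED
    else:
        tech = int(tech)
    return SampleMeta(
        sample_id=str(row["sample_id"]),
        species=str(row["species"]),
        temperature=float(row["temperature"]),
        day=int(row["day"]),
        bio_rep=int(row["bio_rep"]),
        tech_rep=tech,
    )


def read_spectra_table(
    source: Union[str, Path],
    dialect: ReaderDialect = ReaderDialect(),
    metadata: Optional[Union[str, Path, pd.DataFrame]] = None,
) -> SpectrumSet:
    """Read a CSV/TSV spectra table into a :class:`SpectrumSet`.

    Wide layout: first column ``sample_id``, optional metadata columns
    (species, temperature, day, bio_rep, tech_rep), then one numeric-headed
    column per wavenumber.  Long layout: columns sample_id / wavenumber /
    absorbance plus an optional sidecar ``metadata`` table keyed by
    sample_id.  Ascending grids are flipped to the descending convention.
    """
    try:
        df = pd.read_csv(source, sep=dialect.delimiter)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraFormatError(f"could not parse {source}: {exc}") from exc

    if dialect.layout == "long":
        needed = {"sample_id", "wavenumber", "absorbance"}
        if not needed.issubset(df.columns):
            raise SpectraFormatError(
                f"long layout requires columns {sorted(needed)}, got {list(df.columns)}"
            )
        wide = df.pivot(index="sample_id", columns="wavenumber", values="absorbance")
        if wide.isna().any().any():
            raise SpectraFormatError("long table does not cover a complete grid")
        df = wide.reset_index()
        df.columns = [str(c) for c in df.columns]

    if df.columns[0] != "sample_id":
        raise SpectraFormatError("first column must be 'sample_id'")

    meta_cols = [c for c in _META_COLUMNS[1:] if c in df.columns]
    spec_cols = [c for c in df.columns if c == "sample_id" or c in meta_cols]
    wn_cols = [c for c in df.columns if c not in spec_cols]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(
            f"non-numeric wavenumber column header among {wn_cols[:5]}..."
        ) from exc
    if wavenumbers.size == 0:
        raise SpectraFormatError("no wavenumber columns found")

    values = df[wn_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise SpectraFormatError(f"{source}: missing absorbance values (ragged rows?)")

    meta_source = None
    if metadata is not None:
        meta_df = (
            metadata
            if isinstance(metadata, pd.DataFrame)
            else pd.read_csv(metadata, sep=dialect.delimiter)
        )
        meta_df = meta_df.set_index("sample_id", drop=False)
        meta_source = meta_df
    elif len(meta_cols) >= 4:
        meta_source = df.set_index("sample_id", drop=False)

    meta = []
    for sid in df["sample_id"].astype(str):
        if meta_source is not None:
            if sid not in meta_source.index:
                raise MetadataError(f"sample id {sid!r} missing from metadata table")
            meta.append(_meta_from_row(meta_source.loc[sid]))
        else:
            meta.append(_meta_from_id(sid, dialect.id_pattern))

    return SpectrumSet(wavenumbers, values, meta)


def write_spectra_table(s: SpectrumSet, dest: Union[str, Path]) -> None:
    """Write a wide CSV with embedded metadata columns.

    Round-trips through :func:`read_spectra_table` to better than 1e-12
    relative precision (17 significant digits are written).
    """
    mf = s.meta_frame()
    spec = pd.DataFrame(
        s.absorbance, columns=[np.format_float_positional(w, trim="-") for w in s.wavenumbers]
    )
    out = pd.concat([mf.reset_index(drop=True), spec], axis=1)
    out.to_csv(dest, index=False, float_format="%.17g")


def read_jcampdx(source: Union[str, Path]) -> SpectrumSet:
    """Minimal JCAMP-DX importer for a single spectrum.

    Supports the uncompressed ``XYDATA=(X++(Y..Y))`` form with AFFN numbers
    and honours XFACTOR/YFACTOR/FIRSTX/LASTX/NPOINTS.  Convenience only; use
    the CSV readers for batch data.
    """
    text = Path(source).read_text()
    fields: dict = {}
    data_lines: list = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("$$"):
            continue
        if line.upper().startswith("##XYDATA"):
            in_data = True
            continue
        if line.startswith("##"):
            in_data = False
            key, _, val = line[2:].partition("=")
            fields[key.strip().upper()] = val.strip()
            continue
        if in_data:
            data_lines.append(line)
    if not data_lines:
        raise SpectraFormatError(f"{source}: no XYDATA block found")

    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    xs, ys = [], []
    for line in data_lines:
        parts = line.replace(",", " ").split()
        x0 = float(parts[0]) * xfactor
        yvals = [float(p) * yfactor for p in parts[1:]]
        xs.append((x0, len(yvals)))
        ys.extend(yvals)
    npoints = int(fields.get("NPOINTS", len(ys)))
    if npoints != len(ys):
        raise SpectraFormatError(
            f"{source}: NPOINTS={npoints} but {len(ys)} ordinates read"
        )
    firstx = float(fields.get("FIRSTX", xs[0][0]))
    lastx = float(fields.get("LASTX", xs[-1][0]))
    grid = np.linspace(firstx, lastx, npoints)
    title = fields.get("TITLE", Path(source).stem)
    meta = [SampleMeta(sample_id=title, species="unknown", temperature=0.0, day=1, bio_rep=1)]
    return SpectrumSet(grid, np.asarray(ys)[None, :], meta)


def select_region(
    s: SpectrumSet, regions: Iterable[WavenumberRegion]
) -> SpectrumSet:
    """Restrict the grid to the union of closed regions (bounds inclusive).

    Regions must be non-overlapping.  Point order (descending) is preserved,
    so concatenated regions remain globally descending; metadata unchanged.
    """
    regions = sorted(regions, key=lambda r: -r.high)
    for a, b in zip(regions, regions[1:]):
        if b.high >= a.low:
            raise ValueError(f"regions overlap: {a} and {b}")
    mask = np.zeros(s.n_wavenumbers, dtype=bool)
    for r in regions:
        inside = r.contains(s.wavenumbers)
        if not inside.any():
            raise EmptySelectionError(
                f"region [{r.low}, {r.high}] cm^-1 selects no grid points "
                f"(grid spans {s.wavenumbers.min():g}-{s.wavenumbers.max():g})"
            )
        mask |= inside
    return SpectrumSet(
        s.wavenumbers[mask].copy(), s.absorbance[:, mask].copy(), list(s.meta)
    )


def average_technical_replicates(s: SpectrumSet) -> SpectrumSet:
    """Average spectra over technical replicates.

    One output row per (species, temperature, day, bio_rep) group, the
    arithmetic mean of member rows; ``tech_rep`` is marked averaged.  Rows
    already averaged (tech_rep is None) pass through as singleton groups.
    Output order is sorted by group key, independent of input row order.
    """
    groups: dict = {}
    for i, m in enumerate(s.meta):
        groups.setdefault(m.bio_key, []).append(i)
    keys = sorted(groups)
    rows = np.empty((len(keys), s.n_wavenumbers))
    meta = []
    for j, key in enumerate(keys):
        idx = groups[key]
        rows[j] = s.absorbance[idx].mean(axis=0)
        species, temperature, day, bio_rep = key
        temp_str = np.format_float_positional(temperature, trim="-")
        meta.append(
            SampleMeta(
                sample_id=f"{species}_{temp_str}C_d{day:02d}_b{bio_rep}",
                species=species,
                temperature=temperature,
                day=day,
                bio_rep=bio_rep,
                tech_rep=AVERAGED,
            )
        )
    return SpectrumSet(s.wavenumbers.copy(), rows, meta)
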