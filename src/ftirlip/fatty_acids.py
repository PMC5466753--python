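"""GC-FID fatty-acid reference data: FAME quantification and derived
parameters.

Fatty acid methyl esters (FAMEs) measured by GC-FID are quantified against a
C13:0 internal standard with relative response factors:

    mass_i = (area_i / area_IS) * RRF_i * mass_IS

Composition is each mass as % of total FAME mass; total lipid is total FAME
mass as % of cell dry weight.  Derived parameters: SAT/MUFA/PUFA sums and
the unsaturation index

    UI = [sum(% monoene) + 2 * sum(% diene) + 3 * sum(% triene)] / 100,

the average number of double bonds per fatty-acyl chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import CatalogueError, FtirlipError

KEY_COLUMNS = ("species", "temperature", "day")


@dataclass(frozen=True)
class FattyAcidDescriptor:
    id: str
    chain_length: int
    n_double_bonds: int
    omega_class: str = "none"  # n3 | n6 | n9 | none

    def __post_init__(self):
        if self.n_double_bonds < 0:
            raise ValueError("n_double_bonds must be >= 0")


def _catalogue(*descs: FattyAcidDescriptor) -> Dict[str, FattyAcidDescriptor]:
    return {d.id: d for d in descs}


#: Acids seen in oleaginous Mucoromycota / Penicillium screening work.
DEFAULT_CATALOGUE: Dict[str, FattyAcidDescriptor] = _catalogue(
    FattyAcidDescriptor("C12:0", 12, 0),
    FattyAcidDescriptor("C13:0", 13, 0),
    FattyAcidDescriptor("C14:0", 14, 0),
    FattyAcidDescriptor("C15:0", 15, 0),
    FattyAcidDescriptor("C16:0", 16, 0),
    FattyAcidDescriptor("C16:1", 16, 1),
    FattyAcidDescriptor("C17:0", 17, 0),
    FattyAcidDescriptor("C18:0", 18, 0),
    FattyAcidDescriptor("C18:1n9", 18, 1, "n9"),
    FattyAcidDescriptor("C18:2n6", 18, 2, "n6"),
    FattyAcidDescriptor("C18:3n6", 18, 3, "n6"),
    FattyAcidDescriptor("C18:3n3", 18, 3, "n3"),
    FattyAcidDescriptor("C20:0", 20, 0),
    FattyAcidDescriptor("C20:4n6", 20, 4, "n6"),
    FattyAcidDescriptor("C22:0", 22, 0),
    FattyAcidDescriptor("C24:0", 24, 0),
)

#: Sum tolerance (percentage points) for ingested compositions; published
#: tables round minor acids.
SUM_TOLERANCE = 0.5


@dataclass
class FattyAcidTable:
    """Per-sample fatty-acid composition (% of total fatty acids) plus total
    lipid (% of cell dry weight), keyed by (species, temperature, day)."""

    data: pd.DataFrame  # columns: species, temperature, day, <acids...>, total_lipid

    def __post_init__(self):
        missing = [c for c in KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise FtirlipError(f"fatty-acid table missing key columns {missing}")
        if "total_lipid" not in self.data.columns:
            raise FtirlipError("fatty-acid table missing 'total_lipid' column")
        # normalize key dtypes so CSV round-trips are stable
        self.data = self.data.assign(
            temperature=self.data["temperature"].astype(float),
            day=self.data["day"].astype(int),
        )
        comp = self.composition()
        if (comp.to_numpy() < -1e-12).any():
            raise FtirlipError("negative composition values")
        tl = self.data["total_lipid"].to_numpy(float)
        if ((tl < 0) | (tl > 100)).any():
            raise FtirlipError("total_lipid outside [0, 100] % of CDW")
        sums = comp.sum(axis=1).to_numpy()
        off = np.abs(sums - 100.0) > SUM_TOLERANCE
        if off.any():
            raise FtirlipError(
                f"{off.sum()} sample(s) with composition sum outside "
                f"100 +/- {SUM_TOLERANCE} (worst: {sums[off][0]:.3f})"
            )

    @property
    def acid_columns(self) -> List[str]:
        return [
            c
            for c in self.data.columns
            if c not in KEY_COLUMNS and c not in ("total_lipid", "sample_id", "bio_rep")
        ]

    def composition(self) -> pd.DataFrame:
        return self.data[self.acid_columns].astype(float)

    def renormalized(self) -> "FattyAcidTable":
        """Rescale each composition row to sum exactly 100."""
        out = self.data.copy()
        comp = self.composition()
        out[self.acid_columns] = 100.0 * comp.div(comp.sum(axis=1), axis=0)
        return FattyAcidTable(out)

    def to_csv(self, dest: Union[str, Path]) -> None:
        self.data.to_csv(dest, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, source: Union[str, Path], layout: str = "wide") -> "FattyAcidTable":
        df = pd.read_csv(source)
        if layout == "long":
            keys = [c for c in df.columns if c in KEY_COLUMNS or c == "total_lipid"]
            df = (
                df.pivot_table(
                    index=[c for c in keys],
                    columns="fatty_acid",
                    values="composition",
                )
                .reset_index()
            )
            df.columns.name = None
        return cls(df)


@dataclass
class FAMEQuantInput:
    """Raw GC peak areas with internal-standard bookkeeping for one batch."""

    areas: pd.DataFrame  # one row per sample, columns = fatty acid ids
    is_area: np.ndarray  # internal-standard (C13:0) peak area per sample
    is_mass_mg: float  # internal-standard mass added, mg
    rrf: Mapping[str, float]  # relative response factor per fatty acid
    biomass_mg: np.ndarray  # dry biomass per sample, mg
    keys: Optional[pd.DataFrame] = None  # species/temperature/day per sample

    def __post_init__(self):
        self.is_area = np.asarray(self.is_area, float)
        self.biomass_mg = np.asarray(self.biomass_mg, float)
        if (self.areas.to_numpy(float) < 0).any():
            raise FtirlipError("negative peak areas")
        if (self.is_area <= 0).any():
            raise FtirlipError("internal-standard area must be > 0")
        if (self.biomass_mg <= 0).any():
            raise FtirlipError("biomass mass must be > 0")
        missing = [c for c in self.areas.columns if c not in self.rrf]
        if missing:
            raise FtirlipError(f"no RRF supplied for {missing}")


def quantify_fames(q: FAMEQuantInput) -> FattyAcidTable:
    """Internal-standard quantification of FAME peak areas.

    mass_i = (area_i / area_IS) * RRF_i * mass_IS; composition is mass as a
    percentage of total FAME mass, total lipid the FAME-mass sum as a
    percentage of dry biomass.
    """
    acids = list(q.areas.columns)
    rrf = np.array([q.rrf[a] for a in acids], float)
    masses = q.areas.to_numpy(float) / q.is_area[:, None] * rrf[None, :] * q.is_mass_mg
    total = masses.sum(axis=1)
    if (total <= 0).any():
        raise FtirlipError("sample with zero total FAME mass (all areas zero?)")
    comp = 100.0 * masses / total[:, None]
    total_lipid = 100.0 * total / q.biomass_mg
    out = pd.DataFrame(comp, columns=acids)
    if q.keys is not None:
        out = pd.concat([q.keys.reset_index(drop=True), out], axis=1)
    else:
        out.insert(0, "species", "unknown")
        out.insert(1, "temperature", np.nan)
        out.insert(2, "day", 1)
    out["total_lipid"] = np.clip(total_lipid, 0.0, 100.0)
    return FattyAcidTable(out)


def _lookup(acid: str, catalogue: Mapping[str, FattyAcidDescriptor]) -> FattyAcidDescriptor:
    try:
        return catalogue[acid]
    except KeyError:
        raise CatalogueError(
            f"fatty acid {acid!r} has no descriptor; extend the catalogue"
        ) from None


def unsaturation_index(
    composition: Mapping[str, float],
    catalogue: Mapping[str, FattyAcidDescriptor] = DEFAULT_CATALOGUE,
) -> float:
    """Average double bonds per chain: sum of % times double-bond count, /100."""
    total = 0.0
    for acid, pct in composition.items():
        if pct < 0:
            raise FtirlipError(f"negative composition for {acid}")
        total += pct * _lookup(acid, catalogue).n_double_bonds
    return total / 100.0


def summed_parameters(
    t: FattyAcidTable,
    catalogue: Mapping[str, FattyAcidDescriptor] = DEFAULT_CATALOGUE,
) -> pd.DataFrame:
    """Per-sample SAT / MUFA / PUFA sums, unsaturation index and total lipid.

    SAT sums acids with no double bond, MUFA exactly one, PUFA two or more;
    the three always add up to the total composition sum.
    """
    comp = t.composition()
    db = np.array([_lookup(a, catalogue).n_double_bonds for a in comp.columns])
    values = comp.to_numpy(float)
    out = pd.DataFrame(
        {
            "SAT": values[:, db == 0].sum(axis=1),
            "MUFA": values[:, db == 1].sum(axis=1),
            "PUFA": values[:, db >= 2].sum(axis=1),
            "unsaturation_index": values @ db / 100.0,
            "total_lipid": t.data["total_lipid"].to_numpy(float),
        },
        index=t.data.index,
    )
    return out


def autoscale(matrix: Union[np.ndarray, pd.DataFrame]):
    """Center each column to mean 0 and scale to unit SD (n-1 denominator).

    Returns (scaled, means, sds) so the transform is invertible.  A
    zero-variance column is an error naming the column.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = list(matrix.columns)
        X = matrix.to_numpy(float)
    else:
        X = np.asarray(matrix, float)
        cols = [str(i) for i in range(X.shape[1])]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise FtirlipError(f"zero-variance column(s): {[cols[i] for i in dead]}")
    scaled = (X - means) / sds
    if isinstance(matrix, pd.DataFrame):
        scaled = pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
    return scaled, means, sds


def pooled_sd(groups: Iterable[Sequence[float]]) -> float:
    """Pooled standard deviation over replicate groups.

    sqrt( sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1) ) with per-group sample SD
    s_i; every group must have at least two members.
    """
    num = 0.0
    den = 0
    n_groups = 0
    for g in groups:
        v = np.asarray(list(g), float)
        if v.size < 2:
            raise FtirlipError("pooled SD requires every group size >= 2")
        num += (v.size - 1) * v.std(ddof=1) ** 2
        den += v.size - 1
        n_groups += 1
    if n_groups == 0:
        raise FtirlipError("pooled SD of zero groups is undefined")
    return float(np.sqrt(num / den))
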