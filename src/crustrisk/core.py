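"""Core domain types, table I/O, validation, and nondetect substitution.

The interchange format is a long-format CSV with one row per
(sample, congener) cell and an explicit detect flag, because wide
tables cannot carry left-censoring information. Concentrations are
ug/kg wet weight throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import datasets

logger = logging.getLogger(__name__)

SPECIES = ("freshwater_shrimp", "marine_prawn", "marine_crab")
CONGENER_CLASSES = ("chlorinated", "alkyl", "aryl", "brominated")
SUBSTITUTION_POLICIES = ("zero", "half_lod", "lod")

LONG_COLUMNS = [
    "sample_id", "species", "region", "month", "year",
    "congener", "concentration", "detected",
]


class CrustRiskError(Exception):
    """Base class for package errors."""


class SchemaError(CrustRiskError):
    """A file does not conform to the documented schema."""


class ValidationError(CrustRiskError):
    """In-memory data violates an invariant."""


class ConfigurationError(CrustRiskError):
    """An invalid configuration or policy was requested."""


class DegenerateInputError(CrustRiskError):
    """Input is degenerate for the requested statistic (e.g. constant)."""


@dataclass(frozen=True)
class CongenerRecord:
    """One OPE congener: identity, chemical class, toxicity and detection limit.

    rfd is the oral reference dose in ug/kg bw/day (absent for the 12
    congeners without a published value); lod is the method detection
    limit in ug/kg ww.
    """

    abbrev: str
    full_name: str
    cls: str
    rfd: float | None = None
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.cls not in CONGENER_CLASSES:
            raise ValidationError(
                f"{self.abbrev}: class {self.cls!r} not in {CONGENER_CLASSES}")
        if self.rfd is not None and not self.rfd > 0:
            raise ValidationError(f"{self.abbrev}: rfd must be > 0, got {self.rfd}")
        if self.lod is not None and self.lod < 0:
            raise ValidationError(f"{self.abbrev}: lod must be >= 0, got {self.lod}")


@dataclass(frozen=True)
class CongenerCatalog:
    """Ordered collection of congeners; order defines the canonical row order."""

    records: tuple[CongenerRecord, ...]

    def __post_init__(self) -> None:
        abbrevs = [r.abbrev for r in self.records]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValidationError(f"duplicate congener abbrevs in catalog: {dupes}")

    @property
    def abbrevs(self) -> tuple[str, ...]:
        return tuple(r.abbrev for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.abbrevs

    def __getitem__(self, abbrev: str) -> CongenerRecord:
        for r in self.records:
            if r.abbrev == abbrev:
                return r
        raise KeyError(abbrev)

    def __iter__(self) -> Iterator[CongenerRecord]:
        return iter(self.records)

    def classes(self) -> dict[str, str]:
        """Mapping abbrev -> chemical class."""
        return {r.abbrev: r.cls for r in self.records}

    def rfds(self) -> dict[str, float]:
        """Mapping abbrev -> RfD, restricted to congeners that have one."""
        return {r.abbrev: r.rfd for r in self.records if r.rfd is not None}

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "abbrev": [r.abbrev for r in self.records],
                "full_name": [r.full_name for r in self.records],
                "class": [r.cls for r in self.records],
                "rfd": [r.rfd for r in self.records],
                "lod": [r.lod for r in self.records],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CongenerCatalog":
        df = pd.read_csv(path)
        required = {"abbrev", "full_name", "class", "rfd", "lod"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"catalog file {path}: missing columns {sorted(required - set(df.columns))}")
        records = tuple(
            CongenerRecord(
                abbrev=str(row["abbrev"]),
                full_name=str(row["full_name"]),
                cls=str(row["class"]),
                rfd=None if pd.isna(row["rfd"]) else float(row["rfd"]),
                lod=None if pd.isna(row["lod"]) else float(row["lod"]),
            )
            for _, row in df.iterrows()
        )
        return cls(records)


def default_catalog() -> CongenerCatalog:
    """The 22-congener survey catalog with classes, RfDs and default LODs."""
    records = tuple(
        CongenerRecord(
            abbrev=abbrev,
            full_name=full_name,
            cls=cls,
            rfd=datasets.RFD.get(abbrev),
            lod=datasets.LOD[abbrev],
        )
        for abbrev, (full_name, cls) in datasets.CONGENERS.items()
    )
    return CongenerCatalog(records)


@dataclass(frozen=True)
class SampleRecord:
    """One crustacean sample with its full congener measurement vector."""

    sample_id: str
    species: str
    region: str
    month: int
    year: int
    values: Mapping[str, tuple[float, bool]]  # abbrev -> (concentration, detected)


@dataclass
class ConcentrationTable:
    """Per-sample, per-congener concentrations with censoring flags.

    Internally a long-format DataFrame with columns
    sample_id, species, region, month, year, congener, concentration,
    detected — one row per (sample, congener), every catalog congener
    present exactly once per sample.
    """

    data: pd.DataFrame
    catalog: CongenerCatalog

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"table missing columns {missing}")
        unknown = set(df["congener"]) - set(self.catalog.abbrevs)
        if unknown:
            raise SchemaError(f"unknown congeners not in catalog: {sorted(unknown)}")
        bad_species = set(df["species"]) - set(SPECIES)
        if bad_species:
            raise ValidationError(f"unknown species: {sorted(bad_species)}")
        if len(df) and ((df["month"] < 1) | (df["month"] > 12)).any():
            raise ValidationError("month outside 1..12")
        if len(df) and (df["concentration"] < 0).any():
            bad = df.loc[df["concentration"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative concentration for sample {bad!r}")
        if df.duplicated(["sample_id", "congener"]).any():
            dupe = df[df.duplicated(["sample_id", "congener"])].iloc[0]
            raise ValidationError(
                f"duplicate cell ({dupe['sample_id']!r}, {dupe['congener']!r})")
        counts = df.groupby("sample_id", sort=False)["congener"].count()
        if len(counts) and (counts != len(self.catalog)).any():
            bad = counts.index[counts != len(self.catalog)][0]
            raise ValidationError(
                f"sample {bad!r} has {counts[bad]} congener rows, "
                f"expected {len(self.catalog)}")

    @property
    def n_samples(self) -> int:
        return self.data["sample_id"].nunique()

    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def to_wide(self) -> pd.DataFrame:
        """Samples x congeners concentration matrix (catalog column order)."""
        wide = self.data.pivot(index="sample_id", columns="congener",
                               values="concentration")
        return wide.reindex(columns=list(self.catalog.abbrevs)).sort_index()

    def detected_wide(self) -> pd.DataFrame:
        wide = self.data.pivot(index="sample_id", columns="congener",
                               values="detected")
        return wide.reindex(columns=list(self.catalog.abbrevs)).sort_index().astype(bool)

    def sample_meta(self) -> pd.DataFrame:
        """One row per sample: species, region, month, year (sample_id index)."""
        meta = self.data.drop_duplicates("sample_id").set_index("sample_id")
        return meta[["species", "region", "month", "year"]].sort_index()

    def sum_opes(self) -> pd.Series:
        """Per-sample Sigma-OPEs: plain sum of all congener concentrations."""
        return self.to_wide().sum(axis=1).rename("sum_opes")

    def samples(self) -> Iterator[SampleRecord]:
        for sid, grp in self.data.groupby("sample_id", sort=True):
            first = grp.iloc[0]
            values = {
                row.congener: (float(row.concentration), bool(row.detected))
                for row in grp.itertuples()
            }
            yield SampleRecord(
                sample_id=str(sid), species=first["species"], region=first["region"],
                month=int(first["month"]), year=int(first["year"]), values=values)

    @classmethod
    def from_records(cls, records: Iterable[SampleRecord],
                     catalog: CongenerCatalog) -> "ConcentrationTable":
        rows = []
        for rec in records:
            for abbrev in catalog.abbrevs:
                conc, det = rec.values[abbrev]
                rows.append((rec.sample_id, rec.species, rec.region, rec.month,
                             rec.year, abbrev, conc, det))
        df = pd.DataFrame(rows, columns=LONG_COLUMNS)
        return cls(df, catalog)


def load_concentration_table(path: str | Path, catalog: CongenerCatalog,
                             fill_missing: bool = False) -> ConcentrationTable:
    """Read a long-format concentration CSV.

    Samples missing rows for some catalog congeners are rejected unless
    ``fill_missing`` is set, in which case the absent cells are filled
    as nondetects (concentration 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "region": str})
    if list(df.columns) != LONG_COLUMNS:
        raise SchemaError(
            f"{path}: header {list(df.columns)} does not match {LONG_COLUMNS}")
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        if pd.isna(row.concentration) or pd.isna(row.month) or pd.isna(row.year):
            raise SchemaError(f"{path}: malformed row at line {i}")
    df["month"] = df["month"].astype(int)
    df["year"] = df["year"].astype(int)
    df["concentration"] = df["concentration"].astype(float)
    df["detected"] = df["detected"].astype(int).astype(bool)

    if fill_missing:
        meta = df.drop_duplicates("sample_id")
        have = df.groupby("sample_id")["congener"].apply(set)
        extra = []
        for m in meta.itertuples():
            for abbrev in set(catalog.abbrevs) - have[m.sample_id]:
                extra.append((m.sample_id, m.species, m.region, m.month, m.year,
                              abbrev, 0.0, False))
        if extra:
            df = pd.concat(
                [df, pd.DataFrame(extra, columns=LONG_COLUMNS)], ignore_index=True)
    return ConcentrationTable(df, catalog)


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> None:
    """Write the long-format CSV, rows ordered by sample_id then catalog order."""
    order = {a: i for i, a in enumerate(table.catalog.abbrevs)}
    df = table.data.copy()
    df["_corder"] = df["congener"].map(order)
    df = df.sort_values(["sample_id", "_corder"], kind="mergesort")
    df = df.drop(columns="_corder")
    df["detected"] = df["detected"].astype(int)
    df.to_csv(path, index=False)


def write_wide_table(table: ConcentrationTable, path: str | Path) -> None:
    """Convenience wide export (loses the detect flags)."""
    table.to_wide().to_csv(path)


def substitute_nondetects(table: ConcentrationTable,
                          policy: str = "zero") -> ConcentrationTable:
    """Replace nondetect concentrations by 0, LOD/2 or LOD.

    Detected values are never altered. The survey's own convention is
    substitution by 0; LOD-based policies require an LOD for every
    congener that has at least one nondetect.
    """
    if policy not in SUBSTITUTION_POLICIES:
        raise ConfigurationError(
            f"policy {policy!r} not in {SUBSTITUTION_POLICIES}")
    df = table.data.copy()
    nd = ~df["detected"].to_numpy(dtype=bool)
    if policy == "zero":
        sub = np.zeros(len(df))
    else:
        lods = {r.abbrev: r.lod for r in table.catalog}
        affected = sorted(set(df.loc[nd, "congener"]))
        missing = [a for a in affected if lods.get(a) is None]
        if missing:
            raise ConfigurationError(
                f"policy {policy!r} needs an LOD for: {missing}")
        factor = 0.5 if policy == "half_lod" else 1.0
        sub = df["congener"].map({a: (lods[a] or 0.0) * factor
                                  for a in set(df["congener"])}).to_numpy(float)
    conc = df["concentration"].to_numpy(float).copy()
    conc[nd] = sub[nd]
    df["concentration"] = conc
    return ConcentrationTable(df, table.catalog)
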