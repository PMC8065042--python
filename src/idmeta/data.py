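"""Reading, validation and filtering of the two tabular inputs.

Two tables drive the analysis:

* an inbreeding-depression (ID) table — one row per published effect size
  with its standard error, species, study, life stage (1-4), inbreeding
  coefficient F and, optionally, a connectivity group code; and
* an Fst table — one row per published Fst estimate with the marker type
  used to obtain it (Table 1 of the source compilation is bundled with the
  package as ``fixtures/table1_fst.csv``).

Both are comma-separated UTF-8 with a header row and decimal points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("idmeta")

__all__ = [
    "IDRecord",
    "FstRecord",
    "SchemaError",
    "ValidationError",
    "F_LEVELS",
    "LIFE_STAGES",
    "MARKER_VOCAB",
    "CODOMINANT_NUCLEAR",
    "load_id_table",
    "write_id_table",
    "id_records_to_frame",
    "dedupe_lowest_se",
    "load_fst_table",
    "write_fst_table",
    "fst_records_to_frame",
    "filter_fst_markers",
    "load_table1_fixture",
    "table1_fixture_path",
]

#: Inbreeding coefficients realisable by the four crossing designs
#: (half-sib, full-sib, one and two generations of selfing).
F_LEVELS = (0.125, 0.25, 0.5, 0.75)

#: Life-stage codes: 1 embryonic, 2 juvenile vegetative, 3 adult
#: vegetative, 4 adult reproductive.
LIFE_STAGES = (1, 2, 3, 4)

#: Controlled vocabulary for Fst marker types.
MARKER_VOCAB = frozenset(
    {"SNP", "ncSSR", "Isozyme/Allozyme", "EST-SSR", "cpSSR", "AFLP", "RAPD", "other"}
)

#: Marker types retained for the connectivity regression: codominant markers
#: based on nuclear DNA.  EST-SSRs are nuclear SSRs and are kept; cpSSRs are
#: organellar and dropped, as are dominant marker systems (AFLP, RAPD).
CODOMINANT_NUCLEAR = frozenset({"SNP", "ncSSR", "EST-SSR", "Isozyme/Allozyme"})


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a record invariant."""


@dataclass(frozen=True)
class IDRecord:
    """One inbreeding-depression effect size.

    ``id_value`` is the dimensionless depression delta = 1 - w_self/w_out
    (positive when inbred progeny do worse; at most 1, may be negative for
    outbreeding depression), ``se`` its standard error.
    """

    id_value: float
    se: float
    species: str
    study: str
    life_stage: int
    f_coef: float
    connectivity: int | None = None
    trait_label: str | None = None
    age_years: float | None = None
    n_families: int | None = None

    def validate(self, row: int | None = None) -> "IDRecord":
        where = "" if row is None else f" (row {row})"
        if not np.isfinite(self.id_value):
            raise ValidationError(f"id_value must be finite{where}: {self.id_value}")
        if self.id_value > 1.0:
            # a fitness ratio bounds ID at 1; flag but accept (model draws
            # and digitized estimates can exceed it)
            warnings.warn(f"id_value above 1{where}: {self.id_value}", stacklevel=2)
        if not (self.se > 0):
            raise ValidationError(f"se must be > 0{where}: {self.se}")
        if self.life_stage not in LIFE_STAGES:
            raise ValidationError(f"life_stage must be in {LIFE_STAGES}{where}: {self.life_stage}")
        if not any(np.isclose(self.f_coef, f) for f in F_LEVELS):
            raise ValidationError(f"f_coef must be one of {F_LEVELS}{where}: {self.f_coef}")
        if self.connectivity is not None and self.connectivity not in (1, 2):
            raise ValidationError(f"connectivity must be 1 or 2{where}: {self.connectivity}")
        if self.n_families is not None and self.n_families < 3:
            raise ValidationError(f"n_families must be >= 3{where}: {self.n_families}")
        return self


@dataclass(frozen=True)
class FstRecord:
    """One published Fst estimate with its marker metadata."""

    species: str
    fst: float
    marker_type: str
    n_markers: int | None = None
    n_pops: int | None = None
    region: str | None = None
    manual_group: int | None = None
    reference: str | None = None
    common_name: str | None = None
    kmeans_group_published: int | None = None

    def validate(self, row: int | None = None) -> "FstRecord":
        where = "" if row is None else f" (row {row})"
        if not (0.0 < self.fst < 1.0):
            raise ValidationError(f"fst must lie in the open interval (0, 1){where}: {self.fst}")
        if self.marker_type not in MARKER_VOCAB:
            raise ValidationError(
                f"marker_type {self.marker_type!r} not in vocabulary {sorted(MARKER_VOCAB)}{where}"
            )
        if self.manual_group is not None and self.manual_group not in (1, 2):
            raise ValidationError(f"manual_group must be 1 or 2{where}: {self.manual_group}")
        return self


_ID_REQUIRED = ("id_value", "se", "species", "study", "life_stage", "f_coef")
_ID_OPTIONAL = ("connectivity", "trait_label", "age_years", "n_families")


def _resolve_columns(df: pd.DataFrame, required: Sequence[str],
                     schema: Mapping[str, str] | None) -> Mapping[str, str]:
    """Map canonical field names onto the file's column names."""
    schema = dict(schema or {})
    colmap = {}
    for name in required:
        col = schema.get(name, name)
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} (field {name!r}) missing; "
                              f"file has {list(df.columns)}")
        colmap[name] = col
    return colmap


def _opt_int(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return int(v)


def _opt_float(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_str(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


def load_id_table(path: str | Path,
                  schema: Mapping[str, str] | None = None) -> list[IDRecord]:
    """Read and validate an ID-estimate table.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical field names (``id_value``, ``se``,
        ``species``, ``study``, ``life_stage``, ``f_coef`` and the optional
        fields) to the file's column names.

    Returns
    -------
    list of validated :class:`IDRecord`, in file order.
    """
    df = pd.read_csv(path)
    colmap = _resolve_columns(df, _ID_REQUIRED, schema)
    opt = {n: (schema or {}).get(n, n) for n in _ID_OPTIONAL}
    records = []
    for i, row in df.iterrows():
        rec = IDRecord(
            id_value=float(row[colmap["id_value"]]),
            se=float(row[colmap["se"]]),
            species=str(row[colmap["species"]]),
            study=str(row[colmap["study"]]),
            life_stage=int(row[colmap["life_stage"]]),
            f_coef=float(row[colmap["f_coef"]]),
            connectivity=_opt_int(row.get(opt["connectivity"])),
            trait_label=_opt_str(row.get(opt["trait_label"])),
            age_years=_opt_float(row.get(opt["age_years"])),
            n_families=_opt_int(row.get(opt["n_families"])),
        )
        rec.validate(row=i)
        records.append(rec)
    species = sorted({r.species for r in records})
    studies = sorted({r.study for r in records})
    if not records:
        warnings.warn(f"{path}: empty ID table")
    else:
        logger.info("loaded %d ID records: %d species, %d studies",
                    len(records), len(species), len(studies))
    return records


def id_records_to_frame(records: Iterable[IDRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(IDRecord)]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


def write_id_table(records: Iterable[IDRecord], path: str | Path) -> None:
    id_records_to_frame(records).to_csv(path, index=False)


def dedupe_lowest_se(records: Sequence[IDRecord]) -> list[IDRecord]:
    """Keep one estimate per treatment combination: the lowest-SE one.

    When several populations of the same study report the same treatment
    combination (species, life stage, inbreeding level and trait), only the
    estimate with the smallest standard error is retained, to avoid
    between-population biases.  Records from distinct treatment combinations
    pass through unchanged; input order is preserved.  Exact SE ties keep the
    first record in input order (with a warning).
    """
    best: dict[tuple, int] = {}
    for idx, rec in enumerate(records):
        key = (rec.study, rec.species, rec.life_stage, rec.f_coef, rec.trait_label)
        if key not in best:
            best[key] = idx
            continue
        cur = records[best[key]]
        if rec.se < cur.se:
            best[key] = idx
        elif rec.se == cur.se:
            warnings.warn(
                f"SE tie within treatment combination {key}: keeping first record",
                stacklevel=2)
    keep = sorted(best.values())
    return [records[i] for i in keep]


def load_fst_table(path: str | Path, drop_invalid: bool = False) -> list[FstRecord]:
    """Read and validate an Fst table.

    With ``drop_invalid=True`` rows violating the open-interval invariant
    0 < Fst < 1 (e.g. organellar RAPD values printed as 1.000) are dropped
    with a warning instead of raising.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty Fst table")
        return []
    _resolve_columns(df, ("species", "fst", "marker_type"), None)
    records = []
    for i, row in df.iterrows():
        rec = FstRecord(
            species=str(row["species"]),
            fst=float(row["fst"]),
            marker_type=str(row["marker_type"]),
            n_markers=_opt_int(row.get("n_markers")),
            n_pops=_opt_int(row.get("n_pops")),
            region=_opt_str(row.get("region")),
            manual_group=_opt_int(row.get("manual_group")),
            reference=_opt_str(row.get("reference")),
            common_name=_opt_str(row.get("common_name")),
            kmeans_group_published=_opt_int(row.get("kmeans_group_published")),
        )
        try:
            rec.validate(row=i)
        except ValidationError:
            if drop_invalid:
                warnings.warn(f"{path}: dropping invalid Fst row {i} "
                              f"(fst={rec.fst}, marker={rec.marker_type})", stacklevel=2)
                continue
            raise
        records.append(rec)
    _warn_group_column(records)
    return records


def _warn_group_column(records: Sequence[FstRecord]) -> None:
    """Surface inconsistencies in the published manual-group column."""
    groups: dict[str, set] = {}
    for r in records:
        groups.setdefault(r.species, set()).add(r.manual_group)
    missing = sorted(s for s, g in groups.items() if g == {None})
    n2 = sum(1 for s, g in groups.items() if 2 in g)
    if missing:
        warnings.warn(f"species without a manual connectivity code: {missing}",
                      stacklevel=3)
    if n2 > 8:
        warnings.warn(
            f"manual-group column codes {n2} species as fragmented; the source "
            "text describes a 10/8 continuous/patchy split — the column is "
            "stored verbatim and left unreconciled", stacklevel=3)


def fst_records_to_frame(records: Iterable[FstRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(FstRecord)]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


def write_fst_table(records: Iterable[FstRecord], path: str | Path) -> None:
    fst_records_to_frame(records).to_csv(path, index=False)


def filter_fst_markers(records: Sequence[FstRecord]) -> list[FstRecord]:
    """Retain Fst estimates from codominant nuclear markers only.

    Keeps SNP, nuclear SSR (including EST-SSR) and isozyme/allozyme rows;
    drops organellar (cpSSR) and dominant (AFLP, RAPD) systems, logging the
    per-marker-type counts dropped.
    """
    kept = [r for r in records if r.marker_type in CODOMINANT_NUCLEAR]
    dropped = [r for r in records if r.marker_type not in CODOMINANT_NUCLEAR]
    if dropped:
        counts = pd.Series([r.marker_type for r in dropped]).value_counts().to_dict()
        warnings.warn(f"dropped {len(dropped)} Fst rows by marker type: {counts}",
                      stacklevel=2)
    if not kept:
        warnings.warn("no Fst rows left after marker filtering", stacklevel=2)
    return kept


def table1_fixture_path() -> Path:
    """Path of the bundled Fst compilation (Table 1 of the source survey)."""
    return Path(resources.files("idmeta") / "fixtures" / "table1_fst.csv")


def load_table1_fixture(filtered: bool = False) -> list[FstRecord]:
    """Load the bundled Fst table.

    Invalid rows (Fst printed as 1.000) are dropped with a warning.  With
    ``filtered=True`` the codominant-nuclear marker filter is applied too.
    """
    records = load_fst_table(table1_fixture_path(), drop_invalid=True)
    if filtered:
        records = filter_fst_markers(records)
    return records
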