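"""Tabular I/O, sample metadata, panel definitions and volume bookkeeping.

The pipeline consumes two kinds of exported qPCR tables:

* an *array export* — one row per target of a large screening card, with a
  cycle-threshold (Ct) column and a normalized-reporter (dRn) column, written
  by instrument software (QuantStudio-style column names by default); and
* a *tidy assay table* — one row per (miRNA, sample) from individual RT-qPCR
  assays, joined against a sample-metadata table.

Non-amplification within the run's cycle limit ("Undetermined") is stored as a
censored Ct (``ct=None``), never as a number: arithmetic on censored values is
forbidden except where an operation explicitly substitutes the cycle limit.
Any numeric Ct at or past the cycle limit is likewise stored censored.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    RowParseError,
    UsageError,
    ValidationError,
)

# --------------------------------------------------------------------------
# controlled vocabularies
# --------------------------------------------------------------------------

SAMPLE_TYPES = ("cohort_lysate", "conditioned_media", "blank_media", "water")

STAGES = (
    "oocyte",
    "zygote",
    "two_cell",
    "four_to_eight_cell",
    "morula",
    "blastocyst",
    "expanded_blastocyst",
)

TREATMENTS = ("none", "vehicle", "rhein", "degenerate", "pre_uc", "post_uc")

#: group labels the simulator / profiles use for the three-stage media design
STAGE_GROUPS = ("zygote", "four_cell", "blastocyst")


def canonical_mirna_id(name: str) -> str:
    """Normalize a miRNA target name to a canonical id.

    Trims whitespace, strips species prefixes (``mmu-``, ``hsa-``) and folds
    the ``miR`` prefix capitalization, so that e.g. ``"mmu-mir-294-3p "`` and
    ``"miR-294-3p"`` compare equal.  Array cards and text use mixed naming.
    """
    s = str(name).strip()
    low = s.lower()
    for prefix in ("mmu-", "hsa-", "rno-", "bta-"):
        if low.startswith(prefix):
            s = s[len(prefix):]
            low = s.lower()
            break
    if low.startswith("mir") and not s.startswith("miR"):
        s = "miR" + s[3:]
    return s


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayMeasurement:
    """One target x one sample qPCR result: censored Ct plus optional dRn.

    ``ct is None`` encodes "undetermined": no amplification within the run's
    cycle limit.  ``delta_rn`` is only present for array data.
    """

    mirna_id: str
    sample_id: str
    ct: float | None = None
    delta_rn: float | None = None

    def __post_init__(self):
        if not self.mirna_id:
            raise ValidationError("mirna_id must be nonempty")
        if self.ct is not None:
            if not math.isfinite(self.ct) or self.ct <= 0:
                raise ValidationError(
                    f"{self.mirna_id}: observed ct must be finite and > 0, got {self.ct}"
                )
        if self.delta_rn is not None and self.delta_rn < 0:
            raise ValidationError(f"{self.mirna_id}: delta_rn must be >= 0")

    @property
    def censored(self) -> bool:
        return self.ct is None


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: compartment, stage/treatment, replicate."""

    sample_id: str
    sample_type: str
    stage: str | None = None
    treatment: str = "none"
    replicate: int = 1
    cohort_size: int = 20  # embryos per microdroplet

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"unknown sample_type {self.sample_type!r}; expected one of {SAMPLE_TYPES}"
            )
        if self.stage is not None and self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")
        if self.sample_type == "cohort_lysate" and self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1 for cohort_lysate samples")

    @property
    def group(self) -> str:
        """Analysis group label: the treatment when treated, else the stage.

        The 4- to 8-cell stage is labeled ``four_cell`` in analysis outputs
        (the conditioning experiments start from 4-cell embryos).
        """
        if self.treatment not in ("none",):
            return self.treatment
        stage = self.stage or "none"
        return {"four_to_eight_cell": "four_cell"}.get(stage, stage)


@dataclass(frozen=True)
class VolumeModel:
    """Volume bookkeeping linking one qPCR data point to droplet contents.

    A 20-uL culture microdroplet is sampled (15 uL), lysed 1:1, and 2.5 uL of
    the lysate enters each reverse transcription, so one media data point
    represents ``15/(15+15) * 2.5 = 1.25`` uL of conditioned media.  The
    cohort lysate is prepared in a small total volume (default 2.75 uL: 2 uL
    lysis plus kit additions — a documented convention, not a measured value)
    of which 2.5 uL enters the RT.
    """

    droplet_volume_ul: float = 20.0
    media_sampled_ul: float = 15.0
    media_lysis_added_ul: float = 15.0
    lysate_total_ul: float = 2.75
    aliquot_per_rt_ul: float = 2.5
    uc_dilution_factor: float = 3.0  # 15 uL media + 30 uL PBS before the spin

    def __post_init__(self):
        for name in (
            "droplet_volume_ul",
            "media_sampled_ul",
            "media_lysis_added_ul",
            "lysate_total_ul",
            "aliquot_per_rt_ul",
            "uc_dilution_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def media_equivalent_per_datapoint_ul(self) -> float:
        """uL of conditioned media represented by one media data point (1.25 default)."""
        return (
            self.media_sampled_ul
            / (self.media_sampled_ul + self.media_lysis_added_ul)
            * self.aliquot_per_rt_ul
        )

    @property
    def scale_media(self) -> float:
        """Droplet-to-datapoint scale for media samples (16 with defaults)."""
        return self.droplet_volume_ul / self.media_equivalent_per_datapoint_ul

    @property
    def scale_lysate(self) -> float:
        """Lysate-to-datapoint scale for cohort lysates (1.1 with defaults)."""
        return self.lysate_total_ul / self.aliquot_per_rt_ul


@dataclass(frozen=True)
class PanelDefinition:
    """A named, ordered panel of miRNA ids."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError("panel must have at least one member")
        object.__setattr__(
            self, "members", tuple(canonical_mirna_id(m) for m in self.members)
        )


#: conserved secretome-relevant sequences
PANEL_A = PanelDefinition(
    "A", ("miR-20a-5p", "miR-30c-5p", "miR-142-3p", "miR-191-5p", "miR-320a-3p")
)
#: miR-290-cluster sequences
PANEL_B = PanelDefinition(
    "B", ("miR-291-3p", "miR-292-3p", "miR-293-3p", "miR-294-3p", "miR-295-3p")
)
#: earlier panel B used for the ultracentrifugation arm
PANEL_B_UC = PanelDefinition(
    "B_uc_variant",
    ("miR-290-3p", "miR-290-5p", "miR-293-3p", "miR-294-3p", "miR-295-3p"),
)

PANELS: dict[str, PanelDefinition] = {p.name: p for p in (PANEL_A, PANEL_B, PANEL_B_UC)}


# --------------------------------------------------------------------------
# array export parsing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrayDialect:
    """Column mapping and censoring token of an instrument array export."""

    target_col: str = "Target Name"
    ct_col: str = "CT"
    drn_col: str | None = "Delta Rn"
    delimiter: str = ","
    censor_token: str = "Undetermined"
    max_cycles: float = 40.0

    def __post_init__(self):
        if self.max_cycles <= 0:
            raise ValidationError("max_cycles must be > 0")


ARRAY_DIALECT_DEFAULT = ArrayDialect()


def _parse_ct(token: str, dialect: ArrayDialect) -> float | None:
    s = str(token).strip()
    if not s or s.casefold() == dialect.censor_token.casefold():
        return None
    ct = float(s)  # caller wraps conversion errors with the row index
    if ct >= dialect.max_cycles:
        return None  # at/past the cycle limit: treated as non-amplification
    return ct


def parse_array_export(
    path: str | Path,
    dialect: ArrayDialect = ARRAY_DIALECT_DEFAULT,
    sample_id: str = "array",
    errors: str = "raise",
) -> list[AssayMeasurement]:
    """Read an array export into measurements, one per data row, order preserved.

    ``errors="collect"`` returns ``(records, row_errors)`` instead of raising on
    the first malformed row; either way no row is silently dropped.
    """
    if errors not in ("raise", "collect"):
        raise UsageError("errors must be 'raise' or 'collect'")
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        required = [dialect.target_col, dialect.ct_col]
        if dialect.drn_col is not None:
            required.append(dialect.drn_col)
        for col in required:
            if col not in header:
                raise FormatError(f"array export {path} lacks mandatory column {col!r}")
        records: list[AssayMeasurement] = []
        row_errors: list[RowParseError] = []
        for i, row in enumerate(reader):
            try:
                ct = _parse_ct(row[dialect.ct_col], dialect)
            except ValueError:
                err = RowParseError(
                    f"non-numeric Ct {row[dialect.ct_col]!r} "
                    f"(censoring token is {dialect.censor_token!r})",
                    row=i,
                )
                if errors == "raise":
                    raise err from None
                row_errors.append(err)
                continue
            drn = None
            if dialect.drn_col is not None:
                try:
                    drn = float(row[dialect.drn_col])
                except (TypeError, ValueError):
                    err = RowParseError(
                        f"non-numeric dRn {row[dialect.drn_col]!r}", row=i
                    )
                    if errors == "raise":
                        raise err from None
                    row_errors.append(err)
                    continue
            records.append(
                AssayMeasurement(
                    mirna_id=canonical_mirna_id(row[dialect.target_col]),
                    sample_id=sample_id,
                    ct=ct,
                    delta_rn=drn,
                )
            )
    if errors == "collect":
        return records, row_errors  # type: ignore[return-value]
    return records


def write_array_export(
    measurements: Iterable[AssayMeasurement],
    path: str | Path,
    dialect: ArrayDialect = ARRAY_DIALECT_DEFAULT,
) -> Path:
    """Write measurements in the array-export format (round-trips with the parser)."""
    path = Path(path)
    cols = ["Well", dialect.target_col, dialect.ct_col]
    if dialect.drn_col is not None:
        cols.append(dialect.drn_col)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(cols)
        for well, m in enumerate(measurements, start=1):
            row = [
                well,
                m.mirna_id,
                dialect.censor_token if m.ct is None else repr(m.ct),
            ]
            if dialect.drn_col is not None:
                row.append("" if m.delta_rn is None else repr(m.delta_rn))
            writer.writerow(row)
    return path


# --------------------------------------------------------------------------
# tidy assay tables and sample metadata
# --------------------------------------------------------------------------

ASSAY_COLUMNS = ("mirna_id", "sample_id", "ct", "delta_rn")
META_COLUMNS = ("sample_id", "sample_type", "stage", "treatment", "replicate", "cohort_size")

CENSOR_TOKEN = "Undetermined"


def parse_assay_table(
    path: str | Path,
    meta_path: str | Path | None = None,
    max_cycles: float = 40.0,
) -> tuple[list[AssayMeasurement], list[SampleMeta]]:
    """Read a tidy per-assay Ct table (TSV) and its sample-metadata table.

    One row per (mirna_id, sample_id); duplicates are rejected.  The ``ct``
    field holds a number, or the censoring token / empty for no amplification.
    If ``meta_path`` is omitted, metadata columns may be embedded in the table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], []
    if df.empty and len(df.columns) == 0:
        return [], []
    for col in ("mirna_id", "sample_id", "ct"):
        if col not in df.columns:
            raise FormatError(f"assay table {path} lacks mandatory column {col!r}")

    measurements: list[AssayMeasurement] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        mid = canonical_mirna_id(getattr(row, "mirna_id"))
        sid = str(getattr(row, "sample_id")).strip()
        key = (mid, sid)
        if key in seen:
            raise IntegrityError(f"duplicate (mirna_id, sample_id) pair {key}")
        seen.add(key)
        ct_tok = str(getattr(row, "ct")).strip()
        if not ct_tok or ct_tok.casefold() == CENSOR_TOKEN.casefold():
            ct = None
        else:
            try:
                ct = float(ct_tok)
            except ValueError:
                raise RowParseError(f"non-numeric Ct {ct_tok!r}", row=i) from None
            if ct >= max_cycles:
                ct = None
        drn = None
        if "delta_rn" in df.columns:
            tok = str(getattr(row, "delta_rn")).strip()
            drn = float(tok) if tok else None
        measurements.append(AssayMeasurement(mid, sid, ct, drn))

    metas: list[SampleMeta] = []
    if meta_path is not None:
        metas = parse_sample_meta(meta_path)
    elif "sample_type" in df.columns:
        meta_df = df[[c for c in META_COLUMNS if c in df.columns]].drop_duplicates(
            subset="sample_id"
        )
        metas = [_meta_from_row(r) for r in meta_df.to_dict("records")]
    return measurements, metas


def _meta_from_row(rec: Mapping[str, object]) -> SampleMeta:
    stage = str(rec.get("stage", "") or "").strip() or None
    if stage in ("none", "None", "NA"):
        stage = None
    return SampleMeta(
        sample_id=str(rec["sample_id"]).strip(),
        sample_type=str(rec["sample_type"]).strip(),
        stage=stage,
        treatment=str(rec.get("treatment", "none") or "none").strip(),
        replicate=int(rec.get("replicate", 1) or 1),
        cohort_size=int(rec.get("cohort_size", 20) or 20),
    )


def parse_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata TSV (columns: SampleMeta fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "sample_type"):
        if col not in df.columns:
            raise FormatError(f"metadata table {path} lacks mandatory column {col!r}")
    metas = [_meta_from_row(rec) for rec in df.to_dict("records")]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate sample_id in metadata table")
    return metas


def write_assay_table(
    measurements: Iterable[AssayMeasurement], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for m in measurements:
        rows.append(
            {
                "mirna_id": m.mirna_id,
                "sample_id": m.sample_id,
                "ct": CENSOR_TOKEN if m.ct is None else repr(m.ct),
                "delta_rn": "" if m.delta_rn is None else repr(m.delta_rn),
            }
        )
    pd.DataFrame(rows, columns=list(ASSAY_COLUMNS)).to_csv(path, sep="\t", index=False)
    return path


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "sample_id": m.sample_id,
            "sample_type": m.sample_type,
            "stage": m.stage or "",
            "treatment": m.treatment,
            "replicate": m.replicate,
            "cohort_size": m.cohort_size,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(path, sep="\t", index=False)
    return path


# --------------------------------------------------------------------------
# results output
# --------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping[str, object] | None = None,
    create_dirs: bool = True,
) -> dict[str, Path]:
    """Write result tables as TSVs plus a run-metadata JSON.

    Column order is taken from each frame (stable); floats are written with
    ``repr`` precision so a re-read reproduces the table bit-exactly.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        if not create_dirs:
            raise IOError(f"output directory {out_dir} does not exist")
        out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=None)
        paths[name] = p
    meta = dict(metadata or {})
    meta.setdefault("tables", sorted(tables))
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    paths["run_metadata"] = meta_path
    return paths


def read_result_table(path: str | Path) -> pd.DataFrame:
    # round_trip float parsing: re-reading reproduces written tables bit-exactly
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# --------------------------------------------------------------------------
# frame helpers
# --------------------------------------------------------------------------


def measurements_to_frame(measurements: Sequence[AssayMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [m.mirna_id for m in measurements],
            "sample_id": [m.sample_id for m in measurements],
            "ct": [m.ct for m in measurements],
            "delta_rn": [m.delta_rn for m in measurements],
        }
    )


def index_measurements(
    measurements: Iterable[AssayMeasurement],
) -> dict[tuple[str, str], AssayMeasurement]:
    """Index by (sample_id, mirna_id); duplicate keys are an integrity error."""
    out: dict[tuple[str, str], AssayMeasurement] = {}
    for m in measurements:
        key = (m.sample_id, m.mirna_id)
        if key in out:
            raise IntegrityError(f"duplicate measurement for {key}")
        out[key] = m
    return out
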