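"""Record model, delimited-table input/output and run configuration.

The package works on individual-level consumer records (one row per
specimen: isotope values, elemental composition, physiological endpoints,
treatment and mesocosm labels) plus mesocosm-level covariates (survival,
oxygen penetration depth).  Tables are plain CSV; configuration is YAML or
JSON.  All numeric columns round-trip through :func:`write_specimens` /
:func:`read_specimens` at full float precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ParseError(ValueError):
    """A cell could not be parsed as the declared type."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


#: columns every specimen table must carry
REQUIRED_SPECIMEN_COLUMNS = (
    "specimen_id",
    "experiment",
    "treatment",
    "mesocosm",
    "d13c_raw",
    "d15n",
    "cn_ratio",
)
#: optional physiology / design columns
OPTIONAL_SPECIMEN_COLUMNS = (
    "body_mass",
    "rna_dna",
    "fecundity",
    "viable_embryos",
    "parasite",
    "is_initial",
)
SPECIMEN_COLUMNS = REQUIRED_SPECIMEN_COLUMNS + OPTIONAL_SPECIMEN_COLUMNS

REQUIRED_MESOCOSM_COLUMNS = ("mesocosm", "treatment", "survival_pct")
MESOCOSM_COLUMNS = REQUIRED_MESOCOSM_COLUMNS + ("oxygen_depth",)

_NUMERIC_SPECIMEN_COLUMNS = (
    "d13c_raw",
    "d15n",
    "cn_ratio",
    "body_mass",
    "rna_dna",
    "fecundity",
    "viable_embryos",
)


@dataclass
class SpecimenRecord:
    """One consumer individual.

    Isotope values are per-mil (d13c_raw vs VPDB, d15n vs atmospheric N2),
    cn_ratio is the dimensionless mass C:N, body_mass is mg dry weight.
    Optional physiology is ``None`` when not measured, never silently zero.
    """

    specimen_id: str
    experiment: int
    treatment: str
    mesocosm: str | None
    d13c_raw: float
    d15n: float
    cn_ratio: float
    body_mass: float | None = None
    rna_dna: float | None = None
    fecundity: int | None = None
    viable_embryos: int | None = None
    parasite: bool | None = None
    is_initial: bool = False

    def validate(self) -> None:
        if self.experiment not in (1, 2):
            raise ValidationError(
                f"specimen {self.specimen_id}: experiment must be 1 or 2"
            )
        if not self.treatment:
            raise ValidationError(f"specimen {self.specimen_id}: missing treatment")
        if not self.is_initial and not self.mesocosm:
            raise ValidationError(
                f"specimen {self.specimen_id}: non-initial record lacks a mesocosm"
            )
        if not math.isfinite(self.d13c_raw) or not math.isfinite(self.d15n):
            raise ValidationError(
                f"specimen {self.specimen_id}: non-finite isotope value"
            )
        if not (self.cn_ratio > 0):
            raise ValidationError(
                f"specimen {self.specimen_id}: cn_ratio must be > 0"
            )
        if self.body_mass is not None and not (self.body_mass > 0):
            raise ValidationError(
                f"specimen {self.specimen_id}: body_mass must be > 0"
            )
        if (
            self.viable_embryos is not None
            and self.fecundity is not None
            and self.viable_embryos > self.fecundity
        ):
            raise ValidationError(
                f"specimen {self.specimen_id}: viable_embryos "
                f"({self.viable_embryos}) exceeds fecundity ({self.fecundity})"
            )
        if self.parasite is not None and self.parasite not in (True, False):
            raise ValidationError(
                f"specimen {self.specimen_id}: parasite must be binary"
            )


@dataclass
class MesocosmRecord:
    """One replicated experimental container.

    survival_pct is the percentage of introduced animals recovered at
    termination; oxygen_depth the weighted mean oxygen penetration depth in
    the sediment (mm), measured in the feeding-regime experiment only.
    """

    mesocosm: str
    treatment: str
    survival_pct: float
    oxygen_depth: float | None = None

    def validate(self) -> None:
        if not (0.0 <= self.survival_pct <= 100.0):
            raise ValidationError(
                f"mesocosm {self.mesocosm}: survival_pct outside [0, 100]"
            )
        if self.oxygen_depth is not None and not (self.oxygen_depth > 0):
            raise ValidationError(
                f"mesocosm {self.mesocosm}: oxygen_depth must be > 0"
            )


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    The seed is the single source of randomness and is embedded in every
    output the pipeline writes.
    """

    specimen_path: str | None = None
    mesocosm_path: str | None = None
    out_dir: str = "isoniche_out"
    experiment: int = 1
    # simulation instead of file input (see isoniche.simulate)
    simulate: bool = False
    # which treatment labels count as stressed for the discriminator
    stressed_treatments: list[str] = field(default_factory=list)
    # labels excluded from the discriminator (initial groups are always excluded)
    excluded_treatments: list[str] = field(default_factory=list)
    outlier_ids: list[str] = field(default_factory=list)
    outlier_variables: list[str] = field(default_factory=list)
    bootstrap_reps: int = 2000
    posterior_draws: int = 10_000
    seed: int = 0
    levene_center: str = "mean"  # mean | median
    roc_cutoff: str = "youden"
    split_parasitized: bool = False
    standardize_predictors: bool = False
    zscore_cn_within_treatment: bool = False
    make_plots: bool = False
    csv_sep: str = ","
    csv_decimal: str = "."

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if self.levene_center not in ("mean", "median"):
            raise ValidationError("levene_center must be 'mean' or 'median'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# frame <-> record conversion


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(round(v))


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip().lower()
        if value in ("true", "1", "yes", "present"):
            return True
        if value in ("false", "0", "no", "absent"):
            return False
        raise ParseError(f"cannot parse {value!r} as binary")
    return bool(int(value))


def frame_to_specimens(df: pd.DataFrame) -> list[SpecimenRecord]:
    records = []
    for i, row in enumerate(df.to_dict("records")):
        rec = SpecimenRecord(
            specimen_id=str(row["specimen_id"]),
            experiment=int(row["experiment"]),
            treatment=str(row["treatment"]),
            mesocosm=(
                None
                if row.get("mesocosm") is None
                or (isinstance(row["mesocosm"], float) and math.isnan(row["mesocosm"]))
                else str(row["mesocosm"])
            ),
            d13c_raw=float(row["d13c_raw"]),
            d15n=float(row["d15n"]),
            cn_ratio=float(row["cn_ratio"]),
            body_mass=_opt_float(row.get("body_mass")),
            rna_dna=_opt_float(row.get("rna_dna")),
            fecundity=_opt_int(row.get("fecundity")),
            viable_embryos=_opt_int(row.get("viable_embryos")),
            parasite=_opt_bool(row.get("parasite")),
            is_initial=bool(row.get("is_initial", False)),
        )
        try:
            rec.validate()
        except ValidationError as err:
            raise ValidationError(f"row {i + 2}: {err}") from None
        records.append(rec)
    return records


def specimens_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.reindex(columns=list(SPECIMEN_COLUMNS))


def mesocosms_to_frame(records: Iterable[MesocosmRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.reindex(columns=list(MESOCOSM_COLUMNS))


def frame_to_mesocosms(df: pd.DataFrame) -> list[MesocosmRecord]:
    records = []
    for i, row in enumerate(df.to_dict("records")):
        rec = MesocosmRecord(
            mesocosm=str(row["mesocosm"]),
            treatment=str(row["treatment"]),
            survival_pct=float(row["survival_pct"]),
            oxygen_depth=_opt_float(row.get("oxygen_depth")),
        )
        try:
            rec.validate()
        except ValidationError as err:
            raise ValidationError(f"row {i + 2}: {err}") from None
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# CSV I/O


def _read_table(
    path: str | Path,
    required: Sequence[str],
    numeric: Sequence[str],
    config: RunConfig | None,
) -> pd.DataFrame:
    sep = config.csv_sep if config else ","
    decimal = config.csv_decimal if config else "."
    df = pd.read_csv(path, sep=sep, decimal=decimal, comment="#", dtype=object)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    for col in numeric:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column '{col}' at row {row}"
            )
        df[col] = converted
    return df


def read_specimens(
    path: str | Path,
    config: RunConfig | None = None,
    mesocosm_path: str | Path | None = None,
) -> tuple[list[SpecimenRecord], list[MesocosmRecord]]:
    """Read a specimen CSV (and optional mesocosm CSV) into typed records.

    Raises :class:`SchemaError` when a required column is absent,
    :class:`ParseError` (with the row number) for unparseable numerics and
    :class:`ValidationError` for invariant violations.
    """
    df = _read_table(
        path, REQUIRED_SPECIMEN_COLUMNS, _NUMERIC_SPECIMEN_COLUMNS, config
    )
    if "is_initial" in df.columns:
        df["is_initial"] = df["is_initial"].map(
            lambda v: bool(_opt_bool(v)) if v is not None else False
        )
    specimens = frame_to_specimens(df)
    mesocosms: list[MesocosmRecord] = []
    mpath = mesocosm_path or (config.mesocosm_path if config else None)
    if mpath:
        mdf = _read_table(
            mpath,
            REQUIRED_MESOCOSM_COLUMNS,
            ("survival_pct", "oxygen_depth"),
            config,
        )
        mesocosms = frame_to_mesocosms(mdf)
    n_missing = specimens_to_frame(specimens)[list(_NUMERIC_SPECIMEN_COLUMNS)].isna().sum()
    for col, n in n_missing.items():
        if n:
            logger.info("read_specimens: %d records missing optional '%s'", n, col)
    return specimens, mesocosms


def write_specimens(
    records: Iterable[SpecimenRecord] | pd.DataFrame,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    df = records if isinstance(records, pd.DataFrame) else specimens_to_frame(records)
    _write_csv(df, path, header_comment)


def write_mesocosms(
    records: Iterable[MesocosmRecord] | pd.DataFrame,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    df = records if isinstance(records, pd.DataFrame) else mesocosms_to_frame(records)
    _write_csv(df, path, header_comment)


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# outlier replacement


def replace_outliers(
    records: Sequence[SpecimenRecord] | pd.DataFrame,
    outlier_ids: Sequence[str],
    variables: Sequence[str],
) -> tuple[list[SpecimenRecord] | pd.DataFrame, list[str]]:
    """Replace flagged specimens' values with their treatment mean.

    For each flagged specimen, each named numeric variable is replaced by
    the mean over the *non-flagged* members of the same treatment.  The
    operation is idempotent for a fixed flag set and returns a log of every
    replacement made.
    """
    as_frame = isinstance(records, pd.DataFrame)
    df = records.copy() if as_frame else specimens_to_frame(records)
    if not outlier_ids:
        return (df if as_frame else frame_to_specimens(df)), []

    ids = df["specimen_id"].astype(str)
    unknown = set(map(str, outlier_ids)) - set(ids)
    if unknown:
        raise ValidationError(f"unknown outlier ids: {sorted(unknown)}")
    for var in variables:
        if var not in df.columns or not pd.api.types.is_numeric_dtype(
            pd.to_numeric(df[var], errors="coerce")
        ):
            raise ValidationError(f"outlier variable '{var}' is not numeric")

    flagged = ids.isin(set(map(str, outlier_ids)))
    log: list[str] = []
    for treatment, sub in df[flagged].groupby("treatment"):
        keep = df[(df["treatment"] == treatment) & ~flagged]
        if keep.empty:
            raise ValidationError(
                f"all specimens in treatment '{treatment}' are flagged; "
                "no mean available for replacement"
            )
        for var in variables:
            mean = pd.to_numeric(keep[var], errors="coerce").mean()
            df.loc[sub.index, var] = mean
            for sid in sub["specimen_id"]:
                log.append(
                    f"replaced {var} of specimen {sid} with "
                    f"{treatment} mean {mean:.6g}"
                )
    for line in log:
        logger.info("replace_outliers: %s", line)
    return (df if as_frame else frame_to_specimens(df)), log
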