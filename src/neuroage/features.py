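"""Feature-table schema, validated CSV I/O, and quality-control exclusions.

The pipeline's universal currency is a participant x feature table holding
28 network-wise cortical morphometric features -- 4 measures (cortical
thickness, sulcal depth, surface area, cortical volume) x 7 canonical
resting-state networks (Yeo parcellation: VIS, SMN, DAN, VAN, LIM, FPN,
DMN) -- together with covariates (age, sex, education, Zung depression
score, Euler number, rsfMRI head-motion index), a scanner/site label, and
cohort/disorder-group labels.

Coding conventions: sex 0 = male, 1 = female; education 1 = high-school
non-graduate, 0 = graduate; group = number of disorders present (0, 1, 2)
and must equal hiv + cu when both indicators are given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("neuroage")

MEASURES = ("thickness", "sulcal_depth", "surface_area", "volume")
NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")


def feature_key(measure: str, network: str) -> str:
    """String form ``<measure>__<network>`` of a feature key."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if network not in NETWORKS:
        raise ValueError(f"unknown network {network!r}")
    return f"{measure}__{network}"


def parse_feature_key(key: str) -> tuple[str, str]:
    """Inverse of :func:`feature_key`; round-trips for all 28 keys."""
    measure, sep, network = key.partition("__")
    if not sep or measure not in MEASURES or network not in NETWORKS:
        raise ValueError(f"not a feature key: {key!r}")
    return measure, network


#: Fixed ordering of the 28 feature columns (measure-major, network-minor).
FEATURE_COLUMNS = tuple(feature_key(m, n) for m in MEASURES for n in NETWORKS)

COVARIATE_COLUMNS = ("age", "sex", "education", "zung", "euler", "motion")
LABEL_COLUMNS = ("site", "cohort", "group", "hiv", "cu", "nci")

#: Deterministic on-disk column order: id, covariates, labels, features.
COLUMN_ORDER = ("participant_id",) + COVARIATE_COLUMNS + LABEL_COLUMNS + FEATURE_COLUMNS

REQUIRED_COLUMNS = ("participant_id",) + COVARIATE_COLUMNS + ("site",) + FEATURE_COLUMNS

_NUMERIC_REQUIRED = COVARIATE_COLUMNS + FEATURE_COLUMNS


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """Row-level constraint violated (e.g. duplicate participant ids)."""


def validate_schema(table: pd.DataFrame) -> list[str]:
    """Report violations of the feature-table invariants.

    Returns a list of human-readable violation strings; an empty list means
    the table is valid. This never raises: it is the reporting counterpart
    of :func:`read_feature_table`, which enforces.
    """
    report: list[str] = []
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            report.append(f"missing required column {col!r}")
    if report:
        return report
    dup = table["participant_id"][table["participant_id"].duplicated()]
    for pid in dup.unique():
        report.append(f"duplicate participant_id {pid!r}")
    for col in _NUMERIC_REQUIRED:
        bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()]
        for idx in bad:
            report.append(f"row {idx}: missing or non-numeric {col!r}")
    age = pd.to_numeric(table["age"], errors="coerce")
    for idx in table.index[age <= 0]:
        report.append(f"row {idx}: age must be > 0")
    motion = pd.to_numeric(table["motion"], errors="coerce")
    for idx in table.index[motion < 0]:
        report.append(f"row {idx}: motion must be >= 0")
    if {"group", "hiv", "cu"} <= set(table.columns):
        sub = table[["group", "hiv", "cu"]].dropna()
        bad = sub.index[sub["group"] != sub["hiv"] + sub["cu"]]
        for idx in bad:
            report.append(f"row {idx}: group != hiv + cu")
    return report


def read_feature_table(path, cohort_hint: str | None = None) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    Rows with any missing required field are dropped with a logged per-row
    report. A missing required column raises :class:`SchemaError`; duplicate
    participant ids raise :class:`IntegrityError`.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if table["participant_id"].duplicated().any():
        dups = table["participant_id"][table["participant_id"].duplicated()].unique()
        raise IntegrityError(f"duplicate participant_id(s): {list(dups)}")
    keep = np.ones(len(table), dtype=bool)
    for col in _NUMERIC_REQUIRED:
        bad = pd.to_numeric(table[col], errors="coerce").isna().to_numpy()
        for idx in np.flatnonzero(bad & keep):
            logger.warning("rejecting row %s (%s): missing %s",
                           idx, table["participant_id"].iloc[idx], col)
        keep &= ~bad
    table = table.loc[keep].reset_index(drop=True)
    if cohort_hint is not None:
        table = table.assign(cohort=table.get("cohort", cohort_hint)).fillna(
            {"cohort": cohort_hint}
        )
    violations = validate_schema(table)
    if violations:
        raise IntegrityError("; ".join(violations))
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV with the deterministic column order.

    Columns listed in :data:`COLUMN_ORDER` come first (those present);
    any extra columns follow in their existing order. Floats are written
    with 17 significant digits so a read round-trips to full precision.
    """
    ordered = [c for c in COLUMN_ORDER if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    table[ordered + extra].to_csv(path, index=False, float_format="%.17g")


@dataclass
class ExclusionReport:
    """Accounting of a cohort quality-control pass."""

    n_initial: int
    n_recon_failure: int
    n_high_motion: int
    n_retained: int
    excluded_ids: list = field(default_factory=list)


def apply_qc_exclusions(
    roster: pd.DataFrame,
    motion_max: float = 0.4,
    recon_col: str = "recon_ok",
    motion_col: str = "motion",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the cohort exclusion filter and report the flow.

    Participants are removed if cortical-surface reconstruction failed
    (``recon_ok`` falsy) or if mean Euclidean head displacement during the
    resting-state scan exceeds ``motion_max`` millimetres (default 0.4 mm,
    a conventional cut-off for morphometry-quality screening). Motion is
    only assessed for participants with a usable reconstruction, so the two
    exclusion counts are disjoint.
    """
    recon_fail = ~roster[recon_col].astype(bool)
    high_motion = (roster[motion_col] > motion_max) & ~recon_fail
    keep = ~(recon_fail | high_motion)
    report = ExclusionReport(
        n_initial=len(roster),
        n_recon_failure=int(recon_fail.sum()),
        n_high_motion=int(high_motion.sum()),
        n_retained=int(keep.sum()),
        excluded_ids=list(roster.loc[~keep, "participant_id"]),
    )
    return roster.loc[keep].reset_index(drop=True), report
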