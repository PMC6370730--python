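"""Expression and clinical table input, patient alignment, and z-score scaling.

The pipeline operates on *views*: patient x feature numeric matrices, one per
omics layer (gene expression, miRNA expression, isoform expression, ...),
measured on a shared patient cohort, plus an optional clinical table with
follow-up time and an event indicator used for survival-based evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionView",
    "SurvivalTable",
    "Cohort",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "align_cohort",
    "zscore_normalize",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionView:
    """One omics layer: an ``n_patients x n_features`` numeric matrix.

    Rows are patients, columns are features. Values must be finite after
    loading; missing-value handling happens at read time (see
    :func:`read_expression_tsv`).
    """

    values: np.ndarray
    patient_ids: list[str]
    feature_ids: list[str]
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.patient_ids) or m != len(self.feature_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )
        _check_unique(self.patient_ids, "patient ids")
        _check_unique(self.feature_ids, "feature ids")
        if not np.isfinite(self.values).all():
            raise ValueError(f"view {self.view_name!r} contains non-finite entries")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_patients(self, ids: Sequence[str]) -> "ExpressionView":
        """Return a copy restricted (and re-ordered) to ``ids``."""
        index = {p: i for i, p in enumerate(self.patient_ids)}
        rows = [index[p] for p in ids]
        return ExpressionView(
            self.values[rows], list(ids), list(self.feature_ids), self.view_name
        )


@dataclass
class SurvivalTable:
    """Per-patient follow-up time and event indicator.

    ``event`` is 1 when death (or the endpoint of interest) was observed and 0
    when the patient was censored at ``time``.
    """

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    time_unit: str = "days"

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.patient_ids, "patient ids")
        if self.time.shape != (len(self.patient_ids),) or self.event.shape != self.time.shape:
            raise ValueError("time/event length must match patient_ids")
        if np.any(self.time < 0):
            bad = [self.patient_ids[i] for i in np.flatnonzero(self.time < 0)]
            raise ValueError(f"negative follow-up time for patients {bad}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (observed)")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def subset_patients(self, ids: Sequence[str]) -> "SurvivalTable":
        index = {p: i for i, p in enumerate(self.patient_ids)}
        rows = [index[p] for p in ids]
        return SurvivalTable(list(ids), self.time[rows], self.event[rows], self.time_unit)


@dataclass
class Cohort:
    """Two or more views restricted to one common, ordered patient list."""

    views: list[ExpressionView]
    survival: SurvivalTable | None = None

    def __post_init__(self) -> None:
        if len(self.views) < 2:
            raise ValueError("a cohort needs at least two views")
        ref = self.views[0].patient_ids
        if len(ref) < 3:
            raise ValueError("a cohort needs at least 3 patients")
        for v in self.views[1:]:
            if v.patient_ids != ref:
                raise ValueError(
                    f"view {v.view_name!r} patient list differs from {self.views[0].view_name!r}"
                )
        if self.survival is not None and self.survival.patient_ids != ref:
            raise ValueError("survival table patient list differs from the views")

    @property
    def patient_ids(self) -> list[str]:
        return self.views[0].patient_ids

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        # sniff among tab / comma; the python engine handles sep=None itself
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_expression_tsv(
    path: str | Path,
    orientation: str = "patients_in_rows",
    delimiter: str | None = None,
    view_name: str | None = None,
    max_missing_fraction: float = 0.2,
) -> ExpressionView:
    """Load an expression matrix from a delimited text file.

    The first column holds row identifiers and the first row column
    identifiers. ``orientation`` declares which axis carries patients; the
    returned view always has patients in rows.

    Features missing in more than ``max_missing_fraction`` of patients are
    dropped; remaining missing entries are imputed with the feature mean so
    that downstream kernels are well defined.
    """
    if orientation not in ("patients_in_rows", "patients_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path, delimiter)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    parse_fail = numeric.isna() & raw.notna()
    if parse_fail.to_numpy().any():
        r, c = np.argwhere(parse_fail.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {raw.index[r]!r}, column {raw.columns[c]!r} "
            f"in {path}: {raw.iat[r, c]!r}"
        )
    if orientation == "patients_in_columns":
        numeric = numeric.T

    name = view_name if view_name is not None else Path(path).stem
    patient_ids = [str(p) for p in numeric.index]
    _check_unique(patient_ids, "patient ids")
    _check_unique([str(f) for f in numeric.columns], "feature ids")

    # missing-value policy: drop mostly-absent features, mean-impute the rest
    missing_frac = numeric.isna().mean(axis=0)
    keep = missing_frac <= max_missing_fraction
    if (~keep).any():
        logger.info(
            "view %s: dropped %d/%d features with >%.0f%% missing values",
            name, int((~keep).sum()), numeric.shape[1], 100 * max_missing_fraction,
        )
    numeric = numeric.loc[:, keep]
    n_imputed = int(numeric.isna().to_numpy().sum())
    if n_imputed:
        numeric = numeric.fillna(numeric.mean(axis=0))
        logger.info("view %s: mean-imputed %d missing entries", name, n_imputed)

    return ExpressionView(
        numeric.to_numpy(dtype=float),
        patient_ids,
        [str(f) for f in numeric.columns],
        name,
    )


def write_expression_tsv(view: ExpressionView, path: str | Path) -> None:
    """Write a view as a TSV with patients in rows (inverse of the reader)."""
    df = pd.DataFrame(view.values, index=view.patient_ids, columns=view.feature_ids)
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical_tsv(
    path: str | Path,
    time_col: str,
    event_col: str,
    event_recode: Mapping[str, int] | None = None,
    time_unit: str = "days",
    delimiter: str | None = None,
) -> SurvivalTable:
    """Load a clinical table with survival time and event status.

    Rows with a missing time or event are dropped (a count is logged). String
    event codes (e.g. ``dead``/``alive``) are mapped through ``event_recode``.
    """
    raw = _read_table(path, delimiter)
    for col in (time_col, event_col):
        if col not in raw.columns:
            raise ValueError(f"column {col!r} not found in {path} (has {list(raw.columns)})")
    time = pd.to_numeric(raw[time_col], errors="coerce")
    event = raw[event_col]
    if event_recode is not None:
        event = event.map(lambda v: event_recode.get(str(v), v))
    event = pd.to_numeric(event, errors="coerce")

    ok = time.notna() & event.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("clinical table %s: dropped %d rows with missing time/event", path, n_dropped)
    return SurvivalTable(
        [str(p) for p in raw.index[ok]],
        time[ok].to_numpy(),
        event[ok].to_numpy(),
        time_unit,
    )


def align_cohort(
    views: Sequence[ExpressionView], survival: SurvivalTable | None = None
) -> Cohort:
    """Restrict all inputs to their common patients, sorted lexicographically.

    The shared patient list is the intersection of every view's (and, when
    given, the survival table's) identifiers. Dropped-patient counts are
    logged per input. Fewer than 3 common patients is an error.
    """
    if len(views) < 2:
        raise ValueError("need at least two views to align")
    common = set(views[0].patient_ids)
    for v in views[1:]:
        common &= set(v.patient_ids)
    if survival is not None:
        common &= set(survival.patient_ids)
    order = sorted(common)
    if len(order) < 3:
        raise ValueError(f"only {len(order)} patients shared across inputs (need >= 3)")
    for v in views:
        dropped = v.n_patients - len(order)
        if dropped:
            logger.info("align: view %s loses %d patients", v.view_name, dropped)
    if survival is not None and survival.n_patients != len(order):
        logger.info("align: survival table loses %d patients", survival.n_patients - len(order))
    return Cohort(
        [v.subset_patients(order) for v in views],
        survival.subset_patients(order) if survival is not None else None,
    )


def zscore_normalize(view: ExpressionView, ddof: int = 0) -> ExpressionView:
    """Standardize each feature to mean 0, unit standard deviation.

    x' = (x - mean) / sd, computed per feature across patients. The default
    uses the population standard deviation (``ddof=0``); set ``ddof=1`` for
    the sample convention. Constant features (sd = 0) map to all-zeros.
    """
    mean = view.values.mean(axis=0)
    sd = view.values.std(axis=0, ddof=ddof)
    constant = sd == 0
    if constant.any():
        logger.info(
            "view %s: %d constant features set to zero after z-scoring",
            view.view_name, int(constant.sum()),
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = (view.values - mean) / safe_sd
    z[:, constant] = 0.0
    return replace(view, values=z)
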