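"""Expression-matrix and clinical-table IO, cleaning, and label derivation.

Expression matrices travel as tab-delimited text with a single header line,
the convention of microarray expression exports: probes (features) as rows,
samples as columns, and ``probe_id`` as the first header field.  In memory
the matrix is always oriented samples x features.  Orientation of a file is
auto-detected from the header (``probe_id`` marker or a majority of
``_at``-suffixed row identifiers, the Affymetrix probe naming scheme) and
can be overridden.

Cleaning follows the usual microarray conventions: a probe with no observed
value in any sample is dropped outright, and a probe missing in only some
samples has those cells imputed with the probe's mean over the remaining
samples.

Class labels for the recurrence experiments are derived from the clinical
table given a cutoff in months: a sample whose recurrence event occurred at
or before the cutoff is high risk (+1); a sample known to be recurrence-free
past the cutoff -- either because the event came later or because follow-up
exceeded the cutoff -- is low risk (-1); a sample censored before the cutoff
has an unknowable class and is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Cell contents treated as missing in expression files.
MISSING_MARKERS = ("NA", "")

CLINICAL_COLUMNS = ["sample_id", "time_months", "event", "age", "gender", "stage"]

#: Identifiers of clinical covariates when appended as expression columns.
COVARIATE_IDS = ["cov_age", "cov_gender", "cov_stage"]


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """A samples x features real matrix with identifier lists.

    ``values[i, j]`` is the expression of feature ``feature_ids[j]`` in
    sample ``sample_ids[i]``, in whatever units the upstream normalization
    produced.  Values may contain NaN until :func:`clean_expression` runs.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValidationError(
                f"id lists ({len(self.sample_ids)} samples, "
                f"{len(self.feature_ids)} features) do not match matrix shape {n}x{p}"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def subset_features(self, ids) -> "ExpressionMatrix":
        """Return a copy restricted to ``ids`` (kept in the given order)."""
        index = {f: j for j, f in enumerate(self.feature_ids)}
        try:
            cols = [index[str(f)] for f in ids]
        except KeyError as exc:
            raise ValidationError(f"unknown feature id {exc.args[0]!r}") from exc
        return ExpressionMatrix(
            self.values[:, cols], [self.feature_ids[j] for j in cols],
            list(self.sample_ids),
        )


def _looks_like_probe_axis(ids) -> bool:
    ids = [str(x) for x in ids]
    if not ids:
        return False
    hits = sum("_at" in x for x in ids)
    return hits / len(ids) > 0.5


def read_expression(path, orientation: str | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression file into samples x features form.

    Parameters
    ----------
    path : str or Path
        Tab-delimited text with one header row and one identifier column.
    orientation : {"features_as_rows", "samples_as_rows", None}
        ``None`` auto-detects: a ``probe_id`` header field, or a majority of
        row identifiers containing ``_at``, marks rows as features.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=list(MISSING_MARKERS),
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed expression file {path}: {exc}") from exc
    if orientation is None:
        if (df.index.name or "").strip().lower() == "probe_id":
            orientation = "features_as_rows"
        elif _looks_like_probe_axis(df.index):
            orientation = "features_as_rows"
        elif _looks_like_probe_axis(df.columns):
            orientation = "samples_as_rows"
        else:
            orientation = "samples_as_rows"
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if orientation == "features_as_rows":
        df = df.T
    # Reject non-numeric payloads with a line-number diagnostic.
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        obj = df.infer_objects()
        for i, col in enumerate(obj.columns):
            coerced = pd.to_numeric(obj[col], errors="coerce")
            bad = coerced.isna() & obj[col].notna()
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                # +2: one header line, 1-based numbering; transposed files
                # report the original file row of the offending feature.
                line = i + 2 if orientation == "features_as_rows" else row + 2
                raise ParseError(
                    f"non-numeric value {obj[col][bad].iloc[0]!r} "
                    f"in {path} near line {line}"
                )
        raise ParseError(f"could not interpret {path} as a numeric matrix")
    return ExpressionMatrix(values, list(df.columns), list(df.index))


def write_expression(xm: ExpressionMatrix, path) -> None:
    """Write features-as-rows tab-delimited text (header field ``probe_id``)."""
    df = xm.to_frame().T
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def clean_expression(
    xm: ExpressionMatrix, drop_all_missing: bool = True
) -> ExpressionMatrix:
    """Impute per-feature means and drop features missing in every sample.

    A feature with no observed value in any sample is removed when
    ``drop_all_missing`` is true, otherwise it is an error.  Any remaining
    missing cell is replaced by the mean of that feature over the samples
    where it was observed, which leaves the feature's mean unchanged.
    """
    values = xm.values
    missing = np.isnan(values)
    if not missing.any():
        return xm
    all_missing = missing.all(axis=0)
    if all_missing.any():
        if not drop_all_missing:
            bad = [f for f, m in zip(xm.feature_ids, all_missing) if m]
            raise ValidationError(
                f"features missing in all samples: {bad[:5]}"
            )
        keep = ~all_missing
        values = values[:, keep]
        feature_ids = [f for f, k in zip(xm.feature_ids, keep) if k]
        missing = missing[:, keep]
    else:
        feature_ids = list(xm.feature_ids)
    values = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(values, axis=0)
    rows, cols = np.nonzero(missing)
    values[rows, cols] = col_means[cols]
    return ExpressionMatrix(values, feature_ids, list(xm.sample_ids))


@dataclass
class ClinicalTable:
    """Per-sample follow-up and covariates.

    Columns: ``sample_id`` (unique), ``time_months`` (nonnegative,
    recurrence-free follow-up), ``event`` (1 = recurrence observed, 0 =
    censored), ``age``, ``gender``, ``stage``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"clinical table lacks columns {missing_cols}")
        df = df[CLINICAL_COLUMNS].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids")
        df["time_months"] = df["time_months"].astype(float)
        if (df["time_months"] < 0).any():
            raise ValidationError("negative time_months")
        events = df["event"].astype(int)
        if not df["event"].isin((0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        df["event"] = events
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")


def read_clinical(path) -> ClinicalTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed clinical file {path}: {exc}") from exc
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index=False, float_format="%.17g")


def derive_labels(clinical: ClinicalTable, cutoff_months: float) -> pd.Series:
    """Map samples to recurrence classes at a cutoff; drop the unknowable.

    Returns a series of {+1, -1} indexed by sample id.  +1 (high risk):
    recurrence observed at or before the cutoff.  -1 (low risk): event or
    censoring after the cutoff, i.e. known recurrence-free past it.
    Samples censored at or before the cutoff are omitted: their class
    cannot be determined.
    """
    if cutoff_months <= 0:
        raise ValidationError("cutoff_months must be positive")
    df = clinical.data
    recurred = (df["event"] == 1) & (df["time_months"] <= cutoff_months)
    known_free = df["time_months"] > cutoff_months
    labels = pd.Series(
        np.where(recurred, 1, -1), index=df["sample_id"], dtype=int
    )
    return labels[recurred.to_numpy() | known_free.to_numpy()]


@dataclass
class LabeledDataset:
    """An expression matrix aligned with +-1 recurrence labels."""

    X: ExpressionMatrix
    y: np.ndarray
    cutoff_months: float
    covariate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != self.X.n_samples:
            raise ValidationError("label vector does not match sample count")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValidationError("labels must be coded +1 / -1")


def _encode_covariates(clin: pd.DataFrame) -> np.ndarray:
    """Encode age as-is, gender as 0/1, stage as ordinal integers."""
    age = clin["age"].astype(float).to_numpy()
    gender_codes = {g: i for i, g in enumerate(sorted(clin["gender"].astype(str).unique()))}
    gender = clin["gender"].astype(str).map(gender_codes).to_numpy(dtype=float)
    stage_codes = {s: i for i, s in enumerate(sorted(clin["stage"].astype(str).unique()))}
    stage = clin["stage"].astype(str).map(stage_codes).to_numpy(dtype=float)
    return np.column_stack([age, gender, stage])


def build_labeled_dataset(
    xm: ExpressionMatrix,
    clinical: ClinicalTable,
    cutoff_months: float,
    use_covariates: bool = False,
) -> LabeledDataset:
    """Align expression rows with derived labels, optionally appending the
    age/gender/stage covariates as three extra feature columns."""
    labels = derive_labels(clinical, cutoff_months)
    keep = [s for s in labels.index if s in set(xm.sample_ids)]
    if not keep:
        raise ValidationError("no overlap between expression and labeled samples")
    sub = xm.to_frame().loc[keep]
    values = sub.to_numpy()
    feature_ids = list(xm.feature_ids)
    covariate_ids: list[str] = []
    if use_covariates:
        clin = clinical.indexed().loc[keep]
        values = np.column_stack([values, _encode_covariates(clin)])
        covariate_ids = list(COVARIATE_IDS)
        feature_ids = feature_ids + covariate_ids
    X = ExpressionMatrix(values, feature_ids, keep)
    return LabeledDataset(X, labels.loc[keep].to_numpy(), cutoff_months, covariate_ids)
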