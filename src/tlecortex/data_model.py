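"""Region-level cortical feature tables and their on-disk formats.

The pipeline's universal currency is a subjects x features matrix whose
columns are labelled by (region, hemisphere, measure) triples drawn from the
Desikan-Killiany parcellation (34 gyral-based regions per hemisphere) and
four surface measures: cortical thickness (CTh), cortical surface area
(CSA), gray matter volume (GMV), and mean curvature (MCu).  A single measure
therefore spans 68 features and the full four-measure design spans 272.

Feature labels serialize as ``<hemi>_<region>_<measure>`` with the
FreeSurfer region spelling (e.g. ``lh_entorhinal_CSA``) so that tables
exported by FreeSurfer's ``aparcstats2table`` load unmodified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DK_REGIONS",
    "HEMISPHERES",
    "MEASURES",
    "GROUPS",
    "FeatureLabel",
    "SubjectRecord",
    "GroupComparison",
    "CorticalFeatureTable",
    "TableFormatError",
    "TableValidationError",
    "canonical_labels",
    "parse_label",
    "read_feature_table",
    "write_feature_table",
    "subset",
]

# The 34 Desikan-Killiany cortical regions, in FreeSurfer's aparc order.
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

HEMISPHERES: tuple[str, ...] = ("left", "right")
MEASURES: tuple[str, ...] = ("CTh", "CSA", "GMV", "MCu")
GROUPS: tuple[str, ...] = ("LTLE", "RTLE", "NC")

_HEMI_CODE = {"left": "lh", "right": "rh"}
_CODE_HEMI = {v: k for k, v in _HEMI_CODE.items()}

# aparcstats2table column suffixes per measure.
_APARC_SUFFIX = {
    "thickness": "CTh",
    "area": "CSA",
    "volume": "GMV",
    "meancurv": "MCu",
}

_METADATA_COLUMNS = ("subject_id", "group", "age", "sex", "scanner")


class TableFormatError(ValueError):
    """A file could not be parsed as a feature table."""


class TableValidationError(ValueError):
    """Parsed content violates the feature-table invariants."""


@dataclass(frozen=True, order=True)
class FeatureLabel:
    """One (region, hemisphere, measure) cortical feature."""

    region: str
    hemisphere: str
    measure: str

    def __post_init__(self) -> None:
        if self.region not in DK_REGIONS:
            raise TableValidationError(
                f"unknown Desikan-Killiany region {self.region!r}; "
                f"valid names: {', '.join(DK_REGIONS)}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise TableValidationError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        if self.measure not in MEASURES:
            raise TableValidationError(f"measure must be one of {MEASURES}, got {self.measure!r}")

    def __str__(self) -> str:
        return f"{_HEMI_CODE[self.hemisphere]}_{self.region}_{self.measure}"

    @property
    def canonical_index(self) -> int:
        """Position in the canonical 272-label ordering."""
        return (
            MEASURES.index(self.measure) * 68
            + HEMISPHERES.index(self.hemisphere) * 34
            + DK_REGIONS.index(self.region)
        )


def parse_label(text: str) -> FeatureLabel:
    """Parse ``lh_entorhinal_CSA``-style text into a :class:`FeatureLabel`."""
    parts = text.split("_")
    if len(parts) != 3:
        raise TableFormatError(f"malformed feature label {text!r} (expected hemi_region_measure)")
    hemi_code, region, measure = parts
    if hemi_code not in _CODE_HEMI:
        raise TableFormatError(f"malformed feature label {text!r}: unknown hemisphere {hemi_code!r}")
    return FeatureLabel(region=region, hemisphere=_CODE_HEMI[hemi_code], measure=measure)


def canonical_labels(measures: Sequence[str] = MEASURES) -> list[FeatureLabel]:
    """All labels for the given measures in canonical (measure, hemi, region) order."""
    return [
        FeatureLabel(region=r, hemisphere=h, measure=m)
        for m in measures
        for h in HEMISPHERES
        for r in DK_REGIONS
    ]


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata attached to a feature-table row."""

    subject_id: str
    group: str
    age: float
    sex: str
    scanner: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TableValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (self.age > 0 and math.isfinite(self.age)):
            raise TableValidationError(f"age must be a positive real, got {self.age!r}")
        if self.sex not in ("M", "F"):
            raise TableValidationError(f"sex must be M or F, got {self.sex!r}")
        if self.scanner not in ("1.5T", "3.0T"):
            raise TableValidationError(f"scanner must be 1.5T or 3.0T, got {self.scanner!r}")


@dataclass(frozen=True)
class GroupComparison:
    """A two-group contrast; the positive group is counted in TP/FN.

    By convention the patient group is positive in patient-vs-control
    comparisons, and LTLE is positive in LTLE-RTLE.
    """

    positive_group: str
    negative_group: str

    def __post_init__(self) -> None:
        if self.positive_group == self.negative_group:
            raise TableValidationError("comparison groups must differ")

    @property
    def name(self) -> str:
        return f"{self.positive_group}-{self.negative_group}"

    def __str__(self) -> str:
        return self.name


LTLE_NC = GroupComparison("LTLE", "NC")
RTLE_NC = GroupComparison("RTLE", "NC")
LTLE_RTLE = GroupComparison("LTLE", "RTLE")
DEFAULT_COMPARISONS = (LTLE_NC, RTLE_NC, LTLE_RTLE)


@dataclass
class CorticalFeatureTable:
    """Subjects x features matrix with metadata; rows are subjects."""

    subjects: list[SubjectRecord]
    labels: list[FeatureLabel]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.subjects), len(self.labels)):
            raise TableValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.labels)} features"
            )
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise TableValidationError("duplicate subject_id in table")
        if len(set(self.labels)) != len(self.labels):
            raise TableValidationError("duplicate feature label in table")
        if self.values.size and not np.isfinite(self.values).all():
            raise TableValidationError("non-finite values in table")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.labels)

    @property
    def groups(self) -> np.ndarray:
        return np.asarray([s.group for s in self.subjects])

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "scanner": [s.scanner for s in self.subjects],
            }
        )
        feats = pd.DataFrame(self.values, columns=[str(l) for l in self.labels])
        return pd.concat([meta, feats], axis=1)


def _metadata_records(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                age=float(row.age),
                sex=str(row.sex),
                scanner=str(row.scanner),
            )
        )
    return records


def _impute_group_means(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    out = values.copy()
    for g in np.unique(groups):
        rows = groups == g
        block = out[rows]
        col_means = np.nanmean(block, axis=0)
        idx = np.where(np.isnan(block))
        block[idx] = col_means[idx[1]]
        out[rows] = block
    return out


def _check_row_arity(path: Path) -> None:
    """Reject rows whose field count differs from the header's."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        n_cols = len(header.split("\t")) if header else 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if len(line.split("\t")) != n_cols:
                raise TableFormatError(
                    f"{path}: line {lineno} has {len(line.split(chr(9)))} fields, "
                    f"expected {n_cols}"
                )


def read_feature_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    metadata_path: str | Path | None = None,
    impute: bool = False,
) -> CorticalFeatureTable:
    """Load a feature table from delimited text.

    ``generic_tsv`` expects columns ``subject_id, group, age, sex, scanner``
    followed by feature columns named like ``lh_entorhinal_CSA``.  The
    ``aparcstats`` dialect reads a file as emitted by FreeSurfer's
    ``aparcstats2table`` (first column the subject id, remaining columns
    ``lh_<region>_<thickness|area|volume|meancurv>``) and requires a sidecar
    metadata TSV via ``metadata_path`` carrying the generic metadata columns.

    Missing values are rejected unless ``impute=True``, which fills each gap
    with the per-group feature mean.
    """
    path = Path(path)
    if dialect not in ("generic_tsv", "aparcstats"):
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_row_arity(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, index_col=False, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # wrong arity rows etc.
        raise TableFormatError(f"{path}: {exc}") from None

    if dialect == "aparcstats":
        if metadata_path is None:
            raise TableFormatError("aparcstats dialect requires a sidecar metadata_path")
        subj_col = df.columns[0]
        feature_cols = list(df.columns[1:])
        labels = []
        for col in feature_cols:
            parts = str(col).split("_")
            if len(parts) != 3 or parts[2] not in _APARC_SUFFIX:
                raise TableFormatError(f"{path}: unrecognized aparcstats column {col!r}")
            hemi_code, region, suffix = parts
            if hemi_code not in _CODE_HEMI:
                raise TableFormatError(f"{path}: unrecognized aparcstats column {col!r}")
            labels.append(
                FeatureLabel(region=region, hemisphere=_CODE_HEMI[hemi_code], measure=_APARC_SUFFIX[suffix])
            )
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
        missing_meta = [c for c in _METADATA_COLUMNS if c not in meta.columns]
        if missing_meta:
            raise TableFormatError(f"{metadata_path}: missing metadata column(s) {missing_meta}")
        meta = meta.set_index("subject_id")
        order = df[subj_col].astype(str)
        absent = [s for s in order if s not in meta.index]
        if absent:
            raise TableFormatError(f"{metadata_path}: no metadata for subject(s) {absent}")
        meta = meta.loc[order].reset_index()
        records = _metadata_records(meta)
        values = df[feature_cols].to_numpy(dtype=float)
    else:
        missing_meta = [c for c in _METADATA_COLUMNS if c not in df.columns]
        if missing_meta:
            raise TableFormatError(f"{path}: missing metadata column(s) {missing_meta}")
        feature_cols = [c for c in df.columns if c not in _METADATA_COLUMNS]
        labels = [parse_label(str(c)) for c in feature_cols]
        records = _metadata_records(df[list(_METADATA_COLUMNS)])
        values = df[feature_cols].to_numpy(dtype=float) if feature_cols else np.empty((len(df), 0))

    if np.isnan(values).any():
        if not impute:
            raise TableValidationError(f"{path}: missing feature values (pass impute=True to fill)")
        values = _impute_group_means(values, np.asarray([r.group for r in records]))
    return CorticalFeatureTable(subjects=records, labels=labels, values=values)


def write_feature_table(table: CorticalFeatureTable, path: str | Path) -> None:
    """Write a generic TSV that round-trips through :func:`read_feature_table`.

    Values are written with ``repr`` precision so read(write(t)) == t exactly.
    """
    path = Path(path)
    header = list(_METADATA_COLUMNS) + [str(l) for l in table.labels]
    lines = ["\t".join(header)]
    for record, row in zip(table.subjects, table.values):
        cells = [
            record.subject_id,
            record.group,
            repr(float(record.age)),
            record.sex,
            record.scanner,
        ] + [repr(float(v)) for v in row]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def subset(
    table: CorticalFeatureTable,
    comparison: GroupComparison,
    measures: Iterable[str] | None = None,
) -> CorticalFeatureTable:
    """Restrict a table to the two compared groups and selected measures.

    Subject and feature order are preserved.  ``measures=None`` keeps all
    measures present in the table.
    """
    keep_groups = {comparison.positive_group, comparison.negative_group}
    row_idx = [i for i, s in enumerate(table.subjects) if s.group in keep_groups]
    for g in keep_groups:
        if not any(table.subjects[i].group == g for i in row_idx):
            raise TableValidationError(f"group {g!r} absent from table")
    if measures is None:
        col_idx = list(range(table.n_features))
    else:
        measures = set(measures)
        unknown = measures - set(MEASURES)
        if unknown:
            raise TableValidationError(f"unknown measure(s) {sorted(unknown)}")
        col_idx = [j for j, l in enumerate(table.labels) if l.measure in measures]
        if not col_idx:
            raise TableValidationError(f"no features with measure(s) {sorted(measures)} in table")
    return CorticalFeatureTable(
        subjects=[table.subjects[i] for i in row_idx],
        labels=[table.labels[j] for j in col_idx],
        values=table.values[np.ix_(row_idx, col_idx)] if row_idx else table.values[:0, col_idx],
    )
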