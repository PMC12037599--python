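"""Reading, validating and writing subject-level morphometric cohorts.

Morphometric tables are TSV files with one row per subject: a subject-ID
column followed by one column per cortical region.  Two header dialects are
auto-detected:

* FreeSurfer ``aparcstats2table`` style: ``lh_bankssts_area``,
  ``rh_precuneus_thickness`` (an arbitrary measure suffix);
* plain dotted style: ``lh.bankssts``.

Metadata is a second TSV keyed on the same subject IDs with columns
``subject``, ``group``, ``age``, ``sex`` and optional clinical columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .regions import RegionSet

log = logging.getLogger(__name__)

SURFACE_AREA = "surface_area_mm2"
THICKNESS = "thickness_mm"

#: measure suffix used when writing aparcstats2table-style headers
_MEASURE_SUFFIX = {SURFACE_AREA: "area", THICKNESS: "thickness"}

#: clinical columns recognised in metadata (all optional)
CLINICAL_COLUMNS = (
    "updrs_iii",
    "mmse",
    "pdq39",
    "bdi",
    "ledd",
    "onset_age",
    "duration",
    "hoehn_yahr",
    "education",
)

_META_REQUIRED = ("subject", "group", "age", "sex")

MIN_GROUP_SIZE = 4
SMALL_GROUP_WARN = 30


@dataclass
class MorphometricCohort:
    """Subject x region morphometric values plus per-subject metadata.

    ``values`` is indexed by subject ID with one column per region label in
    canonical order.  ``meta`` shares the index and holds ``group`` (two
    levels), ``age``, ``sex`` ('F'/'M') and any clinical columns.
    ``corrected`` marks covariate-adjusted residuals, which may be negative.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    regions: RegionSet
    metric: str = SURFACE_AREA
    corrected: bool = False
    adjustment: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.regions.labels):
            raise ValidationError("value columns do not match region set order")
        if not self.values.index.equals(self.meta.index):
            raise ValidationError("values and metadata index on different subjects")
        if self.values.isna().any().any():
            raise ValidationError("missing morphometric values after validation")
        if not self.corrected and (self.values.to_numpy() <= 0).any():
            bad = self.values.columns[(self.values <= 0).any()].tolist()
            raise ValidationError(f"non-positive morphometric values in {bad}")
        groups = self.group_labels
        if len(groups) != 2:
            raise ValidationError(f"expected exactly two groups, got {list(groups)}")
        for g, n in self.group_sizes.items():
            if n < MIN_GROUP_SIZE:
                raise ValidationError(
                    f"group {g!r} has {n} subjects; at least {MIN_GROUP_SIZE} required"
                )
            if n < SMALL_GROUP_WARN:
                warnings.warn(
                    f"group {g!r} has only {n} subjects; correlation estimates "
                    "will be unstable",
                    stacklevel=2,
                )

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_labels(self) -> tuple:
        return tuple(sorted(self.meta["group"].unique()))

    @property
    def group_sizes(self) -> dict:
        return {g: int((self.meta["group"] == g).sum()) for g in self.group_labels}

    def group_values(self, group) -> np.ndarray:
        """Value matrix (subjects x regions) restricted to one group."""
        mask = (self.meta["group"] == group).to_numpy()
        if not mask.any():
            raise ValidationError(f"unknown group label {group!r}")
        return self.values.to_numpy()[mask]

    def with_values(self, values: np.ndarray, corrected: bool | None = None,
                    adjustment: pd.DataFrame | None = None) -> "MorphometricCohort":
        """Copy of this cohort with the value matrix replaced."""
        frame = pd.DataFrame(values, index=self.values.index, columns=self.values.columns)
        return replace(
            self,
            values=frame,
            corrected=self.corrected if corrected is None else corrected,
            adjustment=adjustment,
        )


def _match_columns(columns: list[str], regions: RegionSet) -> dict[str, str]:
    """Map canonical region label -> input column name, auto-detecting dialect."""
    colset = set(columns)
    mapping: dict[str, str] = {}
    missing: list[str] = []
    for name, hemi in regions:
        label = f"{hemi}_{name}"
        dotted = f"{hemi}.{name}"
        if dotted in colset:
            mapping[label] = dotted
            continue
        prefixed = [c for c in colset if c == label or c.startswith(label + "_")]
        if len(prefixed) == 1:
            mapping[label] = prefixed[0]
        elif len(prefixed) > 1:
            raise ValidationError(f"ambiguous columns for region {label}: {sorted(prefixed)}")
        else:
            missing.append(label)
    if missing:
        raise ValidationError(f"morphometric table is missing region column(s): {missing}")
    return mapping


def load_cohort(
    morph_path,
    meta_path,
    regions: RegionSet,
    metric: str = SURFACE_AREA,
) -> MorphometricCohort:
    """Load and validate a cohort from a morphometric TSV and a metadata TSV.

    The first column of the morphometric table is taken as the subject ID.
    Subjects present in only one of the two tables are dropped with a
    warning (inner join); region columns are re-ordered to canonical order.
    """
    morph = pd.read_csv(morph_path, sep="\t", float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep="\t")

    subj_col = morph.columns[0]
    morph = morph.set_index(subj_col)
    morph.index = morph.index.astype(str)

    for col in _META_REQUIRED:
        if col not in meta.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    meta = meta.set_index("subject")
    meta.index = meta.index.astype(str)

    mapping = _match_columns(list(morph.columns), regions)
    values = morph[[mapping[lab] for lab in regions.labels]]
    values.columns = list(regions.labels)

    only_morph = values.index.difference(meta.index)
    only_meta = meta.index.difference(values.index)
    for idx, where in ((only_morph, "metadata"), (only_meta, "morphometrics")):
        if len(idx):
            warnings.warn(
                f"{len(idx)} subject(s) absent from {where} excluded: {list(idx)[:5]}",
                stacklevel=2,
            )
    common = values.index.intersection(meta.index)
    values = values.loc[common].astype(float)
    meta = meta.loc[common]

    cohort = MorphometricCohort(values=values, meta=meta, regions=regions, metric=metric)
    log.info("loaded cohort: %s subjects, groups %s", len(common), cohort.group_sizes)
    return cohort


def write_cohort(cohort: MorphometricCohort, morph_path, meta_path) -> None:
    """Write a cohort back to the TSV pair consumed by :func:`load_cohort`.

    Region columns use the ``aparcstats2table`` naming so files round-trip
    through the same loader; float formatting uses full ``repr`` precision
    so reloaded values are bit-identical.
    """
    suffix = _MEASURE_SUFFIX.get(cohort.metric, "value")
    out = cohort.values.copy()
    out.columns = [f"{c}_{suffix}" for c in out.columns]
    out.index.name = "subject"
    out.to_csv(morph_path, sep="\t")
    meta = cohort.meta.copy()
    meta.index.name = "subject"
    meta.to_csv(meta_path, sep="\t")
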