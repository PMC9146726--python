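"""Demographics, STAI scoring, stress labels, and the five dataset variants.

Each subject contributes seven demographic features (age in years plus six
Boolean fields) and a state-anxiety (SXE) score from the 20-item STAI state
scale.  The binary academic-stress label is 1 when the SXE score exceeds the
gender-specific cutoff (43.01 for males, 43.69 for females), else 0.

Five feature sets are assembled from the same cohort:

  1. demographics only (one instance per subject, 7 features);
  2. HR-RAW values only (one instance per heart-rate interval, 1 feature);
  3. demographics + HR-RAW (per interval, 8 features);
  4. HR-CLEAN values only (per interval, 1 feature);
  5. demographics + HR-CLEAN (per interval, 8 features).

For the per-interval variants the subject's demographics and label are
replicated across all of that subject's intervals; an optional per-subject
granularity aggregates each subject's intervals to their mean instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .hr_postprocess import HRClean, HRRaw

#: SXE cutoffs above which the label is "high academic stress".
SXE_CUTOFF_MALE = 43.01
SXE_CUTOFF_FEMALE = 43.69

DEMOGRAPHIC_FEATURES = ("age", "gender", "public_school", "sports",
                        "extracurricular", "family_issues", "failed_classes")

#: Standard keying of the 20-item STAI state scale: these item numbers
#: (1-based) describe absence of anxiety and are scored reversed (r -> 5-r).
STAI_STATE_REVERSE_ITEMS = (1, 2, 5, 8, 10, 11, 15, 16, 19, 20)


@dataclass
class SubjectRecord:
    """One subject's demographics plus anxiety scores.

    ``gender`` is 0 for male, 1 for female; the six Boolean fields are
    0/1; ``sxe_score`` (state anxiety) and the optional ``sxr_score``
    (trait anxiety) lie in [20, 80].
    """

    subject_id: str
    age: float
    gender: int
    public_school: int
    sports: int
    extracurricular: int
    family_issues: int
    failed_classes: int
    sxe_score: int
    sxr_score: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("gender", "public_school", "sports", "extracurricular",
                     "family_issues", "failed_classes"):
            if getattr(self, name) not in (0, 1):
                raise InputError(f"{name} must be 0 or 1, got "
                                 f"{getattr(self, name)!r}")
        for name in ("sxe_score", "sxr_score"):
            v = getattr(self, name)
            if v is not None and not 20 <= v <= 80:
                raise InputError(f"{name} must lie in [20, 80], got {v}")

    @property
    def label(self) -> int:
        return label_from_sxe(self.sxe_score, self.gender)

    def demographics(self) -> np.ndarray:
        return np.array([float(getattr(self, f))
                         for f in DEMOGRAPHIC_FEATURES])


@dataclass
class FeatureDataset:
    """Instances of one dataset variant with binary stress labels."""

    variant: int
    X: np.ndarray
    y: np.ndarray
    feature_names: Tuple[str, ...]
    subject_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise InputError("X must be (n, arity) aligned with y")
        if self.X.shape[1] != len(self.feature_names):
            raise InputError("feature_names arity mismatch")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "subject_id", self.subject_ids)
        df["label"] = self.y
        return df


def score_stai(item_responses: Sequence[int],
               reverse_keyed_items: Sequence[int] = STAI_STATE_REVERSE_ITEMS
               ) -> int:
    """Total score of one 20-item STAI scale.

    ``item_responses`` are the 4-point Likert answers (1..4) in item order;
    ``reverse_keyed_items`` lists the 1-based item numbers scored as
    5 - response.  The total lies in [20, 80].
    """
    if len(item_responses) != 20:
        raise InputError(f"expected 20 responses, got {len(item_responses)}")
    total = 0
    rev = set(reverse_keyed_items)
    if not rev <= set(range(1, 21)):
        raise InputError("reverse-keyed item numbers must be in 1..20")
    for i, r in enumerate(item_responses, start=1):
        if r not in (1, 2, 3, 4):
            raise InputError(f"item {i}: response must be 1..4, got {r!r}")
        total += (5 - r) if i in rev else r
    return total


def label_from_sxe(sxe_score: float, gender: int,
                   cutoff_male: float = SXE_CUTOFF_MALE,
                   cutoff_female: float = SXE_CUTOFF_FEMALE) -> int:
    """Binary academic-stress label from the state-anxiety score.

    1 (high stress) when the score strictly exceeds the gender cutoff;
    with integer STAI totals and non-integer cutoffs, strict and
    greater-or-equal comparison coincide.
    """
    if gender not in (0, 1):
        raise InputError(f"gender must be 0 (male) or 1 (female), "
                         f"got {gender!r}")
    if not 20 <= sxe_score <= 80:
        raise InputError(f"SXE score must lie in [20, 80], got {sxe_score}")
    cutoff = cutoff_female if gender == 1 else cutoff_male
    return int(sxe_score > cutoff)


VARIANT_SOURCES = {1: None, 2: "raw", 3: "raw", 4: "clean", 5: "clean"}


def build_dataset(records: Sequence[SubjectRecord],
                  hr_raw_map: Optional[Mapping[str, HRRaw]] = None,
                  hr_clean_map: Optional[Mapping[str, HRClean]] = None,
                  variant: int = 1,
                  granularity: str = "interval") -> FeatureDataset:
    """Assemble one of the five dataset variants.

    Variant 1 uses demographics only (always one instance per subject).
    Variants 2/4 use the single HR value of each RAW/CLEAN interval;
    variants 3/5 append that value to the demographics.  With
    ``granularity="subject"`` the per-interval variants use each subject's
    mean HR instead, yielding one instance per subject.
    """
    if variant not in VARIANT_SOURCES:
        raise InputError(f"variant must be 1..5, got {variant}")
    if granularity not in ("interval", "subject"):
        raise InputError(f"unknown granularity {granularity!r}")
    source = VARIANT_SOURCES[variant]
    hr_map: Optional[Mapping] = None
    if source == "raw":
        hr_map = hr_raw_map
    elif source == "clean":
        hr_map = hr_clean_map
    if source is not None and hr_map is None:
        raise InputError(f"variant {variant} needs an HR-{source.upper()} "
                         "series map")

    rows: List[np.ndarray] = []
    labels: List[int] = []
    sids: List[str] = []
    for rec in records:
        if variant == 1:
            rows.append(rec.demographics())
            labels.append(rec.label)
            sids.append(rec.subject_id)
            continue
        if rec.subject_id not in hr_map:
            raise InputError(f"subject {rec.subject_id}: missing "
                             f"HR-{source.upper()} series")
        series = hr_map[rec.subject_id]
        values = np.asarray(getattr(series, "values", series), dtype=float)
        if granularity == "subject":
            values = np.array([values.mean()])
        for hr in values:
            if variant in (2, 4):
                rows.append(np.array([hr]))
            else:
                rows.append(np.append(rec.demographics(), hr))
            labels.append(rec.label)
            sids.append(rec.subject_id)

    if variant == 1:
        names: Tuple[str, ...] = DEMOGRAPHIC_FEATURES
    elif variant in (2, 4):
        names = (f"hr_{source}",)
    else:
        names = DEMOGRAPHIC_FEATURES + (f"hr_{source}",)
    y = np.array(labels)
    if np.unique(y).size < 2:
        raise ValidationError(f"variant {variant}: both classes must be "
                              "present for cross-validation")
    prov = "demographics" if source is None else f"hr_{source}"
    return FeatureDataset(variant=variant, X=np.array(rows), y=y,
                          feature_names=names, subject_ids=np.array(sids),
                          provenance=prov)


def build_all_variants(records: Sequence[SubjectRecord],
                       hr_raw_map: Mapping[str, HRRaw],
                       hr_clean_map: Mapping[str, HRClean],
                       granularity: str = "interval"
                       ) -> Dict[int, FeatureDataset]:
    return {v: build_dataset(records, hr_raw_map, hr_clean_map, v,
                             granularity) for v in range(1, 6)}


# ---------------------------------------------------------------------------
# CSV interop
# ---------------------------------------------------------------------------

SUBJECT_CSV_COLUMNS = ("subject_id",) + DEMOGRAPHIC_FEATURES + (
    "sxe_score", "sxr_score")


def subjects_to_csv(records: Sequence[SubjectRecord], path: str) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "sxe_score": r.sxe_score,
               "sxr_score": r.sxr_score}
        row.update({f: getattr(r, f) for f in DEMOGRAPHIC_FEATURES})
        rows.append(row)
    pd.DataFrame(rows, columns=list(SUBJECT_CSV_COLUMNS)).to_csv(
        path, index=False)


def subjects_from_csv(path: str) -> List[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(SUBJECT_CSV_COLUMNS) - {"sxr_score"} - set(df.columns)
    if missing:
        raise InputError(f"subject CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        sxr = row.get("sxr_score")
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), age=float(row["age"]),
            gender=int(row["gender"]),
            public_school=int(row["public_school"]),
            sports=int(row["sports"]),
            extracurricular=int(row["extracurricular"]),
            family_issues=int(row["family_issues"]),
            failed_classes=int(row["failed_classes"]),
            sxe_score=int(row["sxe_score"]),
            sxr_score=None if pd.isna(sxr) else int(sxr)))
    return records
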