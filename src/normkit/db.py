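"""Validated document store for the cohort.

Seven document classes arranged in three levels:

- level 1: ``subject``
- level 2: ``epilepsy_status``, ``exam``, ``treatment`` (reference a subject)
- level 3: ``channel``, ``iceeg_segment``, ``seizure`` (reference an exam)

Each class declares required fields, optional fields, constrained
vocabularies and uniqueness rules; inserts are validated and referential
integrity is enforced.  Raw signal data never enters the store -- segments
record only a file location.  The store serialises to one canonical JSON
file per class so a saved database is diffable and reload-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

CLASSES = (
    "subject",
    "epilepsy_status",
    "exam",
    "treatment",
    "channel",
    "iceeg_segment",
    "seizure",
)

#: Default constrained vocabularies.  ``hospital`` is extensible via
#: :class:`CohortDB`'s ``extra_hospitals`` argument.
VOCABULARIES: dict[str, tuple[str, ...]] = {
    "hospital": ("UCLH", "GOSH"),
    "sex": ("M", "F"),
    "handedness": ("L", "R", "A"),
    "exam_type": ("icEEG", "MRI", "CT"),
    "treatment_type": ("epilepsy surgery",),
    "electrode_type": ("grid", "strip", "depth"),
    "reference": ("referential", "bipolar"),
    "wake_status": ("W", "N1", "N2", "N3", "R", "NA"),
    "seizure_type": ("focal", "subclin", "sg"),
    "hemisphere": ("left", "right"),
}

_BOOL_FIELDS = {
    "status_epilepticus",
    "complex_partial_seizures",
    "secondary_generalised_seizures",
    "is_resected",
    "is_spiking",
    "is_structurally_abnormal",
    "is_within_soz",
}


@dataclass(frozen=True)
class ClassSchema:
    required: tuple[str, ...]
    optional: tuple[str, ...]
    #: field name -> vocabulary key
    vocab: Mapping[str, str]
    #: tuple of field names whose combination must be unique
    unique: tuple[str, ...]
    #: field name -> referenced class
    references: Mapping[str, str]


SCHEMA: dict[str, ClassSchema] = {
    "subject": ClassSchema(
        required=("hospital", "subject_id"),
        optional=("dob", "sex", "handedness", "age_of_epilepsy_onset"),
        vocab={"hospital": "hospital", "sex": "sex", "handedness": "handedness"},
        unique=("hospital", "subject_id"),
        references={},
    ),
    "epilepsy_status": ClassSchema(
        required=("subject_id", "date_of_status"),
        optional=(
            "status_epilepticus",
            "complex_partial_seizures",
            "cps_monthly_frequency",
            "secondary_generalised_seizures",
            "sgs_monthly_frequency",
        ),
        vocab={},
        unique=("subject_id", "date_of_status"),
        references={"subject_id": "subject"},
    ),
    "exam": ClassSchema(
        required=("subject_id", "exam_id", "exam_type", "exam_date"),
        optional=(
            "iceeg_report_file_location",
            "raw_iceeg_folder_location",
            "pre_implantation_mri_file_location",
            "post_surgery_mri_file_location",
            "post_implantation_ct_file_location",
        ),
        vocab={"exam_type": "exam_type"},
        unique=("subject_id", "exam_id"),
        references={"subject_id": "subject"},
    ),
    "treatment": ClassSchema(
        required=("subject_id", "treatment_type", "treatment_date"),
        optional=(
            "outcome_ilae",
            "outcome_engel",
            "outcome_date",
            "surgery_type",
            "surgery_pathology",
            "surgery_hemisphere",
        ),
        vocab={"treatment_type": "treatment_type", "surgery_hemisphere": "hemisphere"},
        unique=("subject_id", "treatment_type", "treatment_date"),
        references={"subject_id": "subject"},
    ),
    "channel": ClassSchema(
        required=("subject_id", "exam_id", "channel_name"),
        optional=(
            "hemisphere",
            "electrode_type",
            "location",
            "roi_ids",
            "roi_names",
            "is_resected",
            "is_spiking",
            "is_structurally_abnormal",
            "is_within_soz",
        ),
        vocab={"hemisphere": "hemisphere", "electrode_type": "electrode_type"},
        unique=("exam_id", "channel_name"),
        references={"subject_id": "subject", "exam_id": "exam"},
    ),
    "iceeg_segment": ClassSchema(
        required=(
            "subject_id",
            "exam_id",
            "datetime",
            "duration",
            "sampling_frequency",
            "reference",
            "wake_status",
            "file_location",
        ),
        optional=("segment_number",),
        vocab={"reference": "reference", "wake_status": "wake_status"},
        unique=("exam_id", "datetime"),
        references={"subject_id": "subject", "exam_id": "exam"},
    ),
    "seizure": ClassSchema(
        required=("subject_id", "exam_id", "datetime"),
        optional=("duration", "type", "onset_channels"),
        vocab={"type": "seizure_type"},
        unique=("exam_id", "datetime"),
        references={"subject_id": "subject", "exam_id": "exam"},
    ),
}


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.field}: {self.message}"


class ValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


def _canonical(doc: Mapping[str, Any]) -> str:
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), default=str)


def document_id(class_name: str, doc: Mapping[str, Any]) -> str:
    """Deterministic id: content hash of the class name + required fields."""
    schema = SCHEMA[class_name]
    key = {f: doc.get(f) for f in schema.required}
    h = hashlib.sha256((class_name + _canonical(key)).encode()).hexdigest()
    return h[:16]


def _normalise_datetime(value: Any) -> str:
    """Compare date-times at second precision."""
    s = str(value)
    return s.split(".")[0]


class CohortDB:
    """In-memory document collection with JSON persistence."""

    def __init__(self, extra_hospitals: tuple[str, ...] = ("SYNH",)):
        self._docs: dict[str, dict[str, dict]] = {c: {} for c in CLASSES}
        self._unique: dict[str, set[tuple]] = {c: set() for c in CLASSES}
        self._vocab = dict(VOCABULARIES)
        self._vocab["hospital"] = tuple(VOCABULARIES["hospital"]) + tuple(extra_hospitals)
        self._extra_hospitals = tuple(extra_hospitals)

    # -- validation ---------------------------------------------------------
    def validate_document(self, doc: Mapping[str, Any], class_name: str) -> list[Violation]:
        """Return every violation (empty list when the document is valid)."""
        if class_name not in SCHEMA:
            raise KeyError(f"unknown document class {class_name!r}")
        schema = SCHEMA[class_name]
        violations: list[Violation] = []
        for f in schema.required:
            if f not in doc or doc[f] in (None, ""):
                violations.append(Violation(f, "required", "required field absent"))
        allowed = set(schema.required) | set(schema.optional)
        for f in doc:
            if f not in allowed:
                violations.append(Violation(f, "unknown_field", "not in schema"))
        for f, vkey in schema.vocab.items():
            if f in doc and doc[f] is not None and doc[f] not in self._vocab[vkey]:
                violations.append(
                    Violation(
                        f,
                        "vocabulary",
                        f"{doc[f]!r} not in {list(self._vocab[vkey])}",
                    )
                )
        for f in _BOOL_FIELDS & set(doc):
            if doc[f] is not None and not isinstance(doc[f], bool):
                violations.append(Violation(f, "type", "must be boolean"))
        # referential integrity
        if "subject_id" in schema.references and "subject_id" in doc:
            if not self._subject_exists(doc["subject_id"]):
                violations.append(
                    Violation("subject_id", "reference", f"unknown subject {doc['subject_id']!r}")
                )
        if "exam_id" in schema.references and "exam_id" in doc:
            if not self._exam_exists(doc.get("subject_id"), doc["exam_id"]):
                violations.append(
                    Violation("exam_id", "reference", f"unknown exam {doc['exam_id']!r}")
                )
        # uniqueness
        key = self._unique_key(class_name, doc)
        if None not in key and key in self._unique[class_name]:
            violations.append(
                Violation(
                    "+".join(SCHEMA[class_name].unique),
                    "uniqueness",
                    f"duplicate under unique rule {SCHEMA[class_name].unique}",
                )
            )
        return violations

    def _unique_key(self, class_name: str, doc: Mapping[str, Any]) -> tuple:
        parts = []
        for f in SCHEMA[class_name].unique:
            v = doc.get(f)
            if v is not None and f in ("datetime", "date_of_status", "treatment_date"):
                v = _normalise_datetime(v)
            parts.append(v)
        return tuple(parts)

    def _subject_exists(self, subject_id: Any) -> bool:
        return any(d["subject_id"] == subject_id for d in self._docs["subject"].values())

    def _exam_exists(self, subject_id: Any, exam_id: Any) -> bool:
        return any(
            d["exam_id"] == exam_id and (subject_id is None or d["subject_id"] == subject_id)
            for d in self._docs["exam"].values()
        )

    # -- mutation -----------------------------------------------------------
    def insert(self, class_name: str, doc: Mapping[str, Any]) -> str:
        violations = self.validate_document(doc, class_name)
        if violations:
            raise ValidationError(violations)
        doc_id = document_id(class_name, doc)
        self._docs[class_name][doc_id] = dict(doc)
        self._unique[class_name].add(self._unique_key(class_name, doc))
        return doc_id

    def fetch(self, class_name: str, doc_id: str) -> dict:
        return dict(self._docs[class_name][doc_id])

    def count(self, class_name: str) -> int:
        return len(self._docs[class_name])

    # -- queries ------------------------------------------------------------
    def _query(self, class_name: str, criteria: Mapping[str, Any]) -> list[dict]:
        schema = SCHEMA[class_name]
        allowed = set(schema.required) | set(schema.optional)
        for f in criteria:
            if f not in allowed:
                raise KeyError(f"unknown field {f!r} for class {class_name!r}")
        out = []
        for doc_id in sorted(self._docs[class_name]):
            doc = self._docs[class_name][doc_id]
            if all(_match(doc.get(f), v) for f, v in criteria.items()):
                out.append(dict(doc, _id=doc_id))
        return out

    def query_segments(self, criteria: Mapping[str, Any] | None = None) -> list[dict]:
        """Matching segments, each joined to its subject/exam context."""
        hits = self._query("iceeg_segment", criteria or {})
        exams = {d["exam_id"]: d for d in self._docs["exam"].values()}
        subjects = {d["subject_id"]: d for d in self._docs["subject"].values()}
        for h in hits:
            exam = exams.get(h["exam_id"], {})
            subj = subjects.get(h["subject_id"], {})
            h["hospital"] = subj.get("hospital")
            h["exam_date"] = exam.get("exam_date")
        return hits

    def query_channels(self, criteria: Mapping[str, Any] | None = None) -> list[dict]:
        return self._query("channel", criteria or {})

    def query(self, class_name: str, criteria: Mapping[str, Any] | None = None) -> list[dict]:
        if class_name not in SCHEMA:
            raise KeyError(f"unknown document class {class_name!r}")
        return self._query(class_name, criteria or {})

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for class_name in CLASSES:
            payload = {k: self._docs[class_name][k] for k in sorted(self._docs[class_name])}
            (directory / f"{class_name}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True, default=str)
            )
        meta = {"extra_hospitals": list(self._extra_hospitals)}
        (directory / "dbmeta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "CohortDB":
        directory = Path(directory)
        meta_path = directory / "dbmeta.json"
        extra = ("SYNH",)
        if meta_path.exists():
            extra = tuple(json.loads(meta_path.read_text()).get("extra_hospitals", []))
        db = cls(extra_hospitals=extra)
        # insert in dependency order so references resolve
        for class_name in CLASSES:
            path = directory / f"{class_name}.json"
            if not path.exists():
                continue
            for doc in json.loads(path.read_text()).values():
                db.insert(class_name, doc)
        return db

    def content_digest(self) -> str:
        blob = json.dumps(
            {c: {k: self._docs[c][k] for k in sorted(self._docs[c])} for c in CLASSES},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def _match(value: Any, criterion: Any) -> bool:
    if callable(criterion):
        return bool(criterion(value))
    return value == criterion
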