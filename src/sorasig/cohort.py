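"""Patient cohorts and the RECIST -> binary response mapping.

Sorafenib response is recorded per patient with RECIST categories
(complete response CR, partial response PR, stable disease SD,
progressive disease PD).  The pipeline collapses these to a binary
label: PD is a *poor responder*, PR and SD are *responders*.  CR --
never observed in the cohorts this package ships -- is mapped to
responder with a warning, since a complete response cannot be a worse
outcome than a partial one.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Union

import pandas as pd

from .errors import DataError, DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "Recist",
    "ResponseLabel",
    "Platform",
    "PatientRecord",
    "CohortAnnotation",
    "classify_recist",
    "parse_recist",
    "load_annotation",
    "cohort_summary",
]


class Recist(str, Enum):
    """RECIST best-response category."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


class ResponseLabel(str, Enum):
    RESPONDER = "responder"
    POOR_RESPONDER = "poor_responder"


class Platform(str, Enum):
    MICROARRAY = "microarray"
    RNASEQ_COUNTS = "rnaseq_counts"
    PCR_CT = "pcr_ct"


#: accepted spellings (lower-cased) for each RECIST category
_RECIST_ALIASES = {
    "cr": Recist.CR,
    "complete response": Recist.CR,
    "pr": Recist.PR,
    "partial response": Recist.PR,
    "sd": Recist.SD,
    "stable disease": Recist.SD,
    "pd": Recist.PD,
    "progressive disease": Recist.PD,
}


def parse_recist(token: str) -> Recist:
    """Parse a RECIST status string (case-insensitive; full names or
    two-letter codes).  Anything else raises rather than guesses."""
    key = str(token).strip().lower()
    try:
        return _RECIST_ALIASES[key]
    except KeyError:
        raise DataError(f"unrecognized RECIST response status: {token!r}") from None


def classify_recist(status: Union[Recist, str]) -> ResponseLabel:
    """Map a RECIST category to the binary response label.

    PD -> poor_responder; PR and SD -> responder.  CR -> responder with
    a warning (a strictly better outcome than PR cannot be a poor
    response; no CR was observed in the cohorts shipped here).
    """
    if not isinstance(status, Recist):
        status = parse_recist(status)
    if status is Recist.PD:
        return ResponseLabel.POOR_RESPONDER
    if status is Recist.CR:
        warnings.warn(
            "RECIST 'Complete response' encountered; mapped to responder "
            "(convention: CR is a strictly better outcome than PR)",
            stacklevel=2,
        )
    return ResponseLabel.RESPONDER


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    response_status: Recist
    age: int
    sex: str  # "male" | "female"
    t_stage: str = ""
    n_stage: str = ""
    m_stage: str = ""
    grade: str = ""

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise DataError(f"patient {self.patient_id}: age must be positive")
        if self.sex not in ("male", "female"):
            raise DataError(f"patient {self.patient_id}: sex must be male/female, got {self.sex!r}")

    @property
    def label(self) -> ResponseLabel:
        return classify_recist(self.response_status)


@dataclass
class CohortAnnotation:
    """Ordered patient collection with derived binary labels."""

    records: list[PatientRecord]
    platform: Platform | None = None

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> pd.Series:
        """Binary label per sample id, in cohort order."""
        return pd.Series(
            [r.label.value for r in self.records], index=self.sample_ids, name="label"
        )

    @property
    def is_responder(self) -> pd.Series:
        return self.labels == ResponseLabel.RESPONDER.value

    def subset(self, sample_ids: list[str]) -> "CohortAnnotation":
        by_id = {r.patient_id: r for r in self.records}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise DataError(f"sample ids absent from annotation: {missing}")
        return CohortAnnotation([by_id[s] for s in sample_ids], platform=self.platform)


_REQUIRED_COLUMNS = ("patient_id", "response", "age", "sex")


def _read_delimited(source: Union[str, Path, io.IOBase]) -> pd.DataFrame:
    """TSV by default; falls back to comma if the header has no tabs."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    header = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(io.StringIO(text), sep=sep, dtype=str).rename(
        columns=lambda c: c.strip().lower()
    )


def load_annotation(
    source: Union[str, Path, io.IOBase],
    platform: Platform | str | None = None,
) -> CohortAnnotation:
    """Load a per-sample annotation table.

    Expected columns: patient_id, response, age, sex; optional
    t_stage/n_stage/m_stage/grade are carried through uninterpreted.
    """
    df = _read_delimited(source)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"annotation table missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]).strip(),
                response_status=parse_recist(row["response"]),
                age=int(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                t_stage=str(row.get("t_stage", "") or ""),
                n_stage=str(row.get("n_stage", "") or ""),
                m_stage=str(row.get("m_stage", "") or ""),
                grade=str(row.get("grade", "") or ""),
            )
        )
    if platform is not None:
        platform = Platform(platform)
    logger.info("cohort: loaded %d patient records", len(records))
    return CohortAnnotation(records, platform=platform)


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cohort_summary(annotation: CohortAnnotation) -> dict:
    """Counts and descriptive statistics for reporting.

    ``age_mean_reported`` is the mean age rounded half-up to an integer
    (the style used in clinical summaries); ``age_mean`` is the raw value.
    """
    if len(annotation) == 0:
        raise DegenerateDataError("cannot summarize an empty cohort")
    recs = annotation.records
    ages = [r.age for r in recs]
    labels = [r.label for r in recs]
    n_resp = sum(1 for l in labels if l is ResponseLabel.RESPONDER)
    mean_age = sum(ages) / len(ages)
    return {
        "n_total": len(recs),
        "n_responder": n_resp,
        "n_poor": len(recs) - n_resp,
        "n_male": sum(1 for r in recs if r.sex == "male"),
        "n_female": sum(1 for r in recs if r.sex == "female"),
        "age_min": min(ages),
        "age_max": max(ages),
        "age_mean": mean_age,
        "age_mean_reported": _round_half_up(mean_age),
    }
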