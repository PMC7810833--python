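"""Subject-level metadata shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

GROUPS = ("control", "patient")
SEXES = ("M", "F")


@dataclass
class SubjectRecord:
    """Demographics, group label and clinical scores for one subject.

    Clinical fields (``duration_years``, ``n_aeds``, ``qolie31``, ``lsss``)
    are only populated for patients; they stay ``None`` for controls.
    """

    subject_id: str
    age: float
    sex: str
    group: str
    duration_years: Optional[float] = None
    n_aeds: Optional[int] = None
    qolie31: Optional[float] = None
    lsss: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
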