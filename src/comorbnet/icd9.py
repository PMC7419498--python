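"""ICD-9-CM code normalisation and organ-system chapter classification.

Diagnoses are identified by their 3-digit ICD-9-CM category (the first three
digits of a 3-5 digit code), and each 3-digit category belongs to exactly one
of 18 organ-system chapters.  The chapter boundary table is bundled as a
delimited file and can be overridden for sensitivity analyses.  Chapter 17
(symptoms, signs and ill-defined conditions, 780-799) is flagged for
exclusion from comorbidity analysis.

The nervous system (chapter 6, 320-359) and sense organs (chapter 7,
360-389) are kept as separate chapters even though ICD-9-CM formally groups
320-389 together, because the 18-class organ-system scheme used downstream
distinguishes them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Icd9Chapter",
    "Icd9CodeError",
    "SYMPTOM_CHAPTER",
    "chapter_name",
    "chapter_of",
    "load_chapters",
    "truncate",
    "try_truncate",
]

#: chapter excluded from comorbidity analysis (general symptoms, 780-799)
SYMPTOM_CHAPTER = 17

_CODE_RE = re.compile(r"^(\d{3})(?:\.?\d{0,2})?$")


class Icd9CodeError(ValueError):
    """Raised for V/E-prefixed or otherwise malformed ICD-9 codes."""


@dataclass(frozen=True)
class Icd9Chapter:
    """One organ-system chapter: an inclusive range of 3-digit categories."""

    chapter_id: int
    name: str
    lo: int
    hi: int

    @property
    def excluded_from_comorbidity(self) -> bool:
        return self.chapter_id == SYMPTOM_CHAPTER

    def __contains__(self, code3: str | int) -> bool:
        return self.lo <= int(code3) <= self.hi


def load_chapters(path: str | Path | None = None) -> list[Icd9Chapter]:
    """Load the chapter boundary table (bundled TSV by default).

    The table must partition 001-999 into non-overlapping inclusive ranges;
    this is validated on load.
    """
    if path is None:
        ref = resources.files("comorbnet.data").joinpath("icd9_chapters.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep=None, engine="python")
    chapters = [
        Icd9Chapter(int(r.chapter_id), str(r.name), int(r.lo), int(r.hi))
        for r in table.itertuples(index=False)
    ]
    chapters.sort(key=lambda c: c.lo)
    if chapters[0].lo != 1 or chapters[-1].hi != 999:
        raise ValueError("chapter table must span 001-999")
    for a, b in zip(chapters, chapters[1:]):
        if b.lo != a.hi + 1:
            raise ValueError(f"chapter ranges must tile 001-999; gap/overlap at {a.hi}/{b.lo}")
    return chapters


_DEFAULT_CHAPTERS = load_chapters()
_CHAPTER_BY_CODE = {
    code: ch.chapter_id for ch in _DEFAULT_CHAPTERS for code in range(ch.lo, ch.hi + 1)
}
_NAME_BY_ID = {ch.chapter_id: ch.name for ch in _DEFAULT_CHAPTERS}


def truncate(code: str) -> str:
    """Normalise an ICD-9-CM code to its 3-digit category, zero-padded.

    >>> truncate("250.00")
    '250'
    >>> truncate("401.1")
    '401'

    Raises :class:`Icd9CodeError` for V-codes, E-codes and malformed input;
    callers in the ingest stage drop and count those.
    """
    text = str(code).strip()
    m = _CODE_RE.match(text)
    if m is None:
        raise Icd9CodeError(f"not a numeric ICD-9-CM code: {code!r}")
    return m.group(1)


def try_truncate(code: str) -> str | None:
    """:func:`truncate`, returning ``None`` instead of raising."""
    try:
        return truncate(code)
    except Icd9CodeError:
        return None


def chapter_of(code3: str | int, chapters: list[Icd9Chapter] | None = None) -> int:
    """Map a 3-digit category (001-999) to its chapter id (1-18)."""
    value = int(code3)
    if chapters is None:
        try:
            return _CHAPTER_BY_CODE[value]
        except KeyError:
            raise ValueError(f"code {code3!r} outside 001-999") from None
    for ch in chapters:
        if value in ch:
            return ch.chapter_id
    raise ValueError(f"code {code3!r} outside 001-999")


def chapter_name(chapter_id: int) -> str:
    return _NAME_BY_ID[chapter_id]
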