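"""Fraction of functionally-unknown proteins per genome and its group test.

A protein counts as functionally unknown when its annotation contains at
least one of eight keywords ("hypothetical", "predicted", "putative",
"unknown", "-related", "-family", "-like", "probable") as a case-insensitive
substring; the hyphen is significant for the hyphenated keywords, so
"flagellin-like" matches but "unlikely" does not.  Per-genome fractions are
compared across the three oxygen-requirement classes with a Kruskal–Wallis
test — a difference here would mean network annotations are systematically
less complete in one class, confounding the network metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats as st

from .errors import ValidationError

UNKNOWN_KEYWORDS = (
    "hypothetical",
    "predicted",
    "putative",
    "unknown",
    "-related",
    "-family",
    "-like",
    "probable",
)


@dataclass(frozen=True)
class UnknownFractionRecord:
    organism_id: str
    n_proteins: int
    n_unknown: int
    fraction: float


def is_unknown(
    annotation: str,
    keywords: Sequence[str] = UNKNOWN_KEYWORDS,
    case_sensitive: bool = False,
) -> bool:
    text = annotation if case_sensitive else annotation.lower()
    kws = keywords if case_sensitive else [k.lower() for k in keywords]
    return any(k in text for k in kws)


def unknown_fraction(
    annotations: Iterable[str],
    organism_id: str = "",
    keywords: Sequence[str] = UNKNOWN_KEYWORDS,
    case_sensitive: bool = False,
) -> UnknownFractionRecord:
    """Fraction of a genome's proteins whose annotation matches a keyword."""
    annotations = list(annotations)
    if not annotations:
        raise ValidationError("annotation list is empty")
    n_unknown = sum(is_unknown(a, keywords, case_sensitive) for a in annotations)
    return UnknownFractionRecord(
        organism_id=organism_id,
        n_proteins=len(annotations),
        n_unknown=n_unknown,
        fraction=n_unknown / len(annotations),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal–Wallis H with midrank tie correction.

    Returns (H, degrees of freedom, chi-square p).  Complete ties across all
    observations give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least 2 values")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = st.kruskal(*arrays)
    return float(h), df, float(p)
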