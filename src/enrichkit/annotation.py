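"""Keyword mining over homology-annotation tables and length profiling."""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatchMode",
    "AnnotationRecord",
    "KeywordSet",
    "DEFAULT_SEX_KEYWORDS",
    "keyword_select",
    "length_annotation_profile",
    "category_counts",
]

# The study's keyword rule for predicting sex-related genes.
DEFAULT_SEX_KEYWORDS = ("sex", "egg", "ovary", "sperm", "testis", "female", "male")


class MatchMode(str, enum.Enum):
    WORD = "word"
    SUBSTRING = "substring"


@dataclass(frozen=True)
class AnnotationRecord:
    contig_id: str
    description: str = ""
    length_bp: int = 1
    go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(
                f"contig {self.contig_id!r}: length_bp must be >= 1, "
                f"got {self.length_bp}"
            )


@dataclass(frozen=True)
class KeywordSet:
    """Ordered lowercase keywords plus the matching mode.

    Word mode tokenises the description on non-alphanumeric boundaries
    (hyphens split: "testis-specific" yields "testis") and tolerates a
    naive plural: "eggs" matches the keyword "egg".  It does not stem
    beyond that, so "sexual" does NOT match "sex" in word mode; substring
    mode would match it.
    """

    keywords: tuple[str, ...] = DEFAULT_SEX_KEYWORDS
    match_mode: MatchMode = MatchMode.WORD

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword set must be non-empty")
        lowered = tuple(k.lower() for k in self.keywords)
        if len(set(lowered)) != len(lowered):
            raise ValueError("keyword set contains duplicates")
        object.__setattr__(self, "keywords", lowered)
        if isinstance(self.match_mode, str) and not isinstance(
            self.match_mode, MatchMode
        ):
            object.__setattr__(self, "match_mode", MatchMode(self.match_mode))

    def matches(self, text: str) -> tuple[str, ...]:
        """Keywords firing on ``text``, in keyword-set order."""
        if not text:
            return ()
        low = text.lower()
        if self.match_mode is MatchMode.SUBSTRING:
            return tuple(k for k in self.keywords if k in low)
        tokens = set(re.split(r"[^a-z0-9]+", low))
        tokens.discard("")
        # naive plural tolerance: "eggs" -> "egg"
        tokens |= {t[:-1] for t in tokens if t.endswith("s") and len(t) > 1}
        return tuple(k for k in self.keywords if k in tokens)


def keyword_select(
    records: Iterable[AnnotationRecord],
    keys: KeywordSet | None = None,
    include_go_terms: bool = False,
) -> list[tuple[AnnotationRecord, tuple[str, ...]]]:
    """Records whose description matches any keyword, with the hits listed.

    Matching is case-insensitive on the description; ``include_go_terms``
    extends it to GO term names.  Output preserves input order and is
    idempotent (a subset of the input).
    """
    keys = keys or KeywordSet()
    selected = []
    for rec in records:
        text = rec.description
        if include_go_terms and rec.go_terms:
            text = " ".join([text, *rec.go_terms])
        hits = keys.matches(text)
        if hits:
            selected.append((rec, hits))
    return selected


def length_annotation_profile(
    records: Sequence[AnnotationRecord],
    annotated: Mapping[str, bool] | Callable[[AnnotationRecord], bool] | None = None,
    bin_width_bp: int = 100,
) -> pd.DataFrame:
    """Fraction of annotated contigs per length bin.

    ``annotated`` may be a contig_id -> bool mapping, a predicate, or None
    (then a record counts as annotated iff its description is non-empty).
    Bins of ``bin_width_bp`` (>= 50) cover [min length, max length]; bin
    counts sum to the number of records.
    """
    if bin_width_bp < 50:
        raise ValueError(f"bin_width_bp must be >= 50, got {bin_width_bp}")
    if not records:
        return pd.DataFrame(
            columns=["bin_start", "bin_end", "n_contigs", "n_annotated", "fraction"]
        )
    if annotated is None:
        flag = lambda r: bool(r.description.strip())
    elif callable(annotated):
        flag = annotated
    else:
        flag = lambda r: bool(annotated.get(r.contig_id, False))

    lengths = np.array([r.length_bp for r in records])
    flags = np.array([flag(r) for r in records], dtype=bool)
    start = (lengths.min() // bin_width_bp) * bin_width_bp
    edges = np.arange(start, lengths.max() + bin_width_bp, bin_width_bp)
    if edges[-1] <= lengths.max():
        edges = np.append(edges, edges[-1] + bin_width_bp)
    which = np.digitize(lengths, edges) - 1

    rows = []
    for b in range(len(edges) - 1):
        in_bin = which == b
        n = int(in_bin.sum())
        k = int(flags[in_bin].sum())
        rows.append(
            {
                "bin_start": int(edges[b]),
                "bin_end": int(edges[b + 1]),
                "n_contigs": n,
                "n_annotated": k,
                "fraction": k / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def category_counts(
    records: Iterable[AnnotationRecord],
    category_keyword_map: Mapping[str, KeywordSet | Sequence[str]]
    | Iterable[tuple[str, KeywordSet | Sequence[str]]],
    include_go_terms: bool = False,
) -> dict[str, int]:
    """Distinct contigs matching each functional category's keyword set.

    A contig may count in several categories but at most once per
    category.  Category names must be unique (case-insensitively).
    """
    pairs = (
        list(category_keyword_map.items())
        if isinstance(category_keyword_map, Mapping)
        else list(category_keyword_map)
    )
    names = [name.lower() for name, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("category names overlap (case-insensitively)")

    records = list(records)
    counts: dict[str, int] = {}
    for name, keys in pairs:
        if not isinstance(keys, KeywordSet):
            keys = KeywordSet(keywords=tuple(keys))
        counts[name] = len(
            {
                rec.contig_id
                for rec, _ in keyword_select(
                    records, keys, include_go_terms=include_go_terms
                )
            }
        )
    return counts
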