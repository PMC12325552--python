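"""Two-character compound lexicons, frequency filtering, and family size.

A compound entry carries the compound token, its first and second
constituent characters (C1, C2), and three raw corpus frequency counts
(whole word, C1, C2).  The frequency filter mirrors the exclusion used
when preparing the composition-model training set: items whose whole-word
frequency *or* either constituent frequency falls at or below the
threshold are dropped.  Positional family size — the number of compounds
sharing a character at a given position — is the lexicon's second job;
it is normally computed on the full pre-filter lexicon, since it is a
property of the corpus rather than of the filtered training set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundEntry",
    "CompoundLexicon",
    "FilterReport",
    "apply_frequency_filter",
    "family_size",
    "read_lexicon",
    "write_lexicon",
]

LEXICON_COLUMNS = ["compound", "c1", "c2", "word_freq", "c1_freq", "c2_freq"]


class LexiconIntegrityError(ValueError):
    """A row violates the compound = c1 + c2 identity or duplicates another."""


@dataclass(frozen=True)
class CompoundEntry:
    compound: str
    c1: str
    c2: str
    word_freq: int
    c1_freq: int
    c2_freq: int

    def __post_init__(self) -> None:
        if self.compound != self.c1 + self.c2:
            raise LexiconIntegrityError(
                f"compound {self.compound!r} != c1+c2 ({self.c1!r}+{self.c2!r})"
            )
        for name in ("word_freq", "c1_freq", "c2_freq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for {self.compound!r}")


class CompoundLexicon:
    """Ordered collection of unique compound entries with position indices."""

    def __init__(self, entries: list[CompoundEntry]):
        seen: set[str] = set()
        for e in entries:
            if e.compound in seen:
                raise LexiconIntegrityError(f"duplicate compound {e.compound!r}")
            seen.add(e.compound)
        self.entries: list[CompoundEntry] = list(entries)
        # (character, position) -> set of compound tokens
        self._index: dict[tuple[str, int], set[str]] = {}
        for e in self.entries:
            self._index.setdefault((e.c1, 1), set()).add(e.compound)
            self._index.setdefault((e.c2, 2), set()).add(e.compound)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, compound: str) -> bool:
        return any(e.compound == compound for e in self.entries)

    def get(self, compound: str) -> CompoundEntry | None:
        for e in self.entries:
            if e.compound == compound:
                return e
        return None

    def family_size(self, character: str, position: int) -> int:
        if position not in (1, 2):
            raise ValueError(f"position must be 1 or 2, got {position}")
        return len(self._index.get((character, position), set()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.compound, e.c1, e.c2, e.word_freq, e.c1_freq, e.c2_freq) for e in self.entries],
            columns=LEXICON_COLUMNS,
        )


def family_size(lexicon: CompoundLexicon, character: str, position: int) -> int:
    """Number of distinct compounds with `character` at `position` (1 or 2)."""
    return lexicon.family_size(character, position)


@dataclass
class FilterReport:
    n_before: int
    n_after: int
    threshold: int

    @property
    def drop_rate_percent(self) -> float:
        return round(100.0 * (1.0 - self.n_after / self.n_before), 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_before": self.n_before,
                "n_after": self.n_after,
                "threshold": self.threshold,
                "drop_rate_percent": self.drop_rate_percent,
            }
        )


def apply_frequency_filter(
    lexicon: CompoundLexicon,
    threshold: int,
    boundary: str = "exclusive",
) -> tuple[CompoundLexicon, FilterReport]:
    """Drop low-frequency entries; return the survivors and a report.

    With ``boundary="exclusive"`` (default) an entry survives iff all of
    word_freq, c1_freq, c2_freq are strictly greater than ``threshold``,
    i.e. items with frequency <= threshold are excluded.  The
    ``"inclusive"`` alternative keeps frequency == threshold.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if boundary not in ("exclusive", "inclusive"):
        raise ValueError(f"boundary must be 'exclusive' or 'inclusive', got {boundary!r}")
    if len(lexicon) == 0:
        raise ValueError("cannot filter an empty lexicon (drop rate undefined)")

    if boundary == "exclusive":
        keep = lambda e: e.word_freq > threshold and e.c1_freq > threshold and e.c2_freq > threshold
    else:
        keep = lambda e: e.word_freq >= threshold and e.c1_freq >= threshold and e.c2_freq >= threshold

    survivors = [e for e in lexicon if keep(e)]
    report = FilterReport(n_before=len(lexicon), n_after=len(survivors), threshold=threshold)
    logger.info(
        "frequency filter (>%d): %d -> %d entries (drop rate %.1f%%)",
        threshold, report.n_before, report.n_after, report.drop_rate_percent,
    )
    return CompoundLexicon(survivors), report


def read_lexicon(path: str | Path) -> CompoundLexicon:
    """Read a lexicon TSV with columns compound, c1, c2, word_freq, c1_freq, c2_freq."""
    df = pd.read_csv(path, sep="\t", dtype={"compound": str, "c1": str, "c2": str})
    missing = [c for c in LEXICON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(
                CompoundEntry(
                    compound=row.compound, c1=row.c1, c2=row.c2,
                    word_freq=int(row.word_freq), c1_freq=int(row.c1_freq),
                    c2_freq=int(row.c2_freq),
                )
            )
        except LexiconIntegrityError as exc:
            raise LexiconIntegrityError(f"{path}: row {i}: {exc}") from exc
    return CompoundLexicon(entries)


def write_lexicon(lexicon: CompoundLexicon, path: str | Path) -> None:
    lexicon.to_frame().to_csv(path, sep="\t", index=False)
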