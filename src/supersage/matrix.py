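"""Tag-count matrices and per-library summaries.

The central container of a SAGE/SuperSAGE experiment is the tag x library
count table.  Rows are unique 22-nt tag sequences (the printed form, with
the CATG anchor stripped), columns are sequencing libraries, entries are
the number of times a tag was extracted from that library's ditag reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percent

#: Abundance bins of the per-library unitag summary: singletons, 2-4,
#: 5-9, 10-100 (inclusive) and >100 copies.  The bins partition [1, inf).
ABUNDANCE_BINS: tuple[tuple[int, float], ...] = (
    (1, 1),
    (2, 4),
    (5, 9),
    (10, 100),
    (101, float("inf")),
)

ABUNDANCE_LABELS: tuple[str, ...] = ("1", "2-4", "5-9", "10-100", ">100")


class TagCountMatrix:
    """Tag x library count table backed by a pandas DataFrame.

    Parameters
    ----------
    counts
        DataFrame indexed by tag sequence with one integer column per
        library, or a mapping usable to build one.
    """

    def __init__(self, counts: pd.DataFrame | Mapping) -> None:
        df = pd.DataFrame(counts)
        if df.index.has_duplicates:
            raise ValueError("duplicate tag rows in count matrix")
        if (df.values < 0).any():
            raise ValueError("negative counts")
        lengths = {len(t) for t in df.index}
        if len(lengths) > 1:
            raise ValueError("tag strings must have uniform length")
        self.counts = df.astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def tags(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Per-library total tag counts (column sums)."""
        return self.counts.sum(axis=0)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        """Label-based equality: same tags, libraries and counts."""
        if not isinstance(other, TagCountMatrix):
            return NotImplemented
        if set(self.counts.columns) != set(other.counts.columns):
            return False
        a = self.counts.sort_index()
        b = other.counts.sort_index()[a.columns]
        return a.shape == b.shape and a.equals(b)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.counts.reset_index().rename(columns={"index": "tag"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TagCountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str})
        return cls(df.set_index("tag"))


@dataclass
class LibrarySummary:
    """Per-library accounting of extracted tags and unitag abundance."""

    library: str
    total_tags: int
    unitags: int
    pct_unitags: float
    abundance_classes: dict[str, int] = field(default_factory=dict)


def summarize_library(matrix: TagCountMatrix, library: str) -> LibrarySummary:
    """Summarise one library: totals, unitags and abundance-class counts.

    A unitag is a distinct tag sequence with count >= 1 in the library;
    ``pct_unitags`` is 100 * unitags / total tags rounded to one decimal.
    """
    if library not in matrix.counts.columns:
        raise KeyError(f"unknown library: {library!r}")
    col = matrix.counts[library].values
    col = col[col > 0]
    total = int(col.sum())
    unitags = int(len(col))
    classes: dict[str, int] = {}
    for (lo, hi), label in zip(ABUNDANCE_BINS, ABUNDANCE_LABELS):
        classes[label] = int(((col >= lo) & (col <= hi)).sum())
    return LibrarySummary(
        library=library,
        total_tags=total,
        unitags=unitags,
        pct_unitags=percent(unitags, total),
        abundance_classes=classes,
    )


def summarize_all(matrix: TagCountMatrix) -> list[LibrarySummary]:
    return [summarize_library(matrix, lib) for lib in matrix.libraries]


def pooled_abundance(summaries: Iterable[LibrarySummary]) -> pd.DataFrame:
    """Pool abundance-class counts over libraries.

    Returns a frame indexed by abundance class with the summed unitag
    count per class and the percentage each class represents of all
    pooled unitags (one decimal, matching printed summary tables).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to pool")
    totals = {
        label: sum(s.abundance_classes.get(label, 0) for s in summaries)
        for label in ABUNDANCE_LABELS
    }
    grand = sum(totals.values())
    frame = pd.DataFrame(
        {
            "unitags": [totals[label] for label in ABUNDANCE_LABELS],
            "pct": [percent(totals[label], grand) for label in ABUNDANCE_LABELS],
        },
        index=list(ABUNDANCE_LABELS),
    )
    return frame


def summaries_to_frame(summaries: Sequence[LibrarySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "library": s.library,
            "total_tags": s.total_tags,
            "unitags": s.unitags,
            "pct_unitags": s.pct_unitags,
        }
        row.update({f"class_{k}": v for k, v in s.abundance_classes.items()})
        rows.append(row)
    return pd.DataFrame(rows)
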