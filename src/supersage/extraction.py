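"""Ditag read QC and mono-tag extraction.

Raw pyrosequencing reads carry a library-identifying linker at both ends
of a ditag (two 26-nt tags joined tail-to-tail, the downstream one
reverse-complemented).  Extraction applies the stringent quality-control
filters — full linker match at both ends, no linker sequence inside the
ditag, no ambiguous bases, and removal of duplicated ditags within a
library — then splits each passing ditag into two sense-strand 26-nt
tags anchored by CATG and accumulates counts keyed by the 22-nt printed
tag form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._util import ANCHOR, TAG_LEN, revcomp
from .matrix import TagCountMatrix

QC_STATUSES = (
    "pass",
    "duplicate",
    "incomplete_linker",
    "internal_linker",
    "ambiguous_base",
)


@dataclass
class DitagRead:
    read_id: str
    sequence: str
    library: str | None
    qc_status: str


def demultiplex_and_filter(
    reads: Iterable[tuple[str, str]],
    linkers: Mapping[str, str],
) -> Iterator[DitagRead]:
    """Assign each raw read to a library and set its QC status.

    ``reads`` yields (read id, sequence) pairs; ``linkers`` maps library
    names to their linker/barcode strings.  A read passes only when
    exactly one library's linker fully matches at both ends, the region
    between the linkers contains neither any linker sequence nor a
    character outside ACGT, and no byte-identical read was seen earlier
    in the same library (later copies are flagged ``duplicate``).
    """
    linkers = dict(linkers)
    if not linkers or any(not l for l in linkers.values()):
        raise ValueError("linkers must be nonempty")
    if len(set(linkers.values())) != len(linkers):
        raise ValueError("linkers must be mutually distinct")
    seen: dict[str, set[str]] = {lib: set() for lib in linkers}

    for read_id, seq in reads:
        seq = seq.upper()
        matches = [lib for lib, lk in linkers.items() if seq.startswith(lk)]
        if len(matches) != 1:
            yield DitagRead(read_id, seq, None, "incomplete_linker")
            continue
        lib = matches[0]
        lk = linkers[lib]
        if len(seq) < 2 * len(lk) or not seq.endswith(lk):
            yield DitagRead(read_id, seq, lib, "incomplete_linker")
            continue
        interior = seq[len(lk):len(seq) - len(lk)]
        if any(other in interior for other in linkers.values()):
            yield DitagRead(read_id, seq, lib, "internal_linker")
            continue
        if any(c not in "ACGT" for c in interior):
            yield DitagRead(read_id, seq, lib, "ambiguous_base")
            continue
        if seq in seen[lib]:
            yield DitagRead(read_id, seq, lib, "duplicate")
            continue
        seen[lib].add(seq)
        yield DitagRead(read_id, seq, lib, "pass")


def extract_monotags(
    ditags: Iterable[DitagRead],
    linkers: Mapping[str, str],
    libraries: Iterable[str] | None = None,
) -> tuple[TagCountMatrix, int]:
    """Split QC-passing ditags into mono-tags and count them per library.

    The interior of a read must be one tag (26 nt) or a full ditag
    (52 nt); the downstream tag is reverse-complemented back to the
    sense strand.  Every tag must begin with the CATG anchor; reads
    violating length or anchor rules are discarded and tallied in the
    returned rejects count.  Counts are keyed by the 22-nt tag core.
    """
    counts: dict[str, dict[str, int]] = {}
    rejects = 0
    libs_seen: list[str] = []
    for dt in ditags:
        if dt.qc_status != "pass":
            raise ValueError("extract_monotags expects only QC-passing reads")
        lk = linkers[dt.library]
        interior = dt.sequence[len(lk):len(dt.sequence) - len(lk)]
        if len(interior) == TAG_LEN:
            tags = [interior]
        elif len(interior) == 2 * TAG_LEN:
            tags = [interior[:TAG_LEN], revcomp(interior[TAG_LEN:])]
        else:
            rejects += 1
            continue
        if any(not t.startswith(ANCHOR) for t in tags):
            rejects += 1
            continue
        if dt.library not in counts:
            counts[dt.library] = {}
            libs_seen.append(dt.library)
        lib_counts = counts[dt.library]
        for t in tags:
            core = t[len(ANCHOR):]
            lib_counts[core] = lib_counts.get(core, 0) + 1

    columns = list(libraries) if libraries is not None else libs_seen
    for lib in counts:
        if lib not in columns:
            columns.append(lib)
    series = {lib: pd.Series(counts.get(lib, {}), dtype=float) for lib in columns}
    frame = pd.DataFrame(series).fillna(0).astype(int)
    frame = frame.sort_index()
    return TagCountMatrix(frame), rejects


def extract_from_reads(
    reads: Iterable[tuple[str, str]],
    linkers: Mapping[str, str],
    libraries: Iterable[str] | None = None,
) -> tuple[TagCountMatrix, pd.Series, int]:
    """Full extraction: demultiplex, QC-filter, count mono-tags.

    Returns the count matrix, the tally of reads per QC status, and the
    number of passing reads rejected at the tag-splitting step.
    """
    status_tally = {s: 0 for s in QC_STATUSES}
    passing = []
    for dt in demultiplex_and_filter(reads, linkers):
        status_tally[dt.qc_status] += 1
        if dt.qc_status == "pass":
            passing.append(dt)
    matrix, rejects = extract_monotags(passing, linkers, libraries)
    return matrix, pd.Series(status_tally), rejects
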