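"""Exact-match tag-to-DNA annotation with antisense detection.

A 26-nt tag (CATG anchor + 22-nt core) is mapped to three reference DNA
collections — curated cDNAs, genome-predicted cDNAs and the genome
itself — by exact substring search on both strands.  At the default
stringency every one of the 26 nucleotides must match (a perfect-match
rule under which exact search and an alignment search are equivalent by
definition); a reduced 24/24 mode matches the 5'-most 24 nt (anchor +
20), tolerating distal mismatches from sequencing errors or SNPs.

Protein identity is then taken from a precomputed DNA-to-protein table
(BLASTX-style: DNA id, E-value, alignment orientation, GO terms) with
the hierarchical preference curated cDNA > predicted cDNA > genome
upstream fragment, accepting E < 1e-5 for identity and E < 1e-10 for GO
transfer.  A tag whose DNA-match orientation disagrees with the
DNA-to-protein orientation is flagged as a putative natural antisense
transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ANCHOR, TAG_LEN, is_dna, percent, revcomp

DATASET_PREFERENCE = ("ncbi_cdna", "ensembl_cdna", "genome")

E_IDENTITY = 1e-5
E_GO = 1e-10


@dataclass
class TagHit:
    tag: str
    dataset: str
    seq_id: str
    start: int  # 0-based, half-open interval of the match
    end: int
    strand: str  # "+" | "-"


@dataclass
class ProteinAssignment:
    protein_id: str
    evalue: float
    dataset: str
    dna_id: str
    orientation: str
    gene_symbol: str
    go_terms: tuple[str, ...] = ()


@dataclass
class AnnotationRecord:
    tag: str
    hits: list[TagHit] = field(default_factory=list)
    assignment: ProteinAssignment | None = None
    status: str = "unannotated"  # annotated_protein | anonymous_dna | unannotated
    antisense: bool = False
    ambiguous: bool = False  # >1 distinct genomic location
    gene_symbol: str = ""

    @property
    def n_genomic_locations(self) -> int:
        return len({(h.seq_id, h.start, h.strand) for h in self.hits if h.dataset == "genome"})


class TagIndex:
    """Exact k-mer index of a DNA collection, both strands queryable.

    Positions containing characters outside ACGT are skipped, so
    ambiguity codes in the reference never match a query.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = TAG_LEN) -> None:
        self.k = k
        self.sequences = dict(sequences)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in self.sequences.items():
            seq = seq.upper()
            clean = np.frombuffer(seq.encode(), dtype=np.uint8)
            ok = (
                (clean == ord("A")) | (clean == ord("C"))
                | (clean == ord("G")) | (clean == ord("T"))
            )
            bad = np.where(~ok)[0]
            next_bad = np.full(len(seq) + 1, len(seq))
            # next_bad[i]: first non-ACGT position >= i
            ptr = len(seq)
            for i in range(len(seq) - 1, -1, -1):
                if not ok[i]:
                    ptr = i
                next_bad[i] = ptr
            for i in range(len(seq) - k + 1):
                if next_bad[i] < i + k:
                    continue
                self._index.setdefault(seq[i:i + k], []).append((sid, i))

    def query(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (sequence id, start, strand) occurrences of ``kmer``."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != index k {self.k}")
        out = [(sid, pos, "+") for sid, pos in self._index.get(kmer, [])]
        rc = revcomp(kmer)
        out += [(sid, pos, "-") for sid, pos in self._index.get(rc, [])]
        return sorted(out)


def build_tag_index(sequences: Mapping[str, str], k: int = TAG_LEN) -> TagIndex:
    """Build an exact k-mer index over a named DNA collection."""
    return TagIndex(sequences, k)


def naive_scan(sequences: Mapping[str, str], kmer: str) -> list[tuple[str, int, str]]:
    """Brute-force substring oracle equivalent to ``TagIndex.query``."""
    hits = []
    for probe, strand in ((kmer, "+"), (revcomp(kmer), "-")):
        for sid, seq in sequences.items():
            seq = seq.upper()
            at = seq.find(probe)
            while at != -1:
                if is_dna(seq[at:at + len(probe)]):
                    hits.append((sid, at, strand))
                at = seq.find(probe, at + 1)
    return sorted(hits)


def map_tag(
    tag: str,
    indexes: Mapping[str, TagIndex],
    stringency: int = 26,
) -> list[TagHit]:
    """Map one 22-nt printed tag against the indexed datasets.

    ``stringency`` 26 requires the full anchor+core match; 24 matches
    only the 5'-most 24 nt (anchor + 20 core nucleotides), the reduced
    mode that tolerates distal mismatches.
    """
    tag = tag.upper()
    if not is_dna(tag):
        raise ValueError(f"tag contains non-DNA characters: {tag!r}")
    if stringency not in (26, 24):
        raise ValueError("stringency must be 26 or 24")
    probe = (ANCHOR + tag)[:stringency]
    hits: list[TagHit] = []
    for dataset, index in indexes.items():
        if index.k != stringency:
            raise ValueError(
                f"index for {dataset!r} built at k={index.k}, need {stringency}"
            )
        for sid, pos, strand in index.query(probe):
            hits.append(TagHit(tag, dataset, sid, pos, pos + stringency, strand))
    return hits


def extract_upstream_fragment(
    sequence: str, hit: TagHit, length: int = 1000
) -> tuple[str, bool]:
    """Strand-aware DNA fragment upstream (5') of a tag match site.

    For a plus-strand hit the fragment covers [start-length, start) in
    sequence coordinates; for a minus-strand hit it is the reverse
    complement of [end, end+length).  Returns (fragment, truncated flag);
    fragments are truncated at sequence boundaries.
    """
    if hit.strand == "+":
        a, b = max(0, hit.start - length), hit.start
        frag = sequence[a:b]
    else:
        a, b = hit.end, min(len(sequence), hit.end + length)
        frag = revcomp(sequence[a:b])
    return frag, len(frag) < length


def fragment_id(sequence: str, hit: TagHit, length: int = 1000) -> str:
    """Stable id of the upstream fragment: "seq:start-end:strand"."""
    if hit.strand == "+":
        a, b = max(0, hit.start - length), hit.start
    else:
        a, b = hit.end, min(len(sequence), hit.end + length)
    return f"{hit.seq_id}:{a}-{b}:{hit.strand}"


def assign_protein(
    hits: Sequence[TagHit],
    blastx_table: pd.DataFrame,
    genome: Mapping[str, str] | None = None,
    upstream_length: int = 1000,
) -> ProteinAssignment | None:
    """Protein identity for a tag via the dataset preference hierarchy.

    The first dataset in the order curated cDNA > predicted cDNA >
    genome that supplies a table row with E < 1e-5 for one of the tag's
    matched DNAs wins; ties within a dataset break by lowest E-value,
    then lexicographic protein id.  Genome hits are looked up by their
    upstream-fragment id.  GO terms are the union over qualifying rows
    (E < 1e-10) of the winning dataset's matched DNAs.
    """
    by_dna = {}
    for _, row in blastx_table.iterrows():
        by_dna.setdefault(str(row["dna_id"]), []).append(row)

    for dataset in DATASET_PREFERENCE:
        ds_hits = [h for h in hits if h.dataset == dataset]
        if not ds_hits:
            continue
        candidates = []
        go: set[str] = set()
        for h in ds_hits:
            if dataset == "genome":
                if genome is None or h.seq_id not in genome:
                    continue
                dna_id = fragment_id(genome[h.seq_id], h, upstream_length)
            else:
                dna_id = h.seq_id
            for row in by_dna.get(dna_id, []):
                e = float(row["evalue"])
                if e < E_IDENTITY:
                    candidates.append((e, str(row["protein_id"]), dna_id, row))
                if e < E_GO and row.get("go_terms"):
                    go.update(t for t in str(row["go_terms"]).split(";") if t)
        if candidates:
            e, pid, dna_id, row = min(candidates, key=lambda c: (c[0], c[1]))
            return ProteinAssignment(
                protein_id=pid,
                evalue=e,
                dataset=dataset,
                dna_id=dna_id,
                orientation=str(row.get("protein_orientation", "+")),
                gene_symbol=str(row.get("gene_symbol", "")),
                go_terms=tuple(sorted(go)),
            )
    return None


def detect_antisense(tag_strand: str, protein_orientation: str) -> bool:
    """Antisense when tag-to-DNA and DNA-to-protein orientations disagree."""
    if tag_strand not in "+-" or protein_orientation not in "+-":
        raise ValueError("orientations must be '+' or '-'")
    return tag_strand != protein_orientation


def annotate_tags(
    tags: Iterable[str],
    indexes: Mapping[str, TagIndex],
    blastx_table: pd.DataFrame,
    genome: Mapping[str, str] | None = None,
    stringency: int = 26,
    upstream_length: int = 1000,
) -> list[AnnotationRecord]:
    """Map and annotate a collection of tags end to end."""
    records = []
    for tag in tags:
        hits = map_tag(tag, indexes, stringency)
        rec = AnnotationRecord(tag=tag, hits=hits)
        if hits:
            rec.assignment = assign_protein(
                hits, blastx_table, genome, upstream_length
            )
            if rec.assignment is not None:
                rec.status = "annotated_protein"
                rec.gene_symbol = rec.assignment.gene_symbol
                used = [
                    h for h in hits if h.dataset == rec.assignment.dataset
                ]
                rec.antisense = any(
                    detect_antisense(h.strand, rec.assignment.orientation)
                    for h in used
                )
            else:
                rec.status = "anonymous_dna"
        rec.ambiguous = rec.n_genomic_locations > 1
        records.append(rec)
    return records


def annotation_summary(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Tag-annotation accounting with one-decimal percentages.

    Reports, of all tags: how many matched any DNA and how many did not;
    of the matched DNAs, how many gained a protein identity; and the
    global three-way split (protein / anonymous DNA / unannotated), plus
    antisense and multi-genomic-location counts.
    """
    records = list(records)
    n = len(records)
    matched = sum(1 for r in records if r.hits)
    protein = sum(1 for r in records if r.status == "annotated_protein")
    anonymous = sum(1 for r in records if r.status == "anonymous_dna")
    unann = n - matched
    antisense = sum(1 for r in records if r.antisense)
    ambiguous = sum(1 for r in records if r.ambiguous)
    rows = [
        ("tags_with_dna_match", matched, percent(matched, n)),
        ("tags_without_dna_match", unann, percent(unann, n)),
        ("total_tags", n, percent(n, n) if n else 0.0),
        ("dna_with_protein_match", protein, percent(protein, matched)),
        ("dna_without_protein_match", matched - protein, percent(matched - protein, matched)),
        ("unannotated_tags", unann, percent(unann, n)),
        ("anonymous_dna_tags", anonymous, percent(anonymous, n)),
        ("protein_tags", protein, percent(protein, n)),
        ("antisense_tags", antisense, percent(antisense, max(protein, 1) if protein else n)),
        ("multi_genomic_location_tags", ambiguous, percent(ambiguous, n)),
    ]
    return pd.DataFrame(rows, columns=["quantity", "count", "pct"]).set_index("quantity")


def records_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        a = r.assignment
        rows.append(
            {
                "tag": r.tag,
                "n_hits": len(r.hits),
                "datasets": ";".join(sorted({h.dataset for h in r.hits})),
                "status": r.status,
                "protein_id": a.protein_id if a else "",
                "evalue": a.evalue if a else "",
                "gene_symbol": r.gene_symbol,
                "antisense": r.antisense,
                "ambiguous": r.ambiguous,
                "go_terms": ";".join(a.go_terms) if a else "",
            }
        )
    return pd.DataFrame(rows)
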