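"""GO-term enrichment of tag lists against a control-transcriptome background.

Each GO term observed in a tag list or in the background is tested with
a one-tailed two-proportion z-test (pooled variance, upper tail toward
enrichment) between the share of list tags carrying the term and the
share of background tags carrying it; the background is the set of tags
expressed in the control libraries of the relevant time scope.
P-values are Benjamini-Hochberg adjusted across all terms tested in the
run, and a term is called enriched when its adjusted p falls below the
FDR threshold (0.01 by default) with the list proportion exceeding the
background proportion.  An exact binomial variant (list counts against
the background rate) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationRecord, E_GO
from .matrix import TagCountMatrix


@dataclass
class EnrichmentRecord:
    go_id: str
    namespace: str
    x1: int
    n1: int
    x2: int
    n2: int
    p: float
    p_adjusted: float
    enriched: bool


def build_go_map(
    records: Iterable[AnnotationRecord] | pd.DataFrame,
    e_threshold: float = E_GO,
) -> dict[str, set[str]]:
    """Tag -> GO-term sets from annotation records or a blastx-style frame.

    Only terms transferred from hits passing the GO E-value threshold
    qualify; tags without qualifying hits map to the empty set.
    """
    go_map: dict[str, set[str]] = {}
    if isinstance(records, pd.DataFrame):
        for _, row in records.iterrows():
            terms = {
                t for t in str(row.get("go_terms", "")).split(";") if t
            }
            ev = row.get("evalue")
            if ev is not None and str(ev) != "" and float(ev) >= e_threshold:
                terms = set()
            go_map[str(row["tag"])] = terms
        return go_map
    for rec in records:
        terms: set[str] = set()
        if rec.assignment is not None:
            terms = set(rec.assignment.go_terms)
        go_map[rec.tag] = terms
    return go_map


def build_background(
    go_map: Mapping[str, set[str]],
    matrix: TagCountMatrix,
    control_libraries: Sequence[str],
) -> dict[str, set[str]]:
    """Background = tags expressed (count >= 1) in the scoped control libraries."""
    missing = [l for l in control_libraries if l not in matrix.counts.columns]
    if missing:
        raise KeyError(f"control libraries absent from matrix: {missing}")
    if not control_libraries:
        raise ValueError("no control libraries given")
    expressed = matrix.counts[list(control_libraries)].sum(axis=1) > 0
    tags = matrix.counts.index[expressed]
    return {t: set(go_map.get(t, set())) for t in tags}


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """One-tailed pooled two-proportion z-test toward enrichment.

    Returns the upper-tail normal probability of the pooled z statistic;
    a degenerate pooled proportion (0 or 1) gives p = 1 (no evidence).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    p0 = (x1 + x2) / (n1 + n2)
    if p0 <= 0.0 or p0 >= 1.0:
        return 1.0
    z = (x1 / n1 - x2 / n2) / np.sqrt(p0 * (1 - p0) * (1 / n1 + 1 / n2))
    return float(stats.norm.sf(z))


def _binom_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Exact upper-tail binomial oracle at the background rate."""
    rate = x2 / n2
    if rate <= 0:
        return 1.0 if x1 == 0 else 0.0
    return float(stats.binom.sf(x1 - 1, n1, rate))


def enrich(
    tag_list: Iterable[str],
    background: Mapping[str, set[str]],
    go_map: Mapping[str, set[str]] | None = None,
    alpha_fdr: float = 0.01,
    namespaces: Mapping[str, str] | None = None,
    method: str = "z",
) -> list[EnrichmentRecord]:
    """Test every GO term of a tag list against the background.

    ``background`` maps background tags to their GO sets; ``go_map``
    supplies GO sets for list tags absent from the background (defaults
    to the background map).  One test per term present in either set;
    BH adjustment spans all terms of the run; records are sorted by
    adjusted p.  ``method`` "z" uses the one-tailed proportion test,
    "binom" the exact binomial variant.
    """
    tag_list = list(dict.fromkeys(tag_list))
    if not tag_list:
        return []
    go_map = go_map if go_map is not None else background
    list_terms: dict[str, int] = {}
    for t in tag_list:
        for term in go_map.get(t, background.get(t, set())):
            list_terms[term] = list_terms.get(term, 0) + 1
    bg_terms: dict[str, int] = {}
    for t, terms in background.items():
        for term in terms:
            bg_terms[term] = bg_terms.get(term, 0) + 1

    all_terms = sorted(set(list_terms) | set(bg_terms))
    if not all_terms:
        return []
    n1 = len(tag_list)
    n2 = len(background)
    test = proportion_test if method == "z" else _binom_test
    raw = []
    for term in all_terms:
        x1 = list_terms.get(term, 0)
        x2 = bg_terms.get(term, 0)
        raw.append(test(x1, n1, x2, n2))
    _, adj, _, _ = multipletests(raw, method="fdr_bh")

    records = []
    for term, p, pa in zip(all_terms, raw, adj):
        x1 = list_terms.get(term, 0)
        x2 = bg_terms.get(term, 0)
        records.append(
            EnrichmentRecord(
                go_id=term,
                namespace=(namespaces or {}).get(term, ""),
                x1=x1,
                n1=n1,
                x2=x2,
                n2=n2,
                p=float(p),
                p_adjusted=float(pa),
                enriched=bool(pa < alpha_fdr and x1 / n1 > x2 / n2),
            )
        )
    records.sort(key=lambda r: (r.p_adjusted, r.p, r.go_id))
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "go_id": r.go_id,
                "namespace": r.namespace,
                "list_count": r.x1,
                "list_size": r.n1,
                "background_count": r.x2,
                "background_size": r.n2,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "enriched": r.enriched,
            }
            for r in records
        ]
    )
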