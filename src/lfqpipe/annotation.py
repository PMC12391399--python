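"""GO-term summarization of differentially expressed protein lists.

Descriptive categorization against a user-supplied annotation map:
each GO term's count is the number of listed proteins directly
annotated to it (no DAG ancestor propagation, no live database).
Proteins absent from the map are reported separately as unannotated.
An optional hypergeometric enrichment mode is provided as a clearly
labelled extension; the default output is plain counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .tables_io import GOAnnotationMap, GO_ASPECTS

__all__ = ["GOSummary", "summarize_go", "enrichment_test", "write_go_summary"]


@dataclass(frozen=True)
class GOSummary:
    """Per-term counts over a protein list.

    ``table`` columns: aspect, go_id, term_name, count, accessions
    (semicolon-joined), sorted by descending count then GO ID.
    """

    table: pd.DataFrame
    unannotated: frozenset

    def __len__(self) -> int:
        return len(self.table)


def summarize_go(
    proteins: Iterable[str],
    gomap: GOAnnotationMap,
    aspect_filter: str | None = None,
) -> GOSummary:
    """Count DE proteins per GO term, optionally restricted to one aspect."""
    if aspect_filter is not None and aspect_filter not in GO_ASPECTS:
        raise ValueError(f"aspect_filter must be one of {GO_ASPECTS}")
    prots = set(proteins)
    t = gomap.table
    if aspect_filter is not None:
        t = t[t["aspect"] == aspect_filter]
    hits = t[t["accession"].isin(prots)]
    rows = []
    for (aspect, go_id, term_name), sub in hits.groupby(
        ["aspect", "go_id", "term_name"], sort=False
    ):
        members = sorted(set(sub["accession"]))
        rows.append({
            "aspect": aspect, "go_id": go_id, "term_name": term_name,
            "count": len(members), "accessions": ";".join(members),
        })
    table = pd.DataFrame(
        rows, columns=["aspect", "go_id", "term_name", "count", "accessions"]
    ).sort_values(["count", "go_id"], ascending=[False, True], ignore_index=True)
    annotated = set(hits["accession"])
    # unannotated = no record in ANY aspect, regardless of the filter
    any_hit = set(gomap.table.loc[gomap.table["accession"].isin(prots), "accession"])
    return GOSummary(table=table, unannotated=frozenset(prots - any_hit))


def enrichment_test(
    proteins: Iterable[str],
    gomap: GOAnnotationMap,
    background: Iterable[str],
    aspect_filter: str | None = None,
) -> pd.DataFrame:
    """EXTENSION — hypergeometric over-representation test per GO term.

    Not part of the descriptive summarization the pipeline reports by
    default; provided for exploratory use. ``background`` is the
    universe of tested accessions.
    """
    prots = set(proteins)
    bg = set(background)
    if not prots <= bg:
        raise ValueError("protein list must be a subset of the background")
    summary = summarize_go(prots, gomap, aspect_filter).table
    rows = []
    t = gomap.table
    if aspect_filter is not None:
        t = t[t["aspect"] == aspect_filter]
    for _, r in summary.iterrows():
        term_bg = set(t.loc[t["go_id"] == r["go_id"], "accession"]) & bg
        k, K, n, N = r["count"], len(term_bg), len(prots), len(bg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({**r.to_dict(), "bg_count": K, "p_hypergeom": p})
    return pd.DataFrame(rows)


def write_go_summary(summary: GOSummary, path) -> None:
    summary.table.to_csv(path, sep="\t", index=False)
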