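"""Semantic post-processing of enrichment-term tables.

Enrichment servers return long lists of GO/Reactome terms; this module
reduces them to an interpretable summary the way the network analysis does:

* size filters — very large terms (term_size over a cutoff) are too general
  to be informative and are dropped; terms with too few query genes behind
  them (intersection_size <= a cutoff) are unsupported and dropped;
* keyword grouping — terms are binned into semantic classes by an ordered
  keyword lexicon matched case-insensitively against the term name, each
  class reporting its term count, percentage of the filtered enrichment and
  best (smallest) adjusted p;
* top-group selection — the largest classes that cumulatively cover more
  than half of the filtered enrichment summarize a cluster's function;
* ontology components — connected components of the filtered terms under
  parent-child relations, for hierarchy-style summaries.

The keyword lexicon is data, not code: reproducing a grouping requires the
exact ordered lexicon used.  A small melanoma-flavored default ships for
demonstrations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TermGroup",
    "DEFAULT_LEXICON",
    "filter_terms",
    "group_by_keywords",
    "top_groups",
    "term_dag_components",
    "read_terms",
    "read_relations",
    "read_lexicon",
]

UNASSIGNED = "unassigned"

#: Demo lexicon of melanoma-relevant semantic classes (ordered: first match wins).
DEFAULT_LEXICON = (
    "telomere",
    "dna repair",
    "dna damage",
    "pigment",
    "melanin",
    "ageing",
    "antigen",
    "cell cycle",
    "adhesion",
    "migration",
    "calcium",
    "autophagy",
    "differentiation",
    "stress",
    "transcription",
    "apoptosis",
)


@dataclass
class TermGroup:
    """A keyword-defined semantic class of enrichment terms."""

    keyword: str
    members: list[str]  # term ids
    n_terms: int
    pct_of_filtered: float
    min_p_adj: float


def filter_terms(
    terms: pd.DataFrame,
    max_term_size: int | None = None,
    min_intersection: int | None = None,
    size_op: str = "lt",
) -> pd.DataFrame:
    """Apply the term-size and intersection-size filters.

    ``size_op`` selects the term-size comparator: "lt" keeps
    term_size < max_term_size, "le" keeps term_size <= max_term_size (the
    published analyses use both conventions depending on the experiment).
    The intersection filter removes terms with intersection_size <=
    ``min_intersection``.  The operation is idempotent.
    """
    out = terms
    if max_term_size is not None:
        if size_op == "lt":
            out = out[out["term_size"] < max_term_size]
        elif size_op == "le":
            out = out[out["term_size"] <= max_term_size]
        else:
            raise ValueError(f"unknown size_op {size_op!r}")
    if min_intersection is not None:
        out = out[out["intersection_size"] > min_intersection]
    return out.reset_index(drop=True)


def group_by_keywords(
    terms: pd.DataFrame, lexicon=DEFAULT_LEXICON
) -> tuple[list[TermGroup], pd.DataFrame]:
    """Bin terms into semantic classes by an ordered keyword lexicon.

    Each term goes to the first lexicon keyword found (case-insensitive
    substring) in its name; unmatched terms land in the ``unassigned``
    bucket.  Returns the group list (every keyword with >= 1 member, plus
    the unassigned bucket) and the term table with an added ``group``
    column.  Percentages are over the filtered term count, so group
    membership partitions the input.
    """
    lexicon = [str(k) for k in lexicon]
    if not lexicon:
        raise ValueError("empty keyword lexicon")
    n_total = len(terms)
    assignment = []
    for name in terms["term_name"].astype(str):
        lowered = name.lower()
        for kw in lexicon:
            if kw.lower() in lowered:
                assignment.append(kw)
                break
        else:
            assignment.append(UNASSIGNED)
    annotated = terms.copy()
    annotated["group"] = assignment
    groups = []
    for kw in [*lexicon, UNASSIGNED]:
        sub = annotated[annotated["group"] == kw]
        if len(sub) == 0:
            continue
        groups.append(
            TermGroup(
                keyword=kw,
                members=list(sub["term_id"]),
                n_terms=len(sub),
                pct_of_filtered=100.0 * len(sub) / n_total if n_total else 0.0,
                min_p_adj=float(sub["adjusted_p_value"].min()),
            )
        )
    return groups, annotated


def top_groups(groups: list[TermGroup], coverage: float = 0.5) -> list[TermGroup]:
    """Largest semantic classes cumulatively covering > ``coverage`` of terms.

    Groups are ranked by term count (descending), ties by smaller best
    adjusted p, then keyword; the shortest prefix whose cumulative
    percentage strictly exceeds ``coverage * 100`` is returned.
    """
    if not groups or sum(g.n_terms for g in groups) == 0:
        raise ValueError("no terms to cover")
    ranked = sorted(groups, key=lambda g: (-g.n_terms, g.min_p_adj, g.keyword))
    selected = []
    cum = 0.0
    for g in ranked:
        selected.append(g)
        cum += g.pct_of_filtered
        if cum > coverage * 100.0:
            break
    return selected


def term_dag_components(
    terms: pd.DataFrame, relations: pd.DataFrame
) -> list[dict]:
    """Connected components of the term set under parent-child relations.

    ``relations`` has columns (parent_id, child_id); edges referencing term
    ids absent from ``terms`` are ignored with a warning.  Components are
    ranked by size (ties by smallest member id) and annotated with their
    smallest adjusted p and smallest term size.
    """
    known = set(terms["term_id"])
    g = nx.Graph()
    g.add_nodes_from(known)
    unknown = 0
    for r in relations.itertuples(index=False):
        if r.parent_id in known and r.child_id in known:
            g.add_edge(r.parent_id, r.child_id)
        else:
            unknown += 1
    if unknown:
        log.warning("%d relation edges reference unknown term ids; ignored", unknown)
    indexed = terms.set_index("term_id")
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    out = []
    for members in comps:
        sub = indexed.loc[members]
        out.append(
            {
                "members": members,
                "n_terms": len(members),
                "min_p_adj": float(sub["adjusted_p_value"].min()),
                "min_term_size": int(sub["term_size"].min()),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Readers (g:Profiler-export-shaped TSVs)

def read_terms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"term_id": str, "term_name": str})
    required = {"term_id", "term_name", "adjusted_p_value", "term_size", "intersection_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"term table missing columns: {sorted(missing)}")
    bad = df[df["intersection_size"] > df["term_size"]]
    if len(bad):
        raise ValueError(f"intersection_size > term_size for {bad['term_id'].tolist()}")
    return df


def read_relations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_lexicon(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
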