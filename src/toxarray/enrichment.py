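"""Over-representation analysis with BH-FDR tiers and term-overlap networks.

For a query gene list (e.g. all UP calls) against a gene-set collection and
a background universe (default: every gene on the array), each term is
scored with the one-sided hypergeometric upper tail

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

where N is the background size, K the term size within the background, n the
query size and k the query/term overlap.  Fold enrichment FE = (k/n)/(K/N).
P-values are Benjamini-Hochberg adjusted within the collection; terms are
tiered as significant (FDR <= 0.05, and FE >= 5 when the FE filter is on),
suggestive (0.05 < FDR <= 0.10), or none.  Tiered terms can be laid out as
a network whose edges mark gene overlap between terms (Jaccard similarity of
the query-restricted memberships).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import GeneSetCollection

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NONE = "none"


def hypergeom_enrich(
    query, collection: GeneSetCollection, background
) -> pd.DataFrame:
    """One record per term with k >= 1: counts, fold enrichment, raw p.

    The query must be a subset of the background; each term is intersected
    with the background before testing.  Columns:
    ``term_id, term_name, k, n, K, N, fold_enrichment, p``.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValidationError("query gene set is empty")
    if not background:
        raise ValidationError("background gene set is empty")
    stray = query - background
    if stray:
        raise ValidationError(
            f"query genes outside the background: {sorted(stray)[:10]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for term_id, (name, members) in collection.items():
        in_bg = members & background
        K = len(in_bg)
        k = len(in_bg & query)
        if k < 1:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": term_id,
            "term_name": name,
            "k": k, "n": n, "K": K, "N": N,
            "fold_enrichment": (k / n) / (K / N),
            "p": min(max(p, np.finfo(float).tiny), 1.0),
        })
    return pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "n", "K", "N",
                 "fold_enrichment", "p"],
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tier_and_filter(
    records: pd.DataFrame,
    fdr_sig: float = 0.05,
    fdr_sugg: float = 0.10,
    fe_min: float = 5.0,
    apply_fe: bool = True,
) -> pd.DataFrame:
    """Assign significance tiers; optionally demote low fold-enrichment terms.

    Tiers (inclusive boundaries): significant at FDR <= ``fdr_sig``,
    suggestive at ``fdr_sig`` < FDR <= ``fdr_sugg``.  With ``apply_fe``,
    records with FE < ``fe_min`` are demoted to tier ``none`` but retained
    in the output (column ``fe_pass`` records the raw verdict).
    """
    if "fdr" not in records.columns:
        raise ValidationError("records lack an 'fdr' column; adjust first")
    out = records.copy()
    fdr = out["fdr"].to_numpy(float)
    tier = np.where(
        fdr <= fdr_sig, TIER_SIGNIFICANT,
        np.where(fdr <= fdr_sugg, TIER_SUGGESTIVE, TIER_NONE),
    ).astype(object)
    out["fe_pass"] = out["fold_enrichment"] >= fe_min
    if apply_fe:
        tier[~out["fe_pass"].to_numpy()] = TIER_NONE
    out["tier"] = tier
    return out


def build_term_network(
    records: pd.DataFrame,
    collection: GeneSetCollection,
    query,
    min_similarity: float = 0.2,
) -> nx.Graph:
    """Term-overlap network for the tiered terms in ``records``.

    Nodes carry ``k`` (size attribute), ``fdr`` and ``neglog10_fdr`` (color
    attribute); an edge joins two terms whose query-restricted member sets
    have Jaccard similarity >= ``min_similarity``, weighted by the shared
    gene count.
    """
    query = set(query)
    graph = nx.Graph()
    hit_sets = {}
    for row in records.itertuples(index=False):
        members = collection.members(row.term_id) & query
        hit_sets[row.term_id] = members
        graph.add_node(
            row.term_id,
            name=row.term_name,
            k=int(row.k),
            fdr=float(row.fdr),
            neglog10_fdr=float(-np.log10(row.fdr)),
        )
    for t1, t2 in ((a, b) for i, a in enumerate(hit_sets) for b in list(hit_sets)[i + 1:]):
        s1, s2 = hit_sets[t1], hit_sets[t2]
        shared = s1 & s2
        union = s1 | s2
        if not union:
            continue
        jac = len(shared) / len(union)
        if jac >= min_similarity:
            graph.add_edge(t1, t2, weight=len(shared), similarity=jac)
    return graph


class EnrichmentAnalysis:
    """Over-representation model for one query against one collection.

    Follows the model/results convention: construct with the data, call
    :meth:`fit` for an :class:`EnrichmentResults`.  BH adjustment happens
    within this collection only; run one analysis per collection (e.g. one
    per GO branch) to mirror per-analysis FDR reporting.
    """

    def __init__(
        self,
        query,
        collection: GeneSetCollection,
        background,
        fdr_sig: float = 0.05,
        fdr_sugg: float = 0.10,
        fe_min: float = 5.0,
        apply_fe: bool = True,
    ):
        self.query = set(query)
        self.collection = collection
        self.background = set(background)
        self.fdr_sig = fdr_sig
        self.fdr_sugg = fdr_sugg
        self.fe_min = fe_min
        self.apply_fe = apply_fe

    def fit(self) -> "EnrichmentResults":
        records = hypergeom_enrich(self.query, self.collection, self.background)
        if len(records):
            records["fdr"] = bh_adjust(records["p"])
            records = tier_and_filter(
                records, self.fdr_sig, self.fdr_sugg, self.fe_min, self.apply_fe
            )
            records = records.sort_values(
                ["p", "term_id"]
            ).reset_index(drop=True)
        else:
            records["fdr"] = []
            records["fe_pass"] = []
            records["tier"] = []
        return EnrichmentResults(self, records)


class EnrichmentResults:
    """Tiered enrichment records plus network/report helpers."""

    def __init__(self, model: EnrichmentAnalysis, records: pd.DataFrame):
        self.model = model
        self.records = records

    @property
    def significant(self) -> pd.DataFrame:
        return self.records[self.records["tier"] == TIER_SIGNIFICANT]

    @property
    def suggestive(self) -> pd.DataFrame:
        return self.records[self.records["tier"] == TIER_SUGGESTIVE]

    def network(self, min_similarity: float = 0.2, tiers=("significant", "suggestive")) -> nx.Graph:
        sub = self.records[self.records["tier"].isin(tiers)]
        return build_term_network(
            sub, self.model.collection, self.model.query, min_similarity
        )

    def summary(self) -> str:
        lines = [
            "Over-representation analysis",
            "=" * 60,
            f"query {len(self.model.query)} genes; background "
            f"{len(self.model.background)}; {len(self.model.collection)} terms "
            f"({len(self.records)} with k >= 1)",
            f"significant (FDR <= {self.model.fdr_sig:g}"
            + (f", FE >= {self.model.fe_min:g}" if self.model.apply_fe else "")
            + f"): {len(self.significant)}",
            f"suggestive ({self.model.fdr_sig:g} < FDR <= "
            f"{self.model.fdr_sugg:g}): {len(self.suggestive)}",
        ]
        for row in self.records.head(10).itertuples(index=False):
            lines.append(
                f"  {row.term_id:<12} k={row.k:<4d} FE={row.fold_enrichment:6.2f} "
                f"FDR={row.fdr:0.4g} {row.tier}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)
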