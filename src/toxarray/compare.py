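"""Symbol standardization and study-vs-literature overlap classification.

Study calls (UP/DOWN/STABLE) are crossed with curated literature labels
(UP/DOWN/SEG) to classify each differentially expressed gene as concordant,
discordant, or novel relative to prior reports, plus Venn-style region
counts for 2- or 3-set comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .exceptions import ValidationError
from .io import LiteratureDB

logger = logging.getLogger(__name__)

#: Partition categories for study DEGs (pairwise disjoint; union = DEG list).
PARTITION_CATEGORIES = (
    "concordant_up",
    "concordant_down",
    "discordant_down_vs_litUP",
    "discordant_up_vs_litDOWN",
    "study_only_up",
    "study_only_down",
)


def load_alias_table(path=None) -> dict:
    """Alias -> canonical symbol map (TSV, two columns), keys case-folded.

    With no path, the small packaged table is used.
    """
    if path is None:
        source = resources.files("toxarray.data").joinpath("gene_aliases.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, comment="#")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) != ["alias", "canonical"]:
        raise ValidationError("alias table needs columns: alias, canonical")
    return {
        str(a).strip().upper(): str(c).strip().upper()
        for a, c in zip(df["alias"], df["canonical"])
    }


def standardize_symbols(
    symbols, alias_table: dict | None = None
) -> tuple[list, list]:
    """Trim, uppercase, and alias-resolve gene symbols.

    Returns ``(canonical, log)`` where ``log`` records each applied alias
    substitution as ``(original, canonical)``.  Unresolved symbols pass
    through (case-folded) unchanged.  Idempotent.
    """
    symbols = list(symbols)
    if not symbols:
        raise ValidationError("symbol list must be nonempty")
    table = alias_table or {}
    out, changed = [], []
    for s in symbols:
        canon = str(s).strip().upper()
        if canon in table:
            changed.append((s, table[canon]))
            canon = table[canon]
        out.append(canon)
    if changed:
        logger.info("resolved %d alias(es): %s", len(changed), changed[:5])
    return out, changed


@dataclass
class OverlapReport:
    """Study-vs-literature classification.

    ``categories`` holds the six-way partition of the study DEG list (see
    :data:`PARTITION_CATEGORIES`); ``lit_seg_not_de`` lists literature-SEG
    genes absent from the study DEGs; ``stable_overlap_up``/``down`` list
    DEGs whose basal (control-condition) call is STABLE — these necessarily
    re-use DEG members and sit outside the partition.
    """

    categories: dict = field(default_factory=dict)
    lit_seg_not_de: list = field(default_factory=list)
    stable_overlap_up: list = field(default_factory=list)
    stable_overlap_down: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        d = {k: len(v) for k, v in self.categories.items()}
        d["lit_seg_not_de"] = len(self.lit_seg_not_de)
        d["stable_overlap_up"] = len(self.stable_overlap_up)
        d["stable_overlap_down"] = len(self.stable_overlap_down)
        return d

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": k, "count": len(v), "genes": ";".join(v)}
            for k, v in self.categories.items()
        ]
        rows.append({
            "category": "lit_seg_not_de",
            "count": len(self.lit_seg_not_de),
            "genes": ";".join(self.lit_seg_not_de),
        })
        for name in ("stable_overlap_up", "stable_overlap_down"):
            rows.append({
                "category": name,
                "count": len(getattr(self, name)),
                "genes": ";".join(getattr(self, name)),
            })
        return pd.DataFrame(rows)


def classify_overlap(
    calls: pd.DataFrame,
    lit: LiteratureDB,
    stable_calls: pd.DataFrame | None = None,
) -> OverlapReport:
    """Cross study UP/DOWN calls with literature UP/DOWN/SEG labels.

    ``calls`` needs columns ``gene`` and ``call``; symbols on both sides
    must already be standardized.  Each study DEG lands in exactly one
    partition category; literature-SEG genes not among the DEGs are listed
    separately.  ``stable_calls`` (defaults to ``calls``) supplies the
    STABLE set intersected with the DEG lists for the basal-stability
    overlap.
    """
    if calls["gene"].duplicated().any():
        raise ValidationError("duplicate genes in study calls")
    by_call = calls.groupby("call")["gene"].agg(set).to_dict()
    study_up = by_call.get("UP", set())
    study_down = by_call.get("DOWN", set())

    cats = {k: [] for k in PARTITION_CATEGORIES}
    for gene in sorted(study_up):
        label = lit.label(gene) if gene in lit else None
        if label == "UP":
            cats["concordant_up"].append(gene)
        elif label == "DOWN":
            cats["discordant_up_vs_litDOWN"].append(gene)
        else:
            cats["study_only_up"].append(gene)
    for gene in sorted(study_down):
        label = lit.label(gene) if gene in lit else None
        if label == "DOWN":
            cats["concordant_down"].append(gene)
        elif label == "UP":
            cats["discordant_down_vs_litUP"].append(gene)
        else:
            cats["study_only_down"].append(gene)

    degs = study_up | study_down
    seg_not_de = sorted(lit.symbols_with("SEG") - degs)

    stable_src = stable_calls if stable_calls is not None else calls
    stable = set(
        stable_src.loc[stable_src["call"] == "STABLE", "gene"]
    )
    return OverlapReport(
        categories=cats,
        lit_seg_not_de=seg_not_de,
        stable_overlap_up=sorted(study_up & stable),
        stable_overlap_down=sorted(study_down & stable),
    )


def venn_counts(sets: dict) -> pd.DataFrame:
    """Region counts for a 2- or 3-set Venn partition.

    Returns one row per non-trivial region with the membership pattern,
    count, and percentage of the union.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValidationError(
            f"venn_counts supports 2 or 3 sets, got {len(names)}"
        )
    sets = {k: set(v) for k, v in sets.items()}
    union = set().union(*sets.values())
    rows = []
    for pattern in itertools.product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        region = union.copy() if union else set()
        for name, inside in zip(names, pattern):
            region &= sets[name] if inside else (union - sets[name])
        rows.append({
            "region": "&".join(n for n, i in zip(names, pattern) if i)
            + "".join(f"-{n}" for n, i in zip(names, pattern) if not i),
            **{n: i for n, i in zip(names, pattern)},
            "count": len(region),
            "percent_of_union": 100.0 * len(region) / len(union) if union else 0.0,
        })
    return pd.DataFrame(rows)
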