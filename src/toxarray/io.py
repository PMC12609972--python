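"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain text so results stay diffable and portable:

* spot tables — TSV with canonical columns ``spot_id, gene, fg1, bg1, fg2,
  bg2, flag`` (one file per hybridization); a header-mapping dict supports
  GenePix-style exports (``"F635 Mean"`` -> ``fg2`` etc.)
* gene sets — standard GMT (term, description, members...)
* protein interaction edges — 3-column TSV ``node1, node2, score`` with
  scores in [0, 1]
* literature labels — CSV/TSV ``symbol, label, provenance`` with labels in
  {UP, DOWN, SEG}
* clinical cohorts — TSV ``subject, time, event`` plus one column per gene

Identifiers are case-sensitive here; any case-folding happens downstream in
:mod:`toxarray.compare` so file provenance is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["spot_id", "gene", "fg1", "bg1", "fg2", "bg2", "flag"]
INTENSITY_COLUMNS = ["fg1", "bg1", "fg2", "bg2"]

#: Header mapping for GenePix-style exports. Channel 1 is the 532 nm (Cy3 /
#: Alexa555, control) channel; channel 2 is 635 nm (Cy5 / Alexa647, treated).
GPR_DIALECT: Mapping[str, str] = {
    "ID": "spot_id",
    "Name": "gene",
    "F532 Mean": "fg1",
    "B532 Mean": "bg1",
    "F635 Mean": "fg2",
    "B635 Mean": "bg2",
    "Flags": "flag",
}

#: Flag vocabularies seen in quantification exports, normalised to OK/BAD.
DEFAULT_FLAG_MAP: Mapping[str, str] = {
    "OK": "OK",
    "GOOD": "OK",
    "0": "OK",
    "BAD": "BAD",
    "ABSENT": "BAD",
    "NOT FOUND": "BAD",
    "-50": "BAD",
    "-75": "BAD",
    "-100": "BAD",
}


class SpotRecord(NamedTuple):
    """One printed spot: two-channel foreground/background plus a quality flag."""

    spot_id: str
    gene: str
    fg1: float
    bg1: float
    fg2: float
    bg2: float
    flag: str = "OK"


@dataclass
class ArrayScan:
    """One hybridization: an ordered table of spots with canonical columns.

    ``data`` always carries :data:`SPOT_COLUMNS`; an optional ``flag_reason``
    column records why a spot was marked BAD.
    """

    array_id: str
    data: pd.DataFrame
    dye_orientation: str = "standard"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dye_orientation not in ("standard", "swapped"):
            raise ValidationError(
                f"dye_orientation must be 'standard' or 'swapped', "
                f"got {self.dye_orientation!r}"
            )
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"spot table missing columns: {missing}")
        if len(self.data) == 0:
            raise ValidationError(f"array {self.array_id!r} has no spots")
        dup = self.data["spot_id"][self.data["spot_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate spot_ids in array {self.array_id!r}: "
                f"{sorted(set(dup))[:5]}"
            )
        if (self.data["gene"].astype(str).str.len() == 0).any():
            raise ValidationError("empty gene symbol in spot table")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def spots(self) -> Iterator[SpotRecord]:
        for row in self.data.itertuples(index=False):
            yield SpotRecord(
                str(row.spot_id), str(row.gene),
                float(row.fg1), float(row.bg1), float(row.fg2), float(row.bg2),
                str(row.flag),
            )

    def copy(self) -> "ArrayScan":
        return ArrayScan(
            self.array_id, self.data.copy(), self.dye_orientation,
            list(self.provenance),
        )


class GeneSetCollection:
    """Mapping of term_id -> (term_name, member set), GMT-round-trippable."""

    def __init__(self, terms: Mapping[str, tuple[str, Iterable[str]]] | None = None):
        self._terms: dict[str, tuple[str, frozenset]] = {}
        if terms:
            for tid, (name, members) in terms.items():
                self.add(tid, name, members)

    def add(self, term_id: str, name: str, members: Iterable[str]) -> None:
        unique = frozenset(members)
        if not unique:
            raise ValidationError(f"term {term_id!r} has no members")
        self._terms[term_id] = (name, unique)

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def name(self, term_id: str) -> str:
        return self._terms[term_id][0]

    def members(self, term_id: str) -> frozenset:
        return self._terms[term_id][1]

    def items(self):
        return self._terms.items()


class LiteratureDB:
    """One UP/DOWN/SEG label per symbol, with a provenance string each."""

    LABELS = frozenset({"UP", "DOWN", "SEG"})

    def __init__(self, rows: Iterable[tuple[str, str, str]] = ()):
        self._labels: dict[str, str] = {}
        self._provenance: dict[str, str] = {}
        for symbol, label, prov in rows:
            self.add(symbol, label, prov)

    def add(self, symbol: str, label: str, provenance: str = "") -> None:
        if label not in self.LABELS:
            raise ValidationError(
                f"label for {symbol!r} must be one of {sorted(self.LABELS)}, "
                f"got {label!r}"
            )
        if symbol in self._labels and self._labels[symbol] != label:
            raise ValidationError(
                f"conflicting labels for symbol {symbol!r}: "
                f"{self._labels[symbol]} vs {label}"
            )
        self._labels[symbol] = label
        self._provenance[symbol] = provenance

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._labels

    def label(self, symbol: str) -> str:
        return self._labels[symbol]

    def provenance(self, symbol: str) -> str:
        return self._provenance[symbol]

    def symbols_with(self, label: str) -> frozenset:
        return frozenset(s for s, l in self._labels.items() if l == label)

    def items(self):
        return self._labels.items()


# ---------------------------------------------------------------------------
# spot tables


def read_spot_table(
    path,
    dialect: Mapping[str, str] | None = None,
    array_id: str | None = None,
    dye_orientation: str = "standard",
    flag_map: Mapping[str, str] = DEFAULT_FLAG_MAP,
) -> ArrayScan:
    """Read a spot quantification table into an :class:`ArrayScan`.

    ``dialect`` maps file headers to canonical column names (see
    :data:`GPR_DIALECT`); the native dialect needs no mapping.  Flags are
    normalised through ``flag_map``; unrecognised flag values are treated as
    BAD and logged.  Negative intensities are rejected with row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    df = df[list(df.columns.intersection(SPOT_COLUMNS + ["flag_reason"]))]
    for col in INTENSITY_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path.name}: non-numeric value in {col}: {exc}")
    bad_rows = df.index[(df[INTENSITY_COLUMNS] < 0).any(axis=1)]
    if len(bad_rows):
        # +2: header line plus 1-based numbering
        rows = [int(i) + 2 for i in bad_rows[:10]]
        raise ValidationError(
            f"{path.name}: negative intensity at file row(s) {rows}"
        )
    raw_flags = df["flag"].astype(str).str.strip().str.upper()
    norm = raw_flags.map(lambda f: flag_map.get(f))
    unknown = raw_flags[norm.isna()]
    if len(unknown):
        logger.warning(
            "%s: %d spot(s) with unrecognised flag value(s) %s treated as BAD",
            path.name, len(unknown), sorted(set(unknown))[:5],
        )
    df["flag"] = norm.fillna("BAD")
    return ArrayScan(
        array_id=array_id or path.stem,
        data=df.reset_index(drop=True),
        dye_orientation=dye_orientation,
    )


def write_spot_table(scan: ArrayScan, path) -> None:
    cols = SPOT_COLUMNS + (
        ["flag_reason"] if "flag_reason" in scan.data.columns else []
    )
    scan.data[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (term, description, members...) with validation.

    Duplicate members within a term are collapsed with one logged warning;
    lines with fewer than three fields raise :class:`FormatError` with the
    line number.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{Path(path).name}: line {lineno} has "
                    f"{len(fields)} field(s), expected >= 3"
                )
            term_id, name, *members = fields
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                logger.warning(
                    "%s: line %d (term %s): duplicate members collapsed",
                    Path(path).name, lineno, term_id,
                )
            collection.add(term_id, name, members)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, members) in collection.items():
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# scored edge lists


def read_edge_list(path) -> pd.DataFrame:
    """Read a 3-column TSV of scored, undirected interactions.

    Self-loops are dropped with a warning; duplicate pairs (in either node
    order) keep the maximum score.  Returns a DataFrame with columns
    ``node1, node2, score`` where ``node1 < node2`` lexicographically.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["node1", "node2", "score"],
        dtype={"node1": str, "node2": str}, comment="#", skip_blank_lines=True,
    )
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    out_of_range = df[(df["score"] < 0) | (df["score"] > 1)]
    if len(out_of_range):
        raise ValidationError(
            f"{Path(path).name}: {len(out_of_range)} edge score(s) outside "
            f"[0, 1], first at file row {int(out_of_range.index[0]) + 1}"
        )
    loops = df["node1"] == df["node2"]
    if loops.any():
        logger.warning(
            "%s: dropped %d self-loop(s)", Path(path).name, int(loops.sum())
        )
        df = df[~loops]
    lo = df[["node1", "node2"]].min(axis=1)
    hi = df[["node1", "node2"]].max(axis=1)
    df = pd.DataFrame({"node1": lo, "node2": hi, "score": df["score"]})
    df = (
        df.groupby(["node1", "node2"], as_index=False)["score"].max()
        .sort_values(["node1", "node2"])
        .reset_index(drop=True)
    )
    return df


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges[["node1", "node2", "score"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# literature label tables


def read_literature_table(path, sep: str | None = None) -> LiteratureDB:
    """Read a symbol/label/provenance table into a :class:`LiteratureDB`.

    The separator is sniffed from the extension (.csv -> comma, else tab)
    unless given.  Unknown labels and conflicting duplicate symbols raise
    :class:`ValidationError` naming the offenders.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    required = ["symbol", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    if "provenance" not in df.columns:
        df["provenance"] = ""
    bad = df[~df["label"].isin(LiteratureDB.LABELS)]
    if len(bad):
        raise ValidationError(
            f"{path.name}: unknown label(s) at file row(s) "
            f"{[int(i) + 2 for i in bad.index[:10]]}: "
            f"{sorted(set(bad['label']))}"
        )
    db = LiteratureDB()
    for row in df.itertuples(index=False):
        db.add(str(row.symbol), str(row.label), str(row.provenance))
    return db


def write_literature_table(db: LiteratureDB, path) -> None:
    rows = [
        {"symbol": s, "label": l, "provenance": db.provenance(s)}
        for s, l in db.items()
    ]
    pd.DataFrame(rows, columns=["symbol", "label", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# clinical cohort tables


def read_cohort_table(path) -> pd.DataFrame:
    """Read a cohort TSV (subject, time, event, then one column per gene)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("subject", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    if (df["time"] <= 0).any():
        raise ValidationError("follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event column must be 0/1")
    return df


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)
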