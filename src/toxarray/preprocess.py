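"""Spot-level preprocessing for two-color arrays.

The chain mirrors standard two-channel practice: (1) subtract local
background per channel; (2) drop flagged and low signal-to-noise spots;
(3) express each spot in M/A coordinates, M = log2(treated/control),
A = average log2 intensity; (4) remove the intensity-dependent dye-bias
trend by subtracting a LOWESS fit of M on A; (5) average duplicate spots
within each array, then biological replicate arrays.  A QC report carries
spot-pass fractions and between-array correlations with the conventional
pass thresholds (>95% spots passing, array-to-array r > 0.90,
replicate/dye-swap consistency r > 0.85).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .exceptions import DegenerateDataError, EmptyResultError, ValidationError
from .io import ArrayScan

logger = logging.getLogger(__name__)

RATIO_COLUMNS = ["gene", "A", "M", "array_id", "spot_id"]


@dataclass
class FilterReport:
    """Per-reason spot counts from :func:`filter_spots`."""

    array_id: str
    total: int
    retained: int
    flagged: int = 0
    low_snr: int = 0

    @property
    def pass_fraction(self) -> float:
        return self.retained / self.total if self.total else 0.0


@dataclass
class QCReport:
    """Array-level quality metrics with threshold verdicts."""

    spot_pass_fraction: dict
    array_correlations: dict
    replicate_consistency: float | None
    array_reproducibility: float | None
    thresholds: dict = field(
        default_factory=lambda: {
            "spot_pass": 0.95, "array_r": 0.90, "replicate_r": 0.85,
        }
    )

    @property
    def verdicts(self) -> dict:
        t = self.thresholds
        return {
            "spot_pass": all(
                f > t["spot_pass"] for f in self.spot_pass_fraction.values()
            ),
            "array_r": (
                None if self.array_reproducibility is None
                else bool(self.array_reproducibility > t["array_r"])
            ),
            "replicate_r": (
                None if self.replicate_consistency is None
                else bool(self.replicate_consistency > t["replicate_r"])
            ),
        }


def correct_background(scan: ArrayScan) -> ArrayScan:
    """Subtract local background per channel; flag nonpositive signals.

    Adds ``s1``/``s2`` columns (``fg - bg``).  Spots where either corrected
    signal is <= 0 are flagged BAD with reason ``nonpositive`` rather than
    dropped, so the audit trail survives until :func:`filter_spots`.
    """
    out = scan.copy()
    df = out.data
    df["s1"] = df["fg1"] - df["bg1"]
    df["s2"] = df["fg2"] - df["bg2"]
    nonpos = (df["s1"] <= 0) | (df["s2"] <= 0)
    if "flag_reason" not in df.columns:
        df["flag_reason"] = ""
    df.loc[nonpos, "flag"] = "BAD"
    df.loc[nonpos, "flag_reason"] = "nonpositive"
    out.provenance.append(
        f"background-corrected ({int(nonpos.sum())} nonpositive flagged)"
    )
    return out


def filter_spots(
    scan: ArrayScan, min_snr: float = 1.5, drop_flagged: bool = True
) -> tuple[ArrayScan, FilterReport]:
    """Remove BAD-flagged and low-SNR spots, with per-reason counts.

    SNR is ``min(fg1/max(bg1,1), fg2/max(bg2,1))``; spots below ``min_snr``
    are removed.  Raises :class:`EmptyResultError` if nothing survives.
    """
    out = scan.copy()
    df = out.data
    flagged = (df["flag"] == "BAD") if drop_flagged else pd.Series(False, index=df.index)
    snr = np.minimum(
        df["fg1"] / np.maximum(df["bg1"], 1.0),
        df["fg2"] / np.maximum(df["bg2"], 1.0),
    )
    low = (snr < min_snr) & ~flagged
    keep = ~(flagged | low)
    report = FilterReport(
        array_id=scan.array_id,
        total=len(df),
        retained=int(keep.sum()),
        flagged=int(flagged.sum()),
        low_snr=int(low.sum()),
    )
    if report.retained == 0:
        raise EmptyResultError(
            f"array {scan.array_id!r}: every spot removed by filtering"
        )
    out.data = df[keep].reset_index(drop=True)
    out.provenance.append(
        f"filtered (flagged={report.flagged}, low_snr={report.low_snr})"
    )
    return out, report


def compute_ratios(scan: ArrayScan) -> pd.DataFrame:
    """Per-spot M/A records: M = log2(s2) - log2(s1), A = their mean.

    The scan must be background-corrected and filtered; any nonpositive
    signal reaching this stage is an internal-contract violation.  For
    dye-swapped arrays M is negated so it is always treated minus control.
    """
    df = scan.data
    if "s1" not in df.columns or "s2" not in df.columns:
        raise ValidationError(
            "scan lacks corrected signals; run correct_background first"
        )
    if ((df["s1"] <= 0) | (df["s2"] <= 0)).any():
        raise ValidationError(
            f"array {scan.array_id!r}: nonpositive corrected signal reached "
            "compute_ratios; filter_spots must run first"
        )
    l1 = np.log2(df["s1"].to_numpy(float))
    l2 = np.log2(df["s2"].to_numpy(float))
    M = l2 - l1
    if scan.dye_orientation == "swapped":
        M = -M
    return pd.DataFrame(
        {
            "gene": df["gene"].to_numpy(),
            "A": (l1 + l2) / 2.0,
            "M": M,
            "array_id": scan.array_id,
            "spot_id": df["spot_id"].to_numpy(),
        },
        columns=RATIO_COLUMNS,
    )


def lowess_normalize(
    records: pd.DataFrame,
    span: float = 0.3,
    robustness_iters: int = 3,
    delta: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract a LOWESS fit of M on A (tri-cube weighted local lines).

    ``span`` is the fraction of points in each local fit; three robustness
    (residual-reweighting) iterations are run by default.  Below 50 records
    the local fit is unreliable and plain median-centering is applied with a
    warning.  Returns ``(normalized_records, fit)`` where ``fit`` holds the
    fitted curve evaluated at each record's A (for MA plots).
    """
    if len(records) == 0:
        raise EmptyResultError("no ratio records to normalize")
    A = records["A"].to_numpy(float)
    M = records["M"].to_numpy(float)
    out = records.copy()
    if len(records) < 50:
        logger.warning(
            "only %d records: falling back to median-centering", len(records)
        )
        fitted = np.full(len(records), float(np.median(M)))
    else:
        if np.ptp(A) == 0.0:
            raise DegenerateDataError(
                "all records share one A value; LOWESS fit is degenerate"
            )
        if delta is None:
            delta = 0.005 * np.ptp(A)
        fitted = sm_lowess(
            M, A, frac=span, it=robustness_iters, delta=delta,
            return_sorted=False,
        )
    out["M"] = M - fitted
    fit = pd.DataFrame({"A": A, "fitted": fitted}).sort_values("A")
    return out, fit.reset_index(drop=True)


def average_replicates(
    per_array_records: list[pd.DataFrame], min_arrays: int = 1
) -> pd.DataFrame:
    """Two-stage averaging: duplicate spots within arrays, then across arrays.

    Returns gene-level records ``gene, A, R, n_spots, n_arrays`` where R is
    the unweighted mean over arrays of each array's mean normalized M.
    Genes seen in fewer than ``min_arrays`` arrays are dropped and recorded
    in ``result.attrs['dropped_genes']``.
    """
    if not per_array_records:
        raise EmptyResultError("no arrays supplied")
    per_array = [
        df.groupby("gene", sort=True).agg(
            A=("A", "mean"), M=("M", "mean"), n_spots=("M", "size")
        )
        for df in per_array_records
    ]
    combined = pd.concat(per_array, axis=0)
    gene_level = combined.groupby(level=0, sort=True).agg(
        A=("A", "mean"), R=("M", "mean"), n_spots=("n_spots", "sum"),
        n_arrays=("M", "size"),
    )
    dropped = gene_level.index[gene_level["n_arrays"] < min_arrays].tolist()
    if dropped:
        logger.warning(
            "%d gene(s) present in < %d arrays dropped", len(dropped), min_arrays
        )
    gene_level = gene_level[gene_level["n_arrays"] >= min_arrays]
    if len(gene_level) == 0:
        raise EmptyResultError("no genes survive replicate averaging")
    result = gene_level.reset_index()
    result.attrs["dropped_genes"] = dropped
    return result


def qc_report(
    per_array_gene_level: list[pd.DataFrame],
    filter_reports: list[FilterReport] | None = None,
    dye_orientations: dict | None = None,
) -> QCReport:
    """Spot-pass fractions and between-array gene-level M correlations.

    ``per_array_gene_level`` holds per-array gene means (columns ``gene``
    and ``M``; output of the first stage of :func:`average_replicates`, or
    any frame with those columns).  Array reproducibility is the minimum
    pairwise Pearson r on shared genes; replicate consistency is the minimum
    over pairs of opposite dye orientation when orientations are given,
    otherwise the same minimum.  With a single array both are None.
    """
    series = {}
    for i, df in enumerate(per_array_gene_level):
        aid = df["array_id"].iloc[0] if "array_id" in df.columns else f"array{i}"
        series[aid] = df.groupby("gene")["M"].mean()
    pair_r: dict = {}
    for (a, sa), (b, sb) in itertools.combinations(series.items(), 2):
        shared = sa.index.intersection(sb.index)
        if len(shared) >= 3:
            pair_r[(a, b)] = float(np.corrcoef(sa[shared], sb[shared])[0, 1])
    reproducibility = min(pair_r.values()) if pair_r else None
    consistency = reproducibility
    if dye_orientations and pair_r:
        swap_pairs = [
            r for (a, b), r in pair_r.items()
            if dye_orientations.get(a) != dye_orientations.get(b)
        ]
        if swap_pairs:
            consistency = min(swap_pairs)
    pass_frac = (
        {r.array_id: r.pass_fraction for r in filter_reports}
        if filter_reports else {}
    )
    return QCReport(
        spot_pass_fraction=pass_frac,
        array_correlations={f"{a}|{b}": r for (a, b), r in pair_r.items()},
        replicate_consistency=consistency,
        array_reproducibility=reproducibility,
    )


def run_preprocessing(
    scans: list[ArrayScan],
    min_snr: float = 1.5,
    span: float = 0.3,
    min_arrays: int = 1,
) -> tuple[pd.DataFrame, QCReport]:
    """The full spot-to-gene chain over replicate arrays.

    Returns ``(gene_level, qc)`` where ``gene_level`` has columns
    ``gene, A, R, n_spots, n_arrays``.
    """
    per_array = []
    reports = []
    orientations = {}
    for scan in scans:
        corrected = correct_background(scan)
        filtered, rep = filter_spots(corrected, min_snr=min_snr)
        reports.append(rep)
        orientations[scan.array_id] = scan.dye_orientation
        ratios = compute_ratios(filtered)
        normalized, _ = lowess_normalize(ratios, span=span)
        per_array.append(normalized)
    gene_level = average_replicates(per_array, min_arrays=min_arrays)
    qc = qc_report(per_array, reports, orientations)
    return gene_level, qc
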