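"""Synthetic data with planted ground truth for every pipeline stage.

The experiment generator emulates a two-color spotted oligonucleotide
platform: ~5000 gene probes printed in duplicate, paired control (channel 1,
Alexa555) vs treated (channel 2, Alexa647) labeling on each slide, additive
background, an intensity-dependent dye-bias curve in M/A coordinates, ratio
noise whose SD grows toward low intensity, and biological replicate arrays.
Companion generators produce literature label tables, gene-set collections
with one planted enriched term, scored interaction edge lists with a planted
hub, and clinical cohorts with a planted signature hazard ratio and a planted
Spearman coupling between one gene and an infiltration score.

All generators are deterministic under their seed; the experiment generator
derives one independent stream per array from ``(seed, array_index)`` so
adding arrays never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .io import ArrayScan, SPOT_COLUMNS


@dataclass(frozen=True)
class DoseRegimen:
    """An intraperitoneal dosing schedule: dose x injections/cycle x cycles."""

    dose_per_injection: float = 2.0  # mg/kg
    injections_per_cycle: int = 2
    n_cycles: int = 5

    def __post_init__(self):
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"{f.name} must be strictly positive")


def cumulative_dose(regimen: DoseRegimen) -> float:
    """Total administered dose in mg/kg over the whole regimen."""
    return (
        regimen.dose_per_injection
        * regimen.injections_per_cycle
        * regimen.n_cycles
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-color experiment.

    Intensities live on the log2 scale: a gene's true signal is drawn as
    ``2**N(base_intensity_log_mean, base_intensity_log_sd)``.  The dye-bias
    curve ``c(A)`` is a polynomial (coefficients in increasing order) in the
    standardized intensity ``u = (A - base_mean) / (2 * base_sd)``, added to
    the true log-ratio M.  Ratio noise SD is log-linear in A between the
    anchors ``base_mean -/+ 2*base_sd``.
    """

    n_genes: int = 5000
    n_duplicate_spots: int = 2
    n_arrays: int = 2
    prop_de: float = 0.03
    de_log2fc_magnitude: float = 1.5
    base_intensity_log_mean: float = 10.0
    base_intensity_log_sd: float = 1.5
    dye_bias_coeffs: tuple = (0.25, -0.3, 0.0, 0.2)
    background_level: float = 100.0
    noise_sd_at_high_A: float = 0.15
    noise_sd_at_low_A: float = 0.45
    spot_intensity_jitter: float = 0.3
    prop_bad_spots: float = 0.01
    include_dye_swap: bool = False
    seed: int = 0
    regimen: DoseRegimen = field(default_factory=DoseRegimen)

    def __post_init__(self):
        for name in ("n_genes", "n_duplicate_spots", "n_arrays"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("prop_de", "prop_bad_spots"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("noise_sd_at_high_A", "noise_sd_at_low_A"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.base_intensity_log_sd <= 0:
            raise ConfigurationError("base_intensity_log_sd must be > 0")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")
        if self.de_log2fc_magnitude < 0:
            raise ConfigurationError("de_log2fc_magnitude must be >= 0")
        if self.spot_intensity_jitter < 0:
            raise ConfigurationError("spot_intensity_jitter must be >= 0")


def dye_bias_curve(A: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Evaluate the configured bias curve c(A) at average log2 intensity A."""
    u = (np.asarray(A, float) - config.base_intensity_log_mean) / (
        2.0 * config.base_intensity_log_sd
    )
    return npoly.polyval(u, np.asarray(config.dye_bias_coeffs, float))


def noise_sd_curve(A: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Ratio-noise SD at intensity A: log-linear between the two anchors."""
    lo = config.base_intensity_log_mean - 2.0 * config.base_intensity_log_sd
    hi = config.base_intensity_log_mean + 2.0 * config.base_intensity_log_sd
    s_lo, s_hi = config.noise_sd_at_low_A, config.noise_sd_at_high_A
    if s_lo == 0.0 or s_hi == 0.0:
        return np.zeros_like(np.asarray(A, float))
    t = np.clip((np.asarray(A, float) - lo) / (hi - lo), 0.0, 1.0)
    return np.exp(np.log(s_lo) + t * (np.log(s_hi) - np.log(s_lo)))


def _gene_symbols(n: int) -> list:
    return [f"G{i:05d}" for i in range(n)]


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[ArrayScan], pd.DataFrame]:
    """Generate replicate two-channel arrays plus a ground-truth table.

    Returns ``(scans, truth)`` where ``truth`` has columns
    ``gene, true_log2fc, is_de`` and exactly ``round(prop_de * n_genes)``
    rows with ``is_de`` set.  Each scan holds
    ``n_genes * n_duplicate_spots`` spots; channel intensities are
    ``background + signal`` with ``log2(s2/s1) = true_log2fc + c(A) + noise``.
    """
    genes = _gene_symbols(config.n_genes)
    rng_genes = np.random.default_rng([config.seed, 0xA11CE])

    base_A = rng_genes.normal(
        config.base_intensity_log_mean,
        config.base_intensity_log_sd,
        config.n_genes,
    )
    n_de = int(round(config.prop_de * config.n_genes))
    true_lfc = np.zeros(config.n_genes)
    de_idx = rng_genes.choice(config.n_genes, size=n_de, replace=False)
    signs = rng_genes.choice([-1.0, 1.0], size=n_de)
    true_lfc[de_idx] = signs * config.de_log2fc_magnitude
    if config.de_log2fc_magnitude == 0:
        true_lfc[:] = 0.0
    truth = pd.DataFrame(
        {"gene": genes, "true_log2fc": true_lfc, "is_de": true_lfc != 0.0}
    )

    n_dup = config.n_duplicate_spots
    n_spots = config.n_genes * n_dup
    gene_col = np.repeat(genes, n_dup)
    lfc_spot = np.repeat(true_lfc, n_dup)
    A_gene = np.repeat(base_A, n_dup)
    spot_ids = [f"s{i:06d}" for i in range(n_spots)]

    scans: list[ArrayScan] = []
    for a in range(config.n_arrays):
        rng = np.random.default_rng([config.seed, 1, a])
        A_spot = A_gene + (
            rng.normal(0.0, config.spot_intensity_jitter, n_spots)
            if config.spot_intensity_jitter > 0
            else 0.0
        )
        sd = noise_sd_curve(A_spot, config)
        eps = rng.standard_normal(n_spots) * sd
        M = lfc_spot + dye_bias_curve(A_spot, config) + eps
        s1 = np.exp2(A_spot - M / 2.0)
        s2 = np.exp2(A_spot + M / 2.0)
        if config.background_level > 0:
            bg1 = config.background_level * rng.uniform(0.8, 1.2, n_spots)
            bg2 = config.background_level * rng.uniform(0.8, 1.2, n_spots)
        else:
            bg1 = np.zeros(n_spots)
            bg2 = np.zeros(n_spots)
        swapped = config.include_dye_swap and (a % 2 == 1)
        if swapped:
            s1, s2 = s2, s1
        flags = np.where(
            rng.random(n_spots) < config.prop_bad_spots, "BAD", "OK"
        )
        data = pd.DataFrame(
            {
                "spot_id": spot_ids,
                "gene": gene_col,
                "fg1": s1 + bg1,
                "bg1": bg1,
                "fg2": s2 + bg2,
                "bg2": bg2,
                "flag": flags,
            },
            columns=SPOT_COLUMNS,
        )
        scans.append(
            ArrayScan(
                array_id=f"array{a}",
                data=data,
                dye_orientation="swapped" if swapped else "standard",
                provenance=[f"simulated(seed={config.seed}, array={a})"],
            )
        )
    return scans, truth


def simulate_literature_db(
    genes: Sequence[str],
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    frac_seg: float = 0.05,
    seed: int = 0,
):
    """Label disjoint random gene subsets UP / DOWN / SEG.

    Fractions apply to ``len(genes)`` and must sum to <= 1; duplicate input
    symbols are rejected.  Returns a :class:`~toxarray.io.LiteratureDB`.
    """
    from .io import LiteratureDB

    genes = list(genes)
    if not genes:
        raise ValidationError("gene list must be nonempty")
    if len(set(genes)) < len(genes):
        from collections import Counter

        dup = sorted(g for g, c in Counter(genes).items() if c > 1)
        raise ValidationError(f"duplicate symbols in gene list: {dup[:10]}")
    if frac_up + frac_down + frac_seg > 1.0 + 1e-12:
        raise ConfigurationError("label fractions must sum to <= 1")
    rng = np.random.default_rng([seed, 0x11B])
    perm = rng.permutation(genes)
    n_up = int(round(frac_up * len(genes)))
    n_down = int(round(frac_down * len(genes)))
    n_seg = int(round(frac_seg * len(genes)))
    db = LiteratureDB()
    cursor = 0
    for label, n in (("UP", n_up), ("DOWN", n_down), ("SEG", n_seg)):
        for g in perm[cursor:cursor + n]:
            db.add(str(g), label, f"sim:{label.lower()}(seed={seed})")
        cursor += n
    return db


def simulate_geneset_collection(
    genes: Sequence[str],
    query: Sequence[str],
    n_terms: int = 50,
    planted_term_size: int = 40,
    planted_overlap: int = 15,
    term_size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
):
    """Random gene sets plus one planted term overlapping a designated query.

    The planted term (id ``"PLANTED"``) shares exactly ``planted_overlap``
    members with ``query``; the remaining members are drawn outside it.
    Returns ``(collection, "PLANTED")``.
    """
    from .io import GeneSetCollection

    genes = list(genes)
    query = list(dict.fromkeys(query))
    if not 0 <= planted_overlap <= planted_term_size <= len(genes):
        raise ValidationError(
            "need 0 <= planted_overlap <= planted_term_size <= len(genes)"
        )
    if planted_overlap > len(query):
        raise ValidationError("planted_overlap exceeds query size")
    outside = [g for g in genes if g not in set(query)]
    n_out = planted_term_size - planted_overlap
    if n_out > len(outside):
        raise ValidationError(
            "planted term cannot avoid the query: too few genes outside it"
        )
    rng = np.random.default_rng([seed, 0x65E7])
    planted = list(rng.choice(query, size=planted_overlap, replace=False)) + (
        list(rng.choice(outside, size=n_out, replace=False)) if n_out else []
    )
    collection = GeneSetCollection()
    collection.add("PLANTED", "planted enriched term", planted)
    lo, hi = term_size_range
    hi = min(hi, len(genes))
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        collection.add(f"T{t:04d}", f"random term {t}", [str(m) for m in members])
    return collection, "PLANTED"


def simulate_ppi_edges(
    genes: Sequence[str],
    hub_gene: str,
    hub_degree: int = 12,
    n_background_edges: int = 50,
    score_range: tuple[float, float] = (0.15, 0.95),
    seed: int = 0,
) -> pd.DataFrame:
    """Scored edge list with one planted hub of known post-filter degree.

    ``hub_gene`` gets exactly ``hub_degree`` edges with scores in
    [0.700, 1.0]; background edges connect the remaining genes with scores
    spanning ``score_range`` and never touch the hub.
    """
    genes = list(genes)
    if hub_gene not in genes:
        raise ValidationError(f"hub_gene {hub_gene!r} not in gene list")
    others = [g for g in genes if g != hub_gene]
    if hub_degree >= len(genes):
        raise ValidationError(
            f"hub_degree ({hub_degree}) must be < number of genes ({len(genes)})"
        )
    rng = np.random.default_rng([seed, 0x991])
    partners = rng.choice(others, size=hub_degree, replace=False)
    rows = [
        (min(hub_gene, str(p)), max(hub_gene, str(p)), rng.uniform(0.700, 1.0))
        for p in partners
    ]
    seen = {(r[0], r[1]) for r in rows}
    max_bg = len(others) * (len(others) - 1) // 2
    if n_background_edges > max_bg:
        raise ValidationError(
            f"n_background_edges ({n_background_edges}) exceeds the "
            f"{max_bg} possible non-hub pairs"
        )
    while len(rows) < hub_degree + n_background_edges:
        a, b = rng.choice(others, size=2, replace=False)
        key = (min(str(a), str(b)), max(str(a), str(b)))
        if key in seen:
            continue
        seen.add(key)
        rows.append((*key, rng.uniform(*score_range)))
    df = pd.DataFrame(rows, columns=["node1", "node2", "score"])
    return df.sort_values(["node1", "node2"]).reset_index(drop=True)


def simulate_clinical_cohort(
    n_subjects: int,
    signature_genes: Sequence[str],
    planted_log_hr: float = 0.0,
    planted_rho: float = 0.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    infiltration_gene: str | None = None,
    baseline_hazard: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival cohort with a planted signature effect and infiltration coupling.

    Event times are exponential with log-hazard
    ``log(baseline_hazard) + planted_log_hr * (h - 1/2)`` where ``h``
    indicates the upper median-split half of the standardized mean signature
    score — so ``exp(planted_log_hr)`` is exactly the high-vs-low hazard
    ratio the downstream median-split analysis estimates, making the planted
    value identifiable.  Censoring selects a
    ``censor_rate`` fraction of subjects independently of covariates and
    truncates their follow-up uniformly inside (0, T).  The infiltration
    column is coupled to ``infiltration_gene`` (default: first signature
    gene) through a Gaussian copula with Pearson parameter
    ``2*sin(pi*rho/6)``, which targets Spearman ``planted_rho`` and is exact
    at rho = +/-1.

    Returns ``(cohort, infiltration)`` DataFrames keyed by ``subject``.
    """
    if n_subjects < 20:
        raise ValidationError("n_subjects must be >= 20")
    if not -1.0 <= planted_rho <= 1.0:
        raise ValidationError("planted_rho must be in [-1, 1]")
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must be in [0, 1)")
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise ValidationError("signature_genes must be nonempty")
    rng = np.random.default_rng([seed, 0xC0403])
    n = n_subjects
    X = rng.standard_normal((n, len(signature_genes)))
    score = X.mean(axis=1)
    score = (score - score.mean()) / score.std(ddof=0)
    high = score > np.median(score)
    hazard = baseline_hazard * np.exp(planted_log_hr * (high.astype(float) - 0.5))
    T = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censor_rate
    time = np.where(censored, T * rng.uniform(0.0, 1.0, n), T)
    event = (~censored).astype(int)

    g = infiltration_gene or signature_genes[0]
    if g not in signature_genes:
        raise ValidationError(f"infiltration_gene {g!r} not in signature_genes")
    x = X[:, signature_genes.index(g)]
    # rank-normal scores of the coupled gene (Blom offsets avoid +/-inf)
    ranks = stats.rankdata(x)
    z_g = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    r = 2.0 * np.sin(np.pi * planted_rho / 6.0)
    infil = r * z_g + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)

    subjects = [f"P{i:05d}" for i in range(n)]
    cohort = pd.DataFrame({"subject": subjects, "time": time, "event": event})
    for j, gene in enumerate(signature_genes):
        cohort[gene] = X[:, j]
    infiltration = pd.DataFrame({"subject": subjects, "infiltration": infil})
    return cohort, infiltration
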