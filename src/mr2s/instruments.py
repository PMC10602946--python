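"""Instrument strength diagnostics, cis/trans classification, LD clumping,
and statistical power for binary-outcome MR.

Variance explained per variant uses R^2 = 2 * beta^2 * EAF * (1 - EAF), the
standard approximation for a standardized continuous trait; the F-statistic
is F = ((N - K - 1) / K) * (R^2 / (1 - R^2)), with K = 1 for per-variant
diagnostics.  Instruments with F < 10 are flagged as weak.  Power follows
the usual non-centrality approximation for a log-odds causal effect
estimated by IVW with instrument strength R^2 in a case-control sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import SummaryDataset, VariantAssociation
from .harmonize import LDTable

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class GeneWindow:
    """A cis window around a gene's transcription start site."""

    gene_label: str
    chromosome: str
    tss_position: int
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


#: Default cis window for the resistin-coding gene (GRCh37).
RETN_WINDOW = GeneWindow("RETN", "19", 7_733_000, 1_000_000)


@dataclass(frozen=True)
class VariantDiagnostics:
    rsid: str
    r2_explained: float
    f_statistic: float
    is_weak: bool


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Per-variant and aggregate instrument-strength summaries.

    ``total_r2`` sums per-variant variance explained (valid for uncorrelated
    instruments); ``mean_f`` is the arithmetic mean of per-variant F.
    """

    per_variant: tuple[VariantDiagnostics, ...]

    @property
    def total_r2(self) -> float:
        return float(sum(v.r2_explained for v in self.per_variant))

    @property
    def mean_f(self) -> float:
        return float(np.mean([v.f_statistic for v in self.per_variant]))

    @property
    def k_instruments(self) -> int:
        return len(self.per_variant)

    @property
    def any_weak(self) -> bool:
        return any(v.is_weak for v in self.per_variant)


def variance_explained(beta: float, eaf: float) -> float:
    """Proportion of exposure variance explained by one variant."""
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf must lie in (0,1), got {eaf}")
    return 2.0 * beta * beta * eaf * (1.0 - eaf)


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """Instrument-strength F for variance explained r2, sample size n, k instruments."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0,1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1, got n={n}, k={k}")
    return ((n - k - 1) / k) * (r2 / (1.0 - r2))


def diagnose(dataset: SummaryDataset, weak_threshold: float = WEAK_F_THRESHOLD) -> InstrumentDiagnostics:
    """Per-variant R^2 and F (k=1, each variant's own N) for a set of instruments."""
    per = []
    for rec in dataset.records.values():
        if rec.eaf is None or rec.sample_size is None:
            raise ValueError(f"{rec.rsid}: diagnostics need eaf and sample size")
        r2 = variance_explained(rec.beta, rec.eaf)
        f = f_statistic(r2, rec.sample_size, k=1)
        per.append(VariantDiagnostics(rec.rsid, r2, f, f < weak_threshold))
    return InstrumentDiagnostics(tuple(per))


def classify_cis_trans(variant: VariantAssociation, window: GeneWindow = RETN_WINDOW) -> str:
    """'cis' iff the variant lies within the gene window, else 'trans'."""
    if str(variant.chromosome) == str(window.chromosome) and \
            abs(variant.position - window.tss_position) <= window.window_bp:
        return "cis"
    return "trans"


def clump_cis_candidates(
    candidates: SummaryDataset,
    ld: LDTable,
    region: GeneWindow,
    max_r2: float = 0.1,
    min_distance_bp: int = 100,
) -> list[str]:
    """Greedy LD clumping of candidate variants inside a gene region.

    Candidates are restricted to the region and visited in ascending p-value
    order (ties: position, then rsid); one is retained iff its LD r^2 with
    every already-retained variant is <= ``max_r2`` and its distance to each
    is >= ``min_distance_bp``.  Pairs absent from the LD table are treated as
    unlinked (r^2 = 0) with a warning.
    """
    in_region = [r for r in candidates.records.values()
                 if classify_cis_trans(r, region) == "cis"]
    if not in_region:
        logger.warning("no candidates inside %s region", region.gene_label)
        return []
    in_region.sort(key=lambda r: (r.pvalue, r.position, r.rsid))
    selected: list[VariantAssociation] = []
    for cand in in_region:
        ok = True
        for kept_v in selected:
            r = ld.r_between(cand.rsid, kept_v.rsid, default=np.nan)
            if np.isnan(r):
                logger.warning("LD pair (%s, %s) missing; assuming r2=0",
                               cand.rsid, kept_v.rsid)
                r = 0.0
            if r * r > max_r2 or abs(cand.position - kept_v.position) < min_distance_bp:
                ok = False
                break
        if ok:
            selected.append(cand)
    return [v.rsid for v in selected]


def _case_fraction(case_control_ratio: float) -> float:
    if not (0.0 < case_control_ratio < np.inf):
        raise ValueError(f"case:control ratio must be finite and positive, got {case_control_ratio}")
    return case_control_ratio / (1.0 + case_control_ratio)


def power_binary(n_total: float, case_control_ratio: float, r2: float,
                 odds_ratio: float, alpha: float = 0.05) -> float:
    """Power to detect a given OR per SD of exposure in a binary-outcome MR."""
    k = _case_fraction(case_control_ratio)
    ncp = abs(np.log(odds_ratio)) * np.sqrt(n_total * r2 * k * (1.0 - k))
    return float(stats.norm.cdf(ncp - stats.norm.ppf(1.0 - alpha / 2.0)))


def minimum_detectable_or(n_total: float, case_control_ratio: float, r2: float,
                          power: float = 0.80, alpha: float = 0.05) -> float:
    """Smallest OR per SD detectable at the given power and alpha.

    Closed-form inversion of :func:`power_binary`:
    b = (z_{1-alpha/2} + z_power) / sqrt(N * R^2 * k * (1-k)), returned as exp(b).
    """
    if not (0.0 < r2 < 1.0):
        raise ValueError(f"r2 must lie in (0,1), got {r2}")
    if not (0.0 < power < 1.0 and 0.0 < alpha < 1.0):
        raise ValueError("power and alpha must lie in (0,1)")
    k = _case_fraction(case_control_ratio)
    b = (stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)) \
        / np.sqrt(n_total * r2 * k * (1.0 - k))
    return float(np.exp(b))
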