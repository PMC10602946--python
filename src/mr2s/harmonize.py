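"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires the exposure effect beta_j and outcome effect Gamma_j
of every instrument to refer to the same allele.  This module aligns the
outcome record to the exposure's effect allele, rescuing strand flips for
non-palindromic variants, excluding strand-ambiguous palindromic variants
(A/T or C/G with intermediate MAF), and substituting an LD proxy when the
index variant is missing from the outcome dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .gwas_io import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Exclusion reasons carried by HarmonizedInstrument.
REASONS = ("missing_no_proxy", "palindromic_ambiguous", "user_excluded")

DEFAULT_AMBIGUITY_MAF = 0.42
DEFAULT_PROXY_MIN_R2 = 0.80
DEFAULT_PROXY_WINDOW_BP = 500_000


class HarmonizationError(ValueError):
    """Allele pairs cannot be reconciled even after strand complementing."""


class EmptyInstrumentSetError(RuntimeError):
    """Harmonization left zero usable instruments."""


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure-outcome aligned instrument with provenance.

    ``flipped`` records whether the outcome effect sign was negated during
    alignment.  Excluded instruments carry exactly one ``exclusion_reason``
    and no outcome fields.
    """

    rsid: str
    beta_exp: float
    se_exp: float
    eaf: float | None
    status: str = "kept"  # kept | excluded
    beta_out: float | None = None
    se_out: float | None = None
    eaf_out: float | None = None
    flipped: bool = False
    proxy_rsid: str | None = None
    proxy_r2: float | None = None
    locus_class: str | None = None  # cis | trans
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.status == "kept":
            if self.beta_out is None or self.se_out is None or self.se_out <= 0 or self.se_exp <= 0:
                raise ValueError(f"{self.rsid}: kept instrument lacks valid outcome statistics")
            if self.exclusion_reason is not None:
                raise ValueError(f"{self.rsid}: kept instrument cannot carry an exclusion reason")
        elif self.status == "excluded":
            if self.exclusion_reason not in REASONS:
                raise ValueError(f"{self.rsid}: excluded instrument needs a reason from {REASONS}")
        else:
            raise ValueError(f"{self.rsid}: status must be 'kept' or 'excluded'")

    @property
    def wald_ratio(self) -> float:
        return self.beta_out / self.beta_exp


@dataclass
class LDTable:
    """Pairwise signed LD correlations with positions and allele orientation.

    ``entries`` columns: rsid_a, rsid_b, r (signed, for alleles allele_a /
    allele_b), r2, distance_bp, allele_a, allele_b.  Lookups are symmetric in
    (a, b); the sign of r refers to the stated allele pairing.
    """

    entries: pd.DataFrame

    REQUIRED = ("rsid_a", "rsid_b", "r", "r2", "distance_bp")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise ValueError(f"LD table missing columns {missing}")
        bad = (self.entries["r"] ** 2 - self.entries["r2"]).abs() > 1e-12
        if bad.any():
            raise ValueError(f"LD table rows where r2 != r^2: {self.entries.index[bad].tolist()}")
        if ((self.entries["r2"] < 0) | (self.entries["r2"] > 1)).any():
            raise ValueError("LD r2 outside [0,1]")

    @classmethod
    def read(cls, path: str | Path) -> "LDTable":
        return cls(pd.read_csv(path, sep="\t"))

    def partners_of(self, rsid: str) -> pd.DataFrame:
        """All entries touching ``rsid``, normalized so rsid_a == rsid."""
        e = self.entries
        fwd = e[e["rsid_a"] == rsid]
        rev = e[e["rsid_b"] == rsid].rename(columns={
            "rsid_a": "rsid_b", "rsid_b": "rsid_a",
            "allele_a": "allele_b", "allele_b": "allele_a"})
        out = pd.concat([fwd, rev], ignore_index=True)
        if "distance_bp" in out.columns:
            out["distance_bp"] = out["distance_bp"].abs()
        return out

    def r_between(self, rsid_a: str, rsid_b: str, default: float = 0.0) -> float:
        """Signed r between two variants; ``default`` when the pair is absent."""
        if rsid_a == rsid_b:
            return 1.0
        p = self.partners_of(rsid_a)
        hit = p[p["rsid_b"] == rsid_b]
        if hit.empty:
            return default
        return float(hit.iloc[0]["r"])


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-symmetric ({A,T} or {C,G})."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if len(ea) != 1 or len(oa) != 1 or ea not in _COMPLEMENT or oa not in _COMPLEMENT:
        raise HarmonizationError(f"unsupported alleles for palindrome test: {ea!r}/{oa!r}")
    return _COMPLEMENT[ea] == oa


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def harmonize_variant(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    ambiguity_maf_threshold: float = DEFAULT_AMBIGUITY_MAF,
    locus_class: str | None = None,
    proxy_rsid: str | None = None,
    proxy_r2: float | None = None,
) -> HarmonizedInstrument:
    """Align one outcome record to the exposure's effect allele.

    Resolution order: direct allele match; allele swap (sign flip, EAF
    complement); strand complement then match/swap (non-palindromic only).
    Palindromic variants with MAF above ``ambiguity_maf_threshold`` are
    excluded as strand-ambiguous; below the threshold they are aligned by
    matching the minor allele between the two datasets.
    """
    ea_x, oa_x = exposure.effect_allele, exposure.other_allele
    ea_y, oa_y = outcome.effect_allele, outcome.other_allele
    common = dict(rsid=exposure.rsid, beta_exp=exposure.beta, se_exp=exposure.se,
                  eaf=exposure.eaf, locus_class=locus_class,
                  proxy_rsid=proxy_rsid, proxy_r2=proxy_r2)

    if is_palindromic(ea_x, oa_x):
        maf = exposure.maf
        if maf is None or maf > ambiguity_maf_threshold:
            return HarmonizedInstrument(status="excluded",
                                        exclusion_reason="palindromic_ambiguous", **common)
        # Unambiguous palindrome: orient by minor-allele identity.  The
        # exposure effect allele is minor iff eaf < 0.5; the outcome is
        # aligned iff its reported frequency for the same label agrees.
        if {ea_y, oa_y} != {ea_x, oa_x}:
            raise HarmonizationError(
                f"{exposure.rsid}: palindromic allele sets differ: {ea_x}/{oa_x} vs {ea_y}/{oa_y}")
        if outcome.eaf is None:
            return HarmonizedInstrument(status="excluded",
                                        exclusion_reason="palindromic_ambiguous", **common)
        exp_effect_is_minor = exposure.eaf < 0.5
        # frequency of the exposure's effect-allele *label* in the outcome
        out_freq = outcome.eaf if ea_y == ea_x else 1.0 - outcome.eaf
        out_label_is_minor = out_freq < 0.5
        if exp_effect_is_minor == out_label_is_minor:
            flip = ea_y != ea_x   # same strand labelling
            eaf_out = out_freq
        else:
            flip = ea_y == ea_x   # opposite strand labelling: complement == swap
            eaf_out = 1.0 - out_freq
        beta_out = -outcome.beta if flip else outcome.beta
        return HarmonizedInstrument(status="kept", beta_out=beta_out, se_out=outcome.se,
                                    eaf_out=eaf_out, flipped=flip, **common)

    for candidate_ea, candidate_oa, complemented in (
            (ea_y, oa_y, False), (*_complement_pair(ea_y, oa_y), True)):
        if (candidate_ea, candidate_oa) == (ea_x, oa_x):
            return HarmonizedInstrument(status="kept", beta_out=outcome.beta,
                                        se_out=outcome.se, eaf_out=outcome.eaf,
                                        flipped=False, **common)
        if (candidate_ea, candidate_oa) == (oa_x, ea_x):
            eaf_out = None if outcome.eaf is None else 1.0 - outcome.eaf
            return HarmonizedInstrument(status="kept", beta_out=-outcome.beta,
                                        se_out=outcome.se, eaf_out=eaf_out,
                                        flipped=True, **common)
    raise HarmonizationError(
        f"{exposure.rsid}: alleles irreconcilable: exposure {ea_x}/{oa_x}, outcome {ea_y}/{oa_y}")


def select_proxy(
    index_rsid: str,
    outcome: SummaryDataset,
    ld: LDTable,
    min_r2: float = DEFAULT_PROXY_MIN_R2,
    window_bp: int = DEFAULT_PROXY_WINDOW_BP,
) -> tuple[str, float] | None:
    """Best available LD proxy for an instrument missing from the outcome set.

    Candidates are LD partners within ``window_bp`` of the index at
    r2 >= ``min_r2`` that are present in the outcome dataset; the one with
    maximal r2 wins, ties broken by smaller distance then rsid.
    """
    partners = ld.partners_of(index_rsid)
    if partners.empty:
        logger.info("no LD entries for %s; no proxy available", index_rsid)
        return None
    ok = partners[(partners["r2"] >= min_r2)
                  & (partners["distance_bp"] <= window_bp)
                  & partners["rsid_b"].isin(outcome.records)]
    if ok.empty:
        return None
    ok = ok.sort_values(["r2", "distance_bp", "rsid_b"],
                        ascending=[False, True, True], kind="mergesort")
    best = ok.iloc[0]
    return str(best["rsid_b"]), float(best["r2"])


@dataclass
class HarmonizationConfig:
    ambiguity_maf_threshold: float = DEFAULT_AMBIGUITY_MAF
    proxy_min_r2: float = DEFAULT_PROXY_MIN_R2
    proxy_window_bp: int = DEFAULT_PROXY_WINDOW_BP
    user_exclusions: tuple[str, ...] = ()


def build_instrument_set(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDTable | None = None,
    config: HarmonizationConfig | None = None,
    locus_classes: dict[str, str] | None = None,
) -> list[HarmonizedInstrument]:
    """Harmonize every exposure variant against an outcome dataset.

    Returns one :class:`HarmonizedInstrument` per exposure variant in input
    order: kept instruments with aligned (beta_exp, beta_out) pairs, or
    excluded records with a single reason (missing_no_proxy,
    palindromic_ambiguous, user_excluded).  Proxies are substituted via
    ``ld`` when the index variant is absent from the outcome set.
    """
    if len(exposure) == 0:
        raise EmptyInstrumentSetError("exposure dataset is empty")
    cfg = config or HarmonizationConfig()
    locus_classes = locus_classes or {}
    out: list[HarmonizedInstrument] = []
    for rsid, exp in exposure.records.items():
        lc = locus_classes.get(rsid)
        base = dict(rsid=rsid, beta_exp=exp.beta, se_exp=exp.se, eaf=exp.eaf,
                    locus_class=lc)
        if rsid in cfg.user_exclusions:
            out.append(HarmonizedInstrument(status="excluded",
                                            exclusion_reason="user_excluded", **base))
            continue
        proxy: tuple[str, float] | None = None
        if rsid in outcome:
            target = outcome[rsid]
        else:
            if ld is not None:
                proxy = select_proxy(rsid, outcome, ld,
                                     min_r2=cfg.proxy_min_r2, window_bp=cfg.proxy_window_bp)
            if proxy is None:
                out.append(HarmonizedInstrument(status="excluded",
                                                exclusion_reason="missing_no_proxy", **base))
                continue
            target = outcome[proxy[0]]
        try:
            out.append(harmonize_variant(
                exp, target, ambiguity_maf_threshold=cfg.ambiguity_maf_threshold,
                locus_class=lc,
                proxy_rsid=proxy[0] if proxy else None,
                proxy_r2=proxy[1] if proxy else None))
        except HarmonizationError as exc:
            logger.warning("dropping %s: %s", rsid, exc)
            out.append(HarmonizedInstrument(status="excluded",
                                            exclusion_reason="missing_no_proxy", **base))
    kept = [h for h in out if h.status == "kept"]
    counts: dict[str, int] = {}
    for h in out:
        key = h.exclusion_reason or "kept"
        counts[key] = counts.get(key, 0) + 1
    logger.info("harmonization %s vs %s: %s", exposure.label, outcome.label, counts)
    if not kept:
        raise EmptyInstrumentSetError(
            f"no instrument could be harmonized against {outcome.label!r}")
    return out


def kept(instruments: list[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Only the instruments that survived harmonization."""
    return [h for h in instruments if h.status == "kept"]


def instruments_to_frame(instruments: list[HarmonizedInstrument]) -> pd.DataFrame:
    """Harmonized set as a DataFrame (one row per exposure variant)."""
    import dataclasses
    df = pd.DataFrame([dataclasses.asdict(h) for h in instruments])
    floats = ["beta_exp", "se_exp", "eaf", "beta_out", "se_out", "eaf_out", "proxy_r2"]
    strings = ["rsid", "status", "proxy_rsid", "locus_class", "exclusion_reason"]
    return df.astype({**{c: "float64" for c in floats},
                      **{c: "string" for c in strings}})
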