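"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a pQTL-based MR study: a handful of
independent instruments for a continuous exposure (optionally including one
large-effect, low-frequency cis variant), outcome effects generated as
Gamma_j = theta * beta_j + alpha_j with configurable balanced or directional
pleiotropy alpha_j (and optional correlation between alpha_j and instrument
strength, violating InSIDE), and sampling noise at the level implied by the
GWAS sample sizes.  Standard asymptotic approximations give the standard
errors: se = 1/sqrt(2 n eaf (1-eaf)) for a standardized continuous trait and
the same with the effective case-control sample size n_eff = 4 /
(1/n_cases + 1/n_controls) / 2 for a binary trait.

Optional wrinkles exercise every harmonization path: a palindromic A/T
variant at intermediate MAF, a variant missing from the outcome dataset but
recoverable through an LD proxy, and an AR(1)-correlated cis block with
correspondingly correlated effect-estimate noise.

All randomness flows from the single scenario seed through
``numpy.random.SeedSequence`` spawning, so each sub-stream (effects,
exposure noise, outcome noise, ...) is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import SummaryDataset, VariantAssociation, load_resistin_instruments
from .harmonize import LDTable

logger = logging.getLogger(__name__)

_ALLELES = ("A", "G")  # non-palindromic default pair


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one synthetic two-sample dataset."""

    seed: int
    n_snps: int = 13
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation_corr: float = 0.0
    n_exposure: int = 20_000
    n_cases: int = 58_131
    n_controls: int = 67_347
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_size_mean: float = 0.08
    effect_size_sd: float = 0.03
    signed_effects: bool = True  # False keeps every true exposure effect positive
    big_cis_effect: tuple[float, float] | None = (1.10, 0.017)
    include_palindromic: bool = False
    include_missing_with_proxy: bool = False
    ld_block: tuple[int, float] | None = None  # (size, ar1_rho)
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("scenario field 'seed' is mandatory")
        if self.pleiotropy_sd < 0:
            raise ValueError("scenario field 'pleiotropy_sd' must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("scenario field 'maf_range' must lie within (0, 0.5]")
        if abs(self.inside_violation_corr) > 1:
            raise ValueError("scenario field 'inside_violation_corr' must lie in [-1,1]")
        if self.n_snps < 1:
            raise ValueError("scenario field 'n_snps' must be >= 1")
        if self.ld_block is not None:
            size, rho = self.ld_block
            if size > self.n_snps or not (0 <= rho < 1):
                raise ValueError("scenario field 'ld_block' invalid: size <= n_snps, 0 <= rho < 1")


def _binary_se(eaf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n_eff = n_cases * n_controls / (n_cases + n_controls)
    return 1.0 / np.sqrt(2.0 * n_eff * eaf * (1.0 - eaf))


def _continuous_se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _ar1_chol(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return np.linalg.cholesky(rho ** np.abs(idx[:, None] - idx[None, :]))


def generate_two_sample(scenario: SyntheticScenario):
    """Generate (exposure dataset, outcome dataset, LD table, truth record).

    The truth record carries every latent quantity: true per-variant exposure
    and outcome effects, the pleiotropy draws, and the scenario itself.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_fx, rng_eaf, rng_alpha, rng_noise_x, rng_noise_y, rng_misc = \
        [np.random.default_rng(s) for s in ss.spawn(6)]

    j = scenario.n_snps
    beta_true = rng_fx.normal(scenario.effect_size_mean, scenario.effect_size_sd, size=j)
    if scenario.signed_effects:
        beta_true *= rng_fx.choice([-1.0, 1.0], size=j)
    else:
        beta_true = np.abs(beta_true)
    maf = rng_eaf.uniform(*scenario.maf_range, size=j)
    # assign the minor allele to the effect allele at random so EAF spans (0,1)
    eaf = np.where(rng_eaf.random(j) < 0.5, maf, 1.0 - maf)
    if scenario.big_cis_effect is not None:
        beta_true[0], eaf[0] = scenario.big_cis_effect

    # pleiotropy, optionally correlated with instrument strength (InSIDE violation)
    z = rng_alpha.standard_normal(j)
    if scenario.inside_violation_corr != 0.0 and j > 1 and np.std(beta_true) > 0:
        zb = (beta_true - beta_true.mean()) / np.std(beta_true)
        rho = scenario.inside_violation_corr
        z = rho * zb + np.sqrt(1.0 - rho ** 2) * z
    alpha = scenario.pleiotropy_mean + scenario.pleiotropy_sd * z
    gamma_true = scenario.theta * beta_true + alpha

    se_x = _continuous_se(eaf, scenario.n_exposure)
    se_y = _binary_se(eaf, scenario.n_cases, scenario.n_controls)

    noise_x = rng_noise_x.standard_normal(j)
    noise_y = rng_noise_y.standard_normal(j)
    ld_rows: list[dict] = []
    if scenario.ld_block is not None:
        size, rho = scenario.ld_block
        chol = _ar1_chol(size, rho)
        noise_x[:size] = chol @ noise_x[:size]
        noise_y[:size] = chol @ noise_y[:size]
        for a in range(size):
            for b in range(a + 1, size):
                r = rho ** (b - a)
                ld_rows.append({"rsid_a": f"rs{a + 1:06d}", "rsid_b": f"rs{b + 1:06d}",
                                "r": r, "r2": r * r, "distance_bp": 1000 * (b - a),
                                "allele_a": _ALLELES[0], "allele_b": _ALLELES[0]})
    beta_obs = beta_true + se_x * noise_x
    gamma_obs = gamma_true + se_y * noise_y

    exposure = SummaryDataset(label=f"{scenario.label}_exposure", trait_type="continuous")
    outcome = SummaryDataset(label=f"{scenario.label}_outcome", trait_type="binary",
                             n_cases=scenario.n_cases, n_controls=scenario.n_controls)
    positions = 1_000_000 + 1000 * np.arange(j)
    missing_rsid = None
    for i in range(j):
        rsid = f"rs{i + 1:06d}"
        pz = abs(beta_obs[i]) / se_x[i]
        exposure.add(VariantAssociation(
            rsid=rsid, chromosome="19", position=int(positions[i]),
            effect_allele=_ALLELES[0], other_allele=_ALLELES[1],
            eaf=float(eaf[i]), beta=float(beta_obs[i]), se=float(se_x[i]),
            pvalue=float(max(2.0 * _norm_sf(pz), 1e-300)),
            sample_size=scenario.n_exposure))
        if scenario.include_missing_with_proxy and i == j - 1:
            missing_rsid = rsid
            continue
        outcome.add(_outcome_record(rsid, int(positions[i]), eaf[i],
                                    gamma_obs[i], se_y[i], scenario))

    if scenario.include_missing_with_proxy:
        # proxy carries the same underlying signal plus its own noise
        proxy_rsid = f"rs{j + 900_000}"
        r = 0.95
        g_proxy = r * gamma_true[j - 1] + se_y[j - 1] * rng_misc.standard_normal()
        outcome.add(_outcome_record(proxy_rsid, int(positions[-1]) + 5000,
                                    eaf[j - 1], g_proxy, se_y[j - 1], scenario))
        ld_rows.append({"rsid_a": missing_rsid, "rsid_b": proxy_rsid,
                        "r": r, "r2": r * r, "distance_bp": 5000,
                        "allele_a": _ALLELES[0], "allele_b": _ALLELES[0]})

    if scenario.include_palindromic:
        rsid = f"rs{j + 800_000}"
        pal_eaf = float(rng_misc.uniform(0.44, 0.5))
        pal_beta = float(rng_misc.normal(scenario.effect_size_mean, scenario.effect_size_sd))
        pal_se = float(_continuous_se(np.array([pal_eaf]), scenario.n_exposure)[0])
        exposure.add(VariantAssociation(
            rsid=rsid, chromosome="19", position=int(positions[-1]) + 10_000,
            effect_allele="A", other_allele="T", eaf=pal_eaf,
            beta=pal_beta, se=pal_se, pvalue=1e-9, sample_size=scenario.n_exposure))
        outcome.add(VariantAssociation(
            rsid=rsid, chromosome="19", position=int(positions[-1]) + 10_000,
            effect_allele="A", other_allele="T", eaf=pal_eaf,
            beta=float(scenario.theta * pal_beta), se=float(_binary_se(
                np.array([pal_eaf]), scenario.n_cases, scenario.n_controls)[0]),
            pvalue=0.5, sample_size=scenario.n_cases + scenario.n_controls))

    ld = LDTable(pd.DataFrame(ld_rows, columns=["rsid_a", "rsid_b", "r", "r2",
                                                "distance_bp", "allele_a", "allele_b"]))
    truth = {
        "scenario": scenario,
        "beta_true": beta_true, "gamma_true": gamma_true, "alpha": alpha,
        "eaf": eaf, "se_exposure": se_x, "se_outcome": se_y,
        "missing_rsid": missing_rsid,
    }
    return exposure, outcome, ld, truth


def _norm_sf(z: float) -> float:
    from scipy.stats import norm
    return float(norm.sf(z))


def _outcome_record(rsid: str, position: int, eaf: float, gamma: float,
                    se: float, scenario: SyntheticScenario) -> VariantAssociation:
    pz = abs(gamma) / se
    return VariantAssociation(
        rsid=rsid, chromosome="19", position=position,
        effect_allele=_ALLELES[0], other_allele=_ALLELES[1],
        eaf=float(eaf), beta=float(gamma), se=float(se),
        pvalue=float(max(2.0 * _norm_sf(pz), 1e-300)),
        sample_size=scenario.n_cases + scenario.n_controls)


# ---------------------------------------------------------------------------
# Study-shaped bundle

#: Case/control shapes of the two outcome GWAS used for power computations:
#: a balanced consortium meta-analysis (ratio 0.86) and a biobank cohort
#: (ratio 0.0198).
GECCO_SHAPE = {"label": "GECCO_like", "n_cases": 58_131, "n_controls": 67_347}
FINNGEN_SHAPE = {"label": "FinnGen_like", "n_cases": 4_861, "n_controls": 245_538}

#: Subgroups available per dataset shape (the biobank release lacks
#: subsite-beyond-colon/rectal and sex-stratified tables).
SUBGROUPS = {
    "GECCO_like": ("colon", "rectal", "proximal_colon", "distal_colon", "female", "male"),
    "FinnGen_like": ("colon", "rectal"),
}


@dataclass
class StudyBundle:
    exposure: SummaryDataset
    outcomes: dict[str, SummaryDataset]
    subgroup_outcomes: dict[str, dict[str, SummaryDataset]]
    ld: LDTable
    truth: dict


def _outcome_for_fixture(exposure: SummaryDataset, theta: float, shape: dict,
                         rng: np.random.Generator, label: str,
                         scale: float = 1.0) -> SummaryDataset:
    out = SummaryDataset(label=label, trait_type="binary",
                         n_cases=int(shape["n_cases"] * scale),
                         n_controls=int(shape["n_controls"] * scale))
    for rec in exposure.records.values():
        se = float(_binary_se(np.array([rec.eaf]), out.n_cases, out.n_controls)[0])
        gamma = theta * rec.beta + se * rng.standard_normal()
        out.add(_noisy_outcome_record(rec, gamma, se, out))
    return out


def _noisy_outcome_record(rec: VariantAssociation, gamma: float, se: float,
                   ds: SummaryDataset) -> VariantAssociation:
    pz = abs(gamma) / se
    return VariantAssociation(
        rsid=rec.rsid, chromosome=rec.chromosome, position=rec.position,
        effect_allele=rec.effect_allele, other_allele=rec.other_allele,
        eaf=rec.eaf, beta=gamma, se=se,
        pvalue=float(max(2.0 * _norm_sf(pz), 1e-300)),
        sample_size=ds.n_cases + ds.n_controls)


def replicate_study_shape(theta: float = 0.0, seed: int = 0) -> StudyBundle:
    """A full study-shaped synthetic bundle around the packaged pQTL fixture.

    Uses the real 15-variant exposure fixture and synthesizes outcome
    datasets under a known causal effect ``theta``: one consortium-shaped
    and one biobank-shaped overall dataset plus subgroup datasets with the
    real availability pattern.  The 15 -> 13 instrument accounting is
    reproduced structurally: one rare variant is absent from both outcome
    sets (no proxy), the palindromic variant is present but strand-ambiguous,
    and one variant is absent from the biobank-shaped set with an LD proxy
    at r^2 = 0.82 (+30,330 bp) standing in.
    """
    exposure = load_resistin_instruments()
    ss = np.random.SeedSequence([seed, 2_000_001])
    rngs = [np.random.default_rng(s) for s in ss.spawn(2 + sum(len(v) for v in SUBGROUPS.values()))]
    rit = iter(rngs)

    analysis = SummaryDataset(label=exposure.label, trait_type="continuous")
    for rsid, rec in exposure.records.items():
        if rsid != "rs199752470":  # absent from every outcome dataset
            analysis.add(rec)

    outcomes: dict[str, SummaryDataset] = {}
    for shape in (GECCO_SHAPE, FINNGEN_SHAPE):
        ds = _outcome_for_fixture(analysis, theta, shape, next(rit), shape["label"])
        outcomes[shape["label"]] = ds

    # biobank-shaped set: index variant rs73008259 replaced by its LD proxy
    fg = outcomes[FINNGEN_SHAPE["label"]]
    idx = fg.records.pop("rs73008259")
    proxy = VariantAssociation(
        rsid="rs72992130", chromosome=idx.chromosome,
        position=idx.position + 30_330, effect_allele=idx.effect_allele,
        other_allele=idx.other_allele, eaf=idx.eaf, beta=idx.beta, se=idx.se,
        pvalue=idx.pvalue, sample_size=idx.sample_size)
    fg.add(proxy)
    ld = LDTable(pd.DataFrame([{
        "rsid_a": "rs73008259", "rsid_b": "rs72992130",
        "r": np.sqrt(0.82), "r2": 0.82, "distance_bp": 30_330,
        "allele_a": idx.effect_allele, "allele_b": idx.effect_allele}]))

    subgroup_outcomes: dict[str, dict[str, SummaryDataset]] = {}
    for shape in (GECCO_SHAPE, FINNGEN_SHAPE):
        label = shape["label"]
        subgroup_outcomes[label] = {}
        for sg in SUBGROUPS[label]:
            scale = 0.5 if sg in ("female", "male") else 0.4
            ds = _outcome_for_fixture(analysis, theta, shape, next(rit),
                                      f"{label}_{sg}", scale=scale)
            if label == FINNGEN_SHAPE["label"]:
                rec = ds.records.pop("rs73008259")
                ds.add(VariantAssociation(
                    rsid="rs72992130", chromosome=rec.chromosome,
                    position=rec.position + 30_330, effect_allele=rec.effect_allele,
                    other_allele=rec.other_allele, eaf=rec.eaf, beta=rec.beta,
                    se=rec.se, pvalue=rec.pvalue, sample_size=rec.sample_size))
            subgroup_outcomes[label][sg] = ds

    return StudyBundle(exposure=exposure, outcomes=outcomes,
                       subgroup_outcomes=subgroup_outcomes, ld=ld,
                       truth={"theta": theta, "seed": seed})
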