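"""Random-effects meta-analytic pooling of per-dataset MR estimates.

Estimates obtained from independent outcome datasets (here, two colorectal
cancer GWAS consortia) are combined by inverse-variance random-effects
meta-analysis.  The between-dataset variance tau^2 uses the Sidik-Jonkman
estimator by default (DerSimonian-Laird available for cross-checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, HeterogeneityStats, Z975, _normal_p

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaEstimate:
    """A pooled causal estimate across outcome datasets."""

    inputs: tuple[tuple[str, float, float], ...]  # (label, beta, se)
    tau2: float
    pooled_beta: float
    pooled_se: float
    pvalue: float
    heterogeneity: HeterogeneityStats

    @property
    def or_value(self) -> float:
        return float(np.exp(self.pooled_beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.pooled_beta - Z975 * self.pooled_se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.pooled_beta + Z975 * self.pooled_se))


def sj_tau2(estimates: list[tuple[float, float]]) -> float:
    """Sidik-Jonkman between-study variance.

    Initialized at the unweighted variance tau0^2 = mean((beta_s - mean)^2);
    one reweighting step with v_s = se_s^2/tau0^2 + 1 then gives
    tau^2 = sum(v_s^-1 (beta_s - mu)^2) / (S - 1).  All-equal inputs give 0.
    """
    if len(estimates) < 2:
        raise ValueError("Sidik-Jonkman needs >=2 estimates")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    tau0 = float(np.mean((beta - beta.mean()) ** 2))
    if tau0 == 0.0:
        return 0.0
    v = se ** 2 / tau0 + 1.0
    mu = float(np.sum(beta / v) / np.sum(1.0 / v))
    return float(np.sum((beta - mu) ** 2 / v) / (len(beta) - 1))


def dl_tau2(estimates: list[tuple[float, float]]) -> float:
    """DerSimonian-Laird between-study variance (cross-check alternative)."""
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    w = 1.0 / se ** 2
    mu = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - mu) ** 2))
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    return max(0.0, (q - (len(beta) - 1)) / c)


_TAU2 = {"sidik_jonkman": sj_tau2, "dersimonian_laird": dl_tau2}


def meta_random_effects(estimates: list[tuple[str, float, float]],
                        tau2_method: str = "sidik_jonkman") -> MetaEstimate:
    """Inverse-variance random-effects pooling of labelled (beta, se) inputs.

    Weights are 1/(se_s^2 + tau^2).  A single input passes through unchanged
    with tau^2 = 0.  Fixed-effect Cochran's Q over the inputs summarizes
    between-dataset heterogeneity.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    labels = [e[0] for e in estimates]
    beta = np.array([e[1] for e in estimates], dtype=float)
    se = np.array([e[2] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if len(estimates) == 1:
        return MetaEstimate(
            inputs=((labels[0], float(beta[0]), float(se[0])),),
            tau2=0.0, pooled_beta=float(beta[0]), pooled_se=float(se[0]),
            pvalue=_normal_p(float(beta[0]), float(se[0])),
            heterogeneity=HeterogeneityStats.from_q(0.0, 0))
    tau2 = _TAU2[tau2_method]([(b, s) for b, s in zip(beta, se)])
    w = 1.0 / (se ** 2 + tau2)
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    wf = 1.0 / se ** 2
    mu_f = float(np.sum(wf * beta) / np.sum(wf))
    q = float(np.sum(wf * (beta - mu_f) ** 2))
    het = HeterogeneityStats.from_q(q, len(beta) - 1)
    return MetaEstimate(inputs=tuple(zip(labels, beta.tolist(), se.tolist())),
                        tau2=float(tau2), pooled_beta=pooled, pooled_se=pooled_se,
                        pvalue=_normal_p(pooled, pooled_se), heterogeneity=het)


def pool_mr_estimates(per_dataset: dict[str, MREstimate],
                      tau2_method: str = "sidik_jonkman") -> MetaEstimate:
    """Pool MREstimate objects keyed by dataset label."""
    return meta_random_effects(
        [(label, est.beta, est.se) for label, est in per_dataset.items()],
        tau2_method=tau2_method)


def run_subgroups(exposure, outcome_sets: dict[str, dict[str, "object"]],
                  config=None, instrument_sets: tuple[str, ...] = ("all", "cis"),
                  locus_classes: dict[str, str] | None = None,
                  tau2_method: str = "sidik_jonkman"):
    """Stratified MR: harmonize, estimate and pool each subgroup.

    ``outcome_sets`` maps dataset label -> {subgroup label -> SummaryDataset};
    a subgroup simply absent from a dataset is analyzed with the datasets
    that do carry it.  Subgroups present in >=2 datasets are meta-pooled;
    single-dataset subgroups are reported with a provenance flag.  Subgroups
    where harmonization fails are recorded as failed and the run continues.

    Returns a DataFrame with one row per (subgroup, instrument_set).
    """
    import pandas as pd

    from . import estimators as _est
    from .harmonize import EmptyInstrumentSetError, build_instrument_set, kept as _kept

    rows = []
    subgroups = sorted({sg for per_ds in outcome_sets.values() for sg in per_ds})
    for sg in subgroups:
        available = {ds: per_ds[sg] for ds, per_ds in outcome_sets.items() if sg in per_ds}
        for iv_set in instrument_sets:
            per_dataset: dict[str, MREstimate] = {}
            for ds_label, outcome in available.items():
                try:
                    harmonized = build_instrument_set(
                        exposure, outcome, config=config, locus_classes=locus_classes)
                except EmptyInstrumentSetError as exc:
                    logger.warning("subgroup %s/%s failed: %s", sg, ds_label, exc)
                    continue
                ins = _kept(harmonized)
                if iv_set != "all":
                    ins = [h for h in ins if h.locus_class == iv_set]
                if len(ins) < 2:
                    logger.warning("subgroup %s/%s/%s: <2 instruments", sg, ds_label, iv_set)
                    continue
                per_dataset[ds_label] = _est.ivw(ins)
            if not per_dataset:
                rows.append({"subgroup": sg, "instrument_set": iv_set, "status": "failed"})
                continue
            pooled = pool_mr_estimates(per_dataset, tau2_method=tau2_method)
            rows.append({
                "subgroup": sg, "instrument_set": iv_set,
                "status": "pooled" if len(per_dataset) > 1 else "single_dataset",
                "datasets": ",".join(per_dataset),
                "n_datasets": len(per_dataset),
                "or": pooled.or_value, "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                "pvalue": pooled.pvalue, "tau2": pooled.tau2,
                "q_meta": pooled.heterogeneity.q, "i2_meta": pooled.heterogeneity.i2,
            })
    return pd.DataFrame(rows)
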