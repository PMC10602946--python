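"""End-to-end study orchestration: load, harmonize, diagnose, estimate, pool.

`run_study` executes the full workflow for one exposure instrument set
against any number of outcome datasets — harmonization (with proxy rescue
and palindromic exclusion), instrument diagnostics and power, the estimator
battery on all/cis/trans instrument subsets, leave-one-out and
single-variant scans, funnel tables, and cross-dataset meta-analytic
pooling — and writes a versioned TSV/JSON report directory with a run log
recording configuration, seeds and the exclusion accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import instruments as instr
from . import pooling
from .gwas_io import (SummaryDataset, load_resistin_instruments,
                      read_association_table, write_table, instrument_metadata)
from .harmonize import (HarmonizationConfig, LDTable, build_instrument_set,
                        instruments_to_frame, kept)

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw", "egger", "simple_median", "weighted_median", "weighted_mode")


@dataclass
class StudyConfig:
    """Resolved configuration of one study run."""

    exposure_path: str | None = None          # None -> packaged instrument fixture
    outcome_paths: dict[str, str] = field(default_factory=dict)
    ld_path: str | None = None
    outcome_schema: dict[str, str] = field(default_factory=dict)
    gene_window: instr.GeneWindow = instr.RETN_WINDOW
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    weak_f: float = instr.WEAK_F_THRESHOLD
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_boot: int = 10_000
    seed: int = 0
    exclusions: tuple[str, ...] = ()
    subgroup_paths: dict[str, dict[str, str]] = field(default_factory=dict)
    output_dir: str = "mr2s_report"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "gene_window" in raw:
            raw["gene_window"] = instr.GeneWindow(**raw["gene_window"])
        if "harmonization" in raw:
            raw["harmonization"] = HarmonizationConfig(**raw["harmonization"])
        for key in ("methods", "exclusions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _estimate_battery(instruments, methods, n_boot, seed,
                      ld: LDTable | None = None) -> list[dict]:
    """Run every requested estimator on one harmonized subset."""
    rows = []
    for method in methods:
        try:
            if method == "ivw":
                res = est.ivw(instruments)
            elif method == "egger":
                res = est.egger(instruments)
            elif method == "simple_median":
                res = est.median_estimator(instruments, weighted=False,
                                           n_boot=n_boot, seed=seed)
            elif method == "weighted_median":
                res = est.median_estimator(instruments, weighted=True,
                                           n_boot=n_boot, seed=seed + 1)
            elif method == "weighted_mode":
                res = est.mode_estimator(instruments, n_boot=n_boot, seed=seed + 2)
            elif method == "ivw_correlated":
                rho = _correlation_matrix(instruments, ld)
                res = est.ivw_correlated(instruments, rho)
            else:
                raise ValueError(f"unknown method {method!r}")
        except (est.InsufficientInstrumentsError, np.linalg.LinAlgError) as exc:
            logger.warning("method %s skipped: %s", method, exc)
            continue
        rows.append(_estimate_row(res))
    return rows

def _estimate_row(res: est.MREstimate) -> dict:
    row = {"method": res.method, "n_snps": res.n_variants, "beta": res.beta,
           "se": res.se, "or": res.or_value, "ci_low": res.ci_low,
           "ci_high": res.ci_high, "pvalue": res.pvalue, "phi": res.scale_phi,
           "intercept": res.intercept, "intercept_p": res.intercept_p}
    if res.heterogeneity is not None:
        h = res.heterogeneity
        row.update({"Q": h.q, "df": h.df, "p_Q": h.p_q, "I2": h.i2})
    return row


def _correlation_matrix(instruments, ld: LDTable | None) -> np.ndarray:
    if ld is None:
        raise ValueError("correlated IVW requested without an LD table")
    ins = kept(instruments)
    j = len(ins)
    rho = np.eye(j)
    for a in range(j):
        for b in range(a + 1, j):
            rho[a, b] = rho[b, a] = ld.r_between(ins[a].rsid, ins[b].rsid, default=0.0)
    return rho


def run_study(config: StudyConfig,
              exposure: SummaryDataset | None = None,
              outcomes: dict[str, SummaryDataset] | None = None,
              ld: LDTable | None = None,
              subgroup_outcomes: dict[str, dict[str, SummaryDataset]] | None = None) -> dict:
    """Execute the full analysis; returns the report bundle as a dict of tables.

    Datasets may be passed in memory (tests, simulations) or loaded from the
    paths in ``config``.  The report directory receives one TSV per table
    plus ``run.json`` with the resolved configuration, seeds and exclusion
    accounting.
    """
    if exposure is None:
        exposure = (load_resistin_instruments() if config.exposure_path is None
                    else read_association_table(config.exposure_path, trait_type="continuous"))
    if outcomes is None:
        outcomes = {label: read_association_table(path, schema=config.outcome_schema,
                                                  trait_type="binary", label=label)
                    for label, path in config.outcome_paths.items()}
    if not outcomes:
        raise ValueError("no outcome datasets configured")
    if ld is None and config.ld_path:
        ld = LDTable.read(config.ld_path)

    locus_classes = {rsid: instr.classify_cis_trans(rec, config.gene_window)
                     for rsid, rec in exposure.records.items()}
    hcfg = dataclasses.replace(config.harmonization,
                               user_exclusions=tuple(config.exclusions))

    # instrument diagnostics on the exposure side (analysis variants only)
    try:
        meta = instrument_metadata(exposure)
        analysis_rsids = set(meta.index[meta["status"] == "analysis"])
    except AttributeError:
        analysis_rsids = set(exposure.records)
    diag_ds = SummaryDataset(label=exposure.label, trait_type="continuous")
    for rsid in exposure.records:
        if rsid in analysis_rsids:
            diag_ds.add(exposure.records[rsid])
    diagnostics = instr.diagnose(diag_ds, weak_threshold=config.weak_f)
    diag_table = pd.DataFrame([dataclasses.asdict(v) for v in diagnostics.per_variant])

    report: dict[str, object] = {
        "diagnostics": diag_table,
        "diagnostics_summary": {
            "total_r2": diagnostics.total_r2, "mean_f": diagnostics.mean_f,
            "k_instruments": diagnostics.k_instruments,
            "any_weak": diagnostics.any_weak,
        },
    }

    power_rows, estimate_rows, harmonized_frames = [], [], []
    scan_rows, loo_rows, funnel_frames = [], [], []
    per_dataset_ivw: dict[str, dict[str, est.MREstimate]] = {"all": {}, "cis": {}, "trans": {}}
    accounting: dict[str, dict[str, int]] = {}

    for label, outcome in outcomes.items():
        harmonized = build_instrument_set(exposure, outcome, ld=ld, config=hcfg,
                                          locus_classes=locus_classes)
        frame = instruments_to_frame(harmonized)
        frame.insert(0, "dataset", label)
        harmonized_frames.append(frame)
        counts: dict[str, int] = {}
        for h in harmonized:
            counts[h.exclusion_reason or "kept"] = counts.get(h.exclusion_reason or "kept", 0) + 1
        accounting[label] = counts

        if outcome.case_control_ratio is not None:
            n_total = outcome.n_cases + outcome.n_controls
            power_rows.append({
                "dataset": label, "n_total": n_total,
                "case_control_ratio": outcome.case_control_ratio,
                "r2": diagnostics.total_r2,
                "minimum_detectable_or": instr.minimum_detectable_or(
                    n_total, outcome.case_control_ratio, diagnostics.total_r2),
            })

        ins_all = kept(harmonized)
        subsets = {"all": ins_all,
                   "cis": [h for h in ins_all if h.locus_class == "cis"],
                   "trans": [h for h in ins_all if h.locus_class == "trans"]}
        for subset, ins in subsets.items():
            if len(ins) < 2:
                continue
            for row in _estimate_battery(ins, config.methods, config.n_boot,
                                         config.seed, ld=ld):
                row.update({"dataset": label, "instrument_set": subset})
                estimate_rows.append(row)
            per_dataset_ivw[subset][label] = est.ivw(ins)

        for rsid, res in est.single_variant_scan(ins_all):
            scan_rows.append({"dataset": label, "rsid": rsid, **_estimate_row(res)})
        if len(ins_all) >= 3:
            for dropped, res in est.leave_one_out(ins_all):
                loo_rows.append({"dataset": label, "dropped": dropped, **_estimate_row(res)})
        fd = est.funnel_data(ins_all)
        fd.insert(0, "dataset", label)
        funnel_frames.append(fd)

    pooled_rows = []
    for subset, per_ds in per_dataset_ivw.items():
        if not per_ds:
            continue
        pooled = pooling.pool_mr_estimates(per_ds)
        pooled_rows.append({
            "instrument_set": subset, "n_datasets": len(per_ds),
            "datasets": ",".join(per_ds), "tau2": pooled.tau2,
            "beta": pooled.pooled_beta, "se": pooled.pooled_se,
            "or": pooled.or_value, "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
            "pvalue": pooled.pvalue, "q_meta": pooled.heterogeneity.q,
            "i2_meta": pooled.heterogeneity.i2,
        })

    report.update({
        "harmonized": pd.concat(harmonized_frames, ignore_index=True),
        "power": pd.DataFrame(power_rows),
        "estimates": pd.DataFrame(estimate_rows),
        "single_variant": pd.DataFrame(scan_rows),
        "leave_one_out": pd.DataFrame(loo_rows),
        "funnel": pd.concat(funnel_frames, ignore_index=True),
        "pooled": pd.DataFrame(pooled_rows),
        "exclusion_accounting": accounting,
    })

    if subgroup_outcomes is None and config.subgroup_paths:
        subgroup_outcomes = {
            ds: {sg: read_association_table(path, schema=config.outcome_schema,
                                            trait_type="binary", label=f"{ds}_{sg}")
                 for sg, path in per_ds.items()}
            for ds, per_ds in config.subgroup_paths.items()}
    if subgroup_outcomes:
        report["subgroups"] = pooling.run_subgroups(
            exposure, subgroup_outcomes, config=hcfg, locus_classes=locus_classes)

    _write_report(report, config)
    return report


def _write_report(report: dict, config: StudyConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in report.items():
        if isinstance(table, pd.DataFrame) and not table.empty:
            write_table(table, outdir / f"{name}.tsv")
    meta = {
        "config": _jsonable(config.to_dict()),
        "exclusion_accounting": report.get("exclusion_accounting", {}),
        "diagnostics_summary": report.get("diagnostics_summary", {}),
    }
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, default=str))
    logger.info("report written to %s", outdir)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
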