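"""Reading and writing GWAS summary-statistic tables.

The in-memory containers are small frozen dataclasses rather than bare
DataFrames so that invariants (allele alphabet, frequency bounds, positive
standard errors) are enforced once, at the boundary.  Tabular I/O itself is
delegated to pandas; the on-disk dialect is header-bearing TSV with a
configurable column mapping so that differently named consortium exports can
be loaded without preprocessing.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

#: Canonical column names understood by :func:`read_association_table`.
CANONICAL_COLUMNS = (
    "rsid", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class DuplicateVariantError(ValueError):
    """The same rsid appears more than once within one dataset."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait in one GWAS.

    ``beta`` is in SD units of the exposure for continuous traits and in
    log-odds per effect allele for binary traits.  ``eaf`` may be None for
    outcome datasets that do not export allele frequencies; it is only needed
    to resolve palindromic variants during harmonization.
    """

    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    sample_size: int | None = None

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if not ea or not oa or not (set(ea) <= _VALID_BASES and set(oa) <= _VALID_BASES):
            raise ValueError(f"{self.rsid}: alleles must be nonempty strings over A/C/G/T, got {ea!r}/{oa!r}")
        if ea == oa:
            raise ValueError(f"{self.rsid}: effect and other allele are identical ({ea})")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie strictly in (0,1), got {self.eaf}")
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue must lie in (0,1], got {self.pvalue}")
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValueError(f"{self.rsid}: sample size must be positive, got {self.sample_size}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, min(EAF, 1-EAF)."""
        return None if self.eaf is None else min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryDataset:
    """A labelled collection of variant associations for one trait.

    ``records`` is keyed by rsid (unique within a dataset).  Binary traits may
    carry case/control counts; both must be given or neither.
    """

    label: str
    trait_type: str  # "continuous" | "binary"
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}")
        if (self.n_cases is None) != (self.n_controls is None):
            raise ValueError("n_cases and n_controls must be given together")
        if self.n_cases is not None and (self.n_cases <= 0 or self.n_controls <= 0):
            raise ValueError("case/control counts must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> VariantAssociation:
        return self.records[rsid]

    def add(self, rec: VariantAssociation) -> None:
        if rec.rsid in self.records:
            raise DuplicateVariantError(f"duplicate rsid {rec.rsid} in dataset {self.label!r}")
        self.records[rec.rsid] = rec

    @property
    def case_control_ratio(self) -> float | None:
        if self.n_cases is None:
            return None
        return self.n_cases / self.n_controls

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame in insertion order."""
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records.values()])


def read_association_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    label: str | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryDataset:
    """Load a TSV of summary statistics into a :class:`SummaryDataset`.

    Parameters
    ----------
    schema
        Mapping from canonical field names (see :data:`CANONICAL_COLUMNS`) to
        the column names actually present in the file.  Unmapped canonical
        names default to themselves.  ``eaf`` and ``n`` columns are optional.

    Rows violating the type invariants are rejected individually; the rejects
    are logged with their row index and the load continues.  A missing mapped
    column raises :class:`SchemaError`; a repeated rsid raises
    :class:`DuplicateVariantError`.
    """
    path = Path(path)
    colmap = {k: k for k in CANONICAL_COLUMNS}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [colmap[k] for k in ("rsid", "chromosome", "position",
                                    "effect_allele", "other_allele",
                                    "beta", "se", "pvalue")]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} not found (have {list(df.columns)})")

    ds = SummaryDataset(label=label or path.stem, trait_type=trait_type,
                        n_cases=n_cases, n_controls=n_controls)
    if df.empty:
        logger.warning("%s: no data rows (header only)", path)
        return ds

    dupes = df[colmap["rsid"]][df[colmap["rsid"]].duplicated()].tolist()
    if dupes:
        raise DuplicateVariantError(f"{path}: duplicate rsids {sorted(set(dupes))}")

    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            eaf_col = colmap["eaf"]
            n_col = colmap["n"]
            eaf = float(row[eaf_col]) if eaf_col in df.columns and pd.notna(row[eaf_col]) else None
            n = int(float(row[n_col])) if n_col in df.columns and pd.notna(row[n_col]) else None
            ds.add(VariantAssociation(
                rsid=str(row[colmap["rsid"]]),
                chromosome=str(row[colmap["chromosome"]]),
                position=int(float(row[colmap["position"]])),
                effect_allele=str(row[colmap["effect_allele"]]),
                other_allele=str(row[colmap["other_allele"]]),
                eaf=eaf,
                beta=float(row[colmap["beta"]]),
                se=float(row[colmap["se"]]),
                pvalue=float(row[colmap["pvalue"]]),
                sample_size=n,
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        logger.warning("%s: rejected %d row(s): %s", path, len(errors), "; ".join(errors))
    ds.rejected_rows = errors  # type: ignore[attr-defined]
    return ds


def write_table(records: pd.DataFrame | Iterable, path: str | Path,
                float_precision: int = 6) -> None:
    """Write any tabular result as TSV with deterministic column and row order.

    Floats are serialized with ``float_precision`` significant digits; rows
    keep their input order.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r
                                for r in records])
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}g")


# ---------------------------------------------------------------------------
# Packaged instrument fixture

_FIXTURE = "resistin_pqtls_scallop.tsv"


def load_resistin_instruments(analysis_only: bool = False) -> SummaryDataset:
    """The published SCALLOP resistin pQTL instrument list as a packaged fixture.

    Returns all 15 pQTLs identified by the SCALLOP consortium GWAS of
    circulating resistin (N up to 21,749 Europeans), 13 of which carry status
    ``analysis``.  The other two are recorded with their exclusion status:
    rs199752470 (absent from both outcome datasets, no proxy) and rs7746716
    (palindromic A/T with MAF 0.48, strand-ambiguous).  For those two rows the
    numeric summary fields beyond what was published (rs7746716's MAF) are
    synthetic placeholders, flagged in the ``note`` column; they never enter
    an analysis.

    Each record also carries ``gene``, ``locus_class`` (cis/trans relative to
    RETN) and ``status`` in the ``extras`` frame returned alongside.
    """
    with importlib.resources.files("mr2s.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if analysis_only:
        df = df[df["status"] == "analysis"].reset_index(drop=True)
    ds = SummaryDataset(label="SCALLOP_resistin", trait_type="continuous")
    for _, row in df.iterrows():
        ds.add(VariantAssociation(
            rsid=row["rsid"], chromosome=row["chromosome"],
            position=int(row["position"]),
            effect_allele=row["effect_allele"], other_allele=row["other_allele"],
            eaf=float(row["eaf"]), beta=float(row["beta"]), se=float(row["se"]),
            pvalue=float(row["pvalue"]), sample_size=int(row["n"]),
        ))
    ds.metadata = df.set_index("rsid")[["gene", "locus_class", "status", "note"]]  # type: ignore[attr-defined]
    return ds


def instrument_metadata(ds: SummaryDataset) -> pd.DataFrame:
    """gene / locus_class / status annotations attached by the fixture loader."""
    meta = getattr(ds, "metadata", None)
    if meta is None:
        raise AttributeError("dataset carries no instrument metadata")
    return meta
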