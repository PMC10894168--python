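"""Reading, writing, and harmonizing GWAS summary statistics.

Summary statistics travel as tab-delimited text with a header row.  Column
names are configurable through a ``column_map``; the defaults match the
embedded instrument tables (SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N).

The module also ships the per-target instrument tables for the three
LDL-lowering drug-target genes (PCSK9, HMGCR, NPC1L1) as package data and
provides the two-sample allele harmonization step that aligns outcome
effects onto the exposure's effect allele.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, EmptyInputError, HarmonizationError

logger = logging.getLogger(__name__)

#: default field -> column-header mapping for summary-statistics files
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_MANDATORY_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval",
)

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))

#: names of the embedded drug-target instrument tables
TABLE1_TARGETS = ("PCSK9", "HMGCR", "NPC1L1")

#: harmonization outcomes
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary-statistic record for exposure or outcome.

    ``beta`` is the additive per-effect-allele association: log-odds for a
    case-control trait, phenotype units for a quantitative trait.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _VALID_ALLELES:
                raise ValueError(f"{self.snp_id}: invalid allele {allele!r}")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")
        if not self.se > 0.0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval {self.pval} outside (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be positive, got {self.n}")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_SETS


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one variant on a shared effect allele."""

    snp_id: str
    exposure_beta: float
    exposure_se: float
    exposure_eaf: float
    outcome_beta: float | None
    outcome_se: float | None
    outcome_eaf: float | None
    harmonization_action: str

    @property
    def retained(self) -> bool:
        return self.harmonization_action in (KEPT, FLIPPED)


class LDMatrix:
    """Pairwise r-squared between a fixed, ordered set of variants."""

    def __init__(self, variant_ids: Sequence[str], r2: np.ndarray) -> None:
        r2 = np.asarray(r2, dtype=float)
        ids = list(variant_ids)
        if r2.shape != (len(ids), len(ids)):
            raise ValueError("r2 shape does not match number of variant ids")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD matrix")
        if not np.allclose(r2, r2.T, atol=1e-10):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-10):
            raise ValueError("r2 matrix diagonal must be 1")
        if (r2 < -1e-12).any() or (r2 > 1 + 1e-12).any():
            raise ValueError("r2 entries must lie in [0, 1]")
        self.variant_ids = ids
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {snp: i for i, snp in enumerate(ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __len__(self) -> int:
        return len(self.variant_ids)

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        """LD matrix for mutually independent variants."""
        return cls(variant_ids, np.eye(len(variant_ids)))


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantAssociation]:
    """Read tab-delimited summary statistics into variant records.

    Rows whose numeric fields fail to parse, or that violate record
    invariants (e.g. ``se <= 0``), are skipped; the skip count is logged.

    Raises
    ------
    ConfigurationError
        if a mandatory mapped column is absent from the header.
    EmptyInputError
        if the file has no data rows.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)

    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for fld in _MANDATORY_FIELDS:
            if columns[fld] not in header:
                raise ConfigurationError(
                    f"{path}: mandatory column {columns[fld]!r} (field {fld!r}) "
                    f"not found in header {header}"
                )
        has_n = columns["n"] in header

        records: list[VariantAssociation] = []
        n_skipped = 0
        for row in reader:
            try:
                n_val = None
                if has_n and row[columns["n"]] not in ("", "NA", None):
                    n_val = int(float(row[columns["n"]]))
                records.append(
                    VariantAssociation(
                        snp_id=row[columns["snp_id"]].strip(),
                        chrom=str(row[columns["chrom"]]).strip(),
                        pos=int(float(row[columns["pos"]])),
                        effect_allele=row[columns["effect_allele"]].strip().upper(),
                        other_allele=row[columns["other_allele"]].strip().upper(),
                        eaf=float(row[columns["eaf"]]),
                        beta=float(row[columns["beta"]]),
                        se=float(row[columns["se"]]),
                        pval=float(row[columns["pval"]]),
                        n=n_val,
                    )
                )
            except (TypeError, ValueError):
                n_skipped += 1

    if not records and n_skipped == 0:
        raise EmptyInputError(f"{path}: no data rows")
    if n_skipped:
        logger.info("read_summary_stats: skipped %d unparseable row(s) in %s",
                    n_skipped, path)
    return records


def write_summary_stats(
    records: Iterable[VariantAssociation],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records as tab-delimited text; numeric fields round-trip exactly."""
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    fields = list(_MANDATORY_FIELDS) + ["n"]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([columns[f] for f in fields])
        for rec in records:
            row = []
            for f in fields:
                value = getattr(rec, f)
                # repr() is the shortest string that round-trips a float
                row.append(repr(value) if isinstance(value, float) else
                           ("" if value is None else value))
            writer.writerow(row)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square tab-delimited r2 matrix with rsID header row/column."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 2:
        raise EmptyInputError(f"{path}: no LD matrix data")
    ids = rows[0][1:]
    values = np.array([[float(x) for x in row[1:]] for row in rows[1:]])
    row_ids = [row[0] for row in rows[1:]]
    if row_ids != ids:
        raise ConfigurationError(f"{path}: LD matrix row ids differ from column ids")
    return LDMatrix(ids, values)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([""] + ld.variant_ids)
        for snp, row in zip(ld.variant_ids, ld.r2):
            writer.writerow([snp] + [repr(float(x)) for x in row])


def load_table1_fixture(target: str) -> list[VariantAssociation]:
    """Load the embedded instrument table for one drug-target gene.

    Exposure sample size (n = 440,546) is attached to every record.
    """
    if target not in TABLE1_TARGETS:
        raise ConfigurationError(
            f"unknown target {target!r}; valid targets: {', '.join(TABLE1_TARGETS)}"
        )
    ref = resources.files("cismr.data") / f"table1_{target.lower()}.tsv"
    with resources.as_file(ref) as path:
        records = read_summary_stats(path)
    return [replace(rec, n=440546) for rec in records]


def load_table1_f_column(target: str) -> dict[str, float]:
    """Per-variant published F statistics from the embedded table."""
    if target not in TABLE1_TARGETS:
        raise ConfigurationError(
            f"unknown target {target!r}; valid targets: {', '.join(TABLE1_TARGETS)}"
        )
    ref = resources.files("cismr.data") / f"table1_{target.lower()}.tsv"
    out: dict[str, float] = {}
    with resources.as_file(ref) as path, path.open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["SNP"]] = float(row["F"])
    return out


def _check_unique(records: Sequence[VariantAssociation], label: str) -> dict[str, VariantAssociation]:
    by_id: dict[str, VariantAssociation] = {}
    for rec in records:
        if rec.snp_id in by_id:
            raise HarmonizationError(
                f"duplicate snp_id {rec.snp_id!r} in {label} records (ambiguous join)"
            )
        by_id[rec.snp_id] = rec
    return by_id


def _same_side(a: float, b: float) -> bool:
    return (a - 0.5) * (b - 0.5) > 0


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Align outcome effects onto each exposure record's effect allele.

    The join key is rsID.  When outcome alleles are swapped relative to the
    exposure, the outcome beta is negated and its EAF replaced by 1 - EAF.
    Palindromic variants (A/T, C/G) are retained only when both EAFs lie
    outside ``0.5 +/- palindromic_eaf_window`` and agree in orientation;
    otherwise they are recorded as ``dropped_palindromic``.  Allele sets
    matching neither orientation become ``dropped_mismatch``.  Dropped
    records are returned with their action so attrition can be audited;
    use :attr:`HarmonizedPair.retained` to filter before estimation.
    """
    if not 0.0 <= palindromic_eaf_window < 0.5:
        raise ValueError("palindromic_eaf_window must lie in [0, 0.5)")
    _check_unique(exposure, "exposure")
    outcome_by_id = _check_unique(outcome, "outcome")

    lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window

    pairs: list[HarmonizedPair] = []
    for exp in exposure:
        out = outcome_by_id.get(exp.snp_id)
        if out is None:
            continue

        def pair(action: str, beta=None, se=None, eaf=None) -> HarmonizedPair:
            return HarmonizedPair(
                snp_id=exp.snp_id,
                exposure_beta=exp.beta,
                exposure_se=exp.se,
                exposure_eaf=exp.eaf,
                outcome_beta=beta,
                outcome_se=se,
                outcome_eaf=eaf,
                harmonization_action=action,
            )

        same = (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele)
        swapped = (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele)

        if not (same or swapped):
            pairs.append(pair(DROPPED_MISMATCH))
            continue

        if exp.is_palindromic:
            ambiguous = (lo <= exp.eaf <= hi) or (lo <= out.eaf <= hi)
            if ambiguous:
                pairs.append(pair(DROPPED_PALINDROMIC))
                continue
            if same:
                if _same_side(exp.eaf, out.eaf):
                    pairs.append(pair(KEPT, out.beta, out.se, out.eaf))
                else:
                    pairs.append(pair(DROPPED_PALINDROMIC))
            else:
                if _same_side(exp.eaf, 1.0 - out.eaf):
                    pairs.append(pair(FLIPPED, -out.beta, out.se, 1.0 - out.eaf))
                else:
                    pairs.append(pair(DROPPED_PALINDROMIC))
            continue

        if same:
            pairs.append(pair(KEPT, out.beta, out.se, out.eaf))
        else:
            pairs.append(pair(FLIPPED, -out.beta, out.se, 1.0 - out.eaf))

    n_dropped = sum(not p.retained for p in pairs)
    if n_dropped:
        logger.info("harmonize: dropped %d of %d joined variant(s)", n_dropped, len(pairs))
    return pairs


def retained_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """Pairs that survived harmonization and may enter estimation."""
    return [p for p in pairs if p.retained]
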