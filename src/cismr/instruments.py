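"""Cis-instrument selection, LD clumping, and instrument-strength statistics.

Instruments for each drug-target gene are genome-wide-significant LDL
variants inside the gene's flanked window (GRCh37), thinned by greedy LD
clumping.  Two F-statistic formulas are provided: the Wald form
``beta^2 / se^2`` and the explained-variance form
``(n - 2) R^2 / (1 - R^2)`` with ``R^2 = 2 eaf (1 - eaf) beta^2``; the
embedded instrument tables are reproduced by the latter at n = 440,546.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import EmptySelectionError
from .gwas_io import (
    HarmonizedPair,
    LDMatrix,
    VariantAssociation,
    harmonize,
    retained_pairs,
)

logger = logging.getLogger(__name__)

#: default flank added on each side of a gene when building its cis window
DEFAULT_FLANK = 100_000

#: conventional weak-instrument threshold
WEAK_F_THRESHOLD = 10.0

#: exposure GWAS sample size behind the embedded instrument tables
DEFAULT_EXPOSURE_N = 440_546


@dataclass(frozen=True)
class GeneRegion:
    """A named cis window: gene body plus a symmetric flank (1-based, GRCh37)."""

    name: str
    chrom: str
    gene_start: int
    gene_end: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.name}: gene_start > gene_end")
        if self.flank < 0:
            raise ValueError(f"{self.name}: flank must be >= 0")

    @property
    def window_start(self) -> int:
        return self.gene_start - self.flank

    @property
    def window_end(self) -> int:
        return self.gene_end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        """Inclusive on both flanked boundaries."""
        return str(chrom) == str(self.chrom) and self.window_start <= pos <= self.window_end


# GRCh37 gene coordinates for the three LDL-lowering drug targets
PCSK9_REGION = GeneRegion("PCSK9", "1", 55_505_221, 55_530_525)
HMGCR_REGION = GeneRegion("HMGCR", "5", 74_632_154, 74_657_929)
NPC1L1_REGION = GeneRegion("NPC1L1", "7", 44_552_134, 44_580_914)

DRUG_TARGET_REGIONS: dict[str, GeneRegion] = {
    r.name: r for r in (PCSK9_REGION, HMGCR_REGION, NPC1L1_REGION)
}


@dataclass
class InstrumentSet:
    """Harmonized instruments for one target with per-variant strength."""

    target: str
    pairs: list[HarmonizedPair]
    f_stats: list[float]            # configured formula, aligned with pairs
    f_wald: list[float]             # beta^2 / se^2, aligned with pairs
    f_r2: list[float]               # explained-variance formula, aligned with pairs
    mean_f: float
    f_formula: str = "r2"
    attrition: dict = field(default_factory=dict)


def f_statistic(beta: float, se: float) -> float:
    """Wald instrument-strength statistic: beta^2 / se^2."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def f_statistic_from_r2(beta: float, eaf: float, n: int) -> float:
    """Explained-variance F: (n - 2) R^2 / (1 - R^2), R^2 = 2 eaf (1 - eaf) beta^2.

    Assumes a standardized quantitative exposure so that
    ``2 eaf (1 - eaf) beta^2`` is the variance explained by the variant.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"eaf must lie in (0, 1), got {eaf}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    if r2 >= 1.0:
        raise ValueError(f"explained variance R^2 = {r2} >= 1")
    return (n - 2) * r2 / (1.0 - r2)


def clump(
    candidates: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float,
) -> list[VariantAssociation]:
    """Greedy p-value clumping.

    Candidates are ranked by ascending p-value (ties: ascending position,
    then rsID); the best remaining variant is kept and every remaining
    variant with ``r2 >= r2_threshold`` against it is discarded, until no
    candidates remain.  Output order is selection order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2_threshold must lie in (0, 1], got {r2_threshold}")
    for cand in candidates:
        if cand.snp_id not in ld:
            raise KeyError(f"candidate {cand.snp_id!r} missing from LD matrix")

    remaining = sorted(candidates, key=lambda v: (v.pval, v.pos, v.snp_id))
    kept: list[VariantAssociation] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            v for v in remaining if ld.r2_between(best.snp_id, v.snp_id) < r2_threshold
        ]
    return kept


def select_cis_instruments(
    exposure: Sequence[VariantAssociation],
    region: GeneRegion,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.3,
) -> list[VariantAssociation]:
    """Genome-wide-significant variants inside a flanked gene window, clumped.

    Thresholds are strict: a variant enters only with ``pval < p_threshold``,
    and clumping discards at ``r2 >= r2_threshold``.  ``ld=None`` treats all
    candidates as independent (no clumping), with a logged warning.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    selected = [
        v for v in exposure
        if v.pval < p_threshold and region.contains(v.chrom, v.pos)
    ]
    if not selected:
        raise EmptySelectionError(
            f"no variant passes p < {p_threshold} inside {region.name} "
            f"[{region.chrom}:{region.window_start}-{region.window_end}]"
        )
    if ld is None:
        logger.warning(
            "select_cis_instruments(%s): no LD matrix supplied; "
            "treating %d candidates as independent", region.name, len(selected))
        return selected
    return clump(selected, ld, r2_threshold)


def select_genomewide_ldl_instruments(
    exposure: Sequence[VariantAssociation],
    drug_regions: Sequence[GeneRegion],
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
) -> list[VariantAssociation]:
    """Genome-wide exposure instrument excluding the drug-target gene windows."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    selected = [
        v for v in exposure
        if v.pval < p_threshold
        and not any(region.contains(v.chrom, v.pos) for region in drug_regions)
    ]
    if not selected:
        raise EmptySelectionError(
            f"no variant passes p < {p_threshold} outside the drug-target regions"
        )
    if ld is None:
        logger.warning(
            "select_genomewide_ldl_instruments: no LD matrix supplied; "
            "treating %d candidates as independent", len(selected))
        return selected
    return clump(selected, ld, r2_threshold)


@dataclass(frozen=True)
class InstrumentConfig:
    """Knobs for instrument building."""

    p_threshold: float = 5e-8
    r2_threshold_cis: float = 0.3
    r2_threshold_genomewide: float = 0.001
    f_formula: str = "r2"           # "r2" or "wald"
    f_filter: bool = False
    f_threshold: float = WEAK_F_THRESHOLD
    exposure_n: int = DEFAULT_EXPOSURE_N
    palindromic_eaf_window: float = 0.08

    def __post_init__(self) -> None:
        if self.f_formula not in ("r2", "wald"):
            raise ValueError(f"f_formula must be 'r2' or 'wald', got {self.f_formula!r}")


def _pair_f_stats(
    pairs: Sequence[HarmonizedPair],
    exposure_n: Mapping[str, int | None],
    default_n: int,
) -> tuple[list[float], list[float]]:
    f_wald = [f_statistic(p.exposure_beta, p.exposure_se) for p in pairs]
    f_r2 = [
        f_statistic_from_r2(
            p.exposure_beta, p.exposure_eaf, exposure_n.get(p.snp_id) or default_n
        )
        for p in pairs
    ]
    return f_wald, f_r2


def build_instrument_set(
    target: str,
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    region: GeneRegion | None,
    ld: LDMatrix | None = None,
    config: InstrumentConfig | None = None,
) -> InstrumentSet:
    """Select, harmonize, and strength-check instruments for one target.

    ``region=None`` builds the genome-wide exposure instrument (all drug
    target windows excluded) instead of a cis instrument.
    """
    config = config or InstrumentConfig()

    if region is not None:
        selected = select_cis_instruments(
            exposure, region, config.p_threshold, ld, config.r2_threshold_cis
        )
    else:
        selected = select_genomewide_ldl_instruments(
            exposure, list(DRUG_TARGET_REGIONS.values()), ld,
            config.p_threshold, config.r2_threshold_genomewide,
        )

    all_pairs = harmonize(selected, outcome, config.palindromic_eaf_window)
    pairs = retained_pairs(all_pairs)
    attrition = {
        "candidates": len(exposure),
        "selected": len(selected),
        "joined": len(all_pairs),
        "dropped_palindromic": sum(
            p.harmonization_action == "dropped_palindromic" for p in all_pairs),
        "dropped_mismatch": sum(
            p.harmonization_action == "dropped_mismatch" for p in all_pairs),
        "harmonized": len(pairs),
    }

    n_by_snp = {v.snp_id: v.n for v in selected}
    f_wald, f_r2 = _pair_f_stats(pairs, n_by_snp, config.exposure_n)
    f_primary = f_r2 if config.f_formula == "r2" else f_wald

    if config.f_filter:
        keep = [i for i, f in enumerate(f_primary) if f > config.f_threshold]
        attrition["weak_f_removed"] = len(pairs) - len(keep)
        pairs = [pairs[i] for i in keep]
        f_wald = [f_wald[i] for i in keep]
        f_r2 = [f_r2[i] for i in keep]
        f_primary = [f_primary[i] for i in keep]
    else:
        attrition["weak_f_removed"] = 0

    if not pairs:
        raise EmptySelectionError(f"{target}: no instrument retained after filtering")
    if len(pairs) < 3:
        logger.warning(
            "%s: only %d instrument(s) retained; Egger/median/mode unreliable",
            target, len(pairs))

    return InstrumentSet(
        target=target,
        pairs=pairs,
        f_stats=f_primary,
        f_wald=f_wald,
        f_r2=f_r2,
        mean_f=sum(f_primary) / len(f_primary),
        f_formula=config.f_formula,
        attrition=attrition,
    )
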