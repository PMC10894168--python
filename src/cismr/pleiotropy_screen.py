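"""Instrument exclusion on known variant-trait associations.

Emulates a curated genotype-phenotype lookup: instruments associated with a
listed confounding trait below a p-value threshold are excluded.  The screen
consumes a local tab-delimited table (SNP, TRAIT, P) so runs are
reproducible offline.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import EmptyInputError
from .gwas_io import HarmonizedPair

logger = logging.getLogger(__name__)

#: traits screened by default (established outcome risk factors)
DEFAULT_EXCLUDED_TRAITS = ("smoking", "psoriasis")

#: default exclusion threshold
DEFAULT_TRAIT_P_THRESHOLD = 1e-5


@dataclass(frozen=True)
class TraitAssociation:
    """One variant-trait association from the lookup table."""

    snp_id: str
    trait: str
    pval: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}/{self.trait}: pval outside (0, 1]")


@dataclass(frozen=True)
class ScreenRemoval:
    """A removed pair with every (trait, pval) association that triggered it."""

    pair: HarmonizedPair
    reasons: tuple[tuple[str, float], ...]


def read_trait_table(path: str | Path) -> list[TraitAssociation]:
    """Read a tab-delimited variant-trait table with columns SNP, TRAIT, P."""
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(TraitAssociation(
                snp_id=row["SNP"].strip(),
                trait=row["TRAIT"].strip(),
                pval=float(row["P"]),
            ))
    if not records:
        raise EmptyInputError(f"{path}: no trait associations")
    return records


def screen_instruments(
    pairs: Sequence[HarmonizedPair],
    trait_table: Sequence[TraitAssociation],
    excluded_traits: Sequence[str] = DEFAULT_EXCLUDED_TRAITS,
    p_threshold: float = DEFAULT_TRAIT_P_THRESHOLD,
) -> tuple[list[HarmonizedPair], list[ScreenRemoval]]:
    """Partition pairs into kept and removed by trait association.

    A pair is removed iff the table holds an association for its snp_id with
    a matched trait at ``pval < p_threshold`` (strict).  Trait matching is a
    case-insensitive substring test of each excluded label against the
    table's trait text.  Every triggering (trait, pval) is reported.
    """
    if not excluded_traits and trait_table:
        logger.warning("screen_instruments: excluded_traits is empty; screen is a no-op")

    labels = [t.lower() for t in excluded_traits]
    by_snp: dict[str, list[TraitAssociation]] = {}
    for assoc in trait_table:
        by_snp.setdefault(assoc.snp_id, []).append(assoc)

    kept: list[HarmonizedPair] = []
    removed: list[ScreenRemoval] = []
    for pair in pairs:
        reasons = tuple(
            (assoc.trait, assoc.pval)
            for assoc in by_snp.get(pair.snp_id, ())
            if assoc.pval < p_threshold
            and any(label in assoc.trait.lower() for label in labels)
        )
        if reasons:
            removed.append(ScreenRemoval(pair=pair, reasons=reasons))
        else:
            kept.append(pair)
    if removed:
        logger.info("screen_instruments: removed %d of %d instrument(s)",
                    len(removed), len(pairs))
    return kept, removed
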