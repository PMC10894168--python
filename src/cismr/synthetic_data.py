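"""Two-sample GWAS simulation with known ground truth.

Generates exposure and case-control outcome summary statistics under the
additive model the estimators assume.  Per variant j the generator draws an
allele frequency ``p_j`` and a positive per-allele exposure effect
``gamma_j`` (the effect allele is oriented to raise the exposure), then

* exposure SE     ``sx_j = 1 / sqrt(2 p_j (1 - p_j) n_exposure)``
* observed exposure beta ~ Normal(gamma_j, sx_j)
* pleiotropy      ``alpha_j`` = 0 / Normal(0, sd) / Normal(mean, sd)
* true outcome effect = b * gamma_j + alpha_j
* outcome SE      ``sy_j = 1 / sqrt(2 p_j (1 - p_j) n_eff)`` with
  ``n_eff = n_cases * n_controls / (n_cases + n_controls)``
* observed outcome beta ~ Normal(true, sy_j)

Exposure and outcome noise come from independent random streams spawned
from the master seed, honoring the non-overlapping-samples assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import LDMatrix, VariantAssociation

# non-palindromic allele codings cycled across variants
_ALLELE_CYCLE = (("A", "G"), ("T", "C"), ("G", "A"), ("C", "T"))

PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one two-sample GWAS simulation."""

    seed: int
    n_variants: int = 30
    causal_effect: float = 0.0
    exposure_n: int = 440_546
    n_cases: int = 1_637
    n_controls: int = 212_242
    eaf_range: tuple[float, float] = (0.05, 0.5)
    exposure_effect_range: tuple[float, float] = (0.02, 0.10)
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 1_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_variants", "exposure_n", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"degenerate eaf_range {self.eaf_range}")
        lo, hi = self.exposure_effect_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"degenerate exposure_effect_range {self.exposure_effect_range}")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}")

    @property
    def outcome_n_eff(self) -> float:
        return self.n_cases * self.n_controls / (self.n_cases + self.n_controls)


def _snp_ids(n: int) -> list[str]:
    return [f"rs{9_000_000 + j}" for j in range(n)]


def _streams(scenario: SyntheticScenario, n_streams: int = 4) -> list[np.random.Generator]:
    children = np.random.SeedSequence(scenario.seed).spawn(n_streams)
    return [np.random.default_rng(s) for s in children]


def _draw_alpha(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    if scenario.pleiotropy_mode == "none":
        return np.zeros(scenario.n_variants)
    mean = scenario.pleiotropy_mean if scenario.pleiotropy_mode == "directional" else 0.0
    return rng.normal(mean, scenario.pleiotropy_sd, scenario.n_variants)


def _records(
    scenario: SyntheticScenario,
    betas: np.ndarray,
    ses: np.ndarray,
    eafs: np.ndarray,
    n: int,
) -> list[VariantAssociation]:
    pvals = 2 * stats.norm.sf(np.abs(betas) / ses)
    out = []
    for j, snp in enumerate(_snp_ids(scenario.n_variants)):
        ea, oa = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]
        out.append(VariantAssociation(
            snp_id=snp,
            chrom=scenario.chrom,
            pos=scenario.pos_start + j * scenario.pos_step,
            effect_allele=ea,
            other_allele=oa,
            eaf=float(eafs[j]),
            beta=float(betas[j]),
            se=float(ses[j]),
            pval=float(max(pvals[j], np.finfo(float).tiny)),
            n=n,
        ))
    return out


def _simulate(
    scenario: SyntheticScenario,
    outcome_stream: int,
) -> tuple[list[VariantAssociation], list[VariantAssociation], dict]:
    rng_params, rng_exposure, rng_primary, rng_control = _streams(scenario)
    rng_outcome = rng_control if outcome_stream == 3 else rng_primary

    n = scenario.n_variants
    eaf = rng_params.uniform(*scenario.eaf_range, n)
    gamma = rng_params.uniform(*scenario.exposure_effect_range, n)
    alpha = _draw_alpha(scenario, rng_params)

    sx = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * scenario.exposure_n)
    beta_x = rng_exposure.normal(gamma, sx)

    true_outcome = scenario.causal_effect * gamma + alpha
    sy = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * scenario.outcome_n_eff)
    beta_y = rng_outcome.normal(true_outcome, sy)

    exposure = _records(scenario, beta_x, sx, eaf, scenario.exposure_n)
    outcome = _records(scenario, beta_y, sy, eaf, scenario.n_cases + scenario.n_controls)
    truth = {
        "causal_effect": scenario.causal_effect,
        "gamma": gamma,
        "alpha": alpha,
        "eaf": eaf,
        "exposure_se": sx,
        "outcome_se": sy,
        "snp_ids": _snp_ids(n),
    }
    return exposure, outcome, truth


def simulate_two_sample(
    scenario: SyntheticScenario,
) -> tuple[list[VariantAssociation], list[VariantAssociation], dict]:
    """Exposure and outcome summary statistics plus the generative truth."""
    return _simulate(scenario, outcome_stream=2)


def simulate_positive_control(scenario: SyntheticScenario) -> list[VariantAssociation]:
    """Outcome summary statistics for a positive-control trait.

    Shares the exposure-side truth (same seed, same parameter and exposure
    streams) but draws outcome noise from a separate stream, so the control
    outcome is independent of the primary outcome given the truth.
    """
    _, outcome, _ = _simulate(scenario, outcome_stream=3)
    return outcome


def simulate_ld_matrix(scenario: SyntheticScenario) -> LDMatrix:
    """Block-diagonal r2 matrix matching simulate_two_sample's variant ids."""
    blocks: Sequence[tuple[int, float]]
    if scenario.ld_blocks is None:
        blocks = tuple((1, 0.0) for _ in range(scenario.n_variants))
    else:
        blocks = scenario.ld_blocks
    if sum(size for size, _ in blocks) != scenario.n_variants:
        raise ValueError("ld block sizes must sum to n_variants")

    r2 = np.zeros((scenario.n_variants, scenario.n_variants))
    start = 0
    for size, within in blocks:
        if not 0.0 <= within <= 1.0:
            raise ValueError(f"within-block r2 {within} outside [0, 1]")
        r2[start:start + size, start:start + size] = within
        start += size
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(_snp_ids(scenario.n_variants), r2)
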