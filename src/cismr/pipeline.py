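"""Study orchestration: instruments -> harmonization -> screen -> estimates.

``run_study`` drives the per-target analyses (three cis drug-target
instruments plus, optionally, the genome-wide exposure instrument) against a
primary and an optional validation outcome, writes tab-delimited tables and
a JSON summary, and records every filtering step.  A stage failure for one
target is reported and the remaining targets still run.

Reported effects are per unit *increase* of the exposure on the log-odds
scale; each estimate also carries ``or_inhibition = exp(-beta)``, the
odds ratio for genetically proxied inhibition (exposure lowering), which is
the headline scale and drives the positive-control pass flag.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import estimators
from .errors import CismrError, ConfigurationError
from .estimators import MREstimate, all_estimates, leave_one_out, wald_ratios
from .gwas_io import (
    LDMatrix,
    VariantAssociation,
    load_table1_fixture,
    read_ld_matrix,
    read_summary_stats,
)
from .instruments import (
    DRUG_TARGET_REGIONS,
    GeneRegion,
    InstrumentConfig,
    InstrumentSet,
    build_instrument_set,
)
from .pleiotropy_screen import (
    DEFAULT_EXCLUDED_TRAITS,
    DEFAULT_TRAIT_P_THRESHOLD,
    read_trait_table,
    screen_instruments,
)
from .synthetic_data import (
    SyntheticScenario,
    simulate_positive_control,
    simulate_two_sample,
)

logger = logging.getLogger(__name__)

GENOMEWIDE_LABEL = "LDL"


@dataclass
class RunConfig:
    """Everything one study run needs, loadable from YAML."""

    seed: int
    out_dir: str = "results"
    exposure_path: str | None = None      # None -> embedded instrument tables
    outcome_path: str | None = None
    validation_path: str | None = None
    ld_path: str | None = None
    trait_table_path: str | None = None
    regions: list[GeneRegion] = field(
        default_factory=lambda: list(DRUG_TARGET_REGIONS.values()))
    include_genomewide: bool = False
    p_threshold: float = 5e-8
    r2_threshold_cis: float = 0.3
    r2_threshold_genomewide: float = 0.001
    f_formula: str = "r2"
    f_filter: bool = False
    f_threshold: float = 10.0
    exposure_n: int = 440_546
    palindromic_eaf_window: float = 0.08
    excluded_traits: list[str] = field(
        default_factory=lambda: list(DEFAULT_EXCLUDED_TRAITS))
    trait_p_threshold: float = DEFAULT_TRAIT_P_THRESHOLD
    n_boot: int = 2000
    bandwidth_factor: float = 1.0
    positive_control_path: str | None = None
    positive_control_scenario: dict | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "regions" in raw:
            raw["regions"] = [GeneRegion(**r) for r in raw["regions"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def instrument_config(self) -> InstrumentConfig:
        return InstrumentConfig(
            p_threshold=self.p_threshold,
            r2_threshold_cis=self.r2_threshold_cis,
            r2_threshold_genomewide=self.r2_threshold_genomewide,
            f_formula=self.f_formula,
            f_filter=self.f_filter,
            f_threshold=self.f_threshold,
            exposure_n=self.exposure_n,
            palindromic_eaf_window=self.palindromic_eaf_window,
        )


def _estimate_dict(est: MREstimate) -> dict:
    import math

    d = {k: v for k, v in dataclasses.asdict(est).items() if v is not None}
    d["or_inhibition"] = math.exp(-est.beta)
    d["or_inhibition_ci_low"] = math.exp(-est.ci_high)
    d["or_inhibition_ci_high"] = math.exp(-est.ci_low)
    return d


def _load_exposure(config: RunConfig) -> list[VariantAssociation]:
    if config.exposure_path:
        return read_summary_stats(config.exposure_path)
    records: list[VariantAssociation] = []
    for target in DRUG_TARGET_REGIONS:
        records.extend(load_table1_fixture(target))
    return records


def _analyze_outcome(
    inst: InstrumentSet,
    outcome_label: str,
    config: RunConfig,
    trait_table,
) -> dict:
    pairs = inst.pairs
    removed_info = []
    if trait_table is not None:
        pairs, removals = screen_instruments(
            pairs, trait_table, config.excluded_traits, config.trait_p_threshold)
        removed_info = [
            {"snp": r.pair.snp_id,
             "reasons": [{"trait": t, "p": p} for t, p in r.reasons]}
            for r in removals
        ]

    if len(pairs) < 3:
        raise CismrError(
            f"{inst.target}/{outcome_label}: only {len(pairs)} instrument(s) "
            "after screening; estimator suite needs >= 3")

    estimates = all_estimates(
        pairs, n_boot=config.n_boot,
        bandwidth_factor=config.bandwidth_factor, seed=config.seed)
    ivw = estimates[estimators.IVW_MRE]
    loo = leave_one_out(pairs)
    ratios = wald_ratios(pairs)

    return {
        "n_snps": len(pairs),
        "screen_removed": removed_info,
        "estimates": {m: _estimate_dict(e) for m, e in estimates.items()},
        "heterogeneity": {"q": ivw.q_stat, "q_pval": ivw.q_pval,
                          "df": ivw.n_snps - 1},
        "wald_ratios": [
            {"snp": r.snp_id, "ratio": r.ratio, "se": r.ratio_se}
            for r in ratios
        ],
        "leave_one_out": [
            {"snp": snp, "beta": est.beta, "se": est.se,
             "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval}
            for snp, est in loo
        ],
    }


def _build_all_instruments(
    config: RunConfig,
    exposure: list[VariantAssociation],
    outcome: list[VariantAssociation],
    ld: LDMatrix | None,
    errors: list[dict],
) -> dict[str, InstrumentSet]:
    sets: dict[str, InstrumentSet] = {}
    units: list[tuple[str, GeneRegion | None]] = [(r.name, r) for r in config.regions]
    if config.include_genomewide:
        units.append((GENOMEWIDE_LABEL, None))
    for name, region in units:
        try:
            sets[name] = build_instrument_set(
                name, exposure, outcome, region, ld, config.instrument_config())
        except (CismrError, KeyError, ValueError) as exc:
            logger.error("instrument building failed for %s: %s", name, exc)
            errors.append({"target": name, "stage": "instruments", "message": str(exc)})
    return sets


def run_study(config: RunConfig) -> dict:
    """Run the full per-target study; returns (and writes) the report."""
    errors: list[dict] = []
    exposure = _load_exposure(config)
    if not config.outcome_path:
        raise ConfigurationError("outcome_path must be set")
    outcome = read_summary_stats(config.outcome_path)
    validation = (read_summary_stats(config.validation_path)
                  if config.validation_path else None)
    if validation is None:
        logger.warning("no validation outcome configured; primary-only report")
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    trait_table = (read_trait_table(config.trait_table_path)
                   if config.trait_table_path else None)

    report: dict = {
        "config": {
            "seed": config.seed,
            "p_threshold": config.p_threshold,
            "r2_threshold_cis": config.r2_threshold_cis,
            "r2_threshold_genomewide": config.r2_threshold_genomewide,
            "f_formula": config.f_formula,
            "f_filter": config.f_filter,
            "exposure_n": config.exposure_n,
            "palindromic_eaf_window": config.palindromic_eaf_window,
            "excluded_traits": list(config.excluded_traits),
            "trait_p_threshold": config.trait_p_threshold,
            "n_boot": config.n_boot,
            "bandwidth_factor": config.bandwidth_factor,
        },
        "targets": {},
        "errors": errors,
    }

    outcomes = {"primary": outcome}
    if validation is not None:
        outcomes["validation"] = validation

    for label, outcome_records in outcomes.items():
        inst_sets = _build_all_instruments(
            config, exposure, outcome_records, ld, errors)
        for name, inst in inst_sets.items():
            block = report["targets"].setdefault(name, {"outcomes": {}})
            block.setdefault("instruments", {})[label] = {
                "n": len(inst.pairs),
                "snps": [p.snp_id for p in inst.pairs],
                "f_stats": list(inst.f_stats),
                "f_wald": list(inst.f_wald),
                "f_r2": list(inst.f_r2),
                "mean_f": inst.mean_f,
                "f_formula": inst.f_formula,
                "attrition": inst.attrition,
            }
            try:
                block["outcomes"][label] = _analyze_outcome(
                    inst, label, config, trait_table)
            except (CismrError, ValueError) as exc:
                logger.error("estimation failed for %s/%s: %s", name, label, exc)
                errors.append({"target": name, "stage": f"estimation:{label}",
                               "message": str(exc)})

    _write_report(report, Path(config.out_dir))
    return report


def run_positive_control(config: RunConfig) -> dict:
    """Per-target estimates against a positive-control outcome with pass flag.

    Passes iff every target's IVW odds ratio for genetically proxied
    inhibition (exp(-beta)) is below 1.
    """
    if config.positive_control_path:
        control = read_summary_stats(config.positive_control_path)
    elif config.positive_control_scenario is not None:
        scenario = SyntheticScenario(**config.positive_control_scenario)
        control = simulate_positive_control(scenario)
    else:
        raise ConfigurationError(
            "positive control needs positive_control_path or "
            "positive_control_scenario")

    errors: list[dict] = []
    exposure = _load_exposure(config)
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    inst_sets = _build_all_instruments(config, exposure, control, ld, errors)

    control_report: dict = {"targets": {}, "errors": errors}
    all_protective = bool(inst_sets)
    for name, inst in inst_sets.items():
        try:
            block = _analyze_outcome(inst, "positive_control", config, None)
        except (CismrError, ValueError) as exc:
            errors.append({"target": name, "stage": "estimation:positive_control",
                           "message": str(exc)})
            all_protective = False
            continue
        ivw = block["estimates"][estimators.IVW_MRE]
        protective = ivw["or_inhibition"] < 1.0
        all_protective = all_protective and protective
        control_report["targets"][name] = {
            "estimates": block["estimates"],
            "or_inhibition_ivw": ivw["or_inhibition"],
            "protective": protective,
        }
    control_report["positive_control"] = {
        "passed": all_protective and not errors,
        "n_targets": len(control_report["targets"]),
    }
    return control_report


def write_simulated_study(scenario: SyntheticScenario, out_dir: str | Path) -> dict:
    """Write a simulated exposure/outcome/LD trio in pipeline-readable form."""
    from .gwas_io import write_ld_matrix, write_summary_stats
    from .synthetic_data import simulate_ld_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = simulate_two_sample(scenario)
    ld = simulate_ld_matrix(scenario)
    write_summary_stats(exposure, out / "exposure.tsv")
    write_summary_stats(outcome, out / "outcome.tsv")
    write_ld_matrix(ld, out / "ld.tsv")
    serializable = {
        k: (v.tolist() if hasattr(v, "tolist") else v) for k, v in truth.items()
    }
    (out / "truth.json").write_text(
        json.dumps(serializable, sort_keys=True, indent=2) + "\n")
    return truth


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(dumps_report(report))

    est_rows = ["target\toutcome\tmethod\tn_snps\tbeta\tse\tci_low\tci_high\t"
                "pval\tor\tor_ci_low\tor_ci_high\tor_inhibition\tq\tq_pval\t"
                "egger_intercept\tegger_intercept_pval"]
    for target in sorted(report["targets"]):
        block = report["targets"][target]
        for outcome_label in sorted(block["outcomes"]):
            analysis = block["outcomes"][outcome_label]
            for method in sorted(analysis["estimates"]):
                e = analysis["estimates"][method]
                fields = [
                    target, outcome_label, method, e["n_snps"], e["beta"],
                    e["se"], e["ci_low"], e["ci_high"], e["pval"],
                    e.get("or_", ""), e.get("or_ci_low", ""),
                    e.get("or_ci_high", ""), e["or_inhibition"],
                    e.get("q_stat", ""), e.get("q_pval", ""),
                    e.get("egger_intercept", ""),
                    e.get("egger_intercept_pval", ""),
                ]
                est_rows.append("\t".join(str(f) for f in fields))
    (out_dir / "estimates.tsv").write_text("\n".join(est_rows) + "\n")

    for target in sorted(report["targets"]):
        block = report["targets"][target]
        for outcome_label, analysis in sorted(block["outcomes"].items()):
            rows = ["snp\tbeta\tse\tci_low\tci_high\tpval"]
            for entry in analysis["leave_one_out"]:
                rows.append("\t".join(str(entry[k]) for k in (
                    "snp", "beta", "se", "ci_low", "ci_high", "pval")))
            path = out_dir / f"leave_one_out_{target}_{outcome_label}.tsv"
            path.write_text("\n".join(rows) + "\n")


def dumps_report(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, plain floats)."""

    def default(obj):
        if hasattr(obj, "item"):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    return json.dumps(report, sort_keys=True, indent=2, default=default) + "\n"


def render_report(report: dict, out_dir: str | Path) -> list[Path]:
    """Forest and leave-one-out figures; failures never abort the run."""
    out = Path(out_dir) / "figures"
    written: list[Path] = []
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out.mkdir(parents=True, exist_ok=True)
        outcome_labels = sorted({
            label
            for block in report["targets"].values()
            for label in block["outcomes"]
        })
        for label in outcome_labels:
            entries = []
            for target in sorted(report["targets"]):
                analysis = report["targets"][target]["outcomes"].get(label)
                if not analysis:
                    continue
                for method in sorted(analysis["estimates"]):
                    e = analysis["estimates"][method]
                    entries.append((f"{target} [{method}]", e["or_"],
                                    e["or_ci_low"], e["or_ci_high"]))
            if not entries:
                continue
            fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
            ys = range(len(entries))
            for y, (name, or_, lo, hi) in zip(ys, entries):
                ax.plot([lo, hi], [y, y], color="steelblue")
                ax.plot([or_], [y], "o", color="navy")
            ax.axvline(1.0, color="grey", linestyle="--", linewidth=0.8)
            ax.set_yticks(list(ys))
            ax.set_yticklabels([e[0] for e in entries])
            ax.set_xscale("log")
            ax.set_xlabel("odds ratio per unit exposure increase (95% CI)")
            ax.set_title(f"MR estimates — {label} outcome")
            fig.tight_layout()
            path = out / f"forest_{label}.png"
            fig.savefig(path, dpi=150)
            plt.close(fig)
            written.append(path)

        for target in sorted(report["targets"]):
            for label, analysis in sorted(
                    report["targets"][target]["outcomes"].items()):
                loo = analysis["leave_one_out"]
                if not loo:
                    continue
                fig, ax = plt.subplots(figsize=(6, 0.25 * len(loo) + 1.5))
                for y, entry in enumerate(loo):
                    ax.plot([entry["ci_low"], entry["ci_high"]], [y, y],
                            color="darkseagreen")
                    ax.plot([entry["beta"]], [y], "o", color="darkgreen",
                            markersize=3)
                ax.axvline(0.0, color="grey", linestyle="--", linewidth=0.8)
                ax.set_yticks(range(len(loo)))
                ax.set_yticklabels([e["snp"] for e in loo], fontsize=6)
                ax.set_xlabel("IVW beta omitting variant (95% CI)")
                ax.set_title(f"Leave-one-out — {target}, {label}")
                fig.tight_layout()
                path = out / f"loo_{target}_{label}.png"
                fig.savefig(path, dpi=150)
                plt.close(fig)
                written.append(path)
    except Exception:  # plotting must never abort an analysis run
        logger.exception("report rendering failed; continuing")
    return written
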