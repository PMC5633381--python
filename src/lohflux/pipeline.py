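"""End-to-end analyses: classification tables, rate tables, test panels.

These functions orchestrate the genetics, simulation, estimation and testing
modules over tabular inputs (real or simulated) and produce the summary
artifacts of an LOH study: per-genotype class distributions, per-class rate
tables with confidence intervals, and the complex-event test panel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .markers import (
    AnomalousPhenotypeError,
    ComplexSubclass,
    LOHClass,
    classify_phenotype,
    subclassify_complex,
)
from .io import culture_results_from_table, row_to_phenotype
from .rates import (
    NON_CL_LABEL,
    TOTAL_LABEL,
    RateEstimate,
    class_rate_table,
)
from .simulate import CultureConfig, EventRates, simulate_assay
from .stats import (
    ContingencyTable2x2,
    TestResult,
    binomial_independence_test,
    fisher_exact_2x2,
    holm_bonferroni,
    independence_expected_rate,
    mann_whitney,
    round_to_sig,
    welch_t_test,
)

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "run_classify",
    "run_rates",
    "run_complex_panel",
    "run_simulation_study",
]

CLASS_ORDER = [
    LOHClass.GENE_CONVERSION.value,
    LOHClass.CHROMOSOME_LOSS.value,
    LOHClass.SEGMENTAL.value,
    LOHClass.COMPLEX.value,
    LOHClass.NO_LOH.value,
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared across pipeline stages."""

    marker_map: str = "cen"  # cen | tel | path to JSON
    assay_mode: str = "independent-colonies"  # or "fluctuation"
    estimator: str = "per-culture"  # or "pooled-median"
    correction: str = "holm"  # holm | bonferroni | none
    confidence: float = 0.95
    seed: Optional[int] = None
    n0: int = 1000
    output_dir: Optional[str] = None

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """Everything one analysis run produced, JSON-serialisable."""

    class_distribution: Optional[pd.DataFrame] = None
    rate_table: Optional[pd.DataFrame] = None
    test_panel: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, include_provenance: bool = True) -> str:
        payload = {
            "class_distribution": (
                None
                if self.class_distribution is None
                else self.class_distribution.to_dict(orient="records")
            ),
            "rate_table": (
                None
                if self.rate_table is None
                else self.rate_table.to_dict(orient="records")
            ),
            "test_panel": self.test_panel,
            "warnings": self.warnings,
        }
        if include_provenance:
            payload["provenance"] = self.provenance
        return json.dumps(payload, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _provenance(config: AnalysisConfig) -> dict:
    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "lohflux_version": __version__,
    }


def run_classify(
    config: AnalysisConfig, phenotype_table: pd.DataFrame
) -> ReportBundle:
    """Classify colony phenotypes into LOH classes, per genotype.

    Malformed rows are rejected (with line numbers) without aborting the run;
    anomalous 5FOA-resistant patterns are tallied separately, never merged
    into a class.
    """
    records: list[dict] = []
    rejected: list[str] = []
    anomalous: dict[str, dict[str, int]] = {}
    counts: dict[str, dict[str, int]] = {}

    for idx, row in phenotype_table.iterrows():
        genotype = str(row.get("genotype", "NA"))
        try:
            pheno = row_to_phenotype(row)
            loh_class = classify_phenotype(pheno)
        except AnomalousPhenotypeError as err:
            anomalous.setdefault(genotype, {}).setdefault(err.pattern, 0)
            anomalous[genotype][err.pattern] += 1
            continue
        except (ValueError, KeyError) as err:
            rejected.append(f"line {idx + 2}: {err}")  # +2: header + 1-based
            continue
        counts.setdefault(genotype, {}).setdefault(loh_class.value, 0)
        counts[genotype][loh_class.value] += 1

    for genotype in sorted(set(counts) | set(anomalous)):
        class_counts = counts.get(genotype, {})
        total = sum(class_counts.values())
        anomalous_n = sum(anomalous.get(genotype, {}).values())
        for label in CLASS_ORDER:
            n = class_counts.get(label, 0)
            records.append(
                {
                    "genotype": genotype,
                    "class": label,
                    "count": n,
                    "percent": 100.0 * n / total if total else 0.0,
                    "total_classified": total,
                }
            )
        records.append(
            {
                "genotype": genotype,
                "class": "ANOMALOUS",
                "count": anomalous_n,
                "percent": float("nan"),
                "total_classified": total,
            }
        )

    bundle = ReportBundle(
        class_distribution=pd.DataFrame(records),
        warnings=[f"rejected rows: {len(rejected)}"] + rejected if rejected else [],
        provenance=_provenance(config),
    )
    return bundle


def _rate_row(genotype: str, estimate: RateEstimate) -> dict:
    return {
        "genotype": genotype,
        "class": estimate.class_label,
        "median_rate_per_division": estimate.median_rate,
        "rate_per_1e7_divisions": round_to_sig(estimate.per_1e7, 2),
        "ci_lower_per_1e7": (
            None if estimate.ci_lower is None else round_to_sig(estimate.ci_lower * 1e7, 2)
        ),
        "ci_upper_per_1e7": (
            None if estimate.ci_upper is None else round_to_sig(estimate.ci_upper * 1e7, 2)
        ),
        "achieved_level": estimate.achieved_level,
        "n_cultures": estimate.n_cultures,
        "method": estimate.method,
        "flags": ";".join(estimate.flags),
    }


def run_rates(
    config: AnalysisConfig,
    culture_table: pd.DataFrame,
) -> ReportBundle:
    """Per-genotype, per-class rate table from a classified culture table.

    Needs at least 2 cultures per genotype; genotypes below that are skipped
    with a warning.  Rates are reported per 10^7 cell divisions.
    """
    rows: list[dict] = []
    notes: list[str] = []
    genotype_col = (
        culture_table["genotype"] if "genotype" in culture_table.columns
        else pd.Series(["NA"] * len(culture_table))
    )
    for genotype, group in culture_table.groupby(genotype_col):
        if len(group) < 2:
            notes.append(f"genotype {genotype}: fewer than 2 cultures, skipped")
            continue
        cultures = culture_results_from_table(group)
        table = class_rate_table(
            cultures,
            level=config.confidence,
            estimator=config.estimator,
        )
        ordered = [TOTAL_LABEL] + CLASS_ORDER + [NON_CL_LABEL]
        for label in ordered:
            if label in table:
                rows.append(_rate_row(str(genotype), table[label]))
        for label, estimate in table.items():
            if label not in ordered:
                rows.append(_rate_row(str(genotype), estimate))
    return ReportBundle(
        rate_table=pd.DataFrame(rows),
        warnings=notes,
        provenance=_provenance(config),
    )


def subclass_distribution(phenotype_table: pd.DataFrame) -> pd.DataFrame:
    """Subclass counts among COMPLEX colonies, per genotype."""
    rows = []
    genotype_col = (
        phenotype_table["genotype"] if "genotype" in phenotype_table.columns
        else pd.Series(["NA"] * len(phenotype_table))
    )
    for genotype, group in phenotype_table.groupby(genotype_col):
        tallies = {sub.value: 0 for sub in ComplexSubclass}
        het = hom = 0
        for _, row in group.iterrows():
            try:
                pheno = row_to_phenotype(row)
                if classify_phenotype(pheno) is not LOHClass.COMPLEX:
                    continue
                sub = subclassify_complex(pheno)
            except (ValueError, KeyError):
                continue
            tallies[sub.value] += 1
            if sub is ComplexSubclass.HET_TELOMERIC:
                het += 1
            elif sub in (
                ComplexSubclass.HALF_CO_NAT_TYR1,
                ComplexSubclass.HALF_CO_TYR1_URA3,
            ):
                hom += 1
        for label, n in tallies.items():
            rows.append(
                {"genotype": str(genotype), "subclass": label, "count": n,
                 "het": het, "hom": hom}
            )
    return pd.DataFrame(rows)


def run_complex_panel(
    config: AnalysisConfig,
    phenotype_table: Optional[pd.DataFrame] = None,
    het_hom_by_genotype: Optional[dict[str, tuple[int, int]]] = None,
    segmental_rate: Optional[float] = None,
    cl_rate: Optional[float] = None,
    observed_complex_rate: Optional[float] = None,
    n_divisions: int = 10_000_000,
    pfge_fractions: Optional[dict[str, Sequence[float]]] = None,
    pfge_test: str = "mann-whitney",
) -> ReportBundle:
    """The complex-event analysis panel.

    Emits (a) the subclass distribution, (b) a Fisher exact comparison of
    telomeric-marker heterozygosity between two genotypes, (c) the
    independent-events product rate with a binomial upper-tail bound against
    the observed complex rate, and (d) a PFGE chromosome II fraction
    comparison when band data are supplied.  Items whose inputs are missing
    are marked unavailable rather than failed.
    """
    panel: list[dict] = []
    bundle = ReportBundle(provenance=_provenance(config))

    if phenotype_table is not None:
        dist = subclass_distribution(phenotype_table)
        bundle.class_distribution = dist
        if het_hom_by_genotype is None:
            het_hom_by_genotype = {
                genotype: (
                    int(group["het"].iloc[0]) if len(group) else 0,
                    int(group["hom"].iloc[0]) if len(group) else 0,
                )
                for genotype, group in dist.groupby("genotype")
            }

    if het_hom_by_genotype and len(het_hom_by_genotype) >= 2:
        (g1, (het1, hom1)), (g2, (het2, hom2)) = list(het_hom_by_genotype.items())[:2]
        if het1 + hom1 > 0 and het2 + hom2 > 0:
            result = fisher_exact_2x2(
                ContingencyTable2x2(
                    het1, hom1, het2, hom2,
                    row_labels=(g1, g2), col_labels=("het", "hom"),
                )
            )
            panel.append(
                {"item": f"heterozygosity {g1} vs {g2}", **result.to_record()}
            )
        else:
            panel.append(
                {"item": "heterozygosity comparison", "status": "unavailable",
                 "reason": "no zygosity-genotyped complex colonies"}
            )
    else:
        panel.append(
            {"item": "heterozygosity comparison", "status": "unavailable",
             "reason": "needs zygosity calls for two genotypes"}
        )

    if segmental_rate is not None and cl_rate is not None:
        expected = independence_expected_rate(segmental_rate, cl_rate)
        record = {
            "item": "independent-events expected complex rate",
            "expected_rate_per_division": expected,
            "expected_rate_1sf": round_to_sig(expected, 1),
        }
        if observed_complex_rate is not None:
            k = int(round(observed_complex_rate * n_divisions))
            test = binomial_independence_test(k, n_divisions, expected)
            record.update(
                {
                    "observed_rate_per_division": observed_complex_rate,
                    "n_divisions": n_divisions,
                    **test.to_record(),
                }
            )
        panel.append(record)
    else:
        panel.append(
            {"item": "independence test", "status": "unavailable",
             "reason": "needs segmental and CL rates"}
        )

    if pfge_fractions and len(pfge_fractions) >= 2:
        groups = list(pfge_fractions.items())
        reference_name, reference = groups[0]
        raw_results = []
        for name, values in groups[1:]:
            test_fn = mann_whitney if pfge_test == "mann-whitney" else welch_t_test
            raw_results.append((name, test_fn(reference, list(values))))
        adjusted = _adjust([r.p_value for _, r in raw_results], config.correction)
        for (name, result), p_adj in zip(raw_results, adjusted):
            record = result.to_record()
            record["p_adjusted"] = p_adj
            panel.append(
                {"item": f"PFGE chrII fraction {reference_name} vs {name}", **record}
            )

    bundle.test_panel = panel
    return bundle


def _adjust(p_values: list[float], correction: str) -> list[Optional[float]]:
    if not p_values:
        return []
    if correction == "holm":
        return list(holm_bonferroni(p_values))
    if correction == "bonferroni":
        return [min(1.0, p * len(p_values)) for p in p_values]
    return [None] * len(p_values)


def run_simulation_study(
    config: AnalysisConfig,
    rate_grid: Sequence[EventRates],
    culture_configs: Sequence[CultureConfig],
    n_cultures: int = 24,
    n_replicates: int = 10,
    true_rates_attr: str = "chromosome_loss",
) -> pd.DataFrame:
    """Estimator-validation harness over a grid of rates × culture designs.

    For each grid point, repeated assays are simulated and re-estimated; the
    report records relative bias of the median-rate estimate, empirical CI
    coverage against the achieved order-statistic level, and the fraction of
    replicates whose estimate falls within 30% of truth.  Infeasible points
    (total rate too high for the growth model) are skipped and logged.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    rows = []
    for rates in rate_grid:
        for culture_config in culture_configs:
            truth = getattr(rates, true_rates_attr)
            if rates.total >= 0.1:
                rows.append(
                    {"true_rate": truth, "n_final": culture_config.n_final,
                     "status": "skipped: total rate too high"}
                )
                continue
            child_seeds = seed_seq.spawn(n_replicates)
            estimates, covered, within = [], 0, 0
            # the coverage target is the long-run median of per-culture rates,
            # estimated once from a large reference assay
            reference = simulate_assay(
                rates, culture_config, max(2000, 50 * n_cultures),
                seed=int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31)),
            )
            reference_table = class_rate_table(
                reference, level=config.confidence, estimator=config.estimator,
                include_total=False, include_non_cl=False,
            )
            label = {
                "chromosome_loss": LOHClass.CHROMOSOME_LOSS.value,
                "gene_conversion": LOHClass.GENE_CONVERSION.value,
                "segmental": LOHClass.SEGMENTAL.value,
                "complex_event": LOHClass.COMPLEX.value,
            }[true_rates_attr]
            target_median = float(
                np.median(reference_table[label].per_culture_rates)
            )
            achieved_levels = []
            for child in child_seeds:
                assay_seed = int(child.generate_state(1)[0] % (2**31))
                cultures = simulate_assay(
                    rates, culture_config, n_cultures, seed=assay_seed
                )
                table = class_rate_table(
                    cultures, level=config.confidence, estimator=config.estimator,
                    include_total=False, include_non_cl=False,
                )
                estimate = table[label]
                estimates.append(estimate.median_rate)
                if truth > 0 and abs(estimate.median_rate - truth) <= 0.3 * truth:
                    within += 1
                if estimate.ci_lower is not None and estimate.ci_upper is not None:
                    if estimate.ci_lower <= target_median <= estimate.ci_upper:
                        covered += 1
                    achieved_levels.append(estimate.achieved_level)
            rows.append(
                {
                    "true_rate": truth,
                    "n_final": culture_config.n_final,
                    "n_cultures": n_cultures,
                    "n_replicates": n_replicates,
                    "median_estimate": float(np.median(estimates)),
                    "relative_bias": (
                        float(np.median(estimates) / truth - 1.0) if truth else np.nan
                    ),
                    "fraction_within_30pct": within / n_replicates,
                    "ci_coverage": covered / n_replicates,
                    "achieved_level": (
                        float(np.mean(achieved_levels)) if achieved_levels else np.nan
                    ),
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)
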