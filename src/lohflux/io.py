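"""Tabular and config I/O.

All tables are tab-delimited UTF-8 with a header row and ``NA`` for missing
values.  Phenotype tables carry one colony per row; culture tables carry one
fluctuation culture per row.  Event-rate and analysis configs are JSON (or
YAML for the analysis config).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .markers import Call, ColonyPhenotype, ComplexSubclass, Zygosity
from .simulate import CultureConfig, CultureResult, EventRates

__all__ = [
    "PHENOTYPE_COLUMNS",
    "CULTURE_COLUMNS",
    "phenotype_to_row",
    "row_to_phenotype",
    "write_phenotype_table",
    "read_phenotype_table",
    "write_culture_table",
    "read_culture_table",
    "read_event_rates",
    "write_event_rates",
    "read_analysis_config",
]

PHENOTYPE_COLUMNS = [
    "culture_id", "colony_id", "genotype",
    "foa", "nat", "hyg", "trp",
    "nat_zyg", "trp1_zyg", "tyr1_alleles",
]

CULTURE_COLUMNS = [
    "culture_id", "genotype", "n0", "cells_plated_total_medium",
    "dilution_total", "colonies_total_medium", "colonies_5foa", "dilution_5foa",
]


def _fmt_call(call: Call) -> str:
    return call.value


def _fmt_zyg(zyg: Zygosity) -> str:
    return zyg.value


def phenotype_to_row(
    pheno: ColonyPhenotype,
    culture_id: str,
    colony_id: str,
    genotype: str = "NA",
) -> dict:
    return {
        "culture_id": culture_id,
        "colony_id": colony_id,
        "genotype": genotype,
        "foa": _fmt_call(pheno.foa_resistant),
        "nat": _fmt_call(pheno.nat_resistant),
        "hyg": _fmt_call(pheno.hyg_resistant),
        "trp": _fmt_call(pheno.trp_prototroph),
        "nat_zyg": _fmt_zyg(pheno.nat_zygosity),
        "trp1_zyg": _fmt_zyg(pheno.trp1_zygosity),
        "tyr1_alleles": pheno.tyr1_alleles or "NA",
    }


def row_to_phenotype(row) -> ColonyPhenotype:
    tyr1 = str(row.get("tyr1_alleles", "NA")).strip()
    return ColonyPhenotype(
        foa_resistant=Call.parse(row["foa"]),
        nat_resistant=Call.parse(row["nat"]),
        hyg_resistant=Call.parse(row["hyg"]),
        trp_prototroph=Call.parse(row["trp"]),
        nat_zygosity=Zygosity.parse(row.get("nat_zyg", "NA")),
        trp1_zygosity=Zygosity.parse(row.get("trp1_zyg", "NA")),
        tyr1_alleles=None if tyr1.lower() in ("na", "nan", "") else tyr1,
    )


def write_phenotype_table(
    phenotypes: Sequence[ColonyPhenotype],
    path: str | Path,
    culture_ids: Optional[Sequence[str]] = None,
    genotype: str = "NA",
) -> pd.DataFrame:
    """Write colony phenotypes as a TSV; one mini-culture per colony by default."""
    rows = []
    for idx, pheno in enumerate(phenotypes):
        culture_id = culture_ids[idx] if culture_ids is not None else f"mc{idx + 1}"
        rows.append(phenotype_to_row(pheno, culture_id, f"c{idx + 1}", genotype))
    frame = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"foa", "nat", "hyg", "trp"} - set(frame.columns)
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {sorted(missing)}")
    return frame


def write_culture_table(
    cultures: Sequence[CultureResult],
    path: str | Path,
    genotype: str = "NA",
) -> pd.DataFrame:
    """Write fluctuation cultures, one row per culture plus per-class counts."""
    class_labels: list[str] = []
    for culture in cultures:
        for label in culture.resistant_by_class:
            if label not in class_labels:
                class_labels.append(label)
    rows = []
    for idx, culture in enumerate(cultures):
        row = {
            "culture_id": f"f{idx + 1}",
            "genotype": genotype,
            "n0": culture.n0,
            "cells_plated_total_medium": culture.n_final,
            "dilution_total": 1.0,
            "colonies_total_medium": culture.n_final,
            "colonies_5foa": culture.total_resistant,
            "dilution_5foa": culture.dilution * culture.plating_efficiency,
        }
        for label in class_labels:
            row[f"r_{label}"] = culture.resistant_by_class.get(label, 0)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_culture_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = {"culture_id", "colonies_5foa"} - set(frame.columns)
    if missing:
        raise ValueError(f"culture table lacks required columns: {sorted(missing)}")
    return frame


def culture_results_from_table(frame: pd.DataFrame) -> list[CultureResult]:
    """Rebuild CultureResult records from a culture TSV.

    The viable population is ``colonies_total_medium / dilution_total``; the
    per-class resistant counts come from ``r_<CLASS>`` columns (falling back
    to a single TOTAL-like class from ``colonies_5foa``).
    """
    class_columns = [c for c in frame.columns if c.startswith("r_")]
    results = []
    for _, row in frame.iterrows():
        n_final = int(round(row["colonies_total_medium"] / row["dilution_total"]))
        n0 = int(row["n0"]) if "n0" in frame.columns and pd.notna(row.get("n0")) else 1
        if class_columns:
            counts = {c[2:]: int(row[c]) for c in class_columns}
        else:
            counts = {"ALL": int(row["colonies_5foa"])}
        results.append(
            CultureResult(
                n0=n0,
                n_final=n_final,
                generations=0,
                resistant_by_class=counts,
                resistant_pre_dilution=counts,
                event_log=(),
                dilution=float(row.get("dilution_5foa", 1.0)),
                plating_efficiency=1.0,
            )
        )
    return results


def read_event_rates(path: str | Path) -> EventRates:
    payload = json.loads(Path(path).read_text())
    subclass_probs = payload.get("complex_subclass_probs")
    kwargs = {
        key: float(payload.get(key, 0.0))
        for key in (
            "chromosome_loss", "gene_conversion", "segmental",
            "complex_event", "point_mutation",
        )
    }
    if subclass_probs is not None:
        kwargs["complex_subclass_probs"] = {
            ComplexSubclass[name]: float(p) for name, p in subclass_probs.items()
        }
    return EventRates(**kwargs)


def write_event_rates(rates: EventRates, path: str | Path) -> None:
    payload = {
        "chromosome_loss": rates.chromosome_loss,
        "gene_conversion": rates.gene_conversion,
        "segmental": rates.segmental,
        "complex_event": rates.complex_event,
        "point_mutation": rates.point_mutation,
        "complex_subclass_probs": {
            sub.name: p for sub, p in rates.complex_subclass_probs.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_culture_config(payload: dict) -> CultureConfig:
    return CultureConfig(
        n0=int(payload.get("n0", 1000)),
        n_final=int(payload.get("n_final", 1_000_000)),
        dilution=float(payload.get("dilution", 1.0)),
        plating_efficiency=float(payload.get("plating_efficiency", 1.0)),
        relative_fitness=float(payload.get("relative_fitness", 1.0)),
    )


def read_analysis_config(path: str | Path) -> dict:
    """Load a YAML or JSON analysis config into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
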