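"""End-to-end pipeline: curated tables in, multi-section report out.

``run_pipeline`` wires the modules together over the bundled (or
user-supplied) tables: parse and classify the reported mutation lineage,
annotate it against the gene model, run the predictor consensus over the
database candidates, aggregate allele frequencies into carrier estimates,
classify substitution chemistry and pool the patient cohort.  Every
number in the report is recomputed from the inputs; checks against the
values printed in the curated source literature land in the discrepancy
log rather than being reconciled silently.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .chemistry import load_category_table, stability_summary
from .consensus import Thresholds, load_score_table, run_consensus
from .frequency import (FrequencyRecord, carrier_frequency, cumulative_af,
                        format_one_in_n, one_in_n, rank_by_af,
                        read_frequency_table, resolve_duplicates)
from .gene_model import GeneModel, domain_fraction, exon_hotspots, load_gene_model
from .phenotype import (cohort_stats, load_patient_table, pool_outcomes,
                        region_stage_association)
from .variants import (consequence_tally, curated_label_conflicts,
                       load_variant_table)


class PipelineError(RuntimeError):
    pass


_DATA = ("variants_reported", "database_variants", "predictor_scores",
         "frequencies_reported", "frequencies_database", "patients")


@dataclass
class PipelineConfig:
    """Input locations; every entry defaults to the bundled curated tables."""

    gene_model: Optional[str] = None
    thresholds: Optional[str] = None
    aa_categories: Optional[str] = None
    variants_reported: Optional[str] = None
    database_variants: Optional[str] = None
    predictor_scores: Optional[str] = None
    frequencies_reported: Optional[str] = None
    frequencies_database: Optional[str] = None
    patients: Optional[str] = None
    carrier_model: str = "paper_convention"
    seed: Optional[int] = None

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PipelineConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**cfg)

    def resolve(self, name: str) -> Path:
        override = getattr(self, name, None)
        if override is not None:
            p = Path(override)
            if not p.exists():
                raise FileNotFoundError(f"input file not found: {p}")
            return p
        return Path(str(resources.files("patlas.data").joinpath(f"{name}.tsv")))


@dataclass
class ReportBundle:
    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    discrepancy_log: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {"sections": _jsonable(self.sections),
                   "discrepancy_log": self.discrepancy_log,
                   "provenance": self.provenance}
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, out_dir: str | Path, fmt: str = "json") -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        if fmt in ("json", "both"):
            p = out / "report.json"
            p.write_text(self.to_json())
            written.append(p)
        if fmt in ("tsv", "both"):
            for name in ("exon_hotspots", "top_frequencies", "transition_matrix",
                         "region_stage"):
                obj = self.sections.get(name)
                if isinstance(obj, pd.DataFrame):
                    p = out / f"{name}.tsv"
                    obj.to_csv(p, sep="\t", index=name in
                               ("transition_matrix", "region_stage"))
                    written.append(p)
        return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj, key=str) if True] \
            if isinstance(obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.reset_index().to_dict(orient="records")
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_reference_values() -> dict:
    with resources.files("patlas.data").joinpath(
            "source_reported_values.yaml").open() as fh:
        return yaml.safe_load(fh)


def run_pipeline(config_path: str | Path | None = None,
                 config: Optional[PipelineConfig] = None) -> ReportBundle:
    """Execute every stage over the configured inputs and build the report."""
    cfg = config or PipelineConfig.load(config_path)
    model = load_gene_model(cfg.gene_model)
    thresholds = Thresholds.load(cfg.thresholds)
    categories = load_category_table(cfg.aa_categories)
    ref = _load_reference_values()

    reported = load_variant_table(cfg.resolve("variants_reported"))
    database = load_variant_table(cfg.resolve("database_variants"))
    scores = load_score_table(cfg.resolve("predictor_scores"))
    freq_reported = read_frequency_table(cfg.resolve("frequencies_reported"))
    freq_database = read_frequency_table(cfg.resolve("frequencies_database"))
    patients = load_patient_table(cfg.resolve("patients"))

    bundle = ReportBundle()
    log = bundle.discrepancy_log

    # --- mutation lineage ---------------------------------------------------
    tally = consequence_tally(reported)
    for conflict in curated_label_conflicts(reported):
        log.append({"check": "curated_consequence_conflict", **conflict})

    domain_dist = {name: domain_fraction(reported, name, model)
                   for name in list(model.domains) + ["helical",
                                                      "non_helical_or_intron"]}
    hotspots = exon_hotspots(reported, model)

    ref_dom = ref.get("domain_percent", {})
    if "pat1_alternative" in ref_dom and \
            domain_dist["PAT1"]["percent"] != ref_dom["pat1_alternative"]:
        log.append({"check": "pat1_percent_alternative_source_value",
                    "computed": domain_dist["PAT1"]["percent"],
                    "source_alternative": ref_dom["pat1_alternative"]})

    # --- consensus over database candidates ---------------------------------
    results = run_consensus(database, scores, model, thresholds)
    status_of = {r.variant_id: r for r in results}
    predicted = sorted(r.variant_id for r in results
                       if r.status == "predicted_pathogenic")
    auto = sorted(r.variant_id for r in results if r.status == "auto_pathogenic")
    insufficient = sorted(r.variant_id for r in results if r.insufficient_evidence)

    # --- frequencies --------------------------------------------------------
    freq_reported = resolve_duplicates(freq_reported)
    snp_set = [r for r in freq_reported if r.subset == "reported_snp"]
    del13 = [r for r in freq_reported if r.subset == "recurrent_deletion"]
    cum_reported = cumulative_af(snp_set)

    db_missense = [r for r in resolve_duplicates(freq_database)
                   if r.subset == "database_missense"
                   and r.variant_id in set(predicted)]
    db_nonsense = [r for r in resolve_duplicates(freq_database)
                   if r.subset == "database_nonsense"]
    cum_db_missense = cumulative_af(db_missense)
    cum_db_nonsense = cumulative_af(db_nonsense)
    cum_total = cum_reported + cum_db_missense + cum_db_nonsense
    carrier = carrier_frequency(cum_total, cfg.carrier_model)

    headline = ref.get("carrier", {}).get("headline_per_mille")
    if headline is not None and round(cum_total * 1000, 2) != headline:
        log.append({"check": "carrier_component_sum_vs_headline",
                    "computed_per_mille": round(cum_total * 1000, 4),
                    "source_headline_per_mille": headline,
                    "source_headline_one_in_n":
                        ref["carrier"].get("headline_one_in_n")})

    # --- chemistry ----------------------------------------------------------
    chem = stability_summary(reported, categories)
    for conflict in ref.get("transition_label_conflicts", []):
        log.append({"check": "transition_label_conflict", **conflict})

    # --- phenotype ----------------------------------------------------------
    spectrum = pool_outcomes(patients)
    stats = cohort_stats(patients)
    link_records = reported
    assoc = region_stage_association(patients, link_records, model)

    ref_cohort = ref.get("cohort", {})
    mean_cycles = float(stats.loc["cycles", "mean"])
    if ref_cohort.get("mean_cycles") is not None and \
            mean_cycles != ref_cohort["mean_cycles"]:
        log.append({"check": "mean_cycles_vs_source", "computed": mean_cycles,
                    "source": ref_cohort["mean_cycles"]})
    sd_cycles = float(stats.loc["cycles", "sd"])
    if ref_cohort.get("sd_cycles") is not None and sd_cycles != ref_cohort["sd_cycles"]:
        log.append({"check": "sd_cycles_vs_source", "computed": sd_cycles,
                    "source": ref_cohort["sd_cycles"]})
    alt = ref.get("stage_percent_alternative", {})
    for stage, key in (("pb1", "pb1"), ("empty_atretic", "empty_atretic")):
        if key in alt and spectrum.percents[stage] != alt[key]:
            log.append({"check": f"stage_percent_alternative_{stage}",
                        "computed": spectrum.percents[stage],
                        "source_alternative": alt[key]})

    # --- union of the mutation sets -----------------------------------------
    reported_ids = {r.variant_id for r in reported}
    union = reported_ids | set(predicted) | set(auto)
    if reported_ids & (set(predicted) | set(auto)):
        log.append({"check": "reported_database_overlap",
                    "overlap": sorted(reported_ids & (set(predicted) | set(auto)))})

    bundle.sections = {
        "consequence_tally": tally,
        "n_reported_sites": len(reported),
        "domain_distribution": domain_dist,
        "exon_hotspots": hotspots,
        "consensus": {
            "predicted_pathogenic": predicted,
            "n_predicted_pathogenic": len(predicted),
            "auto_pathogenic_nonsense": auto,
            "n_auto_pathogenic": len(auto),
            "insufficient_evidence": insufficient,
            "votes": {r.variant_id: r.votes for r in results},
        },
        "frequency_estimates": {
            "cumulative_af_reported": cum_reported,
            "cumulative_af_reported_per_100k": round(cum_reported * 1e5, 2),
            "one_in_n_reported": one_in_n(cum_reported),
            "cumulative_af_database_missense": cum_db_missense,
            "cumulative_af_database_missense_per_100k":
                round(cum_db_missense * 1e5, 2),
            "cumulative_af_database_nonsense": cum_db_nonsense,
            "cumulative_af_database_nonsense_per_100k":
                round(cum_db_nonsense * 1e5, 2),
            "cumulative_af_total": cum_total,
            "carrier_model": carrier.model,
            "carrier_frequency": carrier.carrier_frequency,
            "carrier_per_mille": round(carrier.carrier_frequency * 1000, 2),
            "carrier_one_in_n": carrier.one_in_n,
            "carrier_one_in_n_formatted": format_one_in_n(carrier.one_in_n),
            "del13_carrier_per_mille":
                round(del13[0].allele_frequency * 1000, 2) if del13 else None,
        },
        "top_frequencies": rank_by_af(snp_set).head(10),
        "transition_matrix": chem["matrix"],
        "transition_flags": chem["flag_totals"],
        "n_missense": chem["n_missense"],
        "phenotype_spectrum": {
            "total_oocytes": spectrum.total_oocytes,
            "counts": spectrum.counts,
            "percents": spectrum.percents,
            "n_patients": spectrum.n_patients,
        },
        "cohort_stats": stats,
        "region_stage": assoc["table"],
        "region_stage_double_counted": assoc["double_counted"],
        "mutation_union": {
            "n_reported": len(reported_ids),
            "n_database_predicted": len(predicted),
            "n_database_nonsense": len(auto),
            "n_total": len(union),
        },
    }
    bundle.provenance = {
        "tool_version": __version__,
        "carrier_model": cfg.carrier_model,
        "seed": cfg.seed,
        "input_digests": {name: _digest(cfg.resolve(name)) for name in _DATA},
    }
    return bundle
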