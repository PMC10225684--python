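"""Synthetic cohorts, rare-variant frequency extracts and predictor scores.

The generators emulate the statistical structure the analysis assumes: a
pooled oocyte-stage multinomial (defaults are the pooled clinical
proportions 53.81 / 9.22 / 14.72 / 22.25 %), log-uniform rare-variant
allele frequencies down to the 1-in-150,000 scale, and per-tool predictor
scores whose thresholded votes recover a configured pathogenic fraction.

One integer seed drives everything: per-generator substreams are spawned
deterministically from it, so adding one generator never perturbs the
draws of another.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import SCORED_TOOLS, Thresholds
from .frequency import FrequencyRecord
from .phenotype import STAGES, PatientOutcome

#: substream labels in fixed spawn order
_STREAMS = ("patients", "frequencies", "scores")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_patients: int = 34
    n_variants: int = 50
    stage_probabilities: tuple[float, float, float, float] = (0.5381, 0.0922,
                                                              0.1472, 0.2225)
    af_log10_range: tuple[float, float] = (-6.0, -2.3)
    allele_number: int = 250000
    mean_cycles: float = 2.47
    oocytes_per_cycle: float = 11.24
    fraction_pathogenic: float = 0.5
    exceedance: float = 0.9     # P(score beyond threshold | pathogenic label)

    def __post_init__(self) -> None:
        if abs(sum(self.stage_probabilities) - 1.0) > 1e-9:
            raise ValueError("stage probabilities must sum to 1")
        if any(p < 0 for p in self.stage_probabilities):
            raise ValueError("stage probabilities must be non-negative")
        lo, hi = self.af_log10_range
        if lo > hi:
            raise ValueError("af_log10_range must be ordered")

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])


def gen_patients(cfg: GeneratorConfig) -> list[PatientOutcome]:
    """Cohort with multinomial stage splits; identical under identical seed."""
    rng = cfg.rng("patients")
    out = []
    for i in range(cfg.n_patients):
        cycles = 1 + rng.poisson(max(cfg.mean_cycles - 1.0, 0.0))
        total = rng.poisson(cycles * cfg.oocytes_per_cycle)
        stage_counts = rng.multinomial(total, cfg.stage_probabilities)
        out.append(PatientOutcome(
            patient_id=f"S{i + 1:03d}",
            age=float(np.clip(round(rng.normal(31.4, 4.3), 1), 20, 45)),
            infertility_years=float(np.clip(round(rng.normal(7.0, 3.0), 1), 0.5, 20)),
            cycles=int(cycles),
            oocytes=dict(zip(STAGES, (int(c) for c in stage_counts)))))
    return out


def gen_frequencies(cfg: GeneratorConfig) -> list[FrequencyRecord]:
    """Rare-variant sites with log-uniform AF; AC/AN made integer-consistent."""
    rng = cfg.rng("frequencies")
    lo, hi = cfg.af_log10_range
    out = []
    for i in range(cfg.n_variants):
        af = 10.0 ** rng.uniform(lo, hi)
        ac = max(1, int(round(af * cfg.allele_number)))
        out.append(FrequencyRecord(
            variant_id=f"sim{i + 1:04d}",
            allele_frequency=ac / cfg.allele_number,
            allele_count=ac, allele_number=cfg.allele_number,
            source_db="synthetic", subset="simulated"))
    return out


def gen_truth_labels(cfg: GeneratorConfig) -> pd.Series:
    """Bernoulli pathogenic/benign truth per simulated variant."""
    rng = cfg.rng("scores")
    labels = rng.random(cfg.n_variants) < cfg.fraction_pathogenic
    return pd.Series(labels, index=[f"sim{i + 1:04d}" for i in range(cfg.n_variants)],
                     name="pathogenic")


def gen_predictor_scores(cfg: GeneratorConfig, truth_labels: pd.Series,
                         thresholds: Optional[Thresholds] = None) -> pd.DataFrame:
    """Scores whose votes land beyond each tool's cutoff with the configured
    exceedance probability for pathogenic-labelled variants, and below it
    otherwise."""
    thresholds = thresholds or Thresholds.load()
    rng = cfg.rng("scores")
    rng.random(cfg.n_variants)  # skip the label draw to decouple scores
    rows = []
    for vid, is_path in truth_labels.items():
        row = {"variant_id": vid}
        for tool in SCORED_TOOLS:
            cutoff, direction = thresholds.cutoffs[tool]
            beyond = rng.random() < (cfg.exceedance if is_path
                                     else 1.0 - cfg.exceedance)
            u = rng.random()
            if direction == "le":
                score = u * cutoff if beyond else cutoff + u * (1.0 - cutoff)
            else:
                span = max(cutoff, 1.0)
                score = cutoff + u * span if beyond else u * cutoff
            row[tool] = round(float(score), 4)
        rows.append(row)
    return pd.DataFrame(rows)
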