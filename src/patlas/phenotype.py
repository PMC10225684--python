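"""Pooling of per-patient ART outcomes into the oocyte stage spectrum.

Oocytes are counted in four bins: germinal-vesicle arrested (GV),
metaphase-I arrested (MI), first-polar-body / mature (PB1), and
empty-follicle or atretic.  ``max_stage`` ranks a patient's most advanced
oocyte under the developmental order empty < GV < MI < PB1 (the order is
an argument; empty follicles are treated as least advanced by default).
Oocytes-per-cycle is a ratio of totals, not a mean of per-patient ratios.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel, assign_region
from .variants import VariantRecord

STAGES = ("gv", "mi", "pb1", "empty_atretic")
#: default developmental order, least to most advanced
STAGE_ORDER = ("empty_atretic", "gv", "mi", "pb1")


class PhenotypeError(ValueError):
    pass


@dataclass
class PatientOutcome:
    patient_id: str
    age: float
    infertility_years: float
    cycles: int
    oocytes: dict[str, int]         # stage -> count
    variants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for stage in STAGES:
            if self.oocytes.get(stage, 0) < 0:
                raise PhenotypeError(f"{self.patient_id}: negative {stage} count")

    @property
    def total_oocytes(self) -> int:
        return sum(self.oocytes.get(s, 0) for s in STAGES)


@dataclass
class SpectrumSummary:
    total_oocytes: int
    counts: dict[str, int]
    percents: dict[str, float]
    n_patients: int


def load_patient_table(path: str | Path) -> list[PatientOutcome]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    required = {"patient_id", "age", "infertility_years", "cycles", *STAGES}
    missing = required - set(df.columns)
    if missing:
        raise PhenotypeError(f"{path}: missing column(s) {sorted(missing)}")
    return [PatientOutcome(
        patient_id=str(r.patient_id), age=float(r.age),
        infertility_years=float(r.infertility_years), cycles=int(r.cycles),
        oocytes={s: int(getattr(r, s)) for s in STAGES})
        for r in df.itertuples(index=False)]


def pool_outcomes(patients: Sequence[PatientOutcome]) -> SpectrumSummary:
    """Pooled stage counts and percentages (2 decimals) across a cohort."""
    if not patients:
        raise PhenotypeError("cannot pool an empty cohort")
    counts = {s: sum(p.oocytes.get(s, 0) for p in patients) for s in STAGES}
    total = sum(counts.values())
    if total == 0:
        raise PhenotypeError("cohort has zero oocytes; percentages undefined")
    percents = {s: round(100.0 * counts[s] / total, 2) for s in STAGES}
    return SpectrumSummary(total_oocytes=total, counts=counts,
                           percents=percents, n_patients=len(patients))


def cohort_stats(patients: Sequence[PatientOutcome]) -> pd.DataFrame:
    """Mean and sample SD per cohort field; oocytes/cycle as ratio of totals."""
    if not patients:
        raise PhenotypeError("cannot summarize an empty cohort")
    fields = {
        "age": [p.age for p in patients],
        "infertility_years": [p.infertility_years for p in patients],
        "cycles": [float(p.cycles) for p in patients],
        "oocytes_total": [float(p.total_oocytes) for p in patients],
    }
    rows = []
    for name, values in fields.items():
        arr = np.array([v for v in values if not np.isnan(v)], dtype=float)
        if arr.size == 0:
            warnings.warn(f"cohort field {name!r} entirely missing; omitted",
                          stacklevel=2)
            continue
        sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
        rows.append({"field": name, "n": int(arr.size),
                     "mean": round(float(arr.mean()), 2),
                     "sd": round(sd, 2) if arr.size > 1 else None})
    total_oocytes = sum(p.total_oocytes for p in patients)
    total_cycles = sum(p.cycles for p in patients)
    per_cycle = [p.total_oocytes / p.cycles for p in patients if p.cycles > 0]
    rows.append({"field": "oocytes_per_cycle", "n": len(patients),
                 "mean": round(total_oocytes / total_cycles, 2),
                 "sd": round(float(np.std(per_cycle, ddof=1)), 2)
                 if len(per_cycle) > 1 else None})
    return pd.DataFrame(rows).set_index("field")


def max_stage(p: PatientOutcome, order: Sequence[str] = STAGE_ORDER) -> str:
    """Most advanced stage with a nonzero count, under ``order``."""
    if p.total_oocytes == 0:
        raise PhenotypeError(f"{p.patient_id}: no oocytes, max stage undefined")
    best = None
    for stage in order:
        if p.oocytes.get(stage, 0) > 0:
            best = stage
    return best


#: default residue buckets for genotype-phenotype cross-tabulation
REGION_BUCKETS = (("pre_p217", 1, 216), ("p217_341", 217, 341),
                  ("p342_446", 342, 446), ("post_p446", 447, 543))


def region_stage_association(patients: Sequence[PatientOutcome],
                             records: Sequence[VariantRecord],
                             model: GeneModel,
                             buckets: Sequence[tuple[str, int, int]] = REGION_BUCKETS,
                             order: Sequence[str] = STAGE_ORDER) -> dict:
    """Contingency table: residue-region bucket x most advanced stage.

    A compound-heterozygous patient is counted once in every bucket one of
    their variants falls in; patients hitting more than one bucket are
    listed in ``double_counted``.  Patients with no resolvable variant are
    excluded with a warning.
    """
    by_patient: dict[str, set[str]] = {}
    for rec in records:
        a = assign_region(rec, model)
        for pid in rec.patients:
            for name, lo, hi in buckets:
                if any(lo <= r <= hi for r in a.residues):
                    by_patient.setdefault(pid, set()).add(name)
    table = pd.DataFrame(0, index=[b[0] for b in buckets], columns=list(order))
    double_counted, excluded = [], []
    for p in patients:
        regions = by_patient.get(p.patient_id)
        if not regions:
            excluded.append(p.patient_id)
            continue
        if len(regions) > 1:
            double_counted.append(p.patient_id)
        stage = max_stage(p, order)
        for name in regions:
            table.loc[name, stage] += 1
    if excluded:
        warnings.warn(f"patients without variant links excluded: {excluded}",
                      stacklevel=2)
    return {"table": table, "double_counted": sorted(double_counted),
            "excluded": sorted(excluded)}
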