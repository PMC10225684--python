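"""Variant records: curated table I/O and consequence classification.

A :class:`VariantRecord` is one mutation site with its zygosity
observations across patients.  Consequence labels follow the priority
nonsense > splice > deletion > missense: a premature stop wins regardless
of other features, canonical-intron changes (offset magnitude <= 20) are
splice candidates, and deletions without a stated protein product stay
"deletion" rather than "frameshift".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .hgvs import CdnaVariant, HgvsParseError, ProteinVariant, parse_cdna, parse_protein

#: canonical splice-candidate window (intron-offset magnitude, bases)
SPLICE_WINDOW = 20

CONSEQUENCES = ("missense", "nonsense", "splice", "deletion")

ZYGOSITY_STATES = ("homozygous", "heterozygous", "compound_het_partner")


@dataclass
class ZygosityObservation:
    patient_id: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in ZYGOSITY_STATES:
            raise ValueError(f"unknown zygosity state {self.state!r}")


@dataclass
class VariantRecord:
    """One curated mutation site (cDNA and/or protein notation)."""

    variant_id: str
    cdna: Optional[CdnaVariant] = None
    protein: Optional[ProteinVariant] = None
    consequence: Optional[str] = None
    curated_consequence: Optional[str] = None
    zygosity_observations: list[ZygosityObservation] = field(default_factory=list)
    source: str = "reported_clinical"

    def __post_init__(self) -> None:
        if self.cdna is None and self.protein is None:
            raise ValueError(f"{self.variant_id}: need at least one of cdna/protein")

    @property
    def patients(self) -> list[str]:
        return [o.patient_id for o in self.zygosity_observations]


def classify_consequence(record: VariantRecord) -> str:
    """Assign exactly one consequence label (see module docstring for priority)."""
    c, p = record.cdna, record.protein
    if p is not None and p.kind == "nonsense":
        label = "nonsense"
    elif c is not None and c.kind == "substitution" and c.is_intronic \
            and abs(c.intron_offset) <= SPLICE_WINDOW:
        label = "splice"
    elif c is not None and c.kind == "range_deletion" and _spans_junction(c):
        label = "splice"
    elif c is not None and c.kind in ("deletion", "range_deletion"):
        label = "deletion"
    elif p is not None and p.kind == "missense":
        label = "missense"
    elif p is not None and p.kind == "synonymous":
        label = "synonymous"
    else:
        warnings.warn(f"{record.variant_id}: unclassifiable variant", stacklevel=2)
        label = "unknown"
    record.consequence = label
    return label


def _spans_junction(c: CdnaVariant) -> bool:
    """True when a range deletion has one intronic and one exonic endpoint."""
    return (c.intron_offset is None) != (c.end_offset is None)


def consequence_tally(records: list[VariantRecord]) -> dict[str, int]:
    """Counts per consequence label over a record set (typed labels only)."""
    tally = {k: 0 for k in CONSEQUENCES}
    for r in records:
        label = r.consequence or classify_consequence(r)
        if label in tally:
            tally[label] += 1
    return tally


def load_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read the long-format curated variant TSV (one row per observation).

    Columns: variant_id, cdna, protein, consequence (optional curated
    label), zygosity, patient_id, source; "." marks missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    required = {"variant_id", "cdna", "protein", "zygosity", "patient_id", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    records: dict[str, VariantRecord] = {}
    for row in df.itertuples(index=False):
        vid = row.variant_id
        if vid not in records:
            cdna = parse_cdna(row.cdna) if isinstance(row.cdna, str) and row.cdna else None
            prot = parse_protein(row.protein) if isinstance(row.protein, str) and row.protein else None
            curated = getattr(row, "consequence", None)
            curated = curated if isinstance(curated, str) and curated else None
            records[vid] = VariantRecord(
                variant_id=vid, cdna=cdna, protein=prot,
                curated_consequence=curated, source=row.source,
            )
        if isinstance(row.patient_id, str) and row.patient_id:
            records[vid].zygosity_observations.append(
                ZygosityObservation(row.patient_id, row.zygosity))
    out = list(records.values())
    for r in out:
        classify_consequence(r)
    return out


def curated_label_conflicts(records: list[VariantRecord]) -> list[dict]:
    """Sites whose curated consequence label disagrees with the computed one."""
    hits = []
    for r in records:
        if r.curated_consequence and r.curated_consequence != r.consequence:
            hits.append({
                "variant_id": r.variant_id,
                "curated": r.curated_consequence,
                "computed": r.consequence,
            })
    return hits


def _try_parse(raw: str):
    try:
        return parse_cdna(raw) if raw.startswith("c.") else parse_protein(raw)
    except HgvsParseError:
        return None
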