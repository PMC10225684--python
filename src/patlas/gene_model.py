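"""PATL2 gene model and region annotation.

The model holds the merged coding coordinate system (16 exons), the named
protein domains (PAT1, FUGUE, N-/C-terminal), a curated alpha-helix table
and the conserved residue intervals.  All intervals are 1-based and
inclusive at both ends; a BED-like 0-based half-open export is provided
for interoperability.

Intronic variants are anchored to their nearest coding base, so a splice
change such as c.1225-2A>G maps to the first residue of the exon it
serves; for domain membership this anchor residue is used, while helix and
exon labels for intronic variants are "non-helical" / "intronic".
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .variants import VariantRecord


class GeneModelError(ValueError):
    pass


@dataclass(frozen=True)
class Exon:
    label: str
    cdna_start: int
    cdna_end: int
    prot_start: int
    prot_end: int


@dataclass(frozen=True)
class Interval:
    start: int
    end: int

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class GeneModel:
    protein_length: int
    exons: list[Exon]
    domains: dict[str, Interval]
    helices: dict[str, Interval]
    conserved_regions: list[Interval]
    provenance: str = ""

    def validate(self) -> None:
        for name, iv in self.domains.items():
            if not (1 <= iv.start <= iv.end <= self.protein_length):
                raise GeneModelError(f"domain {name} outside protein: {iv}")
        for name, iv in self.helices.items():
            if iv.start > iv.end:
                raise GeneModelError(f"helix {name} start > end")
            if not (1 <= iv.start <= iv.end <= self.protein_length):
                raise GeneModelError(f"helix {name} outside protein: {iv}")
        prev_end = 0
        for e in self.exons:
            if e.prot_start <= prev_end:
                raise GeneModelError(f"exon {e.label} protein span overlaps previous")
            prev_end = e.prot_end
        prev_c = 0
        for e in self.exons:
            if e.cdna_start != prev_c + 1:
                raise GeneModelError(f"exon {e.label} leaves a coding gap")
            prev_c = e.cdna_end

    # -- coordinate helpers -------------------------------------------------
    def residue_of_cdna(self, position: int) -> int:
        """Residue index encoded by coding base `position` (codon = ceil(pos/3))."""
        if position < 1 or position > self.exons[-1].cdna_end:
            raise GeneModelError(f"coding position {position} outside CDS")
        return min(math.ceil(position / 3), self.protein_length)

    def exon_of_cdna(self, position: int) -> Exon:
        for e in self.exons:
            if e.cdna_start <= position <= e.cdna_end:
                return e
        raise GeneModelError(f"coding position {position} outside exon table")

    def exon_of_residue(self, residue: int) -> Optional[Exon]:
        for e in self.exons:
            if e.prot_start <= residue <= e.prot_end:
                return e
        return None

    def affected_residues(self, record: VariantRecord) -> list[int]:
        """Residues directly altered by a variant.

        Exonic substitutions alter the codon they hit; exonic deletions
        alter every codon they overlap; intronic changes are anchored to
        the flanking coding base.  Protein notation wins when present.
        """
        if record.protein is not None:
            return [record.protein.position]
        c = record.cdna
        if c is None:
            return []
        if c.kind == "substitution" or c.is_intronic:
            return [self.residue_of_cdna(c.position)]
        if c.kind == "deletion":
            return [self.residue_of_cdna(c.position)]
        first = self.residue_of_cdna(c.position)
        last = self.residue_of_cdna(c.end_position or c.position)
        return list(range(first, last + 1))

    def in_conserved_region(self, residue: int) -> bool:
        return any(residue in iv for iv in self.conserved_regions)

    # -- export -------------------------------------------------------------
    def exons_to_bed(self) -> pd.DataFrame:
        """Exon coding spans as BED-like 0-based half-open intervals."""
        return pd.DataFrame(
            {"chrom": "PATL2_CDS",
             "start": [e.cdna_start - 1 for e in self.exons],
             "end": [e.cdna_end for e in self.exons],
             "name": [e.label for e in self.exons]})


@dataclass
class RegionAssignment:
    variant_id: str
    domain_labels: set[str]
    helix_label: str            # helix name or "non-helical"
    exon_label: str             # exon name or "intronic"
    residues: list[int]


def load_gene_model(path: str | Path | None = None) -> GeneModel:
    """Load the gene model from YAML; defaults to the packaged PATL2 model."""
    if path is None:
        with resources.files("patlas.data").joinpath("gene_model.yaml").open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    model = GeneModel(
        protein_length=int(cfg["protein_length"]),
        exons=[Exon(**e) for e in cfg["exons"]],
        domains={k: Interval(v["start"], v["end"]) for k, v in cfg["domains"].items()},
        helices={h["label"]: Interval(h["start"], h["end"]) for h in cfg["helices"]},
        conserved_regions=[Interval(r["start"], r["end"]) for r in cfg["conserved_regions"]],
        provenance=cfg.get("provenance", ""),
    )
    model.validate()
    return model


def assign_region(record: VariantRecord, model: GeneModel) -> RegionAssignment:
    """Map a variant to domains, helix and exon by inclusive interval tests."""
    residues = model.affected_residues(record)
    for r in residues:
        if not (1 <= r <= model.protein_length):
            raise GeneModelError(
                f"{record.variant_id}: residue {r} outside 1..{model.protein_length}")
    domains = {name for name, iv in model.domains.items()
               if any(r in iv for r in residues)}

    intronic = record.cdna is not None and record.cdna.is_intronic
    if intronic:
        helix_label = "non-helical"
        exon_label = "intronic"
    else:
        helix_label = next((name for name, iv in model.helices.items()
                            if any(r in iv for r in residues)), "non-helical")
        if record.cdna is not None:
            exon_label = model.exon_of_cdna(record.cdna.position).label
        else:
            exon = model.exon_of_residue(residues[0])
            exon_label = exon.label if exon else "intronic"
    return RegionAssignment(record.variant_id, domains, helix_label, exon_label, residues)


def domain_fraction(records: list[VariantRecord], region: str,
                    model: GeneModel) -> dict:
    """Count and percentage of variants falling in a named region.

    ``region`` is a domain name, ``"helical"``, or
    ``"non_helical_or_intron"``.  Percentages are 100*count/len(records)
    rounded to 2 decimals.
    """
    if not records:
        raise ValueError("domain_fraction of an empty record set is undefined")
    assignments = [assign_region(r, model) for r in records]
    if region in model.domains:
        count = sum(1 for a in assignments if region in a.domain_labels)
    elif region == "helical":
        count = sum(1 for a in assignments if a.helix_label != "non-helical")
    elif region == "non_helical_or_intron":
        count = sum(1 for a in assignments if a.helix_label == "non-helical")
    else:
        raise GeneModelError(f"unknown region {region!r}")
    return {"count": count, "total": len(records),
            "percent": round(100.0 * count / len(records), 2)}


def exon_hotspots(records: list[VariantRecord], model: GeneModel) -> pd.DataFrame:
    """Ranked exon table: distinct sites, distinct patients, altered-residue %.

    Intronic variants are excluded (they belong to no exon).  Rank is by
    site count then patient count, descending; ties break toward the
    lower-numbered exon.  ``altered_aa_pct`` is distinct altered residues
    within the exon's protein span over the residues it encodes.
    """
    per_exon: dict[str, dict] = {}
    for rec in records:
        a = assign_region(rec, model)
        if a.exon_label == "intronic":
            continue
        slot = per_exon.setdefault(a.exon_label, {"sites": set(), "patients": set(),
                                                  "residues": set()})
        slot["sites"].add(rec.variant_id)
        slot["patients"].update(rec.patients)
        slot["residues"].update(a.residues)
    rows = []
    for e in model.exons:
        if e.label not in per_exon:
            continue
        slot = per_exon[e.label]
        encoded = e.prot_end - e.prot_start + 1
        altered = {r for r in slot["residues"] if e.prot_start <= r <= e.prot_end}
        rows.append({"exon": e.label,
                     "site_count": len(slot["sites"]),
                     "patient_count": len(slot["patients"]),
                     "residues_encoded": encoded,
                     "altered_residues": len(altered),
                     "altered_aa_pct": round(100.0 * len(altered) / encoded, 2),
                     "_order": int(e.label[1:])})
    if not rows:
        return pd.DataFrame(columns=["exon", "site_count", "patient_count",
                                     "residues_encoded", "altered_residues",
                                     "altered_aa_pct"])
    df = pd.DataFrame(rows).sort_values(
        by=["site_count", "patient_count", "_order"],
        ascending=[False, False, True], kind="mergesort").drop(columns="_order")
    return df.reset_index(drop=True)
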