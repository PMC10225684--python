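"""Population allele-frequency aggregation and carrier-frequency estimates.

Cumulative allele frequency is the sum of per-site frequencies over unique
sites (duplicate sites across databases are resolved first, by default to
the source with the larger allele number).  Two carrier models are
offered: the source literature's convention equates carrier frequency with
cumulative allele frequency; the Hardy-Weinberg alternative uses
2p(1-p).  "1 in N" figures are reciprocals rounded to three significant
figures, matching 1/877 from 1.14 per mille and 1/2080 from 48.09 per
100,000.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd


class FrequencyError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyRecord:
    variant_id: str
    allele_frequency: float
    allele_count: Optional[int] = None
    allele_number: Optional[int] = None
    source_db: str = ""
    subset: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise FrequencyError(
                f"{self.variant_id}: allele frequency outside [0,1]")
        if self.allele_count is not None and self.allele_number is not None:
            if not (0 <= self.allele_count <= self.allele_number):
                raise FrequencyError(f"{self.variant_id}: AC outside [0, AN]")
            if abs(self.allele_frequency - self.allele_count / self.allele_number) > 1e-12:
                raise FrequencyError(
                    f"{self.variant_id}: AF inconsistent with AC/AN")


@dataclass(frozen=True)
class CarrierEstimate:
    cumulative_af: float
    carrier_frequency: float
    model: str
    one_in_n: Optional[int]


def _make_record(vid, ac, an, af, source, subset) -> FrequencyRecord:
    ac = int(ac) if ac is not None and not pd.isna(ac) else None
    an = int(an) if an is not None and not pd.isna(an) else None
    if af is None or pd.isna(af):
        if ac is None or an is None:
            raise FrequencyError(f"{vid}: neither AF nor AC/AN given")
        af = ac / an
    return FrequencyRecord(variant_id=str(vid), allele_frequency=float(af),
                           allele_count=ac, allele_number=an,
                           source_db=str(source), subset=str(subset))


def read_frequency_table(path: str | Path) -> list[FrequencyRecord]:
    """TSV with columns variant_id, AC, AN, AF, source_db[, subset]; "." missing."""
    df = pd.read_csv(path, sep="\t", na_values=["."])
    return [_make_record(r.variant_id, getattr(r, "AC", None), getattr(r, "AN", None),
                         getattr(r, "AF", None), getattr(r, "source_db", ""),
                         getattr(r, "subset", ""))
            for r in df.itertuples(index=False)]


def read_frequency_vcf(path: str | Path) -> list[FrequencyRecord]:
    """VCF whose INFO carries AC/AN/AF; the ID column keys the variant."""
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(path)):
        info = dict(v.INFO)
        ac = info.get("AC")
        an = info.get("AN")
        af = info.get("AF")
        out.append(_make_record(v.ID or f"{v.CHROM}:{v.POS}", ac, an, af,
                                info.get("DB", ""), ""))
    return out


def resolve_duplicates(records: Iterable[FrequencyRecord],
                       rule: str = "max_an") -> list[FrequencyRecord]:
    """One record per variant site.

    ``max_an`` keeps the source with the larger allele number (records
    without AN rank lowest only among duplicates that do carry AN; a
    duplicate pair where neither has AN is ambiguous and raises).
    """
    by_site: dict[str, list[FrequencyRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.variant_id, []).append(rec)
    out = []
    for vid, group in by_site.items():
        if len(group) == 1:
            out.append(group[0])
            continue
        if rule != "max_an":
            raise FrequencyError(f"unknown duplicate rule {rule!r}")
        with_an = [g for g in group if g.allele_number is not None]
        if not with_an:
            raise FrequencyError(
                f"duplicate site {vid} cannot be resolved (no allele numbers)")
        out.append(max(with_an, key=lambda g: g.allele_number))
    return out


def cumulative_af(records: Iterable[FrequencyRecord]) -> float:
    """Sum of per-site allele frequencies over unique sites."""
    records = list(records)
    seen: set[str] = set()
    for rec in records:
        if rec.variant_id in seen:
            raise FrequencyError(
                f"duplicate unresolved site {rec.variant_id}; resolve first")
        seen.add(rec.variant_id)
    return float(sum(rec.allele_frequency for rec in records))


def one_in_n(freq: float) -> Optional[int]:
    """Reciprocal rounded to 3 significant figures; None for freq <= 0."""
    if freq <= 0:
        return None
    n = 1.0 / freq
    digits = 2 - int(math.floor(math.log10(n)))
    return int(round(n, digits))


def carrier_frequency(cum_af: float, model: str = "paper_convention") -> CarrierEstimate:
    """Carrier estimate under the source convention or Hardy-Weinberg."""
    if not (0.0 <= cum_af <= 1.0):
        raise FrequencyError(f"cumulative AF outside [0,1]: {cum_af}")
    if model == "paper_convention":
        carrier = cum_af
    elif model == "hardy_weinberg":
        carrier = 2.0 * cum_af * (1.0 - cum_af)
    else:
        raise FrequencyError(f"unknown carrier model {model!r}")
    return CarrierEstimate(cumulative_af=cum_af, carrier_frequency=carrier,
                           model=model, one_in_n=one_in_n(carrier))


def format_one_in_n(n: Optional[int]) -> str:
    return "—" if n is None else f"1/{n}"


def rank_by_af(records: Iterable[FrequencyRecord]) -> pd.DataFrame:
    """Sites ordered by descending frequency; ties by variant_id."""
    rows = [{"variant_id": r.variant_id, "allele_frequency": r.allele_frequency,
             "source_db": r.source_db} for r in records]
    if not rows:
        return pd.DataFrame(columns=["variant_id", "allele_frequency", "source_db"])
    df = pd.DataFrame(rows)
    df = df.sort_values(by=["allele_frequency", "variant_id"],
                        ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)
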