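"""Amino-acid side-chain chemistry of missense substitutions.

Residues fall into four polarity categories (nonpolar, polar uncharged,
polar with positive charge, polar with negative charge).  A substitution
that crosses categories is a candidate structural destabiliser; a few
transitions get extra flags (proline gain, glycine loss, charge gain or
loss, hydrophobic-to-polar).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .hgvs import ProteinVariant
from .variants import VariantRecord

CATEGORIES = ("nonpolar", "polar_uncharged", "polar_positive", "polar_negative")
CHARGED = {"polar_positive", "polar_negative"}

FLAGS = ("proline_gain", "glycine_loss", "charge_gain", "charge_loss",
         "hydrophobic_to_polar")


class ChemistryError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionClass:
    ref_category: str
    alt_category: str
    cross_category: bool
    flags: frozenset[str]


def load_category_table(path: str | Path | None = None) -> dict[str, str]:
    """aa (one-letter) -> category; validates the 20-residue partition."""
    if path is None:
        with resources.files("patlas.data").joinpath("aa_categories.yaml").open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    table: dict[str, str] = {}
    for cat in CATEGORIES:
        for aa in cfg.get(cat, []):
            if aa in table:
                raise ChemistryError(f"{aa} assigned to two categories")
            table[aa] = cat
    if len(table) != 20:
        raise ChemistryError(f"category table covers {len(table)} residues, need 20")
    return table


def categorize(aa: str, table: dict[str, str]) -> str:
    try:
        return table[aa]
    except KeyError:
        raise ChemistryError(f"unknown amino-acid code {aa!r}") from None


def classify_transition(v: ProteinVariant, table: dict[str, str]) -> TransitionClass:
    """Category pair and danger flags for a missense change."""
    if v.kind != "missense":
        raise ChemistryError(f"{v.raw or v.render()}: transition defined only "
                             f"for missense changes, got {v.kind}")
    ref_cat = categorize(v.ref_aa, table)
    alt_cat = categorize(v.alt_aa, table)
    flags = set()
    if v.alt_aa == "P":
        flags.add("proline_gain")
    if v.ref_aa == "G":
        flags.add("glycine_loss")
    if alt_cat in CHARGED and ref_cat not in CHARGED:
        flags.add("charge_gain")
    if ref_cat in CHARGED and alt_cat not in CHARGED:
        flags.add("charge_loss")
    if ref_cat == "nonpolar" and alt_cat != "nonpolar":
        flags.add("hydrophobic_to_polar")
    return TransitionClass(ref_cat, alt_cat, ref_cat != alt_cat, frozenset(flags))


def stability_summary(records: list[VariantRecord],
                      table: dict[str, str]) -> dict:
    """Transition matrix (ref x alt category counts) and flag totals.

    Only missense records enter; cells partition them, so the matrix sum
    equals the missense count.
    """
    matrix = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    flag_totals = {f: 0 for f in FLAGS}
    members: dict[tuple[str, str], list[str]] = {}
    n_missense = 0
    for rec in records:
        if rec.protein is None or rec.protein.kind != "missense":
            continue
        n_missense += 1
        t = classify_transition(rec.protein, table)
        matrix.loc[t.ref_category, t.alt_category] += 1
        members.setdefault((t.ref_category, t.alt_category), []).append(rec.variant_id)
        for f in t.flags:
            flag_totals[f] += 1
    cross = int(matrix.to_numpy().sum() - pd.Series(
        [matrix.loc[c, c] for c in CATEGORIES]).sum())
    return {"matrix": matrix, "flag_totals": flag_totals, "members": members,
            "n_missense": n_missense, "n_cross_category": cross}
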