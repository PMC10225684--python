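"""In-silico pathogenicity consensus.

Each prediction tool casts a pathogenic/benign vote by thresholding its
score (cutoffs live in config, not code); residue conservation votes
pathogenic when the variant falls inside a conserved interval of the gene
model.  A variant is *predicted pathogenic* when at least ``min_votes``
(default 4) distinct tools vote pathogenic.  Nonsense variants bypass the
vote entirely (``auto_pathogenic``): truncating alleles are tallied
separately from predicted missense ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .gene_model import GeneModel
from .variants import VariantRecord

SCORED_TOOLS = ("SIFT", "CADD", "REVEL", "MutationAssessor", "PolyPhen2")
CONSERVATION = "Conservation"

PATHOGENIC, BENIGN, MISSING = "pathogenic", "benign", "missing"


class ConsensusError(ValueError):
    pass


@dataclass
class Thresholds:
    cutoffs: dict[str, tuple[float, str]]   # tool -> (cutoff, "le"|"ge")
    min_votes: int = 4

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Thresholds":
        if path is None:
            with resources.files("patlas.data").joinpath("thresholds.yaml").open() as fh:
                cfg = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                cfg = yaml.safe_load(fh)
        min_votes = int(cfg.pop("min_votes", 4))
        cutoffs = {tool: (float(v["cutoff"]), v["direction"]) for tool, v in cfg.items()}
        return cls(cutoffs=cutoffs, min_votes=min_votes)


@dataclass
class PredictorProfile:
    """Per-tool scores and votes for one variant."""

    variant_id: str
    scores: dict[str, float] = field(default_factory=dict)
    calls: dict[str, str] = field(default_factory=dict)

    @property
    def pathogenic_votes(self) -> int:
        return sum(1 for v in self.calls.values() if v == PATHOGENIC)

    @property
    def tools_scored(self) -> int:
        return len(self.calls)


@dataclass
class ConsensusResult:
    variant_id: str
    status: str                 # predicted_pathogenic | not_labelled | auto_pathogenic
    votes: int
    tools_scored: int
    insufficient_evidence: bool = False


def call_predictor(tool: str, score: float, thresholds: Thresholds) -> str:
    """Deterministic pathogenic/benign vote for one tool's score."""
    if tool not in thresholds.cutoffs:
        raise ConsensusError(f"unknown predictor tool {tool!r}")
    cutoff, direction = thresholds.cutoffs[tool]
    if direction == "le":
        return PATHOGENIC if score <= cutoff else BENIGN
    return PATHOGENIC if score >= cutoff else BENIGN


def build_profiles(scores: pd.DataFrame, records: list[VariantRecord],
                   model: GeneModel, thresholds: Thresholds) -> dict[str, PredictorProfile]:
    """Vote tables for each scored variant; adds the conservation vote."""
    by_id = {r.variant_id: r for r in records}
    profiles: dict[str, PredictorProfile] = {}
    for row in scores.itertuples(index=False):
        vid = row.variant_id
        prof = PredictorProfile(variant_id=vid)
        for tool in SCORED_TOOLS:
            val = getattr(row, tool, None)
            if val is None or (isinstance(val, float) and pd.isna(val)):
                continue
            score = float(val)
            prof.scores[tool] = score
            prof.calls[tool] = call_predictor(tool, score, thresholds)
        rec = by_id.get(vid)
        if rec is not None:
            residues = model.affected_residues(rec)
            if residues:
                conserved = any(model.in_conserved_region(r) for r in residues)
                prof.calls[CONSERVATION] = PATHOGENIC if conserved else BENIGN
        profiles[vid] = prof
    return profiles


def consensus(profile: Optional[PredictorProfile], record: VariantRecord,
              thresholds: Thresholds) -> ConsensusResult:
    """Apply the >=min_votes rule; nonsense records are auto-pathogenic."""
    if record.consequence == "nonsense":
        votes = profile.pathogenic_votes if profile else 0
        return ConsensusResult(record.variant_id, "auto_pathogenic", votes,
                               profile.tools_scored if profile else 0)
    if profile is None:
        raise ConsensusError(f"{record.variant_id}: no predictor profile for a "
                             f"non-nonsense variant")
    if profile.tools_scored < thresholds.min_votes:
        return ConsensusResult(record.variant_id, "not_labelled",
                               profile.pathogenic_votes, profile.tools_scored,
                               insufficient_evidence=True)
    status = ("predicted_pathogenic"
              if profile.pathogenic_votes >= thresholds.min_votes else "not_labelled")
    return ConsensusResult(record.variant_id, status, profile.pathogenic_votes,
                           profile.tools_scored)


def load_score_table(path: str | Path | None = None) -> pd.DataFrame:
    if path is None:
        path = resources.files("patlas.data").joinpath("predictor_scores.tsv")
    return pd.read_csv(path, sep="\t", na_values=["."])


def run_consensus(records: list[VariantRecord], scores: pd.DataFrame,
                  model: GeneModel, thresholds: Thresholds) -> list[ConsensusResult]:
    profiles = build_profiles(scores, records, model, thresholds)
    return [consensus(profiles.get(r.variant_id), r, thresholds) for r in records]
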