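"""Parsing and rendering of coding-DNA and protein change notation.

The curated PATL2 literature writes cDNA substitutions in a ref-first
dialect (``c.T478C``) alongside standard HGVS (``c.478T>C``); intronic
changes appear as ``c.A1225-2G`` (= ``c.1225-2A>G``) and deletions as
``c.716delA`` or ``c.223-14_223-2del13``.  Both dialects parse to the same
structure, and :func:`render_cdna` emits the standard form, so that
``parse(render(parse(s)))`` is the identity on the parsed value.

Equality of parsed values deliberately ignores the original string, which
is retained on the ``raw`` attribute for provenance.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils import seq1

_NUCS = "ACGT"
_AA1 = set("ACDEFGHIKLMNPQRSTVWY")


class HgvsParseError(ValueError):
    """Raised when a variant string cannot be interpreted."""


@dataclass(frozen=True)
class CdnaVariant:
    """A coding-DNA change in merged-CDS coordinates (1-based).

    ``position`` anchors intronic changes to the nearest coding base;
    ``intron_offset`` is the signed distance into the intron (e.g. -14 for
    ``c.223-14``).  ``kind`` is one of ``substitution``, ``deletion``
    (single base) or ``range_deletion``.
    """

    position: int
    kind: str
    intron_offset: Optional[int] = None
    end_position: Optional[int] = None
    end_offset: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    deleted_length: Optional[int] = None
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HgvsParseError(f"coding position must be >= 1, got {self.position}")
        if self.kind == "substitution":
            if not (self.ref_base and self.alt_base):
                raise HgvsParseError(f"substitution needs ref and alt: {self.raw!r}")
        elif self.kind in ("deletion", "range_deletion"):
            if self.deleted_length is None or self.deleted_length < 1:
                raise HgvsParseError(f"deletion needs a positive length: {self.raw!r}")
        else:
            raise HgvsParseError(f"unknown cDNA variant kind {self.kind!r}")

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset is not None

    def render(self) -> str:
        """Standard-HGVS rendering (``c.478T>C``, ``c.223-14_223-2del13``)."""
        def pos(p: int, off: Optional[int]) -> str:
            return f"{p}{off:+d}" if off is not None else f"{p}"

        if self.kind == "substitution":
            return f"c.{pos(self.position, self.intron_offset)}{self.ref_base}>{self.alt_base}"
        if self.kind == "deletion":
            seq = self.ref_base or ""
            return f"c.{pos(self.position, self.intron_offset)}del{seq}"
        start = pos(self.position, self.intron_offset)
        end = pos(self.end_position, self.end_offset)
        return f"c.{start}_{end}del{self.deleted_length}"


@dataclass(frozen=True)
class ProteinVariant:
    """A single-residue protein change; STOP is rendered ``*``."""

    ref_aa: str
    position: int
    alt_aa: Optional[str]
    kind: str
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HgvsParseError(f"residue index must be >= 1, got {self.position}")
        if (self.kind == "nonsense") != (self.alt_aa == "*"):
            raise HgvsParseError(f"nonsense iff the new residue is a stop: {self.raw!r}")

    def render(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa or '?'}"


_POS = r"(\d+)([+-]\d+)?"
_RE_SUB_STD = re.compile(rf"^{_POS}([{_NUCS}])>([{_NUCS}])$")
_RE_SUB_DIALECT = re.compile(rf"^([{_NUCS}]){_POS}([{_NUCS}])$")
_RE_DEL_SINGLE = re.compile(rf"^{_POS}del([{_NUCS}]*)(\d*)$")
_RE_DEL_RANGE = re.compile(rf"^{_POS}_{_POS}del([{_NUCS}]*)(\d*)$")


def parse_cdna(raw: str) -> CdnaVariant:
    """Parse a cDNA change in either standard HGVS or the ref-first dialect."""
    if not raw.startswith("c."):
        raise HgvsParseError(f"cDNA notation must start with 'c.': {raw!r}")
    body = raw[2:].replace(" ", "")
    # Unicode minus occasionally survives copy-editing
    body = body.replace("−", "-")

    m = _RE_SUB_STD.match(body)
    if m:
        pos, off, ref, alt = m.groups()
        return CdnaVariant(position=int(pos), kind="substitution",
                           intron_offset=int(off) if off else None,
                           ref_base=ref, alt_base=alt, raw=raw)
    m = _RE_SUB_DIALECT.match(body)
    if m:
        ref, pos, off, alt = m.groups()
        return CdnaVariant(position=int(pos), kind="substitution",
                           intron_offset=int(off) if off else None,
                           ref_base=ref, alt_base=alt, raw=raw)
    m = _RE_DEL_SINGLE.match(body)
    if m:
        pos, off, seq, num = m.groups()
        length = int(num) if num else (len(seq) if seq else 1)
        return CdnaVariant(position=int(pos), kind="deletion",
                           intron_offset=int(off) if off else None,
                           ref_base=seq or None, deleted_length=length, raw=raw)
    m = _RE_DEL_RANGE.match(body)
    if m:
        pos, off, end, end_off, seq, num = m.groups()
        position, end_position = int(pos), int(end)
        intron_offset = int(off) if off else None
        end_offset = int(end_off) if end_off else None
        if num:
            length = int(num)
        elif seq:
            length = len(seq)
        elif intron_offset is not None and end_offset is not None and position == end_position:
            length = end_offset - intron_offset + 1
        elif intron_offset is None and end_offset is None:
            length = end_position - position + 1
        else:
            raise HgvsParseError(f"cannot infer deleted length of {raw!r}")
        return CdnaVariant(position=position, kind="range_deletion",
                           intron_offset=intron_offset, end_position=end_position,
                           end_offset=end_offset, deleted_length=length, raw=raw)
    raise HgvsParseError(f"unrecognized cDNA notation: {raw!r}")


def _one_letter(token: str, raw: str) -> str:
    if token in ("*", "Ter", "ter", "X"):
        return "*"
    if len(token) == 1:
        if token.upper() not in _AA1:
            raise HgvsParseError(f"unknown amino-acid code {token!r} in {raw!r}")
        return token.upper()
    if len(token) == 3:
        aa = seq1(token)
        if aa not in _AA1:
            raise HgvsParseError(f"unknown amino-acid code {token!r} in {raw!r}")
        return aa
    raise HgvsParseError(f"unknown amino-acid code {token!r} in {raw!r}")


_RE_PROT = re.compile(r"^([A-Za-z]{3}|[A-Za-z])(\d+)(\*|Ter|[A-Za-z]{3}|[A-Za-z]|=)$")


def parse_protein(raw: str) -> ProteinVariant:
    """Parse a protein change; one- and three-letter forms yield equal values."""
    if not raw.startswith("p."):
        raise HgvsParseError(f"protein notation must start with 'p.': {raw!r}")
    body = raw[2:].replace(" ", "").strip("()")
    m = _RE_PROT.match(body)
    if not m:
        raise HgvsParseError(f"unrecognized protein notation: {raw!r}")
    ref_tok, pos, alt_tok = m.groups()
    ref = _one_letter(ref_tok, raw)
    if ref == "*":
        raise HgvsParseError(f"reference residue cannot be a stop: {raw!r}")
    alt = ref if alt_tok == "=" else _one_letter(alt_tok, raw)
    if alt == "*":
        kind = "nonsense"
    elif alt == ref:
        kind = "synonymous"
    else:
        kind = "missense"
    return ProteinVariant(ref_aa=ref, position=int(pos), alt_aa=alt, kind=kind, raw=raw)
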