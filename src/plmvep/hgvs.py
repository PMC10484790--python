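"""Parsing and canonical formatting of protein-level variant notation.

Accepts the common HGVS.p dialects with one- or three-letter residue
codes (``p.Arg123Cys``, ``R123C``, ``p.Val600del``,
``p.Lys10_Leu12delinsTrp``, ``p.Lys10_Thr11insAla``, ``p.Gln25Ter``)
and emits a canonical three-letter form. Frameshift notation is
rejected as out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .backend import AA_INDEX
from .errors import UnsupportedVariantError, VariantParseError
from .scoring import IndelVariant, MissenseVariant, StopGainVariant

THREE_TO_ONE = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F",
    "Gly": "G", "His": "H", "Ile": "I", "Lys": "K", "Leu": "L",
    "Met": "M", "Asn": "N", "Pro": "P", "Gln": "Q", "Arg": "R",
    "Ser": "S", "Thr": "T", "Val": "V", "Trp": "W", "Tyr": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_RES = r"(?:[A-Z][a-z]{2}|[A-Z])"  # one residue token, 3- or 1-letter
_TERM = r"(?:Ter|\*|X)"


def _aa(token: str, raw: str) -> str:
    """Residue token -> one-letter code."""
    if len(token) == 3:
        if token not in THREE_TO_ONE:
            raise VariantParseError(f"unknown residue {token!r} in {raw!r}")
        return THREE_TO_ONE[token]
    if token not in AA_INDEX:
        raise VariantParseError(f"unknown residue {token!r} in {raw!r}")
    return token


def _aa_string(tokens: str, raw: str) -> str:
    """Concatenated residue tokens -> one-letter string."""
    if re.fullmatch(r"(?:[A-Z][a-z]{2})+", tokens):
        return "".join(
            _aa(tokens[i : i + 3], raw) for i in range(0, len(tokens), 3)
        )
    if re.fullmatch(r"[A-Z]+", tokens):
        return "".join(_aa(t, raw) for t in tokens)
    raise VariantParseError(f"cannot read inserted residues in {raw!r}")


@dataclass(frozen=True)
class VariantRecord:
    """A parsed variant notation, normalized to one-letter residues."""

    raw: str
    kind: str  # missense | deletion | insertion | delins | stop_gain
    position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    span: Optional[tuple] = None
    span_ref: Optional[tuple] = None  # (first, last) residue letters of the span
    inserted: str = ""
    anchor: Optional[int] = None
    anchor_ref: Optional[tuple] = None  # residue letters flanking an insertion

    def to_missense(self, protein_id: str) -> MissenseVariant:
        if self.kind != "missense":
            raise VariantParseError(f"{self.raw!r} is not a missense variant")
        return MissenseVariant(
            protein_id=protein_id,
            position=self.position,
            ref_aa=self.ref_aa,
            alt_aa=self.alt_aa,
        )

    def to_indel(self, protein_id: str) -> IndelVariant:
        if self.kind == "insertion":
            return IndelVariant(
                protein_id=protein_id,
                kind="insertion",
                inserted=self.inserted,
                anchor=self.anchor,
            )
        if self.kind in ("deletion", "delins"):
            return IndelVariant(
                protein_id=protein_id,
                kind=self.kind,
                span=self.span,
                inserted=self.inserted,
            )
        raise VariantParseError(f"{self.raw!r} is not an indel")

    def to_stop_gain(self, protein_id: str) -> StopGainVariant:
        if self.kind != "stop_gain":
            raise VariantParseError(f"{self.raw!r} is not a stop-gain variant")
        return StopGainVariant(protein_id=protein_id, stop_position=self.position)


def parse_variant(notation: str) -> VariantRecord:
    raw = notation.strip()
    body = raw
    if body.startswith("p."):
        body = body[2:]
    body = body.strip("()")
    if not body:
        raise VariantParseError(f"empty variant notation {raw!r}")
    if "fs" in body:
        raise UnsupportedVariantError(
            f"frameshift variants are not scored: {raw!r}"
        )

    m = re.fullmatch(rf"({_RES})(\d+){_TERM}", body)
    if m:
        return VariantRecord(
            raw=raw,
            kind="stop_gain",
            position=int(m.group(2)),
            ref_aa=_aa(m.group(1), raw),
        )

    m = re.fullmatch(rf"({_RES})(\d+)(?:_({_RES})(\d+))?delins([A-Za-z]+)", body)
    if m:
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        first = _aa(m.group(1), raw)
        last = _aa(m.group(3), raw) if m.group(3) else first
        if end < start:
            raise VariantParseError(f"span out of order in {raw!r}")
        return VariantRecord(
            raw=raw,
            kind="delins",
            span=(start, end),
            span_ref=(first, last),
            inserted=_aa_string(m.group(5), raw),
        )

    m = re.fullmatch(rf"({_RES})(\d+)(?:_({_RES})(\d+))?del", body)
    if m:
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        first = _aa(m.group(1), raw)
        last = _aa(m.group(3), raw) if m.group(3) else first
        if end < start:
            raise VariantParseError(f"span out of order in {raw!r}")
        return VariantRecord(
            raw=raw,
            kind="deletion",
            span=(start, end),
            span_ref=(first, last),
        )

    m = re.fullmatch(rf"({_RES})(\d+)_({_RES})(\d+)ins([A-Za-z]+)", body)
    if m:
        left, right = int(m.group(2)), int(m.group(4))
        if right != left + 1:
            raise VariantParseError(
                f"insertion anchors must be consecutive in {raw!r}"
            )
        return VariantRecord(
            raw=raw,
            kind="insertion",
            anchor=left,
            anchor_ref=(_aa(m.group(1), raw), _aa(m.group(3), raw)),
            inserted=_aa_string(m.group(5), raw),
        )

    m = re.fullmatch(rf"({_RES})(\d+)({_RES})", body)
    if m:
        ref = _aa(m.group(1), raw)
        alt = _aa(m.group(3), raw)
        return VariantRecord(
            raw=raw, kind="missense", position=int(m.group(2)), ref_aa=ref, alt_aa=alt
        )

    raise VariantParseError(f"cannot parse variant notation {raw!r}")


def format_variant(record: VariantRecord) -> str:
    """Canonical three-letter HGVS.p form of a parsed record."""
    t = ONE_TO_THREE
    if record.kind == "missense":
        return f"p.{t[record.ref_aa]}{record.position}{t[record.alt_aa]}"
    if record.kind == "stop_gain":
        return f"p.{t[record.ref_aa]}{record.position}Ter"
    if record.kind == "deletion":
        s, e = record.span
        first, last = record.span_ref
        if s == e:
            return f"p.{t[first]}{s}del"
        return f"p.{t[first]}{s}_{t[last]}{e}del"
    if record.kind == "delins":
        s, e = record.span
        first, last = record.span_ref
        ins = "".join(t[a] for a in record.inserted)
        if s == e:
            return f"p.{t[first]}{s}delins{ins}"
        return f"p.{t[first]}{s}_{t[last]}{e}delins{ins}"
    if record.kind == "insertion":
        left, right = record.anchor_ref
        ins = "".join(t[a] for a in record.inserted)
        return f"p.{t[left]}{record.anchor}_{t[right]}{record.anchor + 1}ins{ins}"
    raise VariantParseError(f"unknown record kind {record.kind!r}")
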