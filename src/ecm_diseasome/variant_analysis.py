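"""Protein-level variant analysis.

Parses HGVS-style protein-change strings (``p.Gly661Arg``, ``G661R``) into
missense events, accumulates reference->alternate amino-acid substitution
matrices, ranks the most substituted residues and their targets, checks
positions against the collagen Gly-X-Y triplet periodicity, and counts
variants per disease.

Parsing is a total function with three tagged outcomes: ``missense``,
``not_missense`` (synonymous, frameshift, deletion, duplication, insertion,
extension, and -- by default -- stop gain), and ``unparseable``.
"""

from __future__ import annotations

import enum
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .records import VariantRecord, normalize_disease

# One-letter <-> three-letter bijection over the 20 standard residues plus
# X (unknown) and * (stop, "Ter").
AA_1TO3: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "X": "Xaa", "*": "Ter",
}
AA_3TO1: dict[str, str] = {v: k for k, v in AA_1TO3.items()}

#: Matrix axis: the 20 standard residues by alphabetical three-letter code,
#: then Xaa, then Ter.
RESIDUE_ORDER: tuple[str, ...] = tuple(
    sorted(c for c in AA_3TO1 if c not in ("Xaa", "Ter"))) + ("Xaa", "Ter")
_RESIDUE_INDEX = {code: i for i, code in enumerate(RESIDUE_ORDER)}


@dataclass(frozen=True, slots=True)
class AminoAcid:
    """A residue identified by its one- and three-letter codes."""

    code1: str

    def __post_init__(self) -> None:
        if self.code1 not in AA_1TO3:
            raise ValueError(f"unsupported amino-acid code {self.code1!r}")

    @property
    def code3(self) -> str:
        return AA_1TO3[self.code1]

    @classmethod
    def from_any(cls, code: str) -> "AminoAcid":
        code = code.strip()
        if len(code) == 1:
            return cls(code.upper() if code != "*" else "*")
        return cls(AA_3TO1[code.capitalize()])


@dataclass(frozen=True, slots=True)
class Missense:
    """A single-residue substitution at a 1-based protein coordinate."""

    ref: AminoAcid
    position: int
    alt: AminoAcid

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("protein position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("missense requires ref != alt")

    def render(self) -> str:
        """Canonical HGVS-style form, e.g. ``p.Gly661Arg``."""
        return f"p.{self.ref.code3}{self.position}{self.alt.code3}"


class ParseOutcome(str, enum.Enum):
    MISSENSE = "missense"
    NOT_MISSENSE = "not_missense"
    UNPARSEABLE = "unparseable"


@dataclass(frozen=True, slots=True)
class ParseResult:
    outcome: ParseOutcome
    missense: Missense | None = None
    kind: str = ""  # sub-classification for not_missense outcomes

    @property
    def is_missense(self) -> bool:
        return self.outcome is ParseOutcome.MISSENSE


_THREE = r"[A-Za-z]{3}"
_SUB3 = re.compile(rf"^({_THREE})(\d+)({_THREE}|\*|=)$")
_SUB1 = re.compile(r"^([A-Z\*])(\d+)([A-Z\*=])$")
# Non-missense event notations (classified, not parsed in detail).
_NOT_MISSENSE = re.compile(
    rf"^({_THREE}|[A-Z])\d+(_({_THREE}|[A-Z])\d+)?"
    r"(fs|del|dup|ins|delins|ext)", re.IGNORECASE)

_NOT_MISSENSE_KINDS = ("fs", "delins", "del", "dup", "ins", "ext")


def _strip_prefix(text: str) -> str:
    text = text.strip()
    if text.lower().startswith("p."):
        text = text[2:]
    if text.startswith("(") and text.endswith(")"):
        text = text[1:-1]
    return text.strip()


def _residue(token: str) -> AminoAcid | None:
    try:
        return AminoAcid.from_any(token)
    except (KeyError, ValueError):
        return None


def parse_protein_change(text: str | None, *, stop_gain_is_missense: bool = False) -> ParseResult:
    """Classify a protein-change string; never raises.

    Accepts ``p.``-prefixed and bare forms, three-letter (case-insensitive)
    and one-letter codes.  Synonymous (``p.Gly661=``), frameshift, deletion,
    duplication, insertion, extension, and stop-gain notations are
    ``not_missense`` (stop gain counts as missense only when
    ``stop_gain_is_missense`` is set).  Anything else is ``unparseable``.
    """
    if text is None or not text.strip():
        return ParseResult(ParseOutcome.UNPARSEABLE, kind="empty")
    body = _strip_prefix(text)
    match = _SUB3.match(body) or _SUB1.match(body)
    if match is None:
        if _NOT_MISSENSE.match(body):
            lowered = body.lower()
            kind = next((k for k in _NOT_MISSENSE_KINDS if k in lowered), "other")
            return ParseResult(ParseOutcome.NOT_MISSENSE, kind=kind)
        return ParseResult(ParseOutcome.UNPARSEABLE, kind="syntax")
    ref_tok, pos_tok, alt_tok = match.groups()
    if alt_tok == "=":
        return ParseResult(ParseOutcome.NOT_MISSENSE, kind="synonymous")
    if alt_tok.lower() in ("del", "dup", "ins", "ext"):
        return ParseResult(ParseOutcome.NOT_MISSENSE, kind=alt_tok.lower())
    ref = _residue(ref_tok)
    alt = _residue(alt_tok)
    if ref is None or alt is None:
        return ParseResult(ParseOutcome.UNPARSEABLE, kind="residue")
    if alt.code3 == "Ter" and not stop_gain_is_missense:
        return ParseResult(ParseOutcome.NOT_MISSENSE, kind="stop_gain")
    position = int(pos_tok)
    if position < 1 or ref == alt:
        return ParseResult(ParseOutcome.NOT_MISSENSE,
                           kind="synonymous" if ref == alt else "position")
    return ParseResult(ParseOutcome.MISSENSE, Missense(ref, position, alt))


class SubstitutionMatrix:
    """Counts of reference->alternate residue substitutions.

    Rows are reference residues, columns alternates, both ordered by
    :data:`RESIDUE_ORDER`.  The diagonal is identically zero and the grand
    total equals the number of missense records counted.
    """

    def __init__(self) -> None:
        n = len(RESIDUE_ORDER)
        self.counts = np.zeros((n, n), dtype=np.int64)

    def add(self, missense: Missense) -> None:
        self.counts[_RESIDUE_INDEX[missense.ref.code3],
                    _RESIDUE_INDEX[missense.alt.code3]] += 1

    def __getitem__(self, key: tuple[str, str]) -> int:
        ref, alt = key
        return int(self.counts[_RESIDUE_INDEX[ref], _RESIDUE_INDEX[alt]])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> dict[str, int]:
        return {code: int(self.counts[i].sum()) for code, i in _RESIDUE_INDEX.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(RESIDUE_ORDER),
                            columns=list(RESIDUE_ORDER))

    def to_long(self) -> pd.DataFrame:
        """Long-form (ref, alt, count) triples for nonzero cells."""
        rows = [(r, a, self[r, a])
                for r in RESIDUE_ORDER for a in RESIDUE_ORDER if self[r, a]]
        return pd.DataFrame(rows, columns=["ref", "alt", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="ref")


def substitution_matrix(records: Iterable[VariantRecord],
                        gene_filter: Callable[[str], bool] | None = None,
                        *, stop_gain_is_missense: bool = False) -> SubstitutionMatrix:
    """Accumulate one count per record that parses to a missense event.

    ``gene_filter`` restricts which genes contribute (e.g. collagens only for
    the collagen-helix heatmap); ``None`` counts every record.
    """
    matrix = SubstitutionMatrix()
    for record in records:
        if gene_filter is not None and not gene_filter(record.gene_symbol):
            continue
        result = parse_protein_change(record.protein_change,
                                      stop_gain_is_missense=stop_gain_is_missense)
        if result.is_missense:
            matrix.add(result.missense)
    return matrix


def rank_substituted(matrix: SubstitutionMatrix) -> list[tuple[str, int]]:
    """Reference residues by descending row total; ties alphabetical by code3."""
    totals = matrix.row_totals()
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


def rank_targets(matrix: SubstitutionMatrix, ref: str) -> list[tuple[str, int]]:
    """Alternate residues for one reference, descending; ties alphabetical."""
    if len(ref) == 1:
        ref = AA_1TO3[ref.upper()]
    row = {alt: matrix[ref, alt] for alt in RESIDUE_ORDER}
    return sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True, slots=True)
class TripletSlot:
    position_in_triplet: int  # 1, 2 or 3
    is_glycine_slot: bool


def triplet_position(position: int, helix_start: int = 1, offset: int = 0,
                     glycine_slot: int = 1) -> TripletSlot:
    """Locate a protein coordinate within the collagen Gly-X-Y repeat.

    ``position_in_triplet = ((position - helix_start + offset) mod 3) + 1``;
    positions p and p + 3 always share a slot.  The glycine slot defaults to
    1 (Gly written first in the motif) but is configurable.
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    if glycine_slot not in (1, 2, 3):
        raise ValueError("glycine_slot must be 1, 2 or 3")
    if position < helix_start:
        raise ValueError(f"position {position} precedes helix start {helix_start}")
    slot = ((position - helix_start + offset) % 3) + 1
    return TripletSlot(position_in_triplet=slot, is_glycine_slot=slot == glycine_slot)


def variants_per_disease(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Unique variant ids per normalized disease, descending.

    A variant id mapping to several diseases counts once under each, so the
    column sum is at least the number of distinct variant ids.
    """
    per_disease: dict[str, set[str]] = defaultdict(set)
    for record in records:
        per_disease[normalize_disease(record.condition)].add(record.variant_id)
    rows = sorted(((d, len(v)) for d, v in per_disease.items()),
                  key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["disease", "n_variants"])
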