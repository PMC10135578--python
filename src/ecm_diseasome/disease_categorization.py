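"""Disease categorization by substring matching against term lists.

Diseases are grouped into three overlapping categories:

* **A** -- connective-tissue / typical ECM diseases (Ehlers-Danlos,
  osteogenesis imperfecta, Marfan, Alport, ...);
* **B** -- common diseases without a direct ECM link (asthma, autism,
  schizophrenia, ...);
* **C** -- age-related diseases (arthritis, Alzheimer, cancer, fibrosis, ...).

A disease may match several lists; the combination label is the sorted
member set joined by underscores (``A``, ``B_C``, ``A_B_C``), and a disease
matching nothing is labeled ``uncategorized``.  Matching is a plain
case-insensitive substring test on the normalized name -- no word boundaries,
so e.g. "cancerous" matches the term "cancer"; the shipped default lists are
deliberately small and user-replaceable.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .data_io import ConfigurationError
from .records import normalize_disease

CATEGORY_KEYS = ("A", "B", "C")

#: Default term lists, reconstructed from the canonical examples of each
#: category; replace via :func:`load_terms` for real analyses.
DEFAULT_TERMS: dict[str, tuple[str, ...]] = {
    "A": (
        "ehlers-danlos", "ehlers danlos", "osteogenesis imperfecta", "marfan",
        "alport", "fraser", "von willebrand", "stickler", "ullrich",
        "epidermolysis bullosa", "cutis laxa",
    ),
    "B": (
        "diabetes type 1", "type 1 diabetes", "diabetes mellitus type 1",
        "asthma", "autism", "lissencephaly", "schizophrenia", "seizure",
        "muscular dystrophy", "obesity", "stroke", "intellectual disability",
    ),
    "C": (
        "arthritis", "alzheimer", "cancer", "carcinoma",
        "diabetes type 2", "type 2 diabetes", "diabetes mellitus type 2",
        "chronic obstructive pulmonary", "fibrosis", "parkinson", "cirrhosis",
        "osteoporosis", "hypertension", "macular degeneration", "glaucoma",
    ),
}


@dataclass(frozen=True)
class CategoryTerms:
    """Three term lists keyed 'A', 'B', 'C'; terms lowercase and deduplicated."""

    terms: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing = [k for k in CATEGORY_KEYS if k not in self.terms]
        if missing:
            raise ConfigurationError(f"missing term list(s): {', '.join(missing)}")
        for key in CATEGORY_KEYS:
            if any(not t for t in self.terms[key]):
                raise ConfigurationError(f"empty term in list {key}")

    @classmethod
    def from_lists(cls, a: Iterable[str], b: Iterable[str], c: Iterable[str]) -> "CategoryTerms":
        def clean(items: Iterable[str]) -> tuple[str, ...]:
            seen: dict[str, None] = {}
            for term in items:
                term = term.strip().lower()
                if not term:
                    raise ConfigurationError("term lists may not contain empty terms")
                seen.setdefault(term)
            return tuple(seen)
        return cls({"A": clean(a), "B": clean(b), "C": clean(c)})

    def __getitem__(self, key: str) -> tuple[str, ...]:
        return self.terms[key]


def default_terms() -> CategoryTerms:
    return CategoryTerms.from_lists(*(DEFAULT_TERMS[k] for k in CATEGORY_KEYS))


def load_terms(path: str | Path) -> CategoryTerms:
    """Load term lists from a JSON config with arrays under "A", "B", "C"."""
    with open(path, encoding="utf-8") as handle:
        data = json.load(handle)
    missing = [k for k in CATEGORY_KEYS if k not in data]
    if missing:
        raise ConfigurationError(
            f"{path}: missing term list(s) {', '.join(missing)}")
    return CategoryTerms.from_lists(data["A"], data["B"], data["C"])


@dataclass(frozen=True, slots=True)
class CategoryAssignment:
    disease: str  # normalized name
    categories: frozenset[str]

    @property
    def label(self) -> str:
        if not self.categories:
            return "uncategorized"
        return "_".join(sorted(self.categories))


def categorize_disease(name: str, terms: CategoryTerms) -> CategoryAssignment:
    """Assign a disease to every category any of whose terms it contains."""
    normalized = normalize_disease(name)
    members = frozenset(
        key for key in CATEGORY_KEYS
        if any(term in normalized for term in terms[key]))
    return CategoryAssignment(disease=normalized, categories=members)


def category_counts(assignments: Iterable[CategoryAssignment],
                    weight: str = "by_disease") -> tuple[pd.DataFrame, dict[str, int]]:
    """Tabulate combination-label counts and per-category marginals.

    ``by_disease`` counts each unique disease once; ``by_association`` counts
    every assignment (one per gene-disease association).  Label counts
    partition the input; ``marginal[X]`` sums every label containing X, so
    overlapping diseases contribute to several marginals.
    """
    if weight not in ("by_disease", "by_association"):
        raise ValueError(f"unknown weight {weight!r}")
    items = list(assignments)
    if weight == "by_disease":
        unique: dict[str, CategoryAssignment] = {}
        for a in items:
            unique.setdefault(a.disease, a)
        items = list(unique.values())
    labels = Counter(a.label for a in items)
    marginals = {key: sum(1 for a in items if key in a.categories)
                 for key in CATEGORY_KEYS}
    table = pd.DataFrame(sorted(labels.items()), columns=["label", "count"])
    return table, marginals
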