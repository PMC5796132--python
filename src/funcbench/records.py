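"""Core domain types: protein records and per-family dataset triples.

A benchmark family is an independent binary problem: its members are the
positive class and sequences drawn from unrelated coherent groups
(pseudo-Pfam families) are the negative class. Each family carries three
disjoint labeled sets — training, testing (used for hyperparameter tuning)
and an independent set used exactly once for the final evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

POSITIVE = "positive"
NEGATIVE = "negative"

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BJOUXZ"


@dataclass
class ProteinRecord:
    """One protein sequence with its identifier and known family labels.

    ``family_labels`` holds the functional-family annotations (possibly
    empty); ``group_id`` identifies the coherent negative group (pseudo-Pfam
    family) a record was drawn from, when applicable.
    """

    id: str
    sequence: str
    family_labels: set[str] = field(default_factory=set)
    group_id: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()


@dataclass
class DatasetTriple:
    """Disjoint training / testing / independent sets for one family.

    Each set is a list of ``(ProteinRecord, class_label)`` pairs with
    ``class_label`` in ``{"positive", "negative"}``. No two records anywhere
    in the triple share an identical sequence string, and each set contains
    at least one member of each class.
    """

    family_id: str
    training: list[tuple[ProteinRecord, str]]
    testing: list[tuple[ProteinRecord, str]]
    independent: list[tuple[ProteinRecord, str]]

    def validate(self) -> None:
        seen: set[str] = set()
        for name, part in self.parts():
            labels = {lab for _, lab in part}
            if labels - {POSITIVE, NEGATIVE}:
                raise ValueError(f"{name}: bad class labels {labels}")
            if POSITIVE not in labels or NEGATIVE not in labels:
                raise ValueError(
                    f"family {self.family_id}: {name} set lacks one class"
                )
            for rec, _ in part:
                if rec.sequence in seen:
                    raise ValueError(
                        f"family {self.family_id}: duplicate sequence for "
                        f"record {rec.id!r}"
                    )
                seen.add(rec.sequence)

    def parts(self):
        return (
            ("training", self.training),
            ("testing", self.testing),
            ("independent", self.independent),
        )
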