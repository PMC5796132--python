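"""CTD (composition / transition / distribution) feature encoding.

Every feature-based classifier in the benchmark sees a protein as a fixed
188-dimensional vector: 20 amino-acid composition fractions followed, for
each of eight physicochemical properties, by 3 composition, 3 transition
and 15 distribution values. Each property partitions the 20 standard
residues into three disjoint groups (e.g. charge: positive {K,R} /
neutral / negative {D,E}); composition is the fraction of residues per
group, transition the fraction of adjacent residue pairs whose members
fall in two different groups, and distribution the positions (as percent
of sequence length) of the first, 25%, 50%, 75% and last residue of each
group.

The residue partitions are the canonical three-group tables from the
descriptor's source literature, shipped as a machine-readable TSV
(``data/ctd_groups.tsv``) whose row order fixes the feature layout.
Ambiguous residue codes (B, J, O, U, X, Z) are skipped entirely: they
join no group, no adjacent pair, and do not count toward sequence length.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from math import ceil

import numpy as np

from .records import STANDARD_AA

N_FEATURES = 188
#: per property: 3 composition + 3 transition + 15 distribution
_PER_PROPERTY = 21


class EncodingError(ValueError):
    """Sequence cannot be encoded (fewer than 2 standard residues)."""


@dataclass(frozen=True)
class PropertyGrouping:
    """An ordered partition of the 20 standard residues into 3 groups."""

    property_name: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str]]
    group_names: tuple[str, str, str]

    def __post_init__(self) -> None:
        union = set().union(*self.groups)
        total = sum(len(g) for g in self.groups)
        if union != set(STANDARD_AA) or total != 20:
            raise ValueError(
                f"{self.property_name}: groups must partition the 20 "
                f"standard residues"
            )

    def group_of(self) -> dict[str, int]:
        """Residue -> 0-based group index."""
        return {aa: i for i, grp in enumerate(self.groups) for aa in grp}


def load_groupings() -> list[PropertyGrouping]:
    """Load the packaged property partitions, in fixed layout order."""
    path = resources.files("funcbench.data") / "ctd_groups.tsv"
    rows: dict[str, list[tuple[int, str, str]]] = {}
    order: list[str] = []
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            prop = row["property"]
            if prop not in rows:
                rows[prop] = []
                order.append(prop)
            rows[prop].append(
                (int(row["group_index"]), row["group_name"], row["residues"])
            )
    groupings = []
    for prop in order:
        triples = sorted(rows[prop])
        groupings.append(
            PropertyGrouping(
                property_name=prop,
                groups=tuple(frozenset(res) for _, _, res in triples),
                group_names=tuple(name for _, name, _ in triples),
            )
        )
    return groupings


_GROUPINGS: list[PropertyGrouping] | None = None


def groupings() -> list[PropertyGrouping]:
    global _GROUPINGS
    if _GROUPINGS is None:
        _GROUPINGS = load_groupings()
    return _GROUPINGS


def _standard_only(sequence: str) -> str:
    return "".join(c for c in sequence.upper() if c in STANDARD_AA)


def aa_composition(sequence: str) -> np.ndarray:
    """Fractions of the 20 standard residues, in alphabetical order."""
    seq = _standard_only(sequence)
    if not seq:
        raise EncodingError("sequence has no standard residues")
    counts = np.array([seq.count(aa) for aa in STANDARD_AA], dtype=float)
    return counts / len(seq)


def composition(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Per-group residue fractions (3 values summing to 1)."""
    seq = _standard_only(sequence)
    if not seq:
        raise EncodingError("sequence has no standard residues")
    idx = grouping.group_of()
    counts = np.zeros(3)
    for aa in seq:
        counts[idx[aa]] += 1
    return counts / len(seq)


def transition(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Cross-group adjacent-pair frequencies for pairs (1,2), (1,3), (2,3).

    Adjacency is taken over the standard-residue subsequence; each value is
    the number of adjacent pairs whose residues lie in the two groups (in
    either order) divided by the total number of adjacent pairs.
    """
    seq = _standard_only(sequence)
    if len(seq) < 2:
        raise EncodingError("transition needs >= 2 standard residues")
    idx = grouping.group_of()
    codes = [idx[aa] for aa in seq]
    pair_counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
    for a, b in zip(codes, codes[1:]):
        if a != b:
            pair_counts[(min(a, b), max(a, b))] += 1
    n_pairs = len(seq) - 1
    return np.array(
        [pair_counts[(0, 1)], pair_counts[(0, 2)], pair_counts[(1, 2)]],
        dtype=float,
    ) / n_pairs


def distribution(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Positional spread of each group: 5 percentages per group, 15 total.

    For a group occurring n times at 1-based positions p_1 < ... < p_n in
    the standard-residue subsequence of length L, reports 100*p_j/L for
    j = 1, ceil(n/4), ceil(n/2), ceil(3n/4), n. An absent group reports
    five zeros.
    """
    seq = _standard_only(sequence)
    if not seq:
        raise EncodingError("sequence has no standard residues")
    L = len(seq)
    idx = grouping.group_of()
    positions: list[list[int]] = [[], [], []]
    for pos, aa in enumerate(seq, start=1):
        positions[idx[aa]].append(pos)
    out = np.zeros(15)
    for g, plist in enumerate(positions):
        n = len(plist)
        if n == 0:
            continue
        for q, frac in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
            j = max(1, ceil(frac * n))
            out[5 * g + q] = 100.0 * plist[j - 1] / L
    return out


def encode(sequence: str) -> np.ndarray:
    """Full 188-dimensional feature vector for one sequence."""
    seq = _standard_only(sequence)
    if len(seq) < 2:
        raise EncodingError("sequence has fewer than 2 standard residues")
    parts = [aa_composition(seq)]
    for grouping in groupings():
        parts.append(composition(seq, grouping))
        parts.append(transition(seq, grouping))
        parts.append(distribution(seq, grouping))
    vec = np.concatenate(parts)
    assert vec.shape == (N_FEATURES,)
    return vec


def encode_many(sequences: list[str]) -> np.ndarray:
    """Stack :func:`encode` over sequences into an (n, 188) matrix."""
    return np.vstack([encode(s) for s in sequences])


def feature_names() -> list[str]:
    """Column names matching the vector layout."""
    names = [f"aa_{aa}" for aa in STANDARD_AA]
    for grouping in groupings():
        p = grouping.property_name
        names += [f"{p}_comp_g{i}" for i in (1, 2, 3)]
        names += [f"{p}_trans_g{a}{b}" for a, b in ((1, 2), (1, 3), (2, 3))]
        for i in (1, 2, 3):
            names += [f"{p}_dist_g{i}_p{q}" for q in (0, 25, 50, 75, 100)]
    return names


@dataclass
class MinMaxScaler:
    """Min-max scaling to [0, 1] fitted on the training matrix only.

    CTD blocks mix fractions ([0,1]) and percentages ([0,100]); distance
    based classifiers need a common scale. Constant columns map to 0.
    """

    mins: np.ndarray | None = None
    ranges: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.mins = X.min(axis=0)
        span = X.max(axis=0) - self.mins
        span[span == 0] = 1.0  # constant column -> (x - min)/1 = 0
        self.ranges = span
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.mins) / self.ranges

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_features(
    training: np.ndarray, *others: np.ndarray
) -> tuple[list[np.ndarray], MinMaxScaler]:
    """Fit min-max on ``training`` and apply to it plus all ``others``."""
    scaler = MinMaxScaler().fit(training)
    return [scaler.transform(m) for m in (training, *others)], scaler
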