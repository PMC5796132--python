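"""Synthetic protein families, negative pools and proteome scan sets.

Everything the benchmark needs can be generated with known ground truth:

* a *family* is a set of sequences independently derived from one common
  ancestor by per-site substitution (rate ``substitution_rate``, always
  to a different residue) and single-residue indels (rate ``indel_rate``).
  Two members then agree at an ancestral site when neither mutated, so,
  ignoring indels and back-coincidences, expected pairwise identity is
  approximately (1 - r)^2 for substitution rate r — e.g. r = 0.15 gives
  roughly 72% identity, a strongly conserved family.
* a *negative pool* is a collection of such families (pseudo-Pfam
  groups), each with its own ancestor and, by default, its own dirichlet-
  perturbed residue-composition bias so composition features carry
  realistic (but not trivially separable) signal.
* a *proteome* is a shuffled mixture of background sequences and freshly
  derived family members ("cousins" of the benchmark sets, not copies),
  each record carrying a hidden truth label for the false-discovery audit.

Background residue frequencies default to average composition observed
across well-annotated proteomes rather than uniform. All generators are
pure functions of their specs (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import STANDARD_AA, ProteinRecord

# Average residue frequencies of reviewed protein sequences (Swiss-Prot
# release statistics, rounded), alphabetical one-letter order; renormalized.
_BG = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0966,
    "M": 0.0241, "N": 0.0406, "P": 0.0471, "Q": 0.0393, "R": 0.0553,
    "S": 0.0657, "T": 0.0534, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}
BACKGROUND_FREQS = np.array([_BG[aa] for aa in STANDARD_AA])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated homologous family."""

    family_id: str
    n_members: int = 60
    length_range: tuple[int, int] = (120, 220)
    substitution_rate: float = 0.15
    indel_rate: float = 0.01
    composition_bias: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_members < 3:
            raise SimulationConfigError("n_members must be >= 3")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise SimulationConfigError("length bounds must be >= 30 and ordered")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise SimulationConfigError("rates must lie in [0, 1)")


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of one simulated scan proteome."""

    n_background: int = 1900
    planted: tuple[tuple[str, int], ...] = ()
    length_range: tuple[int, int] = (120, 220)
    background_composition: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_background < 0 or any(n < 0 for _, n in self.planted):
            raise SimulationConfigError("counts must be nonnegative")


def _draw_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=freqs)
    return "".join(STANDARD_AA[i] for i in idx)


def _mutate(
    rng: np.random.Generator,
    ancestor: str,
    sub_rate: float,
    indel_rate: float,
    freqs: np.ndarray,
) -> str:
    out = []
    for aa in ancestor:
        u = rng.random()
        if u < indel_rate / 2:
            continue  # deletion
        if u < indel_rate:  # insertion before the site
            out.append(_draw_sequence(rng, 1, freqs))
        if rng.random() < sub_rate:
            # substitute to a *different* residue so the rate is the
            # observed per-site change probability
            while True:
                new = STANDARD_AA[rng.choice(20, p=freqs)]
                if new != aa:
                    break
            out.append(new)
        else:
            out.append(aa)
    return "".join(out) if out else ancestor[:1]


@dataclass
class Family:
    spec: FamilySpec
    ancestor: str
    members: list[ProteinRecord] = field(default_factory=list)


def generate_family(spec: FamilySpec) -> Family:
    """Derive ``n_members`` sequences independently from one ancestor."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    freqs = (
        BACKGROUND_FREQS
        if spec.composition_bias is None
        else np.asarray(spec.composition_bias) / np.sum(spec.composition_bias)
    )
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    ancestor = _draw_sequence(rng, length, freqs)
    members = [
        ProteinRecord(
            id=f"{spec.family_id}_m{i:04d}",
            sequence=_mutate(
                rng, ancestor, spec.substitution_rate, spec.indel_rate, freqs
            ),
            family_labels={spec.family_id},
        )
        for i in range(spec.n_members)
    ]
    return Family(spec=spec, ancestor=ancestor, members=members)


def derive_members(
    family: Family, n: int, seed: int, id_prefix: str = "cousin"
) -> list[ProteinRecord]:
    """Fresh members from the same ancestor (never copies of existing ones)."""
    rng = np.random.default_rng(seed)
    spec = family.spec
    freqs = (
        BACKGROUND_FREQS
        if spec.composition_bias is None
        else np.asarray(spec.composition_bias) / np.sum(spec.composition_bias)
    )
    return [
        ProteinRecord(
            id=f"{spec.family_id}_{id_prefix}{i:04d}",
            sequence=_mutate(
                rng, family.ancestor, spec.substitution_rate, spec.indel_rate, freqs
            ),
            family_labels={spec.family_id},
        )
        for i in range(n)
    ]


def generate_negative_pool(
    n_groups: int,
    group_size_range: tuple[int, int] = (3, 8),
    seed: int = 0,
    substitution_rate: float = 0.15,
    composition_jitter: float = 120.0,
) -> list[ProteinRecord]:
    """Coherent unrelated groups standing in for Pfam negative families.

    Each group gets its own ancestor and a dirichlet-perturbed copy of the
    background composition (concentration ``composition_jitter * freqs``),
    so groups differ in residue bias without becoming caricatures.
    """
    if n_groups < 1:
        raise SimulationConfigError("need at least one negative group")
    rng = np.random.default_rng(seed)
    pool: list[ProteinRecord] = []
    for g in range(n_groups):
        gid = f"NG{g:03d}"
        bias = rng.dirichlet(composition_jitter * BACKGROUND_FREQS)
        size = int(rng.integers(group_size_range[0], group_size_range[1] + 1))
        fam = generate_family(
            FamilySpec(
                family_id=gid,
                n_members=max(size, 3),
                substitution_rate=substitution_rate,
                composition_bias=bias,
                seed=int(rng.integers(2**31)),
            )
        )
        for rec in fam.members[:size]:
            rec.family_labels = set()
            rec.group_id = gid
            pool.append(rec)
    return pool


def generate_proteome(
    spec: ProteomeSpec, families: dict[str, Family]
) -> tuple[list[ProteinRecord], np.ndarray]:
    """Background plus planted cousins, shuffled, with truth labels.

    Returns ``(records, truth)`` where ``truth[i]`` is True when record i
    is a planted member of any listed family.
    """
    spec.validate()
    for fid, _ in spec.planted:
        if fid not in families:
            raise SimulationConfigError(f"unknown planted family {fid!r}")
    rng = np.random.default_rng(spec.seed)
    freqs = (
        BACKGROUND_FREQS
        if spec.background_composition is None
        else np.asarray(spec.background_composition)
        / np.sum(spec.background_composition)
    )
    records: list[tuple[ProteinRecord, bool]] = []
    for i in range(spec.n_background):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        records.append(
            (
                ProteinRecord(id=f"bg{i:05d}", sequence=_draw_sequence(rng, length, freqs)),
                False,
            )
        )
    for fid, n in spec.planted:
        for rec in derive_members(
            families[fid], n, seed=int(rng.integers(2**31)), id_prefix="planted"
        ):
            records.append((rec, True))
    order = rng.permutation(len(records))
    shuffled = [records[i] for i in order]
    return [r for r, _ in shuffled], np.array([t for _, t in shuffled])
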