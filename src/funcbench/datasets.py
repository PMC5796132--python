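"""Per-family dataset construction with negative sampling.

Positives are dealt round-robin (after a seeded shuffle) into training,
testing and independent sets, so the three positive counts differ by at
most one. Negatives come from a pool of coherent groups (pseudo-Pfam
families): any group containing a member of the positive family is
excluded outright, and from each remaining group three representatives
are drawn at random and dealt one each to training, testing and
independent, in that order. Duplicate sequences are removed so the triple
never contains the same sequence twice.
"""

from __future__ import annotations

import numpy as np

from .records import NEGATIVE, POSITIVE, DatasetTriple, ProteinRecord


class DatasetConfigError(ValueError):
    """Raised when a valid triple cannot be built from the given inputs."""


def deduplicate(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the first occurrence of each distinct sequence string."""
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def group_by_id(records: list[ProteinRecord]) -> dict[str, list[ProteinRecord]]:
    groups: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        if rec.group_id is None:
            raise DatasetConfigError(f"negative record {rec.id!r} has no group_id")
        groups.setdefault(rec.group_id, []).append(rec)
    return groups


def build_family_datasets(
    family_id: str,
    positives: list[ProteinRecord],
    negative_pool: list[ProteinRecord],
    seed: int,
) -> DatasetTriple:
    """Build the training/testing/independent triple for one family.

    ``negative_pool`` records must carry ``group_id``; groups with any member
    labeled with ``family_id`` are dropped ("positive" groups). ``seed``
    drives a single pseudo-random stream covering the positive permutation
    and every negative draw, so equal seeds give byte-identical triples.
    """
    rng = np.random.default_rng(seed)
    positives = deduplicate(positives)
    if len(positives) < 3:
        raise DatasetConfigError(
            f"family {family_id}: need >= 3 distinct positive sequences, "
            f"got {len(positives)}"
        )

    sets: list[list[tuple[ProteinRecord, str]]] = [[], [], []]
    seen: set[str] = set()

    order = rng.permutation(len(positives))
    for i, idx in enumerate(order):
        rec = positives[idx]
        sets[i % 3].append((rec, POSITIVE))
        seen.add(rec.sequence)

    groups = group_by_id(negative_pool)
    eligible = {
        gid: members
        for gid, members in groups.items()
        if not any(family_id in rec.family_labels for rec in members)
    }
    if not eligible:
        raise DatasetConfigError(
            f"family {family_id}: no negative group free of positive members"
        )

    for gid in sorted(eligible):
        members = deduplicate(eligible[gid])
        members = [m for m in members if m.sequence not in seen]
        if not members:
            continue
        n_draw = min(3, len(members))
        picks = rng.choice(len(members), size=n_draw, replace=False)
        for j, pick in enumerate(picks):
            rec = members[pick]
            sets[j].append((rec, NEGATIVE))
            seen.add(rec.sequence)

    triple = DatasetTriple(
        family_id=family_id,
        training=sets[0],
        testing=sets[1],
        independent=sets[2],
    )
    try:
        triple.validate()
    except ValueError as exc:
        raise DatasetConfigError(str(exc)) from exc
    return triple
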