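import numpy as np
import pytest

from funcbench.datasets import DatasetConfigError, build_family_datasets, deduplicate
from funcbench.records import NEGATIVE, POSITIVE, ProteinRecord
from funcbench.simulate import generate_negative_pool


def recs(seqs):
    return [ProteinRecord(id=f"p{i}", sequence=s) for i, s in enumerate(seqs)]


@pytest.mark.parametrize(
    "seqs,expected",
    [
        (["MKV", "GGG", "MKV"], ["MKV", "GGG"]),
        (["MKV", "GGG", "AAA"], ["MKV", "GGG", "AAA"]),
        (["MKV"] * 100, ["MKV"]),
    ],
)
def test_deduplicate_keeps_first_occurrence(seqs, expected):
    assert [r.sequence for r in deduplicate(recs(seqs))] == expected


def _pool(n_groups, size=4, seed=0):
    return generate_negative_pool(n_groups, group_size_range=(size, size), seed=seed)


def test_round_robin_deal_nine_positives_four_groups(small_family):
    # 9 positives dealt in thirds; 4 groups contribute one negative per set
    positives = small_family.members[:9]
    triple = build_family_datasets("FAMX", positives, _pool(4), seed=1)
    for _, part in triple.parts():
        assert sum(1 for _, lab in part if lab == POSITIVE) == 3
        assert sum(1 for _, lab in part if lab == NEGATIVE) == 4


def test_positive_contaminated_group_contributes_nothing(small_family):
    positives = small_family.members[:9]
    pool = _pool(3)
    # contaminate one group with a member of the positive family
    tainted = pool[0].group_id
    pool[0].family_labels = {"FAMX"}
    triple = build_family_datasets("FAMX", positives, pool, seed=1)
    groups_used = {
        rec.group_id for _, part in triple.parts() for rec, lab in part if lab == NEGATIVE
    }
    assert tainted not in groups_used
    assert len(groups_used) == 2


def test_same_seed_reproduces_identical_triple(small_family, small_pool):
    a = build_family_datasets("FAMX", small_family.members, small_pool, seed=9)
    b = build_family_datasets("FAMX", small_family.members, small_pool, seed=9)
    for (_, pa), (_, pb) in zip(a.parts(), b.parts()):
        assert [(r.id, lab) for r, lab in pa] == [(r.id, lab) for r, lab in pb]


def test_small_groups_contribute_what_they_have(small_family):
    # two size-2 groups (deal train, test) alongside two full-size groups
    pool = _pool(2, size=3)
    small = _pool(2, size=2, seed=99)
    for rec in small:
        rec.group_id = "S" + rec.group_id
        rec.id = "s_" + rec.id
    triple = build_family_datasets("FAMX", small_family.members, pool + small, seed=4)
    n_neg = [sum(1 for _, lab in part if lab == NEGATIVE) for _, part in triple.parts()]
    assert sum(n_neg) == 10  # 2x3 full groups + 2x2 short groups
    assert n_neg == [4, 4, 2]  # short groups dealt to train and test first


def test_all_short_groups_cannot_fill_independent_set(small_family):
    pool = _pool(3, size=2)
    with pytest.raises(DatasetConfigError, match="lacks one class"):
        build_family_datasets("FAMX", small_family.members, pool, seed=4)


def test_too_few_positives_rejected(small_pool):
    two = [ProteinRecord(id="a", sequence="MKVLAWGGMKVLAWGG"),
           ProteinRecord(id="b", sequence="MKVLAWGGMKVLAWGG")]  # dedups to 1
    with pytest.raises(DatasetConfigError, match=">= 3"):
        build_family_datasets("F", two, small_pool, seed=0)


def test_no_eligible_negative_group_rejected(small_family):
    pool = _pool(2)
    for rec in pool:
        rec.family_labels = {"FAMX"}
    with pytest.raises(DatasetConfigError, match="negative group"):
        build_family_datasets("FAMX", small_family.members, pool, seed=0)


def test_invariants_over_many_seeds(small_family, small_pool):
    """Disjointness, duplicate-freedom and balanced positive counts hold
    for every seed."""
    n_pos = len({r.sequence for r in small_family.members})
    for seed in range(100):
        triple = build_family_datasets("FAMX", small_family.members, small_pool, seed=seed)
        triple.validate()  # raises on duplicates / missing classes
        counts = [
            sum(1 for _, lab in part if lab == POSITIVE) for _, part in triple.parts()
        ]
        assert sum(counts) == n_pos
        assert max(counts) - min(counts) <= 1
        for _, part in triple.parts():
            for rec, lab in part:
                if lab == NEGATIVE:
                    assert rec.group_id is not None
                    assert "FAMX" not in rec.family_labels
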