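import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcbench.features import (
    EncodingError,
    MinMaxScaler,
    N_FEATURES,
    aa_composition,
    composition,
    distribution,
    encode,
    feature_names,
    groupings,
    scale_features,
    transition,
)
from funcbench.records import STANDARD_AA

seqs = st.text(alphabet=STANDARD_AA, min_size=2, max_size=60)


def test_groupings_partition_the_alphabet():
    gs = groupings()
    assert len(gs) == 8
    for g in gs:
        union = sorted("".join(sorted(grp)) for grp in g.groups)
        assert sorted("".join(union)) == sorted(STANDARD_AA)


def test_aa_composition_examples():
    v = aa_composition("AAAA")
    assert v[0] == 1.0 and v.sum() == 1.0
    v = aa_composition("ACAC")
    assert v[0] == 0.5 and v[1] == 0.5
    # nonstandard residues are skipped entirely
    assert aa_composition("AXA")[0] == 1.0


def test_charge_composition_hand_count(charge):
    v = composition("KKDD", charge)
    assert v == pytest.approx([0.5, 0.0, 0.5])
    v = composition("AAAA", charge)
    assert v == pytest.approx([0.0, 1.0, 0.0])


def test_charge_transition_hand_counts(charge):
    # pairs KK, KD, DD: one positive<->negative crossing out of three
    assert transition("KKDD", charge) == pytest.approx([0, 1 / 3, 0])
    assert transition("AAAAA", charge) == pytest.approx([0, 0, 0])
    # every adjacent pair crosses the positive/negative boundary
    assert transition("KDKDKD", charge) == pytest.approx([0, 1.0, 0])


def test_distribution_hand_example(charge):
    # positives K at 1-based positions {1,2} in a length-4 sequence
    d = distribution("KKDD", charge)
    assert d[0:5] == pytest.approx([25, 25, 25, 50, 50])
    # negatives D at {3,4}
    assert d[10:15] == pytest.approx([75, 75, 75, 100, 100])
    # absent neutral group reports zeros
    assert d[5:10] == pytest.approx([0, 0, 0, 0, 0])


def test_encoding_errors():
    with pytest.raises(EncodingError):
        encode("X")
    with pytest.raises(EncodingError):
        transition("K", groupings()[0])


def test_encode_layout_and_names():
    v = encode("MKVLAWGG")
    assert v.shape == (N_FEATURES,)
    assert len(feature_names()) == N_FEATURES
    assert encode("MKVLAWGG") == pytest.approx(v)  # pure function


@given(seq=seqs)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_composition_blocks_sum_to_one(seq):
    assert aa_composition(seq).sum() == pytest.approx(1.0, abs=1e-9)
    for g in groupings():
        assert composition(seq, g).sum() == pytest.approx(1.0, abs=1e-9)


@given(seq=seqs)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_transition_matches_brute_force(seq):
    g = groupings()[0]
    idx = g.group_of()
    pairs = list(zip(seq, seq[1:]))
    expected = np.zeros(3)
    order = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
    for a, b in pairs:
        ga, gb = idx[a], idx[b]
        if ga != gb:
            expected[order[(min(ga, gb), max(ga, gb))]] += 1
    assert transition(seq, g) == pytest.approx(expected / len(pairs))


@given(seq=seqs)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_distribution_quantiles_nondecreasing(seq):
    L = len(seq)
    for g in groupings():
        d = distribution(seq, g).reshape(3, 5)
        idx = g.group_of()
        for gi in range(3):
            vals = d[gi]
            assert np.all(np.diff(vals) >= -1e-12)
            positions = [p for p, aa in enumerate(seq, 1) if idx[aa] == gi]
            if positions:
                assert vals[4] == pytest.approx(100 * positions[-1] / L)
            else:
                assert vals == pytest.approx([0] * 5)


def test_permuting_residues_preserves_composition_features(rng):
    seq = "MKVLAWGGACDEFGHIKLMNPQRSTVWY"
    shuffled = "".join(rng.permutation(list(seq)))
    a, b = encode(seq), encode(shuffled)
    assert a[:20] == pytest.approx(b[:20])
    for p in range(8):
        base = 20 + 21 * p
        assert a[base : base + 3] == pytest.approx(b[base : base + 3])


def test_minmax_scaling_contract():
    train = np.array([[0.0, 5.0], [100.0, 5.0]])
    other = np.array([[50.0, 7.0]])
    (t, o), scaler = scale_features(train, other)
    assert t[:, 0] == pytest.approx([0.0, 1.0])
    assert t[:, 1] == pytest.approx([0.0, 0.0])  # constant column -> 0
    assert o[0, 0] == pytest.approx(0.5)
    assert scaler.transform(other) == pytest.approx(o)  # stable reapplication


def test_scaler_requires_fit():
    with pytest.raises(RuntimeError):
        MinMaxScaler().transform(np.zeros((1, 2)))
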