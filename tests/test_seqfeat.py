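"""Sequence descriptor blocks, PCA reduction and pair-vector assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrcomm import seqfeat
from lrcomm.seqfeat import (
    ALPHABET,
    CTD_PROPERTY_GROUPS,
    CTRIAD_CLASSES,
    ProteinRecord,
    encode_aac,
    encode_cksaap,
    encode_ctd,
    encode_ctriad,
    encode_protein,
    fit_pca,
    make_pair_vector,
    sanitize_sequence,
)

seq_strategy = st.text(alphabet=ALPHABET, min_size=8, max_size=60)


def random_seqs(n, rng, lo=8, hi=40):
    return [
        "".join(rng.choice(list(ALPHABET), size=rng.integers(lo, hi + 1)))
        for _ in range(n)
    ]


# ---------------------------------------------------------------- oracles
def cksaap_oracle(seq, gaps=range(6)):
    """Direct enumeration of gapped residue pairs."""
    out = []
    pairs = ["".join(p) for p in itertools.product(ALPHABET, repeat=2)]
    for k in gaps:
        counts = dict.fromkeys(pairs, 0)
        for i in range(len(seq) - k - 1):
            counts[seq[i] + seq[i + k + 1]] += 1
        out.extend(counts[p] / (len(seq) - k - 1) for p in pairs)
    return np.array(out)


def ctd_oracle(seq):
    """Direct lookup implementation of composition/transition/distribution."""
    L = len(seq)
    comp, trans, dist = [], [], []
    for groups in CTD_PROPERTY_GROUPS.values():
        gi = [next(g for g in range(3) if ch in groups[g]) for ch in seq]
        for g in range(3):
            comp.append(gi.count(g) / L)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            n = sum(
                1
                for x, y in zip(gi[:-1], gi[1:])
                if (x, y) in ((a, b), (b, a))
            )
            trans.append(n / (L - 1))
        for g in range(3):
            pos = [i + 1 for i, x in enumerate(gi) if x == g]
            if not pos:
                dist.extend([0.0] * 5)
                continue
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                rank = max(1, int(np.ceil(frac * len(pos))))
                dist.append(pos[rank - 1] / L * 100)
    return np.array(comp + trans + dist)


def ctriad_oracle(seq):
    cls = {aa: i for i, grp in enumerate(CTRIAD_CLASSES) for aa in grp}
    counts = np.zeros(343)
    for i in range(len(seq) - 2):
        a, b, c = cls[seq[i]], cls[seq[i + 1]], cls[seq[i + 2]]
        counts[a * 49 + b * 7 + c] += 1
    return counts / (len(seq) - 2)


# ------------------------------------------------------------- sanitize
def test_sanitize_folds_case_and_strips_noncanonical(caplog):
    assert sanitize_sequence("acde") == "ACDE"
    with caplog.at_level("WARNING"):
        assert sanitize_sequence("AXC") == "AC"
    assert "X" in caplog.text


def test_sanitize_rejects_fully_noncanonical():
    with pytest.raises(ValueError, match="rec1"):
        sanitize_sequence("UU", record_id="rec1")


def test_protein_record_rejects_raw_sequences():
    with pytest.raises(ValueError):
        ProteinRecord("p", "ACXDE")
    with pytest.raises(ValueError):
        ProteinRecord("p", "")


# ------------------------------------------------------------------ AAC
@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAAA", {"A": 1.0}),
        (ALPHABET, {aa: 0.05 for aa in ALPHABET}),
        ("GGGC", {"G": 0.75, "C": 0.25}),
    ],
)
def test_aac_hand_cases(seq, expected):
    v = encode_aac(seq)
    for i, aa in enumerate(ALPHABET):
        assert v[i] == pytest.approx(expected.get(aa, 0.0))


@settings(derandomize=True, max_examples=40)
@given(seq_strategy)
def test_aac_sums_to_one(seq):
    assert encode_aac(seq).sum() == pytest.approx(1.0)


# --------------------------------------------------------------- CKSAAP
def test_cksaap_hand_cases():
    v = encode_cksaap("AA", gaps=(0,))
    assert v[0] == 1.0 and v[1:].sum() == 0
    v = encode_cksaap("ACA", gaps=(1,))
    assert v[0] == 1.0 and v[1:].sum() == 0


def test_cksaap_rejects_too_short():
    with pytest.raises(ValueError, match="minimum"):
        encode_cksaap("ACDEFG")  # needs >= 7 for gap 5


def test_cksaap_matches_bruteforce_on_random_sequences():
    rng = np.random.default_rng(0)
    for seq in random_seqs(50, rng, lo=8, hi=30):
        np.testing.assert_allclose(encode_cksaap(seq), cksaap_oracle(seq))


@settings(derandomize=True, max_examples=30)
@given(seq_strategy)
def test_cksaap_gap_blocks_are_distributions(seq):
    v = encode_cksaap(seq)
    for b in range(6):
        assert v[b * 400 : (b + 1) * 400].sum() == pytest.approx(1.0)


# ------------------------------------------------------------------ CTD
def test_ctd_homopolymer():
    v = encode_ctd("A" * 10)
    comp, trans = v[:39], v[39:78]
    assert trans.sum() == 0
    # per property the composition of A's group is 1, others 0
    for pi, groups in enumerate(CTD_PROPERTY_GROUPS.values()):
        g_of_a = next(g for g in range(3) if "A" in groups[g])
        for g in range(3):
            assert comp[pi * 3 + g] == (1.0 if g == g_of_a else 0.0)


def test_ctd_matches_bruteforce_on_random_sequences():
    rng = np.random.default_rng(1)
    for seq in random_seqs(50, rng, lo=8, hi=30):
        np.testing.assert_allclose(encode_ctd(seq), ctd_oracle(seq))


@settings(derandomize=True, max_examples=30)
@given(seq_strategy)
def test_ctd_invariants(seq):
    v = encode_ctd(seq)
    comp, dist = v[:39], v[78:]
    assert np.all((dist >= 0) & (dist <= 100))
    for pi in range(13):
        assert comp[pi * 3 : pi * 3 + 3].sum() == pytest.approx(1.0)


def test_ctd_rejects_length_one():
    with pytest.raises(ValueError):
        encode_ctd("A")


# --------------------------------------------------------------- CTriad
def test_ctriad_homopolymer_single_entry():
    v = encode_ctriad("AAAA")
    cls_a = next(i for i, g in enumerate(CTRIAD_CLASSES) if "A" in g)
    code = cls_a * 49 + cls_a * 7 + cls_a
    assert v[code] == 1.0
    assert v.sum() == pytest.approx(1.0)


def test_ctriad_rejects_too_short():
    with pytest.raises(ValueError):
        encode_ctriad("AA")


def test_ctriad_matches_bruteforce_on_random_sequences():
    rng = np.random.default_rng(2)
    for seq in random_seqs(50, rng, lo=8, hi=30):
        np.testing.assert_allclose(encode_ctriad(seq), ctriad_oracle(seq))


# --------------------------------------------------------------- concat
def test_encode_protein_layout():
    rec = ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY" * 2)
    fv = encode_protein(rec)
    assert fv.values.shape == (3036,)
    np.testing.assert_array_equal(fv.values[:20], encode_aac(rec.sequence))
    spans = fv.block_layout
    assert spans["AAC"][1] - spans["AAC"][0] == 20
    assert spans["CKSAAP"][1] - spans["CKSAAP"][0] == 2400
    assert spans["CTD"][1] - spans["CTD"][0] == 273
    assert spans["CTriad"][1] - spans["CTriad"][0] == 343
    assert sum(hi - lo for lo, hi in spans.values()) == 3036


def test_encode_protein_propagates_errors_with_id():
    with pytest.raises(ValueError, match="short1"):
        encode_protein(ProteinRecord("short1", "ACDE"))


def test_feature_names_count():
    assert len(seqfeat.feature_names()) == 3036


# ------------------------------------------------------------------ PCA
def test_pca_transform_of_mean_is_zero():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 6))
    model = fit_pca(X, d=3)
    np.testing.assert_allclose(
        model.transform(X.mean(axis=0)), np.zeros((1, 3)), atol=1e-10
    )


def test_pca_rank2_reconstruction_matches_eigendecomposition():
    rng = np.random.default_rng(4)
    # rank-2 data in 3 dims
    basis = rng.normal(size=(2, 3))
    X = rng.normal(size=(30, 2)) @ basis
    model = fit_pca(X, d=2)
    recon = model.inverse_transform(model.transform(X))
    np.testing.assert_allclose(recon, X, atol=1e-8)
    # oracle: explicit eigendecomposition of the 3x3 covariance
    C = np.cov(X, rowvar=False, bias=False)
    evals = np.sort(np.linalg.eigvalsh(C))[::-1]
    np.testing.assert_allclose(model.explained_variance, evals[:2], atol=1e-8)


def test_pca_components_orthonormal_and_variance_decreasing():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 10)) * np.arange(1, 11)
    model = fit_pca(X, d=5)
    G = model.components @ model.components.T
    np.testing.assert_allclose(G, np.eye(5), atol=1e-8)
    assert np.all(np.diff(model.explained_variance) <= 1e-12)


def test_pca_reconstruction_error_nonincreasing_in_d():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 8))
    errs = []
    for d in (1, 3, 5, 8):
        m = fit_pca(X, d=d)
        errs.append(np.linalg.norm(X - m.inverse_transform(m.transform(X))))
    assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))


def test_pca_deterministic_and_roundtrips(tmp_path):
    rng = np.random.default_rng(7)
    X = rng.normal(size=(25, 6))
    m1, m2 = fit_pca(X, d=4), fit_pca(X, d=4)
    np.testing.assert_array_equal(m1.components, m2.components)
    path = tmp_path / "pca.npz"
    m1.save(path)
    m3 = seqfeat.PcaModel.load(path)
    np.testing.assert_array_equal(m1.components, m3.components)
    assert m3.d == 4


def test_pca_rejects_bad_d():
    X = np.eye(4)
    with pytest.raises(ValueError):
        fit_pca(X, d=9)


# --------------------------------------------------------- pair vectors
def test_pair_vector_concatenation_and_asymmetry():
    v = make_pair_vector([1, 2], [3, 4])
    np.testing.assert_array_equal(v, [1, 2, 3, 4])
    assert not np.array_equal(
        make_pair_vector([1, 2], [3, 4]), make_pair_vector([3, 4], [1, 2])
    )


def test_pair_vector_default_dim():
    rng = np.random.default_rng(8)
    l, r = rng.normal(size=200), rng.normal(size=200)
    assert make_pair_vector(l, r).size == 400


def test_pair_vector_rejects_mismatch():
    with pytest.raises(ValueError):
        make_pair_vector([1, 2], [3, 4, 5])
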