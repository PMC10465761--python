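"""KS enrichment statistic, connectivity scoring and the permutation null."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigreverse import (
    DiseaseSignature,
    PerturbationProfile,
    connectivity_score,
    ks_enrichment,
    permutation_null,
    score_library,
)
from sigreverse.errors import DisjointSignatureError


def ks_bruteforce(positions, n):
    """Independent plain-loop maximisation of the two running-sum deviations."""
    t = len(positions)
    a = max((j + 1) / t - positions[j] / n for j in range(t))
    b = max(positions[j] / n - j / t for j in range(t))
    return a if a >= b else -b


def block_profile(n, top=(), bottom=(), drug_id="d"):
    """Profile of n genes with named genes forced into top/bottom blocks."""
    genes = [f"g{i:04d}" for i in range(n - len(top) - len(bottom))]
    stats = {g: 0.0 for g in genes}
    stats.update({g: 10.0 - i * 1e-6 for i, g in enumerate(top)})
    stats.update({g: -10.0 - i * 1e-6 for i, g in enumerate(bottom)})
    return PerturbationProfile.from_stats(drug_id, stats)


@pytest.mark.parametrize(
    "positions, n, expected",
    [
        (range(1, 11), 100, 0.90),   # top block: 1 - t/n
        (range(91, 101), 100, -0.91),  # bottom block: -(1 - (t-1)/n)
        ([1], 1, -1.0),              # whole-list degenerate case: a=0, b=1/n
    ],
)
def test_ks_closed_form(positions, n, expected):
    assert ks_enrichment(list(positions), n) == pytest.approx(expected, abs=1e-12)


def test_ks_matches_bruteforce_exhaustively():
    """Statistic equals plain-loop maximisation for every tag set, t<=6, n<=12."""
    for n in range(1, 13):
        for t in range(1, min(6, n) + 1):
            for combo in itertools.combinations(range(1, n + 1), t):
                assert ks_enrichment(combo, n) == pytest.approx(
                    ks_bruteforce(list(combo), n), abs=1e-12
                )


@pytest.mark.parametrize(
    "positions, n",
    [([], 10), ([0, 2], 10), ([2, 2], 10), ([5, 11], 10), ([3, 2], 10)],
    ids=["empty", "below-range", "duplicate", "above-range", "decreasing"],
)
def test_ks_rejects_invalid_positions(positions, n):
    with pytest.raises(ValueError):
        ks_enrichment(positions, n)


@settings(max_examples=200, derandomize=True)
@given(st.data())
def test_ks_range_and_oracle_property(data):
    """ES lies in (-1, 1] and agrees with the brute-force oracle."""
    n = data.draw(st.integers(1, 30))
    t = data.draw(st.integers(1, n))
    positions = sorted(data.draw(st.permutations(range(1, n + 1)))[:t])
    es = ks_enrichment(positions, n)
    assert -1.0 <= es <= 1.0  # -1 only in the degenerate whole-list case
    assert es == pytest.approx(ks_bruteforce(positions, n), abs=1e-12)


def _signature(n_tags=10):
    ups = [f"up{i}" for i in range(n_tags)]
    downs = [f"dn{i}" for i in range(n_tags)]
    return DiseaseSignature(ups, downs)


def test_perfect_reverser_scores_negative():
    """Up tags at the bottom, down tags at the top -> negative class."""
    signat = _signature()
    profile = block_profile(100, top=signat.down_genes, bottom=signat.up_genes)
    rec = connectivity_score(signat, profile)
    assert rec.score < 0 and rec.cls == "negative"
    assert rec.n_matched_up == rec.n_matched_down == 10


def test_mimic_matches_block_closed_form():
    """Up tags top-10, down tags bottom-10 of n=100 -> (0.90 + 0.91)/2."""
    signat = _signature()
    profile = block_profile(100, top=signat.up_genes, bottom=signat.down_genes)
    rec = connectivity_score(signat, profile)
    assert rec.es_up == pytest.approx(0.90, abs=1e-12)
    assert rec.es_down == pytest.approx(-0.91, abs=1e-12)
    assert rec.score == pytest.approx(0.905, abs=1e-12)
    assert rec.cls == "positive"


def test_same_sign_enrichment_is_structural_zero():
    """Both tag sets at the top -> ES same sign -> score exactly 0."""
    signat = _signature()
    profile = block_profile(100, top=signat.up_genes + signat.down_genes)
    rec = connectivity_score(signat, profile)
    assert rec.es_up > 0 and rec.es_down > 0
    assert rec.score == 0.0 and rec.cls == "zero"


def test_disjoint_signature_raises():
    signat = _signature()
    profile = block_profile(50)  # no tag genes present
    with pytest.raises(DisjointSignatureError, match="disjoint signature"):
        connectivity_score(signat, profile)


def test_score_library_orders_reverser_first():
    signat = _signature()
    reverser = block_profile(100, top=signat.down_genes, bottom=signat.up_genes, drug_id="rev")
    mimic = block_profile(100, top=signat.up_genes, bottom=signat.down_genes, drug_id="mim")
    neutral = block_profile(100, top=signat.up_genes + signat.down_genes, drug_id="neu")
    result = score_library(signat, [mimic, neutral, reverser])
    assert [r.drug_id for r in result.records] == ["rev", "neu", "mim"]
    assert (result.n_negative, result.n_zero, result.n_positive) == (1, 1, 1)


def test_score_library_single_and_ties():
    signat = _signature()
    solo = block_profile(100, top=signat.down_genes, bottom=signat.up_genes, drug_id="only")
    assert len(score_library(signat, [solo]).records) == 1

    twin_a = block_profile(100, top=signat.down_genes, bottom=signat.up_genes, drug_id="b_twin")
    twin_b = block_profile(100, top=signat.down_genes, bottom=signat.up_genes, drug_id="a_twin")
    result = score_library(signat, [twin_a, twin_b])
    assert result.records[0].score == result.records[1].score
    assert [r.drug_id for r in result.records] == ["a_twin", "b_twin"]


def test_score_library_skips_disjoint_drugs():
    signat = _signature()
    good = block_profile(100, top=signat.down_genes, bottom=signat.up_genes, drug_id="good")
    bad = block_profile(50, drug_id="bad")
    result = score_library(signat, [good, bad])
    assert [r.drug_id for r in result.records] == ["good"]
    assert result.skipped[0][0] == "bad"


def test_score_bounded_for_random_profiles():
    rng = np.random.default_rng(5)
    signat = _signature()
    genes = signat.up_genes + signat.down_genes + [f"g{i}" for i in range(80)]
    for i in range(25):
        stats = dict(zip(genes, rng.normal(size=len(genes))))
        rec = connectivity_score(signat, PerturbationProfile.from_stats(f"d{i}", stats))
        assert -1.0 <= rec.score <= 1.0
        assert -1.0 < rec.es_up <= 1.0 and -1.0 < rec.es_down <= 1.0


def test_reversing_profile_flips_score_sign():
    """For block profiles, reversing the ranking negates the score within 2t/n."""
    signat = _signature()
    n, t = 200, 10
    forward = block_profile(n, top=signat.up_genes, bottom=signat.down_genes)
    reversed_stats = {g: -s for g, s in forward.stats.items()}
    backward = PerturbationProfile.from_stats("rev", reversed_stats)
    s_fwd = connectivity_score(signat, forward).score
    s_bwd = connectivity_score(signat, backward).score
    assert abs(s_fwd + s_bwd) <= 2 * t / n


def test_permutation_null_centred_and_reproducible():
    signat = _signature()
    rng = np.random.default_rng(9)
    genes = signat.up_genes + signat.down_genes + [f"g{i}" for i in range(180)]
    profile = PerturbationProfile.from_stats("d", dict(zip(genes, rng.normal(size=len(genes)))))
    summary = permutation_null(signat, profile, n_perm=1000, seed=4)
    assert abs(summary.mean) < 0.05
    assert summary == permutation_null(signat, profile, n_perm=1000, seed=4)


def test_permutation_null_extreme_for_perfect_reverser():
    signat = _signature()
    profile = block_profile(200, top=signat.down_genes, bottom=signat.up_genes)
    summary = permutation_null(signat, profile, n_perm=200, seed=0)
    assert summary.p_empirical <= 1 / 201 + 1e-12
    with pytest.raises(ValueError):
        permutation_null(signat, profile, n_perm=50, seed=0)
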