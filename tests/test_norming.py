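"""Normed variables: entropy, agreement, Zipf scale, weighted averages."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

import namingnorms as nn
from namingnorms.norming import EmptyImageError


def dist(counts: dict, n_invalid: int = 0, image_id: str = "img") -> nn.NameDistribution:
    n_all = sum(counts.values()) + n_invalid
    return nn.NameDistribution(image_id, counts, n_all)


FIXTURE_LEXICON = nn.Lexicon(
    {
        "sofa": 1_594_000,  # zipf ~ 3.9 at 1e9 tokens... raw counts are per corpus
        "cup": 10_000,
        "mug": 100_000,
        "jug": 100_000,
        "a": 1000, "b": 100, "c": 10,
    },
    corpus_tokens=1_000_000_000,
    bigram_counts={"fire engine": 1000},
)


# ---------------------------------------------------------------------------
# H-statistic and normalised H
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"a": 30}, 0.0),                 # unanimity
        ({"a": 16, "b": 16}, 1.0),        # uniform over two names
        ({"a": 2, "b": 1, "c": 1}, 1.5),  # 0.5*1 + 0.25*2 + 0.25*2
    ],
)
def test_h_statistic_worked_examples(counts, expected):
    assert nn.h_statistic(dist(counts)) == pytest.approx(expected, abs=1e-12)


def test_h_statistic_matches_entropy_oracle_on_random_vectors():
    """Direct summation agrees with scipy's entropy to 1e-12 on 1,000 vectors."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        k = int(rng.integers(1, 12))
        counts = rng.integers(1, 40, size=k)
        d = dist({f"n{i}": int(c) for i, c in enumerate(counts)})
        oracle = sps.entropy(counts, base=2)
        assert abs(nn.h_statistic(d) - oracle) <= 1e-12


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"a": 30}, 0.0),
        ({"a": 1, "b": 1, "c": 1, "d": 1}, 1.0),   # maximal diversity
        ({"a": 8, "b": 8, "c": 8, "d": 8}, 0.4),   # H=2 bits over log2(32)=5
    ],
)
def test_normalised_h_examples(counts, expected):
    assert nn.normalised_h(dist(counts)) == pytest.approx(expected, abs=1e-12)


@given(
    st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=12)
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_h_bounds_and_normalised_range(counts):
    d = dist({f"n{i}": c for i, c in enumerate(counts)})
    h = nn.h_statistic(d)
    assert 0.0 <= h <= math.log2(d.k) + 1e-12
    assert 0.0 <= nn.normalised_h(d) <= 1.0


@given(
    st.dictionaries(
        st.sampled_from(list("abcdef")),
        st.integers(min_value=1, max_value=30),
        min_size=1,
        max_size=5,
    )
)
@settings(max_examples=150, derandomize=True, deadline=None)
def test_splitting_off_a_new_name_never_decreases_h(counts):
    """Moving one response from the modal name to a fresh name cannot reduce H."""
    d = dist(dict(counts))
    modal, _, _ = nn.modal_name(d)
    before = nn.h_statistic(d)
    moved = dict(counts)
    moved[modal] -= 1
    if moved[modal] == 0:
        del moved[modal]
    moved["zz_new"] = moved.get("zz_new", 0) + 1
    after = nn.h_statistic(dist(moved))
    assert after >= before - 1e-12


# ---------------------------------------------------------------------------
# Tallying and the modal name
# ---------------------------------------------------------------------------

def test_tally_names_counts_valid_only():
    coded = pd.DataFrame(
        {
            "image_id": ["i"] * 32,
            "canonical_name": ["dog"] * 20 + ["puppy"] * 8 + [None] * 4,
            "include_in_H": [True] * 28 + [False] * 4,
        }
    )
    d = nn.tally_names(coded)
    assert d.counts == {"dog": 20, "puppy": 8}
    assert d.k == 2 and d.n_valid == 28 and d.n_all_responses == 32


def test_tally_empty_image_raises():
    with pytest.raises(EmptyImageError):
        nn.tally_names(pd.DataFrame(columns=["image_id", "canonical_name",
                                             "include_in_H"]), image_id="x")


def test_modal_name_agreement_uses_all_responses():
    name, agreement, freq = nn.modal_name(dist({"dog": 20, "puppy": 8}, n_invalid=4))
    assert (name, agreement, freq) == ("dog", 62.5, 20)


def test_modal_name_unanimity():
    assert nn.modal_name(dist({"glass": 32})) == ("glass", 100.0, 32)


def test_modal_tie_breaks_on_zipf_then_alphabetical():
    # mug has the higher fixture Zipf than cup
    name, _, _ = nn.modal_name(dist({"cup": 10, "mug": 10}), FIXTURE_LEXICON)
    assert name == "mug"
    # equal Zipf (jug == mug): alphabetical wins
    name, _, _ = nn.modal_name(dist({"mug": 10, "jug": 10}), FIXTURE_LEXICON)
    assert name == "jug"
    # no lexicon at all: alphabetical
    assert nn.modal_name(dist({"b": 5, "a": 5}))[0] == "a"


# ---------------------------------------------------------------------------
# Zipf scale
# ---------------------------------------------------------------------------

def test_zipf_scale_definition():
    assert nn.zipf_unigram(1, 100_000_000) == pytest.approx(1.0, abs=1e-12)
    assert nn.zipf_unigram(1, 100) == pytest.approx(7.0, abs=1e-12)
    assert nn.zipf_unigram(1, 1_000_000) == pytest.approx(3.0, abs=1e-12)


def test_zipf_bigram_same_scale_and_log_law():
    assert nn.zipf_bigram(1, 100_000_000) == pytest.approx(1.0, abs=1e-12)
    assert nn.zipf_bigram(1000, 10**9) == pytest.approx(3.0, abs=1e-12)
    base = nn.zipf_unigram(42, 10**9)
    assert nn.zipf_unigram(420, 10**9) == pytest.approx(base + 1.0, abs=1e-12)


def test_zipf_zero_count_is_missing_not_zero():
    assert math.isnan(nn.zipf_unigram(0, 10**9))
    with pytest.raises(ValueError):
        nn.zipf_unigram(1, 0)


def test_lexicon_lookup_and_tsv_round_trip(tmp_path):
    FIXTURE_LEXICON.to_tsv(tmp_path / "uni.tsv", tmp_path / "bi.tsv")
    again = nn.Lexicon.from_tsv(tmp_path / "uni.tsv", 10**9, tmp_path / "bi.tsv")
    assert again.zipf("fire engine") == pytest.approx(3.0, abs=1e-12)
    assert again.zipf("mug") == FIXTURE_LEXICON.zipf("mug")
    assert math.isnan(again.zipf("absent"))


# ---------------------------------------------------------------------------
# Word length and weighted lexical variables
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name, expected",
    [("palm tree", 8), ("can", 3), ("fire engine", 10)],
)
def test_word_length_excludes_spaces(name, expected):
    assert nn.word_length(name) == expected


def test_word_length_empty_raises():
    with pytest.raises(ValueError):
        nn.word_length("   ")


def test_weighted_lexical_examples():
    lex = nn.Lexicon({"sofa": 15_849}, 10**9)  # zipf ~ 4.2
    wz, wl = nn.weighted_lexical(dist({"sofa": 30}), lex)
    assert wz == pytest.approx(math.log10(15_849), abs=1e-12)
    assert wl == 4.0

    # singleton b is excluded entirely
    lex2 = nn.Lexicon({"aaa": 10_000, "bbbbbbbbb": 100}, 10**9)
    wz, wl = nn.weighted_lexical(dist({"aaa": 3, "bbbbbbbbb": 1}), lex2)
    assert wz == pytest.approx(4.0, abs=1e-12)
    assert wl == pytest.approx(3.0, abs=1e-12)

    # equal weights average the Zipf values
    lex3 = nn.Lexicon({"aaa": 10_000, "bb": 100}, 10**9)
    wz, _ = nn.weighted_lexical(dist({"aaa": 3, "bb": 3}), lex3)
    assert wz == pytest.approx(3.0, abs=1e-12)


def test_weighted_length_does_not_require_lexicon_presence():
    lex = nn.Lexicon({"aaa": 10_000}, 10**9)
    wz, wl = nn.weighted_lexical(dist({"aaa": 2, "zzzz": 2}), lex)
    assert wz == pytest.approx(4.0, abs=1e-12)  # only aaa has a frequency
    assert wl == pytest.approx(3.5, abs=1e-12)  # both count for length


def test_weighted_all_excluded_gives_missing():
    lex = nn.Lexicon({"aaa": 10}, 10**9)
    wz, wl = nn.weighted_lexical(dist({"x": 1, "y": 1}), lex)
    assert math.isnan(wz) and math.isnan(wl)


@given(
    st.dictionaries(
        st.sampled_from(["aa", "bbb", "cccc", "ddddd", "eee"]),
        # counts >= 2 keep the singleton-exclusion set fixed under scaling
        st.integers(min_value=2, max_value=20),
        min_size=1,
        max_size=5,
    ),
    st.integers(min_value=2, max_value=5),
)
@settings(max_examples=150, derandomize=True, deadline=None)
def test_weighted_values_are_convex_and_scale_invariant(counts, scale):
    lex = nn.Lexicon({"aa": 10**7, "bbb": 10**5, "cccc": 10**3, "eee": 10**6}, 10**9)
    d = dist(dict(counts))
    wz, wl = nn.weighted_lexical(d, lex)
    retained = [n for n, c in counts.items() if c >= 2]
    with_freq = [n for n in retained if n in lex]
    if with_freq:
        vals = [lex.zipf(n) for n in with_freq]
        assert min(vals) - 1e-12 <= wz <= max(vals) + 1e-12
    else:
        assert math.isnan(wz)
    if retained:
        lens = [nn.word_length(n) for n in retained]
        assert min(lens) - 1e-12 <= wl <= max(lens) + 1e-12
    # invariance under scaling all counts by a constant
    scaled = dist({n: c * scale for n, c in counts.items()})
    wz2, wl2 = nn.weighted_lexical(scaled, lex)
    if with_freq:
        assert wz2 == pytest.approx(wz, rel=1e-12)
    if retained:
        assert wl2 == pytest.approx(wl, rel=1e-12)


# ---------------------------------------------------------------------------
# Norms table
# ---------------------------------------------------------------------------

def test_unanimous_study_norms_are_degenerate():
    study = nn.simulate_study(
        design=__import__("conftest").SMALL_DESIGN,
        rt_model=nn.RTModel(slope_per_H=0.0, participant_sd=0.0, residual_sd=0.0,
                            p_long_outlier=0.0, p_short_outlier=0.0),
        noise=nn.NoiseConfig(0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        seed=33,
        n_candidates=1,
    )
    coded = nn.code_trials(study.trials, study.resources)
    retained, _ = nn.trim_rts(coded)
    norms, summary = nn.compile_image_norms(
        coded, study.lexicon, nn.image_mean_rt(retained)
    )
    assert (norms["agreement_pct"] == 100.0).all()
    assert (norms["h_bits"] == 0.0).all()
    assert (norms["h_normalised"] == 0.0).all()
    assert summary.loc["h_bits", "sd"] == 0.0
    assert np.allclose(norms["weighted_zipf"], norms["modal_zipf"], atol=1e-12)


def test_norms_table_structure_and_bounds(default_norms):
    norms = default_norms["norms"]
    assert len(norms) == 800
    assert norms["agreement_pct"].between(0, 100).all()
    assert (norms["h_bits"] >= 0).all()
    assert norms["h_normalised"].between(0, 1).all()
    assert (norms["modal_production_frequency"] >= 1).all()
    # alternative names serialised in descending frequency
    row = norms.loc[norms["k_names"] > 2].iloc[0]
    freqs = [int(p.split(":")[1]) for p in row["alternative_names"].split(";")]
    assert freqs == sorted(freqs, reverse=True)
    assert row["modal_production_frequency"] >= freqs[0]
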