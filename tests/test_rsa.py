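"""Exact-enumeration listener models against hand derivations and an
independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pragint.rsa import (
    Lexicon,
    Referent,
    Utterance,
    lesion_no_common_ground,
    lesion_no_speaker_informativeness,
    literal_listener,
    p_novel_pragmatic,
    pragmatic_listener,
    speaker,
)

NOV, FAM = Referent.NOVEL, Referent.FAMILIAR
NW, FW = Utterance.NOVEL_WORD, Utterance.FAMILIAR_WORD


# -- independent oracle: explicit tables, explicit normalization ------------


def oracle_p_novel(u, alpha, theta, prior):
    """Brute-force L1: enumerate lexica/referents/utterances from raw truth
    tables and normalize explicitly.  Kept deliberately separate from the
    library's enumeration."""
    # truth[lexicon][utterance] = (value on NOVEL, value on FAMILIAR)
    truth = {
        "known": {"nw": (1, 1), "fw": (0, 1)},
        "unknown": {"nw": (1, 1), "fw": (0, 0)},
    }
    uu = "nw" if u is NW else "fw"

    def l0(utt, lex):
        row = truth[lex][utt]
        s = sum(row)
        return (0.5, 0.5) if s == 0 else (row[0] / s, row[1] / s)

    def s1(r_idx, lex):
        scores = []
        for utt in ("nw", "fw"):
            scores.append(l0(utt, lex)[r_idx] ** alpha)
        z = sum(scores)
        if z == 0:
            return {"nw": 0.5, "fw": 0.5}
        return {"nw": scores[0] / z, "fw": scores[1] / z}

    weights = []
    for r_idx, pr in ((0, prior), (1, 1 - prior)):
        like = theta * s1(r_idx, "known")[uu] + (1 - theta) * s1(r_idx, "unknown")[uu]
        weights.append(pr * like)
    z = sum(weights)
    if z == 0:
        return 0.5
    return weights[0] / z


# -- literal listener -------------------------------------------------------


@pytest.mark.parametrize(
    "u, lex, expected",
    [
        (NW, Lexicon.known(), (0.5, 0.5)),
        (FW, Lexicon.known(), (0.0, 1.0)),
        (FW, Lexicon.unknown(), (0.5, 0.5)),  # no literal information
        (NW, Lexicon.unknown(), (0.5, 0.5)),
    ],
)
def test_literal_listener_truth_conditions(u, lex, expected):
    d = literal_listener(u, lex)
    assert (d.p_novel, d.p_familiar) == pytest.approx(expected)


# -- speaker ----------------------------------------------------------------


@pytest.mark.parametrize(
    "r, alpha, p_novel_word",
    [
        (NOV, 1.0, 1.0),  # 0.5 vs 0 -> always the novel word
        (FAM, 1.0, 1 / 3),  # 0.5 vs 1 -> 0.5 / 1.5
        (FAM, 0.0, 0.5),  # alpha = 0 flattens everything
    ],
)
def test_speaker_known_lexicon(r, alpha, p_novel_word):
    assert speaker(r, alpha, Lexicon.known())[NW] == pytest.approx(p_novel_word)


def test_speaker_rejects_negative_alpha():
    with pytest.raises(ValueError):
        speaker(NOV, -0.1, Lexicon.known())


# -- pragmatic listener ------------------------------------------------------


@pytest.mark.parametrize(
    "alpha, theta, prior, expected",
    [
        (1.0, 1.0, 0.5, 0.75),  # hand enumeration: 0.5 / (0.5 + 0.5/3)
        (1.0, 1.0, 0.88, 0.88 / (0.88 + 0.12 / 3)),  # ~0.957
        (2.5, 0.0, 0.7, 0.7),  # no lexical knowledge: posterior = prior
        (0.0, 0.6, 0.3, 0.3),  # uninformative speaker: posterior = prior
    ],
)
def test_pragmatic_listener_values(alpha, theta, prior, expected):
    d = pragmatic_listener(NW, alpha, theta, prior)
    assert d.p_novel == pytest.approx(expected, abs=1e-12)


def test_lesions_match_their_definitions():
    assert lesion_no_speaker_informativeness(0.7).p_novel == 0.7
    assert lesion_no_speaker_informativeness(1.0).p_novel == 1.0
    assert lesion_no_common_ground(NW, 1.0, 1.0).p_novel == pytest.approx(0.75)
    assert lesion_no_common_ground(NW, 1.0, 0.0).p_novel == pytest.approx(0.5)


@given(
    alpha=st.floats(0, 8, allow_nan=False),
    theta=st.floats(0, 1, allow_nan=False),
    prior=st.floats(0, 1, allow_nan=False),
)
@settings(deadline=None, max_examples=200)
def test_listener_distributions_normalize(alpha, theta, prior):
    for u in (NW, FW):
        d = pragmatic_listener(u, alpha, theta, prior)
        assert abs(d.p_novel + d.p_familiar - 1.0) < 1e-10
        assert d.p_novel >= 0 and d.p_familiar >= 0


def test_lesion_identities_on_grid():
    """alpha=0 reduces the rational listener to the prior-only lesion, and a
    flat prior reduces it to the no-common-ground lesion."""
    thetas = np.linspace(0, 1, 21)
    priors = np.linspace(0, 1, 21)
    for theta in thetas:
        for prior in priors:
            rational = pragmatic_listener(NW, 0.0, theta, prior)
            assert rational.p_novel == pytest.approx(
                lesion_no_speaker_informativeness(prior).p_novel, abs=1e-12
            )
    for alpha in np.linspace(0, 5, 21):
        for theta in thetas:
            rational = pragmatic_listener(NW, alpha, theta, 0.5)
            assert rational.p_novel == pytest.approx(
                lesion_no_common_ground(NW, alpha, theta).p_novel, abs=1e-12
            )


def test_monotone_in_theta_and_alpha():
    """More lexical knowledge and a more informative speaker both strengthen
    the novel-word -> novel-object inference."""
    grid = np.linspace(0, 1, 20)
    for alpha in (0.5, 1.0, 2.0):
        p = [pragmatic_listener(NW, alpha, t, 0.5).p_novel for t in grid]
        assert np.all(np.diff(p) >= -1e-12)
    for theta in (0.3, 0.7, 1.0):
        p = [pragmatic_listener(NW, a, theta, 0.5).p_novel for a in np.linspace(0, 6, 20)]
        assert np.all(np.diff(p) >= -1e-12)


def test_matches_bruteforce_oracle_on_grid():
    alphas = np.linspace(0, 4, 20)
    thetas = np.linspace(0, 1, 20)
    priors = np.linspace(0.05, 0.95, 5)
    for a in alphas:
        for t in thetas:
            for pr in priors:
                expect = oracle_p_novel(NW, a, t, pr)
                assert pragmatic_listener(NW, a, t, pr).p_novel == pytest.approx(
                    expect, abs=1e-10
                )
                assert float(p_novel_pragmatic(a, t, pr)) == pytest.approx(expect, abs=1e-10)


def test_vectorized_matches_scalar_for_familiar_word():
    for a in (0.0, 1.0, 2.3):
        for t in (0.0, 0.4, 1.0):
            for pr in (0.2, 0.5, 0.9):
                scalar = pragmatic_listener(FW, a, t, pr).p_novel
                vec = float(p_novel_pragmatic(a, t, pr, u=FW))
                assert vec == pytest.approx(scalar, abs=1e-12)


def test_lexicon_invariants_enforced():
    with pytest.raises(ValueError):
        Lexicon(
            {
                (NW, NOV): 0,
                (NW, FAM): 1,
                (FW, NOV): 0,
                (FW, FAM): 1,
            }
        )
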