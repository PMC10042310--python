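"""Rational Speech Act listener models for the two-object reference game.

The world contains exactly two candidate referents — a novel object and a
familiar object — and two utterance alternatives: a novel (nonce) word and
the familiar object's conventional label.  A pragmatic listener (L1) infers
the intended referent of an utterance by inverting a speaker model (S1) that
soft-maximizes informativity with respect to a literal listener (L0), and by
weighing the result against a contextual prior over referents.

Semantic knowledge enters through lexical uncertainty: the listener is
unsure whether the (modeled) literal listener has acquired the familiar
word's meaning.  With probability ``theta`` the literal listener interprets
words under the *known* lexicon (familiar word true of the familiar object
only); otherwise under the *unknown* lexicon (familiar word true of
nothing).  The novel word is literally true of both objects in every
lexicon, so all of its interpretive content is pragmatic.

Everything here is computed by exact enumeration over the discrete world
(2 referents x 2 utterances x 2 lexica); no sampling is involved.  Two
lesioned listeners are provided for model comparison: one that ignores
speaker informativeness (returns the prior) and one that ignores common
ground (uses a uniform prior).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "Referent",
    "Utterance",
    "Lexicon",
    "ReferentDist",
    "literal_listener",
    "speaker",
    "pragmatic_listener",
    "lesion_no_speaker_informativeness",
    "lesion_no_common_ground",
    "p_novel_pragmatic",
]

_ATOL = 1e-10


class Referent(enum.Enum):
    NOVEL = "novel"
    FAMILIAR = "familiar"


class Utterance(enum.Enum):
    NOVEL_WORD = "novel_word"
    FAMILIAR_WORD = "familiar_word"


@dataclass(frozen=True)
class Lexicon:
    """Boolean truth-conditional lexicon over (utterance, referent) pairs.

    The novel word is true of both objects in every admissible lexicon; the
    familiar word is true of the familiar object only (known lexicon) or of
    neither object (unknown lexicon, i.e. the word carries no meaning for
    the literal listener).
    """

    truth: Mapping[tuple[Utterance, Referent], int]

    def __post_init__(self) -> None:
        for u in Utterance:
            for r in Referent:
                if (u, r) not in self.truth:
                    raise ValueError(f"lexicon missing entry for ({u}, {r})")
        if not (
            self.truth[(Utterance.NOVEL_WORD, Referent.NOVEL)] == 1
            and self.truth[(Utterance.NOVEL_WORD, Referent.FAMILIAR)] == 1
        ):
            raise ValueError("novel word must be true of both referents")
        if self.truth[(Utterance.FAMILIAR_WORD, Referent.NOVEL)] != 0:
            raise ValueError("familiar word may not be true of the novel referent")

    @staticmethod
    def known() -> "Lexicon":
        """Lexicon of a literal listener who has acquired the familiar word."""
        return Lexicon(
            {
                (Utterance.NOVEL_WORD, Referent.NOVEL): 1,
                (Utterance.NOVEL_WORD, Referent.FAMILIAR): 1,
                (Utterance.FAMILIAR_WORD, Referent.NOVEL): 0,
                (Utterance.FAMILIAR_WORD, Referent.FAMILIAR): 1,
            }
        )

    @staticmethod
    def unknown() -> "Lexicon":
        """Lexicon of a literal listener for whom the familiar word is meaningless."""
        return Lexicon(
            {
                (Utterance.NOVEL_WORD, Referent.NOVEL): 1,
                (Utterance.NOVEL_WORD, Referent.FAMILIAR): 1,
                (Utterance.FAMILIAR_WORD, Referent.NOVEL): 0,
                (Utterance.FAMILIAR_WORD, Referent.FAMILIAR): 0,
            }
        )


@dataclass(frozen=True)
class ReferentDist:
    """Normalized probability distribution over the two referents."""

    p_novel: float
    p_familiar: float

    def __post_init__(self) -> None:
        if self.p_novel < -_ATOL or self.p_familiar < -_ATOL:
            raise ValueError("negative probability")
        if abs(self.p_novel + self.p_familiar - 1.0) > _ATOL:
            raise ValueError("referent distribution does not sum to 1")

    def __getitem__(self, r: Referent) -> float:
        return self.p_novel if r is Referent.NOVEL else self.p_familiar

    def as_array(self) -> np.ndarray:
        return np.array([self.p_novel, self.p_familiar])


def _normalize(scores: dict) -> dict:
    total = sum(scores.values())
    if total == 0.0:
        n = len(scores)
        return {k: 1.0 / n for k in scores}
    return {k: v / total for k, v in scores.items()}


def literal_listener(u: Utterance, lex: Lexicon) -> ReferentDist:
    """L0: interpret ``u`` purely by its truth conditions under ``lex``.

    Probability is proportional to the truth value; an utterance true of no
    referent carries no literal information and yields a uniform
    distribution.
    """
    scores = {r: float(lex.truth[(u, r)]) for r in Referent}
    p = _normalize(scores)
    return ReferentDist(p[Referent.NOVEL], p[Referent.FAMILIAR])


def speaker(r: Referent, alpha: float, lex: Lexicon) -> dict[Utterance, float]:
    """S1: choose an utterance in proportion to its informativity^alpha.

    Informativity of ``u`` for referent ``r`` is the probability L0 assigns
    to ``r`` after hearing ``u``.  ``alpha`` >= 0 controls how strongly the
    speaker prefers informative utterances; alpha = 0 yields a uniform
    (uninformative) speaker.  The corner convention 0**0 = 1 makes the
    alpha -> 0 limit continuous.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    scores = {}
    for u in Utterance:
        informativity = literal_listener(u, lex)[r]
        scores[u] = float(informativity) ** alpha  # numpy/python: 0.0**0 == 1.0
    return _normalize(scores)


def pragmatic_listener(
    u: Utterance, alpha: float, theta: float, prior: float
) -> ReferentDist:
    """L1: the rational-integration listener (focal model).

    Marginalizes the speaker over lexical uncertainty — with probability
    ``theta`` the speaker addresses a literal listener who knows the
    familiar word (known lexicon), else one who does not — and multiplies
    by the common-ground prior::

        P(r | u) \\propto prior(r) * [theta * S1(u | r, known)
                                      + (1 - theta) * S1(u | r, unknown)]

    Parameters
    ----------
    u : utterance heard by the listener.
    alpha : nonnegative speaker-informativeness exponent.
    theta : probability in [0, 1] that the familiar word is acquired.
    prior : prior probability that the NOVEL referent is intended.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if not 0.0 <= prior <= 1.0:
        raise ValueError(f"prior must be in [0, 1], got {prior}")
    s_known = {r: speaker(r, alpha, Lexicon.known()) for r in Referent}
    s_unknown = {r: speaker(r, alpha, Lexicon.unknown()) for r in Referent}
    prior_of = {Referent.NOVEL: prior, Referent.FAMILIAR: 1.0 - prior}
    scores = {
        r: prior_of[r] * (theta * s_known[r][u] + (1.0 - theta) * s_unknown[r][u])
        for r in Referent
    }
    p = _normalize(scores)
    return ReferentDist(p[Referent.NOVEL], p[Referent.FAMILIAR])


def lesion_no_speaker_informativeness(prior: float) -> ReferentDist:
    """Lesioned listener that ignores the speaker (alpha = 0 limit).

    With an uninformative speaker the likelihood term is constant, so the
    posterior over referents is exactly the common-ground prior.
    """
    if not 0.0 <= prior <= 1.0:
        raise ValueError(f"prior must be in [0, 1], got {prior}")
    return ReferentDist(prior, 1.0 - prior)


def lesion_no_common_ground(u: Utterance, alpha: float, theta: float) -> ReferentDist:
    """Lesioned listener that ignores common ground: uniform prior.

    Identical to :func:`pragmatic_listener` with prior 0.5 — the listener
    runs the full mutual-exclusivity inference but cannot differentiate
    discourse conditions.
    """
    return pragmatic_listener(u, alpha, theta, prior=0.5)


def p_novel_pragmatic(alpha, theta, prior, u: Utterance = Utterance.NOVEL_WORD):
    """Vectorized p(NOVEL | u) under the rational-integration listener.

    Broadcasts ``alpha``, ``theta`` and ``prior`` (arrays or scalars) and
    performs the same exact enumeration as :func:`pragmatic_listener` with
    numpy arithmetic.  Used by the likelihood and prediction layers where
    per-trial scalar enumeration would be too slow.
    """
    alpha = np.asarray(alpha, dtype=float)
    theta = np.asarray(theta, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("alpha must be nonnegative")

    # L0 truth-conditional interpretation probabilities, per lexicon.
    # Known lexicon: novel word -> (.5, .5); familiar word -> (0, 1).
    # Unknown lexicon: both words uninformative -> (.5, .5).
    half_a = 0.5**alpha
    # S1(u | r) under the known lexicon, enumerating both utterances:
    #   r = NOVEL:    scores (0.5^a for novel word, 0^a for familiar word)
    #   r = FAMILIAR: scores (0.5^a, 1)
    zero_a = np.where(alpha == 0, 1.0, 0.0)  # 0**0 := 1
    if u is Utterance.NOVEL_WORD:
        s_known_nov = half_a / (half_a + zero_a)
        s_known_fam = half_a / (half_a + 1.0)
        s_unknown = 0.5  # all informativities equal -> uniform speaker
    else:
        s_known_nov = zero_a / (half_a + zero_a)
        s_known_fam = 1.0 / (half_a + 1.0)
        s_unknown = 0.5
    like_nov = theta * s_known_nov + (1.0 - theta) * s_unknown
    like_fam = theta * s_known_fam + (1.0 - theta) * s_unknown
    w_nov = prior * like_nov
    w_fam = (1.0 - prior) * like_fam
    total = w_nov + w_fam
    # Zero total mass (e.g. prior 1 with zero likelihood) -> uniform fallback.
    return np.where(total > 0, w_nov / np.where(total > 0, total, 1.0), 0.5)
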