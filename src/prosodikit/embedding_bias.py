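"""Valence bias of words in an embedding space.

A word's linguistic valence bias is quantified as the standardized
difference (Hedges g) between its cosine similarities to a set of positive
attribute words (freedom, health, love, …) and a set of negative attribute
words (filth, death, vomit, …). Positive g means the word keeps positive
company in the training corpus of the vectors; the 95% CI uses the normal
approximation g ± 1.96·SE (a noncentral-t interval is available behind a
flag).

Similarity samples pool every (inflected form × attribute word) cosine as
one observation; out-of-vocabulary forms and attributes are dropped and
reported, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import math

import numpy as np
from scipy import stats

from .errors import DomainError
from .io_formats import EmbeddingSpace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributeSets:
    """Positive and negative attribute word lists (disjoint, nonempty)."""

    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = tuple(w.lower() for w in self.positive)
        neg = tuple(w.lower() for w in self.negative)
        if not pos or not neg:
            raise ValueError("attribute sets must be nonempty")
        if set(pos) & set(neg):
            raise ValueError("attribute sets must be disjoint")
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)

    def swapped(self) -> "AttributeSets":
        return AttributeSets(positive=self.negative, negative=self.positive)


@dataclass(frozen=True)
class BiasResult:
    """Hedges-g valence bias of a word or word group.

    Positive g ⇒ positive-leaning. ``degenerate`` flags zero pooled
    variance with unequal means (g undefined, reported as ±inf).
    """

    target_words: tuple[str, ...]
    n_pos: int
    n_neg: int
    mean_pos: float
    mean_neg: float
    g: float
    ci_low: float
    ci_high: float
    oov: tuple[str, ...] = ()
    degenerate: bool = False


# Default inflected-form generation for verbs: {base, -s, -ed, -ing} with a
# small irregulars table; callers can pass explicit forms per word instead.
IRREGULAR_FORMS: dict[str, tuple[str, ...]] = {
    "be": ("be", "is", "was", "being"),
    "have": ("have", "has", "had", "having"),
    "do": ("do", "does", "did", "doing"),
    "go": ("go", "goes", "went", "going"),
    "make": ("make", "makes", "made", "making"),
    "take": ("take", "takes", "took", "taking"),
    "give": ("give", "gives", "gave", "giving"),
    "ease": ("ease", "eases", "eased", "easing"),
    "cause": ("cause", "causes", "caused", "causing"),
    "restore": ("restore", "restores", "restored", "restoring"),
    "guarantee": ("guarantee", "guarantees", "guaranteed", "guaranteeing"),
    "provide": ("provide", "provides", "provided", "providing"),
}


def verb_forms(word: str) -> tuple[str, ...]:
    """Default four-form inflection set {base, -s, -ed, -ing}."""
    word = word.lower()
    if word in IRREGULAR_FORMS:
        return IRREGULAR_FORMS[word]
    if word.endswith("e"):
        stem = word[:-1]
        return (word, word + "s", stem + "ed", stem + "ing")
    if word.endswith(("s", "x", "z", "ch", "sh")):
        return (word, word + "es", word + "ed", word + "ing")
    if word.endswith("y") and len(word) > 1 and word[-2] not in "aeiou":
        return (word, word[:-1] + "ies", word[:-1] + "ied", word + "ing")
    return (word, word + "s", word + "ed", word + "ing")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [−1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DomainError(f"dimension mismatch {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DomainError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def attribute_similarities(
    forms: list[str] | tuple[str, ...],
    space: EmbeddingSpace,
    sets: AttributeSets,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Cosine-similarity samples of the found forms against each attribute set.

    Returns ``(pos_sample, neg_sample, oov)`` where each sample pools one
    cosine per (found form × found attribute) pair.
    """
    forms = [f.lower() for f in forms]
    found = [f for f in forms if f in space]
    oov = tuple(f for f in forms if f not in space)
    if not found:
        raise DomainError(f"all forms out of vocabulary: {forms}")
    pos_attrs = [a for a in sets.positive if a in space]
    neg_attrs = [a for a in sets.negative if a in space]
    oov = oov + tuple(a for a in sets.positive + sets.negative if a not in space)
    if not pos_attrs or not neg_attrs:
        raise DomainError("an attribute set has no in-vocabulary member")
    if oov:
        logger.info("%d out-of-vocabulary forms/attributes dropped", len(oov))

    form_mat = np.stack([space[f] for f in found]).astype(float)
    form_mat /= np.linalg.norm(form_mat, axis=1, keepdims=True)

    def sims(attrs: list[str]) -> np.ndarray:
        mat = np.stack([space[a] for a in attrs]).astype(float)
        mat /= np.linalg.norm(mat, axis=1, keepdims=True)
        return (form_mat @ mat.T).ravel()

    return sims(pos_attrs), sims(neg_attrs), oov


def hedges_g(
    sample1: np.ndarray, sample2: np.ndarray, ci_method: str = "normal"
) -> tuple[float, float, float, bool]:
    """Bias-corrected standardized mean difference with a 95% CI.

    d = (mean1 − mean2)/s_pooled, g = J·d with the small-sample correction
    J = 1 − 3/(4(n1+n2−2)−1); SE² = (n1+n2)/(n1·n2) + g²/(2(n1+n2−2)).
    Returns ``(g, ci_low, ci_high, degenerate)``; equal constant samples
    give g = 0, unequal-mean zero-variance samples give ±inf flagged
    degenerate.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DomainError("both samples must have size >= 2")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    )
    diff = x.mean() - y.mean()
    if s_pooled == 0.0:
        if diff == 0.0:
            return 0.0, 0.0, 0.0, False
        g = math.inf if diff > 0 else -math.inf
        return g, g, g, True
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = correction * diff / s_pooled
    se = math.sqrt((n1 + n2) / (n1 * n2) + g * g / (2.0 * df))
    if ci_method == "normal":
        half = 1.959963984540054 * se
        return g, g - half, g + half, False
    if ci_method == "noncentral-t":
        # CI on the noncentrality parameter of t = d/sqrt(1/n1+1/n2), mapped
        # back to the g scale.
        scale = math.sqrt(1.0 / n1 + 1.0 / n2)
        t_obs = (g / correction) / scale
        lo = _ncp_ci_bound(t_obs, df, 0.975)
        hi = _ncp_ci_bound(t_obs, df, 0.025)
        return g, correction * lo * scale, correction * hi * scale, False
    raise ValueError("ci_method must be 'normal' or 'noncentral-t'")


def _ncp_ci_bound(t_obs: float, df: int, prob: float) -> float:
    from scipy.optimize import brentq

    def fn(nc: float) -> float:
        return stats.nct.cdf(t_obs, df, nc) - prob

    lo, hi = t_obs - 20.0 - 5.0, t_obs + 20.0 + 5.0
    return brentq(fn, lo, hi)


def group_bias(
    words_with_forms: dict[str, tuple[str, ...]],
    space: EmbeddingSpace,
    sets: AttributeSets,
    ci_method: str = "normal",
) -> BiasResult:
    """Valence bias of a word group: pool all forms of all members."""
    all_forms: list[str] = []
    for word, forms in words_with_forms.items():
        all_forms.extend(forms if forms else verb_forms(word))
    pos, neg, oov = attribute_similarities(all_forms, space, sets)
    g, lo, hi, degenerate = hedges_g(pos, neg, ci_method=ci_method)
    return BiasResult(
        target_words=tuple(words_with_forms),
        n_pos=len(pos),
        n_neg=len(neg),
        mean_pos=float(np.mean(pos)),
        mean_neg=float(np.mean(neg)),
        g=g,
        ci_low=lo,
        ci_high=hi,
        oov=oov,
        degenerate=degenerate,
    )


def word_bias(
    word: str,
    space: EmbeddingSpace,
    sets: AttributeSets,
    tense_forms: tuple[str, ...] | None = None,
    ci_method: str = "normal",
) -> BiasResult:
    """Valence bias of a single word (all its inflected forms pooled)."""
    forms = tense_forms if tense_forms is not None else verb_forms(word)
    return group_bias({word: tuple(forms)}, space, sets, ci_method=ci_method)


def random_baseline(
    space: EmbeddingSpace,
    n_words: int,
    seed: int,
    sets: AttributeSets,
    exclude: set[str] | None = None,
) -> BiasResult:
    """Bias of a uniform random word sample — the null reference.

    Words are drawn without replacement from the vocabulary (attribute
    words and *exclude* removed) and treated as one group, each word as its
    own single form.
    """
    if n_words < 1:
        raise DomainError("n_words must be >= 1")
    banned = set(sets.positive) | set(sets.negative) | (exclude or set())
    candidates = [w for w in space.vocabulary if w not in banned]
    if n_words > len(candidates):
        raise DomainError(
            f"requested {n_words} words but vocabulary has {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_words, replace=False)
    sample = [candidates[i] for i in sorted(chosen)]
    return group_bias({w: (w,) for w in sample}, space, sets)
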