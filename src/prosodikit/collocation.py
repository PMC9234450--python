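"""Collocate extraction and frequency-weighted collocate-valence scoring.

A word has *semantic prosody* when human raters call it neutral but its
corpus collocates are predominantly valenced. The pipeline here mirrors
standard corpus-linguistics practice: collect every token within a fixed
window to the **right** of the node word (windows never cross sentence
boundaries), keep collocates whose mutual information with the node exceeds
a threshold after removing overly common function words, rank by
co-occurrence frequency, and average the collocates' normed valences
weighted by co-occurrence frequency.

Mutual information follows the English-Corpora.org convention

    MI = log2( co_freq * N / (node_freq * coll_freq * span) )

(N = corpus token count). The ``span`` term in the denominator corrects the
expected co-occurrence count for the window width; other PMI conventions
omit it, so scores from this module are comparable to corpus-interface MI
scores, not to textbook PMI.
"""

from __future__ import annotations

import logging
import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from ._stopwords import DEFAULT_STOPLIST
from .errors import DomainError
from .io_formats import VALENCE_NEUTRAL, ValenceLexicon

logger = logging.getLogger(__name__)

#: Sentence-boundary sentinel emitted by :func:`tokenize`; collocation
#: windows never extend past it and it is excluded from unigram counts.
EOS = "⟨EOS⟩"

_SENT_FINAL = (".", "!", "?", "…")
_TRAILING_CLOSERS = "\"'”’»)]}"


@dataclass(frozen=True)
class CollocationConfig:
    """Window, ranking and filtering parameters for collocate extraction."""

    span: int = 4
    top_k: int = 100
    mi_min: float = 3.0
    stoplist: frozenset[str] = DEFAULT_STOPLIST

    def __post_init__(self) -> None:
        if self.span < 1:
            raise ValueError("span must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        object.__setattr__(self, "stoplist", frozenset(self.stoplist))


@dataclass(frozen=True)
class CollocateRecord:
    node: str
    collocate: str
    co_freq: int
    node_freq: int
    coll_freq: int
    mi: float | None = None


@dataclass(frozen=True)
class ProsodyScore:
    """Frequency-weighted collocate valence of a node word.

    ``weighted_valence`` lives on the same 1–9 scale as the norms;
    ``label`` is ``indeterminate`` iff no collocate carried a valence or
    the node's own explicit valence is unknown.
    """

    node: str
    n_collocates_used: int
    total_weight: int
    weighted_valence: float | None
    explicit_valence: float | None = None
    label: str = "indeterminate"
    missing_collocates: tuple[str, ...] = ()


def _strip_token(raw: str) -> tuple[str, bool]:
    """Strip leading/trailing punctuation; report a sentence-final mark."""
    stripped = raw.rstrip(_TRAILING_CLOSERS)
    sentence_final = stripped.endswith(_SENT_FINAL)
    core = raw
    start, end = 0, len(core)
    while start < end and _is_strippable(core[start]):
        start += 1
    while end > start and _is_strippable(core[end - 1]):
        end -= 1
    return core[start:end], sentence_final


def _is_strippable(char: str) -> bool:
    return unicodedata.category(char).startswith(("P", "S"))


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Whitespace tokenization with punctuation stripping.

    Leading/trailing punctuation is removed (internal apostrophes and
    hyphens survive, so ``don't`` stays one token); a sentence-final mark
    emits the :data:`EOS` boundary sentinel after its token, and the end of
    a non-empty text is itself a boundary. Empty text yields an empty
    sequence.
    """
    tokens: list[str] = []
    for raw in text.split():
        core, sentence_final = _strip_token(raw)
        if core:
            tokens.append(core.lower() if lowercase else core)
        if sentence_final and tokens and tokens[-1] != EOS:
            tokens.append(EOS)
    if tokens and tokens[-1] != EOS:
        tokens.append(EOS)
    return tokens


def count_collocates(
    tokens: Sequence[str], node: str, config: CollocationConfig
) -> list[CollocateRecord]:
    """Count right-window collocates of *node* (MI not yet filled).

    For every node occurrence, each of the next ``span`` tokens — stopping
    at a sentence boundary, skipping stoplist members — increments that
    pair's co-occurrence count. Unigram frequencies are whole-corpus counts
    excluding the boundary sentinel. An absent node yields an empty list.
    """
    unigrams: Counter[str] = Counter(t for t in tokens if t != EOS)
    node_freq = unigrams.get(node, 0)
    if node_freq == 0:
        logger.info("node %r absent from corpus", node)
        return []
    co_freq: Counter[str] = Counter()
    for pos, token in enumerate(tokens):
        if token != node:
            continue
        for offset in range(1, config.span + 1):
            if pos + offset >= len(tokens):
                break
            neighbour = tokens[pos + offset]
            if neighbour == EOS:
                break
            if neighbour in config.stoplist:
                continue
            co_freq[neighbour] += 1
    return [
        CollocateRecord(
            node=node,
            collocate=coll,
            co_freq=freq,
            node_freq=node_freq,
            coll_freq=unigrams[coll],
        )
        for coll, freq in sorted(co_freq.items())
    ]


def mutual_information(record: CollocateRecord, corpus_size: int, span: int) -> float:
    """Corpus-interface MI in bits (see module docstring for the convention)."""
    if corpus_size <= 0:
        raise DomainError("corpus_size must be positive")
    if min(record.co_freq, record.node_freq, record.coll_freq) < 1:
        raise DomainError("all counts must be >= 1")
    return math.log2(
        record.co_freq * corpus_size / (record.node_freq * record.coll_freq * span)
    )


def corpus_size(tokens: Sequence[str]) -> int:
    """Token count excluding sentence-boundary sentinels."""
    return sum(1 for t in tokens if t != EOS)


def with_mi(
    records: Iterable[CollocateRecord], corpus_size: int, config: CollocationConfig
) -> list[CollocateRecord]:
    """Return records with the MI field computed."""
    return [
        replace(rec, mi=mutual_information(rec, corpus_size, config.span))
        for rec in records
    ]


def top_collocates(
    records: Iterable[CollocateRecord], config: CollocationConfig
) -> list[CollocateRecord]:
    """Filter and rank collocates the way corpus interfaces do.

    Stoplist members and records at or below ``mi_min`` bits are dropped
    (the threshold is strict: exactly ``mi_min`` is excluded); survivors
    are ranked by co-occurrence frequency descending, ties broken by higher
    MI then lexicographically, and capped at ``top_k``.
    """
    qualifying = [
        rec
        for rec in records
        if rec.collocate not in config.stoplist
        and rec.mi is not None
        and rec.mi > config.mi_min
    ]
    qualifying.sort(key=lambda r: (-r.co_freq, -r.mi, r.collocate))
    kept = qualifying[: config.top_k]
    logger.info("kept %d of %d qualifying collocates", len(kept), len(qualifying))
    return kept


def weighted_collocate_valence(
    ranked: Sequence[CollocateRecord],
    lexicon: ValenceLexicon,
    explicit_valence: float | None = None,
    weight: str = "co_freq",
) -> ProsodyScore:
    """Frequency-weighted average collocate valence of the node.

    Collocates missing from the lexicon are excluded from both the
    numerator and the denominator (and reported); by default the weight is
    the node–collocate co-occurrence frequency (``weight="coll_freq"``
    switches to the collocate's corpus frequency).
    """
    if weight not in ("co_freq", "coll_freq"):
        raise ValueError("weight must be 'co_freq' or 'coll_freq'")
    node = ranked[0].node if ranked else ""
    num = 0.0
    denom = 0
    used = 0
    missing: list[str] = []
    for rec in ranked:
        valence = lexicon.get(rec.collocate)
        if valence is None:
            missing.append(rec.collocate)
            continue
        w = rec.co_freq if weight == "co_freq" else rec.coll_freq
        num += w * valence
        denom += w
        used += 1
    if missing:
        logger.info("%d collocates of %r missing from lexicon", len(missing), node)
    if used == 0:
        return ProsodyScore(
            node=node,
            n_collocates_used=0,
            total_weight=0,
            weighted_valence=None,
            explicit_valence=explicit_valence,
            label="indeterminate",
            missing_collocates=tuple(missing),
        )
    return ProsodyScore(
        node=node,
        n_collocates_used=used,
        total_weight=denom,
        weighted_valence=num / denom,
        explicit_valence=explicit_valence,
        label="indeterminate",
        missing_collocates=tuple(missing),
    )


def classify_prosody(
    score: ProsodyScore,
    neutral_band: tuple[float, float] = (4.5, 6.0),
    prosody_margin: float = 0.5,
) -> ProsodyScore:
    """Attach a prosody label given the node's explicit valence.

    A node is semantically prosodic when its own rating sits inside the
    neutral band while its weighted collocate valence departs from the
    scale midpoint by at least ``prosody_margin``; a node rated outside the
    band is simply ``valenced``; a neutral node with neutral company is
    ``non_prosodic``.
    """
    lo, hi = neutral_band
    if score.explicit_valence is None or score.n_collocates_used == 0:
        return replace(score, label="indeterminate")
    if not (lo <= score.explicit_valence <= hi):
        label = "valenced"
    elif score.weighted_valence >= VALENCE_NEUTRAL + prosody_margin:
        label = "positive_prosody"
    elif score.weighted_valence <= VALENCE_NEUTRAL - prosody_margin:
        label = "negative_prosody"
    else:
        label = "non_prosodic"
    logger.info(
        "classified %r as %s (band=[%g, %g], margin=%g)",
        score.node, label, lo, hi, prosody_margin,
    )
    return replace(score, label=label)


def score_node(
    tokens: Sequence[str],
    node: str,
    lexicon: ValenceLexicon,
    config: CollocationConfig | None = None,
    neutral_band: tuple[float, float] = (4.5, 6.0),
    prosody_margin: float = 0.5,
) -> tuple[ProsodyScore, list[CollocateRecord]]:
    """End-to-end prosody scoring of one node word on a tokenized corpus."""
    config = config or CollocationConfig()
    records = count_collocates(tokens, node, config)
    n_tokens = corpus_size(tokens)
    records = with_mi(records, n_tokens, config)
    ranked = top_collocates(records, config)
    score = weighted_collocate_valence(ranked, lexicon, explicit_valence=lexicon.get(node))
    return classify_prosody(score, neutral_band, prosody_margin), ranked
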