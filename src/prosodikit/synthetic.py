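"""Synthetic inputs with planted ground truth for every pipeline stage.

Real semantic-prosody studies consume a licensed corpus, pretrained word
vectors, and human reaction times. The generators here emulate all three
so the full pipeline is exercisable and testable offline:

* :func:`gen_corpus` — unigram token stream in which chosen node →
  collocate pairs co-occur ``lift``-fold above chance inside the
  collocation window (the asymptotic corpus-interface MI of such a plant
  is log2(lift));
* :func:`gen_embeddings` — an embedding space whose attribute words form
  two clusters and whose target words carry a planted standardized
  positive-vs-negative similarity gap;
* :func:`gen_trials` — lognormal evaluative-priming latencies with
  participant random intercepts, an additive congruity effect on the log
  scale per prime type, and a condition-independent error rate.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .collocation import EOS
from .errors import ConfigError
from .io_formats import EmbeddingSpace, TrialRecord, ValenceLexicon

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Corpus generation


@dataclass(frozen=True)
class Plant:
    """One planted node → collocate association."""

    node: str
    collocate: str
    lift: float
    valence: float = 5.0

    def __post_init__(self) -> None:
        if self.lift < 0:
            raise ConfigError("lift must be nonnegative")


@dataclass(frozen=True)
class SynthCorpusConfig:
    vocab: Mapping[str, float]  # word -> unigram probability
    plants: tuple[Plant, ...] = ()
    n_tokens: int = 100_000
    span: int = 4
    mean_sentence_len: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.vocab.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigError(f"unigram probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.vocab.values()):
            raise ConfigError("negative unigram probability")
        object.__setattr__(self, "plants", tuple(self.plants))
        seen: set[str] = set()
        for plant in self.plants:
            if plant.node not in self.vocab or plant.collocate not in self.vocab:
                raise ConfigError(f"plant {plant} references unknown vocabulary")
            if plant.node == plant.collocate:
                raise ConfigError("a plant's node and collocate must differ")
            if plant.collocate in seen:
                raise ConfigError(
                    f"collocate {plant.collocate!r} planted more than once"
                )
            seen.add(plant.collocate)
        # feasibility of the in-window distribution and of rate preservation
        for node in {p.node for p in self.plants}:
            window_mass = sum(
                self.vocab[p.collocate] * p.lift
                for p in self.plants if p.node == node
            )
            if window_mass >= 1.0:
                raise ConfigError(
                    f"boosted collocate mass {window_mass:.3f} for node "
                    f"{node!r} >= 1"
                )
        w = self._window_fractions()
        for plant in self.plants:
            if w[plant.node] * plant.lift >= 1.0:
                raise ConfigError(
                    f"plant {plant.node!r}->{plant.collocate!r}: windows too "
                    "frequent to preserve the collocate's unigram rate "
                    "(reduce lift or the node's probability)"
                )

    def truncation_factor(self) -> float:
        """Expected fraction of the nominal window that fits before the
        sentence end, for a node at a uniform position in a sentence of
        Poisson(mean_sentence_len) length (floored at 1)."""
        lam = self.mean_sentence_len
        upper = int(lam + 10.0 * math.sqrt(lam) + 20.0)
        from scipy.stats import poisson

        pmf = poisson.pmf(np.arange(0, upper + 1), lam)
        pmf[1] += pmf[0]  # lengths are floored at 1
        pmf[0] = 0.0
        expected = 0.0
        for length in range(1, upper + 1):
            if pmf[length] == 0.0:
                continue
            avail = sum(min(self.span, j) for j in range(length)) / length
            expected += pmf[length] * avail
        return expected / self.span

    def _window_fractions(self) -> dict[str, float]:
        """Per planted node: expected fraction of token slots inside one of
        its collocation windows (first order in the node's probability)."""
        s_trunc = self.truncation_factor()
        return {
            node: self.vocab[node] * self.span * s_trunc
            for node in {p.node for p in self.plants}
        }


def _corpus_distributions(
    config: SynthCorpusConfig, words: list[str]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Outside-window and per-node in-window sampling distributions.

    In a node's window each planted collocate appears with probability
    p·lift; outside any window its probability is lowered so that its
    *unconditional* rate stays at its configured unigram probability —
    planting changes where the collocate occurs, not how often.
    """
    index = {w: i for i, w in enumerate(words)}
    base = np.array([config.vocab[w] for w in words])
    w_frac = config._window_fractions()

    outside = base.copy()
    planted_idx: list[int] = []
    for plant in config.plants:
        i = index[plant.collocate]
        w = w_frac[plant.node]
        outside[i] = (base[i] - w * base[i] * plant.lift) / (1.0 - w)
        planted_idx.append(i)
    others = np.ones(len(words), dtype=bool)
    others[planted_idx] = False
    outside[others] = base[others] * (
        (1.0 - outside[planted_idx].sum()) / base[others].sum()
    )

    in_window: dict[str, np.ndarray] = {}
    for node in {p.node for p in config.plants}:
        probs = outside.copy()
        mask = np.ones(len(words), dtype=bool)
        q_mass = 0.0
        for plant in config.plants:
            if plant.node != node:
                continue
            i = index[plant.collocate]
            probs[i] = base[i] * plant.lift
            mask[i] = False
            q_mass += probs[i]
        probs[mask] *= (1.0 - q_mass) / outside[mask].sum()
        in_window[node] = probs
    return outside, in_window


def gen_corpus(config: SynthCorpusConfig) -> tuple[list[str], dict]:
    """Token stream (with sentence boundaries) plus a ground-truth table.

    Inside the ``span`` tokens after a planted node the planted
    collocates' probabilities are lifted to p·lift (their overall unigram
    rates are preserved by compensation outside the windows), so the
    corpus-interface MI of a plant converges to log2(lift) plus a
    sentence-truncation correction; the ground truth carries both the
    corrected expectation (``expected_mi``) and the asymptotic
    ``log2(lift)``.
    """
    rng = np.random.default_rng(config.seed)
    words = sorted(config.vocab)
    outside, in_window = _corpus_distributions(config, words)
    base_cum = np.cumsum(outside)
    boosted_cum = {node: np.cumsum(dist) for node, dist in in_window.items()}
    planted_nodes = set(boosted_cum)

    tokens: list[str] = []
    emitted = 0
    window_left = 0
    active_node: str | None = None
    sentence_left = max(1, int(rng.poisson(config.mean_sentence_len)))
    while emitted < config.n_tokens:
        if window_left > 0 and active_node is not None:
            cum = boosted_cum[active_node]
        else:
            cum = base_cum
        word = words[int(np.searchsorted(cum, rng.random(), side="right"))]
        tokens.append(word)
        emitted += 1
        window_left = max(0, window_left - 1)
        if word in planted_nodes:
            active_node = word
            window_left = config.span
        sentence_left -= 1
        if sentence_left == 0:
            tokens.append(EOS)
            window_left = 0
            active_node = None
            sentence_left = max(1, int(rng.poisson(config.mean_sentence_len)))
    if tokens[-1] != EOS:
        tokens.append(EOS)

    s_trunc = config.truncation_factor()
    ground_truth = {
        "plants": [
            {
                "node": p.node,
                "collocate": p.collocate,
                "lift": p.lift,
                "valence": p.valence,
                "expected_mi": (
                    math.log2(p.lift * s_trunc) if p.lift > 0 else -math.inf
                ),
                "asymptotic_mi": math.log2(p.lift) if p.lift > 0 else -math.inf,
            }
            for p in config.plants
        ],
        "n_tokens": emitted,
        "span": config.span,
        "truncation_factor": s_trunc,
    }
    return tokens, ground_truth


def corpus_lexicon(config: SynthCorpusConfig, neutral: float = 5.0) -> ValenceLexicon:
    """Valence norms covering the synthetic vocabulary: every word neutral
    except planted collocates, which carry their planted valence."""
    entries = {w: (neutral, None) for w in config.vocab}
    for plant in config.plants:
        entries[plant.collocate] = (plant.valence, None)
    return ValenceLexicon(entries)


# --------------------------------------------------------------------------
# Embedding generation


@dataclass(frozen=True)
class SynthEmbeddingConfig:
    """Embedding space with two attribute clusters and biased targets.

    ``targets`` maps word → (inflected forms, planted standardized
    similarity gap); the gap is realized by placing the word's forms along
    the axis joining the two attribute centroids (offset found by
    bisection against a fixed quadrature sample of attribute draws — the
    cosine geometry has no usable closed form).
    """

    dimension: int = 50
    n_attributes: int = 25
    centroid_separation: float = 1.0
    within_spread: float = 0.3
    targets: Mapping[str, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    noise_sd: float = 0.02
    n_filler_words: int = 0
    filler_spread: float | None = None  # defaults to within_spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ConfigError("dimension must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_attributes < 2:
            raise ConfigError("need >= 2 attribute words per set")


def _centroids(config: SynthEmbeddingConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axis = np.zeros(config.dimension)
    axis[0] = 1.0
    half = 0.5 * config.centroid_separation
    offset = np.zeros(config.dimension)
    offset[1] = 1.0  # common shift keeps cosines off the degenerate ±1 rails
    return offset + half * axis, offset - half * axis, axis


def _standardized_gap(
    form_vecs: np.ndarray, pos_attrs: np.ndarray, neg_attrs: np.ndarray
) -> float:
    def unit(mat: np.ndarray) -> np.ndarray:
        return mat / np.linalg.norm(mat, axis=1, keepdims=True)

    pos = (unit(form_vecs) @ unit(pos_attrs).T).ravel()
    neg = (unit(form_vecs) @ unit(neg_attrs).T).ravel()
    n1, n2 = len(pos), len(neg)
    s_pooled = math.sqrt(
        ((n1 - 1) * pos.var(ddof=1) + (n2 - 1) * neg.var(ddof=1)) / (n1 + n2 - 2)
    )
    return float((pos.mean() - neg.mean()) / s_pooled)


def _mirror(mat: np.ndarray) -> np.ndarray:
    out = mat.copy()
    out[:, 0] *= -1.0
    return out


def _calibrate_offset(config: SynthEmbeddingConfig, planted: float) -> float:
    """Bisect the along-axis offset so the population standardized gap
    matches the planted value.

    The quadrature sample is mirror-symmetric across the hyperplane
    between the two centroids (the negative attribute cloud is the exact
    reflection of the positive one, and the form-noise cloud is closed
    under reflection), so the gap is exactly zero at zero offset and
    exactly antisymmetric in the offset — the calibration has no
    even-order Monte-Carlo error. Zero planted bias therefore maps to a
    zero offset directly.
    """
    if planted == 0.0:
        return 0.0
    key = (
        config.dimension, config.n_attributes, config.centroid_separation,
        config.within_spread, config.noise_sd, planted,
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    cal_rng = np.random.default_rng(987654321)
    pos_c, neg_c, axis = _centroids(config)
    centre = 0.5 * (pos_c + neg_c)
    attr_noise = cal_rng.normal(0, config.within_spread, (1000, config.dimension))
    pos_attrs = pos_c + np.vstack([attr_noise, _mirror(attr_noise)])
    neg_attrs = neg_c + np.vstack([_mirror(attr_noise), attr_noise])
    half_forms = cal_rng.normal(0, config.noise_sd, (64, config.dimension))
    form_noise = np.vstack([half_forms, _mirror(half_forms)])

    def gap(beta: float) -> float:
        return _standardized_gap(
            centre + beta * axis + form_noise, pos_attrs, neg_attrs
        )

    lo, hi = -4.0 * max(config.centroid_separation, 1.0), 4.0 * max(
        config.centroid_separation, 1.0
    )
    g_lo, g_hi = gap(lo), gap(hi)
    if not (g_lo <= planted <= g_hi):
        raise ConfigError(
            f"planted bias {planted} infeasible with noise_sd={config.noise_sd} "
            f"(reachable range [{g_lo:.2f}, {g_hi:.2f}])"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) < planted:
            lo = mid
        else:
            hi = mid
    beta = 0.5 * (lo + hi)
    _CALIBRATION_CACHE[key] = beta
    return beta


_CALIBRATION_CACHE: dict[tuple, float] = {}


def gen_embeddings(config: SynthEmbeddingConfig) -> tuple[EmbeddingSpace, dict]:
    """Embedding space with planted attribute geometry and target biases.

    Attribute words are ``pos_attr_01`` … and ``neg_attr_01`` …; target
    forms keep their configured names; optional filler words
    (``filler_0001`` …) are isotropic noise around the attribute midpoint,
    giving the random-baseline operation an unbiased vocabulary to sample.
    """
    rng = np.random.default_rng(config.seed)
    pos_c, neg_c, axis = _centroids(config)
    centre = 0.5 * (pos_c + neg_c)
    vectors: dict[str, np.ndarray] = {}
    for i in range(config.n_attributes):
        vectors[f"pos_attr_{i + 1:02d}"] = pos_c + rng.normal(
            0, config.within_spread, config.dimension
        )
        vectors[f"neg_attr_{i + 1:02d}"] = neg_c + rng.normal(
            0, config.within_spread, config.dimension
        )
    truth_targets = {}
    for word, (forms, planted) in config.targets.items():
        beta = _calibrate_offset(config, planted)
        for form in forms:
            vectors[form.lower()] = (
                centre + beta * axis + rng.normal(0, config.noise_sd, config.dimension)
            )
        truth_targets[word] = {"forms": list(forms), "planted_bias": planted,
                               "offset": beta}
    filler_spread = (
        config.filler_spread if config.filler_spread is not None
        else config.within_spread
    )
    for i in range(config.n_filler_words):
        vectors[f"filler_{i + 1:04d}"] = centre + rng.normal(
            0, filler_spread, config.dimension
        )
    space = EmbeddingSpace(dimension=config.dimension, vectors=vectors)
    truth = {
        "positive_attributes": [f"pos_attr_{i + 1:02d}" for i in range(config.n_attributes)],
        "negative_attributes": [f"neg_attr_{i + 1:02d}" for i in range(config.n_attributes)],
        "targets": truth_targets,
    }
    return space, truth


# --------------------------------------------------------------------------
# Trial generation

#: Study-1 target nouns and their published rated valences (1–9 scale).
STUDY1_TARGET_NOUNS: dict[str, dict[str, float]] = {
    "positive": {
        "comedy": 8.05, "joy": 8.21, "delight": 8.21,
        "sunshine": 8.14, "laughter": 8.05, "creativity": 7.73,
    },
    "negative": {
        "rapist": 1.30, "racism": 1.48, "bigotry": 2.24,
        "greed": 2.48, "insult": 2.62, "nightmares": 1.79,
    },
}

#: The eight semantically prosodic primes identified in pretesting.
PROSODIC_PRIMES: dict[str, str] = {
    "gain": "positive", "guarantee": "positive", "restore": "positive",
    "provide": "positive",
    "cause": "negative", "commit": "negative", "ease": "negative",
    "peddle": "negative",
}

# Non-prosodic control primes are not individually listed in the published
# materials; these are synthetic placeholders with the right structure
# (four nominally positive, four nominally negative, all rated-neutral).
CONTROL_PRIMES: dict[str, str] = {
    "reply": "positive", "describe": "positive", "indicate": "positive",
    "consist": "positive",
    "depict": "negative", "convey": "negative", "denote": "negative",
    "render": "negative",
}

# Strongly valenced primes (Study 2 adds these); the paper names hate and
# comfort as examples, the rest are synthetic placeholders.
VALENCED_PRIMES: dict[str, str] = {
    "comfort": "positive", "delight": "positive", "cherish": "positive",
    "praise": "positive",
    "hate": "negative", "torture": "negative", "punish": "negative",
    "insult": "negative",
}


@dataclass(frozen=True)
class SynthTrialConfig:
    """Lognormal evaluative-priming simulator parameters.

    ``delta`` maps prime type → congruity effect on the log-RT scale,
    defined as (congruent − incongruent) mean log latency; negative values
    mean congruent trials are faster. Defaults echo the magnitudes of a
    ≈45 ms congruity spread around ≈640 ms baselines and are fixtures, not
    estimates.
    """

    n_participants: int = 78
    primes: Mapping[str, Mapping[str, str]] = field(
        default_factory=lambda: {"prosodic": dict(PROSODIC_PRIMES),
                                 "control": dict(CONTROL_PRIMES)}
    )
    targets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "positive": tuple(STUDY1_TARGET_NOUNS["positive"]),
            "negative": tuple(STUDY1_TARGET_NOUNS["negative"]),
        }
    )
    trials_per_prime: int = 4
    mu_log: float = math.log(640.0)
    sigma_log: float = 0.20
    tau_participant: float = 0.15
    delta: Mapping[str, float] = field(
        default_factory=lambda: {"valenced": -0.075, "prosodic": -0.060,
                                 "control": 0.0}
    )
    error_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("need >= 1 participant")
        if self.sigma_log <= 0 or self.tau_participant <= 0:
            raise ConfigError("all SDs must be > 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must lie in [0, 1)")
        if self.trials_per_prime % 2 != 0 or self.trials_per_prime < 2:
            raise ConfigError("trials_per_prime must be even and >= 2")
        for ptype, mapping in self.primes.items():
            if ptype not in self.delta:
                raise ConfigError(f"no delta for prime type {ptype!r}")
            if any(v not in ("positive", "negative") for v in mapping.values()):
                raise ConfigError("prime valences must be positive/negative")


def study2_trial_config(seed: int = 0, n_participants: int = 89) -> SynthTrialConfig:
    """Three-prime-type configuration with picture targets (96 trials)."""
    return SynthTrialConfig(
        n_participants=n_participants,
        primes={
            "valenced": dict(VALENCED_PRIMES),
            "prosodic": dict(PROSODIC_PRIMES),
            "control": dict(CONTROL_PRIMES),
        },
        targets={
            "positive": tuple(f"picture_pos_{i + 1:02d}" for i in range(12)),
            "negative": tuple(f"picture_neg_{i + 1:02d}" for i in range(12)),
        },
        seed=seed,
    )


def gen_trials(config: SynthTrialConfig) -> tuple[list[TrialRecord], dict]:
    """Simulated experiment: balanced prime × target-valence assignment.

    Each prime appears ``trials_per_prime`` times per participant, half
    before positive and half before negative targets (targets drawn from
    the configured pools); log RT = mu + participant intercept +
    delta/2·(±1 for congruent/incongruent) + residual noise; accuracy is
    Bernoulli(1 − error_rate) independent of condition.
    """
    rng = np.random.default_rng(config.seed)
    records: list[TrialRecord] = []
    per_valence = config.trials_per_prime // 2
    prime_list = [
        (ptype, prime, pval)
        for ptype in sorted(config.primes)
        for prime, pval in sorted(config.primes[ptype].items())
    ]
    width = len(str(config.n_participants))
    for i in range(config.n_participants):
        pid = f"p{i + 1:0{width}d}"
        intercept = rng.normal(0.0, config.tau_participant)
        slots: list[tuple[str, str, str, str, str]] = []
        for ptype, prime, pval in prime_list:
            for tval in ("positive", "negative"):
                pool = config.targets[tval]
                for _ in range(per_valence):
                    target = pool[int(rng.integers(len(pool)))]
                    slots.append((ptype, prime, pval, tval, target))
        order = rng.permutation(len(slots))
        for trial_index, slot in enumerate(order):
            ptype, prime, pval, tval, target = slots[int(slot)]
            congruent = pval == tval
            shift = config.delta[ptype] / 2.0 * (1.0 if congruent else -1.0)
            log_rt = (
                config.mu_log + intercept + shift
                + rng.normal(0.0, config.sigma_log)
            )
            accurate = bool(rng.random() >= config.error_rate)
            response = tval if accurate else (
                "negative" if tval == "positive" else "positive"
            )
            records.append(
                TrialRecord(
                    participant_id=pid,
                    trial_index=trial_index,
                    phase="experimental",
                    prime=prime,
                    prime_type=ptype,
                    prime_valence=pval,
                    target=target,
                    target_valence=tval,
                    response=response,
                    accurate=accurate,
                    rt_ms=round(float(math.exp(log_rt)), 3),
                )
            )
    truth = {
        "delta": dict(config.delta),
        "mu_log": config.mu_log,
        "sigma_log": config.sigma_log,
        "tau_participant": config.tau_participant,
        "error_rate": config.error_rate,
        "trials_per_participant": len(prime_list) * config.trials_per_prime,
    }
    logger.info(
        "generated %d trials for %d participants",
        len(records), config.n_participants,
    )
    return records, truth
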