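"""Readers and writers for the external formats the pipeline touches.

Three formats are supported, all plain text:

* valence norms — CSV ``word,valence_mean[,valence_sd]`` carrying human
  pleasantness ratings on the 1 (unpleasant) … 9 (pleasant) scale with 5 as
  the neutral midpoint;
* word vectors — word2vec *text* format (``<vocab> <dim>`` header, then one
  ``word v1 … vdim`` row per line); the binary format is out of scope, see
  the conversion note in the docs;
* evaluative-priming trials — CSV, one row per trial, milliseconds as the
  native latency unit.

All readers are total over valid files and raise typed errors (never silent
skips) on invalid ones; every repair (e.g. duplicate vocabulary entries) is
logged with counts. Words are case-folded to lowercase at every boundary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALENCE_MIN = 1.0
VALENCE_MAX = 9.0
VALENCE_NEUTRAL = 5.0

#: Column order of the canonical trial CSV schema.
TRIAL_COLUMNS = (
    "participant_id",
    "trial_index",
    "phase",
    "prime",
    "prime_type",
    "prime_valence",
    "target",
    "target_valence",
    "response",
    "accurate",
    "rt_ms",
)

PHASES = ("practice", "experimental")
PRIME_TYPES = ("valenced", "prosodic", "control")
VALENCES = ("positive", "negative")


@dataclass(frozen=True)
class ValenceLexicon:
    """Word → (mean valence, optional SD) lookup on the 1–9 norm scale.

    Lookup of an absent word is a detectable miss (``KeyError`` /
    ``None`` from :meth:`get`), never a silent default.
    """

    entries: Mapping[str, tuple[float, float | None]]

    def __post_init__(self) -> None:
        for word, (mean, sd) in self.entries.items():
            if not (VALENCE_MIN <= mean <= VALENCE_MAX):
                raise ValidationError(
                    f"valence_mean {mean} for {word!r} outside [1, 9]"
                )
            if sd is not None and sd < 0:
                raise ValidationError(f"negative valence_sd for {word!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def valence(self, word: str) -> float:
        """Mean valence of *word*; raises ``KeyError`` on a miss."""
        return self.entries[word.lower()][0]

    def get(self, word: str) -> float | None:
        entry = self.entries.get(word.lower())
        return entry[0] if entry is not None else None


@dataclass(frozen=True)
class EmbeddingSpace:
    """A finite word → vector map of fixed dimension.

    Zero vectors are rejected at construction: cosine similarity is
    undefined for them and every downstream use is cosine-based.
    """

    dimension: int
    vectors: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValidationError("dimension must be positive")
        for word, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValidationError(
                    f"vector for {word!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )
            if not np.any(vec):
                raise ValidationError(f"zero vector for {word!r}")

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    @property
    def vocabulary(self) -> list[str]:
        return list(self.vectors)


@dataclass(frozen=True)
class TrialRecord:
    """One evaluative-priming trial.

    ``accurate`` must equal ``response == target_valence``; latencies are
    positive milliseconds. Practice-phase records are carried through IO but
    excluded from all inferential statistics downstream.
    """

    participant_id: str
    trial_index: int
    phase: str
    prime: str
    prime_type: str
    prime_valence: str
    target: str
    target_valence: str
    response: str
    accurate: bool
    rt_ms: float

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValidationError("trial_index must be nonnegative")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.prime_type not in PRIME_TYPES:
            raise ValidationError(f"unknown prime_type {self.prime_type!r}")
        for name in ("prime_valence", "target_valence", "response"):
            if getattr(self, name) not in VALENCES:
                raise ValidationError(f"unknown {name} {getattr(self, name)!r}")
        if self.accurate != (self.response == self.target_valence):
            raise ValidationError(
                f"trial {self.participant_id}/{self.trial_index}: accurate flag "
                "inconsistent with response vs. target_valence"
            )
        if not self.rt_ms > 0:
            raise ValidationError("rt_ms must be positive")


def read_valence_norms(path: str | Path) -> ValenceLexicon:
    """Load a valence-norm CSV (``word,valence_mean[,valence_sd]``)."""
    path = Path(path)
    entries: dict[str, tuple[float, float | None]] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = [h.strip().lower() for h in header]
        if header[:2] != ["word", "valence_mean"]:
            raise FormatError(
                f"{path}: header must start with 'word,valence_mean', got {header}"
            )
        has_sd = len(header) > 2 and header[2] == "valence_sd"
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            word = row[0].strip().lower()
            try:
                mean = float(row[1])
            except (IndexError, ValueError):
                raise FormatError(f"{path}:{lineno}: unparseable valence_mean")
            if not (VALENCE_MIN <= mean <= VALENCE_MAX):
                raise ValidationError(
                    f"{path}:{lineno}: valence_mean {mean} outside [1, 9]"
                )
            sd: float | None = None
            if has_sd and len(row) > 2 and row[2].strip():
                sd = float(row[2])
            entries[word] = (mean, sd)
    logger.info("read %d valence norms from %s", len(entries), path)
    return ValenceLexicon(entries)


def read_embeddings(path: str | Path) -> EmbeddingSpace:
    """Load word vectors in word2vec text format.

    Duplicate words are resolved last-wins with a logged warning; any row
    whose value count disagrees with the declared dimension is a
    :class:`FormatError` naming the line.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    duplicates = 0
    with path.open(encoding="utf-8") as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: header must be '<vocab_count> <dimension>'")
        try:
            declared_vocab, dim = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}: non-integer header fields {header}")
        for lineno, line in enumerate(handle, start=2):
            parts = line.rstrip("\n").split(" ")
            parts = [p for p in parts if p != ""]
            if not parts:
                continue
            word = parts[0].lower()
            if len(parts) - 1 != dim:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(parts) - 1}"
                )
            vec = np.asarray(parts[1:], dtype=float)
            if not np.any(vec):
                raise ValidationError(f"{path}:{lineno}: zero vector for {word!r}")
            if word in vectors:
                duplicates += 1
            vectors[word] = vec
    if duplicates:
        logger.warning("%s: %d duplicate words, last occurrence kept", path, duplicates)
    if len(vectors) != declared_vocab:
        logger.warning(
            "%s: header declared %d words, loaded %d", path, declared_vocab, len(vectors)
        )
    logger.info("read %d vectors of dimension %d from %s", len(vectors), dim, path)
    return EmbeddingSpace(dimension=dim, vectors=vectors)


def _parse_bool(text: str, where: str) -> bool:
    lowered = text.strip().lower()
    if lowered in ("true", "1"):
        return True
    if lowered in ("false", "0"):
        return False
    raise FormatError(f"{where}: unparseable boolean {text!r}")


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Load a trial CSV; accuracy/response inconsistencies are collected
    and reported together as a single :class:`ValidationError`."""
    path = Path(path)
    records: list[TrialRecord] = []
    bad_rows: list[str] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = tuple(h.strip() for h in next(reader))
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        if header != TRIAL_COLUMNS:
            raise FormatError(
                f"{path}: expected columns {','.join(TRIAL_COLUMNS)}, got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRIAL_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(TRIAL_COLUMNS)} fields")
            try:
                records.append(
                    TrialRecord(
                        participant_id=row[0],
                        trial_index=int(row[1]),
                        phase=row[2],
                        prime=row[3].lower(),
                        prime_type=row[4],
                        prime_valence=row[5],
                        target=row[6].lower(),
                        target_valence=row[7],
                        response=row[8],
                        accurate=_parse_bool(row[9], f"{path}:{lineno}"),
                        rt_ms=float(row[10]),
                    )
                )
            except ValidationError as exc:
                bad_rows.append(f"line {lineno}: {exc}")
    if bad_rows:
        raise ValidationError(
            f"{path}: {len(bad_rows)} invalid trial rows:\n" + "\n".join(bad_rows)
        )
    logger.info("read %d trials from %s", len(records), path)
    return records


def _format_rt(rt_ms: float) -> str:
    fixed = format(rt_ms, ".3f")
    return fixed if float(fixed) == rt_ms else repr(rt_ms)


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials in the canonical CSV schema (exact round-trip with
    :func:`read_trials` at ≥ 3 decimal places of latency)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(TRIAL_COLUMNS)
        n = 0
        for rec in records:
            writer.writerow(
                [
                    rec.participant_id,
                    rec.trial_index,
                    rec.phase,
                    rec.prime,
                    rec.prime_type,
                    rec.prime_valence,
                    rec.target,
                    rec.target_valence,
                    rec.response,
                    "true" if rec.accurate else "false",
                    _format_rt(rec.rt_ms),
                ]
            )
            n += 1
    logger.info("wrote %d trials to %s", n, path)


def iter_corpus_texts(path: str | Path, per_line: bool = False) -> Iterator[str]:
    """Yield documents from a UTF-8 plain-text corpus.

    *path* may be a single file or a directory of ``.txt`` files; with
    ``per_line=True`` every line is one document, otherwise each file is.
    """
    path = Path(path)
    files = sorted(path.glob("**/*.txt")) if path.is_dir() else [path]
    for file in files:
        text = file.read_text(encoding="utf-8")
        if per_line:
            yield from (line for line in text.splitlines() if line.strip())
        else:
            yield text


def load_config(path: str | Path) -> dict:
    """Load a flat key/value YAML config; nested mappings are rejected."""
    with Path(path).open(encoding="utf-8") as handle:
        loaded = yaml.safe_load(handle) or {}
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: config must be a mapping")
    for key, value in loaded.items():
        if isinstance(value, dict):
            raise FormatError(f"{path}: nested mapping under {key!r}; config is flat")
    logger.info("resolved config from %s: %s", path, loaded)
    return loaded
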