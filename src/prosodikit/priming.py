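"""Inferential analysis of evaluative-priming reaction-time data.

The congruity effect — faster categorization of targets whose valence
matches the prime's — is the prime-valence × target-valence interaction in
a fully within-subjects factorial design (prime type × prime valence ×
target valence). The analysis chain is:

1. :func:`preprocess` — drop inaccurate trials, log-transform latencies,
   winsorize at the grand mean ± 2.5 SD on the log scale;
2. :func:`cell_means` — per-participant mean log latency per design cell;
3. :func:`rm_anova` — repeated-measures ANOVA in which every within
   effect is tested against its own effect × subject interaction;
4. :func:`simple_effect` — paired-t contrasts between design cells;
5. :func:`congruity_report` — everything assembled into one deterministic
   document, including raw-millisecond cell descriptives.

The log base does not affect F, t, p, dz or partial η² (the transform is a
positive rescaling of every cell mean); it only changes the units of mean
differences and their CIs. Natural log is the default.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError
from .io_formats import TRIAL_COLUMNS, TrialRecord

logger = logging.getLogger(__name__)

DESIGN_FACTORS = ("prime_type", "prime_valence", "target_valence")
#: Canonical level orders (only levels present in the data are used).
CANONICAL_LEVELS = {
    "prime_type": ("valenced", "prosodic", "control"),
    "prime_valence": ("positive", "negative"),
    "target_valence": ("positive", "negative"),
}


@dataclass(frozen=True)
class PreprocessConfig:
    """Latency preprocessing parameters.

    ``sd_mult`` is the winsorization multiplier on the log scale around the
    grand latency mean (pooled over participants and conditions).
    """

    sd_mult: float = 2.5
    log_base: str = "natural"  # or "base10"
    exclude_inaccurate: bool = True
    practice_excluded: bool = True

    def __post_init__(self) -> None:
        if not self.sd_mult > 0:
            raise ValueError("sd_mult must be > 0")
        if self.log_base not in ("natural", "base10"):
            raise ValueError("log_base must be 'natural' or 'base10'")


@dataclass(frozen=True)
class PreprocessReport:
    n_input: int
    n_practice_dropped: int
    n_inaccurate_dropped: int
    prop_inaccurate: float
    grand_mean_log: float
    grand_sd_log: float
    cutoff_low: float
    cutoff_high: float
    n_winsorized_low: int
    n_winsorized_high: int


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss_effect: float
    ss_error: float
    df1: int
    df2: int
    F: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class SimpleEffectResult:
    contrast: tuple[str, str]
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    dz: float
    degenerate: bool = False


@dataclass(frozen=True)
class CellMeansTable:
    """Per-participant mean log latency in every design cell.

    ``data`` is wide: one row per participant, one column per cell
    (a MultiIndex over the factor levels). Participants with any empty
    cell are excluded from ``data`` and listed in ``excluded``.
    """

    factors: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]
    data: pd.DataFrame
    excluded: tuple[str, ...] = ()

    @property
    def participants(self) -> list[str]:
        return list(self.data.index)

    def array(self) -> np.ndarray:
        """Values as an ndarray shaped (participants, *levels per factor*)."""
        shape = (len(self.data),) + tuple(len(self.levels[f]) for f in self.factors)
        cols = list(itertools.product(*(self.levels[f] for f in self.factors)))
        ordered = self.data[[c if len(c) > 1 else c[0] for c in cols]]
        return ordered.to_numpy(dtype=float).reshape(shape)

    def cell(self, **levels: str) -> pd.Series:
        key = tuple(levels[f] for f in self.factors)
        return self.data[key if len(key) > 1 else key[0]]


def trials_to_frame(trials: Iterable[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        missing = set(TRIAL_COLUMNS) - set(trials.columns)
        if missing:
            raise ValidationError(f"trial frame missing columns {sorted(missing)}")
        return trials.copy()
    return pd.DataFrame([vars(t) for t in trials], columns=list(TRIAL_COLUMNS))


def preprocess(
    trials: Iterable[TrialRecord] | pd.DataFrame,
    config: PreprocessConfig | None = None,
    frozen_cutoffs: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop inaccurate trials, log-transform, winsorize at ±sd_mult SD.

    The winsorization cutoffs come from the grand mean and SD of the log
    latencies pooled over all remaining trials (out-of-range values are
    replaced by the nearest cutoff, not dropped). ``frozen_cutoffs``
    bypasses step 3's statistics — reprocessing with the cutoffs from a
    first pass is then idempotent.
    """
    config = config or PreprocessConfig()
    df = trials_to_frame(trials)
    n_input = len(df)
    if (df["rt_ms"] <= 0).any():
        raise ValidationError("nonpositive rt_ms in trials")

    n_practice = 0
    if config.practice_excluded:
        practice = df["phase"] == "practice"
        n_practice = int(practice.sum())
        df = df[~practice]
    n_inacc = 0
    denom = len(df)
    if config.exclude_inaccurate:
        inacc = ~df["accurate"].astype(bool)
        n_inacc = int(inacc.sum())
        df = df[~inacc]
    if len(df) == 0:
        raise DomainError("no trials remain after exclusions")

    df = df.copy()
    log = np.log if config.log_base == "natural" else np.log10
    df["log_rt"] = log(df["rt_ms"].to_numpy(dtype=float))

    if frozen_cutoffs is None:
        grand_mean = float(df["log_rt"].mean())
        grand_sd = float(df["log_rt"].std(ddof=1)) if len(df) > 1 else 0.0
        lo = grand_mean - config.sd_mult * grand_sd
        hi = grand_mean + config.sd_mult * grand_sd
    else:
        lo, hi = frozen_cutoffs
        grand_mean = float("nan")
        grand_sd = float("nan")
    n_low = int((df["log_rt"] < lo).sum())
    n_high = int((df["log_rt"] > hi).sum())
    df["log_rt"] = df["log_rt"].clip(lower=lo, upper=hi)

    report = PreprocessReport(
        n_input=n_input,
        n_practice_dropped=n_practice,
        n_inaccurate_dropped=n_inacc,
        prop_inaccurate=n_inacc / denom if denom else 0.0,
        grand_mean_log=grand_mean,
        grand_sd_log=grand_sd,
        cutoff_low=lo,
        cutoff_high=hi,
        n_winsorized_low=n_low,
        n_winsorized_high=n_high,
    )
    logger.info(
        "preprocess: %d in, %d practice dropped, %d inaccurate (%.1f%%), "
        "%d winsorized",
        n_input, n_practice, n_inacc, 100 * report.prop_inaccurate, n_low + n_high,
    )
    return df, report


def _level_order(factor: str, observed: Sequence[str]) -> tuple[str, ...]:
    canonical = CANONICAL_LEVELS.get(factor)
    observed_set = set(observed)
    if canonical:
        ordered = tuple(l for l in canonical if l in observed_set)
        extra = tuple(sorted(observed_set - set(ordered)))
        return ordered + extra
    return tuple(sorted(observed_set))


def cell_means(
    processed: pd.DataFrame,
    factors: Sequence[str] = DESIGN_FACTORS,
    value: str = "log_rt",
) -> CellMeansTable:
    """Per-participant mean of *value* in every factor-level combination."""
    factors = tuple(factors)
    levels = {f: _level_order(f, processed[f].unique()) for f in factors}
    grouped = processed.groupby(["participant_id", *factors], sort=False)[value].mean()
    wide = grouped.unstack(list(factors))
    full_cols = list(itertools.product(*(levels[f] for f in factors)))
    if len(factors) == 1:
        full_cols = [c[0] for c in full_cols]
    wide = wide.reindex(columns=full_cols)
    incomplete = wide.isna().any(axis=1)
    excluded = tuple(str(p) for p in wide.index[incomplete])
    if excluded:
        logger.warning(
            "%d participants with empty cells excluded: %s", len(excluded), excluded
        )
    wide = wide[~incomplete].sort_index()
    return CellMeansTable(factors=factors, levels=levels, data=wide, excluded=excluded)


def _effect_array(arr: np.ndarray, axes: tuple[int, ...], cache: dict) -> np.ndarray:
    """Inclusion–exclusion effect estimate over the given axes."""
    all_axes = tuple(range(arr.ndim))
    total = np.zeros_like(arr, shape=tuple(
        arr.shape[a] if a in axes else 1 for a in all_axes
    ))
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            if sub not in cache:
                other = tuple(a for a in all_axes if a not in sub)
                cache[sub] = arr.mean(axis=other, keepdims=True)
            sign = (-1) ** (len(axes) - len(sub))
            total = total + sign * cache[sub]
    return total


def rm_anova(table: CellMeansTable) -> list[AnovaEffect]:
    """Fully within-subjects factorial ANOVA on a balanced cell-means table.

    Sums of squares come from the classical decomposition of a complete
    subjects × factors layout with one observation per cell; each within
    effect is tested against its own interaction with subjects
    (F = MS_effect / MS_effect×subject). Partial η² is
    SS_effect / (SS_effect + SS_error).
    """
    if table.data.isna().any().any() or len(table.data) < 2:
        raise DomainError(
            "rm_anova needs a balanced table with >= 2 participants; "
            "see the cell_means report for excluded participants"
        )
    arr = table.array()  # axis 0 = subjects, axes 1.. = factors
    factor_axes = tuple(range(1, arr.ndim))
    cache: dict = {}

    def ss_and_df(axes: tuple[int, ...]) -> tuple[float, int]:
        effect = _effect_array(arr, axes, cache)
        multiplier = np.prod(
            [arr.shape[a] for a in range(arr.ndim) if a not in axes], dtype=float
        )
        ss = float(multiplier * np.sum(effect**2))
        df = int(np.prod([arr.shape[a] - 1 for a in axes]))
        return ss, df

    effects: list[AnovaEffect] = []
    for r in range(1, len(factor_axes) + 1):
        for axes in itertools.combinations(factor_axes, r):
            ss_eff, df1 = ss_and_df(axes)
            ss_err, df2 = ss_and_df((0,) + axes)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            f_stat = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else math.inf)
            p = float(stats.f.sf(f_stat, df1, df2)) if math.isfinite(f_stat) else 0.0
            effects.append(
                AnovaEffect(
                    name=":".join(table.factors[a - 1] for a in axes),
                    ss_effect=ss_eff,
                    ss_error=ss_err,
                    df1=df1,
                    df2=df2,
                    F=f_stat,
                    p=p,
                    partial_eta_sq=ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
                )
            )
    return effects


def ss_decomposition(table: CellMeansTable) -> dict[str, float]:
    """Every SS term of the complete decomposition (incl. subject terms).

    The terms sum to the total SS about the grand mean — a conservation
    identity used as a correctness check.
    """
    arr = table.array()
    cache: dict = {}
    out: dict[str, float] = {}
    names = ("subject",) + table.factors
    for r in range(1, arr.ndim + 1):
        for axes in itertools.combinations(range(arr.ndim), r):
            effect = _effect_array(arr, axes, cache)
            multiplier = np.prod(
                [arr.shape[a] for a in range(arr.ndim) if a not in axes], dtype=float
            )
            out[":".join(names[a] for a in axes)] = float(multiplier * np.sum(effect**2))
    return out


def _resolve_cell(table: CellMeansTable, cell: Mapping[str, str] | Sequence[str]):
    if isinstance(cell, Mapping):
        key = tuple(cell[f] for f in table.factors)
    else:
        key = tuple(cell)
    if len(key) != len(table.factors):
        raise ValueError(f"cell must specify all factors {table.factors}")
    return key if len(key) > 1 else key[0]


def simple_effect(
    table: CellMeansTable,
    cell_a: Mapping[str, str] | Sequence[str],
    cell_b: Mapping[str, str] | Sequence[str],
) -> SimpleEffectResult:
    """Paired t test of cell A vs. cell B on participant cell means.

    ``mean_diff`` is mean(A) − mean(B); ``dz`` standardizes it by the SD of
    the participant difference scores. A zero-variance nonzero difference
    is reported as a degenerate infinite t, not an exception.
    """
    key_a = _resolve_cell(table, cell_a)
    key_b = _resolve_cell(table, cell_b)
    a = table.data[key_a].to_numpy(dtype=float)
    b = table.data[key_b].to_numpy(dtype=float)
    n = len(a)
    if n < 3:
        raise DomainError("simple_effect needs >= 3 participants")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    df = n - 1
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            return SimpleEffectResult(
                contrast=(str(key_a), str(key_b)), mean_diff=0.0, ci_low=0.0,
                ci_high=0.0, t=0.0, df=df, p=1.0, dz=0.0,
            )
        t_stat = math.inf if mean_diff > 0 else -math.inf
        return SimpleEffectResult(
            contrast=(str(key_a), str(key_b)), mean_diff=mean_diff,
            ci_low=mean_diff, ci_high=mean_diff, t=t_stat, df=df, p=0.0,
            dz=math.copysign(math.inf, mean_diff), degenerate=True,
        )
    se = sd_diff / math.sqrt(n)
    t_stat = mean_diff / se
    t_crit = float(stats.t.ppf(0.975, df))
    return SimpleEffectResult(
        contrast=(str(key_a), str(key_b)),
        mean_diff=mean_diff,
        ci_low=mean_diff - t_crit * se,
        ci_high=mean_diff + t_crit * se,
        t=float(t_stat),
        df=df,
        p=float(2 * stats.t.sf(abs(t_stat), df)),
        dz=mean_diff / sd_diff,
    )


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> AnovaEffect:
    """Between-groups one-way ANOVA (stimulus-property checks)."""
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise DomainError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    grand = np.concatenate(arrays)
    grand_mean = grand.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand_mean) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1 = len(arrays) - 1
    df2 = len(grand) - len(arrays)
    if ss_within == 0.0:
        raise DomainError("zero within-group variance")
    f_stat = (ss_between / df1) / (ss_within / df2)
    return AnovaEffect(
        name="group",
        ss_effect=ss_between,
        ss_error=ss_within,
        df1=df1,
        df2=df2,
        F=f_stat,
        p=float(stats.f.sf(f_stat, df1, df2)),
        partial_eta_sq=ss_between / (ss_between + ss_within),
    )


def _effect_to_dict(e: AnovaEffect) -> dict:
    return {
        "name": e.name, "ss_effect": e.ss_effect, "ss_error": e.ss_error,
        "df1": e.df1, "df2": e.df2, "F": e.F, "p": e.p,
        "partial_eta_sq": e.partial_eta_sq,
    }


def _simple_to_dict(s: SimpleEffectResult) -> dict:
    return {
        "contrast": list(s.contrast), "mean_diff": s.mean_diff,
        "ci_low": s.ci_low, "ci_high": s.ci_high, "t": s.t, "df": s.df,
        "p": s.p, "dz": s.dz, "degenerate": s.degenerate,
    }


def congruity_report(
    trials: Iterable[TrialRecord] | pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> dict:
    """Full congruity analysis of one experiment, as one JSON-able document.

    Contains raw-millisecond cell descriptives (mean and SD across
    participants of per-participant cell means, computed from accurate,
    non-winsorized trials; a winsorized alternative is included), the
    complete repeated-measures ANOVA, per-prime-type simple effects of
    prime valence within each target valence (congruity contrasts:
    incongruent − congruent, so positive differences mean facilitation),
    per-prime-type simple prime-valence × target-valence interactions, and
    the preprocessing report. Deterministic given the input.
    """
    config = config or PreprocessConfig()
    df = trials_to_frame(trials)
    processed, report = preprocess(df, config)
    table = cell_means(processed)
    prime_types = table.levels["prime_type"]

    # Raw-ms descriptives from accurate, non-winsorized experimental trials.
    raw = df[(df["phase"] == "experimental") & (df["accurate"].astype(bool))]
    raw_cells = cell_means(raw, value="rt_ms")
    win_ms = processed.copy()
    base = math.e if config.log_base == "natural" else 10.0
    win_ms["rt_ms_winsorized"] = np.power(base, win_ms["log_rt"])
    win_cells = cell_means(win_ms, value="rt_ms_winsorized")

    def descriptives(cells: CellMeansTable) -> list[dict]:
        out = []
        for col in cells.data.columns:
            levels = col if isinstance(col, tuple) else (col,)
            series = cells.data[col]
            out.append(
                {
                    **dict(zip(cells.factors, levels)),
                    "mean": float(series.mean()),
                    "sd": float(series.std(ddof=1)),
                }
            )
        return out

    anova = rm_anova(table)

    simple_effects = []
    simple_interactions = []
    for ptype in prime_types:
        for tval in table.levels["target_valence"]:
            congruent = {"prime_type": ptype, "prime_valence": tval,
                         "target_valence": tval}
            incongruent_val = "negative" if tval == "positive" else "positive"
            incongruent = {"prime_type": ptype, "prime_valence": incongruent_val,
                           "target_valence": tval}
            result = simple_effect(table, incongruent, congruent)
            simple_effects.append(
                {"prime_type": ptype, "target_valence": tval,
                 **_simple_to_dict(result)}
            )
        sub = processed[processed["prime_type"] == ptype]
        sub_table = cell_means(sub, factors=("prime_valence", "target_valence"))
        interaction = [
            e for e in rm_anova(sub_table) if e.name == "prime_valence:target_valence"
        ][0]
        simple_interactions.append({"prime_type": ptype, **_effect_to_dict(interaction)})

    return {
        "design": "x".join(
            str(len(table.levels[f])) for f in table.factors
        ),
        "n_participants": len(table.participants),
        "excluded_participants": list(table.excluded),
        "preprocessing": vars(report).copy(),
        "cell_means_ms": descriptives(raw_cells),
        "cell_means_ms_winsorized": descriptives(win_cells),
        "anova": [_effect_to_dict(e) for e in anova],
        "simple_effects": simple_effects,
        "simple_interactions": simple_interactions,
    }
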