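"""Brain-decoding outcome statistics.

Per-session tenderness-classification percentages, session differences,
one- and two-sample t tests on those percentages, and exact binomial
tests of per-subject classifier performance against chance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import Condition, VolumeLabel


class Group(str, enum.Enum):
    NFB = "NFB"
    CTR = "CTR"


class DegenerateTestError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    kind: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class SubjectOutcome:
    """One subject's classification trajectory across sessions.

    ``pct_tenderness_by_session`` holds, per classification session, the
    share (%) of usable tenderness-condition volumes classified as
    tenderness.  ``last_counts`` carries the raw (successes, n) of the
    last session for the exact binomial flag.
    """

    subject_id: str
    group: Group
    pct_tenderness_by_session: tuple[float, ...]
    last_counts: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for p in self.pct_tenderness_by_session:
            if not 0.0 <= p <= 100.0:
                raise ValueError("percentage outside [0, 100]")

    @property
    def delta_last_first(self) -> float:
        p = self.pct_tenderness_by_session
        return p[-1] - p[0]

    @property
    def covariate_run3_minus_run1(self) -> float:
        """Second-level GLM covariate: classification run 3 minus run 1."""
        return self.delta_last_first


def pct_tenderness(
    predictions: Sequence[Condition], labels: Sequence[VolumeLabel]
) -> float:
    """Percent of usable tenderness-condition volumes classified tenderness.

    ``predictions`` must cover all volumes of the run (entries at
    non-usable positions are ignored; use any placeholder there).
    """
    idx = [
        l.volume_index
        for l in labels
        if l.usable_for_decoding and l.condition is Condition.TENDERNESS
    ]
    if not idx:
        raise UndefinedMetricError("no usable tenderness volumes")
    hits = sum(1 for i in idx if predictions[i] is Condition.TENDERNESS)
    return 100.0 * hits / len(idx)


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample Student t of mean(values) against mu0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateTestError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero variance")
    return one_sample_t_from_stats(x.mean(), sd, x.size, mu0)


def one_sample_t_from_stats(
    mean: float, sd: float, n: int, mu0: float = 0.0
) -> TestResult:
    """One-sample t from summary statistics: t = (mean - mu0)/(sd/sqrt(n))."""
    if n < 2:
        raise DegenerateTestError("need n >= 2")
    if sd <= 0:
        raise DegenerateTestError("sd must be positive")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), "one_sample_t")


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pooled-variance Student t for mean(a) - mean(b), df = na + nb - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateTestError("each group needs n >= 2")
    return two_sample_t_from_stats(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def two_sample_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if pooled_var == 0:
        raise DegenerateTestError("both groups degenerate")
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), "two_sample_t_pooled")


def binomial_exact(
    successes: int, n: int, p0: float = 0.5, tail: str = "greater"
) -> TestResult:
    """Exact binomial tail probability.

    For ``tail='greater'`` returns P(X >= successes) under Binomial(n, p0),
    the one-sided test of classifier accuracy above chance.
    """
    if not 0 <= successes <= n:
        raise ValueError("successes outside [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    res = sps.binomtest(successes, n, p0, alternative=tail)
    return TestResult(float(successes), float(n), float(res.pvalue), "binomial_exact")


RELIABILITY_ACCURACY_PCT = 60.0  # per-subject criterion on the last session


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean_delta: float
    sd_delta: float
    delta_vs_zero: TestResult | None
    mean_last: float
    sd_last: float
    last_vs_chance: TestResult | None


@dataclass(frozen=True)
class CohortReport:
    """The decoding-results panel: per-group deltas, t tests, binomial flags."""

    groups: dict[Group, GroupSummary]
    between_groups_delta: TestResult | None
    between_groups_last: TestResult | None
    reliable_subjects: dict[str, bool]
    insufficient_n: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, s in self.groups.items():
            rows.append(
                {
                    "group": g.value,
                    "n": s.n,
                    "mean_delta_last_first": s.mean_delta,
                    "sd_delta": s.sd_delta,
                    "t_delta_vs_0": s.delta_vs_zero.statistic if s.delta_vs_zero else np.nan,
                    "p_delta_vs_0": s.delta_vs_zero.p_value if s.delta_vs_zero else np.nan,
                    "mean_last_session": s.mean_last,
                    "sd_last_session": s.sd_last,
                    "t_last_vs_50": s.last_vs_chance.statistic if s.last_vs_chance else np.nan,
                    "p_last_vs_50": s.last_vs_chance.p_value if s.last_vs_chance else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = []
        for g, s in self.groups.items():
            lines.append(
                f"{g.value} (n={s.n}): delta last-first = "
                f"{s.mean_delta:.1f}% +/- {s.sd_delta:.1f}%"
                + (
                    f", t({s.delta_vs_zero.df:.0f}) = {s.delta_vs_zero.statistic:.2f},"
                    f" p = {s.delta_vs_zero.p_value:.3f}"
                    if s.delta_vs_zero
                    else " [insufficient n]"
                )
            )
            lines.append(
                f"  last session = {s.mean_last:.1f}% +/- {s.sd_last:.1f}% vs 50%"
                + (
                    f", t({s.last_vs_chance.df:.0f}) = {s.last_vs_chance.statistic:.2f},"
                    f" p = {s.last_vs_chance.p_value:.3f}"
                    if s.last_vs_chance
                    else " [insufficient n]"
                )
            )
        if self.between_groups_delta is not None:
            t = self.between_groups_delta
            lines.append(
                f"CTR - NFB delta: t({t.df:.0f}) = {t.statistic:.2f}, p = {t.p_value:.3f}"
            )
        n_rel = sum(self.reliable_subjects.values())
        lines.append(
            f"reliable subjects (>{RELIABILITY_ACCURACY_PCT:.0f}% last-session"
            f" accuracy, exact binomial p < .05): {n_rel}/{len(self.reliable_subjects)}"
        )
        return "\n".join(lines)


def _summarize_group(outcomes: list[SubjectOutcome]) -> GroupSummary:
    deltas = np.array([o.delta_last_first for o in outcomes])
    lasts = np.array([o.pct_tenderness_by_session[-1] for o in outcomes])
    n = len(outcomes)

    def _try(values: np.ndarray, mu0: float) -> TestResult | None:
        try:
            return one_sample_t(values, mu0)
        except DegenerateTestError:
            return None

    return GroupSummary(
        n=n,
        mean_delta=float(deltas.mean()),
        sd_delta=float(deltas.std(ddof=1)) if n > 1 else float("nan"),
        delta_vs_zero=_try(deltas, 0.0) if n > 1 else None,
        mean_last=float(lasts.mean()),
        sd_last=float(lasts.std(ddof=1)) if n > 1 else float("nan"),
        last_vs_chance=_try(lasts, 50.0) if n > 1 else None,
    )


def cohort_report(outcomes: Sequence[SubjectOutcome]) -> CohortReport:
    """Aggregate subject outcomes into the group-level results panel."""
    by_group: dict[Group, list[SubjectOutcome]] = {}
    for o in outcomes:
        by_group.setdefault(o.group, []).append(o)
    if not by_group:
        raise ValueError("no outcomes")
    groups = {g: _summarize_group(v) for g, v in by_group.items()}

    between_delta = between_last = None
    if Group.NFB in by_group and Group.CTR in by_group:
        nfb, ctr = by_group[Group.NFB], by_group[Group.CTR]
        if len(nfb) >= 2 and len(ctr) >= 2:
            try:
                between_delta = two_sample_t(
                    [o.delta_last_first for o in ctr],
                    [o.delta_last_first for o in nfb],
                )
                between_last = two_sample_t(
                    [o.pct_tenderness_by_session[-1] for o in nfb],
                    [o.pct_tenderness_by_session[-1] for o in ctr],
                )
            except DegenerateTestError:
                pass

    reliable: dict[str, bool] = {}
    for o in outcomes:
        if o.last_counts is None:
            reliable[o.subject_id] = False
            continue
        successes, n = o.last_counts
        accurate = 100.0 * successes / n > RELIABILITY_ACCURACY_PCT
        significant = binomial_exact(successes, n, 0.5, "greater").p_value < 0.05
        reliable[o.subject_id] = accurate and significant

    insufficient = any(len(v) < 2 for v in by_group.values())
    return CohortReport(
        groups=groups,
        between_groups_delta=between_delta,
        between_groups_last=between_last,
        reliable_subjects=reliable,
        insufficient_n=insufficient,
    )
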