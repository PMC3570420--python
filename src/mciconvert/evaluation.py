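"""Diagnostic-accuracy statistics: confusion metrics with exact binomial
confidence intervals, conversion rates, McNemar's paired test, Cohen's
kappa, and six-category accuracy tables.

Percentages are rounded half-up to integers throughout, matching the
reporting style of the reference tables; ratios of integer counts use
exact integer arithmetic so the rounding is never at the mercy of
floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import GROUP_CONVERTER, GROUP_REVERTER, GROUP_STABLE
from .criteria import Prediction


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rounding helpers


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent_of(numerator: int, denominator: int) -> int:
    """Exact half-up integer percent of an integer ratio."""
    if denominator <= 0:
        raise EvaluationError("percent of a non-positive denominator")
    num, den = int(numerator), int(denominator)
    return (200 * num + den) // (2 * den)


# ---------------------------------------------------------------------------
# binomial machinery


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) central confidence interval."""
    if not 0 <= successes <= n or n < 1:
        raise EvaluationError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2.0, successes, n - successes + 1)
    )
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes)
    )
    return lo, hi


def binomial_ci_pct(successes: int, n: int, level: float = 0.95) -> tuple[int, int]:
    lo, hi = binomial_ci(successes, n, level)
    return round_half_up(100.0 * lo), round_half_up(100.0 * hi)


def conversion_rate(n_converters: int, n_total: int) -> int:
    """Converters as a half-up rounded integer percent of the subgroup."""
    if n_total < 1:
        raise EvaluationError("n_total must be >= 1")
    if not 0 <= n_converters <= n_total:
        raise EvaluationError("n_converters outside [0, n_total]")
    return percent_of(n_converters, n_total)


# ---------------------------------------------------------------------------
# confusion summary


def _as_label(x) -> bool:
    """True = converter (reverters count as non-converters)."""
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if x in (GROUP_CONVERTER, "AD", 1):
        return True
    if x in (GROUP_STABLE, GROUP_REVERTER, "nonconverter", "Healthy", "MCI", 0):
        return False
    raise EvaluationError(f"unrecognized outcome label {x!r}")


def _as_prediction(x) -> bool | None:
    """True/False = predicted converter/nonconverter; None = not evaluable."""
    if x is None:
        return None
    if isinstance(x, Prediction):
        x = x.value
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if x in ("predict_converter", "converter", 1):
        return True
    if x in ("predict_nonconverter", "nonconverter", 0):
        return False
    if x in ("not_evaluable",) or (isinstance(x, float) and math.isnan(x)):
        return None
    raise EvaluationError(f"unrecognized prediction {x!r}")


@dataclass
class ConfusionSummary:
    """TP/FP/TN/FN with derived metrics, exact CIs, and percent forms."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0
    level: float = 0.95

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_evaluable

    @property
    def sensitivity_pct(self) -> int:
        return percent_of(self.tp, self.tp + self.fn)

    @property
    def specificity_pct(self) -> int:
        return percent_of(self.tn, self.tn + self.fp)

    @property
    def accuracy_pct(self) -> int:
        return percent_of(self.tp + self.tn, self.n_evaluable)

    def sensitivity_ci(self) -> tuple[float, float]:
        return binomial_ci(self.tp, self.tp + self.fn, self.level)

    def specificity_ci(self) -> tuple[float, float]:
        return binomial_ci(self.tn, self.tn + self.fp, self.level)

    def accuracy_ci(self) -> tuple[float, float]:
        return binomial_ci(self.tp + self.tn, self.n_evaluable, self.level)

    def sensitivity_ci_pct(self) -> tuple[int, int]:
        return binomial_ci_pct(self.tp, self.tp + self.fn, self.level)

    def specificity_ci_pct(self) -> tuple[int, int]:
        return binomial_ci_pct(self.tn, self.tn + self.fp, self.level)

    def as_dict(self) -> dict:
        sens_ci = self.sensitivity_ci_pct()
        spec_ci = self.specificity_ci_pct()
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_evaluable": self.n_evaluable, "n_excluded": self.n_excluded,
            "sensitivity_pct": self.sensitivity_pct,
            "sensitivity_ci_low_pct": sens_ci[0],
            "sensitivity_ci_high_pct": sens_ci[1],
            "specificity_pct": self.specificity_pct,
            "specificity_ci_low_pct": spec_ci[0],
            "specificity_ci_high_pct": spec_ci[1],
            "accuracy_pct": self.accuracy_pct,
        }


def confusion(predictions: Sequence, labels: Sequence, level: float = 0.95) -> ConfusionSummary:
    """Tally a confusion summary; not-evaluable predictions are excluded
    from the counts and reported in ``n_excluded``."""
    if len(predictions) != len(labels):
        raise EvaluationError("predictions and labels differ in length")
    tp = fp = tn = fn = excluded = 0
    for p_raw, l_raw in zip(predictions, labels):
        p = _as_prediction(p_raw)
        if p is None:
            excluded += 1
            continue
        l = _as_label(l_raw)
        if p and l:
            tp += 1
        elif p and not l:
            fp += 1
        elif not p and l:
            fn += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise EvaluationError("zero evaluable subjects")
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, n_excluded=excluded, level=level)


# ---------------------------------------------------------------------------
# McNemar


@dataclass(frozen=True)
class McNemarResult:
    b: int  # correct by A only
    c: int  # correct by B only
    p_value: float
    method: str  # exact | chi2_cc | degenerate
    no_discordance: bool = False


def mcnemar(correct_a: Sequence[bool], correct_b: Sequence[bool],
            exact_threshold: int = 25) -> McNemarResult:
    """Paired comparison of two classifiers via discordant correctness.

    Exact two-sided binomial test when b + c <= ``exact_threshold``,
    otherwise chi-square with continuity correction. Zero discordant
    pairs yields p = 1.0, flagged.
    """
    if len(correct_a) != len(correct_b):
        raise EvaluationError("correctness vectors differ in length")
    a = np.asarray(correct_a, dtype=bool)
    bv = np.asarray(correct_b, dtype=bool)
    b = int(np.sum(a & ~bv))
    c = int(np.sum(~a & bv))
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, p_value=1.0, method="degenerate",
                             no_discordance=True)
    if n <= exact_threshold:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return McNemarResult(b=b, c=c, p_value=p, method="exact")
    statistic = (max(0.0, abs(b - c) - 1.0)) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(b=b, c=c, p_value=min(1.0, p), method="chi2_cc")


# ---------------------------------------------------------------------------
# Cohen's kappa


@dataclass(frozen=True)
class KappaResult:
    kappa: float  # nan when undefined
    n: int
    observed_agreement: float
    expected_agreement: float
    undefined: bool = False


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa over a shared categorical label set.

    Undefined (nan, flagged) when chance agreement is exactly 1, i.e.
    both raters are single-category constants.
    """
    if len(ratings_a) != len(ratings_b):
        raise EvaluationError("rating vectors differ in length")
    if len(ratings_a) == 0:
        raise EvaluationError("empty rating vectors")
    labels = sorted(set(ratings_a) | set(ratings_b), key=repr)
    index = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    table = np.zeros((k, k), dtype=float)
    for ra, rb in zip(ratings_a, ratings_b):
        table[index[ra], index[rb]] += 1
    n = table.sum()
    po = float(np.trace(table) / n)
    pe = float(np.sum(table.sum(axis=0) * table.sum(axis=1)) / n**2)
    if pe == 1.0:
        return KappaResult(kappa=float("nan"), n=int(n), observed_agreement=po,
                           expected_agreement=pe, undefined=True)
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa=kappa, n=int(n), observed_agreement=po,
                       expected_agreement=pe)


def collapse_six_to_binary(levels: Iterable[int]) -> list[str]:
    """Six-level scale to the binary call: levels 1-3 non-AD, 4-6 AD."""
    out = []
    for lv in levels:
        if lv not in (1, 2, 3, 4, 5, 6):
            raise EvaluationError(f"level {lv!r} outside 1-6")
        out.append("AD" if lv >= 4 else "non-AD")
    return out


# ---------------------------------------------------------------------------
# six-category accuracy table

FINAL_LABELS = ("AD", "Healthy", "MCI")


def final_label_from_group(group: str) -> str:
    return {GROUP_CONVERTER: "AD", GROUP_REVERTER: "Healthy", GROUP_STABLE: "MCI"}[group]


@dataclass(frozen=True)
class CategoryRow:
    label: str
    ad: int
    healthy: int
    mci: int
    n_correct: int

    @property
    def total(self) -> int:
        return self.ad + self.healthy + self.mci

    @property
    def accuracy_pct(self) -> int:
        return percent_of(self.n_correct, self.total)


@dataclass
class CategoryAccuracyTable:
    """Per six-level category: final-diagnosis counts, row accuracy, the
    pooled non-AD (1-3) and AD (4-6) rows, and overall accuracy. Correct
    means Healthy or MCI in levels 1-3 and AD in levels 4-6; reverters
    (Healthy) still belong to the non-AD group."""

    rows: list[CategoryRow]
    pooled_non_ad: CategoryRow
    pooled_ad: CategoryRow

    @property
    def n_total(self) -> int:
        return sum(r.total for r in self.rows)

    @property
    def overall_accuracy_pct(self) -> int:
        return percent_of(sum(r.n_correct for r in self.rows), self.n_total)

    def share_pct(self, row: CategoryRow) -> int:
        return percent_of(row.total, self.n_total)


def category_table_from_counts(
    counts: Mapping[int, tuple[int, int, int]]
) -> CategoryAccuracyTable:
    """Build the table from per-level (AD, Healthy, MCI) counts."""
    rows = []
    for level in range(1, 7):
        ad, healthy, mci = (int(v) for v in counts.get(level, (0, 0, 0)))
        correct = healthy + mci if level <= 3 else ad
        rows.append(CategoryRow(label=f"level_{level}", ad=ad, healthy=healthy,
                                mci=mci, n_correct=correct))

    def pool(subset: list[CategoryRow], label: str) -> CategoryRow:
        return CategoryRow(
            label=label,
            ad=sum(r.ad for r in subset),
            healthy=sum(r.healthy for r in subset),
            mci=sum(r.mci for r in subset),
            n_correct=sum(r.n_correct for r in subset),
        )

    return CategoryAccuracyTable(
        rows=rows,
        pooled_non_ad=pool(rows[:3], "non_ad_1_3"),
        pooled_ad=pool(rows[3:], "ad_4_6"),
    )


def category_table(
    categories: Sequence[int], final_labels: Sequence[str]
) -> CategoryAccuracyTable:
    if len(categories) != len(final_labels):
        raise EvaluationError("categories and labels differ in length")
    counts = {lv: [0, 0, 0] for lv in range(1, 7)}
    for cat, lab in zip(categories, final_labels):
        if cat not in counts:
            raise EvaluationError(f"category {cat!r} outside 1-6")
        if lab not in FINAL_LABELS:
            raise EvaluationError(f"final label {lab!r} not in {FINAL_LABELS}")
        counts[cat][FINAL_LABELS.index(lab)] += 1
    return category_table_from_counts({lv: tuple(v) for lv, v in counts.items()})
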