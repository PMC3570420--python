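"""Disease state index (DSI): composite 0-1 disease-state score.

Per feature, *fitness* positions a measured value between an empirical
negative (non-converter) and positive (converter) reference population:

    fitness(x) = FN(x) / (FN(x) + FP(x))

where, for ``abnormal_direction='high'``, FN(x) is the fraction of the
positive reference at or below x and FP(x) the fraction of the negative
reference above x (empirical distribution functions, ties counted at
half weight); ``'low'`` mirrors this. When both vanish (x falls between
the two supports) fitness is 0.5, maximal ambiguity.

Per feature, *relevance* is Youden's J = max_t (sensitivity(t) +
specificity(t) - 1) over candidate thresholds at midpoints of adjacent
pooled order statistics.

The composite aggregates leaf fitnesses up a grouping tree (modality
branches under a root) by relevance-weighted mean, skipping branches
with no observed data, so arbitrary missingness is tolerated. Fitting
and scoring involve no randomness.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import GROUP_CONVERTER, SubjectRecord

CATEGORY_BOUNDS = (0.17, 0.33, 0.50, 0.67, 0.83)

#: default grouping: modality branches under the root
DEFAULT_TREE: dict[str, list[str]] = {
    "root": ["demographics_genetics", "neuropsychology", "mri", "csf"],
    "demographics_genetics": ["age", "male", "education_years", "apoe4"],
    "neuropsychology": [
        "mmse",
        "ravlt_recall",
        "ravlt_recognition",
        "adas_cog11",
        "adas_cog13",
        "clock_drawing",
        "digit_span_forward",
        "digit_span_backward",
        "category_fluency",
        "tmt_a",
        "tmt_b",
        "digit_symbol",
    ],
    "mri": ["scheltens"],
    "csf": ["csf_tau", "csf_abeta42"],
}


class DsiFitError(ValueError):
    """Reference population unusable for fitting."""


class DsiScoreError(ValueError):
    """Subject cannot be scored (no observed features)."""


# ---------------------------------------------------------------------------
# per-feature reference


def _clean(values: Iterable[float | None]) -> np.ndarray:
    arr = [float(v) for v in values if v is not None and not math.isnan(float(v))]
    return np.sort(np.asarray(arr, dtype=float))


def _mid_leq(sorted_vals: np.ndarray, x: float) -> float:
    """Fraction of values <= x, equal values counted at half weight."""
    lo = np.searchsorted(sorted_vals, x, side="left")
    hi = np.searchsorted(sorted_vals, x, side="right")
    return (lo + 0.5 * (hi - lo)) / len(sorted_vals)


def _youden(neg: np.ndarray, pos: np.ndarray, direction: str) -> float:
    """Max of sensitivity + specificity - 1 over midpoint thresholds."""
    pooled = np.unique(np.concatenate([neg, pos]))
    if len(pooled) < 2:
        return 0.0
    cuts = (pooled[1:] + pooled[:-1]) / 2.0
    if direction == "high":
        sens = 1.0 - np.searchsorted(pos, cuts, side="right") / len(pos)
        spec = np.searchsorted(neg, cuts, side="right") / len(neg)
    else:
        sens = np.searchsorted(pos, cuts, side="left") / len(pos)
        spec = 1.0 - np.searchsorted(neg, cuts, side="left") / len(neg)
    return float(max(0.0, np.max(sens + spec - 1.0)))


@dataclass(frozen=True)
class FeatureReference:
    """Empirical negative/positive reference samples for one feature."""

    name: str
    neg: np.ndarray  # sorted
    pos: np.ndarray  # sorted
    direction: str  # low | high
    relevance: float

    def fitness(self, x: float) -> float:
        if x is None or math.isnan(x):
            raise ValueError(f"{self.name}: fitness of a missing value")
        if self.direction == "high":
            fn = _mid_leq(self.pos, x)
            fp = 1.0 - _mid_leq(self.neg, x)
        else:
            fn = 1.0 - _mid_leq(self.pos, x)
            fp = _mid_leq(self.neg, x)
        total = fn + fp
        if total == 0.0:
            return 0.5
        return fn / total


def fit_feature_reference(
    name: str,
    values_neg: Iterable[float | None],
    values_pos: Iterable[float | None],
    direction: str | None = None,
) -> FeatureReference:
    """Fit one feature's reference; ``direction=None`` infers it from the
    sample means (positive mean higher -> 'high')."""
    neg = _clean(values_neg)
    pos = _clean(values_pos)
    if len(neg) < 2 or len(pos) < 2:
        raise DsiFitError(
            f"feature {name!r}: needs >= 2 observed values per reference "
            f"population (got {len(neg)} negative, {len(pos)} positive)"
        )
    if direction is None:
        direction = "high" if pos.mean() >= neg.mean() else "low"
    if direction not in ("low", "high"):
        raise DsiFitError(f"feature {name!r}: bad direction {direction!r}")
    return FeatureReference(
        name=name, neg=neg, pos=pos, direction=direction,
        relevance=_youden(neg, pos, direction),
    )


# ---------------------------------------------------------------------------
# model


@dataclass
class DsiModel:
    """Per-feature references plus the grouping tree."""

    refs: dict[str, FeatureReference]
    tree: dict[str, list[str]]
    root: str = "root"

    def __post_init__(self):
        self.validate()

    @property
    def leaves(self) -> list[str]:
        return [n for ch in self.tree.values() for n in ch if n not in self.tree]

    def validate(self) -> None:
        leaves = self.leaves
        if len(set(leaves)) != len(leaves):
            raise ValueError("a leaf appears more than once in the tree")
        if self.root not in self.tree:
            raise ValueError(f"root {self.root!r} not in tree")
        missing = set(leaves) - set(self.refs)
        if missing:
            raise ValueError(f"leaves without references: {sorted(missing)}")
        # acyclicity / reachability
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise ValueError("grouping tree contains a cycle")
            seen.add(node)
            stack.extend(c for c in self.tree.get(node, []) if c in self.tree)

    def score(self, subject, cutoff: float = 0.5) -> "DsiResult":
        return composite_dsi(subject, self, cutoff=cutoff)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "root": self.root,
            "tree": self.tree,
            "refs": {
                n: {
                    "neg": r.neg.tolist(),
                    "pos": r.pos.tolist(),
                    "direction": r.direction,
                    "relevance": r.relevance,
                }
                for n, r in sorted(self.refs.items())
            },
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DsiModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        refs = {
            n: FeatureReference(
                name=n,
                neg=np.asarray(d["neg"], dtype=float),
                pos=np.asarray(d["pos"], dtype=float),
                direction=d["direction"],
                relevance=float(d["relevance"]),
            )
            for n, d in payload["refs"].items()
        }
        return cls(refs=refs, tree=payload["tree"], root=payload["root"])


def fit_dsi_model(
    records: Sequence[SubjectRecord],
    tree: Mapping[str, list[str]] | None = None,
    features: Sequence[str] | None = None,
    directions: Mapping[str, str] | None = None,
) -> DsiModel:
    """Fit references from a training cohort (converters = positive).

    With ``tree=None`` the default modality tree is used, pruned to the
    features that are actually fittable; features in the data but not in
    the default tree are grouped under an ``other`` branch (a cohort with
    none of the default features yields a flat tree). An explicit
    ``features`` list yields a flat tree over those features and fitting
    failures become errors.
    """
    neg_records = [r for r in records if r.group != GROUP_CONVERTER]
    pos_records = [r for r in records if r.group == GROUP_CONVERTER]
    if features is not None:
        candidate = list(features)
        base_tree = {"root": candidate} if tree is None else {
            k: list(v) for k, v in tree.items()
        }
    elif tree is not None:
        base_tree = {k: list(v) for k, v in tree.items()}
        candidate = [n for ch in base_tree.values() for n in ch if n not in base_tree]
    else:
        present: list[str] = []
        for r in records:
            for name in r.features:
                if name not in present:
                    present.append(name)
        default_leaves = {
            n for ch in DEFAULT_TREE.values() for n in ch if n not in DEFAULT_TREE
        }
        known = [n for n in present if n in default_leaves]
        extra = [n for n in present if n not in default_leaves]
        if not known:
            base_tree = {"root": extra}
        else:
            base_tree = {
                node: [c for c in ch if c in DEFAULT_TREE or c in known]
                for node, ch in DEFAULT_TREE.items()
            }
            if extra:
                base_tree["root"] = base_tree["root"] + ["other"]
                base_tree["other"] = extra
        candidate = known + extra

    refs: dict[str, FeatureReference] = {}
    for name in candidate:
        try:
            refs[name] = fit_feature_reference(
                name,
                (r.features.get(name) for r in neg_records),
                (r.features.get(name) for r in pos_records),
                direction=None if directions is None else directions.get(name),
            )
        except DsiFitError:
            if features is not None:
                raise
    if not refs:
        raise DsiFitError("no fittable features in the training cohort")

    # prune unfittable leaves and empty branches
    pruned: dict[str, list[str]] = {}
    for node, children in base_tree.items():
        pruned[node] = [c for c in children if c in base_tree or c in refs]

    def alive(node: str) -> bool:
        if node not in pruned:
            return node in refs
        return any(alive(c) for c in pruned[node])

    tree_final = {
        node: [c for c in children if alive(c)]
        for node, children in pruned.items()
        if alive(node)
    }
    return DsiModel(refs=refs, tree=tree_final)


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class NodeScore:
    dsi: float | None
    relevance: float | None
    n_observed: int
    n_missing: int


@dataclass
class DsiResult:
    composite: float
    category: int
    call: str  # converter | nonconverter
    cutoff: float
    n_observed: int
    n_missing: int
    nodes: dict[str, NodeScore]
    tree: dict[str, list[str]]


def dsi_category(value: float) -> int:
    """Six-level scale over [0,1]: boundaries 0.17/0.33/0.50/0.67/0.83,
    lower bound inclusive from level 2 upward."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"DSI value {value} outside [0, 1]")
    return 1 + bisect_right(CATEGORY_BOUNDS, value)


def classify(value: float, cutoff: float = 0.5) -> str:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"DSI value {value} outside [0, 1]")
    return "converter" if value >= cutoff else "nonconverter"


def composite_dsi(
    subject: SubjectRecord | Mapping[str, float | None],
    model: DsiModel,
    cutoff: float = 0.5,
) -> DsiResult:
    """Score one subject; branches with no observed descendant are
    excluded from the weighting. Raises if nothing is observed."""
    features = subject.features if isinstance(subject, SubjectRecord) else subject
    nodes: dict[str, NodeScore] = {}

    def visit(node: str) -> NodeScore:
        if node not in model.tree:  # leaf
            ref = model.refs[node]
            v = features.get(node)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                score = NodeScore(None, None, 0, 1)
            else:
                score = NodeScore(ref.fitness(float(v)), ref.relevance, 1, 0)
            nodes[node] = score
            return score
        children = [visit(c) for c in model.tree[node]]
        included = [c for c in children if c.n_observed > 0]
        n_obs = sum(c.n_observed for c in children)
        n_miss = sum(c.n_missing for c in children)
        if not included:
            score = NodeScore(None, None, 0, n_miss)
        else:
            rel_sum = sum(c.relevance for c in included)
            if rel_sum > 0:
                dsi = sum(c.relevance * c.dsi for c in included) / rel_sum
            else:  # all-zero relevance: fall back to the plain mean
                dsi = sum(c.dsi for c in included) / len(included)
            relevance = sum(c.relevance for c in included) / len(included)
            score = NodeScore(dsi, relevance, n_obs, n_miss)
        nodes[node] = score
        return score

    root = visit(model.root)
    if root.n_observed == 0:
        sid = getattr(subject, "subject_id", "<subject>")
        raise DsiScoreError(f"{sid}: all features missing, cannot score")
    value = min(1.0, max(0.0, root.dsi))  # clamp float jitter
    return DsiResult(
        composite=value,
        category=dsi_category(value),
        call=classify(value, cutoff),
        cutoff=cutoff,
        n_observed=root.n_observed,
        n_missing=root.n_missing,
        nodes=nodes,
        tree={k: list(v) for k, v in model.tree.items()},
    )


# ---------------------------------------------------------------------------
# fingerprint export


def export_fingerprint(result: DsiResult, path=None) -> str:
    """Structured text rendering of the per-node breakdown.

    Branches with no observed data are flagged ``"no_data": true`` and
    carry no index value.
    """
    payload = {
        "composite": result.composite,
        "category": result.category,
        "call": result.call,
        "cutoff": result.cutoff,
        "n_observed": result.n_observed,
        "n_missing": result.n_missing,
        "tree": result.tree,
        "nodes": {
            name: {
                "dsi": ns.dsi,
                "relevance": ns.relevance,
                "n_observed": ns.n_observed,
                "n_missing": ns.n_missing,
                "no_data": ns.n_observed == 0,
            }
            for name, ns in sorted(result.nodes.items())
        },
    }
    text = json.dumps(payload, sort_keys=True, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_fingerprint(source) -> dict:
    if hasattr(source, "read"):
        return json.load(source)
    try:
        return json.loads(source)
    except (ValueError, TypeError):
        with open(source) as fh:
            return json.load(fh)


# ---------------------------------------------------------------------------
# train/test split


def split_cohort(
    records: Sequence[SubjectRecord], seed: int, test_fraction: float = 0.5
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Group-stratified train/test split, deterministic per seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for group in sorted({r.group for r in records}):
        idx = [i for i, r in enumerate(records) if r.group == group]
        n_test = int(round(test_fraction * len(idx)))
        chosen = rng.permutation(len(idx))[:n_test]
        test_idx.update(idx[i] for i in chosen)
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test
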