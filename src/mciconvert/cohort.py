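"""Seeded synthetic MCI cohort generation and lossless CSV round-trip I/O.

A :class:`CohortSpec` holds group-conditional generative parameters
(means/SDs for continuous and integer features, carrier frequencies for
binary features), exact modality-availability counts, and the outcome mix
(converters / stable MCI / reverters).  :func:`generate_cohort` draws a
cohort that honors every count *exactly* (not in expectation) and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr

log = logging.getLogger(__name__)

GROUP_CONVERTER = "converter"
GROUP_STABLE = "stable_mci"
GROUP_REVERTER = "reverter"
GROUPS = (GROUP_CONVERTER, GROUP_STABLE, GROUP_REVERTER)

#: spec-level strata (the generator parameterizes non-converters jointly)
STRATUM_NEG = "non_converter"
STRATUM_POS = "converter"

MRI_FEATURES = ("scheltens",)
CSF_FEATURES = ("csf_tau", "csf_abeta42")
APOE_FEATURE = "apoe4"

RESERVED_COLUMNS = ("subject_id", "group", "mri_present", "csf_present")


class CohortConfigError(ValueError):
    """Invalid or infeasible cohort specification."""


class CohortValidationError(ValueError):
    """A cohort file or record violates a structural invariant."""


# ---------------------------------------------------------------------------
# specification types


@dataclass(frozen=True)
class FeatureSpec:
    """Group-conditional generative parameters for one feature."""

    name: str
    kind: str  # continuous | integer | binary
    abnormal_direction: str  # low | high
    mean_neg: float | None = None
    sd_neg: float | None = None
    mean_pos: float | None = None
    sd_pos: float | None = None
    p_neg: float | None = None
    p_pos: float | None = None
    clip_min: float | None = None
    clip_max: float | None = None

    def validate(self) -> None:
        if self.kind not in ("continuous", "integer", "binary"):
            raise CohortConfigError(f"{self.name}: unknown kind {self.kind!r}")
        if self.abnormal_direction not in ("low", "high"):
            raise CohortConfigError(
                f"{self.name}: unknown abnormal_direction {self.abnormal_direction!r}"
            )
        if self.kind == "binary":
            for p in (self.p_neg, self.p_pos):
                if p is None or not 0.0 <= p <= 1.0:
                    raise CohortConfigError(f"{self.name}: binary p outside [0, 1]")
        else:
            for v in (self.mean_neg, self.sd_neg, self.mean_pos, self.sd_pos):
                if v is None:
                    raise CohortConfigError(f"{self.name}: missing mean/sd")
            if self.sd_neg < 0 or self.sd_pos < 0:
                raise CohortConfigError(f"{self.name}: negative sd")
            lo = -math.inf if self.clip_min is None else self.clip_min
            hi = math.inf if self.clip_max is None else self.clip_max
            if lo > hi:
                raise CohortConfigError(f"{self.name}: clip_min > clip_max")


@dataclass(frozen=True)
class MissingnessSpec:
    """Exact modality-availability counts, total and per stratum."""

    mri_available_total: int
    csf_available_total: int
    both_available_total: int
    scheltens_available: Mapping[str, int]
    csf_available: Mapping[str, int]
    apoe_available: Mapping[str, int] | None = None


@dataclass
class CohortSpec:
    """Machine form of the cohort summary table driving the generator."""

    n_total: int
    n_converters: int
    n_reverters: int
    features: Sequence[FeatureSpec]
    missingness: MissingnessSpec | None = None
    correlation: float = 0.0

    @property
    def n_nonconverters(self) -> int:
        return self.n_total - self.n_converters

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self) -> None:
        if self.n_converters < 0 or self.n_converters > self.n_total:
            raise CohortConfigError("n_converters outside [0, n_total]")
        if self.n_reverters < 0 or self.n_reverters > self.n_nonconverters:
            raise CohortConfigError("n_reverters exceeds non-converter stratum")
        if not 0.0 <= self.correlation < 1.0:
            raise CohortConfigError("correlation must be in [0, 1)")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise CohortConfigError("duplicate feature names")
        for f in self.features:
            f.validate()
        m = self.missingness
        if m is None:
            return
        sizes = {STRATUM_NEG: self.n_nonconverters, STRATUM_POS: self.n_converters}
        if m.both_available_total > min(m.mri_available_total, m.csf_available_total):
            raise CohortConfigError("both_available_total exceeds a modality total")
        if sum(m.scheltens_available.values()) != m.mri_available_total:
            raise CohortConfigError("per-stratum Scheltens counts do not sum to MRI total")
        if sum(m.csf_available.values()) != m.csf_available_total:
            raise CohortConfigError("per-stratum CSF counts do not sum to CSF total")
        for tbl in (m.scheltens_available, m.csf_available) + (
            (m.apoe_available,) if m.apoe_available else ()
        ):
            for stratum, count in tbl.items():
                if stratum not in sizes:
                    raise CohortConfigError(f"unknown stratum {stratum!r}")
                if not 0 <= count <= sizes[stratum]:
                    raise CohortConfigError(
                        f"availability count {count} infeasible for stratum {stratum!r}"
                    )
        _solve_both_counts(self)  # raises if jointly infeasible

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        feats = [FeatureSpec(**f) for f in d["features"]]
        miss = d.get("missingness")
        missingness = MissingnessSpec(**miss) if miss else None
        return cls(
            n_total=int(d["n_total"]),
            n_converters=int(d["n_converters"]),
            n_reverters=int(d.get("n_reverters", 0)),
            features=feats,
            missingness=missingness,
            correlation=float(d.get("correlation", 0.0)),
        )

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_converters": self.n_converters,
            "n_reverters": self.n_reverters,
            "correlation": self.correlation,
            "features": [
                {k: v for k, v in vars(f).items() if v is not None}
                for f in self.features
            ],
        }
        if self.missingness is not None:
            m = self.missingness
            d["missingness"] = {
                "mri_available_total": m.mri_available_total,
                "csf_available_total": m.csf_available_total,
                "both_available_total": m.both_available_total,
                "scheltens_available": dict(m.scheltens_available),
                "csf_available": dict(m.csf_available),
            }
            if m.apoe_available is not None:
                d["missingness"]["apoe_available"] = dict(m.apoe_available)
        return d

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_cohort_spec() -> CohortSpec:
    """The packaged default: 391 subjects, 158 converters, 15 reverters,
    387/199/195 MRI/CSF/both availability, and per-feature parameters of
    the reference MCI sample."""
    ref = resources.files("mciconvert").joinpath("data/default_cohort.yaml")
    spec = CohortSpec.from_dict(yaml.safe_load(ref.read_text()))
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# subject records


@dataclass
class SubjectRecord:
    """One MCI subject: feature map (None = missing) plus outcome group."""

    subject_id: str
    group: str
    features: dict[str, float | None]
    mri_present: bool = True
    csf_present: bool = True

    @property
    def is_converter(self) -> bool:
        return self.group == GROUP_CONVERTER


# ---------------------------------------------------------------------------
# generation


def _solve_both_counts(spec: CohortSpec) -> dict[str, int]:
    """Allocate the total 'both modalities available' count across strata.

    Bounded by max(0, mri_g + csf_g - n_g) <= both_g <= min(mri_g, csf_g)
    per stratum; the remainder above the lower bounds is distributed in
    fixed stratum order so the allocation is deterministic.
    """
    m = spec.missingness
    assert m is not None
    sizes = {STRATUM_NEG: spec.n_nonconverters, STRATUM_POS: spec.n_converters}
    lower, upper = {}, {}
    for g in (STRATUM_NEG, STRATUM_POS):
        mri_g = m.scheltens_available.get(g, 0)
        csf_g = m.csf_available.get(g, 0)
        lower[g] = max(0, mri_g + csf_g - sizes[g])
        upper[g] = min(mri_g, csf_g)
    total = m.both_available_total
    if not sum(lower.values()) <= total <= sum(upper.values()):
        raise CohortConfigError(
            "both_available_total infeasible given per-stratum modality counts"
        )
    both = dict(lower)
    remaining = total - sum(lower.values())
    for g in (STRATUM_NEG, STRATUM_POS):
        take = min(remaining, upper[g] - both[g])
        both[g] += take
        remaining -= take
    return both


def _draw_group(
    spec: CohortSpec, n: int, positive: bool, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw an n-by-features matrix for one stratum.

    A single-parameter Gaussian copula (equicorrelation) couples the
    features when spec.correlation > 0; marginals are untouched.
    """
    z = rng.standard_normal((n, len(spec.features)))
    rho = spec.correlation
    if rho > 0.0:
        shared = rng.standard_normal((n, 1))
        z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * z
    out: dict[str, np.ndarray] = {}
    for j, f in enumerate(spec.features):
        col = z[:, j]
        if f.kind == "binary":
            p = f.p_pos if positive else f.p_neg
            out[f.name] = (ndtr(col) < p).astype(float)
            continue
        mean = f.mean_pos if positive else f.mean_neg
        sd = f.sd_pos if positive else f.sd_neg
        x = mean + sd * col
        if f.kind == "integer":
            x = np.floor(x + 0.5)  # half-up
        lo = -math.inf if f.clip_min is None else f.clip_min
        hi = math.inf if f.clip_max is None else f.clip_max
        out[f.name] = np.clip(x, lo, hi)
    return out


def _availability_flags(
    n: int, n_mri: int, n_csf: int, n_both: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pick subjects without replacement so MRI / CSF / both counts are exact."""
    if n_mri + n_csf - n_both > n:
        raise CohortConfigError("modality counts exceed stratum size")
    perm = rng.permutation(n)
    mri = np.zeros(n, dtype=bool)
    csf = np.zeros(n, dtype=bool)
    mri[perm[:n_both]] = True
    csf[perm[:n_both]] = True
    mri[perm[n_both : n_both + (n_mri - n_both)]] = True
    start = n_both + (n_mri - n_both)
    csf[perm[start : start + (n_csf - n_both)]] = True
    return mri, csf


def generate_cohort(spec: CohortSpec, seed: int) -> list[SubjectRecord]:
    """Generate a cohort matching ``spec`` exactly; reproducible per seed.

    Stratum counts, reverter count, and MRI/CSF/both availability are hit
    exactly in every cohort; feature values are drawn group-conditionally
    and clipped/rounded per feature kind.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_pos = spec.n_converters
    n_neg = spec.n_nonconverters

    x_neg = _draw_group(spec, n_neg, positive=False, rng=rng)
    x_pos = _draw_group(spec, n_pos, positive=True, rng=rng)

    reverters = set(
        rng.choice(n_neg, size=spec.n_reverters, replace=False).tolist()
        if spec.n_reverters
        else []
    )

    m = spec.missingness
    feature_names = [f.name for f in spec.features]
    if m is not None:
        both = _solve_both_counts(spec)
        mri_neg, csf_neg = _availability_flags(
            n_neg,
            m.scheltens_available.get(STRATUM_NEG, 0),
            m.csf_available.get(STRATUM_NEG, 0),
            both[STRATUM_NEG],
            rng,
        )
        mri_pos, csf_pos = _availability_flags(
            n_pos,
            m.scheltens_available.get(STRATUM_POS, 0),
            m.csf_available.get(STRATUM_POS, 0),
            both[STRATUM_POS],
            rng,
        )
        apoe_flags = {}
        if m.apoe_available is not None and APOE_FEATURE in feature_names:
            for g, n_g in ((STRATUM_NEG, n_neg), (STRATUM_POS, n_pos)):
                avail = np.zeros(n_g, dtype=bool)
                avail[rng.permutation(n_g)[: m.apoe_available.get(g, n_g)]] = True
                apoe_flags[g] = avail
        else:
            apoe_flags = {
                STRATUM_NEG: np.ones(n_neg, dtype=bool),
                STRATUM_POS: np.ones(n_pos, dtype=bool),
            }
    else:
        mri_neg = np.ones(n_neg, dtype=bool)
        csf_neg = np.ones(n_neg, dtype=bool)
        mri_pos = np.ones(n_pos, dtype=bool)
        csf_pos = np.ones(n_pos, dtype=bool)
        apoe_flags = {
            STRATUM_NEG: np.ones(n_neg, dtype=bool),
            STRATUM_POS: np.ones(n_pos, dtype=bool),
        }

    records: list[SubjectRecord] = []
    width = len(str(spec.n_total))

    def build(i_global, group, values, i, mri_ok, csf_ok, apoe_ok):
        feats: dict[str, float | None] = {}
        for name in feature_names:
            v: float | None = float(values[name][i])
            if name in MRI_FEATURES and not mri_ok:
                v = None
            elif name in CSF_FEATURES and not csf_ok:
                v = None
            elif name == APOE_FEATURE and not apoe_ok:
                v = None
            feats[name] = v
        return SubjectRecord(
            subject_id=f"mci_{i_global:0{width}d}",
            group=group,
            features=feats,
            mri_present=bool(mri_ok),
            csf_present=bool(csf_ok),
        )

    k = 1
    for i in range(n_pos):
        records.append(
            build(k, GROUP_CONVERTER, x_pos, i, mri_pos[i], csf_pos[i],
                  apoe_flags[STRATUM_POS][i])
        )
        k += 1
    for i in range(n_neg):
        group = GROUP_REVERTER if i in reverters else GROUP_STABLE
        records.append(
            build(k, group, x_neg, i, mri_neg[i], csf_neg[i],
                  apoe_flags[STRATUM_NEG][i])
        )
        k += 1
    return records


def simulate_rater(
    dsi_values: Iterable[float], disagreement_sd: float, seed: int
) -> list[int]:
    """Six-level categorizations of DSI values by a noisy simulated rater.

    Gaussian noise with ``disagreement_sd`` is added before binning;
    ``disagreement_sd=0`` reproduces the deterministic binning exactly.
    """
    from .dsi import dsi_category

    arr = np.asarray(list(dsi_values), dtype=float)
    if disagreement_sd < 0:
        raise ValueError("disagreement_sd must be non-negative")
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("DSI values must lie in [0, 1]")
    if disagreement_sd > 0:
        rng = np.random.default_rng(seed)
        arr = np.clip(arr + rng.normal(0.0, disagreement_sd, size=arr.shape), 0.0, 1.0)
    return [dsi_category(float(v)) for v in arr]


# ---------------------------------------------------------------------------
# CSV I/O

_CANONICAL_CHECKS = {
    "scheltens": ("integer 0-4", lambda v: float(v).is_integer() and 0 <= v <= 4),
    "ravlt_recall": ("non-negative integer", lambda v: float(v).is_integer() and v >= 0),
    "ravlt_recognition": ("non-negative integer", lambda v: float(v).is_integer() and v >= 0),
    "csf_tau": ("strictly positive", lambda v: v > 0),
    "csf_abeta42": ("strictly positive", lambda v: v > 0),
}


def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    """Write one row per subject; missing values become empty cells."""
    if not records:
        pd.DataFrame(columns=list(RESERVED_COLUMNS)).to_csv(path, index=False)
        return
    feature_names = list(records[0].features)
    rows = []
    for r in records:
        row: dict = {
            "subject_id": r.subject_id,
            "group": r.group,
            "mri_present": int(r.mri_present),
            "csf_present": int(r.csf_present),
        }
        for name in feature_names:
            row[name] = r.features.get(name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path, feature_names: Sequence[str] | None = None) -> list[SubjectRecord]:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-built).

    ``feature_names``, when given, closes the schema: any other feature
    column raises. Canonical columns (scheltens, RAVLT, CSF analytes) are
    range-validated regardless.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"subject_id": str, "group": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        log.warning("cohort file %s is empty", path)
        return []
    if df.empty:
        log.warning("cohort file %s has a header but no rows", path)
        return []
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    feats = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if feature_names is not None:
        unknown = sorted(set(feats) - set(feature_names))
        if unknown:
            raise CohortValidationError(f"unknown columns: {unknown}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortValidationError(f"duplicate subject_id: {dupes}")
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise CohortValidationError(f"unknown group labels: {bad_groups}")

    for c in feats:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(f"non-numeric value in column {c!r}") from exc
    for c, (desc, ok) in _CANONICAL_CHECKS.items():
        if c in df.columns:
            vals = df[c].dropna()
            if not vals.map(ok).all():
                raise CohortValidationError(f"column {c!r} must be {desc}")

    has_mri_col = "mri_present" in df.columns
    has_csf_col = "csf_present" in df.columns
    records = []
    for _, row in df.iterrows():
        features = {
            c: (None if pd.isna(row[c]) else float(row[c])) for c in feats
        }
        mri_ok = bool(row["mri_present"]) if has_mri_col else any(
            features.get(c) is not None for c in MRI_FEATURES if c in features
        ) or not any(c in features for c in MRI_FEATURES)
        csf_ok = bool(row["csf_present"]) if has_csf_col else any(
            features.get(c) is not None for c in CSF_FEATURES if c in features
        ) or not any(c in features for c in CSF_FEATURES)
        if not mri_ok:
            for c in MRI_FEATURES:
                if features.get(c) is not None:
                    raise CohortValidationError(
                        f"{row['subject_id']}: MRI flagged absent but {c} present"
                    )
        if not csf_ok:
            for c in CSF_FEATURES:
                if features.get(c) is not None:
                    raise CohortValidationError(
                        f"{row['subject_id']}: CSF flagged absent but {c} present"
                    )
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                features=features,
                mri_present=mri_ok,
                csf_present=csf_ok,
            )
        )
    return records
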