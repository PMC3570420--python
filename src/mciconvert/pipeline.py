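"""End-to-end comparison pipeline.

Simulate (or load) a cohort, run the criteria arm and the DSI arm on
byte-identical inputs, evaluate both, and write a deterministic report
bundle: per-subject predictions, conversion-rate / rule-metric /
category-accuracy tables, the pairwise McNemar matrix, and a manifest
with seeds and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    SubjectRecord,
    default_cohort_spec,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .criteria import (
    DEFAULT_CUTOFFS,
    CriteriaCutoffs,
    Likelihood,
    Prediction,
    RULES,
    assign_likelihood,
    dichotomize,
    predict_rule,
)
from .dsi import fit_dsi_model, split_cohort
from .evaluation import (
    ConfusionSummary,
    category_table,
    confusion,
    conversion_rate,
    final_label_from_group,
    mcnemar,
)
from .reference_tables import verify_reference_tables

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One run: exactly one cohort source, cutoffs, DSI and evaluation
    options, output directory."""

    out_dir: str
    cohort_csv: str | None = None
    spec_path: str | None = None  # None with cohort_csv=None -> packaged default
    seed: int = 1
    split_seed: int = 1
    dsi_cutoff: float = 0.5
    dsi_in_sample: bool = False
    denominators: str = "evaluable"  # evaluable | full
    csf_combination: str = "or"
    cutoffs: CriteriaCutoffs = field(default_factory=CriteriaCutoffs)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.cohort_csv is not None and self.spec_path is not None:
            raise ValueError("give either cohort_csv or spec_path, not both")
        if self.denominators not in ("evaluable", "full"):
            raise ValueError("denominators must be 'evaluable' or 'full'")
        if not 0.0 <= self.dsi_cutoff <= 1.0:
            raise ValueError("dsi_cutoff outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cut = raw.pop("cutoffs", None)
        cfg = cls(**raw)
        if cut:
            cfg.cutoffs = CriteriaCutoffs(**cut)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()


def run_comparison(config: RunConfig) -> dict:
    """Execute the full comparison; returns the manifest dict.

    Rerunning with the same config reproduces every output file
    bit-identically.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # ---- cohort ----------------------------------------------------------
    if config.cohort_csv is not None:
        records = read_cohort(config.cohort_csv)
        cohort_source = {"cohort_csv": str(config.cohort_csv)}
    else:
        spec = (
            CohortSpec.from_yaml(config.spec_path)
            if config.spec_path
            else default_cohort_spec()
        )
        records = generate_cohort(spec, config.seed)
        cohort_source = {"spec": config.spec_path or "<packaged default>",
                         "seed": config.seed}
    cohort_path = out / "cohort.csv"
    write_cohort(records, cohort_path)
    written.append(cohort_path)

    # ---- criteria arm ----------------------------------------------------
    statuses = {r.subject_id: dichotomize(r, config.cutoffs) for r in records}
    likelihoods = {
        sid: assign_likelihood(st, config.csf_combination)
        for sid, st in statuses.items()
    }
    rule_preds = {
        rule: {sid: predict_rule(st, rule) for sid, st in statuses.items()}
        for rule in RULES
    }
    n_indeterminate = sum(
        1 for lv in likelihoods.values() if lv is Likelihood.INDETERMINATE
    )
    if n_indeterminate:
        log.warning("%d subjects have indeterminate likelihood", n_indeterminate)

    # ---- DSI arm ---------------------------------------------------------
    if config.dsi_in_sample:
        train, test = records, records
    else:
        train, test = split_cohort(records, seed=config.split_seed)
    model = fit_dsi_model(train)
    dsi_results = {r.subject_id: model.score(r, cutoff=config.dsi_cutoff) for r in test}
    model.to_json(out / "dsi_model.json")
    written.append(out / "dsi_model.json")
    train_ids = {r.subject_id for r in train}

    # ---- per-subject predictions ----------------------------------------
    rows = []
    for r in records:
        st = statuses[r.subject_id]
        res = dsi_results.get(r.subject_id)
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "ravlt": st.ravlt.value,
            "mta": st.mta.value,
            "tau": st.tau.value,
            "abeta": st.abeta.value,
            "csf_or": st.csf_or.value,
            "csf_and": st.csf_and.value,
            "likelihood": likelihoods[r.subject_id].value,
        }
        for rule in RULES:
            row[rule] = rule_preds[rule][r.subject_id].value
        row["dsi_split"] = "train" if r.subject_id in train_ids else "test"
        row["dsi"] = None if res is None else res.composite
        row["dsi_category"] = None if res is None else res.category
        row["dsi_call"] = None if res is None else res.call
        rows.append(row)
    pred_path = out / "predictions.csv"
    pd.DataFrame(rows).to_csv(pred_path, index=False)
    written.append(pred_path)

    # ---- conversion-rate table ------------------------------------------
    conv_rows = []

    def conv_row(name: str, members: list[SubjectRecord]) -> None:
        n = len(members)
        k = sum(1 for r in members if r.is_converter)
        conv_rows.append({
            "subgroup": name, "cases": n, "converters": k,
            "conversion_rate_pct": conversion_rate(k, n) if n else None,
        })

    conv_row("baseline", records)
    by_id = {r.subject_id: r for r in records}
    for rule in ("r1", "r2", "r3a", "r3b"):
        members = [
            by_id[sid] for sid, p in rule_preds[rule].items()
            if p is Prediction.CONVERTER
        ]
        conv_row(f"{rule}_positive", members)
    for lv in Likelihood:
        members = [by_id[sid] for sid, l in likelihoods.items() if l is lv]
        conv_row(f"likelihood_{lv.value}", members)
    conv_path = out / "table_conversion_rates.csv"
    pd.DataFrame(conv_rows).to_csv(conv_path, index=False)
    written.append(conv_path)

    # ---- rule metrics table ---------------------------------------------
    metric_rows = []
    correctness: dict[str, dict[str, bool]] = {}  # classifier -> sid -> correct

    def eval_classifier(name: str, preds: dict[str, Prediction | str]) -> None:
        sids, ps, ls = [], [], []
        for sid, p in preds.items():
            if config.denominators == "full" and p is Prediction.NOT_EVALUABLE:
                p = Prediction.NONCONVERTER
            if p is Prediction.NOT_EVALUABLE:
                continue
            sids.append(sid)
            ps.append(p)
            ls.append(by_id[sid].group)
        row: dict = {"classifier": name, "n_evaluable": len(sids)}
        if sids and any(by_id[s].is_converter for s in sids) and not all(
            by_id[s].is_converter for s in sids
        ):
            cs = confusion(ps, ls)
            row.update(cs.as_dict())
            correct = {
                sid: (p is Prediction.CONVERTER) == by_id[sid].is_converter
                for sid, p in zip(sids, ps)
            }
            correctness[name] = correct
        metric_rows.append(row)

    for rule in RULES:
        eval_classifier(rule, rule_preds[rule])
    dsi_preds = {
        sid: (Prediction.CONVERTER if res.call == "converter"
              else Prediction.NONCONVERTER)
        for sid, res in dsi_results.items()
    }
    eval_classifier("dsi", dsi_preds)
    metrics_path = out / "table_rule_metrics.csv"
    pd.DataFrame(metric_rows).to_csv(metrics_path, index=False)
    written.append(metrics_path)

    # ---- DSI category table ---------------------------------------------
    scored = sorted(dsi_results)
    cat_tbl = category_table(
        [dsi_results[sid].category for sid in scored],
        [final_label_from_group(by_id[sid].group) for sid in scored],
    )
    cat_rows = []
    for row in cat_tbl.rows + [cat_tbl.pooled_non_ad, cat_tbl.pooled_ad]:
        cat_rows.append({
            "category": row.label, "ad": row.ad, "healthy": row.healthy,
            "mci": row.mci, "total": row.total,
            "accuracy_pct": row.accuracy_pct if row.total else None,
        })
    cat_rows.append({"category": "overall", "ad": None, "healthy": None,
                     "mci": None, "total": cat_tbl.n_total,
                     "accuracy_pct": cat_tbl.overall_accuracy_pct})
    cat_path = out / "table_dsi_categories.csv"
    pd.DataFrame(cat_rows).to_csv(cat_path, index=False)
    written.append(cat_path)

    # ---- pairwise McNemar matrix ----------------------------------------
    names = sorted(correctness)
    mat_rows = []
    for a in names:
        row = {"classifier": a}
        for b in names:
            if a == b:
                row[b] = None
                continue
            shared = sorted(set(correctness[a]) & set(correctness[b]))
            if not shared:
                row[b] = None
                continue
            res = mcnemar([correctness[a][s] for s in shared],
                          [correctness[b][s] for s in shared])
            row[b] = res.p_value
        mat_rows.append(row)
    mcnemar_path = out / "mcnemar_matrix.csv"
    pd.DataFrame(mat_rows).to_csv(mcnemar_path, index=False)
    written.append(mcnemar_path)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "cohort_source": cohort_source,
        "seeds": {"cohort": config.seed, "dsi_split": config.split_seed},
        "n_subjects": len(records),
        "n_indeterminate_likelihood": n_indeterminate,
        "files": {p.name: _sha256(p) for p in written},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def verify_paper_tables() -> list:
    """Recompute the fixture-table targets; see `reference_tables`."""
    return verify_reference_tables()
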