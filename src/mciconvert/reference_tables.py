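"""Published count tables from the reference ADNI MCI 3-year conversion
analysis, shipped as fixtures so the reporting statistics can be verified
offline.

Every verification quantity is *recomputed* from these raw counts through
the evaluation operations; none of the printed percentages is used as an
input.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import (
    CategoryAccuracyTable,
    ConfusionSummary,
    category_table_from_counts,
    conversion_rate,
    percent_of,
)

# Six-category count tables: level -> (AD, Healthy, MCI) final diagnoses.
# Tool-computed index categories:
DSI_CATEGORY_COUNTS: dict[int, tuple[int, int, int]] = {
    1: (2, 9, 43),
    2: (9, 4, 51),
    3: (27, 2, 53),
    4: (58, 0, 46),
    5: (51, 0, 20),
    6: (11, 0, 5),
}
# Clinician categorizations made with the tool's assistance:
CLINICIAN_CATEGORY_COUNTS: dict[int, tuple[int, int, int]] = {
    1: (6, 12, 64),
    2: (15, 3, 46),
    3: (18, 0, 34),
    4: (43, 0, 38),
    5: (31, 0, 19),
    6: (45, 0, 17),
}

# Subgroup conversion counts: subgroup -> (cases, converters).
SUBGROUP_CONVERSION: dict[str, tuple[int, int]] = {
    "baseline": (391, 158),
    "ravlt": (136, 72),
    "mta": (92, 51),
    "csf_or": (150, 76),
    "csf_and": (84, 48),
    "high_likelihood": (20, 13),
    "low_likelihood": (29, 2),
    "intermediate_likelihood": (21, 12),
    "uninformative_likelihood": (58, 37),
}

N_CONVERTERS = 158
N_NONCONVERTERS = 233
SCHELTENS_AVAILABLE = {"non_converter": 230, "converter": 157}
CSF_AVAILABLE = {"non_converter": 115, "converter": 84}

#: printed values of the twelve verification targets
PRINTED_TARGETS: dict[str, int] = {
    "t1": 72,   # overall accuracy, tool-computed six-category table
    "t2": 71,   # overall accuracy, clinician-with-tool table
    "t3": 81,   # pooled non-AD accuracy (levels 1-3) of the tool table
    "t4": 65,   # conversion rate, high-likelihood subgroup
    "t5": 7,    # conversion rate, low-likelihood subgroup
    "t6": 46,   # RAVLT rule sensitivity
    "t7": 62,   # RAVLT rule accuracy
    "t8": 90,   # CSF OR-rule sensitivity
    "t9": 59,   # CSF OR-rule accuracy (CSF-evaluable subset)
    "t10": 82,  # visual-MTA rule specificity (MRI-evaluable subset)
    "t11": 64,  # conversion rate, uninformative-likelihood subgroup
    "t12": 84,  # accuracy of the pooled highest-confidence clinician calls
}


def ravlt_rule_confusion() -> ConfusionSummary:
    """Confusion matrix of the RAVLT core-criterion rule over the full
    cohort, derived from the rule-positive subgroup counts."""
    cases, converters = SUBGROUP_CONVERSION["ravlt"]
    tp = converters
    fp = cases - converters
    fn = N_CONVERTERS - tp
    tn = N_NONCONVERTERS - fp
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def csf_or_rule_confusion() -> ConfusionSummary:
    """Confusion matrix of the CSF OR-rule over the CSF-evaluable subset."""
    cases, converters = SUBGROUP_CONVERSION["csf_or"]
    tp = converters
    fp = cases - converters
    fn = CSF_AVAILABLE["converter"] - tp
    tn = CSF_AVAILABLE["non_converter"] - fp
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def mta_rule_confusion() -> ConfusionSummary:
    """Confusion matrix of the visual-MTA rule over the MRI-evaluable subset."""
    cases, converters = SUBGROUP_CONVERSION["mta"]
    tp = converters
    fp = cases - converters
    fn = SCHELTENS_AVAILABLE["converter"] - tp
    tn = SCHELTENS_AVAILABLE["non_converter"] - fp
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def dsi_category_table() -> CategoryAccuracyTable:
    return category_table_from_counts(DSI_CATEGORY_COUNTS)


def clinician_category_table() -> CategoryAccuracyTable:
    return category_table_from_counts(CLINICIAN_CATEGORY_COUNTS)


def recompute_targets() -> dict[str, dict[str, int]]:
    """Recompute every verification target from raw fixture counts.

    Returns ``{target_id: {"value": ..., "n": ...}}`` with values as
    integer percents.
    """
    tool_tbl = dsi_category_table()
    clin_tbl = clinician_category_table()
    ravlt = ravlt_rule_confusion()
    csf = csf_or_rule_confusion()
    mta = mta_rule_confusion()

    high = SUBGROUP_CONVERSION["high_likelihood"]
    low = SUBGROUP_CONVERSION["low_likelihood"]
    uninf = SUBGROUP_CONVERSION["uninformative_likelihood"]

    clear_rows = [clin_tbl.rows[0], clin_tbl.rows[5]]
    clear_correct = sum(r.n_correct for r in clear_rows)
    clear_total = sum(r.total for r in clear_rows)

    return {
        "t1": {"value": tool_tbl.overall_accuracy_pct, "n": tool_tbl.n_total},
        "t2": {"value": clin_tbl.overall_accuracy_pct, "n": clin_tbl.n_total},
        "t3": {
            "value": tool_tbl.pooled_non_ad.accuracy_pct,
            "n": tool_tbl.pooled_non_ad.total,
        },
        "t4": {"value": conversion_rate(high[1], high[0]), "n": high[0]},
        "t5": {"value": conversion_rate(low[1], low[0]), "n": low[0]},
        "t6": {"value": ravlt.sensitivity_pct, "n": ravlt.tp + ravlt.fn},
        "t7": {"value": ravlt.accuracy_pct, "n": ravlt.n_evaluable},
        "t8": {"value": csf.sensitivity_pct, "n": csf.tp + csf.fn},
        "t9": {"value": csf.accuracy_pct, "n": csf.n_evaluable},
        "t10": {"value": mta.specificity_pct, "n": mta.tn + mta.fp},
        "t11": {"value": conversion_rate(uninf[1], uninf[0]), "n": uninf[0]},
        "t12": {"value": percent_of(clear_correct, clear_total), "n": clear_total},
    }


@dataclass(frozen=True)
class TargetCheck:
    target: str
    expected: int
    computed: int

    @property
    def passed(self) -> bool:
        return self.expected == self.computed


def verify_reference_tables() -> list[TargetCheck]:
    """Recompute all targets and compare with the printed values."""
    computed = recompute_targets()
    return [
        TargetCheck(target=t, expected=PRINTED_TARGETS[t],
                    computed=computed[t]["value"])
        for t in PRINTED_TARGETS
    ]
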