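"""Cohort-level validation statistics.

Two checks relate predicted responder calls to clinical observations:

* :func:`correlate_with_trials` - Pearson correlation between the response
  rate reported by a clinical trial for (cancer type, drug) and the fraction
  of expression-profiled patients of that cancer type whose drug score
  exceeds the responder cutoff, both on the percent scale.
* :func:`compare_cohorts` - Fisher's exact test comparing the predicted
  responder proportions of two patient cohorts for the same drug and rule
  (e.g. BRAF-mutant vs. wild-type melanomas under a positive-DS rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from pascore.drug_scoring import ResponderCall
from pascore.errors import ParseError, ValidationError

__all__ = [
    "TrialRecord",
    "ValidationResult",
    "CohortComparison",
    "read_trials",
    "correlate_with_trials",
    "fisher_exact_2x2",
    "compare_cohorts",
]


@dataclass(frozen=True)
class TrialRecord:
    """One clinical-trial row: observed responder percentage for (cohort, drug)."""

    cohort_id: str
    drug: str
    response_rate: float  # percent of responders, 0..100
    n_patients: int
    study_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.response_rate <= 100.0):
            raise ValidationError(
                f"response_rate must be in [0, 100], got {self.response_rate}"
            )
        if self.n_patients <= 0:
            raise ValidationError(f"n_patients must be positive, got {self.n_patients}")


@dataclass
class ValidationResult:
    """Paired (trial rate, predicted rate) points with their Pearson statistics."""

    pairs: list[tuple[str, str, float, float]]  # cohort, drug, trial %, predicted %
    pearson_r: float
    pvalue: float


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trials TSV: ``cohort_id drug pct_responders study_id n_patients``.

    A header row is detected by a non-numeric third field.
    """
    path = Path(path)
    records: list[TrialRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            try:
                rate = float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}:{lineno}: non-numeric response rate {parts[2]!r}")
            try:
                n = int(parts[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric patient count {parts[4]!r}")
            records.append(
                TrialRecord(
                    cohort_id=parts[0], drug=parts[1], response_rate=rate,
                    study_id=parts[3], n_patients=n,
                )
            )
    if not records:
        raise ParseError(f"{path}: no trial records")
    return records


def correlate_with_trials(
    records: Sequence[TrialRecord],
    fractions: Mapping[tuple[str, str], float],
) -> ValidationResult:
    """Correlate trial response rates with predicted responder fractions.

    ``fractions`` maps (cohort_id, drug) to the predicted responder fraction
    on the 0..1 scale; it is converted to percent so both axes match.  The
    p-value is the two-sided test of zero correlation via the t distribution
    with n - 2 degrees of freedom.
    """
    missing = [
        (r.cohort_id, r.drug) for r in records if (r.cohort_id, r.drug) not in fractions
    ]
    if missing:
        raise ValidationError(f"no predicted fraction for trial keys: {missing}")
    if len(records) < 3:
        raise ValidationError(f"need >=3 (trial, prediction) pairs, got {len(records)}")
    pairs = [
        (r.cohort_id, r.drug, r.response_rate, 100.0 * fractions[(r.cohort_id, r.drug)])
        for r in records
    ]
    x = np.array([p[2] for p in pairs], dtype=float)
    y = np.array([p[3] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Pearson r undefined: one coordinate is constant")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(pairs)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return ValidationResult(pairs=pairs, pearson_r=r, pvalue=p)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of tables with
    probability at most that of the observed one, at fixed margins)."""
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValidationError("Fisher test needs a non-negative 2x2 table")
    if arr.sum(axis=1).min() == 0 or arr.sum(axis=0).min() == 0:
        # a degenerate margin carries no information; conventionally p = 1
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


@dataclass
class CohortComparison:
    """2x2 responder table for two cohorts and its Fisher exact p-value."""

    drug: str
    rule: str
    table: np.ndarray  # rows: cohorts a, b; cols: responders, non-responders
    pvalue: float
    fraction_a: float
    fraction_b: float


def compare_cohorts(calls_a: ResponderCall, calls_b: ResponderCall) -> CohortComparison:
    """Fisher's exact comparison of responder proportions in two cohorts.

    Both calls must concern the same drug under the same rule (and cutoff).
    """
    if calls_a.drug != calls_b.drug:
        raise ValidationError(
            f"cohorts scored for different drugs: {calls_a.drug!r} vs {calls_b.drug!r}"
        )
    if calls_a.rule != calls_b.rule or calls_a.cutoff_value != calls_b.cutoff_value:
        raise ValidationError("cohorts scored under different responder rules")
    na, nb = calls_a.flags.size, calls_b.flags.size
    if na == 0 or nb == 0:
        raise ValidationError("empty cohort")
    table = np.array(
        [
            [calls_a.n_responders, na - calls_a.n_responders],
            [calls_b.n_responders, nb - calls_b.n_responders],
        ],
        dtype=np.int64,
    )
    return CohortComparison(
        drug=calls_a.drug,
        rule=calls_a.rule,
        table=table,
        pvalue=fisher_exact_2x2(table),
        fraction_a=calls_a.fraction,
        fraction_b=calls_b.fraction,
    )
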