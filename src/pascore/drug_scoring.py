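"""Drug scores (DS) from pathway activation profiles.

A drug's score in a sample sums pathway activation over every
(target, pathway) incidence of the drug's targets:

    DS[d, s] = sum over targets t of d, sum over pathways p containing t,
               of AMCF(p) * PAS[p, s]

AMCF (+1/-1) converts pathway activation into a mitosis-promotion sign, so a
high DS marks a drug whose targets sit in tumour-promoting pathways that the
sample has activated - blocking them is predicted to help.  One pathway is
counted once per target it contains, so a drug with k targets in the same
pathway accrues that pathway's contribution k times.

Missing PAS cells (pathways with no measured members) contribute 0; the
per-drug ``coverage`` counts the (target, pathway) pairs actually backed by a
measured pathway, so the loss is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pascore.errors import ValidationError
from pascore.pas_engine import PASProfile
from pascore.pathway_model import DrugTargetMap, PathwayDB

__all__ = [
    "DrugScoreProfile",
    "ResponderCall",
    "compute_ds",
    "rank_drugs",
    "call_responders",
    "write_ds",
    "read_ds",
]

RESPONDER_RULES = ("cutoff", "nonzero", "positive")


@dataclass
class DrugScoreProfile:
    """Drug x case-sample score matrix.

    ``coverage`` maps each drug to the number of (target, pathway) pairs that
    contributed; a drug whose targets touch no measured pathway scores 0
    everywhere with coverage 0.
    """

    drugs: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    coverage: dict[str, int]
    mode: str

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.drugs), len(self.sample_ids)):
            raise ValidationError("DS matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("DS contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.drugs, columns=self.sample_ids)

    def row(self, drug: str) -> np.ndarray:
        try:
            i = self.drugs.index(drug)
        except ValueError:
            raise KeyError(f"drug {drug!r} not in profile") from None
        return self.scores[i]


@dataclass
class ResponderCall:
    """Boolean responder flags for one drug across case samples."""

    drug: str
    sample_ids: list[str]
    flags: np.ndarray
    rule: str
    cutoff_value: float | None = None

    @property
    def fraction(self) -> float:
        return float(self.flags.mean())

    @property
    def n_responders(self) -> int:
        return int(self.flags.sum())


def compute_ds(
    pas: PASProfile, db: PathwayDB, dtm: DrugTargetMap
) -> DrugScoreProfile:
    """Fold a PAS profile over every drug's targets.

    Requires ``pas`` to have been computed against the same pathway database
    (all pathway ids must match).
    """
    missing = [p for p in pas.pathway_ids if p not in db]
    if missing:
        raise ValidationError(f"PAS profile has pathways unknown to the DB: {missing[:5]}")
    pw_pos = {p: i for i, p in enumerate(pas.pathway_ids)}
    values = np.nan_to_num(pas.values, nan=0.0)
    pathway_missing = np.isnan(pas.values).all(axis=1)

    drugs = dtm.drugs
    scores = np.zeros((len(drugs), len(pas.sample_ids)))
    coverage: dict[str, int] = {}
    for di, drug in enumerate(drugs):
        n_pairs = 0
        for target in sorted(dtm[drug]):
            for pid in db.pathways_for_gene(target):
                i = pw_pos.get(pid)
                if i is None:
                    continue
                if pathway_missing[i]:
                    continue  # contributes 0, not counted as covered
                scores[di] += db[pid].amcf * values[i]
                n_pairs += 1
        coverage[drug] = n_pairs
    return DrugScoreProfile(
        drugs=list(drugs),
        sample_ids=list(pas.sample_ids),
        scores=scores,
        coverage=coverage,
        mode=pas.mode,
    )


def rank_drugs(dsp: DrugScoreProfile, aggregate: str = "mean") -> pd.DataFrame:
    """Rank drugs by mean or median DS across samples, descending.

    Ties on the aggregate break alphabetically by drug name so the order is
    deterministic.
    """
    if aggregate == "mean":
        agg = dsp.scores.mean(axis=1)
    elif aggregate == "median":
        agg = np.median(dsp.scores, axis=1)
    else:
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    df = pd.DataFrame(
        {
            "drug": dsp.drugs,
            f"{aggregate}_ds": agg,
            # coverage is unknown (-1) for profiles re-read from disk
            "coverage": [c if (c := dsp.coverage[d]) >= 0 else "NA" for d in dsp.drugs],
        }
    )
    df = df.sort_values(
        by=[f"{aggregate}_ds", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def call_responders(
    dsp: DrugScoreProfile,
    drug: str,
    rule: str = "cutoff",
    cutoff: float = 250.0,
) -> ResponderCall:
    """Flag predicted responders for one drug.

    ``rule='cutoff'`` flags DS > cutoff (default 250); ``rule='nonzero'``
    (alias ``'positive'``) flags DS > 0 - a negative score means the drug
    would reinforce tumour-promoting signalling, so only strictly positive
    scores count as predicted benefit.
    """
    if rule not in RESPONDER_RULES:
        raise ValueError(f"rule must be one of {RESPONDER_RULES}, got {rule!r}")
    row = dsp.row(drug)
    if row.size == 0:
        raise ValidationError("no samples to call")
    if rule == "cutoff":
        flags = row > cutoff
        return ResponderCall(drug, list(dsp.sample_ids), flags, rule, float(cutoff))
    flags = row > 0
    return ResponderCall(drug, list(dsp.sample_ids), flags, rule, None)


def write_ds(dsp: DrugScoreProfile, path: str | Path) -> None:
    df = dsp.to_frame()
    df.index.name = "drug"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_ds(path: str | Path, mode: str = "standard") -> DrugScoreProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    drugs = [str(d) for d in df.index]
    return DrugScoreProfile(
        drugs=drugs,
        sample_ids=[str(c) for c in df.columns],
        scores=df.to_numpy(float),
        coverage={d: -1 for d in drugs},  # unknown after round-trip
        mode=mode,
    )
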