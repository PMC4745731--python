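"""Shared fixtures: tiny hand-built cohorts and a demo pathway/drug database."""

from __future__ import annotations

import numpy as np
import pytest

from pascore.expression import ExpressionCohort, compute_btif, compute_cnr
from pascore.pathway_model import DrugTargetMap, PathwayDB, PathwayDefinition


@pytest.fixture
def demo_db() -> PathwayDB:
    """Three pathways: mixed roles, pure repressor, mitosis-inhibiting."""
    return PathwayDB(
        [
            PathwayDefinition("growth", {"EGFR": 1, "KRAS": 1, "PTEN": -1}, amcf=1),
            PathwayDefinition("brake", {"TP53": -1, "RB1": -1}, amcf=-1),
            PathwayDefinition("angio", {"VEGFA": 1, "KDR": 1}, amcf=1),
        ]
    )


@pytest.fixture
def demo_dtm() -> DrugTargetMap:
    return DrugTargetMap(
        {
            "erlotinib": frozenset({"EGFR"}),
            "sunitinib": frozenset({"KDR", "VEGFA"}),
            "inert": frozenset({"ACTB"}),  # in no pathway
        }
    )


@pytest.fixture
def demo_cohort(demo_db) -> ExpressionCohort:
    """Deterministic 8-gene cohort; controls tightly clustered near 100.

    Case sample s1 strongly over-expresses EGFR/KRAS/VEGFA/KDR and
    under-expresses PTEN/TP53/RB1; s2 sits at the control mean everywhere.
    """
    genes = ["EGFR", "KRAS", "PTEN", "TP53", "RB1", "VEGFA", "KDR", "ACTB"]
    rng = np.random.default_rng(42)
    control = 100.0 * 2.0 ** rng.normal(0.0, 0.05, size=(len(genes), 5))
    ctrl_mean = control.mean(axis=1)
    fold_s1 = np.array([10.0, 4.0, 0.1, 0.25, 0.2, 8.0, 5.0, 1.0])
    case = np.column_stack([ctrl_mean * fold_s1, ctrl_mean])
    return ExpressionCohort(
        genes=genes,
        case_matrix=case,
        control_matrix=control,
        case_ids=["s1", "s2"],
        control_ids=[f"n{i}" for i in range(1, 6)],
    )


@pytest.fixture
def demo_stats(demo_cohort):
    stats = compute_cnr(demo_cohort)
    return compute_btif(stats, demo_cohort)


def make_random_instance(rng, n_genes=30, n_pathways=5, n_samples=4):
    """Random stats + db + dtm for oracle-equivalence checks.

    Returns (stats, db, dtm).  Gene symbols include some absent from the
    pathway DB and pathways include genes absent from the universe.
    """
    from pascore.expression import GeneSampleStats

    genes = [f"g{i}" for i in range(n_genes)]
    cnr = rng.lognormal(0.0, 1.0, size=(n_genes, n_samples))
    defined = rng.random((n_genes, n_samples)) > 0.1
    cnr = np.where(defined, cnr, np.nan)
    btif = ((rng.random((n_genes, n_samples)) > 0.4) & defined).astype(np.int8)
    stats = GeneSampleStats(
        genes=[g.upper() for g in genes],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        cnr=cnr,
        defined_mask=defined.astype(np.int8),
        pvalue=np.where(btif == 1, 0.01, 0.5),
        btif=btif,
    )
    defs = []
    for p in range(n_pathways):
        size = int(rng.integers(1, 8))
        picks = rng.choice(n_genes + 5, size=size, replace=False)  # some off-universe
        members = {
            (f"G{i}" if i < n_genes else f"MISSING{i}"): int(rng.choice([-1, 1]))
            for i in picks
        }
        defs.append(
            PathwayDefinition(f"p{p}", members, amcf=int(rng.choice([-1, 1])))
        )
    db = PathwayDB(defs)
    all_members = sorted({g for pw in db for g in pw.members})
    n_drugs = int(rng.integers(1, 6))
    targets = {}
    for d in range(n_drugs):
        k = int(rng.integers(1, min(4, len(all_members) + 1)))
        targets[f"d{d}"] = frozenset(
            str(x) for x in rng.choice(all_members, size=k, replace=False)
        )
    return stats, db, DrugTargetMap(targets)
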