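"""Synthetic case/control cohorts with known pathway-level ground truth.

The generator emulates the statistical structure pathway scoring assumes:
lognormal gene expression around a per-gene baseline, with coherent
fold-changes along designated activated pathways.  Each gene g draws one
baseline b_g ~ Normal(baseline_log2_mean, baseline_log2_sd) on the log2
scale; a control sample observes 2**(b_g + eps), eps ~ Normal(0, noise_sigma).
A case sample observes the same law shifted by the pathway effect: in an
activated pathway with fold f, activator genes gain log2(f) and repressor
genes lose log2(f) (i.e. x f and x 1/f on the linear scale), so the pathway's
signed activation score has the closed form

    PAS = (#activators + #repressors) * log10(f)     (at zero noise)

because repressors move down by 1/f and carry role -1.  Genes in no
activated pathway are unchanged between cases and controls.

All randomness flows from the single integer seed in the spec; runs are
bit-reproducible.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from pascore.errors import ValidationError
from pascore.expression import ExpressionCohort
from pascore.pathway_model import DrugTargetMap, PathwayDB, PathwayDefinition

__all__ = ["SimulationSpec", "SimulatedCohort", "simulate", "make_drug_panel"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated cohort.

    ``activated_pathways`` maps pathway ids (``pw01``, ``pw02``, ...) to the
    linear fold effect applied to their activator genes (repressors get the
    inverse fold).  ``activator_fraction`` sets the fraction of each
    pathway's members that are activators (the rest are repressors);
    ``amcf`` is the mitosis flag given to every generated pathway.
    """

    n_genes: int = 200
    n_pathways: int = 8
    genes_per_pathway: int = 10
    n_cases: int = 20
    n_controls: int = 20
    activated_pathways: Mapping[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    activator_fraction: float = 1.0
    amcf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_pathways": self.n_pathways,
            "genes_per_pathway": self.genes_per_pathway,
            "n_cases": self.n_cases,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValidationError(f"{name} must be >= 1, got {value}")
        if self.n_controls < 2:
            raise ValidationError(f"n_controls must be >= 2, got {self.n_controls}")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValidationError(
                "n_genes too small: pathways partition the gene universe and need "
                f"{self.n_pathways * self.genes_per_pathway} genes, have {self.n_genes}"
            )
        for pid, fold in self.activated_pathways.items():
            if fold <= 0:
                raise ValidationError(f"fold effect for {pid!r} must be > 0, got {fold}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not (0.0 <= self.activator_fraction <= 1.0):
            raise ValidationError("activator_fraction must be in [0, 1]")
        if self.amcf not in (-1, 1):
            raise ValidationError(f"amcf must be -1 or +1, got {self.amcf}")
        object.__setattr__(
            self, "activated_pathways", dict(self.activated_pathways)
        )

    def pathway_id(self, index: int) -> str:
        return f"pw{index + 1:02d}"


@dataclass
class SimulatedCohort:
    """A simulated cohort plus the ground truth that generated it."""

    cohort: ExpressionCohort
    db: PathwayDB
    spec: SimulationSpec

    @property
    def truth(self) -> dict[str, float]:
        """Activated pathway ids -> fold effects, as simulated."""
        return dict(self.spec.activated_pathways)

    @property
    def quiescent_pathways(self) -> list[str]:
        return [p for p in self.db.pathway_ids if p not in self.spec.activated_pathways]


def simulate(spec: SimulationSpec) -> SimulatedCohort:
    """Draw one cohort under ``spec``; deterministic given ``spec.seed``.

    Pathways partition the front of the gene universe: pathway i owns genes
    ``G{i*k+1} .. G{(i+1)*k}`` with k = genes_per_pathway; the first
    ``ceil(k * activator_fraction)`` members of each pathway are activators,
    the rest repressors.  Leftover genes belong to no pathway and act as a
    null background.
    """
    unknown = set(spec.activated_pathways) - {
        spec.pathway_id(i) for i in range(spec.n_pathways)
    }
    if unknown:
        raise ValidationError(f"activated_pathways refer to unknown ids: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]

    k = spec.genes_per_pathway
    n_act = int(np.ceil(k * spec.activator_fraction))
    defs = []
    for i in range(spec.n_pathways):
        members = OrderedDict(
            (genes[i * k + j], 1 if j < n_act else -1) for j in range(k)
        )
        defs.append(PathwayDefinition(spec.pathway_id(i), members, spec.amcf))
    db = PathwayDB(defs)

    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)

    # per-gene log2 shift applied to the case generative mean
    shift = np.zeros(spec.n_genes)
    for pid, fold in spec.activated_pathways.items():
        pw = db[pid]
        for gene, arr in pw.members.items():
            g = int(gene[1:]) - 1
            shift[g] = arr * np.log2(fold)

    ctrl_noise = rng.normal(0.0, spec.noise_sigma, (spec.n_genes, spec.n_controls))
    case_noise = rng.normal(0.0, spec.noise_sigma, (spec.n_genes, spec.n_cases))
    control = 2.0 ** (baseline[:, None] + ctrl_noise)
    case = 2.0 ** (baseline[:, None] + shift[:, None] + case_noise)

    cohort = ExpressionCohort(
        genes=genes,
        case_matrix=case,
        control_matrix=control,
        case_ids=[f"case{i + 1:03d}" for i in range(spec.n_cases)],
        control_ids=[f"ctrl{i + 1:03d}" for i in range(spec.n_controls)],
    )
    return SimulatedCohort(cohort=cohort, db=db, spec=spec)


def make_drug_panel(
    sim: SimulatedCohort,
    n_on_target: int,
    n_off_target: int,
    targets_per_drug: int = 1,
) -> DrugTargetMap:
    """Build drugs whose targets lie wholly in activated ("ON_*") or wholly
    in quiescent ("OFF_*") pathways, so truth is recoverable from the name.

    Targets are taken round-robin over the relevant pathways' member genes,
    deterministically, so the same cohort always yields the same panel.
    """
    if n_on_target < 0 or n_off_target < 0 or targets_per_drug < 1:
        raise ValidationError("panel sizes must be non-negative, targets_per_drug >= 1")
    if n_on_target + n_off_target == 0:
        raise ValidationError("empty drug panel requested")
    activated = [p for p in sim.db.pathway_ids if p in sim.truth]
    quiescent = sim.quiescent_pathways
    if n_on_target > 0 and not activated:
        raise ValidationError("no activated pathways to draw on-target drugs from")
    if n_off_target > 0 and not quiescent:
        raise ValidationError("no quiescent pathways to draw off-target drugs from")

    def pick(pathway_ids: list[str], n_drugs: int, prefix: str) -> dict[str, frozenset[str]]:
        pool = [g for pid in pathway_ids for g in sim.db[pid].members]
        out: dict[str, frozenset[str]] = {}
        cursor = 0
        for d in range(n_drugs):
            chosen = [pool[(cursor + j) % len(pool)] for j in range(targets_per_drug)]
            cursor += targets_per_drug
            out[f"{prefix}_{d + 1:02d}"] = frozenset(chosen)
        return out

    targets: dict[str, frozenset[str]] = {}
    targets.update(pick(activated, n_on_target, "ON"))
    targets.update(pick(quiescent, n_off_target, "OFF"))
    return DrugTargetMap(targets)
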