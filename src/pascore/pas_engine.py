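"""Pathway activation strength (PAS).

For one case sample s and pathway p,

    PAS[p, s] = sum over member genes n of  ARR(n, p) * BTIF(n, s) * log10(CNR(n, s))

where ARR is the +1/-1 activator/repressor role and BTIF the significance
gate computed in :mod:`pascore.expression`.  Positive PAS means the pathway
is activated in the sample relative to normal tissue, negative means
inhibited.  The killer-Mab variant drops the role weighting (ARR := 1): an
antibody-drug conjugate benefits from any overexpressed target, whatever the
target's signalling role, so only the magnitude of overexpression matters.

A pathway with no member present in the measured gene universe has no
evidence either way; its PAS is reported as missing (NaN), distinct from an
exact 0 produced when members are measured but none passes the BTIF gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pascore.errors import ValidationError
from pascore.expression import GeneSampleStats
from pascore.pathway_model import PathwayDB

__all__ = ["PASProfile", "compute_pas", "pas_sign_summary", "write_pas", "read_pas"]

MODES = ("standard", "killermab")


@dataclass
class PASProfile:
    """Pathway x case-sample activation matrix with per-cell provenance.

    ``values`` holds PAS (NaN marks a pathway with zero measured members);
    ``n_contributing`` counts BTIF-passing genes behind each cell and
    ``measured_fraction`` the fraction of each pathway's members present in
    the gene universe.
    """

    pathway_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mode: str
    n_contributing: np.ndarray
    measured_fraction: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        shape = (len(self.pathway_ids), len(self.sample_ids))
        if self.values.shape != shape or self.n_contributing.shape != shape:
            raise ValidationError("PAS matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pathway_ids, columns=self.sample_ids)


def compute_pas(
    stats: GeneSampleStats, db: PathwayDB, mode: str = "standard"
) -> PASProfile:
    """Score every pathway in every case sample.

    ``mode='standard'`` applies the activator/repressor role weights;
    ``mode='killermab'`` replaces every role with +1.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    btif = stats.require_btif()
    n_samples = len(stats.sample_ids)

    # gated log-ratio contribution of every measured gene; BTIF=1 implies the
    # CNR is defined and positive, so the log is finite there.
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(btif == 1, np.log10(np.where(btif == 1, stats.cnr, 1.0)), 0.0)

    n_pw = len(db)
    values = np.zeros((n_pw, n_samples))
    n_contributing = np.zeros((n_pw, n_samples), dtype=np.int64)
    measured_fraction = np.zeros(n_pw)

    for i, pw in enumerate(db):
        rows = []
        arrs = []
        for gene, arr in pw.members.items():
            pos = stats.gene_pos.get(gene)
            if pos is not None:
                rows.append(pos)
                arrs.append(1 if mode == "killermab" else arr)
        measured_fraction[i] = len(rows) / len(pw.members)
        if not rows:
            values[i, :] = np.nan
            continue
        sub = contrib[rows, :]
        w = np.asarray(arrs, dtype=float)[:, None]
        values[i, :] = (w * sub).sum(axis=0)
        n_contributing[i, :] = btif[rows, :].sum(axis=0)

    # cells with measured members but no passing gene are exactly 0
    zero_cells = (n_contributing == 0) & ~np.isnan(values)
    values[zero_cells] = 0.0

    return PASProfile(
        pathway_ids=db.pathway_ids,
        sample_ids=list(stats.sample_ids),
        values=values,
        mode=mode,
        n_contributing=n_contributing,
        measured_fraction=measured_fraction,
    )


def pas_sign_summary(profile: PASProfile) -> pd.DataFrame:
    """Per-pathway counts of activated (>0), inhibited (<0) and neutral (=0) samples.

    Missing cells are excluded; the three counts partition the non-missing
    cells of each pathway row.
    """
    v = profile.values
    with np.errstate(invalid="ignore"):
        activated = np.nansum(v > 0, axis=1)
        inhibited = np.nansum(v < 0, axis=1)
        neutral = np.nansum(v == 0, axis=1)
    return pd.DataFrame(
        {
            "activated": activated.astype(int),
            "inhibited": inhibited.astype(int),
            "neutral": neutral.astype(int),
        },
        index=profile.pathway_ids,
    )


def write_pas(profile: PASProfile, path: str | Path, qc_path: str | Path | None = None) -> None:
    """Write PAS as TSV (missing cells as ``NA``) plus an optional QC table."""
    df = profile.to_frame()
    df.index.name = "pathway_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    if qc_path is not None:
        qc = pd.DataFrame(
            profile.n_contributing, index=profile.pathway_ids, columns=profile.sample_ids
        )
        qc.insert(0, "measured_fraction", profile.measured_fraction)
        qc.index.name = "pathway_id"
        qc.to_csv(qc_path, sep="\t", float_format="%.10g")


def read_pas(path: str | Path, mode: str = "standard") -> PASProfile:
    """Read a PAS TSV written by :func:`write_pas` (QC fields are rebuilt as unknown)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values = df.to_numpy(float)
    return PASProfile(
        pathway_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
        mode=mode,
        n_contributing=np.zeros_like(values, dtype=np.int64),
        measured_fraction=np.where(np.isnan(values).all(axis=1), 0.0, np.nan),
    )
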