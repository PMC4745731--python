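"""Expression matrices, case-to-normal ratios (CNR) and the BTIF gate.

The cohort model is a pair of linear-scale, gene-level expression matrices
over one shared gene list: cases (tumour samples) and controls (normal
tissue).  For every gene and case sample the case-to-normal ratio is

    CNR[g, s] = case[g, s] / mean(control[g, :])

and the beyond-tolerance-interval flag (BTIF) marks the gene as usable for
pathway scoring when the case value is both statistically distinguishable
from the control distribution and outside a fold-change tolerance interval
(default 0.66 - 1.5).

The significance test is a two-sided prediction-interval t-test on log2
values: with m controls of log2 mean ``m_bar`` and sd ``s``, a single case
observation x has

    t = (x - m_bar) / (s * sqrt(1 + 1/m)),  df = m - 1.

Under lognormal multiplicative noise this is the exact level-alpha test of
whether one new observation comes from the control law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from pascore.errors import ParseError, ValidationError

__all__ = [
    "ExpressionCohort",
    "GeneSampleStats",
    "read_expression",
    "split_by_phenotype",
    "load_cohort",
    "compute_cnr",
    "compute_btif",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionCohort:
    """Case and control expression matrices over a shared gene universe.

    Matrices are linear-scale, non-negative, genes x samples, with identical
    gene order.  At least two control samples are required so that control
    variance is estimable.
    """

    genes: list[str]
    case_matrix: np.ndarray
    control_matrix: np.ndarray
    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        self.genes = [g.strip().upper() for g in self.genes]
        self.case_matrix = np.asarray(self.case_matrix, dtype=float)
        self.control_matrix = np.asarray(self.control_matrix, dtype=float)
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ValidationError("duplicate gene symbols in cohort")
        if self.case_matrix.shape != (n, len(self.case_ids)):
            raise ValidationError(
                f"case matrix shape {self.case_matrix.shape} does not match "
                f"{n} genes x {len(self.case_ids)} samples"
            )
        if self.control_matrix.shape != (n, len(self.control_ids)):
            raise ValidationError(
                f"control matrix shape {self.control_matrix.shape} does not match "
                f"{n} genes x {len(self.control_ids)} samples"
            )
        if len(self.control_ids) < 2:
            raise ValidationError("need >=2 control samples to estimate variance")
        if len(self.case_ids) < 1:
            raise ValidationError("need >=1 case sample")
        for name, mat in (("case", self.case_matrix), ("control", self.control_matrix)):
            if not np.all(np.isfinite(mat)):
                raise ValidationError(f"{name} matrix contains non-finite values")
            if np.any(mat < 0):
                raise ValidationError(f"{name} matrix contains negative values")
        ids = self.case_ids + self.control_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids across case/control")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


@dataclass
class GeneSampleStats:
    """Per-gene, per-case-sample CNR, significance and BTIF.

    ``defined_mask`` is 1 where the CNR is computable (positive case value and
    positive control mean); genes with mask 0 never contribute to pathway
    scores.  ``pvalue`` and ``btif`` are filled by :func:`compute_btif`.
    """

    genes: list[str]
    sample_ids: list[str]
    cnr: np.ndarray
    defined_mask: np.ndarray
    pvalue: np.ndarray | None = None
    btif: np.ndarray | None = None
    gene_pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_pos = {g: i for i, g in enumerate(self.genes)}

    def require_btif(self) -> np.ndarray:
        if self.btif is None:
            raise ValidationError("BTIF not computed; call compute_btif first")
        return self.btif


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, format: str = "tsv", log2_input: bool = False
) -> pd.DataFrame:
    """Read a genes x samples expression matrix as a DataFrame.

    TSV dialect: first column gene symbol, header row of sample ids.  GCT 1.2
    is supported read-only.  Gene symbols are upper-cased; duplicate symbols
    are collapsed by their mean with a logged warning.  ``log2_input=True``
    un-logs the body (2**x) so the result is linear scale.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        df = _read_gct(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dup}")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        g, s = np.argwhere(body.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    body.index = [str(g).strip().upper() for g in body.index]
    if body.index.duplicated().any():
        dup = sorted(set(body.index[body.index.duplicated()]))
        log.warning("%s: %d duplicate gene symbols collapsed by mean: %s",
                    path, len(dup), ", ".join(dup[:10]))
        body = body.groupby(level=0, sort=False).mean()
    if log2_input:
        body = 2.0 ** body
    return body


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}: expected GCT header '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ParseError(f"{path}: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description", "DESCRIPTION"], errors="ignore")
    if df.shape != (n_genes, n_samples):
        raise ParseError(
            f"{path}: GCT header declares {n_genes}x{n_samples} "
            f"but body is {df.shape[0]}x{df.shape[1]}"
        )
    return df


def split_by_phenotype(
    matrix: pd.DataFrame, phenotype_path: str | Path
) -> ExpressionCohort:
    """Split one matrix into a cohort using a ``sample<TAB>{case|control}`` TSV."""
    path = Path(phenotype_path)
    labels: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected sample<TAB>label")
            sample, label = parts[0].strip(), parts[1].strip().lower()
            if lineno == 1 and label not in {"case", "control"}:
                continue  # header row
            if label not in {"case", "control"}:
                raise ParseError(
                    f"{path}:{lineno}: label must be 'case' or 'control', got {label!r}"
                )
            labels[sample] = label
    missing = [s for s in matrix.columns if s not in labels]
    if missing:
        raise ValidationError(f"phenotype file lacks labels for samples: {missing}")
    case_ids = [s for s in matrix.columns if labels[s] == "case"]
    control_ids = [s for s in matrix.columns if labels[s] == "control"]
    return ExpressionCohort(
        genes=list(matrix.index),
        case_matrix=matrix[case_ids].to_numpy(float),
        control_matrix=matrix[control_ids].to_numpy(float),
        case_ids=case_ids,
        control_ids=control_ids,
    )


def load_cohort(
    case_path: str | Path,
    control_path: str | Path | None = None,
    phenotype_path: str | Path | None = None,
    format: str = "tsv",
    log2_input: bool = False,
) -> ExpressionCohort:
    """Load a cohort from two matrices, or one matrix plus a phenotype TSV."""
    matrix = read_expression(case_path, format=format, log2_input=log2_input)
    if phenotype_path is not None:
        return split_by_phenotype(matrix, phenotype_path)
    if control_path is None:
        raise ValueError("need either control_path or phenotype_path")
    controls = read_expression(control_path, format=format, log2_input=log2_input)
    shared = [g for g in matrix.index if g in set(controls.index)]
    if not shared:
        raise ValidationError("case and control matrices share no genes")
    dropped = (len(matrix) - len(shared)) + (len(controls) - len(shared))
    if dropped:
        log.warning("dropping %d genes absent from one of the two matrices", dropped)
    return ExpressionCohort(
        genes=shared,
        case_matrix=matrix.loc[shared].to_numpy(float),
        control_matrix=controls.loc[shared].to_numpy(float),
        case_ids=list(matrix.columns),
        control_ids=list(controls.columns),
    )


# ---------------------------------------------------------------------------
# CNR and BTIF
# ---------------------------------------------------------------------------

def compute_cnr(cohort: ExpressionCohort) -> GeneSampleStats:
    """Case-to-normal ratios against the arithmetic mean of linear controls.

    CNR is undefined (``defined_mask = 0``) where the case value or the
    control mean is not strictly positive; such cells never enter pathway
    scores.
    """
    control_mean = cohort.control_matrix.mean(axis=1)
    case = cohort.case_matrix
    defined = (case > 0) & (control_mean[:, None] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cnr = np.where(defined, case / control_mean[:, None], np.nan)
    return GeneSampleStats(
        genes=list(cohort.genes),
        sample_ids=list(cohort.case_ids),
        cnr=cnr,
        defined_mask=defined.astype(np.int8),
    )


def compute_btif(
    stats: GeneSampleStats,
    cohort: ExpressionCohort,
    alpha: float = 0.05,
    fc_low: float = 0.66,
    fc_high: float = 1.5,
) -> GeneSampleStats:
    """Fill p-values and the beyond-tolerance-interval flag in place.

    BTIF[g, s] = 1 iff the CNR is defined, the prediction-interval t-test on
    log2 values gives p < alpha, and CNR < fc_low or CNR > fc_high.

    Genes with zero control variance use the convention p = 1 when the case
    log2 value equals the control log2 mean and p = 0 otherwise.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if not (0 < fc_low < fc_high):
        raise ValidationError(f"need 0 < fc_low < fc_high, got {fc_low}, {fc_high}")

    m = cohort.n_controls
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ctrl = np.where(cohort.control_matrix > 0,
                            np.log2(np.maximum(cohort.control_matrix, 1e-300)), np.nan)
        log_case = np.where(cohort.case_matrix > 0,
                            np.log2(np.maximum(cohort.case_matrix, 1e-300)), np.nan)
    ctrl_mean = np.nanmean(log_ctrl, axis=1)
    # genes with any non-positive control value: keep t-stats on the positive
    # subset is not meaningful; such genes typically have defined_mask 0 via
    # the control mean.  ddof=1 sample sd.
    with np.errstate(invalid="ignore"):
        ctrl_sd = np.nanstd(log_ctrl, axis=1, ddof=1)

    diff = log_case - ctrl_mean[:, None]
    scale = np.broadcast_to(
        ctrl_sd[:, None] * np.sqrt(1.0 + 1.0 / m), diff.shape
    )
    pvalue = np.ones_like(diff)
    ok = stats.defined_mask.astype(bool) & np.isfinite(diff) & np.isfinite(scale)

    zero_var = ok & (scale == 0)
    pvalue[zero_var] = np.where(diff[zero_var] == 0, 1.0, 0.0)

    regular = ok & (scale > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.zeros_like(diff)
        t[regular] = diff[regular] / scale[regular]
    pvalue[regular] = 2.0 * sps.t.sf(np.abs(t[regular]), df=m - 1)

    outside = np.zeros(diff.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        outside[ok] = (stats.cnr[ok] < fc_low) | (stats.cnr[ok] > fc_high)
    btif = (ok & (pvalue < alpha) & outside).astype(np.int8)

    stats.pvalue = pvalue
    stats.btif = btif
    return stats
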