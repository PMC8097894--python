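"""geNorm-style qPCR normalization and fold changes.

Raw threshold-cycle (Ct) tables are converted to relative quantities
``Q = E**(Ct_calibrator − Ct)`` (amplification efficiency E, default 2;
calibrator = lowest Ct of the gene across samples).  Each sample's
quantities are divided by the normalization factor NF — the geometric
mean of the housekeeping genes' quantities in that sample (two
housekeeping genes at minimum, e.g. B2M and EEF1A1) — and per-condition
means are expressed as fold changes relative to a reference condition
(adult muscle tissue in the assay this reproduces), whose mean fold is
1 by construction.

The full geNorm expression-stability ranking (M values) is available as
a diagnostic; it is not used to select the housekeeping set, which the
assay fixes a priori.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean


class QpcrError(ValueError):
    pass


@dataclass
class CtTable:
    """A Ct matrix (genes × samples) with condition labels.

    ``ct`` has gene ids as the index and sample ids as columns; missing
    measurements are NaN and are dropped per gene–sample pair, never
    imputed.
    """

    ct: pd.DataFrame
    conditions: Mapping[str, str]  # sample id -> condition label
    hk_genes: Sequence[str]
    reference_condition: str
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        missing_cond = [s for s in self.ct.columns if s not in self.conditions]
        if missing_cond:
            raise QpcrError(f"samples without condition label: {missing_cond}")
        if len(self.hk_genes) < 2:
            raise QpcrError("at least 2 housekeeping genes required")
        absent = [g for g in self.hk_genes if g not in self.ct.index]
        if absent:
            raise QpcrError(f"housekeeping genes absent from table: {absent}")
        if not (self.efficiency > 1):
            raise QpcrError("amplification efficiency must be > 1")
        if self.reference_condition not in set(self.conditions.values()):
            raise QpcrError(
                f"reference condition {self.reference_condition!r} has no samples"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    def condition_of(self, sample: str) -> str:
        return self.conditions[sample]


@dataclass
class FoldChangeResult:
    """Per gene × condition mean fold change and SEM over samples."""

    mean: pd.DataFrame  # genes × conditions
    sem: pd.DataFrame
    reference_condition: str
    normalized_quantities: pd.DataFrame  # genes × samples, Q/NF
    normalization_factors: pd.Series  # per sample


# ----------------------------------------------------------------------

def relative_quantities(
    table: CtTable, calibrator: Literal["min", "mean"] = "min"
) -> pd.DataFrame:
    """Per-gene relative quantities ``Q = E**(Ct_cal − Ct)``.

    The calibrator Ct is the gene's minimum Ct across samples (its most
    abundant sample has Q = 1) or, optionally, the gene's mean Ct.  NaN
    Ct values stay NaN (sample excluded for that gene).
    """
    ct = table.ct.astype(float)
    if calibrator == "min":
        cal = ct.min(axis=1, skipna=True)
    elif calibrator == "mean":
        cal = ct.mean(axis=1, skipna=True)
    else:
        raise QpcrError(f"unknown calibrator {calibrator!r}")
    return table.efficiency ** ct.rsub(cal, axis=0)


def normalization_factors(
    quantities: pd.DataFrame, hk_genes: Sequence[str]
) -> pd.Series:
    """Per-sample NF: geometric mean of the housekeeping quantities.

    Raises if any housekeeping quantity is missing in a sample (the NF
    would not be comparable across samples).
    """
    hk = quantities.loc[list(hk_genes)]
    if hk.isna().any().any():
        bad = hk.columns[hk.isna().any()].tolist()
        raise QpcrError(f"housekeeping quantity missing in samples: {bad}")
    return pd.Series(gmean(hk.to_numpy(), axis=0), index=quantities.columns)


def fold_changes(
    table: CtTable, calibrator: Literal["min", "mean"] = "min"
) -> FoldChangeResult:
    """geNorm-normalized fold changes relative to the reference condition.

    Per sample the normalized quantity is Q/NF; per condition the mean
    over samples is divided by the reference-condition mean, so the
    reference fold change is exactly 1 for every gene.
    """
    Q = relative_quantities(table, calibrator=calibrator)
    nf = normalization_factors(Q, table.hk_genes)
    norm = Q.div(nf, axis=1)

    cond = pd.Series({s: table.condition_of(s) for s in table.samples})
    by_cond_mean = norm.T.groupby(cond).mean().T  # genes × conditions
    ref_mean = by_cond_mean[table.reference_condition]
    if (ref_mean == 0).any() or ref_mean.isna().any():
        raise QpcrError("reference-condition mean quantity is 0 or undefined")
    mean_fc = by_cond_mean.div(ref_mean, axis=0)
    sem_fc = norm.div(ref_mean, axis=0).T.groupby(cond).sem(ddof=1).T
    if (mean_fc.stack(future_stack=True).dropna() <= 0).any():
        raise QpcrError("fold changes must be positive")
    return FoldChangeResult(
        mean=mean_fc,
        sem=sem_fc,
        reference_condition=table.reference_condition,
        normalized_quantities=norm,
        normalization_factors=nf,
    )


def genorm_stability(quantities: pd.DataFrame) -> pd.Series:
    """geNorm expression-stability measure M per gene (diagnostic).

    M_j is the mean, over all other genes k, of the standard deviation
    across samples of log2(Q_j / Q_k); lower M means more stable
    expression.  Provided for inspection only — the housekeeping set is
    fixed by the assay design, not chosen from this ranking.
    """
    genes = list(quantities.index)
    if len(genes) < 2:
        raise QpcrError("stability ranking needs ≥ 2 genes")
    logq = np.log2(quantities.astype(float))
    M = {}
    for g in genes:
        sds = [
            (logq.loc[g] - logq.loc[k]).std(ddof=1) for k in genes if k != g
        ]
        M[g] = float(np.mean(sds))
    return pd.Series(M, name="M")
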