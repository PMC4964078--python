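"""Per-sample prognostic scores from a Z-standardized, gene-keyed matrix.

Three scores are implemented:

* the unscaled recurrence score (RS): weighted group means of 16 genes
  combined linearly — higher is worse;
* the subtype-correlation risk-of-recurrence score (ROR-S-like): Spearman
  correlations of each sample's gene vector to the intrinsic-subtype
  centroids, combined with fixed coefficients — higher is worse;
* the directional mean-Z index (the Ellen construction): mean Z over
  good-outcome genes minus mean Z over poor-outcome genes — higher is better.

Genes absent from the matrix abort scoring with a named error rather than
silently renormalizing, so namespace problems surface immediately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_data import ExpressionMatrix, ZSCORE
from .errors import InvalidInputError, MissingFeatureError, UndefinedStatisticError
from .signature_registry import (
    GeneSignature,
    SubtypeCentroids,
    canonical_symbol,
    load_builtin,
)

HIGHER_IS_WORSE = "higher_is_worse"
HIGHER_IS_BETTER = "higher_is_better"


@dataclass
class ScoreVector:
    """A named per-sample score with its risk orientation."""

    name: str
    scores: pd.Series  # indexed by sample id
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER_IS_WORSE, HIGHER_IS_BETTER):
            raise InvalidInputError(f"unknown orientation {self.orientation!r}")

    def risk(self) -> pd.Series:
        """Scores re-signed so that higher always means higher risk."""
        return self.scores if self.orientation == HIGHER_IS_WORSE else -self.scores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.scores.index,
                "score": self.scores.values,
                "signature": self.name,
                "orientation": self.orientation,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _canonical_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    if matrix.scale != ZSCORE:
        raise InvalidInputError("scoring expects a zscore-scale matrix")
    vals = matrix.values.copy()
    vals.index = [canonical_symbol(s) for s in vals.index]
    if vals.index.duplicated().any():
        vals = vals.groupby(level=0).mean()
    return vals


def oncotype_rs(matrix: ExpressionMatrix, sig: Optional[GeneSignature] = None) -> ScoreVector:
    """Unscaled recurrence score on the Z scale.

    Each gene group's score is its fixture-weighted mean of member Z values;
    the RS is the fixture's linear combination of group scores. All 16 genes
    must be present (after alias resolution); housekeeping normalization does
    not apply to Z-standardized input.
    """
    if sig is None:
        sig = load_builtin("oncotype")
    if sig.group_coefficients is None:
        raise InvalidInputError("signature has no group structure for an RS")
    vals = _canonical_matrix(matrix)
    missing = [g.symbol for g in sig.genes if g.symbol not in vals.index]
    if missing:
        raise MissingFeatureError(f"recurrence-score genes absent from matrix: {missing}")
    rs = pd.Series(0.0, index=vals.columns)
    for group, coef in sig.group_coefficients.items():
        members = [g for g in sig.genes if g.group == group]
        group_score = sum(vals.loc[g.symbol] * g.weight for g in members)
        rs = rs + coef * group_score
    return ScoreVector("oncotype", rs, HIGHER_IS_WORSE)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Constant vectors have no defined rank
    correlation and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("spearman_rho needs two equal-length 1-D vectors")
    if x.size < 3:
        raise InvalidInputError("spearman_rho needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def prosigna_ror(
    matrix: ExpressionMatrix,
    centroids: Optional[SubtypeCentroids] = None,
    gene_subset: Optional[Sequence[str]] = None,
) -> ScoreVector:
    """Subtype-correlation risk-of-recurrence score.

    For each sample, the Spearman correlation of its gene vector to each
    subtype centroid is computed over the shared genes, and the score is the
    coefficient-weighted sum over the coefficient-bearing subtypes
    (the Normal-like subtype carries no coefficient). ``gene_subset``
    restricts scoring, e.g. to mimic a platform with missing probesets.
    """
    if centroids is None:
        centroids = load_builtin("pam50")
    vals = _canonical_matrix(matrix)
    genes = [g for g in centroids.genes if g in vals.index]
    if gene_subset is not None:
        allowed = {canonical_symbol(g) for g in gene_subset}
        genes = [g for g in genes if g in allowed]
    if len(genes) < 10:
        raise MissingFeatureError(
            f"only {len(genes)} centroid genes shared with the matrix (need >= 10)"
        )
    sub = vals.loc[genes]
    cent = centroids.matrix.loc[genes]
    ror = pd.Series(0.0, index=sub.columns)
    for subtype, coef in centroids.ror_coefficients.items():
        c = cent[subtype].to_numpy()
        rho = np.array([spearman_rho(sub[s].to_numpy(), c) for s in sub.columns])
        ror = ror + coef * pd.Series(rho, index=sub.columns)
    return ScoreVector("prosigna", ror, HIGHER_IS_WORSE)


def directional_mean_index(
    matrix: ExpressionMatrix, sig: GeneSignature, allow_one_sided: bool = False
) -> ScoreVector:
    """Good-minus-poor mean-Z prognostic index (higher = better prognosis).

    score = mean(Z over good-direction genes) - mean(Z over poor-direction
    genes). Both direction classes must be represented in the matrix unless
    ``allow_one_sided`` is set, in which case an absent class contributes a
    mean of zero (useful for discovered signatures whose surviving genes all
    point one way).
    """
    vals = _canonical_matrix(matrix)
    good = [s for s in sig.symbols_by_direction("good")]
    poor = [s for s in sig.symbols_by_direction("poor")]
    good_present = [canonical_symbol(s) for s in good if canonical_symbol(s) in vals.index]
    poor_present = [canonical_symbol(s) for s in poor if canonical_symbol(s) in vals.index]
    if (not good_present or not poor_present) and not (
        allow_one_sided and (good_present or poor_present)
    ):
        raise MissingFeatureError(
            f"signature {sig.name!r}: {len(good_present)}/{len(good)} good and "
            f"{len(poor_present)}/{len(poor)} poor genes present; both classes required"
        )
    zero = pd.Series(0.0, index=vals.columns)
    good_mean = vals.loc[good_present].mean(axis=0) if good_present else zero
    poor_mean = vals.loc[poor_present].mean(axis=0) if poor_present else zero
    return ScoreVector(sig.name, good_mean - poor_mean, HIGHER_IS_BETTER)
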