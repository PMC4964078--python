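"""Expression and clinical data containers, standardization, and cohort filtering.

The analysis operates on pre-normalized (RMA-like, log2) expression matrices.
Per-gene Z-standardization across samples mimics assay-style scoring on
microarray data: each probe/gene row is centred on its cohort mean and scaled
by its cohort standard deviation. Cohorts are restricted to ER+/HER2- tumours,
with HER2 status callable from the expression of designated HER2 probes when
the clinical table does not provide it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import (
    EmptyResultError,
    InvalidInputError,
    MissingFeatureError,
)

LOG2 = "log2"
ZSCORE = "zscore"

#: months of follow-up defining the distant-metastasis-free-survival endpoint
DMFS_HORIZON_MONTHS = 120.0


@dataclass
class ExpressionMatrix:
    """Genes/probes x samples expression matrix with an explicit value scale.

    ``values`` is a DataFrame whose index holds feature identifiers (probes or
    gene symbols) and whose columns hold sample identifiers. ``scale`` is
    ``"log2"`` for RMA-like intensities or ``"zscore"`` after per-row
    standardization.
    """

    values: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LOG2, ZSCORE):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise InvalidInputError(f"duplicated sample ids: {dups}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise InvalidInputError(f"duplicated feature ids: {dups}")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        """Check the z-score invariant: every row mean ~0 and sample SD ~1.

        Only meaningful for freshly standardized matrices; probe-collapsed
        matrices keep ``scale="zscore"`` but relax the unit-SD requirement
        (a mean of unit-variance rows has variance at most 1).
        """
        if self.scale != ZSCORE:
            return
        means = self.values.mean(axis=1).to_numpy()
        sds = self.values.std(axis=1, ddof=1).to_numpy()
        if np.abs(means).max(initial=0.0) > atol:
            raise InvalidInputError("zscore matrix has a row mean away from 0")
        if np.abs(sds - 1.0).max(initial=0.0) > atol:
            raise InvalidInputError("zscore matrix has a row SD away from 1")

    def subset_samples(self, sample_ids: Iterable) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])


@dataclass
class CohortTable:
    """Per-sample clinical record for an ER+/HER2- DMFS analysis.

    Columns: ``sample_id``, ``er_status`` (positive/negative), ``her2_status``
    (positive/negative/unknown), ``ln_status`` (positive/negative),
    ``dmfs_time`` (months), ``dmfs_event`` (1 = distant metastasis).
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "er_status", "her2_status", "ln_status", "dmfs_time", "dmfs_event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise InvalidInputError(f"clinical table missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            raise InvalidInputError("duplicated sample_id in clinical table")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.df["sample_id"])

    def subset(self, sample_ids: Iterable) -> "CohortTable":
        keep = self.df[self.df["sample_id"].isin(set(sample_ids))]
        # preserve the requested order
        keep = keep.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return CohortTable(keep)

    def durations(self) -> pd.Series:
        return self.df.set_index("sample_id")["dmfs_time"].astype(float)

    def events(self) -> pd.Series:
        return self.df.set_index("sample_id")["dmfs_event"].astype(int)

    def ln_mask(self, stratum: str) -> pd.Series:
        """Boolean sample mask for ``"lnpos"``, ``"lnneg"`` or ``"all"``."""
        s = self.df.set_index("sample_id")["ln_status"]
        if stratum in ("lnpos", "positive"):
            return s == "positive"
        if stratum in ("lnneg", "negative"):
            return s == "negative"
        if stratum == "all":
            return pd.Series(True, index=s.index)
        raise InvalidInputError(f"unknown stratum {stratum!r}")


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_tsv(path, sep: str = "\t", scale: str = LOG2) -> ExpressionMatrix:
    """Read a feature x sample table: first column feature id, header sample ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), scale=scale)


def read_geo_series_matrix(path, scale: str = LOG2) -> ExpressionMatrix:
    """Parse the expression block of a GEO series-matrix text file.

    Only the lines between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` are read; metadata lines are ignored.
    """
    rows = []
    header = None
    inside = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if not inside or not stripped:
                continue
            fields = [f.strip().strip('"') for f in stripped.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None or not rows:
        raise InvalidInputError("no series-matrix table found in file")
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), scale=scale)


def read_clinical_tsv(path) -> CohortTable:
    """Read a clinical TSV with columns sample_id, er_status, her2_status,
    ln_status, dmfs_time_months, dmfs_event."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df = df.rename(columns={"dmfs_time_months": "dmfs_time"})
    return CohortTable(df)


def write_clinical_tsv(cohort: CohortTable, path) -> None:
    out = cohort.df.rename(columns={"dmfs_time": "dmfs_time_months"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def z_standardize(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, dict]:
    """Per-row Z-standardization: z = (x - row mean) / row sample SD (n-1).

    Rows with zero variance carry no ranking information and would divide by
    zero, so they are dropped and listed in the report.

    Returns the standardized matrix (scale ``"zscore"``) and a report dict
    ``{"dropped_zero_variance": [...], "n_dropped": int}``.
    """
    if matrix.scale != LOG2:
        raise InvalidInputError("z_standardize expects a log2-scale matrix")
    if matrix.n_samples < 2:
        raise InvalidInputError("z_standardize needs at least 2 samples")
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    zero = sd <= 0.0
    dropped = list(vals.index[zero])
    kept = vals.loc[~zero]
    if kept.empty:
        raise EmptyResultError("all rows have zero variance")
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~zero], axis=0)
    report = {"dropped_zero_variance": dropped, "n_dropped": len(dropped)}
    return ExpressionMatrix(z, scale=ZSCORE), report


def classify_her2(
    matrix: ExpressionMatrix,
    her2_probe_ids: Iterable[str],
    random_state: int = 0,
) -> pd.Series:
    """Call per-sample HER2 overexpression from one or more HER2 probes.

    A sample is positive iff ANY listed probe is called overexpressed (OR
    semantics). Per probe, a two-component Gaussian mixture is fit to the
    log2 intensities and a sample is overexpressed when its posterior
    membership in the upper-mean component exceeds 0.5. When the mixture is
    degenerate — component means closer than half the pooled within-component
    SD, or a one-component fit preferred by BIC (a unimodal probe split in
    half by the two-component fit passes the distance check but not the model
    comparison) — the call falls back to a mean + 2*SD threshold.

    Returns a Series indexed by sample id with values "positive"/"negative".
    """
    if matrix.scale != LOG2:
        raise InvalidInputError("classify_her2 expects log2 intensities")
    probes = [p for p in her2_probe_ids if p in matrix.values.index]
    if not probes:
        raise MissingFeatureError(f"none of the HER2 probes {list(her2_probe_ids)} present")
    positive = pd.Series(False, index=matrix.values.columns)
    for probe in probes:
        x = matrix.values.loc[probe].to_numpy(dtype=float).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, n_init=5, random_state=random_state)
        gm.fit(x)
        gm1 = GaussianMixture(n_components=1, random_state=random_state).fit(x)
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        upper = int(np.argmax(means))
        pooled_sd = float(np.sqrt(np.mean(sds**2)))
        too_close = abs(means[0] - means[1]) < 0.5 * pooled_sd
        unimodal = gm1.bic(x) <= gm.bic(x)
        if too_close or unimodal:
            # degenerate mixture: unimodal probe, threshold at mean + 2 SD
            thr = float(x.mean()) + 2.0 * float(x.std(ddof=1))
            calls = x.ravel() > thr
        else:
            post_upper = gm.predict_proba(x)[:, upper]
            calls = post_upper > 0.5
        positive |= pd.Series(calls, index=matrix.values.columns)
    return positive.map({True: "positive", False: "negative"})


def filter_cohort(
    matrix: ExpressionMatrix, cohort: CohortTable
) -> tuple[ExpressionMatrix, CohortTable, dict]:
    """Restrict to analysis-ready ER+/non-HER2+ samples with complete records.

    Removal attribution is deterministic and ordered: missing/invalid clinical
    fields first, then ER-negative, then HER2-positive; a sample failing
    several criteria is counted once, under the first.
    """
    shared = [s for s in matrix.sample_ids if s in set(cohort.sample_ids)]
    if not shared:
        raise EmptyResultError("expression and clinical tables share no samples")
    df = cohort.subset(shared).df

    time = pd.to_numeric(df["dmfs_time"], errors="coerce")
    event = pd.to_numeric(df["dmfs_event"], errors="coerce")
    missing = (
        df["er_status"].isna()
        | df["ln_status"].isna()
        | ~df["er_status"].isin(["positive", "negative"])
        | ~df["ln_status"].isin(["positive", "negative"])
        | time.isna()
        | (time <= 0)
        | ~event.isin([0, 1])
    )
    er_neg = ~missing & (df["er_status"] != "positive")
    her2_pos = ~missing & ~er_neg & (df["her2_status"] == "positive")
    keep = ~(missing | er_neg | her2_pos)

    report = {
        "n_input": int(len(df)),
        "removed_missing_clinical": int(missing.sum()),
        "removed_er_negative": int(er_neg.sum()),
        "removed_her2_positive": int(her2_pos.sum()),
        "n_retained": int(keep.sum()),
    }
    if not keep.any():
        raise EmptyResultError(f"no samples retained after filtering: {report}")
    kept_ids = list(df.loc[keep, "sample_id"])
    return matrix.subset_samples(kept_ids), cohort.subset(kept_ids), report


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> tuple[ExpressionMatrix, dict]:
    """Collapse a probe-keyed Z matrix to gene symbols by averaging probe rows.

    Genes mapped only to absent probes do not appear in the output and are
    listed in the report. Averaging Z rows keeps scores continuous but the
    collapsed rows are no longer guaranteed unit-SD.
    """
    if matrix.scale != ZSCORE:
        raise InvalidInputError("collapse_probes expects a zscore matrix")
    if not probe_to_gene:
        raise InvalidInputError("probe_to_gene map is empty")
    mapping = pd.Series(dict(probe_to_gene))
    present = mapping.index.intersection(matrix.values.index)
    genes_all = sorted(set(mapping.values))
    if len(present) == 0:
        raise EmptyResultError("no mapped probe present in matrix")
    sub = matrix.values.loc[present]
    collapsed = sub.groupby(mapping.loc[present]).mean()
    collapsed.index.name = matrix.values.index.name
    missing_genes = sorted(set(genes_all) - set(collapsed.index))
    report = {"genes_without_probe": missing_genes, "n_genes": int(collapsed.shape[0])}
    return ExpressionMatrix(collapsed, scale=ZSCORE), report
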