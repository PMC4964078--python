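"""Orchestration of the full study replica.

filter cohort -> z-standardize (and collapse probes) -> score the three
bundled signatures -> per-lymph-node-stratum survival evaluation ->
optionally discover a new directional signature on a training cohort and
validate it on a held-out cohort -> optionally run per-stratum GSEA.

Every stage is pure with respect to its inputs; the report records seeds and
fixture versions so any fit can be reproduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cohort_data as cd
from . import enrichment as enr
from . import signature_discovery as disc
from . import signature_registry as reg
from . import signature_scoring as scoring
from . import survival_eval as se
from .errors import NodesigError
from .synthetic_data import SimulationConfig, SyntheticCohort, simulate_cohort

STRATA = ("lnneg", "lnpos")


@dataclass
class AnalysisReport:
    """Aggregated pipeline output; serializable to JSON and TSV tables."""

    cohort_summary: dict
    filter_report: dict
    fits: list = field(default_factory=list)  # SurvivalFit
    discovered_signature: Optional[dict] = None
    discovery_fits: list = field(default_factory=list)
    overlaps: dict = field(default_factory=dict)
    pathway_table: Optional[pd.DataFrame] = None
    gsea: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def fits_table(self) -> pd.DataFrame:
        return se.fits_to_table(list(self.fits) + list(self.discovery_fits))

    def to_dict(self) -> dict:
        out = {
            "cohort_summary": self.cohort_summary,
            "filter_report": self.filter_report,
            "fits": [f.to_dict() for f in self.fits],
            "discovered_signature": self.discovered_signature,
            "discovery_fits": [f.to_dict() for f in self.discovery_fits],
            "overlaps": self.overlaps,
            "gsea": {
                k: [r.to_dict() for r in v] for k, v in self.gsea.items()
            },
            "metadata": self.metadata,
        }
        if self.pathway_table is not None:
            out["pathway_table"] = self.pathway_table.to_dict(orient="records")
        return out

    def to_json(self, path=None, **kw) -> str:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify, **kw)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def summarize_cohort(cohort: cd.CohortTable) -> dict:
    """Cohort description: n, LN+ count, events, 10-year DMFS by stratum."""
    df = cohort.df
    out = {"n": int(len(df))}
    for label, mask in (
        ("all", pd.Series(True, index=df.index)),
        ("ln_positive", df["ln_status"] == "positive"),
        ("ln_negative", df["ln_status"] == "negative"),
    ):
        sub = df[mask]
        out[label] = {
            "n": int(len(sub)),
            "events": int(sub["dmfs_event"].sum()),
            "event_fraction": float(sub["dmfs_event"].mean()) if len(sub) else float("nan"),
        }
    return out


def score_signatures(matrix: cd.ExpressionMatrix) -> dict[str, scoring.ScoreVector]:
    """Compute the three bundled prognostic scores on a gene-keyed Z matrix."""
    cents = reg.load_builtin("pam50")
    available = [g for g in cents.genes if g not in set(cents.default_exclusion)]
    return {
        "oncotype": scoring.oncotype_rs(matrix),
        "prosigna": scoring.prosigna_ror(matrix, cents, gene_subset=available),
        "ellen": scoring.directional_mean_index(matrix, reg.load_builtin("ellen")),
    }


def evaluate_by_stratum(
    score: scoring.ScoreVector,
    cohort: cd.CohortTable,
    strata: tuple = STRATA,
) -> list[se.SurvivalFit]:
    fits = []
    for stratum in strata:
        mask = cohort.ln_mask(stratum)
        ids = list(mask.index[mask])
        sub = cohort.subset(ids)
        sub_score = scoring.ScoreVector(score.name, score.scores.loc[ids], score.orientation)
        fits.append(se.cox_fit(sub_score, sub, stratum=stratum))
    return fits


def discover_and_validate(
    train: SyntheticCohort | tuple,
    test: SyntheticCohort | tuple,
    seed: int = 0,
    delta_grid=None,
) -> dict:
    """Train a directional signature on one cohort, validate on another.

    Mirrors the cross-cohort transfer design: nearest-shrunken-centroid
    selection with CV-chosen shrinkage on the training cohort's 10-year
    outcome classes, then the derived mean-Z index is scored on the held-out
    cohort and evaluated per LN stratum.
    """
    tr_matrix, tr_cohort = _as_pair(train)
    te_matrix, te_cohort = _as_pair(test)
    z_tr, _ = cd.z_standardize(tr_matrix)
    z_te, _ = cd.z_standardize(te_matrix)
    labels, excluded = disc.make_outcome_classes(tr_cohort)
    X = z_tr.values.loc[:, labels.index]
    cv = disc.nsc_cv(X, labels, delta_grid=delta_grid, seed=seed)
    model = disc.nsc_train(X, labels, delta=cv.chosen_delta)
    signature = disc.derive_signature(model)
    score = scoring.directional_mean_index(z_te, signature, allow_one_sided=True)
    fits = evaluate_by_stratum(score, te_cohort)
    return {
        "cv": cv,
        "model": model,
        "signature": signature,
        "validation_score": score,
        "validation_fits": fits,
        "n_train_excluded_censored": len(excluded),
    }


def _as_pair(x):
    if isinstance(x, SyntheticCohort):
        return x.expression, x.cohort
    return x


def run_analysis(
    expression_path,
    clinical_path,
    config_path=None,
    config: Optional[dict] = None,
) -> AnalysisReport:
    """Execute the staged pipeline on files and return an AnalysisReport.

    ``config`` (or JSON at ``config_path``) may carry: ``probe_map`` (TSV
    path probe->gene), ``her2_probes`` (probe ids for expression-based HER2
    calls), ``seed``, ``gsea`` ({"gmt": path, "n_perm": int}), ``discovery``
    ({"expression": path, "clinical": path} for a held-out validation
    cohort). Inputs are never mutated.
    """
    cfg = dict(config or {})
    if config_path is not None:
        cfg = {**json.loads(Path(config_path).read_text()), **cfg}
    seed = int(cfg.get("seed", 0))

    expression_path = str(expression_path)
    if expression_path.endswith(("series_matrix.txt", ".series_matrix")):
        matrix = cd.read_geo_series_matrix(expression_path)
    else:
        matrix = cd.read_expression_tsv(expression_path)
    cohort = cd.read_clinical_tsv(clinical_path)

    if cfg.get("her2_probes"):
        calls = cd.classify_her2(matrix, cfg["her2_probes"], random_state=seed)
        df = cohort.df.copy()
        unknown = ~df["her2_status"].isin(["positive", "negative"])
        df.loc[unknown, "her2_status"] = (
            df.loc[unknown, "sample_id"].map(calls).fillna("unknown")
        )
        cohort = cd.CohortTable(df)

    matrix, cohort, filt_report = cd.filter_cohort(matrix, cohort)
    zmat, z_report = cd.z_standardize(matrix)
    if cfg.get("probe_map"):
        pm = pd.read_csv(cfg["probe_map"], sep="\t", index_col=0).iloc[:, 0].to_dict()
        zmat, collapse_report = cd.collapse_probes(zmat, pm)
    else:
        collapse_report = None

    scores = score_signatures(zmat)
    fits: list[se.SurvivalFit] = []
    for sv in scores.values():
        fits.extend(evaluate_by_stratum(sv, cohort))

    onc, pam, ellen = (reg.load_builtin(n) for n in ("oncotype", "pam50", "ellen"))
    overlaps = {
        "oncotype_pam50": reg.signature_overlap(onc, pam),
        "oncotype_ellen": reg.signature_overlap(onc, ellen),
        "pam50_ellen": reg.signature_overlap(pam, ellen),
    }
    pathway_table, unique_counts = reg.pathway_counts(reg.load_builtin("ellen_pathways"))

    report = AnalysisReport(
        cohort_summary=summarize_cohort(cohort),
        filter_report={
            "filter": filt_report,
            "z_standardize": z_report,
            "collapse": collapse_report,
        },
        fits=fits,
        overlaps=overlaps,
        pathway_table=pathway_table,
        metadata={
            "seed": seed,
            "ellen_unique_counts": unique_counts,
            "ellen_counts": ellen.meta,
            "pam50_version": pam.version,
            "pam50_centroids_synthetic": pam.synthetic,
        },
    )

    if cfg.get("discovery"):
        d = cfg["discovery"]
        te_matrix = cd.read_expression_tsv(d["expression"])
        te_cohort = cd.read_clinical_tsv(d["clinical"])
        res = discover_and_validate((matrix, cohort), (te_matrix, te_cohort), seed=seed)
        report.discovered_signature = {
            "n_genes": len(res["signature"].genes),
            "delta": res["model"].delta,
            "genes": [
                {"symbol": g.symbol, "direction": g.direction} for g in res["signature"].genes
            ],
            "n_train_excluded_censored": res["n_train_excluded_censored"],
        }
        report.discovery_fits = res["validation_fits"]

    if cfg.get("gsea"):
        g = cfg["gsea"]
        gene_sets = reg.read_gmt(g["gmt"])
        n_perm = int(g.get("n_perm", 200))
        for stratum in STRATA:
            mask = cohort.ln_mask(stratum)
            ids = list(mask.index[mask])
            sub = cohort.subset(ids)
            labels, _ = disc.make_outcome_classes(sub)
            try:
                report.gsea[stratum] = enr.gsea_permutation(
                    zmat.values.loc[:, labels.index],
                    labels,
                    gene_sets,
                    n_perm=n_perm,
                    seed=seed,
                    pos_class=disc.EVENT_CLASS,
                )
            except NodesigError as exc:
                report.gsea[stratum] = []
                report.metadata[f"gsea_{stratum}_error"] = str(exc)

    return report


def simulate_to_files(out_dir, config: Optional[SimulationConfig] = None, seed: int = 0):
    """Write a simulated cohort as the TSV formats the loaders read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig(seed=seed)
    syn = simulate_cohort(config)
    expr_path = out / "expression.tsv"
    clin_path = out / "clinical.tsv"
    syn.expression.values.to_csv(expr_path, sep="\t")
    cd.write_clinical_tsv(syn.cohort, clin_path)
    truth = {
        "seed": syn.truth.seed,
        "informative_genes": syn.truth.informative_genes.to_dict(orient="records"),
        "linear_predictor": syn.truth.linear_predictor["realized"].to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=_jsonify))
    return expr_path, clin_path, syn
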