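"""Gene-set enrichment engine: signal-to-noise ranking, weighted running-sum
enrichment score, phenotype-permutation significance.

Genes are ranked by a signal-to-noise metric between two outcome classes.
Walking the ranked list, set members ("hits") increment a running sum by
their weighted metric share and non-members ("misses") decrement it evenly;
the enrichment score (ES) is the running sum's maximum-magnitude deviation
from zero, signed. Significance comes from permuting the phenotype labels:
NES normalizes ES by the mean same-sign permuted |ES| and the nominal p is
the fraction of same-sign permuted scores at least as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .cohort_data import ExpressionMatrix
from .errors import (
    DegenerateSetError,
    EmptyOverlapError,
    InvalidInputError,
)


@dataclass
class RankedList:
    """Genes ordered by metric (descending), ties broken by symbol ascending."""

    symbols: list
    metric: pd.Series  # indexed by symbol, in ranked order

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class EnrichmentResult:
    name: str
    es: float
    n_genes: int  # set members represented in the ranked list
    nes: Optional[float] = None
    p: Optional[float] = None
    running_sum: Optional[np.ndarray] = field(default=None, repr=False)
    hit_positions: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "es": self.es,
            "nes": self.nes,
            "p": self.p,
            "n_genes": self.n_genes,
        }


def _class_stats(vals: pd.DataFrame, mask: np.ndarray) -> tuple[pd.Series, pd.Series]:
    sub = vals.loc[:, mask]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    floor = np.maximum(0.2 * mu.abs(), 0.2)
    return mu, pd.Series(np.maximum(sd, floor), index=sd.index)


def rank_by_signal_to_noise(
    X,
    labels,
    pos_class=None,
) -> RankedList:
    """Rank genes by signal-to-noise between two phenotype classes.

    metric = (mu_pos - mu_neg) / (sd_pos + sd_neg), with each class SD floored
    at max(0.2 * |class mean|, 0.2) — the usual guard against tiny-variance
    genes dominating the ranking. Positive metric = higher in ``pos_class``
    (default: first label in first-appearance order). Both classes need at
    least 3 samples.
    """
    vals = X.values if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
    y = pd.Series(labels, index=vals.columns) if not isinstance(labels, pd.Series) else labels
    y = y.loc[vals.columns]
    classes = list(dict.fromkeys(y))
    if len(classes) != 2:
        raise InvalidInputError(f"need exactly 2 classes, got {classes}")
    if pos_class is None:
        pos_class = classes[0]
    if pos_class not in classes:
        raise InvalidInputError(f"pos_class {pos_class!r} not among {classes}")
    neg_class = classes[0] if pos_class == classes[1] else classes[1]
    n_pos = int((y == pos_class).sum())
    n_neg = int((y == neg_class).sum())
    if min(n_pos, n_neg) < 3:
        raise InvalidInputError(f"each class needs >= 3 samples ({n_pos} vs {n_neg})")
    mu_p, sd_p = _class_stats(vals, (y == pos_class).to_numpy())
    mu_n, sd_n = _class_stats(vals, (y == neg_class).to_numpy())
    metric = (mu_p - mu_n) / (sd_p + sd_n)
    order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
    ordered = metric.loc[order]
    return RankedList(symbols=list(order), metric=ordered)


def enrichment_score(
    ranked: RankedList,
    gene_set: Iterable,
    name: str = "",
    p: float = 1.0,
) -> EnrichmentResult:
    """Weighted Kolmogorov-Smirnov-style running-sum enrichment score.

    Hits increment by |metric|^p normalized over all hits; misses decrement by
    1/(N - N_H). ES is the signed maximum-magnitude deviation of the running
    sum. If every hit has zero metric the hit weights fall back to uniform.
    """
    members = set(gene_set)
    n = len(ranked)
    hit = np.array([g in members for g in ranked.symbols], dtype=bool)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise EmptyOverlapError(f"gene set {name!r} shares no member with the ranked list")
    if n_hits == n:
        raise DegenerateSetError(f"gene set {name!r} covers the whole ranked list")
    w = np.abs(ranked.metric.to_numpy()) ** p
    w = np.where(hit, w, 0.0)
    total = w.sum()
    if total == 0:
        w = hit.astype(float)
        total = w.sum()
    steps = np.where(hit, w / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return EnrichmentResult(
        name=name,
        es=float(running[i]),
        n_genes=n_hits,
        running_sum=running,
        hit_positions=np.flatnonzero(hit),
    )


def gsea_permutation(
    X,
    labels,
    gene_sets: Mapping[str, Iterable],
    n_perm: int = 1000,
    seed: int = 0,
    pos_class=None,
    p: float = 1.0,
) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA over a collection of gene sets.

    Labels are permuted ``n_perm`` times (seeded); for each permutation the
    ranking and each set's ES are recomputed. NES = ES / mean(|permuted ES|
    of matching sign); nominal p = fraction of same-sign permuted ES at least
    as extreme as the observed one. Sets with no member in the list are
    skipped silently (reported with NaN ES would be noise).
    """
    if n_perm < 10:
        raise InvalidInputError("n_perm must be >= 10")
    vals = X.values if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
    y = pd.Series(labels, index=vals.columns) if not isinstance(labels, pd.Series) else labels
    y = y.loc[vals.columns]
    ranked = rank_by_signal_to_noise(vals, y, pos_class=pos_class)
    observed: dict[str, EnrichmentResult] = {}
    for name, members in gene_sets.items():
        try:
            observed[name] = enrichment_score(ranked, members, name=name, p=p)
        except EmptyOverlapError:
            continue
    rng = np.random.default_rng(seed)
    perm_es = {name: np.empty(n_perm) for name in observed}
    y_arr = y.to_numpy()
    for b in range(n_perm):
        y_perm = pd.Series(rng.permutation(y_arr), index=y.index)
        ranked_b = rank_by_signal_to_noise(vals, y_perm, pos_class=pos_class)
        for name in observed:
            perm_es[name][b] = enrichment_score(
                ranked_b, gene_sets[name], name=name, p=p
            ).es
    results = []
    for name, res in observed.items():
        null = perm_es[name]
        same_sign = null[np.sign(null) == np.sign(res.es)] if res.es != 0 else null
        if same_sign.size:
            res.nes = float(res.es / np.abs(same_sign).mean())
            res.p = float((np.abs(same_sign) >= abs(res.es)).mean())
        else:
            res.nes = np.nan
            res.p = 1.0 / n_perm
        results.append(res)
    return results
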