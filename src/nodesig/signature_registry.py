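"""Bundled prognostic signatures: gene lists, weights, centroids, annotations.

Three signatures are served:

* ``oncotype`` — the 16 prognostic recurrence-score genes in their 7 weighted
  groups (unscaled linear form; housekeeping genes excluded).
* ``pam50`` — the 50 intrinsic-subtype genes with a gene x subtype centroid
  matrix and the subtype-correlation (ROR-S) combination coefficients.
  The bundled centroid values are a synthetic stand-in structured by known
  subtype biology; the combination coefficients are the published ones.
* ``ellen`` — the mean-Z prognostic signature with every gene labelled by its
  outcome direction (good = low risk of distant metastasis, poor = high risk),
  together with its pathway annotation (``ellen_pathways``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .errors import CorruptFixtureError, InvalidInputError

#: symbol aliases applied at load/scoring time (published name -> canonical)
ALIASES = {
    "KI-67": "MKI67",
    "KI67": "MKI67",
    "HER2": "ERBB2",
    "HER-2": "ERBB2",
    "STK15": "AURKA",
    "AURORA-A": "AURKA",
    "SURVIVIN": "BIRC5",
    "ER": "ESR1",
    "PR": "PGR",
    "CTSL2": "CTSV",
    "KNTC2": "NDC80",
    "CDCA1": "NUF2",
    "ORC6L": "ORC6",
    "GPR172A": "SLC52A2",
    "GLTSCR2": "NOP53",
    "H3F3A": "H3-3A",
    "WISP1": "CCN4",
}

#: the 50 intrinsic-subtype genes (canonical symbols)
PAM50_GENES = (
    "ACTR3B ANLN BAG1 BCL2 BIRC5 BLVRA CCNB1 CCNE1 CDC20 CDC6 NUF2 CDH3 "
    "CENPF CEP55 CXXC5 EGFR ERBB2 ESR1 EXO1 FGFR4 FOXA1 FOXC1 GPR160 GRB7 "
    "KIF2C NDC80 KRT14 KRT17 KRT5 MAPT MDM2 MELK MIA MKI67 MLPH MMP11 "
    "MYBL2 MYC NAT1 ORC6 PGR PHGDH PTTG1 RRM2 SFRP1 SLC39A6 TMEM45B TYMS "
    "UBE2C UBE2T"
).split()


def canonical_symbol(symbol: str) -> str:
    """Upper-case a gene symbol and resolve known aliases."""
    s = str(symbol).strip().upper()
    return ALIASES.get(s, s)


@dataclass
class SignatureGene:
    symbol: str
    direction: str = "none"  # good | poor | none
    group: Optional[str] = None
    weight: Optional[float] = None


@dataclass
class GeneSignature:
    """A named list of genes with direction/group/weight metadata.

    ``group_coefficients`` holds, for group-structured signatures such as the
    recurrence score, the linear coefficient applied to each group mean;
    per-gene ``weight`` is then the within-group weight already divided by the
    group divisor, so the score is fully determined by this object.
    """

    name: str
    genes: list[SignatureGene]
    group_coefficients: Optional[dict[str, float]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise CorruptFixtureError(f"duplicated symbols in {self.name}: {dup}")

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def symbols_by_direction(self, direction: str) -> list[str]:
        return [g.symbol for g in self.genes if g.direction == direction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.symbol, g.direction, g.group, g.weight) for g in self.genes],
            columns=["symbol", "direction", "group", "weight"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SubtypeCentroids:
    """Gene x intrinsic-subtype centroid matrix plus ROR combination weights."""

    matrix: pd.DataFrame  # genes x subtypes
    ror_coefficients: dict[str, float]
    default_exclusion: list[str] = field(default_factory=list)
    synthetic: bool = False
    version: str = ""

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise CorruptFixtureError("duplicated genes in centroid matrix")
        unknown = set(self.ror_coefficients) - set(self.matrix.columns)
        if unknown:
            raise CorruptFixtureError(f"ROR coefficients for unknown subtypes: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def symbols(self) -> list[str]:
        return self.genes


@dataclass
class PathwayAnnotation:
    """Gene -> biological-pathway records with outcome direction labels."""

    records: pd.DataFrame  # columns: symbol, pathway, direction

    def __post_init__(self) -> None:
        need = {"symbol", "pathway", "direction"}
        if not need.issubset(self.records.columns):
            raise CorruptFixtureError("pathway annotation needs symbol/pathway/direction")
        bad = ~self.records["direction"].isin(["good", "poor"])
        if bad.any():
            raise CorruptFixtureError("pathway annotation directions must be good/poor")


def _data_path(name: str):
    return resources.files("nodesig").joinpath("data", name)


def _load_oncotype() -> GeneSignature:
    spec = json.loads(_data_path("oncotype_rs.json").read_text())
    genes: list[SignatureGene] = []
    coeffs: dict[str, float] = {}
    for group, g in spec["groups"].items():
        coeffs[group] = float(g["coefficient"])
        for sym, w in g["weights"].items():
            genes.append(
                SignatureGene(
                    symbol=canonical_symbol(sym),
                    direction=g["direction"],
                    group=group,
                    weight=float(w) / float(g["divisor"]),
                )
            )
    sig = GeneSignature("oncotype", genes, group_coefficients=coeffs)
    if len(sig.genes) != 16 or len(coeffs) != 7:
        raise CorruptFixtureError("recurrence-score fixture must have 16 genes in 7 groups")
    groups_per_gene = pd.Series([g.group for g in sig.genes], index=sig.symbols)
    if groups_per_gene.index.duplicated().any():
        raise CorruptFixtureError("a recurrence-score gene belongs to more than one group")
    return sig


def _load_pam50() -> SubtypeCentroids:
    meta = json.loads(_data_path("pam50_ror.json").read_text())
    with resources.as_file(_data_path(meta["centroid_file"])) as p:
        mat = pd.read_csv(p, sep="\t", index_col=0)
    mat.index = [canonical_symbol(s) for s in mat.index]
    cents = SubtypeCentroids(
        matrix=mat,
        ror_coefficients={k: float(v) for k, v in meta["ror_coefficients"].items()},
        default_exclusion=[canonical_symbol(s) for s in meta["default_exclusion"]],
        synthetic=bool(meta.get("centroids_synthetic", False)),
        version=meta.get("version", ""),
    )
    if sorted(cents.genes) != sorted(PAM50_GENES):
        raise CorruptFixtureError("centroid fixture does not cover exactly the 50 subtype genes")
    return cents


def _load_ellen_pathways() -> PathwayAnnotation:
    with resources.as_file(_data_path("ellen_pathways.tsv")) as p:
        rec = pd.read_csv(p, sep="\t")
    rec["symbol"] = rec["symbol"].map(canonical_symbol)
    return PathwayAnnotation(rec)


def _load_ellen() -> GeneSignature:
    """Build the Ellen signature from its pathway annotation.

    A symbol annotated in both directions (the bundled table contains one such
    gene) is resolved deterministically to ``poor`` — flagging elevated risk is
    the conservative call — and the unresolved per-direction counts are kept in
    ``meta`` alongside the publication's stated totals.
    """
    ann = _load_ellen_pathways().records
    by_gene = ann.groupby("symbol")["direction"].agg(set)
    genes = []
    n_conflicts = 0
    for sym, dirs in sorted(by_gene.items()):
        if len(dirs) > 1:
            n_conflicts += 1
            direction = "poor"
        else:
            direction = next(iter(dirs))
        genes.append(SignatureGene(symbol=sym, direction=direction))
    sig = GeneSignature(
        "ellen",
        genes,
        meta={
            "n_genes": len(genes),
            "n_good": sum(g.direction == "good" for g in genes),
            "n_poor": sum(g.direction == "poor" for g in genes),
            "n_direction_conflicts": n_conflicts,
            "published_counts": {"n_genes": 57, "n_good": 33, "n_poor": 24},
        },
    )
    if any(g.direction not in ("good", "poor") for g in sig.genes):
        raise CorruptFixtureError("every Ellen gene must be labelled good or poor")
    return sig


def load_builtin(name: str):
    """Load a bundled fixture: ``oncotype``, ``pam50``, ``ellen`` or
    ``ellen_pathways``. Raises on unknown names or corrupt fixtures."""
    loaders = {
        "oncotype": _load_oncotype,
        "pam50": _load_pam50,
        "ellen": _load_ellen,
        "ellen_pathways": _load_ellen_pathways,
    }
    if name not in loaders:
        raise InvalidInputError(f"unknown builtin {name!r}; choose from {sorted(loaders)}")
    return loaders[name]()


def _symbol_set(obj) -> set[str]:
    if hasattr(obj, "symbols"):
        syms: Iterable[str] = obj.symbols
    elif isinstance(obj, (list, tuple, set)):
        syms = obj
    else:
        raise InvalidInputError(f"cannot extract gene symbols from {type(obj).__name__}")
    return {canonical_symbol(s) for s in syms}


def signature_overlap(a, b) -> list[str]:
    """Case-normalized, alias-resolved set intersection of two signatures'
    symbols, returned sorted."""
    return sorted(_symbol_set(a) & _symbol_set(b))


def pathway_counts(ann: PathwayAnnotation) -> tuple[pd.DataFrame, dict]:
    """Count annotation records per pathway and direction.

    Returns ``(table, unique_counts)``: the table has one row per pathway with
    ``n_good``, ``n_poor`` and ``n_total`` record counts (a gene annotated to
    two pathways contributes to both rows); ``unique_counts`` deduplicates
    symbols across pathways within each direction.
    """
    rec = ann.records
    tab = (
        rec.pivot_table(index="pathway", columns="direction", values="symbol", aggfunc="count")
        .reindex(columns=["good", "poor"])
        .fillna(0)
        .astype(int)
        .rename(columns={"good": "n_good", "poor": "n_poor"})
    )
    tab["n_total"] = tab["n_good"] + tab["n_poor"]
    # stable, first-appearance pathway order
    tab = tab.loc[rec["pathway"].drop_duplicates()]
    unique = {
        "good": int(rec.loc[rec["direction"] == "good", "symbol"].nunique()),
        "poor": int(rec.loc[rec["direction"] == "poor", "symbol"].nunique()),
        "total": int(rec["symbol"].nunique()),
    }
    return tab.reset_index(), unique


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise InvalidInputError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
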