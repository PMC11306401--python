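"""Single-cell polygenic burden score (scPBS).

scPBS maps case-control rare protein-truncating-variant burden onto the
individual cells of an scRNA-seq dataset. For each cell it assembles the
genes that are both highly expressed in that cell and specific to its
cell type, tests whether carrying a rare PTV in that gene set is
associated with case status (Firth logistic regression with sex, ancestry
PCs and total exome count as covariates), and takes the fitted log-odds
coefficient as the cell's polygenic burden score. Genes whose expression
correlates with the score across cells (Pearson) are the trait-relevant
genes; the final rare-variant trait-relevance score (rvTRS) of a cell is
the mean expression of the top-decile trait-relevant genes minus a
bin-matched random control-gene score (the module-score construction used
for single-cell gene signatures).

Expression lives in an :class:`anndata.AnnData` with raw counts in ``X``,
log-normalized values in ``layers["lognorm"]`` and the cell-type label in
``obs["cell_type"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator

from .burden import FULL_COVARIATES, CarrierMatrix, unit_burden_test
from .firth import firth_logistic_fit

logger = logging.getLogger(__name__)

LOGNORM_LAYER = "lognorm"


def ensure_lognorm(adata, target_sum: float = 1e4):
    """Attach the log1p library-size-normalized layer if absent."""
    if LOGNORM_LAYER in adata.layers:
        return adata
    import scanpy as sc

    tmp = adata.copy()
    sc.pp.normalize_total(tmp, target_sum=target_sum)
    sc.pp.log1p(tmp)
    adata.layers[LOGNORM_LAYER] = tmp.X
    return adata


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def tpm_and_specificity(adata, cell_type_key: str = "cell_type") -> pd.DataFrame:
    """Expression-specificity matrix s[gene, cell type] in [0, 1].

    Per-type mean counts are scaled to one million (TPM-like); each gene's
    per-type TPM is divided by its maximum across types, so every expressed
    gene attains 1 in its most specific type and genes with no expression
    anywhere are 0 everywhere.
    """
    types = adata.obs[cell_type_key].astype(str)
    uniq = sorted(types.unique())
    if len(uniq) < 2:
        raise ValueError("specificity needs at least two cell types")
    X = adata.X
    means = np.zeros((adata.n_vars, len(uniq)))
    for j, t in enumerate(uniq):
        mask = (types == t).to_numpy()
        means[:, j] = np.ravel(X[mask].mean(axis=0))
    totals = means.sum(axis=0)
    if np.any(totals == 0):
        dead = [uniq[j] for j in np.where(totals == 0)[0]]
        raise ValueError(f"cell type(s) with zero total counts: {dead}")
    tpm = means / totals * 1e6
    mx = tpm.max(axis=1)
    spec = np.divide(tpm, mx[:, None], out=np.zeros_like(tpm), where=mx[:, None] > 0)
    return pd.DataFrame(spec, index=adata.var_names, columns=uniq)


def _rank_sum_z(X: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected Wilcoxon rank-sum z per gene (columns)."""
    n = X.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # tie correction per column
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 1e-300)
    return (r1 - mu) / np.sqrt(var)


def celltype_marker_genes(
    adata,
    fraction: float = 0.10,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    cell_type_key: str = "cell_type",
) -> dict[str, list[str]]:
    """Top-fraction marker genes per cell type, one-vs-rest.

    Genes pass if detected in >= ``min_pct`` of the type's cells and have a
    positive natural-log fold change >= ``logfc_threshold`` (fold change of
    mean un-logged normalized expression, with a pseudocount of 1); passing
    genes are ranked by the Wilcoxon rank-sum z statistic and the top
    ``fraction`` (ceil) kept.
    """
    ensure_lognorm(adata)
    Xl = _dense(adata.layers[LOGNORM_LAYER])
    detected = _dense(adata.X) > 0
    types = adata.obs[cell_type_key].astype(str)
    out: dict[str, list[str]] = {}
    expm1 = np.expm1(Xl)
    for t in sorted(types.unique()):
        mask = (types == t).to_numpy()
        if mask.sum() < 3:
            logger.warning("cell type %s has <3 cells; no markers", t)
            out[t] = []
            continue
        pct_in = detected[mask].mean(axis=0)
        logfc = np.log(
            (expm1[mask].mean(axis=0) + 1.0) / (expm1[~mask].mean(axis=0) + 1.0)
        )
        passing = (pct_in >= min_pct) & (logfc >= logfc_threshold)
        if not passing.any():
            logger.warning("cell type %s: no genes pass marker filters", t)
            out[t] = []
            continue
        z = _rank_sum_z(Xl[:, passing], mask)
        genes = np.asarray(adata.var_names)[passing]
        order = np.lexsort((genes, -z))  # z desc, gene id asc on ties
        k = int(np.ceil(fraction * passing.sum()))
        out[t] = [str(g) for g in genes[order[:k]]]
    return out


def celltype_burden_enrichment(
    markers: Mapping[str, Sequence[str]],
    gene_carriers: CarrierMatrix,
    design: pd.DataFrame,
    test: str = "firth",
    covariates: Optional[Sequence[str]] = None,
    control_carriers: Optional[CarrierMatrix] = None,
) -> pd.DataFrame:
    """Per-cell-type burden test of the type's marker-gene union.

    ``gene_carriers`` holds per-gene qualifying PTV carriage; when
    ``control_carriers`` (typically the synonymous class) is given, the
    same test is run on it and reported alongside as a negative control.
    """
    rows = []
    for t, genes in markers.items():
        for label, cm in (("PTV", gene_carriers), ("control", control_carriers)):
            if cm is None:
                continue
            hit = [g for g in genes if g in cm.values.index]
            if not hit:
                rows.append(
                    {"cell_type": t, "class": label, "OR": np.nan, "p": np.nan,
                     "n_case_carriers": 0, "n_control_carriers": 0, "null_flag": True}
                )
                continue
            carriers = (cm.values.loc[hit].sum(axis=0) > 0).astype(int)
            res = unit_burden_test(carriers, design, test, covariates, unit=t)
            rows.append(
                {
                    "cell_type": t,
                    "class": label,
                    "OR": res.odds_ratio,
                    "beta": res.beta,
                    "p": res.p_value,
                    "n_case_carriers": res.n_case_carriers,
                    "n_control_carriers": res.n_control_carriers,
                    "null_flag": res.null_flag,
                }
            )
    return pd.DataFrame(rows)


def per_cell_gene_sets(
    adata,
    specificity: pd.DataFrame,
    fraction: float = 0.10,
    min_expressed: int = 10,
    cell_type_key: str = "cell_type",
) -> dict[str, np.ndarray]:
    """The most cell-specific highly expressed genes, per cell.

    Each cell's expressed genes are scored by (log-normalized expression)
    x (specificity of the cell's assigned type); the top ``fraction``
    (ceil of the cell's expressed-gene count) are its gene set, ties broken
    lexicographically by gene id. Cells with fewer than ``min_expressed``
    expressed genes are skipped with a warning. Returns gene index arrays.
    """
    ensure_lognorm(adata)
    Xl = _dense(adata.layers[LOGNORM_LAYER])
    counts = _dense(adata.X)
    genes = np.asarray(adata.var_names)
    spec = specificity.reindex(genes)
    types = adata.obs[cell_type_key].astype(str).to_numpy()
    sets: dict[str, np.ndarray] = {}
    for i, cell in enumerate(adata.obs_names):
        expressed = np.where(counts[i] > 0)[0]
        if expressed.size < min_expressed:
            logger.warning("cell %s has <%d expressed genes; skipped", cell, min_expressed)
            continue
        score = Xl[i, expressed] * spec[types[i]].to_numpy()[expressed]
        order = np.lexsort((genes[expressed], -score))
        k = int(np.ceil(fraction * expressed.size))
        sets[str(cell)] = np.sort(expressed[order[:k]])
    return sets


def per_cell_burden_score(
    gene_sets: Mapping[str, np.ndarray],
    gene_carrier_bool: np.ndarray,
    gene_index: pd.Index,
    design: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
    test: str = "firth",
) -> pd.DataFrame:
    """Per-cell polygenic burden score.

    ``gene_carrier_bool`` is a gene x sample boolean matrix of qualifying
    PTV carriage aligned to ``gene_index`` (rows) and ``design.index``
    (columns). For each cell, samples carrying a qualifying allele in any
    gene of the cell's set form the carrier indicator; the score is the
    Firth log-odds coefficient of that indicator with the covariates.
    Cells whose set has no carriers score 0 and are null-flagged. Fits are
    cached on the carrier pattern, which repeats heavily across cells of
    one type.
    """
    covariates = list(covariates or [])
    y = design["status"].to_numpy()
    C = np.column_stack([design[c].to_numpy(float) for c in covariates]) if covariates else None
    cache: dict[bytes, float] = {}
    rows = []
    for cell, gidx in gene_sets.items():
        carrier = gene_carrier_bool[gidx].any(axis=0)
        if not carrier.any():
            rows.append({"cell": cell, "scpbs": 0.0, "null_flag": True})
            continue
        key = np.packbits(carrier).tobytes()
        if key not in cache:
            xv = carrier.astype(float)
            if test == "firth":
                X = np.column_stack([xv] + ([C] if C is not None else []))
                cache[key] = firth_logistic_fit(y, X)["beta"]
            else:
                n1 = int(y.sum())
                n0 = len(y) - n1
                a = int(xv[y == 1].sum())
                c = int(xv[y == 0].sum())
                from .burden import fisher_exact_2x2

                cache[key] = float(np.log(fisher_exact_2x2(a, n1 - a, c, n0 - c)["odds_ratio"]))
        rows.append({"cell": cell, "scpbs": cache[key], "null_flag": False})
    return pd.DataFrame(rows).set_index("cell")


def trait_relevant_genes(
    scpbs: pd.DataFrame, adata, fraction: float = 0.10
) -> tuple[pd.Series, list[str]]:
    """Pearson correlation of each gene's expression with scPBS across
    cells, and the top-``fraction`` trait-relevant gene list.

    Null-flagged cells are excluded; genes with zero expression variance
    over the remaining cells have undefined correlation and are excluded.
    Ranking is by signed correlation, descending, gene id breaking ties.
    """
    ensure_lognorm(adata)
    ok = scpbs.index[~scpbs["null_flag"]]
    if len(ok) < 3:
        raise ValueError("fewer than 3 cells with a defined scPBS")
    pos = adata.obs_names.get_indexer(ok)
    Xl = _dense(adata.layers[LOGNORM_LAYER])[pos]
    s = scpbs.loc[ok, "scpbs"].to_numpy()
    sc_ = s - s.mean()
    Xc = Xl - Xl.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (sc_**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ sc_) / denom
    pcc = pd.Series(r, index=adata.var_names).dropna()
    pcc = pcc[np.isfinite(pcc)]
    genes = pcc.index.to_numpy()
    order = np.lexsort((genes, -pcc.to_numpy()))
    k = int(np.ceil(fraction * len(pcc)))
    return pcc, [str(g) for g in genes[order[:k]]]


def rvtrs_score(
    adata,
    trait_genes: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Rare-variant trait-relevance score per cell.

    All genes are cut into ``n_bins`` equal-frequency bins of average
    log-normalized expression; for each trait gene, ``n_ctrl`` control
    genes are drawn (seeded) from its bin. rvTRS = mean expression of the
    trait genes minus mean expression of the pooled control draw, per cell
    (the standard module-score construction).
    """
    ensure_lognorm(adata)
    missing = set(trait_genes) - set(adata.var_names)
    if missing:
        raise KeyError(f"trait genes absent from the expression data: {sorted(missing)[:5]}")
    Xl = _dense(adata.layers[LOGNORM_LAYER])
    avg = pd.Series(Xl.mean(axis=0), index=adata.var_names)
    bins = pd.qcut(avg.rank(method="first"), min(n_bins, len(avg)), labels=False)
    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    var_pos = pd.Series(np.arange(adata.n_vars), index=adata.var_names)
    n_small_bins = 0
    for g in trait_genes:
        pool = var_pos[bins == bins[g]].to_numpy()
        if len(pool) < n_ctrl:
            n_small_bins += 1
            ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
        else:
            ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=False))
    if n_small_bins:
        logger.warning(
            "rvtrs_score: %d/%d trait genes sit in expression bins smaller than "
            "n_ctrl=%d; controls drawn with replacement",
            n_small_bins, len(trait_genes), n_ctrl,
        )
    ctrl = np.concatenate(ctrl_idx)
    tpos = var_pos[list(trait_genes)].to_numpy()
    score = Xl[:, tpos].mean(axis=1) - Xl[:, ctrl].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="rvtrs")


def candidate_gene_celltype_profile(
    adata, gene: str, cell_type_key: str = "cell_type"
) -> pd.Series:
    """Relative expression of one gene across cell types: per-type mean of
    log-normalized expression, z-scaled across types."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in the expression data")
    ensure_lognorm(adata)
    x = np.ravel(_dense(adata.layers[LOGNORM_LAYER][:, adata.var_names.get_loc(gene)]))
    types = adata.obs[cell_type_key].astype(str)
    means = pd.Series(x).groupby(types.to_numpy()).mean().sort_index()
    sd = means.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return means * 0.0
    return (means - means.mean()) / sd


@dataclass
class ScPBSResult:
    scpbs: pd.DataFrame
    pcc: pd.Series
    trait_genes: list[str]
    rvtrs: pd.Series
    per_cell: pd.DataFrame
    per_type: pd.DataFrame
    specificity: pd.DataFrame


class ScPBS(BaseEstimator):
    """End-to-end single-cell polygenic burden scoring.

    Parameters
    ----------
    fraction : float, default 0.10
        Top fraction both for per-cell specific gene sets and for the
        trait-relevant gene list.
    n_bins, n_ctrl : module-score control-gene scheme (25 equal-frequency
        expression bins, 100 control genes per trait gene).
    covariates : covariate columns of the per-cell burden model; ``None``
        selects sex + PC1..PC10 + total_exome_count when present.
    test : "firth" (default) or "FET" for the per-cell burden coefficient.
    seed : seed for the control-gene draw.

    Attributes (after :meth:`fit`)
    ------------------------------
    specificity_ : gene x cell-type specificity matrix.
    gene_sets_ : per-cell specific gene sets (gene index arrays).
    scpbs_ : per-cell burden coefficient table with null flags.
    pcc_ : per-gene Pearson correlation with scPBS.
    trait_genes_ : top-decile trait-relevant genes.
    rvtrs_ : per-cell rare-variant trait-relevance score.
    result_ : :class:`ScPBSResult` bundling the above with summaries.
    """

    def __init__(
        self,
        fraction: float = 0.10,
        n_bins: int = 25,
        n_ctrl: int = 100,
        covariates: Optional[Sequence[str]] = None,
        test: str = "firth",
        seed: int = 0,
        cell_type_key: str = "cell_type",
    ):
        self.fraction = fraction
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.covariates = covariates
        self.test = test
        self.seed = seed
        self.cell_type_key = cell_type_key

    def fit(self, adata, gene_carriers: CarrierMatrix, design: pd.DataFrame):
        ensure_lognorm(adata)
        covs = self.covariates
        if covs is None:
            covs = [c for c in FULL_COVARIATES if c in design.columns]
        self.specificity_ = tpm_and_specificity(adata, self.cell_type_key)
        self.gene_sets_ = per_cell_gene_sets(
            adata, self.specificity_, self.fraction, cell_type_key=self.cell_type_key
        )
        carrier_bool = (
            gene_carriers.values.reindex(
                index=adata.var_names, columns=design.index
            )
            .fillna(0)
            .to_numpy()
            > 0
        )
        self.scpbs_ = per_cell_burden_score(
            self.gene_sets_, carrier_bool, adata.var_names, design, covs, self.test
        )
        self.pcc_, self.trait_genes_ = trait_relevant_genes(
            self.scpbs_, adata, self.fraction
        )
        self.rvtrs_ = rvtrs_score(
            adata, self.trait_genes_, self.n_bins, self.n_ctrl, self.seed
        )
        per_cell = pd.DataFrame(
            {
                "cell_type": adata.obs[self.cell_type_key].astype(str),
                "scpbs": self.scpbs_["scpbs"].reindex(adata.obs_names),
                "scpbs_null": self.scpbs_["null_flag"].reindex(adata.obs_names),
                "rvtrs": self.rvtrs_,
            }
        )
        if "X_embed" in adata.obsm:
            per_cell["embed_x"] = adata.obsm["X_embed"][:, 0]
            per_cell["embed_y"] = adata.obsm["X_embed"][:, 1]
        per_type = (
            per_cell.groupby("cell_type", observed=True)["rvtrs"]
            .agg(["count", "median", "mean", "std"])
            .sort_values("median", ascending=False)
        )
        self.per_cell_ = per_cell
        self.per_type_ = per_type
        self.result_ = ScPBSResult(
            self.scpbs_, self.pcc_, self.trait_genes_, self.rvtrs_,
            per_cell, per_type, self.specificity_,
        )
        return self


def run_scpbs(
    adata,
    gene_carriers: CarrierMatrix,
    design: pd.DataFrame,
    **params,
) -> ScPBSResult:
    """Functional wrapper over :class:`ScPBS`; returns the result bundle."""
    return ScPBS(**params).fit(adata, gene_carriers, design).result_
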