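"""Burden and collapsing association tests.

Association of qualifying-variant carriage with case status at three
resolutions: single genes (collapsing analysis with a Bonferroni
exome-wide threshold and a label-permutation expected p-value curve),
gene sets (Fisher scan with Benjamini-Hochberg FDR and a length-matched
resampling null), and the whole exome (Firth logistic regression with
sex, ancestry PCs and total exome count as covariates). Carrier coding
is an indicator of carrying at least one qualifying allele in the unit;
allele-count coding is available behind ``mode="count"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .firth import firth_logistic_fit

logger = logging.getLogger(__name__)

#: covariate columns of the most conservative model
FULL_COVARIATES = ["sex"] + [f"PC{i}" for i in range(1, 11)] + ["total_exome_count"]


@dataclass
class BurdenResult:
    unit: str
    odds_ratio: float
    p_value: float
    ci95: tuple
    test: str
    n_case_carriers: int
    n_control_carriers: int
    beta: Optional[float] = None
    se: Optional[float] = None
    model: str = "unadjusted"
    null_flag: bool = False
    haldane: bool = False


@dataclass
class EmpiricalNull:
    B: int
    observed: float
    resampled: np.ndarray
    empirical_p: float


@dataclass
class CarrierMatrix:
    """Unit (gene or gene set) x sample carrier data.

    ``values`` is a DataFrame indexed by unit with one column per sample;
    indicator mode holds 0/1 (any qualifying allele), count mode holds
    allele sums. ``total_exome_count`` is the per-sample qualifying-allele
    total over all four variant classes, used as a burden covariate.
    """

    values: pd.DataFrame
    mode: str
    variant_class: str
    total_exome_count: Optional[pd.Series] = None


def build_carrier_matrix(
    dosages: pd.DataFrame,
    variant_class: pd.Series,
    variant_gene: pd.Series,
    units: Mapping[str, Sequence[str]] | None = None,
    mode: str = "indicator",
    use_class: str = "PTV",
) -> CarrierMatrix:
    """Collapse qualifying-variant dosages to unit x sample carrier data.

    Parameters
    ----------
    dosages : qualifying-variant x sample allele dosages (NaN = missing;
        missing is treated as non-carrier, the site call-rate filter having
        already bounded the information loss).
    variant_class, variant_gene : per-variant class label and gene symbol,
        indexed like ``dosages``.
    units : mapping unit name -> gene list; ``None`` means one unit per gene.
    """
    if mode not in ("indicator", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    d = dosages.fillna(0.0)
    n_missing = int(dosages.isna().to_numpy().sum())
    if n_missing:
        logger.warning(
            "build_carrier_matrix: %d missing calls treated as non-carrier", n_missing
        )
    total = d.sum(axis=0)  # qualifying alleles over all classes present
    sel = d.loc[variant_class == use_class]
    genes = variant_gene.loc[sel.index]
    per_gene = sel.groupby(genes).sum()
    if units is None:
        agg = per_gene
    else:
        rows = {}
        for name, members in units.items():
            hit = [g for g in members if g in per_gene.index]
            if not hit:
                logger.warning("unit %s has no qualifying variants", name)
                rows[name] = pd.Series(0.0, index=per_gene.columns)
            else:
                rows[name] = per_gene.loc[hit].sum(axis=0)
        agg = pd.DataFrame(rows).T
        agg = agg.reindex(list(units.keys()))
    if mode == "indicator":
        agg = (agg > 0).astype(int)
    else:
        agg = agg.astype(int)
    return CarrierMatrix(agg, mode, use_class, total_exome_count=total.astype(int))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    Returns the sample odds ratio (a*d)/(b*c) with a Haldane 0.5 correction
    applied, and flagged, only when a zero cell occurs; the two-sided
    p-value sums hypergeometric probabilities of tables no more probable
    than the observed one; the 95% CI uses the log-OR normal approximation.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        # degenerate margin: no information
        return {
            "odds_ratio": np.nan,
            "p_value": 1.0,
            "ci95": (np.nan, np.nan),
            "haldane": False,
        }
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in cells
    if haldane:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = (float(x) for x in cells)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(np.log(or_) - z * se)), float(np.exp(np.log(or_) + z * se)))
    return {"odds_ratio": float(or_), "p_value": float(p), "ci95": ci, "haldane": haldane}


def unit_burden_test(
    carriers: pd.Series,
    design: pd.DataFrame,
    test: str = "FET",
    covariates: Optional[Sequence[str]] = None,
    unit: str = "",
) -> BurdenResult:
    """Burden test of one unit's carrier vector against case status.

    ``design`` is indexed by sample id with a binary ``status`` column
    (1 = case) and any covariate columns. ``test`` selects the carrier
    Fisher exact test or Firth logistic regression of
    status ~ carrier + covariates.
    """
    x = carriers.reindex(design.index)
    if x.isna().any():
        raise ValueError("carrier vector missing samples present in design")
    y = design["status"].to_numpy()
    xv = (x.to_numpy() > 0).astype(float)
    n_case = int(xv[y == 1].sum())
    n_ctrl = int(xv[y == 0].sum())
    if n_case + n_ctrl == 0:
        return BurdenResult(
            unit, np.nan, 1.0, (np.nan, np.nan), test, 0, 0, null_flag=True
        )
    if test == "FET":
        n1, n0 = int((y == 1).sum()), int((y == 0).sum())
        r = fisher_exact_2x2(n_case, n1 - n_case, n_ctrl, n0 - n_ctrl)
        return BurdenResult(
            unit,
            r["odds_ratio"],
            r["p_value"],
            r["ci95"],
            "FET",
            n_case,
            n_ctrl,
            haldane=r["haldane"],
        )
    if test == "firth":
        covariates = list(covariates or [])
        X = np.column_stack([xv] + [design[c].to_numpy(float) for c in covariates])
        fit = firth_logistic_fit(y, X)
        model = "+".join(["carrier"] + covariates) if covariates else "carrier"
        return BurdenResult(
            unit,
            fit["odds_ratio"],
            fit["p_value"],
            fit["ci95"],
            "firth",
            n_case,
            n_ctrl,
            beta=fit["beta"],
            se=fit["se"],
            model=model,
        )
    raise ValueError(f"unknown test {test!r}")


def _results_frame(results: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit": [r.unit for r in results],
            "n_case_carriers": [r.n_case_carriers for r in results],
            "n_control_carriers": [r.n_control_carriers for r in results],
            "OR": [r.odds_ratio for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.p_value for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "test": [r.test for r in results],
            "model": [r.model for r in results],
        }
    )


def geneset_scan(
    carriers: CarrierMatrix,
    design: pd.DataFrame,
    test: str = "FET",
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-set burden scan with Benjamini-Hochberg FDR over the collection,
    sorted by p-value (stable for ties)."""
    results = []
    for name, row in carriers.values.iterrows():
        results.append(unit_burden_test(row, design, test, covariates, unit=str(name)))
    df = _results_frame(results)
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def length_matched_empirical_p(
    target_genes: Sequence[str],
    gene_lengths: pd.Series,
    stat_fn: Callable[[list], float],
    B: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
) -> EmpiricalNull:
    """Empirical p for a gene-set statistic against length-matched random sets.

    Genes are binned into coding-length deciles; each of the B resampled
    sets reproduces the target set's per-decile composition (sampling
    without replacement within a decile; with replacement, warned, when a
    decile is too small). empirical_p = (1 + #{resampled >= observed}) / (B+1).
    """
    target = [g for g in target_genes if g in gene_lengths.index]
    if not target:
        raise ValueError("no target gene has a coding length")
    bins = pd.qcut(gene_lengths.rank(method="first"), n_bins, labels=False)
    rng = np.random.default_rng(seed)
    by_bin = {b: gene_lengths.index[bins == b].to_numpy() for b in range(n_bins)}
    composition = bins.loc[target].value_counts()
    observed = float(stat_fn(list(target)))
    resampled = np.empty(B)
    for i in range(B):
        draw = []
        for b, k in composition.items():
            pool = by_bin[int(b)]
            if len(pool) < k:
                logger.warning("length decile %d smaller than draw; with replacement", b)
                draw.extend(rng.choice(pool, size=k, replace=True))
            else:
                draw.extend(rng.choice(pool, size=k, replace=False))
        resampled[i] = stat_fn(draw)
    emp = (1.0 + float((resampled >= observed).sum())) / (B + 1.0)
    return EmpiricalNull(B, observed, resampled, emp)


def collapsing_scan(
    gene_carriers: CarrierMatrix,
    design: pd.DataFrame,
    B_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Per-gene carrier Fisher exact scan with exome-wide Bonferroni
    threshold and a permutation-based expected p-value curve.

    Every gene in the carrier matrix is tested (a gene with zero carriers
    gets p = 1); the Bonferroni threshold divides alpha by the number of
    genes in the matrix, which callers build from genes carrying at least
    one qualifying variant. The expected curve permutes case-control
    labels ``B_perm`` times, sorts each permutation's p-values and
    averages across permutations rank by rank (for QQ plots).
    """
    y = design["status"].to_numpy().astype(int)
    V = (gene_carriers.values.reindex(columns=design.index).to_numpy() > 0)
    n_testable = V.shape[0]
    if n_testable == 0:
        raise ValueError("empty carrier matrix")
    names = gene_carriers.values.index
    Vt = V
    n1, n0 = int(y.sum()), int((1 - y).sum())

    cache: dict[tuple[int, int], float] = {}

    def fet_p(k_case: int, k_tot: int) -> float:
        key = (k_case, k_tot)
        if key not in cache:
            a, c = k_case, k_tot - k_case
            _, p = stats.fisher_exact([[a, n1 - a], [c, n0 - c]])
            cache[key] = float(p)
        return cache[key]

    k_tot = Vt.sum(axis=1)
    k_case = Vt[:, y == 1].sum(axis=1)
    rows = []
    for i, g in enumerate(names):
        a, c = int(k_case[i]), int(k_tot[i] - k_case[i])
        r = fisher_exact_2x2(a, n1 - a, c, n0 - c)
        rows.append(
            {
                "gene": g,
                "n_case_carriers": a,
                "n_control_carriers": c,
                "OR": r["odds_ratio"],
                "p": r["p_value"],
            }
        )
    res = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    threshold = alpha / n_testable
    res["exome_wide_significant"] = res["p"] < threshold

    rng = np.random.default_rng(seed)
    expected = np.zeros(n_testable)
    for _ in range(B_perm):
        perm = rng.permutation(y)
        kc = Vt[:, perm == 1].sum(axis=1)
        ps = np.array([fet_p(int(kc[i]), int(k_tot[i])) for i in range(n_testable)])
        ps.sort()
        expected += ps
    if B_perm > 0:
        expected /= B_perm
    else:
        expected = np.array([])
    return {
        "results": res,
        "bonferroni_threshold": threshold,
        "n_tested": n_testable,
        "expected_p": expected,
    }


def attach_external_pvalues(
    results: pd.DataFrame,
    external: Mapping[str, pd.Series],
    on: str = "gene",
) -> pd.DataFrame:
    """Join externally computed per-gene p-values for joint reporting.

    Variance-component and combination tests (SKAT, SKAT-O, ACAT, mixed
    models) are run with their published implementations; this hook merges
    their per-gene p-values into a collapsing-scan result table as
    ``p_<method>`` columns. Genes absent from a method's series get NaN.
    """
    out = results.copy()
    for method, pvals in external.items():
        bad = pvals[(pvals < 0) | (pvals > 1)]
        if len(bad):
            raise ValueError(f"{method}: p-values outside [0,1] for {list(bad.index[:3])}")
        out[f"p_{method}"] = out[on].map(pvals)
    return out


def genomic_control(
    p_values: Optional[np.ndarray] = None,
    chi2_stats: Optional[np.ndarray] = None,
    median_1df: float = 0.456,
) -> dict:
    """Genomic-control inflation factor and corrected statistics.

    lambda = median(chi-square) / 0.456 (the 1-df median); when lambda > 1
    every statistic is divided by lambda, otherwise left unchanged.
    """
    if chi2_stats is None:
        if p_values is None:
            raise ValueError("provide p_values or chi2_stats")
        p_values = np.asarray(p_values, dtype=float)
        if p_values.size == 0:
            raise ValueError("empty input")
        chi2_stats = stats.chi2.isf(p_values, df=1)
    chi2_stats = np.asarray(chi2_stats, dtype=float)
    if chi2_stats.size == 0:
        raise ValueError("empty input")
    if chi2_stats.size < 10:
        logger.warning("genomic_control: fewer than 10 statistics; lambda unstable")
    lam = float(np.median(chi2_stats) / median_1df)
    adj = chi2_stats / lam if lam > 1.0 else chi2_stats.copy()
    return {
        "lambda": lam,
        "chi2_adjusted": adj,
        "p_adjusted": stats.chi2.sf(adj, df=1),
    }
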