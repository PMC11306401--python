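"""Cohort and variant quality control.

Implements the QC ladder applied to a case-control exome cohort before
burden testing: per-call filters (depth, quality, allele balance),
per-site filters (low-complexity regions, VQSR flag, call rate, exact
Hardy-Weinberg test on the combined cohort), per-sample filters (hard
thresholds plus 4-SD outlier exclusion on Ti/Tv, het/hom and ins/del
ratios), X-inbreeding sex inference, ancestry principal components from
common variants, and greedy PC-space case-control matching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Variant x sample allele dosages with per-call metrics.

    ``dosages`` holds 0/1/2 with NaN for missing calls. ``dp``/``gq`` are
    per-call depth and genotype quality; ``ab`` is the allele balance,
    defined only for heterozygous calls (NaN elsewhere).
    """

    dosages: np.ndarray
    variant_ids: list
    sample_ids: list
    dp: Optional[np.ndarray] = None
    gq: Optional[np.ndarray] = None
    ab: Optional[np.ndarray] = None

    def __post_init__(self):
        n_var, n_samp = self.dosages.shape
        if len(self.variant_ids) != n_var or len(self.sample_ids) != n_samp:
            raise ValueError("dosage dimensions do not match registries")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            list(self.variant_ids),
            list(self.sample_ids),
            None if self.dp is None else self.dp.copy(),
            None if self.gq is None else self.gq.copy(),
            None if self.ab is None else self.ab.copy(),
        )


def filter_genotype_calls(
    g: GenotypeMatrix,
    min_dp: int = 10,
    min_gq: int = 20,
    ab_low: float = 0.2,
    ab_high: float = 0.8,
) -> GenotypeMatrix:
    """Set to missing every call with DP < 10, GQ < 20, or a heterozygous
    allele balance outside [0.2, 0.8]. Calls with a missing metric are
    treated as failing (set to missing, counted in the log)."""
    out = g.copy()
    d = out.dosages
    present = ~np.isnan(d)
    bad = np.zeros_like(present)
    if out.dp is not None:
        bad |= present & ~(out.dp >= min_dp)
    if out.gq is not None:
        bad |= present & ~(out.gq >= min_gq)
    if out.ab is not None:
        het = present & (d == 1)
        bad |= het & ~((out.ab >= ab_low) & (out.ab <= ab_high))
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("filter_genotype_calls: %d calls set to missing", n_bad)
    d[bad] = np.nan
    return out


def filter_variant_sites(
    low_complexity: bool,
    vqsr_pass: bool,
    call_rate: float,
    hwe_p: float,
    min_call_rate: float = 0.90,
    hwe_threshold: float = 1e-6,
) -> tuple[bool, Optional[str]]:
    """Keep/drop decision for one site with the first matching drop reason
    among low_complexity, vqsr_fail, call_rate, hwe (in that order)."""
    if not (0.0 <= call_rate <= 1.0) or not (0.0 <= hwe_p <= 1.0):
        raise ValueError("call_rate and hwe_p must lie in [0,1]")
    if low_complexity:
        return False, "low_complexity"
    if not vqsr_pass:
        return False, "vqsr_fail"
    if call_rate < min_call_rate:
        return False, "call_rate"
    if hwe_p < hwe_threshold:
        return False, "hwe"
    return True, None


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows a known discrete distribution; the two-sided p-value sums
    the probabilities of all heterozygote counts no more probable than the
    observed one (no mid-p correction). Monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    # log P(het = h | allele counts) up to a common constant:
    #   log n! - log n_aa! - log n_ab! - log n_bb! + h*log 2
    # with n_ab = h, minor homs = (n_minor - h)/2, major homs fill in.
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    minor_hom = (n_minor - hets) // 2
    major_hom = n - hets - minor_hom
    lg = lambda x: np.array([math.lgamma(v + 1) for v in x])
    logp = hets * math.log(2.0) - lg(hets) - lg(minor_hom) - lg(major_hom)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_het)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def sample_qc(
    stats: pd.DataFrame,
    min_call_rate: float = 0.9,
    min_mean_depth: float = 10.0,
    min_mean_gq: float = 65.0,
    sd_limit: float = 4.0,
) -> pd.DataFrame:
    """Per-sample keep/drop with reasons.

    ``stats`` is indexed by sample id with columns call_rate, mean_depth,
    mean_gq, titv, het_hom, ins_del. Hard thresholds are applied first;
    the one-pass 4-SD outlier exclusion for the three ratios is computed
    on the samples that survived the hard thresholds. Cohorts of fewer
    than 3 surviving samples skip the outlier step.
    """
    reasons = {s: [] for s in stats.index}
    hard = {
        "call_rate": ("low_call_rate", min_call_rate),
        "mean_depth": ("low_mean_depth", min_mean_depth),
        "mean_gq": ("low_mean_gq", min_mean_gq),
    }
    for col, (label, thresh) in hard.items():
        for s in stats.index[stats[col] < thresh]:
            reasons[s].append(label)
    survivors = [s for s in stats.index if not reasons[s]]
    if len(survivors) < 3:
        logger.warning("sample_qc: <3 samples after hard filters; outlier step skipped")
    else:
        sub = stats.loc[survivors]
        for col in ("titv", "het_hom", "ins_del"):
            mu, sd = sub[col].mean(), sub[col].std(ddof=1)
            if sd == 0 or np.isnan(sd):
                continue
            out = sub.index[np.abs(sub[col] - mu) > sd_limit * sd]
            for s in out:
                reasons[s].append(f"{col}_outlier")
    return pd.DataFrame(
        {
            "keep": [not reasons[s] for s in stats.index],
            "reasons": [",".join(reasons[s]) for s in stats.index],
        },
        index=stats.index,
    )


def x_inbreeding_coefficient(x_dosages: np.ndarray) -> np.ndarray:
    """Per-sample F = 1 - observed het / expected het over X variants.

    ``x_dosages`` is variants x samples (NaN missing). Expected
    heterozygosity per sample sums 2p(1-p) over that sample's non-missing
    variants, with p the variant's cohort alternate-allele frequency.
    """
    d = np.asarray(x_dosages, dtype=float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=1) / 2.0
    exp_het_var = 2.0 * p * (1.0 - p)
    present = ~np.isnan(d)
    obs = np.nansum(d == 1, axis=0).astype(float)
    exp = present.T @ np.nan_to_num(exp_het_var)
    f = np.full(d.shape[1], np.nan)
    ok = exp > 0
    f[ok] = 1.0 - obs[ok] / exp[ok]
    return f


def infer_sex(
    x_dosages: np.ndarray,
    male_threshold: float = 0.8,
    female_threshold: float = 0.4,
) -> np.ndarray:
    """Classify samples as male (F > 0.8), female (F < 0.4) or excluded
    (ambiguous F, or no usable X variants). Boundary values are excluded
    (strict inequalities)."""
    f = x_inbreeding_coefficient(x_dosages)
    labels = np.full(f.shape, "excluded", dtype=object)
    if np.isnan(f).all():
        logger.warning("infer_sex: no usable X-chromosome variants")
        return labels
    labels[f > male_threshold] = "male"
    labels[f < female_threshold] = "female"
    labels[np.isnan(f)] = "excluded"
    return labels


def compute_ancestry_pcs(
    dosages: np.ndarray,
    sample_ids: Sequence,
    n_pcs: int = 10,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Ancestry PCs from common variants (cohort MAF > 1%).

    Each variant is mean-centered at 2p and scaled by sqrt(2p(1-p))
    (unit variance under HWE); scores come from the SVD of the sample x
    variant matrix, ordered by decreasing eigenvalue, with the sign of
    each PC fixed so its largest-magnitude variant loading is positive.
    Missing dosages are mean-imputed (centered to zero).
    """
    d = np.asarray(dosages, dtype=float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=1) / 2.0
    maf = np.minimum(p, 1.0 - p)
    common = maf > maf_min
    if common.sum() < n_pcs:
        logger.warning(
            "compute_ancestry_pcs: only %d common variants for %d PCs",
            int(common.sum()),
            n_pcs,
        )
    d = d[common]
    p = p[common]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[denom == 0] = 1.0
    z = (d - 2.0 * p[:, None]) / denom[:, None]
    z = np.nan_to_num(z)  # mean imputation after centering
    z = z - z.mean(axis=1, keepdims=True)  # exact per-variant centering
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    k = min(n_pcs, (s > 1e-10 * max(s[0], 1e-300)).sum()) if s.size else 0
    if k < n_pcs:
        logger.warning("compute_ancestry_pcs: returning %d of %d PCs", k, n_pcs)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=list(sample_ids), columns=[f"PC{i+1}" for i in range(k)]
    )


def match_controls(
    case_pcs: pd.DataFrame, control_pcs: pd.DataFrame, k_pcs: int = 3
) -> list:
    """Greedy nearest-neighbor matching without replacement on the top
    ``k_pcs`` PCs; one control per case, case order as given, distance ties
    broken by lowest control id. Deterministic."""
    if len(control_pcs) < len(case_pcs):
        raise ValueError(
            f"{len(control_pcs)} controls cannot match {len(case_pcs)} cases"
        )
    if k_pcs > case_pcs.shape[1] or k_pcs > control_pcs.shape[1]:
        raise ValueError("k_pcs exceeds available PCs")
    ctrl = control_pcs.iloc[:, :k_pcs]
    order = np.argsort(ctrl.index.astype(str))
    ctrl = ctrl.iloc[order]  # id order makes ties resolve to lowest id
    ctrl_x = ctrl.to_numpy()
    available = np.ones(len(ctrl), dtype=bool)
    chosen = []
    for _, row in case_pcs.iloc[:, :k_pcs].iterrows():
        dist = np.linalg.norm(ctrl_x - row.to_numpy(), axis=1)
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # argmin takes the first = lowest id on ties
        available[j] = False
        chosen.append(ctrl.index[j])
    return chosen


def diagnostic_yield_summary(carrier_table: pd.DataFrame, n_cases: int) -> dict:
    """Summarize an externally curated table of per-case diagnostic findings.

    ``carrier_table`` has one row per detected pathogenic/likely-pathogenic
    finding with columns sample_id, gene, variant_class and (optionally)
    zygosity. Returns carrier yield percent (2 dp), class proportions,
    zygosity proportions and per-gene allele counts.
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    carriers = carrier_table["sample_id"].nunique()
    out = {
        "n_cases": n_cases,
        "n_carriers": carriers,
        "yield_percent": round(100.0 * carriers / n_cases, 2),
        "class_percent": {},
        "gene_allele_counts": carrier_table.groupby("gene").size().to_dict(),
    }
    n_findings = len(carrier_table)
    if n_findings:
        out["class_percent"] = {
            k: round(100.0 * v / n_findings, 2)
            for k, v in carrier_table["variant_class"].value_counts().items()
        }
    if "zygosity" in carrier_table.columns and carriers:
        per_sample = carrier_table.groupby("sample_id")["zygosity"].agg(
            lambda z: "monoallelic" if (len(z) == 1 and (z == "het").all()) else "other"
        )
        mono = int((per_sample == "monoallelic").sum())
        out["monoallelic_percent"] = round(100.0 * mono / carriers, 2)
    return out
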