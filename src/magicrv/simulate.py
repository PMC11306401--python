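"""Coupled genotype/phenotype and scRNA-seq simulation with known truth.

The generator emulates the structure the analysis pipeline assumes, at
desk scale: a case-control exome cohort in which rare protein-truncating
variant carriage is enriched in cases for a designated causal gene set
(enrichment applied on the odds scale, so the planted odds ratio is the
estimand the burden tests target), and an scRNA-seq count matrix with
distinct cell types whose planted marker genes are up-shifted
negative-binomial means. Linking the two — the causal gene set is one
cell type's marker genes — creates the ground truth scPBS is designed to
recover. Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .burden import CarrierMatrix
from .scpbs import ensure_lognorm


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort and expression data.

    Defaults are the recovery conditions the package is validated under:
    500 cases / 500 controls, 5 cell types x 200 cells, and a planted
    odds ratio of 5 concentrated in one cell type's 15 marker genes.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_genes: int = 1000
    baseline_carrier_rate: float = 0.01
    causal_set: Optional[Sequence[str]] = None
    causal_or: float = 5.0
    n_cell_types: int = 5
    cells_per_type: int = 200
    marker_genes_per_type: int = 15
    marker_logfc: float = 2.0
    type_effect_sd: float = 0.35
    nb_dispersion: float = 0.3
    variants_per_gene: int = 3
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def cell_type_names(self) -> list[str]:
        return [f"CT{i}" for i in range(self.n_cell_types)]

    def marker_map(self) -> dict[str, list[str]]:
        """Planted marker genes per type: consecutive blocks of the registry."""
        genes = self.gene_ids()
        need = self.n_cell_types * self.marker_genes_per_type
        if need > self.n_genes:
            raise ValueError("not enough genes for the requested marker blocks")
        return {
            t: genes[i * self.marker_genes_per_type : (i + 1) * self.marker_genes_per_type]
            for i, t in enumerate(self.cell_type_names())
        }


@dataclass
class SimulatedCohort:
    genotypes: pd.DataFrame  # variant x sample dosages
    annotations: pd.DataFrame  # module-1 annotation table dialect
    design: pd.DataFrame  # sample_id-indexed status + covariates
    gene_carriers: CarrierMatrix  # gene x sample PTV carrier indicators
    causal_genes: list


def _case_probability(baseline: float, odds_ratio: float) -> float:
    odds = odds_ratio * baseline / (1.0 - baseline)
    p = odds / (1.0 + odds)
    if not (0.0 < p < 1.0):
        raise ValueError(
            f"carrier probability {p} outside (0,1) for baseline={baseline}, OR={odds_ratio}"
        )
    return p


def simulate_cohort(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedCohort:
    """Simulate gene-level PTV carriage, materialized variants and covariates.

    Controls carry a qualifying PTV in each gene with the baseline rate;
    for causal genes the case carrier probability is the baseline odds
    scaled by ``causal_or``. Each carrier is assigned one of the gene's
    ``variants_per_gene`` synthetic frameshift variants; annotations are
    emitted in the pipeline's annotation-table dialect with gnomAD-style
    reference frequencies below the rarity threshold.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = config.gene_ids()
    causal = list(config.causal_set or [])
    unknown = set(causal) - set(genes)
    if unknown:
        raise ValueError(f"causal genes outside the registry: {sorted(unknown)[:5]}")
    n = config.n_cases + config.n_controls
    samples = [f"S{i:05d}" for i in range(n)]
    status = np.array([1] * config.n_cases + [0] * config.n_controls)

    p_ctrl = config.baseline_carrier_rate
    p_case_causal = _case_probability(p_ctrl, config.causal_or)
    p = np.full((config.n_genes, n), p_ctrl)
    causal_mask = np.isin(genes, causal)
    p[np.ix_(causal_mask, status == 1)] = p_case_causal
    carrier = rng.random((config.n_genes, n)) < p

    # materialize one synthetic PTV per carrier among the gene's variants
    var_rows = []
    dosage_rows = []
    var_ids = []
    for gi, g in enumerate(genes):
        chosen = rng.integers(0, config.variants_per_gene, size=n)
        for k in range(config.variants_per_gene):
            vid = f"chr1-{1000 + gi * 10 + k}-AT-A"
            dos = ((carrier[gi]) & (chosen == k)).astype(float)
            if dos.sum() == 0 and k > 0:
                continue  # keep at least one variant row per gene
            var_ids.append(vid)
            dosage_rows.append(dos)
            var_rows.append(
                {
                    "variant_id": vid,
                    "gene": g,
                    "consequence": "frameshift_variant",
                    "polyphen": "",
                    "sift": "",
                    "cadd_phred": 35.0,
                    "loftee": "HC",
                    "af_gnomad": float(rng.uniform(0, 2e-4)),
                    "af_1kg": 0.0,
                    "af_esp": 0.0,
                    "low_complexity": False,
                    "vqsr_pass": True,
                }
            )
    genotypes = pd.DataFrame(np.vstack(dosage_rows), index=var_ids, columns=samples)
    annotations = pd.DataFrame(var_rows).set_index("variant_id")

    pcs = rng.standard_normal((n, 10))
    design = pd.DataFrame(
        {
            "status": status,
            "sex": rng.integers(0, 2, size=n),
            **{f"PC{i+1}": pcs[:, i] for i in range(10)},
        },
        index=pd.Index(samples, name="sample_id"),
    )
    # total exome count: background qualifying alleles of all classes plus
    # the carried PTVs themselves
    design["total_exome_count"] = rng.poisson(100, size=n) + carrier.sum(axis=0)

    carriers = CarrierMatrix(
        pd.DataFrame(carrier.astype(int), index=genes, columns=samples),
        mode="indicator",
        variant_class="PTV",
        total_exome_count=design["total_exome_count"],
    )
    return SimulatedCohort(genotypes, annotations, design, carriers, causal)


def simulate_expression(config: SimulationConfig, seed: Optional[int] = None) -> ad.AnnData:
    """Negative-binomial scRNA-seq counts with planted cell-type markers.

    Gene base means are log-normal, modulated per (gene, type) by a
    lognormal effect of scale ``type_effect_sd`` (cell types differ in most
    genes, as real tissues do); each planted marker gene's mean is further
    multiplied by exp(marker_logfc) in its home type. ``nb_dispersion`` is
    the NB over-dispersion alpha (variance mu(1 + alpha*mu)); alpha -> 0
    degenerates to Poisson. Cells get their type label and a 2-D embedding
    of per-type Gaussian blobs.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = config.gene_ids()
    marker_map = config.marker_map()
    types = config.cell_type_names()
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes) * 0.5
    mu_by_type = np.tile(base, (config.n_cell_types, 1))
    if config.type_effect_sd > 0:
        mu_by_type = mu_by_type * np.exp(
            rng.normal(0.0, config.type_effect_sd, size=mu_by_type.shape)
        )
    for j, t in enumerate(types):
        idx = [genes.index(g) for g in marker_map[t]]
        mu_by_type[j, idx] *= np.exp(config.marker_logfc)

    n_cells = config.n_cell_types * config.cells_per_type
    counts = np.empty((n_cells, config.n_genes), dtype=np.int64)
    labels = []
    embed = np.empty((n_cells, 2))
    alpha = config.nb_dispersion
    for j, t in enumerate(types):
        sl = slice(j * config.cells_per_type, (j + 1) * config.cells_per_type)
        mu = np.tile(mu_by_type[j], (config.cells_per_type, 1))
        if alpha <= 1e-12:
            counts[sl] = rng.poisson(mu)
        else:
            theta = 1.0 / alpha
            lam = rng.gamma(theta, mu / theta)
            counts[sl] = rng.poisson(lam)
        labels.extend([t] * config.cells_per_type)
        center = 10.0 * np.array([np.cos(2 * np.pi * j / len(types)), np.sin(2 * np.pi * j / len(types))])
        embed[sl] = center + rng.standard_normal((config.cells_per_type, 2))
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"cell_type": pd.Categorical(labels)},
            index=[f"C{i:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obsm["X_embed"] = embed
    adata.uns["marker_map"] = {t: list(v) for t, v in marker_map.items()}
    ensure_lognorm(adata)
    return adata


@dataclass
class LinkedDataset:
    cohort: SimulatedCohort
    adata: ad.AnnData
    causal_type: str
    causal_genes: list
    config: SimulationConfig


def simulate_linked_dataset(
    config: SimulationConfig,
    causal_type: Optional[str] = None,
    extra_causal_types: Sequence[str] = (),
) -> LinkedDataset:
    """Coupled fixture: rare-PTV case enrichment planted in the marker
    genes of one (or more) designated cell types.

    ``config.causal_set`` must be unset; it is derived from the planted
    marker map. ``extra_causal_types`` supports the two-hit variant where
    two disjoint types' markers are both enriched.
    """
    if config.causal_set is not None:
        raise ValueError("causal_set is derived from the marker map; leave it unset")
    marker_map = config.marker_map()
    causal_type = causal_type or config.cell_type_names()[0]
    causal_genes: list[str] = []
    for t in [causal_type, *extra_causal_types]:
        causal_genes.extend(marker_map[t])
    cfg = SimulationConfig(**{**asdict(config), "causal_set": causal_genes})
    cohort = simulate_cohort(cfg)
    adata = simulate_expression(cfg)
    return LinkedDataset(cohort, adata, causal_type, causal_genes, cfg)
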