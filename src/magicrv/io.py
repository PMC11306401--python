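"""Readers and writers for the interchange formats.

VCF v4.2 genotypes (pysam), the tab-separated variant-annotation table,
the sample/design table, GMT gene sets, MatrixMarket sparse expression
with gene/cell registries, deterministic TSV result writing and a JSON
run manifest recording config hash, seeds and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .qc import GenotypeMatrix
from .variants import VariantAnnotation

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "variant_id",
    "consequence",
    "polyphen",
    "sift",
    "cadd_phred",
    "loftee",
    "af_gnomad",
    "af_1kg",
    "af_esp",
    "low_complexity",
    "vqsr_pass",
]


def read_vcf(path) -> GenotypeMatrix:
    """Read a plain or bgzipped VCF v4.2 into a :class:`GenotypeMatrix`.

    Dosages are alternate-allele counts (0/1/2, NaN missing); multi-allelic
    records are split into biallelic variants, one per ALT allele; the
    allele balance of heterozygous calls is derived from FORMAT/AD as
    alt-depth over total depth. Variant ids are ``chrom-pos-ref-alt``.
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    ids, dos_rows, dp_rows, gq_rows, ab_rows = [], [], [], [], []
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            ids.append(f"{rec.chrom}-{rec.pos}-{rec.ref}-{alt}")
            dos = np.full(len(samples), np.nan)
            dp = np.full(len(samples), np.nan)
            gq = np.full(len(samples), np.nan)
            ab = np.full(len(samples), np.nan)
            for si, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                dos[si] = sum(1 for a in gt if a == ai)
                if call.get("DP") is not None:
                    dp[si] = call["DP"]
                if call.get("GQ") is not None:
                    gq[si] = call["GQ"]
                adp = call.get("AD")
                if dos[si] == 1 and adp is not None and None not in adp:
                    tot = sum(adp)
                    if tot > 0:
                        ab[si] = adp[ai] / tot
            dos_rows.append(dos)
            dp_rows.append(dp)
            gq_rows.append(gq)
            ab_rows.append(ab)
    if not ids:
        raise ValueError(f"VCF {path} contains no variant records")
    return GenotypeMatrix(
        np.vstack(dos_rows),
        ids,
        samples,
        dp=np.vstack(dp_rows),
        gq=np.vstack(gq_rows),
        ab=np.vstack(ab_rows),
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF v4.2 (GT only), for simulated data."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, g.sample_ids)) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for vi, vid in enumerate(g.variant_ids):
            chrom, pos, ref, alt = str(vid).split("-")
            calls = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosages[vi]
            ]
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t")
            fh.write("\t".join(calls) + "\n")


def read_annotation_table(path) -> pd.DataFrame:
    """Read the variant-annotation TSV; enforces the required columns and
    unique variant ids; empty numeric cells become NaN, empty categorical
    cells empty strings."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns and c != "variant_id"]
    if "variant_id" not in df.columns:
        missing = ["variant_id"] + missing
    if missing:
        raise ValueError(f"annotation table {path} missing column(s): {missing}")
    if df["variant_id"].duplicated().any():
        dup = df["variant_id"][df["variant_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicated variant_id in {path}: {dup}")
    for col in ("consequence", "polyphen", "sift", "loftee"):
        df[col] = df[col].fillna("").astype(str)
    for col in ("low_complexity", "vqsr_pass"):
        df[col] = df[col].astype(bool)
    return df.set_index("variant_id", drop=False)


def annotation_row_to_record(row: pd.Series) -> VariantAnnotation:
    ref_afs = {
        panel: (None if pd.isna(row[f"af_{panel}"]) else float(row[f"af_{panel}"]))
        for panel in ("gnomad", "1kg", "esp")
        if f"af_{panel}" in row.index
    }
    return VariantAnnotation(
        variant_id=row["variant_id"],
        consequence=row["consequence"],
        gene=row.get("gene"),
        polyphen=row["polyphen"] or None,
        sift=row["sift"] or None,
        cadd_phred=None if pd.isna(row["cadd_phred"]) else float(row["cadd_phred"]),
        loftee=row["loftee"] or None,
        ref_afs=ref_afs,
        low_complexity=bool(row["low_complexity"]),
        vqsr_pass=bool(row["vqsr_pass"]),
    )


def read_design_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise ValueError(f"design table {path} needs sample_id and status columns")
    return df.set_index("sample_id")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def read_expression(mtx_path, genes_path, cells_path) -> ad.AnnData:
    """MatrixMarket counts (genes x cells on disk) plus gene and cell
    registries into an AnnData (cells x genes). The cell table needs
    columns cell, type and optionally x, y embedding coordinates."""
    m = scipy.io.mmread(str(mtx_path)).tocsr()
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    if m.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix {m.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    zero_cells = int((np.ravel(m.sum(axis=0)) == 0).sum())
    if zero_cells:
        logger.warning("read_expression: %d all-zero cells retained", zero_cells)
    obs = pd.DataFrame({"cell_type": cells["type"].astype(str).to_numpy()},
                       index=cells["cell"].astype(str))
    adata = ad.AnnData(
        X=m.T.tocsr(),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes["gene"].astype(str), name="gene")),
    )
    if {"x", "y"} <= set(cells.columns):
        adata.obsm["X_embed"] = cells[["x", "y"]].to_numpy(float)
    return adata


def write_expression(adata: ad.AnnData, outdir) -> None:
    outdir = Path(outdir)
    X = adata.X
    m = sp.coo_matrix(X.T if not sp.issparse(X) else X.T)
    scipy.io.mmwrite(str(outdir / "counts.mtx"), m)
    pd.DataFrame({"gene": adata.var_names}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    cells = pd.DataFrame(
        {"cell": adata.obs_names, "type": adata.obs["cell_type"].astype(str).to_numpy()}
    )
    if "X_embed" in adata.obsm:
        cells["x"] = adata.obsm["X_embed"][:, 0]
        cells["y"] = adata.obsm["X_embed"][:, 1]
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    outdir,
    config: Optional[dict] = None,
    inputs: Optional[list] = None,
    force: bool = False,
) -> None:
    """Write result tables as TSVs plus a run manifest.

    Tables are written with a deterministic column order (as given) after
    a stable sort on all columns is NOT applied — callers own row order,
    which must itself be deterministic. Refuses a non-empty output
    directory unless ``force``. The manifest records the config (and its
    hash, covering every seed), package version and input checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.name != "manifest.json"]
    if existing and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True to overwrite")
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    from . import __version__

    config = config or {}
    manifest = {
        "package": "magicrv",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": {k: v for k, v in config.items() if "seed" in str(k)},
        "inputs": {str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()},
        "tables": sorted(tables),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
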