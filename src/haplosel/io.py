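"""TSV / VCF readers and writers for every table the pipeline exchanges.

All tables are tab-separated with a header row. Genotype panels can also
be written as a minimal VCF (GT field only, diploid unphased, CHROM =
gene id) and read back; VCF reading uses cyvcf2 when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sexlinkage import HET, HOM_ALT, HOM_REF, MISSING, GenotypePanel

__all__ = [
    "write_counts",
    "read_counts",
    "write_table",
    "read_table",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "write_dataset",
    "read_dataset",
]


def write_table(df: pd.DataFrame, path, index: bool = False):
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path):
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_genotypes_tsv(panel: GenotypePanel, prefix):
    """Writes <prefix>.genotypes.tsv (gene_id, pos, one column per
    individual; codes 0/1/2/-1) and <prefix>.individuals.tsv (id, sex)."""
    prefix = str(prefix)
    panel.genotypes.reset_index().to_csv(prefix + ".genotypes.tsv", sep="\t", index=False)
    panel.individuals.to_csv(prefix + ".individuals.tsv", sep="\t", index=False)


def read_genotypes_tsv(prefix) -> GenotypePanel:
    prefix = str(prefix)
    geno = pd.read_csv(prefix + ".genotypes.tsv", sep="\t")
    geno = geno.set_index(["gene_id", "pos"])
    geno = geno.astype(np.int8)
    individuals = pd.read_csv(prefix + ".individuals.tsv", sep="\t")
    return GenotypePanel(individuals=individuals, genotypes=geno)


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_genotypes_vcf(panel: GenotypePanel, path):
    """Minimal VCF 4.2 with GT only; CHROM is the gene id, POS the site."""
    inds = panel.individuals["individual"].tolist()
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds),
    ]
    for (gene, pos), row in panel.genotypes.iterrows():
        gts = "\t".join(_GT_STR[int(row[i])] for i in inds)
        lines.append(f"{gene}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path, sex_by_individual: dict) -> GenotypePanel:
    """Read a GT-only VCF into a panel; sexes come from a separate map."""
    from cyvcf2 import VCF  # heavy optional dependency

    vcf = VCF(str(path), gts012=True)
    inds = list(vcf.samples)
    genes, positions, rows = [], [], []
    for var in vcf:
        genes.append(var.CHROM)
        positions.append(var.POS)
        # gts012: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        codes = np.asarray(var.gt_types, dtype=np.int8)
        codes[codes == 3] = MISSING
        rows.append(codes)
    genotypes = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(inds)), dtype=np.int8),
        index=pd.MultiIndex.from_arrays([genes, positions], names=["gene_id", "pos"]),
        columns=inds,
    )
    individuals = pd.DataFrame(
        {"individual": inds, "sex": [sex_by_individual[i] for i in inds]}
    )
    return GenotypePanel(individuals=individuals, genotypes=genotypes)


def write_dataset(dataset, outdir):
    """Write a SimulatedDataset's tables under a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(dataset.catalog, out / "catalog.tsv")
    write_counts(dataset.counts, out / "counts.tsv")
    write_table(dataset.meta, out / "samples.tsv")
    write_table(dataset.allelic, out / "allelic_counts.tsv")
    if dataset.site_truth is not None:
        write_table(dataset.site_truth, out / "site_truth.tsv")
    for sp, panel in dataset.panels.items():
        write_genotypes_tsv(panel, out / f"panel_{sp}")
    dataset.config.to_file(out / "sim_config.txt")


def read_dataset(indir):
    """Load a dataset directory written by :func:`write_dataset`."""
    from .simulate import SPECIES, SimConfig, SimulatedDataset

    d = Path(indir)
    config = SimConfig.from_file(d / "sim_config.txt")
    panels = {}
    for sp in SPECIES:
        if (d / f"panel_{sp}.genotypes.tsv").exists():
            panels[sp] = read_genotypes_tsv(d / f"panel_{sp}")
    truth_path = d / "site_truth.tsv"
    return SimulatedDataset(
        config=config,
        catalog=read_table(d / "catalog.tsv"),
        counts=read_counts(d / "counts.tsv"),
        meta=read_table(d / "samples.tsv"),
        panels=panels,
        allelic=read_table(d / "allelic_counts.tsv"),
        site_truth=read_table(truth_path) if truth_path.exists() else None,
    )
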