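"""Readers and writers for the pipeline's on-disk formats.

Truth panels travel as VCF 4.2 with phased GT plus a sample-annotation TSV
(sample_id, population, ancestry_group); imputed results as VCF with GT
(best guess), GP (P0,P1,P2) and DS (dosage) FORMAT fields and a TYPED INFO
flag; arrays as two-column chrom/pos TSVs.  Reading goes through pysam;
multiallelic records are skipped with a count, and a truth panel with
unphased genotypes is rejected.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .impute import ImputedDosages
from .simulate import ArrayDefinition, HaplotypePanel

__all__ = [
    "write_panel_vcf",
    "read_panel_vcf",
    "write_samples_tsv",
    "read_samples_tsv",
    "write_imputed_vcf",
    "read_imputed_vcf",
    "write_array_tsv",
    "read_array_tsv",
]

log = logging.getLogger("covpower")

_VCF_HEADER = "##fileformat=VCFv4.2\n"


def _contig_lines(variants: pd.DataFrame) -> str:
    lines = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        lines.append(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
    return "".join(lines)


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write a phased truth panel as uncompressed VCF 4.2."""
    path = Path(path)
    n = panel.n_samples
    haps = panel.haplotypes
    gt_codes = np.array(["0|0", "0|1", "1|0", "1|1"])
    idx = 2 * haps[0::2].astype(np.int64) + haps[1::2]  # (n, L)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(panel.variants))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"])
            + "\n"
        )
        chroms = panel.variants["chrom"].to_numpy()
        poss = panel.variants["pos"].to_numpy()
        vids = panel.variants["variant_id"].to_numpy()
        refs = panel.variants["ref"].to_numpy()
        alts = panel.variants["alt"].to_numpy()
        for j in range(panel.n_variants):
            row = "\t".join(gt_codes[idx[:, j]])
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t{vids[j]}\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{row}\n"
            )


def write_samples_tsv(panel: HaplotypePanel, path) -> None:
    panel.samples.to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "ancestry_group"}
    if not required.issubset(df.columns):
        raise ValueError(f"samples TSV must have columns {sorted(required)}")
    return df


def read_panel_vcf(path, samples_tsv) -> tuple[HaplotypePanel, int]:
    """Read a phased truth panel; returns (panel, n_skipped_multiallelic).

    Unphased genotypes are an error; records that are not biallelic SNVs are
    skipped and counted.
    """
    samples = read_samples_tsv(samples_tsv)
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    if set(samples["sample_id"]) != set(vcf_samples):
        raise ValueError("samples TSV does not match the VCF sample set")
    samples = samples.set_index("sample_id").loc[vcf_samples].reset_index()

    rows = []
    hap_cols = []
    skipped = 0
    for lineno, rec in enumerate(vf, start=1):
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            skipped += 1
            continue
        col = np.empty(2 * len(vcf_samples), dtype=np.uint8)
        for i, s in enumerate(vcf_samples):
            call = rec.samples[s]
            if not call.phased:
                raise ValueError(
                    f"unphased genotype for sample {s} at record {lineno} ({rec.chrom}:{rec.pos})"
                )
            a, b = call["GT"]
            col[2 * i] = a
            col[2 * i + 1] = b
        rows.append(
            (rec.chrom, rec.pos, rec.id or f"{rec.chrom}:{rec.pos}", rec.ref, rec.alts[0])
        )
        hap_cols.append(col)
    vf.close()
    if skipped:
        log.info("read_panel_vcf: skipped %d non-biallelic-SNV records", skipped)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "variant_id", "ref", "alt"])
    panel = HaplotypePanel(
        samples=samples,
        variants=variants,
        haplotypes=np.stack(hap_cols, axis=1) if hap_cols else np.empty((2 * len(vcf_samples), 0), dtype=np.uint8),
    )
    panel.validate()
    return panel, skipped


def write_imputed_vcf(imputed: ImputedDosages, path) -> None:
    """Write imputed results: GT best guess, GP to 4 d.p., DS to 4 d.p., TYPED flag."""
    path = Path(path)
    variants = imputed.variants
    probs = imputed.probs
    bg = np.argmax(probs, axis=2)
    dos = imputed.dosage
    gt_codes = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(variants))
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Variant on the array scaffold">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Most likely genotype">\n')
        fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior P0,P1,P2">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alt dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in imputed.sample_ids)
            + "\n"
        )
        chroms = variants["chrom"].to_numpy()
        poss = variants["pos"].to_numpy()
        vids = variants["variant_id"].to_numpy()
        refs = variants["ref"].to_numpy()
        alts = variants["alt"].to_numpy()
        n = probs.shape[0]
        for j in range(len(variants)):
            info = "TYPED" if imputed.typed[j] else "."
            cells = [
                f"{gt_codes[bg[i, j]]}:{probs[i, j, 0]:.4f},{probs[i, j, 1]:.4f},{probs[i, j, 2]:.4f}:{dos[i, j]:.4f}"
                for i in range(n)
            ]
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t{vids[j]}\t{refs[j]}\t{alts[j]}\t.\tPASS\t{info}\tGT:GP:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_imputed_vcf(path) -> ImputedDosages:
    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    rows = []
    probs_cols = []
    typed = []
    for rec in vf:
        rows.append(
            (rec.chrom, rec.pos, rec.id or f"{rec.chrom}:{rec.pos}", rec.ref, rec.alts[0])
        )
        typed.append("TYPED" in rec.info)
        col = np.empty((len(sample_ids), 3))
        for i, s in enumerate(sample_ids):
            col[i] = rec.samples[s]["GP"]
        probs_cols.append(col)
    vf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "variant_id", "ref", "alt"])
    probs = np.stack(probs_cols, axis=1)  # (n, L, 3)
    probs = probs / probs.sum(axis=2, keepdims=True)  # undo 4-d.p. rounding drift
    return ImputedDosages(
        sample_ids=sample_ids,
        variants=variants,
        probs=probs,
        typed=np.array(typed, dtype=bool),
    )


def write_array_tsv(array: ArrayDefinition, path) -> None:
    df = pd.DataFrame(sorted(array.positions), columns=["chrom", "pos"])
    df.to_csv(path, sep="\t", index=False)


def read_array_tsv(path, name: str | None = None) -> ArrayDefinition:
    """Read a 2-column (chrom, pos) TSV; duplicated positions are dropped with a log line."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64})
    if not {"chrom", "pos"}.issubset(df.columns):
        raise ValueError("array TSV must have columns chrom, pos")
    n0 = len(df)
    df = df.drop_duplicates(["chrom", "pos"])
    if len(df) < n0:
        log.info("read_array_tsv: deduplicated %d positions", n0 - len(df))
    if name is None:
        name = Path(path).stem
    return ArrayDefinition.from_pairs(name, zip(df["chrom"], df["pos"]))
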