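"""VCF readers/writers for panels, genotype calls, likelihoods and dosages.

Writers emit plain-text VCF 4.2; readers go through cyvcf2.  Conventions:
phased panels store two consecutive haplotypes per diploid sample with the
'|' separator; genotype likelihoods use the GL field (log10, normalized);
imputed output carries GT (hard call) and DS (expected alt dosage).
"""

from __future__ import annotations

import numpy as np
from cyvcf2 import VCF

from .genolik import LikelihoodMatrix
from .hmm import DosageVector
from .panel import HaplotypePanel

_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"


def _site_lines(panel: HaplotypePanel):
    for i in range(panel.n_sites):
        yield (
            f"{panel.chrom}\t{panel.positions[i]}\tsite{i}\t"
            f"{panel.ref_alleles[i]}\t{panel.alt_alleles[i]}\t.\tPASS\t"
            f"AF={panel.allele_freq[i]:.6g}"
        )


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write phased panel haplotypes, two per diploid sample (GT '0|1' style)."""
    K = panel.n_haplotypes
    if K % 2:
        raise ValueError("panel must have an even number of haplotypes")
    samples = [f"PANEL{j:04d}" for j in range(K // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel alt allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write(_HEADER + "\t" + "\t".join(samples) + "\n")
        H = panel.haplotypes
        for i, line in enumerate(_site_lines(panel)):
            gts = "\t".join(f"{H[2 * j, i]}|{H[2 * j + 1, i]}" for j in range(K // 2))
            fh.write(f"{line}\tGT\t{gts}\n")


def read_panel_vcf(path, map_cm_per_mb: float = 1.0) -> HaplotypePanel:
    """Read a phased VCF back into a panel; the genetic map is rebuilt as a
    uniform ``map_cm_per_mb`` map (the VCF itself carries no map)."""
    vcf = VCF(str(path))
    positions, ref, alt, haps = [], [], [], []
    for v in vcf:
        gts = np.array(v.genotypes)  # (n_samples, 3): a, b, phased
        if not gts[:, 2].all():
            raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
        positions.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        haps.append(gts[:, :2].reshape(-1))
    chrom = v.CHROM
    positions = np.asarray(positions)
    return HaplotypePanel(
        positions=positions,
        cm_positions=positions * (map_cm_per_mb / 1e6),
        haplotypes=np.asarray(haps, dtype=np.uint8).T,
        ref_alleles=np.asarray(ref),
        alt_alleles=np.asarray(alt),
        chrom=chrom,
    )


def _gt_string(g: float) -> str:
    if np.isnan(g):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(g)]


def write_genotype_vcf(panel: HaplotypePanel, genotypes: dict[str, np.ndarray], path) -> None:
    """Write hard genotype vectors (values in {0,1,2}, NaN = missing) as GT."""
    samples = list(genotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel alt allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(_HEADER + "\t" + "\t".join(samples) + "\n")
        for i, line in enumerate(_site_lines(panel)):
            gts = "\t".join(_gt_string(genotypes[s][i]) for s in samples)
            fh.write(f"{line}\tGT\t{gts}\n")


def read_genotype_vcf(path) -> dict[str, np.ndarray]:
    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for v in vcf:
        gts = np.array(v.genotypes)[:, :2].astype(np.float64)
        gts[gts < 0] = np.nan
        rows.append(gts.sum(axis=1))
    out = np.asarray(rows)
    return {s: out[:, j] for j, s in enumerate(samples)}


def write_likelihood_vcf(
    panel: HaplotypePanel, lik: LikelihoodMatrix, path, sample: str = "SAMPLE"
) -> None:
    """Forced-genotyping output: per-site GL (log10 of the normalized triple,
    shifted so the maximum is 0) plus DP; GT left missing (no call made)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel alt allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(_HEADER + f"\t{sample}\n")
        with np.errstate(divide="ignore"):
            gl = np.log10(np.maximum(lik.lik, 1e-300))
        gl = gl - gl.max(axis=1, keepdims=True)
        for i, line in enumerate(_site_lines(panel)):
            triple = ",".join(f"{gl[i, g]:.4f}" for g in range(3))
            fh.write(f"{line}\tGT:GL:DP\t./.:{triple}:{int(lik.depth[i])}\n")


def read_likelihood_vcf(path) -> LikelihoodMatrix:
    vcf = VCF(str(path))
    gl_rows, dp_rows = [], []
    for v in vcf:
        gl_rows.append(v.format("GL")[0])
        dp_rows.append(v.format("DP")[0][0])
    lik = np.power(10.0, np.asarray(gl_rows, dtype=np.float64))
    lik /= lik.sum(axis=1, keepdims=True)
    return LikelihoodMatrix(lik=lik, depth=np.asarray(dp_rows, dtype=np.int64))


def write_imputed_vcf(
    panel: HaplotypePanel, dosages: DosageVector, path, sample: str = "SAMPLE"
) -> None:
    """Imputed output: GT = argmax posterior genotype, DS = expected dosage."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel alt allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed alt dosage">\n')
        fh.write(_HEADER + f"\t{sample}\n")
        for i, line in enumerate(_site_lines(panel)):
            fh.write(
                f"{line}\tGT:DS\t{_gt_string(float(dosages.hard_genotype[i]))}:"
                f"{dosages.dosage[i]:.4f}\n"
            )


def read_dosage_vcf(path) -> np.ndarray:
    """Read the DS field of a single-sample imputed VCF."""
    vcf = VCF(str(path))
    return np.array([float(v.format("DS")[0][0]) for v in vcf])
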