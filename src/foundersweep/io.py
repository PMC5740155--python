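"""File I/O: VCF 4.2, BED6/GFF3 gene annotations, TSV matrices.

VCF reading goes through cyvcf2; writing emits minimal VCF 4.2 text
(one biallelic SNP per record, QUAL and INFO/DP populated, unphased GT).
Window statistics, null thresholds, spectra and scan results are plain
TSV so every artefact of a run is diffable text.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeTable, JointSFS, Site, WindowStats

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_genes",
    "read_go_annotation",
    "write_window_stats",
    "write_joint_sfs",
    "read_joint_sfs",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_vcf(path: str | Path, popmap: dict[str, str] | None = None) -> GenotypeTable:
    """Read a VCF into a GenotypeTable.

    ``popmap`` maps sample name -> population id; unmapped samples (or
    all samples when popmap is None) go to population "pop1".  QUAL and
    INFO/DP are consumed; multi-allelic records are kept (with missing
    genotypes) so the biallelic filter can count them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    populations: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        pop = (popmap or {}).get(s, "pop1")
        populations.setdefault(pop, []).append(i)
    sites: list[Site] = []
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else "."
        if len(v.ALT or []) == 1:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            g = np.array(
                [{0: 0, 1: 1, 3: 2, 2: MISSING}[int(t)] for t in v.gt_types],
                dtype=np.int8,
            )
        else:
            g = np.full(len(samples), MISSING, dtype=np.int8)
        dp = v.INFO.get("DP")
        sites.append(
            Site(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                depth=float(dp) if dp is not None else 0.0,
                genotypes=g,
            )
        )
    vcf.close()
    return GenotypeTable(sites=sites, samples=samples, populations=populations)


def write_vcf(table: GenotypeTable, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a GenotypeTable as VCF 4.2 text (unphased GT, INFO/DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_lines or []:
            fh.write(f"##{line}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Float,Description="Mean sample depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in table.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for s in table.sites:
            gts = "\t".join(_GT.get(int(g), "./.") for g in s.genotypes)
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{s.qual:g}\t.\t"
                f"DP={s.depth:g}\tGT\t{gts}\n"
            )


def read_genes(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED6 (0-based half-open) or GFF3 (1-based).

    Returns columns chrom, start, end (0-based half-open), gene_id.
    GFF3 rows of type "gene" are used; the gene id comes from the ID=
    attribute.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                rows.append(
                    {
                        "chrom": f[0],
                        "start": int(f[3]) - 1,
                        "end": int(f[4]),
                        "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}"),
                    }
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
    )
    return df


def read_go_annotation(path: str | Path) -> pd.DataFrame:
    """gene_id <tab> term_id pairs, one per line, optional header."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_id", "term_id"])
    if df.iloc[0, 0] in ("gene_id", "gene"):
        df = df.iloc[1:].reset_index(drop=True)
    return df


def write_window_stats(
    stats: list[WindowStats], path: str | Path, header_comment: str | None = None
) -> None:
    """TSV: chrom, start, end (1-based inclusive output), callable, S,
    pi_10kb, theta_10kb, tajima_d, fst."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("chrom\tstart\tend\tcallable\tS\tpi_10kb\ttheta_10kb\ttajima_d\tfst\n")
        for ws in stats:
            w = ws.window
            d = "NA" if ws.tajima_d is None else f"{ws.tajima_d:.6g}"
            f = "NA" if ws.fst is None else f"{ws.fst:.6g}"
            fh.write(
                f"{w.chrom}\t{w.start + 1}\t{w.end}\t{w.callable_sites}\t{ws.S}\t"
                f"{ws.pi_10kb:.6g}\t{ws.theta_w_10kb:.6g}\t{d}\t{f}\n"
            )


def write_joint_sfs(sfs: JointSFS, path: str | Path) -> None:
    """Dense matrix TSV with a trailing mask block (1 = masked)."""
    with open(path, "w") as fh:
        fh.write(f"# joint SFS folded={int(sfs.folded)} shape={sfs.data.shape}\n")
        np.savetxt(fh, sfs.data, delimiter="\t", fmt="%.10g")
        fh.write("# mask\n")
        np.savetxt(fh, sfs.mask.astype(int), delimiter="\t", fmt="%d")


def read_joint_sfs(path: str | Path) -> JointSFS:
    text = Path(path).read_text().splitlines()
    folded = "folded=1" in text[0]
    split = text.index("# mask")
    data = np.loadtxt(_io.StringIO("\n".join(text[1:split])), delimiter="\t")
    mask = np.loadtxt(_io.StringIO("\n".join(text[split + 1:])), delimiter="\t")
    return JointSFS(data, mask.astype(bool), folded=folded)
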