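"""Readers and writers for the plain-text interchange formats.

Phased VCF (written here, read back through :func:`dmbtkit.selscan.read_phased_vcf`),
PED-like pedigree tables, tab-separated copy-number and isoform tables, BED
repeat-unit annotations, GFF3/BED12 transcript exon chains, and a flat
``key = value`` simulation-config format.
"""

from __future__ import annotations

import ast
from dataclasses import fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from .selscan import HaplotypeMatrix
from .synthdata import SimConfig
from .txrepeats import RepeatAnnotation, TranscriptAlignment


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def write_phased_vcf(hapmat: HaplotypeMatrix, path: str | Path,
                     contig_length: int | None = None) -> None:
    """Write a haplotype matrix as a phased VCF (GT with '|').

    Haplotype rows are paired in order into diploid samples; ids of the form
    ``name|0`` / ``name|1`` collapse to ``name``.  REF/ALT are the
    placeholder alleles A/C.
    """
    if hapmat.n_hap % 2:
        raise ValueError("need an even number of haplotypes to form samples")
    samples = []
    for i in range(0, hapmat.n_hap, 2):
        hid = hapmat.haplotype_ids[i]
        samples.append(hid.rsplit("|", 1)[0] if "|" in hid else f"S{i // 2}")
    if contig_length is None:
        contig_length = int(hapmat.positions[-1]) + 1000 if hapmat.n_sites else 1000
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hapmat.chrom},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(hapmat.n_sites):
            gts = "\t".join(
                f"{hapmat.alleles[2 * i, j]}|{hapmat.alleles[2 * i + 1, j]}"
                for i in range(len(samples)))
            fh.write(f"{hapmat.chrom}\t{hapmat.positions[j]}\t.\tA\tC\t.\tPASS"
                     f"\t.\tGT\t{gts}\n")


# --------------------------------------------------------------------------
# Tabular formats
# --------------------------------------------------------------------------

def write_ped(pedigree: pd.DataFrame, path: str | Path) -> None:
    """family, individual, father, mother, sex — tab-separated, '0' = founder."""
    pedigree[["family", "individual", "father", "mother", "sex"]].to_csv(
        path, sep="\t", index=False)


def read_ped(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "individual": str,
                                            "father": str, "mother": str})
    return df


def write_cn_table(observations: pd.DataFrame, path: str | Path) -> None:
    observations.to_csv(path, sep="\t", index=False)


def read_cn_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual": str})


def write_tag_phase(tag_phase: pd.DataFrame, path: str | Path) -> None:
    tag_phase.to_csv(path, sep="\t", index=False)


def write_transmissions(transmissions: pd.DataFrame, path: str | Path) -> None:
    transmissions.to_csv(path, sep="\t", index=False)


def read_transmissions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_tag_phase(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_isoform_table(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_isoform_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "bands": str,
                                              "secretor": str})


# --------------------------------------------------------------------------
# Repeat units and exon chains
# --------------------------------------------------------------------------

def write_bed_units(ann: RepeatAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(ann.units):
            fh.write(f"{ann.contig}\t{s}\t{e}\tunit{i + 1}\t0\t{ann.strand}\n")


def read_bed_units(path: str | Path) -> RepeatAnnotation:
    units, contig, strand = [], None, "+"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig = parts[0]
            units.append((int(parts[1]), int(parts[2])))
            if len(parts) >= 6:
                strand = parts[5]
    if contig is None:
        raise ValueError(f"no intervals in {path}")
    return RepeatAnnotation(contig=contig, units=units, strand=strand)


def write_transcripts_gff3(reads: Sequence[TranscriptAlignment],
                           path: str | Path) -> None:
    """One mRNA feature per read, exons as children; mappable-end flags in
    the mRNA attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in reads:
            if not r.exons:
                continue
            start = r.exons[0][0] + 1
            end = r.exons[-1][1]
            attrs = (f"ID={r.transcript_id};five_prime_mappable="
                     f"{str(r.five_prime_mappable).lower()};"
                     f"three_prime_mappable={str(r.three_prime_mappable).lower()}")
            fh.write(f"{r.contig}\ttx\tmRNA\t{start}\t{end}\t.\t+\t.\t{attrs}\n")
            for i, (s, e) in enumerate(r.exons):
                fh.write(f"{r.contig}\ttx\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                         f"ID={r.transcript_id}.exon{i + 1};"
                         f"Parent={r.transcript_id}\n")


def read_transcripts_gff3(path: str | Path) -> list[TranscriptAlignment]:
    flags: dict[str, tuple[bool, bool]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    contigs: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            contig, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            if ftype == "mRNA":
                tid = attrs["ID"]
                order.append(tid)
                contigs[tid] = contig
                flags[tid] = (attrs.get("five_prime_mappable", "true") == "true",
                              attrs.get("three_prime_mappable", "true") == "true")
                exons.setdefault(tid, [])
            elif ftype == "exon":
                tid = attrs["Parent"]
                contigs.setdefault(tid, contig)
                exons.setdefault(tid, []).append((int(start) - 1, int(end)))
                if tid not in order:
                    order.append(tid)
    return [TranscriptAlignment(transcript_id=tid, contig=contigs[tid],
                                exons=exons[tid],
                                five_prime_mappable=flags.get(tid, (True, True))[0],
                                three_prime_mappable=flags.get(tid, (True, True))[1])
            for tid in order if exons.get(tid)]


def read_transcripts_bed12(path: str | Path) -> list[TranscriptAlignment]:
    """Exon chains from BED12 blocks; both mappable-end flags default true."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, name = p[0], int(p[1]), p[3]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            starts = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + off, start + off + sz)
                     for off, sz in zip(starts, sizes)]
            reads.append(TranscriptAlignment(transcript_id=name, contig=chrom,
                                             exons=exons))
    return reads


# --------------------------------------------------------------------------
# Simulation config as key = value text
# --------------------------------------------------------------------------

def write_sim_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)!r}\n")


def read_sim_config(path: str | Path) -> SimConfig:
    """Parse ``key = value`` lines; values are Python literals."""
    known = {f.name: f for f in fields(SimConfig)}
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = ast.literal_eval(value)
    return SimConfig(**kwargs)
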