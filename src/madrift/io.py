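"""Readers and writers for the interchange formats.

Genomes travel as FASTA (one record per chromosome tag), mutations and calls
as VCF v4.2, pileups and trait panels as TSV, and likelihood fits as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import MutationCall, PileupTable
from .drift import NeFit
from .simulate import Genome, TraitPanel, TrueMutation

__all__ = [
    "write_genome_fasta",
    "read_genome_fasta",
    "write_true_mutations_vcf",
    "read_true_mutations_vcf",
    "write_calls_vcf",
    "read_calls_vcf",
    "write_pileups_tsv",
    "read_pileups_tsv",
    "write_trait_panel_tsv",
    "read_trait_panel_tsv",
    "write_nefit_json",
    "read_nefit_json",
]


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    records = []
    if genome.x_length:
        records.append(SeqRecord(Seq(genome.sequence[: genome.x_length]), id="X", description=""))
    records.append(SeqRecord(Seq(genome.sequence[genome.x_length :]), id="A", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> Genome:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    x = seqs.get("X", "")
    a = seqs.get("A", "")
    return Genome(sequence=x + a, x_length=len(x))


def _vcf_header(genome: Genome, info_lines: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if genome.x_length:
        header.contigs.add("X", length=genome.x_length)
    header.contigs.add("A", length=len(genome.sequence) - genome.x_length)
    for line in info_lines:
        header.add_line(line)
    return header


def write_true_mutations_vcf(
    mutations: dict[str, list[TrueMutation]], genome: Genome, path: str | Path, t: int
) -> None:
    """Ground-truth mutations with INFO LINE, GEN (origin) and AF at G``t``."""
    header = _vcf_header(
        genome,
        [
            '##INFO=<ID=LINE,Number=1,Type=String,Description="MA line">',
            '##INFO=<ID=GEN,Number=1,Type=Integer,Description="Origin generation">',
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Mutant frequency at sequencing generation">',
        ],
    )
    recs = []
    for line_id in sorted(mutations):
        for m in mutations[line_id]:
            chrom, cpos = genome.chrom_pos(m.position - 1)
            recs.append((chrom, cpos, m))
    recs.sort(key=lambda r: (r[0], r[1]))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, cpos, m in recs:
            rec = vcf.new_record(
                contig=chrom, start=cpos - 1, alleles=(m.ancestral, m.mutant)
            )
            rec.info["LINE"] = m.line_id
            rec.info["GEN"] = m.origin_generation
            rec.info["AF"] = (m.freq_at(t),)
            vcf.write(rec)


def read_true_mutations_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append(
                (
                    rec.info["LINE"],
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alts[0],
                    rec.info["GEN"],
                    float(rec.info["AF"][0]),
                )
            )
    return pd.DataFrame(
        rows, columns=["line_id", "chrom", "pos", "ancestral", "mutant", "origin_generation", "af"]
    )


def write_calls_vcf(calls: list[MutationCall], genome: Genome, path: str | Path) -> None:
    """Called mutations with INFO LINE, AF, CLASS and a TITV flag for SBS."""
    from .calling import _sbs_change, _TRANSITIONS

    header = _vcf_header(
        genome,
        [
            '##INFO=<ID=LINE,Number=1,Type=String,Description="Mutant MA line">',
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Mutant read frequency in the mutant line">',
            '##INFO=<ID=CLASS,Number=1,Type=String,Description="SBS/MBS/INS/DEL/COMPLEX">',
            '##INFO=<ID=TITV,Number=1,Type=String,Description="Ti or Tv for SBS calls">',
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.line_id)):
            rec = vcf.new_record(
                contig=call.chrom, start=call.pos - 1, alleles=(call.ancestral, call.mutant)
            )
            rec.info["LINE"] = call.line_id
            rec.info["AF"] = (call.frequency,)
            rec.info["CLASS"] = call.mclass
            if call.mclass == "SBS":
                rec.info["TITV"] = "Ti" if _sbs_change(call) in _TRANSITIONS else "Tv"
            vcf.write(rec)


def read_calls_vcf(path: str | Path) -> list[MutationCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            calls.append(
                MutationCall(
                    line_id=rec.info["LINE"],
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ancestral=rec.ref,
                    mutant=rec.alts[0],
                    frequency=float(rec.info["AF"][0]),
                    mclass=rec.info["CLASS"],
                )
            )
    return calls


def write_pileups_tsv(pileups: PileupTable, path: str | Path) -> None:
    df = pileups.data.copy()
    df.insert(0, "parental", (df["line_id"] == pileups.parental_id).map({True: 1, False: 0}))
    df.to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path: str | Path, parental_id: str | None = None) -> PileupTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str, "strand": str})
    if parental_id is None:
        if "parental" not in df.columns:
            raise ValueError("no parental column and no parental_id given")
        parents = df.loc[df["parental"] == 1, "line_id"].unique()
        if len(parents) != 1:
            raise ValueError("exactly one parental line required")
        parental_id = parents[0]
    return PileupTable(df.drop(columns=["parental"], errors="ignore"), parental_id=parental_id)


def write_trait_panel_tsv(panel: TraitPanel, path: str | Path) -> None:
    df = panel.data.copy()
    df.insert(0, "trait", panel.trait)
    df.insert(1, "sex", panel.sex)
    df["pool_n"] = panel.pool_n
    df.to_csv(path, sep="\t", index=False)


def read_trait_panel_tsv(path: str | Path) -> list[TraitPanel]:
    df = pd.read_csv(path, sep="\t")
    panels = []
    for (trait, sex), sub in df.groupby(["trait", "sex"], sort=True):
        pool_n = int(sub["pool_n"].iloc[0]) if "pool_n" in sub.columns else 1
        panels.append(
            TraitPanel(
                trait=trait, sex=sex,
                data=sub[["line", "replicate", "value"]].reset_index(drop=True),
                pool_n=pool_n,
            )
        )
    return panels


def write_nefit_json(fit: NeFit, path: str | Path) -> None:
    payload = {
        "grid": [int(g) for g in fit.grid],
        "logliks": [float(x) for x in fit.logliks],
        "bin_probs": [[float(p) for p in row] for row in fit.bin_probs],
        "ml_two_ne": fit.ml_two_ne,
        "p_detect": fit.p_detect,
        "reps": fit.reps,
        "t": fit.t,
        "seed": fit.seed,
        "impossible": fit.impossible,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_nefit_json(path: str | Path) -> NeFit:
    d = json.loads(Path(path).read_text())
    return NeFit(
        grid=np.asarray(d["grid"], dtype=np.int64),
        logliks=np.asarray(d["logliks"], dtype=np.float64),
        bin_probs=np.asarray(d["bin_probs"], dtype=np.float64),
        ml_two_ne=int(d["ml_two_ne"]),
        p_detect=float(d["p_detect"]),
        reps=int(d["reps"]),
        t=int(d["t"]),
        seed=int(d["seed"]),
        impossible=bool(d["impossible"]),
    )
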