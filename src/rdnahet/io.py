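"""Plain-text I/O: FASTA/FASTQ, minimal VCF v4.2, newick, TSV, YAML configs.

Every intermediate artifact of the pipeline is plain text so the full
workflow remains inspectable with standard tools.
"""

from __future__ import annotations

import os
from typing import Iterable

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import FILTER_PASS, VariantTable
from .errors import FastaParseError
from .sequencing import ReadSet

_IUPAC = set("ACGTUMRWSYKVHDBN-")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs, rejecting non-IUPAC residues with the
    offending line number."""
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    bad = [
        (rid, {c for c in seq if c not in _IUPAC})
        for rid, seq in records
        if set(seq) - _IUPAC
    ]
    if bad:
        rid, chars = bad[0]
        line = _find_bad_line(path, chars)
        raise FastaParseError(
            f"non-IUPAC residue(s) {sorted(chars)} in record {rid!r}", line=line
        )
    return records


def _find_bad_line(path, chars: set[str]) -> int | None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & chars:
                return lineno
    return None


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def write_fastq(
    readset: ReadSet, path: str | os.PathLike, quality: int = 30
) -> None:
    """Reads as FASTQ with a constant phred quality."""
    with open(path, "w") as handle:
        for read in readset.reads:
            records = SeqRecord(
                Seq(read.sequence),
                id=read.read_id,
                description=f"strand={read.strand} run={read.run_id}",
            )
            records.letter_annotations["phred_quality"] = [quality] * len(
                read.sequence
            )
            SeqIO.write(records, handle, "fastq")


def write_vcf(
    table: VariantTable,
    path: str | os.PathLike,
    contig_id: str = "rDNA_unit",
    contig_length: int | None = None,
    reference: str | None = None,
) -> None:
    """Minimal VCF v4.2: INFO fields DP, QD, FS, AF, METHOD, RUN; the FILTER
    column mirrors the hard-filter status.

    Indels are emitted with the conventional anchor-base representation when
    the reference sequence is supplied; without it the anchor base is 'N'.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=rdnahet",
    ]
    if contig_length:
        lines.append(f"##contig=<ID={contig_id},length={contig_length}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency">',
        '##INFO=<ID=METHOD,Number=1,Type=String,Description="Detection method">',
        '##INFO=<ID=RUN,Number=1,Type=String,Description="Sequencing run">',
        '##FILTER=<ID=fail_depth,Description="Depth below cutoff">',
        '##FILTER=<ID=fail_qual,Description="QUAL below 30">',
        '##FILTER=<ID=fail_qd,Description="QD below 2">',
        '##FILTER=<ID=fail_fs,Description="FS above 200">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for call in table.calls:
        if call.alt_allele == "-":  # deletion: anchored on the previous base
            pos = max(call.position - 1, 1)
            anchor = (
                reference[pos - 1] if reference and call.position > 1 else "N"
            )
            ref = anchor + call.ref_base
            alt = anchor
        elif call.alt_allele.startswith("+"):
            pos = call.position
            ref = call.ref_base or "N"
            alt = ref + call.alt_allele[1:]
        else:
            pos = call.position
            ref = call.ref_base
            alt = call.alt_allele
        filt = "PASS" if call.filter_status == FILTER_PASS else call.filter_status
        info = (
            f"DP={call.depth};QD={call.qd:.2f};FS={call.fs:.2f};"
            f"AF={call.frequency:.4f};METHOD={call.method};"
            f"RUN={call.run_id or '.'}"
        )
        lines.append(
            f"{contig_id}\t{pos}\t.\t{ref}\t{alt}\t{call.qual:.1f}\t{filt}\t{info}"
        )
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tsv(df, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def save_config(config: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=False)


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)
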