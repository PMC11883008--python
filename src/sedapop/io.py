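"""FASTA/FASTQ input and output via Biopython."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readmap import ReadRecord, PHRED_OFFSET


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path, sample_id: str = "", mate: int = 0) -> list[ReadRecord]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            reads.append(
                ReadRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities="".join(chr(q + PHRED_OFFSET) for q in quals),
                    sample_id=sample_id,
                    mate=mate,
                )
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record near index {len(reads)} in {path}: {exc}") from exc
    return reads


def write_fastq(reads: list[ReadRecord], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [q - 0 for q in (r.phred.tolist())]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def reads_by_key(reads: list[ReadRecord]) -> dict[tuple[str, int], ReadRecord]:
    """Index reads by (id, mate) for alignment-side lookups."""
    return {(r.id, r.mate): r for r in reads}
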