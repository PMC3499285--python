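"""Standard-format I/O: FASTA, GFF3 and delimited reports.

FASTA goes through Biopython; GFF3 is written 1-based inclusive with
gene/exon features and read back into plain records.  Everything the
pipeline writes can be re-read by the functions here (round-trip safe).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import GeneModel


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(models: Sequence[Tuple[str, GeneModel]], path) -> None:
    """Write gene models as GFF3 (1-based inclusive, gene + exon rows)."""
    lines = ["##gff-version 3"]
    for name, m in models:
        if not m.exons:
            continue
        lo = min(s for s, _ in m.exons)
        hi = max(e for _, e in m.exons)
        attrs = f"ID={name};classification={m.classification}"
        lines.append(
            f"{m.contig_id}\tdefmine\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}"
        )
        for k, ((s, e), phase) in enumerate(zip(m.exons, m.phases), start=1):
            lines.append(
                f"{m.contig_id}\tdefmine\texon\t{min(s, e)}\t{max(s, e)}\t.\t"
                f"{m.strand}\t{phase % 3}\tID={name}.exon{k};Parent={name}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> List[dict]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, source, ftype, start, end, score, strand, phase, attrs = line.split("\t")
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        out.append(
            dict(
                seqid=seqid, type=ftype, start=int(start), end=int(end),
                strand=strand, phase=phase, attributes=fields,
            )
        )
    return out
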