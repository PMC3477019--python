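"""Sequence and annotation I/O, promoter extraction, and sequence quality control.

Promoter regions follow the convention used throughout the toolkit: 1500 nt
upstream of the transcription start site plus the first 500 nt of the gene
(exon 1 included), reported 5'->3' on the gene's coding strand.  All internal
coordinates are 0-based half-open on the forward chromosome strand; GFF3
(1-based inclusive) and BED (0-based half-open) are converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = set("ACGTN-")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(s: str) -> str:
    """Reverse complement over the {A,C,G,T,N,-} alphabet."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, optionally tagged with its species."""

    id: str
    residues: str
    species: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval in 0-based half-open chromosome coordinates.

    ``tss`` is the 5' end of the interval: ``start`` on the + strand and
    ``end - 1`` on the - strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PromoterRegion:
    """Promoter residues around a TSS, 5'->3' on the coding strand.

    ``tss_offset`` indexes the TSS base within ``residues`` and equals the
    (possibly truncated) upstream length.
    """

    gene_id: str
    residues: str
    upstream_len: int
    downstream_len: int
    tss_offset: int
    truncated: bool = False


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path_or_handle: Union[str, TextIO]) -> list[SequenceRecord]:
    """Read a multi-FASTA file; residues are uppercased (soft-masking dropped)."""
    records = []
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids in FASTA: {dup}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path_or_handle: Union[str, TextIO]) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            SeqIO.write(bio, fh, "fasta")
    else:
        SeqIO.write(bio, path_or_handle, "fasta")


# ---------------------------------------------------------------------------
# Annotations

def parse_annotations(path_or_handle: Union[str, TextIO], dialect: str) -> list[GeneAnnotation]:
    """Parse gene annotations from GFF3 or 6-column BED.

    GFF3 coordinates (1-based inclusive) and BED coordinates (0-based
    half-open) are both converted to the internal 0-based half-open
    convention.  Input order is preserved.  Malformed lines raise
    ``ValueError`` naming the offending line number.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if isinstance(path_or_handle, str):
        handle: TextIO = open(path_or_handle)
        close = True
    else:
        handle, close = path_or_handle, False
    try:
        out: list[GeneAnnotation] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (dialect == "bed" and line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated columns")
                    chrom, _source, _type, start_s, end_s, _score, strand, _phase, attrs = fields[:9]
                    start = int(start_s) - 1  # 1-based inclusive -> 0-based
                    end = int(end_s)
                    gene_id = _gff3_id(attrs)
                else:
                    if len(fields) < 6:
                        raise ValueError("expected 6 tab-separated columns")
                    chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
                    start = int(start_s)
                    end = int(end_s)
                if strand not in "+-":
                    raise ValueError(f"unknown strand symbol {strand!r}")
                out.append(GeneAnnotation(gene_id=gene_id, chromosome=chrom,
                                          strand=strand, start=start, end=end))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
        return out
    finally:
        if close:
            handle.close()


def _gff3_id(attrs: str) -> str:
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith("ID="):
            return kv[3:]
        if kv.startswith("gene_id="):
            return kv[8:]
    raise ValueError("no ID= attribute in GFF3 column 9")


def write_gff3(genes: Iterable[GeneAnnotation], path: str, feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tcoregscan\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Promoter extraction

def extract_promoter(
    genome: Union[dict, Sequence[SequenceRecord]],
    gene: GeneAnnotation,
    upstream_len: int = 1500,
    downstream_len: int = 500,
) -> PromoterRegion:
    """Extract the promoter window around a gene's TSS.

    On the + strand the window is ``[tss - upstream_len, tss + downstream_len)``
    on the forward chromosome; on the - strand it is the mirror-image window
    reverse-complemented, so residues always read 5'->3' on the coding strand.
    Windows reaching past a chromosome edge are truncated and flagged, never
    an error.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r for r in genome}
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not present in genome")
    chrom = genome[gene.chromosome].residues
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - upstream_len, tss + downstream_len
    else:
        # mirror image: upstream lies at higher coordinates
        lo, hi = tss + 1 - downstream_len, tss + 1 + upstream_len
    clipped_lo, clipped_hi = max(lo, 0), min(hi, len(chrom))
    truncated = (clipped_lo != lo) or (clipped_hi != hi)
    seq = chrom[clipped_lo:clipped_hi]
    if gene.strand == "+":
        eff_up = tss - clipped_lo
        eff_down = clipped_hi - tss
    else:
        seq = reverse_complement(seq)
        eff_up = clipped_hi - (tss + 1)
        eff_down = tss + 1 - clipped_lo
    return PromoterRegion(
        gene_id=gene.gene_id,
        residues=seq,
        upstream_len=eff_up,
        downstream_len=eff_down,
        tss_offset=eff_up,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Quality control

@dataclass
class Discard:
    record: SequenceRecord
    reason: str


def qc_filter_sequences(
    seqs: Sequence[SequenceRecord],
    max_unknown_frac: float = 0.10,
    drop_gapped: bool = True,
    region: Optional[tuple[int, int]] = None,
) -> tuple[list[SequenceRecord], list[Discard]]:
    """Partition sequences into (kept, discarded-with-reason).

    A sequence is discarded iff it contains a gap character (when
    ``drop_gapped``) or its N fraction over the assessed region *strictly*
    exceeds ``max_unknown_frac``; a sequence sitting exactly on the threshold
    is kept.  ``region`` restricts the fraction computation to a slice of the
    sequence (e.g. the promoter part).
    """
    if not 0 <= max_unknown_frac <= 1:
        raise ValueError("max_unknown_frac must lie in [0, 1]")
    kept: list[SequenceRecord] = []
    discarded: list[Discard] = []
    for rec in seqs:
        if drop_gapped and "-" in rec.residues:
            discarded.append(Discard(rec, "gap"))
            continue
        assessed = rec.residues if region is None else rec.residues[region[0]:region[1]]
        n_frac = assessed.count("N") / len(assessed) if assessed else 0.0
        if n_frac > max_unknown_frac:
            discarded.append(Discard(rec, "unknown-fraction"))
        else:
            kept.append(rec)
    return kept, discarded


def write_discard_report(discarded: Iterable[Discard], path_or_handle: Union[str, TextIO]) -> None:
    """Write the discard report as a two-column TSV (id, reason)."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_discard_report(discarded, fh)
        return
    for d in discarded:
        path_or_handle.write(f"{d.record.id}\t{d.reason}\n")
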