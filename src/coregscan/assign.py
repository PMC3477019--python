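"""Clone-to-chromosome mapping of model hits and candidate gene selection.

Model hits are found in clones (contigs) whose placement on the chromosome is
known: start ``x``, end ``y``, and orientation.  The chromosomal anchor
coordinate ``a'`` of a hit at clone offset ``a``, the far bound ``z`` of the
TSS search window (W = 2000 nt by default), and the resulting chromosomal
model strand follow four orientation cases, keyed by
(model-in-clone, clone-on-chromosome, chromosomal-model) signs:

    A (+/+/+): a' = x + a,  z = a' + W
    B (-/+/-): a' = x + a,  z = a' - W
    C (-/-/+): a' = y - a,  z = a' + W
    D (+/-/-): a' = y - a,  z = a' - W

The chromosomal strand is the product of the model and clone signs.  Within
the [a', z] window, a gene is retained when it lies directly downstream of the
model on the same strand, its TSS at most ``max_tss_distance`` (default 500
nt) past the model's 3' end, or overlapping the model by at most
``max_overlap`` (default 200 nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

from .models import ModelHit
from .seqio import GeneAnnotation

DEFAULT_WINDOW = 2000
DEFAULT_MAX_TSS_DISTANCE = 500
DEFAULT_MAX_OVERLAP = 200

CASES = {
    # (model_orientation, clone_strand) -> (case, chrom_strand)
    ("+", "+"): ("A", "+"),
    ("-", "+"): ("B", "-"),
    ("-", "-"): ("C", "+"),
    ("+", "-"): ("D", "-"),
}


@dataclass(frozen=True)
class CloneMapping:
    """A clone/contig placed on the chromosome: [x, y), oriented."""

    clone_id: str
    chromosome: str
    x: int
    y: int
    clone_strand: str

    def __post_init__(self) -> None:
        if not self.x < self.y:
            raise ValueError(f"clone {self.clone_id!r}: x must be < y")
        if self.clone_strand not in "+-":
            raise ValueError(f"clone {self.clone_id!r}: bad strand {self.clone_strand!r}")

    @property
    def length(self) -> int:
        return self.y - self.x


@dataclass
class MappedHit:
    """A model hit lifted to chromosomal coordinates."""

    hit: ModelHit
    clone: CloneMapping
    case: str
    a: int              # model offset within the clone
    a_prime: int        # chromosomal anchor (model 5' side)
    z: int              # far bound of the TSS search window
    chrom_strand: str
    span: int           # model span in nt

    @property
    def chromosome(self) -> str:
        return self.clone.chromosome

    @property
    def model_3prime(self) -> int:
        """Chromosomal coordinate of the model's 3' end in reading direction."""
        return self.a_prime + self.span if self.chrom_strand == "+" else self.a_prime - self.span


def map_hit_to_chromosome(
    hit: ModelHit,
    clone: CloneMapping,
    window: int = DEFAULT_WINDOW,
) -> MappedHit:
    """Lift a clone-frame model hit onto the chromosome (cases A-D above)."""
    a = hit.start
    span = hit.end - hit.start
    if a + span > clone.length:
        raise ValueError(
            f"hit [{hit.start}, {hit.end}) extends past clone {clone.clone_id!r} "
            f"of length {clone.length}"
        )
    case, chrom_strand = CASES[(hit.orientation, clone.clone_strand)]
    if clone.clone_strand == "+":
        a_prime = clone.x + a
    else:
        a_prime = clone.y - a
    z = a_prime + window if chrom_strand == "+" else a_prime - window
    return MappedHit(hit=hit, clone=clone, case=case, a=a, a_prime=a_prime,
                     z=z, chrom_strand=chrom_strand, span=span)


def invert_mapping(mapped: MappedHit) -> int:
    """Recover the clone offset ``a`` from a mapped hit (mapping inverse)."""
    if mapped.clone.clone_strand == "+":
        return mapped.a_prime - mapped.clone.x
    return mapped.clone.y - mapped.a_prime


@dataclass
class CandidateGene:
    """A gene evaluated against one mapped hit, with named filter outcomes."""

    gene: GeneAnnotation
    hit: MappedHit
    tss_distance: int      # model 3' end -> TSS in reading direction; < 0 = overlap
    overlap_len: int       # nt of model within the gene's 5' sequence
    passed_filters: dict[str, bool] = field(default_factory=dict)

    @property
    def retained(self) -> bool:
        return all(self.passed_filters.values())

    @property
    def failed_filters(self) -> list[str]:
        return [k for k, ok in self.passed_filters.items() if not ok]


def assign_genes(
    hits: Sequence[MappedHit],
    genes: Sequence[GeneAnnotation],
    max_tss_distance: int = DEFAULT_MAX_TSS_DISTANCE,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[CandidateGene]:
    """Evaluate genes inside each hit's TSS search window against the filters.

    Every gene whose TSS lies in the inclusive [a', z] window on the hit's
    chromosome is returned as a :class:`CandidateGene` carrying three named
    filter booleans:

    - ``orientation``: gene strand equals the hit's chromosomal strand and the
      gene lies downstream of the model in its reading direction;
    - ``tss_distance``: 0 <= distance <= ``max_tss_distance``, or the gene
      overlaps (distance < 0) and is routed to the overlap filter;
    - ``overlap``: overlap length <= ``max_overlap``.

    Retained candidates (all filters true) are the co-regulation calls; the
    rest document why each neighbor was rejected.  Sorted by (chromosome, a',
    gene_id).
    """
    out: list[CandidateGene] = []
    for mh in hits:
        lo, hi = min(mh.a_prime, mh.z), max(mh.a_prime, mh.z)
        for gene in genes:
            if gene.chromosome != mh.chromosome:
                continue
            if not lo <= gene.tss <= hi:
                continue
            if mh.chrom_strand == "+":
                d = gene.tss - mh.model_3prime
            else:
                d = mh.model_3prime - gene.tss
            overlap = max(-d, 0)
            # downstream-ness is enforced by the window itself: a TSS behind
            # the model's 5' anchor a' falls outside [a', z] and is never a
            # candidate, matching "directly downstream of the model"
            filters = {
                "orientation": gene.strand == mh.chrom_strand,
                "tss_distance": d <= max_tss_distance,
                "overlap": overlap <= max_overlap,
            }
            out.append(CandidateGene(gene, mh, d, overlap, filters))
    out.sort(key=lambda c: (c.gene.chromosome, c.hit.a_prime, c.gene.gene_id))
    return out


def retained_genes(candidates: Iterable[CandidateGene]) -> list[CandidateGene]:
    return [c for c in candidates if c.retained]


# ---------------------------------------------------------------------------
# I/O

def read_clone_mappings(path_or_handle: Union[str, TextIO]) -> list[CloneMapping]:
    """TSV: clone_id, chromosome, x, y, clone_strand."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_clone_mappings(fh)
    out = []
    for line in path_or_handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cid, chrom, x, y, strand = line.split("\t")[:5]
        out.append(CloneMapping(cid, chrom, int(x), int(y), strand))
    return out


def write_clone_mappings(clones: Iterable[CloneMapping], path: str) -> None:
    with open(path, "w") as fh:
        for c in clones:
            fh.write(f"{c.clone_id}\t{c.chromosome}\t{c.x}\t{c.y}\t{c.clone_strand}\n")


def write_candidates(candidates: Iterable[CandidateGene], path_or_handle: Union[str, TextIO]) -> None:
    """TSV: gene_id, chromosome, strand, a', tss_distance, overlap_len, filters."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_candidates(candidates, fh)
        return
    fh = path_or_handle
    fh.write("gene_id\tchromosome\tstrand\ta_prime\ttss_distance\toverlap_len\t"
             "retained\tfailed_filters\n")
    for c in candidates:
        fh.write(
            f"{c.gene.gene_id}\t{c.gene.chromosome}\t{c.gene.strand}\t{c.hit.a_prime}\t"
            f"{c.tss_distance}\t{c.overlap_len}\t{int(c.retained)}\t"
            f"{','.join(c.failed_filters)}\n"
        )
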