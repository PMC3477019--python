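"""Regulatory models — ordered PWM/IUPAC element chains with gap constraints —
and their screening against promoter sets and genome-scale FASTA.

A model hit requires every element (or at least ``quorum_k`` of them under
relaxed screening) in the stated order on one orientation, with each gap
between consecutively matched adjacent elements inside its inclusive
[dmin, dmax] range.  The minus orientation is a scan of the reverse
complement reported back in forward coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from .motifs import (
    IUPACMotif,
    MotifHit,
    PositionWeightMatrix,
    scan_iupac,
    scan_pwm,
)
from .seqio import SequenceRecord, reverse_complement


@dataclass
class ModelElement:
    """One slot of a model: a PWM or IUPAC motif with its stringency."""

    name: str
    motif: Optional[Union[PositionWeightMatrix, IUPACMotif]] = None
    core_threshold: float = 0.75
    matrix_threshold: float = 0.80
    max_mismatches: int = 0

    @property
    def kind(self) -> str:
        if isinstance(self.motif, PositionWeightMatrix):
            return "pwm"
        if isinstance(self.motif, IUPACMotif):
            return "iupac"
        return "unresolved"


@dataclass
class RegulatoryModel:
    """An ordered element chain with inclusive per-gap distance ranges."""

    name: str
    elements: list[ModelElement]
    gaps: list[tuple[int, int]]
    quorum_k: Optional[int] = None  # None = all elements required

    def __post_init__(self) -> None:
        if len(self.elements) < 1:
            raise ValueError("a model needs at least one element")
        if len(self.gaps) != max(len(self.elements) - 1, 0):
            raise ValueError("need one gap range per adjacent element pair")
        for dmin, dmax in self.gaps:
            if dmin > dmax:
                raise ValueError("gap range must have dmin <= dmax")
        if self.quorum_k is not None and not 1 <= self.quorum_k <= len(self.elements):
            raise ValueError("quorum_k must lie in [1, number of elements]")

    @property
    def required(self) -> int:
        return self.quorum_k if self.quorum_k is not None else len(self.elements)

    def resolve(self, library: Mapping[str, Union[PositionWeightMatrix, IUPACMotif]]) -> None:
        """Fill unresolved element motifs from a name-keyed library."""
        for el in self.elements:
            if el.motif is None:
                if el.name not in library:
                    raise KeyError(f"unresolvable motif reference {el.name!r}")
                el.motif = library[el.name]


@dataclass
class ModelHit:
    """A located model occurrence spanning first to last matched element."""

    sequence_id: str
    start: int
    end: int
    orientation: str
    element_hits: list[MotifHit]
    matched_count: int
    model_name: str = ""

    def check(self, model: RegulatoryModel) -> bool:
        """Re-verify order, gaps and quorum independently of the scanner."""
        if self.matched_count < model.required:
            return False
        if len(self.element_hits) != self.matched_count:
            return False
        # map hits back to model element indices in order
        names = [h.motif for h in self.element_hits]
        idxs: list[int] = []
        j = 0
        for nm in names:
            while j < len(model.elements) and model.elements[j].name != nm:
                j += 1
            if j == len(model.elements):
                return False
            idxs.append(j)
            j += 1
        for (h1, i1), (h2, i2) in zip(
            zip(self.element_hits, idxs), zip(self.element_hits[1:], idxs[1:])
        ):
            # along the minus orientation, model order runs right-to-left in
            # forward coordinates
            gap = (h2.start - h1.end) if self.orientation == "+" else (h1.start - h2.end)
            if gap < 0:
                return False
            if i2 == i1 + 1:  # gap constrained only between adjacent elements
                dmin, dmax = model.gaps[i1]
                if not dmin <= gap <= dmax:
                    return False
        return True


def _element_hits(seq: SequenceRecord, el: ModelElement) -> list[MotifHit]:
    if el.kind == "pwm":
        hits = scan_pwm(seq, el.motif, el.core_threshold, el.matrix_threshold,
                        strands="forward")
    elif el.kind == "iupac":
        hits = scan_iupac(seq, el.motif, strands="forward")
    else:
        raise KeyError(f"unresolvable motif reference {el.name!r}")
    return [MotifHit(el.name, h.sequence_id, h.start, h.end, h.strand,
                     h.core_similarity, h.matrix_similarity) for h in hits]


def scan_model(seq: SequenceRecord, model: RegulatoryModel) -> list[ModelHit]:
    """Locate model occurrences on both orientations of a sequence.

    Left-to-right chaining: element-1 hits seed partial chains; a chain
    extends to the next element through any hit whose gap to the chain tail
    lies in the inclusive [dmin, dmax] range.  Under relaxed quorum
    (``quorum_k`` below the element count) elements may be skipped; the gap
    across a skipped element is unconstrained.  Complete chains are reported
    for both orientations, minus-orientation chains in forward coordinates,
    sorted by start.
    """
    out: list[ModelHit] = []
    for orientation in "+-":
        if orientation == "+":
            view = seq
        else:
            view = SequenceRecord(id=seq.id, residues=reverse_complement(seq.residues))
        hits_per_element = [_element_hits(view, el) for el in model.elements]
        chains = _chain(hits_per_element, model)
        for chain in chains:
            ehits = [h for h in chain if h is not None]
            if orientation == "-":
                L = len(seq.residues)
                # map to forward coordinates; keep element_hits in model order,
                # which runs right-to-left along the forward strand
                ehits = [
                    MotifHit(h.motif, seq.id, L - h.end, L - h.start, "-",
                             h.core_similarity, h.matrix_similarity)
                    for h in ehits
                ]
                start = min(h.start for h in ehits)
                end = max(h.end for h in ehits)
            else:
                start = ehits[0].start
                end = ehits[-1].end
            out.append(ModelHit(seq.id, start, end, orientation, ehits,
                                len(ehits), model.name))
    out.sort(key=lambda m: (m.start, m.orientation))
    return out


def _chain(hits_per_element: list[list[MotifHit]], model: RegulatoryModel):
    """Enumerate all legal chains over per-element hit lists (forward frame)."""
    n = len(model.elements)
    required = model.required
    complete: list[tuple] = []

    def extend(idx: int, chain: tuple, matched: int, last: Optional[MotifHit],
               last_idx: Optional[int]):
        if idx == n:
            if matched >= required:
                complete.append(chain)
            return
        remaining = n - idx
        if matched + remaining < required:
            return
        # option 1: skip this element (relaxed screening only)
        if n - required >= 1 and (matched + remaining - 1) >= required:
            extend(idx + 1, chain + (None,), matched, last, last_idx)
        # option 2: take a hit for this element
        for h in hits_per_element[idx]:
            if last is not None:
                if h.start < last.end:
                    continue
                if last_idx == idx - 1:
                    dmin, dmax = model.gaps[idx - 1]
                    if not dmin <= h.start - last.end <= dmax:
                        continue
            extend(idx + 1, chain + (h,), matched + 1, h, idx)

    extend(0, (), 0, None, None)
    # deduplicate identical hit tuples (skips at different slots can coincide)
    seen = set()
    unique = []
    for ch in complete:
        key = tuple((h.start, h.end, h.motif) for h in ch if h is not None)
        if key not in seen:
            seen.add(key)
            unique.append(ch)
    return unique


@dataclass
class ScreenSummary:
    per_sequence: dict[str, list[ModelHit]]
    n_with_hit: int
    n_total: int

    def __str__(self) -> str:
        return f"{self.n_with_hit}/{self.n_total} sequences with >=1 model hit"


def screen_promoter_set(
    promoters: Sequence[SequenceRecord], model: RegulatoryModel
) -> ScreenSummary:
    """Apply :func:`scan_model` to every record; summarize hit prevalence."""
    per_seq = {rec.id: scan_model(rec, model) for rec in promoters}
    n_with = sum(1 for hits in per_seq.values() if hits)
    return ScreenSummary(per_seq, n_with, len(per_seq))


@dataclass
class ConservationReport:
    per_species: dict[str, bool]
    min_species: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_present(self) -> int:
        return sum(self.per_species.values())

    @property
    def passed(self) -> bool:
        return self.n_present >= self.min_species

    @property
    def present_species(self) -> list[str]:
        return sorted(s for s, p in self.per_species.items() if p)


def conserved_across_species(
    model: RegulatoryModel,
    ortholog_sets: Mapping[str, Sequence[SequenceRecord]],
    min_species: int,
) -> ConservationReport:
    """Check whether a model occurs in the ortholog promoters of enough species."""
    if not ortholog_sets:
        raise ValueError("need at least one species promoter set")
    report = ConservationReport({}, min_species)
    if min_species > len(ortholog_sets):
        report.warnings.append(
            f"min_species {min_species} exceeds the {len(ortholog_sets)} species given; "
            "the test can never pass"
        )
    for species, promoters in ortholog_sets.items():
        if not promoters:
            report.per_species[species] = False
            report.warnings.append(f"species {species!r} has an empty promoter set")
            continue
        report.per_species[species] = any(
            scan_model(rec, model) for rec in promoters
        )
    return report


# ---------------------------------------------------------------------------
# Model file I/O: one model per block.
#   model NAME [quorum K]
#   element pwm NAME CORE_TH MATRIX_TH      (or: element iupac NAME PATTERN MM)
#   gap DMIN DMAX
# Elements and gaps alternate in order; blocks separated by blank lines.

def write_models(models: Iterable[RegulatoryModel], path_or_handle: Union[str, TextIO]) -> None:
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_models(models, fh)
        return
    fh = path_or_handle
    for model in models:
        head = f"model\t{model.name}"
        if model.quorum_k is not None:
            head += f"\tquorum\t{model.quorum_k}"
        fh.write(head + "\n")
        for i, el in enumerate(model.elements):
            if el.kind == "iupac":
                fh.write(f"element\tiupac\t{el.name}\t{el.motif.pattern}\t{el.motif.max_mismatches}\n")
            else:
                fh.write(f"element\tpwm\t{el.name}\t{el.core_threshold}\t{el.matrix_threshold}\n")
            if i < len(model.gaps):
                dmin, dmax = model.gaps[i]
                fh.write(f"gap\t{dmin}\t{dmax}\n")
        fh.write("\n")


def read_models(
    path_or_handle: Union[str, TextIO],
    pwm_library: Optional[Mapping[str, PositionWeightMatrix]] = None,
) -> list[RegulatoryModel]:
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_models(fh, pwm_library)
    models: list[RegulatoryModel] = []
    name = None
    quorum = None
    elements: list[ModelElement] = []
    gaps: list[tuple[int, int]] = []

    def flush():
        nonlocal name, quorum, elements, gaps
        if name is not None:
            models.append(RegulatoryModel(name, elements, gaps, quorum))
        name, quorum, elements, gaps = None, None, [], []

    for line in path_or_handle:
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        fields = line.split("\t")
        if fields[0] == "model":
            flush()
            name = fields[1]
            if len(fields) >= 4 and fields[2] == "quorum":
                quorum = int(fields[3])
        elif fields[0] == "element":
            kind, el_name = fields[1], fields[2]
            if kind == "iupac":
                motif = IUPACMotif(el_name, fields[3], int(fields[4]))
                elements.append(ModelElement(el_name, motif))
            elif kind == "pwm":
                motif = pwm_library.get(el_name) if pwm_library else None
                elements.append(ModelElement(
                    el_name, motif,
                    core_threshold=float(fields[3]), matrix_threshold=float(fields[4]),
                ))
            else:
                raise ValueError(f"unknown element kind {kind!r}")
        elif fields[0] == "gap":
            gaps.append((int(fields[1]), int(fields[2])))
        else:
            raise ValueError(f"unrecognized model-file line: {line!r}")
    flush()
    return models


def write_model_hits(hits: Iterable[ModelHit], path_or_handle: Union[str, TextIO]) -> None:
    """TSV: sequence_id, start, end, orientation, matched_count, element chain."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_model_hits(hits, fh)
        return
    for h in hits:
        chain = ",".join(f"{e.motif}:{e.start}" for e in h.element_hits)
        path_or_handle.write(
            f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.orientation}\t"
            f"{h.matched_count}\t{chain}\n"
        )
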