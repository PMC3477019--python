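"""Discovery of conserved ordered motif combinations ("frameworks").

A framework is an ordered chain of 2-6 motif elements with a consistent gap
(3' end of one element to 5' start of the next) observed in at least a quorum
of promoter sequences.  The search is Apriori-style: every ordered motif pair
with consistent gaps across >= quorum sequences seeds a 2-element framework,
and seeds are extended rightward one element at a time; support can only
shrink under extension, so the search is complete for chains reported at the
given quorum.

Gap consistency is a window rule: the observed gaps of the new adjacency must
admit a window of width <= 2 * gap_tolerance covering instances from at least
``quorum`` sequences; the recorded [dmin, dmax] is the observed min/max inside
the best such window (maximum support, then smallest dmin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from .motifs import MotifHit


@dataclass
class Framework:
    """An ordered motif chain with per-gap distance ranges and its support."""

    elements: tuple[str, ...]
    gaps: tuple[tuple[int, int], ...]  # per adjacent pair: (dmin, dmax)
    support: int
    instances: dict[str, list[tuple[MotifHit, ...]]]  # sequence_id -> hit chains

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError("a framework needs at least 2 elements")
        if len(self.gaps) != len(self.elements) - 1:
            raise ValueError("need one gap range per adjacent element pair")
        for dmin, dmax in self.gaps:
            if dmin > dmax:
                raise ValueError("gap range must have dmin <= dmax")

    def is_subchain_of(self, other: "Framework") -> bool:
        """True if this element chain is a (not necessarily contiguous)
        subsequence of the other's."""
        it = iter(other.elements)
        return all(e in it for e in self.elements)


def _gap(prev: MotifHit, nxt: MotifHit) -> int:
    return nxt.start - prev.end


def _best_gap_window(
    per_seq_gaps: Mapping[str, list[int]], width: int, quorum: int
) -> Optional[tuple[int, int, set]]:
    """Best [g, g+width] window by supporting-sequence count, then smallest g.

    Returns (dmin, dmax, supporting_ids) over observed gaps inside the window,
    or None when no window reaches the quorum.
    """
    all_gaps = sorted({g for gaps in per_seq_gaps.values() for g in gaps})
    best = None
    best_rank = None
    for g0 in all_gaps:
        inside = {
            sid for sid, gaps in per_seq_gaps.items()
            if any(g0 <= g <= g0 + width for g in gaps)
        }
        if len(inside) < quorum:
            continue
        observed = [
            g for sid in inside for g in per_seq_gaps[sid] if g0 <= g <= g0 + width
        ]
        # most sequences, then most instances covered, then smallest dmin
        rank = (len(inside), len(observed), -min(observed))
        if best_rank is None or rank > best_rank:
            best_rank = rank
            best = (min(observed), max(observed), inside)
    return best


def discover_frameworks(
    hit_sets: Mapping[str, Sequence[MotifHit]],
    quorum: int,
    max_elements: int = 6,
    gap_tolerance: int = 10,
    same_strand: bool = True,
) -> list[Framework]:
    """Mine maximal ordered motif chains supported by >= quorum sequences.

    ``hit_sets`` maps sequence id to its motif hits (sorted by start).  Only
    frameworks that are not a subsequence of another reported framework with
    equal support are returned, ordered by element count (descending) then
    element names.
    """
    n_seqs = len(hit_sets)
    if quorum > n_seqs:
        raise ValueError(f"quorum {quorum} exceeds number of sequences {n_seqs}")
    if quorum < 2:
        raise ValueError("quorum must be >= 2")
    width = 2 * gap_tolerance

    sorted_hits = {
        sid: sorted(hits, key=lambda h: (h.start, h.end, h.motif))
        for sid, hits in hit_sets.items()
    }

    # --- seeds: ordered pairs ------------------------------------------------
    pair_gaps: dict[tuple[str, str], dict[str, list[int]]] = {}
    for sid, hits in sorted_hits.items():
        for i, h1 in enumerate(hits):
            for h2 in hits[i + 1:]:
                if h2.start < h1.end:
                    continue  # must be downstream, non-overlapping
                if same_strand and h2.strand != h1.strand:
                    continue
                key = (h1.motif, h2.motif)
                pair_gaps.setdefault(key, {}).setdefault(sid, []).append(_gap(h1, h2))

    frameworks: list[Framework] = []
    frontier: list[Framework] = []
    for (m1, m2), per_seq in pair_gaps.items():
        if len(per_seq) < quorum:
            continue
        window = _best_gap_window(per_seq, width, quorum)
        if window is None:
            continue
        dmin, dmax, ids = window
        instances = {
            sid: [
                (h1, h2)
                for i, h1 in enumerate(sorted_hits[sid])
                for h2 in sorted_hits[sid][i + 1:]
                if h1.motif == m1 and h2.motif == m2 and h2.start >= h1.end
                and (not same_strand or h1.strand == h2.strand)
                and dmin <= _gap(h1, h2) <= dmax
            ]
            for sid in ids
        }
        instances = {sid: ch for sid, ch in instances.items() if ch}
        if len(instances) < quorum:
            continue
        frontier.append(Framework((m1, m2), ((dmin, dmax),), len(instances), instances))

    frameworks.extend(frontier)

    # --- rightward extension -------------------------------------------------
    while frontier:
        next_frontier: list[Framework] = []
        for fw in frontier:
            if len(fw.elements) >= max_elements:
                continue
            # candidate next elements: any motif appearing downstream of a chain
            ext_gaps: dict[str, dict[str, list[int]]] = {}
            ext_chains: dict[str, dict[str, list[tuple]]] = {}
            for sid, chains in fw.instances.items():
                for chain in chains:
                    tail = chain[-1]
                    for h in sorted_hits[sid]:
                        if h.start < tail.end:
                            continue
                        if same_strand and h.strand != tail.strand:
                            continue
                        ext_gaps.setdefault(h.motif, {}).setdefault(sid, []).append(_gap(tail, h))
                        ext_chains.setdefault(h.motif, {}).setdefault(sid, []).append(chain + (h,))
            for motif, per_seq in ext_gaps.items():
                if len(per_seq) < quorum:
                    continue
                window = _best_gap_window(per_seq, width, quorum)
                if window is None:
                    continue
                dmin, dmax, ids = window
                instances = {
                    sid: [
                        ch for ch in ext_chains[motif][sid]
                        if dmin <= _gap(ch[-2], ch[-1]) <= dmax
                    ]
                    for sid in ids
                }
                instances = {sid: ch for sid, ch in instances.items() if ch}
                if len(instances) < quorum:
                    continue
                next_frontier.append(Framework(
                    fw.elements + (motif,),
                    fw.gaps + ((dmin, dmax),),
                    len(instances),
                    instances,
                ))
        frameworks.extend(next_frontier)
        frontier = next_frontier

    # --- maximality ----------------------------------------------------------
    maximal = [
        fw for fw in frameworks
        if not any(
            other is not fw
            and len(other.elements) > len(fw.elements)
            and other.support == fw.support
            and fw.is_subchain_of(other)
            for other in frameworks
        )
    ]
    maximal.sort(key=lambda f: (-len(f.elements), f.elements, f.gaps))
    return maximal


def framework_to_model(
    fw: Framework,
    reference_sequence_id: str,
    distance_factor: float = 2.0,
    motif_library: Optional[Mapping[str, object]] = None,
    core_threshold: float = 0.75,
    matrix_threshold: float = 0.80,
    max_mismatches: int = 0,
):
    """Turn a discovered framework into a screenable regulatory model.

    Per-gap allowed ranges are ``[0, distance_factor * g_ref]`` where g_ref is
    the gap observed in the reference-sequence instance; the default doubles
    the reference promoter's distances.  ``motif_library`` maps element names
    to PWM or IUPAC motif objects for resolution.
    """
    from .models import ModelElement, RegulatoryModel

    if reference_sequence_id not in fw.instances:
        raise ValueError(
            f"framework has no instance on reference sequence {reference_sequence_id!r}"
        )
    chain = min(fw.instances[reference_sequence_id], key=lambda ch: ch[0].start)
    gaps = []
    for prev, nxt in zip(chain, chain[1:]):
        g_ref = _gap(prev, nxt)
        gaps.append((0, int(round(distance_factor * g_ref))))
    elements = []
    for name in fw.elements:
        motif = motif_library.get(name) if motif_library else None
        elements.append(ModelElement(
            name=name, motif=motif,
            core_threshold=core_threshold, matrix_threshold=matrix_threshold,
            max_mismatches=max_mismatches,
        ))
    return RegulatoryModel(
        name="+".join(fw.elements), elements=elements, gaps=gaps,
    )


# ---------------------------------------------------------------------------
# Serialization

def write_frameworks(fws: Iterable[Framework], path_or_handle: Union[str, TextIO]) -> None:
    """One block per framework: elements, gap ranges, support, instances."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_frameworks(fws, fh)
        return
    fh = path_or_handle
    for fw in fws:
        fh.write(f"framework\t{' '.join(fw.elements)}\n")
        fh.write("gaps\t" + " ".join(f"{a}:{b}" for a, b in fw.gaps) + "\n")
        fh.write(f"support\t{fw.support}\n")
        for sid in sorted(fw.instances):
            for chain in fw.instances[sid]:
                fh.write("instance\t" + " ".join(
                    f"{sid}:{h.start}:{h.strand}" for h in chain) + "\n")
        fh.write("\n")
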