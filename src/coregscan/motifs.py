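"""Position weight matrices, IUPAC motifs, and strand-aware occurrence scanning.

Scoring follows the information-vector-weighted similarity scheme of
MatInspector-style scanners: each PWM position i carries a conservation value
Ci in [0, 100] (0 for a uniform position, 100 for a single-base position) and
a window scores

    sim = sum_i Ci * f(i, b_i) / sum_i Ci * max_b f(i, b)

over all positions (matrix similarity) or over the designated core window
only (core similarity).  The consensus sequence therefore always scores 1.0.
The core is the run of (usually four) consecutive positions with the highest
total conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

from .seqio import SequenceRecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CLASSES: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence, always in forward coordinates."""

    motif: str
    sequence_id: str
    start: int
    end: int
    strand: str
    core_similarity: float
    matrix_similarity: float

    @property
    def sort_key(self):
        return (self.start, self.strand, self.motif)


class PositionWeightMatrix:
    """Per-position base frequencies with a conservation vector and core window.

    Parameters
    ----------
    name : matrix name, e.g. ``V$MZF1.01``; the family is the name up to the
        last ``.NN`` suffix (``V$MZF1``).
    freqs : (L, 4) array of base frequencies in A, C, G, T order; each row
        must sum to 1.
    core : (start, length) of the core window (0-based); defaults to the
        ``core_length`` consecutive positions maximizing total conservation,
        leftmost on ties.
    """

    def __init__(
        self,
        name: str,
        freqs: np.ndarray,
        core: Optional[tuple[int, int]] = None,
        core_length: int = 4,
        family: Optional[str] = None,
        ci: Optional[np.ndarray] = None,
    ):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4:
            raise ValueError("freqs must be an (L, 4) array")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position's frequencies must sum to 1")
        self.name = name
        self.family = family if family is not None else _family_of(name)
        self.f = freqs
        if ci is None:
            self.ci = _conservation_vector(freqs)
        else:
            # vendor matrix files may state Ci explicitly alongside counts
            self.ci = np.asarray(ci, dtype=float)
            if self.ci.shape != (len(freqs),) or (self.ci < 0).any() or (self.ci > 100).any():
                raise ValueError("ci must be per-position values in [0, 100]")
        L = len(freqs)
        if core is None:
            k = min(core_length, L)
            sums = [self.ci[s:s + k].sum() for s in range(L - k + 1)]
            start = int(np.argmax(sums))  # argmax is leftmost on ties
            core = (start, k)
        cs, cl = core
        if not (0 <= cs and cs + cl <= L and cl >= 1):
            raise ValueError("core window must lie within the matrix")
        self.core = core

    def __len__(self) -> int:
        return len(self.f)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.f.argmax(axis=1))

    def __repr__(self) -> str:
        return f"PositionWeightMatrix({self.name!r}, L={len(self)}, core={self.core})"


def _family_of(name: str) -> str:
    head, dot, tail = name.rpartition(".")
    if dot and tail.isdigit():
        return head
    return name


def _conservation_vector(freqs: np.ndarray) -> np.ndarray:
    """Ci = (100/ln4) * (sum_b f ln f + ln 4), with 0*ln0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    ci = (100.0 / math.log(4)) * (plogp.sum(axis=1) + math.log(4))
    return np.clip(ci, 0.0, 100.0)


def build_pwm(
    sites: Optional[Sequence[str]] = None,
    counts: Optional[np.ndarray] = None,
    name: str = "PWM",
    pseudocount: float = 0.0,
    core_length: int = 4,
) -> PositionWeightMatrix:
    """Build a PWM from aligned binding sites or a position-count table.

    Frequencies are ``(count + pseudocount) / (n + 4 * pseudocount)`` per
    position.  Exactly one of ``sites`` and ``counts`` must be given.
    """
    if (sites is None) == (counts is None):
        raise ValueError("provide exactly one of sites or counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if sites is not None:
        if not sites:
            raise ValueError("need at least one site")
        L = len(sites[0])
        if any(len(s) != L for s in sites):
            raise ValueError("sites must all have equal length")
        counts = np.zeros((L, 4))
        for s in sites:
            s = s.upper()
            for i, b in enumerate(s):
                if b not in _BASE_INDEX:
                    raise ValueError(f"illegal base {b!r} in site {s!r}")
                counts[i, _BASE_INDEX[b]] += 1
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("all-zero count column; use a positive pseudocount")
    freqs = (counts + pseudocount) / (totals + 4 * pseudocount)[:, None]
    return PositionWeightMatrix(name, freqs, core_length=core_length)


def score_window(pwm: PositionWeightMatrix, window: str, part: str = "matrix") -> float:
    """Information-weighted similarity of a window against a PWM.

    ``part`` selects all positions (``matrix``) or the core window only
    (``core``).  An N in the window contributes frequency 0 at that position.
    """
    window = window.upper()
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != matrix length {len(pwm)}")
    if part == "matrix":
        idx = range(len(pwm))
    elif part == "core":
        cs, cl = pwm.core
        idx = range(cs, cs + cl)
    else:
        raise ValueError(f"unknown part {part!r}")
    num = 0.0
    den = 0.0
    for i in idx:
        ci = pwm.ci[i]
        den += ci * pwm.f[i].max()
        b = window[i]
        if b in _BASE_INDEX:
            num += ci * pwm.f[i, _BASE_INDEX[b]]
    if den == 0.0:
        return 1.0  # fully uninformative (sub)matrix cannot penalize
    return num / den


def scan_pwm(
    seq: SequenceRecord,
    pwm: PositionWeightMatrix,
    core_threshold: float = 0.75,
    matrix_threshold: float = 0.80,
    strands: str = "both",
) -> list[MotifHit]:
    """Locate PWM occurrences passing both the core and matrix thresholds.

    Minus-strand windows are scored on the reverse complement and reported in
    forward coordinates.  Hits are sorted by start, then strand.
    """
    L = len(pwm)
    s = seq.residues
    hits: list[MotifHit] = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for off in range(len(s) - L + 1):
        window = s[off:off + L]
        for strand in strand_list:
            w = window if strand == "+" else reverse_complement(window)
            core = score_window(pwm, w, "core")
            if core < core_threshold:
                continue
            mat = score_window(pwm, w, "matrix")
            if mat < matrix_threshold:
                continue
            hits.append(MotifHit(pwm.name, seq.id, off, off + L, strand, core, mat))
    hits.sort(key=lambda h: h.sort_key)
    return hits


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate nucleotide string with a mismatch allowance."""

    name: str
    pattern: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = set(self.pattern) - set(IUPAC_CLASSES)
        if bad:
            raise ValueError(f"illegal IUPAC symbols in pattern: {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def __len__(self) -> int:
        return len(self.pattern)


def _iupac_mismatches(pattern: str, window: str) -> int:
    # N in the sequence never satisfies a non-N pattern symbol
    return sum(1 for p, b in zip(pattern, window) if b not in IUPAC_CLASSES[p])


def scan_iupac(seq: SequenceRecord, motif: IUPACMotif, strands: str = "both") -> list[MotifHit]:
    """Locate IUPAC-string occurrences with at most ``max_mismatches`` misses.

    ``matrix_similarity`` of a hit is the fraction of matched positions;
    ``core_similarity`` is reported identically (strings have no core).
    """
    pat = motif.pattern
    L = len(pat)
    rc_pat = iupac_reverse_complement(pat)
    s = seq.residues
    hits: list[MotifHit] = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for off in range(len(s) - L + 1):
        window = s[off:off + L]
        for strand in strand_list:
            p = pat if strand == "+" else rc_pat
            mm = _iupac_mismatches(p, window)
            if mm <= motif.max_mismatches:
                frac = (L - mm) / L
                hits.append(MotifHit(motif.name, seq.id, off, off + L, strand, frac, frac))
    hits.sort(key=lambda h: h.sort_key)
    return hits


# ---------------------------------------------------------------------------
# Library I/O

def read_pwm_library(path_or_handle: Union[str, TextIO]) -> dict[str, PositionWeightMatrix]:
    """Read a PWM library: TSV blocks of ``>name[TAB]family`` then L count rows.

    Each count row holds four tab-separated numbers (A, C, G, T).  Blocks are
    separated by blank lines or the next ``>`` header.
    """
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_pwm_library(fh)
    pwms: dict[str, PositionWeightMatrix] = {}
    name = None
    family = None
    rows: list[list[float]] = []

    def flush():
        nonlocal name, family, rows
        if name is not None:
            counts = np.array(rows, dtype=float)
            pwm = build_pwm(counts=counts, name=name, pseudocount=0.0)
            if family:
                pwm.family = family
            pwms[name] = pwm
        name, family, rows = None, None, []

    for line in path_or_handle:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split("\t")
            name = parts[0].strip()
            family = parts[1].strip() if len(parts) > 1 else None
        else:
            rows.append([float(x) for x in line.split("\t")])
    flush()
    return pwms


def write_pwm_library(pwms: Iterable[PositionWeightMatrix], path: str, scale: int = 100) -> None:
    """Write PWMs as count blocks (frequencies scaled to ``scale`` counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\t{pwm.family}\n")
            for row in pwm.f:
                fh.write("\t".join(f"{v * scale:.6g}" for v in row) + "\n")
            fh.write("\n")


def read_iupac_motifs(path_or_handle: Union[str, TextIO]) -> list[IUPACMotif]:
    """Read a motif list TSV: name, pattern, max_mismatches."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_iupac_motifs(fh)
    out = []
    for line in path_or_handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        mm = int(fields[2]) if len(fields) > 2 else 0
        out.append(IUPACMotif(fields[0], fields[1], mm))
    return out


def write_hits(hits: Iterable[MotifHit], path_or_handle: Union[str, TextIO]) -> None:
    """Write hits as BED-like TSV: seq_id, start, end, name, score, strand."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_hits(hits, fh)
        return
    for h in hits:
        path_or_handle.write(
            f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.motif}\t"
            f"{h.matrix_similarity:.4f}\t{h.strand}\n"
        )


def read_hits(path_or_handle: Union[str, TextIO]) -> list[MotifHit]:
    """Read hits from the BED-like TSV written by :func:`write_hits`.

    Core similarity is not stored in the BED-like format; it is read back
    equal to the score column.
    """
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_hits(fh)
    out = []
    for line in path_or_handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seq_id, start, end, name, score, strand = line.split("\t")[:6]
        sc = float(score)
        out.append(MotifHit(name, seq_id, int(start), int(end), strand, sc, sc))
    return out
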