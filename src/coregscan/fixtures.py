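"""Synthetic, ground-truthed inputs for every pipeline stage.

Three generators cover the pipeline: promoter sets with a regulatory model
planted at known positions (framework discovery and model screening), toy
genomes with clones, planted model instances and target/decoy genes for each
of the four clone-orientation cases (gene assignment), and expression
matrices with planted fold changes (expression validation).  Each generator
is driven by a single integer seed, emits only the toolkit's standard text
formats, and returns a :class:`FixtureTruth` that fully determines the
expected output of the stage under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assign import CloneMapping
from .models import ModelElement, RegulatoryModel
from .motifs import IUPAC_CLASSES, IUPACMotif, PositionWeightMatrix
from .seqio import GeneAnnotation, SequenceRecord, reverse_complement

BASES = "ACGT"


@dataclass
class FixtureTruth:
    """Planted ground truth: typed records plus the generator's parameters."""

    kind: str
    seed: int
    parameters: dict
    planted: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"kind": self.kind, "seed": self.seed,
                 "parameters": self.parameters, "planted": self.planted},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "FixtureTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["kind"], d["seed"], d["parameters"], d["planted"])


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _realize_element(el: ModelElement, rng: np.random.Generator) -> str:
    """A concrete site for a model element: PWM consensus, or one base drawn
    per degenerate IUPAC symbol."""
    if isinstance(el.motif, PositionWeightMatrix):
        return el.motif.consensus
    if isinstance(el.motif, IUPACMotif):
        return "".join(
            sorted(IUPAC_CLASSES[sym] - {"N"})[rng.integers(0, len(IUPAC_CLASSES[sym] - {"N"}))]
            for sym in el.motif.pattern
        )
    raise ValueError(f"element {el.name!r} has no resolvable motif")


def _model_realization(model: RegulatoryModel, gaps: Sequence[int],
                       rng: np.random.Generator) -> tuple[str, list[tuple[str, int]]]:
    """Concatenated element sites with the stated gaps; returns the insert
    string and per-element (name, offset-within-insert)."""
    parts: list[str] = []
    placements: list[tuple[str, int]] = []
    pos = 0
    for i, el in enumerate(model.elements):
        site = _realize_element(el, rng)
        placements.append((el.name, pos))
        parts.append(site)
        pos += len(site)
        if i < len(gaps):
            filler = _random_dna(rng, gaps[i])
            parts.append(filler)
            pos += gaps[i]
    return "".join(parts), placements


def make_promoter_set(
    n_sequences: int,
    planted_model: RegulatoryModel,
    length: int = 2000,
    gap_jitter: int = 2,
    background_gc: float = 0.5,
    plant_fraction: float = 1.0,
    base_gaps: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], FixtureTruth]:
    """Promoter-length sequences with the model planted in a subset.

    Background is i.i.d. at the stated GC.  In a ``plant_fraction`` subset the
    model's elements are inserted in order, gaps drawn uniformly from
    [g - jitter, g + jitter] around ``base_gaps`` (default: the midpoint of
    each model gap range).  Placements are recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    if base_gaps is None:
        base_gaps = [(dmin + dmax) // 2 for dmin, dmax in planted_model.gaps]
    max_span = sum(
        len(_realize_element(el, np.random.default_rng(0)))
        for el in planted_model.elements
    ) + sum(g + gap_jitter for g in base_gaps)
    if max_span > length:
        raise ValueError(f"planted model span {max_span} exceeds sequence length {length}")
    n_planted = int(round(plant_fraction * n_sequences))
    records: list[SequenceRecord] = []
    truth = FixtureTruth(
        kind="promoter_set", seed=seed,
        parameters={
            "n_sequences": n_sequences, "length": length, "gap_jitter": gap_jitter,
            "background_gc": background_gc, "plant_fraction": plant_fraction,
            "model": planted_model.name, "base_gaps": list(base_gaps),
        },
    )
    for i in range(n_sequences):
        sid = f"promoter_{i:03d}"
        seq = _random_dna(rng, length, background_gc)
        if i < n_planted:
            gaps = [int(rng.integers(max(g - gap_jitter, 0), g + gap_jitter + 1))
                    for g in base_gaps]
            insert, placements = _model_realization(planted_model, gaps, rng)
            offset = int(rng.integers(0, length - len(insert) + 1))
            seq = seq[:offset] + insert + seq[offset + len(insert):]
            truth.planted.append({
                "sequence_id": sid, "offset": offset, "gaps": gaps,
                "elements": [
                    {"name": name, "start": offset + rel}
                    for name, rel in placements
                ],
            })
        records.append(SequenceRecord(id=sid, residues=seq))
    return records, truth


# ---------------------------------------------------------------------------
# Genome fixture for the clone-orientation cases

_CASE_SIGNS = {
    "A": ("+", "+", "+"),
    "B": ("-", "+", "-"),
    "C": ("-", "-", "+"),
    "D": ("+", "-", "-"),
}

_DECOY_KINDS = ("wrong_strand", "too_far", "too_much_overlap")


def make_genome_fixture(
    model: RegulatoryModel,
    cases: Sequence[str] = ("A", "B", "C", "D"),
    decoy_genes: int = 3,
    target_tss_distance: int = 300,
    gene_length: int = 1000,
    chromosome_length: int = 20000,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[CloneMapping], list[GeneAnnotation], FixtureTruth]:
    """One chromosome per clone-orientation case with planted truth.

    Each chromosome carries a clone at known (x, y, strand), a model instance
    at clone offset ``a``, a target gene with its TSS ``target_tss_distance``
    nt downstream of the model's 3' end in reading direction, and decoy genes
    each violating exactly one selection filter (wrong strand; TSS beyond the
    500 nt default; overlap beyond the 200 nt default).
    """
    if not cases:
        raise ValueError("cases must be non-empty")
    rng = np.random.default_rng(seed)
    genome: list[SequenceRecord] = []
    clones: list[CloneMapping] = []
    genes: list[GeneAnnotation] = []
    truth = FixtureTruth(
        kind="genome", seed=seed,
        parameters={
            "cases": list(cases), "decoy_genes": decoy_genes,
            "target_tss_distance": target_tss_distance,
            "gene_length": gene_length, "chromosome_length": chromosome_length,
            "model": model.name,
        },
    )
    base_gaps = [(dmin + dmax) // 2 for dmin, dmax in model.gaps]
    for case in cases:
        model_sign, clone_sign, chrom_sign = _CASE_SIGNS[case]
        chrom_name = f"chr{case}"
        chrom = _random_dna(rng, chromosome_length)
        # clone occupies the middle of the chromosome
        x = chromosome_length // 4
        y = 3 * chromosome_length // 4
        clone_id = f"clone{case}"
        insert, _ = _model_realization(model, base_gaps, rng)
        span = len(insert)
        if decoy_genes > 2 and span <= 221:
            raise ValueError(
                "overlap decoys need a model span above ~220 nt; widen the "
                "model's gap ranges"
            )
        a = int(rng.integers(200, (y - x) - span - 200))
        # build the clone in its own frame, plant the model at offset a
        clone_seq = chrom[x:y] if clone_sign == "+" else reverse_complement(chrom[x:y])
        planted = insert if model_sign == "+" else reverse_complement(insert)
        clone_seq = clone_seq[:a] + planted + clone_seq[a + span:]
        # write the clone back into the chromosome
        chrom_piece = clone_seq if clone_sign == "+" else reverse_complement(clone_seq)
        chrom = chrom[:x] + chrom_piece + chrom[y:]
        genome.append(SequenceRecord(id=chrom_name, residues=chrom))
        clones.append(CloneMapping(clone_id, chrom_name, x, y, clone_sign))

        a_prime = x + a if clone_sign == "+" else y - a
        model_3p = a_prime + span if chrom_sign == "+" else a_prime - span

        def add_gene(gene_id: str, tss_distance: int, strand: str) -> GeneAnnotation:
            if chrom_sign == "+":
                tss = model_3p + tss_distance
            else:
                tss = model_3p - tss_distance
            if strand == "+":
                g = GeneAnnotation(gene_id, chrom_name, "+", tss, tss + gene_length)
            else:
                g = GeneAnnotation(gene_id, chrom_name, "-", tss + 1 - gene_length, tss + 1)
            genes.append(g)
            return g

        target = add_gene(f"target_{case}", target_tss_distance, chrom_sign)
        truth.planted.append({
            "case": case, "chromosome": chrom_name, "clone_id": clone_id,
            "x": x, "y": y, "clone_strand": clone_sign,
            "a": a, "a_prime": a_prime, "span": span,
            "model_orientation": model_sign, "chrom_strand": chrom_sign,
            "target_gene": target.gene_id, "tss_distance": target_tss_distance,
            "decoys": [],
        })
        other = "-" if chrom_sign == "+" else "+"
        for k in range(decoy_genes):
            kind = _DECOY_KINDS[k % len(_DECOY_KINDS)]
            gid = f"decoy_{case}_{k}_{kind}"
            if kind == "wrong_strand":
                add_gene(gid, 100 + 7 * k, other)
                expect = "orientation"
            elif kind == "too_far":
                add_gene(gid, 501 + 40 * k, chrom_sign)
                expect = "tss_distance"
            else:
                ov = min(201 + 10 * k, span)  # stay inside the model span so
                add_gene(gid, -ov, chrom_sign)  # only the overlap filter trips
                expect = "overlap"
            truth.planted[-1]["decoys"].append({"gene_id": gid, "violates": expect})
    return genome, clones, genes, truth


# ---------------------------------------------------------------------------
# Expression fixture

def make_expression_fixture(
    n_probes: int = 200,
    n_samples_per_tissue: int = 10,
    tissues: Sequence[str] = ("testis", "brain"),
    planted_up: Optional[Sequence[tuple[str, float]]] = None,
    n_planted: int = 20,
    fold: float = 2.0,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Expression matrix with probes up-regulated in the first (target) tissue.

    Baselines are log-normal per probe; planted probes are multiplied by their
    fold in the target tissue; Gaussian noise is added on the log scale.
    Returns (:class:`~coregscan.expression.ExpressionMatrix`, truth).
    """
    from .expression import ExpressionMatrix
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    probes = [f"probe_{i:04d}" for i in range(n_probes)]
    if planted_up is None:
        planted_up = [(probes[i], fold) for i in range(min(n_planted, n_probes))]
    folds = dict(planted_up)
    if any(f <= 0 for f in folds.values()):
        raise ValueError("planted folds must be > 0")
    target = tissues[0]
    samples, groups = [], {}
    for t in tissues:
        for j in range(n_samples_per_tissue):
            s = f"{t}_{j:02d}"
            samples.append(s)
            groups[s] = t
    # baselines on a dyadic grid so that exact planted ratios (e.g. the 1.5
    # flag boundary) survive floating point in the noiseless limit
    baseline = np.round(np.exp(rng.normal(5.0, 1.0, size=n_probes)) * 64) / 64
    baseline = np.maximum(baseline, 1.0 / 64)
    X = np.empty((n_probes, len(samples)))
    for si, s in enumerate(samples):
        for pi, p in enumerate(probes):
            v = baseline[pi]
            if groups[s] == target and p in folds:
                v = v * folds[p]
            X[pi, si] = v * np.exp(rng.normal(0.0, noise_sd))
    m = ExpressionMatrix(pd.DataFrame(X, index=probes, columns=samples), groups)
    truth = FixtureTruth(
        kind="expression", seed=seed,
        parameters={
            "n_probes": n_probes, "n_samples_per_tissue": n_samples_per_tissue,
            "tissues": list(tissues), "noise_sd": noise_sd, "target": target,
        },
        planted=[{"probe": p, "fold": f} for p, f in planted_up],
    )
    return m, truth


# ---------------------------------------------------------------------------
# A small default model used by examples, tests and the CLI simulator: the
# four anchor elements of the glycolysis-regulated promoter arrangement
# (GRBOX string, an MZF1-like and an EGR1-like matrix, and a TATA string).

def example_model(gap_ranges: Optional[Sequence[tuple[int, int]]] = None) -> RegulatoryModel:
    mzf1 = PositionWeightMatrix(
        "V$MZF1.01",
        np.array([
            [0.05, 0.05, 0.05, 0.85],
            [0.04, 0.88, 0.04, 0.04],
            [0.04, 0.88, 0.04, 0.04],
            [0.04, 0.88, 0.04, 0.04],
            [0.04, 0.88, 0.04, 0.04],
        ]),
    )
    egr1 = PositionWeightMatrix(
        "V$EGR1.02",
        np.array([
            [0.04, 0.04, 0.88, 0.04],
            [0.04, 0.04, 0.88, 0.04],
            [0.04, 0.04, 0.88, 0.04],
            [0.04, 0.88, 0.04, 0.04],
        ]),
    )
    if gap_ranges is None:
        gap_ranges = [(5, 30), (0, 20), (5, 40)]
    return RegulatoryModel(
        name="GRBOX_module",
        elements=[
            ModelElement("GRBOX", IUPACMotif("GRBOX", "CATTGTT", 0)),
            ModelElement("V$MZF1.01", mzf1),
            ModelElement("V$EGR1.02", egr1),
            ModelElement("TATA", IUPACMotif("TATA", "TATAA", 0)),
        ],
        gaps=list(gap_ranges),
    )
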