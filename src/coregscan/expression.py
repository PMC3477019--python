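"""Expression-matrix validation of candidate co-regulated genes.

Intensities (probes x samples) are quantile-normalized, averaged per tissue,
and each probe is tested between two tissues with the two-sided Wilcoxon
rank-sum test; probes with at least a 1.5-fold mean increase in the target
tissue are flagged over-expressed (the flag follows fold change only; raw
p-values and Benjamini-Hochberg FDR are reported alongside).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT = 12  # largest n_a + n_b for automatic exact enumeration


@dataclass
class ExpressionMatrix:
    """Probes x samples intensities with a sample -> tissue grouping."""

    values: pd.DataFrame             # index = probes, columns = samples
    groups: dict[str, str]           # sample -> tissue

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in samples: {bad}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a tissue group: {missing}")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tissue_samples(self, tissue: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == tissue]

    @classmethod
    def from_tsv(cls, matrix_path: Union[str, TextIO], groups_path: Union[str, TextIO]) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        g = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "tissue"],
                        dtype=str, comment="#")
        return cls(values, dict(zip(g["sample"], g["tissue"])))

    def to_tsv(self, matrix_path: str, groups_path: Optional[str] = None) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        if groups_path is not None:
            with open(groups_path, "w") as fh:
                for s in self.samples:
                    fh.write(f"{s}\t{self.groups[s]}\n")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization to the mean of order statistics.

    Each sample's rank r is replaced by the across-sample mean of the r-th
    smallest values; tied entries receive the mean of their ranks' reference
    values.  Afterwards every sample shares an identical sorted value vector.
    A single-sample matrix is returned unchanged with a warning.
    """
    X = m.values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return ExpressionMatrix(m.values.copy(), dict(m.groups))
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(n_probes, dtype=float)
    for j in range(n_samples):
        ranks = rankdata(X[:, j], method="average") - 1.0
        # average ranks are half-integers at worst; linear interpolation on the
        # reference vector yields the mean of the tied ranks' reference values
        out[:, j] = np.interp(ranks, grid, reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        dict(m.groups),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) test

def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by enumeration of all C(n, n_a) group assignments.

    Ties receive midranks; the p-value is the null probability of a rank sum
    at least as extreme (on either side of its mean) as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    n, na = len(pooled), len(a)
    w_obs = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    count = total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            count += 1
    return count / total


def _rank_sum_normal(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    na, nb = len(a), len(b)
    n = na + nb
    w = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0  # all observations tied: no evidence either way
    zed = (abs(w - mu) - 0.5) / math.sqrt(var)
    zed = max(zed, 0.0)
    return min(1.0, 2.0 * norm.sf(zed))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``auto`` enumerates the exact null when the pooled size is at most 12 and
    the data are tie-free, otherwise uses the tie-corrected normal
    approximation.  ``exact`` forces enumeration (midranks handle ties);
    ``normal-approx`` forces the approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        mode = "exact" if (len(a) + len(b) <= EXACT_LIMIT and tie_free) else "normal-approx"
    if mode == "exact":
        if len(a) + len(b) > 24:
            raise ValueError("exact enumeration is limited to pooled sizes <= 24")
        return _rank_sum_exact(a, b)
    if mode == "normal-approx":
        return _rank_sum_normal(a, b)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Tissue comparison

@dataclass
class TissueComparison:
    """Per-probe (or per-gene) target-vs-reference comparison."""

    probe_id: str
    mean_target: float
    mean_reference: float
    fold_change: float          # mean_target / mean_reference; nan if undefined
    log2_ratio: float
    p_value: float
    overexpressed: bool
    fdr: float = math.nan
    fold_undefined: bool = False


def compare_tissues(
    m: ExpressionMatrix,
    target: str,
    reference: str,
    fold_threshold: float = 1.5,
    probe_gene_map: Optional[Mapping[str, str]] = None,
    mode: str = "auto",
) -> list[TissueComparison]:
    """Compare every probe between two tissues.

    Fold change is the ratio of tissue-averaged intensities; the
    over-expression flag is inclusive at ``fold_threshold`` ("at least" 1.5
    fold by default).  ``probe_gene_map`` optionally aggregates probes to
    genes: gene fold change is the average of probe-level ratios and the
    gene p-value comes from Wilcoxon on per-sample means across the gene's
    probes.  Benjamini-Hochberg FDR is filled across the returned rows.
    """
    ts = m.tissue_samples(target)
    rs = m.tissue_samples(reference)
    if not ts or not rs:
        raise ValueError(f"both tissues need >= 1 sample (target {len(ts)}, reference {len(rs)})")
    results: list[TissueComparison] = []

    def one(probe_id, tvals, rvals, fold=None) -> TissueComparison:
        mt, mr = float(np.mean(tvals)), float(np.mean(rvals))
        undefined = False
        if fold is None:
            if mr == 0:
                fold, undefined = math.nan, True
            else:
                fold = mt / mr
        log2r = math.log2(fold) if fold and fold > 0 else math.nan
        p = wilcoxon_rank_sum(tvals, rvals, mode=mode)
        over = (not undefined) and (not math.isnan(fold)) and fold >= fold_threshold
        return TissueComparison(probe_id, mt, mr, fold, log2r, p, over,
                                fold_undefined=undefined)

    if probe_gene_map is None:
        for probe in m.probes:
            row = m.values.loc[probe]
            results.append(one(probe, row[ts].to_numpy(float), row[rs].to_numpy(float)))
    else:
        genes: dict[str, list[str]] = {}
        for probe in m.probes:
            genes.setdefault(probe_gene_map.get(probe, probe), []).append(probe)
        for gene, probes in genes.items():
            sub = m.values.loc[probes]
            tvals = sub[ts].mean(axis=0).to_numpy(float)
            rvals = sub[rs].mean(axis=0).to_numpy(float)
            folds = []
            for probe in probes:
                row = m.values.loc[probe]
                mr = row[rs].mean()
                if mr != 0:
                    folds.append(row[ts].mean() / mr)
            fold = float(np.mean(folds)) if folds else math.nan
            results.append(one(gene, tvals, rvals, fold=fold))

    ps = [r.p_value for r in results]
    if ps:
        fdrs = multipletests(ps, method="fdr_bh")[1]
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    return results


def write_comparisons(rows: Sequence[TissueComparison], path_or_handle: Union[str, TextIO]) -> None:
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_comparisons(rows, fh)
        return
    fh = path_or_handle
    fh.write("id\tmean_target\tmean_reference\tfold_change\tlog2_ratio\t"
             "p_value\tfdr\toverexpressed\n")
    for r in rows:
        fh.write(
            f"{r.probe_id}\t{r.mean_target:.4f}\t{r.mean_reference:.4f}\t"
            f"{r.fold_change:.4f}\t{r.log2_ratio:.4f}\t{r.p_value:.4g}\t"
            f"{r.fdr:.4g}\t{int(r.overexpressed)}\n"
        )


def plot_comparison(
    rows: Sequence[TissueComparison], path: str,
    target: str = "target", reference: str = "reference",
) -> None:
    """Scatter of tissue means with over-expressed probes highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    over = [r for r in rows if r.overexpressed]
    rest = [r for r in rows if not r.overexpressed]
    ax.scatter([r.mean_reference for r in rest], [r.mean_target for r in rest],
               s=10, c="grey", label="other")
    ax.scatter([r.mean_reference for r in over], [r.mean_target for r in over],
               s=14, c="red", marker="D", label=">= 1.5-fold")
    lim = max(max((r.mean_reference for r in rows), default=1),
              max((r.mean_target for r in rows), default=1))
    ax.plot([0, lim], [0, lim], lw=0.5, c="black")
    ax.set_xlabel(f"mean intensity, {reference}")
    ax.set_ylabel(f"mean intensity, {target}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
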