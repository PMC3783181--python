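"""Per-gene sensitivity to tRNA-availability shifts, ranking and genome context.

The sensitivity of a gene between a reference condition c1 and an
alternative c2 is the length-normalized L1 distance between its two
smoothed time profiles,

    S = (1/l) * sum_j | t_j^{c1} - t_j^{c2} | ,

with *l* the number of smoothed positions.  S is a metric on profiles
(up to the shared gene/length precondition) and scales linearly with a
uniform time scaling.

The module also provides the genome-wide companions: ranking with
head/tail slicing, rank-based group comparison, fixed-width genome
binning with per-bin metric averages, the codon adaptation index, and
Spearman correlation of gene-level covariates with S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .codon_rates import STOP_CODONS
from .profiles import CodingSequence, SpeedProfile
from .trna_io import bundled_path

__all__ = [
    "SensitivityResult",
    "GenomeBin",
    "GroupComparison",
    "CorrelationResult",
    "sensitivity",
    "sensitivity_table",
    "rank_and_slice",
    "group_compare",
    "bin_genome",
    "cai",
    "cai_weights_from_counts",
    "read_cai_weights",
    "bundled_cai_weights",
    "correlate",
    "write_sensitivity_tsv",
    "write_bins_tsv",
]


@dataclass(frozen=True)
class SensitivityResult:
    gene_id: str
    condition_pair: Tuple[str, str]
    S: float
    l: int

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("sensitivity cannot be negative")


def sensitivity(p_ref: SpeedProfile, p_alt: SpeedProfile) -> SensitivityResult:
    """Length-normalized absolute difference between two smoothed profiles."""
    if p_ref.gene_id != p_alt.gene_id:
        raise ValueError(f"profiles are for different genes: {p_ref.gene_id} vs {p_alt.gene_id}")
    if len(p_ref) != len(p_alt):
        raise ValueError(f"{p_ref.gene_id}: profile length mismatch {len(p_ref)} vs {len(p_alt)}")
    if p_ref.window != p_alt.window:
        raise ValueError(f"{p_ref.gene_id}: smoothing windows differ")
    diff = np.abs(p_ref.smoothed_times - p_alt.smoothed_times)
    return SensitivityResult(
        gene_id=p_ref.gene_id,
        condition_pair=(p_ref.condition, p_alt.condition),
        S=float(diff.mean()),
        l=len(p_ref),
    )


def sensitivity_table(
    profiles_by_condition: Mapping[str, Mapping[str, SpeedProfile]],
    reference_condition: str,
) -> List[SensitivityResult]:
    """S for every gene under every non-reference condition.

    Genes missing a profile under either condition of a pair are skipped
    for that pair.
    """
    ref = profiles_by_condition[reference_condition]
    out: List[SensitivityResult] = []
    for cond, per_gene in profiles_by_condition.items():
        if cond == reference_condition:
            continue
        for gene_id, p_alt in per_gene.items():
            if gene_id in ref:
                out.append(sensitivity(ref[gene_id], p_alt))
    return out


_EXCLUDED_CATEGORIES = frozenset({"untranslated", "pseudo"})


def rank_and_slice(
    results: Sequence[SensitivityResult],
    fraction: float = 0.10,
    categories: Optional[Mapping[str, Optional[str]]] = None,
) -> Tuple[List[str], List[str]]:
    """The most- and least-sensitive gene lists at a given fraction.

    Genes tagged ``untranslated`` or ``pseudo`` are excluded before
    slicing.  Ties at either cut are broken by lexicographic gene id, so
    the slices are deterministic across runs.  Returns
    ``(most_sensitive, least_sensitive)``, each of
    ``ceil(fraction * n)`` genes, ordered by descending / ascending S.
    """
    if not results:
        raise ValueError("empty result list")
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    categories = categories or {}
    kept = [r for r in results if categories.get(r.gene_id) not in _EXCLUDED_CATEGORIES]
    n_slice = max(1, math.ceil(fraction * len(kept)))
    by_desc = sorted(kept, key=lambda r: (-r.S, r.gene_id))
    by_asc = sorted(kept, key=lambda r: (r.S, r.gene_id))
    return (
        [r.gene_id for r in by_desc[:n_slice]],
        [r.gene_id for r in by_asc[:n_slice]],
    )


@dataclass(frozen=True)
class GroupComparison:
    """One-sided Wilcoxon rank-sum comparison of S between two gene groups."""

    n_a: int
    n_b: int
    statistic: float
    pvalue: float
    test: str = "wilcoxon_rank_sum_one_sided_greater"


def group_compare(
    results: Sequence[SensitivityResult],
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> GroupComparison:
    """Test whether group A's sensitivities are located above group B's.

    One-sided Wilcoxon rank-sum (Mann-Whitney U with alternative
    "greater").  Groups must be disjoint and nonempty after restriction
    to genes present in ``results``.  With singleton groups the exact
    null has only two orderings, so the smallest attainable p is 0.5.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError("groups overlap")
    s = {r.gene_id: r.S for r in results}
    a = [s[g] for g in sorted(group_a) if g in s]
    b = [s[g] for g in sorted(group_b) if g in s]
    if not a or not b:
        raise ValueError("a group is empty (after matching against the results)")
    stat, p = stats.mannwhitneyu(a, b, alternative="greater")
    return GroupComparison(n_a=len(a), n_b=len(b), statistic=float(stat), pvalue=float(p))


# ---------------------------------------------------------------------------
# Genome binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeBin:
    index: int
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    member_genes: Tuple[str, ...]
    means: Mapping[str, float]  # metric name -> mean over member genes

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_genes", tuple(self.member_genes))
        object.__setattr__(self, "means", dict(self.means))

    @property
    def empty(self) -> bool:
        return not self.member_genes


def bin_genome(
    genes: Sequence[CodingSequence],
    genome_length: int,
    n_bins: int = 200,
    metrics: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> List[GenomeBin]:
    """Tile the genome into ``n_bins`` equal stretches and average per bin.

    Bin width is ``genome_length // n_bins`` (the last bin absorbs the
    remainder); a gene belongs to the bin containing its start
    coordinate.  ``metrics`` maps a metric name (e.g. a condition label,
    ``"CAI"``, ``"GC"``) to per-gene values; each bin reports the mean
    over its member genes that carry the metric.  ``"GC"`` is always
    computed from the sequences themselves.
    """
    if n_bins < 1 or genome_length < n_bins:
        raise ValueError("need genome_length >= n_bins >= 1")
    width = genome_length // n_bins
    metrics = dict(metrics or {})
    metrics.setdefault("GC", {g.id: g.gc_fraction for g in genes})
    members: List[List[str]] = [[] for _ in range(n_bins)]
    for g in genes:
        if g.genome_start is None:
            raise ValueError(f"{g.id}: no genome coordinate")
        if not 1 <= g.genome_start <= genome_length:
            raise ValueError(
                f"{g.id}: start {g.genome_start} outside genome of length {genome_length}"
            )
        idx = min((g.genome_start - 1) // width, n_bins - 1)
        members[idx].append(g.id)
    bins = []
    for i in range(n_bins):
        start = i * width + 1
        end = genome_length if i == n_bins - 1 else (i + 1) * width
        means = {}
        for name, per_gene in metrics.items():
            vals = [per_gene[g] for g in members[i] if g in per_gene]
            means[name] = float(np.mean(vals)) if vals else math.nan
        bins.append(GenomeBin(index=i, start=start, end=end, member_genes=members[i], means=means))
    return bins


# ---------------------------------------------------------------------------
# CAI and correlations
# ---------------------------------------------------------------------------

def cai(
    cds: CodingSequence,
    reference_weights: Mapping[str, float],
    zero_floor: float = 0.01,
) -> float:
    """Codon adaptation index: geometric mean of relative codon weights.

    ``reference_weights`` maps each sense codon to its relative
    adaptiveness (1 for the preferred synonym).  Codons with weight 0 in
    the reference set are substituted by ``zero_floor`` so the geometric
    mean stays defined.
    """
    weights = []
    for codon in cds.codons:
        if codon in STOP_CODONS:
            continue
        try:
            w = reference_weights[codon]
        except KeyError as exc:
            raise ValueError(f"{cds.id}: no reference weight for codon {exc}") from exc
        weights.append(w if w > 0 else zero_floor)
    if not weights:
        raise ValueError(f"{cds.id}: no codons to score")
    return float(np.exp(np.mean(np.log(weights))))


def cai_weights_from_counts(counts: Mapping[str, int]) -> Dict[str, float]:
    """Relative adaptiveness from codon counts of a highly expressed gene set.

    Within each synonymous family the most frequent codon gets weight 1
    and the others their count ratio to it.
    """
    from Bio.Data.CodonTable import unambiguous_rna_by_id

    table = unambiguous_rna_by_id[11].forward_table
    families: Dict[str, List[str]] = {}
    for codon, aa in table.items():
        families.setdefault(aa, []).append(codon)
    weights: Dict[str, float] = {}
    for codons in families.values():
        top = max(counts.get(c, 0) for c in codons)
        for c in codons:
            weights[c] = counts.get(c, 0) / top if top > 0 else 0.0
    return weights


def read_cai_weights(path) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(c).upper().replace("T", "U"): float(w)
        for c, w in zip(df["codon"], df["weight"])
    }


def bundled_cai_weights() -> Dict[str, float]:
    """Bundled synthetic example weight table (not derived from real data)."""
    return read_cai_weights(bundled_path("synthetic_cai_weights.tsv"))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    pvalue: float
    r_squared: float  # goodness of fit of the rank-rank linear relation
    n: int
    defined: bool = True


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation of a gene covariate against sensitivity.

    Ties are handled by midranks (scipy).  Constant input leaves the
    correlation undefined; the result is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(math.nan, math.nan, math.nan, int(x.size), defined=False)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), float(rho) ** 2, int(x.size))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_sensitivity_tsv(results: Sequence[SensitivityResult], path) -> None:
    """Gene, condition pair, l, S, rank and percentile (per condition pair)."""
    rows = []
    for (c1, c2) in sorted({r.condition_pair for r in results}):
        group = sorted(
            (r for r in results if r.condition_pair == (c1, c2)),
            key=lambda r: (-r.S, r.gene_id),
        )
        n = len(group)
        for rank, r in enumerate(group, start=1):
            rows.append(
                {
                    "gene": r.gene_id,
                    "c1": c1,
                    "c2": c2,
                    "l": r.l,
                    "S": r.S,
                    "rank": rank,
                    "percentile": 100.0 * (n - rank + 1) / n,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bins_tsv(bins: Sequence[GenomeBin], path) -> None:
    metric_names = sorted({m for b in bins for m in b.means})
    rows = []
    for b in bins:
        row = {"index": b.index, "start": b.start, "end": b.end, "n_genes": len(b.member_genes)}
        for m in metric_names:
            row[f"mean_{m}"] = b.means.get(m, math.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
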