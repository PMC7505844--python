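"""Clonotype assignment and per-clone tissue-enrichment statistics.

A cell's clonotype is the combined alpha- and beta-chain CDR3 nucleotide
sequences.  Cells flagged as multiplets because they carry two or more beta
chains cannot have their alpha/beta pairing resolved, so (optionally) all
cells sharing that exact beta-chain set are treated as a single clone keyed on
the beta chains alone; alpha-only and empty cells never join a clone.

Per-clone enrichment between two compartments of the same patient (e.g.
synovial fluid vs blood) uses a two-sided Fisher's exact test with
Benjamini-Hochberg correction across all clones of that patient pair, calling
a clone enriched in the compartment with the higher proportion when the
adjusted p value is at or below the significance level.  Association of
enriched cells with phenotype clusters uses Fisher tests with Bonferroni
correction across clusters.
"""
from __future__ import annotations

import math
from collections import Counter, OrderedDict
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import UsageError
from .vdj_io import CellPartition, PartitionStatus

#: relative tolerance used when comparing hypergeometric probabilities, as in
#: the conventional two-sided Fisher tail summation
_REL_TOL = 1e-7

CellKey = tuple[str, str, str]  # (patient_id, sample_id, barcode)


@dataclass(frozen=True)
class Clone:
    clone_id: str
    key: str
    alpha_nt: tuple[str, ...]
    beta_nt: tuple[str, ...]
    member_cells: tuple[CellKey, ...]
    chain_class: str = "UNKNOWN"  # CD4 / CD8 / UNKNOWN

    @property
    def size(self) -> int:
        return len(self.member_cells)


@dataclass
class ClonotypeTable:
    """Partition of eligible cells of one patient into clones."""

    patient_id: str
    clones: list[Clone]
    per_sample_counts: dict[tuple[str, str], int]  # (clone_id, sample_id) -> n

    def sample_total(self, sample_id: str) -> int:
        return sum(n for (_, s), n in self.per_sample_counts.items() if s == sample_id)

    def clone_by_id(self, clone_id: str) -> Clone:
        for clone in self.clones:
            if clone.clone_id == clone_id:
                return clone
        raise KeyError(clone_id)

    @property
    def n_cells(self) -> int:
        return sum(c.size for c in self.clones)


@dataclass(frozen=True)
class EnrichmentResult:
    clone_id: str
    key: str
    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: float
    p_raw: float
    p_adj: float
    enriched_in: str | None


@dataclass(frozen=True)
class ClusterAssociation:
    cluster_label: str
    table: tuple[int, int, int, int]
    odds_ratio: float
    p_raw: float
    p_adj: float


def clone_key(alpha_nt: Iterable[str], beta_nt: Iterable[str]) -> str:
    """Canonical clonotype key, invariant to the ordering of a cell's chains."""
    return "|".join(sorted(alpha_nt)) + "+" + "|".join(sorted(beta_nt))


def assign_clonotypes(
    partitions: Sequence[CellPartition],
    include_multiplet_beta: bool = True,
    chain_class_of: Mapping[str, str] | Callable[[CellKey], str] | None = None,
) -> ClonotypeTable:
    """Group eligible cells of one patient into clones.

    OK cells are keyed on their (sorted) alpha CDR3 nucleotide tuple plus beta
    CDR3.  When ``include_multiplet_beta`` is true, multiplet cells carrying
    two or more beta chains are keyed on the sorted beta tuple alone (pairing
    is unknowable) and form clones of their own; when false they are excluded,
    as is appropriate whenever clonality is linked to expression data.
    Multiplets flagged only for excess alpha chains, alpha-only cells and
    empty cells never become clone members.
    """
    patients = {p.patient_id for p in partitions}
    if len(patients) > 1:
        raise UsageError(f"clonotypes are per-patient entities; got patients {sorted(patients)}")
    patient_id = next(iter(patients)) if patients else ""

    members: "OrderedDict[tuple[tuple[str, ...], tuple[str, ...]], list[CellKey]]" = OrderedDict()
    for part in partitions:
        if part.status == PartitionStatus.OK:
            key = (tuple(sorted(r.cdr3_nt for r in part.alpha_chains)),
                   tuple(r.cdr3_nt for r in part.beta_chains))
        elif (part.status == PartitionStatus.MULTIPLET
              and include_multiplet_beta and len(part.beta_chains) >= 2):
            key = ((), tuple(sorted(r.cdr3_nt for r in part.beta_chains)))
        else:
            continue
        members.setdefault(key, []).append(part.cell_key)

    def _chain_class(cells: list[CellKey]) -> str:
        if chain_class_of is None:
            return "UNKNOWN"
        votes: Counter[str] = Counter()
        for cell in cells:
            label = (chain_class_of(cell) if callable(chain_class_of)
                     else chain_class_of.get(cell[2], ""))
            if label in ("CD4", "CD8"):
                votes[label] += 1
        if not votes:
            return "UNKNOWN"
        (top, n), *rest = votes.most_common(2)
        if rest and rest[0][1] == n:
            return "UNKNOWN"
        return top

    ordered = sorted(members.items(), key=lambda kv: (-len(kv[1]), clone_key(*kv[0])))
    clones: list[Clone] = []
    counts: dict[tuple[str, str], int] = {}
    for idx, ((alpha, beta), cells) in enumerate(ordered):
        clone_id = f"{patient_id}_C{idx + 1:04d}"
        clones.append(Clone(clone_id=clone_id, key=clone_key(alpha, beta),
                            alpha_nt=alpha, beta_nt=beta,
                            member_cells=tuple(cells),
                            chain_class=_chain_class(cells)))
        for _, sample_id, _ in cells:
            counts[(clone_id, sample_id)] = counts.get((clone_id, sample_id), 0) + 1
    return ClonotypeTable(patient_id=patient_id, clones=clones, per_sample_counts=counts)


def cross_product_odds_ratio(
    table: tuple[int, int, int, int], haldane: bool = False
) -> float:
    """Unconditional cross-product odds ratio (a*d)/(b*c).

    ``haldane`` applies the Haldane-Anscombe 0.5 continuity correction (for
    display only); without it, a zero denominator yields +inf when the
    numerator is positive and NaN when both products are zero.
    """
    a, b, c, d = table
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    ad, bc = a * d, b * c
    if bc == 0:
        return math.nan if ad == 0 else math.inf
    return ad / bc


def fisher_exact_2x2(table: tuple[int, int, int, int]) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table ``(a, b, c, d)``.

    Returns ``(odds_ratio, p)`` where p is the sum of hypergeometric
    probabilities (margins fixed) of all tables at most as probable as the
    observed one, and the odds ratio is the cross-product ratio.
    """
    a, b, c, d = table
    for entry in table:
        if entry < 0 or int(entry) != entry:
            raise ValueError(f"table entries must be nonnegative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    odds = cross_product_odds_ratio((a, b, c, d))
    if n == 0 or row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return odds, 1.0
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return odds, min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values (order-aligned, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    # p * m / rank can round one ulp below p when m == rank; the adjusted
    # value can never be smaller than the raw one
    return np.maximum(out, p).tolist()


def test_clonal_enrichment(
    clonotypes: ClonotypeTable,
    sample_pair: tuple[str, str],
    alpha_level: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-clone compartment enrichment between two samples of one patient.

    For each clone observed in either sample, the 2x2 table compares clone
    cells vs all other eligible cells across the pair.  The BH family is the
    set of all such clones; a clone is called enriched (inclusively at
    ``alpha_level``) in the sample where its proportion is higher.
    """
    sample_a, sample_b = sample_pair
    total_a = clonotypes.sample_total(sample_a)
    total_b = clonotypes.sample_total(sample_b)
    if total_a == 0 or total_b == 0:
        raise UsageError(
            f"both samples need at least one eligible cell (got {sample_a}={total_a}, "
            f"{sample_b}={total_b})")

    rows: list[tuple[Clone, tuple[int, int, int, int], float, float]] = []
    for clone in clonotypes.clones:
        a = clonotypes.per_sample_counts.get((clone.clone_id, sample_a), 0)
        c = clonotypes.per_sample_counts.get((clone.clone_id, sample_b), 0)
        if a == 0 and c == 0:
            continue
        table = (a, total_a - a, c, total_b - c)
        odds, p = fisher_exact_2x2(table)
        rows.append((clone, table, odds, p))

    adjusted = bh_adjust([p for *_, p in rows])
    results: list[EnrichmentResult] = []
    for (clone, table, odds, p), p_adj in zip(rows, adjusted):
        a, b, c, d = table
        prop_a, prop_b = a / (a + b), c / (c + d)
        enriched_in: str | None = None
        if p_adj <= alpha_level and prop_a != prop_b:
            enriched_in = sample_a if prop_a > prop_b else sample_b
        results.append(EnrichmentResult(clone_id=clone.clone_id, key=clone.key,
                                        table=table, odds_ratio=odds, p_raw=p,
                                        p_adj=p_adj, enriched_in=enriched_in))
    return results


def associate_clusters(
    enriched_cells: Iterable[Hashable],
    cell_clusters: Mapping[Hashable, str],
) -> list[ClusterAssociation]:
    """Test each phenotype cluster for overrepresentation of enriched-clone cells.

    ``cell_clusters`` maps every analysed cell to its cluster label;
    ``enriched_cells`` must be a subset of those cells.  One two-sided Fisher
    test per cluster with at least one cell, Bonferroni-corrected over the
    number of clusters tested.
    """
    enriched = set(enriched_cells)
    if not enriched:
        raise UsageError("enriched cell set is empty")
    missing = enriched - set(cell_clusters)
    if missing:
        raise UsageError(f"{len(missing)} enriched cells are absent from the cell universe")
    labels = sorted(set(cell_clusters.values()))
    if len(labels) < 2:
        raise UsageError("need at least two distinct cluster labels")

    n_enr = len(enriched)
    n_non = len(cell_clusters) - n_enr
    per_label: Counter[str] = Counter(cell_clusters.values())
    enr_per_label: Counter[str] = Counter(cell_clusters[c] for c in enriched)

    tested = [lab for lab in labels if per_label[lab] > 0]
    m = len(tested)
    results = []
    for lab in tested:
        a = enr_per_label.get(lab, 0)
        c = per_label[lab] - a
        table = (a, n_enr - a, c, n_non - c)
        odds, p = fisher_exact_2x2(table)
        results.append(ClusterAssociation(cluster_label=lab, table=table,
                                          odds_ratio=odds, p_raw=p,
                                          p_adj=min(1.0, p * m)))
    return results


def subsample_equal_depth(
    cells: Mapping[str, Sequence],
    target: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, list]:
    """Uniform random equal-depth subsets, one per sample, reproducible under seed.

    With no explicit ``target`` the smallest sample size is used; an explicit
    target larger than some sample is a usage error.  Selected cells keep
    their original within-sample order.
    """
    sizes = {name: len(seq) for name, seq in cells.items()}
    if target is None:
        if not sizes:
            return {}
        target = min(sizes.values())
    else:
        too_small = {k: v for k, v in sizes.items() if v < target}
        if too_small:
            raise UsageError(f"samples smaller than target {target}: {too_small}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, list] = {}
    for name in sorted(cells):
        seq = cells[name]
        idx = np.sort(rng.choice(len(seq), size=target, replace=False))
        out[name] = [seq[i] for i in idx]
    return out
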