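"""GLIPH-style TCR convergence (specificity) grouping on beta-chain CDR3s.

Two sequences are linked *globally* when their CDR3 amino-acid sequences have
equal length and Hamming distance at most one, and *locally* when they share a
short interior motif (k-mer with the flanking residues trimmed) that is
enriched in the sample relative to an unselected naive reference repertoire.
Motif enrichment is scored by the observed/reference frequency fold change and
a resampling p value: the fraction of random reference subsets, of the same
size as the sample, whose motif frequency reaches the observed one, floored at
1/n_subsamples.  Convergence groups are the connected components (>= 2
members) of the union graph.
"""
from __future__ import annotations

import logging
import math
from collections import Counter, OrderedDict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import UsageError
from .vdj_io import CellPartition, PartitionStatus

log = logging.getLogger(__name__)

DEFAULT_K_VALUES: tuple[int, ...] = (2, 3, 4)
DEFAULT_FLANK_TRIM = 3


@dataclass(frozen=True)
class GliphSequence:
    seq_id: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    patient_id: str
    source_cells: int


@dataclass
class GliphInputSet:
    sequences: list[GliphSequence]
    reference: list[str]


@dataclass(frozen=True)
class MotifResult:
    motif: str
    k: int
    observed_freq: float
    reference_freq: float
    fold_change: float
    p_resampled: float
    sample_count: int


@dataclass(frozen=True)
class ConvergenceGroup:
    crg_id: str
    members: frozenset[str]
    motifs: tuple[MotifResult, ...]
    patients_represented: frozenset[str]
    edge_types: Mapping[tuple[str, str], str]

    @property
    def size(self) -> int:
        return len(self.members)


def prepare_gliph_input(
    partitions: Sequence[CellPartition],
    reference: Sequence[str],
    *,
    report: dict | None = None,
) -> GliphInputSet:
    """Build the beta-chain sequence set for convergence grouping.

    Single-beta partitions are aggregated to one entry per unique
    (CDR3aa, V, J) per patient with cell counts summed.  Multi-beta multiplet
    partitions cannot be resolved, so each of their beta chains is emitted as
    a separate entry whose id carries a ``-v<i>`` variant suffix.  Alpha-only
    partitions contribute nothing (counted).
    """
    if len(reference) == 0:
        raise UsageError("empty naive reference CDR3 set")
    dropped_alpha_only = 0
    aggregated: "OrderedDict[tuple[str, str, str, str], int]" = OrderedDict()
    variant_entries: list[GliphSequence] = []
    for part in partitions:
        if not part.beta_chains:
            if part.status == PartitionStatus.ALPHA_ONLY:
                dropped_alpha_only += 1
            continue
        if len(part.beta_chains) >= 2:
            for i, rec in enumerate(sorted(part.beta_chains, key=lambda r: r.cdr3_aa)):
                variant_entries.append(GliphSequence(
                    seq_id=(f"{part.patient_id}:{rec.v_gene}:{rec.j_gene}:"
                            f"{rec.cdr3_aa}:{part.barcode}-v{i + 1}"),
                    cdr3_aa=rec.cdr3_aa, v_gene=rec.v_gene, j_gene=rec.j_gene,
                    patient_id=part.patient_id, source_cells=1))
            continue
        rec = part.beta_chains[0]
        key = (part.patient_id, rec.cdr3_aa, rec.v_gene, rec.j_gene)
        aggregated[key] = aggregated.get(key, 0) + 1
    sequences = [
        GliphSequence(seq_id=f"{patient}:{v}:{j}:{aa}", cdr3_aa=aa, v_gene=v,
                      j_gene=j, patient_id=patient, source_cells=n)
        for (patient, aa, v, j), n in aggregated.items()
    ] + variant_entries
    if dropped_alpha_only:
        log.info("dropped %d alpha-only partitions from convergence input",
                 dropped_alpha_only)
    if report is not None:
        report["alpha_only_dropped"] = dropped_alpha_only
        report["n_sequences"] = len(sequences)
    return GliphInputSet(sequences=sequences, reference=list(reference))


def interior(cdr3_aa: str, flank_trim: int = DEFAULT_FLANK_TRIM) -> str:
    """CDR3 with ``flank_trim`` residues removed from each end ('' if too short)."""
    if len(cdr3_aa) <= 2 * flank_trim:
        return ""
    return cdr3_aa[flank_trim: len(cdr3_aa) - flank_trim]


def motif_set(
    cdr3_aa: str,
    k_values: Iterable[int] = DEFAULT_K_VALUES,
    flank_trim: int = DEFAULT_FLANK_TRIM,
) -> set[str]:
    """Distinct interior k-mers of one CDR3 (presence semantics)."""
    core = interior(cdr3_aa, flank_trim)
    out: set[str] = set()
    for k in k_values:
        for i in range(len(core) - k + 1):
            out.add(core[i: i + k])
    return out


def enumerate_motifs(
    cdr3_set: Iterable[str],
    k_values: Iterable[int] = DEFAULT_K_VALUES,
    flank_trim: int = DEFAULT_FLANK_TRIM,
) -> dict[str, int]:
    """Count, over a set of CDR3s, how many sequences contain each interior k-mer.

    A motif is counted at most once per sequence; CDR3s shorter than
    ``2 * flank_trim + k`` contribute nothing at that k.
    """
    bad = [k for k in k_values if k not in (2, 3, 4)]
    if bad:
        raise UsageError(f"k values must be within {{2,3,4}}, got {bad}")
    if flank_trim < 0:
        raise UsageError("flank_trim must be nonnegative")
    counts: Counter[str] = Counter()
    for seq in cdr3_set:
        counts.update(motif_set(seq, k_values, flank_trim))
    return dict(counts)


def motif_enrichment(
    sample: GliphInputSet,
    k_values: Iterable[int] = DEFAULT_K_VALUES,
    n_subsamples: int = 1000,
    seed: int | np.random.Generator | None = None,
    flank_trim: int = DEFAULT_FLANK_TRIM,
) -> list[MotifResult]:
    """Score every sample motif against the naive reference repertoire.

    For each motif present in the sample: ``observed_freq`` is the fraction of
    unique sample CDR3 sequences containing it, ``reference_freq`` the same
    fraction in the reference, ``fold_change`` their ratio (+inf when the
    reference lacks the motif), and ``p_resampled`` the fraction of
    ``n_subsamples`` random reference subsets (of the unique-sample size,
    drawn without replacement) whose motif frequency is at least the observed
    one, floored at ``1/n_subsamples``.
    """
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    k_values = tuple(sorted(set(k_values)))
    # the motif universe is the set of unique CDR3 amino-acid sequences:
    # multiplet variant entries duplicating a known CDR3 must not inflate
    # motif support
    seqs = sorted({s.cdr3_aa for s in sample.sequences})
    n = len(seqs)
    n_ref = len(sample.reference)
    if n_ref < n:
        raise UsageError(f"reference ({n_ref}) must be at least sample size ({n})")

    sample_counts = enumerate_motifs(seqs, k_values, flank_trim)
    motifs = sorted(sample_counts)
    if not motifs:
        return []
    motif_index = {m: i for i, m in enumerate(motifs)}
    obs_counts = np.array([sample_counts[m] for m in motifs])

    # reference presence matrix restricted to sample motifs
    presence = np.zeros((n_ref, len(motifs)), dtype=np.uint8)
    for row, ref_seq in enumerate(sample.reference):
        for m in motif_set(ref_seq, k_values, flank_trim):
            idx = motif_index.get(m)
            if idx is not None:
                presence[row, idx] = 1
    ref_counts = presence.sum(axis=0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = np.zeros(len(motifs), dtype=np.int64)
    chunk = max(1, min(200, n_subsamples))
    done = 0
    while done < n_subsamples:
        size = min(chunk, n_subsamples - done)
        idx = np.stack([rng.choice(n_ref, size=n, replace=False) for _ in range(size)])
        counts = presence[idx].sum(axis=1)  # (size, n_motifs)
        hits += (counts >= obs_counts).sum(axis=0)
        done += size

    floor = 1.0 / n_subsamples
    results = []
    for i, motif in enumerate(motifs):
        obs_f = obs_counts[i] / n
        ref_f = ref_counts[i] / n_ref
        fold = math.inf if ref_f == 0 else obs_f / ref_f
        p = max(hits[i] / n_subsamples, floor)
        results.append(MotifResult(motif=motif, k=len(motif), observed_freq=obs_f,
                                   reference_freq=ref_f, fold_change=fold,
                                   p_resampled=p, sample_count=int(obs_counts[i])))
    results.sort(key=lambda m: (m.p_resampled, -m.observed_freq, m.motif))
    return results


def global_edges(sequences: Sequence[GliphSequence]) -> list[tuple[str, str]]:
    """Pairs of sequence ids with equal CDR3 length and Hamming distance <= 1."""
    buckets: dict[str, list[int]] = {}
    for i, s in enumerate(sequences):
        seq = s.cdr3_aa
        for pos in range(len(seq)):
            key = f"{pos}:{seq[:pos]}*{seq[pos + 1:]}"
            buckets.setdefault(key, []).append(i)
    pairs: set[tuple[str, str]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i, j in combinations(members, 2):
            a, b = sequences[i].seq_id, sequences[j].seq_id
            if a != b:
                pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)


def build_convergence_groups(
    sequences: Sequence[GliphSequence],
    motif_results: Sequence[MotifResult],
    fold_min: float = 10.0,
    p_max: float = 0.001,
    min_depth: int = 3,
    k_values: Iterable[int] = DEFAULT_K_VALUES,
    flank_trim: int = DEFAULT_FLANK_TRIM,
) -> list[ConvergenceGroup]:
    """Connected components of the global + local (enriched shared motif) graph.

    Local edges connect all sequences sharing a motif with fold change at
    least ``fold_min``, resampled p at most ``p_max`` and sample support of at
    least ``min_depth`` sequences.  Groups (components with >= 2 members) are
    ordered by descending size, ties broken by lexicographically smallest
    member id.
    """
    passing = [m for m in motif_results
               if m.p_resampled <= p_max and m.sample_count >= min_depth
               and m.fold_change >= fold_min]

    graph = nx.Graph()
    graph.add_nodes_from(s.seq_id for s in sequences)
    edge_types: dict[tuple[str, str], str] = {}
    for a, b in global_edges(sequences):
        graph.add_edge(a, b)
        edge_types[(a, b)] = "GLOBAL"

    motif_members: dict[str, list[str]] = {}
    if passing:
        wanted = {m.motif for m in passing}
        for s in sequences:
            for motif in motif_set(s.cdr3_aa, k_values, flank_trim) & wanted:
                motif_members.setdefault(motif, []).append(s.seq_id)
    for motif in sorted(motif_members):
        for a, b in combinations(sorted(set(motif_members[motif])), 2):
            edge = (a, b) if a < b else (b, a)
            graph.add_edge(*edge)
            edge_types.setdefault(edge, "LOCAL")  # GLOBAL takes precedence

    patient_of = {s.seq_id: s.patient_id for s in sequences}
    cdr3_of = {s.seq_id: s.cdr3_aa for s in sequences}
    # a component must span >= 2 distinct (patient, CDR3) combinations:
    # duplicate entries of one clone (multiplet variants) are not convergence
    components = [
        frozenset(c) for c in nx.connected_components(graph)
        if len(c) >= 2 and len({(patient_of[s], cdr3_of[s]) for s in c}) >= 2
    ]
    components.sort(key=lambda c: (-len(c), min(c)))

    groups = []
    for i, comp in enumerate(components):
        support = tuple(m for m in passing
                        if len(set(motif_members.get(m.motif, ())) & comp) >= 2)
        comp_edges = {e: t for e, t in edge_types.items()
                      if e[0] in comp and e[1] in comp}
        groups.append(ConvergenceGroup(
            crg_id=f"CRG-{i + 1}", members=comp,
            motifs=support,
            patients_represented=frozenset(patient_of[s] for s in comp),
            edge_types=comp_edges))
    return groups
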