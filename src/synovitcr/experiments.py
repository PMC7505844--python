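"""Validation experiments: oracle sweeps, calibration and planted-truth recovery.

Every function here recomputes its quantity from scratch by running the
package on freshly simulated inputs, so the same code backs both the test
suite and the reproducibility script.  Oracles (exact-rational Fisher
enumeration, direct Benjamini-Hochberg step-up, exhaustive subset
enumeration for resampled motif p values) are implemented independently of
the code paths they check.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import math
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np

from . import clonality, convergence, pipeline, summary_stats, synthetic_data, vdj_io

# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def fisher_p_by_enumeration(table: tuple[int, int, int, int]) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact rational arithmetic; a table is included when its probability is at
    most the observed one within relative tolerance 1e-7 (the tie rule of the
    implementation under test), so the only possible disagreement is floating
    error in the implementation itself.
    """
    a, b, c, d = (int(x) for x in table)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    denom = comb(n, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {k: Fraction(comb(col1, k) * comb(n - col1, row1 - k), denom)
             for k in range(lo, hi + 1)}
    cutoff = probs[a] * (1 + Fraction(1, 10**7))
    return float(sum(p for p in probs.values() if p <= cutoff))


def bh_by_definition(p_values: list[float]) -> list[float]:
    """Plain step-up BH: p_(i) * m / i with a cumulative min from the largest rank."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


# --------------------------------------------------------------------------
# oracle sweeps
# --------------------------------------------------------------------------

def fisher_oracle_sweep(n_tables: int = 1000, seed: int = 0) -> float:
    """Max relative p error of fisher_exact_2x2 vs enumeration (margins <= 40)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        table = tuple(int(x) for x in rng.integers(0, 11, size=4))
        p_impl = clonality.fisher_exact_2x2(table)[1]
        p_oracle = fisher_p_by_enumeration(table)
        denom = max(p_oracle, 1e-300)
        worst = max(worst, abs(p_impl - p_oracle) / denom)
    return worst


def bh_oracle_sweep(n_vectors: int = 1000, seed: int = 1) -> float:
    """Max absolute deviation of bh_adjust from the step-up definition."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        length = int(rng.integers(1, 201))
        p = rng.uniform(0, 1, size=length).tolist()
        impl = clonality.bh_adjust(p)
        oracle = bh_by_definition(p)
        worst = max(worst, max(abs(x - y) for x, y in zip(impl, oracle)))
    return worst


# --------------------------------------------------------------------------
# clonal enrichment calibration and power
# --------------------------------------------------------------------------

def _calibration_config(seed: int, planted: int) -> synthetic_data.RepertoireConfig:
    """Single-patient paired compartments: 300 background clones, 2x2000 cells."""
    return synthetic_data.RepertoireConfig(
        n_patients=1,
        cells_per_sample={"PBMC": 2000, "SFMC": 2000},
        n_clones=300,
        n_planted_enriched=planted,
        planted_groups=(),
        seed=seed,
    )


def _enrich_one(cfg: synthetic_data.RepertoireConfig):
    sim = synthetic_data.simulate_repertoire(cfg)
    records = vdj_io.records_from_frame(sim.contigs)
    parts = vdj_io.build_cell_partitions(records)
    table = clonality.assign_clonotypes(parts)
    patient = cfg.patient_ids()[0]
    pair = (f"{patient}_{cfg.enriched_sample}",
            *(f"{patient}_{s}" for s in sorted(cfg.cells_per_sample)
              if s != cfg.enriched_sample))
    results = clonality.test_clonal_enrichment(table, pair[:2])
    return sim, results, pair[0]


def null_calibration(n_replicates: int = 200, seed: int = 2) -> float:
    """Fraction of no-effect replicates with >= 1 enriched call at BH <= 0.05."""
    flagged = 0
    for rep in range(n_replicates):
        cfg = _calibration_config(pipeline.derive_seed(seed, f"null{rep}"), planted=0)
        _, results, _ = _enrich_one(cfg)
        flagged += any(r.enriched_in is not None for r in results)
    return flagged / n_replicates


def planted_clone_recovery(n_replicates: int = 200, seed: int = 3) -> float:
    """Fraction of planted enriched clones (size 30, 10x ratio) called enriched."""
    recovered = total = 0
    for rep in range(n_replicates):
        cfg = _calibration_config(pipeline.derive_seed(seed, f"power{rep}"), planted=5)
        sim, results, enriched_sample = _enrich_one(cfg)
        by_key = {r.key: r for r in results}
        for truth in sim.truth.clones.values():
            if truth.enriched_in is None:
                continue
            total += 1
            key = clonality.clone_key(truth.alpha_nt, (truth.beta_nt,))
            res = by_key.get(key)
            if res is not None and res.enriched_in == enriched_sample:
                recovered += 1
    return recovered / total


# --------------------------------------------------------------------------
# convergence-group recovery
# --------------------------------------------------------------------------

def _convergence_config(seed: int) -> synthetic_data.RepertoireConfig:
    """Three patients, 5 planted cross-patient groups (6 clones each) over a
    modest shared background — the sizing rationale is in docs/methods.md."""
    return synthetic_data.RepertoireConfig(
        n_patients=3,
        cells_per_sample={"PBMC": 150, "SFMC": 150},
        n_clones=25,
        n_planted_enriched=0,
        planted_groups=synthetic_data.DEFAULT_PLANTED_GROUPS,
        seed=seed,
    )


def convergence_recovery(
    n_replicates: int = 50, seed: int = 4, reference_size: int = 10_000,
) -> tuple[float, float]:
    """(fraction of planted groups recovered intact, fraction of spurious groups).

    A planted group is recovered intact when one reported group contains every
    planted member sequence; a reported group is spurious when it contains no
    planted member at all.
    """
    intact = planted_total = spurious = reported_total = 0
    for rep in range(n_replicates):
        cfg = _convergence_config(pipeline.derive_seed(seed, f"crg{rep}"))
        sim = synthetic_data.simulate_repertoire(cfg)
        reference = synthetic_data.simulate_reference(
            reference_size, seed=pipeline.derive_seed(seed, f"crgref{rep}"))
        parts = vdj_io.build_cell_partitions(vdj_io.records_from_frame(sim.contigs))
        gliph = convergence.prepare_gliph_input(parts, reference)
        motifs = convergence.motif_enrichment(
            gliph, seed=pipeline.derive_seed(seed, f"crgmotif{rep}"))
        groups = convergence.build_convergence_groups(gliph.sequences, motifs)
        present_ids = {s.seq_id for s in gliph.sequences}
        planted_ids: dict[str, set[str]] = {}
        for truth in sim.truth.clones.values():
            if truth.crg_motif is None:
                continue
            seq_id = (f"{truth.patient_id}:{truth.v_gene}:{truth.j_gene}:"
                      f"{truth.beta_aa}")
            planted_ids.setdefault(truth.crg_motif, set()).add(seq_id)
        all_planted = set().union(*planted_ids.values()) if planted_ids else set()
        for motif, ids in sorted(planted_ids.items()):
            planted_total += 1
            ids = ids & present_ids  # clones fully absorbed into doublets drop out
            intact += any(ids and ids <= g.members for g in groups)
        for g in groups:
            reported_total += 1
            spurious += not (g.members & all_planted)
    return (intact / planted_total if planted_total else 0.0,
            spurious / reported_total if reported_total else 0.0)


# --------------------------------------------------------------------------
# motif resampling floor vs exhaustive enumeration
# --------------------------------------------------------------------------

def motif_floor_experiment(seed: int = 5, n_subsamples: int = 1000) -> dict:
    """Resampled motif p values vs exhaustive subset enumeration (12-seq reference).

    Returns the minimum reported p for a motif absent from the reference
    (expected: exactly 1/n_subsamples) and the largest deviation of any
    resampled p from its exhaustively enumerated value, in binomial
    Monte-Carlo sigma units.
    """
    carrier = "CASSANQNTEAFF"      # NQNT in the trimmed interior
    non_carrier = "CASSAGGGGEAFF"
    sample_seqs = [carrier, "CASSGNQNTEAFF", non_carrier, "CASSTGGGGEAFF",
                   "CASSAGGGGEQYFF"]  # 5 distinct CDR3s, 2 carrying the motif
    reference = [carrier] * 4 + [non_carrier] * 8
    sample = convergence.GliphInputSet(
        sequences=[convergence.GliphSequence(f"P01:TRBV28:TRBJ1-1:{s}:{i}", s,
                                             "TRBV28", "TRBJ1-1", "P01", 1)
                   for i, s in enumerate(sample_seqs)],
        reference=reference)
    results = convergence.motif_enrichment(sample, n_subsamples=n_subsamples,
                                           seed=seed)

    # exhaustive enumeration over all C(12, 5) reference subsets
    presence = {m.motif: [m.motif in convergence.motif_set(r) for r in reference]
                for m in results}
    n = len(sample_seqs)
    exact: dict[str, float] = {}
    subsets = list(itertools.combinations(range(len(reference)), n))
    for res in results:
        flags = presence[res.motif]
        hits = sum(1 for subset in subsets
                   if sum(flags[i] for i in subset) >= res.sample_count)
        exact[res.motif] = hits / len(subsets)

    floor = 1.0 / n_subsamples
    max_sigma = 0.0
    min_absent_p = math.inf
    for res in results:
        p_exact = exact[res.motif]
        if res.reference_freq == 0.0:
            min_absent_p = min(min_absent_p, res.p_resampled)
            continue
        if p_exact < floor:
            max_sigma = max(max_sigma, 0.0 if res.p_resampled == floor else math.inf)
            continue
        sigma = math.sqrt(p_exact * (1 - p_exact) / n_subsamples)
        dev = abs(res.p_resampled - p_exact)
        max_sigma = max(max_sigma, dev / sigma if sigma > 0 else
                        (0.0 if dev == 0 else math.inf))
    return {"min_absent_p": min_absent_p, "max_sigma_dev": max_sigma,
            "floor": floor}


# --------------------------------------------------------------------------
# deterministic rule fixtures
# --------------------------------------------------------------------------

def _chain(barcode: str, locus: str, idx: int) -> vdj_io.ContigRecord:
    v, j = ("TRAV1-2", "TRAJ33") if locus == "TRA" else ("TRBV28", "TRBJ1-1")
    aa = f"CA{'SS' if locus == 'TRB' else 'V'}" + "GG" + "ACDEFGHIKL"[idx] + "F"
    nt = "".join({"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
                  "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
                  "S": "TCT", "V": "GTT"}[x] for x in aa)
    return vdj_io.ContigRecord(barcode, "P01_SFMC", "P01", locus, v, "", j,
                               nt, aa, True, 5)


def multiplet_rule_check() -> float:
    """Fraction of a 10-cell chain-count fixture handled per the multiplet rules.

    Covers every alpha/beta count combination up to (3, 2), the clonotype
    membership of 2-beta cells in both inclusion modes, and the exclusion of
    alpha-only cells.
    """
    combos = [(0, 1), (1, 1), (2, 1), (1, 0), (2, 0), (3, 0), (0, 2), (1, 2),
              (3, 1), (2, 2)]
    expected = {
        (0, 1): vdj_io.PartitionStatus.OK, (1, 1): vdj_io.PartitionStatus.OK,
        (2, 1): vdj_io.PartitionStatus.OK,
        (1, 0): vdj_io.PartitionStatus.ALPHA_ONLY,
        (2, 0): vdj_io.PartitionStatus.ALPHA_ONLY,
        (3, 0): vdj_io.PartitionStatus.MULTIPLET,
        (0, 2): vdj_io.PartitionStatus.MULTIPLET,
        (1, 2): vdj_io.PartitionStatus.MULTIPLET,
        (3, 1): vdj_io.PartitionStatus.MULTIPLET,
        (2, 2): vdj_io.PartitionStatus.MULTIPLET,
    }
    contigs = []
    for cell_idx, (n_alpha, n_beta) in enumerate(combos):
        barcode = f"BC{cell_idx:02d}-1"
        for i in range(n_alpha):
            contigs.append(_chain(barcode, "TRA", i))
        for i in range(n_beta):
            contigs.append(_chain(barcode, "TRB", i + 4))
    parts = vdj_io.build_cell_partitions(contigs)
    status_of = {p.barcode: p.status for p in parts}
    correct = sum(status_of[f"BC{i:02d}-1"] == expected[combo]
                  for i, combo in enumerate(combos))

    inclusive = clonality.assign_clonotypes(parts, include_multiplet_beta=True)
    exclusive = clonality.assign_clonotypes(parts, include_multiplet_beta=False)
    members_incl = {c[2] for clone in inclusive.clones for c in clone.member_cells}
    members_excl = {c[2] for clone in exclusive.clones for c in clone.member_cells}
    ok_cells = {f"BC{i:02d}-1" for i, combo in enumerate(combos)
                if expected[combo] == vdj_io.PartitionStatus.OK}
    two_beta = {f"BC{i:02d}-1" for i, (na, nb) in enumerate(combos) if nb >= 2}
    rules_ok = (members_excl == ok_cells
                and members_incl == ok_cells | two_beta)
    return (correct + (len(combos) if rules_ok else 0)) / (2 * len(combos))


def qc_boundary_check() -> float:
    """Fraction of boundary fixtures where the preset rules fire exactly as printed."""
    def cell(n_genes=1500, n_counts=6000, pct_mito=5.0, barcode="b"):
        return summary_stats.CellMetrics(barcode, n_genes, n_counts, pct_mito)

    cases = [  # (preset, cell, expect_kept)
        ("droplet_fluid_blood", cell(pct_mito=10.0), True),
        ("droplet_fluid_blood", cell(pct_mito=10.01), False),
        ("droplet_fluid_blood", cell(n_genes=499), False),
        ("droplet_fluid_blood", cell(n_genes=500), True),
        ("droplet_fluid_blood", cell(n_genes=3500), True),
        ("droplet_fluid_blood", cell(n_genes=3501), False),
        ("droplet_fluid_blood", cell(n_counts=25_000), True),
        ("droplet_fluid_blood", cell(n_counts=25_001), False),
        ("droplet_tissue", cell(n_genes=199, n_counts=900), False),
        ("droplet_tissue", cell(n_genes=200, n_counts=900), True),
        ("droplet_tissue", cell(n_genes=2000, n_counts=9000), True),
        ("droplet_tissue", cell(n_genes=2001, n_counts=9000), False),
        ("droplet_tissue", cell(n_counts=10_001), False),
    ]
    correct = 0
    for preset, one_cell, expect_kept in cases:
        result = summary_stats.filter_cells([one_cell], preset)
        correct += (len(result.kept) == 1) == expect_kept
    return correct / len(cases)


def vj_worked_example() -> dict:
    """Two-patient equal-weight V-J usage: 100% V1-J1 vs a 50/50 split."""
    import pandas as pd

    rows = ([("patient1", "TRBV28", "TRBJ1-1")] * 40
            + [("patient2", "TRBV28", "TRBJ1-1")] * 10
            + [("patient2", "TRBV19", "TRBJ2-7")] * 10)
    usage = summary_stats.vj_usage(
        pd.DataFrame(rows, columns=["patient_id", "v_gene", "j_gene"]))
    return {
        "v1j1": float(usage.combined.loc["TRBV28", "TRBJ1-1"]),
        "v2j2": float(usage.combined.loc["TRBV19", "TRBJ2-7"]),
        "total": float(usage.combined.values.sum()),
    }


def pipeline_determinism(seed: int, workdir: str | Path) -> float:
    """1.0 when two default-config runs with one seed are byte-identical."""
    workdir = Path(workdir)
    digests = []
    for run in ("run_a", "run_b"):
        cfg = pipeline.PipelineConfig(out_dir=workdir / run, seed=seed)
        pipeline.run_pipeline(cfg)
        files = sorted(p for p in (workdir / run).iterdir() if p.is_file())
        digests.append({p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                        for p in files})
    return 1.0 if digests[0] == digests[1] else 0.0


def end_to_end_truth_recovery(n_seeds: int = 20, seed: int = 6) -> dict:
    """Run the full default pipeline over several seeds and score planted truth."""
    clone_rec = clone_tot = crg_rec = crg_tot = spurious = groups_tot = 0
    for rep in range(n_seeds):
        rep_seed = pipeline.derive_seed(seed, f"e2e{rep}")
        cfg = dataclasses.replace(
            pipeline.default_pipeline_repertoire(), seed=rep_seed)
        sim = synthetic_data.simulate_repertoire(cfg)
        parts = vdj_io.build_cell_partitions(vdj_io.records_from_frame(sim.contigs))
        by_patient = vdj_io.partitions_by_patient(parts)
        enriched_by_key: dict[tuple[str, str], str | None] = {}
        for patient, patient_parts in by_patient.items():
            table = clonality.assign_clonotypes(patient_parts)
            pair = (f"{patient}_SFMC", f"{patient}_PBMC")
            for res in clonality.test_clonal_enrichment(table, pair):
                enriched_by_key[(patient, res.key)] = res.enriched_in
        reference = synthetic_data.simulate_reference(
            10_000, seed=pipeline.derive_seed(rep_seed, "reference"))
        gliph = convergence.prepare_gliph_input(parts, reference)
        motifs = convergence.motif_enrichment(
            gliph, seed=pipeline.derive_seed(rep_seed, "motifs"))
        groups = convergence.build_convergence_groups(gliph.sequences, motifs)
        present_ids = {s.seq_id for s in gliph.sequences}

        planted_ids: dict[str, set[str]] = {}
        for truth in sim.truth.clones.values():
            if truth.enriched_in is not None:
                clone_tot += 1
                key = clonality.clone_key(truth.alpha_nt, (truth.beta_nt,))
                called = enriched_by_key.get((truth.patient_id, key))
                clone_rec += called == f"{truth.patient_id}_{truth.enriched_in}"
            if truth.crg_motif is not None:
                seq_id = (f"{truth.patient_id}:{truth.v_gene}:{truth.j_gene}:"
                          f"{truth.beta_aa}")
                planted_ids.setdefault(truth.crg_motif, set()).add(seq_id)
        all_planted = set().union(*planted_ids.values()) if planted_ids else set()
        for motif, ids in sorted(planted_ids.items()):
            crg_tot += 1
            ids = ids & present_ids
            crg_rec += any(ids and ids <= g.members for g in groups)
        for g in groups:
            groups_tot += 1
            spurious += not (g.members & all_planted)
    return {
        "clone_recovery": clone_rec / clone_tot if clone_tot else 0.0,
        "crg_recovery": crg_rec / crg_tot if crg_tot else 0.0,
        "spurious_fraction": spurious / groups_tot if groups_tot else 0.0,
    }
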