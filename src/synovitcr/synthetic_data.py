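"""Synthetic paired-chain repertoire generator with planted ground truth.

Emulates paired blood (PBMC) / synovial fluid (SFMC) T-cell repertoires per
patient: a power-law background of shared clones, planted compartment-enriched
clones at a configured proportion ratio, planted motif-sharing convergence
groups with configurable V/J bias, alpha-chain dropout, dual-alpha clones,
droplet doublets, and phenotype cluster labels with a controlled
enriched-clone/cluster odds ratio.  Every cell is traceable to its truth clone
(doublets to two), so each pipeline stage can be tested against known truth.

CDR3s are built as a germline V-anchored prefix, a random insert and a
J-anchored suffix; nucleotide sequences are random synonymous
back-translations, so amino-acid length times three always equals nucleotide
length.  The insert draws uniformly over the 20 standard residues — this
generator tests statistics, not recombination biology.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import germline
from .errors import ConfigError

DEFAULT_SEED = 20200921

DEFAULT_CLUSTERS: tuple[str, ...] = (
    "HLA-DR-low CD8", "HLA-DR-high CD8", "ZNF683+ CD8", "CD8 cycling",
    "CD8 central memory", "CD4 Treg", "CD4 central memory", "CD4 transitional",
)
DEFAULT_CLUSTER_WEIGHTS: tuple[float, ...] = (
    0.25, 0.12, 0.08, 0.05, 0.15, 0.10, 0.15, 0.10,
)


@dataclass(frozen=True)
class PlantedGroup:
    """A planted convergence group: clones sharing an interior CDR3 motif."""

    motif: str = "NQNT"
    n_clones: int = 6
    clone_size: int = 3
    patients: tuple[str, ...] | None = None  # None -> all patients
    v_gene: str = "TRBV28"
    j_gene: str = "TRBJ1-1"


#: five cross-patient planted groups (mirroring the handful of shared
#: specificity groups a small patient panel can support), the first biased
#: toward TRBV28/TRBJ1-1
DEFAULT_PLANTED_GROUPS: tuple[PlantedGroup, ...] = (
    PlantedGroup("NQNT", 6, 3, None, "TRBV28", "TRBJ1-1"),
    PlantedGroup("GQGD", 6, 3, None, "TRBV27", "TRBJ2-7"),
    PlantedGroup("WKDR", 6, 3, None, "TRBV19", "TRBJ2-3"),
    PlantedGroup("PHMR", 6, 3, None, "TRBV9", "TRBJ1-2"),
    PlantedGroup("YRGL", 6, 3, None, "TRBV5-1", "TRBJ2-1"),
)


@dataclass
class RepertoireConfig:
    """Study conditions for one simulated cohort.

    Defaults follow the calibration geometry used throughout the validation
    experiments: 300 background clones per patient drawn from a truncated
    power law, 2000 cells in each of the two compartments, planted enriched
    clones of 30 cells at a 10:1 synovial:blood proportion ratio, a 5%
    doublet rate and 10% alpha dropout.
    """

    n_patients: int = 3
    cells_per_sample: Mapping[str, int] = field(
        default_factory=lambda: {"PBMC": 2000, "SFMC": 2000})
    n_clones: int = 300  # background clones per patient
    clone_size_exponent: float = 2.5
    clone_size_max: int = 50
    n_planted_enriched: int = 5  # per patient
    planted_enriched_size: int = 30
    enrichment_ratio: float = 10.0
    enriched_sample: str = "SFMC"
    planted_groups: tuple[PlantedGroup, ...] = ()
    v_usage: Mapping[str, float] | None = None
    j_usage: Mapping[str, float] | None = None
    doublet_rate: float = 0.05
    alpha_dropout_rate: float = 0.10
    second_alpha_rate: float = 0.10
    nonproductive_rate: float = 0.0
    cluster_labels: tuple[str, ...] = DEFAULT_CLUSTERS
    cluster_weights: tuple[float, ...] = DEFAULT_CLUSTER_WEIGHTS
    planted_cluster: str = "HLA-DR-high CD8"
    planted_cluster_or: float = 5.0
    seed: int = DEFAULT_SEED

    def patient_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_patients)]

    def validate(self) -> None:
        for name in ("doublet_rate", "alpha_dropout_rate", "second_alpha_rate",
                     "nonproductive_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name}={rate} outside [0, 1]")
        if self.enriched_sample not in self.cells_per_sample:
            raise ConfigError(f"enriched_sample {self.enriched_sample!r} not in "
                              f"cells_per_sample {sorted(self.cells_per_sample)}")
        if len(self.cluster_labels) != len(self.cluster_weights):
            raise ConfigError("cluster_labels and cluster_weights lengths differ")
        if self.planted_cluster not in self.cluster_labels:
            raise ConfigError(f"planted_cluster {self.planted_cluster!r} unknown")
        planted = self._planted_cells_per_sample(self.patient_ids())
        for patient, per_sample in planted.items():
            for sample, n in per_sample.items():
                if n > self.cells_per_sample[sample]:
                    raise ConfigError(
                        f"planted clones need {n} cells in {patient}/{sample} but "
                        f"only {self.cells_per_sample[sample]} are configured")

    # -- planted allocation helpers -------------------------------------------
    def _enriched_split(self) -> dict[str, int]:
        """Deterministic per-clone allocation realizing the enrichment ratio.

        The enriched-compartment count is the smallest integer whose realized
        cell-count ratio is at least the configured ratio, so a planted
        "r-fold" clone is never weaker than r-fold before sampling noise.
        """
        size, r = self.planted_enriched_size, self.enrichment_ratio
        n_target = math.ceil(size * r / (1.0 + r))
        while size - n_target > 0 and n_target < r * (size - n_target):
            n_target += 1
        others = [s for s in sorted(self.cells_per_sample) if s != self.enriched_sample]
        split = {self.enriched_sample: n_target}
        if others:
            split[others[0]] = size - n_target
        return split

    def _group_split(self, size: int) -> dict[str, int]:
        samples = sorted(self.cells_per_sample)
        base, extra = divmod(size, len(samples))
        return {s: base + (1 if i < extra else 0) for i, s in enumerate(samples)}

    def _planted_cells_per_sample(self, patients: list[str]) -> dict[str, dict[str, int]]:
        out = {p: {s: 0 for s in self.cells_per_sample} for p in patients}
        enr = self._enriched_split()
        for p in patients:
            for s, n in enr.items():
                out[p][s] += n * self.n_planted_enriched
        for group in self.planted_groups:
            group_patients = list(group.patients) if group.patients else patients
            for i in range(group.n_clones):
                p = group_patients[i % len(group_patients)]
                for s, n in self._group_split(group.clone_size).items():
                    out[p][s] += n
        return out


@dataclass(frozen=True)
class TruthClone:
    clone_id: str
    patient_id: str
    alpha_nt: tuple[str, ...]
    alpha_aa: tuple[str, ...]
    beta_nt: str
    beta_aa: str
    v_gene: str
    j_gene: str
    counts: Mapping[str, int]  # sample_type -> cells
    enriched_in: str | None
    crg_motif: str | None
    cluster_biased: bool


@dataclass(frozen=True)
class CellTruth:
    clone_ids: tuple[str, ...]
    is_doublet: bool


@dataclass
class TruthTable:
    clones: dict[str, TruthClone]
    cells: dict[str, CellTruth]


@dataclass
class SimulatedRepertoire:
    contigs: pd.DataFrame
    metadata: pd.DataFrame
    truth: TruthTable


_TENX_COLUMNS = ("barcode", "chain", "v_gene", "d_gene", "j_gene", "cdr3",
                 "cdr3_nt", "productive", "umis", "patient_id", "sample_id")


def _random_middle(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(len(germline.AMINO_ACIDS), size=length)
    return "".join(germline.AMINO_ACIDS[i] for i in idx)


def _pick(rng, segments, weights):
    return segments[rng.choice(len(segments), p=weights)]


def _make_cdr3(rng, prefix: str, suffix: str, motif: str | None = None) -> str:
    # junction inserts of 3-9 residues: the D segment plus N additions make
    # near-empty junctions rare in real beta chains, and such junctions would
    # dominate chance CDR3 near-identity
    if motif is None:
        return prefix + _random_middle(rng, int(rng.integers(3, 10))) + suffix
    return (prefix + _random_middle(rng, int(rng.integers(1, 3))) + motif
            + _random_middle(rng, int(rng.integers(1, 3))) + suffix)


class _CloneFactory:
    """Draws clone-level chain definitions under configured V/J usage."""

    def __init__(self, config: RepertoireConfig, rng: np.random.Generator):
        self.rng = rng
        self.config = config
        self.bv_w = germline.segment_weights(germline.TRBV_SEGMENTS, config.v_usage)
        self.bj_w = germline.segment_weights(germline.TRBJ_SEGMENTS, config.j_usage)
        self.av_w = germline.segment_weights(germline.TRAV_SEGMENTS, None)
        self.aj_w = germline.segment_weights(germline.TRAJ_SEGMENTS, None)

    def beta(self, v_gene: str | None = None, j_gene: str | None = None,
             motif: str | None = None):
        rng = self.rng
        if v_gene is None:
            v_gene, prefix = _pick(rng, germline.TRBV_SEGMENTS, self.bv_w)
        else:
            prefix = dict(germline.TRBV_SEGMENTS)[v_gene]
        if j_gene is None:
            j_gene, suffix = _pick(rng, germline.TRBJ_SEGMENTS, self.bj_w)
        else:
            suffix = dict(germline.TRBJ_SEGMENTS)[j_gene]
        aa = _make_cdr3(rng, prefix, suffix, motif)
        d_gene = germline.TRBD_GENES[rng.integers(len(germline.TRBD_GENES))]
        return v_gene, d_gene, j_gene, aa, germline.back_translate(aa, rng)

    def alpha(self):
        rng = self.rng
        v_gene, prefix = _pick(rng, germline.TRAV_SEGMENTS, self.av_w)
        j_gene, suffix = _pick(rng, germline.TRAJ_SEGMENTS, self.aj_w)
        aa = _make_cdr3(rng, prefix, suffix)
        return v_gene, "", j_gene, aa, germline.back_translate(aa, rng)


def _power_law_sizes(rng, n, exponent, max_size) -> np.ndarray:
    support = np.arange(1, max_size + 1)
    weights = support.astype(float) ** -exponent
    weights /= weights.sum()
    return rng.choice(support, size=n, p=weights)


def _biased_cluster_probs(base: np.ndarray, target_idx: int, odds_ratio: float) -> np.ndarray:
    p0 = base[target_idx]
    p_target = odds_ratio * p0 / (odds_ratio * p0 + (1.0 - p0))
    out = base * (1.0 - p_target) / (1.0 - p0)
    out[target_idx] = p_target
    return out


def simulate_repertoire(config: RepertoireConfig) -> SimulatedRepertoire:
    """Generate a cohort of contigs + metadata + ground truth (seeded, deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    factory = _CloneFactory(config, rng)
    patients = config.patient_ids()
    samples = sorted(config.cells_per_sample)
    base_cluster = np.asarray(config.cluster_weights, dtype=float)
    base_cluster = base_cluster / base_cluster.sum()
    target_idx = config.cluster_labels.index(config.planted_cluster)
    biased_cluster = _biased_cluster_probs(base_cluster, target_idx,
                                           config.planted_cluster_or)

    # ---- clone definitions --------------------------------------------------
    clone_specs: list[dict] = []  # per-clone dicts incl. per-sample counts
    counter = {p: 0 for p in patients}

    def _new_clone(patient, counts, enriched_in=None, crg=None, biased=False,
                   v_gene=None, j_gene=None, motif=None):
        counter[patient] += 1
        clone_id = f"{patient}_T{counter[patient]:04d}"
        bv, bd, bj, baa, bnt = factory.beta(v_gene, j_gene, motif)
        n_alpha = 2 if rng.random() < config.second_alpha_rate else 1
        alphas = [factory.alpha() for _ in range(n_alpha)]
        clone_specs.append(dict(
            clone_id=clone_id, patient=patient, beta=(bv, bd, bj, baa, bnt),
            alphas=alphas, counts=dict(counts), enriched_in=enriched_in,
            crg=crg, biased=biased))
        return clone_id

    # planted convergence-group clones
    for group in config.planted_groups:
        group_patients = list(group.patients) if group.patients else patients
        for i in range(group.n_clones):
            patient = group_patients[i % len(group_patients)]
            _new_clone(patient, config._group_split(group.clone_size), crg=group.motif,
                       v_gene=group.v_gene, j_gene=group.j_gene, motif=group.motif)

    # planted enriched clones (deterministic allocation at the configured ratio)
    enriched_split = config._enriched_split()
    for patient in patients:
        for _ in range(config.n_planted_enriched):
            _new_clone(patient, enriched_split,
                       enriched_in=config.enriched_sample, biased=True)

    # background clones: shared weights across compartments (null geometry)
    planted_totals = config._planted_cells_per_sample(patients)
    for patient in patients:
        weights = _power_law_sizes(rng, config.n_clones, config.clone_size_exponent,
                                   config.clone_size_max).astype(float)
        probs = weights / weights.sum()
        bg_ids = [_new_clone(patient, {s: 0 for s in samples}) for _ in range(config.n_clones)]
        spec_by_id = {c["clone_id"]: c for c in clone_specs}
        for sample in samples:
            remaining = config.cells_per_sample[sample] - planted_totals[patient][sample]
            counts = rng.multinomial(remaining, probs)
            for clone_id, n in zip(bg_ids, counts):
                spec = spec_by_id[clone_id]
                spec["counts"][sample] = spec["counts"].get(sample, 0) + int(n)

    # ---- cells --------------------------------------------------------------
    cells: list[dict] = []
    for spec in clone_specs:
        probs = biased_cluster if spec["biased"] else base_cluster
        for sample in samples:
            for _ in range(spec["counts"].get(sample, 0)):
                cluster = config.cluster_labels[rng.choice(len(probs), p=probs)]
                chains = []
                bv, bd, bj, baa, bnt = spec["beta"]
                chains.append(("TRB", bv, bd, bj, baa, bnt))
                if rng.random() >= config.alpha_dropout_rate:
                    for av, ad, aj, aaa, ant in spec["alphas"]:
                        chains.append(("TRA", av, ad, aj, aaa, ant))
                cells.append(dict(patient=spec["patient"], sample=sample,
                                  clone_ids=[spec["clone_id"]], cluster=cluster,
                                  chains=chains, is_doublet=False))

    # ---- doublets: merge chains of two random cells of the same sample ------
    by_sample: dict[tuple[str, str], list[int]] = {}
    for i, cell in enumerate(cells):
        by_sample.setdefault((cell["patient"], cell["sample"]), []).append(i)
    absorbed: set[int] = set()
    for key in sorted(by_sample):
        idx = by_sample[key]
        n_doublets = rng.binomial(len(idx), config.doublet_rate)
        n_doublets = min(n_doublets, len(idx) // 2)
        if n_doublets == 0:
            continue
        chosen = rng.choice(len(idx), size=2 * n_doublets, replace=False)
        for h, a in zip(chosen[:n_doublets], chosen[n_doublets:]):
            host, other = cells[idx[h]], cells[idx[a]]
            host["chains"] = host["chains"] + other["chains"]
            host["clone_ids"] = host["clone_ids"] + other["clone_ids"]
            host["is_doublet"] = True
            absorbed.add(idx[a])

    # ---- emit tables --------------------------------------------------------
    contig_rows, meta_rows = [], []
    truth_cells: dict[str, CellTruth] = {}
    barcode_counter: dict[tuple[str, str], int] = {}
    for i, cell in enumerate(cells):
        if i in absorbed:
            continue
        key = (cell["patient"], cell["sample"])
        barcode_counter[key] = barcode_counter.get(key, 0) + 1
        barcode = f"{cell['patient']}_{cell['sample']}_BC{barcode_counter[key]:05d}-1"
        sample_id = f"{cell['patient']}_{cell['sample']}"
        meta_rows.append((barcode, cell["patient"], sample_id, cell["sample"],
                          cell["cluster"]))
        truth_cells[barcode] = CellTruth(clone_ids=tuple(cell["clone_ids"]),
                                         is_doublet=cell["is_doublet"])
        for locus, v, d, j, aa, nt in cell["chains"]:
            contig_rows.append((barcode, locus, v, d, j, aa, nt, "True",
                                int(rng.poisson(5) + 1), cell["patient"], sample_id))
        if config.nonproductive_rate and rng.random() < config.nonproductive_rate:
            junk_nt = "".join("ACGT"[k] for k in rng.integers(4, size=11))
            contig_rows.append((barcode, "TRB", "TRBV28", "", "TRBJ1-1", "",
                                junk_nt, "False", 1, cell["patient"], sample_id))

    truth_clones = {
        spec["clone_id"]: TruthClone(
            clone_id=spec["clone_id"], patient_id=spec["patient"],
            alpha_nt=tuple(sorted(a[4] for a in spec["alphas"])),
            alpha_aa=tuple(sorted(a[3] for a in spec["alphas"])),
            beta_nt=spec["beta"][4], beta_aa=spec["beta"][3],
            v_gene=spec["beta"][0], j_gene=spec["beta"][2],
            counts=dict(spec["counts"]), enriched_in=spec["enriched_in"],
            crg_motif=spec["crg"], cluster_biased=spec["biased"])
        for spec in clone_specs
    }

    contigs = pd.DataFrame(contig_rows, columns=_TENX_COLUMNS)
    metadata = pd.DataFrame(
        meta_rows, columns=["barcode", "patient_id", "sample_id", "sample_type",
                            "cluster_label"])
    return SimulatedRepertoire(contigs=contigs, metadata=metadata,
                               truth=TruthTable(clones=truth_clones, cells=truth_cells))


def simulate_reference(
    n: int,
    v_usage: Mapping[str, float] | None = None,
    j_usage: Mapping[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    motif_freqs: Mapping[str, float] | None = None,
) -> list[str]:
    """Unselected naive beta-chain CDR3 amino-acid reference set.

    By default no motifs are planted beyond germline anchors.  ``motif_freqs``
    optionally seeds chosen motifs at given carrier frequencies so that a
    configured sample-vs-reference fold change can be realized.
    """
    if n < 1:
        raise ConfigError("reference size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v_w = germline.segment_weights(germline.TRBV_SEGMENTS, v_usage)
    j_w = germline.segment_weights(germline.TRBJ_SEGMENTS, j_usage)
    planted = sorted((motif_freqs or {}).items())
    out = []
    for _ in range(n):
        _, prefix = _pick(rng, germline.TRBV_SEGMENTS, v_w)
        _, suffix = _pick(rng, germline.TRBJ_SEGMENTS, j_w)
        motif = None
        for m, freq in planted:
            if rng.random() < freq:
                motif = m
                break
        out.append(_make_cdr3(rng, prefix, suffix, motif))
    return out


_METRIC_MODELS = {
    # platform -> (log-mean genes, log-sd, counts-per-gene range, mito gamma shape/scale)
    "DROPLET_FLUID_BLOOD": (math.log(1500), 0.25, (3.0, 6.0), (2.0, 2.0)),
    "DROPLET_TISSUE": (math.log(900), 0.25, (3.0, 6.0), (2.0, 2.0)),
    "PLATE": (math.log(3000), 0.20, (300.0, 600.0), (2.0, 2.0)),
}

_GENE_BOUNDS = {"DROPLET_FLUID_BLOOD": (600, 3300), "DROPLET_TISSUE": (250, 1900),
                "PLATE": (1200, 5500)}


def simulate_metrics(
    barcodes: Sequence[str],
    platform: str = "DROPLET_FLUID_BLOOD",
    outlier_fraction: float = 0.08,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics with a configured fraction of rule-violating cells."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, sigma, cpg, (g_shape, g_scale) = _METRIC_MODELS[platform]
    lo, hi = _GENE_BOUNDS[platform]
    rows = []
    for barcode in barcodes:
        n_genes = int(np.clip(rng.lognormal(mu, sigma), lo, hi))
        n_counts = int(n_genes * rng.uniform(*cpg))
        pct_mito = float(np.clip(rng.gamma(g_shape, g_scale), 0.0, 9.5))
        if rng.random() < outlier_fraction:
            mode = rng.integers(3)
            if mode == 0:
                pct_mito = float(rng.uniform(10.5, 40.0))
            elif mode == 1:
                n_genes = int(rng.uniform(lo * 0.05, lo * 0.5))
                n_counts = int(n_genes * rng.uniform(*cpg))
            else:
                n_genes = int(hi * rng.uniform(1.3, 2.5))
                n_counts = int(n_genes * rng.uniform(cpg[1], cpg[1] * 3))
        rows.append((barcode, n_genes, n_counts, round(pct_mito, 3), platform))
    return pd.DataFrame(rows, columns=["barcode", "n_genes", "n_counts",
                                       "pct_mito", "platform"])


def simulate_panel(
    n_subjects: int = 11,
    effect_sizes: Sequence[float] = (1.5, 1.0, 1.0, 0.0),
    noise_sd: float = 0.5,
    seed: int | np.random.Generator | None = None,
    analytes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Paired plasma/synovial-fluid analyte concentrations (log-normal).

    ``effect_sizes`` are per-analyte paired log-scale shifts of the synovial
    side relative to plasma; ``noise_sd`` is the per-measurement log-scale
    noise.  Eleven subjects and a four-chemokine panel by default.
    """
    if n_subjects < 3:
        raise ConfigError("paired panel needs at least three subjects")
    if analytes is None:
        analytes = (["CXCL10", "CXCL9", "MIP1a", "MIP1b"]
                    if len(effect_sizes) == 4
                    else [f"A{i + 1:02d}" for i in range(len(effect_sizes))])
    if len(analytes) != len(effect_sizes):
        raise ConfigError("analytes and effect_sizes lengths differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for a_idx, (analyte, effect) in enumerate(zip(analytes, effect_sizes)):
        mu = 7.0 - 0.3 * a_idx
        for s in range(n_subjects):
            subject = f"S{s + 1:02d}"
            base = mu + rng.normal(0.0, 0.6)
            plasma = math.exp(base + rng.normal(0.0, noise_sd))
            sf = math.exp(base + effect + rng.normal(0.0, noise_sd))
            rows.append((subject, analyte, plasma, sf))
    return pd.DataFrame(rows, columns=["subject_id", "analyte", "plasma",
                                       "synovial_fluid"])
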