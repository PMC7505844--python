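"""End-to-end orchestration: simulate -> partition -> enrich -> associate ->
converge -> qc -> usage -> panel, with a manifest of every output.

All randomness flows from one top-level seed through per-stage derived seeds,
so every stage is independently reproducible and two runs with the same config
produce byte-identical outputs.  The bundled default run config is a
desk-scale cohort: 3 patients with paired 300-cell blood/synovial compartments,
25 background clones per patient, 3 planted synovial-enriched clones per
patient and the 5 default planted convergence groups scored against a
10,000-sequence naive reference (see docs/methods.md for the sizing
rationale).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clonality, convergence, summary_stats, synthetic_data, vdj_io
from .errors import ConfigError

log = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


def default_pipeline_repertoire() -> synthetic_data.RepertoireConfig:
    """Desk-scale end-to-end study conditions for the bundled default run."""
    return synthetic_data.RepertoireConfig(
        n_patients=3,
        cells_per_sample={"PBMC": 300, "SFMC": 300},
        n_clones=25,
        n_planted_enriched=3,
        planted_groups=synthetic_data.DEFAULT_PLANTED_GROUPS,
    )


@dataclass
class PipelineConfig:
    out_dir: Path = Path("synovitcr_run")
    seed: int = synthetic_data.DEFAULT_SEED
    simulate: bool = True
    contigs: Path | None = None      # external 10x contig CSV for real-data runs
    metadata: Path | None = None
    reference: Path | None = None    # naive CDR3 set, one per line
    repertoire: synthetic_data.RepertoireConfig = field(
        default_factory=default_pipeline_repertoire)
    reference_size: int = 10_000
    pair: tuple[str, str] = ("SFMC", "PBMC")
    alpha_level: float = 0.05
    include_multiplet_beta: bool = True
    k_values: tuple[int, ...] = (2, 3, 4)
    flank_trim: int = 3
    n_subsamples: int = 1000
    fold_min: float = 10.0
    p_max: float = 0.001
    min_depth: int = 3
    qc_preset: str = "droplet_fluid_blood"
    qc_outlier_fraction: float = 0.08
    panel_effects: tuple[float, ...] = (1.5, 1.0, 1.0, 0.0)
    panel_subjects: int = 11
    panel_noise_sd: float = 0.5

    def validate(self) -> None:
        if not self.simulate:
            for name in ("contigs", "metadata"):
                if getattr(self, name) is None:
                    raise ConfigError(
                        f"config field {name!r} is required when simulate is false")
        self.repertoire.validate()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    rep_fields = {f.name for f in dataclasses.fields(synthetic_data.RepertoireConfig)}
    for key, value in raw.items():
        if key == "repertoire":
            bad = set(value) - rep_fields
            if bad:
                raise ConfigError(f"unknown repertoire config keys: {sorted(bad)}")
            groups = value.pop("planted_groups", None)
            cfg.repertoire = dataclasses.replace(cfg.repertoire, **value)
            if groups is not None:
                cfg.repertoire.planted_groups = tuple(
                    synthetic_data.PlantedGroup(**g) for g in groups)
        elif hasattr(cfg, key):
            current = getattr(cfg, key)
            if isinstance(current, tuple) and not isinstance(value, tuple):
                value = tuple(value)
            if isinstance(current, Path) or (current is None and key in
                                             ("contigs", "metadata", "reference")):
                value = Path(value) if value is not None else None
            setattr(cfg, key, value)
        else:
            raise ConfigError(f"unknown config key {key!r}")
    cfg.out_dir = Path(cfg.out_dir)
    cfg.validate()
    return cfg


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {"seed": config.seed, "stages": {}, "files": {}}

    def record(self, stage: str, path: Path, rows: int) -> None:
        self.data["stages"].setdefault(stage, []).append(path.name)
        self.data["files"][path.name] = {"path": path.name, "rows": int(rows),
                                         "sha256": _sha256(path)}

    def note(self, stage: str, **info) -> None:
        self.data.setdefault("counters", {}).setdefault(stage, {}).update(info)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    A stage failure raises after the manifest (with the completed stages and
    the name of the failed one) has been written; partial outputs remain on
    disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:  # record the failed stage, keep partial outputs
        manifest.data["failed"] = repr(exc)
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest.data


def _write_manifest(manifest: _Manifest, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest.data, indent=2, sort_keys=True) + "\n")


def _run_stages(config: PipelineConfig, out: Path, manifest: _Manifest) -> None:
    # -- simulate -------------------------------------------------------------
    if config.simulate:
        rep_cfg = dataclasses.replace(config.repertoire,
                                      seed=derive_seed(config.seed, "repertoire"))
        sim = synthetic_data.simulate_repertoire(rep_cfg)
        contigs_path, meta_path = out / "contigs.csv", out / "metadata.csv"
        sim.contigs.to_csv(contigs_path, index=False)
        sim.metadata.to_csv(meta_path, index=False)
        manifest.record("simulate", contigs_path, len(sim.contigs))
        manifest.record("simulate", meta_path, len(sim.metadata))

        truth_rows = [(c.clone_id, c.patient_id, "|".join(c.alpha_nt), c.beta_nt,
                       c.v_gene, c.j_gene,
                       ";".join(f"{s}={n}" for s, n in sorted(c.counts.items())),
                       c.enriched_in or "", c.crg_motif or "", c.cluster_biased)
                      for c in sim.truth.clones.values()]
        truth_df = pd.DataFrame(truth_rows, columns=[
            "clone_id", "patient_id", "alpha_nt", "beta_nt", "v_gene", "j_gene",
            "counts", "enriched_in", "crg_motif", "cluster_biased"])
        truth_path = out / "truth.tsv"
        _write_tsv(truth_df.sort_values("clone_id"), truth_path)
        manifest.record("simulate", truth_path, len(truth_df))

        metrics = synthetic_data.simulate_metrics(
            sim.metadata["barcode"].tolist(),
            outlier_fraction=config.qc_outlier_fraction,
            seed=derive_seed(config.seed, "metrics"))
        metrics_path = out / "metrics.csv"
        metrics.to_csv(metrics_path, index=False)
        manifest.record("simulate", metrics_path, len(metrics))
    else:
        contigs_path, meta_path = Path(config.contigs), Path(config.metadata)

    if config.reference is not None:
        reference = [line.strip() for line in
                     Path(config.reference).read_text().splitlines() if line.strip()]
    else:
        reference = synthetic_data.simulate_reference(
            config.reference_size, seed=derive_seed(config.seed, "reference"))
        ref_path = out / "reference.txt"
        ref_path.write_text("\n".join(reference) + "\n")
        manifest.record("simulate", ref_path, len(reference))

    # -- partition ------------------------------------------------------------
    report: dict = {}
    contig_records = vdj_io.read_contig_table(contigs_path, "tenx", report=report)
    partitions = vdj_io.build_cell_partitions(contig_records)
    airr_path = out / "partitions.airr.tsv"
    vdj_io.write_airr(partitions, airr_path)
    status_counts = pd.Series([p.status.value for p in partitions]).value_counts()
    manifest.record("partition", airr_path,
                    sum(len(p.chains) for p in partitions))
    manifest.note("partition", **report, **{f"status_{k}": int(v)
                                            for k, v in status_counts.items()})
    log.info("partition: %d cells (%s); dropped %d non-productive contigs",
             len(partitions), dict(status_counts), report.get("non_productive", 0))

    metadata = vdj_io.read_cell_metadata(meta_path)
    sample_type_of = dict(zip(metadata["sample_id"], metadata["sample_type"]))
    cluster_of_barcode = dict(zip(metadata["barcode"], metadata["cluster_label"]))

    # -- clonotypes + enrichment ---------------------------------------------
    chain_class = {b: ("CD8" if "CD8" in c else "CD4" if "CD4" in c else "")
                   for b, c in cluster_of_barcode.items()}
    enr_rows, clone_rows = [], []
    enriched_cells: list[tuple] = []
    all_assigned_cells: list[tuple] = []
    for patient, parts in vdj_io.partitions_by_patient(partitions).items():
        table = clonality.assign_clonotypes(
            parts, include_multiplet_beta=config.include_multiplet_beta,
            chain_class_of=chain_class)
        for clone in table.clones:
            clone_rows.append((clone.clone_id, patient, clone.key, clone.size,
                               clone.chain_class))
        sample_of = {}  # sample_id per sample_type for this patient
        for part in parts:
            sample_of[sample_type_of.get(part.sample_id, "")] = part.sample_id
        pair_ids = tuple(sample_of.get(t) for t in config.pair)
        if None in pair_ids:
            log.warning("patient %s lacks one of the paired sample types %s",
                        patient, config.pair)
            continue
        results = clonality.test_clonal_enrichment(table, pair_ids,
                                                   config.alpha_level)
        enriched_sample = pair_ids[0]
        for res in results:
            enr_rows.append((res.clone_id, patient, res.key, *res.table,
                             res.odds_ratio, res.p_raw, res.p_adj,
                             res.enriched_in or ""))
            clone = table.clone_by_id(res.clone_id)
            members = [c for c in clone.member_cells if c[1] == enriched_sample]
            all_assigned_cells.extend(members)
            if res.enriched_in == enriched_sample:
                enriched_cells.extend(members)

    clones_path = out / "clonotypes.tsv"
    _write_tsv(pd.DataFrame(clone_rows, columns=["clone_id", "patient_id", "key",
                                                 "size", "chain_class"]),
               clones_path)
    manifest.record("clonotypes", clones_path, len(clone_rows))
    enr_path = out / "enrichment.tsv"
    _write_tsv(pd.DataFrame(enr_rows, columns=["clone_id", "patient_id", "key",
                                               "a", "b", "c", "d", "odds_ratio",
                                               "p_raw", "p_adj", "enriched_in"]),
               enr_path)
    manifest.record("enrich", enr_path, len(enr_rows))
    manifest.note("enrich", n_enriched_clones=sum(1 for r in enr_rows if r[-1]))

    # -- cluster association --------------------------------------------------
    assoc_rows = []
    if enriched_cells:
        universe = {cell: cluster_of_barcode[cell[2]] for cell in all_assigned_cells
                    if cell[2] in cluster_of_barcode}
        members = [c for c in enriched_cells if c in universe]
        if members and len(set(universe.values())) >= 2:
            for assoc in clonality.associate_clusters(members, universe):
                assoc_rows.append((assoc.cluster_label, *assoc.table,
                                   assoc.odds_ratio, assoc.p_raw, assoc.p_adj))
    assoc_path = out / "association.tsv"
    _write_tsv(pd.DataFrame(assoc_rows, columns=["cluster_label", "a", "b", "c",
                                                 "d", "odds_ratio", "p_raw",
                                                 "p_adj"]), assoc_path)
    manifest.record("associate", assoc_path, len(assoc_rows))

    # -- convergence ----------------------------------------------------------
    gliph_report: dict = {}
    gliph_input = convergence.prepare_gliph_input(partitions, reference,
                                                  report=gliph_report)
    motif_results = convergence.motif_enrichment(
        gliph_input, config.k_values, config.n_subsamples,
        seed=derive_seed(config.seed, "motifs"), flank_trim=config.flank_trim)
    groups = convergence.build_convergence_groups(
        gliph_input.sequences, motif_results, config.fold_min, config.p_max,
        config.min_depth, config.k_values, config.flank_trim)
    motifs_path = out / "motifs.tsv"
    _write_tsv(pd.DataFrame(
        [(m.motif, m.k, m.sample_count, m.observed_freq, m.reference_freq,
          m.fold_change, m.p_resampled) for m in motif_results],
        columns=["motif", "k", "sample_count", "observed_freq", "reference_freq",
                 "fold_change", "p_resampled"]), motifs_path)
    manifest.record("converge", motifs_path, len(motif_results))
    group_rows = [(g.crg_id, len(g.members), ";".join(sorted(g.members)),
                   ";".join(sorted(g.patients_represented)),
                   g.motifs[0].motif if g.motifs else "",
                   g.motifs[0].fold_change if g.motifs else "",
                   g.motifs[0].p_resampled if g.motifs else "")
                  for g in groups]
    groups_path = out / "convergence_groups.tsv"
    _write_tsv(pd.DataFrame(group_rows, columns=["crg_id", "n_members", "members",
                                                 "patients", "top_motif",
                                                 "fold_change", "p_resampled"]),
               groups_path)
    manifest.record("converge", groups_path, len(groups))
    manifest.note("converge", **gliph_report, n_groups=len(groups))

    # -- qc -------------------------------------------------------------------
    if config.simulate:
        metrics_df = pd.read_csv(out / "metrics.csv")
        cells = [summary_stats.CellMetrics(r.barcode, int(r.n_genes),
                                           int(r.n_counts), float(r.pct_mito),
                                           summary_stats.Platform(r.platform))
                 for r in metrics_df.itertuples()]
        qc = summary_stats.filter_cells(cells, config.qc_preset)
        kept_path, removed_path = out / "qc_kept.csv", out / "qc_removed.csv"
        pd.DataFrame([(c.barcode,) for c in qc.kept],
                     columns=["barcode"]).to_csv(kept_path, index=False)
        pd.DataFrame([(c.barcode, ";".join(reasons)) for c, reasons in qc.removed],
                     columns=["barcode", "reasons"]).to_csv(removed_path, index=False)
        manifest.record("qc", kept_path, len(qc.kept))
        manifest.record("qc", removed_path, len(qc.removed))

    # -- V-J usage ------------------------------------------------------------
    beta_rows = []
    for part in partitions:
        if part.status == vdj_io.PartitionStatus.OK and part.beta_chains:
            rec = part.beta_chains[0]
            beta_rows.append((part.patient_id, sample_type_of.get(part.sample_id, ""),
                              rec.v_gene, rec.j_gene))
    beta_df = pd.DataFrame(beta_rows, columns=["patient_id", "sample_type",
                                               "v_gene", "j_gene"])
    for sample_type, sub in beta_df.groupby("sample_type", sort=True):
        usage = summary_stats.vj_usage(sub)
        usage_path = out / f"vj_usage_{sample_type}.tsv"
        usage.combined.to_csv(usage_path, sep="\t", float_format=_FLOAT_FORMAT)
        manifest.record("usage", usage_path, usage.combined.shape[0])

    # -- analyte panel --------------------------------------------------------
    panel = synthetic_data.simulate_panel(
        config.panel_subjects, config.panel_effects, config.panel_noise_sd,
        seed=derive_seed(config.seed, "panel"))
    panel_path = out / "panel.csv"
    panel.to_csv(panel_path, index=False, float_format=_FLOAT_FORMAT)
    manifest.record("panel", panel_path, len(panel))
    stats = summary_stats.paired_panel_test(panel)
    stats_path = out / "panel_stats.tsv"
    _write_tsv(stats, stats_path)
    manifest.record("panel", stats_path, len(stats))
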