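"""Cell QC filtering, V-J usage matrices and paired analyte statistics.

The QC engine applies absolute-threshold and median-absolute-deviation rules
to per-cell metrics tables.  Three named presets reproduce the droplet
fluid/blood, droplet tissue and plate-based (Smart-seq 2) rule sets used for
synovial single-cell data; all inequalities are strict, as printed in the
source protocols, so a cell exactly at a boundary is kept.

V-J usage matrices give each patient equal weight: per-patient V-J pairing
frequencies (each summing to 1) are averaged without weighting by cell count.

Paired analyte panels (e.g. plasma vs synovial fluid chemokine concentrations)
are tested per analyte with a two-sided paired t test and Bonferroni
correction over the analytes tested.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UsageError

log = logging.getLogger(__name__)


class Platform(str, Enum):
    DROPLET_FLUID_BLOOD = "DROPLET_FLUID_BLOOD"
    DROPLET_TISSUE = "DROPLET_TISSUE"
    PLATE = "PLATE"


@dataclass(frozen=True)
class CellMetrics:
    barcode: str
    n_genes: int
    n_counts: int  # UMIs for droplet platforms, reads for plate
    pct_mito: float
    platform: Platform = Platform.DROPLET_FLUID_BLOOD


class RuleKind(str, Enum):
    GT = "GT"
    LT = "LT"
    MAD_GT = "MAD_GT"
    MAD_LT = "MAD_LT"


@dataclass(frozen=True)
class FilterRule:
    metric: str
    kind: RuleKind
    threshold: float | None = None
    k_mad: float | None = None

    def __post_init__(self):
        if self.kind in (RuleKind.GT, RuleKind.LT) and self.threshold is None:
            raise ConfigError(f"absolute rule on {self.metric} needs a threshold")
        if self.kind in (RuleKind.MAD_GT, RuleKind.MAD_LT) and self.k_mad is None:
            raise ConfigError(f"MAD rule on {self.metric} needs k_mad")

    @property
    def name(self) -> str:
        if self.kind == RuleKind.GT:
            return f"{self.metric}>{self.threshold:g}"
        if self.kind == RuleKind.LT:
            return f"{self.metric}<{self.threshold:g}"
        op = ">" if self.kind == RuleKind.MAD_GT else "<"
        return f"{self.metric}{op}median{'+' if op == '>' else '-'}{self.k_mad:g}*MAD"


_METRIC_FIELDS = ("n_genes", "n_counts", "pct_mito")

#: Named rule presets: droplet fluid/blood (mito > 10%, genes outside
#: (500, 3500), UMIs > 25,000), droplet tissue (mito > 10%, genes outside
#: (200, 2000), UMIs > 10,000) and plate/SS2 (mito above median + 5 MAD,
#: reads outside (500,000, 5,000,000), counts above median + 3 MAD, genes
#: outside (1000, 6000)).  ``plate_fixed_mito`` swaps the MAD-based
#: mitochondrial rule for an absolute 8.35% cutoff — an alternative reading
#: of the printed plate protocol, exposed but not asserted as its intent.
QC_PRESETS: dict[str, tuple[FilterRule, ...]] = {
    "droplet_fluid_blood": (
        FilterRule("pct_mito", RuleKind.GT, threshold=10.0),
        FilterRule("n_genes", RuleKind.LT, threshold=500),
        FilterRule("n_genes", RuleKind.GT, threshold=3500),
        FilterRule("n_counts", RuleKind.GT, threshold=25_000),
    ),
    "droplet_tissue": (
        FilterRule("pct_mito", RuleKind.GT, threshold=10.0),
        FilterRule("n_genes", RuleKind.LT, threshold=200),
        FilterRule("n_genes", RuleKind.GT, threshold=2000),
        FilterRule("n_counts", RuleKind.GT, threshold=10_000),
    ),
    "plate": (
        FilterRule("pct_mito", RuleKind.MAD_GT, k_mad=5.0),
        FilterRule("n_counts", RuleKind.LT, threshold=500_000),
        FilterRule("n_counts", RuleKind.GT, threshold=5_000_000),
        FilterRule("n_counts", RuleKind.MAD_GT, k_mad=3.0),
        FilterRule("n_genes", RuleKind.LT, threshold=1000),
        FilterRule("n_genes", RuleKind.GT, threshold=6000),
    ),
}
QC_PRESETS["plate_fixed_mito"] = (
    FilterRule("pct_mito", RuleKind.GT, threshold=8.35),
) + QC_PRESETS["plate"][1:]

PLATFORM_PRESET = {
    Platform.DROPLET_FLUID_BLOOD: "droplet_fluid_blood",
    Platform.DROPLET_TISSUE: "droplet_tissue",
    Platform.PLATE: "plate",
}


def mad_bounds(values: Sequence[float], k: float) -> tuple[float, float]:
    """``median +/- k * MAD`` with the unscaled MAD ``median(|x - median|)``.

    A degenerate MAD of zero collapses both bounds onto the median.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise UsageError("mad_bounds needs at least two finite values")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return med - k * mad, med + k * mad


def resolve_rules(
    metrics: Sequence[CellMetrics], rules: Iterable[FilterRule]
) -> list[tuple[FilterRule, FilterRule]]:
    """Resolve MAD rules to absolute thresholds against this cohort.

    Returns ``(original, resolved)`` pairs where the resolved rule is always
    an absolute GT/LT rule.  Absolute rules resolve to themselves.
    """
    out = []
    for rule in rules:
        if rule.metric not in _METRIC_FIELDS:
            raise ConfigError(f"unknown metric {rule.metric!r}; "
                              f"known metrics: {_METRIC_FIELDS}")
        if rule.kind in (RuleKind.GT, RuleKind.LT):
            out.append((rule, rule))
            continue
        values = [getattr(m, rule.metric) for m in metrics]
        lower, upper = mad_bounds(values, rule.k_mad)
        if rule.kind == RuleKind.MAD_GT:
            out.append((rule, FilterRule(rule.metric, RuleKind.GT, threshold=upper)))
        else:
            out.append((rule, FilterRule(rule.metric, RuleKind.LT, threshold=lower)))
    return out


@dataclass
class FilterResult:
    kept: list[CellMetrics]
    removed: list[tuple[CellMetrics, tuple[str, ...]]]
    resolved_rules: list[tuple[FilterRule, FilterRule]]


def filter_cells(
    metrics: Sequence[CellMetrics], rules: Iterable[FilterRule] | str
) -> FilterResult:
    """Remove every cell for which at least one rule fires, with reasons.

    ``rules`` may be a preset name from :data:`QC_PRESETS`.  MAD-based rules
    are resolved against the cohort passed in (the resolved absolute bounds
    are returned, which makes a re-run with those bounds idempotent).
    """
    if isinstance(rules, str):
        try:
            rules = QC_PRESETS[rules]
        except KeyError:
            raise ConfigError(f"unknown QC preset {rules!r}; "
                              f"known: {sorted(QC_PRESETS)}") from None
    resolved = resolve_rules(metrics, rules)
    kept, removed = [], []
    for cell in metrics:
        reasons = []
        for original, rule in resolved:
            value = getattr(cell, rule.metric)
            fired = (value > rule.threshold if rule.kind == RuleKind.GT
                     else value < rule.threshold)
            if fired:
                reasons.append(original.name)
        if reasons:
            removed.append((cell, tuple(reasons)))
        else:
            kept.append(cell)
    return FilterResult(kept=kept, removed=removed, resolved_rules=resolved)


@dataclass
class UsageMatrix:
    """V-J pairing frequencies, equal patient weighting.

    ``combined`` is the unweighted mean of the per-patient matrices (each of
    which sums to 1), aligned on the union of V and J genes.
    """

    combined: pd.DataFrame
    per_patient: dict[str, pd.DataFrame]


def vj_usage(
    cells: pd.DataFrame,
    patient_col: str = "patient_id",
    v_col: str = "v_gene",
    j_col: str = "j_gene",
) -> UsageMatrix:
    """Per-cell V-J usage averaged across patients with equal weight.

    Every row is one clonotype-bearing cell with beta V and J calls.  Patients
    with zero cells are excluded from the average with a warning.
    """
    for col in (patient_col, v_col, j_col):
        if col not in cells.columns:
            raise UsageError(f"usage input is missing column {col!r}")
    per_patient: dict[str, pd.DataFrame] = {}
    for patient, sub in cells.groupby(patient_col, sort=True):
        if len(sub) == 0:
            log.warning("patient %s has no cells; excluded from usage average", patient)
            continue
        mat = pd.crosstab(sub[v_col], sub[j_col]).astype(float)
        per_patient[str(patient)] = mat / mat.values.sum()
    if not per_patient:
        raise UsageError("no patients with cells")
    all_v = sorted(set().union(*(m.index for m in per_patient.values())))
    all_j = sorted(set().union(*(m.columns for m in per_patient.values())))
    aligned = [m.reindex(index=all_v, columns=all_j, fill_value=0.0)
               for m in per_patient.values()]
    combined = sum(aligned) / len(aligned)
    return UsageMatrix(combined=combined, per_patient=per_patient)


def paired_panel_test(
    panel: pd.DataFrame,
    analyte_col: str = "analyte",
    subject_col: str = "subject_id",
    value_cols: tuple[str, str] = ("plasma", "synovial_fluid"),
) -> pd.DataFrame:
    """Two-sided paired t test per analyte with Bonferroni correction.

    Subjects missing either side of a pair are dropped pairwise per analyte
    (each analyte needs >= 3 complete pairs).  Zero variance of the paired
    differences yields NaN statistics with a warning rather than a 0/1 p.
    """
    for col in (analyte_col, subject_col, *value_cols):
        if col not in panel.columns:
            raise UsageError(f"panel table is missing column {col!r}")
    rows = []
    analytes = sorted(panel[analyte_col].unique())
    for analyte in analytes:
        sub = panel[panel[analyte_col] == analyte].dropna(subset=list(value_cols))
        n = len(sub)
        if n < 3:
            raise UsageError(f"analyte {analyte!r} has {n} complete pairs; need >= 3")
        x = sub[value_cols[0]].to_numpy(float)
        y = sub[value_cols[1]].to_numpy(float)
        diff = y - x
        if np.allclose(diff.std(ddof=1), 0.0):
            log.warning("analyte %s has zero-variance paired differences", analyte)
            rows.append((analyte, n, float(diff.mean()), float("nan"),
                         float("nan")))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_rel(y, x)
        rows.append((analyte, n, float(diff.mean()), float(t), float(p)))
    out = pd.DataFrame(rows, columns=[analyte_col, "n_pairs", "mean_diff", "t", "p_raw"])
    m = len(out)
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * m)
    return out
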