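"""Multi-stage differential-gene screen.

Stage 1 ("statistic merge") is the conventional filter: per-gene fold change
against control and a two-sample test on per-cell values, gated at FC 1.2
(two-sided) and p < 0.05 in at least one irradiated group.

Stage 2 ("microdosimetric merge") keeps genes whose expression-difference
dispersion strictly decreases across the low-dose groups (10 -> 100 mGy by
default), mirroring the behaviour of the nucleus specific-energy distribution,
whose dispersion decreases as cumulative dose increases.

Genes passing both stages are ranked by the RMSE between their
expression-difference distribution and a matched normal distribution (smaller
= closer to normal), and the top N become the "multi-filtered" gene set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__
from .expression import ExpressionGroup, read_tenx_trio
from .scdiff import expression_difference, metrics_table

__all__ = [
    "ScreeningConfig",
    "ScreenReport",
    "statistic_merge",
    "microdosimetric_merge",
    "rank_and_select",
    "run_screen",
    "run_screen_from_groups",
]


def _dose_tag(dose: float):
    return int(dose) if float(dose).is_integer() else dose


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds and options of the multi-stage screen.

    ``fc_threshold`` is applied two-sided (FC >= t or FC <= 1/t); ``test`` is
    the two-sample test on per-cell values ("welch_t" or "wilcoxon");
    ``p_adjust`` optionally applies Benjamini-Hochberg across genes per group.
    ``low_dose_groups`` are the doses (mGy) over which the dispersion must
    strictly decrease and over which the RMSE ranking is aggregated.
    ``fc_gate`` exists for calibration studies where only the p-value gate is
    of interest.
    """

    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    low_dose_groups: Tuple[float, ...] = (10.0, 100.0)
    top_n_per_group: int = 100
    top_n_multifiltered: int = 50
    test: str = "welch_t"
    p_adjust: str = "none"
    rmse_aggregation: str = "mean"
    n_bins: int = 50
    fc_gate: bool = True
    normalize_library: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("fc_threshold and p_threshold must be positive")
        if self.top_n_per_group < 1 or self.top_n_multifiltered < 1:
            raise ValueError("top_n values must be >= 1")
        if list(self.low_dose_groups) != sorted(set(self.low_dose_groups)):
            raise ValueError("low_dose_groups must be strictly increasing")
        if self.test not in ("welch_t", "wilcoxon"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.p_adjust not in ("none", "BH"):
            raise ValueError(f"unknown p_adjust {self.p_adjust!r}")
        if self.rmse_aggregation not in ("mean", "max", "per_group"):
            raise ValueError(f"unknown rmse_aggregation {self.rmse_aggregation!r}")


def statistic_merge(
    groups: Mapping[float, ExpressionGroup],
    control: ExpressionGroup,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> pd.DataFrame:
    """Fold change and significance per gene and irradiated group.

    Returns one row per gene with, per dose d: ``fc_<d>``, ``p_<d>``,
    ``p_adj_<d>``, ``pass_<d>``; plus ``statistic_merge_any`` /
    ``statistic_merge_all`` (significant in at least one / every irradiated
    group).  Genes that are all-zero in both populations have undefined p and
    never pass.
    """
    if control.n_cells < 2:
        raise ValueError("control group needs >= 2 cells")
    ctrl = control.counts.astype(float)
    ctrl_mean = ctrl.mean(axis=1)
    out = pd.DataFrame(index=pd.Index(control.gene_ids, name="gene_id"))
    pass_cols = []
    for dose in sorted(groups):
        grp = groups[dose]
        if grp.n_cells < 2:
            raise ValueError(f"group {dose} mGy needs >= 2 cells")
        if set(grp.gene_ids) != set(control.gene_ids):
            raise ValueError("gene sets of group and control differ")
        counts = grp.counts
        if not np.array_equal(grp.gene_ids, control.gene_ids):
            order = pd.Index(grp.gene_ids).get_indexer(control.gene_ids)
            counts = counts[order]
        x = counts.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(ctrl_mean > 0, x.mean(axis=1) / ctrl_mean, np.nan)
        if cfg.test == "welch_t":
            res = stats.ttest_ind(x, ctrl, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, dtype=float)
        else:
            res = stats.mannwhitneyu(x, ctrl, axis=1)
            p = np.asarray(res.pvalue, dtype=float)
            # identical constant rows give p = 1 rather than NaN; mirror the
            # Welch convention of flagging fully degenerate genes
            degenerate = (x.std(axis=1) == 0) & (ctrl.std(axis=1) == 0)
            p[degenerate] = np.nan
        if cfg.p_adjust == "BH":
            p_adj = np.full_like(p, np.nan)
            ok = np.isfinite(p)
            if ok.any():
                p_adj[ok] = stats.false_discovery_control(p[ok], method="bh")
        else:
            p_adj = p
        with np.errstate(invalid="ignore"):
            fc_pass = (
                (fc >= cfg.fc_threshold) | (fc <= 1.0 / cfg.fc_threshold)
                if cfg.fc_gate
                else np.ones_like(fc, dtype=bool)
            )
            sig = np.isfinite(p_adj) & (p_adj < cfg.p_threshold)
        passed = np.isfinite(fc) & fc_pass & sig
        tag = _dose_tag(dose)
        out[f"fc_{tag}"] = fc
        out[f"p_{tag}"] = p
        out[f"p_adj_{tag}"] = p_adj
        out[f"pass_{tag}"] = passed
        pass_cols.append(f"pass_{tag}")
    out["statistic_merge_any"] = out[pass_cols].any(axis=1)
    out["statistic_merge_all"] = out[pass_cols].all(axis=1)
    return out


def microdosimetric_merge(
    metrics: pd.DataFrame,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> pd.Series:
    """True where dispersion strictly decreases along the low-dose groups.

    Genes with undefined dispersion (zero mean or sigma = 0) in any low-dose
    group fail the merge.
    """
    cols = []
    for dose in cfg.low_dose_groups:
        col = f"dispersion_{_dose_tag(dose)}"
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks {col}; dose group missing")
        cols.append(col)
    disp = metrics[cols].to_numpy(float)
    sigma_cols = [f"sigma_zero_{_dose_tag(d)}" for d in cfg.low_dose_groups]
    defined = np.isfinite(disp).all(axis=1)
    if all(c in metrics.columns for c in sigma_cols):
        defined &= ~metrics[sigma_cols].to_numpy(bool).any(axis=1)
    decreasing = np.all(np.diff(disp, axis=1) < 0, axis=1)
    return pd.Series(defined & decreasing, index=metrics.index, name="microdosimetric_merge")


def rank_and_select(
    records: pd.DataFrame,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> pd.DataFrame:
    """Rank genes passing both merges by RMSE-to-normal and select the top N.

    Candidates are sorted ascending by the aggregated RMSE over the low-dose
    groups (``rmse_aggregation``: mean or max; smaller = closer to normal),
    ties broken lexicographically by gene_id.  Adds ``rmse_aggregate``,
    ``rank`` (1-based over candidates, NaN otherwise) and ``selected``.
    """
    records = records.copy()
    rmse_cols = [f"rmse_to_normal_{_dose_tag(d)}" for d in cfg.low_dose_groups]
    both = (
        records["statistic_merge_any"].to_numpy(bool)
        & records["microdosimetric_merge"].to_numpy(bool)
    )
    rm = records[rmse_cols].to_numpy(float)
    candidate = both & np.isfinite(rm).all(axis=1)
    agg = rm.mean(axis=1) if cfg.rmse_aggregation != "max" else rm.max(axis=1)
    records["rmse_aggregate"] = np.where(candidate, agg, np.nan)
    records["rank"] = np.nan
    cand = pd.DataFrame(
        {
            "agg": records.loc[candidate, "rmse_aggregate"],
            "gene": records.index[candidate].astype(str),
        },
        index=records.index[candidate],
    ).sort_values(["agg", "gene"], kind="mergesort")
    records.loc[cand.index, "rank"] = np.arange(1, len(cand) + 1, dtype=float)
    records["selected"] = records["rank"] <= cfg.top_n_multifiltered
    return records


def _per_group_top(records: pd.DataFrame, cfg: ScreeningConfig) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    both = records["statistic_merge_any"] & records["microdosimetric_merge"]
    for dose in cfg.low_dose_groups:
        col = f"rmse_to_normal_{_dose_tag(dose)}"
        sub = records.loc[both & np.isfinite(records[col])]
        order = np.lexsort(
            (sub.index.astype(str).to_numpy(), sub[col].to_numpy(float))
        )
        out[str(_dose_tag(dose))] = list(sub.index[order][: cfg.top_n_per_group])
    return out


@dataclass
class ScreenReport:
    """All per-gene records plus the selected lists and provenance."""

    records: pd.DataFrame
    selected: List[str]
    per_group_top: Dict[str, List[str]]
    excluded_genes: List[Tuple[str, str]]
    counts: Dict[str, int]
    config: ScreeningConfig
    provenance: Dict[str, object] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "config": asdict(self.config),
            "counts": self.counts,
            "selected": self.selected,
            "per_group_top": self.per_group_top,
            "excluded_genes": self.excluded_genes,
            "provenance": self.provenance,
        }

    def write(self, out_dir) -> List[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records_path = out_dir / "screen_records.tsv"
        self.records.to_csv(records_path, sep="\t", float_format="%.10g")
        summary_path = out_dir / "screen_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return [records_path, summary_path]


def run_screen_from_groups(
    control: ExpressionGroup,
    groups: Mapping[float, ExpressionGroup],
    cfg: ScreeningConfig = ScreeningConfig(),
    provenance: Optional[dict] = None,
) -> ScreenReport:
    """End-to-end screen on in-memory expression groups (deterministic)."""
    for dose in cfg.low_dose_groups:
        if dose not in groups:
            raise ValueError(f"low-dose group {dose} mGy missing from inputs")
    stat = statistic_merge(groups, control, cfg)
    diffs = {
        dose: expression_difference(grp, control, cfg.normalize_library)
        for dose, grp in groups.items()
        if dose in cfg.low_dose_groups
    }
    excluded = next(iter(diffs.values())).excluded_genes if diffs else []
    metrics = metrics_table(diffs, n_bins=cfg.n_bins)
    records = stat.join(metrics, how="left")
    records["microdosimetric_merge"] = microdosimetric_merge(records, cfg)
    records = rank_and_select(records, cfg)
    selected = list(records.index[records["selected"]])
    counts = {
        "n_genes": int(len(records)),
        "n_excluded_zero_control": int(len(excluded)),
        "n_statistic_merge": int(records["statistic_merge_any"].sum()),
        "n_microdosimetric_merge": int(records["microdosimetric_merge"].sum()),
        "n_candidates": int(np.isfinite(records["rank"]).sum()),
        "n_selected": len(selected),
    }
    prov = {"microdose_version": __version__}
    prov.update(provenance or {})
    prov["config_sha256"] = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()
    return ScreenReport(
        records=records,
        selected=selected,
        per_group_top=_per_group_top(records, cfg),
        excluded_genes=excluded,
        counts=counts,
        config=cfg,
        provenance=prov,
    )


def run_screen(
    control_dir,
    group_dirs: Mapping[float, object],
    cfg: ScreeningConfig = ScreeningConfig(),
) -> ScreenReport:
    """Screen from 10x trio directories on disk.

    ``group_dirs`` maps dose (mGy) to trio directory.  Fails fast if any
    directory is missing before reading matrices.
    """
    paths = {0.0: Path(control_dir)}
    paths.update({float(d): Path(p) for d, p in group_dirs.items()})
    for dose, p in paths.items():
        if not p.is_dir():
            raise FileNotFoundError(
                f"input directory for {dose} mGy not found: {p}"
            )
    control = read_tenx_trio(paths[0.0], dose_mGy=0.0)
    groups = {
        dose: read_tenx_trio(p, dose_mGy=dose)
        for dose, p in paths.items()
        if dose != 0.0
    }
    # directory basenames only: keeps reruns byte-identical wherever the
    # inputs live
    provenance = {
        "control_dir": paths[0.0].name,
        "group_dirs": {str(_dose_tag(d)): p.name for d, p in paths.items() if d != 0.0},
    }
    return run_screen_from_groups(control, groups, cfg, provenance=provenance)
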