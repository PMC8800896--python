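"""End-to-end Mokken analysis pipeline with subgroup stratification.

Runs the full battery in a fixed order — scalability (with optional
bootstrap SEs), AISP lower-bound sweep (with optional per-item exclusion
thresholds), per-item manifest monotonicity, MIIO with backward selection,
H^T, reliability, level-sum-score summary — for the pooled sample and for
every stratum of each grouping column, and repeats scalability/H^T for a
reduced scale with configured items excluded (the "without AD" comparison is
the generic case of this).  Pooled statistics are always computed
independently, never aggregated from strata.

Every step logs N, dropped or skipped units and undefined flags; undefined
statistics are carried as explicit nulls, never silent blanks.  Reports are
written as TSV tables plus a JSON twin whose round-trip equals the in-memory
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .item_ordering import backward_selection, check_miio, classify_ht, coefficient_ht
from .item_selection import AispConfig, membership_table, refine_exclusion_threshold, sweep_lbound
from .monotonicity import check_monotonicity
from .reliability import reliability_report
from .response_data import ConfigError, ResponseMatrix
from .scalability import classify_scale, compute_h_scale, standard_errors

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "StudyReport", "run_full_analysis", "write_reports"]


@dataclass
class AnalysisConfig:
    """Settings for :func:`run_full_analysis`; YAML-loadable."""

    item_columns: list[str] | None = None      # None: all items in the matrix
    group_columns: list[str] = field(default_factory=list)
    minvi: float = 0.03
    minsize: int | None = None                 # None: automatic rule
    aisp_start: float = 0.0
    aisp_stop: float = 0.55
    aisp_step: float = 0.05
    refine_resolution: float = 0.001           # 0: skip threshold refinement
    bootstrap_b: int = 0                       # 0: skip bootstrap SEs
    seed: int = 0
    alpha: float = 0.05
    exclude_items: list[str] = field(default_factory=list)
    min_stratum_n: int = 200

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_against(self, m: ResponseMatrix) -> None:
        if self.item_columns:
            for col in self.item_columns:
                if col not in m.item_labels:
                    raise ConfigError(f"item column {col!r} not in data")
        for col in self.group_columns:
            if col not in m.group_labels:
                raise ConfigError(f"group column {col!r} not in data")
        for lab in self.exclude_items:
            if lab not in m.item_labels:
                raise ConfigError(f"exclusion item {lab!r} not in data")


@dataclass
class StudyReport:
    """Per-stratum analysis blocks plus the configuration that produced them."""

    config: dict
    strata: dict[str, dict]    # "pooled" plus "<column>=<value>" blocks
    skipped: dict[str, int] = field(default_factory=dict)  # stratum -> N

    def to_dict(self) -> dict:
        return _jsonable(
            {"config": self.config, "strata": self.strata, "skipped": self.skipped}
        )


def _jsonable(obj):
    """Convert to JSON-native types; NaN becomes null (explicit, not blank)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _scale_block(m: ResponseMatrix, cfg: AnalysisConfig, full_battery: bool) -> dict:
    """The analysis battery for one (sub)matrix."""
    n = m.n_persons
    if cfg.bootstrap_b > 0:
        scal = standard_errors(m, B=cfg.bootstrap_b, seed=cfg.seed)
    else:
        scal = compute_h_scale(m)
    block: dict = {
        "n": n,
        "items": list(m.item_labels),
        "h_item": scal.h_item,
        "h_pair": scal.h_pair,
        "z_pair": scal.z_pair,
        "h_scale": scal.h_scale,
        "se_item": scal.se_item,
        "se_pair": scal.se_pair,
        "se_scale": scal.se_scale,
        "scale_class": classify_scale(scal.h_scale),
        "undefined_items": [m.item_labels[i] for i in scal.undefined_items],
        "negative_pairs": scal.negative_pairs(),
    }
    if scal.undefined_items:
        logger.warning("stratum N=%d: undefined H for items %s", n, block["undefined_items"])
    lss = m.level_sum_score()
    block["lss"] = {
        "mean": float(lss.mean()),
        "sd": float(lss.std(ddof=1)) if n > 1 else None,
        "min": int(lss.min()),
        "max": int(lss.max()),
        "median": float(np.median(lss)),
    }
    if not full_battery:
        return block
    # AISP sweep + exclusion thresholds
    sweep = sweep_lbound(
        m, cfg.aisp_start, cfg.aisp_stop, cfg.aisp_step, AispConfig(alpha=cfg.alpha)
    )
    block["aisp_membership"] = {
        f"{c:.2f}": sweep[c].scale_assignment for c in sorted(sweep)
    }
    if cfg.refine_resolution > 0:
        thresholds = {}
        for lab in m.item_labels:
            thr = refine_exclusion_threshold(m, lab, cfg.refine_resolution)
            thresholds[lab] = thr if thr is not None else "never"
        block["exclusion_thresholds"] = thresholds
    # manifest monotonicity per item
    mono = {}
    for lab in m.item_labels:
        _, summ = check_monotonicity(m, lab, cfg.minvi, cfg.minsize)
        mono[lab] = {
            "ac": summ.active_pairs,
            "vi": summ.violations,
            "maxvi": summ.maxvi,
            "zmax": summ.zmax,
            "crit": summ.crit,
            "undefined": summ.undefined,
        }
    block["monotonicity"] = mono
    # MIIO + backward selection + HT
    if m.n_items >= 3:
        rep = check_miio(m, minsize=cfg.minsize, alpha=cfg.alpha)
        after = backward_selection(m, rep, minsize=cfg.minsize, alpha=cfg.alpha)
        block["miio"] = {
            "item_order": rep.item_order,
            "minvi_pair": rep.minvi_pair,
            "items": rep.item_summary.to_dict(orient="records"),
            "pairs": [
                {
                    "easy": p.easy,
                    "hard": p.hard,
                    "ac": p.active_pairs,
                    "vi": p.violations,
                    "sig_vi": p.significant_violations,
                    "maxvi": p.maxvi,
                    "tmax": p.tmax,
                }
                for p in rep.pairs
            ],
            "tied_means": rep.tied_means,
            "removed_items": after.removed_items,
            "violations_after_removal": after.total_violations,
        }
        block["ht"] = coefficient_ht(m)
        block["ht_class"] = classify_ht(block["ht"])
    rel = reliability_report(m)
    block["reliability"] = {
        "rho": rel.ms_rho,
        "lambda2": rel.lambda2,
        "alpha_cronbach": rel.alpha,
        "undefined": rel.undefined,
    }
    return block


def _stratum_report(m: ResponseMatrix, cfg: AnalysisConfig) -> dict:
    out = {"full": _scale_block(m, cfg, full_battery=True)}
    if cfg.exclude_items:
        reduced = m.drop_items(cfg.exclude_items)
        red = _scale_block(reduced, cfg, full_battery=True)
        out["reduced"] = red
        out["excluded_items"] = list(cfg.exclude_items)
    return out


def run_full_analysis(m: ResponseMatrix, cfg: AnalysisConfig | None = None) -> StudyReport:
    """Pooled plus per-stratum battery; deterministic given ``cfg.seed``."""
    cfg = cfg or AnalysisConfig()
    cfg.validate_against(m)
    if cfg.item_columns:
        m = m.subset_items(cfg.item_columns)
    logger.info("full analysis: N=%d, J=%d, seed=%d", m.n_persons, m.n_items, cfg.seed)
    strata: dict[str, dict] = {"pooled": _stratum_report(m, cfg)}
    skipped: dict[str, int] = {}
    for col in cfg.group_columns:
        for tag, sub in m.iter_groups(col):
            name = f"{col}={tag}"
            if sub.n_persons < cfg.min_stratum_n:
                logger.warning(
                    "stratum %s skipped: N=%d below minimum %d",
                    name, sub.n_persons, cfg.min_stratum_n,
                )
                skipped[name] = sub.n_persons
                continue
            strata[name] = _stratum_report(sub, cfg)
    return StudyReport(config=_jsonable(asdict(cfg)), strata=strata, skipped=skipped)


# ---------------------------------------------------------------------------
# writers

ITEM_TABLE_COLUMNS = [
    "stratum", "scale", "item", "mean", "h_item", "se",
    "mono_ac", "mono_vi", "mono_crit", "miio_ac", "miio_vi", "miio_crit",
]
SCALE_TABLE_COLUMNS = [
    "stratum", "scale", "n", "h_scale", "se", "scale_class",
    "ht", "ht_class", "rho", "lambda2", "removed_items",
]
PAIR_TABLE_COLUMNS = ["stratum", "scale", "item_a", "item_b", "h_pair", "se", "z"]


def _report_frames(report: StudyReport) -> dict[str, pd.DataFrame]:
    item_rows, scale_rows, pair_rows, sweep_rows = [], [], [], []
    for stratum, blocks in report.strata.items():
        for scale_name in ("full", "reduced"):
            if scale_name not in blocks:
                continue
            b = blocks[scale_name]
            items = b["items"]
            miio_items = {r["item"]: r for r in b.get("miio", {}).get("items", [])}
            for k, lab in enumerate(items):
                mono = b.get("monotonicity", {}).get(lab, {})
                mi = miio_items.get(lab, {})
                item_rows.append(
                    {
                        "stratum": stratum,
                        "scale": scale_name,
                        "item": lab,
                        "mean": mi.get("mean"),
                        "h_item": _get(b["h_item"], k),
                        "se": _get(b.get("se_item"), k),
                        "mono_ac": mono.get("ac"),
                        "mono_vi": mono.get("vi"),
                        "mono_crit": mono.get("crit"),
                        "miio_ac": mi.get("ac"),
                        "miio_vi": mi.get("vi"),
                        "miio_crit": mi.get("crit"),
                    }
                )
                for k2 in range(k + 1, len(items)):
                    pair_rows.append(
                        {
                            "stratum": stratum,
                            "scale": scale_name,
                            "item_a": lab,
                            "item_b": items[k2],
                            "h_pair": _get2(b["h_pair"], k, k2),
                            "se": _get2(b.get("se_pair"), k, k2),
                            "z": _get2(b.get("z_pair"), k, k2),
                        }
                    )
            rel = b.get("reliability", {})
            scale_rows.append(
                {
                    "stratum": stratum,
                    "scale": scale_name,
                    "n": b["n"],
                    "h_scale": b["h_scale"],
                    "se": b.get("se_scale"),
                    "scale_class": b["scale_class"],
                    "ht": b.get("ht"),
                    "ht_class": b.get("ht_class"),
                    "rho": rel.get("rho"),
                    "lambda2": rel.get("lambda2"),
                    "removed_items": ";".join(b.get("miio", {}).get("removed_items", [])),
                }
            )
            for c, assign in b.get("aisp_membership", {}).items():
                for lab, s in zip(items, assign):
                    sweep_rows.append(
                        {"stratum": stratum, "scale": scale_name, "item": lab,
                         "lbound": float(c), "scale_id": int(s)}
                    )
    return {
        "items": pd.DataFrame(item_rows, columns=ITEM_TABLE_COLUMNS),
        "scales": pd.DataFrame(scale_rows, columns=SCALE_TABLE_COLUMNS),
        "pairwise": pd.DataFrame(pair_rows, columns=PAIR_TABLE_COLUMNS),
        "aisp_sweep": pd.DataFrame(
            sweep_rows, columns=["stratum", "scale", "item", "lbound", "scale_id"]
        ),
    }


def _get(vec, k):
    if vec is None:
        return None
    v = float(np.asarray(vec)[k])
    return v if np.isfinite(v) else None


def _get2(mat, a, b):
    if mat is None:
        return None
    v = float(np.asarray(mat)[a, b])
    return v if np.isfinite(v) else None


def write_reports(report: StudyReport, outdir) -> list[Path]:
    """Write the TSV tables and the JSON twin; returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in _report_frames(report).items():
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        written.append(p)
    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, allow_nan=False)
    written.append(p)
    return written
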