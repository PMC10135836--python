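"""End-to-end orchestration: (simulate | load) -> normalize -> scan -> classify -> evaluate.

A run is configured by one mapping (typically a YAML file) with blocks

    input:     {sweeps: <csv>, labels: <csv>}   # or
    simulate:  {n_male, n_female, onset_day, band: [lo, hi], seed, ...}
    normalize: {num: "2-3", den: "2-4"}
    scan:      {alpha, variant, tails, final_day}
    classify:  {day, frequency_hz, threshold, margin, band_average}
    evaluate:  {}
    output_dir: <dir>

Unknown keys anywhere are errors (fail-fast). Outputs — ratios.csv,
scan.json, calls.csv, report.json — are a pure function of (inputs,
config); every file records the SHA-256 hash of the canonical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .scanstats import (
    GroupSummary,
    ScanConfig,
    ScanResult,
    persistence_onset,
    scan,
    t_test_summary,
)
from .selfnorm import ratio_dataset, write_ratios
from .sexing import ClassifierConfig, classify_egg, evaluate
from .spectra_io import (
    ElectrodePair,
    Sex,
    make_default_grid,
    nearest_grid_frequency,
    read_labels,
    read_sweeps,
    write_labels,
)
from .synthetic_data import CohortSimConfig, EggSimParams, simulate_cohort

__all__ = ["run_pipeline", "day_summary_table", "config_hash"]

logger = logging.getLogger(__name__)


def config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _check_keys(block: Mapping[str, Any], allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config block '{name}': {sorted(unknown)}")


def day_summary_table(
    summaries: Iterable[GroupSummary],
    cfg: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Per-day male/female mean, SD, n and recomputed p, with persistence stars.

    Expects summaries for both groups at a single frequency; a row is
    emitted per day with both groups present (missing groups are warned
    about and skipped). The ``persistent`` column stars the days from
    the persistence onset through the final day, the standard layout
    for reporting the ratio statistic over an incubation.
    """
    by_day: dict[int, dict[Sex, GroupSummary]] = {}
    freqs = set()
    for s in summaries:
        freqs.add(s.frequency_hz)
        by_day.setdefault(s.day, {})[s.group] = s
    if len(freqs) > 1:
        raise ValueError(f"summaries span multiple frequencies: {sorted(freqs)}")

    rows = []
    for day in sorted(by_day):
        cell = by_day[day]
        if Sex.MALE not in cell or Sex.FEMALE not in cell:
            logger.warning("day %d: missing a group, row omitted", day)
            continue
        m, f = cell[Sex.MALE], cell[Sex.FEMALE]
        tt = t_test_summary(m.mean, m.sd, m.n, f.mean, f.sd, f.n, cfg)
        rows.append(
            {
                "day": day,
                "male_mean": m.mean,
                "male_sd": m.sd,
                "male_n": m.n,
                "female_mean": f.mean,
                "female_sd": f.sd,
                "female_n": f.n,
                "p_value": tt.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        df["persistent"] = []
        return df
    onset = persistence_onset(
        dict(zip(df["day"], df["p_value"])), alpha=cfg.alpha
    )
    df["persistent"] = df["day"] >= onset if onset is not None else False
    return df


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError("config must be a mapping")
    return dict(config)


def run_pipeline(config: Mapping[str, Any] | str | Path, output_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the configured pipeline; returns the report dict.

    Stage failures propagate with the stage named in the log. See the
    module docstring for the config schema.
    """
    cfg = _load_config(config)
    _check_keys(
        cfg,
        {"input", "simulate", "normalize", "scan", "classify", "evaluate", "output_dir"},
        "top-level",
    )
    if ("input" in cfg) == ("simulate" in cfg):
        raise ValueError("config needs exactly one of the blocks 'input' or 'simulate'")
    chash = config_hash(cfg)
    out_dir = Path(output_dir or cfg.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    comment = f"config_hash={chash}"

    # --- input / simulate ---
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        _check_keys(
            sim,
            {
                "n_male", "n_female", "onset_day", "band", "seed", "days",
                "mu_male", "sd_male", "mu_female", "sd_female", "baseline_ratio_sd",
            },
            "simulate",
        )
        sim_cfg = CohortSimConfig(
            n_male=sim.get("n_male", 8),
            n_female=sim.get("n_female", 8),
            effect_band_hz=tuple(sim.get("band", (3.76e5, 2.79e6))),
            effect_onset_day=sim.get("onset_day", 9),
            mu_male=sim.get("mu_male", 1.122262),
            sd_male=sim.get("sd_male", 0.112674),
            mu_female=sim.get("mu_female", 0.953107),
            sd_female=sim.get("sd_female", 0.124892),
            baseline_ratio_sd=sim.get("baseline_ratio_sd", 0.12),
            seed=sim.get("seed", 0),
        )
        days = tuple(sim.get("days", range(1, 14)))
        logger.info("stage simulate: %d+%d eggs, seed %d", sim_cfg.n_male, sim_cfg.n_female, sim_cfg.seed)
        sweeps, labels = simulate_cohort(sim_cfg, EggSimParams(), days=days)
    else:
        inp = dict(cfg["input"])
        _check_keys(inp, {"sweeps", "labels"}, "input")
        if "sweeps" not in inp:
            raise ValueError("config block 'input' needs a 'sweeps' path")
        logger.info("stage input: loading %s", inp["sweeps"])
        sweeps = read_sweeps(inp["sweeps"])
        labels = read_labels(inp["labels"]) if "labels" in inp else []

    needs_labels = "evaluate" in cfg or "scan" in cfg
    if needs_labels and not labels:
        raise ValueError("scan/evaluate require labels; config block 'input' is missing 'labels'")

    # --- normalize ---
    norm = dict(cfg.get("normalize", {}))
    _check_keys(norm, {"num", "den"}, "normalize")
    num = ElectrodePair.parse(norm.get("num", "2-3"))
    den = ElectrodePair.parse(norm.get("den", "2-4"))
    logger.info("stage normalize: ratio %s / %s", num, den)
    ratios, excluded = ratio_dataset(sweeps, num, den)
    write_ratios(ratios, out_dir / "ratios.csv", header_comment=comment)

    report: dict[str, Any] = {
        "config_hash": chash,
        "version": __version__,
        "n_sweeps": len(sweeps),
        "n_ratios": len(ratios),
        "excluded": [list(e) for e in excluded],
    }

    # --- scan ---
    scan_result: ScanResult | None = None
    if "scan" in cfg or "classify" in cfg:
        sc = dict(cfg.get("scan", {}))
        _check_keys(sc, {"alpha", "variant", "tails", "final_day", "bonferroni"}, "scan")
        scan_cfg = ScanConfig(
            alpha=sc.get("alpha", 0.05),
            variant=sc.get("variant", "welch"),
            tails=sc.get("tails", 2),
            final_day=sc.get("final_day", 13),
            bonferroni=sc.get("bonferroni", False),
        )
        fit_labels = [l for l in labels if l.sex in (Sex.MALE, Sex.FEMALE)]
        logger.info("stage scan: alpha=%g variant=%s", scan_cfg.alpha, scan_cfg.variant)
        scan_result = scan(ratios, fit_labels, scan_cfg)
        scan_payload = {
            "config_hash": chash,
            "days": list(scan_result.days),
            "frequencies_hz": list(scan_result.frequencies_hz),
            "p_matrix": scan_result.p_matrix.tolist(),
            "alpha": scan_result.alpha,
            "onset_day": scan_result.onset_day,
            "band_hz": list(scan_result.band_hz) if scan_result.band_hz else None,
            "best_frequency_hz": scan_result.best_frequency_hz,
        }
        with open(out_dir / "scan.json", "w", encoding="utf-8") as fh:
            json.dump(scan_payload, fh, indent=1)
        report["onset_day"] = scan_result.onset_day
        report["band_hz"] = scan_payload["band_hz"]
        report["best_frequency_hz"] = scan_result.best_frequency_hz

    # --- classify ---
    calls = None
    if "classify" in cfg:
        cl = dict(cfg["classify"]) if isinstance(cfg["classify"], Mapping) else {}
        _check_keys(
            cl, {"day", "frequency_hz", "threshold", "margin", "band_average"}, "classify"
        )
        day = cl.get("day", 9)
        grid = ratios[0].grid if ratios else make_default_grid()
        _, f_grid = nearest_grid_frequency(grid, cl.get("frequency_hz", 3.76e5))
        band = None
        if cl.get("band_average"):
            band = scan_result.band_hz if scan_result and scan_result.band_hz else (3.76e5, 2.79e6)
        clf = ClassifierConfig(
            frequency_hz=f_grid,
            day=day,
            threshold=cl.get("threshold", 1.0),
            margin=cl.get("margin", 0.0),
            band_hz=band,
        )
        logger.info("stage classify: day %d at %.4g Hz", clf.day, clf.frequency_hz)
        calls = [classify_egg(r, clf) for r in ratios if r.day == clf.day]
        write_labels(calls, out_dir / "calls.csv", header_comment=comment)
        report["n_calls"] = len(calls)

    # --- evaluate ---
    if "evaluate" in cfg:
        _check_keys(dict(cfg["evaluate"] or {}), set(), "evaluate")
        if calls is None:
            raise ValueError("config block 'evaluate' requires the 'classify' block")
        logger.info("stage evaluate: %d calls", len(calls))
        rep = evaluate(calls, labels)
        report["evaluation"] = {
            "confusion": {
                f"{t.value}->{p.value}": c for (t, p), c in sorted(rep.confusion.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value))
            },
            "n_indeterminate": rep.n_indeterminate,
            "per_class_accuracy": {s.value: a for s, a in rep.per_class_accuracy.items()},
            "overall_accuracy": rep.overall_accuracy,
            "balanced_accuracy": rep.balanced_accuracy,
        }

    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    return report
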