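"""End-to-end reliability reporting: qualitative labels and the pipeline.

``interpret_icc`` applies the Shrout qualitative bands; ``run_pipeline``
chains simulation (or CSV ingestion), REML fitting, ICC construction,
bootstrap intervals and the repetition curve into a set of report files:

* ``fit.json``            — components, variance shares, boundary flags;
* ``icc_table.csv``       — the ICC panel with CIs and labels;
* ``repetition_curve.csv``— ICCk(session) against repetition count L;
* ``summary.txt``         — a readable narrative of the same numbers.

Numbers are rounded only in the text summary (ICCs to 2 decimals,
percentages to 1); JSON and CSV keep full precision.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from .bootstrap import IntervalEstimate, parametric_bootstrap
from .icc import ICCSpec, construct_icc, icc_two_component, icck_session, repetition_curve
from .io import PPTDataError, read_ppt_csv, validate_ppt_frame
from .reml import FitResult, fit_reml, variance_percentages
from .simulate import simulate_dataset
from .types import COMPONENT_NAMES, Design, VarianceComponents

__all__ = ["ReliabilityLabel", "interpret_icc", "PipelineConfig", "run_pipeline"]

#: Shrout qualitative reliability bands; a boundary value belongs to the
#: lower band ("substantial" means strictly above 0.80), except that 0.10
#: itself counts as slight because "virtually none" is strictly below 0.10.
_BANDS = (
    ("substantial", 0.80, 1.00),
    ("moderate", 0.60, 0.80),
    ("fair", 0.40, 0.60),
    ("slight", 0.10, 0.40),
    ("virtually_none", 0.00, 0.10),
)


@dataclass(frozen=True)
class ReliabilityLabel:
    band: str
    lower_bound: float
    upper_bound: float

    def __str__(self) -> str:
        return self.band


def interpret_icc(value: float) -> ReliabilityLabel:
    """Qualitative Shrout band for an ICC value in [0, 1]."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"ICC value must lie in [0, 1], got {value}")
    for band, lo, hi in _BANDS:
        if value > lo or (band == "slight" and value == lo):
            return ReliabilityLabel(band, lo, hi)
    return ReliabilityLabel(*_BANDS[-1])


# ---------------------------------------------------------------------------
# pipeline

_PANEL = (
    ("icc_session", frozenset({"session"})),
    ("icc_session_reps", frozenset({"session", "repetition"})),
    ("icc_session_side_reps", frozenset({"session", "side", "repetition"})),
)


@dataclass
class PipelineConfig:
    """Everything one run needs; built from a YAML mapping or keyword args.

    Exactly one of ``input_csv`` and ``simulate`` must be given.
    """

    input_csv: Optional[str] = None
    simulate: Optional[dict] = None          # {design: {...}, components: {...}}
    k_avg: int = 2
    l_range: tuple[int, ...] = tuple(range(1, 11))
    bootstrap_iterations: int = 1000
    bootstrap_level: float = 0.95
    seed: int = 0
    output_dir: str = "ppticc_report"

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, Any], **overrides) -> "PipelineConfig":
        merged = {**dict(cfg), **{k: v for k, v in overrides.items() if v is not None}}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(merged) - known
        if unknown:
            raise PPTDataError(f"unknown config key(s): {sorted(unknown)}")
        if "l_range" in merged:
            merged["l_range"] = tuple(int(x) for x in merged["l_range"])
        return cls(**merged)

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise PPTDataError(
                "config must name exactly one of 'input_csv' or 'simulate'")


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def _load_or_simulate(config: PipelineConfig, quiet: bool) -> pd.DataFrame:
    if config.input_csv is not None:
        _log(f"reading measurements from {config.input_csv}", quiet)
        return read_ppt_csv(config.input_csv)
    sim = dict(config.simulate)
    design = Design(**sim.get("design", {}))
    comp = VarianceComponents(**sim["components"])
    _log(f"simulating {design.n_obs} observations "
         f"(I={design.n_subjects}, J={design.n_sessions}, "
         f"K={design.n_sides}, L={design.n_repetitions}, seed={config.seed})",
         quiet)
    return simulate_dataset(design, comp, seed=config.seed)


def build_icc_table(fit: FitResult, intervals: Mapping[str, IntervalEstimate],
                    k_avg: int, l_avg: int) -> pd.DataFrame:
    """The ICC panel as a tidy table with CIs and qualitative labels."""
    rows = []
    comp = fit.components
    for name, diff in _PANEL:
        res = construct_icc(comp, ICCSpec(diff))
        ci = intervals.get(name)
        rows.append({
            "icc_name": name,
            "differing_factors": "+".join(sorted(diff)),
            "K": 1, "L": 1,
            "numerator": res.numerator, "denominator": res.denominator,
            "value": res.value,
            "ci_lower": ci.lower if ci else None,
            "ci_upper": ci.upper if ci else None,
            "interpretation": interpret_icc(res.value).band,
        })
    resk = icck_session(comp, k_avg, l_avg)
    ci = intervals.get("icck_session")
    rows.append({
        "icc_name": "icck_session",
        "differing_factors": "session",
        "K": k_avg, "L": l_avg,
        "numerator": resk.numerator, "denominator": resk.denominator,
        "value": resk.value,
        "ci_lower": ci.lower if ci else None,
        "ci_upper": ci.upper if ci else None,
        "interpretation": interpret_icc(resk.value).band,
    })
    return pd.DataFrame(rows)


def _summary_text(fit: FitResult, pct: Mapping[str, float],
                  table: pd.DataFrame, curve: pd.DataFrame,
                  config: PipelineConfig) -> str:
    comp = fit.components
    lines = [
        "PPT reliability report",
        "======================",
        "",
        f"Observations: {fit.n_obs} "
        f"({fit.design_summary.n_subjects} subjects x "
        f"{fit.design_summary.n_sessions} sessions x "
        f"{fit.design_summary.n_sides} sides x "
        f"{fit.design_summary.n_repetitions} repetitions max/cell); "
        f"REML converged: {fit.converged}",
        "",
        "Variance components (share of total variance):",
    ]
    ranked = sorted(COMPONENT_NAMES, key=lambda n: -getattr(comp, n))
    for name in ranked:
        flag = " [at zero boundary]" if fit.boundary_flags.get(name) else ""
        lines.append(f"  {name:<12s} = {getattr(comp, name):8.2f} N^2 "
                     f"({pct[name]:.1f}%){flag}")
    lines += ["", f"Grand mean PPT: {comp.grand_mean:.2f} N", "",
              "ICC panel:"]
    for _, r in table.iterrows():
        ci = ""
        if r["ci_lower"] is not None and not pd.isna(r["ci_lower"]):
            ci = f" (95% CI: {r['ci_lower']:.2f} to {r['ci_upper']:.2f})"
        extra = (f" [mean of K={r['K']} sides x L={r['L']} reps]"
                 if r["icc_name"] == "icck_session" else "")
        lines.append(f"  {r['icc_name']:<22s} = {r['value']:.2f}{ci} "
                     f"-> {r['interpretation']}{extra}")
    naive = icc_two_component(comp.sigma2_subj, comp.sigma2_sess)
    lines += [
        f"  two-component (naive)  = {naive:.2f} "
        "(subjects and sessions only; ignores side and repetition variability)",
        "",
        f"Repetition curve (ICCk(session), K={config.k_avg}):",
    ]
    for _, r in curve.iterrows():
        lines.append(f"  L={int(r['L']):>2d}: {r['icck_session']:.2f}")
    lines += [
        "",
        "Settings: seed={}, bootstrap iterations={}, level={:.2f}, "
        "percentile method=inverted-CDF".format(
            config.seed, config.bootstrap_iterations, config.bootstrap_level),
    ]
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig, quiet: bool = False) -> dict[str, Any]:
    """Run the full analysis and write the report files.

    Returns a dict with the in-memory results (``fit``, ``icc_table``,
    ``curve``, ``intervals``) and the paths written.
    """
    data = _load_or_simulate(config, quiet)
    data = validate_ppt_frame(data)

    _log(f"fitting 5-component REML model to {len(data)} rows", quiet)
    fit = fit_reml(data)
    if not fit.converged:
        raise RuntimeError("REML fit did not converge")
    pct = variance_percentages(fit.components)

    l_max = max(config.l_range)
    stats = {name: (lambda c, d=diff: construct_icc(c, ICCSpec(d)).value)
             for name, diff in _PANEL}
    stats["icck_session"] = lambda c: icck_session(c, config.k_avg, l_max).value
    for name in COMPONENT_NAMES:
        stats[name] = (lambda c, n=name: getattr(c, n))
    for L in config.l_range:
        stats[f"icck_L{L}"] = (lambda c, LL=L:
                               icck_session(c, config.k_avg, LL).value)

    _log(f"parametric bootstrap: {config.bootstrap_iterations} iterations", quiet)
    intervals = parametric_bootstrap(
        fit, fit.design_summary, stats,
        n_iterations=config.bootstrap_iterations,
        level=config.bootstrap_level, seed=config.seed)

    table = build_icc_table(fit, intervals, config.k_avg, l_max)
    curve_pts = repetition_curve(fit.components, config.k_avg, config.l_range)
    curve = pd.DataFrame({
        "L": [L for L, _ in curve_pts],
        "icck_session": [r.value for _, r in curve_pts],
        "ci_lower": [intervals[f"icck_L{L}"].lower for L, _ in curve_pts],
        "ci_upper": [intervals[f"icck_L{L}"].upper for L, _ in curve_pts],
    })

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit_payload = {
        **fit.to_dict(),
        "variance_percentages": dict(pct),
        "component_ci": {
            name: {"ci_lower": intervals[name].lower,
                   "ci_upper": intervals[name].upper,
                   "ci_level": config.bootstrap_level,
                   "n_boot": config.bootstrap_iterations,
                   "n_failed": intervals[name].n_failed}
            for name in COMPONENT_NAMES},
    }
    (out / "fit.json").write_text(json.dumps(fit_payload, indent=2))
    table.to_csv(out / "icc_table.csv", index=False)
    curve.to_csv(out / "repetition_curve.csv", index=False)
    summary = _summary_text(fit, pct, table, curve, config)
    (out / "summary.txt").write_text(summary)
    _log(f"report written to {out}/", quiet)

    return {"fit": fit, "percentages": pct, "icc_table": table, "curve": curve,
            "intervals": intervals, "summary": summary,
            "paths": {n: str(out / f) for n, f in
                      (("fit", "fit.json"), ("icc_table", "icc_table.csv"),
                       ("curve", "repetition_curve.csv"),
                       ("summary", "summary.txt"))}}
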