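"""Cohort-level association analysis.

Orchestrates, in order: the paired lesion-vs-NAWM g-ratio comparison, the
patient-vs-control NfL comparison, correlations of NfL with lesion volume
and lesional g-ratio, the elevated-NfL rule (control mean + 3 SD), and the
lesion-load-stratified contingency analysis with sensitivity reruns of the
load threshold.  Everything is deterministic given the cohort table and
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (
    ContingencyTable2x2,
    StatResult,
    elevated_nfl_threshold,
    fisher_exact_2x2,
    mann_whitney_u,
    paired_t_test,
    spearman_rho,
    wilcoxon_signed_rank,
)

__all__ = ["AnalysisConfig", "StratifiedTables", "stratify_patients", "run_full_analysis", "report_to_markdown"]


@dataclass
class AnalysisConfig:
    load_threshold_pct: float = 0.5
    sensitivity_thresholds_pct: tuple[float, ...] = (0.4, 0.6)
    gratio_cut: float | None = None  # None -> whole-cohort median of g_wml
    alpha: float = 0.05
    include_paired_t: bool = True


@dataclass
class StratifiedTables:
    """The two load strata's g-ratio x elevated-NfL contingency tables."""

    low_load: ContingencyTable2x2
    substantial_load: ContingencyTable2x2
    load_threshold_pct: float
    gratio_cut: float
    n_low: int
    n_substantial: int

    def to_dict(self) -> dict:
        return {
            "load_threshold_pct": self.load_threshold_pct,
            "gratio_cut": self.gratio_cut,
            "n_low": self.n_low,
            "n_substantial": self.n_substantial,
            "low_load": self.low_load.to_dict(),
            "substantial_load": self.substantial_load.to_dict(),
        }


def _patients(cohort: pd.DataFrame) -> pd.DataFrame:
    pat = cohort[cohort["group"] == "patient"]
    complete = pat.dropna(subset=["nfl_pg_ml", "lesion_vol_pct_icv", "g_wml", "g_nawm"])
    return complete


def stratify_patients(
    cohort: pd.DataFrame,
    nfl_threshold: float,
    load_threshold_pct: float = 0.5,
    gratio_cut: float | None = None,
) -> StratifiedTables:
    """Cross-tabulate g-ratio stratum against elevated NfL within load strata.

    The g-ratio split uses the whole-patient-cohort median of lesional g
    (not per-stratum medians): "normal" is <= the cut, "abnormal" is above.
    Lesion-load strata are <= / > the load threshold.  Empty strata yield
    zero-filled tables.
    """
    pat = _patients(cohort)
    if pat.empty:
        raise ValueError("no complete patient records")
    cut = float(pat["g_wml"].median()) if gratio_cut is None else float(gratio_cut)
    abnormal = pat["g_wml"].to_numpy() > cut
    elevated = pat["nfl_pg_ml"].to_numpy() > nfl_threshold
    substantial = pat["lesion_vol_pct_icv"].to_numpy() > load_threshold_pct

    def table(sel: np.ndarray) -> ContingencyTable2x2:
        return ContingencyTable2x2(
            a=int(np.sum(sel & abnormal & elevated)),
            b=int(np.sum(sel & abnormal & ~elevated)),
            c=int(np.sum(sel & ~abnormal & elevated)),
            d=int(np.sum(sel & ~abnormal & ~elevated)),
        )

    return StratifiedTables(
        low_load=table(~substantial),
        substantial_load=table(substantial),
        load_threshold_pct=load_threshold_pct,
        gratio_cut=cut,
        n_low=int(np.sum(~substantial)),
        n_substantial=int(np.sum(substantial)),
    )


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Run the complete association analysis and return a structured report.

    The report is JSON-serialisable: every test result, all contingency
    tables (primary and sensitivity load thresholds), the elevated-NfL
    threshold and the configuration used.
    """
    cfg = config or AnalysisConfig()
    pat = _patients(cohort)
    ctl = cohort[cohort["group"] == "control"]
    if pat.empty or ctl.empty:
        raise ValueError("cohort must contain complete patients and controls")
    excluded = int((cohort["group"] == "patient").sum() - len(pat))

    def stage(name: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"analysis stage {name!r} failed: {exc}") from exc

    results: dict[str, StatResult] = {}
    g_wml = pat["g_wml"].to_numpy()
    g_nawm = pat["g_nawm"].to_numpy()
    results["gratio_wml_vs_nawm_wilcoxon"] = stage(
        "paired_region_comparison", wilcoxon_signed_rank, g_wml, g_nawm
    )
    if cfg.include_paired_t:
        results["gratio_wml_vs_nawm_paired_t"] = stage(
            "paired_region_comparison_t", paired_t_test, g_wml, g_nawm
        )
    results["nfl_patients_vs_controls"] = stage(
        "group_nfl_comparison", mann_whitney_u,
        pat["nfl_pg_ml"].to_numpy(), ctl["nfl_pg_ml"].to_numpy(),
    )
    results["nfl_vs_lesion_volume"] = stage(
        "volume_correlation", spearman_rho,
        pat["lesion_vol_pct_icv"].to_numpy(), pat["nfl_pg_ml"].to_numpy(),
    )
    results["nfl_vs_wml_gratio"] = stage(
        "gratio_correlation", spearman_rho, g_wml, pat["nfl_pg_ml"].to_numpy()
    )

    threshold = stage(
        "elevated_threshold", elevated_nfl_threshold, ctl["nfl_pg_ml"].to_numpy()
    )
    n_elevated = int((pat["nfl_pg_ml"] > threshold).sum())

    stratified: dict[str, dict] = {}
    fisher: dict[str, dict] = {}
    for thr in (cfg.load_threshold_pct, *cfg.sensitivity_thresholds_pct):
        tables = stratify_patients(cohort, threshold, thr, cfg.gratio_cut)
        key = f"load_threshold_{thr:g}"
        stratified[key] = tables.to_dict()
        fisher[key] = {
            "low_load": fisher_exact_2x2(tables.low_load).to_dict(),
            "substantial_load": fisher_exact_2x2(tables.substantial_load).to_dict(),
        }

    from . import __version__

    return {
        "software": {"package": "gratiokit", "version": __version__},
        "config": {
            "load_threshold_pct": cfg.load_threshold_pct,
            "sensitivity_thresholds_pct": list(cfg.sensitivity_thresholds_pct),
            "gratio_cut": cfg.gratio_cut,
            "alpha": cfg.alpha,
        },
        "n_patients": int(len(pat)),
        "n_controls": int(len(ctl)),
        "n_patients_excluded_incomplete": excluded,
        "elevated_nfl_threshold_pg_ml": float(threshold),
        "n_patients_elevated_nfl": n_elevated,
        "tests": {k: v.to_dict() for k, v in results.items()},
        "stratified": stratified,
        "fisher": fisher,
    }


def report_to_markdown(report: dict) -> str:
    """Human-readable rendering of a :func:`run_full_analysis` report."""
    lines = [
        "# Cohort analysis report",
        "",
        f"- patients: {report['n_patients']} (excluded incomplete: "
        f"{report['n_patients_excluded_incomplete']}), controls: {report['n_controls']}",
        f"- elevated-NfL threshold (control mean + 3 SD): "
        f"{report['elevated_nfl_threshold_pg_ml']:.2f} pg/ml; "
        f"{report['n_patients_elevated_nfl']} patients elevated",
        "",
        "## Tests",
    ]
    for key, t in report["tests"].items():
        lines.append(
            f"- {key}: statistic={t['statistic']:.4g}, p={t['p_value']:.4g}, "
            f"n={t['n']} ({t['method']})"
        )
    lines.append("")
    lines.append("## Stratified contingency analysis")
    for key, s in report["stratified"].items():
        f = report["fisher"][key]
        lines.append(f"### {key} (g-ratio cut {s['gratio_cut']:.4g})")
        for stratum, n_key in (("low_load", "n_low"), ("substantial_load", "n_substantial")):
            cells = s[stratum]["cells"]
            p = f[stratum]["p_value"]
            lines.append(
                f"- {stratum} (n={s[n_key]}): "
                f"abnormal-g {cells[0][0]}/{cells[0][0] + cells[0][1]} vs "
                f"normal-g {cells[1][0]}/{cells[1][0] + cells[1][1]} elevated; "
                f"Fisher p={p:.4g}"
            )
        lines.append("")
    return "\n".join(lines)


def save_report(report: dict, json_path, md_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if md_path is not None:
        with open(md_path, "w") as fh:
            fh.write(report_to_markdown(report))
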