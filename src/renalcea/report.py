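"""End-to-end pipeline orchestration and human-readable reporting."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .config import AppConfig, RunManifest
from .markov import ArmResult, CEAComparison, compare_arms, run_arm
from .psa import PSAResult, run_psa
from .threshold import ThresholdResult, find_breakeven_dialysis_cost

__all__ = ["PipelineReport", "run_pipeline", "summary_markdown"]

log = logging.getLogger("renalcea")


@dataclass(frozen=True)
class PipelineReport:
    rhp: ArmResult
    soc: ArmResult
    comparison: CEAComparison
    psa: PSAResult | None
    threshold: ThresholdResult | None
    manifest: RunManifest


def _fmt(x, nd=2):
    return "undefined" if x is None else f"{x:,.{nd}f}"


def summary_markdown(report: PipelineReport) -> str:
    """Markdown summary table of the base-case comparison (plus PSA/threshold).

    All monetary figures are USD; differences use the intervention-minus-
    comparator (RHP minus standard of care) sign convention.
    """
    rhp, soc, cmp = report.rhp, report.soc, report.comparison
    lines = [
        "# Cost-effectiveness results",
        "",
        "| Quantity | Renal Health Program | Standard of care | Difference (RHP − SoC) |",
        "|---|---:|---:|---:|",
        f"| Costs (USD, per person) | {rhp.total_cost:,.2f} | {soc.total_cost:,.2f} | {cmp.delta_cost:,.2f} |",
        f"| YL, dialysis-free (per person) | {rhp.total_yl:.2f} | {soc.total_yl:.2f} | {cmp.delta_yl:.2f} |",
        f"| QALY (per person) | {rhp.total_qaly:.2f} | {soc.total_qaly:.2f} | {cmp.delta_qaly:.2f} |",
        f"| ICER: USD/YL | | | {_fmt(cmp.icer_per_yl)} |",
        f"| ICER: USD/QALY | | | {_fmt(cmp.icer_per_qaly)} |",
        f"| Dominance | | | {cmp.dominance.value} |",
    ]
    if report.psa is not None:
        s = report.psa.summary
        lines += [
            "",
            f"PSA ({s.n_iterations} iterations, {s.sampling} sampling, "
            f"sign convention {s.sign_convention}): RHP dominant in "
            f"{s.n_dominant}/{s.n_iterations} iterations.",
        ]
    if report.threshold is not None:
        t = report.threshold
        lines += [
            "",
            f"Break-even annual dialysis cost (incremental cost = 0): "
            f"USD {t.breakeven_value:,.2f} (bisection over "
            f"[{t.bracket[0]:,.0f}, {t.bracket[1]:,.0f}], tolerance {t.tolerance}).",
        ]
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: AppConfig,
    manifest: RunManifest,
    outdir: str | Path | None = None,
    with_psa: bool = True,
    with_threshold: bool = True,
    psa_iterations: int | None = None,
    psa_seed: int | None = None,
) -> PipelineReport:
    """Run base case, comparison, and optionally PSA and threshold analysis.

    If ``outdir`` is given, per-cycle traces (CSV), results (JSON), the PSA
    iteration table/scatter (CSV) and a markdown summary are written there.
    """
    settings = config.settings()
    costs = config.cost_inputs()
    for key, value in sorted(manifest.resolved_parameters.items()):
        log.info("parameter %s = %s", key, value)

    soc = run_arm(config.transitions("soc"), costs, settings, "soc")
    rhp = run_arm(config.transitions("rhp"), costs, settings, "rhp")
    comparison = compare_arms(rhp, soc, settings)

    psa_result = None
    if with_psa:
        psa_result = run_psa(
            config.parameter_ranges(),
            costs,
            settings,
            n_iterations=psa_iterations or config.psa.n_iterations,
            seed=psa_seed if psa_seed is not None else config.psa.seed,
        )
    threshold_result = None
    if with_threshold:
        threshold_result = find_breakeven_dialysis_cost(
            costs,
            config.transitions("rhp"),
            config.transitions("soc"),
            settings,
            bracket=config.threshold.bracket,
            tolerance=config.threshold.tolerance,
        )
    report = PipelineReport(rhp, soc, comparison, psa_result, threshold_result, manifest)
    if outdir is not None:
        _write_outputs(report, Path(outdir))
    return report


def results_dict(report: PipelineReport) -> dict:
    cmp = report.comparison
    out = {
        "sign_convention": "rhp_minus_soc",
        "currency": "USD",
        "arms": {
            a.arm: {"total_cost": a.total_cost, "total_yl": a.total_yl, "total_qaly": a.total_qaly}
            for a in (report.rhp, report.soc)
        },
        "incremental": {
            "delta_cost": cmp.delta_cost,
            "delta_yl": cmp.delta_yl,
            "delta_qaly": cmp.delta_qaly,
            "icer_per_yl": cmp.icer_per_yl,
            "icer_per_qaly": cmp.icer_per_qaly,
            "dominance": cmp.dominance.value,
        },
    }
    if report.psa is not None:
        s = report.psa.summary
        out["psa"] = {
            "n_iterations": s.n_iterations,
            "n_dominant": s.n_dominant,
            "sampling": s.sampling,
            "sign_convention": s.sign_convention,
            "stats": s.stats,
        }
    if report.threshold is not None:
        t = report.threshold
        out["threshold"] = {
            "parameter": t.parameter,
            "breakeven_value": t.breakeven_value,
            "affine_root": t.affine_root,
            "bracket": list(t.bracket),
            "tolerance": t.tolerance,
        }
    return out


def _write_outputs(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for arm in (report.rhp, report.soc):
        arm.trace.to_frame().to_csv(outdir / f"trace_{arm.arm}.csv", index=False)
    (outdir / "results.json").write_text(json.dumps(results_dict(report), indent=2))
    (outdir / "summary.md").write_text(summary_markdown(report))
    (outdir / "manifest.json").write_text(report.manifest.to_json())
    if report.psa is not None:
        report.psa.iterations.to_csv(outdir / "psa_iterations.csv", index=False)
        # incremental cost-vs-QALY plane, ready for scatter plotting
        report.psa.iterations[["delta_qaly", "delta_cost"]].to_csv(
            outdir / "psa_scatter.csv", index=False
        )
    log.info("report written to %s", outdir)
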