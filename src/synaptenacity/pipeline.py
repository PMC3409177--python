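"""End-to-end orchestration: simulate/load -> metrics -> compare -> report.

A :class:`RunConfig` fully determines a run (including the seed); the
config, seed and package version are serialised with every report so
reruns reproduce outputs exactly.  No punctum is dropped silently: every
exclusion (split/merge rejection, loss) is counted per group and reported.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constancy import (
    SICurve,
    compare_distributions,
    compare_si_curves,
    loss_rate,
    normalized_si_curve,
    range_over_mean,
    si_endpoint,
)
from .datatypes import NeuronRecord, TraceStatus
from .errors import InsufficientDataError, ParameterError, SchemaError
from .frap import (
    FRAPFit,
    average_frap_curve,
    bleach_correct,
    fit_double_exponential,
    fractional_recovery,
)
from .io import read_frap_table, read_trace_table, write_trace_table
from .synthkit import (
    GeneratorParams,
    frap_schedule,
    genotype_presets,
    simulate_frap_experiment,
    simulate_trace_population,
)

logger = logging.getLogger("synaptenacity")

__all__ = ["RunConfig", "Report", "run_constancy_pipeline", "run_frap_pipeline", "FRAP_TRUTHS"]

# Two-pool parameter bundles used as generating truths in simulate mode.
# Time constants in minutes; f_bl is a calibration choice (the immediate
# post-bleach level is set by the bleaching procedure, not by the pools).
FRAP_TRUTHS: dict[str, FRAPFit] = {
    "ko": FRAPFit(f_bl=0.2, p_f=0.30, tau_f=18.0, tau_s=7.2 * 60.0,
                  residual_norm=0.0, converged=True),
    "wt": FRAPFit(f_bl=0.2, p_f=0.24, tau_f=20.0, tau_s=4.7 * 60.0,
                  residual_norm=0.0, converged=True),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``simulate`` (groups name presets) or ``traces`` (groups
    name trace-table files).  ``groups`` maps group label -> preset name or
    path.  Metric parameters mirror the analysis defaults: 5-point
    smoothing, 10 SI shuffles, alpha = 0.05, 7x7 measurement boxes.
    """

    mode: str = "simulate"
    groups: dict = field(default_factory=lambda: {"wt": "wt", "ko": "ko"})
    n_neurons: int = 10
    seed: int = 0
    outdir: str = "results"
    smoothing_width: int = 5
    si_shuffles: int = 10
    alpha: float = 0.05
    box: int = 7
    # FRAP-specific knobs
    frap_noise_sd: float = 0.02
    frap_n_synapses: int = 30
    frap_bleach_rate: float = 1e-3
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParameterError("config", f"unknown keys {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Report:
    """Aggregated outputs of one pipeline run (all numbers also on disk)."""

    group_summaries: dict
    comparisons: dict
    exclusions: dict
    files: list
    config: dict

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {
                "version": __version__,
                "config": self.config,
                "group_summaries": self.group_summaries,
                "comparisons": self.comparisons,
                "exclusions": self.exclusions,
                "files": [str(f) for f in self.files],
            },
            indent=2,
            default=float,
        ))
        return path


def _load_group_records(config: RunConfig, label: str, spec_value: str, seed: int) -> list[NeuronRecord]:
    if config.mode == "simulate":
        params = genotype_presets(spec_value, seed=seed)
        records, _ = simulate_trace_population(
            params, genotype_label=label, n_neurons=config.n_neurons
        )
        return records
    if config.mode == "traces":
        return read_trace_table(spec_value)
    raise ParameterError("mode", f"unsupported input mode {config.mode!r}")


def _ks_dict(res) -> dict:
    return {
        "statistic": res.statistic,
        "pvalue": res.pvalue,
        "n_a": res.n_a,
        "n_b": res.n_b,
        "mean_a": res.mean_a,
        "mean_b": res.mean_b,
        "sd_a": res.sd_a,
        "sd_b": res.sd_b,
    }


def run_constancy_pipeline(config: RunConfig) -> Report:
    """Full content-constancy analysis with pairwise group comparisons.

    Emits per-punctum metrics, per-neuron SI curves and loss rates as CSV,
    a JSON summary, and (optionally) SI-decay and range-over-mean figures.
    Deterministic given ``config`` (including its seed).
    """
    if len(config.groups) < 2:
        raise ParameterError("groups", "need at least 2 groups for comparisons")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    group_records: dict[str, list[NeuronRecord]] = {}
    for gi, (label, value) in enumerate(sorted(config.groups.items())):
        group_records[label] = _load_group_records(config, label, value, seed=config.seed + gi)

    punctum_rows, neuron_rows, si_rows = [], [], []
    group_rom: dict[str, list[float]] = {}
    group_loss: dict[str, list[float]] = {}
    group_si: dict[str, list[SICurve]] = {}
    group_counts: dict[str, list[int]] = {}
    exclusions: dict[str, dict] = {}

    for label, records in group_records.items():
        roms, losses, curves, counts = [], [], [], []
        n_rej = n_lost = n_tracked = n_short = 0
        for rec in records:
            counts.append(len(rec.traces))
            n_rej += rec.n_rejected()
            n_lost += rec.n_lost()
            n_tracked += rec.n_tracked()
            for tr in rec.traces_with_status(TraceStatus.TRACKED):
                try:
                    rom = range_over_mean(tr, width=config.smoothing_width)
                except InsufficientDataError:
                    n_short += 1
                    continue
                roms.append(rom.value)
                punctum_rows.append(
                    {"group": label, "neuron": rec.neuron_id, "punctum": tr.punctum_id,
                     "range_over_mean": rom.value, "f_mean": rom.f_mean}
                )
            lr = loss_rate(rec)
            losses.append(lr)
            curve = normalized_si_curve(rec, n_shuffles=config.si_shuffles, seed=config.seed)
            curves.append(curve)
            neuron_rows.append(
                {"group": label, "neuron": rec.neuron_id, "loss_rate": lr,
                 "si_shuffled": curve.si_shuffled, "si_endpoint_norm": si_endpoint(curve),
                 "n_puncta": len(rec.traces), "n_tracked": rec.n_tracked(),
                 "n_lost": rec.n_lost(), "n_rejected": rec.n_rejected()}
            )
            for t, raw, norm in zip(curve.t, curve.si_raw, curve.si_norm):
                si_rows.append(
                    {"group": label, "neuron": rec.neuron_id, "t_min": t,
                     "si_raw": raw, "si_norm": norm}
                )
        group_rom[label] = roms
        group_loss[label] = losses
        group_si[label] = curves
        group_counts[label] = counts
        exclusions[label] = {
            "rejected_split_merge": n_rej, "lost": n_lost,
            "tracked": n_tracked, "too_short_for_rom": n_short,
        }

    for name, rows in (
        ("per_punctum_metrics.csv", punctum_rows),
        ("per_neuron_metrics.csv", neuron_rows),
        ("si_curves.csv", si_rows),
    ):
        p = outdir / name
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.10g")
        files.append(p)

    if config.mode == "simulate":
        p = outdir / "traces.csv"
        write_trace_table([r for recs in group_records.values() for r in recs], p)
        files.append(p)

    group_summaries = {}
    for label in group_records:
        roms = np.array(group_rom[label])
        losses = np.array(group_loss[label])
        endpoints = np.array([si_endpoint(c) for c in group_si[label]])
        group_summaries[label] = {
            "n_neurons": len(group_records[label]),
            "n_puncta": int(np.sum(group_counts[label])),
            "puncta_per_neuron_mean": float(np.mean(group_counts[label])),
            "puncta_per_neuron_sd": float(np.std(group_counts[label], ddof=1))
            if len(group_counts[label]) > 1 else 0.0,
            "range_over_mean_pct_mean": float(100 * roms.mean()),
            "range_over_mean_pct_sd": float(100 * roms.std(ddof=1)) if roms.size > 1 else 0.0,
            "loss_rate_pct_mean": float(100 * losses.mean()),
            "loss_rate_pct_sd": float(100 * losses.std(ddof=1)) if losses.size > 1 else 0.0,
            "si_endpoint_norm_mean": float(endpoints.mean()),
            "si_endpoint_norm_sem": float(endpoints.std(ddof=1) / np.sqrt(endpoints.size))
            if endpoints.size > 1 else 0.0,
        }

    comparisons = {}
    labels = sorted(group_records)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            key = f"{a}_vs_{b}"
            comparisons[key] = {
                "range_over_mean": _ks_dict(compare_distributions(group_rom[a], group_rom[b])),
                "si_decay": _ks_dict(compare_si_curves(group_si[a], group_si[b])),
                "loss_rate": _ks_dict(compare_distributions(group_loss[a], group_loss[b])),
                "alpha": config.alpha,
            }

    if config.make_figures:
        files += _constancy_figures(outdir, group_si, group_rom)

    report = Report(
        group_summaries=group_summaries,
        comparisons=comparisons,
        exclusions=exclusions,
        files=files,
        config=config.to_dict(),
    )
    files.append(report.to_json(outdir / "summary.json"))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    files.append(outdir / "config.yaml")
    return report


def _constancy_figures(outdir: Path, group_si, group_rom) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, curves in group_si.items():
        t = curves[0].t / 60.0
        mat = np.vstack([c.si_norm for c in curves])
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else 0 * mean
        ax.errorbar(t, mean, yerr=sem, label=label, capsize=2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized SI")
    ax.legend()
    fig.tight_layout()
    p = outdir / "si_decay.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, roms in group_rom.items():
        ax.hist(100 * np.asarray(roms), bins=30, alpha=0.5, label=label, density=True)
    ax.set_xlabel("range over mean (%)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    p = outdir / "range_over_mean_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out.append(p)
    return out


def run_frap_pipeline(config: RunConfig) -> Report:
    """FRAP analysis: correct, fit, summarise and compare groups.

    In simulate mode each group label must name a generating-truth bundle
    (``wt`` or ``ko``); in traces mode each group value is a directory or
    list of FRAP table files.  Per punctum: bleach-corrected curve, two-pool
    fit and fractional recovery.  Per group: averaged curve +/- SEM and a
    fit of the average.  Between groups: KS test on fractional recoveries.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    schedule = frap_schedule()

    group_curves: dict[str, list] = {}
    for gi, (label, value) in enumerate(sorted(config.groups.items())):
        curves = []
        if config.mode == "simulate":
            if value not in FRAP_TRUTHS:
                raise ParameterError("groups", f"no FRAP generating truth named {value!r}")
            truth = FRAP_TRUTHS[value]
            for k in range(config.frap_n_synapses):
                rec = simulate_frap_experiment(
                    truth,
                    schedule,
                    noise_sd=config.frap_noise_sd,
                    bleach_rate=config.frap_bleach_rate,
                    n_reference=10,
                    seed=config.seed + 10_000 * gi + k,
                    punctum_id=f"{label}_s{k}",
                )
                curves.append((rec.punctum_id, bleach_correct(rec)))
        elif config.mode == "traces":
            paths = sorted(Path(value).glob("*.csv")) if Path(value).is_dir() else [Path(value)]
            if not paths:
                raise SchemaError(f"no FRAP tables found under {value}")
            for p in paths:
                rec = read_frap_table(p)
                curves.append((rec.punctum_id, bleach_correct(rec)))
        else:
            raise ParameterError("mode", f"unsupported input mode {config.mode!r}")
        group_curves[label] = curves

    fit_rows = []
    group_frac: dict[str, list[float]] = {}
    group_summaries = {}
    avg_curves = {}
    for label, curves in group_curves.items():
        fracs = []
        for pid, curve in curves:
            fit = fit_double_exponential(curve)
            frac = fractional_recovery(curve)
            fracs.append(frac)
            fit_rows.append(
                {"group": label, "punctum": pid, "f_bl": fit.f_bl, "p_f": fit.p_f,
                 "tau_f_min": fit.tau_f, "tau_s_min": fit.tau_s,
                 "fractional_recovery": frac, "converged": fit.converged,
                 "well_separated": fit.well_separated}
            )
        group_frac[label] = fracs
        avg = average_frap_curve([c for _, c in curves])
        avg_curves[label] = avg
        avg_fit = fit_double_exponential(avg)
        if not avg_fit.converged:
            logger.warning("average-curve fit for group %s did not converge", label)
        group_summaries[label] = {
            "n_synapses": len(curves),
            "fractional_recovery_mean": float(np.mean(fracs)),
            "fractional_recovery_sd": float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0,
            "avg_fit": {
                "f_bl": avg_fit.f_bl, "p_f": avg_fit.p_f,
                "tau_f_min": avg_fit.tau_f, "tau_s_min": avg_fit.tau_s,
                "tau_s_hr": avg_fit.tau_s / 60.0,
                "converged": avg_fit.converged,
                "well_separated": avg_fit.well_separated,
            },
        }

    p = outdir / "frap_fits.csv"
    pd.DataFrame(fit_rows).to_csv(p, index=False, float_format="%.10g")
    files.append(p)
    avg_rows = []
    for label, avg in avg_curves.items():
        for t, v, s in zip(avg.t, avg.value, avg.sem):
            avg_rows.append({"group": label, "t_min": t, "mean": v, "sem": s})
    p = outdir / "frap_average_curves.csv"
    pd.DataFrame(avg_rows).to_csv(p, index=False, float_format="%.10g")
    files.append(p)

    comparisons = {}
    labels = sorted(group_curves)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            comparisons[f"{a}_vs_{b}"] = {
                "fractional_recovery": _ks_dict(
                    compare_distributions(group_frac[a], group_frac[b])
                ),
                "alpha": config.alpha,
            }

    if config.make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for label, avg in avg_curves.items():
            ax.errorbar(avg.t, avg.value, yerr=avg.sem, label=label, capsize=2)
        ax.set_xlabel("time after bleach (min)")
        ax.set_ylabel("normalized fluorescence")
        ax.legend()
        fig.tight_layout()
        p = outdir / "frap_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        files.append(p)

    report = Report(
        group_summaries=group_summaries,
        comparisons=comparisons,
        exclusions={},
        files=files,
        config=config.to_dict(),
    )
    files.append(report.to_json(outdir / "frap_summary.json"))
    return report
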