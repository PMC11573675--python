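"""Command-line pipeline: simulate, fit, compare, posterior-simulate, stats.

A YAML configuration (flags override file values) fully determines every
output: each stochastic stage derives its random stream from the master
seed plus a stage-specific offset. Outputs are CSV tables stamped with
the configuration hash; a JSON run log records the configuration,
seeds, package versions and runtime. The CLI is a thin shell over the
library modules — everything it does is available as importable
functions.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior_stats, model_comparison, synthetic_data
from .fitting import FitResult, ModelSpec, enumerate_model_space, fit_subject
from .synthetic_data import SchemaError, read_table, validate_table
from .task_graphs import TaskProtocol, build_protocol

#: Stage offsets added to the master seed so stages draw from distinct streams.
STAGE_SEEDS = {"cohort": 1, "fit": 2, "compare": 3, "posterior": 4, "stats": 5}

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "protocol": {
        "n_prior_trials": 48,
        "n_transfer_trials": 36,
        "sequence_length": 12,
    },
    "cohort": {
        "n_per_condition": 10,
        "model": "M3",
        "n_alphas": 2,
        "n_taus": 2,
        "params": {
            "alpha_prior": [0.1, 0.5],
            "alpha_transfer": [0.1, 0.5],
            "tau_exp": [0.1, 0.5],
            "tau_inf": [0.1, 0.5],
            "omega": [0.3, 0.9],
        },
    },
    "fitting": {"n_starts": 5, "maxfev": 500, "models": "generating"},
    "comparison": {"n_draws": 200, "n_reps": 10, "criterion": "waic"},
    "stats": {"n_bins": 4, "n_boot": 2000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None, **overrides) -> dict:
    """Merge defaults, an optional YAML file, and keyword overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, {k: v for k, v in overrides.items() if v is not None})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# srcompose_config={cfg_hash}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# protocol serialization


def protocol_to_frame(protocol: TaskProtocol) -> pd.DataFrame:
    """Flat table of one session: one row per observation and per probe."""
    rows = []
    for phase in ("prior", "transfer"):
        data = protocol.phase(phase)
        for trial, seq in enumerate(data.sequences, start=1):
            for step, s in enumerate(seq, start=1):
                rows.append(
                    {
                        "phase": phase,
                        "trial": trial,
                        "kind": "observation",
                        "step": step,
                        "compound": s.label(data.f1, data.f2),
                        "probed_size": "",
                        "cue": "",
                        "option_correct": "",
                        "option_lure": "",
                    }
                )
        for exp, inf in data.probes:
            for q in (exp, inf):
                rows.append(
                    {
                        "phase": phase,
                        "trial": q.trial + 1,
                        "kind": f"{q.probe_type}_probe",
                        "step": "",
                        "compound": "",
                        "probed_size": q.probed_size,
                        "cue": q.cue.label(data.f1, data.f2),
                        "option_correct": q.option_correct.label(data.f1, data.f2),
                        "option_lure": q.option_lure.label(data.f1, data.f2),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fit result round trip

_PARAM_COLS = ("alpha_prior", "alpha_transfer", "tau_exp", "tau_inf", "omega")


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    rows = []
    for fit in fits:
        row = {
            "subject_id": fit.subject_id,
            "model": fit.model_spec.model,
            "n_alphas": fit.model_spec.n_alphas,
            "n_taus": fit.model_spec.n_taus,
            "spec": fit.model_spec.name,
            "nll": fit.nll,
            "aic": model_comparison.aic(fit),
            "n_starts": fit.n_starts,
            "converged": fit.converged,
            "seed": fit.seed,
            "flags": ";".join(fit.flags),
        }
        for name in _PARAM_COLS:
            val = getattr(fit.mle_params, name)
            row[name] = np.nan if val is None else val
        rows.append(row)
    return pd.DataFrame(rows)


def load_fits(
    path: Path, table: pd.DataFrame
) -> tuple[dict[str, FitResult], dict[str, TaskProtocol]]:
    """Rebuild FitResult objects (and their protocols) from a fits CSV.

    Pointwise log-likelihoods are recomputed by deterministic replay at
    the stored MLE, so downstream comparison stages see exactly the
    likelihoods of the stored parameters. When a subject carries several
    model variants, the one with the lowest AIC is kept.
    """
    from .fitting import pointwise_loglik

    df = pd.read_csv(path, comment="#")
    fits: dict[str, FitResult] = {}
    protocols: dict[str, TaskProtocol] = {}
    for sid, grp in df.groupby("subject_id"):
        row = grp.sort_values("aic", kind="mergesort").iloc[0]
        spec = ModelSpec(row["model"], int(row["n_alphas"]), int(row["n_taus"]))
        vec = [row["alpha_prior"] if n == "alpha" else
               row["tau_exp"] if n == "tau" else row[n]
               for n in spec.free_names]
        params = spec.to_params(vec)
        sub = table[table["subject_id"] == sid]
        if sub.empty:
            raise SchemaError(f"fitted subject {sid} not present in the table")
        protocol = synthetic_data.protocol_for_subject(
            sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
        )
        pw = pointwise_loglik(params, spec, sub, protocol)
        fits[sid] = FitResult(
            subject_id=sid,
            model_spec=spec,
            mle_params=params,
            mle_vector=np.asarray(vec, dtype=float),
            nll=float(-pw.sum()),
            pointwise=pw,
            n_starts=int(row["n_starts"]),
            converged=bool(row["converged"]),
            seed=int(row["seed"]),
        )
        protocols[sid] = protocol
    return fits, protocols


# ---------------------------------------------------------------------------
# pipeline stages (importable; the CLI wraps these)


def _cohort_sampler(cfg: dict):
    params = dict(cfg["cohort"]["params"])
    model = cfg["cohort"]["model"]
    if model != "M3":
        params.pop("omega", None)
    return synthetic_data.uniform_sampler(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in params.items()}
    )


def stage_simulate_agents(cfg: dict) -> pd.DataFrame:
    spec = ModelSpec(
        cfg["cohort"]["model"], cfg["cohort"]["n_alphas"], cfg["cohort"]["n_taus"]
    )
    return synthetic_data.simulate_cohort(
        cfg["cohort"]["n_per_condition"],
        spec,
        _cohort_sampler(cfg),
        master_seed=cfg["master_seed"] + STAGE_SEEDS["cohort"],
    )


def _specs_to_fit(cfg: dict) -> list[ModelSpec]:
    models = cfg["fitting"]["models"]
    if models == "all":
        return enumerate_model_space()
    if models == "generating":
        return [
            ModelSpec(
                cfg["cohort"]["model"],
                cfg["cohort"]["n_alphas"],
                cfg["cohort"]["n_taus"],
            )
        ]
    return [ModelSpec(m["model"], m["n_alphas"], m["n_taus"]) for m in models]


def stage_fit(cfg: dict, table: pd.DataFrame) -> list[FitResult]:
    validate_table(table)
    fits = []
    base_seed = cfg["master_seed"] + STAGE_SEEDS["fit"]
    for i, (sid, sub) in enumerate(table.groupby("subject_id")):
        protocol = synthetic_data.protocol_for_subject(
            sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
        )
        for spec in _specs_to_fit(cfg):
            fits.append(
                fit_subject(
                    spec,
                    sub,
                    protocol,
                    n_starts=cfg["fitting"]["n_starts"],
                    seed=base_seed + i,
                    maxfev=cfg["fitting"]["maxfev"],
                )
            )
    return fits


def stage_compare(
    cfg: dict, table: pd.DataFrame, fits: list[FitResult]
) -> pd.DataFrame:
    rows = []
    base_seed = cfg["master_seed"] + STAGE_SEEDS["compare"]
    for i, fit in enumerate(fits):
        sub = table[table["subject_id"] == fit.subject_id]
        protocol = synthetic_data.protocol_for_subject(
            sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
        )
        rows.append(
            model_comparison.subject_report(
                fit, sub, protocol,
                n_draws=cfg["comparison"]["n_draws"],
                seed=base_seed + i,
            )
        )
    return pd.DataFrame(rows)


def stage_posterior_sim(cfg, table, fits_map, protocols):
    return model_comparison.posterior_simulate(
        fits_map,
        protocols,
        n_reps=cfg["comparison"]["n_reps"],
        seed=cfg["master_seed"] + STAGE_SEEDS["posterior"],
    )


def stage_stats(cfg: dict, table: pd.DataFrame):
    bins = behavior_stats.bin_accuracy(table, n_bins=cfg["stats"]["n_bins"])
    trends = behavior_stats.trend_per_subject(table)
    interaction = behavior_stats.interaction_contrast(
        table,
        n_boot=cfg["stats"]["n_boot"],
        seed=cfg["master_seed"] + STAGE_SEEDS["stats"],
    )
    return bins, trends, interaction


# ---------------------------------------------------------------------------
# CLI


class _Run:
    """Tracks outputs so a failing command leaves no partial files."""

    def __init__(self, cfg: dict, out_dir: str):
        self.cfg = cfg
        self.hash = config_hash(cfg)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []
        self.t0 = time.time()

    def write(self, df: pd.DataFrame, name: str) -> Path:
        path = self.out / name
        _write_csv(df, path, self.hash)
        self.files.append(path)
        return path

    def write_json(self, obj, name: str) -> Path:
        path = self.out / name
        payload = {"srcompose_config": self.hash}
        payload.update(obj if isinstance(obj, dict) else {"data": obj})
        path.write_text(json.dumps(payload, indent=2, default=str))
        self.files.append(path)
        return path

    def finish(self, command: str) -> None:
        log = {
            "command": command,
            "config": self.cfg,
            "config_hash": self.hash,
            "master_seed": self.cfg["master_seed"],
            "stage_seeds": STAGE_SEEDS,
            "versions": {
                "srcompose": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": sys.version.split()[0],
            },
            "runtime_s": round(time.time() - self.t0, 3),
            "outputs": [str(p) for p in self.files],
        }
        (self.out / "run_log.json").write_text(json.dumps(log, indent=2))

    def abort(self) -> None:
        for path in self.files:
            path.unlink(missing_ok=True)


def _run_command(command: str, cfg: dict, out_dir: str, body) -> None:
    run = _Run(cfg, out_dir)
    try:
        body(run)
    except (SchemaError, ValueError, FileNotFoundError, KeyError) as err:
        run.abort()
        raise click.ClickException(str(err)) from err
    run.finish(command)


_cfg_opt = click.option("--config", "config_path", type=click.Path(exists=True),
                        default=None, help="YAML configuration file.")
_out_opt = click.option("--out-dir", default="srcompose_out", show_default=True)
_seed_opt = click.option("--seed", "master_seed", type=int, default=None,
                         help="Override the master seed.")


@click.group()
@click.version_option(__version__)
def cli():
    """Simulate, fit and compare successor models of the product-graph task."""


@cli.command("simulate-task")
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--condition", type=click.Choice(["prior4cycle", "prior6cycle"]),
              default="prior4cycle", show_default=True)
def cmd_simulate_task(config_path, out_dir, master_seed, condition):
    """Export one session protocol as a flat observation/probe table."""
    cfg = load_config(config_path, master_seed=master_seed)

    def body(run: _Run):
        protocol = build_protocol(
            condition, cfg["master_seed"], **cfg["protocol"]
        )
        run.write(protocol_to_frame(protocol), f"protocol_{condition}.csv")

    _run_command("simulate-task", cfg, out_dir, body)


@cli.command("simulate-agents")
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--n-per-condition", type=int, default=None)
@click.option("--model", type=click.Choice(["M1", "M2", "M3"]), default=None)
def cmd_simulate_agents(config_path, out_dir, master_seed, n_per_condition, model):
    """Simulate an agent cohort and write the behavioral table."""
    cfg = load_config(config_path, master_seed=master_seed)
    if n_per_condition is not None:
        cfg["cohort"]["n_per_condition"] = n_per_condition
    if model is not None:
        cfg["cohort"]["model"] = model

    def body(run: _Run):
        table = stage_simulate_agents(cfg)
        run.write(table, "cohort.csv")

    _run_command("simulate-agents", cfg, out_dir, body)


@cli.command("fit")
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--table", "table_path", required=True, type=click.Path(exists=True))
@click.option("--models", type=click.Choice(["generating", "all"]), default=None)
def cmd_fit(config_path, out_dir, master_seed, table_path, models):
    """Fit model variants to every subject of a behavioral table."""
    cfg = load_config(config_path, master_seed=master_seed)
    if models is not None:
        cfg["fitting"]["models"] = models

    def body(run: _Run):
        table = read_table(table_path)
        fits = stage_fit(cfg, table)
        run.write(fits_to_frame(fits), "fits.csv")

    _run_command("fit", cfg, out_dir, body)


@cli.command("compare")
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--table", "table_path", required=True, type=click.Path(exists=True))
@click.option("--fits", "fits_path", required=True, type=click.Path(exists=True))
def cmd_compare(config_path, out_dir, master_seed, table_path, fits_path):
    """WAIC/AIC comparison report and model frequencies."""
    cfg = load_config(config_path, master_seed=master_seed)

    def body(run: _Run):
        table = read_table(table_path)
        fits_map, protocols = load_fits(Path(fits_path), table)
        report = stage_compare(cfg, table, list(fits_map.values()))
        run.write(report, "comparison.csv")
        if report.groupby("subject_id")["spec"].count().eq(12).all():
            freq, class_freq = model_comparison.model_frequencies(
                report, criterion=cfg["comparison"]["criterion"]
            )
            run.write(freq.rename("frequency").reset_index(names="spec"),
                      "model_frequencies.csv")
            run.write(class_freq.rename("frequency").reset_index(names="model"),
                      "class_frequencies.csv")

    _run_command("compare", cfg, out_dir, body)


@cli.command("posterior-sim")
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--table", "table_path", required=True, type=click.Path(exists=True))
@click.option("--fits", "fits_path", required=True, type=click.Path(exists=True))
def cmd_posterior_sim(config_path, out_dir, master_seed, table_path, fits_path):
    """Simulate sessions at the fitted parameters; summarize accuracy."""
    cfg = load_config(config_path, master_seed=master_seed)

    def body(run: _Run):
        table = read_table(table_path)
        fits_map, protocols = load_fits(Path(fits_path), table)
        sim = stage_posterior_sim(cfg, table, fits_map, protocols)
        run.write(sim.cells, "posterior_cells.csv")
        run.write(sim.across_condition, "posterior_across_condition.csv")

    _run_command("posterior-sim", cfg, out_dir, body)


@cli.command("stats")
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--table", "table_path", required=True, type=click.Path(exists=True))
def cmd_stats(config_path, out_dir, master_seed, table_path):
    """Binned learning curves, per-subject trends, interaction contrast."""
    cfg = load_config(config_path, master_seed=master_seed)

    def body(run: _Run):
        table = read_table(table_path)
        bins, trends, interaction = stage_stats(cfg, table)
        run.write(bins.summary, "accuracy_bins.csv")
        run.write(trends, "trends.csv")
        run.write_json(interaction.__dict__, "interaction.json")

    _run_command("stats", cfg, out_dir, body)


@cli.command("run-all")
@_cfg_opt
@_out_opt
@_seed_opt
@click.option("--n-per-condition", type=int, default=None)
@click.option("--model", type=click.Choice(["M1", "M2", "M3"]), default=None)
def cmd_run_all(config_path, out_dir, master_seed, n_per_condition, model):
    """simulate-agents -> fit -> compare -> posterior-sim -> stats."""
    cfg = load_config(config_path, master_seed=master_seed)
    if n_per_condition is not None:
        cfg["cohort"]["n_per_condition"] = n_per_condition
    if model is not None:
        cfg["cohort"]["model"] = model

    def body(run: _Run):
        table = stage_simulate_agents(cfg)
        run.write(table, "cohort.csv")
        fits = stage_fit(cfg, table)
        run.write(fits_to_frame(fits), "fits.csv")
        report = stage_compare(cfg, table, fits)
        run.write(report, "comparison.csv")
        best: dict[str, FitResult] = {}
        protocols: dict[str, TaskProtocol] = {}
        for fit in fits:
            cur = best.get(fit.subject_id)
            if cur is None or model_comparison.aic(fit) < model_comparison.aic(cur):
                best[fit.subject_id] = fit
        for sid in best:
            sub = table[table["subject_id"] == sid]
            protocols[sid] = synthetic_data.protocol_for_subject(
                sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
            )
        sim = stage_posterior_sim(cfg, table, best, protocols)
        run.write(sim.cells, "posterior_cells.csv")
        run.write(sim.across_condition, "posterior_across_condition.csv")
        bins, trends, interaction = stage_stats(cfg, table)
        run.write(bins.summary, "accuracy_bins.csv")
        run.write(trends, "trends.csv")
        run.write_json(interaction.__dict__, "interaction.json")

    _run_command("run-all", cfg, out_dir, body)


if __name__ == "__main__":  # pragma: no cover
    cli()
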