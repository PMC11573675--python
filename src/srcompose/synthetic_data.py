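"""Synthetic behavioral datasets with the structure of the two-phase study.

Every downstream stage (fitting, model comparison, descriptive
statistics) operates on a long-format *behavioral table*: one row per
answered probe, two probes per trial, 48 prior-learning and 36
transfer-learning trials per subject, under two between-subject
conditions (4-cycle prior vs 6-cycle prior). This module generates such
tables from simulated agent cohorts (with matched parameter draws across
conditions, as in a-priori simulation designs) or from fixed
accuracy-profile subjects (independent Bernoulli cells, useful as
statistics fixtures), and round-trips them through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import sr_models
from .sr_models import Params
from .task_graphs import build_protocol

__all__ = [
    "REQUIRED_COLUMNS",
    "TRUE_PARAM_COLUMNS",
    "SchemaError",
    "validate_table",
    "simulate_cohort",
    "simulate_profile_subjects",
    "write_table",
    "read_table",
    "uniform_sampler",
    "fixed_sampler",
    "protocol_for_subject",
]

CONDITIONS = ("prior4cycle", "prior6cycle")

#: Required columns of the behavioral table, in canonical order.
REQUIRED_COLUMNS = (
    "subject_id",
    "condition",
    "phase",
    "trial",
    "probe_type",
    "probed_size",
    "cue",
    "option_correct",
    "option_lure",
    "chosen",
    "accuracy",
    "generator",
    "protocol_seed",
)

#: Generating parameters are carried with a ``true_`` prefix so fitted and
#: generating values can never be confused.
TRUE_PARAM_COLUMNS = (
    "true_alpha_prior",
    "true_alpha_transfer",
    "true_tau_exp",
    "true_tau_inf",
    "true_omega",
)

_CATEGORICAL = {
    "phase": {"prior", "transfer"},
    "probe_type": {"experience", "inference"},
    "condition": set(CONDITIONS),
    "chosen": {"correct", "lure"},
}


class SchemaError(ValueError):
    """Raised when a behavioral table violates the documented schema."""


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a behavioral table against the schema; return it unchanged.

    Checks required columns, categorical values, the accuracy/chosen
    consistency, integer probed sizes, and the two-probes-per-trial
    invariant. Missing choices (empty ``chosen``) are allowed and must
    have missing accuracy.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing required column '{col}'")
    for col, allowed in _CATEGORICAL.items():
        vals = table[col].dropna()
        bad = set(vals.unique()) - allowed
        if bad:
            raise SchemaError(f"invalid values in column '{col}': {sorted(bad)}")
    for col in ("trial", "probed_size", "protocol_seed"):
        if not pd.api.types.is_integer_dtype(table[col]):
            raise SchemaError(f"column '{col}' must be integer-typed")
    sizes = set(table["probed_size"].unique()) - {4, 6}
    if sizes:
        raise SchemaError(f"invalid probed_size values: {sorted(sizes)}")
    if (table["trial"] < 1).any():
        raise SchemaError("trial numbers must be 1-based positive integers")
    answered = table["chosen"].notna()
    acc = pd.to_numeric(table["accuracy"], errors="coerce")
    if acc[answered].isna().any():
        raise SchemaError("answered probes must carry 0/1 accuracy")
    mismatch = acc[answered] != (table.loc[answered, "chosen"] == "correct")
    if mismatch.any():
        raise SchemaError("accuracy must equal 1 iff chosen == correct")
    counts = table.groupby(["subject_id", "phase", "trial"]).size()
    if (counts != 2).any():
        key = counts[counts != 2].index[0]
        raise SchemaError(
            f"expected exactly 2 probe rows per (subject, phase, trial); "
            f"found {counts[key]} at {key}"
        )
    return table


# ---------------------------------------------------------------------------
# parameter samplers

ParamSampler = Callable[[np.random.Generator], Params]


def fixed_sampler(**kwargs) -> ParamSampler:
    """Sampler that always returns the given parameter values."""
    params = Params(**kwargs)

    def sample(rng: np.random.Generator) -> Params:
        return params

    return sample


def uniform_sampler(**ranges) -> ParamSampler:
    """Sampler drawing each named parameter independently.

    Each keyword is a parameter name mapped to a fixed float or a
    ``(low, high)`` uniform range. Ranges must lie inside the parameter
    bounds; ``Params`` validation rejects anything outside.
    """

    def sample(rng: np.random.Generator) -> Params:
        vals = {}
        for name, spec in ranges.items():
            if isinstance(spec, (tuple, list)):
                lo, hi = spec
                if not np.isfinite([lo, hi]).all() or hi < lo:
                    raise SchemaError(f"invalid range for '{name}': {spec}")
                vals[name] = float(rng.uniform(lo, hi))
            else:
                vals[name] = float(spec)
        return Params(**vals)

    return sample


def _subject_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def protocol_for_subject(condition: str, protocol_seed: int, **kwargs):
    """Rebuild the session protocol recorded in a behavioral table row."""
    return build_protocol(condition, int(protocol_seed), **kwargs)


def _params_columns(params: Params) -> dict[str, float]:
    return {
        "true_alpha_prior": params.alpha_prior,
        "true_alpha_transfer": params.alpha_transfer,
        "true_tau_exp": params.tau_exp,
        "true_tau_inf": params.tau_inf,
        "true_omega": np.nan if params.omega is None else params.omega,
    }


def simulate_cohort(
    n_per_condition: int,
    model_spec,
    param_sampler: ParamSampler,
    master_seed: int,
    conditions: Sequence[str] = CONDITIONS,
    n_restarts: int = 5,
) -> pd.DataFrame:
    """Simulate a cohort of agents with matched parameters across conditions.

    Subject ``k`` receives the same parameter draw in every condition
    (the matched-parameters contract of a-priori simulation designs) but
    a condition-specific protocol seed. Returns the concatenated
    behavioral table with generating parameters in ``true_*`` columns.
    """
    if n_per_condition < 1:
        raise SchemaError("n_per_condition must be >= 1")
    model = sr_models._model_name(model_spec)
    tag = getattr(model_spec, "name", model)
    root = np.random.SeedSequence(master_seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    frames = []
    for k in range(n_per_condition):
        params = param_sampler(param_rng)
        params.validate_for(model)
        for condition in conditions:
            ss_proto, ss_choice = np.random.SeedSequence(
                (master_seed, k, CONDITIONS.index(condition))
            ).spawn(2)
            protocol_seed = _subject_seed(ss_proto)
            protocol = build_protocol(condition, protocol_seed)
            rng = np.random.default_rng(ss_choice)
            records, _ = sr_models.run_agent(
                model_spec, params, protocol, rng, n_restarts=n_restarts
            )
            records["subject_id"] = f"{tag}_{condition}_{k:03d}"
            records["condition"] = condition
            records["generator"] = tag
            records["protocol_seed"] = protocol_seed
            for col, val in _params_columns(params).items():
                records[col] = val
            frames.append(records)
    table = pd.concat(frames, ignore_index=True)
    extra = [c for c in table.columns if c not in REQUIRED_COLUMNS]
    table = table[list(REQUIRED_COLUMNS) + extra]
    return validate_table(table)


def simulate_profile_subjects(
    accuracy_map: Mapping[tuple[str, str, int, str], float],
    n: int,
    seed: int,
    n_prior_trials: int = 48,
    n_transfer_trials: int = 36,
) -> pd.DataFrame:
    """Simulate subjects whose accuracy is a fixed probability per cell.

    ``accuracy_map`` maps ``(phase, probe_type, probed_size, condition)``
    to a success probability; cells not listed default to 0.5. Choices
    are independent Bernoulli draws, so these subjects carry no
    sequential structure — they are fixtures for the statistics stages,
    with the same schema as agent-generated tables.
    """
    for key, p in accuracy_map.items():
        if not 0 <= p <= 1:
            raise SchemaError(f"probability out of range for cell {key}: {p}")
    conditions = sorted({key[3] for key in accuracy_map})
    rng = np.random.default_rng(seed)
    rows = []
    for condition in conditions:
        for k in range(n):
            sid = f"profile_{condition}_{k:03d}"
            for phase, n_trials in (
                ("prior", n_prior_trials),
                ("transfer", n_transfer_trials),
            ):
                for trial in range(1, n_trials + 1):
                    for probe_type in ("experience", "inference"):
                        size = 4 if (trial + (probe_type == "inference")) % 2 else 6
                        p = accuracy_map.get(
                            (phase, probe_type, size, condition), 0.5
                        )
                        correct = bool(rng.random() < p)
                        rows.append(
                            {
                                "subject_id": sid,
                                "condition": condition,
                                "phase": phase,
                                "trial": trial,
                                "probe_type": probe_type,
                                "probed_size": size,
                                "cue": "cue",
                                "option_correct": "opt+",
                                "option_lure": "opt-",
                                "chosen": "correct" if correct else "lure",
                                "accuracy": int(correct),
                                "generator": "profile",
                                "protocol_seed": -1,
                            }
                        )
    return validate_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# CSV round trip

_READ_DTYPES = {
    "trial": np.int64,
    "probed_size": np.int64,
    "protocol_seed": np.int64,
}


def write_table(table: pd.DataFrame, path) -> None:
    """Write a validated behavioral table as UTF-8 CSV with a header row."""
    validate_table(table)
    table.to_csv(path, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    """Read and validate a behavioral table; lossless for written tables.

    Missing choices round-trip as empty fields. Unknown extra columns are
    preserved. Raises :class:`SchemaError` naming the first problem
    (including the offending column or row group).
    """
    try:
        table = pd.read_csv(path, keep_default_na=False, na_values=[""], comment="#")
    except pd.errors.ParserError as err:
        raise SchemaError(f"malformed CSV {path}: {err}") from err
    for col, dtype in _READ_DTYPES.items():
        if col in table.columns and table[col].notna().all():
            try:
                table[col] = table[col].astype(dtype)
            except (TypeError, ValueError) as err:
                raise SchemaError(
                    f"column '{col}' is not integer-typed: {err}"
                ) from err
    return validate_table(table)
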