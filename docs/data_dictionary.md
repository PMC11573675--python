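# Data dictionary

## Behavioral table (`cohort.csv` and all table inputs/outputs)

UTF-8 CSV, header row, one row per answered probe. Files written by the
CLI start with a comment line `# srcompose_config=<hash>`; readers skip
`#` lines.

| column | type | values / meaning |
| --- | --- | --- |
| `subject_id` | str | unique per subject |
| `condition` | str | `prior4cycle` or `prior6cycle` (between-subject prior condition) |
| `phase` | str | `prior` (48 trials) or `transfer` (36 trials) |
| `trial` | int | 1-based trial (sequence) number within phase |
| `probe_type` | str | `experience` or `inference` |
| `probed_size` | int | 4 or 6 — the graph factor this probe tests |
| `cue` | str | compound label shown as cue, e.g. `D'8'` |
| `option_correct` | str | next compound under the generative dynamics |
| `option_lure` | str | foil differing only on the probed factor |
| `chosen` | str | `correct` or `lure`; empty = no response (excluded from likelihoods) |
| `accuracy` | int | 1 iff `chosen == correct`; empty when unanswered |
| `generator` | str | producing model/profile tag, e.g. `M3_2a2t`, `profile` |
| `protocol_seed` | int | seed that rebuilds this subject's full session (`-1` for profile fixtures) |
| `true_alpha_prior` … `true_omega` | float | generating parameters of simulated subjects (`true_` prefix; NaN where not applicable) |
| `p_correct`, `v_correct`, `v_lure` | float | (extras from agent simulation) model probability and option values |

Invariants: exactly two probe rows per (subject, phase, trial);
`accuracy == 1` iff `chosen == "correct"`.

## Fits table (`fits.csv`)

One row per subject × fitted variant: `subject_id`, `model`,
`n_alphas`, `n_taus`, `spec` (e.g. `M3_2a2t`), `nll`, `aic`,
`n_starts`, `converged`, `seed`, `flags`, and the MLE parameters
`alpha_prior`, `alpha_transfer`, `tau_exp`, `tau_inf`, `omega`
(NaN for M1/M2).

## Comparison report (`comparison.csv`)

One row per subject × variant: `subject_id`, `model`, `spec`,
`n_free`, `nll`, `waic`, `lppd`, `p_waic` (Laplace-approximate), `aic`,
`flags`. `model_frequencies.csv` / `class_frequencies.csv` hold
best-fit proportions per variant and per model class.

## Posterior simulation (`posterior_cells.csv`, `posterior_across_condition.csv`)

Cells: `condition`, `phase`, `probe_type`, `probed_size`, `mean`,
`sem`, `n` (subject-level means first). Across-condition file:
`probe_type`, `probed_size`, `across_condition_diff` =
mean(prior4cycle) − mean(prior6cycle) on transfer accuracy.

## Protocol export (`protocol_<condition>.csv`)

One row per observation (`kind = observation`, with `step` and
`compound`) and per probe (`kind = experience_probe|inference_probe`,
with `probed_size`, `cue`, `option_correct`, `option_lure`).
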