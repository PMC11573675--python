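"""Render the standard figure panels from a small simulated cohort.

Writes three PNGs under scratch/: binned learning curves, the transfer
crossover panel (accuracy by prior condition and probed size), and the
model-comparison bars for the fitted variants.
"""

from pathlib import Path

from srcompose import bin_accuracy
from srcompose.fitting import ModelSpec, fit_subject
from srcompose.model_comparison import subject_report
from srcompose.plots import (
    plot_learning_curves,
    plot_model_comparison,
    plot_transfer_crossover,
)
from srcompose.synthetic_data import (
    protocol_for_subject,
    simulate_cohort,
    uniform_sampler,
)

import pandas as pd

out = Path("scratch")
out.mkdir(exist_ok=True)

sampler = uniform_sampler(
    alpha_prior=(0.1, 0.5), alpha_transfer=(0.1, 0.5),
    tau_exp=(0.1, 0.5), tau_inf=(0.1, 0.5), omega=(0.4, 0.9),
)
table = simulate_cohort(8, ModelSpec("M3", 2, 2), sampler, master_seed=13)

plot_learning_curves(bin_accuracy(table)).savefig(out / "learning_curves.png", dpi=120)
plot_transfer_crossover(table).savefig(out / "transfer_crossover.png", dpi=120)

rows = []
for i, sid in enumerate(table["subject_id"].unique()[:4]):
    sub = table[table["subject_id"] == sid]
    protocol = protocol_for_subject(
        sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
    )
    for spec in (ModelSpec("M2", 2, 2), ModelSpec("M3", 2, 2)):
        fit = fit_subject(spec, sub, protocol, n_starts=2, seed=i, maxfev=300)
        rows.append(subject_report(fit, sub, protocol, n_draws=100, seed=i))
plot_model_comparison(pd.DataFrame(rows)).savefig(out / "model_comparison.png", dpi=120)
print("wrote", sorted(p.name for p in out.glob("*.png")))
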