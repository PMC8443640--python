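"""AIC model selection on a synthetic folded joint SFS generated under M7 at
the Table-1 ML values: does M7 beat the constant-size and single-change
panmictic alternatives?

Writes results/model_selection.json.
"""

import json
import os
import time

from demoscope import FitOptions, fit_scenario, get_template, rank_models
from demoscope.workflows import m7_dataset

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, "..", "results")
os.makedirs(RESULTS, exist_ok=True)

t0 = time.time()
obs, _ = m7_dataset(S=50_000, nsam=(10, 10), R_obs=200_000, seed=3)
print(f"dataset: {obs.total():.0f} SNPs ({time.time() - t0:.0f} s)")

fits = []
for tid, starts, budget in [("M1", 3, 30), ("M3", 2, 40), ("M7", 1, 40)]:
    fit = fit_scenario(
        obs, get_template(tid), FitOptions(R=20_000, n_starts=starts, budget=budget, seed=5)
    )
    fits.append(fit)
    print(f"{tid}: lnCL = {fit.lnCL:.1f}, AIC = {fit.aic:.1f} ({time.time() - t0:.0f} s)")

ranking = rank_models(fits)
payload = {
    "winner": ranking.best.template_id,
    "ranking": [
        {"template": f.template_id, "lnCL": f.lnCL, "k": f.k, "AIC": f.aic, "dAIC": d}
        for f, d in zip(ranking.fits, ranking.delta_aic)
    ],
    "winner_params": ranking.best.params,
}
out = os.path.join(RESULTS, "model_selection.json")
with open(out, "w") as fh:
    json.dump(payload, fh, indent=1, default=float)
print(f"winner: {ranking.best.template_id}")
print(f"wrote {out}")
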