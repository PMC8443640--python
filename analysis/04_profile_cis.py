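"""Profile composite-likelihood recovery of the M7 parameters from synthetic
data, compared against the study's printed 95% CIs, plus a block-bootstrap CI
demonstration on a small one-parameter family.

Writes results/profile_cis.json.  The full acceptance-grade settings
(R_eval up to 5e5) live in scripts/acceptance.py; this script uses lighter
settings for a quick end-to-end run.
"""

import json
import os
import time

from demoscope import (
    FitOptions,
    Scenario,
    ScenarioTemplate,
    SyntheticDatasetSpec,
    TABLE1_M7_CI,
    block_bootstrap,
    draw_observed_sfs,
    profile_parameter,
)
from demoscope.workflows import m7_dataset, profile_recover_m7

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, "..", "results")
os.makedirs(RESULTS, exist_ok=True)

t0 = time.time()
obs, _ = m7_dataset(S=50_000, nsam=(10, 10), R_obs=1_000_000, seed=0)
print(f"dataset ready ({time.time() - t0:.0f} s)")

profiles = {}
for name, R_eval in [("2NM0", 100_000), ("T2", 100_000), ("N0POP", 100_000),
                     ("T1", 100_000)]:
    out = profile_recover_m7(obs, name, seed=1, R_eval=R_eval, n_grid=11,
                             refine_iters=8)
    est = out.get("estimate_years", out["estimate"])
    lo, hi = TABLE1_M7_CI[name]
    out["ci"] = [lo, hi]
    out["inside_ci"] = bool(lo <= est <= hi)
    profiles[name] = out
    print(f"{name}: estimate {est:.1f}, CI [{lo}, {hi}], "
          f"inside = {out['inside_ci']} ({time.time() - t0:.0f} s)")

# --- bootstrap CI on a controlled one-parameter family ----------------------
ISL2 = ScenarioTemplate(
    "ISL2",
    "two-deme island, connectivity free",
    {"2NM0": (0.1, 100.0, True)},
    lambda p: Scenario((2000.0, 2000.0), migration=p["2NM0"], samples=(0, 1)),
)
TRUTH = 5.0
spec = SyntheticDatasetSpec(
    scenario=ISL2.build({"2NM0": TRUTH}), S=2_000, nsam=(6, 6), R=20_000,
    block_size=50, seed=42,
)
_, blocks = draw_observed_sfs(spec)


def fit_fn(obs_b, seed):
    est, _, _ = profile_parameter(
        obs_b, ISL2, "2NM0", {}, FitOptions(R=1_500, seed=seed, n_starts=1),
        bounds=(0.5, 50.0), n_grid=6, refine_iters=3,
    )
    return {"2NM0": est}


ci = block_bootstrap(blocks, ISL2, B=100, options=FitOptions(R=1_500, seed=7),
                     fit_fn=fit_fn)
boot = {
    "truth": TRUTH,
    "lower": ci.lower["2NM0"],
    "upper": ci.upper["2NM0"],
    "covers": bool(ci.lower["2NM0"] <= TRUTH <= ci.upper["2NM0"]),
    "B": ci.B,
}
print(f"bootstrap CI: [{boot['lower']:.2f}, {boot['upper']:.2f}] "
      f"covers truth = {boot['covers']} ({time.time() - t0:.0f} s)")

out_path = os.path.join(RESULTS, "profile_cis.json")
with open(out_path, "w") as fh:
    json.dump({"profiles": profiles, "bootstrap": boot}, fh, indent=1, default=float)
print(f"wrote {out_path}")
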