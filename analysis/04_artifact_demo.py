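"""How subgrouping skewed data manufactures differential correlations.

Two quantitative demonstrations of the range-restriction artifact:

1. Trivariate demo: three positively correlated variables; skew them
   with a lognormal transform and split on quartiles of the first.  The
   subgroup correlations of the other two rise monotonically with the
   subgroup variance — with no change in the underlying dependence.
   The multivariate-normal control shows no such gradient.

2. The classical direct-selection attenuation formula
   r' = rho*k / sqrt(1 - rho^2 + rho^2 k^2), verified against brute-force
   truncation experiments on a rho x k grid.

Writes results/artifact_demo.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from esmstaging.artifact_sim import (
    range_restriction_attenuation,
    simulate_fig1_demo,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    out = {}
    for transform in ("lognormal", "none"):
        res = simulate_fig1_demo(skew_transform=transform, n=100_000, seed=SEED)
        out[transform] = {
            "subgroup_variances_a": [round(v, 4) for v in res.subgroup_variances_a],
            "subgroup_r_bc": [round(v, 4) for v in res.subgroup_r_bc],
            "full_r_bc": round(res.full_r_bc, 4),
        }
        print(f"{transform:10s} subgroup r(B,C): "
              + "  ".join(f"{v:.3f}" for v in res.subgroup_r_bc)
              + f"   (pooled {res.full_r_bc:.3f})")
    print("lognormal skew turns equal dependence into an apparent "
          "severity gradient; the normal control does not\n")

    rng = np.random.default_rng(SEED)
    grid = {}
    for rho in (0.3, 0.5, 0.7):
        for k in (0.4, 0.6, 0.8):
            n = 200_000
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            c = optimize.brentq(lambda c: stats.truncnorm.std(-c, c) - k, 1e-3, 10)
            m = np.abs(x) <= c
            emp = float(np.corrcoef(x[m], y[m])[0, 1])
            formula = float(range_restriction_attenuation(rho, float(np.std(x[m]))))
            grid[f"rho={rho},k={k}"] = {"empirical": round(emp, 4),
                                        "formula": round(formula, 4)}
            print(f"rho={rho} k={k}: truncation r={emp:.3f}  formula {formula:.3f}")
    out["attenuation_grid"] = grid

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "artifact_demo.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"\nwrote {RESULTS / 'artifact_demo.json'}")


if __name__ == "__main__":
    main()
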