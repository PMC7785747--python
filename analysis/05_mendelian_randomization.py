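#!/usr/bin/env python
"""Bidirectional two-sample MR on a synthetic central-obesity -> insulin system.

Plants a causal slope of 1.86 from the adiposity-like exposure on the
insulin-like outcome in women only (slope 0 in men, and 0 in both
reverse directions), at the reference instrument count k = 222, with
mild directional pleiotropy (-0.002) in women.  Runs random-effect IVW
and MR-Egger in all four direction x sex cells and judges significance
at the Bonferroni level 0.0125.  Writes results/mr_results.tsv.
"""

import pandas as pd

from sexdimorph.mr_causal import egger, ivw
from sexdimorph.synthetic_data import generate_mr_system

OUT = "results/mr_results.tsv"
SEED = 77
K = 222

CELLS = [
    # (exposure, sex, true slope, pleiotropy mean)
    ("adiposity->insulin", "female", 1.86, -0.002),
    ("adiposity->insulin", "male", 0.0, 0.0),
    ("insulin->adiposity", "female", 0.0, 0.0),
    ("insulin->adiposity", "male", 0.0, 0.0),
]


def main() -> None:
    rows = []
    for i, (direction, sex, slope, pleio) in enumerate(CELLS):
        tab, truth = generate_mr_system(
            K, slope, pleiotropy_mean=pleio, seed=SEED + i
        )
        for res in (ivw(tab), egger(tab)):
            rows.append(
                {
                    "DIRECTION": direction, "SEX": sex, "METHOD": res.method,
                    "TRUE_SLOPE": slope, "BETA_IV": res.beta_iv, "SE_IV": res.se_iv,
                    "P_IV": res.p_iv, "INTERCEPT": res.intercept,
                    "SE_INTERCEPT": res.se_intercept,
                    "P_INTERCEPT": res.p_intercept, "K": res.k,
                    "SIGNIFICANT": res.p_iv < 0.0125,
                }
            )
    out = pd.DataFrame(rows)
    out.to_csv(OUT, sep="\t", index=False)
    print(out[["DIRECTION", "SEX", "METHOD", "TRUE_SLOPE", "BETA_IV", "P_IV",
               "SIGNIFICANT"]].to_string(index=False))
    fw = out[(out["SEX"] == "female") & (out["DIRECTION"] == "adiposity->insulin")]
    print(f"\nforward-women IVW estimate: {fw.iloc[0]['BETA_IV']:.3f} "
          f"+- {fw.iloc[0]['SE_IV']:.3f} (truth 1.86; the zero-intercept IVW "
          f"absorbs part of the planted directional pleiotropy)")
    print(f"forward-women Egger slope:  {fw.iloc[1]['BETA_IV']:.3f} "
          f"+- {fw.iloc[1]['SE_IV']:.3f}, intercept "
          f"{fw.iloc[1]['INTERCEPT']:.4f} +- {fw.iloc[1]['SE_INTERCEPT']:.4f} "
          f"(planted -0.002)")


if __name__ == "__main__":
    main()
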