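"""Arithmetic checks against the published reference tables.

Two identities make the printed outcome tables internally checkable:
(1) in a balanced design the subject-level OLS slope of TTL on TTA equals
the slope through the five per-angle means, so the published prediction-
equation slopes are recomputable from the sex-stratified mean table; and
(2) the pooled per-angle means are the sample-size-weighted averages of the
sex-stratified means.  Writes results/reference_checks.json.
"""

import argparse
import json
from pathlib import Path

from pcltunnel.reference import (
    PRINTED_SLOPES,
    TTL_POOLED,
    pooled_mean_from_sex_means,
    slope_from_angle_means,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = {}
    print("prediction-equation slopes recomputed from the per-angle means:")
    for (sex, approach), printed in PRINTED_SLOPES.items():
        slope = slope_from_angle_means(sex, approach)
        out[f"slope_{sex}_{approach}"] = round(slope, 4)
        print(f"  {sex:6s} {approach}: {slope:.4f} -> rounds to {round(slope, 2):.2f} "
              f"(published {printed:.2f})")

    print("pooled means from sample-size weighting of the sex means:")
    for angle, approach, published in ((40.0, "AM", TTL_POOLED["AM"][0]),
                                       (60.0, "AL", TTL_POOLED["AL"][-1])):
        pooled = pooled_mean_from_sex_means(angle, approach)
        out[f"pooled_ttl_{angle:.0f}_{approach}"] = round(pooled, 4)
        print(f"  {angle:.0f} deg {approach}: {pooled:.2f} -> rounds to "
              f"{round(pooled, 1):.1f} (published {published:.1f})")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "reference_checks.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {args.out / 'reference_checks.json'}")


if __name__ == "__main__":
    main()
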