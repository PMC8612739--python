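#!/usr/bin/env python
"""Inter-observer reliability of the simulated dual-rater coding.

Reads results/data/rating_pairs.csv, reports Cohen's kappa and weighted
kappa for response side and modality, the RT correlation and mean signed
RT difference, then reconciles the two raters into the analysis trial
table (residual disagreements become excluded null trials).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from audiotactile.pipeline import reliability_summary
from audiotactile.trials import reconcile_ratings, write_trials


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    pairs = pd.read_csv(args.data / "rating_pairs.csv", keep_default_na=False,
                        na_values=[""], dtype={"participant_id": str})
    for c in ("rt_s_r1", "rt_s_r2"):
        pairs[c] = pd.to_numeric(pairs[c], errors="coerce")

    summary = reliability_summary(pairs)
    for name in ("side", "modality"):
        k = summary[f"kappa_{name}"]
        kw = summary[f"weighted_kappa_{name}"]
        print(f"kappa ({name}): {k['kappa']:.3f} "
              f"(95% CI {k['ci'][0]:.3f}-{k['ci'][1]:.3f}); "
              f"weighted {kw['kappa']:.3f}")
    rt = summary.get("rt")
    if rt:
        print(f"RT agreement: r = {rt['pearson_r']:.3f}, mean signed diff "
              f"{rt['mean_signed_diff_s']*1000:.0f} ms (n = {rt['n']})")

    reconciled, rec = reconcile_ratings(pairs)
    print(f"reconciliation: {rec.n_agreed} agreed, {rec.n_disagreed} excluded as null")
    args.out.mkdir(parents=True, exist_ok=True)
    write_trials(reconciled.drop(columns=["rater_agreed"]), args.data / "trials_reconciled.csv")
    (args.out / "reliability.json").write_text(json.dumps(summary, indent=2, default=float))
    print(f"wrote {args.out}/reliability.json and {args.data}/trials_reconciled.csv")


if __name__ == "__main__":
    main()
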