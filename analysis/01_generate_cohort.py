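#!/usr/bin/env python
"""Step 1 - generate the synthetic raw patient export.

Draws the default 1083-patient cohort (plus 4 deliberately implausible
records) calibrated to the published cohort table and writes it as a raw
hospital-export CSV under results/.
"""

import argparse
import os

import numpy as np

import triage_sim as ts


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    params = ts.GeneratorParams(seed=args.seed)
    records = ts.generate_cohort(params)
    path = os.path.join(args.outdir, "raw_export.csv")
    ts.write_export(records, path)

    ages = [r.age for r in records if r.age is not None]
    print(f"wrote {len(records)} raw records -> {path}")
    print(f"  n_patients={params.n_patients}  n_implausible={params.n_implausible}")
    print(f"  raw age mean {np.mean(ages):.1f} (target {params.age_mean})")


if __name__ == "__main__":
    main()
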