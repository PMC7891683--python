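#!/usr/bin/env python
"""Fit the SVL/TL allometries on the synthetic sample and check recovery.

Imputes missing centrum lengths from conspecific profiles, fits the SMA
power laws of SVL and TL against every region mean and series sum, and
reports how closely the whole-column TL fit recovers the generating
exponent (0.983) and coefficient (2.504).
"""

import argparse
from pathlib import Path

import numpy as np

from crocvert.column import read_column_table
from crocvert.impute import impute_all
from crocvert.registry import fit_absolute_registry


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", type=Path, default=Path("results/synthetic/specimens.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/fitted_models.csv"))
    args = ap.parse_args()

    columns = impute_all(read_column_table(args.table))
    reg = fit_absolute_registry(columns)
    frame = reg.to_frame()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False)

    m = reg.get("TL", "C2-Ca10sum")
    se = abs(m.slope) * np.sqrt((1 - m.r_squared) / (m.n - 2))
    print(f"fitted {len(frame)} models on {len(columns)} individuals")
    print(f"  TL ~ C2-Ca10 sum: coefficient {10**m.elevation:.3f} "
          f"(generator 2.504), exponent {m.slope:.4f} ± {se:.4f} "
          f"(generator 0.983), R² = {m.r_squared:.4f}")
    dev = abs(m.slope - 0.983) / se
    print(f"  exponent within {dev:.2f} SE of the generating value")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
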