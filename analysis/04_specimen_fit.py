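#!/usr/bin/env python
"""External-field chi_i / chi_a fit and sin^2(theta) microstructure fit.

The core specimen analysis: fits the agar-shell field jointly over the 10
rotations for the isotropic and anisotropic susceptibility and the
per-orientation baselines, then fits the internal residual field with
A sin^2(theta) + B.  Runs the noiseless phantom (exact recovery) and an
SNR-50 noisy phantom (estimates with propagated confidence intervals), and
writes one results row per case.
"""

import argparse
from pathlib import Path

import pandas as pd

from oriqsm import PhantomSpec, field_noise_sd_ppb, simulate_study
from oriqsm.pipeline import specimen_fit_table


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = []
    for label, noise in (("noiseless", 0.0),
                         ("snr50", field_noise_sd_ppb(50.0))):
        spec = PhantomSpec(noise_sd_ppb=noise, seed=args.seed)
        study, model, truth = simulate_study(spec, keep_responses=True)
        table = specimen_fit_table(study, model, specimen_id=label,
                                   responses=truth.responses)
        rows.append(table)
        r = table.iloc[0]
        print(f"{label}: chi_i = {r.chi_i_ppb:.3f} +- {r.chi_i_se:.3f} ppb, "
              f"chi_a = {r.chi_a_ppb:.3f} +- {r.chi_a_se:.3f} ppb")
        print(f"          A = {r.A_ppb:.3f} [{r.A_ci_lo:.3f}, {r.A_ci_hi:.3f}] ppb, "
              f"B = {r.B_ppb:.3f} [{r.B_ci_lo:.3f}, {r.B_ci_hi:.3f}] ppb, "
              f"r2(sin^2) = {r.r2_sin2:.4f}")

    args.results_dir.mkdir(parents=True, exist_ok=True)
    out = args.results_dir / "specimen_fit.csv"
    pd.concat(rows, ignore_index=True).to_csv(out, index=False)
    print(f"generator truth: chi_i 1.17, chi_a 4.03, A 1.46, B -2.75 ppb")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
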