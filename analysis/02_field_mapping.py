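#!/usr/bin/env python
"""Multi-echo field mapping and background removal on synthetic GRE data.

Simulates complex multi-echo signals for a known field (internal dipole
sources plus an external harmonic background), recombines the echoes into a
field map, removes the background with the harmonic interior solver, and
reports recovery errors at several SNR levels.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from oriqsm import (
    B0Direction,
    VolumeGrid,
    combine_echoes,
    forward_field,
    hz_to_ppb,
    ppb_to_hz,
    remove_background_field,
    simulate_multiecho,
)
from oriqsm.synthetic import sphere_mask


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    shape = (64, 64, 64)
    mask = sphere_mask(shape, (31.5,) * 3, 14)
    internal = np.zeros(shape)
    internal[31, 31, 31] = internal[32, 32, 32] = 100.0  # ppb point dipoles
    external = sphere_mask(shape, (56, 31.5, 31.5), 4).astype(float) * 50.0
    b0 = B0Direction([0, 0, 1])
    tissue_true = forward_field(VolumeGrid(internal), b0)
    background = forward_field(VolumeGrid(external), b0)
    total_ppb = tissue_true.data + background.data
    total_hz = VolumeGrid(ppb_to_hz(total_ppb))

    eroded = ndi.binary_erosion(mask, ndi.generate_binary_structure(3, 1),
                                iterations=2)
    ref = tissue_true.data - tissue_true.data[mask].mean()

    rows = []
    for snr in (np.inf, 100.0, 50.0):
        me = simulate_multiecho(total_hz, snr=snr, seed=args.seed)
        field_hz, _ = combine_echoes(me, mask=None)
        tissue = remove_background_field(
            VolumeGrid(hz_to_ppb(field_hz.data)), mask)
        err = np.sqrt(np.mean((tissue.data[eroded] - ref[eroded]) ** 2))
        noise_floor = np.sqrt(np.mean(
            (hz_to_ppb(field_hz.data)[mask] - total_ppb[mask]) ** 2))
        rows.append({
            "snr": "inf" if np.isinf(snr) else snr,
            "fieldmap_noise_ppb": float(noise_floor),
            "tissue_rmse_ppb": float(err),
            # ~1 means background removal adds nothing beyond the per-voxel
            # field-map noise propagated from the complex signal
            "tissue_rmse_over_noise_floor": float(err / noise_floor)
            if np.isfinite(snr) else 0.0,
        })
        r = rows[-1]
        if np.isfinite(snr):
            print(f"SNR {r['snr']}: field-map noise {r['fieldmap_noise_ppb']:.3f} ppb, "
                  f"tissue-field error {r['tissue_rmse_ppb']:.3f} ppb "
                  f"({r['tissue_rmse_over_noise_floor']:.2f}x the noise floor)")
        else:
            print(f"SNR {r['snr']}: noiseless round trip, tissue-field error "
                  f"{r['tissue_rmse_ppb']:.4f} ppb ({100*err/np.sqrt(np.mean(ref[eroded]**2)):.2f}% of signal)")

    args.results_dir.mkdir(parents=True, exist_ok=True)
    out = args.results_dir / "field_mapping_recovery.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
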