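#!/usr/bin/env python
"""Time-dependent fluorescence shift pipeline on synthetic TCSPC data,
plus the Langmuir-Freundlich fit of a zeta-potential titration.

Generates Laurdan-like and Dtmac-like measurements (per-wavelength decays,
IRF, steady-state spectrum) with known total shift and integrated
relaxation time, runs the full reconvolution -> TRES -> log-normal ->
Delta_nu / tau chain, and reports recovery.  Writes
results/tdfs_recovery.csv and results/zeta_langmuir_freundlich.json.
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from calcimem import tdfs

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

PROBES = {
    # nu0 (cm^-1), Delta_nu (cm^-1), biphasic C(t): Laurdan-like slow
    # carbonyl-level relaxation vs Dtmac-like fast headgroup relaxation
    "laurdan": dict(nu0=tdfs.NU0_LAURDAN, delta_nu=1700.0,
                    relax_amplitudes=(0.5, 0.5), relax_times=(0.5, 3.5)),
    "dtmac": dict(nu0=tdfs.NU0_DTMAC, delta_nu=1400.0,
                  relax_amplitudes=(0.7, 0.3), relax_times=(0.2, 1.2)),
}


def main() -> int:
    OUT.mkdir(exist_ok=True)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for probe, params in PROBES.items():
            for seed in range(5):
                decays, irf, ss, truth = tdfs.generate_synthetic_tdfs(
                    seed=9000 + seed, **params
                )
                res = tdfs.analyze_tdfs(decays, irf, ss, nu0=truth.nu0)
                rows.append({
                    "probe": probe, "seed": 9000 + seed,
                    "delta_nu_true": truth.delta_nu,
                    "delta_nu_est": round(res.delta_nu, 1),
                    "tau_true_ns": truth.tau_ns,
                    "tau_est_ns": round(res.tau_ns, 4),
                })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "tdfs_recovery.csv", index=False)
    print(df.to_string(index=False))
    for probe in PROBES:
        sub = df[df.probe == probe]
        d_err = (sub.delta_nu_est - sub.delta_nu_true).abs().mean()
        t_err = (sub.tau_est_ns - sub.tau_true_ns).abs().mean()
        print(f"{probe}: mean |Delta_nu error| {d_err:.1f} cm^-1, "
              f"mean |tau error| {t_err:.3f} ns "
              "(intrinsic uncertainties: 50 cm^-1, 0.05 ns)")

    # zeta-potential titration of an overcharging anionic vesicle system
    rng = np.random.default_rng(77)
    c_mM = np.array([0.0, 1, 2.5, 5, 10, 25, 50, 100, 200, 500, 1000])
    truth_lf = {"zeta0": -45.0, "zeta_max": 15.0, "K": 40.0, "n": 0.9}
    zeta = tdfs._lf_model(c_mM / 1000, **truth_lf) + rng.normal(0, 1.0, len(c_mM))
    fit = tdfs.fit_langmuir_freundlich(c_mM / 1000, zeta)
    payload = {"true": truth_lf, "fit": {k: round(v, 3) for k, v in fit.items()},
               "concentrations_mM": c_mM.tolist(),
               "zeta_mV": np.round(zeta, 2).tolist()}
    (OUT / "zeta_langmuir_freundlich.json").write_text(json.dumps(payload, indent=1))
    print(f"\nLangmuir-Freundlich fit: zeta0 {fit['zeta0']:.1f} mV -> "
          f"zeta_max {fit['zeta_max']:.1f} mV, K {fit['K']:.1f} 1/M, n {fit['n']:.2f} "
          "(sign reversal = overcharging)")
    print(f"wrote tdfs_recovery.csv and zeta_langmuir_freundlich.json to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
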