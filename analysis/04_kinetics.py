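#!/usr/bin/env python
"""Fit second-order solid-liquid extraction kinetics to ultrasound-assisted
(UAE) and reflux (TSE) time-courses and compare the techniques.

The raw time-concentration measurements were never tabulated, so this driver
regenerates synthetic stand-ins from the published parameter estimates
(UAE: Cs = 6.31 mg/g, k = 0.33; TSE: Cs = 4.76, k = 0.11) with 2%
multiplicative noise, then fits them blind.

Finding: both the linearized (t/C vs t) and direct nonlinear fits recover
the saturated concentrations within ~1%, reproducing the ~24.5% Cs advantage
of ultrasound (published: 24.7% from unrounded values; the printed estimates
give 24.6%).  The rate constants are only weakly identified from noisy data
because sampling starts near saturation: the linearized k rides on a tiny
intercept, so the fitted k ratio (~2) drifts from the planted 3; the
nonlinear fit recovers both k values closely here.
"""

import json
from pathlib import Path

from extractopt.kinetics import compare_techniques, fit_linearized, fit_nls
from extractopt.synth import KineticsTruth, simulate_kinetics

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    report = {}
    fits = {}
    for label, cs, k in [("UAE", 6.31, 0.33), ("TSE", 4.76, 0.11)]:
        tc = simulate_kinetics(
            KineticsTruth(cs=cs, k=k, noise_sd=0.02, seed=42), label=label)
        lin = fit_linearized(tc)
        nls = fit_nls(tc, init=lin)
        fits[label] = lin
        report[label] = {m.method: {"cs": m.cs, "k": m.k,
                                    "r_squared": m.r_squared,
                                    "initial_rate": m.initial_rate}
                         for m in (lin, nls)}
        print(f"{label}: truth (Cs={cs}, k={k})")
        for m in (lin, nls):
            print(f"  {m.method:10s} Cs {m.cs:5.2f}  k {m.k:5.3f}  "
                  f"R^2 {m.r_squared:.4f}  h0 {m.initial_rate:5.2f} mg/g/min")

    cmp = compare_techniques(fits["UAE"], fits["TSE"])
    report["comparison"] = cmp
    print(f"ultrasound vs reflux: Cs reduction "
          f"{cmp['cs_reduction_percent']:.1f}%, k ratio {cmp['k_ratio']:.2f}")

    (OUT / "kinetics.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT / 'kinetics.json'}")


if __name__ == "__main__":
    main()
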