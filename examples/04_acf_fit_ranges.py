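"""ACF fitting and its fit-range sensitivity.

Fits the closed-form two-exponential ACF to the empirical one over nested
lag ranges.  Short ranges recover the inputs; long ranges drift badly because
ACF estimates at neighbouring lags share the same slow fluctuations, which
the constant-variance Gaussian fit wrongly treats as independent noise.
This script runs a reduced-scale version of the full range study (the full
scale is Ts/tau1 = 2000, dt/tau_S = 0.1).
"""

import viscotrap as vt

result = vt.run_fit_range_study(
    seed=1, ts_over_tau1=500.0, dt_over_tauS=0.2,
    ranges=(0.1, 0.5, 1.0, 5.0, 10.0),
)

print(f"stage-I stiffness k* = {result.k_star * 1e6:.4f} uN/m "
      f"(input 0.1000), N = {result.n_samples}")
print(result.to_frame().to_string(index=False))
print(
    "\ninputs: eta0 = 1.0 mPa s, eta1 = 100 mPa s, tau1 = 1.0 s.\n"
    "The 'best' flag marks the range with the smallest summed relative\n"
    "standard error; estimates there sit closest to the inputs, while the\n"
    "longest ranges show the characteristic drift of ACF fitting."
)
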