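"""Validate the reported fit uncertainty as a frequentist standard error.

Generates many independent synthetic datasets with a known true scale
factor, fits each, and compares the spread of the fitted values with the
1-sigma uncertainty each fit reports, plus the 2-sigma coverage of the
truth (nominally 95.4%).
"""

from vibscale import SyntheticConfig, recovery_experiment

cfg = SyntheticConfig(n_molecules=400, s_true=0.96, noise_abs=30.0, seed=7)
summary = recovery_experiment(cfg, n_reps=100, objective="absolute")

print(f"{summary.n_reps} replicate fits, true s = {summary.s_true}")
print(f"mean fitted s:        {summary.mean_s:.6f}")
print(f"bias:                 {summary.bias:+.2e}")
print(f"empirical SD:         {summary.sd_s:.2e}")
print(f"mean reported sigma:  {summary.mean_sigma:.2e}")
print(f"2-sigma coverage:     {summary.coverage_2sigma:.2f}")
print(
    "\nIf the reported sigma is a valid standard error, the empirical SD\n"
    "matches it and the coverage sits near 0.95. The slight excess of the\n"
    "SD over sigma reflects value-sorted pairing: noise occasionally swaps\n"
    "neighbouring modes, which correlates residuals."
)
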