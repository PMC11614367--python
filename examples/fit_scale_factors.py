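"""Fit absolute and relative scale factors from a paired-frequency dataset.

Builds a synthetic training set whose "experimental" fundamentals are the
"computed" harmonics times a known factor (0.96) plus 30 cm^-1 of Gaussian
scatter, then fits both scale-factor variants and prints a compact report.
"""

from vibscale import (
    SyntheticConfig, build_pair_table, fit_absolute, fit_relative,
    format_fit, generate_dataset,
)

cfg = SyntheticConfig(n_molecules=400, s_true=0.96, noise_abs=30.0, seed=11)
dataset = generate_dataset(cfg)
table = build_pair_table(dataset, cfg.method)

print(f"{len(dataset)} molecules, {table.n_total} frequency pairs\n")
print(f"{'objective':<10}{'s(sigma)':<14}{'aRMSD/cm-1':<12}{'rRMSD':<10}")
for fit in (fit_absolute(table), fit_relative(table)):
    print(f"{fit.objective:<10}{format_fit(fit):<14}"
          f"{fit.armsd:<12.1f}{fit.rrmsd:<10.4f}")

print(
    "\ns(sigma) is the fitted scale factor with its 1-sigma uncertainty in\n"
    "parentheses at the last quoted digit. The absolute fit recovers the\n"
    "true factor 0.96 within its sigma, since the noise here is additive;\n"
    "the relative fit sits below it, dragged by the large *relative*\n"
    "scatter of the low-frequency modes — each objective is calibrated for\n"
    "its own error structure. aRMSD is the expected deviation (cm^-1) of\n"
    "scaled band positions from experiment; rRMSD its relative counterpart."
)
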