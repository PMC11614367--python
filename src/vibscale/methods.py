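"""Canonical method labels for which published scale factors exist.

24 labels follow the "DF-Dn/B" pattern (density functional, dispersion
correction, basis set) and three are 3c composite methods.  These labels
are a convenience only: dataset method keys are free-form text matched
exactly, so any other label works as long as it is consistent between the
dataset and the fit request.
"""

FUNCTIONALS = ("BLYP", "PBE", "B3LYP", "PBE0")
DISPERSION = ("D3BJ", "D4")
BASIS_SETS = ("6-31G", "def2-SVP", "def2-TZVP")
COMPOSITE_3C = ("HF-3c", "PBEh-3c", "r2SCAN-3c")

METHOD_LABELS: tuple[str, ...] = tuple(
    f"{df}-{dn}/{basis}"
    for df in FUNCTIONALS
    for dn in DISPERSION
    for basis in BASIS_SETS
) + COMPOSITE_3C
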