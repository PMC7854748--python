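"""Published rate constants for the cysteine-capped hydrogenase and variants.

These are the chronoamperometry-derived rate constants of the
A1 <-> A2 <-> H_inact scheme (5 degrees C; k_react quoted at -0.196 V vs
SHE), used as ground-truth inputs for synthetic experiments and parameter
recovery studies.  ``DETERMINATION_ACCURACY`` is the experimenters'
estimate of the maximal relative error of each rate-constant
determination.
"""

from __future__ import annotations

from .kinetics import RateConstants

__all__ = ["REFERENCE_RATES", "DETERMINATION_ACCURACY", "WT_PH7"]

REFERENCE_RATES: dict[str, RateConstants] = {
    "WT_pH10": RateConstants(k1=0.095, k_neg1=0.019, k_inact=0.65, k_react=0.015),
    "WT_pH8.5": RateConstants(k1=0.068, k_neg1=0.018, k_inact=0.54, k_react=0.069),
    "WT_pH7": RateConstants(k1=0.061, k_neg1=0.016, k_inact=0.42, k_react=0.17),
    "A561F_pH7": RateConstants(k1=0.025, k_neg1=0.058, k_inact=0.28, k_react=0.19),
    "L364F_pH7": RateConstants(k1=0.055, k_neg1=0.017, k_inact=0.14, k_react=1.45),
    "P386L_pH7": RateConstants(k1=0.049, k_neg1=0.051, k_inact=0.15, k_react=1.50),
    "A561F-L364F_pH7": RateConstants(k1=0.017, k_neg1=0.067, k_inact=0.13, k_react=2.09),
}

WT_PH7 = REFERENCE_RATES["WT_pH7"]

# maximal relative determination error per rate constant
DETERMINATION_ACCURACY: dict[str, float] = {
    "k1": 0.08,
    "k_neg1": 0.28,
    "k_inact": 0.07,
    "k_react": 0.06,
}
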