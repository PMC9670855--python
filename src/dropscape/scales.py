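"""Per-residue propensity scales used by the built-in baseline predictors.

The pipeline's upstream quantities — disorder probability, binding-mode
probability and solubility — are normally produced by external trained
predictors and can be supplied as user score tracks. The baselines here are
deterministic compositional surrogates built on two published scales, so the
full pipeline runs offline:

* ``TOP_IDP``: the TOP-IDP disorder propensity scale (Campen et al., 2008,
  Protein Pept. Lett. 15:956), min-max normalised to [0, 1] so that proline
  (most disorder-promoting) maps to 1 and tryptophan to 0.
* ``KD_AGGREGATION``: the Kyte-Doolittle hydropathy index (Kyte & Doolittle,
  1982, J. Mol. Biol. 157:105) divided by its maximum magnitude 4.5, giving
  values in [-1, 1] with positive = hydrophobic/aggregation-prone.
"""

from __future__ import annotations

_TOP_IDP_RAW = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}

_lo = min(_TOP_IDP_RAW.values())
_hi = max(_TOP_IDP_RAW.values())

#: Disorder propensity in [0, 1] (higher = more disorder-promoting).
TOP_IDP: dict[str, float] = {
    aa: (v - _lo) / (_hi - _lo) for aa, v in _TOP_IDP_RAW.items()
}

_KD_RAW = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Aggregation propensity in [-1, 1] (positive = aggregation-prone).
KD_AGGREGATION: dict[str, float] = {aa: v / 4.5 for aa, v in _KD_RAW.items()}


def validate_scale(scale: dict[str, float], lo: float, hi: float, name: str = "scale") -> None:
    """Check a scale covers all 20 canonical letters with values in [lo, hi]."""
    from .seq_io import CANONICAL_AA

    missing = [aa for aa in CANONICAL_AA if aa not in scale]
    if missing:
        raise ValueError(f"{name}: missing letters {missing}")
    bad = {aa: v for aa, v in scale.items() if not lo <= v <= hi}
    if bad:
        raise ValueError(f"{name}: values outside [{lo}, {hi}]: {bad}")
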