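"""Droplet-promoting propensity and the droplet landscape.

The droplet-promoting probability p_DP of a residue is a binary-logistic
function of its free-state disorder p_D and disordered-binding probability
p_DD:

    F_S = lambda1 * p_D + lambda2 * p_DD + gamma
    p_DP = 1 / (1 + exp(-F_S))

The droplet landscape places each residue at (MBM, p_DP) and carves three
regions: droplet-promoting residues (high p_DP, low MBM — committed to
disordered binding), amyloid-promoting residues (low p_DP, high MBM) and
aggregation hot-spots (intermediate p_DP, high MBM — residues that can
nucleate ordering within a condensate). All landscape boundaries are strict
inequalities; boundary values are `unclassified`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd

from .mbm import DEFAULT_N_BINS, BindingModeHistogram, shannon_entropy
from .residue_scoring import (
    REGION_MAX_LEN,
    REGION_MIN_LEN,
    BindingModePredictor,
    CompositionBiasPredictor,
    ScoreTrack,
    baseline_p_ap,
    baseline_p_d,
)
from .seq_io import ProteinSequence

#: p_DP at or above which a residue is predicted to drive spontaneous
#: phase separation.
P_DP_THRESHOLD = 0.60
#: p_AP above which a residue is predicted to readily aggregate.
P_AP_THRESHOLD = 0.90

#: Landscape boxes: (p_DP, MBM) thresholds, all strict.
DROPLET_BOX = {"p_dp_min": 0.85, "mbm_max": 2.0}
AMYLOID_BOX = {"p_dp_max": 0.75, "mbm_min": 2.25}
HOTSPOT_BOX = {"p_dp_min": 0.75, "p_dp_max": 0.85, "mbm_min": 2.25}


@dataclass(frozen=True)
class LogisticCoefficients:
    """Coefficients of the droplet-propensity logistic model.

    The original model was fitted on experimental phase-separation data and
    its coefficients are not published; the shipped default is calibrated
    so a fully disordered, fully disordered-binding residue
    (p_D = p_DD = 1) maps to p_DP = 0.95 and the opposite extreme to 0.05:
    lambda1 = lambda2 = ln(19), gamma = -ln(19).
    """

    lambda1: float = log(19.0)
    lambda2: float = log(19.0)
    gamma: float = -log(19.0)

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "gamma"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def droplet_propensity(p_d, p_dd, coeffs: LogisticCoefficients | None = None):
    """p_DP from disorder and disordered-binding probabilities.

    Accepts scalars or arrays; the result is strictly inside (0, 1) and,
    for positive coefficients, strictly increasing in both inputs.
    """
    if coeffs is None:
        coeffs = LogisticCoefficients()
    p_d = np.asarray(p_d, dtype=float)
    p_dd = np.asarray(p_dd, dtype=float)
    if (p_d < 0).any() or (p_d > 1).any() or (p_dd < 0).any() or (p_dd > 1).any():
        raise ValueError("p_d and p_dd must lie in [0, 1]")
    f_s = coeffs.lambda1 * p_d + coeffs.lambda2 * p_dd + coeffs.gamma
    out = 1.0 / (1.0 + np.exp(-f_s))
    return float(out) if out.ndim == 0 else out


def is_droplet_promoting(p_dp: float, threshold: float = P_DP_THRESHOLD) -> bool:
    """Whether a residue is predicted to readily phase-separate
    (inclusive at the threshold)."""
    if not 0.0 <= p_dp <= 1.0:
        raise ValueError(f"p_dp {p_dp} outside [0, 1]")
    return p_dp >= threshold


def is_aggregation_prone(p_ap: float, threshold: float = P_AP_THRESHOLD) -> bool:
    """Whether a residue is predicted to readily aggregate (strictly above
    the threshold)."""
    return p_ap > threshold


def classify_landscape(p_dp: float, mbm: float) -> str:
    """Class of a (p_DP, MBM) point on the droplet landscape.

    Returns ``droplet``, ``amyloid``, ``hotspot`` or ``unclassified``.
    All comparisons are strict, so points exactly on a boundary are
    unclassified.
    """
    if p_dp > DROPLET_BOX["p_dp_min"] and mbm < DROPLET_BOX["mbm_max"]:
        return "droplet"
    if p_dp < AMYLOID_BOX["p_dp_max"] and mbm > AMYLOID_BOX["mbm_min"]:
        return "amyloid"
    if (
        HOTSPOT_BOX["p_dp_min"] < p_dp < HOTSPOT_BOX["p_dp_max"]
        and mbm > HOTSPOT_BOX["mbm_min"]
    ):
        return "hotspot"
    return "unclassified"


def is_variant_shift_prone(p_dp: float, mbm: float) -> bool:
    """Query for residues with high droplet propensity and many binding
    modes (p_DP >= 0.75 and MBM > 2.25), where mutations most readily
    shift behaviour toward aggregation."""
    return p_dp >= 0.75 and mbm > 2.25


def _all_window_pis(
    seq: ProteinSequence,
    plugin: BindingModePredictor,
    min_len: int,
    max_len: int,
) -> dict[int, np.ndarray]:
    """pi_DD of every window, grouped by window length; index j of the
    length-l array is the window starting at internal position j+1."""
    n = len(seq)
    out: dict[int, np.ndarray] = {}
    for length in range(min_len, max_len + 1):
        if length > n:
            continue
        out[length] = np.array(
            [plugin.region_pi(seq, s, s + length - 1) for s in range(1, n - length + 2)]
        )
    return out


def profile_sequence(
    seq: ProteinSequence,
    plugin: BindingModePredictor | None = None,
    coeffs: LogisticCoefficients | None = None,
    tracks: dict[str, ScoreTrack] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    p_d_window: int = 21,
    p_ap_window: int = 7,
    min_len: int = REGION_MIN_LEN,
    max_len: int = REGION_MAX_LEN,
) -> pd.DataFrame:
    """Full residue profile: p_D, p_DD, MBM, p_DP, p_AP and landscape class.

    ``tracks`` may supply user tracks (external predictor output) for any
    of ``p_d``, ``p_dd``, ``p_ap`` or ``p_dp``; missing tracks fall back to
    the built-in baselines. A user ``p_dp`` track bypasses the logistic
    model entirely. Deterministic for fixed plugin, coefficients and tracks.
    """
    if plugin is None:
        plugin = CompositionBiasPredictor()
    if coeffs is None:
        coeffs = LogisticCoefficients()
    tracks = tracks or {}
    n = len(seq)

    pis_by_len = _all_window_pis(seq, plugin, min_len, max_len)

    if "p_dd" in tracks:
        p_dd = tracks["p_dd"].as_array()
    else:
        p_dd = np.empty(n)
    mbm = np.empty(n)
    for i in range(1, n + 1):
        pis = []
        for length, arr in pis_by_len.items():
            lo = max(1, i - length + 1)
            hi = min(i, n - length + 1)
            if hi >= lo:
                pis.append(arr[lo - 1 : hi])
        pis = np.concatenate(pis)
        if "p_dd" not in tracks:
            p_dd[i - 1] = pis.mean()
        idx = np.minimum((pis * n_bins).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        mbm[i - 1] = shannon_entropy(
            BindingModeHistogram(n_bins=n_bins, counts=tuple(int(c) for c in counts))
        ).s_bind

    p_d = (
        tracks["p_d"].as_array()
        if "p_d" in tracks
        else baseline_p_d(seq, window=p_d_window).as_array()
    )
    p_ap = (
        tracks["p_ap"].as_array()
        if "p_ap" in tracks
        else baseline_p_ap(seq, window=p_ap_window).as_array()
    )
    for name, track in tracks.items():
        if len(track) != n:
            raise ValueError(f"track {name}: length {len(track)} != sequence length {n}")

    if "p_dp" in tracks:
        p_dp = tracks["p_dp"].as_array()
    else:
        p_dp = droplet_propensity(p_d, p_dd, coeffs)

    return pd.DataFrame(
        {
            "position": list(seq.positions),
            "aa": list(seq.residues),
            "p_d": p_d,
            "p_dd": p_dd,
            "mbm": mbm,
            "p_dp": p_dp,
            "p_ap": p_ap,
            "landscape_class": [classify_landscape(d, m) for d, m in zip(p_dp, mbm)],
        }
    )


def write_profile(profile: pd.DataFrame, path) -> None:
    """Write a residue profile as TSV."""
    profile.to_csv(path, sep="\t", index=False, float_format="%.6f")
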