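"""Primary per-residue score tracks.

Three quantities feed the droplet landscape:

* ``p_DD`` — probability of disordered binding: the average over all 5-9
  residue regions containing a residue of the region binding-mode
  probability pi_DD(R), where pi_DD = 1 means binding that stays fully
  disordered and pi_DD = 0 means binding that becomes ordered.
* ``p_D`` — probability of disorder in the free state.
* ``p_AP`` — amyloid-promoting propensity, the negated solubility score
  (p_AP = -p_CS).

Each track normally comes from an external trained predictor; this module
defines the plugin contract plus deterministic compositional baselines
(clearly labelled surrogates) so the pipeline is testable offline. The
baseline binding-mode predictor scores a region by its local sequence bias:
how strongly its amino-acid composition deviates from the composition of
its flanking sequence. Compositionally unbiased regions bind without
acquiring order (pi_DD near 1); strongly biased regions favour ordered
binding (pi_DD near 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .scales import KD_AGGREGATION, TOP_IDP, validate_scale
from .seq_io import CANONICAL_AA, ProteinSequence

REGION_MIN_LEN = 5
REGION_MAX_LEN = 9

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

_TRACK_RANGES = {
    "p_d": (0.0, 1.0),
    "p_dd": (0.0, 1.0),
    "p_dp": (0.0, 1.0),
    "p_ap": (-1.0, 1.0),
    "p_cs": (-1.0, 1.0),
}


@dataclass(frozen=True)
class BindingRegion:
    """A contiguous 5-9 residue window with its binding-mode probability."""

    start: int  # 1-based inclusive, internal sequence coordinates
    end: int
    pi_dd: float

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        if not REGION_MIN_LEN <= length <= REGION_MAX_LEN:
            raise ValueError(f"region length {length} outside [{REGION_MIN_LEN}, {REGION_MAX_LEN}]")
        if not 0.0 <= self.pi_dd <= 1.0:
            raise ValueError(f"pi_dd {self.pi_dd} outside [0, 1]")


@dataclass(frozen=True)
class ScoreTrack:
    """A per-residue score aligned to a sequence.

    ``source`` records whether the values came from the built-in baseline
    surrogate or from user-supplied external predictor output.
    """

    track_name: str
    values: tuple[float, ...]
    source: str = "baseline"  # baseline | user_supplied

    def __post_init__(self) -> None:
        if self.track_name not in _TRACK_RANGES:
            raise ValueError(f"unknown track name {self.track_name!r}")
        lo, hi = _TRACK_RANGES[self.track_name]
        arr = np.asarray(self.values, dtype=float)
        if arr.size and (arr.min() < lo - 1e-12 or arr.max() > hi + 1e-12):
            raise ValueError(
                f"track {self.track_name}: values outside [{lo}, {hi}] "
                f"(range {arr.min():.4g}..{arr.max():.4g})"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


class BindingModePredictor(Protocol):
    """Contract for region-level binding-mode predictors.

    Implementations must be deterministic: the same sequence and parameters
    always give the same pi_DD.
    """

    def region_pi(self, seq: ProteinSequence, start: int, end: int) -> float:
        """pi_DD of the region [start, end] (1-based internal coordinates)."""
        ...


def enumerate_regions(
    seq_length: int,
    position: int,
    min_len: int = REGION_MIN_LEN,
    max_len: int = REGION_MAX_LEN,
) -> list[tuple[int, int]]:
    """All windows of ``min_len``..``max_len`` residues that contain
    ``position`` and lie fully within the sequence.

    Windows are existence-counted: no virtual padding, so residues near a
    terminus simply have fewer regions (interior residues have 35 for the
    default 5-9 range). Coordinates are 1-based inclusive.
    """
    if not 1 <= position <= seq_length:
        raise ValueError(f"position {position} outside [1, {seq_length}]")
    regions = []
    for length in range(min_len, max_len + 1):
        lo = max(1, position - length + 1)
        hi = min(position, seq_length - length + 1)
        for start in range(lo, hi + 1):
            regions.append((start, start + length - 1))
    return regions


def _composition(fragment: str) -> np.ndarray:
    counts = np.zeros(len(CANONICAL_AA))
    for aa in fragment:
        counts[_AA_INDEX[aa]] += 1
    return counts


@lru_cache(maxsize=1_000_000)
def _pi_from_fragments(region: str, flank: str) -> float:
    # degenerate case: region spans the whole sequence, no flank to compare
    if not flank:
        return 0.5
    jsd = jensenshannon(_composition(region), _composition(flank), base=2) ** 2
    # guard tiny negative/overshoot from floating sqrt round-trip
    return float(min(1.0, max(0.0, 1.0 - jsd)))


@dataclass(frozen=True)
class CompositionBiasPredictor:
    """Baseline binding-mode surrogate scoring local sequence bias.

    pi_DD(R) = 1 - JSD(composition of R, composition of its flanks), where
    JSD is the Jensen-Shannon divergence with base-2 logarithm (bounded in
    [0, 1]). Flanks are up to ``flank_len`` residues on each side, clipped
    at the sequence ends and concatenated. Identical compositions give
    pi_DD = 1 (no local bias, disordered binding); disjoint compositions
    give pi_DD = 0 (maximal bias, ordered binding).
    """

    flank_len: int = 15
    kind: str = field(default="binding_mode", init=False)

    def region_pi(self, seq: ProteinSequence, start: int, end: int) -> float:
        n = len(seq)
        if not (1 <= start <= end <= n):
            raise ValueError(f"region {start}-{end} outside sequence of length {n}")
        s = seq.residues
        region = s[start - 1 : end]
        left = s[max(0, start - 1 - self.flank_len) : start - 1]
        right = s[end : end + self.flank_len]
        return _pi_from_fragments(region, left + right)


def baseline_region_pi_dd(
    seq: ProteinSequence, region: tuple[int, int], flank_len: int = 15
) -> float:
    """pi_DD of one region under the compositional-bias baseline."""
    return CompositionBiasPredictor(flank_len=flank_len).region_pi(seq, region[0], region[1])


def residue_pi_values(
    seq: ProteinSequence,
    position: int,
    plugin: BindingModePredictor | None = None,
    min_len: int = REGION_MIN_LEN,
    max_len: int = REGION_MAX_LEN,
) -> np.ndarray:
    """pi_DD(R) of every region containing ``position`` (numbering frame)."""
    if plugin is None:
        plugin = CompositionBiasPredictor()
    internal = position - seq.numbering_offset + 1
    regions = enumerate_regions(len(seq), internal, min_len, max_len)
    return np.array([plugin.region_pi(seq, s, e) for s, e in regions])


def residue_p_dd(
    seq: ProteinSequence,
    position: int,
    plugin: BindingModePredictor | None = None,
) -> float:
    """Disordered-binding probability: mean pi_DD over all regions
    containing the residue."""
    return float(residue_pi_values(seq, position, plugin).mean())


def _sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean with the window clipped at the termini."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def baseline_p_d(
    seq: ProteinSequence,
    window: int = 21,
    scale: dict[str, float] | None = None,
) -> ScoreTrack:
    """Baseline disorder-probability surrogate: sliding-window mean of a
    per-residue disorder propensity scale (default TOP-IDP, normalised to
    [0, 1])."""
    if scale is None:
        scale = TOP_IDP
    validate_scale(scale, 0.0, 1.0, "disorder scale")
    raw = np.array([scale[aa] for aa in seq.residues])
    return ScoreTrack("p_d", tuple(_sliding_mean(raw, window)), source="baseline")


def baseline_p_ap(
    seq: ProteinSequence,
    window: int = 7,
    scale: dict[str, float] | None = None,
) -> ScoreTrack:
    """Baseline amyloid-promoting propensity surrogate.

    The solubility track is p_CS = -(windowed mean of the aggregation
    scale) and p_AP = -p_CS, i.e. the windowed mean itself. Default scale:
    Kyte-Doolittle hydropathy rescaled to [-1, 1].
    """
    if scale is None:
        scale = KD_AGGREGATION
    validate_scale(scale, -1.0, 1.0, "aggregation scale")
    raw = np.array([scale[aa] for aa in seq.residues])
    return ScoreTrack("p_ap", tuple(_sliding_mean(raw, window)), source="baseline")


def load_user_track(path, track_name: str, seq: ProteinSequence) -> ScoreTrack:
    """Load an external predictor's per-residue output from a TSV with
    columns ``position`` and ``value``.

    Positions are 1-based in the sequence's numbering frame and must cover
    the sequence exactly once.
    """
    if track_name not in _TRACK_RANGES:
        raise ValueError(f"unknown track name {track_name!r}")
    df = pd.read_csv(path, sep="\t")
    if not {"position", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'position' and 'value'")
    positions = df["position"].astype(int)
    dup = positions[positions.duplicated()].unique()
    if dup.size:
        raise ValueError(f"{path}: duplicate positions {sorted(dup.tolist())}")
    expected = set(seq.positions)
    missing = sorted(expected - set(positions))
    if missing:
        raise ValueError(f"{path}: missing positions {missing}")
    extra = sorted(set(positions) - expected)
    if extra:
        raise ValueError(f"{path}: positions outside sequence {extra}")
    values = df.set_index("position")["value"].loc[list(seq.positions)]
    lo, hi = _TRACK_RANGES[track_name]
    bad = values[(values < lo) | (values > hi)]
    if not bad.empty:
        raise ValueError(
            f"{path}: {track_name} values outside [{lo}, {hi}] at positions "
            f"{bad.index.tolist()[:10]}"
        )
    return ScoreTrack(track_name, tuple(values.astype(float)), source="user_supplied")
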