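"""Multiplicity of binding modes (MBM).

A residue whose 5-9 residue regions all bind the same way (all pi_DD values
in one bin) has a single binding mode; a residue whose regions spread across
ordered and disordered binding samples many modes. The MBM quantifies this
as the Shannon entropy S_bind of the binned pi_DD values, in nats, so the
10-bin maximum is ln(10) ~ 2.303 and the landscape thresholds (2.0, 2.25)
are attainable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .residue_scoring import (
    REGION_MAX_LEN,
    REGION_MIN_LEN,
    BindingModePredictor,
    residue_pi_values,
)
from .seq_io import ProteinSequence

DEFAULT_N_BINS = 10


@dataclass(frozen=True)
class BindingModeHistogram:
    """Binned binding-mode probabilities of one residue's regions.

    Equal-width bins partition [0, 1]; bin k is [k/n, (k+1)/n) except the
    last, which is closed at 1.0 so pi_DD = 1 is counted.
    """

    n_bins: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != self.n_bins:
            raise ValueError("counts length must equal n_bins")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def frequencies(self) -> np.ndarray:
        counts = np.asarray(self.counts, dtype=float)
        return counts / counts.sum()


@dataclass(frozen=True)
class MbmValue:
    """Shannon entropy of binding modes, in nats."""

    s_bind: float
    n_bins: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.s_bind <= np.log(self.n_bins) + 1e-12:
            raise ValueError(f"S_bind {self.s_bind} outside [0, ln({self.n_bins})]")


def bin_binding_modes(pi_values, n_bins: int = DEFAULT_N_BINS) -> BindingModeHistogram:
    """Tally binding-mode probabilities into equal-width bins over [0, 1]."""
    arr = np.asarray(pi_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty pi_DD list")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("pi_DD values must lie in [0, 1]")
    idx = np.minimum((arr * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return BindingModeHistogram(n_bins=n_bins, counts=tuple(int(c) for c in counts))


def shannon_entropy(hist: BindingModeHistogram) -> MbmValue:
    """S_bind = -sum_k f_k ln f_k with 0 ln 0 := 0 (natural logarithm)."""
    f = hist.frequencies
    nz = f[f > 0]
    return MbmValue(s_bind=float(-(nz * np.log(nz)).sum()), n_bins=hist.n_bins)


def residue_mbm(
    seq: ProteinSequence,
    position: int,
    plugin: BindingModePredictor | None = None,
    n_bins: int = DEFAULT_N_BINS,
    min_len: int = REGION_MIN_LEN,
    max_len: int = REGION_MAX_LEN,
) -> MbmValue:
    """MBM of a residue: entropy of the binned pi_DD values of all regions
    containing it (same region enumeration as the p_DD average)."""
    pis = residue_pi_values(seq, position, plugin, min_len, max_len)
    return shannon_entropy(bin_binding_modes(pis, n_bins))
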