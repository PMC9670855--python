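"""Mutation-delta features for single and double missense variants.

For a single mutant the features are the differences (mutant - wild type)
of p_DP, p_AP and MBM at the mutated position. For a double mutant the
three tracks are first averaged over a fixed window (residues 312-341 in
the TDP-43 frame, spanning the amyloid core and both flanking hot-spots)
and the deltas are differences of those averages. Variants are labelled by
the landscape region their mutated positions fall in, and a k-sigma filter
selects large-effect variants from measured toxicity changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_io import MutationSpec

#: Default region ranges in the TDP-43 full-protein (UniProt Q13148) frame.
DEFAULT_AMYLOID_CORE = ((321, 330),)
DEFAULT_HOTSPOT = ((312, 320), (331, 341))
DEFAULT_DROPLET = ((262, 311), (342, 414))
DEFAULT_AVERAGING_REGION = (312, 341)

FEATURE_COLUMNS = ["delta_p_dp", "delta_p_ap", "delta_mbm"]
_TRACKS = ("p_dp", "p_ap", "mbm")


@dataclass(frozen=True)
class RegionMap:
    """Landscape-region assignment of sequence positions.

    Ranges are 1-based inclusive and must not overlap across classes.
    """

    amyloid_core: tuple = DEFAULT_AMYLOID_CORE
    hotspot: tuple = DEFAULT_HOTSPOT
    droplet: tuple = DEFAULT_DROPLET
    averaging_region: tuple[int, int] = DEFAULT_AVERAGING_REGION

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for label in ("amyloid_core", "hotspot", "droplet"):
            for start, end in getattr(self, label):
                if start > end:
                    raise ValueError(f"{label}: empty range {start}-{end}")
                for pos in range(start, end + 1):
                    if pos in seen:
                        raise ValueError(
                            f"position {pos} in both {seen[pos]} and {label}"
                        )
                    seen[pos] = label

    def label_of(self, position: int) -> str:
        for label in ("amyloid_core", "hotspot", "droplet"):
            for start, end in getattr(self, label):
                if start <= position <= end:
                    return label
        raise ValueError(f"position {position} outside all mapped regions")


@dataclass
class VariantFeatures:
    """Delta features of one variant, with optional measured/predicted
    toxicity changes."""

    variant_id: str
    mutations: list[MutationSpec]
    delta_p_dp: float
    delta_p_ap: float
    delta_mbm: float
    e_tox: float | None = None
    p_tox: float | None = None
    region_label: str | None = None

    def as_row(self) -> dict:
        from .seq_io import format_mutations

        return {
            "variant_id": self.variant_id,
            "mutations": format_mutations(self.mutations),
            "n_mutations": len(self.mutations),
            "region_label": self.region_label,
            "delta_p_dp": self.delta_p_dp,
            "delta_p_ap": self.delta_p_ap,
            "delta_mbm": self.delta_mbm,
            "e_tox": self.e_tox,
            "p_tox": self.p_tox,
        }


def _profile_row(profile: pd.DataFrame, position: int) -> pd.Series:
    rows = profile.loc[profile["position"] == position]
    if len(rows) != 1:
        raise ValueError(f"position {position} not found exactly once in profile")
    return rows.iloc[0]


def _check_alignment(wt_profile: pd.DataFrame, mut_profile: pd.DataFrame) -> None:
    if len(wt_profile) != len(mut_profile) or not (
        wt_profile["position"].to_numpy() == mut_profile["position"].to_numpy()
    ).all():
        raise ValueError("wild-type and mutant profiles cover different positions")


def single_mutant_features(
    wt_profile: pd.DataFrame,
    mut_profile: pd.DataFrame,
    mutation: MutationSpec,
    variant_id: str | None = None,
) -> VariantFeatures:
    """Deltas (mutant - wild type) of p_DP, p_AP and MBM at the mutated
    position."""
    _check_alignment(wt_profile, mut_profile)
    wt_row = _profile_row(wt_profile, mutation.position)
    mut_row = _profile_row(mut_profile, mutation.position)
    if wt_row["aa"] != mutation.wt_residue:
        raise ValueError(
            f"wild-type profile has {wt_row['aa']!r} at {mutation.position}, "
            f"mutation expects {mutation.wt_residue!r}"
        )
    return VariantFeatures(
        variant_id=variant_id or str(mutation),
        mutations=[mutation],
        delta_p_dp=float(mut_row["p_dp"] - wt_row["p_dp"]),
        delta_p_ap=float(mut_row["p_ap"] - wt_row["p_ap"]),
        delta_mbm=float(mut_row["mbm"] - wt_row["mbm"]),
    )


def double_mutant_features(
    wt_profile: pd.DataFrame,
    mut_profile: pd.DataFrame,
    mutations: list[MutationSpec],
    region: tuple[int, int] = DEFAULT_AVERAGING_REGION,
    variant_id: str | None = None,
) -> VariantFeatures:
    """Deltas of the track means over a fixed averaging window.

    The window defaults to residues 312-341 regardless of where the
    mutations fall, mirroring the region-average construction used for
    double mutants.
    """
    _check_alignment(wt_profile, mut_profile)
    start, end = region
    mask = (wt_profile["position"] >= start) & (wt_profile["position"] <= end)
    if mask.sum() != end - start + 1:
        raise ValueError(
            f"averaging region {start}-{end} not fully covered by the profile"
        )
    wt_means = wt_profile.loc[mask, list(_TRACKS)].mean()
    mut_means = mut_profile.loc[mask, list(_TRACKS)].mean()
    from .seq_io import format_mutations

    return VariantFeatures(
        variant_id=variant_id or format_mutations(mutations),
        mutations=list(mutations),
        delta_p_dp=float(mut_means["p_dp"] - wt_means["p_dp"]),
        delta_p_ap=float(mut_means["p_ap"] - wt_means["p_ap"]),
        delta_mbm=float(mut_means["mbm"] - wt_means["mbm"]),
    )


def assign_region(mutations: list[MutationSpec], region_map: RegionMap | None = None) -> str:
    """Common region label of a variant's mutations, or ``mixed`` when the
    mutations span different landscape regions."""
    if region_map is None:
        region_map = RegionMap()
    if not mutations:
        raise ValueError("no mutations to assign")
    labels = {region_map.label_of(m.position) for m in mutations}
    return labels.pop() if len(labels) == 1 else "mixed"


def filter_by_effect(
    variants: pd.DataFrame,
    k: float = 3.0,
    sigma_mode: str = "sd",
) -> tuple[pd.DataFrame, dict]:
    """Retain variants whose measured toxicity change is at least k sigma.

    sigma is computed over all input variants: ``sd`` uses the standard
    deviation of e_tox (the conventional reading), ``mean_abs`` the mean
    absolute change. The filter is on |e_tox| and is inclusive at the
    threshold. Returns the filtered table plus metadata recording sigma,
    k and the mode used.
    """
    if variants.empty:
        raise ValueError("empty variant table")
    if "e_tox" not in variants.columns or variants["e_tox"].isna().any():
        raise ValueError("every variant must carry a measured e_tox")
    e = variants["e_tox"].to_numpy(dtype=float)
    if sigma_mode == "sd":
        sigma = float(e.std(ddof=0))
    elif sigma_mode == "mean_abs":
        sigma = float(np.abs(e).mean())
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    threshold = k * sigma
    kept = variants.loc[np.abs(e) >= threshold].copy()
    meta = {"sigma": sigma, "k": k, "sigma_mode": sigma_mode, "threshold": threshold,
            "n_in": len(variants), "n_kept": len(kept)}
    return kept, meta


def features_table(feature_list: list[VariantFeatures]) -> pd.DataFrame:
    """Assemble VariantFeatures into the standard CSV-ready table."""
    if not feature_list:
        return pd.DataFrame(
            columns=["variant_id", "mutations", "n_mutations", "region_label",
                     "delta_p_dp", "delta_p_ap", "delta_mbm", "e_tox", "p_tox"]
        )
    return pd.DataFrame([v.as_row() for v in feature_list])
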