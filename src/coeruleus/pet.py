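"""PET SUVR metrics: reference-ratio uptake and the global amyloid summary.

Standardized uptake value ratio (SUVR) is tracer uptake in a target region
relative to a reference region (inferior cerebellar gray matter for tau,
whole cerebellar gray matter for amyloid).  Global amyloid burden is the
volume-weighted mean SUVR over 20 neocortical Desikan-Killiany regions,

    SUVR_VW = sum_i(SUVR_i * V_i) / sum_i(V_i),

optionally converted to centiloids through a user-supplied linear mapping
and binarized at a positivity threshold (default 30 cL, boundary counted
positive).  Tracer-specific centiloid calibration is deliberately not baked
in; slope and intercept come from configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import VolumeGrid

__all__ = [
    "RegionSUVR",
    "GlobalAmyloid",
    "CentiloidMapping",
    "amyloid_region_roster",
    "compute_suvr",
    "volume_weighted_global",
    "binarize_amyloid",
    "read_region_table",
]

CENTILOID_THRESHOLD = 30.0


def amyloid_region_roster() -> tuple[str, ...]:
    """The 20 Desikan-Killiany cortical regions entering the global summary."""
    text = resources.files("coeruleus.data").joinpath("dk_amyloid_regions.txt").read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


@dataclass(frozen=True)
class RegionSUVR:
    """One cortical region's SUVR and its volume in mm^3."""

    region_name: str
    suvr: float
    volume: float

    def __post_init__(self) -> None:
        if self.suvr <= 0:
            raise ValueError(f"{self.region_name}: SUVR must be positive")
        if self.volume <= 0:
            raise ValueError(f"{self.region_name}: volume must be positive")


@dataclass(frozen=True)
class CentiloidMapping:
    """Linear SUVR -> centiloid conversion, cL = slope * SUVR + intercept."""

    slope: float
    intercept: float

    def __call__(self, suvr: float) -> float:
        return self.slope * suvr + self.intercept


@dataclass
class GlobalAmyloid:
    """Volume-weighted global amyloid burden, optionally on the cL scale."""

    suvr_vw: float
    centiloid: float | None = None
    positive: bool | None = None

    def to_dict(self) -> dict:
        return {
            "suvr_vw": self.suvr_vw,
            "centiloid": self.centiloid,
            "positive": self.positive,
        }


def compute_suvr(
    pet: VolumeGrid,
    target_mask: np.ndarray,
    reference_mask: np.ndarray,
) -> float:
    """Mean target uptake divided by mean reference uptake."""
    target_mask = np.asarray(target_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    for name, mask in (("target", target_mask), ("reference", reference_mask)):
        if mask.shape != pet.shape:
            raise ValueError(f"{name} mask shape {mask.shape} != volume {pet.shape}")
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
    ref_mean = pet.data[reference_mask].mean()
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean {ref_mean:g}")
    return float(pet.data[target_mask].mean() / ref_mean)


def volume_weighted_global(
    regions: Sequence[RegionSUVR],
    mapping: CentiloidMapping | None = None,
    threshold_cl: float = CENTILOID_THRESHOLD,
    check_roster: bool = False,
) -> GlobalAmyloid:
    """Volume-weighted mean SUVR across cortical regions.

    With a centiloid ``mapping``, the summary is also expressed in cL and
    binarized at ``threshold_cl``.  ``check_roster=True`` warns when the
    supplied region names do not match the packaged 20-region roster.
    """
    if len(regions) == 0:
        raise ValueError("at least one region is required")
    if check_roster:
        expected = {r.lower() for r in amyloid_region_roster()}
        got = {r.region_name.lower() for r in regions}
        if got != expected:
            warnings.warn(
                "region names do not match the 20-region global-amyloid roster "
                f"(missing: {sorted(expected - got)}, extra: {sorted(got - expected)})",
                stacklevel=2,
            )
    suvr = np.array([r.suvr for r in regions], dtype=float)
    vol = np.array([r.volume for r in regions], dtype=float)
    vw = float(np.sum(suvr * vol) / np.sum(vol))
    out = GlobalAmyloid(suvr_vw=vw)
    if mapping is not None:
        out.centiloid = float(mapping(vw))
        out.positive = binarize_amyloid(out.centiloid, threshold_cl)
    return out


def binarize_amyloid(global_cl: float, threshold: float = CENTILOID_THRESHOLD) -> bool:
    """Amyloid positivity at a centiloid threshold; the boundary is positive."""
    return bool(global_cl >= threshold)


def read_region_table(path) -> list[RegionSUVR]:
    """Read a region CSV with columns region, suvr, volume_mm3."""
    df = pd.read_csv(path)
    required = {"region", "suvr", "volume_mm3"}
    if not required.issubset(df.columns):
        raise ValueError(f"region table needs columns {sorted(required)}")
    return [
        RegionSUVR(str(r.region), float(r.suvr), float(r.volume_mm3))
        for r in df.itertuples()
    ]
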