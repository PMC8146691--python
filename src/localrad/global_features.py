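"""Reduce a patient's seven parametric maps to 84 global histogram features.

Map values at valid window centres are pooled across all slices into one
sample per map (one histogram per patient), and 12 global descriptors are
computed on each pooled sample: maximum, sample standard deviation (n-1),
unscaled median absolute deviation, mean and median of the last decile, plus
the same seven first-order statistics used for the local maps.  7 maps x 12
descriptors = 84 features; the headline feature s_e is ``skewness_entropy``,
the Shannon entropy of the pooled local-skewness values — a measure of the
spatial heterogeneity of local asymmetry, not of raw intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PipelineConfig, RoiImageStack
from .local_maps import STAT_NAMES, LocalMapSet, compute_local_maps, local_statistics

__all__ = [
    "MAP_NAMES",
    "DESCRIPTOR_NAMES",
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureMatrix",
    "pool_map_values",
    "global_descriptors",
    "extract_features",
    "GROUP_LABELS",
]

MAP_NAMES = STAT_NAMES  # entropy, mean, median, skewness, kurtosis, iqr, cv

#: canonical order of the 12 global descriptors
DESCRIPTOR_NAMES = (
    "max",
    "sd",
    "mad",
    "mean_last_decile",
    "median_last_decile",
    "entropy",
    "mean",
    "median",
    "skewness",
    "kurtosis",
    "iqr",
    "cv",
)

#: the 84 canonical feature names, "<map>_<descriptor>", map-major order
FEATURE_NAMES = tuple(f"{m}_{d}" for m in MAP_NAMES for d in DESCRIPTOR_NAMES)

GROUP_LABELS = ("TRG01", "TRG23")  # responders (positives), non-responders


@dataclass
class FeatureVector:
    """The 84 named global descriptors of one patient."""

    patient_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            if missing or extra:
                raise ValueError(f"non-canonical feature set: missing {sorted(missing)}, extra {sorted(extra)}")
            self.values = {name: self.values[name] for name in FEATURE_NAMES}
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad}")

    @property
    def s_e(self) -> float:
        """Entropy of the local-skewness map — the headline feature."""
        return self.values["skewness_entropy"]


class FeatureMatrix:
    """Cohort feature table: one row per patient, 84 features plus labels."""

    def __init__(self, frame: pd.DataFrame):
        expected = ["patient_id", "group"] + list(FEATURE_NAMES)
        if list(frame.columns) != expected:
            raise ValueError("feature matrix columns are not canonical")
        bad = set(frame["group"]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_vectors(cls, vectors, groups) -> "FeatureMatrix":
        rows = []
        for vec, grp in zip(vectors, groups):
            rows.append({"patient_id": vec.patient_id, "group": grp, **vec.values})
        frame = pd.DataFrame(rows, columns=["patient_id", "group"] + list(FEATURE_NAMES))
        return cls(frame)

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[list(FEATURE_NAMES)]

    def group_values(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (TRG01 values, TRG23 values) of one feature."""
        g = self.frame["group"].to_numpy()
        v = self.frame[feature].to_numpy(dtype=float)
        return v[g == GROUP_LABELS[0]], v[g == GROUP_LABELS[1]]

    def __len__(self) -> int:
        return len(self.frame)


def pool_map_values(mapset: LocalMapSet) -> dict[str, np.ndarray]:
    """Concatenate each map's values at valid centres across all slices."""
    if mapset.n_valid == 0:
        raise ValueError("no valid centres to pool")
    pooled = {}
    for name in MAP_NAMES:
        pooled[name] = np.concatenate(
            [m[v] for m, v in zip(mapset.maps[name], mapset.valid_masks)]
        )
    return pooled


def global_descriptors(sample, global_entropy_bins: int = 64) -> dict[str, float]:
    """The 12 global descriptors of one pooled map sample (>= 10 values).

    The last decile is the set of values at or above the 90th percentile
    (linear interpolation).
    """
    x = np.asarray(sample, dtype=np.float64).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 values for decile statistics, got {x.size}")
    p90 = np.quantile(x, 0.9)
    decile = x[x >= p90]
    local = local_statistics(x, entropy_bins=global_entropy_bins)
    out = {
        "max": float(x.max()),
        "sd": float(x.std(ddof=1)),
        "mad": float(np.median(np.abs(x - np.median(x)))),
        "mean_last_decile": float(decile.mean()),
        "median_last_decile": float(np.median(decile)),
    }
    out.update(local)
    return {name: out[name] for name in DESCRIPTOR_NAMES}


def extract_features(stack: RoiImageStack, config: PipelineConfig | None = None) -> FeatureVector:
    """Full per-patient extraction: local maps -> pooling -> 84 descriptors."""
    config = config or PipelineConfig()
    mapset = compute_local_maps(stack, config)
    pooled = pool_map_values(mapset)
    values: dict[str, float] = {}
    for map_name in MAP_NAMES:
        desc = global_descriptors(pooled[map_name], config.global_entropy_bins)
        for d_name, v in desc.items():
            values[f"{map_name}_{d_name}"] = v
    return FeatureVector(patient_id=stack.patient_id, values=values)


def write_feature_manifest(path) -> None:
    """Export the canonical 84-feature name list as JSON for downstream
    tools (maps, descriptors and the composed feature names, in order)."""
    import json
    from pathlib import Path

    manifest = {
        "maps": list(MAP_NAMES),
        "descriptors": list(DESCRIPTOR_NAMES),
        "features": list(FEATURE_NAMES),
        "headline_feature": "skewness_entropy",
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
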