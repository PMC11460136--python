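"""Assay-validation calculus: repeatability, LOD, LOQ, linearity.

The decision rules are those of targeted-quantification method validation:

* repeatability — per-level mean and relative standard deviation, with the
  sample (n−1) standard deviation.  This convention is load-bearing: the
  published replicate tables this package's tests reproduce only match under
  ddof = 1.
* LOD — the lowest adulteration level whose replicates detect the adulterant
  allele in at least 95% of runs, with every higher tested level also
  passing (stable detection).
* LOQ — the lowest level whose replicate RSD is at or below 25%, again with
  stability over the higher tested levels.  LOD and LOQ are independent
  criteria; neither ordering between them is assumed.

"Detected" is operationalised as: the adulterant allele's measured frequency
reaches the detection threshold (default 1%, deliberately below the 2%
quantification presence threshold so that detection saturates before
quantification becomes reliable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .quantify import StandardCurve, fit_standard_curve

DETECTION_MIN = 0.95
RSD_MAX = 25.0
DETECTION_THRESHOLD = 0.01
#: Replicate count below which LOD estimates are statistically weak.
RECOMMENDED_LOD_REPLICATES = 20


def repeatability_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and RSD (%) of replicate measurements, (n−1) convention."""
    if len(values) < 2:
        raise InputError("repeatability needs at least 2 replicate values")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if mean == 0:
        raise InputError("mean of replicates is 0; RSD undefined")
    rsd = float(arr.std(ddof=1) / mean * 100.0)
    return mean, rsd


def _sorted_levels(series: Mapping[float, Sequence]) -> list[float]:
    if not series:
        raise InputError("empty dilution series")
    return sorted(series)


def determine_lod(
    series: Mapping[float, Sequence[bool]],
    detection_min: float = DETECTION_MIN,
) -> float | None:
    """Lowest level with stable detection.

    ``series`` maps adulteration level to per-replicate detected flags.  The
    reported level's detection rate must reach ``detection_min`` and so must
    every higher tested level; returns ``None`` when no level qualifies.
    """
    levels = _sorted_levels(series)
    rates = {}
    for level in levels:
        flags = list(series[level])
        if not flags:
            raise InputError(f"level {level} has no replicates")
        if len(flags) < RECOMMENDED_LOD_REPLICATES:
            warnings.warn(
                f"level {level}: only {len(flags)} replicates "
                f"(recommend >= {RECOMMENDED_LOD_REPLICATES} for LOD)",
                stacklevel=2,
            )
        rates[level] = sum(bool(f) for f in flags) / len(flags)
    for i, level in enumerate(levels):
        if all(rates[lv] >= detection_min for lv in levels[i:]):
            return level
    return None


def determine_loq(
    series: Mapping[float, Sequence[float]],
    rsd_max: float = RSD_MAX,
) -> float | None:
    """Lowest level whose replicate RSD (and every higher level's) ≤ ``rsd_max``."""
    levels = _sorted_levels(series)
    rsds = {level: repeatability_stats(series[level])[1] for level in levels}
    for i, level in enumerate(levels):
        if all(rsds[lv] <= rsd_max for lv in levels[i:]):
            return level
    return None


@dataclass(frozen=True)
class LevelStats:
    """Summary of one adulteration level of a dilution study."""

    level: float
    n: int
    mean: float
    rsd: float | None  # None when < 2 replicates
    detection_rate: float


@dataclass
class ValidationReport:
    """Assembled validation result: per-level stats, LOD, LOQ, linearity."""

    per_level: list[LevelStats]
    lod: float | None
    loq: float | None
    linearity: StandardCurve | None
    detection_min: float = DETECTION_MIN
    rsd_max: float = RSD_MAX
    detection_threshold: float = DETECTION_THRESHOLD

    @property
    def passes(self) -> bool:
        """All three gates defined and satisfied."""
        return (
            self.lod is not None
            and self.loq is not None
            and self.linearity is not None
            and self.linearity.passes_linearity
        )

    def to_dict(self) -> dict:
        return {
            "per_level": [
                {
                    "level": s.level,
                    "n": s.n,
                    "mean_frequency": s.mean,
                    "rsd_percent": s.rsd,
                    "detection_rate": s.detection_rate,
                }
                for s in self.per_level
            ],
            "lod": self.lod,
            "loq": self.loq,
            "linearity": (
                None
                if self.linearity is None
                else {
                    "slope": self.linearity.slope,
                    "intercept": self.linearity.intercept,
                    "r_squared": self.linearity.r_squared,
                    "passes": self.linearity.passes_linearity,
                }
            ),
            "parameters": {
                "detection_min": self.detection_min,
                "rsd_max": self.rsd_max,
                "detection_threshold": self.detection_threshold,
            },
            "passes": self.passes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("level\tn\tmean_frequency\trsd_percent\tdetection_rate\n")
            for s in self.per_level:
                rsd = "" if s.rsd is None else f"{s.rsd:.2f}"
                fh.write(
                    f"{s.level:g}\t{s.n}\t{s.mean:.6f}\t{rsd}\t{s.detection_rate:.3f}\n"
                )


def validate_assay(
    table: pd.DataFrame,
    *,
    detection_threshold: float = DETECTION_THRESHOLD,
    detection_min: float = DETECTION_MIN,
    rsd_max: float = RSD_MAX,
    target_allele: str | None = None,
) -> ValidationReport:
    """Assemble a full validation report from a dilution-series table.

    ``table`` needs columns ``level``, ``replicate`` and ``frequency`` (the
    adulterant allele's measured frequency per replicate); an optional
    boolean ``detected`` column overrides the threshold rule.  Tables that
    carry both alleles (simulator output with an ``allele`` column) are
    narrowed to ``target_allele`` when given.

    Linearity is fitted on (level, mean frequency) whenever at least three
    levels are present; LOD/LOQ are ``None`` (undefined, flagged in the
    report) when no level qualifies or too few levels exist.
    """
    required = {"level", "replicate", "frequency"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"dilution table lacks column(s) {sorted(missing)}")
    if table.empty:
        raise InputError("dilution table is empty")
    if target_allele is not None and "allele" in table.columns:
        table = table[table["allele"] == target_allele]
        if table.empty:
            raise InputError(f"no rows for allele {target_allele!r}")

    per_level: list[LevelStats] = []
    detect_series: dict[float, list[bool]] = {}
    rsd_series: dict[float, list[float]] = {}
    for level, block in table.groupby("level", sort=True):
        values = block["frequency"].astype(float).tolist()
        detected = (
            block["detected"].astype(bool).tolist()
            if "detected" in block.columns
            else [v >= detection_threshold for v in values]
        )
        rsd = None
        if len(values) >= 2 and np.mean(values) != 0:
            rsd = repeatability_stats(values)[1]
        per_level.append(
            LevelStats(
                level=float(level),
                n=len(values),
                mean=float(np.mean(values)),
                rsd=rsd,
                detection_rate=sum(detected) / len(detected),
            )
        )
        detect_series[float(level)] = detected
        if len(values) >= 2:
            rsd_series[float(level)] = values

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate-count advisories
        lod = determine_lod(detect_series, detection_min)
    loq = determine_loq(rsd_series, rsd_max) if rsd_series else None
    linearity = None
    if len(per_level) >= 3:
        linearity = fit_standard_curve([(s.level, s.mean) for s in per_level])
    return ValidationReport(
        per_level=per_level,
        lod=lod,
        loq=loq,
        linearity=linearity,
        detection_min=detection_min,
        rsd_max=rsd_max,
        detection_threshold=detection_threshold,
    )
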