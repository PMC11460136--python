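"""External-standard mass quantification from allele frequencies.

The method rests on two lines of arithmetic.  A known mass ``w_ext`` of a
species absent from the sample is spiked in; its allele frequency ``r_ext``
at its species-diagnostic site then anchors the total amplifying mass,

    w_total = w_ext / r_ext                                       (step 1)

and each identified component's mass follows from its own allele frequency,

    w_component = w_total * r_component.                          (step 2)

Both steps assume equal DNA yield per unit mass across species, which is what
makes an allele frequency a mass share.  Non-amplifying impurities (soil,
flour) never enter the frequencies, so ``w_total`` is the amplifying mass
only.  A result is accepted when |calculated − actual| / actual stays below
25%.

Standard-curve fitting (frequency on mass proportion, ordinary least
squares) provides the linearity gate: R² ≥ 0.99.  The fitted line can
optionally be inverted to correct measured frequencies before the mass math,
but by default frequencies enter the equations raw, matching how the assay's
worked examples are computed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignments import TaxonGrouping
from .errors import (
    ConfigError,
    DegenerateFitError,
    InputError,
    MissingDataError,
    NoValidStandardError,
    UnquantifiableSampleError,
    UnresolvedCompositionError,
)
from .screen import SPECIES_DIAGNOSTIC, DiagnosticSite, SitePanel
from .simulate import FrequencyMeasurement, measurements_to_frame

#: Linearity gate on the coefficient of determination.
R_SQUARED_GATE = 0.99
#: Acceptance bound on quantification bias, percent.
BIAS_BOUND = 25.0
#: Default presence threshold — the assay's validated LOD/LOQ level.
PRESENCE_THRESHOLD = 0.02
#: Identified-component frequencies should sum to 1 within this tolerance.
FREQUENCY_SUM_TOLERANCE = 0.05

PURE_TARGET = "pure_target"
PURE_BACKGROUND = "pure_background"
MIXED = "mixed"


# ---------------------------------------------------------------------------
# standard curve


@dataclass(frozen=True)
class StandardCurve:
    """OLS line relating mass proportion (x) to allele frequency (y)."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]
    passes_linearity: bool

    def predict(self, proportion: float) -> float:
        return self.slope * proportion + self.intercept

    def invert(self, frequency: float) -> float:
        """Map a measured frequency back onto the proportion scale."""
        return (frequency - self.intercept) / self.slope


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    *,
    r2_gate: float = R_SQUARED_GATE,
) -> StandardCurve:
    """Ordinary least squares of frequency on proportion with the R² gate.

    ``points`` are (proportion, mean frequency) pairs — replicates must be
    averaged before fitting.  At least three distinct proportions are
    required; zero variance in the proportions is a degenerate fit.
    """
    if len(points) < 3:
        raise InputError("standard curve needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(set(x.tolist())) < 3:
        raise InputError("standard curve needs at least 3 distinct proportions")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in proportions")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        points=tuple((float(a), float(b)) for a, b in points),
        passes_linearity=r2 >= r2_gate,
    )


# ---------------------------------------------------------------------------
# the two-step mass arithmetic


def total_weight(w_ext: float, r_ext: float) -> float:
    """Total amplifying mass from the external-standard spike (step 1)."""
    if w_ext <= 0:
        raise InputError("external-standard weight must be > 0")
    if r_ext <= 0:
        raise UnquantifiableSampleError(
            "external-standard frequency is 0; total weight cannot be deduced"
        )
    if r_ext > 1:
        raise InputError(f"frequency {r_ext} exceeds 1")
    return w_ext / r_ext


def component_weight(w_total: float, r_tar: float) -> float:
    """Mass of one component from its allele frequency (step 2)."""
    if w_total <= 0:
        raise InputError("total weight must be > 0")
    if not 0.0 <= r_tar <= 1.0:
        raise InputError(f"frequency {r_tar} outside [0, 1]")
    return w_total * r_tar


@dataclass(frozen=True)
class BiasResult:
    """Relative quantification error in percent, with the 25% pass flag."""

    percent: float
    passes: bool


def compute_bias(calculated: float, actual: float, bound: float = BIAS_BOUND) -> BiasResult:
    """|calculated − actual| / actual × 100, flagged against ``bound``."""
    if actual <= 0:
        raise InputError("actual weight must be > 0 to express a relative bias")
    pct = abs(calculated - actual) / actual * 100.0
    return BiasResult(percent=pct, passes=pct < bound)


def mean_bias(biases: Iterable[float]) -> float:
    """Arithmetic mean of bias percentages (summary across samples)."""
    vals = list(biases)
    if not vals:
        raise InputError("no biases to average")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# qualitative calls


@dataclass(frozen=True)
class SiteCall:
    """Presence call at one site: pure-target, pure-background, or mixed."""

    site_key: str
    call: str
    frequencies: Mapping[str, float]  # mean frequency per allele

    @property
    def target_present(self) -> bool:
        return self.call in (PURE_TARGET, MIXED)


def _mean_site_frequencies(
    frame: pd.DataFrame, site: DiagnosticSite
) -> dict[str, float]:
    """Mean replicate frequency of the site's two alleles.

    When only one of the two alleles was exported the other is inferred as
    its complement (the site is biallelic by construction).
    """
    rows = frame[(frame["locus"] == site.locus) & (frame["position"] == site.position)]
    if rows.empty:
        raise MissingDataError(f"no measurements for site {site.key}")
    means = rows.groupby("allele")["frequency"].mean()
    freqs: dict[str, float] = {}
    for allele in (site.target_allele, site.background_allele):
        if allele in means.index:
            freqs[allele] = float(means[allele])
    if site.target_allele not in freqs and site.background_allele in freqs:
        freqs[site.target_allele] = 1.0 - freqs[site.background_allele]
    if site.background_allele not in freqs and site.target_allele in freqs:
        freqs[site.background_allele] = 1.0 - freqs[site.target_allele]
    if not freqs:
        raise MissingDataError(
            f"measurements at {site.key} cover neither panel allele"
        )
    return freqs


def call_presence(
    measurements: Sequence[FrequencyMeasurement] | pd.DataFrame,
    site: DiagnosticSite,
    threshold: float = PRESENCE_THRESHOLD,
) -> SiteCall:
    """Classify a site from mean replicate frequencies.

    An allele counts as present when its mean frequency is at or above
    ``threshold`` (default: the assay's validated LOD/LOQ of 2%).
    """
    if not 0.0 < threshold <= 0.5:
        raise InputError("presence threshold must lie in (0, 0.5]")
    frame = (
        measurements
        if isinstance(measurements, pd.DataFrame)
        else measurements_to_frame(measurements)
    )
    freqs = _mean_site_frequencies(frame, site)
    target_in = freqs[site.target_allele] >= threshold
    background_in = freqs[site.background_allele] >= threshold
    if target_in and background_in:
        call = MIXED
    elif target_in:
        call = PURE_TARGET
    else:
        call = PURE_BACKGROUND
    return SiteCall(site_key=site.key, call=call, frequencies=freqs)


@dataclass(frozen=True)
class Composition:
    """Qualitative composition of a sample.

    ``unresolved`` is raised-to-true whenever the group site shows an
    adulterant allele that no species-diagnostic site accounts for — the
    sample is adulterated but the adulterant is untyped, so its mass cannot
    be attributed.  Missing species-site data degrades to unresolved, never
    silently to "pure".
    """

    group_present: bool
    adulterants: frozenset[str]
    unresolved: bool
    group_label: str = "target_group"

    @property
    def members(self) -> frozenset[str]:
        base = set(self.adulterants)
        if self.group_present:
            base.add(self.group_label)
        return frozenset(base)


def identify_composition(
    panel_calls: Mapping[str, SiteCall],
    grouping: TaxonGrouping,
    *,
    expected_taxa: Iterable[str] | None = None,
) -> Composition:
    """Combine the group-site call with species-site calls.

    ``panel_calls`` maps taxon labels (the grouping's target label plus
    adulterant species / joint-taxon names) to their site calls.
    ``expected_taxa`` lists the taxa whose species sites *should* have been
    measured; any that were not leave the composition unresolved when the
    group site shows adulteration.
    """
    group_call = panel_calls.get(grouping.target_label)
    if group_call is None:
        raise MissingDataError("no call available for the group-diagnostic site")
    species_calls = {
        taxon: call for taxon, call in panel_calls.items()
        if taxon != grouping.target_label
    }
    positives = frozenset(
        taxon for taxon, call in species_calls.items() if call.target_present
    )
    group_present = group_call.target_present
    adulterant_signal = group_call.call in (MIXED, PURE_BACKGROUND)
    missing = (
        set(expected_taxa) - set(species_calls)
        if expected_taxa is not None
        else set()
    )
    unresolved = adulterant_signal and (not positives or bool(missing))
    return Composition(
        group_present=group_present,
        adulterants=positives,
        unresolved=unresolved,
        group_label=grouping.target_label,
    )


def select_external_standard(
    composition: Composition | Iterable[str],
    candidates: Sequence[str],
) -> str:
    """First candidate species not already present in the sample.

    The spike's site signal must be attributable solely to the spike, so the
    standard has to be absent from the sample.
    """
    if not candidates:
        raise InputError("no candidate external standards given")
    present = (
        set(composition.members)
        if isinstance(composition, Composition)
        else set(composition)
    )
    for candidate in candidates:
        if candidate not in present:
            return candidate
    raise NoValidStandardError(
        "every candidate external standard is present in the sample"
    )


# ---------------------------------------------------------------------------
# sample quantification


@dataclass
class QuantSample:
    """One quantification request: spiked sample plus its measurements."""

    sample_id: str
    external_standard: str
    w_ext: float  # grams of spiked standard
    measurements: Sequence[FrequencyMeasurement] | pd.DataFrame
    actual_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.w_ext <= 0:
            raise InputError("external-standard weight must be > 0")

    @property
    def frame(self) -> pd.DataFrame:
        if isinstance(self.measurements, pd.DataFrame):
            return self.measurements
        return measurements_to_frame(self.measurements)


@dataclass
class QuantResult:
    """Total and per-component masses with optional bias assessment.

    Masses are kept at full precision; rounding to 4 decimals (g) and whole
    percent happens only in the report serialisers.
    """

    sample_id: str
    w_total: float
    component_weights: dict[str, float]
    frequencies_used: dict[str, float]
    biases: dict[str, BiasResult] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "w_total_g": round(self.w_total, 4),
            "component_weights_g": {
                k: round(v, 4) for k, v in self.component_weights.items()
            },
            "frequencies_percent": {
                k: round(v * 100) for k, v in self.frequencies_used.items()
            },
            "biases_percent": {
                k: {"percent": round(b.percent, 3), "passes": b.passes}
                for k, b in self.biases.items()
            },
            "warnings": list(self.warnings),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("component\tfrequency_pct\tweight_g\tbias_pct\tbias_pass\n")
            for name, w in self.component_weights.items():
                freq = self.frequencies_used.get(name, math.nan)
                bias = self.biases.get(name)
                fh.write(
                    f"{name}\t{round(freq * 100)}\t{w:.4f}\t"
                    f"{'' if bias is None else f'{bias.percent:.3f}'}\t"
                    f"{'' if bias is None else ('pass' if bias.passes else 'FAIL')}\n"
                )
            fh.write(f"TOTAL\t\t{self.w_total:.4f}\t\t\n")


def quantify_sample(
    sample: QuantSample,
    panel: SitePanel,
    *,
    threshold: float = PRESENCE_THRESHOLD,
    curve: StandardCurve | None = None,
    sum_tolerance: float = FREQUENCY_SUM_TOLERANCE,
    bias_bound: float = BIAS_BOUND,
    grouping: TaxonGrouping | None = None,
) -> QuantResult:
    """Full two-step quantification of a spiked sample.

    Calls every panel site, identifies the composition, anchors the total
    amplifying mass on the external standard's site (step 1) and converts
    each identified component's mean allele frequency into grams (step 2).
    The external standard itself is quantified like any component; by the
    algebra of the two steps its computed mass equals ``w_ext`` exactly.

    When ``curve`` is given, measured frequencies are mapped through its
    inverse before the mass math (off by default: the worked examples of the
    assay use raw frequencies).

    Raises :class:`UnresolvedCompositionError` when the group site shows
    adulteration that no species site explains — the untyped mass cannot be
    attributed, so quantification is refused rather than silently wrong.
    """
    frame = sample.frame
    if grouping is None:
        grouping = _grouping_from_panel(panel)

    calls: dict[str, SiteCall] = {}
    sites_by_label: dict[str, DiagnosticSite] = {}
    for site in panel.sites:
        label = site.label or site.key
        try:
            calls[label] = call_presence(frame, site, threshold)
            sites_by_label[label] = site
        except MissingDataError:
            continue  # absent sites degrade to unresolved below

    species_taxa = [
        s.label or s.key for s in panel.sites if s.mode == SPECIES_DIAGNOSTIC
    ]
    composition = identify_composition(
        calls, grouping, expected_taxa=species_taxa
    )
    if composition.unresolved:
        raise UnresolvedCompositionError(
            f"sample {sample.sample_id!r}: adulterant allele present at the "
            "group site but no species-diagnostic site is positive/measured; "
            "untyped mass cannot be quantified"
        )

    def freq_of(label: str) -> float:
        site = sites_by_label[label]
        f = calls[label].frequencies[site.target_allele]
        return curve.invert(f) if curve is not None else f

    # step 1 — anchor the total on the external standard
    std_site = panel.site_for(sample.external_standard)
    std_label = std_site.label or std_site.key
    if std_label not in calls:
        raise MissingDataError(
            f"external standard site {std_site.key} was not measured"
        )
    r_ext = freq_of(std_label)
    w_tot = total_weight(sample.w_ext, r_ext)

    # step 2 — every identified component, the standard included
    component_labels: list[str] = []
    if composition.group_present:
        component_labels.append(grouping.target_label)
    component_labels.extend(sorted(composition.adulterants))
    if std_label not in component_labels:
        component_labels.append(std_label)

    weights: dict[str, float] = {}
    freqs: dict[str, float] = {}
    for label in component_labels:
        f = freq_of(label)
        freqs[label] = f
        weights[label] = component_weight(w_tot, f)

    notes: list[str] = []
    fsum = sum(freqs.values())
    if abs(fsum - 1.0) > sum_tolerance:
        msg = (
            f"identified-component frequencies sum to {fsum:.3f}, outside "
            f"1 ± {sum_tolerance:g}; unidentified amplifying material "
            "or measurement drift is likely"
        )
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)

    biases: dict[str, BiasResult] = {}
    if sample.actual_weights:
        for label, actual in sample.actual_weights.items():
            if label in weights:
                biases[label] = compute_bias(weights[label], actual, bias_bound)

    return QuantResult(
        sample_id=sample.sample_id,
        w_total=w_tot,
        component_weights=weights,
        frequencies_used=freqs,
        biases=biases,
        warnings=notes,
    )


def _grouping_from_panel(panel: SitePanel) -> TaxonGrouping:
    """Reconstruct a minimal grouping from the panel's own site metadata."""
    group_site = panel.primary
    adulterant_labels: set[str] = set()
    joint: dict[str, frozenset[str]] = {}
    for s in panel.sites:
        if s.mode != SPECIES_DIAGNOSTIC:
            continue
        label = s.label or s.key
        adulterant_labels.update(s.target_taxa)
        if len(s.target_taxa) > 1:
            joint[label] = frozenset(s.target_taxa)
    if not adulterant_labels:
        raise ConfigError(
            "panel carries no species-diagnostic sites; supply a grouping"
        )
    return TaxonGrouping(
        target_group=group_site.target_taxa,
        adulterants=frozenset(adulterant_labels),
        joint_taxa=joint,
        target_label=group_site.label or "target_group",
    )
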