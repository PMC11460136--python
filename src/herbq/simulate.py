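"""Synthetic mixtures, pyrosequencing measurements and toy alignments.

The observation model is deliberately the same one the quantification math
inverts: under equal DNA yield per unit mass, the frequency of a site's
target allele equals the mass share of the species carrying that allele
among the *amplifying* components (non-amplifying impurities such as soil or
flour contribute nothing).  The instrument response is an affine distortion
near identity — default slope/intercept (0.994, 0.002), the empirically
fitted frequency response of the assay this package models — and replicate
scatter is Gaussian with absolute standard deviation ``noise_sd`` (default
0.005), truncated to [0, 1] by clamping.  With these defaults a 1% (wt/wt)
adulteration level shows replicate RSD well above 25% while 2% stays below
it, which is the calibration the validation module's LOD/LOQ rules probe.

Full pyrogram traces (per-dispensation peak heights) are not simulated; the
instrument's exported allele frequencies are the level all downstream math
consumes.

The module also synthesises gap-free toy alignments with planted diagnostic
columns (rejection-sampling the background so *only* the planted columns are
diagnostic) and ships an eleven-species Fritillaria demo mimicking the
ITS/matK panel structure: one group site (T vs C), per-adulterant unique
sites, and one joint site shared by F. pallidiflora and F. walujewii (FPB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentRecord, BarcodeAlignment, TaxonGrouping
from .errors import DegenerateMixtureError, InputError
from .screen import (
    GROUP_DIAGNOSTIC,
    SPECIES_DIAGNOSTIC,
    DiagnosticSite,
    SitePanel,
)

MEASUREMENT_COLUMNS = [
    "sample_id", "locus", "position", "allele", "replicate", "frequency",
]


@dataclass
class MixtureSpec:
    """Ground-truth composition and noise model of one simulated sample.

    Parameters
    ----------
    components:
        Mass in grams per amplifying species.
    impurity_mass:
        Grams of non-amplifying material (soil, flour); excluded from every
        frequency but part of the physical sample weight.
    yield_factor:
        Relative DNA yield per unit mass (default 1.0 for every species).
        Anything other than 1.0 breaks the equal-yield assumption that makes
        allele frequency a mass share; it exists for sensitivity analysis.
    noise_sd:
        Absolute SD of replicate frequency noise on the [0, 1] scale.
    distortion:
        ``(slope, intercept)`` of the affine frequency response.
    seed:
        RNG seed; a fixed seed makes every simulation reproducible.
    """

    components: dict[str, float]
    impurity_mass: float = 0.0
    yield_factor: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.005
    distortion: tuple[float, float] = (0.994, 0.002)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise InputError("mixture has no components")
        for sp, m in self.components.items():
            if m < 0:
                raise InputError(f"negative mass for {sp!r}")
        if all(m == 0 for m in self.components.values()):
            raise InputError("at least one component mass must be > 0")
        if self.impurity_mass < 0:
            raise InputError("impurity mass must be >= 0")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        for sp, y in self.yield_factor.items():
            if y <= 0:
                raise InputError(f"yield factor for {sp!r} must be > 0")

    def effective_mass(self, species: str) -> float:
        """Mass × yield factor — the species' share of amplifiable DNA."""
        return self.components[species] * self.yield_factor.get(species, 1.0)

    @property
    def total_mass(self) -> float:
        """Physical sample weight including non-amplifying impurities."""
        return sum(self.components.values()) + self.impurity_mass

    def scaled(self, c: float) -> "MixtureSpec":
        """Every mass multiplied by ``c`` (frequencies are scale-free)."""
        return MixtureSpec(
            components={sp: m * c for sp, m in self.components.items()},
            impurity_mass=self.impurity_mass * c,
            yield_factor=dict(self.yield_factor),
            noise_sd=self.noise_sd,
            distortion=self.distortion,
            seed=self.seed,
        )


@dataclass(frozen=True)
class FrequencyMeasurement:
    """One measured allele frequency at one site for one replicate."""

    locus: str
    position: int
    allele: str
    frequency: float
    replicate: int
    sample_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise InputError(f"frequency {self.frequency} outside [0, 1]")
        if self.replicate < 1:
            raise InputError("replicate numbering starts at 1")

    @property
    def site_key(self) -> str:
        return f"{self.locus}:{self.position}"


def expected_frequency(
    mixture: MixtureSpec,
    site: DiagnosticSite,
    genotypes: Mapping[str, str],
) -> float:
    """Noise-free target-allele frequency of ``site`` under equal yield.

    Σ(mass·yield over species carrying the target allele) divided by
    Σ(mass·yield over all amplifying components); the impurity mass appears
    in neither sum.
    """
    missing = [sp for sp in mixture.components if sp not in genotypes]
    if missing:
        raise InputError(
            f"no genotype at {site.key} for component(s) {sorted(missing)}"
        )
    den = sum(mixture.effective_mass(sp) for sp in mixture.components)
    if den == 0:
        raise DegenerateMixtureError("mixture has no amplifying mass")
    num = sum(
        mixture.effective_mass(sp)
        for sp in mixture.components
        if genotypes[sp] == site.target_allele
    )
    return num / den


def simulate_measurements(
    mixture: MixtureSpec,
    panel: SitePanel,
    genotypes: Mapping[str, Mapping[str, str]] | None = None,
    n_replicates: int = 3,
    *,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> list[FrequencyMeasurement]:
    """Draw noisy allele-frequency measurements for every panel site.

    Per replicate the observed target-allele frequency is
    ``clamp(slope·expected + intercept + ε, 0, 1)`` with ε ~ N(0, noise_sd²);
    the complementary (background) allele is emitted as 1 − observed, so the
    two frequencies of a replicate sum to 1 exactly.  Deterministic for a
    fixed ``mixture.seed``.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    if genotypes is None:
        genotypes = panel.genotypes
    if genotypes is None:
        raise InputError("no genotypes given and panel carries none")
    if rng is None:
        rng = np.random.default_rng(mixture.seed)
    slope, intercept = mixture.distortion

    out: list[FrequencyMeasurement] = []
    for site in panel.sites:
        expected = expected_frequency(mixture, site, genotypes[site.key])
        noise = (
            rng.normal(0.0, mixture.noise_sd, size=n_replicates)
            if mixture.noise_sd > 0
            else np.zeros(n_replicates)
        )
        observed = np.clip(slope * expected + intercept + noise, 0.0, 1.0)
        for rep, obs in enumerate(observed, start=1):
            out.append(
                FrequencyMeasurement(
                    site.locus, site.position, site.target_allele,
                    float(obs), rep, sample_id,
                )
            )
            out.append(
                FrequencyMeasurement(
                    site.locus, site.position, site.background_allele,
                    float(1.0 - obs), rep, sample_id,
                )
            )
    return out


def simulate_dilution_series(
    base: MixtureSpec,
    adulterant: str,
    levels: Sequence[float],
    n_replicates: int,
    *,
    panel: SitePanel,
    genotypes: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Measurement table across adulteration levels, for assay validation.

    ``base.components`` define the genuine matrix; at each level *l* the
    matrix is scaled to ``1 − l`` of the total mass and ``adulterant`` is
    added at ``l`` of it (wt/wt).  One measurement block per level, labelled
    with the ground-truth level; replicate noise is drawn from a single
    stream seeded by ``base.seed`` so the whole study is reproducible.
    """
    for level in levels:
        if not 0.0 < level <= 1.0:
            raise InputError(f"adulteration level {level} outside (0, 1]")
    if adulterant in base.components:
        raise InputError(f"adulterant {adulterant!r} already in the base matrix")
    rng = np.random.default_rng(base.seed)
    total = sum(base.components.values())
    matrix_total = total if total > 0 else 1.0

    frames = []
    for level in levels:
        components = {
            sp: m / matrix_total * (1.0 - level) * total
            for sp, m in base.components.items()
        }
        components[adulterant] = level * total
        mixture = MixtureSpec(
            components=components,
            impurity_mass=base.impurity_mass,
            yield_factor=dict(base.yield_factor),
            noise_sd=base.noise_sd,
            distortion=base.distortion,
        )
        measurements = simulate_measurements(
            mixture, panel, genotypes, n_replicates,
            sample_id=f"level_{level:g}", rng=rng,
        )
        frame = measurements_to_frame(measurements)
        frame.insert(0, "level", level)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["level", *MEASUREMENT_COLUMNS])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# measurement table I/O


def measurements_to_frame(
    measurements: Iterable[FrequencyMeasurement],
) -> pd.DataFrame:
    rows = [
        (m.sample_id, m.locus, m.position, m.allele, m.replicate, m.frequency)
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_measurements(frame: pd.DataFrame) -> list[FrequencyMeasurement]:
    return [
        FrequencyMeasurement(
            locus=str(r.locus), position=int(r.position), allele=str(r.allele),
            frequency=float(r.frequency), replicate=int(r.replicate),
            sample_id=str(r.sample_id),
        )
        for r in frame.itertuples(index=False)
    ]


def write_measurements(
    frame: pd.DataFrame, path: str | Path, *, seed: int | None = None
) -> None:
    """Write a measurement TSV; the seed is recorded in a comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed: {seed if seed is not None else 'none'}\n")
        # %.17g round-trips doubles exactly
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement TSV written by :func:`write_measurements`."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path} contains no measurements") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"{path} lacks column(s) {missing}")
    return frame


# ---------------------------------------------------------------------------
# synthetic alignments with planted diagnostic columns


@dataclass(frozen=True)
class PlantedSite:
    """Specification of one diagnostic column to plant in a toy alignment."""

    position: int  # 1-based
    mode: str  # group_diagnostic | species_diagnostic
    taxon: str  # ignored for group mode; species or joint-taxon name otherwise
    target_allele: str
    background_allele: str


def _is_any_diagnostic(
    col_by_species: Mapping[str, str], grouping: TaxonGrouping
) -> bool:
    """Would this (per-species) column be reported by any screening mode?"""

    def fixed(species: Iterable[str]) -> str | None:
        bases = {col_by_species[sp] for sp in species}
        return next(iter(bases)) if len(bases) == 1 else None

    t = fixed(grouping.target_group)
    a = fixed(grouping.adulterants)
    if t is not None and a is not None and t != a:
        return True
    taxa = list(grouping.adulterants) + list(grouping.joint_taxa)
    for taxon in taxa:
        members = grouping.resolve(taxon)
        t = fixed(members)
        b = fixed(grouping.universe - members)
        if t is not None and b is not None and t != b:
            return True
    return False


def synthesize_alignment(
    grouping: TaxonGrouping,
    length: int,
    planted: Sequence[PlantedSite],
    *,
    locus: str = "ITS",
    n_copies: int = 2,
    seed: int | None = None,
) -> BarcodeAlignment:
    """Random gap-free alignment in which exactly the planted columns are
    diagnostic.

    Background columns draw one base per species (copies of a species are
    identical) and are rejection-sampled until they satisfy no diagnostic
    predicate, so a screen over the result recovers the planted sites with
    neither false positives nor false negatives.
    """
    rng = np.random.default_rng(seed)
    species = sorted(grouping.universe)
    bases = np.array(list("ACGT"))
    by_pos = {p.position: p for p in planted}
    for p in planted:
        if not 1 <= p.position <= length:
            raise InputError(f"planted position {p.position} outside 1..{length}")
    columns: list[dict[str, str]] = []
    for pos in range(1, length + 1):
        plant = by_pos.get(pos)
        if plant is not None:
            if plant.mode == GROUP_DIAGNOSTIC:
                members = grouping.target_group
            else:
                members = grouping.resolve(plant.taxon)
            col = {
                sp: plant.target_allele if sp in members else plant.background_allele
                for sp in species
            }
        else:
            while True:
                col = dict(zip(species, rng.choice(bases, size=len(species))))
                if not _is_any_diagnostic(col, grouping):
                    break
        columns.append(col)
    records = [
        AlignmentRecord(
            seq_id=f"{sp.replace(' ', '_')}_{i}",
            species=sp,
            seq="".join(col[sp] for col in columns),
        )
        for sp in species
        for i in range(1, n_copies + 1)
    ]
    return BarcodeAlignment(locus=locus, records=records)


# ---------------------------------------------------------------------------
# eleven-species Fritillaria demo

FCB_SPECIES = (
    "F. cirrhosa",
    "F. unibracteata",
    "F. przewalskii",
    "F. delavayi",
    "F. taipaiensis",
    "F. unibracteata var. wabuensis",
)
ADULTERANT_SPECIES = (
    "F. hupehensis",
    "F. ussuriensis",
    "F. thunbergii",
    "F. pallidiflora",
    "F. walujewii",
)


def fritillaria_grouping() -> TaxonGrouping:
    """The six-origin FCB target group vs five adulterants, FPB joint."""
    return TaxonGrouping(
        target_group=frozenset(FCB_SPECIES),
        adulterants=frozenset(ADULTERANT_SPECIES),
        joint_taxa={"FPB": frozenset({"F. pallidiflora", "F. walujewii"})},
        target_label="FCB",
    )


def fritillaria_demo(
    *, n_copies: int = 2, seed: int = 0
) -> tuple[TaxonGrouping, dict[str, BarcodeAlignment]]:
    """Synthetic ITS + matK alignments carrying the canonical panel pattern.

    Plants a group site T/C at ITS column 341, a second (A-involving) group
    site A/G at matK 336, unique sites for F. thunbergii (ITS 361, C),
    F. ussuriensis (ITS 366, G), F. hupehensis (matK 923, A) and the joint
    FPB pair (matK 1173, A).  Positions echo the field's published panel but
    are columns of these synthetic alignments, not of any reference
    accession.
    """
    grouping = fritillaria_grouping()
    its = synthesize_alignment(
        grouping,
        length=420,
        planted=[
            PlantedSite(341, GROUP_DIAGNOSTIC, "", "T", "C"),
            PlantedSite(361, SPECIES_DIAGNOSTIC, "F. thunbergii", "C", "T"),
            PlantedSite(366, SPECIES_DIAGNOSTIC, "F. ussuriensis", "G", "A"),
        ],
        locus="ITS",
        n_copies=n_copies,
        seed=seed,
    )
    matk = synthesize_alignment(
        grouping,
        length=1200,
        planted=[
            PlantedSite(336, GROUP_DIAGNOSTIC, "", "A", "G"),
            PlantedSite(923, SPECIES_DIAGNOSTIC, "F. hupehensis", "A", "G"),
            PlantedSite(1173, SPECIES_DIAGNOSTIC, "FPB", "A", "T"),
        ],
        locus="matK",
        n_copies=n_copies,
        seed=seed + 1,
    )
    return grouping, {"ITS": its, "matK": matk}
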