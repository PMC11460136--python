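"""Diagnostic-SNP screening over barcode alignments.

Two screening modes mirror the two-step strategy used to authenticate a
multi-origin herbal drug against congeneric adulterants:

* *group-diagnostic*: a column where every target-group sequence is fixed for
  one unambiguous base and every adulterant sequence is fixed for a different
  unambiguous base.  One such site suffices to detect adulteration per se.
* *species-diagnostic*: a column where one adulterant taxon (a species, or a
  named joint taxon) is fixed for a base that no other species carries, the
  rest of the universe being fixed for a single alternative base.  These
  sites type *which* adulterant is present.

Columns containing a gap or an IUPAC ambiguity code in any considered
sequence are disqualified (conservative fixedness policy).

Because pyrosequencing dispenses nucleotides one at a time and incorporation
of base A consumes extra substrate, sites whose two alleles avoid A give
cleaner quantitative signal; :func:`rank_sites_for_quantification` encodes
that preference for group-diagnostic sites.  Species-diagnostic sites are
unique identifiers, so the A-penalty is waived for them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignments import UNAMBIGUOUS, BarcodeAlignment, TaxonGrouping
from .errors import ConfigError, CoverageError, InputError, PanelError

GROUP_DIAGNOSTIC = "group_diagnostic"
SPECIES_DIAGNOSTIC = "species_diagnostic"


@dataclass(frozen=True)
class DiagnosticSite:
    """One alignment column that discriminates a taxon (group) from the rest.

    ``target_allele`` is the base fixed in ``target_taxa``; ``background_allele``
    the base fixed in the contrasted taxa.  ``label`` is the human name of the
    discriminated taxon (the grouping's target label for group sites, the
    species or joint-taxon name for species sites).  ``n_supporting`` counts
    the sequences consistent with the call (all considered sequences).
    """

    locus: str
    position: int  # 1-based alignment column
    mode: str
    target_taxa: frozenset[str]
    target_allele: str
    background_allele: str
    n_supporting: int
    label: str = ""
    flank: "Flank | None" = None

    def __post_init__(self) -> None:
        if self.target_allele == self.background_allele:
            raise InputError("target and background allele must differ")
        if self.mode not in (GROUP_DIAGNOSTIC, SPECIES_DIAGNOSTIC):
            raise InputError(f"unknown site mode {self.mode!r}")

    @property
    def key(self) -> str:
        return f"{self.locus}:{self.position}"

    @property
    def involves_a(self) -> bool:
        """True when either allele is A (energy-consuming in pyrosequencing)."""
        return "A" in (self.target_allele, self.background_allele)


@dataclass(frozen=True)
class Flank:
    """Gap-stripped sequence context around a diagnostic site.

    ``site_index`` is the 0-based offset of the SNP base within ``seq``;
    ``truncated`` flags that the requested width overran a sequence end.
    """

    seq: str
    site_index: int
    truncated: bool

    def __str__(self) -> str:  # noqa: D105
        return self.seq

    @property
    def marked(self) -> str:
        """Sequence with the SNP base bracketed, e.g. ``ACG[T]CCA``."""
        i = self.site_index
        return f"{self.seq[:i]}[{self.seq[i]}]{self.seq[i + 1:]}"


@dataclass
class SitePanel:
    """Ordered collection of diagnostic sites plus a taxon coverage map.

    The first group-diagnostic site in ``sites`` is the primary detection
    site.  ``coverage`` maps every adulterant species (and the target label)
    to the key of the site that covers it, or ``"uncovered"``.  ``genotypes``
    optionally records, per site key, each species' base at that column so the
    panel alone suffices to drive the simulator.
    """

    sites: list[DiagnosticSite]
    coverage: dict[str, str] = field(default_factory=dict)
    genotypes: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sites]
        if len(keys) != len(set(keys)):
            raise PanelError("two panel sites share (locus, position)")

    @property
    def primary(self) -> DiagnosticSite:
        for s in self.sites:
            if s.mode == GROUP_DIAGNOSTIC:
                return s
        raise PanelError("panel has no group-diagnostic site")

    def site_for(self, taxon: str) -> DiagnosticSite:
        """The species-diagnostic site covering ``taxon`` (member or label)."""
        for s in self.sites:
            if s.mode == SPECIES_DIAGNOSTIC and (
                taxon == s.label or taxon in s.target_taxa
            ):
                return s
        raise ConfigError(f"panel has no species-diagnostic site for {taxon!r}")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def site_dict(s: DiagnosticSite) -> dict:
            d = {
                "locus": s.locus,
                "position": s.position,
                "mode": s.mode,
                "target_taxa": sorted(s.target_taxa),
                "target_allele": s.target_allele,
                "background_allele": s.background_allele,
                "n_supporting": s.n_supporting,
                "label": s.label,
            }
            if s.flank is not None:
                d["flank"] = {
                    "seq": s.flank.seq,
                    "site_index": s.flank.site_index,
                    "truncated": s.flank.truncated,
                }
            return d

        return {
            "sites": [site_dict(s) for s in self.sites],
            "coverage": dict(self.coverage),
            "genotypes": self.genotypes,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SitePanel":
        sites = []
        for d in data["sites"]:
            flank = None
            if d.get("flank"):
                flank = Flank(**d["flank"])
            sites.append(
                DiagnosticSite(
                    locus=d["locus"],
                    position=d["position"],
                    mode=d["mode"],
                    target_taxa=frozenset(d["target_taxa"]),
                    target_allele=d["target_allele"],
                    background_allele=d["background_allele"],
                    n_supporting=d["n_supporting"],
                    label=d.get("label", ""),
                    flank=flank,
                )
            )
        return cls(
            sites=sites,
            coverage=dict(data.get("coverage", {})),
            genotypes=data.get("genotypes"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SitePanel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "locus", "position", "mode", "label", "target_taxa",
            "target_allele", "background_allele", "n_supporting", "flank",
        ]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for s in self.sites:
                fh.write(
                    "\t".join(
                        [
                            s.locus, str(s.position), s.mode, s.label,
                            ",".join(sorted(s.target_taxa)),
                            s.target_allele, s.background_allele,
                            str(s.n_supporting),
                            s.flank.marked if s.flank else "",
                        ]
                    )
                    + "\n"
                )

    def flanks_to_fasta(self, path: str | Path) -> None:
        """Export flanks as FASTA for manual BLAST verification."""
        with open(path, "w", encoding="utf-8") as fh:
            for s in self.sites:
                if s.flank is None:
                    continue
                fh.write(f">{s.key}|{s.label}|{s.target_allele}\n{s.flank.seq}\n")


# ---------------------------------------------------------------------------
# screening


def _char_matrix(alignment: BarcodeAlignment) -> tuple[np.ndarray, list[str]]:
    """Alignment as an (n_records, n_cols) array of single characters."""
    mat = np.array([list(r.seq) for r in alignment.records], dtype="<U1")
    return mat, [r.species for r in alignment.records]


def _fixed_base(chars: np.ndarray) -> str | None:
    """The single unambiguous base of ``chars``, or None if not fixed/clean."""
    uniq = np.unique(chars)
    if len(uniq) != 1 or uniq[0] not in UNAMBIGUOUS:
        return None
    return str(uniq[0])


def find_group_diagnostic_sites(
    alignment: BarcodeAlignment, grouping: TaxonGrouping
) -> list[DiagnosticSite]:
    """Columns separating the whole target group from all adulterants.

    A column qualifies when every target-group sequence carries one fixed
    unambiguous base and every adulterant sequence carries a different fixed
    unambiguous base.  Any gap or ambiguity code among the considered
    sequences disqualifies the column.
    """
    missing = grouping.universe - alignment.species
    if missing:
        raise CoverageError(
            f"species in grouping absent from {alignment.locus!r} alignment: "
            f"{sorted(missing)}"
        )
    mat, species = _char_matrix(alignment)
    tgt_rows = np.array([sp in grouping.target_group for sp in species])
    adl_rows = np.array([sp in grouping.adulterants for sp in species])
    n_support = int(tgt_rows.sum() + adl_rows.sum())

    sites = []
    for col in range(alignment.length):
        t = _fixed_base(mat[tgt_rows, col])
        if t is None:
            continue
        a = _fixed_base(mat[adl_rows, col])
        if a is None or a == t:
            continue
        sites.append(
            DiagnosticSite(
                locus=alignment.locus,
                position=col + 1,
                mode=GROUP_DIAGNOSTIC,
                target_taxa=grouping.target_group,
                target_allele=t,
                background_allele=a,
                n_supporting=n_support,
                label=grouping.target_label,
            )
        )
    return sites


def find_species_diagnostic_sites(
    alignment: BarcodeAlignment,
    grouping: TaxonGrouping,
    taxon: str,
    *,
    require_fixed_background: bool = True,
) -> list[DiagnosticSite]:
    """Columns where ``taxon`` (species or joint taxon) is uniquely fixed.

    By default the complement must itself be fixed for a single alternative
    base.  With ``require_fixed_background=False`` the complement may be
    polymorphic as long as it is unambiguous, gap-free and nowhere carries the
    taxon's base; the reported background allele is then the most common
    complement base (exploratory mode).
    """
    members = grouping.resolve(taxon)
    missing = members - alignment.species
    if missing:
        raise CoverageError(
            f"taxon {taxon!r} member(s) absent from alignment: {sorted(missing)}"
        )
    others = grouping.universe - members
    missing = others - alignment.species
    if missing:
        raise CoverageError(
            f"species absent from {alignment.locus!r} alignment: {sorted(missing)}"
        )
    mat, species = _char_matrix(alignment)
    in_rows = np.array([sp in members for sp in species])
    out_rows = np.array([sp in others for sp in species])
    n_support = int(in_rows.sum() + out_rows.sum())

    sites = []
    for col in range(alignment.length):
        t = _fixed_base(mat[in_rows, col])
        if t is None:
            continue
        out_chars = mat[out_rows, col]
        if require_fixed_background:
            b = _fixed_base(out_chars)
            if b is None or b == t:
                continue
        else:
            uniq, counts = np.unique(out_chars, return_counts=True)
            if t in uniq or not set(uniq) <= UNAMBIGUOUS:
                continue
            b = str(uniq[np.argmax(counts)])
        sites.append(
            DiagnosticSite(
                locus=alignment.locus,
                position=col + 1,
                mode=SPECIES_DIAGNOSTIC,
                target_taxa=members,
                target_allele=t,
                background_allele=b,
                n_supporting=n_support,
                label=taxon,
            )
        )
    return sites


def rank_sites_for_quantification(
    sites: Sequence[DiagnosticSite],
) -> list[DiagnosticSite]:
    """Order candidate quantification sites by pyrosequencing suitability.

    Sites free of base A in both alleles rank first; ties break by support
    (descending) then position (ascending).  Intended for group-diagnostic
    candidates — species-diagnostic sites are unique identifiers and exempt
    from the A-penalty.
    """
    if not sites:
        raise InputError("no sites to rank")
    return sorted(sites, key=lambda s: (s.involves_a, -s.n_supporting, s.position))


def extract_flank(
    alignment: BarcodeAlignment,
    site: DiagnosticSite,
    width: int = 55,
    *,
    representative: str | None = None,
) -> Flank:
    """Gap-stripped context of ``width`` nt around a site, for BLAST checks.

    The flank is cut from a single representative accession (by default the
    first record belonging to ``site.target_taxa``), never from a consensus.
    When the sequence ends before the full width is available the flank is
    truncated and flagged.
    """
    if width < 1:
        raise InputError("flank width must be >= 1")
    if representative is None:
        rec = next(
            (r for r in alignment.records if r.species in site.target_taxa), None
        )
        if rec is None:
            raise ConfigError(
                f"no representative record for taxa {sorted(site.target_taxa)}"
            )
    else:
        rec = next((r for r in alignment.records if r.seq_id == representative), None)
        if rec is None:
            raise ConfigError(f"representative record {representative!r} not found")
    if rec.seq[site.position - 1] == "-":
        raise ConfigError(
            f"representative {rec.seq_id!r} is gapped at column {site.position}"
        )
    # map the alignment column onto the ungapped coordinate of the record
    ungapped_index = sum(1 for c in rec.seq[: site.position - 1] if c != "-")
    ungapped = rec.seq.replace("-", "")
    left = (width - 1) // 2
    right = width - 1 - left
    lo = max(0, ungapped_index - left)
    hi = min(len(ungapped), ungapped_index + right + 1)
    return Flank(
        seq=ungapped[lo:hi],
        site_index=ungapped_index - lo,
        truncated=(hi - lo) < width,
    )


def build_panel(
    group_sites: Sequence[DiagnosticSite],
    species_sites_by_taxon: Mapping[str, Sequence[DiagnosticSite]],
    grouping: TaxonGrouping,
) -> SitePanel:
    """Assemble a panel: one primary group site plus one site per adulterant.

    The top-ranked group site becomes the primary detection site.  For each
    adulterant species the best available site is chosen — its own if one
    exists, else the site of a joint taxon containing it.  Species with no
    site are marked ``"uncovered"`` in the coverage map.
    """
    if not group_sites:
        raise PanelError("no group-diagnostic site available")
    primary = rank_sites_for_quantification(group_sites)[0]

    def best(sites: Sequence[DiagnosticSite]) -> DiagnosticSite:
        return sorted(sites, key=lambda s: (-s.n_supporting, s.position))[0]

    chosen: dict[str, DiagnosticSite] = {}
    for taxon, sites in species_sites_by_taxon.items():
        if sites:
            chosen[taxon] = best(sites)

    panel_sites: list[DiagnosticSite] = [primary]
    coverage: dict[str, str] = {grouping.target_label: primary.key}
    seen_keys = {primary.key}
    for species in sorted(grouping.adulterants):
        site = chosen.get(species)
        if site is None:
            # fall back to a joint taxon containing this species
            for joint, members in grouping.joint_taxa.items():
                if species in members and joint in chosen:
                    site = chosen[joint]
                    break
        if site is None:
            coverage[species] = "uncovered"
            continue
        coverage[species] = site.key
        if site.key not in seen_keys:
            panel_sites.append(site)
            seen_keys.add(site.key)
    return SitePanel(sites=panel_sites, coverage=coverage)


def attach_genotypes(
    panel: SitePanel, alignments: Mapping[str, BarcodeAlignment]
) -> SitePanel:
    """Record each species' fixed base at every panel site.

    Species that are polymorphic, gapped or ambiguous at a site are omitted
    from that site's genotype map (they cannot be simulated or called there).
    """
    genos: dict[str, dict[str, str]] = {}
    for site in panel.sites:
        aln = alignments[site.locus]
        per_species = aln.species_residues(site.position)
        genos[site.key] = {
            sp: next(iter(chars))
            for sp, chars in per_species.items()
            if len(chars) == 1 and next(iter(chars)) in UNAMBIGUOUS
        }
    panel.genotypes = genos
    return panel


def attach_flanks(
    panel: SitePanel,
    alignments: Mapping[str, BarcodeAlignment],
    width: int = 55,
) -> SitePanel:
    """Attach a representative flank to every panel site (in place)."""
    panel.sites = [
        replace(s, flank=extract_flank(alignments[s.locus], s, width))
        for s in panel.sites
    ]
    return panel


def discover_panel(
    alignments: Mapping[str, BarcodeAlignment],
    grouping: TaxonGrouping,
    *,
    flank_width: int = 55,
) -> SitePanel:
    """Full screening workflow over one or more loci.

    Screens every locus for group-diagnostic sites and, per adulterant species
    and joint taxon, for species-diagnostic sites; ranks, assembles the panel,
    and attaches flanks and genotype maps.
    """
    group_sites: list[DiagnosticSite] = []
    species_sites: dict[str, list[DiagnosticSite]] = {}
    taxa = sorted(grouping.adulterants) + sorted(grouping.joint_taxa)
    for aln in alignments.values():
        group_sites.extend(find_group_diagnostic_sites(aln, grouping))
        for taxon in taxa:
            species_sites.setdefault(taxon, []).extend(
                find_species_diagnostic_sites(aln, grouping, taxon)
            )
    panel = build_panel(group_sites, species_sites, grouping)
    attach_flanks(panel, alignments, flank_width)
    attach_genotypes(panel, alignments)
    return panel
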