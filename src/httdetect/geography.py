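"""Geographic corroboration of incongruence-based transfer candidates.

Horizontal transfer requires some spatial overlap of the taxa involved, so
each incongruence is annotated with whether the focal clade's species and
its context species share at least one geographic region. Species are
assigned to coarse regions (biogeographic realms / bioregions separated by
expected migration barriers); the shipped seven-region default list is a
configurable placeholder, not a fixed partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .treeops import Incongruence

__all__ = [
    "DEFAULT_REGIONS",
    "RegionMap",
    "GeoSummary",
    "load_region_map",
    "regions_overlap",
    "tally_geographic_concordance",
]

DEFAULT_REGIONS = (
    "Europe",
    "East_Asia",
    "Southeast_Asia",
    "South_Asia_Oceania",
    "Nearctic",
    "Neotropic",
    "Afrotropic",
)


@dataclass
class RegionMap:
    """Per-species geographic assignments.

    ``sample`` holds the region(s) where sequenced samples were collected;
    ``distribution`` additionally unions known-distribution regions.
    """

    regions: tuple[str, ...] = DEFAULT_REGIONS
    sample: dict[str, frozenset[str]] = field(default_factory=dict)
    distribution: dict[str, frozenset[str]] = field(default_factory=dict)

    def add(self, species: str, sample_region: str,
            extra_regions: Iterable[str] = ()) -> None:
        for r in [sample_region, *extra_regions]:
            if r not in self.regions:
                raise ValueError(
                    f"unknown region {r!r}; allowed: {', '.join(self.regions)}"
                )
        self.sample[species] = self.sample.get(species, frozenset()) | {sample_region}
        self.distribution[species] = (
            self.distribution.get(species, frozenset())
            | {sample_region}
            | set(extra_regions)
        )

    def regions_of(self, species: str, mode: str = "sample_only") -> frozenset[str]:
        if mode not in ("sample_only", "with_distribution"):
            raise ValueError(f"unknown mode {mode!r}")
        table = self.sample if mode == "sample_only" else self.distribution
        if species not in table:
            raise KeyError(f"species {species!r} has no region assignment")
        return table[species]


def load_region_map(path, regions: Sequence[str] = DEFAULT_REGIONS) -> RegionMap:
    """Read a TSV with columns species, sample_region[, extra_regions]
    (extra_regions a ;-separated list). Duplicate species rows are unioned."""
    rm = RegionMap(regions=tuple(regions))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (
                lineno == 1 and line.lower().startswith("species")
            ):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: need species and sample_region")
            extra = [r for r in fields[2].split(";") if r] if len(fields) > 2 else []
            rm.add(fields[0], fields[1], extra)
    return rm


def regions_overlap(a: frozenset[str] | set, b: frozenset[str] | set) -> bool:
    """True iff the two region sets intersect."""
    if not a or not b:
        raise ValueError("region sets must be non-empty")
    return bool(set(a) & set(b))


@dataclass
class GeoSummary:
    n_incongruences: int
    n_same_region: int
    flags: list[bool]
    annotated: list[Incongruence]


def tally_geographic_concordance(
    incs: Sequence[Incongruence],
    region_map: RegionMap,
    species_of: Mapping[str, str],
    mode: str = "sample_only",
) -> GeoSummary:
    """Count how many incongruences involve geographically overlapping taxa.

    The focal clade's regions are unioned across its species, likewise the
    context side; overlap is a non-empty intersection. ``species_of`` maps
    leaf ids to species names. ``mode`` "sample_only" uses collection
    regions alone; "with_distribution" also counts known-distribution
    regions, so its tally can only be larger.
    """
    flags: list[bool] = []
    annotated: list[Incongruence] = []
    for inc in incs:
        rf = frozenset().union(
            *(region_map.regions_of(species_of[lf], mode) for lf in inc.focal_clade)
        )
        rc = frozenset().union(
            *(region_map.regions_of(species_of[lf], mode) for lf in inc.context_leaves)
        )
        flag = regions_overlap(rf, rc)
        flags.append(flag)
        annotated.append(
            Incongruence(
                focal_clade=inc.focal_clade, focal_label=inc.focal_label,
                context_label=inc.context_label, context_leaves=inc.context_leaves,
                supporting_edge=inc.supporting_edge, ambiguous=inc.ambiguous,
                basal_origin=inc.basal_origin,
                regions_focal=rf, regions_context=rc,
            )
        )
    return GeoSummary(
        n_incongruences=len(incs),
        n_same_region=sum(flags),
        flags=flags,
        annotated=annotated,
    )
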