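"""Evidence synthesis: rank candidate horizontal transposon transfers.

Three evidence channels are combined per candidate:

* phylogenetic incongruence — a label-uniform clade nested in a context of
  a different taxonomic label (from the parsimony labeling);
* divergence-time deviation — the TE-based time T = K/(2r) is far smaller
  than the dated species divergence (ratio >= theta, default one order of
  magnitude);
* geographic overlap — the taxa involved share a region, a precondition
  for transfer that corroborates but never creates a call.

Transfer direction is deliberately not inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DEFAULT_RATE, divergence_time
from .geography import RegionMap, regions_overlap, tally_geographic_concordance
from .treeops import LabelingResult, SupportTree, enumerate_incongruences

__all__ = [
    "HTTCandidate",
    "DEFAULT_WEIGHTS",
    "call_candidates",
    "minimum_events_summary",
    "load_species_divergence",
    "candidates_to_dataframe",
]

DEFAULT_WEIGHTS = {"incongruence": 1.0, "deviation": 1.0, "geography": 0.5}


@dataclass(frozen=True)
class HTTCandidate:
    """One putative horizontal transfer with its evidence flags."""

    kind: str                       # "incongruence" or "pair"
    taxa_a: frozenset[str]          # focal clade leaves / first leaf
    taxa_b: frozenset[str]          # context leaves / second leaf
    focal_label: str
    context_label: str
    K_observed: float
    T_te_years: float
    T_species_years: float | None
    deviation_ratio: float | None
    incongruent: bool
    ambiguous: bool
    geographic_overlap: bool
    score: float

    @property
    def flagged(self) -> bool:
        return self.incongruent or self.kind == "pair"


def load_species_divergence(path) -> dict[frozenset, float]:
    """Read a dated species-divergence TSV (taxon_a, taxon_b, divergence_my)
    into a map of unordered pairs to years."""
    table: dict[frozenset, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (
                lineno == 1 and line.lower().startswith(("taxon", "species"))
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: need 3 columns")
            table[frozenset((fields[0], fields[1]))] = float(fields[2]) * 1e6
    return table


def _species_time(
    species_div: Mapping[frozenset, float] | None,
    species_a: set[str],
    species_b: set[str],
) -> float | None:
    """Mean dated divergence over cross pairs with an entry; None if none."""
    if species_div is None:
        return None
    vals = [
        species_div[frozenset((a, b))]
        for a in species_a
        for b in species_b
        if a != b and frozenset((a, b)) in species_div
    ]
    return float(np.mean(vals)) if vals else None


def _ratio(t_species: float | None, t_te: float) -> float | None:
    if t_species is None:
        return None
    if t_te == 0.0:
        return math.inf if t_species > 0 else 0.0
    return t_species / t_te


def call_candidates(
    stree: SupportTree,
    labels: Mapping[str, str],
    dist: np.ndarray,
    ids: Sequence[str],
    species_of: Mapping[str, str],
    region_map: RegionMap | None = None,
    species_div: Mapping[frozenset, float] | None = None,
    theta: float = 10.0,
    r: float = DEFAULT_RATE,
    generations_per_year: float = 1.0,
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
    geo_mode: str = "sample_only",
    root_mode: str = "auto",
) -> list[HTTCandidate]:
    """Combine incongruence, time-deviation and geography into ranked calls.

    One candidate is emitted per non-basal incongruence edge and one per
    leaf pair (of distinct species) whose deviation ratio
    T_species / T_te meets ``theta``. Missing species-divergence entries
    withhold the deviation evidence rather than aborting. The returned list
    is sorted by evidence score, then deviation ratio, then taxa, and is
    deterministic for fixed inputs.
    """
    if theta <= 1:
        raise ValueError("theta must exceed 1")
    pos = {lid: i for i, lid in enumerate(ids)}
    candidates: list[HTTCandidate] = []

    incs = [
        inc for inc in enumerate_incongruences(stree, labels, root_mode=root_mode)
        if not inc.basal_origin
    ]
    if region_map is not None and incs:
        incs = tally_geographic_concordance(incs, region_map, species_of,
                                            mode=geo_mode).annotated
    for inc in incs:
        cross = [
            dist[pos[a], pos[b]]
            for a in inc.focal_clade for b in inc.context_leaves
            if not np.isnan(dist[pos[a], pos[b]])
        ]
        K = float(np.mean(cross)) if cross else float("nan")
        t_te = divergence_time(K, r, generations_per_year).T_years if cross else math.nan
        t_sp = _species_time(
            species_div,
            {species_of[a] for a in inc.focal_clade},
            {species_of[b] for b in inc.context_leaves},
        )
        ratio = _ratio(t_sp, t_te) if cross else None
        dev_flag = ratio is not None and math.isfinite(theta) and ratio >= theta
        geo = regions_overlap(inc.regions_focal, inc.regions_context) \
            if inc.regions_focal and inc.regions_context else False
        score = (weights["incongruence"]
                 + weights["deviation"] * dev_flag
                 + weights["geography"] * geo)
        candidates.append(HTTCandidate(
            kind="incongruence",
            taxa_a=inc.focal_clade, taxa_b=inc.context_leaves,
            focal_label=inc.focal_label, context_label=inc.context_label,
            K_observed=K, T_te_years=t_te, T_species_years=t_sp,
            deviation_ratio=ratio, incongruent=True, ambiguous=inc.ambiguous,
            geographic_overlap=geo, score=score,
        ))

    if species_div is not None:
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                sa, sb = species_of[ids[i]], species_of[ids[j]]
                if sa == sb or np.isnan(dist[i, j]):
                    continue
                t_sp = species_div.get(frozenset((sa, sb)))
                if t_sp is None:
                    continue
                K = float(dist[i, j])
                t_te = divergence_time(K, r, generations_per_year).T_years
                ratio = _ratio(t_sp, t_te)
                if not (math.isfinite(theta) and ratio >= theta):
                    continue
                geo = False
                if region_map is not None:
                    geo = regions_overlap(
                        region_map.regions_of(sa, geo_mode),
                        region_map.regions_of(sb, geo_mode),
                    )
                score = (weights["deviation"] + weights["geography"] * geo)
                candidates.append(HTTCandidate(
                    kind="pair",
                    taxa_a=frozenset({ids[i]}), taxa_b=frozenset({ids[j]}),
                    focal_label=labels.get(ids[i], ""),
                    context_label=labels.get(ids[j], ""),
                    K_observed=K, T_te_years=t_te, T_species_years=t_sp,
                    deviation_ratio=ratio, incongruent=False, ambiguous=False,
                    geographic_overlap=geo, score=score,
                ))

    def sort_key(c: HTTCandidate):
        dev = c.deviation_ratio if c.deviation_ratio is not None else -1.0
        return (-c.score, -dev, tuple(sorted(c.taxa_a)), tuple(sorted(c.taxa_b)))

    return sorted(candidates, key=sort_key)


def minimum_events_summary(results: Mapping[str, LabelingResult]) -> pd.DataFrame:
    """Per-rank minimum-event table for nested taxonomic ranks.

    Ranks should be given coarse to fine; ``additional_events`` is the
    finer rank's excess beyond the previous rank's (floored at 0), so the
    running nested total equals the finest rank's excess when ranks refine
    each other.
    """
    rows = []
    prev_excess = 0
    for i, (rank, res) in enumerate(results.items()):
        additional = res.excess_events if i == 0 else max(
            res.excess_events - prev_excess, 0)
        rows.append({
            "rank": rank,
            "parsimony_score": res.parsimony_score,
            "n_labels": res.n_labels,
            "excess_events": res.excess_events,
            "additional_events": additional,
        })
        prev_excess = res.excess_events
    return pd.DataFrame(rows)


def candidates_to_dataframe(candidates: Sequence[HTTCandidate]) -> pd.DataFrame:
    """Flatten candidates for TSV reporting (deterministic column text)."""
    rows = []
    for c in candidates:
        rows.append({
            "kind": c.kind,
            "taxa_a": ";".join(sorted(c.taxa_a)),
            "taxa_b": ";".join(sorted(c.taxa_b)),
            "focal_label": c.focal_label,
            "context_label": c.context_label,
            "K_observed": c.K_observed,
            "T_te_years": c.T_te_years,
            "T_species_years": c.T_species_years if c.T_species_years is not None else "",
            "deviation_ratio": c.deviation_ratio if c.deviation_ratio is not None else "",
            "incongruent": c.incongruent,
            "ambiguous": c.ambiguous,
            "geographic_overlap": c.geographic_overlap,
            "score": c.score,
        })
    return pd.DataFrame(rows)
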