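"""Forward simulation of TE evolution with injected horizontal transfers.

A single TE copy evolves neutrally (Jukes–Cantor, rate ``mu`` per site per
generation) along a dated species tree. A horizontal-transfer event at time
``t`` copies the donor lineage's current sequence into the recipient
lineage, after which both evolve independently — equivalently, the copy
genealogy is the species tree with the recipient's branch detached at
``t`` and regrafted onto the donor's branch. The simulator emits the
sequences, a taxon-metadata table, the true copy genealogy, a JSON truth
log (events, per-branch substitution counts, provenance), and synthetic
homology-hit tables with partial/degraded copies so that every pipeline
stage can be exercised without external data.

Substitutions are realized exactly as an event process: per site, a
Poisson(mu * generations) number of events, each replacing the base with
one of the other three uniformly. Branch lengths in input species trees
are YEARS; emitted genealogies use millions of years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geography import DEFAULT_REGIONS, RegionMap
from .treeops import SupportTree, read_newick

__all__ = [
    "HTEvent",
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "HitPlan",
    "make_hit_plans",
    "emit_hit_table",
    "deep_split_tree",
    "recent_ht_scenario",
    "closed_loop_call",
    "score_candidates",
    "jc_expected_p",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class HTEvent:
    """Transfer of the donor lineage's TE into the recipient lineage at
    ``time_years`` before present. Lineages are named nodes; the time must
    fall within each node's parent-edge span."""

    donor: str
    recipient: str
    time_years: float


@dataclass
class SimulationConfig:
    species_tree: str                      # Newick, branch lengths in years
    mu: float = 3.0e-9
    generations_per_year: float = 1.0
    seq_length: int = 5294
    ht_events: list[HTEvent] = field(default_factory=list)
    degradation: float = 0.0               # fraction of copies truncated
    regions: dict[str, str] = field(default_factory=dict)
    taxonomy: dict[str, dict[str, str]] = field(default_factory=dict)
    seed: int = 0


class _LNode:
    __slots__ = ("name", "age", "children", "parent")

    def __init__(self, name: str, age: float):
        self.name = name
        self.age = age
        self.children: list[_LNode] = []
        self.parent: _LNode | None = None

    def add(self, child: "_LNode") -> None:
        child.parent = self
        self.children.append(child)

    def iter_descendants(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class _Genealogy:
    """Mutable copy genealogy: species tree plus HT regrafts."""

    def __init__(self, newick_years: str):
        stree = read_newick(newick_years)
        t = stree.tree
        depths = {t.seed_node: 0.0}
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        max_depth = max(d for n, d in depths.items() if n.is_leaf())
        for lf in t.leaf_node_iter():
            if abs(depths[lf] - max_depth) > 1e-6 * max(max_depth, 1.0):
                raise ValueError("species tree must be ultrametric (dated)")
        self.by_name: dict[str, _LNode] = {}
        counter = [0]

        def build(dnode) -> _LNode:
            if dnode.is_leaf():
                name = dnode.taxon.label
                age = 0.0
            else:
                counter[0] += 1
                name = dnode.label if isinstance(dnode.label, str) and dnode.label \
                    else f"anc{counter[0]}"
                age = max_depth - depths[dnode]
            node = _LNode(name, age)
            self.by_name[name] = node
            for c in dnode.child_nodes():
                node.add(build(c))
            return node

        self.root = build(t.seed_node)
        self.leaf_names = sorted(
            n.name for n in self.root.iter_descendants() if not n.children
        )

    def _is_descendant(self, node: _LNode, of: _LNode) -> bool:
        cur = node
        while cur is not None:
            if cur is of:
                return True
            cur = cur.parent
        return False

    def apply_event(self, ev: HTEvent, att_name: str) -> None:
        for role, name in (("donor", ev.donor), ("recipient", ev.recipient)):
            if name not in self.by_name:
                raise ValueError(f"{role} lineage {name!r} not in tree")
        donor = self.by_name[ev.donor]
        recip = self.by_name[ev.recipient]
        if donor is recip:
            raise ValueError("donor and recipient must differ")
        if self._is_descendant(donor, recip):
            raise ValueError("donor lineage descends from the recipient")
        t = ev.time_years
        for role, node in (("donor", donor), ("recipient", recip)):
            if node.parent is None:
                raise ValueError(f"{role} lineage is the root")
            if not (node.age <= t < node.parent.age):
                raise ValueError(
                    f"{role} lineage {node.name!r} not present at {t:.3g} years "
                    f"(edge spans {node.age:.3g}..{node.parent.age:.3g})"
                )
        # detach recipient, splicing out a resulting unary parent
        rp = recip.parent
        rp.children.remove(recip)
        recip.parent = None
        if len(rp.children) == 1:
            only = rp.children[0]
            gp = rp.parent
            if gp is None:
                only.parent = None
                self.root = only
            else:
                gp.children[gp.children.index(rp)] = only
                only.parent = gp
            del self.by_name[rp.name]
        # insert attachment node on the donor's (possibly spliced) edge
        dp = donor.parent
        att = _LNode(att_name, t)
        if dp is None:          # donor became the root after splicing
            self.root = att
        else:
            dp.children[dp.children.index(donor)] = att
            att.parent = dp
        att.add(donor)
        att.add(recip)
        self.by_name[att_name] = att

    def newick_my(self, leaf_rename: Mapping[str, str]) -> str:
        def rec(node: _LNode) -> str:
            if not node.children:
                label = leaf_rename.get(node.name, node.name)
            else:
                label = ""
            inner = (
                "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.children else ""
            )
            if node.parent is None:
                return f"{inner}{label}"
            blen = (node.parent.age - node.age) / 1e6
            return f"{inner}{label}:{blen:.8f}"

        return rec(self.root) + ";"


def jc_expected_p(divergence_years: float, mu: float = 3.0e-9,
                  generations_per_year: float = 1.0) -> float:
    """Expected proportion of differing sites for two lineages separated by
    2 * t generations of Jukes–Cantor evolution at rate mu."""
    d = 2.0 * divergence_years * generations_per_year * mu
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _evolve_branch(seq: np.ndarray, t_gen: float, mu: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """JC event process along one branch: per-site Poisson event counts, each
    event an equal-probability change to one of the other three bases."""
    L = seq.size
    m = rng.poisson(mu * t_gen, size=L)
    out = seq.copy()
    hit = np.flatnonzero(m)
    if hit.size:
        # base distribution after k events: P(same) = 1/4 (1 + 3 (-1/3)^k)
        p_same = 0.25 * (1.0 + 3.0 * (-1.0 / 3.0) ** m[hit])
        stay = rng.random(hit.size) < p_same
        change = hit[~stay]
        out[change] = (out[change] + rng.integers(1, 4, change.size)) % 4
    return out, int(m.sum())


@dataclass
class SimulationResult:
    config: SimulationConfig
    copy_ids: list[str]
    sequences: dict[str, str]              # full-length copies
    emitted_sequences: dict[str, str]      # with truncation applied
    metadata: pd.DataFrame
    true_tree: SupportTree
    truth: dict
    species_divergence: dict[frozenset, float]   # unordered pair -> years

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.metadata["id"], self.metadata["species"]))

    def labels(self, rank: str = "order") -> dict[str, str]:
        return dict(zip(self.metadata["id"], self.metadata[rank]))

    def region_map(self) -> RegionMap:
        rm = RegionMap(regions=tuple(
            dict.fromkeys(list(DEFAULT_REGIONS) + sorted(set(self.metadata["region"])))
        ))
        for sp, reg in zip(self.metadata["species"], self.metadata["region"]):
            rm.add(sp, reg)
        return rm

    def alignment(self):
        from .distances import AlignedMatrix

        return AlignedMatrix(self.copy_ids,
                             [self.sequences[i] for i in self.copy_ids])

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "copies.fasta", "w") as fh:
            for cid in self.copy_ids:
                fh.write(f">{cid}\n{self.emitted_sequences[cid]}\n")
        with open(out / "alignment.fasta", "w") as fh:
            for cid in self.copy_ids:
                fh.write(f">{cid}\n{self.sequences[cid]}\n")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        from .treeops import write_newick

        write_newick(self.true_tree, out / "true_tree.nwk")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, sort_keys=True, indent=1)
        with open(out / "species_divergence.tsv", "w") as fh:
            fh.write("taxon_a\ttaxon_b\tdivergence_my\n")
            for pair in sorted(self.species_divergence, key=sorted):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{self.species_divergence[pair] / 1e6:.6f}\n")
        with open(out / "regions.tsv", "w") as fh:
            fh.write("species\tsample_region\n")
            for _, row in self.metadata.drop_duplicates("species").iterrows():
                fh.write(f"{row['species']}\t{row['region']}\n")


_RANKS = ("class", "order", "superfamily", "family")


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the simulator; identical configs (including seed) give identical
    results byte for byte."""
    if config.seq_length <= 0:
        raise ValueError("seq_length must be positive")
    rng = np.random.default_rng(config.seed)

    # species divergences from the undisturbed species tree
    species_gen = _Genealogy(config.species_tree)
    ages: dict[frozenset, float] = {}
    leaves_below: dict[int, list[str]] = {}

    def collect(node: _LNode) -> list[str]:
        if not node.children:
            return [node.name]
        groups = [collect(c) for c in node.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        ages[frozenset((a, b))] = node.age
        return [x for g in groups for x in g]

    collect(species_gen.root)

    # copy genealogy: regraft recipients onto donors, oldest event first
    gen = _Genealogy(config.species_tree)
    events = sorted(config.ht_events, key=lambda e: -e.time_years)
    for i, ev in enumerate(events):
        gen.apply_event(ev, att_name=f"ht{i}")

    # evolve sequences down the copy genealogy
    L = config.seq_length
    root_seq = rng.integers(0, 4, L, dtype=np.int8)
    seqs: dict[str, np.ndarray] = {gen.root.name: root_seq}
    sub_counts: dict[str, int] = {}
    stack = [gen.root]
    while stack:
        node = stack.pop(0)
        for child in node.children:
            t_gen = (node.age - child.age) * config.generations_per_year
            seqs[child.name], n = _evolve_branch(seqs[node.name], t_gen,
                                                 config.mu, rng)
            sub_counts[child.name] = n
            stack.append(child)

    species_names = gen.leaf_names
    copy_ids = [f"{sp}_TE" for sp in species_names]
    rename = {sp: cid for sp, cid in zip(species_names, copy_ids)}
    sequences = {
        rename[sp]: "".join(chr(_BASES[b]) for b in seqs[sp]) for sp in species_names
    }

    # degradation plan: a fixed fraction of copies truncated to a uniform
    # fraction of their length
    n_trunc = int(round(config.degradation * len(copy_ids)))
    trunc_idx = sorted(rng.choice(len(copy_ids), size=n_trunc, replace=False)) \
        if n_trunc else []
    truncations: dict[str, tuple[int, int]] = {}
    emitted = dict(sequences)
    for i in trunc_idx:
        cid = copy_ids[i]
        frac = float(rng.uniform(0.1, 0.95))
        span = max(1, int(round(frac * L)))
        start = int(rng.integers(0, L - span + 1))
        truncations[cid] = (start + 1, start + span)   # 1-based inclusive
        emitted[cid] = sequences[cid][start : start + span]

    # provenance: path of lineage names root -> leaf, with HT nodes marked
    provenance: dict[str, dict] = {}
    for sp in species_names:
        node = gen.by_name[sp]
        path = []
        while node is not None:
            path.append(node.name)
            node = node.parent
        path.reverse()
        provenance[rename[sp]] = {
            "species": sp,
            "path": path,
            "ht_on_path": [p for p in path if p.startswith("ht")],
        }

    taxonomy = config.taxonomy
    rows = []
    for sp, cid in zip(species_names, copy_ids):
        tax = taxonomy.get(sp, {})
        rows.append({
            "id": cid,
            "species": sp,
            **{rank: tax.get(rank, sp) for rank in _RANKS},
            "region": config.regions.get(sp, DEFAULT_REGIONS[0]),
        })
    metadata = pd.DataFrame(rows)

    truth = {
        "seed": config.seed,
        "mu": config.mu,
        "generations_per_year": config.generations_per_year,
        "seq_length": L,
        "events": [
            {"donor": e.donor, "recipient": e.recipient, "time_years": e.time_years}
            for e in events
        ],
        "substitutions_per_branch": sub_counts,
        "provenance": provenance,
        "truncations": {k: list(v) for k, v in truncations.items()},
    }
    true_tree = read_newick(gen.newick_my(rename))
    return SimulationResult(
        config=config,
        copy_ids=copy_ids,
        sequences=sequences,
        emitted_sequences=emitted,
        metadata=metadata,
        true_tree=true_tree,
        truth=truth,
        species_divergence=ages,
    )


# ---------------------------------------------------------------------------
# synthetic homology-hit tables


@dataclass(frozen=True)
class HitPlan:
    """Planned HSP rows for one copy: query intervals and an identity, both
    known by construction so the expected filter outcome is computable."""

    copy_id: str
    species: str
    intervals: tuple[tuple[int, int], ...]
    identity_pct: float


def make_hit_plans(
    result: SimulationResult,
    rng: np.random.Generator,
    split_prob: float = 0.4,
    low_identity_frac: float = 0.2,
) -> list[HitPlan]:
    """Build hit plans from a simulation: truncated copies cover only their
    surviving span, a fraction of full copies are split into two HSPs with a
    small uncovered gap, and a fraction get sub-threshold identity."""
    L = result.config.seq_length
    species_of = result.species_of()
    plans = []
    for cid in result.copy_ids:
        if cid in result.truth["truncations"]:
            s, e = result.truth["truncations"][cid]
            intervals = ((s, e),)
        elif rng.random() < split_prob:
            cut = int(rng.integers(L // 4, 3 * L // 4))
            gap = int(rng.integers(1, max(2, L // 50)))
            intervals = ((1, cut), (min(cut + 1 + gap, L), L))
        else:
            intervals = ((1, L),)
        low = rng.random() < low_identity_frac
        ident = float(rng.uniform(60.0, 79.5) if low else rng.uniform(85.0, 99.5))
        plans.append(HitPlan(cid, species_of[cid], intervals, round(ident, 2)))
    return plans


def expected_survivors(
    plans: Sequence[HitPlan],
    query_length: int,
    min_identity_pct: float = 80.0,
    min_cover_fraction: float = 0.70,
) -> set[str]:
    """Copies that must pass the filter, decided by a per-base bitmap —
    independent of the interval-union arithmetic under test."""
    keep = set()
    for p in plans:
        if p.identity_pct <= min_identity_pct:
            continue
        mask = np.zeros(query_length, dtype=bool)
        for s, e in p.intervals:
            mask[s - 1 : e] = True
        if mask.sum() / query_length > min_cover_fraction:
            keep.add(p.copy_id)
    return keep


def emit_hit_table(
    plans: Sequence[HitPlan],
    query_length: int,
    path=None,
    rng: np.random.Generator | None = None,
    query_id: str = "TE_query",
) -> pd.DataFrame:
    """Materialize hit plans as 12-column tabular homology rows. Subject
    coordinates are offset and a random half are minus-strand to exercise
    strand normalization."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for p in plans:
        offset = int(rng.integers(1, 100000))
        for qs, qe in p.intervals:
            length = qe - qs + 1
            ss, se = offset + qs, offset + qe
            if rng.random() < 0.5:
                ss, se = se, ss
            rows.append((query_id, p.copy_id, p.identity_pct, length,
                         int(round((1 - p.identity_pct / 100) * length)), 0,
                         qs, qe, ss, se, 0.0, round(2.0 * length, 1)))
    df = pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ])
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df


# ---------------------------------------------------------------------------
# study-condition scenarios


def deep_split_tree(
    n_orders: int = 5,
    species_per_order: int = 4,
    order_split_my: float = 300.0,
    within_split_my: float = 120.0,
) -> tuple[str, dict[str, dict[str, str]]]:
    """A dated species tree of anciently diverged insect orders: all orders
    split at ``order_split_my``; within an order, species split along a
    caterpillar at evenly spaced ages down from ``within_split_my``.
    Returns (newick with branch lengths in years, taxonomy map)."""
    taxonomy: dict[str, dict[str, str]] = {}
    clades = []
    for o in range(n_orders):
        order = f"order{o}"
        names = [f"sp{o}{chr(ord('a') + s)}" for s in range(species_per_order)]
        for nm in names:
            taxonomy[nm] = {"class": "Insecta", "order": order,
                            "superfamily": f"sf{o}", "family": f"fam{o}"}
        k = len(names)
        ages = [within_split_my * 1e6 * (k - 1 - i) / (k - 1) for i in range(k - 1)] \
            if k > 1 else []
        # caterpillar: ((..(sp_a,sp_b)t_last, sp_c).., sp_k) with given ages
        sub = names[0]
        depth = 0.0
        for i, nm in enumerate(names[1:]):
            age = ages[len(ages) - 1 - i] if ages else 0.0
            sub = f"({sub}:{age - depth:.1f},{nm}:{age:.1f})"
            depth = age
        clades.append(f"{sub}:{order_split_my * 1e6 - depth:.1f}")
    return "(" + ",".join(clades) + ");", taxonomy


def recent_ht_scenario(
    seed: int,
    n_events: int = 5,
    n_orders: int = 5,
    species_per_order: int = 4,
    order_split_my: float = 300.0,
    within_split_my: float = 120.0,
    max_event_my: float = 1.0,
    seq_length: int = 5294,
    same_region: bool = True,
    degradation: float = 0.0,
) -> SimulationConfig:
    """The canonical stress scenario: recent transfers (<= 1 MY) between
    orders that diverged hundreds of millions of years ago. Donors and
    recipients are distinct extant species from different orders; all
    species share one region when ``same_region`` (so every true transfer
    is geographically plausible)."""
    newick, taxonomy = deep_split_tree(n_orders, species_per_order,
                                       order_split_my, within_split_my)
    rng = np.random.default_rng(seed)
    species = sorted(taxonomy)
    order_of = {sp: taxonomy[sp]["order"] for sp in species}
    recipients = list(rng.choice(species, size=n_events, replace=False))
    events = []
    for rec in recipients:
        donors = [s for s in species
                  if order_of[s] != order_of[rec] and s not in recipients]
        donor = str(rng.choice(donors))
        t = float(rng.uniform(0.2, max_event_my) * 1e6)
        events.append(HTEvent(donor=donor, recipient=str(rec), time_years=t))
    if same_region:
        regions = {sp: "Europe" for sp in species}
    else:
        regions = {sp: DEFAULT_REGIONS[int(order_of[sp][5:]) % len(DEFAULT_REGIONS)]
                   for sp in species}
    return SimulationConfig(
        species_tree=newick,
        seq_length=seq_length,
        ht_events=events,
        regions=regions,
        taxonomy=taxonomy,
        degradation=degradation,
        seed=seed,
    )


def closed_loop_call(result: SimulationResult, theta: float = 10.0,
                     rank: str = "order"):
    """Run the full pipeline on a simulation: pairwise distances, a
    neighbor-joining tree, incongruence enumeration, and candidate calling
    against the true species-divergence table. Returns (candidates,
    distance matrix, tree)."""
    from .distances import pairwise_matrix
    from .htt_caller import call_candidates
    from .treeops import neighbor_joining

    aln = result.alignment()
    dist = pairwise_matrix(aln)
    tree = neighbor_joining(dist, result.copy_ids)
    candidates = call_candidates(
        tree,
        result.labels(rank),
        dist,
        result.copy_ids,
        result.species_of(),
        region_map=result.region_map(),
        species_div=result.species_divergence,
        theta=theta,
    )
    return candidates, dist, tree


def score_candidates(candidates, result: SimulationResult) -> tuple[float, float]:
    """Precision and recall of called candidates against the truth log.

    A candidate is a true positive when its focal clade consists solely of
    copies from recipient species (incongruence kind) or when either member
    of a deviation pair is a recipient. An injected event is recovered when
    its recipient species appears in any true-positive candidate."""
    species_of = result.species_of()
    recipients = {e["recipient"] for e in result.truth["events"]}
    n_events = len(result.truth["events"])
    tp = 0
    recovered: set[str] = set()
    for c in candidates:
        if c.kind == "incongruence":
            focal_species = {species_of[lf] for lf in c.taxa_a}
            ok = focal_species <= recipients and bool(focal_species)
        else:
            pair_species = {species_of[lf] for lf in (c.taxa_a | c.taxa_b)}
            ok = bool(pair_species & recipients)
            focal_species = pair_species & recipients
        if ok:
            tp += 1
            recovered |= focal_species & recipients
    precision = tp / len(candidates) if candidates else 1.0
    recall = len(recovered) / n_events if n_events else 1.0
    return precision, recall
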