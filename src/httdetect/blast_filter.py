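"""Homology-hit filtering: parse tabular BLAST output, stitch HSP coverage,
apply identity/coverage selection, and rename retained sequences.

The selection rule follows the common TE-screening practice of retaining a
subject only when its HSPs each exceed a nucleotide-identity floor and when
their union covers more than a stated fraction of the query element.
Coordinates in the 12-column tabular dialect are 1-based inclusive; interval
arithmetic internally uses 0-based half-open intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HSP",
    "HSPSet",
    "TECopy",
    "BlastTabError",
    "parse_blast_tab",
    "group_by_subject",
    "merge_intervals",
    "query_coverage",
    "coverage_threshold_bp",
    "select_hits",
    "copies_from_hits",
    "rename_record",
    "parse_record_name",
    "write_retained_fasta",
    "write_manifest",
]


class BlastTabError(ValueError):
    """Raised for malformed tabular homology-search input."""


@dataclass(frozen=True)
class HSP:
    """One high-scoring segment pair from a tabular homology search.

    Query coordinates are 1-based inclusive and ascending; subject
    coordinates may be descending (minus strand) and are preserved as given.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if not (1 <= self.query_start <= self.query_end):
            raise ValueError(
                f"query interval [{self.query_start}, {self.query_end}] invalid"
            )

    @property
    def subject_range(self) -> tuple[int, int]:
        """Strand-normalized (min, max) subject coordinates."""
        a, b = self.subject_start, self.subject_end
        return (a, b) if a <= b else (b, a)

    @property
    def minus_strand(self) -> bool:
        return self.subject_start > self.subject_end


@dataclass
class HSPSet:
    """All HSPs of one subject sequence against the query element."""

    subject_id: str
    species: str
    hsps: list[HSP]
    query_length: int

    def __post_init__(self) -> None:
        if self.query_length <= 0:
            raise ValueError("query_length must be positive")
        for h in self.hsps:
            if h.subject_id != self.subject_id:
                raise ValueError(
                    f"HSP subject {h.subject_id!r} does not match set {self.subject_id!r}"
                )


@dataclass
class TECopy:
    """One retained TE copy: accession, match range on the subject, species,
    taxonomy ranks, geographic region and (optionally) sequence."""

    accession: str
    match_range: tuple[int, int]
    species: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    region: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        s, e = self.match_range
        if s > e:
            self.match_range = (e, s)
        if self.sequence:
            s, e = self.match_range
            if len(self.sequence) != e - s + 1:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != range span {e - s + 1}"
                )


def parse_blast_tab(path) -> list[HSP]:
    """Parse a 12-column tabular homology-search file into HSP records.

    Columns (outfmt-6 order): qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore. Extra trailing columns are
    ignored; rows with fewer than 12 fields raise BlastTabError naming the
    line. Empty files yield an empty list.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastTabError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                hsps.append(
                    HSP(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        query_start=int(fields[6]),
                        query_end=int(fields[7]),
                        subject_start=int(fields[8]),
                        subject_end=int(fields[9]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise BlastTabError(f"{path}: line {lineno}: {exc}") from exc
    return hsps


def group_by_subject(
    hsps: Iterable[HSP],
    query_length: int,
    species: Mapping[str, str] | None = None,
) -> list[HSPSet]:
    """Group HSPs into one HSPSet per subject id, preserving first-seen order.

    ``species`` maps subject id to species name; unmapped subjects get "".
    """
    by_subject: dict[str, list[HSP]] = {}
    for h in hsps:
        by_subject.setdefault(h.subject_id, []).append(h)
    species = species or {}
    return [
        HSPSet(subject_id=sid, species=species.get(sid, ""), hsps=lst,
               query_length=query_length)
        for sid, lst in by_subject.items()
    ]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals into a disjoint sorted union."""
    ivs = sorted((min(a, b), max(a, b)) for a, b in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def query_coverage(hsp_set: HSPSet) -> tuple[int, float]:
    """Base pairs of the query covered by the union of the set's HSP query
    intervals, and the covered fraction of the query length."""
    if not hsp_set.hsps:
        raise ValueError(f"HSPSet {hsp_set.subject_id!r} has no HSPs")
    for h in hsp_set.hsps:
        if h.query_end > hsp_set.query_length:
            raise ValueError(
                f"HSP query interval [{h.query_start}, {h.query_end}] exceeds "
                f"query length {hsp_set.query_length}"
            )
    covered = sum(e - s + 1 for s, e in
                  merge_intervals((h.query_start, h.query_end) for h in hsp_set.hsps))
    return covered, covered / hsp_set.query_length


def coverage_threshold_bp(query_length: int, min_fraction: float) -> int:
    """Minimum covered base pairs implied by a fractional coverage floor:
    floor(query_length * min_fraction). For the 5,294 bp query at 0.70 this
    is 3,705 bp."""
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    return int(query_length * min_fraction)


def select_hits(
    hsp_sets: Sequence[HSPSet],
    min_identity_pct: float = 80.0,
    min_cover_fraction: float = 0.70,
) -> list[HSPSet]:
    """Retain subjects whose HSPs all exceed the identity floor and whose
    stitched query coverage strictly exceeds the coverage floor.

    HSPs at or below the identity floor are discarded before coverage is
    stitched; comparisons are strict (> not >=). Input order is preserved and
    the operation is idempotent.
    """
    retained: list[HSPSet] = []
    for hs in hsp_sets:
        good = [h for h in hs.hsps if h.pct_identity > min_identity_pct]
        if not good:
            continue
        candidate = HSPSet(hs.subject_id, hs.species, good, hs.query_length)
        _, frac = query_coverage(candidate)
        if frac > min_cover_fraction:
            retained.append(candidate)
    return retained


def copies_from_hits(
    hsp_sets: Sequence[HSPSet],
    subject_sequences: Mapping[str, str] | None = None,
    taxonomy: Mapping[str, dict[str, str]] | None = None,
    regions: Mapping[str, str] | None = None,
) -> list[TECopy]:
    """Turn retained HSP sets into TE copies.

    Strand-normalized subject intervals of one subject are clustered: ranges
    closer than the query length merge into one copy (one locus hit in
    pieces); clusters separated by more than the query length become separate
    copies (distinct insertions on the same scaffold). Sequence is sliced
    from ``subject_sequences`` when provided.
    """
    taxonomy = taxonomy or {}
    regions = regions or {}
    copies: list[TECopy] = []
    for hs in hsp_sets:
        ranges = sorted(h.subject_range for h in hs.hsps)
        clusters: list[tuple[int, int]] = []
        for s, e in ranges:
            if clusters and s - clusters[-1][1] <= hs.query_length:
                clusters[-1] = (clusters[-1][0], max(clusters[-1][1], e))
            else:
                clusters.append((s, e))
        for s, e in clusters:
            seq = ""
            if subject_sequences is not None and hs.subject_id in subject_sequences:
                seq = subject_sequences[hs.subject_id][s - 1 : e]
            copies.append(
                TECopy(
                    accession=hs.subject_id,
                    match_range=(s, e),
                    species=hs.species,
                    taxonomy=dict(taxonomy.get(hs.species, {})),
                    region=regions.get(hs.species, ""),
                    sequence=seq,
                )
            )
    return copies


def rename_record(copy: TECopy) -> str:
    """Canonical description of a retained copy: ``ACC:start-end Species_name``
    with the strand-normalized range and spaces in the species underscored."""
    if not copy.species:
        raise ValueError(f"copy {copy.accession!r} has no species")
    s, e = copy.match_range
    return f"{copy.accession}:{s}-{e} {copy.species.replace(' ', '_')}"


_RECORD_RE = re.compile(r"^(?P<acc>\S+):(?P<start>\d+)-(?P<end>\d+)\s+(?P<sp>\S+)$")


def parse_record_name(text: str) -> tuple[str, tuple[int, int], str]:
    """Inverse of rename_record: (accession, (start, end), species)."""
    m = _RECORD_RE.match(text.strip())
    if m is None:
        raise ValueError(f"unparsable record description: {text!r}")
    return (
        m.group("acc"),
        (int(m.group("start")), int(m.group("end"))),
        m.group("sp").replace("_", " "),
    )


def write_retained_fasta(copies: Sequence[TECopy], path) -> None:
    """Write retained copies as FASTA with renamed descriptions."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=rename_record(c).split()[0],
                  description=rename_record(c))
        for c in copies
    ]
    seqio_write(records, str(path), "fasta")


def write_manifest(
    hsp_sets: Sequence[HSPSet],
    path,
    min_identity_pct: float = 80.0,
) -> None:
    """TSV manifest of retained subjects: accession, range, species, coverage."""
    with open(path, "w") as fh:
        fh.write("accession\trange\tspecies\tcoverage_bp\tcoverage_fraction\tmin_identity\n")
        for hs in hsp_sets:
            bp, frac = query_coverage(hs)
            ranges = merge_intervals(h.subject_range for h in hs.hsps)
            rng = ";".join(f"{s}-{e}" for s, e in ranges)
            min_id = min(h.pct_identity for h in hs.hsps)
            fh.write(
                f"{hs.subject_id}\t{rng}\t{hs.species}\t{bp}\t{frac:.4f}\t{min_id:.2f}\n"
            )
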