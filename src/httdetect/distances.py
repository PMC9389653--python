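"""Pairwise nucleotide divergence and neutral divergence-time estimation.

K is the uncorrected proportion of differing sites (p-distance) under
pairwise deletion: a site enters one pair's comparison only when both rows
carry an unambiguous A/C/G/T there. Divergence time follows the neutral
molecular clock T = K / (2 r), with r the per-site per-generation
substitution rate (equal to the mutation rate under neutrality; default
3.0e-9 for insects) and an assumed number of generations per year
(default 1, a conservative floor for most insect taxa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_RATE",
    "AlignedMatrix",
    "DivergenceEstimate",
    "UndefinedDistanceError",
    "read_alignment",
    "p_distance",
    "pairwise_matrix",
    "group_mean_distance",
    "divergence_time",
    "identity_to_time",
    "jukes_cantor_correct",
]

#: per-site per-generation neutral substitution rate for insects
DEFAULT_RATE = 3.0e-9

_VALID = frozenset(b"ACGT")


class UndefinedDistanceError(ValueError):
    """Raised when two rows share no comparable (ungapped, unambiguous) site."""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@dataclass
class AlignedMatrix:
    """A gapped nucleotide alignment: unique ids and equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self._mat = (
            np.vstack([_encode(r) for r in self.rows])
            if self.rows
            else np.empty((0, 0), dtype=np.uint8)
        )
        valid_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        self._valid = np.isin(self._mat, valid_codes)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self._mat.shape[1]


def read_alignment(path) -> AlignedMatrix:
    """Read an aligned FASTA into an AlignedMatrix."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    return AlignedMatrix(ids, rows)


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing sites between two gapped rows under pairwise
    deletion. Gaps, N and IUPAC ambiguity codes are treated as missing.

    Raises UndefinedDistanceError when no site is comparable.
    """
    a, b = _encode(row_i), _encode(row_j)
    if a.shape != b.shape:
        raise ValueError("rows have unequal lengths")
    valid_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    mask = np.isin(a, valid_codes) & np.isin(b, valid_codes)
    compared = int(mask.sum())
    if compared == 0:
        raise UndefinedDistanceError("no comparable sites between rows")
    return float((a[mask] != b[mask]).sum()) / compared


def pairwise_matrix(aln: AlignedMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise p-distances; undefined cells are NaN."""
    n = len(aln)
    if n < 2:
        raise ValueError("need >= 2 rows for a distance matrix")
    mat, valid = aln._mat, aln._valid
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            compared = int(mask.sum())
            if compared == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                d = float((mat[i, mask] != mat[j, mask]).sum()) / compared
                out[i, j] = out[j, i] = d
    return out


def group_mean_distance(aln: AlignedMatrix, groups: Mapping[str, str]) -> pd.DataFrame:
    """Average base differences per site between (and within) groups.

    Off-diagonal cells average all cross-group pairwise K; diagonal cells
    average within-group pairs (0.0 for singleton groups). Every alignment id
    must be labeled and no group may be empty.
    """
    missing = [i for i in aln.ids if i not in groups]
    if missing:
        raise KeyError(f"unlabeled alignment ids: {missing}")
    labels = sorted(set(groups[i] for i in aln.ids))
    members = {lab: [k for k, i in enumerate(aln.ids) if groups[i] == lab]
               for lab in labels}
    dm = pairwise_matrix(aln)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for ai, la in enumerate(labels):
        for lb in labels[ai:]:
            if la == lb:
                idx = members[la]
                vals = [dm[i, j] for x, i in enumerate(idx) for j in idx[x + 1:]]
            else:
                vals = [dm[i, j] for i in members[la] for j in members[lb]]
            mean = float(np.nanmean(vals)) if vals else 0.0
            out.loc[la, lb] = out.loc[lb, la] = mean
    return out


@dataclass(frozen=True)
class DivergenceEstimate:
    """Neutral-clock divergence time derived from K via T = K / (2 r)."""

    K: float
    r: float
    generations_per_year: float
    T_generations: float
    T_years: float


def divergence_time(
    K: float,
    r: float = DEFAULT_RATE,
    generations_per_year: float = 1.0,
) -> DivergenceEstimate:
    """Time since divergence of two neutrally evolving sequences separated by
    K substitutions per site: T = K / (2 r) generations."""
    if K < 0:
        raise ValueError("K must be non-negative")
    if r <= 0 or generations_per_year <= 0:
        raise ValueError("r and generations_per_year must be positive")
    t_gen = K / (2.0 * r)
    return DivergenceEstimate(
        K=K,
        r=r,
        generations_per_year=generations_per_year,
        T_generations=t_gen,
        T_years=t_gen / generations_per_year,
    )


def identity_to_time(
    min_identity_fraction: float,
    r: float = DEFAULT_RATE,
    generations_per_year: float = 1.0,
) -> float:
    """Divergence time in years implied by a nucleotide-identity floor,
    taking K = 1 - identity (e.g. identity 0.80 -> ~33.3 million years)."""
    if not (0.0 < min_identity_fraction <= 1.0):
        raise ValueError("identity must lie in (0, 1]")
    return divergence_time(1.0 - min_identity_fraction, r, generations_per_year).T_years


def jukes_cantor_correct(p: float) -> float:
    """Optional multiple-hit correction d = -3/4 ln(1 - 4p/3); off by default
    everywhere since the clock arithmetic here uses uncorrected K."""
    if not (0.0 <= p < 0.75):
        raise ValueError("p must lie in [0, 0.75) for the correction")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def write_distance_tsv(dm: np.ndarray, ids: Sequence[str], path) -> None:
    pd.DataFrame(dm, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")
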