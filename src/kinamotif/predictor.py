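"""Dot-product kinase ranking for a query phosphopeptide.

A query 13-mer is encoded as a Boolean 13x20 matrix x (one 1 per
non-placeholder position, at the query's residue).  Each kinase k gets
the scalar

    M = sum_{i,j} x(i,j) * P_j^k

where P^k is the kinase's dense information-height matrix — i.e. the sum
over positions of the letter height at the query's residue, in bits.
Kinases are ranked by descending score, restricted by default to the
class (S/T vs Y) matching the query's phosphoacceptor.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np

from ._alphabet import AA_INDEX, HALF_WINDOW, N_AA, PAD, WINDOW
from .exceptions import KinamotifError, NoEligibleKinasesError
from .motif import KinaseProfile
from .seqio import CenteredPeptide


@dataclass
class OneHotMatrix:
    """Boolean 13x20 encoding of a query peptide (x(i,j) of the score)."""

    x: np.ndarray  # (13, 20) bool

    @property
    def n_ones(self) -> int:
        return int(self.x.sum())


@dataclass(frozen=True)
class PredictionRow:
    rank: int
    kinase: str
    score: float
    kinase_class: str
    n: int


@dataclass
class PredictionResult:
    """Rank-ordered kinases for one query peptide."""

    query: CenteredPeptide
    rows: list[PredictionRow]
    restricted_class: str  # "ST" | "Y" | "all"

    def top(self, k: int = 10) -> list[PredictionRow]:
        return self.rows[:k]

    def rank_of(self, kinase: str) -> int:
        """1-based rank of a kinase; raises KeyError if absent."""
        for row in self.rows:
            if row.kinase == kinase:
                return row.rank
        raise KeyError(kinase)


def encode_onehot(peptide: CenteredPeptide | str) -> OneHotMatrix:
    """Encode a centered 13-mer as a Boolean position-by-residue matrix.

    Placeholder (J) positions get an all-zero row, so windows that
    overhang a protein terminus simply contribute nothing to scores.
    """
    if not isinstance(peptide, CenteredPeptide):
        peptide = CenteredPeptide(peptide)
    x = np.zeros((WINDOW, N_AA), dtype=bool)
    for row, ch in enumerate(peptide.residues):
        if ch != PAD:
            x[row, AA_INDEX[ch]] = True
    return OneHotMatrix(x=x)


def score_kinase(x: OneHotMatrix, profile: KinaseProfile) -> float:
    """The dot product sum_{i,j} x(i,j) * h_k(i,j), in bits."""
    h = profile.information.heights
    if x.x.shape != h.shape:
        raise KinamotifError(
            f"dimension mismatch: query {x.x.shape} vs profile {h.shape}"
        )
    # accumulate position by position (<= 1 hit per row) so the result is
    # bitwise identical to a plain double loop over the 13x20 cells
    total = 0.0
    for row in range(WINDOW):
        hits = np.nonzero(x.x[row])[0]
        if hits.size:
            total += float(h[row, hits[0]])
    return total


def rank_kinases(
    peptide: CenteredPeptide | str,
    profiles: list[KinaseProfile],
    restrict: str = "auto",
) -> PredictionResult:
    """Score a query against every profile and return the ranked list.

    ``restrict="auto"`` (default) scores only profiles whose class
    matches the query's center residue (S/T center -> "ST" kinases,
    Y center -> "Y" kinases); ``restrict="all"`` scores everything.
    Ties are broken lexicographically by kinase name; ranks are dense
    1..K.
    """
    if not isinstance(peptide, CenteredPeptide):
        peptide = CenteredPeptide(peptide)
    if not profiles:
        raise KinamotifError("rank_kinases requires at least one profile")
    if restrict not in ("auto", "all"):
        raise KinamotifError(f"restrict must be 'auto' or 'all', got {restrict!r}")
    if restrict == "auto":
        query_class = "Y" if peptide.center == "Y" else "ST"
        eligible = [p for p in profiles if p.kinase_class == query_class]
        if not eligible:
            raise NoEligibleKinasesError(
                f"no {query_class}-class kinase profiles available for a "
                f"query centered on {peptide.center!r}"
            )
        restricted = query_class
    else:
        eligible = list(profiles)
        restricted = "all"
    x = encode_onehot(peptide)
    scored = sorted(
        ((score_kinase(x, p), p) for p in eligible),
        key=lambda t: (-t[0], t[1].kinase),
    )
    rows = [
        PredictionRow(rank=i + 1, kinase=p.kinase, score=s,
                      kinase_class=p.kinase_class, n=p.n)
        for i, (s, p) in enumerate(scored)
    ]
    return PredictionResult(query=peptide, rows=rows, restricted_class=restricted)


def export_csv(result: PredictionResult, path: str | os.PathLike) -> None:
    """Write the ranked list as CSV: rank,kinase,class,n,score.

    Scores are rendered with 6 significant digits; names containing
    delimiters are quoted per CSV convention.
    """
    if not result.rows:
        raise KinamotifError("cannot export an empty prediction result")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "kinase", "class", "n", "score"])
        for row in result.rows:
            writer.writerow(
                [row.rank, row.kinase, row.kinase_class, row.n, f"{row.score:.6g}"]
            )
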