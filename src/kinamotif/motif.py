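"""Position-specific probability, information, and logo models per kinase.

Given a kinase's set of centered 13-mer peptides, this module tallies a
count matrix, converts it to per-position residue probabilities, and
summarizes each position by its Shannon information content

    R(j) = log2(20) - H(j),    H(j) = -sum_i p(i,j) log2 p(i,j),

in bits: 0 for a uniform position, log2(20) ~ 4.32 for an invariant one.
Letter heights h(i,j) = p(i,j) * R(j) form the dense information matrix
used both for logo display and as the scoring matrix P_j^k of the kinase
predictor.

Logos and anti-logos are the chi-square-filtered views of that matrix:
each (position, residue) cell is tested against a background residue
distribution with a 1-df dichotomous goodness-of-fit test, and only
cells significant at a raw alpha (default 1e-4, no multiple-testing
correction) enter the displayed logo (enriched) or anti-logo (depleted).

``J`` placeholders from windows that overhang a protein terminus reduce
the effective count at their position; they are never treated as a 21st
residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    CENTER_ROW,
    HALF_WINDOW,
    N_AA,
    PAD,
    WINDOW,
    row_to_offset,
)
from .exceptions import KinamotifError, TooFewPeptidesError
from .seqio import CenteredPeptide

MAX_BITS = math.log2(N_AA)

#: minimum peptides per kinase for a trustworthy profile
DEFAULT_MIN_N = 30
#: raw per-cell significance level for logo filtering
DEFAULT_ALPHA = 1e-4
#: floor applied to background probabilities so chi-square expectations
#: are never zero
BACKGROUND_FLOOR = 1e-6

_COLSUM_TOL = 1e-6


@dataclass
class CountMatrix:
    """Residue tallies per window position.

    ``counts[row, i]`` is the number of peptides with amino acid ``i`` at
    the offset mapped to ``row``; ``j_counts[row]`` counts J placeholders
    there, so counts.sum(axis=1) + j_counts == n at every position.
    """

    counts: np.ndarray  # (13, 20) int64
    j_counts: np.ndarray  # (13,) int64
    n: int

    @property
    def effective_n(self) -> np.ndarray:
        """Non-placeholder observations per position: n - j_counts."""
        return self.n - self.j_counts


@dataclass(frozen=True)
class Background:
    """Reference residue distribution for information and chi-square tests."""

    b: np.ndarray  # (20,) float64, sums to 1, all > 0

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "b", b)
        if b.shape != (N_AA,):
            raise KinamotifError(f"background must have {N_AA} entries")
        if not np.all(b > 0):
            raise KinamotifError("background probabilities must all be positive")
        if abs(b.sum() - 1.0) > 1e-9:
            raise KinamotifError("background probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(N_AA, 1.0 / N_AA))


@dataclass
class ProbabilityMatrix:
    """Per-position residue probabilities with J-adjusted denominators.

    Positions observed only as J (``effective_n == 0``) carry an
    all-zero column flagged unusable rather than a uniform one.
    """

    p: np.ndarray  # (13, 20) float64
    effective_n: np.ndarray  # (13,) int64
    usable: np.ndarray  # (13,) bool


@dataclass
class InformationMatrix:
    """Per-position information content R (bits) and letter heights p*R."""

    R: np.ndarray  # (13,)
    heights: np.ndarray  # (13, 20)


@dataclass(frozen=True)
class LogoCell:
    """One chi-square-significant (offset, residue) cell of a logo."""

    offset: int
    residue: str
    height: float
    p_value: float
    direction: str  # "enriched" | "depleted"


@dataclass
class LogoModel:
    """Chi-square-filtered favored (logo) and disfavored (anti-logo) cells."""

    logo: list[LogoCell] = field(default_factory=list)
    antilogo: list[LogoCell] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    def logo_cells(self) -> set[tuple[int, str]]:
        return {(c.offset, c.residue) for c in self.logo}

    def antilogo_cells(self) -> set[tuple[int, str]]:
        return {(c.offset, c.residue) for c in self.antilogo}


@dataclass
class KinaseProfile:
    """Everything fitted for one kinase from its peptide set."""

    kinase: str
    n: int
    kinase_class: str  # "ST" | "Y"
    counts: CountMatrix
    probabilities: ProbabilityMatrix
    information: InformationMatrix
    logo: LogoModel

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def cells(cs: list[LogoCell]) -> list[list]:
            return [[c.offset, c.residue, c.height, c.p_value, c.direction] for c in cs]

        return {
            "kinase": self.kinase,
            "n": self.n,
            "class": self.kinase_class,
            "counts": self.counts.counts.tolist(),
            "j_counts": self.counts.j_counts.tolist(),
            "probability_matrix": self.probabilities.p.tolist(),
            "position_information": self.information.R.tolist(),
            "information_matrix": self.information.heights.tolist(),
            "alpha": self.logo.alpha,
            "logo": cells(self.logo.logo),
            "antilogo": cells(self.logo.antilogo),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KinaseProfile":
        from .exceptions import ProfileStoreError

        try:
            counts = CountMatrix(
                counts=np.asarray(d["counts"], dtype=np.int64),
                j_counts=np.asarray(d["j_counts"], dtype=np.int64),
                n=int(d["n"]),
            )
            eff = counts.effective_n
            prob = ProbabilityMatrix(
                p=np.asarray(d["probability_matrix"], dtype=float),
                effective_n=eff,
                usable=eff > 0,
            )
            info = InformationMatrix(
                R=np.asarray(d["position_information"], dtype=float),
                heights=np.asarray(d["information_matrix"], dtype=float),
            )
            logo = LogoModel(
                logo=[LogoCell(int(o), r, float(h), float(p), dr)
                      for o, r, h, p, dr in d["logo"]],
                antilogo=[LogoCell(int(o), r, float(h), float(p), dr)
                          for o, r, h, p, dr in d["antilogo"]],
                alpha=float(d["alpha"]),
            )
            return cls(
                kinase=d["kinase"],
                n=int(d["n"]),
                kinase_class=d["class"],
                counts=counts,
                probabilities=prob,
                information=info,
                logo=logo,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ProfileStoreError(f"malformed profile record: {exc}") from exc


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def count_matrix(peptides: list[CenteredPeptide]) -> CountMatrix:
    """Tally residues per position over a peptide set.

    J placeholders are counted separately per position, never as one of
    the 20 residues.
    """
    if not peptides:
        raise KinamotifError("count_matrix requires at least one peptide")
    counts = np.zeros((WINDOW, N_AA), dtype=np.int64)
    j_counts = np.zeros(WINDOW, dtype=np.int64)
    for pep in peptides:
        for row, ch in enumerate(pep.residues):
            if ch == PAD:
                j_counts[row] += 1
            else:
                counts[row, AA_INDEX[ch]] += 1
    return CountMatrix(counts=counts, j_counts=j_counts, n=len(peptides))


def background_from_dataset(all_peptides: list[CenteredPeptide]) -> Background:
    """Dataset-wide residue frequencies over all flank positions.

    Pools every peptide of every kinase, excluding the phosphoacceptor
    position (offset 0) and J placeholders; frequencies are floored at
    ``BACKGROUND_FLOOR`` and renormalized so chi-square expectations are
    never zero.
    """
    tot = np.zeros(N_AA, dtype=np.int64)
    for pep in all_peptides:
        for row, ch in enumerate(pep.residues):
            if row == CENTER_ROW or ch == PAD:
                continue
            tot[AA_INDEX[ch]] += 1
    if tot.sum() == 0:
        raise KinamotifError("no usable flank residues to build a background from")
    b = tot / tot.sum()
    b = np.maximum(b, BACKGROUND_FLOOR)
    return Background(b / b.sum())


def probability_matrix(
    counts: CountMatrix, pseudocount: float = 0.0
) -> ProbabilityMatrix:
    """Per-position probabilities p(i,j) = (c + pc) / (effective_n + 20 pc)."""
    if pseudocount < 0:
        raise KinamotifError("pseudocount must be >= 0")
    eff = counts.effective_n
    usable = eff > 0
    p = np.zeros((WINDOW, N_AA), dtype=float)
    denom = eff.astype(float) + N_AA * pseudocount
    rows = np.nonzero(usable)[0]
    p[rows] = (counts.counts[rows] + pseudocount) / denom[rows, None]
    return ProbabilityMatrix(p=p, effective_n=eff.copy(), usable=usable)


def position_information(p_column: np.ndarray) -> float:
    """Shannon information content R = log2(20) - H of one position, in bits.

    An all-zero (unusable) column returns 0.  The convention
    0 * log2(0) = 0 applies.
    """
    p = np.asarray(p_column, dtype=float)
    if p.shape != (N_AA,):
        raise KinamotifError(f"probability column must have {N_AA} entries")
    s = p.sum()
    if s == 0:
        return 0.0
    if abs(s - 1.0) > _COLSUM_TOL:
        raise KinamotifError(f"probability column sums to {s}, expected 1")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return MAX_BITS - entropy


def information_matrix(prob: ProbabilityMatrix) -> InformationMatrix:
    """Dense letter-height matrix h(i,j) = p(i,j) * R(j) over all 13 positions."""
    R = np.array([position_information(prob.p[row]) for row in range(WINDOW)])
    heights = prob.p * R[:, None]
    return InformationMatrix(R=R, heights=heights)


def chisq_cell(
    observed: int, effective_n: int, b_i: float
) -> tuple[float, float, str]:
    """1-df dichotomous goodness-of-fit of one (position, residue) cell.

    Tests observed occurrences of residue i against the background
    expectation e = effective_n * b_i over the dichotomy
    {residue i, not residue i}; no continuity correction.

    Returns (statistic, p_value, direction) with direction "enriched"
    if observed > e, "depleted" if observed < e, "none" if equal.
    """
    if effective_n < 1:
        raise KinamotifError("effective_n must be >= 1")
    if not 0 < b_i < 1:
        raise KinamotifError("background probability must lie strictly in (0, 1)")
    if observed > effective_n:
        raise KinamotifError(
            f"observed count {observed} exceeds effective_n {effective_n}"
        )
    e = effective_n * b_i
    stat = (observed - e) ** 2 / e + (observed - e) ** 2 / (effective_n - e)
    p = float(stats.chi2.sf(stat, df=1))
    if observed > e:
        direction = "enriched"
    elif observed < e:
        direction = "depleted"
    else:
        direction = "none"
    return float(stat), p, direction


def _deficit_information(observed: np.ndarray, expected: np.ndarray) -> float:
    """Information content of the normalized deficit column (e - o)+.

    Used to scale anti-logo letter heights: a position whose depletion
    is concentrated on few residues scores higher than one with diffuse
    deficits.
    """
    deficit = np.maximum(expected - observed, 0.0)
    tot = deficit.sum()
    if tot <= 0:
        return 0.0
    return position_information(deficit / tot)


def build_logo(
    counts: CountMatrix, background: Background, alpha: float = DEFAULT_ALPHA
) -> LogoModel:
    """Chi-square filter every flank cell into logo / anti-logo sets.

    Cells at the phosphoacceptor position (offset 0) are excluded.
    Enriched significant cells get height h(i,j) = p(i,j) * R(j);
    depleted ones get depletion height
    d(i,j) = ((e - o) / effective_n) * R_dep(j), with R_dep the
    information content of the position's normalized deficit column.
    """
    if not 0 < alpha < 1:
        raise KinamotifError(f"alpha must lie in (0, 1), got {alpha}")
    prob = probability_matrix(counts, pseudocount=0.0)
    info = information_matrix(prob)
    model = LogoModel(alpha=alpha)
    for row in range(WINDOW):
        if row == CENTER_ROW:
            continue
        eff = int(counts.effective_n[row])
        if eff < 1:
            continue
        expected = eff * background.b
        r_dep = _deficit_information(counts.counts[row].astype(float), expected)
        for i, aa in enumerate(AMINO_ACIDS):
            obs = int(counts.counts[row, i])
            stat, p, direction = chisq_cell(obs, eff, float(background.b[i]))
            if p >= alpha or direction == "none":
                continue
            offset = row_to_offset(row)
            if direction == "enriched":
                model.logo.append(
                    LogoCell(offset, aa, float(info.heights[row, i]), p, direction)
                )
            else:
                d = (expected[i] - obs) / eff * r_dep
                model.antilogo.append(LogoCell(offset, aa, float(d), p, direction))
    return model


def kinase_class(peptides: list[CenteredPeptide]) -> str:
    """"Y" if strictly more than half of center residues are tyrosine,
    else "ST" (ties go to the majority class of the kinome)."""
    if not peptides:
        raise KinamotifError("kinase_class requires at least one peptide")
    n_y = sum(1 for p in peptides if p.center == "Y")
    return "Y" if n_y * 2 > len(peptides) else "ST"


def build_profile(
    kinase: str,
    peptides: list[CenteredPeptide],
    background: Background | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = DEFAULT_MIN_N,
    pseudocount: float = 0.0,
) -> KinaseProfile:
    """Fit the full profile for one kinase.

    The information (heights) matrix is UNFILTERED and includes the
    phosphoacceptor column — it is the scoring matrix of the predictor.
    Chi-square filtering affects only the displayed logo model.  When no
    background is supplied, it is derived from this kinase's own
    peptides (pipelines normally pass the pooled dataset background).
    """
    if len(peptides) < min_n:
        raise TooFewPeptidesError(kinase, len(peptides), min_n)
    if background is None:
        background = background_from_dataset(peptides)
    counts = count_matrix(peptides)
    prob = probability_matrix(counts, pseudocount=pseudocount)
    info = information_matrix(prob)
    logo = build_logo(counts, background, alpha=alpha)
    return KinaseProfile(
        kinase=kinase,
        n=len(peptides),
        kinase_class=kinase_class(peptides),
        counts=counts,
        probabilities=prob,
        information=info,
        logo=logo,
    )
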