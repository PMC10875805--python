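"""Synthetic kinase-like peptide sets from parameterized PWMs.

Stands in for recombinant-kinase substrate pools: each generator PWM
plants a classical specificity archetype (basic residues upstream for
PKA-like kinases, proline at +1 for CDK/MAPK-like, acidic residues
downstream for CK2-like, acidic flanks around a tyrosine acceptor for
EGFR-like) into an otherwise uniform residue background, and peptides
are drawn position-independently from its columns.

:func:`make_benchmark` additionally splices each sampled peptide into a
random host protein and emits the exact FASTA/TSV dialects ``seqio``
reads, so the whole site-table -> centralize -> profile -> rank pipeline
can be exercised end-to-end with a known ground truth, including the
J-padding paths near protein termini.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    CENTER_ROW,
    HALF_WINDOW,
    N_AA,
    PAD,
    WINDOW,
    offset_to_row,
)
from .exceptions import KinamotifError
from .seqio import CenteredPeptide, PhosphositeRow, ProteinRecord

PRESET_NAMES = ("basophilic", "proline_directed", "acidophilic", "tyrosine_acidic")

#: host-protein length used by make_benchmark
HOST_LENGTH = 50


@dataclass
class GeneratorPWM:
    """Sampling distribution for synthetic peptides of one kinase."""

    name: str
    probs: np.ndarray  # (13, 20), columns sum to 1
    center_class: str  # "ST" | "Y"

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (WINDOW, N_AA):
            raise KinamotifError(f"PWM must be {WINDOW}x{N_AA}")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise KinamotifError("every PWM position must sum to 1")
        center = probs[CENTER_ROW]
        allowed = {"ST": {"S", "T"}, "Y": {"Y"}}[self.center_class]
        mass = sum(center[AA_INDEX[a]] for a in allowed)
        if abs(mass - 1.0) > 1e-9:
            raise KinamotifError(
                f"center position mass must be confined to {sorted(allowed)}"
            )
        object.__setattr__(self, "probs", probs)

    def consensus(self) -> CenteredPeptide:
        """Most probable residue at each position."""
        chars = [AMINO_ACIDS[int(np.argmax(self.probs[row]))] for row in range(WINDOW)]
        return CenteredPeptide("".join(chars))


def _uniform_pwm(center_class: str) -> np.ndarray:
    probs = np.full((WINDOW, N_AA), 1.0 / N_AA)
    center = np.zeros(N_AA)
    if center_class == "ST":
        center[AA_INDEX["S"]] = center[AA_INDEX["T"]] = 0.5
    else:
        center[AA_INDEX["Y"]] = 1.0
    probs[CENTER_ROW] = center
    return probs


def _plant(probs: np.ndarray, offset: int, residues: str, sharpness: float) -> None:
    """Put `sharpness` mass on `residues` (split evenly) at one offset,
    spreading the remainder uniformly over all 20."""
    row = offset_to_row(offset)
    col = np.full(N_AA, (1.0 - sharpness) / N_AA)
    for aa in residues:
        col[AA_INDEX[aa]] += sharpness / len(residues)
    probs[row] = col


#: the (offset, residues) signal cells each preset plants
PRESET_SIGNALS: dict[str, list[tuple[int, str]]] = {
    "basophilic": [(-3, "RK"), (-2, "RK")],
    "proline_directed": [(+1, "P")],
    "acidophilic": [(+1, "DE"), (+3, "DE")],
    "tyrosine_acidic": [(o, "DE") for o in (-3, -2, -1, +1, +2, +3)],
}


def preset_pwm(name: str, sharpness: float = 0.9) -> GeneratorPWM:
    """A classical kinase-specificity archetype as a generator PWM.

    ``sharpness`` in (0, 1] is the probability mass planted on the
    signal residues at each signal position (split evenly among them);
    the remainder is uniform over the 20 amino acids.
    """
    if name not in PRESET_NAMES:
        raise KinamotifError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        )
    if not 0 < sharpness <= 1:
        raise KinamotifError(f"sharpness must lie in (0, 1], got {sharpness}")
    center_class = "Y" if name == "tyrosine_acidic" else "ST"
    probs = _uniform_pwm(center_class)
    for offset, residues in PRESET_SIGNALS[name]:
        _plant(probs, offset, residues, sharpness)
    return GeneratorPWM(name=name, probs=probs, center_class=center_class)


def random_pwm(
    name: str,
    rng: np.random.Generator,
    sharpness: float = 0.9,
    n_signal: int = 3,
    center_class: str = "ST",
) -> GeneratorPWM:
    """A PWM with `n_signal` random flank positions each dominated by one
    random residue with probability `sharpness`; uniform elsewhere."""
    if not 0 < sharpness <= 1:
        raise KinamotifError(f"sharpness must lie in (0, 1], got {sharpness}")
    probs = _uniform_pwm(center_class)
    flanks = [o for o in range(-HALF_WINDOW, HALF_WINDOW + 1) if o != 0]
    offsets = rng.choice(flanks, size=n_signal, replace=False)
    for offset in offsets:
        residue = AMINO_ACIDS[int(rng.integers(N_AA))]
        _plant(probs, int(offset), residue, sharpness)
    return GeneratorPWM(name=name, probs=probs, center_class=center_class)


def sample_peptides(
    pwm: GeneratorPWM, n: int, seed: int | np.random.Generator
) -> list[CenteredPeptide]:
    """Draw n peptides, one residue per position from the PWM columns.

    Reproducible for a fixed integer seed; outputs contain no J and a
    center residue from the PWM's acceptor class.
    """
    if n < 1:
        raise KinamotifError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # one multinomial draw per position, vectorized over peptides
    idx = np.empty((n, WINDOW), dtype=np.int64)
    for row in range(WINDOW):
        idx[:, row] = rng.choice(N_AA, size=n, p=pwm.probs[row])
    return [
        CenteredPeptide("".join(AMINO_ACIDS[i] for i in idx[k])) for k in range(n)
    ]


@dataclass
class Benchmark:
    """An end-to-end synthetic dataset with ground truth.

    ``truth`` maps substrate accession -> {kinase, position, peptide}
    where ``peptide`` is the expected centralized 13-mer (J-padded when
    the site sits within 6 residues of a host terminus).
    """

    rows: list[PhosphositeRow]
    records: list[ProteinRecord]
    truth: dict[str, dict]
    pwms: dict[str, GeneratorPWM]


def _default_pwms(k: int, rng: np.random.Generator, sharpness: float = 0.9
                  ) -> list[GeneratorPWM]:
    pwms = [preset_pwm(name, sharpness) for name in PRESET_NAMES[: min(k, 4)]]
    for i in range(len(pwms), k):
        pwms.append(random_pwm(f"KIN{i + 1:03d}", rng, sharpness=sharpness))
    return pwms


def make_benchmark(
    k: int,
    n_per_kinase: int,
    seed: int,
    out_dir: str | os.PathLike | None = None,
    sharpness: float = 0.9,
) -> Benchmark:
    """Simulate k kinases with n_per_kinase substrate sites each.

    Each sampled peptide is spliced into a fresh random host protein
    (i.i.d. uniform residues, length 50) at a random position.  The
    first two sites of every kinase are pinned near the N- and
    C-terminus so overhang J-padding is always exercised.  The expected
    centralized peptide (after truncation at the termini) is recorded in
    the truth map, so a round trip through ``seqio.build_substrate_sets``
    must recover every peptide exactly.

    With ``out_dir`` set, writes sites.tsv, substrates.fasta and
    truth.json in the dialects ``seqio`` reads.
    """
    if k < 2:
        raise KinamotifError(f"k must be >= 2, got {k}")
    if n_per_kinase < 1:
        raise KinamotifError(f"n_per_kinase must be >= 1, got {n_per_kinase}")
    rng = np.random.default_rng(seed)
    pwms = _default_pwms(k, rng, sharpness=sharpness)

    rows: list[PhosphositeRow] = []
    records: list[ProteinRecord] = []
    truth: dict[str, dict] = {}
    site_no = 0
    for pwm in pwms:
        peptides = sample_peptides(pwm, n_per_kinase, rng)
        for j, pep in enumerate(peptides):
            site_no += 1
            accession = f"SYN{site_no:06d}"
            if j == 0:
                position = int(rng.integers(1, HALF_WINDOW + 1))  # N-overhang
            elif j == 1:
                position = int(rng.integers(HOST_LENGTH - HALF_WINDOW + 1,
                                            HOST_LENGTH + 1))  # C-overhang
            else:
                position = int(rng.integers(1, HOST_LENGTH + 1))
            host = list(AMINO_ACIDS[i] for i in rng.integers(N_AA, size=HOST_LENGTH))
            expected = []
            for off in range(-HALF_WINDOW, HALF_WINDOW + 1):
                idx = position - 1 + off
                ch = pep[off]
                if 0 <= idx < HOST_LENGTH:
                    host[idx] = ch
                    expected.append(ch)
                else:
                    expected.append(PAD)
            records.append(ProteinRecord(accession, "".join(host)))
            rows.append(PhosphositeRow(kinase=pwm.name, accession=accession,
                                       position=position))
            truth[accession] = {
                "kinase": pwm.name,
                "position": position,
                "peptide": "".join(expected),
            }

    bench = Benchmark(rows=rows, records=records, truth=truth,
                      pwms={p.name: p for p in pwms})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "sites.tsv", "w") as fh:
            fh.write("kinase\taccession\tposition\n")
            for row in rows:
                fh.write(f"{row.kinase}\t{row.accession}\t{row.position}\n")
        with open(out / "substrates.fasta", "w") as fh:
            for rec in records:
                fh.write(f">{rec.accession}\n{rec.sequence}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return bench
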