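"""Model/Results facade over the profile-building and ranking pipeline.

``KinaseSpecificityModel`` holds the raw kinase -> peptide data plus the
fitting configuration; ``fit()`` estimates one profile per kinase
(count, probability and Shannon-information matrices and the
chi-square-filtered logo) and returns a ``KinaseSpecificityResults``
carrying the fitted profiles, the pooled background, diagnostics, a
``summary()`` table, and the ``predict()`` method that ranks kinases for
a query phosphopeptide.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import motif, predictor, seqio
from .exceptions import KinamotifError
from .motif import Background, KinaseProfile
from .predictor import PredictionResult
from .seqio import CenteredPeptide, PhosphositeRow, ProteinRecord, SubstrateSet


@dataclass
class KinaseSpecificityModel:
    """Per-kinase substrate-specificity model built from phosphosite data.

    Parameters
    ----------
    substrate_sets
        One peptide set per kinase (duplicates retained).
    alpha
        Raw per-cell chi-square significance level for logo filtering.
    min_n
        Minimum peptides required to fit a kinase profile; kinases below
        it are skipped and listed in the results' diagnostics.
    pseudocount
        Additive smoothing for probability matrices (default 0).
    background
        "dataset" (pooled flank frequencies over all kinases),
        "uniform", or an explicit :class:`~kinamotif.motif.Background`.
    """

    substrate_sets: list[SubstrateSet]
    alpha: float = motif.DEFAULT_ALPHA
    min_n: int = motif.DEFAULT_MIN_N
    pseudocount: float = 0.0
    background: str | Background = "dataset"
    skip_summary: dict[str, int] = field(default_factory=dict)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        site_table: str | os.PathLike,
        fasta: str | os.PathLike | None = None,
        **config,
    ) -> "KinaseSpecificityModel":
        """Build from a site table (TSV/CSV) and, unless the table carries
        pre-centralized peptides, a substrate FASTA."""
        rows = seqio.read_site_table(site_table)
        records = seqio.read_fasta(fasta) if fasta is not None else []
        return cls.from_rows(rows, records, **config)

    @classmethod
    def from_rows(
        cls,
        rows: list[PhosphositeRow],
        records: list[ProteinRecord] = (),
        **config,
    ) -> "KinaseSpecificityModel":
        sets, skips = seqio.build_substrate_sets(rows, records)
        return cls(substrate_sets=sets, skip_summary=skips, **config)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, records: list[ProteinRecord] = (), **config
    ) -> "KinaseSpecificityModel":
        """Build from a DataFrame with columns kinase/accession/position
        or kinase/peptide."""
        rows = []
        if {"kinase", "peptide"} <= set(df.columns):
            for rec in df.itertuples(index=False):
                rows.append(PhosphositeRow(kinase=rec.kinase,
                                           peptide=CenteredPeptide(rec.peptide)))
        elif {"kinase", "accession", "position"} <= set(df.columns):
            for rec in df.itertuples(index=False):
                rows.append(PhosphositeRow(kinase=rec.kinase,
                                           accession=rec.accession,
                                           position=int(rec.position)))
        else:
            raise KinamotifError(
                "DataFrame needs columns kinase/accession/position or "
                "kinase/peptide"
            )
        return cls.from_rows(rows, records, **config)

    # -- fitting -----------------------------------------------------------

    def _resolve_background(self) -> Background:
        if isinstance(self.background, Background):
            return self.background
        if self.background == "uniform":
            return Background.uniform()
        if self.background == "dataset":
            pooled = [p for s in self.substrate_sets for p in s.peptides]
            return motif.background_from_dataset(pooled)
        raise KinamotifError(
            f"background must be 'dataset', 'uniform' or a Background, "
            f"got {self.background!r}"
        )

    def fit(self) -> "KinaseSpecificityResults":
        """Fit one profile per kinase with at least ``min_n`` peptides."""
        if not self.substrate_sets:
            raise KinamotifError("no substrate sets to fit")
        bg = self._resolve_background()
        profiles: list[KinaseProfile] = []
        skipped: dict[str, int] = {}
        for s in self.substrate_sets:
            if len(s) < self.min_n:
                skipped[s.kinase] = len(s)
                continue
            profiles.append(
                motif.build_profile(
                    s.kinase, s.peptides, background=bg, alpha=self.alpha,
                    min_n=self.min_n, pseudocount=self.pseudocount,
                )
            )
        if not profiles:
            raise KinamotifError(
                f"no kinase reached the minimum of {self.min_n} peptides"
            )
        return KinaseSpecificityResults(
            model=self, profiles=profiles, background=bg,
            skipped_kinases=skipped,
        )


@dataclass
class KinaseSpecificityResults:
    """Fitted kinase profiles plus diagnostics and prediction."""

    model: KinaseSpecificityModel | None
    profiles: list[KinaseProfile]
    background: Background
    skipped_kinases: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, kinase: str) -> KinaseProfile:
        for p in self.profiles:
            if p.kinase == kinase:
                return p
        raise KeyError(kinase)

    @property
    def kinases(self) -> list[str]:
        return [p.kinase for p in self.profiles]

    def summary_frame(self) -> pd.DataFrame:
        """One row per fitted kinase: class, n, logo sizes, peak position."""
        rows = []
        for p in self.profiles:
            flank_R = [
                (off, float(p.information.R[row]))
                for row in range(13)
                if (off := row - 6) != 0
            ]
            peak_off, peak_R = max(flank_R, key=lambda t: t[1])
            rows.append({
                "kinase": p.kinase,
                "class": p.kinase_class,
                "n": p.n,
                "logo_cells": len(p.logo.logo),
                "antilogo_cells": len(p.logo.antilogo),
                "peak_offset": peak_off,
                "peak_bits": round(peak_R, 4),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        frame = self.summary_frame()
        header = (
            f"Kinase specificity fit: {len(self.profiles)} profiles"
            f" ({len(self.skipped_kinases)} kinases below min_n)"
        )
        return header + "\n" + frame.to_string(index=False)

    # -- prediction --------------------------------------------------------

    def predict(
        self, peptide: CenteredPeptide | str, restrict: str = "auto"
    ) -> PredictionResult:
        """Rank the fitted kinases for a query centered 13-mer."""
        return predictor.rank_kinases(peptide, self.profiles, restrict=restrict)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        seqio.write_profiles(self.profiles, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "KinaseSpecificityResults":
        """Reload saved profiles; the background is not stored, so
        prediction works but refitting diagnostics are unavailable."""
        profiles = seqio.read_profiles(path)
        return cls(model=None, profiles=profiles,
                   background=Background.uniform(), skipped_kinases={})
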