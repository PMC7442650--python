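"""Model/Results interface over the full scoring pipeline.

``LiPQuant`` is built from an :class:`~lipquant.quantio.Experiment` (or from
the quant/design files) and ``fit()`` runs differential testing, candidate
filtering, 4PL dose-response fitting and scoring, returning a
:class:`LiPQuantResults` carrying the ranked peptide and protein tables, the
component breakdown and a text ``summary()``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffstats, dosefit, scoring
from .quantio import (
    Experiment,
    TargetAnnotation,
    attach,
    read_design,
    read_quant_table,
)
from .scoring import PFLibrary, Weights

logger = logging.getLogger(__name__)


class LiPQuant:
    """Dose-response drug-target deconvolution model for one experiment.

    Parameters
    ----------
    experiment
        Validated quant table + design (+ optional target annotation).
    weights
        Component weights; the shipped defaults put 69% on the dose-response
        correlation.
    pfl
        Protein frequency library for contaminant down-weighting; an empty
        library (no down-weighting) is used when omitted.
    preset
        Candidate filter preset ("rank" by default; "train", "smap").
    threshold
        Calling threshold on the 0-6 score (default 1.5).
    known_ec50
        Compound EC50 in molar units for the dose window and component IV;
        taken from the annotation when present.
    """

    def __init__(
        self,
        experiment: Experiment,
        weights: Weights | None = None,
        pfl: PFLibrary | None = None,
        preset: str = "rank",
        threshold: float = scoring.DEFAULT_THRESHOLD,
        known_ec50: float | None = None,
        storey_lambda: float = 0.5,
    ) -> None:
        self.experiment = experiment
        self.weights = weights or Weights()
        self.pfl = pfl or PFLibrary.empty()
        self.preset = preset
        self.threshold = threshold
        self.known_ec50 = (
            known_ec50 if known_ec50 is not None else experiment.known_ec50
        )
        self.storey_lambda = storey_lambda

    @classmethod
    def from_files(
        cls,
        quant_path: str | Path,
        design_path: str | Path,
        annotation: TargetAnnotation | None = None,
        dialect: dict | None = None,
        **kwargs,
    ) -> "LiPQuant":
        quant = read_quant_table(quant_path, dialect=dialect)
        design = read_design(design_path)
        return cls(attach(quant, design, annotation), **kwargs)

    def fit(self) -> "LiPQuantResults":
        """Run the full pipeline and return the ranked results."""
        diffs = diffstats.differential_analysis(
            self.experiment, lam=self.storey_lambda
        )
        candidates = diffstats.filter_candidates(
            diffs, preset=self.preset, known_ec50=self.known_ec50
        )
        fits = dosefit.fit_experiment(self.experiment, sorted(candidates.peptides))
        components = scoring.score_components(
            candidates,
            fits,
            self.pfl,
            diffs,
            known_ec50=self.known_ec50,
        )
        scored = scoring.score_peptides(components, self.weights)
        peptides, proteins = scoring.rank_and_call(scored, threshold=self.threshold)
        return LiPQuantResults(
            model=self,
            differential=diffs,
            candidates=candidates,
            fits=fits,
            peptides=peptides,
            proteins=proteins,
        )


@dataclasses.dataclass
class LiPQuantResults:
    """Ranked peptide/protein tables with component breakdown and diagnostics."""

    model: LiPQuant
    differential: pd.DataFrame
    candidates: diffstats.CandidateSet
    fits: dict[str, dosefit.DoseResponseFit]
    peptides: pd.DataFrame
    proteins: pd.DataFrame

    @property
    def called_proteins(self) -> pd.DataFrame:
        return self.proteins[self.proteins["is_called"]]

    @property
    def called_peptides(self) -> pd.DataFrame:
        return self.peptides[self.peptides["is_called"]]

    def ppv(self, truth: set[str] | None = None, k: int = 50):
        truth = truth if truth is not None else set(self.model.experiment.targets)
        return scoring.compute_ppv(self.peptides, truth, k=k)

    def roc(self, truth: set[str] | None = None):
        """Protein-level ROC over the whole quantified proteome.

        Proteins absent from the ranking (no candidate peptide) enter with
        score 0, so targets the filter missed count against sensitivity.
        """
        truth = truth if truth is not None else set(self.model.experiment.targets)
        ranked = self.proteins[["protein", "score"]]
        everything = pd.DataFrame(
            {"protein": self.model.experiment.quant.proteins}
        ).merge(ranked, on="protein", how="left")
        everything["score"] = everything["score"].fillna(0.0)
        return scoring.roc_auc(everything, truth)

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary: inputs, filters and the top ranking."""
        exp = self.model.experiment
        lines = [
            "LiP-Quant dose-response target deconvolution",
            "=" * 54,
            f"compound:            {exp.design.compound}",
            f"peptides quantified: {exp.quant.data['peptide'].nunique()}",
            f"proteins:            {exp.quant.data['protein'].nunique()}",
            f"doses (incl. veh.):  {len(exp.design.doses)}",
            f"filter preset:       {self.candidates.preset} "
            f"(q < {self.candidates.q_max}, "
            f"|log2FC| > {self.candidates.min_abs_log2fc:.2f})",
            f"candidate peptides:  {len(self.candidates)}",
            f"score threshold:     {self.model.threshold}",
            f"peptides called:     {int(self.peptides['is_called'].sum())}",
            f"proteins called:     {int(self.proteins['is_called'].sum())}",
            "",
            f"top {min(top, len(self.proteins))} proteins:",
        ]
        cols = ["rank", "protein", "score", "n_peptides", "ec50_molar"]
        head = self.proteins.head(top)[cols]
        with pd.option_context("display.float_format", "{:.3g}".format):
            lines.append(head.to_string(index=False))
        return "\n".join(lines)

    def protein_ec50(self, protein: str) -> float:
        """Median EC50 of the protein's converged, called peptides (molar)."""
        sub = self.proteins.loc[self.proteins["protein"] == protein, "ec50_molar"]
        return float(sub.iloc[0]) if len(sub) else float("nan")

    def plot_dose_response(self, peptide: str, ax=None):
        """Relative-intensity dose-response points and the fitted 4PL curve."""
        import matplotlib.pyplot as plt

        rel = dosefit.normalize_relative_intensity(self.model.experiment, peptide)
        fit = self.fits.get(peptide)
        if ax is None:
            _, ax = plt.subplots()
        pos = rel[rel["dose_molar"] > 0]
        veh = rel[rel["dose_molar"] == 0]
        ax.semilogx(pos["dose_molar"], pos["relative"], "o", label="measured")
        if len(veh):
            floor = pos["dose_molar"].min() / 10
            ax.semilogx([floor] * len(veh), veh["relative"], "s", label="vehicle")
        if fit is not None and fit.converged:
            xs = np.logspace(
                np.log10(pos["dose_molar"].min()) - 1,
                np.log10(pos["dose_molar"].max()) + 1,
                200,
            )
            ax.semilogx(
                xs,
                dosefit.four_pl(xs, fit.lower, fit.upper, fit.ec50, fit.slope),
                "-",
                label=f"4PL (EC50 = {fit.ec50:.3g} M, R2 = {fit.r2:.3f})",
            )
        ax.set_xlabel("dose (M)")
        ax.set_ylabel("relative intensity")
        ax.set_title(peptide)
        ax.legend()
        return ax

    def write(self, outdir: str | Path) -> None:
        """Write the differential, candidate, fit and ranking tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        diffstats.write_differential(self.differential, outdir / "differential.tsv")
        diffstats.write_candidates(self.candidates, outdir / "candidates.tsv")
        protein_of = self.model.experiment.quant.protein_of
        dosefit.write_fits(self.fits, protein_of, outdir / "fits.tsv")
        self.peptides.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
        self.proteins.to_csv(outdir / "proteins.tsv", sep="\t", index=False)
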