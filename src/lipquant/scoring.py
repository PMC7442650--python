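"""The LiP-Quant score: four normalised components combined into a 0-6 scale.

Component I is the dose-response R^2 (69% of the weight by default); component
II down-weights proteins that recur as hits in experiments where they are not
the known target (protein frequency library, PFL); component III rewards
proteins contributing several strongly regulated peptides; component IV is the
capped -log10 of the best q-value near the compound's known EC50. Weights can
be re-trained by repeated linear discriminant analysis against resampled
background peptides.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score, roc_curve

from .diffstats import CandidateSet
from .dosefit import DoseResponseFit
from .quantio import TargetAnnotation

logger = logging.getLogger(__name__)

SCORE_SCALE = 6.0
DEFAULT_THRESHOLD = 1.5
#: cap on the number of sibling peptides credited in component III
C3_CAP = 5
#: -log10(q) saturating value for component IV
C4_CAP = 10.0

PFL_SCHEMA_VERSION = 1
WEIGHTS_SCHEMA_VERSION = 1


@dataclasses.dataclass(frozen=True)
class Weights:
    """Non-negative component weights summing to 1, scaled to a 0-6 score.

    The shipped defaults give the dose-response correlation 69% of the weight
    and split the remainder roughly equally (rounding remainder on w4).
    """

    w: tuple[float, float, float, float] = (0.69, 0.1033, 0.1033, 0.1034)
    scale: float = SCORE_SCALE

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float)
        if arr.size != 4 or (arr < 0).any():
            raise ValueError("weights must be 4 non-negative numbers")
        if not np.isclose(arr.sum(), 1.0, atol=1e-6):
            raise ValueError(f"weights must sum to 1, got {arr.sum()}")

    def to_json(self, path) -> None:
        payload = {
            "schema_version": WEIGHTS_SCHEMA_VERSION,
            "weights": list(self.w),
            "scale": self.scale,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Weights":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(w=tuple(payload["weights"]), scale=payload.get("scale", SCORE_SCALE))


@dataclasses.dataclass(frozen=True)
class PFLibrary:
    """Per-protein frequency of being a non-target hit across a panel.

    Proteins that never appeared as non-target hits are absent; looking them
    up returns frequency 0.
    """

    counts: dict[str, int]
    n_total: int

    def frequency(self, protein: str) -> float:
        return self.counts.get(protein, 0) / self.n_total

    def __contains__(self, protein: str) -> bool:
        return protein in self.counts

    def to_json(self, path) -> None:
        payload = {
            "schema_version": PFL_SCHEMA_VERSION,
            "n_total": self.n_total,
            "counts": self.counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PFLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(counts=dict(payload["counts"]), n_total=int(payload["n_total"]))

    @classmethod
    def empty(cls) -> "PFLibrary":
        return cls(counts={}, n_total=1)


def build_pfl(panel: list[tuple[CandidateSet, TargetAnnotation]]) -> PFLibrary:
    """Count, per protein, the panel experiments where it was a filtered hit
    but not that experiment's annotated target.

    Repeated experiments count separately. A protein hit in 9 of 11 non-target
    experiments gets frequency 9/11 = 81.8%.
    """
    if len(panel) < 2:
        raise ValueError("PFL requires a panel of >= 2 annotated experiments")
    counts: dict[str, int] = {}
    for cands, annot in panel:
        hit_proteins = set(cands.table["protein"])
        for prot in hit_proteins:
            # protein groups: join on the first accession
            first = prot.split(";")[0]
            if first in annot.targets or prot in annot.targets:
                continue
            counts[prot] = counts.get(prot, 0) + 1
    return PFLibrary(counts=counts, n_total=len(panel))


@dataclasses.dataclass(frozen=True)
class ComponentVector:
    """The four normalised score components, each in [0, 1]."""

    c1: float  # dose-response correlation (R^2)
    c2: float  # 1 - PFL contamination frequency
    c3: float  # sibling-peptide support
    c4: float  # capped -log10 best q near the known EC50

    def __post_init__(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"component {name} = {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4])


def lipquant_score(c: ComponentVector, w: Weights | None = None) -> float:
    """Combined score = scale * sum_k w_k c_k, in [0, scale] (default 0-6)."""
    w = w or Weights()
    return float(w.scale * np.dot(np.asarray(w.w), c.as_array()))


def component_iv_doses(doses: np.ndarray, known_ec50: float | None,
                       fallback: tuple[float, ...]) -> tuple[float, ...]:
    """The three smallest doses strictly above the known EC50; without a known
    EC50 the candidate-filter window is used."""
    if known_ec50 is None:
        return tuple(fallback)
    doses = np.sort(np.asarray(doses, dtype=float))
    above = doses[doses > known_ec50]
    if above.size == 0:
        return tuple(fallback)
    return tuple(above[:3])


def score_components(
    candidates: CandidateSet,
    fits: dict[str, DoseResponseFit],
    pfl: PFLibrary,
    diffs: pd.DataFrame,
    known_ec50: float | None = None,
    c3_cap: int = C3_CAP,
    c4_cap: float = C4_CAP,
) -> pd.DataFrame:
    """Compute the four components for every candidate peptide.

    Returns a frame with columns peptide, protein, c1..c4, q_star, ec50,
    converged. Component III counts, per protein, candidate peptides whose
    best q ranks in the top 10% of all candidate peptides (capped, scaled to
    [0, 1]). Component IV takes the minimum q over the three smallest doses
    strictly above the compound's known EC50 (falling back to the filter
    window when unknown).
    """
    tab = candidates.table
    if tab.empty:
        return pd.DataFrame(
            columns=["peptide", "protein", "c1", "c2", "c3", "c4",
                     "q_star", "ec50", "converged"]
        )
    # top-10% membership by best q over the candidate list
    n_top = max(1, int(np.ceil(0.10 * len(tab))))
    top_peptides = set(tab.nsmallest(n_top, "best_q")["peptide"])
    n_top10_by_protein = (
        tab[tab["peptide"].isin(top_peptides)].groupby("protein")["peptide"].nunique()
    )

    iv_doses = component_iv_doses(
        diffs["dose_molar"].unique(), known_ec50, candidates.window_doses
    )
    iv_sub = diffs[diffs["dose_molar"].isin(iv_doses)]
    q_star_by_pep = iv_sub.groupby("peptide")["q"].min()

    rows = []
    for rec in tab.itertuples(index=False):
        fit = fits.get(rec.peptide)
        if fit is None:
            logger.warning("peptide %s has no dose-response fit; c1 = 0", rec.peptide)
        c1 = fit.r2 if (fit is not None and fit.converged) else 0.0
        c2 = 1.0 - pfl.frequency(rec.protein)
        c3 = min(int(n_top10_by_protein.get(rec.protein, 0)), c3_cap) / c3_cap
        q_star = q_star_by_pep.get(rec.peptide, np.nan)
        if np.isnan(q_star):
            q_star = rec.best_q  # peptide untested in the IV dose set
        q_star = max(float(q_star), 1e-300)
        c4 = min(-np.log10(q_star), c4_cap) / c4_cap
        rows.append(
            {
                "peptide": rec.peptide,
                "protein": rec.protein,
                "c1": c1,
                "c2": c2,
                "c3": c3,
                "c4": max(0.0, c4),
                "q_star": q_star,
                "ec50": fit.ec50 if (fit is not None and fit.converged) else np.nan,
                "converged": bool(fit.converged) if fit is not None else False,
            }
        )
    return pd.DataFrame(rows)


def score_peptides(components: pd.DataFrame, weights: Weights | None = None
                   ) -> pd.DataFrame:
    """Attach the combined 0-6 score to a component table."""
    w = weights or Weights()
    comp = components.copy()
    if comp.empty:
        comp["score"] = pd.Series(dtype=float)
        return comp
    mat = comp[["c1", "c2", "c3", "c4"]].to_numpy()
    comp["score"] = w.scale * mat @ np.asarray(w.w)
    return comp


def rank_and_call(scored: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank peptides and proteins and call hits above the threshold.

    Peptides sort descending by score with a deterministic tie-break (smaller
    q_star, then lexicographic peptide). The protein score is the best peptide
    score; calling uses the strict inequality score > threshold.
    """
    pep = scored.sort_values(
        ["score", "q_star", "peptide"], ascending=[False, True, True]
    ).reset_index(drop=True)
    pep["rank"] = np.arange(1, len(pep) + 1)
    pep["is_called"] = pep["score"] > threshold

    if pep.empty:
        prot = pd.DataFrame(columns=["protein", "score", "n_peptides",
                                     "ec50_molar", "rank", "is_called"])
        return pep, prot
    grp = pep.groupby("protein")
    prot = pd.DataFrame(
        {
            "score": grp["score"].max(),
            "n_peptides": grp["peptide"].nunique(),
            # protein EC50: median over converged, above-threshold peptides
            "ec50_molar": grp.apply(
                lambda g: float(
                    np.median(g.loc[(g["score"] > threshold) & g["converged"],
                                    "ec50"].dropna())
                )
                if ((g["score"] > threshold) & g["converged"] & g["ec50"].notna()).any()
                else np.nan,
                include_groups=False,
            ),
        }
    ).reset_index()
    best_pep = pep.drop_duplicates("protein")[["protein", "q_star"]]
    prot = prot.merge(best_pep, on="protein")
    prot = prot.sort_values(
        ["score", "q_star", "protein"], ascending=[False, True, True]
    ).drop(columns="q_star").reset_index(drop=True)
    prot["rank"] = np.arange(1, len(prot) + 1)
    prot["is_called"] = prot["score"] > threshold
    return pep, prot


def derive_threshold(nontarget_scores: np.ndarray) -> float:
    """Calling threshold = median(non-target scores) + 3 * sample sd.

    Promiscuous compounds (e.g. pan-kinase binders) should be excluded from
    the control set before calling this.
    """
    x = np.asarray(nontarget_scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 non-target scores to derive a threshold")
    return float(np.median(x) + 3.0 * x.std(ddof=1))


@dataclasses.dataclass(frozen=True)
class TrainingResult:
    weights: Weights
    per_repeat: np.ndarray  # (repeats, 4) normalised |coefficients|
    stable: bool

    @property
    def weight_sd(self) -> np.ndarray:
        return self.per_repeat.std(axis=0, ddof=1)


def train_weights_lda(
    features: pd.DataFrame,
    positives: set[str],
    n_neg: int = 400,
    repeats: int = 5,
    seed: int = 0,
    stability_sd: float = 0.05,
) -> TrainingResult:
    """Train component weights by repeated two-class LDA.

    ``features`` has one row per modified peptide with columns peptide and
    c1..c4 (already stabilised to [0, 1]); ``positives`` are peptides of known
    target proteins. Each repeat fits LDA on the positives against ``n_neg``
    freshly resampled background peptides; the absolute LDA coefficients are
    normalised to sum 1 and averaged over repeats. Large per-repeat spread
    marks the run unstable.
    """
    pos_mask = features["peptide"].isin(positives)
    pos = features.loc[pos_mask, ["c1", "c2", "c3", "c4"]].to_numpy()
    bg = features.loc[~pos_mask, ["c1", "c2", "c3", "c4"]].to_numpy()
    if len(pos) < 10:
        raise ValueError(f"need >= 10 positive peptides, got {len(pos)}")
    if len(bg) < n_neg:
        raise ValueError(f"background pool {len(bg)} smaller than n_neg {n_neg}")
    rng = np.random.default_rng(seed)
    per_repeat = np.empty((repeats, 4))
    for r in range(repeats):
        idx = rng.choice(len(bg), size=n_neg, replace=False)
        X = np.vstack([pos, bg[idx]])
        y = np.concatenate([np.ones(len(pos)), np.zeros(n_neg)])
        # lsqr + shrinkage keeps the fit defined when a component is constant
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
        # standardized coefficients (|coef| x pooled within-class sd): the
        # discriminative contribution per feature, insensitive to its scale
        resid = np.vstack([pos - pos.mean(axis=0), bg[idx] - bg[idx].mean(axis=0)])
        pooled_sd = resid.std(axis=0, ddof=2)
        coef = np.abs(lda.coef_.ravel()) * pooled_sd
        if coef.sum() == 0:
            coef = np.ones(4)
        per_repeat[r] = coef / coef.sum()
    mean_w = per_repeat.mean(axis=0)
    mean_w = mean_w / mean_w.sum()
    stable = bool(np.all(per_repeat.std(axis=0, ddof=1) < stability_sd))
    if not stable:
        logger.warning("LDA weights unstable across repeats: sd = %s",
                       per_repeat.std(axis=0, ddof=1))
    return TrainingResult(weights=Weights(w=tuple(mean_w)), per_repeat=per_repeat,
                          stable=stable)


@dataclasses.dataclass(frozen=True)
class BenchmarkResult:
    ppv: float
    tp: int
    fp: int
    k: int
    auc: float | None = None
    roc_points: tuple | None = None


def compute_ppv(ranked_peptides: pd.DataFrame, truth: set[str], k: int = 50
                ) -> BenchmarkResult:
    """Positive predictive value over the top-k ranked peptides.

    A peptide whose protein (first accession of the group) is in ``truth``
    counts as a true positive; PPV = TP / (TP + FP).
    """
    if ranked_peptides.empty:
        raise ValueError("empty ranking")
    if not truth:
        raise ValueError("empty truth set")
    if k > len(ranked_peptides):
        logger.warning("k = %d exceeds ranking length %d; using full list",
                       k, len(ranked_peptides))
        k = len(ranked_peptides)
    top = ranked_peptides.nsmallest(k, "rank")
    is_tp = top["protein"].map(lambda p: (p.split(";")[0] in truth) or (p in truth))
    tp = int(is_tp.sum())
    fp = k - tp
    return BenchmarkResult(ppv=tp / k, tp=tp, fp=fp, k=k)


def roc_auc(protein_scores: pd.DataFrame, truth: set[str]) -> BenchmarkResult:
    """Tie-aware ROC curve and AUC for a protein ranking against a truth set.

    ``protein_scores`` needs columns protein and score; external ranked lists
    can be benchmarked by supplying (len - rank) as the score.
    """
    if len(protein_scores) < 2:
        raise ValueError("need >= 2 proteins for a ROC curve")
    labels = protein_scores["protein"].map(
        lambda p: (p.split(";")[0] in truth) or (p in truth)
    ).astype(int)
    if labels.nunique() < 2:
        raise ValueError("both classes must be present in the ranking")
    scores = protein_scores["score"].to_numpy(dtype=float)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    tp = int(labels.sum())
    return BenchmarkResult(
        ppv=np.nan, tp=tp, fp=int(len(labels) - tp), k=len(labels),
        auc=auc, roc_points=(tuple(fpr), tuple(tpr)),
    )
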