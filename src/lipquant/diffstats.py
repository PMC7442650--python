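"""Differential peptide abundance between each dose and vehicle.

Each dose is compared against the vehicle by per-replicate log2 ratios and a
one-sample two-sided t-test (H0: mean log2 ratio = 0), corrected within each
dose-vs-vehicle comparison by Storey q-values. Candidate peptides entering the
scoring stage must pass a q-value and an absolute log2 fold-change cutoff in at
least one comparison inside a configurable dose window.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quantio import Experiment

logger = logging.getLogger(__name__)

#: named filter presets: (q cutoff, |log2FC| cutoff, uses dose window)
PRESETS = {
    # classifier-training filter
    "train": {"q_max": 0.01, "min_abs_log2fc": 0.58, "window": False},
    # automated ranking filter; window = [EC50, 1000 x EC50]
    "rank": {"q_max": 0.01, "min_abs_log2fc": 0.46, "window": True},
    # single-dose structural-mapping filter: q < 1e-4, fold change 1.5
    "smap": {"q_max": 1e-4, "min_abs_log2fc": float(np.log2(1.5)), "window": False},
}


@dataclasses.dataclass(frozen=True)
class CandidateSet:
    """Peptides passing the differential filters, with their best statistics.

    ``table`` has one row per passing peptide: peptide, protein, best (minimum)
    q over the admitted comparisons, the log2FC at that comparison, and the
    dose at which the minimum was attained.
    """

    table: pd.DataFrame
    preset: str
    q_max: float
    min_abs_log2fc: float
    window_doses: tuple[float, ...]

    @property
    def peptides(self) -> set[str]:
        return set(self.table["peptide"])

    def __len__(self) -> int:
        return len(self.table)


def replicate_log2_ratios(exp: Experiment, dose: float) -> dict[str, np.ndarray]:
    """Per-peptide vectors of log2(treated/vehicle), paired by replicate index.

    Replicate i of the dose is divided by vehicle replicate i. Pairs with a
    missing, zero or negative member are dropped; a peptide whose pairs are all
    dropped gets an empty vector (untestable).
    """
    treated = exp.design.samples_at(dose)
    vehicle = exp.design.vehicle_samples
    if treated.empty:
        raise ValueError(f"dose {dose} not present in design")
    pairs = pd.merge(
        treated[["sample", "replicate"]],
        vehicle[["sample", "replicate"]],
        on="replicate",
        suffixes=("_t", "_v"),
    )
    wide = exp.quant.pivot()
    out: dict[str, np.ndarray] = {}
    tmat = wide.reindex(columns=pairs["sample_t"]).to_numpy(dtype=float)
    vmat = wide.reindex(columns=pairs["sample_v"]).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(tmat / vmat)
    ok = np.isfinite(ratios) & (tmat > 0) & (vmat > 0)
    for i, pep in enumerate(wide.index):
        out[pep] = ratios[i, ok[i]]
    return out


def one_sample_ttest(ratios: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t-test of H0: mean = 0 with df = n - 1.

    Degenerate conventions for tied replicates: sd = 0 with mean = 0 gives
    p = 1; sd = 0 with mean != 0 gives the machine-minimum p. Fewer than two
    ratios returns (nan, nan) — the peptide is untestable.
    """
    x = np.asarray(ratios, dtype=float)
    n = x.size
    if n < 2:
        return (np.nan, np.nan)
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0.0:
        if mean == 0.0:
            return (0.0, 1.0)
        return (np.inf if mean > 0 else -np.inf, np.finfo(float).tiny)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return (float(t), float(p))


def storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 estimator.

    pi0 = min(1, #{p > lambda} / (m * (1 - lambda))); q_i is the minimum over
    p_j >= p_i of pi0 * m * p_j / rank(p_j), so q is monotone in p and bounded
    by 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    m = p.size
    pi0 = np.count_nonzero(p > lam) / (m * (1.0 - lam))
    pi0 = min(1.0, pi0)
    if pi0 == 0.0:
        pi0 = 1.0 / m  # all p below lambda; keep a non-degenerate estimate
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_analysis(exp: Experiment, lam: float = 0.5) -> pd.DataFrame:
    """All dose-vs-vehicle comparisons for every peptide.

    Returns a long table with columns peptide, protein, dose_molar, log2fc,
    p, q, n_ratios. q-values are computed within each dose-vs-vehicle
    comparison across peptides (never pooled across doses). Untestable
    peptides (n_ratios < 2) carry NaN statistics.
    """
    protein_of = exp.quant.data.drop_duplicates("peptide").set_index("peptide")[
        "protein"
    ]
    frames = []
    for dose in exp.design.positive_doses:
        ratios = replicate_log2_ratios(exp, dose)
        rows = []
        for pep, vec in ratios.items():
            t, p = one_sample_ttest(vec)
            log2fc = float(vec.mean()) if vec.size else np.nan
            rows.append((pep, protein_of[pep], dose, log2fc, p, vec.size))
        df = pd.DataFrame(
            rows, columns=["peptide", "protein", "dose_molar", "log2fc", "p", "n_ratios"]
        )
        testable = df["p"].notna()
        df["q"] = np.nan
        if testable.any():
            df.loc[testable, "q"] = storey_qvalues(
                df.loc[testable, "p"].to_numpy(), lam=lam
            )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["peptide", "protein", "dose_molar", "log2fc", "p", "q", "n_ratios"]]


def dose_window(
    doses: np.ndarray, known_ec50: float | None, fold: float = 1000.0
) -> tuple[float, ...]:
    """Doses admitted to candidate filtering: [EC50, fold x EC50].

    When no dose falls inside the window, the closest available contiguous
    dose range (the dose nearest the window) is used; with no known EC50 all
    positive doses are admitted.
    """
    doses = np.sort(np.asarray(doses, dtype=float))
    doses = doses[doses > 0]
    if known_ec50 is None:
        return tuple(doses)
    inside = doses[(doses >= known_ec50) & (doses <= fold * known_ec50)]
    if inside.size:
        return tuple(inside)
    # no dose in window: take the dose closest to the window boundary
    lo, hi = known_ec50, fold * known_ec50
    dist = np.where(doses < lo, lo - doses, doses - hi)
    return (float(doses[np.argmin(dist)]),)


def filter_candidates(
    diffs: pd.DataFrame,
    preset: str = "rank",
    known_ec50: float | None = None,
    q_max: float | None = None,
    min_abs_log2fc: float | None = None,
) -> CandidateSet:
    """Gate peptides into scoring: pass if ANY admitted comparison satisfies
    both the q-value and the absolute log2 fold-change cutoff.

    ``preset`` selects the shipped cutoffs ("train", "rank", "smap"); explicit
    ``q_max``/``min_abs_log2fc`` override them. The dose window applies to the
    "rank" preset only and requires a known compound EC50 (otherwise all doses
    are admitted, with a warning).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    q_cut = cfg["q_max"] if q_max is None else q_max
    fc_cut = cfg["min_abs_log2fc"] if min_abs_log2fc is None else min_abs_log2fc
    all_doses = np.sort(diffs["dose_molar"].unique())
    if cfg["window"]:
        if known_ec50 is None:
            warnings.warn(
                "preset 'rank' without a known EC50: dose window defaults to all doses",
                stacklevel=2,
            )
            window = tuple(all_doses)
        else:
            window = dose_window(all_doses, known_ec50)
    else:
        window = tuple(all_doses)

    sub = diffs[diffs["dose_molar"].isin(window)].copy()
    passing = sub[(sub["q"] < q_cut) & (sub["log2fc"].abs() > fc_cut)]
    if passing.empty:
        warnings.warn("no peptides pass the candidate filter", stacklevel=2)
        table = pd.DataFrame(
            columns=["peptide", "protein", "best_q", "log2fc_at_best", "dose_at_best"]
        )
    else:
        best = passing.loc[passing.groupby("peptide")["q"].idxmin()]
        table = (
            best.rename(
                columns={"q": "best_q", "log2fc": "log2fc_at_best",
                         "dose_molar": "dose_at_best"}
            )[["peptide", "protein", "best_q", "log2fc_at_best", "dose_at_best"]]
            .sort_values("peptide")
            .reset_index(drop=True)
        )
    return CandidateSet(
        table=table,
        preset=preset,
        q_max=q_cut,
        min_abs_log2fc=fc_cut,
        window_doses=tuple(float(d) for d in window),
    )


def write_differential(diffs: pd.DataFrame, path) -> None:
    diffs.to_csv(path, sep="\t", index=False)


def write_candidates(cands: CandidateSet, path) -> None:
    """Candidate TSV with '#'-prefixed filter metadata header lines."""
    with open(path, "w") as fh:
        fh.write(f"# preset: {cands.preset}\n")
        fh.write(f"# q_max: {cands.q_max}\n")
        fh.write(f"# min_abs_log2fc: {cands.min_abs_log2fc}\n")
        fh.write(f"# window_doses: {','.join(str(d) for d in cands.window_doses)}\n")
        cands.table.to_csv(fh, sep="\t", index=False)
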