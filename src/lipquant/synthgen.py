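"""Synthetic LiP-Quant experiments with known ground truth.

Emulates the vehicle + 7-dose, 4-replicate design: responder peptides of the
target proteins follow a 4PL dose-response with configurable EC50, direction
and dynamic range; the background is flat; every observation is perturbed by
multiplicative lognormal noise parameterised by its coefficient of variation,
and a fraction of observations is dropped uniformly at random. Panels of
experiments share a contaminant pool so the protein frequency library can be
built and exercised.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .dosefit import four_pl
from .quantio import Experiment, QuantTable, SampleDesign, TargetAnnotation, attach

#: default dose ladder: 7 half-log steps from 1 nM to 1 mM-free micromolar range
DEFAULT_DOSES = tuple(10 ** (-9 + 0.5 * i) for i in range(7))  # 1e-9 .. 1e-6 M

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dose-response experiment."""

    n_proteins: int = 120
    mean_peptides_per_protein: float = 4.0
    n_target_proteins: int = 5
    target_offset: int = 0  # targets are proteins[offset : offset + n_targets]
    responders_per_target: int = 4
    doses: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 4
    ec50: float = 1e-8  # molar; per-responder EC50s are jittered around this
    ec50_log_jitter: float = 0.3  # sd of log10 jitter across responders
    direction: str | None = None  # "up", "down" or None (random 50/50)
    dynamic_range: float = 3.0  # fold change between asymptotes at saturation
    noise_cv: float = 0.10
    missing_rate: float = 0.02
    baseline_log10_mean: float = 6.0
    baseline_log10_sd: float = 0.5
    contaminant_shift_log2: float = 1.0  # drug-independent responder magnitude
    compound: str = "compound"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_cv", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.target_offset + self.n_target_proteins > self.n_proteins:
            raise ValueError("more target proteins than proteins")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive (vehicle is implicit)")
        if self.direction not in (None, "up", "down"):
            raise ValueError("direction must be 'up', 'down' or None")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: targets, responders and contaminants."""

    target_proteins: tuple[str, ...]
    responders: pd.DataFrame  # peptide, protein, ec50, direction, dynamic_range
    compound_ec50: float
    contaminant_proteins: tuple[str, ...] = ()

    def to_json(self, path) -> None:
        payload = {
            "target_proteins": list(self.target_proteins),
            "responders": self.responders.to_dict(orient="records"),
            "compound_ec50": self.compound_ec50,
            "contaminant_proteins": list(self.contaminant_proteins),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 26))
    return "".join(rng.choice(_AA, size=length)) + "K"


def simulate_experiment(
    cfg: SimConfig,
    contaminant_proteins: tuple[str, ...] = (),
) -> tuple[Experiment, GroundTruth]:
    """Generate one experiment: quant table, design and ground truth.

    Responder peptide means follow the 4PL model; contaminant proteins (drug-
    independent structural responders shared across a panel) shift at every
    dose regardless of concentration. Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    targets = tuple(
        proteins[cfg.target_offset : cfg.target_offset + cfg.n_target_proteins]
    )

    n_peps = np.maximum(
        1, rng.poisson(cfg.mean_peptides_per_protein, size=cfg.n_proteins)
    )
    # targets need room for their responder peptides
    for i in range(cfg.target_offset, cfg.target_offset + cfg.n_target_proteins):
        n_peps[i] = max(n_peps[i], cfg.responders_per_target)

    doses = np.array([0.0, *cfg.doses])
    design_rows = []
    for d_idx, dose in enumerate(doses):
        for rep in range(1, cfg.replicates + 1):
            design_rows.append(
                {
                    "sample": f"D{d_idx}R{rep}",
                    "compound": cfg.compound,
                    "dose_molar": dose,
                    "replicate": rep,
                }
            )
    design = SampleDesign(pd.DataFrame(design_rows))

    responder_rows = []
    quant_rows = []
    seen_peptides: set[str] = set()
    for p_idx, prot in enumerate(proteins):
        is_target = prot in targets
        is_contam = prot in contaminant_proteins
        for k in range(int(n_peps[p_idx])):
            while True:
                pep = _random_peptide(rng)
                if pep not in seen_peptides:
                    seen_peptides.add(pep)
                    break
            baseline = 10 ** rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd)
            responder = is_target and k < cfg.responders_per_target
            if responder:
                direction = cfg.direction or ("up" if rng.random() < 0.5 else "down")
                ec50 = cfg.ec50 * 10 ** rng.normal(0.0, cfg.ec50_log_jitter)
                # keep the planted EC50 inside the dosed range
                ec50 = float(np.clip(ec50, min(cfg.doses), max(cfg.doses)))
                if direction == "down":
                    upper, lower, slope = 1.0, 1.0 / cfg.dynamic_range, 1.0
                else:
                    upper, lower, slope = 1.0, cfg.dynamic_range, 1.0
                rel_mean = four_pl(doses, lower, upper, ec50, slope)
                responder_rows.append(
                    {
                        "peptide": pep,
                        "protein": prot,
                        "ec50": ec50,
                        "direction": direction,
                        "dynamic_range": cfg.dynamic_range,
                    }
                )
            elif is_contam:
                # drug-independent structural responder: every dose shifts, but
                # with random sign/magnitude, so there is no sigmoidal trend
                signs = rng.choice([-1.0, 1.0], size=doses.size)
                mags = cfg.contaminant_shift_log2 * rng.uniform(
                    1.0, 1.5, size=doses.size
                )
                rel_mean = np.where(doses > 0, 2.0 ** (signs * mags), 1.0)
            else:
                rel_mean = np.ones_like(doses)
            for d_idx, dose in enumerate(doses):
                noise = _lognormal_noise(rng, cfg.noise_cv, cfg.replicates)
                values = baseline * rel_mean[d_idx] * noise
                for rep in range(1, cfg.replicates + 1):
                    quant_rows.append(
                        (pep, prot, f"D{d_idx}R{rep}", values[rep - 1])
                    )

    quant_df = pd.DataFrame(
        quant_rows, columns=["peptide", "protein", "sample", "intensity"]
    )
    if cfg.missing_rate > 0:
        drop = rng.random(len(quant_df)) < cfg.missing_rate
        quant_df.loc[drop, "intensity"] = np.nan
    quant = QuantTable(quant_df)
    annot = TargetAnnotation(
        compound=cfg.compound, targets=frozenset(targets), known_ec50=cfg.ec50
    )
    truth = GroundTruth(
        target_proteins=targets,
        responders=pd.DataFrame(
            responder_rows,
            columns=["peptide", "protein", "ec50", "direction", "dynamic_range"],
        ),
        compound_ec50=cfg.ec50,
        contaminant_proteins=tuple(contaminant_proteins),
    )
    return attach(quant, design, annot), truth


@dataclasses.dataclass(frozen=True)
class PanelTruth:
    experiments: tuple[GroundTruth, ...]
    contaminant_pool: tuple[str, ...]
    fired: pd.DataFrame  # columns: experiment, protein (contaminants that fired)


def simulate_panel(
    configs: list[SimConfig],
    n_contaminants: int = 10,
    contamination_probability: float = 0.5,
    contaminant_pool_start: int | None = None,
    seed: int = 0,
) -> tuple[list[Experiment], PanelTruth]:
    """Generate a panel of experiments sharing a contaminant protein pool.

    Each contaminant fires (responds drug-independently) in each experiment
    with ``contamination_probability``; the truth records where each fired.
    By default the pool sits just past every experiment's target block, but
    ``contaminant_pool_start`` may place it so that a contaminant is also the
    annotated target of some experiments (those count toward the PFL
    denominator, not toward its hit count). Every experiment gets a distinct
    compound id and a seed derived from ``seed`` and its position.
    """
    if not configs:
        raise ValueError("empty panel")
    rng = np.random.default_rng(seed)
    n_prot = min(c.n_proteins for c in configs)
    if contaminant_pool_start is None:
        contaminant_pool_start = max(
            c.target_offset + c.n_target_proteins for c in configs
        )
    pool_ids = range(contaminant_pool_start, contaminant_pool_start + n_contaminants)
    if max(pool_ids, default=-1) >= n_prot:
        raise ValueError("contaminant pool does not fit in the smallest proteome")
    pool = tuple(f"P{i:04d}" for i in pool_ids)

    experiments: list[Experiment] = []
    truths: list[GroundTruth] = []
    fired_rows = []
    for e_idx, cfg in enumerate(configs):
        fired = tuple(
            p for p in pool if rng.random() < contamination_probability
        )
        cfg_e = dataclasses.replace(
            cfg,
            seed=int(rng.integers(0, 2**31 - 1)),
            compound=f"{cfg.compound}_{e_idx}",
        )
        exp, truth = simulate_experiment(cfg_e, contaminant_proteins=fired)
        experiments.append(exp)
        truths.append(truth)
        fired_rows.extend({"experiment": e_idx, "protein": p} for p in fired)
    return experiments, PanelTruth(
        experiments=tuple(truths),
        contaminant_pool=pool,
        fired=pd.DataFrame(fired_rows, columns=["experiment", "protein"]),
    )
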