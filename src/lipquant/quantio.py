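"""Input/output and validation of peptide quantification tables and sample designs.

The canonical input is a long (tidy) table of peptide-level intensities as
exported by DIA search engines: one row per (modified peptide, sample), with a
protein accession and a non-negative intensity. Intensities are assumed to be
already normalised by the upstream search engine; missing intensities are kept
as missing (NaN), never imputed here.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column names of the canonical long format
DEFAULT_DIALECT = {
    "peptide_col": "peptide",
    "protein_col": "protein",
    "sample_col": "sample",
    "intensity_col": "intensity",
}


class QuantIOError(ValueError):
    """Raised for malformed quantification tables or designs."""


@dataclasses.dataclass(frozen=True)
class QuantTable:
    """Long-format peptide x sample intensity records.

    ``data`` has columns ``peptide, protein, sample, intensity``; (peptide,
    sample) pairs are unique and every peptide maps to exactly one protein
    accession string (protein groups are carried verbatim as one string).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["peptide", "protein", "sample", "intensity"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise QuantIOError(f"quant table missing columns: {missing}")
        dup = df.duplicated(subset=["peptide", "sample"])
        if dup.any():
            keys = df.loc[dup, ["peptide", "sample"]].head(5).to_records(index=False)
            raise QuantIOError(f"duplicate (peptide, sample) pairs, e.g. {list(keys)}")
        multi = df.groupby("peptide")["protein"].nunique()
        bad = multi[multi > 1]
        if len(bad):
            raise QuantIOError(
                f"peptides mapped to >1 protein accession: {list(bad.index[:5])}"
            )
        neg = df["intensity"].dropna() < 0
        if neg.any():
            raise QuantIOError("negative intensities present")

    @property
    def peptides(self) -> list[str]:
        return sorted(self.data["peptide"].unique())

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def protein_of(self, peptide: str) -> str:
        sub = self.data.loc[self.data["peptide"] == peptide, "protein"]
        if sub.empty:
            raise KeyError(peptide)
        return sub.iloc[0]

    def pivot(self) -> pd.DataFrame:
        """Peptide x sample wide matrix (NaN where missing)."""
        return self.data.pivot(index="peptide", columns="sample", values="intensity")


@dataclasses.dataclass(frozen=True)
class SampleDesign:
    """Dose-response sample layout for one compound.

    One row per sample: ``sample, compound, dose_molar, replicate, vehicle``.
    Vehicle is defined as dose == 0; the default design is vehicle + 7 doses
    with 4 replicates each.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["sample", "compound", "dose_molar", "replicate"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise QuantIOError(f"design missing columns: {missing}")
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise QuantIOError(f"duplicate sample ids in design: {dups}")
        if (df["dose_molar"] < 0).any():
            raise QuantIOError("negative dose in design")
        if not (df["dose_molar"] == 0).any():
            raise QuantIOError("no vehicle (dose == 0) row in design")
        if df["compound"].nunique() > 1:
            raise QuantIOError("design mixes compounds; one compound per experiment")
        if "vehicle" not in df.columns:
            object.__setattr__(
                self, "data", df.assign(vehicle=df["dose_molar"] == 0.0)
            )
        counts = self.data.groupby("dose_molar")["replicate"].nunique()
        if (counts < 2).any():
            logger.warning("some doses have < 2 replicates: %s",
                           counts[counts < 2].index.tolist())

    @property
    def doses(self) -> np.ndarray:
        """All distinct doses including vehicle, ascending."""
        return np.sort(self.data["dose_molar"].unique())

    @property
    def positive_doses(self) -> np.ndarray:
        d = self.doses
        return d[d > 0]

    @property
    def compound(self) -> str:
        return self.data["compound"].iloc[0]

    def samples_at(self, dose: float) -> pd.DataFrame:
        # relative-only tolerance: molar doses span many decades, so any
        # absolute tolerance would conflate neighbouring dilutions
        sub = self.data[
            np.isclose(self.data["dose_molar"], dose, rtol=1e-9, atol=0.0)
        ]
        return sub.sort_values("replicate")

    @property
    def vehicle_samples(self) -> pd.DataFrame:
        return self.samples_at(0.0)


@dataclasses.dataclass(frozen=True)
class TargetAnnotation:
    """Known target proteins of a compound, optionally with its known EC50 (M)."""

    compound: str
    targets: frozenset[str]
    known_ec50: float | None = None

    def __post_init__(self) -> None:
        if any(not t for t in self.targets):
            raise QuantIOError("empty accession in target annotation")
        if self.known_ec50 is not None and self.known_ec50 <= 0:
            raise QuantIOError("known EC50 must be > 0")

    @classmethod
    def empty(cls, compound: str = "") -> "TargetAnnotation":
        return cls(compound=compound, targets=frozenset())


@dataclasses.dataclass(frozen=True)
class Experiment:
    """A validated quant table joined with its design and (optional) targets."""

    quant: QuantTable
    design: SampleDesign
    annotation: TargetAnnotation | None = None

    @property
    def targets(self) -> frozenset[str]:
        return self.annotation.targets if self.annotation else frozenset()

    @property
    def known_ec50(self) -> float | None:
        return self.annotation.known_ec50 if self.annotation else None


def _resolve_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_quant_table(path: str | Path, dialect: dict | None = None) -> QuantTable:
    """Read a long-format TSV/CSV quantification table.

    ``dialect`` maps canonical names to file columns via keys ``peptide_col``,
    ``protein_col``, ``sample_col``, ``intensity_col``. Empty or "NaN"
    intensity fields are preserved as missing values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = {**DEFAULT_DIALECT, **(dialect or {})}
    try:
        df = pd.read_csv(path, sep=_resolve_sep(path), comment="#")
    except pd.errors.EmptyDataError:
        raise QuantIOError(f"no records in {path}") from None
    if df.empty:
        raise QuantIOError(f"no records in {path}")
    mapping = {
        d["peptide_col"]: "peptide",
        d["protein_col"]: "protein",
        d["sample_col"]: "sample",
        d["intensity_col"]: "intensity",
    }
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise QuantIOError(f"{path}: cannot resolve columns {missing}")
    df = df.rename(columns=mapping)[["peptide", "protein", "sample", "intensity"]]
    raw = df["intensity"]
    df["intensity"] = pd.to_numeric(raw, errors="coerce")
    bad = df["intensity"].isna() & raw.notna() & (raw.astype(str).str.strip() != "") \
        & (raw.astype(str).str.lower() != "nan")
    if bad.any():
        raise QuantIOError(
            f"{path}: unparseable intensity at rows {list(df.index[bad][:5])}"
        )
    df["peptide"] = df["peptide"].astype(str)
    df["protein"] = df["protein"].astype(str)
    df["sample"] = df["sample"].astype(str)
    return QuantTable(df.reset_index(drop=True))


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write the canonical long format; missing intensities become empty fields."""
    table.data.to_csv(Path(path), sep="\t", index=False, na_rep="")


def read_design(path: str | Path) -> SampleDesign:
    """Read a design TSV with columns sample, compound, dose_molar, replicate.

    The vehicle flag is inferred (dose == 0) and rows are returned with doses
    sorted ascending, vehicle first.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_resolve_sep(path), comment="#")
    required = ["sample", "dose_molar", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise QuantIOError(f"{path}: design missing columns {missing}")
    if "compound" not in df.columns:
        df["compound"] = "compound"
    df["sample"] = df["sample"].astype(str)
    df["dose_molar"] = pd.to_numeric(df["dose_molar"])
    df = df.sort_values(["dose_molar", "replicate"]).reset_index(drop=True)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.data.to_csv(Path(path), sep="\t", index=False)


def read_targets(path: str | Path) -> dict[str, TargetAnnotation]:
    """Read target annotations: TSV with columns compound, protein[, known_ec50_molar]."""
    path = Path(path)
    df = pd.read_csv(path, sep=_resolve_sep(path), comment="#")
    out: dict[str, TargetAnnotation] = {}
    for compound, grp in df.groupby("compound"):
        ec50 = None
        if "known_ec50_molar" in grp.columns:
            vals = grp["known_ec50_molar"].dropna()
            if len(vals):
                ec50 = float(vals.iloc[0])
        out[str(compound)] = TargetAnnotation(
            compound=str(compound),
            targets=frozenset(grp["protein"].astype(str)),
            known_ec50=ec50,
        )
    return out


def attach(
    quant: QuantTable,
    design: SampleDesign,
    annotation: TargetAnnotation | None = None,
) -> Experiment:
    """Join a quant table with its design, enforcing referential integrity."""
    quant_samples = set(quant.data["sample"])
    design_samples = set(design.data["sample"])
    unmatched = sorted(quant_samples - design_samples)
    if unmatched:
        raise QuantIOError(f"quant samples absent from design: {unmatched}")
    logger.info(
        "experiment: %d peptides, %d proteins, %d samples, %d doses",
        quant.data["peptide"].nunique(),
        quant.data["protein"].nunique(),
        len(quant_samples),
        len(design.doses),
    )
    return Experiment(quant=quant, design=design, annotation=annotation)
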