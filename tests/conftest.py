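"""Shared fixtures: hand-built toy experiments and programmatic toy structures."""

from __future__ import annotations

import gemmi
import numpy as np
import pandas as pd
import pytest

from lipquant.quantio import (
    Experiment,
    QuantTable,
    SampleDesign,
    TargetAnnotation,
    attach,
)
from lipquant.structsite import StructureModel


def build_design(
    doses=(0.0, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5), replicates=4, compound="drugX"
) -> SampleDesign:
    rows = [
        {
            "sample": f"D{i}R{r}",
            "compound": compound,
            "dose_molar": dose,
            "replicate": r,
        }
        for i, dose in enumerate(doses)
        for r in range(1, replicates + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


def build_experiment(intensity_fn, peptides, design=None, annot=None) -> Experiment:
    """Experiment from a callable intensity_fn(peptide, dose, replicate) -> float.

    ``peptides`` maps peptide -> protein; NaN returns become missing values.
    """
    design = design or build_design()
    rows = []
    for pep, prot in peptides.items():
        for row in design.data.itertuples(index=False):
            rows.append(
                {
                    "peptide": pep,
                    "protein": prot,
                    "sample": row.sample,
                    "intensity": intensity_fn(pep, row.dose_molar, row.replicate),
                }
            )
    return attach(QuantTable(pd.DataFrame(rows)), design, annot)


@pytest.fixture
def flat_experiment() -> Experiment:
    """Three flat peptides, no dose response, no noise."""
    peptides = {"AAAK": "P1", "CCCK": "P1", "DDDK": "P2"}
    return build_experiment(lambda p, d, r: 100.0, peptides)


@pytest.fixture
def annotated_design() -> tuple[SampleDesign, TargetAnnotation]:
    return build_design(), TargetAnnotation(
        compound="drugX", targets=frozenset({"P1"}), known_ec50=1e-8
    )


# --- toy structures -------------------------------------------------------

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def build_structure(
    sequence: str,
    ligand_xyz: tuple[float, float, float],
    spacing: float = 3.8,
    unresolved: set[int] | None = None,
) -> StructureModel:
    """A straight-chain toy protein along the x-axis with one ligand atom.

    Residue i (1-based) sits at x = (i - 1) * spacing with three heavy atoms
    (N, CA, C) offset slightly in y; residues listed in ``unresolved`` carry
    no atoms. The ligand is a single carbon named LIG in chain L.
    """
    st = gemmi.Structure()
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    unresolved = unresolved or set()
    for i, letter in enumerate(sequence, start=1):
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE[letter]
        res.seqid = gemmi.SeqId(i, " ")
        if i not in unresolved:
            for name, elem, dy in (("N", "N", -0.5), ("CA", "C", 0.0),
                                   ("C", "C", 0.5)):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(elem)
                atom.pos = gemmi.Position((i - 1) * spacing, dy, 0.0)
                res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)

    lig_chain = gemmi.Chain("L")
    lig = gemmi.Residue()
    lig.name = "LIG"
    lig.seqid = gemmi.SeqId(1, " ")
    atom = gemmi.Atom()
    atom.name = "C1"
    atom.element = gemmi.Element("C")
    atom.pos = gemmi.Position(*ligand_xyz)
    lig.add_atom(atom)
    lig_chain.add_residue(lig)
    model.add_chain(lig_chain)
    st.add_model(model)
    return StructureModel(structure=st, ligand_name="LIG")


@pytest.fixture
def toy_structure() -> StructureModel:
    # 20 residues along x; ligand near the middle of the chain
    return build_structure("MKTAYIAKQRGSWFELNHPV", ligand_xyz=(9 * 3.8, 0.0, 2.0))


def rigid_transform(model: StructureModel, rotation: np.ndarray,
                    translation: np.ndarray) -> StructureModel:
    """Apply a rotation + translation to every atom of a copy of the model."""
    st = model.structure.clone()
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    v = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    nv = rotation @ v + translation
                    atom.pos = gemmi.Position(*nv)
    return StructureModel(structure=st, ligand_name=model.ligand_name)
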