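"""Approximate drug binding sites from high-scoring peptides on a structure.

The highest-scoring peptides of the candidate target are mapped onto a PDB
chain by exact sequence match, the mass-weighted center of mass (COM) of their
atoms is computed, and the minimal distance between the residues surrounding
the COM and the bound ligand decides whether the estimate touches the binding
cleft (van der Waals criterion, 4 Angstrom). A random-peptide null quantifies
how unusual the observed distance is.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

VDW_RADIUS = 4.0  # Angstrom, contact criterion
#: spans with fewer resolved residues than this fraction are rejected
MIN_RESOLVED_FRACTION = 0.5

# innermost-first so nested annotations like "(Oxidation (M))" strip cleanly
_MODIFICATION_RE = re.compile(r"\[[^\[\]]*\]|\([^()]*\)|_")


def strip_modifications(peptide: str) -> str:
    """Reduce a modified peptide string to its bare one-letter sequence.

    Bracketed and parenthesised annotations and underscores are removed, e.g.
    ``_C[Carbamidomethyl (C)]PEPTIDEK_`` -> ``CPEPTIDEK``.
    """
    prev = None
    seq = peptide
    while prev != seq:  # nested parentheses inside brackets
        prev = seq
        seq = _MODIFICATION_RE.sub("", seq)
    return seq


@dataclasses.dataclass(frozen=True)
class StructureModel:
    """A parsed structure with a designated ligand selection."""

    structure: gemmi.Structure
    ligand_name: str

    def __post_init__(self) -> None:
        if not self.ligand_atoms():
            raise ValueError(f"ligand {self.ligand_name!r} not found in structure")

    @classmethod
    def from_pdb(cls, path: str | Path, ligand_name: str) -> "StructureModel":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return cls(structure=st, ligand_name=ligand_name)

    @property
    def model(self) -> gemmi.Model:
        return self.structure[0]

    def chain(self, chain_id: str) -> gemmi.Chain:
        chain = self.model.find_chain(chain_id)
        if chain is None:
            raise KeyError(f"chain {chain_id!r} not in structure")
        return chain

    def chain_sequence(self, chain_id: str) -> tuple[str, list[gemmi.Residue]]:
        """One-letter sequence of the polymer residues and the residues themselves."""
        residues = [
            res for res in self.chain(chain_id)
            if res.name != self.ligand_name and gemmi.find_tabulated_residue(res.name)
            and gemmi.find_tabulated_residue(res.name).is_amino_acid()
        ]
        seq = "".join(
            gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
            for res in residues
        )
        return seq, residues

    def ligand_atoms(self) -> list[gemmi.Atom]:
        atoms = []
        for chain in self.model:
            for res in chain:
                if res.name == self.ligand_name:
                    atoms.extend(list(res))
        return atoms

    def protein_atoms(self) -> list[tuple[gemmi.Residue, gemmi.Atom]]:
        out = []
        for chain in self.model:
            for res in chain:
                if res.name == self.ligand_name:
                    continue
                info = gemmi.find_tabulated_residue(res.name)
                if info is None or not info.is_amino_acid():
                    continue
                out.extend((res, atom) for atom in res)
        return out


@dataclasses.dataclass(frozen=True)
class BindingSiteEstimate:
    """Peptide-derived COM, its residue neighborhood and ligand distance."""

    com: np.ndarray  # (3,) Angstrom
    peptides: tuple[str, ...]
    residue_ranges: tuple[tuple[int, int], ...]  # 1-based spans on the chain
    neighborhood_residues: tuple[str, ...]  # author numbering labels
    min_distance: float
    within_vdw: bool


def map_peptide_to_structure(
    model: StructureModel, chain_id: str, peptide: str
) -> tuple[int, int]:
    """Locate a bare peptide sequence on a chain by exact substring match.

    Returns the 1-based (start, end) residue span over the chain sequence.
    Zero matches and ambiguous multiple matches both raise.
    """
    seq, _ = model.chain_sequence(chain_id)
    bare = strip_modifications(peptide)
    if not bare:
        raise ValueError("empty peptide after stripping modifications")
    spans = []
    start = seq.find(bare)
    while start != -1:
        spans.append((start + 1, start + len(bare)))
        start = seq.find(bare, start + 1)
    if not spans:
        raise ValueError(f"peptide {bare!r} not found in chain {chain_id}")
    if len(spans) > 1:
        raise ValueError(
            f"peptide {bare!r} matches chain {chain_id} at multiple spans: {spans}"
        )
    return spans[0]


def _atom_mass(atom: gemmi.Atom) -> float:
    return atom.element.weight


def center_of_mass(atoms: list[gemmi.Atom]) -> np.ndarray:
    """Mass-weighted mean position of the atoms (standard atomic masses)."""
    if not atoms:
        raise ValueError("empty atom selection")
    masses = np.array([_atom_mass(a) for a in atoms])
    coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def _span_atoms(
    model: StructureModel, chain_id: str, span: tuple[int, int]
) -> list[gemmi.Atom]:
    """All atoms of resolved residues inside a 1-based span; rejects spans
    with under half of their residues resolved."""
    _, residues = model.chain_sequence(chain_id)
    start, end = span
    selected = residues[start - 1 : end]
    resolved = [res for res in selected if len(res) > 0]
    if len(resolved) < MIN_RESOLVED_FRACTION * (end - start + 1):
        raise ValueError(
            f"span {span} has only {len(resolved)}/{end - start + 1} resolved residues"
        )
    return [atom for res in resolved for atom in res]


def neighborhood_min_distance(
    model: StructureModel, com: np.ndarray, radius: float = VDW_RADIUS
) -> tuple[list[str], float]:
    """Residues with any atom within ``radius`` of the COM, and the minimal
    distance from the COM point and those residues' atoms to any ligand atom.

    The COM itself participates in the minimum: the reported quantity is the
    distance between the peptide-derived reference point (with the amino acids
    surrounding it) and the ligand.
    """
    com = np.asarray(com, dtype=float)
    labels: set[str] = set()
    for res, atom in model.protein_atoms():
        d = np.linalg.norm(np.array([atom.pos.x, atom.pos.y, atom.pos.z]) - com)
        if d <= radius:
            labels.add(f"{res.name}{res.seqid.num}")
    # all atoms of every neighborhood residue, plus the COM point itself
    points = [com]
    for res, atom in model.protein_atoms():
        if f"{res.name}{res.seqid.num}" in labels:
            points.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
    pn = np.array(points)
    pl = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in model.ligand_atoms()])
    dmat = np.linalg.norm(pn[:, None, :] - pl[None, :, :], axis=2)
    return sorted(labels), float(dmat.min())


def estimate_binding_site(
    model: StructureModel,
    chain_id: str,
    ranked_peptides,
    n_peptides: int = 3,
    pool: int = 15,
    radius: float = VDW_RADIUS,
) -> BindingSiteEstimate:
    """Estimate the ligand binding site from the protein's top-scoring peptides.

    ``ranked_peptides`` is the score-ordered list of the candidate protein's
    peptides restricted to the proteome-wide top ``pool``; the top
    ``n_peptides`` that map unambiguously onto the chain contribute. At least
    two mappable peptides are required (a two-peptide COM is accepted when only
    two qualify). The COM is taken over all atoms of the mapped residues; the
    neighborhood is every residue with an atom within ``radius`` of the COM and
    the reported distance is the minimum from neighborhood atoms to ligand
    atoms.
    """
    spans: list[tuple[str, tuple[int, int]]] = []
    for pep in ranked_peptides:
        if len(spans) == n_peptides:
            break
        try:
            span = map_peptide_to_structure(model, chain_id, pep)
            _span_atoms(model, chain_id, span)  # validates resolution
        except ValueError as exc:
            logger.warning("peptide %s skipped: %s", pep, exc)
            continue
        spans.append((pep, span))
    if len(spans) < 2:
        raise ValueError(
            f"insufficient peptides: {len(spans)} mappable of {n_peptides} required"
        )
    atoms = [a for _, span in spans for a in _span_atoms(model, chain_id, span)]
    com = center_of_mass(atoms)
    labels, min_d = neighborhood_min_distance(model, com, radius=radius)
    return BindingSiteEstimate(
        com=com,
        peptides=tuple(p for p, _ in spans),
        residue_ranges=tuple(span for _, span in spans),
        neighborhood_residues=tuple(labels),
        min_distance=min_d,
        within_vdw=min_d <= VDW_RADIUS,
    )


def random_peptide_null(
    model: StructureModel,
    chain_id: str,
    observed: float | None = None,
    k: int = 3,
    n_samples: int = 100,
    min_len: int = 7,
    max_len: int = 25,
    radius: float = VDW_RADIUS,
    seed: int = 0,
) -> tuple[np.ndarray, float | None]:
    """Null distribution of min_distance from k random contiguous spans.

    Span lengths are uniform in [min_len, max_len] (tryptic-like peptide
    lengths); each draw applies the same COM/neighborhood geometry as
    ``estimate_binding_site``. Returns the sampled distances and, when an
    observed distance is supplied, its left-tail quantile in the null.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    seq, residues = model.chain_sequence(chain_id)
    n = len(seq)
    if n < min_len:
        raise ValueError("chain too short to sample spans")
    max_len = min(max_len, n)
    rng = np.random.default_rng(seed)
    dists = np.empty(n_samples)
    for i in range(n_samples):
        atoms: list[gemmi.Atom] = []
        guard = 0
        spans_drawn = 0
        while spans_drawn < k:
            guard += 1
            if guard > 1000:
                raise ValueError("infeasible sampling: too few resolved spans")
            length = int(rng.integers(min_len, max_len + 1))
            start = int(rng.integers(1, n - length + 2))
            try:
                atoms_i = _span_atoms(model, chain_id, (start, start + length - 1))
            except ValueError:
                continue
            atoms.extend(atoms_i)
            spans_drawn += 1
        com = center_of_mass(atoms)
        _, dists[i] = neighborhood_min_distance(model, com, radius=radius)
    quantile = None
    if observed is not None:
        quantile = float(np.mean(dists <= observed))
    return dists, quantile
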