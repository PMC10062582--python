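"""Atomic models: read/write PDB and mmCIF, enumerate candidate ribose sites.

The in-memory model is a plain hierarchy of chains, residues and heavy atoms in
Å. Only the first model block of multi-model files is kept; for alternate
conformations the highest-occupancy conformer of each atom wins; hydrogens are
dropped (the screen probes heavy-atom geometry only). Residues are addressed by
author numbering throughout, matching how modification sites are reported in
the literature (e.g. A1781 of the yeast 18S rRNA).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import FormatError

__all__ = [
    "Atom", "Residue", "Chain", "AtomicModel", "CandidateSite",
    "read_model", "write_model", "select_candidates",
]


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray          # (3,) float, Å
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names: Sequence[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    def add_atom(self, atom: Atom) -> None:
        if self.atom(atom.name) is not None:
            raise ValueError(
                f"residue {self.chain_id}{self.seq_id}: duplicate atom name {atom.name!r}")
        self.atoms.append(atom)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class AtomicModel:
    chains: list[Chain] = field(default_factory=list)
    source_format: Optional[str] = None  # "pdb" | "mmcif" | None (built in memory)

    def iter_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.iter_residues():
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def find_residue(self, chain_id: str, seq_id: int) -> Optional[Residue]:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                for res in chain.residues:
                    if res.seq_id == seq_id:
                        return res
        return None

    def coordinates(self) -> np.ndarray:
        """All atom positions as an (N, 3) array, in model order."""
        coords = [a.position for _, a in self.iter_atoms()]
        return np.asarray(coords, dtype=float).reshape(-1, 3)

    def copy(self) -> "AtomicModel":
        return copy.deepcopy(self)


@dataclass
class CandidateSite:
    """A residue nominated for hypothetical methylation."""
    chain_id: str
    seq_id: int
    parent_atoms_present: bool
    reason_excluded: Optional[str] = None

    def __post_init__(self):
        if not self.parent_atoms_present and not self.reason_excluded:
            raise ValueError("excluded site requires a non-empty reason_excluded")

    @property
    def residue_ref(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_id)


_FORMAT_BY_EXT = {
    ".pdb": "pdb", ".ent": "pdb",
    ".cif": "mmcif", ".mmcif": "mmcif",
}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("pdb", "mmcif"):
            raise FormatError(f"unknown model format {fmt!r} (expected 'pdb' or 'mmcif')")
        return fmt
    ext = path.suffix.lower()
    if ext not in _FORMAT_BY_EXT:
        raise FormatError(f"cannot infer model format from extension {ext!r} of {path}")
    return _FORMAT_BY_EXT[ext]


def read_model(path, format: Optional[str] = None) -> AtomicModel:
    """Read an atomic model from a PDB or mmCIF file.

    Keeps the first model block only; for altloc groups the highest-occupancy
    conformer is retained; hydrogens and deuteriums are discarded.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"model file not found: {path}")
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no model block in {path}")

    model = AtomicModel(source_format=fmt)
    gm = st[0]
    for gchain in gm:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(chain_id=gchain.name, seq_id=gres.seqid.num, name=gres.name)
            # highest-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            for ga in gres:
                if ga.name in best and best[ga.name] is ga:
                    res.atoms.append(Atom(
                        name=ga.name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        b_factor=ga.b_iso,
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                    ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if model.n_atoms() == 0:
        raise FormatError(f"zero atoms parsed from {path}")
    return model


def _to_gemmi(model: AtomicModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "omescan"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.b_iso = atom.b_factor
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gm.add_chain(gchain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: AtomicModel, path, format: Optional[str] = None) -> None:
    """Write a model as PDB or mmCIF; the emitted file re-parses to equality
    within format precision (1e-3 Å for PDB, 1e-4 Å for mmCIF)."""
    if model.n_atoms() == 0:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    fmt = _infer_format(path, format)
    st = _to_gemmi(model)
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise FormatError(f"failed to write {path}: {exc}") from exc


def select_candidates(model: AtomicModel, spec) -> list[CandidateSite]:
    """Enumerate candidate modification sites in model order.

    One site per residue whose component code is in ``spec.target_residue_codes``.
    Residues missing any of the parent atoms needed to build the adduct frame
    are returned flagged (``parent_atoms_present=False``) with the missing atom
    named, and are excluded from placement downstream.
    """
    required = spec.required_parent_atoms
    sites: list[CandidateSite] = []
    for res in model.iter_residues():
        if res.name not in spec.target_residue_codes:
            continue
        missing = [n for n in required if res.atom(n) is None]
        if missing:
            sites.append(CandidateSite(
                chain_id=res.chain_id, seq_id=res.seq_id,
                parent_atoms_present=False,
                reason_excluded="missing " + ", ".join(missing)))
        else:
            sites.append(CandidateSite(
                chain_id=res.chain_id, seq_id=res.seq_id,
                parent_atoms_present=True))
    return sites
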