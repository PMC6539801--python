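"""Structure parsing and SiRMS atom labelling.

Each atom of a parsed molecule carries four physicochemical properties used
to label simplex fragments: an empirical partial charge (e), an atomic
lipophilicity (logP) contribution, an atomic molar-refractivity contribution,
and an H-bond role (acceptor / donor / indifferent).  The three numeric
properties are discretised into four bins A–D with fixed, upper-inclusive
cut points; the H-bond role and the element symbol act as categorical
labelling schemes of their own.

Partial charges are iteratively-equalised (Gasteiger) charges and the
logP / refractivity contributions follow the Crippen atomic scheme, both as
implemented in RDKit.  These are open empirical surrogates for the
proprietary calculator originally used to derive such labels; bin structure
and everything downstream are independent of the backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Lipinski, rdMolDescriptors, rdPartialCharges

RDLogger.DisableLog("rdApp.*")

AROMATIC_ORDER = 1.5  # internal bond-order code for aromatic bonds

HBOND_LABELS = ("A", "D", "I")


class StructureParseError(ValueError):
    """Raised when a SMILES string or SDF block cannot be parsed."""


class PropertyAssignmentError(RuntimeError):
    """Raised when an atomic property cannot be computed for some atom."""


@dataclass
class Atom:
    """One atom with the four SiRMS labelling properties.

    Numeric properties are ``None`` until :func:`assign_atom_properties`
    has run; ``hbond`` is one of ``A`` (acceptor), ``D`` (donor) or
    ``I`` (indifferent).
    """

    element: str
    charge: float | None = None
    lipophilicity: float | None = None
    refractivity: float | None = None
    hbond: str | None = None


@dataclass
class Molecule:
    """A 2D molecular graph with per-atom properties.

    ``bonds`` holds ``(i, j, order)`` with ``order`` in ``{1, 2, 3, 1.5}``
    (1.5 = aromatic).  ``explicit_hydrogens`` records whether hydrogens are
    part of the graph; the simplex enumeration operates on whatever atoms
    are present.
    """

    compound_id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    explicit_hydrogens: bool
    density: float | None = None
    molar_mass: float | None = None
    _rdkit_mol: Chem.Mol | None = field(default=None, repr=False, compare=False)
    _adjacency: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-loop on atom {i} in {self.compound_id}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i},{j}) in {self.compound_id}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def adjacency(self) -> dict[int, dict[int, float]]:
        """Neighbour map ``{i: {j: order}}``, built lazily."""
        if self._adjacency is None:
            adj: dict[int, dict[int, float]] = {i: {} for i in range(self.n_atoms)}
            for i, j, order in self.bonds:
                adj[i][j] = order
                adj[j][i] = order
            self._adjacency = adj
        return self._adjacency

    def properties_assigned(self) -> bool:
        return all(
            a.charge is not None
            and a.lipophilicity is not None
            and a.refractivity is not None
            and a.hbond in HBOND_LABELS
            for a in self.atoms
        )


@dataclass(frozen=True)
class BinScheme:
    """A labelling scheme: three ascending cut points for numeric schemes,
    ``None`` for the categorical H-bond and element schemes."""

    name: str
    cuts: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.cuts is not None and not (self.cuts[0] < self.cuts[1] < self.cuts[2]):
            raise ValueError(f"cut points must ascend, got {self.cuts}")


CHARGE = BinScheme("CHARGE", (-0.05, 0.0, 0.05))
LIPOPHILICITY = BinScheme("LIPOPHILICITY", (-0.5, 0.0, 0.5))
REFRACTIVITY = BinScheme("REFRACTIVITY", (1.5, 3.0, 8.0))
HB = BinScheme("HB")
ELEMENT = BinScheme("elm")

ALL_SCHEMES: tuple[BinScheme, ...] = (CHARGE, LIPOPHILICITY, REFRACTIVITY, HB, ELEMENT)

_SCHEMES_BY_NAME = {s.name: s for s in ALL_SCHEMES}


def scheme_by_name(name: str) -> BinScheme:
    try:
        return _SCHEMES_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown labelling scheme {name!r}; "
                       f"known: {sorted(_SCHEMES_BY_NAME)}") from None


def bin_value(value: float, scheme: BinScheme) -> str:
    """Discretise ``value`` into A/B/C/D under ``scheme``.

    Intervals are upper-inclusive: ``value <= cut1 -> A``,
    ``cut1 < value <= cut2 -> B``, ``cut2 < value <= cut3 -> C``,
    ``value > cut3 -> D``.
    """
    if scheme.cuts is None:
        raise ValueError(f"scheme {scheme.name!r} is categorical, not binnable")
    if value is None or math.isnan(value):
        raise ValueError(f"cannot bin NaN under scheme {scheme.name}")
    c1, c2, c3 = scheme.cuts
    if value <= c1:
        return "A"
    if value <= c2:
        return "B"
    if value <= c3:
        return "C"
    return "D"


def _bond_order(bond: Chem.Bond) -> float:
    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return AROMATIC_ORDER
    order = bond.GetBondTypeAsDouble()
    if order not in (1.0, 2.0, 3.0):
        raise StructureParseError(f"unsupported bond order {order}")
    return order


def parse_molecule(record: str, compound_id: str, add_hydrogens: bool = True) -> Molecule:
    """Parse a SMILES string or an SDF/MOL (V2000) block into a :class:`Molecule`.

    Records containing a newline are treated as MOL blocks, everything else
    as SMILES.  With ``add_hydrogens`` the hydrogens are made explicit graph
    atoms and participate in fragment enumeration.
    """
    record = record.rstrip()
    if "\n" in record:
        rd = Chem.MolFromMolBlock(record, sanitize=True)
    else:
        rd = Chem.MolFromSmiles(record, sanitize=True)
    if rd is None:
        raise StructureParseError(
            f"could not parse structure for compound {compound_id!r}: {record[:60]!r}"
        )
    if add_hydrogens:
        rd = Chem.AddHs(rd)
    atoms = [Atom(element=a.GetSymbol()) for a in rd.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_order(b)) for b in rd.GetBonds()
    ]
    return Molecule(
        compound_id=compound_id,
        atoms=atoms,
        bonds=bonds,
        explicit_hydrogens=add_hydrogens,
        _rdkit_mol=rd,
    )


def read_smiles_file(path, add_hydrogens: bool = True) -> list[Molecule]:
    """Read a tab-separated SMILES file (``id<TAB>smiles``, one per line)."""
    mols = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                compound_id, smiles = line.split("\t")
            except ValueError:
                raise StructureParseError(
                    f"line {line_no}: expected 'id<TAB>smiles', got {line!r}"
                ) from None
            mols.append(parse_molecule(smiles, compound_id, add_hydrogens))
    return mols


def _donor_acceptor_sets(rd: Chem.Mol) -> tuple[set[int], set[int]]:
    donors = {i for (i,) in rd.GetSubstructMatches(Lipinski.HDonorSmarts)}
    acceptors = {i for (i,) in rd.GetSubstructMatches(Lipinski.HAcceptorSmarts)}
    return donors, acceptors


def hbond_label(mol: Molecule, atom_index: int) -> str:
    """H-bond role of one atom: ``D`` donor, ``A`` acceptor, ``I`` indifferent.

    Amphiprotic heavy atoms (e.g. a hydroxyl oxygen, both donor-bearing and
    acceptor) resolve to ``D``: donor takes precedence because the single-label
    scheme admits no combined state.  An explicit hydrogen bonded to a donor
    heavy atom is itself labelled ``D`` (it is the donated hydrogen).
    """
    rd = mol._rdkit_mol
    if rd is None:
        raise PropertyAssignmentError(
            f"molecule {mol.compound_id!r} has no structure backend for H-bond typing"
        )
    donors, acceptors = _donor_acceptor_sets(rd)
    return _hbond_label_from_sets(mol, atom_index, donors, acceptors)


def _hbond_label_from_sets(
    mol: Molecule, atom_index: int, donors: set[int], acceptors: set[int]
) -> str:
    if mol.atoms[atom_index].element == "H":
        for j in mol.adjacency[atom_index]:
            if j in donors:
                return "D"
        return "I"
    if atom_index in donors:
        return "D"
    if atom_index in acceptors:
        return "A"
    return "I"


def assign_atom_properties(mol: Molecule) -> Molecule:
    """Populate charge, lipophilicity, refractivity and H-bond role in place.

    Deterministic: repeated calls on the same parsed structure produce
    identical property vectors.
    """
    rd = mol._rdkit_mol
    if rd is None:
        raise PropertyAssignmentError(
            f"molecule {mol.compound_id!r} was not produced by parse_molecule"
        )
    rdPartialCharges.ComputeGasteigerCharges(rd)
    contribs = rdMolDescriptors._CalcCrippenContribs(rd)
    donors, acceptors = _donor_acceptor_sets(rd)
    for idx, atom in enumerate(mol.atoms):
        charge = rd.GetAtomWithIdx(idx).GetDoubleProp("_GasteigerCharge")
        logp, mr = contribs[idx]
        if any(math.isnan(v) or math.isinf(v) for v in (charge, logp, mr)):
            raise PropertyAssignmentError(
                f"property calculation failed on atom {idx} "
                f"({atom.element}) of {mol.compound_id!r}"
            )
        atom.charge = float(charge)
        atom.lipophilicity = float(logp)
        atom.refractivity = float(mr)
        atom.hbond = _hbond_label_from_sets(mol, idx, donors, acceptors)
    return mol


def atom_label(mol: Molecule, atom_index: int, scheme: BinScheme) -> str:
    """Label one atom under a scheme (A–D bin, H-bond role, or element)."""
    atom = mol.atoms[atom_index]
    if scheme.name == "elm":
        return atom.element
    if scheme.name == "HB":
        if atom.hbond not in HBOND_LABELS:
            raise PropertyAssignmentError(
                f"atom {atom_index} of {mol.compound_id!r} has no H-bond label"
            )
        return atom.hbond
    value = {
        "CHARGE": atom.charge,
        "LIPOPHILICITY": atom.lipophilicity,
        "REFRACTIVITY": atom.refractivity,
    }[scheme.name]
    if value is None:
        raise PropertyAssignmentError(
            f"atom {atom_index} of {mol.compound_id!r} lacks the "
            f"{scheme.name} property; run assign_atom_properties first"
        )
    return bin_value(value, scheme)
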