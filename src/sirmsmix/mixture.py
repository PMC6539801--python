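"""Mixture-level descriptors for binary miscible liquid mixtures.

Two descriptor blocks describe a binary mixture of compounds 1 and 2 with
mole fractions x1 <= x2, x1 + x2 = 1:

* D_S — mole-fraction weighted single-compound counts,
  ``D_S = x1*D1 + x2*D2``;
* D_M — cross-compound simplex counts (4-atom fragments drawing atoms from
  both compounds) scaled by the doubled minor fraction,
  ``D_M = 2*x1*D_{1+2}``, so an equimolar mixture keeps the raw cross
  counts and a vanishing minor component kills the mixture block.

Volume fractions from the literature are converted to mole fractions via
densities and molar masses before weighting.  The sample matrix is the
concatenation of the two blocks over the union of descriptor names, with
constant columns pruned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chemistry import (
    ALL_SCHEMES,
    BinScheme,
    Molecule,
    assign_atom_properties,
    atom_label,
    parse_molecule,
)
from .simplex import (
    DEFAULT_SIZE,
    SimplexFragment,
    _pattern_key,
    canonical_pattern,
    descriptor_name,
    induced_bonds,
    single_compound_descriptors,
)

FRACTION_TOL = 1e-9

MIXTURE_CSV_COLUMNS = [
    "sample_id",
    "smiles_1",
    "smiles_2",
    "frac_type",
    "frac_1",
    "frac_2",
    "density_1",
    "density_2",
    "mw_1",
    "mw_2",
    "ait_K",
]


class MixtureInputError(ValueError):
    pass


@dataclass
class MixtureSample:
    """One binary mixture: two compounds, mole fractions (x1 <= x2) and an
    optional observed auto-ignition temperature in kelvin."""

    sample_id: str
    compound_1: Molecule
    compound_2: Molecule
    x1: float
    x2: float
    ait_K: float | None = None
    swapped: bool = False  # set when inputs were reordered to enforce x1 <= x2

    def __post_init__(self) -> None:
        if abs(self.x1 + self.x2 - 1.0) > FRACTION_TOL:
            raise MixtureInputError(
                f"sample {self.sample_id!r}: mole fractions must sum to 1, "
                f"got {self.x1} + {self.x2}"
            )
        if self.x1 < -FRACTION_TOL or self.x2 < -FRACTION_TOL:
            raise MixtureInputError(f"sample {self.sample_id!r}: negative fraction")
        if self.x1 > self.x2:
            self.compound_1, self.compound_2 = self.compound_2, self.compound_1
            self.x1, self.x2 = self.x2, self.x1
            self.swapped = not self.swapped

    @property
    def compound_ids(self) -> tuple[str, str]:
        return (self.compound_1.compound_id, self.compound_2.compound_id)


def volume_to_mole(
    v1: float, v2: float, rho1: float, rho2: float, mw1: float, mw2: float
) -> tuple[float, float, bool]:
    """Convert volume fractions to mole fractions.

    x_i is proportional to v_i * rho_i / mw_i.  Returns ``(x1, x2, swapped)``
    ordered so x1 <= x2; ``swapped`` records whether the inputs were
    reordered.
    """
    if rho1 <= 0 or rho2 <= 0 or mw1 <= 0 or mw2 <= 0:
        raise MixtureInputError("densities and molar masses must be positive")
    if v1 < 0 or v2 < 0 or v1 + v2 <= 0:
        raise MixtureInputError("volume fractions must be nonnegative, not both zero")
    n1 = v1 * rho1 / mw1
    n2 = v2 * rho2 / mw2
    x1 = n1 / (n1 + n2)
    x2 = n2 / (n1 + n2)
    if x1 > x2:
        return x2, x1, True
    return x1, x2, False


def weighted_single_descriptors(
    d1: dict[str, float], d2: dict[str, float], x1: float, x2: float
) -> dict[str, float]:
    """Mole-fraction weighted single-compound block: x1*D1 + x2*D2 over the
    union of names, missing names counting as zero."""
    if x1 < 0 or x2 < 0:
        raise MixtureInputError("mole fractions must be nonnegative")
    if abs(x1 + x2 - 1.0) > FRACTION_TOL:
        raise MixtureInputError(f"mole fractions must sum to 1, got {x1 + x2}")
    out: dict[str, float] = {}
    for name in d1.keys() | d2.keys():
        out[name] = x1 * d1.get(name, 0.0) + x2 * d2.get(name, 0.0)
    return out


def weighted_mixture_descriptors(
    d12: dict[str, float], x1: float
) -> dict[str, float]:
    """Cross-compound block scaled by the doubled minor mole fraction."""
    if x1 < 0 or x1 > 0.5 + FRACTION_TOL:
        raise MixtureInputError(
            f"expected the minor mole fraction (0 <= x1 <= 0.5), got {x1}"
        )
    return {name: 2.0 * x1 * v for name, v in d12.items()}


def cross_compound_simplexes(
    mol1: Molecule, mol2: Molecule, k: int = DEFAULT_SIZE
) -> list[SimplexFragment]:
    """All k-atom fragments spanning both compounds: a atoms from mol1 and
    k-a from mol2 for a in 1..k-1, induced bonds only within each compound.

    Total count is sum_a C(n1,a)*C(n2,k-a).
    """
    frags: list[SimplexFragment] = []
    for a in range(1, k):
        b = k - a
        if mol1.n_atoms < a or mol2.n_atoms < b:
            continue
        for sub1 in itertools.combinations(range(mol1.n_atoms), a):
            bonds1 = induced_bonds(mol1, sub1)
            for sub2 in itertools.combinations(range(mol2.n_atoms), b):
                bonds2 = tuple(
                    (i + a, j + a, order) for i, j, order in induced_bonds(mol2, sub2)
                )
                frags.append(
                    SimplexFragment(
                        parents=(mol1,) * a + (mol2,) * b,
                        atom_indices=sub1 + sub2,
                        induced_bonds=bonds1 + bonds2,
                    )
                )
    return frags


# --- factored cross-compound counting --------------------------------------
#
# Bonds never span the two compounds, so the connected parts of a cross
# fragment are parts of each compound's own sub-fragment.  We precompute, per
# molecule / scheme / part size s in 1..k-1, how often each multiset of
# canonical part strings occurs among the C(n,s) subsets; combining the two
# tables then counts every cross fragment without materialising it.  The
# literal enumeration above is kept as the reference route and the two are
# cross-checked in the test suite.


def _part_table(
    mol: Molecule, scheme: BinScheme, size: int, aromatic_glyph: str = "-"
) -> dict[tuple[str, ...], int]:
    cache = getattr(mol, "_part_tables", None)
    if cache is None:
        cache = {}
        mol._part_tables = cache  # type: ignore[attr-defined]
    key = (scheme.name, size, aromatic_glyph)
    if key in cache:
        return cache[key]
    labels_all = tuple(atom_label(mol, i, scheme) for i in range(mol.n_atoms))
    table: dict[tuple[str, ...], int] = {}
    for subset in itertools.combinations(range(mol.n_atoms), size):
        bonds = induced_bonds(mol, subset)
        labels = tuple(labels_all[a] for a in subset)
        pattern = canonical_pattern(labels, list(bonds), scheme, aromatic_glyph)
        parts = tuple(sorted(pattern.split("."), key=_pattern_key))
        table[parts] = table.get(parts, 0) + 1
    cache[key] = table
    return table


def cross_compound_descriptors(
    mol1: Molecule,
    mol2: Molecule,
    schemes: tuple[BinScheme, ...] = ALL_SCHEMES,
    k: int = DEFAULT_SIZE,
    aromatic_glyph: str = "-",
) -> dict[str, int]:
    """Occurrence counts of canonical cross-compound (scope M) names."""
    counts: dict[str, int] = {}
    for scheme in schemes:
        for a in range(1, k):
            b = k - a
            if mol1.n_atoms < a or mol2.n_atoms < b:
                continue
            t1 = _part_table(mol1, scheme, a, aromatic_glyph)
            t2 = _part_table(mol2, scheme, b, aromatic_glyph)
            for parts1, c1 in t1.items():
                for parts2, c2 in t2.items():
                    pattern = ".".join(sorted(parts1 + parts2, key=_pattern_key))
                    name = descriptor_name("M", scheme, pattern, k)
                    counts[name] = counts.get(name, 0) + c1 * c2
    return counts


# --- matrix assembly --------------------------------------------------------


@dataclass
class DescriptorMatrix:
    """Samples x descriptors, single-compound block (D_S) first, then the
    mixture block (D_M); constant columns already pruned."""

    frame: pd.DataFrame
    s_columns: list[str]
    m_columns: list[str]
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)


def _single_descriptor_cache(
    mol: Molecule, schemes: tuple[BinScheme, ...], k: int, aromatic_glyph: str
) -> dict[str, int]:
    cache = getattr(mol, "_single_descriptors", None)
    if cache is None:
        cache = {}
        mol._single_descriptors = cache  # type: ignore[attr-defined]
    key = (tuple(s.name for s in schemes), k, aromatic_glyph)
    if key not in cache:
        cache[key] = single_compound_descriptors(mol, schemes, k, aromatic_glyph)
    return cache[key]


def build_descriptor_matrix(
    samples: list[MixtureSample],
    schemes: tuple[BinScheme, ...] = ALL_SCHEMES,
    k: int = DEFAULT_SIZE,
    aromatic_glyph: str = "-",
    prune_constant: bool = True,
) -> DescriptorMatrix:
    """Assemble the D_S ++ D_M matrix for a list of mixture samples.

    Descriptor names absent from a sample are zero-filled; zero-variance
    columns are dropped (and reported) because they carry no information and
    would make any least-squares design singular.
    """
    if not samples:
        raise MixtureInputError("no samples given")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MixtureInputError(f"duplicate sample ids: {dupes}")

    cross_cache: dict[tuple[int, int], dict[str, int]] = {}
    rows: list[dict[str, float]] = []
    for s in samples:
        d1 = _single_descriptor_cache(s.compound_1, schemes, k, aromatic_glyph)
        d2 = _single_descriptor_cache(s.compound_2, schemes, k, aromatic_glyph)
        ckey = tuple(sorted((id(s.compound_1), id(s.compound_2))))
        if ckey not in cross_cache:
            cross_cache[ckey] = cross_compound_descriptors(
                s.compound_1, s.compound_2, schemes, k, aromatic_glyph
            )
        ds = weighted_single_descriptors(d1, d2, s.x1, s.x2)
        dm = weighted_mixture_descriptors(cross_cache[ckey], min(s.x1, s.x2))
        row = dict(ds)
        row.update(dm)
        rows.append(row)

    frame = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id")).fillna(0.0)
    s_cols = sorted(c for c in frame.columns if c.startswith("|S|"))
    m_cols = sorted(c for c in frame.columns if c.startswith("|M|"))
    frame = frame[s_cols + m_cols]

    dropped: list[str] = []
    if prune_constant:
        nunique = frame.nunique()
        dropped = [c for c in frame.columns if nunique[c] <= 1]
        frame = frame.drop(columns=dropped)
        s_cols = [c for c in s_cols if c not in set(dropped)]
        m_cols = [c for c in m_cols if c not in set(dropped)]
    return DescriptorMatrix(frame=frame, s_columns=s_cols, m_columns=m_cols,
                            dropped_constant=dropped)


# --- CSV input --------------------------------------------------------------


def read_mixtures_csv(
    path: str | Path, add_hydrogens: bool = True
) -> list[MixtureSample]:
    """Read the mixtures CSV dialect into property-assigned samples.

    Columns: sample_id, smiles_1, smiles_2, frac_type in {mole, volume},
    frac_1, frac_2, density_1, density_2, mw_1, mw_2, ait_K (blank allowed
    for prediction-only rows).  Compound structures repeated across rows are
    parsed once and shared, so descriptor caches are reused.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in MIXTURE_CSV_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise MixtureInputError(f"mixtures CSV lacks required columns: {missing}")

    mol_cache: dict[str, Molecule] = {}

    def get_mol(smiles: str) -> Molecule:
        if smiles not in mol_cache:
            mol = parse_molecule(smiles, compound_id=smiles, add_hydrogens=add_hydrogens)
            assign_atom_properties(mol)
            mol_cache[smiles] = mol
        return mol_cache[smiles]

    samples: list[MixtureSample] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            m1, m2 = get_mol(row.smiles_1), get_mol(row.smiles_2)
            f1, f2 = float(row.frac_1), float(row.frac_2)
            if row.frac_type == "volume":
                rho1, rho2 = float(row.density_1), float(row.density_2)
                mw1, mw2 = float(row.mw_1), float(row.mw_2)
                x1, x2, swapped = volume_to_mole(f1, f2, rho1, rho2, mw1, mw2)
                if swapped:
                    m1, m2 = m2, m1
            elif row.frac_type == "mole":
                x1, x2 = f1, f2
            else:
                raise MixtureInputError(
                    f"frac_type must be 'mole' or 'volume', got {row.frac_type!r}"
                )
            ait = getattr(row, "ait_K", None)
            ait_val = None if ait is None or pd.isna(ait) else float(ait)
            samples.append(
                MixtureSample(
                    sample_id=str(row.sample_id),
                    compound_1=m1,
                    compound_2=m2,
                    x1=x1,
                    x2=x2,
                    ait_K=ait_val,
                )
            )
        except MixtureInputError as exc:
            raise MixtureInputError(f"line {line_no}: {exc}") from exc
    if len({s.sample_id for s in samples}) != len(samples):
        ids = [s.sample_id for s in samples]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MixtureInputError(f"duplicate sample ids: {dupes}")
    return samples
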