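"""Synthetic binary-mixture datasets with a planted linear response.

Experimental auto-ignition temperatures for binary liquid mixtures are
scarce and the reference collection of 132 mixtures over 10 pure compounds
is not redistributable, so the pipeline is exercised on generated data that
mirror its statistical shape: binary mixtures of a fixed 11-compound library
spanning alcohols, acids, esters, benzenes, ketones and alkanes; mole
fractions drawn uniformly and ordered x1 <= x2; and a response that is a
sparse linear function of the *actually computed* simplex descriptors plus
Gaussian noise, affinely rescaled onto the 496.15-798.15 K span of real
mixture AIT data.  The planted truth (active descriptor names, effective
coefficients, noise level, rescale) is recorded so selection and estimation
can be scored against it.

The planted active columns are required to be identifiable: maximum
absolute correlation < 0.8 with any other column and < 0.3 pairwise, and
the signed coefficients are redrawn (deterministically) until every active
column retains a marginal correlation of at least 0.15 with the noiseless
signal.  Simplex descriptor blocks are strongly collinear by construction
(mixture columns all share the 2*x1 factor over only ~50 compound pairs),
so recovery of a planted column that is mimicked by a near-duplicate, or
whose effect is cancelled by correlated co-actives, is ill-posed for any
selection method; a planted-recovery benchmark has to plant detectable,
separable effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import ALL_SCHEMES, Molecule, assign_atom_properties, parse_molecule
from .mixture import (
    MIXTURE_CSV_COLUMNS,
    DescriptorMatrix,
    MixtureSample,
    build_descriptor_matrix,
)

TARGET_RANGE_K = (496.15, 798.15)


@dataclass(frozen=True)
class CompoundEntry:
    name: str
    smiles: str
    density_g_ml: float
    molar_mass_g_mol: float
    compound_class: str


# Densities (20 C) and molar masses from standard handbook values.
_LIBRARY: tuple[CompoundEntry, ...] = (
    CompoundEntry("ethanol", "CCO", 0.789, 46.07, "alcohol"),
    CompoundEntry("1-propanol", "CCCO", 0.803, 60.10, "alcohol"),
    CompoundEntry("acetic acid", "CC(=O)O", 1.049, 60.05, "acid"),
    CompoundEntry("propanoic acid", "CCC(=O)O", 0.990, 74.08, "acid"),
    CompoundEntry("ethyl acetate", "CCOC(C)=O", 0.902, 88.11, "ester"),
    CompoundEntry("benzene", "c1ccccc1", 0.876, 78.11, "benzene"),
    CompoundEntry("toluene", "Cc1ccccc1", 0.867, 92.14, "benzene"),
    CompoundEntry("acetone", "CC(C)=O", 0.791, 58.08, "ketone"),
    CompoundEntry("2-butanone", "CCC(C)=O", 0.805, 72.11, "ketone"),
    CompoundEntry("n-hexane", "CCCCCC", 0.659, 86.18, "alkane"),
    CompoundEntry("n-heptane", "CCCCCCC", 0.684, 100.21, "alkane"),
)


def compound_library() -> tuple[CompoundEntry, ...]:
    """Built-in library of pure compounds spanning the six chemical classes
    found in mixture AIT data (alcohols, acids, esters, benzenes, ketones,
    alkanes)."""
    return _LIBRARY


_mol_cache: dict[tuple[str, bool], Molecule] = {}


def library_molecules(add_hydrogens: bool = True) -> dict[str, Molecule]:
    """Parsed, property-assigned molecules for the library, cached so that
    descriptor tables are computed once per process."""
    out = {}
    for entry in _LIBRARY:
        key = (entry.name, add_hydrogens)
        if key not in _mol_cache:
            mol = parse_molecule(entry.smiles, entry.name, add_hydrogens)
            mol.density = entry.density_g_ml
            mol.molar_mass = entry.molar_mass_g_mol
            _mol_cache[key] = assign_atom_properties(mol)
        out[entry.name] = _mol_cache[key]
    return out


@dataclass
class GroundTruth:
    """The planted model behind a generated dataset, on the rescaled
    (kelvin) response axis."""

    active_names: list[str]
    intercept_K: float
    coefficients_K: dict[str, float]
    noise_sd_K: float
    rescale_a: float
    rescale_b: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


@dataclass
class SyntheticDataset:
    mixtures: pd.DataFrame  # the mixtures CSV dialect
    truth: GroundTruth
    samples: list[MixtureSample]
    matrix: DescriptorMatrix
    y: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        self.mixtures.to_csv(path, index=False, float_format="%.10g")


def _random_pair_plan(n_mixtures: int, names: list[str], rng) -> list[tuple[str, str]]:
    pairs = []
    for _ in range(n_mixtures):
        i, j = rng.choice(len(names), size=2, replace=False)
        pairs.append((names[int(i)], names[int(j)]))
    return pairs


def _splittable_pair_plan(names: list[str]) -> list[tuple[str, str]]:
    """132 mixtures over 10 compounds arranged so withholding the last two
    compounds sends exactly 33 mixtures (25%) to the test set."""
    assert len(names) >= 10
    names = names[:10]
    core, held = names[:8], names[8:10]
    core_pairs = [(core[i], core[j]) for i in range(8) for j in range(i + 1, 8)]
    held_pairs = (
        [(c, held[0]) for c in core]
        + [(c, held[1]) for c in core]
        + [(held[0], held[1])]
    )
    plan = []
    for idx, pair in enumerate(core_pairs):  # 28 pairs -> 99 train mixtures
        plan.extend([pair] * (4 if idx < 15 else 3))
    for idx, pair in enumerate(held_pairs):  # 17 pairs -> 33 test mixtures
        plan.extend([pair] * (2 if idx < 16 else 1))
    assert len(plan) == 132
    return plan


def _pick_active_columns(
    frame: pd.DataFrame, n_active: int, rng,
    max_external_corr: float = 0.8, max_internal_corr: float = 0.3,
    min_support: float = 0.15,
) -> list[str]:
    """Choose identifiable planted columns; all statistics are computed on
    ``frame``, which may be a training-block restriction of the full
    matrix (a planted signal must be estimable from the rows a model will
    actually be trained on)."""
    X = frame.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Z = Xc / np.where(sd > 0, sd, 1.0)
    corr = np.abs(Z.T @ Z) / len(X)
    np.fill_diagonal(corr, 0.0)
    # support: fraction of samples whose value differs from the column's
    # modal value; near-indicator columns are undetectable planted effects
    support = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        support[j] = 1.0 - counts.max() / len(X)
    # relax the correlation bounds stepwise if the matrix cannot supply
    # n_active decorrelated well-supported columns at the strict setting
    chosen: list[int] = []
    for external in (max_external_corr, 0.85):
        eligible = [j for j in range(X.shape[1])
                    if sd[j] > 0 and support[j] >= min_support
                    and corr[j].max() < external]
        rng.shuffle(eligible)
        for internal in (max_internal_corr, 0.4, 0.5, 0.6, 0.8):
            chosen = []
            for j in eligible:
                if all(corr[j, i] < internal for i in chosen):
                    chosen.append(j)
                if len(chosen) == n_active:
                    break
            if len(chosen) == n_active:
                return [frame.columns[j] for j in sorted(chosen)]
    raise ValueError(
        f"only {len(chosen)} identifiable nonconstant descriptor columns "
        f"available; cannot plant {n_active} active descriptors"
    )


def simulate_dataset(
    n_mixtures: int = 132,
    seed: int = 0,
    noise_sd_K: float = 10.0,
    n_active: int = 6,
    effect_range_K: tuple[float, float] = (30.0, 80.0),
    target_range: tuple[float, float] = TARGET_RANGE_K,
    add_hydrogens: bool = True,
    pair_plan: list[tuple[str, str]] | None = None,
    core_compounds: list[str] | None = None,
) -> SyntheticDataset:
    """Generate a binary-mixture dataset with a planted sparse linear AIT.

    Compound pairs and mole fractions are drawn with the given seed (or taken
    from an explicit ``pair_plan``); the full descriptor matrix is computed
    through the real chemistry/simplex/mixture pipeline; ``n_active``
    identifiable columns receive coefficients whose per-standard-deviation
    effect sizes are uniform in ``effect_range_K`` with random signs; the
    response signal + N(0, noise_sd_K^2) noise is affinely rescaled to span
    ``target_range`` exactly, and the rescaled truth is recorded.

    With ``core_compounds`` the active columns' identifiability statistics
    are evaluated on the mixtures built solely from those compounds — used
    by the splittable dataset so the planted signal stays estimable from
    the compounds-out training block rather than living on descriptor
    columns that are constant there.
    """
    if n_mixtures < 20:
        raise ValueError("need at least 20 mixtures")
    if n_active < 1:
        raise ValueError("need at least one active descriptor")
    rng = np.random.default_rng(seed)
    mols = library_molecules(add_hydrogens)
    names = [e.name for e in _LIBRARY]
    if pair_plan is None:
        pair_plan = _random_pair_plan(n_mixtures, names, rng)
    elif len(pair_plan) != n_mixtures:
        raise ValueError("pair_plan length must equal n_mixtures")

    samples = []
    for i, (c1, c2) in enumerate(pair_plan):
        x = float(rng.uniform(0.05, 0.95))
        x1, x2 = min(x, 1 - x), max(x, 1 - x)
        samples.append(
            MixtureSample(
                sample_id=f"mix{i + 1:03d}",
                compound_1=mols[c1],
                compound_2=mols[c2],
                x1=x1,
                x2=x2,
            )
        )

    matrix = build_descriptor_matrix(samples)
    pick_frame = matrix.frame
    if core_compounds is not None:
        core = set(core_compounds)
        core_ids = [s.sample_id for s in samples if set(s.compound_ids) <= core]
        pick_frame = matrix.frame.loc[core_ids]
    active = _pick_active_columns(pick_frame, n_active, rng)
    D = matrix.frame[active].to_numpy(dtype=float)
    sd = D.std(axis=0)
    # redraw signed effects until every active column keeps a detectable
    # marginal correlation with the noiseless signal (identifiability)
    for _ in range(100):
        beta = (
            rng.uniform(*effect_range_K, size=n_active)
            * rng.choice([-1.0, 1.0], size=n_active)
            / sd
        )
        linear = D @ beta
        marginal = [abs(float(np.corrcoef(D[:, j], linear)[0, 1]))
                    for j in range(n_active)]
        if min(marginal) >= 0.15:
            break
    intercept = 650.0
    signal = intercept + linear
    y_raw = signal + rng.normal(0.0, noise_sd_K, size=n_mixtures)
    lo, hi = float(y_raw.min()), float(y_raw.max())
    if hi - lo <= 0:
        raise ValueError("degenerate planted response")
    a = (target_range[1] - target_range[0]) / (hi - lo)
    b = target_range[0] - a * lo
    y = a * y_raw + b

    truth = GroundTruth(
        active_names=active,
        intercept_K=float(a * intercept + b),
        coefficients_K={nm: float(a * bb) for nm, bb in zip(active, beta)},
        noise_sd_K=float(a * noise_sd_K),
        rescale_a=float(a),
        rescale_b=float(b),
        seed=seed,
    )

    by_name = {e.name: e for e in _LIBRARY}
    rows = []
    for s, ait in zip(samples, y):
        e1, e2 = by_name[s.compound_1.compound_id], by_name[s.compound_2.compound_id]
        rows.append(
            {
                "sample_id": s.sample_id,
                "smiles_1": e1.smiles,
                "smiles_2": e2.smiles,
                "frac_type": "mole",
                "frac_1": s.x1,
                "frac_2": s.x2,
                "density_1": e1.density_g_ml,
                "density_2": e2.density_g_ml,
                "mw_1": e1.molar_mass_g_mol,
                "mw_2": e2.molar_mass_g_mol,
                "ait_K": float(ait),
            }
        )
        s.ait_K = float(ait)
    mixtures = pd.DataFrame(rows, columns=MIXTURE_CSV_COLUMNS)
    return SyntheticDataset(
        mixtures=mixtures, truth=truth, samples=samples, matrix=matrix, y=y
    )


def make_splittable_dataset(seed: int = 0, **kwargs) -> SyntheticDataset:
    """A 132-mixture dataset over 10 compounds constructed so that a
    compounds-out split at 25% can hold out exactly 33 mixtures (99 train)."""
    names = [e.name for e in _LIBRARY]
    plan = _splittable_pair_plan(names)
    return simulate_dataset(n_mixtures=132, seed=seed, pair_plan=plan,
                            core_compounds=names[:8], **kwargs)
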