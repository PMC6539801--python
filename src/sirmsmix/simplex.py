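"""Simplex fragment enumeration and canonical descriptor naming.

A simplex here is a 4-atom fragment: every 4-subset of a molecule's atoms
together with its induced bonds.  Because enumeration runs over atom subsets
rather than bond subgraphs, fully bonded, partially bonded and completely
unbonded topologies all arise naturally.  Each fragment, labelled under one
of the atom-labelling schemes, is rendered into a canonical descriptor name
of the form

    |S|n|||4|||CHARGE|A.A-A-B
    |M|n|||4|||elm|C-C(-C)=O

where ``S``/``M`` marks single-compound vs cross-compound (mixture) scope,
``n`` marks a count-valued descriptor, ``-``/``=``/``#`` are bond glyphs
(orders rendered only under the element scheme; other schemes draw every
bond as ``-``), ``(...)`` encloses branches, and ``.`` separates
disconnected parts.  The canonical pattern is the minimal rendering over all
depth-first traversals of each connected part, under a comparison key that
prefers unbranched chains, with parts sorted and joined by ``.``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

from .chemistry import AROMATIC_ORDER, BinScheme, Molecule, atom_label

DEFAULT_SIZE = 4


class UnlabeledFragmentError(RuntimeError):
    pass


@dataclass
class SimplexFragment:
    """A k-atom fragment with its induced bonds.

    ``parents[t]`` is the molecule owning local atom ``t`` and
    ``atom_indices[t]`` its index there; ``induced_bonds`` uses local
    indices 0..k-1.  ``scope`` is ``"S"`` when all atoms come from one
    compound and ``"M"`` when they span two.
    """

    parents: tuple[Molecule, ...]
    atom_indices: tuple[int, ...]
    induced_bonds: tuple[tuple[int, int, float], ...]

    @property
    def size(self) -> int:
        return len(self.atom_indices)

    @property
    def scope(self) -> str:
        return "S" if len({id(m) for m in self.parents}) == 1 else "M"

    def labels(self, scheme: BinScheme) -> tuple[str, ...]:
        return tuple(
            atom_label(mol, idx, scheme)
            for mol, idx in zip(self.parents, self.atom_indices)
        )


# --- canonical pattern rendering -------------------------------------------

# '(' must sort AFTER atom and bond glyphs so that an unbranched chain
# rendering beats a branched one of the same fragment ("B-B-B-B", not
# "B(-B)-B-B"); plain byte order would do the opposite since '(' < '-'.
_CANON_KEY = str.maketrans({"(": "\x7b", ")": "\x7d"})


def _pattern_key(s: str) -> str:
    return s.translate(_CANON_KEY)


def bond_glyph(order: float, scheme: BinScheme, aromatic_glyph: str = "-") -> str:
    """Glyph for one bond; non-element schemes render every bond as ``-``."""
    if scheme.name != "elm":
        return "-"
    if order == AROMATIC_ORDER:
        return aromatic_glyph
    return {1.0: "-", 2.0: "=", 3.0: "#"}[order]


def _components(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _dfs_plans(start: int, nodes: list[int], adj: dict[int, list[int]]):
    """All rooted DFS spanning trees of a connected graph, as nested tuples
    ``(node, (children...))``, enumerating every child order."""

    def subtrees(u: int, visited: frozenset):
        visited = visited | {u}
        results = []

        def extend(children: tuple, vis: frozenset):
            cands = [v for v in adj[u] if v not in vis]
            if not cands:
                results.append(((u, children), vis))
                return
            for v in cands:
                for sub, vis2 in subtrees(v, vis):
                    extend(children + (sub,), vis2)

        extend((), visited)
        return results

    return [plan for plan, vis in subtrees(start, frozenset()) if len(vis) == len(nodes)]


def _tree_edges(plan) -> set[frozenset]:
    u, children = plan
    out = set()
    for child in children:
        out.add(frozenset((u, child[0])))
        out |= _tree_edges(child)
    return out


def _preorder(plan) -> list[int]:
    u, children = plan
    order = [u]
    for child in children:
        order.extend(_preorder(child))
    return order


def _render_plan(plan, labels: dict[int, str], glyphs: dict[frozenset, str]) -> str:
    """Render one DFS plan to a pattern string; non-tree edges become ring
    closures written SMILES-style (digit at the opening atom, glyph+digit at
    the closing atom)."""
    tree = _tree_edges(plan)
    order = _preorder(plan)
    pos = {u: i for i, u in enumerate(order)}
    back = [e for e in glyphs if e not in tree and len(e) == 2]
    back.sort(key=lambda e: tuple(sorted(pos[u] for u in e)))
    opens: dict[int, list[int]] = {}
    closes: dict[int, list[int]] = {}
    for digit, e in enumerate(back, start=1):
        a, b = sorted(e, key=pos.get)
        opens.setdefault(a, []).append(digit)
        closes.setdefault(b, []).append(digit)
    digit_edge = {digit: e for digit, e in enumerate(back, start=1)}

    def emit(node_plan) -> str:
        u, children = node_plan
        s = labels[u]
        for digit in sorted(opens.get(u, ())):
            s += str(digit)
        for digit in sorted(closes.get(u, ())):
            s += glyphs[digit_edge[digit]] + str(digit)
        for i, child in enumerate(children):
            part = glyphs[frozenset((u, child[0]))] + emit(child)
            s += part if i == len(children) - 1 else "(" + part + ")"
        return s

    return emit(plan)


_component_cache: dict = {}


def _canonical_component(
    nodes: tuple[int, ...],
    labels: dict[int, str],
    edge_glyphs: dict[frozenset, str],
) -> str:
    """Minimal rendering of one connected labelled component."""
    key = (
        tuple(labels[u] for u in nodes),
        tuple(
            sorted(
                (tuple(sorted(nodes.index(u) for u in e)), g)
                for e, g in edge_glyphs.items()
            )
        ),
    )
    hit = _component_cache.get(key)
    if hit is not None:
        return hit
    adj: dict[int, list[int]] = {u: [] for u in nodes}
    for e in edge_glyphs:
        a, b = tuple(e)
        adj[a].append(b)
        adj[b].append(a)
    best: str | None = None
    for start in nodes:
        for plan in _dfs_plans(start, list(nodes), adj):
            s = _render_plan(plan, labels, edge_glyphs)
            if best is None or _pattern_key(s) < _pattern_key(best):
                best = s
    assert best is not None
    _component_cache[key] = best
    return best


def canonical_pattern(
    labels: tuple[str, ...],
    edges: list[tuple[int, int, float]],
    scheme: BinScheme,
    aromatic_glyph: str = "-",
) -> str:
    """Canonical pattern string for a labelled fragment graph."""
    n = len(labels)
    label_map = dict(enumerate(labels))
    comp_strings = []
    comps = _components(n, [(i, j) for i, j, _ in edges])
    for comp in comps:
        comp_set = set(comp)
        glyphs = {
            frozenset((i, j)): bond_glyph(order, scheme, aromatic_glyph)
            for i, j, order in edges
            if i in comp_set and j in comp_set
        }
        comp_strings.append(_canonical_component(tuple(comp), label_map, glyphs))
    comp_strings.sort(key=_pattern_key)
    return ".".join(comp_strings)


def descriptor_name(scope: str, scheme: BinScheme, pattern: str, size: int = 4) -> str:
    return f"|{scope}|n|||{size}|||{scheme.name}|{pattern}"


def canonical_simplex_name(
    frag: SimplexFragment, scheme: BinScheme, aromatic_glyph: str = "-"
) -> str:
    """Canonical descriptor name of a fragment under one labelling scheme.

    Identical fragments (up to atom reordering) map to identical strings.
    """
    try:
        labels = frag.labels(scheme)
    except Exception as exc:  # missing properties surface as a naming error
        raise UnlabeledFragmentError(str(exc)) from exc
    pattern = canonical_pattern(labels, list(frag.induced_bonds), scheme, aromatic_glyph)
    return descriptor_name(frag.scope, scheme, pattern, frag.size)


# --- enumeration ------------------------------------------------------------


def induced_bonds(
    mol: Molecule, atom_subset: tuple[int, ...]
) -> tuple[tuple[int, int, float], ...]:
    """Bonds of ``mol`` with both ends in ``atom_subset``, in local indices."""
    local = {a: t for t, a in enumerate(atom_subset)}
    adj = mol.adjacency
    out = []
    for t, a in enumerate(atom_subset):
        for b, order in adj[a].items():
            u = local.get(b)
            if u is not None and u > t:
                out.append((t, u, order))
    return tuple(out)


def enumerate_simplexes(mol: Molecule, k: int = DEFAULT_SIZE) -> list[SimplexFragment]:
    """All k-atom fragments of one molecule (one per atom subset, C(n,k) in
    total), with induced bonds recorded."""
    if k < 1:
        raise ValueError(f"fragment size must be >= 1, got {k}")
    frags = []
    for subset in itertools.combinations(range(mol.n_atoms), k):
        frags.append(
            SimplexFragment(
                parents=(mol,) * k,
                atom_indices=subset,
                induced_bonds=induced_bonds(mol, subset),
            )
        )
    return frags


def is_connected(frag: SimplexFragment) -> bool:
    return len(_components(frag.size, [(i, j) for i, j, _ in frag.induced_bonds])) == 1


def single_compound_descriptors(
    mol: Molecule,
    schemes: tuple[BinScheme, ...],
    k: int = DEFAULT_SIZE,
    aromatic_glyph: str = "-",
) -> dict[str, int]:
    """Occurrence counts of canonical single-compound simplex names.

    For each scheme the counts sum to C(n_atoms, k).
    """
    counts: dict[str, int] = {}
    adj = mol.adjacency
    label_cache = {
        scheme.name: tuple(atom_label(mol, i, scheme) for i in range(mol.n_atoms))
        for scheme in schemes
    }
    for subset in itertools.combinations(range(mol.n_atoms), k):
        bonds = induced_bonds(mol, subset)
        for scheme in schemes:
            labels = tuple(label_cache[scheme.name][a] for a in subset)
            pattern = canonical_pattern(labels, list(bonds), scheme, aromatic_glyph)
            name = descriptor_name("S", scheme, pattern, k)
            counts[name] = counts.get(name, 0) + 1
    expected = comb(mol.n_atoms, k)
    for scheme in schemes:
        prefix = f"|S|n|||{k}|||{scheme.name}|"
        total = sum(v for n_, v in counts.items() if n_.startswith(prefix))
        assert total == (expected if mol.n_atoms >= k else 0)
    return counts
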