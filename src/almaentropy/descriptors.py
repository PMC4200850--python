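"""Markov-Shannon entropy descriptors of molecular graphs.

A molecule is treated as a hydrogen-suppressed graph whose nodes carry
Pauling electronegativities (chi). A Markov chain walks the graph: from atom
i the walker moves to a neighbour j (or stays put, via a self-loop) with
probability proportional to chi_j. The order-k descriptor theta_k is the
Shannon entropy, in bits by default, of the k-step state distribution
started from the electronegativity-proportional distribution:

    p0(j)    = chi_j / sum(chi)
    Pi(i, j) = chi_j / sum_{l in N(i) u {i}} chi_l   for j in N(i) u {i}
    pk       = p0 . Pi^k
    theta_k  = -sum_j pk(j) log2 pk(j)

theta_k is invariant to atom relabelling and bounded by log2(n atoms), with
equality on vertex-transitive graphs with uniform chi. The self-loop keeps
the chain well defined on isolated atoms; it can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from sklearn.base import BaseEstimator, TransformerMixin

from .electronegativity import chi_of
from .errors import DataError, ParseError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MolecularGraph",
    "MarkovProfile",
    "build_graph",
    "transition_matrix",
    "step_distributions",
    "entropy_theta",
    "markov_profile",
    "descriptor_block",
    "MarkovShannonEncoder",
]


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph with electronegativity node weights.

    Attributes
    ----------
    identifier : str
        Compound id.
    elements : tuple of str
        Element symbol per atom, in a fixed order.
    chi : numpy.ndarray
        Pauling electronegativity per atom, aligned with ``elements``.
    bonds : frozenset of (int, int)
        Unordered atom-index pairs; no self-pairs.
    """

    identifier: str
    elements: tuple[str, ...]
    chi: np.ndarray
    bonds: frozenset

    def __post_init__(self) -> None:
        n = len(self.elements)
        chi = np.asarray(self.chi, dtype=float)
        if chi.shape != (n,):
            raise DataError("chi must have one weight per atom")
        if n and not np.all(chi > 0):
            raise DataError("every electronegativity weight must be positive")
        for i, j in self.bonds:
            if i == j:
                raise DataError(f"self-pair bond ({i},{i}) is not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise DataError(f"bond ({i},{j}) references a missing atom")
        object.__setattr__(self, "chi", chi)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbours(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


@dataclass
class MarkovProfile:
    """Transition matrix, step distributions and entropies of one molecule."""

    transition: np.ndarray
    step_distributions: list = field(default_factory=list)
    entropies: list = field(default_factory=list)


def build_graph(
    smiles: str,
    compound_id: str = "",
    *,
    keep_all_components: bool = False,
) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens are suppressed (RDKit's default heavy-atom graph). For
    disconnected structures (salts, mixtures) only the largest connected
    component is kept unless ``keep_all_components`` is set; a Markov chain
    never mixes across components, so the largest fragment is the molecule
    of interest in the usual salt case.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ParseError(f"SMILES {smiles!r} has no atoms after parsing")
    if not keep_all_components:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumAtoms())
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    chi = np.array([chi_of(sym) for sym in elements])
    bonds = frozenset(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return MolecularGraph(identifier=compound_id, elements=elements, chi=chi,
                          bonds=bonds)


def transition_matrix(graph: MolecularGraph, *, self_loops: bool = True) -> np.ndarray:
    """Row-stochastic electronegativity-weighted walk matrix.

    Entry (i, j) is chi_j normalised over the destination set N(i) plus,
    with ``self_loops`` (the default), atom i itself. Without self-loops an
    isolated atom has no destination and the matrix is undefined.
    """
    n = graph.n_atoms
    if n == 0:
        raise DataError("transition matrix of an empty graph is undefined")
    mask = np.zeros((n, n), dtype=bool)
    if self_loops:
        np.fill_diagonal(mask, True)
    for i, j in graph.bonds:
        mask[i, j] = mask[j, i] = True
    weights = np.where(mask, graph.chi[np.newaxis, :], 0.0)
    row_sums = weights.sum(axis=1)
    if np.any(row_sums == 0):
        bad = int(np.flatnonzero(row_sums == 0)[0])
        raise DataError(
            f"atom {bad} has no walk destination; isolated atoms require "
            "self_loops=True"
        )
    return weights / row_sums[:, np.newaxis]


def step_distributions(
    graph: MolecularGraph, k_max: int, *, self_loops: bool = True
) -> list[np.ndarray]:
    """State distributions p0 ... p_{k_max} of the electronegativity walk."""
    if k_max < 0:
        raise DataError("k_max must be non-negative")
    pi = transition_matrix(graph, self_loops=self_loops)
    p = graph.chi / graph.chi.sum()
    out = [p]
    for _ in range(k_max):
        p = p @ pi
        out.append(p)
    return out


def _shannon_bits(p: np.ndarray, base: float = 2.0) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def entropy_theta(
    graph: MolecularGraph,
    k: int,
    *,
    self_loops: bool = True,
    base: float = 2.0,
) -> float:
    """Markov-Shannon entropy theta_k of one molecular graph, in bits.

    Terms with pk(j) = 0 contribute zero, so theta_k of a single atom is 0
    and theta_k <= log2(n) always.
    """
    if k < 0:
        raise DataError("entropy order k must be non-negative")
    pk = step_distributions(graph, k, self_loops=self_loops)[k]
    return _shannon_bits(pk, base=base)


def markov_profile(
    graph: MolecularGraph,
    k_max: int = 5,
    *,
    self_loops: bool = True,
    base: float = 2.0,
) -> MarkovProfile:
    """Full profile: transition matrix, p0..p_kmax, theta_0..theta_kmax."""
    dists = step_distributions(graph, k_max, self_loops=self_loops)
    return MarkovProfile(
        transition=transition_matrix(graph, self_loops=self_loops),
        step_distributions=dists,
        entropies=[_shannon_bits(p, base=base) for p in dists],
    )


def descriptor_block(
    molecules: Iterable[tuple[str, str]],
    k_max: int = 5,
    *,
    self_loops: bool = True,
    base: float = 2.0,
    keep_all_components: bool = False,
) -> pd.DataFrame:
    """Batch descriptor table: one row of theta_0..theta_kmax per compound.

    Rows keep input order. A per-row ``error`` column records failures
    (unparsable SMILES, unknown elements) without aborting the batch; failed
    rows carry NaN descriptors.
    """
    molecules = list(molecules)
    if not molecules:
        raise DataError("descriptor_block requires at least one molecule")
    cols = [f"theta{k}" for k in range(k_max + 1)]
    rows = []
    for cid, smi in molecules:
        row: dict[str, object] = {"compound_id": cid}
        try:
            g = build_graph(smi, cid, keep_all_components=keep_all_components)
            dists = step_distributions(g, k_max, self_loops=self_loops)
            for k, p in enumerate(dists):
                row[f"theta{k}"] = _shannon_bits(p, base=base)
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - per-row error reporting
            for c in cols:
                row[c] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=["compound_id", *cols, "error"])


class MarkovShannonEncoder(TransformerMixin, BaseEstimator):
    """Transformer from SMILES strings to theta_0..theta_kmax descriptors.

    Parameters
    ----------
    k_max : int, default 5
        Highest entropy order computed; the activity model downstream uses
        theta_5 only, but all lower orders are exported for diagnostics.
    self_loops : bool, default True
        Include the stay-put move in the walk's destination set.
    base : float, default 2.0
        Logarithm base of the entropy (2.0 gives bits).
    keep_all_components : bool, default False
        Keep every fragment of a disconnected structure instead of the
        largest one.

    Examples
    --------
    >>> enc = MarkovShannonEncoder()
    >>> enc.fit_transform(["c1ccccc1"]).round(3)
    array([[2.585, 2.585, 2.585, 2.585, 2.585, 2.585]])
    """

    def __init__(
        self,
        k_max: int = 5,
        *,
        self_loops: bool = True,
        base: float = 2.0,
        keep_all_components: bool = False,
    ) -> None:
        self.k_max = k_max
        self.self_loops = self_loops
        self.base = base
        self.keep_all_components = keep_all_components

    def fit(self, X: Sequence[str], y=None) -> "MarkovShannonEncoder":
        if self.k_max < 0:
            raise DataError("k_max must be non-negative")
        self.n_features_out_ = self.k_max + 1
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        """Return an (n_molecules, k_max + 1) array of entropies in bits."""
        if not hasattr(self, "n_features_out_"):
            self.fit(X)
        out = np.empty((len(X), self.k_max + 1))
        for i, smi in enumerate(X):
            g = build_graph(
                smi, str(i), keep_all_components=self.keep_all_components
            )
            dists = step_distributions(g, self.k_max, self_loops=self.self_loops)
            out[i] = [_shannon_bits(p, base=self.base) for p in dists]
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([f"theta{k}" for k in range(self.k_max + 1)])
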