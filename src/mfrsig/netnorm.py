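"""Network-based normalization of binary mutation profiles.

Every patient's binary profile is forced to carry exactly ``k`` mutated
genes: patients with more than ``k`` mutations have their lowest-ranked
mutated genes switched off, and patients with fewer gain "proxy" mutated
genes.  Ranking uses gene-gene network topology:

* mutated genes always outrank unmutated genes;
* among mutated genes, higher network degree ranks first;
* among unmutated (proxy candidate) genes, more mutated network
  neighbours in this patient ranks first, then higher degree;
* remaining ties break by ascending gene symbol, so the normalization is
  fully deterministic.

``k`` conventionally equals the median mutated-gene count of the training
split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .profiles import ProfileKind, ProfileMatrix


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected gene-gene interaction network (no self-loops)."""

    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("edges must join two distinct genes (no self-loops)")
        if self.edges:
            endpoints = frozenset().union(*self.edges)
            object.__setattr__(self, "nodes", self.nodes | endpoints)

    @classmethod
    def from_edges(cls, edge_iter, extra_nodes=()) -> "GeneNetwork":
        edges = set()
        nodes = set(extra_nodes)
        for a, b in edge_iter:
            nodes.update((a, b))
            if a != b:  # drop self-loops silently
                edges.add(frozenset((a, b)))
        return cls(nodes=frozenset(nodes), edges=frozenset(edges))

    @classmethod
    def from_networkx(cls, graph) -> "GeneNetwork":
        return cls.from_edges(graph.edges(), extra_nodes=graph.nodes())

    @classmethod
    def read_edge_list(cls, path) -> "GeneNetwork":
        """Read a 2-column TSV edge list; 3-column SIF (gene relation gene) accepted."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] == 2:
            pairs = zip(df[0], df[1])
        elif df.shape[1] == 3:  # SIF: source, interaction type, target
            pairs = zip(df[0], df[2])
        else:
            raise ValueError(f"edge list {path} must have 2 (TSV) or 3 (SIF) columns")
        return cls.from_edges(pairs)

    def degree(self, gene: str) -> int:
        return sum(1 for e in self.edges if gene in e)

    def degrees(self, genes) -> np.ndarray:
        """Degree per gene; genes absent from the network get 0."""
        idx = {g: i for i, g in enumerate(genes)}
        out = np.zeros(len(idx), dtype=np.int64)
        for e in self.edges:
            a, b = tuple(e)
            if a in idx:
                out[idx[a]] += 1
            if b in idx:
                out[idx[b]] += 1
        return out

    def adjacency(self, genes) -> np.ndarray:
        """Boolean adjacency restricted to the given gene order."""
        idx = {g: i for i, g in enumerate(genes)}
        a = np.zeros((len(idx), len(idx)), dtype=bool)
        for e in self.edges:
            u, v = tuple(e)
            if u in idx and v in idx:
                a[idx[u], idx[v]] = True
                a[idx[v], idx[u]] = True
        return a


@dataclass(frozen=True)
class NetNormParams:
    """Target number of mutated genes per normalized patient."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def median_mutated_genes(bm: ProfileMatrix, patients=None) -> int:
    """Median per-patient mutated-gene count; half-integer medians round half-up."""
    if bm.kind is not ProfileKind.BM:
        raise ValueError("median_mutated_genes expects a BM profile")
    if patients is None:
        patients = bm.patients
    patients = set(patients)
    if not patients:
        raise ValueError("empty patient set")
    idx = [i for i, p in enumerate(bm.patients) if p in patients]
    if len(idx) != len(patients):
        raise ValueError("patients must be a subset of the profile's patients")
    counts = bm.values[idx, :].sum(axis=1)
    med = float(np.median(counts))
    return int(math.floor(med + 0.5))


def _rank_order(row: np.ndarray, degrees: np.ndarray, mutated_neighbors: np.ndarray) -> np.ndarray:
    """Indices of genes from highest to lowest NetNorM rank.

    ``row`` is the patient's binary vector over lexicographically sorted
    genes, so index order is the final (ascending-symbol) tie-break.
    """
    mutated = row != 0
    # mutated genes sort by degree; proxy candidates by mutated-neighbour
    # count, then degree
    secondary = np.where(mutated, degrees, mutated_neighbors)
    tertiary = degrees
    # np.lexsort: last key is primary; argsort ascending, so negate
    return np.lexsort((np.arange(row.size), -tertiary, -secondary, -mutated.astype(np.int64)))


def rank_patient_genes(bm_row, genes, network: GeneNetwork) -> list[str]:
    """Total NetNorM ranking of all genes for one patient (best first)."""
    genes = list(genes)
    order = np.argsort(genes)
    genes_sorted = [genes[i] for i in order]
    row = np.asarray(bm_row, dtype=float)[order]
    degrees = network.degrees(genes_sorted)
    adj = network.adjacency(genes_sorted)
    mut_nb = adj @ (row != 0)
    ranked = _rank_order(row, degrees, mut_nb.astype(np.int64))
    return [genes_sorted[i] for i in ranked]


def normalize_patient(bm_row, genes, network: GeneNetwork, params: NetNormParams) -> np.ndarray:
    """Binary vector with exactly ``params.k`` ones at the top-ranked genes."""
    genes = list(genes)
    if params.k > len(genes):
        raise ValueError(f"k={params.k} exceeds the {len(genes)}-gene universe")
    ranked = rank_patient_genes(bm_row, genes, network)
    top = set(ranked[: params.k])
    return np.array([1.0 if g in top else 0.0 for g in genes])


def netnorm_profiles(bm: ProfileMatrix, network: GeneNetwork, params: NetNormParams) -> ProfileMatrix:
    """Normalize a whole BM profile matrix to exactly-k mutated genes per patient."""
    if bm.kind is not ProfileKind.BM:
        raise ValueError("netnorm_profiles expects a BM profile")
    n_genes = len(bm.genes)
    if params.k > n_genes:
        raise ValueError(f"k={params.k} exceeds the {n_genes}-gene universe")
    # genes are lexicographically sorted by construction in build_profile,
    # but do not rely on it
    order = np.argsort(bm.genes)
    genes_sorted = [bm.genes[i] for i in order]
    vals = bm.values[:, order]
    degrees = network.degrees(genes_sorted)
    adj = network.adjacency(genes_sorted)

    out_sorted = np.zeros_like(vals)
    for i in range(vals.shape[0]):
        row = vals[i]
        mut_nb = (adj @ (row != 0)).astype(np.int64)
        ranked = _rank_order(row, degrees, mut_nb)
        out_sorted[i, ranked[: params.k]] = 1.0

    out = np.empty_like(out_sorted)
    out[:, order] = out_sorted
    return replace(bm, kind=ProfileKind.NETNORM, values=out)
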