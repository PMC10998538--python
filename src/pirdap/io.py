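"""Domain types and file I/O: piRNA sequences, disease ontology, associations.

Formats are deliberately plain: FASTA for sequences, two-column TSV edge
lists for associations (``pirna_id<TAB>disease_id``), child->parent TSV or
OBO for the ontology, and labelled dense TSV for matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGT")
MIN_SEQ_LEN = 3  # anything shorter cannot be 3-mer tokenized


@dataclass(frozen=True)
class PirnaRecord:
    """A piRNA with a normalized DNA-alphabet sequence (U mapped to T)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("piRNA id must be non-empty")
        if len(self.sequence) < MIN_SEQ_LEN:
            raise ValueError(
                f"sequence of {self.id!r} has length {len(self.sequence)} < {MIN_SEQ_LEN}"
            )
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"sequence of {self.id!r} has invalid symbols {sorted(bad)}")


def normalize_sequence(raw: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return raw.strip().upper().replace("U", "T")


@dataclass
class DiseaseOntology:
    """Disease terms arranged in a rooted DAG of child -> parent edges."""

    nodes: frozenset
    parent_edges: frozenset  # of (child, parent) pairs

    def __post_init__(self) -> None:
        for c, p in self.parent_edges:
            if c not in self.nodes or p not in self.nodes:
                raise ValueError(f"edge ({c}, {p}) references unknown node")
        g = self.graph()
        if self.nodes and not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def graph(self) -> nx.DiGraph:
        """Directed graph with edges child -> parent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.parent_edges)
        return g

    @property
    def roots(self) -> frozenset:
        children_of = {c for c, _ in self.parent_edges}
        # a root has no parent, i.e. never appears as a child
        return frozenset(n for n in self.nodes if n not in children_of)

    def parents(self, node) -> frozenset:
        return frozenset(p for c, p in self.parent_edges if c == node)

    def ancestors(self, node) -> frozenset:
        """All strict ancestors of ``node`` (transitive parents)."""
        if node not in self.nodes:
            raise KeyError(f"unknown ontology node {node!r}")
        return frozenset(nx.descendants(self.graph(), node))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "DiseaseOntology":
        edges = frozenset((str(c), str(p)) for c, p in edges)
        nodes = frozenset(x for e in edges for x in e)
        return cls(nodes=nodes, parent_edges=edges)


@dataclass
class AssociationDataset:
    """piRNAs, diseases and their binary association matrix A (m x n).

    Row/column order is lexicographic by id so that two loads of the same
    files always produce the same matrix.
    """

    pirnas: list          # of PirnaRecord, sorted by id
    diseases: list        # of disease ids, sorted
    A: np.ndarray         # m x n, dtype int8, values in {0, 1}

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pirnas]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate piRNA ids")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease ids")
        if ids != sorted(ids) or list(self.diseases) != sorted(self.diseases):
            raise ValueError("pirnas and diseases must be sorted by id")
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.pirnas), len(self.diseases)):
            raise ValueError(f"A has shape {self.A.shape}, expected "
                             f"({len(self.pirnas)}, {len(self.diseases)})")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary")
        self.A = self.A.astype(np.int8)

    @property
    def m(self) -> int:
        return len(self.pirnas)

    @property
    def n(self) -> int:
        return len(self.diseases)

    @property
    def density(self) -> float:
        return float(self.A.sum()) / (self.m * self.n)

    @property
    def pirna_ids(self) -> list:
        return [p.id for p in self.pirnas]

    def positive_pairs(self) -> list:
        """Index pairs (i, j) with A[i, j] == 1, row-major order."""
        return [tuple(ij) for ij in np.argwhere(self.A == 1)]

    def unlabelled_pairs(self) -> list:
        return [tuple(ij) for ij in np.argwhere(self.A == 0)]


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> list:
    """Read piRNA records from FASTA, normalizing U->T and case.

    Records are returned in file order. Duplicate ids and too-short
    sequences are errors.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate piRNA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(PirnaRecord(rec.id, normalize_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Sequence[PirnaRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")


def read_associations(path, pirnas: Sequence[PirnaRecord],
                      diseases: Sequence[str]) -> AssociationDataset:
    """Build an AssociationDataset from a TSV edge list.

    Every edge must reference a known piRNA and disease id; duplicate edges
    collapse to a single association.
    """
    edges = read_edge_list(path)
    return build_dataset(pirnas, diseases, edges)


def read_edge_list(path) -> list:
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            edges.append((parts[0], parts[1]))
    return edges


def build_dataset(pirnas: Sequence[PirnaRecord], diseases: Sequence[str],
                  edges: Iterable[tuple]) -> AssociationDataset:
    pirnas = sorted(pirnas, key=lambda r: r.id)
    diseases = sorted(str(d) for d in diseases)
    p_index = {p.id: i for i, p in enumerate(pirnas)}
    d_index = {d: j for j, d in enumerate(diseases)}
    A = np.zeros((len(pirnas), len(diseases)), dtype=np.int8)
    unknown = []
    for pid, did in edges:
        if pid not in p_index or did not in d_index:
            unknown.append((pid, did))
            continue
        A[p_index[pid], d_index[did]] = 1
    if unknown:
        raise ValueError(f"edges reference unknown ids: {unknown[:10]}"
                         + ("..." if len(unknown) > 10 else ""))
    return AssociationDataset(pirnas=pirnas, diseases=diseases, A=A)


def write_associations(path, ds: AssociationDataset) -> None:
    with open(path, "w") as fh:
        for i, j in ds.positive_pairs():
            fh.write(f"{ds.pirnas[i].id}\t{ds.diseases[j]}\n")


def read_ontology(path) -> DiseaseOntology:
    """Read a disease ontology from child->parent TSV or OBO.

    Ids appearing only as parents become implicit nodes. A cyclic edge set
    is an error. An empty file yields an empty ontology.
    """
    path = Path(path)
    if path.suffix.lower() == ".obo":
        return _read_obo(path)
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected child<TAB>parent")
            edges.append((parts[0], parts[1]))
    return DiseaseOntology.from_edges(edges)


def _read_obo(path) -> DiseaseOntology:
    import obonet

    g = obonet.read_obo(str(path))  # edges run child -> parent ("is_a")
    edges = [(c, p) for c, p, k in g.edges(keys=True) if k == "is_a"]
    ont = DiseaseOntology.from_edges(edges)
    isolated = frozenset(g.nodes) - ont.nodes
    if isolated:
        ont = DiseaseOntology(nodes=ont.nodes | isolated,
                              parent_edges=ont.parent_edges)
    return ont


def write_ontology(path, ont: DiseaseOntology) -> None:
    with open(path, "w") as fh:
        for c, p in sorted(ont.parent_edges):
            fh.write(f"{c}\t{p}\n")


# ---------------------------------------------------------------------------
# labelled matrix TSV


def write_matrix(path, M: np.ndarray, row_ids: Sequence[str],
                 col_ids: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(M), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> tuple:
    """Return (M, row_ids, col_ids) from a labelled TSV written by write_matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
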