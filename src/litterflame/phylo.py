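"""Pairwise phylogenetic distance on a dated tree.

The phylogenetic distance between two species is the total branch length
(in million years, My) along the unique path connecting their tips; on an
ultrametric tree this is twice the age of their most recent common
ancestor. Trees are supplied as rooted Newick with branch lengths already
in My — no inference, dating or pruning happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy
import pandas as pd


class Phylogeny:
    """A rooted, branch-length-bearing tree with unique species-code tips.

    Thin wrapper over a :class:`dendropy.Tree` that validates the
    invariants needed for patristic distances (every non-root edge has a
    non-negative length; tip labels unique) and caches the distance matrix.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._pdm = tree.phylogenetic_distance_matrix()
        self._taxa = {t.label: t for t in tree.taxon_namespace}

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValueError("tree has unlabelled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge
                continue
            if edge.length is None:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "<internal>"
                raise ValueError(f"missing branch length on edge above {name!r}")
            if edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def tip_labels(self) -> list:
        return sorted(t.label for t in self._tree.taxon_namespace if t.label)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def distance(self, a: str, b: str) -> float:
        """Patristic distance between tips ``a`` and ``b`` in My."""
        if a == b:
            if a not in self._taxa:
                raise KeyError(f"unknown tip {a!r}")
            return 0.0
        try:
            ta, tb = self._taxa[a], self._taxa[b]
        except KeyError as exc:
            raise KeyError(f"unknown tip {exc.args[0]!r}") from None
        return float(self._pdm.patristic_distance(ta, tb))


@dataclass(frozen=True)
class PairDistance:
    species_a: str
    species_b: str
    distance: float  # My


def parse_tree(newick_text: str) -> Phylogeny:
    """Parse rooted Newick text (branch lengths in My) into a Phylogeny.

    Raises ``ValueError`` on malformed Newick, missing branch lengths or
    duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def load_tree(path: str) -> Phylogeny:
    with open(path) as fh:
        return parse_tree(fh.read())


def pairwise_distance(phylogeny: Phylogeny, a: str, b: str) -> float:
    """Total branch length on the path between tips ``a`` and ``b``, My."""
    return phylogeny.distance(a, b)


def distance_table(phylogeny: Phylogeny, pairs: Iterable[tuple]) -> pd.DataFrame:
    """Patristic distances for a list of (species_a, species_b) pairs.

    Returns a DataFrame with columns ``species_a, species_b, distance_my``.
    """
    rows = [
        {"species_a": a, "species_b": b, "distance_my": pairwise_distance(phylogeny, a, b)}
        for a, b in pairs
    ]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "distance_my"])
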