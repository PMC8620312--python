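"""Shared fixtures and independent oracles.

The oracle implementations here deliberately share no code with the
package: window enumeration, reverse complementation and barcode
subtraction are re-derived character by character so agreement with the
package is a genuine two-route check.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from kbarcode import GenomeRecord, KmerParams, ReferenceCollection

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_windows(seq: str, k: int, canonical: bool) -> set[str]:
    """Every admissible length-k window, by direct per-position scanning."""
    out = set()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in _COMP for c in w):
            continue
        if canonical:
            rc = oracle_revcomp(w)
            if rc < w:
                w = rc
        out.add(w)
    return out


def oracle_barcode(target: GenomeRecord, collection: ReferenceCollection,
                   level: str) -> set[str]:
    """Brute-force barcode: one big exclusion union, one subtraction."""
    k, canonical = collection.params.k, collection.params.canonical
    mine = set()
    for seq, is_pl in zip(target.sequences, target.is_plasmid):
        if not is_pl:
            mine |= oracle_windows(seq, k, canonical)
    excl = set()
    for g in collection:
        for seq, is_pl in zip(g.sequences, g.is_plasmid):
            if is_pl:
                excl |= oracle_windows(seq, k, canonical)
            elif g.is_host:
                excl |= oracle_windows(seq, k, canonical)
            elif g.genome_id != target.genome_id:
                if level == "strain":
                    excl |= oracle_windows(seq, k, canonical)
                elif level == "species" and (g.genus, g.species) != (
                    target.genus,
                    target.species,
                ):
                    excl |= oracle_windows(seq, k, canonical)
                elif level == "genus" and g.genus != target.genus:
                    excl |= oracle_windows(seq, k, canonical)
    return mine - excl


def random_collection(rng: random.Random, k: int, canonical: bool,
                      max_genomes: int = 10, max_total_bp: int = 10_000,
                      with_host: bool = True,
                      with_plasmids: bool = True) -> ReferenceCollection:
    """A small random reference collection with varied taxonomy structure."""
    n = rng.randint(2, max_genomes)
    genera = ["Ga", "Gb"]
    species = ["s1", "s2"]
    genomes = []
    budget = max_total_bp
    for i in range(n):
        n_seq = rng.randint(1, 3)
        seqs, plasmids = [], []
        for j in range(n_seq):
            ln = rng.randint(k, max(k, min(400, budget)))
            budget = max(k, budget - ln)
            alphabet = "ACGT" if rng.random() < 0.8 else "ACGTN"
            seqs.append("".join(rng.choice(alphabet) for _ in range(ln)))
            plasmids.append(with_plasmids and rng.random() < 0.2)
        if all(plasmids):
            plasmids[0] = False
        genomes.append(
            GenomeRecord(
                genome_id=f"g{i}",
                sequences=seqs,
                genus=rng.choice(genera),
                species=rng.choice(species),
                strain=f"g{i}",
                is_plasmid=plasmids,
            )
        )
    if with_host and rng.random() < 0.5:
        genomes.append(
            GenomeRecord(
                genome_id="host",
                sequences=["".join(rng.choice("ACGT") for _ in range(200))],
                is_host=True,
            )
        )
    return ReferenceCollection(genomes, KmerParams(k=k, canonical=canonical))


def random_additive_tree(rng: np.random.Generator, n: int):
    """A random unrooted binary tree and its additive tip-distance matrix.

    Built by repeated random joins with positive branch lengths, ending in
    a trifurcating root, so the matrix determines the topology uniquely.
    Returns (labels, matrix, tree).
    """
    from skbio import TreeNode

    labels = [f"t{i:02d}" for i in range(n)]
    subtrees = []
    for lab in labels:
        node = TreeNode(name=lab)
        node.length = float(rng.uniform(0.05, 1.0))
        subtrees.append(node)
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(int(j))
        a = subtrees.pop(int(i))
        parent = TreeNode()
        parent.extend([a, b])
        parent.length = float(rng.uniform(0.05, 1.0))
        subtrees.append(parent)
    root = TreeNode()
    root.extend(subtrees)
    skdm = root.tip_tip_distances()
    order = [list(skdm.ids).index(lab) for lab in labels]
    mat = np.asarray(skdm.data)[np.ix_(order, order)]
    return labels, mat, root


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240917)
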