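"""Synthetic pangenomes and metagenomes with known ground truth.

The generator emulates intraspecies structure: every strain shares a
common core sequence, strains of the same phylogroup share an accessory
block, and each strain carries one private random segment whose k-mers
become its strain-specific barcode.  Segments are emitted as separate
contigs, so (absent random k-mer collisions) a strain's non-canonical
strain-specific barcode has exactly ``unique_len − k + 1`` words.

Sequences are i.i.d. uniform over A/C/G/T — no GC bias, repeats or gene
structure — which is sufficient for correctness testing but deliberately
non-biological.  Reads are substitution-error only; indels are out of
scope because the profiler contract is exact k-mer matching.
All outputs are bit-reproducible functions of the seed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .barcode import GenomeRecord, KmerParams, ParameterError, ReferenceCollection

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth of a simulation: composition and/or sample proportions."""

    seed: int
    k: int = 18
    strains: dict[str, dict] = field(default_factory=dict)
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: Path | str) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "k": self.k,
                    "strains": self.strains,
                    "proportions": self.proportions,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return path


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_pangenome(
    n_strains: int,
    core_len: int = 20_000,
    accessory_len: int = 5_000,
    n_phylogroups: int = 4,
    unique_len: int = 2_000,
    k: int = 18,
    seed: int = 0,
    genus: str = "Simulibacillus",
    species: str = "synthetica",
    allow_empty_unique: bool = False,
    duplicate_pairs: Sequence[tuple[int, int]] = (),
) -> tuple[list[GenomeRecord], SimTruth]:
    """Generate a phylogroup-structured synthetic pangenome.

    Each strain's genome is three contigs: the shared core, its
    phylogroup's accessory block, and a strain-private segment of length
    ``unique_len`` (≥ k, or 0 with ``allow_empty_unique=True`` to model
    strains indistinguishable from their group).  ``duplicate_pairs``
    (src, dst) copies strain *src*'s contigs onto strain *dst*, making
    both strain-specific barcodes empty.
    """
    if n_strains < 1:
        raise ParameterError("n_strains must be >= 1")
    if core_len < k or accessory_len < k:
        raise ParameterError("core_len and accessory_len must be >= k")
    if unique_len == 0 and not allow_empty_unique:
        raise ParameterError(
            "unique_len = 0 requires allow_empty_unique=True (yields empty strain barcodes)"
        )
    if 0 < unique_len < k:
        raise ParameterError(f"unique_len must be 0 or >= k ({k})")
    rng = np.random.default_rng(seed)
    core = _random_seq(rng, core_len)
    n_groups = max(1, min(n_phylogroups, n_strains))
    accessory = [_random_seq(rng, accessory_len) for _ in range(n_groups)]
    genomes: list[GenomeRecord] = []
    truth = SimTruth(seed=seed, k=k)
    for i in range(n_strains):
        group = i % n_groups
        sid = f"S{i + 1:02d}"
        contigs = [core, accessory[group]]
        if unique_len:
            contigs.append(_random_seq(rng, unique_len))
        genomes.append(
            GenomeRecord(
                genome_id=sid,
                sequences=contigs,
                genus=genus,
                species=species,
                strain=sid,
            )
        )
        truth.strains[sid] = {
            "phylogroup": f"PG{group + 1}",
            "unique_len": int(unique_len),
        }
    for src, dst in duplicate_pairs:
        genomes[dst].sequences = list(genomes[src].sequences)
        truth.strains[genomes[dst].genome_id] = dict(
            truth.strains[genomes[src].genome_id], duplicate_of=genomes[src].genome_id
        )
    return genomes, truth


def pangenome_collection(
    genomes: Sequence[GenomeRecord], k: int = 18, canonical: bool = True
) -> ReferenceCollection:
    """Wrap simulated genomes as a barcoding reference collection."""
    return ReferenceCollection(
        genomes=list(genomes), params=KmerParams(k=k, canonical=canonical)
    )


_SUBS = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_metagenome(
    genomes: Sequence[GenomeRecord],
    proportions: Sequence[float],
    n_reads: int,
    read_len: int = 100,
    error_rate: float = 0.0,
    k: int = 18,
    seed: int = 0,
    sample_id: str = "S1",
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Draw shotgun reads from a strain mixture.

    Reads are sampled per strain according to ``proportions``, positions
    uniform over contigs long enough to host a read (contigs weighted by
    the number of admissible start positions), strand uniform, and an
    optional uniform substitution error applied per base.  Returns
    (id, sequence) pairs; qualities are a constant placeholder when
    written as FASTQ.  Read ids carry the source strain as ground truth.
    """
    if n_reads <= 0:
        raise ParameterError("n_reads must be > 0")
    if read_len < k:
        raise ParameterError(f"read_len ({read_len}) must be >= k ({k})")
    props = np.asarray(list(proportions), dtype=float)
    if len(props) != len(genomes) or np.any(props < 0) or not np.isclose(
        props.sum(), 1.0
    ):
        raise ParameterError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed, k=k)
    truth.proportions[sample_id] = {
        g.genome_id: float(p) for g, p in zip(genomes, props)
    }
    # per-genome contig start-position weights
    weights = []
    for g in genomes:
        w = np.array([max(0, len(s) - read_len + 1) for s in g.sequences], dtype=float)
        if w.sum() == 0:
            raise ParameterError(
                f"genome {g.genome_id} has no contig of length >= read_len"
            )
        weights.append(w / w.sum())
    reads: list[tuple[str, str]] = []
    strain_idx = rng.choice(len(genomes), size=n_reads, p=props)
    for i, gi in enumerate(strain_idx):
        g = genomes[gi]
        ci = int(rng.choice(len(g.sequences), p=weights[gi]))
        contig = g.sequences[ci]
        pos = int(rng.integers(0, len(contig) - read_len + 1))
        seq = contig[pos : pos + read_len]
        if rng.integers(0, 2):
            seq = seq.translate(_COMPLEMENT)[::-1]
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_len) < error_rate)
            if errs.size:
                chars = list(seq)
                for e in errs:
                    chars[e] = _SUBS[chars[e]][rng.integers(0, 3)]
                seq = "".join(chars)
        reads.append((f"{sample_id}.{i + 1} strain={g.genome_id}", seq))
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: Path | str) -> Path:
    """Write (id, seq) pairs as FASTQ with constant placeholder qualities."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def write_fasta(genomes: Sequence[GenomeRecord], path: Path | str) -> Path:
    """Write simulated genomes as multi-record FASTA (contig per record)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for g in genomes:
            for ci, seq in enumerate(g.sequences):
                fh.write(f">{g.genome_id}.c{ci + 1}\n")
                for ofs in range(0, len(seq), 80):
                    fh.write(seq[ofs : ofs + 80] + "\n")
    return path
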