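"""Unique k-mer barcoding of genomes against a reference collection.

A *barcode* is the set of k-mers (default k=18) present in a target genome
and absent from a defined exclusion set of other sequences.  Three
specificity levels are supported, differing only in how broad the exclusion
set is:

* ``genus``   — markers absent from every genome outside the target's genus
  (and from all plasmids and host sequences); they may recur in other
  genomes of the same genus.
* ``species`` — markers additionally absent from other species of the genus.
* ``strain``  — markers absent from every genome in the collection except
  the target itself; such markers identify one genome uniquely.

Because the exclusion sets are nested, so are the barcodes:
strain ⊆ species ⊆ genus for any fixed target and collection.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

logger = logging.getLogger("kbarcode")

DEFAULT_K = 18

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_RUN = re.compile(r"[ACGT]+")


class KbarcodeError(Exception):
    """Base class for all package errors."""


class ParameterError(KbarcodeError, ValueError):
    """Invalid parameter value (e.g. k < 2, mixed k across barcodes)."""


class ConfigurationError(KbarcodeError, ValueError):
    """Inconsistent inputs (e.g. missing taxonomy label for a level)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerParams:
    """Word length and strand handling for k-mer extraction.

    canonical=True identifies each k-mer with its reverse complement
    (the lexicographically smaller of the two is stored), which makes
    matching strand-agnostic — the right default for shotgun reads.
    canonical=False matches one strand literally.
    """

    k: int = DEFAULT_K
    canonical: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or self.k < 2:
            raise ParameterError(f"k must be an integer >= 2, got {self.k!r}")


@dataclass(frozen=True)
class KmerSet:
    """A finite set of fixed-length words over {A,C,G,T}."""

    words: frozenset[str]
    params: KmerParams

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.words


def canonical(word: str) -> str:
    """The lexicographic minimum of a word and its reverse complement."""
    rc = reverse_complement(word)
    return word if word <= rc else rc


def _window_words(sequence: str, params: KmerParams) -> set[str]:
    """All admissible length-k windows of one sequence (internal).

    Windows containing any symbol other than A/C/G/T are skipped; in
    canonical mode each window is replaced by min(window, revcomp(window)).
    """
    k = params.k
    words: set[str] = set()
    seq = sequence.upper()
    # Split on degenerate symbols: only pure-ACGT runs can host windows.
    for m in _VALID_RUN.finditer(seq):
        run = m.group(0)
        n = len(run)
        if n < k:
            continue
        if params.canonical:
            rc = reverse_complement(run)
            for i in range(n - k + 1):
                w = run[i : i + k]
                wrc = rc[n - k - i : n - i]
                words.add(w if w <= wrc else wrc)
        else:
            for i in range(n - k + 1):
                words.add(run[i : i + k])
    return words


def extract_kmers(sequence: str, params: KmerParams) -> KmerSet:
    """Extract the set of k-mers of one nucleotide sequence.

    Sequences shorter than k yield an empty set; degenerate-base windows
    (anything outside A/C/G/T, e.g. N) are skipped rather than erroring.
    """
    return KmerSet(frozenset(_window_words(sequence, params)), params)


class SpecificityLevel(str, Enum):
    """How broad the barcode exclusion set is."""

    GENUS = "genus"
    SPECIES = "species"
    STRAIN = "strain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_level(level: "SpecificityLevel | str") -> SpecificityLevel:
    if isinstance(level, SpecificityLevel):
        return level
    return SpecificityLevel(str(level).lower())


@dataclass
class GenomeRecord:
    """One genome of a reference collection.

    ``sequences`` holds the contigs/chromosome; ``is_plasmid`` flags each
    sequence individually so a genome may carry both a chromosome and
    plasmids.  ``is_host`` marks host-genome entries (e.g. *Homo sapiens*)
    whose k-mers are always excluded from barcodes.
    """

    genome_id: str
    sequences: list[str]
    genus: str = ""
    species: str = ""
    strain: str = ""
    is_plasmid: list[bool] | None = None
    is_host: bool = False

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ConfigurationError(f"genome {self.genome_id!r} has no sequences")
        if self.is_plasmid is None:
            self.is_plasmid = [False] * len(self.sequences)
        if len(self.is_plasmid) != len(self.sequences):
            raise ConfigurationError(
                f"genome {self.genome_id!r}: is_plasmid flags do not match sequences"
            )

    def chromosome_sequences(self) -> list[str]:
        return [s for s, p in zip(self.sequences, self.is_plasmid) if not p]

    def plasmid_sequences(self) -> list[str]:
        return [s for s, p in zip(self.sequences, self.is_plasmid) if p]


@dataclass
class ReferenceCollection:
    """Genomes plus the k-mer parameters used to barcode against them."""

    genomes: list[GenomeRecord]
    params: KmerParams = field(default_factory=KmerParams)

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ConfigurationError("reference collection must contain >= 1 genome")
        ids = [g.genome_id for g in self.genomes]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ConfigurationError(f"duplicate genome ids in collection: {dup}")

    def __iter__(self):
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def get(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def digest(self) -> str:
        """Order-insensitive fingerprint of genome content + params."""
        h = hashlib.sha256()
        per_genome = []
        for g in self.genomes:
            gh = hashlib.sha256()
            gh.update(g.genome_id.encode())
            gh.update(f"|{g.genus}|{g.species}|{g.strain}|{int(g.is_host)}".encode())
            for seq, pl in zip(g.sequences, g.is_plasmid):
                gh.update(f"|{int(pl)}|".encode())
                gh.update(seq.upper().encode())
            per_genome.append(gh.hexdigest())
        for d in sorted(per_genome):
            h.update(d.encode())
        h.update(f"k={self.params.k};canonical={self.params.canonical}".encode())
        return h.hexdigest()[:16]


@dataclass
class Barcode:
    """The marker k-mer set of one genome at one specificity level."""

    genome_id: str
    level: SpecificityLevel
    kmers: KmerSet
    collection_digest: str = ""

    @property
    def size(self) -> int:
        return len(self.kmers)

    @property
    def params(self) -> KmerParams:
        return self.kmers.params


def _taxonomy_excluded(
    target: GenomeRecord, other: GenomeRecord, level: SpecificityLevel
) -> bool:
    """Is *other* (a non-host genome) in the exclusion set for *target*?"""
    if other.genome_id == target.genome_id:
        return False
    if level is SpecificityLevel.STRAIN:
        return True
    if level is SpecificityLevel.SPECIES:
        return (other.genus, other.species) != (target.genus, target.species)
    return other.genus != target.genus


def _require_labels(target: GenomeRecord, level: SpecificityLevel) -> None:
    if level is SpecificityLevel.GENUS and not target.genus:
        raise ConfigurationError(
            f"genus-level barcode for {target.genome_id!r} requires a genus label"
        )
    if level is SpecificityLevel.SPECIES and not (target.genus and target.species):
        raise ConfigurationError(
            f"species-level barcode for {target.genome_id!r} requires genus+species labels"
        )


def build_barcode(
    target: GenomeRecord,
    collection: ReferenceCollection,
    level: SpecificityLevel | str,
) -> Barcode:
    """Compute the specificity-filtered barcode of *target*.

    The result is kmers(target chromosome sequences) minus the union of
    k-mers of every exclusion sequence: all plasmid sequences, all host
    sequences, and every genome whose taxonomy differs from the target's
    at the requested level (at strain level: every other genome).

    Exclusion genomes are streamed one sequence at a time, so the exclusion
    union is never materialised; the result is provably independent of the
    processing order because set difference against a union equals iterated
    set difference.

    An empty result is legal (e.g. a genome identical to another collection
    member at strain level) and returns a size-0 barcode with a warning.
    """
    level = _as_level(level)
    if target.is_host:
        raise ConfigurationError("host genomes are not barcoded")
    _require_labels(target, level)
    params = collection.params

    result: set[str] = set()
    for seq in target.chromosome_sequences():
        result |= _window_words(seq, params)

    for genome in collection:
        if not result:
            break
        # Plasmid sequences (including the target's own) are always excluded.
        for seq in genome.plasmid_sequences():
            result -= _window_words(seq, params)
        if genome.is_host or _taxonomy_excluded(target, genome, level):
            for seq in genome.chromosome_sequences():
                if not result:
                    break
                result -= _window_words(seq, params)

    if not result:
        logger.warning(
            "barcode of %s at %s level is empty", target.genome_id, level.value
        )
    return Barcode(
        genome_id=target.genome_id,
        level=level,
        kmers=KmerSet(frozenset(result), params),
        collection_digest=collection.digest(),
    )


def clear_cross_links(barcodes: Sequence[Barcode]) -> list[Barcode]:
    """Remove every k-mer occurring in two or more barcodes from all of them.

    After clearing, the output sets are pairwise disjoint, so a read hit is
    attributable to a single target.  Idempotent; preserves input order.
    """
    if not barcodes:
        return []
    params = barcodes[0].params
    for b in barcodes:
        if b.params != params:
            raise ParameterError(
                "clear_cross_links requires identical k-mer params across barcodes"
            )
    counts: Counter[str] = Counter()
    for b in barcodes:
        counts.update(b.kmers.words)
    shared = {w for w, c in counts.items() if c >= 2}
    if shared:
        logger.info("clear_cross_links: removing %d cross-linking k-mers", len(shared))
    out = []
    for b in barcodes:
        out.append(
            Barcode(
                genome_id=b.genome_id,
                level=b.level,
                kmers=KmerSet(frozenset(b.kmers.words - shared), params),
                collection_digest=b.collection_digest,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Persistence: sorted plain-text k-mer list + JSON sidecar
# ---------------------------------------------------------------------------


def barcode_paths(directory: Path | str, genome_id: str, level: SpecificityLevel | str):
    level = _as_level(level)
    directory = Path(directory)
    safe = re.sub(r"[^A-Za-z0-9._-]+", "_", genome_id)
    stem = f"{safe}.{level.value}"
    return directory / f"{stem}.kmers.txt", directory / f"{stem}.json"


def write_barcode(barcode: Barcode, directory: Path | str) -> tuple[Path, Path]:
    """Write one word per line (sorted) plus a JSON sidecar; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    txt, sidecar = barcode_paths(directory, barcode.genome_id, barcode.level)
    with open(txt, "w") as fh:
        for w in sorted(barcode.kmers.words):
            fh.write(w)
            fh.write("\n")
    meta = {
        "genome_id": barcode.genome_id,
        "level": barcode.level.value,
        "k": barcode.params.k,
        "canonical": barcode.params.canonical,
        "size": barcode.size,
        "collection_digest": barcode.collection_digest,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return txt, sidecar


def read_barcode(txt_path: Path | str) -> Barcode:
    """Read a barcode written by :func:`write_barcode` (bit-exact round-trip)."""
    txt_path = Path(txt_path)
    sidecar = txt_path.with_suffix("").with_suffix(".json")  # strip .kmers.txt
    if not sidecar.exists():
        sidecar = Path(str(txt_path).replace(".kmers.txt", ".json"))
    with open(sidecar) as fh:
        meta = json.load(fh)
    params = KmerParams(k=int(meta["k"]), canonical=bool(meta["canonical"]))
    with open(txt_path) as fh:
        words = frozenset(line.strip() for line in fh if line.strip())
    if len(words) != int(meta["size"]):
        raise ConfigurationError(
            f"{txt_path}: word count {len(words)} does not match sidecar size {meta['size']}"
        )
    return Barcode(
        genome_id=meta["genome_id"],
        level=SpecificityLevel(meta["level"]),
        kmers=KmerSet(words, params),
        collection_digest=meta.get("collection_digest", ""),
    )


def read_barcode_dir(
    directory: Path | str, level: SpecificityLevel | str | None = None
) -> list[Barcode]:
    """All barcodes in a directory, sorted by genome id, optionally one level."""
    directory = Path(directory)
    wanted = _as_level(level).value if level is not None else None
    out = []
    for txt in sorted(directory.glob("*.kmers.txt")):
        b = read_barcode(txt)
        if wanted is None or b.level.value == wanted:
            out.append(b)
    return sorted(out, key=lambda b: b.genome_id)


# ---------------------------------------------------------------------------
# Manifest + FASTA loading
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["genome_id", "genus", "species", "strain", "role", "path"]
_ROLES = {"chromosome", "plasmid", "host"}


def open_maybe_gzip(path: Path | str, mode: str = "rt"):
    """Open a file, transparently handling .gz suffixes."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_fasta_records(path: Path | str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with open_maybe_gzip(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def load_collection(
    manifest_path: Path | str, params: KmerParams | None = None
) -> ReferenceCollection:
    """Build a ReferenceCollection from a manifest TSV.

    Columns: genome_id, genus, species, strain, role in {chromosome, plasmid,
    host}, path (FASTA, optionally gzipped), record_ids (optional
    comma-separated subset of FASTA record ids).  Several rows may share a
    genome_id, e.g. one chromosome row plus one plasmid row.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"manifest is missing columns: {missing}")
    records: dict[str, GenomeRecord] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        role = row["role"].strip().lower()
        if role not in _ROLES:
            raise ConfigurationError(f"unknown role {row['role']!r} in manifest")
        fasta = Path(row["path"])
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        seqs = _read_fasta_records(fasta)
        wanted = [s.strip() for s in row.get("record_ids", "").split(",") if s.strip()]
        if wanted:
            by_id = dict(seqs)
            try:
                seqs = [(rid, by_id[rid]) for rid in wanted]
            except KeyError as e:
                raise ConfigurationError(
                    f"record id {e.args[0]!r} not found in {fasta}"
                ) from None
        gid = row["genome_id"]
        if gid not in records:
            records[gid] = GenomeRecord(
                genome_id=gid,
                sequences=[s for _, s in seqs],
                genus=row["genus"],
                species=row["species"],
                strain=row["strain"],
                is_plasmid=[role == "plasmid"] * len(seqs),
                is_host=role == "host",
            )
            order.append(gid)
        else:
            rec = records[gid]
            rec.sequences.extend(s for _, s in seqs)
            rec.is_plasmid.extend([role == "plasmid"] * len(seqs))
            if role == "host":
                rec.is_host = True
    genomes = [records[g] for g in order]
    non_host = [g for g in genomes if not g.is_host]
    for g in non_host:
        if not g.genus and not all(g.is_plasmid):
            logger.warning("genome %s has no genus label", g.genome_id)
    return ReferenceCollection(genomes=genomes, params=params or KmerParams())


def brute_force_barcode(
    target: GenomeRecord,
    collection: ReferenceCollection,
    level: SpecificityLevel | str,
) -> set[str]:
    """Reference implementation by full enumeration (small inputs only).

    Materialises every admissible window of every exclusion sequence into one
    explicit union before a single set subtraction.  Exists as an in-package
    oracle for validating :func:`build_barcode` on small collections.
    """
    level = _as_level(level)
    _require_labels(target, level)
    params = collection.params
    mine: set[str] = set()
    for seq in target.chromosome_sequences():
        mine |= _window_words(seq, params)
    exclusion: set[str] = set()
    for genome in collection:
        for seq in genome.plasmid_sequences():
            exclusion |= _window_words(seq, params)
        if genome.is_host or _taxonomy_excluded(target, genome, level):
            for seq in genome.chromosome_sequences():
                exclusion |= _window_words(seq, params)
    return mine - exclusion
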