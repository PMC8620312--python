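"""Run configuration and the staged pipeline behind the command line.

Every run writes its resolved configuration (YAML) and a manifest of
input-file digests next to its outputs, so any artifact directory can be
reproduced from what it contains.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .barcode import (
    Barcode,
    ConfigurationError,
    KmerParams,
    SpecificityLevel,
    _as_level,
    build_barcode,
    clear_cross_links,
    load_collection,
    read_barcode_dir,
    write_barcode,
)
from .phylogeny import (
    neighbor_joining,
    pairwise_distance_matrix,
    write_newick,
    write_phylip,
)
from .profiler import (
    SPECIES_NORM_CONST,
    STRAIN_NORM_CONST,
    DEFAULT_MIN_READ_LEN,
    normalize_abundance,
    scan_reads,
    write_abundance_tsv,
)

logger = logging.getLogger("kbarcode")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    mode: str  # "phylogeny" or "profile"
    manifest: str = ""
    fastq: list[str] = field(default_factory=list)
    out_dir: str = "kbarcode_out"
    k: int = 18
    canonical: bool = True
    level: str = "strain"
    norm_const: float | None = None
    min_read_len: int = DEFAULT_MIN_READ_LEN
    clear: bool = False
    alpha: float = 0.05
    seed: int = 0

    def resolved_norm_const(self) -> float:
        if self.norm_const is not None:
            return float(self.norm_const)
        return (
            SPECIES_NORM_CONST
            if _as_level(self.level) is SpecificityLevel.SPECIES
            else STRAIN_NORM_CONST
        )

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(config: RunConfig, out_dir: Path) -> None:
    with open(out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    inputs = {}
    for p in [config.manifest, *config.fastq]:
        if p and Path(p).exists():
            inputs[str(p)] = _sha256(Path(p))
    with open(out_dir / "inputs_manifest.json", "w") as fh:
        json.dump(inputs, fh, indent=2, sort_keys=True)
        fh.write("\n")


def build_all_barcodes(config: RunConfig, out_dir: Path) -> list[Barcode]:
    collection = load_collection(
        config.manifest, KmerParams(k=config.k, canonical=config.canonical)
    )
    level = _as_level(config.level)
    barcodes = []
    for genome in collection:
        if genome.is_host or all(genome.is_plasmid):
            continue
        barcodes.append(build_barcode(genome, collection, level))
    if config.clear:
        barcodes = clear_cross_links(barcodes)
    bdir = out_dir / "barcodes"
    for b in barcodes:
        write_barcode(b, bdir)
    n_empty = sum(1 for b in barcodes if b.size == 0)
    logger.info(
        "built %d %s-level barcodes (%d empty)", len(barcodes), level.value, n_empty
    )
    return barcodes


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stage chain; returns the artifact directory.

    mode="phylogeny": barcode → distance matrix → NJ tree
    (barcodes/, dist.phylip, tree.nwk).
    mode="profile": barcode → read scan → normalized abundance
    (barcodes/, abundance.tsv, one row per sample × genome).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "barcode"
    try:
        barcodes = build_all_barcodes(config, out_dir)
        if config.mode == "phylogeny":
            stage = "distmat"
            nonempty = [b for b in barcodes if b.size > 0]
            dropped = sorted(b.genome_id for b in barcodes if b.size == 0)
            if dropped:
                logger.info("excluding %d empty barcodes from tree: %s", len(dropped), dropped)
            dm = pairwise_distance_matrix(nonempty)
            write_phylip(dm, out_dir / "dist.phylip")
            stage = "tree"
            tree = neighbor_joining(dm)
            write_newick(tree, out_dir / "tree.nwk")
        elif config.mode == "profile":
            stage = "profile"
            sizes = {b.genome_id: b.size for b in barcodes}
            records = []
            for fq in config.fastq:
                scan = scan_reads(
                    fq,
                    [b for b in barcodes if b.size > 0],
                    min_len=config.min_read_len,
                    sample_id=Path(fq).name.split(".")[0],
                )
                records.extend(
                    normalize_abundance(
                        scan, sizes, config.resolved_norm_const(), config.level
                    )
                )
            write_abundance_tsv(records, out_dir / "abundance.tsv")
        else:
            raise ConfigurationError(f"unknown pipeline mode {config.mode!r}")
    except Exception:
        logger.error("pipeline failed at stage %r; outputs may be partial", stage)
        (out_dir / "FAILED_STAGE.txt").write_text(stage + "\n")
        raise
    _write_provenance(config, out_dir)
    return out_dir
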