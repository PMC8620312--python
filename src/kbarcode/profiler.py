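"""Scan metagenome reads for marker k-mers and normalize abundances.

Counting is read-level: a read contributes at most once to each genome no
matter how many of that genome's markers it carries (long identical k-mer
tracks would otherwise be multiply counted), but one read may hit several
genomes when their barcodes overlap.  The percentage of marker-carrying
reads is then scaled by C / markers_n — a normalization constant divided
by the barcode size — so genomes with very different barcode sizes become
comparable.  Conventional constants: C = 1,000,000 at species level,
C = 37,000 at strain level (the rounded average strain-specific set size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode import (
    Barcode,
    KbarcodeError,
    KmerParams,
    ParameterError,
    SpecificityLevel,
    _as_level,
    _window_words,
    open_maybe_gzip,
)

logger = logging.getLogger("kbarcode")

SPECIES_NORM_CONST = 1_000_000.0
STRAIN_NORM_CONST = 37_000.0
DEFAULT_MIN_READ_LEN = 20


class MalformedReadError(KbarcodeError, ValueError):
    """A FASTQ record could not be parsed; carries the record index."""


@dataclass
class ReadScanResult:
    """Per-sample read-hit counts for a set of barcodes."""

    sample_id: str
    reads_total: int
    reads_hit: dict[str, int]

    def __add__(self, other: "ReadScanResult") -> "ReadScanResult":
        """Component-wise sum — scanning concatenated files equals adding scans."""
        keys = set(self.reads_hit) | set(other.reads_hit)
        return ReadScanResult(
            sample_id=self.sample_id,
            reads_total=self.reads_total + other.reads_total,
            reads_hit={
                g: self.reads_hit.get(g, 0) + other.reads_hit.get(g, 0) for g in keys
            },
        )


@dataclass
class AbundanceRecord:
    """Normalized presence of one genome's relatives in one sample."""

    sample_id: str
    genome_id: str
    level: SpecificityLevel
    reads_total: int
    reads_hit: int
    markers_n: int
    norm_const: float

    @property
    def percent_reads(self) -> float:
        return 100.0 * self.reads_hit / self.reads_total

    @property
    def normalized(self) -> float:
        return self.percent_reads * self.norm_const / self.markers_n


def _iter_fastq(source) -> Iterable[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ path/handle or an iterable of pairs."""
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        with open_maybe_gzip(source) as fh:
            idx = -1
            try:
                for idx, rec in enumerate(SeqIO.parse(fh, "fastq")):
                    yield rec.id, str(rec.seq)
            except ValueError as e:
                raise MalformedReadError(
                    f"malformed FASTQ record at index {idx + 1} in {source}: {e}"
                ) from e
        return
    for item in source:
        if isinstance(item, str):
            yield "", item
        else:
            yield item[0], item[1]


def scan_reads(
    reads,
    barcodes: Sequence[Barcode],
    min_len: int = DEFAULT_MIN_READ_LEN,
    sample_id: str = "sample",
) -> ReadScanResult:
    """Count reads carrying at least one marker of each barcode.

    ``reads`` may be a FASTQ path (optionally .gz), or any iterable of
    sequences / (id, sequence) pairs.  Reads shorter than ``min_len`` are
    excluded from ``reads_total``.  K-mers are extracted from each read with
    the same canonical/degenerate-window rules used for genomes, so in
    canonical mode scanning is strand-agnostic.
    """
    if not barcodes:
        raise ParameterError("scan_reads needs at least one barcode")
    params: KmerParams = barcodes[0].params
    for b in barcodes:
        if b.params != params:
            raise ParameterError("barcodes have different k-mer params")
    if min_len < params.k:
        raise ParameterError(
            f"min_len ({min_len}) must be >= k ({params.k}); shorter reads hold no k-mer"
        )
    index: dict[str, list[int]] = {}
    for gi, b in enumerate(barcodes):
        for w in b.kmers.words:
            index.setdefault(w, []).append(gi)
    hits = [0] * len(barcodes)
    total = 0
    dropped = 0
    for _rid, seq in _iter_fastq(reads):
        if len(seq) < min_len:
            dropped += 1
            continue
        total += 1
        seen: set[int] = set()
        for w in _window_words(seq, params):
            gis = index.get(w)
            if gis:
                seen.update(gis)
        for gi in seen:
            hits[gi] += 1
    if dropped:
        logger.info(
            "scan_reads[%s]: dropped %d reads shorter than %d b",
            sample_id,
            dropped,
            min_len,
        )
    return ReadScanResult(
        sample_id=sample_id,
        reads_total=total,
        reads_hit={b.genome_id: hits[gi] for gi, b in enumerate(barcodes)},
    )


def normalize_abundance(
    scan: ReadScanResult,
    barcode_sizes: Mapping[str, int],
    norm_const: float,
    level: SpecificityLevel | str = SpecificityLevel.STRAIN,
) -> list[AbundanceRecord]:
    """Turn read-hit counts into normalized abundances.

    normalized = (100·reads_hit/reads_total) · (C / markers_n).  Genomes
    with empty barcodes (markers_n = 0) are skipped with a warning — they
    cannot be profiled.
    """
    if scan.reads_total <= 0:
        raise ParameterError("cannot normalize a scan with zero retained reads")
    level = _as_level(level)
    out: list[AbundanceRecord] = []
    for genome_id, hit in sorted(scan.reads_hit.items()):
        n = int(barcode_sizes.get(genome_id, 0))
        if n <= 0:
            logger.warning(
                "normalize_abundance: skipping %s (empty barcode)", genome_id
            )
            continue
        out.append(
            AbundanceRecord(
                sample_id=scan.sample_id,
                genome_id=genome_id,
                level=level,
                reads_total=scan.reads_total,
                reads_hit=hit,
                markers_n=n,
                norm_const=float(norm_const),
            )
        )
    return out


ABUNDANCE_COLUMNS = [
    "sample_id",
    "genome_id",
    "level",
    "reads_total",
    "reads_hit",
    "percent",
    "markers_n",
    "norm_const",
    "normalized",
]


def abundance_frame(records: Sequence[AbundanceRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "genome_id": r.genome_id,
            "level": r.level.value,
            "reads_total": r.reads_total,
            "reads_hit": r.reads_hit,
            "percent": r.percent_reads,
            "markers_n": r.markers_n,
            "norm_const": r.norm_const,
            "normalized": r.normalized,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def write_abundance_tsv(records: Sequence[AbundanceRecord], path: Path | str) -> Path:
    path = Path(path)
    abundance_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_abundance_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogroup aggregation
# ---------------------------------------------------------------------------

SINGLETON = "singleton"


def aggregate_by_phylogroup(
    records: Sequence[AbundanceRecord] | pd.DataFrame,
    phylogroups: Mapping[str, str],
) -> pd.DataFrame:
    """Summarise normalized abundances per phylogroup for one sample.

    Genomes mapped to the ``singleton`` label form one-member groups keyed
    ``singleton:<genome_id>`` so lone lineages stay individually visible.
    Returns a frame with member count, mean, median and quartiles per group.
    """
    df = (
        abundance_frame(records)
        if not isinstance(records, pd.DataFrame)
        else records.copy()
    )
    unmapped = sorted(set(df["genome_id"]) - set(phylogroups))
    if unmapped:
        raise ParameterError(f"genomes missing from phylogroup map: {unmapped}")

    def group_key(g: str) -> str:
        label = phylogroups[g]
        return f"{SINGLETON}:{g}" if label == SINGLETON else label

    df = df.assign(phylogroup=df["genome_id"].map(group_key))
    rows = []
    for pg, sub in df.groupby("phylogroup", sort=True):
        v = sub["normalized"].to_numpy(dtype=float)
        rows.append(
            {
                "phylogroup": pg,
                "n_genomes": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "members": ",".join(sorted(sub["genome_id"])),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired trajectories across time points
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["sample_id", "subject", "time_point", "arm"]


@dataclass
class Trajectory:
    """Ordered abundance of one genome in one subject across time points."""

    genome_id: str
    subject: str
    arm: str
    time_points: list
    values: list[float]
    complete: bool
    initial_response: str = ""  # decrease | no-change | increase
    final_outcome: str = ""  # recovery | overshoot | further-decline | partial-recovery


def _classify(values: Sequence[float], threshold: float) -> tuple[str, str]:
    """Scenario labels from (baseline, post-treatment, ..., final) values.

    The initial response compares the second point with baseline; the final
    outcome compares the last point with a ±threshold band around baseline,
    with a drop below the post-treatment level marked further-decline.
    """
    base, after, final = values[0], values[1], values[-1]
    if base > 0:
        rel = (after - base) / base
        initial = (
            "decrease" if rel < -threshold else "increase" if rel > threshold else "no-change"
        )
    else:
        initial = "increase" if after > 0 else "no-change"
    lo, hi = base * (1 - threshold), base * (1 + threshold)
    if final > hi:
        outcome = "overshoot"
    elif final >= lo:
        outcome = "recovery"
    elif final <= after * (1 - threshold) or final == 0 <= after:
        outcome = "further-decline"
    else:
        outcome = "partial-recovery"
    return initial, outcome


def paired_trajectory(
    records: Sequence[AbundanceRecord] | pd.DataFrame,
    design: pd.DataFrame,
    threshold: float = 0.2,
) -> list[Trajectory]:
    """Per genome × subject time series with adaptive-response scenarios.

    ``design`` maps sample_id → (subject, time_point, arm); time points are
    ordered by sorting their values.  A subject missing any design time
    point for a genome yields an incomplete trajectory that is excluded
    from scenario classification.  ``threshold`` is the relative change
    (default ±20%) below which two abundances count as unchanged.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ParameterError(f"design table is missing columns: {missing}")
    df = (
        abundance_frame(records)
        if not isinstance(records, pd.DataFrame)
        else records.copy()
    )
    merged = df.merge(design[DESIGN_COLUMNS], on="sample_id", how="inner")
    all_tps = sorted(design["time_point"].unique())
    out: list[Trajectory] = []
    for (genome, subject), sub in merged.groupby(["genome_id", "subject"], sort=True):
        sub = sub.sort_values("time_point")
        arm = str(sub["arm"].iloc[0])
        tps = list(sub["time_point"])
        vals = [float(v) for v in sub["normalized"]]
        complete = tps == all_tps and len(tps) >= 3
        traj = Trajectory(
            genome_id=str(genome),
            subject=str(subject),
            arm=arm,
            time_points=tps,
            values=vals,
            complete=complete,
        )
        if complete:
            traj.initial_response, traj.final_outcome = _classify(vals, threshold)
        else:
            logger.warning(
                "trajectory %s/%s incomplete (time points %s); excluded from scenarios",
                genome,
                subject,
                tps,
            )
        out.append(traj)
    return out


def scenario_counts(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Count complete trajectories per (initial_response, final_outcome)."""
    rows = [
        {"initial_response": t.initial_response, "final_outcome": t.final_outcome}
        for t in trajectories
        if t.complete
    ]
    if not rows:
        return pd.DataFrame(columns=["initial_response", "final_outcome", "count"])
    df = pd.DataFrame(rows)
    return (
        df.value_counts(["initial_response", "final_outcome"])
        .rename("count")
        .reset_index()
        .sort_values(["initial_response", "final_outcome"])
        .reset_index(drop=True)
    )
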