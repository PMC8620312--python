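"""Packaged inventory of published marker 18-mer counts.

Two small TSVs ship with the package, transcribing the published marker
18-mer inventory for a *Lacticaseibacillus* reference panel:

* genus level — 75 genomes (47 *L. paracasei*, 2 *L. casei*, 1 *L. zeae*,
  1 *L. manihotivorans*, 24 *L. rhamnosus*) with the number of 18-mers
  unique to the genus (absent from all other genera and all plasmids);
* species/strain level — the 47 *L. paracasei* genomes with phylogroup
  labels (I–IV or singleton), species-specific and strain-specific set
  sizes, and a ``retained`` flag marking the 31 genomes whose
  strain-specific sets were large enough for metagenome profiling
  (the 16 smallest sets, two of them empty, were dropped).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .barcode import KbarcodeError, ParameterError

_GENUS_FILE = "lacticaseibacillus_genus_barcode_sizes.tsv"
_SPECIES_FILE = "lparacasei_species_strain_barcode_sizes.tsv"

_SHA256 = {
    _GENUS_FILE: "db989be6812084ac02dfb38c92df9f835dbe09c503bcf1233238d7728cac3848",
    _SPECIES_FILE: "59b7fe0dd0e5d1f56789b987519cd319b7aa39b4916d67914d183735629459bb",
}


class IntegrityError(KbarcodeError, RuntimeError):
    """A packaged data file does not match its recorded checksum."""


@dataclass
class TableFixture:
    """The packaged marker-count inventory.

    ``genus``: 75 rows (strain, species, phylogroup, genus_specific_18mers).
    ``species``: 47 rows (strain, phylogroup, species_specific_18mers,
    strain_specific_18mers, retained).
    """

    genus: pd.DataFrame
    species: pd.DataFrame

    @property
    def retained(self) -> pd.DataFrame:
        return self.species[self.species["retained"]]

    @property
    def excluded(self) -> pd.DataFrame:
        return self.species[~self.species["retained"]]


def _data_bytes(name: str) -> bytes:
    ref = resources.files("kbarcode").joinpath("data").joinpath(name)
    return ref.read_bytes()


def load_table_fixture() -> TableFixture:
    """Load and checksum-verify the packaged marker-count tables."""
    frames = {}
    for name in (_GENUS_FILE, _SPECIES_FILE):
        raw = _data_bytes(name)
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _SHA256[name]:
            raise IntegrityError(
                f"packaged table {name} checksum mismatch: {digest}"
            )
        from io import BytesIO

        frames[name] = pd.read_csv(BytesIO(raw), sep="\t", keep_default_na=False)
    species = frames[_SPECIES_FILE]
    species["retained"] = species["retained"].astype(bool)
    return TableFixture(genus=frames[_GENUS_FILE], species=species)


def summarize_barcode_sizes(
    rows: pd.DataFrame, column: str, subset: pd.Series | None = None
) -> tuple[int, int, int]:
    """(min, max, mean) of one size column; mean rounded half-up to integer."""
    if subset is not None:
        rows = rows[subset]
    if rows.empty:
        raise ParameterError("summarize_barcode_sizes: empty subset")
    values = rows[column].astype(int)
    exact_mean = Decimal(int(values.sum())) / Decimal(len(values))
    mean = int(exact_mean.quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return int(values.min()), int(values.max()), mean
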