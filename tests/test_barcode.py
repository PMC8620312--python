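"""Unit and property tests for k-mer extraction and barcode building."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from kbarcode import (
    Barcode,
    ConfigurationError,
    GenomeRecord,
    KmerParams,
    KmerSet,
    ParameterError,
    ReferenceCollection,
    SpecificityLevel,
    build_barcode,
    clear_cross_links,
    extract_kmers,
    read_barcode,
    reverse_complement,
    write_barcode,
)

from conftest import oracle_barcode, oracle_windows, random_collection

dna = st.text(alphabet="ACGT", min_size=0, max_size=80)
dna_iupac = st.text(alphabet="ACGTNRYW", min_size=0, max_size=80)


class TestExtractKmers:
    @pytest.mark.parametrize(
        "seq,k,canonical,expected",
        [
            ("ACGT", 3, False, {"ACG", "CGT"}),
            ("ACGNT", 3, False, {"ACG"}),
            ("ACGT", 3, True, {"ACG"}),  # CGT canonicalizes to ACG
            ("AC", 3, False, set()),
            ("AC", 3, True, set()),
        ],
    )
    def test_worked_examples(self, seq, k, canonical, expected):
        ks = extract_kmers(seq, KmerParams(k=k, canonical=canonical))
        assert set(ks.words) == expected

    def test_k_below_two_rejected(self):
        with pytest.raises(ParameterError):
            KmerParams(k=1)

    @given(seq=dna_iupac, k=st.integers(2, 6), canonical=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_matches_window_oracle(self, seq, k, canonical):
        got = set(extract_kmers(seq, KmerParams(k=k, canonical=canonical)).words)
        assert got == oracle_windows(seq, k, canonical)

    @given(seq=dna, k=st.integers(2, 6))
    @settings(max_examples=100, deadline=None)
    def test_canonical_strand_symmetry(self, seq, k):
        params = KmerParams(k=k, canonical=True)
        fwd = extract_kmers(seq, params).words
        rev = extract_kmers(reverse_complement(seq), params).words
        assert fwd == rev

    @given(seq=dna, k=st.integers(2, 6))
    @settings(max_examples=100, deadline=None)
    def test_all_words_have_length_k(self, seq, k):
        params = KmerParams(k=k, canonical=True)
        ks = extract_kmers(seq, params)
        assert all(len(w) == k for w in ks.words)
        assert all(w <= reverse_complement(w) for w in ks.words)


def _mini_collection(params=None):
    target = GenomeRecord("T", ["ACGTAACC"], genus="Ga", species="s1", strain="T")
    other = GenomeRecord("E", ["TTACGTT"], genus="Gb", species="s2", strain="E")
    return target, ReferenceCollection([target, other], params or KmerParams(3, False))


class TestBuildBarcode:
    def test_subtraction_example(self):
        target, coll = _mini_collection()
        bc = build_barcode(target, coll, "strain")
        assert set(bc.kmers.words) == {"GTA", "TAA", "AAC", "ACC"}
        assert bc.size == 4

    def test_identical_genome_gives_empty_strain_barcode(self, caplog):
        a = GenomeRecord("a", ["ACGTACGTAG"], genus="G", species="s", strain="a")
        b = GenomeRecord("b", ["ACGTACGTAG"], genus="G", species="s", strain="b")
        coll = ReferenceCollection([a, b], KmerParams(3, False))
        with caplog.at_level("WARNING", logger="kbarcode"):
            bc = build_barcode(a, coll, SpecificityLevel.STRAIN)
        assert bc.size == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_lone_genome_keeps_all_kmers(self):
        g = GenomeRecord("solo", ["ACGTAACC"], genus="G", species="s", strain="x")
        coll = ReferenceCollection([g], KmerParams(3, False))
        bc = build_barcode(g, coll, "strain")
        assert set(bc.kmers.words) == set(extract_kmers("ACGTAACC", coll.params).words)

    def test_missing_genus_label_is_configuration_error(self):
        g = GenomeRecord("x", ["ACGTACGT"])
        coll = ReferenceCollection([g], KmerParams(3, False))
        with pytest.raises(ConfigurationError):
            build_barcode(g, coll, "genus")

    def test_own_plasmid_excluded_from_barcode(self):
        g = GenomeRecord(
            "x",
            ["ACGTAACC", "ACGTT"],
            genus="G",
            species="s",
            strain="x",
            is_plasmid=[False, True],
        )
        coll = ReferenceCollection([g], KmerParams(3, False))
        bc = build_barcode(g, coll, "strain")
        # ACG and CGT live on the plasmid too, so they are excluded
        assert set(bc.kmers.words) == {"GTA", "TAA", "AAC", "ACC"}

    @pytest.mark.parametrize("canonical", [False, True])
    def test_matches_bruteforce_oracle_random_collections(self, canonical):
        rng = random.Random(1234 + canonical)
        for trial in range(40):
            k = rng.choice([3, 4, 5])
            coll = random_collection(rng, k, canonical)
            sizes = {}
            for target in coll:
                if target.is_host:
                    continue
                prev = None
                for level in ("genus", "species", "strain"):
                    got = build_barcode(target, coll, level)
                    want = oracle_barcode(target, coll, level)
                    assert set(got.kmers.words) == want, (trial, target.genome_id, level)
                    if prev is not None:  # nesting: strain ⊆ species ⊆ genus
                        assert set(got.kmers.words) <= prev
                    prev = set(got.kmers.words)

    def test_exclusion_order_invariance(self):
        rng = random.Random(77)
        coll = random_collection(rng, 4, True)
        target = next(g for g in coll if not g.is_host)
        ref = build_barcode(target, coll, "strain").kmers.words
        for _ in range(3):
            genomes = list(coll.genomes)
            rng.shuffle(genomes)
            shuffled = ReferenceCollection(genomes, coll.params)
            assert build_barcode(target, shuffled, "strain").kmers.words == ref

    def test_canonical_barcode_invariant_under_revcomp_inputs(self):
        rng = random.Random(99)
        coll = random_collection(rng, 4, True, with_host=False)
        flipped = ReferenceCollection(
            [
                GenomeRecord(
                    g.genome_id,
                    [reverse_complement(s) for s in g.sequences],
                    genus=g.genus,
                    species=g.species,
                    strain=g.strain,
                    is_plasmid=list(g.is_plasmid),
                    is_host=g.is_host,
                )
                for g in coll
            ],
            coll.params,
        )
        for g, gf in zip(coll, flipped):
            if g.is_host:
                continue
            a = build_barcode(g, coll, "species").kmers.words
            b = build_barcode(gf, flipped, "species").kmers.words
            assert a == b


class TestClearCrossLinks:
    def _bc(self, words, gid="g", k=3):
        return Barcode(
            genome_id=gid,
            level=SpecificityLevel.STRAIN,
            kmers=KmerSet(frozenset(words), KmerParams(k=k, canonical=False)),
        )

    def test_shared_word_removed_from_all(self):
        out = clear_cross_links([self._bc({"AAA", "CCC"}, "a"), self._bc({"CCC", "GGG"}, "b")])
        assert set(out[0].kmers.words) == {"AAA"}
        assert set(out[1].kmers.words) == {"GGG"}

    def test_disjoint_unchanged_and_identical_emptied(self):
        out = clear_cross_links([self._bc({"AAA"}, "a"), self._bc({"GGG"}, "b")])
        assert [set(b.kmers.words) for b in out] == [{"AAA"}, {"GGG"}]
        out = clear_cross_links([self._bc({"AAA"}, "a"), self._bc({"AAA"}, "b")])
        assert [b.size for b in out] == [0, 0]

    def test_mixed_k_rejected(self):
        with pytest.raises(ParameterError):
            clear_cross_links([self._bc({"AAA"}, k=3), self._bc({"AAAA"}, k=4)])

    def test_output_pairwise_disjoint_and_idempotent(self):
        rng = random.Random(5)
        words = ["".join(rng.choice("ACGT") for _ in range(4)) for _ in range(60)]
        bcs = [
            self._bc(set(rng.sample(words, rng.randint(1, 25)), ), f"g{i}", k=4)
            for i in range(5)
        ]
        once = clear_cross_links(bcs)
        for i in range(len(once)):
            for j in range(i + 1, len(once)):
                assert not (once[i].kmers.words & once[j].kmers.words)
        twice = clear_cross_links(once)
        assert [b.kmers.words for b in twice] == [b.kmers.words for b in once]
        assert [b.genome_id for b in once] == [b.genome_id for b in bcs]


class TestBarcodeIO:
    def test_roundtrip_bitexact(self, tmp_path):
        rng = random.Random(3)
        words = {"".join(rng.choice("ACGT") for _ in range(5)) for _ in range(200)}
        bc = Barcode(
            genome_id="Strain X/1",
            level=SpecificityLevel.SPECIES,
            kmers=KmerSet(frozenset(words), KmerParams(5, True)),
            collection_digest="abc123",
        )
        txt, sidecar = write_barcode(bc, tmp_path)
        back = read_barcode(txt)
        assert back.kmers.words == bc.kmers.words
        assert back.params == bc.params
        assert back.level == bc.level
        assert back.genome_id == bc.genome_id
        assert back.collection_digest == "abc123"
        # writing the reread barcode reproduces the file byte-for-byte
        twice, _ = write_barcode(back, tmp_path / "again")
        assert twice.read_bytes() == txt.read_bytes()
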