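"""Join classification, splitting, and overlap-window geometry."""

import numpy as np
import pytest

from prfscan.candidates import (GenomeView, classify_join, find_overlap_regions,
                                split_joined)
from prfscan.dna import STOP_CODONS, revcomp
from prfscan.fixtures import FixtureSpec, make_genome
from prfscan.genbank_io import CDSFeature, GenomeRecord, Location


def _genome_with_join(sep: int, strand: int = 1) -> tuple[GenomeRecord, CDSFeature]:
    seq = "ACGT" * 300
    locs = [Location(101, 200, strand), Location(201 + sep, 350 + sep, strand)]
    if strand == -1:
        # biological order on the minus strand: frag1 high, frag2 low
        locs = [Location(601, 700, -1), Location(451 - sep, 600 - sep, -1)]
    feat = CDSFeature(locs)
    genome = GenomeRecord("J", seq, features=[feat])
    return genome, feat


class TestClassifyJoin:
    @pytest.mark.parametrize("sep", range(0, 21))
    def test_threshold_probe(self, sep):
        """Separations <= 10 bp are frameshifts; wider ones are not."""
        genome, feat = _genome_with_join(sep)
        jc = classify_join(feat, genome)
        assert jc.fragment_separation == sep
        assert jc.kind == ("frameshift" if sep <= 10 else "other")

    def test_worked_example_abutting_fragments(self, two_gene_text):
        from prfscan.genbank_io import read_genbank
        genome = read_genbank(two_gene_text)[0]
        jc = classify_join(genome.features[1], genome)
        assert jc.kind == "frameshift"
        assert jc.fragment_separation == 0

    def test_wide_separation_is_annotation_error(self):
        genome, feat = _genome_with_join(72)
        assert classify_join(feat, genome).kind == "other"

    def test_circular_wrap(self):
        seq = "ACGT" * 250
        feat = CDSFeature([Location(901, 1000, 1), Location(1, 80, 1)])
        genome = GenomeRecord("C", seq, circular=True, features=[feat])
        assert classify_join(feat, genome).kind == "circular_wrap"

    def test_three_fragments_are_other(self):
        feat = CDSFeature([Location(1, 30, 1), Location(31, 60, 1),
                           Location(61, 90, 1)])
        genome = GenomeRecord("T", "ACGT" * 30, features=[feat])
        assert classify_join(feat, genome).kind == "other"

    @pytest.mark.parametrize("sep", [0, 1, 5, 15])
    def test_invariant_under_strand_complementation(self, sep):
        plus, fplus = _genome_with_join(sep, strand=1)
        minus, fminus = _genome_with_join(sep, strand=-1)
        minus = GenomeRecord(minus.name, revcomp(plus.sequence),
                             features=minus.features)
        assert classify_join(fplus, plus).kind == classify_join(fminus, minus).kind


class TestSplitJoined:
    def test_worked_example(self):
        feat = CDSFeature([Location(200, 300, 1), Location(301, 400, 1)])
        a, b = split_joined(feat)
        assert a.locations == [Location(200, 300, 1)]
        assert b.locations == [Location(301, 400, 1)]
        assert not a.is_joined and not b.is_joined

    def test_reverse_strand_fragments_in_biological_order(self):
        feat = CDSFeature([Location(301, 400, -1), Location(200, 300, -1)])
        a, b = split_joined(feat)
        assert a.locations[0].start == 301     # 5'-most on the minus strand
        assert b.locations[0].start == 200

    def test_union_of_spans_reproduces_compound_location(self):
        for seed in range(60, 70):
            rec, _ = make_genome(FixtureSpec(seed=seed, genome_length=2000))
            for feat in rec.features:
                if feat.is_joined:
                    a, b = split_joined(feat)
                    spans = sorted([a.locations[0], b.locations[0]],
                                   key=lambda l: l.start)
                    assert spans == sorted(feat.locations, key=lambda l: l.start)

    def test_refuses_wide_join(self):
        feat = CDSFeature([Location(1, 100, 1), Location(200, 300, 1)])
        with pytest.raises(ValueError):
            split_joined(feat)


def _fig3_layout_genome() -> GenomeRecord:
    """geneA of 10 codons; geneB starts inside geneA's stop codon, and the
    nearest upstream stop in geneB's frame is exactly six codons away."""
    rng = np.random.default_rng(5)
    for _ in range(1000):
        seq = list("ATG" + "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=24)) + "TAA")
        seq += list("".join("ACGT"[i] for i in rng.integers(0, 4, size=60)))
        s = "".join(seq)
        # geneA [0, 30), frame 0; geneB starts at 28, frame 1
        b_start = 28
        seq[10:13] = "TAA"                       # planted upstream stop
        s = "".join(seq)
        if any(s[i:i + 3] in STOP_CODONS for i in range(0, 27, 3)):
            continue
        if any(s[q:q + 3] in STOP_CODONS for q in range(13, b_start, 3)):
            continue
        gene_b_end = b_start + 33
        if any(s[q:q + 3] in STOP_CODONS for q in range(b_start, gene_b_end - 3, 3)):
            continue
        s = s[:gene_b_end - 3] + "TAA" + s[gene_b_end:]
        if any(s[i:i + 3] in STOP_CODONS for i in range(0, 27, 3)):
            continue
        return GenomeRecord("FIG3LIKE", s, features=[
            CDSFeature([Location(1, 30, 1)], product="geneA"),
            CDSFeature([Location(b_start + 1, gene_b_end, 1)], product="geneB"),
        ])
    raise AssertionError("could not build layout")


class TestOverlapRegions:
    def test_upstream_stop_six_codons_away(self):
        genome = _fig3_layout_genome()
        regions = find_overlap_regions(genome)
        assert len(regions) == 1
        region = regions[0]
        assert region.upstream_stop_offset_codons == 6
        assert region.window_start == 13          # just after the planted stop
        assert region.window_end == 30            # end of geneA's stop codon
        assert region.stop_a_start == 27

    def test_opposite_strand_pair_yields_nothing(self):
        seq = "ATG" + "GCA" * 8 + "TAA" + "C" * 10 + revcomp("ATG" + "GCA" * 8 + "TAA")
        genome = GenomeRecord("OPP", seq, features=[
            CDSFeature([Location(1, 30, 1)]),
            CDSFeature([Location(41, 70, -1)]),
        ])
        assert find_overlap_regions(genome) == []

    def test_window_bounds_match_exhaustive_stop_scan(self):
        """Brute-force oracle: scan every codon position for stops."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(200):
            n = 400
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            a_start, a_len = 30, 90
            b_start = int(rng.integers(a_start + 31, a_start + 150))
            if (b_start - a_start) % 3 == 0:
                continue
            genome = GenomeRecord("R", seq, features=[
                CDSFeature([Location(a_start + 1, a_start + a_len, 1)]),
                CDSFeature([Location(b_start + 1, b_start + 60, 1)]),
            ])
            regions = find_overlap_regions(genome)
            # oracle: independent stop scans in each frame
            fa, fb = a_start % 3, b_start % 3
            p = a_start + a_len - 3
            while p < n - 2 and seq[p:p + 3] not in STOP_CODONS:
                p += 3
            stop_a = p if p < n - 2 and seq[p:p + 3] in STOP_CODONS else None
            q = b_start - 3
            while q >= 0 and seq[q:q + 3] not in STOP_CODONS:
                q -= 3
            win_start = q + 3 if q >= 0 else fb
            win_start = max(win_start, a_start)   # shift starts inside geneA
            if stop_a is None or win_start >= a_start + a_len or \
                    win_start >= stop_a:
                assert not [r for r in regions if r.strand == 1]
                continue
            plus = [r for r in regions if r.strand == 1]
            if not plus:
                # rejected for having no usable codon boundary
                continue
            assert plus[0].window_start == win_start
            assert plus[0].window_end == stop_a + 3
            checked += 1
        assert checked > 30

    def test_windows_are_stop_free_in_geneB_frame(self, small_corpus):
        for item in small_corpus:
            for region in find_overlap_regions(item.record):
                seq = region.view.seq
                fb = region.gene_b.frame
                q = region.window_start + (fb - region.window_start) % 3
                while q + 3 <= region.gene_b.start:
                    assert seq[q:q + 3] not in STOP_CODONS
                    q += 3

    def test_planted_site_lies_in_exactly_one_region(self, small_corpus):
        for item in small_corpus:
            regions = find_overlap_regions(item.record)
            for t in item.truth:
                containing = [r for r in regions
                              if r.strand == t.strand and
                              r.window_start <= t.a_site_view < r.window_end]
                assert len(containing) == 1
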