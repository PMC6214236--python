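"""Tests of VCF/BAM input, fragment encoding, block building, and output."""

import textwrap

import numpy as np
import pysam
import pytest

from hierphase.assembly import PhasedBlock
from hierphase.fragments import (
    Fragment,
    VariantBlock,
    VariantSite,
    build_blocks,
    extract_fragments,
    read_fragment_file,
    read_phased_blocks,
    read_variants,
    write_fragment_file,
    write_phased_vcf,
)

from conftest import make_fragment, make_sites

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##contig=<ID=chr2,length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1
    """
)


def write_vcf(tmp_path, records, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return str(path)


class TestReadVariants:
    def test_het_only(self, tmp_path):
        path = write_vcf(
            tmp_path,
            [
                "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1",
                "chr1\t200\t.\tG\tT\t.\tPASS\t.\tGT\t1/1",
            ],
        )
        sites = read_variants(path)
        assert len(sites) == 1 and sites[0].pos == 100

    def test_indel_and_multiallelic_excluded(self, tmp_path):
        path = write_vcf(
            tmp_path,
            [
                "chr1\t100\t.\tAT\tA\t.\tPASS\t.\tGT\t0/1",
                "chr1\t150\t.\tA\tC,G\t.\tPASS\t.\tGT\t1/2",
                "chr1\t200\t.\tG\tT\t.\tPASS\t.\tGT\t0/1",
            ],
        )
        sites = read_variants(path)
        assert [s.pos for s in sites] == [200]

    def test_site_index_per_chromosome(self, tmp_path):
        path = write_vcf(
            tmp_path,
            [
                "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1",
                "chr1\t300\t.\tG\tT\t.\tPASS\t.\tGT\t0/1",
                "chr2\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/1",
            ],
        )
        sites = read_variants(path)
        assert len(sites) == 3
        by_chrom = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s.site_index)
        assert by_chrom == {"chr1": [0, 1], "chr2": [0]}

    def test_missing_sample_errors(self, tmp_path):
        path = write_vcf(tmp_path, ["chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1"])
        with pytest.raises(ValueError, match="sample"):
            read_variants(path, sample_id="nope")


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def write_sam(tmp_path, lines, name="test.sam"):
    path = tmp_path / name
    path.write_text(SAM_HEADER + "".join(l + "\n" for l in lines))
    return str(path)


def sam_line(name, pos, seq, flag=0, mapq=60, cigar=None, qual=None):
    cigar = cigar or f"{len(seq)}M"
    qual = qual or "I" * len(seq)
    return f"{name}\t{flag}\t{chr1}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"


chr1 = "chr1"


class TestExtractFragments:
    # sites at 1-based positions 101 and 105 (ref A, alt C)
    def sites(self):
        return [
            VariantSite("chr1", 101, "A", "C", 0),
            VariantSite("chr1", 105, "A", "C", 1),
            VariantSite("chr1", 301, "A", "C", 2),
        ]

    def test_single_read_ref_alt(self, tmp_path):
        sam = write_sam(tmp_path, [sam_line("r1", 101, "AAAAC")])
        frags = extract_fragments(sam, self.sites())
        assert len(frags) == 1
        assert frags[0].alleles == {0: "0", 1: "1"}

    def test_mate_merge_with_gap(self, tmp_path):
        sam = write_sam(
            tmp_path,
            [
                sam_line("rp", 101, "A", flag=99),
                sam_line("rp", 301, "C", flag=147),
            ],
        )
        frags = extract_fragments(sam, self.sites())
        assert len(frags) == 1
        assert frags[0].alleles == {0: "0", 2: "1"}  # site 1 uncovered -> gap

    def test_mate_conflict_becomes_unreliable(self, tmp_path):
        sam = write_sam(
            tmp_path,
            [
                sam_line("rp", 101, "AAAAA", flag=99),
                sam_line("rp", 103, "AACAA", flag=147),  # C at pos 105: conflicts
                sam_line("solo", 301, "C", flag=0),  # single-site read, dropped (<2 sites)
            ],
        )
        frags = extract_fragments(sam, self.sites())
        # conflicting site 105 -> '-', only site 101 remains -> uninformative
        assert frags == []

    def test_other_base_maps_to_gap(self, tmp_path):
        sam = write_sam(tmp_path, [sam_line("r1", 101, "GAAAC")])
        frags = extract_fragments(sam, self.sites())
        assert frags == []  # 'G' at first site -> '-', only one call left

    def test_chromosome_mismatch_errors(self, tmp_path):
        sam = write_sam(tmp_path, [sam_line("r1", 101, "AAAAC")])
        bad = [VariantSite("chrX", 101, "A", "C", 0)]
        with pytest.raises(ValueError, match="chrX"):
            extract_fragments(sam, bad)

    def test_base_quality_filter(self, tmp_path):
        sam = write_sam(tmp_path, [sam_line("r1", 101, "AAAAC", qual="I" * 4 + "#")])
        frags = extract_fragments(sam, self.sites(), min_baseq=20)
        assert frags == []  # low-quality alt call removed -> uninformative


class TestFragmentFile:
    def test_round_trip(self, tmp_path):
        frags = [
            make_fragment("a", (0, "01")),
            make_fragment("b", (2, "1-0")),
        ]
        path = tmp_path / "frags.tsv"
        with open(path, "w") as fh:
            write_fragment_file(frags, fh)
        with open(path) as fh:
            back = read_fragment_file(fh)
        assert [(f.name, f.alleles) for f in back] == [(f.name, f.alleles) for f in frags]

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "frags.tsv"
        path.write_text("onlyonefield\n")
        with open(path) as fh:
            with pytest.raises(ValueError, match="line 1"):
                read_fragment_file(fh)


class TestBuildBlocks:
    def test_transitive_connection(self):
        sites = make_sites([100, 200, 300])
        frags = [make_fragment("ab", {0: "0", 1: "0"}), make_fragment("bc", {1: "0", 2: "1"})]
        blocks, singles = build_blocks(frags, sites)
        assert len(blocks) == 1 and len(blocks[0].sites) == 3
        assert singles == []

    def test_disconnected_pairs(self):
        sites = make_sites([100, 200, 300, 400])
        frags = [make_fragment("ab", {0: "0", 1: "0"}), make_fragment("cd", {2: "0", 3: "1"})]
        blocks, _ = build_blocks(frags, sites)
        assert sorted(len(b.sites) for b in blocks) == [2, 2]

    def test_uncovered_site_is_singleton(self):
        sites = make_sites([100, 200, 300])
        frags = [make_fragment("ab", {0: "0", 1: "0"})]
        blocks, singles = build_blocks(frags, sites)
        assert len(blocks) == 1 and [s.pos for s in singles] == [300]

    def test_matches_networkx_components(self, rng):
        """Block partition equals graph connected components (nx oracle)."""
        import networkx as nx

        for trial in range(20):
            n = int(rng.integers(5, 30))
            sites = make_sites(range(100, 100 + 100 * n, 100))
            frags = []
            for k in range(int(rng.integers(3, 25))):
                a = int(rng.integers(0, n - 1))
                b = int(rng.integers(a + 1, min(n, a + 4) + 1 if a + 4 < n else n))
                if a == b:
                    continue
                frags.append(make_fragment(f"f{k}", {a: "0", b: "0"}))
            blocks, singles = build_blocks(frags, sites)

            g = nx.Graph()
            g.add_nodes_from(range(n))
            for f in frags:
                idxs = sorted(f.alleles)
                g.add_edges_from(zip(idxs, idxs[1:]))
            comps = [sorted(c) for c in nx.connected_components(g)]
            multi = sorted([c for c in comps if len(c) > 1])
            ours = sorted(sorted(s.site_index for s in b.sites) for b in blocks)
            assert ours == multi
            assert len(singles) == sum(1 for c in comps if len(c) == 1)

    def test_fragments_partitioned_no_overlap(self):
        sites = make_sites([100, 200, 300, 400])
        frags = [make_fragment("ab", {0: "0", 1: "0"}), make_fragment("cd", {2: "0", 3: "1"})]
        blocks, _ = build_blocks(frags, sites)
        names = [sorted(f.name for f in b.fragments) for b in blocks]
        assert sorted(n for group in names for n in group) == ["ab", "cd"]
        assert all(len(set(a) & set(b)) == 0 for a in names for b in names if a is not b)


class TestPhasedVcf:
    def _phase_and_read(self, tmp_path, hap1):
        vcf_path = write_vcf(
            tmp_path,
            [
                "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1",
                "chr1\t200\t.\tG\tT\t.\tPASS\t.\tGT\t0/1",
                "chr1\t900\t.\tA\tG\t.\tPASS\t.\tGT\t0/1",  # singleton, no fragment
            ],
        )
        sites = read_variants(vcf_path)
        block = VariantBlock(
            sites=[s for s in sites if s.pos < 900],
            fragments=[make_fragment("f", {0: "0", 1: "0"})],
        )
        sol = PhasedBlock(
            site_indices=[0, 1],
            positions=[100, 200],
            hap1=hap1,
            hap2="".join("1" if c == "0" else "0" for c in hap1),
            phased=[True, True],
        )
        out = str(tmp_path / "phased.vcf")
        write_phased_vcf([block], [sol], vcf_path, out)
        return out

    def test_round_trip_recovers_partition(self, tmp_path):
        out = self._phase_and_read(tmp_path, "00")
        blocks = read_phased_blocks(out)
        assert len(blocks) == 1
        assert blocks[0].positions == [100, 200]
        assert blocks[0].hap1 in ("00", "11")

    def test_complement_writes_same_partition(self, tmp_path):
        a = read_phased_blocks(self._phase_and_read(tmp_path, "01"))[0]
        b = read_phased_blocks(self._phase_and_read(tmp_path, "10"))[0]
        assert a.hap1 in (b.hap1, b.hap2)

    def test_singleton_left_unphased(self, tmp_path):
        out = self._phase_and_read(tmp_path, "00")
        rec_by_pos = {}
        with pysam.VariantFile(out) as vcf:
            sample = list(vcf.header.samples)[0]
            for rec in vcf:
                rec_by_pos[rec.pos] = rec.samples[sample]
        assert rec_by_pos[900].phased is False
        assert rec_by_pos[100].phased and rec_by_pos[200].phased
        assert rec_by_pos[100]["PS"] == rec_by_pos[200]["PS"] == 100
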