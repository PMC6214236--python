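"""SNP-fragment extraction, variant blocks, and phased-VCF output.

Heterozygous bi-allelic SNPs are read from a VCF; aligned reads (BAM/SAM)
are condensed into *fragments*: per read-pair strings over the variant
sites in the alphabet ``{0, 1, -}`` where ``0`` is the reference allele,
``1`` the alternate, and ``-`` anything else (other base, low quality,
deletion, or simply not covered).  Fragments covering at least two sites
are haplotype-informative; the transitive closure of "covered by a common
fragment" partitions the sites into variant blocks, the unit of phasing.

A plain-text fragment format (one fragment per line:
``name<TAB>first_site_index<TAB>allele_string``) lets the core algorithm
run without any alignment files.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "Fragment",
    "VariantBlock",
    "read_variants",
    "extract_fragments",
    "build_blocks",
    "write_phased_vcf",
    "read_fragment_file",
    "write_fragment_file",
    "read_phased_blocks",
]


@dataclass(frozen=True)
class VariantSite:
    """One heterozygous bi-allelic SNP."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    site_index: int  # 0-based ordinal within chromosome, sorted by pos

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class Fragment:
    """One sequencing unit (read pair merged) over a block's variants.

    ``alleles`` maps site_index -> '0' | '1' ('-' entries are simply not
    stored).  A fragment is informative iff it covers >= 2 sites.
    """

    name: str
    alleles: dict[int, str]

    @property
    def span(self) -> tuple[int, int]:
        return min(self.alleles), max(self.alleles)

    @property
    def informative(self) -> bool:
        return len(self.alleles) >= 2

    def to_string(self) -> tuple[int, str]:
        """(first_site_index, allele string with '-' gaps)."""
        lo, hi = self.span
        return lo, "".join(self.alleles.get(i, "-") for i in range(lo, hi + 1))


@dataclass
class VariantBlock:
    """A connected component of variants plus its informative fragments."""

    sites: list[VariantSite]
    fragments: list[Fragment]

    @property
    def site_indices(self) -> list[int]:
        return [s.site_index for s in self.sites]

    @property
    def positions(self) -> dict[int, int]:
        return {s.site_index: s.pos for s in self.sites}


# ---------------------------------------------------------------------------
# VCF input

def read_variants(vcf_source: str, sample_id: str | None = None) -> list[VariantSite]:
    """Read heterozygous bi-allelic SNPs from a VCF, sorted by (chrom, pos).

    Multi-allelic records, indels, and homozygous genotypes are dropped (a
    summary count is logged).  ``site_index`` restarts at 0 per chromosome.
    """
    vcf = pysam.VariantFile(vcf_source)
    samples = list(vcf.header.samples)
    if not samples:
        raise ValueError(f"{vcf_source}: VCF has no sample columns")
    if sample_id is None:
        sample_id = samples[0]
    elif sample_id not in samples:
        raise ValueError(f"sample {sample_id!r} not found in {vcf_source} (has {samples})")

    raw: dict[str, list[tuple[int, str, str]]] = {}
    dropped = {"multiallelic": 0, "indel": 0, "not_het": 0, "no_gt": 0}
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            dropped["multiallelic"] += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            dropped["indel"] += 1
            continue
        gt = rec.samples[sample_id].get("GT")
        if gt is None or None in gt:
            dropped["no_gt"] += 1
            continue
        if set(gt) != {0, 1}:
            dropped["not_het"] += 1
            continue
        raw.setdefault(rec.chrom, []).append((rec.pos, ref, alt))
    vcf.close()

    sites: list[VariantSite] = []
    for chrom in raw:
        entries = sorted(set(raw[chrom]))
        for idx, (pos, ref, alt) in enumerate(entries):
            sites.append(VariantSite(chrom, pos, ref, alt, idx))
    total_dropped = sum(dropped.values())
    if total_dropped:
        logger.info("read_variants: kept %d sites, dropped %s", len(sites), dropped)
    return sites


# ---------------------------------------------------------------------------
# BAM/SAM fragment extraction

def _read_alleles(
    read: pysam.AlignedSegment,
    positions: Sequence[int],
    site_by_pos: dict[int, VariantSite],
    min_baseq: int,
) -> dict[int, str]:
    """Alleles observed by one read at the given (0-based) positions."""
    out: dict[int, str] = {}
    lo = bisect_left(positions, read.reference_start)
    hi = bisect_right(positions, read.reference_end - 1)
    if lo >= hi:
        return out
    wanted = positions[lo:hi]
    covered = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=False):
        if rpos is not None and rpos in site_by_pos:
            covered[rpos] = qpos
    seq = read.query_sequence
    quals = read.query_qualities
    for rpos in wanted:
        site = site_by_pos[rpos]
        qpos = covered.get(rpos)
        if qpos is None:  # deletion or refskip at the site
            out[site.site_index] = "-"
            continue
        if quals is not None and quals[qpos] < min_baseq:
            out[site.site_index] = "-"
            continue
        base = seq[qpos].upper()
        if base == site.ref_allele.upper():
            out[site.site_index] = "0"
        elif base == site.alt_allele.upper():
            out[site.site_index] = "1"
        else:
            out[site.site_index] = "-"
    return out


def extract_fragments(
    alignment_source: str,
    sites: Sequence[VariantSite],
    min_mapq: int = 0,
    min_baseq: int = 0,
    chrom: str | None = None,
) -> list[Fragment]:
    """Condense aligned reads into informative SNP fragments.

    Mates sharing a read name are merged into one fragment; if the mates
    disagree at a shared site the site is set to ``-`` (unreliable).
    Fragments with fewer than two called sites are discarded.
    """
    if not sites:
        return []
    chroms = {s.chrom for s in sites}
    if chrom is None:
        if len(chroms) > 1:
            raise ValueError("sites span multiple chromosomes; pass chrom explicitly")
        chrom = next(iter(chroms))
    sites = sorted((s for s in sites if s.chrom == chrom), key=lambda s: s.pos)

    mode = "rb" if str(alignment_source).endswith(".bam") else "r"
    aln = pysam.AlignmentFile(alignment_source, mode)
    if chrom not in aln.references:
        raise ValueError(
            f"chromosome {chrom!r} absent from alignment file "
            f"(references: {list(aln.references)[:8]}...)"
        )
    positions = [s.pos - 1 for s in sites]  # pysam is 0-based
    site_by_pos = {s.pos - 1: s for s in sites}

    try:  # indexed region fetch; plain SAM has no index -> stream instead
        reads = aln.fetch(chrom, positions[0], positions[-1] + 1)
    except ValueError:
        reads = (r for r in aln.fetch(until_eof=True) if r.reference_name == chrom)

    by_name: dict[str, dict[int, str]] = {}
    conflicts = 0
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        if read.mapping_quality < min_mapq:
            continue
        calls = _read_alleles(read, positions, site_by_pos, min_baseq)
        if not calls:
            continue
        acc = by_name.setdefault(read.query_name, {})
        for idx, sym in calls.items():
            prev = acc.get(idx)
            if prev is None:
                acc[idx] = sym
            elif prev != sym and "-" not in (prev, sym):
                acc[idx] = "-"  # mates disagree: treat as unreliable
                conflicts += 1
    aln.close()
    if conflicts:
        logger.info("extract_fragments: %d mate-conflict sites set to '-'", conflicts)

    fragments = []
    for name, calls in by_name.items():
        alleles = {i: s for i, s in calls.items() if s != "-"}
        if len(alleles) >= 2:
            fragments.append(Fragment(name=name, alleles=alleles))
    return fragments


# ---------------------------------------------------------------------------
# Plain-text fragment format

def write_fragment_file(fragments: Iterable[Fragment], fh: IO[str]) -> None:
    """One fragment per line: ``name<TAB>first_site_index<TAB>alleles``."""
    for frag in fragments:
        first, alleles = frag.to_string()
        fh.write(f"{frag.name}\t{first}\t{alleles}\n")


def read_fragment_file(fh: IO[str]) -> list[Fragment]:
    fragments = []
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"fragment file line {lineno}: expected 3 tab-separated fields")
        name, first_s, allele_str = parts
        first = int(first_s)
        alleles = {
            first + off: sym
            for off, sym in enumerate(allele_str)
            if sym in "01"
        }
        if not alleles:
            raise ValueError(f"fragment file line {lineno}: no called alleles")
        fragments.append(Fragment(name=name, alleles=alleles))
    return fragments


# ---------------------------------------------------------------------------
# Variant blocks

class _UnionFind:
    def __init__(self, items: Iterable[int]):
        self.parent = {i: i for i in items}

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_blocks(
    fragments: Iterable[Fragment],
    sites: Sequence[VariantSite],
) -> tuple[list[VariantBlock], list[VariantSite]]:
    """Partition sites into variant blocks (connected components).

    Returns ``(blocks, singletons)`` where singletons are sites with no
    informative coverage; they cannot be phased.  Each block's fragment list
    holds exactly the fragments informative within that block.
    """
    site_by_index = {s.site_index: s for s in sites}
    uf = _UnionFind(site_by_index)
    informative = [f for f in fragments if f.informative]
    for frag in informative:
        idxs = [i for i in frag.alleles if i in site_by_index]
        for a, b in zip(idxs, idxs[1:]):
            uf.union(a, b)

    members: dict[int, list[int]] = {}
    for idx in site_by_index:
        members.setdefault(uf.find(idx), []).append(idx)

    frag_sets: dict[int, list[Fragment]] = {}
    for frag in informative:
        idxs = [i for i in frag.alleles if i in site_by_index]
        if len(idxs) < 2:
            continue
        frag_sets.setdefault(uf.find(idxs[0]), []).append(frag)

    blocks: list[VariantBlock] = []
    singletons: list[VariantSite] = []
    for root, idxs in members.items():
        if len(idxs) == 1 and root not in frag_sets:
            singletons.append(site_by_index[idxs[0]])
            continue
        block_sites = sorted((site_by_index[i] for i in idxs), key=lambda s: s.pos)
        blocks.append(VariantBlock(sites=block_sites, fragments=frag_sets.get(root, [])))
    blocks.sort(key=lambda b: b.sites[0].pos)
    singletons.sort(key=lambda s: s.pos)
    return blocks, singletons


# ---------------------------------------------------------------------------
# Phased VCF output

def write_phased_vcf(
    blocks: Sequence[VariantBlock],
    solutions: Sequence,  # Sequence[PhasedBlock]
    vcf_source: str,
    out: str,
) -> None:
    """Write phased genotypes (0|1 / 1|0 + PS tag) back into the input VCF.

    The phase-set (PS) identifier is the position of the block's first
    variant.  Sites left undecided, and variants outside any block, are
    emitted unphased (0/1, no PS).  Other records pass through unchanged.
    """
    vcf = pysam.VariantFile(vcf_source)
    header = vcf.header.copy()
    if "PS" not in header.formats:
        header.formats.add("PS", 1, "Integer", "Phase set identifier")
    sample = list(header.samples)[0]

    # (chrom, pos) -> (hap1 allele, phase set)
    phase_map: dict[tuple[str, int], tuple[int, int]] = {}
    for block, sol in zip(blocks, solutions):
        if sol is None:
            continue
        ps = block.sites[0].pos
        for site, allele, phased in zip(block.sites, sol.hap1, sol.phased):
            if phased:
                phase_map[(site.chrom, site.pos)] = (int(allele), ps)

    with pysam.VariantFile(out, "w", header=header) as writer:
        for rec in vcf:
            rec.translate(header)
            key = (rec.chrom, rec.pos)
            if key in phase_map:
                a1, ps = phase_map[key]
                rec.samples[sample]["GT"] = (a1, 1 - a1)
                rec.samples[sample].phased = True
                rec.samples[sample]["PS"] = ps
            writer.write(rec)
    vcf.close()


def read_phased_blocks(vcf_source: str, sample_id: str | None = None):
    """Decode a phased VCF back into phased blocks.

    Phased heterozygous SNPs are grouped by (chrom, PS); sites without a PS
    tag on the same chromosome form one group.  Site identifiers are
    genomic positions, so blocks from different files over the same variants
    are directly comparable.  Returns a list of
    :class:`hierphase.assembly.PhasedBlock`.
    """
    from .assembly import PhasedBlock  # local import: avoid cycle

    vcf = pysam.VariantFile(vcf_source)
    samples = list(vcf.header.samples)
    if sample_id is None:
        sample_id = samples[0]
    groups: dict[tuple[str, object], list[tuple[int, int]]] = {}
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            continue
        call = rec.samples[sample_id]
        gt = call.get("GT")
        if gt is None or None in gt or set(gt) != {0, 1} or not call.phased:
            continue
        ps = call.get("PS")
        groups.setdefault((rec.chrom, ps), []).append((rec.pos, gt[0]))
    vcf.close()

    blocks = []
    for (chrom, ps), entries in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        entries.sort()
        positions = [p for p, _ in entries]
        hap1 = "".join(str(a) for _, a in entries)
        hap2 = "".join(str(1 - a) for _, a in entries)
        blocks.append(
            PhasedBlock(
                site_indices=positions,
                positions=positions,
                hap1=hap1,
                hap2=hap2,
                phased=[True] * len(entries),
            )
        )
    return blocks
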