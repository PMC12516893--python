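"""Synthetic dual-haplotype amplicons, EMS mutation spiking, and pooled reads.

This module stands in for the raw data of an amplicon TILLING-by-sequencing
screen: a panel of short PCR amplicons designed on conserved regions of two
low-divergence parental genomes, a population of M2 families carrying rare
heterozygous EMS mutations (G:C -> A:T transitions), and deep pooled amplicon
sequencing of the tridimensional pools.

Coordinates are 0-based, half-open throughout; the GFF3 export converts to
1-based inclusive.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import seqcodes as sc
from .pooling import PoolingScheme

# Wrap-around split pieces shorter than this are re-extended to this length
# (emulating size selection without losing depth at the amplicon ends).
MIN_READ_LEN = 30


@dataclass
class AmpliconModel:
    """One target amplicon on both parental references.

    The two parental sequences have equal length (divergence is
    substitution-only) and share the primer regions at both ends, mirroring
    primer design on conserved regions.
    """

    amplicon_id: str
    gene_id: str
    seq_a: str
    seq_b: str
    exons: tuple[tuple[int, int], ...]
    cds_offset: int
    strand: str
    primer_len: int = 20

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.amplicon_id}: parental sequences differ in length")
        if self.strand not in "+-":
            raise ValueError(f"{self.amplicon_id}: strand must be + or -")
        prev = 0
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.seq_a)):
                raise ValueError(f"{self.amplicon_id}: exon ({s},{e}) out of bounds")
            if s < prev:
                raise ValueError(f"{self.amplicon_id}: exons unsorted or overlapping")
            prev = e

    @property
    def length(self) -> int:
        return len(self.seq_a)

    @property
    def primer_fwd(self) -> str:
        return self.seq_a[: self.primer_len]

    @property
    def primer_rev(self) -> str:
        return sc.revcomp(self.seq_a[-self.primer_len:])

    @cached_property
    def codes(self) -> np.ndarray:
        """(2, L) uint8 array of both parental sequences (0=A ... 3=T)."""
        return np.stack([sc.encode(self.seq_a), sc.encode(self.seq_b)])

    @cached_property
    def divergent_sites(self) -> np.ndarray:
        """Positions where the two parental sequences differ."""
        return np.flatnonzero(self.codes[0] != self.codes[1])


@dataclass(frozen=True)
class MutationRecord:
    family_id: int
    amplicon_id: str
    position: int  # 0-based on the amplicon
    ref_base: str
    alt_base: str
    zygosity: str  # het | hom

    def __post_init__(self):
        if (self.ref_base, self.alt_base) not in {("G", "A"), ("C", "T")}:
            raise ValueError(
                f"non-EMS mutation {self.ref_base}>{self.alt_base}: EMS induces "
                "G:C -> A:T transitions only"
            )


def truth_to_frame(truth: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.family_id, m.amplicon_id, m.position, m.ref_base, m.alt_base, m.zygosity) for m in truth],
        columns=["family_id", "amplicon_id", "position", "ref_base", "alt_base", "zygosity"],
    )


def write_truth_tsv(truth: Sequence[MutationRecord], path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        MutationRecord(int(r.family_id), str(r.amplicon_id), int(r.position),
                       str(r.ref_base), str(r.alt_base), str(r.zygosity))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _random_exons(length: int, primer_len: int, n_exons: int, rng: np.random.Generator
                  ) -> tuple[tuple[int, int], ...]:
    """Random sorted, non-overlapping exons in the primer-free interior."""
    lo, hi = primer_len, length - primer_len
    interior = hi - lo
    min_exon, min_intron = 30, 20
    while n_exons > 1 and n_exons * min_exon + (n_exons - 1) * min_intron > interior:
        n_exons -= 1
    if n_exons <= 1:
        return ((lo, hi),)
    # 2n-1 alternating segments (exon, intron, exon, ...) filling the interior.
    n_seg = 2 * n_exons - 1
    mins = np.array([min_exon if i % 2 == 0 else min_intron for i in range(n_seg)])
    slack = interior - mins.sum()
    extra = rng.multinomial(slack, np.full(n_seg, 1.0 / n_seg))
    seg = mins + extra
    bounds = lo + np.concatenate([[0], np.cumsum(seg)])
    return tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons))


def generate_references(
    n_amplicons: int = 17,
    length_range: tuple[int, int] = (452, 704),
    divergence: float = 0.005,
    n_exons_range: tuple[int, int] = (1, 3),
    seed: int | np.random.Generator = 0,
    n_genes: int = 13,
    primer_len: int = 20,
) -> list[AmpliconModel]:
    """Generate a dual-haplotype amplicon panel.

    Genome B differs from genome A at Bernoulli(``divergence``) positions,
    never inside the primer regions (primers sit on conserved sequence).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0,1], got {divergence}")
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"inverted length_range {length_range}")
    if lo < 1:
        raise ValueError("minimum amplicon length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_genes = min(n_genes, n_amplicons)
    # First (n_amplicons - n_genes) genes carry a second amplicon.
    gene_of = list(range(n_genes)) + list(range(n_amplicons - n_genes))
    gene_of.sort()

    amplicons = []
    for i in range(n_amplicons):
        length = int(rng.integers(lo, hi + 1))
        codes_a = rng.integers(0, 4, size=length).astype(np.uint8)
        codes_b = codes_a.copy()
        interior = slice(min(primer_len, length), max(length - primer_len, 0))
        if divergence > 0 and interior.stop > interior.start:
            mask = rng.random(interior.stop - interior.start) < divergence
            idx = np.arange(interior.start, interior.stop)[mask]
            # substitute with a uniformly random *different* base
            codes_b[idx] = (codes_a[idx] + rng.integers(1, 4, size=idx.size)) % 4
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exons = _random_exons(length, min(primer_len, length // 4), n_exons, rng)
        amplicons.append(
            AmpliconModel(
                amplicon_id=f"amp{i:02d}",
                gene_id=f"gene{gene_of[i]:02d}",
                seq_a=sc.decode(codes_a),
                seq_b=sc.decode(codes_b),
                exons=exons,
                cds_offset=int(rng.integers(0, 3)),
                strand="+" if rng.random() < 0.5 else "-",
                primer_len=primer_len,
            )
        )
    return amplicons


def write_fasta(amplicons: Sequence[AmpliconModel], path_a, path_b) -> None:
    recs_a = [SeqRecord(Seq(a.seq_a), id=a.amplicon_id, description=f"gene={a.gene_id} genome=A")
              for a in amplicons]
    recs_b = [SeqRecord(Seq(a.seq_b), id=a.amplicon_id, description=f"gene={a.gene_id} genome=B")
              for a in amplicons]
    SeqIO.write(recs_a, str(path_a), "fasta")
    SeqIO.write(recs_b, str(path_b), "fasta")


def read_fasta_pair(path_a, path_b, gff3_path=None) -> list[AmpliconModel]:
    """Rebuild AmpliconModels from the two FASTA files (+ optional GFF3)."""
    recs_a = {r.id: r for r in SeqIO.parse(str(path_a), "fasta")}
    recs_b = {r.id: r for r in SeqIO.parse(str(path_b), "fasta")}
    struct = _parse_gff3(gff3_path) if gff3_path else {}
    amplicons = []
    for aid, rec in recs_a.items():
        if aid not in recs_b:
            raise ValueError(f"{aid} present in genome A FASTA but missing from genome B")
        gene = rec.description.split("gene=")[-1].split()[0] if "gene=" in rec.description else aid
        exons, cds_offset, strand = struct.get(aid, (((0, len(rec.seq)),), 0, "+"))
        amplicons.append(
            AmpliconModel(aid, gene, str(rec.seq), str(recs_b[aid].seq),
                          exons, cds_offset, strand)
        )
    return amplicons


def write_gff3(amplicons: Sequence[AmpliconModel], path) -> None:
    """Exon/CDS models per amplicon, 1-based inclusive per the GFF3 standard."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in amplicons:
            fh.write(f"##sequence-region {a.amplicon_id} 1 {a.length}\n")
        for a in amplicons:
            gid = f"{a.gene_id}.{a.amplicon_id}"
            fh.write(
                f"{a.amplicon_id}\ttillseq\tgene\t1\t{a.length}\t.\t{a.strand}\t.\t"
                f"ID={gid}\n"
            )
            for j, (s, e) in enumerate(a.exons):
                fh.write(
                    f"{a.amplicon_id}\ttillseq\texon\t{s + 1}\t{e}\t.\t{a.strand}\t.\t"
                    f"ID={gid}.exon{j};Parent={gid}\n"
                )
                frame = a.cds_offset if j == 0 else "."
                fh.write(
                    f"{a.amplicon_id}\ttillseq\tCDS\t{s + 1}\t{e}\t.\t{a.strand}\t{frame}\t"
                    f"ID={gid}.cds{j};Parent={gid}\n"
                )


def _parse_gff3(path) -> dict[str, tuple[tuple[tuple[int, int], ...], int, str]]:
    exons: dict[str, list[tuple[int, int]]] = {}
    offsets: dict[str, int] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            seqid, _, ftype, start, end, _, strand, frame = f[:8]
            if ftype == "exon":
                exons.setdefault(seqid, []).append((int(start) - 1, int(end)))
                strands[seqid] = strand
            elif ftype == "CDS" and frame != "." and seqid not in offsets:
                offsets[seqid] = int(frame)
    return {
        aid: (tuple(sorted(ex)), offsets.get(aid, 0), strands.get(aid, "+"))
        for aid, ex in exons.items()
    }


# ---------------------------------------------------------------------------
# Mutation spiking
# ---------------------------------------------------------------------------

def spike_mutations(
    scheme: PoolingScheme,
    amplicons: Sequence[AmpliconModel],
    freq_kb_per_mutation: float = 320.0,
    het_fraction: float = 1.0,
    seed: int | np.random.Generator = 0,
    n_mutations: int | None = None,
) -> list[MutationRecord]:
    """Spike EMS mutations at a target frequency of one per ``freq_kb`` kb.

    The number of mutations is Poisson with mean
    ``sum(amplicon lengths) * n_families / 1000 / freq_kb`` (``n_mutations``
    overrides it, e.g. 0 for a mutation-free run).  Each mutation hits a
    uniformly random family and a uniformly random G or C site at which the
    two parental genomes agree (divergent sites are genotype, not mutation,
    and are masked from calling), mutating G->A or C->T.
    """
    if freq_kb_per_mutation <= 0:
        raise ValueError("freq_kb_per_mutation must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    eligible: list[tuple[int, np.ndarray]] = []
    for ai, a in enumerate(amplicons):
        same = a.codes[0] == a.codes[1]
        gc = (a.codes[0] == sc.G) | (a.codes[0] == sc.C)
        sites = np.flatnonzero(same & gc)
        eligible.append((ai, sites))
    n_sites = np.array([s.size for _, s in eligible])
    if n_sites.sum() == 0:
        raise RuntimeError("no conserved G/C site available for EMS spiking")

    total_kb = sum(a.length for a in amplicons) * scheme.n_families / 1000.0
    if n_mutations is None:
        n_mutations = int(rng.poisson(total_kb / freq_kb_per_mutation))

    truth: list[MutationRecord] = []
    used: set[tuple[int, str, int]] = set()
    p_amp = n_sites / n_sites.sum()
    while len(truth) < n_mutations:
        fam = int(rng.integers(0, scheme.n_families))
        ai = int(rng.choice(len(amplicons), p=p_amp))
        amp = amplicons[ai]
        pos = int(rng.choice(eligible[ai][1]))
        key = (fam, amp.amplicon_id, pos)
        if key in used:
            continue
        used.add(key)
        ref = amp.seq_a[pos]
        alt = "A" if ref == "G" else "T"
        zyg = "het" if rng.random() < het_fraction else "hom"
        truth.append(MutationRecord(fam, amp.amplicon_id, pos, ref, alt, zyg))
    return truth


# ---------------------------------------------------------------------------
# Pooled read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Reads of one pool: a padded code matrix plus per-read lengths.

    ``source_amplicon`` records which amplicon each read was simulated from;
    it is carried only for read naming and truth-side bookkeeping and is
    never consulted by the aligner.
    """

    bases: np.ndarray  # (N, width) uint8, padded with 0 beyond `lengths`
    lengths: np.ndarray  # (N,) int32
    source_amplicon: np.ndarray  # (N,) int16, index into the amplicon list

    @property
    def n_reads(self) -> int:
        return self.bases.shape[0]

    @property
    def width(self) -> int:
        return self.bases.shape[1]


def _family_haplotype_parents(
    n_families: int, n_amplicons: int, genome_mix: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_families, n_amplicons, 2) parental origin (0=A, 1=B) per haplotype.

    A haplotype derives from genome B with probability ``genome_mix``.  The
    draw is per family (consistent across the three pools a family enters).
    """
    return (rng.random((n_families, n_amplicons, 2)) < genome_mix).astype(np.int8)


def _mutation_haplotypes(truth: Sequence[MutationRecord], rng: np.random.Generator) -> np.ndarray:
    """Which of the two haplotypes carries each het mutation (hom -> both)."""
    return rng.integers(0, 2, size=len(truth)).astype(np.int8)


def simulate_pool_reads(
    scheme: PoolingScheme,
    amplicons: Sequence[AmpliconModel],
    truth: Sequence[MutationRecord],
    coverage_per_family: float = 11.3,
    read_length: int = 150,
    error_rate: float = 0.002,
    genome_mix: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> dict[str, ReadSet]:
    """Simulate pooled amplicon sequencing reads for every pool.

    Each pool independently samples ``coverage_per_family``-fold coverage
    from every member family and amplicon.  A family contributes its two
    haplotypes at equal rates; each haplotype derives from parental genome A
    or B (``genome_mix``), and het mutations sit on one haplotype, so the
    expected pool variant allele fraction of a het carrier is
    ``1 / (2 * pool_size)``.  Fragments are tiled circularly and wrap-around
    fragments are split into two reads at the amplicon boundary; pieces that
    would fall under 30 bp are re-extended to 30 bp at the boundary (size
    selection without depth loss), which keeps per-position depth uniform at
    ``coverage_per_family * pool_size``.  Substitution errors are i.i.d. at
    ``error_rate`` per base.
    """
    if coverage_per_family <= 0:
        raise ValueError("coverage_per_family must be > 0")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    amp_index = {a.amplicon_id: i for i, a in enumerate(amplicons)}
    hap_parents = _family_haplotype_parents(scheme.n_families, len(amplicons), genome_mix, rng)
    mut_haps = _mutation_haplotypes(truth, rng)
    # mutations indexed by (amplicon_idx, family) for fast lookup
    muts_by_amp_fam: dict[tuple[int, int], list[tuple[int, int, str]]] = {}
    for m, hap in zip(truth, mut_haps):
        ai = amp_index[m.amplicon_id]
        muts_by_amp_fam.setdefault((ai, m.family_id), []).append(
            (m.position, int(hap), m.zygosity)
        )

    alt_code = {"A": sc.A, "T": sc.T}
    truth_alt = {
        (amp_index[m.amplicon_id], m.family_id, m.position): sc.encode(m.alt_base)[0]
        for m in truth
    }

    readsets: dict[str, ReadSet] = {}
    for pool in scheme.pool_labels:
        fams = np.array(scheme.members(pool), dtype=np.int64)
        chunks_b: list[np.ndarray] = []
        chunks_l: list[np.ndarray] = []
        chunks_a: list[np.ndarray] = []
        for ai, amp in enumerate(amplicons):
            L = amp.length
            rl = read_length
            if rl > L:
                warnings.warn(
                    f"read_length {read_length} exceeds {amp.amplicon_id} length {L}; "
                    "reads truncated to the amplicon length"
                )
                rl = L
            # fragments per family: expectation coverage * L / rl
            mean_frags = coverage_per_family * L / rl
            base_n = int(np.floor(mean_frags))
            n_frags = base_n + (rng.random(fams.size) < (mean_frags - base_n))
            total = int(n_frags.sum())
            if total == 0:
                continue
            fam_of = np.repeat(fams, n_frags)
            # evenly spaced circular tiling with a random phase per family
            starts = np.empty(total, dtype=np.int64)
            off = 0
            for nf in n_frags:
                if nf == 0:
                    continue
                phase = rng.random() * L
                starts[off:off + nf] = ((phase + np.arange(nf) * (L / nf)) % L).astype(np.int64)
                off += nf
            hap_of = rng.integers(0, 2, size=total).astype(np.int8)
            parent = hap_parents[fam_of, ai, hap_of]
            idx = (starts[:, None] + np.arange(rl)) % L
            bases = amp.codes[parent[:, None], idx]
            # place spiked mutations on the carrier haplotype
            for f in np.unique(fam_of):
                for pos, hap, zyg in muts_by_amp_fam.get((ai, int(f)), []):
                    rows = (fam_of == f) if zyg == "hom" else ((fam_of == f) & (hap_of == hap))
                    rsel = np.flatnonzero(rows)
                    if rsel.size == 0:
                        continue
                    sub = bases[rsel]
                    sub[idx[rsel] == pos] = truth_alt[(ai, int(f), pos)]
                    bases[rsel] = sub
            # sequencing errors: uniform substitutions
            if error_rate > 0:
                err = rng.random(bases.shape) < error_rate
                n_err = int(err.sum())
                if n_err:
                    bases[err] = (bases[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
            # split wrap-around fragments into two reads
            wraps = starts > L - rl
            keep = ~wraps
            if keep.any():
                chunks_b.append(bases[keep])
                chunks_l.append(np.full(int(keep.sum()), rl, dtype=np.int32))
                chunks_a.append(np.full(int(keep.sum()), ai, dtype=np.int16))
            if wraps.any():
                min_len = min(MIN_READ_LEN, L)

                def _window_reads(rows: np.ndarray, w_start: int, w_len: int) -> np.ndarray:
                    """Fresh reads on a fixed window for re-extended short pieces."""
                    b = amp.codes[parent[rows]][:, w_start:w_start + w_len]
                    for f in np.unique(fam_of[rows]):
                        for pos, hap, zyg in muts_by_amp_fam.get((ai, int(f)), []):
                            if not w_start <= pos < w_start + w_len:
                                continue
                            sel = (fam_of[rows] == f) if zyg == "hom" else (
                                (fam_of[rows] == f) & (hap_of[rows] == hap))
                            b[sel, pos - w_start] = truth_alt[(ai, int(f), pos)]
                    if error_rate > 0:
                        e = rng.random(b.shape) < error_rate
                        ne = int(e.sum())
                        if ne:
                            b = b.copy() if not b.flags.writeable else b
                            b[e] = (b[e] + rng.integers(1, 4, size=ne).astype(np.uint8)) % 4
                    return b

                def _emit(mat: np.ndarray, lens: np.ndarray) -> None:
                    if mat.shape[1] < rl:
                        mat = np.pad(mat, ((0, 0), (0, rl - mat.shape[1])))
                    chunks_b.append(mat)
                    chunks_l.append(lens.astype(np.int32))
                    chunks_a.append(np.full(mat.shape[0], ai, dtype=np.int16))

                wsel = np.flatnonzero(wraps)
                len1 = (L - starts[wsel]).astype(np.int32)
                len2 = (rl - len1).astype(np.int32)
                cols = np.arange(rl)
                # first piece [start, L): prefix of the row, mask by length
                k1 = len1 >= min_len
                if k1.any():
                    b1 = bases[wsel[k1]].copy()
                    b1[cols >= len1[k1, None]] = 0
                    _emit(b1, len1[k1])
                if (~k1).any():
                    # too short: regenerate as a min_len read ending at L
                    rows = wsel[~k1]
                    _emit(_window_reads(rows, L - min_len, min_len),
                          np.full(rows.size, min_len))
                # second piece [0, len2): shift left by len1
                k2 = len2 >= min_len
                if k2.any():
                    src = np.minimum(len1[k2, None] + cols, rl - 1)
                    b2 = np.take_along_axis(bases[wsel[k2]], src, axis=1)
                    b2[cols >= len2[k2, None]] = 0
                    _emit(b2, len2[k2])
                if (~k2).any():
                    # too short: regenerate as a min_len read starting at 0
                    rows = wsel[~k2]
                    _emit(_window_reads(rows, 0, min_len),
                          np.full(rows.size, min_len))
        if chunks_b:
            width = max(c.shape[1] for c in chunks_b)
            mats = [
                np.pad(c, ((0, 0), (0, width - c.shape[1]))) if c.shape[1] < width else c
                for c in chunks_b
            ]
            readsets[pool] = ReadSet(
                bases=np.concatenate(mats),
                lengths=np.concatenate(chunks_l),
                source_amplicon=np.concatenate(chunks_a),
            )
        else:
            readsets[pool] = ReadSet(
                bases=np.zeros((0, read_length), dtype=np.uint8),
                lengths=np.zeros(0, dtype=np.int32),
                source_amplicon=np.zeros(0, dtype=np.int16),
            )
    return readsets


def phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * np.log10(error_rate))))
    return chr(q + 33)


def write_pool_fastq(
    pool_label: str,
    readset: ReadSet,
    amplicons: Sequence[AmpliconModel],
    path,
    error_rate: float = 0.002,
) -> None:
    """Write one pool's reads as FASTQ (gzip if the path ends in .gz).

    Read names encode pool and amplicon but never the family: recovering the
    family is the deconvolution step's job.
    """
    qchar = phred_char(error_rate)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i in range(readset.n_reads):
            n = int(readset.lengths[i])
            seq = sc.decode(readset.bases[i, :n])
            amp = amplicons[readset.source_amplicon[i]].amplicon_id
            fh.write(f"@{pool_label}|{amp}|{i}\n{seq}\n+\n{qchar * n}\n")


def read_pool_fastq(path) -> ReadSet:
    """Load a FASTQ file into a ReadSet (source_amplicon is set to -1)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    seqs: list[np.ndarray] = []
    with opener(path, "rt") as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            seqs.append(sc.encode(seq))
    if not seqs:
        return ReadSet(np.zeros((0, 0), dtype=np.uint8), np.zeros(0, dtype=np.int32),
                       np.zeros(0, dtype=np.int16))
    lengths = np.array([s.size for s in seqs], dtype=np.int32)
    width = int(lengths.max())
    bases = np.zeros((len(seqs), width), dtype=np.uint8)
    for i, s in enumerate(seqs):
        bases[i, : s.size] = s
    return ReadSet(bases, lengths, np.full(len(seqs), -1, dtype=np.int16))
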