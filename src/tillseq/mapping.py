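"""Dual-reference read assignment and per-pool base-count pileups.

Reads are assigned by a seed-anchored Hamming alignment: an exact 21-mer seed
(tried at successive 21-bp offsets along the read, forward then
reverse-complement) places the read on an amplicon, and the full-length
mismatch count against *both* parental sequences decides the genome, with
ties broken toward genome A.  Amplicons are short and the divergence is
substitution-only, so no gapped alignment is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import seqcodes as sc
from .simulate import AmpliconModel, ReadSet

SEED_LEN = 21
_POW4 = 4 ** np.arange(SEED_LEN, dtype=np.int64)


@dataclass
class ReadAssignment:
    """Per-read placement; amplicon == -1 means unassigned."""

    amplicon: np.ndarray  # (N,) int32
    offset: np.ndarray  # (N,) int32, amplicon coordinate of read base 0
    genome: np.ndarray  # (N,) int8: 0 = A, 1 = B, -1 = unassigned
    strand: np.ndarray  # (N,) int8: 0 = forward, 1 = reverse-complemented
    mismatches: np.ndarray  # (N,) int32 (-1 = unassigned)

    @property
    def n_reads(self) -> int:
        return self.amplicon.size

    @property
    def n_assigned(self) -> int:
        return int((self.amplicon >= 0).sum())

    @property
    def n_unassigned(self) -> int:
        return self.n_reads - self.n_assigned

    @property
    def mapping_efficiency(self) -> float:
        """Assigned fraction; NaN (not 0) for an empty read set."""
        if self.n_reads == 0:
            return float("nan")
        return self.n_assigned / self.n_reads


def build_seed_index(amplicons: Sequence[AmpliconModel], seed_len: int = SEED_LEN):
    """Map every packed seed k-mer of both genomes to its (amplicon, offset).

    Returns (sorted_kmers, first_amp, first_off, multi) where ``multi`` holds
    the rare k-mers occurring at more than one (amplicon, offset).
    """
    locs: dict[int, list[tuple[int, int]]] = {}
    pow4 = 4 ** np.arange(seed_len, dtype=np.int64)
    for ai, a in enumerate(amplicons):
        L = a.length
        if L < seed_len:
            continue
        for codes in a.codes:
            c = codes.astype(np.int64)
            win = np.lib.stride_tricks.sliding_window_view(c, seed_len)
            packed = win @ pow4
            for off, km in enumerate(packed):
                lst = locs.setdefault(int(km), [])
                if (ai, off) not in lst:
                    lst.append((ai, off))
    kmers = np.array(sorted(locs), dtype=np.int64)
    first_amp = np.array([locs[int(k)][0][0] for k in kmers], dtype=np.int32)
    first_off = np.array([locs[int(k)][0][1] for k in kmers], dtype=np.int32)
    multi = {int(k): v for k, v in locs.items() if len(v) > 1}
    return kmers, first_amp, first_off, multi


def _pack_seeds(bases: np.ndarray, lengths: np.ndarray, at: int, seed_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed seed k-mer starting at read offset ``at``; valid flag per read."""
    n, width = bases.shape
    valid = lengths >= at + seed_len
    if at + seed_len > width:
        return np.full(n, -1, dtype=np.int64), np.zeros(n, dtype=bool)
    window = bases[:, at:at + seed_len].astype(np.int64)
    packed = window @ _POW4[:seed_len]
    # any ambiguous base (code 4) poisons the seed
    valid &= ~(bases[:, at:at + seed_len] >= 4).any(axis=1)
    return packed, valid


def assign_reads(
    readset: ReadSet,
    amplicons: Sequence[AmpliconModel],
    max_mismatch_frac: float = 0.1,
    seed_len: int = SEED_LEN,
    max_seed_offsets: int = 3,
    index=None,
) -> ReadAssignment:
    """Assign each read to (amplicon, offset, genome) or leave it unassigned.

    Seeds are tried at read offsets 0, 21, 42 ... (``max_seed_offsets`` of
    them), first on the forward read, then on its reverse complement; the
    first seed hit whose full-length Hamming mismatch fraction against the
    better genome is <= ``max_mismatch_frac`` wins.  Ties between genomes go
    to genome A; reverse-complement hits are collapsed to reference-forward
    orientation before pileup.
    """
    if not amplicons:
        raise ValueError("amplicon set must be non-empty")
    if index is None:
        index = build_seed_index(amplicons, seed_len)
    kmers, first_amp, first_off, multi = index

    n = readset.n_reads
    out = ReadAssignment(
        amplicon=np.full(n, -1, dtype=np.int32),
        offset=np.zeros(n, dtype=np.int32),
        genome=np.full(n, -1, dtype=np.int8),
        strand=np.zeros(n, dtype=np.int8),
        mismatches=np.full(n, -1, dtype=np.int32),
    )
    if n == 0 or kmers.size == 0:
        return out

    lengths = readset.lengths.astype(np.int32)
    width = readset.width
    cols = np.arange(width)

    for strand in (0, 1):
        if strand == 0:
            bases = readset.bases
        else:
            if (out.amplicon >= 0).all():
                break
            # reverse-complement each read in place of its own length
            bases = np.zeros_like(readset.bases)
            for l in np.unique(lengths):
                rows = np.flatnonzero(lengths == l)
                seg = readset.bases[rows, :l]
                bases[rows, :l] = sc.complement_codes(seg)[:, ::-1]
        for k in range(max_seed_offsets):
            active = np.flatnonzero(out.amplicon < 0)
            if active.size == 0:
                return out
            packed, valid = _pack_seeds(bases[active], lengths[active], k * seed_len, seed_len)
            if not valid.any():
                continue
            pos = np.searchsorted(kmers, packed)
            pos_c = np.minimum(pos, kmers.size - 1)
            hit = valid & (kmers.size > 0) & (kmers[pos_c] == packed)
            hit_rows = active[hit]
            if hit_rows.size == 0:
                continue
            cand_amp = first_amp[pos_c[hit]].copy()
            cand_off = first_off[pos_c[hit]] - k * seed_len
            # resolve multi-location k-mers by smallest full-length mismatch
            for j, km in enumerate(packed[hit]):
                if int(km) in multi:
                    r = hit_rows[j]
                    best = None
                    for ai2, off2 in multi[int(km)]:
                        o2 = off2 - k * seed_len
                        mm = _pair_mismatches(
                            bases[r:r + 1], lengths[r:r + 1],
                            amplicons[ai2], np.array([o2]), cols
                        )
                        m2 = int(mm.min())
                        if best is None or m2 < best[0]:
                            best = (m2, ai2, o2)
                    cand_amp[j], cand_off[j] = best[1], best[2]
            ok = cand_off >= 0
            hit_rows, cand_amp, cand_off = hit_rows[ok], cand_amp[ok], cand_off[ok]
            # full-length Hamming against both genomes, grouped by amplicon
            for ai in np.unique(cand_amp):
                grp = cand_amp == ai
                rows = hit_rows[grp]
                offs = cand_off[grp]
                amp = amplicons[ai]
                mm = _pair_mismatches(bases[rows], lengths[rows], amp, offs, cols)
                genome = (mm[:, 1] < mm[:, 0]).astype(np.int8)  # tie -> A
                best_mm = np.where(genome == 1, mm[:, 1], mm[:, 0])
                passing = best_mm <= max_mismatch_frac * lengths[rows]
                sel = rows[passing]
                out.amplicon[sel] = ai
                out.offset[sel] = offs[passing]
                out.genome[sel] = genome[passing]
                out.strand[sel] = strand
                out.mismatches[sel] = best_mm[passing]
    return out


def _pair_mismatches(bases, lengths, amp: AmpliconModel, offs, cols) -> np.ndarray:
    """(n, 2) mismatch counts vs genome A and B at the given offsets."""
    L = amp.length
    idx = offs[:, None] + cols
    inside = (idx >= 0) & (idx < L)
    idx_c = np.where(inside, idx, 0)
    within = cols < lengths[:, None]
    refa = amp.codes[0][idx_c]
    refb = amp.codes[1][idx_c]
    mm_out = within & ~inside  # read runs off the amplicon end: mismatch
    mma = (((bases != refa) | (bases >= 4)) & within & inside).sum(axis=1) + mm_out.sum(axis=1)
    mmb = (((bases != refb) | (bases >= 4)) & within & inside).sum(axis=1) + mm_out.sum(axis=1)
    return np.stack([mma, mmb], axis=1)


@dataclass
class AlleleCountMatrix:
    """Per-position base counts of one (pool, amplicon) after assignment."""

    pool_id: str
    amplicon_id: str
    counts: np.ndarray  # (L, 4) int64, columns A C G T
    depth: np.ndarray  # (L,) int64, includes reads with ambiguous base at the position
    n_assigned_reads: int
    n_unassigned_reads: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(sc.BASES))
        df.insert(0, "pos", np.arange(self.counts.shape[0]))
        df.insert(0, "amplicon", self.amplicon_id)
        df.insert(0, "pool", self.pool_id)
        df["depth"] = self.depth
        return df


def pileup(
    readset: ReadSet,
    assignment: ReadAssignment,
    amplicons: Sequence[AmpliconModel],
    pool_id: str,
) -> dict[str, AlleleCountMatrix]:
    """Accumulate base counts per amplicon position (genome-A coordinates).

    Both genomes share coordinates (substitution-only divergence), so
    genome-B private alleles land at homologous positions.  Reads assigned on
    the reverse strand are complemented back to reference-forward before
    counting.
    """
    out: dict[str, AlleleCountMatrix] = {}
    n_un = assignment.n_unassigned
    cols = np.arange(readset.width) if readset.n_reads else np.arange(0)
    for ai, amp in enumerate(amplicons):
        L = amp.length
        rows = np.flatnonzero(assignment.amplicon == ai)
        counts = np.zeros((L, 4), dtype=np.int64)
        depth = np.zeros(L, dtype=np.int64)
        if rows.size:
            bases = readset.bases[rows]
            rc = np.flatnonzero(assignment.strand[rows] == 1)
            if rc.size:
                bases = bases.copy()
                for r in rc:
                    l = int(readset.lengths[rows[r]])
                    bases[r, :l] = sc.complement_codes(bases[r, :l])[::-1]
            idx = assignment.offset[rows][:, None] + cols
            within = (cols < readset.lengths[rows][:, None]) & (idx < L)
            flat_pos = idx[within]
            flat_base = bases[within]
            depth += np.bincount(flat_pos, minlength=L)
            unamb = flat_base < 4
            counts = np.bincount(
                flat_pos[unamb] * 4 + flat_base[unamb], minlength=4 * L
            ).reshape(L, 4)
        out[amp.amplicon_id] = AlleleCountMatrix(
            pool_id=pool_id,
            amplicon_id=amp.amplicon_id,
            counts=counts,
            depth=depth,
            n_assigned_reads=int(rows.size),
            n_unassigned_reads=n_un,
        )
    return out


def counts_to_tsv(matrices: Sequence[AlleleCountMatrix], path) -> None:
    pd.concat([m.to_frame() for m in matrices], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def write_sam(
    readset: ReadSet,
    assignment: ReadAssignment,
    amplicons: Sequence[AmpliconModel],
    path,
    read_group: str = "pool",
) -> None:
    """Minimal unsorted SAM export of the assignments (via pysam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": a.amplicon_id, "LN": a.length} for a in amplicons],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i in range(readset.n_reads):
            seg = pysam.AlignedSegment(fh.header)
            l = int(readset.lengths[i])
            seg.query_name = f"{read_group}|{i}"
            seg.query_sequence = sc.decode(readset.bases[i, :l])
            seg.query_qualities = pysam.qualitystring_to_array("I" * l)
            ai = int(assignment.amplicon[i])
            if ai < 0:
                seg.is_unmapped = True
            else:
                seg.reference_id = ai
                seg.reference_start = int(assignment.offset[i])
                seg.cigarstring = f"{l}M"
                seg.mapping_quality = 60
                seg.is_reverse = bool(assignment.strand[i])
                if seg.is_reverse:
                    seq = sc.decode(
                        sc.revcomp_codes(readset.bases[i, :l])
                    )
                    seg.query_sequence = seq
                    seg.query_qualities = pysam.qualitystring_to_array("I" * l)
            fh.write(seg)
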