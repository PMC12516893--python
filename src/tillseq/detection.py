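"""Low-allele-fraction EMS mutation calling from pooled base counts.

A heterozygous EMS mutation in one of the 64 families of a pool is expected
at a variant allele fraction of 1/128 (~0.8%), against a sequencing-error
background.  The caller works site by site over the EMS-consistent tests
(G->A at G reference sites, C->T at C sites; inter-genome divergent sites are
masked as genotype, not mutation):

1. per pool, the alternate-allele count is compared with an error-only
   binomial null (``test_position``, exact upper tail at per-alternate-base
   error rate e/3);
2. a site becomes a candidate when every axis (R, C, D) has a pool with at
   least ``min_alt`` alternate reads AND the sum of the three per-axis
   maximum counts reaches a threshold t* calibrated exactly under the
   error-only null so that the expected number of false candidates per run
   is at most ``alpha`` (family-wise control over all EMS-consistent tests);
3. the per-axis maximal pools are intersected (deconvolved) to the candidate
   family; ties produce an ambiguous call, reported rather than dropped.

The error rate of the null is estimated per amplicon as the median
non-reference allele fraction at unmasked sites, floored at 1e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import seqcodes as sc
from .mapping import AlleleCountMatrix
from .pooling import AXES, DeconvolutionResult, PoolingScheme, deconvolve
from .simulate import AmpliconModel

EMS_PAIRS = {("G", "A"), ("C", "T")}
ERROR_RATE_FLOOR = 1e-4


def ems_canonical(ref_base: str, alt_base: str) -> bool:
    """True iff (ref, alt) is an EMS transition in reference-forward
    orientation: G->A, or its opposite-strand presentation C->T."""
    for b in (ref_base, alt_base):
        if b not in "ACGT":
            raise ValueError(f"base must be one of A,C,G,T, got {b!r}")
    return (ref_base, alt_base) in EMS_PAIRS


def test_position(
    alt_count: int,
    depth: int,
    error_rate: float,
    alpha: float = 0.05,
    min_alt: int = 2,
    n_tests: int = 1,
) -> tuple[float, bool]:
    """Exact binomial upper-tail test of one pool position.

    p = P(X >= alt_count | n = depth, p = error_rate/3), the per-alternate-
    base error null.  The pass flag applies a Bonferroni correction over
    ``n_tests`` and the ``min_alt`` read floor.  Depth 0 is untestable:
    (nan, False).
    """
    if not 0 < error_rate < 1:
        raise ValueError(f"error_rate must be in (0,1), got {error_rate}")
    if depth < 1:
        return (float("nan"), False)
    if alt_count <= 0:
        return (1.0, False)
    p = float(stats.binom.sf(alt_count - 1, depth, error_rate / 3.0))
    return (p, p < alpha / n_tests and alt_count >= min_alt)


def mask_divergent_sites(amplicons: Sequence[AmpliconModel]) -> dict[str, np.ndarray]:
    """Positions excluded from calling: anywhere the parental genomes differ.

    A fixed inter-genome difference segregates through every family and shows
    up at VAF ~0.25-0.5 in every pool — genotype, not induced mutation.
    """
    return {a.amplicon_id: a.divergent_sites.copy() for a in amplicons}


def estimate_error_rate(
    counts_by_pool: Mapping[str, AlleleCountMatrix],
    amplicon: AmpliconModel,
    floor: float = ERROR_RATE_FLOOR,
) -> float:
    """Median per-position non-reference allele fraction at unmasked sites,
    pooled over all pools, floored at ``floor``."""
    ref = sc.encode(amplicon.seq_a)
    total = np.zeros((amplicon.length, 4), dtype=np.int64)
    for acm in counts_by_pool.values():
        total += acm.counts
    depth = total.sum(axis=1)
    nonref = depth - total[np.arange(amplicon.length), ref]
    keep = np.ones(amplicon.length, dtype=bool)
    keep[amplicon.divergent_sites] = False
    keep &= depth > 0
    if not keep.any():
        return floor
    return max(float(np.median(nonref[keep] / depth[keep])), floor)


def calibrate_threshold(
    mean_depth: float,
    error_rate: float,
    cube_dim: int,
    n_tests: int,
    min_alt: int = 2,
    alpha: float = 0.05,
    max_count: int = 200,
) -> int:
    """Smallest t such that the expected number of error-only sites with all
    three axis maxima >= min_alt and axis-max sum >= t is <= alpha.

    The null per-pool alternate count is Binomial(mean_depth, error_rate/3);
    the per-axis maximum over ``cube_dim`` pools and the three-axis sum are
    computed by exact convolution.
    """
    d = max(int(round(mean_depth)), 1)
    p0 = error_rate / 3.0
    x = np.arange(max_count + 1)
    cdf = stats.binom.cdf(x, d, p0)
    cdf[-1] = 1.0  # lump the far tail
    cdf_prev = np.concatenate([[0.0], cdf[:-1]])
    max_pmf = cdf**cube_dim - cdf_prev**cube_dim  # pmf of max over one axis
    axis = max_pmf.copy()
    axis[:min_alt] = 0.0  # axis must reach min_alt
    s = np.convolve(np.convolve(axis, axis), axis)
    tail = np.cumsum(s[::-1])[::-1]
    ok = np.flatnonzero(n_tests * tail <= alpha)
    if ok.size == 0:
        return int(3 * max_count + 1)
    return max(int(ok[0]), 3 * min_alt)


@dataclass(frozen=True)
class PoolVariantCall:
    pool_id: str
    amplicon_id: str
    position: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    p_value: float
    passed: bool
    ems_flag: bool = True

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else float("nan")


@dataclass
class CandidateMutation:
    amplicon_id: str
    position: int
    ref_base: str
    alt_base: str
    supporting_pools: dict  # axis -> list of pool labels with alt >= min_alt
    axis_max_pools: dict  # axis -> list of maximal pool labels (ties kept)
    pool_calls: list  # PoolVariantCall for each supporting pool
    deconvolution: DeconvolutionResult | None
    families: tuple  # assigned family ids (singleton when unique)
    score: int  # sum of per-axis maximum alt counts
    joint_p: float
    low_confidence: bool = False
    effect: object = None  # filled by the annotation module

    @property
    def status(self) -> str:
        return self.deconvolution.status if self.deconvolution else "incomplete"


@dataclass
class CallParams:
    alpha: float = 0.05
    min_alt: int = 2
    error_rate: float | None = None  # None: estimate per amplicon
    strict_axes: bool = True  # require all 3 axes (else >= 2, low-confidence)


def _axis_of_pool(label: str) -> str:
    return label[0]


def call_mutations(
    counts: Mapping[str, Mapping[str, AlleleCountMatrix]],
    scheme: PoolingScheme,
    amplicons: Sequence[AmpliconModel],
    params: CallParams | None = None,
) -> list[CandidateMutation]:
    """Call candidate EMS mutations from {pool -> {amplicon -> counts}}.

    Requires counts for every pool of the scheme (all three axes).
    """
    params = params or CallParams()
    pool_order = scheme.pool_labels
    missing = [p for p in pool_order if p not in counts]
    if missing:
        raise ValueError(f"counts missing for pools {missing}: all three axes required")

    masks = mask_divergent_sites(amplicons)

    # number of EMS-consistent tests across the run (Bonferroni universe)
    per_amp_sites: dict[str, np.ndarray] = {}
    n_tests = 0
    for a in amplicons:
        ref = a.codes[0]
        ems = (ref == sc.G) | (ref == sc.C)
        ems[masks[a.amplicon_id]] = False
        per_amp_sites[a.amplicon_id] = ems
        n_tests += int(ems.sum())
    if n_tests == 0:
        return []

    axis_pools = {ax: [p for p in pool_order if p.startswith(ax)] for ax in AXES}

    candidates: list[CandidateMutation] = []
    for a in amplicons:
        aid = a.amplicon_id
        L = a.length
        ref = a.codes[0]
        alt = np.where(ref == sc.G, sc.A, sc.T)  # EMS alternate per site
        err = params.error_rate or estimate_error_rate(
            {p: counts[p][aid] for p in pool_order}, a
        )
        alt_mat = np.zeros((len(pool_order), L), dtype=np.int64)
        dep_mat = np.zeros((len(pool_order), L), dtype=np.int64)
        pos_idx = np.arange(L)
        for pi, p in enumerate(pool_order):
            acm = counts[p][aid]
            alt_mat[pi] = acm.counts[pos_idx, alt]
            dep_mat[pi] = acm.depth
        axis_rows = {ax: [pool_order.index(p) for p in axis_pools[ax]] for ax in AXES}
        axis_max = np.stack([alt_mat[axis_rows[ax]].max(axis=0) for ax in AXES])
        n_axes_ok = (axis_max >= params.min_alt).sum(axis=0)
        score = axis_max.sum(axis=0)

        mean_depth = float(dep_mat.mean()) if dep_mat.size else 0.0
        t_star = calibrate_threshold(
            mean_depth, err, scheme.cube_dim, n_tests,
            min_alt=params.min_alt, alpha=params.alpha,
        )

        need_axes = 3 if params.strict_axes else 2
        sites = np.flatnonzero(
            per_amp_sites[aid] & (n_axes_ok >= need_axes) & (score >= t_star)
        )
        for pos in sites:
            pos = int(pos)
            supporting: dict[str, list[str]] = {}
            max_pools: dict[str, list[str]] = {}
            calls: list[PoolVariantCall] = []
            for ax in AXES:
                rows = axis_rows[ax]
                vals = alt_mat[rows, pos]
                sup = [axis_pools[ax][j] for j in range(len(rows)) if vals[j] >= params.min_alt]
                supporting[ax] = sup
                mx = int(vals.max())
                max_pools[ax] = (
                    [axis_pools[ax][j] for j in range(len(rows)) if vals[j] == mx]
                    if mx >= params.min_alt else []
                )
                for lab in sup:
                    pi = pool_order.index(lab)
                    pv, passed = test_position(
                        int(alt_mat[pi, pos]), int(dep_mat[pi, pos]), err,
                        alpha=params.alpha, min_alt=params.min_alt, n_tests=n_tests,
                    )
                    calls.append(PoolVariantCall(
                        pool_id=lab, amplicon_id=aid, position=pos,
                        ref_base=sc.BASES[ref[pos]], alt_base=sc.BASES[alt[pos]],
                        alt_count=int(alt_mat[pi, pos]), depth=int(dep_mat[pi, pos]),
                        p_value=pv, passed=passed,
                    ))
            flat_max = [lab for ax in AXES for lab in max_pools[ax]]
            deconv = deconvolve(scheme, flat_max)
            s = int(score[pos])
            # joint binomial tail over the maximal pools (diagnostic p-value)
            jdepth = sum(
                int(dep_mat[pool_order.index(lab), pos]) for lab in flat_max
            )
            jalt = sum(
                int(alt_mat[pool_order.index(lab), pos]) for lab in flat_max
            )
            joint_p = float(stats.binom.sf(jalt - 1, jdepth, err / 3.0)) if jdepth else float("nan")
            candidates.append(CandidateMutation(
                amplicon_id=aid, position=pos,
                ref_base=sc.BASES[ref[pos]], alt_base=sc.BASES[alt[pos]],
                supporting_pools=supporting, axis_max_pools=max_pools,
                pool_calls=calls, deconvolution=deconv,
                families=deconv.candidate_family_ids, score=s, joint_p=joint_p,
                low_confidence=bool(n_axes_ok[pos] < 3),
            ))
    candidates.sort(key=lambda c: (c.amplicon_id, c.position))
    return candidates


def export_vaf_matrix(
    counts: Mapping[str, Mapping[str, AlleleCountMatrix]],
    scheme: PoolingScheme,
    amplicons: Sequence[AmpliconModel],
) -> pd.DataFrame:
    """Per-position VAF of the top non-reference base in every pool.

    The table that replaces eyeballing raw pileups: one row per (amplicon,
    position), one column per pool, plus a ``masked`` flag for inter-genome
    divergent sites.
    """
    masks = mask_divergent_sites(amplicons)
    frames = []
    for a in amplicons:
        ref = a.codes[0]
        L = a.length
        block = {"amplicon": np.repeat(a.amplicon_id, L), "pos": np.arange(L)}
        for p in scheme.pool_labels:
            acm = counts[p][a.amplicon_id]
            nonref = acm.counts.copy()
            nonref[np.arange(L), ref] = 0
            top = nonref.max(axis=1)
            depth = acm.depth
            with np.errstate(invalid="ignore", divide="ignore"):
                vaf = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
            block[p] = vaf
        masked = np.zeros(L, dtype=bool)
        masked[masks[a.amplicon_id]] = True
        block["masked"] = masked
        frames.append(pd.DataFrame(block))
    return pd.concat(frames, ignore_index=True)


def write_vcf(
    candidates: Sequence[CandidateMutation],
    amplicons: Sequence[AmpliconModel],
    path,
    sample_note: str = "tillseq pooled caller",
) -> None:
    """One VCF record per candidate (contig = amplicon, 1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={sample_note}\n")
        for a in amplicons:
            fh.write(f"##contig=<ID={a.amplicon_id},length={a.length}>\n")
        fh.write('##INFO=<ID=POOLS,Number=.,Type=String,Description="Supporting pools">\n')
        fh.write('##INFO=<ID=FAM,Number=.,Type=Integer,Description="Assigned family ids">\n')
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,Description="Deconvolution status">\n')
        fh.write('##INFO=<ID=S,Number=1,Type=Integer,Description="Axis-max alt count sum">\n')
        fh.write('##INFO=<ID=JP,Number=1,Type=Float,Description="Joint binomial p-value">\n')
        fh.write('##INFO=<ID=LOWCONF,Number=0,Type=Flag,Description="Only two axes supported">\n')
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Predicted protein effect">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in candidates:
            pools = ",".join(lab for ax in AXES for lab in c.supporting_pools.get(ax, []))
            info = [
                f"POOLS={pools or '.'}",
                f"FAM={','.join(map(str, c.families)) or '.'}",
                f"STATUS={c.status}",
                f"S={c.score}",
                f"JP={c.joint_p:.3g}",
            ]
            if c.low_confidence:
                info.append("LOWCONF")
            if c.effect is not None:
                info.append(f"EFF={c.effect.effect_class}")
            qual = min(999.0, -10 * math.log10(max(c.joint_p, 1e-300)))
            fh.write(
                f"{c.amplicon_id}\t{c.position + 1}\t.\t{c.ref_base}\t{c.alt_base}\t"
                f"{qual:.1f}\tPASS\t{';'.join(info)}\n"
            )


def candidates_to_frame(candidates: Sequence[CandidateMutation]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "amplicon_id": c.amplicon_id,
            "position": c.position,
            "ref_base": c.ref_base,
            "alt_base": c.alt_base,
            "status": c.status,
            "families": ";".join(map(str, c.families)),
            "score": c.score,
            "joint_p": c.joint_p,
            "low_confidence": c.low_confidence,
            "pools": ";".join(lab for ax in AXES for lab in c.supporting_pools.get(ax, [])),
            "effect": c.effect.effect_class if c.effect is not None else "",
        })
    cols = ["amplicon_id", "position", "ref_base", "alt_base", "status", "families",
            "score", "joint_p", "low_confidence", "pools", "effect"]
    return pd.DataFrame(rows, columns=cols)
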