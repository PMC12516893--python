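"""Allele-specific PCR (PACE/KASP-style) marker design and segregation tests.

A confirmed SNP is converted to two tailed allele-specific primers (each
ending on one allele at its 3' terminus, prefixed with the standard FAM or
HEX universal tail) plus one common reverse primer.  Melting temperatures
come from nearest-neighbor thermodynamics with the unified parameter set
(Allawi & SantaLucia 1997) at 50 mM monovalent salt and 200 nM primer.

Genotype segregation in backcross progeny is tested with a Pearson
chi-square against the expected ratio (1:1 heterozygous : homozygous WT for
BC1 progeny of a heterozygous mutant), no continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from . import seqcodes as sc
from .simulate import AmpliconModel

# Standard KASP/PACE universal tails (FAM- and HEX-associated).
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

# Unified nearest-neighbor parameters: dH (kcal/mol), dS (cal/mol/K)
NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# terminal initiation corrections
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)

R_GAS = 1.987  # cal/(mol K)


def melting_temperature(seq: str, na_mM: float = 50.0, primer_nM: float = 200.0) -> float:
    """Nearest-neighbor Tm (degrees C) of a primer against its perfect
    complement, with the SantaLucia 1998 entropy salt correction."""
    seq = seq.upper()
    if len(seq) < 2 or any(b not in "ACGT" for b in seq):
        raise ValueError(f"primer must be >= 2 ACGT bases, got {seq!r}")
    dh = ds = 0.0
    for a, b in ((seq[0], None), (seq[-1], None)):
        h, s = INIT_AT if a in "AT" else INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i:i + 2]]
        dh += h
        ds += s
    # entropy salt correction: +0.368 * (N-1) * ln[Na+]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    # non-self-complementary duplex at primer excess: CT/4
    ct = primer_nM * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(ct / 4.0)) - 273.15


@dataclass(frozen=True)
class MarkerDesign:
    amplicon_id: str
    position: int
    ref_base: str
    alt_base: str
    allele_primer_ref: str  # FAM tail + genomic sequence ending on ref allele
    allele_primer_alt: str  # HEX tail + genomic sequence ending on alt allele
    common_primer: str  # reverse-orientation, downstream of the SNP
    tm_ref: float
    tm_alt: float
    tm_common: float
    product_size: int


class DesignError(ValueError):
    """No primer satisfying the constraints exists."""


@dataclass(frozen=True)
class DesignParams:
    tm_window: tuple[float, float] = (57.0, 63.0)
    len_range: tuple[int, int] = (18, 30)
    product_range: tuple[int, int] = (60, 120)


def _grow_allele_primers(seq: str, pos: int, ref: str, alt: str, params: DesignParams):
    """Shortest primer ending at the SNP whose ref and alt variants are both
    inside the Tm window."""
    lo, hi = params.tm_window
    for length in range(params.len_range[0], params.len_range[1] + 1):
        start = pos - length + 1
        if start < 0:
            break
        core = seq[start:pos]
        p_ref, p_alt = core + ref, core + alt
        t_ref, t_alt = melting_temperature(p_ref), melting_temperature(p_alt)
        if lo <= t_ref <= hi and lo <= t_alt <= hi:
            return p_ref, p_alt, t_ref, t_alt
    raise DesignError(
        f"no allele primer in len {params.len_range} reaches Tm window {params.tm_window} "
        f"at position {pos}"
    )


def design_pace(
    amplicon: AmpliconModel,
    snp: tuple[int, str, str],
    params: DesignParams | None = None,
) -> MarkerDesign:
    """Design a PACE/KASP marker for one SNP (position, ref, alt) on the
    genome-A amplicon sequence.

    The two allele primers are identical except for the fluorophore tail and
    the 3'-terminal base; the common primer sits on the opposite strand
    downstream so the product size falls inside ``product_range``.
    """
    params = params or DesignParams()
    pos, ref, alt = snp
    seq = amplicon.seq_a
    if seq[pos] != ref:
        raise ValueError(f"amplicon base at {pos} is {seq[pos]}, not {ref}")
    if pos < params.len_range[1]:
        raise DesignError(
            f"insufficient 5' flank: SNP at {pos} but allele primers may need "
            f"{params.len_range[1]} bases"
        )
    if amplicon.length - 1 - pos < params.product_range[0] - params.len_range[1]:
        raise DesignError("insufficient 3' flank for the common primer")

    p_ref, p_alt, t_ref, t_alt = _grow_allele_primers(seq, pos, ref, alt, params)
    allele_start = pos - len(p_ref) + 1

    lo, hi = params.tm_window
    best = None
    # common primer: 5' end at template position q_end (product boundary),
    # covering [q_end - len + 1, q_end] on the template, reverse complemented
    for q_end in range(pos + 1 + params.len_range[0], amplicon.length):
        product = q_end - allele_start + 1
        if product < params.product_range[0]:
            continue
        if product > params.product_range[1]:
            break
        for length in range(params.len_range[0], params.len_range[1] + 1):
            q_start = q_end - length + 1
            if q_start <= pos:  # must not overlap the SNP
                break
            primer = sc.revcomp(seq[q_start:q_end + 1])
            tm = melting_temperature(primer)
            if lo <= tm <= hi:
                best = (primer, tm, product)
                break
        if best:
            break
    if best is None:
        raise DesignError(
            f"no common primer satisfies Tm window {params.tm_window} with product "
            f"size in {params.product_range}"
        )
    common, t_common, product = best
    return MarkerDesign(
        amplicon_id=amplicon.amplicon_id,
        position=pos,
        ref_base=ref,
        alt_base=alt,
        allele_primer_ref=FAM_TAIL + p_ref,
        allele_primer_alt=HEX_TAIL + p_alt,
        common_primer=common,
        tm_ref=t_ref,
        tm_alt=t_alt,
        tm_common=t_common,
        product_size=product,
    )


def anneal_sites(primer_core: str, amplicon: AmpliconModel) -> list[tuple[int, str]]:
    """Exact-match binding sites of a primer (tail removed) on either strand
    of the genome-A amplicon; used to check design uniqueness."""
    seq = amplicon.seq_a
    rc = sc.revcomp(seq)
    hits = []
    start = seq.find(primer_core)
    while start != -1:
        hits.append((start, "+"))
        start = seq.find(primer_core, start + 1)
    start = rc.find(primer_core)
    while start != -1:
        hits.append((len(seq) - start - len(primer_core), "-"))
        start = rc.find(primer_core, start + 1)
    return hits


def designs_to_tsv(designs, path) -> None:
    """Primer table: one row per primer (name, sequence, Tm, product size)."""
    import pandas as pd

    rows = []
    for d in designs:
        stem = f"{d.amplicon_id}_{d.position + 1}{d.ref_base}>{d.alt_base}"
        rows.append((f"{stem}_allele_{d.ref_base}", d.allele_primer_ref, d.tm_ref, d.product_size))
        rows.append((f"{stem}_allele_{d.alt_base}", d.allele_primer_alt, d.tm_alt, d.product_size))
        rows.append((f"{stem}_common", d.common_primer, d.tm_common, d.product_size))
    pd.DataFrame(rows, columns=["primer", "sequence", "tm_c", "product_bp"]).to_csv(
        path, sep="\t", index=False, float_format="%.2f"
    )


def designs_to_fasta(designs, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = []
    for d in designs:
        stem = f"{d.amplicon_id}_{d.position + 1}{d.ref_base}>{d.alt_base}"
        for suffix, seq in ((f"allele_{d.ref_base}", d.allele_primer_ref),
                            (f"allele_{d.alt_base}", d.allele_primer_alt),
                            ("common", d.common_primer)):
            recs.append(SeqRecord(Seq(seq), id=f"{stem}_{suffix}", description=""))
    seqio_write(recs, str(path), "fasta")


def segregation_to_tsv(results, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(r.n_het, r.n_hom_wt, f"{r.expected_ratio[0]}:{r.expected_ratio[1]}",
          r.chi2, r.p_value, r.fits) for r in results],
        columns=["n_het", "n_hom_wt", "expected_ratio", "chi2", "p_value", "fits"],
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Segregation testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegregationResult:
    n_het: int
    n_hom_wt: int
    expected_ratio: tuple[int, int]
    chi2: float
    p_value: float
    fits: bool  # p >= alpha: observed counts consistent with the ratio


def segregation_test(
    n_het: int,
    n_hom_wt: int,
    ratio: tuple[int, int] = (1, 1),
    alpha: float = 0.05,
) -> SegregationResult:
    """Pearson chi-square (df=1, no continuity correction) of an observed
    het : hom-WT split against an expected ratio.

    >>> r = segregation_test(13, 12)
    >>> round(r.chi2, 2), r.fits
    (0.04, True)
    """
    if n_het < 0 or n_hom_wt < 0:
        raise ValueError("counts must be non-negative")
    n = n_het + n_hom_wt
    if n < 1:
        raise ValueError("at least one genotyped plant required")
    w = ratio[0] + ratio[1]
    expected = [n * ratio[0] / w, n * ratio[1] / w]
    chi2, p = stats.chisquare([n_het, n_hom_wt], f_exp=expected)
    return SegregationResult(
        n_het=n_het, n_hom_wt=n_hom_wt, expected_ratio=tuple(ratio),
        chi2=float(chi2), p_value=float(p), fits=bool(p >= alpha),
    )
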