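"""Protein-effect classification and platform-level statistics.

Effects are predicted from the amplicon-local exon/CDS model with the
standard nuclear genetic code.  Intronic bases within 2 bp of an exon
boundary (the essential GT donor / AG acceptor dinucleotides) are splice
sites; exonic classification wins when a base is both exonic and near a
boundary.  Positions in primer regions or outside the gene model are
noncoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import seqcodes as sc
from .simulate import AmpliconModel, MutationRecord

# Standard nuclear genetic code (stop = '*').
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SPLICE_WINDOW = 2


@dataclass(frozen=True)
class EffectAnnotation:
    effect_class: str  # synonymous|missense|stop_gained|stop_lost|splice_site|intronic|noncoding
    codon_ref: str = ""
    codon_alt: str = ""
    aa_ref: str = ""
    aa_alt: str = ""
    aa_position: int = 0  # 1-based within the amplicon-local CDS

PROTEIN_AFFECTING = {"missense", "stop_gained", "stop_lost", "splice_site"}


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon.upper()]


def _minus_to_plus(amplicon: AmpliconModel) -> AmpliconModel:
    """Mirror a minus-strand amplicon into transcript orientation."""
    L = amplicon.length
    return AmpliconModel(
        amplicon_id=amplicon.amplicon_id,
        gene_id=amplicon.gene_id,
        seq_a=sc.revcomp(amplicon.seq_a),
        seq_b=sc.revcomp(amplicon.seq_b),
        exons=tuple(sorted((L - e, L - s) for s, e in amplicon.exons)),
        cds_offset=amplicon.cds_offset,
        strand="+",
        primer_len=amplicon.primer_len,
    )


def classify_effect(
    mutation: MutationRecord | tuple,
    amplicon: AmpliconModel,
    splice_window: int = SPLICE_WINDOW,
) -> EffectAnnotation:
    """Classify the predicted protein effect of one substitution.

    ``mutation`` may be a MutationRecord or a (position, ref, alt) tuple in
    amplicon coordinates (reference-forward bases).
    """
    if isinstance(mutation, MutationRecord):
        pos, ref, alt = mutation.position, mutation.ref_base, mutation.alt_base
    else:
        pos, ref, alt = mutation
    L = amplicon.length
    if not 0 <= pos < L:
        raise ValueError(f"position {pos} outside amplicon {amplicon.amplicon_id}")
    if amplicon.seq_a[pos] != ref:
        raise ValueError(
            f"{amplicon.amplicon_id}:{pos} reference is {amplicon.seq_a[pos]}, not {ref}"
        )

    if amplicon.strand == "-":
        flipped = _minus_to_plus(amplicon)
        comp = str.maketrans("ACGT", "TGCA")
        return classify_effect(
            (L - 1 - pos, ref.translate(comp), alt.translate(comp)),
            flipped, splice_window,
        )

    # primer regions carry no annotation (conserved, non-modelled sequence)
    if pos < amplicon.primer_len or pos >= L - amplicon.primer_len:
        return EffectAnnotation("noncoding")

    exons = amplicon.exons
    in_exon = None
    for s, e in exons:
        if s <= pos < e:
            in_exon = (s, e)
            break

    if in_exon is None:
        # intronic only between the first exon start and the last exon end
        if not exons or pos < exons[0][0] or pos >= exons[-1][1]:
            return EffectAnnotation("noncoding")
        for s, e in exons:
            # within `splice_window` intronic bases of a boundary
            if e <= pos < e + splice_window or s - splice_window <= pos < s:
                return EffectAnnotation("splice_site")
        return EffectAnnotation("intronic")

    # exonic: map to the amplicon-local CDS
    cds_pos = sum(min(e, pos) - s for s, e in exons if s < pos) + amplicon.cds_offset
    # cds_offset = frame of the first exonic base: shift so codons start at 0
    codon_idx, in_codon = divmod(cds_pos, 3)
    codon_start_cds = cds_pos - in_codon
    cds = "".join(amplicon.seq_a[s:e] for s, e in exons)
    cds_local = codon_start_cds - amplicon.cds_offset
    if cds_local < 0 or cds_local + 3 > len(cds):
        # partial codon at the amplicon edge: effect not determinable
        return EffectAnnotation("noncoding")
    codon_ref = cds[cds_local:cds_local + 3]
    codon_alt = codon_ref[:in_codon] + alt + codon_ref[in_codon + 1:]
    aa_ref = translate_codon(codon_ref)
    aa_alt = translate_codon(codon_alt)
    if aa_ref == aa_alt:
        cls = "synonymous"
    elif aa_alt == "*":
        cls = "stop_gained"
    elif aa_ref == "*":
        cls = "stop_lost"
    else:
        cls = "missense"
    return EffectAnnotation(cls, codon_ref, codon_alt, aa_ref, aa_alt, codon_idx + 1)


def annotate_candidates(candidates, amplicons: Sequence[AmpliconModel],
                        splice_window: int = SPLICE_WINDOW):
    """Fill the ``effect`` slot of each candidate in place; returns the list."""
    by_id = {a.amplicon_id: a for a in amplicons}
    for c in candidates:
        c.effect = classify_effect(
            (c.position, c.ref_base, c.alt_base), by_id[c.amplicon_id], splice_window
        )
    return candidates


# ---------------------------------------------------------------------------
# Platform statistics
# ---------------------------------------------------------------------------

def affecting_fraction(n_affecting: int, n_total: int) -> float:
    """Percentage of mutations predicted to affect protein function,
    to one decimal (e.g. 134 of 3935 -> 3.4)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_affecting > n_total:
        raise ValueError("n_affecting cannot exceed n_total")
    return round(100.0 * n_affecting / n_total, 1)


def mutation_frequency(n_confirmed: int, total_screened_kb: float) -> tuple[float, str]:
    """Screened kb per confirmed mutation: raw value and a '1/X kb' report
    string rounded to the nearest 10 kb (14, 4474 -> 319.6, '1/320 kb')."""
    if total_screened_kb <= 0:
        raise ValueError("total_screened_kb must be > 0")
    if n_confirmed == 0:
        return (float("nan"), "none detected")
    raw = total_screened_kb / n_confirmed
    return (raw, f"1/{int(round(raw / 10.0) * 10)} kb")


def detection_accuracy(n_confirmed: int, n_clean_traces: int) -> int:
    """Confirmed fraction among clean validation traces, as a whole
    percentage (14 of 17 -> 82)."""
    if n_clean_traces < 1:
        raise ValueError("n_clean_traces must be >= 1")
    if n_confirmed > n_clean_traces:
        raise ValueError("n_confirmed cannot exceed n_clean_traces")
    return int(round(100.0 * n_confirmed / n_clean_traces))


def total_screened_kb(amplicons: Sequence[AmpliconModel], n_families: int) -> float:
    return sum(a.length for a in amplicons) * n_families / 1000.0


@dataclass(frozen=True)
class TruthScore:
    n_truth: int
    n_candidates: int
    true_positive: int  # correct site+alt and unique correct family
    partial: int  # correct site+alt, wrong or non-unique family
    false_positive: int  # site+alt absent from the truth set

    @property
    def sensitivity(self) -> float:
        return self.true_positive / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (
            self.true_positive / self.n_candidates if self.n_candidates else float("nan")
        )

    @property
    def family_accuracy(self) -> float:
        sited = self.true_positive + self.partial
        return self.true_positive / sited if sited else float("nan")


def score_against_truth(candidates, truth: Sequence[MutationRecord]) -> TruthScore:
    """Score detected candidates against the simulation's spiked truth.

    A candidate is a true positive only when (amplicon, position, alt)
    matches a spiked mutation AND the deconvolution is unique with the
    correct family; a correct site with a wrong or ambiguous family scores
    as partial."""
    truth_sites: dict[tuple, set[int]] = {}
    for m in truth:
        truth_sites.setdefault((m.amplicon_id, m.position, m.alt_base), set()).add(m.family_id)
    tp = partial = fp = 0
    for c in candidates:
        fams = truth_sites.get((c.amplicon_id, c.position, c.alt_base))
        if fams is None:
            fp += 1
        elif c.status == "unique" and c.families[0] in fams:
            tp += 1
        else:
            partial += 1
    return TruthScore(
        n_truth=len(truth), n_candidates=len(candidates),
        true_positive=tp, partial=partial, false_positive=fp,
    )
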