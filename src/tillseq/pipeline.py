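"""End-to-end orchestration: simulate -> map -> detect -> annotate -> score.

The in-memory path (`run_end_to_end`) is the library workhorse used by the
tests and by replicate studies; the fixture path (`write_fixture` /
`load_fixture`) round-trips everything through the on-disk formats (FASTA,
GFF3, FASTQ, TSV) and is what the CLI drives.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import detection, mapping, simulate
from .annotation import (TruthScore, annotate_candidates, mutation_frequency,
                         score_against_truth, total_screened_kb)
from .config import RunConfig
from .detection import CallParams, CandidateMutation
from .mapping import AlleleCountMatrix
from .pooling import PoolingScheme, build_scheme, write_scheme_tsv
from .simulate import AmpliconModel, MutationRecord, ReadSet


@dataclass
class Fixture:
    scheme: PoolingScheme
    amplicons: list[AmpliconModel]
    truth: list[MutationRecord]
    readsets: dict[str, ReadSet]


@dataclass
class RunResult:
    fixture: Fixture
    counts: dict  # pool -> amplicon_id -> AlleleCountMatrix
    mapping_efficiency: float
    candidates: list[CandidateMutation]
    score: TruthScore

    @property
    def estimated_freq_kb(self) -> float:
        """Screened kb per detected mutation (NaN when nothing was called)."""
        kb = total_screened_kb(self.fixture.amplicons, self.fixture.scheme.n_families)
        return mutation_frequency(len(self.candidates), kb)[0]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_fixture(config: RunConfig, seed: int | None = None,
                     n_mutations: int | None = None) -> Fixture:
    """Generate scheme, references, truth and pooled reads in memory."""
    seed = config.seed if seed is None else seed
    rng_ref, rng_mut, rng_reads = _spawn(seed, 3)
    scheme = build_scheme(config.n_families, config.cube_dim)
    amplicons = simulate.generate_references(
        n_amplicons=config.n_amplicons,
        length_range=config.length_range,
        divergence=config.divergence,
        n_exons_range=config.n_exons_range,
        seed=rng_ref,
        n_genes=config.n_genes,
        primer_len=config.primer_len,
    )
    truth = simulate.spike_mutations(
        scheme, amplicons,
        freq_kb_per_mutation=config.freq_kb,
        het_fraction=config.het_fraction,
        seed=rng_mut,
        n_mutations=n_mutations,
    )
    readsets = simulate.simulate_pool_reads(
        scheme, amplicons, truth,
        coverage_per_family=config.coverage,
        read_length=config.read_length,
        error_rate=config.error_rate,
        genome_mix=config.genome_mix,
        seed=rng_reads,
    )
    return Fixture(scheme, amplicons, truth, readsets)


def map_pools(
    readsets: Mapping[str, ReadSet],
    amplicons: Sequence[AmpliconModel],
    max_mismatch_frac: float = 0.1,
) -> tuple[dict, float]:
    """Assign and pile up every pool; returns (counts, mapping efficiency)."""
    index = mapping.build_seed_index(amplicons)
    counts: dict[str, dict[str, AlleleCountMatrix]] = {}
    assigned = total = 0
    for pool, rs in readsets.items():
        asg = mapping.assign_reads(rs, amplicons, max_mismatch_frac, index=index)
        counts[pool] = mapping.pileup(rs, asg, amplicons, pool)
        assigned += asg.n_assigned
        total += asg.n_reads
    eff = assigned / total if total else float("nan")
    return counts, eff


def detect(
    counts: Mapping[str, Mapping[str, AlleleCountMatrix]],
    scheme: PoolingScheme,
    amplicons: Sequence[AmpliconModel],
    config: RunConfig,
) -> list[CandidateMutation]:
    params = CallParams(
        alpha=config.alpha,
        min_alt=config.min_alt,
        error_rate=config.null_error_rate,
        strict_axes=config.strict_axes,
    )
    cands = detection.call_mutations(counts, scheme, amplicons, params)
    return annotate_candidates(cands, amplicons, config.splice_window)


def run_end_to_end(config: RunConfig, seed: int | None = None,
                   n_mutations: int | None = None) -> RunResult:
    """Simulate, map, detect and score one replicate."""
    fx = simulate_fixture(config, seed=seed, n_mutations=n_mutations)
    counts, eff = map_pools(fx.readsets, fx.amplicons, config.max_mismatch_frac)
    cands = detect(counts, fx.scheme, fx.amplicons, config)
    score = score_against_truth(cands, fx.truth)
    return RunResult(fx, counts, eff, cands, score)


# ---------------------------------------------------------------------------
# On-disk fixtures
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(fx: Fixture, out_dir, config: RunConfig) -> dict:
    """Write the complete fixture (FASTA x2, GFF3, FASTQ per pool, scheme TSV,
    truth TSV) plus a manifest JSON with checksums; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    simulate.write_fasta(fx.amplicons, out / "genome_a.fasta", out / "genome_b.fasta")
    simulate.write_gff3(fx.amplicons, out / "amplicons.gff3")
    write_scheme_tsv(fx.scheme, out / "scheme.tsv")
    simulate.write_truth_tsv(fx.truth, out / "truth.tsv")
    for pool, rs in fx.readsets.items():
        simulate.write_pool_fastq(pool, rs, fx.amplicons, out / f"{pool}.fastq",
                                  error_rate=config.error_rate)
    config.to_yaml(out / "config.yaml")
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "checksums": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_fixture(fixture_dir, config: RunConfig | None = None) -> Fixture:
    d = Path(fixture_dir)
    if config is None:
        config = RunConfig.from_yaml(d / "config.yaml")
    amplicons = simulate.read_fasta_pair(
        d / "genome_a.fasta", d / "genome_b.fasta", d / "amplicons.gff3"
    )
    from .pooling import read_scheme_tsv

    scheme = read_scheme_tsv(d / "scheme.tsv")
    truth_path = d / "truth.tsv"
    truth = simulate.read_truth_tsv(truth_path) if truth_path.exists() else []
    readsets = {}
    for pool in scheme.pool_labels:
        fq = d / f"{pool}.fastq"
        if not fq.exists():
            raise FileNotFoundError(f"missing pool FASTQ: {fq}")
        readsets[pool] = simulate.read_pool_fastq(fq)
    return Fixture(scheme, amplicons, truth, readsets)
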