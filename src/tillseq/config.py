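"""Run configuration: one flat namespace of every tunable parameter.

Defaults reproduce the platform-scale scenario: 512 M2 families on an 8x8x8
cube (24 pools of 64), 17 amplicons of 452-704 bp from 13 genes, 0.5%
inter-genome divergence, one EMS mutation per 320 kb screened, 11.3x
coverage per family, 0.2% sequencing error, 150 bp reads.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    # pooling
    cube_dim: int = 8
    n_families: int = 512
    # references
    n_amplicons: int = 17
    n_genes: int = 13
    length_range: tuple[int, int] = (452, 704)
    divergence: float = 0.005
    n_exons_range: tuple[int, int] = (1, 3)
    primer_len: int = 20
    # mutations + reads
    freq_kb: float = 320.0
    het_fraction: float = 1.0
    coverage: float = 11.3
    error_rate: float = 0.002
    read_length: int = 150
    genome_mix: float = 0.5
    # mapping
    max_mismatch_frac: float = 0.1
    # detection
    alpha: float = 0.05
    min_alt: int = 2
    null_error_rate: float | None = None  # None -> estimated per amplicon
    strict_axes: bool = True
    # annotation
    splice_window: int = 2
    # markers
    tm_window: tuple[float, float] = (57.0, 63.0)
    len_range: tuple[int, int] = (18, 30)
    product_range: tuple[int, int] = (60, 120)
    # run
    seed: int = 0
    output_dir: str = "tillseq_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
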