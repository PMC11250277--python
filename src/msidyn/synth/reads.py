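"""Synthetic read-length distributions at a coding homopolymer.

Each read is drawn from the population's allele-length fractions and then, with
probability ``stutter_rate``, slips one repeat unit up or down (PCR/sequencing
stutter, equiprobable direction). This is the fixture for the frameshift caller
and the repeat-allele Shannon diversity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..homopolymers import HomopolymerSite, LengthDistribution

__all__ = ["MsSimSpec", "gen_ms_reads"]


@dataclass(frozen=True)
class MsSimSpec:
    ref_length: int = 8
    allele_fractions: dict[int, float] = field(default_factory=lambda: {8: 1.0})
    depth: int = 300
    stutter_rate: float = 0.0
    unit: str = "C"
    chrom: str = "chrS"
    start: int = 1000
    gene: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.ref_length):
            raise ValueError("ref_length must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 <= self.stutter_rate <= 1.0):
            raise ValueError("stutter_rate must be a probability")
        fracs = np.array(list(self.allele_fractions.values()), dtype=float)
        if (fracs < 0).any():
            raise ValueError("allele fractions must be non-negative")
        if self.allele_fractions and abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("allele fractions must sum to 1")


def gen_ms_reads(spec: MsSimSpec) -> LengthDistribution:
    """Draw ``depth`` reads and return their length distribution.

    Total reads always equals ``depth`` (stutter shifts reads between lengths
    but never creates or destroys them).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = np.array(sorted(spec.allele_fractions), dtype=int)
    probs = np.array([spec.allele_fractions[k] for k in lengths], dtype=float)
    if spec.depth == 0 or len(lengths) == 0:
        reads = np.array([], dtype=int)
    else:
        reads = rng.choice(lengths, size=spec.depth, p=probs)
        if spec.stutter_rate > 0:
            slip = rng.random(spec.depth) < spec.stutter_rate
            direction = rng.choice([-1, 1], size=spec.depth)
            reads = reads + slip * direction
            reads = np.maximum(reads, 1)  # a run cannot shrink below 1 base
    values, counts = np.unique(reads, return_counts=True)
    site = HomopolymerSite(
        chrom=spec.chrom,
        start=spec.start,
        unit=spec.unit,
        ref_length=spec.ref_length,
        gene=spec.gene,
    )
    return LengthDistribution(
        site=site,
        tumor_counts={int(v): int(c) for v, c in zip(values, counts)},
    )
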