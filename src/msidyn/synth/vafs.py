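"""Synthetic VAF spectra: a clonal cluster plus a neutral 1/f tail.

Under neutral exponential growth the number of subclonal mutations at variant
allele frequency >= f follows M(f) = mu (1/f - 1/f_max). ``deterministic`` mode
places mutations at the exact inverse of M at counts 1..N, giving an exact
recovery oracle for the tail-slope estimator; ``sampled`` mode draws a Poisson
number of mutations from the corresponding density and adds binomial read
sampling at the given depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ratetail import VafSpectrum

__all__ = ["TailSimSpec", "gen_neutral_vafs"]


@dataclass(frozen=True)
class TailSimSpec:
    mu_true: float = 100.0
    f_min: float = 0.05
    f_max: float = 0.25
    n_clonal: int = 100
    clonal_center: float = 0.5
    depth: int = 300
    mode: str = "deterministic"  # or "sampled"
    diploid_region_size_bp: int = 30_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.mu_true < 0:
            raise ValueError("mu_true must be non-negative")
        if not (0.0 < self.f_min < self.f_max <= 0.5):
            raise ValueError("need 0 < f_min < f_max <= 0.5")
        if self.mode not in ("deterministic", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_clonal < 0:
            raise ValueError("n_clonal must be >= 0")


def expected_tail_count(mu: float, f: float, f_max: float) -> float:
    """M(f) = mu (1/f - 1/f_max), the cumulative neutral-tail count."""
    return mu * (1.0 / f - 1.0 / f_max)


def gen_neutral_vafs(spec: TailSimSpec) -> VafSpectrum:
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.mu_true == 0:
        tail_vafs = np.array([])
    elif spec.mode == "deterministic":
        n_tail = int(np.floor(expected_tail_count(spec.mu_true, spec.f_min, spec.f_max)))
        k = np.arange(1, n_tail + 1, dtype=float)
        # inverse of M: the k-th mutation sits where the cumulative equals k
        tail_vafs = 1.0 / (k / spec.mu_true + 1.0 / spec.f_max)
    else:
        lam = expected_tail_count(spec.mu_true, spec.f_min, spec.f_max)
        n_tail = rng.poisson(lam)
        u = rng.random(n_tail)
        # inverse-CDF of density prop. to 1/f^2 on [f_min, f_max]
        inv = (1.0 / spec.f_min) + u * (1.0 / spec.f_max - 1.0 / spec.f_min)
        tail_vafs = 1.0 / inv

    clonal_vafs = np.full(spec.n_clonal, spec.clonal_center)
    all_true = np.concatenate([tail_vafs, clonal_vafs])

    n = len(all_true)
    total = np.full(n, spec.depth, dtype=int)
    if spec.mode == "sampled":
        alt = rng.binomial(total, all_true)
    else:
        alt = np.rint(all_true * spec.depth).astype(int)
    keep = alt > 0
    alt, total = alt[keep], total[keep]
    vaf = alt / total
    if spec.mode == "deterministic":
        # exact oracle: report the analytic frequencies, reads are cosmetic
        vaf = all_true[keep]

    order = np.argsort(vaf)[::-1]
    return VafSpectrum(
        vaf=vaf[order],
        alt_reads=alt[order],
        total_reads=total[order],
        sample="synthetic",
        diploid_region_size_bp=spec.diploid_region_size_bp,
    )
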