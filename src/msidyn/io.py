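"""Readers and writers for the file dialects shared across the package.

Conventions: BED-like inputs are 0-based half-open and converted to the
internal 1-based inclusive coordinates at the boundary; all reports are
1-based. Every reader round-trips bit-exactly on the output of the matching
writer.

Dialects
--------
MSIsensor "dis": per site a header line ``chrom position left_flank
repeat_unit right_flank`` followed by ``T: c0 c1 ... c99`` (counts indexed by
observed repeat length) and an optional ``N: ...`` line.

Distribution TSV (long): columns site_id, chrom, pos_1based, unit,
ref_length, length, count.

Variants: VCF v4.2 with per-sample AD, or a TSV with columns chrom, pos,
ref, alt, ref_reads, alt_reads.

CN segments TSV: chrom, start, end, major, minor (0-based half-open).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .homopolymers import HomopolymerSite, LengthDistribution

__all__ = [
    "VariantRecord",
    "read_msisensor_dis",
    "write_msisensor_dis",
    "read_distribution_tsv",
    "write_distribution_tsv",
    "read_variants",
    "write_variants_tsv",
    "read_catalog_bed",
    "read_cn_segments",
    "write_image",
    "read_image",
    "write_vaf_tsv",
    "read_vaf_tsv",
]

_MAX_LEN = 100  # dis count vectors are fixed-width


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int

    @property
    def vaf(self) -> float:
        return self.alt_reads / (self.ref_reads + self.alt_reads)

    def get(self, key):
        return getattr(self, key)


# ---------------------------------------------------------------- MSIsensor


def _counts_to_vector(counts: dict[int, int]) -> list[int]:
    vec = [0] * _MAX_LEN
    for length, c in counts.items():
        if not (0 <= length < _MAX_LEN):
            raise ValueError(f"repeat length {length} outside dis range")
        vec[length] = c
    return vec


def write_msisensor_dis(dists: list[LengthDistribution], path: str | Path) -> None:
    lines = []
    for d in dists:
        unit_len = d.site.ref_length
        lines.append(
            f"{d.site.chrom} {d.site.start} NA {d.site.unit * unit_len} NA"
        )
        lines.append("T: " + " ".join(map(str, _counts_to_vector(d.tumor_counts))))
        if d.normal_counts is not None:
            lines.append("N: " + " ".join(map(str, _counts_to_vector(d.normal_counts))))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_msisensor_dis(path: str | Path) -> list[LengthDistribution]:
    """Parse the dis dialect; zero-count lengths are dropped."""
    out: list[LengthDistribution] = []
    header = None
    tumor = None
    normal = None

    def flush(lineno):
        nonlocal header, tumor, normal
        if header is None:
            return
        if tumor is None:
            raise ParseError(f"line {lineno}: site without T: counts")
        chrom, pos, _, repeat, _ = header
        site = HomopolymerSite(
            chrom=chrom, start=int(pos), unit=repeat[0], ref_length=len(repeat)
        )
        out.append(LengthDistribution(site=site, tumor_counts=tumor,
                                      normal_counts=normal))
        header = tumor = normal = None

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("T:") or line.startswith("N:"):
            if header is None:
                raise ParseError(f"line {lineno}: counts before any site header")
            try:
                vec = [int(x) for x in line[2:].split()]
            except ValueError as e:
                raise ParseError(f"line {lineno}: bad count line: {e}") from None
            counts = {i: c for i, c in enumerate(vec) if c > 0}
            if line.startswith("T:"):
                tumor = counts
            else:
                normal = counts
        else:
            flush(lineno)
            fields = line.split()
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 5-field site header")
            header = fields
    flush(lineno="EOF")
    return out


# ----------------------------------------------------------- distribution TSV


def write_distribution_tsv(dists: list[LengthDistribution], path: str | Path) -> None:
    rows = []
    for d in dists:
        for length, count in sorted(d.tumor_counts.items()):
            rows.append(
                dict(site_id=d.site.site_id, chrom=d.site.chrom,
                     pos_1based=d.site.start, unit=d.site.unit,
                     ref_length=d.site.ref_length, length=length, count=count)
            )
    pd.DataFrame(
        rows,
        columns=["site_id", "chrom", "pos_1based", "unit", "ref_length",
                 "length", "count"],
    ).to_csv(path, sep="\t", index=False)


def read_distribution_tsv(path: str | Path) -> list[LengthDistribution]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, grp in df.groupby("site_id", sort=False):
        first = grp.iloc[0]
        site = HomopolymerSite(
            chrom=str(first["chrom"]), start=int(first["pos_1based"]),
            unit=str(first["unit"]), ref_length=int(first["ref_length"]),
        )
        counts = {int(r["length"]): int(r["count"]) for _, r in grp.iterrows()}
        out.append(LengthDistribution(site=site, tumor_counts=counts))
    return out


# ----------------------------------------------------------------- variants


def read_variants(path: str | Path, sample: str | None = None) -> list[VariantRecord]:
    """Read variants with read support from VCF v4.2 (via AD) or TSV.

    Multi-allelic VCF records are split into one record per ALT; records
    without usable depths are skipped (a count is reported via logging).
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, sample)
    df = pd.read_csv(path, sep="\t")
    records = []
    skipped = 0
    for _, r in df.iterrows():
        ref_reads, alt_reads = int(r["ref_reads"]), int(r["alt_reads"])
        if ref_reads + alt_reads == 0:
            skipped += 1
            continue
        records.append(VariantRecord(str(r["chrom"]), int(r["pos"]), str(r["ref"]),
                                     str(r["alt"]), ref_reads, alt_reads))
    if skipped:
        import logging
        logging.getLogger(__name__).warning("skipped %d zero-depth rows", skipped)
    return records


def _read_vcf(path: Path, sample: str | None) -> list[VariantRecord]:
    import pysam

    records = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise ParseError("VCF has no sample columns with read depths")
        use = sample or sample_names[0]
        for rec in vcf:
            call = rec.samples[use]
            ad = call.get("AD")
            if ad is None or ad[0] is None:
                skipped += 1
                continue
            for i, alt in enumerate(rec.alts or ()):
                alt_reads = ad[i + 1] if len(ad) > i + 1 and ad[i + 1] is not None else None
                if alt_reads is None or ad[0] + alt_reads == 0:
                    skipped += 1
                    continue
                records.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt,
                                             int(ad[0]), int(alt_reads)))
    if skipped:
        import logging
        logging.getLogger(__name__).warning("skipped %d VCF records without AD", skipped)
    return records


def write_variants_tsv(records: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [dict(chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
              ref_reads=r.ref_reads, alt_reads=r.alt_reads) for r in records],
        columns=["chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"],
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ catalogs


def read_catalog_bed(path: str | Path) -> list[HomopolymerSite]:
    """Homopolymer catalog: BED (0-based half-open) + columns unit,
    ref_length[, gene]. Converted to 1-based inclusive starts."""
    sites = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 5:
            raise ParseError(f"line {lineno}: need chrom,start,end,unit,ref_length")
        gene = f[5] if len(f) > 5 and f[5] != "." else None
        sites.append(HomopolymerSite(chrom=f[0], start=int(f[1]) + 1, unit=f[3],
                                     ref_length=int(f[4]), gene=gene))
    return sites


def read_cn_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "major", "minor"}
    if not required.issubset(df.columns):
        raise ParseError(f"CN segments need columns {sorted(required)}")
    return df


# -------------------------------------------------------------------- images


def write_image(
    channels: dict[str, np.ndarray],
    path: str | Path,
    um_per_px: float,
    truth=None,
) -> None:
    """Multi-page TIFF (one page per channel) with a JSON sidecar holding
    the pixel scale, channel names and any ground truth."""
    import tifffile

    path = Path(path)
    names = list(channels)
    stack = np.stack([np.asarray(channels[c], dtype=np.float32) for c in names])
    tifffile.imwrite(path, stack)
    sidecar = {"um_per_px": um_per_px, "channels": names}
    if truth is not None:
        sidecar["truth"] = {
            "ellipses": [list(map(float, e)) for e in truth.ellipses],
            "phenotypes": list(truth.phenotypes),
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path: str | Path) -> tuple[dict[str, np.ndarray], float, dict | None]:
    import tifffile

    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    channels = {name: stack[i] for i, name in enumerate(sidecar["channels"])}
    return channels, float(sidecar["um_per_px"]), sidecar.get("truth")


# ----------------------------------------------------------------- VAF files


def write_vaf_tsv(spectrum, path: str | Path) -> None:
    """VafSpectrum as TSV with synthetic coordinates."""
    n = len(spectrum)
    ref = spectrum.total_reads - spectrum.alt_reads
    pd.DataFrame(
        dict(chrom=["chrS"] * n, pos=np.arange(1, n + 1) * 1000,
             ref_reads=ref, alt_reads=spectrum.alt_reads, vaf=spectrum.vaf)
    ).to_csv(path, sep="\t", index=False)


def read_vaf_tsv(path: str | Path, diploid_region_size_bp: int = 30_000_000):
    from .ratetail import VafSpectrum

    df = pd.read_csv(path, sep="\t")
    total = df["ref_reads"].to_numpy() + df["alt_reads"].to_numpy()
    return VafSpectrum(
        vaf=df["vaf"].to_numpy(), alt_reads=df["alt_reads"].to_numpy(),
        total_reads=total, diploid_region_size_bp=diploid_region_size_bp,
    )
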