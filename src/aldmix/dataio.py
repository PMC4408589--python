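"""Readers and writers for the standard interchange formats.

Phased haplotypes come in as VCF (phased GT, the canonical interchange)
or Oxford HAPS/SAMPLE; genetic maps as whitespace text (see
genome_windows); results go out as delimited tables (ancestry field,
BED-like segment tracks, scan tables) plus a JSON run manifest.
Unphased VCF entries are an error unless a permissive flag turns them
into missing haplotypes; multi-allelic sites are dropped with a logged
count.  Coordinates are 1-based throughout, as in VCF.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_windows import WindowSet, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedDataset",
    "read_phased",
    "write_phased_vcf",
    "write_ancestry_table",
    "write_segments_bed",
    "write_manifest",
]


@dataclass
class PhasedDataset:
    """Phased biallelic haplotypes plus marker metadata.

    haplotypes: (2N, M) int8, rows 2i/2i+1 = individual i; -1 missing.
    markers: DataFrame with id, chromosome, position_bp, ref, alt.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    haplotypes: np.ndarray
    phase_note: str = "phased input"
    dropped_multiallelic: int = 0

    def __post_init__(self):
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must be 2 x individual count")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("marker table and haplotype matrix disagree")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)


def _read_vcf(path, permissive: bool) -> PhasedDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    haps = []
    dropped = 0
    for rec_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            dropped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for s, g in enumerate(v.genotypes):
            a0, a1, phased = g[0], g[1], bool(g[-1])
            if a0 < 0 or a1 < 0:
                col[2 * s], col[2 * s + 1] = -1, -1
                continue
            if not phased and a0 != a1:
                if not permissive:
                    raise ValueError(
                        f"unphased heterozygote at record {rec_no} "
                        f"({v.CHROM}:{v.POS}, sample {samples[s]}); "
                        "re-run with permissive=True to treat as missing"
                    )
                col[2 * s], col[2 * s + 1] = -1, -1
                continue
            col[2 * s], col[2 * s + 1] = a0, a1
        rows.append(
            dict(
                id=v.ID or f"{v.CHROM}:{v.POS}",
                chromosome=normalize_chrom(v.CHROM),
                position_bp=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0],
            )
        )
        haps.append(col)
    if dropped:
        logger.info("dropped %d multi-allelic sites", dropped)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    return PhasedDataset(
        sample_ids=samples,
        markers=pd.DataFrame(rows),
        haplotypes=np.array(haps, dtype=np.int8).T,
        phase_note=f"VCF {Path(path).name}",
        dropped_multiallelic=dropped,
    )


def _read_haps(path, sample_path=None, chromosome="1") -> PhasedDataset:
    """Oxford HAPS: chr id bp ref alt then two allele columns per sample."""
    rows = []
    haps = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"malformed HAPS record at line {line_no}")
            chrom, mid, bp, ref, alt = parts[:5]
            alleles = parts[5:]
            try:
                col = np.array(
                    [-1 if a in ("?", ".", "NA") else int(a) for a in alleles],
                    dtype=np.int8,
                )
            except ValueError as err:
                raise ValueError(f"malformed allele at line {line_no}: {err}") from err
            rows.append(dict(id=mid, chromosome=normalize_chrom(chrom),
                             position_bp=int(bp), ref=ref, alt=alt))
            haps.append(col)
    H = np.array(haps, dtype=np.int8).T
    if sample_path is not None:
        samp = pd.read_csv(sample_path, sep=r"\s+")
        sample_ids = [str(s) for s in samp.iloc[1:, 1]] if len(samp) else []
        if len(sample_ids) * 2 != H.shape[0]:
            sample_ids = [f"ind{i}" for i in range(H.shape[0] // 2)]
    else:
        sample_ids = [f"ind{i}" for i in range(H.shape[0] // 2)]
    return PhasedDataset(
        sample_ids=sample_ids,
        markers=pd.DataFrame(rows),
        haplotypes=H,
        phase_note=f"HAPS {Path(path).name}",
    )


def read_phased(path, format: str = "vcf", permissive: bool = False, sample_path=None) -> PhasedDataset:
    """Read phased haplotypes from VCF or Oxford HAPS."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, permissive)
    if format == "haps":
        return _read_haps(path, sample_path)
    raise ValueError(f"unknown format: {format}")


def write_phased_vcf(dataset: PhasedDataset, path) -> None:
    """Write a minimal phased VCF (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=aldmix\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in dataset.sample_ids) + "\n")
        H = dataset.haplotypes
        for m, row in dataset.markers.iterrows():
            gts = []
            for i in range(dataset.n_individuals):
                a0, a1 = H[2 * i, m], H[2 * i + 1, m]
                gts.append(
                    "./."
                    if a0 < 0 or a1 < 0
                    else f"{a0}|{a1}"
                )
            fh.write(
                f"{row['chromosome']}\t{row['position_bp']}\t{row['id']}\t"
                f"{row.get('ref', 'A')}\t{row.get('alt', 'G')}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_ancestry_table(field, windows: WindowSet, sample_ids, path, pop_names=None) -> None:
    """Long-format gamma/G table: one row per (individual, haplotype, window)."""
    K = field.n_pops
    names = pop_names or [f"pop{k}" for k in range(K)]
    tab = windows.table
    rows = []
    for h in range(field.gamma.shape[0]):
        ind, copy = divmod(h, 2)
        for j in range(windows.n_windows):
            row = {
                "individual": sample_ids[ind],
                "haplotype": copy,
                "chromosome": tab.iloc[j]["chromosome"],
                "start_cm": tab.iloc[j]["start_cm"],
                "end_cm": tab.iloc[j]["end_cm"],
                "state": int(field.G[h, j]) if field.G is not None else -1,
            }
            for k in range(K):
                row[f"gamma_{names[k]}"] = field.gamma[h, j, k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_segments_bed(field, windows: WindowSet, sample_ids, path) -> None:
    """BED-like track of constant-ancestry segments (hard calls on gamma)."""
    calls = np.argmax(field.gamma, axis=2)
    tab = windows.table
    with open(path, "w") as fh:
        fh.write("#chrom\tstart_cm\tend_cm\tindividual\thaplotype\tancestry\n")
        for h in range(calls.shape[0]):
            ind, copy = divmod(h, 2)
            j = 0
            while j < calls.shape[1]:
                j2 = j
                while (
                    j2 + 1 < calls.shape[1]
                    and calls[h, j2 + 1] == calls[h, j]
                    and tab.iloc[j2 + 1]["chromosome"] == tab.iloc[j]["chromosome"]
                ):
                    j2 += 1
                fh.write(
                    f"{tab.iloc[j]['chromosome']}\t{tab.iloc[j]['start_cm']:.4f}\t"
                    f"{tab.iloc[j2]['end_cm']:.4f}\t{sample_ids[ind]}\t{copy}\t"
                    f"{int(calls[h, j])}\n"
                )
                j = j2 + 1


def write_manifest(path, seed=None, config=None, extra=None) -> None:
    """JSON run manifest: package version, seed and a config hash."""
    from . import __version__

    cfg_txt = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "aldmix_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_txt.encode()).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
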