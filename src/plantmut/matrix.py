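"""Per-site x per-sample read support: the call-level input of the pipeline.

The pipeline does not work from raw reads; its input boundary is a
multi-sample variant matrix: for every candidate site and sample, the read
depth, mutant-allele read counts split by strand, the count of mutant reads
with base quality >= 20, and the genotype status assigned by the upstream
caller(s). Site-level metadata records the variant quality score and which
of the two upstream call sets (A = alignment-direct caller, B = local
reassembly caller) reported the site.

On disk a matrix is a pair of files: a VCF with sites and genotypes, and a
read-support TSV sidecar with the per-sample read counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

# genotype status codes
REF, VAR, MISSING = 0, 1, 2

SUPPORT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample",
    "depth",
    "mut_fwd",
    "mut_rev",
    "mut_bq20",
    "status",
]

_STATUS_STR = {REF: "ref", VAR: "variant", MISSING: "missing"}
_STATUS_CODE = {v: k for k, v in _STATUS_STR.items()}


@dataclass(frozen=True)
class Site:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class SiteCallMatrix:
    """Dense per-site x per-sample read-support matrix.

    Arrays are shaped ``(n_sites, n_samples)``; sites are `Site` records and
    carry a variant quality score plus call-set provenance flags.
    """

    def __init__(
        self,
        sites: list[Site],
        samples: list[str],
        depth: np.ndarray,
        mut_fwd: np.ndarray,
        mut_rev: np.ndarray,
        mut_bq20: np.ndarray,
        status: np.ndarray,
        variant_quality: np.ndarray,
        callset_a: np.ndarray,
        callset_b: np.ndarray,
    ) -> None:
        self.sites = list(sites)
        self.samples = list(samples)
        self.depth = np.asarray(depth, dtype=np.int32)
        self.mut_fwd = np.asarray(mut_fwd, dtype=np.int32)
        self.mut_rev = np.asarray(mut_rev, dtype=np.int32)
        self.mut_bq20 = np.asarray(mut_bq20, dtype=np.int32)
        self.status = np.asarray(status, dtype=np.int8)
        self.variant_quality = np.asarray(variant_quality, dtype=float)
        self.callset_a = np.asarray(callset_a, dtype=bool)
        self.callset_b = np.asarray(callset_b, dtype=bool)
        self._index = {s.key: i for i, s in enumerate(self.sites)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}
        self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def empty(cls, samples: list[str]) -> "SiteCallMatrix":
        z = np.zeros((0, len(samples)), dtype=np.int32)
        return cls(
            sites=[],
            samples=samples,
            depth=z,
            mut_fwd=z.copy(),
            mut_rev=z.copy(),
            mut_bq20=z.copy(),
            status=z.astype(np.int8),
            variant_quality=np.zeros(0),
            callset_a=np.zeros(0, bool),
            callset_b=np.zeros(0, bool),
        )

    def validate(self) -> None:
        n, m = len(self.sites), len(self.samples)
        for name in ("depth", "mut_fwd", "mut_rev", "mut_bq20", "status"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        for name in ("variant_quality", "callset_a", "callset_b"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per site")
        if len(self._index) != n:
            raise ValueError("duplicate sites in matrix")
        if any(s.pos < 1 for s in self.sites):
            raise ValueError("positions are 1-based; pos < 1 found")
        mut = self.mut_fwd + self.mut_rev
        if np.any(mut > self.depth):
            raise ValueError("mut_fwd + mut_rev exceeds depth")
        if np.any(self.mut_bq20 > mut):
            raise ValueError("mut_bq20 exceeds mut_fwd + mut_rev")
        if np.any((self.mut_fwd < 0) | (self.mut_rev < 0) | (self.depth < 0)):
            raise ValueError("negative read counts")

    # -- accessors ----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def mut_reads(self) -> np.ndarray:
        return self.mut_fwd + self.mut_rev

    def site_index(self, site: Site) -> int | None:
        return self._index.get(site.key)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def variant_samples(self, i: int) -> frozenset[str]:
        """Samples with variant genotype status at site row ``i``."""
        mask = self.status[i] == VAR
        return frozenset(s for s, m in zip(self.samples, mask) if m)

    def missing_count(self, i: int) -> int:
        return int(np.sum(self.status[i] == MISSING))

    # -- I/O ----------------------------------------------------------------

    def to_files(self, vcf_path, support_path, contig_lengths=None) -> None:
        """Write the matrix as a VCF (sites + genotypes) plus a support TSV."""
        header = pysam.VariantHeader()
        header.add_line('##source=plantmut')
        header.add_line(
            '##INFO=<ID=CSA,Number=0,Type=Flag,Description='
            '"Reported by call set A (alignment-direct caller)">'
        )
        header.add_line(
            '##INFO=<ID=CSB,Number=0,Type=Flag,Description='
            '"Reported by call set B (reassembly caller)">'
        )
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lengths: dict[str, int] = dict(contig_lengths or {})
        for s in self.sites:
            lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.pos + len(s.ref) + 1)
        for chrom, length in lengths.items():
            header.add_line(f"##contig=<ID={chrom},length={length}>")
        for sample in self.samples:
            header.add_sample(sample)
        order = np.lexsort(
            (
                [s.pos for s in self.sites],
                [s.chrom for s in self.sites],
            )
        )
        with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
            for i in order:
                s = self.sites[i]
                rec = vcf.new_record(
                    contig=s.chrom,
                    start=s.pos - 1,
                    stop=s.pos - 1 + len(s.ref),
                    alleles=(s.ref, s.alt),
                    qual=float(self.variant_quality[i]),
                )
                if self.callset_a[i]:
                    rec.info["CSA"] = True
                if self.callset_b[i]:
                    rec.info["CSB"] = True
                for j, sample in enumerate(self.samples):
                    st = self.status[i, j]
                    if st == MISSING:
                        rec.samples[sample]["GT"] = (None, None)
                    elif st == VAR:
                        rec.samples[sample]["GT"] = (0, 1)
                    else:
                        rec.samples[sample]["GT"] = (0, 0)
                vcf.write(rec)
        self.support_frame().to_csv(support_path, sep="\t", index=False)

    def support_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sites):
            for j, sample in enumerate(self.samples):
                rows.append(
                    (
                        s.chrom,
                        s.pos,
                        s.ref,
                        s.alt,
                        sample,
                        int(self.depth[i, j]),
                        int(self.mut_fwd[i, j]),
                        int(self.mut_rev[i, j]),
                        int(self.mut_bq20[i, j]),
                        _STATUS_STR[int(self.status[i, j])],
                    )
                )
        return pd.DataFrame(rows, columns=SUPPORT_COLUMNS)

    @classmethod
    def from_files(cls, vcf_path, support_path) -> "SiteCallMatrix":
        """Read a matrix back from a VCF + read-support TSV pair."""
        sites: list[Site] = []
        quals: list[float] = []
        csa: list[bool] = []
        csb: list[bool] = []
        status_rows: list[np.ndarray] = []
        with pysam.VariantFile(str(vcf_path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                sites.append(Site(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
                quals.append(rec.qual if rec.qual is not None else 0.0)
                csa.append("CSA" in rec.info)
                csb.append("CSB" in rec.info)
                row = np.zeros(len(samples), dtype=np.int8)
                for j, sample in enumerate(samples):
                    gt = rec.samples[sample]["GT"]
                    if gt is None or any(a is None for a in gt):
                        row[j] = MISSING
                    elif any(a == 1 for a in gt):
                        row[j] = VAR
                row_status = row
                status_rows.append(row_status)
        support = pd.read_csv(support_path, sep="\t", dtype={"chrom": str})
        n, m = len(sites), len(samples)
        shape = (n, m)
        depth = np.zeros(shape, np.int32)
        fwd = np.zeros(shape, np.int32)
        rev = np.zeros(shape, np.int32)
        bq20 = np.zeros(shape, np.int32)
        idx = {s.key: i for i, s in enumerate(sites)}
        jdx = {s: j for j, s in enumerate(samples)}
        for row in support.itertuples(index=False):
            key = (row.chrom, int(row.pos), row.ref, row.alt)
            if key not in idx:
                raise ValueError(f"support TSV row {key} not present in VCF")
            i, j = idx[key], jdx[row.sample]
            depth[i, j] = row.depth
            fwd[i, j] = row.mut_fwd
            rev[i, j] = row.mut_rev
            bq20[i, j] = row.mut_bq20
        status = np.vstack(status_rows) if status_rows else np.zeros(shape, np.int8)
        return cls(
            sites=sites,
            samples=samples,
            depth=depth,
            mut_fwd=fwd,
            mut_rev=rev,
            mut_bq20=bq20,
            status=status,
            variant_quality=np.array(quals),
            callset_a=np.array(csa, bool),
            callset_b=np.array(csb, bool),
        )
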