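"""Multi-sample VCF I/O and GATK-style hard filtering.

The data model is deliberately small: a list of :class:`SiteRecord` (one per
biallelic SNV, in ``(chrom, pos)`` order) paired with a :class:`GenotypeMatrix`
whose rows follow the same order.  Reading goes through cyvcf2/htslib; writing
is a plain-text VCFv4.2 emitter so that output bytes are a pure function of the
inputs (fixed float formatting, fixed header), which the simulator's
determinism contract relies on.

Hard filters re-implement the canonical short-variant hard-filter recipe:
each expression describes a *failure* condition and contributes a FILTER label
when true; a site passes only when it collects no label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._utils import chrom_sort_key

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing genotype

VALID_BASES = frozenset("ACGT")

# FILTER labels, one per hard-filter criterion.
LOW_DP = "lowDP"
LOW_QUAL = "lowQUAL"
LOW_QD = "lowQD"
HIGH_SB = "highSB"
HIGH_MQ0 = "highMQ0"
SNP_CLUSTER = "snpCluster"
FILTER_LABELS = (LOW_DP, LOW_QUAL, LOW_QD, HIGH_SB, HIGH_MQ0, SNP_CLUSTER)

IMPACT_CLASSES = (
    "synonymous",
    "non_synonymous",
    "start_gained",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "other",
)


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into the site/genotype model."""


@dataclass
class SiteRecord:
    """One biallelic SNV site.

    ``qual`` is the VCF QUAL column (phred-scaled site quality), while the
    ``info_*`` fields mirror the INFO keys the hard filters consume.  Any of
    them may be ``None`` (absent), in which case the corresponding filter
    criterion is simply not applied.  ``filters`` holds the names of failed
    criteria; an empty set renders as ``PASS``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    info_dp: float | None = None
    info_qd: float | None = None
    info_mq0: float | None = None
    info_sb: float | None = None
    filters: set[str] = field(default_factory=set)
    ann_class: str | None = None
    ann_impact: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"invalid bases {self.ref}>{self.alt} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF equals ALT at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def passes(self) -> bool:
        return not self.filters


@dataclass
class GenotypeMatrix:
    """Sites x samples ALT-allele dosages, plus optional per-call read depth.

    ``gt`` is int8 with values 0/1/2 (diploid) or 0/1 (haploid); ``MISSING``
    (-1) marks an uncalled genotype.  Row order matches the accompanying
    SiteRecord list, column order matches ``sample_ids``.
    """

    sample_ids: list[str]
    gt: np.ndarray
    depth: np.ndarray | None = None
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.ndim != 2 or self.gt.shape[1] != len(self.sample_ids):
            raise ValueError("gt must be (n_sites, n_samples)")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.gt.shape:
                raise ValueError("depth shape must match gt shape")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.gt.size and int(self.gt.max()) > self.ploidy:
            raise ValueError("dosage exceeds ploidy")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def take_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            gt=self.gt[idx],
            depth=None if self.depth is None else self.depth[idx],
            ploidy=self.ploidy,
        )


def sort_sites(
    sites: Sequence[SiteRecord], matrix: GenotypeMatrix | None = None
) -> tuple[list[SiteRecord], GenotypeMatrix | None]:
    """Order sites (and matrix rows) by natural chromosome order, then position."""
    order = sorted(range(len(sites)), key=lambda i: (chrom_sort_key(sites[i].chrom), sites[i].pos))
    sorted_sites = [sites[i] for i in order]
    if matrix is None:
        return sorted_sites, None
    return sorted_sites, matrix.take_sites(order)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _restore_f32(v: float) -> float:
    """Shortest decimal value that round-trips the single-precision float.

    htslib stores QUAL and Float INFO values in single precision; the shortest
    round-tripping decimal recovers exactly the number that was written.
    """
    return float(np.format_float_positional(np.float32(v), unique=True))


def _dosage(genotype: list) -> tuple[int, int]:
    """(dosage, ploidy) from a cyvcf2 genotype entry [allele, ..., phased]."""
    alleles = genotype[:-1]
    if any(a < 0 for a in alleles):
        return MISSING, len(alleles)
    return sum(1 for a in alleles if a > 0), len(alleles)


def read_vcf(path: str) -> tuple[list[SiteRecord], GenotypeMatrix]:
    """Load biallelic SNVs from a VCF into the site/genotype model.

    Multi-allelic records and indels are skipped (a single summary line is
    logged); missing genotypes become ``MISSING`` dosages.  Output is sorted
    by (chrom, pos).  Raises :class:`VcfParseError` on malformed input.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib reports its own diagnostics
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    sites: list[SiteRecord] = []
    dosages: list[list[int]] = []
    depths: list[np.ndarray] | None = []
    n_skipped = 0
    ploidy = 2
    try:
        for var in vcf:
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_skipped += 1
                continue
            if var.REF not in VALID_BASES or var.ALT[0] not in VALID_BASES:
                n_skipped += 1
                continue
            row = []
            for g in var.genotypes:
                d, p = _dosage(g)
                ploidy = p if p in (1, 2) else ploidy
                row.append(d)
            dosages.append(row)
            if depths is not None:
                try:
                    dp = var.format("DP")
                except KeyError:
                    dp = None
                if dp is None:
                    depths = None
                else:
                    depths.append(dp.reshape(-1))
            filt = var.FILTER  # None means PASS
            info = var.INFO

            def fget(key: str) -> float | None:
                v = info.get(key)
                return None if v is None else _restore_f32(v)

            mq0 = info.get("MQ0")
            sites.append(
                SiteRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=var.ALT[0],
                    qual=None if var.QUAL is None else _restore_f32(var.QUAL),
                    info_dp=fget("DP"),
                    info_qd=fget("QD"),
                    info_mq0=None if mq0 is None else float(mq0),
                    info_sb=fget("SB"),
                    filters=set() if filt is None else set(filt.split(";")),
                    ann_class=info.get("FC"),
                    ann_impact=info.get("IMP"),
                )
            )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed record in {path} near site #{len(sites) + 1}: {exc}") from exc

    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV/multi-allelic records", path, n_skipped)

    gt = np.asarray(dosages, dtype=np.int8).reshape(len(sites), len(sample_ids))
    depth = None
    if depths is not None and len(depths) == len(sites) and sites:
        depth = np.vstack(depths).astype(np.int32)
        depth[depth < 0] = 0
    matrix = GenotypeMatrix(sample_ids=sample_ids, gt=gt, depth=depth, ploidy=ploidy)
    sorted_sites, sorted_matrix = sort_sites(sites, matrix)
    assert sorted_matrix is not None
    return sorted_sites, sorted_matrix


def contig_lengths(path: str) -> dict[str, int]:
    """Chromosome lengths from the VCF ##contig header lines."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    return {name: int(length) for name, length in zip(vcf.seqnames, vcf.seqlens)}


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_FILTER_HEADER = {
    LOW_DP: "Total depth below 10",
    LOW_QUAL: "Site quality below 50",
    LOW_QD: "Quality by depth below 1.5",
    HIGH_SB: "Strand bias above -0.1",
    HIGH_MQ0: "MQ0 >= 4 and MQ0/DP > 0.1",
    SNP_CLUSTER: "Member of a dense SNV cluster",
}


def _fmt_num(x: float) -> str:
    """Render a number without trailing float noise (ints stay ints)."""
    if x == int(x):
        return str(int(x))
    return f"{x:g}"


def write_vcf(
    sites: Sequence[SiteRecord],
    matrix: GenotypeMatrix,
    path: str,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write sites + genotypes as VCFv4.2 text, sorted by (chrom, pos).

    FILTER is ``PASS`` or the semicolon-joined failed-criterion labels; INFO
    carries DP/QD/MQ0/SB plus AC/AN and the optional annotation keys FC
    (functional class) and IMP (coding impact); FORMAT is GT:DP (GT only when
    the matrix has no depths).
    """
    if len(sites) != matrix.n_sites:
        raise ValueError(f"{len(sites)} sites but {matrix.n_sites} genotype rows")
    ordered, m = sort_sites(sites, matrix)
    assert m is not None

    lines = ["##fileformat=VCFv4.2"]
    contigs: dict[str, int] = {}
    if chrom_lengths:
        contigs.update(chrom_lengths)
    for s in ordered:
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos)
    for chrom in sorted(contigs, key=chrom_sort_key):
        lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    for label in FILTER_LABELS:
        lines.append(f'##FILTER=<ID={label},Description="{_FILTER_HEADER[label]}">')
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with mapping quality zero">',
        '##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias">',
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="ALT allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">',
        '##INFO=<ID=FC,Number=1,Type=String,Description="Functional region class">',
        '##INFO=<ID=IMP,Number=1,Type=String,Description="Coding impact class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(m.sample_ids))

    has_dp = m.depth is not None
    fmt = "GT:DP" if has_dp else "GT"
    if m.ploidy == 2:
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    else:
        gt_str = {0: "0", 1: "1", MISSING: "."}

    out = []
    for i, s in enumerate(ordered):
        valid = m.gt[i] != MISSING
        ac = int(m.gt[i][valid].sum())
        an = int(m.ploidy * valid.sum())
        info = []
        if s.info_dp is not None:
            info.append(f"DP={_fmt_num(s.info_dp)}")
        if s.info_qd is not None:
            info.append(f"QD={_fmt_num(s.info_qd)}")
        if s.info_mq0 is not None:
            info.append(f"MQ0={_fmt_num(s.info_mq0)}")
        if s.info_sb is not None:
            info.append(f"SB={_fmt_num(s.info_sb)}")
        info.append(f"AC={ac}")
        info.append(f"AN={an}")
        if s.ann_class is not None:
            info.append(f"FC={s.ann_class}")
        if s.ann_impact is not None:
            info.append(f"IMP={s.ann_impact}")
        qual = "." if s.qual is None else _fmt_num(s.qual)
        filt = "PASS" if not s.filters else ";".join(sorted(s.filters))
        if has_dp:
            calls = [f"{gt_str[int(g)]}:{int(d)}" for g, d in zip(m.gt[i], m.depth[i])]
        else:
            calls = [gt_str[int(g)] for g in m.gt[i]]
        out.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{qual}\t{filt}\t"
            + ";".join(info) + f"\t{fmt}\t" + "\t".join(calls)
        )

    with open(path, "w") as fh:
        fh.write("\n".join(lines + out) + "\n")


# ---------------------------------------------------------------------------
# Hard filters
# ---------------------------------------------------------------------------

def apply_filters(
    sites: Sequence[SiteRecord], window: int = 10, cluster_size: int = 3
) -> list[SiteRecord]:
    """Label each site with the hard-filter criteria it fails.

    Criteria (failure conditions, evaluated independently; all comparisons
    strict where written strict): DP < 10, QUAL < 50, QD < 1.5, SB > -0.1,
    MQ0 >= 4 and MQ0/DP > 0.1, and membership in a cluster of >= cluster_size
    SNVs within any inclusive ``window``-bp span on one chromosome.  A site
    with an absent metric skips that criterion (logged once per call).
    Re-application is idempotent.
    """
    missing_logged: set[str] = set()

    def note_missing(name: str) -> None:
        if name not in missing_logged:
            missing_logged.add(name)
            logger.info("apply_filters: metric %s absent on some sites; criterion skipped there", name)

    for s in sites:
        if s.info_dp is None:
            note_missing("DP")
        elif s.info_dp < 10:
            s.filters.add(LOW_DP)
        if s.qual is None:
            note_missing("QUAL")
        elif s.qual < 50:
            s.filters.add(LOW_QUAL)
        if s.info_qd is None:
            note_missing("QD")
        elif s.info_qd < 1.5:
            s.filters.add(LOW_QD)
        if s.info_sb is None:
            note_missing("SB")
        elif s.info_sb > -0.1:
            s.filters.add(HIGH_SB)
        if s.info_mq0 is None or s.info_dp is None:
            note_missing("MQ0/DP")
        elif s.info_mq0 >= 4 and s.info_mq0 / (1.0 * s.info_dp) > 0.1:
            s.filters.add(HIGH_MQ0)

    # snpCluster: sites i..i+c-1 all fail when they fit in an inclusive
    # window-bp span, i.e. pos[i+c-1] - pos[i] <= window - 1.
    by_chrom: dict[str, list[SiteRecord]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for group in by_chrom.values():
        group.sort(key=lambda s: s.pos)
        pos = [s.pos for s in group]
        for i in range(len(pos) - cluster_size + 1):
            j = i + cluster_size - 1
            if pos[j] - pos[i] <= window - 1:
                for k in range(i, j + 1):
                    group[k].filters.add(SNP_CLUSTER)
    return list(sites)


def pass_sites(sites: Iterable[SiteRecord]) -> list[SiteRecord]:
    """Sites whose FILTER set is empty, input order preserved."""
    return [s for s in sites if not s.filters]


def filter_summary(sites: Sequence[SiteRecord]) -> dict[str, int]:
    """Per-criterion failure counts plus pass/fail totals."""
    out = {label: 0 for label in FILTER_LABELS}
    n_pass = 0
    for s in sites:
        if not s.filters:
            n_pass += 1
        for label in s.filters:
            out[label] = out.get(label, 0) + 1
    out["n_sites"] = len(sites)
    out["n_pass"] = n_pass
    out["n_fail"] = len(sites) - n_pass
    return out
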