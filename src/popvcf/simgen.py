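"""Synthetic population call-set generator with a ground-truth ledger.

Emulates the genotype-level signatures a population SNV survey must handle:

* segregating sites whose ALT-allele count follows a configurable site
  frequency spectrum (neutral 1/i by default, optional singleton enrichment),
  with the drawn count placed **exactly** on the 2N haplotypes by uniform
  permutation, so spectrum tests are free of sampling noise;
* reference-private sites (all samples ALT-homozygous — the reference
  individual carried a unique allele);
* collapsed-duplication artifact regions: dense runs of all-heterozygous
  MAF=0.5 pseudo-sites at roughly twice the baseline read depth;
* per-site QUAL/INFO metrics spanning pass and fail of each hard-filter
  criterion at a configurable rate;
* haploid mitochondrial haplotypes structured by founder mare, with Poisson
  private mutations and injected pedigree errors.

Randomness uses one master seed split into per-chromosome substreams
(``SeedSequence(seed, spawn_key=(crc32(label),))``), so each chromosome's
output is reproducible on its own.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import chrom_sort_key
from .sitestats import Annotation
from .vcfio import GenotypeMatrix, SiteRecord, sort_sites

MITO_GENOME_BP = 16_660  # horse reference mitochondrial genome length
MITO_CHROM = "MT"

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

IMPACTS = ("synonymous", "non_synonymous", "start_gained", "start_lost", "stop_gained", "stop_lost")
IMPACT_PROBS = (0.45, 0.45, 0.025, 0.025, 0.025, 0.025)

#: birth-year cohort sizes of the 101-horse study panel (sums to 101)
BIRTH_YEAR_COHORTS = {
    1985: 1, 1990: 1, 1993: 1, 1994: 1, 1996: 1, 1998: 1, 1999: 3, 2000: 1,
    2001: 1, 2002: 1, 2007: 5, 2008: 2, 2010: 2, 2011: 1, 2012: 4, 2013: 18,
    2014: 20, 2015: 21, 2016: 16,
}
N_MALES_101 = 58  # study panel: 58 males, 43 females

# gene-model layout (bp), tiled every SimParams.gene_spacing_bp
GENE_FIRST_START = 50_001
FLANK_BP = 5_000
GENE_SEGMENTS = (  # (class, length); total 10,000 bp
    ("utr5", 200),
    ("exon", 400),
    ("intron", 3_000),
    ("exon", 400),
    ("intron", 3_000),
    ("exon", 2_700),
    ("utr3", 300),
)
GENE_LENGTH = sum(length for _, length in GENE_SEGMENTS)


def _default_chrom_lengths() -> dict[str, int]:
    # a small multi-chromosome genome: three autosomes (one carrying a
    # chromosome-start duplication, like the ECA29 pericentromere) plus X
    return {"1": 6_000_000, "2": 5_000_000, "29": 4_000_000, "X": 3_000_000}


def _default_dup_regions() -> list[tuple[str, int, int, float]]:
    return [("29", 1, 250_000, 6.0)]


@dataclass
class SimParams:
    """Parameters of the synthetic population; defaults mirror the study panel
    (101 diploid samples, one SNV per ~198 bp, transitions:transversions 2:1,
    ~37x coverage) on a desk-scale genome."""

    n_samples: int = 101
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    snv_rate: float = 1.0 / 198.0
    sfs_shape: np.ndarray | None = None  # weights over ALT count 1..2N-1; None -> 1/i
    singleton_boost: float = 1.0
    n_ref_private: int = 30
    dup_regions: list[tuple[str, int, int, float]] = field(default_factory=_default_dup_regions)
    ts_tv_ratio: float = 2.0
    coverage_mean: float = 36.8
    fail_fraction: float = 0.02
    gene_spacing_bp: int = 100_000
    n_founders: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.snv_rate <= 0 or self.coverage_mean <= 0 or self.ts_tv_ratio <= 0:
            raise ValueError("rates must be > 0")
        if not 0 <= self.fail_fraction < 1:
            raise ValueError("fail_fraction must be in [0, 1)")
        if self.singleton_boost <= 0:
            raise ValueError("singleton_boost must be > 0")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, mult in self.dup_regions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"dup region on unknown chromosome {chrom}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValueError(f"dup region {chrom}:{start}-{end} out of bounds")
            if mult <= 0:
                raise ValueError("site_rate_multiplier must be > 0")
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError("dup regions overlap")

    def sfs_weights(self) -> np.ndarray:
        """Normalized ALT-count weights over k = 1..2N-1."""
        two_n = 2 * self.n_samples
        if self.sfs_shape is not None:
            w = np.asarray(self.sfs_shape, dtype=float).copy()
            if w.shape != (two_n - 1,):
                raise ValueError(f"sfs_shape must have length {two_n - 1}")
        else:
            w = 1.0 / np.arange(1, two_n, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("sfs weights must be non-negative with positive sum")
        w[0] *= self.singleton_boost
        return w / w.sum()


@dataclass
class TruthLedger:
    """Simulator ground truth used by recovery tests."""

    site_class: dict[tuple[str, int], str] = field(default_factory=dict)
    site_ac: dict[tuple[str, int], int] = field(default_factory=dict)  # drawn ALT count
    singleton_carrier: dict[tuple[str, int], str] = field(default_factory=dict)
    site_impact: dict[tuple[str, int], str] = field(default_factory=dict)
    dup_truth: list[tuple[str, int, int]] = field(default_factory=list)
    mito_lineage: dict[str, str] = field(default_factory=dict)
    mito_errors: list[str] = field(default_factory=list)
    mito_private: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "site_class": {f"{c}:{p}": v for (c, p), v in self.site_class.items()},
            "site_ac": {f"{c}:{p}": v for (c, p), v in self.site_ac.items()},
            "singleton_carrier": {f"{c}:{p}": v for (c, p), v in self.singleton_carrier.items()},
            "site_impact": {f"{c}:{p}": v for (c, p), v in self.site_impact.items()},
            "dup_truth": [list(t) for t in self.dup_truth],
            "mito_lineage": self.mito_lineage,
            "mito_errors": self.mito_errors,
            "mito_private": self.mito_private,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "TruthLedger":
        with open(path) as fh:
            d = json.load(fh)

        def unkey(m: dict) -> dict:
            out = {}
            for k, v in m.items():
                chrom, pos = k.rsplit(":", 1)
                out[(chrom, int(pos))] = v
            return out

        return cls(
            site_class=unkey(d["site_class"]),
            site_ac={k: int(v) for k, v in unkey(d["site_ac"]).items()},
            singleton_carrier=unkey(d["singleton_carrier"]),
            site_impact=unkey(d["site_impact"]),
            dup_truth=[(t[0], int(t[1]), int(t[2])) for t in d["dup_truth"]],
            mito_lineage=d["mito_lineage"],
            mito_errors=list(d["mito_errors"]),
            mito_private={k: [int(x) for x in v] for k, v in d["mito_private"].items()},
        )

    def merge(self, other: "TruthLedger") -> "TruthLedger":
        return TruthLedger(
            site_class={**self.site_class, **other.site_class},
            site_ac={**self.site_ac, **other.site_ac},
            singleton_carrier={**self.singleton_carrier, **other.singleton_carrier},
            site_impact={**self.site_impact, **other.site_impact},
            dup_truth=self.dup_truth + other.dup_truth,
            mito_lineage={**self.mito_lineage, **other.mito_lineage},
            mito_errors=self.mito_errors + other.mito_errors,
            mito_private={**self.mito_private, **other.mito_private},
        )


@dataclass
class SampleMeta:
    sample_id: str
    sex: str  # "M" | "F"
    birth_year: int
    founder: str


def metadata_frame(meta: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": m.sample_id, "sex": m.sex, "birth_year": m.birth_year, "founder": m.founder}
         for m in meta]
    )


def write_metadata_tsv(meta: list[SampleMeta], path: str) -> None:
    metadata_frame(meta).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "founder": str})
    required = {"sample_id", "sex", "birth_year", "founder"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# PRNG plumbing
# ---------------------------------------------------------------------------

def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    key = zlib.crc32(label.encode())
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(key,))))


def _unique_positions(
    rng: np.random.Generator, low: int, high: int, k: int, exclude: set[int] | None = None
) -> np.ndarray:
    """k distinct integers in [low, high], excluding a given set; sorted."""
    exclude = exclude or set()
    available = high - low + 1 - len(exclude)
    if k > available:
        raise ValueError(
            f"chromosome overflow: need {k} positions in [{low},{high}] with "
            f"{len(exclude)} excluded, only {available} available"
        )
    chosen: set[int] = set()
    while len(chosen) < k:
        batch = rng.integers(low, high + 1, size=max(64, int((k - len(chosen)) * 1.3)))
        for p in batch:
            p = int(p)
            if p not in exclude and p not in chosen:
                chosen.add(p)
                if len(chosen) == k:
                    break
    return np.array(sorted(chosen), dtype=np.int64)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def sample_metadata(params: SimParams) -> list[SampleMeta]:
    """Deterministic panel metadata: sex, birth year, founder-mare label.

    For the default panel size the birth-year cohorts and the 58:43 sex split
    of the study panel are reproduced exactly; other sizes draw from the same
    distributions.  Every founder label is used at least once when the panel
    is large enough.
    """
    rng = _substream(params.seed, "meta")
    n = params.n_samples
    ids = [f"S{i + 1:03d}" for i in range(n)]

    years = [y for y, c in sorted(BIRTH_YEAR_COHORTS.items()) for _ in range(c)]
    if n == len(years):
        pool = np.array(years)
    else:
        probs = np.array([c for _, c in sorted(BIRTH_YEAR_COHORTS.items())], dtype=float)
        probs /= probs.sum()
        pool = rng.choice(sorted(BIRTH_YEAR_COHORTS), size=n, p=probs)
    rng.shuffle(pool)

    n_males = round(n * N_MALES_101 / 101)
    sexes = np.array(["M"] * n_males + ["F"] * (n - n_males))
    rng.shuffle(sexes)

    founders = [f"F{(i % params.n_founders) + 1:02d}" for i in range(n)]
    rng.shuffle(founders)

    return [
        SampleMeta(sample_id=ids[i], sex=str(sexes[i]), birth_year=int(pool[i]), founder=founders[i])
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(params: SimParams) -> Annotation:
    """Tile non-overlapping gene models on each chromosome.

    Each gene contributes 5'-UTR, exon and intron segments plus 5 kb
    upstream/downstream flanks (all genes on the plus strand); residual space
    is emitted as explicit intergenic intervals, so the classes partition each
    chromosome.
    """
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for chrom in sorted(params.chrom_lengths, key=chrom_sort_key):
        length = params.chrom_lengths[chrom]
        ivs: list[tuple[int, int, str]] = []
        covered: list[tuple[int, int]] = []
        start = GENE_FIRST_START
        while start + GENE_LENGTH - 1 + FLANK_BP <= length and start - FLANK_BP >= 1:
            ivs.append((start - FLANK_BP, start - 1, "upstream"))
            pos = start
            for cls, seg_len in GENE_SEGMENTS:
                ivs.append((pos, pos + seg_len - 1, cls))
                pos += seg_len
            ivs.append((pos, pos + FLANK_BP - 1, "downstream"))
            covered.append((start - FLANK_BP, pos + FLANK_BP - 1))
            start += params.gene_spacing_bp
        # residual space -> intergenic
        cursor = 1
        for s, e in covered:
            if cursor < s:
                ivs.append((cursor, s - 1, "intergenic"))
            cursor = e + 1
        if cursor <= length:
            ivs.append((cursor, length, "intergenic"))
        intervals[chrom] = sorted(ivs)
    return Annotation(intervals=intervals)


# ---------------------------------------------------------------------------
# Nuclear population simulation
# ---------------------------------------------------------------------------

def _draw_alleles(rng: np.random.Generator, n: int, ts_tv_ratio: float) -> tuple[list[str], list[str]]:
    refs = rng.choice(list("ACGT"), size=n)
    is_ts = rng.random(n) < ts_tv_ratio / (ts_tv_ratio + 1.0)
    tv_pick = rng.integers(0, 2, size=n)
    ref_list, alt_list = [], []
    for i in range(n):
        r = str(refs[i])
        a = TRANSITION[r] if is_ts[i] else TRANSVERSIONS[r][tv_pick[i]]
        ref_list.append(r)
        alt_list.append(a)
    return ref_list, alt_list


def _site_metrics(
    rng: np.random.Generator,
    depth_sum: np.ndarray,
    fail_mask_allowed: np.ndarray,
    fail_fraction: float,
) -> dict[str, np.ndarray]:
    """QUAL/INFO per site; where allowed, each criterion fails at fail_fraction."""
    n = depth_sum.size
    dp = depth_sum.astype(np.int64).copy()
    qual = np.round(rng.uniform(60.0, 2000.0, size=n), 2)
    qd = np.round(rng.uniform(2.0, 35.0, size=n), 2)
    sb = np.round(rng.uniform(-3.0, -0.2, size=n), 2)
    mq0 = rng.integers(0, 4, size=n).astype(np.int64)

    def fail_draw() -> np.ndarray:
        return fail_mask_allowed & (rng.random(n) < fail_fraction)

    m = fail_draw()
    dp[m] = rng.integers(1, 10, size=int(m.sum()))
    m = fail_draw()
    qual[m] = np.round(rng.uniform(0.0, 49.4, size=int(m.sum())), 2)
    m = fail_draw()
    qd[m] = np.round(rng.uniform(0.0, 1.45, size=int(m.sum())), 2)
    m = fail_draw()
    sb[m] = np.round(rng.uniform(-0.05, 1.0, size=int(m.sum())), 2)
    m = fail_draw()
    mq0[m] = np.maximum(4, dp[m] // 10 + 1)
    return {"dp": dp, "qual": qual, "qd": qd, "sb": sb, "mq0": mq0}


def _allocate_counts(total: int, lengths: dict[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of a total across chromosomes."""
    chroms = sorted(lengths, key=chrom_sort_key)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    exact = total * weights / weights.sum()
    base = np.floor(exact).astype(int)
    rest = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rest]:
        base[i] += 1
    return dict(zip(chroms, base.tolist()))


def simulate_population(
    params: SimParams,
) -> tuple[list[SiteRecord], GenotypeMatrix, list[SampleMeta], TruthLedger]:
    """Generate the nuclear call set, metadata, and truth ledger.

    Per segregating site the drawn ALT count is realized exactly on the 2N
    haplotypes; reference-private sites are all-ALT-homozygous; duplication-
    artifact sites are all-heterozygous at ~2x depth inside the planted
    intervals.  Deterministic per chromosome under a fixed seed.
    """
    params.validate()
    meta = sample_metadata(params)
    annotation = generate_annotation(params)
    n = params.n_samples
    two_n = 2 * n
    weights = params.sfs_weights()
    ref_priv_alloc = _allocate_counts(params.n_ref_private, params.chrom_lengths)

    all_sites: list[SiteRecord] = []
    gt_blocks: list[np.ndarray] = []
    depth_blocks: list[np.ndarray] = []
    ledger = TruthLedger(dup_truth=[(c, s, e) for c, s, e, _ in params.dup_regions])
    sample_ids = [m.sample_id for m in meta]

    for chrom in sorted(params.chrom_lengths, key=chrom_sort_key):
        length = params.chrom_lengths[chrom]
        rng = _substream(params.seed, f"chrom:{chrom}")

        n_seg = int(rng.poisson(params.snv_rate * length))
        n_priv = ref_priv_alloc.get(chrom, 0)
        regions = [(s, e, m) for c, s, e, m in params.dup_regions if c == chrom]
        n_dup_per_region = [int(rng.poisson(params.snv_rate * m * (e - s + 1))) for s, e, m in regions]

        seg_priv_pos = _unique_positions(rng, 1, length, n_seg + n_priv)
        perm = rng.permutation(n_seg + n_priv)
        seg_pos = np.sort(seg_priv_pos[perm[:n_seg]])
        priv_pos = np.sort(seg_priv_pos[perm[n_seg:]])
        used = set(seg_priv_pos.tolist())
        dup_pos_list = []
        for (s, e, _m), n_dup in zip(regions, n_dup_per_region):
            p = _unique_positions(rng, s, e, n_dup, exclude=used)
            used.update(p.tolist())
            dup_pos_list.append(p)
        dup_pos = np.concatenate(dup_pos_list) if dup_pos_list else np.array([], dtype=np.int64)

        # genotypes: exact placement of the drawn ALT count on 2N haplotypes
        n_total = n_seg + n_priv + dup_pos.size
        gt = np.empty((n_total, n), dtype=np.int8)
        ks = rng.choice(np.arange(1, two_n), size=n_seg, p=weights) if n_seg else np.array([], dtype=int)
        carriers: dict[int, str] = {}
        for i in range(n_seg):
            hap_idx = rng.choice(two_n, size=int(ks[i]), replace=False)
            gt[i] = np.bincount(hap_idx // 2, minlength=n)
            if ks[i] == 1:
                carriers[i] = sample_ids[int(hap_idx[0]) // 2]
        gt[n_seg:n_seg + n_priv] = 2
        gt[n_seg + n_priv:] = 1

        depth = rng.poisson(params.coverage_mean, size=(n_total, n)).astype(np.int32)
        if dup_pos.size:
            depth[n_seg + n_priv:] = rng.poisson(2.0 * params.coverage_mean, size=(dup_pos.size, n))

        pos = np.concatenate([seg_pos, priv_pos, dup_pos])
        classes = (["segregating"] * n_seg + ["ref_private"] * n_priv + ["dup_artifact"] * int(dup_pos.size))
        refs, alts = _draw_alleles(rng, n_total, params.ts_tv_ratio)
        fail_allowed = np.array([c == "segregating" for c in classes])
        metrics = _site_metrics(rng, depth.sum(axis=1), fail_allowed, params.fail_fraction)

        exonic = annotation.contains(chrom, pos, "exon")
        impacts = rng.choice(IMPACTS, size=n_total, p=IMPACT_PROBS)

        for i in range(n_total):
            p = int(pos[i])
            imp = str(impacts[i]) if exonic[i] else None
            all_sites.append(
                SiteRecord(
                    chrom=chrom, pos=p, ref=refs[i], alt=alts[i],
                    qual=float(metrics["qual"][i]),
                    info_dp=float(metrics["dp"][i]),
                    info_qd=float(metrics["qd"][i]),
                    info_mq0=float(metrics["mq0"][i]),
                    info_sb=float(metrics["sb"][i]),
                    ann_impact=imp,
                )
            )
            ledger.site_class[(chrom, p)] = classes[i]
            if classes[i] == "segregating":
                ledger.site_ac[(chrom, p)] = int(ks[i])
            elif classes[i] == "ref_private":
                ledger.site_ac[(chrom, p)] = two_n
            else:
                ledger.site_ac[(chrom, p)] = n
            if imp is not None:
                ledger.site_impact[(chrom, p)] = imp
            if i in carriers:
                ledger.singleton_carrier[(chrom, p)] = carriers[i]
        gt_blocks.append(gt)
        depth_blocks.append(depth)

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        gt=np.vstack(gt_blocks) if gt_blocks else np.empty((0, n), dtype=np.int8),
        depth=np.vstack(depth_blocks) if depth_blocks else None,
        ploidy=2,
    )
    sites, matrix = sort_sites(all_sites, matrix)
    assert matrix is not None
    return sites, matrix, meta, ledger


# ---------------------------------------------------------------------------
# Mitochondrial simulation
# ---------------------------------------------------------------------------

def simulate_mito(
    params: SimParams,
    n_founders: int | None = None,
    n_mito_sites: int = 335,
    error_rate: float = 0.03,
    private_rate: float = 0.3,
) -> tuple[list[SiteRecord], GenotypeMatrix, TruthLedger]:
    """Generate haploid mitochondrial haplotypes grouped by founder mare.

    Each sample inherits its founder's haplotype plus Poisson(``private_rate``)
    private mutations; a fraction ``error_rate`` of samples get a haplotype
    from a *different* founder while keeping their recorded label (injected
    pedigree errors, listed in the ledger).  With the default ``n_founders``
    the lineage labels match :func:`sample_metadata` exactly.
    """
    params.validate()
    if n_mito_sites > MITO_GENOME_BP:
        raise ValueError(f"n_mito_sites exceeds the {MITO_GENOME_BP} bp mitochondrial genome")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    nf = params.n_founders if n_founders is None else n_founders
    if nf < 1:
        raise ValueError("n_founders must be >= 1")

    rng = _substream(params.seed, "mito")
    n = params.n_samples
    founder_labels = [f"F{i + 1:02d}" for i in range(nf)]

    if n_founders is None or n_founders == params.n_founders:
        lineage = {m.sample_id: m.founder for m in sample_metadata(params)}
    else:
        assigned = [founder_labels[i % nf] for i in range(n)]
        rng.shuffle(assigned)
        lineage = {f"S{i + 1:03d}": assigned[i] for i in range(n)}
    sample_ids = sorted(lineage, key=lambda s: int(s.lstrip("S")))

    positions = _unique_positions(rng, 1, MITO_GENOME_BP, n_mito_sites)

    # founder haplotypes: distinct, with a minimum pairwise divergence
    min_div = max(1, n_mito_sites // 10)
    founders = np.zeros((nf, n_mito_sites), dtype=np.int8)
    for i in range(nf):
        for _attempt in range(1000):
            hap = (rng.random(n_mito_sites) < 0.35).astype(np.int8)
            if all(int(np.count_nonzero(hap != founders[j])) >= min_div for j in range(i)):
                founders[i] = hap
                break
        else:
            raise RuntimeError("could not draw sufficiently distinct founder haplotypes")

    founder_of = {lab: i for i, lab in enumerate(founder_labels)}
    n_err = int(round(error_rate * n)) if nf > 1 else 0
    err_samples = set(
        rng.choice(sample_ids, size=n_err, replace=False).tolist() if n_err else []
    )

    gt = np.zeros((n_mito_sites, n), dtype=np.int8)
    ledger = TruthLedger(mito_lineage=dict(lineage))
    for j, sid in enumerate(sample_ids):
        labeled = lineage[sid]
        if labeled not in founder_of:
            raise ValueError(f"sample {sid} has founder label {labeled!r} outside the simulated set")
        true_founder = founder_of[labeled]
        if sid in err_samples:
            others = [i for i in range(nf) if i != true_founder]
            true_founder = int(rng.choice(others))
            ledger.mito_errors.append(sid)
        hap = founders[true_founder].copy()
        n_mut = int(rng.poisson(private_rate))
        n_mut = min(n_mut, n_mito_sites)
        if n_mut:
            flip = rng.choice(n_mito_sites, size=n_mut, replace=False)
            hap[flip] ^= 1
            ledger.mito_private[sid] = sorted(int(positions[f]) for f in flip)
        gt[:, j] = hap

    refs, alts = _draw_alleles(rng, n_mito_sites, params.ts_tv_ratio)
    depth = rng.poisson(params.coverage_mean, size=(n_mito_sites, n)).astype(np.int32)
    qual = np.round(rng.uniform(60.0, 2000.0, size=n_mito_sites), 2)
    sites = [
        SiteRecord(
            chrom=MITO_CHROM, pos=int(positions[i]), ref=refs[i], alt=alts[i],
            qual=float(qual[i]), info_dp=float(depth[i].sum()),
        )
        for i in range(n_mito_sites)
    ]
    matrix = GenotypeMatrix(sample_ids=sample_ids, gt=gt, depth=depth, ploidy=1)
    return sites, matrix, ledger
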