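"""Allele counts, site-frequency spectrum, singletons, and frequency lookup.

The SFS is the histogram of per-site ALT-allele counts k over the 2N sampled
alleles (202 for a 101-horse diploid panel).  A singleton (rare variant) is a
site with exactly one ALT allele in the panel; its carrier is the unique
heterozygous sample.  Sites where every sample is ALT-homozygous (k = 2N) mark
alleles private to the reference individual rather than the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import is_autosome, round_half_up
from .vcfio import MISSING, GenotypeMatrix, SiteRecord


def allele_counts(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ac, an): ALT-allele count and total called alleles.

    Missing genotypes reduce ``an`` by the ploidy and contribute nothing
    to ``ac``.
    """
    valid = matrix.gt != MISSING
    ac = np.where(valid, matrix.gt, 0).sum(axis=1).astype(np.int64)
    an = (matrix.ploidy * valid.sum(axis=1)).astype(np.int64)
    return ac, an


def alt_freq(ac: int, an: int) -> float:
    """ALT-allele frequency ac/an, rounded half-up to 4 decimals."""
    if an <= 0:
        raise ValueError("an must be positive")
    if not 0 <= ac <= an:
        raise ValueError("need 0 <= ac <= an")
    return round_half_up(ac / an, 4)


@dataclass
class SfsTable:
    """Site-frequency spectrum: number of sites per ALT-allele count k.

    ``counts[k]`` for k = 0..an_max; the k = an_max bin holds all-ALT-
    homozygous (reference-private) sites.  ``to_frame`` also reports the
    REF-allele orientation (an_max - k) used when plotting the spectrum
    with the REF count on the axis.
    """

    an_max: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.an_max + 1,):
            raise ValueError("counts must have length an_max + 1")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def n_singletons(self) -> int:
        return int(self.counts[1]) if self.an_max >= 1 else 0

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(self.an_max + 1)
        return pd.DataFrame(
            {"alt_count": k, "ref_count": self.an_max - k, "n_sites": self.counts}
        )


def sfs(matrix: GenotypeMatrix) -> SfsTable:
    """Histogram of ALT-allele counts over all sites."""
    an_max = matrix.ploidy * matrix.n_samples
    ac, _ = allele_counts(matrix)
    counts = np.bincount(ac, minlength=an_max + 1)
    return SfsTable(an_max=an_max, counts=counts)


@dataclass
class RareReport:
    """Singleton (one-ALT-allele) sites and their per-sample attribution."""

    site_index: np.ndarray  # row indices of singleton sites
    carriers: list[str]  # carrier sample id per singleton site
    per_sample: pd.Series  # sample id -> singleton count (all samples)
    n_singletons: int
    n_sites_denominator: int
    fraction_pct: float  # 100 * n_singletons / denominator, 1 decimal


def singletons(
    matrix: GenotypeMatrix,
    sites: list[SiteRecord],
    autosomes_only: bool = True,
) -> RareReport:
    """Identify singleton sites and attribute each to its carrier sample.

    A singleton has ac = 1; its carrier is the unique sample with dosage 1.
    The reported fraction uses autosomal sites as denominator by default
    (the convention of an autosome-restricted spectrum); set
    ``autosomes_only=False`` to use all sites.
    """
    if len(sites) != matrix.n_sites:
        raise ValueError("sites and matrix length mismatch")
    ac, _ = allele_counts(matrix)
    idx = np.flatnonzero(ac == 1)
    carriers: list[str] = []
    tally = dict.fromkeys(matrix.sample_ids, 0)
    for i in idx:
        het = np.flatnonzero(matrix.gt[i] == 1)
        if het.size != 1:
            s = sites[i]
            raise ValueError(
                f"inconsistent singleton at {s.chrom}:{s.pos}: ac=1 but no unique heterozygote"
            )
        sid = matrix.sample_ids[int(het[0])]
        carriers.append(sid)
        tally[sid] += 1

    if autosomes_only:
        denom_mask = np.array([is_autosome(s.chrom) for s in sites], dtype=bool)
        n_single = int(np.count_nonzero(denom_mask[idx]))
        denom = int(denom_mask.sum())
    else:
        n_single = int(idx.size)
        denom = len(sites)
    fraction = round_half_up(100.0 * n_single / denom, 1) if denom else 0.0
    return RareReport(
        site_index=idx,
        carriers=carriers,
        per_sample=pd.Series(tally, name="singleton_count"),
        n_singletons=n_single,
        n_sites_denominator=denom,
        fraction_pct=fraction,
    )


def singleton_fraction(n_singletons: int, n_sites: int) -> float:
    """Percentage of sites that are singletons, to 1 decimal (half-up)."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return round_half_up(100.0 * n_singletons / n_sites, 1)


def rare_by_group(
    report: RareReport,
    meta: pd.DataFrame,
    group_key: str = "birth_year",
) -> pd.Series:
    """Mean per-sample singleton count within each metadata group.

    ``meta`` must be indexed by (or contain) ``sample_id`` and cover every
    sample in the report; groups are returned in ascending order.
    """
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = set(report.per_sample.index) - set(m.index)
    if missing:
        raise KeyError(f"samples without metadata: {sorted(missing)[:5]}")
    df = pd.DataFrame(
        {"count": report.per_sample, group_key: m.loc[report.per_sample.index, group_key]}
    )
    return df.groupby(group_key)["count"].mean().sort_index()


def ref_private_sites(
    matrix: GenotypeMatrix, sites: list[SiteRecord]
) -> list[SiteRecord]:
    """Sites where every sample is ALT-homozygous (ac = an, no missing).

    These flag alleles private to the reference individual: the panel is
    fixed for ALT because the reference genome carried a unique allele.
    """
    ac, an = allele_counts(matrix)
    full = matrix.ploidy * matrix.n_samples
    idx = np.flatnonzero((ac == an) & (an == full))
    return [sites[i] for i in idx]


def query_positions(
    sites: list[SiteRecord],
    matrix: GenotypeMatrix,
    targets: list[str],
) -> pd.DataFrame:
    """Look up ``chrom:pos`` targets in the call set.

    Returns one row per unique target (input order preserved): REF/ALT,
    ac/an, frequency, and FILTER status for found positions; absent targets
    are reported with ``found = False`` rather than raising.
    """
    ac, an = allele_counts(matrix)
    index = {s.key: i for i, s in enumerate(sites)}
    seen: set[tuple[str, int]] = set()
    rows = []
    for t in targets:
        try:
            chrom, pos_s = t.rsplit(":", 1)
            pos = int(pos_s)
        except ValueError as exc:
            raise ValueError(f"malformed position {t!r}; expected chrom:pos") from exc
        key = (chrom, pos)
        if key in seen:
            continue
        seen.add(key)
        i = index.get(key)
        if i is None:
            rows.append(
                {"chrom": chrom, "pos": pos, "found": False, "ref": None, "alt": None,
                 "ac": None, "an": None, "freq": None, "filter": None}
            )
        else:
            s = sites[i]
            rows.append(
                {"chrom": chrom, "pos": pos, "found": True, "ref": s.ref, "alt": s.alt,
                 "ac": int(ac[i]), "an": int(an[i]),
                 "freq": alt_freq(int(ac[i]), int(an[i])) if an[i] else None,
                 "filter": "PASS" if not s.filters else ";".join(sorted(s.filters))}
            )
    return pd.DataFrame(rows)
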