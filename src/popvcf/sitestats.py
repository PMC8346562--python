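"""Substitution spectra, SNV spacing, functional-region assignment and density.

Substitution classes are strand-symmetric: an ordered REF>ALT pair and its
reverse complement fall in the same class, giving six classes; a four-way
rollup merges the two transition classes into one and the two A:C-type
transversion classes into one, leaving A:T and G:C transversions separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import chrom_sort_key, round_half_up_int
from .vcfio import SiteRecord, VALID_BASES

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# canonical representative has REF in {A, C}
CLASS6 = ("A>C/T>G", "A>G/T>C", "A>T/T>A", "C>A/G>T", "C>G/G>C", "C>T/G>A")
CLASS4 = ("transition", "A:T", "A:C", "G:C")

_CLASS4_OF6 = {
    "A>G/T>C": "transition",
    "C>T/G>A": "transition",
    "A>T/T>A": "A:T",
    "A>C/T>G": "A:C",
    "C>A/G>T": "A:C",
    "C>G/G>C": "G:C",
}

FUNCTIONAL_CLASSES = ("exon", "utr5", "utr3", "intron", "upstream", "downstream", "intergenic")
#: assignment precedence, highest first; anything unannotated is intergenic
PRECEDENCE = ("exon", "utr5", "utr3", "intron", "upstream", "downstream")


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Strand-symmetric substitution class of a REF>ALT pair.

    Returns ``(class6, class4)``, e.g. ``("A>G/T>C", "transition")``.
    """
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("REF equals ALT is not a substitution")
    if ref not in ("A", "C"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    class6 = f"{ref}>{alt}/{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
    return class6, _CLASS4_OF6[class6]


@dataclass
class SpectrumTable:
    """Per-chromosome substitution-class counts at both resolutions."""

    six: pd.DataFrame  # chrom x CLASS6 counts
    four: pd.DataFrame  # chrom x CLASS4 counts

    @property
    def totals6(self) -> pd.Series:
        return self.six.sum(axis=0)

    @property
    def totals4(self) -> pd.Series:
        return self.four.sum(axis=0)


def spectrum(sites: list[SiteRecord]) -> SpectrumTable:
    """Count substitution classes per chromosome."""
    rows = [(s.chrom, *classify_substitution(s.ref, s.alt)) for s in sites]
    chroms = sorted({r[0] for r in rows}, key=chrom_sort_key)
    six = pd.DataFrame(0, index=pd.Index(chroms, name="chrom"), columns=list(CLASS6), dtype=int)
    for chrom, c6, _ in rows:
        six.at[chrom, c6] += 1
    four = pd.DataFrame(0, index=six.index, columns=list(CLASS4), dtype=int)
    for c6, c4 in _CLASS4_OF6.items():
        four[c4] += six[c6]
    return SpectrumTable(six=six, four=four)


def mean_spacing(total_length_bp: float, n_snvs: int) -> int:
    """Average spacing in bp per SNV: round(total bp / number of SNVs)."""
    if n_snvs <= 0:
        raise ValueError("n_snvs must be positive")
    return round_half_up_int(total_length_bp / n_snvs)


# ---------------------------------------------------------------------------
# Functional-region annotation
# ---------------------------------------------------------------------------


@dataclass
class Annotation:
    """Labelled genomic intervals, stored 1-based inclusive per chromosome.

    ``intervals[chrom]`` is a list of ``(start, end, cls)``.  Intervals of the
    same class are merged on index construction, so overlapping same-class
    input is harmless; cross-class overlap is resolved by :data:`PRECEDENCE`
    at lookup time.
    """

    intervals: dict[str, list[tuple[int, int, str]]]
    _index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def _class_index(self, chrom: str, cls: str) -> tuple[np.ndarray, np.ndarray]:
        key = (chrom, cls)
        if key not in self._index:
            ivs = sorted((s, e) for s, e, c in self.intervals.get(chrom, []) if c == cls)
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self._index[key] = (starts, ends)
        return self._index[key]

    def contains(self, chrom: str, pos: np.ndarray, cls: str) -> np.ndarray:
        """Boolean membership of positions in intervals of one class."""
        starts, ends = self._class_index(chrom, cls)
        pos = np.asarray(pos, dtype=np.int64)
        if starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] <= ends[idx[ok]]
        return out

    def class_span(self, chrom: str, cls: str) -> int:
        """Total bases covered by one class on one chromosome (merged)."""
        starts, ends = self._class_index(chrom, cls)
        return int((ends - starts + 1).sum())

    @classmethod
    def from_bed(cls, path: str) -> "Annotation":
        """Read a BED file (0-based half-open, class label in column 4)."""
        intervals: dict[str, list[tuple[int, int, str]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: need 4 BED columns (chrom,start,end,class)")
                chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
                intervals.setdefault(chrom, []).append((start + 1, end, label))
        return cls(intervals=intervals)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals, key=chrom_sort_key):
                for start, end, label in sorted(self.intervals[chrom]):
                    fh.write(f"{chrom}\t{start - 1}\t{end}\t{label}\n")


def assign_classes(
    sites: list[SiteRecord],
    annotation: Annotation,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SiteRecord]:
    """Assign each site its functional class in place (and return the list).

    A site in several features gets the highest-precedence class
    (exon > 5'-UTR > 3'-UTR > intron > upstream > downstream); a site in no
    feature is intergenic.  With ``chrom_lengths`` given, a site beyond its
    chromosome end is an error.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        if chrom_lengths is not None:
            if s.chrom not in chrom_lengths:
                raise KeyError(f"no length for chromosome {s.chrom}")
            if s.pos > chrom_lengths[s.chrom]:
                raise ValueError(f"site {s.chrom}:{s.pos} beyond chromosome end {chrom_lengths[s.chrom]}")
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        pos = np.array([sites[i].pos for i in idx], dtype=np.int64)
        assigned = np.full(len(idx), len(PRECEDENCE), dtype=np.int8)  # sentinel = intergenic
        for rank, cls in enumerate(PRECEDENCE):
            hit = annotation.contains(chrom, pos, cls) & (assigned == len(PRECEDENCE))
            assigned[hit] = rank
        for j, i in enumerate(idx):
            sites[i].ann_class = (
                "intergenic" if assigned[j] == len(PRECEDENCE) else PRECEDENCE[assigned[j]]
            )
    return sites


def assign_functional_class(
    site: SiteRecord,
    annotation: Annotation,
    chrom_lengths: dict[str, int] | None = None,
) -> str:
    """Functional class of a single site (see :func:`assign_classes`)."""
    assign_classes([site], annotation, chrom_lengths)
    assert site.ann_class is not None
    return site.ann_class


def density_table(
    sites: list[SiteRecord],
    chrom_lengths: dict[str, int],
    annotation: Annotation | None = None,
) -> pd.DataFrame:
    """Per chromosome x functional class: count and density (sites per kb).

    Density scales the count by chromosome length: ``count * 1000 / length``.
    With ``annotation`` given, an extra ``density_feature`` column scales by
    the bases the class actually covers on that chromosome instead.
    """
    rows = []
    for s in sites:
        if s.ann_class is None:
            raise ValueError(f"site {s.chrom}:{s.pos} has no functional class; run assign_classes first")
        rows.append((s.chrom, s.ann_class))
    df = pd.DataFrame(rows, columns=["chrom", "cls"])
    chroms = sorted({s.chrom for s in sites} | set(chrom_lengths), key=chrom_sort_key)
    out = []
    counts = df.groupby(["chrom", "cls"]).size() if len(df) else pd.Series(dtype=int)
    for chrom in chroms:
        if chrom not in chrom_lengths:
            raise KeyError(f"missing chromosome length for {chrom}")
        length = chrom_lengths[chrom]
        for cls in FUNCTIONAL_CLASSES:
            n = int(counts.get((chrom, cls), 0))
            rec = {
                "chrom": chrom,
                "class": cls,
                "count": n,
                "length_bp": length,
                "density": n * 1000.0 / length,
            }
            if annotation is not None:
                if cls == "intergenic":
                    span = length - sum(
                        annotation.class_span(chrom, c) for c in PRECEDENCE
                    )
                    # precedence overlaps make this approximate only if classes
                    # overlap each other; the simulator's classes are disjoint
                    span = max(span, 0)
                else:
                    span = annotation.class_span(chrom, cls)
                rec["feature_bp"] = span
                rec["density_feature"] = (n * 1000.0 / span) if span else float("nan")
            out.append(rec)
    return pd.DataFrame(out)


def impact_summary(sites: list[SiteRecord]) -> pd.DataFrame:
    """Per-chromosome counts of coding impact classes.

    Only sites carrying an impact annotation (coding sites) are counted;
    columns cover synonymous/non-synonymous and the start/stop classes.
    """
    from .vcfio import IMPACT_CLASSES

    coding = [(s.chrom, s.ann_impact) for s in sites if s.ann_impact is not None]
    chroms = sorted({c for c, _ in coding}, key=chrom_sort_key)
    out = pd.DataFrame(0, index=pd.Index(chroms, name="chrom"), columns=list(IMPACT_CLASSES), dtype=int)
    for chrom, imp in coding:
        if imp not in IMPACT_CLASSES:
            imp = "other"
        out.at[chrom, imp] += 1
    return out
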