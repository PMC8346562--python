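"""Mitochondrial haplotypes, founder-line consensus, pedigree verification.

Mitochondria are maternally inherited, so every sample's haploid mitochondrial
haplotype should match the haplotype of the founder mare recorded in its
pedigree, up to a handful of private mutations accumulated over ~30
generations.  A sample whose Hamming distance to its own founder-line
consensus exceeds a small threshold most plausibly carries a pedigree
registration error (or a sample swap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix

VERDICT_CONSISTENT = "consistent"
VERDICT_DRIFT = "mutation_drift"
VERDICT_DISCREPANCY = "lineage_discrepancy"


@dataclass
class MitoHaplotype:
    """Haploid allele vector (0 = REF, 1 = ALT) over the mito variant sites."""

    sample_id: str
    alleles: np.ndarray
    founder: str

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)


def build_haplotypes(matrix: GenotypeMatrix, meta: pd.DataFrame) -> list[MitoHaplotype]:
    """One haplotype per sample from a haploid (or hom-coded diploid) matrix.

    Diploid-coded records are accepted only when every call is homozygous
    (0/0 -> REF, 1/1 -> ALT); a heterozygous mitochondrial call is an error
    naming the sample and site, since true heteroplasmy is outside the model.
    Missing calls are imputed to REF (logged via the verdict distance, not
    hidden: a run of missing calls inflates distance to consensus).
    """
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing_meta = set(matrix.sample_ids) - set(m.index)
    if missing_meta:
        raise KeyError(f"samples without founder metadata: {sorted(missing_meta)[:5]}")
    haps = []
    for j, sid in enumerate(matrix.sample_ids):
        col = matrix.gt[:, j].astype(np.int8)
        if matrix.ploidy == 2:
            het = np.flatnonzero(col == 1)
            if het.size:
                raise ValueError(
                    f"heterozygous mitochondrial genotype for sample {sid} at site row {int(het[0])}"
                )
            alleles = (col == 2).astype(np.int8)
        else:
            bad = np.flatnonzero(col > 1)
            if bad.size:
                raise ValueError(f"non-haploid dosage for sample {sid} at site row {int(bad[0])}")
            alleles = np.where(col == MISSING, 0, col).astype(np.int8)
        haps.append(MitoHaplotype(sample_id=sid, alleles=alleles, founder=str(m.loc[sid, "founder"])))
    return haps


def founder_consensus(
    haplotypes: list[MitoHaplotype],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per founder label: majority-vote allele vector and tie-site mask.

    Ties (equal REF/ALT votes within the group) resolve toward REF and are
    flagged in the returned boolean mask.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_founder: dict[str, list[np.ndarray]] = {}
    for h in haplotypes:
        by_founder.setdefault(h.founder, []).append(h.alleles)
    for founder, vecs in by_founder.items():
        stack = np.vstack(vecs)
        alt_votes = stack.sum(axis=0)
        n = stack.shape[0]
        consensus = (2 * alt_votes > n).astype(np.int8)  # tie (2*votes == n) -> REF
        ties = 2 * alt_votes == n
        out[founder] = (consensus, ties)
    return out


def flag_discrepancies(
    haplotypes: list[MitoHaplotype],
    consensus: dict[str, tuple[np.ndarray, np.ndarray]],
    max_private: int = 5,
) -> pd.DataFrame:
    """Distance of each sample to its own founder-line consensus, with verdict.

    Verdicts: ``consistent`` at distance 0; ``mutation_drift`` at
    1..max_private (natural private mutations); ``lineage_discrepancy``
    beyond — the haplotype belongs to a different maternal line than the
    pedigree records.
    """
    rows = []
    for h in haplotypes:
        if h.founder not in consensus:
            raise KeyError(f"sample {h.sample_id} has founder {h.founder!r} with no consensus")
        ref_vec, _ = consensus[h.founder]
        dist = int(np.count_nonzero(h.alleles != ref_vec))
        if dist == 0:
            verdict = VERDICT_CONSISTENT
        elif dist <= max_private:
            verdict = VERDICT_DRIFT
        else:
            verdict = VERDICT_DISCREPANCY
        rows.append(
            {"sample_id": h.sample_id, "founder": h.founder, "distance": dist, "verdict": verdict}
        )
    return pd.DataFrame(rows)
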