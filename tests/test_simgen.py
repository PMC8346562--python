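"""Simulator construction guarantees, determinism, and the truth ledger."""

import math

import numpy as np
import pytest

from popvcf import (
    SimParams,
    TruthLedger,
    generate_annotation,
    metadata_frame,
    sample_metadata,
    simulate_mito,
    simulate_population,
    write_vcf,
)
from popvcf.simgen import BIRTH_YEAR_COHORTS, FLANK_BP, GENE_FIRST_START, MITO_GENOME_BP


class TestSimulatePopulation:
    def test_ref_private_sites_all_alt_homozygous(self, tiny_sim):
        sites, matrix, _, ledger = tiny_sim
        priv = [i for i, s in enumerate(sites) if ledger.site_class[s.key] == "ref_private"]
        assert len(priv) == 4
        assert all((matrix.gt[i] == 2).all() for i in priv)

    def test_dup_sites_all_heterozygous_maf_half(self, tiny_sim):
        sites, matrix, _, ledger = tiny_sim
        dup = [i for i, s in enumerate(sites) if ledger.site_class[s.key] == "dup_artifact"]
        assert dup, "dup region should produce artifact sites"
        for i in dup:
            assert (matrix.gt[i] == 1).all()
            assert matrix.gt[i].sum() == matrix.n_samples  # ac = N -> MAF 0.5

    def test_dup_sites_inside_planted_interval(self, tiny_params, tiny_sim):
        sites, _, _, ledger = tiny_sim
        (chrom, start, end, _), = tiny_params.dup_regions
        for s in sites:
            if ledger.site_class[s.key] == "dup_artifact":
                assert s.chrom == chrom and start <= s.pos <= end

    def test_singleton_fraction_matches_neutral_weight(self, study_params, study_sim):
        """Observed singleton share of segregating sites ~ 1/(1*H_{2N-1})."""
        _, _, _, ledger = study_sim
        seg_ac = [ac for key, ac in ledger.site_ac.items()
                  if ledger.site_class[key] == "segregating"]
        n = len(seg_ac)
        w1 = study_params.sfs_weights()[0]
        # neutral 1/i weights: w1 = 1/H_{2N-1}
        h = sum(1.0 / i for i in range(1, 2 * study_params.n_samples))
        assert w1 == pytest.approx(1.0 / h)
        observed = sum(1 for k in seg_ac if k == 1) / n
        se = math.sqrt(w1 * (1 - w1) / n)
        assert abs(observed - w1) <= 3 * se

    def test_positions_unique_per_chromosome(self, tiny_sim):
        sites, _, _, _ = tiny_sim
        keys = [(s.chrom, s.pos) for s in sites]
        assert len(keys) == len(set(keys))

    def test_ledger_site_class_bijective_with_vcf(self, tiny_sim):
        sites, _, _, ledger = tiny_sim
        assert {s.key for s in sites} == set(ledger.site_class)
        assert len(sites) == len(ledger.site_class)

    def test_chromosome_overflow_raises(self):
        params = SimParams(n_samples=4, chrom_lengths={"1": 50}, snv_rate=3.0,
                           dup_regions=[], n_ref_private=0, seed=1)
        with pytest.raises(ValueError, match="overflow"):
            simulate_population(params)

    def test_deterministic_byte_identical(self, tiny_params, tmp_path):
        paths = []
        for tag in ("a", "b"):
            sites, matrix, _, ledger = simulate_population(tiny_params)
            vcf = tmp_path / f"{tag}.vcf"
            led = tmp_path / f"{tag}.json"
            write_vcf(sites, matrix, str(vcf), chrom_lengths=tiny_params.chrom_lengths)
            ledger.to_json(str(led))
            paths.append((vcf.read_bytes(), led.read_bytes()))
        assert paths[0] == paths[1]

    def test_ledger_json_roundtrip(self, tiny_sim, tmp_path):
        _, _, _, ledger = tiny_sim
        p = tmp_path / "truth.json"
        ledger.to_json(str(p))
        back = TruthLedger.from_json(str(p))
        assert back == ledger

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(snv_rate=0).validate()
        with pytest.raises(ValueError):
            SimParams(chrom_lengths={"1": 1000},
                      dup_regions=[("1", 500, 2000, 2.0)]).validate()
        with pytest.raises(ValueError):
            SimParams(chrom_lengths={"1": 10_000},
                      dup_regions=[("1", 1, 500, 2.0), ("1", 400, 900, 2.0)]).validate()

    def test_sfs_weights_normalized_and_boosted(self):
        p = SimParams(n_samples=5, singleton_boost=3.0)
        w = p.sfs_weights()
        assert w.sum() == pytest.approx(1.0)
        base = SimParams(n_samples=5).sfs_weights()
        assert w[0] > base[0]


class TestSampleMetadata:
    def test_study_panel_composition(self, study_params):
        meta = sample_metadata(study_params)
        assert len(meta) == 101
        years = sorted(m.birth_year for m in meta)
        expect = sorted(y for y, c in BIRTH_YEAR_COHORTS.items() for _ in range(c))
        assert years == expect
        assert sum(m.sex == "M" for m in meta) == 58
        assert len({m.founder for m in meta}) == study_params.n_founders

    def test_metadata_frame_columns(self, tiny_params):
        df = metadata_frame(sample_metadata(tiny_params))
        assert list(df.columns) == ["sample_id", "sex", "birth_year", "founder"]


class TestSimulateMito:
    def test_no_noise_haplotypes_equal_within_founder(self):
        p = SimParams(n_samples=12, n_founders=3, seed=5)
        _, matrix, ledger = simulate_mito(p, n_mito_sites=100, error_rate=0.0, private_rate=0.0)
        assert ledger.mito_errors == []
        cols = {sid: matrix.gt[:, j] for j, sid in enumerate(matrix.sample_ids)}
        for founder in set(ledger.mito_lineage.values()):
            group = [cols[s] for s, f in ledger.mito_lineage.items() if f == founder]
            for g in group[1:]:
                assert np.array_equal(group[0], g)

    def test_injected_error_distance_exceeds_divergence_minus_private(self):
        p = SimParams(n_samples=10, seed=9)
        _, matrix, ledger = simulate_mito(p, n_founders=2, n_mito_sites=200,
                                          error_rate=0.1, private_rate=0.3)
        assert ledger.mito_errors
        cols = {sid: matrix.gt[:, j] for j, sid in enumerate(matrix.sample_ids)}
        for bad in ledger.mito_errors:
            labeled = ledger.mito_lineage[bad]
            # consensus of the non-error members of the labeled founder group
            group = [cols[s] for s, f in ledger.mito_lineage.items()
                     if f == labeled and s not in ledger.mito_errors]
            consensus = (np.vstack(group).mean(axis=0) > 0.5).astype(int)
            dist = int((cols[bad] != consensus).sum())
            n_private = len(ledger.mito_private.get(bad, []))
            assert dist >= 200 // 10 - n_private  # founder divergence floor

    def test_deterministic(self):
        p = SimParams(n_samples=6, n_founders=2, seed=3)
        a = simulate_mito(p, n_mito_sites=50)
        b = simulate_mito(p, n_mito_sites=50)
        assert np.array_equal(a[1].gt, b[1].gt)
        assert a[0] == b[0]
        assert a[2] == b[2]

    def test_too_many_sites_rejected(self):
        with pytest.raises(ValueError):
            simulate_mito(SimParams(seed=1), n_mito_sites=MITO_GENOME_BP + 1)

    def test_haploid_matrix(self, study_mito):
        _, matrix, _ = study_mito
        assert matrix.ploidy == 1
        assert set(np.unique(matrix.gt)) <= {0, 1}


class TestGenerateAnnotation:
    def test_zero_genes_single_intergenic(self):
        p = SimParams(chrom_lengths={"1": 30_000}, dup_regions=[])
        ann = generate_annotation(p)
        assert ann.intervals["1"] == [(1, 30_000, "intergenic")]

    def test_classes_partition_chromosome(self):
        p = SimParams(chrom_lengths={"1": 500_000}, dup_regions=[])
        ann = generate_annotation(p)
        ivs = sorted(ann.intervals["1"])
        assert ivs[0][0] == 1 and ivs[-1][1] == 500_000
        for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
            assert s2 == e1 + 1  # contiguous, no gaps or overlaps

    def test_upstream_flank_coordinates(self):
        p = SimParams(chrom_lengths={"1": 500_000}, dup_regions=[])
        ann = generate_annotation(p)
        up = [iv for iv in ann.intervals["1"] if iv[2] == "upstream"]
        assert up[0] == (GENE_FIRST_START - FLANK_BP, GENE_FIRST_START - 1, "upstream")
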