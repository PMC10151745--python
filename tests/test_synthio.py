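"""Synthetic taxonomy, reference-database, read, landscape and occurrence generators."""

import numpy as np
import pandas as pd
import pytest

from floramap import synthio
from floramap.cluster import pairwise_identity
from floramap.spatialstats import moran_correlogram
from floramap.synthio import (PRIMER_F, PRIMER_R, make_barcodes, make_landscape,
                              make_occurrences, make_reads, make_reference_db,
                              make_taxonomy, revcomp)


class TestTaxonomy:
    def test_minimal_tree(self):
        tax = make_taxonomy(1, 1, 1, seed=0)
        assert tax.n_species == 1
        assert len(tax.families) == 1 and len(tax.genera) == 1

    def test_species_count_is_product(self):
        assert make_taxonomy(4, 3, 5, seed=0).n_species == 60

    def test_deterministic_under_seed(self):
        a = make_taxonomy(3, 2, 2, seed=7)
        b = make_taxonomy(3, 2, 2, seed=7)
        assert a.species_names() == b.species_names()
        assert [f.name for f in a.families] == [f.name for f in b.families]

    def test_lineage_nesting(self):
        tax = make_taxonomy(2, 2, 2, seed=1)
        for sp in tax.species:
            k, f, g, s = sp.lineage()
            assert k == synthio.PLANT_KINGDOM
            assert f in {fam.name for fam in tax.families}
            assert g in {gen.name for gen in tax.genera}

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_non_positive_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            make_taxonomy(*bad, seed=0)


class TestReferenceDb:
    def test_full_completeness_one_record_per_species(self):
        tax = make_taxonomy(3, 2, 2, seed=0)
        db = make_reference_db(tax, completeness=1.0, seed=0)
        assert len(db) == tax.n_species
        assert len({r.species for r in db}) == tax.n_species

    def test_half_completeness_exact_count(self):
        tax = make_taxonomy(4, 3, 5, seed=0)
        db = make_reference_db(tax, completeness=0.5, seed=0)
        assert len(db) == 30

    def test_subset_sequences_match_full_db(self):
        tax = make_taxonomy(3, 2, 3, seed=2)
        full = {r.seq_id: r.sequence for r in make_reference_db(tax, seed=5)}
        half = make_reference_db(tax, completeness=0.5, seed=5)
        assert all(full[r.seq_id] == r.sequence for r in half)

    def test_lengths_within_marker_range(self):
        tax = make_taxonomy(6, 2, 2, seed=3)
        db = make_reference_db(tax, length_range=(30, 143), seed=3)
        assert all(30 <= len(r.sequence) <= 143 for r in db)

    def test_congeneric_identity_exceeds_confamilial(self):
        """With rates 0.01 within genus / 0.08 within family, mean congeneric
        identity must exceed mean confamilial identity under the aligner."""
        tax = make_taxonomy(2, 2, 3, seed=4)
        db = make_reference_db(tax, length_range=(90, 110),
                               divergence={"genus": 0.01, "family": 0.08}, seed=4)
        cong, confam = [], []
        for i, a in enumerate(db):
            for b in db[i + 1:]:
                if a.genus == b.genus:
                    cong.append(pairwise_identity(a.sequence, b.sequence)[0])
                elif a.family == b.family:
                    confam.append(pairwise_identity(a.sequence, b.sequence)[0])
        assert np.mean(cong) > np.mean(confam)

    def test_divergence_ordering_enforced(self):
        tax = make_taxonomy(2, 2, 2, seed=0)
        with pytest.raises(ValueError):
            make_reference_db(tax, divergence={"genus": 0.2, "family": 0.1})


class TestReads:
    def _single_species_setup(self, insert_len=120, seed=0):
        tax = make_taxonomy(1, 1, 1, seed=seed)
        db = make_reference_db(tax, length_range=(insert_len, insert_len), seed=seed)
        community = pd.DataFrame({"S1": [4]}, index=[db[0].species])
        barcodes = make_barcodes(["S1"], seed=seed)
        return tax, db, community, barcodes

    def test_readthrough_geometry(self):
        """A 120 nt insert in a 150 nt read: the forward mate is barcode +
        primer + insert running on into the reverse-primer complement."""
        _, db, community, barcodes = self._single_species_setup(120)
        fwd, rev, truth = make_reads(community, db, barcodes, error_rate=0.0,
                                     fail_fraction=0.0, seed=1)
        bc = barcodes["S1"]
        insert = db[0].sequence
        read = str(fwd[0].seq)
        assert read.startswith(bc + PRIMER_F)
        head = len(bc) + len(PRIMER_F)
        assert read[head:head + 120] == insert
        assert read[head + 120:] == revcomp(PRIMER_R)[:150 - head - 120]

    def test_error_free_roundtrip_through_cleaning(self, tmp_path):
        from floramap import readproc

        _, db, community, barcodes = self._single_species_setup(90)
        fwd, rev, _ = make_reads(community, db, barcodes, error_rate=0.0,
                                 fail_fraction=0.0, seed=2)
        synthio.write_fastq(fwd, tmp_path / "R1.fastq")
        synthio.write_fastq(rev, tmp_path / "R2.fastq")
        man = pd.DataFrame({"sample": ["S1"], "barcode": [barcodes["S1"]]})
        cleaned, report = readproc.clean_batch(tmp_path / "R1.fastq",
                                               tmp_path / "R2.fastq", man)
        assert report.cleaned == 4
        assert all(r.sequence == db[0].sequence for r in cleaned)

    def test_observed_error_rate_matches_nominal(self):
        """1000 pairs at 1% substitution: observed mismatch fraction 0.01 +- 0.005."""
        _, db, community, barcodes = self._single_species_setup(100)
        community = pd.DataFrame({"S1": [1000]}, index=[db[0].species])
        err_reads, _, _ = make_reads(community, db, barcodes, error_rate=0.01,
                                     fail_fraction=0.0, seed=3)
        clean_reads, _, _ = make_reads(community, db, barcodes, error_rate=0.0,
                                       fail_fraction=0.0, seed=3)
        template = str(clean_reads[0].seq)
        mism = sum(a != b for rec in err_reads for a, b in zip(str(rec.seq), template))
        frac = mism / (1000 * 150)
        assert frac == pytest.approx(0.01, abs=0.005)

    def test_byte_identical_under_seed(self, tmp_path):
        _, db, community, barcodes = self._single_species_setup(80)
        for tag in ("a", "b"):
            fwd, rev, _ = make_reads(community, db, barcodes, error_rate=0.01, seed=9)
            synthio.write_fastq(fwd, tmp_path / f"{tag}_R1.fastq")
        assert (tmp_path / "a_R1.fastq").read_bytes() == (tmp_path / "b_R1.fastq").read_bytes()

    def test_read_length_shorter_than_insert_rejected(self):
        _, db, community, barcodes = self._single_species_setup(120)
        with pytest.raises(ValueError):
            make_reads(community, db, barcodes, read_length=100, seed=0)


class TestLandscape:
    def test_constant_richness_without_drivers(self):
        land = make_landscape(n_sites=12, richness_model=(2.0, 0.0, 0.0),
                              noise_sd=0.0, seed=0)
        assert len(set(land.true_richness)) == 1

    def test_richness_monotone_in_mat(self):
        land = make_landscape(n_sites=20, richness_model=(2.0, 0.1, 0.0),
                              noise_sd=0.0, seed=1)
        order = np.argsort(land.climate["MAT"].to_numpy())
        rich = land.true_richness[order]
        assert np.all(np.diff(rich) >= 0)
        assert rich[-1] > rich[0]

    def test_spatial_noise_is_autocorrelated(self):
        """Moran's I of the noise field in the nearest distance class is
        positive against a 200-draw permutation null (p < 0.05)."""
        land = make_landscape(n_sites=40, spatial_range=2000.0, noise_sd=0.5, seed=2)
        obs = moran_correlogram(land.noise, land.lats, land.lons,
                                n_classes=5)["moran_i"].iloc[0]
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            null.append(moran_correlogram(rng.permutation(land.noise), land.lats,
                                          land.lons, n_classes=5)["moran_i"].iloc[0])
        assert obs > 0
        assert (1 + sum(v >= obs for v in null)) / 201 < 0.05

    def test_variogram_increases_with_distance(self):
        from floramap.spatialstats import pairwise_distances_km

        land = make_landscape(n_sites=60, spatial_range=2000.0, noise_sd=0.5, seed=3)
        D = pairwise_distances_km(land.lats, land.lons)
        iu, ju = np.triu_indices(land.n_sites, 1)
        d, g = D[iu, ju], 0.5 * (land.noise[iu] - land.noise[ju]) ** 2
        near = g[d < np.quantile(d, 0.25)].mean()
        far = g[d > np.quantile(d, 0.75)].mean()
        assert far > near

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_landscape(n_sites=5)
        with pytest.raises(ValueError):
            make_landscape(n_sites=12, spatial_range=-1.0)

    def test_deterministic_under_seed(self):
        a = make_landscape(n_sites=15, seed=8)
        b = make_landscape(n_sites=15, seed=8)
        assert np.array_equal(a.true_richness, b.true_richness)
        assert a.climate.equals(b.climate)


class TestOccurrences:
    def _landscape_with_pool(self, n_species=100, seed=0, n_sites=10):
        tax = make_taxonomy(10, 2, n_species // 20, seed=seed)
        return make_landscape(n_sites=n_sites, taxonomy=tax, noise_sd=0.0,
                              richness_model=(np.log(n_species + 1), 0.0, 0.0),
                              seed=seed)

    def test_full_detection_matches_true_richness(self):
        land = self._landscape_with_pool()
        occ = make_occurrences(land, detection=1.0)
        per_cell = occ.groupby("cell_id")["species"].nunique()
        for site, rich in zip(land.sites, land.true_richness):
            assert per_cell[f"cell_{site.site_id}"] == rich

    def test_zero_detection_empty_table(self):
        land = self._landscape_with_pool()
        assert make_occurrences(land, detection=0.0).empty

    def test_half_detection_binomial(self):
        """Observed cell richness behaves as Binomial(100, 0.5): every draw
        within 3 SD of 50 and the mean close to 50."""
        counts = []
        for rep in range(20):
            land = self._landscape_with_pool(seed=100 + rep)
            occ = make_occurrences(land, detection=0.5)
            counts.extend(occ.groupby("cell_id")["species"].nunique())
        counts = np.asarray(counts)
        assert np.all(np.abs(counts - 50) <= 3 * 5)
        assert abs(counts.mean() - 50) <= 3 * 5 / np.sqrt(len(counts))
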