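"""Landscape construction, classification, correlations and model ladder."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from curvemut.landscape import (
    STOP_CODONS,
    CodingSequence,
    MutationRecord,
    MutationSet,
    binned_type_rates,
    classify_mutation,
    correlate_features,
    enumerate_potential_nonsense_sites,
    fit_site_models,
    gene_set_compare,
    is_transition,
    logistic_snv_model,
    normalize_snv_type,
    partial_spearman,
    per_nucleotide_rates,
    per_site_counts,
    site_model_frame,
    window_mutation_rate,
)
from curvemut.shape import FeatureTrack, WindowGrid


def brute_force_nonsense_sites(seq: str) -> dict[int, set]:
    """Oracle: try all 3*len substitutions, collect stop-creating ones."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    last = len(codons) - 1 if codons[-1] in STOP_CODONS else len(codons)
    sites: dict[int, set] = {}
    for pos in range(3 * last):
        ci, off = divmod(pos, 3)
        for alt in "ACGT":
            if alt == seq[pos]:
                continue
            mutant = codons[ci][:off] + alt + codons[ci][off + 1 :]
            if mutant in STOP_CODONS:
                sites.setdefault(pos + 1, set()).add(alt)
    return sites


def random_cds(rng, n_codons) -> CodingSequence:
    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    body = "".join(rng.choice(codons) for _ in range(n_codons))
    return CodingSequence("rand", "ATG" + body + "TAA")


class TestCodingSequence:
    def test_validation(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            CodingSequence("x", "ATGA")
        with pytest.raises(ValueError, match="internal"):
            CodingSequence("x", "ATGTAACCC")

    def test_ura3_is_valid(self, ura3):
        assert len(ura3.sequence) == 804
        assert ura3.has_terminal_stop


class TestEnumerateSites:
    def test_toy_example(self, toy_cds):
        # TGG -> TAG (pos 5), TGG -> TGA (pos 6), TGT -> TGA (pos 9); the
        # start codon ATG is >=2 substitutions from every stop
        land = enumerate_potential_nonsense_sites(toy_cds)
        assert set(land.positions) == {5, 6, 9}
        subs = {s.position: set(s.substitutions) for s in land.sites}
        assert subs == {5: {"A"}, 6: {"A"}, 9: {"A"}}

    def test_no_site_cds(self):
        # Met-Pro-Pro-stop: no single-base change reaches TAA/TAG/TGA
        land = enumerate_potential_nonsense_sites(CodingSequence("x", "ATGCCCCCCTAA"))
        assert len(land.sites) == 0

    def test_every_substitution_creates_stop(self, toy_cds):
        from curvemut.landscape import MutationRecord, classify_mutation

        land = enumerate_potential_nonsense_sites(toy_cds)
        for s in land.sites:
            for alt in s.substitutions:
                rec = MutationRecord("p", s.position, s.ref, alt)
                assert classify_mutation(toy_cds, rec) == "nonsense"

    def test_ura3_site_count(self, ura3):
        land = enumerate_potential_nonsense_sites(ura3)
        assert len(land.sites) == 104

    def test_matches_brute_force_on_random_cds(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            cds = random_cds(rng, int(rng.integers(1, 99)))
            land = enumerate_potential_nonsense_sites(cds)
            oracle = brute_force_nonsense_sites(cds.sequence)
            assert {s.position: set(s.substitutions) for s in land.sites} == oracle


class TestClassify:
    @pytest.mark.parametrize(
        "pos, ref, alt, expected",
        [
            (5, "G", "A", "nonsense"),  # TGG -> TAG
            (9, "T", "C", "synonymous"),  # TGT -> TGC
            (4, "T", "A", "missense"),  # TGG -> AGG
        ],
    )
    def test_codon_table_oracle(self, toy_cds, pos, ref, alt, expected):
        rec = MutationRecord("p1", pos, ref, alt)
        assert classify_mutation(toy_cds, rec) == expected

    def test_ref_mismatch_is_hard_error(self, toy_cds):
        with pytest.raises(ValueError, match="position 5"):
            classify_mutation(toy_cds, MutationRecord("p1", 5, "C", "A"))

    def test_classification_partitions_records(self, ura3):
        from curvemut.synthetic import simulate_selection_table
        from curvemut import load_default_table

        muts = simulate_selection_table(ura3, load_default_table(), seed=5).deduplicate()
        classes = [classify_mutation(ura3, r) for r in muts]
        assert len(classes) == len(muts)
        assert set(classes) <= {"synonymous", "missense", "nonsense"}


class TestDeduplicate:
    def test_same_plate_counted_once(self):
        recs = [MutationRecord("p1", 5, "G", "A")] * 2
        dd = MutationSet(recs).deduplicate()
        assert len(dd) == 1 and dd.n_duplicates_removed == 1

    def test_different_plates_kept(self):
        recs = [MutationRecord("p1", 5, "G", "A"), MutationRecord("p2", 5, "G", "A")]
        assert len(MutationSet(recs).deduplicate()) == 2

    def test_empty(self):
        assert len(MutationSet([]).deduplicate()) == 0

    def test_idempotent(self):
        recs = [MutationRecord("p1", 5, "G", "A")] * 3
        once = MutationSet(recs).deduplicate()
        twice = once.deduplicate()
        assert [r.key for r in once] == [r.key for r in twice]


class TestPerSiteCounts:
    def test_distinct_sample_count(self, toy_cds):
        recs = [
            MutationRecord("plate1", 5, "G", "A"),
            MutationRecord("plate1", 5, "G", "A"),
            MutationRecord("plate2", 5, "G", "A"),
        ]
        land = per_site_counts(
            enumerate_potential_nonsense_sites(toy_cds), MutationSet(recs)
        )
        counts = dict(zip(land.positions, land.counts))
        assert counts[5] == 2

    def test_no_mutations_all_zero(self, toy_cds):
        land = per_site_counts(
            enumerate_potential_nonsense_sites(toy_cds), MutationSet([])
        )
        assert land.counts.sum() == 0

    def test_count_conservation(self, ura3, table):
        from curvemut.synthetic import simulate_cds_landscape

        muts = simulate_cds_landscape(ura3, table, beta=0.5, lambda0=0.005,
                                      n_plates=60, seed=8)
        land = per_site_counts(enumerate_potential_nonsense_sites(ura3), muts)
        # every record sits at an enumerated substitution; distinct plates per
        # (site, sub) may collapse when one plate hits two subs of one site
        assert land.n_unmapped == 0
        assert land.total <= len(muts.deduplicate())
        dd = muts.deduplicate()
        n_site_plate = len({(r.sample_id, r.position) for r in dd})
        assert land.total == n_site_plate

    def test_per_nucleotide_rates_toy(self, toy_cds):
        recs = [
            MutationRecord("p1", 5, "G", "A"),
            MutationRecord("p2", 5, "G", "A"),
            MutationRecord("p1", 9, "T", "A"),
        ]
        land = per_site_counts(
            enumerate_potential_nonsense_sites(toy_cds), MutationSet(recs)
        )
        with pytest.warns(UserWarning):  # A and C have no potential sites
            rates = per_nucleotide_rates(land)
        # sites: pos5 (G), pos6 (G), pos9 (T)
        assert rates["G"] == pytest.approx((2 + 0) / 2)
        assert rates["T"] == pytest.approx(1.0)
        assert np.isnan(rates["A"]) and np.isnan(rates["C"])


class TestWindowRate:
    def test_rate_formula(self, toy_cds):
        recs = [
            MutationRecord("p1", 5, "G", "A"),
            MutationRecord("p2", 5, "G", "A"),
            MutationRecord("p3", 5, "G", "A"),
            MutationRecord("p1", 6, "G", "A"),
        ]
        land = per_site_counts(
            enumerate_potential_nonsense_sites(toy_cds), MutationSet(recs)
        )
        track = window_mutation_rate(land, L=6, step=6)
        # window [0,6): sites 5,6 -> counts 3+1 over 2 sites
        assert track.values[0] == pytest.approx(4 / 2)

    def test_window_without_sites_flagged(self, ura3):
        land = per_site_counts(
            enumerate_potential_nonsense_sites(ura3), MutationSet([])
        )
        track = window_mutation_rate(land, L=10, step=10)
        assert np.isnan(track.values[track.flags]).all()

    def test_disjoint_window_conservation(self, ura3, table):
        from curvemut.synthetic import simulate_cds_landscape

        muts = simulate_cds_landscape(ura3, table, beta=0.3, lambda0=0.01,
                                      n_plates=100, seed=4)
        land = per_site_counts(enumerate_potential_nonsense_sites(ura3), muts)
        track = window_mutation_rate(land, L=12, step=12)
        pos0 = land.positions - 1
        total = 0.0
        for w, start in enumerate(track.grid.starts):
            in_w = (pos0 >= start) & (pos0 < start + 12)
            if in_w.sum():
                total += track.values[w] * in_w.sum()
        covered = pos0 < track.grid.ends.max()
        assert total == pytest.approx(land.counts[covered].sum())


class TestCorrelations:
    def _tracks(self, rate_vals, feat_vals):
        grid = WindowGrid(L=10, step=10, seq_len=10 * len(rate_vals) )
        return (
            FeatureTrack(grid, np.asarray(rate_vals, float), "mutation_rate"),
            FeatureTrack(grid, np.asarray(feat_vals, float), "feat"),
        )

    def test_monotone_decreasing_gives_minus_one(self):
        rate, feat = self._tracks([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        res = correlate_features(rate, [feat])[0]
        assert res.rho == pytest.approx(-1.0)

    def test_constant_feature_flagged(self):
        rate, feat = self._tracks([1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
        res = correlate_features(rate, [feat])[0]
        assert res.flagged and np.isnan(res.rho)

    def test_five_pair_rank_formula_oracle(self):
        x, y = [3.0, 1.0, 4.0, 1.5, 5.0], [2.0, 9.0, 2.5, 7.0, 1.0]
        rate, feat = self._tracks(x, y)
        res = correlate_features(rate, [feat])[0]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        d2 = np.sum((rx - ry) ** 2)
        rho_oracle = 1 - 6 * d2 / (5 * 24)  # no ties: classic formula
        assert res.rho == pytest.approx(rho_oracle)

    def test_grid_mismatch_rejected(self):
        rate, _ = self._tracks([1, 2, 3], [1, 2, 3])
        other = FeatureTrack(WindowGrid(L=5, step=5, seq_len=15), np.ones(3), "f")
        with pytest.raises(ValueError):
            correlate_features(rate, [other])


class TestPartialSpearman:
    def test_constant_control_equals_plain_spearman(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_spearman(x, y, np.full(30, 3.0))
        assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-10)

    def test_feature_equals_control_flagged(self):
        x = np.arange(10.0)
        y = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3.5])
        res = partial_spearman(x, y, y)
        assert res.flagged

    def test_six_point_formula_oracle(self):
        x = np.array([1.0, 4.0, 2.0, 6.0, 5.0, 3.0])
        y = np.array([2.0, 3.0, 1.0, 6.0, 4.0, 5.0])
        z = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 5.0])
        r_xy = stats.spearmanr(x, y).statistic
        r_xz = stats.spearmanr(x, z).statistic
        r_yz = stats.spearmanr(y, z).statistic
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        res = partial_spearman(x, y, z)
        assert res.rho == pytest.approx(oracle, abs=1e-12)


class TestSiteModels:
    @pytest.fixture(scope="class")
    def strong_effect_fit(self, ura3, table):
        from curvemut.synthetic import simulate_cds_landscape, _site_curvature_for_cds

        skel = enumerate_potential_nonsense_sites(ura3)
        muts = simulate_cds_landscape(ura3, table, beta=1.5, lambda0=0.01,
                                      n_plates=135, seed=3)
        land = per_site_counts(skel, muts)
        curv = _site_curvature_for_cds(ura3, skel, table)
        return fit_site_models(land, curv)

    def test_curvature_model_dominates(self, strong_effect_fit):
        by_label = {m.label: m for m in strong_effect_fit}
        assert by_label["1"].aic - by_label["5"].aic > 10

    def test_nested_aic_bound(self, strong_effect_fit):
        # adding p predictors can raise AIC by at most 2p (RSS non-increasing)
        by_label = {m.label: m for m in strong_effect_fit}
        assert by_label["6"].aic <= by_label["2"].aic + 2
        assert by_label["6"].aic <= by_label["5"].aic + 2 * (
            by_label["6"].k - by_label["5"].k
        )
        assert by_label["3"].aic <= by_label["2"].aic + 2 * (
            by_label["3"].k - by_label["2"].k
        )

    def test_constant_response_prefers_null(self, ura3, table):
        from curvemut.synthetic import _site_curvature_for_cds

        skel = enumerate_potential_nonsense_sites(ura3)
        land = per_site_counts(skel, MutationSet([]))
        curv = _site_curvature_for_cds(ura3, skel, table)
        res = fit_site_models(land, curv)
        null_aic = res[0].aic
        assert all(m.aic >= null_aic for m in res[1:])

    def test_identical_observations_across_models(self, strong_effect_fit):
        assert len({m.n for m in strong_effect_fit}) == 1

    def test_too_few_observations_error(self, toy_cds, table):
        from curvemut.synthetic import _site_curvature_for_cds

        skel = enumerate_potential_nonsense_sites(toy_cds)
        land = per_site_counts(skel, MutationSet([]))
        with pytest.raises(ValueError):
            fit_site_models(land, np.ones(len(skel.sites)))


class TestLogisticModel:
    def _frame(self, genome, table, beta, seed):
        from curvemut.shape import site_profile
        from curvemut.synthetic import _standardize

        curv = site_profile(genome, "curvature", table)
        sc = np.flatnonzero(np.isfinite(curv))
        z = _standardize(curv[sc])
        rng = np.random.default_rng(seed)
        lab = (rng.random(len(sc)) < 0.15 * np.exp(-beta * z)).astype(int)
        return pd.DataFrame(
            {"mutated": lab, "curvature": curv[sc], "b0": [genome[p] for p in sc]}
        )

    def test_negative_effect_recovered(self, random_genome, table):
        df = self._frame(random_genome, table, beta=1.0, seed=0)
        out = logistic_snv_model(df)
        row = out[out.term == "curvature"].iloc[0]
        assert row.estimate < 0 and abs(row.z) > 2 and not row.separable

    def test_null_effect_near_zero(self, random_genome, table):
        hits = 0
        for seed in range(10):
            df = self._frame(random_genome, table, beta=0.0, seed=seed)
            row = logistic_snv_model(df).query("term == 'curvature'").iloc[0]
            hits += abs(row.z) < 2
        assert hits >= 8  # ~95% coverage, allow slack

    def test_separable_data_flagged(self):
        df = pd.DataFrame(
            {"mutated": [0, 0, 0, 1, 1, 1] * 5,
             "curvature": [1.0, 2, 3, 10, 11, 12] * 5}
        )
        out = logistic_snv_model(df)
        assert out.separable.any()


class TestBinnedTypeRates:
    def test_transition_transversion_labels(self):
        assert is_transition("A", "G") and is_transition("C", "T")
        assert not is_transition("A", "C") and not is_transition("G", "T")

    def test_pyrimidine_normalization(self):
        assert normalize_snv_type("G", "A") == "C>T"
        assert normalize_snv_type("A", "C") == "T>G"
        assert normalize_snv_type("C", "T") == "C>T"

    def test_rates_and_bin_sizes(self, random_genome, table):
        genome = random_genome[:3000]
        snvs = MutationSet([MutationRecord("s1", 1500, genome[1499], "T" if genome[1499] != "T" else "A")])
        df = binned_type_rates(genome, snvs, n_samples=1, table=table, n_bins=5)
        sizes = df.groupby("bin")["at_risk_positions"].sum().to_numpy()
        # bin sizes (C/G + A/T at-risk totals) differ by at most 1
        assert sizes.max() - sizes.min() <= 1
        assert df["n_snvs"].sum() == 1
        hit = df[df.n_snvs > 0].iloc[0]
        assert hit.rate == pytest.approx(1 / (1 * hit.at_risk_positions))

    def test_absent_type_rate_zero(self, random_genome, table):
        genome = random_genome[:2000]
        df = binned_type_rates(genome, MutationSet([]), 3, table, n_bins=4)
        assert (df.rate == 0).all()


class TestGeneSetCompare:
    def test_identical_sets(self):
        p = gene_set_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert 0.3 < p < 0.8

    def test_fully_separated_two_vs_two(self):
        assert gene_set_compare([3.0, 4.0], [1.0, 2.0], "greater") == pytest.approx(1 / 6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gene_set_compare([], [1.0])


class TestMutationTableIO:
    def test_tsv_round_trip(self, tmp_path):
        recs = [MutationRecord("p1", 5, "G", "A"), MutationRecord("p2", 9, "T", "C")]
        path = tmp_path / "muts.tsv"
        MutationSet(recs).to_tsv(path)
        back = MutationSet.from_tsv(path)
        assert [r.key for r in back] == [r.key for r in recs]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tposition\tref\np1\t5\tG\n")
        with pytest.raises(ValueError, match="alt"):
            MutationSet.from_tsv(path)

    def test_vcf_reader(self, tmp_path):
        path = tmp_path / "muts.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t5\t.\tG\tA\t.\t.\tSAMPLE=p1\n"
            "chr1\t9\t.\tT\tC,G\t.\t.\tSAMPLE=p2\n"
        )
        ms = MutationSet.from_vcf(path)
        assert len(ms) == 3
        assert ms.records[0].key == ("p1", 5, "G", "A")
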