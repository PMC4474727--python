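"""Segregating-sites posterior, minimum-risk assignment, and LOOCV."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdbarcoder import (
    BarcodeDB,
    BarcodeRecord,
    BarcodeSimConfig,
    assignment_risk,
    loocv,
    p_distance,
    posterior,
    read_barcode_fasta,
    segregating_sites,
    simulate_barcodes,
    species_profiles,
    standardize_risks,
)


def db_from(*items):
    return BarcodeDB(
        [BarcodeRecord(f"s{i}", sp, seq) for i, (sp, seq) in enumerate(items)]
    )


class TestReadFasta:
    def test_parses_headers_and_length(self, toy_fasta):
        db = read_barcode_fasta(toy_fasta)
        assert db.alignment_length == 4
        assert len(db) == 3
        assert db.records[0].species == "GenX alpha"
        assert db.records[0].genus == "GenX"
        assert db.species_names == ["GenX alpha", "GenY beta"]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="unequal alignment length"):
            read_barcode_fasta(">a|X_y\nACGT\n>b|X_y\nACGTA\n")

    def test_missing_species_field_rejected(self):
        with pytest.raises(ValueError, match="a1"):
            read_barcode_fasta(">a1\nACGT\n")

    def test_fasta_round_trip(self, toy_fasta):
        db = read_barcode_fasta(toy_fasta)
        again = read_barcode_fasta(db.to_fasta())
        assert [(r.seq_id, r.species, r.seq) for r in again.records] == [
            (r.seq_id, r.species, r.seq) for r in db.records
        ]


class TestSegregatingSites:
    def test_direct_definition(self):
        db = db_from(("X a", "ACGT"), ("X a", "AGGT"))
        assert segregating_sites(db) == [1]

    def test_identical_sequences_have_none(self):
        db = db_from(("X a", "ACGT"), ("Y b", "ACGT"))
        assert segregating_sites(db) == []

    def test_gaps_and_ambiguities_ignored(self):
        # column 0 varies only via gap/N; column 1 truly segregates
        db = db_from(("X a", "A-GT"), ("Y b", "NCGT"), ("Z c", "AAGT"))
        assert segregating_sites(db) == [1]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACGT-N"))
        for _ in range(20):
            seqs = ["".join(rng.choice(alphabet, size=12)) for _ in range(5)]
            db = db_from(*[("Sp %d" % (i % 3), s) for i, s in enumerate(seqs)])
            expected = []
            for j in range(12):
                col = {s[j] for s in seqs} & set("ACGT")
                if len(col) >= 2:
                    expected.append(j)
            assert segregating_sites(db) == expected


class TestProfiles:
    def test_consensus_of_identical_pair(self):
        (prof,) = species_profiles(db_from(("X a", "ACGT"), ("X a", "ACGT")))
        assert prof.consensus == "ACGT"
        assert prof.n_seqs == 2

    def test_tie_breaks_to_alphabetical_base(self):
        (prof,) = species_profiles(db_from(("Y b", "AGGT"), ("Y b", "AGGA")))
        assert prof.consensus == "AGGA"  # T/A tie at site 3 -> A

    def test_counts_conserve_unambiguous_bases(self):
        (prof,) = species_profiles(db_from(("X a", "AC-T"), ("X a", "ANGT")))
        assert prof.counts.sum(axis=1).tolist() == [2, 1, 1, 2]

    def test_all_gap_column_yields_gap(self):
        (prof,) = species_profiles(db_from(("X a", "A-GT"), ("X a", "A-GT")))
        assert prof.consensus == "A-GT"


class TestPosteriorAndRisk:
    def test_worked_example(self, toy_fasta):
        db = read_barcode_fasta(toy_fasta)
        profiles = species_profiles(db)
        sites = segregating_sites(db)
        assert sites == [1, 3]
        post = posterior("ACGT", profiles, sites)
        # L_X = (2/5)(2/5), L_Y = (1/6)(2/6); P(X) = 0.16/(0.16 + 1/18)
        lx, ly = 0.4 * 0.4, (1 / 6) * (2 / 6)
        assert post[0] == pytest.approx(lx / (lx + ly), abs=1e-12)
        res = assignment_risk("ACGT", db)
        assert res.risks[0] == pytest.approx(0.0, abs=1e-12)
        assert res.risks[1] == pytest.approx(0.5 * lx / (lx + ly), abs=1e-12)
        assert res.min_risk_species == "GenX alpha"
        assert not res.ambiguous

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(5)]
            db = db_from(*[("Sp %d" % (i % 3), s) for i, s in enumerate(seqs)])
            post = posterior(seqs[0], species_profiles(db), segregating_sites(db))
            assert post.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.filterwarnings("ignore:query has no unambiguous")
    def test_matches_direct_enumeration_small(self):
        """Posterior equals the per-site multinomial product computed naively
        for alignments of <= 6 columns and <= 6 sequences."""
        rng = np.random.default_rng(2)
        for _ in range(15):
            n, L = rng.integers(3, 7), rng.integers(2, 7)
            seqs = ["".join(rng.choice(list("ACGT-"), size=L)) for _ in range(n)]
            species = ["Sp %d" % (i % 3 + 1) for i in range(n)]
            db = db_from(*zip(species, seqs))
            profiles = species_profiles(db)
            sites = segregating_sites(db)
            query = seqs[0]
            # naive route: raw products over usable sites
            raw = []
            for prof in profiles:
                prod = 1.0
                for j in sites:
                    qb = query[j]
                    if qb not in "ACGT":
                        continue
                    members = [s for sp, s in zip(species, seqs) if sp == prof.species]
                    c = sum(1 for s in members if s[j] == qb)
                    nn = sum(1 for s in members if s[j] in "ACGT")
                    prod *= (c + 1) / (nn + 4)
                raw.append(prod)
            raw = np.array(raw)
            expected = raw / raw.sum()
            got = posterior(query, profiles, sites)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_risk_iff_zero_distance_or_certain(self):
        db = db_from(("X a", "AAAA"), ("Y b", "TTTT"), ("Z c", "GGGG"))
        res = assignment_risk("AAAA", db)
        assert res.risks[0] == pytest.approx(0.0)
        assert np.all(res.risks[1:] > 0)
        assert res.min_risk_species == "X a"

    def test_all_ambiguous_query_warns_uniform(self):
        db = db_from(("X a", "ACGT"), ("Y b", "AGGT"))
        with pytest.warns(UserWarning):
            post = posterior("NN-N", species_profiles(db), segregating_sites(db))
        assert post == pytest.approx([0.5, 0.5])

    def test_identical_species_tie_flagged_ambiguous(self):
        db = db_from(("X a", "ACGT"), ("Y b", "ACGT"), ("Z c", "GGGG"))
        res = assignment_risk("ACGT", db)
        assert res.ambiguous
        assert set(res.tied_species) == {"X a", "Y b"}
        assert res.min_risk_species == "X a"  # lexicographic tie-break

    def test_fewer_than_two_species_rejected(self):
        db = db_from(("X a", "ACGT"), ("X a", "ACGA"))
        with pytest.raises(ValueError):
            assignment_risk("ACGT", db)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(6)]
        species = ["Sp %d" % (i % 3 + 1) for i in range(6)]
        items = list(zip(species, seqs))
        base = assignment_risk("ACGTACGTAC", db_from(*items))
        for perm in itertools.islice(itertools.permutations(items), 1, 6):
            res = assignment_risk("ACGTACGTAC", db_from(*perm))
            assert res.species == base.species  # sorted by name
            assert res.posteriors == pytest.approx(base.posteriors, abs=1e-12)
            assert res.risks == pytest.approx(base.risks, abs=1e-12)
            assert res.min_risk_species == base.min_risk_species


class TestPDistance:
    def test_counts_only_shared_unambiguous_sites(self):
        assert p_distance("ACGT", "ACGA") == pytest.approx(0.25)
        assert p_distance("AC-T", "ACNT") == pytest.approx(0.0)
        assert p_distance("ANGT", "A-GA") == pytest.approx(1 / 3)

    def test_no_shared_sites_warns_maximal(self):
        with pytest.warns(UserWarning):
            assert p_distance("NN", "AC") == 1.0


class TestStandardization:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([0.0, 0.2, 0.6], [0.0, 1 / 3, 1.0]),
            ([0.1, 0.3], [0.0, 0.5]),
            ([0.4, 0.4], [0.0, 0.0]),
        ],
    )
    def test_printed_formula(self, row, expected):
        assert standardize_risks(row) == pytest.approx(expected, abs=1e-12)

    def test_conventional_range_variant(self):
        assert standardize_risks([0.1, 0.3], method="range") == pytest.approx([0.0, 1.0])

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            standardize_risks([])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=8))
    def test_in_unit_interval_when_min_is_zero(self, tail):
        row = [0.0] + tail
        std = standardize_risks(row)
        assert np.all(std >= 0) and np.all(std <= 1)
        assert std[int(np.argmin(row))] == 0.0


class TestLoocv:
    def test_recovers_well_separated_species(self):
        db, truth = simulate_barcodes(
            BarcodeSimConfig(
                n_species=8, seqs_per_species=3, interspecific=0.2,
                intraspecific=0.005, seed=4,
            )
        )
        report = loocv(db)
        assert report.species_accuracy >= 0.9
        assert report.seq_accuracy >= 0.9
        assert report.n_singletons == 0
        assert report.n_seqs == len(truth)

    def test_singleton_genus_rule(self):
        # P is a singleton; its nearest candidate is a congener Q
        db = db_from(
            ("Gen alpha", "AAAAAAAACT"),
            ("Gen beta", "AAAAAAAAGG"),
            ("Gen beta", "AAAAAAAAGG"),
            ("Other gamma", "TTTTTTTTTT"),
            ("Other gamma", "TTTTTTTTTT"),
        )
        report = loocv(db)
        row = report.calls[report.calls.true_species == "Gen alpha"].iloc[0]
        assert row.singleton
        assert row.called_species == "Gen beta"
        assert row.correct

    def test_identical_species_confuse_each_other(self):
        # shared barcodes: neither species reliably recovered, and their
        # mutual standardized risks are ~0 in the aggregated matrix
        db = db_from(
            ("X a", "ACGTACGTAC"), ("X a", "ACGTACGTAC"),
            ("Y b", "ACGTACGTAC"), ("Y b", "ACGTACGTAC"),
            ("Z c", "GGGGGGGGGG"), ("Z c", "GGGGGGGGGG"),
        )
        report = loocv(db)
        xy = report.calls.true_species.isin(["X a", "Y b"])
        assert not report.calls[xy].correct.all()
        assert report.risk_matrix_std.loc["X a", "Y b"] == pytest.approx(0.0, abs=1e-9)
        assert report.risk_matrix_std.loc["Y b", "X a"] == pytest.approx(0.0, abs=1e-9)

    def test_species_accuracy_is_strict_majority(self):
        db, _ = simulate_barcodes(
            BarcodeSimConfig(
                n_species=5, seqs_per_species=3, interspecific=0.3,
                intraspecific=0.0, seed=9,
            )
        )
        report = loocv(db)
        per_species = report.calls.groupby("true_species")["correct"].apply(
            lambda c: c.sum() * 2 > len(c)
        )
        assert report.species_accuracy == pytest.approx(per_species.mean())

    def test_requires_two_species(self):
        db = db_from(("X a", "ACGT"), ("X a", "ACGA"))
        with pytest.raises(ValueError):
            loocv(db)
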