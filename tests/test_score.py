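import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from provean.align import GapPenalties
from provean.homologs import build_supporting_set
from provean.score import (
    DEFAULT_THRESHOLD,
    Prediction,
    ProveanScorer,
    classify,
    delta_score,
    provean_score,
    saturation_scan,
    unbiased_average,
)
from provean.seqvar import (
    AA20,
    ProteinSequence,
    Variant,
    VariantKind,
    apply_variant,
    null_variant,
    parse_variant,
)
from provean.synthfam import generate_labeled_variants

from ._oracles import semiglobal_score_oracle
from .conftest import random_protein


class TestDeltaScore:
    def test_forced_ungapped_substitution(self, blosum62, default_gaps):
        """G->C inside an exactly matching context: delta = M(C,G) - M(G,G) = -9."""
        query = ProteinSequence("q", "MKTGAELVRW")
        subject = ProteinSequence("s", "MKTGAELVRW")
        v = parse_variant("G4C", query)
        assert delta_score(query, v, subject, blosum62, default_gaps) == -9

    def test_null_variant_is_zero(self, blosum62, default_gaps, rng):
        query = ProteinSequence("q", random_protein(rng, 25))
        for _ in range(5):
            subject = ProteinSequence("s", random_protein(rng, 25))
            v = null_variant(query, int(rng.integers(1, len(query) + 1)))
            assert delta_score(query, v, subject, blosum62, default_gaps) == 0

    def test_matches_end_to_end_oracle_on_tiny_instances(self, blosum62, default_gaps, rng):
        """delta = oracle(Q', S) - oracle(Q, S) with the enumeration aligner."""
        lookup = lambda x, y: blosum62[x, y]
        for _ in range(40):
            q = ProteinSequence("q", random_protein(rng, int(rng.integers(2, 7))))
            s = random_protein(rng, int(rng.integers(1, 7)))
            pos = int(rng.integers(1, len(q) + 1))
            choice = rng.integers(3)
            if choice == 0:
                alt = random_protein(rng, 1)
                v = Variant.make(pos, q.residue(pos), alt)
                if v.is_null:
                    continue
            elif choice == 1 and len(q) > 1:
                v = Variant(VariantKind.DELETION, pos, q.residue(pos), "")
            else:
                v = Variant(VariantKind.INSERTION, pos, "", random_protein(rng, 2))
            mutated = apply_variant(q, v).residues
            expected = (semiglobal_score_oracle(mutated, s, lookup)
                        - semiglobal_score_oracle(q.residues, s, lookup))
            got = delta_score(q, v, ProteinSequence("s", s), blosum62, default_gaps)
            assert got == expected, (q.residues, s, v)


class TestUnbiasedAverage:
    def test_equal_cluster_weighting(self):
        score, means = unbiased_average([[-6, -6, 0], [3]])
        assert means == (-4.0, 3.0)
        assert score == -0.5  # NOT the size-weighted -2.25

    def test_all_zero(self):
        score, _ = unbiased_average([[0, 0], [0]])
        assert score == 0.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            unbiased_average([[1.0], []])
        with pytest.raises(ValueError):
            unbiased_average([])

    def test_invariant_to_sizes_given_means(self, rng):
        means = [-4.0, 3.0, -1.0]
        expected = np.mean(means)
        for _ in range(5):
            clusters = [[m] * int(rng.integers(1, 9)) for m in means]
            score, _ = unbiased_average(clusters)
            assert score == pytest.approx(expected)


class TestClassify:
    def test_boundary_inclusive(self):
        assert classify(DEFAULT_THRESHOLD) is Prediction.DELETERIOUS
        assert classify(-2.282) is Prediction.DELETERIOUS
        assert classify(-2.281) is Prediction.NEUTRAL
        assert classify(-9.0) is Prediction.DELETERIOUS
        assert classify(0.0) is Prediction.NEUTRAL

    def test_custom_threshold(self):
        assert classify(-1.0, threshold=-0.5) is Prediction.DELETERIOUS

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"))


class TestProveanScore:
    def test_query_only_substitution(self, blosum62, default_gaps):
        """Query-only set, ungapped self-context: score = M(A,V) - M(A,A) = -4."""
        query = ProteinSequence("q", "WKAELRMKWD")
        sset = build_supporting_set(query, [], matrix=blosum62)
        v = parse_variant("A3V", query)
        res = provean_score(query, v, sset, blosum62, default_gaps)
        assert res.score == -4.0
        assert res.n_clusters == 1
        assert res.cluster_means == (-4.0,)
        assert res.prediction is Prediction.DELETERIOUS

    def test_null_variant_scores_zero_any_set(self, blosum62, small_family):
        _, query, homologs = small_family
        sset = build_supporting_set(query, homologs, matrix=blosum62)
        scorer = ProveanScorer(query, sset, blosum62)
        for pos in (1, len(query) // 2, len(query)):
            res = scorer.score(null_variant(query, pos))
            assert res.score == 0.0
            assert res.prediction is Prediction.NEUTRAL

    def test_duplicate_member_invariance(self, blosum62, small_family):
        """Appending an exact copy of a cluster member leaves the score unchanged."""
        _, query, homologs = small_family
        v = Variant.make(3, query.residue(3), "W" if query.residue(3) != "W" else "Y")
        sset = build_supporting_set(query, homologs, matrix=blosum62)
        base = ProveanScorer(query, sset, blosum62).score(v).score
        dup = ProteinSequence("dup_of_h0", homologs[0].residues)
        sset2 = build_supporting_set(query, homologs + [dup], matrix=blosum62)
        again = ProveanScorer(query, sset2, blosum62).score(v).score
        assert again == pytest.approx(base)

    def test_query_only_substitutions_bounded_by_zero(self, blosum62, rng):
        """Diagonal dominance: non-null substitutions never score > 0."""
        query = ProteinSequence("q", random_protein(rng, 20))
        sset = build_supporting_set(query, [], matrix=blosum62)
        scorer = ProveanScorer(query, sset, blosum62)
        for _ in range(20):
            pos = int(rng.integers(1, 21))
            alt = random_protein(rng, 1)
            v = Variant.make(pos, query.residue(pos), alt)
            assert scorer.score(v).score <= 0.0

    def test_query_only_deletions_negative(self, blosum62, rng):
        for _ in range(5):
            query = ProteinSequence("q", random_protein(rng, 15))
            sset = build_supporting_set(query, [], matrix=blosum62)
            scorer = ProveanScorer(query, sset, blosum62)
            for pos in rng.integers(1, 16, size=4):
                v = Variant(VariantKind.DELETION, int(pos), query.residue(int(pos)), "")
                assert scorer.score(v).score < 0.0

    def test_scorer_matches_one_shot_path(self, blosum62, small_family):
        _, query, homologs = small_family
        sset = build_supporting_set(query, homologs, matrix=blosum62)
        scorer = ProveanScorer(query, sset, blosum62)
        v = Variant.make(5, query.residue(5), "P" if query.residue(5) != "P" else "G")
        assert scorer.score(v) == provean_score(query, v, sset, blosum62)

    def test_multi_residue_variant_single_delta(self, blosum62, default_gaps, rng):
        """A replacement is applied as one edit, not summed per residue."""
        lookup = lambda x, y: blosum62[x, y]
        q = ProteinSequence("q", random_protein(rng, 6))
        s = random_protein(rng, 6)
        v = Variant(VariantKind.REPLACEMENT, 2, q.residues[1:4], random_protein(rng, 2))
        mutated = apply_variant(q, v).residues
        expected = (semiglobal_score_oracle(mutated, s, lookup)
                    - semiglobal_score_oracle(q.residues, s, lookup))
        assert delta_score(q, v, ProteinSequence("s", s), blosum62, default_gaps) == expected


@pytest.fixture(scope="module")
def scan_setup(blosum62):
    query = ProteinSequence("q", "MKTWAELG")
    rng = np.random.default_rng(3)
    homologs = []
    for i in range(4):
        res = list(query.residues)
        res[int(rng.integers(len(res)))] = "ACDE"[i]
        homologs.append(ProteinSequence(f"h{i}", "".join(res)))
    sset = build_supporting_set(query, homologs, matrix=blosum62)
    return query, sset, saturation_scan(query, sset, blosum62)


class TestSaturationScan:
    def test_dimensions(self, scan_setup):
        query, _, scan = scan_setup
        assert scan.values.shape == (len(query), 41)
        assert len(scan.column_labels) == 41

    def test_self_substitution_column_zero(self, scan_setup):
        query, _, scan = scan_setup
        for pos in range(1, len(query) + 1):
            col = scan.column_labels.index(f"sub:{query.residue(pos)}")
            assert scan.values[pos - 1, col] == 0.0

    def test_cells_match_scalar_path(self, scan_setup, blosum62):
        query, sset, scan = scan_setup
        checks = [
            (2, f"sub:W", Variant.make(2, query.residue(2), "W")),
            (4, "del", Variant(VariantKind.DELETION, 4, query.residue(4), "")),
            (5, "ins:G", Variant(VariantKind.INSERTION, 5, "", "G")),
        ]
        for pos, label, v in checks:
            cell = scan.values[pos - 1, scan.column_labels.index(label)]
            assert cell == provean_score(query, v, sset, blosum62).score

    def test_tsv_output(self, scan_setup, tmp_path):
        _, _, scan = scan_setup
        out = tmp_path / "scan.tsv"
        scan.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("position\tref\t")
        assert len(lines) == 1 + scan.values.shape[0]


class TestSyntheticDiscrimination:
    def test_conserved_positions_score_lower(self, blosum62, small_family):
        """Substitutions at conserved positions rank stochastically below
        substitutions at free positions (Mann-Whitney, p < 0.01)."""
        model, query, homologs = small_family
        sset = build_supporting_set(query, homologs, matrix=blosum62)
        scorer = ProveanScorer(query, sset, blosum62)
        recs = generate_labeled_variants(
            model, query, 50, 50, seed=99, homologs=homologs,
            kinds=(VariantKind.SUBSTITUTION,))
        cons, free = [], []
        for rec in recs:
            s = scorer.score(rec.variant).score
            (cons if rec.label.value == "deleterious" else free).append(s)
        stat = mannwhitneyu(cons, free, alternative="less")
        assert stat.pvalue < 0.01
        assert np.mean(cons) < np.mean(free)
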