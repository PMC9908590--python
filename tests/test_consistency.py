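"""Agreement metrics (kappa, Dice, BLEU), document comparison, audit diffs,
confusion-matrix reports — checked against independent formulas and
cross-library oracles."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnkit import synthetic as syn
from pnkit.consistency import (
    ConfusionMatrix,
    audit_diff,
    bleu_composite,
    bleu_n,
    classification_report,
    cohen_kappa,
    compare_annotations,
    dice_coefficient,
    per_label_dice,
    tokenize_caption,
)
from pnkit.errors import PnkitError
from pnkit.tiling import PatchGridSpec


def kappa_textbook(a, b):
    """Independent oracle: direct textbook evaluation of Cohen's kappa."""
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    labels = set(a) | set(b)
    p_e = sum((a.count(k) / n) * (b.count(k) / n) for k in labels)
    return (p_o - p_e) / (1 - p_e)


class TestKappa:
    def test_identical_lists(self):
        r = cohen_kappa(["x", "y", "x"], ["x", "y", "x"])
        assert r.kappa == 1.0 and r.p_o == 1.0

    def test_hand_evaluated_example(self):
        r = cohen_kappa(list("AABB"), list("ABBB"))
        assert r.p_o == pytest.approx(0.75)
        assert r.p_e == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.5)

    def test_random_pairs_match_textbook_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 200))
            k = int(rng.integers(2, 5))
            a = [chr(65 + int(x)) for x in rng.integers(0, k, n)]
            b = [chr(65 + int(x)) for x in rng.integers(0, k, n)]
            ours = cohen_kappa(a, b)
            if ours.degenerate:
                continue
            assert ours.kappa == pytest.approx(kappa_textbook(a, b), abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 500).tolist()
        b = rng.integers(0, 3, 500).tolist()
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_invariant_under_label_renaming(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 200).tolist()
        b = rng.integers(0, 3, 200).tolist()
        ren = {0: "alpha", 1: "beta", 2: "gamma"}
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa([ren[x] for x in a], [ren[x] for x in b]).kappa
        )

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = rng.integers(0, 2, 20).tolist()
            b = rng.integers(0, 2, 20).tolist()
            assert cohen_kappa(a, b).kappa <= 1.0 + 1e-12

    def test_shuffled_permutation_near_zero_in_expectation(self):
        rng = np.random.default_rng(4)
        a = (["x"] * 300 + ["y"] * 300 + ["z"] * 300)
        vals = []
        for _ in range(50):
            b = list(a)
            rng.shuffle(b)
            vals.append(cohen_kappa(a, b).kappa)
        assert abs(np.mean(vals)) < 0.02

    def test_both_constant_degenerate(self):
        r = cohen_kappa(["x"] * 5, ["x"] * 5)
        assert r.kappa == 1.0 and r.degenerate

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
                    min_size=1, max_size=60))
    def test_kappa_bounds_and_identity_property(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        r = cohen_kappa(a, b)
        assert r.kappa <= 1.0 + 1e-12
        assert 0.0 <= r.p_o <= 1.0 and 0.0 <= r.p_e <= 1.0
        if a == b:
            assert r.kappa == 1.0


class TestDice:
    def test_identity_disjoint_and_hand_value(self):
        a = np.zeros(10, dtype=bool)
        a[:4] = True
        b = np.zeros(10, dtype=bool)
        b[1:7] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
        assert dice_coefficient(a, b) == pytest.approx(2 * 3 / (4 + 6))

    def test_symmetry_and_empty_convention(self):
        rng = np.random.default_rng(5)
        a = rng.random((20, 20)) > 0.5
        b = rng.random((20, 20)) > 0.5
        assert dice_coefficient(a, b) == dice_coefficient(b, a)
        empty = np.zeros((5, 5), dtype=bool)
        assert dice_coefficient(empty, empty) == 1.0

    def test_monotone_under_growing_symmetric_difference(self):
        base = np.zeros(100, dtype=bool)
        base[:50] = True
        prev = 1.0
        other = base.copy()
        for k in range(50, 100, 10):
            other[k : k + 10] = True  # grow B beyond A
            d = dice_coefficient(base, other)
            assert d <= prev + 1e-12
            prev = d

    def test_per_label(self):
        m1 = np.array([["a", "a"], ["b", "b"]])
        m2 = np.array([["a", "b"], ["b", "b"]])
        d = per_label_dice(m1, m2, ["a", "b"])
        assert d["a"] == pytest.approx(2 * 1 / 3)
        assert d["b"] == pytest.approx(2 * 2 / 5)

    def test_shape_mismatch(self):
        with pytest.raises(PnkitError):
            dice_coefficient(np.zeros(3, bool), np.zeros(4, bool))


def bleu_n_brute(candidate, references, n):
    """Independent oracle: enumerate every candidate n-gram and clip its
    count against the per-reference maxima."""
    cand_grams = [tuple(candidate[k : k + n]) for k in range(len(candidate) - n + 1)]
    if not cand_grams:
        return 0.0
    hits = 0
    counted = Counter()
    for g in cand_grams:
        counted[g] += 1
    for g, c in counted.items():
        best = max((Counter(
            tuple(ref[k : k + n]) for k in range(len(ref) - n + 1)
        )[g] for ref in references), default=0)
        hits += min(c, best)
    return hits / len(cand_grams)


class TestBleu:
    def test_identity_all_orders(self):
        toks = "irregular glands with mucinous differentiation".split()
        for n in range(1, len(toks) + 1):
            assert bleu_n(toks, [toks], n) == 1.0

    def test_clipping_by_max_reference_count(self):
        assert bleu_n(["a", "a", "a"], [["a", "b"]], 1) == pytest.approx(1 / 3)

    def test_candidate_shorter_than_n(self):
        assert bleu_n(["a", "b"], [["a", "b"]], 3) == 0.0

    def test_random_strings_match_brute_force(self):
        rng = np.random.default_rng(6)
        vocab = list("abcde")
        for _ in range(100):
            cand = [vocab[int(x)] for x in rng.integers(0, 5, int(rng.integers(1, 15)))]
            refs = [
                [vocab[int(x)] for x in rng.integers(0, 5, int(rng.integers(1, 15)))]
                for _ in range(int(rng.integers(1, 3)))
            ]
            for n in (1, 2, 3, 4):
                assert bleu_n(cand, refs, n) == pytest.approx(
                    bleu_n_brute(cand, refs, n)
                )

    def test_composite_identical_pair_is_one(self):
        toks = tokenize_caption(
            "Nuclei rod-shaped, nucleus stratified or pseudostratified "
            "arrangement, tubular structure. Low grade adenomas."
        )
        assert bleu_composite(toks, [toks], 4) == 1.0

    def test_composite_no_shared_fourgram_is_zero(self):
        cand = tokenize_caption(
            "The cytoplasm was markedly reduced, karyorrhexis, thickened "
            "chromatin, screen mesh. Moderately differentiated adenocarcinoma."
        )
        ref = tokenize_caption(
            "Nuclei remain polar, nucleus stratified or pseudostratified "
            "arrangement, tubular structure, increased epithelial cell "
            "hierarchy, low grade intraepithelial neoplasia. Low grade adenomas."
        )
        assert bleu_composite(cand, [ref], 4) == 0.0

    def test_brevity_penalty_prefix_half(self):
        ref = list("abcdefgh")
        cand = ref[:4]
        # all clipped precisions are 1; BP = exp(1 - r/c) = exp(1 - 8/4)
        expected = np.exp(1 - 8 / 4)
        assert bleu_composite(cand, [ref], 4) == pytest.approx(expected)

    def test_composite_bounded_and_one_iff_equal(self):
        rng = np.random.default_rng(7)
        vocab = list("abc")
        for _ in range(50):
            cand = [vocab[int(x)] for x in rng.integers(0, 3, int(rng.integers(4, 10)))]
            ref = [vocab[int(x)] for x in rng.integers(0, 3, int(rng.integers(4, 10)))]
            score = bleu_composite(cand, [ref], 4)
            assert 0.0 <= score <= 1.0
            if cand != ref:
                assert score < 1.0 or bleu_n(cand, [ref], len(cand)) == 1.0

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=12),
           st.lists(st.sampled_from("abcd"), min_size=1, max_size=12))
    def test_composite_bounds_and_perfect_iff_equal_property(self, cand, ref):
        score = bleu_composite(cand, [ref], max_n=4)
        assert 0.0 <= score <= 1.0
        if cand == ref and len(cand) >= 4:
            assert score == 1.0
        elif cand == ref:
            # identical but shorter than the top order: no 4-grams exist, so
            # the unsmoothed geometric mean is 0 by definition
            assert score == 0.0

    def test_tokenizer_detokenizes_terminology_ids(self, tree):
        from pnkit.schema import Caption

        toks = tokenize_caption(Caption(["r16", "free text tag"]), tree)
        assert toks[:4] == ["irregular", "arrangement", "of", "glands"]
        assert "tag" in toks


class TestCompareAnnotations:
    def test_document_against_itself_is_perfect(self, sample_doc, tree):
        rep = compare_annotations(
            sample_doc, sample_doc, PatchGridSpec(32), tree=tree, image_size=(512, 512)
        )
        assert rep.slide_agree
        assert rep.patch_kappa_class.kappa == 1.0
        assert rep.patch_kappa_subtype.kappa == 1.0
        assert all(v == 1.0 for v in rep.dice_class.values())
        assert rep.caption_bleu[1] == 1.0

    def test_label_flip_rate_recovered_as_observed_agreement(self, tree):
        """With label-flip probability f = 0.1 the pooled patch-level
        observed agreement should recover 1 - f within a Monte-Carlo CI."""
        cfg = syn.SynthConfig(seed=3, image_size=512, regions_per_wsi=(4, 4))
        num = den = 0.0
        for k in range(12):
            doc = syn.generate_annotation(cfg, f"w{k}", "c-adenocarcinoma", tree)
            other, _ = syn.perturb_annotator(doc, tree, flip_rate=0.1, seed=100 + k)
            r = compare_annotations(doc, other, PatchGridSpec(16), tree=tree,
                                    image_size=(512, 512))
            num += r.patch_kappa_class.p_o * r.patch_kappa_class.n
            den += r.patch_kappa_class.n
        # 48 regions flipped independently at f=0.1: binomial CI on region
        # fraction ~ 0.1 +- 3*sqrt(0.1*0.9/48) = +-0.13
        assert abs(num / den - 0.9) < 0.13

    def test_boundary_jitter_leaves_interior_agreement_dice_below_one(self, tree):
        cfg = syn.SynthConfig(seed=3, image_size=512, regions_per_wsi=(4, 4))
        doc = syn.generate_annotation(cfg, "wj", "c-adenoma", tree)
        other, _ = syn.perturb_annotator(doc, tree, flip_rate=0.0, jitter_px=6, seed=5)
        r = compare_annotations(doc, other, PatchGridSpec(16), tree=tree,
                                image_size=(512, 512))
        # interior (both-labeled) patches still agree perfectly
        assert r.patch_kappa_class.p_o > 0.9
        assert all(d < 1.0 for d in r.dice_class.values())
        assert all(d > 0.8 for d in r.dice_class.values())

    def test_different_slides_rejected(self, sample_doc, tree):
        import copy

        other = copy.deepcopy(sample_doc)
        other.wsi_id = "other"
        with pytest.raises(PnkitError):
            compare_annotations(sample_doc, other, PatchGridSpec(32))


class TestAuditDiff:
    def test_identical_documents_empty_report(self, sample_doc):
        assert audit_diff(sample_doc, sample_doc).empty

    def test_single_deletion(self, sample_doc):
        import copy

        newer = copy.deepcopy(sample_doc)
        gone = newer.regions.pop().id
        newer.bundles = [
            b for b in newer.bundles if gone not in b.member_region_ids
        ]
        rep = audit_diff(sample_doc, newer)
        assert rep.removed == [gone]
        assert rep.added == []

    def test_reconstructs_generator_edit_log(self, tree):
        """Random relabeling script: the diff's modified set equals the
        regions the generator's edit log says were relabeled."""
        cfg = syn.SynthConfig(seed=19, image_size=512, regions_per_wsi=(3, 4))
        for k in range(6):
            doc = syn.generate_annotation(cfg, f"w{k}", "c-adenocarcinoma", tree)
            other, log = syn.perturb_annotator(
                doc, tree, flip_rate=0.4, jitter_px=2, seed=50 + k
            )
            rep = audit_diff(doc, other)
            assert rep.added == [] and rep.removed == []
            flipped = {e["region_id"] for e in log if e["action"] == "relabel"}
            modified = {m.old_id for m in rep.modified}
            assert modified == flipped


class TestClassificationReport:
    def test_diagonal_matrix_all_perfect(self):
        cm = ConfusionMatrix(["a", "b"], [[7, 0], [0, 9]])
        rep = classification_report(cm)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.recall.values())
        assert all(v == 1.0 for v in rep.precision.values())

    def test_coarse_grain_reference_matrix(self):
        cm = ConfusionMatrix(
            ["Normal", "Adenoma", "Adenocarcinoma"],
            [[5317, 483, 2039], [28, 1687, 16], [624, 26, 5517]],
        )
        rep = classification_report(cm)
        assert round(rep.accuracy * 100, 2) == 79.56
        assert round(rep.recall["Normal"] * 100, 2) == 67.83
        assert round(rep.recall["Adenoma"] * 100, 2) == 97.46
        assert round(rep.recall["Adenocarcinoma"] * 100, 2) == 89.46

    def test_fine_grain_reference_matrix(self):
        cm = ConfusionMatrix(
            ["Normal", "Adenoma", "Adenocarcinoma"],
            [[6202, 297, 1340], [69, 1622, 40], [565, 8, 5594]],
        )
        rep = classification_report(cm)
        assert round(rep.accuracy * 100, 2) == 85.26
        assert round(rep.recall["Normal"] * 100, 2) == 79.12
        assert round(rep.recall["Adenoma"] * 100, 2) == 93.70
        assert round(rep.recall["Adenocarcinoma"] * 100, 2) == 90.71

    def test_zero_denominator_is_undefined_not_zero(self):
        cm = ConfusionMatrix(["a", "b"], [[5, 0], [0, 0]])
        rep = classification_report(cm)
        assert rep.recall["b"] is None
        assert rep.precision["b"] is None
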