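"""Scoring: allele matching, orientation, brute-force equivalence, I/O."""

import numpy as np
import pytest

from pgstrend.scoring import (
    COMPLEMENT,
    GwasWeightRecord,
    compute_scores,
    match_variants,
    read_panel,
    read_weights,
    standardize,
)
from pgstrend.simulate import SimConfig, simulate_panel, write_weights

from conftest import make_panel


def rec(vid="v0", ea="C", oa="A", beta=1.0, **kw):
    return GwasWeightRecord(vid, ea, oa, beta, **kw)


def oracle_raw_scores(panel, records):
    """Independent double-loop scorer (no vectorization, no shared code)."""
    raw = [0.0] * panel.n_samples
    for r in records:
        if COMPLEMENT[r.effect_allele] == r.other_allele:
            continue
        if r.variant_id not in panel.variant_ids:
            continue
        j = panel.variant_ids.index(r.variant_id)
        if r.effect_allele == panel.alt[j] and r.other_allele == panel.ref[j]:
            flip = False
        elif r.effect_allele == panel.ref[j] and r.other_allele == panel.alt[j]:
            flip = True
        else:
            continue
        for i in range(panel.n_samples):
            x = panel.dosages[i, j]
            d = 2.0 - x if flip else x
            raw[i] += d * r.beta
    return np.array(raw)


class TestMatching:
    def test_ambiguous_removed(self):
        panel = make_panel([[0, 1], [1, 2]], ref=["A", "A"], alt=["T", "C"])
        matched, report = match_variants(panel, [rec("v0", "T", "A"), rec("v1")])
        assert report.n_ambiguous_removed == 1
        assert report.n_matched == 1
        assert 0 not in matched.variant_index

    def test_identity_orientation_no_flip(self):
        panel = make_panel([[0], [1], [2]])
        matched, report = match_variants(panel, [rec("v0", "C", "A")])
        assert report.n_flipped == 0
        sv = compute_scores(panel, matched)
        assert np.allclose(sv.raw, [0, 1, 2])

    def test_complement_rule_flips_dosage(self):
        panel = make_panel([[0], [1], [2]])
        matched, report = match_variants(panel, [rec("v0", "A", "C")])
        assert report.n_flipped == 1
        sv = compute_scores(panel, matched)
        assert np.allclose(sv.raw, [2, 1, 0])

    def test_irreconcilable_alleles_counted_as_mismatch(self):
        panel = make_panel([[0], [1], [2]], ref=["A"], alt=["C"])
        _, report = match_variants(panel, [rec("v0", "G", "A")])
        assert report.n_allele_mismatch == 1
        assert report.n_matched == 0

    def test_unmatched_id(self):
        panel = make_panel([[0], [2]])
        _, report = match_variants(panel, [rec("nope")])
        assert report.n_unmatched_id == 1

    def test_duplicate_weight_id_errors_with_name(self):
        panel = make_panel([[0], [2]])
        with pytest.raises(ValueError, match="v0"):
            match_variants(panel, [rec("v0"), rec("v0", "G", "A")])

    def test_pvalue_never_filters(self):
        panel = make_panel([[0], [1], [2]])
        matched, _ = match_variants(panel, [rec("v0", pval=0.999)])
        assert len(matched) == 1


class TestScores:
    def test_unit_weight(self):
        panel = make_panel([[0], [1], [2]])
        matched, _ = match_variants(panel, [rec("v0", beta=1.0)])
        assert np.allclose(compute_scores(panel, matched).raw, [0, 1, 2])

    def test_all_zero_weights_raises_zero_variance(self):
        panel = make_panel([[0], [1], [2]])
        matched, _ = match_variants(panel, [rec("v0", beta=0.0)])
        with pytest.raises(ValueError, match="variance"):
            compute_scores(panel, matched)

    def test_zero_matched_weights_raises(self):
        panel = make_panel([[0], [2]])
        matched, _ = match_variants(panel, [rec("missing")])
        with pytest.raises(ValueError, match="no matched"):
            compute_scores(panel, matched)

    def test_missing_dosage_mean_imputed(self):
        panel = make_panel([[0], [2], [np.nan]])
        matched, _ = match_variants(panel, [rec("v0", beta=1.0)])
        sv = compute_scores(panel, matched)
        assert np.allclose(sv.raw, [0, 2, 1])  # imputed with mean dosage 1

    def test_brute_force_oracle_5x4(self):
        rng = np.random.default_rng(42)
        panel = make_panel(
            rng.integers(0, 3, size=(5, 4)).astype(float),
            ref=["A", "G", "C", "T"],
            alt=["C", "A", "A", "G"],
        )
        records = [
            rec("v0", "C", "A", 0.7),
            rec("v1", "G", "A", -1.2),  # flipped
            rec("v2", "A", "C", 0.3),   # flipped
            rec("v3", "G", "T", 2.0),
        ]
        matched, _ = match_variants(panel, records)
        sv = compute_scores(panel, matched)
        assert np.allclose(sv.raw, oracle_raw_scores(panel, records), atol=0)

    @pytest.mark.parametrize("n,m", [(2, 3), (7, 7), (10, 10), (10, 1), (3, 10)])
    def test_oracle_seeded_panels(self, n, m):
        rng = np.random.default_rng(1000 + 11 * n + m)
        letters = np.array(["A", "C", "G", "T"])
        ref, alt = [], []
        for _ in range(m):
            r = letters[rng.integers(4)]
            choices = [a for a in letters if a != r]
            ref.append(r)
            alt.append(choices[rng.integers(3)])
        panel = make_panel(
            rng.integers(0, 3, size=(n, m)).astype(float), ref=ref, alt=alt
        )
        records = []
        for j in range(m):
            if rng.random() < 0.5:
                ea, oa = alt[j], ref[j]
            else:
                ea, oa = ref[j], alt[j]
            records.append(rec(f"v{j}", ea, oa, float(rng.normal())))
        matched, _ = match_variants(panel, records)
        if len(matched) == 0:
            return
        sv = compute_scores(panel, matched)
        assert np.allclose(sv.raw, oracle_raw_scores(panel, records), atol=1e-12)


class TestProperties:
    def _random_case(self, seed):
        rng = np.random.default_rng(seed)
        panel = make_panel(
            rng.integers(0, 3, size=(20, 6)).astype(float),
            ref=["A", "G", "C", "T", "A", "G"],
            alt=["C", "A", "A", "G", "G", "T"],
        )
        records = [
            rec(f"v{j}", panel.alt[j], panel.ref[j], float(rng.normal()))
            for j in range(6)
        ]
        return panel, records

    def test_orientation_invariance(self):
        panel, records = self._random_case(7)
        flipped = [
            GwasWeightRecord(r.variant_id, r.other_allele, r.effect_allele, -r.beta)
            for r in records
        ]
        a = compute_scores(panel, match_variants(panel, records)[0]).raw
        b = compute_scores(panel, match_variants(panel, flipped)[0]).raw
        # complement-dosage rule: swapping alleles and negating beta shifts
        # each contribution by a sample-independent constant -2*beta
        shift = -2.0 * sum(r.beta for r in records)
        assert np.allclose(b, a + shift)
        assert np.allclose(
            compute_scores(panel, match_variants(panel, records)[0]).std,
            compute_scores(panel, match_variants(panel, flipped)[0]).std,
        )

    def test_record_and_sample_order_invariance(self):
        panel, records = self._random_case(8)
        sv = compute_scores(panel, match_variants(panel, records)[0])
        rev = compute_scores(panel, match_variants(panel, records[::-1])[0])
        assert np.allclose(sv.raw, rev.raw)
        perm = np.random.default_rng(0).permutation(panel.n_samples)
        shuffled = make_panel(
            panel.dosages[perm], ref=panel.ref, alt=panel.alt,
            ids=panel.variant_ids,
        )
        sv2 = compute_scores(shuffled, match_variants(shuffled, records)[0])
        assert np.allclose(sv2.raw, sv.raw[perm])

    def test_zero_beta_weight_never_changes_scores(self):
        panel, records = self._random_case(9)
        base = compute_scores(panel, match_variants(panel, records[:-1])[0]).raw
        records2 = records[:-1] + [
            rec(records[-1].variant_id, records[-1].effect_allele,
                records[-1].other_allele, 0.0)
        ]
        with_zero = compute_scores(panel, match_variants(panel, records2)[0]).raw
        assert np.allclose(base, with_zero)

    def test_standardization_bounds(self):
        panel, records = self._random_case(10)
        sv = compute_scores(panel, match_variants(panel, records)[0])
        assert abs(sv.std.mean()) < 1e-8
        assert abs(sv.std.std(ddof=1) - 1.0) < 1e-8


class TestIO:
    def test_empty_but_headered_weights(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("snp\teffect_allele\tother_allele\tbeta\tse\tpval\n")
        assert read_weights(p) == []

    def test_malformed_allele_reports_line(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(
            "snp\teffect_allele\tother_allele\tbeta\n"
            "rs1\tA\tC\t0.1\n"
            "rs2\tX\tC\t0.2\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_weights(p)

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("snp\teffect_allele\tbeta\nrs1\tA\t0.1\n")
        with pytest.raises(ValueError, match="other_allele"):
            read_weights(p)

    def test_weights_roundtrip(self, tmp_path):
        _, weights, _ = simulate_panel(
            SimConfig(n_samples=5, n_variants=30, weight_noise_sd=0.02, seed=4)
        )
        path = tmp_path / "w.tsv"
        write_weights(weights, path)
        back = read_weights(path)
        assert back == weights

    def test_weights_line_count_matches_records(self, tmp_path):
        _, weights, _ = simulate_panel(SimConfig(n_samples=5, n_variants=25, seed=5))
        path = tmp_path / "w.tsv"
        write_weights(weights, path)
        n_lines = len(path.read_text().splitlines())
        assert n_lines - 1 == len(read_weights(path)) == 25

    def test_non_biallelic_vcf_rejected(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
            "1\t1\trs1\tA\tC,G\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="not biallelic"):
            read_panel(p)


def test_standardize_zero_variance_errors():
    with pytest.raises(ValueError, match="variance"):
        standardize(np.ones(5))
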