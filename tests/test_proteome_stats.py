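"""Perseus-style inference chain and downstream motif/set analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phosprefs import proteome_sim as psim
from phosprefs import proteome_stats as pst


@pytest.fixture(scope="module")
def small_dataset():
    sites, truth = psim.generate_sites(4_000, seed=10)
    matrix, meta = pst.preprocess(sites)
    return sites, truth, matrix, meta


def make_sites(rows):
    """Minimal sites frame from dicts of reporter values."""
    base = {
        "Protein": "P1",
        "Position": 10,
        "Amino acid": "S",
        "Localization prob": 0.99,
        "Sequence window": "AAAAASAAAAA",
        "Reverse": "",
        "Potential contaminant": "",
    }
    out = []
    for row in rows:
        rec = dict(base)
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


class TestPreprocess:
    def test_localization_exactly_at_threshold_removed(self):
        rows = [
            {"Localization prob": 0.75},
            {"Localization prob": 0.76},
        ]
        for r in rows:
            r.update({psim.reporter_column(c, b): 100.0
                      for c in psim.CONDITIONS for b in (1, 2, 3)})
        matrix, meta = pst.preprocess(make_sites(rows))
        assert len(matrix) == 1
        assert meta["Localization prob"].iloc[0] == 0.76

    def test_equal_channels_normalize_to_zero(self):
        row = {psim.reporter_column(c, b): 500.0
               for c in psim.CONDITIONS for b in (1, 2, 3)}
        matrix, _ = pst.preprocess(make_sites([row]))
        assert np.allclose(matrix.to_numpy(), 0.0)

    def test_scale_invariance_within_batch(self, rng):
        vals = {psim.reporter_column(c, b): float(rng.uniform(50, 500))
                for c in psim.CONDITIONS for b in (1, 2, 3)}
        scaled = {
            k: v * (7.0 if k.endswith(" 2") else 1.0) for k, v in vals.items()
        }
        m1, _ = pst.preprocess(make_sites([vals]))
        m2, _ = pst.preprocess(make_sites([scaled]))
        pd.testing.assert_frame_equal(m1, m2)

    def test_row_with_two_valid_values_per_group_removed(self):
        row = {psim.reporter_column(c, b): 100.0
               for c in psim.CONDITIONS for b in (1, 2)}
        # batch 3 entirely missing -> 2 valid per condition
        for c in psim.CONDITIONS:
            row[psim.reporter_column(c, 3)] = np.nan
        matrix, _ = pst.preprocess(make_sites([row]))
        assert matrix.empty

    def test_reverse_and_contaminants_dropped(self):
        rows = []
        for flag in ({}, {"Reverse": "+"}, {"Potential contaminant": "+"}):
            r = {psim.reporter_column(c, b): 100.0
                 for c in psim.CONDITIONS for b in (1, 2, 3)}
            r.update(flag)
            rows.append(r)
        matrix, _ = pst.preprocess(make_sites(rows))
        assert len(matrix) == 1

    def test_missing_reporter_columns_rejected(self):
        with pytest.raises(ValueError):
            pst.preprocess(pd.DataFrame({"Protein": ["P1"]}))


class TestImpute:
    def test_no_missing_values_is_identity(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        m.columns = [f"c_{i}" for i in range(6)]
        pd.testing.assert_frame_equal(pst.impute(m, seed=0), m)

    def test_imputed_distribution_matches_downshift(self, rng):
        observed = rng.normal(20.0, 1.0, size=4_000)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        m = pd.DataFrame({"a_1": col})
        full = pst.impute(m, width=0.3, shift=1.8, seed=1)
        imputed = full["a_1"].to_numpy()[4_000:]
        assert np.mean(imputed) == pytest.approx(20.0 - 1.8, abs=0.1)
        assert np.std(imputed) == pytest.approx(0.3, abs=0.05)

    def test_same_seed_reproducible(self, rng):
        m = pd.DataFrame({"a_1": [1.0, 2.0, np.nan, 3.0, np.nan]})
        pd.testing.assert_frame_equal(pst.impute(m, seed=5), pst.impute(m, seed=5))

    def test_column_with_single_observation_rejected(self):
        m = pd.DataFrame({"a_1": [1.0, np.nan, np.nan]})
        with pytest.raises(ValueError):
            pst.impute(m, seed=0)


class TestS0Ttest:
    def columns(self):
        g1 = ["t_1", "t_2", "t_3"]
        g2 = ["u_1", "u_2", "u_3"]
        return g1, g2

    def test_s0_zero_ranking_matches_classical_t(self, rng):
        g1, g2 = self.columns()
        m = pd.DataFrame(rng.normal(size=(100, 6)), columns=g1 + g2)
        res = pst.s0_ttest(m, g1, g2, s0=0.0, n_perm="all", seed=0)
        t_classic = sps.ttest_ind(
            m[g1].to_numpy(), m[g2].to_numpy(), axis=1
        ).statistic
        order_d = np.argsort(np.abs(res.table["d"].to_numpy()))
        order_t = np.argsort(np.abs(t_classic))
        assert (order_d == order_t).all()

    def test_constant_row_not_significant(self):
        g1, g2 = self.columns()
        m = pd.DataFrame(np.ones((5, 6)), columns=g1 + g2)
        m.iloc[1:] = np.random.default_rng(0).normal(size=(4, 6))
        res = pst.s0_ttest(m, g1, g2, seed=0)
        assert res.table["d"].iloc[0] == 0.0
        assert not bool(res.table["significant"].iloc[0])

    def test_degenerate_groups_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 3)), columns=["a_1", "a_2", "b_1"])
        with pytest.raises(ValueError):
            pst.s0_ttest(m, ["a_1", "a_2"], ["b_1"])

    def test_matches_exhaustive_permutation_oracle(self, rng):
        """q-values from the vectorized path equal a brute-force oracle
        enumerating every informative label split on a 4v4 design."""
        g1 = [f"t_{i}" for i in range(4)]
        g2 = [f"u_{i}" for i in range(4)]
        x = rng.normal(size=(40, 8))
        x[:8, :4] += 3.0  # some real effects
        m = pd.DataFrame(x, columns=g1 + g2)
        s0 = 0.1
        res = pst.s0_ttest(m, g1, g2, s0=s0, n_perm="all", seed=0)

        def d_of(cols_a, cols_b):
            a, b = x[:, cols_a], x[:, cols_b]
            va = a.var(axis=1, ddof=1)
            vb = b.var(axis=1, ddof=1)
            sp = np.sqrt((3 * va + 3 * vb) / 6)
            se = sp * math.sqrt(0.5)
            return (a.mean(axis=1) - b.mean(axis=1)) / (se + s0)

        d_obs = d_of(list(range(4)), list(range(4, 8)))
        null = []
        identity = frozenset(range(4))
        complement = frozenset(range(4, 8))
        for combo in itertools.combinations(range(8), 4):
            if frozenset(combo) in (identity, complement):
                continue
            rest = [i for i in range(8) if i not in combo]
            null.append(np.abs(d_of(list(combo), rest)))
        null = np.array(null)
        q_oracle = np.empty(len(d_obs))
        for i, t in enumerate(np.abs(d_obs)):
            r = (np.abs(d_obs) >= t).sum()
            e = (null >= t).sum() / len(null)
            q_oracle[i] = min(e / r, 1.0)
        # step-up monotonization of the oracle
        order = np.argsort(-np.abs(d_obs))
        q_sorted = np.minimum.accumulate(q_oracle[order][::-1])[::-1]
        q_oracle[order] = q_sorted
        assert np.allclose(res.table["q_value"].to_numpy(), q_oracle)

    def test_null_pipeline_controls_fdr(self):
        """Generate -> preprocess -> impute -> s0 test on a global null:
        the significant fraction stays within the Monte Carlo envelope."""
        called = total = 0
        for seed in range(4):
            params = psim.ProteomeSimParams(
                frac_both=0.0, frac_pp1_only=0.0, frac_pp2_only=0.0
            )
            sites, _ = psim.generate_sites(1_500, params, seed=seed)
            matrix, _ = pst.preprocess(sites)
            full = pst.impute(matrix, seed=seed)
            groups = pst.condition_groups(full.columns)
            res = pst.s0_ttest(
                full, groups["PP1"], groups["untreated"],
                fdr=0.05, n_perm="all", seed=seed,
            )
            called += int(res.table["significant"].sum())
            total += len(res.table)
        mc_se = math.sqrt(0.05 * 0.95 / total)
        assert called / total <= 0.05 + 3 * mc_se


class TestAnovaCluster:
    def test_z_rows_are_standardized(self, small_dataset):
        _, _, matrix, _ = small_dataset
        full = pst.impute(matrix, seed=0)
        ac = pst.anova_cluster(full, fdr=0.01, k=3)
        z = ac.z_matrix.to_numpy()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-12)

    def test_planted_patterns_recovered(self, small_dataset):
        from sklearn.metrics import adjusted_rand_score

        _, truth, matrix, meta = small_dataset
        full = pst.impute(matrix, seed=0)
        ac = pst.anova_cluster(full, fdr=0.01, k=3)
        tr = truth.set_index("Protein").loc[meta["Protein"]]
        pat = tr["pattern"].to_numpy()[np.flatnonzero(ac.significant)]
        assert adjusted_rand_score(pat, ac.labels) >= 0.9

    def test_too_few_significant_rows_rejected(self, rng):
        cols = [f"{c}_{b}" for c in ("u", "p", "q") for b in (1, 2, 3)]
        m = pd.DataFrame(rng.normal(size=(20, 9)), columns=cols)
        with pytest.raises(ValueError):
            pst.anova_cluster(m, fdr=1e-9, k=3)

    def test_cluster_share_arithmetic(self):
        shares = pst.cluster_shares([1361, 777, 663])
        assert shares["percent"].sum() == pytest.approx(100.0)
        assert shares["percent"].tolist() == pytest.approx(
            [48.59, 27.74, 23.67], abs=0.01
        )


class TestSensitivityClasses:
    def res_frame(self, fc, sig):
        return pd.DataFrame({"log2_fc": fc, "significant": sig})

    def test_fc_boundary_is_strict(self):
        r1 = self.res_frame([-1.0, -1.1], [True, True])
        r2 = self.res_frame([0.0, 0.0], [False, False])
        classes = pst.sensitivity_classes(r1, r2, criterion="fc")
        assert classes.tolist() == ["insensitive", "PP1"]

    def test_both_significant_is_both(self):
        r1 = self.res_frame([-2.0], [True])
        r2 = self.res_frame([-2.0], [True])
        assert pst.sensitivity_classes(r1, r2).tolist() == ["both"]

    def test_unknown_criterion_rejected(self):
        r = self.res_frame([0.0], [False])
        with pytest.raises(ValueError):
            pst.sensitivity_classes(r, r, criterion="nope")


class TestPthrEnrichment:
    def test_identical_shares_give_unit_odds(self):
        sens = np.array([True, True, False, False])
        res = np.array(["T", "S", "T", "S"])
        odds, p, _ = pst.pthr_enrichment(sens, res)
        assert odds == pytest.approx(1.0)
        assert p == 1.0

    def test_planted_pthr_boost_detected(self):
        sites, truth = psim.generate_sites(20_000, seed=21)
        matrix, meta = pst.preprocess(sites)
        full = pst.impute(matrix, seed=21)
        groups = pst.condition_groups(full.columns)
        res = pst.s0_ttest(full, groups["PP1"], groups["untreated"], seed=21)
        centers = meta["Amino acid"].to_numpy()
        keep = np.isin(centers, ["S", "T"])
        _, p, _ = pst.pthr_enrichment(
            res.table["significant"].to_numpy()[keep], centers[keep]
        )
        assert p < 0.01


class TestPositionalMatrices:
    def test_identical_sets_give_unit_fold_changes(self):
        wins = ["AAAAASAAAAA", "RKRKRSRKRKR", "EDEDESEDEDE"] * 30
        m = pst.positional_fc_matrix(wins, wins, min_count=25, with_tests=False)
        unmasked = m.table[~m.table["masked"]]
        assert len(unmasked) > 0
        assert np.allclose(unmasked["fold_change"], 1.0)

    def test_count_below_threshold_masked(self):
        sens = ["AAAAASAAAAA"] * 24 + ["RAAAASAAAAA"] * 26
        ins = ["AAAAASAAAAA"] * 50
        m = pst.positional_fc_matrix(sens, ins, min_count=25)
        t = m.table.set_index(["position", "residue"])
        assert bool(t.loc[(-5, "R"), "masked"])  # 26 in sensitive, 0 in insensitive
        assert bool(t.loc[(-5, "A"), "masked"])  # 24 < 25 in sensitive

    def test_relative_abundances_sum_to_one_per_position(self):
        sites, _ = psim.generate_sites(2_000, seed=12)
        wins = sites["Sequence window"].iloc[:1_000].tolist()
        m = pst.positional_fc_matrix(wins[:500], wins[500:], with_tests=False)
        for side in ("rel_sensitive", "rel_insensitive"):
            sums = m.table.groupby("position")[side].sum()
            assert np.allclose(sums, 1.0)

    def test_padding_excluded_from_counts(self):
        wins = ["__AAASAAAAA", "AAAAASAAAAA"]
        counts = pst._window_counts(wins)
        at_minus5 = counts[counts["position"] == -5]
        assert at_minus5["count"].sum() == 1  # only the unpadded window

    def test_differential_matrix_identity_and_swap(self):
        a = ["RKAAASAAAAA"] * 40 + ["AAAAASAAAAA"] * 60
        b = ["RKAAASAAAAA"] * 70 + ["AAAAASAAAAA"] * 30
        m1 = pst.positional_fc_matrix(a, b, min_count=10)
        m2 = pst.positional_fc_matrix(b, a, min_count=10)
        same = pst.differential_positional_matrix(m1, m1)
        ok = same.dropna(subset=["fc_ratio"])
        assert np.allclose(ok["fc_ratio"], 1.0)
        assert not same["flagged"].any()
        ab = pst.differential_positional_matrix(m1, m2).set_index(["position", "residue"])
        ba = pst.differential_positional_matrix(m2, m1).set_index(["position", "residue"])
        prod = (ab["fc_ratio"] * ba["fc_ratio"]).dropna()
        assert np.allclose(prod, 1.0)


class TestFrequencyMatrix:
    def test_single_window_is_one_hot(self):
        freq = pst.frequency_matrix(["RKAAASAAAAA"])
        assert np.allclose(freq.sum(axis=0), 1.0)
        assert freq.loc["R", -5] == 1.0

    def test_columns_sum_to_one(self):
        sites, _ = psim.generate_sites(500, seed=13)
        freq = pst.frequency_matrix(sites["Sequence window"].iloc[:300].tolist())
        assert np.allclose(freq.sum(axis=0), 1.0, atol=1e-9)

    def test_half_split_at_single_differing_position(self):
        freq = pst.frequency_matrix(["AAAAASAAAAA", "RAAAASAAAAA"])
        assert freq.loc["A", -5] == 0.5
        assert freq.loc["R", -5] == 0.5

    def test_pssm_export_roundtrip(self, tmp_path):
        freq = pst.frequency_matrix(["AAAAASAAAAA", "RAAAASAAAAA"])
        path = tmp_path / "m.pssm"
        pst.write_pssm(freq, path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), freq.to_numpy())


class TestMotifFlags:
    @pytest.mark.parametrize(
        "window,has_rxxps,n_basic",
        [
            ("RGRLGSVDSFE", True, 2),   # Arg at -3 (and at -5)
            ("NARSASFSQGT", True, 1),
            ("PSPPQSPRVEE", False, 0),
            ("INKRLSLPADI", False, 2),  # Lys/Arg upstream but no Arg at -3
        ],
    )
    def test_annotated_interaction_windows(self, window, has_rxxps, n_basic):
        assert pst.motif_flags(window) == (has_rxxps, n_basic)

    def test_malformed_window_rejected(self):
        with pytest.raises(ValueError):
            pst.motif_flags("SHORT")


class TestOverlapReport:
    def build(self, n_inter, n_diss, n_rxxps, n_basic):
        interactors = {f"P{i}" for i in range(n_inter)}
        dissociated = {f"P{i}" for i in range(n_diss)}
        rows = []
        for i in range(n_rxxps):
            rows.append({"Protein": f"P{i}", "Sequence window": "AARAASAAAAA"})
        for i in range(n_rxxps, n_rxxps + n_basic):
            rows.append({"Protein": f"P{i}", "Sequence window": "KAAAASAAAAA"})
        return interactors, dissociated, pd.DataFrame(
            rows, columns=["Protein", "Sequence window"]
        )

    def test_printed_percentages(self):
        interactors, dissociated, reg = self.build(108, 56, 21, 11)
        rep = pst.overlap_report(interactors, dissociated, reg)
        assert rep["pct_dissociated"] == 52  # 56 of 108
        assert rep["n_rxxps"] == 21 and rep["n_other_basic"] == 11
        assert rep["pct_basic"] == 57  # (21 + 11) of 56

    def test_zero_dissociated(self):
        interactors, _, reg = self.build(10, 0, 0, 0)
        rep = pst.overlap_report(interactors, set(), reg)
        assert rep["n_dissociated"] == 0
        assert rep["pct_dissociated"] == 0 and rep["pct_basic"] == 0

    def test_empty_interactors_rejected(self):
        with pytest.raises(ValueError):
            pst.overlap_report(set(), set(), pd.DataFrame(columns=["Protein", "Sequence window"]))
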