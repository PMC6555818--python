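"""End-to-end pipeline, external-score comparison, clustering stability."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteopin import (
    PipelineConfig,
    clustering_stability,
    compare_external_scores,
    quantify_proteins,
    run_pipeline,
    weibull_pvalue,
    write_peptide_matrix,
    SimulationConfig,
    simulate_peptide_matrix,
)

from conftest import make_matrix


@pytest.fixture
def bench_tsv(tmp_path, bench_matrix):
    matrix, truth = bench_matrix
    p = tmp_path / "bench.tsv"
    write_peptide_matrix(matrix, p)
    return p, truth


class TestRunPipeline:
    def test_simulated_benchmark_end_to_end(self, tmp_path, bench_tsv):
        path, truth = bench_tsv
        out = tmp_path / "out"
        res = run_pipeline(path, out)
        scores = res["sample_scores"]
        assert len(scores) == 6
        for name in (
            "sample_scores.tsv",
            "ipis_matrix.tsv",
            "null_model.json",
            "degradation_prone.tsv",
        ):
            assert (out / name).exists()
        # PIN strictly decreasing in the degradation fraction
        merged = scores.merge(truth, on="sample").sort_values("fraction")
        assert (np.diff(merged["pin"].to_numpy()) < 0).all()

    def test_deterministic_outputs(self, tmp_path, bench_tsv):
        path, _ = bench_tsv
        run_pipeline(path, tmp_path / "a")
        run_pipeline(path, tmp_path / "b")
        for name in ("sample_scores.tsv", "ipis_matrix.tsv", "degradation_prone.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_flags_recomputable_from_report_files(self, tmp_path):
        matrix, _ = simulate_peptide_matrix(
            SimulationConfig(
                n_proteins=40,
                degradation_fraction=(0.3, 0.0, 0.001, 0.002, 0.0, 0.001, 0.002, 0.0),
                seed=21,
            )
        )
        path = tmp_path / "m.tsv"
        write_peptide_matrix(matrix, path)
        out = tmp_path / "out"
        run_pipeline(path, out)
        report = json.loads((out / "null_model.json").read_text())
        scores = pd.read_csv(out / "sample_scores.tsv", sep="\t")
        if report["fitted"]:
            p = weibull_pvalue(
                scores["pin"].to_numpy(),
                report["scale_lambda"],
                report["shape_k"],
            )
            np.testing.assert_allclose(p, scores["p_value"].to_numpy(), rtol=1e-10)
            np.testing.assert_array_equal(
                scores["degraded"].to_numpy(),
                (p < report["significance"]).astype(int),
            )

    def test_all_fully_tryptic_matrix_scores_one_without_flags(self, tmp_path):
        matrix, _ = simulate_peptide_matrix(
            SimulationConfig(n_proteins=20, degradation_fraction=(0.0,) * 6, seed=2)
        )
        path = tmp_path / "clean.tsv"
        write_peptide_matrix(matrix, path)
        res = run_pipeline(path, tmp_path / "out")
        scores = res["sample_scores"]
        assert (scores["pin"] == 1.0).all()
        assert not scores["degraded"].any()
        assert res["report"]["fitted"] is False  # zero-variance cohort has no null

    def test_unreadable_path_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            run_pipeline(tmp_path / "nope.tsv", tmp_path / "out")

    def test_identity_normalization_option(self, tmp_path, bench_tsv):
        path, truth = bench_tsv
        res = run_pipeline(
            path, tmp_path / "out", config=PipelineConfig(normalize="identity")
        )
        merged = res["sample_scores"].merge(truth, on="sample")
        np.testing.assert_allclose(
            merged["pin"], merged["expected_pin_identity_norm"], atol=1e-12
        )


def brute_force_spearman(x, y):
    """Average-rank Spearman computed from first principles."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


class TestCompareExternalScores:
    def _tables(self, pins, ext, ids=None):
        ids = ids or [f"s{i}" for i in range(len(pins))]
        return (
            pd.DataFrame({"sample": ids, "pin": pins}),
            pd.DataFrame({"sample": ids, "score": ext}),
        )

    def test_perfect_concordance_and_discordance(self):
        pins = [0.91, 0.93, 0.95, 0.97, 0.99]
        rep = compare_external_scores(*self._tables(pins, [1, 2, 3, 4, 5]))
        assert rep.spearman_rho == pytest.approx(1.0)
        rep = compare_external_scores(*self._tables(pins, [5, 4, 3, 2, 1]))
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_ties_match_brute_force_and_scipy(self):
        pins = [0.95, 0.93, 0.93, 0.97, 0.91]
        ext = [0.1, 0.4, 0.2, 0.2, 0.3]
        pin_t, ext_t = self._tables(pins, ext)
        rep = compare_external_scores(pin_t, ext_t)
        assert rep.spearman_rho == pytest.approx(
            brute_force_spearman(pins, ext), abs=1e-12
        )
        ref = stats.spearmanr(pins, ext)
        assert rep.spearman_rho == pytest.approx(ref.statistic, abs=1e-12)
        assert rep.p_method == "exact-permutation"

    def test_exact_permutation_p_small_n(self):
        # n=4: p is the fraction of the 24 pairings at least as extreme
        pins = [0.91, 0.93, 0.95, 0.97]
        ext = [1.0, 2.0, 3.0, 4.0]
        rep = compare_external_scores(*self._tables(pins, ext))
        count = 0
        for perm in itertools.permutations(ext):
            if abs(brute_force_spearman(pins, perm)) >= 1.0 - 1e-12:
                count += 1
        assert rep.spearman_p == pytest.approx(count / 24)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        pins = rng.uniform(0.9, 1.0, 12)
        ext = rng.normal(size=12)
        a = compare_external_scores(*self._tables(pins, ext))
        b = compare_external_scores(*self._tables(np.exp(10 * pins), ext**3))
        assert a.spearman_rho == pytest.approx(b.spearman_rho, abs=1e-12)
        assert a.spearman_p == pytest.approx(b.spearman_p, abs=1e-12)

    def test_t_approximation_for_larger_n(self):
        rng = np.random.default_rng(1)
        pins = rng.uniform(0.9, 1.0, 30)
        ext = pins + rng.normal(0, 0.02, 30)
        rep = compare_external_scores(*self._tables(pins, ext))
        ref = stats.spearmanr(pins, ext)
        assert rep.p_method == "t-approximation"
        assert rep.spearman_p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_unmatched_samples_reported(self):
        pin_t = pd.DataFrame({"sample": ["a", "b", "c", "d"], "pin": [1, 2, 3, 4]})
        ext_t = pd.DataFrame({"sample": ["a", "b", "c", "x"], "score": [1, 2, 3, 4]})
        rep = compare_external_scores(pin_t, ext_t)
        assert rep.n_pairs == 3
        assert rep.unmatched_pin == ["d"]
        assert rep.unmatched_external == ["x"]

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_external_scores(*self._tables([0.9, 0.95], [1, 2]))


class TestClusteringStability:
    def _quant(self):
        rng = np.random.default_rng(5)
        mat = rng.lognormal(8, 1, size=(20, 6))
        return pd.DataFrame(
            mat,
            index=[f"P{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )

    def test_empty_removal_gives_identical_trees(self):
        rep = clustering_stability(self._quant(), [])
        assert rep.cophenetic_r == 1.0
        assert rep.removed_proteins == 0

    def test_zero_variance_protein_removal_keeps_distances(self):
        q = self._quant()
        q.loc["PCONST"] = 1000.0  # constant across samples
        rep = clustering_stability(q, ["PCONST"], log_transform=False)
        assert rep.cophenetic_r == pytest.approx(1.0)

    def test_four_sample_toy_matches_hand_computed_ultrametric(self):
        # two "proteins" place the samples at rectangle corners:
        # d(s1,s2)=d(s3,s4)=3, d(s1,s3)=d(s2,s4)=4, diagonals 5.
        # complete linkage: {s1,s2} at 3, {s3,s4} at 3, joined at 5.
        q = pd.DataFrame(
            {"s1": [0.0, 0.0], "s2": [0.0, 3.0], "s3": [4.0, 0.0], "s4": [4.0, 3.0]},
            index=["PA", "PB"],
        )
        from scipy.cluster.hierarchy import linkage, cophenet
        from scipy.spatial.distance import pdist

        z = linkage(pdist(q.to_numpy().T), method="complete")
        got = cophenet(z)
        # pair order: (s1,s2),(s1,s3),(s1,s4),(s2,s3),(s2,s4),(s3,s4)
        np.testing.assert_allclose(got, [3, 5, 5, 5, 5, 3])
        rep = clustering_stability(q, [], log_transform=False)
        assert rep.cophenetic_r == 1.0

    def test_removing_everything_is_error(self):
        q = self._quant()
        with pytest.raises(ValueError, match="empties"):
            clustering_stability(q, list(q.index))

    def test_quantified_matrix_integration(self, bench_matrix):
        matrix, _ = bench_matrix
        abundance, quant = quantify_proteins(matrix)
        # heavy degradation present, yet most quantifying peptides are fully
        # tryptic (they carry 70%+ of the parent intensity)
        assert quant["is_semi_tryptic"].mean() < 0.5
        rep = clustering_stability(abundance, list(abundance.index[:5]))
        assert -1.0 <= rep.cophenetic_r <= 1.0
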