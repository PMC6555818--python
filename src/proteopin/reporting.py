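"""End-to-end pipeline and comparative reports.

``run_pipeline`` chains the whole workflow — read, annotate, filter,
merge, score, fit the null, flag — and writes the standard output files.
``compare_external_scores`` correlates PIN with an external per-sample
integrity score (e.g. mRIN) by Spearman rank correlation, and
``clustering_stability`` measures how much removing degradation-prone
proteins changes the sample dendrogram (cophenetic correlation).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist

from . import null_model, peptide_io, pin_core

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "ComparisonReport",
    "compare_external_scores",
    "DendrogramStability",
    "clustering_stability",
    "dose_response_r2",
]

logger = logging.getLogger("proteopin")


@dataclass
class PipelineConfig:
    """Tunable thresholds of the end-to-end workflow (defaults as published)."""

    format: str = "wide_tsv"
    missing_policy: str = "na"
    normalize: str = "sqrt"
    proteotypic_only: bool = True
    min_detection_fraction: float = 0.5
    merge_method: str = "mean"
    exclusion_p: float = 0.02
    significance: float = 0.01
    ipis_threshold: float = 0.8
    proline_rule: bool = False
    count_non_tryptic: bool = False
    m_score_cutoff: float | None = None
    max_iterations: int = 50


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("[%s] failed after %.2fs: %s", name, dt, exc)
            else:
                logger.info("[%s] done in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(
    matrix_path: str | Path,
    out_dir: str | Path,
    fasta_path: str | Path | None = None,
    replicate_map: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full integrity-scoring workflow and write report files.

    Writes ``sample_scores.tsv``, ``ipis_matrix.tsv``,
    ``null_model.json`` and ``degradation_prone.tsv`` into *out_dir* and
    returns the results in memory.  Cohorts too small or too uniform for
    a Weibull null (e.g. every PIN exactly 1) are scored without
    P-values, with the reason recorded in ``null_model.json``.
    """
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        matrix = peptide_io.read_peptide_matrix(
            matrix_path, cfg.format, cfg.missing_policy, m_score_cutoff=cfg.m_score_cutoff
        )
    if fasta_path is not None:
        with _stage("annotate"):
            matrix = peptide_io.annotate_from_fasta(
                matrix, fasta_path, proline_rule=cfg.proline_rule
            )
            n_un = matrix.meta.attrs.get("n_unmatched", 0)
            if n_un:
                logger.warning("%d peptides not found in their protein; excluded", n_un)
    with _stage("filter"):
        matrix = peptide_io.apply_cohort_filters(
            matrix, cfg.proteotypic_only, cfg.min_detection_fraction
        )
        filter_log = matrix.meta.attrs.get("filter_log", {})
    if replicate_map is not None or matrix.replicate_map is not None:
        with _stage("merge"):
            matrix = peptide_io.merge_replicates(matrix, cfg.merge_method, replicate_map)

    with _stage("score"):
        result = pin_core.compute_ipis_matrix(
            matrix, cfg.normalize, cfg.count_non_tryptic
        )
        scores = pin_core.compute_sample_scores(result)
        prone = pin_core.degradation_prone_proteins(result, cfg.ipis_threshold)

    model = None
    null_report: dict = {"fitted": False}
    with _stage("null_fit"):
        try:
            model = null_model.fit_null_iterative(
                scores, cfg.exclusion_p, cfg.max_iterations
            )
            null_report = {"fitted": True, **model.to_dict()}
        except ValueError as err:
            null_report["reason"] = str(err)
            logger.warning("null model not fitted: %s", err)
    if model is not None:
        scores = null_model.score_cohort(scores, model, cfg.significance)
    else:
        scores = scores.assign(p_value=np.nan, degraded=False)
    null_report["significance"] = cfg.significance
    null_report["thresholds"] = {
        k: v for k, v in asdict(cfg).items() if not isinstance(v, dict)
    }
    null_report["filter_log"] = filter_log

    ipis_out = result.ipis.copy()
    ipis_out["averaged_ipis"] = result.averaged_ipis
    ipis_out.to_csv(out_dir / "ipis_matrix.tsv", sep="\t", na_rep="NA")
    scores_out = scores.copy()
    if "degraded" in scores_out.columns:
        scores_out["degraded"] = scores_out["degraded"].astype(int)
    scores_out.to_csv(out_dir / "sample_scores.tsv", sep="\t", index=False, na_rep="NA")
    prone_df = pd.DataFrame(
        {"protein": prone, "averaged_ipis": result.averaged_ipis.loc[prone].to_numpy()}
    )
    prone_df.to_csv(out_dir / "degradation_prone.tsv", sep="\t", index=False)
    (out_dir / "null_model.json").write_text(json.dumps(null_report, indent=2))

    return {
        "matrix": matrix,
        "integrity": result,
        "sample_scores": scores,
        "null_model": model,
        "degradation_prone": prone,
        "report": null_report,
    }


# ---------------------------------------------------------------------------
# External-score comparison (Spearman)
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Rank correlation between PIN and an external integrity score."""

    spearman_rho: float
    spearman_p: float
    n_pairs: int
    unmatched_pin: list[str]
    unmatched_external: list[str]
    method: str = "spearman"
    p_method: str = "t-approximation"


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    # Pearson correlation of average ranks (handles ties correctly)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry) / denom


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value: enumerate all n! pairings."""
    n = rx.size
    count = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(range(n)):
        rho = _spearman_rho(rx[list(perm)], ry)
        total += 1
        if abs(rho) >= abs(rho_obs) - tol:
            count += 1
    return count / total


def compare_external_scores(
    pin_table: pd.DataFrame,
    external_table: pd.DataFrame,
    join_key: str = "sample",
    score_column: str = "score",
) -> ComparisonReport:
    """Spearman rank correlation of PIN against an external score.

    *pin_table* needs columns ``sample``/``pin``; *external_table* needs
    the join key plus *score_column* (e.g. mRIN values).  Ties get
    average ranks.  The p-value is an exact permutation test for
    n <= 10 and the t-approximation above that (both two-sided), so
    small-n reports are deterministic.
    """
    merged = pin_table.merge(
        external_table[[join_key, score_column]], on=join_key, how="inner"
    ).dropna(subset=["pin", score_column])
    n = len(merged)
    if n < 3:
        raise ValueError(f"need at least 3 joined sample pairs, got {n}")
    unmatched_pin = sorted(set(pin_table[join_key]) - set(merged[join_key]))
    unmatched_ext = sorted(set(external_table[join_key]) - set(merged[join_key]))

    rx = _average_ranks(merged["pin"].to_numpy(dtype=float))
    ry = _average_ranks(merged[score_column].to_numpy(dtype=float))
    rho = _spearman_rho(rx, ry)

    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
        p_method = "exact-permutation"
    else:
        # t-approximation: t = rho * sqrt((n-2)/(1-rho^2))
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        p_method = "t-approximation"
    return ComparisonReport(
        spearman_rho=rho,
        spearman_p=float(p),
        n_pairs=n,
        unmatched_pin=[str(s) for s in unmatched_pin],
        unmatched_external=[str(s) for s in unmatched_ext],
        p_method=p_method,
    )


# ---------------------------------------------------------------------------
# Dendrogram stability after removing degradation-prone proteins
# ---------------------------------------------------------------------------


@dataclass
class DendrogramStability:
    """Similarity of sample dendrograms with/without a protein set."""

    cophenetic_r: float
    removed_proteins: int
    n_samples: int
    linkage: str
    distance: str
    log_transform: bool


def _sample_tree_distances(
    abundance: pd.DataFrame, method: str, metric: str, log_transform: bool
) -> np.ndarray:
    mat = abundance.to_numpy(dtype=float).T  # samples x proteins
    if log_transform:
        mat = np.log2(mat + 1.0)
    mat = np.nan_to_num(mat, nan=0.0)
    z = linkage(pdist(mat, metric=metric), method=method)
    return cophenet(z)


def clustering_stability(
    quant_matrix: pd.DataFrame,
    degradation_prone: list[str],
    linkage_method: str = "complete",
    metric: str = "euclidean",
    log_transform: bool = True,
) -> DendrogramStability:
    """Cophenetic correlation between full and reduced sample dendrograms.

    Samples are clustered hierarchically (default: complete linkage on
    Euclidean distances of log2-transformed abundances) twice — on the
    full protein × sample *quant_matrix* and on the matrix with the
    *degradation_prone* proteins removed — and the Pearson correlation
    of the two cophenetic-distance vectors is returned.  Missing
    abundances are treated as 0 (undetected) before the log transform.
    """
    if quant_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to build a dendrogram")
    removed = [p for p in degradation_prone if p in quant_matrix.index]
    reduced = quant_matrix.drop(index=removed)
    if reduced.empty:
        raise ValueError("removing the degradation-prone proteins empties the matrix")

    d_full = _sample_tree_distances(quant_matrix, linkage_method, metric, log_transform)
    d_red = _sample_tree_distances(reduced, linkage_method, metric, log_transform)
    if np.allclose(d_full, d_red):
        r = 1.0  # identical trees (also covers zero-variance distance vectors)
    else:
        r = float(np.corrcoef(d_full, d_red)[0, 1])
    return DendrogramStability(
        cophenetic_r=r,
        removed_proteins=len(removed),
        n_samples=quant_matrix.shape[1],
        linkage=linkage_method,
        distance=metric,
        log_transform=log_transform,
    )


def dose_response_r2(dose: np.ndarray, pin: np.ndarray, log10_dose: bool = True) -> float:
    """R^2 of the linear regression of PIN on (log10) protease dose."""
    dose = np.asarray(dose, dtype=float)
    pin = np.asarray(pin, dtype=float)
    x = np.log10(dose) if log10_dose else dose
    res = stats.linregress(x, pin)
    return float(res.rvalue**2)
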