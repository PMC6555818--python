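"""Protein-integrity scoring: per-protein iPIS and per-sample PIN.

For each protein in each sample, the individual Protein Integrity Score
is one minus the fraction of the protein's (normalized) peptide
intensity that is carried by semi-tryptic peptides::

    iPIS = 1 - sum(I_semi) / sum(I_all)

Intensities are square-root-normalized by default, which damps the wide
dynamic range of raw MS signals.  The Proteome Integrity Number of a
sample is the arithmetic mean of the iPIS values of the N proteins
scorable in that sample::

    PIN = sum_i iPIS_i / N

Both scores live in [0, 1]; 1 means no degradation evidence.  Because
iPIS is a ratio of sums that are homogeneous in intensity, both scores
are invariant to rescaling a sample's raw intensities by any positive
constant, so no between-sample abundance normalization is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleavage import CleavageClass
from .peptide_io import PeptideMatrix

__all__ = [
    "normalize_intensity",
    "compute_ipis",
    "compute_ipis_matrix",
    "compute_pin",
    "compute_sample_scores",
    "degradation_prone_proteins",
    "quantify_proteins",
    "IntegrityResult",
    "SampleScore",
]

_SEMI_LABELS = {
    CleavageClass.SEMI_TRYPTIC_NTERM_NONCONFORMING.value,
    CleavageClass.SEMI_TRYPTIC_CTERM_NONCONFORMING.value,
}
_NON_LABEL = CleavageClass.NON_TRYPTIC.value


@dataclass
class SampleScore:
    """Per-sample proteome integrity score."""

    sample_id: str
    pin: float
    n_proteins: int
    p_value: float | None = None
    degraded: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pin <= 1.0:
            raise ValueError(f"PIN {self.pin} outside [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass
class IntegrityResult:
    """Protein × sample iPIS matrix plus cohort-averaged iPIS.

    ``ipis`` is NaN where the protein has no scorable (positive
    normalized intensity) peptide in the sample.  ``averaged_ipis`` is
    the unweighted mean of each protein's defined iPIS values.
    """

    ipis: pd.DataFrame
    averaged_ipis: pd.Series = field(init=False)
    normalization: str = "sqrt"

    def __post_init__(self) -> None:
        vals = self.ipis.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= -1e-12) & (vals <= 1 + 1e-12))
        if not ok.all():
            raise ValueError("iPIS values outside [0, 1]")
        self.averaged_ipis = self.ipis.mean(axis=1, skipna=True)


def normalize_intensity(raw, mode: str = "sqrt"):
    """Normalize raw MS intensity; ``sqrt`` (default) or ``identity``.

    Monotone non-decreasing; vectorized over arrays.
    """
    arr = np.asarray(raw, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("intensities must be non-negative")
    if mode == "sqrt":
        out = np.sqrt(arr)
    elif mode == "identity":
        out = arr
    else:
        raise ValueError(f"unknown normalization {mode!r}")
    return float(out) if np.isscalar(raw) else out


def compute_ipis(
    peptide_intensities,
    mode: str = "sqrt",
    count_non_tryptic: bool = False,
) -> float:
    """iPIS of one protein in one sample from (cleavage_class, raw) pairs.

    Non-tryptic peptides are excluded from both sums by default (a
    semi-tryptic search space never produces them); set
    *count_non_tryptic* to treat them as degradation products.  Returns
    NaN when no peptide carries positive normalized intensity.
    """
    semi = total = 0.0
    for cls, raw in peptide_intensities:
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        if isinstance(cls, str):
            cls = CleavageClass.from_label(cls)
        if cls is CleavageClass.NON_TRYPTIC and not count_non_tryptic:
            continue
        v = normalize_intensity(float(raw), mode)
        total += v
        if cls.is_semi_tryptic or (cls is CleavageClass.NON_TRYPTIC and count_non_tryptic):
            semi += v
    if total <= 0.0:
        return float("nan")
    return 1.0 - semi / total


def compute_ipis_matrix(
    matrix: PeptideMatrix,
    mode: str = "sqrt",
    count_non_tryptic: bool = False,
) -> IntegrityResult:
    """Vectorized iPIS for every (protein, sample) pair of a matrix.

    Every peptide must carry a cleavage class (see
    :func:`~proteopin.peptide_io.annotate_from_fasta`).
    """
    cleav = matrix.meta["cleavage"]
    if cleav.isna().any():
        n = int(cleav.isna().sum())
        raise ValueError(
            f"{n} peptides lack a cleavage class; annotate the matrix first"
        )
    norm = pd.DataFrame(
        normalize_intensity(matrix.intensities.to_numpy(dtype=float), mode),
        index=matrix.intensities.index,
        columns=matrix.intensities.columns,
    )
    if not count_non_tryptic:
        norm = norm[cleav != _NON_LABEL]
    is_semi = cleav.reindex(norm.index).isin(_SEMI_LABELS) | (
        count_non_tryptic & (cleav.reindex(norm.index) == _NON_LABEL)
    )
    prot = matrix.meta["protein"].reindex(norm.index)

    total = norm.groupby(prot).sum(min_count=1)
    semi = norm[is_semi].groupby(prot[is_semi]).sum(min_count=1)
    semi = semi.reindex(total.index).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ipis = 1.0 - semi / total
    ipis = ipis.mask(~(total > 0))  # no positive signal -> undefined
    # proteins whose every peptide was excluded (e.g. all non-tryptic)
    # stay in the result as undefined rows
    all_proteins = sorted(set(matrix.meta["protein"]))
    ipis = ipis.reindex(all_proteins)
    ipis.index.name = "protein"
    return IntegrityResult(ipis=ipis, normalization=mode)


def compute_pin(ipis_column: pd.Series | np.ndarray, sample_id: str = "") -> SampleScore:
    """PIN of one sample: arithmetic mean of its defined iPIS values."""
    vals = np.asarray(ipis_column, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"sample {sample_id!r} has no scorable proteins")
    return SampleScore(sample_id=sample_id, pin=float(vals.mean()), n_proteins=int(vals.size))


def compute_sample_scores(result: IntegrityResult) -> pd.DataFrame:
    """PIN for every sample of an :class:`IntegrityResult`.

    Returns a DataFrame with columns ``sample``, ``pin``, ``n_proteins``
    (``p_value`` is added later by the null model).
    """
    rows = [compute_pin(result.ipis[s], s) for s in result.ipis.columns]
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in rows],
            "pin": [r.pin for r in rows],
            "n_proteins": [r.n_proteins for r in rows],
        }
    )


def degradation_prone_proteins(
    result: IntegrityResult, threshold: float = 0.8
) -> list[str]:
    """Proteins whose cohort-averaged iPIS is strictly below *threshold*.

    Sorted ascending by averaged iPIS (most degradation-prone first).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    avg = result.averaged_ipis.dropna()
    hit = avg[avg < threshold].sort_values(kind="stable")
    return [str(p) for p in hit.index]


def quantify_proteins(matrix: PeptideMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein abundance via the most consistently intense peptide.

    For each protein the single quantifying peptide is the one detected
    in the most samples, ties broken by the higher median intensity (over
    detected cells).  Returns ``(abundance, quantifier)`` where
    *abundance* is protein × sample and *quantifier* records the chosen
    peptide and whether it is semi-tryptic — the basis of the "fraction
    of proteins quantified by semi-tryptic peptides" report.
    """
    inten = matrix.intensities
    detected = inten.notna() & (inten != 0)
    n_det = detected.sum(axis=1)
    med = inten.where(detected).median(axis=1, skipna=True).fillna(0.0)

    order = pd.DataFrame(
        {"protein": matrix.meta["protein"], "n_det": n_det, "med": med},
        index=inten.index,
    )
    # stable sort keeps deterministic ties-beyond-the-tiebreak behaviour
    order = order.sort_values(["n_det", "med"], ascending=False, kind="stable")
    best = order.groupby("protein", sort=True).head(1)

    abundance = inten.loc[best.index].copy()
    abundance.index = pd.Index(best["protein"], name="protein")
    cleav = matrix.meta["cleavage"].reindex(best.index)
    quantifier = pd.DataFrame(
        {
            "protein": best["protein"].to_numpy(),
            "peptide": best.index,
            "n_detected": best["n_det"].to_numpy(),
            "is_semi_tryptic": cleav.isin(_SEMI_LABELS).to_numpy(),
        }
    ).set_index("protein")
    return abundance.sort_index(), quantifier.sort_index()
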