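"""Ground-truth degradation simulator for peptide matrices and cohorts.

The generator emulates the kind of calibration experiment used to
validate proteome-integrity scoring: a set of samples in which a known,
controlled fraction of each sample's peptide intensity mass has been
converted into semi-tryptic truncation products, mimicking treatment
with a low-specificity protease at increasing doses.

Degradation is modeled as **intensity transfer**: in a sample with
degradation fraction ``f``, every fully tryptic peptide hands fraction
``f`` of its raw intensity to one semi-tryptic truncation product of
itself (random interior cut point; one conforming terminus retained).
Mass conservation gives the ground truth a closed form — under identity
normalization every protein's iPIS, and hence the sample PIN, equals
exactly ``1 - f``; under square-root normalization it equals
``1 - sqrt(f) / (sqrt(f) + sqrt(1 - f))``.

Per-sample random streams are split from the master seed, so changing
one sample's fraction never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptide_io import PeptideMatrix
from .cleavage import TERMINUS

__all__ = [
    "SimulationConfig",
    "simulate_peptide_matrix",
    "simulate_cohort_pins",
    "expected_pin",
    "DEFAULT_FRACTION_GRID",
]

#: Default per-sample degradation fractions: a protease dose-response
#: grid from heavy (30% of intensity mass degraded) to near-intact.
DEFAULT_FRACTION_GRID = (0.30, 0.20, 0.10, 0.05, 0.02, 0.01)

_RESIDUES = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P in interiors


@dataclass
class SimulationConfig:
    """Parameters of a simulated degradation experiment.

    Defaults emulate a protease-treatment benchmark: six samples on a
    dose grid of degradation fractions, 200 proteins with 3-8 tryptic
    peptides each, log-normal base intensities spanning a SWATH-like
    dynamic range (ln-mean 11.5, ln-sd 1.5, i.e. roughly 1e3-1e7), mild
    per-sample multiplicative noise, and no missingness.
    """

    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (3, 8)
    degradation_fraction: tuple[float, ...] = DEFAULT_FRACTION_GRID
    intensity_log_mean: float = 11.5
    intensity_log_sd: float = 1.5
    sample_noise_log_sd: float = 0.2
    missing_rate: float = 0.0
    peptide_length: tuple[int, int] = (7, 20)
    ladder_depth: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("peptides_per_protein must be an increasing range >= 1")
        lo, hi = self.peptide_length
        if not 5 <= lo <= hi:
            raise ValueError("peptide_length must be an increasing range >= 5")
        if len(self.degradation_fraction) < 1:
            raise ValueError("at least one sample (degradation fraction) required")
        for f in self.degradation_fraction:
            if not 0 <= f < 1:
                raise ValueError(f"degradation fraction {f} outside [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ladder_depth < 1:
            raise ValueError("ladder_depth must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.degradation_fraction)

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def expected_pin(f: float, mode: str = "identity") -> float:
    """Closed-form ground-truth PIN for degradation fraction *f*.

    ``identity``: 1 - f.  ``sqrt``: 1 - sqrt(f)/(sqrt(f)+sqrt(1-f))
    (sqrt compression up-weights the lower-intensity truncation
    product, so for f < 1/2 the sqrt-normalized PIN lies *below* 1 - f).
    """
    if not 0 <= f < 1:
        raise ValueError("fraction must be in [0, 1)")
    if mode == "identity":
        return 1.0 - f
    if mode == "sqrt":
        if f == 0:
            return 1.0
        rf, rr = np.sqrt(f), np.sqrt(1.0 - f)
        return float(1.0 - rf / (rf + rr))
    raise ValueError(f"unknown normalization {mode!r}")


def simulate_peptide_matrix(
    config: SimulationConfig,
) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Simulate a peptide matrix with known per-sample degradation.

    Returns ``(matrix, truth)`` where *truth* has one row per sample
    with columns ``sample``, ``fraction`` and
    ``expected_pin_identity_norm``.  Deterministic for a given config
    (identical seeds give bit-identical matrices).
    """
    master = np.random.SeedSequence(config.seed)
    layout_rng = np.random.default_rng(master.spawn(1)[0])
    sample_seeds = master.spawn(1 + config.n_samples)[1:]

    lo_p, hi_p = config.peptides_per_protein
    lo_l, hi_l = config.peptide_length
    fracs = np.asarray(config.degradation_fraction, dtype=float)
    any_degradation = bool((fracs > 0).any())

    ids, seqs, prots, prev, nxt, cleav = [], [], [], [], [], []
    parent_base = []  # base intensity per parent peptide
    product_of = []  # parent row index for each truncation-product row

    seen: set[str] = set()
    for p in range(config.n_proteins):
        protein = f"PROT{p + 1:04d}"
        n_pep = int(layout_rng.integers(lo_p, hi_p + 1))
        for _ in range(n_pep):
            # tryptic peptide: K/R-free interior, C-terminal K or R
            while True:
                length = int(layout_rng.integers(lo_l, hi_l + 1))
                body = "".join(layout_rng.choice(_RESIDUES, size=length - 1))
                seq = body + ("K" if layout_rng.random() < 0.5 else "R")
                if seq not in seen:
                    seen.add(seq)
                    break
            parent_idx = len(ids)
            ids.append(f"{seq}_2")
            seqs.append(seq)
            prots.append(protein)
            prev.append("K" if layout_rng.random() < 0.5 else "R")
            nxt.append(str(layout_rng.choice(_RESIDUES)))
            cleav.append("full")
            parent_base.append(
                float(
                    np.exp(
                        layout_rng.normal(
                            config.intensity_log_mean, config.intensity_log_sd
                        )
                    )
                )
            )
            if not any_degradation:
                continue
            for d in range(config.ladder_depth):
                cut = int(layout_rng.integers(2, length - 1))
                tag = f"@{seq}" if config.ladder_depth == 1 else f"@{seq}#{d}"
                if layout_rng.random() < 0.5:
                    # keep the C-terminal (conforming) end: N-side ragged
                    sub = seq[cut:]
                    ids.append(f"{sub}_2{tag}")
                    seqs.append(sub)
                    prev.append(seq[cut - 1])  # interior residue, never K/R
                    nxt.append(nxt[parent_idx])
                    cleav.append("semi_n")
                else:
                    # keep the N-terminal (conforming) end: C-side ragged
                    sub = seq[:cut]
                    ids.append(f"{sub}_2{tag}")
                    seqs.append(sub)
                    prev.append(prev[parent_idx])
                    nxt.append(seq[cut])
                    cleav.append("semi_c")
                prots.append(protein)
                product_of.append(parent_idx)

    n_rows = len(ids)
    parents = np.array(
        [i for i, c in enumerate(cleav) if c == "full"], dtype=int
    )
    products = np.array(
        [i for i, c in enumerate(cleav) if c != "full"], dtype=int
    )
    base = np.zeros(n_rows)
    base[parents] = parent_base

    inten = np.full((n_rows, config.n_samples), np.nan)
    for j, (f, seed) in enumerate(zip(fracs, sample_seeds)):
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.normal(0.0, config.sample_noise_log_sd, size=parents.size))
        parent_total = base[parents] * noise  # peptide signal in this sample
        share = f / config.ladder_depth
        inten[parents, j] = parent_total * (1.0 - f)
        if products.size:
            inten[products, j] = np.repeat(parent_total * share, config.ladder_depth)
        if config.missing_rate > 0:
            mask = rng.random(n_rows) < config.missing_rate
            inten[mask, j] = np.nan

    intensities = pd.DataFrame(inten, index=ids, columns=config.samples)
    meta = pd.DataFrame(
        {
            "sequence": seqs,
            "protein": prots,
            "prev_aa": prev,
            "next_aa": nxt,
            "cleavage": cleav,
            "proteotypic": True,
        },
        index=ids,
    )
    truth = pd.DataFrame(
        {
            "sample": config.samples,
            "fraction": fracs,
            "expected_pin_identity_norm": 1.0 - fracs,
        }
    )
    return PeptideMatrix(intensities, meta), truth


def simulate_cohort_pins(
    n: int,
    scale_lambda: float,
    shape_k: float,
    contaminants=(),
    seed: int = 0,
) -> np.ndarray:
    """Cohort PIN vector: *n* Weibull null draws plus verbatim contaminants.

    Draws from Weibull(scale_lambda, shape_k) truncated to (0, 1] by
    resampling; contaminant values (degraded-sample PINs) are appended
    unchanged.  Deterministic under *seed*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale_lambda <= 0 or shape_k <= 0:
        raise ValueError("Weibull parameters must be positive")
    contaminants = np.asarray(list(contaminants), dtype=float)
    if contaminants.size and ((contaminants <= 0) | (contaminants > 1)).any():
        raise ValueError("contaminant PINs must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        draw = scale_lambda * rng.weibull(shape_k, size=2 * n)
        draw = draw[(draw > 0) & (draw <= 1)]
        out = np.concatenate([out, draw])
    return np.concatenate([out[:n], contaminants])
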