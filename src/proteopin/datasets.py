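"""Reference values from published proteome-degradation experiments.

Two small tables ship with the package for calibration, examples and
regression checks; both are printed summary values, not raw data.

``proteinase_k_benchmark()`` — a published calibration experiment in
which HeLa cell lysate aliquots were treated with a dose series of the
low-specificity protease Proteinase K (six treated samples A-F plus an
untreated control pool) and scored by SWATH-MS.  PIN values drop
monotonically with dose and are strongly linear in log10 dose.

``prostate_cohort_reference()`` — summary statistics of a 68-sample
prostate-tissue cohort scored with the same method: the cohort PIN
distribution, the four samples flagged as degraded (P < 0.01), and the
rank correlation of PIN with an mRNA-integrity score (mRIN) measured on
adjacent tissue.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["proteinase_k_benchmark", "prostate_cohort_reference"]


def proteinase_k_benchmark() -> pd.DataFrame:
    """The Proteinase-K dose-response benchmark (one row per sample).

    Columns: ``sample``, ``proteinase_k_ug_ul`` (protease dose; NaN for
    the untreated control), ``pin`` (published PIN), ``p_value``
    (published degradation P-value under the fitted Weibull null).
    """
    return pd.DataFrame(
        {
            "sample": ["A", "B", "C", "D", "E", "F", "Control"],
            "proteinase_k_ug_ul": [0.0200, 0.0100, 0.0040, 0.0020, 0.0010, 0.0005, None],
            "pin": [0.645, 0.714, 0.850, 0.868, 0.900, 0.933, 0.964],
            "p_value": [3.17e-17, 2.07e-13, 2.73e-6, 2.15e-5, 9.87e-4, 0.039, 0.721],
        }
    )


def prostate_cohort_reference() -> dict:
    """Published summary of the 68-sample prostate-tissue cohort."""
    return {
        "n_samples": 68,
        "pin_mean": 0.953,
        "pin_sd": 0.005,
        "pin_min": 0.937,
        "pin_max": 0.964,
        "degraded_pins": [0.937, 0.940, 0.941, 0.941],
        "degraded_p_values": [9.4e-5, 0.0015, 0.0028, 0.0052],
        "significance": 0.01,
        "n_proteins": 3056,
        "n_proteins_ipis_one": 2384,
        "n_degradation_prone": 149,
        "ipis_threshold": 0.8,
        "spearman_rho_vs_mrin": 0.147,
        "spearman_p_vs_mrin": 0.232,
        "cophenetic_r": 0.94,
        "frac_quantified_by_semi": 0.035,
    }
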