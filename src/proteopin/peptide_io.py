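"""Reading, validation and filtering of quantitative peptide matrices.

The central container is :class:`PeptideMatrix`: a peptide-precursor ×
sample table of raw MS intensities together with per-peptide metadata
(protein assignment, flanking residues, tryptic cleavage class,
proteotypicity).  Two on-disk dialects are supported:

* **wide TSV** — one row per peptide precursor, reserved columns
  ``peptide`` and ``protein`` (plus optional ``sequence``, ``prev_aa``,
  ``next_aa``, ``cleavage``, ``proteotypic``), remaining columns are
  per-sample intensities; missing = empty cell or ``NA``.
* **OpenSWATH/TRIC-style long TSV** — one row per (peptide, run) with
  columns ``ProteinName``, ``FullPeptideName``, ``Intensity`` and
  ``filename``; optional ``m_score`` (cutoff filter) and ``decoy``.

Missing cells mean "not detected by targeted extraction", not a measured
zero, and are excluded from all intensity sums downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cleavage import TERMINUS, CleavageClass, classify_cleavage

__all__ = [
    "PeptideRecord",
    "PeptideMatrix",
    "FormatError",
    "read_peptide_matrix",
    "write_peptide_matrix",
    "annotate_from_fasta",
    "apply_cohort_filters",
    "merge_replicates",
    "strip_modifications",
]

#: Reserved (non-sample) columns of the wide TSV dialect, in output order.
META_COLUMNS = ["sequence", "protein", "prev_aa", "next_aa", "cleavage", "proteotypic"]

_LONG_REQUIRED = ["ProteinName", "FullPeptideName", "Intensity", "filename"]


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


@dataclass
class PeptideRecord:
    """Metadata of one peptide precursor (modified sequence + charge key)."""

    peptide_id: str
    sequence: str
    protein_id: str
    preceding_residue: str | None = None
    following_residue: str | None = None
    cleavage_class: CleavageClass | None = None
    proteotypic: bool = True


_MOD_RE = re.compile(r"\(.*?\)|\[.*?\]|\{.*?\}")
_CHARGE_RE = re.compile(r"[_/](\d{1,2})$")


def strip_modifications(peptide_id: str) -> str:
    """Reduce a precursor key to its bare amino-acid sequence.

    Removes bracketed modification annotations — ``(UniMod:4)``,
    ``[+57.02]``, ``{Carbamidomethyl}`` — a trailing charge suffix
    (``_2`` or ``/2``) and any leading ``.`` separators, then keeps
    alphabetic characters only.

    >>> strip_modifications("AGC(UniMod:4)LK_2")
    'AGCLK'
    """
    s = _CHARGE_RE.sub("", peptide_id)
    s = _MOD_RE.sub("", s)
    return "".join(c for c in s if c.isalpha()).upper()


@dataclass
class PeptideMatrix:
    """Peptide-precursor × sample intensity matrix with peptide metadata.

    Attributes
    ----------
    intensities
        DataFrame indexed by peptide id, one float column per sample;
        NaN marks a missing (undetected) cell.  All present values ≥ 0.
    meta
        DataFrame on the same index with columns ``sequence``,
        ``protein``, ``prev_aa``, ``next_aa``, ``cleavage``,
        ``proteotypic``.  Flanks use ``-`` for a protein terminus and
        NaN when unknown; ``cleavage`` holds the short labels of
        :class:`~proteopin.cleavage.CleavageClass` (or NaN when not yet
        classified).
    replicate_map
        Optional mapping run/column identifier → sample identifier, used
        by :func:`merge_replicates`.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    replicate_map: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic interface -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_peptides(self) -> int:
        return len(self.intensities)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def validate(self) -> None:
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate peptide id {dup!r}")
        if self.intensities.columns.has_duplicates:
            raise ValueError("sample identifiers must be unique")
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensity rows do not match")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta lacks columns: {missing}")
        vals = self.intensities.to_numpy(dtype=float)
        neg = np.nan_to_num(vals, nan=0.0) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative intensity at peptide {self.intensities.index[i]!r}, "
                f"sample {self.intensities.columns[j]!r}"
            )

    def copy(self) -> "PeptideMatrix":
        return PeptideMatrix(
            self.intensities.copy(),
            self.meta.copy(),
            dict(self.replicate_map) if self.replicate_map else None,
        )

    def records(self) -> list[PeptideRecord]:
        """Materialize the metadata as a list of :class:`PeptideRecord`."""
        out = []
        for pid, row in self.meta.iterrows():
            cl = row["cleavage"]
            out.append(
                PeptideRecord(
                    peptide_id=str(pid),
                    sequence=row["sequence"],
                    protein_id=row["protein"],
                    preceding_residue=None if pd.isna(row["prev_aa"]) else row["prev_aa"],
                    following_residue=None if pd.isna(row["next_aa"]) else row["next_aa"],
                    cleavage_class=None if pd.isna(cl) else CleavageClass.from_label(cl),
                    proteotypic=bool(row["proteotypic"]),
                )
            )
        return out


def _finalize_meta(meta: pd.DataFrame) -> pd.DataFrame:
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    meta["proteotypic"] = (
        meta["proteotypic"].fillna(1).astype(float).astype(int).astype(bool)
    )
    return meta[META_COLUMNS]


def read_peptide_matrix(
    path: str | Path,
    format: str = "wide_tsv",
    missing_policy: str = "na",
    m_score_cutoff: float | None = None,
) -> PeptideMatrix:
    """Read a quantitative peptide matrix from TSV.

    Parameters
    ----------
    path
        Input file.
    format
        ``"wide_tsv"`` or ``"openswath_long"`` (see module docstring).
    missing_policy
        ``"na"`` keeps missing cells as NaN (recommended: targeted
        extraction below the FDR cutoff yields absence, not a measured
        zero); ``"zero"`` fills them with 0.
    m_score_cutoff
        Long format only: keep rows with ``m_score`` below this value.

    Notes
    -----
    In the long format, duplicate (peptide, run) entries are aggregated
    by **sum** — charge states and repeated feature rows of one
    precursor key pool their signal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wide_tsv":
        return _read_wide(path, missing_policy)
    if format == "openswath_long":
        return _read_long(path, missing_policy, m_score_cutoff)
    raise ValueError(f"unknown format {format!r}")


def _read_wide(path: Path, missing_policy: str) -> PeptideMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein": str})
    for col in ("peptide", "protein"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    reserved = {"peptide", *META_COLUMNS}
    sample_cols = [c for c in df.columns if c not in reserved]
    if not sample_cols:
        raise FormatError(f"{path.name}: no sample intensity columns found")

    df = df.set_index("peptide")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate peptide row {dup!r}")
    inten = df[sample_cols].astype(float)
    _check_nonnegative(inten, path)
    if missing_policy == "zero":
        inten = inten.fillna(0.0)

    meta = df.drop(columns=sample_cols).copy()
    if "sequence" not in meta.columns:
        meta["sequence"] = [strip_modifications(p) for p in df.index]
    meta = _finalize_meta(meta)
    return PeptideMatrix(inten, meta)


def _read_long(
    path: Path, missing_policy: str, m_score_cutoff: float | None
) -> PeptideMatrix:
    df = pd.read_csv(path, sep="\t")
    for col in _LONG_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    if "decoy" in df.columns:
        df = df[df["decoy"].astype(float) != 1]
    if m_score_cutoff is not None:
        if "m_score" not in df.columns:
            raise FormatError(f"{path.name}: m_score cutoff given but no m_score column")
        df = df[df["m_score"].astype(float) < m_score_cutoff]
    if df.empty:
        raise FormatError(f"{path.name}: no rows left after decoy/m_score filtering")

    bad = df["Intensity"].astype(float) < 0
    if bad.any():
        raise ValueError(
            f"{path.name}: negative intensity at row {int(np.flatnonzero(bad)[0])}"
        )

    # duplicate (peptide, run) rows pool by sum
    inten = df.pivot_table(
        index="FullPeptideName",
        columns="filename",
        values="Intensity",
        aggfunc="sum",
    )
    inten.index.name = None
    inten.columns.name = None
    if missing_policy == "zero":
        inten = inten.fillna(0.0)

    prot = df.groupby("FullPeptideName")["ProteinName"].agg(
        lambda s: sorted(set(s))[0]
    )
    meta = pd.DataFrame(index=inten.index)
    meta["protein"] = prot.reindex(inten.index)
    meta["sequence"] = [strip_modifications(p) for p in inten.index]
    # a ProteinName listing several accessions (e.g. "2/P1/P2") is shared
    nprot = df.groupby("FullPeptideName")["ProteinName"].agg(lambda s: len(set(s)))
    shared = meta["protein"].str.contains("/", regex=False) | (
        nprot.reindex(inten.index) > 1
    )
    meta["proteotypic"] = ~shared
    meta = _finalize_meta(meta)
    # runs are columns; a replicate map may be attached by the caller
    return PeptideMatrix(inten.astype(float), meta)


def _check_nonnegative(inten: pd.DataFrame, path: Path) -> None:
    vals = inten.to_numpy(dtype=float)
    neg = np.nan_to_num(vals, nan=0.0) < 0
    if neg.any():
        i = int(np.argwhere(neg)[0][0])
        raise ValueError(f"{path.name}: negative intensity in row {i} ({inten.index[i]!r})")


def write_peptide_matrix(matrix: PeptideMatrix, path: str | Path) -> None:
    """Write a :class:`PeptideMatrix` in the wide TSV dialect.

    Round-trips bit-exactly through :func:`read_peptide_matrix`.
    """
    out = matrix.meta.copy()
    out["proteotypic"] = out["proteotypic"].astype(int)
    out = pd.concat([out, matrix.intensities], axis=1)
    out.index.name = "peptide"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


# ---------------------------------------------------------------------------
# FASTA annotation
# ---------------------------------------------------------------------------

_UNIPROT_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def normalize_protein_id(header: str) -> str:
    """First whitespace token of a FASTA header, with UniProt
    ``sp|ACC|NAME`` reduced to ``ACC``."""
    token = header.split()[0]
    m = _UNIPROT_RE.match(token)
    return m.group(1) if m else token


_CONFORMITY_RANK = {
    CleavageClass.FULLY_TRYPTIC: 2,
    CleavageClass.SEMI_TRYPTIC_NTERM_NONCONFORMING: 1,
    CleavageClass.SEMI_TRYPTIC_CTERM_NONCONFORMING: 1,
    CleavageClass.NON_TRYPTIC: 0,
}


def annotate_from_fasta(
    matrix: PeptideMatrix,
    fasta: str | Path,
    proline_rule: bool = False,
    drop_unmatched: bool = True,
) -> PeptideMatrix:
    """Fill flanking residues and cleavage classes by FASTA lookup.

    Each peptide sequence is located by exact substring search in its
    assigned protein.  When a peptide occurs several times in the
    protein, the occurrence giving the highest tryptic conformity wins
    (FULLY > SEMI > NON), ties broken by the leftmost position.
    Peptides whose sequence is absent from their assigned protein are
    flagged and, when *drop_unmatched*, removed; the count is recorded
    in the returned matrix's ``meta.attrs['n_unmatched']``.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        seqs[normalize_protein_id(rec.description)] = str(rec.seq).upper()

    meta = matrix.meta.copy()
    for col in ("prev_aa", "next_aa", "cleavage"):
        meta[col] = meta[col].astype(object)
    unmatched: list[str] = []
    for pid, row in meta.iterrows():
        pep = row["sequence"]
        prot = seqs.get(normalize_protein_id(str(row["protein"])))
        hit = None  # (rank, -pos, prev, next, class)
        if prot:
            start = prot.find(pep)
            while start != -1:
                prev = prot[start - 1] if start > 0 else TERMINUS
                end = start + len(pep)
                nxt = prot[end] if end < len(prot) else TERMINUS
                cls = classify_cleavage(pep, prev, nxt, proline_rule=proline_rule)
                key = (_CONFORMITY_RANK[cls], -start)
                if hit is None or key > hit[0]:
                    hit = (key, prev, nxt, cls)
                start = prot.find(pep, start + 1)
        if hit is None:
            unmatched.append(str(pid))
        else:
            meta.at[pid, "prev_aa"] = hit[1]
            meta.at[pid, "next_aa"] = hit[2]
            meta.at[pid, "cleavage"] = hit[3].value

    inten = matrix.intensities
    if drop_unmatched and unmatched:
        meta = meta.drop(index=unmatched)
        inten = inten.drop(index=unmatched)
    out = PeptideMatrix(inten.copy(), meta, matrix.replicate_map)
    out.meta.attrs["n_unmatched"] = len(unmatched)
    out.meta.attrs["unmatched_peptides"] = unmatched
    return out


# ---------------------------------------------------------------------------
# Cohort-level post-identification filters
# ---------------------------------------------------------------------------


def apply_cohort_filters(
    matrix: PeptideMatrix,
    proteotypic_only: bool = True,
    min_detection_fraction: float = 0.5,
) -> PeptideMatrix:
    """Apply the standard post-identification cohort filters.

    1. Keep only proteotypic peptides (uniquely attributable to one
       protein) when *proteotypic_only*.
    2. Keep only proteins detected (any peptide with a present, non-zero
       intensity) in **strictly more than** *min_detection_fraction* of
       the samples — "over 50%" by default.

    Idempotent.  Removal counts are stored in
    ``meta.attrs['filter_log']``.
    """
    if not 0 <= min_detection_fraction <= 1:
        raise ValueError("min_detection_fraction must be in [0, 1]")
    meta, inten = matrix.meta, matrix.intensities
    n0_pep = len(meta)
    if proteotypic_only:
        keep = meta["proteotypic"].astype(bool)
        meta, inten = meta[keep], inten[keep]
    n_nonproteotypic = n0_pep - len(meta)

    detected = inten.notna() & (inten != 0)
    frac = detected.groupby(meta["protein"]).any().mean(axis=1)
    good = set(frac.index[frac > min_detection_fraction])
    keep = meta["protein"].isin(good)
    meta, inten = meta[keep], inten[keep]
    if meta.empty:
        raise ValueError("no proteins pass filters")

    out = PeptideMatrix(inten.copy(), meta.copy(), matrix.replicate_map)
    out.meta.attrs["filter_log"] = {
        "peptides_removed_nonproteotypic": n_nonproteotypic,
        "proteins_removed_low_detection": int(len(frac) - len(good)),
        "peptides_removed_total": n0_pep - len(meta),
        "min_detection_fraction": min_detection_fraction,
    }
    return out


def merge_replicates(
    matrix: PeptideMatrix,
    method: str = "mean",
    replicate_map: Mapping[str, str] | None = None,
) -> PeptideMatrix:
    """Merge technical-replicate runs into samples, cell-wise.

    *method* is one of ``mean``/``sum``/``max``, computed over the
    non-missing replicate values of each cell (a cell missing in one run
    but present in the other takes the present value).  Every run must
    appear in the replicate map.
    """
    rmap = dict(replicate_map) if replicate_map is not None else matrix.replicate_map
    if rmap is None:
        raise ValueError("merge_replicates requires a replicate_map")
    if method not in ("mean", "sum", "max"):
        raise ValueError(f"unknown merge method {method!r}")
    orphans = [run for run in matrix.samples if run not in rmap]
    if orphans:
        raise ValueError(f"runs without replicate mapping: {orphans}")

    groups = matrix.intensities.T.groupby([rmap[run] for run in matrix.samples])
    merged = getattr(groups, method)().T  # skipna per cell
    if method == "sum":
        # pandas sum() turns all-NaN groups into 0; restore missingness
        allna = matrix.intensities.T.groupby(
            [rmap[run] for run in matrix.samples]
        ).agg(lambda s: s.isna().all()).T
        merged = merged.mask(allna.astype(bool))
    merged = merged[sorted(merged.columns)]
    return PeptideMatrix(merged, matrix.meta.copy(), None)
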