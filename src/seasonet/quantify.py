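"""Transcript quantification: TPM, taxon abundance fractions, KO aggregation,
and ERCC-style spike-in calibration to transcripts per liter (TPL).

Conventions
-----------
Expression matrices are pandas DataFrames with transcript (or KO) ids as the
row index and sample ids as columns.  Effective lengths are a Series aligned
to the transcript index.  TPM columns sum to 1e6 over whatever universe of
rows the matrix holds (its "normalization universe").

TPL chain
---------
Spike-ins of known molecular input calibrate a per-sample recovery factor
``k`` (reads per molecule·bp).  A transcript's molecule count in the library
input is ``counts / (k · eff_len)``; that is scaled back up to the whole RNA
extract (rna_yield_ng / library_input_ng), to the whole filter residue
(resuspension_volume_ml / extraction_input_ml), and finally divided by the
liters of seawater filtered, yielding molecules per liter.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: rank names addressing positions in the semicolon-separated lineage string
LINEAGE_RANKS = ("group", "genus", "species")

#: metadata fields needed by the TPL scaling chain
TPL_META_FIELDS = (
    "volume_filtered_l",
    "resuspension_volume_ml",
    "extraction_input_ml",
    "rna_yield_ng",
    "library_input_ng",
)

RARE_LABEL = "rare"
UNANNOTATED_LABEL = "unannotated"


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalize counts to transcripts per million, per sample.

    Per column: rate_i = counts_i / eff_len_i, TPM_i = 1e6 * rate_i / sum(rates).
    All-zero columns stay all-zero.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValidationError(f"effective length missing for rows {missing}")
    nonzero_rows = (counts.to_numpy() > 0).any(axis=1)
    if (lengths.to_numpy()[nonzero_rows] <= 0).any():
        raise ValidationError("non-positive effective length for a row with counts")
    safe_len = lengths.to_numpy(dtype=float).copy()
    safe_len[safe_len <= 0] = 1.0  # rows with zero counts only; value irrelevant
    rates = counts.to_numpy(dtype=float) / safe_len[:, None]
    colsum = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = 1e6 * rates / colsum[None, :]
    tpm[:, colsum == 0] = 0.0
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def split_spikes(
    matrix: pd.DataFrame,
    spike_ids: Iterable[str],
    renormalize_tpm: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a matrix into biological and spike-in rows.

    ``renormalize_tpm`` rescales biological columns back to a 1e6 sum after
    removal (only meaningful for TPM-typed input; harmless no-op semantics
    are the caller's responsibility for count-typed input).
    """
    spike_ids = list(spike_ids)
    present = [s for s in spike_ids if s in matrix.index]
    unknown = sorted(set(spike_ids) - set(present))
    if unknown:
        raise ValidationError(f"spike ids not in matrix: {unknown}")
    spikes = matrix.loc[present]
    bio = matrix.drop(index=present)
    if renormalize_tpm and len(present) and len(bio):
        colsum = bio.sum(axis=0)
        scale = np.where(colsum.to_numpy() > 0, 1e6 / colsum.to_numpy(), 0.0)
        bio = bio * scale
    return bio, spikes


def _lineage_level(annotations: pd.DataFrame, rank: str | int) -> pd.Series:
    """Extract one rank from the semicolon-separated lineage column."""
    if isinstance(rank, str):
        if rank not in LINEAGE_RANKS:
            raise ValidationError(
                f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS} or an index"
            )
        idx = LINEAGE_RANKS.index(rank)
    else:
        idx = int(rank)

    def pick(lineage: object) -> object:
        if not isinstance(lineage, str) or not lineage:
            return np.nan
        parts = lineage.split(";")
        return parts[idx] if idx < len(parts) else np.nan

    return annotations["lineage"].map(pick)


def _month_of(sample_ids: Sequence[str], metadata: pd.DataFrame) -> pd.Series:
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    if "month" in meta.columns:
        months = meta["month"]
    else:
        months = pd.to_datetime(meta["date"]).dt.strftime("%Y-%m")
    return months.reindex(sample_ids)


def relative_fractions(
    tpm: pd.DataFrame,
    annotations: pd.DataFrame,
    rank: str | int = "group",
    min_identity: float = 60.0,
    rare_threshold: float = 0.02,
    by: str = "sample",
    metadata: pd.DataFrame | None = None,
    include_unannotated: bool = False,
) -> pd.DataFrame:
    """Relative abundance fractions of taxonomic groups, per sample or month.

    A transcript counts as annotated when its percent identity is strictly
    greater than ``min_identity`` and it carries a lineage.  Fractions are
    computed over annotated transcripts only; groups whose fraction falls
    strictly below ``rare_threshold`` are pooled into ``"rare"``.  Monthly
    mode pools TPM across each month's samples before normalizing.  With
    ``include_unannotated`` an extra row reports the unannotated share of the
    total TPM (not part of the normalized fraction universe).
    """
    ann = annotations.set_index("transcript_id").reindex(tpm.index)
    level = _lineage_level(ann.reset_index(), rank)
    level.index = tpm.index
    identity = pd.to_numeric(ann["percent_identity"], errors="coerce")
    annotated = level.notna() & (identity > min_identity)

    mat = tpm.copy()
    if by == "month":
        if metadata is None:
            raise ValidationError("monthly fractions require sample metadata")
        months = _month_of(list(tpm.columns), metadata)
        mat = mat.T.groupby(months.to_numpy()).sum().T
    elif by != "sample":
        raise ValidationError(f"by must be 'sample' or 'month', got {by!r}")

    grouped = mat[annotated].groupby(level[annotated].to_numpy()).sum()
    out_cols = {}
    for col in mat.columns:
        total = grouped[col].sum()
        if total <= 0:
            warnings.warn(f"no annotated expression in {col}; fractions are null")
            frac = pd.Series(np.nan, index=grouped.index)
        else:
            frac = grouped[col] / total
        out_cols[col] = frac
    frac_tab = pd.DataFrame(out_cols)

    rare_mask = (frac_tab < rare_threshold) & frac_tab.notna()
    kept = frac_tab.where(~rare_mask, 0.0)
    rare_row = frac_tab.where(rare_mask, 0.0).sum(axis=0)
    kept = kept.loc[(kept > 0).any(axis=1)]
    if (rare_row > 0).any():
        kept.loc[RARE_LABEL] = rare_row

    if include_unannotated:
        unann_share = mat[~annotated].sum(axis=0) / mat.sum(axis=0)
        kept.loc[UNANNOTATED_LABEL] = unann_share
    return kept


def aggregate_ko(tpm: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Sum transcript TPM into a KO x sample matrix; KO-less transcripts drop."""
    ann = annotations.set_index("transcript_id").reindex(tpm.index)
    kos = ann["ko_id"]
    mask = kos.notna() & (kos != "")
    return tpm[mask.to_numpy()].groupby(kos[mask.to_numpy()].to_numpy()).sum()


def estimate_spike_recovery(spike_counts: pd.Series, spikes: pd.DataFrame) -> float:
    """Pooled spike recovery k = Σ counts / Σ (molecules_added · length_bp).

    Units: sequenced reads per (molecule · bp) of spike input.  Pooling over
    all spike species length-weights the estimate, which is robust for the
    small spike sets used in practice.
    """
    tab = spikes.set_index("spike_id") if "spike_id" in spikes.columns else spikes
    tab = tab.reindex(spike_counts.index)
    if tab["molecules_added"].isna().any():
        raise ValidationError("spike truth table missing entries for observed spikes")
    if (tab["molecules_added"] <= 0).any():
        raise ValidationError("molecules_added must be positive")
    total = float(spike_counts.sum())
    if total <= 0:
        raise ValidationError("zero spike reads: sample cannot be calibrated")
    denom = float((tab["molecules_added"] * tab["length_bp"]).sum())
    return total / denom


def estimate_tpl(
    counts: pd.Series,
    lengths: pd.Series,
    k: float,
    meta: pd.Series,
) -> pd.Series:
    """Transcripts per liter for one sample column.

    molecules in library input: counts / (k · eff_len); scaled to the whole
    extract, then to the whole residue, then divided by liters filtered.
    """
    if k <= 0:
        raise ValidationError(f"recovery factor must be positive, got {k}")
    missing = [f for f in TPL_META_FIELDS if f not in meta.index or pd.isna(meta[f])]
    if missing:
        raise ValidationError(f"metadata fields required for TPL missing: {missing}")
    bad = [f for f in TPL_META_FIELDS if float(meta[f]) <= 0]
    if bad:
        raise ValidationError(f"metadata fields must be positive: {bad}")
    lengths = lengths.reindex(counts.index)
    molecules_in_library = counts / (k * lengths)
    extract_scale = float(meta["rna_yield_ng"]) / float(meta["library_input_ng"])
    residue_scale = float(meta["resuspension_volume_ml"]) / float(meta["extraction_input_ml"])
    return molecules_in_library * extract_scale * residue_scale / float(meta["volume_filtered_l"])


def tpl_table(
    counts: pd.DataFrame,
    lengths: pd.Series,
    spikes: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Full transcript x sample TPL table from a count matrix with spike rows."""
    spike_ids = [s for s in spikes["spike_id"] if s in counts.index]
    bio, spike_counts = split_spikes(counts, spike_ids, renormalize_tpm=False)
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    cols = {}
    for sample in counts.columns:
        k = estimate_spike_recovery(spike_counts[sample], spikes)
        cols[sample] = estimate_tpl(bio[sample], lengths, k, meta.loc[sample])
    return pd.DataFrame(cols)
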