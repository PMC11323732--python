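"""Readers and writers for every on-disk artifact, plus the run configuration.

The primary dialect is UTF-8 tab-separated text with ``NA`` for nulls;
count matrices may alternatively be MatrixMarket coordinate files
(1-based) with row/column label sidecars.  Dates are ISO 8601 and the
month key ``YYYY-MM`` is derived from them.  All writers and readers are
mutually inverse on valid data.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .errors import FormatError, ValidationError

NA = "NA"

ANNOTATION_COLUMNS = (
    "transcript_id", "taxon_id", "lineage", "percent_identity", "ko_id", "pfam_ids",
)
METADATA_REQUIRED = ("sample_id", "station", "date")
SPIKE_COLUMNS = ("spike_id", "length_bp", "molecules_added")
PATHWAY_COLUMNS = ("ko_id", "pathway_id", "pathway_name")
_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass
class RunConfig:
    """All thresholds of the analysis plus input locations.

    The threshold defaults are the normative constants of the protocol:
    2% rare pooling, strict >90/>60 identity cuts, TPM<1 zeroing, KO
    aggregate <10 removal, minimum module size 70 with deepSplit 4 and
    eigengene merging at r>0.6, >100-transcript species support, >800
    non-zero PFAMs for trophic eligibility, and FDR 0.05.
    """

    data_dir: str = "."
    out_dir: str = "results"
    rare_fraction: float = 0.02
    identity_strict: float = 90.0
    identity_relaxed: float = 60.0
    tpm_floor: float = 1.0
    ko_min_aggregate: float = 10.0
    min_module_size: int = 70
    merge_cor: float = 0.6
    deep_split: int = 4
    active_bin_min_transcripts: int = 100
    trophic_min_pfams: int = 800
    fdr_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.rare_fraction < 1:
            raise ValidationError("rare_fraction must lie in (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.identity_relaxed >= self.identity_strict:
            raise ValidationError("identity_relaxed must be below identity_strict")
        for name in ("tpm_floor", "ko_min_aggregate", "min_module_size",
                     "merge_cor", "active_bin_min_transcripts", "trophic_min_pfams"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: file is empty")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    return frame


def read_counts(path: str | Path, fmt: str = "tsv") -> tuple[pd.DataFrame, pd.Index]:
    """Read a transcript x sample count/TPM matrix (TSV or MatrixMarket)."""
    path = Path(path)
    if fmt == "mtx":
        rows = Path(str(path).replace(".mtx", "") + ".rows.txt")
        cols = Path(str(path).replace(".mtx", "") + ".cols.txt")
        for p in (path, rows, cols):
            if not p.exists():
                raise FormatError(f"{p}: file not found")
        mat = scipy.io.mmread(path)
        row_labels = rows.read_text().split()
        col_labels = cols.read_text().split()
        frame = pd.DataFrame(
            np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
            index=row_labels, columns=col_labels,
        )
    elif fmt == "tsv":
        raw = _read_tsv(path, ("transcript_id",))
        frame = raw.set_index("transcript_id")
        try:
            frame = frame.astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count entry ({exc})") from exc
    else:
        raise ValidationError(f"unknown counts format {fmt!r}")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row id {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    neg = frame.lt(0)
    if neg.any().any():
        row = neg.any(axis=1).idxmax()
        col = neg.loc[row].idxmax()
        raise FormatError(f"{path}: negative value at ({row}, {col})")
    return frame, frame.index


def write_counts(frame: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        frame.rename_axis("transcript_id").to_csv(path, sep="\t", na_rep=NA)
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(frame.to_numpy()))
        Path(str(path).replace(".mtx", "") + ".rows.txt").write_text(
            "\n".join(map(str, frame.index)) + "\n"
        )
        Path(str(path).replace(".mtx", "") + ".cols.txt").write_text(
            "\n".join(map(str, frame.columns)) + "\n"
        )
    else:
        raise ValidationError(f"unknown counts format {fmt!r}")


def read_transcripts(path: str | Path) -> pd.Series:
    frame = _read_tsv(path, ("transcript_id", "effective_length_bp"))
    lengths = pd.to_numeric(frame["effective_length_bp"], errors="coerce")
    if lengths.isna().any():
        raise FormatError(f"{path}: non-numeric effective length")
    return pd.Series(lengths.to_numpy(), index=frame["transcript_id"],
                     name="effective_length_bp")


def read_annotations(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path, ANNOTATION_COLUMNS)
    identity = pd.to_numeric(frame["percent_identity"], errors="coerce")
    bad = identity.notna() & ((identity < 0) | (identity > 100))
    if bad.any():
        raise ValidationError(
            f"{path}: percent identity outside [0, 100] at line {int(bad.idxmax()) + 2}"
        )
    frame["percent_identity"] = identity
    for col in ("taxon_id", "lineage", "ko_id", "pfam_ids"):
        frame[col] = frame[col].mask(frame[col] == "", np.nan)
    return frame


def read_metadata(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path, METADATA_REQUIRED)
    bad = ~frame["date"].astype(str).str.match(_ISO_DATE)
    if bad.any():
        raise FormatError(
            f"{path}: non-ISO-8601 date {frame.loc[bad, 'date'].iloc[0]!r}"
        )
    for col in frame.columns:
        if col not in ("sample_id", "station", "date"):
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    frame["month"] = pd.to_datetime(frame["date"]).dt.strftime("%Y-%m")
    return frame


def read_spikes(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path, SPIKE_COLUMNS)
    for col in ("length_bp", "molecules_added"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
        if frame[col].isna().any() or (frame[col] <= 0).any():
            raise ValidationError(f"{path}: {col} must be positive numbers")
    return frame


def read_pathway_map(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, PATHWAY_COLUMNS[:2])


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", na_rep=NA, index=index)


def _frame_to_json(frame: pd.DataFrame) -> dict:
    return {
        "index": [str(i) for i in frame.index],
        "columns": [str(c) for c in frame.columns],
        "data": np.asarray(frame, dtype=float).round(10).tolist(),
    }


def _frame_from_json(obj: dict) -> pd.DataFrame:
    return pd.DataFrame(obj["data"], index=obj["index"], columns=obj["columns"])


def write_truth(truth, path: str | Path) -> None:
    """Serialize a SyntheticTruth to JSON (deterministic key order)."""
    payload = {
        "taxon_bloom_schedule": _frame_to_json(truth.taxon_bloom_schedule),
        "ko_module_labels": {k: int(v) for k, v in truth.ko_module_labels.items()},
        "module_latents": _frame_to_json(truth.module_latents),
        "molecules_per_liter": _frame_to_json(truth.molecules_per_liter),
        "expected_counts": _frame_to_json(truth.expected_counts),
        "trophic_labels": dict(truth.trophic_labels),
        "spike_recovery": {k: float(v) for k, v in truth.spike_recovery.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_truth(path: str | Path):
    from .simulate import SyntheticTruth

    with open(path) as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        taxon_bloom_schedule=_frame_from_json(payload["taxon_bloom_schedule"]),
        ko_module_labels=pd.Series(payload["ko_module_labels"], name="module"),
        module_latents=_frame_from_json(payload["module_latents"]),
        molecules_per_liter=_frame_from_json(payload["molecules_per_liter"]),
        expected_counts=_frame_from_json(payload["expected_counts"]),
        trophic_labels=pd.Series(payload["trophic_labels"], name="trophic"),
        spike_recovery=pd.Series(payload["spike_recovery"], name="k"),
    )


def write_dataset(dataset, out_dir: str | Path) -> None:
    """Write a SyntheticDataset in the standard artifact layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(dataset.counts, out / "counts.tsv")
    write_table(
        dataset.lengths.rename_axis("transcript_id").reset_index(),
        out / "transcripts.tsv",
    )
    write_table(dataset.annotations, out / "annotations.tsv")
    write_table(dataset.metadata, out / "metadata.tsv")
    write_table(dataset.spikes, out / "spikes.tsv")
    write_table(dataset.pathways, out / "pathways.tsv")
    write_truth(dataset.truth, out / "truth.json")


def read_dataset(data_dir: str | Path):
    """Read the artifact layout back into a SyntheticDataset-shaped bundle."""
    from .simulate import SyntheticDataset

    d = Path(data_dir)
    counts, _ = read_counts(d / "counts.tsv")
    truth = read_truth(d / "truth.json") if (d / "truth.json").exists() else None
    return SyntheticDataset(
        counts=counts,
        lengths=read_transcripts(d / "transcripts.tsv"),
        annotations=read_annotations(d / "annotations.tsv"),
        metadata=read_metadata(d / "metadata.tsv"),
        spikes=read_spikes(d / "spikes.tsv"),
        pathways=read_pathway_map(d / "pathways.tsv"),
        truth=truth,
    )
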