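"""Trophic-mode classification of species-level transcript bins.

Protocol: transcripts with taxonomic identity strictly above 90% are
binned to species; per bin and sample, PFAM expression profiles are built
by summing TPM over transcripts carrying each PFAM.  Only profiles with
strictly more than 800 non-zero PFAMs are eligible for prediction.
Profiles are restricted to the training feature union, missing features
are imputed with zero, values are MinMax-scaled with the scaler fitted on
the training set (out-of-range values clip to [0, 1] by default), and a
pluggable classifier (gradient-boosted trees by default) predicts
phototroph vs heterotroph.  Monthly consensus labels are majority votes
over the month's eligible sample predictions, with exact ties reported as
"ambiguous".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

AMBIGUOUS = "ambiguous"
INELIGIBLE = "ineligible"


def build_species_profiles(
    tpm: pd.DataFrame,
    annotations: pd.DataFrame,
    min_identity: float = 90.0,
    presence: bool = False,
) -> pd.DataFrame:
    """PFAM expression profiles per (species bin, sample).

    A transcript carrying several PFAMs contributes its full TPM to each
    of them.  Returns a wide frame indexed by (bin, sample) with PFAM
    columns; ``presence`` swaps TPM sums for 0/1 indicators.
    """
    ann = annotations.set_index("transcript_id").reindex(tpm.index)
    identity = pd.to_numeric(ann["percent_identity"], errors="coerce")
    keep = (
        ann["taxon_id"].notna()
        & (identity > min_identity)
        & ann["pfam_ids"].notna()
        & (ann["pfam_ids"] != "")
    )
    if not keep.any():
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["bin", "sample"])
        )
    sub = tpm[keep.to_numpy()]
    pfams = ann.loc[keep, "pfam_ids"].str.split(",")
    bins = ann.loc[keep, "taxon_id"]
    long = (
        sub.assign(_bin=bins.to_numpy(), _pfam=pfams.to_numpy())
        .explode("_pfam")
        .groupby(["_bin", "_pfam"])
        .sum()
    )
    # long: (bin, pfam) x sample -> (bin, sample) x pfam
    profiles = long.stack(future_stack=True).unstack("_pfam").fillna(0.0)
    profiles.index.names = ["bin", "sample"]
    if presence:
        profiles = (profiles > 0).astype(float)
    return profiles


def count_nonzero_pfams(profiles: pd.DataFrame) -> pd.Series:
    return (profiles > 0).sum(axis=1).rename("n_nonzero_pfams")


def gate_profiles(profiles: pd.DataFrame, min_nonzero: int = 800) -> pd.Series:
    """Eligibility mask: strictly more than ``min_nonzero`` non-zero PFAMs."""
    return (count_nonzero_pfams(profiles) > min_nonzero).rename("eligible")


@dataclass
class MinMaxScaler:
    """Per-feature min-max scaler fitted on training profiles.

    Features with zero training range scale to 0 (with a warning at fit
    time); application imputes missing features with 0 before scaling and
    clips to [0, 1] unless disabled.
    """

    features: list[str]
    data_min: np.ndarray
    data_max: np.ndarray
    clip: bool = True


def fit_scaler(training: pd.DataFrame, clip: bool = True) -> MinMaxScaler:
    if training.empty:
        raise ValidationError("training set must be non-empty")
    lo = training.min(axis=0).to_numpy(dtype=float)
    hi = training.max(axis=0).to_numpy(dtype=float)
    if (hi == lo).any():
        import warnings

        warnings.warn(
            f"{int((hi == lo).sum())} features have zero training range; "
            "they scale to 0"
        )
    return MinMaxScaler(list(training.columns), lo, hi, clip)


def apply_scaler(scaler: MinMaxScaler, profiles: pd.DataFrame) -> pd.DataFrame:
    """Subset to the training feature union, impute zeros, scale, clip."""
    x = profiles.reindex(columns=scaler.features).fillna(0.0).to_numpy(dtype=float)
    span = scaler.data_max - scaler.data_min
    safe = np.where(span == 0, 1.0, span)
    scaled = (x - scaler.data_min) / safe
    scaled[:, span == 0] = 0.0
    if scaler.clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return pd.DataFrame(scaled, index=profiles.index, columns=scaler.features)


class TrophicClassifier:
    """Thin wrapper giving any fit/predict estimator a stable label interface."""

    def __init__(self, model, classes: list[str]):
        self.model = model
        self.classes = classes

    def predict(self, scaled: pd.DataFrame) -> pd.Series:
        codes = self.model.predict(scaled.to_numpy(dtype=float))
        labels = [self.classes[int(c)] for c in np.asarray(codes).ravel()]
        return pd.Series(labels, index=scaled.index, name="label")


def train_classifier(
    scaled_training: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    model=None,
) -> TrophicClassifier:
    """Fit the (pluggable) trophic classifier; default gradient-boosted trees."""
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("training labels must contain at least 2 classes")
    y = labels.map({c: i for i, c in enumerate(classes)}).to_numpy()
    if model is None:
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.2,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    model.fit(scaled_training.to_numpy(dtype=float), y)
    return TrophicClassifier(model, classes)


def monthly_consensus(predictions: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote consensus per (bin, month) over eligible predictions.

    ``predictions`` needs columns bin, month, label; rows labelled
    ineligible are excluded from the vote, exact ties become "ambiguous",
    and bin-months with no eligible prediction emit no row.
    """
    rows = []
    for (bin_id, month), grp in predictions.groupby(["bin", "month"]):
        votes = [l for l in grp["label"] if l not in (INELIGIBLE, AMBIGUOUS)]
        if not votes:
            continue
        counts = Counter(votes).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            label = AMBIGUOUS
        else:
            label = counts[0][0]
        rows.append({"bin": bin_id, "month": month, "label": label})
    return pd.DataFrame(rows, columns=["bin", "month", "label"])


def predict_trophic_modes(
    tpm: pd.DataFrame,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    training_profiles: pd.DataFrame,
    training_labels: pd.Series,
    min_identity: float = 90.0,
    min_nonzero_pfams: int = 800,
    seed: int = 0,
    model=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full protocol: profiles -> gate -> scale -> classify -> consensus.

    Returns (per-sample predictions, monthly consensus).  Ineligible
    species-samples appear in the prediction table with the "ineligible"
    label.
    """
    profiles = build_species_profiles(tpm, annotations, min_identity)
    if profiles.empty:
        empty = pd.DataFrame(columns=["bin", "sample", "month", "label"])
        return empty, pd.DataFrame(columns=["bin", "month", "label"])
    scaler = fit_scaler(training_profiles)
    clf = train_classifier(apply_scaler(scaler, training_profiles), training_labels,
                           seed=seed, model=model)
    eligible = gate_profiles(profiles, min_nonzero_pfams)
    labels = pd.Series(INELIGIBLE, index=profiles.index, dtype=object)
    if eligible.any():
        scaled = apply_scaler(scaler, profiles.loc[eligible])
        labels.loc[eligible] = clf.predict(scaled)
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    months = pd.to_datetime(meta["date"]).dt.strftime("%Y-%m")
    preds = labels.rename("label").reset_index()
    preds["month"] = preds["sample"].map(months)
    consensus = monthly_consensus(preds)
    return preds[["bin", "sample", "month", "label"]], consensus
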