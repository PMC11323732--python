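"""Functional and active-species richness, and the associated hypothesis tests.

Functional richness of a sample is its number of unique expressed KO
identifiers; active species richness counts species-level taxonomic bins
(identity strictly above 90%) that pass a global support filter (more than
100 transcripts with non-zero expression in at least one sample) and are
present in the sample.  The ANOVA, Kruskal-Wallis and Pearson tests used
on these quantities report p-values through the package's own tail
routines (:mod:`seasonet.tails`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .tails import chi2_sf, f_sf, t_sf


@dataclass
class TestResult:
    """A named test statistic with degrees of freedom and p-value."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float


def functional_richness(ko_tpm: pd.DataFrame, floor: float = 0.0) -> pd.Series:
    """Unique expressed KOs per sample (expression strictly above ``floor``)."""
    return (ko_tpm > floor).sum(axis=0).rename("functional_richness")


def active_species_richness(
    tpm: pd.DataFrame,
    annotations: pd.DataFrame,
    min_identity: float = 90.0,
    min_transcripts: int = 100,
) -> pd.Series:
    """Per-sample count of retained species bins present in the sample.

    A bin is retained globally when, in at least one sample, strictly more
    than ``min_transcripts`` of its >``min_identity``-identity transcripts
    have non-zero expression; a retained bin is present in a sample when at
    least one of its transcripts is non-zero there.
    """
    ann = annotations.set_index("transcript_id").reindex(tpm.index)
    identity = pd.to_numeric(ann["percent_identity"], errors="coerce")
    eligible = ann["taxon_id"].notna() & (identity > min_identity)
    if not eligible.any():
        return pd.Series(0, index=tpm.columns, name="active_species_richness")
    nonzero = (tpm[eligible.to_numpy()] > 0).groupby(
        ann.loc[eligible, "taxon_id"].to_numpy()
    ).sum()
    retained = nonzero.max(axis=1) > min_transcripts
    presence = nonzero.loc[retained] >= 1
    return presence.sum(axis=0).rename("active_species_richness")


def one_way_anova(groups: list[list[float]]) -> TestResult:
    """One-way fixed-effects ANOVA; p from the F upper tail."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2 or any(a.size == 0 for a in arrays):
        raise ValidationError("ANOVA needs at least 2 non-empty groups")
    n_total = sum(a.size for a in arrays)
    if n_total <= k:
        raise ValidationError("ANOVA needs more observations than groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        raise ValidationError("zero pooled within-group variance: F undefined")
    f = (ss_between / df1) / (ss_within / df2)
    return TestResult("anova_F", float(f), (df1, df2), f_sf(f, df1, df2))


def kruskal_wallis(groups: list[list[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p via chi-squared upper tail."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2 or any(a.size == 0 for a in arrays):
        raise ValidationError("Kruskal-Wallis needs at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    if n < k + 1:
        raise ValidationError("Kruskal-Wallis needs at least k+1 observations")
    if np.all(pooled == pooled[0]):
        raise ValidationError("all observations identical: H undefined")
    ranks = rankdata(pooled)
    grand = (n + 1) / 2.0
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += a.size * (r.mean() - grand) ** 2
        start += a.size
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(ranks, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    h /= correction
    return TestResult("kruskal_H", float(h), (k - 1,), chi2_sf(h, k - 1))


def pearson_cor_test(
    x: np.ndarray | list,
    y: np.ndarray | list,
    log_transform: str = "none",
) -> TestResult:
    """Pearson correlation with a two-sided p from the t transform (df = n-2).

    ``log_transform='log10p1'`` applies log10(x+1) to both variables first,
    the transform used for abundance covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("correlation needs matched samples with n >= 3")
    if log_transform == "log10p1":
        x = np.log10(x + 1.0)
        y = np.log10(y + 1.0)
    elif log_transform != "none":
        raise ValidationError(f"unknown transform {log_transform!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = x.size - 2
    if abs(r) >= 1.0:
        return TestResult("pearson_r", r, (df,), 0.0)
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    return TestResult("pearson_r", r, (df,), 2.0 * t_sf(t, df))


def pearson_p_from_r(r: float, df: int) -> float:
    """Two-sided p for a given correlation and residual df (n-2)."""
    if df < 1:
        raise ValidationError("df must be >= 1")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    return 2.0 * t_sf(t, df)


def richness_table(
    ko_tpm: pd.DataFrame,
    tpm: pd.DataFrame,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    ko_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-sample richness summary joined with month and station."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    months = pd.to_datetime(meta["date"]).dt.strftime("%Y-%m")
    out = pd.DataFrame(
        {
            "functional_richness": functional_richness(ko_tpm, ko_floor),
            "active_species_richness": active_species_richness(tpm, annotations),
        }
    )
    out["month"] = months.reindex(out.index)
    out["station"] = meta["station"].reindex(out.index)
    return out
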