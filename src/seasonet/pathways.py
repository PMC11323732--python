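"""Pathway association by ranked module membership, and pathway expression
attribution to taxa.

A pathway is "characteristic" of a module when its member KOs sit nearer
the top of the module-membership ranking than expected by chance, assessed
with a one-sided Mann-Whitney U test and Benjamini-Hochberg FDR control
across pathways.  Pathway expression totals collect the TPM of every
transcript whose KO belongs to the pathway, split into taxonomically
annotated (>90% identity) and taxon-attributed subtotals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .tails import norm_sf

EXACT_LIMIT = 12  # exact U enumeration up to this combined sample size


@dataclass
class PathwayMap:
    """KO -> pathways membership plus pathway display names."""

    ko_to_pathways: dict[str, frozenset[str]]
    names: dict[str, str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayMap":
        ko_map: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in frame.itertuples(index=False):
            ko_map.setdefault(row.ko_id, set()).add(row.pathway_id)
            if getattr(row, "pathway_name", None) is not None:
                names[row.pathway_id] = row.pathway_name
        return cls(
            {k: frozenset(v) for k, v in ko_map.items()},
            names,
        )

    @property
    def pathway_ids(self) -> list[str]:
        out: set[str] = set()
        for ps in self.ko_to_pathways.values():
            out |= ps
        return sorted(out)

    def members(self, pathway_id: str) -> set[str]:
        return {k for k, ps in self.ko_to_pathways.items() if pathway_id in ps}


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    u_x = r_x - len(x) * (len(x) + 1) / 2.0
    return u_x, ranks


def _exact_p(ranks: np.ndarray, n_x: int, u_obs: float, alternative: str) -> float:
    """Exact U-null by enumerating all assignments of the (mid)ranks to x."""
    n = len(ranks)
    offset = n_x * (n_x + 1) / 2.0
    us = np.array(
        [sum(c) - offset for c in combinations(ranks, n_x)]
    )
    eps = 1e-9
    upper = float((us >= u_obs - eps).mean())
    lower = float((us <= u_obs + eps).mean())
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    return min(1.0, 2.0 * min(upper, lower))


def mann_whitney_u(
    x: np.ndarray | list,
    y: np.ndarray | list,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test with midranks for ties.

    Returns (U of x, p).  The p-value comes from exact enumeration when the
    combined sample size is at most 12, otherwise from the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    u_x, ranks = _u_statistic(x, y)
    if n <= EXACT_LIMIT:
        return u_x, _exact_p(ranks, n_x, u_x, alternative)
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    mu = n_x * n_y / 2.0
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return u_x, 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (u_x - mu - 0.5) / sd
        p = norm_sf(z)
    elif alternative == "less":
        z = (u_x - mu + 0.5) / sd
        p = 1.0 - norm_sf(z)
    else:
        z = (abs(u_x - mu) - 0.5) / sd
        p = 2.0 * norm_sf(max(z, 0.0))
    return u_x, float(min(max(p, 0.0), 1.0))


def bh_adjust(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def pathway_rank_test(
    membership: pd.Series,
    pathway_map: PathwayMap,
    fdr: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Rank-based pathway association for one module.

    KOs are ranked by decreasing module membership; each pathway's member
    memberships are compared against all other KOs' with a one-sided
    Mann-Whitney U (members nearer the top).  q-values are BH-adjusted
    across pathways within the module.
    """
    membership = membership.dropna()
    kos = set(membership.index)
    rows = []
    for pid in pathway_map.pathway_ids:
        members = pathway_map.members(pid) & kos
        if not members:
            rows.append(
                {"pathway_id": pid, "U": np.nan, "p": np.nan,
                 "n_in": 0, "n_out": len(kos), "note": "no retained KO"}
            )
            continue
        outside = kos - members
        if not outside:
            rows.append(
                {"pathway_id": pid, "U": np.nan, "p": np.nan,
                 "n_in": len(members), "n_out": 0, "note": "empty complement"}
            )
            continue
        u, p = mann_whitney_u(
            membership.loc[sorted(members)].to_numpy(),
            membership.loc[sorted(outside)].to_numpy(),
            alternative=alternative,
        )
        rows.append(
            {"pathway_id": pid, "U": u, "p": p,
             "n_in": len(members), "n_out": len(outside), "note": ""}
        )
    table = pd.DataFrame(rows).set_index("pathway_id")
    tested = table["p"].notna()
    table["q"] = np.nan
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["significant"] = table["q"] < fdr
    table["pathway_name"] = [pathway_map.names.get(p, "") for p in table.index]
    return table


def pathway_expression(
    tpm: pd.DataFrame,
    annotations: pd.DataFrame,
    pathway_map: PathwayMap,
    pathway_id: str,
    taxon_of_interest: str | None = None,
    rank: str | int = "genus",
    min_identity: float = 90.0,
    by: str = "sample",
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-period expression totals for one pathway.

    ``total`` sums TPM of every transcript whose KO belongs to the pathway
    (a KO in several pathways contributes its transcripts' full TPM to
    each); ``annotated`` is the subtotal with taxonomic identity strictly
    above ``min_identity``; ``attributed`` is the subtotal assigned to the
    named taxon at the given lineage rank.
    """
    from .quantify import _lineage_level, _month_of  # local to avoid cycle

    if pathway_id not in pathway_map.pathway_ids:
        raise ValidationError(f"unknown pathway id {pathway_id!r}")
    members = pathway_map.members(pathway_id)
    ann = annotations.set_index("transcript_id").reindex(tpm.index)
    in_pathway = ann["ko_id"].isin(members).to_numpy()
    identity = pd.to_numeric(ann["percent_identity"], errors="coerce")
    annotated = in_pathway & (identity > min_identity).to_numpy() & ann["lineage"].notna().to_numpy()
    level = _lineage_level(ann.reset_index(), rank)
    level.index = tpm.index
    attributed = annotated & (level == taxon_of_interest).to_numpy()

    mat = tpm
    if by == "month":
        if metadata is None:
            raise ValidationError("monthly totals require sample metadata")
        months = _month_of(list(tpm.columns), metadata)
        mat = tpm.T.groupby(months.to_numpy()).sum().T
        # recompute masks on the same row universe (rows unchanged)
    elif by != "sample":
        raise ValidationError(f"by must be 'sample' or 'month', got {by!r}")

    return pd.DataFrame(
        {
            "total": mat[in_pathway].sum(axis=0),
            "annotated": mat[annotated].sum(axis=0),
            "attributed": mat[attributed].sum(axis=0),
        }
    )
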