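"""Weighted co-expression modules of KEGG KO identifiers.

The pipeline follows the canonical weighted-network recipe: filter and
log-transform the KO x sample TPM matrix, flag outlier samples by scaled
connectivity, pick the smallest soft-thresholding power that achieves an
approximately scale-free topology, raise absolute Pearson correlations to
that power (unsigned adjacency), refine with topological overlap, cluster
with average linkage, cut the tree (static cut plus bounded recursive
re-splitting controlled by ``deep_split``), dissolve undersized clusters,
reassign stray KOs by module membership, and merge modules whose
eigengenes correlate above ``merge_cor``.  Eigengenes are first principal
components of standardized module expression, sign-oriented to correlate
positively with their members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import InsufficientDataError, ValidationError
from .pathways import bh_adjust
from .tails import t_sf

UNASSIGNED = 0  # the "grey" label


@dataclass
class NetConfig:
    """Tunables of the module-detection pipeline (defaults are normative)."""

    tpm_floor: float = 1.0
    ko_min_aggregate: float = 10.0
    log_base: float = 2.0
    outlier_z: float = -2.5
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    scalefree_r2: float = 0.85
    n_connectivity_bins: int = 10
    adjacency_mode: str = "unsigned"
    use_tom: bool = True
    min_module_size: int = 70
    deep_split: int = 4
    cut_height_quantile: float = 0.98
    merge_cor: float = 0.6
    reassign_mm: float = 0.3

    def __post_init__(self) -> None:
        if not self.candidate_powers or list(self.candidate_powers) != sorted(
            self.candidate_powers
        ):
            raise ValidationError("candidate_powers must be non-empty and ascending")
        if not 0 <= self.deep_split <= 4:
            raise ValidationError("deep_split must lie in 0..4")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")
        if not 0 < self.cut_height_quantile <= 1:
            raise ValidationError("cut_height_quantile must lie in (0, 1]")
        if self.adjacency_mode != "unsigned":
            raise ValidationError("only unsigned adjacency is supported")


@dataclass
class ModuleSet:
    """Result bundle of the module pipeline."""

    labels: pd.Series               # KO -> module id (0 = unassigned)
    eigengenes: pd.DataFrame        # module x sample
    membership: pd.DataFrame        # KO x module correlation
    soft_power: int
    power_fit: pd.DataFrame
    merge_history: list = field(default_factory=list)
    outlier_samples: pd.DataFrame | None = None
    explained_variance: dict = field(default_factory=dict)


def preprocess_ko(ko_tpm: pd.DataFrame, cfg: NetConfig | None = None) -> pd.DataFrame:
    """Floor low TPM to zero, drop weakly expressed KOs, log-transform.

    Entries below ``tpm_floor`` are set to 0; rows whose total (after
    flooring) is below ``ko_min_aggregate`` are removed; remaining values
    become log2(x + 1).
    """
    cfg = cfg or NetConfig()
    x = ko_tpm.where(ko_tpm >= cfg.tpm_floor, 0.0)
    kept = x[x.sum(axis=1) >= cfg.ko_min_aggregate]
    if kept.shape[0] < 3 or kept.shape[1] < 3:
        raise InsufficientDataError(
            f"only {kept.shape[0]} KOs x {kept.shape[1]} samples survive filtering"
        )
    return np.log(kept + 1.0) / np.log(cfg.log_base)


def _row_correlations(expr: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows; constant rows correlate 0."""
    sd = expr.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant rows; correlations set to 0")
    centered = expr - expr.mean(axis=1, keepdims=True)
    safe_sd = np.where(constant, 1.0, sd)
    z = centered / safe_sd[:, None]
    cor = z @ z.T / expr.shape[1]
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def flag_outlier_samples(expr: pd.DataFrame, cfg: NetConfig | None = None) -> pd.DataFrame:
    """Standardized sample connectivity Z and outlier flags (Z < outlier_z).

    Connectivity of a sample is its summed Pearson correlation with every
    other sample over KO profiles.
    """
    cfg = cfg or NetConfig()
    if expr.shape[1] < 4:
        raise ValidationError("outlier detection needs at least 4 samples")
    cor = _row_correlations(expr.to_numpy().T)
    k = cor.sum(axis=1) - 1.0
    sd = k.std(ddof=1)
    degenerate = sd <= 1e-12 * max(1.0, float(np.abs(k).max()))
    z = np.zeros_like(k) if degenerate else (k - k.mean()) / sd
    return pd.DataFrame(
        {"connectivity": k, "z": z, "outlier": z < cfg.outlier_z}, index=expr.columns
    )


def adjacency(expr: pd.DataFrame, power: int, mode: str = "unsigned") -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor_ij|^power with unit diagonal."""
    if power < 1:
        raise ValidationError(f"power must be >= 1, got {power}")
    if mode != "unsigned":
        raise ValidationError("only unsigned adjacency is supported")
    cor = _row_correlations(expr.to_numpy())
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def pick_soft_threshold(
    expr: pd.DataFrame, cfg: NetConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Smallest power achieving the scale-free fit target.

    For each candidate power the scale-free fit is the R^2 of the
    log10 p(k) ~ log10 k regression over binned connectivities, signed by
    the negated slope sign (a genuinely scale-free net has negative slope).
    If no power reaches ``scalefree_r2`` the best-fitting power is returned
    and flagged in the fit table.
    """
    cfg = cfg or NetConfig()
    if expr.shape[0] < 20:
        raise ValidationError("soft-threshold selection needs at least 20 KOs")
    x = expr.to_numpy()
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} constant KO rows before fitting")
        x = x[sd > 0]
    cor = np.abs(_row_correlations(x))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in cfg.candidate_powers:
        k = (cor**beta).sum(axis=1)
        fit, slope = _scale_free_fit(k, cfg.n_connectivity_bins)
        rows.append({"power": beta, "fit": fit, "slope": slope, "mean_k": k.mean()})
    table = pd.DataFrame(rows)
    reached = table[table["fit"] >= cfg.scalefree_r2]
    if len(reached):
        power = int(reached["power"].iloc[0])
        table["target_reached"] = True
    else:
        power = int(table.loc[table["fit"].idxmax(), "power"])
        table["target_reached"] = False
        warnings.warn(
            f"no candidate power reached scale-free fit {cfg.scalefree_r2}; "
            f"using best power {power}"
        )
    return power, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    log_p, log_k = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        log_p.append(np.log10(mask.mean()))
        log_k.append(np.log10(k[mask].mean()))
    if len(log_k) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(log_k, log_p, 1)
    pred = slope * np.asarray(log_k) + intercept
    resid = np.asarray(log_p) - pred
    ss_tot = float(((np.asarray(log_p) - np.mean(log_p)) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2, float(slope)


def tom_dissimilarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological-overlap dissimilarity 1 - TOM of an unsigned adjacency."""
    a = adj.to_numpy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    shared = off @ off
    denom = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + off) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    return pd.DataFrame(diss, index=adj.index, columns=adj.columns)


def detect_modules(
    dissimilarity: pd.DataFrame,
    cfg: NetConfig | None = None,
    expr: pd.DataFrame | None = None,
) -> pd.Series:
    """Cut the average-linkage tree of a dissimilarity into module labels.

    A static cut at ``cut_height_quantile`` times the tallest merge height
    yields initial clusters; clusters larger than 3x the minimum module size are
    recursively re-split at progressively lower heights (accepting a split
    only when both children reach the minimum size) down to ``deep_split``
    levels.  Undersized clusters dissolve to the unassigned label 0.  When
    the expression matrix is supplied, unassigned KOs whose best absolute
    module membership reaches ``reassign_mm`` join that module.
    """
    cfg = cfg or NetConfig()
    n = dissimilarity.shape[0]
    if n != dissimilarity.shape[1]:
        raise ValidationError("dissimilarity must be square")
    if cfg.min_module_size > n:
        warnings.warn("min_module_size exceeds the KO count; everything unassigned")
        return pd.Series(UNASSIGNED, index=dissimilarity.index, name="module")
    d = dissimilarity.to_numpy()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    # static cut at a fraction of the tallest merge: joins above it (the
    # near-independent background) stay apart instead of pooling into one
    # spurious cluster, matching dynamic-tree-cut's cutHeight convention
    h0 = float(cfg.cut_height_quantile * z[:, 2].max())
    tree = to_tree(z)

    def maximal_nodes(node, cut):
        if node.dist <= cut:
            return [node]
        return maximal_nodes(node.left, cut) + maximal_nodes(node.right, cut)

    def split(node, depth):
        if (
            depth >= cfg.deep_split
            or node.is_leaf()
            or node.count <= 3 * cfg.min_module_size
        ):
            return [node]
        left, right = node.left, node.right
        if left.count >= cfg.min_module_size and right.count >= cfg.min_module_size:
            return split(left, depth + 1) + split(right, depth + 1)
        return [node]

    final = []
    for cluster in maximal_nodes(tree, h0):
        final.extend(split(cluster, 0))

    labels = np.full(n, UNASSIGNED, dtype=int)
    next_label = 1
    for node in final:
        members = node.pre_order(lambda leaf: leaf.id)
        if len(members) >= cfg.min_module_size:
            labels[members] = next_label
            next_label += 1
    out = pd.Series(labels, index=dissimilarity.index, name="module")
    if expr is not None and (out != UNASSIGNED).any() and (out == UNASSIGNED).any():
        eig, _ = module_eigengene(expr, out)
        mm = module_membership(expr, eig)
        stray = out.index[out == UNASSIGNED]
        best = mm.loc[stray].abs()
        take = best.max(axis=1) >= cfg.reassign_mm
        out.loc[stray[take]] = best.loc[take].idxmax(axis=1).astype(int)
    return out


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First-principal-component eigengenes, unit variance, sign-oriented.

    Member KO rows are standardized across samples before the SVD; each
    eigengene is scaled to unit variance and flipped so its mean
    correlation with member rows is positive.  Returns (module x sample
    eigengene matrix, explained variance fraction per module).
    """
    labels = labels.reindex(expr.index)
    eigs, ev = {}, {}
    for module in sorted(set(labels) - {UNASSIGNED}):
        rows = expr.loc[labels == module].to_numpy(dtype=float)
        if rows.shape[0] < 2:
            raise ValidationError(f"module {module} has fewer than 2 KOs")
        sd = rows.std(axis=1, ddof=1)
        if (sd == 0).all():
            raise ValidationError(f"module {module} has only zero-variance members")
        keep = sd > 0
        rows = rows[keep]
        z = (rows - rows.mean(axis=1, keepdims=True)) / sd[keep][:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0]
        pc = (pc - pc.mean()) / pc.std(ddof=1)
        mean_cor = np.mean([np.corrcoef(pc, row)[0, 1] for row in z])
        if mean_cor < 0:
            pc = -pc
        eigs[module] = pc
        ev[module] = float(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame(eigs, index=expr.columns).T
    eigengenes.index.name = "module"
    return eigengenes, ev


def module_membership(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every KO profile with every module eigengene."""
    x = expr.to_numpy(dtype=float)
    e = eigengenes.to_numpy(dtype=float)
    xs = x.std(axis=1)
    xz = (x - x.mean(axis=1, keepdims=True)) / np.where(xs == 0, 1.0, xs)[:, None]
    es = e.std(axis=1)
    ez = (e - e.mean(axis=1, keepdims=True)) / np.where(es == 0, 1.0, es)[:, None]
    mm = xz @ ez.T / x.shape[1]
    mm[xs == 0, :] = 0.0
    return pd.DataFrame(
        np.clip(mm, -1.0, 1.0), index=expr.index, columns=eigengenes.index
    )


def merge_similar_modules(
    expr: pd.DataFrame, labels: pd.Series, cfg: NetConfig | None = None
) -> tuple[pd.Series, list]:
    """Iteratively merge the most correlated eigengene pair above merge_cor.

    Eigengenes are recomputed after every merge; the merge history records
    (kept module, absorbed module, eigengene correlation).
    """
    cfg = cfg or NetConfig()
    labels = labels.copy()
    history: list[tuple[int, int, float]] = []
    while True:
        modules = sorted(set(labels) - {UNASSIGNED})
        if len(modules) < 2:
            break
        eig, _ = module_eigengene(expr, labels)
        cor = np.corrcoef(eig.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= cfg.merge_cor:
            break
        keep, drop = modules[min(i, j)], modules[max(i, j)]
        labels[labels == drop] = keep
        history.append((keep, drop, float(cor[i, j])))
    # compact labels to 1..M preserving order
    remap = {m: r + 1 for r, m in enumerate(sorted(set(labels) - {UNASSIGNED}))}
    remap[UNASSIGNED] = UNASSIGNED
    return labels.map(remap).rename("module"), history


def module_trait_correlations(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson r, two-sided p (t transform, df = n-2) and BH q per module x trait.

    BH adjustment spans the whole module x trait grid; zero-variance traits
    yield null entries.
    """
    shared = [s for s in eigengenes.columns if s in traits.index]
    if len(shared) < 3:
        raise ValidationError("module-trait correlation needs at least 3 shared samples")
    e = eigengenes[shared].to_numpy(dtype=float)
    t = traits.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    r = np.full((e.shape[0], t.shape[1]), np.nan)
    p = np.full_like(r, np.nan)
    for i in range(e.shape[0]):
        for j in range(t.shape[1]):
            y = t[:, j]
            if np.std(y) == 0 or np.std(e[i]) == 0 or np.isnan(y).any():
                continue
            rij = float(np.corrcoef(e[i], y)[0, 1])
            rij = max(-1.0, min(1.0, rij))
            r[i, j] = rij
            if abs(rij) >= 1.0:
                p[i, j] = 0.0
            else:
                tt = abs(rij) * np.sqrt((n - 2) / (1.0 - rij * rij))
                p[i, j] = 2.0 * t_sf(tt, n - 2)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = bh_adjust(p[mask])
    idx, cols = eigengenes.index, traits.columns
    return (
        pd.DataFrame(r, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(q, index=idx, columns=cols),
    )


def fit_modules(ko_tpm: pd.DataFrame, cfg: NetConfig | None = None) -> ModuleSet:
    """Run the full module pipeline on a KO x sample TPM matrix."""
    cfg = cfg or NetConfig()
    expr = preprocess_ko(ko_tpm, cfg)
    outliers = flag_outlier_samples(expr, cfg)
    power, fit_table = pick_soft_threshold(expr, cfg)
    adj = adjacency(expr, power, cfg.adjacency_mode)
    diss = tom_dissimilarity(adj) if cfg.use_tom else 1.0 - adj.abs()
    labels = detect_modules(diss, cfg, expr=expr)
    if (labels != UNASSIGNED).any():
        labels, history = merge_similar_modules(expr, labels, cfg)
        eigengenes, ev = module_eigengene(expr, labels)
        membership = module_membership(expr, eigengenes)
    else:
        history = []
        eigengenes = pd.DataFrame(columns=expr.columns)
        membership = pd.DataFrame(index=expr.index)
        ev = {}
    return ModuleSet(
        labels=labels,
        eigengenes=eigengenes,
        membership=membership,
        soft_power=power,
        power_fit=fit_table,
        merge_history=history,
        outlier_samples=outliers,
        explained_variance=ev,
    )
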