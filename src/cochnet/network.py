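"""Signed weighted co-expression network construction and module detection.

The network follows the signed WGCNA construction: Pearson correlation across
all samples pooled over the three disease models, signed soft-thresholded
adjacency a_ij = ((1 + cor_ij)/2)**beta, connectivity k_i = sum_j a_ij (j != i),
and the classical topological overlap

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   L_ij = sum_u a_iu a_uj

with u running over all genes other than i and j, TOM_ii = 1.  Modules are
detected by average-linkage hierarchical clustering of 1 - TOM with a static
cut, a minimum-size rule (small clusters go to the unassigned module M0), and
iterative merging of modules whose eigengenes are highly correlated.  The
module eigengene (ME) is the first principal component of the module's
standardized expression, unit-normed over samples and sign-oriented so that it
correlates non-negatively with the module's mean standardized profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .errors import ConfigError, ValidationError
from .expression import ExpressionMatrix

UNASSIGNED = "M0"


# ---------------------------------------------------------------------------
# correlation and adjacency


def correlation_matrix(m: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation of genes across all samples pooled.

    Constant genes (zero variance) get correlation 0 off-diagonal and are
    returned in the flag list rather than raising — synthetic edge cases
    should not abort a run.
    """
    if m.scale != "log2":
        raise ValidationError("correlations are computed on the log2 matrix")
    if m.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlations")
    x = m.values.to_numpy()
    sd = x.std(axis=1)
    # tolerance absorbs the ulp-level jitter of floating-point row means:
    # a truly flat profile can show sd ~ 1e-15 whose "pattern" is identical
    # across genes and would otherwise correlate at +/-1
    constant = sd <= 1e-10 * np.maximum(np.abs(x).max(axis=1), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    genes = m.values.index
    return (pd.DataFrame(cor, index=genes, columns=genes),
            list(genes[constant]))


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + cor_ij)/2)**beta; beta >= 1."""
    if beta < 1:
        raise ConfigError(f"soft-threshold power must be >= 1, got {beta}")
    c = np.asarray(cor, dtype=float)
    return ((1.0 + c) / 2.0) ** beta


def connectivity(a: np.ndarray) -> np.ndarray:
    """Row-sum connectivity k_i, excluding the diagonal."""
    return a.sum(axis=1) - np.diag(a)


# ---------------------------------------------------------------------------
# scale-free topology fit and soft-threshold choice


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins; within each
    non-empty bin the empirical frequency p(k) and the mean connectivity are
    computed, and log10 p(k) is regressed on log10 mean-k.  The returned
    statistic is -sign(slope) * r^2, so approximately scale-free networks
    (negative slope) score near +1.  Returns NaN when fewer than 3 usable
    bins exist.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValidationError("connectivities must be non-negative")
    if k.max() == k.min():
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        freqs.append(mask.sum() / k.size)
        means.append(mean_k)
    if len(freqs) < 3:
        return float("nan")
    log_f = np.log10(freqs)
    if np.ptp(log_f) == 0.0:  # flat histogram: no power-law signature
        return 0.0
    res = linregress(np.log10(means), log_f)
    return float(-np.sign(res.slope) * res.rvalue**2)


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # power, r_squared, mean_connectivity
    beta: float
    target: float


def pick_soft_threshold(
    m: ExpressionMatrix,
    candidates: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 18, 20),
    r2_target: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers; choose the smallest with fit R^2 >= target.

    Falls back to the argmax of R^2 (with a warning) when no candidate
    reaches the target.  The pipeline default skips the scan and uses
    power 15 directly; this scan exists for data-driven runs.
    """
    if len(candidates) == 0:
        raise ConfigError("empty candidate list")
    candidates = tuple(sorted(candidates))
    cor, _ = correlation_matrix(m)
    rows = []
    for p in candidates:
        a = signed_adjacency(cor, p)
        k = connectivity(a)
        rows.append((p, scale_free_fit(k, n_bins=n_bins), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "r_squared", "mean_connectivity"])
    return SoftThresholdScan(table=table, beta=choose_power(table, r2_target),
                             target=r2_target)


def choose_power(table: pd.DataFrame, r2_target: float) -> float:
    """Smallest scanned power with R^2 >= target, else the argmax with a warning."""
    table = table.sort_values("power").reset_index(drop=True)
    ok = table[table["r_squared"] >= r2_target]
    if len(ok):
        return float(ok.iloc[0]["power"])
    beta = float(table.loc[table["r_squared"].idxmax(), "power"])
    warnings.warn(
        f"no candidate power reached R^2 >= {r2_target}; "
        f"using argmax power {beta}", stacklevel=2,
    )
    return beta


# ---------------------------------------------------------------------------
# topological overlap


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Classical TOM on a signed adjacency (dense matrix form).

    L = A_od @ A_od with the diagonal of A zeroed gives exactly
    L_ij = sum_{u != i,j} a_iu a_uj, because the u = i and u = j terms vanish.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    a_od = a.copy()
    np.fill_diagonal(a_od, 0.0)
    k = a_od.sum(axis=1)
    L = a_od @ a_od
    denom = np.minimum.outer(k, k) + 1.0 - a_od
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a_od) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection


@dataclass
class ModulePartition:
    """gene -> module label map; labels M1..Mk by decreasing size, M0 unassigned."""

    labels: pd.Series  # index gene id, values "M0", "M1", ...

    def modules(self) -> list[str]:
        """Assigned module labels, M0 excluded, in numeric order."""
        labs = [l for l in self.labels.unique() if l != UNASSIGNED]
        return sorted(labs, key=lambda l: int(l[1:]))

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def _relabel_by_size(groups: dict[int, list[str]], genes) -> pd.Series:
    """Assign M1..Mk by decreasing size; ties broken by first member order."""
    order = {g: i for i, g in enumerate(genes)}
    ranked = sorted(
        groups.values(), key=lambda mem: (-len(mem), min(order[g] for g in mem))
    )
    labels = pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene_id"),
                       dtype=object)
    for i, mem in enumerate(ranked, start=1):
        labels.loc[mem] = f"M{i}"
    return labels


def cluster_modules(
    tom: np.ndarray | pd.DataFrame,
    expr: ExpressionMatrix,
    min_module_size: int = 30,
    cut_height: float | None = 0.95,
    cut_quantile: float = 0.99,
    merge_cutoff: float = 0.75,
) -> ModulePartition:
    """Detect modules from the TOM by static-cut hierarchical clustering.

    Average-linkage clustering runs on the dissimilarity 1 - TOM.  The tree
    is cut at the absolute ``cut_height`` (default 0.95); passing
    ``cut_height=None`` instead cuts at the ``cut_quantile`` of the merge
    heights.  Clusters below ``min_module_size`` are sent to the unassigned
    module M0, and surviving modules whose eigengenes correlate above
    ``merge_cutoff`` are merged iteratively (closest pair first).  Labels
    M1..Mk are ordered by decreasing final size.
    """
    if min_module_size < 2:
        raise ConfigError("min_module_size must be >= 2")
    if isinstance(tom, pd.DataFrame):
        genes = list(tom.index)
        tom = tom.to_numpy()
    else:
        genes = list(expr.values.index)
    if tom.shape[0] != len(genes) or tom.shape[0] != expr.values.shape[0]:
        raise ValidationError("TOM size does not match the expression matrix")
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    if cut_height is None:
        cut_height = float(np.quantile(z[:, 2], cut_quantile))
    flat = fcluster(z, t=cut_height, criterion="distance")

    groups: dict[int, list[str]] = {}
    for g, c in zip(genes, flat):
        groups.setdefault(int(c), []).append(g)
    groups = {c: mem for c, mem in groups.items() if len(mem) >= min_module_size}

    # iterative eigengene merge: fuse the most correlated pair above cutoff
    while len(groups) > 1:
        labels = {c: mem for c, mem in groups.items()}
        keys = sorted(labels)
        mes = {}
        for c in keys:
            mes[c] = _module_eigengene(expr.values.loc[labels[c]].to_numpy())
        best, best_r = None, merge_cutoff
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                r = float(np.corrcoef(mes[keys[i]], mes[keys[j]])[0, 1])
                if r > best_r:
                    best, best_r = (keys[i], keys[j]), r
        if best is None:
            break
        a, b = best
        groups[a] = groups[a] + groups.pop(b)

    return ModulePartition(_relabel_by_size(groups, genes))


# ---------------------------------------------------------------------------
# module eigengenes


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return (x - mu) / sd


def _module_eigengene(x: np.ndarray) -> np.ndarray:
    """First right singular direction of the standardized module matrix.

    Unit norm over samples; sign oriented so that the correlation with the
    mean standardized module profile is non-negative.
    """
    z = _standardize_rows(np.asarray(x, dtype=float))
    if z.shape[0] == 1:
        v = z[0]
        n = np.linalg.norm(v)
        return v / n if n > 0 else v
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    mean_profile = z.mean(axis=0)
    if me @ mean_profile < 0:
        me = -me
    return me


def module_eigengenes(m: ExpressionMatrix, part: ModulePartition) -> pd.DataFrame:
    """Eigengene (module x sample) matrix for every assigned module."""
    missing = [g for g in part.labels.index if g not in m.values.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} labeled genes absent from expression matrix"
        )
    rows = {}
    for label in part.modules():
        x = m.values.loc[part.members(label)].to_numpy()
        rows[label] = _module_eigengene(x)
    return pd.DataFrame(rows, index=m.values.columns).T
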