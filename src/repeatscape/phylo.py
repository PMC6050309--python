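"""Phylogenetic comparative statistics.

Independent contrasts (Felsenstein pruning), through-origin contrast
regression, censored multi-rate Brownian-motion tests with simulation-based
p values, BM ancestral state reconstruction, Kruskal-Wallis + Dunn/BH
post hoc tests, normality/homoscedasticity gating, and trimmed-median
summarization of Ne time series.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import NeSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tree representation
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree flattened to arrays in postorder.

    Node ids: 0..n_tips-1 are tips (in ``tip_labels`` order), the rest are
    internal, with the root last. ``branch_length[i]`` is the length of the
    edge above node i (0 for the root).
    """

    def __init__(self, tip_labels, parent, children, branch_length, postorder):
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent)
        self.children = children  # list[list[int]] per node
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.postorder = list(postorder)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.children)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def is_binary(self) -> bool:
        return all(
            len(c) in (0, 2) for c in self.children
        )

    @classmethod
    def from_dendropy(cls, tree: "dendropy.Tree") -> "Phylogeny":
        leaves = [nd for nd in tree.leaf_node_iter()]
        tip_labels = [lf.taxon.label if lf.taxon else str(i) for i, lf in enumerate(leaves)]
        ids = {}
        for i, lf in enumerate(leaves):
            ids[lf] = i
        next_id = len(leaves)
        postorder = []
        for nd in tree.postorder_node_iter():
            if nd not in ids:
                ids[nd] = next_id
                next_id += 1
            postorder.append(ids[nd])
        n = next_id
        parent = np.full(n, -1, dtype=int)
        children = [[] for _ in range(n)]
        branch_length = np.zeros(n)
        for nd in tree.postorder_node_iter():
            i = ids[nd]
            branch_length[i] = nd.edge.length or 0.0
            for ch in nd.child_nodes():
                children[i].append(ids[ch])
                parent[ids[ch]] = i
        return cls(tip_labels, parent, children, branch_length, postorder)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def resolve_polytomies(self) -> "Phylogeny":
        """Return a binary tree; polytomies are broken with zero-length
        branches (arbitrary left-ladder order, deterministic)."""
        if self.is_binary:
            return self
        children = [list(c) for c in self.children]
        parent = list(self.parent)
        branch_length = list(self.branch_length)
        n = len(children)
        for node in range(len(children)):
            while len(children[node]) > 2:
                a = children[node].pop()
                b = children[node].pop()
                new = n
                n += 1
                children.append([a, b])
                parent.append(node)
                branch_length.append(0.0)
                parent[a] = new
                parent[b] = new
                children[node].append(new)
        # recompute postorder
        postorder = []
        root = [i for i, p in enumerate(parent) if p == -1][0]
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                postorder.append(node)
            else:
                stack.append((node, True))
                for ch in children[node]:
                    stack.append((ch, False))
        out = Phylogeny(self.tip_labels, parent, children, branch_length, postorder)
        logger.info("resolved polytomies with zero-length branches")
        return out

    def root_to_tip_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for node in reversed(self.postorder):
            for ch in self.children[node]:
                depth[ch] = depth[node] + self.branch_length[ch]
        return depth[: self.n_tips]

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.root_to_tip_depths()
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))

    def tip_values(self, traits: Mapping[str, float]) -> np.ndarray:
        missing = [t for t in self.tip_labels if t not in traits]
        if missing:
            raise ValueError(f"missing trait value for tip(s): {', '.join(missing)}")
        return np.array([traits[t] for t in self.tip_labels], dtype=float)


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastSet:
    contrasts: np.ndarray  # (n_tips - 1,) or (n_tips - 1, m)
    node_ids: np.ndarray  # internal node id per contrast
    trait: str = ""
    node_values: Optional[np.ndarray] = None  # pruning means per node
    node_variances: Optional[np.ndarray] = None  # extended branch variances


def _prune(tree: Phylogeny, x: np.ndarray):
    """Felsenstein pruning pass. ``x`` has shape (n_tips,) or (n_tips, m).

    Returns (contrasts, node_ids, values, extended_variances) where values
    holds the variance-weighted node means and extended_variances the
    node-above-edge variances after the pruning correction.
    """
    single = x.ndim == 1
    xs = x[:, None] if single else x
    n_nodes = tree.n_nodes
    values = np.zeros((n_nodes, xs.shape[1]))
    values[: tree.n_tips] = xs
    var = tree.branch_length.copy()  # effective variance above each node
    contrasts = []
    node_ids = []
    for node in tree.postorder:
        ch = tree.children[node]
        if not ch:
            continue
        if len(ch) != 2:
            raise ValueError("tree must be binary (resolve polytomies first)")
        l, r = ch
        vl, vr = var[l], var[r]
        vsum = vl + vr
        if vsum <= 0:
            raise ValueError(
                "zero variance at a contrast (both child edges have zero "
                "effective length)"
            )
        contrasts.append((values[l] - values[r]) / math.sqrt(vsum))
        node_ids.append(node)
        values[node] = (values[l] * vr + values[r] * vl) / vsum
        var[node] += vl * vr / vsum
    contrasts = np.array(contrasts)
    if single:
        contrasts = contrasts[:, 0]
    return contrasts, np.array(node_ids), values, var


def pic_contrasts(
    tree: Phylogeny, traits: Mapping[str, float] | pd.Series, trait_name: str = ""
) -> ContrastSet:
    """Standardized phylogenetic independent contrasts.

    The tree must be binary (resolve polytomies first); every tip needs a
    value. Contrast count is n_tips - 1.
    """
    tree = tree.resolve_polytomies()
    if isinstance(traits, pd.Series):
        trait_name = trait_name or str(traits.name)
        traits = traits.to_dict()
    x = tree.tip_values(traits)
    contrasts, node_ids, values, var = _prune(tree, x)
    return ContrastSet(
        contrasts=contrasts,
        node_ids=node_ids,
        trait=trait_name,
        node_values=values,
        node_variances=var,
    )


@dataclass
class PicRegression:
    slope: float
    t_statistic: float
    p_value: float
    df: int
    r_squared: float


def pic_regression(y_contrasts: np.ndarray, x_contrasts: np.ndarray) -> PicRegression:
    """Least-squares regression through the origin of y on x contrasts."""
    y = np.asarray(y_contrasts, dtype=float)
    x = np.asarray(x_contrasts, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("contrast vectors must be equal-length 1-D")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("x contrasts have zero variance")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    df = n - 1
    s2 = float(resid @ resid) / df
    se = math.sqrt(s2 / sxx)
    if se == 0:
        t = math.inf if slope > 0 else (-math.inf if slope < 0 else 0.0)
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2 * stats.t.sf(abs(t), df)
    syy = float(y @ y)
    r2 = 1 - float(resid @ resid) / syy if syy > 0 else 0.0
    return PicRegression(slope=slope, t_statistic=t, p_value=float(p), df=df, r_squared=r2)


# ---------------------------------------------------------------------------
# Censored multi-rate BM test
# ---------------------------------------------------------------------------


@dataclass
class RateTestResult:
    sigma2_single: float
    sigma2_per_regime: dict
    lnl_single: float
    lnl_multi: float
    lr_statistic: float
    p_value: float
    n_sims: int
    contrast_regimes: np.ndarray = field(default=None, repr=False)


def _contrast_loglik(u2: np.ndarray, sigma2: float, n: int) -> float:
    # constants from the contrast variances cancel in likelihood ratios
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _lr_from_contrasts(u: np.ndarray, regime_idx: np.ndarray, n_regimes: int):
    """Vectorized LR over columns of ``u`` ((n-1, m) contrasts)."""
    u2 = u * u
    n = u.shape[0]
    s2_single = u2.mean(axis=0)
    lnl_single = -0.5 * n * (np.log(2 * np.pi * s2_single) + 1.0)
    lnl_multi = np.zeros_like(lnl_single)
    s2_regimes = []
    for r in range(n_regimes):
        sel = regime_idx == r
        nr = int(sel.sum())
        s2_r = u2[sel].mean(axis=0)
        s2_regimes.append(s2_r)
        lnl_multi += -0.5 * nr * (np.log(2 * np.pi * s2_r) + 1.0)
    lr = 2 * (lnl_multi - lnl_single)
    return lr, s2_single, s2_regimes, lnl_single, lnl_multi


def assign_contrast_regimes(
    tree: Phylogeny, node_ids: np.ndarray, tip_regimes: Mapping[str, str]
) -> tuple[np.ndarray, list]:
    """Censored regime painting: each contrast takes the regime shared by all
    descendant tips of its node; mixed nodes take the majority regime
    (ties -> lexicographically smallest)."""
    regimes = sorted(set(tip_regimes.values()))
    rindex = {r: i for i, r in enumerate(regimes)}
    tip_sets = [None] * tree.n_nodes
    for node in tree.postorder:
        ch = tree.children[node]
        if not ch:
            label = tree.tip_labels[node]
            tip_sets[node] = {tip_regimes[label]: 1}
        else:
            counts: dict = {}
            for c in ch:
                for r, n in tip_sets[c].items():
                    counts[r] = counts.get(r, 0) + n
            tip_sets[node] = counts
    out = []
    for nid in node_ids:
        counts = tip_sets[nid]
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(rindex[best])
    return np.array(out), regimes


def simulate_bm_matrix(
    tree: Phylogeny,
    sigma2,
    m: int,
    rng: np.random.Generator,
    tip_regimes: Mapping[str, str] | None = None,
    branch_sigma2: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Simulate ``m`` replicate BM traits on the tree; returns (n_tips, m).

    ``sigma2`` is a scalar rate, or (with ``branch_sigma2``) a per-regime
    map applied to branches by the regime of the descendant tips below each
    branch (majority rule for mixed branches).
    """
    rates = np.full(tree.n_nodes, float(sigma2) if np.isscalar(sigma2) else np.nan)
    if branch_sigma2 is not None:
        if tip_regimes is None:
            raise ValueError("branch rates require tip_regimes")
        node_ids = np.arange(tree.n_nodes)
        ridx, regimes = assign_contrast_regimes(tree, node_ids, tip_regimes)
        for i in range(tree.n_nodes):
            rates[i] = branch_sigma2[regimes[ridx[i]]]
    values = np.zeros((tree.n_nodes, m))
    for node in reversed(tree.postorder):
        for ch in tree.children[node]:
            sd = math.sqrt(rates[ch] * tree.branch_length[ch])
            values[ch] = values[node] + rng.normal(0.0, 1.0, size=m) * sd
    return values[: tree.n_tips]


def censored_rate_test(
    tree: Phylogeny,
    traits: Mapping[str, float] | pd.Series,
    tip_regimes: Mapping[str, str],
    n_sims: int = 1000,
    seed: int = 0,
) -> RateTestResult:
    """Single-rate vs multi-rate BM via REML contrast likelihoods.

    sigma^2 per regime is the mean squared standardized contrast over the
    contrasts painted to that regime; LR = 2(lnL_multi - lnL_single); the p
    value is the fraction of ``n_sims`` single-rate parametric simulations
    whose LR is >= the observed one.
    """
    tree = tree.resolve_polytomies()
    if isinstance(traits, pd.Series):
        traits = traits.to_dict()
    cs = pic_contrasts(tree, traits)
    ridx, regimes = assign_contrast_regimes(tree, cs.node_ids, tip_regimes)
    # a single-regime map is allowed: the multi-rate model then collapses to
    # the single-rate model and LR is exactly 0
    for r in range(len(regimes)):
        if int((ridx == r).sum()) < 2:
            raise ValueError(f"regime {regimes[r]!r} has fewer than 2 contrasts")
    u = cs.contrasts[:, None]
    lr, s2s, s2r, lnl_s, lnl_m = _lr_from_contrasts(u, ridx, len(regimes))
    lr_obs = float(lr[0])

    rng = np.random.default_rng(seed)
    sims = simulate_bm_matrix(tree, float(s2s[0]), n_sims, rng)
    u_sim, _, _, _ = _prune(tree, sims)
    lr_sim, _, _, _, _ = _lr_from_contrasts(u_sim, ridx, len(regimes))
    p = float(np.mean(lr_sim >= lr_obs - 1e-12))
    return RateTestResult(
        sigma2_single=float(s2s[0]),
        sigma2_per_regime={regimes[i]: float(s2r[i][0]) for i in range(len(regimes))},
        lnl_single=float(lnl_s[0]),
        lnl_multi=float(lnl_m[0]),
        lr_statistic=max(lr_obs, 0.0),
        p_value=p,
        n_sims=n_sims,
        contrast_regimes=ridx,
    )


# ---------------------------------------------------------------------------
# Ancestral state reconstruction
# ---------------------------------------------------------------------------


def asr_bm(tree: Phylogeny, traits: Mapping[str, float] | pd.Series) -> dict:
    """Maximum-likelihood BM ancestral states per internal node.

    Two-pass algorithm: the pruning downpass gives conditional (subtree)
    means/variances; the uppass folds in the rest of the tree. The root state
    equals the PIC-weighted mean. Returns {node_id: state}; node ids match
    :class:`ContrastSet.node_ids` on the polytomy-resolved tree.
    """
    tree = tree.resolve_polytomies()
    if isinstance(traits, pd.Series):
        traits = traits.to_dict()
    x = tree.tip_values(traits)
    _, _, values, var = _prune(tree, x)
    down_mean = values[:, 0]
    # subtree variance BEFORE adding the node's own branch
    down_var = var - tree.branch_length

    out_mean = np.zeros(tree.n_nodes)
    out_var = np.full(tree.n_nodes, np.inf)
    states = {}
    root = tree.root
    states[root] = float(down_mean[root])
    for node in reversed(tree.postorder):
        ch = tree.children[node]
        if not ch:
            continue
        for c in ch:
            sibs = [s for s in ch if s != c]
            parts = []  # (mean, variance) of independent outside estimates
            if node != root:
                parts.append((out_mean[node], out_var[node]))
            for s in sibs:
                parts.append((down_mean[s], down_var[s] + tree.branch_length[s]))
            w = np.array([1.0 / v if v > 0 else np.inf for _, v in parts])
            if np.any(np.isinf(w)):
                m = [m for (m, v), wi in zip(parts, w) if np.isinf(wi)][0]
                v = 0.0
            else:
                v = 1.0 / w.sum()
                m = float(sum(wi * mi for (mi, _), wi in zip(parts, w)) * v)
            out_mean[c] = m
            out_var[c] = v + tree.branch_length[c]
            if tree.children[c]:  # internal: combine inside + outside
                vd = down_var[c]
                vo = out_var[c]
                if vd == 0:
                    states[c] = float(down_mean[c])
                elif vo == 0:
                    states[c] = float(out_mean[c])
                else:
                    wsum = 1 / vd + 1 / vo
                    states[c] = float((down_mean[c] / vd + out_mean[c] / vo) / wsum)
    return states


# ---------------------------------------------------------------------------
# Rank tests and gating
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_bh(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Dunn's z on mean ranks with tie correction, BH-adjusted across all
    pairwise comparisons. Returns a frame with pair indices, z, raw and
    adjusted p."""
    if len(groups) < 3:
        raise ValueError("need >=3 groups for post hoc comparisons")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    flat = np.concatenate(arrays)
    n_total = len(flat)
    ranks = stats.rankdata(flat)
    mean_ranks = []
    i0 = 0
    for a in arrays:
        mean_ranks.append(ranks[i0 : i0 + len(a)].mean())
        i0 += len(a)
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        var = base_var * (1 / len(arrays[i]) + 1 / len(arrays[j]))
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


@dataclass
class GateReport:
    shapiro_p_raw: Optional[float]
    shapiro_p_log: Optional[float]
    bartlett_p_raw: Optional[float]
    bartlett_p_log: Optional[float]
    scale: str  # "raw", "log", or "rank"
    values: Optional[np.ndarray]


def gate_and_transform(
    values: Sequence[float],
    groups: Optional[Sequence[Sequence[float]]] = None,
    alpha: float = 0.05,
) -> GateReport:
    """Normality (Shapiro-Wilk) and, when groups are given, variance
    homogeneity (Bartlett) gating on raw and log scales.

    Downstream linear analyses should use the returned scale; "rank" means
    neither scale passed (use nonparametric tests). Log transformation of
    non-positive values is refused with an explicit error rather than a
    silent offset.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return GateReport(None, None, None, None, "rank", None)

    def _tests(v, grps):
        sp = float(stats.shapiro(v)[1])
        bp = None
        if grps is not None:
            bp = float(stats.bartlett(*grps)[1])
        return sp, bp

    sp_raw, bp_raw = _tests(x, groups)
    raw_ok = sp_raw > alpha and (bp_raw is None or bp_raw > alpha)
    if raw_ok:
        return GateReport(sp_raw, None, bp_raw, None, "raw", x)

    if np.any(x <= 0):
        raise ValueError(
            "cannot log-transform non-positive values; use the rank-test path"
        )
    lx = np.log(x)
    lgroups = [np.log(np.asarray(g, dtype=float)) for g in groups] if groups else None
    sp_log, bp_log = _tests(lx, lgroups)
    log_ok = sp_log > alpha and (bp_log is None or bp_log > alpha)
    scale = "log" if log_ok else "rank"
    return GateReport(sp_raw, sp_log, bp_raw, bp_log, scale, lx if log_ok else None)


# ---------------------------------------------------------------------------
# Ne summarization
# ---------------------------------------------------------------------------

NE_SCHEMES = ("trim_endpoints", "trim_10pct", "trim_25pct", "window_20ky_10my")


def median_ne(series: NeSeries, scheme: str = "trim_endpoints") -> float:
    """Median Ne after the chosen filtering scheme.

    trim_endpoints drops the first and last time points; trim_{10,25}pct
    drop that fraction of points split evenly between the two ends (at least
    one each); the window scheme keeps points with 20 kyBP <= t <= 10 myBP.
    """
    ne = series.ne_values
    times = series.times
    if scheme == "trim_endpoints":
        if len(ne) < 3:
            raise ValueError("need >=3 points to trim endpoints")
        kept = ne[1:-1]
    elif scheme in ("trim_10pct", "trim_25pct"):
        frac = 0.10 if scheme == "trim_10pct" else 0.25
        k = max(1, math.ceil(len(ne) * frac / 2))
        if len(ne) <= 2 * k:
            raise ValueError("too few points for this trimming scheme")
        kept = ne[k:-k]
    elif scheme == "window_20ky_10my":
        kept = [n for t, n in zip(times, ne) if 20e3 <= t <= 10e6]
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {NE_SCHEMES}")
    if not kept:
        raise ValueError("no points retained after filtering")
    return float(np.median(kept))
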