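"""Group-level inference.

Scalar contrasts (band power, peak frequency) use the pooled-variance
independent-samples Student t-test, two-tailed, with Cohen's d as the
effect size; t and d are algebraically linked through

    t = d * sqrt(n1 * n2 / (n1 + n2)),

which also provides a consistency check between reported t and d values.

Comodulograms are compared with a cluster-based permutation test: per-bin
t-values exceeding the two-tailed 5% critical value are grouped into
connected clusters (4-connectivity by default) separately for positive
and negative signs; each cluster's statistic (max |t| within the cluster
by default, sum-of-t available) is referred to a null distribution of the
largest per-tail cluster statistic under random relabelling of the group
membership.  Tails are corrected separately at alpha = 0.025 each, i.e.
5% family-wise across both tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .pac import Comodulogram

__all__ = [
    "GroupTestResult",
    "Cluster",
    "ClusterResult",
    "EffectSizeMap",
    "independent_t",
    "t_from_d",
    "d_from_t",
    "cluster_permutation",
    "comodulogram_effect_size",
]


@dataclass
class GroupTestResult:
    """Pooled-variance two-sample t-test with effect size."""

    t: float
    df: int
    p: float
    d: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int

    def summary(self) -> str:
        return (f"t({self.df}) = {self.t:.3f}, p = {self.p:.4f}, d = {self.d:.3f} "
                f"(means {self.mean_a:.3f} vs {self.mean_b:.3f}, n = {self.n_a}/{self.n_b})")


def independent_t(a: np.ndarray, b: np.ndarray) -> GroupTestResult:
    """Independent-samples Student t (pooled variance), two-tailed, with Cohen's d."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance; t undefined")
    diff = a.mean() - b.mean()
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    d = diff / np.sqrt(sp2)
    return GroupTestResult(t=float(t), df=df, p=float(p), d=float(d),
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           n_a=n1, n_b=n2)


def t_from_d(d: float, n1: int, n2: int) -> float:
    """t statistic implied by Cohen's d for a pooled two-sample design."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return d * np.sqrt(n1 * n2 / (n1 + n2))


def d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d implied by a pooled two-sample t statistic."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return t / np.sqrt(n1 * n2 / (n1 + n2))


@dataclass
class Cluster:
    """One suprathreshold cluster of comodulogram bins."""

    bins: list[tuple[int, int]]          # (phase index, amp index)
    bins_hz: list[tuple[float, float]]   # (phase Hz, amp Hz)
    sign: int                            # +1: group A > B, -1: A < B
    stat: float                          # cluster statistic
    p_perm: float

    @property
    def phase_range_hz(self) -> tuple[float, float]:
        fp = [b[0] for b in self.bins_hz]
        return min(fp), max(fp)

    @property
    def amp_range_hz(self) -> tuple[float, float]:
        fa = [b[1] for b in self.bins_hz]
        return min(fa), max(fa)


@dataclass
class ClusterResult:
    """Cluster-based permutation test outcome."""

    clusters: list[Cluster]
    t_map: np.ndarray
    df: int
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    n_permutations: int
    threshold_alpha: float = 0.05
    decision_alpha_per_tail: float = 0.025
    connectivity: int = 4
    cluster_stat: str = "max"
    exact: bool = False
    seed: int | None = None
    null_max: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_perm < self.decision_alpha_per_tail]

    def summary(self) -> str:
        lines = [
            f"cluster permutation test: {len(self.clusters)} suprathreshold cluster(s), "
            f"{self.n_permutations} {'exact' if self.exact else 'random'} relabelings, "
            f"stat = {self.cluster_stat}-t, {self.connectivity}-connectivity, df = {self.df}",
        ]
        for c in sorted(self.clusters, key=lambda c: c.p_perm):
            star = " *" if c.p_perm < self.decision_alpha_per_tail else ""
            lines.append(
                f"  {'+' if c.sign > 0 else '-'} cluster: {len(c.bins)} bins, "
                f"phase {c.phase_range_hz[0]:g}-{c.phase_range_hz[1]:g} Hz, "
                f"amp {c.amp_range_hz[0]:g}-{c.amp_range_hz[1]:g} Hz, "
                f"stat = {c.stat:.3f}, p = {c.p_perm:.4f}{star}")
        if not self.clusters:
            lines.append("  no suprathreshold bins")
        return "\n".join(lines)


def _stack_group(group: list[Comodulogram] | np.ndarray) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    if isinstance(group, np.ndarray):
        return np.asarray(group, float), None, None
    arrs = np.stack([g.values for g in group])
    pf, af = group[0].phase_freqs, group[0].amp_freqs
    for g in group[1:]:
        if not (np.array_equal(g.phase_freqs, pf) and np.array_equal(g.amp_freqs, af)):
            raise ValueError("comodulogram frequency grids differ across subjects")
    return arrs, pf, af


def _t_maps(data: np.ndarray, a_idx: np.ndarray) -> np.ndarray:
    """Pooled-t map(s) for one or many relabelings.

    data : (n, n_bins); a_idx : (n_perm, n1) index arrays -> (n_perm, n_bins)
    """
    n = data.shape[0]
    n1 = a_idx.shape[1]
    n2 = n - n1
    df = n - 2
    tot = data.sum(axis=0)
    tot2 = (data ** 2).sum(axis=0)
    s1 = data[a_idx].sum(axis=1)          # (n_perm, n_bins)
    ss1 = (data[a_idx] ** 2).sum(axis=1)
    s2 = tot[None, :] - s1
    ss2 = tot2[None, :] - ss1
    m1, m2 = s1 / n1, s2 / n2
    v1 = (ss1 - n1 * m1 ** 2) / (n1 - 1)
    v2 = (ss2 - n2 * m2 ** 2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.where(np.isfinite(t), t, 0.0)


def _cluster_tail_stats(t_map: np.ndarray, sign: int, t_crit: float,
                        structure: np.ndarray, stat: str):
    """Label one tail's suprathreshold bins; return (labels, n, per-cluster stats)."""
    mask = (sign * t_map) > t_crit
    labels, n_clusters = ndimage.label(mask, structure=structure)
    if n_clusters == 0:
        return labels, 0, np.empty(0)
    idx = np.arange(1, n_clusters + 1)
    if stat == "max":
        stats = ndimage.maximum(np.abs(t_map), labels, idx)
    elif stat == "sum":
        stats = np.abs(ndimage.sum_labels(t_map, labels, idx))
    else:
        raise ValueError(f"unknown cluster_stat {stat!r}")
    return labels, n_clusters, np.atleast_1d(stats)


def cluster_permutation(group_a: list[Comodulogram] | np.ndarray,
                        group_b: list[Comodulogram] | np.ndarray,
                        n_perm: int = 10000, seed: int | None = 0,
                        connectivity: int = 4, cluster_stat: str = "max",
                        threshold_alpha: float = 0.05,
                        decision_alpha_per_tail: float = 0.025,
                        exact: bool = False) -> ClusterResult:
    """Cluster-based permutation comparison of two groups of comodulograms.

    Parameters
    ----------
    group_a, group_b : lists of Comodulogram (or plain arrays of matching shape)
    n_perm : number of random relabelings (ignored when ``exact``)
    exact : enumerate all distinct relabelings instead of sampling; the
        permutation p is then the exact fraction of relabelings (including
        the observed one) with a null statistic at least as large.
    """
    data_a, pf, af = _stack_group(group_a)
    data_b, pf_b, af_b = _stack_group(group_b)
    if data_a.shape[1:] != data_b.shape[1:]:
        raise ValueError("comodulogram grids differ between groups")
    if pf is None:
        pf = np.arange(data_a.shape[1], dtype=float)
        af = np.arange(data_a.shape[2], dtype=float)
    n1, n2 = data_a.shape[0], data_b.shape[0]
    if n1 + n2 < 4 or n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    shape = data_a.shape[1:]
    data = np.concatenate([data_a, data_b]).reshape(n1 + n2, -1)
    n = n1 + n2
    df = n - 2
    t_crit = sps.t.isf(threshold_alpha / 2.0, df)
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")

    obs_t = _t_maps(data, np.arange(n1)[None, :])[0].reshape(shape)

    # observed clusters per tail
    observed: list[tuple[int, np.ndarray, float]] = []
    for sign in (+1, -1):
        labels, n_cl, stats_ = _cluster_tail_stats(obs_t, sign, t_crit,
                                                   structure, cluster_stat)
        for k in range(n_cl):
            members = np.argwhere(labels == k + 1)
            observed.append((sign, members, float(stats_[k])))

    n_distinct = comb(n, n1)
    if exact:
        a_idx = np.array(list(combinations(range(n), n1)), dtype=np.intp)
        n_used = a_idx.shape[0]
    else:
        if n_perm > n_distinct:
            warnings.warn(
                f"n_perm = {n_perm} exceeds the {n_distinct} distinct relabelings; "
                "proceeding with random relabelings", stacklevel=2)
        rng = np.random.default_rng(seed)
        a_idx = np.empty((n_perm, n1), dtype=np.intp)
        for i in range(n_perm):
            a_idx[i] = rng.permutation(n)[:n1]
        n_used = n_perm

    # null distribution of the largest per-tail cluster statistic
    chunk = 512
    null_pos = np.zeros(n_used)
    null_neg = np.zeros(n_used)
    for start in range(0, n_used, chunk):
        t_perm = _t_maps(data, a_idx[start:start + chunk])
        for j, row in enumerate(t_perm):
            tm = row.reshape(shape)
            for sign, null in ((+1, null_pos), (-1, null_neg)):
                _, n_cl, stats_ = _cluster_tail_stats(tm, sign, t_crit,
                                                      structure, cluster_stat)
                if n_cl:
                    null[start + j] = stats_.max()

    clusters: list[Cluster] = []
    for sign, members, stat in observed:
        null = null_pos if sign > 0 else null_neg
        if exact:
            p = float(np.mean(null >= stat - 1e-12))
        else:
            p = float((1 + np.sum(null >= stat)) / (1 + n_used))
        bins = [tuple(map(int, m)) for m in members]
        bins_hz = [(float(pf[i]), float(af[j])) for i, j in bins]
        clusters.append(Cluster(bins=bins, bins_hz=bins_hz, sign=sign,
                                stat=stat, p_perm=p))

    return ClusterResult(clusters=clusters, t_map=obs_t, df=df,
                         phase_freqs=np.asarray(pf), amp_freqs=np.asarray(af),
                         n_permutations=n_used, threshold_alpha=threshold_alpha,
                         decision_alpha_per_tail=decision_alpha_per_tail,
                         connectivity=connectivity, cluster_stat=cluster_stat,
                         exact=exact, seed=seed,
                         null_max={+1: null_pos, -1: null_neg})


@dataclass
class EffectSizeMap:
    """Per-bin Cohen's d over the comodulogram grid."""

    d: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray

    @property
    def max_d(self) -> float:
        return float(np.max(self.d))

    @property
    def max_bin_hz(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.d), self.d.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


def comodulogram_effect_size(group_a: list[Comodulogram] | np.ndarray,
                             group_b: list[Comodulogram] | np.ndarray) -> EffectSizeMap:
    """Element-wise Cohen's d (group A minus group B) over the grid."""
    data_a, pf, af = _stack_group(group_a)
    data_b, _, _ = _stack_group(group_b)
    if data_a.shape[1:] != data_b.shape[1:]:
        raise ValueError("comodulogram grids differ between groups")
    if pf is None:
        pf = np.arange(data_a.shape[1], dtype=float)
        af = np.arange(data_a.shape[2], dtype=float)
    n1, n2 = data_a.shape[0], data_b.shape[0]
    v1 = data_a.var(axis=0, ddof=1)
    v2 = data_b.var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (data_a.mean(axis=0) - data_b.mean(axis=0)) / sp
    d = np.where(np.isfinite(d), d, 0.0)
    return EffectSizeMap(d=d, phase_freqs=np.asarray(pf), amp_freqs=np.asarray(af))
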