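"""Stimulation-induced connectivity via cluster-based permutation testing.

Edge-wise paired t-statistics (stimulation vs baseline across subjects)
are thresholded at an edge-level (cluster-forming) alpha, 0.005 by
default; suprathreshold edges of like sign are grouped into clusters,
two edges being adjacent by default when they share an endpoint channel
(rule "shared"; rule "neighbors" additionally links edges whose
endpoints are montage neighbours).
Isolated suprathreshold edges are discarded. Each cluster is scored by
the sum of its member t-values and referred to a null distribution of
the maximum |cluster score| under within-subject condition-label
exchange (sign flips of the paired differences). Clusters whose
Monte-Carlo p falls below alpha constitute the stimulation-induced
functional connectivity (SFC).

The retained edges' t-values, normalized by the maximum absolute
retained t, are summed per channel into node intensities; the
hemispheric-lateralization (HL) degree is the percentage of SFC channels
in the hemisphere contralateral to the stimulated forearm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .montage import Montage

__all__ = [
    "EdgeStatMap",
    "EdgeCluster",
    "SFCResult",
    "edge_stats",
    "build_edge_clusters",
    "permutation_test",
    "topography_summary",
    "hl_degree",
    "hl_degree_display",
]

log = logging.getLogger(__name__)


@dataclass
class EdgeStatMap:
    """Paired-difference statistics on every unordered channel pair."""

    t_values: np.ndarray  # (n_pairs,)
    p_values: np.ndarray  # two-sided, uncorrected
    df: int
    pairs: np.ndarray  # (n_pairs, 2) channel indices, i < j
    channel_names: tuple[str, ...]


@dataclass
class EdgeCluster:
    """A sign-homogeneous connected set of suprathreshold edges."""

    edges: np.ndarray  # indices into the pair list
    cluster_stat: float  # sum of member t-values
    perm_p: float = float("nan")


@dataclass
class SFCResult:
    """Clusters surviving the permutation test, with edge/node summaries."""

    clusters: list[EdgeCluster]
    all_clusters: list[EdgeCluster]
    stats: EdgeStatMap
    normalized_t: dict[int, float]  # pair index -> t / max|t| over retained
    node_sum: np.ndarray  # per channel, sum of normalized t on its SFC edges
    n_permutations: int
    alpha: float
    seed: int | None
    exhaustive: bool = False

    @property
    def retained_edges(self) -> np.ndarray:
        if not self.clusters:
            return np.array([], dtype=int)
        return np.concatenate([c.edges for c in self.clusters])

    @property
    def sfc_channels(self) -> np.ndarray:
        """Indices of channels incident to at least one retained edge."""
        return np.nonzero(self.node_sum != 0)[0]


def _paired_t(a: np.ndarray, b: np.ndarray, pairs: np.ndarray):
    """Vectorized paired t over the subject axis for listed pairs."""
    diffs = (a - b)[:, pairs[:, 0], pairs[:, 1]]  # (subjects, pairs)
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    # all-zero differences are a well-defined null (t = 0); constant
    # nonzero differences would give t = +-inf, which is an error
    degenerate = (sd == 0) & (mean != 0)
    if np.any(degenerate):
        k = int(np.argmax(degenerate))
        raise ValueError(
            f"zero variance of nonzero paired differences on pair "
            f"({pairs[k, 0]}, {pairs[k, 1]}); t would be infinite"
        )
    with np.errstate(invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n) + (sd == 0)), 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    return t, p, diffs


def edge_stats(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    channel_names: tuple[str, ...] | None = None,
) -> EdgeStatMap:
    """Per-pair paired t (``cond_a`` minus ``cond_b``) across subjects.

    Inputs are (n_subjects, n_ch, n_ch) stacks of per-subject
    connectivity matrices with identical subject order.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("conditions must hold the same subjects")
    if cond_a.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    n_ch = cond_a.shape[1]
    iu = np.triu_indices(n_ch, 1)
    pairs = np.column_stack(iu)
    t, p, _ = _paired_t(cond_a, cond_b, pairs)
    names = channel_names or tuple(f"ch{i}" for i in range(n_ch))
    return EdgeStatMap(
        t_values=t, p_values=p, df=cond_a.shape[0] - 1, pairs=pairs,
        channel_names=names,
    )


def _channel_closeness(montage: Montage, adjacency_rule: str) -> np.ndarray:
    """Boolean channel x channel 'same or adjacent' relation."""
    n = montage.n_channels
    close = np.eye(n, dtype=bool)
    if adjacency_rule == "neighbors":
        for ch, nbrs in montage.neighbors.items():
            i = montage.index(ch)
            for other in nbrs:
                close[i, montage.index(other)] = True
    elif adjacency_rule != "shared":
        raise ValueError(f"unknown adjacency rule {adjacency_rule!r}")
    return close


def _components(
    edge_idx: np.ndarray, pairs: np.ndarray, close: np.ndarray
) -> list[np.ndarray]:
    """Connected components among the given edges.

    Two edges are adjacent when any endpoint of one is identical or
    neighbouring (per ``close``) to an endpoint of the other.
    """
    if len(edge_idx) == 0:
        return []
    endpoints = pairs[edge_idx]  # (m, 2)
    m = len(edge_idx)
    n = close.shape[0]
    inc = np.zeros((m, n), dtype=bool)
    inc[np.arange(m), endpoints[:, 0]] = True
    inc[np.arange(m), endpoints[:, 1]] = True
    closure = inc @ close  # edge x channel: channels close to the edge
    adj = closure @ inc.T  # edge x edge
    n_comp, labels = connected_components(
        sparse.csr_matrix(adj), directed=False
    )
    return [edge_idx[labels == c] for c in range(n_comp)]


def _clusters_from_t(
    t: np.ndarray,
    suprathreshold: np.ndarray,
    pairs: np.ndarray,
    close: np.ndarray,
) -> list[EdgeCluster]:
    """Sign-homogeneous clusters of suprathreshold edges; singletons dropped."""
    out = []
    for sign in (1, -1):
        idx = np.nonzero(suprathreshold & (np.sign(t) == sign))[0]
        for comp in _components(idx, pairs, close):
            if len(comp) < 2:  # isolated edge: no adjacent suprathreshold edge
                continue
            out.append(EdgeCluster(edges=comp, cluster_stat=float(t[comp].sum())))
    return out


def build_edge_clusters(
    stat_map: EdgeStatMap,
    montage: Montage,
    edge_alpha: float = 0.005,
    adjacency_rule: str = "shared",
) -> list[EdgeCluster]:
    """Group suprathreshold (p < ``edge_alpha``) edges into clusters."""
    close = _channel_closeness(montage, adjacency_rule)
    supra = stat_map.p_values < edge_alpha
    return _clusters_from_t(stat_map.t_values, supra, stat_map.pairs, close)


def permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    montage: Montage,
    n_perm: int = 1000,
    alpha: float = 0.05,
    edge_alpha: float = 0.005,
    seed: int | None = None,
    adjacency_rule: str = "shared",
) -> SFCResult:
    """Cluster-based permutation test of ``cond_a`` vs ``cond_b``.

    The null exchanges condition labels within subjects (sign flips of
    the paired differences) and records the maximum absolute cluster
    score per permutation. The maximum score is invariant under the
    global sign mirror, so the flip patterns form ``2**(n-1)`` mirror
    classes; when ``n_perm`` reaches that count every class is
    enumerated instead of sampled (an exact test). All clusters with
    permutation p below ``alpha`` are retained (the maximum statistic
    enters only the null distribution).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    stat_map = edge_stats(cond_a, cond_b, montage.channel_names)
    close = _channel_closeness(montage, adjacency_rule)
    pairs = stat_map.pairs
    n_sub = cond_a.shape[0]
    df = n_sub - 1
    t_crit = stats.t.ppf(1 - edge_alpha / 2, df)
    observed = _clusters_from_t(
        stat_map.t_values, np.abs(stat_map.t_values) > t_crit, pairs, close
    )

    diffs = (cond_a - cond_b)[:, pairs[:, 0], pairs[:, 1]]
    ssq = (diffs**2).sum(axis=0)  # invariant under sign flips

    n_classes = 2 ** (n_sub - 1)  # sign patterns modulo the global mirror
    exhaustive = n_perm >= n_classes
    if exhaustive:
        log.info(
            "n_perm=%d >= 2^%d mirror classes: exhaustive enumeration",
            n_perm, n_sub - 1,
        )
        # subject 0 fixed at +1: one representative per mirror class
        signs = np.array(
            [[1.0] + [1.0 if (k >> s) & 1 else -1.0 for s in range(n_sub - 1)]
             for k in range(n_classes)]
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))

    means = signs @ diffs / n_sub  # (perm, pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means * np.sqrt(n_sub * df) / np.sqrt(ssq - n_sub * means**2)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)

    null_max = np.zeros(len(signs))
    for k in range(len(signs)):
        clusters_k = _clusters_from_t(
            t_perm[k], np.abs(t_perm[k]) > t_crit, pairs, close
        )
        if clusters_k:
            null_max[k] = max(abs(c.cluster_stat) for c in clusters_k)

    retained = []
    for c in observed:
        exceed = int(np.sum(null_max >= abs(c.cluster_stat)))
        if exhaustive:
            c.perm_p = exceed / len(signs)
        else:
            c.perm_p = (1 + exceed) / (1 + n_perm)
        if c.perm_p < alpha:
            retained.append(c)

    node_sum = np.zeros(montage.n_channels)
    normalized_t = {}
    if retained:
        edges = np.concatenate([c.edges for c in retained])
        t_max = np.abs(stat_map.t_values[edges]).max()
        for e in edges:
            nt = float(stat_map.t_values[e] / t_max)
            normalized_t[int(e)] = nt
            node_sum[pairs[e, 0]] += nt
            node_sum[pairs[e, 1]] += nt
    return SFCResult(
        clusters=retained,
        all_clusters=observed,
        stats=stat_map,
        normalized_t=normalized_t,
        node_sum=node_sum,
        n_permutations=len(signs) if exhaustive else n_perm,
        alpha=alpha,
        seed=seed,
        exhaustive=exhaustive,
    )


def hl_degree(n_contra: int, n_total: int) -> float:
    """Hemispheric-lateralization degree: 100 * n_contra / n_total."""
    if n_total <= 0:
        raise ValueError("no channels on the SFC topography")
    return 100.0 * n_contra / n_total


def hl_degree_display(value: float) -> int:
    """Integer display of an HL degree (round half away from zero)."""
    return int(np.floor(value + 0.5)) if value >= 0 else -int(np.floor(-value + 0.5))


def topography_summary(
    sfc: SFCResult, montage: Montage, stimulated_side: str
) -> dict:
    """HL degree and per-hemisphere mean node intensity of an SFC.

    ``n_total`` counts every channel incident to a retained edge
    (midline channels included); ``n_contra`` counts those in the
    hemisphere contralateral to ``stimulated_side``. Mean intensities
    average the per-node sums of normalized t over each hemisphere's
    SFC channels.
    """
    if stimulated_side not in ("left", "right"):
        raise ValueError(f"stimulated_side must be left or right")
    if not sfc.clusters:
        raise ValueError("empty SFC: no retained clusters")
    contra_hemi = "right" if stimulated_side == "left" else "left"
    ipsi_hemi = stimulated_side
    chans = sfc.sfc_channels
    hemis = [montage.hemisphere[i] for i in chans]
    n_total = len(chans)
    n_contra = sum(h == contra_hemi for h in hemis)
    contra_sums = [sfc.node_sum[i] for i, h in zip(chans, hemis) if h == contra_hemi]
    ipsi_sums = [sfc.node_sum[i] for i, h in zip(chans, hemis) if h == ipsi_hemi]
    return {
        "hl_degree": hl_degree(n_contra, n_total),
        "n_contra": n_contra,
        "n_total": n_total,
        "mean_intensity_contra": float(np.mean(contra_sums)) if contra_sums else float("nan"),
        "mean_intensity_ipsi": float(np.mean(ipsi_sums)) if ipsi_sums else float("nan"),
    }
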