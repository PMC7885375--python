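"""Binary brain networks and multiscale graph-theoretic indices.

Per subject and stimulated forearm, each channel pair's trial-wise
connectivity in stimulation is compared against baseline with a paired
t-test; Benjamini–Hochberg FDR at q = 0.05 across the n(n-1)/2 pairs
selects the significant connections, which become the 1-entries of a
binary adjacency matrix (nodes = channels, links = significant FCs).

On that network the indices are computed at three scales:

* large — global efficiency ``E_glo`` (mean inverse shortest-path length
  over all node pairs, disconnected pairs contributing 0), local
  efficiency ``E_loc`` (mean of E_glo over each node's neighbour-induced
  subgraph), and smallworldness ``SW = (E_loc/E_loc_r)/(E_glo/E_glo_r)``
  against random G(n, m) references with the same node and link count;
* intermediate — interdensity ``K_inter`` (inter-hemispheric links over
  N_s^2 possible) and per-hemisphere intradensity ``K_intra`` (links
  within a hemisphere over N_s(N_s-1)/2 possible);
* small — per-node interdegree ``D_inter`` (links crossing hemispheres)
  and intradegree ``D_intra`` (links within the node's hemisphere).

Midline channels belong to neither hemisphere set: they count for the
large-scale indices but contribute zero inter/intra density and degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .montage import Montage

__all__ = [
    "BinaryNetwork",
    "NetworkIndices",
    "write_adjacency",
    "read_adjacency",
    "binarize_subject_network",
    "global_efficiency",
    "local_efficiency",
    "smallworldness",
    "inter_intra_density",
    "inter_intra_degree",
    "compute_indices",
]


@dataclass
class BinaryNetwork:
    """Symmetric 0/1 adjacency over montage channels."""

    adjacency: np.ndarray
    channels: tuple[str, ...]
    hemisphere: tuple[str, ...]  # per channel: left / right / midline

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum() // 2)

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.array(
            [i for i, h in enumerate(self.hemisphere) if h == hemi], dtype=int
        )

    @classmethod
    def from_montage(cls, adjacency: np.ndarray, montage: Montage) -> "BinaryNetwork":
        return cls(adjacency, montage.channel_names, montage.hemisphere)


@dataclass
class NetworkIndices:
    """All indices of one subject-level binary network."""

    e_glo: float
    e_loc: float
    sw: float
    e_glo_r: float
    e_loc_r: float
    k_inter: float
    k_intra_left: float
    k_intra_right: float
    d_inter: np.ndarray  # per node
    d_intra: np.ndarray  # per node
    n_random_refs: int
    seed: int | None


def write_adjacency(net: BinaryNetwork, path) -> None:
    """Write a 0/1 adjacency matrix as TSV with a channel-label header."""
    with open(path, "w") as fh:
        fh.write("\t".join(net.channels) + "\n")
        for row in net.adjacency:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_adjacency(path, montage: Montage) -> BinaryNetwork:
    with open(path) as fh:
        channels = tuple(fh.readline().rstrip("\n").split("\t"))
        adj = np.loadtxt(fh, dtype=np.int8)
    hemis = tuple(montage.hemisphere_of(ch) for ch in channels)
    return BinaryNetwork(adjacency=np.atleast_2d(adj), channels=channels,
                         hemisphere=hemis)


def binarize_subject_network(
    stim_fc: np.ndarray,
    base_fc: np.ndarray,
    montage: Montage,
    alpha: float = 0.05,
) -> BinaryNetwork:
    """Threshold stimulation-vs-baseline pair statistics into a 0/1 net.

    ``stim_fc`` and ``base_fc`` are (n_trials, n_ch, n_ch) per-trial
    connectivity stacks; trial k of stimulation is paired with trial k of
    baseline (session order). Pairs surviving Benjamini–Hochberg FDR at
    ``alpha`` over all unordered pairs become links.
    """
    stim_fc = np.asarray(stim_fc)
    base_fc = np.asarray(base_fc)
    if stim_fc.shape != base_fc.shape:
        raise ValueError(
            f"conditions must have equal trial counts and shapes: "
            f"{stim_fc.shape} vs {base_fc.shape}"
        )
    if stim_fc.shape[0] < 2:
        raise ValueError("need at least 2 trial pairs for a paired t-test")
    n = stim_fc.shape[1]
    iu = np.triu_indices(n, 1)
    diff = (stim_fc - base_fc)[:, iu[0], iu[1]]  # (trials, pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_rel(stim_fc[:, iu[0], iu[1]], base_fc[:, iu[0], iu[1]],
                               axis=0)
    # constant-difference pairs have undefined t; they carry no evidence
    p = np.where(np.isfinite(p), p, 1.0)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")[:4]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][reject], iu[1][reject]] = 1
    adj += adj.T
    return BinaryNetwork.from_montage(adj, montage)


def _pairwise_inverse_distance_sum(adjacency: np.ndarray) -> float:
    """Sum over ordered pairs of 1/d_ij (0 for disconnected pairs)."""
    d = shortest_path(csr_matrix(adjacency), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum())


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    n = a.shape[0]
    if n < 2:
        return 0.0
    return _pairwise_inverse_distance_sum(a) / (n * (n - 1))


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean efficiency of each node's neighbour-induced subgraph.

    Nodes with fewer than two neighbours contribute 0 (their subgraph
    has no pairs).
    """
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs) < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def _random_gnm(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random graph with n nodes and exactly m links."""
    iu = np.triu_indices(n, 1)
    n_pairs = len(iu[0])
    pick = rng.choice(n_pairs, size=m, replace=False)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][pick], iu[1][pick]] = 1
    return adj + adj.T


def smallworldness(
    net: BinaryNetwork,
    n_refs: int = 100,
    seed: int | None = None,
) -> dict:
    """SW against G(n, m) references with matched node and link counts.

    Returns ``{"sw", "e_glo_r", "e_loc_r"}``; ``sw`` is NaN (with a
    warning) when the references are too sparse to carry any triangles
    (``e_loc_r == 0``).
    """
    if net.n_links < 1:
        raise ValueError("smallworldness needs at least one link")
    rng = np.random.default_rng(seed)
    eg, el = [], []
    for _ in range(n_refs):
        ref = _random_gnm(net.n_nodes, net.n_links, rng)
        eg.append(global_efficiency(ref))
        el.append(local_efficiency(ref))
    e_glo_r = float(np.mean(eg))
    e_loc_r = float(np.mean(el))
    e_glo = global_efficiency(net)
    e_loc = local_efficiency(net)
    if e_loc_r == 0.0 or e_glo == 0.0:
        warnings.warn(
            "random references have no clustering (e_loc_r = 0); "
            "smallworldness undefined", RuntimeWarning, stacklevel=2,
        )
        sw = float("nan")
    else:
        sw = (e_loc / e_loc_r) / (e_glo / e_glo_r)
    return {"sw": sw, "e_glo_r": e_glo_r, "e_loc_r": e_loc_r}


def _check_equal_hemispheres(net: BinaryNetwork) -> tuple[np.ndarray, np.ndarray]:
    left = net.hemi_indices("left")
    right = net.hemi_indices("right")
    if len(left) != len(right):
        raise ValueError(
            f"hemisphere sets must be equal-sized (got {len(left)} left, "
            f"{len(right)} right); the 1/N_s^2 interdensity normalization "
            "presumes two equal sets"
        )
    if len(left) == 0:
        raise ValueError("no lateral channels")
    return left, right


def inter_intra_density(net: BinaryNetwork) -> dict:
    """Inter-hemispheric and per-hemisphere link densities, each in [0, 1]."""
    left, right = _check_equal_hemispheres(net)
    ns = len(left)
    a = net.adjacency
    inter = int(a[np.ix_(left, right)].sum())
    intra_l = int(a[np.ix_(left, left)].sum()) // 2
    intra_r = int(a[np.ix_(right, right)].sum()) // 2
    denom_intra = ns * (ns - 1) / 2
    return {
        "k_inter": inter / ns**2,
        "k_intra_left": intra_l / denom_intra,
        "k_intra_right": intra_r / denom_intra,
    }


def inter_intra_degree(net: BinaryNetwork) -> dict:
    """Per-node cross- and within-hemisphere link counts.

    Midline nodes report 0 for both by convention (they belong to
    neither hemisphere set).
    """
    a = net.adjacency
    n = net.n_nodes
    left, right = net.hemi_indices("left"), net.hemi_indices("right")
    side = np.zeros(n, dtype=int)  # 0 midline, -1 left, +1 right
    side[left] = -1
    side[right] = 1
    d_inter = np.zeros(n, dtype=int)
    d_intra = np.zeros(n, dtype=int)
    lateral = np.nonzero(side != 0)[0]
    for i in lateral:
        opp = lateral[side[lateral] == -side[i]]
        same = lateral[(side[lateral] == side[i]) & (lateral != i)]
        d_inter[i] = int(a[i, opp].sum())
        d_intra[i] = int(a[i, same].sum())
    return {"d_inter": d_inter, "d_intra": d_intra}


def compute_indices(
    net: BinaryNetwork,
    n_random_refs: int = 100,
    seed: int | None = None,
) -> NetworkIndices:
    """All multiscale indices of one binary network."""
    dens = inter_intra_density(net)
    deg = inter_intra_degree(net)
    if net.n_links >= 1:
        sw = smallworldness(net, n_refs=n_random_refs, seed=seed)
    else:
        sw = {"sw": float("nan"), "e_glo_r": 0.0, "e_loc_r": 0.0}
    return NetworkIndices(
        e_glo=global_efficiency(net),
        e_loc=local_efficiency(net),
        sw=sw["sw"],
        e_glo_r=sw["e_glo_r"],
        e_loc_r=sw["e_loc_r"],
        k_inter=dens["k_inter"],
        k_intra_left=dens["k_intra_left"],
        k_intra_right=dens["k_intra_right"],
        d_inter=deg["d_inter"],
        d_intra=deg["d_intra"],
        n_random_refs=n_random_refs,
        seed=seed,
    )
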