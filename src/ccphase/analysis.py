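"""Trajectory observables: density profiles, cluster sizes, phase calls,
MSD diffusion, and coil-engagement statistics.

Phase separation is read off two complementary markers: a density transition
along the slab axis (coexisting dense and dilute regions) and molecular
clusters containing nearly all chains.  A system that fails both but spends
most of its time with size-2 clusters as the dominant species is a
dimer-poisoned design; everything else is diffuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from ccphase.engine import Trajectory
from ccphase.forcefield import ForceFieldParams, InteractionMatrix

__all__ = [
    "DensityProfile",
    "ClusterReport",
    "DiffusionResult",
    "EngagementReport",
    "PhaseCall",
    "chain_coms",
    "equilibrated_window",
    "density_profile",
    "realized_contact_pairs",
    "contact_chain_pairs",
    "cluster_distribution",
    "classify_phase",
    "msd_diffusion",
    "coil_engagement",
]

DEFAULT_CONTACT_FACTOR = 1.5  # contact cutoff = 1.5 * sigma_sticky


def chain_coms(traj: Trajectory, frames: slice | None = None) -> np.ndarray:
    """(F, n_chains, 3) unwrapped chain centers of mass."""
    top = traj.topology
    fr = traj.frames if frames is None else traj.frames[frames]
    out = np.empty((fr.shape[0], top.n_chains, 3))
    for c in range(top.n_chains):
        sl = top.chain_slice(c)
        out[:, c] = fr[:, sl].mean(axis=1)
    return out


def equilibrated_window(traj: Trajectory, fraction: float = 0.5) -> slice:
    """Final ``fraction`` of frames, the default equilibrated window."""
    start = int(traj.n_frames * (1.0 - fraction))
    return slice(start, traj.n_frames)


# ---------------------------------------------------------------------------
# density profile
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Chain number density along z, slab-recentered and frame-averaged."""

    bin_centers: np.ndarray  # nm, relative to box center after recentering
    density: np.ndarray  # chains / nm^3
    dense_density: float
    dilute_density: float
    n_chains: int
    box: np.ndarray

    @property
    def ratio(self) -> float:
        floor = self.n_chains / float(np.prod(self.box)) / 100.0
        return self.dense_density / max(self.dilute_density, floor)


def _circular_center(z: np.ndarray, L: float) -> float:
    theta = 2.0 * np.pi * z / L
    return (np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()) % (2 * np.pi)) * L / (
        2 * np.pi
    )


def density_profile(
    traj: Trajectory,
    window: slice | None = None,
    n_bins: int = 50,
    axis: int = 2,
    recenter: bool = True,
) -> DensityProfile:
    """Average chain-COM number density along ``axis``.

    Each frame is recentered on the circular mean of the chain coordinates
    (the dense slab's center under periodic boundaries) before averaging, so
    a drifting slab does not smear the profile.  Dense density is the mean
    over the tenth of bins nearest the center, dilute over the farthest
    quarter.
    """
    if window is None:
        window = equilibrated_window(traj)
    coms = chain_coms(traj, window)
    if coms.shape[0] < 1:
        raise ValueError("empty equilibrated window")
    L = float(traj.box[axis])
    nch = coms.shape[1]
    edges = np.linspace(0.0, L, n_bins + 1)
    bin_vol = np.prod(traj.box) / L * (L / n_bins)
    hist = np.zeros(n_bins)
    for f in range(coms.shape[0]):
        z = coms[f, :, axis] % L
        if recenter:
            center = _circular_center(z, L)
            z = (z - center + L / 2.0) % L
        hist += np.histogram(z, bins=edges)[0]
    density = hist / coms.shape[0] / bin_vol
    centers = 0.5 * (edges[:-1] + edges[1:]) - L / 2.0
    order = np.argsort(np.abs(centers))
    k_dense = max(1, n_bins // 10)
    k_dilute = max(1, n_bins // 4)
    dense = float(density[order[:k_dense]].mean())
    dilute = float(density[order[-k_dilute:]].mean())
    return DensityProfile(
        bin_centers=centers,
        density=density,
        dense_density=dense,
        dilute_density=dilute,
        n_chains=nch,
        box=np.asarray(traj.box, float),
    )


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterReport:
    """Per-frame molecular cluster sizes and their summary statistics."""

    sizes_per_frame: list  # list of sorted int arrays, one per frame
    dimer_dominance_fraction: float
    largest_cluster_fraction: float  # mean over frames, mass fraction
    size_histogram: dict  # size -> mean count per frame
    n_chains: int
    contact_cutoff: float


def _complementary_pairs(pos_wrapped, box, top, matrix, cutoff):
    """(i, j) bead pairs that are matrix-attractive, registry-compatible and
    within ``cutoff`` (periodic)."""
    coil = np.where(top.type_id >= 0)[0]
    if len(coil) == 0:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(pos_wrapped[coil], boxsize=box)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    if len(raw) == 0:
        return np.empty((0, 2), dtype=int)
    i = coil[raw[:, 0]]
    j = coil[raw[:, 1]]
    t1 = top.type_id[i]
    t2 = top.type_id[j]
    rule = matrix.rule_matrix[t1, t2]
    ri = top.registry[i]
    rj = top.registry[j]
    ok_par = (rule == 1) & (ri == rj)
    ok_anti = (rule == 2) & (top.coil_len[i] == top.coil_len[j]) & (
        rj == top.coil_len[i] + 1 - ri
    )
    keep = (ok_par | ok_anti) & (top.coil_seg[i] != top.coil_seg[j])
    return np.column_stack([i[keep], j[keep]])


def realized_contact_pairs(pos, box, top, matrix, cutoff, params=None):
    """Complementary bead pairs the force field currently treats as bound.

    Starts from registry-compatible complementary pairs within ``cutoff``,
    then applies the same orientation gate and mutual-nearest-partner
    selection the sticky potential uses.  Counting only these *realized*
    contacts keeps crowding artifacts out of the cluster graph: a slab of
    fully satisfied dimers is a gas of dimers, not one component.
    """
    params = params or ForceFieldParams()
    pos_w = pos % box
    bp = _complementary_pairs(pos_w, box, top, matrix, cutoff)
    if len(bp) == 0:
        return bp
    from ccphase import _kernels

    axes = np.empty((top.n_coil_segments, 3))
    _kernels.coil_axes(np.ascontiguousarray(pos, dtype=np.float64),
                       np.asarray(box, float), top.seg_start, top.seg_len, axes)
    i, j = bp[:, 0], bp[:, 1]
    dot = np.einsum("ij,ij->i", axes[top.coil_seg[i]], axes[top.coil_seg[j]])
    o = matrix.rule_matrix[top.type_id[i], top.type_id[j]]
    gated = ((o == 1) & (dot >= params.gate_cos)) | (
        (o == 2) & (dot <= -params.gate_cos)
    )
    bp = bp[gated]
    if len(bp) == 0:
        return bp
    # mutual-nearest selection (1:1 valence saturation)
    d = pos[bp[:, 0]] - pos[bp[:, 1]]
    d -= box * np.round(d / box)
    r2 = np.einsum("ij,ij->i", d, d)
    order = np.argsort(r2, kind="stable")
    best = {}
    for p in order:
        a, b = int(bp[p, 0]), int(bp[p, 1])
        if a not in best:
            best[a] = b
        if b not in best:
            best[b] = a
    keep = [p for p in range(len(bp))
            if best.get(int(bp[p, 0])) == int(bp[p, 1])
            and best.get(int(bp[p, 1])) == int(bp[p, 0])]
    return bp[keep]


def contact_chain_pairs(pos, box, top, matrix, cutoff, params=None):
    """Distinct chain pairs linked by >= 1 realized complementary contact."""
    bp = realized_contact_pairs(pos, box, top, matrix, cutoff, params)
    if len(bp) == 0:
        return set()
    c1 = top.chain_id[bp[:, 0]]
    c2 = top.chain_id[bp[:, 1]]
    return {
        (int(min(a, b)), int(max(a, b)))
        for a, b in zip(c1, c2)
        if a != b
    }


def _dominant_size(sizes: np.ndarray) -> int:
    """Cluster size class holding the plurality of chains; ties go larger."""
    uniq, counts = np.unique(sizes, return_counts=True)
    mass = uniq * counts
    best = np.where(mass == mass.max())[0]
    return int(uniq[best].max())


def cluster_distribution(
    traj: Trajectory,
    contact_cutoff: float | None = None,
    matrix: InteractionMatrix | None = None,
    params: ForceFieldParams | None = None,
    window: slice | None = None,
    union_window: int = 5,
) -> ClusterReport:
    """Molecular cluster-size distribution over the equilibrated window.

    Two chains are connected when any realized complementary bead pair
    (registry-compatible, orientation-gated, mutually nearest) sits within
    the contact cutoff (default 1.5 sigma_sticky) in any frame of a sliding
    window of +-``union_window`` frames; clusters are the connected
    components of that chain graph.  The union smooths the instantaneous
    graph, which at small chain counts undercounts droplet membership
    whenever a chain is momentarily between binding partners.
    """
    params = params or ForceFieldParams()
    matrix = matrix or InteractionMatrix.default(params)
    if contact_cutoff is None:
        contact_cutoff = DEFAULT_CONTACT_FACTOR * params.sigma_sticky
    if contact_cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    if window is None:
        window = equilibrated_window(traj)
    top = traj.topology
    nch = top.n_chains
    sizes_per_frame = []
    dominant_is_dimer = 0
    largest_frac = []
    hist: dict = {}
    frames = traj.frames[window]
    per_frame_edges = [
        contact_chain_pairs(frames[f], traj.box, top, matrix,
                            contact_cutoff, params)
        for f in range(frames.shape[0])
    ]
    for f in range(frames.shape[0]):
        # instantaneous graph: species statistics (sizes, dominant class)
        g = nx.Graph()
        g.add_nodes_from(range(nch))
        g.add_edges_from(per_frame_edges[f])
        sizes = np.sort([len(c) for c in nx.connected_components(g)])
        assert sizes.sum() == nch
        sizes_per_frame.append(sizes)
        if _dominant_size(sizes) == 2:
            dominant_is_dimer += 1
        for s, cnt in zip(*np.unique(sizes, return_counts=True)):
            hist[int(s)] = hist.get(int(s), 0) + int(cnt)
        # persistence-smoothed graph: droplet membership ("nearly all
        # chains in one cluster") — a chain momentarily between partners
        # inside the droplet still belongs to it
        lo = max(0, f - union_window)
        hi = min(frames.shape[0], f + union_window + 1)
        gs = nx.Graph()
        gs.add_nodes_from(range(nch))
        gs.add_edges_from(set().union(*per_frame_edges[lo:hi]))
        largest_frac.append(
            max(len(c) for c in nx.connected_components(gs)) / nch
        )
    nf = len(sizes_per_frame)
    return ClusterReport(
        sizes_per_frame=sizes_per_frame,
        dimer_dominance_fraction=dominant_is_dimer / nf,
        largest_cluster_fraction=float(np.mean(largest_frac)),
        size_histogram={s: c / nf for s, c in sorted(hist.items())},
        n_chains=nch,
        contact_cutoff=contact_cutoff,
    )


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------


@dataclass
class PhaseCall:
    """Condensate / dimer / diffuse call with its numeric evidence."""

    label: str
    density_ratio: float
    largest_cluster_fraction: float
    dimer_dominance_fraction: float
    thresholds: dict = field(default_factory=dict)


def classify_phase(
    density: DensityProfile,
    clusters: ClusterReport,
    ratio_min: float = 5.0,
    largest_min: float = 0.8,
    dimer_min: float = 0.5,
) -> PhaseCall:
    """Phase call from density contrast and cluster structure.

    condensate: dense/dilute ratio >= ratio_min AND the largest cluster
    holds >= largest_min of all chains (the "nearly all" criterion);
    dimer: not condensate, but size-2 clusters dominate >= dimer_min of
    frames; diffuse otherwise.
    """
    if clusters.largest_cluster_fraction >= largest_min and density.ratio >= ratio_min:
        label = "condensate"
    elif clusters.dimer_dominance_fraction >= dimer_min:
        label = "dimer"
    else:
        label = "diffuse"
    return PhaseCall(
        label=label,
        density_ratio=density.ratio,
        largest_cluster_fraction=clusters.largest_cluster_fraction,
        dimer_dominance_fraction=clusters.dimer_dominance_fraction,
        thresholds={
            "ratio_min": ratio_min,
            "largest_min": largest_min,
            "dimer_min": dimer_min,
        },
    )


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


@dataclass
class DiffusionResult:
    """Effective diffusion coefficient from chain-COM MSD."""

    D_cm2_s: float
    D_sd_cm2_s: float
    msd: np.ndarray  # nm^2, per lag
    lags_ps: np.ndarray
    fit_window: tuple
    r_squared: float
    subdiffusive: bool


def _msd_curve(coms: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD per chain: (n_lags, n_chains).

    Lags run to a quarter of the window so every lag retains enough
    independent time origins for a stable average.
    """
    F = coms.shape[0]
    lags = max(3, F // 4)
    out = np.empty((lags, coms.shape[1]))
    for lag in range(1, lags + 1):
        d = coms[lag:] - coms[:-lag]
        out[lag - 1] = (d ** 2).sum(axis=2).mean(axis=0)
    return out


def msd_diffusion(
    traj: Trajectory,
    n_bootstrap: int = 200,
    seed: int = 0,
    window: slice | None = None,
    fit_fraction: tuple = (0.1, 0.5),
) -> DiffusionResult:
    """Diffusion coefficient from the chain-COM MSD slope (slope/6, 3D).

    The fit uses lags between 10% and 50% of the maximum lag; the standard
    deviation comes from bootstrap resampling chains.  Fits with R^2 < 0.9
    are flagged subdiffusive but still reported.
    """
    if window is None:
        window = equilibrated_window(traj)
    coms = chain_coms(traj, window)
    if coms.shape[0] < 4:
        raise ValueError("need at least 4 frames for an MSD fit")
    dt_frame = float(np.mean(np.diff(traj.times)))
    per_chain = _msd_curve(coms)  # (lags, chains)
    lags_ps = np.arange(1, per_chain.shape[0] + 1) * dt_frame
    lo = max(0, int(fit_fraction[0] * per_chain.shape[0]) - 1)
    hi = max(lo + 2, int(fit_fraction[1] * per_chain.shape[0]))
    x = lags_ps[lo:hi]

    def fit_D(msd_mean):
        y = msd_mean[lo:hi]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
        return max(slope, 0.0) / 6.0, r2

    msd_mean = per_chain.mean(axis=1)
    D_nm2_ps, r2 = fit_D(msd_mean)
    rng = np.random.default_rng(seed)
    nch = per_chain.shape[1]
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        pick = rng.integers(0, nch, nch)
        boots[b] = fit_D(per_chain[:, pick].mean(axis=1))[0]
    to_cm2_s = 1e-2  # nm^2/ps -> cm^2/s
    return DiffusionResult(
        D_cm2_s=D_nm2_ps * to_cm2_s,
        D_sd_cm2_s=float(boots.std(ddof=1)) * to_cm2_s,
        msd=msd_mean,
        lags_ps=lags_ps,
        fit_window=(float(x[0]), float(x[-1])),
        r_squared=r2,
        subdiffusive=bool(r2 < 0.9),
    )


# ---------------------------------------------------------------------------
# coil engagement
# ---------------------------------------------------------------------------


@dataclass
class EngagementReport:
    """Per-coil engaged-time fractions and unique-partner counts."""

    engaged_fraction: np.ndarray  # per coil segment
    unique_partners: np.ndarray  # per coil segment, int
    mean_engaged_fraction: float
    mean_unique_partners: float
    contact_cutoff: float


def coil_engagement(
    traj: Trajectory,
    contact_cutoff: float | None = None,
    matrix: InteractionMatrix | None = None,
    params: ForceFieldParams | None = None,
    window: slice | None = None,
    min_bead_fraction: float = 0.5,
) -> EngagementReport:
    """Engaged-time fraction and unique partner count per coil segment.

    A coil is engaged in a frame when at least ``min_bead_fraction`` of its
    beads are within the contact cutoff of complementary beads of a single
    partner coil; unique partners are counted over all frames in the window.
    """
    params = params or ForceFieldParams()
    matrix = matrix or InteractionMatrix.default(params)
    if contact_cutoff is None:
        contact_cutoff = DEFAULT_CONTACT_FACTOR * params.sigma_sticky
    if window is None:
        window = equilibrated_window(traj)
    top = traj.topology
    nseg = top.n_coil_segments
    frames = traj.frames[window]
    engaged_count = np.zeros(nseg)
    partners: list = [set() for _ in range(nseg)]
    need = np.maximum(1, np.ceil(min_bead_fraction * top.seg_len).astype(int))
    for f in range(frames.shape[0]):
        bp = realized_contact_pairs(frames[f], traj.box, top, matrix,
                                    contact_cutoff, params)
        # count distinct contacting beads per (segment, partner segment)
        touched: dict = {}
        for i, j in bp:
            si, sj = int(top.coil_seg[i]), int(top.coil_seg[j])
            touched.setdefault((si, sj), set()).add(int(i))
            touched.setdefault((sj, si), set()).add(int(j))
        engaged_now = np.zeros(nseg, dtype=bool)
        for (s, p), beads in touched.items():
            if len(beads) >= need[s]:
                engaged_now[s] = True
                partners[s].add(p)
        engaged_count += engaged_now
    frac = engaged_count / frames.shape[0]
    uniq = np.array([len(p) for p in partners])
    return EngagementReport(
        engaged_fraction=frac,
        unique_partners=uniq,
        mean_engaged_fraction=float(frac.mean()),
        mean_unique_partners=float(uniq.mean()),
        contact_cutoff=contact_cutoff,
    )
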