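"""Observable calculations against brute-force and synthetic oracles."""

import numpy as np
import pytest

from ccphase.analysis import (
    ClusterReport,
    DensityProfile,
    _dominant_size,
    chain_coms,
    classify_phase,
    cluster_distribution,
    coil_engagement,
    contact_chain_pairs,
    density_profile,
    msd_diffusion,
)
from ccphase.constructs import parse_construct
from ccphase.engine import Trajectory
from ccphase.topology import build_system_topology

from test_engine import free_bead_topology


def make_traj(frames, box, topology, dt_frame=1.0):
    frames = np.asarray(frames, float)
    return Trajectory(
        frames=frames,
        times=dt_frame * np.arange(1, frames.shape[0] + 1),
        kinetic_temperature=np.full(frames.shape[0], 300.0),
        box=np.asarray(box, float),
        topology=topology,
    )


def coil_gas_trajectory(n_chains, box, n_frames, seed, construct="(S1h)1"):
    """Chains as tiny compact blobs at uniform random positions per frame."""
    top = build_system_topology([(parse_construct(construct), n_chains)])
    rng = np.random.default_rng(seed)
    nb = top.n_beads // n_chains
    frames = np.empty((n_frames, top.n_beads, 3))
    local = rng.normal(0.0, 0.05, (nb, 3))
    for f in range(n_frames):
        for c in range(n_chains):
            center = rng.uniform(0, 1, 3) * np.asarray(box)
            frames[f, c * nb : (c + 1) * nb] = center + local
    return make_traj(frames, box, top)


def brute_force_clusters(pos, box, top, matrix, cutoff, gate_cos=0.5):
    """Independent O(n^2) connected components over the realized contact graph.

    Re-derives complementarity, the coil-axis orientation gate, and the
    mutual-nearest-partner selection from first principles, without any of
    the package's neighbor-search machinery.
    """
    n = top.n_beads
    # coil axes from summed bond vectors (min image)
    axes = np.zeros((top.n_coil_segments, 3))
    for s in range(top.n_coil_segments):
        a0, L = int(top.seg_start[s]), int(top.seg_len[s])
        v = np.zeros(3)
        for k in range(L - 1):
            d = pos[a0 + k + 1] - pos[a0 + k]
            d -= box * np.round(d / box)
            v += d
        axes[s] = v / np.linalg.norm(v)
    # candidate pairs: complementary, gated, within cutoff
    cand = []
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = top.type_id[i], top.type_id[j]
            if ti < 0 or tj < 0 or top.coil_seg[i] == top.coil_seg[j]:
                continue
            rule = matrix.rule_matrix[ti, tj]
            if rule == 0:
                continue
            ri, rj = top.registry[i], top.registry[j]
            if rule == 1 and ri != rj:
                continue
            if rule == 2 and (
                top.coil_len[i] != top.coil_len[j]
                or rj != top.coil_len[i] + 1 - ri
            ):
                continue
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            r2 = np.dot(d, d)
            if r2 >= cutoff ** 2:
                continue
            dot = np.dot(axes[top.coil_seg[i]], axes[top.coil_seg[j]])
            if rule == 1 and dot < gate_cos:
                continue
            if rule == 2 and dot > -gate_cos:
                continue
            cand.append((r2, i, j))
    # mutual-nearest selection
    best = {}
    for r2, i, j in sorted(cand):
        if i not in best:
            best[i] = j
        if j not in best:
            best[j] = i
    adj = {c: set() for c in range(top.n_chains)}
    for r2, i, j in cand:
        if best.get(i) == j and best.get(j) == i:
            a, b = top.chain_id[i], top.chain_id[j]
            if a != b:
                adj[a].add(b)
                adj[b].add(a)
    seen, sizes = set(), []
    for c in range(top.n_chains):
        if c in seen:
            continue
        stack, comp = [c], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        sizes.append(len(comp))
    return sorted(sizes)


class TestClusters:
    def test_matches_brute_force_on_random_frames(self, ff, matrix):
        box = np.array([6.0, 6.0, 6.0])
        top = build_system_topology(
            [(parse_construct("(S1h)1"), 4), (parse_construct("(S2h)1"), 4)]
        )
        cutoff = 1.5 * ff.sigma_sticky
        rng = np.random.default_rng(7)
        nb = 21
        for trial in range(5):
            pos = np.empty((top.n_beads, 3))
            for c in range(8):
                start = rng.uniform(0, 6.0, 3)
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                pos[c * nb : (c + 1) * nb] = start + 0.38 * np.arange(nb)[:, None] * d
            traj = make_traj(pos[None], box, top)
            rep = cluster_distribution(traj, matrix=matrix, params=ff,
                                       window=slice(0, 1))
            expected = brute_force_clusters(pos, box, top, matrix, cutoff)
            assert list(rep.sizes_per_frame[0]) == expected

    def test_isolated_chains_all_singletons(self, ff, matrix):
        traj = coil_gas_trajectory(5, (50.0, 50.0, 50.0), 3, seed=1)
        rep = cluster_distribution(traj, matrix=matrix, params=ff,
                                   window=slice(0, 3))
        for sizes in rep.sizes_per_frame:
            assert list(sizes) == [1] * 5

    def test_single_bound_pair_among_four(self, ff, matrix):
        top = build_system_topology(
            [(parse_construct("(S1h)1"), 2), (parse_construct("(S2h)1"), 2)]
        )
        pos = np.zeros((84, 3))
        # chains 0,1: S1h; chains 2,3: S2h; bind chain 0 to chain 2
        for c, offset in ((0, (1, 1, 1)), (1, (14, 1, 1)), (2, (1, 1.6, 1)), (3, (14, 14, 14))):
            pos[c * 21 : (c + 1) * 21] = np.asarray(offset) + [[0.38 * k, 0, 0] for k in range(21)]
        traj = make_traj(pos[None], (28.0, 28.0, 28.0), top)
        rep = cluster_distribution(traj, matrix=matrix, params=ff, window=slice(0, 1))
        assert list(rep.sizes_per_frame[0]) == [1, 1, 2]

    def test_sizes_partition_chain_count(self, ff, matrix):
        traj = coil_gas_trajectory(6, (8.0, 8.0, 8.0), 4, seed=3)
        rep = cluster_distribution(traj, matrix=matrix, params=ff, window=slice(0, 4))
        for sizes in rep.sizes_per_frame:
            assert sizes.sum() == 6

    def test_dominant_size_tie_breaks_larger(self):
        assert _dominant_size(np.array([2, 2, 4])) == 4
        assert _dominant_size(np.array([2, 2, 1, 1])) == 2
        assert _dominant_size(np.array([5, 1, 1, 1])) == 5

    def test_bad_cutoff_rejected(self, ff, matrix):
        traj = coil_gas_trajectory(2, (8.0, 8.0, 8.0), 1, seed=0)
        with pytest.raises(ValueError):
            cluster_distribution(traj, contact_cutoff=-1.0, matrix=matrix, params=ff)


class TestDensityProfile:
    def test_uniform_gas_flat_profile(self, ff, matrix):
        n_chains, n_frames, n_bins = 40, 120, 10
        traj = coil_gas_trajectory(n_chains, (12.0, 12.0, 12.0), n_frames, seed=5)
        # recentering is a slab aid; a uniform gas has no slab to center on
        prof = density_profile(traj, window=slice(0, n_frames), n_bins=n_bins,
                               recenter=False)
        per_bin = n_chains / n_bins  # expected chains per slab bin
        sd = np.sqrt(per_bin / n_frames)
        bin_vol = 12.0 ** 3 / n_bins
        counts = prof.density * bin_vol
        assert np.all(np.abs(counts - per_bin) < 3 * sd + 1e-9)

    def test_normalization_integrates_to_chain_count(self, ff, matrix):
        traj = coil_gas_trajectory(17, (9.0, 9.0, 9.0), 20, seed=2)
        prof = density_profile(traj, window=slice(0, 20), n_bins=30)
        bin_vol = 9.0 ** 3 / 30
        assert prof.density.sum() * bin_vol == pytest.approx(17, abs=1e-9)

    def test_slab_gives_large_contrast(self, ff, matrix):
        top = free_bead_topology(n_chains=30)
        rng = np.random.default_rng(0)
        frames = np.empty((10, 30, 3))
        for f in range(10):
            frames[f, :, 0] = rng.uniform(0, 10, 30)
            frames[f, :, 1] = rng.uniform(0, 10, 30)
            frames[f, :, 2] = rng.uniform(24, 26, 30)  # thin slab in z
        traj = make_traj(frames, (10.0, 10.0, 50.0), top)
        prof = density_profile(traj, window=slice(0, 10), n_bins=50)
        assert prof.dilute_density == pytest.approx(0.0, abs=1e-12)
        assert prof.ratio > 5

    def test_empty_window_rejected(self, ff, matrix):
        traj = coil_gas_trajectory(3, (8.0, 8.0, 8.0), 4, seed=0)
        with pytest.raises(ValueError):
            density_profile(traj, window=slice(4, 4))


class TestClassify:
    def make_profile(self, ratio):
        return DensityProfile(
            bin_centers=np.linspace(-5, 5, 10),
            density=np.ones(10),
            dense_density=float(ratio),
            dilute_density=1.0,
            n_chains=100,
            box=np.array([10.0, 10.0, 10.0]),
        )

    def make_clusters(self, largest, dimer_dom):
        return ClusterReport(
            sizes_per_frame=[],
            dimer_dominance_fraction=dimer_dom,
            largest_cluster_fraction=largest,
            size_histogram={},
            n_chains=16,
            contact_cutoff=0.85,
        )

    @pytest.mark.parametrize(
        "ratio, largest, dom, label",
        [
            (50.0, 0.95, 0.0, "condensate"),
            (50.0, 0.5, 0.8, "dimer"),
            (2.0, 0.95, 0.1, "diffuse"),
            (50.0, 0.5, 0.2, "diffuse"),
            (4.9, 0.95, 0.6, "dimer"),
        ],
    )
    def test_threshold_logic(self, ratio, largest, dom, label):
        call = classify_phase(self.make_profile(ratio), self.make_clusters(largest, dom))
        assert call.label == label
        assert call.thresholds == {"ratio_min": 5.0, "largest_min": 0.8,
                                   "dimer_min": 0.5}


class TestMSD:
    def test_frozen_trajectory_zero_diffusion(self):
        top = free_bead_topology(n_chains=5)
        frame = np.tile(np.arange(5)[:, None] * 2.0, (1, 3))
        frames = np.tile(frame, (50, 1, 1))
        traj = make_traj(frames, (50.0, 50.0, 50.0), top)
        res = msd_diffusion(traj, n_bootstrap=20, seed=0, window=slice(0, 50))
        assert res.D_cm2_s == 0.0

    def test_synthetic_random_walk_recovers_D(self):
        top = free_bead_topology(n_chains=30)
        D_nm2_ps = 0.01
        dt_frame = 2.0
        rng = np.random.default_rng(12)
        steps = rng.normal(0, np.sqrt(2 * D_nm2_ps * dt_frame), (400, 30, 3))
        frames = np.cumsum(steps, axis=0) + 100.0
        traj = make_traj(frames, (1e4, 1e4, 1e4), top, dt_frame=dt_frame)
        res = msd_diffusion(traj, n_bootstrap=100, seed=1, window=slice(0, 400))
        assert res.D_cm2_s == pytest.approx(D_nm2_ps * 1e-2, rel=0.1)
        assert not res.subdiffusive
        assert res.D_sd_cm2_s > 0

    def test_bootstrap_sd_shrinks_with_more_chains(self):
        D_nm2_ps, dt_frame = 0.01, 2.0
        sds = []
        for n_chains in (5, 80):
            top = free_bead_topology(n_chains=n_chains)
            rng = np.random.default_rng(3)
            steps = rng.normal(0, np.sqrt(2 * D_nm2_ps * dt_frame),
                               (300, n_chains, 3))
            frames = np.cumsum(steps, axis=0)
            traj = make_traj(frames, (1e4, 1e4, 1e4), top, dt_frame=dt_frame)
            res = msd_diffusion(traj, n_bootstrap=100, seed=2,
                                window=slice(0, 300))
            sds.append(res.D_sd_cm2_s)
        assert sds[1] < sds[0]

    def test_subdiffusive_flagged(self):
        top = free_bead_topology(n_chains=10)
        rng = np.random.default_rng(9)
        # confined motion: positions bounce inside a cage, MSD saturates
        centers = rng.uniform(0, 100, (1, 10, 3))
        base = centers + rng.normal(0, 0.5, (300, 10, 3))
        traj = make_traj(base, (1e4, 1e4, 1e4), top, dt_frame=1.0)
        res = msd_diffusion(traj, n_bootstrap=20, seed=0, window=slice(0, 300))
        assert res.subdiffusive

    def test_too_few_frames_rejected(self):
        top = free_bead_topology(n_chains=2)
        traj = make_traj(np.zeros((2, 2, 3)), (10.0, 10.0, 10.0), top)
        with pytest.raises(ValueError):
            msd_diffusion(traj, window=slice(0, 2))


class TestEngagement:
    def test_permanent_dimer(self, ff, matrix):
        top = build_system_topology(
            [(parse_construct("(S1h)1"), 1), (parse_construct("(S2h)1"), 1)]
        )
        pos = np.zeros((42, 3))
        pos[:21] = [[0.38 * k + 1, 1.0, 1.0] for k in range(21)]
        pos[21:] = [[0.38 * k + 1, 1.62, 1.0] for k in range(21)]
        frames = np.tile(pos, (6, 1, 1))
        traj = make_traj(frames, (12.0, 12.0, 12.0), top)
        rep = coil_engagement(traj, matrix=matrix, params=ff, window=slice(0, 6))
        assert np.allclose(rep.engaged_fraction, 1.0)
        assert list(rep.unique_partners) == [1, 1]

    def test_never_contacting(self, ff, matrix):
        traj = coil_gas_trajectory(4, (60.0, 60.0, 60.0), 4, seed=8)
        rep = coil_engagement(traj, matrix=matrix, params=ff, window=slice(0, 4))
        assert np.allclose(rep.engaged_fraction, 0.0)
        assert rep.mean_unique_partners == 0.0

    def test_grazing_contact_not_engaged(self, ff, matrix):
        """A single-bead touch does not count as an engaged coil."""
        top = build_system_topology(
            [(parse_construct("(S1h)1"), 1), (parse_construct("(S2h)1"), 1)]
        )
        pos = np.zeros((42, 3))
        pos[:21] = [[0.38 * k + 1, 1.0, 1.0] for k in range(21)]
        # perpendicular chain crossing near one end: few complementary contacts
        pos[21:] = [[1.0, 0.38 * k + 0.8, 1.5] for k in range(21)]
        traj = make_traj(pos[None], (12.0, 12.0, 12.0), top)
        rep = coil_engagement(traj, matrix=matrix, params=ff, window=slice(0, 1))
        assert np.all(rep.engaged_fraction < 1.0)
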