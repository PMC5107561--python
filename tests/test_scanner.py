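"""Window arithmetic, peak finding, the allele-frequency track, and
monomorphic-region detection against a brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boltscan import cli_io, poolcalls, scanner, simcross
from boltscan.poolcalls import CallConfig, PoolCall, PooledSite, PoolState, SiteCalls
from boltscan.scanner import (
    MonomorphicRegion,
    ScanConfig,
    allele_frequency_track,
    find_monomorphic_regions,
    find_peak,
    make_windows,
    score_windows,
)
from conftest import small_sim_config


class TestMakeWindows:
    def test_default_windows_on_500kb(self):
        windows = make_windows(500_000)
        assert windows == [
            (1, 200_000),
            (100_001, 300_000),
            (200_001, 400_000),
            (300_001, 500_000),
            (400_001, 500_000),
        ]

    def test_windows_shorter_than_window_size(self):
        assert make_windows(150_000) == [(1, 150_000), (100_001, 150_000)]

    def test_single_bp_scaffold(self):
        assert make_windows(1) == [(1, 1)]

    @given(length=st.integers(1, 10**6), window=st.integers(1, 300_000), data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_window_rule_properties(self, length, window, data):
        step = data.draw(st.integers(1, window))
        cfg = ScanConfig(window_bp=window, step_bp=step, min_region_sites=1)
        windows = make_windows(length, cfg)
        starts = [w[0] for w in windows]
        assert starts == list(range(1, length + 1, step))
        assert all(end == min(start + window - 1, length) for start, end in windows)

    def test_interior_position_in_window_over_step_windows(self):
        """With 200 kb windows and 100 kb steps every interior position is
        covered by exactly 2 windows."""
        windows = make_windows(1_000_000)
        for pos in (200_000, 333_333, 500_001):
            assert sum(1 for s, e in windows if s <= pos <= e) == 2


def _call(state: PoolState, freq: float | None = None, depth: int = 60) -> PoolCall:
    if freq is None:
        freq = {PoolState.HOM_REF: 0.0, PoolState.HOM_ALT: 1.0, PoolState.HET: 0.5}.get(state, 0.0)
    return PoolCall(state, freq, depth)


def make_site_calls(
    positions, br_states, b_states=None, scaffold="s", br_freqs=None
) -> list[SiteCalls]:
    b_states = b_states or [PoolState.HET] * len(positions)
    out = []
    for i, pos in enumerate(positions):
        freq = br_freqs[i] if br_freqs else None
        br = _call(br_states[i], freq)
        b = _call(b_states[i])
        cand = b.state is PoolState.HET and br.state in poolcalls.HOMOZYGOUS
        site = PooledSite(scaffold, pos, "A", "C", 30, 30, 30, 30)
        out.append(SiteCalls(site, br, b, cand))
    return out


class TestScoreWindows:
    def test_counts_in_single_window(self):
        positions = list(range(1000, 11_000, 1000))
        br = [PoolState.HOM_REF] * 7 + [PoolState.HET] * 3
        calls = make_site_calls(positions, br)
        scores = score_windows(calls, {"s": 11_000}, ScanConfig(window_bp=20_000, step_bp=20_000))
        assert scores[0].n_monomorphic_br == 7
        assert scores[0].n_polymorphic_b == 10

    def test_boundary_site_counted_in_two_windows(self):
        calls = make_site_calls([200_000], [PoolState.HOM_ALT])
        scores = score_windows(calls, {"s": 400_000})
        hits = [s for s in scores if s.n_polymorphic_b == 1]
        assert [(s.start, s.end) for s in hits] == [(1, 200_000), (100_001, 300_000)]

    def test_no_sites_gives_zero_windows(self):
        scores = score_windows([], {"s": 300_000})
        assert all(s.n_monomorphic_br == 0 and s.n_polymorphic_b == 0 for s in scores)

    def test_non_b_het_sites_excluded_from_denominator(self):
        calls = make_site_calls([100, 200], [PoolState.HOM_REF] * 2,
                                [PoolState.HET, PoolState.HOM_ALT])
        scores = score_windows(calls, {"s": 300})
        assert scores[0].n_polymorphic_b == 1


class TestFindPeak:
    def test_single_nonzero_window(self):
        scores = score_windows(
            make_site_calls([50], [PoolState.HOM_REF]), {"s": 100_000}
        )
        peak = find_peak(scores)
        assert peak.best.start == 1 and peak.best.n_monomorphic_br == 1

    def test_tie_broken_lexicographically_and_all_reported(self):
        a = scanner.WindowScore("s2", 1, 10, 5, 8)
        b = scanner.WindowScore("s1", 11, 20, 5, 9)
        c = scanner.WindowScore("s1", 1, 10, 3, 9)
        peak = find_peak([a, b, c])
        assert peak.best is b
        assert peak.tied == (b, a)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            find_peak([])

    def test_simulated_peak_on_causal_scaffold(self, desk_dataset, desk_calls):
        scores = score_windows(desk_calls, desk_dataset.config.scaffold_lengths)
        assert find_peak(scores).best.scaffold == desk_dataset.config.causal[0]


class TestAlleleFrequencyTrack:
    def test_track_values(self):
        calls = make_site_calls(
            [10, 20, 30],
            [PoolState.HOM_REF, PoolState.HOM_ALT, PoolState.HET],
            br_freqs=[0.0, 1.0, 0.5],
        )
        track = allele_frequency_track(calls)
        assert track == [("s", 10, 0.0), ("s", 20, 1.0), ("s", 30, 0.5)]

    def test_track_mean_near_half_on_unlinked_scaffold(self, desk_dataset, desk_calls):
        unlinked = [
            t for t in allele_frequency_track(desk_calls)
            if t[0] != desk_dataset.config.causal[0]
        ]
        assert abs(np.mean([t[2] for t in unlinked]) - 0.5) < 0.05


def oracle_regions(calls, min_sites: int, mode: str) -> list[MonomorphicRegion]:
    """Exhaustive search over all (start, end) site pairs for maximal
    all-monomorphic runs of b-HET sites."""
    by_scaffold: dict[str, list] = {}
    for c in calls:
        if c.b.state is PoolState.HET and c.br.state is not PoolState.NO_CALL:
            by_scaffold.setdefault(c.site.scaffold, []).append(c)
    out = []
    for sc, here in by_scaffold.items():
        here.sort(key=lambda c: c.site.pos)
        mono = [
            c.br.alt_frequency in (0.0, 1.0) if mode == "exact" else c.candidate
            for c in here
        ]
        n = len(here)
        for i, j in itertools.combinations(range(n + 1), 2):
            j -= 1
            if not all(mono[i : j + 1]):
                continue
            if i > 0 and mono[i - 1]:
                continue
            if j < n - 1 and mono[j + 1]:
                continue
            if j - i + 1 < min_sites:
                continue
            out.append(
                MonomorphicRegion(
                    sc,
                    here[i].site.pos,
                    here[j].site.pos,
                    j - i + 1,
                    here[i - 1].site.pos if i > 0 else None,
                    here[j + 1].site.pos if j + 1 < n else None,
                )
            )
    out.sort(key=lambda r: (-r.length_bp, r.scaffold, r.start))
    return out


class TestMonomorphicRegions:
    def test_alternating_calls_give_no_region(self):
        states = [PoolState.HOM_REF if i % 2 == 0 else PoolState.HET for i in range(30)]
        calls = make_site_calls(list(range(10, 310, 10)), states)
        assert find_monomorphic_regions(calls) == []

    def test_single_run_inside_polymorphic_flanks(self):
        positions = list(range(100, 100 + 27 * 10, 10))
        states = [PoolState.HET] + [PoolState.HOM_ALT] * 25 + [PoolState.HET]
        calls = make_site_calls(positions, states)
        regions = find_monomorphic_regions(calls)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (positions[1], positions[25])
        assert r.length_bp == positions[25] - positions[1] + 1
        assert (r.flank_left, r.flank_right) == (positions[0], positions[26])

    def test_printed_boundary_arithmetic(self):
        """1-based inclusive interval 4,991,549..5,094,401 spans 102,853 bp."""
        r = MonomorphicRegion("Bvchr9.sca026", 4_991_549, 5_094_401, 100, None, None)
        assert r.length_bp == 102_853

    def test_exact_mode_requires_frequency_exactly_0_or_1(self):
        positions = list(range(10, 260, 10))
        states = [PoolState.HOM_ALT] * 25
        freqs = [1.0] * 25
        freqs[12] = 0.97  # HOM_ALT by call, but not exactly fixed
        calls = make_site_calls(positions, states, br_freqs=freqs)
        cfg = ScanConfig(min_region_sites=5, region_frequency_mode="exact")
        regions = find_monomorphic_regions(calls, cfg)
        assert len(regions) == 2
        by_call = find_monomorphic_regions(calls, ScanConfig(min_region_sites=5))
        assert len(by_call) == 1

    @pytest.mark.parametrize("mode", ["by_call", "exact"])
    def test_matches_brute_force_oracle_on_random_instances(self, mode):
        rng = np.random.default_rng(42)
        for trial in range(200):
            n = int(rng.integers(1, 60))
            positions = np.sort(rng.choice(np.arange(1, 5000), size=n, replace=False))
            states, freqs, b_states = [], [], []
            for _ in range(n):
                u = rng.random()
                if u < 0.4:
                    states.append(PoolState.HOM_ALT)
                    freqs.append(1.0 if rng.random() < 0.7 else 0.93)
                elif u < 0.7:
                    states.append(PoolState.HOM_REF)
                    freqs.append(0.0 if rng.random() < 0.7 else 0.05)
                else:
                    states.append(PoolState.HET)
                    freqs.append(0.5)
                b_states.append(PoolState.HET if rng.random() < 0.9 else PoolState.HOM_ALT)
            calls = make_site_calls(positions.tolist(), states, b_states, br_freqs=freqs)
            min_sites = int(rng.integers(1, 6))
            cfg = ScanConfig(min_region_sites=min_sites, region_frequency_mode=mode)
            assert find_monomorphic_regions(calls, cfg) == oracle_regions(calls, min_sites, mode)

    def test_regions_sorted_by_length_descending(self, desk_calls):
        regions = find_monomorphic_regions(desk_calls)
        lengths = [r.length_bp for r in regions]
        assert lengths == sorted(lengths, reverse=True)
        for r in regions:
            assert r.n_sites >= ScanConfig().min_region_sites


class TestRecovery:
    def test_top_region_contains_causal_site(self, desk_dataset, desk_calls):
        regions = find_monomorphic_regions(desk_calls)
        top = regions[0]
        sc, pos = desk_dataset.config.causal
        assert top.scaffold == sc
        assert top.start <= pos <= top.end
        assert all(r.scaffold == sc for r in regions)

    def test_more_recombinants_do_not_lengthen_region(self):
        """Median top-region length does not increase when the resistant
        pool holds more plants (more recombination breakpoints)."""

        def median_top_length(penetrance: float) -> float:
            lengths = []
            for seed in range(6):
                cfg = small_sim_config(
                    seed=100 + seed, penetrance_resistant=penetrance, n_f2=400, n_b_pool=150
                )
                ds = simcross.simulate_dataset(cfg)
                calls = poolcalls.filter_candidates(cli_io.to_pooled_sites(ds))
                regions = scanner.find_monomorphic_regions(
                    calls, ScanConfig(min_region_sites=5)
                )
                top = [r for r in regions if r.scaffold == cfg.causal[0]]
                lengths.append(top[0].length_bp if top else 0)
            return float(np.median(lengths))

        assert median_top_length(0.9) <= median_top_length(0.15)
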