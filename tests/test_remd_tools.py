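"""Restraint networks, temperature ladders, Metropolis bookkeeping, demux."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clampkit import (
    ExchangeLog,
    RestraintSpec,
    build_restraint_network,
    demux_walkers,
    make_temperature_ladder,
    metropolis_accept_probability,
    restraint_energy,
    round_trip_count,
    select_ca,
)
from clampkit.remd_tools import (
    KB_KCAL_MOL_K,
    read_exchange_log,
    write_exchange_log,
    write_restraints,
)
from tests_helpers import structure_from_ca_coords


def replica_centric_replay(log):
    """Independent oracle: track each replica's occupant walker over time."""
    walker_at = {r: r for r in range(log.n_replicas)}  # replica -> walker
    occupants = np.empty((log.n_steps, log.n_replicas), dtype=int)
    attempts = log.attempts[np.argsort(log.attempts[:, 0], kind="stable")]
    ptr = 0
    for t in range(log.n_steps):
        while ptr < len(attempts) and attempts[ptr][0] == t:
            _, a, b, acc = attempts[ptr]
            if acc:
                walker_at[a], walker_at[b] = walker_at[b], walker_at[a]
            ptr += 1
        occupants[t] = [walker_at[r] for r in range(log.n_replicas)]
    return occupants


class TestRestraintNetwork:
    def test_collinear_triplet_brute_force(self):
        struct = structure_from_ca_coords(
            [[0, 0, 0], [4, 0, 0], [8, 0, 0]], residue_ids=[1, 3, 5]
        )
        sel = select_ca(struct, [1, 2, 3])
        assert len(build_restraint_network(struct, sel, cutoff=8.0)) == 3
        assert len(build_restraint_network(struct, sel, cutoff=5.0)) == 2

    def test_sequence_neighbours_excluded(self):
        struct = structure_from_ca_coords([[0, 0, 0], [3.8, 0, 0]])
        sel = select_ca(struct, [1, 2])
        assert build_restraint_network(struct, sel, cutoff=8.0) == []

    def test_cross_chain_pairs_never_neighbours(self):
        import biotite.structure as bst
        from clampkit.structure_io import Structure, _build_residue_tables

        atoms = bst.AtomArray(2)
        atoms.coord = np.array([[0, 0, 0], [4, 0, 0]], dtype=np.float32)
        atoms.atom_name = np.full(2, "CA")
        atoms.res_name = np.full(2, "GLY")
        atoms.element = np.full(2, "C")
        atoms.chain_id = np.array(["A", "B"])
        atoms.res_id = np.array([1, 1])
        atoms.hetero = np.zeros(2, dtype=bool)
        struct = Structure(atoms, *_build_residue_tables(atoms))
        sel = select_ca(struct, [1, 2])
        assert len(build_restraint_network(struct, sel, cutoff=8.0)) == 1

    def test_knots_centred_on_reference_distance(self):
        struct = structure_from_ca_coords(
            [[0, 0, 0], [6, 0, 0]], residue_ids=[1, 10]
        )
        sel = select_ca(struct, [1, 2])
        (spec,) = build_restraint_network(struct, sel, flat_width=0.5)
        assert (spec.r1, spec.r2, spec.r3, spec.r4) == (5.0, 5.5, 6.5, 7.0)

    def test_brute_force_on_toy_clamp(self, toy_clamp):
        n = toy_clamp.n_atoms
        sel = select_ca(toy_clamp, list(range(1, n + 1)))
        network = build_restraint_network(toy_clamp, sel, cutoff=8.0)
        coords = toy_clamp.coords
        author = toy_clamp.atoms.res_id
        chain = toy_clamp.atoms.chain_id
        brute = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if (chain[i] != chain[j] or abs(int(author[i]) - int(author[j])) >= 2)
            and np.linalg.norm(coords[i] - coords[j]) <= 8.0
        )
        assert len(network) == brute
        assert brute > 0


class TestRestraintEnergy:
    SPEC = RestraintSpec(0, 1, 4.0, 5.0, 7.0, 8.0, 1.0)

    @pytest.mark.parametrize("r", [5.0, 6.0, 7.0])
    def test_plateau_zero(self, r):
        assert restraint_energy(r, self.SPEC) == 0.0

    def test_quadratic_shoulder(self):
        assert restraint_energy(8.0, self.SPEC) == pytest.approx(1.0)
        assert restraint_energy(4.5, self.SPEC) == pytest.approx(0.25)

    def test_linear_tail_slope_matched(self):
        k, r3, r4 = self.SPEC.k, self.SPEC.r3, self.SPEC.r4
        for x in (0.5, 2.0, 10.0):
            expected = k * (r4 - r3) ** 2 + 2 * k * (r4 - r3) * x
            assert restraint_energy(r4 + x, self.SPEC) == pytest.approx(expected)

    def test_c1_continuity_at_all_knots(self):
        h = 1e-6
        for knot in (self.SPEC.r1, self.SPEC.r2, self.SPEC.r3, self.SPEC.r4):
            e_lo = restraint_energy(knot - h, self.SPEC)
            e_hi = restraint_energy(knot + h, self.SPEC)
            assert abs(e_hi - e_lo) < 1e-5  # value continuous
            d_lo = (restraint_energy(knot - h, self.SPEC)
                    - restraint_energy(knot - 3 * h, self.SPEC)) / (2 * h)
            d_hi = (restraint_energy(knot + 3 * h, self.SPEC)
                    - restraint_energy(knot + h, self.SPEC)) / (2 * h)
            assert abs(d_hi - d_lo) < 1e-4  # derivative continuous

    def test_knot_ordering_enforced(self):
        with pytest.raises(ValueError, match="knots"):
            RestraintSpec(0, 1, 5.0, 4.0, 7.0, 8.0, 1.0)


class TestTemperatureLadder:
    def test_two_replicas_are_endpoints(self):
        ladder = make_temperature_ladder(2, 300, 500)
        assert list(ladder.temperatures) == [300, 500]

    def test_three_replica_geometric_midpoint(self):
        # closed form: 300 * sqrt(500/300)
        ladder = make_temperature_ladder(3, 300, 500)
        assert ladder.temperatures[1] == pytest.approx(300 * np.sqrt(5 / 3))
        assert ladder.temperatures[1] == pytest.approx(387.2983, abs=1e-4)

    def test_fifty_replica_production_ladder(self):
        ladder = make_temperature_ladder(50, 300, 500)
        t = ladder.temperatures
        assert len(t) == 50
        assert t[0] == 300 and t[-1] == 500
        assert np.all(np.diff(t) > 0)
        ratios = t[1:] / t[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_linear_schedule(self):
        ladder = make_temperature_ladder(5, 300, 500, schedule="linear")
        assert np.allclose(ladder.temperatures, [300, 350, 400, 450, 500])

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            make_temperature_ladder(5, 500, 300)


class TestMetropolis:
    def test_equal_energy_or_temperature_always_accepts(self):
        assert metropolis_accept_probability(3.0, 3.0, 300, 400) == 1.0
        assert metropolis_accept_probability(1.0, 9.0, 350, 350) == 1.0

    def test_unit_beta_delta_e(self):
        # choose temperatures with beta_i - beta_j = 1 (mol/kcal), dE = -1
        beta_i = 2.0
        beta_j = 1.0
        t_i = 1.0 / (KB_KCAL_MOL_K * beta_i)
        t_j = 1.0 / (KB_KCAL_MOL_K * beta_j)
        p = metropolis_accept_probability(0.0, 1.0, t_i, t_j)
        assert p == pytest.approx(np.exp(-1), rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_detailed_balance_ratio(self, seed):
        rng = np.random.default_rng(seed)
        e_i, e_j = rng.uniform(-50, 50, 2)
        t_i, t_j = rng.uniform(250, 600, 2)
        p_fwd = metropolis_accept_probability(e_i, e_j, t_i, t_j)
        p_rev = metropolis_accept_probability(e_j, e_i, t_i, t_j)
        assert 0 < p_fwd <= 1
        db = (1 / (KB_KCAL_MOL_K * t_i) - 1 / (KB_KCAL_MOL_K * t_j)) * (e_i - e_j)
        assert np.log(p_fwd) - np.log(p_rev) == pytest.approx(db, abs=1e-9)

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept_probability(0, 0, -300, 400)


class TestDemux:
    def test_no_swaps_constant_paths(self):
        log = ExchangeLog(4, np.empty((0, 4), dtype=int))
        path = demux_walkers(log)
        assert np.array_equal(path.replica_of_walker[0], [0, 1, 2, 3])

    def test_single_swap_exchanges_from_that_step(self):
        attempts = np.array([[5, 0, 1, 1], [7, 2, 3, 0]])
        log = ExchangeLog(4, attempts)
        path = demux_walkers(log)
        assert np.array_equal(path.replica_of_walker[4], [0, 1, 2, 3])
        assert np.array_equal(path.replica_of_walker[5], [1, 0, 2, 3])
        assert np.array_equal(path.replica_of_walker[7], [1, 0, 2, 3])

    def test_non_adjacent_swap_rejected(self):
        with pytest.raises(ValueError, match="not adjacent"):
            ExchangeLog(4, np.array([[0, 0, 2, 1]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_against_replica_centric_oracle(self, seed):
        from clampkit.synthetic_clamp import generate_exchange_log

        log, true_path = generate_exchange_log(
            8, 1000, accept_rate=0.4, seed=seed
        )
        path = demux_walkers(log)
        assert np.array_equal(path.replica_of_walker, true_path.replica_of_walker)
        occupants = replica_centric_replay(log)
        # inverse mapping: walker w sits at replica r <=> replica r holds w
        for t in range(path.n_steps):
            inv = np.empty(8, dtype=int)
            inv[occupants[t]] = np.arange(8)
            # inv[w] = replica of walker w
            assert np.array_equal(path.replica_of_walker[t], inv[np.arange(8)])
            assert np.array_equal(np.sort(path.replica_of_walker[t]), np.arange(8))

    def test_log_file_round_trip(self, tmp_path):
        from clampkit.synthetic_clamp import generate_exchange_log

        log, _ = generate_exchange_log(4, 50, accept_rate=0.5, seed=2)
        path = tmp_path / "log.tsv"
        write_exchange_log(log, path)
        back = read_exchange_log(path)
        assert back.n_replicas == 4
        assert np.array_equal(back.attempts, log.attempts)

    def test_malformed_log_line_cited(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# n_replicas=4\n0\t0\t1\t1\n0\t1\n")
        with pytest.raises(ValueError, match=":3"):
            read_exchange_log(path)


class TestRoundTrips:
    def _path_from_series(self, series, n):
        from clampkit.remd_tools import WalkerPath

        # rows where walker 0 occupies replica `r`; permutations stay valid
        out = []
        for r in series:
            row = np.arange(n)
            row[0], row[r] = row[r], row[0]
            out.append(row)
        return WalkerPath(np.array(out))

    def test_constant_path_zero_trips(self):
        path = self._path_from_series([0] * 10, 4)
        assert round_trip_count(path, 0) == 0

    def test_single_traversal(self):
        path = self._path_from_series([0, 1, 2, 3, 2, 1, 0], 4)
        assert round_trip_count(path, 0) == 1

    def test_partial_traversals_not_counted(self):
        path = self._path_from_series([0, 1, 2, 1, 0, 1, 0], 4)
        assert round_trip_count(path, 0) == 0

    def test_two_traversals(self):
        series = [0, 1, 2, 3, 2, 1, 0, 1, 2, 3, 3, 2, 1, 0]
        path = self._path_from_series(series, 4)
        assert round_trip_count(path, 0) == 2


def test_restraint_table_written(tmp_path, toy_clamp):
    sel = select_ca(toy_clamp, list(range(1, toy_clamp.n_atoms + 1)))
    network = build_restraint_network(toy_clamp, sel, cutoff=8.0)
    out = tmp_path / "restraints.tsv"
    write_restraints(network, out)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == len(network)
    first = lines[0].split("\t")
    assert len(first) == 7
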