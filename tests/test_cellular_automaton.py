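"""Cellular-automaton engine: oracle equivalence and fibre behaviour."""

import numpy as np
import pytest

from nodalsim import (CAModel, CAParams, CARangeError, CAState, ca_cv_1d,
                      ca_refractory_period, ca_step, ca_tune_cv)
from nodalsim.cellular_automaton import EXCITED, REFRACTORY, REST
from nodalsim.geometry import Geometry, LabelVolume


def brute_force_step(st: CAState, labels, params):
    """Independent reference automaton: plain Python loops, no shared code
    with the implementation beyond the parameter objects."""
    nx, ny, nz = st.state.shape
    new = st.copy()
    new.step = st.step + 1
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                code = int(labels[i, j, k])
                if code == 0:
                    continue
                p = params[code]
                s = st.state[i, j, k]
                if s == REST:
                    n_exc = 0
                    r = p.reach
                    for di in range(-r, r + 1):
                        for dj in range(-r, r + 1):
                            for dk in range(-r, r + 1):
                                if di == dj == dk == 0:
                                    continue
                                if p.neighborhood == "face":
                                    if r == 1:
                                        if abs(di) + abs(dj) + abs(dk) > 1:
                                            continue
                                    elif di * di + dj * dj + dk * dk > r * r:
                                        continue
                                ii, jj, kk = i + di, j + dj, k + dk
                                if not (0 <= ii < nx and 0 <= jj < ny
                                        and 0 <= kk < nz):
                                    continue
                                if labels[ii, jj, kk] != 0 and \
                                        st.state[ii, jj, kk] == EXCITED:
                                    n_exc += 1
                    e = st.counter[i, j, k] + p.gain * n_exc
                    if e >= p.theta:
                        new.state[i, j, k] = EXCITED
                        new.phase[i, j, k] = 0
                        new.counter[i, j, k] = 0.0
                    else:
                        new.counter[i, j, k] = e
                elif s == EXCITED:
                    if st.phase[i, j, k] + 1 >= p.excited:
                        if p.refractory == 0:
                            new.state[i, j, k] = REST
                            new.phase[i, j, k] = 0
                            new.counter[i, j, k] = 0.0
                        else:
                            new.state[i, j, k] = REFRACTORY
                            new.phase[i, j, k] = 0
                    else:
                        new.phase[i, j, k] = st.phase[i, j, k] + 1
                else:
                    if st.phase[i, j, k] + 1 >= p.refractory:
                        new.state[i, j, k] = REST
                        new.phase[i, j, k] = 0
                        new.counter[i, j, k] = 0.0
                    else:
                        new.phase[i, j, k] = st.phase[i, j, k] + 1
    return new


def _fibre_geom(n, code=1):
    labels = np.full((n, 1, 1), code, dtype=np.int8)
    return Geometry(LabelVolume(labels))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_state_identical_on_random_lattices(self, seed):
        """Implementation matches the brute-force reference state-by-state
        on random 20x20 lattices over 200 steps."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=(20, 20, 1)).astype(np.int8)
        params = {
            1: CAParams(theta=2.0, gain=1.0, excited=4, refractory=7,
                        reach=1),
            2: CAParams(theta=3.0, gain=1.0, excited=3, refractory=5,
                        reach=2),
        }
        st_a = CAState.resting(labels.shape)
        seed_mask = rng.random(labels.shape) < 0.05
        st_a.state[seed_mask & (labels != 0)] = EXCITED
        st_b = st_a.copy()
        for step in range(200):
            st_a = ca_step(st_a, labels, params)
            if step % 20 == 0 or step == 199:
                st_b_ref = st_b
                for _ in range(step + 1 - st_b.step):
                    st_b_ref = brute_force_step(st_b_ref, labels, params)
                st_b = st_b_ref
                assert np.array_equal(st_a.state, st_b.state), step
                assert np.array_equal(st_a.phase, st_b.phase)
                assert np.allclose(st_a.counter, st_b.counter)


class TestBasics:
    def test_all_resting_lattice_unchanged(self):
        labels = np.ones((5, 5, 1), dtype=np.int8)
        p = {1: CAParams(theta=1.0)}
        st = CAState.resting(labels.shape)
        st2 = ca_step(st, labels, p)
        assert np.array_equal(st2.state, st.state)
        assert np.all(st2.counter == 0)

    def test_wavefront_constant_rate(self):
        """After a short transient the 1-D front advances at a constant
        nodes-per-step rate."""
        p = CAParams(theta=2.0, excited=8, refractory=20, reach=1)
        labels = np.full((80, 1, 1), 1, dtype=np.int8)
        st = CAState.resting(labels.shape)
        st.state[0] = EXCITED
        first = np.full(80, -1)
        for step in range(1, 400):
            st = ca_step(st, labels, {1: p})
            newly = (st.state[:, 0, 0] == EXCITED) & (first < 0)
            first[newly] = step
            if first[-1] > 0:
                break
        d = np.diff(first[10:70])
        assert len(set(d.tolist())) == 1  # strictly constant advance

    def test_refractory_node_does_not_refire(self):
        labels = np.ones((1, 1, 1), dtype=np.int8)
        p = {1: CAParams(theta=1.0, excited=2, refractory=5)}
        st = CAState.resting(labels.shape)
        st.state[0] = EXCITED
        st = ca_step(st, labels, p)
        st = ca_step(st, labels, p)   # now refractory
        assert st.state[0, 0, 0] == REFRACTORY
        model_like = st.copy()
        model_like.counter[0] = 100.0  # huge drive must not re-fire it
        nxt = ca_step(model_like, labels, p)
        assert nxt.state[0, 0, 0] == REFRACTORY


class TestRefractoryPeriod:
    def test_degenerate_no_refractory_phase(self):
        """With R = 0 an isolated node can be re-fired as soon as its
        excited period ends: the effective refractory period equals E."""
        p = CAParams(theta=1.0, excited=30, refractory=0, reach=1)
        labels = np.ones((1, 1, 1), dtype=np.int8)
        st = CAState.resting(labels.shape)
        st.state[0] = EXCITED
        for _ in range(p.excited - 1):
            st = ca_step(st, labels, {1: p})
        assert st.state[0, 0, 0] != REST      # still within E
        st = ca_step(st, labels, {1: p})
        assert st.state[0, 0, 0] == REST      # re-excitable at exactly E

    def test_table_values(self, cfg):
        """Default per-tissue automaton constants reproduce the published
        refractory periods at 1 ms steps."""
        targets = {"atrial": 81.0, "ine": 94.0, "tz": 134.0, "pb": 154.0}
        for name, want in targets.items():
            e = cfg.ca["tissues"][name]
            p = CAParams(theta=e["theta"], gain=e.get("gain", 1.0),
                         excited=e["excited"], refractory=e["refractory"],
                         reach=e.get("reach", 1))
            assert ca_refractory_period(p) == pytest.approx(want, abs=1.0)


class TestTuning:
    @pytest.mark.parametrize("target", [0.104, 0.154])
    def test_tuned_cv_within_tolerance(self, target):
        p = ca_tune_cv(target)
        cv = ca_cv_1d(p)
        assert abs(cv - target) / target < 0.10

    def test_one_node_per_step_reachable(self):
        v_node = 0.06 / 1.0  # dx/dt
        p = ca_tune_cv(v_node)
        assert p.theta <= p.reach  # reachable within one step of input

    def test_unreachable_target_raises_with_bounds(self):
        with pytest.raises(CARangeError, match="achievable"):
            ca_tune_cv(5.0)  # far beyond reach * dx / dt


class TestBlockBoundary:
    def test_premature_wave_blocked_exactly_below_rp(self, cfg):
        """On a uniform fibre, an S2 delivered just below the measured
        refractory period fails to reach the distal probe and one just
        above it succeeds (the block boundary is sharp)."""
        e = cfg.ca["tissues"]["atrial"]
        p = CAParams(theta=e["theta"], gain=e.get("gain", 1.0),
                     excited=e["excited"], refractory=e["refractory"],
                     reach=e.get("reach", 1))
        rp = ca_refractory_period(p)

        def far_acts(ci_steps):
            labels = np.full((120, 1, 1), 1, dtype=np.int8)
            geom = Geometry(LabelVolume(labels))
            model = CAModel(geom, {1: p}, 1.0)
            m = np.zeros(geom.shape, dtype=bool)
            m[:2] = True
            trace = model.run(int(ci_steps) + 400,
                              stimuli=[(0, m), (int(ci_steps), m)],
                              probes={"far": (117, 0, 0)})["far"]
            from nodalsim.measurements import activation_times
            return len(activation_times(trace))

        assert far_acts(rp - 2) == 1   # S2 blocked
        assert far_acts(rp + 1) == 2   # S2 conducted
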