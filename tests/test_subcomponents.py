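import numpy as np
import pytest

from mpfm.core_io import BOLDDataset, BOLDRun, ModeDecomposition
from mpfm.subcomponents import (
    SubcomponentSet,
    extract_subcomponents,
    mode_pca,
    spatially_exclusive,
    temporally_exclusive,
    weight_data,
    winner_takes_all,
)


class TestWeightData:
    def test_identity_zero_and_random(self, rng):
        run = BOLDRun(data=rng.normal(size=(30, 20)), tr=1.0,
                      subject_id="s", run_id="r")
        assert np.array_equal(weight_data(run, np.ones(30)).data, run.data)
        zeroed = weight_data(run, np.zeros(30)).data
        assert not np.any(zeroed[1:])  # all-zero rows (row 0 keeps eps)
        w = rng.normal(size=30)
        assert np.allclose(weight_data(run, w).data, run.data * w[:, None])

    def test_wrong_length_rejected(self, rng):
        run = BOLDRun(data=rng.normal(size=(30, 20)), tr=1.0,
                      subject_id="s", run_id="r")
        with pytest.raises(ValueError):
            weight_data(run, np.ones(29))


class TestModePCA:
    def test_single_timecourse_dominates(self, rng):
        spatial = rng.normal(size=100)
        weighted = {f"s{i}": np.outer(spatial, rng.normal(size=50))
                    for i in range(4)}
        _, ev = mode_pca(weighted, k_subject=5, k_group=5)
        assert ev[0] > 0.99
        assert np.all(np.diff(ev) <= 1e-12)

    def test_two_equal_power_sources_split_evenly(self, rng):
        m1 = np.zeros(100)
        m1[:50] = 1.0
        m2 = np.zeros(100)
        m2[50:] = 1.0
        weighted = {}
        for i in range(4):
            t1 = rng.normal(size=60)
            t2 = rng.normal(size=60)
            weighted[f"s{i}"] = np.outer(m1, t1) + np.outer(m2, t2)
        _, ev = mode_pca(weighted, k_subject=4, k_group=4)
        assert ev[0] == pytest.approx(0.5, abs=0.1)
        assert ev[1] == pytest.approx(0.5, abs=0.1)
        assert ev[0] + ev[1] > 0.98

    def test_zero_subject_skipped_with_warning(self, rng):
        weighted = {"good": rng.normal(size=(40, 30)),
                    "dead": np.zeros((40, 30))}
        with pytest.warns(UserWarning, match="dead"):
            pcs, ev = mode_pca(weighted, k_subject=3, k_group=3)
        assert pcs.shape == (40, 3)


def _single_mode_decomp(rng, V=200, S=4, T=120, n_modes=2):
    """Dataset + lowD decomposition where mode 0 carries two embedded
    sub-timecourses in disjoint halves of its support."""
    maps = np.zeros((V, n_modes))
    maps[:120, 0] = 1.0
    maps[150:190, 1] = 1.0
    dec = ModeDecomposition(method="truth", group_maps=maps)
    runs = []
    sub_tcs = {}
    for s in range(S):
        sid = f"s{s}"
        t_a = rng.normal(size=T)
        t_b = rng.normal(size=T)
        t_other = rng.normal(size=T)
        data = np.zeros((V, T))
        data[:60] = np.outer(maps[:60, 0], t_a)[:60]
        data[60:120] = np.outer(maps[60:120, 0], t_b)
        data += np.outer(maps[:, 1], t_other)
        data += 0.05 * rng.normal(size=(V, T))
        runs.append(BOLDRun(data=data, tr=0.72, subject_id=sid, run_id="r"))
        dec.subject_maps[sid] = maps.copy()
        dec.timecourses[(sid, "r")] = np.stack([0.5 * (t_a + t_b), t_other])
        sub_tcs[sid] = np.stack([t_a, t_b])
    return BOLDDataset(runs=runs), dec, sub_tcs


class TestExtraction:
    def test_planted_subcomponents_recovered(self, rng):
        dataset, dec, sub_tcs = _single_mode_decomp(rng)
        subset = extract_subcomponents(dataset, dec, mode=0, k=2,
                                       rng_seed=3)
        rs = []
        for sid, truth_tc in sub_tcs.items():
            got = subset.subject_timecourses[sid]
            corr = np.abs(np.corrcoef(np.vstack([got, truth_tc]))[:2, 2:])
            # best assignment of the 2 extracted to the 2 planted
            rs.append(max(corr[0, 0] + corr[1, 1],
                          corr[0, 1] + corr[1, 0]) / 2)
        assert np.mean(rs) > 0.8

    def test_k1_collapses_to_parent_timecourse(self, rng):
        V, S, T = 150, 3, 100
        maps = np.zeros((V, 2))
        maps[:80, 0] = 1.0
        maps[100:140, 1] = 1.0
        dec = ModeDecomposition(method="truth", group_maps=maps)
        runs = []
        for s in range(S):
            sid = f"s{s}"
            t0 = rng.normal(size=T)
            t1 = rng.normal(size=T)
            data = np.outer(maps[:, 0], t0) + np.outer(maps[:, 1], t1)
            data += 0.05 * rng.normal(size=(V, T))
            runs.append(BOLDRun(data=data, tr=1.0, subject_id=sid,
                                run_id="r"))
            dec.subject_maps[sid] = maps.copy()
            dec.timecourses[(sid, "r")] = np.stack([t0, t1])
        dataset = BOLDDataset(runs=runs)
        subset = extract_subcomponents(dataset, dec, mode=0, k=1, rng_seed=0)
        for sid in subset.subject_timecourses:
            r = np.corrcoef(subset.subject_timecourses[sid][0],
                            dec.timecourses[(sid, "r")][0])[0, 1]
            assert abs(r) > 0.9

    def test_deterministic(self, rng):
        dataset, dec, _ = _single_mode_decomp(rng)
        s1 = extract_subcomponents(dataset, dec, 0, k=2, rng_seed=5)
        s2 = extract_subcomponents(dataset, dec, 0, k=2, rng_seed=5)
        for sid in s1.subject_timecourses:
            assert np.array_equal(s1.subject_timecourses[sid],
                                  s2.subject_timecourses[sid])

    def test_timecourses_are_demeaned(self, rng):
        dataset, dec, _ = _single_mode_decomp(rng)
        subset = extract_subcomponents(dataset, dec, 0, k=2, rng_seed=5)
        for tc in subset.subject_timecourses.values():
            assert np.allclose(tc.mean(axis=1), 0.0, atol=1e-10)


class TestWinners:
    def _subset_from_tcs(self, tcs: dict, k: int) -> SubcomponentSet:
        subset = SubcomponentSet(parent_mode=0, variant="original", k=k,
                                 group_maps=np.zeros((10, k)))
        for sid, tc in tcs.items():
            subset.subject_timecourses[sid] = tc - tc.mean(axis=1,
                                                           keepdims=True)
        return subset

    def _lowd(self, tcs: dict) -> ModeDecomposition:
        n_modes = next(iter(tcs.values())).shape[0]
        dec = ModeDecomposition(method="low",
                                group_maps=np.zeros((10, n_modes)))
        for sid, tc in tcs.items():
            dec.timecourses[(sid, "r")] = tc
        return dec

    def test_planted_secondary_winner_is_significant(self, rng):
        S, T = 8, 200
        low_tcs, prim, sec, sub = {}, {}, {}, {}
        for s in range(S):
            sid = f"s{s}"
            low_tcs[sid] = rng.normal(size=(3, T))
            prim[sid] = rng.normal(size=(3, T))
            sec[sid] = rng.normal(size=(4, T))
            # subcomponent = copy of secondary mode 2 plus tiny noise
            sub[sid] = (sec[sid][2] + 0.05 * rng.normal(size=T))[None, :]
        table = winner_takes_all(self._subset_from_tcs(sub, 1),
                                 self._lowd(low_tcs), prim, sec)
        assert table.winner_category == ["secondary"]
        assert table.winner_mode == [2]
        assert table.margin_stats[0]["significant"] is True
        assert table.counts["secondary"] == 1

    def test_planted_lowd_winner(self, rng):
        S, T = 6, 150
        low_tcs, prim, sec, sub = {}, {}, {}, {}
        for s in range(S):
            sid = f"s{s}"
            low_tcs[sid] = rng.normal(size=(2, T))
            prim[sid] = rng.normal(size=(2, T))
            sec[sid] = rng.normal(size=(2, T))
            sub[sid] = low_tcs[sid][[1]] + 0.05 * rng.normal(size=(1, T))
        table = winner_takes_all(self._subset_from_tcs(sub, 1),
                                 self._lowd(low_tcs), prim, sec)
        assert table.winner_category == ["lowD"]

    def test_white_noise_margins_rarely_significant(self, rng):
        # many candidates, pure-noise subcomponents: after Bonferroni the
        # winner margin should almost never be called significant
        S, T = 8, 100
        n_sig = 0
        reps = 200
        for rep in range(reps):
            low_tcs, prim, sec, sub = {}, {}, {}, {}
            for s in range(S):
                sid = f"s{s}"
                low_tcs[sid] = rng.normal(size=(10, T))
                prim[sid] = rng.normal(size=(40, T))
                sec[sid] = rng.normal(size=(100, T))
                sub[sid] = rng.normal(size=(1, T))
            table = winner_takes_all(self._subset_from_tcs(sub, 1),
                                     self._lowd(low_tcs), prim, sec,
                                     n_tests=5)
            n_sig += int(table.margin_stats[0]["significant"])
        assert n_sig / reps <= 0.05

    def test_too_few_subjects_reports_missing_significance(self, rng):
        T = 80
        low_tcs = {"a": rng.normal(size=(2, T)), "b": rng.normal(size=(2, T))}
        prim = {k: rng.normal(size=(2, T)) for k in low_tcs}
        sec = {k: rng.normal(size=(2, T)) for k in low_tcs}
        sub = {k: rng.normal(size=(1, T)) for k in low_tcs}
        table = winner_takes_all(self._subset_from_tcs(sub, 1),
                                 self._lowd(low_tcs), prim, sec)
        assert table.margin_stats[0]["significant"] is None
        assert table.winner_category[0] in ("lowD", "primary", "secondary")


class TestExclusiveVariants:
    def _case(self, rng, V=80, M=4, T=60, S=3):
        dec = ModeDecomposition(method="x",
                                group_maps=rng.normal(size=(V, M)))
        runs = []
        for s in range(S):
            sid = f"s{s}"
            dec.subject_maps[sid] = rng.normal(size=(V, M))
            dec.timecourses[(sid, "r")] = rng.normal(size=(M, T))
            runs.append(BOLDRun(data=rng.normal(size=(V, T)), tr=1.0,
                                subject_id=sid, run_id="r"))
        return BOLDDataset(runs=runs), dec

    def test_temporal_residuals_match_projector_oracle(self, rng):
        dataset, dec = self._case(rng)
        out = temporally_exclusive(dataset, dec, mode=1)
        for sid, resid in out.items():
            X = dec.timecourses[(sid, "r")][[0, 2, 3]].T  # (T, 3)
            P = np.eye(X.shape[0]) - X @ np.linalg.inv(X.T @ X) @ X.T
            w = dataset.runs_for(sid)[0].data * \
                dec.subject_maps[sid][:, 1][:, None]
            assert np.allclose(resid, w @ P, atol=1e-8)
            # orthogonality to the removed timecourses
            inner = resid @ X
            norms = np.linalg.norm(resid) * np.linalg.norm(X)
            assert np.max(np.abs(inner)) < 1e-8 * max(norms, 1.0)

    def test_zero_regressors_leave_data_unchanged(self, rng):
        dataset, dec = self._case(rng)
        for key in dec.timecourses:
            dec.timecourses[key][[0, 2, 3]] = 0.0
        out = temporally_exclusive(dataset, dec, mode=1)
        for sid in out:
            w = dataset.runs_for(sid)[0].data * \
                dec.subject_maps[sid][:, 1][:, None]
            assert np.allclose(out[sid], w)

    def test_fully_explained_data_leaves_zero_residual(self, rng):
        dataset, dec = self._case(rng)
        for sid in dec.subject_maps:
            X = dec.timecourses[(sid, "r")][[0, 2, 3]]
            coefs = rng.normal(size=(80, 3))
            run = dataset.runs_for(sid)[0]
            run.data = coefs @ X  # inside the span of the other modes
        out = temporally_exclusive(dataset, dec, mode=1)
        for resid in out.values():
            assert np.max(np.abs(resid)) < 1e-8

    def test_spatial_residual_map_orthogonal_and_projector_match(self, rng):
        dataset, dec = self._case(rng)
        weighted, res_maps = spatially_exclusive(dataset, dec, mode=2)
        for sid in res_maps:
            X = dec.subject_maps[sid][:, [0, 1, 3]]
            assert np.max(np.abs(X.T @ res_maps[sid])) < 1e-8 * \
                np.linalg.norm(X) * np.linalg.norm(res_maps[sid])
            P = np.eye(X.shape[0]) - X @ np.linalg.inv(X.T @ X) @ X.T
            w = dataset.runs_for(sid)[0].data * res_maps[sid][:, None]
            assert np.allclose(weighted[sid], P @ w, atol=1e-8)

    def test_orthogonal_map_unchanged(self, rng):
        dataset, dec = self._case(rng)
        for sid in dec.subject_maps:
            X = dec.subject_maps[sid][:, [0, 1, 3]]
            col = dec.subject_maps[sid][:, 2]
            col -= X @ np.linalg.lstsq(X, col, rcond=None)[0]
            dec.subject_maps[sid][:, 2] = col
        _, res_maps = spatially_exclusive(dataset, dec, mode=2)
        for sid in res_maps:
            assert np.allclose(res_maps[sid], dec.subject_maps[sid][:, 2],
                               atol=1e-8)

    def test_map_inside_span_flagged_empty(self, rng):
        dataset, dec = self._case(rng)
        for sid in dec.subject_maps:
            X = dec.subject_maps[sid][:, [0, 1, 3]]
            dec.subject_maps[sid][:, 2] = X @ rng.normal(size=3)
        with pytest.warns(UserWarning, match="span"):
            weighted, res_maps = spatially_exclusive(dataset, dec, mode=2)
        for m in res_maps.values():
            assert np.linalg.norm(m) < 1e-8
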