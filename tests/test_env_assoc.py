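import dataclasses

import numpy as np
import pandas as pd
import pytest

from cryonet.env_assoc import (
    composition_frame,
    env_correlate,
    log_transform_env,
    module_profiles,
    stars,
)
from cryonet.io_model import RelAbundanceTable, SampleMetadata
from cryonet.network_props import ModulePartition
from conftest import make_network


def _meta(factors):
    n = len(next(iter(factors.values())))
    frame = pd.DataFrame(
        {"horizon": ["topsoil"] * n, "site": [1] * n, **factors},
        index=[f"s{j}" for j in range(n)],
    )
    return SampleMetadata(frame)


def _rel(values, taxa):
    values = np.asarray(values, dtype=float)
    return RelAbundanceTable(
        list(taxa), [f"s{j}" for j in range(values.shape[1])], values
    )


@pytest.fixture
def net_and_partition():
    net = make_network(
        [("a", "b", 0.9), ("c", "d", 0.8), ("c", "e", 0.8), ("d", "e", 0.7)]
    )
    part = ModulePartition({"c": 1, "d": 1, "e": 1, "a": 2, "b": 2}, 0.5, "manual")
    return net, part


class TestModuleProfiles:
    def test_additivity(self, net_and_partition):
        net, part = net_and_partition
        rel = _rel(
            [[0.1, 0.2], [0.2, 0.1], [0.05, 0.05], [0.1, 0.1], [0.15, 0.2]],
            ["a", "b", "c", "d", "e"],
        )
        profiles = module_profiles(net, part, rel, top_k=5)
        by_id = {p.module_id: p for p in profiles}
        assert by_id[2].abundance["s0"] == pytest.approx(0.3)
        assert by_id[1].abundance["s0"] == pytest.approx(0.3)
        assert by_id[1].abundance["s1"] == pytest.approx(0.35)

    def test_lifestyle_composition(self, net_and_partition):
        net, part = net_and_partition
        rel = _rel(np.full((5, 2), 0.1), ["a", "b", "c", "d", "e"])
        lifestyles = {"c": "Ectomycorrhizal", "d": "Ectomycorrhizal", "e": "Ectomycorrhizal"}
        profiles = module_profiles(net, part, rel, lifestyles, top_k=1)
        assert profiles[0].module_id == 1
        assert profiles[0].lifestyle_composition == {"Ectomycorrhizal": 1.0}
        lifestyles = {"c": "Ectomycorrhizal", "d": "Ectomycorrhizal", "e": "Ectomycorrhizal",
                      "a": "Ectomycorrhizal"}
        profiles = module_profiles(net, part, rel, lifestyles, top_k=2)
        comp = {p.module_id: p.lifestyle_composition for p in profiles}
        assert comp[2] == {"Ectomycorrhizal": 0.5, "unassigned": 0.5}

    def test_top_k_tie_break_deterministic(self):
        net = make_network([("a", "b", 0.9), ("c", "d", 0.8)])
        part = ModulePartition({"a": 1, "b": 1, "c": 2, "d": 2}, 0.5, "manual")
        rel = _rel(np.full((4, 2), 0.25), ["a", "b", "c", "d"])
        profiles = module_profiles(net, part, rel, top_k=1)
        assert [p.module_id for p in profiles] == [1]

    def test_fewer_modules_than_top_k(self, net_and_partition):
        net, part = net_and_partition
        rel = _rel(np.full((5, 2), 0.1), ["a", "b", "c", "d", "e"])
        assert len(module_profiles(net, part, rel, top_k=10)) == 2

    def test_composition_fractions_sum_to_one(self, net_and_partition):
        net, part = net_and_partition
        rel = _rel(np.full((5, 2), 0.1), ["a", "b", "c", "d", "e"])
        for p in module_profiles(net, part, rel, top_k=5):
            assert sum(p.lifestyle_composition.values()) == pytest.approx(1.0)
        frame = composition_frame(module_profiles(net, part, rel, top_k=5))
        assert np.allclose(frame.sum(axis=1), 1.0)

    def test_conservation_against_total(self, net_and_partition, rng):
        net, part = net_and_partition
        values = rng.random((5, 4))
        values /= values.sum(axis=0)
        rel = _rel(values, ["a", "b", "c", "d", "e"])
        profiles = module_profiles(net, part, rel, top_k=5)
        total = sum(p.abundance for p in profiles)
        assert np.allclose(total, rel.values.sum(axis=0))


class TestStars:
    def test_rule(self):
        assert stars(0.005) == "**"
        assert stars(0.01) == "*"
        assert stars(0.049) == "*"
        assert stars(0.05) == ""

    def test_rederivable_from_p(self, rng):
        series = {"x": pd.Series(rng.random(8), index=[f"s{j}" for j in range(8)])}
        meta = _meta({"moisture": rng.uniform(10, 90, 8), "pH": rng.uniform(4, 9, 8)})
        out = env_correlate(series, meta)
        for row in out.itertuples():
            if not row.flagged:
                assert row.stars == stars(row.p)


class TestEnvCorrelate:
    def test_perfect_monotone(self):
        idx = [f"s{j}" for j in range(6)]
        series = {"m1": pd.Series([1, 2, 3, 4, 5, 6], index=idx, dtype=float)}
        meta = _meta({"moisture": [10, 20, 30, 40, 50, 60.0]})
        out = env_correlate(series, meta)
        row = out[(out.row_id == "m1") & (out.factor == "moisture")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert row.stars == "**"

    def test_perfect_reversal_n5(self):
        idx = [f"s{j}" for j in range(5)]
        series = {"m1": pd.Series([5, 4, 3, 2, 1], index=idx, dtype=float)}
        meta = _meta({"moisture": [10, 20, 30, 40, 50.0]})
        out = env_correlate(series, meta)
        row = out[(out.row_id == "m1") & (out.factor == "moisture")].iloc[0]
        assert row.rho == pytest.approx(-1.0)

    def test_constant_factor_flagged(self):
        idx = [f"s{j}" for j in range(6)]
        series = {"m1": pd.Series(range(6), index=idx, dtype=float)}
        meta = _meta({"pH": [7.0] * 6})
        out = env_correlate(series, meta)
        row = out[(out.row_id == "m1") & (out.factor == "pH")].iloc[0]
        assert row.flagged and row.rho == 0.0 and row.p == 1.0

    def test_pairwise_deletion(self):
        idx = [f"s{j}" for j in range(8)]
        moisture = [10, 20, 30, 40, 50, 60, np.nan, np.nan]
        series = {"m1": pd.Series(range(8), index=idx, dtype=float)}
        out = env_correlate(series, _meta({"moisture": moisture}))
        row = out[(out.row_id == "m1") & (out.factor == "moisture")].iloc[0]
        assert row.n == 6
        assert row.rho == pytest.approx(1.0)

    def test_too_few_complete_pairs_flagged(self):
        idx = [f"s{j}" for j in range(6)]
        series = {"m1": pd.Series(range(6), index=idx, dtype=float)}
        out = env_correlate(series, _meta({"moisture": [50, 60, 70, np.nan, np.nan, np.nan]}))
        row = out[(out.row_id == "m1") & (out.factor == "moisture")].iloc[0]
        assert row.flagged

    def test_log_transform_handles_zeros_and_exempts_ph(self):
        meta = _meta({"BG": [0.0, 1.0, 4.0, 9.0, 2.0], "pH": [5, 6, 7, 8, 6.5]})
        env = log_transform_env(meta)
        assert np.isfinite(env["BG"]).all()
        # eps = half the smallest positive value = 0.5
        assert env.loc["s0", "BG"] == pytest.approx(np.log(0.5))
        assert env["pH"].tolist() == [5, 6, 7, 8, 6.5]

    def test_planted_env_link_recovered(self):
        """Module linked to moisture with effect 1.0 -> |rho| > 0.6, p < 0.05
        in >= 90% of 20 seeds."""
        import dataclasses as dc

        from cryonet.network_build import build_network, spearman_matrix
        from cryonet.network_props import detect_modules
        from cryonet.preprocess import FilterParams, filter_taxa, relative_abundance
        from cryonet.synthetic import SimulationSpec, simulate_community

        spec = SimulationSpec(
            n_samples=40,
            n_taxa=150,
            n_modules=3,
            module_sizes=(20, 20, 20),
            within_module_rho=0.7,
            sequencing_depth=20_000,
            env_spec={"moisture": (1, 1.0)},
            horizons=("topsoil",),
            sites=(1,),
        )
        hits = 0
        for seed in range(20):
            table, meta, tax, traits, truth = simulate_community(
                dc.replace(spec, seed=seed)
            )
            filt = filter_taxa(relative_abundance(table), FilterParams())
            net = build_network(spearman_matrix(filt))
            part = detect_modules(net)
            profiles = module_profiles(net, part, filt, top_k=5)
            series = {f"m{p.module_id}": p.abundance for p in profiles}
            out = env_correlate(series, meta)
            sub = out[(out.factor == "moisture") & ~out.flagged]
            if ((sub.rho.abs() > 0.6) & (sub.p < 0.05)).any():
                hits += 1
        assert hits >= 18
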