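"""Drought-resistance DEG classes and the triad module screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triadscreen import (
    TargetEdge,
    ThresholdConfig,
    classify_drought_degs,
    screen_triads,
)


def result_frame(rows, genotype):
    return pd.DataFrame(
        [
            {"feature": f, "layer": "mRNA", "genotype": genotype,
             "log2fc": lfc, "p": p, "padj": p}
            for f, lfc, p in rows
        ],
        columns=["feature", "layer", "genotype", "log2fc", "p", "padj"],
    )


class TestClassifyDroughtDegs:
    def _classify_one(self, ds_row, dt_row):
        out = classify_drought_degs(
            result_frame([ds_row], "DS"), result_frame([dt_row], "DT")
        )
        return out["drought_class"].iloc[0]

    def test_dt_specific_strong_up_is_class_a(self):
        assert self._classify_one(("g", 0.2, 0.8), ("g", 2.5, 0.001)) == "A"

    def test_shared_up_with_high_ratio_is_class_c(self):
        assert self._classify_one(("g", 1.05, 0.001), ("g", 3.5, 0.001)) == "C"

    def test_opposite_pattern_ds_up_dt_down_is_class_f(self):
        assert self._classify_one(("g", 1.2, 0.001), ("g", -1.3, 0.001)) == "F"

    def test_shared_up_with_low_ratio_is_none(self):
        assert self._classify_one(("g", 1.5, 0.001), ("g", 3.0, 0.001)) == "none"

    def test_dt_specific_but_weak_is_none(self):
        # called in DT only, but |log2FC| below the DT-specific bar
        assert self._classify_one(("g", 0.2, 0.8), ("g", 1.5, 0.001)) == "none"

    def test_feature_missing_from_one_genotype_treated_as_uncalled(self):
        ds = result_frame([], "DS")
        dt = result_frame([("g", 2.5, 0.001)], "DT")
        out = classify_drought_degs(ds, dt)
        assert out["drought_class"].iloc[0] == "A"

    def test_partition_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(47)
        cfg = ThresholdConfig()
        for _ in range(100):
            n = int(rng.integers(1, 30))
            feats = [f"g{i}" for i in range(n)]
            ds = result_frame(
                [(f, rng.normal(0, 2.5), rng.uniform(0, 0.15)) for f in feats],
                "DS")
            dt = result_frame(
                [(f, rng.normal(0, 2.5), rng.uniform(0, 0.15)) for f in feats],
                "DT")
            out = classify_drought_degs(ds, dt, cfg).set_index("feature")
            for f in feats:
                lds = ds.set_index("feature").at[f, "log2fc"]
                ldt = dt.set_index("feature").at[f, "log2fc"]
                cds = (ds.set_index("feature").at[f, "p"] < cfg.de_p
                       and abs(lds) > cfg.de_lfc)
                cdt = (dt.set_index("feature").at[f, "p"] < cfg.de_p
                       and abs(ldt) > cfg.de_lfc)
                if cdt and not cds and abs(ldt) > cfg.dt_specific_lfc:
                    want = "A" if ldt > 0 else "B"
                elif cds and cdt and lds * ldt > 0 and ldt / lds > cfg.lfc_ratio:
                    want = "C" if ldt > 0 else "D"
                elif cds and cdt and lds * ldt < 0:
                    want = "E" if lds < 0 else "F"
                else:
                    want = "none"
                assert out.at[f, "drought_class"] == want


def de_frames(mir, lnc, gene):
    """Build the three-layer DE dict from {feature: direction} maps."""
    def frame(dirs, layer):
        rows = []
        for f, d in dirs.items():
            lfc = {"up": 2.0, "down": -2.0, "none": 0.1}[d]
            p = 0.001 if d != "none" else 0.9
            rows.append({"feature": f, "layer": layer, "genotype": "DT",
                         "log2fc": lfc, "p": p, "padj": p})
        return pd.DataFrame(rows, columns=["feature", "layer", "genotype",
                                           "log2fc", "p", "padj"])
    return {"miRNA": frame(mir, "miRNA"), "lncRNA": frame(lnc, "lncRNA"),
            "mRNA": frame(gene, "mRNA")}


def brute_force_triads(mir, lnc, gene, edges):
    """Enumerate all (DEL, DEM, DEG) triples, then group per DEM."""
    ekeys = {(e.source, e.target, e.etype) for e in edges}
    opposite = {"up": "down", "down": "up"}
    modules = {}
    for m, l, g in itertools.product(mir, lnc, gene):
        if mir[m] == "none":
            continue
        opp = opposite[mir[m]]
        if lnc[l] != opp or gene[g] != opp:
            continue
        if (m, l, "mir2lnc") not in ekeys or (m, g, "mir2mrna") not in ekeys:
            continue
        if (l, g, "lnc_cis") not in ekeys and (l, g, "lnc_trans") not in ekeys:
            continue
        key = (m, 1 if mir[m] == "up" else 2)
        mod = modules.setdefault(key, (set(), set()))
        mod[0].add(l)
        mod[1].add(g)
    return {
        (m, t, frozenset(dels), frozenset(degs))
        for (m, t), (dels, degs) in modules.items()
    }


class TestScreenTriads:
    def test_minimal_positive_instance(self):
        de = de_frames({"m1": "up"}, {"l1": "down"}, {"g1": "down"})
        edges = [TargetEdge("m1", "l1", "mir2lnc"),
                 TargetEdge("m1", "g1", "mir2mrna"),
                 TargetEdge("l1", "g1", "lnc_trans", r=0.95, p=0.001)]
        mods = screen_triads(de, edges, "DT")
        assert len(mods) == 1
        m = mods[0]
        assert (m.dem, m.module_type) == ("m1", 1)
        assert m.dels == {"l1"} and m.degs == {"g1"}

    def test_direction_constraint_blocks_module(self):
        de = de_frames({"m1": "up"}, {"l1": "down"}, {"g1": "up"})
        edges = [TargetEdge("m1", "l1", "mir2lnc"),
                 TargetEdge("m1", "g1", "mir2mrna"),
                 TargetEdge("l1", "g1", "lnc_trans", r=0.95, p=0.001)]
        assert screen_triads(de, edges, "DT") == []

    def test_missing_pair_link_drops_members(self):
        de = de_frames({"m1": "up"}, {"l1": "down"}, {"g1": "down"})
        edges = [TargetEdge("m1", "l1", "mir2lnc"),
                 TargetEdge("m1", "g1", "mir2mrna")]
        assert screen_triads(de, edges, "DT") == []

    @staticmethod
    def _random_instance(rng):
        dirs = ["up", "down", "none"]
        mir = {f"m{i}": dirs[rng.integers(0, 3)] for i in range(rng.integers(1, 6))}
        lnc = {f"l{i}": dirs[rng.integers(0, 3)] for i in range(rng.integers(1, 6))}
        gene = {f"g{i}": dirs[rng.integers(0, 3)] for i in range(rng.integers(1, 6))}
        edges = []
        for m in mir:
            for l in lnc:
                if rng.random() < 0.4:
                    edges.append(TargetEdge(m, l, "mir2lnc"))
            for g in gene:
                if rng.random() < 0.4:
                    edges.append(TargetEdge(m, g, "mir2mrna"))
        for l in lnc:
            for g in gene:
                if rng.random() < 0.3:
                    etype = "lnc_cis" if rng.random() < 0.5 else "lnc_trans"
                    kw = ({"distance": 10} if etype == "lnc_cis"
                          else {"r": 0.95, "p": 0.001})
                    edges.append(TargetEdge(l, g, etype, **kw))
        return mir, lnc, gene, edges

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(53)
        for _ in range(100):
            mir, lnc, gene, edges = self._random_instance(rng)
            mods = screen_triads(de_frames(mir, lnc, gene), edges, "DT")
            got = {(m.dem, m.module_type, m.dels, m.degs) for m in mods}
            assert got == brute_force_triads(mir, lnc, gene, edges)

    def test_monotone_in_edges(self):
        rng = np.random.default_rng(59)
        for _ in range(30):
            mir, lnc, gene, edges = self._random_instance(rng)
            de = de_frames(mir, lnc, gene)
            before = {m.dem: (m.dels, m.degs) for m in screen_triads(de, edges, "DT")}
            extra = TargetEdge(next(iter(mir)), next(iter(lnc)), "mir2lnc")
            after = {m.dem: (m.dels, m.degs)
                     for m in screen_triads(de, edges + [extra], "DT")}
            for dem, (dels, degs) in before.items():
                assert dem in after
                assert dels <= after[dem][0]
                assert degs <= after[dem][1]

    def test_planted_triads_recovered_from_simulation(self, default_sim):
        from triadscreen import nb_test, score_module_recovery

        modules = []
        for genotype in default_sim.config.genotypes:
            de = {
                layer: nb_test(default_sim.counts[layer], genotype, layer=layer)
                for layer in ("mRNA", "lncRNA", "miRNA")
            }
            # use the generator's declared edge table plus planted pair edges
            edges = list(default_sim.edges) + [
                e for e in default_sim.truth.planted_edges
                if e.etype in ("lnc_cis", "lnc_trans")
            ]
            modules.extend(screen_triads(de, edges, genotype))
        rec = score_module_recovery(default_sim.truth, modules)
        assert rec.recall == 1.0
        assert rec.precision == 1.0
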