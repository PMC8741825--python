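"""Replicate intersection, hit criteria, potentiation and cohort ratios."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from funscreen import integrate as intg
from funscreen.io_model import GROUP_CULTURE47, GROUP_CULTURE47_FAS, GROUP_D0


def _quant(rows):
    """rows: (insert_id, group, replicate, raw, total)."""
    df = pd.DataFrame(rows, columns=["insert_id", "group", "replicate", "raw_count", "total"])
    df["rpm"] = df["raw_count"] * 1e6 / df["total"]
    df["present"] = df["raw_count"] >= 10
    return df.drop(columns="total")


class TestReplicateSupport:
    def test_counts_present_replicates(self):
        q = _quant(
            [("I0", GROUP_CULTURE47, r, c, 1000) for r, c in
             [("A", 15), ("B", 12), ("C", 30), ("D", 3)]]
        )
        assert intg.replicate_support(q, GROUP_CULTURE47)["I0"] == 3

    def test_empty_group_rejected(self):
        q = _quant([("I0", GROUP_D0, "A", 5, 100)])
        with pytest.raises(ValueError, match="CULTURE47"):
            intg.replicate_support(q, GROUP_CULTURE47)

    def test_order_invariance(self):
        rows = [("I0", GROUP_CULTURE47, r, 20, 1000) for r in "ABCD"]
        a = intg.replicate_support(_quant(rows), GROUP_CULTURE47)
        b = intg.replicate_support(_quant(rows[::-1]), GROUP_CULTURE47)
        assert a.equals(b)


def _iv(rows):
    return pd.DataFrame(rows, columns=["seqid", "start", "end"])


class TestMultiIntersect:
    def test_three_way_depth_partition(self):
        out = intg.multiintersect_depth(
            [_iv([("c", 0, 10)]), _iv([("c", 5, 15)]), _iv([("c", 8, 20)])]
        )
        d3 = out[out["depth"] == 3]
        assert list(map(tuple, d3.to_numpy())) == [("c", 8, 10, 3)]

    def test_empty_replicate_contributes_nothing(self):
        out = intg.multiintersect_depth([_iv([("c", 0, 10)]), _iv([])])
        assert out["depth"].max() == 1

    def test_random_instances_match_per_base_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            sets = []
            for _ in range(rng.integers(2, 5)):
                sets.append(
                    _iv([("c", int(s), int(s + rng.integers(1, 60)))
                         for s in rng.integers(0, 500, rng.integers(1, 10))])
                )
            out = intg.multiintersect_depth(sets)
            oracle = np.zeros(700, dtype=int)
            for df in sets:
                covered = np.zeros(700, dtype=bool)
                for r in df.itertuples(index=False):
                    covered[r.start : r.end] = True
                oracle += covered
            got = np.zeros(700, dtype=int)
            for r in out.itertuples(index=False):
                got[r.start : r.end] = r.depth
            assert (got == oracle).all()

    def test_matches_bedtools_multiinter(self, tmp_path):
        rng = np.random.default_rng(9)
        paths = []
        sets = []
        for i in range(3):
            rows = sorted(
                ("chr1", int(s), int(s + rng.integers(10, 200)))
                for s in rng.choice(np.arange(0, 10_000, 250), 15, replace=False)
            )
            merged = []
            for c, s, e in rows:  # bedtools multiinter expects merged inputs
                if merged and s <= merged[-1][2]:
                    merged[-1][2] = max(merged[-1][2], e)
                else:
                    merged.append([c, s, e])
            p = tmp_path / f"s{i}.bed"
            p.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in merged))
            paths.append(str(p))
            sets.append(_iv([(c, s, e) for c, s, e in merged]))
        out = subprocess.run(
            ["bedtools", "multiinter", "-i", *paths],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = [
            (f[0], int(f[1]), int(f[2]), int(f[3]))
            for f in (line.split("\t") for line in out.strip().splitlines())
        ]
        got = list(map(tuple, intg.multiintersect_depth(sets).to_numpy()))
        assert got == expected


def _mk_catalogue():
    return pd.DataFrame(
        {"seqid": ["c", "c"], "start": [0, 500], "end": [100, 700],
         "id": ["I0", "I1"]}
    )


class TestCallHits:
    def _call(self, support, directional, distance, **kw):
        rows = []
        for i, (rep_count) in enumerate(support):
            for j, r in enumerate("ABCD"):
                raw = 20 if j < rep_count else 0
                rows.append((f"I{i}", GROUP_CULTURE47_FAS, r, raw, 1000))
                rows.append((f"I{i}", GROUP_D0, r, 15, 1000))
        q = _quant(rows)
        cat = _mk_catalogue()
        d = pd.Series(directional, index=["I0", "I1"])
        rd = pd.Series(distance, index=["I0", "I1"], dtype=float)
        return intg.call_hits(q, cat, d, rd, **kw)

    def test_all_criteria_pass(self):
        hits = self._call([3, 0], [True, True], [40, 40])
        h0 = hits.set_index("insert_id").loc["I0"]
        assert GROUP_CULTURE47_FAS in h0["selected_in"]
        assert h0["high_confidence"]

    def test_no_directional_support_blocks_selection(self):
        hits = self._call([4, 0], [False, True], [40, 40])
        assert hits.set_index("insert_id").loc["I0"]["selected_in"] == ""

    def test_restriction_distance_boundary(self):
        hits = self._call([3, 3], [True, True], [100, 101])
        h = hits.set_index("insert_id")
        assert h.loc["I0"]["high_confidence"]
        assert not h.loc["I1"]["high_confidence"]

    def test_hit_calling_monotone_in_min_replicates(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(30):
            for r in "ABCD":
                rows.append((f"I{i}", GROUP_CULTURE47_FAS, r,
                             int(rng.integers(0, 30)), 1000))
        q = _quant(rows)
        cat = pd.DataFrame(
            {"seqid": "c", "start": np.arange(30) * 100,
             "end": np.arange(30) * 100 + 50, "id": [f"I{i}" for i in range(30)]}
        )
        d = pd.Series(True, index=cat["id"])
        rd = pd.Series(10.0, index=cat["id"])
        sizes = []
        for mr in (1, 2, 3, 4):
            hits = intg.call_hits(q, cat, d, rd, min_replicates=mr)
            sizes.append((hits["selected_in"] != "").sum())
        assert sizes == sorted(sizes, reverse=True)


class TestScores:
    def test_potentiation_arithmetic(self):
        q = _quant(
            [("I0", GROUP_CULTURE47, r, 4, 1_000_000) for r in "AB"]
            + [("I0", GROUP_D0, r, 2, 1_000_000) for r in "AB"]
        )
        pot = intg.potentiation(q, GROUP_CULTURE47)
        assert pot["I0"] == pytest.approx(200.0)

    def test_zero_baseline_is_undefined_not_zero(self):
        q = _quant(
            [("I0", GROUP_CULTURE47, "A", 4, 1000), ("I0", GROUP_D0, "A", 0, 1000)]
        )
        assert np.isnan(intg.potentiation(q, GROUP_CULTURE47)["I0"])

    def test_leave_one_replicate_out(self):
        q = _quant(
            [("I0", GROUP_CULTURE47_FAS, "A", 10, 1_000_000),
             ("I0", GROUP_CULTURE47_FAS, "D", 90, 1_000_000),
             ("I0", GROUP_D0, "A", 10, 1_000_000)]
        )
        full = intg.potentiation(q, GROUP_CULTURE47_FAS)
        nod = intg.potentiation(q, GROUP_CULTURE47_FAS, exclude_replicate="D")
        assert full["I0"] == pytest.approx(500.0)
        assert nod["I0"] == pytest.approx(100.0)

    def test_potentiation_scale_invariant_under_library_size(self):
        """Multiplying every raw count of one sample by a constant leaves
        potentiation unchanged (RPM normalisation cancels depth)."""
        base = [("I0", GROUP_CULTURE47, "A", 4, 100), ("I1", GROUP_CULTURE47, "A", 6, 100),
                ("I0", GROUP_D0, "A", 2, 50), ("I1", GROUP_D0, "A", 3, 50)]
        scaled = [(i, g, r, raw * 7, tot * 7) if g == GROUP_D0 else (i, g, r, raw, tot)
                  for i, g, r, raw, tot in base]
        p1 = intg.potentiation(_quant(base), GROUP_CULTURE47)
        p2 = intg.potentiation(_quant(scaled), GROUP_CULTURE47)
        pd.testing.assert_series_equal(p1, p2)

    def test_ratio_arithmetic_and_undefined(self):
        q = _quant(
            [("I0", GROUP_CULTURE47_FAS, "A", 532, 100_000_000),
             ("I0", GROUP_CULTURE47, "A", 200, 100_000_000),
             ("I1", GROUP_CULTURE47_FAS, "A", 5, 100_000_000),
             ("I1", GROUP_CULTURE47, "A", 0, 100_000_000)]
        )
        r = intg.mf_mfz_ratio(q)
        assert r["I0"] == pytest.approx(2.66)
        assert np.isnan(r["I1"])
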