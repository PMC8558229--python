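"""DE thresholding, XBP1u control subtraction, motif filtering, heat-map order."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xbptargets.expression import (
    GeneSet,
    filter_by_motif,
    linkage_merge_heights,
    order_genes_for_heatmap,
    select_de,
    subtract_control,
)
from xbptargets.motifs import GeneMotifReport


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change", "p_value"])


class TestSelectDe:
    def test_boundary_fold_included_boundary_p_excluded(self):
        table = de_table(
            [
                ("at_fold", 1.0, 0.049),   # |lfc| exactly at threshold: in
                ("at_p", 2.3, 0.05),       # p exactly at threshold: out
                ("above_p", 2.3, 0.051),   # p above threshold: out
                ("down", -1.0, 0.001),
            ]
        )
        up, down = select_de(table)
        assert up.members == {"at_fold"}
        assert down.members == {"down"}

    def test_thresholds_disabled_split_by_sign(self):
        table = de_table([("a", 0.2, 0.9), ("b", -0.1, 0.99), ("c", 0.0, 0.5)])
        up, down = select_de(table, min_abs_log2fc=0.0, max_p=1.0)
        assert up.members == {"a", "c"} and down.members == {"b", "c"}


class TestSubtractControl:
    def _sets(self, **kwargs):
        return {k: GeneSet(k, frozenset(v)) for k, v in kwargs.items()}

    def test_control_genes_removed_and_reported_shared(self):
        s = self._sets(su={"A", "B", "C"}, sd=set(), uu={"B"}, ud=set())
        part = subtract_control(s["su"], s["sd"], s["uu"], s["ud"])
        assert part.xbp1s_only_up.members == {"A", "C"}
        assert part.shared.members == {"B"}

    def test_disjoint_inputs_share_nothing(self):
        s = self._sets(su={"A"}, sd={"B"}, uu={"C"}, ud={"D"})
        part = subtract_control(s["su"], s["sd"], s["uu"], s["ud"])
        assert part.shared.members == set()
        assert part.xbp1u_only_up.members == {"C"}

    def test_random_sets_match_membership_oracle(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(200)]
        su, sd, uu, ud = (
            frozenset(g for g in genes if rng.random() < p) for p in (0.2, 0.2, 0.15, 0.15)
        )
        sd = sd - su  # a gene is up or down in one experiment, not both
        ud = ud - uu
        part = subtract_control(
            GeneSet("su", su), GeneSet("sd", sd), GeneSet("uu", uu), GeneSet("ud", ud)
        )
        u_all = uu | ud
        for g in genes:  # exhaustive membership check
            assert (g in part.xbp1s_only_up.members) == (g in su and g not in u_all)
            assert (g in part.xbp1s_only_down.members) == (g in sd and g not in u_all)
            assert (g in part.shared.members) == (g in (su | sd) and g in u_all)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        su=st.frozensets(st.integers(0, 30)),
        sd=st.frozensets(st.integers(0, 30)),
        uu=st.frozensets(st.integers(0, 30)),
        ud=st.frozensets(st.integers(0, 30)),
    )
    def test_partition_disjoint_and_reconstructs_spliced(self, su, sd, uu, ud):
        to_set = lambda name, s: GeneSet(name, frozenset(map(str, s)))
        part = subtract_control(
            to_set("su", su), to_set("sd", sd), to_set("uu", uu), to_set("ud", ud)
        )
        sets = [s.members for s in part.sets()]
        for a, b in itertools.combinations(sets, 2):
            assert not (a & b)
        reconstructed = (
            part.xbp1s_only_up.members | part.xbp1s_only_down.members | part.shared.members
        )
        assert reconstructed == set(map(str, su | sd))


class TestFilterByMotif:
    def test_zero_hit_candidate_excluded(self):
        kept = filter_by_motif(
            GeneSet("c", frozenset({"A"})), [GeneMotifReport("A", 0, 0, 100)]
        )
        assert kept.members == set()

    def test_include_list_overrides_zero_hits(self):
        # DDIT3 carries no consensus instance but is force-included
        kept = filter_by_motif(
            GeneSet("c", frozenset({"DDIT3", "X"})),
            [GeneMotifReport("DDIT3", 0, 0, 100), GeneMotifReport("X", 2, 0, 100)],
            include_list=GeneSet("inc", frozenset({"DDIT3", "HSPA5"})),
        )
        assert kept.members == {"DDIT3", "HSPA5", "X"}

    def test_missing_report_treated_as_zero(self):
        kept = filter_by_motif(GeneSet("c", frozenset({"A", "B"})), {"A": 3})
        assert kept.members == {"A"}

    def test_synthetic_counts_match_manifest_filter(self):
        rng = np.random.default_rng(29)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 5, size=100))}
        candidates = GeneSet("c", frozenset(counts))
        for min_hits in (1, 2, 3):
            kept = filter_by_motif(candidates, counts, min_hits=min_hits)
            assert kept.members == {g for g, c in counts.items() if c >= min_hits}


def brute_force_average_linkage(values):
    """O(n^3) agglomeration oracle: returns the merge sequence as
    (frozenset_a, frozenset_b, height) triples."""
    n = len(values)
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = float(
                np.mean(
                    [
                        np.linalg.norm(values[i] - values[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
            )
            if best is None or h < best[0] - 1e-12:
                best = (h, a, b)
        h, a, b = best
        merges.append((clusters[a], clusters[b], h))
        clusters[next_id] = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        next_id += 1
    return merges


class TestOrderGenesForHeatmap:
    def test_identical_rows_end_up_adjacent(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [9.0, 9.0], [1.0, 2.0]], index=["a", "far", "b"]
        )
        order = order_genes_for_heatmap(m)
        assert abs(order.index("a") - order.index("b")) == 1

    def test_single_gene_returned_unchanged(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["only"])
        assert order_genes_for_heatmap(m) == ["only"]

    def test_equal_pair_merges_before_outlier(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [100.0, 100.0]], index=["a", "b", "c"]
        )
        heights = linkage_merge_heights(m)
        assert heights[0] == pytest.approx(0.0)
        order = order_genes_for_heatmap(m)
        assert order.index("c") in (0, 2)

    def test_merge_sequence_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(31)
        m = pd.DataFrame(
            rng.normal(size=(10, 6)), index=[f"g{i}" for i in range(10)]
        )
        expected = brute_force_average_linkage(m.sort_index().values)
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        tree = linkage(pdist(m.sort_index().values), method="average")
        members = [frozenset([i]) for i in range(10)]
        for row, (ea, eb, eh) in zip(tree, expected):
            a, b, h = int(row[0]), int(row[1]), float(row[2])
            assert {members[a], members[b]} == {ea, eb}
            assert h == pytest.approx(eh, abs=1e-9)
            members.append(members[a] | members[b])

    def test_row_mean_imputation_allows_missing_values(self):
        m = pd.DataFrame(
            [[1.0, np.nan, 3.0], [1.0, 2.0, 3.0], [50.0, 60.0, 70.0]],
            index=["a", "b", "c"],
        )
        order = order_genes_for_heatmap(m)
        assert set(order) == {"a", "b", "c"}
        assert abs(order.index("a") - order.index("b")) == 1
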