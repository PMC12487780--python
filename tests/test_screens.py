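"""Reprogramming assay, susceptibility and the OE/KD displacement screen."""

import numpy as np
import pytest

import frustnet as fn


def _anchor_markers(grn, anchor_a, anchor_b):
    """Marker set derived from the planted anchors: genes that switch on
    during the A->B transition score PS positively, genes that switch off
    negatively (EM axis left empty)."""
    pos = [g for g, a, b in zip(grn.genes, anchor_a, anchor_b) if a == 0 and b == 1]
    neg = [g for g, a, b in zip(grn.genes, anchor_a, anchor_b) if a == 1 and b == 0]
    return fn.MarkerSet(
        phiPS_pos=frozenset(pos),
        phiPS_neg=frozenset(neg),
        phiEM_pos=frozenset(),
        phiEM_neg=frozenset(),
    )


class TestReprogrammingAssay:
    def test_infinite_threshold_all_unproductive(self, small_planted):
        grn, (a, b) = small_planted
        markers = _anchor_markers(grn, a, b)
        res = fn.reprogramming_assay(
            grn, np.tile(a, (5, 1)), markers,
            clamp=fn.PerturbationSpec({grn.genes[0]: 1}),
            threshold=np.inf, seed=0,
        )
        assert not res.table["productive"].any()
        assert len(res.failed) == 5

    def test_clamp_raises_productive_fraction(self, small_planted):
        """Clamping an anchor-B gene on from anchor-A starts yields strictly
        more productive trajectories than no intervention."""
        grn, (a, b) = small_planted
        markers = _anchor_markers(grn, a, b)
        gene_on_in_b = grn.genes[int(np.flatnonzero((a == 0) & (b == 1))[0])]
        starts = np.tile(a, (20, 1))
        with_clamp = fn.reprogramming_assay(
            grn, starts, markers,
            clamp=fn.PerturbationSpec({gene_on_in_b: 1}),
            threshold=0, seed=1,
        )
        without = fn.reprogramming_assay(
            grn, starts, markers, clamp=fn.PerturbationSpec({}),
            threshold=0, seed=1,
        )
        assert (
            with_clamp.table["productive"].mean()
            > without.table["productive"].mean()
        )

    def test_partition_and_threshold_tie_rule(self, standin, standin_ensemble,
                                              standin_labels):
        grn, _ = standin
        mk = fn.BUILTIN_MARKERS
        starts = np.repeat(
            standin_ensemble.states[standin_labels == "SM"], 5, axis=0
        )
        res = fn.reprogramming_assay(grn, starts, mk, seed=11)
        assert len(res.productive) + len(res.failed) == len(res.table)
        # ties at the threshold are unproductive (strict > for productive)
        at_cut = res.table[res.table["delta_phi_ps"] == res.threshold]
        assert not at_cut["productive"].any()

    def test_productive_starts_more_frustrated(
        self, standin, standin_ensemble, standin_labels
    ):
        """Trajectories that reprogram successfully depart from start states
        of higher pseudo-energy than those that fail."""
        grn, _ = standin
        mk = fn.BUILTIN_MARKERS
        starts = np.repeat(
            standin_ensemble.states[standin_labels == "SM"], 30, axis=0
        )
        res = fn.reprogramming_assay(grn, starts, mk, seed=11)
        summary = res.group_energy_summary()
        assert {"productive", "failed"} <= set(summary.index)
        assert (
            summary.loc["productive", "mean"] > summary.loc["failed", "mean"]
        )

    def test_empty_pool_rejected(self, toy3):
        with pytest.raises(ValueError):
            fn.reprogramming_assay(
                toy3, np.empty((0, 3)), fn.BUILTIN_MARKERS
            )


class TestSusceptibility:
    def test_identical_finals_give_zero(self, toy3):
        starts = np.array([[1, 1, 0], [0, 0, 1]], dtype=np.uint8)
        res = fn.susceptibility_analysis(toy3, starts, starts)
        assert (res.flip_probability == 0).all()
        assert res.high_susceptibility == ()

    def test_half_flip_probability(self, toy3):
        starts = np.array([[1, 1, 0], [1, 1, 0]], dtype=np.uint8)
        finals = np.array([[0, 1, 0], [1, 1, 0]], dtype=np.uint8)
        res = fn.susceptibility_analysis(toy3, starts, finals)
        assert res.flip_probability[toy3.gene_index("a")] == 0.5
        assert "a" in res.high_susceptibility

    def test_perfect_anticorrelation_limit(self, toy3):
        res = fn.susceptibility_analysis(
            toy3,
            np.array([[1, 1, 0], [1, 1, 0], [1, 1, 0]], dtype=np.uint8),
            np.array([[0, 1, 0], [0, 1, 1], [0, 0, 0]], dtype=np.uint8),
        )
        flip = res.flip_probability
        anti = -flip
        rho = np.corrcoef(flip, anti)[0, 1]
        assert rho == pytest.approx(-1.0)

    def test_zero_pairs_rejected(self, toy3):
        with pytest.raises(ValueError):
            fn.susceptibility_analysis(
                toy3, np.empty((0, 3)), np.empty((0, 3))
            )

    def test_high_susceptibility_genes_less_frustrated(
        self, standin, standin_ensemble, standin_labels
    ):
        """Genes that flip during productive reprogramming show lower local
        pseudo-energy at the clamped start states (negative correlation)."""
        grn, _ = standin
        mk = fn.BUILTIN_MARKERS
        starts = np.repeat(
            standin_ensemble.states[standin_labels == "SM"], 30, axis=0
        )
        res = fn.reprogramming_assay(grn, starts, mk, seed=11)
        prod = [
            t for t, p in zip(res.trajectories, res.table["productive"]) if p
        ]
        assert prod, "expected some productive trajectories"
        sus = fn.susceptibility_analysis(
            grn,
            np.stack([t.start for t in prod]),
            np.stack([t.final for t in prod]),
            clamp=res.clamp,
        )
        assert sus.pearson_rho < 0


class TestScreen:
    def test_toy3_hand_relaxations(self, toy3):
        start = np.array([[1, 1, 0]], dtype=np.uint8)
        screen = fn.oe_kd_screen(toy3, start, seed=0)
        t = screen.table.set_index(["gene", "protocol"])["delta"]
        # KD of a: b keeps its state (input 0), c keeps 0 -> only a differs
        assert t[("a", "KD")] == 1
        # OE of c: a's input drops to 0 and holds -> only c differs
        assert t[("c", "OE")] == 1
        # OE of a: already on, no cascade
        assert t[("a", "OE")] == 0

    def test_delta_bounds_and_clamp_floor(self, standin, standin_ensemble):
        grn, _ = standin
        starts = standin_ensemble.states[:40]
        screen = fn.oe_kd_screen(grn, starts, seed=2)
        tab = screen.table
        assert (tab["delta"] >= 0).all()
        assert (tab["delta"] <= grn.n_genes).all()
        # whenever the clamp changes the start bit, delta >= 1
        for _, row in tab.sample(200, random_state=0).iterrows():
            gi = grn.gene_index(row["gene"])
            bit = starts[row["start_id"], gi]
            want = 1 if row["protocol"] == "OE" else 0
            if bit != want:
                assert row["delta"] >= 1

    def test_bit_for_bit_determinism(self, standin, standin_ensemble):
        grn, _ = standin
        starts = standin_ensemble.states[:25]
        a = fn.oe_kd_screen(grn, starts, seed=7)
        b = fn.oe_kd_screen(grn, starts, seed=7)
        assert a.table.equals(b.table)

    def test_core_factors_top_ranked(self, standin, standin_ensemble):
        """Overexpressing the pluripotency program's own factors produces
        the largest displacement cascades."""
        grn, _ = standin
        rank = fn.screen_rank(
            fn.oe_kd_screen(grn, standin_ensemble.states[:300], seed=3)
        )
        oe = rank.ranked[rank.ranked["protocol"] == "OE"]
        top4 = set(oe.head(4)["gene"])
        assert len(top4 & fn.BUILTIN_MARKERS.phiPS_pos) >= 3

    def test_oe_more_effective_than_kd(self, standin, standin_ensemble):
        grn, _ = standin
        rank = fn.screen_rank(
            fn.oe_kd_screen(grn, standin_ensemble.states[:300], seed=3)
        )
        assert rank.mean_effect("OE") > rank.mean_effect("KD")


class TestScreenRank:
    def _table(self, rows):
        import pandas as pd

        return fn.ScreenTable(
            table=pd.DataFrame(
                rows, columns=["gene", "protocol", "start_id", "delta"]
            ),
            n_nonconverged=0,
            seed=0,
        )

    def test_poisson_mle_is_sample_mean(self):
        screen = self._table(
            [("g", "OE", i, 2) for i in range(3)]
        )
        rank = fn.screen_rank(screen)
        assert rank.stats["lambda_hat"].iloc[0] == pytest.approx(2.0)

    def test_zero_delta_gene_filtered_from_ranking(self):
        screen = self._table(
            [("g", "OE", i, 0) for i in range(5)]
            + [("h", "OE", i, 40) for i in range(5)]
        )
        rank = fn.screen_rank(screen)
        assert "g" not in set(rank.ranked["gene"])
        assert "h" in set(rank.ranked["gene"])

    def test_occurrence_cutoff(self):
        screen = self._table(
            [("g", "OE", i, 35) for i in range(12)]
            + [("h", "OE", i, 35) for i in range(4)]
        )
        rank = fn.screen_rank(screen, delta_cutoff=32, min_occurrence=10)
        assert set(rank.occurrences["gene"]) == {"g"}
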