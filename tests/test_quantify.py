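"""TPM normalization, abundance fractions, spike calibration and TPL."""

import numpy as np
import pandas as pd
import pytest

from seasonet.errors import ValidationError
from seasonet.quantify import (
    aggregate_ko,
    compute_tpm,
    estimate_spike_recovery,
    estimate_tpl,
    relative_fractions,
    split_spikes,
    tpl_table,
)


def frame(values, index, columns):
    return pd.DataFrame(values, index=index, columns=columns, dtype=float)


class TestComputeTpm:
    def test_single_transcript_normalizes_to_million(self):
        counts = frame([[7.0]], ["t1"], ["s1"])
        tpm = compute_tpm(counts, pd.Series([500.0], index=["t1"]))
        assert tpm.loc["t1", "s1"] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = frame([[3.0], [3.0]], ["t1", "t2"], ["s1"])
        tpm = compute_tpm(counts, pd.Series([100.0, 100.0], index=["t1", "t2"]))
        assert tpm["s1"].tolist() == pytest.approx([5e5, 5e5])

    def test_length_normalization_hand_worked(self):
        counts = frame([[10.0], [10.0]], ["t1", "t2"], ["s1"])
        tpm = compute_tpm(counts, pd.Series([100.0, 200.0], index=["t1", "t2"]))
        assert tpm.loc["t1", "s1"] == pytest.approx(666666.67, abs=0.01)
        assert tpm.loc["t2", "s1"] == pytest.approx(333333.33, abs=0.01)

    def test_all_zero_column_stays_zero(self):
        counts = frame([[0.0, 4.0], [0.0, 1.0]], ["t1", "t2"], ["s1", "s2"])
        tpm = compute_tpm(counts, pd.Series([100.0, 100.0], index=["t1", "t2"]))
        assert (tpm["s1"] == 0).all()
        assert tpm["s2"].sum() == pytest.approx(1e6)

    def test_column_sums_on_random_matrix(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 6)).astype(float))
        lengths = pd.Series(rng.uniform(200, 2000, size=50), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_zero_length_with_counts_rejected(self):
        counts = frame([[5.0]], ["t1"], ["s1"])
        with pytest.raises(ValidationError):
            compute_tpm(counts, pd.Series([0.0], index=["t1"]))


class TestSplitSpikes:
    def test_no_spikes_leaves_matrix_unchanged(self):
        m = frame([[1.0], [2.0]], ["t1", "t2"], ["s1"])
        bio, spikes = split_spikes(m, [])
        assert bio.equals(m) and spikes.empty

    def test_all_spikes_empties_biological_matrix(self):
        m = frame([[1.0], [2.0]], ["e1", "e2"], ["s1"])
        bio, spikes = split_spikes(m, ["e1", "e2"])
        assert bio.empty and spikes.equals(m)

    def test_renormalization_restores_million(self):
        # spike takes 10% of a TPM column; removal renormalizes to 1e6
        m = frame([[9e5], [1e5]], ["t1", "e1"], ["s1"])
        bio, _ = split_spikes(m, ["e1"])
        assert bio["s1"].sum() == pytest.approx(1e6)

    def test_unknown_spike_rejected(self):
        m = frame([[1.0]], ["t1"], ["s1"])
        with pytest.raises(ValidationError):
            split_spikes(m, ["nope"])


class TestRelativeFractions:
    @staticmethod
    def _ann(groups, identity=95.0):
        n = len(groups)
        return pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "taxon_id": groups,
                "lineage": [f"{g};gen;sp" if g else None for g in groups],
                "percent_identity": [identity] * n,
                "ko_id": [None] * n,
                "pfam_ids": [None] * n,
            }
        )

    def test_boundary_fraction_not_pooled(self):
        # strict <2%: a group at exactly 2% stays
        tpm = frame([[98.0], [2.0]], ["t0", "t1"], ["s1"])
        out = relative_fractions(tpm, self._ann(["A", "B"]), rare_threshold=0.02)
        assert set(out.index) == {"A", "B"}
        assert out.loc["B", "s1"] == pytest.approx(0.02)

    def test_below_threshold_pooled_into_rare(self):
        tpm = frame([[60.0], [39.0], [1.0]], ["t0", "t1", "t2"], ["s1"])
        out = relative_fractions(tpm, self._ann(["A", "B", "C"]))
        assert "rare" in out.index and "C" not in out.index
        assert out.loc["rare", "s1"] == pytest.approx(0.01)
        assert out["s1"].sum() == pytest.approx(1.0)

    def test_single_group_gets_fraction_one(self):
        tpm = frame([[42.0]], ["t0"], ["s1"])
        out = relative_fractions(tpm, self._ann(["A"]))
        assert out.loc["A", "s1"] == pytest.approx(1.0)

    def test_identity_threshold_strict(self):
        tpm = frame([[50.0], [50.0]], ["t0", "t1"], ["s1"])
        ann = self._ann(["A", "B"])
        ann.loc[1, "percent_identity"] = 60.0  # not > 60
        out = relative_fractions(tpm, ann, min_identity=60.0)
        assert out.loc["A", "s1"] == pytest.approx(1.0)
        assert "B" not in out.index

    def test_monthly_mode_pools_tpm_before_normalizing(self):
        tpm = frame([[10.0, 30.0], [30.0, 30.0]], ["t0", "t1"], ["s1", "s2"])
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "station": ["x", "y"],
             "date": ["2021-04-15", "2021-04-20"]}
        )
        out = relative_fractions(
            tpm, self._ann(["A", "B"]), by="month", metadata=meta
        )
        assert out.loc["A", "2021-04"] == pytest.approx(40.0 / 100.0)


class TestAggregateKo:
    def test_additivity_and_null_drop(self, toy_annotations):
        tpm = frame(
            [[10.0], [5.0], [2.0], [7.0], [1.0]],
            ["t1", "t2", "t3", "t4", "t5"],
            ["s1"],
        )
        ko = aggregate_ko(tpm, toy_annotations)
        assert ko.loc["K00001", "s1"] == pytest.approx(15.0)
        assert ko.loc["K00002", "s1"] == pytest.approx(2.0)
        assert ko["s1"].sum() == pytest.approx(17.0)  # t4, t5 have no KO

    def test_row_order_invariance(self, toy_annotations):
        tpm = frame(
            [[10.0], [5.0], [2.0], [7.0], [1.0]],
            ["t1", "t2", "t3", "t4", "t5"],
            ["s1"],
        )
        shuffled = tpm.sample(frac=1.0, random_state=0)
        assert aggregate_ko(tpm, toy_annotations).sort_index().equals(
            aggregate_ko(shuffled, toy_annotations).sort_index()
        )


class TestSpikeRecovery:
    def test_direct_ratio(self):
        counts = pd.Series([1000.0], index=["e1"])
        spikes = pd.DataFrame(
            {"spike_id": ["e1"], "length_bp": [1000], "molecules_added": [1e6]}
        )
        assert estimate_spike_recovery(counts, spikes) == pytest.approx(1e-6)

    def test_linearity(self):
        counts = pd.Series([300.0, 500.0], index=["e1", "e2"])
        spikes = pd.DataFrame(
            {"spike_id": ["e1", "e2"], "length_bp": [500, 900],
             "molecules_added": [2e5, 4e5]}
        )
        k1 = estimate_spike_recovery(counts, spikes)
        k2 = estimate_spike_recovery(2 * counts, spikes)
        assert k2 == pytest.approx(2 * k1)

    def test_proportional_spikes_give_pooled_ratio(self):
        spikes = pd.DataFrame(
            {"spike_id": ["e1", "e2"], "length_bp": [500, 1000],
             "molecules_added": [1e6, 1e6]}
        )
        k = 2e-6  # counts proportional to molecules*length at this k
        counts = pd.Series([k * 1e6 * 500, k * 1e6 * 1000], index=["e1", "e2"])
        assert estimate_spike_recovery(counts, spikes) == pytest.approx(k)
        assert estimate_spike_recovery(
            counts[["e1"]], spikes.iloc[[0]]
        ) == pytest.approx(k)

    def test_zero_spike_reads_uncalibratable(self):
        counts = pd.Series([0.0], index=["e1"])
        spikes = pd.DataFrame(
            {"spike_id": ["e1"], "length_bp": [500], "molecules_added": [1e6]}
        )
        with pytest.raises(ValidationError):
            estimate_spike_recovery(counts, spikes)


class TestEstimateTpl:
    META = pd.Series(
        {
            "volume_filtered_l": 50.0,
            "resuspension_volume_ml": 10.0,
            "extraction_input_ml": 1.0,
            "rna_yield_ng": 1000.0,
            "library_input_ng": 200.0,
        }
    )

    def test_hand_propagated_chain(self):
        # 500/(1e-6*500)=1e6 molecules; x5 extract; x10 residue; /50 L -> 1e6
        counts = pd.Series([500.0], index=["t1"])
        lengths = pd.Series([500.0], index=["t1"])
        tpl = estimate_tpl(counts, lengths, 1e-6, self.META)
        assert tpl["t1"] == pytest.approx(1e6)

    def test_zero_counts_zero_tpl(self):
        tpl = estimate_tpl(
            pd.Series([0.0], index=["t1"]), pd.Series([500.0], index=["t1"]),
            1e-6, self.META,
        )
        assert tpl["t1"] == 0.0

    def test_halving_volume_doubles_tpl(self):
        counts = pd.Series([500.0], index=["t1"])
        lengths = pd.Series([500.0], index=["t1"])
        meta = self.META.copy()
        meta["volume_filtered_l"] = 25.0
        assert estimate_tpl(counts, lengths, 1e-6, meta)["t1"] == pytest.approx(2e6)

    def test_missing_fields_named(self):
        meta = self.META.drop(["rna_yield_ng", "volume_filtered_l"])
        with pytest.raises(ValidationError, match="rna_yield_ng"):
            estimate_tpl(
                pd.Series([1.0], index=["t1"]), pd.Series([500.0], index=["t1"]),
                1e-6, meta,
            )


class TestNoiseFreeClosure:
    def test_tpl_recovers_planted_molecules(self, small_community):
        """Expected counts through the full chain invert to the planted truth."""
        ds = small_community
        tpl = tpl_table(ds.truth.expected_counts, ds.lengths, ds.spikes, ds.metadata)
        truth = ds.truth.molecules_per_liter
        rel = np.abs(tpl.to_numpy() - truth.to_numpy()) / np.maximum(
            truth.to_numpy(), 1e-300
        )
        assert np.nanmax(rel) < 1e-6

    def test_tpl_monotone_in_counts(self, small_community):
        ds = small_community
        sample = ds.counts.columns[0]
        counts = ds.counts[sample].iloc[:-3]  # biological rows
        lengths = ds.lengths.iloc[:-3]
        k = 1e-6
        meta = ds.metadata.set_index("sample_id").loc[sample]
        base = estimate_tpl(counts, lengths, k, meta)
        bumped = counts.copy()
        bumped.iloc[0] += 100
        more = estimate_tpl(bumped, lengths, k, meta)
        assert more.iloc[0] > base.iloc[0]
        assert (more.iloc[1:] == base.iloc[1:]).all()
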