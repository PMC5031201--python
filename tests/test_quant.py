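import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hcpflux import (
    PsmRecord,
    QuantError,
    channel_sum_normalize,
    generate_experiment,
    global_composition,
    hc_lc_series,
    normalize_collection,
    psm_ratios,
    rollup_proteins,
    SyntheticParams,
)

positive_matrices = arrays(
    float,
    st.tuples(st.integers(2, 12), st.integers(2, 8)),
    elements=st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False),
).map(pd.DataFrame)


class TestChannelSumNormalize:
    def test_hand_worked_2x2(self):
        m = pd.DataFrame([[2.0, 2.0], [2.0, 6.0]])
        out = channel_sum_normalize(m)
        # column sums 4 and 8, target 6 -> factors 1.5 and 0.75
        assert out.values.tolist() == [[3.0, 1.5], [3.0, 4.5]]

    def test_equal_sums_identity(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 2.0]])
        out = channel_sum_normalize(m)
        assert np.allclose(out, m)

    @given(positive_matrices)
    def test_column_sums_equalized_and_idempotent(self, m):
        out = channel_sum_normalize(m)
        sums = out.sum(axis=0).to_numpy()
        assert np.allclose(sums, sums.mean(), rtol=1e-9)
        again = channel_sum_normalize(out)
        assert np.allclose(again, out, rtol=1e-12)

    @given(positive_matrices)
    def test_within_column_ratios_preserved(self, m):
        out = channel_sum_normalize(m)
        for c in m.columns:
            before = m[c] / m[c].iloc[0]
            after = out[c] / out[c].iloc[0]
            assert np.allclose(before, after, rtol=1e-12)

    def test_zero_sum_column_names_label(self):
        m = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        with pytest.raises(QuantError, match="B"):
            channel_sum_normalize(m)


class TestPsmRatios:
    def _rec(self, values):
        labels = [f"L{i}" for i in range(len(values))]
        return PsmRecord("s1", "PEP", ("P1",), dict(zip(labels, map(float, values))))

    def test_mean_division(self):
        assert psm_ratios(self._rec([10, 20, 30])) == {"L0": 0.5, "L1": 1.0, "L2": 1.5}

    def test_equal_intensities_all_one(self):
        assert psm_ratios(self._rec([7, 7, 7, 7])) == {f"L{i}": 1.0 for i in range(4)}

    def test_zeros_propagate(self):
        assert psm_ratios(self._rec([0, 0, 6])) == {"L0": 0.0, "L1": 0.0, "L2": 3.0}

    def test_all_zero_excluded(self):
        assert psm_ratios(self._rec([0, 0, 0])) == {}

    @given(st.lists(st.floats(0, 1e9), min_size=2, max_size=10).filter(lambda v: sum(v) > 0))
    def test_ratios_have_mean_one(self, values):
        ratios = psm_ratios(self._rec(values))
        assert np.isclose(np.mean(list(ratios.values())), 1.0, rtol=1e-9)


class TestRollup:
    def test_exhaustive_recount_oracle(self, small_collection):
        """Roll-up bookkeeping must equal a brute-force recount over records."""
        quants = {q.accession: q for q in rollup_proteins(small_collection, min_unique_peptides=3)}
        # independent oracle: loop over dataclass records
        unique_peps: dict[str, set] = {}
        n_spectra: dict[str, int] = {}
        signal: dict[str, np.ndarray] = {}
        labels = list(small_collection.design.labels)
        for rec in small_collection.records:
            for acc in rec.protein_accessions:
                n_spectra[acc] = n_spectra.get(acc, 0) + 1
            if rec.is_unique:
                acc = rec.protein_accessions[0]
                unique_peps.setdefault(acc, set()).add(rec.peptide)
                vec = np.array([rec.intensities[l] for l in labels])
                signal[acc] = signal.get(acc, np.zeros(len(labels))) + vec
        assert set(quants) == set(n_spectra)
        for acc, q in quants.items():
            assert q.n_spectra == n_spectra[acc]
            assert q.n_unique_peptides == len(unique_peps.get(acc, set()))
            assert q.quantifiable == (q.n_unique_peptides >= 3)
            expected = signal.get(acc, np.zeros(len(labels)))
            assert np.allclose([q.signal[l] for l in labels], expected)
        oracle_quantifiable = {a for a, peps in unique_peps.items() if len(peps) >= 3}
        assert {a for a, q in quants.items() if q.quantifiable} == oracle_quantifiable

    def test_two_unique_peptides_not_quantifiable(self, small_collection):
        q = {q.accession: q for q in rollup_proteins(small_collection)}["P4"]
        assert q.n_unique_peptides == 2
        assert not q.quantifiable

    def test_protein_ratio_mean_one(self, small_collection):
        sample = small_collection.design.sample_labels
        for q in rollup_proteins(small_collection):
            vals = [q.ratio[l] for l in sample]
            if not np.isnan(vals[0]):
                assert np.isclose(np.mean(vals), 1.0, rtol=1e-9)

    def test_empty_collection(self, design8, small_collection):
        empty = small_collection.table.iloc[0:0]
        coll = type(small_collection)(design=design8, table=empty, provenance={})
        assert rollup_proteins(coll) == []

    def test_ionization_factors_cancel_noise_free(self, design8):
        """In the noise-free limit the protein stage ratio equals the true
        clearance factor exactly: per-peptide efficiencies cancel."""
        params = SyntheticParams(
            n_hcp=20, seed=5, replicate_cv=0.0, blank_mu=-40.0, blank_sigma=0.0,
            frac_shared_peptides=0.0,
        )
        coll, truth = generate_experiment(params, design8)
        quants = rollup_proteins(coll)  # deliberately unnormalized: raw ratios
        hcp = truth.hcp
        for q in quants:
            if q.accession not in hcp.index:
                continue
            src = np.mean([q.signal[l] for l in design8.labels_for_stage("HCCF")])
            dest = np.mean([q.signal[l] for l in design8.labels_for_stage("ProteinA_eluate")])
            true_c = hcp.loc[q.accession, "clearance_HCCF->ProteinA_eluate"]
            assert np.isclose(dest / src, true_c, rtol=1e-6)


class TestComposition:
    def test_fractions_sum_to_one(self, small_collection):
        comp = global_composition(rollup_proteins(small_collection), small_collection.design)
        for mab, hcp in comp.values():
            assert np.isclose(mab + hcp, 1.0)

    def test_only_mab_proteins(self, design8, small_collection):
        mab_only = small_collection.table[
            small_collection.table["proteins"].isin(list(design8.mab_accessions))
        ].reset_index(drop=True)
        coll = type(small_collection)(design=design8, table=mab_only, provenance={})
        comp = global_composition(rollup_proteins(coll), design8)
        assert all(np.isclose(mab, 1.0) for mab, _ in comp.values())

    def test_mab_fraction_increases_when_hcps_clear(self, design8):
        params = SyntheticParams(n_hcp=100, seed=2, frac_retained=0.0)
        coll, _ = generate_experiment(params, design8)
        normed, _ = normalize_collection(coll)
        comp = global_composition(rollup_proteins(normed), design8)
        stage_frac = [
            np.mean([comp[l][0] for l in design8.labels_for_stage(s)])
            for s in ("HCCF", "ProteinA_eluate")
        ]
        assert stage_frac[1] > stage_frac[0]


class TestHcLcSeries:
    def test_reference_stage_exactly_one(self, design8):
        coll, _ = generate_experiment(SyntheticParams(n_hcp=30, seed=11), design8)
        normed, _ = normalize_collection(coll)
        series = hc_lc_series(rollup_proteins(normed), design8)
        assert series["ProteinA_eluate"] == 1.0

    def test_equal_chains_give_unity(self, design8):
        coll, _ = generate_experiment(
            SyntheticParams(n_hcp=30, seed=11, lc_hc_ratio_hccf=1.0, replicate_cv=0.0), design8
        )
        normed, _ = normalize_collection(coll)
        series = hc_lc_series(rollup_proteins(normed), design8)
        assert all(np.isclose(v, 1.0, rtol=1e-6) for v in series.values())

    def test_invariant_to_global_lc_scaling(self, design8):
        coll, _ = generate_experiment(SyntheticParams(n_hcp=30, seed=11), design8)
        normed, _ = normalize_collection(coll)
        quants = rollup_proteins(normed)
        base = hc_lc_series(quants, design8)
        lc_acc = design8.chain_accessions("LC")[0]
        for q in quants:
            if q.accession == lc_acc:
                q.signal = {l: 7.3 * v for l, v in q.signal.items()}
        scaled = hc_lc_series(quants, design8)
        for stage in base:
            assert np.isclose(base[stage], scaled[stage], rtol=1e-9)

    def test_missing_chain_errors(self, design8, small_collection):
        quants = [q for q in rollup_proteins(small_collection) if q.accession != "X000001"]
        with pytest.raises(QuantError, match="X000001"):
            hc_lc_series(quants, design8)
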