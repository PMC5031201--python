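import numpy as np
import pytest

from hcpflux import (
    SyntheticParams,
    call_detection,
    fit_noise,
    generate_experiment,
    global_composition,
    hcp_summary,
    normalize_collection,
    rollup_proteins,
    set_noise_floor,
    three_lists,
    transition_ratios,
)
from hcpflux.flux import BELOW_DETECTION, DECREASED, RETAINED, FluxError


@pytest.fixture
def quantified(small_collection):
    return rollup_proteins(small_collection)


class TestTransitionRatios:
    def test_direct_division(self, quantified, design8):
        records = transition_ratios(quantified, design8)
        by_key = {(r.accession, r.transition): r for r in records}
        for q in quantified:
            if not q.quantifiable:
                continue
            src = np.mean([q.signal[l] for l in design8.labels_for_stage("HCCF")])
            dest = np.mean([q.signal[l] for l in design8.labels_for_stage("ProteinA_eluate")])
            rec = by_key[(q.accession, "HCCF->ProteinA_eluate")]
            assert np.isclose(rec.mean_ratio, dest / src)

    def test_tie_goes_to_retained(self, quantified, design8):
        q = next(q for q in quantified if q.quantifiable)
        q.signal = {l: 4.0 for l in q.signal}
        recs = [r for r in transition_ratios([q], design8)]
        assert all(r.mean_ratio == 1.0 and r.fate == RETAINED for r in recs)

    def test_zero_denominator_is_infinite_retained(self, quantified, design8):
        q = next(q for q in quantified if q.quantifiable)
        hccf = design8.labels_for_stage("HCCF")
        q.signal = {l: (0.0 if l in hccf else 2.0) for l in q.signal}
        rec = next(
            r for r in transition_ratios([q], design8) if r.transition == "HCCF->ProteinA_eluate"
        )
        assert np.isinf(rec.mean_ratio) and rec.fate == RETAINED

    def test_zero_over_zero_below_detection(self, quantified, design8):
        q = next(q for q in quantified if q.quantifiable)
        q.signal = {l: 0.0 for l in q.signal}
        recs = transition_ratios([q], design8)
        assert all(np.isnan(r.mean_ratio) and r.fate == BELOW_DETECTION for r in recs)

    def test_unknown_stage_rejected(self, quantified, design8):
        with pytest.raises(FluxError, match="Nowhere"):
            transition_ratios(quantified, design8, transitions=[("HCCF", "Nowhere")])

    def test_only_quantifiable_classified(self, quantified, design8):
        accs = {r.accession for r in transition_ratios(quantified, design8)}
        assert accs == {q.accession for q in quantified if q.quantifiable}

    def test_classification_accuracy_against_truth(self, design8):
        """Proteins with clearance well away from 1 are classified correctly
        nearly always; the band (0.8, 1.25) is excluded as genuinely hard."""
        correct = total = 0
        for seed in range(10):
            coll, truth = generate_experiment(SyntheticParams(n_hcp=200, seed=seed), design8)
            normed, _ = normalize_collection(coll)
            quants = rollup_proteins(normed)
            est = {(r.accession, r.transition): r for r in transition_ratios(quants, design8)}
            hcp = truth.hcp
            for t in truth.transitions:
                for acc in hcp.index:
                    c = hcp.loc[acc, f"clearance_{t}"]
                    if 0.8 <= c <= 1.25:
                        continue
                    rec = est.get((acc, t))
                    if rec is None:
                        continue
                    total += 1
                    correct += rec.fate == hcp.loc[acc, f"class_{t}"]
        assert total > 3000
        assert correct / total > 0.95

    def test_composability_noise_free(self, design8):
        """ratio(A->C) = ratio(A->B) * ratio(B->C) exactly without noise."""
        params = SyntheticParams(n_hcp=15, seed=4, replicate_cv=0.0, blank_mu=-40.0, blank_sigma=0.0)
        coll, _ = generate_experiment(params, design8)
        quants = [q for q in rollup_proteins(coll) if q.quantifiable]
        pairs = [("HCCF", "ProteinA_eluate"), ("ProteinA_eluate", "CEX_eluate"), ("HCCF", "CEX_eluate")]
        recs = transition_ratios(quants, design8, transitions=pairs)
        by_key = {(r.accession, r.transition): r.mean_ratio for r in recs}
        for q in quants:
            a_b = by_key[(q.accession, "HCCF->ProteinA_eluate")]
            b_c = by_key[(q.accession, "ProteinA_eluate->CEX_eluate")]
            a_c = by_key[(q.accession, "HCCF->CEX_eluate")]
            assert np.isclose(a_b * b_c, a_c, rtol=1e-9)


class TestThreeLists:
    def _setup(self, design6):
        coll, truth = generate_experiment(SyntheticParams(n_hcp=20, seed=8), design6)
        normed, _ = normalize_collection(coll)
        quants = rollup_proteins(normed)
        detections = call_detection(quants, fit_noise(normed), design6)
        flux = transition_ratios(quants, design6, detections=detections)
        return quants, detections, flux

    def test_partition_property(self, design6):
        _, detections, flux = self._setup(design6)
        lists = three_lists(flux, detections)
        for tl in lists.values():
            assert set(tl.retained) | set(tl.decreased) == set(tl.above_detection)
            assert not set(tl.retained) & set(tl.decreased)

    def test_exhaustive_oracle(self, design6):
        """List membership equals a brute-force per-protein recomputation."""
        quants, detections, flux = self._setup(design6)
        lists = three_lists(flux, detections)
        det = {(c.accession, c.stage): c.detectable for c in detections}
        ratio = {(r.accession, r.transition): r.mean_ratio for r in flux}
        for t, tl in lists.items():
            dest = t.split("->", 1)[1]
            above, retained, decreased = [], [], []
            for q in quants:
                if not q.quantifiable or not det.get((q.accession, dest), False):
                    continue
                above.append(q.accession)
                r = ratio[(q.accession, t)]
                (retained if r >= 1 else decreased).append(q.accession)
            assert tl.above_detection == tuple(sorted(above))
            assert tl.retained == tuple(sorted(retained))
            assert tl.decreased == tuple(sorted(decreased))

    def test_nothing_detectable_gives_empty_lists(self, quantified, design8):
        flux = transition_ratios(quantified, design8)
        detections = call_detection(quantified, set_noise_floor(1e12), design8)
        lists = three_lists(flux, detections)
        for tl in lists.values():
            assert tl == ((), (), ())


class TestHcpSummary:
    def test_recount_oracle(self, small_collection, design8):
        quants = rollup_proteins(small_collection)
        comp = global_composition(quants, design8)
        detections = call_detection(quants, set_noise_floor(10.0), design8)
        summary = hcp_summary(quants, comp, design8, detections=detections)
        det = {(c.accession, c.stage): c.detectable for c in detections}
        for stage in design8.occupied_stages:
            labels = design8.labels_for_stage(stage)
            n_id = sum(1 for q in quants if any(q.signal[l] > 0 for l in labels))
            n_det = sum(1 for q in quants if det.get((q.accession, stage), False))
            assert summary.loc[stage, "n_identified"] == n_id
            assert summary.loc[stage, "n_detectable"] == n_det
            assert summary.loc[stage, "n_quantifiable"] <= summary.loc[stage, "n_identified"]

    def test_empty_input(self, design8):
        summary = hcp_summary([], {l: (np.nan, np.nan) for l in design8.labels}, design8)
        assert (summary[["n_identified", "n_quantifiable", "n_detectable"]] == 0).all().all()
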