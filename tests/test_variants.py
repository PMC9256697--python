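import numpy as np
import pytest

from ctc_concord.io_core import (
    MutationKey,
    RunConfig,
    SampleClass,
    SampleMeta,
    ValidationError,
    VariantCall,
)
from ctc_concord import variants
from ctc_concord.variants import (
    CallMatrix,
    CallStatus,
    called_key_sets,
    categorize,
    filter_artifact_kmer,
    filter_cross_patient,
    filter_vaf,
    rescue_status,
    reverse_complement,
)

KMER = "TTAACTGACAGC"


def _call(chrom, pos, ref="A", alt="C", sample="S", depth=50, alt_reads=25,
          called=True):
    return VariantCall(MutationKey(chrom, pos, ref, alt), sample, depth,
                       alt_reads, called)


def _ref_with(seq_center, pad=60, rng=None):
    rng = rng or np.random.default_rng(0)
    flank = "".join(rng.choice(list("ACGT"), pad))
    return flank + seq_center + flank


class TestKmerFilter:
    def test_call_next_to_motif_removed(self, cfg):
        seq = _ref_with(KMER)
        pos = 61  # 1-based position of the motif start
        ref = {"chr1": seq}
        kept, removed = filter_artifact_kmer(
            [_call("chr1", pos, ref=seq[pos - 1], alt="T" if seq[pos - 1] != "T" else "G")],
            ref, cfg)
        assert not kept and len(removed) == 1

    def test_reverse_complement_motif_removed(self, cfg):
        rc = reverse_complement(KMER)
        assert rc == "GCTGTCAGTTAA"
        seq = _ref_with(rc)
        pos = 61
        ref = {"chr1": seq}
        kept, removed = filter_artifact_kmer(
            [_call("chr1", pos, ref=seq[pos - 1],
                   alt="T" if seq[pos - 1] != "T" else "G")], ref, cfg)
        assert not kept and len(removed) == 1

    def test_matches_exhaustive_scan_oracle_on_random_windows(self, cfg):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), 40_000))
        # plant a handful of motifs
        plant = sorted(rng.choice(30_000, size=12, replace=False) + 2_000)
        seq_l = list(seq)
        for s in plant:
            seq_l[s : s + len(KMER)] = KMER
        seq = "".join(seq_l)
        ref = {"chr1": seq}
        rc = reverse_complement(KMER)
        calls = []
        for pos in rng.integers(20, len(seq) - 20, size=400).tolist():
            base = seq[pos - 1]
            alt = "ACGT"[("ACGT".index(base) + 1) % 4]
            calls.append(_call("chr1", int(pos), ref=base, alt=alt))
        kept, removed = filter_artifact_kmer(calls, ref, cfg)
        flank = cfg.artifact_flank
        for c in calls:
            lo = max(0, c.key.pos - 1 - flank)
            window = seq[lo : c.key.pos + flank]
            hit = KMER in window or rc in window
            assert (c in removed) == hit

    def test_position_outside_reference_rejected(self, cfg):
        ref = {"chr1": "ACGT" * 30}
        with pytest.raises(ValidationError, match="outside"):
            filter_artifact_kmer([_call("chr1", 10_000)], ref, cfg)

    def test_idempotent(self, cfg):
        seq = _ref_with(KMER)
        ref = {"chr1": seq}
        calls = [_call("chr1", 61, ref=seq[60], alt="T" if seq[60] != "T" else "G"),
                 _call("chr1", 5, ref=seq[4], alt="T" if seq[4] != "T" else "G")]
        once, _ = filter_artifact_kmer(calls, ref, cfg)
        twice, removed2 = filter_artifact_kmer(once, ref, cfg)
        assert twice == once and not removed2


class TestCrossPatientFilter:
    def test_key_in_two_patients_removed_everywhere(self):
        shared = _call("chr1", 100, sample="A_bulk")
        shared_b = _call("chr1", 100, sample="B_ctc")
        only_a = _call("chr2", 5, sample="A_bulk")
        kept, removed = filter_cross_patient(
            {"A": [shared, only_a], "B": [shared_b]})
        assert kept["A"] == [only_a]
        assert kept["B"] == []
        assert removed["A"] == [shared] and removed["B"] == [shared_b]

    def test_key_in_two_samples_of_same_patient_kept(self):
        c1 = _call("chr1", 100, sample="A_bulk")
        c2 = _call("chr1", 100, sample="A_ctc")
        kept, removed = filter_cross_patient({"A": [c1, c2], "B": []})
        assert kept["A"] == [c1, c2] and not removed["A"]

    def test_single_patient_is_noop(self):
        calls = [_call("chr1", 100)]
        kept, removed = filter_cross_patient({"A": calls})
        assert kept["A"] == calls and removed["A"] == []

    def test_matches_set_intersection_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        patients = {}
        for p in "ABC":
            calls = []
            for _ in range(150):
                pos = int(rng.integers(1, 400))
                calls.append(_call("chr1", pos, sample=f"{p}_s",
                                   called=bool(rng.random() < 0.8)))
            patients[p] = calls
        kept, removed = filter_cross_patient(patients)
        # oracle: brute-force membership count over called keys
        key_patients = {}
        for p, calls in patients.items():
            for c in calls:
                if c.called:
                    key_patients.setdefault(c.key, set()).add(p)
        recurrent = {k for k, ps in key_patients.items() if len(ps) > 1}
        for p, calls in patients.items():
            assert {c.key for c in removed[p]} <= recurrent
            assert all((c.key in recurrent) == (c in removed[p]) for c in calls)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        patients = {
            p: [_call("chr1", int(rng.integers(1, 50)), sample=p)
                for _ in range(30)]
            for p in "AB"
        }
        once, _ = filter_cross_patient(patients)
        twice, removed2 = filter_cross_patient(once)
        assert twice == once and not any(removed2.values())


class TestVafFilter:
    def test_low_vaf_absent_from_bulk_removed(self, cfg):
        c = _call("chr1", 10, depth=100, alt_reads=15)  # vaf 0.15
        kept, removed = filter_vaf([c], set(), cfg)
        assert removed == [c]

    def test_low_vaf_rescued_by_bulk(self, cfg):
        c = _call("chr1", 10, depth=100, alt_reads=15)
        kept, removed = filter_vaf([c], {c.key}, cfg)
        assert kept == [c]

    def test_vaf_exactly_at_floor_kept(self, cfg):
        c = _call("chr1", 10, depth=100, alt_reads=20)  # exactly 0.20
        kept, removed = filter_vaf([c], set(), cfg)
        assert kept == [c]

    def test_uncalled_support_rows_pass_through(self, cfg):
        c = _call("chr1", 10, depth=100, alt_reads=1, called=False)
        kept, removed = filter_vaf([c], set(), cfg)
        assert kept == [c]

    def test_missing_bulk_is_an_error(self, cfg):
        with pytest.raises(ValidationError, match="bulk"):
            filter_vaf([_call("chr1", 10)], None, cfg)


class TestFilterAlgebra:
    def test_filters_commute(self, cfg):
        """The three filters touch disjoint predicates, so order is irrelevant."""
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 5_000))
        seq = seq[:1000] + KMER + seq[1000 + len(KMER):]
        ref = {"chr1": seq}
        patients = {}
        for p in "AB":
            calls = []
            for _ in range(120):
                pos = int(rng.integers(30, len(seq) - 30))
                base = seq[pos - 1]
                alt = "ACGT"[("ACGT".index(base) + 1) % 4]
                depth = int(rng.integers(10, 80))
                calls.append(VariantCall(
                    MutationKey("chr1", pos, base, alt), f"{p}_s", depth,
                    int(rng.integers(0, depth + 1)), True))
            patients[p] = calls
        bulk_keys = {patients["A"][0].key, patients["A"][1].key}

        def kmer_then_vaf(calls):
            kept, _ = filter_artifact_kmer(calls, ref, cfg)
            kept, _ = filter_vaf(kept, bulk_keys, cfg)
            return kept

        def vaf_then_kmer(calls):
            kept, _ = filter_vaf(calls, bulk_keys, cfg)
            kept, _ = filter_artifact_kmer(kept, ref, cfg)
            return kept

        for calls in patients.values():
            assert kmer_then_vaf(calls) == vaf_then_kmer(calls)

        # cross-patient commutes with the per-sample VAF filter when its
        # recurrence predicate is fixed on the raw callsets
        kept_cp, _ = filter_cross_patient(patients)
        a = {p: filter_vaf(kept_cp[p], bulk_keys, cfg)[0] for p in patients}
        vaf_first = {p: filter_vaf(patients[p], bulk_keys, cfg)[0]
                     for p in patients}
        b, _ = filter_cross_patient(vaf_first, presence_from=patients)
        assert a == b


def _metas(pid="P", n_ctc=3):
    metas = [
        SampleMeta(f"{pid}_B", pid, SampleClass.BULK_TUMOR),
        SampleMeta(f"{pid}_G", pid, SampleClass.GERMLINE_BLOOD),
        SampleMeta(f"{pid}_W", pid, SampleClass.WBC_POOL),
    ]
    metas += [SampleMeta(f"{pid}_C{i}", pid, SampleClass.CTC_SINGLE)
              for i in range(n_ctc)]
    return metas


def _key(pos):
    return MutationKey("chr1", pos, "A", "C")


class TestCategorize:
    def test_bulk_and_ctc_overlap_is_ctc_bulk(self):
        metas = _metas()
        sets = {"P_B": {_key(1)}, "P_G": set(), "P_W": set(),
                "P_C0": {_key(1)}, "P_C1": {_key(1)}, "P_C2": {_key(1)}}
        cats = categorize(sets, metas)
        assert cats.labels[_key(1)] == "ctc_bulk"

    def test_two_ctc_samples_without_bulk_is_shared(self):
        metas = _metas()
        sets = {"P_B": set(), "P_G": set(), "P_W": set(),
                "P_C0": {_key(1)}, "P_C1": {_key(1)}, "P_C2": set()}
        cats = categorize(sets, metas)
        assert cats.labels[_key(1)] == "ctc_shared"

    def test_single_ctc_sample_is_private(self):
        metas = _metas()
        sets = {"P_B": set(), "P_G": set(), "P_W": set(),
                "P_C0": {_key(1)}, "P_C1": set(), "P_C2": set()}
        cats = categorize(sets, metas)
        assert cats.labels[_key(1)] == "ctc_private"

    def test_wbc_membership_excludes(self):
        metas = _metas()
        sets = {"P_B": {_key(1)}, "P_G": set(), "P_W": {_key(1)},
                "P_C0": {_key(1)}, "P_C1": set(), "P_C2": set()}
        cats = categorize(sets, metas)
        assert cats.labels[_key(1)] == "excluded"

    def test_matches_brute_force_oracle_and_partition(self):
        rng = np.random.default_rng(11)
        metas = _metas(n_ctc=4)
        for _ in range(30):
            sets = {
                m.sample_id: {_key(int(p)) for p in rng.integers(1, 60, 25)}
                for m in metas
            }
            cats = categorize(sets, metas)
            oracle = _oracle_categorize(sets, metas)
            assert cats.labels == oracle
            ctc = [v for v in cats.labels.values()
                   if v.startswith("ctc_")]
            n_ctc_muts = len(_ctc_set(sets, metas))
            assert len(ctc) == n_ctc_muts


def _ctc_set(sets, metas):
    wbc = sets[next(m.sample_id for m in metas
                    if m.sample_class == SampleClass.WBC_POOL)]
    union = set()
    for m in metas:
        if m.sample_class.is_ctc:
            union |= sets[m.sample_id]
    return union - wbc


def _oracle_categorize(sets, metas):
    bulk_id = next(m.sample_id for m in metas
                   if m.sample_class == SampleClass.BULK_TUMOR)
    germ_id = next(m.sample_id for m in metas
                   if m.sample_class == SampleClass.GERMLINE_BLOOD)
    wbc_id = next(m.sample_id for m in metas
                  if m.sample_class == SampleClass.WBC_POOL)
    ctc_ids = [m.sample_id for m in metas if m.sample_class.is_ctc]
    bulk = sets[bulk_id] - sets[germ_id] - sets[wbc_id]
    ctc = _ctc_set(sets, metas)
    labels = {}
    universe = set().union(*sets.values())
    for k in universe:
        if k in ctc:
            if k in bulk:
                labels[k] = "ctc_bulk"
            else:
                n = sum(k in sets[s] for s in ctc_ids)
                labels[k] = "ctc_shared" if n >= 2 else "ctc_private"
        elif k in bulk:
            labels[k] = "bulk_only"
        else:
            labels[k] = "excluded"
    return labels


class TestRescueStatus:
    @pytest.mark.parametrize(
        "depth,alt,called,expected",
        [
            (30, 2, False, CallStatus.SUPPORTED),   # manually recoverable
            (0, 0, False, CallStatus.NO_COVERAGE),  # no read covering the site
            (3, 5, True, CallStatus.CALLED),        # caller flag wins
            (12, 0, False, CallStatus.COVERED_REF),
        ],
    )
    def test_status_rules(self, depth, alt, called, expected):
        assert rescue_status(depth, alt, called) == expected

    def test_matrix_status_consistent_with_counts(self):
        calls = {
            "S1": [_call("chr1", 1, depth=10, alt_reads=0, called=False),
                   _call("chr1", 2, depth=9, alt_reads=2, called=False)],
            "S2": [_call("chr1", 1, depth=20, alt_reads=10, called=True)],
        }
        m = CallMatrix.from_calls("P", calls)
        sf = m.status_frame()
        assert sf.at[_key(1), "S1"] == "covered_ref"
        assert sf.at[_key(2), "S1"] == "supported"
        assert sf.at[_key(1), "S2"] == "called"
        assert sf.at[_key(2), "S2"] == "no_coverage"
        for key in m.mutations:
            for sid in m.samples:
                assert m.status(key, sid).value == sf.at[key, sid]
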