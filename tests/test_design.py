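import numpy as np
import pytest

from corepromoter.design import (
    CORE_LEN,
    DEFAULT_LAYOUT,
    DesignError,
    MutationSpec,
    TSS_INDEX,
    annotate,
    apply_mutation,
    assemble,
    enumerate_combinatorial,
    pwm_consensus,
    resolve_clone,
    sanitize_utr,
    validate,
)
from corepromoter.motifs import scan


class TestBlockLayout:
    def test_core_blocks_tile_exactly(self):
        lengths = [hi - lo for lo, hi in DEFAULT_LAYOUT.core_blocks.values()]
        assert lengths == [46, 25, 18, 42]
        assert sum(lengths) == CORE_LEN

    def test_split_join_round_trip(self, promoters):
        core = promoters["promA"].core_sequence
        blocks = DEFAULT_LAYOUT.split_core(core)
        assert DEFAULT_LAYOUT.join_core(blocks) == core

    def test_split_rejects_wrong_length(self):
        with pytest.raises(DesignError):
            DEFAULT_LAYOUT.split_core("ACGT")


class TestAnnotate:
    def test_planted_motifs_recovered_exactly(self, motif_set, promoters):
        p = promoters["promA"]
        record = annotate(p.id, p.core_sequence, motif_set)
        assert {(a.name, a.start) for a in record.annotations} == {
            ("TATA-Box", -30), ("INR", -2),
        }

    def test_motif_less_background_empty(self, motif_set, promoters):
        record = annotate("m", promoters["motifless"].core_sequence, motif_set)
        assert record.annotations == []

    def test_idempotent(self, motif_set, promoters):
        p = promoters["promB"]
        once = annotate(p.id, p.core_sequence, motif_set)
        twice = annotate(p.id, once.core_sequence, motif_set)
        assert [(a.name, a.start) for a in once.annotations] == [
            (a.name, a.start) for a in twice.annotations
        ]


class TestKnockouts:
    def test_knockout_random_clean_rescan(self, motif_set, promoters):
        p = promoters["promA"]
        spec = MutationSpec("knockout_random", ["INR"], seed=1)
        (c,) = apply_mutation(p, spec, motif_set)
        assert len(c.core_sequence) == CORE_LEN
        # brute-force oracle: replaced window plus context is hit-free
        a = p.annotation("INR")
        max_len = max(len(m) for m in motif_set.values())
        lo = max(0, a.index - max_len + 1)
        hi = min(CORE_LEN, a.index + len(motif_set["INR"]) + max_len - 1)
        for pwm in motif_set.values():
            assert not scan(pwm, c.core_sequence[lo:hi])

    def test_knockout_preserves_other_motifs(self, motif_set, promoters):
        p = promoters["promA"]
        (c,) = apply_mutation(p, MutationSpec("knockout_random", ["INR"], seed=2), motif_set)
        record = annotate(c.id, c.core_sequence, motif_set)
        assert ("TATA-Box", -30) in {(a.name, a.start) for a in record.annotations}

    def test_knockout_background_splices_same_coordinates(self, motif_set, promoters):
        p = promoters["promA"]
        bg = promoters["motifless"].core_sequence
        spec = MutationSpec("knockout_background", ["INR"], {"background_core": bg})
        (c,) = apply_mutation(p, spec, motif_set)
        a = p.annotation("INR")
        L = len(motif_set["INR"])
        assert c.core_sequence[a.index : a.index + L] == bg[a.index : a.index + L]

    def test_knockout_pair(self, motif_set, promoters):
        p = promoters["promA"]
        spec = MutationSpec("knockout_pair", ["TATA-Box", "INR"], seed=3)
        (c,) = apply_mutation(p, spec, motif_set)
        assert annotate(c.id, c.core_sequence, motif_set).annotations == []

    def test_knockout_all(self, motif_set, promoters):
        p = promoters["promB"]
        (c,) = apply_mutation(p, MutationSpec("knockout_all", seed=4), motif_set)
        assert annotate(c.id, c.core_sequence, motif_set).annotations == []

    def test_seed_reproducible(self, motif_set, promoters):
        p = promoters["promA"]
        a = apply_mutation(p, MutationSpec("knockout_random", ["INR"], seed=9), motif_set)
        b = apply_mutation(p, MutationSpec("knockout_random", ["INR"], seed=9), motif_set)
        assert a[0].core_sequence == b[0].core_sequence

    def test_missing_target_rejected(self, motif_set, promoters):
        with pytest.raises(DesignError):
            apply_mutation(promoters["motifless"],
                           MutationSpec("knockout_random", ["INR"], seed=1), motif_set)


class TestConsensus:
    def test_consensus_replace_at_native_position(self, motif_set, promoters):
        p = promoters["promA"]
        (c,) = apply_mutation(p, MutationSpec("consensus_replace", ["INR"]), motif_set)
        a = p.annotation("INR")
        L = len(motif_set["INR"])
        assert c.core_sequence[a.index : a.index + L] == pwm_consensus(motif_set["INR"])

    def test_consensus_insert_into_motifless(self, motif_set, promoters):
        p = promoters["motifless"]
        spec = MutationSpec("consensus_insert", ["INR"], {"insert_position": -2})
        (c,) = apply_mutation(p, spec, motif_set)
        assert len(c.core_sequence) == CORE_LEN
        record = annotate(c.id, c.core_sequence, motif_set)
        assert ("INR", -2) in {(a.name, a.start) for a in record.annotations}

    def test_insert_outside_core_rejected(self, motif_set, promoters):
        spec = MutationSpec("consensus_insert", ["INR"], {"insert_position": 49})
        with pytest.raises(DesignError):
            apply_mutation(promoters["motifless"], spec, motif_set)


class TestStrengthSeries:
    def test_scores_fall_in_requested_bins(self, motif_set, promoters):
        p = promoters["promA"]
        pwm = motif_set["INR"]
        # bins bracketing attainable scores: sub-threshold, single-mutant,
        # and consensus strength
        bins = [(pwm.min_score, 5.0), (7.0, 9.0), (12.0, pwm.max_score + 1e-9)]
        spec = MutationSpec("strength_series", ["INR"], {"bins": bins}, seed=5)
        out = apply_mutation(p, spec, motif_set)
        assert len(out) == 3
        a = p.annotation("INR")
        from corepromoter.motifs import score_window
        for c, (lo, hi) in zip(out, bins):
            s = score_window(pwm, c.core_sequence, a.index)
            assert lo <= s < hi


class TestPointMutation:
    def test_three_l_variants_plus_consensus(self, motif_set, promoters):
        p = promoters["promA"]
        out = apply_mutation(p, MutationSpec("point_mutation", ["INR"]), motif_set)
        L = len(motif_set["INR"])
        assert len(out) == 3 * L + 1  # consensus reference + 3L single mutants
        cons = pwm_consensus(motif_set["INR"])
        a = p.annotation("INR")
        seen = {c.core_sequence[a.index : a.index + L] for c in out}
        assert cons in seen
        assert len(seen) == 3 * L + 1
        for variant in seen:
            assert sum(x != y for x, y in zip(variant, cons)) <= 1


class TestSubstitute:
    def test_tss_anchor_alignment(self, motif_set, promoters):
        # INR anchor is its 3rd base; substitute INR with itself must land
        # at the native position
        p = promoters["promA"]
        spec = MutationSpec("substitute", ["INR", "INR"], seed=6)
        (c,) = apply_mutation(p, spec, motif_set)
        a = p.annotation("INR")
        L = len(motif_set["INR"])
        assert c.core_sequence[a.index : a.index + L] == pwm_consensus(motif_set["INR"])

    def test_start_alignment_for_non_anchored(self, motif_set, promoters):
        p = promoters["promA"]
        spec = MutationSpec("substitute", ["TATA-Box", "DRE"], seed=7)
        (c,) = apply_mutation(p, spec, motif_set)
        a = p.annotation("TATA-Box")
        L = len(motif_set["DRE"])
        assert c.core_sequence[a.index : a.index + L] == pwm_consensus(motif_set["DRE"])


class TestShifts:
    def test_shift_zero_is_identity(self, motif_set, promoters):
        p = promoters["promA"]
        spec = MutationSpec("shift_motif", ["INR"], {"delta": 0})
        (c,) = apply_mutation(p, spec, motif_set)
        assert c.core_sequence == p.core_sequence

    @pytest.mark.parametrize("delta", [-5, -1, 1, 3, 10])
    def test_shift_relocates_motif(self, motif_set, promoters, delta):
        p = promoters["promA"]
        spec = MutationSpec("shift_motif", ["INR"], {"delta": delta})
        (c,) = apply_mutation(p, spec, motif_set)
        a = p.annotation("INR")
        L = len(motif_set["INR"])
        motif_seq = p.core_sequence[a.index : a.index + L]
        assert c.core_sequence[a.index + delta : a.index + delta + L] == motif_seq
        assert len(c.core_sequence) == CORE_LEN
        assert sorted(c.core_sequence) == sorted(p.core_sequence)  # pure rearrangement

    def test_shift_out_of_core_rejected(self, motif_set, promoters):
        spec = MutationSpec("shift_motif", ["INR"], {"delta": 60})
        with pytest.raises(DesignError):
            apply_mutation(promoters["promA"], spec, motif_set)

    def test_shift_all_motifs(self, motif_set, promoters):
        p = promoters["promA"]
        spec = MutationSpec("shift_all_motifs", [], {"delta": 3})
        (c,) = apply_mutation(p, spec, motif_set)
        for a in p.annotations:
            L = len(motif_set[a.name])
            motif_seq = p.core_sequence[a.index : a.index + L]
            assert c.core_sequence[a.index + 3 : a.index + 3 + L] == motif_seq

    def test_shift_context_keeps_motifs_in_place(self, motif_set, promoters):
        p = promoters["promA"]
        spec = MutationSpec("shift_context", [], {"delta": 5})
        (c,) = apply_mutation(p, spec, motif_set)
        for a in p.annotations:
            L = len(motif_set[a.name])
            assert (c.core_sequence[a.index : a.index + L]
                    == p.core_sequence[a.index : a.index + L])
        assert c.core_sequence != p.core_sequence


class TestContextExchange:
    def test_donor_motifs_at_native_positions(self, motif_set, promoters):
        host, donor = promoters["promA"], promoters["promB"]
        spec = MutationSpec("context_exchange", [], {"donor": donor}, seed=8)
        (c,) = apply_mutation(host, spec, motif_set)
        for a in donor.annotations:
            L = len(motif_set[a.name])
            assert (c.core_sequence[a.index : a.index + L]
                    == donor.core_sequence[a.index : a.index + L])


class TestCombinatorial:
    def test_inter_block_pool_product_480(self, rng):
        import itertools
        def mk(n, length):
            return [(f"v{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, size=length)))
                    for i in range(n)]
        pools = {"block3": mk(4, 46), "block4": mk(5, 25),
                 "block5": mk(4, 18), "block6": mk(6, 42)}
        out = enumerate_combinatorial(mode="inter_block", pools=pools)
        assert len(out) == 4 * 5 * 4 * 6 == 480
        assert all(len(c.core_sequence) == CORE_LEN for c in out)

    def test_inter_block_empty_pool_rejected(self):
        with pytest.raises(DesignError):
            enumerate_combinatorial(mode="inter_block",
                                    pools={"block3": [], "block4": [("a", "A" * 25)],
                                           "block5": [("a", "A" * 18)],
                                           "block6": [("a", "A" * 42)]})

    def test_intra_all_wild_type_single_construct(self, motif_set, promoters):
        p = promoters["promA"]
        pools = {m: [{"label": "wt"}] for m in ("INR", "TATA-Box")}
        out = enumerate_combinatorial(mode="intra", pools=pools, promoter=p,
                                      pwm_set=motif_set)
        assert len(out) == 1
        assert out[0].core_sequence == p.core_sequence
        assert out[0].features == []

    def test_intra_sampling_deterministic(self, motif_set, promoters):
        p = promoters["promA"]
        pools = {
            "INR": [{"label": "wt"}, {"label": "shift+1", "shift": 1},
                    {"label": "shift-1", "shift": -1}],
            "TATA-Box": [{"label": "wt"}, {"label": "cons",
                                           "seq": pwm_consensus(motif_set["TATA-Box"])}],
        }
        a = enumerate_combinatorial(mode="intra", pools=pools, promoter=p,
                                    pwm_set=motif_set, sample=4, seed=3)
        b = enumerate_combinatorial(mode="intra", pools=pools, promoter=p,
                                    pwm_set=motif_set, sample=4, seed=3)
        assert [c.core_sequence for c in a] == [c.core_sequence for c in b]
        assert len(a) == 4


class TestAssemble:
    def test_with_block7_is_703(self, rng):
        seq = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        full = assemble(seq(239), seq(73), seq(131), seq(240))
        assert len(full) == 703

    def test_without_block7_is_459(self, rng):
        seq = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        assert len(assemble(seq(239), seq(73), seq(131))) == 459

    def test_coordinate_round_trip(self, rng):
        seq = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        b1, b2, core, b7 = seq(239), seq(73), seq(131), seq(240)
        full = assemble(b1, b2, core, b7)
        assert full[4 : 4 + 239] == b1
        assert full[4 + 239 + 4 : 4 + 239 + 4 + 73] == b2
        start = 4 + 239 + 4 + 73 + 4
        assert full[start : start + 131] == core
        assert full[start + 131 + 4 : start + 131 + 4 + 240] == b7

    def test_wrong_block_length_names_block(self):
        with pytest.raises(DesignError, match="block2"):
            assemble("A" * 239, "A" * 70, "A" * 131)


class TestSanitizeUtr:
    def test_single_downstream_atg(self):
        assert sanitize_utr("GGCCATGCC", 2) == "GGCCTAGCC"

    def test_no_downstream_atg_unchanged(self):
        assert sanitize_utr("ATGCCCGGG", 3) == "ATGCCCGGG"

    def test_tandem_atg(self):
        assert sanitize_utr("CCATGATG", 2) == "CCTAGTAG"

    def test_upstream_untouched(self):
        assert sanitize_utr("ATGATG", 6) == "ATGATG"

    def test_bad_offset(self):
        with pytest.raises(DesignError):
            sanitize_utr("ACGT", 9)


class TestValidate:
    def test_identity_construct_clean(self, motif_set, promoters):
        p = promoters["promA"]
        spec = MutationSpec("shift_motif", ["INR"], {"delta": 0})
        (c,) = apply_mutation(p, spec, motif_set)
        report = validate(c, p, motif_set)
        assert not report.dirty
        assert not report.intended_losses and not report.intended_gains

    def test_clean_knockout_reports_intended_loss_only(self, motif_set, promoters):
        p = promoters["promA"]
        (c,) = apply_mutation(p, MutationSpec("knockout_random", ["INR"], seed=11), motif_set)
        report = validate(c, p, motif_set)
        assert not report.dirty
        assert [a.name for a in report.intended_losses] == ["INR"]

    def test_planted_accidental_gain_is_dirty(self, motif_set, promoters):
        p = promoters["promA"]
        (c,) = apply_mutation(p, MutationSpec("knockout_random", ["INR"], seed=12), motif_set)
        # plant a TATA consensus inside its enriched region (-45..-15),
        # upstream of the native site, to simulate a side effect
        tainted = c.core_sequence[:40] + pwm_consensus(motif_set["TATA-Box"]) + c.core_sequence[48:]
        c2 = type(c)(c.id, tainted, c.parent_id, c.spec_chain, c.features, c.intended_motifs)
        report = validate(c2, p, motif_set)
        assert report.dirty
        assert "TATA-Box" in {a.name for a in report.unintended_gains}


class TestResolveClone:
    def test_three_fold_enrichment_accepted(self, promoters):
        lib = {pid: p.core_sequence for pid, p in promoters.items()}
        counts = {lib["promA"]: 60, lib["promB"]: 20}
        cid, identity = resolve_clone(counts, lib)
        assert cid == "promA" and identity == 1.0

    def test_just_below_three_fold_rejected(self, promoters):
        lib = {pid: p.core_sequence for pid, p in promoters.items()}
        counts = {lib["promA"]: 59, lib["promB"]: 20}
        assert resolve_clone(counts, lib) == (None, "ambiguous")

    def test_single_candidate_always_accepted(self, promoters):
        lib = {pid: p.core_sequence for pid, p in promoters.items()}
        cid, identity = resolve_clone({lib["promB"]: 5}, lib)
        assert cid == "promB" and identity == 1.0

    def test_near_match_identity(self, promoters):
        lib = {pid: p.core_sequence for pid, p in promoters.items()}
        mutated = "T" + lib["promA"][1:]
        if mutated == lib["promA"]:
            mutated = "A" + lib["promA"][1:]
        cid, identity = resolve_clone({mutated: 10}, lib)
        assert cid == "promA"
        assert 0.95 <= identity < 1.0

    def test_garbage_rejected_as_defective(self, promoters):
        lib = {pid: p.core_sequence for pid, p in promoters.items()}
        assert resolve_clone({"ACGT" * 33: 10}, lib)[1] == "defective"

    def test_empty_counts_rejected(self, promoters):
        with pytest.raises(DesignError):
            resolve_clone({}, {})
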