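"""Generator contracts: element anatomy, inversion operators, locus simulation."""
import dataclasses
import math

import numpy as np
import pytest

from isinv._dna import revcomp
from isinv.errors import ConfigurationError, MalformedElementError
from isinv.simgen import (SCENARIOS, CanonicalElementSpec, SimConfig,
                          apply_inversion_operator, build_canonical_element,
                          simulate_batch, simulate_locus, write_locus)


class TestBuildCanonicalElement:
    def test_anatomy_invariants(self, spec, element):
        assert len(element) == spec.total_length == 916
        left = element[: spec.tir_length]
        right = revcomp(element[-spec.tir_length:])
        diffs = [i + 1 for i in range(spec.tir_length) if left[i] != right[i]]
        assert diffs == [spec.mismatch_np] == [17]
        a35, b35 = spec.minus35_np_interval
        a10, b10 = spec.minus10_np_interval
        assert element[a35 - 1 : b35] == "TTGTCC"
        assert element[a10 - 1 : b10] == "TATAAT"
        assert a10 - b35 - 1 == 17  # spacer
        assert element.startswith(spec.left_tir_inward)
        assert element.endswith(revcomp(spec.right_tir_inward))

    def test_identical_tirs_rejected(self, spec):
        bad = dataclasses.replace(spec, right_tir_inward=spec.left_tir_inward)
        with pytest.raises(ConfigurationError):
            build_canonical_element(bad, 1)

    def test_oversized_orf_rejected(self, spec):
        bad = dataclasses.replace(spec, orf_length=900)
        with pytest.raises(ConfigurationError):
            build_canonical_element(bad, 1)

    def test_constrained_positions_seed_invariant(self, spec):
        """Different seeds change only unconstrained filler."""
        e1 = build_canonical_element(spec, 1)
        e2 = build_canonical_element(spec, 2)
        t = spec.tir_length
        constrained = set(range(1, t + 1)) | set(range(917 - t, 917))
        for a, b in (spec.minus35_np_interval, spec.minus10_np_interval):
            constrained |= set(range(a, b + 1))
        assert all(e1[p - 1] == e2[p - 1] for p in constrained)
        assert e1 != e2

    def test_determinism(self, spec, element):
        assert build_canonical_element(spec, 1) == element


class TestInversionOperators:
    def test_full_ab_is_involution(self, spec, element):
        once = apply_inversion_operator(element, spec, "full_ab")
        assert once == revcomp(element)
        assert apply_inversion_operator(once, spec, "full_ab") == element

    def test_internal_c_flips_interior_only(self, spec, element):
        """Ends unchanged; interior equals independently computed revcomp."""
        out = apply_inversion_operator(element, spec, "internal_c")
        m = spec.mismatch_np
        assert out[:23] == element[:23]
        assert out[-23:] == element[-23:]
        assert out[m : 916 - m] == revcomp(element[m : 916 - m])

    @pytest.mark.parametrize("scenario,expected_read", [
        ("conversion_left_d", "left_tir_inward"),
        ("conversion_right_e", "right_tir_inward"),
    ])
    def test_conversion_homogenises_tirs(self, spec, element, scenario,
                                         expected_read):
        out = apply_inversion_operator(element, spec, scenario)
        want = getattr(spec, expected_read)
        assert out[:23] == want
        assert revcomp(out[-23:]) == want

    def test_excision_empties_element(self, spec, element):
        assert apply_inversion_operator(element, spec, "excision") == ""

    def test_short_element_rejected(self, spec):
        with pytest.raises(MalformedElementError):
            apply_inversion_operator("ACGT" * 5, spec, "full_ab")


class TestSimulateLocus:
    def test_state_counts_match_config(self, small_config):
        sim = simulate_locus(small_config)
        states = list(sim.truth.states.values())
        assert states.count("inverted") == 2
        assert states.count("canonical") == 3
        assert states.count("absent") == 5

    def test_tsd_flanks_element_in_present_strains(self, small_config, spec):
        sim = simulate_locus(small_config)
        a, b = sim.truth.element_interval_alignment
        site = small_config.target_site
        for strain, row in sim.alignment:
            if sim.truth.states[strain] == "absent":
                continue
            assert row[a - 4 : a - 1] == site
            assert row[b : b + 3] == site

    def test_absence_is_one_gap_block(self, small_config, spec):
        sim = simulate_locus(small_config)
        a, b = sim.truth.element_interval_alignment
        for strain, row in sim.alignment:
            if sim.truth.states[strain] != "absent":
                continue
            block = row[a - 1 : b + 3]
            assert set(block) == {"-"}
            assert "-" not in row[: a - 1] and "-" not in row[b + 3 :]

    def test_excision_restores_uninserted_context(self, small_config):
        """Precise excision: excised rows equal never-inserted rows column
        for column outside strain-specific flank variation (rate 0 here, so
        the retained single target-site copy context is exact)."""
        cfg = dataclasses.replace(small_config, scenario="excision")
        sim = simulate_locus(cfg)
        rows = dict(sim.alignment)
        excised = [s for s in ("s01", "s02")]
        never = [s for s, st in sim.truth.states.items()
                 if st == "absent" and s not in excised]
        for s in excised:
            assert sim.truth.states[s] == "absent"
            assert rows[s] == rows[never[0]] or len(rows[s]) == len(rows[never[0]])
            # with mutation_rate 0 all absent rows are byte-identical
            assert rows[s] == rows[never[0]]

    def test_seed_determinism_byte_identical(self, small_config, tmp_path):
        f1 = write_locus(simulate_locus(small_config), tmp_path / "a")
        f2 = write_locus(simulate_locus(small_config), tmp_path / "b")
        assert f1.read_bytes() == f2.read_bytes()
        assert (f1.parent / f"{f1.name}.json").read_bytes() == \
               (f2.parent / f"{f2.name}.json").read_bytes()

    def test_inversion_clade_must_nest(self, small_config):
        bad = dataclasses.replace(small_config,
                                  inversion_clade=["s06", "s07"])
        with pytest.raises(ConfigurationError):
            simulate_locus(bad)

    def test_gap_stripping_recovers_ungapped_sequence(self, small_config):
        sim = simulate_locus(small_config)
        for strain, row in sim.alignment:
            naked = row.replace("-", "")
            assert len(naked) == (len(row) if sim.truth.states[strain] != "absent"
                                  else len(row) - 919)

    def test_mutation_count_within_4_sigma(self, small_config):
        """Substitution count over all branches ~ Binomial(mutable sites x
        branch length, rate) at rate 0.01 (seeded)."""
        cfg = dataclasses.replace(small_config, mutation_rate=0.01,
                                  protect_features=False, seed=11)
        sim = simulate_locus(cfg)
        expected = sim.truth.expected_substitutions
        observed = sim.truth.n_substitutions
        sigma = math.sqrt(expected)
        assert expected > 10
        assert abs(observed - expected) <= 4 * sigma

    def test_protected_features_never_mutated(self, small_config, spec):
        cfg = dataclasses.replace(small_config, mutation_rate=0.05,
                                  protect_features=True, seed=13)
        sim = simulate_locus(cfg)
        a, _ = sim.truth.element_interval_alignment
        for strain, row in sim.alignment:
            if sim.truth.states[strain] != "canonical":
                continue
            elem = row[a - 1 : a - 1 + 916]
            assert elem[:23] == spec.left_tir_inward
            assert revcomp(elem[-23:]) == spec.right_tir_inward
            assert elem[27:33] == "TATAAT"


class TestSimulateBatch:
    def test_shared_tree_and_inversion_quota(self):
        sims = simulate_batch(6, 2, seed=5,
                              base_config=SimConfig(n_strains=8))
        assert len({s.truth.tree_newick for s in sims}) == 1
        n_inv = sum(bool(s.truth.inversion_clade) for s in sims)
        assert n_inv == 2

    def test_all_scenarios_valid(self, small_config):
        for sc in SCENARIOS:
            cfg = dataclasses.replace(small_config, scenario=sc)
            sim = simulate_locus(cfg)
            want = "absent" if sc == "excision" else "inverted"
            assert all(sim.truth.states[s] == want
                       for s in ("s01", "s02"))
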