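"""Read-species matrix construction, EM convergence, and hard assignment.

The {A},{A},{B},{A,B} instance has a closed-form fixed point: with a
the abundance of A, the ambiguous read splits a:(1-a), so
a = (2 + a/(a + (1-a)))... solving the one-dimensional fixed-point
equation a = (2 + a) / 4 gives a = 2/3 (verified independently below by
iterating the printed update equations).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markerprof.em import (
    EMState,
    aggregate_profile,
    build_read_species_matrix,
    em_iterate,
    hard_assign,
    observed_log_likelihood,
)
from markerprof.model import NucleotideAlignment, TaxLineage


def aln(read, species, AS=1000, MS=1000, ID=0.99, ref=None):
    return NucleotideAlignment(
        read_id=read, ref_id=ref or f"{species}|w0", species=species,
        AS=AS, MS=MS, ID=ID,
    )


def matrix_from_memberships(memberships):
    """Build a matrix where read i validly maps to the listed species."""
    alignments = []
    for i, species_list in enumerate(memberships):
        for sp in species_list:
            alignments.append(aln(f"r{i}", sp))
    return build_read_species_matrix(alignments)


def reference_em(x, tol=1e-5, max_iter=100):
    """Direct transcription of the two update equations (oracle)."""
    n, k = x.shape
    theta = np.full(k, 1 / k)
    for _ in range(max_iter):
        z = x * theta
        z = z / z.sum(axis=1, keepdims=True)
        new = z.sum(axis=0) / n
        if np.abs(new - theta).sum() < tol:
            return new
        theta = new
    return theta


class TestMatrix:
    def test_single_alignment_single_one(self):
        m = build_read_species_matrix([aln("r1", "A")])
        assert m.x.tolist() == [[True]]
        assert m.species == ["A"]

    def test_near_tied_id_admits_second_species(self):
        # B fails AS/MS ratio (990 not > 990) but ID 0.9895 > 0.999*0.99
        m = build_read_species_matrix([
            aln("r1", "A", AS=100, MS=100, ID=0.990),
            aln("r1", "B", AS=98, MS=98, ID=0.9895),
        ])
        assert m.x[0].tolist() == [True, True]

    def test_all_conditions_fail_excludes_species(self):
        m = build_read_species_matrix([
            aln("r1", "A", AS=100, MS=100, ID=0.99),
            aln("r1", "B", AS=90, MS=90, ID=0.95),
        ])
        assert m.species == ["A"]

    def test_best_alignment_per_pair_retained(self):
        m = build_read_species_matrix([
            aln("r1", "A", AS=900, MS=900, ID=0.95),
            aln("r1", "A", AS=1000, MS=1000, ID=0.99),
        ])
        assert m.AS[0, 0] == 1000

    def test_empty_input(self):
        m = build_read_species_matrix([])
        assert m.n == 0 and m.k == 0


class TestEM:
    def test_unique_reads_give_empirical_proportions(self):
        m = matrix_from_memberships([["A"], ["A"], ["A"], ["B"]])
        state = em_iterate(m)
        np.testing.assert_allclose(
            state.theta, [0.75, 0.25], atol=1e-12
        )

    def test_symmetric_instance(self):
        m = matrix_from_memberships([["A"], ["B"], ["A", "B"]])
        state = em_iterate(m)
        np.testing.assert_allclose(state.theta, [0.5, 0.5], atol=1e-6)

    def test_fixed_point_two_thirds(self):
        """{A},{A},{B},{A,B}: algebraic fixed point theta=(2/3, 1/3) and
        the ambiguous read's posterior z=(2/3, 1/3)."""
        m = matrix_from_memberships([["A"], ["A"], ["B"], ["A", "B"]])
        state = em_iterate(m, tol=1e-12, max_iter=10_000)
        np.testing.assert_allclose(state.theta, [2 / 3, 1 / 3], atol=1e-6)
        np.testing.assert_allclose(state.z[3], [2 / 3, 1 / 3], atol=1e-6)

    def test_matches_reference_implementation(self):
        m = matrix_from_memberships(
            [["A"], ["A", "B"], ["B", "C"], ["C"], ["A", "C"]]
        )
        state = em_iterate(m)
        np.testing.assert_allclose(
            state.theta, reference_em(m.x.astype(float)), atol=1e-8
        )

    def test_row_of_zeros_rejected(self):
        m = matrix_from_memberships([["A"]])
        m.x[0, 0] = False
        with pytest.raises(ValueError, match="no valid species"):
            em_iterate(m)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.sets(st.sampled_from("ABCDEF"), min_size=1, max_size=6),
        min_size=1, max_size=30,
    ))
    def test_theta_is_fixed_point_and_normalized(self, memberships):
        m = matrix_from_memberships([sorted(s) for s in memberships])
        state = em_iterate(m, tol=1e-7, max_iter=10_000)
        assert state.converged
        assert state.theta.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(state.z.sum(axis=1), 1.0, atol=1e-9)
        # one more E+M step moves theta by less than the tolerance
        x = m.x.astype(float)
        z = x * state.theta
        z /= z.sum(axis=1, keepdims=True)
        refreshed = z.sum(axis=0) / m.n
        assert np.abs(refreshed - state.theta).sum() < 1e-5

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.sets(st.sampled_from("ABCD"), min_size=1, max_size=4),
        min_size=1, max_size=20,
    ))
    def test_log_likelihood_nondecreasing(self, memberships):
        m = matrix_from_memberships([sorted(s) for s in memberships])
        x = m.x.astype(float)
        theta = np.full(m.k, 1 / m.k)
        prev = observed_log_likelihood(x, theta)
        for _ in range(30):
            z = x * theta
            z /= z.sum(axis=1, keepdims=True)
            theta = z.sum(axis=0) / m.n
            cur = observed_log_likelihood(x, theta)
            assert cur >= prev - 1e-9
            prev = cur

    def test_uniquely_mapped_reads_never_reassigned(self):
        m = matrix_from_memberships([["A"], ["B", "A"], ["B"], ["B"]])
        state = em_iterate(m)
        assign = hard_assign(state, m)
        assert assign["r0"] == "A"
        assert assign["r2"] == assign["r3"] == "B"


class TestHardAssign:
    def test_ambiguous_read_goes_to_heavier_species(self):
        m = matrix_from_memberships([["A"], ["A"], ["B"], ["A", "B"]])
        state = em_iterate(m)
        assert hard_assign(state, m)["r3"] == "A"

    def test_tie_prefers_well_defined_species(self):
        alignments = [
            aln("r1", "Escherichia coli", AS=100, MS=100, ID=0.99),
            aln("r1", "Escherichia sp.", AS=100, MS=100, ID=0.99),
        ]
        m = build_read_species_matrix(alignments)
        state = em_iterate(m)
        lineages = {
            "Escherichia coli": TaxLineage.from_species("Escherichia coli"),
            "Escherichia sp.": TaxLineage.from_species("Escherichia sp."),
        }
        assert hard_assign(state, m, lineages)["r1"] == "Escherichia coli"

    def test_tie_falls_back_to_scores(self):
        alignments = [
            aln("r1", "Aa bb", AS=100, MS=100, ID=0.990),
            aln("r1", "Cc dd", AS=100, MS=100, ID=0.991),
        ]
        m = build_read_species_matrix(alignments)
        state = em_iterate(m)
        assert hard_assign(state, m)["r1"] == "Cc dd"


class TestAggregate:
    def lineages(self, *species):
        return {sp: TaxLineage.from_species(sp) for sp in species}

    def test_single_species(self):
        prof = aggregate_profile({"r1": "Aa bb"}, 2.0, self.lineages("Aa bb"))
        assert prof.total_copies == pytest.approx(2.0)
        assert prof.rel_abundances() == [1.0]

    def test_read_count_apportioning(self):
        assignments = {f"r{i}": ("Aa bb" if i < 6 else "Cc dd")
                       for i in range(8)}
        prof = aggregate_profile(assignments, 1.0,
                                 self.lineages("Aa bb", "Cc dd"))
        copies = prof.copies_by_species()
        assert copies["Aa bb"] == pytest.approx(0.75)
        assert copies["Cc dd"] == pytest.approx(0.25)
        assert prof.rel_abundances() == pytest.approx([0.75, 0.25])

    def test_no_reads_empty_profile(self):
        prof = aggregate_profile({}, 0.0, {})
        assert prof.entries == [] and prof.total_copies == 0

    def test_unclassified_reads_share_copies(self):
        prof = aggregate_profile({"r1": "Aa bb"}, 1.0,
                                 self.lineages("Aa bb"),
                                 n_unclassified_reads=1)
        assert prof.classified_copies == pytest.approx(0.5)
        assert prof.total_copies == pytest.approx(1.0)

    def test_missing_lineage_raises(self):
        with pytest.raises(KeyError):
            aggregate_profile({"r1": "Aa bb"}, 1.0, {})
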