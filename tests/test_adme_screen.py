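"""Tanimoto drug-likeness, OB/DL screening, and deglycosylation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from herbnetpharm import ScreenConfig, apply_ob_dl_filter, compute_dl, deglycosylate
from herbnetpharm.adme_screen import (
    descriptor_drug_likeness,
    reference_centroid,
    reference_scale,
)
from herbnetpharm.core_model_io import CompoundRecord

RESCUE_4 = frozenset({"DS15", "DS19", "DS21", "DS32"})


class TestTanimoto:
    def test_identity(self):
        assert compute_dl((3, 4), (3, 4)) == 1.0

    def test_orthogonal(self):
        assert compute_dl((1, 0), (0, 1)) == 0.0

    def test_hand_arithmetic(self):
        # A.B = 6, |A|^2 = 5, |B|^2 = 8 -> 6 / 7
        assert compute_dl((1, 2), (2, 2)) == pytest.approx(6 / 7, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            compute_dl((1, 2), (1, 2, 3))

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            compute_dl((0, 0), (0, 0))

    # components either zero or well away from the underflow regime
    _component = st.one_of(st.just(0.0), st.floats(0.01, 100))

    @settings(derandomize=True, max_examples=200)
    @given(
        hnp.arrays(np.float64, 5, elements=_component),
        hnp.arrays(np.float64, 5, elements=_component),
    )
    def test_symmetry_and_bounds(self, a, b):
        if not a.any() and not b.any():
            return
        f = compute_dl(a, b)
        assert f == pytest.approx(compute_dl(b, a), abs=1e-12)
        assert -1e-12 <= f <= 1 + 1e-12
        if a.any():
            assert compute_dl(a, a) == pytest.approx(1.0, abs=1e-12)


class TestReferenceCentroid:
    def test_mean_of_two_points(self):
        assert np.allclose(reference_centroid([(0, 0), (2, 2)]), (1, 1))

    def test_single_vector(self):
        assert np.allclose(reference_centroid([(3, 1, 4)]), (3, 1, 4))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            reference_centroid([])

    def test_clt_bound(self):
        rng = np.random.default_rng(0)
        mu, sigma, n = np.array([5.0, -2.0, 10.0]), 2.0, 1000
        sample = rng.normal(mu, sigma, size=(n, 3))
        c = reference_centroid(list(sample))
        assert np.all(np.abs(c - mu) < 4 * sigma / np.sqrt(n))

    def test_zscaled_dl_insensitive_to_component_units(self):
        rng = np.random.default_rng(1)
        ref = rng.normal([300, 3], [100, 1], size=(200, 2))
        v = np.array([350.0, 2.0])
        base = descriptor_drug_likeness(v, list(ref))
        # rescale one component of vectors and reference identically
        scaled_ref = ref * np.array([10.0, 1.0])
        scaled = descriptor_drug_likeness(v * np.array([10.0, 1.0]),
                                          list(scaled_ref))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestObDlFilter:
    def test_radix_salviae_28_then_32(self, radix_salviae_rows):
        base = apply_ob_dl_filter(radix_salviae_rows, ScreenConfig())
        assert len(base.candidates) == 28
        rescued = apply_ob_dl_filter(
            radix_salviae_rows, ScreenConfig(rescue_ids=RESCUE_4)
        )
        assert len(rescued.candidates) == 32
        assert rescued.n_rescued == 4
        assert {c for c, r in rescued.reasons.items() if r == "rescued"} == set(
            RESCUE_4
        )

    def test_boundary_values_pass(self, compound_factory):
        rec = compound_factory(ob=30.0, dl=0.18)
        res = apply_ob_dl_filter([rec], ScreenConfig())
        assert res.candidates == [rec]
        assert res.reasons[rec.compound_id] == "passed_both"

    def test_reason_codes(self, compound_factory):
        recs = [
            compound_factory("a", ob=10, dl=0.5),
            compound_factory("b", ob=50, dl=0.1),
            compound_factory("c", ob=10, dl=0.1),
        ]
        res = apply_ob_dl_filter(recs, ScreenConfig())
        assert res.reasons == {"a": "failed_ob", "b": "failed_dl",
                               "c": "failed_both"}
        assert res.candidates == []
        assert res.excluded == recs

    def test_partition(self, compounds150):
        res = apply_ob_dl_filter(compounds150, ScreenConfig())
        assert len(res.candidates) + len(res.excluded) == 150
        assert len(res.reasons) == 150

    def test_full_table_with_fixture_rescue_gives_150(self, compounds150):
        rescue = frozenset(c.compound_id for c in compounds150 if c.rescued)
        res = apply_ob_dl_filter(compounds150, ScreenConfig(rescue_ids=rescue))
        assert len(res.candidates) == 150

    def test_idempotent(self, compounds150):
        cfg = ScreenConfig(rescue_ids=RESCUE_4)
        first = apply_ob_dl_filter(compounds150, cfg)
        second = apply_ob_dl_filter(first.candidates, cfg)
        assert [c.compound_id for c in second.candidates] == [
            c.compound_id for c in first.candidates
        ]
        assert second.excluded == []

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0, 100), st.floats(0, 1),
        st.floats(0, 100), st.floats(0, 1),
    )
    def test_monotone_in_thresholds(self, compounds150, ob1, dl1, ob2, dl2):
        lo = ScreenConfig(ob_min=min(ob1, ob2), dl_min=min(dl1, dl2))
        hi = ScreenConfig(ob_min=max(ob1, ob2), dl_min=max(dl1, dl2))
        n_lo = len(apply_ob_dl_filter(compounds150, lo).candidates)
        n_hi = len(apply_ob_dl_filter(compounds150, hi).candidates)
        assert n_hi <= n_lo


PHENYL_GLUCOSIDE = "c1ccccc1OC1OC(CO)C(O)C(O)C1O"


class TestDeglycosylate:
    def test_no_sugar_is_identity(self, compound_factory):
        rec = compound_factory(smiles="CC(=O)Oc1ccccc1C(=O)O")
        assert deglycosylate(rec) == [rec]

    def test_no_structure_is_identity(self, compound_factory):
        rec = compound_factory(smiles=None)
        assert deglycosylate(rec) == [rec]

    def test_unparsable_warns_and_passes_through(self, compound_factory):
        rec = compound_factory(smiles="not_a_smiles(((")
        with pytest.warns(UserWarning):
            assert deglycosylate(rec) == [rec]

    def test_aryl_glucoside_yields_qt_phenol(self, compound_factory):
        from rdkit import Chem

        rec = compound_factory(cid="MD02", smiles=PHENYL_GLUCOSIDE)
        (out,) = deglycosylate(rec)
        assert out.compound_id == "MD02_qt"
        assert out.name.endswith("_qt")
        assert out.is_aglycone_derivative
        assert out.descriptors is None
        assert Chem.CanonSmiles(out.smiles) == Chem.CanonSmiles("Oc1ccccc1")

    def test_matches_substructure_deletion_oracle(self, compound_factory):
        from rdkit import Chem

        # independent oracle: delete the glucosyl ring atoms outright,
        # keep the largest surviving fragment
        mol = Chem.MolFromSmiles(PHENYL_GLUCOSIDE)
        sugar = Chem.MolFromSmarts(
            "[CX4]1[OX2][CX4]([CX4][OX2H])[CX4]([OX2H])[CX4]([OX2H])[CX4]1"
        )
        stripped = Chem.DeleteSubstructs(mol, sugar)
        frags = sorted(
            Chem.GetMolFrags(stripped, asMols=True, sanitizeFrags=False),
            key=lambda m: m.GetNumAtoms(),
        )
        oracle = Chem.CanonSmiles(Chem.MolToSmiles(frags[-1]))
        (out,) = deglycosylate(compound_factory(smiles=PHENYL_GLUCOSIDE))
        assert Chem.CanonSmiles(out.smiles) == oracle

    def test_bis_glucoside_unique_aglycone(self, compound_factory):
        from rdkit import Chem

        smi = "OCC1OC(Oc2ccc(OC3OC(CO)C(O)C(O)C3O)cc2)C(O)C(O)C1O"
        out = deglycosylate(compound_factory(smiles=smi))
        assert len(out) == 1  # both cleavages give the same diol
        assert Chem.CanonSmiles(out[0].smiles) == Chem.CanonSmiles(
            "Oc1ccc(O)cc1"
        )
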