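"""Adversarial augmentation: scaffolds, Rogot-Goldberg similarity, edge
gradients, bounded edge selection."""

import numpy as np
import pytest
from rdkit import Chem

from tlinet import FusionParams, smiles_to_graph
from tlinet.augment import (
    AugmentationConfig,
    EdgeCoefficients,
    augment_batch,
    calibrate_mu,
    delete_bond,
    edge_gradients,
    morgan_fp,
    murcko_scaffold,
    rogot_goldberg,
    scaffold_distance,
    scaffold_ref,
    select_and_delete,
)
from tlinet import autodiff as ad
from tlinet.gcn import DESK_CONFIG, GraphBatch
from tlinet.model import ligand_only_logits


class TestMurckoScaffold:
    def test_aspirin_scaffold_is_benzene(self):
        scaffold = murcko_scaffold("CC(=O)Oc1ccccc1C(=O)O")
        assert Chem.MolToSmiles(scaffold) == "c1ccccc1"

    def test_bare_ring_is_its_own_scaffold(self):
        assert Chem.MolToSmiles(murcko_scaffold("c1ccccc1")) == "c1ccccc1"

    def test_acyclic_molecule_has_empty_scaffold(self):
        ref = scaffold_ref("CCO")
        assert ref.empty
        with pytest.raises(ValueError):
            scaffold_distance("CCO", ref)


class TestMorganFingerprint:
    def test_deterministic(self):
        assert np.array_equal(morgan_fp("CCO"), morgan_fp("CCO"))

    def test_distinct_structures_differ(self):
        assert not np.array_equal(morgan_fp("C"), morgan_fp("c1ccccc1"))

    def test_invariant_to_smiles_spelling(self):
        assert np.array_equal(morgan_fp("OCC"), morgan_fp("CCO"))


class TestRogotGoldberg:
    def test_identical_fingerprints_score_one(self):
        fp = morgan_fp("c1ccccc1O")
        assert rogot_goldberg(fp, fp) == 1.0

    def test_hand_computed_eight_bit_example(self):
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[[1, 2]] = 1
        b[[2, 3]] = 1
        # a=1, b=1, c=1, d0=5 -> 1/4 + 5/12
        assert rogot_goldberg(a, b) == pytest.approx(1 / 4 + 5 / 12, abs=1e-4)

    def test_complementary_vectors_score_zero(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        assert rogot_goldberg(a, 1 - a) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rogot_goldberg(np.zeros(4, dtype=np.uint8), np.zeros(8, dtype=np.uint8))

    def test_decreasing_in_symmetric_difference_at_fixed_totals(self):
        base = np.zeros(32, dtype=np.uint8)
        base[:8] = 1
        scores = []
        for flips in (0, 2, 4):
            other = base.copy()
            other[8 : 8 + flips] = 1  # add disagreeing on-bits
            scores.append(rogot_goldberg(base, other))
        assert scores[0] > scores[1] > scores[2]

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            a = (rng.random(64) < 0.3).astype(np.uint8)
            b = (rng.random(64) < 0.3).astype(np.uint8)
            assert 0.0 <= rogot_goldberg(a, b) <= 1.0


class TestScaffoldDistance:
    def test_scaffold_to_itself_is_zero(self):
        ref = scaffold_ref("c1ccccc1")
        assert scaffold_distance("c1ccccc1", ref) == 0.0

    def test_rogot_goldberg_minimizes_mean_scaffold_distance(self, small_benchmark):
        """Among Tanimoto, Dice, Sokal, Russel and Rogot-Goldberg, RGS must
        give the smallest mean molecule-to-own-scaffold distance on a
        50-molecule set."""
        smiles = [s for s, _ in small_benchmark.dataset.records][:50]
        assert len(smiles) >= 40

        def counts(fa, fb):
            fa, fb = fa.astype(bool), fb.astype(bool)
            return (
                int((fa & fb).sum()),
                int((fa & ~fb).sum()),
                int((~fa & fb).sum()),
                int((~fa & ~fb).sum()),
            )

        metrics = {
            "tanimoto": lambda a, b, c, d0: a / (a + b + c) if a + b + c else 1.0,
            "dice": lambda a, b, c, d0: 2 * a / (2 * a + b + c) if 2 * a + b + c else 1.0,
            "sokal": lambda a, b, c, d0: a / (a + 2 * b + 2 * c) if a + 2 * b + 2 * c else 1.0,
            "russel": lambda a, b, c, d0: a / (a + b + c + d0),
        }
        sums = {name: 0.0 for name in metrics} | {"rogot_goldberg": 0.0}
        n = 0
        for s in smiles:
            ref = scaffold_ref(s)
            if ref.empty:
                continue
            fp = morgan_fp(s)
            a, b, c, d0 = counts(ref.fingerprint, fp)
            for name, fn in metrics.items():
                sums[name] += 1.0 - fn(a, b, c, d0)
            sums["rogot_goldberg"] += 1.0 - rogot_goldberg(ref.fingerprint, fp)
            n += 1
        means = {k: v / n for k, v in sums.items()}
        assert means["rogot_goldberg"] == min(means.values())


class TestCalibrateMu:
    def test_self_scaffold_actives_give_zero(self):
        mu, skipped = calibrate_mu(["c1ccccc1", "c1ccc2ccccc2c1"])
        assert mu == 0.0 and skipped == []

    def test_mu_is_the_maximum_distance(self):
        mols = ["c1ccccc1C", "c1ccccc1CCCNC(=O)O"]
        expected = max(scaffold_distance(m, scaffold_ref(m)) for m in mols)
        mu, _ = calibrate_mu(mols)
        assert mu == expected

    def test_adding_a_molecule_cannot_decrease_mu(self):
        base = ["c1ccccc1C", "c1ccccc1CC"]
        mu1, _ = calibrate_mu(base)
        mu2, _ = calibrate_mu(base + ["c1ccccc1CCCNC(=O)O"])
        assert mu2 >= mu1

    def test_acyclic_molecules_are_excluded_and_reported(self):
        mu, skipped = calibrate_mu(["CCO", "c1ccccc1C"])
        assert skipped == ["CCO"]
        with pytest.raises(ValueError):
            calibrate_mu(["CCO", "CCN"])


class TestEdgeGradients:
    def test_zeroed_classifier_gives_zero_gradients(self):
        params = FusionParams(DESK_CONFIG, rng=0)
        params.lm_classifier_w.data[...] = 0.0
        coeffs = edge_gradients(params, smiles_to_graph("CCO"), label=1)
        assert np.allclose(coeffs.gradients, 0.0)

    def test_unit_coefficients_leave_predictions_unchanged(self):
        params = FusionParams(DESK_CONFIG, rng=1)
        batch = GraphBatch.from_graphs([smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O")])
        plain, _ = ligand_only_logits(batch, params)
        ones = ad.parameter(np.ones((batch.edges.shape[0], 1)))
        instrumented, _ = ligand_only_logits(batch, params, edge_coeffs=ones)
        assert np.array_equal(plain.data, instrumented.data)

    def test_symmetric_bonds_get_equal_gradients(self):
        params = FusionParams(DESK_CONFIG, rng=1)
        coeffs = edge_gradients(params, smiles_to_graph("c1ccccc1"), label=1)
        assert coeffs.gradients.shape == (6,)
        assert np.ptp(coeffs.gradients) < 1e-6


def brute_force_selection(smiles, coefficients, ref, mu, config=AugmentationConfig()):
    """Independent oracle: evaluate every single-bond deletion and keep the
    admissible candidate with the most negative gradient (ties by index)."""
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.MolFromSmiles(smiles)))
    best = None
    for b, (i, j) in enumerate(coefficients.bond_atoms):
        g = coefficients.gradients[b]
        if g >= 0:
            continue
        candidate = delete_bond(mol, i, j)
        if candidate is None:
            continue
        if scaffold_distance(candidate, ref, config) > mu:
            continue
        if best is None or g < best[0]:
            best = (g, b, i, j)
    return None if best is None else (best[2], best[3])


class TestSelectAndDelete:
    def test_selection_matches_brute_force_oracle(self, trained_lm):
        params = trained_lm["params"]
        bm = trained_lm["benchmark"]
        actives = [s for s, y in bm.dataset.records if y == 1]
        small = [s for s in actives if smiles_to_graph(s).num_bonds <= 12]
        checked = 0
        for smiles in small or actives[:5]:
            ref = scaffold_ref(smiles)
            if ref.empty:
                continue
            coeffs = edge_gradients(params, smiles_to_graph(smiles), label=1)
            for mu in (0.2, 0.5, 1.0):
                got = select_and_delete(smiles, coeffs, ref, mu)
                expected = brute_force_selection(smiles, coeffs, ref, mu)
                if expected is None:
                    assert got is None
                else:
                    assert got is not None and got.deleted_bond == expected
                checked += 1
        assert checked > 0

    def test_unbounded_mu_with_negative_gradient_removes_one_bond(self):
        smiles = "c1ccccc1CC"
        graph = smiles_to_graph(smiles)
        fake = EdgeCoefficients(
            bond_atoms=[
                (int(graph.directed_edges[2 * b, 0]), int(graph.directed_edges[2 * b, 1]))
                for b in range(graph.num_bonds)
            ],
            gradients=-np.ones(graph.num_bonds),
        )
        result = select_and_delete(smiles, fake, scaffold_ref(smiles), mu=1.0)
        assert result is not None
        before = Chem.MolFromSmiles(result.original_smiles).GetNumBonds()
        after = Chem.MolFromSmiles(result.augmented_smiles).GetNumBonds()
        assert after == before - 1
        assert result.gradient < 0

    def test_all_nonnegative_gradients_skip_the_molecule(self):
        smiles = "c1ccccc1CC"
        graph = smiles_to_graph(smiles)
        fake = EdgeCoefficients(
            bond_atoms=[(0, 1)] * graph.num_bonds,
            gradients=np.abs(np.arange(graph.num_bonds, dtype=float)) + 0.1,
        )
        assert select_and_delete(smiles, fake, scaffold_ref(smiles), mu=1.0) is None

    def test_mu_zero_on_decorated_molecule_skips(self):
        smiles = "c1ccccc1CCNC"
        graph = smiles_to_graph(smiles)
        ref = scaffold_ref(smiles)
        fake = EdgeCoefficients(
            bond_atoms=[
                (int(graph.directed_edges[2 * b, 0]), int(graph.directed_edges[2 * b, 1]))
                for b in range(graph.num_bonds)
            ],
            gradients=-np.ones(graph.num_bonds),
        )
        # verify by brute force that no single deletion reaches distance 0
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.MolFromSmiles(smiles)))
        for i, j in fake.bond_atoms:
            cand = delete_bond(mol, i, j)
            if cand is not None:
                assert scaffold_distance(cand, ref) > 0
        assert select_and_delete(smiles, fake, ref, mu=0.0) is None


class TestAugmentBatch:
    def test_failing_batch_returns_no_augmentations(self):
        params = FusionParams(DESK_CONFIG, rng=0)
        params.lm_classifier_w.data[...] = 0.0  # flat loss: no negative gradients
        assert augment_batch(params, ["c1ccccc1C", "c1ccccc1CC"], mu=1.0) == []

    def test_successful_augmentations_satisfy_every_constraint(self, trained_lm):
        params = trained_lm["params"]
        actives = [s for s, y in trained_lm["benchmark"].dataset.records if y == 1]
        mu, _ = calibrate_mu(actives)
        results = augment_batch(params, actives, mu)
        assert results, "expected at least one successful augmentation"
        for r in results:
            before = Chem.MolFromSmiles(r.original_smiles).GetNumBonds()
            after = Chem.MolFromSmiles(r.augmented_smiles).GetNumBonds()
            assert after == before - 1
            assert r.gradient < 0
            assert r.distance <= mu
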